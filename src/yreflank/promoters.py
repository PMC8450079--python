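"""Response-element scanning and flanking-environment analysis of promoter
libraries.

The questions answered here: which promoters carry exactly one response
element (and nothing else that binds a known factor), what the nucleotides
immediately 5' and 3' of that site are, and whether grouping promoters by a
wider flank context (4 nt per side rather than 2) tightens the spread of their
reporter-expression levels. Coordinates are 0-based and half-open throughout;
minus-strand sites are reported by their forward-strand start.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io_formats import ExpressionProfile, PromoterTable

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: IUPAC degenerate nucleotide codes.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """An exact motif occurrence, located on the forward strand.

    ``start`` is the 0-based forward-strand offset of the site regardless of
    strand; ``matched`` is the forward-strand subsequence at that location.
    """

    promoter_id: str
    motif_name: str
    start: int
    strand: str  # '+' or '-'
    matched: str

    @property
    def length(self) -> int:
        return len(self.matched)

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass(frozen=True)
class FlankContext:
    """The ``width`` nucleotides on each side of a site, in motif orientation:
    ``five_prime`` reads 5'->3' into the motif, ``three_prime`` leaves it."""

    five_prime: str
    three_prime: str

    def __post_init__(self) -> None:
        if len(self.five_prime) != len(self.three_prime):
            raise ValueError("flanks must have equal width")
        for s in (self.five_prime, self.three_prime):
            if not set(s) <= set("ACGT"):
                raise ValueError(f"non-ACGT flank {s!r}")

    @property
    def width(self) -> int:
        return len(self.five_prime)

    @property
    def key(self) -> tuple[str, str]:
        return (self.five_prime, self.three_prime)


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) exact occurrence offsets."""
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def scan_motif(sequence: str, motif: str, *, promoter_id: str = "",
               motif_name: str = "", both_strands: bool = True,
               dedupe_palindrome: bool = True) -> list[MotifHit]:
    """Exact occurrences of ``motif`` in ``sequence``.

    Forward-strand matches are reported with strand '+'. With ``both_strands``,
    occurrences of the motif on the reverse strand are found by searching the
    forward strand for the motif's reverse complement and reported with strand
    '-' at their forward-strand start. For a palindromic motif each site would
    appear once per strand; ``dedupe_palindrome`` keeps only the '+' record.
    A motif longer than the sequence yields an empty list.
    """
    sequence = sequence.upper()
    motif = motif.upper()
    name = motif_name or motif
    hits = [MotifHit(promoter_id, name, s, "+", motif)
            for s in _find_all(sequence, motif)]
    if both_strands:
        rc = reverse_complement(motif)
        is_palindrome = rc == motif
        if not (is_palindrome and dedupe_palindrome):
            hits += [MotifHit(promoter_id, name, s, "-", rc)
                     for s in _find_all(sequence, rc)]
    return sorted(hits, key=lambda h: (h.start, h.strand))


def extract_flanks(sequence: str, hit: MotifHit, width: int) -> FlankContext:
    """Flanking context of a site, always given in motif orientation.

    For a '-' strand hit the flanks are read from the reverse complement, so
    ``five_prime + motif + three_prime`` reconstructs the site neighbourhood on
    the strand the motif matched.
    """
    if hit.start < width or hit.end + width > len(sequence):
        raise ValueError(
            f"insufficient flank: site at [{hit.start}, {hit.end}) in a "
            f"{len(sequence)} nt sequence cannot provide {width} nt per side"
        )
    left = sequence[hit.start - width:hit.start]
    right = sequence[hit.end:hit.end + width]
    if hit.strand == "-":
        left, right = reverse_complement(right), reverse_complement(left)
    return FlankContext(left, right)


def match_environment(context: FlankContext, pattern_5: str,
                      pattern_3: str) -> bool:
    """Position-wise IUPAC match of a flank context against degenerate
    patterns (e.g. the ATR1-like YRGA.../...GCRR environment)."""
    if len(pattern_5) != context.width or len(pattern_3) != context.width:
        raise ValueError("pattern widths must equal the context width")
    return all(
        base in IUPAC[p]
        for base, p in zip(context.five_prime + context.three_prime,
                           pattern_5.upper() + pattern_3.upper())
    )


def filter_single_instance(
    promoters: PromoterTable,
    yre_motifs: dict[str, str],
    exclusion_motifs: dict[str, str] | None = None,
    *,
    flank_width: int = 2,
    both_strands: bool = True,
    dedupe_palindrome: bool = True,
) -> tuple[PromoterTable, dict[str, MotifHit], Counter]:
    """Keep promoters carrying exactly one response element and no excluded
    motif, with room for ``flank_width`` nucleotides on both sides.

    Returns the surviving subset, the single surviving hit per promoter id,
    and a per-reason rejection counter (``multiplicity``, ``none``,
    ``exclusion``, ``insufficient_flank``).
    """
    exclusion_motifs = exclusion_motifs or {}
    if set(yre_motifs) & set(exclusion_motifs):
        raise ValueError("motif sets must be disjoint by name")
    kept, hits_by_id = [], {}
    rejected: Counter = Counter()
    for rec in promoters:
        yre_hits = [
            h
            for name, motif in yre_motifs.items()
            for h in scan_motif(rec.sequence, motif, promoter_id=rec.id,
                                motif_name=name, both_strands=both_strands,
                                dedupe_palindrome=dedupe_palindrome)
        ]
        if not yre_hits:
            rejected["none"] += 1
            continue
        if len(yre_hits) > 1:
            rejected["multiplicity"] += 1
            continue
        excl = any(
            scan_motif(rec.sequence, motif, both_strands=both_strands,
                       dedupe_palindrome=dedupe_palindrome)
            for motif in exclusion_motifs.values()
        )
        if excl:
            rejected["exclusion"] += 1
            continue
        hit = yre_hits[0]
        if hit.start < flank_width or hit.end + flank_width > len(rec.sequence):
            rejected["insufficient_flank"] += 1
            continue
        kept.append(rec)
        hits_by_id[rec.id] = hit
    if rejected:
        log.info("single-instance filter rejections: %s", dict(rejected))
    return (PromoterTable(kept, bin_range=promoters.bin_range),
            hits_by_id, rejected)


@dataclass
class FlankGroup:
    """Promoters sharing one exact flank-context key, with their expression
    statistics (sd is None for singleton groups: undefined)."""

    key: tuple[str, str]
    members: list[str]
    expression: np.ndarray

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def mean(self) -> float | None:
        return float(np.mean(self.expression)) if self.n else None

    @property
    def sd(self) -> float | None:
        if self.n < 2:
            return None
        return float(np.std(self.expression, ddof=1))


def group_by_flanks(promoters: PromoterTable, hits: dict[str, MotifHit],
                    width: int) -> list[FlankGroup]:
    """Partition filtered promoters by their exact flank strings at ``width``
    nucleotides per side; groups are sorted by key."""
    buckets: dict[tuple[str, str], FlankGroup] = {}
    for rec in promoters:
        ctx = extract_flanks(rec.sequence, hits[rec.id], width)
        grp = buckets.get(ctx.key)
        if grp is None:
            grp = buckets[ctx.key] = FlankGroup(ctx.key, [], np.empty(0))
        grp.members.append(rec.id)
        if rec.expression_bin is not None:
            grp.expression = np.append(grp.expression, rec.expression_bin)
    return [buckets[k] for k in sorted(buckets)]


def group_sds(groups: list[FlankGroup]) -> np.ndarray:
    """Standard deviations of expression within each group of size >= 2."""
    return np.array([g.sd for g in groups if g.sd is not None])


def dispersion_test(groups_narrow: list[FlankGroup],
                    groups_wide: list[FlankGroup],
                    *, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t-test comparing within-group expression SDs between two
    grouping widths (classical equal-variance Student test by default;
    ``equal_var=False`` gives Welch).

    Returns ``(t, p)``. Degenerate SD collections with zero pooled variance
    yield ``t = inf`` (sign of the mean difference) and ``p = 0`` when the
    means differ, and ``t = 0, p = 1`` when they are identical.
    """
    sd_narrow, sd_wide = group_sds(groups_narrow), group_sds(groups_wide)
    if len(sd_narrow) < 2 or len(sd_wide) < 2:
        raise ValueError("insufficient groups: need >=2 groups with n>=2 "
                         "on each side")
    if np.var(sd_narrow) == 0 and np.var(sd_wide) == 0:
        diff = float(np.mean(sd_narrow) - np.mean(sd_wide))
        if diff == 0:
            return 0.0, 1.0
        return float(np.sign(diff) * np.inf), 0.0
    t, p = stats.ttest_ind(sd_narrow, sd_wide, equal_var=equal_var)
    return float(t), float(p)


def refinement_map(groups_wide: list[FlankGroup], wide_width: int,
                   narrow_width: int) -> dict[tuple[str, str], tuple[str, str]]:
    """Map each wide-flank group key onto the narrow key it refines (the
    inner ``narrow_width`` nucleotides adjacent to the site)."""
    if narrow_width > wide_width:
        raise ValueError("narrow width must not exceed wide width")
    return {
        g.key: (g.key[0][wide_width - narrow_width:],
                g.key[1][:narrow_width])
        for g in groups_wide
    }


def differential_profile(profile: ExpressionProfile,
                         pseudocount: float = 0.0) -> np.ndarray:
    """Per-timepoint log2(WT / mutant) differential-expression profile."""
    wt = profile.wt + pseudocount
    mut = profile.mutant + pseudocount
    if np.any(wt <= 0) or np.any(mut <= 0):
        raise ValueError("nonpositive expression values; set a pseudocount")
    return np.log2(wt / mut)
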