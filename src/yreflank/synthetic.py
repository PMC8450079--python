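"""Seeded generators for every input class the pipeline consumes, each with a
planted ground truth the downstream analysis should recover.

Three generators mirror the study's three data classes:

* :func:`gen_promoter_library` — random 80-bp promoter libraries with exactly
  one planted response element per promoter, controlled flank composition and
  a flank-determined expression model binned into 18 ordinal levels;
* :func:`gen_helical_series` — paired bound/unbound per-step helical-parameter
  series in which binding displaces the parameter distribution within the
  element and over a configurable number of flanking steps;
* :func:`gen_structure_ensemble` — multi-model coordinate sets of an
  idealized DNA duplex (built by chaining base-pair steps) plus a probe group
  that realises a scheduled on/off pattern of hydrogen-bond, salt-bridge and
  apolar contacts.

Everything is driven by one integer seed; identical seeds give byte-identical
outputs.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _basegeom
from .datasets import YRE_MOTIFS
from .helical import (BDNA_STEP, BaseFrame, StepLabel, StepParameterSeries,
                      chain_frames, label_steps)
from .io_formats import (HELICAL_PARAMETER_NAMES, PromoterRecord,
                         PromoterTable, StructureEnsemble)
from .promoters import reverse_complement, scan_motif

BASES = "ACGT"


def _key_offset(seed: int, key: tuple[str, str]) -> float:
    """Deterministic standard-normal offset for a flank key, independent of
    the order in which keys are encountered."""
    digest = hashlib.sha256(f"{seed}:{key[0]}:{key[1]}".encode()).digest()
    sub = np.random.default_rng(int.from_bytes(digest[:4], "big"))
    return float(sub.standard_normal())


# ---------------------------------------------------------------------------
# Promoter libraries
# ---------------------------------------------------------------------------

@dataclass
class PromoterLibrarySpec:
    """Study conditions for a synthetic promoter library.

    Defaults follow the random-promoter reporter assay the analysis targets:
    80-bp promoters, 18 expression bins, one response element per promoter.
    ``flank_design`` is ``"exhaustive"`` (one group per flank combination at
    ``flank_width``), ``"sampled"`` (random flanks, ``n`` promoters) or
    ``"fixed"`` (every promoter gets ``fixed_flanks``). The expression bin of
    a promoter is its group mean (``bin_center`` plus ``effect_size`` times a
    per-(width-4)-flank-key standard-normal offset) plus Gaussian noise of
    ``noise_sd``, rounded and clamped into the bin range.
    """

    seed: int = 0
    n: int = 256
    length: int = 80
    yre_name: str = "YRE1"
    flank_design: str = "exhaustive"
    flank_width: int = 2
    fixed_flanks: tuple[str, str] | None = None
    n_per_group: int = 1
    exclusion_motifs: dict[str, str] = field(default_factory=dict)
    n_bins: int = 18
    bin_center: float = 8.5
    effect_size: float = 3.0
    noise_sd: float = 1.0
    max_retries: int = 500

    @property
    def motif(self) -> str:
        return YRE_MOTIFS.get(self.yre_name, self.yre_name)


def _random_background(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(BASES), size=n)) if n else ""


def _assemble_promoter(spec: PromoterLibrarySpec, rng: np.random.Generator,
                       flanks: tuple[str, str]) -> tuple[str, int]:
    """A promoter carrying exactly one response element with the prescribed
    immediate flanks, background free of the element and exclusion motifs
    (rejection sampling with bounded retries)."""
    core = flanks[0] + spec.motif + flanks[1]
    n_bg = spec.length - len(core)
    if n_bg < 0:
        raise ValueError("promoter length too short for motif plus flanks")
    for _ in range(spec.max_retries):
        n_left = int(rng.integers(0, n_bg + 1))
        seq = (_random_background(rng, n_left) + core
               + _random_background(rng, n_bg - n_left))
        hits = scan_motif(seq, spec.motif)
        if len(hits) != 1:
            continue
        if any(scan_motif(seq, m) for m in spec.exclusion_motifs.values()):
            continue
        return seq, n_left + len(flanks[0])
    raise RuntimeError(
        f"could not place a unique site in {spec.max_retries} tries; "
        "loosen the exclusion set or lengthen the promoter"
    )


def _flank_iter(spec: PromoterLibrarySpec, rng: np.random.Generator):
    w = spec.flank_width
    if spec.flank_design == "exhaustive":
        combos = ["".join(c) for c in itertools.product(BASES, repeat=w)]
        for f5, f3 in itertools.product(combos, combos):
            for _ in range(spec.n_per_group):
                yield f5, f3
    elif spec.flank_design == "sampled":
        for _ in range(spec.n):
            yield (_random_background(rng, w), _random_background(rng, w))
    elif spec.flank_design == "fixed":
        if spec.fixed_flanks is None:
            raise ValueError("fixed design needs fixed_flanks")
        for _ in range(spec.n):
            yield spec.fixed_flanks
    else:
        raise ValueError(f"unknown flank design {spec.flank_design!r}")


def gen_promoter_library(spec: PromoterLibrarySpec
                         ) -> tuple[PromoterTable, pd.DataFrame]:
    """Generate a promoter library plus its ground-truth table.

    The truth table columns: ``id``, ``site_start`` (forward-strand offset of
    the planted element), ``flank5``/``flank3`` (the designed flanks),
    ``w4_key5``/``w4_key3`` (the realized width-4 context that determines the
    group mean), ``group_mean`` and ``expression_bin``.
    """
    rng = np.random.default_rng(spec.seed)
    records, truth = [], []
    for i, flanks in enumerate(_flank_iter(spec, rng)):
        seq, start = _assemble_promoter(spec, rng, flanks)
        w4_5 = seq[start - 4:start] if start >= 4 else ""
        end = start + len(spec.motif)
        w4_3 = seq[end:end + 4] if end + 4 <= len(seq) else ""
        mean = spec.bin_center + spec.effect_size * _key_offset(
            spec.seed, (w4_5, w4_3))
        raw = mean + rng.normal(0.0, spec.noise_sd)
        bin_ = int(np.clip(round(raw), 0, spec.n_bins - 1))
        pid = f"P{i:05d}"
        records.append(PromoterRecord(pid, seq, bin_))
        truth.append(
            {"id": pid, "site_start": start, "flank5": flanks[0],
             "flank3": flanks[1], "w4_key5": w4_5, "w4_key3": w4_3,
             "group_mean": mean, "expression_bin": bin_}
        )
    table = PromoterTable(records, bin_range=(0, spec.n_bins - 1))
    return table, pd.DataFrame(truth)


# ---------------------------------------------------------------------------
# Helical-parameter series
# ---------------------------------------------------------------------------

@dataclass
class HelicalSeriesSpec:
    """Paired bound/unbound series with a planted alteration.

    The unbound distribution of ``parameter`` at every step is the Gaussian
    mixture ``components`` (weight, mean, sd); per-step overrides go in
    ``step_components``. The bound series draws from the same mixtures but
    displaces the mean by ``displacement`` at every step of the response
    element and at the nearest ``reach_5p``/``reach_3p`` flanking steps. The
    remaining five parameters fluctuate around canonical B-DNA values in both
    series.
    """

    seed: int = 0
    sequence: str = "TATAGTGATTACTAATGGAATGG"
    yre_start: int = 8
    yre_length: int = 7
    n_frames: int = 2000
    parameter: str = "shift"
    components: tuple[tuple[float, float, float], ...] = ((1.0, 0.0, 0.35),)
    step_components: dict[int, tuple[tuple[float, float, float], ...]] = \
        field(default_factory=dict)
    displacement: float = 1.0
    reach_5p: int = 4
    reach_3p: int = 4
    displace_yre: bool = True

    def __post_init__(self) -> None:
        for comps in [self.components, *self.step_components.values()]:
            if not np.isclose(sum(w for w, _, _ in comps), 1.0):
                raise ValueError("mixture weights must sum to 1")


#: B-DNA fluctuation scales for the undisturbed parameters (A / degrees).
_BACKGROUND_SD = {"shift": 0.35, "slide": 0.35, "rise": 0.15,
                  "tilt": 3.0, "roll": 4.0, "twist": 4.0}
_BACKGROUND_MEAN = {"shift": 0.0, "slide": 0.0, "rise": 3.38,
                    "tilt": 0.0, "roll": 0.0, "twist": 34.3}


def _sample_mixture(rng: np.random.Generator, comps, n: int,
                    shift_mean: float = 0.0) -> np.ndarray:
    weights = np.array([w for w, _, _ in comps])
    choice = rng.choice(len(comps), size=n, p=weights)
    means = np.array([m for _, m, _ in comps])[choice] + shift_mean
    sds = np.array([s for _, _, s in comps])[choice]
    return rng.normal(means, sds)


def planted_steps(spec: HelicalSeriesSpec) -> list[tuple[str, int]]:
    """(region, offset) tags of the steps whose distribution is displaced."""
    out = []
    if spec.displace_yre:
        out += [("yre", i) for i in range(spec.yre_length - 1)]
    out += [("flank", -o) for o in range(1, spec.reach_5p + 1)]
    out += [("flank", +o) for o in range(1, spec.reach_3p + 1)]
    return out


def gen_helical_series(spec: HelicalSeriesSpec
                       ) -> tuple[StepParameterSeries, StepParameterSeries,
                                  list[tuple[str, int]]]:
    """Generate (bound, unbound, truth) where truth lists the displaced steps
    as (region, offset) tags."""
    rng = np.random.default_rng(spec.seed)
    labels = label_steps(spec.sequence, spec.yre_start, spec.yre_length)
    truth = set(planted_steps(spec))
    n, n_steps = spec.n_frames, len(labels)
    bound: dict[str, np.ndarray] = {}
    unbound: dict[str, np.ndarray] = {}
    for name in HELICAL_PARAMETER_NAMES:
        if name == spec.parameter:
            ub = np.empty((n, n_steps))
            bd = np.empty((n, n_steps))
            for s, lab in enumerate(labels):
                comps = spec.step_components.get(s, spec.components)
                ub[:, s] = _sample_mixture(rng, comps, n)
                disp = spec.displacement if (lab.region, lab.offset) in truth \
                    else 0.0
                bd[:, s] = _sample_mixture(rng, comps, n, shift_mean=disp)
        else:
            mu, sd = _BACKGROUND_MEAN[name], _BACKGROUND_SD[name]
            ub = rng.normal(mu, sd, size=(n, n_steps))
            bd = rng.normal(mu, sd, size=(n, n_steps))
        unbound[name] = ub
        bound[name] = bd
    return (StepParameterSeries(labels, bound),
            StepParameterSeries(labels, unbound),
            sorted(truth))


# ---------------------------------------------------------------------------
# Structure ensembles with a scheduled probe
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProbeContact:
    """One scheduled contact: a probe atom engages base pair ``bp_index``
    (0-based along the Watson strand) with the given contact type in exactly
    the frames of ``on_frames``."""

    kind: str  # hbond | salt_bridge | apolar
    bp_index: int
    on_frames: frozenset[int]

    def __post_init__(self) -> None:
        if self.kind not in ("hbond", "salt_bridge", "apolar"):
            raise ValueError(f"unknown contact kind {self.kind!r}")


@dataclass
class StructureSpec:
    """An idealized duplex built from per-step parameters, with optional
    per-frame parameter noise and a probe-contact schedule."""

    seed: int = 0
    sequence: str = "GCTTACTAAGC"
    n_frames: int = 1
    step_params: np.ndarray | None = None  # (len-1, 6); default B-DNA
    param_noise_sd: np.ndarray | None = None  # per-parameter sd, 6-vector
    probes: tuple[ProbeContact, ...] = ()


#: Major-groove acceptor used as the hydrogen-bond target of each base.
_HB_TARGET = {"A": "N7", "G": "O6", "T": "O4", "C": "O2"}

#: Pseudo-backbone atoms (local base-pair-frame coordinates, Watson side).
_BACKBONE_LOCAL = {
    "P": np.array([-0.5, 9.0, 2.0]),
    "OP1": np.array([0.3, 9.9, 2.2]),
    "OP2": np.array([-1.4, 9.6, 2.9]),
}

_HBOND_DIST = 2.9
_SALT_DIST = 3.8  # inside the salt-bridge cutoff, outside the h-bond one
_APOLAR_DIST = 4.0
_OFF_DIST = 25.0


def _duplex_atoms(sequence: str) -> list[dict]:
    """Atom table of the idealized duplex in per-bp local coordinates."""
    n = len(sequence)
    atoms = []
    for i, base in enumerate(sequence):
        watson, crick = _basegeom.paired_template(base)
        for name, xyz in {**watson, **_BACKBONE_LOCAL}.items():
            atoms.append({"bp": i, "chain": "A", "resnum": i + 1,
                          "resname": "D" + base, "name": name, "local": xyz})
        flip = _basegeom._FLIP
        for name, xyz in crick.items():
            atoms.append({"bp": i, "chain": "B", "resnum": n - i,
                          "resname": "D" + _basegeom.WATSON_CRICK[base],
                          "name": name, "local": xyz})
        for name, xyz in _BACKBONE_LOCAL.items():
            atoms.append({"bp": i, "chain": "B", "resnum": n - i,
                          "resname": "D" + _basegeom.WATSON_CRICK[base],
                          "name": name, "local": flip @ xyz})
    return atoms


def _probe_atoms(spec: StructureSpec, sequence: str) -> list[dict]:
    atoms = []
    for k, probe in enumerate(spec.probes):
        base = sequence[probe.bp_index]
        if probe.kind == "hbond":
            target, names, dist = _HB_TARGET[base], ("ND", "HD"), _HBOND_DIST
        elif probe.kind == "salt_bridge":
            target, names, dist = "OP1", ("NZ",), _SALT_DIST
        else:
            target = "C7" if base == "T" else "C1'"
            names, dist = ("CP",), _APOLAR_DIST
        for name in names:
            atoms.append({"probe": k, "chain": "P", "resnum": k + 1,
                          "resname": "PRB", "name": name,
                          "target": target, "dist": dist,
                          "bp": probe.bp_index})
    return atoms


def gen_structure_ensemble(spec: StructureSpec
                           ) -> tuple[StructureEnsemble, list[ProbeContact]]:
    """Build a multi-model duplex (plus scheduled probe group) and return it
    with its truth schedule.

    The DNA is constructed by chaining :func:`~yreflank.helical.rebuild_step`
    over the per-step parameters and decorating each base-pair frame with the
    idealized pair template and pseudo-backbone atoms. Probe atoms sit at
    their contact distance from the scheduled target atom in 'on' frames
    (radially outward from the helix axis, hydrogen collinear for bonds) and
    far outside contact range otherwise.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence.upper()
    n_bp = len(seq)
    base_params = (np.tile(BDNA_STEP, (n_bp - 1, 1))
                   if spec.step_params is None
                   else np.atleast_2d(np.asarray(spec.step_params, float)))
    if base_params.shape != (n_bp - 1, 6):
        raise ValueError(f"step_params must have shape ({n_bp - 1}, 6)")
    dna = _duplex_atoms(seq)
    probes = _probe_atoms(spec, seq)
    atoms = dna + probes
    n_atoms = len(atoms)
    coords = np.empty((spec.n_frames, n_atoms, 3))
    for f in range(spec.n_frames):
        params = base_params.copy()
        if spec.param_noise_sd is not None:
            params = params + rng.normal(
                0.0, np.asarray(spec.param_noise_sd, float),
                size=params.shape)
        frames = chain_frames(params)
        world: dict[tuple[int, str, str], np.ndarray] = {}
        for j, atom in enumerate(dna):
            fr: BaseFrame = frames[atom["bp"]]
            pos = fr.axes @ atom["local"] + fr.origin
            coords[f, j] = pos
            world[(atom["bp"], atom["chain"], atom["name"])] = pos
        for j, atom in enumerate(probes, start=len(dna)):
            probe = spec.probes[atom["probe"]]
            fr = frames[probe.bp_index]
            target = world[(probe.bp_index, "A", atom["target"])]
            radial = target - fr.origin
            norm = np.linalg.norm(radial)
            direction = radial / norm if norm > 1e-9 else fr.axes[:, 0]
            on = f in probe.on_frames
            dist = atom["dist"] if on else _OFF_DIST + 5.0 * atom["probe"]
            if atom["name"] == "HD":
                nd_pos = target + direction * (_HBOND_DIST if on else dist)
                coords[f, j] = nd_pos - direction * 1.0
            else:
                coords[f, j] = target + direction * dist
    element = [a["name"][0] if not a["name"][0].isdigit() else a["name"][1]
               for a in atoms]
    ensemble = StructureEnsemble(
        serial=np.arange(1, n_atoms + 1),
        name=np.array([a["name"] for a in atoms]),
        element=np.array(element),
        residue_name=np.array([a["resname"] for a in atoms]),
        residue_number=np.array([a["resnum"] for a in atoms]),
        chain_id=np.array([a["chain"] for a in atoms]),
        coords=coords,
    )
    return ensemble, list(spec.probes)
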