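"""Built-in study fixtures: response elements, the six 23-mer duplexes, and the
system manifest.

The Yap1 response elements (YREs) and the 23-mer oligonucleotides carrying them
in their two native genomic environments (the promoters of the yeast genes ATR1
and OYE2) are the study's printed inputs; they are embedded here so analyses can
be reproduced without network access.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Yap1 response elements. YRE2 is palindromic (its own reverse complement).
YRE_MOTIFS: dict[str, str] = {
    "YRE1": "TTACTAA",
    "YRE2": "TTACGTAA",
    "YRE3": "TGACAAA",
}

#: The six studied 23-mer duplex sequences (Watson strand, 5'->3'), one per
#: response element x genomic environment.
TABLE1_SEQUENCES: dict[str, str] = {
    "YRE1_ATR1": "TATAGTGATTACTAATGGAATGG",
    "YRE1_OYE2": "GTTTTGCTTTACTAAGCACACGA",
    "YRE2_ATR1": "GCCACAGATTACGTAAGCGATTT",
    "YRE2_OYE2": "GAAATATCTTACGTAATGAACTT",
    "YRE3_ATR1": "TGATTATATGACAAAGTTGAGGG",
    "YRE3_OYE2": "GCTAGCGATGACAAAATGTCTCC",
}

#: Width-4 IUPAC flank patterns of the two environments around YRE2, used by the
#: promoter-library environment matcher.
YRE2_FLANK_PATTERNS: dict[str, tuple[str, str]] = {
    "ATR1": ("YRGA", "GCRR"),
    "OYE2": ("YRTC", "TGRR"),
}


@dataclass(frozen=True)
class SystemRecord:
    """One simulated system: a duplex either bound by the Yap1 dimer or free."""

    name: str
    yre: str
    environment: str
    sequence: str
    bound: bool


def system_manifest() -> list[SystemRecord]:
    """Enumerate the study's systems.

    Each of the six response-element/environment duplexes is simulated both as
    the Yap1-bound complex and as naked B-DNA, giving 12 systems in total.
    """
    records = []
    for name, seq in TABLE1_SEQUENCES.items():
        yre, env = name.split("_")
        for bound in (True, False):
            suffix = "bound" if bound else "free"
            records.append(SystemRecord(f"{name}_{suffix}", yre, env, seq, bound))
    return records
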