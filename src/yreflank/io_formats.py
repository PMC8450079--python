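"""Readers and writers for the external representations the pipeline touches.

Formats handled
---------------
* multi-MODEL PDB coordinate files (protein-DNA complexes, naked DNA) via
  :class:`StructureEnsemble`
* Canal-style whitespace-separated per-step helical-parameter series (``.ser``)
  via :class:`SeriesTable`
* TSV promoter libraries with optional expression bins via :class:`PromoterTable`
* FASTA sequence files
* TSV wild-type/mutant expression-profile tables via :class:`ExpressionProfile`

All read/write pairs round-trip losslessly up to documented numeric precision
(PDB coordinates are written at the format's 1e-3 Angstrom precision).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from biotite.structure import AtomArray, AtomArrayStack
from biotite.structure.io.pdb import PDBFile

log = logging.getLogger(__name__)

HELICAL_PARAMETER_NAMES = ("shift", "slide", "rise", "tilt", "roll", "twist")

DNA_RESIDUES = {"DA", "DC", "DG", "DT"}


class FormatError(ValueError):
    """A file violated the expected external format."""


# ---------------------------------------------------------------------------
# Structure ensembles
# ---------------------------------------------------------------------------

@dataclass
class StructureEnsemble:
    """An ordered set of models (frames) of one protein-DNA complex or duplex.

    Every frame shares one atom table: ``serial``, ``name``, ``element``,
    ``residue_name``, ``residue_number``, ``chain_id`` (arrays of length
    n_atoms), with coordinates of shape ``(n_frames, n_atoms, 3)`` in Angstrom.
    The atom ordering of frame 0 is canonical for the whole ensemble.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    residue_name: np.ndarray
    residue_number: np.ndarray
    chain_id: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        n_atoms = self.coords.shape[1]
        for attr in ("serial", "name", "element", "residue_name",
                     "residue_number", "chain_id"):
            arr = np.asarray(getattr(self, attr))
            if arr.shape != (n_atoms,):
                raise ValueError(f"{attr} must have length {n_atoms}")
            setattr(self, attr, arr)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, index: int) -> np.ndarray:
        """Coordinates of one frame, shape (n_atoms, 3)."""
        return self.coords[index]

    def slice_frames(self, start: int = 0, stop: int | None = None) -> "StructureEnsemble":
        """Sub-ensemble over a frame range (e.g. to discard equilibration)."""
        return StructureEnsemble(
            self.serial, self.name, self.element, self.residue_name,
            self.residue_number, self.chain_id, self.coords[start:stop],
        )

    def atom_mask(self, *, chain: str | None = None, heavy_only: bool = False,
                  dna_only: bool = False) -> np.ndarray:
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain is not None:
            mask &= self.chain_id == chain
        if heavy_only:
            mask &= self.element != "H"
        if dna_only:
            mask &= np.isin(_normalize_resnames(self.residue_name),
                            sorted(DNA_RESIDUES))
        return mask


def _normalize_resnames(names: np.ndarray) -> np.ndarray:
    """Map terminal-residue variants (DA5, DT3) onto the plain residue names."""
    out = []
    for n in names:
        if n.startswith("D") and len(n) == 3 and n[2] in "35":
            out.append(n[:2])
        else:
            out.append(n)
    return np.array(out)


def _stack_from_ensemble(ens: StructureEnsemble) -> AtomArrayStack:
    stack = AtomArrayStack(ens.n_frames, ens.n_atoms)
    stack.coord[:] = ens.coords
    stack.set_annotation("atom_id", ens.serial.astype(int))
    stack.set_annotation("atom_name", ens.name.astype("U6"))
    stack.set_annotation("element", ens.element.astype("U2"))
    stack.set_annotation("res_name", ens.residue_name.astype("U5"))
    stack.set_annotation("res_id", ens.residue_number.astype(int))
    stack.set_annotation("chain_id", ens.chain_id.astype("U4"))
    stack.set_annotation("hetero", np.zeros(ens.n_atoms, dtype=bool))
    return stack


def _ensemble_from_models(models: list[AtomArray], path: Path) -> StructureEnsemble:
    first = models[0]
    key0 = list(zip(first.chain_id, first.res_id, first.atom_name))
    for i, model in enumerate(models[1:], start=2):
        key = list(zip(model.chain_id, model.res_id, model.atom_name))
        if key != key0:
            raise FormatError(
                f"{path}: model {i} has inconsistent atom ordering or count "
                f"({len(key)} atoms vs {len(key0)} in model 1)"
            )
    coords = np.stack([m.coord for m in models])
    return StructureEnsemble(
        serial=np.arange(1, first.array_length() + 1),
        name=np.asarray(first.atom_name),
        element=np.asarray(first.element),
        residue_name=np.asarray(first.res_name),
        residue_number=np.asarray(first.res_id),
        chain_id=np.asarray(first.chain_id),
        coords=coords,
    )


def read_structure_ensemble(path: str | Path, *, drop_hydrogens: bool = False
                            ) -> StructureEnsemble:
    """Read a (possibly multi-MODEL) PDB file into a :class:`StructureEnsemble`.

    MODEL/ENDMDL records are honoured; a file without them is a single-frame
    ensemble. Alternate locations are resolved by taking the first altloc;
    hydrogens are kept unless ``drop_hydrogens`` (contact detection uses them
    when present). An inconsistent atom ordering across models is a hard error
    naming the first offending model.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        pdb = PDBFile.read(path)
        n_models = pdb.get_model_count()
        models = [pdb.get_structure(model=i, altloc="first")
                  for i in range(1, n_models + 1)]
    except FormatError:
        raise
    except Exception as exc:  # biotite reports the offending line
        raise FormatError(f"{path}: unparseable PDB content: {exc}") from exc
    ens = _ensemble_from_models(models, path)
    if drop_hydrogens:
        keep = ens.element != "H"
        ens = StructureEnsemble(
            ens.serial[keep], ens.name[keep], ens.element[keep],
            ens.residue_name[keep], ens.residue_number[keep],
            ens.chain_id[keep], ens.coords[:, keep],
        )
    return ens


def write_structure_ensemble(ensemble: StructureEnsemble, path: str | Path) -> None:
    """Write a multi-MODEL PDB file (coordinates at 1e-3 Angstrom precision)."""
    pdb = PDBFile()
    pdb.set_structure(_stack_from_ensemble(ensemble))
    pdb.write(Path(path))


# ---------------------------------------------------------------------------
# Helical-parameter series tables
# ---------------------------------------------------------------------------

@dataclass
class SeriesTable:
    """Per-frame x per-step values of one helical parameter.

    ``values`` has shape (frames, steps); absent measurements are NaN and are
    excluded from downstream histograms.
    """

    values: np.ndarray
    parameter_name: str
    frame_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.parameter_name not in HELICAL_PARAMETER_NAMES:
            raise ValueError(
                f"parameter_name must be one of {HELICAL_PARAMETER_NAMES}, "
                f"got {self.parameter_name!r}"
            )
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a frames x steps matrix")
        if self.frame_index is None:
            self.frame_index = np.arange(self.values.shape[0])

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


def read_series(path: str | Path, parameter_name: str) -> SeriesTable:
    """Read a Canal-style ``.ser`` table: first column frame index, one further
    column per base-pair step. Any non-numeric token marks an absent cell."""
    path = Path(path)
    rows: list[list[float]] = []
    frames: list[float] = []
    width: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if width is None:
                width = len(tokens)
                if width < 2:
                    raise FormatError(f"{path}:{lineno}: need a frame index "
                                      "and at least one step column")
            elif len(tokens) != width:
                raise FormatError(
                    f"{path}:{lineno}: ragged row ({len(tokens)} columns, "
                    f"expected {width})"
                )
            parsed = [_float_or_nan(t) for t in tokens]
            if np.isnan(parsed[0]):
                raise FormatError(f"{path}:{lineno}: non-numeric frame index")
            frames.append(parsed[0])
            rows.append(parsed[1:])
    if not rows:
        raise FormatError(f"{path}: no frames")
    return SeriesTable(np.array(rows), parameter_name,
                       frame_index=np.array(frames))


def _float_or_nan(token: str) -> float:
    try:
        return float(token)
    except ValueError:
        return float("nan")


def write_series(table: SeriesTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for idx, row in zip(table.frame_index, table.values):
            cells = " ".join("NA" if np.isnan(v) else f"{v:.6f}" for v in row)
            fh.write(f"{idx:g} {cells}\n")


# ---------------------------------------------------------------------------
# Promoter tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterRecord:
    id: str
    sequence: str
    expression_bin: int | None = None


@dataclass
class PromoterTable:
    """A promoter library: unique ids, A/C/G/T sequences, optional integer
    expression bins within ``bin_range`` (inclusive)."""

    records: list[PromoterRecord]
    bin_range: tuple[int, int] = (0, 17)

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate promoter ids: {dupes[:5]}")
        lo, hi = self.bin_range
        for r in self.records:
            if not r.sequence:
                raise ValueError(f"promoter {r.id}: empty sequence")
            if r.expression_bin is not None and not lo <= r.expression_bin <= hi:
                raise ValueError(
                    f"promoter {r.id}: expression bin {r.expression_bin} "
                    f"outside [{lo}, {hi}]"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [r.id for r in self.records],
                "sequence": [r.sequence for r in self.records],
                "expression_bin": [r.expression_bin for r in self.records],
            }
        )


_VALID_BASES = frozenset("ACGT")


def _validate_sequences(ids: list[str], seqs: list[str], *,
                        on_invalid: str) -> list[bool]:
    keep = [True] * len(seqs)
    bad = [i for i, s in enumerate(seqs) if not set(s) <= _VALID_BASES]
    if bad:
        bad_ids = [ids[i] for i in bad]
        if on_invalid == "error":
            raise FormatError(
                f"non-ACGT characters in sequences of: {bad_ids[:10]}"
                + (" ..." if len(bad_ids) > 10 else "")
            )
        log.warning("skipping %d sequences with non-ACGT characters: %s",
                    len(bad_ids), bad_ids[:10])
        for i in bad:
            keep[i] = False
    return keep


def read_promoters(path: str | Path, *, bin_range: tuple[int, int] = (0, 17),
                   on_invalid: str = "error") -> PromoterTable:
    """Read a TSV promoter table with columns id/sequence[/expression_bin].

    Sequences are upper-cased; U is rejected (DNA only). ``on_invalid`` is
    ``"error"`` (default) or ``"skip"`` (drop offending rows with a warning).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "sequence": str})
    required = {"id", "sequence"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    ids = df["id"].tolist()
    seqs = [s.upper() for s in df["sequence"]]
    keep = _validate_sequences(ids, seqs, on_invalid=on_invalid)
    has_bins = "expression_bin" in df.columns
    records = []
    for i, (pid, seq) in enumerate(zip(ids, seqs)):
        if not keep[i]:
            continue
        bin_val = None
        if has_bins and pd.notna(df["expression_bin"].iloc[i]):
            bin_val = int(df["expression_bin"].iloc[i])
        records.append(PromoterRecord(pid, seq, bin_val))
    return PromoterTable(records, bin_range=bin_range)


def write_promoters(table: PromoterTable, path: str | Path) -> None:
    df = table.to_frame()
    df["expression_bin"] = df["expression_bin"].astype("Int64")
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, *, on_invalid: str = "error") -> dict[str, str]:
    """Read a DNA FASTA file into an ordered id -> sequence map (upper-cased)."""
    path = Path(path)
    seqs: dict[str, list[str]] = {}
    current: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                current = line[1:].split()[0]
                if current in seqs:
                    raise FormatError(f"{path}:{lineno}: duplicate id {current!r}")
                seqs[current] = []
            else:
                if current is None:
                    raise FormatError(f"{path}:{lineno}: sequence before header")
                seqs[current].append(line.upper())
    joined = {k: "".join(v) for k, v in seqs.items()}
    ids = list(joined)
    keep = _validate_sequences(ids, list(joined.values()), on_invalid=on_invalid)
    return {k: v for (k, v), ok in zip(joined.items(), keep) if ok}


def write_fasta(sequences: dict[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression profiles
# ---------------------------------------------------------------------------

@dataclass
class ExpressionProfile:
    """Wild-type vs mutant expression of one gene over ordered timepoints."""

    gene: str
    timepoints: list[str]
    wt: np.ndarray
    mutant: np.ndarray

    def __post_init__(self) -> None:
        self.wt = np.asarray(self.wt, dtype=float)
        self.mutant = np.asarray(self.mutant, dtype=float)
        n = len(self.timepoints)
        if self.wt.shape != (n,) or self.mutant.shape != (n,):
            raise ValueError("wt and mutant must match the timepoint labels")


def read_expression_profile(path: str | Path, gene: str | None = None
                            ) -> ExpressionProfile:
    """Read a TSV with columns gene/timepoint/wt/mutant (one gene per call)."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "timepoint", "wt", "mutant"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing columns {required - set(df.columns)}")
    if gene is not None:
        df = df[df["gene"] == gene]
        if df.empty:
            raise FormatError(f"{path}: no rows for gene {gene!r}")
    genes = df["gene"].unique()
    if len(genes) != 1:
        raise FormatError(f"{path}: expected one gene, found {list(genes)}")
    return ExpressionProfile(
        gene=str(genes[0]),
        timepoints=[str(t) for t in df["timepoint"]],
        wt=df["wt"].to_numpy(float),
        mutant=df["mutant"].to_numpy(float),
    )


def write_expression_profile(profile: ExpressionProfile, path: str | Path) -> None:
    pd.DataFrame(
        {
            "gene": profile.gene,
            "timepoint": profile.timepoints,
            "wt": profile.wt,
            "mutant": profile.mutant,
        }
    ).to_csv(path, sep="\t", index=False)
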