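"""Geometric detection and strength scoring of protein-DNA contacts.

Three contact types are detected between the protein and the DNA of a
structural ensemble:

* hydrogen bonds — donor-acceptor heavy-atom distance within a cutoff
  (default 3.5 A) and, when the donor hydrogen is present, a D-H...A angle of
  at least 120 degrees; without hydrogens detection falls back to the
  distance-only criterion (logged);
* salt bridges — a cationic heavy atom (e.g. an arginine guanidinium
  nitrogen) within 4.0 A of an anionic one (e.g. a phosphate oxygen);
* apolar contacts — two apolar carbons/sulfurs within 4.5 A.

A contact is *specific* when it joins a protein side-chain atom to a DNA base
atom (direct readout); everything touching the backbones is nonspecific. The
contact strength of a residue pair in one frame is the plain count of its
contacts, every bond type weighted 1. Per-residue contact fingerprints over
frames feed a deterministic substate clustering.

All cutoffs are inclusive at the boundary and exposed as arguments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .io_formats import DNA_RESIDUES, StructureEnsemble, _normalize_resnames

log = logging.getLogger(__name__)

ROLES = ("base", "sugar", "phosphate", "protein_backbone", "protein_sidechain")

DEFAULT_HBOND_DISTANCE = 3.5
DEFAULT_HBOND_ANGLE = 120.0
DEFAULT_SALT_BRIDGE_DISTANCE = 4.0
DEFAULT_APOLAR_DISTANCE = 4.5

#: Maximum covalent D-H distance used to find a donor's hydrogens.
_H_COVALENT = 1.25


@dataclass(frozen=True)
class AtomRole:
    role: str
    donor: bool
    acceptor: bool
    charge: str  # cationic | anionic | neutral
    apolar: bool


class RoleTable:
    """Lookup of (residue_name, atom_name) -> :class:`AtomRole`.

    Ships with entries for the 20 amino acids, the four deoxynucleotides and
    the synthetic probe group; extensible by merging user TSVs of the same
    layout. Unknown heavy atoms are collected and reported, never silently
    dropped; hydrogens resolve to their residue's region with no flags.
    """

    def __init__(self, entries: dict[tuple[str, str], AtomRole]):
        self._entries = dict(entries)
        self.unknown: list[tuple[str, str]] = []

    @classmethod
    def from_tsv(cls, path: str | Path) -> "RoleTable":
        table = cls({})
        table.merge_tsv(path)
        return table

    @classmethod
    def default(cls) -> "RoleTable":
        with resources.as_file(
            resources.files("yreflank.data") / "atom_roles.tsv"
        ) as path:
            return cls.from_tsv(path)

    def merge_tsv(self, path: str | Path) -> None:
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples(index=False):
            if row.role not in ROLES:
                raise ValueError(f"unknown role {row.role!r} in {path}")
            self._entries[(row.residue_name, row.atom_name)] = AtomRole(
                row.role, bool(row.donor), bool(row.acceptor),
                str(row.charge), bool(row.apolar),
            )

    def resolve(self, residue_name: str, atom_name: str,
                element: str) -> AtomRole | None:
        """Role of one atom; None (and a report entry) for unknown heavy
        atoms."""
        entry = self._entries.get((residue_name, atom_name))
        if entry is not None:
            return entry
        if element == "H":
            if residue_name in DNA_RESIDUES:
                region = "sugar" if "'" in atom_name else "base"
            else:
                region = ("protein_backbone"
                          if atom_name in ("H", "H1", "H2", "H3", "HA")
                          else "protein_sidechain")
            return AtomRole(region, False, False, "neutral", False)
        self.unknown.append((residue_name, atom_name))
        return None


@dataclass(frozen=True)
class ResidueKey:
    chain: str
    number: int
    name: str

    def __str__(self) -> str:
        return f"{self.chain}:{self.name}{self.number}"


@dataclass(frozen=True)
class ContactRecord:
    """One detected protein-DNA contact in one frame."""

    frame: int
    protein: ResidueKey
    dna: ResidueKey
    type: str  # hbond | salt_bridge | apolar
    specific: bool
    protein_atom: str
    dna_atom: str

    @property
    def pair(self) -> tuple[ResidueKey, ResidueKey]:
        return (self.protein, self.dna)


@dataclass
class AtomAnnotation:
    """Per-atom annotations of an ensemble, resolved once and reused for every
    frame (the atom table is frame-invariant)."""

    is_protein: np.ndarray
    is_dna: np.ndarray
    roles: list[AtomRole | None]
    residue_keys: list[ResidueKey]

    @classmethod
    def annotate(cls, ensemble: StructureEnsemble,
                 role_table: RoleTable) -> "AtomAnnotation":
        resnames = _normalize_resnames(ensemble.residue_name)
        is_dna = np.isin(resnames, sorted(DNA_RESIDUES))
        roles, keys = [], []
        for i in range(ensemble.n_atoms):
            roles.append(role_table.resolve(resnames[i], ensemble.name[i],
                                            ensemble.element[i]))
            keys.append(ResidueKey(str(ensemble.chain_id[i]),
                                   int(ensemble.residue_number[i]),
                                   str(resnames[i])))
        is_protein = np.array(
            [not d and r is not None and r.role.startswith("protein")
             for d, r in zip(is_dna, roles)]
        )
        if role_table.unknown:
            log.warning("unresolved heavy atoms (excluded from detection): %s",
                        sorted(set(role_table.unknown)))
        return cls(is_protein, is_dna, roles, keys)


def _record(frame: int, ann: AtomAnnotation, i_prot: int, i_dna: int,
            ctype: str, ensemble: StructureEnsemble) -> ContactRecord:
    role_p = ann.roles[i_prot]
    role_d = ann.roles[i_dna]
    specific = (role_p.role == "protein_sidechain" and role_d.role == "base")
    return ContactRecord(
        frame, ann.residue_keys[i_prot], ann.residue_keys[i_dna], ctype,
        specific, str(ensemble.name[i_prot]), str(ensemble.name[i_dna]),
    )


def _cross_pairs(coords: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray,
                 d_max: float) -> list[tuple[int, int]]:
    """Index pairs (a, b) with distance <= d_max (inclusive), via KD-trees."""
    if len(idx_a) == 0 or len(idx_b) == 0:
        return []
    tree_a = cKDTree(coords[idx_a])
    tree_b = cKDTree(coords[idx_b])
    # tiny epsilon keeps the boundary inclusive despite round-off
    pairs = tree_a.query_ball_tree(tree_b, d_max * (1 + 1e-12))
    out = []
    for ia, neighbours in enumerate(pairs):
        for ib in neighbours:
            if np.linalg.norm(coords[idx_a[ia]] - coords[idx_b[ib]]) <= d_max:
                out.append((int(idx_a[ia]), int(idx_b[ib])))
    return out


def _donor_hydrogens(ensemble: StructureEnsemble, frame: int,
                     donor_idx: int) -> np.ndarray:
    """Indices of hydrogens covalently attached to a donor (same residue,
    within bonding distance)."""
    coords = ensemble.frame(frame)
    same_res = (
        (ensemble.chain_id == ensemble.chain_id[donor_idx])
        & (ensemble.residue_number == ensemble.residue_number[donor_idx])
        & (ensemble.element == "H")
    )
    cand = np.flatnonzero(same_res)
    if cand.size == 0:
        return cand
    d = np.linalg.norm(coords[cand] - coords[donor_idx], axis=1)
    return cand[d <= _H_COVALENT]


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Angle a-b-c in degrees."""
    v1, v2 = a - b, c - b
    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def detect_hbonds(ensemble: StructureEnsemble, frame: int,
                  annotation: AtomAnnotation,
                  d_max: float = DEFAULT_HBOND_DISTANCE,
                  angle_min: float = DEFAULT_HBOND_ANGLE) -> list[ContactRecord]:
    """Protein-DNA hydrogen bonds in one frame, both donor directions.

    The donor-acceptor distance criterion is inclusive at ``d_max``. When the
    donor carries at least one hydrogen, the bond additionally requires some
    D-H...A angle >= ``angle_min``; donors without hydrogens are accepted on
    distance alone (logged once per call).
    """
    coords = ensemble.frame(frame)
    records = []
    distance_only = False
    for prot_is_donor in (True, False):
        side_a = annotation.is_protein if prot_is_donor else annotation.is_dna
        side_b = annotation.is_dna if prot_is_donor else annotation.is_protein
        donors = np.flatnonzero(
            side_a & np.array([r is not None and r.donor
                               for r in annotation.roles]))
        acceptors = np.flatnonzero(
            side_b & np.array([r is not None and r.acceptor
                               for r in annotation.roles]))
        for i_d, i_a in _cross_pairs(coords, donors, acceptors, d_max):
            hydrogens = _donor_hydrogens(ensemble, frame, i_d)
            if hydrogens.size:
                ok = any(_angle(coords[i_d], coords[h], coords[i_a])
                         >= angle_min for h in hydrogens)
            else:
                ok, distance_only = True, True
            if ok:
                i_p, i_n = (i_d, i_a) if prot_is_donor else (i_a, i_d)
                records.append(_record(frame, annotation, i_p, i_n,
                                       "hbond", ensemble))
    if distance_only:
        log.debug("frame %d: donor(s) without hydrogens, distance-only "
                  "criterion applied", frame)
    return records


def detect_salt_bridges(ensemble: StructureEnsemble, frame: int,
                        annotation: AtomAnnotation,
                        d_max: float = DEFAULT_SALT_BRIDGE_DISTANCE
                        ) -> list[ContactRecord]:
    """Cationic protein heavy atoms within ``d_max`` (inclusive) of anionic
    DNA heavy atoms (and vice versa), e.g. Arg/Lys nitrogens to phosphate
    oxygens."""
    coords = ensemble.frame(frame)
    records = []
    charges = [r.charge if r is not None else "neutral"
               for r in annotation.roles]
    heavy = ensemble.element != "H"
    for prot_charge, dna_charge in (("cationic", "anionic"),
                                    ("anionic", "cationic")):
        prot = np.flatnonzero(annotation.is_protein & heavy
                              & np.array([c == prot_charge for c in charges]))
        dna = np.flatnonzero(annotation.is_dna & heavy
                             & np.array([c == dna_charge for c in charges]))
        records += [_record(frame, annotation, i_p, i_n, "salt_bridge", ensemble)
                    for i_p, i_n in _cross_pairs(coords, prot, dna, d_max)]
    return records


def detect_apolar(ensemble: StructureEnsemble, frame: int,
                  annotation: AtomAnnotation,
                  d_max: float = DEFAULT_APOLAR_DISTANCE) -> list[ContactRecord]:
    """Hydrophobic contacts: apolar protein atoms within ``d_max`` (inclusive)
    of apolar DNA atoms."""
    coords = ensemble.frame(frame)
    apolar = np.array([r is not None and r.apolar for r in annotation.roles])
    prot = np.flatnonzero(annotation.is_protein & apolar)
    dna = np.flatnonzero(annotation.is_dna & apolar)
    return [_record(frame, annotation, i_p, i_n, "apolar", ensemble)
            for i_p, i_n in _cross_pairs(coords, prot, dna, d_max)]


def detect_all(ensemble: StructureEnsemble, frame: int,
               annotation: AtomAnnotation,
               hbond_distance: float = DEFAULT_HBOND_DISTANCE,
               hbond_angle: float = DEFAULT_HBOND_ANGLE,
               salt_bridge_distance: float = DEFAULT_SALT_BRIDGE_DISTANCE,
               apolar_distance: float = DEFAULT_APOLAR_DISTANCE
               ) -> list[ContactRecord]:
    return (
        detect_hbonds(ensemble, frame, annotation, hbond_distance, hbond_angle)
        + detect_salt_bridges(ensemble, frame, annotation, salt_bridge_distance)
        + detect_apolar(ensemble, frame, annotation, apolar_distance)
    )


def contact_strength(records: list[ContactRecord]) -> int:
    """Strength of one residue pair in one frame: the number of contacts, each
    hydrogen bond, salt bridge or apolar contact contributing 1."""
    return len(records)


@dataclass
class ContactStrengthMap:
    """Per residue-pair, per-frame integer contact strengths.

    ``strength`` has shape (frames, pairs); ``pairs`` lists the
    (protein residue, DNA residue) keys in column order.
    """

    pairs: list[tuple[ResidueKey, ResidueKey]]
    strength: np.ndarray
    records: list[ContactRecord] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.strength = np.asarray(self.strength)
        if np.any(self.strength < 0):
            raise ValueError("strengths must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.strength.shape[0]

    @property
    def mean_strength(self) -> np.ndarray:
        return self.strength.mean(axis=0)

    @property
    def occupancy(self) -> np.ndarray:
        """Fraction of frames in which each pair is in contact (S > 0)."""
        return (self.strength > 0).mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein": [str(p) for p, _ in self.pairs],
                "dna": [str(d) for _, d in self.pairs],
                "mean_strength": self.mean_strength,
                "occupancy": self.occupancy,
            }
        )


def dynamic_contact_map(ensemble: StructureEnsemble,
                        role_table: RoleTable | None = None,
                        *, specific_only: bool = False,
                        **criteria) -> ContactStrengthMap:
    """Contact-strength time series for every protein-DNA residue pair.

    Detects all three contact types in every frame and sums them per pair
    with unit weights. ``specific_only`` restricts the map to side-chain-base
    (direct-readout) contacts; extra keyword arguments are passed to the
    detectors (``hbond_distance``, ``hbond_angle``, ``salt_bridge_distance``,
    ``apolar_distance``).
    """
    if ensemble.n_frames == 0:
        raise ValueError("empty ensemble")
    role_table = role_table or RoleTable.default()
    annotation = AtomAnnotation.annotate(ensemble, role_table)
    all_records: list[ContactRecord] = []
    for f in range(ensemble.n_frames):
        all_records += detect_all(ensemble, f, annotation, **criteria)
    if specific_only:
        all_records = [r for r in all_records if r.specific]
    pairs = sorted({r.pair for r in all_records},
                   key=lambda p: (str(p[0]), str(p[1])))
    index = {p: i for i, p in enumerate(pairs)}
    strength = np.zeros((ensemble.n_frames, len(pairs)), dtype=int)
    for r in all_records:
        strength[r.frame, index[r.pair]] += 1
    return ContactStrengthMap(pairs, strength, all_records)


# ---------------------------------------------------------------------------
# Conformational substates
# ---------------------------------------------------------------------------

@dataclass
class SubstateClustering:
    """Frame labels (0 = most occupied cluster) and per-cluster occupancies."""

    labels: np.ndarray
    occupancies: np.ndarray
    fingerprint_bits: list[tuple[str, str]]  # (partner atom, contact type)

    @property
    def n_clusters(self) -> int:
        return len(self.occupancies)


def residue_fingerprints(map_: ContactStrengthMap, residue: ResidueKey
                         ) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Binary per-frame fingerprints of one protein residue: one bit per
    (DNA partner atom, contact type) it ever engages."""
    recs = [r for r in map_.records if r.protein == residue]
    bits = sorted({(f"{r.dna}:{r.dna_atom}", r.type) for r in recs})
    index = {b: i for i, b in enumerate(bits)}
    fp = np.zeros((map_.n_frames, len(bits)), dtype=bool)
    for r in recs:
        fp[r.frame, index[(f"{r.dna}:{r.dna_atom}", r.type)]] = True
    return fp, bits


def cluster_substates(fingerprints: np.ndarray,
                      bits: list[tuple[str, str]] | None = None,
                      min_bit_occupancy: float = 0.10) -> SubstateClustering:
    """Cluster per-frame contact fingerprints into conformational substates.

    Unique fingerprints are merged by hierarchical average-linkage clustering
    on Jaccard distances, restricted to *significant* bits (those set in at
    least ``min_bit_occupancy`` of frames) and cut at distance zero — so two
    substates always differ in at least one significant bit, and flickering
    rare contacts do not split states. Clusters are numbered by decreasing
    occupancy (ties broken lexicographically on the fingerprint pattern);
    the procedure is fully deterministic.
    """
    fingerprints = np.asarray(fingerprints, dtype=bool)
    n_frames = fingerprints.shape[0]
    if bits is None:
        bits = [(f"bit{i}", "any") for i in range(fingerprints.shape[1])]
    if n_frames < 2:
        log.warning("fewer than 2 frames: trivial single-cluster result")
        return SubstateClustering(np.zeros(max(n_frames, 0), dtype=int),
                                  np.ones(1) if n_frames else np.empty(0), bits)
    occ = fingerprints.mean(axis=0)
    significant = occ >= min_bit_occupancy
    reduced = fingerprints[:, significant]
    uniq, inverse = np.unique(reduced, axis=0, return_inverse=True)
    if uniq.shape[0] == 1 or uniq.shape[1] == 0:
        merged = np.zeros(uniq.shape[0], dtype=int)
    else:
        dist = pdist(uniq, metric="jaccard")
        merged_raw = fcluster(linkage(dist, method="average"),
                              t=1e-9, criterion="distance")
        _, merged = np.unique(merged_raw, return_inverse=True)
    frame_cluster = merged[inverse]
    n_clusters = frame_cluster.max() + 1
    counts = np.bincount(frame_cluster, minlength=n_clusters)
    patterns = ["".join("1" if b else "0" for b in uniq[merged == c][0])
                for c in range(n_clusters)]
    order = sorted(range(n_clusters), key=lambda c: (-counts[c], patterns[c]))
    relabel = {old: new for new, old in enumerate(order)}
    labels = np.array([relabel[c] for c in frame_cluster])
    occupancies = np.array([counts[c] for c in order]) / n_frames
    return SubstateClustering(labels, occupancies, bits)
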