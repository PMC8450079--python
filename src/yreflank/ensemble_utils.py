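"""Ensemble geometry utilities: rigid superposition, RMSD series, windowed
average structures and convergence checks, torsion angles and backbone BI/BII
classification."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .io_formats import StructureEnsemble


@dataclass
class RMSDSeries:
    """RMSD (Angstrom) of every frame against a stated reference structure,
    computed on a described atom selection."""

    frame_indices: np.ndarray
    values: np.ndarray
    selection: str = "all"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < 0):
            raise ValueError("RMSD values must be non-negative")
        if len(self.values) != len(self.frame_indices):
            raise ValueError("one value per frame index required")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares optimal rigid superposition of ``mobile`` onto
    ``reference``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation and ``t`` a
    translation such that ``mobile @ R.T + t`` best fits ``reference``, and
    the RMSD after the transform. Requires >= 3 non-collinear atoms in each
    set.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("coordinate sets must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    mob_c = mobile - mobile.mean(axis=0)
    ref_c = reference - reference.mean(axis=0)
    if (np.linalg.matrix_rank(mob_c, tol=1e-8) < 2
            or np.linalg.matrix_rank(ref_c, tol=1e-8) < 2):
        raise ValueError("degenerate (collinear) coordinate set")
    rot, _ = Rotation.align_vectors(ref_c, mob_c)
    r = rot.as_matrix()
    t = reference.mean(axis=0) - mobile.mean(axis=0) @ r.T
    fitted = mobile @ r.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference) ** 2, axis=1))))
    return r, t, rmsd


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD between two coordinate sets after optimal superposition."""
    return kabsch_superpose(a, b)[2]


def rmsd_series(ensemble: StructureEnsemble, reference: np.ndarray,
                atom_mask: np.ndarray | None = None,
                selection: str = "all") -> RMSDSeries:
    """Per-frame RMSD against an explicit reference structure, each frame
    optimally superposed on the selected atoms first."""
    if atom_mask is None:
        atom_mask = np.ones(ensemble.n_atoms, dtype=bool)
    ref = np.asarray(reference, dtype=float)[atom_mask] \
        if reference.shape[0] == ensemble.n_atoms else np.asarray(reference)
    values = [superposed_rmsd(ensemble.frame(i)[atom_mask], ref)
              for i in range(ensemble.n_frames)]
    return RMSDSeries(np.arange(ensemble.n_frames), np.array(values), selection)


def windowed_average_structure(ensemble: StructureEnsemble,
                               windows: list[tuple[int, int]],
                               atom_mask: np.ndarray | None = None
                               ) -> list[np.ndarray]:
    """Mean coordinates over each half-open frame window.

    Every frame is first superposed (on the selected atoms) onto the mean of
    the first window, which is itself seeded by superposing onto frame 0 —
    i.e. the mean/superpose cycle is iterated once.
    """
    if atom_mask is None:
        atom_mask = np.ones(ensemble.n_atoms, dtype=bool)
    for lo, hi in windows:
        if hi <= lo or lo < 0 or hi > ensemble.n_frames:
            raise ValueError(f"empty or out-of-range window ({lo}, {hi})")

    def align_all(reference: np.ndarray) -> np.ndarray:
        out = np.empty_like(ensemble.coords)
        for i in range(ensemble.n_frames):
            frame = ensemble.frame(i)
            r, t, _ = kabsch_superpose(frame[atom_mask], reference)
            out[i] = frame @ r.T + t
        return out

    lo0, hi0 = windows[0]
    pass1 = align_all(ensemble.frame(0)[atom_mask])
    seed_mean = pass1[lo0:hi0].mean(axis=0)
    aligned = align_all(seed_mean[atom_mask])
    return [aligned[lo:hi].mean(axis=0) for lo, hi in windows]


def convergence_rmsd(ensemble: StructureEnsemble,
                     windows: list[tuple[int, int]],
                     atom_mask: np.ndarray | None = None) -> np.ndarray:
    """Symmetric matrix of superposed RMSDs between window-average structures
    (entry [i, j] compares windows i and j); successive-window convergence is
    the first off-diagonal."""
    means = windowed_average_structure(ensemble, windows, atom_mask)
    if atom_mask is None:
        atom_mask = np.ones(ensemble.n_atoms, dtype=bool)
    n = len(means)
    table = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            table[i, j] = table[j, i] = superposed_rmsd(
                means[i][atom_mask], means[j][atom_mask])
    return table


# ---------------------------------------------------------------------------
# Torsions and BI/BII backbone substates
# ---------------------------------------------------------------------------

def dihedral(a: np.ndarray, b: np.ndarray, c: np.ndarray,
             d: np.ndarray) -> float:
    """Signed dihedral angle a-b-c-d in degrees, in (-180, 180]."""
    a, b, c, d = (np.asarray(p, dtype=float) for p in (a, b, c, d))
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = n1 @ n2
    y = m1 @ n2
    angle = np.degrees(np.arctan2(y, x))
    return 180.0 if np.isclose(angle, -180.0) else float(angle)


def wrap_angle(angle: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    wrapped = (angle + 180.0) % 360.0 - 180.0
    return 180.0 if wrapped == -180.0 else wrapped


def classify_bi_bii(epsilon: float, zeta: float) -> str:
    """Backbone substate from the epsilon and zeta torsions (degrees): BI when
    the wrapped difference epsilon - zeta is negative, BII otherwise."""
    return "BI" if wrap_angle(epsilon - zeta) < 0 else "BII"
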