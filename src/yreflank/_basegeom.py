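"""Idealized planar nucleobase geometry in the standard base-pair reference
frame, plus base-frame fitting.

The coordinates (Angstrom) place each base as it sits in an ideal Watson-Crick
pair whose reference frame has its origin between the bases, x pointing into
the major groove, y along the short base-pair axis toward the Watson strand
backbone, and z along the helix 5'->3' of the Watson strand. The complementary
base of a pair is the ideal geometry of its partner rotated 180 degrees about
x (y, z negated). These templates serve two jobs: building synthetic DNA
coordinates from prescribed step parameters, and recovering base-pair frames
from observed coordinates by least-squares superposition. Both directions use
the same template, so build -> re-extract round-trips are exact up to
coordinate precision.
"""

from __future__ import annotations

import numpy as np

from .ensemble_utils import kabsch_superpose

#: Ring and exocyclic atoms of each base in the standard reference frame.
BASE_ATOMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "C1'": (-2.479, 5.346, 0.000),
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
    },
    "G": {
        "C1'": (-2.477, 5.399, 0.000),
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, 0.000),
        "N3": (-2.342, 2.364, 0.000),
        "C4": (-1.265, 3.177, 0.000),
    },
    "C": {
        "C1'": (-2.477, 5.402, 0.000),
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.000),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.000),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
    },
    "T": {
        "C1'": (-2.481, 5.354, 0.000),
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.000),
        "C6": (-0.024, 5.057, 0.000),
    },
}

#: Atoms used for frame fitting (ring atoms; exocyclic substituents excluded).
FIT_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

WATSON_CRICK = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Rotation flipping a frame onto its paired-strand orientation.
_FLIP = np.diag([1.0, -1.0, -1.0])


def paired_template(base: str) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Atom coordinates of a full Watson-Crick pair, in the pair's reference
    frame: (Watson-base atoms, complementary-base atoms)."""
    watson = {n: np.asarray(xyz) for n, xyz in BASE_ATOMS[base].items()}
    partner = WATSON_CRICK[base]
    crick = {n: _FLIP @ np.asarray(xyz)
             for n, xyz in BASE_ATOMS[partner].items()}
    return watson, crick


def fit_base_frame(base: str, atom_names: list[str], coords: np.ndarray,
                   *, flipped: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares base frame (axes, origin) from observed base atoms.

    The idealized ring template of ``base`` is superposed onto the observed
    coordinates; the frame is where the template's frame lands. ``flipped``
    applies the paired-strand orientation (for bases on the Crick strand, so
    the fitted frame agrees with the base-*pair* frame orientation).
    """
    fit_names = [n for n in FIT_ATOMS[base] if n in atom_names]
    if len(fit_names) < 3:
        raise ValueError(f"too few ring atoms to fit a {base} frame: "
                         f"{fit_names}")
    template = np.array([BASE_ATOMS[base][n] for n in fit_names])
    if flipped:
        template = template @ _FLIP.T
    observed = np.array([coords[atom_names.index(n)] for n in fit_names])
    r, t, _ = kabsch_superpose(template, observed)
    return r, t


def mean_frame(axes_a: np.ndarray, origin_a: np.ndarray, axes_b: np.ndarray,
               origin_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Average two frames: origin midpoint, rotation averaged and
    re-orthonormalised (valid for nearby orientations, as in a base pair)."""
    u, _, vt = np.linalg.svd(axes_a + axes_b)
    return u @ vt, (origin_a + origin_b) / 2.0
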