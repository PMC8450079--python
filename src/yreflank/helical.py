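"""Base-pair-step helical parameters and their distribution analysis.

A base-pair step is the rigid-body transformation between the reference frames
of two successive base pairs, decomposed into three translations (shift, slide,
rise, in Angstrom) and three rotations (tilt, roll, twist, in degrees). The
decomposition used here is the exact mid-step rotation-vector form: with
successive frames ``(R_a, o_a)`` and ``(R_b, o_b)``,

* the step rotation is ``Q = R_a^T R_b`` with rotation vector ``v`` (axis x
  angle); ``(tilt, roll, twist)`` are the x, y, z components of ``v``;
* the mid-step frame is ``R_m = R_a exp(v/2)`` at the origin midpoint, and
  ``(shift, slide, rise) = R_m^T (o_b - o_a)``.

Because the rotation axis of ``Q`` is invariant under its own half rotation,
this decomposition is exactly invertible (:func:`rebuild_step`), which the
synthetic DNA builder relies on. Sign convention: the frame x axis points into
the major groove, so positive shift displaces the base pair out of the major
groove; z advances 5'->3' along the helix, making right-handed twist positive.

Downstream, per-step value distributions are normalised to unit area,
classified into the most populated of {negative, neutral, positive} states,
and compared bound-vs-unbound with a per-step two-sample Kolmogorov-Smirnov
statistic to measure how far into the flanks protein binding alters DNA
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.transform import Rotation

from .io_formats import HELICAL_PARAMETER_NAMES, SeriesTable

TRANSLATION_PARAMETERS = ("shift", "slide", "rise")
ROTATION_PARAMETERS = ("tilt", "roll", "twist")

#: Canonical B-form step parameters (fibre-diffraction averages).
BDNA_STEP = np.array([0.0, 0.0, 3.38, 0.0, 0.0, 34.3])


# ---------------------------------------------------------------------------
# Reference frames and the step decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BaseFrame:
    """A base-pair reference frame: origin (Angstrom) and a proper orthonormal
    axes matrix whose columns are the frame's x, y, z unit vectors."""

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "axes", np.asarray(self.axes, dtype=float))
        if self.origin.shape != (3,) or self.axes.shape != (3, 3):
            raise ValueError("origin must be a 3-vector, axes a 3x3 matrix")
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-8):
            raise ValueError("axes must be orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise ValueError("axes must be right-handed (det +1)")

    @classmethod
    def identity(cls) -> "BaseFrame":
        return cls(np.zeros(3), np.eye(3))


def extract_step_parameters(frame_a: BaseFrame, frame_b: BaseFrame) -> np.ndarray:
    """Six step parameters (shift, slide, rise, tilt, roll, twist) relating
    ``frame_a`` to ``frame_b``; exact inverse of :func:`rebuild_step`."""
    q = frame_a.axes.T @ frame_b.axes
    rotvec = Rotation.from_matrix(q).as_rotvec()  # radians, frame_a coords
    mid = frame_a.axes @ Rotation.from_rotvec(rotvec / 2.0).as_matrix()
    trans = mid.T @ (frame_b.origin - frame_a.origin)
    return np.concatenate([trans, np.degrees(rotvec)])


def rebuild_step(params: np.ndarray, frame_a: BaseFrame) -> BaseFrame:
    """The frame reached from ``frame_a`` by one step of the given parameters."""
    params = np.asarray(params, dtype=float)
    if params.shape != (6,) or not np.all(np.isfinite(params)):
        raise ValueError("params must be six finite numbers")
    rotvec = np.radians(params[3:])
    mid = frame_a.axes @ Rotation.from_rotvec(rotvec / 2.0).as_matrix()
    origin_b = frame_a.origin + mid @ params[:3]
    axes_b = frame_a.axes @ Rotation.from_rotvec(rotvec).as_matrix()
    # re-orthonormalise against accumulated round-off when steps are chained
    u, _, vt = np.linalg.svd(axes_b)
    return BaseFrame(origin_b, u @ vt)


def chain_frames(step_params: np.ndarray,
                 start: BaseFrame | None = None) -> list[BaseFrame]:
    """Frames of an n-bp duplex built from ``n-1`` rows of step parameters."""
    frames = [start or BaseFrame.identity()]
    for row in np.atleast_2d(step_params):
        frames.append(rebuild_step(row, frames[-1]))
    return frames


# ---------------------------------------------------------------------------
# Series containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StepLabel:
    """A dinucleotide step with its region tag: ``region`` is ``"yre"`` with
    ``offset`` the 0-based index inside the response element, or ``"flank"``
    with ``offset`` -1, -2, ... (5' side) / +1, +2, ... (3' side) counted from
    the element's edge."""

    dinucleotide: str
    region: str
    offset: int

    def __post_init__(self) -> None:
        if self.region not in ("yre", "flank"):
            raise ValueError("region must be 'yre' or 'flank'")
        if self.region == "flank" and self.offset == 0:
            raise ValueError("flank offsets are counted from 1")

    def __str__(self) -> str:
        if self.region == "yre":
            return f"{self.dinucleotide}@Y{self.offset}"
        return f"{self.dinucleotide}@{self.offset:+d}"


def label_steps(sequence: str, yre_start: int, yre_length: int) -> list[StepLabel]:
    """Dinucleotide step labels for a duplex with a response element at
    ``[yre_start, yre_start + yre_length)``. Steps wholly inside the element
    are tagged by their 0-based index; the steps straddling the element's
    edges are the first flank steps (-1 on the 5' side, +1 on the 3' side),
    with offsets growing outward."""
    labels = []
    yre_end = yre_start + yre_length
    for i in range(len(sequence) - 1):
        dinuc = sequence[i:i + 2]
        if i < yre_start:
            labels.append(StepLabel(dinuc, "flank", i - yre_start))
        elif i < yre_end - 1:
            labels.append(StepLabel(dinuc, "yre", i - yre_start))
        else:
            labels.append(StepLabel(dinuc, "flank", i - yre_end + 2))
    return labels


@dataclass
class StepParameterSeries:
    """All six helical parameters per base-pair step per frame.

    ``params[name]`` is a (frames x steps) matrix; absent values are NaN.
    """

    step_labels: list[StepLabel]
    params: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(HELICAL_PARAMETER_NAMES) - set(self.params)
        if missing:
            raise ValueError(f"missing parameter matrices: {sorted(missing)}")
        shape = None
        for name in HELICAL_PARAMETER_NAMES:
            mat = np.asarray(self.params[name], dtype=float)
            if mat.ndim != 2:
                raise ValueError(f"{name}: expected frames x steps matrix")
            if shape is None:
                shape = mat.shape
            elif mat.shape != shape:
                raise ValueError("all six parameter matrices must share shape")
            self.params[name] = mat
        if shape[1] != len(self.step_labels):
            raise ValueError(
                f"{shape[1]} step columns but {len(self.step_labels)} labels"
            )

    @property
    def n_frames(self) -> int:
        return self.params["shift"].shape[0]

    @property
    def n_steps(self) -> int:
        return len(self.step_labels)

    def values(self, parameter: str, step: int) -> np.ndarray:
        """Non-absent values of one parameter at one step."""
        col = self.params[parameter][:, step]
        return col[~np.isnan(col)]

    def drop_equilibration(self, *, n_frames: int = 0,
                           fraction: float = 0.0) -> "StepParameterSeries":
        """Discard leading frames (an equilibration transient) before analysis."""
        skip = max(n_frames, int(round(fraction * self.n_frames)))
        if skip >= self.n_frames:
            raise ValueError("cannot discard every frame")
        return StepParameterSeries(
            self.step_labels,
            {k: v[skip:] for k, v in self.params.items()},
        )

    @classmethod
    def from_tables(cls, labels: list[StepLabel],
                    tables: dict[str, SeriesTable]) -> "StepParameterSeries":
        return cls(labels, {name: t.values for name, t in tables.items()})


def series_from_frames(snapshots: list[list[BaseFrame]],
                       labels: list[StepLabel]) -> StepParameterSeries:
    """Extract step parameters for every consecutive frame pair of every
    snapshot. All snapshots must contain the same number of base-pair frames
    (one more than the number of steps)."""
    n_bp = len(snapshots[0])
    if any(len(s) != n_bp for s in snapshots):
        raise ValueError("frame counts differ across snapshots")
    if n_bp - 1 != len(labels):
        raise ValueError(f"{n_bp} frames imply {n_bp - 1} steps, "
                         f"got {len(labels)} labels")
    values = np.empty((len(snapshots), n_bp - 1, 6))
    for f, snap in enumerate(snapshots):
        for s in range(n_bp - 1):
            values[f, s] = extract_step_parameters(snap[s], snap[s + 1])
    return StepParameterSeries(
        labels,
        {name: values[:, :, i] for i, name in enumerate(HELICAL_PARAMETER_NAMES)},
    )


def duplex_frames(ensemble, frame_index: int, *, watson_chain: str = "A",
                  crick_chain: str = "B") -> list[BaseFrame]:
    """Base-pair reference frames of a DNA duplex structure, 5'->3' along the
    Watson strand.

    Watson residues (ascending number) are paired with Crick residues
    (descending number); each base frame is fitted by least-squares
    superposition of the idealized ring template onto the observed base atoms,
    the Crick frame is flipped into pair orientation, and the two are
    averaged.
    """
    from . import _basegeom
    from .io_formats import _normalize_resnames

    coords = ensemble.frame(frame_index)
    resnames = _normalize_resnames(ensemble.residue_name)

    def residues(chain: str, reverse: bool) -> list[tuple[str, list[int]]]:
        nums = sorted({int(n) for n, c in
                       zip(ensemble.residue_number, ensemble.chain_id)
                       if c == chain}, reverse=reverse)
        out = []
        for num in nums:
            idx = [i for i in range(ensemble.n_atoms)
                   if ensemble.chain_id[i] == chain
                   and int(ensemble.residue_number[i]) == num]
            out.append((resnames[idx[0]][-1], idx))
        return out

    watson = residues(watson_chain, reverse=False)
    crick = residues(crick_chain, reverse=True)
    if len(watson) != len(crick):
        raise ValueError("strands differ in residue count")
    frames = []
    for (wb, widx), (cb, cidx) in zip(watson, crick):
        rw, tw = _basegeom.fit_base_frame(
            wb, [str(ensemble.name[i]) for i in widx], coords[widx])
        rc, tc = _basegeom.fit_base_frame(
            cb, [str(ensemble.name[i]) for i in cidx], coords[cidx],
            flipped=True)
        axes, origin = _basegeom.mean_frame(rw, tw, rc, tc)
        frames.append(BaseFrame(origin, axes))
    return frames


# ---------------------------------------------------------------------------
# Distributions and state calls
# ---------------------------------------------------------------------------

def normalized_distribution(series: StepParameterSeries, parameter: str,
                            step: int, bin_width: float | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Unit-area histogram (bin centres, densities) of one parameter at one
    step; bin edges are aligned to multiples of ``bin_width`` (default 0.1 A
    for translations, 2 degrees for rotations)."""
    if bin_width is None:
        bin_width = 0.1 if parameter in TRANSLATION_PARAMETERS else 2.0
    vals = series.values(parameter, step)
    if vals.size == 0:
        raise ValueError(f"all values absent for {parameter} at step {step}")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width
    n_bins = max(int(round((hi - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    if edges[-1] < vals.max():  # guard the inclusive upper boundary
        edges = np.append(edges, edges[-1] + bin_width)
    densities, edges = np.histogram(vals, bins=edges, density=True)
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, densities


@dataclass(frozen=True)
class StateCall:
    """Most populated sign state of one step: the winning state among
    negative / neutral / positive with all three population fractions."""

    step_label: StepLabel
    state: str
    population_fraction: float
    fractions: dict[str, float]


def classify_state(series: StepParameterSeries, parameter: str, step: int,
                   neutral_band: float = 0.3) -> StateCall:
    """Call the most populated of {negative, neutral, positive} for one step.

    A value is neutral when ``|value| <= neutral_band`` (default 0.3 A, suited
    to shift/slide). Ties are called neutral.
    """
    vals = series.values(parameter, step)
    if vals.size == 0:
        raise ValueError(f"all values absent for {parameter} at step {step}")
    n = vals.size
    fractions = {
        "negative": float(np.sum(vals < -neutral_band)) / n,
        "neutral": float(np.sum(np.abs(vals) <= neutral_band)) / n,
        "positive": float(np.sum(vals > neutral_band)) / n,
    }
    best = max(fractions.values())
    winners = [s for s, f in fractions.items() if f == best]
    state = "neutral" if len(winners) > 1 else winners[0]
    return StateCall(series.step_labels[step], state, fractions[state], fractions)


# ---------------------------------------------------------------------------
# Bound-vs-unbound comparison
# ---------------------------------------------------------------------------

@dataclass
class AlterationResult:
    """Per-step bound-vs-unbound alteration and how far it reaches into the
    flanks (contiguously from the response-element edge outward)."""

    step_labels: list[StepLabel]
    scores: np.ndarray  # two-sample KS statistic per step, in [0, 1]
    altered: np.ndarray  # scores > threshold
    threshold: float
    reach_5p: int
    reach_3p: int


def compare_bound_unbound(bound: StepParameterSeries,
                          unbound: StepParameterSeries, parameter: str,
                          threshold: float = 0.2) -> AlterationResult:
    """Quantify, per step, how much protein binding alters the distribution of
    one helical parameter, and the contiguous flank reach of the alteration.

    The per-step score is the two-sample Kolmogorov-Smirnov statistic between
    the bound and unbound value distributions (0 = identical, 1 = disjoint
    supports); a step is *altered* when its score exceeds ``threshold``. The
    flank reach on each side counts outward from the response-element edge
    (offsets -1, -2, ... and +1, +2, ...) and stops at the first unaltered
    step.
    """
    if bound.step_labels != unbound.step_labels:
        raise ValueError("step labels differ between bound and unbound series")
    scores = np.empty(bound.n_steps)
    for s in range(bound.n_steps):
        b, u = bound.values(parameter, s), unbound.values(parameter, s)
        if b.size == 0 or u.size == 0:
            raise ValueError(f"all values absent at step {s}")
        if np.array_equal(np.sort(b), np.sort(u)):
            scores[s] = 0.0  # identical samples: KS statistic is exactly 0
        else:
            scores[s] = stats.ks_2samp(b, u).statistic
    altered = scores > threshold
    by_offset = {
        (lab.region, lab.offset): altered[i]
        for i, lab in enumerate(bound.step_labels)
    }

    def reach(sign: int) -> int:
        r = 0
        off = sign
        while ("flank", off) in by_offset and by_offset[("flank", off)]:
            r += 1
            off += sign
        return r

    return AlterationResult(bound.step_labels, scores, altered, threshold,
                            reach_5p=reach(-1), reach_3p=reach(+1))


def variance_ratio(bound: StepParameterSeries, unbound: StepParameterSeries,
                   parameter: str) -> np.ndarray:
    """Per-step bound/unbound variance ratio — a scale-sensitive companion to
    the distribution-free KS score (ratio < 1: binding narrows the
    distribution)."""
    out = np.empty(bound.n_steps)
    for s in range(bound.n_steps):
        out[s] = np.var(bound.values(parameter, s)) / \
            np.var(unbound.values(parameter, s))
    return out
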