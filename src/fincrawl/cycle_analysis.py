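"""Fin-state, girdle-muscle and gait-cycle analysis.

Fin areas (the observable proxy for abduction/adduction) are computed per
frame, thresholded into abducted/adducted/transition states, and the right
pectoral fin's state transitions define the crawl cycles.  Kinematic
variables are normalised to 20 equally spaced phase increments per cycle and
aggregated as mean +/- SD across cycles; Pearson correlations quantify the
diagonal fin-muscle coupling (RF and LH with the right girdle muscle, LF and
RH with the left) and the anti-phase contraction of the two girdle muscles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter
from shapely.geometry import Polygon as _ShapelyPolygon

from .crawl_simulator import ABDUCTED, ADDUCTED, TRANSITION, FIN_IDS, MUSCLE_IDS

N_PHASE_INCREMENTS = 20

__all__ = [
    "N_PHASE_INCREMENTS",
    "FinTrack",
    "MuscleTrack",
    "CrawlCycle",
    "NormalizedCycle",
    "fin_area",
    "classify_fin_states",
    "detect_cycles",
    "normalize_cycle",
    "aggregate_cycles",
    "muscle_metrics",
    "fin_muscle_correlations",
    "build_fin_track",
]


@dataclass
class FinTrack:
    fin_id: str
    areas: np.ndarray  # (n,) mm^2
    states: list  # per-frame state labels

    def __post_init__(self) -> None:
        if np.any(self.areas < 0):
            raise ValueError("fin areas must be >= 0")
        if len(self.states) != self.areas.size:
            raise ValueError("states must cover every frame")


@dataclass
class MuscleTrack:
    muscle_id: str
    lengths: np.ndarray  # (n,) mm
    contraction_rate: np.ndarray  # (n,) mm/s, smoothed d(length)/dt

    def __post_init__(self) -> None:
        if np.any(self.lengths <= 0):
            raise ValueError("muscle lengths must be positive")


@dataclass
class CrawlCycle:
    start: int  # frame index
    end: int
    duration: float  # s
    direction: str = ""

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("cycle duration must be positive")


@dataclass
class NormalizedCycle:
    """Mean +/- SD of variables at 20 phase increments over n cycles."""

    phase: np.ndarray  # (20,) in [0, 1]
    mean: dict  # variable name -> (20,)
    sd: dict  # variable name -> (20,)
    n_cycles: int

    def __post_init__(self) -> None:
        if self.phase.size != N_PHASE_INCREMENTS:
            raise ValueError(f"expected {N_PHASE_INCREMENTS} phase increments")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def fin_area(polygon: np.ndarray) -> float:
    """Planimetric (shoelace) area of a simple polygon, mm^2.

    Degenerate (collinear) polygons return 0; self-intersecting outlines are
    rejected.
    """
    poly = np.asarray(polygon, dtype=float)
    if poly.ndim != 2 or poly.shape[0] < 3 or poly.shape[1] != 2:
        raise ValueError("polygon must be an (n>=3, 2) array")
    x, y = poly[:, 0], poly[:, 1]
    shoelace = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if not _ShapelyPolygon(poly).is_valid:
        # fully collinear outlines are degenerate (area 0), not crossings
        centered = poly - poly.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) >= 2:
            raise ValueError("self-intersecting polygon")
    return float(abs(shoelace))


def classify_fin_states(
    areas: np.ndarray,
    low: float = 0.3,
    high: float = 0.7,
) -> list:
    """Threshold an area series into abducted/adducted/transition states.

    Areas are min-max normalised over the whole series; >= ``high`` of the
    range is abducted, <= ``low`` adducted, in between a transition.  A
    constant series carries no state information and is labelled abducted
    throughout with a warning.
    """
    areas = np.asarray(areas, dtype=float)
    lo, hi = float(np.min(areas)), float(np.max(areas))
    if hi - lo < 1e-9 * max(abs(hi), 1.0):
        warnings.warn("constant fin-area series; labelling single state", stacklevel=2)
        return [ABDUCTED] * areas.size
    norm = (areas - lo) / (hi - lo)
    return [
        ABDUCTED if v >= high else ADDUCTED if v <= low else TRANSITION for v in norm
    ]


def detect_cycles(
    rf_states: list,
    times: np.ndarray,
    direction: str = "",
) -> tuple[list, float]:
    """Crawl cycles from right-pectoral-fin state transitions.

    A cycle runs between successive entries of the RF state into the
    abducted state (one full abduction-adduction-abduction alternation).
    Returns the cycles and the cycle frequency (cycles per elapsed time
    between the first and last boundary); frequency is NaN when fewer than
    two boundaries exist.
    """
    times = np.asarray(times, dtype=float)
    boundaries = [
        i
        for i in range(1, len(rf_states))
        if rf_states[i] == ABDUCTED and rf_states[i - 1] != ABDUCTED
    ]
    cycles = [
        CrawlCycle(start=a, end=b, duration=float(times[b] - times[a]), direction=direction)
        for a, b in zip(boundaries[:-1], boundaries[1:])
    ]
    if len(boundaries) >= 2:
        freq = len(cycles) / float(times[boundaries[-1]] - times[boundaries[0]])
    else:
        freq = float("nan")
    return cycles, freq


def normalize_cycle(
    times: np.ndarray, values: np.ndarray, cycle: CrawlCycle
) -> np.ndarray:
    """Resample one variable to 20 equally spaced phases of one cycle.

    Linear interpolation at phases 0, 1/19, ..., 1 of the cycle duration
    (both endpoints included, reported as 0-100% in 5% increments).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    t0, t1 = times[cycle.start], times[cycle.end]
    if t0 < times[0] - 1e-12 or t1 > times[-1] + 1e-12:
        raise ValueError("cycle lies outside the series")
    phases = np.linspace(t0, t1, N_PHASE_INCREMENTS)
    return np.interp(phases, times, values)


def aggregate_cycles(normalized: list) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD over cycles of 20-sample profiles."""
    arrs = [np.asarray(a, dtype=float) for a in normalized]
    if not arrs:
        raise ValueError("need at least one cycle")
    if any(a.size != N_PHASE_INCREMENTS for a in arrs):
        raise ValueError(f"all cycles must have {N_PHASE_INCREMENTS} samples")
    stack = np.stack(arrs)
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1) if stack.shape[0] > 1 else np.zeros(N_PHASE_INCREMENTS)
    return mean, sd


def muscle_metrics(
    endpoints: np.ndarray,
    dt: float,
    muscle_id: str = "",
    sg_window: int = 11,
    sg_order: int = 3,
) -> MuscleTrack:
    """Girdle-muscle length and contraction rate from endpoint pairs.

    Length is the Euclidean endpoint distance per frame; the contraction
    rate is its Savitzky-Golay-smoothed central-difference time derivative.
    """
    pts = np.asarray(endpoints, dtype=float)
    if pts.ndim != 3 or pts.shape[1:] != (2, 2):
        raise ValueError("endpoints must be an (n_frames, 2, 2) array")
    lengths = np.linalg.norm(pts[:, 1] - pts[:, 0], axis=1)
    if np.any(lengths < 1e-9):
        raise ValueError("coincident muscle endpoints")
    n = lengths.size
    window = min(sg_window, n if n % 2 == 1 else n - 1)
    if window > sg_order + 1 and n >= 3:
        smoothed = savgol_filter(lengths, window, sg_order)
    else:
        smoothed = lengths
    rate = np.gradient(smoothed, dt) if n >= 2 else np.zeros(n)
    return MuscleTrack(muscle_id=muscle_id, lengths=lengths, contraction_rate=rate)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return float("nan")  # undefined sentinel for zero-variance series
    return float(np.corrcoef(a, b)[0, 1])


def fin_muscle_correlations(fin_areas: dict, muscle_lengths: dict) -> dict:
    """Pearson correlations of fin areas vs muscle lengths over whole cycles.

    Returns ``{(fin, muscle): r}`` for the 4x2 fin-muscle pairs plus
    ``("LG", "RG")`` for the girdle anti-phase; zero-variance series yield
    NaN sentinels rather than propagating errors.
    """
    out = {}
    for fin in FIN_IDS:
        for mus in MUSCLE_IDS:
            out[(fin, mus)] = _pearson(fin_areas[fin], muscle_lengths[mus])
    out[("LG", "RG")] = _pearson(muscle_lengths["LG"], muscle_lengths["RG"])
    return out


def build_fin_track(recording, fin: str, low: float = 0.3, high: float = 0.7) -> FinTrack:
    """Fin areas + thresholded states for one fin of a Recording."""
    areas = np.array([fin_area(p) for p in recording.fin_polygons(fin)])
    states = classify_fin_states(areas, low=low, high=high)
    return FinTrack(fin_id=fin, areas=areas, states=states)
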