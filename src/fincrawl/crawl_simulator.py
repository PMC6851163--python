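"""Quasi-static simulator of two-anisotropic-sucker adhesive crawling.

The rock-climbing fish crawls on vertical underwater surfaces without ever
detaching: an anterior sucker (head + pectoral fins) and a posterior sucker
(pelvic fins) stay in contact while paired girdle muscles pull them against
each other.  Each sucker is laterally anisotropic — friction is high on the
side whose fin is abducted and low on the adducted side — so a pull makes
the sucker pivot about its abducted-fin side instead of sliding bodily.
Alternating the abducted sides between the two gait stages ratchets the fish
along; swapping the fin-state protocol (and nothing else) reverses the
direction of travel.

The simulator implements that pivot rule kinematically: the actively pulled
sucker rotates by a fixed angle about its abducted-side pivot, and the other
sucker's rotation about its own pivot is solved exactly so the spine chord
(distance between sucker centres) is preserved.  On top of the rigid sucker
motion it synthesises the full set of digitised landmarks — 20 midline
points with a tailward-growing lateral envelope, four fin polygons whose
areas follow the abduction/adduction waveform, girdle-muscle endpoint pairs
in anti-phase, and head/sucker reference points — so the module doubles as
the synthetic-data generator for the kinematics pipeline.

Units: mm, s, radians internally; ventral view with x = nominal travel
direction and positive rotation = counter-clockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

FIN_IDS = ("RF", "LF", "RH", "LH")
MUSCLE_IDS = ("RG", "LG")

ABDUCTED = "abducted"
ADDUCTED = "adducted"
TRANSITION = "transition"

#: reference girdle stroke (mm); actuation scales with the ratio of the
#: configured muscle_contraction_amplitude to this value, so a zero stroke
#: produces zero rotation and zero displacement.
DEFAULT_MUSCLE_AMPLITUDE = 3.5

__all__ = [
    "FIN_IDS",
    "MUSCLE_IDS",
    "ABDUCTED",
    "ADDUCTED",
    "TRANSITION",
    "SuckerModel",
    "SuckerForceState",
    "GaitPhase",
    "GaitProtocol",
    "SimConfig",
    "Pose",
    "Frame",
    "Recording",
    "SimulationError",
    "build_protocol",
    "mirror_protocol",
    "step_phase",
    "simulate",
    "net_axial_displacement",
    "write_recording",
    "read_recording",
]


class SimulationError(RuntimeError):
    """Raised when the spine-constraint solve fails for a phase."""


@dataclass
class SuckerModel:
    """Geometry, actuation and friction anisotropy of the two-sucker model.

    The default geometry describes a 50 mm fish (the body length implied by
    the reported mm/s to BL/s conversions): anterior sucker centre 9 mm from
    the head tip, posterior centre 17 mm further back, fin pivots 9 mm
    lateral of each centre.  ``rotation_per_stage`` is calibrated so that a
    16-cycle bout covers more than 130 mm.
    """

    body_length: float = 50.0
    sucker_centers: tuple[tuple[float, float], tuple[float, float]] = (
        (0.0, 0.0),
        (-17.0, 0.0),
    )
    pivot_offset: float = 9.0
    rotation_per_stage: float = 0.47
    mu_abducted: float = 1.99
    mu_adducted: float = 1.11
    spine_length: float = 17.0
    muscle_rest_length: float = 14.0
    muscle_contraction_amplitude: float = 3.5
    n_pectoral_rays: int = 24
    n_pelvic_rays: int = 20
    # landmark-synthesis shape parameters (calibrated defaults; see docs)
    anterior_arc_mm: float = 9.0
    head_taper: float = 1.3
    tail_gain: float = 1.8
    tail_power: float = 0.7
    dwell_fraction: float = 0.3
    fin_half_chord: float = 4.0
    fin_extent: float = 4.0
    fin_base_offset: float = 3.0
    fin_min_factor: float = 0.35

    def __post_init__(self) -> None:
        if self.body_length <= 0:
            raise ValueError("body_length must be positive")
        if not self.mu_abducted > self.mu_adducted:
            raise ValueError("mu_abducted must exceed mu_adducted (anisotropy)")
        if not 0.0 <= self.rotation_per_stage < math.pi / 4:
            raise ValueError("rotation_per_stage must lie in [0, pi/4)")
        c1, c2 = (np.asarray(c, float) for c in self.sucker_centers)
        d = float(np.linalg.norm(c1 - c2))
        if not math.isclose(d, self.spine_length, rel_tol=1e-9):
            raise ValueError(
                f"sucker_centers are {d} mm apart but spine_length is {self.spine_length}"
            )
        if self.muscle_contraction_amplitude < 0:
            raise ValueError("muscle_contraction_amplitude must be >= 0")
        if not 0.0 <= self.dwell_fraction < 1.0:
            raise ValueError("dwell_fraction must lie in [0, 1)")


@dataclass
class SuckerForceState:
    """Qualitative force balance of one displacement phase.

    F2 is the girdle pull on the actively rotated sucker, Fs2 the spine
    constraint reaction, F1 the force transmitted to the passive sucker.
    Magnitudes are a muscle-tension proxy (stroke times a nominal stiffness);
    the load-bearing content is the pivot sides, which are always the
    abducted-fin side of each sucker.
    """

    F1: float
    F2: float
    Fs2: float
    pivot_side: dict  # {"anterior": "left"|"right", "posterior": ...}


@dataclass
class GaitPhase:
    """One phase of a gait protocol.

    ``fin_start``/``fin_end`` give per-fin states at the phase boundaries
    (transitions are eased in between); ``girdle`` maps RG/LG to
    contracting/relaxing/holding; ``muscle_start``/``muscle_end`` give the
    left-girdle contraction level m in [0, 1] (RG is its complement);
    ``active`` names the actively pulled sucker for displacement phases.
    """

    name: str
    fin_start: dict
    fin_end: dict
    girdle: dict
    displacement: bool
    active: str | None  # "anterior" | "posterior" | None
    rotation_sign: float
    muscle_start: float
    muscle_end: float
    duration_fraction: float


@dataclass
class GaitProtocol:
    direction: str
    phases: list

    def __post_init__(self) -> None:
        total = sum(p.duration_fraction for p in self.phases)
        if not math.isclose(total, 1.0, rel_tol=1e-9):
            raise ValueError("phase duration fractions must sum to 1")


@dataclass
class SimConfig:
    cycle_frequency: float = 7.70
    n_cycles: int = 5
    frame_rate: float = 500.0
    noise_sigma: float = 0.0
    seed: int = 0
    body_length_mm: float = 50.0

    def __post_init__(self) -> None:
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.frame_rate < 20.0 * self.cycle_frequency:
            raise ValueError("frame_rate must be at least 20x cycle_frequency")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in ("cycle_frequency", "frame_rate", "body_length_mm"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive and finite")


@dataclass
class Pose:
    """Rigid state of the two suckers: centres and heading angles."""

    c1: np.ndarray  # anterior sucker centre
    c2: np.ndarray  # posterior sucker centre
    theta1: float
    theta2: float

    def copy(self) -> "Pose":
        return Pose(self.c1.copy(), self.c2.copy(), self.theta1, self.theta2)


@dataclass
class Frame:
    time: float
    midline: np.ndarray  # (20, 2)
    fins: dict  # fin id -> (m, 2) polygon
    fin_states: dict  # fin id -> state label
    muscles: dict  # muscle id -> (2, 2) endpoints
    head_ref: np.ndarray  # (2, 2)
    sucker_ref_ant: np.ndarray  # (2, 2)
    sucker_ref_post: np.ndarray  # (2, 2)
    contact: tuple = (True, True)


@dataclass
class Recording:
    frames: list
    seed: int = 0
    frame_rate: float = 500.0
    body_length_mm: float = 50.0
    cycle_frequency: float = 7.70
    direction: str = "forward"

    def __post_init__(self) -> None:
        if self.frames:
            times = np.array([f.time for f in self.frames])
            if np.any(np.diff(times) <= 0):
                raise ValueError("frame times must be strictly increasing")
            for f in self.frames:
                if f.midline.shape != (20, 2):
                    raise ValueError("each frame needs exactly 20 midline points")

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    def midlines(self) -> np.ndarray:
        return np.stack([f.midline for f in self.frames])

    def fin_polygons(self, fin: str) -> list:
        return [f.fins[fin] for f in self.frames]

    def muscle_endpoints(self, muscle: str) -> np.ndarray:
        return np.stack([f.muscles[muscle] for f in self.frames])

    def head_refs(self) -> np.ndarray:
        return np.stack([f.head_ref for f in self.frames])


# ---------------------------------------------------------------------------
# gait protocols

_FWD_STAGE1_START = {"RF": ADDUCTED, "LF": ABDUCTED, "RH": ABDUCTED, "LH": ADDUCTED}
_FWD_STAGE1_END = {"RF": ABDUCTED, "LF": ADDUCTED, "RH": ADDUCTED, "LH": ABDUCTED}


def build_protocol(direction: str) -> GaitProtocol:
    """Canonical forward (2-stage) or backward (4-quarter) gait protocol.

    Forward: each stage rotates the suckers while the fin states swap sides
    mid-rotation, so both stages produce displacement.  Backward: quarters 1
    and 3 swap all four fin states with no motion; quarters 2 and 4 rotate
    with the fin states held, driving the fish backwards.
    """
    if direction == "forward":
        phases = [
            GaitPhase(
                name="stage1",
                fin_start=dict(_FWD_STAGE1_START),
                fin_end=dict(_FWD_STAGE1_END),
                girdle={"LG": "contracting", "RG": "relaxing"},
                displacement=True,
                active="posterior",
                rotation_sign=-1.0,
                muscle_start=0.0,
                muscle_end=1.0,
                duration_fraction=0.5,
            ),
            GaitPhase(
                name="stage2",
                fin_start=dict(_FWD_STAGE1_END),
                fin_end=dict(_FWD_STAGE1_START),
                girdle={"LG": "relaxing", "RG": "contracting"},
                displacement=True,
                active="posterior",
                rotation_sign=1.0,
                muscle_start=1.0,
                muscle_end=0.0,
                duration_fraction=0.5,
            ),
        ]
        return GaitProtocol("forward", phases)
    if direction == "backward":
        phases = [
            GaitPhase(
                name="quarter1",
                fin_start=dict(_FWD_STAGE1_START),
                fin_end=dict(_FWD_STAGE1_END),
                girdle={"LG": "holding", "RG": "holding"},
                displacement=False,
                active=None,
                rotation_sign=0.0,
                muscle_start=0.0,
                muscle_end=0.0,
                duration_fraction=0.25,
            ),
            GaitPhase(
                name="quarter2",
                fin_start=dict(_FWD_STAGE1_END),
                fin_end=dict(_FWD_STAGE1_END),
                girdle={"LG": "contracting", "RG": "relaxing"},
                displacement=True,
                active="anterior",
                rotation_sign=1.0,
                muscle_start=0.0,
                muscle_end=1.0,
                duration_fraction=0.25,
            ),
            GaitPhase(
                name="quarter3",
                fin_start=dict(_FWD_STAGE1_END),
                fin_end=dict(_FWD_STAGE1_START),
                girdle={"LG": "holding", "RG": "holding"},
                displacement=False,
                active=None,
                rotation_sign=0.0,
                muscle_start=1.0,
                muscle_end=1.0,
                duration_fraction=0.25,
            ),
            GaitPhase(
                name="quarter4",
                fin_start=dict(_FWD_STAGE1_START),
                fin_end=dict(_FWD_STAGE1_START),
                girdle={"LG": "relaxing", "RG": "contracting"},
                displacement=True,
                active="anterior",
                rotation_sign=-1.0,
                muscle_start=1.0,
                muscle_end=0.0,
                duration_fraction=0.25,
            ),
        ]
        return GaitProtocol("backward", phases)
    raise ValueError(f"unknown direction {direction!r}; expected 'forward' or 'backward'")


def _swap_lr(states: dict) -> dict:
    pair = {"RF": "LF", "LF": "RF", "RH": "LH", "LH": "RH", "RG": "LG", "LG": "RG"}
    return {pair[k]: v for k, v in states.items()}


def mirror_protocol(protocol: GaitProtocol) -> GaitProtocol:
    """Left-right mirrored protocol (L/R labels swapped, rotations negated)."""
    # mirroring exchanges the roles of LG and RG, hence m -> 1 - m
    phases = [
        replace(
            p,
            fin_start=_swap_lr(p.fin_start),
            fin_end=_swap_lr(p.fin_end),
            girdle=_swap_lr(p.girdle),
            rotation_sign=-p.rotation_sign,
            muscle_start=1.0 - p.muscle_start,
            muscle_end=1.0 - p.muscle_end,
        )
        for p in protocol.phases
    ]
    return GaitProtocol(protocol.direction, phases)


# ---------------------------------------------------------------------------
# rigid-sucker mechanics


def _unit(angle: float) -> np.ndarray:
    return np.array([math.cos(angle), math.sin(angle)])


def _left_normal(angle: float) -> np.ndarray:
    return np.array([-math.sin(angle), math.cos(angle)])


def _rotate_about(point: np.ndarray, pivot: np.ndarray, angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    d = point - pivot
    return pivot + np.array([c * d[0] - s * d[1], s * d[0] + c * d[1]])


def _pivot(center: np.ndarray, theta: float, side: str, offset: float) -> np.ndarray:
    n = _left_normal(theta)
    return center + offset * n if side == "left" else center - offset * n


def _abducted_side(fin_states: dict, sucker: str) -> str:
    left, right = ("LF", "RF") if sucker == "anterior" else ("LH", "RH")
    return "left" if fin_states[left] == ABDUCTED else "right"


def _circle_circle(
    p: np.ndarray, r: float, c: np.ndarray, d: float, ref: np.ndarray
) -> np.ndarray:
    """Intersection of circle(p, r) and circle(c, d) nearest to ``ref``."""
    e = c - p
    ell = float(np.linalg.norm(e))
    if ell < 1e-12:
        raise SimulationError("concentric spine-constraint circles")
    a = (ell**2 + r**2 - d**2) / (2.0 * ell)
    h2 = r**2 - a**2
    if h2 < -1e-9 * r**2:
        raise SimulationError("spine constraint unsatisfiable (circles do not intersect)")
    h = math.sqrt(max(h2, 0.0))
    eh = e / ell
    base = p + a * eh
    perp = np.array([-eh[1], eh[0]])
    cand = (base + h * perp, base - h * perp)
    return min(cand, key=lambda q: float(np.linalg.norm(q - ref)))


def step_phase(
    model: SuckerModel,
    pose: Pose,
    phase: GaitPhase,
    progress: float = 1.0,
    passive_ref: np.ndarray | None = None,
) -> tuple[Pose, SuckerForceState]:
    """Advance the rigid pose through (part of) one gait phase.

    For a displacement phase the active sucker is rotated by
    ``rotation_sign * rotation_per_stage * progress`` about its abducted-side
    pivot (scaled by the girdle stroke ratio), and the passive sucker's
    rotation about its own pivot is solved so the centre distance stays
    exactly ``spine_length``.  Fin-swap phases leave the pose untouched.

    The passive sucker mirrors the rotation (opposite sign, about its own
    abducted-side pivot) and the small residual spine-length error is taken
    up by a slip of its adducted side: the centre is projected back onto the
    spine-length circle around the active centre, orientation unchanged.
    ``passive_ref`` is accepted for interface stability and unused.
    """
    sides = {
        "anterior": _abducted_side(phase.fin_start, "anterior"),
        "posterior": _abducted_side(phase.fin_start, "posterior"),
    }
    tension = model.muscle_contraction_amplitude * 10.0 * abs(progress)
    forces = SuckerForceState(F1=tension, F2=tension, Fs2=tension, pivot_side=sides)

    if not phase.displacement or phase.active is None:
        return pose.copy(), forces

    scale = model.muscle_contraction_amplitude / DEFAULT_MUSCLE_AMPLITUDE
    angle = phase.rotation_sign * model.rotation_per_stage * scale * progress
    if angle == 0.0:
        return pose.copy(), forces

    new = pose.copy()
    if phase.active == "posterior":
        piv_a = _pivot(pose.c2, pose.theta2, sides["posterior"], model.pivot_offset)
        new.c2 = _rotate_about(pose.c2, piv_a, angle)
        new.theta2 = pose.theta2 + angle
        piv_p = _pivot(pose.c1, pose.theta1, sides["anterior"], model.pivot_offset)
        c1_rot = _rotate_about(pose.c1, piv_p, -angle)
        new.theta1 = pose.theta1 - angle
        gap = c1_rot - new.c2
        norm = float(np.linalg.norm(gap))
        if norm < 1e-9:
            raise SimulationError("sucker centres coincide; spine direction undefined")
        new.c1 = new.c2 + model.spine_length * gap / norm
    else:
        piv_a = _pivot(pose.c1, pose.theta1, sides["anterior"], model.pivot_offset)
        new.c1 = _rotate_about(pose.c1, piv_a, angle)
        new.theta1 = pose.theta1 + angle
        piv_p = _pivot(pose.c2, pose.theta2, sides["posterior"], model.pivot_offset)
        c2_rot = _rotate_about(pose.c2, piv_p, -angle)
        new.theta2 = pose.theta2 - angle
        gap = c2_rot - new.c1
        norm = float(np.linalg.norm(gap))
        if norm < 1e-9:
            raise SimulationError("sucker centres coincide; spine direction undefined")
        new.c2 = new.c1 + model.spine_length * gap / norm
    return new, forces


# ---------------------------------------------------------------------------
# landmark synthesis


def _eased(tau: float, dwell: float) -> float:
    """Cosine-eased progress with an initial dwell ('paused briefly, then crawled')."""
    if tau <= dwell:
        return 0.0
    u = (tau - dwell) / (1.0 - dwell)
    return 0.5 * (1.0 - math.cos(math.pi * u))


def _wrap(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _synth_midline(model: SuckerModel, pose: Pose, n_dense: int = 800) -> np.ndarray:
    """Dense midline by integrating a headward unit-tangent field.

    The curve is anchored to the rigid pose: straight chord between the
    sucker centres, head section bending with the anterior sucker heading
    (plus passive overshoot), tail section bending with the posterior sucker
    heading amplified toward the tip (the tail whip).  Arc length is exact by
    construction, so landmark fractions of body length are stable.
    """
    L = model.body_length
    s1 = model.anterior_arc_mm
    s2 = s1 + model.spine_length
    chord = math.atan2(*(pose.c1 - pose.c2)[::-1])
    rel1 = _wrap(pose.theta1 - chord)
    rel2 = _wrap(pose.theta2 - chord)

    s = np.linspace(0.0, L, n_dense)
    phi = np.full(n_dense, chord)
    head = s < s1
    phi[head] = chord + rel1 * (1.0 - model.head_taper * (s1 - s[head]) / s1)
    tail = s > s2
    g = 1.0 + model.tail_gain * ((s[tail] - s2) / (L - s2)) ** model.tail_power
    phi[tail] = chord + rel2 * g

    tx, ty = np.cos(phi), np.sin(phi)
    # position(s) = c1 - integral_{s1}^{s} headward-tangent dsigma
    ds = s[1] - s[0]
    ix = np.concatenate([[0.0], np.cumsum(0.5 * (tx[1:] + tx[:-1]) * ds)])
    iy = np.concatenate([[0.0], np.cumsum(0.5 * (ty[1:] + ty[:-1]) * ds)])
    i1x = np.interp(s1, s, ix)
    i1y = np.interp(s1, s, iy)
    x = pose.c1[0] - (ix - i1x)
    y = pose.c1[1] - (iy - i1y)
    return s, np.column_stack([x, y])


def _sample_curve(s: np.ndarray, pts: np.ndarray, positions: np.ndarray) -> np.ndarray:
    return np.column_stack(
        [np.interp(positions, s, pts[:, 0]), np.interp(positions, s, pts[:, 1])]
    )


def _fin_polygon(
    model: SuckerModel, center: np.ndarray, theta: float, side: str, factor: float
) -> np.ndarray:
    """Five-vertex fin polygon; area is linear in the abduction factor."""
    sgn = 1.0 if side == "left" else -1.0
    c = model.fin_half_chord
    w0 = model.fin_base_offset
    lam = model.fin_min_factor + (1.0 - model.fin_min_factor) * factor
    ext = model.fin_extent * lam
    local = np.array(
        [
            [-c, sgn * w0],
            [c, sgn * w0],
            [0.8 * c, sgn * (w0 + ext)],
            [0.0, sgn * (w0 + 1.1 * ext)],
            [-0.8 * c, sgn * (w0 + ext)],
        ]
    )
    ca, sa = math.cos(theta), math.sin(theta)
    rot = np.array([[ca, -sa], [sa, ca]])
    return center + local @ rot.T


def _state_label(factor: float, low: float = 0.3, high: float = 0.7) -> str:
    if factor >= high:
        return ABDUCTED
    if factor <= low:
        return ADDUCTED
    return TRANSITION


def _fin_factor(state_start: str, state_end: str, p: float) -> float:
    v = {ABDUCTED: 1.0, ADDUCTED: 0.0}
    a0, a1 = v[state_start], v[state_end]
    return a0 + (a1 - a0) * p


def simulate(
    model: SuckerModel,
    protocol: GaitProtocol,
    config: SimConfig,
    initial_pose: Pose | None = None,
) -> Recording:
    """Run the gait forward in time and synthesise a landmark Recording.

    Poses at phase boundaries are committed sequentially with
    :func:`step_phase`; within a phase the rotation follows a cosine easing
    after an initial dwell, so axial velocity accelerates and decelerates
    twice per cycle.  Fin areas and girdle-muscle lengths follow the phase
    waveforms (fins swap mid-rotation in forward crawling, before rotation in
    backward crawling); both sucker contact flags are true in every frame.
    """
    for name in ("rotation_per_stage", "muscle_contraction_amplitude"):
        if not math.isfinite(getattr(model, name)):
            raise ValueError(f"{name} must be finite")
    T = 1.0 / config.cycle_frequency
    total = config.n_cycles * T
    n_frames = int(math.floor(total * config.frame_rate)) + 1
    rng = np.random.default_rng(config.seed)

    if initial_pose is None:
        c1, c2 = (np.asarray(c, float) for c in model.sucker_centers)
        # start mid-oscillation so headings swing symmetrically about zero:
        # the active sucker starts opposite to its first rotation sign, the
        # passive one opposite to its mirrored (negated) rotation
        scale = (
            model.muscle_contraction_amplitude / DEFAULT_MUSCLE_AMPLITUDE
        ) * model.rotation_per_stage
        first = next((p for p in protocol.phases if p.displacement), None)
        sign = first.rotation_sign if first is not None else 0.0
        th_active, th_passive = -sign * scale / 2.0, sign * scale / 2.0
        if first is not None and first.active == "anterior":
            initial_pose = Pose(c1, c2, th_active, th_passive)
        else:
            initial_pose = Pose(c1, c2, th_passive, th_active)

    # commit poses at every phase boundary
    n_phases = len(protocol.phases)
    boundary_poses = [initial_pose.copy()]
    for k in range(config.n_cycles * n_phases):
        phase = protocol.phases[k % n_phases]
        try:
            nxt, _ = step_phase(model, boundary_poses[-1], phase, 1.0)
        except SimulationError as exc:
            raise SimulationError(f"phase index {k}: {exc}") from exc
        boundary_poses.append(nxt)

    fractions = np.array([p.duration_fraction for p in protocol.phases])
    starts = np.concatenate([[0.0], np.cumsum(fractions)])[:-1]

    frames = []
    prev_passive: np.ndarray | None = None
    prev_idx = -1
    for j in range(n_frames):
        t = j / config.frame_rate
        cyc = min(int(t / T), config.n_cycles - 1)
        u = (t - cyc * T) / T
        k = int(np.searchsorted(starts, min(u, 1.0 - 1e-12), side="right")) - 1
        phase = protocol.phases[k]
        tau = (u - starts[k]) / fractions[k]
        tau = min(max(tau, 0.0), 1.0)
        idx = cyc * n_phases + k
        base = boundary_poses[idx]
        if idx != prev_idx:
            prev_passive = None
            prev_idx = idx

        if phase.displacement:
            p_move = _eased(tau, model.dwell_fraction)
            ref = prev_passive
            pose, _ = step_phase(model, base, phase, p_move, passive_ref=ref)
            prev_passive = pose.c1.copy() if phase.active == "posterior" else pose.c2.copy()
            p_fin = p_move
        else:
            pose = base.copy()
            p_fin = 0.5 * (1.0 - math.cos(math.pi * tau))
            p_move = p_fin

        m = phase.muscle_start + (phase.muscle_end - phase.muscle_start) * p_move

        s_grid, dense = _synth_midline(model, pose)
        mid_positions = np.linspace(0.0, model.body_length, 20)
        midline = _sample_curve(s_grid, dense, mid_positions)

        fins = {}
        fin_states = {}
        for fin in FIN_IDS:
            side = "left" if fin[0] == "L" else "right"
            sucker = "anterior" if fin[1] == "F" else "posterior"
            center = pose.c1 if sucker == "anterior" else pose.c2
            theta = pose.theta1 if sucker == "anterior" else pose.theta2
            if sucker == "anterior":
                center = center + 2.0 * _unit(theta)
            factor = _fin_factor(phase.fin_start[fin], phase.fin_end[fin], p_fin)
            fins[fin] = _fin_polygon(model, center, theta, side, factor)
            fin_states[fin] = _state_label(factor)

        len_lg = model.muscle_rest_length - model.muscle_contraction_amplitude * m
        len_rg = model.muscle_rest_length - model.muscle_contraction_amplitude * (1.0 - m)
        axis = math.atan2(*(pose.c2 - pose.c1)[::-1])
        muscles = {}
        for mid, length in (("LG", len_lg), ("RG", len_rg)):
            sgn = 1.0 if mid == "LG" else -1.0
            start = pose.c1 + 3.0 * sgn * _left_normal(pose.theta1) - 1.0 * _unit(pose.theta1)
            end = start + length * _unit(axis)
            muscles[mid] = np.array([start, end])

        head_ref = _sample_curve(s_grid, dense, np.array([0.0, 2.0]))
        ant_ref = np.array([pose.c1, pose.c1 + 3.0 * _unit(pose.theta1)])
        post_ref = np.array([pose.c2, pose.c2 + 3.0 * _unit(pose.theta2)])

        if config.noise_sigma > 0:
            jitter = lambda a: a + rng.normal(0.0, config.noise_sigma, a.shape)
            midline = jitter(midline)
            fins = {k_: jitter(v) for k_, v in fins.items()}
            muscles = {k_: jitter(v) for k_, v in muscles.items()}
            head_ref = jitter(head_ref)
            ant_ref = jitter(ant_ref)
            post_ref = jitter(post_ref)

        frames.append(
            Frame(
                time=t,
                midline=midline,
                fins=fins,
                fin_states=fin_states,
                muscles=muscles,
                head_ref=head_ref,
                sucker_ref_ant=ant_ref,
                sucker_ref_post=post_ref,
                contact=(True, True),
            )
        )

    return Recording(
        frames=frames,
        seed=config.seed,
        frame_rate=config.frame_rate,
        body_length_mm=config.body_length_mm,
        cycle_frequency=config.cycle_frequency,
        direction=protocol.direction,
    )


def net_axial_displacement(recording: Recording, axis: np.ndarray | None = None) -> float:
    """Displacement of the mean sucker centre along ``axis`` (default +x)."""
    if axis is None:
        axis = np.array([1.0, 0.0])
    first, last = recording.frames[0], recording.frames[-1]
    p0 = 0.5 * (first.sucker_ref_ant[0] + first.sucker_ref_post[0])
    p1 = 0.5 * (last.sucker_ref_ant[0] + last.sucker_ref_post[0])
    return float(np.dot(p1 - p0, axis))


# ---------------------------------------------------------------------------
# CSV round trip

_KINDS = (
    ["midline"]
    + [f"fin_{f}" for f in FIN_IDS]
    + [f"muscle_{m}" for m in MUSCLE_IDS]
    + ["head_ref", "sucker_ref_ant", "sucker_ref_post"]
)


class RecordingParseError(ValueError):
    """Malformed recording file; message names the offending line."""


def write_recording(recording: Recording, path) -> None:
    """Write a Recording as the tabular UTF-8 CSV interchange format."""
    if not recording.frames:
        raise ValueError("cannot write a Recording with no frames")
    lines = [
        f"# seed={recording.seed}",
        f"# frame_rate={recording.frame_rate}",
        f"# body_length_mm={recording.body_length_mm}",
        f"# cycle_frequency={recording.cycle_frequency}",
        f"# direction={recording.direction}",
        "frame,time_s,kind,index,x_mm,y_mm,label",
    ]
    for fi, fr in enumerate(recording.frames):
        t = repr(float(fr.time))
        for i, (x, y) in enumerate(fr.midline):
            lines.append(f"{fi},{t},midline,{i},{float(x)!r},{float(y)!r},")
        for fin in FIN_IDS:
            for i, (x, y) in enumerate(fr.fins[fin]):
                lines.append(f"{fi},{t},fin_{fin},{i},{float(x)!r},{float(y)!r},{fr.fin_states[fin]}")
        for mus in MUSCLE_IDS:
            for i, (x, y) in enumerate(fr.muscles[mus]):
                lines.append(f"{fi},{t},muscle_{mus},{i},{float(x)!r},{float(y)!r},")
        for i, (x, y) in enumerate(fr.head_ref):
            lines.append(f"{fi},{t},head_ref,{i},{float(x)!r},{float(y)!r},")
        for name, arr, flag in (
            ("sucker_ref_ant", fr.sucker_ref_ant, fr.contact[0]),
            ("sucker_ref_post", fr.sucker_ref_post, fr.contact[1]),
        ):
            for i, (x, y) in enumerate(arr):
                lines.append(f"{fi},{t},{name},{i},{float(x)!r},{float(y)!r},contact={int(flag)}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def read_recording(path) -> Recording:
    """Read a Recording written by :func:`write_recording` (lossless)."""
    meta = {}
    rows = []
    with open(path, encoding="utf-8") as fh:
        raw = fh.read().splitlines()
    if not raw:
        raise RecordingParseError(f"{path}: empty file")
    header_seen = False
    for ln, line in enumerate(raw, start=1):
        if line.startswith("#"):
            if "=" in line:
                key, val = line[1:].split("=", 1)
                meta[key.strip()] = val.strip()
            continue
        if not line.strip():
            continue
        if not header_seen:
            cols = [c.strip() for c in line.split(",")]
            if cols != ["frame", "time_s", "kind", "index", "x_mm", "y_mm", "label"]:
                raise RecordingParseError(f"{path}:{ln}: unexpected header {line!r}")
            header_seen = True
            continue
        parts = line.split(",")
        if len(parts) != 7:
            raise RecordingParseError(f"{path}:{ln}: expected 7 columns, got {len(parts)}")
        try:
            rows.append(
                (
                    int(parts[0]),
                    float(parts[1]),
                    parts[2],
                    int(parts[3]),
                    float(parts[4]),
                    float(parts[5]),
                    parts[6],
                    ln,
                )
            )
        except ValueError as exc:
            raise RecordingParseError(f"{path}:{ln}: {exc}") from exc
    if not rows:
        raise RecordingParseError(f"{path}: no data rows")

    frames = []
    by_frame: dict[int, list] = {}
    for row in rows:
        by_frame.setdefault(row[0], []).append(row)
    for fi in sorted(by_frame):
        frows = by_frame[fi]
        t = frows[0][1]
        groups: dict[str, dict[int, tuple]] = {}
        labels: dict[str, str] = {}
        for _, _, kind, idx, x, y, label, ln in frows:
            if kind not in _KINDS:
                raise RecordingParseError(f"{path}:{ln}: unknown kind {kind!r}")
            groups.setdefault(kind, {})[idx] = (x, y)
            if label:
                labels[kind] = label
        if "midline" not in groups or len(groups["midline"]) != 20:
            got = len(groups.get("midline", {}))
            ln = frows[0][7]
            raise RecordingParseError(
                f"{path}:{ln}: frame {fi} has {got} midline points, expected 20"
            )

        def arr(kind: str) -> np.ndarray:
            g = groups[kind]
            return np.array([g[i] for i in sorted(g)])

        fins = {}
        fin_states = {}
        for fin in FIN_IDS:
            kind = f"fin_{fin}"
            if kind not in groups:
                raise RecordingParseError(f"{path}: frame {fi} missing {kind}")
            fins[fin] = arr(kind)
            fin_states[fin] = labels.get(kind, "")
        muscles = {m: arr(f"muscle_{m}") for m in MUSCLE_IDS}
        contact = tuple(
            labels.get(k, "contact=1") == "contact=1"
            for k in ("sucker_ref_ant", "sucker_ref_post")
        )
        frames.append(
            Frame(
                time=t,
                midline=arr("midline"),
                fins=fins,
                fin_states=fin_states,
                muscles=muscles,
                head_ref=arr("head_ref"),
                sucker_ref_ant=arr("sucker_ref_ant"),
                sucker_ref_post=arr("sucker_ref_post"),
                contact=contact,
            )
        )
    return Recording(
        frames=frames,
        seed=int(meta.get("seed", 0)),
        frame_rate=float(meta.get("frame_rate", 500.0)),
        body_length_mm=float(meta.get("body_length_mm", 50.0)),
        cycle_frequency=float(meta.get("cycle_frequency", 7.70)),
        direction=meta.get("direction", "forward"),
    )
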