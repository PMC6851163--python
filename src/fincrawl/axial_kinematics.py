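"""Midline kinematics: resampling, landmarks, angles, amplitudes, velocities.

Reproduces the standard digitised-midline analysis for undulatory
locomotion: 20 hand-digitised midline points per frame are interpolated to
101 points equally spaced by arc length; 11 evenly spaced landmarks divide
the body into 10 segments of 10% body length each; per frame the pipeline
computes segment angles to the direction of travel, lateral amplitudes
relative to a straight reference midline, and instantaneous axial/lateral/
resultant velocities of each landmark (Savitzky-Golay smoothed, central
differences).  Coordinates are planar ventral-view mm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import savgol_filter

N_DIGITIZED = 20
N_RESAMPLED = 101
N_LANDMARKS = 11

__all__ = [
    "N_DIGITIZED",
    "N_RESAMPLED",
    "N_LANDMARKS",
    "Midline",
    "ResampledMidline",
    "LandmarkSet",
    "KinematicProfile",
    "interpolate_midline",
    "extract_landmarks",
    "estimate_travel_direction",
    "segment_angles",
    "amplitudes",
    "velocities",
    "analyze_recording",
]


@dataclass
class Midline:
    """One frame of 20 digitised midline points, head to caudal peduncle."""

    points: np.ndarray
    time: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_DIGITIZED, 2):
            raise ValueError(f"midline must have exactly {N_DIGITIZED} points")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("midline contains non-finite coordinates")
        if np.any(np.linalg.norm(np.diff(self.points, axis=0), axis=1) < 1e-12):
            raise ValueError("consecutive midline points must be distinct")


@dataclass
class ResampledMidline:
    """101 points equally spaced by arc length along the fitted spline."""

    points: np.ndarray
    arc_length: float

    def __post_init__(self) -> None:
        if self.points.shape != (N_RESAMPLED, 2):
            raise ValueError(f"resampled midline must have {N_RESAMPLED} points")


@dataclass
class LandmarkSet:
    """11 landmarks (every 10th resampled point) and the 10 segments."""

    points: np.ndarray  # (11, 2)

    def __post_init__(self) -> None:
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(f"landmark set must have {N_LANDMARKS} points")

    @property
    def segments(self) -> np.ndarray:
        """(10, 2, 2) array of segment endpoint pairs."""
        return np.stack([self.points[:-1], self.points[1:]], axis=1)


@dataclass
class KinematicProfile:
    """Per-frame derived kinematics for a whole recording."""

    times: np.ndarray  # (n,)
    landmarks: np.ndarray  # (n, 11, 2)
    segment_angles_deg: np.ndarray  # (n, 10)
    amplitudes_mm: np.ndarray  # (n, 11) signed
    v_axial_mm_s: np.ndarray  # (n, 11)
    v_lateral_mm_s: np.ndarray  # (n, 11)
    v_resultant_mm_s: np.ndarray  # (n, 11)
    travel_direction: np.ndarray  # unit vector
    body_length_mm: float

    @property
    def amplitudes_bl(self) -> np.ndarray:
        return self.amplitudes_mm / self.body_length_mm

    @property
    def v_axial_bl_s(self) -> np.ndarray:
        return self.v_axial_mm_s / self.body_length_mm

    @property
    def v_lateral_bl_s(self) -> np.ndarray:
        return self.v_lateral_mm_s / self.body_length_mm

    @property
    def v_resultant_bl_s(self) -> np.ndarray:
        return self.v_resultant_mm_s / self.body_length_mm


def interpolate_midline(m: Midline, dense: int = 20001) -> ResampledMidline:
    """Resample 20 digitised points to 101 equal-arc-length spline points.

    A natural cubic spline parameterised by cumulative chord length is fit
    through the points; arc length is accumulated over a dense subdivision
    and inverted to find parameters at 101 equal arc increments.
    """
    pts = m.points
    chord = np.concatenate(
        [[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))]
    )
    spline = CubicSpline(chord, pts, axis=0, bc_type="natural")
    u = np.linspace(0.0, chord[-1], dense)
    xy = spline(u)
    seg = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arc[-1], N_RESAMPLED)
    u_eq = np.interp(targets, arc, u)
    return ResampledMidline(points=spline(u_eq), arc_length=float(arc[-1]))


def extract_landmarks(r: ResampledMidline) -> LandmarkSet:
    """Every 10th resampled point: 11 landmarks bounding 10 segments."""
    return LandmarkSet(points=r.points[::10].copy())


def estimate_travel_direction(
    head_positions: np.ndarray,
    head_axis: np.ndarray | None = None,
    min_net_mm: float = 0.1,
) -> np.ndarray:
    """Unit travel direction from the anterior head point's path.

    Total-least-squares (principal-axis) line through the positions,
    oriented by the net displacement; if the net displacement is below
    ``min_net_mm`` the head axis direction is used instead.
    """
    pts = np.asarray(head_positions, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 head positions")
    net = pts[-1] - pts[0]
    if np.allclose(pts, pts[0], atol=1e-12):
        raise ValueError("stationary, direction undefined")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    _, vecs = np.linalg.eigh(cov)
    direction = vecs[:, -1]  # principal axis
    if float(np.linalg.norm(net)) < min_net_mm:
        if head_axis is None:
            raise ValueError(
                "net displacement below threshold and no head axis fallback given"
            )
        direction = np.asarray(head_axis, dtype=float)
        return direction / np.linalg.norm(direction)
    if float(np.dot(direction, net)) < 0:
        direction = -direction
    return direction / np.linalg.norm(direction)


def segment_angles(s: LandmarkSet, travel: np.ndarray) -> np.ndarray:
    """Unsigned angles (deg, folded to [0, 90]) of the 10 segments to travel."""
    travel = np.asarray(travel, dtype=float)
    travel = travel / np.linalg.norm(travel)
    vec = np.diff(s.points, axis=0)
    norms = np.linalg.norm(vec, axis=1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length body segment")
    cosang = np.abs(vec @ travel) / norms
    return np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))


def amplitudes(
    s: LandmarkSet, axis_point: np.ndarray, axis_direction: np.ndarray
) -> np.ndarray:
    """Signed perpendicular offsets of the 11 landmarks from a reference line.

    The reference is the straight body midline: the travel-direction line
    through the cycle-mean head position.  Positive is to the left of travel.
    """
    d = np.asarray(axis_direction, dtype=float)
    d = d / np.linalg.norm(d)
    rel = s.points - np.asarray(axis_point, dtype=float)
    return rel[:, 1] * d[0] - rel[:, 0] * d[1]


def velocities(
    landmark_series: np.ndarray,
    dt: float,
    travel: np.ndarray,
    body_length_mm: float,
    sg_window: int = 11,
    sg_order: int = 3,
) -> dict:
    """Instantaneous landmark velocities, decomposed along/across travel.

    Positions are Savitzky-Golay smoothed along time, differentiated by
    central differences, and projected on the travel direction (axial) and
    its left normal (lateral).  Returns mm/s and BL/s arrays of shape
    (n_frames, 11).
    """
    series = np.asarray(landmark_series, dtype=float)
    if series.ndim != 3 or series.shape[0] < 3:
        raise ValueError("need a (n_frames>=3, n_points, 2) landmark series")
    travel = np.asarray(travel, dtype=float)
    travel = travel / np.linalg.norm(travel)
    normal = np.array([-travel[1], travel[0]])

    n = series.shape[0]
    window = min(sg_window, n if n % 2 == 1 else n - 1)
    if window > sg_order + 1:
        smoothed = savgol_filter(series, window, sg_order, axis=0)
    else:
        smoothed = series
    vel = np.gradient(smoothed, dt, axis=0)
    v_ax = vel @ travel
    v_lat = vel @ normal
    v_res = np.hypot(v_ax, v_lat)
    return {
        "axial_mm_s": v_ax,
        "lateral_mm_s": v_lat,
        "resultant_mm_s": v_res,
        "axial_bl_s": v_ax / body_length_mm,
        "lateral_bl_s": v_lat / body_length_mm,
        "resultant_bl_s": v_res / body_length_mm,
    }


def analyze_recording(
    recording,
    sg_window: int = 11,
    sg_order: int = 3,
) -> KinematicProfile:
    """Run the full midline pipeline on a landmark Recording.

    Interpolates each frame's 20 midline points to 101, extracts the 11
    landmarks, estimates the travel direction from the anterior head
    reference point, and computes segment angles, amplitudes (relative to
    the travel-direction line through the mean head position) and
    velocities.
    """
    times = recording.times
    dts = np.diff(times)
    dt = float(np.mean(dts))
    if np.any(np.abs(dts - dt) > 0.01 * dt):
        raise ValueError("frame interval varies by more than 1%")

    landmark_list = []
    for fr in recording.frames:
        res = interpolate_midline(Midline(fr.midline, fr.time))
        landmark_list.append(extract_landmarks(res).points)
    landmarks = np.stack(landmark_list)

    head = recording.head_refs()[:, 0, :]
    head_axis = recording.frames[0].head_ref[0] - recording.frames[0].head_ref[1]
    travel = estimate_travel_direction(head, head_axis=head_axis)

    n = landmarks.shape[0]
    angles = np.empty((n, 10))
    amps = np.empty((n, 11))
    ref_point = head.mean(axis=0)
    for i in range(n):
        lm = LandmarkSet(landmarks[i])
        angles[i] = segment_angles(lm, travel)
        amps[i] = amplitudes(lm, ref_point, travel)

    vel = velocities(landmarks, dt, travel, recording.body_length_mm, sg_window, sg_order)
    return KinematicProfile(
        times=times,
        landmarks=landmarks,
        segment_angles_deg=angles,
        amplitudes_mm=amps,
        v_axial_mm_s=vel["axial_mm_s"],
        v_lateral_mm_s=vel["lateral_mm_s"],
        v_resultant_mm_s=vel["resultant_mm_s"],
        travel_direction=travel,
        body_length_mm=recording.body_length_mm,
    )
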