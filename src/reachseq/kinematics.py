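"""Trajectory feature extraction for sequential reaching.

Implements the crossing-based coarticulation measures (halfway and
transitional crosses), signed curvature of the sampled path, speed-profile
segmentation at the speed minima inside the target circles, and the fusion
index quantifying how continuously two neighboring segments are executed.

Sign conventions
----------------
* halfway cross: positive when the crossing lies on the same side of the
  start-to-target center line as the *next* target ("inside" of the
  movement); for single-target trials (no next target), positive is left of
  the direction of travel.
* transitional cross: positive on the side of the smallest angle between the
  two center-to-center lines meeting at the target, i.e. when the trajectory
  cuts the corner; negative when it overshoots the turn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .geometry import SequenceGeometry
from .trajectory import Trajectory

__all__ = [
    "Trajectory",
    "CrossRecord",
    "SegmentSplit",
    "CrossingError",
    "halfway_cross",
    "transitional_cross",
    "signed_curvature",
    "max_curvature_in_target",
    "split_segments",
    "fusion_index",
    "trial_features",
]

#: default Savitzky-Golay smoothing window (samples) before differentiation
DEFAULT_SMOOTH_WINDOW = 7
#: turn angles below this (degrees) make the bisector direction degenerate
DEGENERATE_TURN_DEG = 5.0


class CrossingError(ValueError):
    """The trajectory never crosses the requested line."""


@dataclass(frozen=True)
class CrossRecord:
    trial: int
    index: int
    distance: float
    kind: str  # "halfway" | "transitional"
    n_crossings: int = 1


@dataclass(frozen=True)
class SegmentSplit:
    """Split indices at the per-target speed minima, plus normalized time."""

    split_indices: tuple[int, ...]
    segment_slices: tuple[tuple[int, int], ...]
    normalized_times: tuple[np.ndarray, ...]


def _perp(v: np.ndarray) -> np.ndarray:
    """Rotate a 2-vector 90 degrees counterclockwise."""
    return np.array([-v[1], v[0]])


def _line_crossings(
    positions: np.ndarray, point: np.ndarray, normal: np.ndarray
) -> list[np.ndarray]:
    """All crossing points of the polyline with the line through ``point``
    perpendicular to ``normal``-projected coordinate, in time order."""
    s = (positions - point) @ normal
    out = []
    for i in range(len(s) - 1):
        a, b = s[i], s[i + 1]
        if a == 0.0:
            out.append(positions[i])
        elif (a < 0 < b) or (b < 0 < a):
            w = a / (a - b)
            out.append(positions[i] + w * (positions[i + 1] - positions[i]))
    if len(s) and s[-1] == 0.0:
        out.append(positions[-1])
    return out


def halfway_cross(
    traj: Trajectory,
    p_from: np.ndarray,
    p_to: np.ndarray,
    p_next: np.ndarray | None = None,
) -> float:
    """Signed lateral offset (mm) where the path crosses the perpendicular
    at the midpoint of the ``p_from``-``p_to`` center line.

    Positive when on the same side as ``p_next``; with no next target,
    positive is left of travel.  The first crossing in time is used.
    """
    p_from = np.asarray(p_from, float)
    p_to = np.asarray(p_to, float)
    seg = p_to - p_from
    norm = np.linalg.norm(seg)
    if norm == 0:
        raise ValueError("p_from and p_to coincide")
    d_hat = seg / norm
    mid = 0.5 * (p_from + p_to)
    crossings = _line_crossings(traj.positions, mid, d_hat)
    if not crossings:
        raise CrossingError(
            f"trial {traj.trial}: trajectory never crosses the halfway line"
        )
    n_hat = _perp(d_hat)  # left of travel
    if p_next is not None:
        side = np.sign((np.asarray(p_next, float) - mid) @ n_hat)
        if side != 0:
            n_hat = side * n_hat
    return float((crossings[0] - mid) @ n_hat)


def _bisector(p_prev: np.ndarray, p_target: np.ndarray, p_next: np.ndarray) -> np.ndarray:
    """Unit direction of the interior angle bisector at ``p_target``.

    Points toward the inside of the turn (smallest angle between the two
    center-to-center lines).  Near-collinear geometry falls back to the
    normal of the mean travel direction.
    """
    a = p_prev - p_target
    c = p_next - p_target
    a = a / np.linalg.norm(a)
    c = c / np.linalg.norm(c)
    turn = np.degrees(np.pi - np.arccos(np.clip(a @ c, -1.0, 1.0)))
    b = a + c
    if turn < DEGENERATE_TURN_DEG or np.linalg.norm(b) < 1e-12:
        mean_dir = (-a) + c
        mean_dir = mean_dir / np.linalg.norm(mean_dir)
        return _perp(mean_dir)
    return b / np.linalg.norm(b)


def transitional_cross(
    traj: Trajectory,
    p_prev: np.ndarray,
    p_target: np.ndarray,
    p_next: np.ndarray,
) -> float:
    """Signed distance (mm) from the target center to the path's crossing of
    the interior angle bisector at the target.  Positive inside the turn."""
    p_prev = np.asarray(p_prev, float)
    p_target = np.asarray(p_target, float)
    p_next = np.asarray(p_next, float)
    b = _bisector(p_prev, p_target, p_next)
    n = _perp(b)
    crossings = _line_crossings(traj.positions, p_target, n)
    if not crossings:
        raise CrossingError(
            f"trial {traj.trial}: trajectory never crosses the bisector line"
        )
    return float((crossings[0] - p_target) @ b)


def _smoothed_xy(traj: Trajectory, smooth_window: int | None) -> np.ndarray:
    xy = traj.positions
    if smooth_window and smooth_window >= 5 and traj.n_samples >= smooth_window:
        xy = savgol_filter(xy, smooth_window, polyorder=3, axis=0)
    return xy


#: samples slower than this fraction of the trial's peak speed have no
#: well-defined path curvature (the hand is pausing, not turning)
SPEED_FLOOR_FRAC = 0.1


def signed_curvature(
    traj: Trajectory,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
    speed_floor_frac: float = SPEED_FLOOR_FRAC,
) -> np.ndarray:
    """Per-sample signed curvature (1/mm), ``C = (x'y'' - y'x'') / speed^3``.

    Derivatives are central finite differences after optional smoothing.
    The first and last samples are NaN, as are samples whose speed falls
    below ``speed_floor_frac`` of the trial's peak: when the hand (nearly)
    stops, the path direction is undefined and the ratio degenerates.
    """
    if traj.n_samples < 5:
        raise ValueError("need at least 5 samples for curvature")
    xy = _smoothed_xy(traj, smooth_window)
    t = traj.times
    x1 = np.gradient(xy[:, 0], t)
    y1 = np.gradient(xy[:, 1], t)
    x2 = np.gradient(x1, t)
    y2 = np.gradient(y1, t)
    speed2 = x1**2 + y1**2
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = (x1 * y2 - y1 * x2) / speed2**1.5
    floor2 = speed_floor_frac**2 * np.max(speed2)
    curv[speed2 <= floor2] = np.nan
    curv[0] = curv[-1] = np.nan
    return curv


def max_curvature_in_target(
    traj: Trajectory,
    target,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
    speed_floor_frac: float = SPEED_FLOOR_FRAC,
) -> float:
    """Maximum absolute curvature over samples inside the target circle."""
    inside = target.contains(traj.positions)
    if not np.any(inside):
        raise ValueError(
            f"trial {traj.trial}: trajectory never enters target '{target.label}'"
        )
    curv = np.abs(signed_curvature(traj, smooth_window, speed_floor_frac))
    vals = curv[inside]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError(f"trial {traj.trial}: no defined curvature inside target")
    return float(np.max(vals))


def split_segments(traj: Trajectory, geometry: SequenceGeometry) -> SegmentSplit:
    """Split the trial at the speed minimum inside each intermediate target.

    Segments partition the samples; per-segment time is normalized to [0, 1].
    """
    speed = traj.speed()
    splits = []
    prev = 0
    for tgt in geometry.targets[:-1]:
        inside = np.flatnonzero(tgt.contains(traj.positions))
        inside = inside[inside >= prev]
        if inside.size == 0:
            raise ValueError(
                f"trial {traj.trial}: trajectory does not visit target '{tgt.label}'"
            )
        idx = int(inside[np.argmin(speed[inside])])
        splits.append(idx)
        prev = idx
    # final target visit check
    last = geometry.targets[-1]
    if not np.any(last.contains(traj.positions)):
        raise ValueError(
            f"trial {traj.trial}: trajectory does not visit target '{last.label}'"
        )
    bounds = [0, *splits, traj.n_samples - 1]
    slices = tuple((bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1))
    normed = []
    for a, b in slices:
        tt = traj.times[a : b + 1]
        span = tt[-1] - tt[0]
        normed.append((tt - tt[0]) / span if span > 0 else np.zeros_like(tt))
    return SegmentSplit(
        split_indices=tuple(splits),
        segment_slices=slices,
        normalized_times=tuple(normed),
    )


def fusion_index(traj: Trajectory, target_index: int, geometry: SequenceGeometry) -> float:
    """Fusion index at an intermediate target, in [0, 1].

    ``F = v_min / mean(v_max_before, v_max_after)`` where ``v_min`` is the
    minimum speed inside the target circle and the peaks are per-segment
    maxima; 1 means a fully fused pass-through, 0 a full stop.
    """
    if not (0 <= target_index < geometry.n_targets - 1):
        raise ValueError("fusion index is defined for intermediate targets only")
    split = split_segments(traj, geometry)
    speed = traj.speed()
    a0, b0 = split.segment_slices[target_index]
    a1, b1 = split.segment_slices[target_index + 1]
    v1 = float(np.max(speed[a0 : b0 + 1]))
    v2 = float(np.max(speed[a1 : b1 + 1]))
    if v1 <= 0 or v2 <= 0:
        raise ValueError("zero peak speed: fusion index undefined")
    tgt = geometry.targets[target_index]
    inside = tgt.contains(traj.positions)
    v_min = float(np.min(speed[inside]))
    mean_peak = 0.5 * (v1 + v2)
    return float(np.clip(v_min / mean_peak, 0.0, 1.0))


def trial_features(
    traj: Trajectory,
    geometry: SequenceGeometry,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
) -> dict:
    """Standard feature set of one 3-target sequential trial.

    Returns hc1 (halfway cross, first segment), tc1 (transitional cross at
    the first target), maxcurv1/maxcurv2 (max |curvature| inside the first
    and second target circles), and fusion1/fusion2 at intermediate targets.
    """
    wp = geometry.waypoints()
    out = {
        "trial": traj.trial,
        "sequence": traj.sequence_id,
        "tag": traj.tag,
        "hc1": halfway_cross(traj, wp[0], wp[1], wp[2] if len(wp) > 2 else None),
    }
    if geometry.n_targets >= 2:
        out["tc1"] = transitional_cross(traj, wp[0], wp[1], wp[2])
        out["maxcurv1"] = max_curvature_in_target(traj, geometry.targets[0], smooth_window)
        out["maxcurv2"] = max_curvature_in_target(traj, geometry.targets[1], smooth_window)
        try:
            out["fusion1"] = fusion_index(traj, 0, geometry)
        except ValueError:
            out["fusion1"] = np.nan
        if geometry.n_targets >= 3:
            try:
                out["fusion2"] = fusion_index(traj, 1, geometry)
            except ValueError:
                out["fusion2"] = np.nan
    return out
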