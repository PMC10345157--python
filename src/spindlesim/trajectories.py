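"""Parametric closed end-point trajectories for the planar limb.

Five tasks — circle, line, oscillatory, lemniscate, square — each a closed
loop of ``n_points`` equidistant points traversed in one cycle (1 s), in a
forward or reverse direction.  Shapes are generated as dense parametric
polylines and then resampled to equal arc-length spacing, so the end point
moves at constant speed along each path.

Default task geometry: a 5 mm diameter circle traversed clockwise, a 12 mm
there-and-back line on a 50 % (26.57 deg) incline, a 10 Hz sinusoid of
20 mm amplitude swept over a 40 mm horizontal extent, a figure-eight
(1:2 Lissajous) rescaled so its taller lobe pair spans 20 mm, and a 5 mm
axis-aligned square traversed counterclockwise.  All tasks are centered on
the workspace center (by default the end-point position at the reference
posture) so that every sample is reachable by the limb.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .config import TASKS, LimbGeometry, TrajectoryParams
from .errors import (
    DegeneratePathError,
    InvalidResolutionError,
    InvalidTaskError,
)

_DENSE = 8192  # raw parametric samples before arc-length resampling


@dataclass(frozen=True)
class TaskTrajectory:
    """A closed 2-D end-point path: ``points`` has shape (n_points, 2) in
    mm, the closure segment from the last point back to the first being
    implicit."""

    task_id: str
    direction: str
    points: np.ndarray
    n_points: int = 200
    cycle_duration: float = 1.0

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, [0, cycle_duration)."""
        return np.arange(self.n_points) * self.cycle_duration / self.n_points


def path_length(path: np.ndarray, closed: bool = True) -> float:
    """Total Euclidean arc length of a polyline, in mm.

    For closed paths the closure segment (last point back to the first)
    is included.
    """
    p = np.asarray(path, dtype=float)
    if p.ndim != 2 or len(p) == 0:
        raise ValueError("path must be a non-empty (n, 2) array")
    if len(p) == 1:
        return 0.0
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    total = float(seg.sum())
    if closed:
        total += float(np.linalg.norm(p[0] - p[-1]))
    return total


def resample_equidistant(path: np.ndarray, n: int, closed: bool = True) -> np.ndarray:
    """Resample a polyline to ``n`` points with equal arc-length spacing.

    Piecewise-linear interpolation along the cumulative chord length;
    preserves the start point and traversal order.  For closed curves the
    n points sit at arc fractions k/n of the closed length (the implicit
    closure segment completes the cycle); for open curves they span the
    full length inclusively.
    """
    p = np.asarray(path, dtype=float)
    if p.ndim != 2 or len(p) < 2:
        raise DegeneratePathError("need at least two points to resample")
    if closed:
        p = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    total = cum[-1]
    if total <= 0.0:
        raise DegeneratePathError("zero-length path")
    if closed:
        targets = total * np.arange(n) / n
    else:
        targets = np.linspace(0.0, total, n)
    x = np.interp(targets, cum, p[:, 0])
    y = np.interp(targets, cum, p[:, 1])
    return np.stack([x, y], axis=1)


# ---------------------------------------------------------------------------
# shape builders (dense polylines, forward direction)

def _circle(params: TrajectoryParams, center) -> np.ndarray:
    r = params.circle_diameter / 2.0
    # clockwise: angle decreases with time; start at the rightmost point
    th = -2.0 * np.pi * np.arange(_DENSE) / _DENSE
    return np.stack([center[0] + r * np.cos(th),
                     center[1] + r * np.sin(th)], axis=1)


def _line(params: TrajectoryParams, center) -> np.ndarray:
    mid = params.line_midpoint if params.line_midpoint is not None else center
    ang = np.radians(params.line_incline_deg)
    u = np.array([np.cos(ang), np.sin(ang)])
    half = params.line_length_one_way / 2.0
    a = np.asarray(mid) - half * u   # lower-left end: forward goes rightward
    b = np.asarray(mid) + half * u
    return np.vstack([a, b, a])      # there-and-back closed cycle


def _oscillatory(params: TrajectoryParams, center) -> np.ndarray:
    """Sinusoidal wave swept left-to-right across the extent and retraced.

    The waveform is ``oscillatory_spatial_periods`` periods of the
    generating sine A sin(2 pi f t) mapped onto the sweep (one period by
    default: the end point traces the arch out and back, closing the
    loop).  The generating frequency f sets the sine's own time base and
    cancels out of the spatial shape; the number of spatial repetitions
    per cycle is the explicit parameter.
    """
    t = np.arange(_DENSE) / _DENSE
    # x sweeps left-to-right during the forward half cycle and back
    tri = np.where(t < 0.5, 2.0 * t, 2.0 * (1.0 - t))
    x = center[0] - params.oscillatory_extent / 2.0 \
        + params.oscillatory_extent * tri
    phase = 2.0 * np.pi * params.oscillatory_spatial_periods * tri
    y = center[1] + params.oscillatory_amplitude * np.sin(phase)
    return np.stack([x, y], axis=1)


#: printed figure-eight coefficients, meters (x amplitude, y amplitude,
#: y offset); converted to mm and uniformly rescaled to the workspace.
LEMNISCATE_COEFF_M = (4e-2, 5e-1, 2e-1, 11e-2)


def _lemniscate(params: TrajectoryParams, center) -> np.ndarray:
    ax_m, xrate, ay_m, y0_m = LEMNISCATE_COEFF_M
    u = 4.0 * np.pi * np.arange(_DENSE) / _DENSE   # x has period 4*pi
    x = 1000.0 * ax_m * np.sin(xrate * u)
    y = 1000.0 * (ay_m * np.sin(u) + y0_m)
    # literal coefficients span 400 mm vertically, unreachable for a
    # 190 mm limb: rescale uniformly so the taller dimension matches the
    # configured lobe height, then translate to the workspace center.
    scale = params.lemniscate_height / (y.max() - y.min())
    x = center[0] + scale * (x - (x.max() + x.min()) / 2.0)
    y = center[1] + scale * (y - (y.max() + y.min()) / 2.0)
    return np.stack([x, y], axis=1)


def _square(params: TrajectoryParams, center) -> np.ndarray:
    h = params.square_side / 2.0
    cx, cy = center
    # counterclockwise from the bottom-right corner
    return np.array([
        [cx + h, cy - h],
        [cx + h, cy + h],
        [cx - h, cy + h],
        [cx - h, cy - h],
        [cx + h, cy - h],
    ])


_BUILDERS = {
    "circle": _circle,
    "line": _line,
    "oscillatory": _oscillatory,
    "lemniscate": _lemniscate,
    "square": _square,
}


# ---------------------------------------------------------------------------
# public operations

def reverse(traj: TaskTrajectory) -> TaskTrajectory:
    """Same point set traversed in the opposite temporal order, starting
    from the same initial point, with the direction flag flipped."""
    pts = np.vstack([traj.points[:1], traj.points[:0:-1]])
    flipped = "REV" if traj.direction == "FWD" else "FWD"
    return replace(traj, points=pts, direction=flipped)


def generate_trajectory(
    task_id: str,
    params: TrajectoryParams | None = None,
    n_points: int | None = None,
    direction: str = "FWD",
    geom: LimbGeometry | None = None,
) -> TaskTrajectory:
    """Build one closed task trajectory.

    ``geom`` is only consulted when ``params.workspace_center`` is None,
    in which case the center defaults to the end-point position at the
    reference posture of ``geom`` (or of the default limb).
    """
    params = params or TrajectoryParams()
    n = n_points if n_points is not None else params.n_points
    if task_id not in TASKS:
        raise InvalidTaskError(f"unknown task {task_id!r}; expected one of {TASKS}")
    if n < 4:
        raise InvalidResolutionError(f"n_points must be >= 4, got {n}")
    if direction not in ("FWD", "REV"):
        raise ValueError(f"direction must be FWD or REV, got {direction!r}")
    for name in ("circle_diameter", "line_length_one_way",
                 "oscillatory_amplitude", "oscillatory_extent",
                 "lemniscate_height", "square_side"):
        if getattr(params, name) <= 0:
            raise ValueError(f"{name} must be strictly positive")
    center = params.workspace_center
    if center is None:
        from .kinematics import reference_endpoint
        center = reference_endpoint(geom or LimbGeometry())
    dense = _BUILDERS[task_id](params, center)
    pts = resample_equidistant(dense, n, closed=True)
    traj = TaskTrajectory(task_id=task_id, direction="FWD", points=pts,
                          n_points=n, cycle_duration=params.cycle_duration)
    if direction == "REV":
        traj = reverse(traj)
    return traj


def generate_all_conditions(
    params: TrajectoryParams | None = None,
    geom: LimbGeometry | None = None,
    tasks=TASKS,
) -> dict[tuple[str, str], TaskTrajectory]:
    """All task x direction conditions in canonical order."""
    out = {}
    for task in tasks:
        fwd = generate_trajectory(task, params, direction="FWD", geom=geom)
        out[(task, "FWD")] = fwd
        out[(task, "REV")] = reverse(fwd)
    return out


def trajectory_to_csv(traj: TaskTrajectory, path) -> None:
    pd.DataFrame({
        "t_s": traj.times,
        "x_mm": traj.points[:, 0],
        "y_mm": traj.points[:, 1],
    }).to_csv(path, index=False)


def trajectory_from_csv(path, task_id: str = "circle",
                        direction: str = "FWD") -> TaskTrajectory:
    df = pd.read_csv(path)
    pts = df[["x_mm", "y_mm"]].to_numpy(dtype=float)
    dur = float(df["t_s"].iloc[-1] - df["t_s"].iloc[0]) * len(df) / max(len(df) - 1, 1)
    return TaskTrajectory(task_id=task_id, direction=direction, points=pts,
                          n_points=len(pts), cycle_duration=round(dur, 9))
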