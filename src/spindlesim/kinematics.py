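"""Planar 2-link limb kinematics and musculotendon length series.

The limb is a hip-rooted two-link chain (thigh l1, shank l2).  Internally
q1 is the thigh angle from the +x axis of the hip frame and q2 is the
"elbow" angle of the chain (0 = fully extended), related to the anatomical
interior knee angle by ``interior = 180 deg - q2``.  Hip flexion increases
q1 and knee flexion increases q2; under that convention the Table of
signed constant moment arms maps linearly onto musculotendon length:

    L_mt,m(q) = L_ref,m + r_m,hip (q1 - q1_ref) + r_m,knee (q2 - q2_ref)

so each muscle shortens during its named action (dL/dq = +/- r, the
defining property of a constant moment arm).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MUSCLES, ExperimentConfig, LimbGeometry, MuscleParams
from .errors import (
    AnatomicalRangeError,
    OutOfWorkspaceError,
    SingularConfigurationError,
)
from .trajectories import TaskTrajectory

log = logging.getLogger(__name__)


@dataclass
class JointTrajectory:
    """Hip/knee angle series (radians, internal convention) at fs Hz."""

    q1: np.ndarray
    q2: np.ndarray
    fs: float
    task_id: str | None = None
    direction: str | None = None

    def __post_init__(self):
        if len(self.q1) != len(self.q2):
            raise ValueError("q1 and q2 must have equal length")


@dataclass
class MuscleKinematics:
    """Per-muscle normalized fascicle kinematics over warm-up + analysis
    cycles.

    ``L_ce`` is musculotendon length normalized to the optimal length L_O
    (dimensionless), ``V_ce``/``A_ce`` its first/second time derivatives
    (per s, per s^2).  Arrays span ``(warmup_cycles + 1) * n_cycle``
    samples; the final ``n_cycle`` samples are the analysis cycle.
    """

    L_mt: dict[str, np.ndarray]
    L_ce: dict[str, np.ndarray]
    V_ce: dict[str, np.ndarray]
    A_ce: dict[str, np.ndarray]
    fs: float
    n_cycle: int
    warmup_cycles: int
    task_id: str | None = None
    direction: str | None = None
    muscle_order: tuple[str, ...] = field(default=MUSCLES)


# ---------------------------------------------------------------------------
# forward / inverse kinematics

def forward_kinematics(q1, q2, geom: LimbGeometry):
    """End-effector position (mm) of the chain; accepts scalars or arrays."""
    q1 = np.asarray(q1, dtype=float)
    q2 = np.asarray(q2, dtype=float)
    hx, hy = geom.hip_position
    x = hx + geom.l1 * np.cos(q1) + geom.l2 * np.cos(q1 + q2)
    y = hy + geom.l1 * np.sin(q1) + geom.l2 * np.sin(q1 + q2)
    return np.stack([x, y], axis=-1)


def inverse_kinematics(point, geom: LimbGeometry):
    """Closed-form joint angles for end-point targets.

    Uses the non-negative elbow branch: q2 = acos(c) in [0, pi] with
    c = (x^2 + y^2 - l1^2 - l2^2) / (2 l1 l2), and q1 from the matching
    two-argument arctangent form of the printed arcsine relation (same
    branch, quadrant-safe).  Raises for unreachable or singular targets.
    """
    p = np.asarray(point, dtype=float)
    scalar = p.ndim == 1
    p = np.atleast_2d(p)
    x = p[:, 0] - geom.hip_position[0]
    y = p[:, 1] - geom.hip_position[1]
    r2 = x * x + y * y
    if np.any(r2 == 0.0):
        raise SingularConfigurationError("end point coincides with the hip")
    c = (r2 - geom.l1**2 - geom.l2**2) / (2.0 * geom.l1 * geom.l2)
    if np.any(np.abs(c) > 1.0 + 1e-12):
        bad = float(np.max(np.abs(c)))
        raise OutOfWorkspaceError(
            f"target outside reachable annulus (|c| = {bad:.6f} > 1)")
    c = np.clip(c, -1.0, 1.0)
    s = np.sqrt(1.0 - c * c)
    q2 = np.arccos(c)
    q1 = np.arctan2(y, x) - np.arctan2(geom.l2 * s, geom.l1 + geom.l2 * c)
    if scalar:
        return float(q1[0]), float(q2[0])
    return q1, q2


def joint_trajectory(traj: TaskTrajectory, geom: LimbGeometry) -> JointTrajectory:
    """Inverse kinematics applied sample-by-sample to a task trajectory."""
    q1, q2 = inverse_kinematics(traj.points, geom)
    fs = traj.n_points / traj.cycle_duration
    return JointTrajectory(q1=q1, q2=q2, fs=fs,
                           task_id=traj.task_id, direction=traj.direction)


# ---------------------------------------------------------------------------
# musculotendon lengths

def muscle_lengths(
    q1,
    q2,
    muscles: tuple[MuscleParams, ...],
    geom: LimbGeometry,
    joint_limits_deg: dict | None = None,
    strict_bounds: bool = False,
) -> dict[str, np.ndarray]:
    """Linear constant-moment-arm length map for every muscle, in mm.

    Lengths <= 0 always raise.  Lengths above L_max raise only under
    ``strict_bounds``; otherwise they are logged, because the study's
    largest tasks legitimately stretch IL/SM a few mm past L_max.
    """
    q1 = np.atleast_1d(np.asarray(q1, dtype=float))
    q2 = np.atleast_1d(np.asarray(q2, dtype=float))
    if joint_limits_deg is not None:
        hip_lo, hip_hi = (math.radians(v) for v in joint_limits_deg["hip"])
        knee_lo, knee_hi = (math.radians(v) for v in joint_limits_deg["knee"])
        interior = math.pi - q2
        if np.any(q1 < hip_lo) or np.any(q1 > hip_hi):
            raise AnatomicalRangeError(
                f"hip angle outside limits "
                f"[{math.degrees(hip_lo):.0f}, {math.degrees(hip_hi):.0f}] deg")
        if np.any(interior < knee_lo) or np.any(interior > knee_hi):
            raise AnatomicalRangeError("knee interior angle outside limits")
    q1_ref, q2_ref = geom.q_ref
    out: dict[str, np.ndarray] = {}
    for m in muscles:
        L = (m.L_ref
             + m.moment_arm_hip * (q1 - q1_ref)
             + m.moment_arm_knee * (q2 - q2_ref))
        if np.any(L <= 0.0):
            raise AnatomicalRangeError(
                f"{m.name}: non-positive musculotendon length")
        if np.any(L > m.L_max):
            msg = (f"{m.name}: L_mt peaks at {float(L.max()):.2f} mm, above "
                   f"L_max = {m.L_max:.0f} mm")
            if strict_bounds:
                raise AnatomicalRangeError(msg)
            log.warning(msg)
        out[m.name] = L
    return out


def _cyclic_derivatives(x: np.ndarray, fs: float):
    """Central finite differences with periodic wrap on one cycle."""
    xp = np.roll(x, -1)
    xm = np.roll(x, 1)
    v = (xp - xm) * fs / 2.0
    a = (xp - 2.0 * x + xm) * fs * fs
    return v, a


def kinematics_series(
    jt: JointTrajectory,
    muscles: tuple[MuscleParams, ...],
    geom: LimbGeometry,
    warmup_cycles: int = 2,
    joint_limits_deg: dict | None = None,
    strict_bounds: bool = False,
) -> MuscleKinematics:
    """Normalized fascicle length/velocity/acceleration over warm-up plus
    analysis cycles.

    The joint series is one closed cycle; derivatives use central
    differences with periodic wrap, then the per-cycle series is tiled
    ``warmup_cycles + 1`` times (the limb repeats the loop), giving the
    spindle model time to wash out its initial-condition transient.
    """
    if len(jt.q1) < 2:
        raise ValueError("joint trajectory must span at least one cycle")
    lengths = muscle_lengths(jt.q1, jt.q2, muscles, geom,
                             joint_limits_deg=joint_limits_deg,
                             strict_bounds=strict_bounds)
    reps = warmup_cycles + 1
    L_mt, L_ce, V_ce, A_ce = {}, {}, {}, {}
    for m in muscles:
        L = lengths[m.name]
        lce = L / m.L_ref
        v, a = _cyclic_derivatives(lce, jt.fs)
        L_mt[m.name] = np.tile(L, reps)
        L_ce[m.name] = np.tile(lce, reps)
        V_ce[m.name] = np.tile(v, reps)
        A_ce[m.name] = np.tile(a, reps)
    return MuscleKinematics(
        L_mt=L_mt, L_ce=L_ce, V_ce=V_ce, A_ce=A_ce,
        fs=jt.fs, n_cycle=len(jt.q1), warmup_cycles=warmup_cycles,
        task_id=jt.task_id, direction=jt.direction,
        muscle_order=tuple(m.name for m in muscles),
    )


# ---------------------------------------------------------------------------
# exports

def joint_trajectory_to_csv(jt: JointTrajectory, path) -> None:
    t = np.arange(len(jt.q1)) / jt.fs
    pd.DataFrame({
        "t_s": t,
        "q1_deg": np.degrees(jt.q1),
        "q2_deg": np.degrees(jt.q2),
    }).to_csv(path, index=False)


def muscle_kinematics_to_csv(mk: MuscleKinematics, path) -> None:
    """Final analysis cycle only, one column per muscle and quantity."""
    sl = slice(mk.warmup_cycles * mk.n_cycle, None)
    t = np.arange(mk.n_cycle) / mk.fs
    cols = {"t_s": t}
    for name in mk.muscle_order:
        cols[f"{name}_L_ce"] = mk.L_ce[name][sl]
        cols[f"{name}_V_ce"] = mk.V_ce[name][sl]
        cols[f"{name}_A_ce"] = mk.A_ce[name][sl]
    pd.DataFrame(cols).to_csv(path, index=False)


def reference_endpoint(geom: LimbGeometry) -> tuple[float, float]:
    """End-effector position at the reference posture (default workspace
    center for all tasks)."""
    q1, q2 = geom.q_ref
    p = forward_kinematics(q1, q2, geom)
    return float(p[0]), float(p[1])


def default_config_center(config: ExperimentConfig) -> tuple[float, float]:
    wc = config.trajectories.workspace_center
    return wc if wc is not None else reference_endpoint(config.geometry)
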