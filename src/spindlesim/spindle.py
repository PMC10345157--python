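"""Muscle-spindle afferent model: intrafusal fiber dynamics and Ia/II
firing rates.

Each spindle contains three intrafusal fibers (bag1, bag2, chain).  The
stretch of a fiber's sensory region, T / K_SR, follows a second-order
tension dynamic driven by the fascicle kinematics (L_ce, V_ce, A_ce, all
normalized to the optimal length L_O):

    T'' = (K_SR / M) * [ C * beta * sign(dv) * |dv|^a * (L - L0_SR - T/K_SR - R)
                         + K_PR * (L - L0_SR - T/K_SR - L0_PR)
                         + M * A + Gamma - T ],      dv = V - T'/K_SR

where beta is the polar-region damping (asymmetric: C = C_L when the
polar region lengthens, C_S when it shortens) and Gamma the active force
contributed by fusimotor drive.  Dynamic gamma drive acts on bag1, static
drive on bag2 and chain, through a saturating activation
f = gamma^2 / (gamma^2 + freq^2); drives are constant within a run so the
activation is held at its steady value.

Afferent potentials (pps, may be negative; firing rates are the
non-negative clamp):

    primary(fiber)   = G * (T/K_SR - (LN_SR - L0_SR))
    secondary(fiber) = G_sec * [ X * (L_sec/L0_SR) * (T/K_SR - (LN_SR - L0_SR))
                                 + (1 - X) * (L_sec/L0_PR)
                                   * (L - T/K_SR - L0_SR - LN_PR) ]

The Ia rate combines the bag1 branch with the (bag2 + chain) branch under
partial occlusion: the larger branch transmits fully, the smaller at a
fraction S.  The II rate sums the bag2 and chain secondary endings.

Integration is a fixed-step classical Runge-Kutta (RK4) at the sampling
rate with ``substeps`` internal steps per sample, inputs linearly
interpolated between samples; fully deterministic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MUSCLES, FiberParams, SpindleConfig, default_fibers
from .errors import IntegrationFailureError
from .kinematics import MuscleKinematics

log = logging.getLogger(__name__)

FIBER_ORDER = ("bag1", "bag2", "chain")

#: fixed 8-channel ordering of an afferent ensemble
CHANNELS = tuple(f"{m}_Ia" for m in MUSCLES) + tuple(f"{m}_II" for m in MUSCLES)


@dataclass
class SpindleInput:
    """Fascicle kinematics plus fusimotor drive for one muscle."""

    L_ce: np.ndarray
    V_ce: np.ndarray
    A_ce: np.ndarray
    fs: float
    gamma_dynamic: float = 0.0
    gamma_static: float = 0.0

    def __post_init__(self):
        n = len(self.L_ce)
        if len(self.V_ce) != n or len(self.A_ce) != n:
            raise ValueError("L_ce, V_ce, A_ce must have equal length")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.gamma_dynamic < 0 or self.gamma_static < 0:
            raise ValueError("gamma drives must be non-negative")


@dataclass
class AfferentPair:
    """Ia and II firing-rate series (pps, clamped >= 0) for one muscle."""

    Ia: np.ndarray
    II: np.ndarray
    muscle: str


@dataclass
class AfferentEnsemble:
    """8-channel firing-rate ensemble (4 muscles x {Ia, II}) for one
    task-direction condition; ``data`` has shape (n, 8) in pps."""

    data: np.ndarray
    fs: float
    task_id: str | None = None
    direction: str | None = None
    channel_names: tuple[str, ...] = field(default=CHANNELS)

    def channel(self, name: str) -> np.ndarray:
        return self.data[:, self.channel_names.index(name)]

    def muscle_pair(self, muscle: str) -> np.ndarray:
        """(n, 2) array of the muscle's Ia and II channels."""
        return np.stack(
            [self.channel(f"{muscle}_Ia"), self.channel(f"{muscle}_II")],
            axis=1)


# ---------------------------------------------------------------------------
# fiber dynamics

def _lane_arrays(fibers: list[FiberParams]):
    """Stack per-fiber constants into vectorized 'lane' arrays."""
    def col(attr):
        return np.array([getattr(f, attr) for f in fibers], dtype=float)
    keys = ("K_SR", "K_PR", "M", "beta0", "beta_gamma", "gamma_force",
            "C_L", "C_S", "a", "R", "L0_SR", "L0_PR", "LN_SR", "LN_PR",
            "G_primary", "G_secondary", "X", "L_secondary", "freq")
    lanes = {k: col(k) for k in keys}
    lanes["uses_dynamic"] = np.array(
        [f.uses_dynamic_drive for f in fibers], dtype=bool)
    return lanes


def _activation(lanes, gamma_dynamic: float, gamma_static: float):
    """Steady fusimotor activation per lane (drives constant in a run)."""
    gamma = np.where(lanes["uses_dynamic"], gamma_dynamic, gamma_static)
    return gamma**2 / (gamma**2 + lanes["freq"] ** 2)


def _tension_rhs(T, Td, L, V, A, lanes, beta, Gamma):
    """Right-hand side of the tension ODE, vectorized over lanes."""
    dv = V - Td / lanes["K_SR"]
    C = np.where(dv >= 0.0, lanes["C_L"], lanes["C_S"])
    damping = (C * beta * np.sign(dv) * np.abs(dv) ** lanes["a"]
               * (L - lanes["L0_SR"] - T / lanes["K_SR"] - lanes["R"]))
    spring = lanes["K_PR"] * (L - lanes["L0_SR"] - T / lanes["K_SR"]
                              - lanes["L0_PR"])
    Tdd = (lanes["K_SR"] / lanes["M"]) * (
        damping + spring + lanes["M"] * A + Gamma - T)
    return Td, Tdd


def _steady_tension(L0, lanes, Gamma):
    """Fixed point of the tension ODE at constant length, zero velocity."""
    num = lanes["K_PR"] * (L0 - lanes["L0_SR"] - lanes["L0_PR"]) + Gamma
    return num / (1.0 + lanes["K_PR"] / lanes["K_SR"])


def integrate_intrafusal(
    L: np.ndarray,
    V: np.ndarray,
    A: np.ndarray,
    fs: float,
    fibers: list[FiberParams],
    gamma_dynamic: float = 0.0,
    gamma_static: float = 0.0,
    substeps: int = 20,
):
    """Integrate the intrafusal tension ODEs over a sampled input.

    ``L, V, A`` may be 1-D (one muscle) or 2-D with shape (n, m) to run m
    muscles in parallel lanes sharing the same fiber set.  Returns the
    tension series T with shape (n, n_fibers) or (n, n_fibers, m).
    Initial state is the passive fixed point at the first sample, so the
    transient to be washed out by warm-up cycles is small.
    """
    L = np.asarray(L, dtype=float)
    V = np.asarray(V, dtype=float)
    A = np.asarray(A, dtype=float)
    squeeze = L.ndim == 1
    if squeeze:
        L, V, A = L[:, None], V[:, None], A[:, None]
    n, m = L.shape
    lanes = _lane_arrays(fibers)
    f_act = _activation(lanes, gamma_dynamic, gamma_static)[:, None]
    lanes = {k: v[:, None] for k, v in lanes.items()}        # (nf, 1)
    beta = lanes["beta0"] + lanes["beta_gamma"] * f_act
    Gamma = lanes["gamma_force"] * f_act

    T = np.broadcast_to(_steady_tension(L[0][None, :], lanes, Gamma),
                        (len(fibers), m)).copy()
    Td = np.zeros_like(T)
    out = np.empty((n, len(fibers), m), dtype=float)
    out[0] = T
    h = 1.0 / (fs * substeps)
    for i in range(n - 1):
        La, Va, Aa = L[i][None, :], V[i][None, :], A[i][None, :]
        dL = (L[i + 1] - L[i])[None, :] / substeps
        dV = (V[i + 1] - V[i])[None, :] / substeps
        dA = (A[i + 1] - A[i])[None, :] / substeps
        for s in range(substeps):
            L0s, V0s, A0s = La + s * dL, Va + s * dV, Aa + s * dA
            Lh, Vh, Ah = L0s + 0.5 * dL, V0s + 0.5 * dV, A0s + 0.5 * dA
            L1s, V1s, A1s = L0s + dL, V0s + dV, A0s + dA
            k1t, k1d = _tension_rhs(T, Td, L0s, V0s, A0s, lanes, beta, Gamma)
            k2t, k2d = _tension_rhs(T + 0.5 * h * k1t, Td + 0.5 * h * k1d,
                                    Lh, Vh, Ah, lanes, beta, Gamma)
            k3t, k3d = _tension_rhs(T + 0.5 * h * k2t, Td + 0.5 * h * k2d,
                                    Lh, Vh, Ah, lanes, beta, Gamma)
            k4t, k4d = _tension_rhs(T + h * k3t, Td + h * k3d,
                                    L1s, V1s, A1s, lanes, beta, Gamma)
            T = T + (h / 6.0) * (k1t + 2 * k2t + 2 * k3t + k4t)
            Td = Td + (h / 6.0) * (k1d + 2 * k2d + 2 * k3d + k4d)
        if not (np.all(np.isfinite(T)) and np.all(np.isfinite(Td))):
            bad = np.argwhere(~np.isfinite(T))
            fiber = FIBER_ORDER[bad[0][0]] if len(bad) else "?"
            raise IntegrationFailureError(
                f"non-finite tension in fiber {fiber} at sample {i + 1}")
        out[i + 1] = T
    if squeeze:
        return out[:, :, 0]
    return out


# ---------------------------------------------------------------------------
# afferent potentials

def ia_afferent_potential(T, fiber: FiberParams):
    """Primary afferent potential of one fiber (pps, unclamped):
    G * (T/K_SR - (LN_SR - L0_SR))."""
    return fiber.G_primary * (
        np.asarray(T) / fiber.K_SR - (fiber.LN_SR - fiber.L0_SR))


def ii_afferent_potential(T, L, fiber: FiberParams):
    """Secondary afferent potential of one fiber (pps, unclamped).

    Two stretch terms weighted by the fraction X of the ending on the
    sensory region: sensory-region stretch relative to its threshold, and
    polar-region stretch L - T/K_SR - L0_SR relative to LN_PR.
    """
    T = np.asarray(T)
    L = np.asarray(L)
    sensory = (fiber.L_secondary / fiber.L0_SR) * (
        T / fiber.K_SR - (fiber.LN_SR - fiber.L0_SR))
    polar = (fiber.L_secondary / fiber.L0_PR) * (
        L - T / fiber.K_SR - fiber.L0_SR - fiber.LN_PR)
    return fiber.G_secondary * (fiber.X * sensory + (1.0 - fiber.X) * polar)


def _combine_primary(pot_bag1, pot_bag2c, occlusion: float):
    """Partial-occlusion combination of the two Ia encoding branches."""
    lo = np.minimum(pot_bag1, pot_bag2c)
    hi = np.maximum(pot_bag1, pot_bag2c)
    return hi + occlusion * lo


def simulate_spindle(
    inp: SpindleInput,
    cfg: SpindleConfig | None = None,
    muscle: str = "",
    n_analysis: int | None = None,
) -> AfferentPair:
    """Run one spindle over its full input and return Ia/II firing rates.

    When ``n_analysis`` is given, only the final ``n_analysis`` samples
    (the analyzed cycle after warm-up) are returned.
    """
    cfg = cfg or SpindleConfig()
    fibers = [cfg.fibers[name] for name in FIBER_ORDER]
    T = integrate_intrafusal(
        inp.L_ce, inp.V_ce, inp.A_ce, inp.fs, fibers,
        gamma_dynamic=inp.gamma_dynamic, gamma_static=inp.gamma_static,
        substeps=cfg.substeps)
    ia, ii = _rates_from_tension(T, inp.L_ce, fibers, cfg)
    if n_analysis is not None:
        ia, ii = ia[-n_analysis:], ii[-n_analysis:]
    _warn_cap(ia, ii, muscle or "spindle", cfg)
    return AfferentPair(Ia=ia, II=ii, muscle=muscle)


def _rates_from_tension(T, L, fibers, cfg: SpindleConfig):
    """Map tension series (n, 3[, m]) to clamped Ia/II rates."""
    b1, b2, ch = fibers
    pot_b1 = ia_afferent_potential(T[:, 0], b1)
    pot_b2c = (ia_afferent_potential(T[:, 1], b2)
               + ia_afferent_potential(T[:, 2], ch))
    ia = np.maximum(_combine_primary(pot_b1, pot_b2c, cfg.occlusion), 0.0)
    ii_pot = (ii_afferent_potential(T[:, 1], L, b2)
              + ii_afferent_potential(T[:, 2], L, ch))
    ii = np.maximum(ii_pot, 0.0)
    return ia, ii


def _warn_cap(ia, ii, label, cfg: SpindleConfig):
    peak = max(float(np.max(ia)), float(np.max(ii)))
    if peak > cfg.rate_cap_warn:
        log.warning("%s: firing rate %.0f pps exceeds the %.0f pps "
                    "physiological cap", label, peak, cfg.rate_cap_warn)


def simulate_ensemble(
    mk: MuscleKinematics,
    cfg: SpindleConfig | None = None,
) -> AfferentEnsemble:
    """Simulate all four muscles' spindles and assemble the 8-channel
    ensemble for the analyzed (final) cycle.

    Muscles run as independent parallel lanes of one vectorized
    integration; outputs are identical to running each alone.
    """
    cfg = cfg or SpindleConfig()
    fibers = [cfg.fibers[name] for name in FIBER_ORDER]
    order = mk.muscle_order
    L = np.stack([mk.L_ce[m] for m in order], axis=1)
    V = np.stack([mk.V_ce[m] for m in order], axis=1)
    A = np.stack([mk.A_ce[m] for m in order], axis=1)
    T = integrate_intrafusal(L, V, A, mk.fs, fibers,
                             gamma_dynamic=cfg.gamma_dynamic,
                             gamma_static=cfg.gamma_static,
                             substeps=cfg.substeps)
    sl = slice(len(L) - mk.n_cycle, None)
    data = np.empty((mk.n_cycle, 8), dtype=float)
    for j, m in enumerate(order):
        ia, ii = _rates_from_tension(T[:, :, j], L[:, j], fibers, cfg)
        _warn_cap(ia[sl], ii[sl], f"{m} ({mk.task_id}-{mk.direction})", cfg)
        data[:, CHANNELS.index(f"{m}_Ia")] = ia[sl]
        data[:, CHANNELS.index(f"{m}_II")] = ii[sl]
    return AfferentEnsemble(data=data, fs=mk.fs,
                            task_id=mk.task_id, direction=mk.direction)


# ---------------------------------------------------------------------------
# exports

def ensemble_to_csv(ens: AfferentEnsemble, path, sidecar_path=None,
                    cfg: SpindleConfig | None = None) -> None:
    t = np.arange(len(ens.data)) / ens.fs
    df = pd.DataFrame(ens.data, columns=list(ens.channel_names))
    df.insert(0, "t_s", t)
    df.to_csv(path, index=False)
    if sidecar_path is not None:
        cfg = cfg or SpindleConfig()
        meta = {
            "task_id": ens.task_id,
            "direction": ens.direction,
            "fs_hz": ens.fs,
            "gamma_dynamic_pps": cfg.gamma_dynamic,
            "gamma_static_pps": cfg.gamma_static,
            "constants_version": cfg.constants_version,
        }
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def ensemble_from_csv(path, fs: float = 200.0, task_id=None,
                      direction=None) -> AfferentEnsemble:
    df = pd.read_csv(path)
    data = df[list(CHANNELS)].to_numpy(dtype=float)
    return AfferentEnsemble(data=data, fs=fs, task_id=task_id,
                            direction=direction)
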