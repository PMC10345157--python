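"""Experiment configuration: limb geometry, muscle table, task parameters,
spindle constants, and analysis settings.

Defaults reproduce the reference study design: five closed end-point tasks
traversed forward and reverse (10 conditions), 200 equidistant points per
1-second cycle, a 2-joint planar hindlimb (thigh 90 mm, shank 100 mm) with
four musculotendons, and a passive spindle (zero fusimotor drive).

All values are plain dataclass fields and can be loaded from / dumped to
YAML (JSON is a subset and therefore also accepted).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field

import yaml

TASKS = ("circle", "line", "oscillatory", "lemniscate", "square")
DIRECTIONS = ("FWD", "REV")
MUSCLES = ("AB", "IL", "VL", "SM")

#: Short labels used in confusion-matrix exports.
TASK_LABELS = {
    "circle": "CI",
    "line": "LI",
    "oscillatory": "OS",
    "lemniscate": "LE",
    "square": "SQ",
}


@dataclass
class TrajectoryParams:
    """Geometric parameters of the five end-point tasks (all lengths mm).

    ``workspace_center`` of ``None`` means "the end-point position at the
    reference posture", computed from the limb geometry at run time.
    """

    circle_diameter: float = 5.0
    line_length_one_way: float = 6.0           # there-and-back cycle = 12 mm
    line_incline_deg: float = 26.57            # 50 % grade
    line_midpoint: tuple[float, float] | None = None
    oscillatory_amplitude: float = 20.0        # A of the sine, mm
    oscillatory_frequency: float = 10.0        # f, Hz of the generating sine
    oscillatory_extent: float = 40.0           # horizontal sweep width, mm
    oscillatory_spatial_periods: float = 1.0   # sine periods across the sweep
    lemniscate_height: float = 20.0            # larger lobe dimension, mm
    square_side: float = 5.0
    workspace_center: tuple[float, float] | None = None
    n_points: int = 200
    cycle_duration: float = 1.0                # seconds


@dataclass
class LimbGeometry:
    """Planar 2-link chain rooted at the hip.

    The reference posture (hip 65 deg, knee interior angle 100 deg) is the
    posture at which every muscle sits at its optimal length.
    """

    l1: float = 90.0                 # thigh, mm
    l2: float = 100.0                # shank, mm
    hip_position: tuple[float, float] = (0.0, 0.0)
    q_ref_hip_deg: float = 65.0
    q_ref_knee_interior_deg: float = 100.0

    @property
    def q_ref(self) -> tuple[float, float]:
        """Reference joint angles in the internal convention, radians.

        q1 is the thigh angle from the +x axis; q2 is the elbow angle of the
        two-link chain (0 = fully extended), i.e. 180 deg minus the interior
        knee angle.
        """
        return (
            math.radians(self.q_ref_hip_deg),
            math.radians(180.0 - self.q_ref_knee_interior_deg),
        )


@dataclass
class MuscleParams:
    """One musculotendon: maximal length, constant moment arms, and the
    fraction of L_max it occupies at the reference posture."""

    name: str
    L_max: float                       # mm
    moment_arm_hip: float = 0.0        # signed, mm
    moment_arm_knee: float = 0.0       # signed, mm
    L_O_fraction: float = 0.85

    @property
    def L_ref(self) -> float:
        """Optimal (reference-posture) length L_O in mm."""
        return self.L_O_fraction * self.L_max


def default_muscles() -> tuple[MuscleParams, ...]:
    """The four-muscle hindlimb table.

    AB and IL act antagonistically at the hip, VL extends the knee, and SM
    is bifunctional (hip extensor, knee flexor).  Signs follow the
    convention that hip flexion increases q1 and knee flexion increases q2,
    under which each muscle shortens during its named action.
    """
    return (
        MuscleParams("AB", 70.0, moment_arm_hip=30.0, L_O_fraction=0.85),
        MuscleParams("IL", 70.0, moment_arm_hip=-44.0, L_O_fraction=0.85),
        MuscleParams("VL", 50.0, moment_arm_knee=9.0, L_O_fraction=0.85),
        MuscleParams("SM", 70.0, moment_arm_hip=30.0, moment_arm_knee=-38.0,
                     L_O_fraction=0.75),
    )


@dataclass
class FiberParams:
    """Constants of one intrafusal fiber type (bag1, bag2 or chain).

    Lengths are in units of the optimal fascicle length L_O, tensions in
    normalized force units, so stiffness K_SR carries force per L_O.
    ``beta_gamma`` scales damping with fusimotor activation (dynamic drive
    for bag1, static drive for bag2/chain); ``gamma_force`` is the active
    force the same drive contributes.  ``tau`` is the activation time
    constant (chain activation is instantaneous, tau = 0).
    """

    K_SR: float = 10.4649        # sensory-region stiffness
    K_PR: float = 0.15           # polar-region stiffness
    M: float = 0.0002            # effective mass term
    beta0: float = 0.0605        # passive damping
    beta_gamma: float = 0.0      # damping gain of fusimotor activation
    gamma_force: float = 0.0     # active-force gain of fusimotor activation
    C_L: float = 1.0             # damping asymmetry, lengthening
    C_S: float = 0.42            # damping asymmetry, shortening
    a: float = 0.3               # fractional velocity power
    R: float = 0.46              # polar-region resting length offset
    L0_SR: float = 0.04          # sensory-region rest length
    L0_PR: float = 0.76          # polar-region rest length
    LN_SR: float = 0.0423        # sensory-region threshold length
    LN_PR: float = 0.89          # polar-region threshold length
    G_primary: float = 20000.0   # primary afferent gain, pps per L_O
    G_secondary: float = 0.0     # secondary afferent gain, pps per L_O
    X: float = 0.0               # secondary-ending fraction on sensory region
    L_secondary: float = 0.04    # secondary-ending rest length
    freq: float = 60.0           # fusimotor half-activation frequency, pps
    tau: float = 0.149           # fusimotor activation time constant, s
    uses_dynamic_drive: bool = True


def default_fibers() -> dict[str, FiberParams]:
    """Literature default constants for the three intrafusal fiber types."""
    return {
        "bag1": FiberParams(
            beta0=0.0605, beta_gamma=0.2592, gamma_force=0.0289,
            G_primary=20000.0, G_secondary=0.0, X=0.0,
            freq=60.0, tau=0.149, uses_dynamic_drive=True,
        ),
        "bag2": FiberParams(
            beta0=0.0822, beta_gamma=-0.046, gamma_force=0.0636,
            G_primary=10000.0, G_secondary=7250.0, X=0.7,
            freq=60.0, tau=0.205, uses_dynamic_drive=False,
        ),
        "chain": FiberParams(
            beta0=0.0822, beta_gamma=-0.069, gamma_force=0.0954,
            G_primary=10000.0, G_secondary=7250.0, X=0.7,
            freq=90.0, tau=0.0, uses_dynamic_drive=False,
        ),
    }


@dataclass
class SpindleConfig:
    """Spindle-model settings shared by all muscles."""

    gamma_dynamic: float = 0.0       # pps; passive spindle by default
    gamma_static: float = 0.0        # pps
    substeps: int = 20               # RK4 substeps per sample interval
    warmup_cycles: int = 2           # cycles discarded before analysis
    occlusion: float = 0.156         # partial occlusion of the weaker Ia branch
    rate_cap_warn: float = 600.0     # pps; soft physiological ceiling
    constants_version: str = "mammalian-intrafusal-v1"
    fibers: dict[str, FiberParams] = field(default_factory=default_fibers)


@dataclass
class AnalysisConfig:
    """PCA / correlation / clustering settings."""

    pca_k_combined: int = 3
    pca_k_per_muscle: int = 2
    threshold: float = 0.5           # discriminability cut on R_max
    kmeans_seed: int = 0
    kmeans_n_init: int = 10
    kmeans_k_range: tuple[int, int] = (2, 9)
    run_kmeans_baseline: bool = True


@dataclass
class ExperimentConfig:
    """Everything needed to regenerate the full experiment."""

    trajectories: TrajectoryParams = field(default_factory=TrajectoryParams)
    geometry: LimbGeometry = field(default_factory=LimbGeometry)
    muscles: tuple[MuscleParams, ...] = field(default_factory=default_muscles)
    spindle: SpindleConfig = field(default_factory=SpindleConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    joint_limits_deg: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"hip": (10.0, 160.0), "knee": (10.0, 170.0)}
    )
    tasks: tuple[str, ...] = TASKS
    strict_length_bounds: bool = False
    seed: int = 0

    @property
    def conditions(self) -> tuple[tuple[str, str], ...]:
        """Task x direction design, canonical order."""
        return tuple((t, d) for t in self.tasks for d in DIRECTIONS)

    def muscle(self, name: str) -> MuscleParams:
        for m in self.muscles:
            if m.name == name:
                return m
        raise KeyError(name)


# ---------------------------------------------------------------------------
# serialization

def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def config_to_dict(config: ExperimentConfig) -> dict:
    return _to_plain(config)


def config_hash(config: ExperimentConfig) -> str:
    """Stable SHA-256 of the canonical JSON form of a config."""
    blob = json.dumps(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _tuple2(v):
    return None if v is None else (float(v[0]), float(v[1]))


def config_from_dict(d: dict) -> ExperimentConfig:
    cfg = ExperimentConfig()
    if "trajectories" in d:
        t = dict(d["trajectories"])
        for key in ("workspace_center", "line_midpoint"):
            if key in t:
                t[key] = _tuple2(t[key])
        cfg.trajectories = dataclasses.replace(TrajectoryParams(), **t)
    if "geometry" in d:
        g = dict(d["geometry"])
        if "hip_position" in g:
            g["hip_position"] = _tuple2(g["hip_position"])
        cfg.geometry = dataclasses.replace(LimbGeometry(), **g)
    if "muscles" in d:
        cfg.muscles = tuple(MuscleParams(**m) for m in d["muscles"])
    if "spindle" in d:
        s = dict(d["spindle"])
        if "fibers" in s:
            s["fibers"] = {k: FiberParams(**v) for k, v in s["fibers"].items()}
        cfg.spindle = dataclasses.replace(SpindleConfig(), **s)
    if "analysis" in d:
        a = dict(d["analysis"])
        if "kmeans_k_range" in a:
            a["kmeans_k_range"] = tuple(a["kmeans_k_range"])
        cfg.analysis = dataclasses.replace(AnalysisConfig(), **a)
    if "joint_limits_deg" in d:
        cfg.joint_limits_deg = {k: tuple(v)
                                for k, v in d["joint_limits_deg"].items()}
    if "tasks" in d:
        cfg.tasks = tuple(d["tasks"])
    for key in ("strict_length_bounds", "seed"):
        if key in d:
            setattr(cfg, key, d[key])
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)
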