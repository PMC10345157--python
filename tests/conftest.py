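import logging

import numpy as np
import pytest

import spindlesim as ss
from spindlesim.config import ExperimentConfig

logging.getLogger("spindlesim").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_config() -> ExperimentConfig:
    return ExperimentConfig()


@pytest.fixture(scope="session")
def run_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("default_run")


@pytest.fixture(scope="session")
def default_report(default_config, run_dir):
    """One full default experiment, artifacts written once per session."""
    return ss.run_experiment(default_config, outdir=run_dir)


@pytest.fixture(scope="session")
def default_ensembles(default_config):
    """The ten condition ensembles of the default design."""
    cfg = default_config
    trajs = ss.generate_all_conditions(cfg.trajectories, cfg.geometry)
    out = {}
    for cond, traj in trajs.items():
        jt = ss.joint_trajectory(traj, cfg.geometry)
        mk = ss.kinematics_series(
            jt, cfg.muscles, cfg.geometry,
            warmup_cycles=cfg.spindle.warmup_cycles,
            joint_limits_deg=cfg.joint_limits_deg)
        out[cond] = ss.simulate_ensemble(mk, cfg.spindle)
    return out


@pytest.fixture(scope="session")
def circle_kinematics(default_config):
    """Muscle kinematics of one representative condition (circle FWD)."""
    cfg = default_config
    traj = ss.generate_trajectory("circle", cfg.trajectories, geom=cfg.geometry)
    jt = ss.joint_trajectory(traj, cfg.geometry)
    return ss.kinematics_series(jt, cfg.muscles, cfg.geometry,
                                warmup_cycles=cfg.spindle.warmup_cycles)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
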