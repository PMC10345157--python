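"""End-to-end experiment: trajectories -> kinematics -> spindle ensembles
-> PCA -> discriminability report.

``run_experiment`` is deterministic for a given config (the only random
element, K-means++ seeding, uses the configured seed), so re-running
produces bit-identical numeric output.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import discriminability as disc
from . import kinematics as kin
from . import pca as pcamod
from . import spindle as spn
from . import trajectories as trj
from .config import MUSCLES, ExperimentConfig, config_hash, config_to_dict
from .discriminability import Condition
from .errors import DegenerateTestError

log = logging.getLogger(__name__)


@dataclass
class ExperimentReport:
    """Machine-readable results of one full run."""

    discriminability: dict          # per space: percent, counts, span
    explained_variance: dict        # combined + per-muscle scree
    correlations: dict              # per space: list of pair entries
    wilcoxon: dict                  # combined + per-muscle paired tests
    kmeans: dict | None
    provenance: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _score_block(cs, threshold):
    score = disc.discriminability_score(cs, threshold)
    alpha, beta, span_pct = disc.span_metric(cs)
    return {
        "space": cs.space,
        "muscle": cs.muscle,
        "n_pairs": score.n_pairs,
        "n_below_threshold": score.n_below,
        "percent": score.percent,
        "percent_rounded": score.percent_rounded,
        "span_alpha": alpha,
        "span_beta": beta,
        "span_percent": span_pct,
    }


def run_experiment(
    config: ExperimentConfig | None = None,
    outdir: str | Path | None = None,
) -> ExperimentReport:
    """Execute every stage of the study design and assemble the report.

    With ``outdir`` set, stage artifacts (CSV/JSON) are written under
    trajectories/, kinematics/, afferents/, pca/ and discriminability/
    subdirectories, plus a report.json at the root.
    """
    config = config or ExperimentConfig()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        for sub in ("trajectories", "kinematics", "afferents", "pca",
                    "discriminability"):
            (out / sub).mkdir(parents=True, exist_ok=True)

    conditions = config.conditions
    # --- stage 1: trajectories -------------------------------------------
    log.info("stage trajectories: generating %d conditions", len(conditions))
    trajs = trj.generate_all_conditions(config.trajectories, config.geometry,
                                        tasks=config.tasks)

    # --- stage 2: kinematics ---------------------------------------------
    ensembles: dict[Condition, spn.AfferentEnsemble] = {}
    for cond, traj in trajs.items():
        jt = kin.joint_trajectory(traj, config.geometry)
        mk = kin.kinematics_series(
            jt, config.muscles, config.geometry,
            warmup_cycles=config.spindle.warmup_cycles,
            joint_limits_deg=config.joint_limits_deg,
            strict_bounds=config.strict_length_bounds)
        # --- stage 3: spindle ensembles ----------------------------------
        ensembles[cond] = spn.simulate_ensemble(mk, config.spindle)
        if out is not None:
            tag = f"{cond[0]}_{cond[1]}"
            trj.trajectory_to_csv(traj, out / "trajectories" / f"{tag}.csv")
            kin.joint_trajectory_to_csv(
                jt, out / "kinematics" / f"{tag}_joints.csv")
            kin.muscle_kinematics_to_csv(
                mk, out / "kinematics" / f"{tag}_muscles.csv")
            spn.ensemble_to_csv(
                ensembles[cond], out / "afferents" / f"{tag}.csv",
                out / "afferents" / f"{tag}.json", config.spindle)
    log.info("stage spindle: %d ensembles of %d samples x 8 channels",
             len(ensembles), next(iter(ensembles.values())).data.shape[0])

    # --- stage 4: PCA ----------------------------------------------------
    pooled = np.vstack([ensembles[c].data for c in conditions])
    model = pcamod.fit_pca(pooled, config.analysis.pca_k_combined)
    frac, cum = pcamod.explained_variance(model)
    ev = {
        "combined": {
            "fractions_percent": (100.0 * frac).tolist(),
            "cumulative_percent": (100.0 * cum).tolist(),
        }
    }
    scores = {c: pcamod.project(model, ensembles[c].data,
                                task_id=c[0], direction=c[1]).scores
              for c in conditions}

    muscle_models = {}
    muscle_scores: dict[str, dict[Condition, np.ndarray]] = {}
    for m in MUSCLES:
        pooled_m = np.vstack(
            [ensembles[c].muscle_pair(m) for c in conditions])
        mm = pcamod.fit_pca(pooled_m, config.analysis.pca_k_per_muscle)
        muscle_models[m] = mm
        f_m, c_m = pcamod.explained_variance(mm)
        ev[m] = {
            "fractions_percent": (100.0 * f_m).tolist(),
            "cumulative_percent": (100.0 * c_m).tolist(),
        }
        muscle_scores[m] = {
            c: pcamod.project(mm, ensembles[c].muscle_pair(m)).scores
            for c in conditions}
    log.info("stage pca: combined top-%d components explain %.2f%%",
             config.analysis.pca_k_combined,
             100.0 * cum[config.analysis.pca_k_combined - 1])

    if out is not None:
        pcamod.model_to_json(model, out / "pca" / "combined_model.json")
        fs = next(iter(ensembles.values())).fs
        for c in conditions:
            proj = pcamod.ProjectedEnsemble(scores[c], c[0], c[1])
            pcamod.scores_to_csv(
                proj, fs, out / "pca" / f"{c[0]}_{c[1]}_scores.csv")

    # --- stage 5: pairwise correlations ----------------------------------
    threshold = config.analysis.threshold
    raw_8d = disc.pairwise_correlations(
        {c: e.data for c, e in ensembles.items()}, "raw_8d",
        expected=conditions)
    pca_3d = disc.pairwise_correlations(scores, "pca_3d",
                                        expected=conditions)
    sets = {"raw_8d": raw_8d, "pca_3d": pca_3d}
    for m in MUSCLES:
        sets[f"raw_2d_{m}"] = disc.pairwise_correlations(
            {c: e.muscle_pair(m) for c, e in ensembles.items()},
            "raw_2d_per_muscle", muscle=m, expected=conditions)
        sets[f"pca_2d_{m}"] = disc.pairwise_correlations(
            muscle_scores[m], "pca_2d_per_muscle", muscle=m,
            expected=conditions)

    scores_block = {name: _score_block(cs, threshold)
                    for name, cs in sets.items()}
    wilcoxon = {}
    for label, raw_cs, pca_cs in (
            [("combined", raw_8d, pca_3d)]
            + [(m, sets[f"raw_2d_{m}"], sets[f"pca_2d_{m}"]) for m in MUSCLES]):
        try:
            wilcoxon[label] = dataclasses.asdict(
                disc.compare_raw_vs_pca(raw_cs, pca_cs))
        except DegenerateTestError as exc:
            wilcoxon[label] = {"error": str(exc)}
    log.info("stage discriminability: raw %d%% -> pca %d%% (combined)",
             scores_block["raw_8d"]["percent_rounded"],
             scores_block["pca_3d"]["percent_rounded"])

    # --- stage 6: clustering baseline ------------------------------------
    kmeans_block = None
    if config.analysis.run_kmeans_baseline:
        lo, hi = config.analysis.kmeans_k_range
        hi = min(hi, len(pooled) - 1)
        k_sel, diagnostics = disc.select_k(
            pooled, (lo, hi), seed=config.analysis.kmeans_seed)
        kmeans_block = {
            "selected_k": int(k_sel),
            "k_range": [int(lo), int(hi)],
            "diagnostics": {str(k): v for k, v in diagnostics.items()},
        }
        log.info("stage kmeans: silhouette selects k = %d", k_sel)

    correlations = {name: cs.to_frame().to_dict(orient="records")
                    for name, cs in sets.items()}
    report = ExperimentReport(
        discriminability=scores_block,
        explained_variance=ev,
        correlations=correlations,
        wilcoxon=wilcoxon,
        kmeans=kmeans_block,
        provenance={
            "config_hash": config_hash(config),
            "constants_version": config.spindle.constants_version,
            "timestamp": datetime.datetime.now(
                datetime.timezone.utc).isoformat(),
            "config": config_to_dict(config),
        },
    )

    if out is not None:
        ddir = out / "discriminability"
        for name, cs in sets.items():
            cs.to_frame().to_csv(ddir / f"correlations_{name}.csv",
                                 index=False)
        disc.combined_confusion_matrix(raw_8d, pca_3d).to_csv(
            ddir / "confusion_combined.csv")
        disc.confusion_matrix(raw_8d).to_csv(ddir / "confusion_raw_8d.csv")
        disc.confusion_matrix(pca_3d).to_csv(ddir / "confusion_pca_3d.csv")
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return report


def validate_config(config: ExperimentConfig) -> list[str]:
    """Return every detected config violation (empty list means ok)."""
    v: list[str] = []
    g = config.geometry
    if g.l1 <= 0 or g.l2 <= 0:
        v.append("segment lengths must be positive")
    for m in config.muscles:
        if m.L_max <= 0:
            v.append(f"{m.name}: L_max must be positive")
        if not (0.0 < m.L_O_fraction < 1.0):
            v.append(f"{m.name}: L_O fraction must lie in (0, 1)")
        for arm in (m.moment_arm_hip, m.moment_arm_knee):
            if abs(arm) >= m.L_max > 0:
                v.append(f"{m.name}: |moment arm| must be below L_max")
    t = config.trajectories
    for name in ("circle_diameter", "line_length_one_way",
                 "oscillatory_amplitude", "oscillatory_extent",
                 "lemniscate_height", "square_side", "cycle_duration"):
        if getattr(t, name) <= 0:
            v.append(f"trajectories.{name} must be positive")
    if t.n_points < 4:
        v.append("trajectories.n_points must be >= 4")
    if abs(np.tan(np.radians(t.line_incline_deg)) - 0.5) > 0.01:
        v.append("line incline does not correspond to a 50% grade")
    if v:
        return v
    # reachability of every sample of every task
    lo, hi = abs(g.l1 - g.l2), g.l1 + g.l2
    for cond, traj in trj.generate_all_conditions(t, g).items():
        p = traj.points - np.asarray(g.hip_position)
        r = np.linalg.norm(p, axis=1)
        if np.any(r <= lo) or np.any(r >= hi):
            v.append(f"{cond[0]}-{cond[1]}: end point leaves the reachable "
                     f"annulus ({lo:.0f}, {hi:.0f}) mm")
    return v
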