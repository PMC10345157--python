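"""Principal component analysis of afferent ensembles.

Deliberately minimal and explicit: column centering only (no variance
scaling), covariance with 1/n normalization, symmetric eigendecomposition,
components sorted by descending eigenvalue.  Component signs are fixed so
the largest-magnitude loading of each component is positive, making
outputs reproducible despite the eigenvector sign ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidComponentCountError


@dataclass
class PCAModel:
    """Fitted decomposition: d-channel mean, (d, k) orthonormal loadings,
    and the full descending eigenvalue spectrum of the 1/n covariance."""

    mean_vector: np.ndarray
    components: np.ndarray          # (d, k), columns orthonormal
    eigenvalues: np.ndarray         # all d, descending, >= 0
    k: int
    fit_scope: str = "pooled"

    @property
    def explained_variance_fraction(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total


@dataclass
class ProjectedEnsemble:
    """Scores Z = (X - mean) U for one condition, with task metadata."""

    scores: np.ndarray              # (n, k)
    task_id: str | None = None
    direction: str | None = None
    fit_scope: str = "pooled"


def fit_pca(data: np.ndarray, k: int, fit_scope: str = "pooled") -> PCAModel:
    """Fit a PCA on an (n, d) matrix, keeping the top k components.

    Rank-deficient data is permitted: zero eigenvalues are kept in the
    spectrum (tiny negative rounding is clipped to zero).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    n, d = X.shape
    if k > d:
        raise InvalidComponentCountError(f"k = {k} exceeds dimension d = {d}")
    if n <= d:
        raise ValueError(f"need more samples than dimensions (n = {n}, d = {d})")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    mean = X.mean(axis=0)
    Xc = X - mean
    C = (Xc.T @ Xc) / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    U = evecs[:, :k].copy()
    for j in range(k):                       # deterministic sign convention
        i = np.argmax(np.abs(U[:, j]))
        if U[i, j] < 0:
            U[:, j] = -U[:, j]
    return PCAModel(mean_vector=mean, components=U, eigenvalues=evals,
                    k=k, fit_scope=fit_scope)


def project(model: PCAModel, data: np.ndarray, task_id=None,
            direction=None) -> ProjectedEnsemble:
    """Center with the model's mean and project onto its components."""
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.mean_vector):
        raise ValueError(
            f"data has {X.shape[1]} channels, model expects "
            f"{len(model.mean_vector)}")
    Z = (X - model.mean_vector) @ model.components
    return ProjectedEnsemble(scores=Z, task_id=task_id, direction=direction,
                             fit_scope=model.fit_scope)


def explained_variance(model: PCAModel):
    """Per-component variance fractions and their cumulative sums."""
    frac = model.explained_variance_fraction
    return frac, np.cumsum(frac)


# ---------------------------------------------------------------------------
# exports

def model_to_json(model: PCAModel, path) -> None:
    import json
    with open(path, "w") as fh:
        json.dump({
            "mean_vector": model.mean_vector.tolist(),
            "components": model.components.tolist(),
            "eigenvalues": model.eigenvalues.tolist(),
            "k": model.k,
            "fit_scope": model.fit_scope,
        }, fh, indent=2)


def scores_to_csv(proj: ProjectedEnsemble, fs: float, path) -> None:
    n, k = proj.scores.shape
    df = pd.DataFrame(proj.scores, columns=[f"PC{i+1}" for i in range(k)])
    df.insert(0, "t_s", np.arange(n) / fs)
    df["task"] = proj.task_id
    df["direction"] = proj.direction
    df.to_csv(path, index=False)
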