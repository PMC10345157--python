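"""Pairwise discriminability of movement conditions from afferent series.

Two conditions are compared by the maximum, over all circular time lags,
of the normalized cross-correlation of their multichannel blocks, taken
over the flattened (time x channel) block in the uncentered (cosine)
form: R(tau) = <a_tau, b> / (||a|| ||b||), with no mean subtraction.
Raw firing rates are non-negative, so their shared baseline structure
keeps raw correlations clustered in the high positive band; PCA scores
are centered by the pooled-fit mean, so the same statistic spreads over
the full [-1, 1] range after pre-processing — the mechanism behind the
raw-versus-PCA discriminability gap.  A pair is *discriminable* when the
maximum correlation stays below a threshold (0.5, the midpoint of the
positive range).

Also provides the span metric (bandwidth of observed correlations over
the full [-1, 1] range), similarity confusion matrices, a hand-rolled
K-means++ clustering baseline, and the paired Wilcoxon comparison of raw
versus PCA-space correlation sets.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import DIRECTIONS, TASK_LABELS, TASKS
from .errors import (
    DegenerateTestError,
    IncompleteDesignError,
    UndefinedCorrelationError,
)

Condition = tuple[str, str]  # (task_id, direction)

#: canonical ordering of the ten study conditions
CONDITION_ORDER: tuple[Condition, ...] = tuple(
    (t, d) for t in TASKS for d in DIRECTIONS)


def condition_label(cond: Condition) -> str:
    task, direction = cond
    return f"{TASK_LABELS.get(task, task[:2].upper())}{direction.lower()}"


@dataclass
class CorrelationSet:
    """45 pairwise (R_max, tau) entries for one representation space."""

    space: str                                   # e.g. raw_8d, pca_3d
    entries: dict[tuple[Condition, Condition], tuple[float, int]]
    muscle: str | None = None
    condition_order: tuple[Condition, ...] = field(default=CONDITION_ORDER)

    @property
    def r_values(self) -> np.ndarray:
        return np.array([r for r, _ in self.entries.values()])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), (r, tau) in self.entries.items():
            rows.append({
                "task_a": a[0], "dir_a": a[1],
                "task_b": b[0], "dir_b": b[1],
                "R_max": r, "tau": tau,
                "space": self.space, "muscle": self.muscle or "",
            })
        return pd.DataFrame(rows)


@dataclass
class DiscriminabilityScore:
    n_below: int
    n_pairs: int
    threshold: float

    @property
    def fraction(self) -> float:
        return self.n_below / self.n_pairs

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    @property
    def percent_rounded(self) -> int:
        return int(math.floor(self.percent + 0.5))


# ---------------------------------------------------------------------------
# cross-correlation

def xcorr_max(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """Maximum circular-lag normalized cross-correlation of two blocks.

    ``a`` (image) and ``b`` (template) are (n, c) arrays; arrays with a
    single channel may be passed 1-D.  For each lag tau in {0..n-1} the
    image is circularly shifted along time only and the uncentered
    normalized correlation of the flattened blocks is computed.  Returns
    (R_max, argmax tau); ties break toward the smallest lag.

    Signals where every channel is constant carry no temporal
    information and raise, rather than silently reporting a similarity.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if b.ndim == 1:
        b = b[:, None]
    if a.ndim != 2 or b.ndim != 2 or a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    for block, name in ((a, "first"), (b, "second")):
        if np.all(block == block[0:1, :]):
            raise UndefinedCorrelationError(
                f"{name} input is constant in every channel")
    na = float(np.sqrt((a * a).sum()))
    nb = float(np.sqrt((b * b).sum()))
    if na == 0.0 or nb == 0.0:
        raise UndefinedCorrelationError("all-zero block")
    idx = (np.arange(n)[None, :] + np.arange(n)[:, None]) % n   # (lag, i)
    shifted = a[idx]                                            # (lag, n, c)
    num = np.einsum("lic,ic->l", shifted, b)
    r = num / (na * nb)
    tau = int(np.argmax(r))
    return float(np.clip(r[tau], -1.0, 1.0)), tau


def pairwise_correlations(
    ensembles: dict[Condition, np.ndarray],
    space: str,
    muscle: str | None = None,
    expected: tuple[Condition, ...] | None = CONDITION_ORDER,
) -> CorrelationSet:
    """All unordered pairwise xcorr_max values over the given conditions.

    ``ensembles`` maps (task, direction) to an (n, c) block.  With the
    default 10-condition design this yields exactly 45 entries; a missing
    expected condition raises.
    """
    if expected is not None:
        missing = [c for c in expected if c not in ensembles]
        if missing:
            raise IncompleteDesignError(f"missing conditions: {missing}")
        order = expected
    else:
        order = tuple(ensembles.keys())
    entries = {}
    for a, b in itertools.combinations(order, 2):
        r, tau = xcorr_max(ensembles[a], ensembles[b])
        entries[(a, b)] = (r, tau)
    return CorrelationSet(space=space, entries=entries, muscle=muscle,
                          condition_order=order)


def discriminability_score(cs: CorrelationSet,
                           threshold: float = 0.5) -> DiscriminabilityScore:
    """Percent of pairs whose R_max falls below the threshold."""
    r = cs.r_values
    return DiscriminabilityScore(n_below=int(np.sum(r < threshold)),
                                 n_pairs=len(r), threshold=threshold)


def span_metric(cs: CorrelationSet) -> tuple[float, float, float]:
    """(alpha, beta, percent): bandwidth of the observed R values over the
    total possible correlation range beta = 2."""
    r = cs.r_values
    alpha = float(r.max() - r.min())
    beta = 2.0
    return alpha, beta, 100.0 * alpha / beta


def confusion_matrix(cs: CorrelationSet) -> pd.DataFrame:
    """Symmetric 10 x 10 similarity matrix: off-diagonal cells hold the
    pair's R_max mapped to [0, 1] via (R + 1) / 2; the diagonal is 1 by
    convention (a condition is indistinguishable from itself)."""
    order = cs.condition_order
    labels = [condition_label(c) for c in order]
    m = np.eye(len(order))
    for (a, b), (r, _) in cs.entries.items():
        i, j = order.index(a), order.index(b)
        m[i, j] = m[j, i] = (r + 1.0) / 2.0
    return pd.DataFrame(m, index=labels, columns=labels)


def combined_confusion_matrix(raw: CorrelationSet,
                              pca: CorrelationSet) -> pd.DataFrame:
    """Display matrix with raw similarities below the diagonal and
    PCA-space similarities above it."""
    lower = confusion_matrix(raw).to_numpy()
    upper = confusion_matrix(pca).to_numpy()
    m = np.tril(lower, -1) + np.triu(upper, 1) + np.eye(len(lower))
    labels = [condition_label(c) for c in raw.condition_order]
    return pd.DataFrame(m, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# K-means++ baseline

def kmeans_pp(data: np.ndarray, k: int, seed: int = 0, n_init: int = 10,
              tol: float = 1e-8, max_iter: int = 300):
    """K-means with D^2-weighted (k-means++) seeding.

    Runs ``n_init`` restarts with a seeded generator and keeps the lowest
    within-cluster sum of squares (inertia).  Returns (labels, centers,
    inertia); deterministic given the seed.
    """
    X = np.asarray(data, dtype=float)
    n = len(X)
    if k > n:
        raise ValueError(f"k = {k} exceeds number of points n = {n}")
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_init):
        centers = _pp_seed(X, k, rng)
        labels, centers, inertia = _lloyd(X, centers, tol, max_iter, rng)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    return best


def _pp_seed(X, k, rng):
    n = len(X)
    centers = [X[rng.integers(n)]]
    d2 = np.sum((X - centers[0]) ** 2, axis=1)
    for _ in range(1, k):
        total = d2.sum()
        if total == 0:
            centers.append(X[rng.integers(n)])
            continue
        probs = d2 / total
        centers.append(X[rng.choice(n, p=probs)])
        d2 = np.minimum(d2, np.sum((X - centers[-1]) ** 2, axis=1))
    return np.array(centers)


def _lloyd(X, centers, tol, max_iter, rng):
    for _ in range(max_iter):
        d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        labels = np.argmin(d2, axis=1)
        new = centers.copy()
        for j in range(len(centers)):
            pts = X[labels == j]
            if len(pts):
                new[j] = pts.mean(axis=0)
            else:                       # empty cluster -> farthest point
                new[j] = X[np.argmax(np.min(d2, axis=1))]
        shift = float(np.max(np.linalg.norm(new - centers, axis=1)))
        centers = new
        if shift < tol:
            break
    d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    labels = np.argmin(d2, axis=1)
    inertia = float(np.sum(d2[np.arange(len(X)), labels]))
    return labels, centers, inertia


def silhouette(X: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient (direct O(n^2) computation)."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    D = np.sqrt(np.maximum(
        np.sum(X**2, 1)[:, None] + np.sum(X**2, 1)[None, :]
        - 2.0 * (X @ X.T), 0.0))
    s = np.zeros(len(X))
    for i in range(len(X)):
        own = labels == labels[i]
        if own.sum() > 1:
            a = D[i, own].sum() / (own.sum() - 1)
        else:
            s[i] = 0.0
            continue
        b = min(D[i, labels == u].mean() for u in uniq if u != labels[i])
        s[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(s.mean())


def select_k(data: np.ndarray, k_range=(2, 9), seed: int = 0):
    """Silhouette-maximizing cluster count over k_range (ties -> smaller k).

    Returns (k, diagnostics) where diagnostics maps each candidate k to
    its silhouette score and inertia.  If no candidate k >= 2 exists the
    smallest allowed k is returned (silhouette undefined at k = 1).
    """
    lo, hi = k_range
    diagnostics = {}
    best_k, best_s = None, -np.inf
    for k in range(max(lo, 2), hi + 1):
        labels, _, inertia = kmeans_pp(data, k, seed=seed)
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette(data, labels)
        diagnostics[k] = {"silhouette": s, "inertia": inertia}
        if s > best_s + 1e-12:
            best_k, best_s = k, s
    if best_k is None:
        return lo, diagnostics
    return best_k, diagnostics


# ---------------------------------------------------------------------------
# raw vs PCA paired comparison

@dataclass
class PairedTestResult:
    statistic: float
    pvalue: float
    median_difference: float
    n: int


def compare_raw_vs_pca(raw: CorrelationSet,
                       pca: CorrelationSet) -> PairedTestResult:
    """Two-sided Wilcoxon signed-rank test on the paired R_max values.

    Pairs are matched by condition pair across the two sets.  Identical
    sets (all differences zero) raise, since the test is undefined.
    """
    keys = sorted(raw.entries.keys())
    if sorted(pca.entries.keys()) != keys:
        raise IncompleteDesignError("correlation sets cover different pairs")
    x = np.array([raw.entries[k][0] for k in keys])
    y = np.array([pca.entries[k][0] for k in keys])
    diff = y - x
    if np.all(diff == 0.0):
        raise DegenerateTestError("all paired differences are zero")
    res = stats.wilcoxon(x, y, alternative="two-sided", method="auto")
    return PairedTestResult(statistic=float(res.statistic),
                            pvalue=float(res.pvalue),
                            median_difference=float(np.median(diff)),
                            n=len(diff))
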