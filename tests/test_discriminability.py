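"""Cross-correlation discriminability, span, clustering, paired test."""

import itertools

import numpy as np
import pytest

from spindlesim import (
    compare_raw_vs_pca,
    confusion_matrix,
    discriminability_score,
    kmeans_pp,
    pairwise_correlations,
    select_k,
    span_metric,
    xcorr_max,
)
from spindlesim.discriminability import (
    CONDITION_ORDER,
    CorrelationSet,
    combined_confusion_matrix,
    silhouette,
)
from spindlesim.errors import (
    DegenerateTestError,
    IncompleteDesignError,
    UndefinedCorrelationError,
)


def brute_force_xcorr(a, b):
    """Independent oracle: explicit per-lag loop over the correlation
    ratio, no vectorization shared with the implementation."""
    a = np.atleast_2d(a.T).T
    b = np.atleast_2d(b.T).T
    n, c = a.shape
    na = np.sqrt(sum(a[i, j] ** 2 for i in range(n) for j in range(c)))
    nb = np.sqrt(sum(b[i, j] ** 2 for i in range(n) for j in range(c)))
    best_r, best_tau = -np.inf, 0
    for tau in range(n):
        num = sum(a[(i + tau) % n, j] * b[i, j]
                  for i in range(n) for j in range(c))
        r = num / (na * nb)
        if r > best_r + 0:
            best_r, best_tau = r, tau
    return best_r, best_tau


class TestXcorrMax:
    def test_self_correlation_is_one_at_zero_lag(self, rng):
        x = rng.normal(size=(64, 3)) + 2.0
        r, tau = xcorr_max(x, x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert tau == 0

    @pytest.mark.parametrize("shift", [1, 7, 31])
    def test_circular_shift_recovery(self, shift, rng):
        x = rng.normal(size=(64, 2))
        r, tau = xcorr_max(np.roll(x, shift, axis=0), x)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert tau == shift

    def test_sine_versus_cosine_quarter_period(self):
        n = 64
        t = np.arange(n) / n
        r, tau = xcorr_max(np.sin(2 * np.pi * t), np.cos(2 * np.pi * t))
        assert r == pytest.approx(1.0, abs=1e-12)
        assert tau == n // 4

    @pytest.mark.parametrize("n,c", [(8, 1), (17, 3), (32, 2)])
    def test_equals_brute_force_oracle(self, n, c, rng):
        a = rng.normal(size=(n, c)) + rng.uniform(0, 3)
        b = rng.normal(size=(n, c)) + rng.uniform(0, 3)
        r, tau = xcorr_max(a, b)
        r_o, tau_o = brute_force_xcorr(a, b)
        assert r == pytest.approx(r_o, abs=1e-12)
        assert tau == tau_o

    def test_symmetry_of_roles(self, rng):
        a = rng.normal(size=(40, 4))
        b = rng.normal(size=(40, 4))
        r_ab, _ = xcorr_max(a, b)
        r_ba, _ = xcorr_max(b, a)
        assert r_ab == pytest.approx(r_ba, abs=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(20):
            a = rng.normal(size=(30, 2)) * rng.uniform(0.1, 10)
            b = rng.normal(size=(30, 2)) * rng.uniform(0.1, 10)
            r, _ = xcorr_max(a, b)
            assert -1.0 <= r <= 1.0

    def test_constant_inputs_raise(self):
        const = np.full((20, 2), 3.0)
        varying = np.random.default_rng(0).normal(size=(20, 2))
        with pytest.raises(UndefinedCorrelationError):
            xcorr_max(const, const)
        with pytest.raises(UndefinedCorrelationError):
            xcorr_max(const, varying)

    def test_shape_mismatch_raises(self, rng):
        with pytest.raises(ValueError):
            xcorr_max(rng.normal(size=(10, 2)), rng.normal(size=(10, 3)))


class TestPairwise:
    def _fake_ensembles(self, rng):
        return {c: rng.normal(size=(50, 8)) + 5.0 for c in CONDITION_ORDER}

    def test_ten_conditions_make_45_pairs(self, rng):
        cs = pairwise_correlations(self._fake_ensembles(rng), "raw_8d")
        assert len(cs.entries) == 45

    def test_missing_condition_raises(self, rng):
        ens = self._fake_ensembles(rng)
        ens.pop(("square", "REV"))
        with pytest.raises(IncompleteDesignError):
            pairwise_correlations(ens, "raw_8d")

    def test_duplicated_condition_pair_correlates_perfectly(self, rng):
        ens = self._fake_ensembles(rng)
        ens[("circle", "REV")] = ens[("circle", "FWD")].copy()
        cs = pairwise_correlations(ens, "raw_8d")
        r, tau = cs.entries[(("circle", "FWD"), ("circle", "REV"))]
        assert r == pytest.approx(1.0, abs=1e-12)
        assert tau == 0


class TestScores:
    def _set_with_values(self, values):
        pairs = list(itertools.combinations(CONDITION_ORDER, 2))
        return CorrelationSet(
            space="raw_8d",
            entries={p: (v, 0) for p, v in zip(pairs, values)})

    def test_no_pair_below_high_threshold(self):
        cs = self._set_with_values([0.9] * 45)
        assert discriminability_score(cs).percent == 0.0

    @pytest.mark.parametrize("n_below,expected", [(13, 29), (37, 82)])
    def test_rounded_percent_arithmetic(self, n_below, expected):
        vals = [0.1] * n_below + [0.9] * (45 - n_below)
        score = discriminability_score(self._set_with_values(vals))
        assert score.n_below == n_below
        assert score.percent == pytest.approx(100 * n_below / 45)
        assert score.percent_rounded == expected

    def test_antimonotone_in_threshold(self, rng):
        cs = self._set_with_values(rng.uniform(-1, 1, size=45))
        p = [discriminability_score(cs, th).percent
             for th in (0.2, 0.5, 0.8)]
        assert p[0] <= p[1] <= p[2]

    def test_span_metric(self):
        cs = self._set_with_values([0.25] * 45)
        assert span_metric(cs) == (0.0, 2.0, 0.0)
        vals = np.linspace(-0.979, 0.979, 45)
        alpha, beta, pct = span_metric(self._set_with_values(list(vals)))
        assert alpha == pytest.approx(1.958)
        assert pct == pytest.approx(97.9)

    def test_confusion_matrix_structure(self, rng):
        vals = list(rng.uniform(-1, 1, size=45))
        cs = self._set_with_values(vals)
        m = confusion_matrix(cs)
        assert m.shape == (10, 10)
        np.testing.assert_allclose(np.diag(m.to_numpy()), 1.0)
        np.testing.assert_allclose(m.to_numpy(), m.to_numpy().T)
        assert m.to_numpy().min() >= 0.0 and m.to_numpy().max() <= 1.0
        # lower triangle raw, upper triangle pre-processed
        cs2 = self._set_with_values([0.0] * 45)
        both = combined_confusion_matrix(cs, cs2).to_numpy()
        assert both[3, 1] == m.to_numpy()[3, 1]
        assert both[1, 3] == pytest.approx(0.5)


def brute_force_best_inertia(X, k):
    """Exhaustive minimum within-cluster sum of squares over all
    assignments of <= 16 points into k labeled groups."""
    n = len(X)
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        inertia = 0.0
        for j in range(k):
            pts = X[np.array(labels) == j]
            if len(pts):
                inertia += float(((pts - pts.mean(axis=0)) ** 2).sum())
        best = min(best, inertia)
    return best


class TestKMeans:
    def test_single_cluster_is_mean_and_total_ss(self, rng):
        X = rng.normal(size=(40, 3))
        labels, centers, inertia = kmeans_pp(X, 1, seed=0)
        np.testing.assert_allclose(centers[0], X.mean(axis=0), atol=1e-12)
        assert inertia == pytest.approx(((X - X.mean(0)) ** 2).sum())

    def test_k_equals_n_gives_zero_inertia(self, rng):
        X = rng.normal(size=(6, 2))
        _, _, inertia = kmeans_pp(X, 6, seed=0)
        assert inertia == pytest.approx(0.0, abs=1e-12)

    def test_two_separated_clouds_match_exhaustive_oracle(self, rng):
        X = np.vstack([rng.normal(size=(6, 2)) - 8.0,
                       rng.normal(size=(6, 2)) + 8.0])
        labels, _, inertia = kmeans_pp(X, 2, seed=1)
        assert len(set(labels[:6])) == 1 and len(set(labels[6:])) == 1
        assert labels[0] != labels[6]
        assert inertia == pytest.approx(brute_force_best_inertia(X, 2),
                                        rel=1e-9)

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(50, 4))
        a = kmeans_pp(X, 3, seed=7)
        b = kmeans_pp(X, 3, seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[2] == b[2]

    def test_matches_sklearn_on_blobs(self, rng):
        sk = pytest.importorskip("sklearn.cluster")
        X = np.vstack([rng.normal(size=(30, 2)) + off
                       for off in ([0, 0], [10, 0], [0, 10])])
        _, _, inertia = kmeans_pp(X, 3, seed=0)
        ref = sk.KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
        assert inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_k_above_n_raises(self, rng):
        with pytest.raises(ValueError):
            kmeans_pp(rng.normal(size=(4, 2)), 5, seed=0)


class TestSelectK:
    def test_three_blobs_select_three(self, rng):
        X = np.vstack([rng.normal(scale=0.5, size=(40, 2)) + off
                       for off in ([0, 0], [8, 0], [0, 8])])
        k, diag = select_k(X, (2, 6), seed=0)
        assert k == 3
        assert set(diag) == {2, 3, 4, 5, 6}

    def test_row_order_independent(self, rng):
        X = np.vstack([rng.normal(scale=0.5, size=(30, 2)) + off
                       for off in ([0, 0], [6, 6])])
        k1, _ = select_k(X, (2, 4), seed=0)
        k2, _ = select_k(X[rng.permutation(len(X))], (2, 4), seed=0)
        assert k1 == k2 == 2

    def test_silhouette_matches_sklearn(self, rng):
        metrics = pytest.importorskip("sklearn.metrics")
        X = rng.normal(size=(60, 3))
        labels = rng.integers(0, 3, size=60)
        assert silhouette(X, labels) == pytest.approx(
            metrics.silhouette_score(X, labels), abs=1e-9)


class TestRawVsPca:
    def _sets(self, raw_vals, pca_vals):
        pairs = list(itertools.combinations(CONDITION_ORDER, 2))
        raw = CorrelationSet("raw_8d",
                             {p: (v, 0) for p, v in zip(pairs, raw_vals)})
        pca = CorrelationSet("pca_3d",
                             {p: (v, 0) for p, v in zip(pairs, pca_vals)})
        return raw, pca

    def test_identical_sets_raise(self, rng):
        vals = list(rng.uniform(0, 1, 45))
        raw, pca = self._sets(vals, vals)
        with pytest.raises(DegenerateTestError):
            compare_raw_vs_pca(raw, pca)

    def test_uniform_shift_gives_extreme_p(self, rng):
        vals = np.array(rng.uniform(0.4, 0.9, 45))
        raw, pca = self._sets(list(vals), list(vals - 0.3))
        res = compare_raw_vs_pca(raw, pca)
        assert res.n == 45
        assert res.pvalue < 1e-7      # all 45 signs agree
        assert res.median_difference == pytest.approx(-0.3)

    def test_swap_symmetry(self, rng):
        a = np.array(rng.uniform(0, 1, 45))
        b = np.clip(a + rng.normal(scale=0.2, size=45), -1, 1)
        raw, pca = self._sets(list(a), list(b))
        r1 = compare_raw_vs_pca(raw, pca)
        r2 = compare_raw_vs_pca(pca, raw)
        assert r1.pvalue == pytest.approx(r2.pvalue)
        assert r1.median_difference == pytest.approx(-r2.median_difference)


class TestXcorrProperties:
    """Correlation bound and role symmetry on arbitrary signals."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    vals = st.floats(min_value=-100.0, max_value=100.0,
                     allow_nan=False, allow_infinity=False)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(a=st.lists(vals, min_size=4, max_size=40),
           b=st.lists(vals, min_size=4, max_size=40))
    def test_bounded_and_symmetric(self, a, b):
        n = min(len(a), len(b))
        x = np.asarray(a[:n])[:, None]
        y = np.asarray(b[:n])[:, None]
        if np.all(x == x[0]) or np.all(y == y[0]):
            return  # constant blocks are covered by the error test
        r_xy, _ = xcorr_max(x, y)
        r_yx, _ = xcorr_max(y, x)
        assert -1.0 - 1e-12 <= r_xy <= 1.0 + 1e-12
        assert r_xy == pytest.approx(r_yx, abs=1e-12)
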