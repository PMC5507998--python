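"""Global network metrics, PBS distributions, variance decomposition, ICC."""

import itertools

import numpy as np
import pytest

from pbsnet import (ConnectivityMatrix, global_metrics, louvain_partition,
                    weighted_clustering, global_efficiency,
                    diversity_coefficient, pbs_metric_distribution,
                    variance_decomposition, icc, icc_comparison,
                    synth_metric_cohort, METRIC_NAMES)


def conn(w, kind="structural"):
    w = np.asarray(w, dtype=float)
    return ConnectivityMatrix(weights=w, node_sizes=np.ones(len(w)), kind=kind)


def complete_graph(n, w=1.0):
    m = np.full((n, n), w)
    np.fill_diagonal(m, 0.0)
    return m


def two_cliques(k=4):
    """Two disconnected unit-weight k-cliques."""
    w = np.zeros((2 * k, 2 * k))
    w[:k, :k] = complete_graph(k)
    w[k:, k:] = complete_graph(k)
    return w


def modularity_oracle(w, partition):
    """Direct Newman modularity from the definition."""
    two_m = w.sum()
    k = w.sum(axis=1)
    q = 0.0
    for group in partition:
        for i in group:
            for j in group:
                q += w[i, j] - k[i] * k[j] / two_m
    return q / two_m


def best_partition_exhaustive(w):
    """Max-modularity partition by enumerating all set partitions."""
    n = len(w)

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [[first] + part[i]] + part[i + 1:]
            yield [[first]] + part

    return max((modularity_oracle(w, p) for p in partitions(list(range(n)))))


class TestGlobalMetrics:
    @pytest.mark.parametrize("n", [4, 6])
    def test_complete_graph(self, n):
        g = global_metrics(conn(complete_graph(n)))
        assert g.degree == pytest.approx(n - 1)
        assert g.efficiency == pytest.approx(1.0)
        assert g.clustering == pytest.approx(1.0)
        assert g.strength == pytest.approx(n - 1)

    def test_two_cliques_modularity_matches_exhaustive_oracle(self):
        w = two_cliques(4)
        q_best = best_partition_exhaustive(w)
        assert q_best == pytest.approx(0.5)
        g = global_metrics(conn(w))
        assert g.modularity == pytest.approx(0.5, abs=1e-12)

    def test_diversity_zero_when_strength_confined_to_one_module(self):
        w = two_cliques(4)
        part, _ = louvain_partition(w)
        h = diversity_coefficient(w, part)
        np.testing.assert_allclose(h, 0.0)  # all strength inside own module

    def test_diversity_maximal_for_even_spread(self):
        # star-of-modules: node 0 connects equally into both modules
        w = two_cliques(3).astype(float)
        part = [[0, 1, 2], [3, 4, 5]]
        w[0, 3] = w[3, 0] = w[0, 1]  # give node 0 equal strength in each module
        w[0, 2] = w[2, 0] = 0.0
        h = diversity_coefficient(w, part)
        assert h[0] == pytest.approx(1.0)

    def test_empty_graph_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            g = global_metrics(conn(np.zeros((4, 4))))
        assert g.as_array().tolist() == [0.0] * 6

    def test_signed_fc_strength_keeps_sign(self):
        w = np.array([[0, 0.5, -0.5], [0.5, 0, 0], [-0.5, 0, 0]])
        g = global_metrics(conn(w, kind="functional"))
        assert g.strength == pytest.approx(w.sum(axis=1).mean())
        assert g.degree == pytest.approx((w != 0).sum(axis=1).mean())

    def test_efficiency_uses_inverse_weight_costs(self):
        # path a-b-c with strong edges: d(a,c) = 1/w1 + 1/w2
        w = np.array([[0, 2.0, 0], [2.0, 0, 4.0], [0, 4.0, 0]])
        d_ac = 1 / 2.0 + 1 / 4.0
        expected = np.mean([1 / (1 / 2.0), 1 / (1 / 4.0), 1 / d_ac])
        assert global_efficiency(w) == pytest.approx(expected)

    def test_onnela_clustering_triangle_value(self):
        w = np.array([[0, 1.0, 0.5], [1.0, 0, 0.25], [0.5, 0.25, 0]])
        what = np.cbrt(w / w.max())
        # closed 3-walks count both orientations: 2 * product over the triangle
        expected0 = 2 * what[0, 1] * what[1, 2] * what[0, 2]
        c = weighted_clustering(w)
        assert c[0] == pytest.approx(expected0 / (2 * 1))

    def test_modularity_nondecreasing_in_restarts(self):
        rng = np.random.default_rng(8)
        w = (rng.random((30, 30)) < 0.2) * rng.random((30, 30))
        w = np.triu(w, 1)
        w = w + w.T
        qs = [global_metrics(conn(w), n_restarts=r, seed=0).modularity
              for r in (1, 5, 20)]
        assert qs[0] <= qs[1] <= qs[2]


class TestDistribution:
    def test_constant_vector_flagged(self):
        table = np.ones((30, 6))
        out = pbs_metric_distribution(table)
        for name in METRIC_NAMES:
            assert out[name]["constant"]
            assert out[name]["lilliefors_p"] is None
            assert out[name]["sd"] == 0.0

    def test_lilliefors_false_positive_rate_on_normal_draws(self):
        """At alpha=0.05 the test should reject ~5% of normal samples."""
        rng = np.random.default_rng(9)
        rejections = 0
        reps = 400
        for _ in range(reps):
            x = rng.normal(size=(400, 1))
            out = pbs_metric_distribution(x, names=("m",))
            rejections += out["m"]["lilliefors_p"] < 0.05
        rate = rejections / reps
        assert 0.02 < rate < 0.09  # Monte-Carlo band around 5%


class TestVarianceDecomposition:
    def test_identical_scans_zero_between_scan(self):
        rng = np.random.default_rng(10)
        scan = rng.normal(size=(6, 1, 20, 6))
        cohort = np.concatenate([scan, scan], axis=1)
        vd = variance_decomposition(cohort)
        for name in METRIC_NAMES:
            assert vd.sigma_between_scan[name] == 0.0

    def test_two_subject_hand_case(self):
        # subject means (1,1) and (3,3): no scan effect, sd(1,3) across subjects
        cohort = np.zeros((2, 2, 5, 1))
        cohort[0] = 1.0
        cohort[1] = 3.0
        vd = variance_decomposition(cohort[..., 0])
        assert vd.sigma_between_scan["degree"] == 0.0
        assert vd.sigma_subject["degree"] == pytest.approx(np.std([1, 3], ddof=1))
        assert vd.sigma_parcellation["degree"] == 0.0

    def test_affine_shift_invariance(self):
        cohort = synth_metric_cohort(rng_seed=11)
        a = variance_decomposition(cohort)
        b = variance_decomposition(cohort + 100.0)
        for key in ("sigma_parcellation", "sigma_between_scan", "sigma_subject"):
            assert getattr(a, key)["degree"] == \
                pytest.approx(getattr(b, key)["degree"])

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            variance_decomposition(np.zeros((1, 2, 5)))

    def test_component_recovery_on_synthetic_cohort(self):
        """Injected variance components are recovered (averaged over
        replicate cohorts, against the analytic estimator expectations)."""
        s_subj, s_scan, s_parc, n_par = 1.0, 0.3, 0.3, 50
        reps = 10
        est = np.zeros(3)
        for r in range(reps):
            cohort = synth_metric_cohort(20, n_par, sigma_subject=s_subj,
                                         sigma_scan=s_scan,
                                         sigma_parcellation=s_parc,
                                         rng_seed=100 + r)
            vd = variance_decomposition(cohort)
            est += [vd.sigma_parcellation["degree"],
                    vd.sigma_between_scan["degree"],
                    vd.sigma_subject["degree"]]
        est /= reps
        expected = [s_parc,
                    np.sqrt(2 * s_scan ** 2 + 2 * s_parc ** 2 / n_par),
                    np.sqrt(s_subj ** 2 + s_scan ** 2 + s_parc ** 2 / n_par)]
        np.testing.assert_allclose(est, expected, rtol=0.15)


class TestICC:
    def test_perfect_reliability(self):
        y = np.tile(np.arange(5.0)[:, None], (1, 2))
        assert icc(y) == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            icc(np.ones((4, 2)))

    def test_matches_anova_sums_of_squares_oracle(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(5, 2))
        n, k = y.shape
        grand = y.mean()
        ssb = k * ((y.mean(1) - grand) ** 2).sum()
        ssw = ((y - y.mean(1, keepdims=True)) ** 2).sum()
        msb, msw = ssb / (n - 1), ssw / (n * (k - 1))
        oracle = (msb - msw) / (msb + (k - 1) * msw)
        assert icc(y) == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_icc1(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        rng = np.random.default_rng(13)
        y = rng.normal(size=(8, 2)) + rng.normal(size=(8, 1))
        df = pd.DataFrame({"subject": np.repeat(np.arange(8), 2),
                           "rater": np.tile([0, 1], 8),
                           "score": y.ravel()})
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        icc1 = ref.loc[ref["Type"].isin(["ICC1", "ICC(1,1)"]), "ICC"].iloc[0]
        assert icc(y) == pytest.approx(icc1, abs=1e-10)

    def test_can_be_negative(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        assert icc(y) < 0


class TestICCComparison:
    def test_identical_parcellations_equalize_iccs(self):
        rng = np.random.default_rng(14)
        base = rng.normal(size=(6, 2, 1, 1))
        cohort = np.tile(base, (1, 1, 10, 1))
        rep = icc_comparison(cohort[..., 0])
        assert rep.icc_of_mean["degree"] == pytest.approx(rep.mean_icc["degree"])

    def test_parcellation_noise_favors_icc_of_mean(self):
        """Averaging over the ensemble removes independent parcellation
        noise, so the ICC of the mean exceeds the mean per-parcellation
        ICC on almost every synthetic cohort."""
        wins = 0
        n_cohorts = 20
        for r in range(n_cohorts):
            cohort = synth_metric_cohort(20, 50, sigma_subject=1.0,
                                         sigma_scan=0.3,
                                         sigma_parcellation=0.5,
                                         rng_seed=200 + r)
            rep = icc_comparison(cohort)
            wins += rep.icc_of_mean["degree"] > rep.mean_icc["degree"]
        assert wins >= int(0.95 * n_cohorts)
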