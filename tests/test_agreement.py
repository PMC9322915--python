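"""Time-domain agreement statistics: ICC, CCC, Bland-Altman, DTW, NSI, KS."""

import numpy as np
import pytest

from gaitagree import agreement as agr


def brute_force_dtw(a, b):
    """Exhaustive enumeration of all monotone warping paths."""
    n, m = len(a), len(b)
    best = [np.inf]

    def rec(i, j, acc):
        acc = acc + abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            rec(i + 1, j + 1, acc)
        if i + 1 < n:
            rec(i + 1, j, acc)
        if j + 1 < m:
            rec(i, j + 1, acc)

    rec(0, 0, 0.0)
    return best[0]


def anova_icc_oracle(y1, y2):
    """Brute-force two-way ANOVA ICC(A,1) from explicit sums of squares."""
    y = np.column_stack([y1, y2])
    n, k = y.shape
    grand = y.mean()
    msr = k * np.sum((y.mean(axis=1) - grand) ** 2) / (n - 1)
    msc = n * np.sum((y.mean(axis=0) - grand) ** 2) / (k - 1)
    mse = (np.sum((y - y.mean(axis=1, keepdims=True)
                   - y.mean(axis=0, keepdims=True) + grand) ** 2)
           / ((n - 1) * (k - 1)))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


class TestICC:
    def test_duplicated_trial_gives_one(self):
        x = np.sin(np.arange(30))
        res = agr.icc_two_way_absolute_single(x, x)
        assert res.icc == 1.0
        assert res.ci_lower == res.ci_upper == 1.0

    def test_large_offset_penalized_and_matches_oracle(self):
        rng = np.random.default_rng(1)
        y1 = rng.standard_normal(20)
        y2 = y1 + 10.0 * y1.std()
        res = agr.icc_two_way_absolute_single(y1, y2)
        assert res.icc < 0.5
        assert res.icc == pytest.approx(anova_icc_oracle(y1, y2), abs=1e-12)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(2)
        mu = rng.standard_normal(40)
        y1 = mu + rng.standard_normal(40) / 3
        y2 = mu + 0.1 + rng.standard_normal(40) / 3
        res = agr.icc_two_way_absolute_single(y1, y2)
        frame = pd.DataFrame({
            "targets": np.repeat(np.arange(40), 2),
            "raters": np.tile(["t1", "t2"], 40),
            "ratings": np.column_stack([y1, y2]).ravel()})
        ref = pingouin.intraclass_corr(frame, targets="targets",
                                       raters="raters", ratings="ratings")
        row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert res.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin reports the CI rounded to two decimals
        assert res.ci_lower == pytest.approx(row["CI95"][0], abs=6e-3)
        assert res.ci_upper == pytest.approx(row["CI95"][1], abs=6e-3)

    def test_variance_component_recovery(self):
        vals = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            mu = rng.standard_normal(100)
            y1 = mu + rng.standard_normal(100) / 3
            y2 = mu + rng.standard_normal(100) / 3
            vals.append(agr.icc_two_way_absolute_single(y1, y2).icc)
        assert np.mean(vals) == pytest.approx(0.9, abs=0.02)

    def test_input_guards(self):
        with pytest.raises(agr.AgreementError):
            agr.icc_two_way_absolute_single(np.arange(10), np.arange(9))
        with pytest.raises(agr.AgreementError):
            agr.icc_two_way_absolute_single(np.zeros(10), np.zeros(10))


class TestCCC:
    def test_identity_gives_one(self):
        x = np.sin(np.arange(50) / 3)
        assert agr.ccc_nonparametric(x, x).value == 1.0

    def test_independent_equal_distributions_near_zero(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(1000)
        y = rng.standard_normal(1000)
        assert abs(agr.ccc_nonparametric(x, y).value) < 0.08

    def test_agrees_with_lin_moment_estimator(self):
        rng = np.random.default_rng(4)
        xy = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], 2000)
        np_est = agr.ccc_nonparametric(xy[:, 0], xy[:, 1]).value
        assert np_est == pytest.approx(agr.ccc_lin(xy[:, 0], xy[:, 1]),
                                       abs=0.03)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 200))
        assert agr.ccc_nonparametric(x, y).value \
            == pytest.approx(agr.ccc_nonparametric(y, x).value, abs=1e-12)

    def test_invariant_under_common_affine_change(self):
        rng = np.random.default_rng(6)
        xy = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], 300)
        x, y = xy[:, 0], xy[:, 1]
        base = agr.ccc_nonparametric(x, y).value
        moved = agr.ccc_nonparametric(3.0 * x + 5.0, 3.0 * y + 5.0).value
        assert moved == pytest.approx(base, abs=1e-10)
        shifted = agr.ccc_nonparametric(x, y + 2.0).value
        assert shifted < base  # shifting one series degrades agreement

    def test_bootstrap_ci_method_brackets_estimate(self):
        rng = np.random.default_rng(7)
        xy = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], 300)
        res = agr.ccc_nonparametric(xy[:, 0], xy[:, 1],
                                    ci_method="bootstrap", n_boot=400)
        assert res.ci_lower <= res.value <= res.ci_upper

    def test_degenerate_input_rejected(self):
        with pytest.raises(agr.AgreementError):
            agr.ccc_nonparametric(np.ones(20), np.ones(20))


class TestBlandAltman:
    def test_identity_degenerates_to_zero(self):
        x = np.sin(np.arange(40) / 2.0)
        res = agr.bland_altman_percentile(x, x, n_boot=200)
        for est in (res.bias, res.loa_lower, res.loa_upper):
            assert est.value == est.ci_lower == est.ci_upper == 0.0

    def test_constant_offset_fully_attributed_to_bias(self):
        x = np.sin(np.arange(40) / 2.0)
        res = agr.bland_altman_percentile(x, x - 0.05, n_boot=200)
        assert res.bias.value == pytest.approx(0.05, abs=1e-12)
        assert res.loa_lower.value == pytest.approx(0.05, abs=1e-12)
        assert res.loa_upper.value == pytest.approx(0.05, abs=1e-12)

    def test_uniform_differences_closed_form(self):
        rng = np.random.default_rng(8)
        x = rng.standard_normal(10000)
        y = x - rng.uniform(-1.0, 1.0, 10000)
        res = agr.bland_altman_percentile(x, y, n_boot=500, seed=1)
        assert abs(res.bias.value) < 0.03
        assert res.loa_lower.value == pytest.approx(-0.95, abs=0.03)
        assert res.loa_upper.value == pytest.approx(0.95, abs=0.03)

    def test_scales_linearly_with_common_factor(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(100)
        y = x + rng.standard_normal(100) * 0.1
        base = agr.bland_altman_percentile(x, y, n_boot=200, seed=0)
        scaled = agr.bland_altman_percentile(3 * x, 3 * y, n_boot=200,
                                             seed=0)
        assert scaled.bias.value == pytest.approx(3 * base.bias.value,
                                                  abs=1e-12)
        assert scaled.loa_upper.value \
            == pytest.approx(3 * base.loa_upper.value, abs=1e-12)

    def test_input_guards(self):
        x = np.arange(25.0)
        with pytest.raises(agr.AgreementError):
            agr.bland_altman_percentile(x, x[:-1])
        with pytest.raises(agr.AgreementError):
            agr.bland_altman_percentile(x, x, n_boot=10)
        with pytest.raises(agr.AgreementError):
            agr.bland_altman_percentile(x[:10], x[:10])  # < 20 pairs


class TestSpearman:
    def test_proportional_error_detected(self):
        x = np.linspace(1, 10, 50)
        assert agr.spearman_diff_vs_criterion(x, x / 2) \
            == pytest.approx(1.0, abs=1e-9)
        assert agr.spearman_diff_vs_criterion(x, 2 * x) \
            == pytest.approx(-1.0, abs=1e-9)

    def test_independent_noise_uncorrelated(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(2000)
        y = x + rng.standard_normal(2000)
        assert abs(agr.spearman_diff_vs_criterion(x, y)) < 0.06

    def test_constant_differences_rejected(self):
        x = np.arange(20.0)
        with pytest.raises(agr.AgreementError):
            agr.spearman_diff_vs_criterion(x, x)


class TestDTW:
    def test_identical_sequences_zero_distance_diagonal_path(self):
        a = np.array([0.0, 1.0, 0.5, -0.2])
        res = agr.dtw(a, a)
        assert res.distance == 0.0
        assert res.path == [(i, i) for i in range(4)]

    def test_small_worked_example(self):
        assert agr.dtw([0, 1, 2], [0, 2]).distance == 1.0

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            a = rng.standard_normal(rng.integers(2, 9))
            b = rng.standard_normal(rng.integers(2, 9))
            assert agr.dtw(a, b).distance \
                == pytest.approx(brute_force_dtw(a, b), abs=1e-12)

    def test_symmetric_distance(self):
        rng = np.random.default_rng(12)
        a, b = rng.standard_normal((2, 30))
        assert agr.dtw(a, b).distance == pytest.approx(
            agr.dtw(b, a).distance, abs=1e-12)

    def test_path_monotone_with_correct_endpoints(self):
        rng = np.random.default_rng(13)
        a, b = rng.standard_normal(25), rng.standard_normal(18)
        path = agr.dtw(a, b).path
        assert path[0] == (0, 0) and path[-1] == (24, 17)
        steps = np.diff(np.asarray(path), axis=0)
        assert np.all(steps >= 0) and np.all(steps <= 1)


class TestNSI:
    def test_identical_signals_give_one(self):
        x = np.sin(np.arange(30) / 3.0)
        assert agr.nsi(x, x) == 1.0

    def test_two_point_reversal_gives_zero(self):
        assert agr.nsi([0.0, 1.0], [1.0, 0.0]) == 0.0

    def test_worked_example_five_sixths(self):
        assert agr.nsi([0, 1, 2], [0, 2]) == pytest.approx(5.0 / 6.0)

    def test_constant_criterion_rejected(self):
        with pytest.raises(agr.AgreementError):
            agr.nsi(np.ones(10), np.arange(10.0))

    def test_noise_monotonicity_with_ccc(self):
        # agreement indices should not improve as sensor noise grows
        t = np.linspace(0, 2 * np.pi, 65)
        truth = np.cos(t) + 0.3 * np.cos(2 * t)
        noise_grid = [0.0, 0.05, 0.1, 0.2, 0.4]
        ccc_means, nsi_means = [], []
        for sd in noise_grid:
            cccs, nsis = [], []
            for seed in range(20):
                rng = np.random.default_rng(seed)
                noisy = truth + sd * rng.standard_normal(t.size)
                cccs.append(agr.ccc_nonparametric(truth, noisy).value)
                nsis.append(agr.nsi(truth, noisy))
            ccc_means.append(np.mean(cccs))
            nsi_means.append(np.mean(nsis))
        assert sum(np.diff(ccc_means) > 0) <= 1  # allow one MC inversion
        assert sum(np.diff(nsi_means) > 0) <= 1


class TestKSNormality:
    def test_type_i_error_calibrated(self):
        rng = np.random.default_rng(14)
        rejections = sum(
            agr.ks_normality(rng.standard_normal(500))[1] < 0.05
            for _ in range(1000))
        assert 0.02 <= rejections / 1000 <= 0.09

    def test_power_against_exponential(self):
        rng = np.random.default_rng(15)
        rejections = sum(
            agr.ks_normality(rng.exponential(1.0, 500))[1] < 0.05
            for _ in range(200))
        assert rejections / 200 > 0.99

    def test_constant_input_rejected(self):
        with pytest.raises(agr.AgreementError):
            agr.ks_normality(np.ones(20))


class TestCompareSeries:
    def test_identity_summary_is_perfect(self):
        x = np.sin(np.arange(65) / 4.0)
        res = agr.compare_series(x, x, n_boot=200)
        assert res.ccc.value == 1.0
        assert res.nsi == 1.0
        assert res.bias.value == 0.0
        assert res.loa_upper.value - res.loa_lower.value == 0.0

    def test_bias_recovery_inside_bootstrap_ci(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            bias = [-0.05, 0.02, 0.08][seed % 3]
            x = rng.standard_normal(200)
            y = x - bias + 0.05 * rng.standard_normal(200)
            res = agr.bland_altman_percentile(x, y, n_boot=500, seed=seed)
            hits += res.bias.ci_lower <= bias <= res.bias.ci_upper
        assert hits >= 45  # >= 90% coverage
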