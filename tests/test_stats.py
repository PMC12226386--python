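"""Block-design group statistics: normalisation, segmentation, RM-ANOVA
against a from-scratch sums-of-squares oracle and pingouin, paired
comparisons, power, and the nonparametric tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirtrs.design import ExperimentDesign
from nirtrs.stats import (
    gg_epsilon,
    mauchly,
    normalize_baseline,
    paired_t,
    posthoc_power,
    required_n,
    rm_anova,
    segment_periods,
    shapiro_wilk,
    wilcoxon_signed_rank,
)


class TestNormalizeBaseline:
    def test_constant_series_maps_to_one(self, design):
        out = normalize_baseline(np.full(design.n_samples, 5.0), design)
        np.testing.assert_allclose(out, 1.0)

    def test_simple_arithmetic(self, design):
        values = np.full(design.n_samples, 2.0)
        values[50] = 2.2
        out = normalize_baseline(values, design)
        assert out[50] == pytest.approx(1.10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(k=st.floats(1e-3, 1e3, allow_nan=False))
    def test_scale_invariance(self, design, k):
        rng = np.random.default_rng(0)
        values = rng.uniform(4.0, 6.0, design.n_samples)
        np.testing.assert_allclose(
            normalize_baseline(values * k, design),
            normalize_baseline(values, design),
            rtol=1e-12,
        )

    def test_errors(self, design):
        with pytest.raises(ValueError, match="baseline mean"):
            normalize_baseline(np.zeros(design.n_samples), design)
        with pytest.raises(ValueError, match="samples"):
            normalize_baseline(np.ones(5), design)


class TestSegmentPeriods:
    def test_constant_gives_thirteen_ones(self, design):
        out = segment_periods(np.ones(design.n_samples), design)
        np.testing.assert_allclose(out, np.ones(13))

    def test_linear_ramp_mean_is_window_average(self, design):
        """For a linear ramp the window mean equals the mean of its sample
        values, hand-computed from the sample times in that window."""
        t = design.sample_times()
        series = 1.0 + 1e-4 * t
        out = segment_periods(series, design)
        idx = design.period_index(t)
        for p in [0, 6, 12]:
            expected = np.mean(1.0 + 1e-4 * t[idx == p])
            assert out[p] == pytest.approx(expected, rel=1e-12)

    def test_boundary_sample_belongs_to_later_window(self):
        """With dt = 4 s a sample lands exactly on the 60 s boundary; the
        half-open convention assigns it to the later period."""
        d = ExperimentDesign(sampling_rate_hz=0.25, baseline_samples=10)
        t = d.sample_times()
        i60 = np.nonzero(t == 60.0)[0][0]
        series = np.ones(d.n_samples)
        series[i60] = 2.0
        out = segment_periods(series, d)
        assert out[1] > 1.0 and out[0] == pytest.approx(1.0)


def oracle_two_way_rm(data):
    """From-scratch textbook sums-of-squares two-way within-subject ANOVA
    (explicit loops; independent of the vectorised implementation)."""
    n, a, b = data.shape
    grand = data.mean()
    ss_a = sum(
        n * b * (data[:, i, :].mean() - grand) ** 2 for i in range(a)
    )
    ss_b = sum(n * a * (data[:, :, j].mean() - grand) ** 2 for j in range(b))
    ss_ab = 0.0
    for i in range(a):
        for j in range(b):
            ss_ab += n * (
                data[:, i, j].mean()
                - data[:, i, :].mean()
                - data[:, :, j].mean()
                + grand
            ) ** 2
    ss_as = 0.0
    for s in range(n):
        for i in range(a):
            ss_as += b * (
                data[s, i, :].mean() - data[s].mean() - data[:, i, :].mean() + grand
            ) ** 2
    ss_bs = 0.0
    for s in range(n):
        for j in range(b):
            ss_bs += a * (
                data[s, :, j].mean() - data[s].mean() - data[:, :, j].mean() + grand
            ) ** 2
    ss_tot = ((data - grand) ** 2).sum()
    ss_subj = sum(a * b * (data[s].mean() - grand) ** 2 for s in range(n))
    ss_abs = ss_tot - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs
    f_a = (ss_a / (a - 1)) / (ss_as / ((n - 1) * (a - 1)))
    f_b = (ss_b / (b - 1)) / (ss_bs / ((n - 1) * (b - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((n - 1) * (a - 1) * (b - 1)))
    return f_a, f_b, f_ab


class TestRmAnova:
    def test_all_identical_cells_give_zero_f(self):
        res = rm_anova(np.full((5, 2, 13), 3.0))
        assert res.condition.F == 0.0 and res.condition.p == 1.0
        assert res.period.F == 0.0
        assert res.interaction.F == 0.0

    def test_integer_fixture_matches_sums_of_squares_oracle(self):
        data = np.array(
            [
                [[4, 6, 5], [7, 9, 8]],
                [[3, 5, 7], [6, 8, 9]],
                [[5, 4, 6], [8, 7, 10]],
                [[6, 7, 5], [9, 10, 8]],
            ],
            dtype=float,
        )
        f_a, f_b, f_ab = oracle_two_way_rm(data)
        res = rm_anova(data)
        assert res.condition.F == pytest.approx(f_a, rel=1e-12)
        assert res.period.F == pytest.approx(f_b, rel=1e-12)
        assert res.interaction.F == pytest.approx(f_ab, rel=1e-12)

    def test_matches_pingouin_two_way(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        data = rng.normal(0, 1, (10, 2, 5)) + rng.normal(0, 1, (10, 1, 1))
        rows = [
            {"s": s, "c": c, "p": p, "y": data[s, c, p]}
            for s in range(10)
            for c in range(2)
            for p in range(5)
        ]
        aov = pg.rm_anova(
            pd.DataFrame(rows), dv="y", within=["c", "p"], subject="s", detailed=True
        )
        res = rm_anova(data)
        assert res.condition.F == pytest.approx(aov["F"].iloc[0], rel=1e-9)
        assert res.period.F == pytest.approx(aov["F"].iloc[1], rel=1e-9)
        assert res.interaction.F == pytest.approx(aov["F"].iloc[2], rel=1e-9)
        assert res.epsilon_gg_interaction == pytest.approx(
            aov["eps"].iloc[2], rel=1e-9
        )

    def test_epsilon_bounds_for_13_periods(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            data = rng.normal(1.0, 0.02, (23, 2, 13))
            res = rm_anova(data)
            assert 1.0 / 12.0 <= res.epsilon_gg_period <= 1.0
            assert 1.0 / 12.0 <= res.epsilon_gg_interaction <= 1.0

    def test_epsilon_is_one_under_exact_sphericity(self):
        """Scores built so the orthonormal-contrast covariance is exactly
        proportional to the identity have epsilon exactly 1."""
        rng = np.random.default_rng(7)
        n, k = 10, 5
        raw = rng.normal(size=(n, k - 1))
        raw -= raw.mean(axis=0)
        q, _ = np.linalg.qr(raw)  # centered orthonormal columns
        c = np.linalg.qr(np.eye(k)[:, 1:] - 1.0 / k)[0][:, : k - 1]
        scores = q @ c.T + rng.normal(size=(n, 1))
        assert gg_epsilon(scores) == pytest.approx(1.0, abs=1e-10)

    def test_gg_correction_never_lowers_p_when_f_exceeds_one(self):
        """For F >= 1 shrinking both df by epsilon <= 1 cannot decrease
        the p-value (the usual conservativeness of the GG correction)."""
        rng = np.random.default_rng(11)
        data = rng.normal(1.0, 0.01, (12, 2, 13)) * np.linspace(0.97, 1.03, 13)
        data[:, 1, :] *= np.linspace(1.0, 1.02, 13)
        res = rm_anova(data)
        assert res.period.F > 1 and res.interaction.F > 1
        assert res.period.p_corr >= res.period.p
        assert res.interaction.p_corr >= res.interaction.p
        assert res.period.df1_corr <= res.period.df1

    def test_mauchly_matches_pingouin_w(self):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(42)
        scores = rng.normal(0, 1, (10, 5))
        w, p = mauchly(scores)
        sph = pg.sphericity(pd.DataFrame(scores))
        assert w == pytest.approx(sph.W, rel=1e-9)
        assert p == pytest.approx(sph.pval, abs=0.02)

    def test_missing_cells_rejected(self):
        data = np.ones((5, 2, 13))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova(data)


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t(np.arange(5.0), np.arange(5.0))
        assert res.t == 0.0 and res.p == 1.0

    def test_differences_1_2_3_oracle(self):
        """Differences [1,2,3]: t = 2/(1/sqrt(3)) = 3.4641, df = 2,
        two-tailed p = 0.0742 from the t CDF."""
        res = paired_t(np.array([1.0, 2.0, 3.0]), np.zeros(3))
        assert res.t == pytest.approx(3.4641016, rel=1e-6)
        assert res.df == 2
        assert res.p == pytest.approx(0.074180, abs=5e-5)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=(2, 12))
        assert paired_t(x, y).t == pytest.approx(-paired_t(y, x).t, rel=1e-12)

    def test_zero_variance_nonzero_mean_flagged(self):
        res = paired_t(np.array([2.0, 2.0, 2.0]), np.array([1.0, 1.0, 1.0]))
        assert res.extreme and res.p == 0.0

    def test_d_variants(self):
        x = np.array([1.014, 1.02, 1.0, 1.03, 1.01])
        y = np.array([0.99, 0.98, 1.0, 0.99, 0.97])
        res = paired_t(x, y)
        s_av = np.sqrt((x.std(ddof=1) ** 2 + y.std(ddof=1) ** 2) / 2)
        assert res.d == pytest.approx((x - y).mean() / s_av, rel=1e-12)
        assert res.d_z == pytest.approx((x - y).mean() / (x - y).std(ddof=1), rel=1e-12)


class TestPower:
    @pytest.mark.parametrize(
        "d,expected",
        [(0.74, 0.92), (0.49, 0.61), (0.56, 0.73)],
    )
    def test_reproduces_tabled_post_hoc_power(self, d, expected):
        assert posthoc_power(d, 23, 0.05) == pytest.approx(expected, abs=0.01)

    def test_zero_effect_gives_alpha(self):
        assert posthoc_power(0.0, 23, 0.05) == pytest.approx(0.05, abs=1e-9)

    def test_required_n_medium_effect(self):
        assert required_n(0.5, 0.05, 0.8) == 34

    def test_required_n_monotone_in_effect(self):
        assert required_n(0.8, 0.05, 0.8) < required_n(0.5, 0.05, 0.8)

    def test_required_n_matches_brute_force(self):
        """d = 1.0: integer search over the power function gives n = 10."""
        n = 2
        while posthoc_power(1.0, n, 0.05) < 0.8:
            n += 1
        assert n == 10
        assert required_n(1.0, 0.05, 0.8) == 10

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            posthoc_power(-0.1, 23)
        with pytest.raises(ValueError):
            required_n(0.0)


class TestWilcoxon:
    def test_all_positive_differences_give_max_w(self):
        x = np.arange(1.0, 24.0)
        res = wilcoxon_signed_rank(x, np.zeros(23))
        assert res.w == 23 * 24 / 2 == 276

    def test_small_sample_enumeration_oracle(self):
        """Differences [1,-2,3]: signed ranks [1,-2,3], W = 2; exact
        two-tailed p = 6/8 from the 2^3 sign enumeration."""
        res = wilcoxon_signed_rank(np.array([1.0, -2.0, 3.0]), np.zeros(3))
        assert res.w == 2.0
        assert res.p == pytest.approx(0.75, abs=1e-12)

    def test_sign_flip_negates_w(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        a = wilcoxon_signed_rank(x, np.zeros(15))
        b = wilcoxon_signed_rank(-x, np.zeros(15))
        assert a.w == -b.w

    def test_zero_differences_dropped(self):
        res = wilcoxon_signed_rank(
            np.array([1.0, 0.0, 2.0, 0.0]), np.array([0.0, 0.0, 0.0, 0.0])
        )
        assert res.n_used == 2

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(np.ones(5), np.ones(5))


class TestShapiroWilk:
    def test_published_reference_vector(self):
        """Royston's classic weights example: W = 0.789, p = 0.0067
        (independently reproduced with R's shapiro.test)."""
        x = np.array([148, 154, 158, 160, 161, 162, 166, 170, 182, 195, 236.0])
        res = shapiro_wilk(x)
        assert res.w_stat == pytest.approx(0.789, abs=5e-4)
        assert res.p == pytest.approx(0.0067, abs=5e-4)

    def test_affine_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        a = shapiro_wilk(x)
        b = shapiro_wilk(3.5 * x - 7.0)
        assert a.w_stat == pytest.approx(b.w_stat, rel=1e-9)

    def test_two_point_mixture_strongly_rejected(self):
        x = np.concatenate([np.zeros(25), np.ones(25)])
        x += np.random.default_rng(0).normal(0, 1e-6, 50)
        assert shapiro_wilk(x).p < 0.001

    def test_constant_input_degenerate(self):
        res = shapiro_wilk(np.full(10, 2.0))
        assert res.degenerate
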