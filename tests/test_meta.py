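import math

import numpy as np
import pytest

from mcidnorm.errors import DegenerateEffectError, ValidationError
from mcidnorm.meta import (
    EffectSize,
    Z_975,
    effects_from_unified,
    forest_data,
    heterogeneity_stats,
    i2_band,
    md_effect,
    pool_random_effects,
    random_effects_meta,
    reml_tau2,
    render_forest,
)
from mcidnorm.prioritize import UnifiedOutcome
from mcidnorm.simulate import simulate_effects


def grid_reml_tau2(y, v, upper=10.0):
    """Independent brute-force maximizer of the restricted log-likelihood.

    Coarse grid over [0, upper] followed by a fine 1e-6-step refinement around
    the coarse winner; written directly from the restricted-likelihood
    formula, sharing no code with the estimator under test.
    """
    y = np.asarray(y, dtype=float)
    v = np.asarray(v, dtype=float)

    def ll(t2):
        w = 1.0 / (v[None, :] + t2[:, None])
        mu = (w * y).sum(axis=1) / w.sum(axis=1)
        return -0.5 * (
            np.log(v[None, :] + t2[:, None]).sum(axis=1)
            + np.log(w.sum(axis=1))
            + (w * (y - mu[:, None]) ** 2).sum(axis=1)
        )

    coarse = np.arange(0.0, upper + 1e-3, 1e-3)
    t0 = coarse[int(np.argmax(ll(coarse)))]
    fine = np.arange(max(0.0, t0 - 2e-3), t0 + 2e-3, 1e-6)
    return float(fine[int(np.argmax(ll(fine)))])


def effects(y, v):
    return [EffectSize(f"s{i}", yi, vi) for i, (yi, vi) in enumerate(zip(y, v))]


def arm(study, arm_id, mean, sd, n):
    return UnifiedOutcome(study, arm_id, n, "mHHS", mean, sd)


class TestMdEffect:
    def test_identical_arms_give_zero_md(self):
        e = md_effect(arm("s", "1", 8.0, 1.0, 30), arm("s", "2", 8.0, 1.2, 28))
        assert e.md == 0.0

    def test_worked_difference_and_variance(self):
        # printed one-decimal summaries: 8.9 vs 8.8, SD 1.2/1.3, n 22/21
        e = md_effect(arm("s1", "1", 8.9, 1.2, 22), arm("s1", "2", 8.8, 1.3, 21))
        assert e.md == pytest.approx(0.1)
        assert e.variance == pytest.approx(1.2**2 / 22 + 1.3**2 / 21)
        assert e.variance == pytest.approx(0.1459, abs=5e-4)
        assert e.se == pytest.approx(math.sqrt(e.variance))

    def test_second_worked_difference(self):
        e = md_effect(arm("s6", "1", 5.8, 1.0, 45), arm("s6", "2", 5.0, 1.2, 46))
        assert e.md == pytest.approx(0.8)

    def test_different_studies_rejected(self):
        with pytest.raises(ValidationError):
            md_effect(arm("a", "1", 8.0, 1.0, 30), arm("b", "2", 8.0, 1.0, 30))

    def test_zero_variance_in_both_arms_degenerate(self):
        with pytest.raises(DegenerateEffectError):
            md_effect(arm("s", "1", 8.0, 0.0, 30), arm("s", "2", 7.0, 0.0, 30))

    def test_reference_arm_is_subtrahend(self):
        unified = [arm("s", "1", 8.9, 1.2, 22), arm("s", "2", 8.8, 1.3, 21)]
        (e12,) = effects_from_unified(unified, reference_arm="2")
        (e21,) = effects_from_unified(unified, reference_arm="1")
        assert e12.md == pytest.approx(0.1)
        assert e21.md == pytest.approx(-0.1)

    def test_unknown_reference_arm_errors(self):
        unified = [arm("s", "1", 8.9, 1.2, 22), arm("s", "2", 8.8, 1.3, 21)]
        with pytest.raises(ValidationError, match="reference arm"):
            effects_from_unified(unified, reference_arm="3")


class TestRemlTau2:
    def test_zero_dispersion_gives_zero(self):
        assert reml_tau2(effects([0.4] * 5, [0.1, 0.2, 0.05, 0.1, 0.3])) == 0.0

    def test_two_point_case_matches_dense_grid(self):
        y, v = [0.0, 1.0], [0.1, 0.1]
        t2 = reml_tau2(effects(y, v))
        # full-resolution single-pass grid for this one case
        grid = np.arange(0.0, 10.0, 1e-6)
        w = 1.0 / (np.array(v)[None, :] + grid[:, None])
        mu = (w * np.array(y)).sum(axis=1) / w.sum(axis=1)
        ll = -0.5 * (
            np.log(np.array(v)[None, :] + grid[:, None]).sum(axis=1)
            + np.log(w.sum(axis=1))
            + (w * (np.array(y) - mu[:, None]) ** 2).sum(axis=1)
        )
        assert t2 == pytest.approx(float(grid[int(np.argmax(ll))]), abs=1e-5)

    def test_matches_grid_oracle_on_random_small_instances(self):
        rng = np.random.default_rng(2024)
        for _ in range(60):
            k = int(rng.integers(2, 11))
            y = rng.normal(0.3, 0.6, size=k)
            v = rng.uniform(0.01, 0.4, size=k)
            assert reml_tau2(effects(y, v)) == pytest.approx(
                grid_reml_tau2(y, v), abs=1e-5
            )

    def test_recovers_true_tau2_at_scale(self):
        # k=100, tau2=0.09, v~0.01: REML should land near the truth
        rng = np.random.default_rng(11)
        estimates = []
        for _ in range(200):
            theta = 0.4 + 0.3 * rng.standard_normal(100)
            v = rng.uniform(0.008, 0.012, size=100)
            y = theta + np.sqrt(v) * rng.standard_normal(100)
            estimates.append(reml_tau2(effects(y, v)))
        mc_se = np.std(estimates, ddof=1) / math.sqrt(len(estimates))
        assert abs(np.mean(estimates) - 0.09) < 3 * mc_se

    def test_fewer_than_two_studies_rejected(self):
        with pytest.raises(ValidationError):
            reml_tau2(effects([0.4], [0.1]))


class TestPooling:
    def test_single_study_pool_is_that_study(self):
        e = effects([0.5], [0.04])
        res = pool_random_effects(e, 0.0)
        assert res.mu == pytest.approx(0.5)
        assert res.se_mu == pytest.approx(0.2)
        assert res.ci_low == pytest.approx(0.5 - Z_975 * 0.2)

    def test_tau2_zero_reduces_to_fixed_effect(self):
        y, v = [0.1, 0.5, 0.3], [0.1, 0.05, 0.2]
        res = pool_random_effects(effects(y, v), 0.0)
        w = 1 / np.array(v)
        assert res.mu == pytest.approx(float(np.sum(w * y) / np.sum(w)), abs=1e-15)
        assert res.se_mu == pytest.approx(float(np.sum(w) ** -0.5), abs=1e-15)

    def test_equal_variances_pool_to_arithmetic_mean(self):
        res = pool_random_effects(effects([0.1, 0.5, 0.9], [0.1] * 3), 0.0)
        assert res.mu == pytest.approx(0.5)
        assert res.weights == pytest.approx((1 / 3,) * 3)

    def test_pooled_estimate_within_effect_range(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            k = int(rng.integers(2, 12))
            y = rng.normal(0, 1, size=k)
            v = rng.uniform(0.01, 0.5, size=k)
            res = random_effects_meta(effects(y, v))
            assert min(y) - 1e-12 <= res.mu <= max(y) + 1e-12

    def test_huge_tau2_approaches_unweighted_mean(self):
        y, v = [0.1, 0.5, 0.9, 0.2], [0.01, 0.3, 0.05, 0.2]
        res = pool_random_effects(effects(y, v), 1e6)
        assert res.mu == pytest.approx(np.mean(y), abs=1e-6)
        assert res.weights == pytest.approx((0.25,) * 4, abs=1e-7)

    def test_weights_sum_to_one(self):
        res = random_effects_meta(effects([0.1, 0.4, 0.9], [0.1, 0.2, 0.05]))
        assert sum(res.weights) == pytest.approx(1.0, abs=1e-12)

    def test_negative_tau2_rejected(self):
        with pytest.raises(ValidationError):
            pool_random_effects(effects([0.1, 0.2], [0.1, 0.1]), -0.1)

    def test_knapp_hartung_interval(self):
        import scipy.stats

        y, v = [0.1, 0.5, 0.3, 0.8], [0.1, 0.05, 0.2, 0.02]
        eff = effects(y, v)
        tau2 = reml_tau2(eff)
        res = pool_random_effects(eff, tau2, ci_method="knapp-hartung")
        # independent evaluation: var(mu) scaled by weighted residual mean
        # square, t(k-1) critical value
        w = 1.0 / (np.asarray(v) + tau2)
        mu = float(np.sum(w * y) / np.sum(w))
        se = math.sqrt(float(np.sum(w * (np.asarray(y) - mu) ** 2)) / 3 / float(np.sum(w)))
        crit = scipy.stats.t.ppf(0.975, 3)
        assert res.mu == pytest.approx(mu)
        assert res.se_mu == pytest.approx(se)
        assert res.ci_low == pytest.approx(mu - crit * se)
        assert res.ci_high == pytest.approx(mu + crit * se)
        # same point estimate as the Wald pool, wider small-k interval here
        wald = pool_random_effects(eff, tau2)
        assert res.mu == wald.mu
        assert res.ci_high - res.ci_low > wald.ci_high - wald.ci_low

    def test_knapp_hartung_needs_two_studies(self):
        with pytest.raises(ValidationError):
            pool_random_effects(effects([0.5], [0.04]), 0.0, ci_method="knapp-hartung")


class TestHeterogeneity:
    def test_identical_effects_no_heterogeneity(self):
        q, df, i2, band = heterogeneity_stats(effects([0.4, 0.4, 0.4], [0.1, 0.2, 0.1]))
        assert q == pytest.approx(0.0)
        assert df == 2
        assert i2 == 0.0
        assert band == "low"

    def test_hand_evaluated_two_study_case(self):
        # w = 10 each, fixed-effect mean 1: Q = 10*1 + 10*1 = 20, I2 = 95%
        q, df, i2, band = heterogeneity_stats(effects([0.0, 2.0], [0.1, 0.1]))
        assert q == pytest.approx(20.0)
        assert df == 1
        assert i2 == pytest.approx(95.0)
        assert band == "high"

    def test_q_below_df_clamps_i2_to_zero(self):
        q, df, i2, band = heterogeneity_stats(effects([0.40, 0.41], [0.5, 0.5]))
        assert q < df
        assert i2 == 0.0
        assert band == "low"

    @pytest.mark.parametrize("i2,expected", [(0.0, "low"), (24.99, "low"),
                                             (25.0, "moderate"), (50.0, "moderate"),
                                             (75.0, "moderate"), (75.01, "high"),
                                             (100.0, "high")])
    def test_band_boundaries(self, i2, expected):
        # exact boundaries (25, 75) are classified moderate
        assert i2_band(i2) == expected

    def test_band_consistent_with_computed_i2(self):
        # two studies, equal weights w=10: Q = 2 * w * (d/2)^2 = 5 d^2
        for d, expected in [(0.4, "low"), (0.6, "moderate"), (2.0, "high")]:
            q, _, got_i2, band = heterogeneity_stats(effects([0.0, d], [0.1, 0.1]))
            assert q == pytest.approx(5 * d**2)
            assert band == expected == i2_band(got_i2)


class TestCalibration:
    def test_parameter_recovery_and_coverage(self):
        # 500 simulated meta-analyses: k=15, true delta=0.4, tau=0.2
        rng = np.random.default_rng(314159)
        mus, covered = [], 0
        for _ in range(500):
            eff, _ = simulate_effects(15, 0.4, 0.2, rng)
            res = random_effects_meta(eff)
            mus.append(res.mu)
            covered += res.ci_low <= 0.4 <= res.ci_high
        assert abs(np.mean(mus) - 0.4) < 0.02
        assert 0.90 <= covered / 500 <= 0.98


class TestForest:
    def test_rows_and_summary(self):
        eff = effects([0.1, 0.5], [0.1, 0.1])
        res = random_effects_meta(eff)
        rows = forest_data(eff, res)
        assert len(rows) == 3
        assert rows[-1].is_summary
        assert sum(r.weight_percent for r in rows[:-1]) == pytest.approx(100.0, abs=0.1)
        assert rows[0].ci_low == pytest.approx(0.1 - Z_975 * math.sqrt(0.1))

    def test_single_study_row_weight_100(self):
        eff = effects([0.5], [0.04])
        rows = forest_data(eff, pool_random_effects(eff, 0.0))
        assert rows[0].weight_percent == pytest.approx(100.0)

    def test_render_writes_nonzero_file(self, tmp_path, demo_unified):
        eff = effects_from_unified(demo_unified, reference_arm="2")
        res = random_effects_meta(eff)
        path = tmp_path / "forest.svg"
        render_forest(forest_data(eff, res), path, result=res)
        assert path.exists() and path.stat().st_size > 0

    def test_render_empty_rows_errors(self, tmp_path):
        with pytest.raises(ValidationError):
            render_forest([], tmp_path / "x.svg")

    def test_render_deterministic(self, tmp_path):
        eff = effects([0.1, 0.5], [0.1, 0.1])
        res = random_effects_meta(eff)
        rows = forest_data(eff, res)
        p1, p2 = tmp_path / "a.svg", tmp_path / "b.svg"
        render_forest(rows, p1, result=res)
        render_forest(rows, p2, result=res)
        # svg output may embed ids; compare the annotation-bearing rows instead
        assert forest_data(eff, res) == rows
        assert p1.stat().st_size == p2.stat().st_size
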