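"""Residual analysis: deltas, optimum split, correlations, permutations."""

import numpy as np
import pandas as pd
import pytest

from noisefit import loess_fit
from noisefit.noise_fitness_analysis import (AnalysisConfig,
                                             classify_noise_groups,
                                             delta_metrics,
                                             exhaustive_permutation_p,
                                             optimum_split, pearson_test,
                                             permutation_median_test,
                                             robustness_grid)


def _panel(x, noise, fitness):
    return pd.DataFrame({
        "genotype": [f"g{i}" for i in range(len(x))],
        "median_expression_pct": x, "noise_pct": noise, "fitness": fitness})


class TestDeltaMetrics:
    def test_on_trend_noise_gives_zero_residuals(self):
        x = np.linspace(5, 120, 30)
        noise = 20 + 0.5 * x  # a local quadratic reproduces a line
        fitness = 1 - 0.05 * np.clip(1 - x / 85, 0, None) ** 2
        delta = delta_metrics(_panel(x, noise, fitness))
        assert np.allclose(delta.table["delta_noise"], 0.0, atol=1e-8)

    def test_planted_offset_recovered(self):
        # the smoother absorbs a little of a single-point offset (its
        # own tricube weight), so recovery tightens as the panel grows
        x = np.linspace(5, 120, 100)
        noise = 20 + 0.5 * x
        noise[33] += 2.0
        fitness = 1 - 0.05 * np.clip(1 - x / 85, 0, None) ** 2
        delta = delta_metrics(_panel(x, noise, fitness))
        dn = delta.table["delta_noise"]
        assert dn.iloc[33] == pytest.approx(2.0, abs=0.2)
        assert dn.iloc[33] == dn.max()

    def test_expression_cap_excludes_genotype(self):
        x = np.linspace(5, 120, 29).tolist() + [130.0]
        noise = 20 + 0.5 * np.asarray(x)
        fitness = np.ones(30)
        delta = delta_metrics(_panel(x, noise, fitness))
        assert "g29" not in set(delta.table["genotype"])
        assert len(delta.table) == 29

    def test_missing_column_named(self):
        df = _panel([1, 2, 3], [1, 2, 3], [1, 1, 1]).drop(columns="fitness")
        with pytest.raises(ValueError, match="fitness"):
            delta_metrics(df)

    def test_residuals_uncorrelated_with_expression(self, truth_level_panel):
        df, _ = truth_level_panel
        delta = delta_metrics(df)
        t = delta.table
        for col in ("delta_noise", "delta_fitness"):
            r, p, _ = pearson_test(t["median_expression_pct"], t[col])
            assert p > 0.01


class TestOptimumSplit:
    def test_plateau_threshold_matches_analytic_point(self):
        x = np.linspace(5, 124, 60)
        fitness = 1 - 0.05 * np.clip(1 - x / 85, 0, None) ** 2
        fit = loess_fit(x, fitness, span=2 / 3)
        threshold, classes = optimum_split(fit, AnalysisConfig())
        analytic = 85 * (1 - np.sqrt(0.1))  # where the truth drops by 0.005
        assert threshold == pytest.approx(analytic, abs=3.0)
        assert set(classes[x < threshold - 3]) <= {"far"}

    def test_zero_drop_threshold_at_argmax(self):
        x = np.linspace(0, 100, 40)
        y = -(x - 60.0) ** 2
        fit = loess_fit(x, y, span=1.0)
        cfg = AnalysisConfig(fitness_drop=0.0)
        threshold, _ = optimum_split(fit, cfg)
        assert threshold == pytest.approx(60.0, abs=0.5)

    def test_monotone_curve_threshold_low_side(self):
        x = np.linspace(0, 100, 40)
        fit = loess_fit(x, 0.9 + 0.001 * x, span=1.0)
        threshold, classes = optimum_split(fit, AnalysisConfig())
        assert threshold < 100.0
        assert classes[-1] == "close"

    def test_flat_curve_warns_all_close(self):
        x = np.linspace(0, 100, 40)
        fit = loess_fit(x, np.ones(40), span=1.0)
        with pytest.warns(UserWarning):
            _, classes = optimum_split(fit, AnalysisConfig())
        assert set(classes) == {"close"}


class TestPearson:
    def test_perfect_linear(self):
        dx = np.array([1.0, 2.0, 3.0, 4.0])
        r, p, r2 = pearson_test(dx, 2 * dx)
        assert r == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)

    def test_three_collinear_points(self):
        r, p, _ = pearson_test([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert np.isfinite(p)

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(200):
            r, p, _ = pearson_test(rng.normal(size=30), rng.normal(size=30))
            ps.append(p)
        # a uniform p-value distribution has mean 1/2 and ~10% below 0.1
        assert abs(np.mean(ps) - 0.5) < 0.08
        assert abs(np.mean(np.asarray(ps) < 0.1) - 0.1) < 0.08

    def test_permutation_matches_t_for_strong_effect(self):
        rng = np.random.default_rng(1)
        dx = rng.normal(size=40)
        dy = dx + rng.normal(0, 0.5, 40)
        r, p_perm, _ = pearson_test(dx, dy, method="permutation",
                                    n_perm=20_000, seed=2)
        assert r > 0.8
        assert p_perm < 1e-3


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        p = permutation_median_test([1.0, 1.0, 1.0, 1.0],
                                    ["a", "a", "b", "b"], n_perm=1000)
        assert p == 1.0

    def test_small_case_exhaustive_third(self):
        p = exhaustive_permutation_p([1, 2, 3, 4], ["a", "a", "b", "b"])
        assert p == pytest.approx(1 / 3)

    @pytest.mark.parametrize("statistic", ["median", "mean", "sd"])
    def test_monte_carlo_matches_enumeration(self, statistic):
        rng = np.random.default_rng(3)
        values = rng.normal(size=9)
        labels = np.array(["a"] * 4 + ["b"] * 5)
        exact = exhaustive_permutation_p(values, labels, statistic)
        n_perm = 20_000
        mc = permutation_median_test(values, labels, statistic,
                                     n_perm=n_perm, seed=4)
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(mc - exact) <= 3 * se + 1e-12

    def test_separated_groups_tiny_p(self):
        values = np.concatenate([np.arange(20), 100 + np.arange(20)])
        labels = np.array(["a"] * 20 + ["b"] * 20)
        p = permutation_median_test(values, labels, n_perm=100_000, seed=5)
        assert p <= 1e-4

    def test_two_groups_required(self):
        with pytest.raises(ValueError):
            permutation_median_test([1, 2, 3], ["a", "a", "a"])


class TestNoiseGroups:
    def test_three_way_labels(self):
        labels = classify_noise_groups([-1.5, 0.5, 1.01, -1.0, 1.0])
        assert labels.tolist() == ["low", "middle", "high",
                                   "middle", "middle"]


class TestRobustnessGrid:
    def test_grid_has_100_rows(self, truth_level_panel):
        df, _ = truth_level_panel
        grid = robustness_grid(df)
        assert len(grid) == 100
        assert grid[["span_noise", "span_fitness",
                     "fitness_drop"]].drop_duplicates().shape[0] == 100

    def test_planted_effect_positive_everywhere(self, truth_level_panel):
        df, _ = truth_level_panel
        grid = robustness_grid(df)
        far = grid["r_far"].dropna()
        assert (far > 0).all()

    def test_null_panel_sign_not_consistent(self):
        from noisefit.synthetic_data import gen_study_panel
        panel = gen_study_panel(43, noise_effect=0.0, seed=23,
                                generate_events=False)
        t = panel.truth
        # noiseless truth has zero residual scatter in fitness, so add
        # measurement-scale jitter to emulate a finite null experiment
        rng = np.random.default_rng(5)
        df = pd.DataFrame({
            "genotype": t["genotype_id"],
            "median_expression_pct": t["expr_pct_true"],
            "noise_pct": t["noise_pct_true"],
            "fitness": t["w_true"] + rng.normal(0, 0.002, len(t)),
        })
        grid = robustness_grid(df)
        far = grid["r_far"].dropna()
        # no consistently strong correlation of either sign under the null
        assert not (far > 0.4).all()
        assert not (far < -0.4).all()
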