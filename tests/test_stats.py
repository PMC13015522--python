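"""Two-way unbalanced ANOVA and the ANOVA-gated stimulus regression."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binomtest, f as f_dist, kstest

from tiltpost.stats import (
    condition_regression,
    trend_analysis,
    two_way_anova,
)


def table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "condition", "value"])


def _type2_oracle(df):
    """Type-II F and p for the condition factor via explicit model comparison.

    Fits the additive model and the animal-only model with least squares on
    dummy-coded design matrices and forms the extra-sum-of-squares F test.
    """
    y = df["value"].to_numpy(float)

    def rss(cols):
        X = np.column_stack([np.ones(len(df))] + cols)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r), X.shape[1]

    def dummies(col):
        levels = sorted(df[col].unique())[1:]
        return [(df[col] == lv).to_numpy(float) for lv in levels]

    rss_full, p_full = rss(dummies("animal_id") + dummies("condition"))
    rss_red, _ = rss(dummies("animal_id"))
    df_num = len(df["condition"].unique()) - 1
    df_den = len(df) - p_full
    F = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    return F, float(f_dist.sf(F, df_num, df_den))


class TestTwoWayAnova:
    def test_strong_condition_effect_no_animal_effect(self):
        rng = np.random.default_rng(0)
        rows = [
            (animal, cond, {1: 1.0, 2: 2.0, 3: 3.0}[cond] + rng.normal(0, 1e-8))
            for animal in ("a", "b")
            for cond in (1, 2, 3)
            for _ in range(5)
        ]
        p_cond, p_animal = two_way_anova(table(rows))
        assert p_cond < 1e-10
        assert p_animal > 0.025  # no animal effect: not significant

    def test_unbalanced_table_matches_model_comparison_oracle(self):
        rng = np.random.default_rng(42)
        rows = []
        for animal, cond, n in [
            ("a", 1, 3), ("a", 2, 4), ("a", 3, 5),
            ("b", 1, 5), ("b", 2, 3), ("b", 3, 4),
        ]:
            for _ in range(n):
                rows.append((animal, cond, cond * 0.5 + (animal == "b") + rng.normal()))
        df = table(rows)
        p_cond, _ = two_way_anova(df)
        _, p_expected = _type2_oracle(df)
        assert p_cond == pytest.approx(p_expected, rel=1e-10)

    def test_balanced_reduces_to_classical_decomposition(self):
        """On balanced data the Type-II F equals the classical two-way F."""
        rng = np.random.default_rng(7)
        animals, conds, reps = ("a", "b", "c"), (1, 2, 3), 4
        rows = [
            (a, c, c + 0.5 * i + rng.normal())
            for i, a in enumerate(animals)
            for c in conds
            for _ in range(reps)
        ]
        df = table(rows)
        p_cond, _ = two_way_anova(df)
        # classical balanced main-effect SS about the grand mean
        y = df["value"].to_numpy()
        grand = y.mean()
        ss_cond = sum(
            len(g) * (g["value"].mean() - grand) ** 2 for _, g in df.groupby("condition")
        )
        # residual from the additive least-squares fit
        def dummies(col):
            levels = sorted(df[col].unique())[1:]
            return [(df[col] == lv).to_numpy(float) for lv in levels]

        X = np.column_stack([np.ones(len(df))] + dummies("animal_id") + dummies("condition"))
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss_full = float(np.sum((y - X @ beta) ** 2))
        df_num = len(conds) - 1
        df_den = len(df) - X.shape[1]
        F_classical = (ss_cond / df_num) / (rss_full / df_den)
        p_classical = float(f_dist.sf(F_classical, df_num, df_den))
        assert p_cond == pytest.approx(p_classical, rel=1e-10)

    def test_single_level_factor_rejected(self):
        rows = [("a", 1, 0.1), ("a", 1, 0.2), ("b", 1, 0.3)]
        with pytest.raises(ValueError, match="levels"):
            two_way_anova(table(rows))

    def test_missing_values_rejected(self):
        df = table([("a", 1, np.nan), ("b", 2, 1.0), ("a", 2, 1.0), ("b", 1, 2.0)])
        with pytest.raises(ValueError, match="missing"):
            two_way_anova(df)

    def test_null_rejection_rate_calibrated(self):
        """With no effects, rejections at 0.025 stay within the binomial CI."""
        rng = np.random.default_rng(123)
        n_reject = 0
        n_rep = 400
        for _ in range(n_rep):
            rows = [
                (animal, cond, rng.normal())
                for animal in ("a", "b", "c")
                for cond in (1, 2, 3)
                for _ in range(4)
            ]
            p_cond, _ = two_way_anova(table(rows))
            n_reject += p_cond < 0.025
        ci = binomtest(n_reject, n_rep).proportion_ci(0.99)
        assert ci.low <= 0.025 <= ci.high


class TestConditionRegression:
    def test_exact_line(self):
        df = pd.DataFrame({"x": np.tile([20.0, 40.0, 60.0], 5)})
        df["value"] = 0.5 * df["x"]
        slope, intercept, se, p = condition_regression(df, "x")
        assert slope == pytest.approx(0.5, abs=1e-12)
        assert intercept == pytest.approx(0.0, abs=1e-9)
        assert p < 1e-12

    def test_slope_equivariance_under_predictor_scaling(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"x": np.repeat([200.0, 500.0, 1000.0], 10)})
        df["value"] = 0.002 * df["x"] + rng.normal(0, 0.1, len(df))
        s1, *_ = condition_regression(df, "x")
        df2 = df.assign(x=df["x"] * 10.0)
        s2, *_ = condition_regression(df2, "x")
        assert s2 == pytest.approx(s1 / 10.0, rel=1e-9)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"x": np.ones(10), "value": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            condition_regression(df, "x")

    def test_null_slope_p_values_are_uniform(self):
        """Over pure-noise replicates the slope p-value is U(0,1)."""
        rng = np.random.default_rng(99)
        x = np.repeat([20.0, 40.0, 60.0], 10)
        pvals = []
        for _ in range(500):
            df = pd.DataFrame({"x": x, "value": rng.normal(size=len(x))})
            *_, p = condition_regression(df, "x")
            pvals.append(p)
        assert kstest(pvals, "uniform").pvalue > 0.01


class TestTrendAnalysis:
    def _recovery_table(self, gain, seed=3):
        rng = np.random.default_rng(seed)
        rows = []
        for animal, offset in (("a", 0.9), ("b", 1.0), ("c", 1.1)):
            for v in (20.0, 40.0, 60.0):
                for _ in range(20):
                    rows.append((animal, v, gain * v * offset + rng.normal(0, 0.05)))
        return pd.DataFrame(rows, columns=["animal_id", "x", "value"])

    def test_recovers_injected_gain_within_2_se(self):
        gain = 0.02
        res = trend_analysis(self._recovery_table(gain), "x")
        assert res.condition_significant
        assert abs(res.regression_slope - gain) <= 2 * res.regression_slope_se

    def test_gating_suppresses_regression_without_effect(self):
        rng = np.random.default_rng(8)
        rows = [
            (animal, v, rng.normal())
            for animal in ("a", "b")
            for v in (20.0, 40.0, 60.0)
            for _ in range(10)
        ]
        df = pd.DataFrame(rows, columns=["animal_id", "x", "value"])
        res = trend_analysis(df, "x")
        if not res.condition_significant:
            assert res.regression_slope is None
            assert not res.trend_significant
        ungated = trend_analysis(df, "x", enforce_gating=False)
        assert ungated.regression_slope is not None
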