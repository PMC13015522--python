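"""Condition-dependence statistics.

Whether a response metric differs across stimulus levels is tested with a
two-way unbalanced ANOVA (factors: animal and condition, no interaction,
Type-II sums of squares) at a significance threshold of p < 0.025 per
factor (two factors; the threshold halves the familywise 0.05).  When the
condition main effect is significant, the dependence of the pooled
metric on the varied stimulus parameter (peak velocity or angular
acceleration) is quantified by ordinary least-squares regression across
all animals' trials, with a two-sided slope test at alpha = 0.05.

Type II is the standard main-effects decomposition without an
interaction: each factor is tested against the model containing the other
factor, so the sums of squares are well defined under unequal cell sizes
and reduce to the classical decomposition on balanced tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "ANOVA_ALPHA",
    "REGRESSION_ALPHA",
    "TrendResult",
    "two_way_anova",
    "condition_regression",
    "trend_analysis",
]

ANOVA_ALPHA = 0.025
REGRESSION_ALPHA = 0.05


def _validate_table(table: pd.DataFrame, value_col: str) -> None:
    for col in ("animal_id", "condition", value_col):
        if col not in table.columns:
            raise ValueError(f"metric table must have a {col!r} column")
    if table[value_col].isna().any():
        raise ValueError("metric table contains missing values")
    for factor in ("animal_id", "condition"):
        if table[factor].nunique() < 2:
            raise ValueError(f"factor {factor!r} needs >= 2 levels")


def two_way_anova(table: pd.DataFrame, value_col: str = "value") -> tuple[float, float]:
    """Unbalanced two-way ANOVA of a metric on animal and condition.

    ``table`` needs columns ``animal_id``, ``condition`` (categorical
    stimulus level) and the metric value.  Returns
    ``(p_condition, p_animal)`` from a Type-II decomposition of the
    additive model ``value ~ C(animal_id) + C(condition)``.
    """
    _validate_table(table, value_col)
    df = table.rename(columns={value_col: "_y"})
    model = smf.ols("_y ~ C(animal_id) + C(condition)", data=df).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    return float(aov.loc["C(condition)", "PR(>F)"]), float(aov.loc["C(animal_id)", "PR(>F)"])


@dataclass(frozen=True)
class TrendResult:
    """ANOVA and pooled-regression outcome for one metric."""

    anova_p_condition: float
    anova_p_animal: float
    regression_slope: float | None  # metric units per stimulus unit
    regression_intercept: float | None
    regression_slope_se: float | None
    regression_p: float | None
    condition_significant: bool  # ANOVA condition effect, p < 0.025
    animal_significant: bool
    trend_significant: bool  # regression slope, p < 0.05 (False when gated off)


def condition_regression(
    table: pd.DataFrame,
    predictor_col: str,
    value_col: str = "value",
) -> tuple[float, float, float, float]:
    """Pooled OLS of the metric on the stimulus parameter.

    Returns ``(slope, intercept, slope_se, p_slope)`` with a two-sided
    slope test; all animals' trials are pooled.
    """
    x = np.asarray(table[predictor_col], dtype=float)
    y = np.asarray(table[value_col], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"predictor {predictor_col!r} is constant")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return (
        float(fit.params[1]),
        float(fit.params[0]),
        float(fit.bse[1]),
        float(fit.pvalues[1]),
    )


def trend_analysis(
    table: pd.DataFrame,
    predictor_col: str,
    value_col: str = "value",
    enforce_gating: bool = True,
) -> TrendResult:
    """ANOVA-gated trend analysis of one metric against one stimulus set.

    The regression is only run (and only reported) when the ANOVA
    condition effect reaches p < 0.025, mirroring the study's gating;
    ``enforce_gating=False`` computes it unconditionally.
    """
    df = table.copy()
    df["condition"] = df[predictor_col]
    p_cond, p_animal = two_way_anova(df, value_col=value_col)
    cond_sig = p_cond < ANOVA_ALPHA
    slope = intercept = slope_se = p_slope = None
    trend_sig = False
    if cond_sig or not enforce_gating:
        slope, intercept, slope_se, p_slope = condition_regression(
            df, predictor_col, value_col=value_col
        )
        trend_sig = p_slope < REGRESSION_ALPHA
    return TrendResult(
        anova_p_condition=p_cond,
        anova_p_animal=p_animal,
        regression_slope=slope,
        regression_intercept=intercept,
        regression_slope_se=slope_se,
        regression_p=p_slope,
        condition_significant=cond_sig,
        animal_significant=p_animal < ANOVA_ALPHA,
        trend_significant=trend_sig,
    )
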