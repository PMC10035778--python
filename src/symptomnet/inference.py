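"""Total-score and per-symptom treatment comparisons.

The between-arm comparison on PHQ-9 / GAD-7 totals is a baseline-adjusted
linear model (classical ANCOVA): final ~ baseline + treatment, with an
F-test on the treatment term, partial omega-squared as the effect size and
estimated marginal means (arm means at the grand-mean baseline). The same
contrast is run per item with Benjamini-Hochberg FDR adjustment across the
16 symptoms. Descriptive group differences use Cohen's d (continuous) or
Cramer's V (categorical), computable from published summary statistics
alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AncovaResult",
    "EffectSize",
    "ancova_totals",
    "per_symptom_tests",
    "cohens_d",
    "cohens_d_from_summaries",
    "cramers_v",
    "group_difference_stats",
]


@dataclass
class AncovaResult:
    F: float
    df: tuple
    p: float
    omega_sq_partial: float
    emm: dict  # arm -> (estimated marginal mean, SE)
    coef_treatment: float

    def __post_init__(self) -> None:
        assert self.F >= 0 and 0.0 <= self.p <= 1.0


@dataclass
class EffectSize:
    kind: str  # "cohens_d" | "cramers_v"
    value: float
    inputs: dict


def ancova_totals(final_total, baseline_total, treatment) -> AncovaResult:
    """Baseline-adjusted comparison of final totals between arms.

    Partial omega-squared uses the partial-SS form
    ``(SS_t - df_t * MS_e) / (SS_t + (N - df_t) * MS_e)``; EMMs are the
    model predictions at the grand-mean baseline with model-based SEs.
    """
    y = np.asarray(final_total, dtype=float)
    b = np.asarray(baseline_total, dtype=float)
    t = np.asarray(treatment, dtype=float)
    if len(np.unique(t)) < 2:
        raise ValueError("treatment contrast undefined: only one arm present")
    X = sm.add_constant(np.column_stack([b, t]))
    res = sm.OLS(y, X).fit()
    n = len(y)
    tval = res.tvalues[2]
    F = float(tval**2)
    df = (1, int(res.df_resid))
    p = float(res.pvalues[2])
    mse = res.mse_resid
    ss_t = F * mse  # partial SS of a 1-df term
    omega = float((ss_t - 1 * mse) / (ss_t + (n - 1) * mse))
    emm = {}
    for arm in (0, 1):
        x = np.array([1.0, b.mean(), float(arm)])
        mean = float(x @ res.params)
        se = float(np.sqrt(x @ res.cov_params() @ x))
        emm[arm] = (mean, se)
    return AncovaResult(
        F=F, df=df, p=p, omega_sq_partial=omega, emm=emm,
        coef_treatment=float(res.params[2]),
    )


def per_symptom_tests(final_items, baseline_items, treatment) -> pd.DataFrame:
    """Per-item baseline-adjusted contrasts with BH-FDR across the items.

    Returns one row per item: treatment coefficient, F, raw p and
    FDR-adjusted p (step-up Benjamini-Hochberg).
    """
    fin = pd.DataFrame(final_items)
    base = pd.DataFrame(baseline_items)
    if fin.shape != base.shape:
        raise ValueError("final and baseline item matrices must match in shape")
    base.columns = fin.columns
    rows = []
    for col in fin.columns:
        r = ancova_totals(fin[col], base[col], treatment)
        rows.append((col, r.coef_treatment, r.F, r.p))
    out = pd.DataFrame(rows, columns=["item", "coef_treatment", "F", "p_raw"])
    out["p_fdr"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def cohens_d_from_summaries(
    mean1: float, sd1: float, n1: int, mean0: float, sd0: float, n0: int
) -> float:
    """Standardized mean difference with the (n-1)-weighted pooled SD."""
    pooled = np.sqrt(((n1 - 1) * sd1**2 + (n0 - 1) * sd0**2) / (n1 + n0 - 2))
    if pooled == 0:
        raise ZeroDivisionError("pooled SD is zero; d undefined")
    return float((mean1 - mean0) / pooled)


def cohens_d(x1, x0) -> float:
    x1 = np.asarray(x1, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    return cohens_d_from_summaries(
        x1.mean(), x1.std(ddof=1), len(x1), x0.mean(), x0.std(ddof=1), len(x0)
    )


def cramers_v(table) -> float:
    """Cramer's V from a contingency table (rows x columns)."""
    table = np.asarray(table, dtype=float)
    chi2 = stats.chi2_contingency(table, correction=False)[0]
    n = table.sum()
    k = min(table.shape) - 1
    return float(np.sqrt(chi2 / (n * k)))


def group_difference_stats(kind: str, **inputs) -> EffectSize:
    """Descriptive effect size from arm summaries or a contingency table.

    ``kind='cohens_d'`` expects ``mean1, sd1, n1, mean0, sd0, n0`` (or raw
    arrays ``x1, x0``); ``kind='cramers_v'`` expects ``table``.
    """
    if kind == "cohens_d":
        if "table" in inputs:
            raise ValueError("cohens_d takes group summaries, not a table")
        if "x1" in inputs:
            value = cohens_d(inputs["x1"], inputs["x0"])
        else:
            value = cohens_d_from_summaries(**inputs)
    elif kind == "cramers_v":
        value = cramers_v(inputs["table"])
    else:
        raise ValueError(f"unknown effect-size kind {kind!r}")
    return EffectSize(kind=kind, value=value, inputs=inputs)
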