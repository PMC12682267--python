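"""Nonparametric statistics for paired light effects and response counts.

The layer mirrors standard reporting practice for paired slice
electrophysiology: Wilcoxon signed-rank for paired comparisons (light
vs. no light, pre vs. post wash-on), with Bonferroni correction across a
declared comparison family; Mann-Whitney U for unpaired subtype
comparisons; a two-way OLS ANOVA (light condition x relative step) for
input-output curves; and a chi-squared test of independence for response
class distributions across stimulation protocols.

The ANOVA treats every (cell, step) row as independent, as is conventional
for these curve comparisons even though cells contribute several steps; a
warning notes the repeated-measures caveat and ``cluster_robust`` offers a
cell-clustered covariance variant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .io import ParameterError

__all__ = [
    "StatResult",
    "wilcoxon_signed_rank",
    "mann_whitney_u",
    "bonferroni",
    "anova_io_curves",
    "chi_squared_independence",
]

EXACT_WILCOXON_MAX_N = 25
EXACT_MWU_MAX_N = 8


@dataclass
class StatResult:
    """One test outcome with its sample sizes and correction state."""

    test_name: str
    statistic: float
    p_value: float
    n: tuple
    df: float | None = None
    correction: str = "none"
    adjusted_p: float | None = None
    notes: dict = field(default_factory=dict)

    def significant(self, alpha: float = 0.05) -> bool:
        p = self.adjusted_p if self.adjusted_p is not None else self.p_value
        return p < alpha


def wilcoxon_signed_rank(
    values_a,
    values_b=None,
    exact_max_n: int = EXACT_WILCOXON_MAX_N,
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Accepts either paired arrays or precomputed differences. Zero
    differences are dropped before ranking (Wilcoxon's original rule; the
    policy is recorded in the result). The null distribution is exact up to
    ``exact_max_n`` informative pairs and a continuity-corrected normal
    approximation above. All-zero differences yield a defined result with
    p = 1 and a flag rather than an error.
    """
    a = np.asarray(values_a, dtype=float)
    diffs = a if values_b is None else a - np.asarray(values_b, dtype=float)
    n_total = diffs.size
    nonzero = diffs[diffs != 0]
    notes = {"zero_policy": "drop", "n_zeros": int(n_total - nonzero.size)}
    if nonzero.size == 0:
        notes["all_differences_zero"] = True
        return StatResult("wilcoxon_signed_rank", statistic=0.0, p_value=1.0,
                          n=(n_total,), notes=notes)
    method = "exact" if nonzero.size <= exact_max_n and np.unique(np.abs(nonzero)).size == nonzero.size else "approx"
    res = sps.wilcoxon(nonzero, zero_method="wilcox", correction=(method == "approx"),
                       alternative="two-sided", method=method)
    notes["method"] = method
    return StatResult("wilcoxon_signed_rank", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(n_total,), notes=notes)


def mann_whitney_u(group_a, group_b, exact_max_n: int = EXACT_MWU_MAX_N) -> StatResult:
    """Two-sided Mann-Whitney U test on two independent groups.

    Exact null distribution when the smaller group has at most
    ``exact_max_n`` observations and the data are tie-free; otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if min(a.size, b.size) <= exact_max_n and not has_ties else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    return StatResult("mann_whitney_u", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(a.size, b.size),
                      notes={"method": method, "ties": bool(has_ties)})


def bonferroni(results, m: int | None = None) -> list[StatResult]:
    """Bonferroni-adjust a comparison family: adjusted_p = min(1, m * p).

    ``results`` may hold StatResults (adjusted in place and returned) or
    raw p-values (returned as adjusted floats wrapped in StatResults). The
    family size ``m`` defaults to the number of comparisons and may not be
    smaller than it.
    """
    items = list(results)
    if m is None:
        m = len(items)
    if m < 1:
        raise ParameterError("family size m must be >= 1")
    if m < len(items):
        raise ParameterError(f"family size m={m} smaller than {len(items)} comparisons")
    out = []
    for item in items:
        if isinstance(item, StatResult):
            item.correction = f"bonferroni({m})"
            item.adjusted_p = min(1.0, m * item.p_value)
            out.append(item)
        else:
            p = float(item)
            out.append(StatResult("bonferroni", statistic=math.nan, p_value=p,
                                  n=(len(items),), correction=f"bonferroni({m})",
                                  adjusted_p=min(1.0, m * p)))
    return out


def anova_io_curves(
    table: pd.DataFrame,
    response: str = "frequency_hz",
    light_factor: str = "condition",
    step_factor: str = "relative_index",
    cell_column: str = "cell_id",
    cluster_robust: bool = False,
) -> dict[str, StatResult]:
    """Two-way OLS ANOVA (light x step) on a long-format f-I table.

    Treatment-coded OLS with Type II sums of squares; returns a StatResult
    per main effect and for the interaction, keyed ``"light"``, ``"step"``
    and ``"interaction"``. Rows are treated as independent observations
    (the conventional curve comparison); a repeated-measures warning is
    emitted since cells contribute several steps, and ``cluster_robust``
    switches the light-effect inference to a cell-clustered covariance.
    """
    df = pd.DataFrame(table)
    for col in (response, light_factor, step_factor):
        if col not in df.columns:
            raise ParameterError(f"table lacks required column {col!r}")
    if df[light_factor].nunique() < 2 or df[step_factor].nunique() < 2:
        raise ParameterError("each factor needs at least 2 levels")
    warnings.warn(
        "anova_io_curves treats every (cell, step) row as independent; "
        "cells contribute multiple steps (repeated measures)",
        stacklevel=2,
    )
    formula = f"{response} ~ C({light_factor}) * C({step_factor})"
    model = smf.ols(formula, data=df)
    if cluster_robust and cell_column in df.columns:
        fit = model.fit(cov_type="cluster", cov_kwds={"groups": df[cell_column]})
    else:
        fit = model.fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ParameterError("rank-deficient design: interaction aliased with main effects")
    if fit.df_resid <= 0:
        raise ParameterError("saturated design: no residual degrees of freedom")
    aov = sm.stats.anova_lm(fit, typ=2)
    keys = {
        "light": f"C({light_factor})",
        "step": f"C({step_factor})",
        "interaction": f"C({light_factor}):C({step_factor})",
    }
    out = {}
    for name, row_key in keys.items():
        row = aov.loc[row_key]
        out[name] = StatResult(
            test_name=f"two_way_anova[{name}]",
            statistic=float(row["F"]),
            p_value=float(row["PR(>F)"]),
            n=(len(df),),
            df=float(row["df"]),
            notes={"ss": float(row["sum_sq"]),
                   "residual_df": float(aov.loc["Residual", "df"]),
                   "cluster_robust": cluster_robust},
        )
    return out


def chi_squared_independence(counts, continuity: bool = False) -> StatResult:
    """Pearson chi-squared test of independence on a contingency table.

    No continuity correction by default (``continuity`` enables Yates for
    2x2 tables). Raises ParameterError on degenerate tables (fewer than
    two rows/columns, or a zero row/column total).
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ParameterError("contingency table must be at least 2x2")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ParameterError("contingency table has a zero row or column total")
    res = sps.chi2_contingency(table, correction=continuity)
    return StatResult("chi_squared_independence", statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=(int(table.sum()),),
                      df=float(res.dof))
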