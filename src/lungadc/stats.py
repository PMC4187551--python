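"""Statistical battery: group comparisons, correlations, and regression.

The analyses mirror a small-cohort imaging study design:

* exact Mann-Whitney U tests (mid-rank ties, full enumeration of the
  permutation distribution for total n <= 20; tie-corrected normal
  approximation beyond) for never-smoker vs COPD comparisons;
* one-way ANOVA for multi-group comparisons (e.g. SNR across b-values);
* Pearson correlations with two-tailed t-transform p-values, applied
  pairwise with listwise deletion of missing values;
* Holm-Bonferroni step-down correction over a configurable test family;
* multivariate ordinary least squares with classical standard errors.

``cohort_report`` binds these into the cohort summary: group mean/SD
tables, never-smoker vs COPD tests, the ADC x CT correlation matrix with
its 20-test Holm family, and the CT-on-ADC regression model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import StatsError

#: Largest pooled sample size for which the exact Mann-Whitney permutation
#: distribution is enumerated.
EXACT_MW_MAX_N = 20


# --- Mann-Whitney -----------------------------------------------------------

def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U with a two-tailed p-value.

    Returns ``(U_a, p)`` where ``U_a`` counts (with mid-rank tie credit)
    pairs in which an A value exceeds a B value. For total n <= 20 the
    p-value is exact: every assignment of the pooled mid-ranks to the two
    groups is enumerated and the two-tailed p is the fraction of
    assignments at least as extreme (|U - n_a n_b / 2|) as observed.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise StatsError("both groups must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)               # mid-ranks for ties
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2)
    mu = na * nb / 2.0

    if na + nb <= EXACT_MW_MAX_N:
        obs = abs(u_a - mu) - 1e-12            # guard float equality
        rank_sum_base = na * (na + 1) / 2
        count = total = 0
        for combo in itertools.combinations(range(na + nb), na):
            u = ranks[list(combo)].sum() - rank_sum_base
            total += 1
            if abs(u - mu) >= obs:
                count += 1
        return u_a, count / total

    # tie-corrected normal approximation with continuity correction
    n = na + nb
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (n * (n - 1))
    sd = math.sqrt(na * nb / 12.0 * (n + 1 - tie_term))
    if sd == 0:
        return u_a, 1.0
    z = (abs(u_a - mu) - 0.5) / sd
    return u_a, float(2 * sps.norm.sf(max(z, 0.0)))


# --- Pearson ----------------------------------------------------------------

def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with a two-tailed p (t transform, n-2 df).

    Pairs with any missing value are dropped (listwise deletion). Returns
    ``(r, p, n)``; requires n >= 3 and non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StatsError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise StatsError(f"need >= 3 complete pairs; got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p), int(x.size)


# --- Holm-Bonferroni --------------------------------------------------------

def holm_bonferroni(p_values) -> np.ndarray:
    """Step-down Holm correction, returned in the input order.

    Sort ascending; the i-th smallest raw p becomes
    ``max_{j<=i} (m - j + 1) * p_(j)`` capped at 1, which enforces
    monotonicity of the corrected values in the raw ordering.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise StatsError("p-values must be a nonempty 1-D sequence")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = (m - np.arange(m)) * p[order]
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


# --- OLS --------------------------------------------------------------------

@dataclass
class RegressionRow:
    name: str
    coef: float
    se: float
    t: float
    p: float


@dataclass
class RegressionResult:
    rows: list[RegressionRow]
    nobs: int
    df_resid: int
    r_squared: float
    f_pvalue: float

    def row(self, name: str) -> RegressionRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise KeyError(name)


def ols_fit(response, predictors: pd.DataFrame | dict, add_intercept: bool = True
            ) -> RegressionResult:
    """Multivariate OLS with classical (unbiased residual variance) SEs.

    Rows with any missing cell are dropped listwise. A rank-deficient
    design is rejected, naming the collinear columns.
    """
    X = pd.DataFrame(predictors).astype(float)
    y = pd.Series(np.asarray(response, dtype=float), index=X.index, name="y")
    keep = X.notna().all(axis=1) & y.notna()
    X, y = X[keep], y[keep]
    names = list(X.columns)
    if add_intercept:
        X = sm.add_constant(X, prepend=True)
        names = ["intercept"] + names
    n, k = X.shape
    if n <= k:
        raise StatsError(f"n = {n} observations cannot identify {k} coefficients")
    if np.linalg.matrix_rank(X.to_numpy()) < k:
        bad = []
        arr = X.to_numpy()
        for j, nm in enumerate(names):
            rest = np.delete(arr, j, axis=1)
            resid = arr[:, j] - rest @ np.linalg.lstsq(rest, arr[:, j], rcond=None)[0]
            if np.allclose(resid, 0, atol=1e-10):
                bad.append(nm)
        raise StatsError(f"rank-deficient design; collinear columns: {bad}")
    fit = sm.OLS(y.to_numpy(), X.to_numpy()).fit()
    rows = [RegressionRow(nm, float(c), float(s), float(t), float(p))
            for nm, c, s, t, p in zip(names, fit.params, fit.bse, fit.tvalues, fit.pvalues)]
    return RegressionResult(rows, int(fit.nobs), int(fit.df_resid),
                            float(fit.rsquared), float(fit.f_pvalue))


# --- ANOVA ------------------------------------------------------------------

def anova_oneway(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p across two or more groups."""
    if len(groups) < 2:
        raise StatsError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise StatsError("each group needs >= 2 values")
    if np.ptp(np.concatenate(arrays)) == 0:
        return 0.0, 1.0          # constant data: no between- or within-group variance
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


# --- cohort-level report ----------------------------------------------------

@dataclass
class StatReport:
    """Container for the cohort's summary statistics.

    ``group_summary``: (group, metric) -> n, mean, sd.
    ``group_tests``: never-smoker vs COPD Mann-Whitney results per metric.
    ``correlations``: ADC x CT Pearson matrix with raw and Holm p.
    ``regression``: the CT-on-ADC multivariate model.
    """

    group_summary: pd.DataFrame
    group_tests: pd.DataFrame
    correlations: pd.DataFrame
    regression: RegressionResult
    holm_family_size: int = 20
    notes: list[str] = field(default_factory=list)

    def correlation(self, ct_metric: str, adc_metric: str) -> pd.Series:
        sel = (self.correlations["ct_metric"] == ct_metric) \
            & (self.correlations["adc_metric"] == adc_metric)
        if not sel.any():
            raise KeyError((ct_metric, adc_metric))
        return self.correlations[sel].iloc[0]


def cohort_report(df: pd.DataFrame,
                  regression_response: str = "ra950_pct") -> StatReport:
    """Recompute the cohort summary tables from a per-subject table.

    Expects the schema of :func:`lungadc.subjects.cohort_dataframe`:
    a ``group`` column plus the four ADC and five CT metric columns.
    Group summaries cover never-smokers, all COPD, and the emphysema
    subgroup; correlations are computed over COPD subjects only with
    listwise deletion per pair, and the Holm family is the full 20-cell
    ADC x CT block. The regression regresses a CT metric on the three ADC
    columns with n >= 4 complete cases (the b = 30 column, present for
    only three subjects, is excluded as a predictor).
    """
    from .subjects import ADC_COLUMNS, CT_COLUMNS

    required = {"group", *ADC_COLUMNS, *CT_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise StatsError(f"per-subject table lacks columns: {sorted(missing)}")

    copd = df[df["group"] != "never-smoker"]
    never = df[df["group"] == "never-smoker"]
    emph = df[df["group"] == "COPD-with-emphysema"]

    rows = []
    for gname, gdf in (("never-smoker", never), ("COPD", copd),
                       ("COPD-with-emphysema", emph)):
        for metric in ADC_COLUMNS + CT_COLUMNS:
            vals = gdf[metric].dropna()
            rows.append({
                "group": gname, "metric": metric, "n": int(vals.size),
                "mean": float(vals.mean()) if vals.size else np.nan,
                "sd": float(vals.std(ddof=1)) if vals.size > 1 else np.nan,
            })
    group_summary = pd.DataFrame(rows)

    tests = []
    for metric in ADC_COLUMNS:
        a = never[metric].dropna().to_numpy()
        b = copd[metric].dropna().to_numpy()
        if a.size >= 2 and b.size >= 2:
            u, p = mann_whitney(a, b)
            tests.append({"metric": metric, "U": u, "p": p,
                          "n_never": a.size, "n_copd": b.size})
    group_tests = pd.DataFrame(tests)

    corr_rows = []
    for ct_metric in CT_COLUMNS:
        for adc_metric in ADC_COLUMNS:
            r, p, n = pearson_with_p(copd[adc_metric], copd[ct_metric])
            corr_rows.append({"ct_metric": ct_metric, "adc_metric": adc_metric,
                              "r": r, "p_raw": p, "n": n})
    correlations = pd.DataFrame(corr_rows)
    correlations["p_holm"] = holm_bonferroni(correlations["p_raw"].to_numpy())

    predictors = copd[["adc_he3_b1p6", "adc_xe129_b12", "adc_xe129_b20"]]
    regression = ols_fit(copd[regression_response], predictors)

    return StatReport(group_summary, group_tests, correlations, regression,
                      holm_family_size=len(corr_rows))
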