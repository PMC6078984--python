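"""Statistical layer: rank/exact/correlation tests, FDR, covariate-adjusted
model-comparison tests, and Kaplan-Meier / log-rank / Cox survival analysis.

Every comparative analysis in the package routes its inference through this
module so that conventions (two-sided tests, exact small-sample paths,
Benjamini-Hochberg correction, Efron tie handling in Cox models) are applied
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
import statsmodels.formula.api as smf

EXACT_MW_MAX_N = 12  # combined size below which the exact MW null is enumerated


@dataclass
class ComparisonResult:
    """Outcome of a two-group or correlation test."""

    test: str
    statistic: float
    p: float
    group_summaries: dict = field(default_factory=dict)
    adjusted_p: float | None = None
    fdr: float | None = None
    note: str | None = None


@dataclass
class SurvivalFit:
    """Kaplan-Meier curves plus log-rank and/or Cox summaries."""

    km_curves: dict[str, pd.DataFrame] = field(default_factory=dict)
    median_survival: dict[str, float] = field(default_factory=dict)
    logrank_statistic: float | None = None
    logrank_p: float | None = None
    cox_summary: pd.DataFrame | None = None


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.size == 0:
        raise ValueError(f"{name} is empty")
    return arr


def mann_whitney(x, y) -> ComparisonResult:
    """Two-sided Mann-Whitney U test.

    The null distribution is enumerated exactly when the combined sample size
    is at most 12 and there are no ties; otherwise the tie-corrected normal
    approximation (with continuity correction) is used.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= EXACT_MW_MAX_N and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return ComparisonResult(
        test=f"mann_whitney[{method}]",
        statistic=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
        group_summaries={"median_x": float(np.median(x)), "median_y": float(np.median(y))},
    )


def fisher_exact(table) -> ComparisonResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables at most
    as probable as the observed one (the R ``fisher.test`` convention).
    """
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        t = t.astype(int) if t.shape == (2, 2) and np.all(t >= 0) else t
    t = np.asarray(t, dtype=int)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("table must be 2x2 with non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("table has a zero margin")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    n1, n2 = t[0].sum(), t[1].sum()
    return ComparisonResult(
        test="fisher_exact",
        statistic=float(odds),
        p=float(min(p, 1.0)),
        group_summaries={
            "prop_row1": float(t[0, 0] / n1),
            "prop_row2": float(t[1, 0] / n2),
        },
    )


def spearman(x, y, n_resamples: int = 9999) -> ComparisonResult:
    """Spearman rank correlation with average ranks on ties.

    The p-value uses the t approximation for n > 10 and a seeded permutation
    test for small samples.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector has undefined rank correlation")
    if len(x) > 10:
        res = sps.spearmanr(x, y)
        rho, p = float(res.statistic), float(res.pvalue)
        p = max(p, np.finfo(float).tiny)
    else:
        rho = float(sps.spearmanr(x, y).statistic)

        def stat(xx):
            return sps.spearmanr(xx, y).statistic

        perm = sps.permutation_test(
            (x,), stat, permutation_type="pairings", n_resamples=n_resamples,
            alternative="two-sided", rng=np.random.default_rng(0),
        )
        p = float(perm.pvalue)
    return ComparisonResult(test="spearman", statistic=rho, p=min(max(p, np.nextafter(0, 1)), 1.0))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, order of input preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


DEFAULT_COVARIATES = ("age_at_diagnosis", "diagnosis_year", "pathological_stage", "subtype_ihc")


def _covariate_formula(covariates) -> str:
    terms = []
    for c in covariates:
        terms.append(f"C({c})" if c == "subtype_ihc" else c)
    return " + ".join(terms) if terms else "1"


def adjusted_association(
    outcome, group, covariates: pd.DataFrame, kind: str = "linear"
) -> ComparisonResult:
    """Covariate-adjusted test of a group effect by nested-model comparison.

    Fits the model with covariates only and with covariates plus the group
    indicator, and compares them with an F test (linear outcome) or a
    likelihood-ratio test (binary outcome).
    """
    df = covariates.copy()
    df["_outcome"] = np.asarray(outcome, dtype=float)
    df["_group"] = np.asarray(group, dtype=float)
    df = df.dropna()
    if df["_group"].nunique() < 2:
        raise ValueError("group indicator is constant after listwise deletion")
    base = _covariate_formula([c for c in covariates.columns])
    note = None
    if kind == "linear":
        small = smf.ols(f"_outcome ~ {base}", data=df).fit()
        big = smf.ols(f"_outcome ~ {base} + _group", data=df).fit()
        fstat, p, _ = big.compare_f_test(small)
        stat = float(fstat)
    elif kind == "logistic":
        small = smf.logit(f"_outcome ~ {base}", data=df).fit(disp=0)
        big = smf.logit(f"_outcome ~ {base} + _group", data=df).fit(disp=0)
        stat = float(2.0 * (big.llf - small.llf))
        p = float(sps.chi2.sf(stat, df=1))
        if not big.mle_retvals.get("converged", True):
            note = "logistic fit did not converge (possible separation)"
    else:
        raise ValueError(f"unknown kind {kind!r}")
    if np.isnan(p):
        raise ValueError("model comparison produced NaN p (collinear design?)")
    return ComparisonResult(
        test=f"adjusted_{kind}", statistic=stat, p=float(min(max(p, np.nextafter(0, 1)), 1.0)),
        note=note,
    )


def km_logrank(times, events, groups) -> SurvivalFit:
    """Product-limit survival curves per group and the k-sample log-rank test.

    The reported median is the earliest time at which the estimated survival
    function drops to 0.5 or below (``inf`` if it never does).
    """
    times = _as_float_array(times, "times")
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    if not (len(times) == len(events) == len(groups)):
        raise ValueError("times, events, groups must have equal length")
    if events.sum() == 0:
        raise ValueError("no events observed")
    fit = SurvivalFit()
    for g in pd.unique(groups):
        mask = groups == g
        if mask.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(times[mask], events[mask], label=str(g))
        curve = km.survival_function_.copy()
        curve.columns = ["survival"]
        curve["at_risk"] = km.event_table["at_risk"].reindex(curve.index).ffill()
        fit.km_curves[str(g)] = curve
        fit.median_survival[str(g)] = float(km.median_survival_time_)
    if len(fit.km_curves) >= 2:
        lr = multivariate_logrank_test(times, groups, events)
        fit.logrank_statistic = float(lr.test_statistic)
        fit.logrank_p = float(lr.p_value)
    return fit


def cox_fit(times, events, covariates: pd.DataFrame) -> SurvivalFit:
    """Cox proportional-hazards fit (Efron ties), HR with Wald 95% CI per term.

    Categorical columns are dummy-coded against their first level; numeric
    columns (including ordinal stage) enter linearly.
    """
    times = _as_float_array(times, "times")
    events = np.asarray(events, dtype=int)
    X = covariates.copy()
    for col in X.columns:
        if X[col].nunique(dropna=True) < 2:
            raise ValueError(f"covariate {col!r} is constant")
    cat_cols = [c for c in X.columns if X[c].dtype == object or str(X[c].dtype) == "category"]
    X = pd.get_dummies(X, columns=cat_cols, drop_first=True).astype(float)
    X["_time"] = times
    X["_event"] = events
    cph = CoxPHFitter()
    try:
        cph.fit(X, duration_col="_time", event_col="_event")
    except Exception as e:  # convergence failures surface with diagnostics
        raise RuntimeError(f"Cox fit failed: {e}") from e
    summ = cph.summary[["coef", "exp(coef)", "se(coef)",
                        "exp(coef) lower 95%", "exp(coef) upper 95%", "p"]].copy()
    summ.columns = ["coef", "hr", "se", "hr_ci_low", "hr_ci_high", "p"]
    fit = SurvivalFit(cox_summary=summ)
    return fit


def survival_analysis(
    clinical: pd.DataFrame,
    endpoint: str = "dfs",
    covariates=DEFAULT_COVARIATES,
) -> SurvivalFit:
    """KM/log-rank by group plus a multivariable Cox model of BCP status.

    *clinical* needs columns ``group`` (BCP/control), ``{endpoint}_time``,
    ``{endpoint}_event`` and the requested covariates; ``diagnosis_year`` is
    derived from ``date_of_diagnosis`` when absent.
    """
    df = clinical.copy()
    if "diagnosis_year" in covariates and "diagnosis_year" not in df.columns:
        df["diagnosis_year"] = pd.to_datetime(df["date_of_diagnosis"]).dt.year + (
            pd.to_datetime(df["date_of_diagnosis"]).dt.dayofyear / 365.25
        )
    times = df[f"{endpoint}_time"].to_numpy(dtype=float)
    events = df[f"{endpoint}_event"].to_numpy(dtype=int)
    fit = km_logrank(times, events, df["group"].to_numpy())
    covs = df.loc[:, list(covariates)].copy()
    covs.insert(0, "group_bcp", (df["group"] == "BCP").astype(float))
    cox = cox_fit(times, events, covs)
    fit.cox_summary = cox.cox_summary
    return fit
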