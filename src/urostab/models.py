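"""Correlation, paired/group tests and the temporal decay model.

The decay model regresses the mean shared relative abundance of a subject's
two collections (percent scale) on the collection interval in months plus
clinical covariates (age, sex, cancer status, optionally collection method).
With exactly one response row per subject a per-subject random intercept is
not identifiable (it is confounded with the residual), so the model is fitted
by ordinary least squares with Wald-t confidence intervals, which gives the
same fixed-effect point estimates; a mixed-model profile is available for
replicated designs.

Test choice (parametric vs rank-based) is an explicit switch for the caller
rather than an automatic normality gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st
import statsmodels.api as sm

from .errors import DegenerateTestError, DesignError, UndefinedStatisticError

#: nonzero-n at or below which the signed-rank null is enumerated exactly
EXACT_WILCOXON_MAX_N = 25

DEFAULT_TERMS = ("months", "age", "sex", "cancer")
CONTINUOUS_TERMS = frozenset({"months", "age"})


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    method_note: str


@dataclass(frozen=True)
class LinearFit:
    """OLS fit summary for the decay model.

    ``coefficients`` columns: term, estimate, se, ci_low, ci_high, t, df,
    p_value, std_beta.  ``std_beta`` standardizes continuous predictors only
    (z-scored); the response is left on its original (percent) scale — the
    convention is recorded in ``std_convention``.
    """

    response: str
    scale: str
    coefficients: pd.DataFrame
    r2_marginal: float
    n: int
    std_convention: str = "predictors z-scored; response unstandardized"

    def coefficient(self, term: str) -> pd.Series:
        rows = self.coefficients[self.coefficients["term"] == term]
        if rows.empty:
            raise KeyError(term)
        return rows.iloc[0]


def pearson_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Squared Pearson correlation and its two-sided p-value (t-transform)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("correlation is undefined for a constant input")
    r, p = st.pearsonr(x, y)
    return float(r * r), float(p)


def wilcoxon_signed_rank(differences: np.ndarray) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped (the classic convention); the null is
    enumerated exactly for nonzero n <= 25 without ties, otherwise the normal
    approximation with tie and continuity corrections is used.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateTestError("all paired differences are zero")
    has_ties = len(np.unique(np.abs(d))) < len(d)
    if d.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        res = st.wilcoxon(d, method="exact")
        note = "exact sign enumeration"
    else:
        res = st.wilcoxon(d, method="approx", correction=True)
        note = "normal approximation with tie/continuity correction"
    return TestResult(
        name="wilcoxon_signed_rank",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=(int(d.size),),
        method_note=note,
    )


def rank_sum_and_friends(
    groups: list[np.ndarray],
    test: str = "wilcoxon_rank_sum",
    welch: bool = True,
) -> TestResult:
    """Two-or-more-group location tests on independent samples.

    ``test`` is one of ``wilcoxon_rank_sum`` (Mann-Whitney U; exact for small
    tie-free samples), ``student_t`` (Welch by default) or
    ``kruskal_wallis`` (chi-square approximation, mid-ranks for ties).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    sizes = tuple(int(g.size) for g in groups)
    if test == "wilcoxon_rank_sum":
        if len(groups) != 2:
            raise ValueError("rank-sum test takes exactly 2 groups")
        x, y = groups
        pooled = np.concatenate([x, y])
        small = x.size <= 25 and y.size <= 25
        no_ties = len(np.unique(pooled)) == pooled.size
        if small and no_ties:
            res = st.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            note = "exact enumeration"
        else:
            res = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            note = "normal approximation with tie correction"
        stat, p = float(res.statistic), float(res.pvalue)
    elif test == "student_t":
        if len(groups) != 2:
            raise ValueError("t-test takes exactly 2 groups")
        res = st.ttest_ind(groups[0], groups[1], equal_var=not welch)
        stat, p = float(res.statistic), float(res.pvalue)
        note = "Welch t" if welch else "pooled-variance t"
    elif test == "kruskal_wallis":
        stat_, p_ = st.kruskal(*groups)
        stat, p = float(stat_), float(p_)
        note = "chi-square approximation, mid-ranks for ties"
    else:
        raise ValueError(f"unknown test {test!r}")
    return TestResult(name=test, statistic=stat, p_value=p, n=sizes, method_note=note)


def _design_frame(summary: pd.DataFrame, terms: tuple[str, ...]) -> pd.DataFrame:
    cols = {}
    for term in terms:
        if term == "months":
            cols["months"] = summary["interval_months"].astype(float)
        elif term == "age":
            cols["age"] = summary["age"].astype(float)
        elif term == "sex":
            cols["sex"] = (summary["sex"].astype(str) == "M").astype(float)  # F = reference
        elif term == "cancer":
            cols["cancer"] = summary["cancer"].astype(float)
        elif term == "method":
            cols["method"] = (
                summary["method_combo"].astype(str).str.startswith("CATHETER")
            ).astype(float)
        elif term in summary.columns:
            cols[term] = summary[term].astype(float)
        else:
            raise DesignError(f"unknown model term {term!r}")
    return pd.DataFrame(cols, index=summary.index)


def decay_model(
    summary: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    response: str = "shared_abund_mean",
    percent: bool = True,
) -> LinearFit:
    """Fit the temporal decay of shared relative abundance.

    ``summary`` is the per-subject overlap table; the response is put on the
    percent scale by default so the months coefficient reads as "% change in
    shared abundance per month".  Continuous covariates keep their natural
    units (months, years); sex is coded F = 0 / M = 1, cancer and method as
    0/1 indicators.
    """
    x = _design_frame(summary, terms)
    y = summary[response].astype(float) * (100.0 if percent else 1.0)
    n = len(y)
    if n <= len(terms) + 1:
        raise DesignError(f"n = {n} too small for {len(terms)} terms")
    if x.isna().any().any() or y.isna().any():
        raise DesignError("missing covariate or response values")
    exog = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(exog.to_numpy())
    if rank < exog.shape[1]:
        raise DesignError(
            f"rank-deficient design: {exog.shape[1] - rank} aliased column(s) "
            f"among {list(exog.columns)}"
        )
    fit = sm.OLS(y.to_numpy(), exog).fit()
    ci = fit.conf_int(alpha=0.05)

    # standardized betas: z-score the continuous predictors, refit
    xs = x.copy()
    for term in x.columns:
        if term in CONTINUOUS_TERMS:
            xs[term] = (xs[term] - xs[term].mean()) / xs[term].std(ddof=1)
    std_params = sm.OLS(y.to_numpy(), sm.add_constant(xs, has_constant="add")).fit().params

    rows = []
    names = ["intercept"] + list(x.columns)
    for name, sm_name in zip(names, exog.columns):
        rows.append(
            dict(
                term=name,
                estimate=float(fit.params[sm_name]),
                se=float(fit.bse[sm_name]),
                ci_low=float(ci.loc[sm_name, 0]),
                ci_high=float(ci.loc[sm_name, 1]),
                t=float(fit.tvalues[sm_name]),
                df=int(fit.df_resid),
                p_value=float(fit.pvalues[sm_name]),
                std_beta=float(std_params[sm_name]),
            )
        )
    fitted = np.asarray(fit.fittedvalues, dtype=float)
    r2_marginal = float(np.var(fitted) / np.var(y.to_numpy()))
    return LinearFit(
        response=response,
        scale="percent" if percent else "proportion",
        coefficients=pd.DataFrame(rows),
        r2_marginal=r2_marginal,
        n=n,
    )


def mixed_decay_model(
    data: pd.DataFrame,
    terms: tuple[str, ...] = DEFAULT_TERMS,
    response: str = "shared_abund_mean",
    group: str = "subject_id",
    percent: bool = True,
):
    """REML random-intercept profile for replicated designs.

    Only meaningful when subjects contribute multiple response rows; with one
    row per group the random intercept is confounded with the residual and
    :func:`decay_model` should be used instead.
    """
    counts = data[group].value_counts()
    if (counts < 2).all():
        raise DesignError(
            "every group has a single row; the random intercept is "
            "unidentifiable — use decay_model"
        )
    x = _design_frame(data, terms)
    y = data[response].astype(float) * (100.0 if percent else 1.0)
    exog = sm.add_constant(x, has_constant="add")
    model = sm.MixedLM(y.to_numpy(), exog, groups=data[group].to_numpy())
    return model.fit(reml=True)


def interval_subgroup_analysis(
    summary: pd.DataFrame,
    split_months: float = 15.0,
    response: str = "shared_abund_mean",
) -> dict:
    """Short- vs long-interval subgroup means and within-group decay fits.

    Splits subjects at ``split_months`` (boundary goes to the short group),
    reports each group's mean +/- SD of the response (percent scale) and a
    months-only linear fit within each group with a 5%-level significance
    flag.
    """
    short = summary[summary["interval_months"] <= split_months]
    long = summary[summary["interval_months"] > split_months]
    if short.empty or long.empty:
        raise ValueError(
            f"split at {split_months} months leaves an empty group "
            f"(short n={len(short)}, long n={len(long)})"
        )
    out = {}
    for name, group in (("short", short), ("long", long)):
        vals = group[response].astype(float) * 100.0
        entry = dict(
            n=int(len(group)),
            interval_range=(float(group["interval_months"].min()),
                            float(group["interval_months"].max())),
            mean_pct=float(vals.mean()),
            sd_pct=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
        )
        if len(group) >= 3 and group["interval_months"].nunique() > 1:
            fit = decay_model(group, terms=("months",), response=response)
            slope = fit.coefficient("months")
            entry["slope_pct_per_month"] = float(slope["estimate"])
            entry["slope_p_value"] = float(slope["p_value"])
            entry["slope_significant"] = bool(slope["p_value"] < 0.05)
        out[name] = entry
    out["split_months"] = float(split_months)
    return out
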