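"""Standardized OLS, backward selection, contribution shares and tests.

Explanatory variables are z-scored (responses never are); variables flagged
log-scale (population size, habitat area) are natural-logged before
standardization.  Backward selection drops the single least-significant term
while its p exceeds the threshold (0.1 in the study), logging AIC and the
nested-model F-test at every step.  Contribution shares express each
retained term as |standardized coefficient| over the sum of those
magnitudes.  Correlations carry optional permutation p-values (two-sided,
add-one corrected; exact enumeration for tiny n).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

DEFAULT_ALPHA = 0.1


class SingularityError(ValueError):
    """Design matrix is rank deficient or has a constant predictor."""


@dataclass
class FitResult:
    response: str
    terms: list[str]
    coef: pd.Series        # on the fitted (standardized) scale, incl. intercept
    coef_raw: pd.Series    # back-transformed to the original predictor units
    se: pd.Series
    pvalues: pd.Series
    r2: float
    r2_adj: float
    aic: float
    n: int
    resid: np.ndarray
    standardized: bool


@dataclass
class SelectionStep:
    dropped: str
    p_at_drop: float
    aic_before: float
    aic_after: float
    anova_p: float


@dataclass
class CorrelationResult:
    x: str
    y: str
    method: str
    coefficient: float
    p_parametric: float
    p_permutation: float | None = None
    n_perm: int | None = None
    seed: int | None = None


def _prepare_design(
    X: pd.DataFrame, standardize: bool, log_terms: tuple[str, ...]
) -> tuple[pd.DataFrame, pd.Series]:
    X = X.copy().astype(float)
    for term in log_terms:
        if term in X.columns:
            X[term] = np.log(X[term])
    scales = pd.Series(1.0, index=X.columns)
    if standardize:
        sd = X.std(ddof=1)
        if (sd == 0).any():
            bad = list(sd.index[sd == 0])
            raise SingularityError(f"constant predictor(s): {bad}")
        scales = sd
        X = (X - X.mean()) / sd
    return X, scales


def fit_ols(
    y: pd.Series,
    X: pd.DataFrame,
    standardize: bool = True,
    log_terms: tuple[str, ...] = (),
    response: str | None = None,
) -> FitResult:
    """Ordinary least squares with intercept on (optionally z-scored) predictors."""
    y = pd.Series(y, dtype=float)
    if X.shape[1] == 0:
        return _intercept_only_fit(y, response)
    Xs, scales = _prepare_design(X, standardize, log_terms)
    if len(y) <= Xs.shape[1] + 1:
        raise SingularityError(
            f"n={len(y)} too small for {Xs.shape[1]} predictors plus intercept")
    design = sm.add_constant(Xs)
    rank = np.linalg.matrix_rank(design.values)
    if rank < design.shape[1]:
        corr = Xs.corr().abs()
        np.fill_diagonal(corr.values, 0)
        pairs = [
            (a, b) for a in corr.index for b in corr.columns
            if a < b and corr.loc[a, b] > 0.999
        ]
        raise SingularityError(f"rank-deficient design; collinear terms: {pairs}")
    # near-saturated fits (n barely above p, as in 13-population claim tests)
    # can hit ssr ~ 0; the log-likelihood warning is expected there
    with np.errstate(divide="ignore", invalid="ignore"):
        res = sm.OLS(y.values, design.values).fit()
        aic = float(res.aic)
        r2 = float(res.rsquared)
        r2_adj = float(res.rsquared_adj)
    names = ["const"] + list(Xs.columns)
    coef = pd.Series(res.params, index=names)
    coef_raw = coef.copy()
    coef_raw[Xs.columns] = coef[Xs.columns] / scales
    return FitResult(
        response=response or (y.name or "y"),
        terms=list(Xs.columns),
        coef=coef,
        coef_raw=coef_raw,
        se=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r2=r2,
        r2_adj=r2_adj,
        aic=aic,
        n=int(res.nobs),
        resid=np.asarray(res.resid),
        standardized=standardize,
    )


def _intercept_only_fit(y: pd.Series, response: str | None) -> FitResult:
    res = sm.OLS(y.values, np.ones((len(y), 1))).fit()
    names = ["const"]
    return FitResult(
        response=response or (y.name or "y"),
        terms=[],
        coef=pd.Series(res.params, index=names),
        coef_raw=pd.Series(res.params, index=names),
        se=pd.Series(res.bse, index=names),
        pvalues=pd.Series(res.pvalues, index=names),
        r2=0.0,
        r2_adj=0.0,
        aic=float(res.aic),
        n=int(res.nobs),
        resid=np.asarray(res.resid),
        standardized=True,
    )


def _nested_anova_p(y, X_full, X_red, standardize, log_terms) -> float:
    """p of the F-test comparing the reduced against the full model."""
    full = fit_ols(y, X_full, standardize, log_terms)
    red_rss = _rss(y, X_red, standardize, log_terms)
    full_rss = float((full.resid**2).sum())
    df_diff = X_full.shape[1] - X_red.shape[1]
    df_full = len(y) - X_full.shape[1] - 1
    if full_rss <= 0 or df_diff <= 0:
        return 1.0
    f = (red_rss - full_rss) / df_diff / (full_rss / df_full)
    return float(stats.f.sf(f, df_diff, df_full))


def _rss(y, X, standardize, log_terms) -> float:
    if X.shape[1] == 0:
        yv = np.asarray(y, dtype=float)
        return float(((yv - yv.mean())**2).sum())
    return float((fit_ols(y, X, standardize, log_terms).resid**2).sum())


def backward_select(
    y: pd.Series,
    X: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    standardize: bool = True,
    log_terms: tuple[str, ...] = (),
) -> tuple[FitResult, list[SelectionStep]]:
    """Iteratively drop the least significant term while its p > ``alpha``.

    Exactly one term (the maximal-p one; ties broken toward the later
    column) is removed per step; every step records AIC before/after and the
    nested-model F-test p.  Stops at an all-significant model, or at the
    intercept-only boundary (final fit keeps the last single term's result
    with a degenerate trace entry).
    """
    cols = list(X.columns)
    fit = fit_ols(y, X[cols], standardize, log_terms, response=y.name)
    trace: list[SelectionStep] = []
    while cols:
        pv = fit.pvalues.drop("const")
        worst_p = pv.max()
        if worst_p <= alpha:
            break
        # ties: drop the later term in column order
        worst_terms = [t for t in cols if math.isclose(pv[t], worst_p)]
        drop = worst_terms[-1]
        reduced = [c for c in cols if c != drop]
        new_fit = fit_ols(y, X[reduced], standardize, log_terms, response=y.name)
        trace.append(SelectionStep(
            dropped=drop,
            p_at_drop=float(worst_p),
            aic_before=fit.aic,
            aic_after=new_fit.aic,
            anova_p=_nested_anova_p(y, X[cols], X[reduced], standardize, log_terms),
        ))
        cols, fit = reduced, new_fit
    return fit, trace


def contribution_shares(fit: FitResult) -> pd.Series:
    """Percent contribution of each term: |beta_std| / sum|beta_std| x 100."""
    if not fit.standardized:
        raise ValueError("contribution shares need a standardized fit")
    beta = fit.coef.drop("const").abs()
    total = beta.sum()
    if total == 0:
        raise ValueError("all coefficients are zero")
    return beta / total * 100.0


def _corr_stat(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        return stats.pearsonr(x, y)
    if method == "spearman":
        r, p = stats.spearmanr(x, y)
        return float(r), float(p)
    raise ValueError(f"unknown correlation method {method!r}")


def correlation(
    x,
    y,
    method: str = "pearson",
    n_perm: int | None = None,
    seed: int | None = None,
    exact: bool = False,
) -> CorrelationResult:
    """Correlation coefficient with optional permutation p-value.

    Sampled permutation p carries the add-one correction
    (1 + #{|r*| >= |r|}) / (n_perm + 1) so it can never be zero; ``exact``
    enumerates all n! shuffles (n <= 8) and reports the exact two-sided
    tail probability.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) < 3:
        raise ValueError("correlation needs n >= 3")
    if np.std(xv) == 0 or np.std(yv) == 0:
        raise ValueError("correlation undefined for constant input")
    r, p = _corr_stat(xv, yv, method)
    p_perm = None
    if exact:
        if len(yv) > 8:
            raise ValueError("exact enumeration limited to n <= 8")
        hits = total = 0
        for perm in itertools.permutations(range(len(yv))):
            rp, _ = _corr_stat(xv, yv[list(perm)], method)
            hits += abs(rp) >= abs(r) - 1e-12
            total += 1
        p_perm = hits / total
        n_perm = total
    elif n_perm:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            rp, _ = _corr_stat(xv, rng.permutation(yv), method)
            hits += abs(rp) >= abs(r) - 1e-12
        p_perm = (1 + hits) / (n_perm + 1)
    return CorrelationResult(
        x=getattr(x, "name", "x") or "x",
        y=getattr(y, "name", "y") or "y",
        method=method,
        coefficient=float(r),
        p_parametric=float(p),
        p_permutation=p_perm,
        n_perm=n_perm,
        seed=seed,
    )


@dataclass
class GroupDifference:
    test: str           # "anova" | "kruskal"
    statistic: float    # F or chi-square (H)
    pvalue: float
    posthoc: pd.DataFrame = field(default_factory=pd.DataFrame)


def group_difference(
    values, groups, parametric: bool = True, posthoc: bool = True
) -> GroupDifference:
    """One-way ANOVA (F) or Kruskal-Wallis (H, chi-square distributed).

    Post-hoc pairwise comparisons use Tukey's HSD for the parametric branch
    and rank-sum tests with Holm correction otherwise.
    """
    df = pd.DataFrame({"value": np.asarray(values, float), "group": np.asarray(groups)})
    samples = [g["value"].values for _, g in df.groupby("group")]
    if len(samples) < 2:
        raise ValueError("need at least two groups")
    if parametric:
        stat, p = stats.f_oneway(*samples)
        test = "anova"
    else:
        stat, p = stats.kruskal(*samples)
        test = "kruskal"
    table = pd.DataFrame()
    if posthoc:
        if parametric:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            tk = pairwise_tukeyhsd(df["value"], df["group"])
            table = pd.DataFrame(
                tk.summary().data[1:], columns=tk.summary().data[0])
        else:
            names = sorted(df["group"].unique())
            rows = []
            for a, b in itertools.combinations(names, 2):
                u, pu = stats.mannwhitneyu(
                    df.loc[df.group == a, "value"], df.loc[df.group == b, "value"],
                    alternative="two-sided")
                rows.append({"group1": a, "group2": b, "U": u, "p_raw": pu})
            table = pd.DataFrame(rows)
            if not table.empty:
                table["p_holm"] = multipletests(table["p_raw"], method="holm")[1]
    return GroupDifference(test=test, statistic=float(stat), pvalue=float(p),
                           posthoc=table)
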