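"""Nonparametric statistical battery for X-vs-autosome contrasts.

Mann-Whitney U and Wilcoxon signed-rank tests (exact enumeration for
small untied samples, normal approximation with tie and continuity
corrections otherwise), Spearman rank correlation, standardized multiple
regression with residual group contrasts, and the 3-dimensional
decile-stratified matched X-vs-autosome comparison: expression level,
tissue specificity and interaction degree are each cut into equal-size
rank bins, genes are assigned to combined (bin, bin, bin) categories,
and the per-category X-mean minus A-mean differences are tested with a
signed-rank test over categories containing both classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_N = 25  # exact null enumeration up to this sample size, absent ties


@dataclass
class TestResult:
    statistic_name: str  # "U", "T" or "rho"
    statistic: float
    p_value: float
    n: int
    sidedness: str = "two"  # "one" or "two"
    method: str = ""  # "exact" or "asymptotic"
    n1: int | None = None
    n2: int | None = None
    n_pairs: int | None = None
    note: str = ""


@dataclass
class RegressionFit:
    response_name: str
    covariate_names: list
    r_multiple: float
    coefficients: dict  # name -> standardized slope b*
    coefficient_p: dict  # name -> two-sided P
    model_p: float
    residuals: np.ndarray  # standardized-response scale
    n: int


@dataclass
class StratifiedComparison:
    n_bins: int
    categories: pd.DataFrame  # per-category means for X and A + difference
    n_categories_retained: int
    differences: np.ndarray  # X mean - A mean per retained category
    test: TestResult
    bin_index: pd.DataFrame = field(default=None, repr=False)


def _alternative(sidedness: str) -> str:
    if sidedness == "two":
        return "two-sided"
    if sidedness in ("one", "greater"):
        return "greater"
    if sidedness == "less":
        return "less"
    raise ValueError(f"unknown sidedness {sidedness!r}")


def mann_whitney_u(sample_a, sample_b, sidedness: str = "two") -> TestResult:
    """Mann-Whitney U from joint midranks.

    Exact null enumeration when min(n1, n2) <= 25 and the pooled sample
    has no ties; otherwise the normal approximation with tie correction
    and continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    exact = (min(len(a), len(b)) <= EXACT_MAX_N) and not has_ties
    res = sps.mannwhitneyu(
        a,
        b,
        alternative=_alternative(sidedness),
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic_name="U",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=len(a) + len(b),
        n1=len(a),
        n2=len(b),
        sidedness="two" if sidedness == "two" else "one",
        method="exact" if exact else "asymptotic",
    )


def wilcoxon_signed_rank(differences, sidedness: str = "two") -> TestResult:
    """Wilcoxon matched-pairs signed-rank test on paired differences.

    Zero differences are dropped (Wilcoxon convention); T is the smaller
    of the positive- and negative-rank sums over midranks of |d|. Exact
    enumeration for n <= 25 with untied |d|, else normal approximation
    with tie correction.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0.0]
    n = len(d)
    if n == 0:
        return TestResult(
            statistic_name="T",
            statistic=math.nan,
            p_value=math.nan,
            n=0,
            note="all paired differences are zero; T undefined",
        )
    ranks = sps.rankdata(np.abs(d))
    t_pos = float(ranks[d > 0].sum())
    t_neg = float(ranks[d < 0].sum())
    t_small = min(t_pos, t_neg)
    has_ties = len(np.unique(np.abs(d))) < n
    exact = (n <= EXACT_MAX_N) and not has_ties
    res = sps.wilcoxon(
        d,
        alternative=_alternative(sidedness),
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return TestResult(
        statistic_name="T",
        statistic=t_small,
        p_value=float(res.pvalue),
        n=n,
        n_pairs=n,
        sidedness="two" if sidedness == "two" else "one",
        method="exact" if exact else "asymptotic",
    )


def spearman_rho(x, y) -> TestResult:
    """Spearman rank correlation: Pearson correlation of midranks, with
    the t-distribution approximation for P."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(
            statistic_name="rho",
            statistic=math.nan,
            p_value=math.nan,
            n=len(x),
            note="constant input: rho undefined",
        )
    rho, p = sps.spearmanr(x, y)
    return TestResult(
        statistic_name="rho",
        statistic=float(rho),
        p_value=float(p),
        n=len(x),
        method="t-approximation",
    )


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("constant column cannot be standardized")
    return (v - v.mean()) / sd


def fit_standardized_ols(response, covariates: dict) -> RegressionFit:
    """OLS with intercept on z-scored response and covariates.

    Slopes are the standardized coefficients b*; R is the multiple
    correlation; residuals are returned on the standardized-response
    scale. Raises on collinear covariates (design condition number
    above 1e10), naming the most correlated pair.
    """
    import statsmodels.api as sm

    names = list(covariates)
    y = _zscore(np.asarray(response, dtype=float))
    cols = [_zscore(np.asarray(covariates[k], dtype=float)) for k in names]
    x = np.column_stack(cols)
    n = len(y)
    if x.shape[0] != n:
        raise ValueError("response and covariates differ in length")
    if n <= len(names) + 1:
        raise ValueError("need n > number of covariates + 1")
    if np.linalg.cond(x) > 1e10:
        corr = np.corrcoef(x, rowvar=False)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.abs(corr).argmax(), corr.shape)
        raise ValueError(f"collinear covariates: {names[i]!r} and {names[j]!r}")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = max(float(model.rsquared), 0.0)
    return RegressionFit(
        response_name="response",
        covariate_names=names,
        r_multiple=math.sqrt(r2),
        coefficients={k: float(model.params[i + 1]) for i, k in enumerate(names)},
        coefficient_p={k: float(model.pvalues[i + 1]) for i, k in enumerate(names)},
        model_p=float(model.f_pvalue),
        residuals=np.asarray(model.resid),
        n=n,
    )


def residual_group_test(
    fit: RegressionFit, group_labels, sidedness: str = "two"
) -> TestResult:
    """Mann-Whitney U on regression residuals split by X/A label."""
    labels = np.asarray(group_labels)
    if len(labels) != len(fit.residuals):
        raise ValueError("group labels not aligned with residuals")
    x = fit.residuals[labels == "X"]
    a = fit.residuals[labels == "A"]
    if len(x) == 0 or len(a) == 0:
        raise ValueError("a group has zero members")
    return mann_whitney_u(x, a, sidedness=sidedness)


def equal_size_bins(values, n_bins: int) -> np.ndarray:
    """Rank-based equal-size bin indices in [0, n_bins).

    Ties are broken deterministically by input order (stable sort), so
    every bin holds floor(n / n_bins) or floor + 1 members, with the
    remainder going to the lower bins. Bins depend only on ranks, hence
    are invariant to strictly monotone transforms of the values.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    order = np.argsort(v, kind="stable")
    rank = np.empty(n, dtype=np.intp)
    rank[order] = np.arange(n)
    base, extra = divmod(n, n_bins)
    # the first `extra` bins take one extra member
    edges = np.cumsum([base + 1] * extra + [base] * (n_bins - extra))
    return np.searchsorted(edges, rank, side="right")


def stratified_xa_comparison(
    response,
    covariates: dict,
    chrom,
    n_bins: int = 10,
    sidedness: str = "two",
) -> StratifiedComparison:
    """3-dimensional decile-stratified matched X-vs-autosome comparison.

    Each covariate (conventionally expression level, tau and interaction
    degree) is independently cut into ``n_bins`` equal-size rank bins
    over the supplied gene set; each gene gets a combined 3-tuple
    category. Categories containing at least one X-linked and one
    autosomal gene contribute the paired difference of class means of
    the response, and those differences are tested with the Wilcoxon
    signed-rank test.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(response, dtype=float)
    labels = np.asarray(chrom)
    cov_names = list(covariates)
    bins = {k: equal_size_bins(covariates[k], n_bins) for k in cov_names}
    df = pd.DataFrame({"response": y, "chrom": labels})
    for k in cov_names:
        if len(bins[k]) != len(y):
            raise ValueError(f"covariate {k!r} not aligned with response")
        df[f"bin_{k}"] = bins[k]
    bin_cols = [f"bin_{k}" for k in cov_names]
    grouped = df.groupby(bin_cols + ["chrom"], sort=True)["response"].mean().unstack("chrom")
    for cls in ("X", "A"):
        if cls not in grouped.columns:
            grouped[cls] = np.nan
    retained = grouped.dropna(subset=["X", "A"]).copy()
    if len(retained) < 2:
        raise ValueError("insufficient overlap: fewer than 2 categories contain both X and A genes")
    retained["difference"] = retained["X"] - retained["A"]
    diffs = retained["difference"].to_numpy()
    test = wilcoxon_signed_rank(diffs, sidedness=sidedness)
    return StratifiedComparison(
        n_bins=n_bins,
        categories=retained[["X", "A", "difference"]],
        n_categories_retained=len(retained),
        differences=diffs,
        test=test,
        bin_index=df[bin_cols],
    )
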