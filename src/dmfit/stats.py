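"""Statistical analyses applied to fitted sigma values and goodness-of-fit.

Thin, explicitly parameterised wrappers around scipy / statsmodels:
w-scores against healthy controls, ordinary least squares regression with
partial eta squared, type-II ANCOVA, the mean-centered Levene test, Welch
two-sample t-tests with Benjamini-Hochberg FDR correction, and Cohen's d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps

__all__ = [
    "RegressionResult",
    "TestResult",
    "w_scores",
    "regress",
    "ancova",
    "levene",
    "ttests_fdr",
    "cohens_d",
]


@dataclass
class RegressionResult:
    R: float          # signed Pearson correlation
    p: float
    R2: float
    eta_p2: float     # SS_effect / (SS_effect + SS_residual)
    slope: float
    intercept: float


@dataclass
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    method: str


def w_scores(values, control_values):
    """Standardise regional measures against the healthy-control distribution.

    w = (x - mean_HC) / sd_HC per region (sample SD, ddof = 1). The control
    group's own w-scores then have mean 0 and SD 1 under the same divisor
    convention. values may be a vector (one subject) or a subjects x regions
    matrix.
    """
    x = np.asarray(values, dtype=float)
    hc = np.asarray(control_values, dtype=float)
    hc2 = np.atleast_2d(hc)
    if hc2.shape[0] < 2:
        raise ValueError("need at least 2 control subjects")
    mu = hc2.mean(axis=0)
    sd = hc2.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = int(np.argwhere(sd == 0).ravel()[0])
        raise ValueError(f"control SD is zero in region {bad}")
    return (x - mu) / sd


def regress(y, x) -> RegressionResult:
    """Simple OLS of y on x with signed R and partial eta squared."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if len(y) != len(x) or len(y) < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; regression undefined")
    res = sps.linregress(x, y)
    yhat = res.intercept + res.slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_eff = float(np.sum((yhat - y.mean()) ** 2))
    denom = ss_eff + ss_res
    eta = ss_eff / denom if denom > 0 else 0.0
    return RegressionResult(
        R=float(res.rvalue), p=float(res.pvalue), R2=float(res.rvalue**2),
        eta_p2=eta, slope=float(res.slope), intercept=float(res.intercept),
    )


def ancova(y, factor, covariate, formula: str | None = None) -> pd.DataFrame:
    """ANCOVA: linear model y ~ C(factor) + covariate with type-II F tests.

    Returns a tidy frame with one row per term (factor, covariate) holding
    F, p and partial eta squared. A custom statsmodels formula over the
    columns y / factor / covariate may be supplied.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "y": np.asarray(y, dtype=float),
        "factor": pd.Categorical(factor),
        "covariate": np.asarray(covariate, dtype=float),
    })
    levels = df["factor"].cat.categories
    if len(levels) < 2 or (df["factor"].value_counts() < 2).any():
        raise ValueError("need >= 2 factor levels with >= 2 observations each")
    model = smf.ols(formula or "y ~ C(factor) + covariate", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    ss_resid = float(table.loc["Residual", "sum_sq"])
    rows = []
    for term in table.index:
        if term == "Residual":
            continue
        ss = float(table.loc[term, "sum_sq"])
        rows.append({
            "term": "factor" if "factor" in term else ("covariate" if "covariate" in term else term),
            "F": float(table.loc[term, "F"]),
            "p": float(table.loc[term, "PR(>F)"]),
            "eta_p2": ss / (ss + ss_resid) if ss + ss_resid > 0 else 0.0,
        })
    return pd.DataFrame(rows)


def levene(*groups) -> TestResult:
    """Mean-centered (classical) Levene test for equality of spread."""
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if all(np.array_equal(arrays[0], a) for a in arrays[1:]):
        # identical samples: zero spread difference by construction
        return TestResult(statistic=0.0, p_raw=1.0, p_adjusted=1.0, method="levene-mean")
    stat, p = sps.levene(*arrays, center="mean")
    return TestResult(statistic=float(stat), p_raw=float(p), p_adjusted=float(p), method="levene-mean")


def ttests_fdr(samples: dict, comparisons: list[tuple]) -> pd.DataFrame:
    """Welch two-sample t-tests with BH-FDR adjustment across the family.

    samples maps label -> 1-D array; comparisons lists (label_a, label_b)
    pairs. Adjusted p-values are monotone nondecreasing in raw-p rank and a
    single comparison is returned unadjusted.
    """
    from statsmodels.stats.multitest import multipletests

    rows = []
    for a, b in comparisons:
        xa = np.asarray(samples[a], dtype=float)
        xb = np.asarray(samples[b], dtype=float)
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"samples {a!r}, {b!r} need n >= 2")
        if np.array_equal(xa, xb) or (xa.std() == 0 and xb.std() == 0 and xa.mean() == xb.mean()):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.ttest_ind(xa, xb, equal_var=False)
        rows.append({"a": a, "b": b, "statistic": float(stat), "p_raw": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        _, p_adj, _, _ = multipletests(out["p_raw"].to_numpy(), method="fdr_bh")
        out["p_adjusted"] = p_adj
        out["method"] = "welch-t + bh-fdr"
    return out


def cohens_d(a, b) -> float:
    """Cohen's d with the pooled, (n-1)-weighted standard deviation."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs n >= 2")
    na, nb = len(a), len(b)
    pooled_var = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    if pooled_var == 0:
        if a.mean() == b.mean():
            return 0.0
        raise ValueError("zero pooled SD with unequal means")
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))
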