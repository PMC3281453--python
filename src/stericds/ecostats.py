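"""Trap-data summaries, ANOVA, partial correlations and multiple regression.

Trap datasets are long-format pandas DataFrames with columns
``site, date, phase, insecticide, species, count`` where one *assessment* is
a unique (site, date, phase, insecticide) combination of ten pitfall traps.
Abundance is the total number of individuals per assessment, species richness
the number of distinct species per assessment; summaries are means of those
per group.

The regression chain models post-spray rove-beetle abundance N as an ordinary
least-squares function of five physico-chemical descriptors of the sprayed
insecticide: the complex stability index Ds (percent), octanol-water
partition coefficient logP, persistence Pe (hours), water solubility S
(mg/L) and soil adsorption coefficient logKoc.  Reported alongside the
coefficients: R^2, the multiple correlation R = +sqrt(R^2), the overall F
statistic, and the partial correlation of each predictor with N controlling
for the other four (residual method).

One-way ANOVA F/p come from scipy; the two-way ANOVA uses sequential
(Type I) sums of squares with the factor order fixed as (phase, treatment,
interaction), computed through statsmodels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CollinearityError

PREDICTORS = ["Ds", "logP", "Pe", "S", "logKoc"]

TRAP_COLUMNS = ["site", "date", "phase", "insecticide", "species", "count"]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize(dataset: pd.DataFrame,
              by: tuple[str, ...] = ("insecticide", "phase")
              ) -> pd.DataFrame:
    """Mean abundance and species richness per assessment, grouped by *by*.

    Returns a DataFrame indexed by the grouping columns with columns
    ``abundance`` (mean individuals per assessment), ``richness`` (mean
    distinct species per assessment) and ``n_assessments``.
    """
    if dataset.empty:
        raise ValueError("empty trap dataset")
    df = dataset.copy()
    if (df["count"] < 0).any():
        raise ValueError("negative counts in trap dataset")
    assessment_keys = ["site", "date", "phase", "insecticide"]
    present = df[df["count"] > 0]
    per_assessment = df.groupby(assessment_keys, observed=True).agg(
        abundance=("count", "sum")
    )
    richness = present.groupby(assessment_keys, observed=True)["species"] \
        .nunique().rename("richness")
    per_assessment = per_assessment.join(richness).fillna({"richness": 0})
    per_assessment = per_assessment.reset_index()
    grouped = per_assessment.groupby(list(by), observed=True).agg(
        abundance=("abundance", "mean"),
        richness=("richness", "mean"),
        n_assessments=("abundance", "size"),
    )
    if grouped.empty:
        warnings.warn("all groups empty after aggregation", stacklevel=2)
    return grouped


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnovaResult:
    """F statistic, degrees of freedom, exact p value, and the effect label."""

    F: float
    df_effect: int
    df_error: int
    p: float
    effect: str = ""


def anova_oneway(groups: list) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across *groups*.

    Degenerate input with zero between- and within-group variance returns
    F = 0, p = 1 rather than NaN.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least two observations")
    k = len(groups)
    n = sum(len(g) for g in groups)
    df_effect, df_error = k - 1, n - k
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_within <= 1e-300:
        if ss_between <= 1e-300:
            return AnovaResult(0.0, df_effect, df_error, 1.0, "group")
        return AnovaResult(float("inf"), df_effect, df_error, 0.0, "group")
    F = (ss_between / df_effect) / (ss_within / df_error)
    p = float(stats.f.sf(F, df_effect, df_error))
    return AnovaResult(float(F), df_effect, df_error, p, "group")


def anova_twoway(values, factor_a, factor_b,
                 labels: tuple[str, str] = ("phase", "treatment")
                 ) -> dict[str, AnovaResult]:
    """Two-way fixed-effects ANOVA with sequential (Type I) sums of squares.

    The factor order is fixed: *factor_a* (phase) enters first, then
    *factor_b* (treatment), then their interaction; in unbalanced designs the
    order therefore matters and is part of the contract.  A factor with a
    single level degenerates to a one-way ANOVA on the other factor (with a
    warning).
    """
    y = np.asarray(values, dtype=float)
    fa = pd.Categorical(np.asarray(factor_a))
    fb = pd.Categorical(np.asarray(factor_b))
    name_a, name_b = labels
    if len(fa.categories) < 2 or len(fb.categories) < 2:
        single, kept, kept_name = ((fa, fb, name_b)
                                   if len(fa.categories) < 2
                                   else (fb, fa, name_a))
        warnings.warn(
            "factor with a single level: degenerating to one-way ANOVA",
            stacklevel=2,
        )
        groups = [y[np.asarray(kept.codes) == c]
                  for c in range(len(kept.categories))]
        res = anova_oneway(groups)
        return {kept_name: AnovaResult(res.F, res.df_effect, res.df_error,
                                       res.p, kept_name)}

    n = len(y)
    da = np.eye(len(fa.categories))[fa.codes][:, 1:]  # drop-first dummies
    db = np.eye(len(fb.categories))[fb.codes][:, 1:]
    dab = (da[:, :, None] * db[:, None, :]).reshape(n, -1)
    ones = np.ones((n, 1))

    def rss_rank(X):
        beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid), rank

    # sequential (Type I) decomposition: phase, then treatment, interaction
    blocks = [ones, da, db, dab]
    rss, rank = zip(*(rss_rank(np.hstack(blocks[:k + 1]))
                      for k in range(4)))
    df_error = n - rank[3]
    ms_error = (rss[3] / df_error) if df_error > 0 else 0.0
    eps = 1e-12 * (float(y @ y) + 1.0)  # numerical-zero threshold
    out = {}
    for k, label in ((1, name_a), (2, name_b), (3, "interaction")):
        ss = max(rss[k - 1] - rss[k], 0.0)
        df_eff = max(rank[k] - rank[k - 1], 1)
        if ms_error <= eps:
            F, p = (0.0, 1.0) if ss <= eps else (float("inf"), 0.0)
        else:
            F = (ss / df_eff) / ms_error
            p = float(stats.f.sf(F, df_eff, df_error))
        out[label] = AnovaResult(float(F), df_eff, df_error, p, label)
    return out


# ---------------------------------------------------------------------------
# regression chain
# ---------------------------------------------------------------------------

def r_from_r_squared(r_squared: float) -> float:
    """Multiple correlation coefficient R = +sqrt(R^2)."""
    if not 0.0 <= r_squared <= 1.0:
        raise ValueError("R^2 must lie in [0, 1]")
    return float(np.sqrt(r_squared))


def overall_f_statistic(r_squared: float, k: int, n: int) -> float:
    """Overall regression F = (R^2/k) / ((1-R^2)/(n-k-1))."""
    if n <= k + 1:
        raise ValueError("need n > k + 1 observations")
    return float((r_squared / k) / ((1.0 - r_squared) / (n - k - 1)))


def _check_collinearity(X: pd.DataFrame) -> None:
    Xs = X.to_numpy(dtype=float)
    Xc = Xs - Xs.mean(0)
    sd = Xc.std(0, ddof=1)
    constant = sd <= 1e-300
    if constant.any():
        raise CollinearityError(list(X.columns[constant]),
                                "constant predictor columns: "
                                + ", ".join(X.columns[constant]))
    corr = np.corrcoef(Xc / sd, rowvar=False)
    cond = np.linalg.cond(corr)
    if cond > 1e10:
        # name the columns most involved in the near-null space
        w, v = np.linalg.eigh(corr)
        weights = np.abs(v[:, np.argmin(w)])
        bad = [c for c, wt in zip(X.columns, weights) if wt > 0.3]
        raise CollinearityError(bad or list(X.columns))


def partial_correlations(descriptors: pd.DataFrame, abundance,
                         predictors: list[str] | None = None) -> pd.Series:
    """Partial correlation of each predictor with abundance, controlling for
    the remaining predictors (correlation of OLS residuals)."""
    predictors = list(predictors or
                      [c for c in PREDICTORS if c in descriptors.columns])
    X = descriptors[predictors]
    y = np.asarray(abundance, dtype=float)
    n = len(y)
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    _check_collinearity(X)
    out = {}
    Xv = X.to_numpy(dtype=float)
    ones = np.ones((n, 1))
    for j, name in enumerate(predictors):
        others = np.hstack([ones, np.delete(Xv, j, axis=1)])
        res_x = Xv[:, j] - others @ np.linalg.lstsq(others, Xv[:, j],
                                                    rcond=None)[0]
        res_y = y - others @ np.linalg.lstsq(others, y, rcond=None)[0]
        out[name] = float(np.corrcoef(res_x, res_y)[0, 1])
    return pd.Series(out, name="partial_r")


@dataclass
class RegressionResult:
    """OLS fit of abundance on the descriptor set.

    ``r`` is always the positive square root of ``r_squared`` and
    ``f_statistic`` the overall F at (k, n-k-1) degrees of freedom.
    """

    intercept: float
    coefficients: dict[str, float]
    r_squared: float
    r: float
    f_statistic: float
    f_pvalue: float
    df_resid: int
    n: int
    partial_r: dict[str, float] = field(default_factory=dict)
    log10_response: bool = False

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "r_squared": self.r_squared, "r": self.r,
            "f_statistic": self.f_statistic, "f_pvalue": self.f_pvalue,
            "df_resid": self.df_resid, "n": self.n,
            "partial_r": self.partial_r,
            "log10_response": self.log10_response,
        }


def multiple_regression(descriptors: pd.DataFrame, abundance,
                        predictors: list[str] | None = None,
                        log10: bool = False) -> RegressionResult:
    """OLS of abundance N on [1, Ds, logP, Pe, S, logKoc].

    With ``log10=True`` the response is log10-transformed first (all N must
    then be positive).  Raises :class:`CollinearityError` on a numerically
    singular design.
    """
    import statsmodels.api as sm

    predictors = list(predictors or
                      [c for c in PREDICTORS if c in descriptors.columns])
    X = descriptors[predictors]
    y = np.asarray(abundance, dtype=float)
    n = len(y)
    k = len(predictors)
    if n <= k + 1:
        raise ValueError("need n > number of predictors + 1")
    _check_collinearity(X)
    if log10:
        if np.any(y <= 0):
            raise ValueError("log10 response requires positive abundances")
        y = np.log10(y)
    design = sm.add_constant(X.to_numpy(dtype=float))
    fit = sm.OLS(y, design).fit()
    r2 = float(fit.rsquared)
    result = RegressionResult(
        intercept=float(fit.params[0]),
        coefficients={name: float(b)
                      for name, b in zip(predictors, fit.params[1:])},
        r_squared=r2,
        r=r_from_r_squared(max(0.0, min(1.0, r2))),
        f_statistic=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        df_resid=int(fit.df_resid),
        n=n,
        partial_r=dict(partial_correlations(descriptors, y, predictors)),
        log10_response=log10,
    )
    return result
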