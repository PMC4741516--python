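"""Mixed-effects structure-function modeling with automatic model selection.

Each biomarker pair (structural covariate X, functional response Y) is
fitted with three candidate fixed-effects forms of equal parsimony,

    inverse quadratic   Y = a - b / X^2
    linear              Y = a + b X
    quadratic           Y = a + b X^2

each as a linear mixed model with a participant random intercept (eyes of
one person are correlated), estimated by maximum likelihood so that AIC is
comparable across fixed-effects forms.  The best model is the AIC minimum;
goodness of fit is reported as the marginal R^2 (fixed effects only) and
conditional R^2 (fixed plus random), and significance of the slope is an
F-test with Bonferroni correction over the number of responses screened
per covariate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

__all__ = [
    "FAMILIES",
    "ModelFit",
    "fit_candidates",
    "select_model",
    "r2_mixed",
    "significance",
    "age_covariate_wald",
    "paired_eye_test",
    "orientation_test",
    "relationship_screen",
]

#: Candidate family -> transform g(X) with Y = a + b * g(X).
#: The inverse-quadratic transform is -1/X^2 so that b keeps the reported
#: sign convention (Y = a - b/X^2) and always flags correlation direction.
FAMILIES = {
    "inverse_quadratic": lambda x: -1.0 / x**2,
    "linear": lambda x: x,
    "quadratic": lambda x: x**2,
}

N_FIXED = 2  # a, b
N_PARAMS = 4  # a, b, sigma_alpha^2, sigma_eps^2 -> AIC = -2l + 2*4


class AnalysisError(RuntimeError):
    """Cohort-level statistics could not be computed."""


@dataclass
class ModelFit:
    """One fitted candidate mixed model."""

    family: str
    a: float
    b: float
    se_b: float
    sigma_alpha2: float  # between-participant variance
    sigma_eps2: float  # residual variance
    sigma_f2: float  # variance of the fixed-effect predictions
    llf: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool

    @property
    def sign(self) -> str:
        return "+" if self.b >= 0 else "-"

    @property
    def r2(self) -> tuple[float, float]:
        return r2_mixed(self)


def _ols_boundary_fit(exog, y, family, n_groups) -> ModelFit:
    """ML fit at the sigma_alpha^2 = 0 boundary, where the mixed model
    degenerates to ordinary least squares (MixedLM's Hessian is singular
    there)."""
    res = sm.OLS(y, exog).fit()
    a, b = np.asarray(res.params)
    n = len(y)
    sigma_eps2 = float(res.ssr / n)  # ML, not OLS-unbiased, variance
    llf = float(res.llf)
    return ModelFit(
        family=family, a=float(a), b=float(b), se_b=float(np.asarray(res.bse)[1]),
        sigma_alpha2=0.0, sigma_eps2=sigma_eps2,
        sigma_f2=float(np.var(exog @ np.asarray(res.params), ddof=1)),
        llf=llf, aic=-2.0 * llf + 2.0 * N_PARAMS,
        n_obs=n, n_groups=n_groups, converged=True,
    )


def _fit_one(x: np.ndarray, y: np.ndarray, groups: np.ndarray, family: str) -> ModelFit:
    g = FAMILIES[family](x)
    exog = np.column_stack([np.ones_like(g), g])
    model = sm.MixedLM(y, exog, groups=groups)
    n_groups = len(np.unique(groups))
    converged = True
    if np.var(g) < 1e-12 * max(1.0, np.mean(g) ** 2):
        # degenerate covariate: slope unidentifiable
        return ModelFit(family, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                        np.nan, np.inf, len(y), n_groups, False)
    import warnings

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(reml=False, method=["lbfgs", "bfgs", "cg"])
            converged = bool(res.converged)
            if float(np.asarray(res.cov_re)[0, 0]) < 1e-10:
                # variance component on its boundary: OLS is the ML fit there
                return _ols_boundary_fit(exog, y, family, n_groups)
            se_b = float(np.asarray(res.bse_fe)[1])
    except (np.linalg.LinAlgError, ValueError):
        return _ols_boundary_fit(exog, y, family, n_groups)
    a, b = np.asarray(res.fe_params)
    sigma_alpha2 = float(np.asarray(res.cov_re)[0, 0])
    sigma_eps2 = float(res.scale)
    sigma_f2 = float(np.var(exog @ np.asarray(res.fe_params), ddof=1))
    llf = float(res.llf)
    if not np.isfinite(se_b):
        return _ols_boundary_fit(exog, y, family, n_groups)
    return ModelFit(
        family=family, a=float(a), b=float(b), se_b=se_b,
        sigma_alpha2=sigma_alpha2, sigma_eps2=sigma_eps2, sigma_f2=sigma_f2,
        llf=llf, aic=-2.0 * llf + 2.0 * N_PARAMS,
        n_obs=len(y), n_groups=n_groups, converged=converged,
    )


def fit_candidates(
    data: pd.DataFrame,
    x: str = "x",
    y: str = "y",
    group: str = "participant",
    families: tuple = tuple(FAMILIES),
) -> list[ModelFit]:
    """Fit every candidate family as a random-intercept mixed model (ML).

    Rows with non-positive X are excluded before fitting the
    inverse-quadratic family only (the transform diverges at 0).
    """
    df = data[[x, y, group]].dropna()
    if len(df) < 6:
        raise AnalysisError("need at least 6 observations")
    if df[group].nunique() < 2:
        raise AnalysisError("need at least 2 participants (clusters)")
    fits = []
    for family in families:
        sub = df
        if family == "inverse_quadratic":
            sub = df[df[x] > 0]
            if len(sub) < 6 or sub[group].nunique() < 2:
                fits.append(ModelFit(family, np.nan, np.nan, np.nan, np.nan, np.nan,
                                     np.nan, np.nan, np.inf, len(sub), 0, False))
                continue
        fits.append(
            _fit_one(sub[x].to_numpy(float), sub[y].to_numpy(float),
                     sub[group].to_numpy(), family)
        )
    return fits


def select_model(fits: list[ModelFit]) -> ModelFit:
    """AIC minimum among converged fits; exact ties prefer the linear form."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if not ok:
        raise AnalysisError("no candidate model converged")
    best_aic = min(f.aic for f in ok)
    at_min = [f for f in ok if f.aic <= best_aic + 1e-9]
    for f in at_min:
        if f.family == "linear":
            return f
    return at_min[0]


def r2_mixed(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R^2 from the variance decomposition.

    R2m = sf^2 / (sf^2 + sa^2 + se^2) — fixed effects only;
    R2c = (sf^2 + sa^2) / (sf^2 + sa^2 + se^2) — fixed plus random.
    """
    total = fit.sigma_f2 + fit.sigma_alpha2 + fit.sigma_eps2
    if not total > 0:
        raise AnalysisError("all variance components are zero")
    return fit.sigma_f2 / total, (fit.sigma_f2 + fit.sigma_alpha2) / total


def significance(
    fit: ModelFit,
    n_comparisons: int = 1,
    base_alpha: float = 0.05,
    df_method: str = "between_within",
) -> tuple[float, float, bool]:
    """F-test of b = 0 with Bonferroni correction.

    F = (b/se_b)^2 with 1 numerator df; the denominator df is
    ``n_obs - n_groups - 1`` (between-within, default) or ``n_obs - 2``
    (simple residual df).  Returns (p, threshold, significant).
    """
    if not fit.converged:
        raise AnalysisError("cannot test an unconverged fit")
    if df_method == "between_within":
        df_den = max(fit.n_obs - fit.n_groups - 1, 1)
    elif df_method == "residual":
        df_den = max(fit.n_obs - N_FIXED, 1)
    else:
        raise ValueError(f"unknown df_method {df_method!r}")
    F = (fit.b / fit.se_b) ** 2
    p = float(sps.f.sf(F, 1, df_den))
    threshold = base_alpha / n_comparisons
    return p, threshold, bool(p < threshold)


def age_covariate_wald(
    data: pd.DataFrame,
    x: str = "x",
    y: str = "y",
    age: str = "age",
    group: str = "participant",
    family: str = "linear",
) -> tuple[float, float]:
    """Wald test of an optional age covariate.

    Fits Y = a + b g(X) + c age + u + eps by ML and tests c = 0 with the
    Wald z statistic; returns (c_hat, p).  Used to decide whether age
    belongs in the relationship models at all.
    """
    df = data[[x, y, age, group]].dropna()
    if len(df) < 8 or df[group].nunique() < 2:
        raise AnalysisError("too little data for the age-covariate test")
    g = FAMILIES[family](df[x].to_numpy(float))
    exog = np.column_stack([np.ones_like(g), g, df[age].to_numpy(float)])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.MixedLM(df[y].to_numpy(float), exog,
                             groups=df[group].to_numpy()).fit(reml=False)
            c, se = float(np.asarray(res.fe_params)[2]), float(
                np.asarray(res.bse_fe)[2])
        except (np.linalg.LinAlgError, ValueError):
            ols = sm.OLS(df[y].to_numpy(float), exog).fit()
            c, se = float(ols.params[2]), float(ols.bse[2])
    z = c / se
    return c, float(2.0 * sps.norm.sf(abs(z)))


def paired_eye_test(left: np.ndarray, right: np.ndarray) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on right-minus-left differences.

    Zero differences are dropped; exact null distribution for <= 25
    non-zero pairs without ties, normal approximation with tie correction
    otherwise.  All-zero differences return p = 1 by convention.
    """
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right samples must pair up")
    if len(left) < 5:
        raise ValueError("need at least 5 complete pairs")
    d = right - left
    d = d[d != 0]
    if len(d) == 0:
        return 0.0, 1.0
    n = len(d)
    has_ties = len(np.unique(np.abs(d))) < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def orientation_test(h_values: np.ndarray, v_values: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test of H vs V biomarkers.

    Exact for small samples (<= 10 per group, no ties); otherwise the
    normal approximation with tie correction.  Identical samples give
    p = 1.
    """
    h = np.asarray(h_values, dtype=float)
    v = np.asarray(v_values, dtype=float)
    if len(h) < 3 or len(v) < 3:
        raise ValueError("need at least 3 values per orientation")
    pooled = np.concatenate([h, v])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (max(len(h), len(v)) <= 10 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(h, v, alternative="two-sided", method=method)
    return float(res.statistic), min(1.0, float(res.pvalue))


def relationship_screen(
    cohort: pd.DataFrame,
    structural: list[str],
    functional: list[str],
    group: str = "participant",
    base_alpha: float = 0.05,
    df_method: str = "between_within",
) -> pd.DataFrame:
    """Best-fit mixed model for every (structural, functional) pair.

    The Bonferroni divisor is the number of functional responses screened
    per structural covariate.  Pairs whose fits all fail are reported as
    NA rows rather than dropped.
    """
    n_comp = len(functional)
    rows = []
    for sx in structural:
        for fy in functional:
            row = {"structural": sx, "functional": fy, "n": 0}
            try:
                sub = cohort[[sx, fy, group]].dropna()
                fits = fit_candidates(sub, x=sx, y=fy, group=group)
                best = select_model(fits)
                r2m, r2c = r2_mixed(best)
                p, thr, sig = significance(
                    best, n_comparisons=n_comp, base_alpha=base_alpha,
                    df_method=df_method,
                )
                row.update(
                    n=best.n_obs, family=best.family, sign=best.sign,
                    a=best.a, b=best.b, R2m=r2m, R2c=r2c, p=p,
                    threshold=thr, significant=sig,
                )
            except AnalysisError:
                row.update(
                    family=pd.NA, sign=pd.NA, a=np.nan, b=np.nan,
                    R2m=np.nan, R2c=np.nan, p=np.nan,
                    threshold=base_alpha / n_comp, significant=pd.NA,
                )
            rows.append(row)
    return pd.DataFrame(rows)
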