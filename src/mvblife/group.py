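"""Group-level inference: robust quadratic age trajectories, ordinal
regression of model-comparison outcomes, directional Bayes factors,
outlier trimming, the decodability group test and the power-based
sensitivity analysis."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import integrate, optimize, stats
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "GroupFit",
    "BayesFactorResult",
    "AgeTrajectoryModel",
    "robust_quadratic_fit",
    "ordinal_age_model",
    "directional_bayes_factor",
    "minimal_detectable_r2",
    "trim_outliers",
    "group_decodability_test",
]

HUBER_TUNING = 1.345          # 95% Gaussian efficiency
OUTLIER_Z = 5.0
BOOST_ORDER = ("reduction", "equivalent", "boost")


def standardize(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate predictor: zero variance")
    return (x - x.mean()) / sd


@dataclass
class GroupFit:
    """Robust polynomial age-effect fit on one dependent measure."""

    coef_linear: float
    coef_quadratic: float
    t_linear: float
    t_quadratic: float
    p_linear: float
    p_quadratic: float
    f_stat: float
    f_p: float
    r2_adj: float
    n: int
    robust: bool = True

    def summary(self) -> str:
        return (
            f"robust quadratic age fit (n={self.n}): "
            f"F(2,{self.n - 3})={self.f_stat:.3g}, p={self.f_p:.3g}; "
            f"linear t={self.t_linear:.3g} (p={self.p_linear:.3g}), "
            f"quadratic t={self.t_quadratic:.3g} (p={self.p_quadratic:.3g}); "
            f"r2_adj={self.r2_adj:.3g}"
        )


class AgeTrajectoryModel:
    """Second-order polynomial age-trajectory model for one group measure.

    ``fit(robust=True)`` uses Huber M-estimation (tuning constant 1.345);
    ``robust=False`` falls back to ordinary least squares.  Both the linear
    and the quadratic predictor are standardized (the quadratic is the
    squared standardized age, re-standardized).
    """

    def __init__(self, values: np.ndarray, ages: np.ndarray):
        values = np.asarray(values, float)
        ages = np.asarray(ages, float)
        keep = np.isfinite(values) & np.isfinite(ages)
        self.values = values[keep]
        self.ages = ages[keep]
        if len(self.values) < 4:
            raise ValueError("need at least 4 complete observations")

    def design(self) -> np.ndarray:
        z = standardize(self.ages)
        q = standardize(z ** 2)
        return np.column_stack([np.ones_like(z), z, q])

    def fit(self, robust: bool = True) -> GroupFit:
        X = self.design()
        y = self.values
        n = len(y)
        if robust:
            model = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_TUNING))
            res = model.fit()
            params, bse = res.params, res.bse
            cov = res.bcov_scaled
        else:
            res = sm.OLS(y, X).fit()
            params, bse = res.params, res.bse
            cov = res.cov_params()
        tvals = params / bse
        # asymptotic normal theory on the M-estimator covariance
        pvals = 2.0 * stats.norm.sf(np.abs(tvals))
        b = params[1:]
        vb = cov[1:, 1:]
        f_stat = float(b @ np.linalg.solve(vb, b) / 2.0)
        f_p = float(stats.f.sf(f_stat, 2, n - 3))
        fitted = X @ params
        rss = float(((y - fitted) ** 2).sum())
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - rss / tss if tss > 0 else 0.0
        r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 3)
        return GroupFit(
            coef_linear=float(params[1]), coef_quadratic=float(params[2]),
            t_linear=float(tvals[1]), t_quadratic=float(tvals[2]),
            p_linear=float(pvals[1]), p_quadratic=float(pvals[2]),
            f_stat=f_stat, f_p=f_p, r2_adj=float(r2_adj), n=n, robust=robust,
        )

    def coefficient_se(self, robust: bool = True) -> tuple[float, float]:
        """(linear coefficient, its SE) on the standardized-value scale,
        for feeding a directional Bayes factor."""
        y = standardize(self.values)
        X = self.design()
        if robust:
            res = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=HUBER_TUNING)).fit()
        else:
            res = sm.OLS(y, X).fit()
        return float(res.params[1]), float(res.bse[1])


def robust_quadratic_fit(values: np.ndarray, ages: np.ndarray,
                         robust: bool = True) -> GroupFit:
    """Huber M-estimation fit of value ~ z(age) + z(age)^2 (standardized)."""
    return AgeTrajectoryModel(values, ages).fit(robust=robust)


def ordinal_age_model(categories, ages: np.ndarray,
                      quadratic: bool = False) -> tuple[float, float, float]:
    """Proportional-odds (logit) model of ordered model-comparison outcomes
    (reduction < equivalent < boost) on standardized age.

    Returns (age coefficient, t, two-tailed p) for the linear age term.
    """
    import pandas as pd

    cats = pd.Categorical(list(categories), categories=list(BOOST_ORDER),
                          ordered=True)
    if len(set(cats.codes)) < 2:
        raise ValueError("ordinal model non-identifiable: one category only")
    cats = cats.remove_unused_categories()
    z = standardize(np.asarray(ages, float))
    exog = {"age_z": z}
    if quadratic:
        exog["age_z2"] = standardize(z ** 2)
    exog = pd.DataFrame(exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = OrderedModel(pd.Series(cats), exog, distr="logit")
        res = model.fit(method="bfgs", disp=False, maxiter=200)
    coef = float(res.params["age_z"])
    t = float(res.tvalues["age_z"])
    p = float(res.pvalues["age_z"])
    return coef, t, p


@dataclass
class BayesFactorResult:
    bf01: float                  # evidence for H0 over the directional H1
    direction: str
    halfnormal_sd: float


def directional_bayes_factor(estimate: float, se: float,
                             halfnormal_sd: float = 1.0) -> BayesFactorResult:
    """BF01 for a directional hypothesis with a half-normal effect prior
    (mean 0, SD ``halfnormal_sd``) against the point null.

    bf01 = N(estimate; 0, se) / int_0^inf 2 N(d; 0, sd) N(estimate; d, se) dd
    """
    if se <= 0:
        raise ValueError("se must be positive")
    if halfnormal_sd < 0:
        raise ValueError("halfnormal_sd must be non-negative")
    like0 = stats.norm.pdf(estimate, 0.0, se)
    if halfnormal_sd == 0.0:
        return BayesFactorResult(1.0, "directional", 0.0)

    # substitute d = halfnormal_sd * u so the integrand stays well scaled
    # for arbitrarily narrow effect priors
    def integrand(u):
        return (2.0 * stats.norm.pdf(u)
                * stats.norm.pdf(estimate, halfnormal_sd * u, se))

    marg1, _ = integrate.quad(integrand, 0.0, np.inf,
                              epsabs=1e-14, epsrel=1e-10, limit=200)
    return BayesFactorResult(float(like0 / marg1), "directional",
                             float(halfnormal_sd))


def minimal_detectable_r2(n: int, n_predictors: int = 2, alpha: float = 0.05,
                          power: float = 0.80) -> float:
    """Smallest proportion of variance a single coefficient in an
    ``n_predictors`` linear model can detect with the requested power.

    Solves for the effect size f^2 at which the two-tailed single-coefficient
    test (noncentral F with df1 = 1, df2 = n - n_predictors - 1,
    noncentrality lambda = f^2 * n) attains the requested power, and returns
    that variance proportion.
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    if n <= n_predictors + 1:
        raise ValueError("n too small for the requested model")
    df2 = n - n_predictors - 1
    crit = stats.f.ppf(1.0 - alpha, 1, df2)

    def power_at(f2):
        return 1.0 - stats.ncf.cdf(crit, 1, df2, f2 * n)

    if power <= power_at(1e-12):
        return 0.0
    f2 = optimize.brentq(lambda f2: power_at(f2) - power, 1e-12, 10.0,
                         xtol=1e-12, rtol=1e-12)
    return float(f2)


def trim_outliers(values: np.ndarray, z: float = OUTLIER_Z) -> np.ndarray:
    """Indices of values within z sample SDs of the mean (single pass).

    Zero-variance input returns all indices.
    """
    vals = np.asarray(values, float)
    if len(vals) < 3:
        raise ValueError("need at least 3 values to trim")
    sd = vals.std(ddof=1)
    if sd == 0:
        return np.arange(len(vals))
    keep = np.abs(vals - vals.mean()) <= z * sd
    return np.flatnonzero(keep)


def group_decodability_test(deltas: np.ndarray, null_mean: float = 3.0
                            ) -> tuple[float, float, float, float]:
    """One-sample one-tailed t test of real-minus-shuffled log evidences
    against a hypothesised population mean difference.

    Returns (t, one-tailed p for mean > null_mean, adjusted r^2 effect
    size, mean of the deltas).
    """
    d = np.asarray(deltas, float)
    n = len(d)
    if n < 3:
        raise ValueError("need at least 3 subjects")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in decodability deltas")
    t = (d.mean() - null_mean) / (sd / np.sqrt(n))
    p = float(stats.t.sf(t, n - 1))
    r2 = t ** 2 / (t ** 2 + (n - 1))
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    return float(t), p, float(r2_adj), float(d.mean())
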