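"""Regression models for occupancy and cognition analyses.

Three model families are provided behind a common result container:

* **Beta regression** with logit link and a single (fixed) precision
  parameter ``phi`` — the model for fractional-occupancy outcomes in (0, 1).
  Implemented in-package by maximum likelihood: the density is
  ``f(y; mu, phi) = Gamma(phi) / (Gamma(mu phi) Gamma((1-mu) phi)) *
  y^(mu phi - 1) (1-y)^((1-mu) phi - 1)`` with ``logit(mu_i) = x_i' beta``.
  Optimization is quasi-Newton on ``(beta, ln phi)`` with the analytic
  score; Wald standard errors come from the inverse observed information.
* **Gamma GLM** with log link for positive completion times, via iteratively
  reweighted least squares with Pearson dispersion.
* **Binomial GLM** with logit link for bounded scores.

Effect sizes are reported on interpretable scales — odds ratio per
interquartile ratio of the WMH burden, multiplier per 5 percentage points of
occupancy, per 10 years of age — by monotone transforms of the link-scale
coefficients; the transforms never alter p-values.

WMH volumes enter the models as the natural log of the non-zero volume;
exact zeros retain the value zero and are compensated by a binary
zero-volume indicator, included only when zeros are present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "RegressionResult",
    "EffectEstimate",
    "DesignSpec",
    "transform_wmh",
    "shrink_unit_interval",
    "add_wmh_columns",
    "build_design",
    "beta_regression",
    "gamma_glm",
    "binomial_glm",
    "effect_per_iqr",
    "effect_multiplier",
    "effect_per_k_pp",
    "effect_table",
]

_Z975 = float(stats.norm.ppf(0.975))


@dataclass
class RegressionResult:
    """Fitted coefficients with Wald inference on the link scale."""

    model: str
    params: pd.Series
    cov_params: pd.DataFrame
    dispersion: float  # phi for beta; Pearson scale for gamma; 1 for binomial
    loglik: float
    n_obs: int
    converged: bool = True
    detail: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        cov = self.cov_params.to_numpy()
        if not np.allclose(cov, cov.T, atol=1e-8):
            raise ValueError("covariance matrix must be symmetric")
        eig = np.linalg.eigvalsh((cov + cov.T) / 2.0)
        if eig.min() < -1e-8 * max(1.0, eig.max()):
            raise ValueError("covariance matrix must be positive semi-definite")

    @property
    def se(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.se

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2.0 * stats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.params.index,
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = float(stats.norm.ppf(1.0 - alpha / 2.0))
        lo = self.params - z * self.se
        hi = self.params + z * self.se
        return pd.DataFrame({"lower": lo, "upper": hi})


@dataclass
class EffectEstimate:
    """An effect on its reporting scale with a Wald CI carried over."""

    name: str
    scale: str
    estimate: float
    ci_lower: float
    ci_upper: float
    pvalue: float

    def __post_init__(self) -> None:
        if self.ci_lower > self.ci_upper:
            raise ValueError("CI bounds out of order")


@dataclass(frozen=True)
class DesignSpec:
    """A small declarative model description (no expression language).

    ``covariates`` name columns of the analysis table; the WMH transform
    (``ln_wmh`` + ``wmh_zero``) and occupancy/age scalings are applied by
    name, not by formula.
    """

    outcome: str
    covariates: tuple[str, ...]
    family: str  # "beta" | "gamma" | "binomial"


def transform_wmh(volumes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(ln of non-zero volume with zeros kept at 0, zero indicator)."""
    v = np.asarray(volumes, dtype=float)
    if np.any(v < 0.0):
        raise ValueError("WMH volumes must be non-negative")
    zero = v == 0.0
    lnv = np.where(zero, 0.0, np.log(np.where(zero, 1.0, v)))
    return lnv, zero.astype(float)


def shrink_unit_interval(y: np.ndarray) -> np.ndarray:
    """Opt-in boundary shrinkage ``(y (n-1) + 1/2) / n`` for beta outcomes."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


def add_wmh_columns(df: pd.DataFrame, wmh_col: str = "wmh_total_ml") -> pd.DataFrame:
    """Attach ``ln_wmh`` and ``wmh_zero`` derived from ``wmh_col``."""
    out = df.copy()
    lnv, zero = transform_wmh(out[wmh_col].to_numpy())
    out["ln_wmh"] = lnv
    out["wmh_zero"] = zero
    return out


def build_design(df: pd.DataFrame, covariates) -> pd.DataFrame:
    """Design matrix with intercept; drops the zero indicator when no zeros.

    Dropping a constant zero-indicator column guards against collinearity
    and leaves every other estimate untouched.
    """
    cols = list(covariates)
    if "wmh_zero" in cols and "wmh_zero" in df.columns:
        if not (df["wmh_zero"].to_numpy() != 0).any():
            cols = [c for c in cols if c != "wmh_zero"]
    X = pd.DataFrame({"const": np.ones(len(df))}, index=df.index)
    for c in cols:
        if c == "female":
            X[c] = (df["sex"].to_numpy() == "female").astype(float)
        else:
            X[c] = pd.to_numeric(df[c]).astype(float).to_numpy()
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    return X


# ---------------------------------------------------------------------------
# beta regression (fixed dispersion, logit link)
# ---------------------------------------------------------------------------


def _beta_loglik_parts(theta, y, X):
    p = X.shape[1]
    beta = theta[:p]
    phi = np.exp(np.clip(theta[p], -10.0, 25.0))
    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = special.expit(eta)
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = np.sum(
        special.gammaln(phi)
        - special.gammaln(a)
        - special.gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return ll, beta, phi, mu, a, b


def _beta_negll(theta, y, X):
    ll = _beta_loglik_parts(theta, y, X)[0]
    return -ll if np.isfinite(ll) else 1e12


def _beta_negscore(theta, y, X):
    _, beta, phi, mu, a, b = _beta_loglik_parts(theta, y, X)
    ystar = np.log(y) - np.log1p(-y)
    mustar = special.digamma(a) - special.digamma(b)
    w = phi * (ystar - mustar) * mu * (1.0 - mu)
    g_beta = X.T @ w
    g_lnphi = phi * np.sum(
        special.digamma(phi)
        - mu * special.digamma(a)
        - (1.0 - mu) * special.digamma(b)
        + mu * np.log(y)
        + (1.0 - mu) * np.log1p(-y)
    )
    return -np.concatenate([g_beta, [g_lnphi]])


def _newton_polish(theta, y, X, max_iter: int = 50, tol: float = 1e-12):
    """Newton refinement with backtracking on the negative log-likelihood."""
    theta = np.asarray(theta, dtype=float).copy()
    f = _beta_negll(theta, y, X)
    for _ in range(max_iter):
        g = _beta_negscore(theta, y, X)
        if np.max(np.abs(g)) < 1e-10:
            break
        H = approx_hess1(theta, _beta_negll, args=(y, X))
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g
        t = 1.0
        for _ in range(40):
            cand = theta - t * step
            fc = _beta_negll(cand, y, X)
            if fc <= f - 1e-4 * t * float(g @ step) or fc < f:
                break
            t *= 0.5
        else:
            break
        if abs(f - fc) < tol * max(1.0, abs(f)):
            theta, f = cand, fc
            break
        theta, f = cand, fc
    return theta


def beta_regression(
    y: np.ndarray,
    X: pd.DataFrame,
    max_iter: int = 500,
    shrink_boundary: bool = False,
) -> RegressionResult:
    """Fixed-dispersion beta regression by maximum likelihood.

    ``y`` must lie strictly inside (0, 1); exact 0/1 values raise unless the
    caller opts into :func:`shrink_unit_interval` via ``shrink_boundary``.
    Starting values come from a logit-scale least-squares fit; the precision
    is parameterized as ``ln phi`` for positivity.  Standard errors are
    Wald, from the inverse observed information over ``(beta, ln phi)``.
    """
    y = np.asarray(y, dtype=float)
    if shrink_boundary:
        y = shrink_unit_interval(y)
    if np.any((y <= 0.0) | (y >= 1.0)):
        raise ValueError(
            "beta regression requires outcomes strictly inside (0, 1); "
            "use shrink_boundary=True to apply (y(n-1)+1/2)/n explicitly"
        )
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    n, p = Xv.shape

    # starting values: logit-scale least squares, moment estimate of phi
    z = special.logit(y)
    beta0, *_ = np.linalg.lstsq(Xv, z, rcond=None)
    mu0 = special.expit(Xv @ beta0)
    resid_var = max(np.var(z - Xv @ beta0), 1e-8)
    # delta method: var(logit y) ~ var(y) / (mu(1-mu))^2
    phi0 = float(np.clip(np.mean(1.0 / (resid_var * mu0 * (1.0 - mu0))) - 1.0, 1.0, 1e6))
    theta0 = np.concatenate([beta0, [np.log(phi0)]])

    res = optimize.minimize(
        _beta_negll,
        theta0,
        args=(y, Xv),
        jac=_beta_negscore,
        method="L-BFGS-B",
        bounds=[(None, None)] * p + [(-10.0, 25.0)],
        options={"maxiter": max_iter},
    )
    theta = _newton_polish(res.x, y, Xv)
    grad = _beta_negscore(theta, y, Xv)
    if np.max(np.abs(grad)) > 1e-5 * max(1.0, abs(_beta_negll(theta, y, Xv))):
        raise RuntimeError(
            "beta regression did not converge: "
            f"{res.message}; |grad|max={np.max(np.abs(grad)):.2e} "
            f"after Newton polish (n={n}, p={p})"
        )
    hess = approx_hess1(theta, _beta_negll, args=(y, Xv))
    cov_all = np.linalg.inv(hess)
    phi = float(np.exp(theta[p]))
    names = list(X.columns)
    return RegressionResult(
        model="beta",
        params=pd.Series(theta[:p], index=names),
        cov_params=pd.DataFrame(cov_all[:p, :p], index=names, columns=names),
        dispersion=phi,
        loglik=float(-_beta_negll(theta, y, Xv)),
        n_obs=n,
        converged=True,
        detail={"ln_phi_se": float(np.sqrt(cov_all[p, p])), "opt": res.message},
    )


# ---------------------------------------------------------------------------
# gamma / binomial GLMs (statsmodels IRLS behind the module surface)
# ---------------------------------------------------------------------------


def gamma_glm(y: np.ndarray, X: pd.DataFrame) -> RegressionResult:
    """Gamma GLM with log link; Pearson dispersion; Wald inference."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0.0):
        raise ValueError("gamma GLM requires strictly positive outcomes")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(y, Xv, family=sm.families.Gamma(link=sm.families.links.Log()))
    with warnings.catch_warnings():
        # a perfect fit (e.g. constant outcome) is legitimate here
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(scale="X2")
        except ValueError:
            start, *_ = np.linalg.lstsq(Xv, np.log(y), rcond=None)
            fit = model.fit(scale="X2", start_params=start)
    names = list(X.columns)
    return RegressionResult(
        model="gamma",
        params=pd.Series(fit.params, index=names),
        cov_params=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        dispersion=float(fit.scale),
        loglik=float(fit.llf),
        n_obs=int(fit.nobs),
    )


def binomial_glm(
    successes: np.ndarray, trials: np.ndarray, X: pd.DataFrame
) -> RegressionResult:
    """Binomial GLM with logit link on (successes, trials) outcomes."""
    s = np.asarray(successes, dtype=float)
    t = np.asarray(trials, dtype=float)
    if np.any((s < 0) | (s > t)):
        raise ValueError("successes must lie in [0, trials]")
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")
    model = sm.GLM(
        np.column_stack([s, t - s]), Xv, family=sm.families.Binomial()
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            fit = model.fit()
    except (RuntimeWarning, np.linalg.LinAlgError) as exc:
        raise RuntimeError(f"binomial GLM failed to converge: {exc}") from exc
    params = np.asarray(fit.params)
    if np.any(np.abs(params) > 50.0):
        worst = list(X.columns)[int(np.argmax(np.abs(params)))]
        raise RuntimeError(
            f"apparent separation in binomial GLM (covariate '{worst}')"
        )
    names = list(X.columns)
    return RegressionResult(
        model="binomial",
        params=pd.Series(params, index=names),
        cov_params=pd.DataFrame(fit.cov_params(), index=names, columns=names),
        dispersion=1.0,
        loglik=float(fit.llf),
        n_obs=int(fit.nobs),
    )


# ---------------------------------------------------------------------------
# effect-size transforms (reporting scales)
# ---------------------------------------------------------------------------


def _transformed_effect(
    result: RegressionResult, coef: str, factor: float, name: str, scale: str
) -> EffectEstimate:
    if coef not in result.params.index:
        raise KeyError(f"coefficient '{coef}' not present in the fit")
    b = float(result.params[coef])
    se = float(result.se[coef])
    lo = np.exp((b - _Z975 * se) * factor)
    hi = np.exp((b + _Z975 * se) * factor)
    if factor < 0:
        lo, hi = hi, lo
    return EffectEstimate(
        name=name,
        scale=scale,
        estimate=float(np.exp(b * factor)),
        ci_lower=float(lo),
        ci_upper=float(hi),
        pvalue=float(result.pvalues[coef]),
    )


def effect_per_iqr(
    result: RegressionResult, q1: float, q3: float, coef: str = "ln_wmh"
) -> EffectEstimate:
    """Odds ratio (or multiplier) per Q3/Q1-fold increase in WMH volume."""
    if not (0.0 < q1 < q3):
        raise ValueError("need q3 > q1 > 0")
    factor = float(np.log(q3 / q1))
    return _transformed_effect(
        result, coef, factor, name=coef,
        scale=f"per {q3 / q1:.2f}-fold increase",
    )


def effect_multiplier(
    result: RegressionResult, coef: str, per_units: float, scale: str | None = None
) -> EffectEstimate:
    """Generic exp(beta * per_units) multiplier (e.g. age per 10 years)."""
    return _transformed_effect(
        result, coef, float(per_units), name=coef,
        scale=scale or f"per {per_units:g} units",
    )


def effect_per_k_pp(
    result: RegressionResult, k_pp: float = 5.0, coef: str = "fo_high"
) -> EffectEstimate:
    """Multiplier per ``k_pp`` percentage points of occupancy.

    The occupancy covariate is modeled on the proportion scale, so the
    reporting factor is ``k_pp / 100``.
    """
    return _transformed_effect(
        result, coef, float(k_pp) / 100.0, name=coef,
        scale=f"per {k_pp:g} percentage points",
    )


def effect_table(effects: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy effect-size table (estimate, 95% CI, p) on reporting scales."""
    return pd.DataFrame(
        [
            {
                "term": e.name,
                "scale": e.scale,
                "estimate": e.estimate,
                "ci_lower": e.ci_lower,
                "ci_upper": e.ci_upper,
                "p": e.pvalue,
            }
            for e in effects
        ]
    )
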