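"""Random-effects meta-analysis of per-study validation metrics.

Implements inverse-variance random-effects pooling with the REML estimator
of the between-study variance tau^2, 95% prediction intervals in the
Higgins-Thompson-Spiegelhalter form, random-effects meta-regression, and a
Reitsma-style bivariate random-effects model for sensitivity/specificity.

Analysis scales follow standard prognostic-model meta-analysis practice:
the C-statistic is pooled on the logit scale, the E/O ratio on the log
scale, and the calibration slope/intercept on the identity scale; results
are back-transformed for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

logger = logging.getLogger(__name__)

__all__ = [
    "PooledResult",
    "BivariateResult",
    "reml_pool",
    "prediction_interval",
    "meta_regress",
    "MetaRegression",
    "bivariate_pool",
    "SCALE_TRANSFORMS",
]

#: metric name -> (to analysis scale, back-transform)
SCALE_TRANSFORMS = {
    "logit": (lambda x: logit(x), lambda x: expit(x)),
    "log": (np.log, np.exp),
    "identity": (lambda x: x, lambda x: x),
}


@dataclass
class PooledResult:
    """Random-effects summary of one metric across studies.

    All of ``estimate``, ``se``, ``ci``, ``prediction_interval`` and ``tau2``
    live on the analysis scale; the ``natural_*`` fields are their
    back-transforms.
    """

    metric: str
    scale: str
    k: int
    estimate: float
    se: float
    ci: tuple[float, float]
    tau2: float
    prediction_interval: tuple[float, float] | None
    method: str = "REML"
    flags: list[str] = field(default_factory=list)

    @property
    def natural_estimate(self) -> float:
        return float(SCALE_TRANSFORMS[self.scale][1](self.estimate))

    @property
    def natural_ci(self) -> tuple[float, float]:
        back = SCALE_TRANSFORMS[self.scale][1]
        return (float(back(self.ci[0])), float(back(self.ci[1])))

    @property
    def natural_prediction_interval(self) -> tuple[float, float] | None:
        if self.prediction_interval is None:
            return None
        back = SCALE_TRANSFORMS[self.scale][1]
        lo, hi = self.prediction_interval
        return (float(back(lo)), float(back(hi)))

    def to_dict(self) -> dict:
        return {
            "metric": self.metric,
            "scale": self.scale,
            "k": self.k,
            "estimate": self.estimate,
            "se": self.se,
            "ci": list(self.ci),
            "tau2": self.tau2,
            "prediction_interval": (
                list(self.prediction_interval) if self.prediction_interval else None
            ),
            "natural_estimate": self.natural_estimate,
            "natural_ci": list(self.natural_ci),
            "natural_prediction_interval": (
                list(self.natural_prediction_interval)
                if self.natural_prediction_interval is not None
                else None
            ),
            "method": self.method,
            "flags": self.flags,
        }


def _dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu) ** 2)
    k = len(y)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    return max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0


def _reml_tau2(
    y: np.ndarray, v: np.ndarray, tol: float = 1e-8, maxiter: int = 100
) -> tuple[float, bool]:
    """REML estimate of tau^2 by Fisher-scoring iteration, floored at 0."""
    tau2 = _dersimonian_laird(y, v)
    for _ in range(maxiter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        resid2 = (y - mu) ** 2
        # REML estimating equation (one-step update used by standard
        # meta-analysis software): adds 1/sum(w) to correct for estimating mu
        new = np.sum(w**2 * (resid2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, new)
        if abs(new - tau2) < tol:
            return new, True
        tau2 = new
    return tau2, False


def restricted_loglik(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    """Restricted log-likelihood of a random-effects meta-analysis at tau^2."""
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(v + tau2))
        + np.log(np.sum(w))
        + np.sum(w * (y - mu) ** 2)
    )


def reml_pool(
    estimates,
    variances,
    *,
    metric: str = "metric",
    scale: str = "identity",
    conf_level: float = 0.95,
) -> PooledResult:
    """Inverse-variance random-effects pooling with REML tau^2.

    ``estimates`` and ``variances`` (squared SEs) must already be on the
    analysis scale.  The pooled estimate is sum(w_i y_i)/sum(w_i) with
    w_i = 1/(v_i + tau^2) and SE = (sum w_i)^{-1/2}; the CI is normal-based.
    If the REML iteration fails to converge the DerSimonian-Laird estimate
    is used with a logged warning.  A 95% prediction interval is attached
    when k >= 3.
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if len(y) < 2:
        raise ValueError("pooling requires at least 2 studies")
    if np.any(v <= 0) or not np.all(np.isfinite(y)) or not np.all(np.isfinite(v)):
        raise ValueError("variances must be positive and estimates finite")
    tau2, converged = _reml_tau2(y, v)
    method = "REML"
    flags: list[str] = []
    if not converged:
        tau2 = _dersimonian_laird(y, v)
        method = "DL"
        flags.append("REML non-convergence; DerSimonian-Laird fallback")
        logger.warning("REML failed to converge for %s; falling back to DL", metric)
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = stats.norm.ppf(0.5 + conf_level / 2)
    result = PooledResult(
        metric=metric,
        scale=scale,
        k=len(y),
        estimate=pooled,
        se=se,
        ci=(pooled - z * se, pooled + z * se),
        tau2=float(tau2),
        prediction_interval=None,
        method=method,
        flags=flags,
    )
    if len(y) >= 3:
        result.prediction_interval = prediction_interval(result)
    else:
        result.flags.append("prediction interval omitted (k < 3)")
    return result


def prediction_interval(
    pooled: PooledResult, conf_level: float = 0.95
) -> tuple[float, float]:
    """95% prediction interval: pooled +/- t_{k-2} * sqrt(tau^2 + SE^2).

    Describes the metric expected in a new setting; always at least as wide
    as the CI, and requires k >= 3 studies.
    """
    if pooled.k < 3:
        raise ValueError("prediction interval requires k >= 3 studies")
    t = stats.t.ppf(0.5 + conf_level / 2, df=pooled.k - 2)
    half = t * np.sqrt(pooled.tau2 + pooled.se**2)
    return (pooled.estimate - half, pooled.estimate + half)


@dataclass
class MetaRegression:
    """Random-effects meta-regression of an estimate on one study covariate."""

    intercept: float
    slope: float
    cov_params: np.ndarray
    tau2: float
    k: int
    covariate_range: tuple[float, float]
    flags: list[str] = field(default_factory=list)

    def interpolate(self, x: float) -> float:
        """Fitted value at covariate ``x`` (warns when extrapolating)."""
        lo, hi = self.covariate_range
        if not lo <= x <= hi:
            warnings.warn(
                f"interpolating at {x:.3g} outside the observed covariate "
                f"range [{lo:.3g}, {hi:.3g}]",
                stacklevel=2,
            )
        return float(self.intercept + self.slope * x)


def _reml_profile_regression(y, v, X):
    """Maximise the restricted likelihood of y = X beta + u + e over tau^2."""

    def neg_restricted(tau2):
        W = 1.0 / (v + tau2)
        XtWX = X.T @ (X * W[:, None])
        beta = np.linalg.solve(XtWX, X.T @ (W * y))
        r = y - X @ beta
        sign, logdet = np.linalg.slogdet(XtWX)
        return 0.5 * (np.sum(np.log(v + tau2)) + logdet + np.sum(W * r * r))

    res = optimize.minimize_scalar(
        neg_restricted, bounds=(0.0, max(np.var(y) * 10, 1e-6)), method="bounded",
        options={"xatol": 1e-10},
    )
    tau2 = max(float(res.x), 0.0)
    if neg_restricted(0.0) <= res.fun:
        tau2 = 0.0
    return tau2


def meta_regress(estimates, variances, covariate) -> MetaRegression:
    """Random-effects meta-regression (REML residual heterogeneity).

    Regresses per-study estimates on one covariate (here the study MDI
    proportion) with weights 1/(v_i + tau^2); ``interpolate`` then reads the
    fitted line at any covariate value.  With a constant covariate the slope
    is undefined and the fit degenerates to plain random-effects pooling
    (flagged).
    """
    y = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    x = np.asarray(covariate, dtype=float)
    if len(y) < 3:
        raise ValueError(
            "meta-regression requires at least 3 studies; with fewer, update "
            "intercepts per study from the observed event rate instead"
        )
    if np.ptp(x) == 0:
        pooled = reml_pool(y, v)
        return MetaRegression(
            intercept=pooled.estimate,
            slope=0.0,
            cov_params=np.array([[pooled.se**2, 0.0], [0.0, np.nan]]),
            tau2=pooled.tau2,
            k=len(y),
            covariate_range=(float(x[0]), float(x[0])),
            flags=["constant covariate: slope undefined, intercept = pooled mean"],
        )
    X = np.column_stack([np.ones_like(x), x])
    tau2 = _reml_profile_regression(y, v, X)
    W = 1.0 / (v + tau2)
    XtWX = X.T @ (X * W[:, None])
    beta = np.linalg.solve(XtWX, X.T @ (W * y))
    cov = np.linalg.inv(XtWX)
    return MetaRegression(
        intercept=float(beta[0]),
        slope=float(beta[1]),
        cov_params=cov,
        tau2=tau2,
        k=len(y),
        covariate_range=(float(x.min()), float(x.max())),
    )


@dataclass
class BivariateResult:
    """Bivariate random-effects summary of sensitivity and specificity.

    ``mu`` holds the pooled (logit Sn, logit Sp); ``psi`` the between-study
    covariance; ``cov_mu`` the sampling covariance of the pooled point.
    Ellipse parameters for ROC-space plotting derive from ``cov_mu``
    (confidence region) and ``cov_mu + psi`` (prediction region).
    """

    mu: np.ndarray
    cov_mu: np.ndarray
    psi: np.ndarray
    k: int
    converged: bool
    flags: list[str] = field(default_factory=list)

    @property
    def sensitivity(self) -> float:
        return float(expit(self.mu[0]))

    @property
    def specificity(self) -> float:
        return float(expit(self.mu[1]))

    def _ci(self, i: int) -> tuple[float, float]:
        se = np.sqrt(self.cov_mu[i, i])
        return (
            float(expit(self.mu[i] - 1.96 * se)),
            float(expit(self.mu[i] + 1.96 * se)),
        )

    @property
    def sensitivity_ci(self) -> tuple[float, float]:
        return self._ci(0)

    @property
    def specificity_ci(self) -> tuple[float, float]:
        return self._ci(1)

    def ellipse(self, region: str = "confidence", conf_level: float = 0.95) -> dict:
        """Parameters of the 95% region ellipse on the logit-logit plane."""
        cov = self.cov_mu if region == "confidence" else self.cov_mu + self.psi
        evals, evecs = np.linalg.eigh(cov)
        chi2 = stats.chi2.ppf(conf_level, df=2)
        angle = float(np.arctan2(evecs[1, -1], evecs[0, -1]))
        return {
            "center_logit_sn": float(self.mu[0]),
            "center_logit_sp": float(self.mu[1]),
            "semi_axis_major": float(np.sqrt(chi2 * max(evals[-1], 0.0))),
            "semi_axis_minor": float(np.sqrt(chi2 * max(evals[0], 0.0))),
            "angle_rad": angle,
            "region": region,
        }

    def to_dict(self) -> dict:
        return {
            "pooled_sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "pooled_specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "logit_mu": self.mu.tolist(),
            "cov_mu": self.cov_mu.tolist(),
            "between_study_cov": self.psi.tolist(),
            "k": self.k,
            "converged": self.converged,
            "flags": self.flags,
        }


def _bivariate_neg_restricted_ll(params, Y, V):
    # params: log sd_sn, log sd_sp, atanh rho
    s1, s2 = np.exp(params[0]), np.exp(params[1])
    rho = np.tanh(params[2])
    psi = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    k = len(Y)
    Sinv_sum = np.zeros((2, 2))
    Sinv_y_sum = np.zeros(2)
    logdets = 0.0
    Sinvs = []
    for i in range(k):
        S = V[i] + psi
        try:
            Sinv = np.linalg.inv(S)
        except np.linalg.LinAlgError:
            return 1e12
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            return 1e12
        logdets += logdet
        Sinv_sum += Sinv
        Sinv_y_sum += Sinv @ Y[i]
        Sinvs.append(Sinv)
    mu = np.linalg.solve(Sinv_sum, Sinv_y_sum)
    quad = sum(float((Y[i] - mu) @ Sinvs[i] @ (Y[i] - mu)) for i in range(k))
    sign, logdet_sum = np.linalg.slogdet(Sinv_sum)
    # REML: + log|sum S_i^{-1}| accounts for estimating mu
    return 0.5 * (logdets + logdet_sum + quad)


def bivariate_pool(tables) -> BivariateResult:
    """Reitsma-style bivariate random-effects pooling of 2x2 tables.

    Each table is a mapping with integer cells TP/FN/TN/FP.  Per-study
    sensitivity and specificity are logit-transformed with approximate
    binomial within-study variances (1/x + 1/(n-x)); cells of zero receive a
    +0.5 continuity correction (logged).  The between-study 2x2 covariance
    is estimated by REML over (log sd_sn, log sd_sp, atanh rho); if the
    optimiser fails, the two traits are pooled independently and the
    correlation reported as unavailable.
    """
    if len(tables) < 3:
        raise ValueError("bivariate pooling requires at least 3 studies")
    Y, V = [], []
    flags = []
    for i, t in enumerate(tables):
        tp, fn, tn, fp = (float(t[c]) for c in ("TP", "FN", "TN", "FP"))
        if min(tp, fn, tn, fp) == 0:
            tp, fn, tn, fp = tp + 0.5, fn + 0.5, tn + 0.5, fp + 0.5
            flags.append(f"study {i}: +0.5 continuity correction")
            logger.info("bivariate pooling: continuity correction for study %d", i)
        y = np.array([np.log(tp / fn), np.log(tn / fp)])
        v = np.diag([1 / tp + 1 / fn, 1 / tn + 1 / fp])
        Y.append(y)
        V.append(v)
    Y = np.array(Y)
    x0 = np.array([np.log(0.5), np.log(0.5), 0.0])
    res = optimize.minimize(
        _bivariate_neg_restricted_ll, x0, args=(Y, V), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
    )
    converged = bool(res.success) and np.isfinite(res.fun)
    if converged:
        s1, s2 = np.exp(res.x[0]), np.exp(res.x[1])
        rho = np.tanh(res.x[2])
        psi = np.array([[s1**2, rho * s1 * s2], [rho * s1 * s2, s2**2]])
    else:
        flags.append("bivariate REML non-convergence: independent univariate fallback, "
                     "correlation unavailable")
        logger.warning("bivariate REML failed; falling back to univariate pooling")
        sn_pool = reml_pool(Y[:, 0], [V[i][0, 0] for i in range(len(V))])
        sp_pool = reml_pool(Y[:, 1], [V[i][1, 1] for i in range(len(V))])
        psi = np.array([[sn_pool.tau2, np.nan], [np.nan, sp_pool.tau2]])
        mu = np.array([sn_pool.estimate, sp_pool.estimate])
        cov_mu = np.diag([sn_pool.se**2, sp_pool.se**2])
        return BivariateResult(mu=mu, cov_mu=cov_mu, psi=psi, k=len(tables),
                               converged=False, flags=flags)
    Sinv_sum = np.zeros((2, 2))
    Sinv_y_sum = np.zeros(2)
    for i in range(len(Y)):
        Sinv = np.linalg.inv(V[i] + psi)
        Sinv_sum += Sinv
        Sinv_y_sum += Sinv @ Y[i]
    mu = np.linalg.solve(Sinv_sum, Sinv_y_sum)
    cov_mu = np.linalg.inv(Sinv_sum)
    return BivariateResult(
        mu=mu, cov_mu=cov_mu, psi=psi, k=len(tables), converged=True, flags=flags
    )
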