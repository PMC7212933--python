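"""Per-study discrimination and calibration metrics.

Each validation cohort is reduced to complete cases and summarised by:

* C-statistic (AUROC, Mann-Whitney formulation with half credit for ties),
* E/O ratio (sum of predicted risks over observed event count),
* calibration slope and intercept (ML logistic fit of outcome on the
  linear predictor),
* calibration-in-the-large intercept (logistic fit with the LP as a fixed
  offset, i.e. slope held at 1),
* a 2x2 confusion table at the low-risk threshold,
* calibration plot data (quantile bins of predicted risk).

Standard errors come from a nonparametric bootstrap over episodes (the
primary route) or from closed-form/model-based approximations (fast route
used inside large simulation studies).  The C-statistic is pooled on the
logit scale and E/O on the log scale, so the SEs stored for pooling live on
those scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit, logit
from scipy.stats import rankdata

from .model import COVARIATE_COLUMNS, ModelSpec, linear_predictor, predicted_risk

logger = logging.getLogger(__name__)

__all__ = [
    "StudyPerformance",
    "CalibrationPlotData",
    "MetricUndefinedError",
    "complete_cases",
    "c_statistic",
    "e_o_ratio",
    "calibration_slope_intercept",
    "calibration_in_the_large",
    "bootstrap_se",
    "confusion_at_threshold",
    "calibration_plot_data",
    "validate_study",
]


class MetricUndefinedError(ValueError):
    """A metric's preconditions are not met (e.g. single-class outcomes)."""


@dataclass
class CalibrationPlotData:
    """Binned predicted-vs-observed data behind a calibration plot."""

    bin_edges: np.ndarray
    mean_predicted: np.ndarray
    observed_proportion: np.ndarray
    bin_counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(len(self.mean_predicted)),
                "mean_pred": self.mean_predicted,
                "obs_prop": self.observed_proportion,
                "n": self.bin_counts,
            }
        )


@dataclass
class StudyPerformance:
    """Validation metrics for one study (complete cases only).

    SEs are on the pooling scale: ``c_se`` on the logit scale, ``e_o_se`` on
    the log scale, slope/intercept on the identity scale.
    """

    study_id: str
    n_episodes: int
    n_events: int
    c_statistic: float | None = None
    c_se: float | None = None
    c_ci: tuple[float, float] | None = None
    calib_slope: float | None = None
    calib_slope_se: float | None = None
    calib_intercept: float | None = None
    calib_intercept_se: float | None = None
    citl_intercept: float | None = None
    citl_intercept_se: float | None = None
    e_o_ratio: float | None = None
    e_o_se: float | None = None
    e_o_ci: tuple[float, float] | None = None
    confusion: dict | None = None
    bootstrap_draws: int = 0
    flags: list[str] = field(default_factory=list)

    @property
    def usable(self) -> bool:
        return self.n_episodes > 0 and not ("unusable" in self.flags)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        d["c_ci"] = list(self.c_ci) if self.c_ci else None
        d["e_o_ci"] = list(self.e_o_ci) if self.e_o_ci else None
        return d


def complete_cases(cohort: pd.DataFrame) -> pd.DataFrame:
    """Rows with every model covariate and the MDI outcome present.

    Logs the number of rows dropped per field; an empty result is the
    caller's signal to flag the study unusable rather than abort.
    """
    cols = list(COVARIATE_COLUMNS) + ["mdi"]
    mask = pd.Series(True, index=cohort.index)
    for col in cols:
        missing = cohort[col].isna()
        if missing.any():
            logger.info("dropping %d row(s) with missing %s", int(missing.sum()), col)
        mask &= ~missing
    return cohort.loc[mask]


def _check_binary(outcomes: np.ndarray) -> np.ndarray:
    outcomes = np.asarray(outcomes, dtype=float)
    if not np.isin(outcomes, (0.0, 1.0)).all():
        raise ValueError("outcomes must be binary 0/1")
    return outcomes


def c_statistic(risks: Sequence[float], outcomes: Sequence[int]) -> float:
    """Concordance probability (AUROC), ties counted half.

    Equals the proportion of (event, non-event) pairs in which the event
    carries the strictly higher predicted risk, plus half the tied pairs —
    the Mann-Whitney formulation.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = _check_binary(outcomes)
    n1 = int(outcomes.sum())
    n0 = len(outcomes) - n1
    if n1 == 0 or n0 == 0:
        raise MetricUndefinedError("C-statistic needs both an event and a non-event")
    ranks = rankdata(risks)  # midranks handle ties with half credit
    rank_sum_events = ranks[outcomes == 1].sum()
    return float((rank_sum_events - n1 * (n1 + 1) / 2) / (n1 * n0))


def e_o_ratio(risks: Sequence[float], outcomes: Sequence[int]) -> float:
    """Expected/observed event ratio: sum(predicted risks) / sum(outcomes).

    The ideal value is 1; above 1 the model systematically overestimates
    risk.  Undefined when no events were observed.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = _check_binary(outcomes)
    observed = outcomes.sum()
    if observed == 0:
        raise MetricUndefinedError("E/O undefined with zero observed events")
    return float(risks.sum() / observed)


def _logit_fit(endog, exog, offset=None):
    model = sm.GLM(endog, exog, family=sm.families.Binomial(), offset=offset)
    return model.fit(maxiter=200, tol=1e-10)


def calibration_slope_intercept(
    lps: Sequence[float], outcomes: Sequence[int]
) -> tuple[float, float, float, float, bool]:
    """ML logistic refit logit P(y=1) = a + b*LP.

    Returns ``(slope, slope_se, intercept, intercept_se, converged)``.  A
    slope of 1 with intercept 0 indicates perfect calibration.  Raises
    :class:`MetricUndefinedError` on constant LP or single-class outcomes;
    separation yields a flagged (non-converged) extreme estimate.
    """
    lps = np.asarray(lps, dtype=float)
    outcomes = _check_binary(outcomes)
    if outcomes.min() == outcomes.max():
        raise MetricUndefinedError("calibration fit needs both outcome classes")
    if np.ptp(lps) == 0:
        raise MetricUndefinedError("calibration slope undefined for constant LP")
    exog = sm.add_constant(lps)
    res = _logit_fit(outcomes, exog)
    converged = bool(res.converged) and np.all(np.isfinite(res.bse))
    if not converged:
        logger.warning("calibration refit did not converge (possible separation)")
    return (
        float(res.params[1]),
        float(res.bse[1]),
        float(res.params[0]),
        float(res.bse[0]),
        converged,
    )


def calibration_in_the_large(
    lps: Sequence[float], outcomes: Sequence[int]
) -> tuple[float, float]:
    """Intercept update with slope fixed at 1: fit logit P = a + offset(LP).

    Returns ``(a, se)``; ``a`` is the amount the model intercept must shift
    to match average observed risk in this cohort.
    """
    lps = np.asarray(lps, dtype=float)
    outcomes = _check_binary(outcomes)
    if outcomes.min() == outcomes.max():
        raise MetricUndefinedError("intercept update needs both outcome classes")
    exog = np.ones((len(lps), 1))
    res = _logit_fit(outcomes, exog, offset=lps)
    return float(res.params[0]), float(res.bse[0])


def bootstrap_se(
    metric: Callable[[pd.DataFrame], float],
    cohort: pd.DataFrame,
    draws: int = 2000,
    seed: int | np.random.Generator = 0,
) -> dict:
    """Nonparametric bootstrap SE and percentile CI of a cohort metric.

    Episodes are resampled with replacement ``draws`` times and the metric
    recomputed on each resample.  Draws on which the metric is undefined are
    dropped and counted; more than 50% undefined draws marks the SE unstable.

    Returns a dict with keys ``se``, ``ci`` (2.5/97.5 percentiles),
    ``n_undefined``, ``n_used``, ``unstable``.
    """
    rng = np.random.default_rng(seed)
    n = len(cohort)
    values = []
    n_undefined = 0
    for _ in range(draws):
        idx = rng.integers(0, n, size=n)
        sample = cohort.iloc[idx]
        try:
            values.append(metric(sample))
        except (MetricUndefinedError, ValueError):
            n_undefined += 1
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    unstable = len(values) < draws / 2
    if unstable:
        logger.warning(
            "bootstrap unstable: %d/%d draws undefined", n_undefined, draws
        )
    if len(values) == 0:
        return {"se": np.nan, "ci": (np.nan, np.nan), "n_undefined": n_undefined,
                "n_used": 0, "unstable": True}
    return {
        "se": float(values.std(ddof=1)) if len(values) > 1 else 0.0,
        "ci": (float(np.percentile(values, 2.5)), float(np.percentile(values, 97.5))),
        "n_undefined": n_undefined,
        "n_used": int(len(values)),
        "unstable": unstable,
    }


def confusion_at_threshold(
    risks: Sequence[float],
    outcomes: Sequence[int],
    threshold: float = 0.10,
) -> dict:
    """2x2 counts and Sn/Sp when calling risk > threshold "high risk".

    An episode is low-risk iff its predicted risk is <= the threshold
    (boundary inclusive).  A positive (high-risk) call on an event is a true
    positive.  Rates with zero denominators come back as NaN with a flag;
    the counts are always returned.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = _check_binary(outcomes)
    high = risks > threshold
    tp = int(np.sum(high & (outcomes == 1)))
    fn = int(np.sum(~high & (outcomes == 1)))
    tn = int(np.sum(~high & (outcomes == 0)))
    fp = int(np.sum(high & (outcomes == 0)))
    n = len(outcomes)
    flags = []
    if tp + fn == 0:
        sn = np.nan
        flags.append("sensitivity undefined (no events)")
    else:
        sn = tp / (tp + fn)
    if tn + fp == 0:
        sp = np.nan
        flags.append("specificity undefined (no non-events)")
    else:
        sp = tn / (tn + fp)
    return {
        "TP": tp, "FN": fn, "TN": tn, "FP": fp,
        "sensitivity": sn, "specificity": sp,
        "low_risk_fraction": (fn + tn) / n if n else np.nan,
        "threshold": threshold,
        "flags": flags,
    }


def calibration_plot_data(
    risks: Sequence[float],
    outcomes: Sequence[int],
    bins: int = 10,
) -> CalibrationPlotData:
    """Quantile-binned predicted vs observed proportions.

    Equal-count bins on the predicted-risk axis; heavy ties collapse bins
    (logged).  Requires at least as many episodes as requested bins.
    """
    risks = np.asarray(risks, dtype=float)
    outcomes = _check_binary(outcomes)
    if len(risks) < bins:
        raise ValueError(f"need at least {bins} episodes for {bins} bins")
    quantiles = np.quantile(risks, np.linspace(0, 1, bins + 1))
    edges = np.unique(quantiles)
    if len(edges) - 1 < bins:
        logger.info("ties collapsed %d bins to %d", bins, max(len(edges) - 1, 1))
    if len(edges) == 1:  # constant risks -> single bin
        return CalibrationPlotData(
            bin_edges=np.array([edges[0], edges[0]]),
            mean_predicted=np.array([risks.mean()]),
            observed_proportion=np.array([outcomes.mean()]),
            bin_counts=np.array([len(risks)]),
        )
    which = np.clip(np.searchsorted(edges, risks, side="right") - 1, 0, len(edges) - 2)
    mean_pred, obs_prop, counts = [], [], []
    for b in range(len(edges) - 1):
        mask = which == b
        if not mask.any():
            continue
        mean_pred.append(risks[mask].mean())
        obs_prop.append(outcomes[mask].mean())
        counts.append(int(mask.sum()))
    return CalibrationPlotData(
        bin_edges=edges,
        mean_predicted=np.array(mean_pred),
        observed_proportion=np.array(obs_prop),
        bin_counts=np.array(counts),
    )


def _analytic_ln_eo_se(risks: np.ndarray, outcomes: np.ndarray) -> float:
    # delta method on ln(E) - ln(O) treating episodes as iid
    n = len(risks)
    e_mean, o_mean = risks.mean(), outcomes.mean()
    var = np.var(risks / e_mean - outcomes / o_mean, ddof=1) / n
    return float(np.sqrt(max(var, 0.0)))


def hanley_mcneil_se(auc: float, n_events: int, n_nonevents: int) -> float:
    """Closed-form approximation to the SE of the C-statistic."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc**2 / (1 + auc)
    var = (
        auc * (1 - auc)
        + (n_events - 1) * (q1 - auc**2)
        + (n_nonevents - 1) * (q2 - auc**2)
    ) / (n_events * n_nonevents)
    return float(np.sqrt(max(var, 0.0)))


def validate_study(
    study_id: str,
    cohort: pd.DataFrame,
    model: ModelSpec,
    *,
    threshold: float = 0.10,
    bootstrap_draws: int = 2000,
    seed: int | np.random.Generator = 0,
    se_method: str = "bootstrap",
) -> StudyPerformance:
    """Full per-study validation of ``model`` on one cohort.

    ``se_method="bootstrap"`` (default) uses the resampling SEs for the
    C-statistic and E/O ratio; ``"analytic"`` swaps in the Hanley-McNeil and
    delta-method approximations, which large simulation studies use to keep
    runtime manageable.  Calibration slope/intercept SEs are always the
    model-based ones from the logistic refit.
    """
    cc = complete_cases(cohort)
    perf = StudyPerformance(study_id=study_id, n_episodes=len(cc),
                            n_events=int(cc["mdi"].sum()) if len(cc) else 0)
    if len(cc) == 0:
        perf.flags.append("unusable")
        logger.warning("study %s has no complete cases; flagged unusable", study_id)
        return perf
    lp = linear_predictor(model, cc)
    risks = expit(lp.to_numpy())
    outcomes = cc["mdi"].to_numpy(dtype=float)

    perf.confusion = confusion_at_threshold(risks, outcomes, threshold)

    # discrimination
    try:
        perf.c_statistic = c_statistic(risks, outcomes)
    except MetricUndefinedError:
        perf.flags.append("c_statistic undefined (single-class outcomes)")
    # calibration-in-the-large
    try:
        perf.e_o_ratio = e_o_ratio(risks, outcomes)
    except MetricUndefinedError:
        perf.flags.append("e_o undefined (zero events)")
    try:
        (
            perf.calib_slope,
            perf.calib_slope_se,
            perf.calib_intercept,
            perf.calib_intercept_se,
            converged,
        ) = calibration_slope_intercept(lp.to_numpy(), outcomes)
        if not converged:
            perf.flags.append("calibration refit non-convergence")
        perf.citl_intercept, perf.citl_intercept_se = calibration_in_the_large(
            lp.to_numpy(), outcomes
        )
    except MetricUndefinedError as exc:
        perf.flags.append(f"calibration fit undefined: {exc}")

    rng = np.random.default_rng(seed)
    if se_method == "bootstrap":
        def _c(sample: pd.DataFrame) -> float:
            r = predicted_risk(model, sample).to_numpy()
            c = c_statistic(r, sample["mdi"].to_numpy(dtype=float))
            return logit(np.clip(c, 1e-12, 1 - 1e-12))

        def _ln_eo(sample: pd.DataFrame) -> float:
            r = predicted_risk(model, sample).to_numpy()
            return np.log(e_o_ratio(r, sample["mdi"].to_numpy(dtype=float)))

        if perf.c_statistic is not None:
            boot = bootstrap_se(_c, cc, draws=bootstrap_draws, seed=rng)
            perf.c_se = boot["se"]
            perf.c_ci = tuple(expit(np.asarray(boot["ci"])))
            if boot["unstable"]:
                perf.flags.append("unstable c bootstrap SE")
        if perf.e_o_ratio is not None:
            boot = bootstrap_se(_ln_eo, cc, draws=bootstrap_draws, seed=rng)
            perf.e_o_se = boot["se"]
            perf.e_o_ci = tuple(np.exp(np.asarray(boot["ci"])))
            if boot["unstable"]:
                perf.flags.append("unstable e/o bootstrap SE")
        perf.bootstrap_draws = bootstrap_draws
    elif se_method == "analytic":
        if perf.c_statistic is not None:
            n1 = perf.n_events
            n0 = perf.n_episodes - n1
            se_c = hanley_mcneil_se(perf.c_statistic, n1, n0)
            c = np.clip(perf.c_statistic, 1e-6, 1 - 1e-6)
            # delta method to the logit scale
            perf.c_se = se_c / (c * (1 - c))
            perf.c_ci = (
                float(expit(logit(c) - 1.96 * perf.c_se)),
                float(expit(logit(c) + 1.96 * perf.c_se)),
            )
        if perf.e_o_ratio is not None:
            perf.e_o_se = _analytic_ln_eo_se(risks, outcomes)
            ln_eo = np.log(perf.e_o_ratio)
            perf.e_o_ci = (
                float(np.exp(ln_eo - 1.96 * perf.e_o_se)),
                float(np.exp(ln_eo + 1.96 * perf.e_o_se)),
            )
    else:
        raise ValueError(f"unknown se_method {se_method!r}")
    return perf
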