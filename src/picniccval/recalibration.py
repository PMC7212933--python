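"""Recalibration strategies for an externally validated logistic model.

Four standard updates are implemented, mirroring common practice when a
prediction model transfers poorly to new settings:

A. replace the intercept with the random-effects (REML) pooled mean of
   study-level intercepts from the derivation data (supplied as
   configuration, since derivation episode data are not distributed);
B. re-estimate the intercept per validation study so the mean predicted
   risk equals the observed MDI proportion (solved exactly by bracketed
   root finding; by construction the study's E/O becomes 1);
C. regress per-study intercept updates on the study MDI proportion by
   random-effects meta-regression and give each study the interpolated
   intercept at its own proportion;
D. multiply every beta coefficient by the study-specific calibration slope
   and share a pooled intercept across studies (after which the refitted
   calibration slope is 1 per study by construction, and the C-statistic is
   unchanged whenever the estimated slope is positive).

Strategies A-C never touch the beta coefficients.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit, logit

from .model import ModelSpec, linear_predictor
from .pooling import meta_regress, reml_pool
from .validation import complete_cases

logger = logging.getLogger(__name__)

__all__ = [
    "RecalibratedModel",
    "strategy_a",
    "strategy_b",
    "strategy_c",
    "strategy_d",
    "reestimate_coefficients",
]


@dataclass
class RecalibratedModel:
    """Outcome of one recalibration strategy.

    ``specs`` maps study id to the updated :class:`ModelSpec` (a single
    ``"global"`` entry for strategy A).  ``intercepts`` holds the per-study
    (or global) intercepts, ``slope_multipliers`` the per-study beta
    multipliers for strategy D.
    """

    strategy: str
    scope: str
    specs: dict[str, ModelSpec]
    intercepts: dict[str, float]
    slope_multipliers: dict[str, float] | None = None
    notes: list[str] = field(default_factory=list)

    def spec_for(self, study_id: str) -> ModelSpec:
        return self.specs.get(study_id, self.specs.get("global"))

    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "scope": self.scope,
            "intercepts": self.intercepts,
            "slope_multipliers": self.slope_multipliers,
            "notes": self.notes,
        }


def strategy_a(model: ModelSpec, derivation_intercepts, variances) -> RecalibratedModel:
    """Weighted-average intercept from derivation study-level intercepts.

    Pools the supplied intercepts by REML random-effects meta-analysis
    (treating them as draws from a normal distribution of study baselines)
    and installs the pooled mean as a single global intercept.  Betas are
    untouched.
    """
    y = np.asarray(derivation_intercepts, dtype=float)
    notes = []
    if len(y) == 1:
        pooled_value = float(y[0])
        notes.append("single derivation intercept supplied; used directly")
        logger.warning("strategy A: only one derivation intercept; no pooling")
    else:
        pooled = reml_pool(y, variances, metric="derivation intercept")
        pooled_value = pooled.estimate
    spec = model.with_intercept(pooled_value, name=f"{model.name}|A")
    return RecalibratedModel(
        strategy="A",
        scope="global",
        specs={"global": spec},
        intercepts={"global": pooled_value},
        notes=notes,
    )


def _lp0(model: ModelSpec, cohort: pd.DataFrame) -> np.ndarray:
    return linear_predictor(model, cohort, include_intercept=False).to_numpy()


def solve_prevalence_intercept(
    lp0: np.ndarray, target_rate: float, tol: float = 1e-10
) -> float:
    """Intercept a such that mean(expit(a + lp0)) equals ``target_rate``.

    The mean risk is strictly increasing in a, so a bracketed Brent solve
    converges to the unique root.
    """
    if not 0 < target_rate < 1:
        raise ValueError("target rate must be strictly inside (0, 1)")

    def gap(a):
        return expit(a + lp0).mean() - target_rate

    lo, hi = -40.0, 40.0
    return float(optimize.brentq(gap, lo, hi, xtol=tol))


def strategy_b(
    model: ModelSpec,
    cohorts: dict[str, pd.DataFrame],
    method: str = "root",
) -> RecalibratedModel:
    """Per-study intercept matched to the observed MDI proportion.

    ``method="root"`` (default) solves the prevalence-matching equation
    exactly, which forces the study's E/O ratio to 1.  ``method="shortcut"``
    uses the cruder logit(rate) - mean(LP0) approximation, kept for
    comparison.  Studies with no events or all events have no finite
    solution and are flagged.
    """
    specs, intercepts, notes = {}, {}, []
    for study_id, cohort in cohorts.items():
        cc = complete_cases(cohort)
        events = cc["mdi"].sum() if len(cc) else 0
        if len(cc) == 0 or events == 0 or events == len(cc):
            notes.append(f"{study_id}: no finite intercept (degenerate outcome)")
            logger.warning("strategy B: study %s flagged (degenerate outcome)", study_id)
            continue
        lp0 = _lp0(model, cc)
        rate = events / len(cc)
        if method == "root":
            a = solve_prevalence_intercept(lp0, rate)
        elif method == "shortcut":
            a = float(logit(rate) - lp0.mean())
        else:
            raise ValueError(f"unknown method {method!r}")
        intercepts[study_id] = a
        specs[study_id] = model.with_intercept(a, name=f"{model.name}|B[{study_id}]")
    return RecalibratedModel(
        strategy="B", scope="per-study", specs=specs, intercepts=intercepts,
        notes=notes,
    )


def _intercept_updates(model: ModelSpec, cohorts: dict[str, pd.DataFrame]):
    """Per-study absolute intercept updates from the offset-logistic fit
    (slope held at 1), with variances and MDI proportions."""
    from .validation import MetricUndefinedError, calibration_in_the_large

    rows = []
    for study_id, cohort in cohorts.items():
        cc = complete_cases(cohort)
        if len(cc) == 0:
            continue
        lp = linear_predictor(model, cc).to_numpy()
        y = cc["mdi"].to_numpy(dtype=float)
        try:
            a, se = calibration_in_the_large(lp, y)
        except MetricUndefinedError:
            logger.warning("intercept update undefined for study %s", study_id)
            continue
        rows.append(
            {
                "study_id": study_id,
                "intercept": model.intercept + a,
                "variance": se**2,
                "proportion": y.mean(),
            }
        )
    return pd.DataFrame(rows)


def strategy_c(model: ModelSpec, cohorts: dict[str, pd.DataFrame]) -> RecalibratedModel:
    """Intercepts interpolated from a meta-regression on MDI proportion.

    Each study's re-estimated intercept (offset-logistic update, slope held
    at 1) is regressed on its MDI proportion across studies; the study then
    receives the fitted value at its own proportion.  Requires >= 3 studies.
    """
    updates = _intercept_updates(model, cohorts)
    if len(updates) < 3:
        raise ValueError(
            "strategy C needs >= 3 studies with estimable intercepts; "
            "use strategy B for fewer"
        )
    regression = meta_regress(
        updates["intercept"], updates["variance"], updates["proportion"]
    )
    specs, intercepts = {}, {}
    for _, row in updates.iterrows():
        a = regression.interpolate(row["proportion"])
        intercepts[row["study_id"]] = a
        specs[row["study_id"]] = model.with_intercept(
            a, name=f"{model.name}|C[{row['study_id']}]"
        )
    return RecalibratedModel(
        strategy="C", scope="per-study", specs=specs, intercepts=intercepts,
        notes=list(regression.flags),
    )


def _joint_calibration_fit(lp: np.ndarray, y: np.ndarray):
    exog = sm.add_constant(lp)
    res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(maxiter=200, tol=1e-10)
    return res.params, res.cov_params()


def strategy_d(
    model: ModelSpec,
    cohorts: dict[str, pd.DataFrame],
    *,
    intercept_pooling: str = "reml",
    slope_source: str = "per-study",
) -> RecalibratedModel:
    """Beta coefficients rescaled by the observed calibration slope.

    For each study the joint logistic refit logit P = a_s + b_s*LP gives the
    calibration slope b_s; the study's betas are multiplied by b_s.  The
    intercept appropriate to the rescaled betas, c_s = a_s + b_s*alpha_0, is
    pooled across studies (REML by default, ``intercept_pooling="unweighted"``
    for a plain mean) and shared by every study.  Refitting the calibration
    slope on the recalibrated predictor returns 1 per study by construction;
    a negative b_s inverts the risk ranking and is warned about.
    ``slope_source="pooled"`` applies the REML-pooled slope uniformly.
    """
    per_study = []
    for study_id, cohort in cohorts.items():
        cc = complete_cases(cohort)
        if len(cc) == 0 or cc["mdi"].nunique() < 2:
            logger.warning("strategy D: study %s skipped (degenerate outcome)", study_id)
            continue
        lp = linear_predictor(model, cc).to_numpy()
        y = cc["mdi"].to_numpy(dtype=float)
        params, cov = _joint_calibration_fit(lp, y)
        a_s, b_s = float(params[0]), float(params[1])
        # variance of c_s = a_s + b_s * alpha0 via the fit covariance
        alpha0 = model.intercept
        var_c = float(cov[0, 0] + alpha0**2 * cov[1, 1] + 2 * alpha0 * cov[0, 1])
        per_study.append(
            {"study_id": study_id, "slope": b_s,
             "intercept_scaled": a_s + b_s * alpha0, "variance": max(var_c, 1e-12)}
        )
    if len(per_study) < 2:
        raise ValueError("strategy D requires calibration slopes from >= 2 studies")
    table = pd.DataFrame(per_study)
    notes = []
    negative = table.loc[table["slope"] <= 0, "study_id"].tolist()
    if negative:
        msg = (f"negative calibration slope in {negative}: risk ranking inverts, "
               "discrimination is not preserved")
        notes.append(msg)
        warnings.warn(msg, stacklevel=2)
    if intercept_pooling == "reml":
        shared = reml_pool(
            table["intercept_scaled"], table["variance"], metric="shared intercept"
        ).estimate
    elif intercept_pooling == "unweighted":
        shared = float(table["intercept_scaled"].mean())
    else:
        raise ValueError(f"unknown intercept_pooling {intercept_pooling!r}")
    if slope_source == "pooled":
        pooled_slope = reml_pool(
            table["slope"],
            np.maximum(table["variance"], 1e-12),
            metric="calibration slope",
        ).estimate
        table["slope"] = pooled_slope
        notes.append("pooled calibration slope applied uniformly")
    elif slope_source != "per-study":
        raise ValueError(f"unknown slope_source {slope_source!r}")
    specs, multipliers, intercepts = {}, {}, {}
    for _, row in table.iterrows():
        sid = row["study_id"]
        spec = model.scale_betas(row["slope"], name=f"{model.name}|D[{sid}]")
        specs[sid] = spec.with_intercept(shared, name=spec.name)
        multipliers[sid] = float(row["slope"])
        intercepts[sid] = float(shared)
    return RecalibratedModel(
        strategy="D", scope="per-study", specs=specs, intercepts=intercepts,
        slope_multipliers=multipliers, notes=notes,
    )


_SCALAR_TERMS = [
    ("Temperature (per °C from 37)", "temp_coeff"),
    ("Clinical impression of 'Severely unwell'", "unwell_coeff"),
    ("Haemoglobin (per g/dL)", "hb_coeff"),
    ("Natural log (total white cell count)", "ln_wcc_coeff"),
    ("Natural log (absolute monocyte count)", "ln_amc_coeff"),
]


def reestimate_coefficients(
    cohorts: dict[str, pd.DataFrame], model: ModelSpec
) -> pd.DataFrame:
    """Refit the full covariate set on the pooled validation episodes.

    Stacks complete cases from every study and fits a maximum-likelihood
    logistic regression of MDI on the model's covariates (tumour dummies
    against the model's reference category, temperature above 37, severely
    unwell, haemoglobin, ln WCC, ln AMC).  Returns a side-by-side table of
    derivation vs re-estimated coefficients with SEs and per-category
    episode counts.  Empty categories are reported with missing estimates;
    separated categories (e.g. 2-episode groups with uniform outcomes) are
    reported as-is with their characteristically huge SEs.
    """
    stacked = pd.concat(
        [complete_cases(df) for df in cohorts.values()], ignore_index=True
    )
    if stacked.empty:
        raise ValueError("no complete cases in any study")
    y = stacked["mdi"].to_numpy(dtype=float)
    ref = model.reference_tumour
    categories = [c for c in model.categories if c != ref]
    X = pd.DataFrame(index=stacked.index, dtype=float)
    for cat in categories:
        X[cat] = (stacked["tumour_type"] == cat).astype(float)
    X["Temperature (per °C from 37)"] = stacked["temperature"] - 37.0
    X["Clinical impression of 'Severely unwell'"] = stacked["severely_unwell"].astype(float)
    X["Haemoglobin (per g/dL)"] = stacked["haemoglobin"].astype(float)
    X["Natural log (total white cell count)"] = np.log(
        stacked["wcc"].replace(0, 0.005)
    )
    X["Natural log (absolute monocyte count)"] = np.log(
        stacked["amc"].replace(0, 0.005)
    )
    counts = stacked["tumour_type"].value_counts()
    empty = [c for c in categories if counts.get(c, 0) == 0]
    X = X.drop(columns=empty)
    exog = sm.add_constant(X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y, exog, family=sm.families.Binomial()).fit(
            maxiter=500, tol=1e-10
        )
    derivation = model.beta_vector()
    rows = []
    n_total = len(stacked)
    for cat in categories:
        row = {
            "item": cat,
            "derivation_beta": derivation[cat],
            "validation_beta": float(res.params[cat]) if cat in res.params else np.nan,
            "validation_se": float(res.bse[cat]) if cat in res.bse else np.nan,
            "episodes": int(counts.get(cat, 0)),
        }
        if cat in empty:
            row["flag"] = "category absent from validation data"
        elif row["validation_se"] > 50:
            row["flag"] = "separation: extreme estimate, huge SE"
        else:
            row["flag"] = ""
        rows.append(row)
    for label, attr in _SCALAR_TERMS:
        rows.append(
            {
                "item": label,
                "derivation_beta": getattr(model, attr),
                "validation_beta": float(res.params[label]),
                "validation_se": float(res.bse[label]),
                "episodes": n_total,
                "flag": "",
            }
        )
    table = pd.DataFrame(rows)
    table.attrs["intercept"] = float(res.params["const"])
    table.attrs["converged"] = bool(res.converged)
    return table
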