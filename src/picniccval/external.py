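"""Model/Results interface for multi-study external validation.

:class:`ExternalValidation` is constructed from episode-level data (one or
many studies) plus a :class:`~picniccval.model.ModelSpec`; its
:meth:`~ExternalValidation.fit` scores every episode, computes per-study
discrimination and calibration with bootstrap uncertainty, pools the
metrics by REML random-effects meta-analysis, and summarises clinical
utility at the low-risk threshold by bivariate meta-analysis.  The returned
:class:`ExternalValidationResults` carries the estimates, their
uncertainties and a ``summary()`` table, and exposes ``recalibrate()`` to
re-run the whole validation under any of the recalibration strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import ModelSpec, default_model_spec, load_episodes, validate_episodes
from .pooling import BivariateResult, PooledResult, bivariate_pool, reml_pool
from .recalibration import (
    RecalibratedModel,
    reestimate_coefficients,
    strategy_a,
    strategy_b,
    strategy_c,
    strategy_d,
)
from .validation import StudyPerformance, validate_study

logger = logging.getLogger(__name__)

__all__ = ["ExternalValidation", "ExternalValidationResults"]

#: metric -> (analysis scale, StudyPerformance estimate/SE attributes)
_POOLABLE = {
    "c_statistic": ("logit", "c_statistic", "c_se"),
    "e_o_ratio": ("log", "e_o_ratio", "e_o_se"),
    "calib_slope": ("identity", "calib_slope", "calib_slope_se"),
    "calib_intercept": ("identity", "calib_intercept", "calib_intercept_se"),
}


class ExternalValidation:
    """External validation of a logistic risk model on multi-study data.

    Parameters
    ----------
    cohorts : mapping of study id to episode table
        Episode-level data; use :meth:`from_dataframe` for a single stacked
        table with a ``study_id`` column, or :meth:`from_csvs` for files.
    model : ModelSpec, optional
        The model under validation; defaults to the packaged PICNICC spec.
    threshold : float
        Predicted-risk boundary of the low-risk class (inclusive).
    """

    def __init__(
        self,
        cohorts: dict[str, pd.DataFrame],
        model: ModelSpec | None = None,
        threshold: float = 0.10,
    ) -> None:
        self.model = model or default_model_spec()
        self.threshold = threshold
        self.cohorts = {
            str(sid): validate_episodes(df) for sid, df in cohorts.items()
        }

    @classmethod
    def from_dataframe(
        cls, data: pd.DataFrame, model: ModelSpec | None = None, **kwargs
    ) -> "ExternalValidation":
        cohorts = {str(sid): df for sid, df in data.groupby("study_id", sort=False)}
        return cls(cohorts, model=model, **kwargs)

    @classmethod
    def from_csvs(
        cls, paths, model: ModelSpec | None = None, **kwargs
    ) -> "ExternalValidation":
        frames = [load_episodes(p) for p in map(Path, paths)]
        return cls.from_dataframe(pd.concat(frames, ignore_index=True),
                                  model=model, **kwargs)

    def total_events(self) -> int:
        return int(sum(df["mdi"].sum() for df in self.cohorts.values()))

    def fit(
        self,
        bootstrap_draws: int = 2000,
        seed: int = 0,
        se_method: str = "bootstrap",
        per_study_models: dict[str, ModelSpec] | None = None,
        label: str = "original",
    ) -> "ExternalValidationResults":
        """Run the full validation and pool across studies.

        A single ``seed`` spawns an independent child seed per study so each
        study's bootstrap is reproducible in isolation.  ``per_study_models``
        (used by :meth:`ExternalValidationResults.recalibrate`) scores each
        study with its own updated spec.
        """
        root = np.random.SeedSequence(seed)
        children = root.spawn(len(self.cohorts))
        performances: dict[str, StudyPerformance] = {}
        exclusions: dict[str, str] = {}
        for (study_id, cohort), child in zip(self.cohorts.items(), children):
            spec = (per_study_models or {}).get(study_id, self.model)
            if per_study_models is not None and study_id not in per_study_models:
                exclusions[study_id] = "no recalibrated model for this study"
                continue
            perf = validate_study(
                study_id, cohort, spec,
                threshold=self.threshold,
                bootstrap_draws=bootstrap_draws,
                seed=np.random.default_rng(child),
                se_method=se_method,
            )
            if perf.usable:
                performances[study_id] = perf
            else:
                exclusions[study_id] = "; ".join(perf.flags) or "unusable"
        if not performances:
            raise ValueError("no usable studies: validation cannot proceed")
        pooled = _pool_metrics(performances)
        bivariate, bivariate_flags = _pool_bivariate(performances)
        return ExternalValidationResults(
            validation=self,
            label=label,
            performances=performances,
            exclusions=exclusions,
            pooled=pooled,
            bivariate=bivariate,
            bivariate_flags=bivariate_flags,
            seed=seed,
            bootstrap_draws=bootstrap_draws,
            se_method=se_method,
            per_study_models=per_study_models,
        )


def _pool_metrics(
    performances: dict[str, StudyPerformance]
) -> dict[str, PooledResult]:
    pooled: dict[str, PooledResult] = {}
    from .pooling import SCALE_TRANSFORMS

    for metric, (scale, est_attr, se_attr) in _POOLABLE.items():
        ys, vs = [], []
        fwd = SCALE_TRANSFORMS[scale][0]
        for perf in performances.values():
            est = getattr(perf, est_attr)
            se = getattr(perf, se_attr)
            if est is None or se is None or not np.isfinite(se) or se <= 0:
                continue
            if metric == "c_statistic":
                est = float(fwd(np.clip(est, 1e-12, 1 - 1e-12)))
            else:
                est = float(fwd(est)) if scale != "identity" else float(est)
            ys.append(est)
            vs.append(se**2)
        if len(ys) >= 2:
            pooled[metric] = reml_pool(ys, vs, metric=metric, scale=scale)
        else:
            logger.warning("metric %s pooled from <2 studies; skipped", metric)
    return pooled


def _pool_bivariate(performances) -> tuple[BivariateResult | None, list[str]]:
    tables = [
        p.confusion for p in performances.values()
        if p.confusion is not None and p.n_events > 0
        and p.n_episodes - p.n_events > 0
    ]
    if len(tables) < 3:
        return None, ["bivariate pooling skipped (<3 usable studies)"]
    try:
        return bivariate_pool(tables), []
    except Exception as exc:  # noqa: BLE001 - never abort the run
        logger.warning("bivariate pooling failed: %s", exc)
        return None, [f"bivariate pooling failed: {exc}"]


@dataclass
class ExternalValidationResults:
    """Fitted external-validation results.

    Attributes
    ----------
    performances : dict
        Per-study :class:`~picniccval.validation.StudyPerformance`.
    pooled : dict
        Metric name -> :class:`~picniccval.pooling.PooledResult` (C-statistic
        pooled on the logit scale, E/O on the log scale, calibration
        slope/intercept on the identity scale).
    bivariate : BivariateResult or None
        Joint pooled sensitivity/specificity at the low-risk threshold.
    """

    validation: ExternalValidation
    label: str
    performances: dict[str, StudyPerformance]
    exclusions: dict[str, str]
    pooled: dict[str, PooledResult]
    bivariate: BivariateResult | None
    bivariate_flags: list[str] = field(default_factory=list)
    seed: int = 0
    bootstrap_draws: int = 2000
    se_method: str = "bootstrap"
    per_study_models: dict[str, ModelSpec] | None = None
    recalibration: RecalibratedModel | None = None

    # ---------------------------------------------------------------- views
    def performance_frame(self) -> pd.DataFrame:
        rows = []
        for sid, p in self.performances.items():
            conf = p.confusion or {}
            rows.append(
                {
                    "study_id": sid,
                    "n": p.n_episodes,
                    "events": p.n_events,
                    "c_statistic": p.c_statistic,
                    "c_se_logit": p.c_se,
                    "e_o_ratio": p.e_o_ratio,
                    "e_o_se_log": p.e_o_se,
                    "calib_slope": p.calib_slope,
                    "calib_slope_se": p.calib_slope_se,
                    "calib_intercept": p.calib_intercept,
                    "citl_intercept": p.citl_intercept,
                    "sensitivity": conf.get("sensitivity"),
                    "specificity": conf.get("specificity"),
                    "low_risk_fraction": conf.get("low_risk_fraction"),
                    "flags": "; ".join(p.flags),
                }
            )
        return pd.DataFrame(rows).set_index("study_id")

    def forest_frame(self, metric: str) -> pd.DataFrame:
        """Per-study and pooled rows of one metric on its natural scale,
        ready for a forest plot."""
        if metric not in self.pooled:
            raise KeyError(f"metric {metric!r} was not pooled")
        pooled = self.pooled[metric]
        from .pooling import SCALE_TRANSFORMS

        back = SCALE_TRANSFORMS[pooled.scale][1]
        _, est_attr, se_attr = _POOLABLE[metric][0], *_POOLABLE[metric][1:]
        fwd = SCALE_TRANSFORMS[pooled.scale][0]
        w_total = 0.0
        rows = []
        for sid, p in self.performances.items():
            est = getattr(p, est_attr)
            se = getattr(p, se_attr)
            if est is None or se is None or not np.isfinite(se) or se <= 0:
                continue
            if metric == "c_statistic":
                y = float(fwd(np.clip(est, 1e-12, 1 - 1e-12)))
            elif pooled.scale == "identity":
                y = float(est)
            else:
                y = float(fwd(est))
            w = 1.0 / (se**2 + pooled.tau2)
            w_total += w
            rows.append(
                {
                    "row": sid, "kind": "study",
                    "estimate": float(back(y)),
                    "ci_low": float(back(y - 1.96 * se)),
                    "ci_high": float(back(y + 1.96 * se)),
                    "weight": w,
                }
            )
        for r in rows:
            r["weight"] = r["weight"] / w_total * 100
        rows.append(
            {
                "row": "pooled", "kind": "pooled",
                "estimate": pooled.natural_estimate,
                "ci_low": pooled.natural_ci[0],
                "ci_high": pooled.natural_ci[1],
                "weight": 100.0,
            }
        )
        if pooled.natural_prediction_interval is not None:
            lo, hi = pooled.natural_prediction_interval
            rows.append(
                {"row": "prediction interval", "kind": "pri",
                 "estimate": pooled.natural_estimate,
                 "ci_low": lo, "ci_high": hi, "weight": np.nan}
            )
        return pd.DataFrame(rows)

    def rocspace_frame(self) -> pd.DataFrame:
        """Per-study (Sn, Sp) crosshair data plus the pooled point and
        confidence/prediction ellipse parameters for ROC-space plots."""
        rows = []
        for sid, p in self.performances.items():
            c = p.confusion or {}
            if not c:
                continue
            rows.append(
                {"row": sid, "kind": "study",
                 "sensitivity": c.get("sensitivity"),
                 "specificity": c.get("specificity")}
            )
        if self.bivariate is not None:
            rows.append(
                {"row": "pooled", "kind": "pooled",
                 "sensitivity": self.bivariate.sensitivity,
                 "specificity": self.bivariate.specificity}
            )
            for region in ("confidence", "prediction"):
                ell = self.bivariate.ellipse(region)
                ell.update({"row": f"{region} ellipse", "kind": "ellipse"})
                rows.append(ell)
        return pd.DataFrame(rows)

    # ------------------------------------------------------------- actions
    def recalibrate(self, strategy: str, **kwargs) -> "ExternalValidationResults":
        """Apply one recalibration strategy and re-run the validation.

        ``strategy`` is one of ``"a"``/``"b"``/``"c"``/``"d"``; strategy A
        additionally needs ``derivation_intercepts`` and ``variances``.
        Returns a fresh results object scored with the updated spec(s).
        """
        v = self.validation
        strategy = strategy.lower()
        if strategy == "a":
            recal = strategy_a(v.model, **kwargs)
            per_study = {sid: recal.specs["global"] for sid in v.cohorts}
        elif strategy == "b":
            recal = strategy_b(v.model, v.cohorts, **kwargs)
            per_study = dict(recal.specs)
        elif strategy == "c":
            recal = strategy_c(v.model, v.cohorts, **kwargs)
            per_study = dict(recal.specs)
        elif strategy == "d":
            recal = strategy_d(v.model, v.cohorts, **kwargs)
            per_study = dict(recal.specs)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
        result = v.fit(
            bootstrap_draws=self.bootstrap_draws,
            seed=self.seed,
            se_method=self.se_method,
            per_study_models=per_study,
            label=f"strategy {strategy.upper()}",
        )
        result.recalibration = recal
        return result

    def reestimate_coefficients(self) -> pd.DataFrame:
        """Refit all beta coefficients on the stacked validation episodes."""
        return reestimate_coefficients(self.validation.cohorts, self.validation.model)

    # ------------------------------------------------------------- summary
    def summary(self) -> str:
        lines = [
            f"External validation summary [{self.label}]",
            f"model: {self.validation.model.name}",
            f"studies: {len(self.performances)} usable, "
            f"{len(self.exclusions)} excluded; "
            f"threshold {self.validation.threshold:.2f}; "
            f"SEs: {self.se_method} ({self.bootstrap_draws} draws)",
            "",
            "Pooled performance (random effects, REML):",
        ]
        fmt = "  {:<16} {:>7} {:>17} {:>8} {:>19}"
        lines.append(fmt.format("metric", "est", "95% CI", "tau2", "95% PrI"))
        for name, p in self.pooled.items():
            ci = "({:.2f}, {:.2f})".format(*p.natural_ci)
            pri = (
                "({:.2f}, {:.2f})".format(*p.natural_prediction_interval)
                if p.natural_prediction_interval is not None
                else "-"
            )
            lines.append(
                fmt.format(name, f"{p.natural_estimate:.2f}", ci,
                           f"{p.tau2:.2f}", pri)
            )
        if self.bivariate is not None:
            b = self.bivariate
            lines += [
                "",
                "Clinical utility at the low-risk threshold "
                "(bivariate pooling):",
                "  sensitivity {:.1%} (95% CI {:.1%} to {:.1%})".format(
                    b.sensitivity, *b.sensitivity_ci
                ),
                "  specificity {:.1%} (95% CI {:.1%} to {:.1%})".format(
                    b.specificity, *b.specificity_ci
                ),
            ]
        for sid, reason in self.exclusions.items():
            lines.append(f"  excluded {sid}: {reason}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "seed": self.seed,
            "bootstrap_draws": self.bootstrap_draws,
            "se_method": self.se_method,
            "threshold": self.validation.threshold,
            "studies": {sid: p.to_dict() for sid, p in self.performances.items()},
            "exclusions": self.exclusions,
            "pooled": {k: p.to_dict() for k, p in self.pooled.items()},
            "bivariate": self.bivariate.to_dict() if self.bivariate else None,
            "bivariate_flags": self.bivariate_flags,
            "recalibration": (
                self.recalibration.to_dict() if self.recalibration else None
            ),
        }
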