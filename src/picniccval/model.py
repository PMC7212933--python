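"""The PICNICC logistic risk model for paediatric febrile neutropenia.

The PICNICC (Predicting Infectious ComplicatioNs In Children with Cancer)
model predicts the probability of a microbiologically documented infection
(MDI) for a febrile-neutropenia episode from tumour type, presentation
temperature, the clinician's impression of the child being severely unwell,
haemoglobin, and the natural logs of the total white cell count and the
absolute monocyte count.

This module houses the published coefficient set, validation of episode
tables, and the scoring functions (linear predictor, predicted risk,
low-risk classification).  The published report of the model's derivation
does not print the model intercept; the packaged default therefore ships a
documented placeholder intercept (see :data:`DEFAULT_INTERCEPT`) calibrated
so that the mean predicted risk in the package's reference synthetic
population is about 0.25, matching the often-quoted figure that roughly a
quarter of febrile-neutropenia episodes have a documented infection.
"""

from __future__ import annotations

import json
import logging
import numbers
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "TUMOUR_CATEGORIES",
    "REFERENCE_TUMOUR",
    "DERIVATION_TUMOUR_COEFFS",
    "DEFAULT_INTERCEPT",
    "default_model_spec",
    "load_model_spec",
    "load_episodes",
    "validate_episodes",
    "linear_predictor",
    "predicted_risk",
    "classify_low_risk",
    "COVARIATE_COLUMNS",
    "EPISODE_COLUMNS",
]

#: Default label for the baseline tumour category (log-OR fixed at 0).
#: Acute lymphoblastic leukaemia, by far the most common diagnosis in this
#: population, is the natural reference; the label is configurable.
REFERENCE_TUMOUR = "Acute lymphoblastic leukaemia / other"

#: Published log odds ratios per tumour category relative to the reference.
#: The two extreme values near -14 are preserved exactly as published: they
#: arise from categories with no events in the derivation data (complete
#: separation) and drive predicted risk to ~0 for those episodes.
DERIVATION_TUMOUR_COEFFS: dict[str, float] = {
    "Acute myeloid leukaemia": 0.65,
    "Ewing's sarcoma": -0.64,
    "Germ cell tumour": -0.07,
    "Hepatoblastoma": 0.48,
    "High-grade brain tumour": -0.34,
    "Hodgkin's lymphoma": -0.41,
    "High-risk neuroblastoma": 0.92,
    "Langerhans cell histiocytosis": -14.1,
    "Low-grade brain tumour": -14.16,
    "Neuroblastoma": 0.47,
    "Non-Hodgkin's lymphoma": -0.47,
    "Osteosarcoma": -1.19,
    "Other tumour": 0.8,
    "Retinoblastoma": 0.55,
    "Rhabdomyosarcoma": -0.24,
    "Sarcoma": 0.19,
    "Wilms tumour": -0.49,
}

#: Closed list of accepted tumour-type labels (17 named + reference).
TUMOUR_CATEGORIES: tuple[str, ...] = (REFERENCE_TUMOUR,) + tuple(
    DERIVATION_TUMOUR_COEFFS
)

#: Placeholder intercept, NOT a published value.  The derivation report does
#: not print the model intercept, so the package calibrates one such that the
#: mean predicted risk over the default synthetic reference population is
#: approximately 0.25.  Every load of the default spec logs this caveat.
DEFAULT_INTERCEPT = -4.27

COVARIATE_COLUMNS = (
    "tumour_type",
    "temperature",
    "severely_unwell",
    "haemoglobin",
    "wcc",
    "amc",
)
EPISODE_COLUMNS = ("study_id",) + COVARIATE_COLUMNS + ("mdi",)

#: wcc/amc of exactly 0 would make ln() undefined; substitute half the
#: smallest representable assay value (0.01 x 10^9/L) before taking logs.
ZERO_COUNT_SUBSTITUTE = 0.005


@dataclass(frozen=True)
class ModelSpec:
    """A logistic risk model on the PICNICC covariate set.

    Parameters
    ----------
    intercept : float
        Model intercept on the log-odds scale.
    tumour_coeffs : mapping of str to float
        Log odds ratio per tumour category; exactly one category (the
        reference) must carry a coefficient of 0.
    temp_coeff : float
        Log-OR per degree Celsius above 37.
    unwell_coeff : float
        Log-OR for a clinical impression of "severely unwell".
    hb_coeff : float
        Log-OR per g/dL of haemoglobin.
    ln_wcc_coeff, ln_amc_coeff : float
        Log-OR per natural-log unit of total white cell count and absolute
        monocyte count (both in 10^9/L).
    name : str
        Human-readable tag carried through reports.
    """

    intercept: float
    tumour_coeffs: Mapping[str, float]
    temp_coeff: float
    unwell_coeff: float
    hb_coeff: float
    ln_wcc_coeff: float
    ln_amc_coeff: float
    name: str = "model"

    def __post_init__(self) -> None:
        scalar_fields = {
            "intercept": self.intercept,
            "temp_coeff": self.temp_coeff,
            "unwell_coeff": self.unwell_coeff,
            "hb_coeff": self.hb_coeff,
            "ln_wcc_coeff": self.ln_wcc_coeff,
            "ln_amc_coeff": self.ln_amc_coeff,
        }
        for fname, value in scalar_fields.items():
            if not isinstance(value, numbers.Real) or not np.isfinite(value):
                raise ValueError(f"model spec field {fname!r} is not a finite number")
        for cat, value in self.tumour_coeffs.items():
            if not isinstance(value, numbers.Real) or not np.isfinite(value):
                raise ValueError(
                    f"tumour coefficient for {cat!r} is not a finite number"
                )
        refs = [c for c, v in self.tumour_coeffs.items() if v == 0.0]
        if len(refs) != 1:
            raise ValueError(
                "model spec must have exactly one reference tumour category "
                f"with coefficient 0; found {len(refs)}"
            )
        object.__setattr__(self, "tumour_coeffs", dict(self.tumour_coeffs))

    @property
    def reference_tumour(self) -> str:
        return next(c for c, v in self.tumour_coeffs.items() if v == 0.0)

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.tumour_coeffs)

    def beta_vector(self) -> pd.Series:
        """All non-intercept coefficients as a named vector."""
        parts = dict(self.tumour_coeffs)
        parts.update(
            temp_coeff=self.temp_coeff,
            unwell_coeff=self.unwell_coeff,
            hb_coeff=self.hb_coeff,
            ln_wcc_coeff=self.ln_wcc_coeff,
            ln_amc_coeff=self.ln_amc_coeff,
        )
        return pd.Series(parts, dtype=float)

    def scale_betas(self, factor: float, name: str | None = None) -> "ModelSpec":
        """Return a spec with every beta (not the intercept) multiplied by ``factor``."""
        return replace(
            self,
            tumour_coeffs={c: v * factor for c, v in self.tumour_coeffs.items()},
            temp_coeff=self.temp_coeff * factor,
            unwell_coeff=self.unwell_coeff * factor,
            hb_coeff=self.hb_coeff * factor,
            ln_wcc_coeff=self.ln_wcc_coeff * factor,
            ln_amc_coeff=self.ln_amc_coeff * factor,
            name=name or f"{self.name}|betas*{factor:g}",
        )

    def with_intercept(self, intercept: float, name: str | None = None) -> "ModelSpec":
        return replace(self, intercept=float(intercept), name=name or self.name)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intercept": self.intercept,
            "tumour_coeffs": dict(self.tumour_coeffs),
            "temp_coeff": self.temp_coeff,
            "unwell_coeff": self.unwell_coeff,
            "hb_coeff": self.hb_coeff,
            "ln_wcc_coeff": self.ln_wcc_coeff,
            "ln_amc_coeff": self.ln_amc_coeff,
        }


def default_model_spec(intercept: float | None = None) -> ModelSpec:
    """The packaged PICNICC model with the published derivation coefficients.

    The intercept is a placeholder because the published papers do not print
    it; pass ``intercept`` to override.
    """
    if intercept is None:
        intercept = DEFAULT_INTERCEPT
        logger.warning(
            "default model spec uses a placeholder intercept (%.3f); the "
            "published intercept is not available",
            intercept,
        )
    coeffs = {REFERENCE_TUMOUR: 0.0}
    coeffs.update(DERIVATION_TUMOUR_COEFFS)
    return ModelSpec(
        intercept=float(intercept),
        tumour_coeffs=coeffs,
        temp_coeff=0.57,
        unwell_coeff=0.79,
        hb_coeff=0.18,
        ln_wcc_coeff=-0.30,
        ln_amc_coeff=-0.21,
        name="PICNICC (derivation betas, placeholder intercept)",
    )


_SCALAR_COEFF_KEYS = (
    "intercept",
    "temp_coeff",
    "unwell_coeff",
    "hb_coeff",
    "ln_wcc_coeff",
    "ln_amc_coeff",
)


def load_model_spec(source: str | Path | Mapping | None = None) -> ModelSpec:
    """Load a :class:`ModelSpec` from a config mapping, YAML/JSON file, or
    the packaged default.

    Parameters
    ----------
    source : None, "default", mapping, or path
        ``None`` or ``"default"`` returns the packaged default spec.  A
        mapping (or a path to a YAML/JSON file holding one) must provide all
        keys of :data:`_SCALAR_COEFF_KEYS` plus a ``tumour_coeffs`` section
        covering every category in :data:`TUMOUR_CATEGORIES`.

    Raises
    ------
    ValueError
        Naming the offending field when a coefficient is missing, a tumour
        category is unknown, or a value is not finite.
    """
    if source is None or source == "default":
        return default_model_spec()
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        if str(source).endswith(".json"):
            source = json.loads(text)
        else:
            source = yaml.safe_load(text)
    if not isinstance(source, Mapping):
        raise ValueError(f"cannot build a model spec from {type(source).__name__}")

    missing = [k for k in _SCALAR_COEFF_KEYS if k not in source]
    if missing:
        raise ValueError(f"model spec missing field(s): {', '.join(missing)}")
    tumour = source.get("tumour_coeffs")
    if not isinstance(tumour, Mapping):
        raise ValueError("model spec missing field(s): tumour_coeffs")
    unknown = set(tumour) - set(TUMOUR_CATEGORIES)
    reference = source.get("reference_tumour", REFERENCE_TUMOUR)
    unknown -= {reference}
    if unknown:
        raise ValueError(f"unknown tumour categories: {sorted(unknown)}")
    missing_cats = set(DERIVATION_TUMOUR_COEFFS) - set(tumour)
    if missing_cats:
        raise ValueError(f"tumour_coeffs missing categories: {sorted(missing_cats)}")
    coeffs = {reference: 0.0}
    coeffs.update({c: float(v) for c, v in tumour.items()})
    return ModelSpec(
        intercept=float(source["intercept"]),
        tumour_coeffs=coeffs,
        temp_coeff=float(source["temp_coeff"]),
        unwell_coeff=float(source["unwell_coeff"]),
        hb_coeff=float(source["hb_coeff"]),
        ln_wcc_coeff=float(source["ln_wcc_coeff"]),
        ln_amc_coeff=float(source["ln_amc_coeff"]),
        name=str(source.get("name", "custom model")),
    )


def validate_episodes(
    df: pd.DataFrame,
    *,
    temperature_bounds: tuple[float, float] = (34.0, 43.0),
    categories: tuple[str, ...] = TUMOUR_CATEGORIES,
    hb_units: str = "g/dL",
) -> pd.DataFrame:
    """Validate an episode table against the loader invariants.

    Missing values (NaN / empty fields) are allowed everywhere except
    ``study_id`` and are handled downstream by complete-case filtering;
    values that are *present* but out of range are rejected here.
    """
    if hb_units != "g/dL":
        raise ValueError(
            f"haemoglobin must be supplied in g/dL, got {hb_units!r}; "
            "convert before loading (no automatic unit conversion)"
        )
    missing_cols = [c for c in EPISODE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"episode table missing column(s): {missing_cols}")
    df = df.copy()
    tt = df["tumour_type"]
    bad = tt.dropna()[~tt.dropna().isin(categories)]
    if len(bad):
        raise ValueError(
            f"unknown tumour type label(s): {sorted(bad.unique())[:5]}"
        )
    lo, hi = temperature_bounds
    temp = pd.to_numeric(df["temperature"], errors="raise")
    out = temp.dropna()[(temp.dropna() < lo) | (temp.dropna() > hi)]
    if len(out):
        raise ValueError(
            f"{len(out)} temperature value(s) outside [{lo}, {hi}] degC"
        )
    for col in ("wcc", "amc"):
        vals = pd.to_numeric(df[col], errors="raise")
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative values in column {col!r}")
        df[col] = vals
    hb = pd.to_numeric(df["haemoglobin"], errors="raise")
    if (hb.dropna() <= 0).any():
        raise ValueError("haemoglobin must be positive")
    mdi = pd.to_numeric(df["mdi"], errors="raise")
    if not mdi.dropna().isin([0, 1]).all():
        raise ValueError("mdi must be 0, 1 or missing")
    unwell = pd.to_numeric(df["severely_unwell"], errors="raise")
    if not unwell.dropna().isin([0, 1]).all():
        raise ValueError("severely_unwell must be 0, 1 or missing")
    df["temperature"] = temp
    df["haemoglobin"] = hb
    df["mdi"] = mdi
    df["severely_unwell"] = unwell
    return df


def load_episodes(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read an episode CSV (one row per episode, empty fields = missing)."""
    df = pd.read_csv(path)
    return validate_episodes(df, **kwargs)


def linear_predictor(
    model: ModelSpec,
    episodes: pd.DataFrame,
    *,
    zero_count_substitute: float = ZERO_COUNT_SUBSTITUTE,
    include_intercept: bool = True,
) -> pd.Series:
    """Linear predictor (log-odds) of each episode under ``model``.

    LP = intercept + beta_tumour + temp_coeff*(T - 37) + unwell_coeff*unwell
         + hb_coeff*Hb + ln_wcc_coeff*ln(WCC) + ln_amc_coeff*ln(AMC)

    Rows with any missing covariate get NaN (the complete-case exclusion
    signal); counts of exactly zero are substituted with
    ``zero_count_substitute`` before the log (with a warning), and negative
    counts raise.
    """
    tumour = episodes["tumour_type"].map(model.tumour_coeffs)
    unknown = episodes["tumour_type"].notna() & tumour.isna()
    if unknown.any():
        raise ValueError(
            "tumour categories absent from the model: "
            f"{sorted(episodes.loc[unknown, 'tumour_type'].unique())}"
        )
    wcc = episodes["wcc"].astype(float).copy()
    amc = episodes["amc"].astype(float).copy()
    for name, col in (("wcc", wcc), ("amc", amc)):
        if (col.dropna() < 0).any():
            raise ValueError(f"negative {name} encountered while scoring")
        zeros = col == 0
        if zeros.any():
            logger.warning(
                "%d zero %s value(s) substituted with %g before log",
                int(zeros.sum()), name, zero_count_substitute,
            )
            col[zeros] = zero_count_substitute
    lp = (
        tumour
        + model.temp_coeff * (episodes["temperature"].astype(float) - 37.0)
        + model.unwell_coeff * episodes["severely_unwell"].astype(float)
        + model.hb_coeff * episodes["haemoglobin"].astype(float)
        + model.ln_wcc_coeff * np.log(wcc)
        + model.ln_amc_coeff * np.log(amc)
    )
    if include_intercept:
        lp = lp + model.intercept
    return lp.rename("linear_predictor")


def predicted_risk(
    model: ModelSpec, episodes: pd.DataFrame, **kwargs
) -> pd.Series:
    """Predicted MDI probability: inverse-logit of the linear predictor.

    Strictly inside (0, 1) for finite LP; NaN propagates for incomplete rows.
    """
    lp = linear_predictor(model, episodes, **kwargs)
    return pd.Series(expit(lp.to_numpy()), index=lp.index, name="predicted_risk")


def classify_low_risk(risk, threshold: float = 0.10):
    """Low-risk flag: predicted risk at or below ``threshold``.

    The boundary is inclusive ("<= 10% chance" defines low risk), so a risk
    of exactly 0.10 is classified low-risk.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be strictly between 0 and 1")
    arr = np.asarray(risk)
    flag = arr <= threshold
    if isinstance(risk, pd.Series):
        return pd.Series(flag, index=risk.index, name="low_risk")
    if np.isscalar(risk):
        return bool(flag)
    return flag
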