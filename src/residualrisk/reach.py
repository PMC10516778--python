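"""REACH-style 20-month recurrent-event risk equation and horizon conversion.

The risk engine is a proportional-hazards score: a linear predictor over
encoded patient covariates, mapped to a 20-month event probability through
either a baseline-survival parameterization

    p20 = 1 − S0 ** exp(score − reference_score)

or a logistic intercept parameterization ``p20 = expit(intercept + score)``
(published recalibrations of such equations differ in which form they
report, so both are supported behind a flag).  The 20-month probability is
extrapolated to other horizons assuming a constant event rate (exponential
survival), with 10 years = 120 months exactly.

Coefficients are never hard-coded: they load from a structured YAML file
(term name, coefficient, encoding rule; baseline block) validated on load.
The packaged default, ``data/reach_coefficients_synthetic.yaml``, is an
explicitly synthetic coefficient set — see its header and docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from .cohort import PatientRecord

__all__ = [
    "TermEncoding",
    "Term",
    "Baseline",
    "ReachCoefficients",
    "RiskEstimate",
    "load_coefficients",
    "default_coefficients_path",
    "linear_predictor",
    "risk_20_months",
    "ten_year_risk",
    "convert_risk_horizon",
]

RISK_HORIZON_MONTHS = 20.0
TEN_YEARS_MONTHS = 120.0


class TermEncoding(BaseModel):
    """How a patient field is turned into the number a coefficient multiplies.

    ``linear``      — (value − center) / scale
    ``indicator``   — 1.0 if the (boolean) field is true, else 0.0
    ``categorical`` — ``levels[str(value)]`` (levels carry per-level codes)
    """

    model_config = {"frozen": True}

    kind: Literal["linear", "indicator", "categorical"]
    field: str
    center: float = 0.0
    scale: float = 1.0
    levels: Optional[dict[str, float]] = None

    @model_validator(mode="after")
    def _check(self) -> "TermEncoding":
        if self.kind == "categorical" and not self.levels:
            raise ValueError(f"categorical encoding for '{self.field}' requires levels")
        if self.scale == 0:
            raise ValueError("scale must be nonzero")
        return self


class Term(BaseModel):
    model_config = {"frozen": True}

    name: str
    coefficient: float
    encoding: TermEncoding


class Baseline(BaseModel):
    """Baseline block: survival form (S0 at 20 months) or logistic intercept."""

    model_config = {"frozen": True}

    form: Literal["survival", "intercept"]
    s0: Optional[float] = None
    reference_score: float = 0.0
    intercept: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "Baseline":
        if self.form == "survival":
            if self.s0 is None or not (0.0 < self.s0 < 1.0):
                raise ValueError("survival form requires baseline survival s0 in (0, 1)")
        elif self.intercept is None:
            raise ValueError("intercept form requires an intercept")
        return self


class ReachCoefficients(BaseModel):
    """Named coefficient vector plus baseline for the 20-month equation."""

    model_config = {"frozen": True}

    name: str = "unnamed"
    terms: tuple[Term, ...]
    baseline: Baseline


def default_coefficients_path() -> Path:
    return Path(resources.files("residualrisk") / "data" / "reach_coefficients_synthetic.yaml")


def load_coefficients(path: str | Path | None = None) -> ReachCoefficients:
    """Load and validate a coefficient file; None loads the packaged default."""
    path = default_coefficients_path() if path is None else Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return ReachCoefficients.model_validate(raw)


def _encode(record: PatientRecord, enc: TermEncoding) -> float:
    try:
        value = getattr(record, enc.field)
    except AttributeError as exc:
        raise KeyError(f"risk equation requires covariate '{enc.field}' absent from record") from exc
    if enc.kind == "linear":
        return (float(value) - enc.center) / enc.scale
    if enc.kind == "indicator":
        return 1.0 if value else 0.0
    key = value.value if hasattr(value, "value") else str(value)
    assert enc.levels is not None
    if key not in enc.levels:
        raise KeyError(f"covariate '{enc.field}' level '{key}' not in coefficient file")
    return float(enc.levels[key])


def linear_predictor(record: PatientRecord, coeffs: ReachCoefficients) -> float:
    """Sum of coefficient × encoded covariate (log-hazard scale)."""
    return float(sum(t.coefficient * _encode(record, t.encoding) for t in coeffs.terms))


def risk_20_months(record: PatientRecord, coeffs: ReachCoefficients) -> float:
    """Probability of a recurrent cardiovascular event within 20 months."""
    score = linear_predictor(record, coeffs)
    base = coeffs.baseline
    if base.form == "survival":
        assert base.s0 is not None
        return float(1.0 - base.s0 ** math.exp(score - base.reference_score))
    assert base.intercept is not None
    return float(1.0 / (1.0 + math.exp(-(base.intercept + score))))


def convert_risk_horizon(p_from: float, t_from: float, t_to: float) -> float:
    """Re-express a cumulative event probability at another horizon.

    Assumes a constant event rate (exponential survival), so

        p_to = 1 − (1 − p_from) ** (t_to / t_from).

    The map is the CDF transport of an exponential with hazard
    ``−ln(1 − p_from)/t_from``; composing 20→60→120 equals 20→120.
    """
    if t_from <= 0 or t_to <= 0:
        raise ValueError("time horizons must be positive")
    if not 0.0 <= p_from < 1.0:
        raise ValueError("p_from must lie in [0, 1)")
    return float(1.0 - (1.0 - p_from) ** (t_to / t_from))


@dataclass(frozen=True)
class RiskEstimate:
    """20-month risk with its constant-hazard 10-year extrapolation."""

    p20: float
    hazard: float  # events per month
    p120: float

    @classmethod
    def from_p20(cls, p20: float) -> "RiskEstimate":
        hazard = -math.log(1.0 - p20) / RISK_HORIZON_MONTHS
        return cls(
            p20=p20,
            hazard=hazard,
            p120=convert_risk_horizon(p20, RISK_HORIZON_MONTHS, TEN_YEARS_MONTHS),
        )


def ten_year_risk(record: PatientRecord, coeffs: ReachCoefficients) -> RiskEstimate:
    """Predict 20-month risk and extrapolate to the 120-month horizon."""
    return RiskEstimate.from_p20(risk_20_months(record, coeffs))
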