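"""Monte-Carlo simulation of risk reduction under LDL-C treatment goals.

For every patient above the 70 mg/dl threshold the simulation computes the
LDL-C gap to a guideline goal (achieved levels fixed conservatively at 69,
54 or 39 mg/dl), draws rate ratios per 39 mg/dl LDL-C reduction from a
lognormal matched to the meta-analytic point estimate and 95% CI
(inverse-CDF sampling; default 0.78, CI 0.76–0.80, so a 39 mg/dl ≈
1.0 mmol/l reduction yields the canonical 22% relative risk reduction),
scales them to the patient's gap,

    RRR = 1 − rr ** (ΔLDL / 39),

and combines them with the baseline 10-year risk from the risk equation:

    ARR = p120 × RRR,    residual risk = p120 − ARR.

Draw granularity: one independent rate-ratio draw per patient per replicate
(default 100 replicates), pooled for summaries; a shared-draw-per-replicate
mode is available for sensitivity analysis.  With log_sd = 0 every draw is
the point estimate and all headline medians become deterministic quantile
arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .cohort import PatientRecord
from .reach import ReachCoefficients, ten_year_risk
from .report import SummaryStat, median_iqr

logger = logging.getLogger(__name__)

__all__ = [
    "ELIGIBILITY_THRESHOLD",
    "MGDL_PER_MMOL_UNIT",
    "GoalScenario",
    "SCENARIOS",
    "EffectDistribution",
    "GapResult",
    "required_reduction",
    "sample_rate_ratios",
    "rrr_for_reduction",
    "simulate_scenario",
    "residual_risk_below_70",
]

#: Patients at or above this LDL-C (mg/dl) enter the goal simulation.
ELIGIBILITY_THRESHOLD = 70.0
#: The effect model's unit of LDL-C reduction (≈ 1.0 mmol/l), in mg/dl.
MGDL_PER_MMOL_UNIT = 39.0

_Z975 = 1.959964  # standard normal 97.5th percentile


@dataclass(frozen=True)
class GoalScenario:
    """A guideline goal, simulated as an exact achieved LDL-C level."""

    label: str
    achieved_ldl: float

    def __post_init__(self) -> None:
        if not self.achieved_ldl < ELIGIBILITY_THRESHOLD:
            raise ValueError("achieved LDL-C must lie below the 70 mg/dl threshold")


ACC_AHA_70 = GoalScenario("ACC_AHA_70", 69.0)
ESC_EAS_55 = GoalScenario("ESC_EAS_55", 54.0)
EXPLORATORY_40 = GoalScenario("EXPLORATORY_40", 39.0)

SCENARIOS: dict[str, GoalScenario] = {
    s.label: s for s in (ACC_AHA_70, ESC_EAS_55, EXPLORATORY_40)
}


class EffectDistribution(BaseModel):
    """Rate ratio per 39 mg/dl LDL-C reduction, with lognormal uncertainty.

    The log-scale standard deviation derives from the 95% CI:
    ``log_sd = (ln ci_high − ln ci_low) / (2 × 1.959964)``.  Setting
    ``ci_low = ci_high = rr_per_39`` gives the deterministic (log_sd = 0)
    limit.
    """

    model_config = {"frozen": True}

    rr_per_39: float = 0.78
    ci_low: float = 0.76
    ci_high: float = 0.80
    n_draws: int = Field(default=10_000, ge=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "EffectDistribution":
        if not (0.0 < self.ci_low <= self.rr_per_39 <= self.ci_high < 1.0):
            raise ValueError("require 0 < ci_low <= rr_per_39 <= ci_high < 1")
        return self

    @property
    def log_sd(self) -> float:
        return (math.log(self.ci_high) - math.log(self.ci_low)) / (2.0 * _Z975)


@dataclass(frozen=True)
class GapResult:
    """Absolute and relative LDL-C reduction a patient needs."""

    delta_ldl: float
    rel_reduction: float


def required_reduction(ldl_c: float, scenario: GoalScenario) -> GapResult:
    """LDL-C reduction required to land exactly on the scenario's achieved level."""
    if ldl_c < ELIGIBILITY_THRESHOLD:
        raise ValueError(
            f"patient LDL-C {ldl_c} mg/dl is below {ELIGIBILITY_THRESHOLD}; "
            "only patients at or above the threshold are simulated"
        )
    delta = ldl_c - scenario.achieved_ldl
    return GapResult(delta_ldl=delta, rel_reduction=delta / ldl_c)


def sample_rate_ratios(
    effect: EffectDistribution,
    n: Optional[int] = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw rate ratios: ``exp(Normal(ln rr_per_39, log_sd))``.

    Deterministic given the effect's seed (or a supplied generator); all
    draws are positive, and log_sd = 0 returns the point estimate exactly.
    """
    n = effect.n_draws if n is None else n
    rng = np.random.default_rng(effect.seed) if rng is None else rng
    if effect.log_sd == 0.0:
        return np.full(n, effect.rr_per_39)
    return np.exp(rng.normal(math.log(effect.rr_per_39), effect.log_sd, size=n))


def rrr_for_reduction(delta_ldl, rate_ratio, per: float = MGDL_PER_MMOL_UNIT):
    """Relative risk reduction for an LDL-C drop: ``1 − rr ** (Δ/39)``.

    Accepts scalars or arrays (broadcast); monotone increasing in
    ``delta_ldl`` and equal to ``1 − rate_ratio`` at Δ = 39 mg/dl.
    """
    delta = np.asarray(delta_ldl, dtype=float)
    rr = np.asarray(rate_ratio, dtype=float)
    if np.any(delta < 0):
        raise ValueError("delta_ldl must be nonnegative")
    if np.any((rr <= 0) | (rr >= 1)):
        raise ValueError("rate_ratio must lie in (0, 1)")
    out = 1.0 - rr ** (delta / per)
    if np.isscalar(delta_ldl) and np.isscalar(rate_ratio):
        return float(out)
    return out


def simulate_scenario(
    cohort: Sequence[PatientRecord],
    coeffs: ReachCoefficients,
    scenario: GoalScenario,
    effect: EffectDistribution,
    n_replicates: int = 100,
    seed: Optional[int] = None,
    shared_draws: bool = False,
) -> pd.DataFrame:
    """Simulate one goal scenario over the eligible (LDL-C ≥ 70) subcohort.

    Returns a tidy frame with one row per patient × replicate:
    ``patient_id, scenario, replicate, baseline_p120, delta_ldl,
    rel_reduction, rate_ratio, rrr, arr, residual_p120``.  Patients below
    the threshold are excluded (count logged).  ``shared_draws=True`` uses
    one rate-ratio draw per replicate shared by all patients instead of
    independent per-patient draws.
    """
    eligible = [r for r in cohort if r.ldl_c >= ELIGIBILITY_THRESHOLD]
    excluded = len(cohort) - len(eligible)
    logger.info(
        "scenario %s: %d eligible patients (LDL-C >= %g mg/dl), %d excluded",
        scenario.label, len(eligible), ELIGIBILITY_THRESHOLD, excluded,
    )
    if not eligible:
        raise ValueError("no patients with LDL-C >= 70 mg/dl; nothing to simulate")
    n_pat = len(eligible)
    p120 = np.array([ten_year_risk(r, coeffs).p120 for r in eligible])
    ldl = np.array([r.ldl_c for r in eligible])
    delta = ldl - scenario.achieved_ldl
    rel = delta / ldl

    rng = np.random.default_rng(effect.seed if seed is None else seed)
    if shared_draws:
        rr = np.broadcast_to(
            sample_rate_ratios(effect, n_replicates, rng), (n_pat, n_replicates)
        )
    else:
        rr = sample_rate_ratios(effect, n_pat * n_replicates, rng).reshape(n_pat, n_replicates)

    rrr = rrr_for_reduction(delta[:, None], rr)
    arr = p120[:, None] * rrr
    residual = p120[:, None] - arr

    rep = np.tile(np.arange(n_replicates), n_pat)
    return pd.DataFrame(
        {
            "patient_id": np.repeat([r.patient_id for r in eligible], n_replicates),
            "scenario": scenario.label,
            "replicate": rep,
            "baseline_p120": np.repeat(p120, n_replicates),
            "delta_ldl": np.repeat(delta, n_replicates),
            "rel_reduction": np.repeat(rel, n_replicates),
            "rate_ratio": rr.ravel(),
            "rrr": rrr.ravel(),
            "arr": arr.ravel(),
            "residual_p120": residual.ravel(),
        }
    )


def residual_risk_below_70(
    cohort: Sequence[PatientRecord], coeffs: ReachCoefficients
) -> SummaryStat:
    """Median/IQR of baseline 10-year risk among patients already below 70 mg/dl.

    No intervention is applied; this is the residual risk carried by the
    goal-attaining stratum.
    """
    below = [r for r in cohort if r.ldl_c < ELIGIBILITY_THRESHOLD]
    if not below:
        raise ValueError("no patients with LDL-C < 70 mg/dl")
    return median_iqr([ten_year_risk(r, coeffs).p120 for r in below])
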