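"""Seeded synthetic ASCVD cohort generator.

The study whose conditions this package emulates deposited no patient-level
data; only marginal summaries are printed (LDL-C medians with interquartile
ranges per stratum, covariate prevalences, therapy-category frequencies and
subtype counts).  This module generates cohorts that reproduce those
marginals so the whole pipeline is testable end to end:

* LDL-C per stratum follows a three-parameter *shifted lognormal* whose
  25th/50th/75th percentiles match the printed quartiles exactly (a
  two-parameter lognormal cannot match an asymmetric IQR).  Left-skewed
  quartile triples (median closer to the upper quartile) are handled by the
  reflected family ``X = shift − lognormal``; the same closed form yields
  the reflection point.  Exactly symmetric triples degrade to a normal
  distribution with a warning.
* Stratum (LDL-C ≥ 70 vs < 70 mg/dl), subtype and all covariates are drawn
  independently given the stratum from the published per-stratum marginals
  — the joint structure is NOT identified by printed tables and no
  correlation is imposed (documented limitation).
* One master seed is expanded into independent substreams (stratum/subtype
  assignment, per-stratum LDL-C, covariates, therapy) via
  ``numpy.random.SeedSequence`` so adding a stream never perturbs earlier
  draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from pydantic import BaseModel, Field, model_validator
from scipy import stats

from .cohort import (
    AscvdSubtype,
    LLTCategory,
    LLTRegimen,
    PatientRecord,
    Sex,
    Smoking,
    StatinIntensity,
)

__all__ = [
    "Z75",
    "QuantileSpec",
    "ShiftedLognormalParams",
    "NormalParams",
    "fit_shifted_lognormal",
    "sample_ldl",
    "StratumSpec",
    "CohortSpec",
    "default_cohort_spec",
    "generate_cohort",
]

#: Standard normal 75th percentile (0.6744897...), the quartile z-score.
Z75: float = float(stats.norm.ppf(0.75))


class QuantileSpec(BaseModel):
    """Target quartiles (mg/dl) for an LDL-C marginal, with optional truncation."""

    model_config = {"frozen": True}

    q1: float
    median: float
    q3: float
    lower_truncation: Optional[float] = None
    upper_truncation: Optional[float] = None

    @model_validator(mode="after")
    def _check_order(self) -> "QuantileSpec":
        if not (self.q1 < self.median < self.q3):
            raise ValueError("quantiles must satisfy q1 < median < q3")
        if (
            self.lower_truncation is not None
            and self.upper_truncation is not None
            and self.lower_truncation >= self.upper_truncation
        ):
            raise ValueError("truncation bounds must bracket a region of positive probability")
        return self


@dataclass(frozen=True)
class ShiftedLognormalParams:
    """Three-parameter (shifted) lognormal, optionally reflected.

    ``tail="right"``: X = shift + exp(N(log_median, log_sd)) — right skew.
    ``tail="left"``:  X = shift − exp(N(log_median, log_sd)) — left skew.
    """

    shift: float
    log_median: float
    log_sd: float
    tail: Literal["right", "left"] = "right"

    def __post_init__(self) -> None:
        if self.log_sd <= 0:
            raise ValueError("log_sd must be > 0")

    @property
    def _core(self):
        return stats.lognorm(s=self.log_sd, scale=np.exp(self.log_median))

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        if self.tail == "right":
            return self._core.cdf(x - self.shift)
        return self._core.sf(self.shift - x)

    def ppf(self, q):
        q = np.asarray(q, dtype=float)
        if self.tail == "right":
            return self.shift + self._core.ppf(q)
        return self.shift - self._core.ppf(1.0 - q)

    def rvs(self, n: int, rng: np.random.Generator):
        draws = self._core.rvs(size=n, random_state=rng)
        return self.shift + draws if self.tail == "right" else self.shift - draws


@dataclass(frozen=True)
class NormalParams:
    """Fallback marginal for exactly symmetric quartile triples."""

    mean: float
    sd: float

    def cdf(self, x):
        return stats.norm.cdf(x, loc=self.mean, scale=self.sd)

    def ppf(self, q):
        return stats.norm.ppf(q, loc=self.mean, scale=self.sd)

    def rvs(self, n: int, rng: np.random.Generator):
        return rng.normal(self.mean, self.sd, size=n)


def fit_shifted_lognormal(spec: QuantileSpec) -> ShiftedLognormalParams | NormalParams:
    """Fit the three-parameter family to the three quartiles in closed form.

    The shift solves ``(median − s)² = (q3 − s)(q1 − s)`` (geometric
    quartiles after shifting):

        s = (median² − q1·q3) / (2·median − q1 − q3)

    For right-skewed triples (q3 − median > median − q1) the shift lies
    below q1 and the fitted quartiles reproduce q1/median/q3 exactly; for
    left-skewed triples the same s lies above q3 and is the reflection
    point of the mirrored family.  Symmetric triples have no lognormal
    solution and fall back to a quartile-matched normal (with a warning).
    """
    q1, m, q3 = spec.q1, spec.median, spec.q3
    denom = 2.0 * m - q1 - q3
    if denom == 0.0:
        warnings.warn(
            "symmetric quartiles: falling back to a normal distribution",
            stacklevel=2,
        )
        return NormalParams(mean=m, sd=(q3 - q1) / (2.0 * Z75))
    shift = (m * m - q1 * q3) / denom
    if denom < 0.0:  # right skew
        if shift >= q1:
            raise ValueError("infeasible quantile spec: shift >= q1")
        log_sd = float(np.log((q3 - shift) / (m - shift)) / Z75)
        return ShiftedLognormalParams(
            shift=float(shift), log_median=float(np.log(m - shift)), log_sd=log_sd, tail="right"
        )
    # left skew: reflected family, shift sits above q3
    if shift <= q3:
        raise ValueError("infeasible quantile spec: reflection point <= q3")
    log_sd = float(np.log((shift - q1) / (shift - m)) / Z75)
    return ShiftedLognormalParams(
        shift=float(shift), log_median=float(np.log(shift - m)), log_sd=log_sd, tail="left"
    )


def sample_ldl(
    params: ShiftedLognormalParams | NormalParams,
    n: int,
    truncation: tuple[Optional[float], Optional[float]] | None = None,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n`` LDL-C values, rejection-sampled into ``[lower, upper)``.

    The analytic acceptance probability is checked first; below 1e-3 the
    truncation window is considered mis-specified and an error is raised.
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = truncation if truncation is not None else (None, None)
    p_lo = params.cdf(lo) if lo is not None else 0.0
    p_hi = params.cdf(hi) if hi is not None else 1.0
    accept = float(p_hi - p_lo)
    if accept < 1e-3:
        raise ValueError(
            f"truncation window accepts probability {accept:.2e} < 1e-3; "
            "the quantile spec and truncation bounds are inconsistent"
        )
    out = np.empty(0, dtype=float)
    while out.size < n:
        batch = max(int((n - out.size) / accept * 1.2) + 16, 32)
        draws = np.asarray(params.rvs(batch, rng), dtype=float)
        keep = np.ones(draws.shape, dtype=bool)
        if lo is not None:
            keep &= draws >= lo
        if hi is not None:
            keep &= draws < hi
        out = np.concatenate([out, draws[keep]])
    return out[:n]


class StratumSpec(BaseModel):
    """Per-LDL-C-stratum marginals: LDL-C quartiles plus covariate parameters."""

    model_config = {"frozen": True}

    ldl: QuantileSpec
    # Bernoulli prevalences
    female: float = Field(ge=0, le=1)
    diabetes: float = Field(ge=0, le=1)
    hypertension: float = Field(ge=0, le=1)
    ckd_ge3: float = Field(ge=0, le=1)
    chf: float = Field(ge=0, le=1)
    af: float = Field(ge=0, le=1)
    event_within_1y: float = Field(ge=0, le=1)
    # categorical weights (normalized on use)
    smoking_weights: dict[Smoking, float]
    llt_weights: dict[LLTCategory, float]
    # continuous covariates: (mean, sd), clipped to plausible ranges on draw
    age: tuple[float, float]
    sbp: tuple[float, float]
    dbp: tuple[float, float]
    bmi: tuple[float, float]


class CohortSpec(BaseModel):
    """Full recipe for a reproducible synthetic cohort."""

    model_config = {"frozen": True}

    n: int = Field(ge=1)
    seed: int
    stratum_weight_ge70: float = Field(ge=0, le=1)
    subtype_weights: dict[AscvdSubtype, float]
    ge70: StratumSpec
    lt70: StratumSpec
    n_vascular_beds_weights: dict[int, float]
    region_weights: dict[str, float]

    @model_validator(mode="after")
    def _check_weights(self) -> "CohortSpec":
        for name, w in (
            ("subtype_weights", self.subtype_weights),
            ("n_vascular_beds_weights", self.n_vascular_beds_weights),
            ("region_weights", self.region_weights),
        ):
            total = sum(w.values())
            if not np.isclose(total, 1.0, atol=1e-6):
                raise ValueError(f"{name} must sum to 1 (got {total})")
        if set(self.n_vascular_beds_weights) - {1, 2, 3}:
            raise ValueError("n_vascular_beds_weights keys must be in {1,2,3}")
        return self


def default_cohort_spec(n: int = 2039, seed: int = 20390) -> CohortSpec:
    """Calibrated default emulating the published European ASCVD cohort.

    Marginals: 61% of patients in the ≥70 mg/dl stratum; LDL-C quartiles
    81/93/115 mg/dl (≥70, truncated below at 70) and 46/56/63 mg/dl (<70,
    truncated to [20, 70)); subtype mix CAD:CBD:PAD ≈ 23:37:40; per-stratum
    covariate prevalences and therapy-category frequencies from the
    published tables.  Marginals not published (CHF, AF, recent event,
    vascular-bed count, region) use fixed literature-plausible defaults.
    """
    ge70 = StratumSpec(
        ldl=QuantileSpec(q1=81, median=93, q3=115, lower_truncation=70.0),
        female=0.370,
        diabetes=0.393,
        hypertension=0.784,
        ckd_ge3=0.095,
        chf=0.12,
        af=0.10,
        event_within_1y=0.15,
        smoking_weights={
            Smoking.non: 0.407,
            Smoking.ex: 0.406,
            Smoking.light: 0.057,
            Smoking.moderate: 0.076,
            Smoking.heavy: 0.051,
        },
        llt_weights={
            LLTCategory.low_statin_mono: 0.031,
            LLTCategory.moderate_statin_mono: 0.465,
            LLTCategory.high_statin_mono: 0.339,
            LLTCategory.ezetimibe_combo: 0.070,
            LLTCategory.pcsk9i_combo: 0.006,
            LLTCategory.other_llt: 0.088,
        },
        age=(68.0, 10.0),
        sbp=(135.4, 17.2),
        dbp=(77.4, 10.8),
        bmi=(27.4, 4.4),  # sd from IQR 24.9-30.9 => 6.0 / (2 * 0.6745)
    )
    lt70 = StratumSpec(
        ldl=QuantileSpec(q1=46, median=56, q3=63, lower_truncation=20.0, upper_truncation=70.0),
        female=0.250,
        diabetes=0.507,
        hypertension=0.785,
        ckd_ge3=0.110,
        chf=0.12,
        af=0.10,
        event_within_1y=0.15,
        smoking_weights={
            Smoking.non: 0.360,
            Smoking.ex: 0.464,
            Smoking.light: 0.062,
            Smoking.moderate: 0.070,
            Smoking.heavy: 0.040,
        },
        llt_weights={
            LLTCategory.low_statin_mono: 0.011,
            LLTCategory.moderate_statin_mono: 0.388,
            LLTCategory.high_statin_mono: 0.429,
            LLTCategory.ezetimibe_combo: 0.127,
            LLTCategory.pcsk9i_combo: 0.020,
            LLTCategory.other_llt: 0.024,
        },
        age=(68.7, 9.8),
        sbp=(134.8, 18.3),
        dbp=(76.0, 10.9),
        bmi=(28.3, 4.6),  # sd from IQR 25.2-31.4
    )
    return CohortSpec(
        n=n,
        seed=seed,
        stratum_weight_ge70=1238 / 2039,
        subtype_weights={
            AscvdSubtype.CAD: 470 / 2039,
            AscvdSubtype.CBD: 751 / 2039,
            AscvdSubtype.PAD: 818 / 2039,
        },
        ge70=ge70,
        lt70=lt70,
        n_vascular_beds_weights={1: 0.81, 2: 0.16, 3: 0.03},
        region_weights={"western_europe": 0.7, "eastern_europe": 0.3},
    )


_CLIP = {"age": (18.0, 110.0), "sbp": (80.0, 250.0), "dbp": (40.0, 140.0), "bmi": (15.0, 60.0)}

# A concrete regimen consistent with each therapy category.
_CATEGORY_REGIMEN = {
    LLTCategory.low_statin_mono: LLTRegimen(statin_intensity=StatinIntensity.low),
    LLTCategory.moderate_statin_mono: LLTRegimen(statin_intensity=StatinIntensity.moderate),
    LLTCategory.high_statin_mono: LLTRegimen(statin_intensity=StatinIntensity.high),
    LLTCategory.ezetimibe_combo: LLTRegimen(
        statin_intensity=StatinIntensity.moderate, ezetimibe=True
    ),
    LLTCategory.pcsk9i_combo: LLTRegimen(statin_intensity=StatinIntensity.high, pcsk9i=True),
    LLTCategory.other_llt: LLTRegimen(ezetimibe=True),
}


def _choice(rng: np.random.Generator, weights: dict, size: int) -> np.ndarray:
    keys = list(weights.keys())
    p = np.asarray([weights[k] for k in keys], dtype=float)
    p = p / p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return np.asarray(keys, dtype=object)[idx]


def generate_cohort(spec: CohortSpec) -> list[PatientRecord]:
    """Generate ``spec.n`` validated patient records, reproducibly.

    Stratum membership is Bernoulli(``stratum_weight_ge70``), subtype is
    multinomial, LDL-C is drawn from the per-stratum quantile-matched
    marginal (rejection-sampled into its truncation window), and all other
    covariates are drawn independently given the stratum.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(4)
    rng_strat = np.random.default_rng(streams[0])
    rng_ldl = np.random.default_rng(streams[1])
    rng_cov = np.random.default_rng(streams[2])
    rng_llt = np.random.default_rng(streams[3])

    n = spec.n
    in_ge70 = rng_strat.random(n) < spec.stratum_weight_ge70
    subtype = _choice(rng_strat, spec.subtype_weights, n)

    ldl = np.empty(n, dtype=float)
    for mask, stratum in ((in_ge70, spec.ge70), (~in_ge70, spec.lt70)):
        k = int(mask.sum())
        if k == 0:
            continue
        params = fit_shifted_lognormal(stratum.ldl)
        trunc = (stratum.ldl.lower_truncation, stratum.ldl.upper_truncation)
        ldl[mask] = sample_ldl(params, k, truncation=trunc, seed=rng_ldl)

    def per_stratum_bernoulli(attr: str) -> np.ndarray:
        p = np.where(in_ge70, getattr(spec.ge70, attr), getattr(spec.lt70, attr))
        return rng_cov.random(n) < p

    def per_stratum_normal(attr: str) -> np.ndarray:
        mean = np.where(in_ge70, getattr(spec.ge70, attr)[0], getattr(spec.lt70, attr)[0])
        sd = np.where(in_ge70, getattr(spec.ge70, attr)[1], getattr(spec.lt70, attr)[1])
        lo, hi = _CLIP[attr]
        return np.clip(rng_cov.normal(mean, sd), lo, hi)

    female = per_stratum_bernoulli("female")
    diabetes = per_stratum_bernoulli("diabetes")
    hypertension = per_stratum_bernoulli("hypertension")
    ckd = per_stratum_bernoulli("ckd_ge3")
    chf = per_stratum_bernoulli("chf")
    af = per_stratum_bernoulli("af")
    recent = per_stratum_bernoulli("event_within_1y")
    age = per_stratum_normal("age")
    sbp = per_stratum_normal("sbp")
    dbp = per_stratum_normal("dbp")
    bmi = per_stratum_normal("bmi")

    smoking = np.empty(n, dtype=object)
    category = np.empty(n, dtype=object)
    for mask, stratum in ((in_ge70, spec.ge70), (~in_ge70, spec.lt70)):
        k = int(mask.sum())
        if k == 0:
            continue
        smoking[mask] = _choice(rng_cov, stratum.smoking_weights, k)
        category[mask] = _choice(rng_llt, stratum.llt_weights, k)
    beds = _choice(rng_cov, spec.n_vascular_beds_weights, n)
    region = _choice(rng_cov, spec.region_weights, n)

    width = max(4, len(str(n)))
    records = []
    for i in range(n):
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:0{width}d}",
                ascvd_subtype=subtype[i],
                ldl_c=float(ldl[i]),
                age=float(age[i]),
                sex=Sex.female if female[i] else Sex.male,
                smoking=smoking[i],
                diabetes=bool(diabetes[i]),
                hypertension=bool(hypertension[i]),
                chf=bool(chf[i]),
                af=bool(af[i]),
                sbp=float(sbp[i]),
                dbp=float(dbp[i]),
                bmi=float(bmi[i]),
                ckd_ge3=bool(ckd[i]),
                n_vascular_beds=int(beds[i]),
                event_within_1y=bool(recent[i]),
                region=str(region[i]),
                llt=_CATEGORY_REGIMEN[category[i]],
            )
        )
    return records
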