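"""Covariate model: allometry, renal maturation, and creatinine clearance.

Individual parameters derive from typical 70 kg values by fixed-exponent
allometric scaling (power 0.75 for clearances, 1 for volumes), a sigmoid
postmenstrual-age maturation factor on elimination clearance for the youngest
children, and log-normal interindividual random effects.  Creatinine
clearance is computed from height, serum creatinine, and weight as a
descriptive covariate; renal function enters the parameter model only through
the maturation term.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


from .population import PopulationModel
from .structural_pk import PKParameters

__all__ = [
    "PatientCovariates",
    "RandomEffects",
    "compute_pma",
    "compute_crcl",
    "maturation_gfr",
    "individual_parameters",
    "WEEKS_PER_YEAR",
    "PMA_FULL_MATURITY_WEEKS",
]

#: calendar weeks per year used for age conversions
WEEKS_PER_YEAR = 365.25 / 7.0

#: Hill exponent and half-maturation PMA (weeks) of the GFR maturation curve
MATURATION_HILL = 3.4
MATURATION_PMA50 = 47.7

#: postmenstrual age of a 24-month-old; renal function is treated as fully
#: mature beyond this age
PMA_FULL_MATURITY_WEEKS = 24.0 * (365.25 / 12.0) / 7.0 + 40.0


def compute_pma(age_years: float) -> float:
    """Postmenstrual age (weeks): postnatal age plus 40 weeks of gestation."""
    if age_years < 0 or not math.isfinite(age_years):
        raise ValueError(f"age_years must be finite and >= 0, got {age_years!r}")
    return age_years * WEEKS_PER_YEAR + 40.0


def compute_crcl(height_cm: float, serum_creatinine_umol_per_l: float,
                 weight_kg: float) -> float:
    """Creatinine clearance (mL/min), height/creatinine rule with a weight factor.

    CrCL = 42.5 · height / SCr · (weight/70)^0.7
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise ValueError("height and weight must be > 0")
    if serum_creatinine_umol_per_l <= 0:
        raise ValueError("serum creatinine must be > 0")
    return (42.5 * height_cm / serum_creatinine_umol_per_l
            * (weight_kg / 70.0) ** 0.7)


@dataclass(frozen=True)
class PatientCovariates:
    """Demographics of one subject; PMA and CrCL are always derived."""

    age_years: float
    weight_kg: float
    height_cm: float
    serum_creatinine_umol_per_l: float
    sex: str = "unknown"
    pma_weeks: float = field(init=False)
    crcl_ml_per_min: float = field(init=False)

    def __post_init__(self) -> None:
        if self.weight_kg <= 0 or self.height_cm <= 0:
            raise ValueError("weight and height must be > 0")
        object.__setattr__(self, "pma_weeks", compute_pma(self.age_years))
        object.__setattr__(self, "crcl_ml_per_min", compute_crcl(
            self.height_cm, self.serum_creatinine_umol_per_l, self.weight_kg))


@dataclass(frozen=True)
class RandomEffects:
    """Per-subject log-scale deviations; zero means the typical individual."""

    eta_cl: float = 0.0
    eta_v2: float = 0.0
    eta_v3: float = 0.0
    eta_ka1: float = 0.0
    eta_ka2: float = 0.0

    def __post_init__(self) -> None:
        for name in ("eta_cl", "eta_v2", "eta_v3", "eta_ka1", "eta_ka2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


def maturation_gfr(pma_weeks: float) -> float:
    """Fraction of adult glomerular filtration at a given postmenstrual age.

    Hill curve PMA^3.4 / (47.7^3.4 + PMA^3.4); clamped to exactly 1 beyond
    the PMA of a 24-month-old, where the curve already exceeds 0.975 and
    renal function is taken as fully mature.
    """
    if pma_weeks <= 0 or not math.isfinite(pma_weeks):
        raise ValueError(f"pma_weeks must be finite and > 0, got {pma_weeks!r}")
    if pma_weeks > PMA_FULL_MATURITY_WEEKS:
        return 1.0
    num = pma_weeks ** MATURATION_HILL
    return num / (MATURATION_PMA50 ** MATURATION_HILL + num)


def individual_parameters(pop: PopulationModel, cov: PatientCovariates,
                          eta: RandomEffects | None = None,
                          study: str | None = None) -> PKParameters:
    """Individual structural parameters from covariates and random effects.

    Clearances scale with (weight/70)^0.75, volumes with weight/70; the GFR
    maturation fraction multiplies elimination clearance only (the
    intercompartmental clearance is distributional, not renal).  Absorption
    parameters and bioavailability do not scale with size; their random
    effects apply only when the corresponding IIV is enabled in the model.
    """
    if eta is None:
        eta = RandomEffects()
    cl_tv = pop.cl_tv(study) if study is not None else _single_cl(pop)
    size_cl = (cov.weight_kg / 70.0) ** 0.75
    size_v = cov.weight_kg / 70.0
    maturation = maturation_gfr(cov.pma_weeks)
    return PKParameters(
        cl=cl_tv * size_cl * maturation * math.exp(eta.eta_cl),
        v2=pop.v2_tv * size_v * math.exp(eta.eta_v2),
        q=pop.q_tv * size_cl,
        v3=pop.v3_tv * size_v * math.exp(eta.eta_v3),
        ka1=pop.ka1 * math.exp(eta.eta_ka1 if pop.omega_ka1 > 0 else 0.0),
        ka2=pop.ka2 * math.exp(eta.eta_ka2 if pop.omega_ka2 > 0 else 0.0),
        mtime=pop.mtime,
        f1=pop.f1,
    )


def _single_cl(pop: PopulationModel) -> float:
    values = set(pop.cl_tv_by_study.values())
    if len(values) != 1:
        raise ValueError("study label required: the model carries per-study "
                         "typical clearances")
    return values.pop()
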