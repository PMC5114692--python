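"""Population-level parameter container shared across simulation and fitting.

Typical values are expressed at a 70 kg reference body weight.  Clearance and
its interindividual variability (IIV) are study-specific: the rich single-dose
phase 1 study and the sparse multi-dose phase 3 study are described by the
same disposition model but distinct typical clearances, IIV magnitudes, and
residual error, reflecting the very different information content of their
sampling designs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["STUDY_RICH", "STUDY_SPARSE", "PopulationModel", "default_population"]

STUDY_RICH = "PRU-USA-12"
STUDY_SPARSE = "SPD555-303"


@dataclass(frozen=True)
class PopulationModel:
    """Typical values, IIV standard deviations, and residual error.

    ``omega_*`` entries are standard deviations of log-normal random effects;
    ``sigma_by_study`` are additive standard deviations on log-transformed
    concentrations (for small values numerically equal to a CV).  Absorption
    parameters and relative bioavailability are fixed quantities carried from
    the adult model of the same drug and are not estimated.
    """

    cl_tv_by_study: dict[str, float]
    v2_tv: float
    q_tv: float
    v3_tv: float
    ka1: float
    ka2: float
    mtime: float
    f1: float
    omega_cl_by_study: dict[str, float]
    omega_v2: float
    omega_v3: float
    omega_ka1: float = 0.0
    omega_ka2: float = 0.0
    sigma_by_study: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("v2_tv", "q_tv", "v3_tv", "ka1", "ka2", "f1"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.mtime < 0:
            raise ValueError("mtime must be >= 0")
        for name in ("omega_v2", "omega_v3", "omega_ka1", "omega_ka2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for study, val in self.cl_tv_by_study.items():
            if val <= 0:
                raise ValueError(f"cl_tv for {study!r} must be > 0")
        for study, val in self.omega_cl_by_study.items():
            if val < 0:
                raise ValueError(f"omega_cl for {study!r} must be >= 0")
        for study, val in self.sigma_by_study.items():
            if val < 0:
                raise ValueError(f"sigma for {study!r} must be >= 0")

    def cl_tv(self, study: str) -> float:
        try:
            return self.cl_tv_by_study[study]
        except KeyError:
            raise KeyError(f"unknown study label {study!r}; known: "
                           f"{sorted(self.cl_tv_by_study)}") from None

    def omega_cl(self, study: str) -> float:
        try:
            return self.omega_cl_by_study[study]
        except KeyError:
            raise KeyError(f"unknown study label {study!r}") from None

    def sigma(self, study: str) -> float:
        try:
            return self.sigma_by_study[study]
        except KeyError:
            raise KeyError(f"no residual SD configured for study {study!r}") from None

    def with_updates(self, **kwargs) -> "PopulationModel":
        return replace(self, **kwargs)


def default_population() -> PopulationModel:
    """Final pediatric model: typical values at 70 kg with fixed absorption.

    The IIV standard deviations are working assumptions (they are needed to
    simulate realistic cohorts): clearance IIV is markedly larger in the
    sparse outpatient study, consistent with its wide post hoc clearance
    range, and volume IIV is moderate.
    """
    return PopulationModel(
        cl_tv_by_study={STUDY_RICH: 22.9, STUDY_SPARSE: 20.1},
        v2_tv=446.0,
        q_tv=16.9,
        v3_tv=248.0,
        ka1=0.792,
        ka2=3.87,
        mtime=0.734,
        f1=0.858,
        omega_cl_by_study={STUDY_RICH: 0.30, STUDY_SPARSE: 0.60},
        omega_v2=0.40,
        omega_v3=0.50,
        omega_ka1=0.0,
        omega_ka2=0.0,
        sigma_by_study={STUDY_RICH: 0.14, STUDY_SPARSE: 0.35},
    )
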