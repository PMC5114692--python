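"""Virtual pediatric cohorts and trial simulation for both sampling designs.

Two designs are emulated.  The rich design is a phase-1 single-dose study:
children 4–12 years receive 0.03 mg/kg of oral solution once and are sampled
13 times over 72 h (assay LLOQ 0.1 ng/mL).  The sparse design is a phase-3
outpatient study: children 1.7–18 years receive 0.04 mg/kg once daily capped
at 2 mg, with a week-4 adjustment to 0.06 mg/kg (insufficient response) or
0.02 mg/kg (tolerability) in a configurable fraction of subjects; sampling is
one 1–3 h post-dose sample on day 1 plus two 14–26 h troughs at steady state
around weeks 8 and 24 (LLOQ 0.2 ng/mL).

Demographics come from a simple growth model (piecewise-linear median weight
and height for age with log-normal scatter, serum creatinine linear in age)
tuned to the studies' published medians and ranges.  Record-level exclusion
artifacts — forced below-LLOQ values, missing sample times, missing dosing
information, uncollected samples, and one fully excluded subject — are
injected with configurable counts so that downstream filtering reproduces
realistic data-cleaning patterns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import PatientCovariates
from .dataset import COLUMNS, PKDataset
from .population import STUDY_RICH, STUDY_SPARSE, PopulationModel, default_population
from .structural_pk import PKParameters, predict_concentrations

__all__ = [
    "StudyDesign",
    "ExclusionArtifacts",
    "Subject",
    "rich_design",
    "sparse_design",
    "generate_cohort",
    "cohort_table",
    "simulate_trial",
    "inject_exclusion_artifacts",
    "median_weight_for_age",
    "median_height_for_age",
    "write_dataset",
    "read_dataset",
]

# growth-model anchors: combined-sex median weight (kg) and height (cm) by age
_AGE_KNOTS = np.array([0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 10.0, 12.0, 14.0, 16.0, 18.0])
_WEIGHT_KNOTS = np.array([7.6, 9.6, 12.3, 14.3, 16.3, 20.5, 25.5, 31.9, 40.0, 50.0, 58.0, 63.0])
_HEIGHT_KNOTS = np.array([67.0, 75.0, 87.0, 95.0, 102.0, 115.0, 128.0, 138.0, 150.0, 160.0, 168.0, 170.0])

#: log-scale SD of weight around the age median
WEIGHT_SCATTER_SD = 0.18

#: height co-varies with relative weight through a child allometric rule
HEIGHT_WEIGHT_EXPONENT = 0.3

HOURS_PER_DAY = 24.0

_FLAGS_COLS = ["BQL", "MISSTIME", "MISSDOSE", "MISSOBS"]


def median_weight_for_age(age_years: float | np.ndarray) -> float | np.ndarray:
    """Median body weight (kg) at a given age from the growth table."""
    return np.interp(age_years, _AGE_KNOTS, _WEIGHT_KNOTS)


def median_height_for_age(age_years: float | np.ndarray) -> float | np.ndarray:
    """Median height (cm) at a given age from the growth table."""
    return np.interp(age_years, _AGE_KNOTS, _HEIGHT_KNOTS)


@dataclass(frozen=True)
class ExclusionArtifacts:
    """Record-exclusion patterns injected into a simulated dataset.

    Each numeric field is an absolute row count when >= 1 and a fraction of
    observation rows when < 1.  ``uncollected`` rows are removed entirely
    (samples that were never drawn); the remaining categories stay in the
    dataset carrying the corresponding flag.  ``exclude_one_subject`` flags
    every observation of one (seed-stable) subject as missing dosing
    information, so that subject drops out of the analysis population.
    """

    bql: float = 0.0
    missing_time: float = 0.0
    missing_dose_info: float = 0.0
    missing_obs: float = 0.0
    uncollected: float = 0.0
    exclude_one_subject: bool = False

    def count(self, name: str, n_obs: int) -> int:
        value = getattr(self, name)
        if value < 0:
            raise ValueError(f"{name} must be >= 0")
        return int(round(value * n_obs)) if value < 1 else int(round(value))


@dataclass(frozen=True)
class StudyDesign:
    """Dosing, sampling, and assay description of one trial arm."""

    label: str
    per_kg_dose_mg: float
    cap_mg: float
    schedule: str  # "single" | "once_daily_adjusted"
    lloq_ng_ml: float
    n_subjects: int
    age_range: tuple[float, float]
    weight_bounds: tuple[float, float]
    sample_times_h: tuple[float, ...] = ()
    day1_window_h: tuple[float, float] = (1.0, 3.0)
    trough_window_h: tuple[float, float] = (14.0, 26.0)
    trough_weeks: tuple[int, int] = (8, 24)
    adjustment_week: int = 4
    uptitrate_fraction: float = 0.30
    uptitrate_per_kg_mg: float = 0.06
    downtitrate_fraction: float = 0.05
    downtitrate_per_kg_mg: float = 0.02
    age_skew: tuple[float, float] | None = None  # Beta(a, b) shape over the age range
    artifacts: ExclusionArtifacts = field(default_factory=ExclusionArtifacts)

    def __post_init__(self) -> None:
        if self.cap_mg <= 0:
            raise ValueError("cap_mg must be > 0")
        for lo, hi in (self.day1_window_h, self.trough_window_h):
            if not lo < hi:
                raise ValueError("sampling windows must satisfy lo < hi")

    def capped_dose_ug(self, per_kg_mg: float, weight_kg: float) -> float:
        return min(per_kg_mg * weight_kg, self.cap_mg) * 1000.0


def rich_design(n_subjects: int = 38) -> StudyDesign:
    """Single 0.03 mg/kg dose, 13 scheduled samples over 72 h, LLOQ 0.1."""
    return StudyDesign(
        label=STUDY_RICH,
        per_kg_dose_mg=0.03,
        cap_mg=2.0,
        schedule="single",
        lloq_ng_ml=0.1,
        n_subjects=n_subjects,
        age_range=(4.0, 12.0),
        weight_bounds=(15.0, 61.0),
        sample_times_h=(0.5, 1.0, 1.5, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0, 48.0, 72.0),
        artifacts=ExclusionArtifacts(missing_time=0.006),
    )


def sparse_design(n_subjects: int = 107) -> StudyDesign:
    """0.04 mg/kg once daily capped at 2 mg with week-4 adjustment; LLOQ 0.2.

    The default exclusion artifacts emulate outpatient data cleaning: ~8% of
    samples forced below the quantification limit on top of naturally censored
    values, ~7% with missing dosing information, occasional not-analyzed
    samples, ~9% never collected, and one subject excluded entirely.
    """
    return StudyDesign(
        label=STUDY_SPARSE,
        per_kg_dose_mg=0.04,
        cap_mg=2.0,
        schedule="once_daily_adjusted",
        lloq_ng_ml=0.2,
        n_subjects=n_subjects,
        age_range=(1.7, 18.0),
        weight_bounds=(11.0, 110.0),
        age_skew=(1.2, 1.8),
        artifacts=ExclusionArtifacts(
            bql=0.08, missing_dose_info=0.07, missing_obs=0.003,
            uncollected=0.09, exclude_one_subject=True,
        ),
    )


@dataclass(frozen=True)
class Subject:
    """One virtual patient: demographics plus the assigned dosing regimen."""

    sid: str
    study: str
    covariates: PatientCovariates
    initial_dose_ug: float
    adjusted_dose_ug: float  # equals initial dose when no adjustment applies
    dose_group: str = "maintain"  # maintain | uptitrate | downtitrate


def generate_cohort(design: StudyDesign, n: int | None = None,
                    seed: int = 0) -> list[Subject]:
    """Draw a virtual cohort with age-anchored demographics and assigned doses."""
    if n is None:
        n = design.n_subjects
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    lo, hi = design.age_range
    if design.age_skew is not None:
        a, b = design.age_skew
        ages = lo + (hi - lo) * rng.beta(a, b, size=n)
    else:
        ages = rng.uniform(lo, hi, size=n)
    w_med = median_weight_for_age(ages)
    weights = w_med * np.exp(rng.normal(0.0, WEIGHT_SCATTER_SD, size=n))
    weights = np.clip(weights, *design.weight_bounds)
    heights = (median_height_for_age(ages)
               * (weights / w_med) ** HEIGHT_WEIGHT_EXPONENT)
    scr = np.clip(20.0 + 2.2 * ages + rng.normal(0.0, 4.0, size=n), 15.0, None)
    sexes = np.where(rng.random(n) < 0.5, "F", "M")

    subjects: list[Subject] = []
    for i in range(n):
        cov = PatientCovariates(
            age_years=float(ages[i]), weight_kg=float(weights[i]),
            height_cm=float(heights[i]),
            serum_creatinine_umol_per_l=float(scr[i]), sex=str(sexes[i]),
        )
        d1 = design.capped_dose_ug(design.per_kg_dose_mg, cov.weight_kg)
        group = "maintain"
        d2 = d1
        if design.schedule == "once_daily_adjusted":
            u = rng.random()
            if u < design.uptitrate_fraction:
                group = "uptitrate"
                d2 = design.capped_dose_ug(design.uptitrate_per_kg_mg, cov.weight_kg)
            elif u < design.uptitrate_fraction + design.downtitrate_fraction:
                group = "downtitrate"
                d2 = design.capped_dose_ug(design.downtitrate_per_kg_mg, cov.weight_kg)
        subjects.append(Subject(
            sid=f"{design.label}-{i + 1:03d}", study=design.label, covariates=cov,
            initial_dose_ug=d1, adjusted_dose_ug=d2, dose_group=group,
        ))
    return subjects


def _subject_parameters(pop: PopulationModel, subj: Subject,
                        rng: np.random.Generator) -> PKParameters:
    from .covariates import RandomEffects, individual_parameters

    eta = RandomEffects(
        eta_cl=rng.normal(0.0, pop.omega_cl(subj.study)),
        eta_v2=rng.normal(0.0, pop.omega_v2),
        eta_v3=rng.normal(0.0, pop.omega_v3),
        eta_ka1=rng.normal(0.0, pop.omega_ka1) if pop.omega_ka1 > 0 else 0.0,
        eta_ka2=rng.normal(0.0, pop.omega_ka2) if pop.omega_ka2 > 0 else 0.0,
    )
    return individual_parameters(pop, subj.covariates, eta, study=subj.study)


def _dose_rows(design: StudyDesign, subj: Subject) -> list[dict]:
    """Dose events with II/ADDL patterns for one subject."""
    if design.schedule == "single":
        return [{"TIME": 0.0, "AMT": subj.initial_dose_ug, "II": 0.0, "ADDL": 0}]
    adj_day = design.adjustment_week * 7
    w8_day, w24_day = (w * 7 for w in design.trough_weeks)
    # daily dosing; the dose due on the morning of each trough visit is held
    # until after the blood draw, so troughs are 14-26 h after the last dose
    rows = [
        {"TIME": 0.0, "AMT": subj.initial_dose_ug, "II": HOURS_PER_DAY,
         "ADDL": adj_day - 1},
        {"TIME": adj_day * HOURS_PER_DAY, "AMT": subj.adjusted_dose_ug,
         "II": HOURS_PER_DAY, "ADDL": (w8_day - adj_day) - 1},
        {"TIME": (w8_day + 1) * HOURS_PER_DAY, "AMT": subj.adjusted_dose_ug,
         "II": HOURS_PER_DAY, "ADDL": (w24_day - w8_day) - 2},
    ]
    return rows


def _observation_times(design: StudyDesign, subj: Subject,
                       rng: np.random.Generator) -> np.ndarray:
    if design.schedule == "single":
        return np.asarray(design.sample_times_h, float)
    u1 = rng.uniform(*design.day1_window_h)
    u2 = rng.uniform(*design.trough_window_h)
    u3 = rng.uniform(*design.trough_window_h)
    w8_day, w24_day = (w * 7 for w in design.trough_weeks)
    t_w8 = (w8_day - 1) * HOURS_PER_DAY + u2
    t_w24 = (w24_day - 1) * HOURS_PER_DAY + u3
    return np.array([u1, t_w8, t_w24])


def simulate_trial(cohort: list[Subject], design: StudyDesign,
                   pop: PopulationModel | None = None, seed: int = 0,
                   apply_artifacts: bool = True) -> PKDataset:
    """Simulate observed concentrations for a cohort under a design.

    Per subject, random effects are drawn on the log scale, observations are
    the structural prediction multiplied by exp(ε) with ε ~ N(0, σ_study),
    and values below the assay LLOQ are flagged (the censored numeric value
    is retained).  With ``apply_artifacts`` the design's exclusion artifacts
    are injected afterwards using the same seed.
    """
    if pop is None:
        pop = default_population()
    for subj in cohort:
        if subj.study != design.label:
            raise ValueError(f"subject {subj.sid} belongs to study "
                             f"{subj.study!r}, not {design.label!r}")
    sigma = pop.sigma(design.label)
    if not math.isfinite(sigma) or sigma < 0:
        raise ValueError("residual SD must be finite and >= 0")
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for subj in cohort:
        params = _subject_parameters(pop, subj, rng)
        dose_rows = _dose_rows(design, subj)
        obs_times = _observation_times(design, subj, rng)
        dose_times, dose_amounts = _expand(dose_rows)
        pred = predict_concentrations(params, dose_times, dose_amounts, obs_times)
        if not np.all(np.isfinite(pred)):
            raise ValueError(f"non-finite prediction for subject {subj.sid}")
        eps = rng.normal(0.0, sigma, size=obs_times.size) if sigma > 0 else 0.0
        dv = pred * np.exp(eps)
        cov = subj.covariates
        base = {
            "ID": subj.sid, "STUDY": subj.study, "AGE": cov.age_years,
            "WT": cov.weight_kg, "HT": cov.height_cm,
            "SCR": cov.serum_creatinine_umol_per_l, "SEX": cov.sex,
        }
        for d in dose_rows:
            rows.append({**base, **d, "DV": np.nan, "EVID": 1, "MDV": 1,
                         "BQL": 0, "MISSTIME": 0, "MISSDOSE": 0, "MISSOBS": 0})
        for t_obs, value in zip(obs_times, np.atleast_1d(dv)):
            rows.append({**base, "TIME": float(t_obs), "AMT": 0.0,
                         "DV": float(value), "EVID": 0, "MDV": 0,
                         "II": 0.0, "ADDL": 0,
                         "BQL": int(value < design.lloq_ng_ml),
                         "MISSTIME": 0, "MISSDOSE": 0, "MISSOBS": 0})
    df = pd.DataFrame(rows, columns=COLUMNS)
    df = df.sort_values(["ID", "TIME", "EVID"],
                        kind="stable").reset_index(drop=True)
    ds = PKDataset(df)
    if apply_artifacts:
        ds = inject_exclusion_artifacts(ds, design.artifacts,
                                        lloq=design.lloq_ng_ml, seed=seed)
    return ds


def _expand(dose_rows: list[dict]) -> tuple[np.ndarray, np.ndarray]:
    times, amounts = [], []
    for d in dose_rows:
        for k in range(int(d["ADDL"]) + 1):
            times.append(d["TIME"] + k * d["II"])
            amounts.append(d["AMT"])
    order = np.argsort(times, kind="stable")
    return np.asarray(times, float)[order], np.asarray(amounts, float)[order]


def inject_exclusion_artifacts(dataset: PKDataset,
                               artifacts: ExclusionArtifacts,
                               lloq: float | None = None,
                               seed: int = 0) -> PKDataset:
    """Seed-stable injection of exclusion patterns into observation rows.

    Rows are chosen so that no subject other than the designated one (with
    ``exclude_one_subject``) loses its last usable observation: exactly one
    subject drops out of the analysis population when requested, never more.
    Rows that already carry a flag (e.g. naturally censored values) are never
    selected again, so requested counts add to what is already present.
    """
    df = dataset.records.copy()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5EED]))

    def obs_state() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        obs_mask = df["EVID"] == 0
        idx = df.index[obs_mask].to_numpy()
        sids = df.loc[idx, "ID"].to_numpy()
        flagged = (df.loc[idx, _FLAGS_COLS].to_numpy() == 1).any(axis=1)
        return idx, sids, flagged

    def pick_protected(n: int, idx, sids, flagged, protect=frozenset()):
        """Sequentially pick n unflagged rows, never taking a subject's last
        usable row (subjects in `protect` are exempt from selection)."""
        chosen: list[int] = []
        usable = ~flagged
        for _ in range(n):
            counts = {}
            for s, u in zip(sids, usable):
                counts[s] = counts.get(s, 0) + int(u)
            eligible = [k for k in range(idx.size)
                        if usable[k] and sids[k] not in protect
                        and counts[sids[k]] >= 2]
            if not eligible:
                break
            k = eligible[int(rng.integers(len(eligible)))]
            usable[k] = False
            chosen.append(k)
        return np.asarray(chosen, dtype=int)

    idx, sids, flagged = obs_state()
    n_obs0 = idx.size
    n_uncollected = artifacts.count("uncollected", n_obs0)
    if n_uncollected:
        drop_local = pick_protected(n_uncollected, idx, sids, flagged)
        df = df.drop(index=idx[drop_local])

    idx, sids, flagged = obs_state()
    victim = None
    if artifacts.exclude_one_subject and idx.size:
        unique = sorted(set(sids))
        victim = unique[int(rng.integers(len(unique)))]
        mask = sids == victim
        df.loc[idx[mask], "MISSDOSE"] = 1
        flagged |= mask

    protect = frozenset([victim]) if victim is not None else frozenset()

    def apply(column: str, n: int) -> np.ndarray:
        nonlocal flagged
        local = pick_protected(n, idx, sids, flagged, protect)
        flagged[local] = True
        rows = idx[local]
        df.loc[rows, column] = 1
        return rows

    n_missdose = artifacts.count("missing_dose_info", idx.size)
    already = int((df.loc[idx, "MISSDOSE"] == 1).sum())
    if n_missdose > already:
        apply("MISSDOSE", n_missdose - already)
    bql_rows = apply("BQL", artifacts.count("bql", idx.size))
    if bql_rows.size and lloq is not None:
        df.loc[bql_rows, "DV"] = np.minimum(
            df.loc[bql_rows, "DV"].to_numpy(),
            rng.uniform(0.25 * lloq, 0.95 * lloq, size=bql_rows.size))
    apply("MISSTIME", artifacts.count("missing_time", idx.size))
    apply("MISSOBS", artifacts.count("missing_obs", idx.size))
    return PKDataset(df.reset_index(drop=True))


def cohort_table(cohort: list[Subject]) -> pd.DataFrame:
    """Tidy covariate table (one row per subject) for CSV export."""
    return pd.DataFrame([{
        "id": s.sid,
        "age_years": s.covariates.age_years,
        "weight_kg": s.covariates.weight_kg,
        "height_cm": s.covariates.height_cm,
        "scr_umol_l": s.covariates.serum_creatinine_umol_per_l,
        "sex": s.covariates.sex,
        "study": s.study,
    } for s in cohort])


def write_dataset(dataset: PKDataset, path) -> None:
    """Write the NONMEM-dialect CSV (identity round trip with `read_dataset`)."""
    dataset.to_csv(path)


def read_dataset(path) -> PKDataset:
    return PKDataset.read_csv(path)
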