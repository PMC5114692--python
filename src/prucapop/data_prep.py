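"""Analysis-dataset preparation: deterministic record-exclusion filtering.

Observation rows are excluded when the measured concentration is below the
assay quantification limit (simple exclusion, the "M1" approach — no
likelihood-based censoring), when the sample or dose time is missing, when
dosing information is missing, or when the sample was never analyzed.  Dose
rows are never removed.  Subjects whose observations are all excluded drop
out of the analysis population; retained concentration values are never
modified.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import pandas as pd

from .dataset import PKDataset

__all__ = ["ExclusionReport", "filter_records"]


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping of the filtering step; retained = input − sum(excluded)."""

    n_input_records: int
    n_excluded_bql: int
    n_excluded_missing_time: int
    n_excluded_missing_dose_info: int
    n_excluded_other: int
    n_retained: int
    n_subjects_retained: int

    def __post_init__(self) -> None:
        excluded = (self.n_excluded_bql + self.n_excluded_missing_time
                    + self.n_excluded_missing_dose_info + self.n_excluded_other)
        if self.n_retained != self.n_input_records - excluded:
            raise ValueError("inconsistent exclusion counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(self)])

    def to_dict(self) -> dict:
        return asdict(self)


def filter_records(dataset: PKDataset,
                   lloq: float | None = None) -> tuple[PKDataset, ExclusionReport]:
    """Apply the exclusion rules to observation rows.

    A row is excluded if flagged below the quantification limit (or, when
    `lloq` is given, if its value falls below it), flagged missing-time,
    flagged missing-dose-information, or flagged as a missing/not-analyzed
    sample.  Rows meeting several conditions are counted once, in that
    priority order.  The operation is deterministic and idempotent.
    """
    df = dataset.records
    obs = df["EVID"] == 0
    bql = obs & ((df["BQL"] == 1) | ((df["DV"] < lloq) if lloq is not None else False))
    misstime = obs & (df["MISSTIME"] == 1) & ~bql
    missdose = obs & (df["MISSDOSE"] == 1) & ~bql & ~misstime
    other = obs & (df["MISSOBS"] == 1) & ~bql & ~misstime & ~missdose
    excluded = bql | misstime | missdose | other

    kept = PKDataset(df[~excluded].reset_index(drop=True))
    kept_obs = kept.observations
    report = ExclusionReport(
        n_input_records=int(obs.sum()),
        n_excluded_bql=int(bql.sum()),
        n_excluded_missing_time=int(misstime.sum()),
        n_excluded_missing_dose_info=int(missdose.sum()),
        n_excluded_other=int(other.sum()),
        n_retained=int(obs.sum() - excluded.sum()),
        n_subjects_retained=int(kept_obs["ID"].nunique()),
    )
    return kept, report
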