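"""Event-record dataset: one row per dose or observation, NONMEM dialect.

Columns follow the conventional event encoding: ``EVID=1`` dose rows carry an
amount (``AMT``, µg) and optionally a repeat pattern (``II`` hours between
repeats, ``ADDL`` additional doses); ``EVID=0`` observation rows carry the
measured concentration (``DV``, ng/mL).  Exclusion-relevant flags (below
quantification limit, missing sample time, missing dosing information,
missing/not-analyzed sample) travel with the observation rows so that the
data-preparation step is a pure, reproducible filter.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["PKDataset", "COLUMNS"]

COLUMNS = [
    "ID", "TIME", "AMT", "DV", "EVID", "MDV", "II", "ADDL",
    "BQL", "MISSTIME", "MISSDOSE", "MISSOBS",
    "STUDY", "AGE", "WT", "HT", "SCR", "SEX",
]

_FLAGS = ["BQL", "MISSTIME", "MISSDOSE", "MISSOBS"]


@dataclass
class PKDataset:
    """Validated wrapper around the event-record table."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"dataset is missing columns: {missing}")
        df = df[COLUMNS].reset_index(drop=True)
        for col in ("TIME", "AMT", "DV", "II", "AGE", "WT", "HT", "SCR"):
            df[col] = df[col].astype(float)
        for col in ("EVID", "MDV", "ADDL", *_FLAGS):
            df[col] = df[col].astype(int)
        self._validate(df)
        self.records = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if not df["EVID"].isin([0, 1]).all():
            raise ValueError("EVID must be 0 (observation) or 1 (dose)")
        doses = df["EVID"] == 1
        if (df.loc[doses, "MDV"] != 1).any():
            raise ValueError("dose rows must carry MDV=1 (no DV)")
        if (df.loc[~doses, "AMT"] != 0).any():
            raise ValueError("observation rows must not carry an amount")
        if (df.loc[doses, "AMT"] < 0).any():
            raise ValueError("dose amounts must be >= 0")
        for sid, grp in df.groupby("ID", sort=False):
            t = grp["TIME"].to_numpy()
            if np.any(np.diff(t) < 0):
                raise ValueError(f"times are not non-decreasing for subject {sid!r}")

    # -- views -------------------------------------------------------------

    @property
    def observations(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 0]

    @property
    def doses(self) -> pd.DataFrame:
        return self.records[self.records["EVID"] == 1]

    @property
    def subject_ids(self) -> list:
        return list(dict.fromkeys(self.records["ID"]))

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def subject(self, sid) -> pd.DataFrame:
        return self.records[self.records["ID"] == sid]

    def expanded_doses(self, sid) -> tuple[np.ndarray, np.ndarray]:
        """Explicit (times, amounts) for a subject, II/ADDL patterns unrolled."""
        rows = self.records[(self.records["ID"] == sid) & (self.records["EVID"] == 1)]
        times: list[float] = []
        amounts: list[float] = []
        for _, row in rows.iterrows():
            n_rep = int(row["ADDL"]) + 1
            ii = float(row["II"])
            for k in range(n_rep):
                times.append(float(row["TIME"]) + k * ii)
                amounts.append(float(row["AMT"]))
        order = np.argsort(times, kind="stable")
        return np.asarray(times, float)[order], np.asarray(amounts, float)[order]

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        # %.17g round-trips float64 exactly through text
        self.records.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "PKDataset":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        bad_rows = []
        for col in ("TIME", "EVID"):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            bad_rows.extend((df.index[bad] + 2).tolist())  # +2: header + 1-based
        if bad_rows:
            raise ValueError(f"{path}: unparseable rows at lines {sorted(set(bad_rows))}")
        return cls(df)

    def copy(self) -> "PKDataset":
        return PKDataset(self.records.copy())

    def equals(self, other: "PKDataset") -> bool:
        return self.records.equals(other.records)
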