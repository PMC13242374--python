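"""Origin-destination flow aggregation.

The gravity model's dependent variable is T_ij, the count of patients from
ZIP code i treated at hospital j.  Only observed (positive) flows are stored:
the log-linear estimator is defined on positive counts, while prediction
scores every patient-hospital pair regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd


@dataclass
class FlowTable:
    """Positive origin-destination counts with marginal bookkeeping.

    ``entries`` has columns ``origin_zip``, ``hospital_id``, ``count``
    with every stored count >= 1; the total equals the cohort size.
    """

    entries: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["origin_zip", "hospital_id", "count"]
        missing = [c for c in required if c not in self.entries.columns]
        if missing:
            raise ValueError(f"flow table missing columns: {missing}")
        if (self.entries["count"] < 1).any():
            raise ValueError("flow table must store only positive counts")

    @property
    def origin_index(self) -> list:
        return sorted(self.entries["origin_zip"].unique())

    @property
    def destination_index(self) -> list:
        return sorted(self.entries["hospital_id"].unique())

    @property
    def total(self) -> int:
        return int(self.entries["count"].sum())

    def origin_totals(self) -> pd.Series:
        return self.entries.groupby("origin_zip")["count"].sum()

    def destination_totals(self) -> pd.Series:
        """Column sums; equal to cohort hospital volumes V_j by construction."""
        return self.entries.groupby("hospital_id")["count"].sum()

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FlowTable":
        return cls(pd.read_csv(path, dtype={"origin_zip": str, "hospital_id": str}))


def aggregate_flows(included_records: pd.DataFrame) -> FlowTable:
    """Count patients per (home ZIP, hospital) pair after exclusions."""
    if len(included_records) == 0:
        raise ValueError("cannot aggregate flows from an empty cohort")
    entries = (
        included_records.groupby(["home_zip", "hospital_id"], sort=True)
        .size()
        .rename("count")
        .reset_index()
        .rename(columns={"home_zip": "origin_zip"})
    )
    return FlowTable(entries)
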