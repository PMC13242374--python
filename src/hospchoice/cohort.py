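"""Cohort ingestion: patient and hospital tables, exclusions, hospital volume.

The cohort is a table of surgical admissions (one row per patient) plus a
hospital attribute table.  Records are excluded when the patient or hospital
ZIP code is missing or cannot be resolved against the centroid table, and
then when the patient's home ZIP lies outside the study states.  Hospital
volume is the number of cohort patients treated at the hospital.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

PATIENT_COLUMNS = [
    "patient_id", "home_zip", "hospital_id", "state", "age", "sex",
    "race_ethnicity", "rural_urban", "payer", "sdi", "died_in_hospital",
]
HOSPITAL_COLUMNS = ["hospital_id", "zip", "state", "med_school", "rural", "coc", "centralized"]
HOSPITAL_COVARIATES = ["med_school", "rural", "coc", "centralized"]

SEX_LEVELS = ["male", "female"]
RACE_LEVELS = ["nh_white", "black", "hispanic", "other"]
RURAL_URBAN_LEVELS = ["major_metro", "small_metro", "micropolitan_rural"]
PAYER_LEVELS = ["medicare", "medicaid", "private", "other"]

#: ICD-10-PCS procedure codes defining the index operation
#: (pancreaticoduodenectomy): at least one duodenal code AND at least one
#: pancreatic code.  Documented for reference; no claims parsing happens here.
ICD10_PCS_DUODENUM = ("0DB90ZX", "0DB90ZZ", "0DB94ZX", "0DB94ZZ", "0DT90ZZ", "0DT94ZZ")
ICD10_PCS_PANCREAS = ("0FBG0ZX", "0FBG0ZZ", "0FBG4ZX", "0FBG4ZZ", "0FTG0ZZ", "0FTG4ZZ")


@dataclass(frozen=True)
class ExclusionLog:
    """Accounting of cohort exclusions; counts always conserve the input."""

    n_input: int
    n_missing_zip: int
    n_out_of_state: int
    n_included: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_missing_zip + self.n_out_of_state + self.n_included:
            raise ValueError(f"exclusion log does not conserve records: {self}")


def read_patients(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"home_zip": str, "patient_id": str, "hospital_id": str})
    missing = [c for c in PATIENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"patient table missing columns: {missing}")
    return df


def read_hospitals(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"hospital_id": str, "zip": str})
    missing = [c for c in HOSPITAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"hospital table missing columns: {missing}")
    for c in HOSPITAL_COVARIATES:
        df[c] = df[c].astype(int).astype(bool)
    return df


def read_centroids(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"zip": str})
    missing = [c for c in ("zip", "lat", "lon", "state") if c not in df.columns]
    if missing:
        raise ValueError(f"centroid table missing columns: {missing}")
    if df["zip"].duplicated().any():
        dups = df.loc[df["zip"].duplicated(), "zip"].tolist()
        raise ValueError(f"duplicate ZIP codes in centroid table: {dups[:10]}")
    return df.set_index("zip")


def _is_blank(series: pd.Series) -> pd.Series:
    s = series.astype("string")
    return s.isna() | (s.str.strip() == "")


def apply_exclusions(
    records: pd.DataFrame,
    valid_states: Iterable[str],
    centroids: pd.DataFrame,
    hospital_zips: Mapping[str, str] | pd.Series | None = None,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Drop records with missing/unresolvable ZIPs, then out-of-state homes.

    A record counts as *missing-ZIP* when the home ZIP is blank or absent
    from the centroid table, or (when ``hospital_zips`` is supplied) the
    treating hospital has no resolvable ZIP.  Remaining records whose home
    ZIP belongs to a state outside ``valid_states`` count as *out-of-state*.
    Row order of the survivors is preserved.
    """
    valid_states = set(valid_states)
    if not valid_states:
        raise ValueError("valid_states must be non-empty")

    missing = _is_blank(records["home_zip"]) | ~records["home_zip"].isin(centroids.index)
    if hospital_zips is not None:
        if isinstance(hospital_zips, pd.Series):
            hospital_zips = hospital_zips.to_dict()
        hzip = records["hospital_id"].map(hospital_zips)
        missing |= _is_blank(hzip) | ~hzip.isin(centroids.index)

    after_missing = records.loc[~missing]
    home_state = after_missing["home_zip"].map(centroids["state"])
    out_of_state = ~home_state.isin(valid_states)

    included = after_missing.loc[~out_of_state]
    log = ExclusionLog(
        n_input=len(records),
        n_missing_zip=int(missing.sum()),
        n_out_of_state=int(out_of_state.sum()),
        n_included=len(included),
    )
    return included, log


def compute_hospital_volume(included_records: pd.DataFrame) -> pd.Series:
    """Cohort volume V_j per hospital: the count of included patients treated there.

    The sum over hospitals equals the included-cohort size, and every hospital
    appearing in the cohort has volume >= 1.
    """
    if len(included_records) == 0:
        raise ValueError("cannot compute hospital volume on an empty cohort")
    volumes = included_records["hospital_id"].value_counts().sort_index()
    volumes.name = "volume"
    return volumes


def volume_summary(
    volumes: pd.Series,
    hospital_states: Mapping[str, str] | pd.Series | None = None,
) -> pd.DataFrame:
    """Median and interquartile range of hospital volume, overall and per state.

    Quartiles use linear interpolation between order statistics.
    """
    if len(volumes) == 0:
        raise ValueError("volumes must be non-empty")

    def _row(v: pd.Series) -> dict:
        q1, med, q3 = np.percentile(v.to_numpy(dtype=float), [25, 50, 75])
        return {"n_hospitals": len(v), "median": med, "q1": q1, "q3": q3}

    rows = {"overall": _row(volumes)}
    if hospital_states is not None:
        if isinstance(hospital_states, pd.Series):
            hospital_states = hospital_states.to_dict()
        states = pd.Series({h: hospital_states[h] for h in volumes.index})
        for state, idx in states.groupby(states).groups.items():
            rows[str(state)] = _row(volumes.loc[idx])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "stratum"
    return out
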