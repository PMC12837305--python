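"""Cohort data model and CSV I/O.

A cohort is a long-format table: one row per animal x sampling event, with
the ACTH concentration in pg/mL (strictly positive when present; missing
values are first-class because the exclusion rules count months without a
measurement).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendar import CalendarError, canonical_label, get_event
from ._tables import EQUID_TYPES

SEXES = ("female", "male")
AGE_SENIOR_THRESHOLD = 15.0  # strictly greater than 15 years -> senior

COLUMNS = [
    "equid_id", "equid_type", "location", "sex", "age_years",
    "age_class", "event", "collection_date", "acth_pg_ml",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan", "ND", "None"}


class SchemaError(ValueError):
    """Raised when a cohort table violates the data contract."""


def age_class_of(age_years: float) -> str:
    """Binary age classing: ≤15 years young, >15 senior (15.0 is young)."""
    return "senior" if age_years > AGE_SENIOR_THRESHOLD else "young"


@dataclass(frozen=True)
class ACTHRecord:
    """One baseline ACTH measurement."""
    equid_id: str
    equid_type: str
    location: str
    sex: str
    age_years: float
    event: str                       # canonical event label
    acth_pg_ml: float | None = None  # None = no measurement
    collection_date: _dt.date | None = None
    age_class: str = field(default="")

    def __post_init__(self):
        if not self.age_class:
            object.__setattr__(self, "age_class", age_class_of(self.age_years))


@dataclass
class CohortTable:
    """Validated long-format cohort with one row per (animal, event)."""

    data: pd.DataFrame
    provenance: str = "observed"  # observed | synthetic

    def __post_init__(self):
        self.data = _validate(self.data)

    # -- convenience accessors -------------------------------------------------
    @property
    def animals(self) -> pd.DataFrame:
        """One row per animal with its constant covariates."""
        cols = ["equid_id", "equid_type", "location", "sex", "age_years", "age_class"]
        return (self.data[cols].drop_duplicates("equid_id")
                .set_index("equid_id", drop=False))

    def __len__(self) -> int:
        return len(self.data)

    def subset_animals(self, keep_ids) -> "CohortTable":
        keep = set(keep_ids)
        return CohortTable(self.data[self.data["equid_id"].isin(keep)].copy(),
                           provenance=self.provenance)


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    missing_cols = [c for c in COLUMNS if c not in df.columns and c not in ("age_class", "collection_date")]
    if missing_cols:
        raise SchemaError(f"missing required columns: {missing_cols}")
    df = df.copy()

    df["event"] = df["event"].map(canonical_label)
    bad = sorted(set(df["event"]) - {e for e in df["event"] if _known_event(e)})
    if bad:
        raise SchemaError(f"unknown sampling event labels: {bad}")

    dup = df.duplicated(subset=["equid_id", "event"])
    if dup.any():
        rows = df.index[dup].tolist()
        pairs = df.loc[dup, ["equid_id", "event"]].to_records(index=False).tolist()
        raise SchemaError(f"duplicate (equid_id, event) pairs at rows {rows}: {pairs}")

    unknown_types = sorted(set(df["equid_type"]) - set(EQUID_TYPES))
    if unknown_types:
        raise SchemaError(f"unknown equid_type values: {unknown_types}")
    unknown_sex = sorted(set(df["sex"]) - set(SEXES))
    if unknown_sex:
        raise SchemaError(f"unknown sex values: {unknown_sex}")

    df["age_years"] = df["age_years"].astype(float)
    if (df["age_years"] < 0).any():
        rows = df.index[df["age_years"] < 0].tolist()
        raise SchemaError(f"negative age_years at rows {rows}")

    derived = df["age_years"].map(age_class_of)
    if "age_class" not in df.columns:
        df["age_class"] = derived
    else:
        df["age_class"] = df["age_class"].where(
            df["age_class"].isin(["young", "senior"]), derived)
        mismatch = df["age_class"] != derived
        if mismatch.any():
            rows = df.index[mismatch].tolist()
            raise SchemaError(
                f"age_class inconsistent with the >15-year threshold at rows {rows}")

    df["acth_pg_ml"] = pd.to_numeric(df["acth_pg_ml"], errors="coerce")
    nonpos = df["acth_pg_ml"].notna() & (df["acth_pg_ml"] <= 0)
    if nonpos.any():
        rows = df.index[nonpos].tolist()
        raise SchemaError(f"non-positive ACTH concentrations at rows {rows}")

    if "collection_date" not in df.columns:
        df["collection_date"] = pd.NaT
    else:
        df["collection_date"] = pd.to_datetime(df["collection_date"], errors="coerce")
        dated = df["collection_date"].notna()
        for i in df.index[dated]:
            ev = get_event(df.at[i, "event"])
            if not ev.contains(df.at[i, "collection_date"].date()):
                raise SchemaError(
                    f"row {i}: collection_date {df.at[i, 'collection_date'].date()} "
                    f"outside the bounds of event {ev.label}")

    # every animal keeps constant type/sex/location across its records
    for col in ("equid_type", "sex", "location"):
        per = df.groupby("equid_id")[col].nunique()
        bad_ids = per.index[per > 1].tolist()
        if bad_ids:
            raise SchemaError(f"animals with inconsistent {col}: {bad_ids}")

    return df[COLUMNS].reset_index(drop=True)


def _known_event(label: str) -> bool:
    try:
        get_event(label)
        return True
    except CalendarError:
        return False


def load_cohort(path, provenance: str = "observed") -> CohortTable:
    """Read a cohort CSV (RFC-4180, header mandatory) and validate it.

    Missing ACTH may be an empty cell or one of the designated tokens
    (NA/NaN/ND).  ``age_class`` is derived from ``age_years`` when absent.
    """
    df = pd.read_csv(path, dtype={"equid_id": str, "location": str},
                     na_values=sorted(MISSING_TOKENS), keep_default_na=True)
    return CohortTable(df, provenance=provenance)


def write_cohort(cohort: CohortTable, path) -> None:
    """Write a cohort CSV that round-trips through :func:`load_cohort`."""
    out = cohort.data.copy()
    out["collection_date"] = out["collection_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)
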