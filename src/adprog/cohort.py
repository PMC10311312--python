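"""Longitudinal cohort container and plain-CSV reader/writer.

A cohort is a set of patients, each carrying a time-ordered sequence of
clinical visits (numeric longitudinal features, age at visit, a diagnosis
label in {CN, MCI, AD}) plus cross-sectional demographics that are constant
per patient (gender, race, ethnicity, education years, APOE-e4 allele count).

The on-disk format is a wide visit table: one CSV row per patient-visit,
demographic columns repeated on every row.  Missing values are empty cells
or ``NA``; they are preserved as missing (never coerced to zero).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import IntegrityError, SchemaError

DIAGNOSES = ("CN", "MCI", "AD")

#: binary outcome coding used throughout: MCI -> 0, AD -> 1
LABEL_MAP = {"MCI": 0, "AD": 1}

DEMOGRAPHIC_COLUMNS = ("gender", "race", "ethnicity", "education", "apoe4")
RESERVED_COLUMNS = ("patient_id", "visit_month", "age", "diagnosis") + DEMOGRAPHIC_COLUMNS


@dataclass(frozen=True)
class Visit:
    """One clinical visit of one patient."""

    patient_id: str
    visit_index: int  # ordinal, 1-based within patient
    month: float  # months from the patient's first visit
    age: float  # years; NaN until imputed
    diagnosis: str  # one of DIAGNOSES
    features: dict[str, float]  # may contain NaN before imputation


@dataclass(frozen=True)
class Demographics:
    """Cross-sectional per-patient attributes."""

    gender: str
    race: str
    ethnicity: str
    education: float  # years
    apoe4: int  # e4 allele count in {0, 1, 2}


@dataclass
class Schema:
    """Column-name mapping for :func:`load_cohort`.

    ``diagnosis_map`` folds source vocabularies onto {CN, MCI, AD}
    (e.g. ADNI's ``LMCI``/``EMCI`` subtypes both map to ``MCI``).
    ``feature_columns=None`` means: every column that is neither reserved
    nor demographic is a longitudinal feature.
    """

    patient_id: str = "patient_id"
    visit_month: str = "visit_month"
    age: str = "age"
    diagnosis: str = "diagnosis"
    feature_columns: list[str] | None = None
    demographic_columns: dict[str, str] = field(
        default_factory=lambda: {c: c for c in DEMOGRAPHIC_COLUMNS}
    )
    diagnosis_map: dict[str, str] = field(default_factory=dict)


class Cohort:
    """In-memory cohort: a visit table plus a demographics table.

    ``visits`` has columns ``patient_id, visit_index, visit_month, age,
    diagnosis`` followed by the longitudinal feature columns; one row per
    visit, sorted by (patient, visit_index).  ``demographics`` is indexed by
    patient_id.  Both are pandas DataFrames, the canonical containers for
    this kind of tabular longitudinal data.
    """

    def __init__(self, visits: pd.DataFrame, demographics: pd.DataFrame,
                 feature_names: list[str]):
        self.visits = visits.reset_index(drop=True)
        self.demographics = demographics
        self.feature_names = list(feature_names)

    # -- basic accessors -------------------------------------------------

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.visits["patient_id"]))

    @property
    def n_patients(self) -> int:
        return self.visits["patient_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def patient_visits(self, patient_id: str) -> pd.DataFrame:
        sub = self.visits[self.visits["patient_id"] == patient_id]
        return sub.sort_values("visit_index")

    def get_visits(self, patient_id: str) -> list[Visit]:
        out = []
        for _, row in self.patient_visits(patient_id).iterrows():
            out.append(Visit(
                patient_id=row["patient_id"],
                visit_index=int(row["visit_index"]),
                month=float(row["visit_month"]),
                age=float(row["age"]),
                diagnosis=row["diagnosis"],
                features={f: row[f] for f in self.feature_names},
            ))
        return out

    def get_demographics(self, patient_id: str) -> Demographics:
        row = self.demographics.loc[patient_id]
        return Demographics(
            gender=row["gender"], race=row["race"], ethnicity=row["ethnicity"],
            education=float(row["education"]), apoe4=int(row["apoe4"]),
        )

    def iter_patients(self) -> Iterator[tuple[str, pd.DataFrame]]:
        for pid in self.patient_ids:
            yield pid, self.patient_visits(pid)

    def label_series(self, patient_id: str) -> pd.Series:
        """Binary per-visit outcome (0 = MCI, 1 = AD), indexed by visit_index.

        Defined only on visits whose diagnosis is MCI or AD; CN visits are
        absent from the series.
        """
        sub = self.patient_visits(patient_id)
        sub = sub[sub["diagnosis"].isin(LABEL_MAP)]
        return pd.Series(
            sub["diagnosis"].map(LABEL_MAP).to_numpy(),
            index=sub["visit_index"].to_numpy(), dtype=int,
        )

    def is_converter(self, patient_id: str) -> bool:
        """True if the patient's record ever reaches an AD diagnosis."""
        return bool((self.patient_visits(patient_id)["diagnosis"] == "AD").any())

    def subset(self, patient_ids: list[str]) -> "Cohort":
        keep = set(patient_ids)
        visits = self.visits[self.visits["patient_id"].isin(keep)].copy()
        demo = self.demographics.loc[[p for p in self.patient_ids if p in keep]]
        return Cohort(visits, demo, self.feature_names)

    def copy(self) -> "Cohort":
        return Cohort(self.visits.copy(), self.demographics.copy(),
                      list(self.feature_names))

    def equals(self, other: "Cohort") -> bool:
        if self.feature_names != other.feature_names:
            return False
        cols = ["patient_id", "visit_index", "visit_month", "age", "diagnosis"] \
            + self.feature_names
        a = self.visits[cols].reset_index(drop=True)
        b = other.visits[cols].reset_index(drop=True)
        try:
            pd.testing.assert_frame_equal(a, b, check_dtype=False,
                                          check_exact=False, rtol=1e-12)
            pd.testing.assert_frame_equal(
                self.demographics.sort_index(), other.demographics.sort_index(),
                check_dtype=False, check_exact=False, rtol=1e-12)
        except AssertionError:
            return False
        return True


def load_cohort(path, schema: Schema | None = None) -> Cohort:
    """Read a wide-format visit CSV into a :class:`Cohort`.

    Visits are grouped by patient and ordered by the visit-month column when
    present, else by file order.  Empty cells and ``NA`` parse as missing.
    Diagnosis strings outside {CN, MCI, AD} (after ``schema.diagnosis_map``)
    raise :class:`IntegrityError`; duplicate (patient, month) rows too.
    """
    schema = schema or Schema()
    df = pd.read_csv(path, dtype={schema.patient_id: str},
                     keep_default_na=True, na_values=[""])

    for col in (schema.patient_id, schema.diagnosis, schema.age):
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")

    demo_map = schema.demographic_columns
    missing_demo = [c for c in demo_map.values() if c not in df.columns]
    if missing_demo:
        raise SchemaError(f"demographic columns missing: {missing_demo}")

    # normalise diagnosis vocabulary
    diag = df[schema.diagnosis].astype(str).map(
        lambda d: schema.diagnosis_map.get(d, d))
    bad = sorted(set(diag) - set(DIAGNOSES))
    if bad:
        raise IntegrityError(
            f"unmapped diagnosis values {bad}; extend schema.diagnosis_map")

    if schema.feature_columns is not None:
        feature_names = list(schema.feature_columns)
        absent = [f for f in feature_names if f not in df.columns]
        if absent:
            raise SchemaError(f"feature columns missing: {absent}")
    else:
        reserved = {schema.patient_id, schema.visit_month, schema.age,
                    schema.diagnosis, *demo_map.values()}
        feature_names = [c for c in df.columns if c not in reserved]

    out = pd.DataFrame({
        "patient_id": df[schema.patient_id],
        "visit_month": pd.to_numeric(df[schema.visit_month], errors="coerce")
        if schema.visit_month in df.columns else np.arange(len(df), dtype=float),
        "age": pd.to_numeric(df[schema.age], errors="coerce"),
        "diagnosis": diag,
    })
    for f in feature_names:
        out[f] = pd.to_numeric(df[f], errors="coerce")

    has_month = schema.visit_month in df.columns
    if has_month:
        dup = out.duplicated(subset=["patient_id", "visit_month"])
        if dup.any():
            pid = out.loc[dup.idxmax(), "patient_id"]
            raise IntegrityError(f"duplicate (patient, visit_month) row for {pid!r}")

    # stable ordering: month when available, else original file order per patient
    out["_ord"] = np.arange(len(out))
    sort_keys = ["patient_id", "visit_month", "_ord"] if has_month \
        else ["patient_id", "_ord"]
    out = out.sort_values(sort_keys, kind="stable").reset_index(drop=True)
    out["visit_index"] = out.groupby("patient_id").cumcount() + 1
    out = out.drop(columns="_ord")
    out = out[["patient_id", "visit_index", "visit_month", "age", "diagnosis"]
              + feature_names]

    demo = pd.DataFrame({
        "patient_id": df[schema.patient_id],
        **{std: df[src] for std, src in demo_map.items()},
    }).drop_duplicates("patient_id").set_index("patient_id")
    demo["education"] = pd.to_numeric(demo["education"], errors="coerce")
    demo["apoe4"] = pd.to_numeric(demo["apoe4"], errors="coerce").astype("Int64")

    return Cohort(out, demo, feature_names)


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort back to wide CSV; inverse of :func:`load_cohort`.

    Demographic columns are repeated on every visit row; missing values
    serialize as empty cells.
    """
    df = cohort.visits.drop(columns="visit_index").copy()
    demo = cohort.demographics
    for col in DEMOGRAPHIC_COLUMNS:
        df[col] = df["patient_id"].map(demo[col]).to_numpy()
    df.to_csv(path, index=False, na_rep="")


def cohort_to_csv_string(cohort: Cohort) -> str:
    buf = io.StringIO()
    write_cohort(cohort, buf)
    return buf.getvalue()
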