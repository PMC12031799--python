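"""Patient-level data model and CSV I/O.

A record is one child who underwent voiding cystourethrography (VCUG), coded
as binary predictors plus the binary outcome ``severe_vur`` (reflux grade 4-5).
The kidney-scar fields (``any_scar``, ``multiple_scars``) are *defined only
when a DMSA scan was performed*; when ``dmsa_done`` is 0 they are a distinct
missing state (``None`` in memory, ``NA`` in CSV), never 0 -- a scar-negative
child and an unscanned child must stay distinguishable.

Logical structure enforced as invariants:

* imaging: ``utd_p3`` => ``hydronephrosis`` => ``usg_abnormal``
* scintigraphy: ``multiple_scars`` => ``any_scar``; both missing iff no DMSA
* infection: ``non_ecoli`` => ``uti``; ``recurrent_uti`` => ``uti``
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields, replace
from typing import Iterator, Optional, Sequence

import pandas as pd

from .errors import CohortValidationError, SchemaError

logger = logging.getLogger(__name__)

#: Bit-exact CSV header, in order.
CSV_COLUMNS = (
    "patient_id",
    "age_lt2",
    "male",
    "uti",
    "recurrent_uti",
    "non_ecoli",
    "usg_abnormal",
    "hydronephrosis",
    "utd_p3",
    "dmsa_done",
    "any_scar",
    "multiple_scars",
    "severe_vur",
)

#: Columns that may legitimately be missing (scar fields when DMSA absent).
MISSABLE_COLUMNS = ("any_scar", "multiple_scars")

#: Predictor variables in the reference display order (the outcome and the
#: availability flag are not candidate predictors).
PREDICTOR_VARIABLES = (
    "age_lt2",
    "male",
    "uti",
    "recurrent_uti",
    "non_ecoli",
    "usg_abnormal",
    "hydronephrosis",
    "utd_p3",
    "any_scar",
    "multiple_scars",
)

_MISSING_TOKENS = {"", "na", "nan", "none"}


@dataclass(frozen=True)
class PatientRecord:
    """One child's coded predictors, modality availability, and outcome."""

    patient_id: str
    age_lt2: int
    male: int
    uti: int
    recurrent_uti: int
    non_ecoli: int
    usg_abnormal: int
    hydronephrosis: int
    utd_p3: int
    dmsa_done: int
    any_scar: Optional[int]
    multiple_scars: Optional[int]
    severe_vur: int
    age_months: Optional[float] = None

    def get(self, variable: str):
        """Value of *variable*; raises SchemaError for unknown names."""
        if variable not in _FIELD_NAMES:
            raise SchemaError(f"unknown variable {variable!r}")
        return getattr(self, variable)

    def violations(self) -> list[str]:
        """Names of every invariant this record breaks (empty if valid)."""
        out: list[str] = []
        for name in CSV_COLUMNS[1:]:
            v = getattr(self, name)
            if name in MISSABLE_COLUMNS and v is None:
                continue
            if v not in (0, 1):
                out.append(f"domain: {name}={v!r} not in {{0,1}}")
        if self.utd_p3 == 1 and self.hydronephrosis != 1:
            out.append("imaging hierarchy: utd_p3=1 requires hydronephrosis=1")
        if self.hydronephrosis == 1 and self.usg_abnormal != 1:
            out.append("imaging hierarchy: hydronephrosis=1 requires usg_abnormal=1")
        if self.non_ecoli == 1 and self.uti != 1:
            out.append("infection hierarchy: non_ecoli=1 requires uti=1")
        if self.recurrent_uti == 1 and self.uti != 1:
            out.append("infection hierarchy: recurrent_uti=1 requires uti=1")
        if self.dmsa_done == 0:
            if self.any_scar is not None or self.multiple_scars is not None:
                out.append("scar fields must be NA when dmsa_done=0")
        else:
            if self.any_scar is None or self.multiple_scars is None:
                out.append("scar fields must be observed when dmsa_done=1")
            elif self.multiple_scars == 1 and self.any_scar != 1:
                out.append("scar hierarchy: multiple_scars=1 requires any_scar=1")
        if self.age_months is not None:
            if (self.age_months < 24) != bool(self.age_lt2):
                out.append(
                    f"age_months={self.age_months} inconsistent with age_lt2={self.age_lt2}"
                )
        return out


_FIELD_NAMES = {f.name for f in fields(PatientRecord)}


@dataclass(frozen=True)
class Violation:
    """One invariant breach: which record, which rule."""

    patient_id: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.patient_id}] {self.rule}"


@dataclass(frozen=True)
class Cohort:
    """An ordered collection of patient records with a provenance label."""

    records: tuple[PatientRecord, ...]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.records)

    def with_provenance(self, provenance: str) -> "Cohort":
        return replace(self, provenance=provenance)

    def to_frame(self) -> pd.DataFrame:
        """Cohort as a DataFrame; scar columns use pandas' nullable Int64."""
        from dataclasses import asdict

        df = pd.DataFrame(
            [asdict(r) for r in self.records],
            columns=list(CSV_COLUMNS) + ["age_months"],
        )
        for col in MISSABLE_COLUMNS:
            df[col] = df[col].astype("Int64")
        if df["age_months"].isna().all():
            df = df.drop(columns=["age_months"])
        return df


def validate_cohort(cohort: Cohort) -> list[Violation]:
    """All invariant violations in *cohort* (empty list iff fully valid).

    Purely a reporting operation; use ``strict=True`` reading to abort instead.
    """
    out: list[Violation] = []
    seen: set[str] = set()
    for rec in cohort:
        if rec.patient_id in seen:
            out.append(Violation(rec.patient_id, "duplicate patient_id"))
        seen.add(rec.patient_id)
        out.extend(Violation(rec.patient_id, rule) for rule in rec.violations())
    return out


def _parse_cell(raw, column: str, row_number: int):
    if raw is None:
        raw = ""
    text = str(raw).strip()
    if text.lower() in _MISSING_TOKENS:
        if column in MISSABLE_COLUMNS:
            return None
        raise SchemaError(
            f"row {row_number}: column {column!r} may not be missing"
        )
    if text in ("0", "1"):
        return int(text)
    # tolerate float-formatted exports ("1.0")
    try:
        value = float(text)
    except ValueError:
        value = None
    if value in (0.0, 1.0):
        return int(value)
    raise SchemaError(
        f"row {row_number}: non-binary value {text!r} in column {column!r}"
    )


def read_cohort_csv(path, strict: bool = True, provenance: str | None = None) -> Cohort:
    """Read a cohort from CSV.

    The header must contain every schema column (an optional ``age_months``
    column is allowed and checked against ``age_lt2``). With ``strict`` on
    (the default) any invariant violation aborts with
    :class:`CohortValidationError`; with it off, violating rows are dropped
    and counted in the log.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extras = [c for c in df.columns if c not in CSV_COLUMNS and c != "age_months"]
    if extras:
        raise SchemaError(f"unexpected column(s): {', '.join(extras)}")

    records: list[PatientRecord] = []
    dropped = 0
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header = line 1
        row = row._asdict()
        pid = str(row["patient_id"]).strip()
        values = {c: _parse_cell(row[c], c, i) for c in CSV_COLUMNS[1:]}
        age_months = None
        if "age_months" in row:
            text = str(row["age_months"]).strip()
            if text.lower() not in _MISSING_TOKENS:
                try:
                    age_months = float(text)
                except ValueError:
                    raise SchemaError(
                        f"row {i}: non-numeric age_months value {text!r}"
                    ) from None
        rec = PatientRecord(patient_id=pid, age_months=age_months, **values)
        problems = rec.violations()
        if pid in seen:
            problems.append("duplicate patient_id")
        if problems:
            if strict:
                raise CohortValidationError(
                    f"row {i} (patient {pid!r}): " + "; ".join(problems)
                )
            dropped += 1
            continue
        seen.add(pid)
        records.append(rec)
    if dropped:
        logger.warning("dropped %d invalid row(s) while reading %s", dropped, path)
    return Cohort(tuple(records), provenance=provenance or f"csv:{path}")


def write_cohort_csv(cohort: Cohort, path) -> None:
    """Write *cohort* with the documented schema; missing cells become ``NA``."""
    df = cohort.to_frame()
    df.to_csv(path, index=False, na_rep="NA")


def cohort_from_rows(rows: Sequence[dict], provenance: str = "") -> Cohort:
    """Convenience constructor from plain dicts (used by generators/tests)."""
    return Cohort(tuple(PatientRecord(**row) for row in rows), provenance=provenance)
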