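"""Typed data model and text I/O for pharmacovigilance (PV) operational corpora.

The corpus gathers the four operational event streams that feed the audit
risk-assessment pipeline:

* ICSR cases — individual case safety reports with source, validity,
  timeliness and quality-review attributes, plus their submission records
  to health authorities and license partners;
* monthly sales records per affiliate;
* local study records (interventional and non-interventional);
* audit / inspection events with their finding statements.

Everything is plain text on disk: one CSV per stream (submissions in a
separate ``submissions.csv`` keyed by ``case_id``), with an optional
JSON-lines representation for cases that nests the submissions, and a small
``meta.json`` sidecar carrying the corpus span.  In memory each stream is a
:class:`pandas.DataFrame` with a fixed schema; :class:`pydantic` record
types provide a validated row-level view for construction and inspection.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PrimarySource",
    "Destination",
    "EventType",
    "KeyAttribute",
    "SubmissionRecord",
    "IcsrCase",
    "SalesRecord",
    "StudyRecord",
    "Finding",
    "AuditEvent",
    "Corpus",
    "ValidationIssue",
    "CorpusFormatError",
    "read_corpus",
    "write_corpus",
    "validate_corpus",
]


class PrimarySource(str, Enum):
    """Primary source of an adverse-event report."""

    SPONTANEOUS = "spontaneous"
    LITERATURE = "literature"
    CLINICAL_STUDY = "clinical_study"
    NON_INTERVENTIONAL_STUDY = "non_interventional_study"
    OTHER = "other"


#: Sources for which a case must be linked to a local study.
STUDY_SOURCES = frozenset(
    {PrimarySource.CLINICAL_STUDY, PrimarySource.NON_INTERVENTIONAL_STUDY}
)


class Destination(str, Enum):
    """Recipient of an ICSR submission."""

    HEALTH_AUTHORITY = "health_authority"
    LICENSE_PARTNER = "license_partner"


class EventType(str, Enum):
    AUDIT = "audit"
    INSPECTION = "inspection"


class KeyAttribute(str, Enum):
    """Key case data attributes whose correction is tracked in quality review."""

    SERIOUSNESS = "seriousness"
    PREGNANCY_ASSESSMENT = "pregnancy_assessment"
    PRIMARY_SOURCE = "primary_source"


class SubmissionRecord(BaseModel):
    """One (attempted) submission of a case to a destination.

    ``submitted=True`` records carry a date and a non-negative lateness in
    days (0 = on time); ``submitted=False`` records carry instead whether
    the non-submission was justified.
    """

    model_config = ConfigDict(frozen=True)

    destination: Destination
    submitted: bool
    submission_date: Optional[dt.date] = None
    days_late: Optional[int] = Field(default=None, ge=0)
    justified_nonsubmission: Optional[bool] = None


class IcsrCase(BaseModel):
    """One individual case safety report with its processing attributes."""

    model_config = ConfigDict(frozen=True)

    case_id: str
    affiliate_id: str
    received_date: dt.date
    primary_source: PrimarySource
    study_id: Optional[str] = None
    invalidated: bool = False
    transferred_late: Optional[bool] = None
    processed_late: Optional[bool] = None
    disposed_late: Optional[bool] = None
    qc_updated: bool = False
    workflow_cycles: int = Field(default=0, ge=0)
    key_attr_corrections: frozenset[KeyAttribute] = frozenset()
    submissions: tuple[SubmissionRecord, ...] = ()


class SalesRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    affiliate_id: str
    month: dt.date  # normalized to the first day of the month
    units_sold: float = Field(ge=0)


class StudyRecord(BaseModel):
    model_config = ConfigDict(frozen=True)

    study_id: str
    affiliate_id: str
    start_date: dt.date
    end_date: Optional[dt.date] = None  # absent = still active


class Finding(BaseModel):
    """One quality issue raised by an audit or inspection."""

    model_config = ConfigDict(frozen=True)

    finding_id: str
    statement_code: str
    statement_text: str = ""


class AuditEvent(BaseModel):
    """One audit or inspection of an affiliate; findings may be empty."""

    model_config = ConfigDict(frozen=True)

    audit_id: str
    affiliate_id: str
    date: dt.date
    event_type: EventType
    findings: tuple[Finding, ...] = ()


# --------------------------------------------------------------------------
# frame schemas
# --------------------------------------------------------------------------

CASE_COLUMNS = [
    "case_id",
    "affiliate_id",
    "received_date",
    "primary_source",
    "study_id",
    "invalidated",
    "transferred_late",
    "processed_late",
    "disposed_late",
    "qc_updated",
    "workflow_cycles",
    "key_attr_corrections",
]
SUBMISSION_COLUMNS = [
    "case_id",
    "destination",
    "submitted",
    "submission_date",
    "days_late",
    "justified_nonsubmission",
]
SALES_COLUMNS = ["affiliate_id", "month", "units_sold"]
STUDY_COLUMNS = ["study_id", "affiliate_id", "start_date", "end_date"]
AUDIT_COLUMNS = ["audit_id", "affiliate_id", "date", "event_type"]
FINDING_COLUMNS = ["audit_id", "finding_id", "statement_code", "statement_text"]


class CorpusFormatError(ValueError):
    """Raised when corpus files are malformed or violate an invariant."""


def _empty(columns: Sequence[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def _norm_cases(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=CASE_COLUMNS).copy()
    for c in ("case_id", "affiliate_id", "primary_source", "key_attr_corrections"):
        df[c] = df[c].astype(object)
    df["received_date"] = pd.to_datetime(df["received_date"])
    df["study_id"] = df["study_id"].astype(object).where(df["study_id"].notna(), None)
    for c in ("invalidated", "qc_updated"):
        df[c] = df[c].astype(bool)
    for c in ("transferred_late", "processed_late", "disposed_late"):
        df[c] = df[c].astype("boolean")
    df["workflow_cycles"] = df["workflow_cycles"].astype("int64")
    df["key_attr_corrections"] = df["key_attr_corrections"].fillna("").astype(str)
    return df


def _norm_submissions(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=SUBMISSION_COLUMNS).copy()
    for c in ("case_id", "destination"):
        df[c] = df[c].astype(object)
    df["submitted"] = df["submitted"].astype(bool)
    df["submission_date"] = pd.to_datetime(df["submission_date"])
    df["days_late"] = df["days_late"].astype("Int64")
    df["justified_nonsubmission"] = df["justified_nonsubmission"].astype("boolean")
    return df


def _norm_sales(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=SALES_COLUMNS).copy()
    df["affiliate_id"] = df["affiliate_id"].astype(object)
    df["month"] = pd.to_datetime(df["month"]).dt.to_period("M").dt.to_timestamp()
    df["units_sold"] = df["units_sold"].astype(float)
    return df


def _norm_studies(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=STUDY_COLUMNS).copy()
    for c in ("study_id", "affiliate_id"):
        df[c] = df[c].astype(object)
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    return df


def _norm_audits(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=AUDIT_COLUMNS).copy()
    for c in ("audit_id", "affiliate_id", "event_type"):
        df[c] = df[c].astype(object)
    df["date"] = pd.to_datetime(df["date"])
    return df


def _norm_findings(df: pd.DataFrame) -> pd.DataFrame:
    df = df.reindex(columns=FINDING_COLUMNS).copy()
    for c in ("audit_id", "finding_id", "statement_code"):
        df[c] = df[c].astype(object)
    df["statement_text"] = df["statement_text"].fillna("").astype(str)
    return df


Span = Optional[tuple[pd.Timestamp, pd.Timestamp]]


def _norm_span(span) -> Span:
    if span is None:
        return None
    lo, hi = span
    return (pd.Timestamp(lo), pd.Timestamp(hi))


@dataclass
class Corpus:
    """The full PV operational corpus as a set of columnar event streams.

    ``findings`` is kept as a separate frame keyed by ``audit_id`` (an audit
    with no findings simply has no rows there); ``submissions`` likewise is
    keyed by ``case_id``.  ``span`` is the closed date interval the corpus
    covers; ``None`` only for a truly empty corpus.
    """

    cases: pd.DataFrame = field(default_factory=lambda: _empty(CASE_COLUMNS))
    submissions: pd.DataFrame = field(default_factory=lambda: _empty(SUBMISSION_COLUMNS))
    sales: pd.DataFrame = field(default_factory=lambda: _empty(SALES_COLUMNS))
    studies: pd.DataFrame = field(default_factory=lambda: _empty(STUDY_COLUMNS))
    audits: pd.DataFrame = field(default_factory=lambda: _empty(AUDIT_COLUMNS))
    findings: pd.DataFrame = field(default_factory=lambda: _empty(FINDING_COLUMNS))
    span: Span = None

    def __post_init__(self) -> None:
        self.cases = _norm_cases(pd.DataFrame(self.cases))
        self.submissions = _norm_submissions(pd.DataFrame(self.submissions))
        self.sales = _norm_sales(pd.DataFrame(self.sales))
        self.studies = _norm_studies(pd.DataFrame(self.studies))
        self.audits = _norm_audits(pd.DataFrame(self.audits))
        self.findings = _norm_findings(pd.DataFrame(self.findings))
        self.span = _norm_span(self.span)

    # -- roster ------------------------------------------------------------

    @property
    def affiliates(self) -> list[str]:
        """Sorted union of affiliate ids observed across all streams."""
        ids: set[str] = set()
        for frame in (self.cases, self.sales, self.studies, self.audits):
            ids.update(frame["affiliate_id"].dropna().astype(str))
        return sorted(ids)

    # -- record-level views ------------------------------------------------

    @classmethod
    def from_records(
        cls,
        cases: Iterable[IcsrCase] = (),
        sales: Iterable[SalesRecord] = (),
        studies: Iterable[StudyRecord] = (),
        audits: Iterable[AuditEvent] = (),
        span: Span = None,
    ) -> "Corpus":
        sales = list(sales)
        studies = list(studies)
        case_rows, sub_rows = [], []
        for c in cases:
            case_rows.append(
                {
                    "case_id": c.case_id,
                    "affiliate_id": c.affiliate_id,
                    "received_date": pd.Timestamp(c.received_date),
                    "primary_source": c.primary_source.value,
                    "study_id": c.study_id,
                    "invalidated": c.invalidated,
                    "transferred_late": c.transferred_late,
                    "processed_late": c.processed_late,
                    "disposed_late": c.disposed_late,
                    "qc_updated": c.qc_updated,
                    "workflow_cycles": c.workflow_cycles,
                    "key_attr_corrections": encode_key_attrs(c.key_attr_corrections),
                }
            )
            for s in c.submissions:
                sub_rows.append(
                    {
                        "case_id": c.case_id,
                        "destination": s.destination.value,
                        "submitted": s.submitted,
                        "submission_date": pd.Timestamp(s.submission_date)
                        if s.submission_date
                        else pd.NaT,
                        "days_late": s.days_late,
                        "justified_nonsubmission": s.justified_nonsubmission,
                    }
                )
        audit_rows, finding_rows = [], []
        for a in audits:
            audit_rows.append(
                {
                    "audit_id": a.audit_id,
                    "affiliate_id": a.affiliate_id,
                    "date": pd.Timestamp(a.date),
                    "event_type": a.event_type.value,
                }
            )
            for f in a.findings:
                finding_rows.append(
                    {
                        "audit_id": a.audit_id,
                        "finding_id": f.finding_id,
                        "statement_code": f.statement_code,
                        "statement_text": f.statement_text,
                    }
                )
        return cls(
            cases=pd.DataFrame(case_rows, columns=CASE_COLUMNS),
            submissions=pd.DataFrame(sub_rows, columns=SUBMISSION_COLUMNS),
            sales=pd.DataFrame(
                [
                    {
                        "affiliate_id": s.affiliate_id,
                        "month": pd.Timestamp(s.month),
                        "units_sold": s.units_sold,
                    }
                    for s in sales
                ],
                columns=SALES_COLUMNS,
            ),
            studies=pd.DataFrame(
                [
                    {
                        "study_id": s.study_id,
                        "affiliate_id": s.affiliate_id,
                        "start_date": pd.Timestamp(s.start_date),
                        "end_date": pd.Timestamp(s.end_date) if s.end_date else pd.NaT,
                    }
                    for s in studies
                ],
                columns=STUDY_COLUMNS,
            ),
            audits=pd.DataFrame(audit_rows, columns=AUDIT_COLUMNS),
            findings=pd.DataFrame(finding_rows, columns=FINDING_COLUMNS),
            span=span if span is not None else derive_span_frames(
                case_rows, sub_rows, sales, studies, audit_rows
            ),
        )

    def iter_cases(self) -> Iterator[IcsrCase]:
        subs_by_case: dict[str, list[SubmissionRecord]] = {}
        for row in self.submissions.itertuples(index=False):
            subs_by_case.setdefault(row.case_id, []).append(
                SubmissionRecord(
                    destination=Destination(row.destination),
                    submitted=bool(row.submitted),
                    submission_date=None
                    if pd.isna(row.submission_date)
                    else row.submission_date.date(),
                    days_late=None if pd.isna(row.days_late) else int(row.days_late),
                    justified_nonsubmission=None
                    if pd.isna(row.justified_nonsubmission)
                    else bool(row.justified_nonsubmission),
                )
            )
        for row in self.cases.itertuples(index=False):
            yield IcsrCase(
                case_id=row.case_id,
                affiliate_id=row.affiliate_id,
                received_date=row.received_date.date(),
                primary_source=PrimarySource(row.primary_source),
                study_id=None if row.study_id is None or pd.isna(row.study_id) else row.study_id,
                invalidated=bool(row.invalidated),
                transferred_late=None
                if pd.isna(row.transferred_late)
                else bool(row.transferred_late),
                processed_late=None
                if pd.isna(row.processed_late)
                else bool(row.processed_late),
                disposed_late=None
                if pd.isna(row.disposed_late)
                else bool(row.disposed_late),
                qc_updated=bool(row.qc_updated),
                workflow_cycles=int(row.workflow_cycles),
                key_attr_corrections=decode_key_attrs(row.key_attr_corrections),
                submissions=tuple(subs_by_case.get(row.case_id, ())),
            )

    def iter_audits(self) -> Iterator[AuditEvent]:
        by_audit: dict[str, list[Finding]] = {}
        for row in self.findings.itertuples(index=False):
            by_audit.setdefault(row.audit_id, []).append(
                Finding(
                    finding_id=row.finding_id,
                    statement_code=row.statement_code,
                    statement_text=row.statement_text,
                )
            )
        for row in self.audits.itertuples(index=False):
            yield AuditEvent(
                audit_id=row.audit_id,
                affiliate_id=row.affiliate_id,
                date=row.date.date(),
                event_type=EventType(row.event_type),
                findings=tuple(by_audit.get(row.audit_id, ())),
            )

    # -- equality ----------------------------------------------------------

    def equals(self, other: "Corpus") -> bool:
        """Order-insensitive equality of all streams and the span."""
        if (self.span is None) != (other.span is None):
            return False
        if self.span is not None and tuple(self.span) != tuple(other.span):
            return False
        pairs = [
            (self.cases, other.cases, ["case_id"]),
            (
                self.submissions,
                other.submissions,
                ["case_id", "destination", "submitted", "submission_date", "days_late"],
            ),
            (self.sales, other.sales, ["affiliate_id", "month"]),
            (self.studies, other.studies, ["study_id"]),
            (self.audits, other.audits, ["audit_id"]),
            (self.findings, other.findings, ["finding_id"]),
        ]
        for a, b, keys in pairs:
            a = a.sort_values(keys, kind="mergesort").reset_index(drop=True)
            b = b.sort_values(keys, kind="mergesort").reset_index(drop=True)
            if not a.equals(b):
                return False
        return True


def encode_key_attrs(attrs: Iterable[KeyAttribute]) -> str:
    return "|".join(sorted(a.value for a in attrs))


def decode_key_attrs(text: str) -> frozenset[KeyAttribute]:
    if not text:
        return frozenset()
    return frozenset(KeyAttribute(tok) for tok in text.split("|"))


def derive_span_frames(case_rows, sub_rows, sales, studies, audit_rows) -> Span:
    dates: list[pd.Timestamp] = []
    dates += [r["received_date"] for r in case_rows]
    dates += [r["date"] for r in audit_rows]
    dates += [pd.Timestamp(s.month) for s in sales]
    dates += [pd.Timestamp(s.start_date) for s in studies]
    if not dates:
        return None
    return (min(dates), max(dates))


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationIssue:
    record_id: str
    field: str
    rule: str
    message: str


def _dups(series: pd.Series) -> list[str]:
    s = series.dropna().astype(str)
    return sorted(s[s.duplicated()].unique())


def validate_corpus(corpus: Corpus) -> list[ValidationIssue]:
    """Check every type invariant; returns issues instead of raising.

    Each issue carries the offending record id, the field involved and a
    stable rule token, so callers can assert on specific rules.
    """
    issues: list[ValidationIssue] = []
    add = issues.append
    span = corpus.span

    cases, subs = corpus.cases, corpus.submissions

    for cid in _dups(cases["case_id"]):
        add(ValidationIssue(cid, "case_id", "case_id_unique", "duplicate case_id"))
    if span is not None and len(cases):
        bad = cases[(cases["received_date"] < span[0]) | (cases["received_date"] > span[1])]
        for r in bad.itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "received_date",
                    "received_date_in_span",
                    f"received_date {r.received_date.date()} outside corpus span",
                )
            )
    if len(cases):
        bad = cases[cases["workflow_cycles"] < 0]
        for r in bad.itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "workflow_cycles",
                    "workflow_cycles_nonneg",
                    "workflow_cycles must be >= 0",
                )
            )
        is_study = cases["primary_source"].isin([s.value for s in STUDY_SOURCES])
        has_study = cases["study_id"].notna()
        for r in cases[is_study & ~has_study].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "study_id",
                    "study_id_required",
                    "study-sourced case must reference a study",
                )
            )
        for r in cases[~is_study & has_study].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "study_id",
                    "study_id_forbidden",
                    "non-study case must not reference a study",
                )
            )
        known = {s.value for s in PrimarySource}
        for r in cases[~cases["primary_source"].isin(known)].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "primary_source",
                    "primary_source_valid",
                    f"unknown primary_source {r.primary_source!r}",
                )
            )

    if len(subs):
        known_cases = set(cases["case_id"].astype(str))
        sub = subs["submitted"].astype(bool)
        for r in subs[~subs["case_id"].astype(str).isin(known_cases)].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "case_id",
                    "submission_case_ref",
                    "submission references unknown case",
                )
            )
        for r in subs[sub & subs["submission_date"].isna()].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "submission_date",
                    "submitted_date_required",
                    "submitted record lacks submission_date",
                )
            )
        for r in subs[sub & subs["days_late"].isna()].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "days_late",
                    "submitted_days_late_required",
                    "submitted record lacks days_late",
                )
            )
        for r in subs[sub & subs["justified_nonsubmission"].notna()].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "justified_nonsubmission",
                    "submitted_no_justification",
                    "justified_nonsubmission defined only when not submitted",
                )
            )
        for r in subs[~sub & subs["justified_nonsubmission"].isna()].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "justified_nonsubmission",
                    "nonsubmission_justification_required",
                    "non-submitted record lacks justified_nonsubmission",
                )
            )
        for r in subs[~sub & (subs["submission_date"].notna() | subs["days_late"].notna())].itertuples(
            index=False
        ):
            add(
                ValidationIssue(
                    r.case_id,
                    "submission_date",
                    "nonsubmission_no_submission_fields",
                    "submission_date/days_late defined only when submitted",
                )
            )
        neg = subs["days_late"].notna() & (subs["days_late"].astype("Int64") < 0).fillna(False)
        for r in subs[neg].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id, "days_late", "days_late_nonneg", "days_late must be >= 0"
                )
            )
        known_dest = {d.value for d in Destination}
        for r in subs[~subs["destination"].isin(known_dest)].itertuples(index=False):
            add(
                ValidationIssue(
                    r.case_id,
                    "destination",
                    "destination_valid",
                    f"unknown destination {r.destination!r}",
                )
            )

    sales = corpus.sales
    if len(sales):
        dup = sales[sales.duplicated(subset=["affiliate_id", "month"])]
        for r in dup.itertuples(index=False):
            add(
                ValidationIssue(
                    r.affiliate_id,
                    "month",
                    "sales_unique",
                    f"duplicate sales record for {r.month.strftime('%Y-%m')}",
                )
            )
        for r in sales[sales["units_sold"] < 0].itertuples(index=False):
            add(
                ValidationIssue(
                    r.affiliate_id, "units_sold", "units_sold_nonneg", "units_sold must be >= 0"
                )
            )

    studies = corpus.studies
    if len(studies):
        for sid in _dups(studies["study_id"]):
            add(ValidationIssue(sid, "study_id", "study_id_unique", "duplicate study_id"))
        bad = studies[studies["end_date"].notna() & (studies["end_date"] < studies["start_date"])]
        for r in bad.itertuples(index=False):
            add(
                ValidationIssue(
                    r.study_id,
                    "end_date",
                    "study_dates_ordered",
                    "end_date precedes start_date",
                )
            )

    audits, findings = corpus.audits, corpus.findings
    if len(audits):
        for aid in _dups(audits["audit_id"]):
            add(ValidationIssue(aid, "audit_id", "audit_id_unique", "duplicate audit_id"))
        if span is not None:
            bad = audits[(audits["date"] < span[0]) | (audits["date"] > span[1])]
            for r in bad.itertuples(index=False):
                add(
                    ValidationIssue(
                        r.audit_id,
                        "date",
                        "audit_date_in_span",
                        f"audit date {r.date.date()} outside corpus span",
                    )
                )
        known_types = {t.value for t in EventType}
        for r in audits[~audits["event_type"].isin(known_types)].itertuples(index=False):
            add(
                ValidationIssue(
                    r.audit_id,
                    "event_type",
                    "event_type_valid",
                    f"unknown event_type {r.event_type!r}",
                )
            )
    if len(findings):
        for fid in _dups(findings["finding_id"]):
            add(ValidationIssue(fid, "finding_id", "finding_id_unique", "duplicate finding_id"))
        known_audits = set(audits["audit_id"].astype(str))
        for r in findings[~findings["audit_id"].astype(str).isin(known_audits)].itertuples(
            index=False
        ):
            add(
                ValidationIssue(
                    r.finding_id,
                    "audit_id",
                    "finding_audit_ref",
                    "finding references unknown audit",
                )
            )
    return issues


# --------------------------------------------------------------------------
# file I/O
# --------------------------------------------------------------------------

_TRUE, _FALSE = "true", "false"


def _fmt_bool(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v is pd.NA:
        return ""
    return _TRUE if bool(v) else _FALSE


def _fmt_date(v) -> str:
    return "" if pd.isna(v) else pd.Timestamp(v).strftime("%Y-%m-%d")


def _fmt_month(v) -> str:
    return "" if pd.isna(v) else pd.Timestamp(v).strftime("%Y-%m")


def _fmt_int(v) -> str:
    return "" if pd.isna(v) else str(int(v))


def _parse_bool(s: str):
    if s == "":
        return pd.NA
    if s == _TRUE:
        return True
    if s == _FALSE:
        return False
    raise ValueError(f"expected 'true'/'false', got {s!r}")


def _parse_date(s: str):
    if s == "":
        return pd.NaT
    return pd.Timestamp(dt.date.fromisoformat(s))


def _parse_month(s: str):
    if s == "":
        return pd.NaT
    y, m = s.split("-")
    return pd.Timestamp(int(y), int(m), 1)


def _parse_int(s: str):
    if s == "":
        return pd.NA
    return int(s)


def _parse_float(s: str):
    if s == "":
        raise ValueError("missing numeric value")
    return float(s)


def _parse_enum(enum_cls):
    allowed = {e.value for e in enum_cls}

    def parse(s: str):
        if s not in allowed:
            raise ValueError(f"unknown token {s!r} (allowed: {sorted(allowed)})")
        return s

    return parse


def _parse_str(s: str):
    return s


def _parse_opt_str(s: str):
    return None if s == "" else s


def _parse_key_attrs(s: str) -> str:
    decode_key_attrs(s)  # raises on unknown token
    return s


_CASE_PARSERS = {
    "case_id": _parse_str,
    "affiliate_id": _parse_str,
    "received_date": _parse_date,
    "primary_source": _parse_enum(PrimarySource),
    "study_id": _parse_opt_str,
    "invalidated": _parse_bool,
    "transferred_late": _parse_bool,
    "processed_late": _parse_bool,
    "disposed_late": _parse_bool,
    "qc_updated": _parse_bool,
    "workflow_cycles": _parse_int,
    "key_attr_corrections": _parse_key_attrs,
}
_SUBMISSION_PARSERS = {
    "case_id": _parse_str,
    "destination": _parse_enum(Destination),
    "submitted": _parse_bool,
    "submission_date": _parse_date,
    "days_late": _parse_int,
    "justified_nonsubmission": _parse_bool,
}
_SALES_PARSERS = {
    "affiliate_id": _parse_str,
    "month": _parse_month,
    "units_sold": _parse_float,
}
_STUDY_PARSERS = {
    "study_id": _parse_str,
    "affiliate_id": _parse_str,
    "start_date": _parse_date,
    "end_date": _parse_date,
}
_AUDIT_PARSERS = {
    "audit_id": _parse_str,
    "affiliate_id": _parse_str,
    "date": _parse_date,
    "event_type": _parse_enum(EventType),
    "finding_id": _parse_opt_str,
    "statement_code": _parse_opt_str,
    "statement_text": _parse_str,
}


def _read_table(path: Path, parsers: Mapping[str, object]) -> pd.DataFrame:
    try:
        raw = pd.read_csv(path, dtype=str, keep_default_na=False, na_values=[])
    except Exception as exc:  # pragma: no cover - delegated parse failure
        raise CorpusFormatError(f"{path}: cannot read CSV ({exc})") from exc
    missing = [c for c in parsers if c not in raw.columns]
    if missing:
        raise CorpusFormatError(f"{path}: missing columns {missing}")
    out = {}
    for col, fn in parsers.items():
        values = []
        for i, s in enumerate(raw[col].tolist()):
            try:
                values.append(fn(s))
            except (ValueError, KeyError) as exc:
                raise CorpusFormatError(
                    f"{path}, line {i + 2}, field {col}: {exc}"
                ) from exc
        out[col] = pd.Series(values, dtype=object)
    return pd.DataFrame(out)


def _paths(location: Union[str, Path, Mapping[str, Path]], cases_format: str) -> dict:
    if isinstance(location, (str, Path)):
        d = Path(location)
        cases = d / ("cases.jsonl" if cases_format == "jsonl" else "cases.csv")
        return {
            "cases": cases,
            "submissions": d / "submissions.csv",
            "sales": d / "sales.csv",
            "studies": d / "studies.csv",
            "audits": d / "audits.csv",
            "meta": d / "meta.json",
        }
    return dict(location)


def write_corpus(
    corpus: Corpus,
    destination: Union[str, Path],
    cases_format: str = "csv",
) -> dict[str, Path]:
    """Write all streams under ``destination`` as UTF-8 text files.

    ``cases_format`` is ``"csv"`` (cases.csv + submissions.csv) or
    ``"jsonl"`` (cases.jsonl with nested submissions).  Output is
    deterministic for a given corpus.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    paths = _paths(dest, cases_format)

    if cases_format == "csv":
        c = corpus.cases
        out = pd.DataFrame(
            {
                "case_id": c["case_id"],
                "affiliate_id": c["affiliate_id"],
                "received_date": c["received_date"].map(_fmt_date),
                "primary_source": c["primary_source"],
                "study_id": c["study_id"].map(lambda v: "" if v is None or pd.isna(v) else v),
                "invalidated": c["invalidated"].map(_fmt_bool),
                "transferred_late": c["transferred_late"].map(_fmt_bool),
                "processed_late": c["processed_late"].map(_fmt_bool),
                "disposed_late": c["disposed_late"].map(_fmt_bool),
                "qc_updated": c["qc_updated"].map(_fmt_bool),
                "workflow_cycles": c["workflow_cycles"].map(_fmt_int),
                "key_attr_corrections": c["key_attr_corrections"],
            }
        )
        out.to_csv(paths["cases"], index=False)
        s = corpus.submissions
        out = pd.DataFrame(
            {
                "case_id": s["case_id"],
                "destination": s["destination"],
                "submitted": s["submitted"].map(_fmt_bool),
                "submission_date": s["submission_date"].map(_fmt_date),
                "days_late": s["days_late"].map(_fmt_int),
                "justified_nonsubmission": s["justified_nonsubmission"].map(_fmt_bool),
            }
        )
        out.to_csv(paths["submissions"], index=False)
    elif cases_format == "jsonl":
        with open(paths["cases"], "w", encoding="utf-8") as fh:
            for case in _iter_case_dicts(corpus):
                fh.write(json.dumps(case, sort_keys=True) + "\n")
        paths.pop("submissions", None)
    else:
        raise ValueError(f"unknown cases_format {cases_format!r}")

    sl = corpus.sales
    pd.DataFrame(
        {
            "affiliate_id": sl["affiliate_id"],
            "month": sl["month"].map(_fmt_month),
            "units_sold": sl["units_sold"].map(lambda v: repr(float(v))),
        }
    ).to_csv(paths["sales"], index=False)

    st = corpus.studies
    pd.DataFrame(
        {
            "study_id": st["study_id"],
            "affiliate_id": st["affiliate_id"],
            "start_date": st["start_date"].map(_fmt_date),
            "end_date": st["end_date"].map(_fmt_date),
        }
    ).to_csv(paths["studies"], index=False)

    a = corpus.audits.copy()
    f = corpus.findings
    merged = a.merge(f, on="audit_id", how="left")
    pd.DataFrame(
        {
            "audit_id": merged["audit_id"],
            "affiliate_id": merged["affiliate_id"],
            "date": merged["date"].map(_fmt_date),
            "event_type": merged["event_type"],
            "finding_id": merged["finding_id"].map(lambda v: "" if pd.isna(v) else v),
            "statement_code": merged["statement_code"].map(lambda v: "" if pd.isna(v) else v),
            "statement_text": merged["statement_text"].map(lambda v: "" if pd.isna(v) else v),
        }
    ).to_csv(paths["audits"], index=False)

    meta = {
        "span": None
        if corpus.span is None
        else [_fmt_date(corpus.span[0]), _fmt_date(corpus.span[1])]
    }
    with open(paths["meta"], "w", encoding="utf-8") as fh:
        json.dump(meta, fh, sort_keys=True)
        fh.write("\n")
    return paths


def _iter_case_dicts(corpus: Corpus) -> Iterator[dict]:
    subs_by_case: dict[str, list[dict]] = {}
    for r in corpus.submissions.itertuples(index=False):
        subs_by_case.setdefault(r.case_id, []).append(
            {
                "destination": r.destination,
                "submitted": bool(r.submitted),
                "submission_date": None
                if pd.isna(r.submission_date)
                else _fmt_date(r.submission_date),
                "days_late": None if pd.isna(r.days_late) else int(r.days_late),
                "justified_nonsubmission": None
                if pd.isna(r.justified_nonsubmission)
                else bool(r.justified_nonsubmission),
            }
        )
    for r in corpus.cases.itertuples(index=False):
        yield {
            "case_id": r.case_id,
            "affiliate_id": r.affiliate_id,
            "received_date": _fmt_date(r.received_date),
            "primary_source": r.primary_source,
            "study_id": None if r.study_id is None or pd.isna(r.study_id) else r.study_id,
            "invalidated": bool(r.invalidated),
            "transferred_late": None
            if pd.isna(r.transferred_late)
            else bool(r.transferred_late),
            "processed_late": None if pd.isna(r.processed_late) else bool(r.processed_late),
            "disposed_late": None if pd.isna(r.disposed_late) else bool(r.disposed_late),
            "qc_updated": bool(r.qc_updated),
            "workflow_cycles": int(r.workflow_cycles),
            "key_attr_corrections": sorted(
                a.value for a in decode_key_attrs(r.key_attr_corrections)
            ),
            "submissions": subs_by_case.get(r.case_id, []),
        }


def _read_cases_jsonl(path: Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    case_rows, sub_rows = [], []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
                case_rows.append(
                    {
                        "case_id": str(obj["case_id"]),
                        "affiliate_id": str(obj["affiliate_id"]),
                        "received_date": _parse_date(obj["received_date"]),
                        "primary_source": _parse_enum(PrimarySource)(obj["primary_source"]),
                        "study_id": obj.get("study_id"),
                        "invalidated": bool(obj["invalidated"]),
                        "transferred_late": obj.get("transferred_late"),
                        "processed_late": obj.get("processed_late"),
                        "disposed_late": obj.get("disposed_late"),
                        "qc_updated": bool(obj["qc_updated"]),
                        "workflow_cycles": int(obj["workflow_cycles"]),
                        "key_attr_corrections": "|".join(
                            sorted(
                                KeyAttribute(t).value
                                for t in obj.get("key_attr_corrections", [])
                            )
                        ),
                    }
                )
                for s in obj.get("submissions", []):
                    sub_rows.append(
                        {
                            "case_id": str(obj["case_id"]),
                            "destination": _parse_enum(Destination)(s["destination"]),
                            "submitted": bool(s["submitted"]),
                            "submission_date": _parse_date(s.get("submission_date") or ""),
                            "days_late": pd.NA
                            if s.get("days_late") is None
                            else int(s["days_late"]),
                            "justified_nonsubmission": pd.NA
                            if s.get("justified_nonsubmission") is None
                            else bool(s["justified_nonsubmission"]),
                        }
                    )
            except (KeyError, ValueError, TypeError) as exc:
                raise CorpusFormatError(f"{path}, line {lineno}: {exc}") from exc
    return (
        pd.DataFrame(case_rows, columns=CASE_COLUMNS),
        pd.DataFrame(sub_rows, columns=SUBMISSION_COLUMNS),
    )


def read_corpus(location: Union[str, Path, Mapping[str, Path]]) -> Corpus:
    """Read and validate a corpus from a directory or explicit path mapping.

    Accepts either ``cases.csv`` + ``submissions.csv`` or ``cases.jsonl``
    (auto-detected when a directory is given).  Any invariant violation in
    the parsed data aborts with a :class:`CorpusFormatError`; record order
    in the files never affects the result.
    """
    if isinstance(location, (str, Path)):
        d = Path(location)
        fmt = "jsonl" if (d / "cases.jsonl").exists() and not (d / "cases.csv").exists() else "csv"
        paths = _paths(d, fmt)
    else:
        paths = dict(location)

    cases_path = Path(paths["cases"])
    if cases_path.suffix == ".jsonl":
        cases, submissions = _read_cases_jsonl(cases_path)
    else:
        cases = _read_table(cases_path, _CASE_PARSERS)
        submissions = _read_table(Path(paths["submissions"]), _SUBMISSION_PARSERS)

    sales = _read_table(Path(paths["sales"]), _SALES_PARSERS)
    studies = _read_table(Path(paths["studies"]), _STUDY_PARSERS)
    audit_rows = _read_table(Path(paths["audits"]), _AUDIT_PARSERS)

    audits = (
        audit_rows[AUDIT_COLUMNS]
        .drop_duplicates(subset=["audit_id"], keep="first")
        .reset_index(drop=True)
    )
    # a row with empty finding fields encodes a clean audit
    has_finding = audit_rows["finding_id"].map(lambda v: v is not None)
    findings = audit_rows.loc[has_finding, FINDING_COLUMNS].reset_index(drop=True)
    # inconsistent audit-level fields repeated across finding rows are an error
    grp = audit_rows.groupby("audit_id")[["affiliate_id", "date", "event_type"]].nunique()
    bad = grp[(grp > 1).any(axis=1)]
    if len(bad):
        raise CorpusFormatError(
            f"{paths['audits']}: audit rows disagree on audit-level fields for "
            f"{sorted(bad.index.tolist())}"
        )

    span = None
    meta_path = paths.get("meta")
    if meta_path is not None and Path(meta_path).exists():
        with open(meta_path, encoding="utf-8") as fh:
            meta = json.load(fh)
        if meta.get("span"):
            span = (_parse_date(meta["span"][0]), _parse_date(meta["span"][1]))
    if span is None:
        dates = []
        if len(cases):
            dates += [cases["received_date"].min(), cases["received_date"].max()]
        if len(audits):
            dates += [audits["date"].min(), audits["date"].max()]
        if len(sales):
            dates += [sales["month"].min(), sales["month"].max()]
        if len(studies):
            dates += [studies["start_date"].min(), studies["start_date"].max()]
        dates = [d for d in dates if not pd.isna(d)]
        span = (min(dates), max(dates)) if dates else None

    corpus = Corpus(
        cases=cases,
        submissions=submissions,
        sales=sales,
        studies=studies,
        audits=audits,
        findings=findings,
        span=span,
    )
    issues = validate_corpus(corpus)
    if issues:
        head = "; ".join(
            f"{i.rule} (record {i.record_id}, field {i.field})" for i in issues[:5]
        )
        raise CorpusFormatError(
            f"corpus failed validation with {len(issues)} issue(s): {head}"
        )
    return corpus
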