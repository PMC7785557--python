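"""Shared fixtures: small synthetic corpora and record factories."""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd
import pytest

from pvrisk.events import (
    AuditEvent,
    Corpus,
    Destination,
    EventType,
    Finding,
    IcsrCase,
    PrimarySource,
    SalesRecord,
    StudyRecord,
    SubmissionRecord,
)
from pvrisk.features import WindowSpec, build_feature_series, default_catalog
from pvrisk.model import FitConfig, assemble_training_set, fit_risk_model
from pvrisk.synthetic import (
    SyntheticConfig,
    generate_corpus,
    paper_profile_config,
    recovery_profile_config,
)
from pvrisk.taxonomy import ImpactFactor, default_mapping


def make_config(**overrides) -> SyntheticConfig:
    """Small but fully featured generator configuration for unit tests."""
    base = paper_profile_config()
    defaults = dict(
        n_affiliates=3,
        span=(pd.Timestamp("2012-01-01"), pd.Timestamp("2013-12-31")),
        audits_per_year=6,
        inspections_per_year=1,
        total_findings=None,
        cases_per_affiliate_month=5.0,
    )
    defaults.update(overrides)
    return dataclasses.replace(base, **defaults)


@pytest.fixture(scope="session")
def mapping():
    return default_mapping()


@pytest.fixture(scope="session")
def small_corpus():
    corpus, _ = generate_corpus(make_config(), seed=7)
    return corpus


@pytest.fixture(scope="session")
def paper_corpus():
    corpus, truth = generate_corpus(paper_profile_config(), seed=1)
    return corpus, truth


RECOVERY_FEATURES = ("late_submission_ratio", "invalidated_ae_ratio", "qc_updated_ratio")


@pytest.fixture(scope="session")
def recovery_bundle(mapping):
    """Corpus → features → training set → fitted model for the large
    known-coefficient profile; shared across recovery and calibration tests."""
    config = recovery_profile_config()
    corpus, truth = generate_corpus(config, seed=42)
    catalog = [d for d in default_catalog() if d.name in RECOVERY_FEATURES]
    series = build_feature_series(corpus, catalog, WindowSpec())
    train = assemble_training_set(
        series, corpus, mapping, ImpactFactor.ICSR_PROCESS, catalog=catalog
    )
    model = fit_risk_model(train, FitConfig())
    return dict(
        config=config, corpus=corpus, truth=truth, series=series, train=train, model=model
    )


# ---------------------------------------------------------------------------
# record factories for hand-built corpora
# ---------------------------------------------------------------------------


def mk_sub(
    destination=Destination.HEALTH_AUTHORITY,
    submitted=True,
    days_late=0,
    submission_date=dt.date(2012, 6, 15),
    justified=None,
) -> SubmissionRecord:
    if submitted:
        return SubmissionRecord(
            destination=destination,
            submitted=True,
            submission_date=submission_date,
            days_late=days_late,
        )
    return SubmissionRecord(
        destination=destination,
        submitted=False,
        justified_nonsubmission=True if justified is None else justified,
    )


_case_counter = iter(range(1, 10_000_000))


def mk_case(
    received=dt.date(2012, 6, 1),
    affiliate="A1",
    source=PrimarySource.SPONTANEOUS,
    case_id=None,
    **kwargs,
) -> IcsrCase:
    return IcsrCase(
        case_id=case_id or f"TC{next(_case_counter):06d}",
        affiliate_id=affiliate,
        received_date=received,
        primary_source=source,
        **kwargs,
    )


def mk_audit(
    audit_id="AUD-T1",
    affiliate="A1",
    date=dt.date(2013, 6, 10),
    event_type=EventType.AUDIT,
    codes=(),
) -> AuditEvent:
    return AuditEvent(
        audit_id=audit_id,
        affiliate_id=affiliate,
        date=date,
        event_type=event_type,
        findings=tuple(
            Finding(finding_id=f"{audit_id}-F{i}", statement_code=c)
            for i, c in enumerate(codes, start=1)
        ),
    )


def corpus_of(
    cases=(), sales=(), studies=(), audits=(), span=(dt.date(2011, 1, 1), dt.date(2013, 12, 31))
) -> Corpus:
    return Corpus.from_records(
        cases=cases,
        sales=sales,
        studies=studies,
        audits=audits,
        span=(pd.Timestamp(span[0]), pd.Timestamp(span[1])),
    )
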