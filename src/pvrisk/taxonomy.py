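"""Mapping of audit finding statements to PV impact factors.

Audit and inspection findings arrive labeled with controlled finding
statements.  To turn them into modelable outcomes, every statement code is
mapped to at most one *PV impact factor* — a curated risk area such as
"Compliance to Individual Case Safety Report (ICSR) process".  An audit's
binary outcome for factor *f* is 1 iff at least one of its findings maps to
*f*; statements outside the four modeled factors stay ``UNMAPPED`` and
never contribute to an outcome.

Four risk areas (locally managed PASS, health-authority commitments, CAPA
process, business-partner oversight) are deliberately out of scope of the
quantitative models and are therefore not impact-factor members here.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Union

import pandas as pd

from .events import AuditEvent

__all__ = [
    "ImpactFactor",
    "UNMAPPED",
    "DISPLAY_NAMES",
    "FindingMapping",
    "MappingError",
    "load_mapping",
    "default_mapping",
    "map_finding",
    "label_audit_outcomes",
    "label_outcomes_frame",
]


class ImpactFactor(str, Enum):
    """The four modeled PV impact factors."""

    ICSR_PROCESS = "ICSR_PROCESS"
    RISK_MINIMIZATION = "RISK_MINIMIZATION"
    DHPC = "DHPC"
    LOCAL_LABELS = "LOCAL_LABELS"


#: Human-readable impact factor names as used by quality assurance teams.
DISPLAY_NAMES: dict[ImpactFactor, str] = {
    ImpactFactor.ICSR_PROCESS: "Compliance to Individual Case Safety Report (ICSR) process",
    ImpactFactor.RISK_MINIMIZATION: "Compliance to risk minimization activities",
    ImpactFactor.DHPC: "Compliance to DHPC activities",
    ImpactFactor.LOCAL_LABELS: "Compliance to safety updates to local labels",
}

#: Sentinel for statements that belong to none of the modeled factors.
UNMAPPED = "UNMAPPED"


class MappingError(ValueError):
    """Raised for malformed mapping files (unknown factor, duplicate code)."""


@dataclass(frozen=True)
class FindingMapping:
    """Curated statement-code → impact-factor table."""

    entries: Mapping[str, ImpactFactor]
    version: str = "unversioned"

    def __len__(self) -> int:
        return len(self.entries)


def load_mapping(path: Union[str, Path]) -> FindingMapping:
    """Load a mapping from a delimited file with columns
    ``statement_code,impact_factor[,statement_text]``.

    Aborts on an unknown impact-factor name or a duplicated statement code.
    """
    entries: dict[str, ImpactFactor] = {}
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {
            "statement_code",
            "impact_factor",
        }.issubset(reader.fieldnames):
            raise MappingError(
                f"{path}: expected columns statement_code, impact_factor"
            )
        for lineno, row in enumerate(reader, start=2):
            code = row["statement_code"].strip()
            name = row["impact_factor"].strip()
            if code in entries:
                raise MappingError(f"{path}, line {lineno}: duplicate statement_code {code!r}")
            try:
                factor = ImpactFactor(name)
            except ValueError as exc:
                raise MappingError(
                    f"{path}, line {lineno}: unknown impact factor {name!r}"
                ) from exc
            entries[code] = factor
    return FindingMapping(entries=entries, version=path.name)


def default_mapping() -> FindingMapping:
    """The mapping shipped with the package (statement pool used by the
    synthetic generator plus the published example statements)."""
    ref = resources.files("pvrisk").joinpath("data/finding_mapping.csv")
    with resources.as_file(ref) as path:
        mapping = load_mapping(path)
    return FindingMapping(entries=mapping.entries, version="pvrisk-default")


#: Example statement texts for the shipped codes (used in docs and tests).
STATEMENT_TEXTS: dict[str, str] = {
    "ICSR_RECEIVE_DATE_INACCURATE": (
        "ICSR receive dates were inaccurately determined and/or recorded"
    ),
    "ICSR_FOLLOWUP_NOT_PERFORMED": (
        "Follow-up on ICSRs was not performed, untimely and/or not documented"
    ),
    "AE_COLLECTION_PROCEDURE_INADEQUATE": (
        "Processes and/or procedures for case identification and collection of "
        "potential AEs were not defined, inadequate and/or not followed"
    ),
    "RECONCILIATION_NOT_PERFORMED": (
        "Reconciliation/case transmission verification with all relevant internal "
        "functions was not performed, untimely, inadequate and/or not documented"
    ),
    "RMP_COMMUNICATION_NOT_COMPLETED": (
        "Communication and/or submission of Risk Management Plans (RMPs) or "
        "additional RMinAs to the regulatory authority was not completed, "
        "untimely and/or not documented"
    ),
    "RMINA_LOCAL_OVERSIGHT_LACKING": (
        "There was a lack of oversight for local implementation of PV activities or RMinAs"
    ),
    "RSI_UPDATE_PROCEDURE_INADEQUATE": (
        "Procedures and/or processes for updating reference safety information "
        "were not defined, inadequate and/or not followed"
    ),
    "PROMO_MATERIAL_NOT_UPDATED": (
        "Promotional material was not updated with new safety information or "
        "not updated in a timely manner"
    ),
    "DHPC_DISTRIBUTION_UNTIMELY": (
        "DHPC distribution to healthcare professionals was not performed in a timely manner"
    ),
    "DHPC_RECIPIENT_LIST_INCOMPLETE": (
        "The DHPC recipient list was incomplete or not maintained"
    ),
}


def map_finding(statement_code: str, mapping: FindingMapping) -> str:
    """Deterministic lookup; returns an :class:`ImpactFactor` value or
    :data:`UNMAPPED` for codes absent from the mapping."""
    factor = mapping.entries.get(statement_code)
    return factor.value if factor is not None else UNMAPPED


def label_audit_outcomes(
    audit: AuditEvent,
    mapping: FindingMapping,
    any_finding: bool = False,
) -> dict[ImpactFactor, int]:
    """Binary outcome per impact factor for one audit/inspection.

    Factor *f* gets 1 iff the audit has at least one finding mapped to *f*
    (a count of three findings is still 1 — the outcome is Bernoulli, not
    Poisson).  With ``any_finding=True`` every factor instead gets the
    audit-level label "any finding at all".
    """
    labels = {f: 0 for f in ImpactFactor}
    if any_finding:
        hit = 1 if len(audit.findings) > 0 else 0
        return {f: hit for f in ImpactFactor}
    for finding in audit.findings:
        factor = mapping.entries.get(finding.statement_code)
        if factor is not None:
            labels[factor] = 1
    return labels


def label_outcomes_frame(
    audits: pd.DataFrame,
    findings: pd.DataFrame,
    mapping: FindingMapping,
    impact_factor: ImpactFactor,
    any_finding: bool = False,
) -> pd.Series:
    """Vectorized variant of :func:`label_audit_outcomes` for one factor:
    a 0/1 Series indexed by ``audit_id`` covering every audit."""
    labels = pd.Series(0, index=audits["audit_id"].astype(str), dtype=int)
    if len(findings):
        if any_finding:
            hits = findings["audit_id"].astype(str).unique()
        else:
            mapped = findings["statement_code"].map(
                lambda c: mapping.entries.get(c)
            )
            hits = (
                findings.loc[
                    [f == impact_factor for f in mapped], "audit_id"
                ]
                .astype(str)
                .unique()
            )
        labels.loc[labels.index.intersection(hits)] = 1
    return labels
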