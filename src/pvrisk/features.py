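"""Sliding-window risk covariates per affiliate on a monthly grid.

Quality strategists read risk off streams of operational events (case
receptions, submissions, sales, studies) as summary statistics over a
trailing window — typically ratios, so affiliates of very different sizes
remain comparable.  This module automates that: every feature is evaluated
for every affiliate at every month *t* of a monthly grid, over the
half-open window ``[t - W months, t)``.  The month *t* itself is excluded,
so the covariates available at an audit conducted in month *t* use strictly
pre-audit data.

Feature kinds
-------------
``window_ratio``
    count(numerator events) / count(denominator events) in the long (or
    short) window; ``MISSING`` when the denominator is empty.
``source_mix``
    share of reported AEs from one primary source among all AEs in the
    long window.
``quantile_set``
    a lower nearest-rank quantile of submission lateness (days) over the
    long window.
``cross_window_change``
    (short-window AE/sales rate) / (long-window AE/sales rate) — a change
    in reporting pattern relative to drug usage.

``MISSING`` is represented as ``NaN`` throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .events import Corpus, PrimarySource
from .taxonomy import ImpactFactor

__all__ = [
    "MISSING",
    "is_missing",
    "WindowSpec",
    "Predicate",
    "FeatureDefinition",
    "FeatureVector",
    "FeatureSeries",
    "default_catalog",
    "monthly_grid",
    "add_months",
    "window_slice",
    "compute_ratio_feature",
    "compute_source_mix",
    "compute_days_late_quantiles",
    "compute_cross_window_change",
    "compute_feature_cell",
    "build_feature_series",
]

MISSING = float("nan")

DEFAULT_QUANTILES = (0.5, 0.9, 1.0)


def is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def add_months(t: pd.Timestamp, k: int) -> pd.Timestamp:
    return (pd.Timestamp(t).to_period("M") + k).to_timestamp()


def month_start(t: pd.Timestamp) -> pd.Timestamp:
    return pd.Timestamp(t).to_period("M").to_timestamp()


def monthly_grid(span: tuple[pd.Timestamp, pd.Timestamp]) -> pd.DatetimeIndex:
    """First-of-month timestamps covering the corpus span, inclusive."""
    if span is None:
        raise ValueError("corpus has no span; cannot build a monthly grid")
    return pd.date_range(month_start(span[0]), month_start(span[1]), freq="MS")


@dataclass(frozen=True)
class WindowSpec:
    """Trailing-window lengths in whole months."""

    long_window_months: int = 24
    short_window_months: int = 6

    def __post_init__(self) -> None:
        if not (0 < self.short_window_months < self.long_window_months):
            raise ValueError(
                "require 0 < short_window_months < long_window_months, got "
                f"{self.short_window_months} / {self.long_window_months}"
            )


@dataclass(frozen=True)
class Predicate:
    """Declarative event filter over one stream.

    ``where`` is a conjunction of conditions ``(field, op[, value])`` with
    ops ``istrue``, ``isfalse``, ``notna``, ``isna``, ``eq``, ``ne``,
    ``gt``.  Streams: ``cases``, ``submissions`` (joined to their case's
    affiliate and received date), ``active_studies`` (studies active in the
    window, with a derived ``window_ae_count`` column).
    """

    stream: str
    where: tuple = ()

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(df), dtype=bool)
        for cond in self.where:
            fld, op = cond[0], cond[1]
            val = cond[2] if len(cond) > 2 else None
            col = df[fld]
            if op == "istrue":
                m = col.fillna(False).astype(bool).to_numpy()
            elif op == "isfalse":
                m = (~col.fillna(True).astype(bool)).to_numpy()
            elif op == "notna":
                m = col.notna().to_numpy()
            elif op == "isna":
                m = col.isna().to_numpy()
            elif op == "eq":
                m = (col == val).fillna(False).to_numpy()
            elif op == "ne":
                m = (col != val).fillna(False).to_numpy()
            elif op == "gt":
                m = (col > val).fillna(False).to_numpy()
            else:
                raise ValueError(f"unknown predicate op {op!r}")
            out &= m.astype(bool)
        return out


@dataclass(frozen=True)
class FeatureDefinition:
    """One risk covariate, attached to exactly one impact factor."""

    name: str
    impact_factor: ImpactFactor
    kind: str  # window_ratio | quantile_set | cross_window_change | source_mix
    numerator: Optional[Predicate] = None
    denominator: Optional[Predicate] = None
    window_role: str = "long"  # long | short | both
    quantile: Optional[float] = None
    source: Optional[PrimarySource] = None


def default_catalog() -> list[FeatureDefinition]:
    """The shipped covariate catalog for the ICSR-process impact factor:
    timeliness/quality ratios, the source mix, submission-lateness
    quantiles and the cross-window AE/sales reporting-rate change."""
    f = ImpactFactor.ICSR_PROCESS
    cases = "cases"
    subs = "submissions"
    cat: list[FeatureDefinition] = []

    def ratio(name, num, den):
        cat.append(
            FeatureDefinition(
                name=name, impact_factor=f, kind="window_ratio", numerator=num, denominator=den
            )
        )

    for flag, label in (
        ("transferred", "transfer"),
        ("processed", "processing"),
        ("disposed", "disposal"),
    ):
        ratio(
            f"late_{label}_ratio",
            Predicate(cases, ((f"{flag}_late", "istrue"),)),
            Predicate(cases, ((f"{flag}_late", "notna"),)),
        )
    ratio(
        "invalidated_ae_ratio",
        Predicate(cases, (("invalidated", "istrue"),)),
        Predicate(cases),
    )
    ratio(
        "qc_updated_ratio",
        Predicate(cases, (("qc_updated", "istrue"),)),
        Predicate(cases),
    )
    ratio(
        "key_attr_correction_ratio",
        Predicate(cases, (("key_attr_corrections", "ne", ""),)),
        Predicate(cases),
    )
    ratio(
        "late_submission_ratio",
        Predicate(subs, (("submitted", "istrue"), ("days_late", "gt", 0))),
        Predicate(subs, (("submitted", "istrue"),)),
    )
    for dest, tag in (("health_authority", "ha"), ("license_partner", "lp")):
        ratio(
            f"unjustified_nonsubmission_{tag}_ratio",
            Predicate(
                subs,
                (
                    ("destination", "eq", dest),
                    ("submitted", "isfalse"),
                    ("justified_nonsubmission", "isfalse"),
                ),
            ),
            Predicate(subs, (("destination", "eq", dest), ("submitted", "isfalse"))),
        )
    ratio(
        "active_studies_no_ae_ratio",
        Predicate("active_studies", (("window_ae_count", "eq", 0),)),
        Predicate("active_studies"),
    )
    for src in PrimarySource:
        cat.append(
            FeatureDefinition(
                name=f"source_share_{src.value}",
                impact_factor=f,
                kind="source_mix",
                source=src,
            )
        )
    for q in DEFAULT_QUANTILES:
        cat.append(
            FeatureDefinition(
                name=f"days_late_q{int(round(q * 100))}",
                impact_factor=f,
                kind="quantile_set",
                quantile=q,
            )
        )
    cat.append(
        FeatureDefinition(
            name="ae_sales_rate_change",
            impact_factor=f,
            kind="cross_window_change",
            window_role="both",
        )
    )
    return cat


def catalog_for_factor(
    catalog: Sequence[FeatureDefinition], impact_factor: ImpactFactor
) -> list[FeatureDefinition]:
    return [d for d in catalog if d.impact_factor == impact_factor]


# --------------------------------------------------------------------------
# single-cell computations (reference path; the batch path must agree)
# --------------------------------------------------------------------------


def _submissions_frame(corpus: Corpus) -> pd.DataFrame:
    return corpus.submissions.merge(
        corpus.cases[["case_id", "affiliate_id", "received_date"]],
        on="case_id",
        how="left",
    )


def window_slice(
    corpus: Corpus,
    affiliate_id: str,
    t: pd.Timestamp,
    w_months: int,
    stream: str = "cases",
) -> pd.DataFrame:
    """Events of one affiliate with date in the half-open ``[t - W, t)``.

    Cases and submissions are windowed on the case's received date; sales
    on the sale month.  A record dated exactly ``t`` is excluded.
    """
    t = pd.Timestamp(t)
    lo = add_months(t, -w_months)
    if stream == "cases":
        df = corpus.cases
        m = (
            (df["affiliate_id"] == affiliate_id)
            & (df["received_date"] >= lo)
            & (df["received_date"] < t)
        )
        return df[m]
    if stream == "submissions":
        df = _submissions_frame(corpus)
        m = (
            (df["affiliate_id"] == affiliate_id)
            & (df["received_date"] >= lo)
            & (df["received_date"] < t)
        )
        return df[m]
    if stream == "sales":
        df = corpus.sales
        m = (df["affiliate_id"] == affiliate_id) & (df["month"] >= lo) & (df["month"] < t)
        return df[m]
    raise ValueError(f"unknown stream {stream!r}")


def _active_studies_frame(
    corpus: Corpus, affiliate_id: str, t: pd.Timestamp, w_months: int
) -> pd.DataFrame:
    """Studies of the affiliate whose active interval overlaps the window,
    with the count of window AEs linked to each by study_id."""
    t = pd.Timestamp(t)
    lo = add_months(t, -w_months)
    st = corpus.studies
    m = (
        (st["affiliate_id"] == affiliate_id)
        & (st["start_date"] < t)
        & (st["end_date"].isna() | (st["end_date"] >= lo))
    )
    active = st[m].copy()
    win_cases = window_slice(corpus, affiliate_id, t, w_months, stream="cases")
    counts = win_cases["study_id"].dropna().value_counts()
    active["window_ae_count"] = (
        active["study_id"].map(counts).fillna(0).astype(int)
    )
    return active


def _window_frame(
    defn_or_stream, corpus: Corpus, affiliate_id: str, t, w_months: int
) -> pd.DataFrame:
    stream = defn_or_stream if isinstance(defn_or_stream, str) else defn_or_stream.stream
    if stream == "active_studies":
        return _active_studies_frame(corpus, affiliate_id, t, w_months)
    return window_slice(corpus, affiliate_id, t, w_months, stream=stream)


def _ratio_window(defn: FeatureDefinition, spec: WindowSpec) -> int:
    return (
        spec.short_window_months if defn.window_role == "short" else spec.long_window_months
    )


def compute_ratio_feature(
    defn: FeatureDefinition,
    corpus: Corpus,
    affiliate_id: str,
    t: pd.Timestamp,
    spec: WindowSpec = WindowSpec(),
) -> float:
    """Numerator count / denominator count over the feature's window;
    ``MISSING`` when the denominator is empty."""
    if defn.kind != "window_ratio":
        raise ValueError(f"{defn.name} is not a window_ratio feature")
    w = _ratio_window(defn, spec)
    df = _window_frame(defn.denominator, corpus, affiliate_id, t, w)
    den = int(defn.denominator.mask(df).sum())
    if den == 0:
        return MISSING
    num = int(defn.numerator.mask(df).sum())
    return num / den


def compute_source_mix(
    corpus: Corpus,
    affiliate_id: str,
    t: pd.Timestamp,
    spec: WindowSpec = WindowSpec(),
) -> dict[PrimarySource, float]:
    """Share of window AEs per primary source; all ``MISSING`` when the
    window has no AEs, otherwise the shares sum to 1."""
    df = window_slice(corpus, affiliate_id, t, spec.long_window_months, stream="cases")
    total = len(df)
    if total == 0:
        return {s: MISSING for s in PrimarySource}
    counts = df["primary_source"].value_counts()
    return {s: int(counts.get(s.value, 0)) / total for s in PrimarySource}


def nearest_rank_quantile(values: np.ndarray, q: float) -> float:
    """Lower nearest-rank quantile: the ceil(q*n)-th smallest value."""
    n = len(values)
    if n == 0:
        return MISSING
    if not 0 < q <= 1:
        raise ValueError(f"quantile level must be in (0, 1], got {q}")
    idx = max(int(math.ceil(q * n)), 1) - 1
    return float(np.sort(np.asarray(values))[idx])


def compute_days_late_quantiles(
    corpus: Corpus,
    affiliate_id: str,
    t: pd.Timestamp,
    qs: Sequence[float] = DEFAULT_QUANTILES,
    spec: WindowSpec = WindowSpec(),
) -> dict[float, float]:
    """Lateness quantiles (days) over submitted cases in the long window."""
    if not qs:
        raise ValueError("qs must be nonempty")
    df = window_slice(corpus, affiliate_id, t, spec.long_window_months, stream="submissions")
    vals = df.loc[df["submitted"].fillna(False).astype(bool), "days_late"].dropna()
    arr = vals.to_numpy(dtype=float)
    return {q: nearest_rank_quantile(arr, q) for q in qs}


def _ae_sales_rate(corpus: Corpus, affiliate_id: str, t, w: int) -> float:
    ae = len(window_slice(corpus, affiliate_id, t, w, stream="cases"))
    sales = window_slice(corpus, affiliate_id, t, w, stream="sales")["units_sold"].sum()
    if sales == 0:
        return MISSING
    return ae / sales


def compute_cross_window_change(
    defn: FeatureDefinition,
    corpus: Corpus,
    affiliate_id: str,
    t: pd.Timestamp,
    spec: WindowSpec = WindowSpec(),
) -> float:
    """(short-window AE/sales rate) / (long-window AE/sales rate)."""
    if defn.kind != "cross_window_change":
        raise ValueError(f"{defn.name} is not a cross_window_change feature")
    r_long = _ae_sales_rate(corpus, affiliate_id, t, spec.long_window_months)
    r_short = _ae_sales_rate(corpus, affiliate_id, t, spec.short_window_months)
    if is_missing(r_long) or is_missing(r_short) or r_long == 0:
        return MISSING
    return r_short / r_long


def compute_feature_cell(
    defn: FeatureDefinition,
    corpus: Corpus,
    affiliate_id: str,
    t: pd.Timestamp,
    spec: WindowSpec = WindowSpec(),
) -> float:
    """Single-cell dispatch to the kind-appropriate computation."""
    if defn.kind == "window_ratio":
        return compute_ratio_feature(defn, corpus, affiliate_id, t, spec)
    if defn.kind == "source_mix":
        return compute_source_mix(corpus, affiliate_id, t, spec)[defn.source]
    if defn.kind == "quantile_set":
        return compute_days_late_quantiles(corpus, affiliate_id, t, (defn.quantile,), spec)[
            defn.quantile
        ]
    if defn.kind == "cross_window_change":
        return compute_cross_window_change(defn, corpus, affiliate_id, t, spec)
    raise ValueError(f"unknown feature kind {defn.kind!r}")


# --------------------------------------------------------------------------
# feature series (batch path)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FeatureVector:
    affiliate_id: str
    month: pd.Timestamp
    values: dict[str, float]


@dataclass
class FeatureSeries:
    """Multivariate time series of risk covariates for every affiliate.

    ``data`` is a wide frame indexed by (affiliate_id, month) over the
    complete grid — exactly |affiliates| x |grid| rows, NaN for MISSING.
    """

    data: pd.DataFrame
    spec: WindowSpec
    feature_names: list[str]

    @property
    def affiliates(self) -> list[str]:
        return list(self.data.index.levels[0])

    @property
    def months(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.data.index.levels[1])

    def vector(self, affiliate_id: str, month) -> FeatureVector:
        row = self.data.loc[(affiliate_id, pd.Timestamp(month))]
        return FeatureVector(
            affiliate_id=affiliate_id,
            month=pd.Timestamp(month),
            values={k: float(v) for k, v in row.items()},
        )

    def __iter__(self) -> Iterator[FeatureVector]:
        for (aff, month), row in self.data.iterrows():
            yield FeatureVector(aff, month, {k: float(v) for k, v in row.items()})

    def to_long_frame(self) -> pd.DataFrame:
        long = self.data.stack(future_stack=True).reset_index()
        long.columns = ["affiliate_id", "month", "feature", "value"]
        return long

    def to_csv(self, path: Union[str, Path]) -> None:
        long = self.to_long_frame()
        out = pd.DataFrame(
            {
                "affiliate_id": long["affiliate_id"],
                "month": long["month"].dt.strftime("%Y-%m"),
                "feature": long["feature"],
                "value": long["value"].map(lambda v: "" if pd.isna(v) else repr(float(v))),
            }
        )
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path], spec: WindowSpec = WindowSpec()) -> "FeatureSeries":
        raw = pd.read_csv(path, dtype={"affiliate_id": str, "feature": str})
        raw["month"] = pd.to_datetime(raw["month"], format="%Y-%m")
        wide = raw.pivot_table(
            index=["affiliate_id", "month"],
            columns="feature",
            values="value",
            aggfunc="first",
            dropna=False,
        )
        feature_order = list(dict.fromkeys(raw["feature"]))
        wide = wide[feature_order]
        wide.columns.name = None
        return cls(data=wide.astype(float), spec=spec, feature_names=feature_order)


def _window_sums(counts: np.ndarray, w: int) -> np.ndarray:
    """Per grid month t (axis 1): sum of counts over months [t-w, t)."""
    cz = np.concatenate(
        [np.zeros((counts.shape[0], 1)), np.cumsum(counts, axis=1)], axis=1
    )
    t_idx = np.arange(counts.shape[1])
    lo = np.maximum(t_idx - w, 0)
    return cz[:, t_idx] - cz[:, lo]


def _month_index(dates: pd.Series, grid: pd.DatetimeIndex) -> np.ndarray:
    base = grid[0].year * 12 + grid[0].month
    m = dates.dt.year * 12 + dates.dt.month - base
    return m.to_numpy(dtype=int)


def _panel(aff_idx, month_idx, weights, A, T) -> np.ndarray:
    arr = np.zeros((A, T))
    ok = (month_idx >= 0) & (month_idx < T) & (aff_idx >= 0)
    np.add.at(arr, (aff_idx[ok], month_idx[ok]), weights[ok] if weights is not None else 1.0)
    return arr


def build_feature_series(
    corpus: Corpus,
    catalog: Sequence[FeatureDefinition],
    spec: WindowSpec = WindowSpec(),
    affiliates: Optional[Sequence[str]] = None,
) -> FeatureSeries:
    """Evaluate the catalog for every (affiliate, grid month) cell.

    The result agrees exactly with the single-cell computations; it is
    organized around monthly per-affiliate aggregates plus cumulative-sum
    window reductions so large corpora stay cheap.
    """
    if not catalog:
        raise ValueError("feature catalog is empty")
    grid = monthly_grid(corpus.span)
    if affiliates is None:
        affiliates = corpus.affiliates
    affiliates = list(affiliates)
    A, T = len(affiliates), len(grid)
    aff_pos = {a: i for i, a in enumerate(affiliates)}

    cases = corpus.cases
    case_aff = cases["affiliate_id"].map(aff_pos).fillna(-1).to_numpy(dtype=int)
    case_month = (
        _month_index(cases["received_date"], grid) if len(cases) else np.zeros(0, dtype=int)
    )

    subs = _submissions_frame(corpus)
    sub_aff = subs["affiliate_id"].map(aff_pos).fillna(-1).to_numpy(dtype=int)
    sub_month = (
        _month_index(subs["received_date"], grid) if len(subs) else np.zeros(0, dtype=int)
    )

    sales = corpus.sales
    sale_aff = sales["affiliate_id"].map(aff_pos).fillna(-1).to_numpy(dtype=int)
    sale_month = _month_index(sales["month"], grid) if len(sales) else np.zeros(0, dtype=int)

    stream_ix = {
        "cases": (cases, case_aff, case_month),
        "submissions": (subs, sub_aff, sub_month),
    }

    def count_panel(pred: Predicate) -> np.ndarray:
        df, aff_idx, month_idx = stream_ix[pred.stream]
        m = pred.mask(df)
        return _panel(aff_idx[m], month_idx[m], None, A, T)

    columns: dict[str, np.ndarray] = {}
    win_cache: dict = {}

    def windowed(pred: Predicate, w: int) -> np.ndarray:
        key = (pred, w)
        if key not in win_cache:
            win_cache[key] = _window_sums(count_panel(pred), w)
        return win_cache[key]

    studies_needed = any(
        d.kind == "window_ratio" and d.denominator.stream == "active_studies" for d in catalog
    )
    if studies_needed:
        study_panels = _active_study_panels(
            corpus, affiliates, grid, spec.long_window_months
        )

    quantile_defs = [d for d in catalog if d.kind == "quantile_set"]
    if quantile_defs:
        qpanels = _quantile_panels(
            subs, sub_aff, sub_month, A, T, spec.long_window_months, quantile_defs
        )

    for defn in catalog:
        if defn.kind == "window_ratio":
            w = _ratio_window(defn, spec)
            if defn.denominator.stream == "active_studies":
                num, den = study_panels  # (active & no AE, active)
                with np.errstate(invalid="ignore", divide="ignore"):
                    columns[defn.name] = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
            else:
                den = windowed(defn.denominator, w)
                num = windowed(defn.numerator, w)
                columns[defn.name] = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
        elif defn.kind == "source_mix":
            total = windowed(Predicate("cases"), spec.long_window_months)
            srcp = windowed(
                Predicate("cases", (("primary_source", "eq", defn.source.value),)),
                spec.long_window_months,
            )
            columns[defn.name] = np.where(total > 0, srcp / np.where(total > 0, total, 1), np.nan)
        elif defn.kind == "quantile_set":
            columns[defn.name] = qpanels[defn.name]
        elif defn.kind == "cross_window_change":
            ae_l = windowed(Predicate("cases"), spec.long_window_months)
            ae_s = windowed(Predicate("cases"), spec.short_window_months)
            sales_panel = _panel(sale_aff, sale_month, sales["units_sold"].to_numpy(dtype=float), A, T)
            sl = _window_sums(sales_panel, spec.long_window_months)
            ss = _window_sums(sales_panel, spec.short_window_months)
            with np.errstate(invalid="ignore", divide="ignore"):
                rl = np.where(sl > 0, ae_l / np.where(sl > 0, sl, 1), np.nan)
                rs = np.where(ss > 0, ae_s / np.where(ss > 0, ss, 1), np.nan)
                change = np.where(
                    np.isnan(rl) | np.isnan(rs) | (rl == 0), np.nan, rs / np.where(rl != 0, rl, 1)
                )
            columns[defn.name] = change
        else:
            raise ValueError(f"unknown feature kind {defn.kind!r}")

    index = pd.MultiIndex.from_product([affiliates, grid], names=["affiliate_id", "month"])
    names = [d.name for d in catalog]
    data = pd.DataFrame(
        {name: columns[name].reshape(-1) for name in names}, index=index
    )
    return FeatureSeries(data=data, spec=spec, feature_names=names)


def _active_study_panels(
    corpus: Corpus, affiliates: list[str], grid: pd.DatetimeIndex, w: int
) -> tuple[np.ndarray, np.ndarray]:
    """(count of active studies with zero window AEs, count of active
    studies) per (affiliate, grid month)."""
    A, T = len(affiliates), len(grid)
    num = np.zeros((A, T))
    den = np.zeros((A, T))
    grid_ns = grid.asi8
    lo_ts = (grid.to_period("M") - w).to_timestamp()
    lo_ns = pd.DatetimeIndex(lo_ts).asi8
    cases = corpus.cases
    studies = corpus.studies
    for ai, aff in enumerate(affiliates):
        st = studies[studies["affiliate_id"] == aff]
        if not len(st):
            continue
        start_ns = st["start_date"].to_numpy().view("i8")
        end = st["end_date"]
        end_isna = end.isna().to_numpy()
        end_ns = end.to_numpy().view("i8")
        active = (start_ns[:, None] < grid_ns[None, :]) & (
            end_isna[:, None] | (end_ns[:, None] >= lo_ns[None, :])
        )
        # window AE counts per study over months [t-w, t)
        ca = cases[(cases["affiliate_id"] == aff) & cases["study_id"].notna()]
        counts = np.zeros((len(st), T))
        if len(ca):
            sid_pos = {sid: i for i, sid in enumerate(st["study_id"])}
            srow = ca["study_id"].map(sid_pos)
            ok = srow.notna().to_numpy()
            month_idx = _month_index(ca["received_date"], grid)
            inrange = ok & (month_idx >= 0) & (month_idx < T)
            np.add.at(
                counts,
                (srow.to_numpy()[inrange].astype(int), month_idx[inrange]),
                1.0,
            )
        win_counts = _window_sums(counts, w)
        den[ai] = active.sum(axis=0)
        num[ai] = (active & (win_counts == 0)).sum(axis=0)
    return num, den


def _quantile_panels(
    subs: pd.DataFrame,
    sub_aff: np.ndarray,
    sub_month: np.ndarray,
    A: int,
    T: int,
    w: int,
    defs: Sequence[FeatureDefinition],
) -> dict[str, np.ndarray]:
    """Window quantiles of days_late over submitted cases."""
    out = {d.name: np.full((A, T), np.nan) for d in defs}
    submitted = subs["submitted"].fillna(False).astype(bool).to_numpy()
    has_days = subs["days_late"].notna().to_numpy()
    m = submitted & has_days & (sub_aff >= 0) & (sub_month >= 0) & (sub_month < T)
    if not m.any():
        return out
    aff = sub_aff[m]
    mon = sub_month[m]
    val = subs["days_late"].to_numpy(dtype="float", na_value=np.nan)[m]
    order = np.lexsort((mon, aff))
    aff, mon, val = aff[order], mon[order], val[order]
    for ai in range(A):
        sel = aff == ai
        if not sel.any():
            continue
        months = mon[sel]
        values = val[sel]
        # bucket values by month for windowed concatenation
        buckets: list[np.ndarray] = [
            values[months == t] for t in range(T)
        ]
        cum_sizes = np.concatenate([[0], np.cumsum([len(b) for b in buckets])])
        flat = np.concatenate(buckets) if len(values) else np.zeros(0)
        for t in range(T):
            lo = max(t - w, 0)
            window_vals = flat[cum_sizes[lo] : cum_sizes[t]]
            if len(window_vals) == 0:
                continue
            s = np.sort(window_vals)
            n = len(s)
            for d in defs:
                idx = max(int(math.ceil(d.quantile * n)), 1) - 1
                out[d.name][ai, t] = s[idx]
    return out
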