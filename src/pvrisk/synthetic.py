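"""Synthetic PV corpora with known latent risk structure.

The real operational corpus behind this kind of audit risk assessment is
proprietary, so the package ships a generator that emulates its statistical
shape: a roster of affiliates whose operational quality drifts over time,
monthly streams of ICSR cases / submissions / sales / studies whose anomaly
rates follow latent per-affiliate processes, and a yearly schedule of
audits and inspections whose binary outcomes are Bernoulli draws from a
logistic model on those same latent rates.  Because the generating truth is
known, every pipeline stage — window features, training-set assembly,
logistic fit, calibration — can be tested end to end, including parameter
recovery.

Latent covariate dynamics
-------------------------
Each named rate (e.g. ``late_submission_ratio``) follows, per affiliate, a
logit-scale process

    logit(theta[a, t]) = base[a] + drift * t/(T-1) + ar[a, t]

with ``base[a] ~ Normal(logit(base_rate), spread)`` (persistent affiliate
differences), a linear drift over the span, and stationary AR(1) noise.
Audit outcomes for factor *f* are drawn with

    p*[a, t] = logistic(b0 + sum_j b_j * z_j[a, t])

where ``z_j`` standardizes the trailing window mean of ``theta_j`` across
all (affiliate, month) cells — the same quantity the pipeline's window
ratios estimate, so the fitted model is well specified by construction.

Every positive (event, factor) outcome receives at least one finding drawn
from that factor's statement pool; when ``total_findings`` is fixed the
remaining findings are allocated by a seeded multinomial so the corpus
matches the requested size exactly, not just in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .events import (
    AUDIT_COLUMNS,
    CASE_COLUMNS,
    Corpus,
    Destination,
    EventType,
    FINDING_COLUMNS,
    KeyAttribute,
    PrimarySource,
    STUDY_SOURCES,
)
from .features import monthly_grid
from .taxonomy import ImpactFactor, default_mapping

__all__ = [
    "CovariateDynamics",
    "FactorCoefficients",
    "SyntheticConfig",
    "LatentTruth",
    "ConfigError",
    "generate_corpus",
    "paper_profile_config",
    "recovery_profile_config",
    "default_statement_pools",
]


class ConfigError(ValueError):
    """Raised for infeasible generator configurations."""


@dataclass(frozen=True)
class CovariateDynamics:
    """Parameters of one latent rate process (logit scale unless noted)."""

    base_rate: float  # typical event probability, in (0, 1)
    spread: float = 0.7  # sd of the persistent per-affiliate level
    drift: float = 0.0  # total drift over the span
    ar_rho: float = 0.7  # AR(1) autocorrelation of the monthly noise
    ar_sigma: float = 0.25  # innovation sd of the monthly noise


@dataclass(frozen=True)
class FactorCoefficients:
    """Generating logistic coefficients for one impact factor; feature keys
    refer to names in ``covariate_dynamics``."""

    intercept: float
    features: dict[str, float] = field(default_factory=dict)


def _default_dynamics() -> dict[str, CovariateDynamics]:
    d = {
        "late_transfer_ratio": CovariateDynamics(0.10),
        "late_processing_ratio": CovariateDynamics(0.12),
        "late_disposal_ratio": CovariateDynamics(0.08),
        "invalidated_ae_ratio": CovariateDynamics(0.06),
        "qc_updated_ratio": CovariateDynamics(0.15),
        "key_attr_correction_ratio": CovariateDynamics(0.10),
        "late_submission_ratio": CovariateDynamics(0.15),
        "unjustified_nonsubmission_ha_ratio": CovariateDynamics(0.20),
        "unjustified_nonsubmission_lp_ratio": CovariateDynamics(0.25),
        # latent quality traits of the factors that have no corpus-observable
        # covariates; they make those factors' risks vary across affiliates
        "rmina_oversight_gap": CovariateDynamics(0.20),
        "dhpc_timeliness_gap": CovariateDynamics(0.15),
        "label_update_gap": CovariateDynamics(0.15),
    }
    return d


def default_statement_pools() -> dict[ImpactFactor, list[str]]:
    pools: dict[ImpactFactor, list[str]] = {f: [] for f in ImpactFactor}
    for code, factor in default_mapping().entries.items():
        pools[factor].append(code)
    return {f: sorted(codes) for f, codes in pools.items()}


@dataclass
class SyntheticConfig:
    n_affiliates: int
    span: tuple[pd.Timestamp, pd.Timestamp]
    audits_per_year: int
    inspections_per_year: int
    total_findings: Optional[int]  # None = free (AUTO)
    cases_per_affiliate_month: float
    source_mix_base: dict[PrimarySource, float]
    true_coefficients: dict[ImpactFactor, FactorCoefficients]
    covariate_dynamics: dict[str, CovariateDynamics] = field(
        default_factory=_default_dynamics
    )
    statement_pools: dict[ImpactFactor, list[str]] = field(
        default_factory=default_statement_pools
    )
    seed: int = 0
    window_months: int = 24  # trailing window defining the generating risk
    nonsubmission_rate: float = 0.05
    lp_submission_rate: float = 0.4
    studies_per_affiliate: float = 2.0
    auto_extra_findings_mean: float = 2.0

    def __post_init__(self) -> None:
        total = sum(self.source_mix_base.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"source_mix_base must sum to 1, got {total}")
        if self.cases_per_affiliate_month < 0:
            raise ConfigError("cases_per_affiliate_month must be >= 0")
        for factor, coef in self.true_coefficients.items():
            for name in coef.features:
                if name not in self.covariate_dynamics:
                    raise ConfigError(
                        f"{factor.value}: coefficient on unknown dynamics {name!r}"
                    )


@dataclass
class LatentTruth:
    """The unobservable generating state, exported for tests only."""

    theta: pd.DataFrame  # affiliate_id, month, feature, theta, theta_window
    risk: pd.DataFrame  # affiliate_id, month, impact_factor, p_true
    coefficients: dict[ImpactFactor, FactorCoefficients]
    standardization: dict[str, tuple[float, float]]  # feature -> (mean, sd)

    def risk_matrix(self, factor: ImpactFactor) -> pd.DataFrame:
        sub = self.risk[self.risk["impact_factor"] == factor.value]
        return sub.pivot(index="affiliate_id", columns="month", values="p_true")

    def to_csv(self, theta_path, risk_path) -> None:
        self.theta.to_csv(theta_path, index=False)
        self.risk.to_csv(risk_path, index=False)


def paper_profile_config(seed: int = 0) -> SyntheticConfig:
    """The default corpus profile: 8 full years, 24 audits and 2
    inspections per year over 104 affiliates (hence exactly 2 events per
    affiliate), and exactly 1171 findings — about 6 per event."""
    return SyntheticConfig(
        n_affiliates=104,
        span=(pd.Timestamp("2011-01-01"), pd.Timestamp("2018-12-31")),
        audits_per_year=24,
        inspections_per_year=2,
        total_findings=1171,
        cases_per_affiliate_month=8.0,
        source_mix_base={
            PrimarySource.SPONTANEOUS: 0.55,
            PrimarySource.LITERATURE: 0.12,
            PrimarySource.CLINICAL_STUDY: 0.18,
            PrimarySource.NON_INTERVENTIONAL_STUDY: 0.10,
            PrimarySource.OTHER: 0.05,
        },
        true_coefficients={
            ImpactFactor.ICSR_PROCESS: FactorCoefficients(
                intercept=0.3,
                features={
                    "late_submission_ratio": 1.0,
                    "invalidated_ae_ratio": 0.6,
                    "qc_updated_ratio": 0.8,
                },
            ),
            ImpactFactor.RISK_MINIMIZATION: FactorCoefficients(
                intercept=-0.2, features={"rmina_oversight_gap": 0.8}
            ),
            ImpactFactor.DHPC: FactorCoefficients(
                intercept=-0.8, features={"dhpc_timeliness_gap": 0.8}
            ),
            ImpactFactor.LOCAL_LABELS: FactorCoefficients(
                intercept=-0.5, features={"label_update_gap": 0.8}
            ),
        },
        seed=seed,
    )


def recovery_profile_config(seed: int = 42) -> SyntheticConfig:
    """A large-corpus profile for parameter-recovery checks: 5000 audit
    events (625/year over 8 years, 40 per affiliate) and high case volume
    so window ratios estimate the latent rates tightly.  The ICSR-process
    outcome is generated from intercept -1.5 and coefficients
    (1.0, -0.5, 2.0) on three window ratios."""
    return SyntheticConfig(
        n_affiliates=125,
        span=(pd.Timestamp("2011-01-01"), pd.Timestamp("2018-12-31")),
        audits_per_year=600,
        inspections_per_year=25,
        total_findings=None,
        cases_per_affiliate_month=40.0,
        source_mix_base={
            PrimarySource.SPONTANEOUS: 0.55,
            PrimarySource.LITERATURE: 0.12,
            PrimarySource.CLINICAL_STUDY: 0.18,
            PrimarySource.NON_INTERVENTIONAL_STUDY: 0.10,
            PrimarySource.OTHER: 0.05,
        },
        true_coefficients={
            ImpactFactor.ICSR_PROCESS: FactorCoefficients(
                intercept=-1.5,
                features={
                    "late_submission_ratio": 1.0,
                    "invalidated_ae_ratio": -0.5,
                    "qc_updated_ratio": 2.0,
                },
            ),
            ImpactFactor.RISK_MINIMIZATION: FactorCoefficients(intercept=-1.0),
            ImpactFactor.DHPC: FactorCoefficients(intercept=-1.5),
            ImpactFactor.LOCAL_LABELS: FactorCoefficients(intercept=-1.2),
        },
        seed=seed,
    )


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _latent_processes(
    config: SyntheticConfig, rng: np.random.Generator, A: int, T: int
) -> dict[str, np.ndarray]:
    theta = {}
    for name in sorted(config.covariate_dynamics):
        dyn = config.covariate_dynamics[name]
        base = logit(dyn.base_rate) + rng.normal(0.0, dyn.spread, size=A)
        ar = np.zeros((A, T))
        stat_sd = dyn.ar_sigma / math.sqrt(max(1.0 - dyn.ar_rho**2, 1e-12))
        ar[:, 0] = rng.normal(0.0, stat_sd, size=A)
        innov = rng.normal(0.0, dyn.ar_sigma, size=(A, T))
        for t in range(1, T):
            ar[:, t] = dyn.ar_rho * ar[:, t - 1] + innov[:, t]
        trend = dyn.drift * (np.arange(T) / max(T - 1, 1))
        theta[name] = expit(base[:, None] + trend[None, :] + ar)
    return theta


def _window_means(theta: np.ndarray, w: int) -> np.ndarray:
    """Trailing mean over months [t-w, t); at t=0 the current value."""
    A, T = theta.shape
    cz = np.concatenate([np.zeros((A, 1)), np.cumsum(theta, axis=1)], axis=1)
    t_idx = np.arange(T)
    lo = np.maximum(t_idx - w, 0)
    width = np.maximum(t_idx - lo, 1)
    out = (cz[:, t_idx] - cz[:, lo]) / width
    out[:, 0] = theta[:, 0]
    return out


def generate_corpus(
    config: SyntheticConfig, seed: Optional[int] = None
) -> tuple[Corpus, LatentTruth]:
    """Draw a full corpus plus its generating truth, reproducibly.

    The audit/inspection schedule (events per year, per-affiliate balance)
    and, when fixed, the total finding count are deterministic given the
    configuration; only which outcomes fire and the record-level noise
    change with the seed.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    span = (pd.Timestamp(config.span[0]), pd.Timestamp(config.span[1]))
    grid = monthly_grid(span)
    A, T = config.n_affiliates, len(grid)
    affiliates = [f"AFF{i + 1:03d}" for i in range(A)]
    W = config.window_months

    theta = _latent_processes(config, rng, A, T)
    theta_bar = {name: _window_means(arr, W) for name, arr in theta.items()}
    standardization = {}
    zscores = {}
    for name, arr in theta_bar.items():
        mu, sd = float(arr.mean()), float(arr.std())
        standardization[name] = (mu, sd)
        zscores[name] = (arr - mu) / sd if sd > 0 else np.zeros_like(arr)

    p_true = {}
    for factor, coef in config.true_coefficients.items():
        lp = np.full((A, T), coef.intercept)
        for name, b in coef.features.items():
            lp += b * zscores[name]
        p_true[factor] = expit(lp)

    # -- studies -----------------------------------------------------------
    study_rows = []
    studies_per_aff = 1 + rng.poisson(config.studies_per_affiliate, size=A)
    study_ids_by_aff: list[list[str]] = []
    for ai, aff in enumerate(affiliates):
        ids = []
        for k in range(studies_per_aff[ai]):
            start_t = int(rng.integers(0, max(T - 6, 1)))
            start = grid[start_t] + pd.Timedelta(days=int(rng.integers(0, 28)))
            dur = int(rng.integers(6, 60))
            open_ended = rng.random() < 0.3
            end_t = start_t + dur
            end = None if open_ended or end_t >= T else grid[min(end_t, T - 1)]
            sid = f"STUDY_{aff}_{k + 1:02d}"
            ids.append(sid)
            study_rows.append(
                {
                    "study_id": sid,
                    "affiliate_id": aff,
                    "start_date": start,
                    "end_date": pd.NaT if end is None else end,
                }
            )
        study_ids_by_aff.append(ids)

    # -- cases -------------------------------------------------------------
    counts = rng.poisson(config.cases_per_affiliate_month, size=(A, T))
    n_cases = int(counts.sum())
    aff_rep = np.repeat(np.arange(A)[:, None].repeat(T, axis=1).reshape(-1), counts.reshape(-1))
    t_rep = np.repeat(np.tile(np.arange(T), A), counts.reshape(-1))

    def theta_at(name):
        return theta[name][aff_rep, t_rep]

    day = rng.integers(1, 29, size=n_cases)
    received = grid.values[t_rep] + day.astype("timedelta64[D]") - np.timedelta64(1, "D")

    sources = list(PrimarySource)
    base_probs = np.array([config.source_mix_base[s] for s in sources])
    conc = 60.0
    mix = rng.dirichlet(np.maximum(base_probs * conc, 1e-3), size=A)
    cum_mix = np.cumsum(mix, axis=1)
    u = rng.random(n_cases)
    src_idx = (u[:, None] > cum_mix[aff_rep]).sum(axis=1)
    src_values = np.array([s.value for s in sources], dtype=object)[src_idx]

    is_study_case = np.isin(
        src_values, [s.value for s in STUDY_SOURCES]
    )
    study_id_col = np.full(n_cases, None, dtype=object)
    n_st = np.array([len(ids) for ids in study_ids_by_aff])
    if is_study_case.any():
        sel = np.flatnonzero(is_study_case)
        pick = np.floor(rng.random(len(sel)) * n_st[aff_rep[sel]]).astype(int)
        flat_ids = np.array(
            [sid for ids in study_ids_by_aff for sid in ids], dtype=object
        )
        offsets = np.concatenate([[0], np.cumsum(n_st)])
        study_id_col[sel] = flat_ids[offsets[aff_rep[sel]] + pick]

    invalidated = rng.random(n_cases) < theta_at("invalidated_ae_ratio")
    transferred_late = rng.random(n_cases) < theta_at("late_transfer_ratio")
    processed_late = rng.random(n_cases) < theta_at("late_processing_ratio")
    disposed_late = rng.random(n_cases) < theta_at("late_disposal_ratio")
    qc_updated = rng.random(n_cases) < theta_at("qc_updated_ratio")
    has_corr = rng.random(n_cases) < theta_at("key_attr_correction_ratio")
    attr_values = np.array([a.value for a in KeyAttribute], dtype=object)
    corr_pick = attr_values[rng.integers(0, len(attr_values), size=n_cases)]
    key_attrs = np.where(has_corr, corr_pick, "")
    workflow_cycles = rng.poisson(0.3, size=n_cases)

    case_ids = np.array([f"C{i + 1:07d}" for i in range(n_cases)], dtype=object)
    cases = pd.DataFrame(
        {
            "case_id": case_ids,
            "affiliate_id": np.array(affiliates, dtype=object)[aff_rep],
            "received_date": received,
            "primary_source": src_values,
            "study_id": study_id_col,
            "invalidated": invalidated,
            "transferred_late": transferred_late,
            "processed_late": processed_late,
            "disposed_late": disposed_late,
            "qc_updated": qc_updated,
            "workflow_cycles": workflow_cycles,
            "key_attr_corrections": key_attrs,
        },
        columns=CASE_COLUMNS,
    )

    # -- submissions -------------------------------------------------------
    span_end = np.datetime64(span[1], "ns")

    def _submission_block(sel: np.ndarray, destination: str, unjust_feature: str):
        k = len(sel)
        submitted = rng.random(k) >= config.nonsubmission_rate
        late = rng.random(k) < theta["late_submission_ratio"][aff_rep[sel], t_rep[sel]]
        days = np.where(late, rng.geometric(0.25, size=k), 0)
        sub_date = np.minimum(
            received[sel] + rng.integers(1, 40, size=k).astype("timedelta64[D]"),
            span_end,
        )
        unjust = rng.random(k) < theta[unjust_feature][aff_rep[sel], t_rep[sel]]
        return pd.DataFrame(
            {
                "case_id": case_ids[sel],
                "destination": destination,
                "submitted": submitted,
                "submission_date": np.where(submitted, sub_date, np.datetime64("NaT")),
                "days_late": pd.array(
                    np.where(submitted, days, -1), dtype="Int64"
                ),
                "justified_nonsubmission": pd.array(
                    np.where(submitted, None, ~unjust), dtype="boolean"
                ),
            }
        )

    all_idx = np.arange(n_cases)
    sub_ha = _submission_block(
        all_idx, Destination.HEALTH_AUTHORITY.value, "unjustified_nonsubmission_ha_ratio"
    )
    lp_sel = np.flatnonzero(rng.random(n_cases) < config.lp_submission_rate)
    sub_lp = _submission_block(
        lp_sel, Destination.LICENSE_PARTNER.value, "unjustified_nonsubmission_lp_ratio"
    )
    submissions = pd.concat([sub_ha, sub_lp], ignore_index=True)
    submissions.loc[~submissions["submitted"].astype(bool), "days_late"] = pd.NA

    # -- sales -------------------------------------------------------------
    level = rng.lognormal(mean=math.log(5e4), sigma=0.5, size=A)
    # whole units sold: keeps window sums exact in floating point
    units = np.round(level[:, None] * rng.lognormal(0.0, 0.1, size=(A, T)))
    sales = pd.DataFrame(
        {
            "affiliate_id": np.repeat(np.array(affiliates, dtype=object), T),
            "month": np.tile(grid.values, A),
            "units_sold": units.reshape(-1),
        }
    )

    # -- audit schedule ----------------------------------------------------
    years = range(span[0].year, span[1].year + 1)
    events_per_year = config.audits_per_year + config.inspections_per_year
    n_events = events_per_year * len(list(years))
    perm = rng.permutation(A)
    order = np.tile(perm, n_events // A + 1)[:n_events]
    audit_rows = []
    event_aff = []
    event_month = []
    k = 0
    for year in years:
        insp_pos = set(
            rng.choice(events_per_year, size=config.inspections_per_year, replace=False)
        )
        # partial calendar years at the span edges squeeze the schedule
        # into the covered months
        first_m = span[0].month - 1 if year == span[0].year else 0
        last_m = span[1].month - 1 if year == span[1].year else 11
        n_avail = last_m - first_m + 1
        for j in range(events_per_year):
            ai = int(order[k])
            month_in_year = first_m + (j * n_avail) // events_per_year
            date = min(
                pd.Timestamp(year, month_in_year + 1, int(rng.integers(5, 26))), span[1]
            )
            t_event = (year - span[0].year) * 12 + (month_in_year - span[0].month + 1)
            audit_rows.append(
                {
                    "audit_id": f"AUD{k + 1:05d}",
                    "affiliate_id": affiliates[ai],
                    "date": date,
                    "event_type": EventType.INSPECTION.value
                    if j in insp_pos
                    else EventType.AUDIT.value,
                }
            )
            event_aff.append(ai)
            event_month.append(t_event)
            k += 1
    audits = pd.DataFrame(audit_rows, columns=AUDIT_COLUMNS)

    # -- outcomes and findings --------------------------------------------
    factors = list(config.true_coefficients)
    positives: list[tuple[int, ImpactFactor]] = []
    for e in range(n_events):
        draws = rng.random(len(factors))
        for f_idx, factor in enumerate(factors):
            if draws[f_idx] < p_true[factor][event_aff[e], event_month[e]]:
                positives.append((e, factor))
    n_pos = len(positives)

    if config.total_findings is not None:
        if config.total_findings < n_pos:
            raise ConfigError(
                f"total_findings={config.total_findings} below the "
                f"{n_pos} positive (event, factor) outcomes"
            )
        extra = rng.multinomial(
            config.total_findings - n_pos, np.full(n_pos, 1.0 / n_pos)
        ) if n_pos else np.zeros(0, dtype=int)
    else:
        extra = rng.poisson(config.auto_extra_findings_mean, size=n_pos)
    finding_rows = []
    fid = 0
    for (e, factor), extra_k in zip(positives, extra):
        pool = config.statement_pools[factor]
        codes = rng.choice(pool, size=1 + int(extra_k))
        for code in codes:
            fid += 1
            finding_rows.append(
                {
                    "audit_id": audit_rows[e]["audit_id"],
                    "finding_id": f"F{fid:06d}",
                    "statement_code": str(code),
                    "statement_text": "",
                }
            )
    findings = pd.DataFrame(finding_rows, columns=FINDING_COLUMNS)

    corpus = Corpus(
        cases=cases,
        submissions=submissions,
        sales=sales,
        studies=pd.DataFrame(study_rows, columns=["study_id", "affiliate_id", "start_date", "end_date"]),
        audits=audits,
        findings=findings,
        span=span,
    )

    month_strs = grid
    theta_frames = []
    for name in sorted(theta):
        theta_frames.append(
            pd.DataFrame(
                {
                    "affiliate_id": np.repeat(np.array(affiliates, dtype=object), T),
                    "month": np.tile(month_strs, A),
                    "feature": name,
                    "theta": theta[name].reshape(-1),
                    "theta_window": theta_bar[name].reshape(-1),
                }
            )
        )
    risk_frames = []
    for factor in factors:
        risk_frames.append(
            pd.DataFrame(
                {
                    "affiliate_id": np.repeat(np.array(affiliates, dtype=object), T),
                    "month": np.tile(month_strs, A),
                    "impact_factor": factor.value,
                    "p_true": p_true[factor].reshape(-1),
                }
            )
        )
    truth = LatentTruth(
        theta=pd.concat(theta_frames, ignore_index=True),
        risk=pd.concat(risk_frames, ignore_index=True),
        coefficients=dict(config.true_coefficients),
        standardization=standardization,
    )
    return corpus, truth
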