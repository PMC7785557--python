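"""Per-impact-factor logistic risk models on audit outcomes.

The risk of an affiliate at a point in time is the unobserved probability
``p`` that an audit conducted then would yield a finding in the impact
factor of interest; the observed outcome of a past audit is a Bernoulli(p)
draw.  Past audits are single points in the affiliate's covariate time
series, so the model is a logistic regression of the binary audit outcomes
on the window covariates evaluated at the audit months:

    p = logistic(b0 + sum_j b_j * z_j),   z_j = (x_j - mean_j) / sd_j

with z-scoring by training statistics and an L2 penalty on the non-intercept
coefficients (audit outcomes are scarce relative to the covariate count, so
shrinkage is the default).  Factors with too few usable audits, a
single-class outcome, or no catalog features fall back to descriptive mode
and are visualized rather than modeled.

Fitting is a damped Newton iteration on the penalized binomial
log-likelihood, run to a fixed gradient-norm tolerance so identical
training sets give bitwise-identical coefficients.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .events import Corpus
from .features import FeatureDefinition, FeatureSeries, default_catalog
from .taxonomy import FindingMapping, ImpactFactor, label_outcomes_frame

__all__ = [
    "FitConfig",
    "TrainingSet",
    "RiskModel",
    "CalibrationReport",
    "assemble_training_set",
    "fit_risk_model",
    "predict_risk_series",
    "evaluate_model",
    "brier_score",
    "calibration_slope",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class FitConfig:
    """Hyperparameters of the logistic fit.

    l2_strength
        ridge penalty weight on standardized-scale coefficients (the
        intercept is never penalized); 0 disables shrinkage.
    min_audits
        minimum usable audit rows before a model is fitted at all; below
        it the factor falls back to descriptive mode.
    tol
        convergence threshold on the max-norm of the penalized gradient.
    """

    l2_strength: float = 1.0
    min_audits: int = 30
    tol: float = 1e-6
    max_iter: int = 200


@dataclass
class TrainingSet:
    """One row per audit/inspection event with usable covariates."""

    impact_factor: ImpactFactor
    X: pd.DataFrame  # imputed covariates, one row per kept event
    y: np.ndarray
    affiliate_ids: list[str]
    months: list[pd.Timestamp]
    event_types: list[str]
    feature_names: list[str]
    medians: dict[str, float]

    def __len__(self) -> int:
        return len(self.y)


@dataclass
class RiskModel:
    impact_factor: ImpactFactor
    feature_names: list[str]
    mode: str  # "model" | "descriptive"
    retained: list[str] = field(default_factory=list)
    means: dict[str, float] = field(default_factory=dict)
    sds: dict[str, float] = field(default_factory=dict)
    medians: dict[str, float] = field(default_factory=dict)
    intercept: Optional[float] = None
    coefficients: dict[str, float] = field(default_factory=dict)
    l2_strength: float = 1.0
    n_train: int = 0

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """b0 + sum_j b_j z_j for rows of raw (imputed) covariates."""
        if self.mode != "model":
            raise ValueError(f"{self.impact_factor.value}: descriptive model cannot predict")
        lp = np.full(len(X), float(self.intercept))
        for name in self.retained:
            z = (X[name].to_numpy(dtype=float) - self.means[name]) / self.sds[name]
            lp += self.coefficients[name] * z
        return lp


@dataclass(frozen=True)
class CalibrationReport:
    brier_score: float
    calibration_slope: float
    n_eval: int


def assemble_training_set(
    series: FeatureSeries,
    corpus: Corpus,
    mapping: FindingMapping,
    impact_factor: ImpactFactor,
    catalog: Optional[Sequence[FeatureDefinition]] = None,
    any_finding: bool = False,
) -> Optional[TrainingSet]:
    """Pair each audit with the covariate vector of its calendar month.

    The feature vector at the audit's grid month summarizes strictly
    pre-month data, so no audit-month events leak into its own covariates.
    MISSING values are median-imputed from the non-missing training values
    of the same feature; rows with every feature MISSING are dropped.

    Returns ``None`` when the factor has no catalog features (descriptive
    only).
    """
    if catalog is None:
        catalog = default_catalog()
    names = [
        d.name
        for d in catalog
        if d.impact_factor == impact_factor and d.name in series.feature_names
    ]
    if not names:
        return None

    labels = label_outcomes_frame(
        corpus.audits, corpus.findings, mapping, impact_factor, any_finding=any_finding
    )
    audits = corpus.audits
    audit_months = audits["date"].dt.to_period("M").dt.to_timestamp()
    lookup = pd.MultiIndex.from_arrays(
        [audits["affiliate_id"], audit_months], names=["affiliate_id", "month"]
    )
    pos = series.data.index.get_indexer(lookup)
    if (pos < 0).any():
        missing = audits["audit_id"].to_numpy()[pos < 0]
        raise ValueError(
            f"feature series grid does not cover audit(s) {list(missing[:5])}"
        )
    mat = series.data[names].to_numpy(dtype=float)[pos]
    keep = ~np.isnan(mat).all(axis=1) if len(mat) else np.zeros(0, dtype=bool)

    ys = labels.loc[audits["audit_id"].astype(str)].to_numpy()[keep]
    affs = audits["affiliate_id"].to_numpy()[keep].tolist()
    months = [pd.Timestamp(m) for m in audit_months.to_numpy()[keep]]
    etypes = audits["event_type"].to_numpy()[keep].tolist()
    X = pd.DataFrame(mat[keep], columns=names, dtype=float)
    medians = {}
    for name in names:
        defined = X[name].dropna()
        medians[name] = float(defined.median()) if len(defined) else 0.0
        X[name] = X[name].fillna(medians[name])
    return TrainingSet(
        impact_factor=impact_factor,
        X=X,
        y=ys.astype(float),
        affiliate_ids=affs,
        months=months,
        event_types=etypes,
        feature_names=names,
        medians=medians,
    )


def _penalized_logistic(
    X: np.ndarray, y: np.ndarray, l2: float, tol: float, max_iter: int
) -> np.ndarray:
    """Damped Newton maximization of the ridge-penalized binomial
    log-likelihood; the first column of X is the (unpenalized) intercept."""
    n, p = X.shape
    beta = np.zeros(p)
    pen = np.full(p, l2)
    pen[0] = 0.0

    def objective(b):
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(pen @ (b * b))

    obj = objective(beta)
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        grad = X.T @ (y - mu) - pen * beta
        if np.max(np.abs(grad)) < tol:
            return beta
        w = mu * (1.0 - mu)
        H = X.T @ (X * w[:, None]) + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        # step halving keeps the iteration monotone on flat likelihoods
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            cand_obj = objective(cand)
            if cand_obj >= obj - 1e-12:
                beta, obj = cand, cand_obj
                break
            scale *= 0.5
        else:  # pragma: no cover - pathological curvature
            return beta
    eta = X @ beta
    grad = X.T @ (y - expit(eta)) - pen * beta
    if np.max(np.abs(grad)) >= tol:
        raise RuntimeError(
            f"logistic fit did not reach gradient tolerance {tol} "
            f"(final gradient norm {np.max(np.abs(grad)):.3g})"
        )
    return beta


def fit_risk_model(train: TrainingSet, config: FitConfig = FitConfig()) -> RiskModel:
    """Fit the per-factor logistic model, or fall back to descriptive mode
    when there are fewer than ``min_audits`` rows or a single-class outcome.

    Constant features (zero training standard deviation) are dropped; the
    remaining features are z-scored with training means/sds before the
    penalized fit.  The result is deterministic in the training set.
    """
    n = len(train)
    base = dict(
        impact_factor=train.impact_factor,
        feature_names=list(train.feature_names),
        medians=dict(train.medians),
        l2_strength=config.l2_strength,
        n_train=n,
    )
    if n < config.min_audits or len(np.unique(train.y)) < 2:
        return RiskModel(mode="descriptive", **base)

    raw = train.X[train.feature_names].to_numpy(dtype=float)
    if not np.isfinite(raw).all():
        bad = [
            name
            for i, name in enumerate(train.feature_names)
            if not np.isfinite(raw[:, i]).all()
        ]
        raise ValueError(f"non-finite covariates after imputation: {bad}")
    means = raw.mean(axis=0)
    sds = raw.std(axis=0)
    keep = sds > 0
    retained = [name for name, k in zip(train.feature_names, keep) if k]
    Z = (raw[:, keep] - means[keep]) / sds[keep]
    design = np.hstack([np.ones((n, 1)), Z])
    beta = _penalized_logistic(
        design, train.y, config.l2_strength, config.tol, config.max_iter
    )
    return RiskModel(
        mode="model",
        retained=retained,
        means={name: float(m) for name, m in zip(retained, means[keep])},
        sds={name: float(s) for name, s in zip(retained, sds[keep])},
        intercept=float(beta[0]),
        coefficients={name: float(b) for name, b in zip(retained, beta[1:])},
        **base,
    )


def predict_risk_series(model: RiskModel, series: FeatureSeries) -> pd.Series:
    """Time-varying risk p for every (affiliate, month) grid cell.

    MISSING covariates are imputed with the training medians; cells where
    every factor feature is MISSING stay MISSING.  All defined values lie
    strictly inside (0, 1).
    """
    if model.mode != "model":
        raise ValueError(f"{model.impact_factor.value}: model is descriptive-only")
    missing_cols = [n for n in model.feature_names if n not in series.data.columns]
    if missing_cols:
        raise ValueError(
            f"feature series lacks model features {missing_cols}"
        )
    raw = series.data[model.feature_names]
    all_missing = raw.isna().all(axis=1)
    X = raw.fillna(model.medians)
    lp = model.linear_predictor(X)
    p = expit(lp)
    out = pd.Series(p, index=series.data.index, name="risk")
    out[all_missing.to_numpy()] = np.nan
    return out


def brier_score(p: np.ndarray, y: np.ndarray) -> float:
    """Mean squared distance between predicted probability and outcome."""
    p = np.asarray(p, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(p) == 0:
        raise ValueError("empty evaluation set")
    return float(np.mean((p - y) ** 2))


def calibration_slope(lp: np.ndarray, y: np.ndarray, tol: float = 1e-10) -> float:
    """MLE of s in  y ~ Bernoulli(logistic(s * lp)) — a one-parameter
    recalibration of the linear predictor; 1.0 means well calibrated."""
    lp = np.asarray(lp, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(lp) == 0:
        raise ValueError("empty evaluation set")
    if np.allclose(lp, 0.0):
        return float("nan")
    s = 1.0
    for _ in range(100):
        mu = expit(s * lp)
        g = float(lp @ (y - mu))
        h = float((lp * lp) @ (mu * (1.0 - mu)))
        if h <= 0:
            break
        step = g / h
        s += step
        if abs(step) < tol:
            break
    return float(s)


def evaluate_model(model: RiskModel, holdout: TrainingSet) -> CalibrationReport:
    """Brier score and calibration slope of the model on held-out audits."""
    if len(holdout) == 0:
        raise ValueError("empty holdout set")
    lp = model.linear_predictor(holdout.X)
    p = expit(lp)
    return CalibrationReport(
        brier_score=brier_score(p, holdout.y),
        calibration_slope=calibration_slope(lp, holdout.y),
        n_eval=len(holdout),
    )


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------


def save_model(model: RiskModel, path: Union[str, Path]) -> None:
    payload = {
        "impact_factor": model.impact_factor.value,
        "feature_names": model.feature_names,
        "mode": model.mode,
        "retained": model.retained,
        "means": model.means,
        "sds": model.sds,
        "medians": model.medians,
        "intercept": model.intercept,
        "coefficients": model.coefficients,
        "l2_strength": model.l2_strength,
        "n_train": model.n_train,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)
        fh.write("\n")


def load_model(path: Union[str, Path]) -> RiskModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return RiskModel(
        impact_factor=ImpactFactor(payload["impact_factor"]),
        feature_names=list(payload["feature_names"]),
        mode=payload["mode"],
        retained=list(payload["retained"]),
        means={k: float(v) for k, v in payload["means"].items()},
        sds={k: float(v) for k, v in payload["sds"].items()},
        medians={k: float(v) for k, v in payload["medians"].items()},
        intercept=None if payload["intercept"] is None else float(payload["intercept"]),
        coefficients={k: float(v) for k, v in payload["coefficients"].items()},
        l2_strength=float(payload["l2_strength"]),
        n_train=int(payload["n_train"]),
    )
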