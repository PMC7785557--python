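"""Logistic risk model: fitting, prediction, calibration, serialization."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import RECOVERY_FEATURES
from oracles import newton_raphson_logistic
from pvrisk.features import WindowSpec, build_feature_series, default_catalog
from pvrisk.model import (
    CalibrationReport,
    FitConfig,
    TrainingSet,
    assemble_training_set,
    brier_score,
    calibration_slope,
    evaluate_model,
    fit_risk_model,
    load_model,
    predict_risk_series,
    save_model,
)
from pvrisk.taxonomy import ImpactFactor


def _train(X: np.ndarray, y, names=None) -> TrainingSet:
    names = names or [f"x{j}" for j in range(X.shape[1])]
    df = pd.DataFrame(X, columns=names, dtype=float)
    return TrainingSet(
        impact_factor=ImpactFactor.ICSR_PROCESS,
        X=df,
        y=np.asarray(y, dtype=float),
        affiliate_ids=["A"] * len(df),
        months=[pd.Timestamp("2013-01-01")] * len(df),
        event_types=["audit"] * len(df),
        feature_names=names,
        medians={n: float(np.median(df[n])) if len(df) else 0.0 for n in names},
    )


def _random_train(n=40, p=3, seed=0, beta=None):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    beta = np.array(beta if beta is not None else [0.2] + [0.8, -0.5, 0.3][:p])
    lp = beta[0] + X @ beta[1:]
    y = (rng.random(n) < expit(lp)).astype(float)
    return _train(X, y)


class TestFit:
    def test_symmetric_degenerate_fit_is_all_zero(self):
        X = np.zeros((20, 3))
        y = [0, 1] * 10
        model = fit_risk_model(_train(X, y), FitConfig(min_audits=5))
        assert model.mode == "model"
        assert model.retained == []  # constant features dropped
        assert model.intercept == 0.0
        lp = model.linear_predictor(pd.DataFrame(X, columns=["x0", "x1", "x2"]))
        assert np.all(expit(lp) == 0.5)

    def test_below_min_audits_falls_back_to_descriptive(self):
        train = _random_train(n=10)
        model = fit_risk_model(train, FitConfig(min_audits=30))
        assert model.mode == "descriptive"
        assert model.intercept is None

    def test_single_class_outcome_falls_back_to_descriptive(self):
        train = _train(np.random.default_rng(0).normal(size=(50, 2)), [1.0] * 50)
        assert fit_risk_model(train, FitConfig(min_audits=5)).mode == "descriptive"

    def test_fit_is_bitwise_deterministic(self):
        train = _random_train(n=60)
        m1 = fit_risk_model(train)
        m2 = fit_risk_model(train)
        assert m1.intercept == m2.intercept
        assert m1.coefficients == m2.coefficients

    def test_unpenalized_fit_matches_newton_raphson_oracle(self):
        train = _random_train(n=20, p=2, seed=3)
        model = fit_risk_model(train, FitConfig(l2_strength=0.0, min_audits=5))
        raw = train.X.to_numpy()
        Z = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        design = np.hstack([np.ones((len(Z), 1)), Z])
        beta = newton_raphson_logistic(design, train.y)
        got = np.array([model.intercept] + [model.coefficients[n] for n in train.feature_names])
        np.testing.assert_allclose(got, beta, atol=1e-6)

    def test_penalized_fit_matches_sklearn_ridge_logistic(self):
        from sklearn.linear_model import LogisticRegression

        train = _random_train(n=80, p=3, seed=5)
        lam = 1.0
        model = fit_risk_model(train, FitConfig(l2_strength=lam, min_audits=5))
        raw = train.X.to_numpy()
        Z = (raw - raw.mean(axis=0)) / raw.std(axis=0)
        sk = LogisticRegression(
            C=1.0 / lam, solver="lbfgs", tol=1e-12, max_iter=10_000
        ).fit(Z, train.y)
        got = [model.coefficients[n] for n in train.feature_names]
        np.testing.assert_allclose(got, sk.coef_[0], atol=1e-4)
        np.testing.assert_allclose(model.intercept, sk.intercept_[0], atol=1e-4)

    def test_predictions_invariant_to_affine_feature_rescaling(self):
        train = _random_train(n=50, p=2, seed=7)
        cfg = FitConfig(l2_strength=0.0, min_audits=5)
        m1 = fit_risk_model(train, cfg)
        scaled = _train(train.X.to_numpy() * np.array([10.0, -3.0]) + 5.0, train.y)
        m2 = fit_risk_model(scaled, cfg)
        p1 = expit(m1.linear_predictor(train.X))
        p2 = expit(m2.linear_predictor(scaled.X))
        np.testing.assert_allclose(p1, p2, atol=1e-8)

    def test_nonfinite_covariate_aborts(self):
        X = np.random.default_rng(0).normal(size=(40, 2))
        X[3, 1] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            fit_risk_model(_train(X, [0, 1] * 20), FitConfig(min_audits=5))


class TestAssembly:
    def test_zero_audits_gives_empty_training_set(self, mapping):
        from conftest import corpus_of, mk_case

        corpus = corpus_of(cases=[mk_case()])
        series = build_feature_series(corpus, default_catalog(), WindowSpec())
        train = assemble_training_set(series, corpus, mapping, ImpactFactor.ICSR_PROCESS)
        assert len(train) == 0

    def test_factor_without_catalog_features_is_descriptive_only(self, small_corpus, mapping):
        series = build_feature_series(small_corpus, default_catalog(), WindowSpec())
        assert (
            assemble_training_set(series, small_corpus, mapping, ImpactFactor.DHPC)
            is None
        )

    def test_row_count_matches_brute_force_reconstruction(self, small_corpus, mapping):
        series = build_feature_series(small_corpus, default_catalog(), WindowSpec())
        train = assemble_training_set(
            series, small_corpus, mapping, ImpactFactor.ICSR_PROCESS
        )
        names = train.feature_names
        expected = 0
        for r in small_corpus.audits.itertuples(index=False):
            m = pd.Timestamp(r.date.year, r.date.month, 1)
            vec = series.data.loc[(r.affiliate_id, m), names]
            if not vec.isna().all():
                expected += 1
        assert len(train) == expected

    def test_single_positive_audit_row(self, mapping):
        from conftest import corpus_of, mk_audit, mk_case

        cases = [mk_case() for _ in range(6)]
        audit = mk_audit(codes=("ICSR_FOLLOWUP_NOT_PERFORMED",))
        corpus = corpus_of(cases=cases, audits=[audit])
        series = build_feature_series(corpus, default_catalog(), WindowSpec())
        train = assemble_training_set(series, corpus, mapping, ImpactFactor.ICSR_PROCESS)
        assert len(train) == 1
        assert train.y.tolist() == [1.0]


class TestPredict:
    def test_all_zero_coefficients_predict_half(self, small_corpus, mapping):
        series = build_feature_series(small_corpus, default_catalog(), WindowSpec())
        train = assemble_training_set(
            series, small_corpus, mapping, ImpactFactor.ICSR_PROCESS
        )
        model = fit_risk_model(train, FitConfig(min_audits=10**9))  # forces descriptive
        assert model.mode == "descriptive"
        fitted = fit_risk_model(train, FitConfig(min_audits=5))
        fitted.intercept = 0.0
        fitted.coefficients = {k: 0.0 for k in fitted.coefficients}
        risk = predict_risk_series(fitted, series)
        defined = risk.dropna()
        assert (defined == 0.5).all()

    def test_hand_computed_sigmoid_cell(self, recovery_bundle):
        model, series = recovery_bundle["model"], recovery_bundle["series"]
        cell = series.data.dropna().iloc[123]
        lp = model.intercept
        for name in model.retained:
            z = (cell[name] - model.means[name]) / model.sds[name]
            lp += model.coefficients[name] * z
        expected = 1.0 / (1.0 + math.exp(-lp))
        got = predict_risk_series(model, series).loc[cell.name]
        assert math.isclose(got, expected, abs_tol=1e-12)

    def test_risk_strictly_inside_unit_interval(self, recovery_bundle):
        risk = predict_risk_series(recovery_bundle["model"], recovery_bundle["series"])
        defined = risk.dropna().to_numpy()
        assert ((defined > 0) & (defined < 1)).all()

    def test_monotone_in_positive_coefficient_feature(self, recovery_bundle):
        model = recovery_bundle["model"]
        name = max(model.coefficients, key=lambda n: model.coefficients[n])
        base = pd.DataFrame(
            {n: [model.means[n]] for n in model.feature_names}
        )
        bumped = base.copy()
        bumped[name] += model.sds[name]
        assert model.linear_predictor(bumped)[0] > model.linear_predictor(base)[0]

    def test_feature_name_mismatch_aborts(self, recovery_bundle, small_corpus):
        series = build_feature_series(
            small_corpus,
            [d for d in default_catalog() if d.name == "late_transfer_ratio"],
            WindowSpec(),
        )
        with pytest.raises(ValueError, match="lacks model features"):
            predict_risk_series(recovery_bundle["model"], series)


class TestEvaluation:
    def test_perfect_predictions_have_zero_brier(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert brier_score(y, y) == 0.0

    def test_constant_half_has_quarter_brier(self):
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        assert brier_score(np.full(5, 0.5), y) == 0.25

    def test_empty_holdout_raises(self, recovery_bundle):
        empty = _train(np.zeros((0, 3)), [])
        with pytest.raises(ValueError, match="empty"):
            evaluate_model(recovery_bundle["model"], empty)

    def test_slope_near_one_when_outcomes_come_from_the_predictor(self):
        rng = np.random.default_rng(8)
        lp = rng.normal(0, 1.5, size=20_000)
        y = (rng.random(len(lp)) < expit(lp)).astype(float)
        s = calibration_slope(lp, y)
        assert 0.9 < s < 1.1


class TestSerialization:
    def test_model_json_round_trip(self, recovery_bundle, tmp_path):
        model = recovery_bundle["model"]
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert back.intercept == model.intercept
        assert back.coefficients == model.coefficients
        assert back.means == model.means
        assert back.sds == model.sds
        assert back.medians == model.medians
        assert back.mode == model.mode
        assert back.impact_factor == model.impact_factor
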