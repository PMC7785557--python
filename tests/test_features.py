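"""Sliding-window covariates: boundary conventions, arithmetic, oracles."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from conftest import corpus_of, make_config, mk_case, mk_sub
from oracles import oracle_feature, sub_months
from pvrisk.events import Corpus, Destination, PrimarySource, SalesRecord, StudyRecord
from pvrisk.features import (
    MISSING,
    FeatureSeries,
    WindowSpec,
    build_feature_series,
    compute_cross_window_change,
    compute_days_late_quantiles,
    compute_feature_cell,
    compute_ratio_feature,
    compute_source_mix,
    default_catalog,
    is_missing,
    monthly_grid,
    window_slice,
)
from pvrisk.synthetic import generate_corpus

CATALOG = default_catalog()
BY_NAME = {d.name: d for d in CATALOG}
T0 = pd.Timestamp("2013-06-01")


def random_corpus(seed: int) -> Corpus:
    corpus, _ = generate_corpus(
        make_config(n_affiliates=2, cases_per_affiliate_month=5.0), seed=seed
    )
    return corpus


class TestWindowSlice:
    def test_window_before_corpus_start_is_empty(self, small_corpus):
        aff = small_corpus.affiliates[0]
        assert len(window_slice(small_corpus, aff, pd.Timestamp("2011-06-01"), 6)) == 0

    def test_event_on_window_end_is_excluded(self):
        corpus = corpus_of(cases=[mk_case(received=dt.date(2013, 6, 1), affiliate="A1")])
        assert len(window_slice(corpus, "A1", T0, 24)) == 0
        assert len(window_slice(corpus, "A1", pd.Timestamp("2013-07-01"), 24)) == 1

    def test_matches_brute_force_filter(self):
        corpus = random_corpus(11)
        rng = np.random.default_rng(0)
        grid = monthly_grid(corpus.span)
        for _ in range(20):
            aff = rng.choice(corpus.affiliates)
            t = grid[rng.integers(0, len(grid))]
            w = int(rng.integers(1, 30))
            got = window_slice(corpus, aff, t, w)
            lo = sub_months(t, w)
            expected = [
                r.case_id
                for r in corpus.cases.itertuples(index=False)
                if r.affiliate_id == aff and lo <= r.received_date < t
            ]
            assert sorted(got["case_id"]) == sorted(expected)


class TestRatioFeatures:
    def test_zero_denominator_is_missing(self):
        corpus = corpus_of(cases=[])
        val = compute_ratio_feature(BY_NAME["late_submission_ratio"], corpus, "A1", T0)
        assert is_missing(val)

    def test_three_late_of_twelve_submitted_is_quarter(self):
        cases = [
            mk_case(
                received=dt.date(2012, 6, 1),
                submissions=(mk_sub(days_late=5 if i < 3 else 0),),
            )
            for i in range(12)
        ]
        corpus = corpus_of(cases=cases)
        assert compute_ratio_feature(BY_NAME["late_submission_ratio"], corpus, "A1", T0) == 0.25

    def test_unjustified_split_by_destination(self):
        cases = [
            mk_case(
                submissions=(
                    mk_sub(submitted=False, justified=(i % 2 == 0)),
                    mk_sub(
                        destination=Destination.LICENSE_PARTNER,
                        submitted=False,
                        justified=True,
                    ),
                ),
            )
            for i in range(4)
        ]
        corpus = corpus_of(cases=cases)
        ha = compute_ratio_feature(
            BY_NAME["unjustified_nonsubmission_ha_ratio"], corpus, "A1", T0
        )
        lp = compute_ratio_feature(
            BY_NAME["unjustified_nonsubmission_lp_ratio"], corpus, "A1", T0
        )
        assert ha == 0.5
        assert lp == 0.0

    def test_active_study_without_ae(self):
        studies = [
            StudyRecord(study_id="S1", affiliate_id="A1", start_date=dt.date(2012, 1, 1)),
            StudyRecord(study_id="S2", affiliate_id="A1", start_date=dt.date(2012, 1, 1)),
            # ended before the window -> not active
            StudyRecord(
                study_id="S3",
                affiliate_id="A1",
                start_date=dt.date(2011, 1, 1),
                end_date=dt.date(2011, 3, 1),
            ),
        ]
        cases = [
            mk_case(source=PrimarySource.CLINICAL_STUDY, study_id="S1"),
        ]
        corpus = corpus_of(cases=cases, studies=studies)
        val = compute_ratio_feature(BY_NAME["active_studies_no_ae_ratio"], corpus, "A1", T0)
        assert val == 0.5  # S2 of {S1, S2}


class TestSourceMix:
    def test_degenerate_mix_is_all_spontaneous(self):
        corpus = corpus_of(cases=[mk_case() for _ in range(5)])
        mix = compute_source_mix(corpus, "A1", T0)
        assert mix[PrimarySource.SPONTANEOUS] == 1.0
        assert mix[PrimarySource.LITERATURE] == 0.0

    def test_empty_window_is_all_missing(self):
        corpus = corpus_of(cases=[])
        mix = compute_source_mix(corpus, "A1", T0)
        assert all(is_missing(v) for v in mix.values())

    def test_mix_sums_to_one_and_matches_oracle(self):
        corpus = random_corpus(5)
        grid = monthly_grid(corpus.span)
        for aff in corpus.affiliates:
            mix = compute_source_mix(corpus, aff, grid[-1])
            if any(is_missing(v) for v in mix.values()):
                continue
            assert math.isclose(sum(mix.values()), 1.0, abs_tol=1e-12)
            for src, val in mix.items():
                assert val == oracle_feature(
                    f"source_share_{src.value}", corpus, aff, grid[-1]
                )


class TestQuantiles:
    def test_all_on_time_gives_zero_quantiles(self):
        cases = [mk_case(submissions=(mk_sub(days_late=0),)) for _ in range(7)]
        corpus = corpus_of(cases=cases)
        qs = compute_days_late_quantiles(corpus, "A1", T0)
        assert set(qs.values()) == {0.0}

    def test_median_of_0_0_10_is_zero(self):
        cases = [
            mk_case(submissions=(mk_sub(days_late=d),)) for d in (0, 0, 10)
        ]
        corpus = corpus_of(cases=cases)
        assert compute_days_late_quantiles(corpus, "A1", T0, qs=(0.5,))[0.5] == 0.0

    def test_matches_sort_and_index_oracle(self):
        corpus = random_corpus(9)
        grid = monthly_grid(corpus.span)
        for aff in corpus.affiliates:
            got = compute_days_late_quantiles(corpus, aff, grid[-1], qs=(0.5, 0.9, 1.0))
            for q, name in [(0.5, "days_late_q50"), (0.9, "days_late_q90"), (1.0, "days_late_q100")]:
                expected = oracle_feature(name, corpus, aff, grid[-1])
                assert got[q] == expected or (is_missing(got[q]) and is_missing(expected))


class TestCrossWindow:
    def _corpus(self, ae_per_month_long=2, ae_per_month_short=2):
        cases = []
        months = pd.date_range("2011-07-01", "2013-05-01", freq="MS")
        for m in months:
            n = ae_per_month_short if m >= pd.Timestamp("2012-12-01") else ae_per_month_long
            for _ in range(n):
                cases.append(mk_case(received=m.date()))
        sales = [
            SalesRecord(affiliate_id="A1", month=m.date(), units_sold=10.0) for m in months
        ]
        return corpus_of(cases=cases, sales=sales)

    def test_equal_rates_give_unity(self):
        corpus = self._corpus(2, 2)
        val = compute_cross_window_change(
            BY_NAME["ae_sales_rate_change"], corpus, "A1", T0
        )
        assert math.isclose(val, 1.0, rel_tol=1e-12)

    def test_doubled_short_window_rate(self):
        # short window (6m) has 4 AEs/month, earlier months 2/month
        corpus = self._corpus(2, 4)
        val = compute_cross_window_change(
            BY_NAME["ae_sales_rate_change"], corpus, "A1", T0
        )
        # long window holds 23 data months: 17 at 2/month then 6 at 4/month
        long_rate = (17 * 2 + 4 * 6) / (10.0 * 23)
        short_rate = (4 * 6) / (10.0 * 6)
        assert math.isclose(val, short_rate / long_rate, rel_tol=1e-12)

    def test_zero_sales_is_missing(self):
        corpus = corpus_of(cases=[mk_case()])
        val = compute_cross_window_change(
            BY_NAME["ae_sales_rate_change"], corpus, "A1", T0
        )
        assert is_missing(val)


class TestSeries:
    def test_empty_corpus_with_declared_roster_is_all_missing(self):
        corpus = Corpus(span=(pd.Timestamp("2012-01-01"), pd.Timestamp("2012-12-31")))
        series = build_feature_series(
            corpus, CATALOG, WindowSpec(), affiliates=["A1", "A2", "A3"]
        )
        assert series.data.shape == (3 * 12, len(CATALOG))
        assert series.data.isna().all().all()

    def test_complete_grid_cardinality(self, small_corpus):
        series = build_feature_series(small_corpus, CATALOG, WindowSpec())
        grid = monthly_grid(small_corpus.span)
        assert len(series.data) == len(small_corpus.affiliates) * len(grid)

    def test_spot_cells_match_single_cell_computation(self):
        corpus = random_corpus(13)
        spec = WindowSpec()
        series = build_feature_series(corpus, CATALOG, spec)
        grid = monthly_grid(corpus.span)
        rng = np.random.default_rng(1)
        for _ in range(10):
            aff = rng.choice(corpus.affiliates)
            t = grid[rng.integers(0, len(grid))]
            defn = CATALOG[rng.integers(0, len(CATALOG))]
            batch = series.data.at[(aff, t), defn.name]
            single = compute_feature_cell(defn, corpus, aff, t, spec)
            assert batch == single or (is_missing(batch) and is_missing(single))

    def test_shifting_all_events_one_month_shifts_the_series(self):
        corpus = random_corpus(17)
        shifted = Corpus(
            cases=corpus.cases.assign(
                received_date=corpus.cases["received_date"] + pd.DateOffset(months=1)
            ),
            submissions=corpus.submissions.assign(
                submission_date=corpus.submissions["submission_date"]
                + pd.DateOffset(months=1)
            ),
            sales=corpus.sales.assign(month=corpus.sales["month"] + pd.DateOffset(months=1)),
            studies=corpus.studies.assign(
                start_date=corpus.studies["start_date"] + pd.DateOffset(months=1),
                end_date=corpus.studies["end_date"] + pd.DateOffset(months=1),
            ),
            audits=corpus.audits.assign(date=corpus.audits["date"] + pd.DateOffset(months=1)),
            findings=corpus.findings,
            span=(
                corpus.span[0] + pd.DateOffset(months=1),
                corpus.span[1] + pd.DateOffset(months=1),
            ),
        )
        base = build_feature_series(corpus, CATALOG, WindowSpec())
        moved = build_feature_series(shifted, CATALOG, WindowSpec())
        a = base.data.to_numpy()
        b = moved.data.to_numpy()
        np.testing.assert_array_equal(a, b)  # same grid offsets, shifted calendar

    def test_locality_event_outside_window_changes_nothing(self):
        cases = [mk_case(received=dt.date(2012, 6, 1)) for _ in range(5)]
        base = corpus_of(cases=cases)
        extra = corpus_of(cases=cases + [mk_case(received=dt.date(2013, 7, 2))])
        spec = WindowSpec()
        s1 = build_feature_series(base, CATALOG, spec, affiliates=["A1"])
        s2 = build_feature_series(extra, CATALOG, spec, affiliates=["A1"])
        row1 = s1.data.loc[("A1", T0)]
        row2 = s2.data.loc[("A1", T0)]
        pd.testing.assert_series_equal(row1, row2)

    def test_duplicating_events_leaves_ratios_unchanged(self):
        cases = [
            mk_case(
                received=dt.date(2012, 6, 1),
                invalidated=(i % 3 == 0),
                qc_updated=(i % 2 == 0),
                submissions=(mk_sub(days_late=3 if i % 4 == 0 else 0),),
            )
            for i in range(8)
        ]
        dup = [
            mk_case(
                received=c.received_date,
                invalidated=c.invalidated,
                qc_updated=c.qc_updated,
                submissions=c.submissions,
            )
            for c in cases
            for _ in range(2)
        ]
        ratio_names = [d.name for d in CATALOG if d.kind in ("window_ratio", "source_mix")]
        r1 = {
            n: compute_feature_cell(BY_NAME[n], corpus_of(cases=cases), "A1", T0)
            for n in ratio_names
        }
        r3 = {
            n: compute_feature_cell(BY_NAME[n], corpus_of(cases=cases + dup), "A1", T0)
            for n in ratio_names
        }
        for n in ratio_names:
            assert r1[n] == r3[n] or (is_missing(r1[n]) and is_missing(r3[n]))

    def test_ratio_outputs_lie_in_unit_interval(self):
        corpus = random_corpus(23)
        series = build_feature_series(corpus, CATALOG, WindowSpec())
        ratio_names = [d.name for d in CATALOG if d.kind in ("window_ratio", "source_mix")]
        vals = series.data[ratio_names].to_numpy()
        defined = vals[~np.isnan(vals)]
        assert ((defined >= 0) & (defined <= 1)).all()

    def test_long_csv_round_trip(self, small_corpus, tmp_path):
        series = build_feature_series(small_corpus, CATALOG, WindowSpec())
        path = tmp_path / "features.csv"
        series.to_csv(path)
        back = FeatureSeries.from_csv(path)
        pd.testing.assert_frame_equal(series.data, back.data, check_names=False)
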