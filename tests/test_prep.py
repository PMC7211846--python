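"""Person-month construction, censoring rules, risk rule, window covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from droughtdemog.climate import interpolate_daily
from droughtdemog.prep import (
    _risk_vector,
    add_months,
    assign_hydro_year,
    build_person_months,
    extreme_flags,
    infanticide_risk,
    scale_continuous,
    window_covariates,
)


class TestHydroYear:
    @pytest.mark.parametrize(
        "date,label",
        [
            ("2015-05-15", 2015),  # first day of the 2015 hydro-year
            ("2016-05-14", 2015),  # last day of the 2015 hydro-year
            ("2015-11-15", 2015),  # hydro-year midpoint
            ("2015-05-14", 2014),
            ("2015-01-01", 2014),
        ],
    )
    def test_boundaries(self, date, label):
        assert assign_hydro_year(date) == label

    def test_vectorized_matches_scalar(self):
        days = pd.date_range("2010-01-01", "2012-12-31", freq="7D")
        vec = assign_hydro_year(days)
        scalar = [assign_hydro_year(d) for d in days]
        assert list(vec) == scalar

    def test_every_date_maps_to_exactly_one_hydro_year(self):
        days = pd.date_range("2014-01-01", "2017-12-31")
        labels = assign_hydro_year(days)
        # labels partition the calendar: non-decreasing, steps of one year
        assert set(np.diff(labels)) <= {0, 1}
        assert set(labels) == {2013, 2014, 2015, 2016, 2017}


def _bio(rows):
    cols = [
        "individual_id",
        "species",
        "sex",
        "mother_id",
        "group_id",
        "birth_date",
        "entry_type",
        "departure_type",
        "departure_date",
        "last_seen_date",
    ]
    return pd.DataFrame(rows, columns=cols)


def _infant(iid, species, birth, dep_type, dep_date, mother="m1"):
    return (
        iid,
        species,
        "f",
        mother,
        "g0",
        pd.Timestamp(birth),
        "birth",
        dep_type,
        pd.Timestamp(dep_date),
        pd.Timestamp(dep_date),
    )


class TestBuildPersonMonths:
    def test_survivor_censored_at_weaning(self):
        bio = _bio([_infant("i1", "capuchin", "2010-01-10", "censored_alive", "2014-01-01")])
        pm = build_person_months(bio, "capuchin")
        assert len(pm) == 14
        assert pm["event"].sum() == 0
        assert pm["interval_index"].tolist() == list(range(1, 15))
        assert pm["window_close_date"].iloc[0] == pd.Timestamp("2010-02-10")

    def test_infant_only_disappearance_is_death(self):
        # spider monkey disappearing alone at age 3.5 months: 4 rows, event in row 4
        bio = _bio(
            [_infant("i1", "spider_monkey", "2010-01-01", "disappearance_unknown", "2010-04-16")]
        )
        with pytest.warns(UserWarning, match="mother"):
            pm = build_person_months(bio, "spider_monkey")
        assert len(pm) == 4
        assert pm["event"].tolist() == [0, 0, 0, 1]

    def test_joint_disappearance_censored(self):
        rows = [
            _infant("i1", "capuchin", "2010-01-01", "disappearance_unknown", "2010-06-01"),
            (
                "m1",
                "capuchin",
                "f",
                None,
                "g0",
                pd.NaT,
                "start_of_observation",
                "disappearance_unknown",
                pd.Timestamp("2010-06-01"),
                pd.Timestamp("2010-06-01"),
            ),
        ]
        pm = build_person_months(_bio(rows), "capuchin")
        assert len(pm) == 5
        assert pm["event"].sum() == 0

    def test_confirmed_death_mid_interval(self):
        # death at age 3.2 months sits in interval 4
        bio = _bio([_infant("i1", "capuchin", "2010-01-01", "death", "2010-04-07")])
        pm = build_person_months(bio, "capuchin")
        assert len(pm) == 4
        assert pm["event"].tolist() == [0, 0, 0, 1]

    def test_death_after_weaning_censored(self):
        bio = _bio([_infant("i1", "capuchin", "2010-01-01", "death", "2012-01-01")])
        pm = build_person_months(bio, "capuchin")
        assert len(pm) == 14
        assert pm["event"].sum() == 0

    def test_birth_after_departure_rejected(self):
        bio = _bio([_infant("i1", "capuchin", "2010-05-01", "death", "2010-01-01")])
        with pytest.raises(ValueError, match="precedes birth"):
            build_person_months(bio, "capuchin")

    def test_adults_without_birth_dates_excluded(self):
        rows = [
            (
                "a1",
                "capuchin",
                "f",
                None,
                "g0",
                pd.NaT,
                "start_of_observation",
                "censored_alive",
                pd.Timestamp("2015-01-01"),
                pd.Timestamp("2015-01-01"),
            )
        ]
        assert build_person_months(_bio(rows), "capuchin").empty

    @given(st.integers(min_value=1, max_value=30))
    @settings(max_examples=20, deadline=None)
    def test_monotone_censoring(self, months_observed):
        """Shortening an infant's observation never adds rows or events."""
        birth = pd.Timestamp("2010-01-01")
        full = _bio(
            [_infant("i1", "capuchin", birth, "censored_alive", add_months(birth, 30))]
        )
        short = _bio(
            [
                _infant(
                    "i1", "capuchin", birth, "censored_alive", add_months(birth, months_observed)
                )
            ]
        )
        n_full = len(build_person_months(full, "capuchin"))
        n_short = len(build_person_months(short, "capuchin"))
        assert n_short <= n_full


def _tenures(starts, group="g0"):
    starts = [pd.Timestamp(s) for s in starts]
    return pd.DataFrame(
        {
            "group_id": group,
            "male_id": [f"m{i}" for i in range(len(starts))],
            "start_date": starts,
            "end_date": starts[1:] + [pd.NaT],
        }
    )


class TestInfanticideRisk:
    def test_replacement_before_conception_is_low(self):
        # replacement 2 months before conception: condition (i) false
        ten = _tenures(["2008-01-01", "2009-05-01"])
        assert infanticide_risk("2010-01-01", 5, ten) == "low"

    def test_replacement_after_birth_high_while_young(self):
        ten = _tenures(["2008-01-01", "2010-02-01"])
        assert infanticide_risk("2010-01-01", 5, ten) == "high"

    def test_risk_expires_at_one_year(self):
        ten = _tenures(["2008-01-01", "2010-02-01"])
        assert infanticide_risk("2010-01-01", 13, ten) == "low"

    def test_replacement_must_precede_evaluation(self):
        # replacement happens at age 8 months; at age 5 it has not yet occurred
        ten = _tenures(["2008-01-01", "2010-09-01"])
        assert infanticide_risk("2010-01-01", 5, ten) == "low"
        assert infanticide_risk("2010-01-01", 9, ten) == "high"

    def test_no_coverage_rejected(self):
        ten = _tenures(["2012-01-01"])
        with pytest.raises(ValueError, match="cover"):
            infanticide_risk("2010-01-01", 5, ten)

    def test_vectorized_matches_rowwise(self):
        ten = _tenures(["2008-01-01", "2010-03-20", "2011-06-05"])
        birth = pd.Timestamp("2010-01-15")
        pm = pd.DataFrame(
            {
                "birth_date": birth,
                "group_id": "g0",
                "interval_index": np.arange(1, 15),
                "window_close_date": [add_months(birth, m) for m in range(1, 15)],
            }
        )
        vec = _risk_vector(pm, ten, 5.5)
        row = [
            infanticide_risk(birth, m, ten, gestation_months=5.5) for m in range(1, 15)
        ]
        assert list(vec) == row


class TestWindowCovariates:
    def _series(self, days, values):
        return pd.Series(values, index=days, dtype=float)

    def test_constant_fruit(self):
        days = pd.date_range("2010-01-01", "2011-12-31")
        fruit = self._series(days, 3.0)
        spei = {1: pd.Series(0.5, pd.period_range("2010-01", periods=24, freq="M"))}
        out = window_covariates(fruit, spei, "2011-06-15", scales=(1,))
        assert out["fruit_mean_1"] == pytest.approx(3.0)
        assert out["spei_1"] == pytest.approx(0.5)

    def test_linear_ramp_mean_half(self):
        days = pd.date_range("2010-01-01", "2010-12-31")
        ramp = np.linspace(0, 1, len(days))
        fruit = self._series(days, ramp)
        spei = {1: pd.Series(0.0, pd.period_range("2010-01", periods=12, freq="M"))}
        out = window_covariates(fruit, spei, "2010-12-31", scales=(1,))
        window = fruit.loc["2010-12-01":"2010-12-31"]
        assert out["fruit_mean_1"] == pytest.approx(window.mean())

    def test_step_change_matches_brute_force(self):
        days = pd.date_range("2010-01-01", "2010-03-01")
        vals = np.where(days < pd.Timestamp("2010-02-01"), 1.0, 3.0)
        fruit = self._series(days, vals)
        spei = {1: pd.Series(0.0, pd.period_range("2010-01", periods=3, freq="M"))}
        out = window_covariates(fruit, spei, "2010-03-01", scales=(1,))
        brute = fruit.loc["2010-02-02":"2010-03-01"].mean()
        assert out["fruit_mean_1"] == pytest.approx(brute, abs=1e-9)

    def test_window_before_data_start_missing(self):
        days = pd.date_range("2010-06-01", "2010-12-31")
        fruit = self._series(days, 1.0)
        spei = {12: pd.Series(0.0, pd.period_range("2010-06", periods=7, freq="M"))}
        out = window_covariates(fruit, spei, "2010-12-01", scales=(12,))
        assert np.isnan(out["fruit_mean_12"])

    def test_spei_interpolated_to_close_date(self):
        days = pd.date_range("2010-01-01", "2010-12-31")
        fruit = self._series(days, 1.0)
        monthly = pd.Series(
            np.arange(12.0), pd.period_range("2010-01", periods=12, freq="M")
        )
        out = window_covariates(fruit, {1: monthly}, "2010-03-16", scales=(1,))
        daily = interpolate_daily(monthly)
        assert out["spei_1"] == pytest.approx(daily.loc["2010-03-16"])


class TestExtremeFlags:
    def test_integer_sequence_type7(self):
        x = np.arange(1, 101, dtype=float)
        lo, hi = extreme_flags(x)
        # type-7 quantiles of 1..100: q10 = 10.9, q90 = 90.1
        assert np.flatnonzero(lo).max() == 9  # values 1..10
        assert np.flatnonzero(hi).min() == 90  # values 91..100
        assert lo.sum() == 10 and hi.sum() == 10

    def test_matches_numpy_brute_force(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        lo, hi = extreme_flags(x)
        assert (lo == (x <= np.percentile(x, 10))).all()
        assert (hi == (x >= np.percentile(x, 90))).all()

    def test_constant_column_no_extremes(self):
        with pytest.warns(UserWarning, match="constant"):
            lo, hi = extreme_flags(np.ones(50))
        assert not lo.any() and not hi.any()

    def test_closed_inequality_at_threshold(self):
        # thresholds of 0..100 are exactly 10.0 and 90.0; values exactly at
        # the threshold are flagged (closed inequality)
        ref = np.arange(0.0, 101.0)
        lo, hi = extreme_flags(np.array([10.0, 90.0, 10.001, 89.999]), reference=ref)
        assert lo.tolist() == [True, False, False, False]
        assert hi.tolist() == [False, True, False, False]

    def test_external_reference_series(self):
        ref = np.arange(100.0)
        lo, hi = extreme_flags(np.array([0.0, 50.0, 99.0]), reference=ref)
        assert lo.tolist() == [True, False, False]
        assert hi.tolist() == [False, False, True]

    def test_too_few_reference_values(self):
        with pytest.raises(ValueError, match=">= 10"):
            extreme_flags(np.arange(5.0))


class TestScaleContinuous:
    def test_unit_variance_ddof1(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        out, meta = scale_continuous(df, ["x"])
        assert out["x"].tolist() == pytest.approx([-1.0, 0.0, 1.0])
        assert meta["x"] == (2.0, 1.0)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({"x": rng.normal(size=200)})
        once, _ = scale_continuous(df, ["x"])
        twice, _ = scale_continuous(once, ["x"])
        assert np.abs(once["x"] - twice["x"]).max() < 1e-12

    def test_backtransform_recovers_unscaled_coefficient(self):
        """A slope fitted on scaled data, divided by the scaling sd, matches
        the slope of the unscaled fit (refit oracle)."""
        rng = np.random.default_rng(3)
        x = rng.normal(10.0, 5.0, 300)
        y = 2.0 * x + rng.normal(size=300)
        df = pd.DataFrame({"x": x})
        scaled, meta = scale_continuous(df, ["x"])
        bs = np.polyfit(scaled["x"], y, 1)[0]
        bu = np.polyfit(x, y, 1)[0]
        assert bs / meta["x"][1] == pytest.approx(bu, rel=1e-9)

    def test_zero_variance_named(self):
        df = pd.DataFrame({"bad": np.ones(10)})
        with pytest.raises(ValueError, match="bad"):
            scale_continuous(df, ["bad"])


class TestAnalysisTableConservation:
    def test_row_and_event_counts_match_truth(self, capuchin_sim, capuchin_pm):
        """Person-month reconstruction reproduces the generator's own
        row and event counts exactly (conservation invariant)."""
        truth = capuchin_sim.truth_person_months
        assert len(capuchin_pm) == len(truth)
        assert capuchin_pm["event"].sum() == truth["event"].sum()

    def test_one_departure_per_infant(self, capuchin_sim):
        infants = capuchin_sim.biography.dropna(subset=["birth_date"])
        assert infants["individual_id"].is_unique
        assert infants["departure_type"].notna().all()

    def test_at_most_one_event_in_final_interval(self, capuchin_pm):
        per = capuchin_pm.groupby("individual_id").agg(
            events=("event", "sum"),
            last=("interval_index", "max"),
        )
        assert (per["events"] <= 1).all()
        ev = capuchin_pm[capuchin_pm["event"] == 1]
        last = capuchin_pm.groupby("individual_id")["interval_index"].max()
        assert (ev.set_index("individual_id")["interval_index"] == last[ev["individual_id"]].values).all()

    def test_covariates_match_generator_truth(self, capuchin_sim, capuchin_pm):
        truth = capuchin_sim.truth_person_months
        merged = capuchin_pm.merge(
            truth, on=["individual_id", "interval_index"], suffixes=("", "_t")
        )
        assert len(merged) == len(truth)
        assert (merged["risk_low"] == merged["low_risk"].astype(int)).all()
        assert (merged["spei_lo_12"] == merged["extreme_drought"].astype(int)).all()
        assert np.allclose(
            (merged["fruit_mean_12"] - merged["fruit_mean_12"].mean())
            / merged["fruit_mean_12"].std(),
            (merged["fruit_z"] - merged["fruit_z"].mean()) / merged["fruit_z"].std(),
        )
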