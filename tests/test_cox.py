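"""Cox partial likelihood, frailty fitting, and survival prediction."""

import numpy as np
import pandas as pd
import pytest

from droughtdemog.cox import (
    CoxPHFrailty,
    cox_partial_loglik,
    fit_cox,
    fit_cox_frailty,
)


def _brute_force_loglik(df, terms, beta, ties="efron"):
    """Direct enumeration of the partial likelihood over risk sets."""
    beta = np.asarray(beta, dtype=float)
    eta = df[terms].to_numpy() @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in sorted(df.loc[df.event == 1, "stop"].unique()):
        risk = df.index[(df["start"] < t) & (df["stop"] >= t)]
        deaths = df.index[(df["stop"] == t) & (df["event"] == 1)]
        d = len(deaths)
        ll += eta[deaths].sum()
        if ties == "breslow":
            ll -= d * np.log(w[risk].sum())
        else:
            for k in range(d):
                ll -= np.log(w[risk].sum() - (k / d) * w[deaths].sum())
    return ll


@pytest.fixture
def toy6():
    """6-row toy dataset with ties at t=2."""
    return pd.DataFrame(
        {
            "start": [0, 0, 0, 0, 1, 1],
            "stop": [1.0, 2, 2, 3, 2, 3],
            "event": [1, 1, 1, 0, 1, 0],
            "x": [0.5, -0.2, 1.0, 0.0, -1.0, 0.3],
        }
    )


class TestPartialLoglik:
    @pytest.mark.parametrize("ties", ["efron", "breslow"])
    @pytest.mark.parametrize("beta", [[0.0], [0.7], [-1.3]])
    def test_matches_brute_force_enumeration(self, toy6, ties, beta):
        mine = cox_partial_loglik(toy6, ["x"], beta, ties=ties)
        assert mine == pytest.approx(_brute_force_loglik(toy6, ["x"], beta, ties), rel=1e-12)

    def test_closed_form_single_event(self):
        # one event among two at risk: ll = beta*x_event - log(sum exp(beta*x))
        df = pd.DataFrame(
            {"start": [0, 0], "stop": [1.0, 1.0], "event": [1, 0], "x": [1.0, 0.0]}
        )
        for b in (-0.5, 0.0, 1.2):
            expect = b * 1.0 - np.log(np.exp(b) + 1.0)
            assert cox_partial_loglik(df, ["x"], [b]) == pytest.approx(expect)

    def test_no_events_warns_zero(self, toy6):
        df = toy6.assign(event=0)
        with pytest.warns(UserWarning, match="no events"):
            assert cox_partial_loglik(df, ["x"], [0.3]) == 0.0


class TestFitCox:
    def test_duplicating_rows_preserves_maximizer(self):
        rng = np.random.default_rng(5)
        n = 120
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": rng.integers(1, 8, n).astype(float),
                "event": (rng.random(n) < 0.5).astype(int),
                "x": rng.normal(size=n),
            }
        )
        doubled = pd.concat([df, df], ignore_index=True)
        # exact under Breslow ties (Efron's correction depends on the tie
        # multiplicity, which doubling changes)
        b1 = fit_cox(df, ["x"], ties="breslow").coef_["x"]
        b2 = fit_cox(doubled, ["x"], ties="breslow").coef_["x"]
        assert b2 == pytest.approx(b1, abs=1e-7)

    def test_agrees_with_lifelines(self):
        from lifelines import CoxTimeVaryingFitter

        rng = np.random.default_rng(10)
        for rep in range(10):
            n = 150
            df = pd.DataFrame(
                {
                    "start": np.zeros(n),
                    "stop": rng.integers(1, 10, n).astype(float),
                    "x1": rng.normal(size=n),
                    "x2": rng.integers(0, 2, n).astype(float),
                    "event": (rng.random(n) < 0.4).astype(int),
                }
            )
            mine = fit_cox(df, ["x1", "x2"])
            ctv = CoxTimeVaryingFitter()
            ldf = df.rename(columns={"start": "s", "stop": "t"}).assign(id=np.arange(n))
            ctv.fit(ldf, id_col="id", start_col="s", stop_col="t", event_col="event")
            assert np.abs(mine.coef_.to_numpy() - ctv.params_.to_numpy()).max() < 1e-6

    def test_null_covariate_within_wald_bounds(self):
        """Under the null, |beta| < 2 SE in about 95% of replicates."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 60
        for _ in range(reps):
            n = 100
            df = pd.DataFrame(
                {
                    "start": 0.0,
                    "stop": rng.integers(1, 6, n).astype(float),
                    "event": (rng.random(n) < 0.4).astype(int),
                    "x": rng.normal(size=n),
                }
            )
            f = fit_cox(df, ["x"])
            hits += abs(f.coef_["x"]) < 2 * f.se_["x"]
        assert hits >= 0.85 * reps

    def test_perfect_separation_flagged(self):
        df = pd.DataFrame(
            {
                "start": [0, 0, 0, 0],
                "stop": [1.0, 1, 2, 2],
                "event": [1, 0, 0, 0],
                "x": [1.0, 0.0, 0.0, 0.0],
            }
        )
        fit = fit_cox(df, ["x"])
        assert not fit.converged_

    def test_rank_deficient_design_rejected(self):
        df = pd.DataFrame(
            {
                "start": [0, 0],
                "stop": [1.0, 2.0],
                "event": [1, 1],
                "x1": [1.0, 2.0],
                "x2": [2.0, 4.0],
            }
        )
        with pytest.raises(ValueError, match="rank"):
            fit_cox(df, ["x1", "x2"])

    def test_hr_invariant_to_affine_rescaling(self):
        rng = np.random.default_rng(12)
        n = 200
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": rng.integers(1, 8, n).astype(float),
                "event": (rng.random(n) < 0.4).astype(int),
                "x": rng.normal(10, 4, size=n),
            }
        )
        b_raw = fit_cox(df, ["x"]).coef_["x"]
        df2 = df.assign(x=(df["x"] - 3.0) / 2.5)
        b_scaled = fit_cox(df2, ["x"]).coef_["x"]
        assert b_scaled / 2.5 == pytest.approx(b_raw, rel=1e-6)


def _clustered_data(rng, n_groups, per_group, sd, beta=0.0, months=6, h0=0.12):
    rows = []
    for g in range(n_groups):
        b = rng.normal(0, sd)
        for i in range(per_group):
            x = rng.normal()
            h = h0 * np.exp(beta * x + b)
            for m in range(1, months + 1):
                died = rng.random() < 1 - np.exp(-h)
                rows.append((f"g{g}", g * per_group + i, m - 1.0, float(m), int(died), x))
                if died:
                    break
    return pd.DataFrame(rows, columns=["grp", "id", "start", "stop", "event", "x"])


class TestFrailty:
    def test_zero_variance_reduces_to_plain_cox(self, capuchin_pm):
        plain = fit_cox(capuchin_pm, ["risk_low", "spei_lo_12"])
        frail = CoxPHFrailty(
            ["risk_low", "spei_lo_12"],
            frailty_terms=("mother_id", "hydro_year"),
            fixed_variance_components={"mother_id": 0.0, "hydro_year": 0.0},
        ).fit(capuchin_pm)
        assert np.abs(frail.coef_.to_numpy() - plain.coef_.to_numpy()).max() < 1e-6
        assert np.abs(frail.level_effects_["mother_id"]).max() < 1e-5

    def test_variance_recovery(self):
        """sd 0.8 frailty recovered at 100 groups x 20 subjects (median of
        25 replicates inside [0.5, 1.1])."""
        rng = np.random.default_rng(21)
        sds = []
        for _ in range(25):
            df = _clustered_data(rng, 100, 20, sd=0.8)
            fit = CoxPHFrailty([], frailty_terms=("grp",)).fit(df)
            sds.append(np.sqrt(fit.variance_components_["grp"]))
        assert 0.5 <= np.median(sds) <= 1.1

    def test_excess_hazard_year_ranks_top(self):
        """A group simulated with strong excess hazard gets the largest
        estimated random effect."""
        rng = np.random.default_rng(31)
        df = _clustered_data(rng, 12, 40, sd=0.0)
        # inflate hazard in group g3 by refreshing its events
        boost = df["grp"] == "g3"
        df.loc[boost, "event"] = np.where(
            rng.random(boost.sum()) < 0.35, 1, df.loc[boost, "event"]
        )
        # keep at most one event per subject, in its last row
        df = pd.concat(
            [_truncate_at_first_event(g) for _, g in df.groupby("id")],
            ignore_index=True,
        )
        fit = CoxPHFrailty([], frailty_terms=("grp",)).fit(df)
        eff = fit.level_effects_["grp"]
        assert eff.idxmax() == "g3"

    def test_converged_and_boundary_attrs(self, capuchin_pm):
        fit = fit_cox_frailty(capuchin_pm, ["risk_low"])
        assert fit.converged_
        assert set(fit.variance_components_) == {"mother_id", "hydro_year"}
        assert all(v >= 0 for v in fit.variance_components_.values())
        assert fit.n_events_ <= fit.n_rows_


def _truncate_at_first_event(g):
    first = np.flatnonzero(g["event"].to_numpy())
    if len(first):
        return g.iloc[: first[0] + 1]
    return g


class TestReporting:
    def test_hazard_ratio_identities(self, capuchin_pm):
        fit = fit_cox_frailty(capuchin_pm, ["risk_low"])
        hr = fit.hazard_ratios()
        assert hr.loc["risk_low", "hr"] == pytest.approx(
            np.exp(fit.coef_["risk_low"])
        )
        assert (
            hr.loc["risk_low", "hr_lo_95"]
            <= hr.loc["risk_low", "hr"]
            <= hr.loc["risk_low", "hr_hi_95"]
        )
        # nested interval widths: 80% inside 95% inside 99%
        assert hr.loc["risk_low", "hr_lo_99"] <= hr.loc["risk_low", "hr_lo_95"]
        assert hr.loc["risk_low", "hr_lo_95"] <= hr.loc["risk_low", "hr_lo_80"]

    def test_log_hr_round_trip(self):
        # a -1.439 log hazard ratio is a 0.237 hazard ratio
        assert np.exp(-1.439) == pytest.approx(0.237, abs=5e-4)

    def test_predict_survival_baseline_and_monotonicity(self):
        rng = np.random.default_rng(40)
        n = 200
        df = pd.DataFrame(
            {
                "start": 0.0,
                "stop": rng.integers(1, 8, n).astype(float),
                "event": (rng.random(n) < 0.4).astype(int),
                "x": rng.normal(size=n),
            }
        )
        fit = fit_cox(df, ["x"])
        base = fit.predict_survival({"x": 0.0})
        assert base["survival"].iloc[0] == 1.0
        assert (np.diff(base["survival"]) <= 0).all()
        hi = fit.predict_survival({"x": 1.0})  # beta>0 or <0: curves ordered
        sign = np.sign(fit.coef_["x"])
        diff = (hi["survival"] - base["survival"]).iloc[1:]
        assert ((sign * diff) <= 1e-12).all()
        assert (base["lower"] <= base["survival"]).all()
        assert (base["survival"] <= base["upper"]).all()

    def test_breslow_product_hand_computed(self):
        # 10 subjects, no covariates: S(t) at event times equals the
        # hand-computed Breslow product exp(-sum d_k / n_at_risk_k)
        df = pd.DataFrame(
            {
                "start": np.zeros(10),
                "stop": [1.0, 1, 2, 2, 3, 3, 3, 4, 5, 5],
                "event": [1, 0, 1, 0, 1, 1, 0, 0, 1, 0],
            }
        )
        fit = fit_cox(df, [])
        curve = fit.predict_survival({})
        # risk sets: t=1 ->10, t=2 -> 8, t=3 -> 6, t=5 -> 2
        lam = np.cumsum([1 / 10, 1 / 8, 2 / 6, 1 / 2])
        expect = np.exp(-lam)
        surv_at_events = curve.set_index("time")["survival"]
        for t, s in zip([1, 2, 3, 5], expect):
            assert surv_at_events[t] == pytest.approx(s, rel=1e-12)

    def test_out_of_range_profile_warns(self):
        df = pd.DataFrame(
            {
                "start": np.zeros(20),
                "stop": np.arange(1.0, 21.0),
                "event": ([1, 0] * 10),
                "x": np.linspace(-1, 1, 20),
            }
        )
        fit = fit_cox(df, ["x"])
        with pytest.warns(UserWarning, match="outside"):
            fit.predict_survival({"x": 5.0})


class TestEstimatorInterface:
    def test_get_set_params_round_trip(self):
        m = CoxPHFrailty(["a"], ties="breslow")
        params = m.get_params()
        m2 = CoxPHFrailty(["b"]).set_params(**params)
        assert m2.get_params() == params

    def test_unknown_param_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            CoxPHFrailty(["a"]).set_params(bogus=1)

    def test_invalid_event_column(self):
        df = pd.DataFrame({"start": [0.0], "stop": [1.0], "event": [2]})
        with pytest.raises(ValueError, match="0/1"):
            fit_cox(df, [])

    def test_interval_index_derives_counting_process(self, capuchin_pm):
        explicit = capuchin_pm.assign(
            start=capuchin_pm["interval_index"] - 1.0,
            stop=capuchin_pm["interval_index"].astype(float),
        )
        a = fit_cox(capuchin_pm, ["risk_low"]).coef_["risk_low"]
        b = fit_cox(explicit, ["risk_low"]).coef_["risk_low"]
        assert a == pytest.approx(b, abs=1e-12)
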