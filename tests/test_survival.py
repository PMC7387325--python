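import numpy as np
import pandas as pd
import pytest

import predictimand as pm
from predictimand.survival import StepCoefficient

from conftest import exponential_cohort, make_cohort, make_df


def naive_partial_loglik_grid(grid, start, stop, event, x):
    """Brute-force partial log-likelihood over a beta grid (independent
    oracle, valid for untied event times)."""
    lls = np.zeros_like(grid)
    for t in np.sort(stop[event == 1]):
        at = (start < t) & (t <= stop)
        case = (stop == t) & (event == 1)
        lls += grid * x[case].sum() - np.log(
            np.exp(np.outer(grid, x[at])).sum(axis=1)
        )
    return lls


class TestFitCox:
    def test_symmetric_groups_give_zero_coefficient(self):
        # both groups share the exact same event/censoring pattern
        rows, g = [], []
        for grp in (0, 1):
            for i, (t, e) in enumerate([(1, 1), (2, 0), (3, 1), (4, 1), (5, 0)]):
                rows.append((f"{grp}-{i}", 0.0, float(t), e, 0))
                g.append(grp)
        data = make_cohort(rows, roles={"grp": "baseline"}, grp=g)
        fit = pm.fit_cox(data, covariates=["grp"])
        assert abs(fit.coefficients["grp"]) < 1e-8

    def test_six_subject_toy_matches_grid_search(self):
        # no ties; dense grid over the exact partial likelihood
        stop = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        event = np.array([1, 1, 0, 1, 1, 0])
        x = np.array([1.0, 0.0, 1.0, 1.0, 0.0, 0.0])
        start = np.zeros(6)
        df = make_df(
            [(i, 0.0, t, e, 0) for i, (t, e) in enumerate(zip(stop, event))], x=x
        )
        fit = pm.fit_cox(df, covariates=["x"], ties="efron")
        grid = np.arange(-5.0, 5.0, 1e-4)
        lls = naive_partial_loglik_grid(grid, start, stop, event, x)
        assert abs(fit.coefficients["x"] - grid[lls.argmax()]) < 1e-3

    def test_parameter_recovery_hazard_ratio_two(self):
        data = exponential_cohort(5000, seed=3)
        fit = pm.fit_cox(data, covariates=["group"])
        se = fit.standard_errors()["group"]
        assert abs(fit.coefficients["group"] - np.log(2)) < 3 * se

    def test_efron_equals_breslow_without_ties(self):
        data = exponential_cohort(500, seed=4)
        fe = pm.fit_cox(data, covariates=["group"], ties="efron")
        fb = pm.fit_cox(data, covariates=["group"], ties="breslow")
        assert np.abs(fe.coefficients - fb.coefficients).max() < 1e-8
        np.testing.assert_allclose(fe.baseline_cumhaz, fb.baseline_cumhaz, atol=1e-8)

    def test_matches_lifelines_on_tied_weighted_data(self):
        # independent implementation cross-check
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(5)
        n = 300
        x = rng.normal(size=n)
        t = np.ceil(rng.exponential(1 / (0.2 * np.exp(0.4 * x))))
        c = np.full(n, 8.0)
        stop = np.minimum(t, c)
        ev = (t <= c).astype(int)
        w = rng.uniform(0.5, 2.0, n)
        df = make_df(
            [(i, 0.0, s, e, 0) for i, (s, e) in enumerate(zip(stop, ev))], x=x
        )
        fit = pm.fit_cox(df, covariates=["x"], weights=w)
        cph = lifelines.CoxPHFitter()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                pd.DataFrame({"t": stop, "e": ev, "x": x, "w": w}),
                duration_col="t", event_col="e", weights_col="w",
            )
        assert abs(fit.coefficients["x"] - cph.params_["x"]) < 1e-6

    def test_constant_weight_scaling_is_invariant(self):
        data = exponential_cohort(300, seed=6)
        f1 = pm.fit_cox(data, covariates=["group"])
        f2 = pm.fit_cox(data, covariates=["group"], weights=np.full(len(data.df), 2.5))
        assert np.abs(f1.coefficients - f2.coefficients).max() < 1e-9
        np.testing.assert_allclose(f1.baseline_cumhaz, f2.baseline_cumhaz, atol=1e-9)

    def test_zero_events_degenerate(self):
        data = make_cohort([("a", 0, 2, 0, 0), ("b", 0, 3, 0, 0)])
        with pytest.raises(pm.DegenerateDataError):
            pm.fit_cox(data, covariates=[])

    def test_perfect_separation_raises(self):
        # covariate perfectly orders the events: monotone likelihood
        rows, x = [], []
        for i in range(12):
            rows.append((i, 0.0, float(i + 1), 1 if i < 6 else 0, 0))
            x.append(1.0 if i < 6 else 0.0)
        df = make_df(rows, x=x)
        with pytest.raises(pm.ConvergenceError):
            pm.fit_cox(df, covariates=["x"])


class TestPredictSurvival:
    def test_null_model_risk_is_one_minus_exp_cumhaz(self):
        data = exponential_cohort(200, seed=8)
        fit = pm.fit_cox(data, covariates=[])
        grid = np.array([1.0, 3.0, 6.0])
        rc = pm.predict_survival(fit, {}, grid)
        cum = np.concatenate([[0.0], fit.baseline_cumhaz])
        idx = np.searchsorted(fit.baseline_times, grid, side="right")
        np.testing.assert_allclose(rc.risk, 1 - np.exp(-cum[idx]), atol=1e-14)

    def test_protective_path_gives_uniformly_lower_risk(self):
        sim = pm.simulate_cohort(pm.default_scenario(n=400, seed=2))
        fit = pm.fit_cox(
            pm.apply_strategy_view(sim, "ignore"),
            covariates=["age", "treated"],
        )
        grid = np.linspace(0.5, 9.5, 20)
        prof = {"age": 60.0}
        r0 = pm.predict_survival(fit, prof, grid, covariate_path={"treated": 0.0})
        r1 = pm.predict_survival(fit, prof, grid, covariate_path={"treated": 1.0})
        b = fit.coefficients["treated"]
        lower, higher = (r1, r0) if b < 0 else (r0, r1)
        assert (lower.risk <= higher.risk + 1e-12).all()

    def test_step_coefficient_prediction_matches_hand_sum(self):
        # five-step baseline hazard, one covariate with a coefficient jump
        rng = np.random.default_rng(9)
        n = 40
        x = rng.binomial(1, 0.5, n).astype(float)
        stop = rng.uniform(0.2, 9.8, n)
        ev = rng.binomial(1, 0.8, n)
        ev[:5] = 1
        df = make_df(
            [(i, 0.0, s, e, 0) for i, (s, e) in enumerate(zip(stop, ev))], x=x
        )
        cut = 4.0
        fit = pm.fit_cox(df, covariates=["x"], step_terms=[StepCoefficient("x", [cut])])
        assert len(fit.coefficients) == 2
        b1, b2 = fit.coefficients.to_numpy()
        grid = np.array([2.0, 4.0, 6.0, 9.9])
        rc = pm.predict_survival(fit, {"x": 1.0}, grid)
        # hand assembly: sum e^{beta(t_j) x} dL0(t_j) over event times <= t
        hand = []
        for t in grid:
            tot = 0.0
            for tj, dl in zip(fit.baseline_times, fit.baseline_hazard):
                if tj <= t:
                    tot += np.exp(b1 if tj <= cut else b2) * dl
            hand.append(1 - np.exp(-tot))
        np.testing.assert_allclose(rc.risk, hand, atol=1e-12)

    def test_grid_beyond_last_event_flagged_flat(self):
        data = make_cohort([("a", 0, 2, 1, 0), ("b", 0, 3, 0, 0)])
        fit = pm.fit_cox(data, covariates=[])
        rc = pm.predict_survival(fit, {}, [1.0, 2.0, 50.0])
        assert rc.extrapolated
        assert rc.risk[-1] == rc.risk[-2]

    def test_missing_profile_covariate_is_schema_error(self):
        data = exponential_cohort(100, seed=10)
        fit = pm.fit_cox(data, covariates=["group"])
        with pytest.raises(pm.SchemaError, match="profile"):
            pm.predict_survival(fit, {}, [1.0])


class TestKaplanMeier:
    def test_hand_worked_product_limit(self):
        rc = pm.kaplan_meier([1.0, 2.0, 3.0], [1, 1, 0])
        for t, s in [(1.0, 2 / 3), (2.0, 1 / 3), (3.0, 1 / 3)]:
            assert 1.0 - rc.risk_at(t) == pytest.approx(s, abs=1e-15)

    def test_all_censored_survival_one(self):
        rc = pm.kaplan_meier([1.0, 2.0], [0, 0])
        assert rc.times.size == 0
        assert rc.risk_at(5.0) == 0.0

    def test_no_censoring_matches_empirical_cdf(self):
        t = np.array([3.0, 1.0, 4.0, 2.0, 5.0])
        rc = pm.kaplan_meier(t, np.ones(5, int))
        for tt in t:
            assert rc.risk_at(tt) == pytest.approx((t <= tt).mean())

    def test_matches_lifelines_weighted(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(11)
        t = rng.exponential(5, 200)
        e = rng.binomial(1, 0.7, 200)
        w = rng.uniform(0.5, 2, 200)
        mine = pm.kaplan_meier(t, e, weights=w)
        kmf = lifelines.KaplanMeierFitter()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kmf.fit(t, e, weights=w)
        theirs = kmf.survival_function_at_times(mine.times).to_numpy()
        np.testing.assert_allclose(mine.survival, theirs, atol=1e-10)


class TestAalenJohansen:
    def test_hand_worked_example(self):
        stop = [1.0, 2.0, 3.0, 4.0]
        cause = [1, 2, 1, 0]
        cif1, cif2 = pm.aalen_johansen(stop, cause)
        assert cif1.risk_at(1.0) == pytest.approx(1 / 4)
        assert cif1.risk_at(3.0) == pytest.approx(1 / 2)
        assert cif2.risk_at(2.0) == pytest.approx(1 / 4)

    def test_single_cause_reduces_to_km(self):
        rng = np.random.default_rng(12)
        t = rng.exponential(4, 100)
        e = rng.binomial(1, 0.6, 100)
        cif1, cif2 = pm.aalen_johansen(t, e)
        km = pm.kaplan_meier(t, e)
        np.testing.assert_allclose(cif1.risk, km.risk, atol=1e-12)
        assert cif2.risk.max() == 0.0

    def test_conservation_cif1_cif2_survivor(self):
        rng = np.random.default_rng(13)
        t = rng.exponential(4, 150)
        cause = rng.choice([0, 1, 2], 150, p=[0.2, 0.5, 0.3])
        cif1, cif2 = pm.aalen_johansen(t, cause)
        allc = pm.kaplan_meier(t, (np.asarray(cause) > 0).astype(int))
        total = cif1.risk + cif2.risk + allc.survival
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_matches_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(14)
        t = rng.exponential(4, 120)  # continuous: no ties, no AJ jittering
        cause = rng.choice([0, 1, 2], 120, p=[0.3, 0.4, 0.3])
        cif1, _ = pm.aalen_johansen(t, cause)
        import warnings

        ajf = lifelines.AalenJohansenFitter(calculate_variance=False)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ajf.fit(t, cause, event_of_interest=1)
        theirs = ajf.cumulative_density_.iloc[:, 0]
        for tt in np.unique(t[cause == 1]):
            assert cif1.risk_at(tt) == pytest.approx(
                float(theirs[theirs.index <= tt].iloc[-1]), abs=1e-10
            )


class TestCumincFromCauseSpecific:
    def test_null_fits_equal_nonparametric_aj(self):
        rng = np.random.default_rng(15)
        n = 150
        t = rng.exponential(4, n)
        cause = rng.choice([0, 1, 2], n, p=[0.2, 0.5, 0.3])
        df_e = make_df([(i, 0.0, s, int(c == 1), 0) for i, (s, c) in enumerate(zip(t, cause))])
        df_t = make_df([(i, 0.0, s, int(c == 2), 0) for i, (s, c) in enumerate(zip(t, cause))])
        fe = pm.fit_cox(df_e, ties="breslow")
        ft = pm.fit_cox(df_t, ties="breslow")
        grid = np.unique(t)
        mine = pm.cuminc_from_cause_specific(fe, ft, {}, grid)
        cif1, _ = pm.aalen_johansen(t, cause)
        hand = np.array([cif1.risk_at(tt) for tt in grid])
        np.testing.assert_allclose(mine.risk, hand, atol=1e-10)

    def test_no_competing_events_reduces_to_survivor_complement(self):
        data = exponential_cohort(200, seed=16)
        fe = pm.fit_cox(data, covariates=["group"])
        grid = np.array([1.0, 3.0, 6.0])
        prof = {"group": 1.0}
        mine = pm.cuminc_from_cause_specific(fe, None, prof, grid)
        direct = pm.predict_survival(fe, prof, grid)
        np.testing.assert_allclose(mine.risk, direct.risk, atol=1e-12)


class TestSchoenfeld:
    def test_residuals_sum_to_zero_at_mle(self):
        data = exponential_cohort(400, seed=17)
        fit = pm.fit_cox(data, covariates=["group"])
        res = pm.schoenfeld_residuals(fit, data)
        scale = np.abs(res["group"]).sum()
        assert abs((res["group"] * res["weight"]).sum()) < 1e-6 * max(scale, 1.0)

    def test_first_event_residual_matches_hand_formula(self):
        # two events, two censored; residual at the first event is the case
        # covariate minus the weighted risk-set mean
        x = np.array([1.0, 0.0, 1.0, 0.0])
        w = np.array([2.0, 3.0, 1.0, 1.5])
        df = make_df(
            [(0, 0.0, 1.0, 1, 0), (1, 0.0, 2.0, 1, 0),
             (2, 0.0, 3.0, 0, 0), (3, 0.0, 4.0, 0, 0)],
            x=x,
        )
        fit = pm.fit_cox(df, covariates=["x"], weights=w)
        res = pm.schoenfeld_residuals(fit, df, weights=w)
        b = fit.coefficients["x"]
        r = w * np.exp(b * x)
        expected = x[0] - (r * x).sum() / r.sum()  # all four at risk at t=1
        assert res["x"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_null_model_gives_empty_table(self):
        data = exponential_cohort(50, seed=18)
        fit = pm.fit_cox(data, covariates=[])
        assert pm.schoenfeld_residuals(fit, data).empty

    def test_no_time_trend_under_proportional_hazards(self):
        # constant-effect data: residual-vs-time slope should rarely be
        # significant; checked across seeds
        from scipy import stats

        n_sig = 0
        n_rep = 100
        for seed in range(n_rep):
            data = exponential_cohort(2000, seed=100 + seed)
            fit = pm.fit_cox(data, covariates=["group"])
            res = pm.schoenfeld_residuals(fit, data)
            out = stats.linregress(res["time"], res["group"])
            n_sig += out.pvalue < 0.05
        assert n_sig <= 10  # >= 90% of seeds show no significant slope


def test_cox_fit_yaml_roundtrip_preserves_predictions(tmp_path):
    sim = pm.simulate_cohort(pm.default_scenario(n=300, seed=20))
    fit = pm.fit_cox(
        pm.apply_strategy_view(sim, "ignore"),
        covariates=["age", "treated"],
        step_terms=[StepCoefficient("treated", [3.0])],
    )
    p = tmp_path / "fit.yaml"
    fit.to_yaml(p)
    back = pm.CoxFit.from_yaml(p)
    grid = [1.0, 4.0, 8.0]
    prof = {"age": 55.0}
    a = pm.predict_survival(fit, prof, grid, covariate_path={"treated": 0.0})
    b = pm.predict_survival(back, prof, grid, covariate_path={"treated": 0.0})
    np.testing.assert_allclose(a.risk, b.risk, rtol=0, atol=1e-12)


def test_null_cox_baseline_close_to_kaplan_meier():
    data = exponential_cohort(1500, seed=19)
    fit = pm.fit_cox(data, covariates=[])
    km = pm.kaplan_meier(data.df["stop"], data.df["event"])
    risk_cox = 1 - np.exp(-fit.baseline_cumhaz)
    assert np.abs(risk_cox - km.risk).max() < 0.005
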