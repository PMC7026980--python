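import numpy as np
import pandas as pd
import pytest

from pmcox.engine import (
    CellData,
    CoxFit,
    EngineError,
    RankDeficiencyError,
    aggregate_cells,
    cells_from_raw,
    expand_person_months,
    fit_cox,
    partial_loglik,
    rr_per_10,
)
from pmcox.exposure import person_month_exposure

from conftest import tiny_config, toy_cohort, toy_covariates
from pmcox.simulate import simulate_study


def _tiny_pm(study, cause="non_accidental"):
    mat, start = person_month_exposure(study.cohort, study.residence, study.surfaces["PM25"])
    return expand_person_months(
        study.cohort, study.residence, {"pm25_12mo": mat}, start, cause
    )


class TestExpansion:
    def test_three_month_follow_up_event_in_last_row(self):
        cohort, residence, jan = toy_cohort()
        covs, start = toy_covariates(cohort)
        pm = expand_person_months(cohort, residence, covs, start, "all_cvd")
        rows = pm.df  # person 1: Jan-Mar, dies of I21
        p1 = rows[rows["zip"] == 11].groupby("t").size()
        assert pm.df.groupby("t")["event"].sum().sum() == 1
        one = rows[(rows["sex"] == "F") & (rows["race"] == "White")]
        assert list(one["t"]) == [0, 1, 2]
        assert list(one["event"]) == [0, 0, 1]

    def test_other_cause_censors_without_event(self):
        cohort, residence, jan = toy_cohort()
        covs, start = toy_covariates(cohort)
        pm = expand_person_months(cohort, residence, covs, start, "all_cancer")
        assert pm.n_events == 0
        # the CVD death still censors: same number of at-risk rows
        assert pm.n_person_months == 3 + 6 + 3

    def test_age_bin_switches_to_90_plus_at_birthday_month(self):
        cohort, residence, jan = toy_cohort()
        covs, start = toy_covariates(cohort)
        pm = expand_person_months(cohort, residence, covs, start, "all_cause")
        p2 = pm.df[pm.df["sex"] == "M"].sort_values("t")
        assert list(p2["age"].astype(int)) == [89, 89, 90, 90, 90, 90]

    def test_missing_exposure_drops_and_counts(self):
        cohort, residence, jan = toy_cohort()
        covs, start = toy_covariates(cohort)
        covs["x"][1, 3] = np.nan  # one month of one beneficiary
        pm = expand_person_months(cohort, residence, covs, start, "all_cause")
        assert pm.n_dropped_missing == 1
        assert pm.n_person_months == 12 - 1


class TestAggregation:
    def test_shared_covariate_vector_compresses_to_one_cell(self):
        cohort, residence, jan = toy_cohort()
        covs, start = toy_covariates(cohort)
        pm = expand_person_months(cohort, residence, covs, start, "all_cause")
        # collapse strata to one dimension so persons 1+3 share risk sets
        cells = aggregate_cells(pm, strata=("sex",))
        # females share (stratum, t, x): months 0..2 -> 3 cells of size 2
        f_cells = cells.w[cells.w == 2]
        assert len(f_cells) >= 1

    def test_all_distinct_rows_no_compression(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        raw = cells_from_raw(pm)
        assert raw.n_cells == int(raw.w.sum())
        assert set(np.unique(raw.w)) == {1.0}

    def test_lossless_for_likelihood_gradient_information(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        cells = aggregate_cells(pm)
        raw = cells_from_raw(pm)
        assert cells.n_cells < raw.n_cells  # real compression happened
        for beta in (np.array([0.0]), np.array([0.03]), np.array([-0.05])):
            vc, gc, ic = partial_loglik(cells, beta)
            vr, gr, ir = partial_loglik(raw, beta)
            assert vc == pytest.approx(vr, abs=1e-8)
            assert np.allclose(gc, gr, atol=1e-8)
            assert np.allclose(ic, ir, atol=1e-8)

    def test_counts_match_person_months_and_events(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        cells = aggregate_cells(pm)
        assert cells.n_person_months == pm.n_person_months
        assert cells.n_events_total == pm.n_events
        assert int(cells.d.sum()) == int(cells.e.sum())


class TestPartialLoglik:
    def _toy_cells(self):
        """Two risk sets, hand-sized."""
        X = np.array([[1.0], [0.0], [2.0], [2.0]])
        w = np.array([2.0, 3.0, 1.0, 4.0])
        e = np.array([1.0, 0.0, 1.0, 0.0])
        starts = np.array([0, 2])
        d = np.array([1.0, 1.0])
        return CellData(X, w, e, starts, d, ["x"], 10, 2, 4, 2)

    def test_matches_hand_computation_at_zero(self):
        cells = self._toy_cells()
        v, g, i = partial_loglik(cells, np.zeros(1))
        # risk set 1: event x=1, denom log(5); risk set 2: event x=2, denom log(5)
        assert v == pytest.approx(-2 * np.log(5))
        xbar1 = (2 * 1 + 3 * 0) / 5
        xbar2 = (1 * 2 + 4 * 2) / 5
        assert g[0] == pytest.approx((1 - xbar1) + (2 - xbar2))

    def test_gradient_zero_when_no_contrast(self):
        X = np.array([[3.0], [3.0]])
        cells = CellData(X, np.array([5.0, 2.0]), np.array([1.0, 0.0]),
                         np.array([0]), np.array([1.0]), ["x"], 7, 1, 2, 1)
        v0, g0, _ = partial_loglik(cells, np.zeros(1))
        v1, g1, _ = partial_loglik(cells, np.array([2.0]))
        assert g0[0] == pytest.approx(0.0, abs=1e-12)
        assert v0 == pytest.approx(v1)  # constant in beta

    def test_gradient_at_null_equals_event_minus_riskset_mean(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        cells = aggregate_cells(pm)
        _, g, _ = partial_loglik(cells, np.zeros(1))
        expected = 0.0
        bounds = np.r_[cells.starts, cells.n_cells]
        for k in range(len(cells.starts)):
            sl = slice(bounds[k], bounds[k + 1])
            xbar = np.average(cells.X[sl, 0], weights=cells.w[sl])
            expected += cells.e[sl] @ cells.X[sl, 0] - cells.d[k] * xbar
        assert g[0] == pytest.approx(expected, abs=1e-9)

    def test_overflow_guarded(self):
        cells = self._toy_cells()
        v, g, i = partial_loglik(cells, np.array([500.0]))
        assert np.isfinite(v) and np.isfinite(g).all() and np.isfinite(i).all()

    def test_concavity_at_random_betas(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        cells = aggregate_cells(pm)
        rng = np.random.default_rng(0)
        for beta in rng.normal(0, 0.2, size=(10, 1)):
            _, _, info = partial_loglik(cells, beta)
            assert np.linalg.eigvalsh(info).min() >= -1e-9


class TestFit:
    def test_translation_invariance_of_beta(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        cells = aggregate_cells(pm)
        fit1 = fit_cox(cells)
        pm.df["pm25_12mo"] = pm.df["pm25_12mo"] + 7.3
        cells2 = aggregate_cells(pm)
        fit2 = fit_cox(cells2)
        pm.df["pm25_12mo"] = pm.df["pm25_12mo"] - 7.3
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-8)
        assert fit1.se[0] == pytest.approx(fit2.se[0], abs=1e-8)

    def test_perfect_separation_flagged_monotone(self):
        # one stratum, one risk set: the event has the strictly largest x
        X = np.array([[1.0], [0.0]])
        cells = CellData(X, np.array([1.0, 50.0]), np.array([1.0, 0.0]),
                         np.array([0]), np.array([1.0]), ["x"], 51, 1, 2, 1)
        fit = fit_cox(cells)
        assert fit.monotone and not fit.converged

    def test_unconverged_fit_refuses_rr(self):
        X = np.array([[1.0], [0.0]])
        cells = CellData(X, np.array([1.0, 50.0]), np.array([1.0, 0.0]),
                         np.array([0]), np.array([1.0]), ["x"], 51, 1, 2, 1)
        fit = fit_cox(cells)
        with pytest.raises(EngineError):
            rr_per_10(fit, 0)

    def test_duplicated_covariate_reported_as_aliased(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        pm.df["copy"] = pm.df["pm25_12mo"]
        cells = aggregate_cells(pm, covariates=["pm25_12mo", "copy"])
        with pytest.raises(RankDeficiencyError) as exc:
            fit_cox(cells)
        assert set(exc.value.aliased) == {"pm25_12mo", "copy"}

    def test_empty_strata_do_not_alter_estimates(self, tiny_study):
        pm = _tiny_pm(tiny_study)
        cells = aggregate_cells(pm)
        fit1 = fit_cox(cells)
        # an extra stratum of event-free person-months
        extra = pm.df.head(200).copy()
        extra["event"] = 0
        extra["zip"] = -1
        pm2 = type(pm)(pd.concat([pm.df, extra], ignore_index=True),
                       pm.covariate_names, pm.cause)
        fit2 = fit_cox(aggregate_cells(pm2))
        assert fit1.beta[0] == pytest.approx(fit2.beta[0], abs=1e-10)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-10)

    def test_planted_effect_recovered_within_3se(self):
        cfg = tiny_config(
            n_beneficiaries=4000, n_zips=20, n_months=108,
            base_monthly_hazard_65=0.003,
        )
        cfg = cfg.replace(rr_per_10={k: 1.5 for k in cfg.rr_per_10})
        study = simulate_study(cfg, seed=31)
        pm = _tiny_pm(study, "non_accidental")
        fit = fit_cox(aggregate_cells(pm))
        beta_true = np.log(1.5) / 10
        assert fit.converged
        assert abs(fit.beta[0] - beta_true) < 3 * fit.se[0]


class TestRRPer10:
    def _fit(self, beta, se):
        cov = np.array([[se**2]])
        return CoxFit(np.array([beta]), cov, -1.0, 3, True, ["x"], 10, 100, 50, 20, 5)

    def test_arithmetic_inversion(self):
        rr, (lo, hi) = rr_per_10(self._fit(np.log(1.088) / 10, 0.0), 0)
        assert rr == pytest.approx(1.088)
        assert lo == pytest.approx(1.088) and hi == pytest.approx(1.088)

    def test_null_beta(self):
        rr, (lo, hi) = rr_per_10(self._fit(0.0, 0.01), 0)
        assert rr == 1.0 and lo < 1.0 < hi

    def test_ci_width_monotone_in_se(self):
        widths = [
            np.subtract(*rr_per_10(self._fit(0.005, se), 0)[1][::-1])
            for se in (0.001, 0.002, 0.005, 0.01)
        ]
        assert all(w2 > w1 for w1, w2 in zip(widths, widths[1:]))


class TestLifelinesOracleTieFree:
    """lifelines handles ties with Efron's method, so it can serve as an
    independent oracle only where risk sets carry at most one event — there
    the Breslow and Efron partial likelihoods coincide exactly."""

    def test_matches_lifelines_on_tie_free_cohort(self):
        from lifelines import CoxTimeVaryingFitter

        study = simulate_study(
            tiny_config(n_beneficiaries=500, base_monthly_hazard_65=0.002), seed=17
        )
        mat, start = person_month_exposure(
            study.cohort, study.residence, study.surfaces["PM25"]
        )
        pm = expand_person_months(
            study.cohort, study.residence, {"x": mat}, start,
            "non_accidental", keep_ids=True,
        )
        # censor all but the first event in any (stratum, month) risk set
        df = pm.df
        key = (
            df["sex"].astype(str) + "|" + df["zip"].astype(str) + "|" + df["t"].astype(str)
        )
        events = df.index[df["event"] == 1]
        dup = key[events].duplicated()
        df.loc[events[dup.to_numpy()], "event"] = 0

        cells = aggregate_cells(pm, strata=("sex", "zip"))
        assert cells.d.max() == 1  # genuinely tie-free
        fit = fit_cox(cells, tol=1e-12)

        ldf = df.copy()
        ldf["start"], ldf["stop"] = ldf["t"], ldf["t"] + 1
        ldf["stratum"] = ldf["sex"].astype(str) + "|" + ldf["zip"].astype(str)
        ctv = CoxTimeVaryingFitter()
        ctv.fit(
            ldf[["id", "start", "stop", "event", "x", "stratum"]],
            id_col="id", start_col="start", stop_col="stop",
            event_col="event", strata=["stratum"],
        )
        assert fit.beta[0] == pytest.approx(ctv.params_.iloc[0], rel=1e-6)
        assert fit.se[0] == pytest.approx(ctv.standard_errors_.iloc[0], rel=1e-6)
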