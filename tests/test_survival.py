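import numpy as np
import pandas as pd
import pytest

import bmidiscord as bd
from bmidiscord.cluster import Component, MixtureModel
from bmidiscord.survival import SurvivalFit, _efron_null_loglik


class TestLogContrast:
    def test_forced_arithmetic(self):
        alloc = pd.DataFrame({"concordant": [0.8], "d": [0.2]})
        lr = bd.log_contrast(alloc)
        assert lr["lr_d"].iloc[0] == pytest.approx(np.log(0.25), abs=1e-12)

    def test_uniform_gives_zero(self):
        alloc = pd.DataFrame(np.full((5, 4), 0.25),
                             columns=["concordant", "a", "b", "c"])
        lr = bd.log_contrast(alloc)
        assert np.allclose(lr, 0.0, atol=1e-12)

    def test_sqrt_e_shift_property(self):
        # raising a log-ratio by 1 multiplies that profile's probability
        # by sqrt(e) relative to each of the others
        p = np.array([0.6, 0.25, 0.15])
        alloc = pd.DataFrame([p], columns=["concordant", "a", "b"])
        lr0 = bd.log_contrast(alloc).iloc[0]
        f = np.exp(0.5)
        q = np.array([p[0] / f, p[1] * f, p[2] / f])
        q = q / q.sum()
        lr1 = bd.log_contrast(pd.DataFrame([q], columns=alloc.columns)).iloc[0]
        assert lr1["lr_a"] - lr0["lr_a"] == pytest.approx(1.0, abs=1e-12)
        assert lr1["lr_b"] - lr0["lr_b"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            bd.log_contrast(pd.DataFrame({"a": [1.0]}), reference="concordant")


def _surv_frame(n, beta, seed, rate=0.05, horizon=20.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    t = rng.exponential(1.0 / (rate * np.exp(beta * x)))
    e = (t <= horizon).astype(int)
    return pd.DataFrame({"t": np.minimum(t, horizon), "e": e, "x": x})


class TestFitCox:
    def test_two_group_loghr_recovery(self):
        df = _surv_frame(5000, 0.7, seed=0)
        fit = bd.fit_cox(df, "t", "e", ["x"])
        lo = fit.params["x"] - 1.96 * np.sqrt(fit.cov.loc["x", "x"])
        hi = fit.params["x"] + 1.96 * np.sqrt(fit.cov.loc["x", "x"])
        assert lo < 0.7 < hi

    def test_noise_covariate_mostly_null(self):
        hits = 0
        for s in range(10):
            df = _surv_frame(500, 0.0, seed=100 + s)
            fit = bd.fit_cox(df, "t", "e", ["x"])
            z = fit.params["x"] / np.sqrt(fit.cov.loc["x", "x"])
            hits += abs(z) < 2
        assert hits >= 7

    def test_perfect_ranking_concordance_one(self):
        n = 200
        t = np.linspace(1, 10, n)
        df = pd.DataFrame({"t": t, "e": np.ones(n, int), "x": -t})
        fit = bd.fit_cox(df, "t", "e", ["x"])
        assert fit.concordance == pytest.approx(1.0)

    def test_preconditions(self):
        df = _surv_frame(100, 0.0, seed=1)
        df.loc[0, "t"] = 0.0
        with pytest.raises(ValueError, match="positive"):
            bd.fit_cox(df, "t", "e", ["x"])
        df = _surv_frame(60, 0.0, seed=2, rate=0.0001)
        with pytest.raises(ValueError, match="events"):
            bd.fit_cox(df, "t", "e", ["x"])

    def test_null_loglik_matches_lifelines_with_ties(self):
        df = _surv_frame(400, 0.5, seed=3)
        df["t"] = np.ceil(df["t"])  # force heavy ties
        fit = bd.fit_cox(df, "t", "e", ["x"])
        assert fit.loglik_null == pytest.approx(fit.model._ll_null_, abs=1e-8)


class TestCompareNested:
    def test_identity_comparison_is_zero(self, surv_fit):
        full = surv_fit["full"]
        cmp_ = bd.compare_nested(full, full, n_boot=20, seed=0)
        assert cmp_.lrt == pytest.approx(0.0, abs=1e-8)
        assert cmp_.added_variance_pct == pytest.approx(0.0, abs=1e-8)
        assert cmp_.delta_c == pytest.approx(0.0, abs=1e-12)

    def test_planted_logratio_effect_detected(self, surv_fit):
        cmp_ = bd.compare_nested(surv_fit["base"], surv_fit["full"],
                                 n_boot=50, seed=0)
        assert cmp_.df == 3
        assert cmp_.pvalue < 1e-6
        assert cmp_.added_variance_pct > 0
        assert cmp_.delta_c > 0
        assert cmp_.delta_c_se > 0

    def test_lrt_equals_independent_likelihood_difference(self, surv_fit):
        base, full = surv_fit["base"], surv_fit["full"]
        cmp_ = bd.compare_nested(base, full, n_boot=10, seed=0)
        assert cmp_.lrt == pytest.approx(2 * (full.loglik - base.loglik), abs=1e-10)

    def test_non_nested_rejected(self, surv_fit):
        full = surv_fit["full"]
        other = bd.fit_cox(surv_fit["design"], "fu_years_mace", "mace_event",
                           ["age", "smoking"])
        with pytest.raises(ValueError, match="nested|rows"):
            bd.compare_nested(full, other)

    def test_efron_null_closed_form_tiny(self):
        # 3 subjects, no ties: -log 3 - log 2
        t = np.array([1.0, 2.0, 3.0]); e = np.array([1, 1, 0])
        assert _efron_null_loglik(t, e) == pytest.approx(-np.log(3) - np.log(2))


class TestLassoCox:
    def test_huge_penalty_zeroes_everything(self):
        df = _surv_frame(500, 0.8, seed=4)
        with pytest.warns(UserWarning, match="zero"):
            fit = bd.lasso_cox(df, "t", "e", ["x"], n_folds=3, lambdas=[1e4])
        assert abs(fit.params["x"]) < 1e-5

    def test_tiny_penalty_matches_unpenalized(self):
        df = _surv_frame(800, 0.6, seed=5)
        free = bd.fit_cox(df, "t", "e", ["x"])
        lfit = bd.lasso_cox(df, "t", "e", ["x"], n_folds=3, lambdas=[1e-9])
        assert lfit.params["x"] == pytest.approx(free.params["x"], abs=1e-4)

    def test_sparse_support_recovery(self):
        rng = np.random.default_rng(6)
        hits = 0
        for s in range(5):
            n, p = 1200, 12
            X = rng.normal(size=(n, p))
            beta = np.zeros(p); beta[:3] = 0.8
            t = rng.exponential(1.0 / (0.05 * np.exp(X @ beta)))
            e = (t <= 20).astype(int)
            df = pd.DataFrame(X, columns=[f"x{i}" for i in range(p)])
            df["t"] = np.minimum(t, 20); df["e"] = e
            fit = bd.lasso_cox(df, "t", "e", [f"x{i}" for i in range(p)],
                               n_folds=3, lambdas=np.geomspace(0.5, 1e-3, 6),
                               seed=s)
            support = set(np.flatnonzero(np.abs(fit.params.to_numpy()) > 0.05))
            hits += {0, 1, 2} <= support
        assert hits >= 4


def _fp():
    fp = pd.DataFrame(index=bd.BIOMARKERS,
                      columns=["s1_int", "age", "smoking", "b_int", "b_age",
                               "b_smk", "s2_int", "bmi", "center", "scale"],
                      data=0.0)
    fp["s1_int"] = 2.0; fp["age"] = 0.01; fp["bmi"] = 0.05
    fp["scale"] = 1.5
    return fp


def _fixed_fit(covariates, params, cov=None):
    k = len(covariates)
    cov = np.eye(k) * 1e-4 if cov is None else cov
    return SurvivalFit(
        params=pd.Series(params, index=covariates),
        cov=pd.DataFrame(cov, index=covariates, columns=covariates),
        loglik=0.0, loglik_null=0.0, concordance=0.5, n=1000, n_events=100,
        covariates=list(covariates), duration=np.ones(1), event=np.ones(1, int),
        lp=np.zeros(1),
    )


class TestShiftBiomarkers:
    @pytest.fixture()
    def fit_params(self):
        return _fp()

    def test_round_trip_defining_equation(self, small_mixture, fit_params):
        sp = bd.shift_biomarkers(small_mixture, "spike_a", 0.4, fit_params)
        assert sp.posterior["spike_a"] == pytest.approx(0.4, abs=1e-6)
        # biomarkers are the BMI-expectation plus the scaled residual
        expect = (2.0 + 0.01 * 55 + 0.05 * 30) + sp.residual * 1.5
        assert np.allclose(sp.biomarkers.to_numpy(), expect, atol=1e-10)

    def test_monotone_along_ray(self, small_mixture, fit_params):
        ts = [bd.shift_biomarkers(small_mixture, "spike_a", p, fit_params).t
              for p in (0.2, 0.4, 0.6, 0.9)]
        assert np.all(np.diff(ts) > 0)

    def test_unreachable_probability_reports_range(self, small_mixture, fit_params):
        with pytest.raises(ValueError, match="attainable"):
            bd.shift_biomarkers(small_mixture, "spike_a", 1 - 1e-12, fit_params,
                                t_max=0.5)
        with pytest.raises(ValueError):
            bd.shift_biomarkers(small_mixture, "spike_a", 1.2, fit_params)


class TestShiftRisk:
    def test_all_zero_coefficients_give_unit_hr(self, small_mixture):
        fp = _fp()
        covs = ["lr_spike_a", "lr_spike_b"] + bd.BIOMARKERS
        fit = _fixed_fit(covs, np.zeros(len(covs)))
        est = bd.shift_risk(fit, small_mixture, fp, "spike_a", delta=0.10)
        assert est.estimate == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_linear_predictor_oracle(self, small_mixture):
        fp = _fp()
        covs = ["lr_spike_a", "lr_spike_b"] + bd.BIOMARKERS
        rng = np.random.default_rng(7)
        beta = rng.normal(0, 0.2, len(covs))
        fit = _fixed_fit(covs, beta)
        delta = 0.10
        est = bd.shift_risk(fit, small_mixture, fp, "spike_a", delta=delta)
        # independent arithmetic: log-ratio changes from the weight shift,
        # biomarker changes from the two ray points
        w = dict(zip(small_mixture.labels, small_mixture.weights))
        p0 = np.array([w["concordant"], w["spike_a"], w["spike_b"]])
        p1 = np.array([w["concordant"] - delta, w["spike_a"] + delta, w["spike_b"]])
        lr0 = np.log(p0[1:] / p0[0]); lr1 = np.log(p1[1:] / p1[0])
        b0 = bd.shift_biomarkers(small_mixture, "spike_a", p0[1], fp).biomarkers
        b1 = bd.shift_biomarkers(small_mixture, "spike_a", p1[1], fp).biomarkers
        dlp = (beta[0] * (lr1[0] - lr0[0]) + beta[1] * (lr1[1] - lr0[1])
               + beta[2:] @ (b1.to_numpy() - b0.to_numpy()))
        assert est.estimate == pytest.approx(np.exp(dlp), abs=1e-10)

    def test_delta_to_zero_hr_to_one(self, small_mixture):
        fp = _fp()
        covs = ["lr_spike_a", "lr_spike_b"] + bd.BIOMARKERS
        fit = _fixed_fit(covs, np.full(len(covs), 0.3))
        hrs = [bd.shift_risk(fit, small_mixture, fp, "spike_a", delta=d).estimate
               for d in (0.1, 0.01, 0.001, 1e-5)]
        assert np.all(np.diff(np.abs(np.array(hrs) - 1.0)) < 0)
        assert abs(hrs[-1] - 1.0) < 1e-3

    def test_excessive_delta_rejected(self, small_mixture):
        fp = _fp()
        fit = _fixed_fit(["lr_spike_a", "lr_spike_b"], np.zeros(2))
        with pytest.raises(ValueError, match="outside"):
            bd.shift_risk(fit, small_mixture, fp, "spike_a", delta=0.95)


class TestFloorInvariance:
    def test_floor_inert_when_probabilities_unsaturated(self, surv_fit):
        # when no probability falls below the larger floor, the log-ratio
        # matrix (hence any downstream fit) is identical for any floor in
        # [1e-8, 1e-4]; a floor only matters once allocations saturate
        # beneath it, which truncates the log-ratios by construction
        alloc = surv_fit["alloc"]
        k = alloc.shape[1]
        soft = 0.999 * alloc + 0.001 / k  # min probability >= 2.5e-4
        lr_lo = bd.log_contrast(soft, floor=1e-8)
        lr_hi = bd.log_contrast(soft, floor=1e-4)
        assert np.array_equal(lr_lo.to_numpy(), lr_hi.to_numpy())

    def test_saturated_rows_are_floored_not_infinite(self):
        alloc = pd.DataFrame({"concordant": [1.0, 0.5], "d": [0.0, 0.5]})
        lr = bd.log_contrast(alloc, floor=1e-6)
        assert np.isfinite(lr.to_numpy()).all()
        assert lr["lr_d"].iloc[1] == pytest.approx(0.0, abs=1e-12)
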