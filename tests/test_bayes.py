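"""MAP Bayesian estimation: M3 likelihood, objective, fitting, forecasting."""

import math

import numpy as np
import pytest

from tobramipd.bayes import (
    MAPBayesEstimator,
    bloq_loglik,
    estimate_exposure_map,
    iterative_forecast,
    map_fit,
    map_objective,
)
from tobramipd.llr import Observation
from tobramipd.pk import (
    ModelSpec,
    Regimen,
    compute_auc,
    individual_parameters,
    predict_concentrations,
)


def log_phi_oracle(x: float) -> float:
    """Standard-normal log-CDF, independent of scipy.stats.

    Direct erfc evaluation in the bulk; a continued asymptotic expansion of
    the Mills ratio in the deep lower tail.
    """
    if x > -30.0:
        return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)))
    # ln[phi(x)/(-x) * (1 - 1/x^2 + 3/x^4 - 15/x^6 + 105/x^8)]
    x2 = x * x
    series = 1.0 - 1.0 / x2 + 3.0 / x2**2 - 15.0 / x2**3 + 105.0 / x2**4
    return -0.5 * x2 - 0.5 * math.log(2.0 * math.pi) - math.log(-x) + math.log(series)


class TestBloqLoglik:
    def test_prediction_at_loq_gives_log_half(self):
        assert bloq_loglik(0.4, 0.4, 0.5) == pytest.approx(math.log(0.5), rel=1e-12)

    def test_one_sigma_below(self):
        # (loq - pred)/sigma = 1 -> ln Phi(1)
        assert bloq_loglik(0.0, 0.5, 0.5) == pytest.approx(
            math.log(0.8413447460685429), rel=1e-9
        )

    def test_deep_tail_finite(self):
        ll = bloq_loglik(0.4 + 10 * 0.5, 0.4, 0.5)
        assert math.isfinite(ll)
        assert ll == pytest.approx(log_phi_oracle(-10.0), rel=1e-9)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            bloq_loglik(1.0, 0.4, 0.0)


@pytest.fixture
def one_obs_case(spec_1cmt_cl):
    """A single quantified observation where pred(eta=0.3) is exactly 8 mg/L.

    Sampled at end of infusion so the closed form
    pred = D/(tinf CL) (1 - e^{-k tinf}) pins the dose.
    """
    spec = ModelSpec(
        n_compartments=1,
        theta={"CL": 5.0, "V1": 30.0},
        omega=np.array([[0.09]]),
        iiv=("CL",),
        sigma_prop=0.10,
        sigma_add=0.0,
        label="hand-case",
    )
    eta = 0.3
    cl = 5.0 * math.exp(eta)
    k = cl / 30.0
    tinf = 0.5
    dose = 8.0 * tinf * cl / (1.0 - math.exp(-k * tinf))
    reg = Regimen.single(dose, tinf=tinf)
    obs = [Observation(time=tinf, value=10.0)]
    return spec, reg, obs, eta


class TestMapObjective:
    def test_zero_eta_no_observations(self, spec_1cmt_cl):
        reg = Regimen.single(600.0)
        assert map_objective([0.0], spec_1cmt_cl, [], reg, {}) == 0.0

    def test_hand_arithmetic(self, one_obs_case):
        # prior 0.3^2/0.09 = 1; data (2/0.8)^2 + ln 0.64 = 6.25 + ln 0.64
        spec, reg, obs, eta = one_obs_case
        expected = 1.0 + 6.25 + math.log(0.64)
        got = map_objective([eta], spec, obs, reg, {}, w=1.0)
        assert got == pytest.approx(expected, rel=1e-9)
        assert got == pytest.approx(6.8037, abs=2e-4)

    def test_prior_term_linear_in_weight(self, one_obs_case):
        spec, reg, obs, eta = one_obs_case
        full = map_objective([eta], spec, obs, reg, {}, w=1.0)
        half = map_objective([eta], spec, obs, reg, {}, w=0.5)
        assert full - half == pytest.approx(0.5, rel=1e-9)
        assert half == pytest.approx(0.5 + 6.25 + math.log(0.64), rel=1e-9)

    def test_invalid_weight_rejected(self, one_obs_case):
        spec, reg, obs, _ = one_obs_case
        with pytest.raises(ValueError):
            map_objective([0.0], spec, obs, reg, {}, w=0.0)

    def test_censoring_boundary_is_continuous_in_prediction(self, spec_1cmt_cl):
        """Sweeping the prediction through the LOQ changes the censored
        likelihood term smoothly (no jumps from the M3 formulation)."""
        loq, sd = 0.4, 0.2
        preds = np.linspace(loq - 0.2, loq + 0.2, 401)
        vals = np.array([-2.0 * bloq_loglik(p, loq, sd) for p in preds])
        steps = np.abs(np.diff(vals))
        assert np.all(steps < 0.05)  # smooth at the 1e-3 mg/L sweep resolution


class TestMapFit:
    def test_no_observations_returns_prior_mode(self, spec_1cmt_cl):
        reg = Regimen.single(600.0)
        f = map_fit(spec_1cmt_cl, [], reg, {}, w=1.0)
        assert np.all(f.eta_hat == 0.0)
        assert f.n_obs_used == 0 and f.converged
        assert f.params.CL == spec_1cmt_cl.theta["CL"]

    def test_matches_grid_search_oracle(self, one_obs_case):
        """1-D fit agrees with an independent dense grid search over eta."""
        spec, reg, obs, _ = one_obs_case
        f = map_fit(spec, obs, reg, {}, w=1.0)

        # independent vectorized OFV: closed-form 1-cmt prediction
        etas = np.linspace(-2.0, 2.0, 400001)
        cl = spec.theta["CL"] * np.exp(etas)
        k = cl / spec.theta["V1"]
        d, tinf = reg.doses[0].amount, reg.doses[0].tinf
        pred = d / (tinf * cl) * (1.0 - np.exp(-k * tinf))
        sd = spec.sigma_prop * pred
        ofv = etas**2 / 0.09 + ((obs[0].value - pred) / sd) ** 2 + np.log(sd**2)
        eta_grid = etas[np.argmin(ofv)]
        assert f.eta_hat[0] == pytest.approx(eta_grid, abs=1e-4)

    def test_noiseless_dense_recovery(self, spec_1cmt_lownoise):
        """Dense noiseless samples from a matched model pin eta at w=1."""
        spec = spec_1cmt_lownoise
        eta_true = np.array([0.25])
        params = individual_parameters(spec, {}, eta_true)
        reg = Regimen.single(600.0)
        times = np.linspace(1.0, 23.0, 12)
        conc = predict_concentrations(params, reg, times)
        obs = [Observation(float(t), float(c)) for t, c in zip(times, conc)]
        f = map_fit(spec, obs, reg, {}, w=1.0)
        assert f.eta_hat[0] == pytest.approx(eta_true[0], abs=1e-3)

    def test_huge_residual_error_shrinks_to_prior_mode(self, spec_1cmt_cl):
        spec = ModelSpec(
            n_compartments=1,
            theta={"CL": 5.0, "V1": 30.0},
            omega=np.array([[0.09]]),
            iiv=("CL",),
            sigma_prop=0.0,
            sigma_add=1e6,
        )
        reg = Regimen.single(600.0)
        obs = [Observation(2.0, 8.0), Observation(10.0, 2.0)]
        f = map_fit(spec, obs, reg, {})
        assert abs(f.eta_hat[0]) < 1e-3

    def test_flattening_monotonicity_single_dataset(self, hennig, ref_covariates):
        """Lower prior weight never worsens the optimized data-likelihood
        term (OFV minus the weighted prior quadratic form)."""
        rng = np.random.default_rng(7)
        eta_true = rng.multivariate_normal(np.zeros(hennig.n_eta), hennig.omega)
        params = individual_parameters(hennig, ref_covariates, eta_true)
        reg = Regimen.single(700.0)
        times = np.array([1.0, 10.0])
        pred = predict_concentrations(params, reg, times)
        noisy = pred * (1 + hennig.sigma_prop * rng.standard_normal(2))
        obs = [Observation(float(t), float(max(c, 0.5))) for t, c in zip(times, noisy)]
        omega_inv = np.linalg.inv(hennig.omega)

        def datafit(w):
            f = map_fit(hennig, obs, reg, ref_covariates, w=w)
            return f.ofv - w * float(f.eta_hat @ omega_inv @ f.eta_hat)

        fits = [datafit(w) for w in (1.0, 0.75, 0.5, 0.25, 0.1)]
        assert all(b <= a + 1e-6 for a, b in zip(fits, fits[1:]))


class TestIterativeForecast:
    def _course(self, spec, eta, n_doses=3, noise_rng=None):
        params = individual_parameters(spec, {}, eta)
        reg = Regimen.repeated(600.0, n_doses, tinterval=24.0)
        obs = []
        for i in range(n_doses):
            t0 = i * 24.0
            for off in (1.5, 20.0):
                c = float(predict_concentrations(params, reg, [t0 + off])[0])
                if noise_rng is not None:
                    c *= 1 + spec.sigma_prop * noise_rng.standard_normal()
                obs.append(Observation(t0 + off, max(c, 0.5)))
        return reg, obs

    def test_single_group_gives_one_a_priori_record(self, spec_1cmt_cl):
        reg = Regimen.single(600.0)
        obs = [Observation(1.5, 8.0), Observation(20.0, 1.0)]
        recs = iterative_forecast(obs, reg, {}, spec_1cmt_cl)
        assert len(recs) == 1
        assert recs[0].mode == "a priori"
        assert np.all(recs[0].fit.eta_hat == 0.0)

    def test_three_groups_use_strictly_growing_history(self, spec_1cmt_cl):
        reg, obs = self._course(spec_1cmt_cl, [0.2])
        recs = iterative_forecast(obs, reg, {}, spec_1cmt_cl)
        assert [r.mode for r in recs] == ["a priori"] + ["a posteriori"] * (len(recs) - 1)
        used = [r.fit.n_obs_used for r in recs]
        assert used[0] == 0
        assert all(b > a for a, b in zip(used, used[1:]))

    def test_posterior_beats_prior_for_atypical_individual(self, spec_1cmt_lownoise):
        """With a true eta well off 0 and clean data, the group-2 prediction
        from the fitted individual beats the population a-priori one."""
        spec = spec_1cmt_lownoise
        eta = [0.5]
        reg, obs = self._course(spec, eta)
        recs = iterative_forecast(obs, reg, {}, spec)
        g2_obs = np.array([o.value for o in obs[2:4]])
        post_err = np.sum((recs[1].predicted - g2_obs) ** 2)
        prior_pred = predict_concentrations(
            individual_parameters(spec, {}, [0.0]), reg, [o.time for o in obs[2:4]]
        )
        prior_err = np.sum((prior_pred - g2_obs) ** 2)
        assert post_err < prior_err

    def test_bloq_samples_enter_via_m3(self, spec_1cmt_cl):
        reg = Regimen.repeated(600.0, 2, tinterval=24.0)
        obs = [
            Observation(1.5, 8.0),
            Observation(20.0, None, bloq=True, loq=0.4),
            Observation(25.5, 9.0),
        ]
        recs = iterative_forecast(obs, reg, {}, spec_1cmt_cl)
        assert recs[-1].fit.n_obs_used == 2  # BLOQ sample counted in the history


class TestExposure:
    def test_matched_noiseless_auc_round_trip(self, spec_1cmt_lownoise):
        spec = spec_1cmt_lownoise
        eta_true = np.array([0.3])
        params = individual_parameters(spec, {}, eta_true)
        reg = Regimen.single(600.0)
        times = np.linspace(1.0, 23.0, 8)
        obs = [
            Observation(float(t), float(c))
            for t, c in zip(times, predict_concentrations(params, reg, times))
        ]
        f = map_fit(spec, obs, reg, {}, w=1.0)
        auc, _, _ = estimate_exposure_map(f, reg)
        true_auc = compute_auc(params, (0.0, 24.0), reg)
        assert auc == pytest.approx(true_auc, rel=5e-3)

    def test_zero_observations_auc_independent_of_weight(self, spec_1cmt_cl):
        reg = Regimen.single(600.0)
        aucs = {
            w: estimate_exposure_map(map_fit(spec_1cmt_cl, [], reg, {}, w=w), reg)[0]
            for w in (1.0, 0.5, 0.1)
        }
        assert len(set(aucs.values())) == 1

    def test_auc_matches_trapezoid_of_fitted_curve(self, spec_1cmt_cl):
        reg = Regimen.single(600.0)
        f = map_fit(spec_1cmt_cl, [Observation(1.5, 12.0)], reg, {})
        auc, _, _ = estimate_exposure_map(f, reg)
        t = np.linspace(0.0, 24.0, 24001)
        trap = np.trapezoid(predict_concentrations(f.params, reg, t), t)
        assert auc == pytest.approx(trap, rel=1e-3)


class TestEstimatorInterface:
    def test_fit_predict_and_fitted_attributes(self, hennig, ref_covariates):
        from tobramipd.io import Course

        reg = Regimen.single(700.0)
        course = Course(
            course_id="c1",
            patient_id="p1",
            covariates=ref_covariates,
            regimen=reg,
            observations=[Observation(1.0, 25.0), Observation(10.0, 2.0)],
        )
        est = MAPBayesEstimator(model=hennig, prior_weight=0.5).fit(course)
        assert est.converged_
        assert est.eta_.shape == (hennig.n_eta,)
        pred = est.predict([1.0, 10.0])
        assert pred.shape == (2,) and np.all(pred > 0)
        assert est.predict_auc() > 0
        assert est.get_params()["prior_weight"] == 0.5
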