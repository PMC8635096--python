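"""Marginal likelihood approximations and the outer maximum-likelihood fit."""

import math
from dataclasses import replace

import numpy as np
import pytest

from placebo_mbma import (
    FitConfig,
    MetaDataset,
    ModelParameters,
    ObservationRecord,
    Trial,
    TrialCovariates,
    empirical_bayes,
    fit,
    fit_result_from_estimates,
    ofv_laplace,
    ofv_quadrature,
    reference_parameters,
    sample_design,
    simulate_dataset,
    typical_response,
)


def closed_form_deviance(params, ds):
    """Weighted least-squares deviance: the exact OFV when both omegas are 0."""
    total = 0.0
    for t in ds.trials:
        pred = typical_response(params, t.covariates.baseline_essdai, t.times)
        r = t.changes - pred
        total += float(np.sum(r**2 * t.n_subjects / params.sigma**2
                              + np.log(params.sigma**2 / t.n_subjects)))
    return total


@pytest.fixture(scope="module")
def no_omega_params():
    return ModelParameters(4.44, 12.2, {"baseline_essdai": (0.552, 10.1)},
                           omega_emax=0.0, omega_et50=0.0, sigma=1.661)


class TestOfvIdentities:
    def test_laplace_equals_one_node_quadrature(self, ref_params, corpus3,
                                                corpus13):
        for ds in (corpus3, corpus13):
            assert ofv_laplace(ref_params, ds) == pytest.approx(
                ofv_quadrature(ref_params, ds, nodes=1), abs=1e-10
            )

    def test_zero_omega_matches_closed_form(self, no_omega_params, corpus3):
        assert ofv_laplace(no_omega_params, corpus3) == pytest.approx(
            closed_form_deviance(no_omega_params, corpus3), abs=1e-10
        )
        assert ofv_quadrature(no_omega_params, corpus3, nodes=7) == pytest.approx(
            closed_form_deviance(no_omega_params, corpus3), abs=1e-10
        )

    def test_quadrature_converges_with_nodes(self, ref_params, corpus3):
        values = {n: ofv_quadrature(ref_params, corpus3, nodes=n)
                  for n in (5, 9, 15, 21, 31)}
        gaps = [abs(values[a] - values[31]) for a in (5, 9, 15, 21)]
        assert gaps == sorted(gaps, reverse=True)
        assert abs(values[21] - values[31]) < 1e-4

    def test_doubling_sigma_on_perfect_fit(self, no_omega_params):
        # residuals identically zero: OFV = sum log(sigma^2/N), so doubling
        # sigma raises it by exactly n_obs * 2 * log 2
        cov = TrialCovariates(baseline_essdai=9.0, duration_weeks=48.0)
        times = np.array([8.0, 16.0, 24.0, 48.0])
        pred = typical_response(no_omega_params, 9.0, times)
        obs = tuple(ObservationRecord(t, y, 30) for t, y in zip(times, pred))
        ds = MetaDataset((Trial("T1", cov, obs),))
        doubled = replace(no_omega_params, sigma=2 * no_omega_params.sigma)
        delta = ofv_laplace(doubled, ds) - ofv_laplace(no_omega_params, ds)
        assert delta == pytest.approx(len(times) * 2.0 * math.log(2.0), abs=1e-10)

    def test_ofv_invariant_to_trial_order_and_labels(self, ref_params, corpus13):
        ref = ofv_laplace(ref_params, corpus13)
        shuffled = MetaDataset(tuple(reversed(corpus13.trials)))
        relabeled = MetaDataset(tuple(
            Trial(f"X{i}", t.covariates, t.observations)
            for i, t in enumerate(corpus13.trials)
        ))
        assert ofv_laplace(ref_params, shuffled) == pytest.approx(ref, abs=1e-9)
        assert ofv_laplace(ref_params, relabeled) == pytest.approx(ref, abs=1e-9)

    def test_sigma_zero_rejected(self, corpus3):
        bad = ModelParameters(4.44, 12.2, {}, sigma=0.0)
        with pytest.raises(ValueError, match="sigma"):
            ofv_laplace(bad, corpus3)


class TestFit:
    def test_recovery_small_variances(self):
        # nearly-deterministic generator: estimates must land close to truth
        truth = ModelParameters(4.44, 12.2, {"baseline_essdai": (0.552, 10.1)},
                                omega_emax=0.01, omega_et50=0.01, sigma=0.2)
        design = sample_design(40, seed=50)
        ds = simulate_dataset(design, truth, seed=51)
        res = fit(ds, ["baseline_essdai"], FitConfig(compute_covariance=False))
        assert res.converged
        from placebo_mbma import trial_emax

        emax_ref = trial_emax(res.params, {"baseline_essdai": 10.1}, 0.0)
        assert emax_ref == pytest.approx(4.44, rel=0.10)
        assert res.params.theta_et50 == pytest.approx(12.2, rel=0.10)
        assert res.params.covariate_effects["baseline_essdai"].coefficient == (
            pytest.approx(0.552, rel=0.15)
        )

    def test_refit_is_stationary(self, ref_params, corpus13):
        res = fit(corpus13, ["baseline_essdai"], FitConfig(compute_covariance=False))
        refit = fit(corpus13, ["baseline_essdai"],
                    FitConfig(initial=res.params, compute_covariance=False))
        assert res.ofv - refit.ofv < 0.01
        assert refit.ofv <= res.ofv + 1e-6

    def test_multistart_stability(self, corpus13):
        a = fit(corpus13, (), FitConfig(compute_covariance=False))
        b = fit(corpus13, (), FitConfig(compute_covariance=False, n_starts=3,
                                        seed=7))
        assert a.ofv == pytest.approx(b.ofv, abs=0.1)

    def test_covariance_and_rse(self, corpus13):
        res = fit(corpus13, ["baseline_essdai"], FitConfig())
        assert res.converged and res.covariance is not None
        eig = np.linalg.eigvalsh(res.covariance)
        assert eig.min() > -1e-8
        for name, value in res.estimates.items():
            if value != 0:
                assert res.rse_pct[name] == pytest.approx(
                    100 * res.se[name] / abs(value), rel=1e-6
                )

    def test_missing_covariate_rejected(self, corpus13):
        with pytest.raises(ValueError, match="diagnosis_years"):
            ds = MetaDataset(tuple(
                Trial(t.trial_id,
                      replace_cov_none(t.covariates), t.observations)
                for t in corpus13.trials
            ))
            fit(ds, ["diagnosis_years"], FitConfig())


def replace_cov_none(cov):
    from dataclasses import replace as dc_replace

    return dc_replace(cov, diagnosis_years=None)


class TestEmpiricalBayes:
    def _on_curve_trial(self, params, baseline=9.0):
        cov = TrialCovariates(baseline_essdai=baseline, duration_weeks=48.0)
        times = np.array([8.0, 24.0, 48.0])
        pred = typical_response(params, baseline, times)
        obs = tuple(ObservationRecord(t, y, 30) for t, y in zip(times, pred))
        return Trial("T1", cov, obs)

    def test_on_curve_data_gives_zero_etas(self, ref_params):
        trial = self._on_curve_trial(ref_params)
        ebe = empirical_bayes(ref_params, trial)
        assert abs(ebe.eta_emax) < 1e-5 and abs(ebe.eta_et50) < 1e-5

    def test_huge_omega_reproduces_single_observation(self):
        # no shrinkage limit: the trial-level prediction matches the datum
        params = ModelParameters(4.44, 12.2, {}, omega_emax=1e4,
                                 omega_et50=0.0, sigma=1.0)
        cov = TrialCovariates(baseline_essdai=9.0, duration_weeks=24.0)
        trial = Trial("T1", cov, (ObservationRecord(24.0, -3.7, 25),))
        ebe = empirical_bayes(params, trial)
        from placebo_mbma import predict_change

        assert predict_change(params, cov, ebe, 24.0) == pytest.approx(-3.7,
                                                                       abs=1e-4)

    def test_zero_omega_full_shrinkage(self, ref_params):
        params = replace(ref_params, omega_emax=0.0, omega_et50=0.0)
        trial = self._on_curve_trial(ref_params)
        ebe = empirical_bayes(params, trial)
        assert ebe.eta_emax == 0.0 and ebe.eta_et50 == 0.0


def test_fit_result_from_estimates_rse_round_trip(ref_params):
    rse = {"theta_emax": 14.3, "theta_et50": 35.4, "beta_baseline_essdai": 18.8,
           "omega_emax": 24.0, "omega_et50": 29.4, "sigma": 17.3}
    res = fit_result_from_estimates(ref_params, rse)
    assert res.covariance is not None
    assert res.se["theta_emax"] == pytest.approx(0.143 * 4.44)
    assert res.se["theta_et50"] == pytest.approx(0.354 * 12.2)
    # log-scale parameters carry their RSE as the transformed-scale SD
    i = res.param_names.index("log_theta_et50")
    assert math.sqrt(res.covariance[i, i]) == pytest.approx(0.354)
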