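"""Model qualification diagnostics: CWRES, jackknife, VPC, SIR."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from placebo_mbma import (
    FitConfig,
    MetaDataset,
    ModelParameters,
    ObservationRecord,
    Trial,
    TrialCovariates,
    fit,
    fit_result_from_estimates,
    gof_table,
    leave_one_out,
    reference_parameters,
    sample_design,
    simulate_dataset,
    sir,
    sir_from_surface,
    typical_response,
    vpc,
)


def _perfect_fit_dataset(params, baselines=(6.0, 9.0, 12.0)):
    trials = []
    for i, b in enumerate(baselines):
        times = np.array([8.0, 24.0, 48.0])
        pred = typical_response(params, b, times)
        cov = TrialCovariates(baseline_essdai=b, duration_weeks=48.0)
        obs = tuple(ObservationRecord(t, y, 30) for t, y in zip(times, pred))
        trials.append(Trial(f"T{i}", cov, obs))
    return MetaDataset(tuple(trials))


class TestGof:
    def test_zero_omega_cwres_is_scaled_residual(self):
        params = ModelParameters(4.44, 12.2, {"baseline_essdai": (0.552, 10.1)},
                                 omega_emax=0.0, omega_et50=0.0, sigma=1.5)
        ds = _perfect_fit_dataset(params)
        # perturb one observation to get a non-trivial residual
        t0 = ds.trials[0]
        obs = list(t0.observations)
        obs[1] = ObservationRecord(obs[1].time_weeks,
                                   obs[1].change_essdai + 0.9, obs[1].n_subjects)
        ds = MetaDataset((Trial(t0.trial_id, t0.covariates, tuple(obs)),)
                         + ds.trials[1:])
        res = fit_result_from_estimates(params, ds=ds)
        gof = gof_table(res, ds)
        expected = (gof["obs"] - gof["pred"]) * np.sqrt(30) / 1.5
        np.testing.assert_allclose(gof["cwres"], expected, atol=1e-10)

    def test_perfect_fit_gives_zero_cwres(self):
        params = ModelParameters(4.44, 12.2, {"baseline_essdai": (0.552, 10.1)},
                                 omega_emax=0.0, omega_et50=0.0, sigma=1.5)
        ds = _perfect_fit_dataset(params)
        res = fit_result_from_estimates(params, ds=ds)
        gof = gof_table(res, ds)
        np.testing.assert_allclose(gof["cwres"], 0.0, atol=1e-10)
        np.testing.assert_allclose(gof["ipred"], gof["pred"], atol=1e-8)

    def test_cwres_calibration_under_true_model(self, ref_params):
        # data generated from the model itself: CWRES ~ N(0, 1) approximately
        design = sample_design(60, seed=71)
        ds = simulate_dataset(design, ref_params, seed=72)
        res = fit_result_from_estimates(ref_params, ds=ds)
        gof = gof_table(res, ds)
        assert abs(gof["cwres"].mean()) < 0.1
        assert 0.85 <= gof["cwres"].std() <= 1.15


class TestLeaveOneOut:
    def test_requires_three_trials(self, two_trial_dataset):
        with pytest.raises(ValueError, match="3 trials"):
            leave_one_out(two_trial_dataset)

    def test_identical_trials_give_identical_rows(self, ref_params):
        base = _perfect_fit_dataset(ref_params, baselines=(9.0,)).trials[0]
        ds = MetaDataset(tuple(
            Trial(f"T{i}", base.covariates, base.observations) for i in range(4)
        ))
        table = leave_one_out(ds, (), FitConfig(compute_covariance=False))
        est_cols = [c for c in table.columns
                    if c not in ("omitted_trial",) and not c.endswith("_rel_dev")]
        first = table.iloc[0][est_cols].astype(float)
        for _, row in table.iterrows():
            np.testing.assert_allclose(row[est_cols].astype(float), first,
                                       rtol=1e-4, atol=1e-6)


@pytest.fixture(scope="module")
def fitted(corpus13):
    return fit(corpus13, ["baseline_essdai"],
               FitConfig(compute_covariance=False))


class TestVpc:

    def test_determinism(self, fitted, corpus13):
        a = vpc(fitted, corpus13, n_sim=200, seed=5)
        b = vpc(fitted, corpus13, n_sim=200, seed=5)
        assert a.to_frame().equals(b.to_frame())

    def test_band_nesting(self, fitted, corpus13):
        v = vpc(fitted, corpus13, n_sim=300, seed=6)
        assert np.all(v.p2_5 <= v.p50) and np.all(v.p50 <= v.p97_5)

    def test_zero_variance_band_collapses(self):
        # homogeneous corpus (one baseline): bins pool across trials, so the
        # collapse to the typical curve requires identical typical curves
        params = ModelParameters(4.44, 12.2, {"baseline_essdai": (0.552, 10.1)},
                                 omega_emax=0.0, omega_et50=0.0, sigma=1.0)
        ds = _perfect_fit_dataset(params, baselines=(9.0, 9.0, 9.0))
        res = fit_result_from_estimates(params, ds=ds)
        collapsed = replace(res, params=replace(params, sigma=1e-12))
        v = vpc(collapsed, ds, n_sim=100, seed=1)
        np.testing.assert_allclose(v.p2_5, v.p97_5, atol=1e-9)
        expected = typical_response(params, 9.0, v.bins)
        np.testing.assert_allclose(v.p50, expected, atol=1e-9)

    def test_wider_sigma_never_narrows_band(self, fitted, corpus13):
        narrow = vpc(fitted, corpus13, n_sim=400, seed=9)
        wider_params = replace(fitted.params, sigma=2 * fitted.params.sigma,
                               omega_emax=2 * fitted.params.omega_emax)
        wider = vpc(replace(fitted, params=wider_params), corpus13,
                    n_sim=400, seed=9)
        assert np.all(wider.p97_5 - wider.p2_5 >= narrow.p97_5 - narrow.p2_5 - 1e-9)

    def test_self_consistency_coverage(self, ref_params):
        # observations drawn from the very model the bands come from
        design = sample_design(13, seed=31)
        ds = simulate_dataset(design, ref_params, seed=32)
        res = fit_result_from_estimates(ref_params, ds=ds)
        v = vpc(res, ds, n_sim=500, seed=33)
        frac = v.fraction_inside()
        n = ds.n_obs
        assert frac >= 0.95 - 3 * np.sqrt(0.05 * 0.95 / n)


class TestSir:
    def test_resample_count_validated(self):
        with pytest.raises(ValueError, match="n_resample"):
            sir_from_surface(lambda x: 0.0, np.zeros(2), np.eye(2), ["a", "b"],
                             n_proposal=10, n_resample=20)

    def test_quadratic_surface_matches_wald(self):
        # OFV = (x - mu)' A (x - mu): likelihood exp(-OFV/2) = N(mu, A^{-1})
        mu = np.array([1.5, -2.0])
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        wald_cov = np.linalg.inv(A)

        def ofv(x):
            d = x - mu
            return float(d @ A @ d)

        res = sir_from_surface(ofv, mu, wald_cov, ["a", "b"],
                               n_proposal=4000, n_resample=1000, seed=3)
        for i, name in enumerate(("a", "b")):
            lo, med, hi = res.band(name)
            se = np.sqrt(wald_cov[i, i])
            assert med == pytest.approx(mu[i], abs=0.12 * se)
            assert hi - lo == pytest.approx(2 * 1.96 * se, rel=0.12)

    def test_degenerate_weights_raise(self):
        mu = np.zeros(2)

        def ofv(x):
            return float(1e4 * x @ x)  # posterior far narrower than proposal

        with pytest.raises(RuntimeError, match="ESS"):
            sir_from_surface(ofv, mu, np.eye(2), ["a", "b"],
                             n_proposal=300, n_resample=50, seed=1)

    def test_fit_based_sir_tracks_estimates(self, corpus13):
        res = fit(corpus13, ["baseline_essdai"], FitConfig())
        out = sir(res, corpus13, n_proposal=800, n_resample=200, seed=11)
        assert out.ess >= 50
        est = res.estimates
        for name in ("theta_emax", "theta_et50", "sigma"):
            lo, med, hi = out.band(name)
            assert lo <= est[name] <= hi
            assert med == pytest.approx(est[name], rel=0.25)
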