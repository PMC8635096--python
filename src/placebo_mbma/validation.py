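"""Model qualification: GOF residuals, jackknife, predictive check, SIR.

Four complementary diagnostics:

* conditional weighted residuals (CWRES) from a first-order conditional
  linearization of the model about the empirical Bayes effects;
* leave-one-trial-out refits (jackknife) for influence analysis;
* a visual predictive check (VPC): percentile bands of many replicate corpora
  simulated at the estimates under the original design;
* sampling-importance-resampling (SIR) of the parameter uncertainty from the
  asymptotic covariance, reweighted by the true OFV surface.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import multivariate_normal

from .data_io import MetaDataset, Trial
from .estimation import (
    FitConfig,
    FitResult,
    _arrays,
    _natural_names,
    _unpack,
    fit,
)
from .structural_model import (
    ModelParameters,
    TrialRandomEffects,
    predict_change,
    trial_emax,
    trial_et50,
)
from .synthetic_data import SimulationDesign, TrialDesign

__all__ = [
    "GofRecord",
    "VpcResult",
    "SirResult",
    "gof_table",
    "leave_one_out",
    "vpc",
    "sir",
    "sir_from_surface",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GofRecord:
    trial_id: str
    time_weeks: float
    obs: float
    pred: float
    ipred: float
    cwres: float


def _linearized_cov(params: ModelParameters, trial: Trial,
                    etas: TrialRandomEffects) -> tuple[np.ndarray, np.ndarray]:
    """FOCE linearization about the EBEs: returns (F, V) with F the Jacobian
    of the prediction in eta and V the implied marginal covariance."""
    t = trial.times
    emax_i = trial_emax(params, trial.covariates, etas.eta_emax)
    et50_i = trial_et50(params, etas.eta_et50)
    d = et50_i + t
    F = np.zeros((len(t), 2))
    F[:, 0] = -t / d                       # d f / d eta_emax
    F[:, 1] = emax_i * t * et50_i / d**2   # d f / d eta_et50
    omega = np.diag([params.omega_emax**2, params.omega_et50**2])
    V = F @ omega @ F.T + np.diag(params.sigma**2 / trial.n_subjects)
    return F, V


def gof_table(fit_result: FitResult, ds: MetaDataset) -> pd.DataFrame:
    """Per-observation goodness-of-fit table: OBS, PRED, IPRED, CWRES.

    PRED is the population prediction (random effects at zero, covariates at
    the trial's values); IPRED evaluates the model at the trial's empirical
    Bayes effects; CWRES decorrelates the residual about the linearized
    conditional mean with the Cholesky inverse of the marginal covariance, so
    under a correct model CWRES is approximately standard normal.
    """
    if not fit_result.converged:
        raise ValueError("goodness of fit requires a converged fit")
    params = fit_result.params
    records = []
    for trial in ds.trials:
        etas = fit_result.ebes.get(trial.trial_id, TrialRandomEffects())
        y = trial.changes
        pred = predict_change(params, trial.covariates, TrialRandomEffects(),
                              trial.times)
        ipred = predict_change(params, trial.covariates, etas, trial.times)
        F, V = _linearized_cov(params, trial, etas)
        eta_vec = np.array([etas.eta_emax, etas.eta_et50])
        cond_mean = ipred - F @ eta_vec  # first-order conditional expectation
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"singular marginal covariance for trial {trial.trial_id!r}"
            ) from exc
        cwres = np.linalg.solve(L, y - cond_mean)
        for j in range(len(y)):
            records.append(GofRecord(trial.trial_id, float(trial.times[j]),
                                     float(y[j]), float(pred[j]),
                                     float(ipred[j]), float(cwres[j])))
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# jackknife
# ---------------------------------------------------------------------------


def leave_one_out(
    ds: MetaDataset,
    cov_spec: Sequence = (),
    config: Optional[FitConfig] = None,
) -> pd.DataFrame:
    """Leave-one-trial-out sensitivity analysis.

    Refits the model once per omitted trial and reports each refit's
    estimates alongside their relative deviation from the all-data fit.
    Non-convergent refits are flagged, not fatal.  Requires >= 3 trials.
    """
    if ds.n_trials < 3:
        raise ValueError("leave-one-out requires at least 3 trials")
    config = config or FitConfig()
    quiet = replace(config, compute_covariance=False)
    full = fit(ds, cov_spec, quiet)
    full_est = full.estimates
    rows = []
    for trial in ds.trials:
        sub = ds.drop_trial(trial.trial_id)
        res = fit(sub, cov_spec, quiet)
        row: dict = {"omitted_trial": trial.trial_id, "converged": res.converged,
                     "ofv": res.ofv}
        for name, value in res.estimates.items():
            row[name] = value
            ref = full_est[name]
            row[f"{name}_rel_dev"] = (value - ref) / abs(ref) if ref != 0 else np.nan
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["full_fit_estimates"] = full_est
    return out


# ---------------------------------------------------------------------------
# visual predictive check
# ---------------------------------------------------------------------------


@dataclass
class VpcResult:
    """Per-nominal-time percentile bands of simulated corpora plus observations."""

    bins: np.ndarray            # nominal times, sorted
    p2_5: np.ndarray
    p50: np.ndarray
    p97_5: np.ndarray
    observed: dict[float, np.ndarray]  # nominal time -> observed changes
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, b in enumerate(self.bins):
            for obs in self.observed.get(float(b), []):
                rows.append({"bin": float(b), "obs": float(obs),
                             "p2.5": self.p2_5[i], "p50": self.p50[i],
                             "p97.5": self.p97_5[i]})
            if float(b) not in self.observed or len(self.observed[float(b)]) == 0:
                rows.append({"bin": float(b), "obs": np.nan,
                             "p2.5": self.p2_5[i], "p50": self.p50[i],
                             "p97.5": self.p97_5[i]})
        return pd.DataFrame(rows)

    def fraction_inside(self) -> float:
        """Fraction of observations inside their bin's 2.5-97.5 band."""
        inside = total = 0
        for i, b in enumerate(self.bins):
            for obs in self.observed.get(float(b), []):
                total += 1
                if self.p2_5[i] <= obs <= self.p97_5[i]:
                    inside += 1
        return inside / total if total else float("nan")


def _design_from_dataset(ds: MetaDataset) -> SimulationDesign:
    trials = []
    for t in ds.trials:
        n = int(round(float(np.median(t.n_subjects))))
        trials.append(TrialDesign(t.trial_id, max(n, 1),
                                  tuple(float(x) for x in t.times), t.covariates))
    return SimulationDesign(tuple(trials))


def vpc(
    fit_result: FitResult,
    ds: MetaDataset,
    n_sim: int = 1000,
    seed: int = 0,
) -> VpcResult:
    """Visual predictive check: simulate ``n_sim`` replicate corpora at the
    estimates under the original design and summarize per nominal visit week.

    Bins are the nominal visit weeks themselves (the corpus shares a sparse
    protocol grid; no smoothing or binning heuristics).
    """
    if not fit_result.converged:
        raise ValueError("VPC requires a converged fit")
    params = fit_result.params
    rng = np.random.default_rng(seed)
    sim_values: dict[float, list] = {}
    # vectorized across replicates, trial by trial
    for trial in ds.trials:
        t = trial.times
        nsub = trial.n_subjects
        emax_typ = trial_emax(params, trial.covariates, 0.0)
        eta1 = (rng.normal(0.0, params.omega_emax, size=n_sim)
                if params.omega_emax > 0 else np.zeros(n_sim))
        eta2 = (rng.normal(0.0, params.omega_et50, size=n_sim)
                if params.omega_et50 > 0 else np.zeros(n_sim))
        emax_i = emax_typ + eta1                       # (n_sim,)
        et50_i = params.theta_et50 * np.exp(eta2)
        mean = -emax_i[:, None] * t[None, :] / (et50_i[:, None] + t[None, :])
        if params.sigma > 0:
            mean = mean + rng.normal(0.0, 1.0, size=mean.shape) * (
                params.sigma / np.sqrt(nsub)[None, :]
            )
        for j, tj in enumerate(t):
            sim_values.setdefault(float(tj), []).append(mean[:, j])
    bins = np.array(sorted(sim_values))
    p2_5 = np.empty(len(bins)); p50 = np.empty(len(bins)); p97_5 = np.empty(len(bins))
    for i, b in enumerate(bins):
        pooled = np.concatenate(sim_values[float(b)])
        p2_5[i], p50[i], p97_5[i] = np.percentile(pooled, [2.5, 50.0, 97.5])
    observed = {}
    for trial in ds.trials:
        for tj, yj in zip(trial.times, trial.changes):
            observed.setdefault(float(tj), []).append(float(yj))
    observed_arr = {k: np.asarray(v) for k, v in observed.items()}
    return VpcResult(bins, p2_5, p50, p97_5, observed_arr, n_sim)


# ---------------------------------------------------------------------------
# sampling importance resampling
# ---------------------------------------------------------------------------


@dataclass
class SirResult:
    """Resampled parameter distribution summaries (median, 95% CI)."""

    summary: pd.DataFrame       # index: parameter (natural name); columns median/lo95/hi95
    samples: np.ndarray         # resampled parameter vectors (natural scale)
    param_names: tuple[str, ...]
    ess: float
    n_proposal: int
    n_resample: int

    def band(self, name: str) -> tuple[float, float, float]:
        row = self.summary.loc[name]
        return float(row["lo95"]), float(row["median"]), float(row["hi95"])


def sir_from_surface(
    ofv_fn: Callable[[np.ndarray], float],
    center: np.ndarray,
    covariance: np.ndarray,
    param_names: Sequence[str],
    n_proposal: int = 5000,
    n_resample: int = 1000,
    inflation: float = 1.5,
    seed: int = 0,
    transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
) -> SirResult:
    """Single-iteration SIR on an arbitrary OFV surface.

    Proposal: multivariate normal at ``center`` with ``inflation *
    covariance``.  Importance weights are exp(-(OFV - OFV_min)/2) divided by
    the proposal density; ``n_resample`` draws are taken without replacement
    with probability proportional to weight.  ``transform`` maps a sampled
    vector to the reporting (natural) scale.
    """
    if n_resample > n_proposal:
        raise ValueError("n_resample must not exceed n_proposal")
    center = np.asarray(center, dtype=float)
    covariance = np.asarray(covariance, dtype=float)
    rng = np.random.default_rng(seed)
    prop_cov = inflation * covariance
    # guard tiny asymmetries from finite differencing
    prop_cov = 0.5 * (prop_cov + prop_cov.T)
    draws = rng.multivariate_normal(center, prop_cov, size=n_proposal,
                                    method="svd")
    logq = multivariate_normal(mean=center, cov=prop_cov,
                               allow_singular=True).logpdf(draws)
    ofvs = np.array([ofv_fn(x) for x in draws])
    loglik = -0.5 * (ofvs - np.min(ofvs))
    logw = loglik - logq
    logw -= np.max(logw)
    w = np.exp(logw)
    w /= np.sum(w)
    ess = float(1.0 / np.sum(w**2))
    if ess < 50:
        raise RuntimeError(
            f"degenerate importance weights (ESS = {ess:.1f} < 50); "
            "increase the proposal inflation factor or n_proposal"
        )
    idx = rng.choice(n_proposal, size=n_resample, replace=False, p=w)
    resampled = draws[idx]
    natural = np.array([transform(x) if transform else x for x in resampled])
    lo, med, hi = np.percentile(natural, [2.5, 50.0, 97.5], axis=0)
    summary = pd.DataFrame(
        {"median": med, "lo95": lo, "hi95": hi}, index=list(param_names)
    )
    return SirResult(summary, natural, tuple(param_names), ess, n_proposal,
                     n_resample)


def sir(
    fit_result: FitResult,
    ds: MetaDataset,
    n_proposal: int = 5000,
    n_resample: int = 1000,
    inflation: float = 1.5,
    seed: int = 0,
) -> SirResult:
    """SIR of the fitted model's parameter uncertainty.

    Operates on the estimation (transformed) scale, where the asymptotic
    normal proposal respects positivity of ET50, the omegas and sigma; the
    reported summaries are back-transformed to the natural scale.
    """
    if not fit_result.converged or fit_result.covariance is None:
        raise ValueError("SIR requires a converged fit with a valid covariance")
    trial_arrays = _arrays(ds)
    names = fit_result.param_names
    cov_names = [n[5:] for n in names if n.startswith("beta_")]
    centers = {n: fit_result.params.covariate_effects[n].center for n in cov_names}

    from .estimation import _ofv  # local import to keep the module surface tidy

    def ofv_fn(x: np.ndarray) -> float:
        try:
            return _ofv(_unpack(x, cov_names, centers), trial_arrays, nodes=None)
        except (ValueError, FloatingPointError):
            return 1e10

    def transform(x: np.ndarray) -> np.ndarray:
        return np.array([math.exp(v) if n.startswith("log_") else v
                         for n, v in zip(names, x)])

    natural_names = _natural_names(names)
    return sir_from_surface(
        ofv_fn, fit_result.x, fit_result.covariance, natural_names,
        n_proposal=n_proposal, n_resample=n_resample, inflation=inflation,
        seed=seed, transform=transform,
    )
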