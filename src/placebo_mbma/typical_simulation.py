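"""Typical placebo response surfaces and their Monte-Carlo confidence bands.

The *typical* response is the population-level curve (random effects at
zero).  Its uncertainty band reflects fixed-effect (parameter) uncertainty
only — inter-trial variability describes how a new trial deviates, not how
uncertain the typical value is — obtained by drawing fixed-effect vectors
from the asymptotic normal of the fit (on the estimation scale, so ET50 stays
positive) and evaluating the typical curve for each draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import FitResult
from .structural_model import CovariateEffect, ModelParameters, typical_response

__all__ = ["TypicalResponseBand", "typical_table", "typical_ci"]


@dataclass
class TypicalResponseBand:
    """Median and 95% CI of the typical response over time at one baseline."""

    baseline: float
    times: np.ndarray
    median: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    n_draws: int

    def __post_init__(self) -> None:
        if not (np.all(self.lo95 <= self.median + 1e-12)
                and np.all(self.median <= self.hi95 + 1e-12)):
            raise ValueError("band percentiles must nest: lo95 <= median <= hi95")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "baseline": self.baseline,
                "time_weeks": self.times,
                "median": self.median,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )

    def at_time(self, t: float) -> tuple[float, float, float]:
        """(lo95, median, hi95) at nominal time ``t`` (must be a band time)."""
        idx = np.where(np.isclose(self.times, t))[0]
        if len(idx) == 0:
            raise KeyError(f"time {t} not in band times {self.times.tolist()}")
        i = int(idx[0])
        return float(self.lo95[i]), float(self.median[i]), float(self.hi95[i])


def typical_table(
    params: ModelParameters,
    baselines: Sequence[float],
    times: Sequence[float],
) -> pd.DataFrame:
    """Deterministic typical-response grid: rows = baselines, columns = weeks."""
    data = {
        float(t): [typical_response(params, float(b), float(t)) for b in baselines]
        for t in times
    }
    out = pd.DataFrame(data, index=[float(b) for b in baselines])
    out.index.name = "baseline"
    out.columns.name = "time_weeks"
    return out


def _fixed_effect_draws(
    fit_result: FitResult, n_draws: int, rng: np.random.Generator
) -> list[ModelParameters]:
    """Draw fixed-effect vectors from the fit's asymptotic normal.

    Random-effect and residual components are irrelevant to the typical curve
    and are held at zero in the returned parameter sets.  When the fit carries
    no joint covariance but has per-parameter RSEs, independent normals are
    used, with ET50 drawn lognormally to preserve positivity.
    """
    names = fit_result.param_names
    fixed = fit_result.fixed_effect_names()
    idx = [names.index(n) for n in fixed]
    center = fit_result.x[idx]
    if fit_result.covariance is not None:
        cov = fit_result.covariance[np.ix_(idx, idx)]
        cov = 0.5 * (cov + cov.T)
        draws = rng.multivariate_normal(center, cov, size=n_draws, method="svd")
    elif fit_result.rse_pct:
        sds = []
        for n in fixed:
            natural = n[4:] if n.startswith("log_") else n
            r = fit_result.rse_pct.get(natural, 0.0) / 100.0
            sds.append(r if n.startswith("log_") else
                       r * abs(center[fixed.index(n)]))
        draws = center[None, :] + rng.normal(size=(n_draws, len(fixed))) * np.array(sds)
    else:
        raise ValueError("fit carries no uncertainty information (covariance or RSE)")

    cov_names = [n[5:] for n in fixed if n.startswith("beta_")]
    centers = {n: fit_result.params.covariate_effects[n].center for n in cov_names}
    out = []
    for row in draws:
        effects = {}
        for n in cov_names:
            effects[n] = CovariateEffect(float(row[fixed.index(f"beta_{n}")]),
                                         centers[n])
        out.append(
            ModelParameters(
                theta_emax=float(row[fixed.index("theta_emax")]),
                theta_et50=float(np.exp(row[fixed.index("log_theta_et50")])),
                covariate_effects=effects,
                sigma=max(fit_result.params.sigma, 1e-12),
            )
        )
    return out


def typical_ci(
    fit_result: FitResult,
    baseline: float,
    times: Sequence[float],
    n_draws: int = 10000,
    seed: int = 0,
    samples: Optional[np.ndarray] = None,
) -> TypicalResponseBand:
    """Monte-Carlo 95% CI of the typical response at one baseline.

    Default source of parameter draws is the asymptotic normal of the fit;
    passing ``samples`` (rows = transformed-scale fixed-effect vectors in the
    order of ``fit_result.fixed_effect_names()``, e.g. SIR output mapped to
    that scale) overrides it.  Percentiles reported are 2.5 / 50 / 97.5.
    """
    times_arr = np.asarray(list(times), dtype=float)
    rng = np.random.default_rng(seed)
    if samples is not None:
        names = fit_result.param_names
        fixed = fit_result.fixed_effect_names()
        take = samples[rng.integers(0, len(samples), size=n_draws)]
        curves = np.empty((n_draws, len(times_arr)))
        cov_names = [n[5:] for n in fixed if n.startswith("beta_")]
        centers = {n: fit_result.params.covariate_effects[n].center
                   for n in cov_names}
        for i, row in enumerate(take):
            effects = {n: CovariateEffect(float(row[fixed.index(f"beta_{n}")]),
                                          centers[n]) for n in cov_names}
            p = ModelParameters(
                theta_emax=float(row[fixed.index("theta_emax")]),
                theta_et50=float(np.exp(row[fixed.index("log_theta_et50")])),
                covariate_effects=effects, sigma=1e-12,
            )
            curves[i] = typical_response(p, baseline, times_arr)
    else:
        draws = _fixed_effect_draws(fit_result, n_draws, rng)
        curves = np.array([typical_response(p, baseline, times_arr) for p in draws])
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    return TypicalResponseBand(float(baseline), times_arr, med, lo, hi, n_draws)
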