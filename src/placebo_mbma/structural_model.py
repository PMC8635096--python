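"""Structural placebo-response model: Emax time-course with covariates.

The population (typical) placebo response at time ``t`` weeks is

    change(t) = -Emax * t / (ET50 + t)

where ``Emax`` (ESSDAI points, stored positive) is the asymptotic maximum
placebo response and ``ET50`` (weeks) the time to half-maximum ("onset
time").  The leading minus encodes that the placebo response is a *decrease*
in disease activity.  Trial-level heterogeneity enters through random effects:
additive on Emax and exponential (log-scale) on ET50, so ET50 stays positive.
Covariates act linearly on Emax around a fixed centring constant; the retained
model of the pooled Sjögren corpus has

    Emax = 4.44 + (baseline ESSDAI - 10.1) * 0.552.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np

from .data_io import TrialCovariates

__all__ = [
    "CovariateEffect",
    "ModelParameters",
    "TrialRandomEffects",
    "reference_parameters",
    "trial_emax",
    "trial_et50",
    "predict_change",
    "typical_response",
]


@dataclass(frozen=True)
class CovariateEffect:
    """A linear covariate term on a structural parameter.

    Contribution to the parameter is ``coefficient * (value - center)``; the
    centring constant is stored with the model (not recomputed from data) so
    fitted models are portable across datasets.
    """

    coefficient: float
    center: float


@dataclass(frozen=True)
class ModelParameters:
    """Fixed effects, inter-trial SDs and residual SD of the model.

    ``theta_emax`` is the typical maximum placebo response (ESSDAI points) at
    the covariate reference point; ``theta_et50`` the typical onset half-time
    in weeks.  ``omega_emax`` is the SD of the additive trial-level effect on
    Emax (points); ``omega_et50`` the SD of the log-scale effect on ET50.
    ``sigma`` is the residual SD of an arm-level observation before the
    1/sqrt(N) sample-size scaling.
    """

    theta_emax: float
    theta_et50: float
    covariate_effects: Mapping[str, CovariateEffect] = field(default_factory=dict)
    omega_emax: float = 0.0
    omega_et50: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if not (self.theta_et50 > 0):
            raise ValueError(f"theta_et50 must be > 0, got {self.theta_et50}")
        if self.omega_emax < 0 or self.omega_et50 < 0:
            raise ValueError("omega_emax and omega_et50 must be >= 0")
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")
        object.__setattr__(
            self,
            "covariate_effects",
            {
                k: v if isinstance(v, CovariateEffect) else CovariateEffect(*v)
                for k, v in dict(self.covariate_effects).items()
            },
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "theta_emax": self.theta_emax,
            "theta_et50": self.theta_et50,
            "covariate_effects": {
                name: {"coefficient": e.coefficient, "center": e.center}
                for name, e in self.covariate_effects.items()
            },
            "omega_emax": self.omega_emax,
            "omega_et50": self.omega_et50,
            "sigma": self.sigma,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelParameters":
        effects = {
            name: CovariateEffect(e["coefficient"], e["center"])
            for name, e in d.get("covariate_effects", {}).items()
        }
        return cls(
            theta_emax=float(d["theta_emax"]),
            theta_et50=float(d["theta_et50"]),
            covariate_effects=effects,
            omega_emax=float(d.get("omega_emax", 0.0)),
            omega_et50=float(d.get("omega_et50", 0.0)),
            sigma=float(d.get("sigma", 1.0)),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "ModelParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class TrialRandomEffects:
    """Trial-level random effects: additive on Emax, log-scale on ET50."""

    eta_emax: float = 0.0
    eta_et50: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.eta_emax) and np.isfinite(self.eta_et50)):
            raise ValueError("random effects must be finite")


def reference_parameters() -> ModelParameters:
    """Final pooled-model estimates for the 13-trial Sjögren placebo corpus.

    Emax 4.44 points at the reference baseline ESSDAI of 10.1 with a baseline
    coefficient of 0.552 points per point, ET50 12.2 weeks, inter-trial SDs
    0.563 (Emax, additive) and 0.794 (log ET50), residual SD 1.661 points.
    """
    return ModelParameters(
        theta_emax=4.44,
        theta_et50=12.2,
        covariate_effects={"baseline_essdai": CovariateEffect(0.552, 10.1)},
        omega_emax=0.563,
        omega_et50=0.794,
        sigma=1.661,
    )


CovariateSource = Union[TrialCovariates, Mapping[str, Optional[float]]]


def _covariate_value(cov: CovariateSource, name: str) -> Optional[float]:
    if isinstance(cov, TrialCovariates):
        return cov.get(name)
    return cov.get(name)


def trial_emax(params: ModelParameters, cov: CovariateSource, eta_emax: float = 0.0) -> float:
    """Trial-level Emax: fixed effect + covariate contributions + additive eta.

    Not clamped at zero: the covariate model is linear, so very low baselines
    can legitimately produce a (near-)zero or negative trial Emax.
    """
    value = params.theta_emax
    for name, effect in params.covariate_effects.items():
        x = _covariate_value(cov, name)
        if x is None:
            raise ValueError(f"covariate {name!r} required by the model is missing")
        value += effect.coefficient * (x - effect.center)
    return value + eta_emax


def trial_et50(params: ModelParameters, eta_et50: float = 0.0) -> float:
    """Trial-level ET50 = theta_et50 * exp(eta); strictly positive."""
    return params.theta_et50 * float(np.exp(eta_et50))


def predict_change(
    params: ModelParameters,
    cov: CovariateSource,
    etas: TrialRandomEffects,
    time: float | np.ndarray,
):
    """Deterministic trial-level ESSDAI change from baseline at ``time`` weeks.

    Returns ``-Emax_i * t / (ET50_i + t)``: zero at t = 0, monotone towards
    the asymptote ``-Emax_i``.
    """
    t = np.asarray(time, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    emax_i = trial_emax(params, cov, etas.eta_emax)
    et50_i = trial_et50(params, etas.eta_et50)
    out = -emax_i * t / (et50_i + t)
    return float(out) if np.isscalar(time) else out


def typical_response(
    params: ModelParameters, baseline: float, time: float | np.ndarray
):
    """Population-level (typical) placebo response at a given baseline ESSDAI.

    All random effects are zero and only the baseline covariate is set; any
    other covariate effect in the model is evaluated at its centring constant
    and therefore contributes nothing.
    """
    cov = {name: effect.center for name, effect in params.covariate_effects.items()}
    cov["baseline_essdai"] = baseline
    return predict_change(params, cov, TrialRandomEffects(), time)
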