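"""Virtual placebo control for single-arm trials.

A single-arm drug trial has no concurrent placebo group.  The fitted placebo
response model supplies one: the 95% CI band of the typical placebo response
at the trial's own baseline ESSDAI is simulated over the trial's visit weeks,
and each observed mean change is classified against that band.  A point
falling *below* the lower band edge shows more improvement than the placebo
model allows and drives the efficacy verdict; a point above the upper edge
(less improvement than placebo) is flagged separately as possible harm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path


import numpy as np
import pandas as pd

from .estimation import FitResult
from .typical_simulation import TypicalResponseBand, typical_ci

__all__ = [
    "SingleArmObservation",
    "SingleArmTrial",
    "SingleArmComparison",
    "read_single_arm_trial",
    "write_single_arm_trial",
    "compare_single_arm",
]


@dataclass(frozen=True)
class SingleArmObservation:
    time_weeks: float
    change_essdai: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("standard error must be >= 0")


@dataclass(frozen=True)
class SingleArmTrial:
    """An external drug arm: label, baseline, and mean-change observations."""

    label: str
    baseline_essdai: float
    observations: tuple[SingleArmObservation, ...]
    n_subjects: int

    def __post_init__(self) -> None:
        times = [o.time_weeks for o in self.observations]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("observation times must be strictly increasing")
        if len(self.observations) == 0:
            raise ValueError("a single-arm trial needs at least one observation")

    @property
    def times(self) -> np.ndarray:
        return np.array([o.time_weeks for o in self.observations])


@dataclass
class SingleArmComparison:
    """Per-observation band placement and the overall efficacy verdict.

    ``verdict`` is ``"exceeds-placebo"`` iff at least one observed mean falls
    below the band's lower edge (greater improvement than the virtual placebo
    control); otherwise ``"comparable-to-placebo"``.  Points above the upper
    edge set ``possible_harm`` without affecting the efficacy verdict.
    """

    trial: SingleArmTrial
    band: TypicalResponseBand
    inside_band: tuple[bool, ...]
    below_band: tuple[bool, ...]
    above_band: tuple[bool, ...]
    verdict: str
    possible_harm: bool

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for o, ins, below, above in zip(self.trial.observations, self.inside_band,
                                        self.below_band, self.above_band):
            lo, med, hi = self.band.at_time(o.time_weeks)
            rows.append({
                "label": self.trial.label,
                "time_weeks": o.time_weeks,
                "obs_change": o.change_essdai,
                "obs_se": o.se,
                "lo95": lo, "median": med, "hi95": hi,
                "inside_band": ins, "below_band": below, "above_band": above,
            })
        return pd.DataFrame(rows)


def read_single_arm_trial(path: str | Path) -> SingleArmTrial:
    """Read a single-arm trial file: ``# key: value`` metadata lines (label,
    baseline_essdai, n_subjects) followed by a time_weeks,change_essdai,se CSV."""
    path = Path(path)
    meta: dict[str, str] = {}
    data_lines = []
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            key, _, value = line.lstrip("#").partition(":")
            meta[key.strip()] = value.strip()
        elif line.strip():
            data_lines.append(line)
    for key in ("label", "baseline_essdai", "n_subjects"):
        if key not in meta:
            raise ValueError(f"missing metadata line '# {key}: ...' in {path}")
    from io import StringIO

    df = pd.read_csv(StringIO("\n".join(data_lines)))
    for col in ("time_weeks", "change_essdai"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r} in {path}")
    if "se" not in df.columns:
        df["se"] = 0.0
    obs = tuple(
        SingleArmObservation(float(r.time_weeks), float(r.change_essdai),
                             float(r.se) if np.isfinite(r.se) else 0.0)
        for r in df.sort_values("time_weeks").itertuples()
    )
    return SingleArmTrial(meta["label"], float(meta["baseline_essdai"]), obs,
                          int(meta["n_subjects"]))


def write_single_arm_trial(trial: SingleArmTrial, path: str | Path) -> Path:
    path = Path(path)
    lines = [
        f"# label: {trial.label}",
        f"# baseline_essdai: {trial.baseline_essdai!r}",
        f"# n_subjects: {trial.n_subjects}",
        "time_weeks,change_essdai,se",
    ]
    lines += [f"{o.time_weeks!r},{o.change_essdai!r},{o.se!r}"
              for o in trial.observations]
    path.write_text("\n".join(lines) + "\n")
    return path


def compare_single_arm(
    fit_result: FitResult,
    trial: SingleArmTrial,
    n_draws: int = 10000,
    seed: int = 0,
    include_trial_variability: bool = False,
) -> SingleArmComparison:
    """Evaluate a single-arm trial against the virtual placebo control.

    The band is the typical-response 95% CI (parameter uncertainty) at the
    trial's baseline over the trial's visit weeks.  Observed means are
    compared as point estimates; their SEs are carried for display only.
    ``include_trial_variability=True`` additionally draws trial-level random
    effects, widening the band into a new-trial prediction band (clearly a
    different, more permissive comparison; off by default).
    """
    band = typical_ci(fit_result, trial.baseline_essdai,
                      [o.time_weeks for o in trial.observations],
                      n_draws=n_draws, seed=seed)
    if include_trial_variability:
        band = _prediction_band(fit_result, trial, n_draws, seed)
    below, inside, above = [], [], []
    for o in trial.observations:
        lo, _, hi = band.at_time(o.time_weeks)
        below.append(o.change_essdai < lo)
        above.append(o.change_essdai > hi)
        inside.append(lo <= o.change_essdai <= hi)
    verdict = "exceeds-placebo" if any(below) else "comparable-to-placebo"
    return SingleArmComparison(
        trial=trial, band=band,
        inside_band=tuple(inside), below_band=tuple(below),
        above_band=tuple(above), verdict=verdict, possible_harm=any(above),
    )


def _prediction_band(fit_result: FitResult, trial: SingleArmTrial,
                     n_draws: int, seed: int) -> TypicalResponseBand:
    """New-trial prediction band: fixed-effect draws plus eta draws."""
    from .structural_model import TrialRandomEffects, predict_change
    from .typical_simulation import _fixed_effect_draws

    rng = np.random.default_rng(seed)
    times = trial.times.astype(float)
    params_draws = _fixed_effect_draws(fit_result, n_draws, rng)
    om1 = fit_result.params.omega_emax
    om2 = fit_result.params.omega_et50
    curves = np.empty((n_draws, len(times)))
    cov = {"baseline_essdai": trial.baseline_essdai}
    for i, p in enumerate(params_draws):
        etas = TrialRandomEffects(
            float(rng.normal(0.0, om1)) if om1 > 0 else 0.0,
            float(rng.normal(0.0, om2)) if om2 > 0 else 0.0,
        )
        full_cov = {name: e.center for name, e in p.covariate_effects.items()}
        full_cov.update(cov)
        curves[i] = predict_change(p, full_cov, etas, times)
    lo, med, hi = np.percentile(curves, [2.5, 50.0, 97.5], axis=0)
    return TypicalResponseBand(trial.baseline_essdai, times, med, lo, hi, n_draws)
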