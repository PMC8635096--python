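"""Covariate screening and stepwise selection on the objective function value.

Covariate effects are judged by the likelihood-ratio drop in OFV against
chi-square(1) cutoffs: a univariate screen and forward inclusion use
delta-OFV > 3.84 (P < 0.05), backward elimination retains a covariate only if
its removal would raise the OFV by at least 6.63 (P < 0.01).  Ties in forward
selection are broken by candidate listing order, and a candidate whose fit
fails to converge counts as delta-OFV = 0 (conservative), so the search always
terminates deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .data_io import MetaDataset
from .estimation import FitConfig, FitResult, covariate_center, fit
from .structural_model import CovariateEffect

__all__ = [
    "FORWARD_CUT",
    "BACKWARD_CUT",
    "CovariateCandidate",
    "StepRecord",
    "StepLog",
    "screen_univariate",
    "forward_backward",
]

logger = logging.getLogger(__name__)

#: delta-OFV cutoff for the univariate screen and forward inclusion (P < 0.05).
FORWARD_CUT = 3.84
#: delta-OFV cutoff for backward elimination (P < 0.01).
BACKWARD_CUT = 6.63


@dataclass(frozen=True)
class CovariateCandidate:
    """A covariate-parameter pairing to test.

    Only linear-centred effects on Emax are searched by default (the covariate
    finding of the pooled model concerns Emax); effects on ET50 are accepted
    but must be requested explicitly.
    """

    name: str
    target: str = "emax"
    form: str = "linear"

    def __post_init__(self) -> None:
        if self.target not in ("emax", "et50"):
            raise ValueError(f"target must be 'emax' or 'et50', got {self.target!r}")
        if self.form != "linear":
            raise ValueError("only the linear-centred form is implemented")


@dataclass(frozen=True)
class StepRecord:
    step: str  # univariate | forward | backward
    candidate: str
    ofv_before: float
    ofv_after: float
    decision: str

    @property
    def delta_ofv(self) -> float:
        return self.ofv_before - self.ofv_after


@dataclass
class StepLog:
    """Ordered record of every fit in the covariate search; replays the search."""

    records: list[StepRecord] = field(default_factory=list)

    def append(self, record: StepRecord) -> None:
        self.records.append(record)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "step": r.step,
                    "candidate": r.candidate,
                    "ofv_before": r.ofv_before,
                    "ofv_after": r.ofv_after,
                    "delta_ofv": r.delta_ofv,
                    "decision": r.decision,
                }
                for r in self.records
            ],
            columns=["step", "candidate", "ofv_before", "ofv_after", "delta_ofv",
                     "decision"],
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def _candidates(cands: Sequence) -> list[CovariateCandidate]:
    return [c if isinstance(c, CovariateCandidate) else CovariateCandidate(str(c))
            for c in cands]


def _quiet(config: FitConfig) -> FitConfig:
    return replace(config, compute_covariance=False)


def _warm_config(config: FitConfig, reference: FitResult, ds: MetaDataset,
                 cov_names: Sequence[str]) -> FitConfig:
    """Quiet config warm-started from a reference fit's estimates.

    The initial values carry the reference model's parameters with any new
    covariate entering at coefficient zero (centred per corpus convention)
    and any removed covariate dropped.  Starting nested fits from the current
    optimum keeps the search's delta-OFVs non-negative up to optimizer
    wobble, which a cold start cannot guarantee on a multimodal surface.
    """
    from dataclasses import replace as dc_replace

    effects = {}
    for name in cov_names:
        if name in reference.params.covariate_effects:
            effects[name] = reference.params.covariate_effects[name]
        else:
            effects[name] = CovariateEffect(0.0, covariate_center(ds, name))
    initial = dc_replace(reference.params, covariate_effects=effects)
    return replace(config, compute_covariance=False, initial=initial)


def _fit_nested(ds: MetaDataset, names: Sequence[str], config: FitConfig,
                reference: FitResult) -> FitResult:
    """Fit a nested model from both the warm (reference) and cold starts.

    The warm start guarantees the nested delta-OFV structure; the cold start
    keeps the exploration a cold-started search would have.  The better
    converged optimum wins.
    """
    warm = fit(ds, list(names), _warm_config(config, reference, ds, list(names)))
    cold = fit(ds, list(names), _quiet(config))
    converged = [f for f in (warm, cold) if f.converged]
    if not converged:
        return warm
    return min(converged, key=lambda f: f.ofv)


def _delta(base: FitResult, candidate_fit: FitResult, name: str) -> float:
    if not candidate_fit.converged:
        logger.warning("candidate %s: fit did not converge; treated as delta-OFV 0",
                       name)
        return 0.0
    return base.ofv - candidate_fit.ofv


def screen_univariate(
    ds: MetaDataset,
    base_config: Optional[FitConfig] = None,
    candidates: Sequence = (),
) -> tuple[StepLog, FitResult]:
    """Test each candidate alone against the covariate-free base model.

    A candidate is significant iff adding it drops the OFV by more than 3.84.
    Returns the log of every fit and the base-model fit.
    """
    config = base_config or FitConfig()
    cands = _candidates(candidates)
    base = fit(ds, (), _quiet(config))
    if not base.converged:
        raise RuntimeError("base model did not converge; cannot screen covariates")
    log = StepLog()
    for cand in cands:
        cand_fit = _fit_nested(ds, [cand.name], config, base)
        delta = _delta(base, cand_fit, cand.name)
        log.append(
            StepRecord(
                "univariate", cand.name, base.ofv,
                cand_fit.ofv if cand_fit.converged else base.ofv,
                "significant" if delta > FORWARD_CUT else "not significant",
            )
        )
    return log, base


def forward_backward(
    ds: MetaDataset,
    candidates: Sequence,
    config: Optional[FitConfig] = None,
    forward_cut: float = FORWARD_CUT,
    backward_cut: float = BACKWARD_CUT,
) -> tuple[list[str], StepLog, FitResult]:
    """Forward-inclusion / backward-elimination search over the candidates.

    Forward: repeatedly add the candidate with the largest delta-OFV among
    those exceeding ``forward_cut`` (ties broken by listing order).  Backward:
    repeatedly remove the included covariate whose removal raises the OFV
    least, while that rise is below ``backward_cut``.  Returns the surviving
    covariate names, the full step log, and the final fit.
    """
    config = config or FitConfig()
    cands = _candidates(candidates)
    log = StepLog()
    current: list[str] = []
    current_fit = fit(ds, current, _quiet(config))
    if not current_fit.converged:
        raise RuntimeError("base model did not converge; cannot run the search")

    remaining = [c.name for c in cands]
    while remaining:
        deltas = []
        fits = []
        for name in remaining:
            cand_fit = _fit_nested(ds, current + [name], config, current_fit)
            fits.append(cand_fit)
            deltas.append(_delta(current_fit, cand_fit, name))
        best_i = max(range(len(remaining)), key=lambda i: (deltas[i], -i))
        for i, name in enumerate(remaining):
            if i == best_i:
                continue
            log.append(StepRecord("forward", name, current_fit.ofv,
                                  fits[i].ofv if fits[i].converged else current_fit.ofv,
                                  "not added"))
        name = remaining[best_i]
        if deltas[best_i] > forward_cut:
            log.append(StepRecord("forward", name, current_fit.ofv,
                                  fits[best_i].ofv, "added"))
            current.append(name)
            current_fit = fits[best_i]
            remaining.pop(best_i)
        else:
            log.append(StepRecord("forward", name, current_fit.ofv,
                                  fits[best_i].ofv if fits[best_i].converged
                                  else current_fit.ofv,
                                  "not added"))
            break

    while current:
        rises = []
        fits = []
        for name in current:
            reduced = [n for n in current if n != name]
            red_fit = _fit_nested(ds, reduced, config, current_fit)
            fits.append(red_fit)
            rises.append(red_fit.ofv - current_fit.ofv if red_fit.converged
                         else float("inf"))
        worst_i = min(range(len(current)), key=lambda i: (rises[i], i))
        name = current[worst_i]
        if rises[worst_i] < backward_cut:
            log.append(StepRecord("backward", name, current_fit.ofv,
                                  fits[worst_i].ofv, "removed"))
            current.pop(worst_i)
            current_fit = fits[worst_i]
        else:
            log.append(StepRecord("backward", name, current_fit.ofv,
                                  fits[worst_i].ofv, "retained"))
            break

    final_fit = fit(ds, current, config) if config.compute_covariance else current_fit
    return current, log, final_fit
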