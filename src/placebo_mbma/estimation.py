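"""Marginal maximum-likelihood estimation of the nonlinear mixed-effects model.

Each trial contributes a 2-D integral over its random effects (additive on
Emax, exponential on ET50) of a Gaussian likelihood whose residual variance is
``sigma^2 / N`` per observation.  The integral is approximated by a Laplace
expansion at the per-trial mode of the joint log-density — the behaviour of
conditional-estimation (FOCE-type) algorithms for this model class — with an
adaptive Gauss-Hermite quadrature routine as the brute-force oracle: one-node
adaptive quadrature *is* the Laplace approximation, and increasing the node
count arbitrates its accuracy.

The objective function value (OFV) is -2 times the approximate log marginal
likelihood with the ``n * log(2*pi)`` constant dropped; only OFV differences
enter any decision (chi-square cutoffs 3.84 / 6.63), so the constant
convention is immaterial but fixed here for reproducibility.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize

from .data_io import MetaDataset, Trial, TrialCovariates, FRACTION_COVARIATES
from .structural_model import (
    CovariateEffect,
    ModelParameters,
    TrialRandomEffects,
    trial_emax,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "ofv_laplace",
    "ofv_quadrature",
    "fit",
    "empirical_bayes",
    "fit_result_from_estimates",
]

logger = logging.getLogger(__name__)

_PENALTY_OFV = 1e10  # returned when the density is non-finite at a parameter point

# transformed-scale box constraints, generous enough never to bind in practice
_BOUNDS = {
    "theta_emax": (-60.0, 60.0),
    "log_theta_et50": (math.log(0.1), math.log(300.0)),
    "log_omega_emax": (math.log(1e-4), math.log(30.0)),
    "log_omega_et50": (math.log(1e-4), math.log(30.0)),
    "log_sigma": (math.log(1e-4), math.log(30.0)),
}
_BETA_BOUND = (-20.0, 20.0)


# ---------------------------------------------------------------------------
# per-trial working arrays and the joint (y, eta) log-density
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _TrialArrays:
    trial_id: str
    t: np.ndarray
    y: np.ndarray
    n: np.ndarray
    cov: TrialCovariates
    # observation triples as plain floats: the inner Newton loop runs orders
    # of magnitude more often than anything else, and scalar arithmetic beats
    # numpy dispatch overhead at 1-5 observations per trial
    obs: tuple[tuple[float, float, float], ...] = ()

    @classmethod
    def from_trial(cls, tr: Trial) -> "_TrialArrays":
        return cls(tr.trial_id, tr.times, tr.changes, tr.n_subjects,
                   tr.covariates,
                   tuple(zip(map(float, tr.times), map(float, tr.changes),
                             map(float, tr.n_subjects))))


def _arrays(ds: MetaDataset) -> list[_TrialArrays]:
    return [_TrialArrays.from_trial(tr) for tr in ds.trials]


def _h_grad_hess(
    params: ModelParameters,
    ta: _TrialArrays,
    eta: np.ndarray,
    active: Sequence[int],
    emax_typ: float,
):
    """Negative joint log-density h (up to constants), gradient and exact
    Hessian over the *active* random-effect dimensions.

    h(eta) = 0.5 * sum_j w_j (y_j - f_j)^2 + 0.5 * sum_k eta_k^2 / omega_k^2
    with w_j = N_j / sigma^2.
    """
    e1, e2 = float(eta[0]), float(eta[1])
    em = emax_typ + e1
    # clamp the log-scale effect: |eta2| > 60 only occurs in rejected
    # line-search candidates, and exp would overflow further out
    et50 = params.theta_et50 * math.exp(min(max(e2, -60.0), 60.0))
    inv_s2 = 1.0 / (params.sigma * params.sigma)
    # scalar accumulation: overflow at extreme line-search candidates yields
    # inf/nan, which the caller's line search rejects
    h = g0 = g1 = 0.0
    G00 = G01 = G11 = 0.0
    H01 = H11 = 0.0
    for t, y, n in ta.obs:
        d = et50 + t
        f = -em * t / d
        r = y - f
        w = n * inv_s2
        wr = w * r
        h += 0.5 * wr * r
        f1 = -t / d
        f2 = em * t * et50 / (d * d)
        g0 -= wr * f1
        g1 -= wr * f2
        f12 = t * et50 / (d * d)
        f22 = em * f12 * (d - 2.0 * et50) / d
        G00 += w * f1 * f1
        G01 += w * f1 * f2
        G11 += w * f2 * f2
        H01 -= wr * f12
        H11 -= wr * f22

    # exact Hessian of h, and its Gauss-Newton part (drops the
    # residual-weighted curvature term; always positive semidefinite)
    g = np.array([g0, g1])
    G = np.array([[G00, G01], [G01, G11]])
    H = np.array([[G00, G01 + H01], [G01 + H01, G11 + H11]])

    omegas = (params.omega_emax, params.omega_et50)
    for k in active:
        inv = 1.0 / omegas[k] ** 2
        h += 0.5 * eta[k] ** 2 * inv
        g[k] += eta[k] * inv
        H[k, k] += inv
        G[k, k] += inv

    if not math.isfinite(h):
        h = np.inf
    if len(active) == 2:
        return h, g, H, G
    idx = np.asarray(active, dtype=int)
    return h, g[idx], H[np.ix_(idx, idx)], G[np.ix_(idx, idx)]


def _eta_mode(
    params: ModelParameters,
    ta: _TrialArrays,
    active: Sequence[int],
    emax_typ: float,
    x0: Optional[np.ndarray] = None,
    tol: float = 1e-8,
    max_iter: int = 100,
):
    """Damped-Newton search for the per-trial posterior mode of eta.

    Returns (eta_full, h, H_active, ok): the mode embedded in the full 2-vector,
    the value of h there, the exact Hessian over active dimensions, and a
    convergence flag.
    """
    starts: list[np.ndarray] = [np.zeros(len(active))]
    if x0 is not None and np.any(x0 != 0.0):
        starts.insert(0, np.asarray(x0, dtype=float))
    best: Optional[tuple] = None
    for s in starts:
        cand = _newton_descent(params, ta, active, emax_typ, s, tol, max_iter)
        if best is None or cand[1] < best[1]:
            best = cand
        if best[3]:  # converged from the warm start: skip the zero restart
            break
    assert best is not None
    return best


def _newton_descent(
    params: ModelParameters,
    ta: _TrialArrays,
    active: Sequence[int],
    emax_typ: float,
    start: np.ndarray,
    tol: float,
    max_iter: int,
):
    d = len(active)
    eta = np.zeros(2)
    for j, k in enumerate(active):
        eta[k] = start[j]
    h, g, H, G = _h_grad_hess(params, ta, eta, active, emax_typ)
    for _ in range(max_iter):
        if _norm(g) < tol:
            break
        # exact-Hessian Newton step when positive definite (quadratic
        # convergence); otherwise the Gauss-Newton surrogate, which is PSD
        # and therefore always yields a descent direction
        step = _solve_pd(H, g)
        if step is None or _dot(step, g) <= 0:
            lam = 0.0
            step = _solve_pd(G, g)
            trace = abs(G[0, 0]) + (abs(G[1, 1]) if d == 2 else 0.0)
            while step is None or _dot(step, g) <= 0:
                lam = max(2.0 * lam, 1e-6 * (1.0 + trace / d))
                if lam > 1e12 * (1.0 + trace):
                    step = None
                    break
                step = _solve_pd(G + lam * np.eye(d), g)
            if step is None:
                break
        alpha = 1.0
        improved = False
        for _ in range(40):
            cand = eta.copy()
            for j, k in enumerate(active):
                cand[k] = eta[k] - alpha * step[j]
            h_new, g_new, H_new, G_new = _h_grad_hess(
                params, ta, cand, active, emax_typ
            )
            if h_new <= h - 1e-14:
                eta, h, g, H, G = cand, h_new, g_new, H_new, G_new
                improved = True
                break
            alpha *= 0.5
        if not improved:
            break  # no further progress: current point is the mode numerically
    ok = bool(_norm(g) < max(100.0 * tol, 1e-5))
    # Laplace needs a positive definite curvature at the mode: use the exact
    # Hessian when it qualifies, else the Gauss-Newton surrogate
    H_use = H if _is_pd(H) else G
    return eta, h, H_use, ok


def _norm(g: np.ndarray) -> float:
    return math.sqrt(float(np.dot(g, g)))


def _dot(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.dot(a, b))


def _is_pd(A: np.ndarray) -> bool:
    if A.shape[0] == 1:
        return A[0, 0] > 0
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    return A[0, 0] > 0 and det > 0


def _solve_pd(A: np.ndarray, b: np.ndarray) -> Optional[np.ndarray]:
    """Closed-form solve of a 1x1 or 2x2 SPD system; None if not PD."""
    if not np.all(np.isfinite(A)):
        return None
    if A.shape[0] == 1:
        return np.array([b[0] / A[0, 0]]) if A[0, 0] > 0 else None
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if A[0, 0] <= 0 or det <= 0:
        return None
    return np.array([
        (A[1, 1] * b[0] - A[0, 1] * b[1]) / det,
        (A[0, 0] * b[1] - A[1, 0] * b[0]) / det,
    ])


def _closed_form_contrib(params: ModelParameters, ta: _TrialArrays, emax_typ: float) -> float:
    """OFV contribution when both omegas are zero: weighted LS deviance."""
    t = ta.t
    f = -emax_typ * t / (params.theta_et50 + t)
    r = ta.y - f
    w = ta.n / params.sigma**2
    return float(np.dot(w * r, r) + np.sum(np.log(params.sigma**2 / ta.n)))


def _active_dims(params: ModelParameters) -> list[int]:
    active = []
    if params.omega_emax > 0:
        active.append(0)
    if params.omega_et50 > 0:
        active.append(1)
    return active


def _check_params(params: ModelParameters) -> None:
    if params.sigma <= 0:
        raise ValueError("sigma must be > 0 for likelihood evaluation")


def _ofv(
    params: ModelParameters,
    trial_arrays: Sequence[_TrialArrays],
    nodes: Optional[int],
    inner_tol: float = 1e-8,
) -> float:
    """Shared OFV kernel: Laplace when ``nodes`` is None, adaptive GH otherwise."""
    _check_params(params)
    active = _active_dims(params)
    d = len(active)
    omegas = (params.omega_emax, params.omega_et50)
    total = 0.0
    if nodes is not None:
        z1, w1 = hermgauss(nodes)
    with np.errstate(over="ignore", invalid="ignore"):
        for ta in trial_arrays:
            emax_typ = trial_emax(params, ta.cov, 0.0)
            const = float(np.sum(np.log(params.sigma**2 / ta.n)))
            if d == 0:
                total += _closed_form_contrib(params, ta, emax_typ)
                continue
            eta_hat, h_hat, H, ok = _eta_mode(params, ta, active, emax_typ,
                                              tol=inner_tol)
            sign, logdetH = np.linalg.slogdet(H)
            if sign <= 0 or not np.isfinite(h_hat):
                logger.warning(
                    "non-finite or non-concave joint density for trial %s; "
                    "penalty OFV", ta.trial_id,
                )
                return _PENALTY_OFV
            if not ok:
                # stalled inner search: the descent property still guarantees
                # a usable point; penalizing here would put cliffs in the
                # outer objective
                logger.debug("inner mode search stalled for trial %s",
                             ta.trial_id)
            prior_logdet = sum(2.0 * math.log(omegas[k]) for k in active)
            if nodes is None:
                total += 2.0 * h_hat + const + prior_logdet + logdetH
                continue
            # adaptive GH centred at the mode, scaled by the mode Hessian
            C = np.linalg.cholesky(H)
            log_det_L = -float(np.sum(np.log(np.diag(C))))  # L = C^{-T}, LL' = H^{-1}
            grids = np.meshgrid(*([z1] * d), indexing="ij")
            Z = np.stack([gz.ravel() for gz in grids], axis=1)  # (nodes^d, d)
            wgrids = np.meshgrid(*([np.log(w1)] * d), indexing="ij")
            Wlog = np.sum([gw.ravel() for gw in wgrids], axis=0)
            Linv_t = np.linalg.solve(C.T, np.sqrt(2.0) * Z.T)  # eta offsets, (d, K)
            logs = np.empty(len(Z))
            for k_idx in range(len(Z)):
                eta_k = eta_hat.copy()
                for j, kdim in enumerate(active):
                    eta_k[kdim] = eta_hat[kdim] + Linv_t[j, k_idx]
                h_k = _h_grad_hess(params, ta, eta_k, active, emax_typ)[0]
                logs[k_idx] = Wlog[k_idx] + float(np.dot(Z[k_idx], Z[k_idx])) - h_k
            m = np.max(logs)
            log_integral = (0.5 * d * math.log(2.0) + log_det_L + m
                            + math.log(np.sum(np.exp(logs - m))))
            total += (d * math.log(2.0 * math.pi) + const + prior_logdet
                      - 2.0 * log_integral)
    return total


def ofv_laplace(params: ModelParameters, ds: MetaDataset) -> float:
    """-2 log marginal likelihood by the Laplace approximation (constant-free).

    With both inter-trial SDs zero this reduces exactly to the closed-form
    weighted least-squares deviance
    ``sum_ij [ (y-pred)^2 * N / sigma^2 + log(sigma^2/N) ]``.
    """
    return _ofv(params, _arrays(ds), nodes=None)


def ofv_quadrature(params: ModelParameters, ds: MetaDataset, nodes: int = 21) -> float:
    """-2 log marginal likelihood by adaptive Gauss-Hermite quadrature.

    ``nodes=1`` reproduces :func:`ofv_laplace` exactly (same mode, same
    Hessian scaling); larger node counts serve as the accuracy oracle.
    """
    if nodes < 1:
        raise ValueError("nodes must be >= 1")
    return _ofv(params, _arrays(ds), nodes=nodes)


def empirical_bayes(params: ModelParameters, trial: Trial) -> TrialRandomEffects:
    """Posterior mode of the trial-level random effects at fixed parameters.

    Dimensions whose omega is zero are pinned at zero (full shrinkage).  If
    the inner optimizer fails the zero vector is returned with a warning.
    """
    _check_params(params)
    active = _active_dims(params)
    if not active:
        return TrialRandomEffects(0.0, 0.0)
    ta = _TrialArrays.from_trial(trial)
    emax_typ = trial_emax(params, ta.cov, 0.0)
    with np.errstate(over="ignore", invalid="ignore"):
        eta, _, _, ok = _eta_mode(params, ta, active, emax_typ)
    if not ok:
        logger.warning("EBE optimization failed for trial %s; returning zeros",
                       trial.trial_id)
        return TrialRandomEffects(0.0, 0.0)
    return TrialRandomEffects(float(eta[0]), float(eta[1]))


# ---------------------------------------------------------------------------
# outer maximum-likelihood fit
# ---------------------------------------------------------------------------


@dataclass
class FitConfig:
    """Settings for the outer ML optimization.

    ``approximation`` selects the marginal-likelihood approximation used as
    the fitting objective; quadrature is slower and exists mainly as an
    oracle.  ``n_starts > 1`` adds perturbed restarts of the initial values
    (seeded) and keeps the best optimum.
    """

    initial: Optional[ModelParameters] = None
    approximation: str = "laplace"  # "laplace" | "quadrature"
    nodes: int = 9
    maxiter: int = 500
    outer_tol: float = 1e-6
    inner_tol: float = 1e-8
    n_starts: int = 1
    seed: int = 0
    compute_covariance: bool = True

    def __post_init__(self) -> None:
        if self.approximation not in ("laplace", "quadrature"):
            raise ValueError(f"unknown approximation {self.approximation!r}")
        if self.outer_tol <= 0 or self.inner_tol <= 0:
            raise ValueError("tolerances must be > 0")
        if self.nodes < 1:
            raise ValueError("nodes must be >= 1")


@dataclass
class FitResult:
    """Estimates, OFV, uncertainty and per-trial empirical Bayes effects."""

    params: ModelParameters
    ofv: float
    param_names: tuple[str, ...]  # transformed-scale names
    x: np.ndarray  # transformed-scale optimum
    covariance: Optional[np.ndarray]  # transformed scale
    se: dict[str, float]  # natural scale
    rse_pct: dict[str, float]
    ebes: dict[str, TrialRandomEffects]
    converged: bool
    n_obs: int
    n_trials: int
    message: str = ""

    @property
    def estimates(self) -> dict[str, float]:
        out = {
            "theta_emax": self.params.theta_emax,
            "theta_et50": self.params.theta_et50,
        }
        for name, eff in self.params.covariate_effects.items():
            out[f"beta_{name}"] = eff.coefficient
        out["omega_emax"] = self.params.omega_emax
        out["omega_et50"] = self.params.omega_et50
        out["sigma"] = self.params.sigma
        return out

    def summary(self) -> str:
        """Human-readable parameter table (Parameter, Value, RSE%)."""
        lines = [f"{'Parameter':<22}{'Value':>10}{'RSE (%)':>10}"]
        for name, value in self.estimates.items():
            rse = self.rse_pct.get(name)
            rse_s = f"{rse:10.1f}" if rse is not None and np.isfinite(rse) else f"{'-':>10}"
            lines.append(f"{name:<22}{value:10.3g}{rse_s}")
        lines.append(f"OFV: {self.ofv:.3f}   converged: {self.converged}   "
                     f"trials: {self.n_trials}   observations: {self.n_obs}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "ofv": self.ofv,
            "param_names": list(self.param_names),
            "x": [float(v) for v in self.x],
            "covariance": None if self.covariance is None
            else [[float(v) for v in row] for row in self.covariance],
            "se": self.se,
            "rse_pct": self.rse_pct,
            "ebes": {k: {"eta_emax": v.eta_emax, "eta_et50": v.eta_et50}
                     for k, v in self.ebes.items()},
            "converged": self.converged,
            "n_obs": self.n_obs,
            "n_trials": self.n_trials,
            "message": self.message,
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_dict(cls, d: Mapping) -> "FitResult":
        return cls(
            params=ModelParameters.from_dict(d["params"]),
            ofv=float(d["ofv"]),
            param_names=tuple(d["param_names"]),
            x=np.asarray(d["x"], dtype=float),
            covariance=None if d.get("covariance") is None
            else np.asarray(d["covariance"], dtype=float),
            se=dict(d["se"]),
            rse_pct=dict(d["rse_pct"]),
            ebes={k: TrialRandomEffects(v["eta_emax"], v["eta_et50"])
                  for k, v in d.get("ebes", {}).items()},
            converged=bool(d["converged"]),
            n_obs=int(d["n_obs"]),
            n_trials=int(d["n_trials"]),
            message=str(d.get("message", "")),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "FitResult":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def fixed_effect_names(self) -> list[str]:
        return [n for n in self.param_names
                if n in ("theta_emax", "log_theta_et50") or n.startswith("beta_")]


def covariate_center(ds: MetaDataset, name: str) -> float:
    """Centring constant for a covariate: 0 for percentage-type covariates,
    otherwise the across-trial median (the convention of the pooled model,
    whose baseline centring 10.1 is the corpus median baseline)."""
    if name in FRACTION_COVARIATES:
        return 0.0
    values = [t.covariates.get(name) for t in ds.trials]
    present = [v for v in values if v is not None]
    if not present:
        raise ValueError(f"covariate {name!r} missing in every trial")
    return float(np.median(present))


def _spec_names(cov_spec: Sequence) -> list[str]:
    names = []
    for c in cov_spec:
        names.append(c if isinstance(c, str) else c.name)
    return names


def _initial_parameters(ds: MetaDataset, cov_names: Sequence[str],
                        centers: Mapping[str, float]) -> ModelParameters:
    last = np.array([t.changes[-1] for t in ds.trials])
    theta_emax0 = -float(np.mean(last))
    if abs(theta_emax0) < 0.25:
        theta_emax0 = 0.5 if theta_emax0 >= 0 else -0.5
    et50_0 = 0.5 * float(np.median([t.times[-1] for t in ds.trials]))
    et50_0 = max(et50_0, 1.0)
    # naive residual scale: deviations from the initial typical curve, put back
    # on the per-subject sigma scale by sqrt(N)
    resid = []
    for t in ds.trials:
        f0 = -theta_emax0 * t.times / (et50_0 + t.times)
        resid.extend(((t.changes - f0) * np.sqrt(t.n_subjects)).tolist())
    sigma0 = float(np.std(resid)) if len(resid) > 1 else 1.0
    sigma0 = min(max(sigma0, 0.3), 20.0)
    return ModelParameters(
        theta_emax=theta_emax0,
        theta_et50=et50_0,
        covariate_effects={n: CovariateEffect(0.0, centers[n]) for n in cov_names},
        omega_emax=0.3,
        omega_et50=0.3,
        sigma=sigma0,
    )


def _pack(params: ModelParameters, cov_names: Sequence[str]) -> tuple[np.ndarray, tuple[str, ...]]:
    names = ["theta_emax", "log_theta_et50"]
    x = [params.theta_emax, math.log(params.theta_et50)]
    for n in cov_names:
        names.append(f"beta_{n}")
        x.append(params.covariate_effects[n].coefficient)
    names += ["log_omega_emax", "log_omega_et50", "log_sigma"]
    x += [
        math.log(max(params.omega_emax, 1e-4)),
        math.log(max(params.omega_et50, 1e-4)),
        math.log(params.sigma),
    ]
    return np.asarray(x, dtype=float), tuple(names)


def _unpack(x: np.ndarray, cov_names: Sequence[str],
            centers: Mapping[str, float]) -> ModelParameters:
    k = len(cov_names)
    return ModelParameters(
        theta_emax=float(x[0]),
        theta_et50=float(math.exp(x[1])),
        covariate_effects={
            n: CovariateEffect(float(x[2 + i]), centers[n])
            for i, n in enumerate(cov_names)
        },
        omega_emax=float(math.exp(x[2 + k])),
        omega_et50=float(math.exp(x[3 + k])),
        sigma=float(math.exp(x[4 + k])),
    )


def _fd_hessian(f: Callable[[np.ndarray], float], x: np.ndarray,
                rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian on the transformed scale."""
    p = len(x)
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((p, p))
    for i in range(p):
        ei = np.zeros(p); ei[i] = h[i]
        f0 = f(x)
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, p):
            ej = np.zeros(p); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return H


def fit(
    ds: MetaDataset,
    cov_spec: Sequence = (),
    config: Optional[FitConfig] = None,
) -> FitResult:
    """Fit the mixed-effects Emax time-course model to a trial-level corpus.

    ``cov_spec`` lists covariates entering the Emax model linearly (names or
    :class:`~placebo_mbma.covariate_selection.CovariateCandidate`); centring
    constants are the corpus medians (0 for percentage covariates) and are
    frozen into the returned parameters.  Positivity of ET50, the omegas and
    sigma is enforced by log transforms; the covariance of the estimates is
    the inverse of half the finite-difference OFV Hessian at the optimum, and
    empirical Bayes effects are the per-trial posterior modes at the final
    estimates.  Non-convergence is reported via ``converged=False``, never as
    an exception.
    """
    config = config or FitConfig()
    cov_names = _spec_names(cov_spec)
    for name in cov_names:
        for t in ds.trials:
            if t.covariates.get(name) is None:
                raise ValueError(
                    f"covariate {name!r} missing in trial {t.trial_id!r}; "
                    "run prepare_covariates first"
                )
    centers = {n: covariate_center(ds, n) for n in cov_names}
    init = config.initial or _initial_parameters(ds, cov_names, centers)
    if config.initial is not None and set(cov_names) - set(init.covariate_effects):
        raise ValueError("initial parameters lack requested covariate effects")
    x0, names = _pack(init, cov_names)
    trial_arrays = _arrays(ds)
    nodes = None if config.approximation == "laplace" else config.nodes

    def objective(x: np.ndarray) -> float:
        try:
            p = _unpack(x, cov_names, centers)
            val = _ofv(p, trial_arrays, nodes=nodes, inner_tol=config.inner_tol)
        except (ValueError, FloatingPointError, OverflowError):
            return _PENALTY_OFV
        return val if np.isfinite(val) else _PENALTY_OFV

    bounds = [
        _BOUNDS.get(n, _BETA_BOUND) for n in names
    ]
    rng = np.random.default_rng(config.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    opts = {"maxiter": config.maxiter, "ftol": config.outer_tol * 1e-2,
            "eps": 1e-6}

    def run(xs):
        res = minimize(objective, xs, method="L-BFGS-B", bounds=bounds,
                       options=opts)
        # a restart from the terminal point recovers most line-search aborts
        res2 = minimize(objective, res.x, method="L-BFGS-B", bounds=bounds,
                        options=opts)
        if res2.fun <= res.fun:
            res = res2
        if not res.success:
            res3 = minimize(objective, res.x, method="Nelder-Mead",
                            options={"maxiter": 500, "fatol": 1e-5,
                                     "xatol": 1e-5})
            if res3.fun <= res.fun:
                # polish the rescue with a final quasi-Newton pass, which
                # also restores a meaningful convergence status
                res4 = minimize(objective, np.clip(res3.x, lo, hi),
                                method="L-BFGS-B", bounds=bounds, options=opts)
                res = res4 if res4.fun <= res3.fun else res3
        return res

    best = None
    for start in range(max(1, config.n_starts)):
        xs = x0 if start == 0 else x0 + rng.normal(0.0, 0.3, size=x0.shape)
        xs = np.clip(xs, lo, hi)
        res = run(xs)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    xopt = np.asarray(best.x, dtype=float)
    params = _unpack(xopt, cov_names, centers)
    ofv = float(best.fun)
    converged = bool(best.success) and ofv < _PENALTY_OFV / 2

    covariance = None
    se: dict[str, float] = {}
    rse: dict[str, float] = {}
    if config.compute_covariance and converged:
        H = _fd_hessian(objective, xopt)
        try:
            covariance = 2.0 * np.linalg.pinv(H)
            eig = np.linalg.eigvalsh(covariance)
            if np.min(eig) < -1e-8 * max(1.0, np.max(np.abs(eig))):
                logger.warning("covariance not positive semidefinite")
            diag = np.clip(np.diag(covariance), 0.0, None)
            se_x = np.sqrt(diag)
            naturals = _natural_names(names)
            for i, (tn, nn) in enumerate(zip(names, naturals)):
                value = _natural_value(params, nn)
                if tn.startswith("log_"):
                    se[nn] = abs(value) * se_x[i]
                    rse[nn] = 100.0 * se_x[i]
                else:
                    se[nn] = se_x[i]
                    rse[nn] = 100.0 * se_x[i] / abs(value) if value != 0 else float("inf")
        except np.linalg.LinAlgError:
            logger.warning("Hessian inversion failed; no covariance reported")
            covariance = None

    ebes = {t.trial_id: empirical_bayes(params, t) for t in ds.trials}
    return FitResult(
        params=params, ofv=ofv, param_names=names, x=xopt,
        covariance=covariance, se=se, rse_pct=rse, ebes=ebes,
        converged=converged, n_obs=ds.n_obs, n_trials=ds.n_trials,
        message=str(best.message),
    )


def _natural_names(transformed: Sequence[str]) -> list[str]:
    return [n[4:] if n.startswith("log_") else n for n in transformed]


def _natural_value(params: ModelParameters, natural_name: str) -> float:
    if natural_name.startswith("beta_"):
        return params.covariate_effects[natural_name[5:]].coefficient
    return getattr(params, natural_name)


def fit_result_from_estimates(
    params: ModelParameters,
    rse_pct: Optional[Mapping[str, float]] = None,
    ds: Optional[MetaDataset] = None,
) -> FitResult:
    """Wrap externally reported estimates (and optional RSEs) as a FitResult.

    Useful for downstream simulation from published parameter tables when the
    underlying corpus is unavailable.  RSEs (percent, keyed by natural names
    such as ``theta_emax`` or ``beta_baseline_essdai``) become a diagonal
    covariance on the transformed scale: identity-scale SE = RSE/100 * |value|
    for unconstrained parameters, log-scale SE = RSE/100 for positive ones
    (so ET50 and the variance components stay positive under sampling).
    """
    cov_names = list(params.covariate_effects)
    x, names = _pack(params, cov_names)
    rse_pct = dict(rse_pct or {})
    covariance = None
    se: dict[str, float] = {}
    if rse_pct:
        diag = []
        for tn, nn in zip(names, _natural_names(names)):
            r = rse_pct.get(nn, 0.0) / 100.0
            value = _natural_value(params, nn)
            if tn.startswith("log_"):
                diag.append(r**2)
                se[nn] = abs(value) * r
            else:
                diag.append((r * abs(value)) ** 2)
                se[nn] = r * abs(value)
        covariance = np.diag(diag)
    ebes = {t.trial_id: empirical_bayes(params, t) for t in ds.trials} if ds else {}
    return FitResult(
        params=params, ofv=float("nan"), param_names=names, x=x,
        covariance=covariance, se=se, rse_pct=rse_pct, ebes=ebes,
        converged=True, n_obs=ds.n_obs if ds else 0,
        n_trials=ds.n_trials if ds else 0,
        message="constructed from external estimates",
    )
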