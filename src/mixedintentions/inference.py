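"""Per-subject model fitting: MAP estimation and Laplace model evidence.

Each model's free parameters live on an unconstrained scale with independent
Gaussian priors (default N(0, 3^2)); a per-parameter bijection (logit, log,
or identity) maps to the natural scale.  The posterior mode is found by
multistart quasi-Newton optimization, and the log model evidence is
approximated by the Laplace integral at the mode,

    F = log p(y, theta_MAP) + (d/2) log 2 pi - (1/2) log |-H|,

with H the Hessian of the log posterior at the mode.  F is the quantity the
group-level random-effects model selection consumes; it coincides with the
variational free energy in the Laplace limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .models.base import Model, ParamDef
from .task import SessionData

__all__ = [
    "FitResult",
    "to_natural",
    "from_natural",
    "log_prior",
    "fit_map",
    "laplace_evidence",
]

LOG_2PI = math.log(2.0 * math.pi)


def to_natural(defs: Sequence[ParamDef], theta: np.ndarray) -> dict[str, float]:
    """Map an unconstrained vector to natural-scale named parameters."""
    out: dict[str, float] = {}
    for d, u in zip(defs, theta):
        if d.transform == "logit":
            out[d.name] = float(expit(u))
        elif d.transform == "log":
            # cap to keep extreme optimizer excursions finite
            out[d.name] = float(np.exp(min(u, 50.0)))
        elif d.transform == "id":
            out[d.name] = float(u)
        else:
            raise ValueError(f"unknown transform {d.transform!r}")
    return out


def from_natural(defs: Sequence[ParamDef], params: dict[str, float]) -> np.ndarray:
    """Inverse of :func:`to_natural`; rejects values outside the codomain."""
    theta = np.empty(len(defs))
    for i, d in enumerate(defs):
        v = params[d.name]
        if d.transform == "logit":
            if not 0.0 < v < 1.0:
                raise ValueError(f"{d.name}={v} outside (0, 1)")
            theta[i] = logit(v)
        elif d.transform == "log":
            if v <= 0.0:
                raise ValueError(f"{d.name}={v} outside (0, inf)")
            theta[i] = math.log(v)
        else:
            theta[i] = v
    return theta


def log_prior(defs: Sequence[ParamDef], theta: np.ndarray) -> float:
    """Independent Gaussian log prior density on the unconstrained scale."""
    lp = 0.0
    for d, u in zip(defs, theta):
        z = (u - d.prior_mean) / d.prior_sd
        lp += -0.5 * z * z - math.log(d.prior_sd) - 0.5 * LOG_2PI
    return lp


@dataclass
class FitResult:
    """MAP fit of one model to one session."""

    model_name: str
    param_names: tuple[str, ...]
    theta_map: np.ndarray  # unconstrained scale
    params: dict[str, float]  # natural scale
    loglik: float
    logpost: float
    hessian: np.ndarray  # of the log posterior at the mode
    free_energy: float
    n_restarts_used: int
    converged: bool
    regularized: bool = False
    subject_id: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "subject_id": self.subject_id,
            "param_names": list(self.param_names),
            "theta_map": [float(x) for x in self.theta_map],
            "params": {k: float(v) for k, v in self.params.items()},
            "loglik": float(self.loglik),
            "logpost": float(self.logpost),
            "free_energy": float(self.free_energy),
            "n_restarts_used": int(self.n_restarts_used),
            "converged": bool(self.converged),
            "regularized": bool(self.regularized),
        }


def _fd_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian of a scalar function."""
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * step**2)
    return H


def laplace_evidence(
    logpost_map: float, hessian: np.ndarray
) -> tuple[float, bool]:
    """Laplace approximation to log evidence from the mode and curvature.

    Returns (F, regularized); the Hessian is eigenvalue-clipped if -H is not
    positive definite.
    """
    d = hessian.shape[0]
    neg_h = -np.asarray(hessian, dtype=float)
    neg_h = 0.5 * (neg_h + neg_h.T)
    eigvals = np.linalg.eigvalsh(neg_h)
    regularized = bool(np.any(eigvals <= 0))
    eigvals = np.clip(eigvals, 1e-8, None)
    logdet = float(np.sum(np.log(eigvals)))
    return logpost_map + 0.5 * d * LOG_2PI - 0.5 * logdet, regularized


def fit_map(
    model: Model,
    session: SessionData,
    n_restarts: int = 8,
    seed: int = 0,
    maxiter: int = 300,
    hessian_step: float = 1e-4,
) -> FitResult:
    """Multistart MAP fit of ``model`` to one session.

    The first start is the prior mean; the remaining ``n_restarts - 1``
    starts are standard-normal draws around it.  Deterministic given
    ``seed``.
    """
    defs = model.param_defs
    d = len(defs)

    def neg_logpost(theta: np.ndarray) -> float:
        params = to_natural(defs, theta)
        try:
            ll = model.loglik(params, session)
        except (OverflowError, FloatingPointError):  # pragma: no cover
            return 1e12
        if not math.isfinite(ll):
            return 1e12
        return -(ll + log_prior(defs, theta))

    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 0x5EED])
    starts = [np.array([p.prior_mean for p in defs], dtype=float)]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(starts[0] + rng.standard_normal(d))

    best = None
    any_converged = False
    for x0 in starts:
        res = minimize(
            neg_logpost, x0, method="L-BFGS-B", options={"maxiter": maxiter}
        )
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = np.asarray(best.x, dtype=float)
    logpost_map = -float(best.fun)
    hessian = -_fd_hessian(neg_logpost, theta, step=hessian_step)
    free_energy, regularized = laplace_evidence(logpost_map, hessian)
    params = to_natural(defs, theta)
    return FitResult(
        model_name=model.name,
        param_names=model.param_names,
        theta_map=theta,
        params=params,
        loglik=model.loglik(params, session),
        logpost=logpost_map,
        hessian=hessian,
        free_energy=free_energy,
        n_restarts_used=len(starts),
        converged=any_converged,
        subject_id=session.subject_id,
    )
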