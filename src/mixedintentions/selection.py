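"""Random-effects Bayesian model selection over per-subject log evidences.

Model frequencies in the population carry a Dirichlet prior (alpha0 = 1 per
model).  A variational scheme alternates subject-level responsibilities
(softmax of evidence plus digamma terms) with Dirichlet concentration
updates.  Exceedance probabilities (EP) are the posterior probabilities that
each model is the most frequent; the Bayesian omnibus risk (BOR) is the
posterior probability that all models are equally frequent (null) rather
than the random-effects model, and the protected exceedance probability is

    pEP_k = EP_k * (1 - BOR) + BOR / K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import betainc, digamma, gammaln, logsumexp

__all__ = [
    "BMSResult",
    "rfx_bms",
    "exceedance_prob",
    "omnibus_risk",
    "protected_ep",
    "bms",
]


class BMSConvergenceError(RuntimeError):
    pass


@dataclass
class BMSResult:
    model_names: tuple[str, ...]
    alpha: np.ndarray  # Dirichlet posterior concentrations
    expected_freq: np.ndarray
    responsibilities: np.ndarray  # subjects x models posterior assignments
    ep: np.ndarray
    bor: float
    pep: np.ndarray
    n_iter: int

    @property
    def winner(self) -> str:
        return self.model_names[int(np.argmax(self.pep))]


def _validate(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] < 2:
        raise ValueError("evidence matrix must be subjects x models with >= 2 models")
    if not np.all(np.isfinite(F)):
        raise ValueError("evidence matrix must be finite")
    return F


def rfx_bms(
    F: np.ndarray,
    alpha0: float = 1.0,
    tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Variational random-effects update.

    Returns (alpha, expected_freq, responsibilities, n_iter).
    """
    F = _validate(F)
    n, k = F.shape
    alpha = np.full(k, alpha0 + n / k)
    for it in range(1, max_iter + 1):
        logu = F + digamma(alpha) - digamma(alpha.sum())
        logu -= logsumexp(logu, axis=1, keepdims=True)
        u = np.exp(logu)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    else:
        raise BMSConvergenceError(
            f"RFX-BMS did not converge in {max_iter} iterations "
            f"(last alpha = {alpha})"
        )
    return alpha, alpha / alpha.sum(), u, it


def exceedance_prob(
    alpha: np.ndarray, n_draws: int = 10_000_000, seed: int = 0
) -> np.ndarray:
    """P(freq_k is the largest) under Dirichlet(alpha).

    Exact (regularized incomplete beta) when K = 2; seeded Monte Carlo in
    chunks otherwise.
    """
    alpha = np.asarray(alpha, dtype=float)
    if np.any(alpha <= 0):
        raise ValueError("alpha must be positive")
    k = len(alpha)
    if k == 2:
        # P(x1 > 0.5), x1 ~ Beta(a1, a2)
        p1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    counts = np.zeros(k, dtype=np.int64)
    remaining = int(n_draws)
    while remaining > 0:
        m = min(remaining, 1_000_000)
        draws = rng.dirichlet(alpha, size=m)
        counts += np.bincount(np.argmax(draws, axis=1), minlength=k)
        remaining -= m
    return counts / float(n_draws)


def _rfx_free_energy(
    F: np.ndarray, alpha: np.ndarray, u: np.ndarray, alpha0: float
) -> float:
    """Variational free energy of the random-effects model."""
    n, k = F.shape
    a0 = np.full(k, alpha0)
    psi = digamma(alpha) - digamma(alpha.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        entropy = -np.where(u > 0, u * np.log(u), 0.0).sum()
    out = float(np.sum(u * (F + psi)) + entropy)
    out += float(
        gammaln(a0.sum())
        - gammaln(a0).sum()
        - gammaln(alpha.sum())
        + gammaln(alpha).sum()
        + np.dot(a0 - alpha, psi)
    )
    return out


def _null_free_energy(F: np.ndarray) -> float:
    """Log evidence of the null: every model equally frequent in the group."""
    n, k = F.shape
    return float(np.sum(logsumexp(F, axis=1)) - n * math.log(k))


def omnibus_risk(F: np.ndarray, alpha0: float = 1.0) -> float:
    """Posterior probability of the equal-frequency null vs the RFX model."""
    F = _validate(F)
    alpha, _, u, _ = rfx_bms(F, alpha0=alpha0)
    f1 = _rfx_free_energy(F, alpha, u, alpha0)
    f0 = _null_free_energy(F)
    # BOR = P(null | data) with a 50/50 prior over the two hypotheses
    return float(1.0 / (1.0 + math.exp(min(max(f1 - f0, -700.0), 700.0))))


def protected_ep(ep: np.ndarray, bor: float, k: int | None = None) -> np.ndarray:
    """Exceedance probabilities shrunk toward uniform by the omnibus risk."""
    ep = np.asarray(ep, dtype=float)
    if k is None:
        k = len(ep)
    if not 0.0 <= bor <= 1.0:
        raise ValueError("BOR must lie in [0, 1]")
    return ep * (1.0 - bor) + bor / k


def bms(
    F: np.ndarray,
    model_names: tuple[str, ...] | list[str] | None = None,
    alpha0: float = 1.0,
    n_draws: int = 10_000_000,
    seed: int = 0,
) -> BMSResult:
    """Full pipeline: RFX updates, EP, BOR, and protected EP."""
    F = _validate(F)
    n, k = F.shape
    if model_names is None:
        model_names = tuple(f"M{i + 1}" for i in range(k))
    if len(model_names) != k:
        raise ValueError("model_names length must match the number of models")
    alpha, freq, u, n_iter = rfx_bms(F, alpha0=alpha0)
    ep = exceedance_prob(alpha, n_draws=n_draws, seed=seed)
    bor = omnibus_risk(F, alpha0=alpha0)
    pep = protected_ep(ep, bor, k)
    return BMSResult(
        model_names=tuple(model_names),
        alpha=alpha,
        expected_freq=freq,
        responsibilities=u,
        ep=ep,
        bor=bor,
        pep=pep,
        n_iter=n_iter,
    )
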