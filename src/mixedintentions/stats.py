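"""Trial-level behavioral covariates and panel regressions.

The covariate builder derives, for each trial t of a session, the stay /
switch indicator, lagged outcomes and switches (t-1..t-3), and the lagged
"Cooperativity signature of AA": a binary variable set to 1 when the AA
stayed on the same card after the participant's win, or switched after the
participant's loss — the behavior a genuinely cooperative partner would
show.  When controller latents are attached, the reliability difference,
the previous reward prediction error, and the arbitration valence
(+1 cooperative / -1 competitive) are added.

The panel logistic regression is a random-intercept logit estimated by
maximum likelihood with Gauss-Hermite quadrature (default 12 nodes), with
Eicker-Huber-White cluster sandwich standard errors for panels nested in
participants.  The linear panel regression uses OLS with the same
cluster-robust covariance.  Marginal effects default to the average
marginal effect (AME): the mean change in the marginal predicted
probability for a unit change of the covariate; a literal
``mean(logit^-1(w))`` variant is kept behind a flag for compatibility.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from numpy.polynomial.hermite_e import hermegauss
from scipy import stats as sps
from scipy.optimize import minimize
from scipy.special import expit
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .models.mixture import COOPERATIVE, ControllerTrace
from .task import SessionData

__all__ = [
    "SeparationError",
    "CollinearityError",
    "RegressionResult",
    "derive_covariates",
    "covariates_table",
    "panel_logit",
    "panel_linear",
    "marginal_effects",
    "vif_check",
]


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class CollinearityError(ValueError):
    """Singular design matrix; names the offending columns."""


# ---------------------------------------------------------------------------
# covariates


def derive_covariates(
    session: SessionData,
    trace: Optional[ControllerTrace] = None,
    drop_first: int = 5,
    max_lag: int = 3,
) -> pd.DataFrame:
    """Analysis-ready covariate rows for one session.

    Rows are the trials with all lags defined and the first ``drop_first``
    trials excluded.  ``coop_sig`` at trial t is defined from the outcome at
    t-1 and the AA's stay/switch between t-1 and t; its lagged values (and
    all other lags) are taken relative to the predicted trial.
    """
    n = len(session)
    if n < max_lag + 1:
        raise ValueError("session too short for lagged covariates")
    pc = np.array([r.participant_choice for r in session.records])
    aa = np.array([r.aa_choice for r in session.records])
    win = np.array([r.outcome for r in session.records])
    mode = np.array([r.mode.value for r in session.records], dtype=object)

    stay = np.full(n, np.nan)
    stay[1:] = (pc[1:] == pc[:-1]).astype(float)
    aa_stay = np.full(n, np.nan)
    aa_stay[1:] = (aa[1:] == aa[:-1]).astype(float)
    # Cooperativity signature of AA at trial t: AA stayed after a win at t-1
    # or switched after a loss at t-1
    coop_sig = np.full(n, np.nan)
    coop_sig[1:] = np.where(win[:-1] == 1, aa_stay[1:], 1.0 - aa_stay[1:])

    rows = {}
    t = np.arange(1, n + 1)
    rows["subject_id"] = np.repeat(session.subject_id, n)
    rows["trial"] = t
    rows["rank"] = t
    rows["mode"] = mode
    rows["stay"] = stay
    rows["switch"] = 1.0 - stay
    for lag in range(1, max_lag + 1):
        rows[f"win_tm{lag}"] = _lag(win.astype(float), lag)
        rows[f"switch_tm{lag}"] = _lag(1.0 - stay, lag)
        rows[f"coop_sig_tm{lag}"] = _lag(coop_sig, lag)
    rows["mode_tm1"] = _lag(mode, 1, fill=None)
    rows["comp_mode_tm1"] = np.where(
        rows["mode_tm1"] == "COMPETITIVE", 1.0,
        np.where(rows["mode_tm1"] == "COOPERATIVE", 0.0, np.nan),
    )

    if trace is not None:
        if len(trace) != n:
            raise ValueError("trace length must match the session")
        rows["delta"] = trace.delta
        rows["omega"] = trace.omega
        rows["classification"] = trace.classification
        rows["valence"] = np.where(trace.classification == COOPERATIVE, 1.0, -1.0)
        rows["rpe_tm1"] = _lag(trace.rpe, 1)
        rows["dv_stay"] = trace.dv_stay

    df = pd.DataFrame(rows)
    keep = (df["trial"] > drop_first) & (df["trial"] > max_lag + 1)
    df = df.loc[keep].reset_index(drop=True)
    return df


def _lag(x: np.ndarray, lag: int, fill=np.nan) -> np.ndarray:
    out = np.empty(len(x), dtype=x.dtype if x.dtype == object else float)
    out[:lag] = fill
    out[lag:] = x[:-lag]
    return out


def covariates_table(
    sessions: Sequence[SessionData],
    traces: Optional[Sequence[ControllerTrace]] = None,
    **kwargs,
) -> pd.DataFrame:
    """Stacked covariate rows over a population of sessions."""
    if traces is None:
        traces = [None] * len(sessions)
    return pd.concat(
        [derive_covariates(s, tr, **kwargs) for s, tr in zip(sessions, traces)],
        ignore_index=True,
    )


# ---------------------------------------------------------------------------
# design handling


def _design(
    data: pd.DataFrame, covariates: Sequence[str], add_intercept: bool = True
) -> tuple[np.ndarray, list[str]]:
    names = (["const"] if add_intercept else []) + list(covariates)
    X = data[list(covariates)].to_numpy(dtype=float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns via pivoted QR
        _, _, piv = _qr_pivot(X)
        bad = sorted(names[j] for j in piv[rank:])
        raise CollinearityError(f"singular design; collinear columns: {bad}")
    return X, names


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    return qr(X, pivoting=True)


def _check_separation(X: np.ndarray, y: np.ndarray, names: list[str]) -> None:
    # column-wise check: a binary column identical (or opposite) to y
    for j, nm in enumerate(names):
        col = X[:, j]
        if set(np.unique(col)) <= {0.0, 1.0} and len(np.unique(col)) == 2:
            if np.all(col == y) or np.all(col == 1 - y):
                raise SeparationError(f"perfect separation on column {nm!r}")
    if np.all(y == y[0]):
        raise SeparationError("outcome is constant")


# ---------------------------------------------------------------------------
# results container


@dataclass
class RegressionResult:
    kind: str  # 'logit' or 'linear'
    names: list[str]
    params: np.ndarray
    cov: np.ndarray  # cluster-robust
    n_obs: int
    n_clusters: int
    sigma_b: float = 0.0  # random-intercept SD (logit)
    loglik: float = math.nan
    vif: Optional[pd.Series] = None
    _X: np.ndarray = field(default=None, repr=False)
    _y: np.ndarray = field(default=None, repr=False)

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    @property
    def chi2(self) -> np.ndarray:
        """Per-coefficient Wald chi-square statistics (1 df)."""
        return (self.params / self.se) ** 2

    @property
    def pvalues(self) -> np.ndarray:
        return sps.chi2.sf(self.chi2, df=1)

    def conf_int(self, level: float = 0.95) -> np.ndarray:
        z = sps.norm.ppf(0.5 + level / 2.0)
        return np.column_stack(
            [self.params - z * self.se, self.params + z * self.se]
        )

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        ci = self.conf_int()
        df = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.se,
                "chi2": self.chi2,
                "p": self.pvalues,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            },
            index=self.names,
        )
        if self.kind == "logit":
            df["ame"] = [marginal_effects(self, name) for name in self.names]
        else:
            df["ame"] = self.params
        return df


# ---------------------------------------------------------------------------
# random-intercept logit (Gauss-Hermite)


def _gh_nodes(n_quad: int) -> tuple[np.ndarray, np.ndarray]:
    # probabilists' Hermite rule: integrates against the standard normal
    z, w = hermegauss(n_quad)
    return z, w / math.sqrt(2.0 * math.pi)


def _cluster_logliks(
    beta: np.ndarray,
    log_sigma: float,
    X: np.ndarray,
    y: np.ndarray,
    starts: np.ndarray,
    z: np.ndarray,
    logw: np.ndarray,
) -> np.ndarray:
    """Integrated log-likelihood per cluster."""
    eta = X @ beta
    sb = math.exp(log_sigma)
    A = eta[:, None] + sb * z[None, :]
    # log Bernoulli likelihood row-by-node; stable via logaddexp
    row_ll = np.where(y[:, None] == 1, -np.logaddexp(0.0, -A), -np.logaddexp(0.0, A))
    csum = np.add.reduceat(row_ll, starts, axis=0)
    m = csum.max(axis=1, keepdims=True)
    return (m[:, 0] + np.log(np.exp(csum - m + logw[None, :]).sum(axis=1)))


def panel_logit(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    cluster: str = "subject_id",
    n_quad: int = 12,
    add_intercept: bool = True,
    fixed_sigma: Optional[float] = None,
    compute_vif: bool = True,
) -> RegressionResult:
    """Random-intercept logit with cluster-robust (sandwich) covariance."""
    df = data.dropna(subset=[outcome, *covariates, cluster]).sort_values(cluster)
    y = df[outcome].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X, names = _design(df, covariates, add_intercept)
    _check_separation(X, y, names)
    groups = df[cluster].to_numpy()
    _, starts = np.unique(groups, return_index=True)
    starts = np.sort(starts)
    n_clusters = len(starts)
    if n_clusters < 2 and fixed_sigma is None:
        # a single panel cannot identify the random-intercept variance
        fixed_sigma = 1e-8
    z, w = _gh_nodes(n_quad)
    logw = np.log(w)
    p = X.shape[1]

    estimate_sigma = fixed_sigma is None

    def unpack(theta):
        if estimate_sigma:
            return theta[:p], float(theta[p])
        return theta, math.log(fixed_sigma)

    def nll(theta):
        beta, log_sigma = unpack(theta)
        log_sigma = min(log_sigma, 3.0)
        return -float(
            _cluster_logliks(beta, log_sigma, X, y, starts, z, logw).sum()
        )

    start_beta = sm.Logit(y, X).fit(disp=0, maxiter=200).params
    theta0 = (
        np.concatenate([start_beta, [math.log(0.5)]])
        if estimate_sigma
        else np.asarray(start_beta)
    )
    res = minimize(nll, theta0, method="BFGS", options={"maxiter": 500})
    theta = res.x
    beta, log_sigma = unpack(theta)
    if np.max(np.abs(beta)) > 25:
        raise SeparationError("diverging coefficients suggest (quasi-)separation")

    # cluster sandwich on the full parameter vector, reported for beta
    H = _fd_hessian_generic(nll, theta)
    scores = _cluster_scores(theta, unpack, X, y, starts, z, logw)
    meat = scores.T @ scores * (n_clusters / max(n_clusters - 1, 1))
    bread = np.linalg.pinv(H)
    cov_full = bread @ meat @ bread
    cov = cov_full[:p, :p]

    vif = None
    if compute_vif and len(names) - int(add_intercept) >= 2:
        vif = vif_check(df, covariates)
    return RegressionResult(
        kind="logit",
        names=names,
        params=np.asarray(beta, dtype=float),
        cov=cov,
        n_obs=len(y),
        n_clusters=n_clusters,
        sigma_b=float(math.exp(min(log_sigma, 3.0))),
        loglik=-res.fun,
        vif=vif,
        _X=X,
        _y=y,
    )


def _fd_hessian_generic(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    d = len(x)
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / step**2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = step
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * step**2)
    return H


def _cluster_scores(theta, unpack, X, y, starts, z, logw, step: float = 1e-5):
    def per_cluster(th):
        beta, log_sigma = unpack(th)
        return _cluster_logliks(beta, min(log_sigma, 3.0), X, y, starts, z, logw)

    d = len(theta)
    g = np.empty((len(starts), d))
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = step
        g[:, i] = (per_cluster(theta + ei) - per_cluster(theta - ei)) / (2 * step)
    return g


# ---------------------------------------------------------------------------
# marginal effects


def marginal_effects(
    fit: RegressionResult,
    covariate: str | None = None,
    literal: bool = False,
) -> float | pd.Series:
    """Marginal effect(s) on the outcome probability.

    Default is the average marginal effect: for a binary covariate the mean
    discrete change in the marginal predicted probability between its two
    levels; for a continuous covariate the mean derivative.  ``literal=True``
    instead returns ``mean(logit^-1(w))`` of the raw coefficient (a
    compatibility mode; it equals 0.5 for a null effect).
    """
    if covariate is None:
        return pd.Series(
            {nm: marginal_effects(fit, nm, literal) for nm in fit.names}
        )
    j = fit.names.index(covariate)
    if fit.kind == "linear":
        return float(fit.params[j])
    if literal:
        return float(expit(fit.params[j]))
    X, beta, sb = fit._X, fit.params, fit.sigma_b
    z, w = _gh_nodes(24)

    def marg_prob(Xm):
        eta = Xm @ beta
        return expit(eta[:, None] + sb * z[None, :]) @ w

    col = X[:, j]
    uniq = np.unique(col)
    if set(uniq) <= {0.0, 1.0}:
        X1, X0 = X.copy(), X.copy()
        X1[:, j] = 1.0
        X0[:, j] = 0.0
        return float(np.mean(marg_prob(X1) - marg_prob(X0)))
    eta = X @ beta
    dens = expit(eta[:, None] + sb * z[None, :])
    return float(np.mean((dens * (1 - dens)) @ w) * beta[j])


# ---------------------------------------------------------------------------
# linear panel regression


def panel_linear(
    data: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str],
    cluster: str = "subject_id",
    add_intercept: bool = True,
    compute_vif: bool = True,
) -> RegressionResult:
    """Linear regression with Eicker-Huber-White cluster-robust SEs.

    Coefficients are the marginal effects directly.
    """
    df = data.dropna(subset=[outcome, *covariates, cluster])
    y = df[outcome].to_numpy(dtype=float)
    X, names = _design(df, covariates, add_intercept)
    groups = df[cluster].to_numpy()
    n_clusters = len(np.unique(groups))
    if n_clusters >= 2:
        ols = sm.OLS(y, X).fit(cov_type="cluster", cov_kwds={"groups": groups})
    else:
        ols = sm.OLS(y, X).fit(cov_type="HC1")
    vif = None
    if compute_vif and len(names) - int(add_intercept) >= 2:
        vif = vif_check(df, covariates)
    return RegressionResult(
        kind="linear",
        names=names,
        params=np.asarray(ols.params, dtype=float),
        cov=np.asarray(ols.cov_params(), dtype=float),
        n_obs=len(y),
        n_clusters=n_clusters,
        loglik=float(ols.llf),
        vif=vif,
        _X=X,
        _y=y,
    )


# ---------------------------------------------------------------------------
# multicollinearity


def vif_check(
    data: pd.DataFrame, covariates: Sequence[str], warn_above: float = 5.0
) -> pd.Series:
    """Variance inflation factor per covariate (intercept included)."""
    X, names = _design(data.dropna(subset=list(covariates)), covariates, True)
    vals = {}
    for j, nm in enumerate(names):
        if nm == "const":
            continue
        vals[nm] = float(variance_inflation_factor(X, j))
    s = pd.Series(vals, name="VIF")
    s.attrs["warn"] = [nm for nm, v in vals.items() if v > warn_above]
    return s
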