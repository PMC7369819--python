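"""Logistic-regression primitives used by the disease scans and the causal inference test.

The causal inference test replicates its component-4 statistic over hundreds of
parametric bootstrap outcomes that share one design matrix, so alongside the
ordinary single-response Newton fit there is a batched fit that solves all
bootstrap replicates simultaneously.  Firth's bias-reduced fit handles
separated data, where the maximum-likelihood estimate diverges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

# |coefficient x predictor sd| beyond this on the logit scale is divergence
_DIVERGENCE_BOUND = 15.0
_RIDGE = 1e-10


def _column_scales(X: np.ndarray) -> np.ndarray:
    """Per-column sd; (near-)constant columns such as the intercept get 0 so
    they never trigger the scale-aware divergence check."""
    sd = X.std(axis=0)
    return np.where(sd > 1e-8, sd, 0.0)


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float | np.ndarray:
    # log p(y|eta) summed over observations, numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class LogisticFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float
    converged: bool
    separated: bool
    n_iter: int

    def wald_p(self, j: int) -> float:
        se = np.sqrt(self.cov[j, j])
        z = self.coef[j] / se
        return float(2.0 * stats.norm.sf(abs(z)))


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> LogisticFit:
    """Newton–Raphson maximum likelihood for logistic regression.

    X must include an intercept column if one is wanted.  Separation is
    reported via ``separated`` (coefficients escaping a large bound or
    fitted probabilities collapsing to 0/1); callers decide whether to
    fall back to the Firth fit.
    """
    n, p = X.shape
    beta = np.zeros(p)
    # start the intercept (assumed column of ones if present) near logit(mean)
    ybar = min(max(y.mean(), 1e-6), 1 - 1e-6)
    ones = np.where(np.all(X == 1.0, axis=0))[0]
    if ones.size:
        beta[ones[0]] = np.log(ybar / (1 - ybar))
    ll_old = -np.inf
    converged = False
    it = 0
    H = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * w[:, None]).T @ X
        H.flat[:: p + 1] += _RIDGE
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        # step-halving keeps the likelihood monotone
        ll_cur = _bernoulli_loglik(y, eta)
        t = 1.0
        for _ in range(25):
            cand = beta + t * step
            if _bernoulli_loglik(y, X @ cand) >= ll_cur - 1e-12:
                break
            t *= 0.5
        beta = beta + t * step
        ll_new = _bernoulli_loglik(y, X @ beta)
        if abs(ll_new - ll_old) < tol and np.max(np.abs(grad)) < 1e-5:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = X @ beta
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    H.flat[:: p + 1] += _RIDGE
    cov = np.linalg.pinv(H)
    effect_scale = np.abs(beta) * _column_scales(X)
    separated = (not converged) or bool(np.max(effect_scale) > _DIVERGENCE_BOUND)
    return LogisticFit(beta, cov, _bernoulli_loglik(y, eta), converged, separated, it)


def fit_logistic_batch(
    X: np.ndarray,
    Y: np.ndarray,
    *,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Fit logistic models for every column of ``Y`` against a shared ``X``.

    Returns ``(loglik, coef)`` with one log-likelihood per column and the
    (p, B) coefficient matrix.  ``beta0`` warm-starts the iteration: a
    vector is broadcast to all replicates, a (p, B) matrix is used as-is.
    A vectorized backtracking line search keeps every replicate's
    likelihood monotone, so a fit warm-started at a nested model's optimum
    can never end below it.
    """
    n, p = X.shape
    B = Y.shape[1]
    beta = np.zeros((p, B))
    if beta0 is not None:
        b0 = np.asarray(beta0, dtype=float)
        beta[:] = b0[:, None] if b0.ndim == 1 else b0
    else:
        ybar = np.clip(Y.mean(axis=0), 1e-6, 1 - 1e-6)
        ones = np.where(np.all(X == 1.0, axis=0))[0]
        if ones.size:
            beta[ones[0]] = np.log(ybar / (1 - ybar))

    def loglik(Xa, Ya, bmat):
        eta = Xa @ bmat
        return eta, np.sum(Ya * eta - np.logaddexp(0.0, eta), axis=0)

    # per-replicate Hessians via one GEMM: H[b] = X' diag(W[:, b]) X
    XXf = (X[:, :, None] * X[:, None, :]).reshape(n, p * p)
    _, ll_all = loglik(X, Y, beta)
    active = np.arange(B)
    beta_a = beta.copy()
    Ya = Y
    eta_a = X @ beta_a
    ll_a = ll_all.copy()
    for _ in range(max_iter):
        mu = _sigmoid(eta_a)
        W = mu * (1.0 - mu)
        grad = X.T @ (Ya - mu)  # (p, n_active)
        H = (W.T @ XXf).reshape(len(active), p, p)
        H[:, np.arange(p), np.arange(p)] += _RIDGE
        step = np.linalg.solve(H, grad.T[:, :, None])[:, :, 0].T
        t = np.ones(len(active))
        for _ in range(15):
            cand = beta_a + t * step
            eta_c, ll_c = loglik(X, Ya, cand)
            bad = ll_c < ll_a - 1e-12
            if not bad.any():
                break
            t[bad] *= 0.5
        stuck = ll_c < ll_a
        if stuck.any():  # keep the current estimate where the search failed
            cand[:, stuck] = beta_a[:, stuck]
            eta_c[:, stuck] = eta_a[:, stuck]
            ll_c[stuck] = ll_a[stuck]
        moved = ll_c - ll_a
        beta_a, eta_a, ll_a = cand, eta_c, ll_c
        done = moved < tol
        beta[:, active] = beta_a
        ll_all[active] = ll_a
        if done.all():
            break
        if done.any():  # freeze converged replicates
            keep = ~done
            active = active[keep]
            beta_a = beta_a[:, keep]
            eta_a = eta_a[:, keep]
            ll_a = ll_a[keep]
            Ya = Y[:, active]
    return ll_all, beta


def logistic_lrt(
    X: np.ndarray, y: np.ndarray, drop: int | list[int]
) -> tuple[float, float, LogisticFit]:
    """Likelihood-ratio test for the column(s) ``drop`` of X.

    Returns (chi-square statistic, p-value, full-model fit).  Falls back to
    Firth penalized likelihood for both models when the full fit separates.
    """
    drop_idx = np.atleast_1d(drop)
    keep = [j for j in range(X.shape[1]) if j not in set(drop_idx.tolist())]
    full = fit_logistic(X, y)
    if full.separated:
        ll_full = fit_logistic_firth(X, y).loglik
        ll_red = fit_logistic_firth(X[:, keep], y).loglik
    else:
        ll_full = full.loglik
        ll_red = fit_logistic(X[:, keep], y).loglik
    stat = max(2.0 * (ll_full - ll_red), 0.0)
    p = float(stats.chi2.sf(stat, df=len(drop_idx)))
    return stat, p, full


@dataclass
class FirthFit:
    coef: np.ndarray
    cov: np.ndarray
    loglik: float  # penalized log-likelihood
    converged: bool

    def wald_p(self, j: int) -> float:
        se = np.sqrt(self.cov[j, j])
        z = self.coef[j] / se
        return float(2.0 * stats.norm.sf(abs(z)))


def fit_logistic_firth(
    X: np.ndarray,
    y: np.ndarray,
    *,
    max_iter: int = 120,
    tol: float = 1e-9,
) -> FirthFit:
    """Firth's bias-reduced logistic regression (Jeffreys-prior penalty).

    Score is adjusted by the hat-matrix leverages, giving finite estimates
    under complete or quasi-complete separation.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = mu * (1.0 - mu)
        XW = X * w[:, None]
        H = XW.T @ X
        H.flat[:: p + 1] += _RIDGE
        Hinv = np.linalg.inv(H)
        # leverages of W^(1/2) X
        h = np.einsum("ij,jk,ik->i", XW, Hinv, X)
        grad = X.T @ (y - mu + h * (0.5 - mu))
        step = Hinv @ grad
        # damp large steps for stability
        m = np.max(np.abs(step))
        if m > 5.0:
            step *= 5.0 / m
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = X @ beta
    mu = _sigmoid(eta)
    w = mu * (1.0 - mu)
    H = (X * w[:, None]).T @ X
    H.flat[:: p + 1] += _RIDGE
    cov = np.linalg.inv(H)
    sign, logdet = np.linalg.slogdet(H)
    ll = _bernoulli_loglik(y, eta) + 0.5 * logdet
    return FirthFit(beta, cov, ll, converged)
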