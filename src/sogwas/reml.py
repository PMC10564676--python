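"""Restricted maximum likelihood for multi-kernel linear mixed models.

Model: y = X b + sum_k u_k,  u_k ~ N(0, sigma2_k V_k), independent,
with the V_k arbitrary PSD covariance contributions (genomic kinships
mapped through plot-to-individual incidence, identity residuals,
per-environment masks, ...).

The optimizer is a monotone scheme: EM-style updates (guaranteed ascent
direction) for the first iterations and whenever an acceleration step
fails, then average-information (AI) steps with step-halving so the
restricted likelihood never decreases.  Variance components are kept
non-negative by projection; a component pinned at zero with a negative
gradient is frozen (boundary estimate).

Convergence: relative log-REML change < ``tol_ll`` and maximum absolute
parameter change < ``tol_par``; at most ``max_iter`` iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve


class RemlConvergenceError(RuntimeError):
    """REML failed to converge; carries the log-likelihood trajectory."""

    def __init__(self, message: str, trajectory: list[float]):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class RemlResult:
    sigma2: dict[str, float]
    loglik: float
    beta: np.ndarray
    beta_cov: np.ndarray  # (X' V^-1 X)^-1
    py: np.ndarray  # P y, for BLUPs: u_hat_k = sigma2_k V_k(term pieces) P y
    vi: np.ndarray  # V^-1 at the optimum
    n_iter: int
    converged: bool
    trajectory: list[float] = field(default_factory=list)
    boundary: list[str] = field(default_factory=list)

    @property
    def n_varparams(self) -> int:
        return len(self.sigma2)

    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_varparams

    def bic(self, n_obs: int) -> float:
        return -2.0 * self.loglik + np.log(n_obs) * self.n_varparams


def _restricted_ll(y, X, V):
    n, p = X.shape
    c = cho_factor(V, lower=True)
    logdet_v = 2.0 * np.log(np.diag(c[0])).sum()
    vi = cho_solve(c, np.eye(n))
    w = vi @ X
    xtvx = X.T @ w
    cx = cho_factor(xtvx, lower=True)
    logdet_x = 2.0 * np.log(np.diag(cx[0])).sum()
    beta = cho_solve(cx, X.T @ (vi @ y))
    r = y - X @ beta
    py = vi @ r
    quad = float(r @ py)
    ll = -0.5 * (logdet_v + logdet_x + quad)
    return ll, vi, w, xtvx, cx, beta, py


def reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: dict[str, np.ndarray],
    init: dict[str, float] | None = None,
    max_iter: int = 500,
    tol_ll: float = 1e-8,
    tol_par: float = 1e-6,
) -> RemlResult:
    """Fit the variance components of a multi-kernel mixed model.

    Parameters
    ----------
    y : (n,) response
    X : (n, p) fixed-effect design, full column rank
    terms : mapping name -> (n, n) PSD covariance contribution V_k.
        The caller must include at least one term that keeps V positive
        definite (typically an identity or per-group diagonal residual).
    init : optional starting values (defaults to var(y)/K each)
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[0]
    names = list(terms)
    K = len(names)
    mats = [np.asarray(terms[nm], dtype=float) for nm in names]
    for nm, M in zip(names, mats):
        if M.shape != (n, n):
            raise ValueError(f"term {nm!r} has shape {M.shape}, expected {(n, n)}")
    vary = float(np.var(y)) or 1.0
    jitter = 1e-10 * vary * np.eye(n)

    if init is None:
        sig = np.full(K, vary / K)
    else:
        sig = np.array([float(init.get(nm, vary / K)) for nm in names])
    sig = np.maximum(sig, 0.0)
    if sig.sum() <= 0:
        sig = np.full(K, vary / K)

    def assemble(s):
        V = jitter.copy()
        for k in range(K):
            if s[k] > 0:
                V += s[k] * mats[k]
        return V

    ll, vi, w, xtvx, cx, beta, py = _restricted_ll(y, X, assemble(sig))
    trajectory = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # gradient pieces: tr(P V_k) and Py' V_k Py
        u = np.stack([M @ py for M in mats], axis=1)  # (n, K)
        quad = py @ u  # (K,)
        # tr(P V_k) = tr(Vi V_k) - tr[(X'ViX)^-1 W' V_k W]
        tr_p = np.empty(K)
        for k in range(K):
            tvk = float(np.sum(vi * mats[k].T))
            m2 = cho_solve(cx, w.T @ (mats[k] @ w))
            tr_p[k] = tvk - float(np.trace(m2))
        grad = 0.5 * (quad - tr_p)

        free = ~((sig <= 0) & (grad < 0))
        if not free.any():
            converged = True
            break

        # AI matrix on free components: 0.5 u_j' P u_k
        uf = u[:, free]
        pu = vi @ uf - w @ cho_solve(cx, w.T @ uf)
        ai = 0.5 * (uf.T @ pu)

        proposals = []
        try:
            delta_ai = np.linalg.solve(ai + 1e-12 * np.eye(ai.shape[0]), grad[free])
            proposals.append(("ai", delta_ai))
        except np.linalg.LinAlgError:
            pass
        # EM-style ascent direction (Searle et al. form, q_k = n)
        delta_em = (sig[free] ** 2) * 2.0 * grad[free] / n
        proposals.append(("em", delta_em))

        accepted = False
        for _, delta in proposals:
            step = 1.0
            for _ in range(12):
                cand = sig.copy()
                cand[free] = np.maximum(sig[free] + step * delta, 0.0)
                if cand.sum() <= 0:
                    step *= 0.5
                    continue
                try:
                    out = _restricted_ll(y, X, assemble(cand))
                except np.linalg.LinAlgError:
                    step *= 0.5
                    continue
                if out[0] >= ll - 1e-12:
                    dpar = float(np.max(np.abs(cand - sig)))
                    sig = cand
                    ll_prev = ll
                    ll, vi, w, xtvx, cx, beta, py = out
                    trajectory.append(ll)
                    accepted = True
                    break
                step *= 0.5
            if accepted:
                break
        if not accepted:
            # no ascent found in either direction: treat as converged at
            # the current (possibly boundary) point
            converged = True
            break
        if abs(ll - ll_prev) < tol_ll * (1.0 + abs(ll)) and dpar < tol_par * (1.0 + sig.max()):
            converged = True
            break

    if not converged:
        raise RemlConvergenceError(
            f"REML did not converge in {max_iter} iterations", trajectory
        )

    beta_cov = cho_solve(cx, np.eye(X.shape[1]))
    return RemlResult(
        sigma2={nm: float(s) for nm, s in zip(names, sig)},
        loglik=float(ll),
        beta=beta,
        beta_cov=beta_cov,
        py=py,
        vi=vi,
        n_iter=it,
        converged=converged,
        trajectory=trajectory,
        boundary=[nm for nm, s in zip(names, sig) if s == 0.0],
    )


def incidence(labels, levels=None) -> tuple[np.ndarray, list]:
    """0/1 incidence matrix mapping observations to factor levels."""
    labels = list(labels)
    if levels is None:
        levels = list(dict.fromkeys(labels))
    idx = {lv: j for j, lv in enumerate(levels)}
    Z = np.zeros((len(labels), len(levels)))
    for i, lab in enumerate(labels):
        Z[i, idx[lab]] = 1.0
    return Z, list(levels)
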