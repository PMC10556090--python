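"""Light-weight Newton solver for the Cox partial likelihood.

Used where the package needs direct access to coefficients and Wald
statistics on a handful of covariates: the univariable gene screen and the
two-component image simulation.  Breslow handling of tied event times.  An
optional L2 (ridge) term stabilizes separable configurations, where the
unpenalized likelihood has no finite maximizer.
"""

from __future__ import annotations

import numpy as np

__all__ = ["CoxFit", "cox_newton", "univariable_cox_z"]


class CoxFit:
    __slots__ = ("beta", "information", "n_iter", "converged")

    def __init__(self, beta, information, n_iter, converged):
        self.beta = beta
        self.information = information
        self.n_iter = n_iter
        self.converged = converged


def _suffix_groups(time: np.ndarray):
    """Ascending order plus, per position, the start of its tied-time block."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    # first index of each run of equal times
    starts = np.zeros(len(t), dtype=int)
    for i in range(1, len(t)):
        starts[i] = starts[i - 1] if t[i] == t[i - 1] else i
    return order, starts


def _loglik_terms(X, event_idx, risk_start, eta):
    """Breslow log partial likelihood plus score and information."""
    n, p = X.shape
    # shift-invariant likelihood; the clip keeps exp from underflowing to an
    # all-zero risk set when coefficients diverge on separable data
    eta = np.clip(eta - eta.max(), -700.0, 0.0)
    w = np.exp(eta)
    # suffix sums over the ascending-time ordering
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum((w[:, None] * X)[::-1], axis=0)[::-1]
    s2 = np.cumsum((w[:, None, None] * (X[:, :, None] * X[:, None, :]))[::-1], axis=0)[::-1]
    r = risk_start[event_idx]
    s0e, s1e, s2e = s0[r], s1[r], s2[r]
    mu = s1e / s0e[:, None]
    ll = float(np.sum(eta[event_idx] - np.log(s0e)))
    score = (X[event_idx] - mu).sum(axis=0)
    info = (s2e / s0e[:, None, None] - mu[:, :, None] * mu[:, None, :]).sum(axis=0)
    return ll, score, info


def cox_newton(
    X,
    time,
    event,
    *,
    ridge: float = 0.0,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> CoxFit:
    """Maximize the (optionally ridge-penalized) Cox partial likelihood.

    Parameters are on the standard proportional-hazards scale: the hazard of
    sample ``i`` is ``h0(t) * exp(X_i @ beta)``.  Returns coefficients and
    the observed information matrix at the optimum.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(int)
    order, starts = _suffix_groups(time)
    Xs = X[order]
    ev = event[order]
    event_idx = np.flatnonzero(ev == 1)
    n, p = Xs.shape
    if event_idx.size == 0:
        raise ValueError("Cox fit requires at least one observed event")

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    info = np.eye(p)
    for it in range(1, max_iter + 1):
        eta = Xs @ beta
        ll, score, info = _loglik_terms(Xs, event_idx, starts, eta)
        if ridge > 0:
            ll -= 0.5 * ridge * float(beta @ beta)
            score = score - ridge * beta
            info = info + ridge * np.eye(p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # step-halving if the update overshoots
        scale = 1.0
        for _ in range(20):
            cand = beta + scale * step
            eta_c = Xs @ cand
            ll_c = _loglik_terms(Xs, event_idx, starts, eta_c)[0]
            if ridge > 0:
                ll_c -= 0.5 * ridge * float(cand @ cand)
            if ll_c >= ll - 1e-12:
                break
            scale *= 0.5
        beta = beta + scale * step
        if abs(ll - ll_prev) < tol * (abs(ll) + 1.0):
            converged = True
            break
        ll_prev = ll
    return CoxFit(beta=beta, information=info, n_iter=it, converged=converged)


def univariable_cox_z(x, time, event, *, ridge: float = 1e-8) -> tuple[float, float]:
    """Coefficient and Wald z of a one-covariate Cox model.

    Returns ``(beta, z)`` with ``z = beta * sqrt(I(beta))``; a covariate with
    no information (constant column) yields ``(0, 0)``.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0.0:
        return 0.0, 0.0
    fit = cox_newton(x[:, None], time, event, ridge=ridge)
    beta = float(fit.beta[0])
    info = float(fit.information[0, 0])
    if info <= 0:
        return beta, 0.0
    return beta, beta * np.sqrt(info)
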