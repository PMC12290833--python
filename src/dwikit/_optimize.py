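"""Shared nonlinear least-squares machinery (Gauss-Newton with step halving)."""

from __future__ import annotations

import numpy as np

__all__ = ["gauss_newton"]


def gauss_newton(predict_jac, beta0, y, weights=None, max_iter: int = 50,
                 gtol: float = 1e-8, max_halvings: int = 20):
    """Minimize ``sum w (y - f(beta))^2`` by Gauss-Newton with step halving.

    Parameters
    ----------
    predict_jac : callable
        ``predict_jac(beta) -> (pred (N,), J (N, P))`` with ``J = d pred/d beta``.
    beta0 : array (P,)
        Starting point (typically an OLS fit of the linearized model).
    y : array (N,)
        Observed signal.
    weights : array (N,), optional
        Non-negative observation weights.
    max_iter : int
        Iteration cap; non-convergence is reported, not raised.
    gtol : float
        Infinity-norm tolerance on the (scaled) gradient ``J^T W r``.

    Returns
    -------
    beta : array (P,)
    converged : bool
    n_iter : int
    """
    beta = np.asarray(beta0, dtype=float).copy()
    y = np.asarray(y, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)

    pred, jac = predict_jac(beta)
    resid = y - pred
    cost = float(np.sum(w * resid ** 2))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = jac.T @ (w * resid)
        # column equilibration keeps the normal matrix well conditioned even
        # when coefficient scales span many orders of magnitude (b^2 terms)
        scale = np.maximum(np.abs(jac).max(axis=0), 1e-300)
        js = jac / scale
        a = js.T @ (w[:, None] * js)
        g = js.T @ (w * resid)
        if np.linalg.norm(grad, np.inf) <= gtol * max(1.0, np.sqrt(cost)):
            converged = True
            break
        try:
            step = np.linalg.solve(a + 1e-14 * np.trace(a) / a.shape[0] * np.eye(a.shape[0]), g)
        except np.linalg.LinAlgError:
            break
        step = step / scale
        # step halving line search
        alpha = 1.0
        improved = False
        for _ in range(max_halvings):
            cand = beta + alpha * step
            pred_c, jac_c = predict_jac(cand)
            resid_c = y - pred_c
            cost_c = float(np.sum(w * resid_c ** 2))
            if np.isfinite(cost_c) and cost_c <= cost:
                improved = cost_c < cost * (1 - 1e-15) or np.linalg.norm(alpha * step) > 0
                beta, pred, jac, resid = cand, pred_c, jac_c, resid_c
                if cost - cost_c <= 1e-15 * max(cost, 1e-300):
                    cost = cost_c
                    converged = True
                else:
                    cost = cost_c
                break
            alpha *= 0.5
        else:
            converged = True  # no descent possible: at a (local) minimum
            break
        if converged:
            break
        if not improved:
            converged = True
            break
    return beta, converged, it
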