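"""Internal weighted logistic solver used in TMLE inner loops.

The cross-validated candidate selection refits small logistic regressions
hundreds of times per dataset; this module provides a minimal Newton/IRLS
solver with observation weights and an offset, which those loops need and
which is validated against ``statsmodels`` in the test suite. Responses may
be fractional in [0, 1] (quasi-binomial), as cluster-level proportions are.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, logit

__all__ = ["fit_logistic", "expit", "logit", "SeparationError"]

_EPS = 1e-10


class SeparationError(RuntimeError):
    """Raised when the logistic fit is degenerate (separation / singular)."""


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    offset: np.ndarray | None = None,
    max_iter: int = 60,
    tol: float = 1e-10,
) -> np.ndarray:
    """Weighted logistic MLE of ``y`` on ``X`` (no implicit intercept).

    Maximizes ``sum_i w_i [y_i log(p_i) + (1-y_i) log(1-p_i)]`` with
    ``p = expit(X beta + offset)`` by Newton's method with step halving.
    Raises :class:`SeparationError` on separation (diverging coefficients)
    or a singular information matrix.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    off = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)

    beta = np.zeros(p)

    def loglik(b: np.ndarray) -> float:
        eta = X @ b + off
        # numerically stable: log(1+exp(eta)) via logaddexp
        return float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))

    ll = loglik(beta)
    for _ in range(max_iter):
        eta = X @ beta + off
        mu = expit(eta)
        grad = X.T @ (w * (y - mu))
        v = w * mu * (1.0 - mu)
        info = X.T @ (X * v[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix in logistic fit") from exc
        # damped Newton: halve until the log-likelihood does not decrease
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new = loglik(cand)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            break
        moved = np.max(np.abs(scale * step))
        beta = cand
        ll = ll_new
        if moved < tol:
            break
    if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > 40.0:
        raise SeparationError("diverging coefficients; data likely separated")
    return beta


def clip_probability(p: np.ndarray | float, lo: float = _EPS, hi: float = 1.0 - _EPS):
    """Clip probabilities away from {0, 1} so the logit is defined."""
    return np.clip(p, lo, hi)
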