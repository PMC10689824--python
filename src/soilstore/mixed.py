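"""Profiled maximum-likelihood fitting of a one-variance-component LMM.

The model is y = X b + Z u + e with a single random intercept per group
(u ~ N(0, sigma2 * lam * I_q), e ~ N(0, sigma2 * I_n)).  For a fixed
variance ratio lam, beta and sigma2 have closed-form GLS solutions, so the
deviance is profiled down to a one-dimensional search over lam >= 0
(log-scale bracket + bounded refinement, tolerance 1e-8 on the deviance).

This stays well behaved in the degenerate corners a general-purpose mixed
solver rejects (zero residual variance, zero group variance), which the
noise-free synthetic checks exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DegenerateDesignError

_SIGMA2_FLOOR = 1e-300


@dataclass
class LMMResult:
    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2: float          # residual variance (ML)
    tau2: float            # random-intercept variance (= lam * sigma2)
    llf: float
    n_obs: int
    warnings: list[str] = field(default_factory=list)


def _profile(lam: float, y: np.ndarray, X: np.ndarray, Z: np.ndarray):
    """GLS estimates and -2 log likelihood at a fixed variance ratio."""
    n = len(y)
    V = np.eye(n) + lam * (Z @ Z.T)
    L = np.linalg.cholesky(V)
    # whiten by L^{-1} so ordinary least squares on (Xt, yt) is GLS on (X, y)
    Xt = np.linalg.solve(L, X)
    yt = np.linalg.solve(L, y)
    XtX = Xt.T @ Xt
    beta, *_ = np.linalg.lstsq(XtX, Xt.T @ yt, rcond=None)
    resid = yt - Xt @ beta
    rss = float(resid @ resid)
    sigma2 = max(rss / n, _SIGMA2_FLOOR)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    dev = n * np.log(2.0 * np.pi * sigma2) + logdet + rss / sigma2
    xtx_inv = np.linalg.pinv(XtX)
    cov_beta = sigma2 * xtx_inv
    return beta, cov_beta, sigma2, dev


def fit_lmm_ml(y, X, groups) -> LMMResult:
    """ML fit of y = X beta + (1 | groups) + error.

    ``groups`` is any label array; ``X`` must include its own intercept
    column.  Returns ML (not REML) estimates, so likelihood-ratio tests on
    nested fixed-effect structures are valid.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != len(X):
        raise DegenerateDesignError("X must be 2-D and conform with y")
    n, p = X.shape
    if n <= p:
        raise DegenerateDesignError(
            f"n_obs = {n} must exceed the {p} fixed-effect parameters"
        )
    labels, idx = np.unique(np.asarray(groups), return_inverse=True)
    Z = np.zeros((n, len(labels)))
    Z[np.arange(n), idx] = 1.0

    def dev_at(log10_lam: float) -> float:
        return _profile(10.0 ** log10_lam, y, X, Z)[3]

    # bracket on a log grid (plus the boundary lam = 0), then refine
    grid = np.linspace(-8.0, 6.0, 29)
    devs = [dev_at(g) for g in grid]
    best = int(np.argmin(devs))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = minimize_scalar(
        dev_at, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-10},
    )
    lam = 10.0 ** float(res.x)
    dev_interior = float(res.fun)
    beta0, cov0, sigma2_0, dev_boundary = _profile(0.0, y, X, Z)
    warnings: list[str] = []
    if dev_boundary <= dev_interior + 1e-8:
        lam, (beta, cov_beta, sigma2, dev) = 0.0, (beta0, cov0, sigma2_0, dev_boundary)
        warnings.append("singular fit: random-intercept variance estimated at zero")
    else:
        beta, cov_beta, sigma2, dev = _profile(lam, y, X, Z)
    return LMMResult(
        beta=beta,
        cov_beta=cov_beta,
        sigma2=sigma2,
        tau2=lam * sigma2,
        llf=-0.5 * dev,
        n_obs=n,
        warnings=warnings,
    )
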