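"""Identity-link Poisson maximum likelihood.

The mean is a *linear* function of the covariates, mu_i = x_i . beta, so
coefficients read directly as additive counts (mutations per unit of
exposure, per year of age). Unlike the canonical log link, the parameter
space is constrained — every fitted mean must stay positive wherever a
positive count was observed — and the likelihood need not be globally
concave. The solver is Fisher scoring with step-halving against the
positivity boundary, started from a non-negative least squares solution
(covariates here are non-negative exposures, so the start is feasible).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

_MU_FLOOR = 1e-300


class FitError(RuntimeError):
    """Raised when the scoring iteration fails to converge."""


@dataclass
class PoissonIdentityFit:
    """MLE of y_i ~ Poisson(x_i . beta) with identity link, no intercept
    unless a constant column is part of X."""

    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_obs: int
    n_iter: int
    converged: bool

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=float) @ self.beta


def _loglik(y: np.ndarray, mu: np.ndarray) -> float:
    # constant term log(y!) omitted throughout
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(y > 0, y * np.log(np.maximum(mu, _MU_FLOOR)), 0.0)
    return float(np.sum(terms) - np.sum(mu))


def fit_poisson_identity(
    X: np.ndarray,
    y: np.ndarray,
    start: np.ndarray | None = None,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PoissonIdentityFit:
    """Fit the identity-link Poisson model by Fisher scoring.

    ``X`` is the (n, p) design (include a constant column for an
    intercept); ``y`` the non-negative counts. Convergence requires the
    relative score to fall below ``tol``. Standard errors come from the
    inverse Fisher information at the optimum.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError("X and y shapes disagree")
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    if n < p:
        raise ValueError(f"need at least {p} observations for {p} parameters")

    if start is None:
        beta, _ = nnls(X, np.maximum(y, 0.5))
        beta = np.asarray(beta, dtype=float)
        if np.any(X @ beta <= 0):
            # fall back to a flat positive mean
            beta = np.linalg.lstsq(X, np.full(n, max(y.mean(), 0.5)), rcond=None)[0]
    else:
        beta = np.asarray(start, dtype=float).copy()
    mu = X @ beta
    if np.any(mu <= 0):
        raise FitError("starting values give non-positive fitted means")

    ll = _loglik(y, mu)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        w = 1.0 / mu  # identity-link Poisson working weights
        score = X.T @ ((y - mu) * w)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise FitError(f"singular information matrix at iteration {it}") from exc
        # step-halve into the feasible region / uphill
        lam = 1.0
        for _ in range(60):
            cand = beta + lam * step
            mu_c = X @ cand
            if np.all(mu_c > 0):
                ll_c = _loglik(y, mu_c)
                if ll_c >= ll - 1e-12:
                    break
            lam *= 0.5
        else:
            raise FitError(f"step-halving failed at iteration {it}")
        beta, mu, ll = cand, mu_c, ll_c
        scale = np.abs(X.T @ (y * (1.0 / np.maximum(mu, _MU_FLOOR)))) + 1.0
        if np.max(np.abs(score) / scale) < tol or np.max(np.abs(lam * step)) < tol * (
            np.max(np.abs(beta)) + tol
        ):
            converged = True
            break
    if not converged:
        raise FitError(
            f"no convergence after {max_iter} iterations (last score norm "
            f"{np.linalg.norm(score):.3g})"
        )
    w = 1.0 / np.maximum(mu, _MU_FLOOR)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    return PoissonIdentityFit(
        beta=beta, cov=cov, loglik=ll, n_obs=n, n_iter=it, converged=True
    )


def brute_force_mle(
    X: np.ndarray,
    y: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    n_grid: int = 200,
    refine: int = 4,
) -> np.ndarray:
    """Grid-search MLE for tiny instances; an independent check on the
    scoring iteration. Repeatedly zooms a rectangular grid around the best
    point."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    lo = np.asarray(lo, dtype=float).copy()
    hi = np.asarray(hi, dtype=float).copy()
    p = X.shape[1]
    best = (lo + hi) / 2
    for _ in range(refine):
        axes = [np.linspace(lo[j], hi[j], n_grid) for j in range(p)]
        mesh = np.meshgrid(*axes, indexing="ij")
        betas = np.stack([m.ravel() for m in mesh], axis=1)
        mu = betas @ X.T
        ok = np.all(mu > 0, axis=1)
        ll = np.full(len(betas), -np.inf)
        mu_ok = mu[ok]
        ll[ok] = np.where(y > 0, y * np.log(mu_ok), 0.0).sum(axis=1) - mu_ok.sum(axis=1)
        best = betas[np.argmax(ll)]
        span = (hi - lo) / n_grid * 4
        lo, hi = best - span, best + span
    return best
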