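"""Restricted-likelihood evaluation for the random-effect model.

The model is ``y = 1*mu + u + e`` with ``Var(u) = 2*K*sigma_a2`` and
``Var(e) = I*sigma_e2``, where the kinship ``K`` is built solely from the
pseudo-QTN dosage columns.  Because ``K`` has rank at most t (the number of
pseudo QTNs), the restricted log-likelihood is evaluated through the
singular value decomposition of the centered pseudo-QTN matrix — cost
linear in n for fixed t — instead of an n x n eigendecomposition.

The restricted log-likelihood is profiled over the intercept and
``sigma_a2`` at a fixed variance ratio ``delta = sigma_e2 / sigma_a2``;
``delta`` itself is optimized by a log-grid search refined with Brent's
method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "KinshipFactor",
    "VarianceComponents",
    "build_kinship_factor",
    "reml_criterion",
    "estimate_variance_components",
]

DELTA_RANGE = (1e-5, 1e5)
GRID_POINTS = 100
#: spread of restricted log-likelihood across the grid below which the
#: optimization is reported as non-converged (flat likelihood, no signal)
FLAT_TOL = 1e-8


@dataclass
class KinshipFactor:
    """Low-rank factor of G/sigma_a2 = 2K built from pseudo-QTN dosages.

    ``left`` (n x k) and ``eigenvalues`` (k) satisfy
    ``2K = left @ diag(eigenvalues) @ left.T`` up to the rank-k truncation;
    K is VanRaden-scaled and rescaled so its mean diagonal is exactly 1.
    """

    left: np.ndarray
    eigenvalues: np.ndarray
    n_samples: int
    marker_indices: np.ndarray
    scale: float  # multiplier applied to ZZ' to obtain 2K

    @property
    def rank(self) -> int:
        return self.eigenvalues.size

    def implied_kinship(self) -> np.ndarray:
        """Dense K (for diagnostics/tests; O(n^2) memory)."""
        two_k = (self.left * self.eigenvalues) @ self.left.T
        return two_k / 2.0


def build_kinship_factor(genotypes, pseudo) -> KinshipFactor:
    """SVD factor of the kinship implied by the pseudo-QTN columns.

    Columns are centered at twice the allele frequency, the cross-product is
    divided by ``sum 2p(1-p)`` and rescaled so the mean diagonal of K is 1.
    Constant columns are dropped with a warning.
    """
    indices = np.asarray(getattr(pseudo, "indices", pseudo), dtype=int)
    if indices.size == 0:
        raise ValueError("kinship requires at least one pseudo QTN")
    z = genotypes.dosages[:, indices].astype(float)
    n = z.shape[0]
    p_hat = z.mean(axis=0) / 2.0
    zc = z - 2.0 * p_hat
    nonconst = zc.std(axis=0) > 0
    if not nonconst.any():
        raise ValueError("degenerate kinship: all pseudo-QTN columns constant")
    if not nonconst.all():
        warnings.warn(
            f"dropping {int((~nonconst).sum())} constant pseudo-QTN columns "
            "from kinship"
        )
        zc = zc[:, nonconst]
        indices = indices[nonconst]
        p_hat = p_hat[nonconst]
    norm = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    if norm <= 0:  # fractional dosages may evade 2p(1-p); fall back to trace
        norm = float(np.sum(zc ** 2)) / n
    diag_mean = float(np.sum(zc ** 2)) / (n * norm)
    scale = 2.0 / (norm * diag_mean)

    u, s, _ = np.linalg.svd(zc, full_matrices=False)
    keep = s > s[0] * 1e-12 if s.size else np.zeros(0, bool)
    return KinshipFactor(
        left=u[:, keep],
        eigenvalues=(s[keep] ** 2) * scale,
        n_samples=n,
        marker_indices=indices,
        scale=scale,
    )


def _profiled_terms(factor: KinshipFactor, y: np.ndarray, delta: float):
    """Inner products against (2K + delta*I)^-1 via the low-rank identity."""
    lam = factor.eigenvalues
    u = factor.left
    n = factor.n_samples
    x = np.ones(n)
    shrink = lam / (lam + delta)

    uy = u.T @ y
    ux = u.T @ x
    yhy = (y @ y - shrink @ (uy ** 2)) / delta
    xhx = (n - shrink @ (ux ** 2)) / delta
    xhy = (x @ y - shrink @ (ux * uy)) / delta
    logdet = float(np.sum(np.log(lam + delta)) + (n - lam.size) * np.log(delta))
    return yhy, xhy, xhx, logdet


def reml_criterion(factor: KinshipFactor, y, delta: float) -> float:
    """Restricted log-likelihood at variance ratio ``delta``, profiled over
    the intercept and ``sigma_a2``."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    y = np.asarray(getattr(y, "values", y), dtype=float)
    if y.shape != (factor.n_samples,):
        raise ValueError("phenotype length does not match kinship factor")
    n = factor.n_samples
    yhy, xhy, xhx, logdet = _profiled_terms(factor, y, delta)
    rhr = yhy - xhy ** 2 / xhx  # residual quadratic form after GLS intercept
    if rhr <= 0:
        rhr = np.finfo(float).tiny
    sigma_a2 = rhr / (n - 1)
    ll = -0.5 * (
        (n - 1) * (np.log(2.0 * np.pi * sigma_a2) + 1.0)
        + logdet
        + np.log(xhx)
        - np.log(float(n))
    )
    if not np.isfinite(ll):
        raise FloatingPointError(f"non-finite restricted likelihood at delta={delta}")
    return float(ll)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    delta: float
    loglik: float
    converged: bool = True


def estimate_variance_components(factor: KinshipFactor, y) -> VarianceComponents:
    """Maximize the restricted log-likelihood over delta.

    A 100-point log grid over [1e-5, 1e5] seeds a bounded Brent refinement.
    A likelihood flat across the whole grid (zero-heritability pathology) is
    flagged ``converged=False``; the caller decides the fallback.
    """
    y = np.asarray(getattr(y, "values", y), dtype=float)
    grid = np.logspace(
        np.log10(DELTA_RANGE[0]), np.log10(DELTA_RANGE[1]), GRID_POINTS
    )
    values = np.array([reml_criterion(factor, y, d) for d in grid])
    best = int(np.argmax(values))
    flat = values.max() - values.min() < FLAT_TOL

    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, grid.size - 1)]
    res = optimize.minimize_scalar(
        lambda logd: -reml_criterion(factor, y, float(np.exp(logd))),
        bounds=(np.log(lo), np.log(hi)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = float(np.exp(res.x))
    loglik = float(-res.fun)
    if values[best] > loglik:  # refinement should never lose to the grid
        delta, loglik = float(grid[best]), float(values[best])

    n = factor.n_samples
    yhy, xhy, xhx, _ = _profiled_terms(factor, y, delta)
    sigma_a2 = max((yhy - xhy ** 2 / xhx) / (n - 1), 0.0)
    return VarianceComponents(
        sigma_a2=sigma_a2,
        sigma_e2=delta * sigma_a2,
        delta=delta,
        loglik=loglik,
        converged=not flat,
    )
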