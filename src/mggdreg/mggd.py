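"""Multivariate generalized Gaussian distribution (MGGD).

The MGGD is an elliptical density with an extra shape parameter ``beta``
controlling peakedness and tail weight,

.. math::

    p(x) = \\frac{\\Gamma(d/2)\\,\\beta}
                {\\Gamma(d/(2\\beta))\\,\\pi^{d/2}\\,2^{d/(2\\beta)}
                 \\,m^{d/2}\\,|\\Sigma|^{1/2}}
           \\exp\\!\\left(-\\frac{[(x-\\mu)^T\\Sigma^{-1}(x-\\mu)]^{\\beta}}
                               {2\\,m^{\\beta}}\\right),

with mean ``mu``, symmetric positive-definite scatter matrix ``Sigma``,
scale ``m > 0`` and shape ``beta > 0``.  ``beta = 1`` recovers the
multivariate Gaussian with covariance ``m * Sigma``; ``beta < 1`` gives a
sharper peak and heavier tails.  Only the product ``C = m * Sigma`` is
identifiable in the density.

This module provides the plain, weighted and Gamma-marginalized densities
(all computed in log space), the stochastic radial sampler, and small
moment utilities.  Everything else in the package builds on it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.special import gammaln

__all__ = [
    "ParameterError",
    "DimensionError",
    "MGGDComponent",
    "PointCloud",
    "mggd_logpdf",
    "mggd_pdf",
    "weighted_logpdf",
    "weighted_pdf",
    "marginal_logpdf",
    "marginal_pdf",
    "sample_mggd",
    "correlation_coefficient",
]

# Mahalanobis term exactly 0 raises y**(beta-1) to a negative power for
# beta < 1; the singularity is removable (measure zero), so clamp.
_Y_FLOOR = 1e-12

_SYM_RTOL = 1e-8


class ParameterError(ValueError):
    """Invalid distribution parameter (non-SPD scatter, m <= 0, ...)."""


class DimensionError(ValueError):
    """Shape mismatch between a point and a distribution."""


def _as_points(x, dim: int) -> np.ndarray:
    """Coerce ``x`` to an (N, dim) float array; accept a single point."""
    arr = np.atleast_2d(np.asarray(x, dtype=float))
    if arr.shape[1] != dim:
        raise DimensionError(
            f"points have dimension {arr.shape[1]}, component has {dim}"
        )
    return arr


@dataclass(frozen=True)
class MGGDComponent:
    """One multivariate generalized Gaussian component.

    Parameters
    ----------
    mean : (d,) array
        Location vector mu.
    scatter : (d, d) array
        Symmetric positive-definite scatter matrix Sigma.
    shape : float
        Shape parameter beta (> 0; the fixed-point estimators assume
        beta <= 1, density evaluation does not).
    scale : float
        Scale parameter m (> 0).
    """

    mean: np.ndarray
    scatter: np.ndarray
    shape: float
    scale: float
    _chol: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        mean = np.asarray(self.mean, dtype=float).ravel()
        scatter = np.asarray(self.scatter, dtype=float)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "scatter", scatter)
        d = mean.size
        if scatter.shape != (d, d):
            raise DimensionError(
                f"scatter has shape {scatter.shape}, expected ({d}, {d})"
            )
        if not np.all(np.isfinite(mean)) or not np.all(np.isfinite(scatter)):
            raise ParameterError("non-finite parameters")
        sym_err = np.abs(scatter - scatter.T)
        tol = _SYM_RTOL * max(1.0, float(np.abs(scatter).max()))
        if sym_err.max() > tol:
            raise ParameterError("scatter matrix is not symmetric")
        try:
            chol = np.linalg.cholesky(scatter)
        except np.linalg.LinAlgError as exc:
            raise ParameterError("scatter matrix is not positive definite") from exc
        object.__setattr__(self, "_chol", chol)
        if not (self.shape > 0):
            raise ParameterError(f"shape must be > 0, got {self.shape}")
        if not (self.scale > 0):
            raise ParameterError(f"scale must be > 0, got {self.scale}")

    @property
    def dim(self) -> int:
        return self.mean.size

    @property
    def full_scatter(self) -> np.ndarray:
        """The identifiable scatter C = m * Sigma."""
        return self.scale * self.scatter

    def mahalanobis_sq(self, x) -> np.ndarray:
        """y_i = (x_i - mu)^T Sigma^{-1} (x_i - mu), floored at 1e-12."""
        pts = _as_points(x, self.dim)
        diff = pts - self.mean
        u = solve_triangular(self._chol, diff.T, lower=True).T
        y = np.einsum("ij,ij->i", u, u)
        return np.maximum(y, _Y_FLOOR)

    def log_norm_const(self, scale: float | np.ndarray | None = None):
        """log of the Eq.-style normalizing constant for a given scale."""
        d = self.dim
        b = self.shape
        m = self.scale if scale is None else scale
        half_logdet = float(np.log(np.diag(self._chol)).sum())
        return (
            gammaln(d / 2.0)
            + np.log(b)
            - gammaln(d / (2.0 * b))
            - (d / 2.0) * np.log(np.pi)
            - (d / (2.0 * b)) * np.log(2.0)
            - (d / 2.0) * np.log(m)
            - half_logdet
        )


@dataclass
class PointCloud:
    """An N x d point set with optional per-point weights and labels."""

    points: np.ndarray
    weights: np.ndarray | None = None
    labels: np.ndarray | None = None

    def __post_init__(self):
        pts = np.atleast_2d(np.asarray(self.points, dtype=float))
        if pts.size == 0:
            raise ValueError("point cloud must contain at least one point")
        if not np.all(np.isfinite(pts)):
            raise ValueError("point cloud contains non-finite coordinates")
        self.points = pts
        if self.weights is not None:
            w = np.asarray(self.weights, dtype=float).ravel()
            if w.size != pts.shape[0]:
                raise ValueError("weights length does not match point count")
            if np.any(w <= 0) or np.any(w > 1):
                raise ValueError("weights must lie in (0, 1]")
            self.weights = w
        if self.labels is not None:
            self.labels = np.asarray(self.labels).ravel()
            if self.labels.size != pts.shape[0]:
                raise ValueError("labels length does not match point count")

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]


def mggd_logpdf(x, comp: MGGDComponent) -> np.ndarray:
    """Log-density of the MGGD at ``x`` ((d,) or (N, d))."""
    y = comp.mahalanobis_sq(x)
    b = comp.shape
    out = comp.log_norm_const() - 0.5 * (y / comp.scale) ** b
    return out if np.ndim(x) > 1 else float(out[0])


def mggd_pdf(x, comp: MGGDComponent) -> np.ndarray:
    """MGGD density at ``x``; strictly positive for finite points."""
    return np.exp(mggd_logpdf(x, comp))


def weighted_logpdf(x, comp: MGGDComponent, w) -> np.ndarray:
    """Log of the weighted density p(x)^w, renormalized.

    A point weight ``w`` in (0, 1] enters the likelihood as ``p(x)^w``,
    which is proportional to the same MGGD with scale ``m * w**(-1/beta)``;
    that rescaled density is what is evaluated here.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ParameterError("weights must be strictly positive")
    y = comp.mahalanobis_sq(x)
    b = comp.shape
    m_eff = comp.scale * w ** (-1.0 / b)
    out = comp.log_norm_const(scale=m_eff) - 0.5 * (y / m_eff) ** b
    scalar = np.ndim(x) <= 1 and w.ndim == 0
    return float(out.ravel()[0]) if scalar else out


def weighted_pdf(x, comp: MGGDComponent, w) -> np.ndarray:
    return np.exp(weighted_logpdf(x, comp, w))


def marginal_logpdf(x, comp: MGGDComponent, a, b) -> np.ndarray:
    """Log of the Gamma-marginalized (heavy-tailed) density.

    Integrating the weighted density against a Gamma(a, b) prior on the
    weight gives a closed-form Student-like density

    .. math::

        \\bar p(x) = \\frac{\\beta\\,\\Gamma(d/2)\\,\\Gamma(a + d/(2\\beta))}
                          {(m\\pi)^{d/2} (2b)^{d/(2\\beta)} |\\Sigma|^{1/2}
                           \\Gamma(a)\\,\\Gamma(d/(2\\beta))}
              \\left(\\frac{y^{\\beta}}{2 b m^{\\beta}} + 1\\right)^{-(a+d/(2\\beta))}

    with ``y`` the Mahalanobis term.  ``a`` and ``b`` may be scalars or
    per-point arrays aligned with ``x``.
    """
    a = np.asarray(a, dtype=float)
    bb = np.asarray(b, dtype=float)
    if np.any(a <= 0) or np.any(bb <= 0):
        raise ParameterError("Gamma prior parameters must be positive")
    d = comp.dim
    beta = comp.shape
    m = comp.scale
    y = comp.mahalanobis_sq(x)
    half_logdet = float(np.log(np.diag(comp._chol)).sum())
    e = a + d / (2.0 * beta)
    out = (
        np.log(beta)
        + gammaln(d / 2.0)
        + gammaln(e)
        - (d / 2.0) * (np.log(m) + np.log(np.pi))
        - (d / (2.0 * beta)) * np.log(2.0 * bb)
        - half_logdet
        - gammaln(a)
        - gammaln(d / (2.0 * beta))
        - e * np.log1p(y**beta / (2.0 * bb * m**beta))
    )
    scalar = np.ndim(x) <= 1 and a.ndim == 0 and bb.ndim == 0
    return float(out.ravel()[0]) if scalar else out


def marginal_pdf(x, comp: MGGDComponent, a, b) -> np.ndarray:
    return np.exp(marginal_logpdf(x, comp, a, b))


def sample_mggd(
    n: int, comp: MGGDComponent, seed=None, rng: np.random.Generator | None = None
) -> PointCloud:
    """Draw ``n`` points from the MGGD by its stochastic representation.

    x = mu + tau * C^{1/2} u with u uniform on the unit d-sphere,
    tau^(2 beta) ~ Gamma(shape = d / (2 beta), scale = 2) and C = m * Sigma.
    The symmetric (eigendecomposition) square root of C is used; the law
    is invariant to that choice.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    d = comp.dim
    beta = comp.shape
    g = rng.standard_normal((n, d))
    u = g / np.linalg.norm(g, axis=1, keepdims=True)
    tau = rng.gamma(shape=d / (2.0 * beta), scale=2.0, size=n) ** (1.0 / (2.0 * beta))
    evals, evecs = np.linalg.eigh(comp.full_scatter)
    c_half = (evecs * np.sqrt(np.maximum(evals, 0.0))) @ evecs.T
    pts = comp.mean + tau[:, None] * (u @ c_half.T)
    return PointCloud(points=pts)


def correlation_coefficient(comp: MGGDComponent) -> float:
    """Correlation coefficient of a 2-D component's full scatter C = m*Sigma.

    Invariant to the scale factor m, so equal to
    Sigma_12 / sqrt(Sigma_11 * Sigma_22).
    """
    if comp.dim != 2:
        raise DimensionError("correlation coefficient is defined for d = 2 only")
    c = comp.full_scatter
    return float(c[0, 1] / np.sqrt(c[0, 0] * c[1, 1]))
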