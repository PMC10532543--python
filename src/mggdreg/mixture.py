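"""Weighted-data EM for MGGD mixtures with MML model selection.

Fits a K-component mixture of multivariate generalized Gaussians in which
every observation carries a weight.  Weights are either fixed numbers in
(0, 1] or, by default, Gamma-distributed random variables whose conjugate
posteriors are updated inside EM (the expectation step splits into an E-Z
step over component labels and an E-W step over weights).  The mean and
scatter of each component are solved by fixed-point iteration, the shape
parameter by damped Newton-Raphson on the profiled expected complete-data
log-likelihood, and the number of components is selected during EM by a
minimum-message-length (MML) criterion whose mixing-weight update
annihilates under-supported components.

The main entry point is :func:`fit`; the individual update operations are
exposed for testing and reuse.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.special import digamma, gammaln, logsumexp, polygamma
from sklearn.cluster import KMeans

from .mggd import (
    MGGDComponent,
    PointCloud,
    marginal_logpdf,
    weighted_logpdf,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EMConfig",
    "MixtureModel",
    "WeightState",
    "ModelCollapseError",
    "kernel_weights",
    "init_model",
    "e_z_step",
    "e_w_step",
    "m_step_pi",
    "update_mu",
    "update_sigma",
    "update_m",
    "update_beta",
    "beta_objective",
    "profile_q",
    "q_function",
    "mml_score",
    "fit",
]

# floor for clamped posterior weights; keeps log w finite
_W_FLOOR = 1e-10

_BETA_MIN, _BETA_MAX = 0.05, 1.0


class ModelCollapseError(RuntimeError):
    """Every mixture component was annihilated (K_max too large for N)."""


@dataclass
class EMConfig:
    """Tuning knobs of the weighted EM fit.

    Defaults follow the method's standard operating point: shape
    initialized at 0.5 (middle of the (0, 1] convergence regime), Gaussian
    kernel weights with sigma = 25 and q = 20 neighbors, Newton learning
    rate 0.1.
    """

    k_max: int = 8
    beta_init: float = 0.5
    kernel_sigma: float = 25.0
    kernel_q: int = 20
    newton_rate: float = 0.1
    fp_tol: float = 1e-6
    newton_tol: float = 1e-5
    mml_tol: float = 1e-4  # relative to |MML| after the first sweep
    fp_max_iter: int = 100
    newton_max_iter: int = 50
    em_max_iter: int = 200
    weight_mode: str = "bayesian"  # or "fixed"
    seed: int | None = None

    def __post_init__(self):
        if self.weight_mode not in ("bayesian", "fixed"):
            raise ValueError("weight_mode must be 'bayesian' or 'fixed'")
        if not (0 < self.beta_init <= 1):
            raise ValueError("beta_init must lie in (0, 1]")
        for name in ("fp_tol", "newton_tol", "mml_tol", "kernel_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MixtureModel:
    """A fitted MGGD mixture: mixing weights plus components."""

    weights_mix: np.ndarray
    components: list[MGGDComponent]

    def __post_init__(self):
        pi = np.asarray(self.weights_mix, dtype=float).ravel()
        if pi.size != len(self.components):
            raise ValueError("weights_mix length must match component count")
        if np.any(pi < 0) or abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("mixing weights must be a probability vector")
        self.weights_mix = pi / pi.sum()

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def dim(self) -> int:
        return self.components[0].dim

    def logpdf(self, x) -> np.ndarray:
        """Mixture log-density at points ``x`` ((N, d) or (d,))."""
        pts = np.atleast_2d(np.asarray(x, dtype=float))
        logs = np.empty((pts.shape[0], self.k))
        for j, (p, c) in enumerate(zip(self.weights_mix, self.components)):
            if p == 0:
                logs[:, j] = -np.inf
            else:
                logs[:, j] = np.log(p) + _comp_logpdf(pts, c)
        out = logsumexp(logs, axis=1)
        return out if np.ndim(x) > 1 else float(out[0])

    def pdf(self, x) -> np.ndarray:
        return np.exp(self.logpdf(x))

    def to_dict(self) -> dict:
        return {
            "dim": self.dim,
            "pi": self.weights_mix.tolist(),
            "components": [
                {
                    "mean": c.mean.tolist(),
                    "scatter": c.scatter.tolist(),
                    "beta": c.shape,
                    "m": c.scale,
                }
                for c in self.components
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureModel":
        comps = [
            MGGDComponent(
                mean=np.array(c["mean"], dtype=float),
                scatter=np.array(c["scatter"], dtype=float),
                shape=float(c["beta"]),
                scale=float(c["m"]),
            )
            for c in d["components"]
        ]
        return cls(weights_mix=np.array(d["pi"], dtype=float), components=comps)


def _comp_logpdf(pts: np.ndarray, comp: MGGDComponent) -> np.ndarray:
    y = comp.mahalanobis_sq(pts)
    return comp.log_norm_const() - 0.5 * (y / comp.scale) ** comp.shape


@dataclass
class WeightState:
    """Gamma prior/posterior bookkeeping for the random-variable weights.

    ``a0``/``b0`` are the fixed per-point prior parameters; ``a_post`` /
    ``b_post`` the per-point, per-component posteriors; ``w_bar`` the
    posterior-mean weights clamped to (0, 1] (the range the fixed-point
    convergence argument requires).
    """

    a0: np.ndarray
    b0: np.ndarray
    a_post: np.ndarray
    b_post: np.ndarray
    w_bar: np.ndarray


# ---------------------------------------------------------------------------
# initialization


def kernel_weights(cloud: PointCloud, sigma: float = 25.0, q: int = 20) -> np.ndarray:
    """Gaussian-kernel density weights from q nearest neighbors.

    w_i = (1/q) * sum_{j in S_iq} exp(-d2(x_i, x_j) / sigma) where d2 is
    the squared Euclidean distance and S_iq the q nearest neighbors of
    x_i excluding x_i itself.  Dense regions get weights near 1, isolated
    points small weights.
    """
    n = cloud.n
    if q < 1 or q >= n:
        raise ValueError(f"q must satisfy 1 <= q < N (got q={q}, N={n})")
    tree = cKDTree(cloud.points)
    dist, _ = tree.query(cloud.points, k=q + 1)
    d2 = dist[:, 1:] ** 2  # drop self (distance zero)
    w = np.exp(-d2 / sigma).mean(axis=1)
    return np.clip(w, _W_FLOOR, 1.0)


def _init_m(y: np.ndarray, beta: float, d: int) -> float:
    """Scale from a pre-cluster: m = [beta/(d n) * sum y^beta]^(1/beta)."""
    return float((beta * np.mean(y**beta) / d) ** (1.0 / beta))


def init_model(
    cloud: PointCloud, config: EMConfig
) -> tuple[MixtureModel, WeightState]:
    """K-means seeding of the mixture plus kernel-weight priors.

    Cluster fractions seed pi, centroids the means, regularized
    within-cluster covariances the scatters; every shape starts at
    ``beta_init`` and each scale comes from the pre-cluster scale formula.
    The Gamma priors are set to a_i = w_i**2, b_i = w_i so that
    E[w] = w_i and Var[w] = 1.
    """
    X = cloud.points
    n, d = X.shape
    k_max = config.k_max
    min_n = k_max * (d + 1)
    if n < min_n:
        k_max = max(1, n // (d + 1))
        warnings.warn(
            f"N={n} too small for k_max={config.k_max}; reduced to {k_max}",
            stacklevel=2,
        )
    km = KMeans(n_clusters=k_max, n_init=10, random_state=config.seed)
    labels = km.fit_predict(X)

    if cloud.weights is not None:
        w = np.clip(cloud.weights, _W_FLOOR, 1.0)
    else:
        w = kernel_weights(cloud, sigma=config.kernel_sigma, q=config.kernel_q)

    pis, comps = [], []
    for k in range(k_max):
        mask = labels == k
        nk = int(mask.sum())
        if nk == 0:
            raise RuntimeError("k-means produced an empty cluster")
        xk = X[mask]
        mu = xk.mean(axis=0)
        diff = xk - mu
        sigma = diff.T @ diff / max(nk, 1)
        sigma += 1e-6 * (np.trace(sigma) / d + 1e-12) * np.eye(d)
        comp = MGGDComponent(mean=mu, scatter=sigma, shape=config.beta_init, scale=1.0)
        y = comp.mahalanobis_sq(xk)
        m = _init_m(y, config.beta_init, d)
        comps.append(
            MGGDComponent(mean=mu, scatter=sigma, shape=config.beta_init, scale=m)
        )
        pis.append(nk / n)

    model = MixtureModel(weights_mix=np.array(pis), components=comps)
    a0 = w**2
    b0 = w.copy()
    wstate = WeightState(
        a0=a0,
        b0=b0,
        a_post=np.repeat(a0[:, None], k_max, axis=1),
        b_post=np.repeat(b0[:, None], k_max, axis=1),
        w_bar=np.repeat(w[:, None], k_max, axis=1),
    )
    return model, wstate


# ---------------------------------------------------------------------------
# E steps


def e_z_step(
    cloud: PointCloud,
    model: MixtureModel,
    wstate: WeightState,
    config: EMConfig,
) -> np.ndarray:
    """Responsibilities eta (N x K), rows normalized by log-sum-exp.

    Bayesian mode weighs each component by the Gamma-marginalized density
    at the carried-forward per-point, per-component weight posteriors
    (eta_ik proportional to pi_k * p_bar(x_i; theta_k, a_ik, b_ik); the
    weight posterior of one iteration acts as the prior of the next, the
    conjugate-update workflow).  Fixed mode uses the weighted density at
    the fixed weights E[w] = a0/b0.

    Evaluating the marginal at the initial prior instead is a coherent
    alternative reading of the E-step; it recovers mixing weights
    slightly better on heavy-tailed components but drags the shape
    estimates onto the upper bound of their domain, so the
    posterior-as-prior convention is used.
    """
    X = cloud.points
    n = X.shape[0]
    K = model.k
    log_eta = np.full((n, K), -np.inf)
    for k in range(K):
        pi_k = model.weights_mix[k]
        if pi_k <= 0:
            continue
        comp = model.components[k]
        if config.weight_mode == "bayesian":
            lp = marginal_logpdf(X, comp, wstate.a_post[:, k], wstate.b_post[:, k])
        else:
            lp = weighted_logpdf(X, comp, wstate.a0 / wstate.b0)
        log_eta[:, k] = np.log(pi_k) + lp
    norm = logsumexp(log_eta, axis=1)
    bad = ~np.isfinite(norm)
    if np.any(bad):
        logger.warning("%d responsibility rows underflowed; set uniform", bad.sum())
        active = model.weights_mix > 0
        log_eta[bad] = np.where(active, 0.0, -np.inf)
        norm = logsumexp(log_eta, axis=1)
    eta = np.exp(log_eta - norm[:, None])
    return eta


def e_w_step(
    cloud: PointCloud, model: MixtureModel, wstate: WeightState
) -> WeightState:
    """Conjugate Gamma posterior update of the per-point weights.

    a_ik = a0_i + d/(2 beta_k); b_ik = b0_i + y_ik^beta_k / (2 m_k^beta_k).
    The posterior mean a_ik/b_ik is clamped to (0, 1] before use in the
    fixed-point updates; clamping is monotone, so the outlier ordering
    (larger Mahalanobis term -> smaller weight) is preserved.
    """
    X = cloud.points
    d = X.shape[1]
    a_post = wstate.a_post.copy()
    b_post = wstate.b_post.copy()
    for k, comp in enumerate(model.components):
        if model.weights_mix[k] <= 0:
            continue
        y = comp.mahalanobis_sq(X)
        beta = comp.shape
        a_post[:, k] = wstate.a0 + d / (2.0 * beta)
        b_post[:, k] = wstate.b0 + y**beta / (2.0 * comp.scale**beta)
    w_bar = np.clip(a_post / b_post, _W_FLOOR, 1.0)
    return WeightState(
        a0=wstate.a0, b0=wstate.b0, a_post=a_post, b_post=b_post, w_bar=w_bar
    )


# ---------------------------------------------------------------------------
# M steps


def m_step_pi(eta: np.ndarray, k_plus: int, M: int) -> np.ndarray:
    """MML mixing-weight update with component annihilation.

    pi_k = max(0, sum_i eta_ik - M*K+/2), normalized.  Components whose
    support falls below the threshold get pi = 0 and are excluded from
    K+ afterwards.
    """
    if k_plus < 1:
        raise ValueError("k_plus must be >= 1")
    support = eta.sum(axis=0)
    num = np.maximum(0.0, support - M * k_plus / 2.0)
    total = num.sum()
    if total <= 0:
        raise ModelCollapseError(
            "all components fell below the MML support threshold"
        )
    return num / total


def update_mu(
    cloud: PointCloud,
    comp: MGGDComponent,
    eta_k: np.ndarray,
    w_k: np.ndarray,
    fp_tol: float = 1e-6,
    fp_max_iter: int = 100,
) -> np.ndarray:
    mu, ok = _fp_mu(
        cloud.points, comp.mean, comp._chol, comp.shape, eta_k, w_k, fp_tol, fp_max_iter
    )
    if not ok:
        logger.warning("mean fixed-point did not converge in %d iters", fp_max_iter)
    return mu


def _maha(X, mu, chol):
    from scipy.linalg import solve_triangular

    diff = X - mu
    u = solve_triangular(chol, diff.T, lower=True).T
    return np.maximum(np.einsum("ij,ij->i", u, u), 1e-12)


def _fp_mu(X, mu0, chol, beta, eta_k, w_k, fp_tol, fp_max_iter):
    """Fixed point mu <- sum(eta w y^(beta-1) x) / sum(eta w y^(beta-1))."""
    mu = mu0.copy()
    ew = eta_k * w_k
    for _ in range(fp_max_iter):
        y = _maha(X, mu, chol)
        c = ew * y ** (beta - 1.0)
        mu_new = (c[:, None] * X).sum(axis=0) / c.sum()
        if np.linalg.norm(mu_new - mu) < fp_tol:
            return mu_new, True
        mu = mu_new
    return mu, False


def update_sigma(
    cloud: PointCloud,
    comp: MGGDComponent,
    eta_k: np.ndarray,
    w_k: np.ndarray,
    fp_tol: float = 1e-6,
    fp_max_iter: int = 100,
    mu: np.ndarray | None = None,
) -> np.ndarray:
    mu = comp.mean if mu is None else mu
    sig, ok = _fp_sigma(
        cloud.points, mu, comp.scatter, comp.shape, eta_k, w_k, fp_tol, fp_max_iter
    )
    if not ok:
        logger.warning("scatter fixed-point did not converge in %d iters", fp_max_iter)
    return sig


def _fp_sigma(X, mu, sigma0, beta, eta_k, w_k, fp_tol, fp_max_iter):
    """Scale-free fixed point for the scatter matrix.

    Sigma <- d * sum(eta w y^(beta-1) (x-mu)(x-mu)^T) / sum(eta w y^beta),
    symmetrized each pass; a small ridge restores positive definiteness
    if an iterate loses it.
    """
    d = X.shape[1]
    sigma = sigma0.copy()
    diff = X - mu
    ew = eta_k * w_k
    ok = False
    for _ in range(fp_max_iter):
        chol = np.linalg.cholesky(sigma)
        y = _maha(X, mu, chol)
        c = ew * y ** (beta - 1.0)
        num = d * np.einsum("i,ij,ik->jk", c, diff, diff)
        den = float((ew * y**beta).sum())
        sigma_new = num / den
        sigma_new = 0.5 * (sigma_new + sigma_new.T)
        try:
            np.linalg.cholesky(sigma_new)
        except np.linalg.LinAlgError:
            sigma_new += 1e-8 * (np.trace(sigma_new) / d) * np.eye(d)
        if np.linalg.norm(sigma_new - sigma, ord="fro") < fp_tol:
            sigma = sigma_new
            ok = True
            break
        sigma = sigma_new
    return sigma, ok


def update_m(
    cloud: PointCloud,
    comp: MGGDComponent,
    eta_k: np.ndarray,
    w_k: np.ndarray,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
    beta: float | None = None,
) -> float:
    """Closed-form scale update m = [beta sum(eta w y^beta)/(d sum eta)]^(1/beta)."""
    X = cloud.points
    d = X.shape[1]
    mu = comp.mean if mu is None else mu
    sigma = comp.scatter if sigma is None else sigma
    beta = comp.shape if beta is None else beta
    chol = np.linalg.cholesky(sigma)
    y = _maha(X, mu, chol)
    num = beta * float((eta_k * w_k * y**beta).sum())
    den = d * float(eta_k.sum())
    return float((num / den) ** (1.0 / beta))


# ---------------------------------------------------------------------------
# shape parameter: profiled objective and Newton-Raphson


def _beta_sums(beta, y, eta_k, w_k):
    logy = np.log(y)
    t = eta_k * w_k * y**beta
    s0 = float(t.sum())
    s1 = float((t * logy).sum())
    s2 = float((t * logy**2).sum())
    return s0, s1, s2


def profile_q(beta: float, y: np.ndarray, eta_k: np.ndarray, w_k: np.ndarray, d: int) -> float:
    """Per-component expected log-likelihood with the scale profiled out.

    Substituting the closed-form scale update m(beta) into the Q function
    leaves a one-dimensional criterion in beta; its stationary point is
    what the Newton iteration targets.  Terms independent of beta are
    dropped.
    """
    nk = float(eta_k.sum())
    s0, _, _ = _beta_sums(beta, y, eta_k, w_k)
    L = float((eta_k * np.log(w_k)).sum())
    r = d / (2.0 * beta)
    return (
        nk * np.log(beta)
        + r * L
        - nk * gammaln(r)
        - nk * r * np.log(2.0)
        - nk * r * np.log(beta * s0 / (d * nk))
        - nk * r
    )


def beta_objective(
    beta: float, y: np.ndarray, eta_k: np.ndarray, w_k: np.ndarray, d: int
) -> tuple[float, float]:
    """(f, f') where f(beta) = d(profile_q)/d(beta).

    Derived by differentiating the profiled Q function; the digamma /
    trigamma terms come from the Gamma normalizing constant.
    """
    nk = float(eta_k.sum())
    L = float((eta_k * np.log(w_k)).sum())
    s0, s1, s2 = _beta_sums(beta, y, eta_k, w_k)
    r = d / (2.0 * beta)
    psi = digamma(r)
    psi1 = polygamma(1, r)
    g = psi + np.log(2.0) + np.log(beta * s0 / (d * nk))
    f = (
        nk / beta
        - d * L / (2.0 * beta**2)
        + (nk * d / (2.0 * beta**2)) * g
        - (d * nk / (2.0 * beta)) * s1 / s0
    )
    g_prime = -(d / (2.0 * beta**2)) * psi1 + 1.0 / beta + s1 / s0
    h_prime = (
        s2 / (beta * s0) - s1 / (beta**2 * s0) - s1**2 / (beta * s0**2)
    )
    f_prime = (
        -nk / beta**2
        + d * L / beta**3
        - (nk * d / beta**3) * g
        + (nk * d / (2.0 * beta**2)) * g_prime
        - (d * nk / 2.0) * h_prime
    )
    return float(f), float(f_prime)


def update_beta(
    cloud: PointCloud,
    comp: MGGDComponent,
    eta_k: np.ndarray,
    w_k: np.ndarray,
    config: EMConfig,
    mu: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> float:
    """Damped Newton-Raphson for the shape parameter on [0.05, 1].

    beta <- beta - xi * f / f'; the learning rate xi (default 0.1) is
    halved whenever |f| grows between iterates (exponential decay), which
    damps the oscillation the raw iteration is prone to.
    """
    X = cloud.points
    d = X.shape[1]
    mu = comp.mean if mu is None else mu
    sigma = comp.scatter if sigma is None else sigma
    chol = np.linalg.cholesky(sigma)
    y = _maha(X, mu, chol)

    beta = float(np.clip(comp.shape, _BETA_MIN, _BETA_MAX))
    xi = config.newton_rate
    f, fp = beta_objective(beta, y, eta_k, w_k, d)
    best_beta, best_f = beta, abs(f)
    for _ in range(config.newton_max_iter):
        if abs(fp) < 1e-12:
            xi *= 0.5
            step = -np.sign(f) * xi * 0.05
        else:
            step = -xi * f / fp
        beta_new = float(np.clip(beta + step, _BETA_MIN, _BETA_MAX))
        if abs(beta_new - beta) < config.newton_tol:
            beta = beta_new
            f, fp = beta_objective(beta, y, eta_k, w_k, d)
            if abs(f) < best_f:
                best_beta, best_f = beta, abs(f)
            return best_beta
        f_new, fp_new = beta_objective(beta_new, y, eta_k, w_k, d)
        if abs(f_new) > abs(f):
            xi *= 0.5  # exponential decay on oscillation
        beta, f, fp = beta_new, f_new, fp_new
        if abs(f) < best_f:
            best_beta, best_f = beta, abs(f)
    logger.debug("beta Newton hit max iterations; returning best iterate")
    return best_beta


# ---------------------------------------------------------------------------
# objective and model selection


def q_function(
    cloud: PointCloud,
    model: MixtureModel,
    wstate: WeightState,
    eta: np.ndarray,
    weight_mode: str = "bayesian",
) -> float:
    """Expected complete-data log-likelihood with posterior-mean weights.

    Q = sum_ik eta_ik [ln pi_k + ln p_hat(x_i; theta_k, w_bar_ik)] where
    p_hat is the weighted density; in fixed mode w_bar is replaced by the
    fixed weights.
    """
    X = cloud.points
    total = 0.0
    for k, comp in enumerate(model.components):
        pi_k = model.weights_mix[k]
        if pi_k <= 0:
            continue
        ek = eta[:, k]
        w = wstate.w_bar[:, k] if weight_mode == "bayesian" else wstate.a0 / wstate.b0
        lp = weighted_logpdf(X, comp, w)
        total += float((ek * (np.log(pi_k) + lp)).sum())
    return total


def free_parameters_per_component(d: int) -> int:
    """Mean (d) + scatter (d(d+1)/2) + shape + scale."""
    return d + d * (d + 1) // 2 + 2


@dataclass
class MMLScore:
    value: float
    k_plus: int
    M: int
    n: int


def mml_score(model: MixtureModel, q_value: float, n: int, M: int) -> MMLScore:
    """Minimum-message-length criterion (lower is better).

    value = (M/2) * sum_{k in K+} log pi_k - Q
            + K+ (M+1)/2 * (1 + log(n/12)).
    Empty (pi = 0) components contribute nothing.
    """
    pi = model.weights_mix
    active = pi > 0
    k_plus = int(active.sum())
    if k_plus < 1:
        raise ValueError("model must have at least one non-empty component")
    value = (
        (M / 2.0) * float(np.log(pi[active]).sum())
        - q_value
        + (k_plus * (M + 1) / 2.0) * (1.0 + np.log(n / 12.0))
    )
    return MMLScore(value=float(value), k_plus=k_plus, M=M, n=n)


# ---------------------------------------------------------------------------
# full component-wise EM


def fit(
    cloud: PointCloud, config: EMConfig | None = None
) -> tuple[MixtureModel, WeightState, dict]:
    """Fit a weighted MGGD mixture with component-wise EM and MML pruning.

    Each sweep visits the components in turn: responsibilities and weight
    posteriors are refreshed, the MML mixing-weight update annihilates
    under-supported components, and surviving components get fixed-point
    mean/scatter, Newton shape and closed-form scale updates.  When the
    MML score stabilizes at the current K, the search turns to model
    selection: every surviving component is tried for annihilation, the
    sweeps re-converge in each branch, and the branch with the lowest
    MML score is adopted, down to a single component.  The model
    returned is the one with the minimum MML score over the whole
    trajectory.  (Annihilating the weakest component unconditionally is
    cheaper but brittle here: when a genuine component is removed, the
    data weights mask its orphaned points as outliers instead of letting
    a neighboring component migrate, so the search would skip the good
    smaller model.)

    Returns the pruned mixture (non-empty components only), the matching
    weight state, and a report with the MML trajectory and convergence
    flags.
    """
    if config is None:
        config = EMConfig()
    model, wstate = init_model(cloud, config)
    X = cloud.points
    n, d = X.shape
    M = free_parameters_per_component(d)

    pi = model.weights_mix.copy()
    comps = list(model.components)
    mml_history: list[float] = []
    k_history: list[int] = []
    mml_ref = None
    n_sweeps = 0
    converged = False
    best: tuple[float, np.ndarray, list, WeightState] | None = None

    def one_sweep(pi, comps, wstate):
        for k in range(len(comps)):
            if pi[k] <= 0:
                continue
            model = MixtureModel(weights_mix=pi, components=comps)
            eta = e_z_step(cloud, model, wstate, config)
            k_plus = int((pi > 0).sum())
            wstate = e_w_step(cloud, model, wstate)
            pi = m_step_pi(eta, k_plus, M)
            if pi[k] <= 0:
                continue
            comp = comps[k]
            eta_k = eta[:, k]
            if eta_k.sum() <= d:  # not enough support to estimate a scatter
                continue
            w_k = (
                wstate.w_bar[:, k]
                if config.weight_mode == "bayesian"
                else np.clip(wstate.a0 / wstate.b0, _W_FLOOR, 1.0)
            )
            mu = _fp_mu(
                X, comp.mean, comp._chol, comp.shape, eta_k, w_k,
                config.fp_tol, config.fp_max_iter,
            )[0]
            sigma = _fp_sigma(
                X, mu, comp.scatter, comp.shape, eta_k, w_k,
                config.fp_tol, config.fp_max_iter,
            )[0]
            tmp = MGGDComponent(mean=mu, scatter=sigma, shape=comp.shape, scale=comp.scale)
            beta = update_beta(cloud, tmp, eta_k, w_k, config)
            m = update_m(cloud, tmp, eta_k, w_k, beta=beta)
            comps[k] = MGGDComponent(mean=mu, scatter=sigma, shape=beta, scale=m)
        return pi, comps, wstate

    def converge(pi, comps, wstate, record=True):
        """Sweep at the current K until |delta MML| settles; returns the
        final state and its score."""
        nonlocal n_sweeps, mml_ref, converged
        mml_prev = np.inf
        score = None
        while n_sweeps < config.em_max_iter:
            n_sweeps += 1
            pi, comps, wstate = one_sweep(pi, comps, wstate)
            model = MixtureModel(weights_mix=pi, components=comps)
            eta = e_z_step(cloud, model, wstate, config)
            q_val = q_function(cloud, model, wstate, eta, config.weight_mode)
            score = mml_score(model, q_val, n, M)
            if record:
                mml_history.append(score.value)
                k_history.append(score.k_plus)
            if mml_ref is None:
                mml_ref = max(abs(score.value), 1.0)
            if abs(score.value - mml_prev) < config.mml_tol * mml_ref:
                converged = True
                break
            mml_prev = score.value
        return pi, comps, wstate, score

    pi, comps, wstate, score = converge(pi, comps, wstate)
    best = (score.value, pi.copy(), list(comps), wstate)

    # backward model selection: branch on every candidate annihilation,
    # re-converge each branch, and adopt the one with the lowest MML
    while int((pi > 0).sum()) > 1 and n_sweeps < config.em_max_iter:
        branch_best = None
        for j in np.flatnonzero(pi > 0):
            pi_j = pi.copy()
            pi_j[j] = 0.0
            pi_j /= pi_j.sum()
            out = converge(pi_j, list(comps), wstate, record=False)
            if out[3] is None:
                continue
            if branch_best is None or out[3].value < branch_best[3].value:
                branch_best = out
        if branch_best is None:
            break
        pi, comps, wstate, score = branch_best
        mml_history.append(score.value)
        k_history.append(score.k_plus)
        if score.value < best[0]:
            best = (score.value, pi.copy(), list(comps), wstate)
    _, pi, comps, wstate = best
    active = np.flatnonzero(pi > 0)
    final = MixtureModel(
        weights_mix=pi[active], components=[comps[j] for j in active]
    )
    final_wstate = WeightState(
        a0=wstate.a0,
        b0=wstate.b0,
        a_post=wstate.a_post[:, active],
        b_post=wstate.b_post[:, active],
        w_bar=wstate.w_bar[:, active],
    )
    report = {
        "iterations": n_sweeps,
        "converged": converged,
        "mml_history": mml_history,
        "k_history": k_history,
        "k_plus": int(active.size),
        "best_mml": best[0],
        "seed": config.seed,
        "weight_mode": config.weight_mode,
    }
    return final, final_wstate, report
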