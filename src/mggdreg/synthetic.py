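"""Synthetic MGGD-mixture benchmarks.

Generators for the conditions every stage of the package is tested
under: two reference 2-D mixtures (a four-component and a
three-component design with fixed means, full scatters and shapes),
uniform noise contamination over a fixed box, sampling-rate-mismatched
registration pairs under a known rigid transform, and a near-centrally-
symmetric "trap" cloud whose 180-degree rotation is distinguishable only
through one small component.

The reference designs specify the identifiable full scatter
C = m * Sigma; the generator factors it as m = det(C)^(1/d) and
Sigma = C / m (unit-determinant Sigma).  The density depends on C only,
so the factorization is a pure convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mggd import MGGDComponent, PointCloud, sample_mggd
from .registration import RigidTransform, transform_points

__all__ = [
    "MixtureSpec",
    "ScenarioSpec",
    "four_component_spec",
    "three_component_spec",
    "noise_base_spec",
    "symmetric_trap_spec",
    "make_mixture_dataset",
    "add_uniform_noise",
    "make_registration_pair",
    "make_symmetric_trap",
    "NOISE_BOX",
    "PRESETS",
]

# the box uniform contamination is drawn on, per axis
NOISE_BOX = (-5.25, 5.25)


@dataclass
class MixtureSpec:
    """Generating parameters of a synthetic MGGD mixture.

    ``scatters`` holds the identifiable full scatters C_k = m_k Sigma_k;
    ``counts`` the per-component sample sizes (their proportions are the
    mixing weights).
    """

    means: np.ndarray  # (K, d)
    scatters: np.ndarray  # (K, d, d)
    shapes: np.ndarray  # (K,)
    counts: np.ndarray  # (K,)

    def __post_init__(self):
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.scatters = np.asarray(self.scatters, dtype=float)
        self.shapes = np.asarray(self.shapes, dtype=float).ravel()
        self.counts = np.asarray(self.counts, dtype=int).ravel()
        k, d = self.means.shape
        if self.scatters.shape != (k, d, d):
            raise ValueError("scatters shape must be (K, d, d)")
        if self.shapes.size != k or self.counts.size != k:
            raise ValueError("shapes/counts must have one entry per component")
        if np.any(self.counts < 1):
            raise ValueError("every component needs at least one sample")
        for c in self.scatters:
            np.linalg.cholesky(c)  # raises if not SPD

    @property
    def k(self) -> int:
        return self.means.shape[0]

    @property
    def dim(self) -> int:
        return self.means.shape[1]

    @property
    def pis(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def components(self) -> list[MGGDComponent]:
        """Factor each C into (m, Sigma) with unit-determinant Sigma."""
        d = self.dim
        out = []
        for c, beta in zip(self.scatters, self.shapes):
            m = float(np.linalg.det(c)) ** (1.0 / d)
            out.append(
                MGGDComponent(
                    mean=np.zeros(d), scatter=c / m, shape=float(beta), scale=m
                )
            )
        return [
            MGGDComponent(mean=mu, scatter=c.scatter, shape=c.shape, scale=c.scale)
            for mu, c in zip(self.means, out)
        ]

    def scaled(self, n_total: int, rng: np.random.Generator) -> "MixtureSpec":
        """Same mixture with component counts ~ Multinomial(n_total, pi)."""
        counts = rng.multinomial(n_total, self.pis)
        counts = np.maximum(counts, 1)
        return MixtureSpec(
            means=self.means, scatters=self.scatters, shapes=self.shapes, counts=counts
        )


@dataclass
class ScenarioSpec:
    """A registration scenario: base mixture, contamination, ground truth."""

    base: MixtureSpec
    transform: RigidTransform
    scene_n: int = 1200
    model_n: int = 800
    noise_fraction: float = 0.0
    noise_bounds: tuple[float, float] = NOISE_BOX

    def __post_init__(self):
        if not (0 <= self.noise_fraction < 1):
            raise ValueError("noise_fraction must lie in [0, 1)")
        if self.scene_n < 1 or self.model_n < 1:
            raise ValueError("scene_n and model_n must be >= 1")


def four_component_spec() -> MixtureSpec:
    """Four equally weighted components, shape 0.85, 300 points each."""
    return MixtureSpec(
        means=[[1, 1], [15, 2], [1, 18], [16, 16]],
        scatters=[
            [[3, 1], [1, 5]],
            [[2, 0], [0, 2]],
            [[3, -2], [-2, 4]],
            [[3, -1], [-1, 3]],
        ],
        shapes=[0.85, 0.85, 0.85, 0.85],
        counts=[300, 300, 300, 300],
    )


def three_component_spec() -> MixtureSpec:
    """Three components with mixing 0.25/0.25/0.50 (300/300/600 points)."""
    return MixtureSpec(
        means=[[8, 16], [15, 2], [1, 3]],
        scatters=[
            [[3, -2], [-2, 4]],
            [[2, 0], [0, 2]],
            [[3, 1], [1, 5]],
        ],
        shapes=[0.60, 0.85, 0.85],
        counts=[300, 300, 600],
    )


def noise_base_spec() -> MixtureSpec:
    """Three-component mixture living inside the contamination box.

    Used for the noise-robustness experiments, where uniform clutter is
    added over the primary distribution area [-5.25, 5.25]^2.
    """
    return MixtureSpec(
        means=[[-2.5, 2.5], [2.5, 2.5], [0.0, -2.5]],
        scatters=[
            [[0.8, 0.2], [0.2, 1.0]],
            [[0.7, 0.0], [0.0, 0.7]],
            [[1.0, -0.3], [-0.3, 0.8]],
        ],
        shapes=[0.85, 0.85, 0.85],
        counts=[300, 300, 600],
    )


def symmetric_trap_spec(
    n: int = 1200, asymmetry_fraction: float = 0.05
) -> MixtureSpec:
    """Mixture invariant under a 180-degree rotation about the origin,
    except for one small symmetry-breaking component.

    Four components form two antipodal pairs (a rotation by pi maps each
    onto its twin; their scatters are invariant since (-I) C (-I)^T = C),
    one sits at the center, and a small component holding
    ``asymmetry_fraction`` of the points breaks the symmetry.
    """
    if not (0 < asymmetry_fraction < 0.5):
        raise ValueError("asymmetry_fraction must lie in (0, 0.5)")
    n_asym = max(int(round(asymmetry_fraction * n)), 1)
    # antipodal pairs at unequal radii and weights so that only the
    # 180-degree rotation (not e.g. 90 degrees) maps the symmetric part
    # onto itself; blobs kept well separated so mixture fits of
    # independent draws are stable
    n_b = int(round(0.205 * n))
    n_a = (n - n_asym - 2 * n_b) // 2
    n_asym = n - 2 * n_a - 2 * n_b  # absorb rounding
    c_a = [[1.0, 0.25], [0.25, 0.7]]
    c_b = [[0.45, -0.12], [-0.12, 0.8]]
    return MixtureSpec(
        means=[[-4.5, 0], [4.5, 0], [0, -3.0], [0, 3.0], [2.8, 2.8]],
        scatters=[c_a, c_a, c_b, c_b, [[0.22, 0], [0, 0.22]]],
        shapes=[0.85] * 5,
        counts=[n_a, n_a, n_b, n_b, n_asym],
    )


def make_mixture_dataset(
    spec: MixtureSpec, seed=None, rng: np.random.Generator | None = None
) -> tuple[PointCloud, np.ndarray]:
    """Sample every component of ``spec``; returns the cloud and labels."""
    if rng is None:
        rng = np.random.default_rng(seed)
    parts, labels = [], []
    for k, comp in enumerate(spec.components()):
        nk = int(spec.counts[k])
        parts.append(sample_mggd(nk, comp, rng=rng).points)
        labels.append(np.full(nk, k))
    pts = np.vstack(parts)
    lab = np.concatenate(labels)
    cloud = PointCloud(points=pts, labels=lab)
    return cloud, lab


def add_uniform_noise(
    cloud: PointCloud,
    fraction: float,
    bounds: tuple[float, float] = NOISE_BOX,
    seed=None,
    rng: np.random.Generator | None = None,
) -> PointCloud:
    """Append round(fraction * N) uniform clutter points (label -1).

    ``fraction`` is the clutter count relative to the clean count, not
    the clutter share of the output.
    """
    if not (0 <= fraction < 1):
        raise ValueError("fraction must lie in [0, 1)")
    lo, hi = bounds
    if not (hi > lo):
        raise ValueError("empty noise bounds")
    if fraction == 0:
        return cloud
    if rng is None:
        rng = np.random.default_rng(seed)
    n_noise = int(round(fraction * cloud.n))
    noise = rng.uniform(lo, hi, size=(n_noise, cloud.dim))
    labels = cloud.labels if cloud.labels is not None else np.zeros(cloud.n, dtype=int)
    return PointCloud(
        points=np.vstack([cloud.points, noise]),
        labels=np.concatenate([labels, np.full(n_noise, -1)]),
    )


def make_registration_pair(
    spec: ScenarioSpec, seed=None, rng: np.random.Generator | None = None
) -> tuple[PointCloud, PointCloud, RigidTransform]:
    """Scene and model clouds whose registration should recover ``truth``.

    The scene is drawn from the base mixture (plus optional clutter); the
    model cloud is an independent draw, also contaminated, then mapped
    through the inverse of the ground-truth transform, so applying the
    recovered transform to the model cloud should reproduce the scene's
    frame.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    scene, _ = make_mixture_dataset(spec.base.scaled(spec.scene_n, rng), rng=rng)
    model, _ = make_mixture_dataset(spec.base.scaled(spec.model_n, rng), rng=rng)
    if spec.noise_fraction > 0:
        scene = add_uniform_noise(
            scene, spec.noise_fraction, spec.noise_bounds, rng=rng
        )
        model = add_uniform_noise(
            model, spec.noise_fraction, spec.noise_bounds, rng=rng
        )
    model = transform_points(model, spec.transform.inverse())
    return scene, model, spec.transform


def make_symmetric_trap(
    n: int = 1200, asymmetry_n: int | None = None, seed=None,
    rng: np.random.Generator | None = None,
) -> PointCloud:
    """A near-centrally-symmetric cloud with one symmetry-breaking cluster.

    ``asymmetry_n`` defaults to 5% of ``n`` (the 'one point' that tells
    the true orientation from its 180-degree rotation).
    """
    frac = 0.05 if asymmetry_n is None else asymmetry_n / n
    cloud, _ = make_mixture_dataset(symmetric_trap_spec(n, frac), seed=seed, rng=rng)
    return cloud


def _default_truth() -> RigidTransform:
    return RigidTransform.from_angle(0.7, [4.0, -3.0])


PRESETS = {
    "four_component": lambda: ("mixture", four_component_spec(), None),
    "three_component": lambda: ("mixture", three_component_spec(), None),
    "noise10": lambda: ("noisy_mixture", noise_base_spec(), 0.10),
    "noise20": lambda: ("noisy_mixture", noise_base_spec(), 0.20),
    "noise30": lambda: ("noisy_mixture", noise_base_spec(), 0.30),
    "pair": lambda: (
        "pair",
        ScenarioSpec(base=three_component_spec(), transform=_default_truth()),
        None,
    ),
    "trap": lambda: (
        "pair",
        ScenarioSpec(
            base=symmetric_trap_spec(),
            transform=_default_truth(),
            scene_n=1200,
            model_n=1200,
        ),
        None,
    ),
}
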