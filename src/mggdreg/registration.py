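"""Rigid point-cloud registration via mixture KL divergence.

Both clouds are summarized by fitted weighted-MGGD mixtures.  A rigid
transform acts on a mixture in closed form (means rotated and shifted,
scatters conjugated by the rotation; shape and scale untouched), so the
models are fitted once and never refitted during optimization.  The
registration objective is the Kullback-Leibler divergence from the scene
mixture to the transformed model mixture, approximated by Monte-Carlo
averaging over a fixed sample drawn once from the scene mixture, and is
minimized over rotation angle and translation by simulated annealing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .mggd import DimensionError, MGGDComponent, PointCloud, sample_mggd
from .mixture import EMConfig, MixtureModel, fit

__all__ = [
    "RigidTransform",
    "RegistrationConfig",
    "RegistrationErrors",
    "transform_points",
    "transform_model",
    "sample_mixture",
    "kld_mc",
    "register",
    "registration_errors",
]

# exp(-745) is the smallest positive double; used as a log-density floor
_LOG_FLOOR = -745.0


def rotation_matrix_2d(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s], [s, c]])


def wrap_angle(angle: float) -> float:
    """Map an angle to (-pi, pi]."""
    a = (-angle + np.pi) % (2.0 * np.pi) - np.pi
    return float(-a)


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid map x -> R x + t (det R = +1)."""

    rotation: np.ndarray
    translation: np.ndarray
    angle: float | None = None

    def __post_init__(self):
        r = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float).ravel()
        d = t.size
        if r.shape != (d, d):
            raise DimensionError("rotation and translation dimensions disagree")
        if np.abs(r @ r.T - np.eye(d)).max() > 1e-10:
            raise ValueError("rotation matrix is not orthogonal")
        if abs(np.linalg.det(r) - 1.0) > 1e-10:
            raise ValueError("rotation matrix must have determinant +1")
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)
        if d == 2 and self.angle is None:
            object.__setattr__(self, "angle", float(math.atan2(r[1, 0], r[0, 0])))

    @classmethod
    def from_angle(cls, angle: float, translation) -> "RigidTransform":
        return cls(
            rotation=rotation_matrix_2d(angle),
            translation=np.asarray(translation, dtype=float),
            angle=float(angle),
        )

    @classmethod
    def identity(cls, dim: int = 2) -> "RigidTransform":
        return cls(rotation=np.eye(dim), translation=np.zeros(dim))

    @property
    def dim(self) -> int:
        return self.translation.size

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rotation=rt, translation=-rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self o other)(x) = self(other(x))."""
        return RigidTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.rotation @ other.translation + self.translation,
        )

    def to_dict(self) -> dict:
        return {
            "angle": self.angle,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(
            rotation=np.array(d["rotation"], dtype=float),
            translation=np.array(d["translation"], dtype=float),
            angle=d.get("angle"),
        )


@dataclass
class RegistrationConfig:
    """Simulated-annealing settings for the rigid search.

    ``n_mc`` Monte-Carlo samples approximate the KLD (default 1000).  The
    Metropolis rule with geometric cooling is the default acceptance;
    ``greedy`` accepts only improving proposals.  Proposal standard
    deviations default to 5% of the search bounds and shrink with the
    temperature.
    """

    n_mc: int = 1000
    sa_iters: int = 500
    sa_restarts: int = 3  # independent chains; the best result wins
    sa_temp0: float | None = None  # calibrated to the initial objective scale
    sa_cooling: float = 0.97
    accept_rule: str = "metropolis"  # or "greedy"
    angle_bounds: tuple[float, float] = (-math.pi, math.pi)
    trans_bound: float | None = None  # defaults to half the scene bbox diagonal
    proposal_scale: float = 0.05  # fraction of the bound width
    seed: int | None = None

    def __post_init__(self):
        if self.n_mc < 1:
            raise ValueError("n_mc must be >= 1")
        if not (0 < self.sa_cooling < 1):
            raise ValueError("sa_cooling must lie in (0, 1)")
        if self.accept_rule not in ("metropolis", "greedy"):
            raise ValueError("accept_rule must be 'metropolis' or 'greedy'")


def transform_points(cloud: PointCloud, tf: RigidTransform) -> PointCloud:
    """Apply a rigid map to every point; weights and labels carry over."""
    if cloud.dim != tf.dim:
        raise DimensionError("cloud and transform dimensions disagree")
    return PointCloud(
        points=tf.apply(cloud.points), weights=cloud.weights, labels=cloud.labels
    )


def transform_model(model: MixtureModel, tf: RigidTransform) -> MixtureModel:
    """Rigid map of a mixture: mu' = R mu + t, Sigma' = R Sigma R^T.

    Shape, scale and mixing weights are unchanged.  The conjugation
    direction is fixed by density invariance: the transformed model
    evaluated at R x + t must equal the original model at x.
    """
    r = tf.rotation
    comps = [
        MGGDComponent(
            mean=r @ c.mean + tf.translation,
            scatter=r @ c.scatter @ r.T,
            shape=c.shape,
            scale=c.scale,
        )
        for c in model.components
    ]
    return MixtureModel(weights_mix=model.weights_mix.copy(), components=comps)


def sample_mixture(
    model: MixtureModel, n: int, seed=None, rng: np.random.Generator | None = None
) -> PointCloud:
    """Ancestral sampling: component index ~ pi, then the component's MGGD."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, model.weights_mix)
    parts, labels = [], []
    for k, (c, nk) in enumerate(zip(model.components, counts)):
        if nk == 0:
            continue
        parts.append(sample_mggd(int(nk), c, rng=rng).points)
        labels.append(np.full(nk, k))
    pts = np.vstack(parts)
    lab = np.concatenate(labels)
    perm = rng.permutation(n)
    return PointCloud(points=pts[perm], labels=lab[perm])


def kld_mc(
    model_s: MixtureModel, model_m: MixtureModel, samples: PointCloud
) -> float:
    """Monte-Carlo KL divergence KLD(S || M) over samples drawn from S.

    (1/n) * sum_i [log P_S(x_i) - log P_M(x_i)]; may be slightly negative
    for finite n.  Log-densities that underflow are floored at -745.
    """
    ls = np.maximum(model_s.logpdf(samples.points), _LOG_FLOOR)
    lm = np.maximum(model_m.logpdf(samples.points), _LOG_FLOOR)
    return float(np.mean(ls - lm))


class RegistrationErrors(NamedTuple):
    rot_err: float
    trans_err: float
    rot_abs: float
    trans_abs: float
    relative: bool


def registration_errors(
    estimated: RigidTransform, truth: RigidTransform
) -> RegistrationErrors:
    """Rotational and translational errors, relative and absolute.

    rot_err = |wrap(angle_est - angle_true)| / |angle_true| and
    trans_err = ||t_est - t_true|| / ||t_true||; the angle difference is
    wrapped to (-pi, pi].  If the true angle or translation is zero the
    relative fields fall back to the absolute ones and ``relative`` is
    False.
    """
    rot_abs = abs(wrap_angle((estimated.angle or 0.0) - (truth.angle or 0.0)))
    trans_abs = float(np.linalg.norm(estimated.translation - truth.translation))
    denom_a = abs(wrap_angle(truth.angle or 0.0))
    denom_t = float(np.linalg.norm(truth.translation))
    if denom_a == 0.0 or denom_t == 0.0:
        return RegistrationErrors(rot_abs, trans_abs, rot_abs, trans_abs, False)
    return RegistrationErrors(
        rot_abs / denom_a, trans_abs / denom_t, rot_abs, trans_abs, True
    )


def _objective_factory(model_s, model_m, samples):
    """KLD(S || transformed M) as a function of (angle, translation).

    Evaluating the transformed model at x equals evaluating the original
    model at R^{-1}(x - t), so no mixture is rebuilt per proposal.
    """
    ls = np.maximum(model_s.logpdf(samples), _LOG_FLOOR)

    def objective(angle: float, trans: np.ndarray) -> float:
        r = rotation_matrix_2d(angle)
        back = (samples - trans) @ r  # (x - t) @ (R^T)^T = R^{-1}(x - t)
        lm = np.maximum(model_m.logpdf(back), _LOG_FLOOR)
        return float(np.mean(ls - lm))

    return objective


def register(
    scene: PointCloud,
    model_cloud: PointCloud,
    em_config: EMConfig | None = None,
    reg_config: RegistrationConfig | None = None,
) -> tuple[RigidTransform, dict]:
    """Register ``model_cloud`` onto ``scene`` (2-D rigid).

    Fits a weighted MGGD mixture to each cloud once, draws ``n_mc``
    samples from the scene mixture once (common random numbers make the
    objective deterministic given the seed), and anneals over rotation
    angle and translation.  The translation is parameterized around the
    centroid-aligning value, mirroring a centralize-then-register
    workflow.  Returns the best transform (model frame -> scene frame)
    and a trace dictionary.
    """
    if scene.dim != 2 or model_cloud.dim != 2:
        raise DimensionError("simulated-annealing registration is 2-D")
    em_config = em_config or EMConfig()
    reg_config = reg_config or RegistrationConfig()
    rng = np.random.default_rng(reg_config.seed)

    model_s, _, rep_s = fit(scene, em_config)
    model_m, _, rep_m = fit(model_cloud, em_config)

    samples = sample_mixture(model_s, reg_config.n_mc, rng=rng).points
    objective = _objective_factory(model_s, model_m, samples)

    c_s = scene.points.mean(axis=0)
    c_m = model_cloud.points.mean(axis=0)
    bbox = scene.points.max(axis=0) - scene.points.min(axis=0)
    diag = float(np.linalg.norm(bbox))
    t_bound = reg_config.trans_bound if reg_config.trans_bound is not None else 0.5 * diag

    def full_translation(angle, delta):
        # t such that R x + t maps the model centroid onto the scene
        # centroid, plus the annealed offset delta
        return c_s - rotation_matrix_2d(angle) @ c_m + delta

    scale_a = reg_config.proposal_scale * (
        reg_config.angle_bounds[1] - reg_config.angle_bounds[0]
    )
    scale_t = reg_config.proposal_scale * 2.0 * t_bound

    def anneal_once():
        angle = 0.0
        delta = np.zeros(2)
        cur = objective(angle, full_translation(angle, delta))
        temp0 = reg_config.sa_temp0
        if temp0 is None:
            # a third of the initial objective keeps early acceptance free
            # without outlasting the proposal-scale annealing
            temp0 = max(1.0, abs(cur) / 3.0)
        temp = temp0
        best = (cur, angle, delta.copy())
        trace = [cur]
        accepted = worse_accepted = worse_proposed = 0
        for _ in range(reg_config.sa_iters):
            anneal = max(temp / temp0, 0.05)  # floor keeps late-phase mobility
            ang_new = wrap_angle(angle + rng.normal(0.0, scale_a * anneal))
            delta_new = np.clip(
                delta + rng.normal(0.0, scale_t * anneal, size=2), -t_bound, t_bound
            )
            val = objective(ang_new, full_translation(ang_new, delta_new))
            dv = val - cur
            if dv >= 0:
                worse_proposed += 1
            if reg_config.accept_rule == "greedy":
                accept = dv < 0
            else:
                accept = dv < 0 or rng.random() < math.exp(-dv / max(temp, 1e-300))
            if accept:
                if dv >= 0:
                    worse_accepted += 1
                angle, delta, cur = ang_new, delta_new, val
                accepted += 1
                if cur < best[0]:
                    best = (cur, angle, delta.copy())
            temp *= reg_config.sa_cooling
            trace.append(best[0])
        return best, trace, accepted, worse_accepted, worse_proposed

    best = None
    trace: list[float] = []
    accepted = worse_accepted = worse_proposed = 0
    for _ in range(max(1, reg_config.sa_restarts)):
        b, tr, acc, wacc, wprop = anneal_once()
        trace.extend(tr)
        accepted += acc
        worse_accepted += wacc
        worse_proposed += wprop
        if best is None or b[0] < best[0]:
            best = b

    # greedy polish with shrinking steps: the annealed proposal floor
    # limits endgame resolution, so refine the best state locally
    cur, angle, delta = best
    factor = 0.05
    for _ in range(150):
        ang_new = wrap_angle(angle + rng.normal(0.0, scale_a * factor))
        delta_new = np.clip(
            delta + rng.normal(0.0, scale_t * factor, size=2), -t_bound, t_bound
        )
        val = objective(ang_new, full_translation(ang_new, delta_new))
        if val < cur:
            angle, delta, cur = ang_new, delta_new, val
        factor = max(factor * 0.97, 5e-4)
        trace.append(cur)
    best = (cur, angle, delta)

    best_val, best_angle, best_delta = best
    tf = RigidTransform.from_angle(
        best_angle, full_translation(best_angle, best_delta)
    )
    trace = np.minimum.accumulate(trace).tolist()  # global best-so-far
    info = {
        "kld_trace": trace,
        "best_kld": best_val,
        "accept_rate": accepted / max(len(trace) - 1, 1),
        "worse_accept_rate": worse_accepted / max(worse_proposed, 1),
        "scene_model": model_s,
        "model_model": model_m,
        "scene_fit_report": rep_s,
        "model_fit_report": rep_m,
        "seed": reg_config.seed,
    }
    return tf, info
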