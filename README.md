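# mggdreg

Robust rigid registration of 2-D point clouds via data-weighted mixtures
of multivariate generalized Gaussian distributions (MGGD).

## Who this is for

Point-cloud registration pipelines (microscopy montaging, scan
stitching, image-based localization) that must cope with clutter,
outliers and mismatched sampling rates, where a probabilistic summary of
each cloud is preferable to point-to-point matching. Instead of aligning
points directly, each cloud is compressed into a small mixture model
that captures its dense, information-carrying regions; the rigid
transform is then found by aligning the two mixtures.

## The model

Each mixture component is an MGGD

```
p(x; μ, Σ, β, m) = Γ(d/2) β / [Γ(d/2β) π^{d/2} 2^{d/2β} m^{d/2} |Σ|^{1/2}]
                   · exp( −[(x−μ)ᵀ Σ⁻¹ (x−μ)]^β / (2 m^β) )
```

with mean μ, scatter Σ, scale m and shape β (β = 1 is the Gaussian;
β < 1 gives a sharper peak and heavier tails, which fits the dense
feature blocks of real point clouds better than a Gaussian). Every
observation additionally carries a weight w ∈ (0, 1] entering the
likelihood as p(x)^w ∝ p(x; μ, Σ, β, m·w^(−1/β)); weights are Gamma
random variables with conjugate posteriors, so outliers and clutter are
discounted automatically during EM. Estimation uses:

* fixed-point iterations for μ and Σ (convergent for β ∈ (0, 1]),
* damped Newton–Raphson on the profiled likelihood for β,
* a closed form for m,
* a minimum-message-length (MML) criterion that annihilates
  under-supported components and selects the number of components K.

Registration fits one mixture per cloud, then minimizes the Monte-Carlo
Kullback–Leibler divergence

```
KLD_MC(P_S ‖ P_M∘T⁻¹) = (1/n) Σ_i [log P_S(x_i) − log P_M(R⁻¹(x_i − t))]
```

over rotation angle and translation by simulated annealing; the mixture
transforms in closed form (μ′ = Rμ + t, Σ′ = RΣRᵀ), so nothing is
refitted during the search.

## Worked example

```python
import numpy as np
from mggdreg import (EMConfig, RegistrationConfig, ScenarioSpec,
                     RigidTransform, make_registration_pair, register,
                     registration_errors, three_component_spec)

truth = RigidTransform.from_angle(0.7, [4.0, -3.0])
spec = ScenarioSpec(base=three_component_spec(), transform=truth,
                    scene_n=1200, model_n=800)
scene, model_cloud, _ = make_registration_pair(spec, seed=2)

tf, info = register(scene, model_cloud,
                    EMConfig(k_max=8, seed=2), RegistrationConfig(seed=2))
err = registration_errors(tf, truth)
print(f"angle = {tf.angle:.4f} rad (true 0.7)")
print(f"translation = {np.round(tf.translation, 3)} (true [4, -3])")
print(f"relative errors: rotation {100*err.rot_err:.2f}%, "
      f"translation {100*err.trans_err:.2f}%")
```

prints

```
angle = 0.6896 rad (true 0.7)
translation = [ 3.88  -3.033] (true [4, -3])
relative errors: rotation 1.49%, translation 2.48%
```

i.e. the 800-point cloud is registered onto the 1200-point scene to
about a percent in rotation although the two clouds share no
corresponding points — only a common generating distribution. The same
API fits standalone mixtures (`mggdreg.fit`), and the `mggdreg` CLI
exposes `simulate`, `fit`, `register` and `evaluate` subcommands over
CSV/TSV/XYZ/PLY clouds and JSON models/transforms.

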