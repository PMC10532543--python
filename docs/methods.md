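# Methods

This note documents the statistical model, the estimation machinery, the
synthetic benchmarks and the numerical choices behind `mggdreg`.

## The weighted MGGD mixture

A point cloud X = {x₁…x_N} ⊂ ℝ^d is modeled as a K-component mixture of
multivariate generalized Gaussians. One component has density

p(x; μ, Σ, β, m) = Γ(d/2) β / [Γ(d/2β) π^{d/2} 2^{d/2β} m^{d/2} |Σ|^{1/2}]
· exp(−y^β / 2m^β), y = (x−μ)ᵀΣ⁻¹(x−μ),

with location μ, symmetric positive-definite scatter Σ, scale m > 0 and
shape β > 0. β = 1 recovers the Gaussian with covariance mΣ; β < 1
sharpens the peak and thickens the tails. Only the product C = mΣ is
identifiable; estimates are therefore reported as Ĉ = m̂Σ̂ together with
β̂, π̂, μ̂ and, in 2-D, the correlation coefficient ρ = C₁₂/√(C₁₁C₂₂).

Each observation carries a weight wᵢ ∈ (0, 1] entering the likelihood as
p(xᵢ)^{wᵢ}, which is proportional to the same MGGD with scale
m·wᵢ^{−1/β}. Weights are initialized from local density — the mean
Gaussian-kernel affinity to the q = 20 nearest neighbors with bandwidth
σ = 25 (w = (1/q) Σ_j exp(−‖xᵢ−x_j‖²/σ)) — and then treated as Gamma
random variables with conjugate updates: prior Gamma(aᵢ, bᵢ) with
aᵢ = wᵢ², bᵢ = wᵢ (so E[w] = wᵢ, Var[w] = 1), posterior
a_{ik} = aᵢ + d/2β_k, b_{ik} = bᵢ + y_{ik}^{β_k}/2m_k^{β_k}. The
posterior mean w̄_{ik} = a_{ik}/b_{ik} is a strictly decreasing function
of the Mahalanobis term, which is what shields the estimates from
outliers and clutter. w̄ is clamped to (0, 1] before entering the M-step
— the fixed-point convergence argument for Σ requires weights at most 1,
and clamping is monotone so the outlier ordering survives. Integrating
the weight out gives a closed-form heavy-tailed (Student-like) marginal
density used in the E-step over labels.

σ trades robustness against support: small σ sharpens the contrast
between dense and sparse regions (stronger outlier rejection) but
effectively removes tail points from estimation; 25 is a workable
middle ground at the coordinate scales of the benchmarks (clouds
spanning ~10–20 units). q = 20 simply stabilizes the local density
estimate.

### E-step conventions

The label responsibilities are η_{ik} ∝ π_k · p̄(xᵢ; θ_k, a_{ik}, b_{ik})
with p̄ the Gamma-marginalized density and (a_{ik}, b_{ik}) the
carried-forward weight posteriors — the posterior of one iteration acts
as the prior of the next, the natural conjugate-update workflow.
Evaluating p̄ at the initial prior instead is a coherent alternative; on
the benchmark designs it recovers mixing weights of heavy-tailed
components slightly better but pushes the shape estimates onto the
upper boundary of their domain, so the posterior-as-prior convention is
the default. A `weight_mode="fixed"` ablation treats the kernel weights
as known constants throughout (no E-W step).

### M-step

With weights and responsibilities fixed, the updates per component are,
in order: μ by fixed-point iteration on the w·y^{β−1}-weighted average;
Σ by the scale-free fixed point Σ ← d·Σᵢ η w y^{β−1}(x−μ)(x−μ)ᵀ / Σᵢ η w y^β
(symmetrized each pass; iterates that lose positive definiteness get a
ridge of 1e−8·tr/d); β by damped Newton–Raphson; m in closed form,
m = [β Σ η w y^β / (d Σ η)]^{1/β}. y is recomputed after each
sub-update.

The Newton objective f(β) is the derivative of the expected
complete-data log-likelihood with m profiled out (m replaced by its
closed-form optimum), derived analytically in `beta_objective`; its
correctness is pinned by a test comparing it against central differences
of the profiled objective `profile_q` and by matching the Newton root
against a bisection root of the numerical derivative. The iteration uses
learning rate ξ = 0.1, halved whenever |f| grows (exponential decay),
and the search domain is clamped to [0.05, 1.0]: the fixed-point
convergence theory covers β ∈ (0, 1], and the 0.05 floor avoids
degenerate spikes. Estimates that genuinely want β > 1 (e.g. clipped
heavy downweighting of tails) saturate at 1.

### Model selection

The number of components is chosen by a minimum-message-length score

MML = (M/2) Σ_{k∈K⁺} log π_k − Q + K⁺(M+1)/2 · (1 + log(N/12)),

with M = d + d(d+1)/2 + 2 free parameters per component (7 in 2-D) and
K⁺ the non-empty components. The mixing update
π_k ∝ max(0, Σᵢ η_{ik} − M·K⁺/2) annihilates components whose support
falls below the (K⁺-scaled) threshold, which prunes aggressively early.

Threshold pruning alone, however, regularly leaves split clusters
standing: once the sweeps converge, no component falls below threshold
even when merging two of them would lower the MML score, and — specific
to the weighted model — points orphaned by removing a component are
masked as outliers instead of pulling a neighbor over. The fit therefore
runs an explicit backward search after the sweeps settle at each K:
every surviving component is tried for annihilation, each branch
re-converges, the lowest-MML branch is adopted, and the recursion
continues down to K⁺ = 1. The returned model is the global MML minimum
over the whole trajectory. Within a K level the MML trajectory is
non-increasing (tested); across forced annihilations it may jump.

### Defaults and tolerances

k_max = 8, β₀ = 0.5, fixed-point tolerance 1e−6 (Euclidean/Frobenius)
with at most 100 inner iterations, Newton tolerance 1e−5 with at most
50 iterations, EM stops at |ΔMML| < 1e−4·|MML₁| with a global budget of
200 sweeps. k-means (10 restarts, seeded) seeds π, μ, Σ; Σ seeds get a
1e−6·tr/d ridge; the Mahalanobis term is floored at 1e−12 to remove the
measure-zero y^{β−1} singularity at x = μ. All densities are computed in
log space. If N < k_max(d+1) the requested k_max is reduced with a
warning.

## Registration

Both clouds are fitted once. A rigid map x ↦ Rx + t acts on a mixture in
closed form: μ′ = Rμ + t, Σ′ = RΣRᵀ, with β, m, π unchanged. (The
conjugation direction is fixed by density invariance — the transformed
model evaluated at Rx + t must equal the original at x, which holds for
RΣRᵀ and not RᵀΣR; a pointwise test enforces this.) The objective is the
Kullback–Leibler divergence from the scene mixture to the transformed
model mixture, approximated by Monte-Carlo over n = 1000 points drawn
once from the scene mixture by exact ancestral sampling
(component ~ π, then the MGGD's stochastic representation
x = μ + τ C^{1/2} u with τ^{2β} ~ Gamma(d/2β, 2), u uniform on the
sphere; the symmetric matrix root is a deterministic convention). An
MCMC sampler would add autocorrelation with no distributional benefit
for a finite mixture. Freezing the sample (common random numbers) makes
the objective deterministic given the seed; evaluating the transformed
model at x is implemented as evaluating the original model at
R⁻¹(x − t), so no mixture is rebuilt per proposal.

The search over (α, t) uses simulated annealing with Metropolis
acceptance (a greedy rule is available): translation is parameterized
around the centroid-aligning value (the "centralize, then register"
workflow), proposals are Gaussian with scales 5% of the bounds
(α ∈ (−π, π], offsets within half the scene bounding-box diagonal),
annealed with temperature down to a 5% floor that keeps late-phase
mobility. The initial temperature is a third of the initial objective —
large enough for free exploration early, small enough that basin
selection begins before the proposal scales shrink. Geometric cooling
0.97 over 500 iterations, 3 independent restarts (best result wins),
then a 150-step greedy polish with shrinking steps, because the annealed
proposal floor otherwise limits endgame resolution to ~10 mrad. Restarts
and polish are standard stochastic-optimization practice layered on the
basic annealing loop.

Accuracy floor: even registering a cloud against itself leaves a
residual of order the Monte-Carlo noise of the objective (≈0.01 rad and
≈0.1 data units, <1% of the scene diagonal, at n = 1000) — the MC
minimizer is displaced from the true minimizer by sampling noise. This,
not the optimizer, bounds attainable precision.

Errors are reported both absolutely and relative to the ground truth:
|wrap(α̂−α*)|/|α*| and ‖t̂−t*‖/‖t*‖, with angle differences wrapped to
(−π, π]; zero-magnitude truths fall back to absolute errors with a
flag. A run whose absolute rotation error exceeds π/2 is classified as
caught in the 180° local optimum.

## Synthetic benchmarks

The generators define the benchmark conditions end to end; no external
data is needed.

* **Reference mixtures.** A four-component design (π = 0.25 each,
  N = 300 each, β = 0.85, means (1,1), (15,2), (1,18), (16,16), fixed
  full scatters) and a three-component design (π = 0.25/0.25/0.50,
  N = 300/300/600, β = 0.60/0.85/0.85). The designs specify C = mΣ; the
  generator factors m = det(C)^{1/d}, Σ = C/m (unit-determinant Σ) —
  observationally equivalent, fixed for comparability.
* **Clutter.** `add_uniform_noise` appends round(f·N) uniform points on
  [−5.25, 5.25]² (f = clutter/clean, "proportional addition"). The
  fit-robustness experiments use a three-component mixture placed inside
  that box, so that the clutter overlaps the data it is meant to disturb; the
  registration noise experiments instead contaminate the
  three-component reference mixture with the same box clutter.
* **Registration pairs.** Scene = scene_n draws from the base mixture
  (component counts multinomial in π); model = model_n independent
  draws, contaminated identically, then mapped through the inverse of
  the ground-truth transform, so registering model→scene recovers the
  truth. Default truth: α = 0.7 rad, t = (4, −3).
* **Symmetry trap.** A five-component mixture invariant under 180°
  rotation about the origin except for one component holding 5% of the
  points: antipodal pairs at (±4.5, 0) and (0, ±3) with unequal weights
  and radii (so no rotation other than π maps the symmetric part onto
  itself — an earlier draft with four components on a square had a
  spurious 90° near-symmetry), plus a small breaker at (2.8, 2.8).
  Blobs are kept well separated so that mixture fits of independent
  draws are stable; any centrally-near-symmetric mixture with a small
  symmetry-breaking component exercises the same failure mode.

What the generators do **not** emulate: real scanner physics (occlusion,
quantization, anisotropic noise), non-rigid deformation, 3-D scenes, or
clouds whose information lives in contours rather than dense regions.
Passing benchmarks therefore demonstrates correctness of the estimation
and registration machinery under the stated generating laws, not
field performance on sensor data.

## Problem sizes

The shipped experiments use desk scales: 1200-point clouds
for fitting, 1200-vs-800 registration pairs, 20 seeded runs for the
symmetry-trap statistics, and 3–8 seeds elsewhere; a complete
benchmark pass (`scripts/acceptance.py`) takes a few minutes on one
CPU.

## Known limitations

* Estimation assumes β ∈ (0, 1]; β > 1 densities evaluate correctly but
  are never produced by the fit, and shape estimates can saturate at 1.
* Mixing-weight recovery on strongly heavy-tailed components carries a
  small systematic drift (far-tail points have nearly flat
  responsibilities and migrate toward large components); observed
  deviations are ≲0.08 at the benchmark sample sizes.
* The annealing search is 2-D (one angle); the transform algebra is
  d-dimensional, but a d > 2 search would need a rotation
  parameterization and proposal design of its own.
* MML selection on heavily overlapping components (centers closer than
  ~3–4 effective standard deviations) legitimately merges them.
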