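# Methods

## Signal model

Each voxel is modeled as a slow-exchange mixture of an isotropic free-water
compartment and up to three anisotropic fascicle compartments:

S(g_k) = S0 [ f_iso exp(−b_k D_iso) + Σ_i f_i exp(−b_k ĝ_kᵀ D_i ĝ_k) ],

where ĝ_k is the unit gradient direction, b_k the effective b-value,
D_i a symmetric positive-definite (SPD) 3×3 tensor per fascicle, and the
fractions (f_iso, f_1, …, f_N) lie on the simplex.  Each compartment decays
mono-exponentially; non-mono-exponential behavior of the voxel arises from
the mixture itself.  Free-water diffusivity defaults to D_iso = 3.0×10⁻³
mm²/s (body-temperature free water) and is configurable.

Assumptions: Gaussian diffusion per compartment, slow exchange, cylindrical
fascicle tensors by default (λ₂ = λ₃ — four free parameters per tensor: two
orientation angles plus axial and radial diffusivity), and a noise model
that is Gaussian in the fitting criterion even though simulated noise is
Rician (the standard small-bias approximation at the SNRs considered; kept
deliberately).

## Identifiability and the gauge transformation

With a single non-zero b-value b, the map

f₁ → ε f₁, D₁ → D₁ + (ln ε / b) I,  f₂ → f₁ + f₂ − ε f₁,
D₂ → D₂ + (ln(f₂′/f₂) / b) I

preserves every prediction on that shell, so tensor size and fractions
cannot be jointly determined.  `gauge_transform` implements the map and
enforces its admissibility directly: both transformed tensors must remain
SPD (equivalently ε > exp(−b λ_min(D₁)), with the symmetric condition on
D₂), and the transformed fractions must stay in [0, 1].  The executable
theorem — bit-level agreement (≤ 10⁻¹⁰) on any single-shell scheme,
strictly positive discrepancy on any scheme with two distinct non-zero
b-values — is asserted by the test suite over random mixtures.

## Gradient schemes

The cube of constant TE is the set of gradient-coil vectors with every
component ≤ 1 in magnitude; the effective b-value of a vector v is
b_nom‖v‖², so corners reach 3× and edge midpoints 2× the nominal b-value at
no echo-time cost.  Nominal b-value defaults to 1000 s/mm² (a standard
adult-brain operating point); the 2× and 3× shells of the truncated scheme
are forced by cube geometry, not chosen.

Directions on the unit shell minimize the antipodally symmetrized Coulomb
energy Σ 1/|g_i − g_j| + 1/|g_i + g_j| by L-BFGS descent over spherical
coordinates with the analytic force, best of 10 seeded restarts.  Multi-
subset schemes are optimized sequentially: the inner shell first, then the
outer subset with the inner shell and any force-included vectors held fixed
in the energy.  The projected variant force-includes the four tetrahedral
and six hexahedral lattice vectors, optimizes the remaining outer
directions against everything already placed, and projects them to the cube
faces (dividing by the largest component magnitude, preserving
orientation).  The exponentially truncated variant spaces shell radii as
r_j = 3^(j/2m) for j = 1…m — geometric in b-value — so shell density rises
where per-image SNR falls.  Generated directions are canonicalized to the
hemisphere with non-positive last non-zero component.

## Estimation

Tensors are handled in the log-Euclidean frame: the optimizer's tensor
parameters are Euler angles and (log-bounded) eigenvalues, so every
candidate is SPD by construction and no eigenvalue clamping exists anywhere
in the pipeline.  The per-voxel fit proceeds in stages of increasing
complexity, warm-starting each stage from the last:

1. **One-tensor robust least squares** — weighted log-linear fit (weights
   S_k², the delta-method variance correction), three Cauchy reweighting
   iterations (scale 1.4826·MAD, tuning constant 2.385); on noise-free data
   the reweighting is a no-op.  A non-SPD solution triggers refits with a
   tightened robust scale; if that fails an isotropic tensor at the
   apparent mean diffusivity is substituted (constructed, not clamped) and
   logged.
2. **Orientations + fractions** at fixed eigenvalues.  The first two
   fascicles are initialized from the one-tensor fit rotated by ±θ_init in
   the plane of its two largest eigenvalues, θ_init = (π/4)(λ₂/λ₁) — nearly
   parallel when the fit is prolate, perpendicular when it is oblate (the
   signature of a crossing); each initial tensor is cylindrical about its
   rotated axis with eigenvalues shrunk by 0.8, a third fascicle is seeded
   by a random rotation, and initial fractions are f_iso = 0.1 with the
   remainder split equally.
3. **Cylindrical eigenvalues** added (box bounds 10⁻⁵–9×10⁻³ mm²/s).
4. **Full model** including f_iso, repeated until the objective stops
   improving, with seeded perturbation restarts to escape plateaus (a
   collapsed-fascicle configuration is a flat region for any optimizer);
   perturbed solutions are accepted only on improvement, so the objective
   is monotone across stages and repeats.

Fractions are parameterized by stick-breaking on [0, 1] boxes (a bijection
onto the simplex — no flat renormalization directions) and renormalized
exactly on reconstruction.  Orientation angles get periodic bounds wider
than their principal range so line searches never stall on a bound; the
principal-range representative is recovered when the tensor is built.
S0 is fixed at the b=0 mean.

Each stage is solved by a derivative-free bound-constrained optimizer.  The
default is scipy's bounded Powell conjugate-direction search, chosen
because its per-evaluation overhead is ~50× lower than the trust-region
quadratic-model alternative (COBYQA) at this problem size (7–13
dimensions), which matters when fitting 10³–10⁴ voxels; `FitConfig.optimizer
= "cobyqa"` selects the trust-region method for users who prefer it.  The
orientation stage runs from several perturbed initializations (default 4)
because the crossing-angle landscape is multi-modal.

**Spatial prior.**  The regularizer penalizes, per fascicle j, φ(|∇L_j|/K)
with L_j = log D_j, φ(s) = 2√(1+s²) − 2 (edge-preserving: quadratic near 0,
linear in the tails), and K a gradient normalization defaulting to the
median |∇L| of the one-tensor log field.  The finite-difference derivative
along each axis pairs L_j with the *most similar* neighbor fascicle
(log-Euclidean distance) on each side — only tensors belonging to the same
fascicle are smoothed together, and voxels with different fascicle counts
pose no difficulty; one-sided differences at mask boundaries, zero with no
neighbors.  An exact min is used by default (the stage optimizer is
derivative-free); a softmax with sharpness γ is available for
gradient-based extensions and reproduces the exact min as γ → ∞.  The
prior weight β·α is annealed linearly from 0 to 1 over n_sweeps = 5 outer
sweeps (α = 1 by default): early sweeps explore, late sweeps smooth.
Sweeps re-solve one voxel at a time with neighbors fixed and never accept
an increase of the local objective.

**Model order.**  Nested orders 1…3 are compared by an ascending F-test on
residual sums of squares with p = 5N free parameters per order (4 per
cylindrical tensor + N fraction degrees of freedom), threshold α = 0.05.

**Noise scale.**  When requested, σ is estimated as 1.4826·MAD/√2 of b=0
replicate differences, assuming constant noise characteristics across
volumes.

## Synthetic data

Phantoms are built from cylindrical tensors constructed in closed form from
a requested FA and trace:

λ∥ = (T/3)(1 + 2·FA/√(3 − 2FA²)),  λ⊥ = (T/3)(1 − FA/√(3 − 2FA²)).

Defaults — trace 2.1×10⁻³ mm²/s, FA pair (0.8, 0.7), fractions
(f_iso, f₁, f₂) = (0.2, 0.4, 0.4), S0 = 400 — are typical white-matter
values; every parameter is configurable and recorded in the phantom's
`meta`, from which a phantom regenerates bit-identically.  Noise is Rician:
each value v → √((v+n₁)² + n₂²), n₁, n₂ ~ N(0, σ²), with σ set from the
b=0 SNR in dB (20·log₁₀(mean b0 / σ)).

Two geometries: a grid of independent two-tensor crossings at a fixed angle
with random global orientation per voxel, and a 2-D slice with two straight
uniform fascicle bands (width 3 voxels, one horizontal, one oblique through
the center) whose intersection voxels carry both tensors at fractions
(1−f_iso)/2.  What the phantoms do **not** emulate: curved or fanning
fascicles, partial-volume geometry beyond the straight bands, spatially
varying noise, eddy-current or motion artifacts.  Passing tests therefore
demonstrate correctness of the estimator under the model's own assumptions,
not performance on scanner data.

## Evaluation

tALED, fAAD and tAMA compare an estimate with ground truth per voxel,
minimizing over the fascicle-matching permutation (≤ 3 fascicles, so the
exhaustive search over ≤ 6 permutations *is* brute force).  fAAD reuses the
tALED-optimal permutation — the fraction comparison follows the tensor
correspondence — and includes the isotropic fraction.  tAMA takes, for each
reference principal axis, the minimum axial angle (antipodally symmetric,
[0°, 90°]) to any estimated axis, and works across differing fascicle
counts.

The residual bootstrap resamples raw per-voxel residuals with replacement
onto the model predictions, refits each virtual acquisition, and reports
the standard deviation of the maximum per-fascicle FA (ties broken by the
larger fraction) — a proxy that tracks the same fascicle across replicates.
Residuals are not leverage-standardized.  All replicates of a voxel share
one optimizer seed so the replicate spread measures data variability rather
than the stochastic restarts of the fitter.

## Numerical choices and problem sizes

- SPD tolerance: eigenvalues ≤ 10⁻¹² are rejected, never clamped.
- Eigenvalue descending order; eigenvector sign fixed to the upper
  hemisphere; Euler bounds ψ, φ ∈ [−π, π), θ ∈ [0, π/2] for uniqueness.
- dvs gradient tables are written with 5-decimal components (zero vectors
  as integers) and re-read to the identity; unicode minus signs in pasted
  tables are normalized on read.  bval files round to integer s/mm².
- Simulation sizes in the test suite and acceptance script (chosen to keep
  a full run at minutes on one CPU): accuracy contrast on a 100-voxel
  (tests) / 50-voxel (script) 70° crossing phantom at 30 dB with 20 / 6
  noise replicates; noise-free recovery on 100 / 50 voxels; FA-uniformity
  on an 11-voxel tract with 10 / 5 replicates; bootstrap with 50 replicates
  at three noise levels on a 3-voxel phantom.  Two fit budgets are used:
  a light one for the large noisy batches (2 orientation restarts, ≤ 900
  evaluations per voxel), where the scheme contrast rather than per-voxel
  convergence is under test, and a thorough one (6 restarts, ≤ 3000
  evaluations) for noise-free recovery.

## Known limitations

- Per-fascicle mono-exponential decay: kurtosis/restricted-diffusion
  effects at high b-values are outside the model.
- The Gaussian likelihood ignores the Rician noise floor; at very low SNR
  (≪ 15 dB) this biases diffusivity estimates.
- The regularized field sweep is a coordinate (one-voxel-at-a-time)
  descent; it guarantees monotone objective decrease, not a global optimum.
- The estimator's derivative-free stages make per-voxel cost the binding
  constraint for whole-brain volumes; the design targets small fields,
  phantoms, and method studies.
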