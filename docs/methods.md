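# Methods

## Problem setting

A diffusion-MRI acquisition samples, per voxel, a paired series of q-vectors
and scalar signals `x_obs = {(q_i, s_i)}`, where a q-vector encodes gradient
direction and diffusion weighting (`|q| ∝ √b`).  The package addresses
*q-space super-resolution*: predicting the signal at arbitrary query q-vectors
from an arbitrary observation set, per voxel and without spatial context.
This supports scan acceleration (reconstruct a dense scheme from a short
acquisition), denoising, and harmonization (resample different acquisition
schemes onto a common one).

Physical structure exploited throughout:

* **Antipodal symmetry** — `s(q) = s(−q)`: the measurement is insensitive to
  the gradient sign.
* **Rotational relativity** — only the relative geometry of observation and
  query vectors matters, not the laboratory frame.
* **T2-shinethrough** — each measurement carries a diffusion-independent
  T2-weighted factor; dividing by the mean b0 image removes it, after which
  `s(q ≡ 0) = 1`.
* **Order/choice irrelevance** — the observation set is a set; its ordering
  and the particular subset acquired are acquisition artifacts.

## Model

The reconstruction model is a conditional set-to-function network
`ŝ = D(q | E(x_obs))`:

* **Sign-invariance module** `SI(q) = MLP(q) + MLP(−q)`, a 3→128 map shared
  between encoder and decoder.  Because IEEE addition is commutative, the
  symmetry holds *bit-exactly* for any weights.
* **Encoder**: one processing path per observation.  `SI(q_i)` is concatenated
  with the scalar signal `s_i` (129 features) and passed through alternating
  *transform* stages (a per-path MLP, weights shared across paths) and masked
  max-*pooling* over paths; an *assembly* step concatenates each path's
  features with the pooled global features (128 + 128 → 256).  The final
  transform stage outputs the latent width; a final masked max-pool collapses
  the paths to the latent code `z ∈ R^16`.
* **Decoder**: one path per query; `SI(q)` concatenated with `z`
  (128 + 16 → 144) and mapped to a scalar by an MLP.  Queries are processed
  independently, so predictions do not depend on the other queries in a batch.

Layer composition follows the reference design: transform layers are
linear → batch-norm → tanh; sign-invariance and decoder layers are
linear → ReLU, except the decoder's output layer, which is purely linear.
The sign-invariance MLP has 3 hidden + 1 output layers; transform and decoder
MLPs have 2 hidden + 1 output layers; all widths are 128 except the final
transform output (16) and the decoder output (1).

### Parameter budget and encoder depth

The reference describes the module pattern but not the exact number of
transform/pool stages; it does state a ≈170k trainable-parameter budget.
With the stated layer counts, three stages yield ≈254k parameters; two stages
yield 187,697 with affine batch-norm parameters and 186,385 without.  The
default is therefore **two encoder stages with affine-free batch
normalization** (186,385 parameters, within ±10% of 170k).  Both the stage
count and the affine flag are `NetworkConfig` fields.

### Batch normalization and invariance

Normalization statistics are computed over (batch × *active* paths) — a
permutation-invariant set — with masked paths excluded; running statistics
are used at inference.  Consequently inference-mode encoding is *exactly*
invariant to path permutation, sign flips, and the values of masked paths,
and masked encoding equals encoding the physically retained subset.  In
training mode the statistics depend on the batch as a set, so permutation
invariance holds to floating-point accumulation order (≲1e-6 relative).

The masked max-pool replaces inactive paths with `−inf` sentinels before the
maximum, so no finite feature value of a masked path can be selected;
gradient is routed to the first path attaining the maximum.

### NumPy implementation

The network, its backward passes, and the optimizer are implemented directly
in NumPy (float32): the architecture is small and static, explicit
reverse-mode code keeps the package dependency-light, and a single-CPU BLAS
saturates the arithmetic.  Gradients are verified against central finite
differences in float64 in the test suite.

## Training

* **Augmentations**, drawn independently per training sample: a uniform
  random rotation (quaternion method) applied jointly to observation and
  query vectors, and a random observation subset of size
  `Uniform{5, …, K}` encoded as a binary mask inside every pooling operation.
  The non-observed vectors become supervised queries.  A per-batch
  sub-sampling mode (one shared subset) exists as an ablation and is
  measurably worse.
* **b0 query**: since signals are normalized, `q ≡ 0` is queried each sample
  with target 1.
* **Loss**: `L = (1−λ)·mean_{O}(ŝ−s)² + λ·mean_{Q\O}(ŝ−s)²` with λ = 0.4.
  Per-partition *means* are used (the reference formula is written as sums
  but described as mean squared error); means keep λ's interpretation
  independent of the random subset sizes.
* **Optimizer**: Adam at 1e-3 by default.  The reference names momentum-SGD
  (0.9, initial rate 0.01) only for its discrete baselines; at desk-scale
  step counts (hundreds to a few thousand updates, versus tens of thousands
  at GPU scale) momentum-SGD stalls on this architecture at the
  voxel-independent mean predictor, whereas Adam fits it reliably — so Adam
  is the default and momentum-SGD remains available
  (`optimizer="sgd", initial_lr=0.01`).  In either case the learning rate is
  multiplied by 0.1 when the validation loss has plateaued for 20 epochs
  (relative improvement < 1e-4), and early stopping triggers after a minimum
  of 40 epochs once the validation loss has not improved for 40 successive
  epochs.
* **Validation loss** uses λ = 1 (query-only) on a frozen augmentation draw,
  so model selection targets generalization to unseen q-vectors rather than
  reproduction of (noisy) inputs.
* **Batch size** defaults to 4096 (the reference trains with 4k–10k on GPU);
  the scaled-down desk benchmarks below use 128 so that the short schedule
  still takes enough optimizer steps.

## Synthetic phantom

The generator emulates per-voxel diffusion with Gaussian mixtures
(multi-tensor model): `s(b, g) = Σ_k f_k exp(−b gᵀ D_k g)`, which is exactly
antipodally symmetric, rotation-equivariant, and normalized (`s(0) = 1`).
Voxel cohorts mix single-fiber, two- and three-fiber crossing, and isotropic
configurations (default proportions 0.45 / 0.30 / 0.15 / 0.10) with uniform
random fiber orientations.  Diffusivities are white-matter-plausible: axial
1.4–2.0e-3 mm²/s, radial 0.2–0.6e-3 mm²/s (mono-exponential regime over the
emulated b-ranges); isotropic voxels draw 0.7–3.0e-3 mm²/s.  Noise is Rician
(`|s + n₁ + i n₂|`, n ~ N(0, (1/SNR)²)) at SNR 30 on the normalized scale by
default — magnitude-MR-like, though without the spatial correlations,
multi-coil effects, partial-volume CSF, or exchange/restriction behaviour of
real tissue.  Passing benchmarks on this phantom therefore demonstrates the
method's geometric and statistical machinery, not clinical-grade performance.

Emulated sampling schemes: single-shell (90 directions, b = 1000 s/mm²),
multi-shell (3 × 90 at b = 1000/2000/3000), and sparse Cartesian-grid
(112 q-vectors from an 11³ lattice, b up to 6800 s/mm²).  Shell directions
use an in-package electrostatic-repulsion construction under antipodal
symmetry (uniformity is what matters, not any specific published point set).

## Evaluation protocol

Observation/query sets: 30 query vectors are drawn first for best uniform
coverage, then nested observation sets (N = 10 ⊂ 20 ⊂ 30 ⊂ …) from the
remainder.  Uniform draws group vectors into 1000 s/mm² b-bins, order each
bin greedily by maximum-minimum spherical distance from a seeded random
start, and take evenly spaced entries; the spherical distance identifies
antipodes, `d(u, v) = arccos |û·v̂|`, consistent with `s(q) = s(−q)` (the
plain great-circle alternative is configurable).

Metrics: `Error_signal = (1/J) Σ_j (ŝ_j − s_j)²/s_j²` per voxel over queries,
`Error_metric = (m̂ − m)²/m²` for scalar map values; distributions are
summarized by median/quartiles with 1.5-IQR whiskers capped at the extremes.
Reference signals below 1e-6 mark degenerate voxels and are excluded.  DTI
reference fits for metric errors use only measurements outside the
observation set, so overfitting observation noise is not rewarded.

When comparing robustness to the *choice* of observation set, note that
re-drawing the set changes its information content, not just its labelling:
even the spherical-harmonics fit — which has no notion of input ordering or
wiring — shifts its median `Error_signal` by up to tens of percent across
re-drawn N = 20 sets on this phantom.  Permutation isolates wiring
sensitivity exactly (the set encoder is bit-for-bit permutation-invariant;
the discrete MLP collapses), while re-draw comparisons are qualitative.

The DTI fit is log-linear (weighted) least squares of
`log s = c₀ − b gᵀ D g` with an intercept; FA/MD are the closed-form
eigenvalue invariants.  The fit is validated against a brute-force nonlinear
least-squares oracle on noiseless data.

## Scaled-down benchmark sizes

The desk-scale learning benchmark (tests and `scripts/acceptance.py`) trains
on 3,000 synthetic single-shell voxels (batch 128) with a two-phase
schedule — 90 epochs at learning rate 1e-3 followed by 25 refinement epochs
at 1e-4, the short-schedule analogue of the reduce-on-plateau rule — and
evaluates on 2,000 held-out voxels.  Because both augmentations resample per
voxel and epoch, the effective training distribution scales with
voxel-epochs rather than voxel count, and many optimizer steps matter more
than a large cohort at this scale; the validation loss plateaus within this
schedule.
These sizes are the package's default desk-scale configuration; cohort-scale
training (hundreds of thousands of voxels per subject) is expected to behave
like the reference implementation but is out of scope here.

## Numerical choices

* b0 threshold: b < 50 s/mm² counts as q ≡ 0 (the field's conventional cut).
* q-magnitude convention: `|q| = sqrt(b/b_ref)` with `b_ref` = the scheme's
  maximum b, keeping network inputs in [0, 1]ⁿ shells.
* SH baseline: order 8 (45 coefficients), Laplace–Beltrami regularization
  weight 0.006 by default (a conventional value; the reference does not print
  its own), closed-form normal-equations solve; with `reg = 0` an
  ill-conditioned system raises with guidance instead of returning noise.
* Non-positive signals are clipped at 1e-6 before log transforms, with a
  warning.
* Weight initialization: fan-in-scaled uniform, seeded; all randomness in a
  run flows from one `numpy` generator per entry point.
* Tie-breaking in max-pool backprop: first attaining path.

## Known limitations

* The phantom's noise and tissue models are deliberately simple (see above).
* The encoder stage count is inferred from the parameter budget, not from a
  published schematic; reconstruction quality is insensitive to ±1 stage at
  matched budget, but exact parity with the reference implementation is not
  claimed.
* The discrete MLP and MLP-SH baselines are trained per observation set, as
  designed; they exist to quantify the cost of fixed wiring, not as
  recommended methods.
* SHORE, MAP-MRI and compressed-sensing reconstructions are out of scope;
  the benchmark harness accepts any object implementing the
  `ReconstructionMethod` protocol, so external implementations can be plugged
  in.
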