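# Methods

## Problem setting

Cryo-electron tomography (cryo-ET) captures macromolecules in situ as small
cubic grayscale sub-volumes ("subtomograms"), heavily degraded by detector
blur, additive noise and the missing wedge of single-tilt acquisition.
Classifiers for subtomograms need large labeled training sets, which real
experiments rarely provide. One remedy is simulation: translate clean
macromolecule density maps into realistic-looking subtomograms. `tomocycle`
implements both routes — the conventional physics-based simulator, and a
learned unpaired image-translation model — together with the metric suite
needed to judge generated data and a Monte-Carlo-dropout procedure for
per-voxel uncertainty.

## Classical simulator

The forward model composes four stages in physical acquisition order:

1. **Rigid pose.** A uniform (Haar) random rotation and a translation drawn
   within ±8% of the side length, applied by trilinear interpolation about
   the grid centre. Near-integer rotation matrices are snapped at 1e-12 so
   right-angle poses are voxel-exact; voxels pulled from outside the support
   are filled with the volume minimum (background). Round trips (R then R⁻¹)
   are accurate to a few percent of the dynamic range inside the inscribed
   ball; information outside it is legitimately lost to the background fill,
   which is why round-trip checks evaluate only that region.
2. **MTF blur.** The 3D spectrum is multiplied by a radially symmetric
   Gaussian `exp(-f² / 2σ²)` with σ in cycles/voxel (default 0.25, i.e. half
   of Nyquist — a moderate detector envelope). The operator is linear and
   real-preserving. A Gaussian is used because only the qualitative low-pass
   behaviour matters at fixture scale; no detector is being fit.
3. **Missing wedge.** Single-tilt geometry, tilt axis y: Fourier
   coefficients whose (k_x, k_z) direction lies within the wedge half-angle
   (default 30°) of the k_z axis are zeroed. The measured plane k_z = 0 —
   which carries the DC term — is always kept. The operator is an orthogonal
   projection, hence idempotent.
4. **Noise to target SNR.** Zero-mean Gaussian noise with variance
   `var(signal) / SNR`, the variance-ratio convention that dominates the
   cryo-ET literature (default SNR 0.5). A constant signal has no defined
   SNR and is rejected. Realized ratios land within 10% of the target for
   32³ volumes at SNR ∈ [0.1, 2].

The composed pipeline ends with symmetric min-max normalization to [-1, 1],
the generator's tanh range. With a fixed seed the pipeline is a pure
function.

### Synthetic two-domain fixtures

Real experiments use curated archive data; the fixture generator instead
emulates the *structure* of such datasets with four geometric families
(solid sphere, concentric shell, two-lobe dumbbell, rod), each jittered a
few percent per instance. The classes are >90% linearly separable on clean
data — verified in the test suite — so downstream classification is
meaningful. Domain D holds clean, randomly posed, normalized maps; domain S
holds *independently generated and posed* instances pushed through the full
degradation pipeline. No volume in S is a degraded copy of a volume in D:
the domains are genuinely unpaired, matching the training assumption.

What the fixtures do **not** model: real structural heterogeneity and
conformational variability, crowding and neighbouring densities, non-Gaussian
and spatially correlated noise, CTF oscillations with defocus ramps, dose
weighting, or reconstruction artefacts beyond the ideal wedge. Passing tests
therefore demonstrate correctness of the machinery and qualitative behaviour
at desk scale, not parity with experiments on archive data.

## Translation model

Two generators map between the domains (`G_ds`: density → subtomogram,
`G_sd`: the reverse); two critics score realism of each domain. The
generator is the standard image-translation encoder/decoder, in compact
notation c7s1-32, d64, d128, R128×6, u64, u32, c7s1-1, realized in 3D:

* 7³ stem conv (reflect padding), instance norm, ReLU;
* two stride-2 3³ convs doubling channels (zero padding);
* six residual blocks at 1/4 resolution (two 3³ convs each, instance norm,
  identity skip);
* a **noise junction**: one Gaussian noise channel of bottleneck shape is
  concatenated to the 128-channel representation, so the first upsampling
  layer consumes 129 channels. The channel diversifies outputs for a fixed
  input and counteracts mode collapse. (Plain channel arithmetic places the
  junction before the *first* up layer — 128 + 1 = 129 — and that is where
  it sits.)
* two fractional-stride (stride-½, realized as transposed) 3³ convs back to
  full resolution;
* a 7³ head conv to one channel with tanh and **no** normalization, so
  outputs live strictly in (-1, 1).

The critic stacks three spectrally normalized 4³ stride-1 convs (64, 128,
256 filters) with instance norm and LeakyReLU(0.2), then a 1-filter
projection conv whose spatial mean is the scalar score (a Wasserstein
critic needs a scalar; the projection head is the minimal way to get one).
Spectral normalization divides each weight, viewed as an
out-channels × rest matrix, by its top singular value estimated with a
persistent-vector power iteration (3 iterations per weight update, 50 at
first use); the backward pass includes the exact rank-one term from
d(σ)/dW. Width (`base_width`, `critic_width`) and residual depth are
configurable so the same architecture runs at reduced scale on one CPU;
defaults are the full plan.

### Numerical engine

No GPU framework is used: layers are implemented directly on numpy with
analytic backward passes, checked element-wise against central differences.
Stride-1 convolutions run through the Fourier domain (circular correlation
on the padded grid, cropped to the valid region; adjoints are circular
convolutions), which removes the k³ work inflation of im2col and makes the
4³ stride-1 critic affordable; stride-2 convolutions use im2col, and
transposed convolutions use one large contraction plus strided scatter-adds.
Kernel spectra are memoized on a random-projection fingerprint of the
weight, so repeated forwards with unchanged weights (critic real/fake
passes, MC-dropout draws) pay for the FFT once. Reflect padding has an
exact fold-back adjoint. All computation is float32 with float64
accumulations where it matters (losses, statistics).

## Training objective and loop

Adversarial losses exist in two forms, switchable by one config flag
(`adv_mode`), which realizes the published ablation axis:

* **wasserstein** (default): critic loss `mean(fake) − mean(real)`,
  generator loss `−mean(fake)`, critic weights clamped to [−c, c] after
  every critic update (default c = 0.01) to maintain a Lipschitz bound;
* **logistic**: sigmoid cross-entropy with the non-saturating generator
  form.

Cycle consistency is the mean absolute error of both reconstruction
directions, weighted by λ (default 10 — the conventional weighting; λ = 0
cleanly disables the reconstruction gradient while the term is still
reported). The full generator objective is `adv_ds + adv_sd + λ·cycle`.

Each step runs `n_critic` critic updates (default 5; the smoke protocol
uses 2) and one joint generator update. All networks use RMSProp at
α = 5e-4 — the standard recipe for weight-clipped critics, where adaptive
momentum methods destabilize training. Density-map inputs can be corrupted
with zero-mean Gaussian noise scaled by `input_noise_std` × dynamic range
(default 0.2 in the smoke protocol), a regularizer that also has its own
ablation axis. Spectral normalization is a model-level flag
(`spectral_norm=False` swaps plain convs into the critic).

One sequential RNG seeded from the config drives shuffling, noise channels
and corruption, so a rerun with the same seed is bit-identical, including
the loss history. A non-finite loss aborts immediately with the step and
term named. History (one row per generator step: adv_ds, adv_sd, cycle,
critic losses, total) is returned and optionally written as CSV next to a
single-file npz checkpoint carrying parameters and plan metadata.

### Reference problem sizes

The package's reference CPU experiment ("smoke protocol") is 16³ volumes,
4 classes × 10 per domain, generators at base width 4 with 2 residual
blocks, critics at width 8, batch 4, n_critic 2, 200 generator steps. These
sizes were chosen as the smallest configuration at which the qualitative
behaviour — cycle-loss descent, stable critic scores, clipping and spectral
constraints holding throughout — is reliably visible; the full-width plan
is exercised separately for its architectural contracts (shape
preservation, the 129-channel junction, output range, σ ≈ 1).

## Evaluation suite

Embedding-space metrics take any object with `features` and
`predict_proba`/`predict`:

* **k-NN manifold metrics** (k default 5; the value is a convention, larger
  k smooths the manifold): precision, recall, density, coverage as defined
  above, with the boundary rule *distance ≤ radius counts as inside* — this
  makes the identical-set identities exact. The vectorized implementation is
  tested for exact agreement with a naive double-loop oracle on hundreds of
  random instances.
* **Inception-score analog** over a fixture-trained classifier's posteriors
  (bounded by the class count; 0·log 0 = 0).
* **Frechet distance** between Gaussian moment fits, with the trace term
  computed exactly via the symmetric similarity transform
  `S_r^{1/2} S_g S_r^{1/2}` (same spectrum as `S_r S_g`); negative
  eigenvalues from rank-deficient empirical covariances are clipped with a
  warning and the final value is floored at zero.
* **3D SSIM** with standard sliding windows. Unpaired data has no canonical
  SSIM pairing, so the suite pairs each generated volume with its nearest
  same-class real exemplar in embedding space and averages; this convention
  makes the self-evaluation fixed point exactly 1 and is stated here because
  other pairings give different absolute values.
* **Classification accuracy** of generated volumes against their source
  class, under a classifier trained on real labeled data.

Two embedders ship: a small 3D conv classifier trained with cross-entropy
on the labeled fixture set (feature dimension configurable), and a
training-free centroid embedder (average-pooled voxels, softmax over
negative centroid distances) used where determinism and speed matter more
than representational power.

## Uncertainty maps

With dropout active at inference (placed after each residual block's second
conv; rate configurable, 0 outside uncertainty mode), T stochastic forward
passes on one density map (default T = 20) yield a per-voxel standard
deviation map. The injected noise channel is held **fixed** across draws by
default so the variance isolates dropout; `resample` mode measures total
generative variance instead. Standard deviations use the population
convention (divide by T); the sample convention differs by √(T/(T−1)),
which the tests pin down explicitly.

## Known limitations

* The fixture gap to real data listed above: results at fixture scale do not
  certify performance on archive subtomograms.
* The numpy engine targets small cubic volumes (side ≲ 64); tomogram-scale
  I/O and training are out of scope.
* Weight clipping and spectral normalization are both active in the default
  Wasserstein configuration (independent flags); no gradient-penalty
  variant is provided.
* The exact Earth-Mover distance is never computed — only the critic-based
  surrogate, as in standard Wasserstein training.
* Reduced-scale adversarial training is noisy: adversarial loss curves at
  smoke scale are indicative, not converged.
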