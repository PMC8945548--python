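# Methods

## Problem and model

Resting-state fMRI records spontaneous BOLD fluctuations at thousands of
cortical surface vertices and subcortical voxels ("grayordinates") over time,
for many subjects. Large-scale brain networks — the default mode network
(DMN) being the canonical example — appear as spatial patterns whose time
series covary. This package identifies such networks at the group level and
quantifies how strongly small subcortical nuclei participate in them.

The group model treats the synchronized multi-subject data as a 3-way tensor
`X ∈ R^{V×T×S}` (space × time × subject) and approximates it by a rank-R
canonical polyadic (CP) expansion

    X ≈ Σ_r λ_r · a_r ∘ b_r ∘ c_r

where `a_r` (unit-norm, length V) is network r's spatial map, `b_r` (length
T) its temporal dynamics, `c_r` (length S) the per-subject participation
level, and `λ_r ≥ 0` its magnitude. No sign constraint is placed on the
spatial maps: anti-correlated regions (negative weights) are a finding, not
an artifact.

### Why synchronization first

Spontaneous activity is not temporally aligned across subjects, and a shared
temporal factor `b_r` is meaningless without alignment. For row-normalized
data (each time series zero-mean, unit-norm), the transform that best aligns
one subject to another while preserving all within-subject correlation
structure is an orthogonal matrix acting on the time axis — the orthogonal
Procrustes solution `O = UVᵀ` from the SVD of `X_movᵀ X_ref`. The group
variant builds a *virtual reference subject*: starting from the most central
subject (largest summed squared homologous-row correlation to all others, to
avoid anointing an arbitrary reference), it alternates (i) Procrustes
alignment of every subject to the reference and (ii) reference re-estimation
as the row-renormalized mean of the aligned data. The row-renormalized mean
is the exact minimizer of the summed squared distance over references with
unit-norm rows, so the alternation is a block-coordinate descent on that
constrained objective and the logged objective never increases. Defaults:
tolerance 1e-6 on the reference change (Frobenius), at most 20 iterations;
non-convergence is reported, not raised, because the factorization is
insensitive to the last fraction of a percent of alignment.

Because the transforms are orthogonal and applied on the right,
whole-window connectivity (inner products of unit-norm rows, equal to
Pearson correlation on the original zero-mean data) is preserved to machine
precision; `connectivity_preservation_check` asserts this.

### The CP solver

The solver is rank-incremental with warm starts: solve rank 1; for r = 2..R
keep the rank-(r−1) factors as initialization, add one new component, and
jointly re-optimize all factor entries by full-gradient Nadam
(Nesterov-accelerated adaptive moment estimation; step 1e-2, moment decays
0.9/0.999, ε=1e-8). The gradient of ½‖X − Σ λ a∘b∘c‖² is computed through
matricized tensor–Khatri-Rao products; one shared contraction `X₍₁₎ᵀA`
serves both the time- and subject-mode gradients, and the exact relative
reconstruction error falls out of the same quantities at no extra cost, so
convergence is monitored every iteration.

The new component at each rank is not left at a raw random draw: random
time/subject vectors are refined by a few alternating power iterations
against the current residual, so each added component starts at the dominant
rank-1 direction of what is still unexplained. The spatial factor is always
the least-squares optimum for the current (b, c) pair. Two consequences:
the initialization is nearly seed-independent, and no random draw is ever
indexed by voxel, which is one ingredient of the exact shuffle invariance
described below.

**Early stopping as regularization.** The rank R is conventionally an
over-estimate (R = 30 on real data; single digits at desk scale). An
over-ranked CP model of noisy data is not identifiable along "splitting"
directions: a network can donate part of its spatial map to a surplus
component that copies its temporal and subject profile, with almost no cost
in reconstruction error. Experiments against synthetic ground truth show
that optimizing the objective to full convergence makes the surplus
components slowly absorb structured noise and bend the true networks'
spatial maps (fit improves in the fourth decimal while factor congruence
with the ground truth degrades), whereas stopping each rank's joint
optimization after on the order of a hundred Nadam steps recovers the planted networks
both better and with much less run-to-run variability. The default is
therefore `max_iter` = 100 Nadam steps per rank with relative-error
tolerance 1e-6 checked every 10 iterations; both are exposed in
`NascarOptions` for users who want a fully converged (but less
well-identified) fit. Divergence — persistent error increase well above the
best value seen — aborts with a diagnostic.

After the final rank, factor columns are renormalized, the scale folded into
λ, signs fixed (largest-magnitude entry of the subject and spatial factors
positive, the temporal factor absorbing the flips), and components sorted by
descending λ.

### Exact vertex-order invariance

Results should not depend on how voxels happen to be ordered on disk.
Floating-point reductions are not associative, so naive BLAS contractions
over a permuted space axis produce 1-ulp differences that then amplify
through thousands of iterations. The solver therefore sorts voxels into a
canonical order (lexicographic by the first unfolding columns) before
optimization and restores the caller's order on output; every reduction over
space happens in canonical order, making permutation invariance *bitwise
exact* rather than approximate.

### Identifiability caveat of row normalization

Each subject's rows are normalized to zero mean and unit norm before
synchronization. For a multi-network mixture this rescales voxel i of
subject s by 1/‖row‖, a subject-dependent diagonal, so the identifiable
common spatial factor is the planted map bent by the loading-weighted
average of those row scalings. Tests that check exact recovery therefore
either use homogeneous subject loadings (`loading_sigma=0`, where the
rescaling is a common diagonal and the noiseless tensor is exactly CP) or
compare against the rescaled target; tests of the end-to-end scientific
claims (sign structure, nucleus significance, split-half reproducibility)
use the heterogeneous default.

## Network maps and ROI statistics

The target network is selected as the component whose cortical spatial part
has maximal absolute Pearson correlation with a cortical template map; the
component is sign-aligned so the correlation is positive, and its magnitude
rank is logged (on both real and synthetic data the global "physiological"
component is strongest and the DMN second). Selection below |r| = 0.3 raises
an error, signalling a failed decomposition rather than silently analyzing
noise.

Because absolute values in normalized-data space are not interpretable, the
subcortical part of the map is divided by the 95% quantile (linear
interpolation convention, signed values after sign alignment) of the
cortical part: the normalized subcortical map reads as a fraction of
cortical network strength. The subcortical vector is scattered into its 3-D
grid and upsampled trilinearly (voxel-centre alignment: output sample j sits
at source coordinate j/factor; source voxel centres reproduce their values
exactly; NaN outside the subcortical support propagates). The default
upsampling factor is 2 (2 mm → 1 mm at the emulated resolution); the atlas
is nearest-neighbour upsampled onto the same grid.

Per ROI, the map values are summarized and each nucleus is tested against
its containing anatomical region with a one-sided Welch two-sample t-test of
mean(nucleus) > mean(region). The region sample *includes* the nucleus
voxels (the anatomical region contains the nucleus; an `include_roi=False`
variant exists for sensitivity analysis). Welch rather than pooled variance
because nucleus and region differ grossly in size and variance; one-sided
because the scientific claim is directional ("significantly higher").

Interpolation and intrinsic smoothness make voxels dependent, so raw
p-values are corrected by random field theory: the ROI's resel count is
volume/FWHM³ (default FWHM 2 mm — the nominal smoothing of the emulated
preprocessing — configurable because effective smoothness exceeds applied
smoothing), and the corrected p-value is p_raw plus resels times the 3-D
t-field Euler-characteristic density, clamped below at zero so
p_corrected ≥ p_raw always. Boundary (2-D/1-D) resel terms are omitted: the
resel definition used here involves only ROI volume and FWHM. The
Monte-Carlo validation of this formula simulates t-fields smoothed with
periodic boundary conditions (a torus), where boundary terms vanish exactly
and the volume-only expected Euler characteristic is the correct tail
approximation; on bounded regions the formula under-approximates the
correction by the missing surface terms, which is the documented trade-off
of the volume-only convention.

Mask utilities: morphological erosion with a sphere of given physical radius
(used to separate touching structures such as putamen and pallidum before
analysis; radius 0 is the identity, and a mask that erodes to nothing warns
instead of raising) and probability-map thresholding that reports the
percentile of the chosen threshold within the map's nonzero support, so a
stated threshold/percentile pairing is checkable.

## Seed-based comparison

The classical alternative: Pearson correlation between a single cortical
seed vertex and every subcortical voxel, per subject; group maps combine by
Fisher-z averaging (variance-stabilized; the group rule is this package's
choice). Global signal regression (GSR) — projecting every row onto the
orthogonal complement of the mean grayordinate time series, then
re-normalizing — is available per subject; residuals are exactly orthogonal
to the global signal, and re-centring preserves this because the global
signal of zero-mean rows is itself zero-mean. GSR mathematically introduces
negative correlations: with a dominant all-positive global component and
strictly nonnegative network weights, the post-GSR seed map still contains
negative values. The tensor route needs no GSR because the global component
is captured as a separate factor. Correlations are computed on the
unsynchronized data; synchronization provably cannot change them
(orthogonal invariance), and a test asserts rather than assumes this.

## Synthetic data: what it emulates, and what it does not

`generate_dataset` draws, per subject, `(Σ_r λ_r c_rs a_r b_rᵀ) Q_s + ε`,
then centres and normalizes rows. Ingredients:

* **Spatial maps**: smooth compact Gaussian blobs — two cortical hubs per
  network in disjoint blocks of the cortical index line, and 3-D Gaussian
  blobs on the subcortical grid. The DMN-like network (index 1) is positive
  over the toy CL, VTA and caudate and negative over putamen and globus
  pallidus, mirroring the hypothesized anatomy; the global component (index
  0, largest λ) is near-uniform positive everywhere.
* **Temporal courses**: band-limited Gaussian noise (default band
  0.01–0.12 cycles/frame, the slow range where resting-state power
  concentrates), QR-orthogonalized across networks so CP recovery is
  well-posed; the band excludes DC so courses are zero-mean.
* **Subject loadings**: lognormal (spread `loading_sigma`, default 0.5),
  normalized — participation is strictly positive and right-skewed.
* **Misalignment**: independent Haar-random orthogonal `Q_s` per subject
  (sign-fixed QR of a Gaussian matrix), the exact condition the
  synchronization stage assumes.
* **Noise**: i.i.d. Gaussian, scaled per subject so signal/noise variance
  equals `snr`. All draws are independent of the magnitudes and of `snr`, so
  doubling all λ leaves the emitted normalized data bit-identical.

Defaults are the desk-scale study conditions used throughout the acceptance
experiments: V = 2000 grayordinates (1600 cortical, 400 subcortical on a
10×10×4 grid), T = 300, S = 40, five networks with magnitudes
(8, 5, 3.5, 2.5, 2), snr = 2, misalignment on. The toy atlas places seven
spherical ROIs (thalamus ⊃ CL, brainstem ⊃ VTA, caudate, putamen, GP) on
the grid, with Gaussian-falloff probability maps for thresholding.

Not emulated: hemodynamics, head motion, physiological noise spectra,
spatial autocorrelation of the noise, surface geometry, registration error.
Passing tests therefore demonstrate the correctness and statistical
behaviour of the pipeline under its own model assumptions, not performance
on real scanner data — in real data the signal fraction is far lower (a
rank-30 model explains on the order of a tenth of the variance) and
inter-subject registration error adds spatial blur that no amount of
temporal synchronization removes.

## Numerical choices and degenerate inputs

* Quantile convention: linear interpolation (the numpy default), stated
  because the 95% quantile is a published normalization constant.
* Trilinear upsampling uses voxel-centre alignment; zero-weight corners are
  skipped so NaN support does not leak into exact-centre samples.
* Constant (dead) time series raise an error naming the row.
* A zero tensor decomposes to all-zero magnitudes with placeholder unit
  factors; explained variance of a zero tensor is an error.
* Welch df follows the Welch–Satterthwaite formula; a zero-variance sample
  degrades gracefully (df from the other sample's term).
* The group-sync objective is logged against the unit-row-constrained
  reference, the form under which monotonicity is provable.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical configuration and seed reproduce
  every output bit-for-bit.

## Problem sizes

Unit tests run on tensors of a few hundred voxels and seconds of runtime.
The reproducibility experiment and the end-to-end acceptance checks use the
default study conditions above (two independent 20-subject pipelines on
2000×300 matrices; the sign-structure check uses 16 subjects and rank 6),
sized so the full suite completes comfortably on a single CPU.

## Known limitations

* Group synchronization of subjects that differ in network *participation*
  (not merely temporal frame) is not a no-op: the Procrustes transform of a
  subject whose network weights differ from the reference rotates the
  temporal subspace slightly to compensate, so each subject's effective
  temporal factors deviate from the common ones. On data already in a
  common temporal frame, synchronization can therefore reduce recovery
  accuracy; both the model and the pipeline expose `sync=False` for that
  case. On genuinely misaligned data the alignment benefit dominates.
* Over-ranked CP non-identifiability is mitigated, not eliminated, by warm
  starts and early stopping; surplus components can still trade small
  amounts of spatial structure with true networks.
* The volume-only resel formula under-corrects on bounded ROIs (see above).
* The temporal factors of a synchronized decomposition are identified only
  up to a common orthogonal transform of the time axis; comparisons against
  pre-synchronization ground truth must restrict to the spatial and subject
  modes (`match_components(..., modes=("spatial", "subject"))`).
* Fisher-z group averaging assumes roughly independent per-subject maps;
  no spatial dependence correction is applied to the seed-based maps.
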