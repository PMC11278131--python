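# Methods

This note records the models, parameter choices and numerical conventions
behind `spatialrqa`, and what the packaged synthetic data can and cannot
show about real histology.

## Feature extraction

**Pipeline.** A patch is converted to relative luminance
(0.2126 R + 0.7152 G + 0.0722 B, scaled to [0, 1]), smoothed, and
contrast-normalized; the level-1 Haar approximation subband (exact 2×2 block
means, obtained by dividing the LL coefficients by 2 per level so the values
stay on the [0, 1] scale) is then read into a 1-D attribute vector along a
Hilbert curve; delay embedding with dimension 2 and lag 1 produces
state-space points; a depth-2 dyadic quadtree of the unit square assigns
each point one of 16 cell symbols; and seven recurrence statistics are
computed per cell. The parameterization (embedding dimension 2, lag 1,
quadtree depth 2, seven measures per cell) is the uniform per-cell inventory
that yields 16 × 7 = 112 features.

**Noise reduction and normalization.** The smoother is a grey opening
followed by a grey closing with the 3×3 4-connected (cross) structuring
element; the contrast stretch maps `median ± 1.5·IQR` linearly onto [0, 1]
and clips outside. Three properties motivated this pair over the more
common median-filter + 1st–99th-percentile stretch:

* *Exact idempotence.* The opening–closing composition is idempotent, flat
  (rank-based) morphology commutes with monotone point maps, and the
  quartiles are order statistics untouched by tail clipping — so applying
  the pre-processing to its own output is a no-op to floating-point
  exactness. A median filter is not idempotent; repeated passes drift.
* *Noise-floor robustness.* The 1st/99th percentiles sit in the extreme
  tails, exactly where additive pixel noise inflates the distribution most;
  anchoring the stretch on quartiles decouples the global value mapping
  from the image's noise level, so recurrence features do not shift when
  only the noise floor changes (the situation a real-vs-generated
  comparison must tolerate).
* *Edge preservation.* The cross footprint biases edges less than the full
  3×3 square while still removing 4-connected speckle.

The half-width 1.5 IQR is the conventional robust-fence constant; values
beyond it (deep nuclei, bare background) saturate at 0/1, which further
stabilizes cell occupancies against calibration shifts. A constant patch has
no contrast to stretch and degenerates to all zeros with a warning.

**Recurrence measures.** With symbol sequence `s_1..s_T` and cell `c`
visited `k` times: occupancy `k/T`; pairwise recurrence rate
`[C(k,2)/C(T,2)]/(k/T)` (0 when k < 2); mean and Shannon entropy (nats) of
the empirical distribution of maximal run lengths, counting only runs of
length ≥ `run_min` = 2 (the analogue of the minimum line length in
recurrence quantification, suppressing single-sample visits produced by
boundary jitter); mean and entropy of the gaps between successive visits;
and the self-transition probability. Unvisited cells contribute a zero
block, so feature vectors are comparable across patches — the reason the
quadtree uses fixed dyadic cells rather than data-adaptive splits. The
boundary value 1.0 belongs to the last cell of its axis (half-open cells).

**Hilbert orientation.** With image-convention rows (downward from top
left), the order-1 curve visits bottom-left, top-left, top-right,
bottom-right. Any consistent orientation is equivalent for cross-patch
comparison; the convention is fixed in code and exercised by exhaustive
bijection/4-adjacency checks for sides 2–16.

## Cohort comparison

**Selection then testing.** The LASSO (logistic, L1, columns z-scored,
penalty chosen by 10-fold stratified cross-validated log-loss at the
CV-minimum, liblinear solver, seeded folds) is fit on the *phenotype*
contrast — normal-analogue vs cancer-analogue — and the Hotelling tests for
all three cohort pairs then run on the selected features. Selecting on the
phenotype axis rather than on real-vs-synthetic keeps the null comparison
(real vs near-copy) free of selection bias, mirroring the intended study
design in which features are chosen for their relation to tumour
architecture. Exactly constant columns are dropped before fitting
(constancy is tested with the column range, since a column-wise standard
deviation of an exactly constant column can round to ~1e−15 instead of 0).
CV-minimum is deliberately liberal; under permuted labels it usually — but
not always — returns an empty model, and the tests assert that behaviour at
its measured rate rather than as an absolute.

**Hotelling's T².** `T² = (n₁n₂/(n₁+n₂)) d′S⁻¹d` with pooled covariance S;
`F = T²(n₁+n₂−p−1)/(p(n₁+n₂−2))` on (p, n₁+n₂−p−1) degrees of freedom. When
the selected dimension approaches the sample size the pipeline reduces the
pair to principal components retaining 95% variance, and a near-singular
pooled covariance falls back to 10% diagonal shrinkage; the method actually
used is recorded in `comparison.json`. Raw p-values are reported alongside
Bonferroni-adjusted ones (three pairwise tests, no correction in the
original design). With p = 1 the statistic reduces exactly to the squared
pooled-variance t (verified to 1e−10), and 1000-replicate null simulations
put the empirical size at the 5% level within [0.03, 0.07].

**PCA profiles.** Features are z-scored before PCA because the 112 features
mix scales (probabilities, counts ≤ T, entropies). Per-group radar profiles
report the mean score and a t-based 95% CI on each of the first five
components; groups under 3 rows get no CI.

## Generative-model metrics

FID is the Fréchet distance between moment-matched embedding Gaussians,
`‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2})`, with the cross term computed by
symmetric eigendecomposition of `Σ₁^{1/2}Σ₂Σ₁^{1/2}` (stabler than a direct
product square root); eigenvalues above −1e−8 are clipped to zero, anything
more negative is an error. Inception Score is `exp(mean KL(row‖marginal))`
over a class-probability table, with the usual split-mean ± SD when
`n_splits > 1`; the Relative Inception Score is IS(synthetic)/IS(real)
under the same classifier — the only reading consistent with "relative" —
with first-order SD propagation. Embedders are pluggable inputs: the
package neither bundles nor downloads network weights. The shipped mock
embedder (seeded random projection of a 16×16 block-mean intensity grid)
exists to exercise the metric paths deterministically; its FID/RIS values
characterize the mock embedding space, not Inception-V3 space. The
whole-image intensity PCA averages channels while retaining positions
(optionally block-averaged to 16×16) and feeds the standardized PCA.

## Synthetic data: what it emulates, what it does not

`TextureSpec` renders dark Gaussian-profile discs ("glands") composited
multiplicatively on a 1/f (pink-noise) background, tinted along an
eosin-like colour axis. Regularity is one knob: REGULAR uses lattice jitter
0.05 (normal-tissue analogue), IRREGULAR jitter 0.6 plus element-size
dispersion (cancer analogue); NOISE is spatially uncorrelated. Each patch
additionally draws macro parameters — background level N(0.88, 0.02), a
log-normal gland-caliber multiplier (σ = 0.10), stain-uptake amplitude
N(0.50, 0.04) — emulating the patch-to-patch variability of patches cut
from different slide regions; without it, cohorts are unrealistically
homogeneous and any systematic processing artefact becomes arbitrarily
significant. Additive pixel noise (SD 0.02 on [0, 1]) stands in for sensor
and compression grain. The generative near-copy (`perturb_patch`) applies a
smooth random displacement field (SD 1 px, Gaussian correlation σ = 8 px,
bilinear resampling) plus fresh additive noise.

Everything is a pure function of its spec including the seed (Philox
streams keyed per patch; per-patch seeds derive from the master seed and
the (class, index) position, so subsets are reproducible).

Limitations: the textures are not photorealistic histology — no nuclei,
stroma, lumina or stain-separation physics — and no claim is made that
their image statistics match scanned tissue. Passing tests therefore show
that the pipeline's mathematics and its robustness/power trade-offs behave
as designed on textures with a controlled regularity contrast; they do not
certify performance on any particular scanner, stain or tumour type.
The tissue-content criterion (fraction of pixels below relative luminance
0.86) is a plain background threshold, not a stain segmentation; tiling
defaults to the 90% tissue threshold used for recurrence analysis, with
75% available for looser curation.

## Problem sizes and defaults

The packaged demo re-enacts the three-cohort design at desk scale:
n = 100 patches per cohort at 128 px (features extracted in ~10 ms/patch;
a full three-cohort run takes a few seconds on one CPU). The type-I
calibration uses 1000 replicates at n = 50/group, 10 dimensions. The
whole-image outlier screen flags images whose RGB mean lies more than 2
cohort SDs from the cohort mean, computed in a single pass over all images
with no iterative re-screening; shifting every image by a constant changes
no memberships. Patch sizes 64/128/256 are the standard tiling set; other
sizes work with a warning.
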