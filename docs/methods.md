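# Methods

This note documents the models, parameter choices and limitations of
`braintexture`, in the order the pipeline runs.

## Synthetic cohorts

**What is emulated.** The generator stands in for segmentation-normalized,
MNI-registered T1 volumes ("already registered": all subjects share one
coordinate frame) of two classes, VisDys+ and VisDys−.  A brain is an
ellipsoid of three nested intensity compartments (CSF-, GM- and WM-like
analogues at intensities 1, 2, 3; background exactly 0, semi-axes 0.42 /
0.31 / 0.19 of the volume).  Two class-controllable texture mechanisms
mirror the two feature maps the analysis focuses on:

* *boundary smoothness* (Gaussian blur of the compartment boundaries, in
  voxels) — the inner-cortex regularity that GLCM **energy** is sensitive
  to;
* *cortical folding* (smooth random undulation of the outer surface:
  a unit-variance Gaussian-process field, 70%, plus a random-phase
  sinusoid in the spherical angles, 30%, scaled to roughly the requested
  amplitude in voxels) — the surface complexity that **entropy** tracks.

Additive Gaussian intensity noise (default sd 0.05 on compartment
intensities of 1–3, i.e. a few percent of the dynamic range) models
acquisition noise inside the mask only.

**Energy–smoothness coupling.** After equalization to 16 levels, blurring
the boundaries spreads the in-mask intensity distribution, so each grey
level covers a wider intensity band and the acquisition noise crosses
level boundaries less often; cube GLCMs concentrate on fewer entries and
boundary-shell energy rises (entropy falls).  This monotone coupling is a
*noisy-regime* property: in a strictly noise-free, piecewise-constant
volume the sharp boundary is itself maximally ordered and blurring lowers
energy.  Both regimes separate the classes by a threshold on shell energy;
only the direction differs.  Tests exercise the monotone coupling at the
default noise level and threshold separability at zero noise.

**Clinical scores.** A latent severity is standard normal within class
with a +1.5 shift for VisDys+.  Each score is coupled to it by a Gaussian
copula: the target Spearman ρ is converted to the latent Pearson
correlation r = 2·sin(πρ/6), variables are conditionally independent given
the latent (single-factor structure, always positive semi-definite for
|r| < 1), and marginals are normal at mid-instrument range with
sd = range/6, clipped to the instrument range (clipping < 1% by
construction, so rank correlations are essentially unattenuated).
Follow-up scores are T0 + per-variable shift + N(0, 1) noise.  Instrument
ranges (PANSS factors, SANS factors, GAF 1–100, BDI-II 0–63, VisDys 0–56)
are plausible analogues, not scored instruments.

**Default sizes.** 20 subjects per class at 64³ voxels as the generator
default; tests and the acceptance script use 48³ (classification recovery)
and 32³ (end-to-end) cohorts, sizes at which the full analysis runs in
minutes on one CPU while every stage still has non-trivial spatial
structure.  Effect sizes (smoothness 0.5 vs 2.0 by default, 0 vs 2.5 in
the strong-contrast recovery settings) are free parameters of the
generator, not calibrated to any real cohort.

**What passing tests do not show.** The generator has no neuroanatomy,
no scanner/site effects, no partial-volume structure and no registration
error; recovery results on it demonstrate that the pipeline's machinery is
correct and sensitive, not that comparable accuracies are attainable on
clinical MRI.

## Quantization

Per-volume histogram equalization onto G levels: level(v) = ⌈G·F(v)⌉ − 1
with F the empirical CDF over in-mask voxels.  This mapping is monotone,
idempotent at fixed G, maps an already-uniform 16-value image bijectively,
and yields the flattest achievable level histogram under a monotone map.
Equalization is per-volume (cohort pooling would leak information across
CV folds) and background is pinned to level 0 and excluded from the CDF —
background is non-informative and the texture stage excludes pure-
background cubes anyway.  Default G = 16; `select_bin_count` searches any
candidate grid (conventionally 2–256 in steps of 2) by a caller-supplied
downstream balanced-accuracy evaluator, breaking ties toward fewer levels
and skipping candidates whose evaluation fails.

## Texture feature maps

Defaults: cube 5³, stride 1, the four standard in-plane unit offsets on
each axial slice of the cube, symmetric GLCMs, natural-log entropies.  A
5³ cube at G = 16 yields 5 slices × 4 offsets × ≈40 symmetric pairs per
GLCM — enough pairs for stable statistics while keeping near-voxel map
resolution.  A cube is valid if it contains at least one voxel of nonzero
original intensity (literal exclusion of empty cubes); invalid positions
carry NaN and a False mask entry.

The implementation computes, per offset, a pair-code image (g₁·G + g₂) and
windowed histograms of all cube positions at once (bincount over
offset-shifted codes), evaluating the Haralick statistics on integer count
vectors with a c·ln c lookup table.  This is numerically exact — tests
verify equality with a per-cube `glcm_2d` + `haralick_features`
recomputation at 1e-9 and with brute-force pair enumeration exactly — and
roughly two orders of magnitude faster than looping cubes.  Cost grows as
G², so searches beyond G ≈ 64 are slow; the conventional G = 16 extracts
one feature from a 48³ volume in about 1.3 s.

## Classification

The default model is a compact bias-free conv net: an average-pooling stem
(factor chosen so the pooled grid is ≈8–11 per axis), conv(4 channels, 3³),
ReLU, pool(2), conv(8 channels), ReLU, global average pooling, dense
2-way read-out.  Inputs are per-voxel z-scored with training-fold
statistics; training is full-batch Adam on softmax cross-entropy (default
3×3 learning-rate × weight-decay grid, early stopping on inner-fold BAC).
The architecture is config-driven; any stack of the supported layer types
works with the relevance module.

Nested CV: stratified outer folds (default 20, reducible for desk-scale
runs; tests use 5) with stratified inner folds (default 20 / tests 3)
selecting hyperparameters by mean inner BAC; the fold model is refit on
the full outer-train set and predicts the outer test set; outer-test
predictions are pooled into the reported metrics.  The "winner" model —
the hyperparameters selected in the most outer folds, refit on all data —
is the frozen artifact applied unchanged in external validation, which
also verifies that the validation maps carry the identical texture
configuration (G, cube, stride, offsets).  Optionally the whole outer loop
repeats with reshuffled partitions and predictions pool across repeats.

Percentages (sensitivity, specificity, BAC) are reported to two decimals,
rounded half away from zero in decimal arithmetic, so printed values are
exactly reproducible from printed rate pairs.

## Relevance propagation

The ε-stabilized rule with ε = 1e-6 is the single propagation rule:
for a linear layer with output z, R_in = x ⊙ Jᵀ(R_out / (z + ε·sign z));
ReLU passes relevance through; pooling layers are linear and use the same
rule.  Relevance starts at the predicted-class logit.  Networks are
**bias-free by default**: under the ε-rule a bias absorbs part of the
relevance and the conservation identity Σ R_in ≈ output score — the
property that makes mean brain relevance comparable across subjects —
would degrade with depth.  Bias-free ReLU networks lose little capacity
here and keep the worst-case conservation error below 1e-3.

Relevance lives on the network's input grid, i.e. the (standardized)
feature-map grid, one value per cube centre.  "Significant" voxels for the
region-fraction summary are those strictly above the 95th percentile of
in-brain relevance by default (the percentile is a parameter; at
percentile 0 the comparison is ≥, so every in-support voxel counts).  A
synthetic atlas (the generator's compartment labels, resampled to cube
centres) stands in for a neuroanatomical atlas; any integer label volume
of matching shape plugs in.

## Clustering

Affinity propagation on the negative squared Euclidean distances between
heatmaps that were z-scored within the brain mask — the z-scoring removes
per-subject output-scale differences that conservation ties to the logit
magnitude.  Median preference, damping 0.9, max 500 iterations,
15-iteration convergence window (the algorithm's conventional settings;
all exposed).  Exactly coincident heatmaps are short-circuited to a single
cluster (the message-passing fixed point is degenerate there).
Non-convergence returns the partition flagged `converged=False`.
Per-cluster profiles report baseline means and mean T1 − T0 change scores
per variable.

## Association statistics

Spearman ρ is the Pearson correlation of average ranks; p-values come from
the t-transform t = ρ·√((n−2)/(1−ρ²)) on n−2 degrees of freedom (|ρ| = 1
gives p = 0 by convention), which tests verify against both scipy and a
10,000-permutation oracle.  Each association table is one Holm family:
step-down adjusted p-values (running maximum of (m−i+1)·p₍ᵢ₎, capped at 1)
with rejection while adjusted p < α.  Change scores are T1 − T0, always;
whether a positive coefficient means improvement or deterioration depends
on the instrument's polarity and is left to interpretation.  By default
associations are computed on correctly classified subjects only — the
heatmap of a misclassified subject explains a wrong decision — with the
subset exposed as an argument.

## Pipeline and reproducibility

Stages run in the fixed order simulate → quantize → texture → train →
explain → cluster → associate, with prerequisites checked before any work.
One global seed fans out to per-stage seeds by stable hashing (SHA-256 of
"seed:stage", reduced below 2³¹), so stages are individually reproducible
and mutually independent.  The manifest records the configuration hash
(filesystem paths excluded), seed, input hashes and a hash of every output
file; rerunning with the same configuration and inputs reproduces all of
them bit-identically.  Wall-clock timings are stored under a separate
`timings` key that is explicitly outside the determinism contract.
Coordinates are 0-based voxel indices in stored axis order; affines are
carried through untouched.

## Known limitations

* No real-data validation: PRONIA-style clinical MRI is not available to
  this package, and synthetic recovery does not transfer to claims about
  clinical accuracy.
* Texture cost grows as G² (dense windowed histograms); bin searches far
  above G = 64 are impractical.
* The equalization is rank-based, so downstream accuracy is nearly
  invariant to G for any class signal that preserves intensity ranks; the
  bin-count search only matters when discretization itself interacts with
  the signal.
* The conv net trains full-batch on CPU-scale cohorts; very large cohorts
  would need minibatching (supported) and more epochs.
* 2D (slice-wise) GLCMs only; no 3D co-occurrence, run-length or wavelet
  features.
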