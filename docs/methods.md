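# Methods note

This note describes what the `sfmap` package computes and why the numerical
choices were made. It is a description of the implementation, not a report of
empirical findings; every quantity mentioned here is recomputed by the test
suite or by `scripts/acceptance.py`.

## Problem

Glaucoma damages retinal ganglion cells; the damage is visible structurally in
optical coherence tomography (OCT) volumes of the macula and functionally as
sensitivity loss at the 52 test locations of a 24-2 visual field (VF). The
package asks: *given a model that predicts pointwise VF sensitivity from an
OCT volume, which retinal locations does the model rely on for each VF
point, and do those locations agree across a group of eyes?* The answer is a
group-level structure–function map: for each VF point, a statistical map over
en-face retinal patches.

Because no clinical data ships with the package, all experiments run on a
synthetic cohort with a *planted* structure–function mapping, so recovery can
be scored exactly.

## Visual field grid (`vf_grid`)

The 24-2 pattern is built from first principles: a 6°-spaced lattice covering
±27° horizontally and ±21° vertically, restricted to the standard 54
locations, minus the two blind-spot points at (15°, ±3°), giving 52 points
serialized row-major (superior to inferior, nasal step included). The module
provides the two symmetry permutations used throughout:

- **vertical mirror** — maps each point to its reflection across the
  horizontal midline; an involution on indices.
- **left/right flip** — maps a left-eye field into right-eye convention by
  negating the horizontal coordinate; also an involution.

Mean deviation (MD) is the reliability-unweighted mean of total deviation
against a radially decaying normative profile. Test reliability uses the
conventional cutoffs (fixation losses < 33%, false positives and false
negatives < 15%); per-test weights are inverse pointwise-SD, normalized to a
maximum of 1.

## Synthetic cohort (`synthetic_cohort`)

Each synthetic eye consists of a raw OCT-like volume series and a VF series.
A planted mapping assigns each VF point a small set of en-face patches with
the anatomic vertical inversion (superior field ↔ inferior retina) and exact
mirror symmetry between hemifield twins. Damage is a smooth spatial field
concentrated on the patches mapped from the eye's defect pattern; it darkens
a bright band in the rendered volume and attenuates VF sensitivity through a
linear forward rule (`forward_truth`). Severity classes (healthy / early /
moderate–advanced) are drawn with fixed probabilities; left eyes are stored
in their native frame and flipped during preprocessing.

Per-eye noise streams are independent substreams
(`np.random.default_rng([seed, eye_index])`), so cohorts are reproducible
and adding eyes never perturbs existing ones.

`OracleRegressor` inverts the generative rule directly from the rendered
band intensity. It is used wherever an exactness property is asserted
(locality, mirror symmetry, severity direction), isolating those properties
from training variance.

## Preprocessing (`preprocess`)

1. **Flattening** — each A-scan is shifted so the detected surface lands on a
   common plane (the rounded median surface height); vacated voxels are
   filled with the volume mean so later occlusion baselines are unaffected.
2. **Central crop** — a half-open window `[c − w/2, c + w/2)` around the
   volume center en face, anchored at one third of the axial extent.
3. **Downsampling** — Gaussian anti-aliasing (σ = factor/2) followed by
   block-mean decimation. Block means keep the operation exactly
   mirror-equivariant, which the symmetry guarantees rely on.
4. **Temporal smoothing of VF series** — per-point ordinary least squares
   over a sliding window of 5 visits, evaluated at the window center.

Left eyes are flipped to right-eye convention (volume axis reversal plus the
VF flip permutation) before any pooled analysis.

## Regressor (`regressor`)

The regressor is a small fully connected network written in NumPy: features
are non-overlapping 3D average-pool means of the processed volume (one value
per pooling block), standardized by the feature mean and a **single global
scalar** standard deviation. A per-feature scale would inflate low-variance
background patches and distort occlusion attributions, so it is deliberately
avoided. Targets are centered by the training-set mean and the output layer
is zero-initialized, so the model starts at the cohort-mean baseline.

Training uses hand-written Adam with **coupled L2 regularization**: the
penalty `λ‖W‖²` is added to the loss and its gradient, so stationary points
are exactly ridge minima. With ~50–60 training pairs against several hundred
features the unpenalized problem is in the interpolation regime; the fit then
spreads weight diffusely across patches and occlusion attribution collapses.
Ridge shrinkage restores localized attributions. Decoupled weight decay
(AdamW-style) does *not* have this property under Adam's preconditioner and
was found insufficient; see the default `weight_decay = 1e-2`.

Validation uses a by-eye split so that no eye contributes to both sides.
Reported accuracy is weighted MAE against held-out smoothed VF targets,
compared with the cohort-mean baseline. A SHA-256 checksum of the final
weights makes determinism testable.

## Occlusion saliency (`occlusion`)

The volume is tiled by non-overlapping patches (default 4×4×4 voxels). For
each patch the occluded volume replaces the patch with the **global volume
mean**, computed once from the unmodified volume so occlusion is idempotent.
Saliency for VF point *p* and patch *j* is `|f_p(V) − f_p(T_j(V))|`. The
3D saliency grid is projected en face by averaging over the depth patch
axis. For a linear model this has a closed form, which the tests check to
1e-10.

## Group mapping (`group_mapping`)

Per-pair en-face maps are registered to a common grid by integer patch-shift
alignment of the disc center (vacated cells become NaN and are excluded
per-cell). Pairs are split by MD of the associated smoothed VF test:
healthy-to-early (MD > −6 dB) versus moderate-to-advanced (MD ≤ −6 dB).

For each en-face cell *k* the group statistic is a one-sample, one-sided
t-statistic against a data-derived null level `μ = mean(S) + 0.75·sd(S)`
pooled over all cells and pairs:

    t_k = (S̄_k − μ) / (s_k / √N_k)

Cells with p > 0.05, zero variance, or fewer than two contributing pairs are
zeroed. Benjamini–Hochberg correction is available but off by default, which
is the more conservative choice for *recovery* scoring (fewer suppressed
cells means false positives are penalized by precision, not hidden).

Recovery against the planted mapping is scored per VF point by precision and
recall of supra-threshold cells, a top-*m* hit rate (*m* = planted region
size) that counts only supra-threshold cells — a map with no supra-threshold
cell makes no localization claim and scores 0 — and a hemifield-inversion
index measuring how much map mass falls in the anatomically opposite retinal
half.

`severity_correlation` computes, per VF point, the Pearson correlation
between total en-face saliency and the point's smoothed sensitivity; under
the generative rule more damage means more saliency and less sensitivity, so
the correlation direction is negative.

## Pipeline (`pipeline`, `cli`)

Two profiles exist: a **desk** profile (64×64×192 raw volumes, 60 eyes) that
completes on one CPU in minutes, and a full-scale **"paper"** profile with
literature-typical geometry (144×144×576 crop, 72×72×144 processed,
18×18×36 patch grid, 200 epochs) that validates but is not exercised by the
tests. Profile constants are checked against a frozen table at validation
time so they cannot drift silently.

The file-based pipeline writes each stage (simulate → preprocess → train →
occlude → map → score) to disk with a checksummed manifest; re-running
verifies checksums and skips clean stages, and a tampered file triggers
recomputation that reproduces the original checksums bit-for-bit. Three
details make that determinism hold:

- intermediate volumes are stored as float64 NIfTI (float32 round-tripping
  perturbs training inputs);
- VF CSVs are parsed with round-trip float precision;
- NIfTI arrays are converted to C order before pooling, because summation
  order differs between C- and Fortran-ordered memory by ~1 ULP, which
  training amplifies.

## Limitations

The synthetic generator is a caricature: the forward rule is linear, noise
is Gaussian, and anatomy is reduced to a bright band with a planted dark
crater. It is designed so that correctness properties (locality, symmetry,
monotonicity) have exact ground truth, not to be biologically realistic.
Conclusions about clinical OCT/VF data require real cohorts and are out of
scope for this package.
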