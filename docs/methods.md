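# Methods

`ihctps` re-implements an automated tumor proportion score (TPS) workflow for
PD-L1 immunohistochemistry on non-small cell lung carcinoma, together with the
statistics used to compare automated scores against pathologist panels, and a
synthetic H-DAB image simulator that supplies ground truth for every stage.
This note records the models, the parameters that matter, the numerical
choices, and what the synthetic validation does and does not demonstrate.

## Stain model

Brightfield absorbance follows Beer–Lambert: per channel,
`OD_c = log10(i0 / max(pixel_c, 1))` with white point `i0 = 255`. The floor of
one grey level keeps OD finite; white maps exactly to OD 0. A pixel's OD
3-vector is modelled as a non-negative combination of unit absorbance vectors
for hematoxylin, DAB and a residual direction (the normalized cross product of
the first two). Defaults are the standard published H-DAB directions,
hematoxylin ≈ (0.651, 0.701, 0.290) and DAB ≈ (0.269, 0.568, 0.778), each
renormalized; they are configuration, recorded in output manifests, because
real scanners and staining batches differ. Deconvolution is the per-pixel
linear solve; negative concentrations from noise are preserved internally
(keeping the operation exactly linear and testable) and clamped to zero only
when intensities are measured.

Round-trip accuracy: in floating point the compose → deconvolve cycle is exact
to ~1e-15. Through 8-bit quantization, the worst-case OD error is bounded by
`0.5/(pixel·ln 10)` amplified by the inverse stain matrix; over the intensity
regimes the simulator produces (nucleus-dominated hematoxylin up to ~1.0 OD,
membrane-ring DAB up to ~1.15 OD, never both maximal in one pixel) the
measured bound is ≤ 0.02 OD. The bound grows without limit as pixels approach
black, so no claim is made for jointly saturated stains.

## Cell detection

Nuclei are segmented in the deconvolved hematoxylin channel: Gaussian
smoothing (default σ = 1.5 px) → fixed OD threshold (default 0.1) → hole
filling → optional watershed splitting of touching objects, seeded at
distance-transform maxima at least 4 px apart → area gate (default 30–800
px²). All defaults are configuration at the simulator's scale, not claims
about any particular acquisition.

Cell areas are estimated by proximity-constrained expansion: every pixel
within `cell_expansion` (default 5 px) of a nucleus joins the nucleus whose
pixel set is nearest in Euclidean distance; exact ties go to the lower nucleus
id, making the partition deterministic. The implementation processes nuclei in
ascending id with per-nucleus distance maps and strict-less updates, which the
test suite verifies against a per-pixel brute-force assignment with integer
squared distances on 128×128 images. Cells are disjoint by construction, and
zero expansion returns cell = nucleus (cytoplasm intensity features then fall
back to nucleus values, flagged per cell).

## Features and classification

Each cell is summarized by a frozen manifest of exactly 67 features:

- 14 geometry features (nucleus area/perimeter/circularity/eccentricity/
  max- and min-caliper/solidity; cell area/perimeter/circularity/calipers;
  cytoplasm area; nucleus-to-cell area ratio),
- 30 intensity statistics (mean/SD/min/max/range of hematoxylin and DAB OD
  over nucleus, cytoplasm and whole cell, measured on zero-clamped channels),
- 3 local-density features (neighbor count within 25 px, mean neighbor
  distance, nearest-neighbor distance), and
- 20 neighborhood-smoothed features (means of the geometry and
  mean-intensity features over all cells within 25 px, including self).

Circularity is `4π·area/perimeter²` capped at 1.01 to absorb discretization.
The manifest is data: its SHA-256 hash ships with every trained model and
classification refuses to run against a mismatched manifest.

The tumor-vs-background classifier is a random forest (100 trees,
sqrt-features per split, fixed seed), trained from polygon region annotations:
a cell inherits an annotation's class iff its nucleus centroid lies strictly
inside the polygon (boundary excluded, so vertex-aligned centroids behave
deterministically); overlapping polygons of different classes are an error
naming the cells. A two-class contract (tumor vs combined stroma/immune
background) is used throughout, since the score only needs tumor vs
non-tumor.

## TPS scoring

A classified tumor cell is PD-L1 positive iff the mean DAB OD over its whole
cell region strictly exceeds the threshold ("exceeded" ⇒ equality is
negative). The default threshold is 0.2 OD at the simulator's scale; because
the appropriate value is assay- and batch-dependent, a calibration helper
sweeps candidate thresholds against annotated positive/negative cells and
reports the accuracy-maximizing value. Positivity is deliberately computed
over the whole cell region, not a membrane sub-compartment: membrane staining
falling outside the estimated cell area is a documented failure mode the
simulator must be able to reproduce (the `oversize_cells` artifact), not one
the scorer silently fixes.

Patch TPS = 100 · positives / tumor cells. Patches with zero tumor cells are
unscorable — a distinct signal, never TPS 0 — and are excluded from case
pooling (treating them as 0% would bias pooled scores with no evidence). Case
scores pool raw counts across patches, which is algebraically identical to
the tumor-count-weighted mean of patch TPS values (property-tested on random
count tables). Categories <1, 1–49 and ≥50 percent are assigned only after
any averaging, with boundaries at exactly 1 (inclusive) and 50 (inclusive).
The multi-rater gold standard is the arithmetic mean of the raters'
continuous scores, categorized afterwards; the tests demonstrate this differs
from majority-voting categories.

## Agreement statistics

- **Lin's CCC** uses population (1/n) moments — the original definition;
  sample-variance variants differ at small n — with a Fisher-z confidence
  interval from Lin's large-sample variance.
- **Cohen's kappa** uses marginal-product expected agreement, the standard
  large-sample SE `sqrt(p_o(1-p_o)/(n(1-p_e)²))`, Wald bounds truncated to
  [-1, 1], and the interpretation bands 0.40–0.69 weak, 0.70–0.79 moderate,
  0.80–0.89 strong, ≥ 0.90 near perfect. Degenerate marginals (p_e = 1) are
  signalled; batch evaluation reports such cells as undefined rather than
  aborting.
- **Dichotomized agreement** treats score ≥ threshold as positive (consistent
  with the 1–49% and ≥50% category bounds); the gold standard defines truth
  for sensitivity and specificity.
- **Rank tests** are scipy's tie-corrected Wilcoxon signed-rank (zeros split)
  and Mann-Whitney U, two-sided; all-zero paired differences are reported as
  degenerate with p = 1. Category distributions are compared with Pearson
  chi-squared (no continuity correction). No multiple-testing correction is
  applied.
- **Bland–Altman** limits are mean difference ± 2·SD (n−1 denominator).
- **Kappa power arithmetic** uses the two-independent-group normal
  approximation: minimum detectable difference
  `d = (z_{1-α/2} + z_power)·sd·sqrt(2/n)` and its exact inverse for power.
  At the study's sample sizes this evaluates to a detectable difference of
  0.11 at n = 207 (power 0.80) and power 0.6 for d = 0.15 at n = 69, with
  sd = 0.4 and α = 0.05.

## The simulator

Synthetic patches emulate H-DAB-stained NSCLC tissue: elliptical nuclei of
two morphological populations — tumor (radius 5.0 ± 0.6 px) roughly three
times the area of stroma/immune background (2.8 ± 0.3 px) — with nuclear
hematoxylin 0.7 ± 0.08 OD over a faint tissue wash, and a membranous DAB
annulus (0.9 ± 0.08 OD, 1–4 px outside the nucleus boundary) on a
Bernoulli(true_positive_fraction) subset of tumor cells. Tumor and background
cells occupy opposite sides of a random straight compartment boundary so that
region annotations can separate them, as an annotating pathologist would.
Rendering goes through the same forward stain model the pipeline inverts.

Nuclei sit on a jittered square grid (pitch 24 px, jitter ±1 px) whose
geometry guarantees a minimum separation; this keeps packing feasible at any
density the experiments need, keeps rings attributable to their own cell, and
makes infeasible requests fail fast, at the cost of mild spatial regularity
that pure Poisson placement would not have. Everything is reproducible from
the spec seed; identical specs give byte-identical images and masks.

Artifact modes corrupt the image, never the stored truth:

- `debris`: off-nucleus specks of radius 2.5–4 px at ~1.5 OD DAB — some land
  in cell cytoplasm and flip negative tumor cells positive;
- `macrophages`: background-class cells with tumor-sized nuclei and strong
  membranous DAB, placed in the tumor compartment — the classifier calls
  them tumor and the scorer calls them positive;
- `edge_artifact`: a faint 0.15-OD DAB band along one border;
- `faint_staining`: 60% of positive rings re-drawn at 0.12 OD, below the
  default threshold;
- `oversize_cells`: 60% of remaining positive rings moved beyond the
  expansion radius, so the membrane signal falls outside the estimated cell.

With the default pipeline these reproduce the documented asymmetric error
structure in *direction*: debris+macrophages inflate estimates at low true
TPS (mean bias ≈ +5 points at ≤ 5% truth), faint+oversize deflate them at
high true TPS (mean bias ≈ −30 points at ~35% truth). Magnitudes are
simulator-dependent by design and are not calibrated to any cohort.

A simulated study draws case-level TPS from a clinically shaped mixture
(30% in 0–2.5%, 40% in 1.5–45%, 30% in 50–95%) and jitters patch-level
positive fractions around the case value with a Beta distribution
(concentration 40), since patches within a case are chosen to show different
staining levels. Three simulated pathologists score each patch through a
logit-normal error model `score = expit(logit(truth) + bias + ε)` with per-
rater biases (+0.30, 0.00, −0.15 logits — one reads systematically high) and
noise sd 0.7 logits, calibrated so pairwise categorical concordance at the 1%
threshold over 2000 simulated patches lands in the 80–95% range typical of
pathologist panels (~94% at 1%, ~88% at 50% as measured by the tests).

## What the synthetic validation shows — and does not

On artifact-free patches with ≥ 300 tumor cells the pipeline recovers true
TPS within 2 percentage points in ≥ 95% of seeds (measured: 100%, mean
absolute error < 0.2 points), and estimated-vs-true CCC across a 20-case ×
3-patch study exceeds 0.999. These numbers certify internal consistency —
detection, expansion, classification, thresholding and aggregation compose
correctly — not clinical performance: real tissue has texture, overlapping
and crushed nuclei, staining gradients, mucinous and sarcomatoid
morphologies, and batch variation that the simulator deliberately omits. The
two-population morphology is nearly separable by nuclear area, so classifier
accuracies near 1.0 say nothing about harder real-world discrimination; the
label-permutation control (balanced accuracy ~0.5) guards against leakage,
not against optimism.

## Problem sizes and numerical choices

Experiments default to sizes chosen for fast, deterministic runs: training
uses 30 annotated patches from 10 simulated cases (the study's training
budget) at 256² px; recovery uses 20 patches at 576² px with 320 tumor cells;
bias experiments use 10 seeds per artifact mode at 448² px; the study-shape
check generates the full 69 × 3 = 207-patch layout. Tie-breaks (lower nucleus
id wins equidistant pixels; lowest threshold wins calibration ties),
boundary rules (strict polygon interior; strict positivity inequality;
category bounds inclusive at 1 and 50) and degenerate-input behavior (blank
images, zero-tumor patches, zero-variance series, degenerate marginals) are
all fixed and covered by tests.
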