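# Methods

## The problem and the pipeline

Linear positive-mode MALDI-TOF fingerprints of *Bifidobacterium longum*
strains contain, besides a large shared backbone of ribosomal and
housekeeping-protein peaks, a small set of peaks whose presence differs
systematically between subsp. *longum* and subsp. *infantis*. The pipeline
turns a cohort of raw spectra into (1) a table of candidate discriminatory
peaks with exact association statistics, (2) trained classifiers operating
on the aligned peak features, and (3) strain-level subspecies calls
aggregated over replicate spectra. Because the original cohort's spectra were never
publicly deposited, a synthetic-spectrum generator reproducing the cohort's
statistical structure serves as the test bed; its defaults are fixed to the
published cohort conditions and are not tuned per experiment.

## Synthetic cohort model

Each cohort has `n_longum = 59` and `n_infantis = 41` strains with
`replicates_per_strain = 4` (400 spectra total). The 18 discriminatory
markers carry per-subspecies presence probabilities equal to the published
strain-count fractions (e.g. m/z 5,381: 6/59 in *longum*, 41/41 in
*infantis*). Marker carriage is a **strain-level Bernoulli draw** — the
published frequencies have per-strain denominators — after which each
present marker is dropped independently per replicate with probability
0.05, so replicates of one strain can disagree; without that imperfect
concordance, replicate voting would be vacuous.

Shared structure and noise:

- **Backbone peaks** (default 30) are drawn once per cohort, uniform over
  2–12 kDa, where most bacterial fingerprint biomarkers live. Positions
  within 2000 ppm of any configured marker are rejected and redrawn:
  backbone peaks are by definition distinct from the markers, and a
  collision inside the 500 ppm alignment tolerance would silently fuse a
  marker column with an always-present peak, destroying the very contrast
  the marker is defined by.
- **Intensities** are log-normal per strain × peak (σ = 0.3) with an extra
  per-replicate log-normal factor at half that spread; mean amplitude 1
  (arbitrary units) for all peaks. No detector-saturation model.
- **Mass jitter**: every peak center receives relative Gaussian error with
  sd 100 ppm, so the 3σ span matches the instrument's stated <300 ppm
  calibration accuracy.
- **Peak shape** (profile mode): Gaussians with FWHM = m/z / resolution,
  resolution 1000 — no resolution was published; this value keeps the
  5,381/5,394 doublet (13 Da ≈ 2,400 ppm apart) clearly resolved, as the
  published spectra show it to be. Rendered on a uniform 0.5 Da grid over
  2–20 kDa with an exponentially decaying chemical baseline
  (amplitude 0.05, scale 3 kDa) and additive Gaussian noise (sd 0.01),
  clipped at zero. Centroid mode emits the jittered stick list directly.

The generator is deterministic given its config (including the seed). What
it does **not** emulate: isotope envelopes, adducts other than [M+H]⁺,
matrix clusters, detector saturation, batch drift, or intensity
correlations between proteins — so green tests demonstrate that the
algorithms recover the *designed* statistical structure, not that they are
robust to every artifact of real acquisitions.

## Preprocessing

Conditioning = moving-average smoothing (default 7 points; no smoothing
algorithm was specified upstream, a moving average is the simplest
adequate choice), then baseline subtraction, then optional TIC
normalization. The baseline has two passes:

1. coarse envelope: rolling minimum followed by rolling mean, window
   500 Da;
2. fine centering: subtraction of the local median computed on a strided
   grid (window 100 Da, exact medians every 64 points, linearly
   interpolated).

The second pass exists because a rolling minimum sits ~2–3 noise sd below
the true baseline and lags sloped backgrounds; the residual pedestal this
leaves at low m/z generated hundreds of spurious low-intensity "peaks"
per spectrum, which chained the single-linkage alignment across the whole
mass axis. Local medians are unaffected by peaks (which are far narrower
than the median window) and remove the pedestal exactly where it matters.
Negative residuals are clipped at zero.

Peak picking keeps local maxima above
`max(snr_min × noise, min_rel_intensity × base peak)` with
`snr_min = 3`, `min_rel_intensity = 0.01`, and noise = 1.4826 × the median
absolute deviation of the conditioned trace. Peak m/z is the
intensity-weighted centroid over the FWHM span. Deduplication merges peaks
within 500 ppm (single linkage), keeping the maximum intensity —
laser-shot accumulation is already summed upstream — at the
intensity-weighted mean position; output spacing is guaranteed to exceed
the tolerance.

## Alignment and features

Cohort reference peaks: pool all centroids, sort, cut at gaps exceeding
500 ppm of the local mass (single linkage), take each cluster's arithmetic
mean, and drop clusters supported by fewer than 5% of spectra
(`min_support_frac`, a noise filter the original analysis does not
document). 500 ppm absorbs the ≤300 ppm calibration error while keeping
the 5,381/5,394 pair in separate bins. Featurization marks presence when a
spectrum has a peak within tolerance of the reference (nearest wins on
ties) and records relative intensity = matched intensity / base-peak
intensity. Strain-level presence, used by the screening statistics,
requires detection in at least half of the strain's replicates — the
replicate-collapse rule behind per-strain frequencies is otherwise
unspecified.

## Screening statistics

- **Fisher exact test** (two-sided, probability-mass summation with a 1e-7
  relative tie tolerance) on the strain-level 2×2 presence table. Sidedness
  was not specified upstream; two-sided by mass summation is the common
  convention (and what `scipy.stats.fisher_exact` computes — the
  implementation here enumerates the hypergeometric masses explicitly and
  is cross-checked against both scipy and an exact-rational oracle in the
  tests). No multiple-testing correction is applied, matching the original
  analysis.
- **Single-feature AUC** on strain-average relative intensity, positive
  class *infantis*. Longum-specific peaks therefore score *below* 0.5;
  reports that want "discriminative power regardless of direction" should
  read max(AUC, 1 − AUC).
- **Specificity call**: a peak is called specific to a subspecies when its
  frequency there is ≥ 0.95 while the other class is ≤ 0.05 — thresholds
  chosen to formalize "exclusively found" given observed exclusive
  frequencies of 94.9–100%.
- **PCA** on strain-average feature vectors (column mean-centered, top-2
  SVD); **heatmap matrix** keeps the 50% of peaks with smallest Fisher p
  and orders strains and peaks by average-linkage clustering on Hamming
  distance (leaf order only; rendering is out of scope).

## Supervised stage

70/30 split, stratified by label and **grouped by strain** by default:
splitting 400 spectra at random would put replicates of one strain on both
sides of the split and leak identity information; the ungrouped behavior
is still available for comparison and the report records which was used.
Min-Max scaling uses training statistics only; a constant training feature
maps to zero everywhere.

RFECV: the elimination path repeatedly drops the feature with the smallest
absolute L2-logistic-regression coefficient; within each of 5 stratified
folds the held-out **accuracy** (the unnamed "cross-validation score" is
taken to be accuracy) is recorded at every subset size, and the final
subset is the full-data elimination-path prefix of the size with maximal
mean score, ties to the smaller size.

Classifiers: scikit-learn logistic regression (L2), RBF SVM with
Platt-calibrated probability scores, and a 200-tree random forest; scores
are the probability of *infantis*. Evaluation sweeps thresholds for the
ROC (trapezoid AUC) and, when no threshold is supplied, operates at the
Youden-optimal cutoff of the evaluated scores, ties toward the higher
cutoff. SHAP-style attribution is deliberately replaced by permutation
importance (mean AUC drop over label-preserving column shuffles): it is
model-agnostic and answers the same ranking question.

## Voting and thresholds

A strain is called by majority over its replicates' thresholded calls; an
exact tie falls back to the mean score against the same threshold and is
flagged. The operating threshold for voting is learned **on training data
via out-of-fold cross-validation** (StratifiedGroupKFold by strain):
resubstitution scores of a near-separable model pile up at 0 and 1, and a
Youden cutoff taken from them sits far too high for unseen replicates —
on the default simulated cohort this single change moved SVM/RF strain
accuracy from 90% to ≥96.7%. A fixed threshold can be forced through the
configuration.

## Numerical and degenerate-input conventions

Empty peak lists are legal everywhere (an all-zero spectrum picks zero
peaks); an empty cohort manifest, single-class labels, fewer than two
strains per class, and unknown residues in protein sequences raise errors
naming the offending input. Fisher on the all-zero table returns p = 1.
Average protein masses use the standard average residue table plus one
water (18.0153 Da); [M+H]⁺ adds 1.008 Da; annotation tolerance defaults to
±5 Da because the published experimental/theoretical pairs differ by up to
4 Da; N-terminal Met-loss candidates (−131.1926 Da) are generated because
ribosomal-protein observed masses commonly reflect Met excision.

## Problem sizes

The default cohort — 400 profile spectra on a 36,001-point grid — runs the
full pipeline in roughly ten seconds on one core; unit tests use smaller
centroid-mode cohorts (tens of strains) chosen to keep each statistical
check's sampling error well inside its asserted band.

## Known limitations and documented discrepancies

- The published narrative and the published frequency table disagree on
  two peaks (5,394 described as 100% of *longum* vs. tabulated 81.36%;
  4,448 described as 94.9% vs. tabulated 55.93%). The generator follows
  the table, whose counts carry explicit denominators; the screening code
  reports whatever it computes.
- The published external-set sensitivities for LR and RF are swapped
  between the narrative and the metrics table; the internally consistent
  LR row (0.983 + 0.900 − 1 = 0.883) is the one used as a fixed
  arithmetic check.
- Real-data headline metrics (external AUC 0.984, strain accuracies
  95–96.67%) are not reproducible without the undeposited spectra; the
  synthetic cohort yields the qualitative analogue (AUC ≥ 0.95, voting
  ≥ 95%), which is a statement about the pipeline, not about the
  instrument data.
- Two peaks at 5,381/5,394 are both attributed to ribosomal protein L34
  in the original report's text but split across two differently named rows in its
  table; annotation output carries free-text names and does not resolve
  this.
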