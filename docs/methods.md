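# Methods

## Scope and data model

The pipeline turns 4D fluorescence recordings of labelled nuclei (or tables
of nucleus centroids) into per-embryo division-synchrony statistics and
cohort-level outcome tests.  All coordinates live in *isotropic units*: one
unit equals the lateral pixel pitch dx (0.8 µm by default), and the axial
coordinate is stored pre-multiplied by the anisotropy dz/dx (2.5 for
0.8/0.8/2.0 µm voxels), so dividing a stored z by 2.5 recovers the slice
index.  Times are hours; the default frame interval is 10 min (1/6 h).

Division rounds are indexed from 1 (zygote).  The cells of round r are those
whose divisions take the embryo from 2^(r−1) to 2^r cells; the *second /
third / fourth durations* are the cell-cycle times of the round-2/3/4 cells
(2→4, 4→8, 8→16 cells).  The synchrony index is the within-embryo sample CV
(n−1 denominator) of a round's durations; embryos with third-duration
CV ≥ 0.15 (boundary inclusive) are classed asynchronous ("high").  The n−1
convention matters at n = 4 and matches the default of R, the environment
the statistical layer mirrors.

## Synthetic embryo generator

The generator defines the study conditions every property test runs under.

**Lineage.**  Each blastomere's cell-cycle duration is drawn from a
log-normal parameterized by its round's mean and CV
(σ² = ln(1+CV²), µ = ln(mean) − σ²/2), so durations are strictly positive
and the CV maps exactly.  Defaults: round means (17, 14, 12, 11, 10) h for
rounds 1–5 — first cleavage near 17 h and subsequent cycles shortening
toward 10–12 h, the usual mouse preimplantation timing — with round CVs
(0.05, 0.05, 0.10, 0.10, 0.10).  Daughters are born at the instant the
parent divides.

**Trajectories.**  Nuclei perform an isotropic Gaussian random walk
(0.5 µm/frame SD by default) radially reflected inside a sphere of radius
embryo_radius − nucleus_radius (30 − 5 µm defaults).  At a division the two
daughters appear one nucleus diameter (10 µm) apart along a uniformly random
axis through the parent position — the axis is unconstrained because the
analysis never uses division orientation.  Cells do not repel each other;
occasional close encounters are deliberate, as they are the hard case for
tracking.

**Rendering.**  Each nucleus contributes an isotropic Gaussian blob
(σ = 3 µm, unit peak) sampled on the anisotropic voxel lattice
(0.8/0.8/2.0 µm, default grid 64×128×128), multiplied by exponential depth
attenuation exp(−0.01 × depth µm) (≈ 3.6-fold loss across the 128 µm stack),
plus additive Gaussian noise (SD 0.05 of peak) clipped at zero.

**Outcome rule.**  Each synthetic embryo receives a born/abort label with
P(abort) = logistic(slope × (third CV − 0.15)), slope 100 per CV unit —
calibrated so an embryo 0.05 above the cutoff has >99% abort probability,
mirroring the strong class separation the index is meant to carry.  The CV
entering the rule is the embryo's *realized* sample CV (recomputed from its
lineage), not the generator parameter, so labels and measurable truth agree.

**What it does not emulate:** optical blur beyond a Gaussian PSF, cell
death or fragmentation, chromosome-segregation errors, compaction geometry,
uneven illumination in x/y, detector artifacts.  Passing tests therefore
demonstrate correctness of the measurement chain under a clean imaging
model, not robustness to every real-microscope pathology.

## Nucleus detection

Per volume: (1) background subtraction — a large-scale Gaussian estimate
(σ = background_radius voxels laterally, scaled by dx/dz axially) subtracted
and clipped at zero.  A literal rolling-ball/grey-opening at this radius
costs O(radius³) per voxel in 3D; the Gaussian surrogate is the standard
fast replacement and behaves identically on blob-on-flat-background data.
(2) Contrast normalization — by default a saturating percentile stretch
(1st–99.9th percentile to [0,1]).  True global histogram equalization is
available (`equalize_mode="hist"`) but is not the default: rank
equalization maps any global threshold to a fixed volume fraction, which
destroys Otsu separability when nuclei occupy ~1% of the voxels.
(3) Median denoising (radius 1).  (4) Depth-bias correction: every z-slice
with enough voxels above the volume's Otsu threshold is rescaled so its
99th-percentile foreground intensity matches the brightest slice's, with
gains capped at 20× so signal-free planes are never amplified; slices
without detectable signal are left untouched.  (5) Binarization: global
Otsu, then removal of 26-connected components below min_component_size
(64 voxels ≈ 1/6 of a 5 µm nucleus).  (6) Subdivision: iteratively, each
label's length/width are its first/second principal-axis extents in
isotropic units; labels exceeding 1.5× the median length or width are
re-split by watershed on the (lightly smoothed) Euclidean distance
transform, with marker separation med_width/2 converted to voxel index
space — the conversion divides by the anisotropy, since an axially oriented
nucleus pair is 2.5× closer in slice indices than in µm.  The loop stops
when no candidate remains, nothing changes, or after max_subdivision_iters
(10).  (7) Centroids are unweighted (binary) label centroids.

Manual add/remove/move corrections are applied from an ordered edit table
with a full audit log, mirroring curation practice for such recordings.

## Tracking and morphokinetics

Frame-to-frame correspondence is an optimal one-to-one assignment
(Hungarian algorithm) on Euclidean distance.  A count increase spawns a
division: each unmatched centroid is attributed to the active track with the
best *division gain* — the distance from the track's previous position to
the midpoint of the putative daughter pair, minus its plain continuation
distance.  A true parent sits near its daughters' midpoint and far from
either daughter, so its gain is strongly negative, whereas a bystander that
merely passes near the new centroid gains nothing; this criterion resolves
nearly all close encounters that defeat naive nearest-neighbour parenting.
The division time is the midpoint of the two frame times, so its error is
bounded by half a frame interval.  A disappearance persisting more than
2 frames marks the embryo unanalyzable (tracking failure), mirroring the
exclusion of uninterpretable recordings.

Count curves use the cleaned per-frame counts: single-frame dips (strict
local minima) are lifted first, remaining single-frame spikes flattened,
then a running maximum enforces monotonicity.  Dips are lifted before spike
detection on purpose: a genuine step followed by a one-frame dropout must
not be mistaken for a spike.  The time origin t = 0 is the first frame at
which the cleaned count reaches 2 (first mitosis); recordings without a
1→2 transition are an error.  Intra-stage durations are the residence times
at exactly 2/4/8/16/32 cells, inter-stage durations the residence inside
the bands 3, 5–7, 9–15, 17–31, both under previous-value interpolation;
stages the recording never exits are reported but flagged incomplete.

## Morphometrics

Distance-CV: sample CV of the nucleus-to-barycenter distances (0 for a
coincident degenerate frame).  Motility: summed optimally-matched
displacement per hour; unmatched points at count changes are excluded (a
flag to split a parent's displacement between daughters was considered and
rejected as it double-counts motion).  Procrustes: full Procrustes distance
after optimal translation, scaling and *proper* rotation — reflections are
excluded because embryos are chiral physical objects.  Nuclei carry no
labels, so correspondence is minimized exhaustively over permutations for
n ≤ 8 (batched SVD over all n! pairings) and by greedy optimal assignment on
the preshapes for larger n or when requested; consecutive-frame series use
the greedy mode since successive configurations are nearly identical.  The
residual is computed by applying the optimal transform explicitly rather
than via √(1−trace²), which loses half its significant digits to
cancellation near zero distance.

## Outcome statistics

Two-group test policy ("auto" mode): Kolmogorov–Smirnov normality with
estimated parameters (Lilliefors) on both groups at α = 0.05; if both pass,
a two-sided F-test for variance equality selects Student's t (equal) or
Welch's t (unequal); any non-normal group routes to the Wilcoxon rank-sum
test (normal approximation with continuity correction, the R default).  All
tests two-sided.  Groups smaller than 4 or constant are treated as
non-normal; identical constant groups return p = 1 flagged degenerate.

Proportion test: chi-square two-proportion test with Yates continuity
correction, identical to R's `prop.test` — the correction is on by default
because the reference environment's default includes it.  Spearman
correlation uses mid-rank ties and a two-sided p.

Count-curve comparison interpolates each embryo's cleaned count at the
requested times (previous value) and applies the rank-sum test per time;
no multiple-testing correction is applied by default since the per-time
p-values are reported raw, but a flag exists.

ROC cutoff analysis sweeps all observed scores plus midpoints between
adjacent unique scores; prediction is positive (abort) iff score ≥ cutoff.
The selected cutoff maximizes accuracy (Youden's J available), with ties
broken toward higher specificity and then lower cutoff — on the published
retrospective counts this selects 0.15 with sensitivity 0.26, specificity
1.00, accuracy 0.69.  A sklearn-compatible `SynchronyCutoffClassifier`
wraps fit (cutoff selection) and predict (thresholding).

## Problem sizes and numerical choices

Property tests and the acceptance script use 63 embryos over a third-CV
grid 0–0.30 (9 per level, simulated to the 8-cell stage) for recovery, a
40-embryo bimodal cohort for classification, and 20 rendered 64×128×128
volumes spanning 2–16 nuclei for detection — sizes at which every Monte
Carlo tolerance is comfortably resolved while a full run stays around half
a minute.  Fixture nuclei are placed with ≥ 12.5 µm pairwise separation
("well-separated": 2.5 nucleus radii); merged-mask subdivision is exercised
separately with pairs at 1.5 radii.  Seeds derive from a single integer per
run; per-embryo streams use numpy's seed-sequence spawning, so cohorts are
reproducible elementwise.

Known limitations: tracking assumes at most a handful of simultaneous
divisions per frame interval and no re-appearing false detections lasting
more than one frame; the detector assumes one embryo per field of view
(crop externally); the Procrustes exhaustive search is factorial and capped
at n = 8; stage durations beyond the recording end are censored, not
extrapolated.
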