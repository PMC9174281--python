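# embryosync

Division-synchrony morphokinetics for preimplantation-embryo time-lapse
imaging.

## The problem

In cleavage-stage embryos (mouse, and by extension human IVF material), the
timing regularity of blastomere divisions carries prognostic information:
embryos whose blastomeres divide asynchronously during the 4→8-cell wave
implant and develop to term less often than synchronous ones.  Quantifying
this from 4D fluorescence recordings of labelled nuclei requires a chain of
steps — 3D nucleus detection, lineage reconstruction, per-blastomere
cell-cycle timing, and cohort statistics — that this package implements as a
single tested pipeline for embryologists and quantitative developmental
biologists.

## The statistic

Let $d_1,\dots,d_n$ be the cell-cycle durations (hours) of the blastomeres of
one division round within one embryo: the *second durations* are the
lifetimes of the two cells carrying the embryo from 2 to 4 cells, the
*third durations* those of the four cells from 4 to 8, the *fourth
durations* those of the eight cells from 8 to 16.  The synchrony index is
the within-embryo coefficient of variation

$$\mathrm{CV} = \frac{s}{\bar d}, \qquad
  s = \sqrt{\tfrac{1}{n-1}\sum_i (d_i-\bar d)^2},$$

computed per round.  An embryo is classed *high* (asynchronous) when its
third-duration CV ≥ 0.15, the cutoff selected by ROC analysis (maximum
accuracy) of the third CV against transfer outcome (born/abort).  Around the
index sit:

- **detection** — background subtraction, contrast normalization, median
  denoising, per-slice depth-bias correction, Otsu thresholding,
  small-component removal, and iterative watershed subdivision of merged
  masks; centroids are reported in isotropic units (1 unit = 0.8 µm, the
  axial coordinate pre-scaled by dz/dx = 2.5 so z ÷ 2.5 is the slice index);
- **tracking** — optimal per-frame assignment with explicit division
  hypotheses, yielding the lineage tree and division times;
- **morphokinetics** — aligned cell-count curves (t = 0 at first mitosis),
  intra-/inter-stage durations, the normalized second-duration difference;
- **morphometrics** — distance-CV of the nucleus arrangement, embryo
  motility, and pairwise full Procrustes shape distance;
- **outcome statistics** — a normality/variance-driven two-group test
  policy, the Yates-corrected two-proportion test, Spearman correlation,
  per-time-point count-curve comparison, and the ROC cutoff sweep;
- **a synthetic embryo generator** — log-normal per-round division
  durations with controllable CV, confined nucleus random walks, and
  rendered anisotropic volumes (Gaussian nuclei, depth attenuation, noise) —
  so the whole chain is testable against ground truth without any data
  download.

## Worked example

```python
import embryosync as es
from embryosync.simulate import SimulationConfig, simulate_embryo

cfg = SimulationConfig(seed=7, n_rounds=4)        # one synthetic embryo to 16 cells
gt = simulate_embryo(cfg, 0)                      # lineage + trajectories + outcome
tree = es.link_tracks(gt.observations, gt.embryo_id)
profile = es.synchrony_profile(tree)
print(f"embryo {profile.embryo_id}: third CV = {profile.third_cv:.3f} "
      f"(true {gt.true_round_cvs[3]:.3f}), fourth CV = {profile.fourth_cv:.3f}, "
      f"class = {profile.synchrony_class}, outcome = {gt.outcome}")

p = es.two_proportion_test(4, 34, 19, 40)
print(f"born-rate comparison 4/34 vs 19/40: p = {p:.4f}")
```

prints

```
embryo sim000: third CV = 0.049 (true 0.048), fourth CV = 0.071, class = low, outcome = born
born-rate comparison 4/34 vs 19/40: p = 0.0022
```

The estimated third CV (0.049) is the sample CV of the four 4→8-cell
blastomere durations recovered purely from per-frame centroid tracking; it
matches the generator's ground truth to three decimals.  The embryo is
classed `low` (synchronous).  The proportion test compares born rates of 4/34
asynchronous vs 19/40 synchronous transferred embryos — the difference is
significant at p ≈ 0.002.

A command-line interface mirrors the stages:

```sh
embryosync simulate --out sim --n-embryos 10 --seed 1
embryosync track sim/coordinates.tsv --out sim/synchrony.tsv
embryosync run --config run.yaml --seed 1 --out results/
```

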