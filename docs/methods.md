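# Methods

This note documents the models and procedures implemented in `dubscreen`,
the assumptions behind them, the defaults that matter, and what the
synthetic-data generators do and do not emulate.

## Screen model and hit calling

The screen compares, per construct, the distribution of per-cell reporter
intensities at the final time point against an empty-vector control
measured in the same run. Three criteria are combined with AND semantics:

1. **Significance.** Two-sided Student's t-test (classical pooled-variance
   form; Welch is available behind the `welch` flag but the pooled form is
   the default, matching the conventional "Student's t-test"). The cutoff
   is not fixed a priori but chosen from the data as the knee of the
   p-value waterfall: all constructs' p-values are sorted, plotted as
   −log₁₀ p against rank with both axes min–max normalized to [0, 1], and
   the knee is the point of maximum perpendicular distance from the chord
   joining the first and last points. Normalizing both axes makes the knee
   scale-free — it matches the visual corner of the curve regardless of how
   extreme the smallest p-values are. Ties in distance resolve to the
   smaller p-value (the more conservative cutoff). The cutoff is applied
   strictly (`p < cutoff`). On an L-shaped waterfall the maximum-distance
   point is the first point of the flat branch, i.e. the smallest p-value
   of the non-responding constructs; the strict inequality therefore
   admits exactly the steep branch. A perfectly geometric p-value sequence
   is collinear on the log waterfall and has no knee; the function raises
   and directs the caller to a fixed cutoff. Wilcoxon rank-sum p-values
   (exact by enumeration up to n = 25 without ties, otherwise the
   tie-corrected normal approximation) and their Bonferroni-corrected
   versions (m = number of treated constructs by default) are computed and
   reported alongside, but criterion 1 uses the uncorrected t-test p.
2. **Median fold.** median(treated)/median(control) at the final time
   point must exceed 1.2 strictly; a construct at exactly 1.2 fails. The
   median is used to resist the heavy right tail of per-cell fluorescence.
3. **Last-24-h increment.** The difference between the summary mean
   intensity at the final time point and at 24 h earlier (linearly
   interpolated if no frame lies exactly there) must exceed the control's
   increment. Summary means are the default because population mean
   trajectories are what time-lapse screens conventionally plot; medians
   are available via `stat="median"`.

Hit calls are deterministic given the input tables and invariant to
construct relabeling and row order (up to floating-point summation order).

## Per-cell quantification

* **Background subtraction**: Gaussian smoothing (default σ = 2 px)
  followed by subtraction of the grayscale opening with a disk structuring
  element (default radius 100 px) and clipping at zero. Opening with a
  flat disk is the standard rolling-ball equivalent; a flat frame maps
  exactly to zero, and the output is never negative. By default the disk
  footprint uses a fast sequence decomposition (a close approximation);
  `decomposition=None` gives the exact disk for small images.
* **Segmentation**: Otsu's threshold on the subtracted reporter frame
  (parameter-free and standard for bright nuclei on a dark background; the
  threshold is overridable for other regimes), hole filling, removal of
  objects strictly smaller than `min_area` (default 50 px), 8-connected
  labeling. `split_touching` adds a distance-transform watershed seeded at
  distance maxima. Otsu assumes a bimodal histogram: on fields whose
  cell-to-cell brightness spans a wide range it can place the threshold
  inside the dim cells, so exact-count guarantees are only claimed for
  moderately homogeneous populations (see the generator section).
* **Measurements**: per-object area, centroid, and per-channel mean and
  population standard deviation (divisor n; the divisor choice is exposed
  through the raw sums, and population SD is the default because
  microscope vendor software reports per-object channel SD without a
  stated divisor). Implemented with exact per-mask sums, so values agree
  with a direct mask-indexing oracle to machine precision.
* **Bleed-through**: reporter := reporter − α·marker, floored at zero; α
  may be estimated from a marker-only control well as the
  regression-through-origin slope Σ(r·m)/Σ(m²).
* Cells are **not tracked** between frames; the analysis operates on
  per-time-point population distributions, which is all the hit-calling
  procedure needs.

## Decay kinetics

One-phase exponential decay Y(t) = (Y₀ − plateau)·e^(−kt) + plateau,
unweighted least squares with k ≥ 0. Initialization: Y₀ from the first
sample, plateau from the series minimum (or 0 when fixed), k from the
slope of a log-linear regression on plateau-subtracted values;
convergence tolerances 1e−12 on parameters and cost, capped at 500
function evaluations per parameter. `plateau_mode="fixed_zero"` is the
default for reporter chases — a reporter chased to completion decays to
background, and with plateau = 0 the identity t½ = ln 2 / k holds exactly
(ln 2 / 0.3402 h⁻¹ = 2.04 h at two decimals). `free` suits densitometry
with residual background. Minutes-labeled series are converted to hours at
construction, so unit mismatches cannot reach the comparison step; every
reported rate is per hour. A non-decreasing series yields k = 0 with a
warning and an infinite half-life rather than an error. Condition
comparisons tabulate k, t½, and the remaining fraction at a reference
time (default: the control's half-life) with ratios against a designated
control.

## Colocalization

Intensity-weighted Manders split coefficients within a nuclear mask:
M1 = ΣA over pixels with A > t_a and B > t_b, divided by ΣA over pixels
with A > t_a; M2 symmetric. The nuclear mask comes from Otsu thresholding
of a counterstain channel with hole filling and small-object removal.
Automatic thresholds use a Costes-style criterion implemented as a joint
threshold-scaling scan: the largest common quantile scale s (thresholds
s·max per channel) at which the pixels below both thresholds show
nonpositive Pearson correlation and both channels retain above-threshold
pixels. The scan form was chosen over the classical regression-line walk
because the latter terminates immediately on anticorrelated channels
(e.g. spatially disjoint signals), which are exactly the cases a screen's
negative controls produce. Fixed thresholds override the scan verbatim.
M1/M2 are invariant to uniform rescaling of either channel when its
threshold is rescaled with it. Analysis is single-plane 2-D.

## Cohort statistics

* **Ranking**: genes are ranked within a gene set by median FPKM across
  samples (rank 1 = highest; ties share the smaller rank); the median
  resists FPKM outliers, and the mean is available behind a flag.
  Percentile = 100·(1 − (rank − 1)/|set|).
* **Quartiles**: boundaries at the 25th/75th percentiles with linear
  interpolation; the bottom group takes values ≤ Q25 and the top group
  values strictly > Q75, so boundary ties fall to the lower group. For 811
  samples with distinct values this yields 203 samples in each extreme
  quartile deterministically.
* **Log-rank (Mantel–Cox)** is computed from the formula: at each distinct
  event time, expected events per group proportional to at-risk counts
  with the hypergeometric variance; χ² = (O₁ − E₁)²/Var on 1 df. The
  Kaplan–Meier estimator is likewise the direct product-limit form. Both
  are cross-checked against an independent survival-analysis library and
  a permutation null in the test suite.
* **Growth comparison**: paired two-sided t-test on per-replicate counts
  pooled over days strictly after the threshold day (default 4). A
  constant nonzero paired difference is degenerate for the t statistic and
  is reported as p = 0 with a warning.
* **ΔΔCt** averages replicate Ct values before differencing and returns
  2^(−ΔΔCt); **densitometry folds** are loading-normalized band ratios
  versus a reference lane.

## Synthetic-data generators

The generators define the study conditions the pipeline is validated
under; their defaults are fixed and not tuned per experiment.

* **Screen measurements**: 41 constructs plus one empty-vector control,
  2400 cells per construct per time point, frames every 2 h over 72 h.
  Per-cell intensities follow a log-normal law (median 100, log-scale
  σ = 0.5) — fluorescence distributions are right-skewed and strictly
  positive — plus additive Gaussian noise (SD 2, clipped at zero).
  A stabilizer's population median is multiplied by its planted fold at
  72 h, rising linearly over the last 24 h (the increment criterion only
  requires a larger rise than control, not a functional form); an explicit
  per-construct slope can override the ramp. The planted fold acts on all
  cells of a construct's table, and the transfection fraction defaults to
  1.0 at the measurement level — the interpretation is that the analyzed
  population is the marker-gated transfected population. Cell counts are
  constant over time (no division or death).
* **Screen images**: nuclei are non-overlapping disks (default radius
  10 px) on a uniform background (default 5), placed by rejection sampling
  with a capped attempt count; the simplest geometry for which area and
  intensity oracles are exact. Frames are 16-bit; out-of-range values are
  clipped and the clip count logged. The marker channel is nonzero only in
  transfected cells; optional marker→reporter bleed-through and Poisson
  shot noise can be enabled. Not emulated: cell motion, division, focus
  drift, uneven illumination, autofluorescence, or realistic nuclear
  texture — so passing segmentation tests demonstrates correctness of the
  measurement chain, not robustness to all real-microscopy artifacts.
* **Chase series**: exact model samples plus Gaussian noise.
* **Colocalization pairs**: channel B occupies a random half of the
  nuclear pixels; channel A's support is split between B-positive and
  B-negative nuclear pixels so the planted fraction of A mass inside
  B-positive pixels is exact up to integer rounding. Background defaults
  to zero so the direct mass-ratio oracle is exact.
* **Cohorts**: 171 genes × 811 samples by default. Gene base medians are
  log-normal; the focal gene's label is assigned to the row whose
  *realized* median lands exactly at the target rank, making planted ranks
  exact rather than probabilistic. Survival times are exponential with the
  hazard multiplied by the planted ratio (default 2.0) for samples in the
  focal gene's top expression quartile; independent exponential censoring
  is calibrated to the requested baseline censoring fraction (default
  0.3). The default baseline hazard is 0.05 events per month, giving
  median survivals around a year on the arbitrary time scale. Proportional
  hazards hold exactly by construction, which real cohorts do not
  guarantee.

## Problem sizes used in validation

The bundled test suite and acceptance script run the screen at full
default scale (42 × 37 time points × 2400 cells ≈ 3.7 M rows, a few
seconds per screen); null-rate checks use 20 seeded replicates, decay
recovery 100 noisy replicates (5% noise, 25 samples over 12 h),
segmentation 20 seeded images of 12 disks at 256×256 px with subtraction
radius 50, and cohort null calibration 200 seeded cohorts of 200 samples.

## Known limitations

* The knee rule is a geometric stand-in for a visually chosen cutoff; on
  waterfalls without a clear corner it selects *some* maximum-distance
  point, and the fixed-cutoff mode should be preferred when the shape is
  not L-like.
* Otsu segmentation assumes bright objects on a dark background and a
  roughly bimodal histogram; the threshold is swappable.
* The exact vendor implementations being emulated (background-subtraction
  kernel, segmentation algorithm, colocalization thresholds) are not
  public; the choices here are standard equivalents, exposed as
  parameters.
* The log-rank implementation covers two groups only; no Cox regression
  or multivariate adjustment is provided.
* Bleed-through correction is a linear single-coefficient model.
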