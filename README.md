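# dubscreen

A tested, reusable pipeline for imaging-based overexpression screens of
deubiquitinating proteases (DUBs) acting on a fluorescent reporter — the
kind of screen in which a ZsGreen1–c-MYC fusion is tracked by live-cell
microscopy while individual deubiquitinases are overexpressed, and
constructs that stabilize the reporter are called as hits. The package
covers the full downstream analysis: per-cell fluorescence quantification,
statistical hit calling, protein decay kinetics, nuclear colocalization,
and cohort-level expression/survival statistics — all exercisable on
synthetic data with planted ground truth.

## Who this is for

Groups running high-content screens where the readout is a per-cell
fluorescence distribution over time and the question is "which perturbation
shifted it?", as well as anyone needing the accompanying bench statistics
(cycloheximide-chase half-lives, Manders colocalization, Kaplan–Meier /
log-rank stratification, ΔΔCt, densitometry folds) in one tested place.

## The core procedure

**Hit calling** (module `screenstats`). Each construct's per-cell reporter
intensities at the final (72 h) time point are compared with the
empty-vector control. A construct is a hit when it passes all three
criteria:

1. *Significance with a knee-point cutoff.* Student's t-test p-values of
   all constructs are sorted on a logarithmic waterfall curve
   (rank vs −log₁₀ p, both axes min–max normalized); the cutoff is the
   p-value at the point of maximum perpendicular distance from the chord
   joining the curve's endpoints, applied as p < cutoff. Wilcoxon rank-sum
   p-values with Bonferroni correction are reported alongside.
2. *Median fold change.* median(treated) / median(control) at 72 h must be
   strictly greater than 1.2.
3. *Last-24-h increment.* The rise in mean intensity over the final 24 h
   must exceed the control's rise.

**Quantification** (module `imquant`). Frames are Gaussian-smoothed,
background-subtracted by grayscale opening with a disk of radius 100 px
(the rolling-ball equivalent), segmented by Otsu threshold into
8-connected objects, and measured per object (area, per-channel mean and
population SD), with optional marker→reporter bleed-through correction
estimated from marker-only control wells.

**Decay kinetics** (module `kinetics`). One-phase exponential decay
Y(t) = (Y₀ − plateau)·e^(−kt) + plateau is fit by least squares (plateau
fixed at zero by default); half-life t½ = ln 2 / k.

**Colocalization** (module `coloc`). Intensity-weighted Manders split
coefficients M1/M2 within an Otsu-derived nuclear mask, with fixed or
Costes-style automatic thresholds.

**Cohort statistics** (module `cohort`). Median-FPKM expression ranking
within a gene set, quartile stratification, from-formula Kaplan–Meier and
two-group Mantel–Cox (log-rank) tests, paired growth-curve comparison,
ΔΔCt, and densitometry folds.

**Synthetic data** (module `simdata`). Every input above can be generated
with planted ground truth: screens with chosen per-construct fold effects
and trajectories, disk-nuclei image series, decay series, channel pairs
with planted overlap fractions, and expression/survival cohorts with
planted hazard ratios. Fixing the seed makes every generator
bit-reproducible.

## Worked example

Simulate the default screen layout — 41 constructs plus an empty-vector
control (`EV`), 2400 cells per construct per time point, frames every 2 h
for 72 h — with 11 planted 1.5-fold stabilizers, then call hits:

```python
import numpy as np
from dubscreen import simdata, screenstats

effects = np.ones(41)
effects[:11] = 1.5          # constructs DUB01..DUB11 stabilize the reporter
cfg = simdata.ScreenSimConfig(planted_effects=effects, seed=1)
measurements, truth = simdata.simulate_screen_measurements(cfg)
result = screenstats.screen_measurements(measurements, control_id="EV")
print(f"chosen cutoff (knee): {result.cutoff:.3g}")
print(f"hits ({len(result.hits)}): {result.hits}")
```

prints

```
chosen cutoff (knee): 0.013
hits (11): ['DUB01', 'DUB02', 'DUB03', 'DUB04', 'DUB05', 'DUB06', 'DUB07', 'DUB08', 'DUB09', 'DUB10', 'DUB11']
```

The knee of the p-value waterfall lands just below the smallest null
p-value (0.013 here), so the 11 constructs with astronomically small
p-values sit below the cutoff while every null construct sits above it.
Per-construct detail shows why each criterion fires — a planted stabilizer
versus a null:

```
DUB01: p_t=7.74e-138, fold=1.502, incr=56.4 vs control -0.5
DUB20: p_t=0.508,     fold=1.010, incr=-0.3
```

A decay-kinetics example — fit a noiseless chase series and report the
half-life:

```python
from dubscreen import kinetics
df = simdata.simulate_chase_series(simdata.ChaseSimConfig(k=0.3402, noise_sd=0))
fit = kinetics.fit_one_phase_decay(
    kinetics.DecaySeries("CHX", df.time_h, df.intensity))
print(f"k = {fit.k:.4f} /h, half-life = {fit.half_life:.2f} h")
# k = 0.3402 /h, half-life = 2.04 h
```

The same workflows are available from the shell via the `dubscreen` CLI
(`simulate-screen`, `simulate-images`, `simulate-chase`, `simulate-coloc`,
`simulate-cohort`, `quantify`, `screen`, `chase`, `coloc`, `cohort`, and an
end-to-end `report`); every subcommand takes `--config` (YAML), `--seed`,
and `--out`, and records the seed and a config hash in its output
metadata.

## Documentation

`docs/methods.md` describes the models, the synthetic-data generators and
what they do and do not emulate, numerical choices, and known limitations.
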