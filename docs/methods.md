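# Methods

## Signal model and fitting

Each voxel's magnitude signal is modeled as a two-pool transverse decay,
`S(TE) = S0·[f·exp(−TE/T2s) + (1−f)·exp(−TE/T2l)]`, with `S0 ≥ 0`,
`f ∈ [0, 1]`, and `T2s ≤ T2l` (ms). `S0` is the model's value at TE = 0 and is
the quantification target. The default echo schedule is the sorted merge of
three interleaved 8-echo trains — 24 unique echo times from 0.20 to 70.78 ms —
which samples both the fast early decay and the slow tail.

The voxelwise fit is bounded nonlinear least squares
(`scipy.optimize.least_squares`, trust-region reflective, analytic Jacobian)
with defaults `f ∈ [0, 1]`, `T2s ∈ [0.1, 15] ms`, `T2l ∈ [15, 80] ms`,
`S0 ≥ 0`. The 15 ms pool split and the 80 ms cap are implementation choices
sized to the sampling window, not physiological claims; all bounds are
configurable. Initialization: a log-linear mono-exponential fit on the last 8
echoes seeds `T2l`; `T2s` starts at 4 ms and `f` at 0.5, with `S0` chosen so
the model matches the first echo. Because the two-pool problem is ill
conditioned, up to two further starts (`f` = 0.15, 0.85) are tried when the
first solve leaves a relative residual above 1e-8, and the best solution by
cost is kept. Results are canonicalized to `T2s ≤ T2l` (pool swap with
`f → 1 − f`). An all-zero series returns the exact degenerate solution
`S0 = 0`. Tolerances are set to 1e-13 (xtol/ftol/gtol); on noiseless data
within the bounds the fitted `S0` agrees with ground truth to ~1e-9 relative.
No Rician noise-floor correction is applied by default. Non-converged voxels
are flagged in a convergence mask and excluded from tube means and ROI means
downstream.

`fit_volume` caches results by the raw byte pattern of each voxel's echo
series, so per-voxel outputs are identical to independent `fit_voxel` calls
while piecewise-constant (noiseless) phantoms collapse to one fit per
compartment — this is why a full 48³ noiseless subject fits in about a
second.

## Calibration and ROI extraction

The six reference tubes (default concentrations 25, 40, 55, 70, 85,
100 mmol/L — six equally spaced values over the stated 25–100 range) provide
per-tube mean fitted `S0` over converged voxels. Calibration is an ordinary
least-squares line `s0 = slope·conc + intercept` with a free intercept; a
forced-zero-intercept (pure ratio) mode is available. The line is inverted
voxelwise, negatives are clipped to zero and counted. ROI statistics are the
arithmetic mean TSC over converged ROI voxels and the normalized volume
`100 · roi_voxels / icv_voxels` (% of intracranial volume, computed over all
anatomical ROI voxels regardless of convergence).

## Phantom and acquisition simulator

The simulator emulates the *structure* of a head acquisition, not its
anatomy: on a 48³ grid at 3 mm isotropic (configurable, minimum 24³), a
spherical ICV contains a central CSF sphere, five deep-gray ellipsoids sized
in rough proportion to their normalized volumes, a cortical gray-matter
shell, and white matter filling the remainder; six spherical tubes sit in a
ring below the brain, outside the ICV but inside the field of view.
Explicitly shaped compartments must be pairwise disjoint (overlap is an
error naming both labels); the white-matter compartment is a declared
"fill" region that takes the leftover voxels of the inner ball, which is how
crisp nested anatomy is represented without overlap semantics.

Noiseless signal is exactly `S0 = signal_per_mmol × TSC` times the unit
decay curve of the voxel's compartment — a single global proportionality
constant shared by tissue and tubes (the simulator assumes exact signal–
concentration proportionality; relaxation-weighting differences between
tissue types are representable by giving compartments different relaxation
parameters). Default relaxation parameters everywhere are `T2s = 4 ms`,
`T2l = 35 ms`, `f = 0.6` — a plausible bi-exponential regime for the sampling
window; the tubes share the same form because their true relaxation
properties are a simulation choice, flagged in config. Ground-truth TSC
defaults: the six ROIs carry the iPD group means; white matter 35 mmol/L and
CSF 140 mmol/L (typical literature-scale values; they are generator inputs
only and do not enter any graded comparison). An optional isotropic Gaussian
blur (FWHM in mm) stands in for the point-spread function of radial
sampling — default 0 so round-trip tests are exact. Noise is Rician: the
magnitude of the blurred signal plus two-channel Gaussian noise of standard
deviation `noise_sd` (signal units; with the default
`signal_per_mmol = 1`, peak tissue signal is ~140, so `noise_sd = 7`
corresponds to 5% of peak).

What passing round-trip tests show: the estimation chain (fit → calibration
→ ROI means) is unbiased and numerically exact under the generator's
assumptions. What they do not show: robustness to partial volume,
B0/B1 inhomogeneity, coil sensitivity, registration error, or anatomically
realistic geometry — none of which the simulator models.

## Cohort generator and statistics

Per-subject ROI values are drawn independently per ROI from the group's
Gaussian truncated at zero (rejection sampling; only marginal means and SDs
are specified, so independence across ROIs is the least-informative choice).
Default design: 10 iPD vs 12 controls with the published group means/SDs for
TSC and normalized volumes. Seeding: one master seed; child seeds are
derived per subject and per stage via `numpy.random.SeedSequence` spawning.
Users running many replicates should likewise spawn replicate seeds from one
root rather than using consecutive integers, which can correlate across
replicates.

The group battery: per ROI × measure, group mean ± SD and a two-sided
Wilcoxon rank-sum p-value. "Wilcoxon" here is the two-sample rank-sum
(Mann–Whitney) test — the groups are unpaired. For pooled n ≤ 12 the p-value
is exact, computed by enumerating all C(n, n_a) group assignments of the
midranked data (a permutation test that is valid with ties and reduces to
the classical exact rank-sum distribution without them); larger samples use
the normal approximation with tie and continuity corrections. An entirely
constant pooled sample returns p = 1. Bonferroni control uses m = 6 (the six
ROI TSC comparisons; volume comparisons are reported uncorrected as a
secondary family), the exact threshold 0.05/6 with strict inequality, and a
3-decimal display value (0.008). Fisher's exact test (two-sided,
probability-based convention) covers sparse 2×2 demographics and Pearson
chi-square the rest, with the policy of preferring Fisher when any expected
count is below 5. Spearman correlations use midranks, an exact permutation
p for n ≤ 8 and the t approximation otherwise; a constant input yields
(nan, nan) and is excluded from reports rather than raising.

## Pipeline

`run_pipeline` executes simulate → fit → calibrate → summarize → compare for
every subject, writing each stage's outputs (NIfTI-1 volumes, CSV tables, a
text report, `manifest.json` with config hash and per-stage seeds) so stages
are individually re-runnable; the CLI subcommands are thin wrappers over the
same functions. The stats stage requires at least two subjects per group and
is skipped (and recorded as skipped) otherwise. Default problem sizes — 48³
grid for quantitative runs, 24³ in the test suite, 500 replicates for null
calibration checks — were chosen to keep a full desk run in seconds to a few
minutes.

## Known limitations

- Geometry is parametric, aligned, and crisp; no partial volume, motion, or
  registration effects.
- The simulator's S0∝TSC assumption makes calibration exact by construction;
  real tube calibrations inherit relaxation-correction error the model does
  not expose.
- The asymptotic rank-sum path is slightly conservative at n ≈ 22; the exact
  path is used automatically only up to pooled n = 12.
- Short/long pool-fraction maps are produced but not statistically analyzed.
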