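# natsc — quantitative sodium (²³Na) MRI analysis

`natsc` is a tested, reusable implementation of the quantitative brain sodium
MRI workflow used in small case–control neuroimaging studies (the motivating
setting is early idiopathic Parkinson's disease vs healthy controls at 7 T):
simulate multi-echo ²³Na volumes with known ground truth, fit a bi-exponential
T2\* decay per voxel, calibrate the TE = 0 signal to absolute Total Sodium
Concentration (TSC) with reference tubes, extract per-ROI statistics, and run
the nonparametric two-group comparison battery.

Because sodium relaxes with two transverse pools, the magnitude signal at echo
time TE follows

    S(TE) = S0 · [ f · exp(−TE/T2*short) + (1 − f) · exp(−TE/T2*long) ]

and the quantity of interest is S0, the ordinate at TE = 0: a relaxation-free
signal proportional to tissue sodium content. Six agar tubes of known
concentration (25–100 mmol/L) imaged in the same field of view pin the scale —
an ordinary least-squares line through (concentration, mean fitted S0) is
inverted voxelwise to give TSC in mmol/L of wet tissue. ROI means over six
regions (substantia nigra, putamen, caudate, pallidum, thalamus, cortical gray
matter) and ICV-normalized volumes then enter two-sided Wilcoxon rank-sum
group comparisons with Bonferroni control over the six TSC tests
(0.05/6, displayed as p < 0.008).

No real acquisitions are bundled: the `phantom` module generates labeled
digital phantoms and noisy (Rician) multi-echo stacks whose default schedule
is the study's 24 echo times from 0.20 to 70.78 ms, and whose default cohort
is 10 iPD patients vs 12 controls with the published group means and SDs.

## Worked example

`examples/phantom_roundtrip.py` simulates one noiseless subject whose ROIs
carry the iPD group-mean concentrations, fits and calibrates it, and prints:

```
fitted 17544 voxels, convergence 100.0%
calibration: slope 1.0000, intercept 0.0000, R^2 1.000000
         ROI  recovered    truth  nvol %ICV
          SN     43.730    43.73      0.093
     putamen     48.650    48.65      0.649
     caudate     54.220    54.22      0.464
    pallidum     45.800    45.80      0.232
    thalamus     50.600    50.60      1.020
 cortical_gm     56.340    56.34     45.943
```

Recovered means equal the ground truth because the pipeline is exact in the
noiseless limit: the fit recovers S0 to ~1e-9 relative and the tube
calibration is the identity when signal is exactly proportional to
concentration. `examples/fit_single_voxel.py` shows the voxel-level fit with
and without noise, and `examples/group_comparison.py` runs the statistical
battery on a sampled cohort.

There is also a thin CLI over the same library code:

```sh
natsc print-config > config.yaml
natsc run-all --config config.yaml --seed 7 --out run/
natsc stats --cohort run/cohort.csv --out run/
```

`run-all` writes per-subject NIfTI volumes (`<subject>_echoes.nii.gz`,
`<subject>_s0.nii.gz`, `<subject>_tsc.nii.gz`, `labels_<subject>.nii.gz`),
`cohort.csv`, `comparison.csv`, a text report, and a `manifest.json`
recording the config hash and per-stage seeds.

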