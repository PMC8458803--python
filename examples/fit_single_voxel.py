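"""Fit the bi-exponential decay model to one simulated voxel.

Builds the default 24-echo schedule (0.20-70.78 ms), evaluates the two-pool
decay for a voxel with known parameters, adds Rician noise, and fits.  The
printed S0 is the curve's ordinate at TE = 0 — the relaxation-free signal
that the calibration step later converts to an absolute concentration.
"""

import numpy as np

from natsc import biexp_signal, default_echo_schedule, fit_voxel

schedule = default_echo_schedule()
te = schedule.as_array()
print(f"{len(schedule)} echo times, {te[0]:.2f} to {te[-1]:.2f} ms")

truth = dict(s0=100.0, short_fraction=0.6, t2_short=4.0, t2_long=35.0)
clean = biexp_signal(te, **truth)

rng = np.random.default_rng(0)
noisy = np.sqrt((clean + rng.normal(0, 1.0, te.size)) ** 2 + rng.normal(0, 1.0, te.size) ** 2)

for label, signal in (("noiseless", clean), ("noisy (sd=1)", noisy)):
    r = fit_voxel(signal, schedule)
    print(
        f"{label:>12s}: S0 = {r.s0:7.3f} (truth {truth['s0']}), "
        f"f = {r.short_fraction:.3f}, T2s = {r.t2_short:.2f} ms, "
        f"T2l = {r.t2_long:.2f} ms, converged = {r.converged}"
    )
# The noiseless fit recovers S0 to ~1e-9 relative; with noise the estimate
# scatters around the truth by roughly the per-echo noise level.
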