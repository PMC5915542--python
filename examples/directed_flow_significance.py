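"""Directed information flow with surrogate significance.

Runs the full connectivity chain on the two-source simulation: Kalman MVAAR
fit, time-resolved transfer function, normalized ADTF, 4-10 Hz integration,
and a 200-surrogate phase-randomization null.  Prints how often each
direction clears the null's 95th percentile.
"""
import numpy as np

from adtfnet import (band_grid, fit_mvaar_kalman, integrated_adtf,
                     normalized_adtf, simulate_sources, surrogate_null,
                     transfer_function)

FS = 250.0
S = simulate_sources(2000, seed=7)
model = fit_mvaar_kalman(S, p=2, uc=1e-3, sfreq=FS)
H = transfer_function(model, band_grid(4, 10), FS)
theta = integrated_adtf(normalized_adtf(H), 4, 10).theta2

null = surrogate_null(S, p=2, uc=1e-3, n_surrogates=200, seed=7, fs=FS)
q95 = np.quantile(null, 0.95, axis=0)
valid = slice(model.valid_from, None)

fwd = (theta[valid, 1, 0] > q95[valid, 1, 0]).mean()
rev = (theta[valid, 0, 1] > q95[valid, 0, 1]).mean()
print(f"S1 -> S2 flow exceeds surrogate null at {100 * fwd:.1f}% of timepoints")
print(f"S2 -> S1 flow exceeds surrogate null at {100 * rev:.1f}% of timepoints")
print(f"mean integrated ADTF: S1->S2 {theta[valid, 1, 0].mean():.3f}, "
      f"S2->S1 {theta[valid, 0, 1].mean():.3f}")
# The true causal direction should clear the null almost everywhere while the
# reverse direction stays near the nominal 5% false-alarm level.
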