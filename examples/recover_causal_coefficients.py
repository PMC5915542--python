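"""Track the coefficients of the two-source causal system with the Kalman
MVAAR fit.

Simulates S1(t) = 0.9 S1(t-1) - 0.9 S1(t-2) + e1 driving
S2(t) = 0.5 S1(t-2) + e2, fits the time-varying order-2 model, and compares
the time-averaged tracked coefficients with the generating values.
"""

from adtfnet import fit_mvaar_kalman, simulate_sources

S = simulate_sources(n_samples=2000, noise_sd=1.0, seed=1)
model = fit_mvaar_kalman(S, p=2, uc=1e-3, sfreq=250.0)
avg = model.coeffs[1000:].mean(axis=0)  # steady-state average

print("recovered vs true coefficients (time-averaged, last 1000 samples):")
print(f"  S1 lag-1      {avg[0, 0, 0]:+.3f}   (true +0.9)")
print(f"  S1 lag-2      {avg[1, 0, 0]:+.3f}   (true -0.9)")
print(f"  S1->S2 lag-2  {avg[1, 1, 0]:+.3f}   (true +0.5)")
print(f"  S2->S1 lag-1  {avg[0, 0, 1]:+.3f}   (true  0.0)")
# Values within ~0.05 of truth show the random-walk Kalman state has locked
# onto the stationary generating model; the S2->S1 entry stays near zero
# because the system is triangular (no feedback path).
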