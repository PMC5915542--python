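# Methods

## Signal model and Kalman tracking

The pipeline models an n-channel epoch as a time-varying multivariate
autoregression of order p,

    X(t) = Σ_{k=1..p} w(k,t) X(t−k) + ε(t),

with ε multivariate white noise. The coefficient stack is tracked by a Kalman
filter whose state is the vectorized stack (dimension n²p): random-walk state
transition, process noise `uc · trace(P)/dim` on the diagonal (P the state
covariance), and measurement noise estimated adaptively as an exponentially
smoothed outer product of the innovations, `R_t = (1−uc) R_{t−1} + uc e_t e_tᵀ`.
This is the classic adaptive-AR construction; the update coefficient `uc`
(default 1e-3) trades tracking speed for variance — on a coefficient step
change the post-change error falls below 0.15 within a window that shrinks as
`uc` grows (see the step-change test). Initialization is zero coefficients and
identity state covariance; the first p samples are burn-in and are excluded
from all downstream connectivity. Multi-trial input assimilates every trial
sequentially within each time step, updating one shared coefficient
trajectory; the pipeline default, though, fits the trial-averaged ERP
waveform, since the quantity of interest is the evoked (phase-locked)
dynamics. Model order is chosen by the Schwarz Bayesian Criterion,
`ln det(Σ_res) + p n² ln(N)/N`, over stationary least-squares fits evaluated
on a common sample span.

Before fitting, channels are z-scored (mean/SD pooled over the concatenated
epoch samples); constant channels map to zeros. Note that z-scoring rescales
cross-channel coefficients by σ_j/σ_i — the connectivity measures below are
normalized and unaffected, but raw coefficient recovery (as in the acceptance
computation) is done on unnormalized data.

## Transfer function and ADTF

With `A(f,t) = I − Σ_k w_k(t) e^{−j2πfk/fs}` (the sign convention that makes
`H = A⁻¹` the causal transfer matrix from innovations to signals), the
normalized ADTF is `ι²_ij = |H_ij|²/Σ_k|H_ik|²` — row-normalized, so values
lie in [0,1] and each (receiver, f, t) row sums to 1 — and the integrated
ADTF is its mean over the analysis band on a 1 Hz grid, 4–10 Hz by default
(the band where N170 energy concentrates). Edge orientation is fixed
package-wide: matrix entry (i, j) is flow j → i.

## Surrogate null and thresholding

Surrogates are per-channel phase randomizations: Fourier phases replaced by
uniform draws (DC/Nyquist kept real), amplitudes preserved exactly. Each
surrogate goes through the *entire* fit → H → ι² → ϑ² chain (200 surrogates
by default), giving an empirical null per edge and timepoint. Two thresholding
modes:

* single-recording: rank p-value `(1 + #{null ≥ obs})/(1 + S)`, Bonferroni
  over the n(n−1) directed edges within each timepoint (not across
  timepoints, since networks are reported per timepoint at several alphas);
* across subjects: each subject's null is summarized by its median, and a
  one-sided Wilcoxon signed-rank test (observed > null summary, zero
  differences dropped) runs over subjects per edge/timepoint, again
  Bonferroni-corrected per timepoint. With S surrogates the smallest
  attainable rank p is 1/(S+1), and with n subjects the smallest exact
  signed-rank tail is 2⁻ⁿ — both floors bound which corrections can ever
  reach significance and are worth checking before choosing alpha.

Type-I calibration on uncoupled channels and power on the two-source system
are exercised in the acceptance tests.

## Head model, lead fields, and REST

The forward model is three concentric spheres (brain/skull/scalp) with
conductivities 1, 1/80, 1 Ω⁻¹m⁻¹ and radii 0.90/0.95/1.00 (scalp normalized
to 1; the brain radius is set so the simulation's temporal-parietal dipole
coordinates, at radius ≈ 0.88, sit strictly inside it). Radial dipoles only;
the scalp potential is the exact per-harmonic solution of the boundary-value
problem (5×5 linear system per order, 60 terms — converged to ~3·10⁻⁴
relative for the deepest geometry used, and verified against the closed-form
homogeneous-sphere potential).

REST uses an equivalent-source layer of 3000 radial dipoles on a sphere at
0.87 × the scalp radius — the cortical-surface layer of the published REST
construction. (A layer deep inside the brain compartment degrades the
inverse enough that REST reconstructs infinity-referenced potentials worse
than AR does, defeating the method; the cortical-surface layer is also what
the REST literature prescribes.) The AR→infinity operator is
`G_inf · pinv(G_avg)` with a truncated-SVD pseudoinverse (relative cutoff
1e-4). Re-referencing operates on the full recording montage (a standard
64-channel 10-10 cap) before any channel subsetting: with only 19 electrodes
the layer inverse is too coarse for REST to beat AR. Electrode positions come
from the bundled MNE template montage, centered on the best-fit sphere and
projected to unit radius.

## Graph measures

Out-degree of node j at time t is the column sum of significance-masked
weights (total outgoing flow). Directed weighted local efficiency follows the
Rubinov–Sporns form: for node i with neighborhood N_i,

    E_i = ½ Σ_{j≠m∈N_i} (W_ij+W_ji)(W_im+W_mi)(1/d_jm + 1/d_mj)
          / [(k_out+k_in)(k_out+k_in−1) − 2 Σ_j W_ij W_ji],

with d the directed shortest-path length *inside* N_i on reciprocal-weight
distances; unreachable pairs contribute 0, nodes with fewer than two
neighbors (or non-positive denominator) score 0, and every node of a binary
complete digraph scores exactly 1. Hubs are ranked by time-averaged
out-degree (ties alphabetical). Edge onset is the first timepoint the edge is
significant; the reference-comparison pipeline additionally uses a sustained
variant (first run of 5 consecutive significant samples, 20 ms at 250 Hz) to
suppress isolated crossings while the Kalman state is still adapting.

## ERP statistics

Epochs span −200–1000 ms at 250 Hz; trials with any scalp sample beyond
±60 μV (or any EOG sample beyond the same bound — an amplitude criterion
standing in for ocular screening) are rejected, and the −200–0 ms mean is
subtracted per channel. Peaks are measured on the per-subject average
waveform: minimum voltage in the 160–180 ms window, earliest sample on ties,
at P8 by default. Comparisons use the classical paired t with Cohen's
d = mean(Δ)/sd(Δ) (zero-variance differences are an error), and a 2×2
fully-repeated-measures ANOVA (Reference × Stimulus) with partial eta squared
η²_p = SS_effect/(SS_effect+SS_error); two-level factors need no sphericity
correction. The ANOVA is computed by pingouin with η²_p recomputed through
the identity F·df₁/(F·df₁+df₂) (verified against an explicit sums-of-squares
decomposition in the tests), which also resolves the noise-free edge cases.

## Synthetic data

Two generators stand in for unavailable recordings; they define what the
tests can and cannot show.

**Two-source causal system.** `S1(t) = 0.9 S1(t−1) − 0.9 S1(t−2) + ε1`,
`S2(t) = 0.5 S1(t−2) + ε2`, independent unit-variance Gaussian innovations,
100-sample burn-in, 2000 samples at a nominal 250 Hz. The system is
triangular: the only causal path is S1 → S2 at lag 2, so any consistent
estimator must drive the reverse ADTF toward zero. The dipoles sit at
normalized coordinates (−0.57, −0.67, −0.03) and (0.61, −0.63, −0.04) (left
and right temporal-parietal; the nearest 10-20 electrodes are P7 and P8) with
radial orientation. Sensor noise in the reference comparison defaults to 5%
of the scalp-signal RMS.

**Reference-comparison design.** The comparison runs the identical chain on
the sources, the REST-referenced P7/P8 pair, and the AR-referenced pair. The
steady-state true-edge ADTF is strictly ordered source > REST > AR (AR's
channel mixing dilutes the directed component most), but the ordering of
*onset* times is small relative to the sampling noise of independently drawn
surrogate nulls, so the three arms share one set of surrogate phase draws —
common random numbers, the standard variance-reduction device for paired
comparisons. Reported onsets therefore differ only through the data, not
through the null's sampling error.

**N170-like cohort.** Per subject (30 by default, 80 trials/condition,
matching the emulated study design): gamma-shaped negative deflections
(40 ms rise, shape 6) on the two temporal-parietal dipoles, the right
peaking at 170 ms ± 4 ms between-subject jitter and the left lagging by
4 ms (one sample at 250 Hz); face amplitude −6 μV at the P8-analog channel,
letters −3.5 μV; pink (1/f) background noise of 9 μV per trial. The built-in
reference effect makes the AR arm peak 4 ms later and 15% larger than the
REST arm *on the same trials* — the two arms share each trial's noise
realization, as derived views of one recording must. The deflection
sharpness matters: a much broader component leaves the trough so flat that
windowed argmin peak-picking cannot resolve a one-sample offset, and the
generator would fail its own parameter-recovery contract.

What the generators do **not** emulate: realistic cortical geometry and
tangential source orientations, inter-trial latency jitter and alpha-band
oscillatory background, ocular/muscle artifacts beyond amplitude outliers,
volume-conduction differences between subjects, and any nonstationarity of
the sources themselves. Passing tests therefore demonstrate correctness of
the estimators under the stated model, not performance on real recordings.

## Numerical choices and limitations

* Kalman state covariance is symmetrized each step; divergence (non-finite
  state) raises with the offending sample index, and surrogate fits that
  diverge are dropped (run fails above 10%).
* `transfer_function` refuses frequencies outside (0, Nyquist) and names the
  first singular (f, t) point on failure.
* Empirical p-values use the (1+k)/(1+S) rank convention, so they are never
  zero; with 200 surrogates and Bonferroni over many edges the floor can
  exceed the corrected alpha — by design the calibration acceptance run uses
  a 3-channel system where the floor is attainable.
* The EDF writer emits plain 16-bit EDF (one data record per epoch, epoch
  timing in the reserved header field); round-trip error is bounded by the
  physical-range quantization step.
* Acceptance-scale problem sizes — 2000-sample simulations, 200 surrogates,
  20-seed batteries, 30-subject cohorts — were chosen as the package's own
  test conditions; the batched Kalman kernel vectorizes all surrogates of a
  run through one recursion, which keeps the full battery at desk scale.
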