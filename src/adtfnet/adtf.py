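"""Adaptive directed transfer function, surrogate nulls and network thresholding.

The normalized ADTF between channel j (sender) and i (receiver) is

    iota2_ij(f,t) = |H_ij(f,t)|^2 / sum_k |H_ik(f,t)|^2,

a row-normalized squared transfer magnitude in [0, 1]; the integrated ADTF
theta2_ij(t) averages iota2 over the analysis band (4-10 Hz by default, where
the N170's power concentrates).  Edge orientation is fixed package-wide:
matrix entry (i, j) means flow from j to i.

Significance is assessed against phase-randomized surrogates, which keep each
channel's amplitude spectrum but destroy cross-channel (and any nonlinear)
temporal structure; the full fit -> H -> iota2 -> theta2 chain is re-run on
every surrogate to build the empirical null.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import EpochedEEG
from .mvar import TransferFunction, band_grid, kalman_coefficients, \
    spectral_matrix


@dataclass
class ADTFTensor:
    """Normalized (iota2) and band-integrated (theta2) ADTF values."""

    iota2: np.ndarray            # (F, N, n, n), rows (axis -2) sum to 1
    freqs: np.ndarray
    ch_names: tuple[str, ...]
    valid_from: int = 0
    theta2: np.ndarray | None = None  # (N, n, n)
    band: tuple[float, float] | None = None


def _normalize_rows(H2: np.ndarray) -> np.ndarray:
    rowsum = H2.sum(axis=-1, keepdims=True)
    if np.any(rowsum == 0):
        raise ValueError("all-zero transfer row: ADTF normalization undefined")
    return H2 / rowsum


def normalized_adtf(H: TransferFunction) -> ADTFTensor:
    if not np.all(np.isfinite(H.H)):
        raise ValueError("non-finite transfer function")
    iota2 = _normalize_rows(np.abs(H.H) ** 2)
    return ADTFTensor(iota2=iota2, freqs=H.freqs, ch_names=H.ch_names,
                      valid_from=H.valid_from)


def integrated_adtf(adtf: ADTFTensor, f1: float, f2: float) -> ADTFTensor:
    """Band mean of iota2 over grid frequencies in [f1, f2]."""
    sel = (adtf.freqs >= f1) & (adtf.freqs <= f2)
    if not sel.any():
        raise ValueError(f"no grid frequencies inside [{f1}, {f2}] Hz")
    theta2 = adtf.iota2[sel].mean(axis=0)
    return ADTFTensor(iota2=adtf.iota2, freqs=adtf.freqs,
                      ch_names=adtf.ch_names, valid_from=adtf.valid_from,
                      theta2=theta2, band=(f1, f2))


def phase_randomize(x: np.ndarray, seed=None) -> np.ndarray:
    """Phase-randomized surrogate of a (channels, samples) epoch.

    Each channel independently: Fourier transform, substitute uniformly
    random phases (DC and Nyquist bins stay real), inverse transform.  The
    amplitude spectrum is preserved exactly.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(x, dtype=float)
    squeeze = x.ndim == 1
    x = np.atleast_2d(x)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    amp = np.abs(spec)
    phases = rng.uniform(0, 2 * np.pi, size=spec.shape)
    phases[..., 0] = 0.0
    if n % 2 == 0:
        phases[..., -1] = 0.0
    # keep the sign of real-constrained bins so amplitudes survive exactly
    signs = np.ones_like(amp)
    signs[..., 0] = np.sign(spec[..., 0].real) + (spec[..., 0].real == 0)
    if n % 2 == 0:
        signs[..., -1] = np.sign(spec[..., -1].real) + (spec[..., -1].real == 0)
    surr = np.fft.irfft(signs * amp * np.exp(1j * phases), n=n, axis=-1)
    return surr[0] if squeeze else surr


def theta2_from_coeffs(coeffs: np.ndarray, freqs, fs: float) -> np.ndarray:
    """fit-free part of the chain: coefficients -> H -> iota2 -> band mean.

    ``coeffs``: (..., N, p, n, n); returns theta2 (..., N, n, n).
    """
    A = spectral_matrix(coeffs, freqs, fs)
    H2 = np.abs(np.linalg.inv(A)) ** 2
    iota2 = _normalize_rows(H2)
    return iota2.mean(axis=-4)  # average over the frequency axis


def surrogate_null(eeg, p: int, uc: float = 1e-3, band=(4.0, 10.0),
                   n_surrogates: int = 200, seed=None, fs: float | None = None,
                   freqs=None, chunk: int = 25) -> np.ndarray:
    """Empirical null of theta2 from phase-randomized surrogates.

    Runs the full Kalman fit -> transfer function -> normalized ADTF ->
    band-integration chain on each surrogate of the (trial-averaged) input.
    Returns an array (n_surrogates, N, n, n).  Surrogate fits that diverge
    are dropped; more than 10% failures aborts the run.
    """
    if isinstance(eeg, EpochedEEG):
        x = eeg.average()
        fs = eeg.sfreq
    else:
        x = np.asarray(eeg, dtype=float)
        if x.ndim == 3:
            x = x.mean(axis=2)
        fs = fs or 1.0
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate")
    freqs = band_grid(*band) if freqs is None else np.asarray(freqs)
    rng = np.random.default_rng(seed)
    n, N = x.shape
    out = np.empty((n_surrogates, N, n, n))
    n_failed = 0
    for start in range(0, n_surrogates, chunk):
        stop = min(start + chunk, n_surrogates)
        batch = np.stack([phase_randomize(x, rng) for _ in range(start, stop)])
        try:
            W = kalman_coefficients(batch, p, uc)
        except FloatingPointError:
            # retry one-by-one so a single divergent surrogate is isolated
            W = np.zeros((stop - start, N, p, n, n))
            for b in range(stop - start):
                try:
                    W[b] = kalman_coefficients(batch[b:b + 1], p, uc)[0]
                except FloatingPointError:
                    W[b] = np.nan
                    n_failed += 1
        out[start:stop] = theta2_from_coeffs(W, freqs, fs)
    if n_failed > 0.1 * n_surrogates:
        raise RuntimeError(
            f"{n_failed}/{n_surrogates} surrogate fits diverged")
    if n_failed:
        out = out[np.isfinite(out).all(axis=(1, 2, 3))]
    return out


@dataclass
class TimeVaryingNetwork:
    """Per-timepoint directed weighted adjacency with a significance mask.

    ``weights[t, i, j]`` is the flow j -> i at ``times[t]`` (ms); the
    diagonal is excluded.  ``sig_mask`` marks edges surviving the stated
    alpha after the stated correction.
    """

    weights: np.ndarray   # (T, n, n)
    sig_mask: np.ndarray  # (T, n, n) bool
    node_labels: tuple[str, ...]
    times: np.ndarray     # ms
    alpha: float = 1.0
    correction: str = "none"

    def __post_init__(self):
        self.node_labels = tuple(self.node_labels)
        T = len(self.times)
        n = len(self.node_labels)
        if self.weights.shape != (T, n, n):
            raise ValueError("weights must be (T, n, n)")
        idx = np.arange(n)
        self.weights = self.weights.copy()
        self.sig_mask = self.sig_mask.astype(bool).copy()
        self.weights[:, idx, idx] = 0.0
        self.sig_mask[:, idx, idx] = False
        self.sig_mask &= self.weights > 0

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def time_index(self, t_ms: float) -> int:
        i = int(np.argmin(np.abs(self.times - t_ms)))
        if abs(self.times[i] - t_ms) > 1e-6:
            raise KeyError(f"timepoint {t_ms} ms not in network")
        return i

    def masked(self, t_index: int) -> np.ndarray:
        return np.where(self.sig_mask[t_index], self.weights[t_index], 0.0)


def network_from_adtf(theta2: np.ndarray, node_labels, times,
                      sig_mask: np.ndarray | None = None,
                      alpha: float = 1.0, correction: str = "none"
                      ) -> TimeVaryingNetwork:
    """Wrap integrated-ADTF weights as a network (all edges kept by default)."""
    theta2 = np.asarray(theta2)
    if sig_mask is None:
        sig_mask = np.ones_like(theta2, dtype=bool)
    return TimeVaryingNetwork(weights=theta2, sig_mask=sig_mask,
                              node_labels=tuple(node_labels),
                              times=np.asarray(times, dtype=float),
                              alpha=alpha, correction=correction)


def empirical_edge_pvalues(theta2_obs: np.ndarray, null: np.ndarray
                           ) -> np.ndarray:
    """Rank-based one-sided p-values, (1 + #{null >= obs}) / (1 + S)."""
    S = null.shape[0]
    exceed = (null >= theta2_obs[None]).sum(axis=0)
    return (1.0 + exceed) / (1.0 + S)


def threshold_single(theta2_obs: np.ndarray, null: np.ndarray, node_labels,
                     times, alpha: float = 0.05, bonferroni: bool = True,
                     valid_from: int = 0) -> TimeVaryingNetwork:
    """Single-recording mode: observed theta2 against its own surrogate null."""
    pvals = empirical_edge_pvalues(theta2_obs, null)
    n = theta2_obs.shape[-1]
    m = n * (n - 1) if bonferroni else 1
    mask = pvals * m <= alpha
    mask[:valid_from] = False
    return TimeVaryingNetwork(
        weights=theta2_obs, sig_mask=mask, node_labels=node_labels,
        times=np.asarray(times, dtype=float), alpha=alpha,
        correction="bonferroni" if bonferroni else "none")


def threshold_network(obs_list, null_list, node_labels, times,
                      alpha: float = 0.05, valid_from: int = 0
                      ) -> TimeVaryingNetwork:
    """Across-subject thresholding by Wilcoxon signed rank vs surrogate nulls.

    Per edge and timepoint, each subject's surrogate null is summarized by
    its median theta2; the signed-rank test (one-sided, observed > null,
    zero differences dropped) runs across subjects, and edges significant at
    ``alpha`` after Bonferroni correction over the n(n-1) directed edges of
    that timepoint enter the mask.  Weights carry the group-mean observed
    theta2.
    """
    obs = np.stack(list(obs_list))            # (n_subj, T, n, n)
    nulls = np.stack([np.median(nu, axis=0) for nu in null_list])
    n_subj = obs.shape[0]
    if n_subj < 6:
        raise ValueError("across-subject Wilcoxon needs at least 6 subjects")
    if nulls.shape != obs.shape:
        raise ValueError("observed and null stacks disagree in shape")
    T, n = obs.shape[1], obs.shape[2]
    diffs = obs - nulls
    pvals = np.ones((T, n, n))
    for t in range(valid_from, T):
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                d = diffs[:, t, i, j]
                d = d[d != 0.0]
                if len(d) == 0:
                    continue
                pvals[t, i, j] = stats.wilcoxon(
                    d, alternative="greater").pvalue
    m = n * (n - 1)
    mask = pvals * m <= alpha
    mask[:valid_from] = False
    return TimeVaryingNetwork(
        weights=obs.mean(axis=0), sig_mask=mask, node_labels=node_labels,
        times=np.asarray(times, dtype=float), alpha=alpha,
        correction="bonferroni")
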