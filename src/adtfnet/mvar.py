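"""Time-varying MVAR estimation and the time-resolved transfer function.

The signal model is a multivariate adaptive autoregression

    X(t) = sum_{k=1..p} w(k,t) X(t-k) + eps(t),

tracked by a Kalman filter whose state is the vectorized coefficient stack.
The state follows a random walk with process noise scaled by the update
coefficient (UC); the measurement noise covariance is estimated adaptively
from exponentially smoothed residuals -- the classic adaptive-AR formulation.
In the frequency domain,

    A(f,t) = I - sum_k w_k(t) exp(-j 2 pi f k / fs),    H(f,t) = A(f,t)^-1,

so H is the causal transfer matrix from innovations to signals.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochedEEG


def normalize_ensemble(eeg: EpochedEEG) -> EpochedEEG:
    """Per-channel z-scoring pooled over the concatenated epoch samples.

    Constant channels map to zeros.  Idempotent on already-standardized data.
    """
    flat = eeg.data.reshape(eeg.n_channels, -1)
    mean = flat.mean(axis=1)
    sd = flat.std(axis=1)
    sd_safe = np.where(sd > 0, sd, 1.0)
    data = (eeg.data - mean[:, None, None]) / sd_safe[:, None, None]
    data[sd == 0] = 0.0
    return eeg.copy(data=data)


def _as_array(eeg) -> np.ndarray:
    """Accept EpochedEEG or array; return (n_channels, n_samples, n_trials)."""
    if isinstance(eeg, EpochedEEG):
        return eeg.data
    arr = np.asarray(eeg, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError("expected (channels, samples[, trials])")
    return arr


def select_model_order(eeg, p_max: int) -> int:
    """Model order minimizing the Schwarz Bayesian Criterion.

    Stationary MVAR fits by least squares at orders 1..p_max (all on the
    same effective sample span), scored by
    SBC(p) = ln det(Sigma_res) + p n^2 ln(N) / N.
    """
    data = _as_array(eeg)
    n, N, R = data.shape
    if p_max < 1:
        raise ValueError("p_max must be >= 1")
    n_eff = (N - p_max) * R
    if p_max * n * n >= n_eff * n:
        raise ValueError("insufficient samples for the requested p_max")
    best_p, best_sbc = 1, np.inf
    for p in range(1, p_max + 1):
        # regression of X(t) on [X(t-1); ...; X(t-p)], pooled over trials
        ys, regs = [], []
        for r in range(R):
            x = data[:, :, r]
            ys.append(x[:, p_max:].T)
            regs.append(np.concatenate(
                [x[:, p_max - k:N - k].T for k in range(1, p + 1)], axis=1))
        y = np.concatenate(ys)
        reg = np.concatenate(regs)
        coef, *_ = np.linalg.lstsq(reg, y, rcond=None)
        resid = y - reg @ coef
        sigma = (resid.T @ resid) / len(y)
        sign, logdet = np.linalg.slogdet(sigma)
        sbc = logdet + p * n * n * np.log(len(y)) / len(y)
        if sbc < best_sbc:
            best_p, best_sbc = p, sbc
    return best_p


def ols_mvar(eeg, p: int) -> np.ndarray:
    """Stationary least-squares MVAR fit; coefficients (p, n, n)."""
    data = _as_array(eeg)
    n, N, R = data.shape
    ys, regs = [], []
    for r in range(R):
        x = data[:, :, r]
        ys.append(x[:, p:].T)
        regs.append(np.concatenate(
            [x[:, p - k:N - k].T for k in range(1, p + 1)], axis=1))
    coef, *_ = np.linalg.lstsq(np.concatenate(regs), np.concatenate(ys),
                               rcond=None)
    # coef rows ordered k-major (k=1 channels, k=2 channels, ...)
    return coef.T.reshape(n, p, n).transpose(1, 0, 2)


@dataclass
class TVARModel:
    """Kalman-tracked MVAR coefficient stack.

    ``coeffs[t, k-1]`` is the n x n lag-k matrix at sample t (zeros before
    ``valid_from``, the burn-in of p samples).  ``noise_cov[t]`` is the
    adaptively estimated innovation covariance.
    """

    order: int
    coeffs: np.ndarray       # (N, p, n, n)
    noise_cov: np.ndarray    # (N, n, n)
    update_coefficient: float
    sfreq: float
    ch_names: tuple[str, ...]
    valid_from: int

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[0]

    def to_table(self) -> pd.DataFrame:
        """Long-format coefficient table (t, k, i, j, value)."""
        N, p, n, _ = self.coeffs.shape
        t, k, i, j = np.meshgrid(np.arange(N), np.arange(1, p + 1),
                                 np.arange(n), np.arange(n), indexing="ij")
        return pd.DataFrame({
            "t": t.ravel(), "k": k.ravel(), "i": i.ravel(), "j": j.ravel(),
            "value": self.coeffs.ravel(),
        })


def kalman_coefficients(X: np.ndarray, p: int, uc: float,
                        return_noise_cov: bool = False):
    """Batched Kalman tracking of MVAR coefficients.

    ``X`` has shape (B, n, N) or (B, n, N, R); trials R are assimilated
    sequentially within each time step (ensemble tracking of one coefficient
    trajectory).  Returns coefficients with shape (B, N, p, n, n).

    Zero initialization, identity state covariance; process noise per step is
    ``uc * trace(P) / dim(state)`` on the diagonal.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 3:
        X = X[..., None]
    B, n, N, R = X.shape
    if not 0 < uc < 1:
        raise ValueError("update coefficient must lie in (0, 1)")
    if N <= p:
        raise ValueError("need more samples than the model order")
    q = n * p
    m = n * q
    eye_m = np.eye(m)
    x = np.zeros((B, m))
    P = np.tile(eye_m, (B, 1, 1))
    Rm = np.tile(np.eye(n), (B, 1, 1))
    W = np.zeros((B, N, p, n, n))
    Rhist = np.zeros((B, N, n, n)) if return_noise_cov else None
    for t in range(p, N):
        tr = np.trace(P, axis1=1, axis2=2) / m
        P = P + (uc * tr)[:, None, None] * eye_m
        for r in range(R):
            phi = np.concatenate([X[:, :, t - k, r] for k in range(1, p + 1)],
                                 axis=1)  # (B, q)
            Pb = P.reshape(B, n, q, n, q)
            CP = np.einsum("bq,biqjr->bijr", phi, Pb)          # (B, n, n, q)
            S = np.einsum("bijr,br->bij", CP, phi) + Rm
            PCt = CP.transpose(0, 2, 3, 1).reshape(B, m, n)
            K = PCt @ np.linalg.inv(S)
            yhat = np.einsum("bq,biq->bi", phi, x.reshape(B, n, q))
            e = X[:, :, t, r] - yhat
            x = x + np.einsum("bmn,bn->bm", K, e)
            P = P - K @ PCt.transpose(0, 2, 1)
            P = 0.5 * (P + P.transpose(0, 2, 1))
            Rm = (1 - uc) * Rm + uc * np.einsum("bi,bj->bij", e, e)
        W[:, t] = x.reshape(B, n, p, n).transpose(0, 2, 1, 3)
        if return_noise_cov:
            Rhist[:, t] = Rm
    if not np.all(np.isfinite(W)):
        bad = np.argwhere(~np.isfinite(W).all(axis=(2, 3, 4)))
        raise FloatingPointError(
            f"Kalman state diverged (first non-finite at batch={bad[0][0]}, "
            f"t={bad[0][1]})"
        )
    if return_noise_cov:
        return W, Rhist
    return W


def fit_mvaar_kalman(eeg, p: int, uc: float = 1e-3,
                     sfreq: float | None = None) -> TVARModel:
    """Fit the time-varying MVAR model by the adaptive Kalman recursion.

    Multi-trial input updates one coefficient trajectory, assimilating every
    trial at each time step.  The first ``p`` samples are burn-in and carry
    zero coefficients (``valid_from = p``).
    """
    data = _as_array(eeg)
    if isinstance(eeg, EpochedEEG):
        sfreq = eeg.sfreq
        ch_names = eeg.ch_names
    else:
        sfreq = sfreq or 1.0
        ch_names = tuple(f"ch{i}" for i in range(data.shape[0]))
    if p < 1:
        raise ValueError("model order must be >= 1")
    W, Rhist = kalman_coefficients(data[None, ...], p, uc,
                                   return_noise_cov=True)
    return TVARModel(order=p, coeffs=W[0], noise_cov=Rhist[0],
                     update_coefficient=uc, sfreq=sfreq, ch_names=ch_names,
                     valid_from=p)


@dataclass
class TransferFunction:
    """Complex transfer matrices H(f,t) on a frequency grid (Hz)."""

    H: np.ndarray        # (n_freqs, N, n, n) complex
    freqs: np.ndarray
    sfreq: float
    ch_names: tuple[str, ...]
    valid_from: int = 0


def spectral_matrix(coeffs: np.ndarray, freqs, fs: float) -> np.ndarray:
    """A(f,t) = I - sum_k w_k(t) exp(-j 2 pi f k / fs).

    ``coeffs`` may carry leading batch dimensions: (..., N, p, n, n) ->
    (..., F, N, n, n).
    """
    coeffs = np.asarray(coeffs)
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    p, n = coeffs.shape[-3], coeffs.shape[-1]
    lags = np.arange(1, p + 1) / fs
    E = np.exp(-2j * np.pi * freqs[:, None] * lags[None, :])  # (F, p)
    A = -np.einsum("fk,...tkij->...ftij", E, coeffs)
    A[..., np.arange(n), np.arange(n)] += 1.0
    return A


def transfer_function(model: TVARModel, freqs, fs: float | None = None
                      ) -> TransferFunction:
    """Invert the spectral coefficient matrix at each frequency and sample."""
    fs = fs or model.sfreq
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequencies must lie inside (0, Nyquist)")
    A = spectral_matrix(model.coeffs, freqs, fs)
    try:
        H = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        dets = np.abs(np.linalg.det(A))
        f_i, t_i = np.unravel_index(int(np.argmin(dets)), dets.shape)
        raise np.linalg.LinAlgError(
            f"singular coefficient matrix near f={freqs[f_i]:g} Hz, t={t_i}"
        ) from None
    return TransferFunction(H=H, freqs=freqs, sfreq=fs,
                            ch_names=model.ch_names,
                            valid_from=model.valid_from)


def band_grid(f1: float, f2: float, step: float = 1.0) -> np.ndarray:
    """Default analysis grid: 1 Hz steps spanning [f1, f2] inclusive."""
    return np.arange(f1, f2 + 0.5 * step, step)
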