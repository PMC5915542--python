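"""ERP construction and statistics: epoch rejection, baseline, peak
measurement, paired t with Cohen's d, and 2x2 repeated-measures ANOVA."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EpochedEEG, PipelineConfig


@dataclass(frozen=True)
class ERPMeasure:
    """Peak measurement of one averaged waveform."""

    channel: str
    peak_amplitude: float  # uV
    peak_latency: float    # ms
    subject: str | None = None
    condition: str | None = None
    reference: str | None = None


def preprocess_epochs(eeg: EpochedEEG, cfg: PipelineConfig,
                      eog: tuple[str, ...] = (),
                      eog_threshold: float = 60.0) -> EpochedEEG:
    """Artifact rejection and baseline correction.

    Trials are dropped when any scalp channel exceeds the +-threshold (uV)
    anywhere in the epoch, or when any EOG channel exceeds ``eog_threshold``
    (amplitude criterion standing in for ocular-artifact screening).  The
    per-channel mean over the baseline window is then subtracted.  EOG
    channels are removed from the output.
    """
    eog = tuple(eog)
    unknown = [c for c in eog if c not in eeg.ch_names]
    if unknown:
        raise KeyError(f"EOG channels not in data: {unknown}")
    scalp_idx = [i for i, c in enumerate(eeg.ch_names) if c not in eog]
    eog_idx = [i for i, c in enumerate(eeg.ch_names) if c in eog]

    bad_scalp = (np.abs(eeg.data[scalp_idx]) > cfg.reject_threshold
                 ).any(axis=(0, 1))
    bad = bad_scalp
    if eog_idx:
        bad = bad | (np.abs(eeg.data[eog_idx]) > eog_threshold).any(axis=(0, 1))
    keep = ~bad
    if not keep.any():
        raise RuntimeError("all trials rejected by the artifact criterion")

    data = eeg.data[np.ix_(scalp_idx, range(eeg.n_samples), np.where(keep)[0])]
    times = eeg.times
    b0, b1 = cfg.baseline_window
    bsel = (times >= b0) & (times < b1)
    if not bsel.any():
        raise ValueError("baseline window contains no samples")
    data = data - data[:, bsel, :].mean(axis=1, keepdims=True)
    return eeg.copy(data=data,
                    ch_names=tuple(eeg.ch_names[i] for i in scalp_idx))


def peak_measures(erp, channel: str, window: tuple[float, float] = (160.0, 180.0),
                  polarity: str = "negative", **tags) -> ERPMeasure:
    """Peak amplitude/latency of an averaged waveform in a search window.

    ``erp`` is an EpochedEEG (trial-averaged internally).  For negative
    polarity the amplitude is the window minimum and the latency its time;
    the earliest sample wins ties.
    """
    if not isinstance(erp, EpochedEEG):
        raise TypeError("erp must be an EpochedEEG")
    if channel not in erp.ch_names:
        raise KeyError(f"channel {channel!r} not present")
    times = erp.times
    sel = np.where((times >= window[0]) & (times <= window[1]))[0]
    if len(sel) == 0:
        raise ValueError("search window lies outside the epoch")
    wave = erp.average()[erp.ch_names.index(channel), sel]
    if polarity == "negative":
        k = int(np.argmin(wave))
    elif polarity == "positive":
        k = int(np.argmax(wave))
    else:
        raise ValueError("polarity must be 'negative' or 'positive'")
    return ERPMeasure(channel=channel, peak_amplitude=float(wave[k]),
                      peak_latency=float(times[sel[k]]), **tags)


def paired_t_with_d(x, y) -> tuple[float, float, float]:
    """Classical paired t-test plus Cohen's d for paired samples.

    d = mean(x - y) / sd(x - y).  Zero variance of the differences is an
    error (the statistic is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length 1-D with n >= 2")
    diff = x - y
    sd = diff.std(ddof=1)
    if sd == 0:
        if np.allclose(diff, 0):
            return 0.0, 1.0, 0.0
        raise ZeroDivisionError(
            "paired differences have zero variance; t is unbounded")
    res = stats.ttest_rel(x, y)
    d = diff.mean() / sd
    return float(res.statistic), float(res.pvalue), float(d)


def rm_anova_2x2(table: pd.DataFrame, dv: str = "value",
                 subject: str = "subject",
                 factors: tuple[str, str] = ("reference", "stimulus")
                 ) -> pd.DataFrame:
    """Two-way fully repeated-measures ANOVA with partial eta squared.

    ``table`` is long-format with one row per subject x cell of the complete
    balanced 2x2 (or general two-factor) design.  Returns one row per effect
    (factor A, factor B, interaction) with F, p and eta_p^2 =
    SS_effect / (SS_effect + SS_error).
    """
    import pingouin as pg

    fa, fb = factors
    cells = table.pivot_table(index=subject, columns=[fa, fb], values=dv,
                              aggfunc="count")
    n_a = table[fa].nunique()
    n_b = table[fb].nunique()
    if cells.isna().any().any() or (cells != 1).any().any() \
            or cells.shape[1] != n_a * n_b:
        raise ValueError("design must be complete and balanced "
                         "(exactly one value per subject x cell)")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.rm_anova(data=table, dv=dv, within=list(factors),
                          subject=subject, detailed=True, effsize="np2")
    out = res.rename(columns={"p_unc": "p"})
    # eta_p^2 = SS_effect/(SS_effect + SS_error) = F df1 / (F df1 + df2);
    # recomputed from F so the noise-free case resolves cleanly
    f = out["F"].to_numpy(dtype=float)
    df1 = out["ddof1"].to_numpy(dtype=float)
    df2 = out["ddof2"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        np2 = np.where(np.isinf(f), 1.0, f * df1 / (f * df1 + df2))
    out["partial_eta_sq"] = np2
    out.loc[np.isinf(f), "p"] = 0.0
    # a zero-variance effect (SS_effect = 0) has F = 0 by definition even
    # when the error term also vanishes (0/0 in the software)
    degenerate = ~np.isfinite(out["F"].to_numpy()) & \
        np.isclose(res["SS"].to_numpy(), 0.0)
    out.loc[degenerate, ["F", "partial_eta_sq"]] = 0.0
    out.loc[degenerate, "p"] = 1.0
    return out[["Source", "F", "p", "partial_eta_sq"]]


def measures_table(measures) -> pd.DataFrame:
    """ERPMeasure records as a long-format table (TSV-ready)."""
    return pd.DataFrame([{
        "subject": m.subject, "condition": m.condition,
        "reference": m.reference, "channel": m.channel,
        "peak_amplitude_uv": m.peak_amplitude,
        "peak_latency_ms": m.peak_latency,
    } for m in measures])
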