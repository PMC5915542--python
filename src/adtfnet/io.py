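"""Containers and plain-text I/O for epoched EEG, montages, configs and networks.

The package works in microvolts throughout, with epoch time in milliseconds
relative to stimulus onset at t = 0.  Sample timestamps are left-aligned:
sample ``n`` covers ``[n/fs, (n+1)/fs)``.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: The 19-electrode 10-20 subset used for scalp network analysis.
SUBSET_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "T7", "C3", "Cz",
    "C4", "T8", "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
)

#: A standard 64-channel 10-10 cap (the recording montage); re-referencing
#: operates on the full cap, network analysis on the 19-channel subset.
MONTAGE_64 = (
    "Fp1", "Fpz", "Fp2", "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
    "P9", "P10", "Iz",
)


def _fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Algebraic least-squares center of the sphere best fitting ``points``."""
    A = np.c_[2 * points, np.ones(len(points))]
    b = (points**2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol[:3]


@dataclass(frozen=True)
class Montage:
    """Electrode labels with unit-sphere Cartesian positions (head radius 1)."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 3), each row unit norm

    def __post_init__(self):
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        pos = np.asarray(self.positions, dtype=float)
        if len(labels) != len(set(labels)):
            raise ValueError("montage labels must be unique")
        if pos.shape != (len(labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if np.any(norms == 0):
            raise ValueError("zero-length electrode position")
        pos = pos / norms[:, None]
        object.__setattr__(self, "positions", pos)

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    @property
    def subset19(self) -> tuple[str, ...]:
        return tuple(l for l in SUBSET_19 if l in self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in montage") from None

    def subset(self, labels) -> "Montage":
        idx = [self.index(l) for l in labels]
        return Montage(tuple(labels), self.positions[idx])

    @classmethod
    def standard(cls, labels=SUBSET_19) -> "Montage":
        """Standard 10-10 positions projected onto the unit sphere.

        Positions come from the bundled MNE template montage, centered on the
        best-fit sphere of the full cap and normalized to radius 1.
        """
        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mont = mne.channels.make_standard_montage("standard_1020")
        ch_pos = mont.get_positions()["ch_pos"]
        all_pos = np.array(list(ch_pos.values()))
        center = _fit_sphere_center(all_pos)
        missing = [l for l in labels if l not in ch_pos]
        if missing:
            raise KeyError(f"labels not in standard montage: {missing}")
        pos = np.array([ch_pos[l] for l in labels]) - center
        return cls(tuple(labels), pos)


def read_montage(path) -> Montage:
    """Read a 4-column whitespace-delimited file: label, x, y, z."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise ValueError(f"expected 4 columns, got: {line!r}")
        rows.append((parts[0], [float(p) for p in parts[1:]]))
    return Montage(tuple(r[0] for r in rows), np.array([r[1] for r in rows]))


def write_montage(montage: Montage, path) -> None:
    lines = [f"{l}\t{x:.10g}\t{y:.10g}\t{z:.10g}"
             for l, (x, y, z) in zip(montage.labels, montage.positions)]
    Path(path).write_text("\n".join(lines) + "\n")


@dataclass
class EpochedEEG:
    """Channels x samples x trials voltage array in microvolts.

    ``tmin_ms`` is the time of the first sample relative to stimulus onset.
    ``reference`` tags the referencing state ("as-recorded", "AR", "REST",
    "infinity").
    """

    data: np.ndarray  # (n_channels, n_samples, n_trials)
    sfreq: float
    ch_names: tuple[str, ...]
    tmin_ms: float = 0.0
    reference: str = "as-recorded"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 2:
            self.data = self.data[:, :, None]
        if self.data.ndim != 3:
            raise ValueError("data must be (channels, samples[, trials])")
        self.ch_names = tuple(self.ch_names)
        if len(self.ch_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.ch_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Left-aligned sample times in ms."""
        return self.tmin_ms + 1000.0 * np.arange(self.n_samples) / self.sfreq

    def average(self) -> np.ndarray:
        """Trial-average waveform, (channels, samples)."""
        return self.data.mean(axis=2)

    def copy(self, **overrides) -> "EpochedEEG":
        kw = dict(data=self.data.copy(), sfreq=self.sfreq,
                  ch_names=self.ch_names, tmin_ms=self.tmin_ms,
                  reference=self.reference)
        kw.update(overrides)
        return EpochedEEG(**kw)

    def pick(self, labels) -> "EpochedEEG":
        idx = [self.ch_names.index(l) for l in labels]
        return self.copy(data=self.data[idx], ch_names=tuple(labels))

    def time_index(self, t_ms: float) -> int:
        idx = int(np.argmin(np.abs(self.times - t_ms)))
        return idx


@dataclass
class PipelineConfig:
    """Analysis parameters for the full pipeline."""

    sampling_rate: float = 250.0
    epoch_window: tuple[float, float] = (-200.0, 1000.0)  # ms
    baseline_window: tuple[float, float] = (-200.0, 0.0)  # ms
    reject_threshold: float = 60.0  # uV
    band: tuple[float, float] = (4.0, 10.0)  # Hz
    n_surrogates: int = 200
    alphas: tuple[float, ...] = (0.05, 0.03, 0.01)
    model_order: int | str = "auto"
    update_coefficient: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        t0, t1 = self.epoch_window
        b0, b1 = self.baseline_window
        if not (t0 < 0 < t1):
            raise ValueError("epoch window must straddle stimulus onset")
        if not (t0 <= b0 < b1 <= t1):
            raise ValueError("baseline window must lie inside the epoch")
        f1, f2 = self.band
        if not f1 < f2:
            raise ValueError("band must satisfy f1 < f2")
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if not all(0 < a < 1 for a in self.alphas):
            raise ValueError("alphas must lie in (0, 1)")
        if self.model_order != "auto" and int(self.model_order) < 1:
            raise ValueError("model order must be positive or 'auto'")
        if not 0 < self.update_coefficient < 1:
            raise ValueError("update coefficient must lie in (0, 1)")

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("epoch_window", "baseline_window", "band", "alphas"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


# ---------------------------------------------------------------------------
# Delimited epoch files: rows = (epoch, channel), columns = samples.

_EPOCH_MAGIC = "# adtfnet-epochs v1"


def write_epoched_eeg(eeg: EpochedEEG, path) -> None:
    """Write epochs as a tab-separated stack with a metadata header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_EPOCH_MAGIC + "\n")
        fh.write(f"# sfreq_hz={eeg.sfreq:.10g}\n")
        fh.write(f"# tmin_ms={eeg.tmin_ms:.10g}\n")
        fh.write(f"# reference={eeg.reference}\n")
        cols = "\t".join(f"s{i}" for i in range(eeg.n_samples))
        fh.write(f"epoch\tchannel\t{cols}\n")
        for r in range(eeg.n_trials):
            for c, name in enumerate(eeg.ch_names):
                row = "\t".join(f"{v:.10g}" for v in eeg.data[c, :, r])
                fh.write(f"{r}\t{name}\t{row}\n")


def _read_delimited(path, montage: Montage | None) -> EpochedEEG:
    path = Path(path)
    meta = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    if "sfreq_hz" not in meta:
        raise ValueError(f"{path}: missing '# sfreq_hz=' header")
    table = pd.read_csv(path, sep="\t", skiprows=n_header)
    if not {"epoch", "channel"} <= set(table.columns):
        raise ValueError(f"{path}: expected 'epoch' and 'channel' columns")
    ch_names = tuple(table.loc[table["epoch"] == table["epoch"].iloc[0],
                               "channel"])
    n_trials = table["epoch"].nunique()
    samples = table.drop(columns=["epoch", "channel"]).to_numpy(dtype=float)
    n_ch = len(ch_names)
    if len(table) != n_ch * n_trials:
        raise ValueError(f"{path}: ragged epoch stack")
    data = samples.reshape(n_trials, n_ch, -1).transpose(1, 2, 0)
    if montage is not None and set(ch_names) != set(montage.labels):
        raise ValueError(
            f"channel mismatch: file has {n_ch} channels, montage has "
            f"{montage.n_channels}"
        )
    return EpochedEEG(
        data=data,
        sfreq=float(meta["sfreq_hz"]),
        ch_names=ch_names,
        tmin_ms=float(meta.get("tmin_ms", 0.0)),
        reference=meta.get("reference", "as-recorded"),
    )


def read_epoched_eeg(path, format: str = "delimited-matrix",
                     montage: Montage | None = None,
                     events=None) -> EpochedEEG:
    """Read epoched EEG from a delimited stack or a plain EDF file.

    For EDF input each data record is one epoch; ``events`` may be a sequence
    of (onset_ms) per epoch but is unused for the packaged formats, where
    epoch timing is carried in the header / sidecar.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited-matrix":
        return _read_delimited(path, montage)
    if format == "edf":
        from ._edf import read_edf

        eeg = read_edf(path)
        if montage is not None and set(eeg.ch_names) != set(montage.labels):
            raise ValueError(
                f"channel mismatch: file has {eeg.n_channels} channels, "
                f"montage has {montage.n_channels}"
            )
        return eeg
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Network edge lists.

def write_network(net, path) -> None:
    """Write a TimeVaryingNetwork as a TSV edge list.

    One row per nonzero off-diagonal weight: time_ms, source_label,
    target_label, weight, significant_flag, alpha.  Header comments record
    the node set and time axis so the matching reader can round-trip empty
    rows/nodes losslessly.
    """
    if net.weights.size == 0:
        raise ValueError("empty network")
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# adtfnet-network v1\n")
        fh.write("# nodes=" + ",".join(net.node_labels) + "\n")
        fh.write("# times_ms=" + ",".join(f"{t:.10g}" for t in net.times) + "\n")
        fh.write(f"# alpha={net.alpha:.10g}\n")
        fh.write("time_ms\tsource\ttarget\tweight\tsignificant\talpha\n")
        n = len(net.node_labels)
        for ti, t in enumerate(net.times):
            for i in range(n):       # receiver
                for j in range(n):   # sender: entry (i, j) is flow j -> i
                    if i == j or net.weights[ti, i, j] == 0:
                        continue
                    sig = bool(net.sig_mask[ti, i, j])
                    fh.write(
                        f"{t:.10g}\t{net.node_labels[j]}\t{net.node_labels[i]}"
                        f"\t{net.weights[ti, i, j]:.10g}\t{int(sig)}"
                        f"\t{net.alpha:.10g}\n"
                    )


def read_network(path):
    from .adtf import TimeVaryingNetwork

    path = Path(path)
    meta = {}
    n_header = 0
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    labels = tuple(meta["nodes"].split(","))
    times = np.array([float(t) for t in meta["times_ms"].split(",")])
    alpha = float(meta["alpha"])
    table = pd.read_csv(path, sep="\t", skiprows=n_header)
    n = len(labels)
    weights = np.zeros((len(times), n, n))
    sig = np.zeros((len(times), n, n), dtype=bool)
    t_index = {round(t, 6): i for i, t in enumerate(times)}
    l_index = {l: i for i, l in enumerate(labels)}
    for row in table.itertuples(index=False):
        ti = t_index[round(row.time_ms, 6)]
        i, j = l_index[row.target], l_index[row.source]
        weights[ti, i, j] = row.weight
        sig[ti, i, j] = bool(row.significant)
    return TimeVaryingNetwork(weights=weights, sig_mask=sig,
                              node_labels=labels, times=times, alpha=alpha)
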