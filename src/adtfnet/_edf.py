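"""Minimal plain-EDF writer and reader for epoched data.

Each data record holds one epoch.  Only the features the package needs are
implemented: int16 samples, per-channel physical scaling, microvolt units.
Epoch timing (tmin) and reference tag travel in the 44-byte reserved header
field, which standard readers ignore.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np

from .io import EpochedEEG

_DIG_MIN, _DIG_MAX = -32768, 32767


def _field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(eeg: EpochedEEG, path) -> None:
    n_sig = eeg.n_channels
    n_rec = eeg.n_trials
    spr = eeg.n_samples
    record_dur = spr / eeg.sfreq

    phys_min = np.minimum(eeg.data.min(axis=(1, 2)), -1.0)
    phys_max = np.maximum(eeg.data.max(axis=(1, 2)), 1.0)
    # pad so extremes are strictly representable
    span = phys_max - phys_min
    phys_min = phys_min - 0.001 * span
    phys_max = phys_max + 0.001 * span

    header = b"".join([
        _field("0", 8),
        _field("X X X X", 80),
        _field("Startdate X X X X", 80),
        _field("01.01.00", 8),
        _field("00.00.00", 8),
        _field(256 * (1 + n_sig), 8),
        _field(f"tmin_ms={eeg.tmin_ms:.6g};ref={eeg.reference}", 44),
        _field(n_rec, 8),
        _field(f"{record_dur:.6g}", 8),
        _field(n_sig, 4),
    ])
    sig = b"".join([
        b"".join(_field(l, 16) for l in eeg.ch_names),
        b"".join(_field("", 80) for _ in range(n_sig)),        # transducer
        b"".join(_field("uV", 8) for _ in range(n_sig)),
        b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_min),
        b"".join(_field(f"{v:.6g}"[:8], 8) for v in phys_max),
        b"".join(_field(_DIG_MIN, 8) for _ in range(n_sig)),
        b"".join(_field(_DIG_MAX, 8) for _ in range(n_sig)),
        b"".join(_field("", 80) for _ in range(n_sig)),        # prefiltering
        b"".join(_field(spr, 8) for _ in range(n_sig)),
        b"".join(_field("", 32) for _ in range(n_sig)),
    ])
    # physical limits as written (8-char ascii) define the actual scaling
    pmin = np.array([float(f"{v:.6g}"[:8]) for v in phys_min])
    pmax = np.array([float(f"{v:.6g}"[:8]) for v in phys_max])
    gain = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    with Path(path).open("wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            block = eeg.data[:, :, r]
            dig = np.round((block - pmin[:, None]) / gain[:, None]
                           + _DIG_MIN).astype("<i2")
            fh.write(dig.tobytes())


def read_edf(path) -> EpochedEEG:
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError(f"{path}: not an EDF file")

    def ascii_at(off, width):
        return raw[off:off + width].decode("ascii", "replace").strip()

    header_bytes = int(ascii_at(184, 8))
    reserved = ascii_at(192, 44)
    n_rec = int(ascii_at(236, 8))
    record_dur = float(ascii_at(244, 8))
    n_sig = int(ascii_at(252, 4))

    # signal header blocks, in EDF order:
    # label 16, transducer 80, dim 8, phys min 8, phys max 8,
    # dig min 8, dig max 8, prefiltering 80, samples/record 8, reserved 32
    off = 0
    widths = [16, 80, 8, 8, 8, 8, 8, 80, 8, 32]
    blocks = []
    for w in widths:
        base = 256 + off
        blocks.append([ascii_at(base + k * w, w) for k in range(n_sig)])
        off += w * n_sig
    labels = blocks[0]
    pmin = np.array([float(v) for v in blocks[3]])
    pmax = np.array([float(v) for v in blocks[4]])
    dmin = np.array([float(v) for v in blocks[5]])
    dmax = np.array([float(v) for v in blocks[6]])
    spr = np.array([int(v) for v in blocks[8]])
    if len(set(spr)) != 1:
        raise ValueError("non-uniform samples-per-record across channels")
    spr = int(spr[0])

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_rec * n_sig * spr
    if body.size != expected:
        raise ValueError(f"{path}: truncated EDF body "
                         f"({body.size} != {expected} samples)")
    dig = body.reshape(n_rec, n_sig, spr)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (dig - dmin[None, :, None]) * gain[None, :, None] + pmin[None, :, None]
    data = data.transpose(1, 2, 0)  # (channels, samples, epochs)

    tmin_ms, reference = 0.0, "as-recorded"
    for part in reserved.split(";"):
        if part.startswith("tmin_ms="):
            tmin_ms = float(part.split("=", 1)[1])
        elif part.startswith("ref="):
            reference = part.split("=", 1)[1]
    return EpochedEEG(data=data, sfreq=spr / record_dur,
                      ch_names=tuple(labels), tmin_ms=tmin_ms,
                      reference=reference)
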