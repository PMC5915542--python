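"""Average-reference and infinity (REST) re-referencing.

REST estimates the potentials against a reference at infinity from
average-referenced recordings: scalp data are explained by an equivalent
dipole-source layer through the head model's lead field, and the fitted
sources are re-projected with the infinity-referenced gain,

    V_REST = G_inf . pinv(G_avg) . V_avg,

where ``G_avg`` is the average-referenced gain and ``pinv`` a truncated-SVD
pseudoinverse.  Average referencing removes the spatial-mean component; REST
restores the part of it that the source model can see.
"""
from __future__ import annotations

import numpy as np

from .headmodel import LeadField
from .io import EpochedEEG


def apply_average_reference(eeg: EpochedEEG) -> EpochedEEG:
    """Subtract the instantaneous mean over channels; reference tag "AR"."""
    if eeg.n_channels < 2:
        raise ValueError("average reference needs at least 2 channels")
    data = eeg.data - eeg.data.mean(axis=0, keepdims=True)
    return eeg.copy(data=data, reference="AR")


def rest_operator(lf: LeadField, svd_rtol: float = 1e-4) -> np.ndarray:
    """The channels x channels matrix mapping AR data to REST data."""
    g_inf = lf.gain
    g_avg = lf.average_referenced()
    u, s, vt = np.linalg.svd(g_avg, full_matrices=False)
    keep = s > svd_rtol * s[0]
    if keep.sum() < 1:
        raise np.linalg.LinAlgError("rank-deficient lead field")
    pinv = (vt[keep].T / s[keep]) @ u[:, keep].T
    return g_inf @ pinv


def apply_rest_reference(eeg: EpochedEEG, lf: LeadField,
                         svd_rtol: float = 1e-4) -> EpochedEEG:
    """Re-reference to infinity via the equivalent-source layer.

    Input is converted to the average reference first if needed (the
    pseudoinverse is built against the average-referenced gain).
    """
    if tuple(lf.montage.labels) != tuple(eeg.ch_names):
        raise ValueError(
            "lead field channels do not match the EEG channels: "
            f"{lf.montage.labels[:3]}... vs {eeg.ch_names[:3]}..."
        )
    if eeg.reference != "AR":
        eeg = apply_average_reference(eeg)
    R = rest_operator(lf, svd_rtol=svd_rtol)
    shape = eeg.data.shape
    data = (R @ eeg.data.reshape(shape[0], -1)).reshape(shape)
    return eeg.copy(data=data, reference="REST")
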