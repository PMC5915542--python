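"""Three-shell spherical head model and analytic EEG lead fields.

The forward solution is the classical series expansion for a radial current
dipole inside concentric conducting spheres with an insulating exterior.  Per
spherical-harmonic order ``n`` the potential in shell ``k`` is
``A_k r^n + B_k r^-(n+1)`` times a Legendre polynomial; the dipole in the
innermost shell contributes the infinite-medium particular term.  Continuity
of potential and of radial current density at each interface plus the
zero-flux condition at the scalp give a small linear system per order, solved
exactly.  The series is truncated at 60 terms by default, ample for sources
at eccentricities below ~0.9.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import eval_legendre

from .io import Montage


@dataclass(frozen=True)
class HeadModel:
    """Concentric-sphere geometry: (brain, skull, scalp) radii, scalp = 1.

    Default conductivities follow the standard scalp:skull ratio of 80:1,
    with unit cortex and scalp conductivity (Ohm^-1 m^-1).
    """

    shell_radii: tuple[float, float, float] = (0.90, 0.95, 1.00)
    conductivities: tuple[float, float, float] = (1.0, 1.0 / 80.0, 1.0)

    def __post_init__(self):
        r = self.shell_radii
        if not (0 < r[0] < r[1] < r[2]):
            raise ValueError("shell radii must be strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")


def _shell_transfer(n_terms: int, head: HeadModel) -> np.ndarray:
    """Scalp-surface transfer coefficient per harmonic order.

    Returns T such that the scalp potential from a radial unit dipole at
    radius b is  sum_n T[n] * D_n(b) * P_n(cos gamma)  with
    D_n(b) = n b^(n-1) / (4 pi sigma_brain).
    """
    r1, r2, r3 = head.shell_radii
    s1, s2, s3 = head.conductivities
    T = np.zeros(n_terms + 1)
    for n in range(1, n_terms + 1):
        rn = lambda r: r**n
        rm = lambda r: r**-(n + 1)
        drn = lambda r: n * r**(n - 1)
        drm = lambda r: -(n + 1) * r**-(n + 2)
        # unknowns: A1, A2, B2, A3, B3
        A = np.array([
            [rn(r1), -rn(r1), -rm(r1), 0, 0],
            [s1 * drn(r1), -s2 * drn(r1), -s2 * drm(r1), 0, 0],
            [0, rn(r2), rm(r2), -rn(r2), -rm(r2)],
            [0, s2 * drn(r2), s2 * drm(r2), -s3 * drn(r2), -s3 * drm(r2)],
            [0, 0, 0, drn(r3), drm(r3)],
        ])
        rhs = np.array([-rm(r1), -s1 * drm(r1), 0, 0, 0])
        a1, a2, b2, a3, b3 = np.linalg.solve(A, rhs)
        T[n] = a3 * rn(r3) + b3 * rm(r3)
    return T


def forward_gain(electrodes: np.ndarray, dipoles: np.ndarray,
                 head: HeadModel, n_terms: int = 60,
                 moments: np.ndarray | None = None) -> np.ndarray:
    """Gain matrix (electrodes x dipoles) for radially oriented unit dipoles.

    ``electrodes`` are unit-sphere positions (scaled to the scalp radius);
    ``dipoles`` are positions strictly inside the innermost shell.
    ``moments`` optionally scales each dipole.
    """
    electrodes = np.asarray(electrodes, dtype=float)
    dipoles = np.atleast_2d(np.asarray(dipoles, dtype=float))
    r3 = head.shell_radii[2]
    elec = electrodes / np.linalg.norm(electrodes, axis=1)[:, None] * r3
    b = np.linalg.norm(dipoles, axis=1)
    if np.any(b >= head.shell_radii[0]):
        raise ValueError("dipole outside the innermost shell")
    if np.any(b == 0):
        raise ValueError("dipole at the origin has no radial direction")
    T = _shell_transfer(n_terms, head)
    cosg = (elec @ dipoles.T) / (r3 * b[None, :])
    cosg = np.clip(cosg, -1.0, 1.0)
    G = np.zeros((len(elec), len(dipoles)))
    s1 = head.conductivities[0]
    for n in range(1, n_terms + 1):
        Dn = n * b**(n - 1) / (4 * np.pi * s1)
        G += T[n] * Dn[None, :] * eval_legendre(n, cosg)
    if moments is not None:
        G = G * np.asarray(moments)[None, :]
    return G


def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately evenly distributed unit vectors (golden-angle spiral)."""
    k = np.arange(n)
    z = 1 - (2 * k + 1) / n
    phi = k * np.pi * (3 - np.sqrt(5))
    rho = np.sqrt(1 - z**2)
    return np.c_[rho * np.cos(phi), rho * np.sin(phi), z]


@dataclass
class LeadField:
    """Gain matrix from a dipole source layer to scalp electrodes.

    ``gain`` is infinity-referenced (or as tagged by ``reference``), in
    microvolts per unit dipole moment; ``source_positions`` are the radial
    dipole locations.
    """

    gain: np.ndarray  # (n_electrodes, n_sources)
    source_positions: np.ndarray
    montage: Montage
    head: HeadModel
    reference: str = "infinity"

    def __post_init__(self):
        if not np.all(np.isfinite(self.gain)):
            raise ValueError("non-finite lead field gain")
        if self.gain.shape[0] != self.montage.n_channels:
            raise ValueError("gain rows must match montage channels")

    def average_referenced(self) -> np.ndarray:
        """Gain with the average reference applied (zero column means)."""
        return self.gain - self.gain.mean(axis=0, keepdims=True)

    def save(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.gain, delimiter="\t")
        sidecar = {
            "labels": list(self.montage.labels),
            "electrode_positions": self.montage.positions.tolist(),
            "source_positions": self.source_positions.tolist(),
            "shell_radii": list(self.head.shell_radii),
            "conductivities": list(self.head.conductivities),
            "reference": self.reference,
        }
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(sidecar))

    @classmethod
    def load(cls, path) -> "LeadField":
        path = Path(path)
        gain = np.loadtxt(path, delimiter="\t", ndmin=2)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            gain=gain,
            source_positions=np.array(meta["source_positions"]),
            montage=Montage(tuple(meta["labels"]),
                            np.array(meta["electrode_positions"])),
            head=HeadModel(tuple(meta["shell_radii"]),
                           tuple(meta["conductivities"])),
            reference=meta["reference"],
        )


def build_lead_field(montage: Montage, head: HeadModel | None = None,
                     n_sources: int = 3000, layer_scale: float = 0.87,
                     n_terms: int = 60) -> LeadField:
    """Infinity-referenced gain from an equivalent-source dipole layer.

    The layer holds ``n_sources`` radially oriented dipoles evenly spread on
    a sphere at ``layer_scale`` times the scalp radius (0.87 by default, the
    cortical-surface radius the published REST construction uses) -- it must
    stay strictly inside the innermost shell.
    """
    head = head or HeadModel()
    if n_sources < montage.n_channels:
        raise ValueError("need at least as many layer sources as electrodes")
    r_layer = layer_scale * head.shell_radii[2]
    if r_layer >= head.shell_radii[0]:
        raise ValueError("source layer must lie inside the innermost shell")
    layer = fibonacci_sphere(n_sources) * r_layer
    gain = forward_gain(montage.positions, layer, head, n_terms=n_terms)
    return LeadField(gain=gain, source_positions=layer, montage=montage,
                     head=head, reference="infinity")
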