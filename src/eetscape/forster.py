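"""Pairwise excitonic couplings and Forster rates over the chlorophyll network.

Couplings use the ideal point-dipole approximation by default,

    V = f * 5034 * kappa * mu1 * mu2 / R^3   [cm^-1],

with mu in Debye, R in Angstrom, f a multiplicative screening factor, and
kappa = d1.d2 - 3 (d1.R)(d2.R) the orientation factor.  An extended-dipole
scheme (two point charges +-q along the Qy axis) is available for close
pairs.  Rates follow Forster theory,

    k = 1.18 * V^2 * J   [ps^-1],

with J the donor-emission/acceptor-absorption overlap in cm; 1.18 ps^-1 is
the (2 pi)^2 c prefactor expressed in these units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .pigment_model import (
    DEFAULT_FWHM_CM1,
    DEFAULT_STOKES_SHIFT_CM1,
    SiteEnergyTable,
    TransitionDipole,
    gaussian_overlap,
    qy_dipole,
    site_energy,
)
from .structure_io import Species, StructureModel

__all__ = [
    "DIPOLE_COUPLING_CONST",
    "RATE_PREFACTOR_PS",
    "RateParams",
    "RateEdge",
    "RateNetwork",
    "dipole_coupling",
    "extended_dipole_coupling",
    "forster_rate",
    "pairwise_rates",
    "classify_rates",
]

#: 5034 cm^-1 Angstrom^3 / Debye^2 — the CGS conversion mu^2/R^3 -> cm^-1.
DIPOLE_COUPLING_CONST = 5034.0

#: (2 pi)^2 c with V in cm^-1 and J in cm gives k in ps^-1.
RATE_PREFACTOR_PS = 1.18


@dataclass
class RateParams:
    """Configuration for network-wide rate computation."""

    cutoff: float = 40.0           # Mg-Mg pair enumeration cutoff, Angstrom
    screening: float = 1.0         # multiplicative coupling screening factor
    scheme: str = "point_dipole"   # or "extended_dipole"
    extended_separation: float = 8.7  # charge separation for extended scheme, Angstrom
    contact_floor: float = 2.0     # below this the dipole picture is invalid
    fwhm: float = DEFAULT_FWHM_CM1
    stokes_shift: float = DEFAULT_STOKES_SHIFT_CM1
    dipole_strengths: dict | None = None
    site_energies: SiteEnergyTable = field(default_factory=SiteEnergyTable)
    temperature: float = 295.0     # used by the cluster-level theory

    def metadata(self) -> dict:
        return {
            "scheme": self.scheme,
            "screening": self.screening,
            "cutoff_angstrom": self.cutoff,
            "fwhm_cm1": self.fwhm,
            "stokes_shift_cm1": self.stokes_shift,
            "temperature_K": self.temperature,
        }


@dataclass
class RateEdge:
    """One directed donor -> acceptor transfer."""

    coupling: float   # cm^-1
    overlap: float    # cm
    rate: float       # ps^-1

    @property
    def tau(self) -> float:
        """Time constant 1/k in ps (inf for zero rate)."""
        return 1.0 / self.rate if self.rate > 0 else np.inf


@dataclass
class RateNetwork:
    """Directed sparse map (donor pigment id, acceptor pigment id) -> RateEdge."""

    edges: dict[tuple[str, str], RateEdge]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (d, a), e in self.edges.items():
            if e.rate < 0:
                raise ValueError(f"negative rate on edge {d}->{a}")

    def rate(self, donor: str, acceptor: str) -> float:
        return self.edges[(donor, acceptor)].rate

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(self.edges)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (d, a), e in sorted(self.edges.items()):
            dch, _, dres = d.split(":")
            ach, _, ares = a.split(":")
            rows.append(
                {
                    "donor_chain": dch,
                    "donor_resnum": int(dres),
                    "acceptor_chain": ach,
                    "acceptor_resnum": int(ares),
                    "V_cm1": e.coupling,
                    "J_cm": e.overlap,
                    "rate_per_ps": e.rate,
                    "tau_ps": e.tau,
                }
            )
        return pd.DataFrame(rows)


def orientation_factor(
    d1: np.ndarray, d2: np.ndarray, r_hat: np.ndarray
) -> float:
    """kappa = d1.d2 - 3 (d1.r)(d2.r) for unit vectors; kappa^2 in [0, 4]."""
    return float(d1 @ d2 - 3.0 * (d1 @ r_hat) * (d2 @ r_hat))


def dipole_coupling(
    d1: TransitionDipole,
    d2: TransitionDipole,
    screening: float = 1.0,
    contact_floor: float = 2.0,
) -> float:
    """Point-dipole excitonic coupling in cm^-1."""
    r_vec = d2.origin - d1.origin
    r = np.linalg.norm(r_vec)
    if r < contact_floor:
        raise ValueError(
            f"centers {r:.2f} A apart (< contact floor {contact_floor} A): "
            "point-dipole approximation invalid"
        )
    kappa = orientation_factor(d1.direction, d2.direction, r_vec / r)
    return screening * DIPOLE_COUPLING_CONST * kappa * d1.magnitude * d2.magnitude / r**3


def extended_dipole_coupling(
    d1: TransitionDipole,
    d2: TransitionDipole,
    separation: float = 8.7,
    screening: float = 1.0,
    contact_floor: float = 2.0,
) -> float:
    """Extended-dipole coupling: two +-q monopoles along each Qy axis.

    q_i = mu_i / l_i; V = f * 5034 * q1 q2 sum_{s,s'} s s' / |r_ss'|, which
    converges to the point-dipole value as separation -> 0.
    """
    r = np.linalg.norm(d2.origin - d1.origin)
    if r < contact_floor:
        raise ValueError("centers below contact floor: coupling undefined")
    q1 = d1.magnitude / separation
    q2 = d2.magnitude / separation
    total = 0.0
    for s1 in (+1.0, -1.0):
        p1 = d1.origin + s1 * 0.5 * separation * d1.direction
        for s2 in (+1.0, -1.0):
            p2 = d2.origin + s2 * 0.5 * separation * d2.direction
            dist = np.linalg.norm(p2 - p1)
            if dist < 1e-6:
                raise ValueError("extended-dipole charges coincide")
            total += s1 * s2 / dist
    return screening * DIPOLE_COUPLING_CONST * q1 * q2 * total


def forster_rate(coupling: float, overlap: float) -> float:
    """Forster transfer rate k = 1.18 V^2 J in ps^-1 (V in cm^-1, J in cm)."""
    if overlap < 0:
        raise ValueError("spectral overlap must be non-negative")
    return RATE_PREFACTOR_PS * coupling * coupling * overlap


def _coupling(d1: TransitionDipole, d2: TransitionDipole, params: RateParams) -> float:
    if params.scheme == "point_dipole":
        return dipole_coupling(d1, d2, params.screening, params.contact_floor)
    if params.scheme == "extended_dipole":
        return extended_dipole_coupling(
            d1, d2, params.extended_separation, params.screening, params.contact_floor
        )
    raise ValueError(f"unknown coupling scheme {params.scheme!r}")


def pairwise_rates(model: StructureModel, params: RateParams | None = None) -> RateNetwork:
    """Directed Forster rates for every ordered Chl pair within the cutoff.

    Both directions are stored for each retained pair; each direction uses its
    own donor-emission vs acceptor-absorption overlap, so downhill transfer
    (e.g. Chl c -> Chl a) is faster than the uphill back-transfer.
    """
    params = params or RateParams()
    nodes = model.eet_nodes
    if not nodes:
        raise ValueError("model has no EET nodes (run classify_pigments first)")

    dipoles = {p.pigment_id: qy_dipole(p, params.dipole_strengths) for p in nodes}
    energies = {p.pigment_id: site_energy(p, params.site_energies) for p in nodes}

    centers = np.array([dipoles[p.pigment_id].origin for p in nodes])
    tree = cKDTree(centers)
    pairs = tree.query_pairs(params.cutoff, output_type="ndarray")

    edges: dict[tuple[str, str], RateEdge] = {}
    for i, j in pairs:
        pi, pj = nodes[i], nodes[j]
        v = _coupling(dipoles[pi.pigment_id], dipoles[pj.pigment_id], params)
        for donor, acceptor in ((pi, pj), (pj, pi)):
            j_ov = gaussian_overlap(
                energies[donor.pigment_id] - params.stokes_shift,
                params.fwhm,
                energies[acceptor.pigment_id],
                params.fwhm,
            )
            edges[(donor.pigment_id, acceptor.pigment_id)] = RateEdge(
                coupling=v, overlap=j_ov, rate=forster_rate(v, j_ov)
            )
    return RateNetwork(edges=edges, metadata=params.metadata())


#: Display classes of the interpigment rate map: time constants tau <= 1 ps,
#: 1-10 ps, 10-20 ps; slower pairs are omitted from the rendered map.
DEFAULT_CLASS_THRESHOLDS = (1.0, 10.0, 20.0)


def classify_rates(
    net: RateNetwork, thresholds: tuple[float, ...] = DEFAULT_CLASS_THRESHOLDS
) -> dict[tuple[str, str], str]:
    """Label each retained pair with its time-constant class.

    Intervals are half-open (a, b] in tau, so a boundary value falls in the
    slower-looking class (tau = 20 ps -> "10-20 ps").  Pairs slower than the
    last threshold are dropped from the map (they remain in the network).
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise ValueError("thresholds must be non-empty")
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly increasing")

    labels = [f"<{thresholds[0]:g} ps"] + [
        f"{a:g}-{b:g} ps" for a, b in zip(thresholds, thresholds[1:])
    ]
    out: dict[tuple[str, str], str] = {}
    for key, edge in net.edges.items():
        tau = edge.tau
        if tau <= thresholds[0]:
            out[key] = labels[0]
        else:
            for idx, (a, b) in enumerate(zip(thresholds, thresholds[1:])):
                if a < tau <= b:
                    out[key] = labels[idx + 1]
                    break
            # tau beyond the last threshold: omitted
    return out
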