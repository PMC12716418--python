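"""Generalized Forster theory: exciton clusters and cluster-to-cluster rates.

Each subunit's chlorophylls form one exciton cluster.  The cluster Hamiltonian
carries site energies on the diagonal and intra-cluster dipole couplings off
the diagonal (cm^-1); its eigenstates are the donor/acceptor exciton states.
Transfer between two clusters assumes fast thermal equilibration among donor
states (Boltzmann weights at temperature T) and sums Forster-type rates over
exciton-state pairs:

    k(D->A) = sum_a P_a sum_b 1.18 |V_ab|^2 J_ab,
    V_ab    = sum_i sum_j c^D_ai c^A_bj V_ij,

with J_ab the Gaussian overlap of donor-state emission (center e_a - Stokes
shift) and acceptor-state absorption (center e_b).  Exciton-state lineshapes
reuse the site Gaussian width.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .forster import RATE_PREFACTOR_PS, RateParams, _coupling
from .pigment_model import FWHM_TO_SIGMA, qy_dipole, site_energy
from .structure_io import StructureModel

__all__ = [
    "BOLTZMANN_CM1_PER_K",
    "ExcitonCluster",
    "ClusterRateTable",
    "cluster_hamiltonian",
    "diagonalize",
    "gf_rate",
    "inter_cluster_couplings",
    "cluster_network",
]

#: Boltzmann constant in cm^-1 / K.
BOLTZMANN_CM1_PER_K = 0.695034800


@dataclass
class ExcitonCluster:
    """Pigment cluster of one subunit with its exciton-state bookkeeping.

    ``coeffs[a, i]`` is the coefficient of site i in exciton state a
    (rows are eigenvectors, energies ascending once diagonalized).
    """

    subunit_id: str
    pigment_ids: list[str]
    hamiltonian: np.ndarray
    energies: np.ndarray | None = None
    coeffs: np.ndarray | None = None
    weights: np.ndarray | None = None
    temperature: float | None = None

    def __post_init__(self) -> None:
        h = np.asarray(self.hamiltonian, dtype=float)
        if h.ndim != 2 or h.shape[0] != h.shape[1]:
            raise ValueError("Hamiltonian must be square")
        if not np.allclose(h, h.T, atol=1e-9):
            raise ValueError("Hamiltonian must be symmetric")
        self.hamiltonian = h

    @property
    def n(self) -> int:
        return self.hamiltonian.shape[0]

    @property
    def is_diagonalized(self) -> bool:
        return self.energies is not None


@dataclass
class ClusterRateTable:
    """Directed subunit-to-subunit generalized-Forster rates."""

    rates: dict[tuple[str, str], float]          # ps^-1
    dominant_pairs: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, k in self.rates.items():
            if k < 0:
                raise ValueError(f"negative rate for {key}")

    def tau(self, donor: str, acceptor: str) -> float:
        k = self.rates[(donor, acceptor)]
        return 1.0 / k if k > 0 else np.inf

    def states(self) -> list[str]:
        seen: dict[str, None] = {}
        for d, a in self.rates:
            seen.setdefault(d)
            seen.setdefault(a)
        return list(seen)

    def reported(self, cutoff_ps: float = 25.0) -> "ClusterRateTable":
        """The display subset: entries with tau <= cutoff (slower omitted)."""
        keep = {k: v for k, v in self.rates.items() if v > 0 and 1.0 / v <= cutoff_ps}
        return ClusterRateTable(
            rates=keep,
            dominant_pairs={k: v for k, v in self.dominant_pairs.items() if k in keep},
            metadata={**self.metadata, "report_cutoff_ps": cutoff_ps},
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (d, a), k in sorted(self.rates.items()):
            rows.append(
                {
                    "donor": d,
                    "acceptor": a,
                    "rate_per_ps": k,
                    "tau_ps": 1.0 / k if k > 0 else np.inf,
                    "top_state_pair": str(self.dominant_pairs.get((d, a), "")),
                }
            )
        return pd.DataFrame(rows)


def cluster_hamiltonian(
    model: StructureModel,
    subunit_id: str,
    params: RateParams | None = None,
    pigment_ids: list[str] | None = None,
) -> ExcitonCluster:
    """Assemble the exciton Hamiltonian of one subunit's chlorophylls.

    ``pigment_ids`` lets the caller pool several subunits (e.g. the whole PSI
    core) into one cluster.
    """
    params = params or RateParams()
    if pigment_ids is None:
        pigs = [p for p in model.pigments_of(subunit_id) if p.is_eet_node]
    else:
        by_id = {p.pigment_id: p for p in model.pigments}
        pigs = [by_id[pid] for pid in pigment_ids]
    if not pigs:
        raise ValueError(f"subunit {subunit_id} has no chlorophyll EET nodes")

    dipoles = [qy_dipole(p, params.dipole_strengths) for p in pigs]
    h = np.zeros((len(pigs), len(pigs)))
    for i, p in enumerate(pigs):
        h[i, i] = site_energy(p, params.site_energies)
        for j in range(i + 1, len(pigs)):
            v = _coupling(dipoles[i], dipoles[j], params)
            h[i, j] = h[j, i] = v
    return ExcitonCluster(
        subunit_id=subunit_id,
        pigment_ids=[p.pigment_id for p in pigs],
        hamiltonian=h,
    )


def diagonalize(cluster: ExcitonCluster, temperature: float = 295.0) -> ExcitonCluster:
    """Eigen-decompose the cluster Hamiltonian and attach Boltzmann weights.

    Energies ascend; weights are exp(-(e_a - e_min)/kT) normalized (the shift
    by the minimum is exact and avoids underflow).
    """
    energies, vecs = eigh(cluster.hamiltonian)
    coeffs = vecs.T  # row a = state a
    if np.isinf(temperature):
        weights = np.full(len(energies), 1.0 / len(energies))
    else:
        if temperature <= 0:
            raise ValueError("temperature must be positive")
        beta = 1.0 / (BOLTZMANN_CM1_PER_K * temperature)
        w = np.exp(-beta * (energies - energies.min()))
        weights = w / w.sum()
    return ExcitonCluster(
        subunit_id=cluster.subunit_id,
        pigment_ids=list(cluster.pigment_ids),
        hamiltonian=cluster.hamiltonian,
        energies=energies,
        coeffs=coeffs,
        weights=weights,
        temperature=temperature,
    )


def inter_cluster_couplings(
    model: StructureModel,
    donor: ExcitonCluster,
    acceptor: ExcitonCluster,
    params: RateParams | None = None,
) -> np.ndarray:
    """Site-basis coupling matrix V_ij between two clusters (cm^-1)."""
    params = params or RateParams()
    by_id = {p.pigment_id: p for p in model.pigments}
    d_dip = [qy_dipole(by_id[pid], params.dipole_strengths) for pid in donor.pigment_ids]
    a_dip = [qy_dipole(by_id[pid], params.dipole_strengths) for pid in acceptor.pigment_ids]
    v = np.zeros((len(d_dip), len(a_dip)))
    for i, di in enumerate(d_dip):
        for j, aj in enumerate(a_dip):
            v[i, j] = _coupling(di, aj, params)
    return v


def gf_rate(
    donor: ExcitonCluster,
    acceptor: ExcitonCluster,
    couplings: np.ndarray,
    fwhm: float,
    stokes_shift: float,
    return_dominant: bool = False,
):
    """Generalized-Forster rate from a donor to an acceptor cluster (ps^-1).

    ``couplings`` is the site-basis inter-cluster matrix (n_donor x n_acceptor).
    Reduces exactly to the pairwise Forster rate when both clusters hold a
    single pigment.
    """
    if set(donor.pigment_ids) & set(acceptor.pigment_ids):
        raise ValueError("donor and acceptor clusters share pigments")
    if not (donor.is_diagonalized and acceptor.is_diagonalized):
        raise ValueError("clusters must be diagonalized first")
    couplings = np.asarray(couplings, dtype=float)
    if couplings.shape != (donor.n, acceptor.n):
        raise ValueError("coupling matrix shape mismatch")

    v_states = donor.coeffs @ couplings @ acceptor.coeffs.T  # (a, b)
    # Gaussian-Gaussian overlap of donor emission (e_a - Stokes) vs acceptor
    # absorption (e_b), vectorized over all state pairs.
    s = fwhm * FWHM_TO_SIGMA
    var = 2.0 * s * s
    delta = (donor.energies[:, None] - stokes_shift) - acceptor.energies[None, :]
    j_states = np.exp(-0.5 * delta**2 / var) / np.sqrt(2 * np.pi * var)

    contrib = donor.weights[:, None] * RATE_PREFACTOR_PS * v_states**2 * j_states
    rate = float(contrib.sum())
    if return_dominant:
        a, b = np.unravel_index(np.argmax(contrib), contrib.shape)
        return rate, (int(a), int(b))
    return rate


def cluster_network(
    model: StructureModel,
    params: RateParams | None = None,
    core_as_single_cluster: bool = True,
    min_coupling: float = 1e-8,
) -> ClusterRateTable:
    """Directed generalized-Forster rates between all subunit clusters.

    Antenna subunits (and the linker) are one cluster each; the PSI core's
    chlorophylls form a single acceptor supercluster named ``"core"`` unless
    ``core_as_single_cluster`` is False.  The full table is returned; use
    :meth:`ClusterRateTable.reported` for the 25-ps display subset.
    """
    params = params or RateParams()
    clusters: dict[str, ExcitonCluster] = {}

    core_sub = [s for s in model.subunits if s.family == "core"]
    other_sub = [s for s in model.subunits if s.family != "core"]
    if core_as_single_cluster and core_sub:
        core_pids = [
            p.pigment_id
            for s in core_sub
            for p in model.pigments_of(s.subunit_id)
            if p.is_eet_node
        ]
        if core_pids:
            clusters["core"] = cluster_hamiltonian(
                model, "core", params, pigment_ids=core_pids
            )
    else:
        other_sub = list(model.subunits)

    for s in other_sub:
        if any(p.is_eet_node for p in model.pigments_of(s.subunit_id)):
            clusters[s.name] = cluster_hamiltonian(model, s.subunit_id, params)

    clusters = {k: diagonalize(c, params.temperature) for k, c in clusters.items()}

    names = sorted(clusters)
    rates: dict[tuple[str, str], float] = {}
    dominant: dict[tuple[str, str], tuple[int, int]] = {}
    for i, di in enumerate(names):
        for aj in names[i + 1:]:
            cd, ca = clusters[di], clusters[aj]
            v = inter_cluster_couplings(model, cd, ca, params)
            if np.abs(v).max() < min_coupling:
                continue
            k_fwd, dom_f = gf_rate(
                cd, ca, v, params.fwhm, params.stokes_shift, return_dominant=True
            )
            k_bwd, dom_b = gf_rate(
                ca, cd, v.T, params.fwhm, params.stokes_shift, return_dominant=True
            )
            rates[(di, aj)] = k_fwd
            rates[(aj, di)] = k_bwd
            dominant[(di, aj)] = dom_f
            dominant[(aj, di)] = dom_b

    return ClusterRateTable(
        rates=rates, dominant_pairs=dominant, metadata=params.metadata()
    )
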