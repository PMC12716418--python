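"""Exciton clusters and generalized-Forster cluster-to-cluster rates."""

import numpy as np
import pytest

from eetscape.forster import RATE_PREFACTOR_PS, RateParams, dipole_coupling, pairwise_rates
from eetscape.gforster import (
    BOLTZMANN_CM1_PER_K,
    ExcitonCluster,
    cluster_hamiltonian,
    cluster_network,
    diagonalize,
    gf_rate,
    inter_cluster_couplings,
)
from eetscape.pigment_model import gaussian_overlap, qy_dipole, site_energy
from eetscape.structure_io import Species, StructureModel, SubunitRecord
from eetscape.synthetic import AntennaLatticeSpec, make_dimer, make_layered_antenna

from conftest import chl, model_of

FWHM = 250.0
STOKES = 100.0


def test_single_pigment_cluster_hamiltonian():
    model = model_of([chl("X:CLA:1", [0, 0, 0], [0, 0, 1])])
    c = cluster_hamiltonian(model, "X")
    e = site_energy(model.pigments[0], RateParams().site_energies)
    np.testing.assert_allclose(c.hamiltonian, [[e]])


def test_dimer_hamiltonian_off_diagonal_is_coupling():
    pigs = [
        chl("X:CLA:1", [0, 0, 0], [0, 0, 1]),
        chl("X:CLA:2", [10, 0, 0], [0, 0, 1]),
    ]
    model = model_of(pigs)
    c = cluster_hamiltonian(model, "X")
    v = dipole_coupling(qy_dipole(pigs[0]), qy_dipole(pigs[1]))
    assert c.hamiltonian[0, 1] == pytest.approx(v, rel=1e-12)
    assert c.hamiltonian[1, 0] == pytest.approx(v, rel=1e-12)
    assert c.hamiltonian[0, 0] == c.hamiltonian[1, 1]


def test_trimer_hamiltonian_element_wise_oracle():
    pigs = [
        chl("X:CLA:1", [0, 0, 0], [0, 0, 1]),
        chl("X:CLA:2", [11, 0, 0], [0, 1, 0]),
        chl("X:KC2:3", [0, 12, 3], [1, 0, 0], Species.CHL_C),
    ]
    model = model_of(pigs)
    c = cluster_hamiltonian(model, "X")
    params = RateParams()
    for i in range(3):
        assert c.hamiltonian[i, i] == pytest.approx(
            site_energy(pigs[i], params.site_energies)
        )
        for j in range(i + 1, 3):
            v = dipole_coupling(qy_dipole(pigs[i]), qy_dipole(pigs[j]))
            assert c.hamiltonian[i, j] == pytest.approx(v, rel=1e-12)


def test_cluster_without_chlorophylls_errors():
    model = StructureModel(
        subunits=[SubunitRecord("X", "X", family="Lhcq", layer=1)], pigments=[]
    )
    with pytest.raises(ValueError, match="no chlorophyll"):
        cluster_hamiltonian(model, "X")


def test_degenerate_dimer_splitting():
    e0, v = 15000.0, 80.0
    c = ExcitonCluster("X", ["a", "b"], np.array([[e0, v], [v, e0]]))
    d = diagonalize(c, 295.0)
    np.testing.assert_allclose(d.energies, [e0 - abs(v), e0 + abs(v)])
    assert np.sum(d.energies) == pytest.approx(np.trace(c.hamiltonian))
    np.testing.assert_allclose(d.coeffs @ d.coeffs.T, np.eye(2), atol=1e-12)


def test_infinite_temperature_uniform_weights():
    h = np.diag([15000.0, 15200.0, 15400.0])
    h[0, 1] = h[1, 0] = 30.0
    d = diagonalize(ExcitonCluster("X", list("abc"), h), np.inf)
    np.testing.assert_allclose(d.weights, np.full(3, 1 / 3))


def test_boltzmann_weights_normalized_and_ordered():
    h = np.diag([15000.0, 15500.0])
    d = diagonalize(ExcitonCluster("X", list("ab"), h), 295.0)
    assert d.weights.sum() == pytest.approx(1.0)
    beta = 1.0 / (BOLTZMANN_CM1_PER_K * 295.0)
    expected = np.exp(-beta * 500.0)
    assert d.weights[1] / d.weights[0] == pytest.approx(expected, rel=1e-10)


def test_nonsymmetric_hamiltonian_rejected():
    with pytest.raises(ValueError, match="symmetric"):
        ExcitonCluster("X", list("ab"), np.array([[1.0, 2.0], [3.0, 1.0]]))


def test_gf_rate_reduces_to_pairwise_forster():
    """Single-pigment clusters give exactly the pairwise Forster rate."""
    model = make_dimer(10.0)
    params = RateParams()
    net = pairwise_rates(model, params)
    d = diagonalize(cluster_hamiltonian(model, "D", params), params.temperature)
    a = diagonalize(cluster_hamiltonian(model, "A", params), params.temperature)
    v = inter_cluster_couplings(model, d, a, params)
    k = gf_rate(d, a, v, params.fwhm, params.stokes_shift)
    donor_id = d.pigment_ids[0]
    acceptor_id = a.pigment_ids[0]
    # exact reduction (same overlap kernel; tolerance covers multiply ordering)
    assert k == pytest.approx(net.rate(donor_id, acceptor_id), rel=1e-14)


def test_gf_rate_zero_for_orthogonal_coupling_pattern():
    """If every populated donor state has zero effective coupling, rate is 0."""
    d = diagonalize(ExcitonCluster("D", ["p1"], np.array([[15000.0]])), 295.0)
    a = diagonalize(
        ExcitonCluster("A", ["q1", "q2"], np.diag([15000.0, 15000.0])), 295.0
    )
    k = gf_rate(d, a, np.zeros((1, 2)), FWHM, STOKES)
    assert k == 0.0


def test_gf_rate_brute_force_double_sum():
    """2x2 donor / 2x2 acceptor equals an independently coded state-pair sum."""
    hd = np.array([[15000.0, 50.0], [50.0, 15200.0]])
    ha = np.array([[15700.0, -30.0], [-30.0, 15850.0]])
    v_site = np.array([[8.0, -3.0], [2.0, 5.0]])
    temp = 295.0
    d = diagonalize(ExcitonCluster("D", ["d1", "d2"], hd), temp)
    a = diagonalize(ExcitonCluster("A", ["a1", "a2"], ha), temp)
    k = gf_rate(d, a, v_site, FWHM, STOKES)

    # independent brute force from eigendecompositions computed here
    ed, cd = np.linalg.eigh(hd)
    ea, ca = np.linalg.eigh(ha)
    beta = 1.0 / (BOLTZMANN_CM1_PER_K * temp)
    w = np.exp(-beta * (ed - ed.min()))
    w /= w.sum()
    total = 0.0
    for alpha in range(2):
        for betaidx in range(2):
            v_ab = 0.0
            for i in range(2):
                for j in range(2):
                    v_ab += cd[i, alpha] * ca[j, betaidx] * v_site[i, j]
            j_ab = gaussian_overlap(ed[alpha] - STOKES, FWHM, ea[betaidx], FWHM)
            total += w[alpha] * RATE_PREFACTOR_PS * v_ab**2 * j_ab
    assert k == pytest.approx(total, rel=1e-12)


def test_gf_rate_gauge_invariance_under_sign_flips():
    hd = np.array([[15000.0, 50.0], [50.0, 15200.0]])
    ha = np.array([[15700.0, -30.0], [-30.0, 15850.0]])
    v_site = np.array([[8.0, -3.0], [2.0, 5.0]])
    d = diagonalize(ExcitonCluster("D", ["d1", "d2"], hd), 295.0)
    a = diagonalize(ExcitonCluster("A", ["a1", "a2"], ha), 295.0)
    k0 = gf_rate(d, a, v_site, FWHM, STOKES)
    for flips in ([1, -1], [-1, 1], [-1, -1]):
        d2 = ExcitonCluster(
            "D", ["d1", "d2"], hd, d.energies, np.diag(flips) @ d.coeffs,
            d.weights, d.temperature,
        )
        assert gf_rate(d2, a, v_site, FWHM, STOKES) == pytest.approx(k0, rel=1e-12)


def test_gf_rate_rejects_shared_pigments():
    d = diagonalize(ExcitonCluster("D", ["p"], np.array([[15000.0]])), 295.0)
    with pytest.raises(ValueError, match="share"):
        gf_rate(d, d, np.zeros((1, 1)), FWHM, STOKES)


def test_uncoupled_cluster_equals_weighted_pairwise_sum():
    """With zero intra-cluster couplings the generalized rate is the Boltzmann
    average over donor pigments of their summed pairwise rates."""
    ed = np.array([15000.0, 15300.0])
    ea = np.array([15100.0, 15050.0])
    v_site = np.array([[4.0, 1.5], [-2.0, 3.0]])
    d = diagonalize(ExcitonCluster("D", ["d1", "d2"], np.diag(ed)), 295.0)
    a = diagonalize(ExcitonCluster("A", ["a1", "a2"], np.diag(ea)), 295.0)
    k = gf_rate(d, a, v_site, FWHM, STOKES)

    beta = 1.0 / (BOLTZMANN_CM1_PER_K * 295.0)
    w = np.exp(-beta * (ed - ed.min()))
    w /= w.sum()
    expected = 0.0
    for i in range(2):
        for j in range(2):
            expected += (
                w[i]
                * RATE_PREFACTOR_PS
                * v_site[i, j] ** 2
                * gaussian_overlap(ed[i] - STOKES, FWHM, ea[j], FWHM)
            )
    assert k == pytest.approx(expected, rel=1e-12)


def test_rate_moves_toward_unweighted_average_with_temperature():
    hd = np.array([[15000.0, 60.0], [60.0, 15400.0]])
    ha = np.array([[15100.0, 0.0], [0.0, 15200.0]])
    v_site = np.array([[5.0, 0.0], [0.0, 5.0]])
    a = diagonalize(ExcitonCluster("A", ["a1", "a2"], ha), 295.0)

    def rate_at(temp):
        d = diagonalize(ExcitonCluster("D", ["d1", "d2"], hd), temp)
        return gf_rate(d, a, v_site, FWHM, STOKES)

    k_inf = rate_at(np.inf)
    temps = [100.0, 300.0, 1000.0, 10000.0, 1e6, 1e8]
    gaps = [abs(rate_at(t) - k_inf) for t in temps]
    assert all(g1 >= g2 - 1e-15 for g1, g2 in zip(gaps, gaps[1:]))
    assert gaps[-1] < 1e-5 * k_inf


def test_cluster_network_two_subunit_lattice():
    model = make_layered_antenna(
        AntennaLatticeSpec(n_layers=1, n_fibers=1, pigments_per_subunit=2,
                           core_pigments=2, seed=3)
    )
    params = RateParams()
    table = cluster_network(model, params)
    assert set(table.rates) == {("L1F0", "core"), ("core", "L1F0")}
    core_ids = [p.pigment_id for p in model.pigments_of("core")]
    d = diagonalize(cluster_hamiltonian(model, "L1F0", params), params.temperature)
    c = diagonalize(
        cluster_hamiltonian(model, "core", params, pigment_ids=core_ids),
        params.temperature,
    )
    v = inter_cluster_couplings(model, d, c, params)
    assert table.rates[("L1F0", "core")] == pytest.approx(
        gf_rate(d, c, v, params.fwhm, params.stokes_shift), rel=1e-12
    )


def test_cluster_network_report_cutoff_and_retention():
    from eetscape.gforster import ClusterRateTable

    table = ClusterRateTable(rates={("a", "b"): 1 / 30.0, ("b", "a"): 1 / 10.0})
    shown = table.reported(cutoff_ps=25.0)
    assert ("b", "a") in shown.rates
    assert ("a", "b") not in shown.rates      # tau = 30 ps: omitted from display
    assert ("a", "b") in table.rates          # but retained in the full table


def test_cluster_network_label_invariance(small_lattice):
    import copy

    renamed = copy.deepcopy(small_lattice)
    mapping = {}
    for s in renamed.subunits:
        if s.family != "core":
            mapping[s.name] = "Z" + s.name
            s.name = "Z" + s.name
    t0 = cluster_network(small_lattice)
    t1 = cluster_network(renamed)
    assert len(t0.rates) == len(t1.rates)
    for (d, a), k in t0.rates.items():
        key = (mapping.get(d, d), mapping.get(a, a))
        assert t1.rates[key] == pytest.approx(k, rel=1e-12)
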