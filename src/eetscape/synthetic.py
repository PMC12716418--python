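"""Synthetic inputs: pigment dimers, layered fiber-like antenna lattices, a
census-matched inventory fixture, and TA cubes with known decay components.

These generators produce the study conditions for the test suite and the
analysis drivers: geometry fixtures with closed-form expected couplings,
a six-layer antenna whose subunits are arranged in radial fibers around a
core cluster (emulating the layered supercomplex architecture), a placeholder
structure whose pigment census matches the published inventory statistics,
and multi-exponential transient-absorption cubes with Gaussian IRF and
additive noise.  All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .das import TACube, exp_conv_irf
from .forster import DIPOLE_COUPLING_CONST
from .pigment_model import DEFAULT_DIPOLE_STRENGTHS
from .structure_io import (
    CORE_SUBUNITS,
    DEFAULT_FAMILY_MAP,
    DEFAULT_LAYER_MAP,
    PigmentRecord,
    Species,
    StructureModel,
    SubunitRecord,
)

__all__ = [
    "AntennaLatticeSpec",
    "TASimSpec",
    "DASComponent",
    "make_dimer",
    "make_layered_antenna",
    "make_inventory_fixture",
    "make_ta_cube",
    "write_mmcif",
    "write_pdb",
]

#: Distance between the two Qy-axis nitrogens in generated chlorophylls (A).
NN_DISTANCE = 4.0

_SPECIES_TO_HET = {
    Species.CHL_A: "CLA",
    Species.CHL_C: "KC2",
    Species.CHL_C2_MGDG: "KCM",
    Species.FUCOXANTHIN: "FXA",
    Species.HEX_FUCOXANTHIN: "HFX",
    Species.DIADINOXANTHIN: "DD6",
    Species.GYROXANTHIN_DIESTER: "GYR",
    Species.BETA_CAROTENE: "BCR",
}


def _chl_record(
    pigment_id: str,
    species: Species,
    subunit: str,
    mg: np.ndarray,
    direction: np.ndarray,
) -> PigmentRecord:
    direction = np.asarray(direction, dtype=float)
    direction = direction / np.linalg.norm(direction)
    half = 0.5 * NN_DISTANCE * direction
    return PigmentRecord(
        pigment_id=pigment_id,
        species=species,
        host_subunit=subunit,
        key_atoms={"MG": np.asarray(mg, float), "NB": mg - half, "ND": mg + half},
        is_eet_node=True,
        het_code=_SPECIES_TO_HET[species],
    )


def make_dimer(
    r: float,
    geometry: str = "parallel_perp_R",
    species: tuple[Species, Species] = (Species.CHL_A, Species.CHL_A),
    contact_floor: float = 2.0,
) -> StructureModel:
    """Two-chlorophyll fixture with an exactly known orientation factor.

    Geometries: ``parallel_perp_R`` (both dipoles perpendicular to the
    separation vector, |kappa| = 1), ``head_to_tail`` (collinear, |kappa| = 2),
    ``perpendicular`` (mutually orthogonal, kappa = 0).  The expected |kappa|
    and signed point-dipole coupling (at the default dipole strengths) are
    attached in the model provenance.
    """
    if r <= contact_floor:
        raise ValueError(f"separation {r} A must exceed the contact floor")
    z = np.array([0.0, 0.0, 1.0])
    x = np.array([1.0, 0.0, 0.0])
    y = np.array([0.0, 1.0, 0.0])
    if geometry == "parallel_perp_R":
        d1, d2, kappa = z, z, 1.0
    elif geometry == "head_to_tail":
        d1, d2, kappa = x, x, -2.0
    elif geometry == "perpendicular":
        d1, d2, kappa = z, y, 0.0
    else:
        raise ValueError(f"unknown dimer geometry {geometry!r}")

    mu1 = DEFAULT_DIPOLE_STRENGTHS[species[0]]
    mu2 = DEFAULT_DIPOLE_STRENGTHS[species[1]]
    expected_v = DIPOLE_COUPLING_CONST * kappa * mu1 * mu2 / r**3
    subunits = [SubunitRecord("D", "donor-sub", family="Lhcq", layer=1),
                SubunitRecord("A", "acceptor-sub", family="Lhcq", layer=1)]
    pigments = [
        _chl_record(f"D:{_SPECIES_TO_HET[species[0]]}:1", species[0], "D",
                    np.zeros(3), d1),
        _chl_record(f"A:{_SPECIES_TO_HET[species[1]]}:1", species[1], "A",
                    x * r, d2),
    ]
    return StructureModel(
        subunits=subunits,
        pigments=pigments,
        provenance={
            "generator": "make_dimer",
            "geometry": geometry,
            "kappa": abs(kappa),
            "kappa_signed": kappa,
            "expected_coupling_cm1": expected_v,
            "r_angstrom": r,
        },
    )


@dataclass
class AntennaLatticeSpec:
    """Layered, fiber-like antenna geometry around a central core cluster.

    Subunits sit on radial fibers: fiber f of layer l is at radius
    ``core_radius + l * layer_spacing`` and azimuth ``2 pi f / n_fibers``.
    Each subunit carries a small square patch of chlorophylls spaced
    ``intra_spacing`` apart, split chl_a/chl_c by ``chl_c_fraction``.
    """

    n_layers: int = 6
    subunits_per_layer: list[int] | None = None   # default: n_fibers everywhere
    n_fibers: int = 3
    pigments_per_subunit: int = 4
    chl_c_fraction: float = 0.25
    intra_spacing: float = 10.0
    layer_spacing: float = 25.0
    core_radius: float = 20.0
    core_pigments: int = 8
    orientation_noise_deg: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subunits_per_layer is None:
            self.subunits_per_layer = [self.n_fibers] * self.n_layers
        if len(self.subunits_per_layer) != self.n_layers:
            raise ValueError("subunits_per_layer length must equal n_layers")
        if any(s > self.n_fibers for s in self.subunits_per_layer):
            raise ValueError("subunits_per_layer entries cannot exceed n_fibers")
        if min(self.intra_spacing, self.layer_spacing, self.core_radius) <= 2.0:
            raise ValueError("spacings must exceed the 2 A contact floor")


def _rotate_noise(rng: np.random.Generator, v: np.ndarray, degrees: float) -> np.ndarray:
    if degrees == 0:
        return v
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(scale=degrees))
    # Rodrigues rotation
    return (
        v * np.cos(angle)
        + np.cross(axis, v) * np.sin(angle)
        + axis * (axis @ v) * (1 - np.cos(angle))
    )


def make_layered_antenna(spec: AntennaLatticeSpec) -> StructureModel:
    """Deterministic layered-fiber antenna model (same seed, same coordinates).

    The core subunit ("core") is a ring of chl_a at ``core_radius``; antenna
    subunit ``L{l}F{f}`` sits on fiber f in layer l.  Pigment dipoles point
    along z with optional Gaussian orientation noise.
    """
    rng = np.random.default_rng(spec.seed)
    z = np.array([0.0, 0.0, 1.0])
    subunits = [SubunitRecord("core", "core", family="core", layer=0)]
    pigments: list[PigmentRecord] = []

    for i in range(spec.core_pigments):
        theta = 2 * np.pi * i / spec.core_pigments
        pos = spec.core_radius * np.array([np.cos(theta), np.sin(theta), 0.0])
        pigments.append(
            _chl_record(
                f"core:CLA:{i + 1}", Species.CHL_A, "core", pos,
                _rotate_noise(rng, z, spec.orientation_noise_deg),
            )
        )

    side = int(np.ceil(np.sqrt(spec.pigments_per_subunit)))
    for layer in range(1, spec.n_layers + 1):
        radius = spec.core_radius + layer * spec.layer_spacing
        for fiber in range(spec.subunits_per_layer[layer - 1]):
            theta = 2 * np.pi * fiber / spec.n_fibers
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            tangent = np.array([-np.sin(theta), np.cos(theta), 0.0])
            sid = f"L{layer}F{fiber}"
            subunits.append(SubunitRecord(sid, sid, family="Lhcq", layer=layer))
            n_c = int(round(spec.chl_c_fraction * spec.pigments_per_subunit))
            for p in range(spec.pigments_per_subunit):
                row, col = divmod(p, side)
                offset = (
                    radial * (row - (side - 1) / 2) * spec.intra_spacing
                    + tangent * (col - (side - 1) / 2) * spec.intra_spacing
                )
                sp = Species.CHL_C if p < n_c else Species.CHL_A
                pigments.append(
                    _chl_record(
                        f"{sid}:{_SPECIES_TO_HET[sp]}:{p + 1}", sp, sid,
                        radius * radial + offset,
                        _rotate_noise(rng, z, spec.orientation_noise_deg),
                    )
                )
    return StructureModel(
        subunits=subunits,
        pigments=pigments,
        provenance={"generator": "make_layered_antenna", "spec": spec.__dict__.copy()},
    )


# --- census-matched inventory fixture --------------------------------------

# Antenna census the fixture enforces: 291 chl_a, 121 Chl c chromophores (9 of
# them as the Chl c2-MGDG adduct, hosted on non-Lhcq/Lhcf subunits so that
# 112/121 = 92.6% of Chl c sits in Lhcq/Lhcf subunits with 4-7 each), and 224
# carotenoids.  Core + linker carry 96 chl_a (387 total) and 23 carotenoids.
_ANTENNA_CHL_A_TOTAL = 291
_ANTENNA_CHL_C_TOTAL = 121
_ANTENNA_CAR_TOTAL = 224


def _antenna_counts() -> dict[str, dict[Species, int]]:
    names = [f"EFCPI-{i}" for i in range(1, 36)]
    qf = [n for n in names if DEFAULT_FAMILY_MAP[n] in ("Lhcq", "Lhcf")]  # 24
    other = [n for n in names if n not in qf]                              # 11
    counts: dict[str, dict[Species, int]] = {n: {} for n in names}

    # chl_a: 291 = 11 x 9 + 24 x 8
    for i, n in enumerate(names):
        counts[n][Species.CHL_A] = 9 if i < 11 else 8
    # plain chl_c: 112 over the 24 Lhcq/Lhcf subunits, each 4-7
    per = [5] * 16 + [4] * 8
    assert sum(per) == 112 and len(per) == len(qf)
    for n, c in zip(qf, per):
        counts[n][Species.CHL_C] = c
    # chl c2-MGDG adducts: 9 singles on non-Lhcq/Lhcf antenna subunits
    for n in other[:9]:
        counts[n][Species.CHL_C2_MGDG] = 1
    # carotenoids: 224 = 14 x 7 + 21 x 6; species split Fx 109 / hFx 42 /
    # Ddx 70 / GyrE 3 assigned greedily in that order
    car_per = [7] * 14 + [6] * 21
    pool = (
        [Species.FUCOXANTHIN] * 109
        + [Species.HEX_FUCOXANTHIN] * 42
        + [Species.DIADINOXANTHIN] * 70
        + [Species.GYROXANTHIN_DIESTER] * 3
    )
    it = iter(pool)
    for n, c in zip(names, car_per):
        for _ in range(c):
            sp = next(it)
            counts[n][sp] = counts[n].get(sp, 0) + 1
    return counts


def make_inventory_fixture(spacing: float = 12.0) -> StructureModel:
    """Placeholder-geometry structure whose pigment census matches the
    published inventory statistics.

    48 subunits (12 core, 35 antenna, 1 linker); antenna totals 291 chl_a /
    121 Chl c / 224 carotenoids, Chl c concentrated in Lhcq/Lhcf subunits
    (4-7 each).  Coordinates are a coarse grid — this fixture supports
    inventory statistics, not geometry-dependent analyses.
    """
    subunits: list[SubunitRecord] = []
    pigments: list[PigmentRecord] = []
    z = np.array([0.0, 0.0, 1.0])

    def add_subunit(name: str, counts: dict[Species, int], origin: np.ndarray) -> None:
        family = DEFAULT_FAMILY_MAP[name]
        layer = 0 if family == "core" else (1 if family == "linker"
                                            else DEFAULT_LAYER_MAP[name])
        subunits.append(SubunitRecord(name, name, family=family, layer=layer))
        i = 0
        for sp, n in counts.items():
            for _ in range(n):
                pos = origin + spacing * np.array([i % 6, i // 6, 0.0])
                i += 1
                if sp in (Species.CHL_A, Species.CHL_C, Species.CHL_C2_MGDG):
                    pigments.append(
                        _chl_record(f"{name}:{_SPECIES_TO_HET[sp]}:{i}", sp, name, pos, z)
                    )
                else:
                    pigments.append(
                        PigmentRecord(
                            pigment_id=f"{name}:{_SPECIES_TO_HET[sp]}:{i}",
                            species=sp,
                            host_subunit=name,
                            key_atoms={
                                "C1": pos,
                                "C2": pos + np.array([1.5, 0, 0]),
                                "C3": pos + np.array([3.0, 0, 0]),
                            },
                            is_eet_node=False,
                            het_code=_SPECIES_TO_HET[sp],
                        )
                    )

    # core: 95 chl_a + 23 carotenoids (20 beta-Car, 3 Ddx) over 12 subunits
    core_chl = [13, 13, 3, 2, 2, 6, 4, 4, 8, 14, 13, 13]
    core_car = [4, 4, 0, 0, 0, 2, 1, 1, 2, 3, 3, 3]
    assert sum(core_chl) == 95 and sum(core_car) == 23
    bcar_left = 20
    for k, name in enumerate(CORE_SUBUNITS):
        counts: dict[Species, int] = {Species.CHL_A: core_chl[k]}
        n_b = min(core_car[k], bcar_left)
        bcar_left -= n_b
        if n_b:
            counts[Species.BETA_CAROTENE] = n_b
        if core_car[k] - n_b:
            counts[Species.DIADINOXANTHIN] = core_car[k] - n_b
        add_subunit(name, counts, np.array([100.0 * k, -200.0, 0.0]))
    add_subunit("L_EFP", {Species.CHL_A: 1}, np.array([0.0, -100.0, 0.0]))

    for k, (name, counts) in enumerate(sorted(_antenna_counts().items(),
                                              key=lambda kv: int(kv[0].split("-")[1]))):
        add_subunit(name, counts, np.array([100.0 * (k % 7), 100.0 * (k // 7), 0.0]))

    model = StructureModel(
        subunits=subunits,
        pigments=pigments,
        provenance={"generator": "make_inventory_fixture"},
    )
    _audit_census(model)
    return model


def _audit_census(model: StructureModel) -> None:
    """Self-audit: the fixture must satisfy every census total it encodes."""
    ant = {s.subunit_id for s in model.antenna_subunits}
    n_a = sum(p.species is Species.CHL_A for p in model.pigments if p.host_subunit in ant)
    n_c = sum(
        p.species in (Species.CHL_C, Species.CHL_C2_MGDG)
        for p in model.pigments
        if p.host_subunit in ant
    )
    from .structure_io import CAROTENOIDS

    n_car = sum(p.species in CAROTENOIDS for p in model.pigments if p.host_subunit in ant)
    assert (n_a, n_c, n_car) == (
        _ANTENNA_CHL_A_TOTAL,
        _ANTENNA_CHL_C_TOTAL,
        _ANTENNA_CAR_TOTAL,
    ), "inventory fixture census broken"
    assert len(model.antenna_subunits) == 35
    assert len(model.subunits) == 48


# --- synthetic TA cubes -----------------------------------------------------


@dataclass
class DASComponent:
    """One decay component: lifetime plus a sum-of-Gaussians spectrum."""

    lifetime: float                      # ps
    peaks: list[tuple[float, float, float]]  # (center nm, fwhm nm, amplitude)

    def spectrum(self, wavelengths: np.ndarray) -> np.ndarray:
        out = np.zeros_like(wavelengths, dtype=float)
        for center, fwhm, amp in self.peaks:
            s = fwhm / (2 * np.sqrt(2 * np.log(2)))
            out += amp * np.exp(-0.5 * ((wavelengths - center) / s) ** 2)
        return out


def default_ta_components() -> list[DASComponent]:
    """Four-component decay model of the antenna-to-core energy flow.

    Sub-ps relaxation/Chl c -> Chl a feeding, a ~2.8 ps inner-antenna -> core
    transfer with opposite-sign lobes, the dominant ~62 ps antenna-to-core
    decay, and a 5 ns blue-shifted long-lived component from uncoupled Chl a.
    """
    return [
        DASComponent(0.16, [(680.0, 14.0, 1.0), (700.0, 16.0, -0.25)]),
        DASComponent(2.8, [(683.0, 13.0, 0.9), (665.0, 12.0, -0.35), (703.0, 14.0, 0.3)]),
        DASComponent(62.0, [(681.0, 15.0, 1.2)]),
        DASComponent(5000.0, [(676.0, 13.0, -0.4)]),
    ]


@dataclass
class TASimSpec:
    """Specification of a synthetic transient-absorption experiment."""

    components: list[DASComponent] = field(default_factory=default_ta_components)
    irf_fwhm: float = 0.07     # ps (70 fs pulses)
    t0: float = 0.0
    noise_sd: float = 0.01     # fraction of the peak |signal|
    wavelengths: np.ndarray = field(
        default_factory=lambda: np.linspace(660.0, 710.0, 64)
    )
    delays: np.ndarray | None = None   # default: linear to 1 ps, log to 3 ns
    seed: int = 0

    def __post_init__(self) -> None:
        if any(c.lifetime <= 0 for c in self.components):
            raise ValueError("component lifetimes must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.delays is None:
            self.delays = np.concatenate(
                [np.linspace(-1.0, 1.0, 24, endpoint=False), np.geomspace(1.0, 3000.0, 96)]
            )
        self.delays = np.asarray(self.delays, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)


def make_ta_cube(spec: TASimSpec) -> TACube:
    """Synthesize a TA cube: sum of IRF-convolved exponentials plus noise.

    With ``noise_sd = 0`` the cube equals the analytic model exactly; the same
    seed always regenerates the identical cube.
    """
    rng = np.random.default_rng(spec.seed)
    t, wl = spec.delays, spec.wavelengths
    signal = np.zeros((len(t), len(wl)))
    for comp in spec.components:
        signal += np.outer(
            exp_conv_irf(comp.lifetime, spec.t0, spec.irf_fwhm, t),
            comp.spectrum(wl),
        )
    if spec.noise_sd > 0:
        scale = spec.noise_sd * np.abs(signal).max()
        signal = signal + rng.normal(scale=scale, size=signal.shape)
    return TACube(
        delays=t, wavelengths=wl, signal=signal,
        irf_fwhm=spec.irf_fwhm, t0=spec.t0,
    )


# --- structure writers ------------------------------------------------------


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "eetscape-synthetic"
    md = gemmi.Model("1")
    by_sub: dict[str, list[PigmentRecord]] = {}
    for p in model.pigments:
        by_sub.setdefault(p.host_subunit, []).append(p)
    for sub in model.subunits:
        chain = gemmi.Chain(sub.subunit_id)
        for i, p in enumerate(by_sub.get(sub.subunit_id, []), start=1):
            res = gemmi.Residue()
            res.name = p.het_code or "UNL"
            res.seqid = gemmi.SeqId(i, " ")
            res.het_flag = "H"
            for aname, xyz in p.key_atoms.items():
                atom = gemmi.Atom()
                atom.name = aname
                atom.element = gemmi.Element(
                    "Mg" if aname == "MG" else ("N" if aname.startswith("N") else "C")
                )
                atom.pos = gemmi.Position(*xyz)
                atom.occ = 1.0
                atom.b_iso = 20.0
                res.add_atom(atom)
            chain.add_residue(res)
        md.add_chain(chain)
    st.add_model(md)
    st.setup_entities()
    return st


def write_mmcif(model: StructureModel, path: str | Path) -> None:
    """Write the model as mmCIF (chain names may be multi-character)."""
    st = _to_gemmi(model)
    st.make_mmcif_document().write_file(str(path))


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model as PDB (requires single-character chain ids)."""
    for s in model.subunits:
        if len(s.subunit_id) > 1:
            raise ValueError(
                f"PDB dialect needs 1-character chain ids (got {s.subunit_id!r})"
            )
    _to_gemmi(model).write_pdb(str(path))
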