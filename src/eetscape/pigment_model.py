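"""Transition dipoles, site energies, and spectral lineshapes.

The Qy transition dipole of a chlorophyll is approximated geometrically: it
points along the axis joining the ring-B and ring-D nitrogens of the chlorin
macrocycle and sits on the central Mg.  Site energies are fixed per species
(Chl a 663.5 nm, Chl c 633.5 nm by default) with optional per-pigment
overrides; lineshapes are area-normalized Gaussians in wavenumber.  All
internal energies are wavenumbers (cm^-1); nanometres appear only at the I/O
boundary through ``nm_to_wavenumber``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure_io import PigmentRecord, Species, CHLOROPHYLLS

__all__ = [
    "TransitionDipole",
    "SiteEnergyTable",
    "Lineshape",
    "nm_to_wavenumber",
    "qy_dipole",
    "site_energy",
    "make_lineshapes",
    "spectral_overlap",
    "gaussian_overlap",
    "DEFAULT_DIPOLE_STRENGTHS",
    "DEFAULT_FWHM_CM1",
    "DEFAULT_STOKES_SHIFT_CM1",
    "FWHM_TO_SIGMA",
]

#: FWHM = sigma * 2*sqrt(2*ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

#: Default Qy dipole strengths (Debye).  Literature-typical effective
#: magnitudes for protein-embedded chlorophylls; overridable per species.
DEFAULT_DIPOLE_STRENGTHS: dict[Species, float] = {
    Species.CHL_A: 4.0,
    Species.CHL_C: 3.4,
    Species.CHL_C2_MGDG: 3.4,
}

#: Default Gaussian lineshape width and Stokes shift (cm^-1), chosen for
#: room-temperature-like donor-acceptor overlaps; both configurable.
DEFAULT_FWHM_CM1 = 250.0
DEFAULT_STOKES_SHIFT_CM1 = 100.0

#: Default Qy site-energy wavelengths (nm) per species.
DEFAULT_SITE_WAVELENGTHS_NM: dict[Species, float] = {
    Species.CHL_A: 663.5,
    Species.CHL_C: 633.5,
    Species.CHL_C2_MGDG: 633.5,
}


def nm_to_wavenumber(lam_nm: float) -> float:
    """Vacuum wavelength (nm) to wavenumber (cm^-1): E = 1e7 / lambda."""
    return 1.0e7 / lam_nm


@dataclass
class TransitionDipole:
    """Point transition dipole: origin (Angstrom), unit direction, strength (D)."""

    origin: np.ndarray
    direction: np.ndarray
    magnitude: float

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("dipole direction has zero length")
            self.direction = self.direction / norm
        if self.magnitude <= 0:
            raise ValueError("dipole magnitude must be positive")


@dataclass
class SiteEnergyTable:
    """Species-default site energies (cm^-1) plus per-pigment overrides."""

    defaults: dict[Species, float] = field(
        default_factory=lambda: {
            sp: nm_to_wavenumber(lam)
            for sp, lam in DEFAULT_SITE_WAVELENGTHS_NM.items()
        }
    )
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sp, e in self.defaults.items():
            if e <= 0:
                raise ValueError(f"non-positive site energy for {sp}")

    @classmethod
    def from_wavelengths_nm(
        cls, defaults_nm: dict[Species | str, float], overrides_nm: dict[str, float] | None = None
    ) -> "SiteEnergyTable":
        return cls(
            defaults={Species(sp): nm_to_wavenumber(lam) for sp, lam in defaults_nm.items()},
            overrides={k: nm_to_wavenumber(v) for k, v in (overrides_nm or {}).items()},
        )


@dataclass
class Lineshape:
    """Area-normalized Gaussian lineshape in wavenumber space."""

    center: float
    fwhm: float
    kind: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("lineshape fwhm must be positive")
        if self.kind != "gaussian":
            raise ValueError(f"unsupported lineshape kind {self.kind!r}")

    @property
    def sigma(self) -> float:
        return self.fwhm * FWHM_TO_SIGMA

    def __call__(self, nu: np.ndarray) -> np.ndarray:
        nu = np.asarray(nu, dtype=float)
        s = self.sigma
        return np.exp(-0.5 * ((nu - self.center) / s) ** 2) / (s * np.sqrt(2 * np.pi))


def qy_dipole(
    pigment: PigmentRecord,
    strengths: dict[Species, float] | None = None,
) -> TransitionDipole:
    """Construct the Qy transition dipole of a chlorophyll.

    Direction: normalized NB -> ND nitrogen axis; origin: the central Mg;
    magnitude: per-species strength from ``strengths`` (defaults packaged).
    """
    if pigment.species not in CHLOROPHYLLS:
        raise ValueError(
            f"pigment {pigment.pigment_id} ({pigment.species.value}) is not an EET node"
        )
    for atom in ("MG", "NB", "ND"):
        if atom not in pigment.key_atoms:
            raise ValueError(f"pigment {pigment.pigment_id} missing key atom {atom}")
    table = dict(DEFAULT_DIPOLE_STRENGTHS)
    table.update(strengths or {})
    nb, nd = pigment.key_atoms["NB"], pigment.key_atoms["ND"]
    axis = nd - nb
    norm = np.linalg.norm(axis)
    if norm == 0:
        raise ValueError(f"pigment {pigment.pigment_id}: NB and ND coincide")
    return TransitionDipole(
        origin=pigment.key_atoms["MG"],
        direction=axis / norm,
        magnitude=table[pigment.species],
    )


def site_energy(pigment: PigmentRecord, table: SiteEnergyTable) -> float:
    """Site energy (cm^-1): per-pigment override if present, else species default."""
    if not pigment.is_eet_node:
        raise ValueError(f"pigment {pigment.pigment_id} is not an EET node")
    if pigment.pigment_id in table.overrides:
        return table.overrides[pigment.pigment_id]
    try:
        return table.defaults[pigment.species]
    except KeyError:
        raise KeyError(
            f"no default site energy for species {pigment.species.value}"
        ) from None


def make_lineshapes(
    energy: float,
    fwhm: float = DEFAULT_FWHM_CM1,
    stokes_shift: float = DEFAULT_STOKES_SHIFT_CM1,
) -> tuple[Lineshape, Lineshape]:
    """Absorption and emission Gaussians for a site energy (cm^-1).

    Emission is red-shifted by ``stokes_shift``; both are area-normalized.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if stokes_shift < 0:
        raise ValueError("stokes_shift must be non-negative")
    return Lineshape(center=energy, fwhm=fwhm), Lineshape(center=energy - stokes_shift, fwhm=fwhm)


def spectral_overlap(
    donor_emission: Lineshape,
    acceptor_absorption: Lineshape,
    grid: np.ndarray | None = None,
    n_points: int = 4001,
) -> float:
    """Overlap integral J = int F_D(nu) A_A(nu) dnu (units cm).

    Evaluated by quadrature on a wavenumber grid spanning +-6 sigma of both
    lineshapes; a user-supplied grid must cover that span or an error is
    raised (never silent truncation).
    """
    lo = min(
        donor_emission.center - 6 * donor_emission.sigma,
        acceptor_absorption.center - 6 * acceptor_absorption.sigma,
    )
    hi = max(
        donor_emission.center + 6 * donor_emission.sigma,
        acceptor_absorption.center + 6 * acceptor_absorption.sigma,
    )
    if grid is None:
        grid = np.linspace(lo, hi, n_points)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] > lo or grid[-1] < hi:
            raise ValueError(
                f"overlap grid [{grid[0]}, {grid[-1]}] does not cover the "
                f"required span [{lo:.1f}, {hi:.1f}]"
            )
    return float(np.trapezoid(donor_emission(grid) * acceptor_absorption(grid), grid))


def gaussian_overlap(center1: float, fwhm1: float, center2: float, fwhm2: float) -> float:
    """Closed-form overlap of two area-normalized Gaussians (units cm).

    J = exp(-d^2 / (2 (s1^2+s2^2))) / sqrt(2 pi (s1^2+s2^2)).  This is the
    overlap kernel the rate engines use; :func:`spectral_overlap` is its
    quadrature counterpart.
    """
    s1 = fwhm1 * FWHM_TO_SIGMA
    s2 = fwhm2 * FWHM_TO_SIGMA
    var = s1 * s1 + s2 * s2
    d = center1 - center2
    return float(np.exp(-0.5 * d * d / var) / np.sqrt(2 * np.pi * var))
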