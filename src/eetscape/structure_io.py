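"""Coordinate parsing, pigment classification, and inventory statistics.

The structural input is a pigment-protein supercomplex (a photosystem I core
surrounded by layered chlorophyll a/c antenna subunits).  This module turns an
mmCIF/PDB file into a :class:`StructureModel` — a flat list of subunits and
pigment cofactors with the annotations the downstream energy-transfer modules
need: pigment species, host subunit, antenna layer, and whether the pigment is
a node of the chlorophyll-only excitation-energy-transfer (EET) network.
"""

from __future__ import annotations

import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Mapping

import gemmi
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Species",
    "PigmentRecord",
    "SubunitRecord",
    "StructureModel",
    "PigmentInventory",
    "ParseError",
    "parse_structure",
    "classify_pigments",
    "annotate_layers",
    "inventory",
    "DEFAULT_HET_MAP",
    "DEFAULT_LAYER_MAP",
    "DEFAULT_FAMILY_MAP",
]


class Species(str, Enum):
    """Pigment chemical species recognised by the pipeline."""

    CHL_A = "chl_a"
    CHL_C = "chl_c"
    CHL_C2_MGDG = "chl_c2_mgdg"
    FUCOXANTHIN = "fucoxanthin"
    HEX_FUCOXANTHIN = "hexanoyloxyfucoxanthin"
    DIADINOXANTHIN = "diadinoxanthin"
    GYROXANTHIN_DIESTER = "gyroxanthin_diester"
    BETA_CAROTENE = "beta_carotene"
    OTHER = "other"


#: Chlorophyll species — the only EET-network nodes.  The Chl c2-MGDG adduct
#: is treated as a plain Chl c chromophore (its lipid tail is spectroscopically
#: silent).
CHLOROPHYLLS = frozenset({Species.CHL_A, Species.CHL_C, Species.CHL_C2_MGDG})

CAROTENOIDS = frozenset(
    {
        Species.FUCOXANTHIN,
        Species.HEX_FUCOXANTHIN,
        Species.DIADINOXANTHIN,
        Species.GYROXANTHIN_DIESTER,
        Species.BETA_CAROTENE,
    }
)

# Packaged het-code -> species defaults.  Residue naming varies between
# depositions, so every entry can be overridden through `naming_map`.
DEFAULT_HET_MAP: dict[str, Species] = {
    "CLA": Species.CHL_A,
    "CHL": Species.CHL_A,  # some dialects use CHL for chlorophyll a
    "KC1": Species.CHL_C,
    "KC2": Species.CHL_C,
    "KCM": Species.CHL_C2_MGDG,
    "FXA": Species.FUCOXANTHIN,
    "FUX": Species.FUCOXANTHIN,
    "HFX": Species.HEX_FUCOXANTHIN,
    "DD6": Species.DIADINOXANTHIN,
    "DDX": Species.DIADINOXANTHIN,
    "GYR": Species.GYROXANTHIN_DIESTER,
    "BCR": Species.BETA_CAROTENE,
}

# Chlorophyll key atoms: the central metal and the two Qy-axis nitrogens
# (ring B and ring D of the chlorin macrocycle).
CHL_KEY_ATOMS = ("MG", "NB", "ND")

# Default antenna layer assignments (concentric shells around the PSI core).
DEFAULT_LAYER_MAP: dict[str, int] = {
    **{f"EFCPI-{i}": 1 for i in (1, 2, 3, 5, 6, 7, 8, 9, 10, 11)},
    **{f"EFCPI-{i}": 2 for i in (4, 12, 13, 14, 15, 16, 17, 18)},
    **{f"EFCPI-{i}": 3 for i in range(19, 26)},
    **{f"EFCPI-{i}": 4 for i in range(26, 31)},
    **{f"EFCPI-{i}": 5 for i in (31, 32)},
    **{f"EFCPI-{i}": 6 for i in (33, 34, 35)},
}

CORE_SUBUNITS = (
    "PsaA",
    "PsaB",
    "PsaC",
    "PsaD",
    "PsaE",
    "PsaF",
    "PsaI",
    "PsaJ",
    "PsaK",
    "PsaL",
    "PsaM",
    "PsaR",
)

# Antenna subfamily defaults.  Layers 2-6 are Lhcq except EFCPI-4 (Lhcf) and
# EFCPI-18 (Lhcr); the innermost layer mixes Lhcr with the PsaO-substituting
# subunit (EFCPI-3) and a RedCAP member (EFCPI-1).
DEFAULT_FAMILY_MAP: dict[str, str] = {
    **{name: "core" for name in CORE_SUBUNITS},
    "L_EFP": "linker",
    "EFCPI-1": "RedCAP",
    "EFCPI-3": "CgLhcr9_homolog",
    **{f"EFCPI-{i}": "Lhcr" for i in (2, 5, 6, 7, 8, 9, 10, 11, 18)},
    "EFCPI-4": "Lhcf",
    **{
        f"EFCPI-{i}": "Lhcq"
        for i in list(range(12, 18)) + list(range(19, 36))
    },
}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


@dataclass
class PigmentRecord:
    """A single chromophore extracted from the coordinate model.

    ``key_atoms`` maps atom name to a 3-vector in Angstrom; for chlorophylls it
    must contain the central metal (``MG``) and the two Qy-axis nitrogens
    (``NB``, ``ND``).  ``is_eet_node`` marks participation in the Chl-only
    EET network.
    """

    pigment_id: str
    species: Species
    host_subunit: str
    key_atoms: dict[str, np.ndarray]
    is_eet_node: bool = False
    het_code: str = ""

    def __post_init__(self) -> None:
        self.key_atoms = {k: np.asarray(v, dtype=float) for k, v in self.key_atoms.items()}
        for name, xyz in self.key_atoms.items():
            if xyz.shape != (3,) or not np.all(np.isfinite(xyz)):
                raise ValueError(
                    f"pigment {self.pigment_id}: atom {name} has non-finite or "
                    f"malformed coordinates"
                )
        if self.is_eet_node and self.species not in CHLOROPHYLLS:
            raise ValueError(
                f"pigment {self.pigment_id}: only chlorophylls can be EET nodes"
            )

    @property
    def center(self) -> np.ndarray:
        """Central-metal position for chlorophylls, else the atom centroid."""
        if "MG" in self.key_atoms:
            return self.key_atoms["MG"]
        return np.mean(list(self.key_atoms.values()), axis=0)


@dataclass
class SubunitRecord:
    """One protein chain: identity, subfamily, and antenna layer (0 = core)."""

    subunit_id: str
    name: str
    family: str | None = None
    layer: int | None = None

    def __post_init__(self) -> None:
        if self.layer is not None:
            if self.family == "core" and self.layer != 0:
                raise ValueError(f"core subunit {self.name} must be layer 0")
            if self.family not in (None, "core") and self.layer < 1:
                raise ValueError(f"antenna subunit {self.name} must have layer >= 1")


@dataclass
class StructureModel:
    """Subunits plus pigments, with provenance of how they were obtained."""

    subunits: list[SubunitRecord]
    pigments: list[PigmentRecord]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [p.pigment_id for p in self.pigments]
        if len(set(ids)) != len(ids):
            dupes = [k for k, n in Counter(ids).items() if n > 1]
            raise ValueError(f"duplicate pigment ids: {dupes[:5]}")
        known = {s.subunit_id for s in self.subunits}
        for p in self.pigments:
            if p.host_subunit not in known:
                raise ValueError(
                    f"pigment {p.pigment_id} references unknown subunit {p.host_subunit}"
                )

    def subunit(self, subunit_id: str) -> SubunitRecord:
        for s in self.subunits:
            if s.subunit_id == subunit_id:
                return s
        raise KeyError(subunit_id)

    def subunit_by_name(self, name: str) -> SubunitRecord:
        for s in self.subunits:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def eet_nodes(self) -> list[PigmentRecord]:
        return [p for p in self.pigments if p.is_eet_node]

    def pigments_of(self, subunit_id: str) -> list[PigmentRecord]:
        return [p for p in self.pigments if p.host_subunit == subunit_id]

    @property
    def antenna_subunits(self) -> list[SubunitRecord]:
        return [s for s in self.subunits if s.family not in ("core", "linker")]


@dataclass
class PigmentInventory:
    """Census of pigments per subunit and species, with antenna averages."""

    counts: dict[tuple[str, Species], int]
    totals: dict[Species, int]
    n_antenna_subunits: int
    mean_chl_a_per_antenna: float | None
    mean_chl_c_per_antenna: float | None
    mean_car_per_antenna: float | None
    per_family_totals: dict[str, dict[Species, int]]
    n_pigments: int
    n_het_residues: int

    def to_frame(self, model: StructureModel) -> pd.DataFrame:
        rows = []
        for (sid, sp), n in sorted(self.counts.items()):
            sub = model.subunit(sid)
            rows.append(
                {
                    "subunit_id": sid,
                    "name": sub.name,
                    "family": sub.family,
                    "layer": sub.layer,
                    "species": sp.value,
                    "count": n,
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        def r2(x: float | None) -> float | None:
            return None if x is None else round(x, 2)

        return {
            "totals": {sp.value: n for sp, n in sorted(self.totals.items())},
            "n_antenna_subunits": self.n_antenna_subunits,
            "mean_chl_a_per_antenna": r2(self.mean_chl_a_per_antenna),
            "mean_chl_c_per_antenna": r2(self.mean_chl_c_per_antenna),
            "mean_carotenoid_per_antenna": r2(self.mean_car_per_antenna),
            "n_pigments": self.n_pigments,
            "n_het_residues": self.n_het_residues,
        }


def _read_gemmi(path: str | Path, dialect: str) -> gemmi.Structure:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        if dialect == "mmcif":
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        elif dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown dialect {dialect!r}; use 'mmcif' or 'pdb'")
    except (RuntimeError, ValueError) as exc:
        if isinstance(exc, ValueError) and "unknown dialect" in str(exc):
            raise
        raise ParseError(f"cannot parse {path} as {dialect}: {exc}") from exc
    if len(st) == 0 or all(len(ch) == 0 for ch in st[0]):
        raise ParseError(f"{path}: no models/chains found ({dialect})")
    return st


def parse_structure(
    path: str | Path,
    dialect: str = "mmcif",
    name_map: Mapping[str, str] | None = None,
) -> StructureModel:
    """Read a coordinate file into a :class:`StructureModel`.

    Every chain becomes a :class:`SubunitRecord` (name taken from ``name_map``
    or the chain id itself).  Every non-water, non-amino-acid residue becomes a
    :class:`PigmentRecord` with ``species=OTHER`` — run
    :func:`classify_pigments` to assign species.  Chlorophyll-like residues
    missing a required key atom are kept but flagged ``is_eet_node=False``
    with a warning.
    """
    st = _read_gemmi(path, dialect)
    st.setup_entities()
    name_map = dict(name_map or {})

    subunits: list[SubunitRecord] = []
    pigments: list[PigmentRecord] = []
    model0 = st[0]
    for chain in model0:
        cid = chain.name
        subunits.append(SubunitRecord(subunit_id=cid, name=name_map.get(cid, cid)))
        for res in chain:
            info = gemmi.find_tabulated_residue(res.name)
            if info is not None and (info.is_amino_acid() or info.is_water()):
                continue
            if res.name == "HOH":
                continue
            atoms = {a.name: np.array([a.pos.x, a.pos.y, a.pos.z]) for a in res}
            if not atoms:
                warnings.warn(
                    f"residue {res.name} {cid}:{res.seqid.num} has no atoms; skipped"
                )
                continue
            pid = f"{cid}:{res.name}:{res.seqid.num}"
            pigments.append(
                PigmentRecord(
                    pigment_id=pid,
                    species=Species.OTHER,
                    host_subunit=cid,
                    key_atoms=atoms,
                    is_eet_node=False,
                    het_code=res.name,
                )
            )
    return StructureModel(
        subunits=subunits,
        pigments=pigments,
        provenance={"source": str(path), "dialect": dialect},
    )


def classify_pigments(
    model: StructureModel,
    naming_map: Mapping[str, Species | str] | None = None,
) -> StructureModel:
    """Assign a species to every pigment from its het code.

    ``naming_map`` entries override the packaged defaults.  Chlorophylls become
    EET nodes when their key atoms (MG, NB, ND) are all present; unmapped het
    codes stay ``other`` and are logged.  Idempotent.
    """
    mapping = dict(DEFAULT_HET_MAP)
    for code, sp in (naming_map or {}).items():
        mapping[code] = Species(sp)

    new_pigments = []
    for p in model.pigments:
        species = mapping.get(p.het_code, p.species if p.het_code == "" else Species.OTHER)
        if p.het_code and p.het_code not in mapping:
            logger.info("het code %s (pigment %s) not in naming map; species=other",
                        p.het_code, p.pigment_id)
            species = Species.OTHER
        is_node = species in CHLOROPHYLLS and all(
            a in p.key_atoms for a in CHL_KEY_ATOMS
        )
        if species in CHLOROPHYLLS and not is_node:
            missing = [a for a in CHL_KEY_ATOMS if a not in p.key_atoms]
            warnings.warn(
                f"chlorophyll {p.pigment_id} missing key atoms {missing}; "
                f"excluded from the EET network"
            )
        new_pigments.append(replace(p, species=species, is_eet_node=is_node))
    return StructureModel(
        subunits=list(model.subunits),
        pigments=new_pigments,
        provenance=dict(model.provenance),
    )


def annotate_layers(
    model: StructureModel,
    layer_map: Mapping[str, int] | None = None,
    family_map: Mapping[str, str] | None = None,
) -> StructureModel:
    """Attach subfamily and concentric-layer annotations to every subunit.

    Core subunits get layer 0, the linker layer 1; antenna subunits take their
    layer from ``layer_map`` (packaged default covers EFCPI-1..35).  An antenna
    subunit absent from the map is an error.
    """
    lmap = dict(DEFAULT_LAYER_MAP)
    lmap.update(layer_map or {})
    fmap = dict(DEFAULT_FAMILY_MAP)
    fmap.update(family_map or {})

    new_subunits = []
    unmapped = []
    for s in model.subunits:
        family = s.family or fmap.get(s.name)
        if family == "core":
            layer = 0
        elif family == "linker":
            layer = 1
        else:
            if family is None:
                family = "Lhcq" if s.name not in lmap else fmap.get(s.name, "Lhcq")
            layer = s.layer if s.layer is not None else lmap.get(s.name)
            if layer is None:
                unmapped.append(s.name)
                layer = -1
        new_subunits.append(replace(s, family=family, layer=layer if layer >= 0 else None))
    if unmapped:
        raise KeyError(f"antenna subunits missing from layer map: {sorted(unmapped)}")
    return StructureModel(
        subunits=new_subunits,
        pigments=list(model.pigments),
        provenance=dict(model.provenance),
    )


def inventory(model: StructureModel) -> PigmentInventory:
    """Count pigments per (subunit, species) and compute antenna averages.

    Averages divide by the number of antenna subunits (core and linker are
    excluded); the carotenoid average pools all carotenoid species.  A model
    with no antenna subunits reports the averages as unavailable (None), never
    as zero.
    """
    counts: Counter = Counter()
    totals: Counter = Counter()
    fam_totals: dict[str, Counter] = {}
    for p in model.pigments:
        counts[(p.host_subunit, p.species)] += 1
        totals[p.species] += 1
        fam = model.subunit(p.host_subunit).family or "unknown"
        fam_totals.setdefault(fam, Counter())[p.species] += 1

    antenna = model.antenna_subunits
    n_ant = len(antenna)
    ant_ids = {s.subunit_id for s in antenna}
    ant_chl_a = sum(n for (sid, sp), n in counts.items()
                    if sid in ant_ids and sp == Species.CHL_A)
    ant_chl_c = sum(n for (sid, sp), n in counts.items()
                    if sid in ant_ids and sp in (Species.CHL_C, Species.CHL_C2_MGDG))
    ant_car = sum(n for (sid, sp), n in counts.items()
                  if sid in ant_ids and sp in CAROTENOIDS)

    n_pig = sum(n for sp, n in totals.items() if sp != Species.OTHER)
    return PigmentInventory(
        counts=dict(counts),
        totals={sp: n for sp, n in totals.items()},
        n_antenna_subunits=n_ant,
        mean_chl_a_per_antenna=ant_chl_a / n_ant if n_ant else None,
        mean_chl_c_per_antenna=ant_chl_c / n_ant if n_ant else None,
        mean_car_per_antenna=ant_car / n_ant if n_ant else None,
        per_family_totals={f: dict(c) for f, c in fam_totals.items()},
        n_pigments=n_pig,
        n_het_residues=len(model.pigments),
    )
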