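import numpy as np
import pytest

from eetscape.structure_io import PigmentRecord, Species, StructureModel, SubunitRecord
from eetscape.synthetic import (
    AntennaLatticeSpec,
    make_inventory_fixture,
    make_layered_antenna,
)


@pytest.fixture(scope="session")
def inventory_model():
    return make_inventory_fixture()


@pytest.fixture(scope="session")
def small_lattice():
    """3 layers x 2 fibers x 4 pigments: small enough for brute-force oracles."""
    return make_layered_antenna(
        AntennaLatticeSpec(n_layers=3, n_fibers=2, pigments_per_subunit=4, seed=11)
    )


def chl(pid, mg, direction, species=Species.CHL_A, sub="X"):
    """Hand-build a chlorophyll record with an explicit Qy axis."""
    mg = np.asarray(mg, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return PigmentRecord(
        pigment_id=pid,
        species=species,
        host_subunit=sub,
        key_atoms={"MG": mg, "NB": mg - 2.0 * d, "ND": mg + 2.0 * d},
        is_eet_node=True,
        het_code="CLA",
    )


def model_of(pigments, subunit_ids=("X",)):
    subs = [SubunitRecord(s, s, family="Lhcq", layer=1) for s in subunit_ids]
    return StructureModel(subunits=subs, pigments=pigments)
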