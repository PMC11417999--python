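import numpy as np
import pytest

from sorbdock.core import Structure
from sorbdock.materials import build_carbon_sheet
from sorbdock.synthetic import SyntheticSpec, make_protein


def make_structure(coords, elements=None, charges=None, names=None,
                   res_ids=None, res_names=None, chain="A",
                   entity_label="protein"):
    """Ad-hoc structure from raw coordinates for small hand-built cases."""
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    n = len(coords)
    elements = elements or ["C"] * n
    names = names or list(elements)
    res_ids = res_ids if res_ids is not None else np.ones(n, dtype=int)
    res_names = res_names or ["UNK"] * n
    return Structure(
        atom_id=np.arange(1, n + 1), atom_name=names, element=elements,
        res_id=res_ids, res_name=res_names, chain_id=[chain] * n,
        coords=coords, charge=charges, entity_label=entity_label,
    )


@pytest.fixture(scope="session")
def toy_protein():
    """~500-atom rigid dimer used by the docking tests."""
    return make_protein(SyntheticSpec(n_chains=2, residues_per_chain=63))


@pytest.fixture(scope="session")
def small_sheet():
    return build_carbon_sheet(40, 0.0, seed=0)
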