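import numpy as np
import pytest

from fragscore import (ChainMapping, SyntheticComplexSpec, make_complex_pair)
from fragscore.model_io import Residue, ResidueKey, StructureModel


@pytest.fixture
def mapping_ab() -> ChainMapping:
    return ChainMapping(model_domain_chain="A", native_domain_chain="A",
                        model_motif_chain="B", native_motif_chain="B")


@pytest.fixture
def complex_zero():
    """Native/model pair with no motif displacement (perfect model)."""
    return make_complex_pair(SyntheticComplexSpec(displacement=(0, 0, 0)))


@pytest.fixture
def complex_displaced():
    """Model motif rigidly displaced by (1.2, 1.6, 0): norm exactly 2 A."""
    return make_complex_pair(SyntheticComplexSpec(displacement=(1.2, 1.6, 0.0)))


def make_point_model(chain_points: dict[str, list[tuple]],
                     plddt: float = 80.0) -> StructureModel:
    """Model with one single-atom residue per listed coordinate.

    ``chain_points`` maps a chain id to a list of (x, y, z) atom positions;
    residue i of a chain gets residue number i+1.
    """
    chains = {}
    plddt_map = {}
    for chain_id, points in chain_points.items():
        residues = []
        for i, xyz in enumerate(points):
            key = ResidueKey(chain_id=chain_id, residue_number=i + 1,
                             insertion_code="", residue_name="GLY")
            residues.append(Residue(
                key=key, atom_names=["CA"], elements=["C"],
                coords=np.array([xyz], dtype=float),
                b_factors=np.array([plddt]),
                occupancies=np.array([1.0]),
            ))
            plddt_map[key] = plddt
        chains[chain_id] = residues
    return StructureModel(model_id="points", chains=chains,
                          per_residue_plddt=plddt_map, predicted=True)
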