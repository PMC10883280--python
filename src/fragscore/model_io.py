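"""Reading and validation of predicted complex models and native references.

Predicted models arrive as PDB files in which the structure-prediction engine
stores the per-residue pLDDT confidence (0-100) in the B-factor column of
every atom of the residue.  Native reference structures may be PDB or mmCIF.
Score bundles (ipTM, pTM, model confidence, rank, PAE matrix) are consumed as
JSON.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get_structure

logger = logging.getLogger("fragscore")

#: ipTM weight in the model-confidence combination.
IPTM_WEIGHT = 0.8
#: pTM weight in the model-confidence combination.
PTM_WEIGHT = 0.2

_NUCLEOTIDES = {
    "A", "C", "G", "U", "T", "DA", "DC", "DG", "DT", "DU",
}


class ModelParseError(ValueError):
    """Raised when a structure or score file cannot be parsed or validated."""


@dataclass(frozen=True, order=True)
class ResidueKey:
    """Identity of one residue: chain, author residue number, insertion code, name."""

    chain_id: str
    residue_number: int
    insertion_code: str = ""
    residue_name: str = ""


@dataclass
class Residue:
    """One residue with its heavy atoms."""

    key: ResidueKey
    atom_names: list[str]
    elements: list[str]
    coords: np.ndarray          # (n_atoms, 3) in Angstrom
    b_factors: np.ndarray       # (n_atoms,)
    occupancies: np.ndarray     # (n_atoms,)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class StructureModel:
    """A parsed multi-chain atomic model, heavy atoms only, file order preserved."""

    model_id: str
    chains: dict[str, list[Residue]]
    per_residue_plddt: dict[ResidueKey, float] = field(default_factory=dict)
    rank: int | None = None
    predicted: bool = False

    @property
    def chain_ids(self) -> list[str]:
        return list(self.chains)

    def residues(self, chain_id: str | None = None):
        if chain_id is not None:
            if chain_id not in self.chains:
                raise KeyError(f"chain {chain_id!r} not in model {self.model_id!r}")
            yield from self.chains[chain_id]
        else:
            for residues in self.chains.values():
                yield from residues

    def residue_keys(self, chain_id: str | None = None) -> list[ResidueKey]:
        return [r.key for r in self.residues(chain_id)]

    @property
    def n_residues(self) -> int:
        return sum(len(r) for r in self.chains.values())

    def chain_coords(self, chain_id: str) -> np.ndarray:
        """Stacked heavy-atom coordinates of one chain."""
        return np.concatenate([r.coords for r in self.chains[chain_id]])

    def plddt(self, key: ResidueKey) -> float:
        return self.per_residue_plddt[key]


@dataclass
class PAEMatrix:
    """Predicted aligned error in Angstrom; square over all residues, may be asymmetric."""

    values: np.ndarray
    residue_index_map: list[ResidueKey]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_index_map)
        if self.values.shape != (n, n):
            raise ModelParseError(
                f"PAE matrix shape {self.values.shape} does not match "
                f"{n} mapped residues"
            )
        if np.any(self.values < 0) or not np.all(np.isfinite(self.values)):
            raise ModelParseError("PAE values must be finite and >= 0")

    def index_of(self, key: ResidueKey) -> int:
        return self.residue_index_map.index(key)


@dataclass
class ScoreBundle:
    """Confidence scores of one predicted model."""

    iptm: float | None = None
    ptm: float | None = None
    model_confidence: float | None = None
    rank: int | None = None
    pae: PAEMatrix | None = None


def model_confidence(iptm: float, ptm: float) -> float:
    """Weighted combination of interface and global predicted TM-scores.

    model confidence = 0.8 * ipTM + 0.2 * pTM
    """
    for name, value in (("iptm", iptm), ("ptm", ptm)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    return IPTM_WEIGHT * iptm + PTM_WEIGHT * ptm


def _atom_array_from_file(path: Path) -> struc.AtomArray:
    suffix = path.suffix.lower()
    try:
        if suffix in (".cif", ".mmcif"):
            cif = CIFFile.read(str(path))
            arr = cif_get_structure(
                cif, model=1, extra_fields=["b_factor", "occupancy"], altloc="occupancy"
            )
        else:
            pdb = PDBFile.read(str(path))
            arr = pdb.get_structure(
                model=1, extra_fields=["b_factor", "occupancy"], altloc="occupancy"
            )
    except Exception as exc:  # biotite raises several exception types
        raise ModelParseError(f"cannot parse structure file {path}: {exc}") from exc
    return arr


def read_model(path: str | Path, predicted: bool = False,
               model_id: str | None = None, rank: int | None = None) -> StructureModel:
    """Read a PDB (or, for native references, mmCIF) file into a StructureModel.

    Hydrogens and HETATM records are dropped; for alternate locations the
    highest-occupancy conformer is kept (ties: first in file order, which is
    biotite's ``altloc="occupancy"`` behaviour).  When ``predicted`` is set the
    B-factor column is interpreted as per-residue pLDDT and validated to lie
    in [0, 100]; atoms of one residue normally agree, otherwise the mean is
    taken and a warning logged.  Nucleic-acid chains are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise ModelParseError(f"no such file: {path}")
    arr = _atom_array_from_file(path)

    keep = (~arr.hetero) & (arr.element != "H") & (arr.element != "D")
    arr = arr[keep]
    if arr.array_length() == 0:
        raise ModelParseError(f"{path}: no heavy ATOM records")

    chains: dict[str, list[Residue]] = {}
    plddt: dict[ResidueKey, float] = {}
    skipped_nuc: set[str] = set()
    # group consecutive atoms into residues, preserving file order
    starts = struc.get_residue_starts(arr, add_exclusive_stop=True)
    for begin, stop in zip(starts[:-1], starts[1:]):
        sub = arr[begin:stop]
        res_name = str(sub.res_name[0])
        chain_id = str(sub.chain_id[0])
        if res_name in _NUCLEOTIDES:
            skipped_nuc.add(chain_id)
            continue
        key = ResidueKey(
            chain_id=chain_id,
            residue_number=int(sub.res_id[0]),
            insertion_code=str(sub.ins_code[0]),
            residue_name=res_name,
        )
        residue = Residue(
            key=key,
            atom_names=[str(a) for a in sub.atom_name],
            elements=[str(e) for e in sub.element],
            coords=np.array(sub.coord, dtype=float),
            b_factors=np.array(sub.b_factor, dtype=float),
            occupancies=np.array(sub.occupancy, dtype=float),
        )
        chains.setdefault(chain_id, []).append(residue)
        bvals = residue.b_factors
        if predicted:
            if np.any(bvals < 0.0) or np.any(bvals > 100.0):
                raise ModelParseError(
                    f"{path}: predicted model has B-factor outside [0, 100] "
                    f"at {key} (pLDDT expected)"
                )
            if not np.allclose(bvals, bvals[0]):
                logger.warning(
                    "residue %s has non-uniform per-atom pLDDT; taking the mean", key
                )
        plddt[key] = float(np.mean(bvals))

    if skipped_nuc:
        logger.warning("skipped nucleic-acid chain(s): %s", sorted(skipped_nuc))
    if not chains:
        raise ModelParseError(f"{path}: no protein chains")

    return StructureModel(
        model_id=model_id or path.stem,
        chains=chains,
        per_residue_plddt=plddt if predicted else plddt,
        rank=rank,
        predicted=predicted,
    )


def to_atom_array(model: StructureModel) -> struc.AtomArray:
    """Flatten a StructureModel back into a biotite AtomArray (file order)."""
    n = sum(res.n_atoms for res in model.residues())
    arr = struc.AtomArray(n)
    arr.set_annotation("b_factor", np.zeros(n))
    arr.set_annotation("occupancy", np.ones(n))
    i = 0
    for chain_id, residues in model.chains.items():
        for res in residues:
            j = i + res.n_atoms
            arr.chain_id[i:j] = chain_id
            arr.res_id[i:j] = res.key.residue_number
            arr.ins_code[i:j] = res.key.insertion_code
            arr.res_name[i:j] = res.key.residue_name
            arr.atom_name[i:j] = res.atom_names
            arr.element[i:j] = res.elements
            arr.coord[i:j] = res.coords
            arr.b_factor[i:j] = res.b_factors
            arr.occupancy[i:j] = res.occupancies
            i = j
    arr.hetero[:] = False
    return arr


def write_model(model: StructureModel, path: str | Path) -> None:
    """Write a StructureModel to PDB (coordinates at format precision)."""
    pdb = PDBFile()
    pdb.set_structure(to_atom_array(model))
    pdb.write(str(path))


def read_scores(path: str | Path, model: StructureModel | None = None) -> ScoreBundle:
    """Read a JSON score bundle.

    Schema: ``{"iptm": float, "ptm": float, "model_confidence": float?,
    "rank": int?, "pae": [[float]]?, "pae_residues": [["chain", number,
    "icode"]]?}``.  When ``model_confidence`` is absent it is computed from
    ipTM/pTM; if neither is available this is an error.  When ``model`` is
    given, the PAE dimension is validated against the model residue count and
    the residue index map is taken from the model when ``pae_residues`` is
    absent.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ModelParseError(f"cannot read score file {path}: {exc}") from exc

    iptm = data.get("iptm")
    ptm = data.get("ptm")
    confidence = data.get("model_confidence")
    if confidence is None:
        if iptm is None or ptm is None:
            raise ModelParseError(
                f"{path}: need model_confidence or both iptm and ptm"
            )
        confidence = model_confidence(float(iptm), float(ptm))

    pae = None
    if data.get("pae") is not None:
        values = np.asarray(data["pae"], dtype=float)
        if data.get("pae_residues") is not None:
            index_map = [
                ResidueKey(chain_id=str(c), residue_number=int(n),
                           insertion_code=str(i))
                for c, n, i in data["pae_residues"]
            ]
        elif model is not None:
            index_map = [
                ResidueKey(k.chain_id, k.residue_number, k.insertion_code)
                for k in model.residue_keys()
            ]
        else:
            index_map = [ResidueKey("", i + 1) for i in range(values.shape[0])]
        pae = PAEMatrix(values=values, residue_index_map=index_map)
        if model is not None and values.shape[0] != model.n_residues:
            raise ModelParseError(
                f"{path}: PAE is {values.shape[0]}x{values.shape[0]} but the "
                f"model has {model.n_residues} residues"
            )

    return ScoreBundle(
        iptm=None if iptm is None else float(iptm),
        ptm=None if ptm is None else float(ptm),
        model_confidence=float(confidence),
        rank=None if data.get("rank") is None else int(data["rank"]),
        pae=pae,
    )
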