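"""Synthetic fixtures: toy complexes, score sets and titrations.

The generators make every other module testable without any external
downloads.  Synthetic "complexes" are rigid poly-alanine-like traces with
standard backbone atom names (N, CA, C, O) plus one pocket-facing CB per
residue, so that atom-name matching and heavy-atom contact logic are
exercised; they are not physically realistic conformers.  The model copy of
a complex displaces the motif chain by a prescribed vector in the domain
frame, so the expected motif RMSD equals the displacement norm exactly.

All generators are byte-deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
from scipy.spatial.distance import cdist

from .bret import TitrationPoint, hyperbolic_model
from .benchstats import ScoredSet
from .model_io import (PAEMatrix, Residue, ResidueKey, ScoreBundle,
                       StructureModel, model_confidence, write_model)

#: Minimal allowed heavy-atom separation between chains, in Angstrom.
CLASH_DISTANCE = 0.5

_RESIDUE_TEMPLATE = (
    # atom name, element, offset from the residue base point
    ("N", "N", (-0.5, -1.0, 0.0)),
    ("CA", "C", (0.0, 0.0, 0.0)),
    ("C", "C", (0.6, 0.4, 0.6)),
    ("O", "O", (0.6, 1.2, 1.2)),
    ("CB", "C", (0.0, 1.5, 0.5)),
)

_CA_SPACING = 3.8


@dataclass
class SyntheticComplexSpec:
    """Parameters of one synthetic two-chain complex."""

    n_domain_residues: int = 12
    n_motif_residues: int = 5
    #: rigid displacement applied to the motif chain in the model copy
    displacement: tuple[float, float, float] = (0.0, 0.0, 0.0)
    #: x-shift of the motif relative to the domain
    motif_offset_x: float = 3.8
    #: vertical separation between the two chain traces
    motif_height: float = 5.0
    plddt_domain: float = 90.0
    plddt_motif: float = 80.0
    #: PAE fill values (within-chain, between-chain)
    pae_intra: float = 2.0
    pae_inter: float = 5.0
    iptm: float = 0.9
    ptm: float = 0.8
    rank: int = 0
    seed: int = 0
    model_id: str = "synthetic"


def _make_chain(chain_id: str, n_residues: int, base: np.ndarray,
                flip_y: bool, plddt: np.ndarray, start_number: int = 1
                ) -> list[Residue]:
    residues = []
    for i in range(n_residues):
        origin = base + np.array([_CA_SPACING * i, 0.0, 0.0])
        names, elements, coords = [], [], []
        for name, element, offset in _RESIDUE_TEMPLATE:
            off = np.array(offset, dtype=float)
            if flip_y:
                off[1] = -off[1]
            names.append(name)
            elements.append(element)
            coords.append(origin + off)
        key = ResidueKey(chain_id=chain_id, residue_number=start_number + i,
                         insertion_code="", residue_name="ALA")
        residues.append(Residue(
            key=key, atom_names=names, elements=elements,
            coords=np.asarray(coords),
            b_factors=np.full(len(names), plddt[i]),
            occupancies=np.ones(len(names)),
        ))
    return residues


def _build_structure(spec: SyntheticComplexSpec, model_id: str,
                     motif_shift: np.ndarray) -> StructureModel:
    plddt_dom = np.full(spec.n_domain_residues, spec.plddt_domain, dtype=float)
    plddt_mot = np.full(spec.n_motif_residues, spec.plddt_motif, dtype=float)
    domain = _make_chain("A", spec.n_domain_residues, np.zeros(3), False,
                         plddt_dom)
    motif_base = np.array([spec.motif_offset_x, spec.motif_height, 0.5])
    motif = _make_chain("B", spec.n_motif_residues, motif_base + motif_shift,
                        True, plddt_mot)
    chains = {"A": domain, "B": motif}
    plddt = {r.key: float(r.b_factors[0]) for c in chains.values() for r in c}
    structure = StructureModel(model_id=model_id, chains=chains,
                               per_residue_plddt=plddt, rank=spec.rank,
                               predicted=True)
    dom_coords = np.concatenate([r.coords for r in domain])
    mot_coords = np.concatenate([r.coords for r in motif])
    if cdist(dom_coords, mot_coords).min() < CLASH_DISTANCE:
        raise ValueError("synthetic chains clash (< 0.5 A heavy-atom contact)")
    return structure


def make_complex_pair(spec: SyntheticComplexSpec
                      ) -> tuple[StructureModel, StructureModel, ScoreBundle]:
    """(native, model, scores) for one synthetic complex.

    Native and model share chain ids, residue numbering and atom names; the
    model's motif chain is rigidly displaced by ``spec.displacement`` in the
    domain frame, so the all-atom motif RMSD after domain superposition is
    exactly the displacement norm.
    """
    native = _build_structure(spec, spec.model_id + "_native", np.zeros(3))
    model = _build_structure(spec, spec.model_id + "_model",
                             np.asarray(spec.displacement, dtype=float))
    n = model.n_residues
    keys = [ResidueKey(k.chain_id, k.residue_number, k.insertion_code)
            for k in model.residue_keys()]
    pae = np.full((n, n), spec.pae_intra, dtype=float)
    n_dom = spec.n_domain_residues
    pae[:n_dom, n_dom:] = spec.pae_inter
    pae[n_dom:, :n_dom] = spec.pae_inter
    scores = ScoreBundle(
        iptm=spec.iptm, ptm=spec.ptm,
        model_confidence=model_confidence(spec.iptm, spec.ptm),
        rank=spec.rank,
        pae=PAEMatrix(values=pae, residue_index_map=keys),
    )
    return native, model, scores


def write_complex_pair(spec: SyntheticComplexSpec, out_dir: str | Path
                       ) -> tuple[Path, Path, Path]:
    """Write native PDB, model PDB and score JSON; returns the three paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    native, model, scores = make_complex_pair(spec)
    native_path = out_dir / f"{spec.model_id}_native.pdb"
    model_path = out_dir / f"{spec.model_id}_model.pdb"
    scores_path = out_dir / f"{spec.model_id}_scores.json"
    write_model(native, native_path)
    write_model(model, model_path)
    payload = {
        "iptm": spec.iptm,
        "ptm": spec.ptm,
        "rank": spec.rank,
        "pae": scores.pae.values.tolist(),
        "pae_residues": [
            [k.chain_id, k.residue_number, k.insertion_code]
            for k in scores.pae.residue_index_map
        ],
    }
    scores_path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return native_path, model_path, scores_path


def make_benchmark_scores(n_pos: int, n_neg: int, pos_mean: float,
                          neg_mean: float, sd: float, seed: int,
                          metric_name: str = "synthetic_metric",
                          orientation: str = "higher_is_better") -> ScoredSet:
    """Gaussian positive/random score draws for benchmark statistics."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("need at least one score per class")
    rng = np.random.default_rng(seed)
    values = np.concatenate([
        rng.normal(pos_mean, sd, size=n_pos),
        rng.normal(neg_mean, sd, size=n_neg),
    ])
    labels = np.array(["positive"] * n_pos + ["random"] * n_neg, dtype=object)
    return ScoredSet(values=values, labels=labels, metric_name=metric_name,
                     orientation=orientation)  # type: ignore[arg-type]


def make_titration(bretmax: float, bret50: float, ad_grid,
                   noise_sd: float = 0.0, seed: int = 0
                   ) -> list[TitrationPoint]:
    """Hyperbolic titration points with seeded Gaussian noise."""
    ad = np.asarray(ad_grid, dtype=float)
    if np.any(ad <= 0):
        raise ValueError("A/D grid must be positive")
    rng = np.random.default_rng(seed)
    values = hyperbolic_model(ad, bretmax, bret50)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=len(ad))
    return [TitrationPoint(ad_ratio=float(a), cbret=float(v))
            for a, v in zip(ad, values)]
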