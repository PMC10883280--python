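"""Evaluation of predicted models against native reference structures.

The central accuracy measure is the all-atom motif RMSD: model and native are
superposed on the domain chain with an optimal least-squares (Kabsch) fit over
atoms matched strictly by residue mapping and atom name — no outlier
rejection, no refinement — and the RMSD is then taken over all shared heavy
atoms of the motif chain in that frame.  Accuracy categories:

    rmsd <= 2 A        correct sidechain
    2 < rmsd <= 5 A    correct backbone
    5 < rmsd <= 15 A   correct pocket
    rmsd > 15 A        wrong pocket

A model is "accurate" when the motif RMSD is <= 5 A.  The module also
implements DockQ (fnat, iRMS, LRMS and the combined score with classes
incorrect / acceptable / medium / high) and the mean pairwise DockQ over the
top-ranked models of one prediction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import ResidueKey, StructureModel

logger = logging.getLogger("fragscore")

#: Motif-RMSD category boundaries (upper bounds, inclusive), in Angstrom.
RMSD_SIDECHAIN = 2.0
RMSD_BACKBONE = 5.0
RMSD_POCKET = 15.0
#: A model is accurate when motif RMSD <= this value.
ACCURACY_RMSD = 5.0

#: DockQ component constants from the published definition.
DOCKQ_FNAT_CUTOFF = 5.0      # native contact distance, heavy atoms
DOCKQ_IFACE_CUTOFF = 10.0    # interface residue definition for iRMS
DOCKQ_IRMS_SCALE = 1.5
DOCKQ_LRMS_SCALE = 8.5
#: DockQ class boundaries.
DOCKQ_ACCEPTABLE = 0.23
DOCKQ_MEDIUM = 0.49
DOCKQ_HIGH = 0.80

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Absolute tolerance for comparisons against category boundaries, absorbing
#: the rounding noise of the superposition arithmetic.
BOUNDARY_EPS = 1e-9

Category = Literal["correct_sidechain", "correct_backbone",
                   "correct_pocket", "wrong_pocket"]
Quality = Literal["incorrect", "acceptable", "medium", "high"]


class EvaluationError(ValueError):
    """Raised when model and native cannot be compared as requested."""


@dataclass
class ChainMapping:
    """How model chains and residue numbers map onto the native structure."""

    model_domain_chain: str
    native_domain_chain: str
    model_motif_chain: str
    native_motif_chain: str
    #: model residue number -> native residue number, per role
    domain_offset: int = 0
    motif_offset: int = 0
    #: explicit overrides (model number -> native number); win over offsets
    domain_residue_map: dict[int, int] = field(default_factory=dict)
    motif_residue_map: dict[int, int] = field(default_factory=dict)

    def map_residue(self, role: Literal["domain", "motif"], model_number: int) -> int:
        explicit = (self.domain_residue_map if role == "domain"
                    else self.motif_residue_map)
        if model_number in explicit:
            return explicit[model_number]
        offset = self.domain_offset if role == "domain" else self.motif_offset
        return model_number + offset


@dataclass(frozen=True)
class RigidTransform:
    """x -> R x + t"""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(rotation=np.eye(3), translation=np.zeros(3))


@dataclass
class MotifRMSDResult:
    rmsd: float
    n_atoms: int
    category: Category
    accurate: bool
    n_dropped_atoms: int = 0


@dataclass
class DockQResult:
    fnat: float
    irms: float
    lrms: float
    dockq: float
    quality: Quality


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> RigidTransform:
    """Optimal least-squares rigid superposition of ``mobile`` onto ``reference``."""
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise EvaluationError(
            f"need >= 3 matched atom pairs of equal shape, got {mobile.shape} "
            f"vs {reference.shape}"
        )
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = cr - rotation @ cm
    return RigidTransform(rotation=rotation, translation=translation)


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def _matched_coords(model: StructureModel, native: StructureModel,
                    mapping: ChainMapping, role: Literal["domain", "motif"],
                    atom_subset: Sequence[str] | None = None,
                    native_residue_filter: set | None = None,
                    ) -> tuple[np.ndarray, np.ndarray, int]:
    """Coordinates of atoms shared by mapped residues, matched by atom name.

    Returns (model_coords, native_coords, n_dropped) where n_dropped counts
    atoms present on only one side of a mapped residue pair.
    """
    model_chain = (mapping.model_domain_chain if role == "domain"
                   else mapping.model_motif_chain)
    native_chain = (mapping.native_domain_chain if role == "domain"
                    else mapping.native_motif_chain)
    native_res = {
        (r.key.residue_number, r.key.insertion_code): r
        for r in native.chains.get(native_chain, [])
    }
    mc, nc, dropped = [], [], 0
    for res in model.chains.get(model_chain, []):
        nnum = mapping.map_residue(role, res.key.residue_number)
        partner = native_res.get((nnum, res.key.insertion_code))
        if partner is None:
            continue
        if native_residue_filter is not None and \
                (partner.key.residue_number, partner.key.insertion_code) \
                not in native_residue_filter:
            continue
        partner_index = {name: i for i, name in enumerate(partner.atom_names)}
        for i, name in enumerate(res.atom_names):
            if atom_subset is not None and name not in atom_subset:
                continue
            j = partner_index.get(name)
            if j is None:
                dropped += 1
                continue
            mc.append(res.coords[i])
            nc.append(partner.coords[j])
        if atom_subset is None:
            dropped += sum(1 for name in partner.atom_names
                           if name not in res.atom_names)
    if dropped:
        logger.warning("%d unshared atoms dropped while matching %s atoms",
                       dropped, role)
    if not mc:
        return np.empty((0, 3)), np.empty((0, 3)), dropped
    return np.asarray(mc), np.asarray(nc), dropped


def superpose_on_domain(model: StructureModel, native: StructureModel,
                        mapping: ChainMapping
                        ) -> tuple[RigidTransform, float]:
    """Kabsch superposition of the model's domain chain onto the native's.

    All heavy atoms shared by mapped domain residues participate; no outlier
    rejection.  Returns the transform (applied to the whole model downstream)
    and the domain RMSD after superposition.
    """
    mc, nc, _ = _matched_coords(model, native, mapping, "domain")
    if len(mc) < 3:
        raise EvaluationError(
            f"only {len(mc)} matched domain atoms; need >= 3 for superposition"
        )
    transform = kabsch(mc, nc)
    return transform, rmsd(transform.apply(mc), nc)


def categorize_rmsd(value: float) -> Category:
    """Partition of [0, inf) into the four accuracy categories."""
    if value < 0:
        raise ValueError("rmsd must be non-negative")
    if value <= RMSD_SIDECHAIN + BOUNDARY_EPS:
        return "correct_sidechain"
    if value <= RMSD_BACKBONE + BOUNDARY_EPS:
        return "correct_backbone"
    if value <= RMSD_POCKET + BOUNDARY_EPS:
        return "correct_pocket"
    return "wrong_pocket"


def motif_all_atom_rmsd(model: StructureModel, native: StructureModel,
                        transform: RigidTransform, mapping: ChainMapping
                        ) -> MotifRMSDResult:
    """All-atom RMSD of the motif chain in the domain-superposed frame."""
    mc, nc, dropped = _matched_coords(model, native, mapping, "motif")
    if len(mc) == 0:
        raise EvaluationError("no shared motif atoms between model and native")
    value = rmsd(transform.apply(mc), nc)
    return MotifRMSDResult(
        rmsd=value,
        n_atoms=len(mc),
        category=categorize_rmsd(value),
        accurate=value <= ACCURACY_RMSD + BOUNDARY_EPS,
        n_dropped_atoms=dropped,
    )


def evaluate_model(model: StructureModel, native: StructureModel,
                   mapping: ChainMapping) -> MotifRMSDResult:
    """Superpose on the domain and score the motif in one call."""
    transform, _ = superpose_on_domain(model, native, mapping)
    return motif_all_atom_rmsd(model, native, transform, mapping)


# ---------------------------------------------------------------------------
# DockQ
# ---------------------------------------------------------------------------

def _residue_contacts(structure: StructureModel, chain_a: str, chain_b: str,
                      cutoff: float) -> set[tuple]:
    """Cross-chain residue pairs with any heavy-atom distance < cutoff."""
    pairs = set()
    for res_a in structure.chains[chain_a]:
        for res_b in structure.chains[chain_b]:
            d = cdist(res_a.coords, res_b.coords)
            if (d < cutoff).any():
                pairs.add(((res_a.key.residue_number, res_a.key.insertion_code),
                           (res_b.key.residue_number, res_b.key.insertion_code)))
    return pairs


def dockq_quality(score: float) -> Quality:
    if score < DOCKQ_ACCEPTABLE:
        return "incorrect"
    if score < DOCKQ_MEDIUM:
        return "acceptable"
    if score < DOCKQ_HIGH:
        return "medium"
    return "high"


def compute_dockq(model: StructureModel, native: StructureModel,
                  mapping: ChainMapping) -> DockQResult:
    """fnat, iRMS, LRMS and the combined DockQ score.

    * fnat: fraction of native cross-chain residue contacts (heavy atoms
      < 5 A) reproduced by the model, in native numbering via the mapping.
    * iRMS: backbone RMSD over native interface residues (any heavy atom
      < 10 A of the partner chain) after superposing on those atoms.
    * LRMS: backbone RMSD of the motif (ligand) chain after superposing on
      the domain (receptor) backbone.
    * DockQ = (fnat + 1/(1+(iRMS/1.5)^2) + 1/(1+(LRMS/8.5)^2)) / 3.
    """
    nd, nm = mapping.native_domain_chain, mapping.native_motif_chain
    native_contacts = _residue_contacts(native, nd, nm, DOCKQ_FNAT_CUTOFF)
    if not native_contacts:
        raise EvaluationError("native structure has no interface contacts")

    # model contacts expressed in native numbering
    md, mm = mapping.model_domain_chain, mapping.model_motif_chain
    model_contacts_native = set()
    for res_a in model.chains[md]:
        for res_b in model.chains[mm]:
            d = cdist(res_a.coords, res_b.coords)
            if (d < DOCKQ_FNAT_CUTOFF).any():
                model_contacts_native.add((
                    (mapping.map_residue("domain", res_a.key.residue_number),
                     res_a.key.insertion_code),
                    (mapping.map_residue("motif", res_b.key.residue_number),
                     res_b.key.insertion_code),
                ))
    fnat = len(native_contacts & model_contacts_native) / len(native_contacts)

    # interface residues (native definition, 10 A) for iRMS
    iface_pairs = _residue_contacts(native, nd, nm, DOCKQ_IFACE_CUTOFF)
    iface_domain = {a for a, _ in iface_pairs}
    iface_motif = {b for _, b in iface_pairs}
    mcd, ncd, _ = _matched_coords(model, native, mapping, "domain",
                                  atom_subset=BACKBONE_ATOMS,
                                  native_residue_filter=iface_domain)
    mcm, ncm, _ = _matched_coords(model, native, mapping, "motif",
                                  atom_subset=BACKBONE_ATOMS,
                                  native_residue_filter=iface_motif)
    mi = np.concatenate([mcd, mcm])
    ni = np.concatenate([ncd, ncm])
    if len(mi) < 3:
        raise EvaluationError("fewer than 3 matched interface backbone atoms")
    t_iface = kabsch(mi, ni)
    irms = rmsd(t_iface.apply(mi), ni)

    # LRMS: superpose on receptor (domain) backbone, RMSD over ligand backbone
    mrd, nrd, _ = _matched_coords(model, native, mapping, "domain",
                                  atom_subset=BACKBONE_ATOMS)
    mrl, nrl, _ = _matched_coords(model, native, mapping, "motif",
                                  atom_subset=BACKBONE_ATOMS)
    if len(mrd) < 3 or len(mrl) == 0:
        raise EvaluationError("insufficient matched backbone atoms for LRMS")
    t_rec = kabsch(mrd, nrd)
    lrms = rmsd(t_rec.apply(mrl), nrl)

    score = (fnat
             + 1.0 / (1.0 + (irms / DOCKQ_IRMS_SCALE) ** 2)
             + 1.0 / (1.0 + (lrms / DOCKQ_LRMS_SCALE) ** 2)) / 3.0
    return DockQResult(fnat=fnat, irms=irms, lrms=lrms, dockq=score,
                       quality=dockq_quality(score))


def mean_pairwise_dockq(models: Sequence[StructureModel],
                        mapping: ChainMapping | None = None) -> float:
    """Mean DockQ over all pairs of top-ranked models of one prediction.

    Models are ordered by model confidence (rank attribute, best first); for
    each pair the higher-ranked model plays the reference ("native") role.
    """
    if len(models) < 2:
        raise EvaluationError("need >= 2 models for pairwise DockQ")
    if len(models) > 5:
        raise EvaluationError("mean pairwise DockQ is defined over <= 5 models")
    ordered = sorted(models, key=lambda m: math.inf if m.rank is None else m.rank)
    if mapping is None:
        chains = ordered[0].chain_ids
        if len(chains) != 2:
            raise EvaluationError("models must have exactly two chains")
        mapping = ChainMapping(
            model_domain_chain=chains[0], native_domain_chain=chains[0],
            model_motif_chain=chains[1], native_motif_chain=chains[1],
        )
    scores = []
    for i in range(len(ordered)):
        for j in range(i + 1, len(ordered)):
            scores.append(compute_dockq(ordered[j], ordered[i], mapping).dockq)
    return float(np.mean(scores))


def extension_fold_change(rmsd_minimal: float, rmsd_extended: float) -> float:
    """log2(RMSD_minimal / RMSD_extended); positive = extension improved."""
    if rmsd_minimal <= 0 or rmsd_extended <= 0:
        raise ValueError("RMSD values must be positive")
    return math.log2(rmsd_minimal / rmsd_extended)
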