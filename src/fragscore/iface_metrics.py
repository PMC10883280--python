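"""Interface detection and per-model confidence metrics.

A residue is interfacial when at least one of its heavy atoms lies strictly
closer than 5 A to any heavy atom of the partner chain.  From the interface
residue sets the module derives:

* chain interface pLDDT   — mean pLDDT over one chain's interface residues
  (the "motif chain" / "domain chain" interface pLDDT of a two-chain model);
* average interface pLDDT — pooled mean over both chains' interface residues;
* residue-residue and atom-atom contact counts;
* pDockQ                  — sigmoid of mean interface pLDDT x log contact
  count using C-beta contacts (C-alpha for glycine) within 8 A;
* iPAE                    — median predicted aligned error over residue pairs
  in contact at 3.5 A;
* model confidence        — 0.8 * ipTM + 0.2 * pTM (from model_io).

All distance cutoffs are applied with strict inequality.  Metrics over an
empty interface are undefined and reported as ``None``, never as 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .model_io import PAEMatrix, ResidueKey, ScoreBundle, StructureModel
from .model_io import model_confidence  # noqa: F401  (re-exported convenience)

logger = logging.getLogger("fragscore")

#: Heavy-atom interface distance cutoff (strict <), in Angstrom.
INTERFACE_CUTOFF = 5.0
#: C-beta contact cutoff used by pDockQ (strict <), in Angstrom.
PDOCKQ_CUTOFF = 8.0
#: Contact cutoff for iPAE (strict <), in Angstrom.
IPAE_CUTOFF = 3.5

#: pDockQ sigmoid constants, frozen from the reference implementation:
#: score = L / (1 + exp(-k (x - x0))) + b.
PDOCKQ_L = 0.724
PDOCKQ_K = 0.052
PDOCKQ_X0 = 152.611
PDOCKQ_B = 0.018

#: Interface-pLDDT confidence cutoff for calling a model highly confident.
CONFIDENCE_PLDDT_CUTOFF = 70.0
#: Alternative average-interface-pLDDT cutoff for ordered-ordered interfaces.
DDI_PLDDT_CUTOFF = 75.0
#: Optional extra model-confidence cutoff for ordered-ordered pairs.
MODEL_CONFIDENCE_CUTOFF = 0.7


@dataclass(frozen=True)
class ContactPair:
    """A cross-chain residue pair in contact."""

    residue_a: ResidueKey
    residue_b: ResidueKey
    min_heavy_atom_distance: float
    n_atom_contacts: int


@dataclass
class InterfaceReport:
    """Interface residue sets, contact counts and confidence metrics."""

    chain_pair: tuple[str, str]
    distance_cutoff: float
    interface_residues: dict[str, set[ResidueKey]]
    contacts: list[ContactPair]
    residue_contacts: int
    atom_contacts: int
    chain_interface_plddt: dict[str, float | None] = field(default_factory=dict)
    average_interface_plddt: float | None = None
    model_confidence: float | None = None
    pdockq: float | None = None
    ipae: float | None = None

    @property
    def is_empty(self) -> bool:
        return self.residue_contacts == 0


def _chain_atoms(model: StructureModel, chain_id: str):
    """(coords stacked, residue key per atom) for one chain."""
    if chain_id not in model.chains:
        raise KeyError(f"chain {chain_id!r} not present in model {model.model_id!r}")
    coords, keys = [], []
    for res in model.chains[chain_id]:
        coords.append(res.coords)
        keys.extend([res.key] * res.n_atoms)
    return np.concatenate(coords), keys


def find_interface(model: StructureModel, chain_pair: tuple[str, str],
                   cutoff: float = INTERFACE_CUTOFF) -> InterfaceReport:
    """Detect interface residues and count contacts between two chains.

    A residue is interfacial iff any of its heavy atoms is strictly closer
    than ``cutoff`` to any heavy atom of the partner chain.
    ``residue_contacts`` counts unique cross-chain residue pairs with minimal
    heavy-atom distance < cutoff; ``atom_contacts`` counts unique cross-chain
    atom pairs with distance < cutoff.
    """
    ca, cb = chain_pair
    coords_a, keys_a = _chain_atoms(model, ca)
    coords_b, keys_b = _chain_atoms(model, cb)
    dist = cdist(coords_a, coords_b)
    mask = dist < cutoff

    atom_contacts = int(mask.sum())
    iface: dict[str, set[ResidueKey]] = {ca: set(), cb: set()}
    per_pair: dict[tuple[ResidueKey, ResidueKey], list[float]] = {}
    ia, ib = np.nonzero(mask)
    for i, j in zip(ia, ib):
        ka, kb = keys_a[i], keys_b[j]
        iface[ca].add(ka)
        iface[cb].add(kb)
        per_pair.setdefault((ka, kb), []).append(float(dist[i, j]))

    contacts = [
        ContactPair(residue_a=ka, residue_b=kb,
                    min_heavy_atom_distance=min(ds), n_atom_contacts=len(ds))
        for (ka, kb), ds in sorted(per_pair.items())
    ]
    return InterfaceReport(
        chain_pair=(ca, cb),
        distance_cutoff=cutoff,
        interface_residues=iface,
        contacts=contacts,
        residue_contacts=len(contacts),
        atom_contacts=atom_contacts,
    )


def chain_interface_plddt(report: InterfaceReport, model: StructureModel,
                          chain_id: str) -> float | None:
    """Mean pLDDT over one chain's interface residues; None when empty."""
    residues = report.interface_residues.get(chain_id, set())
    if not residues:
        logger.warning("chain %s has no interface residues; interface pLDDT "
                       "undefined", chain_id)
        return None
    return float(np.mean([model.per_residue_plddt[k] for k in residues]))


def average_interface_plddt(report: InterfaceReport,
                            model: StructureModel) -> float | None:
    """Pooled mean pLDDT over both chains' interface residues; None when empty."""
    keys = [k for residues in report.interface_residues.values() for k in residues]
    if not keys:
        logger.warning("empty interface; average interface pLDDT undefined")
        return None
    return float(np.mean([model.per_residue_plddt[k] for k in keys]))


def _cb_coords(model: StructureModel, chain_id: str):
    """Representative C-beta (C-alpha for glycine) coordinate per residue."""
    coords, keys = [], []
    for res in model.chains[chain_id]:
        name = "CA" if res.key.residue_name == "GLY" else "CB"
        if name in res.atom_names:
            coords.append(res.coords[res.atom_names.index(name)])
            keys.append(res.key)
        elif "CA" in res.atom_names:  # fall back for incomplete residues
            coords.append(res.coords[res.atom_names.index("CA")])
            keys.append(res.key)
    return np.asarray(coords), keys


def pdockq(model: StructureModel, chain_pair: tuple[str, str] | None = None,
           cutoff: float = PDOCKQ_CUTOFF) -> float:
    """pDockQ interface score of a two-chain predicted model.

    x = (mean pLDDT over C-beta-contact interface residues) * ln(number of
    contact residue pairs); score = L / (1 + exp(-k (x - x0))) + b.  With zero
    contacts x is defined as 0 and the sigmoid baseline is returned.
    """
    if chain_pair is None:
        if len(model.chains) != 2:
            raise ValueError("model must have exactly two chains or a chain "
                             "pair must be named")
        chain_pair = tuple(model.chain_ids)  # type: ignore[assignment]
    ca, cb = chain_pair
    coords_a, keys_a = _cb_coords(model, ca)
    coords_b, keys_b = _cb_coords(model, cb)
    if len(coords_a) == 0 or len(coords_b) == 0:
        n_pairs = 0
    else:
        mask = cdist(coords_a, coords_b) < cutoff
        n_pairs = int(mask.sum())
    if n_pairs == 0:
        x = 0.0
    else:
        ia, ib = np.nonzero(mask)
        iface_keys = {keys_a[i] for i in ia} | {keys_b[j] for j in ib}
        mean_plddt = float(np.mean([model.per_residue_plddt[k] for k in iface_keys]))
        x = mean_plddt * math.log(n_pairs)
    return PDOCKQ_L / (1.0 + math.exp(-PDOCKQ_K * (x - PDOCKQ_X0))) + PDOCKQ_B


def ipae(model: StructureModel, pae: PAEMatrix,
         chain_pair: tuple[str, str] | None = None,
         cutoff: float = IPAE_CUTOFF) -> float | None:
    """Median predicted aligned error over interface residue pairs at 3.5 A.

    Contacts are cross-chain residue pairs whose minimal heavy-atom distance
    is strictly below ``cutoff``; the median pools both PAE directions (i, j)
    and (j, i).  Returns None when no pair is in contact.
    """
    if chain_pair is None:
        if len(model.chains) != 2:
            raise ValueError("model must have exactly two chains or a chain "
                             "pair must be named")
        chain_pair = tuple(model.chain_ids)  # type: ignore[assignment]
    report = find_interface(model, chain_pair, cutoff=cutoff)
    if report.residue_contacts == 0:
        logger.warning("no residue pair within %.2f A; iPAE undefined", cutoff)
        return None
    index = {
        (k.chain_id, k.residue_number, k.insertion_code): i
        for i, k in enumerate(pae.residue_index_map)
    }

    def idx(key: ResidueKey) -> int:
        return index[(key.chain_id, key.residue_number, key.insertion_code)]

    values = []
    for contact in report.contacts:
        i, j = idx(contact.residue_a), idx(contact.residue_b)
        values.append(pae.values[i, j])
        values.append(pae.values[j, i])
    return float(np.median(values))


def compute_report(model: StructureModel, scores: ScoreBundle | None = None,
                   chain_pair: tuple[str, str] | None = None,
                   cutoff: float = INTERFACE_CUTOFF) -> InterfaceReport:
    """Full InterfaceReport with every metric that the inputs allow."""
    if chain_pair is None:
        if len(model.chains) != 2:
            raise ValueError("model must have exactly two chains or a chain "
                             "pair must be named")
        chain_pair = tuple(model.chain_ids)  # type: ignore[assignment]
    report = find_interface(model, chain_pair, cutoff=cutoff)
    for chain in chain_pair:
        report.chain_interface_plddt[chain] = (
            chain_interface_plddt(report, model, chain)
            if report.interface_residues[chain] else None
        )
    report.average_interface_plddt = (
        average_interface_plddt(report, model) if not report.is_empty else None
    )
    report.pdockq = pdockq(model, chain_pair)
    if scores is not None:
        report.model_confidence = scores.model_confidence
        if scores.pae is not None:
            report.ipae = ipae(model, scores.pae, chain_pair)
    return report


def classify_confident(report: InterfaceReport, scores: ScoreBundle | None,
                       pair_kind: str,
                       disordered_chain: str | None = None,
                       plddt_cutoff: float = CONFIDENCE_PLDDT_CUTOFF,
                       ordered_plddt_cutoff: float = CONFIDENCE_PLDDT_CUTOFF,
                       require_model_confidence: bool = False) -> bool:
    """Highly-confident call for one model.

    Disordered-ordered pairs: the disordered (motif) chain's interface pLDDT
    must be >= 70 (inclusive).  Ordered-ordered pairs: the average interface
    pLDDT must meet the threshold (default 70, configurable to 75), and when
    ``require_model_confidence`` is set additionally model confidence >= 0.7.
    Undefined metrics make the model not confident, with a warning.
    """
    if pair_kind == "disordered-ordered":
        if disordered_chain is None:
            raise ValueError("disordered_chain must be named for "
                             "disordered-ordered pairs")
        value = report.chain_interface_plddt.get(disordered_chain)
        if value is None:
            logger.warning("motif-chain interface pLDDT undefined; model "
                           "called not confident")
            return False
        return value >= plddt_cutoff
    if pair_kind == "ordered-ordered":
        value = report.average_interface_plddt
        if value is None:
            logger.warning("average interface pLDDT undefined; model called "
                           "not confident")
            return False
        if value < ordered_plddt_cutoff:
            return False
        if require_model_confidence:
            mc = scores.model_confidence if scores is not None else None
            if mc is None:
                logger.warning("model confidence undefined; model called not "
                               "confident")
                return False
            return mc >= MODEL_CONFIDENCE_CUTOFF
        return True
    raise ValueError(f"unknown pair_kind {pair_kind!r}")
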