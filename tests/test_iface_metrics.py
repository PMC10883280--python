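"""Interface detection against a brute-force oracle, and confidence metrics."""

import math

import numpy as np
import pytest

from conftest import make_point_model
from fragscore import iface_metrics
from fragscore.iface_metrics import (average_interface_plddt,
                                     chain_interface_plddt, classify_confident,
                                     compute_report, find_interface, ipae,
                                     pdockq)
from fragscore.model_io import PAEMatrix, ResidueKey, ScoreBundle
from fragscore.synthkit import SyntheticComplexSpec, make_complex_pair


def brute_force_interface(model, chain_a, chain_b, cutoff):
    """All-pairs reference scan: residue sets, residue pairs, atom pairs."""
    res_pairs, atom_pairs = set(), 0
    iface_a, iface_b = set(), set()
    for ra in model.chains[chain_a]:
        for rb in model.chains[chain_b]:
            hit = False
            for xa in ra.coords:
                for xb in rb.coords:
                    if np.linalg.norm(xa - xb) < cutoff:
                        atom_pairs += 1
                        hit = True
            if hit:
                res_pairs.add((ra.key, rb.key))
                iface_a.add(ra.key)
                iface_b.add(rb.key)
    return iface_a, iface_b, res_pairs, atom_pairs


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_interface_equals_brute_force_on_random_models(seed):
    rng = np.random.default_rng(seed)
    points_a = [tuple(p) for p in rng.uniform(0, 25, size=(60, 3))]
    points_b = [tuple(p) for p in rng.uniform(0, 25, size=(60, 3))]
    model = make_point_model({"A": points_a, "B": points_b})
    report = find_interface(model, ("A", "B"))
    iface_a, iface_b, res_pairs, atom_pairs = brute_force_interface(
        model, "A", "B", 5.0)
    assert report.interface_residues["A"] == iface_a
    assert report.interface_residues["B"] == iface_b
    assert report.residue_contacts == len(res_pairs)
    assert report.atom_contacts == atom_pairs


def test_strict_inequality_at_five_angstrom():
    near = make_point_model({"A": [(0, 0, 0)], "B": [(4.99, 0, 0)]})
    at = make_point_model({"A": [(0, 0, 0)], "B": [(5.00, 0, 0)]})
    r_near = find_interface(near, ("A", "B"))
    assert r_near.residue_contacts == 1 and r_near.atom_contacts == 1
    assert len(r_near.interface_residues["A"]) == 1
    r_at = find_interface(at, ("A", "B"))
    assert r_at.is_empty and r_at.atom_contacts == 0


def test_symmetry_of_chain_order():
    rng = np.random.default_rng(7)
    model = make_point_model({
        "A": [tuple(p) for p in rng.uniform(0, 15, size=(30, 3))],
        "B": [tuple(p) for p in rng.uniform(0, 15, size=(30, 3))],
    })
    fwd = find_interface(model, ("A", "B"))
    rev = find_interface(model, ("B", "A"))
    assert fwd.residue_contacts == rev.residue_contacts
    assert fwd.atom_contacts == rev.atom_contacts
    assert fwd.interface_residues["A"] == rev.interface_residues["A"]
    assert fwd.interface_residues["B"] == rev.interface_residues["B"]


class TestInterfacePlddt:
    def _two_residue_interface(self, plddts):
        model = make_point_model({
            "A": [(0, 0, 0)],
            "B": [(3, 0, 0), (0, 3, 0)],
        })
        keys = list(model.per_residue_plddt)
        for key, value in zip(keys, plddts):
            model.per_residue_plddt[key] = value
        return model

    def test_chain_mean(self):
        model = self._two_residue_interface([50.0, 80.0, 60.0])
        report = find_interface(model, ("A", "B"))
        assert chain_interface_plddt(report, model, "B") == pytest.approx(70.0)

    def test_pooled_mean_across_chains(self):
        model = self._two_residue_interface([90.0, 70.0, 80.0])
        report = find_interface(model, ("A", "B"))
        assert average_interface_plddt(report, model) == pytest.approx(80.0)

    def test_average_lies_between_chain_means(self):
        rng = np.random.default_rng(3)
        model = make_point_model({
            "A": [tuple(p) for p in rng.uniform(0, 8, size=(10, 3))],
            "B": [tuple(p) for p in rng.uniform(0, 8, size=(10, 3))],
        })
        for key in model.per_residue_plddt:
            model.per_residue_plddt[key] = float(rng.uniform(40, 95))
        report = find_interface(model, ("A", "B"))
        mean_a = chain_interface_plddt(report, model, "A")
        mean_b = chain_interface_plddt(report, model, "B")
        pooled = average_interface_plddt(report, model)
        assert min(mean_a, mean_b) - 1e-9 <= pooled <= max(mean_a, mean_b) + 1e-9

    def test_empty_interface_is_undefined_not_zero(self):
        model = make_point_model({"A": [(0, 0, 0)], "B": [(50, 0, 0)]})
        report = find_interface(model, ("A", "B"))
        assert chain_interface_plddt(report, model, "A") is None
        assert average_interface_plddt(report, model) is None


class TestPdockq:
    def test_zero_contacts_baseline(self):
        model = make_point_model({"A": [(0, 0, 0)], "B": [(100, 0, 0)]})
        expected = (iface_metrics.PDOCKQ_L
                    / (1 + math.exp(iface_metrics.PDOCKQ_K
                                    * iface_metrics.PDOCKQ_X0))
                    + iface_metrics.PDOCKQ_B)
        assert pdockq(model) == pytest.approx(expected)
        assert expected == pytest.approx(0.0183, abs=5e-4)

    def test_monotone_in_plddt(self):
        _, model, _ = make_complex_pair(SyntheticComplexSpec(
            plddt_domain=60, plddt_motif=60))
        low = pdockq(model)
        _, model_hi, _ = make_complex_pair(SyntheticComplexSpec(
            plddt_domain=95, plddt_motif=95))
        assert pdockq(model_hi) >= low

    def test_bounds(self):
        _, model, _ = make_complex_pair(SyntheticComplexSpec())
        value = pdockq(model)
        assert iface_metrics.PDOCKQ_B < value < \
            iface_metrics.PDOCKQ_L + iface_metrics.PDOCKQ_B


class TestIpae:
    def _model_and_pae(self, pae_fill=None):
        model = make_point_model({"A": [(0, 0, 0)], "B": [(3.0, 0, 0)]})
        keys = [ResidueKey(k.chain_id, k.residue_number, k.insertion_code)
                for k in model.residue_keys()]
        if pae_fill is None:
            values = np.full((2, 2), 10.0)
        else:
            values = np.asarray(pae_fill, dtype=float)
        return model, PAEMatrix(values=values, residue_index_map=keys)

    def test_constant_pae_returns_the_constant(self):
        model, pae = self._model_and_pae()
        assert ipae(model, pae) == pytest.approx(10.0)

    def test_median_pools_both_directions(self):
        model, pae = self._model_and_pae([[0.0, 4.0], [6.0, 0.0]])
        assert ipae(model, pae) == pytest.approx(5.0)

    def test_no_contact_at_3_5_is_undefined(self):
        model = make_point_model({"A": [(0, 0, 0)], "B": [(3.6, 0, 0)]})
        keys = [ResidueKey(k.chain_id, k.residue_number, k.insertion_code)
                for k in model.residue_keys()]
        pae = PAEMatrix(values=np.full((2, 2), 7.0), residue_index_map=keys)
        assert ipae(model, pae) is None

    def test_invariant_under_symmetrization_of_symmetric_matrix(self):
        model, pae = self._model_and_pae([[0.0, 8.0], [8.0, 0.0]])
        sym = PAEMatrix(values=(pae.values + pae.values.T) / 2,
                        residue_index_map=pae.residue_index_map)
        assert ipae(model, pae) == ipae(model, sym)


class TestConfidenceCall:
    def _report(self, motif_plddt, avg_plddt):
        report = find_interface(
            make_point_model({"A": [(0, 0, 0)], "B": [(3, 0, 0)]}), ("A", "B"))
        report.chain_interface_plddt = {"A": 90.0, "B": motif_plddt}
        report.average_interface_plddt = avg_plddt
        return report

    @pytest.mark.parametrize("plddt,expected", [
        (70.0, True),     # inclusive at the threshold
        (69.9, False),
        (None, False),    # undefined metric is never confident
    ])
    def test_motif_chain_rule(self, plddt, expected):
        report = self._report(plddt, 80.0)
        assert classify_confident(report, None, "disordered-ordered",
                                  disordered_chain="B") is expected

    def test_ordered_ordered_with_model_confidence_filter(self):
        report = self._report(90.0, 80.0)
        scores = ScoreBundle(iptm=0.6, ptm=0.6, model_confidence=0.6)
        assert classify_confident(report, scores, "ordered-ordered",
                                  require_model_confidence=True) is False
        scores.model_confidence = 0.7
        assert classify_confident(report, scores, "ordered-ordered",
                                  require_model_confidence=True) is True

    def test_ordered_ordered_alternative_cutoff(self):
        report = self._report(90.0, 73.0)
        assert classify_confident(report, None, "ordered-ordered") is True
        assert classify_confident(report, None, "ordered-ordered",
                                  ordered_plddt_cutoff=75.0) is False


def test_compute_report_populates_all_metrics(complex_zero):
    _, model, scores = complex_zero
    report = compute_report(model, scores)
    assert report.residue_contacts > 0
    assert report.average_interface_plddt is not None
    assert report.pdockq is not None
    assert report.model_confidence == pytest.approx(0.88)
    assert report.ipae == pytest.approx(5.0)  # inter-chain PAE fill value
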