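"""Superposition, motif RMSD categories and DockQ."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fragscore.evaluator import (ChainMapping, EvaluationError,
                                 categorize_rmsd, compute_dockq, dockq_quality,
                                 evaluate_model, extension_fold_change, kabsch,
                                 mean_pairwise_dockq, motif_all_atom_rmsd,
                                 rmsd, superpose_on_domain)
from fragscore.synthkit import SyntheticComplexSpec, make_complex_pair


def numeric_superposition_rmsd(mobile, reference):
    """Independent oracle: minimize RMSD over rotation vectors + translation."""
    mobile = np.asarray(mobile)
    reference = np.asarray(reference)

    def objective(params):
        rot = Rotation.from_rotvec(params[:3]).as_matrix()
        moved = mobile @ rot.T + params[3:]
        return np.mean(np.sum((moved - reference) ** 2, axis=1))

    shift = reference.mean(0) - mobile.mean(0)
    best = np.inf
    starts = [np.concatenate([np.zeros(3), shift])]
    for seed in range(5):
        rng = np.random.default_rng(seed)
        starts.append(np.concatenate([rng.uniform(-np.pi, np.pi, 3), shift]))
    for x0 in starts:
        res = minimize(objective, x0, method="BFGS",
                       options={"gtol": 1e-14, "maxiter": 10000})
        best = min(best, res.fun)
    return float(np.sqrt(best))


class TestKabsch:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_numeric_minimization(self, seed):
        rng = np.random.default_rng(seed)
        reference = rng.normal(size=(12, 3)) * 5
        rot = Rotation.from_rotvec(rng.normal(size=3)).as_matrix()
        mobile = (reference + rng.normal(scale=0.3, size=reference.shape)) \
            @ rot.T + rng.normal(size=3)
        transform = kabsch(mobile, reference)
        analytic = rmsd(transform.apply(mobile), reference)
        numeric = numeric_superposition_rmsd(mobile, reference)
        assert analytic == pytest.approx(numeric, abs=1e-6)
        assert analytic <= numeric + 1e-9  # Kabsch is the optimum

    def test_proper_rotation(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=(8, 3)), rng.normal(size=(8, 3))
        transform = kabsch(a, b)
        assert np.linalg.det(transform.rotation) == pytest.approx(1.0)

    def test_too_few_atoms_rejected(self):
        with pytest.raises(EvaluationError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))


class TestSuperposition:
    def test_identical_structures_superpose_to_zero(self, complex_zero,
                                                    mapping_ab):
        native, _, _ = complex_zero
        transform, domain_rmsd = superpose_on_domain(native, native, mapping_ab)
        assert domain_rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(transform.rotation, np.eye(3), atol=1e-9)

    def test_rigid_motion_invariance(self, complex_displaced, mapping_ab):
        native, model, _ = complex_displaced
        baseline = evaluate_model(model, native, mapping_ab).rmsd
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        shift = np.array([10.0, -4.0, 2.5])
        for residues in model.chains.values():
            for res in residues:
                res.coords = res.coords @ rot.T + shift
        moved = evaluate_model(model, native, mapping_ab).rmsd
        assert moved == pytest.approx(baseline, abs=1e-9)

    def test_displaced_domain_atom_rmsd_scaling(self, mapping_ab):
        native, _, _ = make_complex_pair(SyntheticComplexSpec())
        import copy
        model = copy.deepcopy(native)
        # nudge one domain atom by 1 A along +z
        model.chains["A"][0].coords[0] += np.array([0.0, 0.0, 1.0])
        mc = np.concatenate([r.coords for r in model.chains["A"]])
        nc = np.concatenate([r.coords for r in native.chains["A"]])
        _, domain_rmsd = superpose_on_domain(model, native, mapping_ab)
        numeric = numeric_superposition_rmsd(mc, nc)
        assert domain_rmsd == pytest.approx(numeric, abs=1e-6)
        # optimal fit cannot be worse than the unfitted 1/sqrt(N) value
        assert domain_rmsd <= 1.0 / np.sqrt(len(mc)) + 1e-9


class TestMotifRMSD:
    def test_uniform_displacement_gives_vector_norm(self, complex_displaced,
                                                    mapping_ab):
        native, model, _ = complex_displaced
        result = evaluate_model(model, native, mapping_ab)
        assert result.rmsd == pytest.approx(2.0, abs=1e-9)
        assert result.category == "correct_sidechain"
        assert result.accurate

    def test_identical_motif_is_zero(self, complex_zero, mapping_ab):
        native, _, _ = complex_zero
        result = evaluate_model(native, native, mapping_ab)
        assert result.rmsd == pytest.approx(0.0, abs=1e-9)
        assert result.category == "correct_sidechain"

    def test_sixteen_angstrom_is_wrong_pocket(self, mapping_ab):
        native, model, _ = make_complex_pair(
            SyntheticComplexSpec(displacement=(0.0, 0.0, 16.0)))
        result = evaluate_model(model, native, mapping_ab)
        assert result.rmsd == pytest.approx(16.0, abs=1e-9)
        assert result.category == "wrong_pocket"
        assert not result.accurate

    @pytest.mark.parametrize("value,category", [
        (0.0, "correct_sidechain"),
        (2.0, "correct_sidechain"),
        (2.0001, "correct_backbone"),
        (5.0, "correct_backbone"),
        (5.0001, "correct_pocket"),
        (15.0, "correct_pocket"),
        (15.0001, "wrong_pocket"),
        (100.0, "wrong_pocket"),
    ])
    def test_category_partition_boundaries(self, value, category):
        assert categorize_rmsd(value) == category

    def test_every_nonnegative_rmsd_has_exactly_one_category(self):
        for value in np.linspace(0, 30, 301):
            assert categorize_rmsd(float(value)) in {
                "correct_sidechain", "correct_backbone", "correct_pocket",
                "wrong_pocket"}


class TestDockQ:
    def test_self_dockq_is_one(self, complex_zero, mapping_ab):
        native, _, _ = complex_zero
        result = compute_dockq(native, native, mapping_ab)
        assert result.fnat == pytest.approx(1.0)
        assert result.irms == pytest.approx(0.0, abs=1e-6)
        assert result.lrms == pytest.approx(0.0, abs=1e-6)
        assert result.dockq == pytest.approx(1.0, abs=1e-9)
        assert result.quality == "high"

    def test_displaced_model_scores_below_one(self, complex_displaced,
                                              mapping_ab):
        native, model, _ = complex_displaced
        result = compute_dockq(model, native, mapping_ab)
        assert 0.0 < result.dockq < 1.0

    @pytest.mark.parametrize("score,quality", [
        (0.22, "incorrect"),
        (0.23, "acceptable"),
        (0.48, "acceptable"),
        (0.49, "medium"),
        (0.79, "medium"),
        (0.80, "high"),
        (1.0, "high"),
    ])
    def test_quality_thresholds(self, score, quality):
        assert dockq_quality(score) == quality


class TestMeanPairwiseDockq:
    def _ranked_models(self, displacements):
        models = []
        for rank, disp in enumerate(displacements):
            _, model, _ = make_complex_pair(SyntheticComplexSpec(
                displacement=disp, rank=rank, model_id=f"m{rank}"))
            models.append(model)
        return models

    def test_identical_models_give_one(self):
        models = self._ranked_models([(0, 0, 0)] * 5)
        assert mean_pairwise_dockq(models) == pytest.approx(1.0, abs=1e-9)

    def test_two_models_single_pair(self, mapping_ab):
        models = self._ranked_models([(0, 0, 0), (0, 0, 3.0)])
        single = compute_dockq(models[1], models[0], mapping_ab).dockq
        assert mean_pairwise_dockq(models) == pytest.approx(single)

    def test_three_models_average_of_three_pairs(self, mapping_ab):
        models = self._ranked_models([(0, 0, 0), (0, 0, 2.0), (0, 0, 4.0)])
        pairs = [compute_dockq(models[j], models[i], mapping_ab).dockq
                 for i in range(3) for j in range(i + 1, 3)]
        assert mean_pairwise_dockq(models) == pytest.approx(np.mean(pairs))

    def test_single_model_is_undefined(self):
        with pytest.raises(EvaluationError):
            mean_pairwise_dockq(self._ranked_models([(0, 0, 0)]))


@pytest.mark.parametrize("minimal,extended,expected", [
    (4.0, 2.0, 1.0),
    (3.0, 3.0, 0.0),
    (2.0, 4.0, -1.0),
])
def test_extension_fold_change(minimal, extended, expected):
    assert extension_fold_change(minimal, extended) == pytest.approx(expected)


def test_extension_fold_change_rejects_nonpositive():
    with pytest.raises(ValueError):
        extension_fold_change(0.0, 1.0)
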