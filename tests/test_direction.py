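import numpy as np
import pytest

from chardir.direction import (
    CharacteristicDirection,
    DirectionError,
    characteristic_direction,
    gene_significance,
    pca_overview,
    project_samples,
)
from chardir.expr_io import GeneSet
from chardir.synthetic import SimulationSpec, simulate_two_class
from .conftest import make_annotation, make_matrix


def dense_direction_oracle(V, mask, gamma):
    """Independent dense solve of ((1-γ)Σ_pooled + γI) b = μ_case − μ_ctrl."""
    p = V.shape[0]
    case, ctrl = V[:, mask], V[:, ~mask]
    d = case.mean(axis=1) - ctrl.mean(axis=1)
    Sc = (case - case.mean(axis=1, keepdims=True))
    Sk = (ctrl - ctrl.mean(axis=1, keepdims=True))
    pooled = (Sc @ Sc.T + Sk @ Sk.T) / (V.shape[1] - 2)
    b = np.linalg.solve((1 - gamma) * pooled + gamma * np.eye(p), d)
    b = b / np.linalg.norm(b)
    if b @ d < 0:
        b = -b
    return b


class TestCharacteristicDirection:
    def test_gamma_one_reduces_to_mean_difference(self):
        # class means differ only in gene 0 (Δ = +2); shrinkage to identity
        # must give the axis-aligned unit vector
        vals = np.array([[3.0, 3.0, 1.0, 1.0], [2.0, 2.0, 2.0, 2.0]])
        em = make_matrix(vals, samples=["c0", "c1", "k0", "k1"])
        ann = make_annotation(["c0", "c1"], ["k0", "k1"])
        cd = characteristic_direction(em, ann, gamma=1.0)
        np.testing.assert_allclose(cd.b, [1.0, 0.0], atol=1e-12)

    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9])
    def test_matches_dense_oracle_small(self, two_class_8, gamma):
        em, ann = two_class_8
        cd = characteristic_direction(em, ann, gamma=gamma)
        mask = ann.class_mask(em.sample_ids)
        expected = dense_direction_oracle(em.values, mask, gamma)
        np.testing.assert_allclose(cd.b, expected, atol=1e-10)

    def test_woodbury_path_matches_dense_oracle(self):
        # more genes than samples exercises the n×n Woodbury solve
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(50, 10))
        vals[:5, :5] += 1.5
        samples = [f"c{i}" for i in range(5)] + [f"k{i}" for i in range(5)]
        em = make_matrix(vals, samples=samples)
        ann = make_annotation(samples[:5], samples[5:])
        cd = characteristic_direction(em, ann, gamma=0.5)
        expected = dense_direction_oracle(vals, ann.class_mask(samples), 0.5)
        np.testing.assert_allclose(cd.b, expected, atol=1e-10)

    def test_gene_permutation_equivariance(self, two_class_8):
        em, ann = two_class_8
        cd = characteristic_direction(em, ann, gamma=0.5)
        perm = [2, 0, 1]
        em_p = make_matrix(em.values[perm], genes=[em.gene_ids[i] for i in perm],
                           samples=em.sample_ids)
        cd_p = characteristic_direction(em_p, ann, gamma=0.5)
        np.testing.assert_allclose(cd_p.b, cd.b[perm], atol=1e-12)

    def test_unit_norm_and_sign_convention(self, two_class_8):
        em, ann = two_class_8
        cd = characteristic_direction(em, ann, gamma=0.5)
        assert abs(np.linalg.norm(cd.b) - 1) < 1e-9
        scores = project_samples(cd, em)
        mask = ann.class_mask(em.sample_ids)
        assert scores.scores[mask].mean() >= scores.scores[~mask].mean()

    def test_small_class_rejected(self):
        em = make_matrix(np.zeros((2, 3)), samples=["a", "b", "c"])
        ann = make_annotation(["a"], ["b", "c"])
        with pytest.raises(DirectionError, match=">=2 samples"):
            characteristic_direction(em, ann)

    def test_gamma_zero_singular_instructs_regularization(self):
        rng = np.random.default_rng(2)
        samples = [f"c{i}" for i in range(3)] + [f"k{i}" for i in range(3)]
        em = make_matrix(rng.normal(size=(20, 6)), samples=samples)
        ann = make_annotation(samples[:3], samples[3:])
        with pytest.raises(DirectionError, match="gamma > 0"):
            characteristic_direction(em, ann, gamma=0.0)


class TestGeneSignificance:
    def test_requires_enough_permutations(self, two_class_8):
        em, ann = two_class_8
        cd = characteristic_direction(em, ann)
        with pytest.raises(DirectionError, match="n_perm"):
            gene_significance(cd, em, ann, n_perm=50)

    def test_constant_gene_hits_pseudocount_ceiling(self):
        # a gene identical in every sample contributes b_i = 0 both observed
        # and in every permutation, so the inclusive tail gives p = 1 exactly
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(4, 8))
        vals[0, :4] += 3
        vals[3, :] = 5.0
        samples = [f"c{i}" for i in range(4)] + [f"k{i}" for i in range(4)]
        em = make_matrix(vals, samples=samples)
        ann = make_annotation(samples[:4], samples[4:])
        cd = characteristic_direction(em, ann, gamma=1.0)
        cd = gene_significance(cd, em, ann, n_perm=100, seed=0)
        assert cd.p[3] == 1.0

    def test_reproducible_under_seed_and_planted_recovery(self):
        spec = SimulationSpec(n_genes=300, n_case=20, n_ctrl=20, planted_up=5,
                              planted_down=5, effect_size=3.0, seed=11)
        em, ann, up, down = simulate_two_class(spec)
        cd = characteristic_direction(em, ann)
        r1 = gene_significance(cd, em, ann, n_perm=1000, seed=5)
        r2 = gene_significance(cd, em, ann, n_perm=1000, seed=5)
        np.testing.assert_array_equal(r1.p, r2.p)
        planted = up.genes | down.genes
        hits = sum(r1.q[r1.gene_ids.index(g)] < 0.05 for g in planted)
        assert hits >= 9


class TestProjection:
    def test_axis_direction_gives_centered_gene(self, two_class_8):
        em, _ = two_class_8
        b = np.zeros(3)
        b[0] = 1.0
        cd = CharacteristicDirection(em.gene_ids, b, gamma=1.0)
        scores = project_samples(cd, em)
        expected = em.values[0] - em.values[0].mean()
        np.testing.assert_allclose(scores.scores, expected, atol=1e-12)

    def test_subset_with_zero_contributions_scores_zero(self, two_class_8):
        em, _ = two_class_8
        cd = CharacteristicDirection(em.gene_ids, np.array([1.0, 0.0, 0.0]), gamma=1.0)
        subset = GeneSet.from_iterable("nullset", [em.gene_ids[1], em.gene_ids[2]])
        scores = project_samples(cd, em, subset=subset)
        np.testing.assert_allclose(scores.scores, 0.0, atol=1e-12)

    def test_centering_invariance(self, two_class_8):
        em, ann = two_class_8
        cd = characteristic_direction(em, ann)
        shifted = make_matrix(em.values + np.array([[10.0], [-3.0], [0.5]]),
                              genes=em.gene_ids, samples=em.sample_ids)
        s0 = project_samples(cd, em)
        s1 = project_samples(cd, shifted)
        np.testing.assert_allclose(s0.scores, s1.scores, atol=1e-9)

    def test_disjoint_gene_space_is_error(self, two_class_8):
        em, ann = two_class_8
        cd = characteristic_direction(em, ann)
        other = make_matrix(np.zeros((2, 2)), genes=["X", "Y"])
        with pytest.raises(DirectionError, match="share no genes"):
            project_samples(cd, other)

    def test_separation_on_well_separated_data(self):
        spec = SimulationSpec(n_genes=500, n_case=15, n_ctrl=15, planted_up=10,
                              planted_down=10, effect_size=3.0, seed=7)
        em, ann, *_ = simulate_two_class(spec)
        cd = characteristic_direction(em, ann)
        scores = project_samples(cd, em)
        mask = ann.class_mask(em.sample_ids)
        assert scores.scores[mask].min() > scores.scores[~mask].max()


class TestPCAOverview:
    def test_pc1_separates_two_clusters(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 0.05, (10, 12))
        vals[0, :6] += 5.0   # displacement along one gene
        em = make_matrix(vals)
        res = pca_overview(em, k=2)
        pc1 = res.coords["PC1"].to_numpy()
        assert res.explained_variance_ratio[0] > 0.9
        assert max(pc1[:6].min(), pc1[6:].min()) > min(pc1[:6].max(), pc1[6:].max()) \
            or (pc1[:6].max() < pc1[6:].min() or pc1[6:].max() < pc1[:6].min())

    def test_per_gene_offset_leaves_coordinates_unchanged(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(8, 6))
        em = make_matrix(vals)
        shifted = make_matrix(vals + rng.normal(size=(8, 1)))
        a = pca_overview(em, k=3).coords
        b = pca_overview(shifted, k=3).coords
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    @pytest.mark.parametrize("k", [0, 99])
    def test_bad_k_rejected(self, k):
        em = make_matrix(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(DirectionError):
            pca_overview(em, k=k)

    def test_k_beyond_rank_rejected(self):
        vals = np.outer(np.arange(1.0, 6.0), np.ones(4))  # rank 0 after centering
        em = make_matrix(vals)
        with pytest.raises(DirectionError, match="rank"):
            pca_overview(em, k=2)
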