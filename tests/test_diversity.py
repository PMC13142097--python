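import itertools

import numpy as np
import pytest
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from pdzflex.diversity import (
    PairwiseMatrix,
    flat_clusters,
    hierarchical_cluster,
    inter_cluster_distance,
    pairwise_rmsd_matrix,
    per_residue_avg_rmsd,
    tree_to_newick,
)
from pdzflex.errors import InvalidDistanceMatrixError, PdzflexError
from pdzflex.profiles import ResidueProfile, call_regions
from pdzflex.structure import build_ensemble, extract_domain
from pdzflex.superpose import kabsch_superpose
from pdzflex.synthetic import SyntheticEnsembleSpec, make_crystal_set

from conftest import random_rotation
from test_superpose import make_instance


def block_matrix(sizes, within, between, rng=None, jitter=0.0):
    """Distance matrix with dense blocks; optional symmetric jitter."""
    n = sum(sizes)
    labels = [f"m{i:02d}" for i in range(n)]
    groups = np.repeat(np.arange(len(sizes)), sizes)
    values = np.where(groups[:, None] == groups[None, :], within, between).astype(float)
    if jitter and rng is not None:
        noise = rng.uniform(0, jitter, size=(n, n))
        noise = (noise + noise.T) / 2
        values = values + noise
    np.fill_diagonal(values, 0.0)
    return PairwiseMatrix(labels=labels, values=values), {
        lab: int(g) for lab, g in zip(labels, groups)
    }


class TestPairwiseMatrix:
    def test_identical_members_zero_matrix(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3)) * 5
        ens = build_ensemble([make_instance(f"m{i}", coords) for i in range(3)])
        mat = pairwise_rmsd_matrix(ens)
        assert np.allclose(mat.values, 0.0, atol=1e-10)

    def test_twenty_members_has_190_pairs(self, pdz1_ensemble):
        mat = pairwise_rmsd_matrix(pdz1_ensemble)
        n = mat.n
        assert n * (n - 1) // 2 == 190
        off_diag = mat.values[np.triu_indices(n, 1)]
        assert np.all(off_diag > 0)
        assert np.allclose(mat.values, mat.values.T, atol=1e-8)

    def test_rigid_pair_plus_perturbed_member(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(15, 3)) * 5
        rot = random_rotation(rng)
        moved = coords @ rot.T + np.array([1.0, -2.0, 0.5])
        perturbed = coords + rng.normal(scale=0.6, size=coords.shape)
        ens = build_ensemble(
            [
                make_instance("a", coords),
                make_instance("b", moved),
                make_instance("c", perturbed),
            ]
        )
        mat = pairwise_rmsd_matrix(ens)
        assert mat.value("a", "b") <= 1e-8
        assert abs(mat.value("a", "c") - mat.value("b", "c")) <= 1e-6

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(InvalidDistanceMatrixError):
            PairwiseMatrix(labels=["a", "b"], values=np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestHierarchicalCluster:
    def test_hand_computed_upgma_heights(self):
        """d(1,2)=1, d(1,3)=d(2,3)=4: merge at 1, then at (4+4)/2 = 4."""
        mat = PairwiseMatrix(
            labels=["s1", "s2", "s3"],
            values=np.array([[0.0, 1.0, 4.0], [1.0, 0.0, 4.0], [4.0, 4.0, 0.0]]),
        )
        tree = hierarchical_cluster(mat, linkage="average")
        assert len(tree.merges) == 2
        (a1, b1, h1), (a2, b2, h2) = tree.merges
        assert {a1, b1} == {("s1",), ("s2",)}
        assert h1 == pytest.approx(1.0)
        assert h2 == pytest.approx(4.0)

    def test_n_minus_one_merges_and_monotone_heights(self, pdz1_ensemble):
        mat = pairwise_rmsd_matrix(pdz1_ensemble)
        tree = hierarchical_cluster(mat)
        assert len(tree.merges) == mat.n - 1
        heights = tree.heights
        assert all(h2 >= h1 - 1e-12 for h1, h2 in zip(heights, heights[1:]))

    @pytest.mark.parametrize("linkage", ["average", "single", "complete"])
    def test_heights_match_scipy_linkage(self, linkage):
        rng = np.random.default_rng(42)
        mat, _ = block_matrix([4, 4], within=0.5, between=5.0, rng=rng, jitter=0.4)
        tree = hierarchical_cluster(mat, linkage=linkage)
        z = sch.linkage(squareform(mat.values, checks=False), method=linkage)
        assert np.allclose(sorted(tree.heights), sorted(z[:, 2]), atol=1e-10)

    def test_newick_export_parses(self, pdz1_ensemble):
        mat = pairwise_rmsd_matrix(pdz1_ensemble)
        text = tree_to_newick(hierarchical_cluster(mat))
        assert text.endswith(";")
        assert text.count("(") == mat.n - 1
        for lab in mat.labels:
            assert lab.replace(":", "_") in text


class TestFlatClusters:
    def test_k_equals_n_gives_singletons(self):
        mat, _ = block_matrix([3, 3], within=1.0, between=5.0)
        tree = hierarchical_cluster(mat)
        assignment = flat_clusters(tree, k=mat.n)
        assert len(set(assignment.values())) == mat.n

    def test_k_one_gives_single_cluster(self):
        mat, _ = block_matrix([3, 3], within=1.0, between=5.0)
        assignment = flat_clusters(hierarchical_cluster(mat), k=1)
        assert set(assignment.values()) == {0}

    def test_two_block_recovery_ari(self):
        rng = np.random.default_rng(5)
        mat, truth = block_matrix([6, 5], within=0.4, between=5.0, rng=rng, jitter=0.3)
        assignment = flat_clusters(hierarchical_cluster(mat), k=2)
        labels = mat.labels
        ari = adjusted_rand_score(
            [truth[l] for l in labels], [assignment[l] for l in labels]
        )
        assert ari == pytest.approx(1.0)

    def test_k_out_of_range(self):
        mat, _ = block_matrix([2, 2], within=1.0, between=5.0)
        tree = hierarchical_cluster(mat)
        with pytest.raises(ValueError):
            flat_clusters(tree, k=0)
        with pytest.raises(ValueError):
            flat_clusters(tree, k=5)

    def test_stable_under_permutation(self):
        rng = np.random.default_rng(6)
        mat, _ = block_matrix([4, 4], within=0.4, between=5.0, rng=rng, jitter=0.2)
        assignment = flat_clusters(hierarchical_cluster(mat), k=2)
        perm = rng.permutation(mat.n)
        mat2 = PairwiseMatrix(
            labels=[mat.labels[i] for i in perm],
            values=mat.values[np.ix_(perm, perm)],
        )
        assignment2 = flat_clusters(hierarchical_cluster(mat2), k=2)
        assert assignment == assignment2


class TestInterClusterDistance:
    def test_two_singletons(self):
        mat = PairwiseMatrix(labels=["a", "b"], values=np.array([[0.0, 3.0], [3.0, 0.0]]))
        d = inter_cluster_distance(mat, {"a": 0, "b": 1})
        assert d[(0, 1)] == pytest.approx(3.0)

    def test_uniform_cross_block(self):
        mat, truth = block_matrix([3, 3], within=1.0, between=5.0)
        d = inter_cluster_distance(mat, truth)
        assert d[(0, 1)] == pytest.approx(5.0)

    def test_mean_aggregation_of_mixed_cross_pairs(self):
        values = np.array([[0.0, 1.0, 4.0, 6.0], [1.0, 0.0, 6.0, 4.0],
                           [4.0, 6.0, 0.0, 1.0], [6.0, 4.0, 1.0, 0.0]])
        mat = PairwiseMatrix(labels=list("abcd"), values=values)
        d = inter_cluster_distance(mat, {"a": 0, "b": 0, "c": 1, "d": 1})
        assert d[(0, 1)] == pytest.approx(5.0)  # mean of {4, 6, 6, 4}

    def test_single_cluster_rejected(self):
        mat, _ = block_matrix([2, 2], within=1.0, between=5.0)
        with pytest.raises(PdzflexError):
            inter_cluster_distance(mat, {lab: 0 for lab in mat.labels})


class TestPerResidueProfile:
    def test_identical_members_all_zero(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(10, 3)) * 5
        ens = build_ensemble([make_instance(f"m{i}", coords) for i in range(4)])
        prof = per_residue_avg_rmsd(ens)
        assert np.allclose(prof.values, 0.0, atol=1e-10)

    def test_rigid_core_fit_isolates_displacement(self):
        """Fit on an identical 20-residue core; a 2 A displaced residue shows 2.0."""
        rng = np.random.default_rng(3)
        core = rng.normal(size=(20, 3)) * 5
        a = np.vstack([core, [[0.0, 0.0, 0.0]]])
        b = np.vstack([core, [[0.0, 0.0, 2.0]]])
        ens = build_ensemble([make_instance("a", a), make_instance("b", b)])
        prof = per_residue_avg_rmsd(ens, fit_selection=np.arange(20))
        assert prof.values[:20] == pytest.approx(0.0, abs=1e-8)
        assert prof.values[20] == pytest.approx(2.0, abs=1e-8)

    def test_loop_exceeds_scaffold_by_over_fivefold(self, pdz1_ensemble, crystal_models):
        _, truth = crystal_models
        prof = per_residue_avg_rmsd(pdz1_ensemble)
        loop_mask = np.zeros(len(prof), dtype=bool)
        for reg in truth["flexible_regions"]:
            loop_mask |= (prof.residues >= reg["first"]) & (prof.residues <= reg["last"])
        assert prof.values[loop_mask].mean() > 5 * prof.values[~loop_mask].mean()

    def test_within_group_restriction(self, pdz1_ensemble):
        groups = {m.label: m.chain_id for m in pdz1_ensemble.members}
        prof_b = per_residue_avg_rmsd(pdz1_ensemble, groups=groups)
        prof_all = per_residue_avg_rmsd(pdz1_ensemble)
        assert prof_b.values.shape == prof_all.values.shape
        assert not np.allclose(prof_b.values, prof_all.values)

    def test_empty_pair_set_rejected(self, pdz1_ensemble):
        groups = {lab: i for i, lab in enumerate(pdz1_ensemble.labels)}
        with pytest.raises(PdzflexError):
            per_residue_avg_rmsd(pdz1_ensemble, groups=groups)

    def test_matrix_profile_consistency(self, pdz1_ensemble):
        """With fit on all residues, mean squared per-site deviation == rmsd^2."""
        mat = pairwise_rmsd_matrix(pdz1_ensemble)
        for i, j in [(0, 1), (3, 17), (8, 9)]:
            res = kabsch_superpose(pdz1_ensemble.coords[i], pdz1_ensemble.coords[j])
            assert np.mean(res.per_site_deviation**2) == pytest.approx(
                mat.values[i, j] ** 2, rel=1e-10
            )

    def test_permutation_equivariance(self, crystal_models):
        models, _ = crystal_models
        instances = [
            extract_domain(m, c, 114, 193, "PDZ1") for m in models[:4] for c in ("A", "B")
        ]
        ens = build_ensemble(instances)
        ens_rev = build_ensemble(instances[::-1])
        mat = pairwise_rmsd_matrix(ens)
        mat_rev = pairwise_rmsd_matrix(ens_rev)
        perm = [mat.labels.index(lab) for lab in mat_rev.labels]
        assert np.allclose(mat_rev.values, mat.values[np.ix_(perm, perm)], atol=1e-10)
        assert np.allclose(
            per_residue_avg_rmsd(ens).values,
            per_residue_avg_rmsd(ens_rev).values,
            atol=1e-10,
        )


class TestCallRegions:
    def profile(self, residues, values):
        return ResidueProfile(np.array(residues), np.array(values), kind="test")

    def test_single_contiguous_region(self):
        residues = list(range(114, 194))
        values = [0.2] * 80
        for r in range(119, 126):
            values[r - 114] = 1.8
        regions = call_regions(self.profile(residues, values), threshold=1.0)
        assert [(r.first, r.last) for r in regions] == [(119, 125)]
        assert regions[0].peak == pytest.approx(1.8)

    def test_all_below_threshold(self):
        prof = self.profile(range(10), [0.3] * 10)
        assert call_regions(prof, threshold=1.0) == []

    def test_min_length_semantics(self):
        prof = self.profile(range(10), [0.1, 2.0, 0.1, 0.1, 2.0, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert call_regions(prof, threshold=1.0, min_length=2) == []
        singles = call_regions(prof, threshold=1.0, min_length=1)
        assert [(r.first, r.last) for r in singles] == [(1, 1), (4, 4)]

    def test_numbering_gap_breaks_run(self):
        residues = [1, 2, 3, 7, 8, 9]  # gap between 3 and 7
        prof = self.profile(residues, [2.0] * 6)
        regions = call_regions(prof, threshold=1.0)
        assert [(r.first, r.last) for r in regions] == [(1, 3), (7, 9)]

    def test_boundary_value_is_excluded(self):
        prof = self.profile(range(5), [1.0] * 5)
        assert call_regions(prof, threshold=1.0) == []


def test_chain_asymmetry_detected(pdz1_ensemble):
    """Within-free (chain B) mean pairwise RMSD exceeds within-restrained (A)."""
    mat = pairwise_rmsd_matrix(pdz1_ensemble)
    chains = {lab: lab.split(":")[1] for lab in mat.labels}

    def within(chain):
        idx = [i for i, lab in enumerate(mat.labels) if chains[lab] == chain]
        return np.mean([mat.values[i, j] for i, j in itertools.combinations(idx, 2)])

    assert within("B") > within("A")
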