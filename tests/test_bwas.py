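"""Edge-wise GLM, cluster formation and permutation FWER inference."""

import numpy as np
import pytest
from scipy import stats

from bwaskit import bwas
from bwaskit.connectome import ConnectomeStack
from tests.conftest import cohort_stack, grid_voxelset, null_config, planted_config
from tests.oracles import brute_force_fc_clusters, random_cluster_instance


def _stack_from_values(values, shape=(6, 6, 6), coords=None, labels=None):
    n_edges = values.shape[1]
    n_vox = int((1 + np.sqrt(1 + 8 * n_edges)) / 2)
    if coords is None:
        vs = grid_voxelset(shape)
        vs = type(vs)(np.arange(n_vox), vs.coords[:n_vox], np.zeros(n_vox, int),
                      shape)
    else:
        vs = type(grid_voxelset((2, 2, 2)))(
            np.arange(n_vox), coords,
            labels if labels is not None else np.zeros(n_vox, int), shape)
    ids = [f"S{i}" for i in range(values.shape[0])]
    return ConnectomeStack(ids, vs, values)


class TestEdgeGLM:
    def test_matches_pooled_two_sample_t(self):
        """With no covariates the GLM group z equals the t->z-mapped
        equal-variance two-sample t statistic."""
        rng = np.random.default_rng(0)
        n1, n2, e = 12, 14, 21  # 21 edges = 7-voxel upper triangle
        y = rng.standard_normal((n1 + n2, e))
        group = np.r_[np.ones(n1), np.zeros(n2)]
        stack = _stack_from_values(y)
        design = bwas.Design(group, np.empty((n1 + n2, 0)),
                             list(stack.subject_ids))
        res = bwas.edge_glm(stack, design)
        t, _ = stats.ttest_ind(y[:n1], y[n1:], equal_var=True)
        z_oracle = np.sign(t) * stats.norm.isf(stats.t.sf(np.abs(t), n1 + n2 - 2))
        np.testing.assert_allclose(res.z, z_oracle, atol=1e-10)

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            bwas.Design(np.ones(10), np.empty((10, 0)), list(range(10)))

    def test_collinear_design_rejected(self):
        group = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError, match="rank deficient"):
            bwas.Design(group, group[:, None], list(range(10)))

    def test_subject_mismatch_rejected(self):
        stack = _stack_from_values(np.random.default_rng(1).normal(size=(10, 6)))
        design = bwas.Design(np.r_[np.ones(5), np.zeros(5)],
                             np.empty((10, 0)), list(range(10)))
        with pytest.raises(ValueError, match="subjects"):
            bwas.edge_glm(stack, design)

    def test_global_null_z_is_standard_normal(self):
        """Pooled edge z over null replicates passes a KS normality test."""
        zs = []
        for seed in range(10):
            stack, pheno, _ = cohort_stack(null_config(seed))
            design = bwas.design_from_phenotypes(pheno)
            zs.append(bwas.edge_glm(stack, design).z)
        p = stats.kstest(np.concatenate(zs), "norm").pvalue
        assert p > 0.01

    def test_z_invariant_to_subject_reordering(self):
        stack, pheno, _ = cohort_stack(null_config(3))
        design = bwas.design_from_phenotypes(pheno)
        z0 = bwas.edge_glm(stack, design).z
        order = list(np.random.default_rng(0).permutation(len(pheno)))
        ph2 = pheno.iloc[order].reset_index(drop=True)
        z1 = bwas.edge_glm(stack.subset(list(ph2["subject_id"])),
                           bwas.design_from_phenotypes(ph2)).z
        np.testing.assert_allclose(z0, z1, atol=1e-10)


class TestCDT:
    @pytest.mark.parametrize("p, z", [(2e-8, 5.5), (3e-7, 5.0)])
    def test_printed_p_z_pairs(self, p, z):
        assert round(bwas.cdt_from_p(p), 1) == z

    def test_boundary_rejected(self):
        for bad in (0.5, 0.0, 1.0, -1e-9):
            with pytest.raises(ValueError):
                bwas.cdt_from_p(bad)

    def test_two_sided_splits_the_tail(self):
        assert bwas.cdt_from_p(0.05, "two") == pytest.approx(
            stats.norm.isf(0.025))


class TestClusterFormation:
    def test_single_isolated_edge(self):
        coords = np.array([[0, 0, 0], [5, 5, 5]])
        z = np.array([6.0])
        clusters = bwas.form_fc_clusters(
            z, grid_voxelset((6, 6, 6)).__class__(
                np.arange(2), coords, np.zeros(2, int), (6, 6, 6)),
            5.0)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.size == 1 and (cl.n_increased, cl.n_decreased) == (1, 0)

    def test_hand_built_two_by_two(self):
        """A1,A2 adjacent; B1,B2 adjacent; edges A1-B1, A1-B2, A2-B1 form one
        FC cluster of size 3."""
        coords = np.array([[0, 0, 0], [0, 0, 1], [4, 4, 4], [4, 4, 5]])
        vs = grid_voxelset((6, 6, 6)).__class__(
            np.arange(4), coords, np.zeros(4, int), (6, 6, 6))
        z = np.zeros(6)
        iu, ju = np.triu_indices(4, 1)
        for a, b in [(0, 2), (0, 3), (1, 2)]:
            z[np.flatnonzero((iu == a) & (ju == b))[0]] = 6.0
        clusters = bwas.form_fc_clusters(z, vs, 5.0)
        assert len(clusters) == 1 and clusters[0].size == 3

    def test_intra_cluster_edges_excluded_but_logged(self):
        coords = np.array([[0, 0, 0], [0, 0, 1]])
        vs = grid_voxelset((6, 6, 6)).__class__(
            np.arange(2), coords, np.zeros(2, int), (6, 6, 6))
        clusters, intra = bwas.form_fc_clusters(
            np.array([6.0]), vs, 5.0, return_intra=True)
        assert clusters == [] and len(intra) == 1

    def test_empty_suprathreshold_set(self):
        vs = grid_voxelset((3, 3, 3))
        assert bwas.form_fc_clusters(np.zeros(vs.ids.size * (vs.ids.size - 1) // 2),
                                     vs, 5.0) == []

    def test_matches_brute_force_on_random_instances(self):
        """Connected-components + pair-grouping oracle equivalence."""
        rng = np.random.default_rng(42)
        VS = grid_voxelset((2, 2, 2)).__class__
        for _ in range(300):
            coords, edges, zvals = random_cluster_instance(rng)
            n = len(coords)
            vs = VS(np.arange(n), coords, np.zeros(n, int), (6, 6, 6))
            z = np.zeros(n * (n - 1) // 2)
            iu, ju = np.triu_indices(n, 1)
            emap = {(i, j): k for k, (i, j) in enumerate(zip(iu, ju))}
            for (i, j), v in zip(edges, zvals):
                z[emap[(i, j)]] = v
            got, got_intra = bwas.form_fc_clusters(z, vs, 3.0, return_intra=True)
            want, want_intra = brute_force_fc_clusters(
                edges, zvals, {k: c for k, c in enumerate(coords)})
            assert {frozenset(cl.edges) for cl in got} == want
            assert {(i, j) for i, j, _ in got_intra} == want_intra

    def test_nested_under_rising_cdt(self):
        """Raising the CDT never admits new edges: every edge of a
        higher-CDT cluster was already supra-threshold at the lower CDT
        (in a cluster there, or logged as within-voxel-cluster when the
        lower threshold merged its endpoints into one spatial component)."""
        stack, pheno, _ = cohort_stack(planted_config(9, n_per_group=20,
                                                      n_timepoints=120))
        res = bwas.edge_glm(stack, bwas.design_from_phenotypes(pheno))
        lo, lo_intra = bwas.form_fc_clusters(res, stack.voxels, 2.5,
                                             return_intra=True)
        hi = bwas.form_fc_clusters(res, stack.voxels, 3.5)
        lo_edges = {e for cl in lo for e in cl.edges}
        lo_edges |= {(i, j) for i, j, _ in lo_intra}
        hi_edges = {e for cl in hi for e in cl.edges}
        assert hi_edges <= lo_edges
        assert len(hi_edges) <= len(lo_edges)


class TestFWERInference:
    def test_corrected_p_lower_bound(self):
        stack, pheno, _ = cohort_stack(planted_config(1, n_per_group=20,
                                                      n_timepoints=120))
        design = bwas.design_from_phenotypes(pheno)
        clusters, _ = bwas.fwer_cluster_inference(stack, design, 3.5,
                                                  n_perm=99, seed=0)
        assert clusters
        for cl in clusters:
            assert cl.corrected_p >= 1 / 100

    def test_planted_pair_detected(self):
        cfg = planted_config(11)
        stack, pheno, truth = cohort_stack(cfg)
        design = bwas.design_from_phenotypes(pheno)
        clusters, _ = bwas.fwer_cluster_inference(stack, design, 4.0,
                                                  n_perm=199, seed=1)
        sig = [cl for cl in clusters if cl.corrected_p < 0.05]
        assert sig
        planted = {tuple(sorted(p)) for p in
                   truth.planted_voxel_pairs[0]["voxel_pairs"]}
        best = max(sig, key=lambda c: c.size)
        assert set(best.edges) <= planted

    def test_too_few_permutations_rejected(self):
        stack, pheno, _ = cohort_stack(null_config(0))
        with pytest.raises(ValueError):
            bwas.fwer_cluster_inference(
                stack, bwas.design_from_phenotypes(pheno), 3.0, n_perm=10)

    def test_determinism_given_seed(self):
        stack, pheno, _ = cohort_stack(planted_config(2, n_per_group=15,
                                                      n_timepoints=100))
        design = bwas.design_from_phenotypes(pheno)
        a, _ = bwas.fwer_cluster_inference(stack, design, 3.5, 99, seed=5)
        b, _ = bwas.fwer_cluster_inference(stack, design, 3.5, 99, seed=5)
        assert [c.corrected_p for c in a] == [c.corrected_p for c in b]


class TestSummaries:
    def test_ma_star(self):
        ma = bwas.measure_of_association([(0, 1), (0, 2), (0, 3)], 5)
        assert list(ma) == [3, 1, 1, 1, 0]

    def test_ma_empty(self):
        assert bwas.measure_of_association([], 4).sum() == 0

    def test_ma_handshake_identity(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 20))
            iu, ju = np.triu_indices(n, 1)
            pick = rng.random(len(iu)) < 0.3
            edges = list(zip(iu[pick], ju[pick]))
            assert bwas.measure_of_association(edges, n).sum() == 2 * len(edges)

    @pytest.mark.parametrize("labels, expected, tie", [
        ([7, 7, 7, 2, 2], 7, False),
        ([7, 7, 2, 2], 2, True),
        ([0, 0, 0], "NA", False),
    ])
    def test_label_majority_rules(self, labels, expected, tie):
        coords = np.array([[0, 0, i] for i in range(len(labels) + 1)])
        VS = grid_voxelset((2, 2, 2)).__class__
        vs = VS(np.arange(len(labels) + 1), coords,
                np.array(labels + [9]), (1, 1, len(labels) + 1))
        cl = bwas.FCCluster(edges=[(0, len(labels))],
                            endpoint1=np.arange(len(labels)),
                            endpoint2=np.array([len(labels)]),
                            n_increased=1, n_decreased=0, mean_z=1.0)
        l1, l2 = bwas.label_cluster(cl, vs)
        assert l1 == expected and cl.label1_tie == tie and l2 == 9

    def test_mean_strength_single_and_average(self):
        vals = np.array([[0.2, 0.4, 0.9], [0.0, 0.6, 0.9]])
        stack = _stack_from_values(vals)  # 3 voxels -> edges (0,1),(0,2),(1,2)
        single = bwas.FCCluster([(0, 1)], np.array([0]), np.array([1]),
                                1, 0, 1.0)
        np.testing.assert_allclose(
            bwas.cluster_mean_strength(stack, single), vals[:, 0])
        double = bwas.FCCluster([(0, 1), (0, 2)], np.array([0]),
                                np.array([1, 2]), 2, 0, 1.0)
        np.testing.assert_allclose(
            bwas.cluster_mean_strength(stack, double), [0.3, 0.3])

    def test_mean_strength_unknown_edge_rejected(self):
        stack = _stack_from_values(np.zeros((2, 3)))
        cl = bwas.FCCluster([(0, 9)], np.array([0]), np.array([9]), 1, 0, 1.0)
        with pytest.raises(KeyError):
            bwas.cluster_mean_strength(stack, cl)


class TestReplication:
    def _discovery_cluster(self, truth):
        pairs = truth.planted_voxel_pairs[0]["voxel_pairs"]
        e1 = sorted({p[0] for p in pairs})
        e2 = sorted({p[1] for p in pairs})
        return bwas.FCCluster([tuple(sorted(p)) for p in pairs],
                              np.array(e1), np.array(e2),
                              len(pairs), 0, mean_z=1.0)

    def test_same_effect_replicates(self):
        hits = 0
        for seed in range(10):
            cfg = planted_config(seed, n_per_group=30, n_timepoints=150)
            stack, pheno, truth = cohort_stack(cfg)
            cl = self._discovery_cluster(truth)
            val_cfg = planted_config(seed + 500, n_per_group=30,
                                     n_timepoints=150)
            vstack, vpheno, _ = cohort_stack(val_cfg)
            tab = bwas.replicate_clusters(
                [cl], vstack, bwas.design_from_phenotypes(vpheno))
            hits += int(tab["replicated"].iloc[0])
        assert hits >= 9

    def test_sign_flip_not_replicated(self):
        cfg = planted_config(3, n_per_group=30, n_timepoints=150)
        stack, pheno, truth = cohort_stack(cfg)
        cl = self._discovery_cluster(truth)
        cl.mean_z = -1.0  # pretend discovery found a decrease
        val_cfg = planted_config(77, n_per_group=30, n_timepoints=150)
        vstack, vpheno, _ = cohort_stack(val_cfg)
        tab = bwas.replicate_clusters(
            [cl], vstack, bwas.design_from_phenotypes(vpheno))
        assert not tab["replicated"].iloc[0]

    def test_null_validation_rarely_replicates(self):
        hits = 0
        for seed in range(10):
            cfg = planted_config(seed, n_per_group=20, n_timepoints=100)
            _, _, truth = cohort_stack(cfg)
            cl = self._discovery_cluster(truth)
            null_cfg = planted_config(seed + 900, delta_r=0.0,
                                      n_per_group=20, n_timepoints=100)
            vstack, vpheno, _ = cohort_stack(null_cfg)
            tab = bwas.replicate_clusters(
                [cl], vstack, bwas.design_from_phenotypes(vpheno))
            hits += int(tab["replicated"].iloc[0])
        assert hits <= 2
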