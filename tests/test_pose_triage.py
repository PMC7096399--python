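"""Filter cascade, perturbation and GROMOS clustering against oracles."""

import numpy as np
import pytest

from ifacemap.pose_triage import (ClusterResult, ScoredPose, TriageConfig,
                                  cluster_gromos, filter_by_clash,
                                  filter_by_contact, filter_by_score,
                                  gromos_cluster_from_matrix,
                                  ligand_rmsd_matrix, perturb_pose,
                                  run_triage, select_centroid)
from ifacemap.structure_io import ModelSet, superpose_kabsch
from ifacemap.synthetic import PerturbationSpec, gen_complex_poses

from conftest import make_modelset, two_chain_atoms


def brute_force_gromos(rmsd, pose_ids, cutoff):
    """Independent reference: literal neighbor-count extraction by dict scans."""
    alive = dict(enumerate(pose_ids))
    clusters = []
    while alive:
        best = None
        for i in alive:
            nb = [j for j in alive if j != i and rmsd[i][j] < cutoff]
            key = (-len(nb), alive[i])
            if best is None or key < best[0]:
                best = (key, i, nb)
        _, center, nb = best
        clusters.append((center, [center] + nb))
        for j in [center] + nb:
            del alive[j]
    clusters.sort(key=lambda c: (-len(c[1]), pose_ids[c[0]]))
    assign, centers, centroids, sizes = {}, [], [], []
    for label, (center, members) in enumerate(clusters):
        for m in members:
            assign[pose_ids[m]] = label
        centers.append(pose_ids[center])
        sizes.append(len(members))
        if len(members) == 1:
            centroids.append(pose_ids[members[0]])
        else:
            means = {m: sum(rmsd[m][o] for o in members if o != m)
                     / (len(members) - 1) for m in members}
            centroids.append(pose_ids[min(members,
                                          key=lambda m: (means[m], pose_ids[m]))])
    return assign, centers, centroids, sizes


def scored(scores):
    return [ScoredPose(i, i, s) for i, s in enumerate(scores)]


# --------------------------------------------------------------------------
# score filter
# --------------------------------------------------------------------------

class TestScoreFilter:
    def test_keep_all_is_identity(self):
        poses = scored([3.0, 1.0, 2.0])
        assert filter_by_score(poses, 1.0) == sorted(
            poses, key=lambda p: p.interface_score)

    def test_six_percent_of_100_retains_best_six(self, rng):
        poses = scored(list(rng.normal(size=100)))
        kept = filter_by_score(poses, 0.06)
        assert len(kept) == 6
        kept_scores = {p.interface_score for p in kept}
        discarded = [p.interface_score for p in poses
                     if p.interface_score not in kept_scores]
        assert max(kept_scores) <= min(discarded)

    def test_boundary_tie_keeps_lower_pose_id(self):
        poses = scored([0.0, -1.0, 0.0, 0.0])
        kept = filter_by_score(poses, 0.5)
        assert [p.pose_id for p in kept] == [1, 0]

    def test_higher_is_better_convention(self):
        poses = scored([1.0, 5.0, 3.0])
        kept = filter_by_score(poses, 1 / 3, lower_is_better=False)
        assert [p.pose_id for p in kept] == [1]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            filter_by_score([], 0.5)


# --------------------------------------------------------------------------
# contact filter
# --------------------------------------------------------------------------

def pair_ensemble(distances, simple_atoms):
    """One model per requested epitope-receptor minimum distance."""
    models = []
    for d in distances:
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0],            # LYS 54 CA, NZ
                        [1.5 + d, 0, 0], [1.5 + d + 2, 0, 0],  # GLU 560
                        [50.0, 5, 0], [50.0, 0, 5]])           # anchors
        models.append(xyz)
    return make_modelset(models, simple_atoms)


class TestContactFilter:
    def test_strict_inequality_at_six_angstrom(self, simple_pair_atoms):
        ens = pair_ensemble([5.9, 6.0, 6.1], simple_pair_atoms)
        poses = scored([0.0, 0.0, 0.0])
        kept = filter_by_contact(ens, poses, (54,), 6.0)
        assert [p.pose_id for p in kept] == [0]

    def test_matches_generator_truth_table(self):
        ens, truths = gen_complex_poses(15, 15, seed=21)
        poses = scored([t.planted_score for t in truths])
        kept = {p.pose_id for p in filter_by_contact(ens, poses, (54, 60), 6.0)}
        expected = {t.pose_id for t in truths if t.epitope_contact}
        assert kept == expected

    def test_missing_epitope_residue_raises(self, simple_pair_atoms):
        ens = pair_ensemble([5.0], simple_pair_atoms)
        with pytest.raises(ValueError):
            filter_by_contact(ens, scored([0.0]), (54, 99), 6.0)

    def test_idempotent(self):
        ens, truths = gen_complex_poses(5, 5, seed=2)
        poses = scored([t.planted_score for t in truths])
        once = filter_by_contact(ens, poses, (54, 60), 6.0)
        twice = filter_by_contact(ens, once, (54, 60), 6.0)
        assert once == twice


# --------------------------------------------------------------------------
# clash filter
# --------------------------------------------------------------------------

class TestClashFilter:
    def test_empty_context_retains_all(self):
        ens, truths = gen_complex_poses(3, 3, seed=4)
        poses = scored([t.planted_score for t in truths])
        kept = filter_by_clash(ens, poses, np.empty((0, 3)), None)
        assert kept == poses

    def test_forced_clash_discarded(self, simple_pair_atoms):
        ens = pair_ensemble([5.0], simple_pair_atoms)
        rec_fit = ens.coords[0][ens.select(chain_id="R", atom_names=("CA",))]
        lig_atom = ens.coords[0][0]
        context = (lig_atom + np.array([0.0, 1.5, 0.0]))[None, :]
        kept = filter_by_clash(ens, scored([0.0]), context, rec_fit,
                               clash_cutoff=2.0)
        assert kept == []

    def test_matches_all_pairs_distance_oracle(self, rng):
        ens, truths = gen_complex_poses(8, 8, seed=13)
        poses = scored([t.planted_score for t in truths])
        fit_idx = ens.select(chain_id="R", atom_names=("CA",))
        rec_fit = ens.coords[0][fit_idx]  # receptor shared: fit is identity
        context = rng.normal(scale=12.0, size=(40, 3))
        kept = filter_by_clash(ens, poses, context, rec_fit, clash_cutoff=3.0)

        lig_idx = ens.select(chain_id="L", heavy_only=True)
        expected = []
        for p in poses:
            lig = ens.coords[p.model_index][lig_idx]
            dmin = min(np.linalg.norm(a - c)
                       for a in lig for c in context)
            if dmin >= 3.0:
                expected.append(p.pose_id)
        assert [p.pose_id for p in kept] == expected


# --------------------------------------------------------------------------
# perturbation
# --------------------------------------------------------------------------

class TestPerturbation:
    def test_zero_spec_is_identity(self, rng):
        xyz = rng.normal(size=(7, 3))
        out = perturb_pose(xyz, PerturbationSpec(0.0, 0.0, seed=1))
        np.testing.assert_allclose(out, xyz, atol=1e-12)

    def test_rigidity_preserves_internal_distances(self, rng):
        xyz = rng.normal(scale=4.0, size=(10, 3))
        out = perturb_pose(xyz, PerturbationSpec(3.0, 8.0, seed=2))
        d0 = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
        d1 = np.linalg.norm(out[:, None] - out[None, :], axis=-1)
        np.testing.assert_allclose(d1, d0, atol=1e-6)

    def test_recovered_transforms_respect_bounds(self, rng):
        """Kabsch-recover the applied transform from 300 draws."""
        xyz = rng.normal(scale=4.0, size=(12, 3))
        spec = PerturbationSpec(3.0, 8.0)
        for k in range(300):
            out = perturb_pose(xyz, spec, rng=np.random.default_rng(k))
            rot, trans, rmsd = superpose_kabsch(xyz, out)
            assert rmsd < 1e-8
            angle = np.degrees(np.arccos(np.clip((np.trace(rot) - 1) / 2,
                                                 -1, 1)))
            assert angle <= 8.0 + 1e-9
            shift = out.mean(axis=0) - xyz.mean(axis=0)
            assert np.linalg.norm(shift) <= 3.0 + 1e-9

    def test_exact_magnitude_mode(self, rng):
        xyz = rng.normal(scale=4.0, size=(9, 3))
        spec = PerturbationSpec(3.0, 8.0, exact_magnitude=True)
        out = perturb_pose(xyz, spec, rng=np.random.default_rng(3))
        shift = out.mean(axis=0) - xyz.mean(axis=0)
        assert np.linalg.norm(shift) == pytest.approx(3.0)


# --------------------------------------------------------------------------
# clustering
# --------------------------------------------------------------------------

class TestGromosClustering:
    def test_all_within_cutoff_single_cluster(self):
        n = 6
        mat = np.full((n, n), 0.1); np.fill_diagonal(mat, 0.0)
        cr = gromos_cluster_from_matrix(mat, list(range(n)), 0.6)
        assert cr.sizes == [n]
        assert set(cr.assignments.values()) == {0}

    def test_all_beyond_cutoff_singletons(self):
        n = 5
        mat = np.full((n, n), 2.0); np.fill_diagonal(mat, 0.0)
        cr = gromos_cluster_from_matrix(mat, list(range(n)), 0.6)
        assert cr.sizes == [1] * n
        assert cr.centers == list(range(n))

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 21))
        d = rng.uniform(0.0, 1.2, size=(n, n))
        mat = (d + d.T) / 2
        np.fill_diagonal(mat, 0.0)
        ids = list(rng.permutation(100)[:n])
        cr = gromos_cluster_from_matrix(mat, ids, 0.6)
        assign, centers, centroids, sizes = brute_force_gromos(mat, ids, 0.6)
        assert cr.assignments == assign
        assert cr.centers == centers
        assert cr.centroids == centroids
        assert cr.sizes == sizes

    def test_geometric_ensemble_against_oracle(self):
        ens, truths = gen_complex_poses(12, 0, seed=17)
        poses = scored([t.planted_score for t in truths])
        mat = ligand_rmsd_matrix(ens, poses)
        cr = cluster_gromos(ens, poses, cutoff_nm=0.8)
        assign, centers, centroids, sizes = brute_force_gromos(
            mat, [p.pose_id for p in poses], 0.8)
        assert cr.assignments == assign and cr.sizes == sizes

    def test_permutation_invariance_up_to_relabeling(self, rng):
        n = 10
        d = rng.uniform(0, 1.2, size=(n, n))
        mat = (d + d.T) / 2; np.fill_diagonal(mat, 0.0)
        ids = list(range(n))
        base = gromos_cluster_from_matrix(mat, ids, 0.6)
        perm = rng.permutation(n)
        mat_p = mat[np.ix_(perm, perm)]
        ids_p = [ids[i] for i in perm]
        shuffled = gromos_cluster_from_matrix(mat_p, ids_p, 0.6)
        assert shuffled.assignments == base.assignments
        assert shuffled.centers == base.centers
        assert shuffled.sizes == base.sizes

    def test_sizes_non_increasing(self, rng):
        d = rng.uniform(0, 1.0, size=(15, 15))
        mat = (d + d.T) / 2; np.fill_diagonal(mat, 0.0)
        cr = gromos_cluster_from_matrix(mat, list(range(15)), 0.5)
        assert cr.sizes == sorted(cr.sizes, reverse=True)
        assert sum(cr.sizes) == 15


class TestCentroid:
    def test_singleton_returns_sole_member(self):
        ens, truths = gen_complex_poses(1, 0, seed=0)
        poses = scored([truths[0].planted_score])
        assert select_centroid(ens, [0], poses) == 0

    def test_middle_of_three_collinear_poses(self, simple_pair_atoms):
        models = []
        for x in (0.0, 5.0, 10.0):
            models.append(np.array([[x, 0, 0], [x + 1.5, 0, 0],
                                    [40.0, 0, 0], [42.0, 0, 0],
                                    [50.0, 5, 0], [50.0, 0, 5]]))
        ens = make_modelset(models, simple_pair_atoms)
        poses = scored([0.0, 0.0, 0.0])
        assert select_centroid(ens, [0, 1, 2], poses) == 1

    def test_matches_matrix_argmin(self):
        ens, truths = gen_complex_poses(8, 0, seed=23)
        poses = scored([t.planted_score for t in truths])
        got = select_centroid(ens, [p.pose_id for p in poses], poses)
        mat = ligand_rmsd_matrix(ens, poses)
        means = mat.sum(axis=1) / (len(poses) - 1)
        assert got == poses[int(np.argmin(means))].pose_id

    def test_empty_cluster_rejected(self):
        ens, _ = gen_complex_poses(1, 0, seed=0)
        with pytest.raises(ValueError):
            select_centroid(ens, [], [])


# --------------------------------------------------------------------------
# cascade
# --------------------------------------------------------------------------

class TestCascade:
    def test_permissive_config_passes_everything(self):
        ens, truths = gen_complex_poses(5, 0, seed=6)
        poses = scored([t.planted_score for t in truths])
        cfg = TriageConfig(score_keep_fraction=1.0, contact_cutoff=1e3)
        report = run_triage(ens, poses, cfg)
        assert report["stage_counts"] == {"score": 5, "contact": 5, "clash": 5}

    def test_synthetic_survivors_are_all_true(self):
        ens, truths = gen_complex_poses(20, 80, seed=31)
        poses = scored([t.planted_score for t in truths])
        cfg = TriageConfig(score_keep_fraction=0.2)
        report = run_triage(ens, poses, cfg)
        truth = {t.pose_id: t.is_true_interface for t in truths}
        counts = report["stage_counts"]
        assert counts["score"] >= counts["contact"] >= counts["clash"]
        assert all(truth[i] for i in report["retained_ids"]["clash"])

    def test_identical_poses_cluster_rmsd_zero(self, simple_pair_atoms):
        xyz = np.array([[0.0, 0, 0], [1.5, 0, 0], [30.0, 0, 0], [32.0, 0, 0],
                        [50.0, 5, 0], [50.0, 0, 5]])
        ens = make_modelset([xyz, xyz, xyz], simple_pair_atoms)
        cr = cluster_gromos(ens, scored([0.0, 0.0, 0.0]), cutoff_nm=0.6)
        assert cr.sizes == [3]
        assert cr.mean_pairwise_rmsd_nm == [0.0]
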