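import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from tetherdock import restraints, symdock, synthdata
from tetherdock.restraints import evaluate_restraints, uirs_from_crosslinks
from tetherdock.symdock import (
    C2_Z,
    DockingConfig,
    PoseC2,
    cluster_poses,
    dock,
    interface_rmsd,
    ligand_rmsd,
    make_c2_assembly,
    prepare_receptor,
    score_pose,
)
from _geom import ASSEMBLY_MAP


def random_pose(rng):
    q = Rotation.random(random_state=rng.integers(2**31)).as_quat()
    q = q / np.linalg.norm(q)
    return PoseC2(tuple(q), tuple(rng.normal(size=3) * 15))


class TestAssembly:
    def test_identity_pose_keeps_copy1(self, toy7):
        asm = make_c2_assembly(toy7["prepared"], toy7["ligand"], PoseC2.identity())
        c1 = asm.xyz[asm.chain.astype(str) == "C"]
        assert np.allclose(c1, toy7["ligand"].xyz)

    def test_translation_reflected_through_axis(self, toy7):
        pose = PoseC2((0, 0, 0, 1), (10.0, 0.0, 3.0))
        asm = make_c2_assembly(toy7["prepared"], toy7["ligand"], pose)
        c1 = asm.xyz[asm.chain.astype(str) == "C"]
        c2 = asm.xyz[asm.chain.astype(str) == "D"]
        assert c1.mean(axis=0)[0] == pytest.approx(-c2.mean(axis=0)[0])
        assert c1.mean(axis=0)[2] == pytest.approx(c2.mean(axis=0)[2])

    def test_c2_closure_exact_for_random_poses(self, toy7, rng):
        for _ in range(5):
            pose = random_pose(rng)
            asm = make_c2_assembly(toy7["prepared"], toy7["ligand"], pose)
            c1 = asm.xyz[asm.chain.astype(str) == "C"]
            c2 = asm.xyz[asm.chain.astype(str) == "D"]
            assert np.array_equal(c1 @ C2_Z.T, c2)

    def test_ground_truth_reproduced(self, toy7):
        asm = make_c2_assembly(toy7["prepared"], toy7["ligand"], toy7["pose"])
        assert np.allclose(asm.xyz, toy7["assembly"].xyz, atol=1e-9)


class TestPrepareReceptor:
    def test_prepared_is_fixed_point(self, toy7):
        again = prepare_receptor(toy7["prepared"])
        assert np.allclose(again.xyz, toy7["prepared"].xyz, atol=1e-6)

    def test_recovers_axis_after_rigid_motion(self, toy7, rng):
        R = Rotation.random(random_state=5).as_matrix()
        moved = toy7["receptor"].transformed(R, rng.normal(size=3) * 20)
        prep = prepare_receptor(moved)
        i1 = prep.chain.astype(str) == "A"
        i2 = prep.chain.astype(str) == "B"
        assert np.abs(prep.xyz[i1] @ C2_Z.T - prep.xyz[i2]).max() < 1e-6

    def test_non_twofold_rejected(self, toy7, rng):
        broken = toy7["receptor"]
        xyz = broken.xyz.copy()
        n = xyz.shape[0] // 2
        xyz[n:] = xyz[n:] @ Rotation.from_euler("z", 120, degrees=True).as_matrix().T
        with pytest.raises(ValueError):
            prepare_receptor(broken.with_xyz(xyz))

    def test_single_chain_rejected(self, toy7):
        lig = toy7["ligand"]
        with pytest.raises(ValueError):
            prepare_receptor(lig)


class TestScoring:
    def test_ground_truth_restraint_energy_zero(self, toy7):
        sb = score_pose(toy7["prepared"], toy7["ligand"], toy7["pose"], toy7["uirs"])
        assert sb.e_restraint == 0.0

    def test_overlapping_bodies_clash(self, toy7):
        pose = PoseC2.identity()  # ligand centroid at the origin, inside the dimer
        sb = score_pose(toy7["prepared"], toy7["ligand"], pose, [])
        assert sb.e_clash > 0.0

    def test_restraint_term_matches_violation_report(self, toy7, rng):
        # term-by-term oracle: grouped min distances -> quadratic penalty
        pose = random_pose(rng)
        cfg = DockingConfig()
        sb = score_pose(toy7["prepared"], toy7["ligand"], pose, toy7["uirs"], cfg)
        asm = make_c2_assembly(toy7["prepared"], toy7["ligand"], pose)
        report = evaluate_restraints(asm, toy7["uirs"])
        by_group = {}
        for r, rec in zip(toy7["uirs"], report.records):
            d = by_group.setdefault(rec.symmetry_group, [])
            d.append((rec.distance, r.upper))
        expected = sum(
            max(0.0, min(d for d, _ in vals) - vals[0][1]) ** 2
            for vals in by_group.values()
        )
        assert sb.e_restraint == pytest.approx(expected, abs=1e-9)

    def test_adding_satisfied_restraint_keeps_energy(self, toy7):
        base = score_pose(toy7["prepared"], toy7["ligand"], toy7["pose"], toy7["uirs"])
        extra = toy7["uirs"] + toy7["uirs"][:2]  # satisfied at truth
        more = score_pose(toy7["prepared"], toy7["ligand"], toy7["pose"], extra)
        assert more.e_restraint <= base.e_restraint + 1e-12

    def test_larger_violation_scores_worse(self, toy7):
        uirs = toy7["uirs"]
        near = PoseC2((0, 0, 0, 1), tuple(toy7["pose"].translation))
        far_t = np.asarray(toy7["pose"].translation) * 3.0
        far = PoseC2((0, 0, 0, 1), tuple(far_t))
        e_near = score_pose(toy7["prepared"], toy7["ligand"], near, uirs).e_restraint
        e_far = score_pose(toy7["prepared"], toy7["ligand"], far, uirs).e_restraint
        assert e_far > e_near > 0.0


class TestClustering:
    def test_single_pose_single_cluster(self, toy7, rng):
        p = random_pose(rng)
        sb = score_pose(toy7["prepared"], toy7["ligand"], p, toy7["uirs"])
        (c,) = cluster_poses([p], toy7["ligand"], [sb])
        assert c.members == [0] and c.representative == 0

    def test_identical_poses_merge(self, toy7, rng):
        p = random_pose(rng)
        sb = score_pose(toy7["prepared"], toy7["ligand"], p, toy7["uirs"])
        clusters = cluster_poses([p, p], toy7["ligand"], [sb, sb])
        assert len(clusters) == 1 and sorted(clusters[0].members) == [0, 1]

    def test_matches_brute_force_single_linkage(self, toy7, rng):
        poses = [random_pose(rng) for _ in range(20)]
        scores = [
            score_pose(toy7["prepared"], toy7["ligand"], p, toy7["uirs"]) for p in poses
        ]
        cutoff = 7.5
        clusters = cluster_poses(poses, toy7["ligand"], scores, cutoff=cutoff)
        # union-find oracle on the pairwise symmetry-aware RMSD graph
        lig = toy7["ligand"].xyz
        parent = list(range(20))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(20):
            for j in range(i + 1, 20):
                if ligand_rmsd(poses[i], poses[j], lig) <= cutoff:
                    parent[find(i)] = find(j)
        expect = {}
        for i in range(20):
            expect.setdefault(find(i), set()).add(i)
        got = {frozenset(c.members) for c in clusters}
        assert got == {frozenset(m) for m in expect.values()}


class TestDocking:
    def test_recovery_on_easy_toy(self):
        # seed 4 toy, 16 starts: the top cluster must land on the planted pose
        assembly, receptor, ligand, pose = synthdata.make_toy_tetramer(
            synthdata.ToyComplexSpec(seed=4)
        )
        links = synthdata.plant_crosslinks(
            receptor, ligand, pose, synthdata.PlantedCrossLinkSpec(n_true=4, seed=4)
        )
        uirs = uirs_from_crosslinks(links, ASSEMBLY_MAP, fallback_slack=0.0)
        res = dock(receptor, ligand, uirs, DockingConfig(n_starts=16, seed=4))
        prep = prepare_receptor(receptor)
        ir = interface_rmsd(res.best_pose, pose, ligand.xyz, prep.xyz)
        assert ir <= 5.0
        # best pose follows every planted link group
        report = res.reports[res.clusters[0].representative]
        assert all(report.grouped_followed().values())

    def test_seeded_determinism(self, toy7):
        cfg = DockingConfig(n_starts=4, seed=11, refine_iterations=100)
        a = dock(toy7["receptor"], toy7["ligand"], toy7["uirs"], cfg)
        b = dock(toy7["receptor"], toy7["ligand"], toy7["uirs"], cfg)
        assert [p.quaternion for p in a.poses] == [p.quaternion for p in b.poses]
        assert [p.translation for p in a.poses] == [p.translation for p in b.poses]
        assert [s.total for s in a.scores] == [s.total for s in b.scores]
        assert [c.members for c in a.clusters] == [c.members for c in b.clusters]

    def test_requires_restraints_or_clash(self, toy7):
        with pytest.raises(ValueError):
            dock(toy7["receptor"], toy7["ligand"], [], DockingConfig(w_c=0.0))

    def test_span_exceeds_ligand_diameter(self, toy7):
        # the two ligand copies flank the dimer: the assembly span between
        # them exceeds a single ligand's diameter
        asm = toy7["assembly"]
        c1 = asm.xyz[asm.chain.astype(str) == "C"]
        c2 = asm.xyz[asm.chain.astype(str) == "D"]
        span = cdist(c1, c2).max()
        diameter = cdist(c1, c1).max()
        assert span > diameter


class TestPoseMetrics:
    def test_ligand_rmsd_symmetry_aware(self, toy7):
        pose = toy7["pose"]
        q = Rotation.from_matrix(C2_Z @ pose.rotation).as_quat()
        flipped = PoseC2(tuple(q / np.linalg.norm(q)),
                         tuple(C2_Z @ np.asarray(pose.translation)))
        assert ligand_rmsd(pose, flipped, toy7["ligand"].xyz) == pytest.approx(0.0, abs=1e-9)

    def test_interface_rmsd_zero_on_self(self, toy7):
        assert interface_rmsd(
            toy7["pose"], toy7["pose"], toy7["ligand"].xyz, toy7["prepared"].xyz
        ) == pytest.approx(0.0, abs=1e-12)
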