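import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from tetherdock import structio
from tetherdock.structio import (
    AtomSelection,
    EmptyStructureError,
    Structure,
    interface_residues,
    max_pair_distance,
    min_distance,
    read_structure,
    superpose,
    write_structure,
)

from _geom import make_points

SEL_A = AtomSelection(chains=frozenset({"A"}))
SEL_B = AtomSelection(chains=frozenset({"B"}))


class TestReadWrite:
    def test_single_atom_at_origin(self, tmp_path):
        pdb = tmp_path / "one.pdb"
        pdb.write_text(
            "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00"
            "           C\nEND\n"
        )
        s = read_structure(pdb)
        assert s.n_atoms == 1
        assert np.allclose(s.xyz, 0.0)
        assert s.residue_key(0) == ("A", "1")

    def test_round_trip_identity(self, tmp_path, toy7):
        path = tmp_path / "toy.pdb"
        write_structure(toy7["assembly"], path)
        back = read_structure(path)
        a = toy7["assembly"]
        assert back.n_atoms == a.n_atoms
        assert (back.chain == a.chain).all()
        assert (back.resnum == a.resnum).all()
        assert (back.atomname == a.atomname).all()
        # PDB stores coordinates to 3 decimals
        assert np.abs(back.xyz - a.xyz).max() <= 5e-4 + 1e-12

    def test_remark_only_file_is_empty(self, tmp_path):
        pdb = tmp_path / "empty.pdb"
        pdb.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(EmptyStructureError):
            read_structure(pdb)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_structure(tmp_path / "nope.pdb")

    def test_multi_model_blocks(self, tmp_path, toy7):
        lig = toy7["ligand"]
        path = tmp_path / "models.pdb"
        write_structure(lig, path, models=[lig.xyz, lig.xyz + 1.0, lig.xyz + 2.0])
        text = path.read_text()
        assert text.count("MODEL") >= 3 and text.count("ENDMDL") == 3

    def test_serial_limit_refused(self, tmp_path):
        s = make_points(np.zeros((2, 3)))
        big = Structure(
            chain=np.array(["A"] * 100_000, dtype=object),
            resnum=np.arange(100_000),
            icode=np.array([""] * 100_000, dtype=object),
            resname=np.array(["GLY"] * 100_000, dtype=object),
            atomname=np.array(["CA"] * 100_000, dtype=object),
            element=np.array(["C"] * 100_000, dtype=object),
            xyz=np.random.default_rng(0).normal(size=(100_000, 3)),
        )
        with pytest.raises(ValueError):
            write_structure(big, tmp_path / "big.pdb")
        del s


class TestDistances:
    def test_self_distance_zero(self):
        s = make_points([[1.0, 2.0, 3.0]])
        sel = AtomSelection()
        assert min_distance(s, sel, sel) == 0.0

    def test_three_four_five(self):
        s = make_points([[0, 0, 0], [3, 4, 0]], chains=["A", "B"])
        assert min_distance(s, SEL_A, SEL_B) == pytest.approx(5.0)

    def test_scaled_three_four_five_max(self):
        s = make_points([[0, 0, 0], [6, 8, 0]], chains=["A", "B"])
        assert max_pair_distance(s, SEL_A, SEL_B) == pytest.approx(10.0)

    def test_matches_brute_force_on_toy(self, toy7):
        s = toy7["assembly"]
        a = SEL_A.resolve(s)
        c = AtomSelection(chains=frozenset({"C"})).resolve(s)
        d = cdist(s.xyz[a], s.xyz[c])
        assert min_distance(s, SEL_A, AtomSelection(chains=frozenset({"C"}))) == pytest.approx(d.min())
        assert max_pair_distance(s, SEL_A, AtomSelection(chains=frozenset({"C"}))) == pytest.approx(d.max())

    def test_symmetry_and_rigid_invariance(self, toy7, rng):
        s = toy7["assembly"]
        selC = AtomSelection(chains=frozenset({"C"}))
        d_ab = min_distance(s, SEL_A, selC)
        d_ba = min_distance(s, selC, SEL_A)
        assert d_ab == pytest.approx(d_ba)
        R = Rotation.random(random_state=3).as_matrix()
        moved = s.transformed(R, rng.normal(size=3) * 10)
        assert min_distance(moved, SEL_A, selC) == pytest.approx(d_ab, abs=1e-6)
        assert max_pair_distance(moved, SEL_A, selC) == pytest.approx(
            max_pair_distance(s, SEL_A, selC), abs=1e-6
        )

    def test_empty_selection_raises(self):
        s = make_points([[0, 0, 0]])
        with pytest.raises(structio.EmptySelectionError):
            min_distance(s, SEL_A, AtomSelection(chains=frozenset({"Z"})))


class TestInterface:
    def boundary_structure(self, gap):
        return make_points([[0, 0, 0], [gap, 0, 0]], chains=["A", "B"])

    def test_inclusive_boundary(self):
        inside = interface_residues(self.boundary_structure(4.9), SEL_A, SEL_B, 5.0)
        assert inside == [("A", 1)]
        at = interface_residues(self.boundary_structure(5.0), SEL_A, SEL_B, 5.0)
        assert at == [("A", 1)]
        outside = interface_residues(self.boundary_structure(5.1), SEL_A, SEL_B, 5.0)
        assert outside == []

    def test_matches_residue_pair_scan(self, toy7):
        s = toy7["assembly"]
        selC = AtomSelection(chains=frozenset({"C"}))
        got = interface_residues(s, SEL_A, selC, cutoff=7.7)
        a = SEL_A.resolve(s)
        c = selC.resolve(s)
        expect = []
        for i in a:
            key = (str(s.chain[i]), int(s.resnum[i]))
            close = any(np.linalg.norm(s.xyz[i] - s.xyz[j]) <= 7.7 for j in c)
            if close and key not in expect:
                expect.append(key)
        assert got == expect

    def test_monotone_in_cutoff(self, toy7):
        s = toy7["assembly"]
        selC = AtomSelection(chains=frozenset({"C"}))
        small = set(interface_residues(s, SEL_A, selC, cutoff=6.5))
        large = set(interface_residues(s, SEL_A, selC, cutoff=9.0))
        assert small <= large

    def test_overlapping_groups_rejected(self):
        s = make_points([[0, 0, 0], [1, 0, 0]])
        sel = AtomSelection()
        with pytest.raises(ValueError):
            interface_residues(s, sel, sel)


class TestSuperpose:
    def test_identity(self, rng):
        cloud = rng.normal(size=(10, 3))
        sp = superpose(cloud, cloud)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sp.rotation, np.eye(3), atol=1e-9)

    def test_recovers_exact_rotation(self, rng):
        cloud = rng.normal(size=(20, 3)) * 5
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        target = cloud @ R.T
        sp = superpose(cloud, target)
        assert sp.rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(sp.apply(cloud), target, atol=1e-9)

    def test_rmsd_equals_remeasure(self, rng):
        a = rng.normal(size=(50, 3)) * 8
        b = rng.normal(size=(50, 3)) * 8
        sp = superpose(a, b)
        moved = sp.apply(a)
        direct = np.sqrt(((moved - b) ** 2).sum(axis=1).mean())
        assert sp.rmsd == pytest.approx(direct, abs=1e-9)

    def test_rotation_always_proper(self, rng):
        # mirrored cloud: the unconstrained optimum is a reflection
        a = rng.normal(size=(30, 3))
        b = a.copy()
        b[:, 0] *= -1
        sp = superpose(a, b)
        assert np.linalg.det(sp.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_shared_transform_invariance(self, rng):
        a = rng.normal(size=(25, 3)) * 4
        b = rng.normal(size=(25, 3)) * 4
        base = superpose(a, b).rmsd
        R = Rotation.random(random_state=11).as_matrix()
        t = np.array([3.0, -2.0, 7.0])
        again = superpose(a @ R.T + t, b @ R.T + t).rmsd
        assert again == pytest.approx(base, abs=1e-8)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0.0, 0.0])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)


class TestSelections:
    def test_parse_tokens(self):
        sel = AtomSelection.parse("A:142-145,150:CA")
        assert sel.chains == frozenset({"A"})
        assert sel.residues == frozenset({142, 143, 144, 145, 150})
        assert sel.atoms == frozenset({"CA"})

    def test_fallback_resolution(self):
        s = make_points([[0, 0, 0]], atomnames=["CA"])
        sel = AtomSelection(
            chains=frozenset({"A"}),
            residues=frozenset({1}),
            atoms=frozenset({"NZ"}),
            fallback_atoms=frozenset({"CA"}),
        )
        assert sel.resolve(s).tolist() == [0]
        assert sel.used_fallback(s)
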