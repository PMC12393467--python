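"""Coordinate parsing, interface contacts, and Kabsch superposition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from tbmkit.structure import (
    Atom,
    PDBFormatError,
    StructureModel,
    find_hbonds,
    find_salt_bridges,
    interface_residues,
    read_pdb,
    superpose,
    write_pdb,
)

MINIMAL_PDB = """\
ATOM      1  N   GLY A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  GLY A   1      12.560   6.071  -6.350  1.00 55.50           C
END
"""


def _atom(serial, name, resname, resnum, chain, xyz, element=None):
    return Atom(
        serial=serial, name=name, element=element or name[0],
        residue_name=resname, residue_number=resnum, insertion_code="",
        chain_id=chain, xyz=xyz,
    )


class TestReadWritePDB:
    def test_minimal_file_fields_echoed(self):
        model = read_pdb(MINIMAL_PDB)
        assert len(model.atoms) == 2
        a = model.atoms[0]
        assert (a.name, a.residue_name, a.residue_number, a.chain_id) == (
            "N", "GLY", 1, "A"
        )
        assert a.xyz == pytest.approx((11.104, 6.134, -6.504), abs=1e-3)
        assert model.atoms[1].bfactor == pytest.approx(55.5)

    def test_altloc_b_discarded(self):
        text = (
            "ATOM      1  CA AALA A   1       1.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       2.000   0.000   0.000  0.50  0.00           C\n"
        )
        model = read_pdb(text)
        assert len(model.atoms) == 1
        assert model.atoms[0].xyz[0] == pytest.approx(1.0)

    def test_malformed_coordinates_name_line_number(self):
        bad = MINIMAL_PDB.replace("12.560", "twelve")
        with pytest.raises(PDBFormatError, match="line 2"):
            read_pdb(bad)

    def test_round_trip_preserves_coordinates(self):
        from tbmkit.synth import make_toy_complex

        toy = make_toy_complex(seed=0)
        reread = read_pdb(write_pdb(toy.model))
        assert len(reread.atoms) == len(toy.model.atoms)

        def by_key(model):
            return {
                (a.chain_id, a.residue_number, a.name): a.xyz
                for a in model.atoms
            }

        orig, back = by_key(toy.model), by_key(reread)
        assert orig.keys() == back.keys()
        for key, xyz in orig.items():
            assert back[key] == pytest.approx(xyz, abs=1e-3)


@pytest.fixture
def contact_model():
    """Two-chain fixture with one backbone H-bond at 2.9 A and one
    Glu-Arg bridge at 3.8 A (hand-placed coordinates; the bridge sits
    outside the 3.5 A hydrogen-bond cutoff on purpose)."""
    atoms = [
        _atom(1, "N", "ALA", 1, "A", (0.0, 0.0, 0.0)),
        _atom(2, "O", "GLY", 10, "B", (0.0, 2.9, 0.0)),
        _atom(3, "OE1", "GLU", 2, "A", (8.0, 0.0, 0.0), element="O"),
        _atom(4, "NH1", "ARG", 11, "B", (8.0, 3.8, 0.0), element="N"),
    ]
    return StructureModel(atoms=atoms)


class TestContacts:
    def test_single_backbone_hbond_at_hand_distance(self, contact_model):
        bonds = find_hbonds(contact_model, "A", "B")
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9)
        assert bonds[0].kind == "backbone"

    def test_cutoff_excludes_bond(self, contact_model):
        assert find_hbonds(contact_model, "A", "B", d_max=2.5) == []

    def test_salt_bridge_at_hand_distance(self, contact_model):
        bridges = find_salt_bridges(contact_model, "A", "B")
        assert len(bridges) == 1
        assert bridges[0].distance == pytest.approx(3.8)
        assert bridges[0].acidic.name == "OE1"
        assert bridges[0].basic.name == "NH1"

    def test_like_charges_never_bridge(self):
        atoms = [
            _atom(1, "OE1", "GLU", 1, "A", (0.0, 0.0, 0.0), element="O"),
            _atom(2, "OE1", "GLU", 2, "B", (0.0, 3.0, 0.0), element="O"),
        ]
        model = StructureModel(atoms=atoms)
        assert find_salt_bridges(model, "A", "B") == []

    def test_empty_selection_rejected(self, contact_model):
        with pytest.raises(ValueError):
            find_hbonds(contact_model, "Z", "B")

    def test_contacts_match_brute_force_all_pairs(self, rng):
        # random N/O cloud; detector must equal an exhaustive double loop
        atoms = []
        serial = 1
        for chain in "AB":
            for i in range(40):
                name = rng.choice(["N", "O", "CA", "NZ", "OE1"])
                resname = rng.choice(["ALA", "GLU", "LYS", "ARG"])
                atoms.append(
                    Atom(
                        serial=serial, name=str(name), element=str(name)[0],
                        residue_name=str(resname), residue_number=i,
                        insertion_code="", chain_id=chain,
                        xyz=tuple(rng.uniform(0, 15, 3)),
                    )
                )
                serial += 1
        model = StructureModel(atoms=atoms)
        a = model.select(chain="A")
        b = model.select(chain="B")
        expected = set()
        for donors, acceptors in ((a, b), (b, a)):
            for d in donors:
                for acc in acceptors:
                    if d.element == "N" and acc.element == "O" \
                            and d.distance_to(acc) <= 3.5:
                        expected.add((d.serial, acc.serial))
        got = {(hb.donor.serial, hb.acceptor.serial)
               for hb in find_hbonds(model, "A", "B")}
        assert got == expected

    def test_geometry_invariant_under_rigid_transform(self, contact_model):
        rot = Rotation.from_euler("xyz", [0.3, -1.1, 2.0]).as_matrix()
        moved = contact_model.transformed(rot, np.array([5.0, -3.0, 2.0]))
        orig = find_hbonds(contact_model, "A", "B")
        new = find_hbonds(moved, "A", "B")
        assert [round(b.distance, 9) for b in orig] == [
            round(b.distance, 9) for b in new
        ]


class TestInterfaceResidues:
    def test_distant_chains_have_no_interface(self):
        atoms = [
            _atom(1, "CA", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            _atom(2, "CA", "ALA", 1, "B", (20.0, 0.0, 0.0)),
        ]
        assert interface_residues(StructureModel(atoms=atoms), "A", "B") == []

    def test_single_contact_pair_at_hand_distance(self):
        atoms = [
            _atom(1, "CA", "ALA", 1, "A", (0.0, 0.0, 0.0)),
            _atom(2, "CB", "ALA", 1, "A", (1.5, 0.0, 0.0)),
            _atom(3, "CA", "GLY", 7, "B", (5.3, 0.0, 0.0)),
        ]
        pairs = interface_residues(StructureModel(atoms=atoms), "A", "B")
        assert len(pairs) == 1
        (res_a, res_b, dist) = pairs[0]
        assert res_a == ("A", 1, "") and res_b == ("B", 7, "")
        assert dist == pytest.approx(3.8)

    def test_enlarging_cutoff_never_removes_pairs(self, rng):
        atoms = [
            _atom(i + 1, "CA", "ALA", i, "A", tuple(rng.uniform(0, 10, 3)))
            for i in range(10)
        ] + [
            _atom(i + 11, "CA", "ALA", i, "B", tuple(rng.uniform(0, 10, 3)))
            for i in range(10)
        ]
        model = StructureModel(atoms=atoms)
        small = {p[:2] for p in interface_residues(model, "A", "B", cutoff=4.0)}
        large = {p[:2] for p in interface_residues(model, "A", "B", cutoff=6.0)}
        assert small <= large


def _brute_force_rmsd(a, b, n_samples=4000, seed=0):
    """Quaternion-sampled rigid minimizer, polished with Nelder-Mead;
    independent of the SVD path."""
    rng = np.random.default_rng(seed)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def rmsd_of_quat(q):
        q = q / np.linalg.norm(q)
        rot = Rotation.from_quat(q).as_matrix()
        return float(np.sqrt(np.mean(np.sum((a0 @ rot.T - b0) ** 2, axis=1))))

    quats = rng.normal(size=(n_samples, 4))
    best = min(quats, key=rmsd_of_quat)
    res = minimize(rmsd_of_quat, best, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    return float(res.fun)


class TestSuperpose:
    def test_identical_sets_give_zero_rmsd_identity_rotation(self, rng):
        a = rng.normal(size=(8, 3))
        sup = superpose(a, a)
        assert sup.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(sup.rotation, np.eye(3), atol=1e-10)

    def test_rigid_motion_recovered_exactly(self, rng):
        a = rng.normal(size=(12, 3)) * 5
        rot = Rotation.random(random_state=3).as_matrix()
        t = np.array([4.0, -2.0, 7.0])
        b = a @ rot.T + t
        sup = superpose(a, b)
        assert sup.rmsd <= 1e-9
        np.testing.assert_allclose(sup.rotation, rot, atol=1e-8)
        np.testing.assert_allclose(sup.translation, t, atol=1e-8)

    def test_rotation_always_proper_even_for_mirrored_input(self, rng):
        a = rng.normal(size=(10, 3))
        b = a * np.array([-1.0, 1.0, 1.0])  # reflection
        sup = superpose(a, b)
        assert np.linalg.det(sup.rotation) == pytest.approx(1.0, abs=1e-8)
        assert sup.rmsd > 0.01

    def test_rotation_orthonormal(self, rng):
        a, b = rng.normal(size=(6, 3)), rng.normal(size=(6, 3))
        sup = superpose(a, b)
        np.testing.assert_allclose(
            sup.rotation @ sup.rotation.T, np.eye(3), atol=1e-8
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_quaternion_grid_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(4, 3)) * 3
        b = rng.normal(size=(4, 3)) * 3
        sup = superpose(a, b)
        oracle = _brute_force_rmsd(a, b, seed=seed)
        assert sup.rmsd == pytest.approx(oracle, abs=1e-4)

    def test_matches_scipy_align_vectors(self, rng):
        a = rng.normal(size=(20, 3))
        b = rng.normal(size=(20, 3))
        sup = superpose(a, b)
        rot, rssd = Rotation.align_vectors(
            b - b.mean(axis=0), a - a.mean(axis=0)
        )
        assert sup.rmsd == pytest.approx(rssd / np.sqrt(len(a)), rel=1e-6)

    def test_too_few_or_collinear_points_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            superpose(line, line)

    def test_rmsd_invariant_under_global_rigid_transform(self, rng):
        a = rng.normal(size=(9, 3))
        b = rng.normal(size=(9, 3))
        base = superpose(a, b).rmsd
        rot = Rotation.random(random_state=9).as_matrix()
        moved = superpose(a @ rot.T + 2.0, b).rmsd
        assert moved == pytest.approx(base, abs=1e-9)
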