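"""Kabsch superposition, ensemble RMSD, salt-bridge and polar-contact
detection, with brute-force oracles."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fgf21stab.geometry import (
    ACIDIC_ATOMS,
    BASIC_ATOMS,
    AtomRecord,
    ConformerEnsemble,
    StructureModel,
    detect_ion_pairs,
    detect_polar_contacts,
    diff_contacts,
    read_structure,
    rmsd_to_ensemble,
    superpose_kabsch,
    write_structure,
)
from fgf21stab.synthetic import gen_toy_structure, perturb_ensemble


def quaternion_grid_rmsd(P, Q, n_grid=800, seed=0):
    """Brute-force minimal RMSD: random quaternion grid + simplex refinement.

    Deliberately avoids the SVD route used by the implementation.
    """
    rng = np.random.default_rng(seed)
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)

    def rmsd_of(q):
        q = q / np.linalg.norm(q)
        R = Rotation.from_quat(q).as_matrix()
        return np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1)))

    quats = rng.normal(size=(n_grid, 4))
    values = [rmsd_of(q) for q in quats]
    best_q = quats[int(np.argmin(values))]
    res = minimize(
        rmsd_of, best_q / np.linalg.norm(best_q), method="Nelder-Mead",
        options={"xatol": 1e-13, "fatol": 1e-15, "maxiter": 20000,
                 "maxfev": 20000},
    )
    return min(min(values), res.fun)


def random_rigid(rng):
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(0, 10, size=3)
    return R, t


class TestKabsch:
    def test_self_superposition(self, rng):
        X = rng.normal(size=(20, 3))
        res = superpose_kabsch(X, X)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_rigid_transform_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        R, t = random_rigid(rng)
        moved = X @ R.T + t
        assert superpose_kabsch(moved, X).rmsd <= 1e-9
        assert superpose_kabsch(X, moved).rmsd <= 1e-9

    def test_rotation_is_proper(self, rng):
        # a near-reflective pairing must still return det(R) = +1
        X = rng.normal(size=(10, 3))
        Y = X.copy()
        Y[:, 2] *= -1
        res = superpose_kabsch(X, Y)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0)

    def test_matches_quaternion_grid_oracle(self, rng):
        for n in (3, 4, 5):
            P = rng.normal(size=(n, 3))
            Q = rng.normal(size=(n, 3))
            ours = superpose_kabsch(P, Q).rmsd
            oracle = quaternion_grid_rmsd(P, Q)
            assert ours == pytest.approx(oracle, abs=1e-6)
            assert ours <= oracle + 1e-9  # never above the brute-force optimum

    def test_count_mismatch_and_too_few(self, rng):
        with pytest.raises(ValueError):
            superpose_kabsch(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
        with pytest.raises(ValueError):
            superpose_kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


class TestEnsembleRmsd:
    def test_noiseless_ensemble_all_zero(self):
        model = gen_toy_structure(20, [], seed=0)
        ens = perturb_ensemble(model, 10, noise_sd=0.0, seed=1)
        results = rmsd_to_ensemble(model, ens, atom_names=None)
        assert len(results) == 10
        assert all(r.rmsd <= 1e-9 for r in results)

    def test_noisy_ensemble_matches_planted_truth(self):
        model = gen_toy_structure(20, [], seed=0)
        ens = perturb_ensemble(model, 10, noise_sd=0.5, seed=2)
        results = rmsd_to_ensemble(model, ens, atom_names=None)
        for r, planted in zip(results, ens.metadata["planted_rmsd"]):
            assert r.rmsd == pytest.approx(planted, abs=1e-9)

    def test_restricted_selection_atom_count(self):
        model = gen_toy_structure(150, [], seed=0)
        ens = perturb_ensemble(model, 3, noise_sd=0.1, seed=3)
        positions = range(10, 130)  # 120 shared Cα positions
        results = rmsd_to_ensemble(model, ens, atom_names=("CA",), positions=positions)
        assert all(r.n_atoms == 120 for r in results)

    def test_empty_selection_errors(self):
        model = gen_toy_structure(5, [], seed=0)
        ens = perturb_ensemble(model, 2, noise_sd=0.0, seed=0)
        with pytest.raises(ValueError):
            rmsd_to_ensemble(model, ens, atom_names=("CB",))


def ion_pair_oracle(model, cutoff, include_his=True):
    """All-pairs nested-loop scan over charged side-chain atoms."""
    basic = dict(BASIC_ATOMS)
    if not include_his:
        basic.pop("HIS")
    names = model.residue_names()
    amap = model.atom_map()
    pairs = {}
    for ia, na in names.items():
        if na not in ACIDIC_ATOMS:
            continue
        for ib, nb in names.items():
            if nb not in basic:
                continue
            dists = [
                np.linalg.norm(amap[(ia, x)].xyz - amap[(ib, y)].xyz)
                for x in ACIDIC_ATOMS[na] if (ia, x) in amap
                for y in basic[nb] if (ib, y) in amap
            ]
            if dists and min(dists) <= cutoff:
                pairs[(ia, ib)] = min(dists)
    return pairs


def random_charged_structure(n_residues, seed):
    """Toy with random coordinates and a mix of charged residue types."""
    rng = np.random.default_rng(seed)
    cycle = ["ASP", "LYS", "GLU", "ARG", "ALA", "HIS", "SER"]
    side = {**ACIDIC_ATOMS, **BASIC_ATOMS}
    atoms = []
    for i in range(1, n_residues + 1):
        name = cycle[i % len(cycle)]
        center = rng.uniform(0, 30, size=3)
        atoms.append(AtomRecord(i, name, "CA", *center))
        for atom_name in side.get(name, ()):
            pos = center + rng.normal(0, 2, size=3)
            atoms.append(AtomRecord(i, name, atom_name, *pos))
    return StructureModel(atoms=atoms)


class TestIonPairs:
    def test_planted_pair_detected_at_exact_distance(self):
        model = gen_toy_structure(20, [(5, 12, 4.0)], seed=0)
        pairs = detect_ion_pairs(model, cutoff=6.0)
        assert [(p.acidic_index, p.basic_index) for p in pairs] == [(5, 12)]
        assert pairs[0].min_distance == pytest.approx(4.0, abs=0.01)

    def test_planted_pair_beyond_cutoff_absent(self):
        model = gen_toy_structure(20, [(5, 12, 6.5)], seed=0)
        assert detect_ion_pairs(model, cutoff=6.0) == []

    def test_no_planted_pairs_empty(self):
        model = gen_toy_structure(30, [], seed=0)
        assert detect_ion_pairs(model, cutoff=6.0) == []

    def test_matches_allpairs_oracle(self):
        model = random_charged_structure(40, seed=5)
        assert len(model.atoms) <= 500
        for cutoff in (4.0, 6.0, 8.0):
            ours = {
                (p.acidic_index, p.basic_index): p.min_distance
                for p in detect_ion_pairs(model, cutoff=cutoff)
            }
            oracle = ion_pair_oracle(model, cutoff)
            assert set(ours) == set(oracle)
            for key in ours:
                assert ours[key] == pytest.approx(oracle[key])

    def test_monotone_in_cutoff(self):
        model = random_charged_structure(40, seed=5)
        small = {(p.acidic_index, p.basic_index) for p in detect_ion_pairs(model, 4.0)}
        large = {(p.acidic_index, p.basic_index) for p in detect_ion_pairs(model, 6.0)}
        assert small <= large

    def test_his_toggle(self):
        model = random_charged_structure(40, seed=5)
        with_his = detect_ion_pairs(model, 8.0, include_his=True)
        without = detect_ion_pairs(model, 8.0, include_his=False)
        his_ids = {i for i, n in model.residue_names().items() if n == "HIS"}
        assert all(p.basic_index not in his_ids for p in without)
        assert len(without) <= len(with_his)


class TestPolarContacts:
    def test_single_close_pair(self):
        atoms = [
            AtomRecord(1, "ALA", "N", 0.0, 0.0, 0.0),
            AtomRecord(2, "ALA", "O", 3.0, 0.0, 0.0),
        ]
        contacts = detect_polar_contacts(StructureModel(atoms=atoms))
        assert len(contacts) == 1
        assert contacts[0].distance == pytest.approx(3.0)

    def test_within_residue_pairs_excluded(self):
        atoms = [
            AtomRecord(1, "ASN", "ND2", 0.0, 0.0, 0.0),
            AtomRecord(1, "ASN", "OD1", 1.3, 0.0, 0.0),
        ]
        assert detect_polar_contacts(StructureModel(atoms=atoms)) == []

    def test_diff_with_self_is_empty(self):
        model = random_charged_structure(20, seed=9)
        contacts = detect_polar_contacts(model)
        gained, lost = diff_contacts(contacts, contacts)
        assert gained == [] and lost == []

    def test_diff_isolates_a_moved_side_chain(self):
        base = [
            AtomRecord(1, "GLN", "NE2", 0.0, 0.0, 0.0),
            AtomRecord(3, "PRO", "O", 3.0, 0.0, 0.0),
            AtomRecord(5, "LYS", "NZ", 20.0, 0.0, 0.0),
            AtomRecord(7, "MET", "O", 30.0, 0.0, 0.0),
        ]
        moved = [a for a in base if not (a.res_index == 5)]
        moved.append(AtomRecord(5, "LYS", "NZ", 27.2, 0.0, 0.0))
        a = detect_polar_contacts(StructureModel(atoms=base))
        b = detect_polar_contacts(StructureModel(atoms=sorted(
            moved, key=lambda x: (x.res_index, x.atom_name))))
        gained, lost = diff_contacts(a, b)
        assert [(c.res_i, c.res_j) for c in gained] == [(5, 7)]
        assert lost == []

    def test_matches_allpairs_oracle(self):
        model = random_charged_structure(60, seed=3)
        assert len(model.atoms) <= 500
        contacts = detect_polar_contacts(model, donor_acceptor_cutoff=3.5)
        polar = [a for a in model.atoms if a.atom_name[0] in "NO"]
        expected = set()
        for i in range(len(polar)):
            for j in range(i + 1, len(polar)):
                a, b = polar[i], polar[j]
                if a.res_index == b.res_index:
                    continue
                if np.linalg.norm(a.xyz - b.xyz) <= 3.5:
                    expected.add(tuple(sorted(
                        [(a.res_index, a.atom_name), (b.res_index, b.atom_name)]
                    )))
        ours = {((c.res_i, c.atom_i), (c.res_j, c.atom_j)) for c in contacts}
        assert ours == expected


class TestPdbIO:
    def test_write_read_roundtrip(self, tmp_path):
        model = gen_toy_structure(10, [(2, 7, 4.5)], seed=0)
        path = tmp_path / "toy.pdb"
        write_structure(model, path)
        back = read_structure(path)
        assert isinstance(back, StructureModel)
        assert len(back.atoms) == len(model.atoms)
        ours, theirs = model.atom_map(), back.atom_map()
        assert set(ours) == set(theirs)
        for key in ours:
            assert ours[key].res_name == theirs[key].res_name
            assert np.allclose(ours[key].xyz, theirs[key].xyz, atol=1e-3)

    def test_multi_model_file_gives_ensemble(self, tmp_path):
        model = gen_toy_structure(8, [], seed=0)
        ens = perturb_ensemble(model, 10, noise_sd=0.1, seed=4)
        path = tmp_path / "ens.pdb"
        write_structure(ens, path)
        back = read_structure(path)
        assert isinstance(back, ConformerEnsemble)
        assert len(back) == 10

    def test_minimal_two_residue_pdb(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C\n"
            "ATOM      2  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C\n"
            "END\n"
        )
        model = read_structure(path, chain="A")
        assert sorted(model.residue_names().items()) == [(1, "ALA"), (2, "GLY")]

    def test_missing_atoms_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(ValueError):
            read_structure(path)

    def test_altloc_resolves_to_highest_occupancy(self, tmp_path):
        path = tmp_path / "alt.pdb"
        path.write_text(
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.30  0.00           C\n"
            "ATOM      2  CA BALA A   1       5.000   0.000   0.000  0.70  0.00           C\n"
            "END\n"
        )
        model = read_structure(path, chain="A")
        assert len(model.atoms) == 1
        assert model.atoms[0].x == pytest.approx(5.0)
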