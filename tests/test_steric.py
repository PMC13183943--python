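import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from climkit.steric import (
    AtomSet,
    count_i4_hbonds,
    extended_length,
    mc_overlap_volume,
    mutate_sidechain,
    superpose,
)
from climkit.synthetic import make_helix_coords, make_sphere_set


def lens_volume(r: float, d: float) -> float:
    """Closed-form intersection volume of two equal spheres."""
    if d >= 2 * r:
        return 0.0
    return np.pi * (4 * r + d) * (2 * r - d) ** 2 / 12.0


class TestOverlapVolume:
    def test_coincident_unit_spheres(self):
        s = make_sphere_set([[0, 0, 0]], [1.0])
        vol, se = mc_overlap_volume(s, s, n_samples=400_000, seed=1)
        assert abs(vol - 4 * np.pi / 3) <= 3 * se

    def test_two_sphere_lens_oracle(self):
        a = make_sphere_set([[0, 0, 0]], [1.0])
        b = make_sphere_set([[1.0, 0, 0]], [1.0])
        vol, se = mc_overlap_volume(a, b, n_samples=400_000, seed=2)
        assert abs(vol - lens_volume(1.0, 1.0)) <= 3 * se
        assert lens_volume(1.0, 1.0) == pytest.approx(5 * np.pi / 12)

    def test_disjoint_spheres_give_zero(self):
        a = make_sphere_set([[0, 0, 0]], [1.0])
        b = make_sphere_set([[3.0, 0, 0]], [1.0])
        vol, se = mc_overlap_volume(a, b, n_samples=50_000, seed=3)
        assert vol == 0.0 and se == 0.0

    def test_symmetry_and_upper_bound(self):
        rng = np.random.default_rng(8)
        a = make_sphere_set(rng.normal(0, 1, (5, 3)), [1.0] * 5)
        b = make_sphere_set(rng.normal(0.5, 1, (3, 3)), [1.2] * 3)
        va, sa = mc_overlap_volume(a, b, n_samples=200_000, seed=4)
        vb, sb = mc_overlap_volume(b, a, n_samples=200_000, seed=4)
        assert abs(va - vb) <= 4 * (sa + sb)
        # the intersection cannot exceed the volume of either body
        vol_b, se_b = mc_overlap_volume(b, b, n_samples=200_000, seed=5)
        assert va <= vol_b + 3 * (sa + se_b)

    def test_convergence_with_sample_count(self):
        a = make_sphere_set([[0, 0, 0]], [1.0])
        b = make_sphere_set([[0.8, 0, 0]], [1.0])
        exact = lens_volume(1.0, 0.8)
        errs = []
        for n in (2_000, 200_000):
            vol, se = mc_overlap_volume(a, b, n_samples=n, seed=6)
            errs.append((abs(vol - exact), se))
        # standard error shrinks ~1/sqrt(n): factor 10 for 100x samples
        assert errs[1][1] < errs[0][1] / 5
        assert errs[1][0] <= 3 * errs[1][1]

    def test_determinism_and_validation(self):
        a = make_sphere_set([[0, 0, 0]], [1.0])
        b = make_sphere_set([[1, 0, 0]], [1.0])
        assert mc_overlap_volume(a, b, 10_000, seed=9) == mc_overlap_volume(
            a, b, 10_000, seed=9
        )
        with pytest.raises(ValueError):
            mc_overlap_volume(a, b, n_samples=0, seed=1)


def leucine_like_residue():
    """One residue with backbone plus a two-atom sidechain pointing +x."""
    names = ["N", "CA", "C", "O", "CB", "CG"]
    coords = np.array(
        [
            [-1.2, 0.8, 0.0],
            [0.0, 0.0, 0.0],
            [-0.5, -1.4, 0.0],
            [-1.6, -1.8, 0.3],
            [1.0, 0.3, 1.1],
            [2.2, 0.9, 1.4],
        ]
    )
    n = len(names)
    return AtomSet(
        chain=np.full(n, "A", dtype=object),
        res_id=np.full(n, 75),
        res_name=np.full(n, "LEU", dtype=object),
        atom_name=np.array(names, dtype=object),
        coords=coords,
        radius=np.full(n, 1.7),
        element=np.array(["N", "C", "C", "O", "C", "C"], dtype=object),
    )


class TestSidechainTruncation:
    def test_gly_keeps_backbone_only(self):
        res = leucine_like_residue()
        out = mutate_sidechain(res, "A", 75, "GLY")
        assert sorted(out.atom_name) == ["C", "CA", "N", "O"]
        assert set(out.res_name) == {"GLY"}

    def test_ala_keeps_cb(self):
        out = mutate_sidechain(leucine_like_residue(), "A", 75, "ALA")
        assert sorted(out.atom_name) == ["C", "CA", "CB", "N", "O"]

    def test_ala_to_ala_is_identity(self):
        ala = mutate_sidechain(leucine_like_residue(), "A", 75, "ALA")
        again = mutate_sidechain(ala, "A", 75, "ALA")
        assert np.array_equal(again.coords, ala.coords)
        assert list(again.atom_name) == list(ala.atom_name)

    def test_missing_residue_or_backbone_rejected(self):
        res = leucine_like_residue()
        with pytest.raises(ValueError):
            mutate_sidechain(res, "A", 99, "GLY")
        no_ca = res._mask(res.atom_name != "CA")
        with pytest.raises(ValueError):
            mutate_sidechain(no_ca, "A", 75, "GLY")
        with pytest.raises(ValueError):
            mutate_sidechain(res, "A", 75, "TRP")

    def test_truncation_never_increases_overlap(self):
        """Removing sidechain spheres can only shrink the clash volume
        with a probe placed against the sidechain (as for the arrest
        peptide's Leu75 against the release-factor GGQ loop)."""
        res = leucine_like_residue()
        probe = make_sphere_set([[2.5, 1.0, 1.5]], [1.8])
        v_leu, se0 = mc_overlap_volume(res, probe, 150_000, seed=10)
        v_ala, se1 = mc_overlap_volume(
            mutate_sidechain(res, "A", 75, "ALA"), probe, 150_000, seed=10
        )
        v_gly, se2 = mc_overlap_volume(
            mutate_sidechain(res, "A", 75, "GLY"), probe, 150_000, seed=10
        )
        tol = 3 * (se0 + se1 + se2 + 1e-9)
        assert v_ala <= v_leu + tol
        assert v_gly <= v_ala + tol
        assert v_gly < v_leu  # the probe sits against the CG atom


class TestSuperpose:
    def _random_atoms(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return rng.normal(0, 3, (n, 3))

    def test_identity(self):
        P = self._random_atoms()
        R, t, rmsd = superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(R, np.eye(3), atol=1e-12)
        assert np.allclose(t, 0, atol=1e-12)

    def test_pure_rotation_recovered(self):
        P = self._random_atoms(seed=1)
        rot = Rotation.from_euler("z", 90, degrees=True)
        Q = rot.apply(P)
        R, t, rmsd = superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(R, rot.as_matrix(), atol=1e-9)

    def test_noise_rmsd_matches_direct_computation(self):
        rng = np.random.default_rng(2)
        P = self._random_atoms(n=30, seed=3)
        Q = P + rng.normal(0, 0.1, P.shape)
        R, t, rmsd = superpose(P, Q)
        direct = np.sqrt(np.mean(np.sum((P @ R.T + t - Q) ** 2, axis=1)))
        assert rmsd == pytest.approx(direct, abs=1e-12)
        # independent cross-check of the optimum via scipy
        rot, rssd = Rotation.align_vectors(
            Q - Q.mean(axis=0), P - P.mean(axis=0)
        )
        assert rmsd == pytest.approx(rssd / np.sqrt(P.shape[0]), abs=1e-9)

    def test_rmsd_invariant_to_mobile_pretransform(self):
        P = self._random_atoms(n=12, seed=4)
        Q = self._random_atoms(n=12, seed=5)
        _, _, rmsd0 = superpose(P, Q)
        pre = Rotation.from_euler("xyz", [10, 75, -40], degrees=True)
        _, _, rmsd1 = superpose(pre.apply(P) + [5.0, -2.0, 9.0], Q)
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError):
            superpose(line, line)


class TestHbondCensus:
    def test_ideal_helix_ten_residues_has_six_pairs(self):
        helix = make_helix_coords(10)
        n, pairs = count_i4_hbonds(helix, residue_range=range(1, 11))
        assert n == 6
        assert pairs == [(i, i + 4) for i in range(1, 7)]

    def test_extended_chain_has_none(self):
        chain = make_helix_coords(10, phi=-180.0, psi=180.0)
        n, _ = count_i4_hbonds(chain)
        assert n == 0

    def test_short_range_has_no_pairs(self):
        helix = make_helix_coords(10)
        n, _ = count_i4_hbonds(helix, residue_range=range(1, 5))
        assert n == 0

    def test_missing_atoms_skip_with_warning(self):
        helix = make_helix_coords(10)
        gutted = helix._mask(
            ~((helix.res_id == 3) & (helix.atom_name == "O"))
        )
        with pytest.warns(UserWarning):
            n, pairs = count_i4_hbonds(gutted)
        assert n == 5
        assert (3, 7) not in pairs


class TestExtendedLength:
    @pytest.mark.parametrize(
        "n,rise,expected", [(27, 3.5, 94.5), (0, 3.5, 0.0), (10, 3.5, 35.0)]
    )
    def test_values(self, n, rise, expected):
        assert extended_length(n, rise) == expected

    def test_linearity_and_validation(self):
        assert extended_length(12) + extended_length(15) == extended_length(27)
        with pytest.raises(ValueError):
            extended_length(-1)


def test_atomset_validation_and_selection():
    with pytest.raises(ValueError):
        AtomSet.from_spheres([[0, 0, 0]], [-1.0])
    with pytest.raises(ValueError):
        AtomSet.from_spheres([[np.inf, 0, 0]], [1.0])
    helix = make_helix_coords(5, first_res_id=10)
    sel = helix.select(chain="A", res_ids=range(11, 13), atom_names=["CA"])
    assert len(sel) == 2
    assert set(sel.res_id) == {11, 12}


def test_structure_file_roundtrip(tmp_path):
    """AtomSet survives a PDB write/read cycle through gemmi."""
    import gemmi

    helix = make_helix_coords(6)
    st = gemmi.Structure()
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")
    for rid in sorted(set(helix.res_id)):
        res = gemmi.Residue()
        res.name = "ALA"
        res.seqid = gemmi.SeqId(int(rid), " ")
        sub = helix.select(res_ids=[rid])
        for name, xyz, el in zip(sub.atom_name, sub.coords, sub.element):
            atom = gemmi.Atom()
            atom.name = str(name)
            atom.element = gemmi.Element(str(el))
            atom.pos = gemmi.Position(*xyz)
            res.add_atom(atom)
        chain.add_residue(res)
    model.add_chain(chain)
    st.add_model(model)
    path = tmp_path / "helix.pdb"
    st.write_pdb(str(path))

    loaded = AtomSet.from_structure(path)
    assert len(loaded) == len(helix)
    assert np.allclose(loaded.coords, helix.coords, atol=1e-3)
    n, _ = count_i4_hbonds(loaded)
    assert n == 2  # six residues -> pairs (1,5) and (2,6)
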