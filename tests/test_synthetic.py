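import gzip

import numpy as np
import pytest

import climkit as ck
from climkit._fastq import iter_fastq, read_fastq_matrix
from climkit.read_processing import merge_pair, revcomp
from climkit.synthetic import (
    SimulationSpec,
    make_helix_coords,
    make_sphere_set,
    simulate_library,
    simulate_toeprint_peaks,
)
from climkit.toeprint import ToeprintCalibration


def tiny_spec(fitness_map, **kw):
    defaults = dict(
        true_relative_fitness=fitness_map,
        depth_t0=500,
        depth_t1=500,
        per_base_error=0.0,
        seed=3,
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


class TestSimulateLibrary:
    def test_truth_frequencies_conserve(self, clean_library):
        assert clean_library.truth.frame["freq_t0"].sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_metadata_schema_and_sample_grid(self, clean_library):
        md = clean_library.metadata
        assert len(md) == 8  # 2 replicates x 2 conditions x 2 timepoints
        assert set(md["condition"]) == {"spc", "nospc"}
        assert set(md["timepoint"]) == {"t0", "t1"}
        assert (md["cfu"] > 0).all()

    def test_reads_are_150nt_and_overlap_by_42(self, design, clean_library):
        s1, q1 = read_fastq_matrix(
            clean_library.out_dir / "rep1_nospc_t0_R1.fastq.gz"
        )
        s2, q2 = read_fastq_matrix(
            clean_library.out_dir / "rep1_nospc_t0_R2.fastq.gz"
        )
        assert s1.shape[1] == s2.shape[1] == 150
        merged = merge_pair(
            (s1[0].tobytes().decode(), q1[0]),
            (s2[0].tobytes().decode(), q2[0]),
        )
        assert merged.overlap == 2 * 150 - design.insert_len == 42
        assert len(merged.sequence) == design.insert_len

    def test_error_free_reads_reconstruct_planted_inserts(
        self, design, clean_library
    ):
        """Left-inverse property: merging error-free pairs recovers the
        insert of the planted variant for every read checked."""
        from climkit.variant_calling import classify, parse_insert

        drawn = clean_library.drawn_counts["rep2_spc_t1"]
        s1, q1 = read_fastq_matrix(
            clean_library.out_dir / "rep2_spc_t1_R1.fastq.gz"
        )
        s2, q2 = read_fastq_matrix(
            clean_library.out_dir / "rep2_spc_t1_R2.fastq.gz"
        )
        seen = {}
        for i in range(400):
            merged = merge_pair(
                (s1[i].tobytes().decode(), q1[i]),
                (s2[i].tobytes().decode(), q2[i]),
            )
            cls = classify(parse_insert(merged, design), design)
            key = "WT" if cls.kind == "WT" else (cls.position, cls.codon)
            seen[key] = seen.get(key, 0) + 1
        for key, n in seen.items():
            assert drawn.get(key, 0) >= n

    def test_determinism_byte_identical(self, design, fitness_map, tmp_path):
        spec = tiny_spec(fitness_map, per_base_error=0.002)
        a = simulate_library(design, spec, tmp_path / "a")
        b = simulate_library(design, spec, tmp_path / "b")
        for name in ("rep1_spc_t0_R1.fastq.gz", "rep2_nospc_t1_R2.fastq.gz"):
            assert (a.out_dir / name).read_bytes() == (
                b.out_dir / name
            ).read_bytes()
        assert a.metadata.equals(b.metadata)

    def test_zero_depth_yields_empty_valid_fastq(
        self, design, fitness_map, tmp_path
    ):
        spec = tiny_spec(fitness_map, depth_t0=0, depth_t1=0)
        lib = simulate_library(design, spec, tmp_path)
        path = lib.out_dir / "rep1_spc_t0_R1.fastq.gz"
        with gzip.open(path) as fh:
            assert fh.read() == b""
        assert list(iter_fastq(path)) == []

    def test_negative_fitness_rejected(self, design, fitness_map, tmp_path):
        bad = dict(fitness_map)
        bad[(50, "A")] = -0.5
        with pytest.raises(ValueError):
            tiny_spec(bad)

    def test_cfu_reflects_planted_bulk_growth(self, clean_library):
        md = clean_library.metadata.set_index("sample_id")
        tr = clean_library.truth.frame
        h = md.loc["rep1_nospc_t1", "culture_hours"]
        z = float(tr["freq_t0"] @ 2.0 ** (tr["g_nospc"] * h))
        cfu0 = md.loc["rep1_nospc_t0", "cfu"]
        assert md.loc["rep1_nospc_t1", "cfu"] == round(cfu0 * z)


class TestToeprintFixture:
    def test_single_site_noiseless(self):
        calib = ToeprintCalibration(76, 176)
        peaks = simulate_toeprint_peaks([(76, 1.0)], calib, noise_sd=0.0)
        assert peaks.peaks == [(176, 1.0)]

    def test_empty_sites_empty_table(self):
        calib = ToeprintCalibration(76, 176)
        assert len(simulate_toeprint_peaks([], calib)) == 0

    def test_adjacent_codons_are_3nt_apart(self):
        calib = ToeprintCalibration(76, 176)
        peaks = simulate_toeprint_peaks(
            [(75, 0.4), (76, 1.0)], calib, noise_sd=0.0
        )
        lengths = peaks.lengths()
        assert lengths[0] - lengths[1] == 3

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            simulate_toeprint_peaks(
                [(76, -1.0)], ToeprintCalibration(76, 176)
            )


class TestCoordinateFixtures:
    def test_single_residue_backbone(self):
        atoms = make_helix_coords(1)
        assert sorted(atoms.atom_name) == ["C", "CA", "N", "O"]

    def test_helix_geometry(self):
        """Ideal helix: ~1.5 A rise per residue and (i, i+4) O...N
        distances near 3 A, i.e. all hydrogen-bondable."""
        helix = make_helix_coords(20)
        ca = helix.select(atom_names=["CA"]).coords
        # helix axis = principal component of the CA trace
        _, _, vt = np.linalg.svd(ca - ca.mean(axis=0))
        rise = np.abs(np.diff(ca @ vt[0]))
        assert np.mean(rise) == pytest.approx(1.5, abs=0.05)
        assert np.allclose(rise, 1.5, atol=0.1)
        for i in range(1, 16):
            o = helix.select(res_ids=[i], atom_names=["O"]).coords[0]
            n = helix.select(res_ids=[i + 4], atom_names=["N"]).coords[0]
            assert abs(np.linalg.norm(o - n) - 3.0) < 0.35

    def test_extended_chain_has_no_helical_contacts(self):
        chain = make_helix_coords(10, phi=-180.0, psi=180.0)
        n, _ = ck.count_i4_hbonds(chain, residue_range=range(1, 11))
        assert n == 0

    def test_sphere_set_volume_oracle(self):
        s = make_sphere_set([[0.0, 0.0, 0.0]], [1.0])
        vol, se = ck.mc_overlap_volume(s, s, n_samples=200_000, seed=5)
        assert abs(vol - 4.0 * np.pi / 3.0) <= 3.0 * se

    def test_helix_rejects_empty(self):
        with pytest.raises(ValueError):
            make_helix_coords(0)
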