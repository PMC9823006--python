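"""Structure I/O, superposition statistics, CSP painting, clustering test."""

import itertools

import numpy as np
import pytest

import cspmap as cm
from cspmap.structure import (
    StructureError,
    make_synthetic_structure,
    mean_pairwise_rmsd,
    paint_csp,
    patch_clustering,
    read_structure,
    reference_mean_rmsd,
    superpose,
)

PDB_3RES = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00 10.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00 10.00           C
ATOM      3  CA ALYS A   2      12.000   8.000  -4.000  0.40 10.00           C
ATOM      4  CA BLYS A   2      12.100   8.100  -4.100  0.60 10.00           C
ATOM      5  CA  GLY A   3      14.000   9.000  -3.000  1.00 10.00           C
END
"""


def kabsch_rmsd_oracle(x, y):
    """Independent superposition rmsd via gemmi (QCP), ~1e-6 precision."""
    import gemmi

    pa = [gemmi.Position(*p) for p in x]
    pb = [gemmi.Position(*p) for p in y]
    return float(gemmi.superpose_positions(pa, pb).rmsd)


class TestReadStructure:
    def test_three_residues(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(PDB_3RES)
        model = read_structure(p)
        coords = model.ca_coords("A")
        assert sorted(coords) == [1, 2, 3]

    def test_altloc_highest_occupancy_wins(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(PDB_3RES)
        coords = read_structure(p).ca_coords("A")
        assert coords[2] == pytest.approx([12.1, 8.1, -4.1], abs=1e-3)

    def test_round_trip_preserves_ca_coordinates(self, tmp_path):
        model = make_synthetic_structure(20, chains=("A", "B"), jitter=0.3, seed=1)
        out = model.write(tmp_path / "rt.pdb")
        back = read_structure(out)
        for ch in ("A", "B"):
            a, b = model.ca_coords(ch), back.ca_coords(ch)
            for r in a:
                assert b[r] == pytest.approx(a[r], abs=1e-3)

    def test_no_ca_is_error(self, tmp_path):
        p = tmp_path / "noca.pdb"
        p.write_text(
            "ATOM      1  N   ALA A   1      1.000   2.000   3.000  1.00  0.00           N\nEND\n"
        )
        with pytest.raises(StructureError, match="C-alpha"):
            read_structure(p)


class TestSuperpose:
    def test_identity(self):
        model = make_synthetic_structure(30)
        c = model.ca_coords("A")
        _, _, rmsd = superpose(c, c)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        model = make_synthetic_structure(40, seed=2)
        a = model.ca_coords("A")
        rot = Rotation.from_euler("xyz", [20, -40, 65], degrees=True).as_matrix()
        shift = np.array([5.0, -3.0, 12.0])
        b = {r: rot @ xyz + shift for r, xyz in a.items()}
        rmat, _, rmsd = superpose(a, b)
        assert rmsd <= 1e-9
        assert np.linalg.det(rmat) == pytest.approx(1.0, abs=1e-9)

    def test_symmetric_in_arguments(self):
        model = make_synthetic_structure(40, chains=("A", "B"), jitter=0.4, seed=3)
        a, b = model.ca_coords("A"), model.ca_coords("B")
        assert superpose(a, b)[2] == pytest.approx(superpose(b, a)[2], abs=1e-9)

    def test_agrees_with_gemmi_oracle(self):
        model = make_synthetic_structure(50, chains=("A", "B"), jitter=0.5, seed=4)
        a, b = model.ca_coords("A"), model.ca_coords("B")
        common = sorted(set(a) & set(b))
        x = np.array([a[r] for r in common])
        y = np.array([b[r] for r in common])
        assert superpose(a, b)[2] == pytest.approx(kabsch_rmsd_oracle(x, y), abs=1e-5)

    def test_transform_maps_moving_onto_fixed(self):
        model = make_synthetic_structure(30, chains=("A", "B"), jitter=0.2, seed=8)
        a, b = model.ca_coords("A"), model.ca_coords("B")
        rot, trans, rmsd = superpose(a, b)
        common = sorted(set(a) & set(b))
        moved = np.array([rot @ b[r] + trans for r in common])
        fixed = np.array([a[r] for r in common])
        direct = np.sqrt(((moved - fixed) ** 2).sum() / len(common))
        assert direct == pytest.approx(rmsd, abs=1e-9)

    def test_jitter_rmsd_matches_monte_carlo_expectation(self):
        """Two sigma=0.5 A jittered copies: rmsd agrees with the MC oracle."""
        sigma, n = 0.5, 160
        observed = []
        for seed in range(40):
            model = make_synthetic_structure(n, chains=("A", "B"), jitter=sigma, seed=seed)
            observed.append(superpose(model.ca_coords("A"), model.ca_coords("B"))[2])
        # oracle: same statistic from raw Gaussian point clouds
        rng = np.random.default_rng(123)
        mc = []
        for _ in range(200):
            base = rng.normal(0, 10, (n, 3))
            x = base + rng.normal(0, sigma, (n, 3))
            y = base + rng.normal(0, sigma, (n, 3))
            mc.append(kabsch_rmsd_oracle(x, y))
        tol = 3 * (np.std(mc) / np.sqrt(len(mc)) + np.std(observed) / np.sqrt(len(observed)))
        assert np.mean(observed) == pytest.approx(np.mean(mc), abs=tol)

    def test_too_few_shared_residues(self):
        a = {1: np.zeros(3), 2: np.ones(3)}
        with pytest.raises(StructureError):
            superpose(a, a)


class TestMeanPairwiseRmsd:
    def test_duplicated_chain_gives_zero(self):
        model = make_synthetic_structure(30, chains=("A", "B"), jitter=0.0, seed=0)
        mean, mat, n_common = mean_pairwise_rmsd(model)
        assert mean == pytest.approx(0.0, abs=1e-9)
        assert n_common == 30

    def test_matrix_symmetric_zero_diagonal(self):
        model = make_synthetic_structure(25, chains=("A", "B", "C"), jitter=0.4, seed=5)
        _, mat, _ = mean_pairwise_rmsd(model)
        assert np.allclose(mat.values, mat.values.T)
        assert np.allclose(np.diag(mat.values), 0.0)

    def test_single_chain_is_error(self):
        model = make_synthetic_structure(10)
        with pytest.raises(StructureError):
            mean_pairwise_rmsd(model)

    def test_reference_chain_mean(self):
        model = make_synthetic_structure(25, chains=("A", "B", "C"), jitter=0.4, seed=6)
        ref_mean = reference_mean_rmsd(model, "A")
        _, mat, _ = mean_pairwise_rmsd(model)
        assert ref_mean == pytest.approx((mat.loc["A", "B"] + mat.loc["A", "C"]) / 2)


class TestPaintCsp:
    def test_b_factors_carry_scaled_csp(self, tmp_path, fc14_truth, fc14_series):
        tracks = cm.track_series(fc14_series)
        table = cm.csp_table_from_tracks(tracks, unassigned=fc14_truth.missing_residues)
        model = make_synthetic_structure(191, chains=("A", "B"), start_residue=2)
        out, report = paint_csp(model, table, "B", tmp_path / "painted.pdb")
        back = read_structure(out)
        dd = table.dd()
        ch = back.structure[0].find_chain("B")
        for res in ch:
            num = res.seqid.num
            for atom in res:
                if num in dd:
                    assert atom.b_iso == pytest.approx(min(100 * dd[num], 999.99), abs=0.01)
                else:
                    assert atom.b_iso == 0.0
        assert any("unassigned" in line or "not in CSP table" in line for line in report)

    def test_missing_chain_is_error(self, tmp_path, fc14_series):
        tracks = cm.track_series(fc14_series)
        table = cm.csp_table_from_tracks(tracks)
        model = make_synthetic_structure(50)
        with pytest.raises(StructureError):
            paint_csp(model, table, "Z", tmp_path / "x.pdb")

    def test_coordinates_untouched(self, tmp_path, fc14_series):
        tracks = cm.track_series(fc14_series)
        table = cm.csp_table_from_tracks(tracks)
        model = make_synthetic_structure(191, start_residue=2)
        before = model.ca_coords("A")
        out, _ = paint_csp(model, table, "A", tmp_path / "p.pdb")
        after = read_structure(out).ca_coords("A")
        for r in before:
            assert after[r] == pytest.approx(before[r], abs=1e-3)


class TestPatchClustering:
    def test_adjacent_patch_on_extended_chain_matches_enumeration(self):
        """Permutation p agrees with brute-force subset enumeration (10 residues)."""
        model = make_synthetic_structure(10, start_residue=1)
        coords = model.ca_coords("A")
        sig = [1, 2, 3]

        def stat(rs):
            xyz = np.array([coords[r] for r in rs])
            d = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
            iu = np.triu_indices(len(rs), 1)
            return d[iu].mean()

        obs = stat(sig)
        all_stats = [stat(c) for c in itertools.combinations(sorted(coords), 3)]
        exact_frac = np.mean([s <= obs for s in all_stats])
        observed, p = patch_clustering(model, "A", sig, n_perm=2000, seed=0)
        assert observed == pytest.approx(obs)
        assert p == pytest.approx(exact_frac, abs=0.03)
        assert p < 0.2  # adjacent patch is tight vs scattered null

    def test_all_residues_gives_p_near_one(self):
        model = make_synthetic_structure(12)
        _, p = patch_clustering(model, "A", list(model.ca_coords("A")), n_perm=200, seed=1)
        assert p == 1.0

    def test_reproducible_and_in_range(self):
        model = make_synthetic_structure(30, seed=9)
        sig = [5, 6, 7, 8]
        _, p1 = patch_clustering(model, "A", sig, n_perm=300, seed=4)
        _, p2 = patch_clustering(model, "A", sig, n_perm=300, seed=4)
        assert p1 == p2
        assert 0 < p1 <= 1

    def test_small_inputs_rejected(self):
        model = make_synthetic_structure(10)
        with pytest.raises(ValueError):
            patch_clustering(model, "A", [1, 2], n_perm=200, seed=0)
        with pytest.raises(ValueError):
            patch_clustering(model, "A", [1, 2, 3], n_perm=0, seed=0)
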