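import math

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.PDB import PDBParser

from hdacpcm import (
    bundled_p0_matrix,
    bundled_p1_matrix,
    build_p0,
    compute_geometry_descriptors,
    generate_helix_structure,
    global_identity,
    load_similarity_matrix,
)
from hdacpcm.protein_descriptors import global_alignment_stats

# ---------------------------------------------------------------------------
# independent dynamic-programming reference for the global aligner
# (Gotoh affine-gap recursion with free terminal gaps, EMBOSS conventions)
# ---------------------------------------------------------------------------

_B62 = substitution_matrices.load("BLOSUM62")


def _reference_global_score(a: str, b: str, gap_open=10.0, gap_extend=0.5) -> float:
    open_cost = gap_open + gap_extend  # first gapped residue
    ext_cost = gap_extend
    n, m = len(a), len(b)
    NEG = -math.inf
    # state 0 = match/mismatch, 1 = gap in b (a consumed), 2 = gap in a
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # leading gaps are free
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _B62[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - open_cost, X[i - 1][j] - ext_cost,
                          Y[i - 1][j] - open_cost)
            Y[i][j] = max(M[i][j - 1] - open_cost, Y[i][j - 1] - ext_cost,
                          X[i][j - 1] - open_cost)
    # free trailing gaps: best over last row/column
    best = max(M[n][m], X[n][m], Y[n][m])
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best


class TestGlobalIdentity:
    def test_self_identity_is_100(self):
        assert global_identity("MKTAYIAKQR", "MKTAYIAKQR") == pytest.approx(100.0)

    def test_disjoint_equal_length(self):
        assert global_identity("AAAA", "CCCC") == pytest.approx(0.0)

    @pytest.mark.parametrize("a, b", [("MKTAYIAKQR", "MKTAYI"), ("ACDEFG", "ACDKFG"),
                                      ("WWWW", "WAW")])
    def test_symmetry(self, a, b):
        assert global_identity(a, b) == pytest.approx(global_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_identity("", "ACD")

    def test_bad_alphabet_rejected(self):
        with pytest.raises(ValueError, match="non-amino-acid"):
            global_identity("ACDB1", "ACD")

    def test_x_tolerated(self):
        assert global_identity("ACXDE", "ACXDE") == pytest.approx(100.0)

    def test_score_matches_dp_reference_on_random_pairs(self):
        rng = np.random.default_rng(42)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(30):
            a = "".join(rng.choice(list(aa), size=rng.integers(3, 13)))
            b = "".join(rng.choice(list(aa), size=rng.integers(3, 13)))
            stats = global_alignment_stats(a, b)
            assert stats.score == pytest.approx(_reference_global_score(a, b), abs=1e-9)

    def test_identity_denominator_includes_gaps(self):
        # identical 6-mer against itself plus 2 flanking residues: 6 identities
        # over an 8-column alignment
        stats = global_alignment_stats("ACDEFG", "WACDEFGW")
        assert stats.alignment_length == 8
        assert stats.identical == 6
        assert stats.identity_percent == pytest.approx(75.0)


class TestSimilarityMatrices:
    def test_build_p0_single_sequence(self):
        m = build_p0({"A": "MKTAYIAKQR"}, {"A": "MKTAYIAKQR"})
        assert m.values.shape == (1, 1)
        assert m.values[0, 0] == pytest.approx(100.0)

    def test_build_p0_duplicate_reference_warns_keeps_both(self):
        with pytest.warns(UserWarning, match="duplicates"):
            m = build_p0({"A": "MKTAYIAKQR"}, {"r1": "MKTAYIAKQR", "r2": "MKTAYIAKQR"})
        assert m.values.shape == (1, 2)

    def test_bundled_p0_shape_and_self(self):
        m = bundled_p0_matrix()
        assert m.values.shape == (5, 11)
        df = m.to_frame()
        for t in df.index:
            assert df.loc[t, t] == pytest.approx(100.0)

    def test_bundled_p1_fixture(self):
        m = bundled_p1_matrix()
        df = m.to_frame()
        assert df.shape == (5, 5)
        assert df.loc["HDAC4", "HDAC7"] == pytest.approx(0.706)
        assert np.allclose(df.to_numpy(), df.to_numpy().T)
        assert np.allclose(np.diag(df.to_numpy()), 1.0)

    def test_identity_matrix_passes(self, tmp_path):
        path = tmp_path / "sim.csv"
        path.write_text("target_id,A,B\nA,1.0,0.0\nB,0.0,1.0\n")
        m = load_similarity_matrix(path)
        assert np.allclose(m.values, np.eye(2))

    def test_violated_self_similarity(self, tmp_path):
        path = tmp_path / "sim.csv"
        path.write_text("target_id,A,B\nA,0.9,0.1\nB,0.1,1.0\n")
        with pytest.raises(ValueError, match="self-similarity"):
            load_similarity_matrix(path)

    def test_non_numeric_cell(self, tmp_path):
        path = tmp_path / "sim.csv"
        path.write_text("target_id,A,B\nA,1.0,oops\nB,0.1,1.0\n")
        with pytest.raises(ValueError, match="non-numeric|missing value"):
            load_similarity_matrix(path)

    def test_negative_value_rejected(self, tmp_path):
        path = tmp_path / "sim.csv"
        path.write_text("target_id,A,B\nA,1.0,-0.2\nB,0.1,1.0\n")
        with pytest.raises(ValueError, match="non-negative"):
            load_similarity_matrix(path)


class TestGeometryDescriptors:
    def test_vector_length_and_order(self, helix_pdb):
        g = compute_geometry_descriptors(helix_pdb, target_id="helix")
        assert g.features.shape == (30,)
        assert len(g.feature_names) == 30
        assert g.feature_names[0] == "len_N_CA_mean"

    def test_ideal_helix_bond_lengths(self, helix_pdb):
        g = compute_geometry_descriptors(helix_pdb)
        d = dict(zip(g.feature_names, g.features))
        assert 1.30 <= d["len_C_Nnext_mean"] <= 1.36
        assert d["len_C_Nnext_sd"] < 0.02
        # coordinates are quantized to 0.001 A by the PDB format, so the
        # noise-free spread is bounded by rounding, not exactly zero
        for cls in ("len_N_CA", "len_CA_C", "len_C_O", "len_CA_CB"):
            assert d[f"{cls}_sd"] < 2e-3

    def test_ideal_helix_dihedrals(self, helix_pdb):
        g = compute_geometry_descriptors(helix_pdb)
        d = dict(zip(g.feature_names, g.features))
        assert d["dih_phi_mean"] == pytest.approx(-57.0, abs=0.1)
        assert d["dih_psi_mean"] == pytest.approx(-47.0, abs=0.1)

    def test_polyalanine_has_no_chi1(self, helix_pdb):
        g = compute_geometry_descriptors(helix_pdb)
        assert g.missing_classes == ["dih_chi1"]
        d = dict(zip(g.feature_names, g.features))
        assert math.isnan(d["dih_chi1_mean"]) and math.isnan(d["dih_chi1_sd"])

    def test_rigid_motion_invariance(self, helix_pdb):
        parser = PDBParser(QUIET=True)
        ref = compute_geometry_descriptors(helix_pdb)
        structure = parser.get_structure("h", str(helix_pdb))
        # random proper rotation + translation
        rng = np.random.default_rng(7)
        A = rng.standard_normal((3, 3))
        q, _ = np.linalg.qr(A)
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = rng.uniform(-20, 20, 3)
        for atom in structure.get_atoms():
            atom.set_coord(q @ atom.get_coord() + shift)
        moved = compute_geometry_descriptors(structure)
        assert np.allclose(ref.features, moved.features, atol=1e-6, equal_nan=True)

    def test_two_residue_fragment_rejected(self, tmp_path):
        text = generate_helix_structure(3, seed=0)
        # drop the last residue's atoms -> only 2 residues remain
        lines = [l for l in text.splitlines() if not (l.startswith("ATOM") and " A   3 " in l)]
        path = tmp_path / "frag.pdb"
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="insufficient"):
            compute_geometry_descriptors(path)

    def test_hetatm_ignored(self, tmp_path, helix_pdb):
        text = helix_pdb.read_text().replace("END", "")
        text += (
            "HETATM  999  ZN   ZN A 900      10.000  10.000  10.000  1.00  0.00          ZN\n"
            "END\n"
        )
        path = tmp_path / "with_het.pdb"
        path.write_text(text)
        ref = compute_geometry_descriptors(helix_pdb)
        withhet = compute_geometry_descriptors(path)
        assert np.allclose(ref.features, withhet.features, equal_nan=True)
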