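"""MSA parsing, sequence weighting, profile features and coupling statistics."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coevodist.alphabet import AA20
from coevodist.errors import DimensionError, EmptyInputError, MSAFormatError
from coevodist.msa import (
    Alignment,
    ProfileFeatures,
    apc_correct,
    assemble_pair_features,
    column_entropy,
    compute_pssm,
    covariant_contact_potential,
    load_pair_features,
    mutual_information,
    read_coupling_matrix,
    read_msa,
    save_pair_features,
    sequence_weights,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------

def oracle_neff(rows: list[str], thr: float) -> float:
    """O(M^2 L) pairwise identity loop; identity over query non-gap columns."""
    cols = [c for c, q in enumerate(rows[0]) if q != "-"]
    M = len(rows)
    weights = []
    for m in range(M):
        neighbours = 0
        for n in range(M):
            matches = sum(rows[m][c] == rows[n][c] for c in cols)
            if matches / len(cols) >= thr:
                neighbours += 1
        weights.append(1.0 / neighbours)
    return sum(weights)


def oracle_mi(rows: list[str], w: np.ndarray, i: int, j: int) -> float:
    """Direct joint-frequency MI (bits) over jointly non-gap rows."""
    joint: dict[tuple[str, str], float] = {}
    tot = 0.0
    for m, row in enumerate(rows):
        a, b = row[i], row[j]
        if a == "-" or b == "-":
            continue
        joint[(a, b)] = joint.get((a, b), 0.0) + w[m]
        tot += w[m]
    if tot == 0:
        return 0.0
    pa: dict[str, float] = {}
    pb: dict[str, float] = {}
    for (a, b), c in joint.items():
        pa[a] = pa.get(a, 0.0) + c / tot
        pb[b] = pb.get(b, 0.0) + c / tot
    mi = 0.0
    for (a, b), c in joint.items():
        p = c / tot
        mi += p * math.log2(p / (pa[a] * pb[b]))
    return mi


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestReadMSA:
    def test_fasta_identity_parse(self, tmp_path):
        path = tmp_path / "aln.fasta"
        path.write_text(">a\nMKLV\n>b\nMK-V\n>c\nMRLV\n")
        aln = read_msa(path)
        assert aln.depth == 3 and aln.length == 4
        assert aln.ids == ["a", "b", "c"]
        assert aln.rows[1] == "MK-V"

    def test_a3m_lowercase_insertions_removed(self, tmp_path):
        path = tmp_path / "aln.a3m"
        path.write_text(">q\nMKAR\n>h\nMK-lvR\n")
        aln = read_msa(path, format="a3m")
        assert aln.rows[1] == "MK-R"
        assert all(len(r) == 4 for r in aln.rows)

    def test_unequal_lengths_raise_with_offender(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nMKLV\n>offender\nMKL\n")
        with pytest.raises(MSAFormatError, match="offender"):
            read_msa(path)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(EmptyInputError):
            read_msa(path)

    def test_gapped_query_rejected(self):
        with pytest.raises(MSAFormatError):
            Alignment(ids=["a", "b"], rows=["MK-V", "MKLV"])


# ---------------------------------------------------------------------------
# sequence weights / Neff
# ---------------------------------------------------------------------------

class TestSequenceWeights:
    def test_identical_rows_total_redundancy(self):
        aln = Alignment(ids=list("abcde"), rows=["MKLV"] * 5)
        w = sequence_weights(aln, thr=0.8)
        assert np.allclose(w.weights, 0.2)
        assert w.neff == pytest.approx(1.0)

    def test_all_distinct_rows(self):
        rows = ["AAAA", "CCCC", "DDDD", "EEEE"]
        w = sequence_weights(Alignment(ids=list("abcd"), rows=rows), thr=0.8)
        assert np.allclose(w.weights, 1.0)
        assert w.neff == pytest.approx(4.0)

    def test_matches_bruteforce_on_toy(self, toy_alignment):
        w = sequence_weights(toy_alignment, thr=0.8)
        assert w.neff == pytest.approx(oracle_neff(toy_alignment.rows, 0.8), abs=1e-12)

    def test_neff_invariant_under_row_permutation(self, toy_alignment, rng):
        base = sequence_weights(toy_alignment, thr=0.8).neff
        for _ in range(5):
            perm = rng.permutation(toy_alignment.depth)
            while perm[0] != 0:           # keep the ungapped query first
                perm = rng.permutation(toy_alignment.depth)
            aln = Alignment(
                ids=[toy_alignment.ids[i] for i in perm],
                rows=[toy_alignment.rows[i] for i in perm],
            )
            assert sequence_weights(aln, thr=0.8).neff == pytest.approx(base)

    def test_neff_invariant_under_duplication(self, toy_alignment):
        base = sequence_weights(toy_alignment, thr=0.8).neff
        doubled = Alignment(
            ids=toy_alignment.ids + [f"{i}_dup" for i in toy_alignment.ids],
            rows=toy_alignment.rows * 2,
        )
        assert sequence_weights(doubled, thr=0.8).neff == pytest.approx(base)

    def test_invalid_threshold(self, toy_alignment):
        with pytest.raises(ValueError):
            sequence_weights(toy_alignment, thr=0.0)


# ---------------------------------------------------------------------------
# PSSM and entropy
# ---------------------------------------------------------------------------

class TestProfile:
    def test_single_sequence_one_hot(self):
        aln = Alignment(ids=["q"], rows=["ACD"])
        w = sequence_weights(aln)
        pssm = compute_pssm(aln, w, pseudocount=0.0)
        assert pssm[0, AA20.index("A")] == pytest.approx(1.0)
        assert pssm[1, AA20.index("C")] == pytest.approx(1.0)
        assert pssm.sum() == pytest.approx(3.0)

    def test_two_symbol_column_symmetry(self):
        aln = Alignment(ids=["q", "r"], rows=["A", "C"])
        w = sequence_weights(aln, thr=1.0)
        pssm = compute_pssm(aln, w, pseudocount=0.0)
        assert pssm[0, AA20.index("A")] == pytest.approx(0.5)
        assert pssm[0, AA20.index("C")] == pytest.approx(0.5)

    def test_weighted_column_matches_hand_count(self):
        rows = ["A", "A", "C", "D"]
        aln = Alignment(ids=list("abcd"), rows=rows)
        w = sequence_weights(aln, thr=1.0)     # weights: A rows 1/2 each, C, D 1
        pssm = compute_pssm(aln, w, pseudocount=0.0)
        total = w.weights.sum()
        assert pssm[0, AA20.index("A")] == pytest.approx(1.0 / total)
        assert pssm[0, AA20.index("C")] == pytest.approx(1.0 / total)

    @pytest.mark.parametrize("pseudocount", [0.0, 0.5, 1.0, 5.0])
    def test_rows_sum_to_one(self, toy_alignment, pseudocount):
        w = sequence_weights(toy_alignment)
        pssm = compute_pssm(toy_alignment, w, pseudocount=pseudocount)
        assert np.allclose(pssm.sum(axis=1), 1.0, atol=1e-9)

    def test_conserved_column_zero_entropy(self):
        aln = Alignment(ids=list("abc"), rows=["AK", "AR", "AD"])
        h = column_entropy(aln, sequence_weights(aln))
        assert h[0] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_20aa_column_max_entropy(self):
        aln = Alignment(ids=[f"s{i}" for i in range(20)], rows=list(AA20))
        h = column_entropy(aln, sequence_weights(aln, thr=1.0))
        assert h[0] == pytest.approx(math.log2(20), abs=1e-9)

    def test_entropy_matches_direct_formula(self):
        rows = ["A", "A", "C", "D", "D", "D"]
        aln = Alignment(ids=[f"s{i}" for i in range(6)], rows=rows)
        w = sequence_weights(aln, thr=1.0)
        probs = np.array(
            [sum(w.weights[m] for m, r in enumerate(rows) if r == a) for a in "ACD"]
        )
        probs /= probs.sum()
        expected = -np.sum(probs * np.log2(probs))
        assert column_entropy(aln, w)[0] == pytest.approx(expected, abs=1e-12)

    def test_entropy_bounds(self, toy_alignment):
        h = column_entropy(toy_alignment, sequence_weights(toy_alignment))
        assert (h >= 0).all() and (h <= math.log2(21) + 1e-12).all()

    def test_all_x_column_spreads_uniformly(self):
        aln = Alignment(ids=["a", "b"], rows=["XA", "XA"])
        w = sequence_weights(aln)
        pssm = compute_pssm(aln, w, pseudocount=0.0)
        assert np.allclose(pssm[0, :20], 1.0 / 20)


# ---------------------------------------------------------------------------
# mutual information / APC
# ---------------------------------------------------------------------------

class TestCouplings:
    def test_independent_columns_near_zero_mi(self, rng):
        M = 2000
        rows = [
            "".join(AA20[c] for c in rng.integers(0, 20, size=2)) for _ in range(M)
        ]
        aln = Alignment(ids=[f"s{i}" for i in range(M)], rows=rows)
        w = sequence_weights(aln, thr=1.0)
        mi = mutual_information(aln, w)
        # finite-sample bias of MI is O(states^2 / M)
        assert mi[0, 1] < 0.2

    def test_perfect_covariation_one_bit(self):
        # two jointly two-state columns: rows are either AC or DF, equally frequent
        rows = ["AC", "DF"] * 4
        aln = Alignment(ids=[f"s{i}" for i in range(8)], rows=rows)
        from coevodist.msa import SequenceWeights

        sw = SequenceWeights(
            weights=np.full(8, 1 / 8), neff=1.0, identity_threshold=0.8
        )
        mi = mutual_information(aln, sw)
        assert mi[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_matches_joint_count_oracle_on_toy(self, toy_alignment):
        w = sequence_weights(toy_alignment)
        mi = mutual_information(toy_alignment, w)
        L = toy_alignment.length
        for i in range(L):
            for j in range(i + 1, L):
                expected = oracle_mi(toy_alignment.rows, w.weights, i, j)
                assert mi[i, j] == pytest.approx(expected, abs=1e-9), (i, j)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.data())
    def test_mi_matches_oracle_exhaustively(self, data):
        M = data.draw(st.integers(2, 10))
        L = data.draw(st.integers(2, 8))
        alphabet = "ACDE-"
        rows = [
            "".join(data.draw(st.sampled_from(alphabet)) for _ in range(L))
            for _ in range(M)
        ]
        rows[0] = rows[0].replace("-", "A")
        aln = Alignment(ids=[f"s{i}" for i in range(M)], rows=rows)
        w = sequence_weights(aln, thr=0.8)
        mi = mutual_information(aln, w)
        for i in range(L):
            for j in range(i + 1, L):
                expected = oracle_mi(rows, w.weights, i, j)
                assert mi[i, j] == pytest.approx(expected, abs=1e-9)

    def test_apc_symmetric_zero_diagonal(self, toy_alignment):
        cm = covariant_contact_potential(toy_alignment)
        assert cm.source == "internal_mi"
        assert np.allclose(cm.values, cm.values.T, atol=1e-6)
        assert np.allclose(np.diag(cm.values), 0.0)

    def test_apc_formula(self):
        mi = np.array([[0.0, 0.4, 0.1], [0.4, 0.0, 0.2], [0.1, 0.2, 0.0]])
        out = apc_correct(mi)
        row = mi.sum(axis=1) / 2
        overall = mi.sum() / 6
        expected01 = mi[0, 1] - row[0] * row[1] / overall
        assert out[0, 1] == pytest.approx(expected01)

    def test_single_column_pair_with_no_joint_rows(self):
        # columns 0 and 1 never jointly non-gap
        rows = ["AC", "A-", "-C", "A-"]
        aln = Alignment(ids=list("abcd"), rows=rows)
        mi = mutual_information(aln, sequence_weights(aln))
        # rows 'A-'/' -C' exclude each other; only row0 is jointly non-gap -> MI 0
        assert mi[0, 1] == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# coupling file ingestion
# ---------------------------------------------------------------------------

class TestCouplingFiles:
    def test_square_matrix_parse(self, tmp_path):
        path = tmp_path / "m.ccmpred"
        path.write_text("0 0.5 0.1\n0.5 0 0.2\n0.1 0.2 0\n")
        cm = read_coupling_matrix(path, L=3, source="ccmpred")
        assert cm.values.shape == (3, 3)
        assert cm.values[0, 1] == pytest.approx(0.5)

    def test_triplet_mirroring(self, tmp_path):
        path = tmp_path / "fc.out"
        path.write_text("1 3 0.7\n")
        cm = read_coupling_matrix(path, L=3, source="freecontact")
        assert cm.values[0, 2] == pytest.approx(0.7)
        assert cm.values[2, 0] == pytest.approx(0.7)
        assert cm.values.sum() == pytest.approx(1.4)

    def test_dimension_mismatch_raises(self, tmp_path):
        path = tmp_path / "bad.mat"
        path.write_text("0 1 2\n3 4 5\n6 7 8\n9 10 11\n")
        with pytest.raises(DimensionError):
            read_coupling_matrix(path, L=3, source="ccmpred")


# ---------------------------------------------------------------------------
# feature assembly
# ---------------------------------------------------------------------------

class TestAssemble:
    def _profile(self, L: int, rng) -> ProfileFeatures:
        pssm = rng.dirichlet(np.ones(21), size=L)
        return ProfileFeatures(pssm=pssm, entropy=rng.uniform(0, 4, size=L))

    def test_channel_count_formula(self, rng):
        from coevodist.msa import CouplingMatrix

        prof = self._profile(5, rng)
        couplings = [
            CouplingMatrix(np.zeros((5, 5)), "internal_mi"),
            CouplingMatrix(np.zeros((5, 5)), "ccmpred"),
        ]
        pft = assemble_pair_features(prof, couplings)
        assert pft.tensor.shape == (2 * 22 + 2, 5, 5)
        assert len(pft.channel_names) == 46
        assert np.isfinite(pft.tensor).all()

    def test_tiling_symmetry(self, rng):
        prof = self._profile(6, rng)
        pft = assemble_pair_features(prof, [])
        t = pft.tensor
        assert np.allclose(t[0:22, 2, 4], t[22:44, 4, 2])

    def test_zero_couplings_pass_through(self, rng):
        from coevodist.msa import CouplingMatrix

        prof = self._profile(4, rng)
        pft = assemble_pair_features(prof, [CouplingMatrix(np.zeros((4, 4)), "ccmpred")])
        assert np.allclose(pft.tensor[-1], 0.0)

    def test_size_mismatch_raises(self, rng):
        from coevodist.msa import CouplingMatrix

        prof = self._profile(4, rng)
        with pytest.raises(DimensionError):
            assemble_pair_features(prof, [CouplingMatrix(np.zeros((5, 5)), "ccmpred")])

    def test_npz_roundtrip(self, rng, tmp_path):
        prof = self._profile(4, rng)
        pft = assemble_pair_features(prof, [])
        save_pair_features(tmp_path / "feat", pft)
        back = load_pair_features(tmp_path / "feat")
        assert np.allclose(back.tensor, pft.tensor)
        assert back.channel_names == pft.channel_names
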