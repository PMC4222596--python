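"""Alignment I/O, identity, Meff clustering, gap filtering, PSSM."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contactstack.msa import (
    ALPHABET,
    BACKGROUND_FREQS,
    Msa,
    compute_pssm,
    effective_sequences,
    filter_gappy_rows,
    pairwise_identity,
    read_msa,
)

AA = st.sampled_from("ACDEFGHIKLMNPQRSTVWY-")


def rows_strategy(nrow, ncol):
    return st.lists(
        st.text(alphabet="ACDEFG-", min_size=ncol, max_size=ncol),
        min_size=nrow,
        max_size=nrow,
    )


def brute_force_meff(rows, threshold):
    """Independent single-linkage clustering oracle (union-find)."""
    n = len(rows)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if pairwise_identity(rows[i], rows[j]) > threshold:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


class TestReadMsa:
    def test_gapless_fasta(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">s1\nACDEF\n>s2\nACDFF\n")
        msa = read_msa(p)
        assert msa.ncol == 5 and msa.nrow == 2
        assert msa.ids == ["s1", "s2"]

    def test_a3m_insertions_stripped(self, tmp_path):
        p = tmp_path / "a.a3m"
        p.write_text(">query\nACDEF\n>hit\nAcggCDE-\n")
        msa = read_msa(p)
        assert msa.rows[1] == "ACDE-"
        assert all(len(r) == 5 for r in msa.rows)

    def test_five_row_fixture_row_by_row(self, tmp_path):
        rows = ["ACDEF", "ACDE-", "AC--F", "GCDEF", "ACDEF"]
        p = tmp_path / "five.fasta"
        p.write_text("".join(f">s{i}\n{r}\n" for i, r in enumerate(rows)))
        msa = read_msa(p)
        assert msa.rows == rows

    def test_ragged_fasta_raises(self, tmp_path):
        p = tmp_path / "ragged.fasta"
        p.write_text(">s1\nACDEF\n>s2\nAC\n")
        with pytest.raises(ValueError, match="ragged"):
            read_msa(p)

    def test_empty_file_raises(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(ValueError):
            read_msa(p)


class TestPairwiseIdentity:
    def test_identical_rows(self):
        assert pairwise_identity("ACDEF", "ACDEF") == 1.0

    def test_fully_different_rows(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_hand_counted_gap_policy(self):
        # A/A match, C/C match, D/E mismatch, -/G one-sided gap counts as
        # mismatch, F/F match -> 3 of 5
        assert pairwise_identity("ACD-F", "ACEGF") == pytest.approx(3 / 5)

    def test_both_gapped_columns_skipped(self):
        # only columns 0 and 2 are compared
        assert pairwise_identity("A-C", "A-C") == 1.0

    def test_all_gap_pair_raises(self):
        with pytest.raises(ValueError, match="comparable"):
            pairwise_identity("--", "--")

    @settings(max_examples=50, deadline=None)
    @given(rows_strategy(2, 8))
    def test_symmetric_and_bounded(self, rows):
        a, b = rows
        try:
            x = pairwise_identity(a, b)
        except ValueError:
            return
        assert 0.0 <= x <= 1.0
        assert x == pairwise_identity(b, a)


class TestEffectiveSequences:
    def test_identical_rows_collapse_to_one(self):
        msa = Msa(ids=list("abcd"), rows=["ACDEF"] * 4)
        assert effective_sequences(msa) == 1.0

    def test_mutually_dissimilar_rows_all_count(self):
        rows = ["AAAAA", "CCCCC", "DDDDD"]
        msa = Msa(ids=list("abc"), rows=rows)
        assert effective_sequences(msa) == 3.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_single_linkage_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = [
            "".join(rng.choice(list("ACD-"), size=12)) for _ in range(10)
        ]
        msa = Msa(ids=[str(i) for i in range(10)], rows=rows)
        got = effective_sequences(msa, identity_threshold=0.5)
        assert got == brute_force_meff(rows, 0.5)

    def test_bounds_and_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        rows = ["".join(rng.choice(list("ACDE"), size=15)) for _ in range(12)]
        msa = Msa(ids=[str(i) for i in range(12)], rows=rows)
        meffs = [
            effective_sequences(msa, identity_threshold=t)
            for t in (0.9, 0.7, 0.5, 0.3)
        ]
        assert all(1.0 <= m <= 12.0 for m in meffs)
        # lower threshold links more rows -> fewer clusters
        assert all(a >= b for a, b in zip(meffs, meffs[1:]))

    def test_invalid_threshold_raises(self):
        msa = Msa(ids=["a"], rows=["ACD"])
        with pytest.raises(ValueError, match="threshold"):
            effective_sequences(msa, identity_threshold=1.5)

    def test_weights_mode_bounded_by_cluster_count(self):
        rows = ["AAAAA", "AAAAC", "DDDDD"]
        msa = Msa(ids=list("abc"), rows=rows)
        w = effective_sequences(msa, identity_threshold=0.7, mode="weights")
        assert w == pytest.approx(2.0)  # 1/2 + 1/2 + 1


class TestFilterGappyRows:
    def test_gapless_unchanged(self):
        msa = Msa(ids=["a", "b"], rows=["ACDEF", "ACDFF"])
        assert filter_gappy_rows(msa).rows == msa.rows

    def test_row_above_default_threshold_removed(self):
        gappy = "-" * 21 + "A" * 79  # 21% gaps
        msa = Msa(ids=["q", "g"], rows=["A" * 100, gappy])
        out = filter_gappy_rows(msa)
        assert out.rows == ["A" * 100]

    def test_query_always_kept(self):
        msa = Msa(ids=["q", "k"], rows=["-" * 10, "A" * 10])
        out = filter_gappy_rows(msa)
        assert out.rows[0] == "-" * 10

    def test_mixed_fixture_hand_count(self):
        rows = {
            "q": "AAAAAAAAAA",   # 0% kept
            "r1": "AA--AAAAAA",  # 20% kept (boundary, not above)
            "r2": "AAA---AAAA",  # 30% removed
            "r3": "A-AAAAAAAA",  # 10% kept
        }
        msa = Msa(ids=list(rows), rows=list(rows.values()))
        out = filter_gappy_rows(msa)
        assert out.ids == ["q", "r1", "r3"]


class TestComputePssm:
    def test_background_frequencies_give_zero(self):
        # a column containing each symbol exactly in background proportion is
        # impractical; instead pass the observed distribution as background
        msa = Msa(ids=["a", "b"], rows=["AC", "CA"])
        bg = np.full(21, 1e-9)
        bg[0] = bg[1] = 0.5  # A and C at observed frequency
        bg = bg / bg.sum()
        pssm = compute_pssm(msa, background=bg, pseudocount=1.0)
        assert np.allclose(pssm.values[:, :2], 0.0, atol=1e-6)

    def test_single_sequence_uniform_background_hand_computed(self):
        msa = Msa(ids=["q"], rows=["AAA"])
        bg = np.full(21, 1 / 21)
        pssm = compute_pssm(msa, background=bg, pseudocount=1.0)
        # f(A) = 1: value = log(((1 + 1/21)/2) / (1/21)) = log(11)
        expected_a = math.log(((1 + 1 / 21) / 2) * 21)
        assert pssm.values[0, 0] == pytest.approx(expected_a)
        # f(C) = 0: value = log(((0 + 1/21)/2) * 21) = log(1/2)
        assert pssm.values[0, 1] == pytest.approx(math.log(0.5))

    def test_invariant_under_row_duplication(self):
        msa = Msa(ids=["a", "b"], rows=["ACD", "ACC"])
        doubled = Msa(ids=["a", "b", "c", "d"], rows=["ACD", "ACC"] * 2)
        assert np.allclose(
            compute_pssm(msa).values, compute_pssm(doubled).values
        )

    def test_invariant_under_row_permutation(self):
        msa = Msa(ids=["a", "b", "c"], rows=["ACD", "ACC", "GGG"])
        perm = Msa(ids=["c", "a", "b"], rows=["GGG", "ACD", "ACC"])
        assert np.allclose(compute_pssm(msa).values, compute_pssm(perm).values)

    def test_row_count_matches_query_length(self):
        msa = Msa(ids=["a"], rows=["ACDEF"])
        assert compute_pssm(msa).values.shape == (5, len(ALPHABET))

    def test_invalid_background_rejected(self):
        msa = Msa(ids=["a"], rows=["AC"])
        with pytest.raises(ValueError):
            compute_pssm(msa, background=np.full(21, 0.5))

    def test_tsv_export_round_trips(self, tmp_path):
        msa = Msa(ids=["a", "b"], rows=["ACD", "ACC"])
        pssm = compute_pssm(msa)
        p = tmp_path / "pssm.tsv"
        pssm.to_tsv(p)
        back = np.loadtxt(p, skiprows=1, usecols=range(1, 22))
        assert np.allclose(back, pssm.values, atol=1e-6)
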