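"""K-mer counting, filtering, association, assembly and placement."""

import itertools

import numpy as np
import pytest

from dupsweep import kmers as K
from dupsweep import simulate


class TestEncoding:
    def test_round_trip_exhaustive_small_k(self):
        for k in (1, 3):
            for kmer in map("".join, itertools.product("ACGT", repeat=k)):
                assert K.decode_kmer(K.encode_kmer(kmer), k) == kmer

    def test_round_trip_random_k31(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(50):
            kmer = "".join(rng.choice(bases, 31))
            assert K.decode_kmer(K.encode_kmer(kmer), 31) == kmer

    def test_canonical_is_strand_independent(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(20):
            kmer = "".join(rng.choice(bases, 7))
            assert K.canonical_code(kmer) == K.canonical_code(K.revcomp(kmer))

    @pytest.mark.parametrize("k", [2, 4, 32, 0])
    def test_invalid_k_rejected(self, k):
        with pytest.raises(K.KmerConfigError):
            K.count_sequence_kmers("ACGTACGT", k)


class TestCounting:
    def test_homopolymer(self):
        assert K.count_sequence_kmers("AAAAA", 3) == {K.encode_kmer("AAA"): 3}

    def test_reverse_complement_equality(self):
        seq = "ACGTTGCAATG"
        assert K.count_sequence_kmers(seq, 5) == K.count_sequence_kmers(
            K.revcomp(seq), 5
        )

    def test_total_instances_sliding_window_oracle(self, rng):
        bases = np.array(list("ACGTN"))
        seq = "".join(rng.choice(bases, 1000, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        k = 9
        counts = K.count_sequence_kmers(seq, k)
        expected = sum(
            1 for i in range(len(seq) - k + 1) if "N" not in seq[i:i + k]
        )
        assert sum(counts.values()) == expected

    def test_order_independence(self, tmp_path, rng):
        bases = np.array(list("ACGT"))
        reads = ["".join(rng.choice(bases, 40)) for _ in range(20)]
        for name, order in (("fwd", reads), ("rev", reads[::-1])):
            path = tmp_path / f"{name}.fasta"
            path.write_text(
                "".join(f">r{i}\n{s}\n" for i, s in enumerate(order))
            )
        t1 = K.count_kmers({"s": tmp_path / "fwd.fasta"}, k=15)
        t2 = K.count_kmers({"s": tmp_path / "rev.fasta"}, k=15)
        np.testing.assert_array_equal(t1.codes, t2.codes)
        np.testing.assert_array_equal(t1.counts, t2.counts)

    def test_empty_file_zero_counts(self, tmp_path):
        (tmp_path / "empty.fasta").write_text("")
        (tmp_path / "full.fasta").write_text(">r\nACGTACGTACGT\n")
        t = K.count_kmers(
            [("e", tmp_path / "empty.fasta"), ("f", tmp_path / "full.fasta")],
            k=5,
        )
        assert t.counts[:, 0].sum() == 0
        assert t.counts[:, 1].sum() > 0


class TestFilter:
    def _table(self, presence):
        """presence: kmers × samples boolean."""
        presence = np.asarray(presence, dtype=int)
        return K.KmerTable(
            k=3,
            codes=np.arange(presence.shape[0], dtype=np.int64),
            counts=presence,
            sample_ids=[f"s{i}" for i in range(presence.shape[1])],
        )

    def test_rule_boundaries(self):
        n = 10
        rows = [
            [1] * 2 + [0] * 8,   # present in 2 -> dropped
            [1] * 10,            # absent in 0 -> dropped
            [1] * 3 + [0] * 7,   # present 3, absent 7 -> retained
            [1] * 7 + [0] * 3,   # absent exactly 3 -> retained
            [1] * 8 + [0] * 2,   # absent in 2 -> dropped
        ]
        t = K.filter_variant_kmers(self._table(rows), 3, 3)
        assert t.retained.tolist() == [False, False, True, True, False]

    def test_too_few_samples(self):
        with pytest.raises(K.KmerConfigError):
            K.filter_variant_kmers(self._table([[1, 0, 1]]), 3, 3)

    def test_retained_frequencies_sum_to_one(self, rng):
        counts = rng.integers(0, 5, size=(30, 8))
        t = K.KmerTable(
            k=3, codes=np.arange(30, dtype=np.int64), counts=counts,
            sample_ids=[f"s{i}" for i in range(8)],
        )
        K.filter_variant_kmers(t, 3, 3)
        freqs = t.normalised_frequencies()
        sums = freqs[t.retained].sum(axis=0)
        ok = ~np.isnan(sums)
        np.testing.assert_allclose(sums[ok], 1.0)


class TestAssociate:
    def _toy_table(self, counts):
        counts = np.asarray(counts)
        t = K.KmerTable(
            k=3, codes=np.arange(counts.shape[0], dtype=np.int64),
            counts=counts,
            sample_ids=[f"s{i}" for i in range(counts.shape[1])],
        )
        t.retained = np.ones(counts.shape[0], bool)
        return t

    def test_permuted_null_no_significance(self, rng):
        """Phenotype-permuted null over 10^4 k-mers: nothing passes
        FDR < 0.001."""
        n_samples = 40
        counts = rng.integers(0, 20, size=(10_000, n_samples))
        t = K.KmerTable(
            k=3, codes=np.arange(10_000, dtype=np.int64), counts=counts,
            sample_ids=[f"s{i}" for i in range(n_samples)],
        )
        K.filter_variant_kmers(t, 3, 3)
        phen = rng.permutation(np.r_[np.ones(20), np.zeros(20)])
        df = K.associate(t, phen, fdr_threshold=0.001)
        assert int(df["significant"].sum()) == 0

    def test_exact_permutation_small_n(self):
        t = self._toy_table([[5, 5, 5, 0, 0, 0], [0, 0, 0, 5, 5, 5]])
        phen = np.array([1, 1, 1, 0, 0, 0])
        df = K.associate(t, phen, fdr_threshold=1.1)
        assert df.loc[0, "rho"] == pytest.approx(1.0)
        # exact permutation: 36 of 720 orderings tie the observed |rho|
        assert df.loc[0, "p"] == pytest.approx(0.1, rel=1e-9)

    def test_constant_frequency_excluded_with_tally(self):
        # per-sample totals are 4 everywhere, so row 0 has constant
        # normalised frequency 0.25 while rows 1-2 vary
        t = self._toy_table(
            [[1, 1, 1, 1, 1, 1], [3, 1, 2, 0, 3, 1], [0, 2, 1, 3, 0, 2]]
        )
        df = K.associate(t, np.array([1, 1, 1, 0, 0, 0]), denominator="all")
        assert len(df) == 2
        assert df.attrs["n_constant"] == 1


class TestAssembly:
    def test_overlap_30_merges_to_32bp(self):
        s = "ACGTACGTAAGTACCGTACGTAACGTACGTAG"  # 32 bp
        a, b = s[:31], s[1:]
        contigs = K.assemble_significant([a, b])
        assert len(contigs) == 1
        assert contigs[0].contig in (s, K.revcomp(s))

    def test_overlap_9_not_merged(self):
        rng = np.random.default_rng(5)
        bases = np.array(list("ACGT"))
        left = "".join(rng.choice(bases, 31))
        right = left[-9:] + "".join(rng.choice(bases, 22))
        contigs = K.assemble_significant([left, right], min_overlap=10)
        assert len(contigs) == 2

    def test_shred_and_reassemble_round_trip(self, rng):
        bases = np.array(list("ACGT"))
        original = "".join(rng.choice(bases, 60))
        shreds = [original[i:i + 31] for i in range(30)]
        contigs = K.assemble_significant(shreds)
        assert len(contigs) == 1
        assert contigs[0].contig in (original, K.revcomp(original))

    def test_member_conservation(self, rng):
        bases = np.array(list("ACGT"))
        seqs = ["".join(rng.choice(bases, 31)) for _ in range(6)]
        contigs = K.assemble_significant(seqs)
        assert sum(len(c.members) for c in contigs) == len(seqs)

    def test_mean_frequency_over_members(self):
        s = "ACGTACGTAAGTACCGTACGTAACGTACGTAG"
        freqs = np.array([[0.1, 0.3], [0.2, 0.5]])
        contigs = K.assemble_significant([s[:31], s[1:]], frequencies=freqs)
        np.testing.assert_allclose(contigs[0].mean_frequency, [0.15, 0.4])


class TestPlacement:
    def test_forward_reverse_and_unplaced(self, rng):
        bases = np.array(list("ACGT"))
        ref = "".join(rng.choice(bases, 10_000))
        fwd = K.AssembledKmer(contig=ref[100:140])
        rev = K.AssembledKmer(contig=K.revcomp(ref[100:140]))
        random40 = K.AssembledKmer(contig="".join(rng.choice(bases, 40)))
        K.place_contigs([fwd, rev, random40], [("chr", ref)])
        assert ("chr", 101, "+") in fwd.placements
        assert ("chr", 101, "-") in rev.placements
        assert random40.placements == []


class TestResidualCorrelation:
    def test_proportional_within_groups_r_one(self):
        copy = np.array([2, 3, 4, 5, 2, 3, 4, 5], float)
        phen = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        freq = 0.01 * copy
        r, p = K.copy_number_residual_correlation(freq, copy, phen)
        assert r == pytest.approx(1.0)

    def test_independent_matches_permutation_null(self, rng):
        phen = np.r_[np.ones(20), np.zeros(20)]
        copy = rng.integers(2, 6, 40).astype(float)
        observed = []
        for _ in range(200):
            freq = rng.normal(size=40)
            r, _ = K.copy_number_residual_correlation(freq, copy, phen)
            observed.append(abs(r))
        # |r| of unrelated vectors behaves like the permutation null
        perm = []
        freq = rng.normal(size=40)
        for _ in range(200):
            r, _ = K.copy_number_residual_correlation(
                rng.permutation(freq), copy, phen
            )
            perm.append(abs(r))
        q_obs = np.quantile(observed, 0.95)
        q_perm = np.quantile(perm, 0.95)
        assert abs(q_obs - q_perm) < 0.15

    def test_degenerate_group_rejected(self):
        with pytest.raises(K.KmerConfigError):
            K.copy_number_residual_correlation(
                np.ones(4), np.ones(4), np.array([1, 0, 0, 0])
            )


def test_junction_kmers_end_to_end(tmp_path):
    """Junction-spanning k-mers exist only in duplication carriers and
    come out of the association significant at FDR < 0.001, and the
    assembled contigs carrying them place inside the duplicated tract."""
    seqs, ref, (lo, hi) = simulate.junction_cohort_sequences(
        17, n_carriers=12, n_noncarriers=12, locus_length=1500
    )
    paths = simulate.emit_reads(
        seqs, tmp_path, read_length=80, depth=8, seed=17, circular=True
    )
    table = K.count_kmers(paths, k=21)
    K.filter_variant_kmers(table, 3, 3)
    phen = np.array([1] * 12 + [0] * 12)
    df = K.associate(table, phen, fdr_threshold=0.001)
    sig = df[df["significant"]]
    # the junction k-mers (present only in carriers) must be significant
    junction = ref[hi - 20:hi] + ref[lo:lo + 20]
    junction_codes = {
        K.canonical_code(junction[i:i + 21]) for i in range(len(junction) - 20)
    }
    found = set(sig["code"]) & junction_codes
    assert len(found) > 0
    # assembled significant k-mers place inside the duplicated tract
    freqs = table.normalised_frequencies()
    contigs = K.assemble_significant(
        sig["sequence"].tolist(),
        frequencies=freqs[sig["kmer_index"].to_numpy()],
    )
    K.place_contigs(contigs, [("locus", ref)])
    placed = [c for c in contigs if c.placements]
    assert placed, "no contig placed on the reference"
    inside = [
        c for c in placed
        if any(lo <= start - 1 <= hi for _, start, _ in c.placements)
    ]
    assert len(inside) / len(placed) >= 0.95
    # junction-spanning contigs exist only in the duplicated allele, so
    # exact matching leaves them unplaced (the analogue of unaligned
    # k-mers in a read-mapping pipeline)
    assert any(not c.placements for c in contigs)
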