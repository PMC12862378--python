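"""Read filters, BCError pileup, pooling, and read-length tables."""

import numpy as np
import pysam
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from epistress.profiling import (
    PileupProfile,
    ReadFilterParams,
    compute_bcerror,
    filter_reads,
    pool_profiles,
    read_length_table,
    read_profiles,
    write_profiles,
)

from conftest import make_header, make_read, naive_bcerror, random_toy_alignment, write_bam

SEQS = {"tx1": "ACGTACGTACGTACGTACGT", "tx2": "GGGGCCCCAAAATTTTGGCC"}


@pytest.fixture
def header():
    return make_header(SEQS)


class TestFilterReads:
    def test_mean_q_exactly_at_threshold_dropped(self, header, tmp_path):
        """Q score > 9 is strict: a read at exactly 9.0 fails the mRNAe filter."""
        reads = [make_read(header, "at9", "tx1", 0, "20M", SEQS["tx1"], qual=9),
                 make_read(header, "above", "tx1", 0, "20M", SEQS["tx1"], qual=10)]
        bam = write_bam(tmp_path / "q.bam", header, reads)
        kept, report = filter_reads(bam, ReadFilterParams(sample_class="mRNAe"))
        assert [r.query_name for r in kept] == ["above"]
        assert report.dropped == {"low_quality": 1}

    def test_trna_class_default_threshold(self, header, tmp_path):
        reads = [make_read(header, "q6", "tx1", 0, "20M", SEQS["tx1"], qual=6)]
        bam = write_bam(tmp_path / "t.bam", header, reads)
        kept, _ = filter_reads(bam, ReadFilterParams(sample_class="tRNAseq"))
        assert len(kept) == 1  # 6 > 5 passes for tRNA libraries, not mRNAe
        kept, _ = filter_reads(bam, ReadFilterParams(sample_class="mRNAe"))
        assert len(kept) == 0

    def test_secondary_and_unmapped_dropped(self, header, tmp_path):
        reads = [
            make_read(header, "sec", "tx1", 0, "20M", SEQS["tx1"], qual=20, flag=256),
            make_read(header, "sup", "tx1", 0, "20M", SEQS["tx1"], qual=20, flag=2048),
            make_read(header, "ok", "tx1", 0, "20M", SEQS["tx1"], qual=20),
        ]
        unmapped = pysam.AlignedSegment(header)
        unmapped.query_name = "un"
        unmapped.flag = 4
        unmapped.query_sequence = "ACGT"
        unmapped.query_qualities = pysam.qualitystring_to_array("IIII")
        bam = write_bam(tmp_path / "f.bam", header, reads + [unmapped])
        kept, report = filter_reads(bam)
        assert [r.query_name for r in kept] == ["ok"]
        assert report.dropped == {"secondary": 1, "supplementary": 1, "unmapped": 1}

    def test_all_good_reads_kept(self, header, tmp_path):
        reads = [make_read(header, f"r{i}", "tx1", 0, "20M", SEQS["tx1"], qual=12)
                 for i in range(10)]
        bam = write_bam(tmp_path / "g.bam", header, reads)
        kept, report = filter_reads(bam)
        assert report.kept == 10 and len(kept) == 10

    def test_missing_quality_dropped_with_reason(self, header, tmp_path):
        reads = [make_read(header, "nq", "tx1", 0, "20M", SEQS["tx1"], qual=None)]
        bam = write_bam(tmp_path / "nq.bam", header, reads)
        kept, report = filter_reads(bam)
        assert not kept and report.dropped == {"no_quality": 1}

    def test_unknown_sample_class_rejected(self):
        with pytest.raises(ValueError, match="sample_class"):
            ReadFilterParams(sample_class="exotic").resolved_min_q()


class TestComputeBCError:
    def test_hand_counted_pileup(self, header):
        """6 matches, 3 mismatches, 1 spanning deletion at p -> BCError 0.4."""
        p = 5  # 0-based target position
        ref = SEQS["tx1"]
        reads = []
        for i in range(6):
            reads.append(make_read(header, f"m{i}", "tx1", 0, "20M", ref, qual=20))
        for i in range(3):
            mut = ref[:p] + ("A" if ref[p] != "A" else "C") + ref[p + 1:]
            reads.append(make_read(header, f"x{i}", "tx1", 0, "20M", mut, qual=20))
        reads.append(make_read(header, "d", "tx1", 0, f"{p}M1D{19 - p}M",
                               ref[:p] + ref[p + 1:], qual=20))
        profs = compute_bcerror(reads, SEQS, header=header)
        assert profs["tx1"].coverage[p] == 10
        assert profs["tx1"].error_count[p] == 4
        assert profs["tx1"].bcerror[p] == pytest.approx(0.4)

    def test_all_matching_reads_zero_error(self, header):
        reads = [make_read(header, f"r{i}", "tx1", 0, "20M", SEQS["tx1"], qual=20)
                 for i in range(8)]
        profs = compute_bcerror(reads, SEQS, header=header)
        assert np.all(profs["tx1"].error_count == 0)
        assert np.all(profs["tx1"].bcerror == 0)

    def test_low_coverage_masked(self, header):
        reads = [make_read(header, f"r{i}", "tx1", 0, "20M", SEQS["tx1"], qual=20)
                 for i in range(4)]
        profs = compute_bcerror(reads, SEQS, header=header, min_depth=5)
        assert profs["tx1"].mask.all()
        profs = compute_bcerror(reads, SEQS, header=header, min_depth=4)
        assert not profs["tx1"].mask.any()

    def test_insertion_charged_to_5prime_position(self, header):
        # 10M1I10M: insertion opens after 0-based position 9
        seq = SEQS["tx1"][:10] + "A" + SEQS["tx1"][10:]
        reads = [make_read(header, "ins", "tx1", 0, "10M1I10M", seq, qual=20)]
        profs = compute_bcerror(reads, SEQS, header=header, min_depth=1)
        assert profs["tx1"].error_count[9] == 1
        assert profs["tx1"].error_count.sum() == 1
        assert profs["tx1"].coverage.sum() == 20  # insertion adds no coverage

    def test_at_most_one_error_per_read_position(self, header):
        # mismatch at position 9 AND insertion after it: still one error
        seq = SEQS["tx1"][:9] + "A" + "C" + SEQS["tx1"][10:]
        assert SEQS["tx1"][9] != "A"
        reads = [make_read(header, "both", "tx1", 0, "10M1I10M", seq, qual=20)]
        profs = compute_bcerror(reads, SEQS, header=header, min_depth=1)
        assert profs["tx1"].error_count[9] == 1

    def test_soft_clips_ignored(self, header):
        seq = "TTTT" + SEQS["tx1"][:10]
        reads = [make_read(header, "sc", "tx1", 0, "4S10M", seq, qual=20)]
        profs = compute_bcerror(reads, SEQS, header=header, min_depth=1)
        assert profs["tx1"].coverage[:10].sum() == 10
        assert profs["tx1"].error_count.sum() == 0

    def test_reverse_strand_dropped(self, header):
        fwd = make_read(header, "f", "tx1", 0, "20M", SEQS["tx1"], qual=20)
        rev = make_read(header, "r", "tx1", 0, "20M", SEQS["tx1"], qual=20, flag=16)
        profs = compute_bcerror([fwd, rev], SEQS, header=header, min_depth=1)
        assert profs["tx1"].coverage.max() == 1

    def test_unknown_transcript_raises(self, header):
        reads = [make_read(header, "r", "tx2", 0, "20M", SEQS["tx2"], qual=20)]
        with pytest.raises(KeyError, match="tx2"):
            compute_bcerror(reads, {"tx1": SEQS["tx1"]}, header=header)

    @pytest.mark.parametrize("case_seed", range(5))
    def test_oracle_equivalence_random_alignments(self, header, case_seed):
        """Vectorized pileup equals naive per-read enumeration exactly."""
        rng = np.random.default_rng(1000 + case_seed)
        reads = random_toy_alignment(rng, SEQS, header)
        profs = compute_bcerror(reads, SEQS, header=header)
        cov, err = naive_bcerror(reads, SEQS)
        for t in profs:
            assert profs[t].coverage.tolist() == cov[t]
            assert profs[t].error_count.tolist() == err[t]


class TestPooling:
    def test_hand_counted_pooling(self):
        a = PileupProfile("t", [10] * 4, [2, 0, 1, 0])
        b = PileupProfile("t", [10] * 4, [4, 1, 0, 0])
        pooled = pool_profiles([a, b])
        assert pooled.bcerror[0] == pytest.approx(6 / 20)
        assert pooled.coverage.tolist() == [20] * 4

    def test_identity_with_empty_profile(self):
        a = PileupProfile("t", [10, 10], [3, 1])
        zero = PileupProfile("t", [0, 0], [0, 0])
        pooled = pool_profiles([a, zero])
        assert np.array_equal(pooled.coverage, a.coverage)
        assert np.array_equal(pooled.error_count, a.error_count)

    def test_commutative(self):
        a = PileupProfile("t", [10, 5], [3, 1])
        b = PileupProfile("t", [2, 8], [0, 4])
        ab, ba = pool_profiles([a, b]), pool_profiles([b, a])
        assert np.array_equal(ab.coverage, ba.coverage)
        assert np.array_equal(ab.error_count, ba.error_count)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            pool_profiles([PileupProfile("t", [1], [0]),
                           PileupProfile("t", [1, 1], [0, 0])])

    @given(st.lists(st.tuples(st.integers(5, 50), st.integers(0, 50)),
                    min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_pooled_bcerror_bounded_by_inputs(self, counts):
        """Pooled BCError lies within [min, max] of input BCErrors."""
        profiles = [PileupProfile("t", [c], [min(e, c)]) for c, e in counts]
        pooled = pool_profiles(profiles)
        rates = [p.bcerror[0] for p in profiles]
        assert min(rates) - 1e-12 <= pooled.bcerror[0] <= max(rates) + 1e-12

    def test_masking_monotone_in_min_depth(self):
        cov = np.array([3, 5, 8, 12])
        for lo, hi in [(1, 5), (5, 9), (3, 20)]:
            m_lo = PileupProfile("t", cov, [0] * 4, min_depth=lo).mask
            m_hi = PileupProfile("t", cov, [0] * 4, min_depth=hi).mask
            assert np.all(m_hi >= m_lo)  # raising min_depth never unmasks


class TestReadLengthTable:
    def test_lengths_reported(self, header):
        lens = [15, 12, 20]
        reads = [make_read(header, f"r{i}", "tx1", 0, f"{n}M", SEQS["tx1"][:n],
                           qual=20) for i, n in enumerate(lens)]
        table = read_length_table(reads, condition="c", replicate=1)
        assert sorted(table["length"]) == sorted(lens)

    def test_empty_input(self):
        table = read_length_table([])
        assert table.empty

    def test_adapter_trimming(self, header):
        adapter = "GGCCGGCC"
        body = SEQS["tx1"][:12]
        reads = [make_read(header, "a", "tx1", 0, "20M", body + adapter, qual=20)]
        trimmed = read_length_table(reads, trim_adapters=True, adapter=adapter)
        untrimmed = read_length_table(reads)
        assert trimmed["length"].iloc[0] == len(body)
        assert untrimmed["length"].iloc[0] == len(body) + len(adapter)


class TestProfileIO:
    def test_roundtrip(self, tmp_path):
        profs = {"t1": PileupProfile("t1", [10, 20, 3], [1, 4, 0]),
                 "t2": PileupProfile("t2", [7, 7], [0, 2])}
        path = tmp_path / "profiles.tsv"
        write_profiles(profs, path)
        back = read_profiles(path)
        for t in profs:
            assert np.array_equal(back[t].coverage, profs[t].coverage)
            assert np.array_equal(back[t].error_count, profs[t].error_count)
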