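"""Shared fixtures: tiny in-memory alignments and a naive pileup oracle."""

from __future__ import annotations

import numpy as np
import pysam
import pytest

from epistress.synthetic import SyntheticConfig, generate_reference, sample_truth


def make_header(seqs: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": t, "LN": len(s)} for t, s in seqs.items()],
    })


def make_read(header, name, tname, start, cigar, seq, qual=None, flag=0,
              mapq=60) -> pysam.AlignedSegment:
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.query_sequence = seq
    a.flag = flag
    a.reference_id = list(header.references).index(tname)
    a.reference_start = start
    a.mapping_quality = mapq
    a.cigarstring = cigar
    if qual is not None:
        if isinstance(qual, int):
            qual = [qual] * len(seq)
        a.query_qualities = pysam.qualitystring_to_array(
            "".join(chr(q + 33) for q in qual))
    return a


def write_bam(path, header, reads) -> str:
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for r in reads:
            bam.write(r)
    return str(path)


def naive_bcerror(reads, seqs):
    """Brute-force per-read, per-position pileup enumeration (the oracle).

    Mirrors the documented attribution rules with explicit python loops:
    substitution at the position, deletion spanning it, insertion charged to
    the position immediately 5'; one binary error indicator per read.
    """
    cov = {t: [0] * len(s) for t, s in seqs.items()}
    err = {t: [0] * len(s) for t, s in seqs.items()}
    for r in reads:
        if r.is_unmapped or r.is_reverse:
            continue
        t = r.reference_name
        pos, q = r.reference_start, 0
        epos = set()
        for op, ln in r.cigartuples:
            if op in (0, 7, 8):
                for k in range(ln):
                    cov[t][pos + k] += 1
                    if r.query_sequence[q + k].upper() != seqs[t][pos + k].upper():
                        epos.add(pos + k)
                pos += ln
                q += ln
            elif op == 2:
                for k in range(ln):
                    cov[t][pos + k] += 1
                    epos.add(pos + k)
                pos += ln
            elif op == 1:
                if pos > r.reference_start:
                    epos.add(pos - 1)
                q += ln
            elif op == 4:
                q += ln
            elif op == 3:
                pos += ln
        for p in epos:
            err[t][p] += 1
    return cov, err


def random_toy_alignment(rng: np.random.Generator, seqs: dict[str, str],
                         header, max_reads: int = 50):
    """Random small read set with mixed M/I/D/S cigars over the reference."""
    reads = []
    n = int(rng.integers(1, max_reads + 1))
    names = list(seqs)
    for i in range(n):
        t = names[int(rng.integers(len(names)))]
        L = len(seqs[t])
        start = int(rng.integers(0, L - 10))
        end = int(rng.integers(start + 5, min(L, start + 60) + 1))
        # walk the reference segment emitting random events
        ops = []
        qparts = []
        pos = start
        lead_clip = int(rng.integers(0, 4))
        if lead_clip:
            ops.append((4, lead_clip))
            qparts.append("".join(rng.choice(list("ACGT"), lead_clip)))
        while pos < end:
            u = rng.random()
            if u < 0.70 or pos == start or pos == end - 1:  # match/mismatch
                base = seqs[t][pos]
                if rng.random() < 0.15:
                    base = rng.choice([b for b in "ACGT" if b != base])
                ops.append((0, 1))
                qparts.append(base)
                pos += 1
            elif u < 0.85:  # deletion
                ops.append((2, 1))
                pos += 1
            else:  # insertion after current base
                ops.append((0, 1))
                qparts.append(seqs[t][pos])
                ops.append((1, 1))
                qparts.append(str(rng.choice(list("ACGT"))))
                pos += 1
        merged = []
        for op, ln in ops:
            if merged and merged[-1][0] == op:
                merged[-1][1] += ln
            else:
                merged.append([op, ln])
        cigar = "".join(f"{ln}{'MIDNS'[op]}" for op, ln in merged)
        seq = "".join(qparts)
        reads.append(make_read(header, f"r{i}", t, start, cigar, seq, qual=20))
    return reads


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(seed=7, n_transcripts=8, coverage=40,
                           conditions={"no_stress": 2, "acid_stress": 2, "ivt": 1})


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_truth(small_config, small_reference):
    return sample_truth(small_reference, small_config)
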