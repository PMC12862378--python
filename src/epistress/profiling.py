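"""Per-position basecalling-error (BCError) profiles from aligned reads.

In direct RNA sequencing, nucleotide modifications perturb the ionic-current
signal and surface as systematic basecalling errors: substitutions, deletions,
and spurious insertions concentrated at and around the modified position.  The
BCError statistic is the per-reference-position proportion of aligned reads
that show any such discrepancy.  This module computes BCError profiles from
BAM/SAM alignments in transcript space, applies the read-level quality filters
used for nanopore RNA libraries, pools biological replicates by summing
counts, and tabulates read lengths for pre-tRNA maturation analyses.

Error attribution conventions
-----------------------------
* a substitution is charged to the substituted reference position;
* a deletion is charged to every reference position it spans;
* an insertion is charged to the reference position immediately 5' of the
  insertion point (insertions opening before the first aligned base are
  ignored);
* each read contributes at most one error per position (binary indicator),
  so BCError is bounded by 1 even when a read has, say, both a mismatch and
  an adjacent insertion;
* soft-clipped bases contribute neither coverage nor errors;
* coverage counts reads whose alignment spans the position with a match,
  mismatch, or deletion.

Coordinates are 0-based half-open internally and 1-based in every emitted
table, matching the rRNA community convention (e.g. "m4Cm1402").
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "ReadFilterParams",
    "FilterReport",
    "PileupProfile",
    "filter_reads",
    "compute_bcerror",
    "pool_profiles",
    "read_length_table",
    "write_profiles",
    "read_profiles",
]

#: default exclusive mean-quality thresholds per library class
DEFAULT_MIN_Q = {"mRNAe": 9.0, "tRNAseq": 5.0}

DEFAULT_MIN_DEPTH = 5


@dataclass(frozen=True)
class ReadFilterParams:
    """Read-level filters applied before profiling.

    ``min_mean_q`` is exclusive: a read is kept only if its mean Phred
    quality is strictly greater than the threshold.  Defaults follow the
    library class: 9 for mRNA-enriched (mRNAe) runs, 5 for tRNA-dedicated
    runs, reflecting the systematically lower qualities of tRNA reads.
    """

    sample_class: str = "mRNAe"
    min_mean_q: float | None = None
    keep_primary_only: bool = True

    def resolved_min_q(self) -> float:
        if self.min_mean_q is not None:
            return float(self.min_mean_q)
        try:
            return DEFAULT_MIN_Q[self.sample_class]
        except KeyError:
            raise ValueError(
                f"unknown sample_class {self.sample_class!r}; "
                f"expected one of {sorted(DEFAULT_MIN_Q)} or an explicit min_mean_q"
            ) from None


@dataclass
class FilterReport:
    kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def total(self) -> int:
        return self.kept + sum(self.dropped.values())


def mean_read_quality(read: pysam.AlignedSegment) -> float | None:
    """Arithmetic mean of the per-base Phred scores of a read, or None."""
    q = read.query_qualities
    if q is None or len(q) == 0:
        return None
    return float(np.mean(q))


def _passes(read: pysam.AlignedSegment, params: ReadFilterParams,
            min_q: float, report: FilterReport) -> bool:
    if read.is_unmapped:
        report.drop("unmapped")
        return False
    if params.keep_primary_only and read.is_secondary:
        report.drop("secondary")
        return False
    if params.keep_primary_only and read.is_supplementary:
        report.drop("supplementary")
        return False
    mq = mean_read_quality(read)
    if mq is None:
        report.drop("no_quality")
        logger.warning("read %s has no quality string; dropped", read.query_name)
        return False
    if not mq > min_q:
        report.drop("low_quality")
        return False
    report.kept += 1
    return True


def filter_reads(
    alignments: str | Path | pysam.AlignmentFile,
    params: ReadFilterParams | None = None,
    out_path: str | Path | None = None,
) -> tuple[list[pysam.AlignedSegment], FilterReport]:
    """Apply read-level filters; optionally write the retained reads to a BAM.

    Returns the retained reads and a report of kept/dropped counts by reason.
    """
    params = params or ReadFilterParams()
    min_q = params.resolved_min_q()
    report = FilterReport()
    own = isinstance(alignments, (str, Path))
    af = pysam.AlignmentFile(str(alignments), check_sq=False) if own else alignments
    try:
        kept = [r for r in af.fetch(until_eof=True) if _passes(r, params, min_q, report)]
        if out_path is not None:
            with pysam.AlignmentFile(str(out_path), "wb", header=af.header) as out:
                for r in kept:
                    out.write(r)
    finally:
        if own:
            af.close()
    return kept, report


@dataclass
class PileupProfile:
    """Coverage and error counts along one transcript.

    Arrays are 0-based internally; :meth:`to_frame` emits 1-based positions.
    ``bcerror`` is error_count / coverage, NaN where coverage is zero;
    ``mask`` is True wherever coverage < ``min_depth``.
    """

    transcript: str
    coverage: np.ndarray
    error_count: np.ndarray
    min_depth: int = DEFAULT_MIN_DEPTH

    def __post_init__(self) -> None:
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        self.error_count = np.asarray(self.error_count, dtype=np.int64)
        if self.coverage.shape != self.error_count.shape:
            raise ValueError("coverage and error_count must have the same length")
        if np.any(self.error_count > self.coverage):
            raise ValueError(
                f"{self.transcript}: error_count exceeds coverage at some position"
            )
        if np.any(self.error_count < 0) or np.any(self.coverage < 0):
            raise ValueError("negative counts")

    @property
    def length(self) -> int:
        return self.coverage.size

    @property
    def bcerror(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.coverage > 0,
                            self.error_count / np.maximum(self.coverage, 1),
                            np.nan)

    @property
    def mask(self) -> np.ndarray:
        return self.coverage < self.min_depth

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "transcript": self.transcript,
            "pos": np.arange(1, self.length + 1),
            "coverage": self.coverage,
            "error_count": self.error_count,
            "bcerror": self.bcerror,
            "masked": self.mask,
        })


def _load_reference(reference) -> Mapping[str, str]:
    if isinstance(reference, Mapping):
        return {k: str(v).upper() for k, v in reference.items()}
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(reference), "fasta")}


def compute_bcerror(
    alignments: str | Path | pysam.AlignmentFile | Iterable[pysam.AlignedSegment],
    reference: str | Path | Mapping[str, str],
    min_depth: int = DEFAULT_MIN_DEPTH,
    header: pysam.AlignmentHeader | None = None,
) -> dict[str, PileupProfile]:
    """BCError profile per transcript from filtered alignments.

    ``alignments`` may be a BAM/SAM path, an open AlignmentFile, or an
    iterable of reads (``header`` then supplies reference names/lengths).
    Reverse-strand alignments are dropped with a warning: direct RNA reads
    are sense-strand in transcript space by construction.
    """
    seqs = _load_reference(reference)
    own = isinstance(alignments, (str, Path))
    if own:
        af = pysam.AlignmentFile(str(alignments), check_sq=False)
        reads: Iterable[pysam.AlignedSegment] = af.fetch(until_eof=True)
        header = af.header
    elif isinstance(alignments, pysam.AlignmentFile):
        af = None
        reads = alignments.fetch(until_eof=True)
        header = alignments.header
    else:
        af = None
        reads = alignments
        if header is None:
            raise ValueError("header required when passing a raw read iterable")

    cov: dict[str, np.ndarray] = {}
    err: dict[str, np.ndarray] = {}
    ref_arr: dict[str, np.ndarray] = {}
    n_reverse = 0
    try:
        for read in reads:
            if read.is_unmapped:
                continue
            if read.is_reverse:
                n_reverse += 1
                continue
            tname = read.reference_name
            if tname not in seqs:
                raise KeyError(
                    f"transcript {tname!r} present in alignments but absent "
                    f"from the reference FASTA"
                )
            if tname not in cov:
                L = header.get_reference_length(tname) if header is not None else len(seqs[tname])
                if L != len(seqs[tname]):
                    raise ValueError(
                        f"transcript {tname!r}: alignment header length {L} != "
                        f"reference sequence length {len(seqs[tname])}"
                    )
                cov[tname] = np.zeros(L, dtype=np.int64)
                err[tname] = np.zeros(L, dtype=np.int64)
                ref_arr[tname] = np.frombuffer(seqs[tname].encode(), dtype="S1")
            _accumulate_read(read, cov[tname], err[tname], ref_arr[tname])
    finally:
        if af is not None:
            af.close()
    if n_reverse:
        logger.warning("dropped %d reverse-strand alignments", n_reverse)

    return {t: PileupProfile(t, cov[t], err[t], min_depth=min_depth) for t in cov}


_CMATCH, _CINS, _CDEL, _CREF_SKIP, _CSOFT = 0, 1, 2, 3, 4
_CHARD, _CPAD, _CEQUAL, _CDIFF = 5, 6, 7, 8


def _accumulate_read(read: pysam.AlignedSegment, cov: np.ndarray,
                     err: np.ndarray, ref: np.ndarray) -> None:
    """Add one read's coverage and binary per-position error indicators."""
    qseq = read.query_sequence
    q = np.frombuffer(qseq.upper().encode(), dtype="S1") if qseq else None
    rpos = read.reference_start
    qpos = 0
    # binary indicator: collect error positions in a set to avoid double counting
    err_pos: set[int] = set()
    for op, ln in read.cigartuples:
        if op in (_CMATCH, _CEQUAL, _CDIFF):
            cov[rpos:rpos + ln] += 1
            if q is not None:
                mism = np.nonzero(q[qpos:qpos + ln] != ref[rpos:rpos + ln])[0]
                err_pos.update((rpos + mism).tolist())
            rpos += ln
            qpos += ln
        elif op == _CDEL:
            cov[rpos:rpos + ln] += 1
            err_pos.update(range(rpos, rpos + ln))
            rpos += ln
        elif op == _CINS:
            if rpos > read.reference_start:  # charge to position immediately 5'
                err_pos.add(rpos - 1)
            qpos += ln
        elif op == _CSOFT:
            qpos += ln
        elif op == _CREF_SKIP:
            rpos += ln
        elif op in (_CHARD, _CPAD):
            pass
        else:  # pragma: no cover - exotic ops
            raise ValueError(f"unsupported CIGAR op {op}")
    if err_pos:
        idx = np.fromiter(err_pos, dtype=np.int64)
        err[idx] += 1


def pool_profiles(profiles: Iterable[PileupProfile]) -> PileupProfile:
    """Pool replicate profiles by summing counts positionwise.

    BCError is recomputed from the pooled counts (count pooling, not a mean
    of proportions), matching how combined replicate samples are formed.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to pool")
    first = profiles[0]
    cov = first.coverage.copy()
    err = first.error_count.copy()
    for p in profiles[1:]:
        if p.transcript != first.transcript or p.length != first.length:
            raise ValueError(
                f"cannot pool {p.transcript!r} (len {p.length}) with "
                f"{first.transcript!r} (len {first.length})"
            )
        cov += p.coverage
        err += p.error_count
    return PileupProfile(first.transcript, cov, err,
                         min_depth=min(p.min_depth for p in profiles))


def read_length_table(
    alignments: Iterable[pysam.AlignedSegment],
    condition: str = "",
    replicate: str | int = "",
    trim_adapters: bool = False,
    adapter: str | None = None,
) -> pd.DataFrame:
    """One row per retained read with its query length.

    With ``trim_adapters`` and an ``adapter`` sequence, a single 3' adapter
    occurrence is removed from the read before measuring the length (the
    adapter and everything 3' of it is discarded).
    """
    rows = []
    for read in alignments:
        if read.is_unmapped or read.query_sequence is None:
            continue
        seq = read.query_sequence
        if trim_adapters and adapter:
            i = seq.find(adapter)
            if i >= 0:
                seq = seq[:i]
        if len(seq) == 0:
            continue
        rows.append((read.reference_name, condition, replicate, len(seq)))
    return pd.DataFrame(rows, columns=["transcript", "condition", "replicate", "length"])


def write_profiles(profiles: Mapping[str, PileupProfile] | Iterable[PileupProfile],
                   path: str | Path) -> None:
    """Write profiles as a single TSV (transcript, pos, coverage, error_count, bcerror, masked)."""
    if isinstance(profiles, Mapping):
        profiles = profiles.values()
    frames = [p.to_frame() for p in profiles]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_profiles(path: str | Path, min_depth: int = DEFAULT_MIN_DEPTH) -> dict[str, PileupProfile]:
    """Load profiles from a TSV written by :func:`write_profiles`."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for t, sub in df.groupby("transcript", sort=False):
        sub = sub.sort_values("pos")
        if not np.array_equal(sub["pos"].to_numpy(), np.arange(1, len(sub) + 1)):
            warnings.warn(f"profile for {t} has position gaps; reindexing densely")
        out[str(t)] = PileupProfile(str(t), sub["coverage"].to_numpy(),
                                    sub["error_count"].to_numpy(), min_depth=min_depth)
    return out
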