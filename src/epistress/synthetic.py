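"""Synthetic nanopore direct-RNA epitranscriptome generator.

Every downstream stage of the package (BCError profiling, ΔBCError site
detection, tRNA maturation analysis, codon scoring) is testable without any
sequencing download because this module fabricates the whole study design:

* a transcript-space reference with mRNA (5'UTR/CDS/3'UTR), rRNA (16S/23S
  with realistic lengths), tRNA (mature sequence plus leader/trailer
  metadata), and ncRNA entries;
* a ground-truth table of modified positions with per-condition
  stoichiometry ``s`` (the fraction of molecules carrying the modification),
  including an in vitro transcribed (IVT) condition whose stoichiometry is
  exactly zero everywhere, and stress-dependent shifts at tRNA wobble sites;
* coordinate-sorted, indexed BAM alignments in which each molecule is drawn
  modified at a site with probability ``s`` and then basecalling errors are
  injected per position with probability ``e_base`` (unmodified molecule) or
  ``e_base + delta_mod`` (modified molecule), so the expected BCError at a
  site is ``e_base + s * delta_mod`` and ΔBCError against IVT divided by
  ``delta_mod`` is an unbiased estimator of ``s``;
* pre-tRNA read populations mixing mature (~70-100 nt) and immature
  (100-500 nt, leader/trailer-bearing) molecules, where the anticodon
  modification probability of immature reads is damped by an immaturity
  factor < 1 — the negative length-modification coupling the maturation
  analysis must recover;
* a translational-efficiency table whose "increased" class can be enriched
  in modification-dependent codons with a configurable effect size.

Error events are mismatch:deletion:insertion = 0.6:0.3:0.1 by default, at
most one event per read per position.  One master seed drives everything;
sub-streams are derived per (condition, replicate) so adding a replicate
never perturbs the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

__all__ = [
    "ReadLengthModel",
    "SyntheticConfig",
    "TrnaRefMeta",
    "SyntheticReference",
    "SyntheticTruth",
    "generate_reference",
    "sample_truth",
    "simulate_alignments",
    "simulate_pileup",
    "simulate_pretrna_lengths",
    "generate_te_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

MISMATCH, DELETION, INSERTION = 0, 1, 2


def _stream(seed: int, *tags: int | str) -> np.random.Generator:
    """Deterministic sub-stream: master seed plus stable integer tags."""
    words = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        if isinstance(t, str):
            words.append(zlib.crc32(t.encode()) & 0x7FFFFFFF)
        else:
            words.append(int(t) & 0x7FFFFFFF)
    return np.random.default_rng(words)


@dataclass(frozen=True)
class ReadLengthModel:
    """Two-component pre-tRNA read-length mixture.

    Mature reads sit near the mature tRNA length (70-100 nt); immature reads
    retain part of the leader/trailer (100-500 nt).  Each tRNA gets its own
    immature fraction drawn from ``immature_fraction_range``, creating
    between-tRNA variation in processing state.  ``immaturity_factor``
    multiplies the anticodon modification probability of immature reads.
    """

    mature_range: tuple[int, int] = (70, 100)
    immature_range: tuple[int, int] = (100, 500)
    immature_fraction_range: tuple[float, float] = (0.1, 0.6)
    reads_per_trna: int = 200
    immaturity_factor: float = 0.3

    def validate(self) -> None:
        lo, hi = self.immature_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("immature_fraction_range must lie within [0, 1] "
                             "and be ordered (mixture weights must sum to 1)")
        if not (0.0 <= self.immaturity_factor <= 1.0):
            raise ValueError("immaturity_factor must lie in [0, 1]")
        if self.reads_per_trna <= 0:
            raise ValueError("reads_per_trna must be positive")
        for rng_ in (self.mature_range, self.immature_range):
            if rng_[0] > rng_[1] or rng_[0] <= 0:
                raise ValueError(f"invalid length range {rng_}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for the generator.

    ``conditions`` maps condition label to replicate count and must contain
    the IVT label; every non-IVT condition needs at least two biological
    replicates.  ``baseline_error`` and ``mod_error_boost`` are per-position
    error probabilities (their sum must not exceed 1).
    """

    seed: int = 0
    n_transcripts: int = 12
    biotype_weights: Mapping[str, float] = field(
        default_factory=lambda: {"mRNA": 0.5, "rRNA": 0.15, "tRNA": 0.25, "ncRNA": 0.1})
    baseline_error: float = 0.03
    mod_error_boost: float = 0.25
    coverage: int = 100
    conditions: Mapping[str, int] = field(
        default_factory=lambda: {"no_stress": 2, "acid_stress": 2, "ivt": 1})
    ivt_label: str = "ivt"
    control_condition: str = "no_stress"
    error_mix: tuple[float, float, float] = (0.6, 0.3, 0.1)
    read_q_mean: float = 12.0
    low_q_fraction: float = 0.0
    low_q_value: float = 7.0
    sites_per_transcript: int = 2
    stoich_range: tuple[float, float] = (0.2, 0.9)
    wobble_stoich_range: tuple[float, float] = (0.6, 0.9)
    stress_shift: float = 0.3
    n_shifted_trnas: int | None = None
    mrna_utr5_range: tuple[int, int] = (20, 80)
    mrna_cds_codons_range: tuple[int, int] = (60, 200)
    mrna_utr3_range: tuple[int, int] = (20, 100)
    mrna_cds_lengths: Sequence[int] | None = None
    read_length_model: ReadLengthModel = field(default_factory=ReadLengthModel)

    def validate(self) -> None:
        if self.baseline_error < 0 or self.mod_error_boost <= 0:
            raise ValueError("baseline_error must be >= 0 and mod_error_boost > 0")
        if self.baseline_error + self.mod_error_boost > 1.0:
            raise ValueError("baseline_error + mod_error_boost must be <= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be a positive integer")
        if self.ivt_label not in self.conditions:
            raise ValueError(f"conditions must include the IVT label {self.ivt_label!r}")
        for cond, reps in self.conditions.items():
            if cond != self.ivt_label and reps < 2:
                raise ValueError(
                    f"non-IVT condition {cond!r} needs >= 2 replicates, got {reps}")
        if abs(sum(self.biotype_weights.values()) - 1.0) > 1e-9:
            raise ValueError("biotype_weights must sum to 1")
        if abs(sum(self.error_mix) - 1.0) > 1e-9 or min(self.error_mix) < 0:
            raise ValueError("error_mix proportions must be non-negative and sum to 1")
        if self.n_transcripts < sum(1 for w in self.biotype_weights.values() if w > 0):
            raise ValueError("n_transcripts too small to cover every biotype")
        if self.mrna_cds_lengths is not None:
            for L in self.mrna_cds_lengths:
                if L % 3 != 0 or L <= 0:
                    raise ValueError(f"requested CDS length {L} is not a positive multiple of 3")
        self.read_length_model.validate()

    @property
    def stress_conditions(self) -> list[str]:
        return [c for c in self.conditions
                if c not in (self.ivt_label, self.control_condition)]


@dataclass(frozen=True)
class TrnaRefMeta:
    anticodon_start: int  # 1-based within the mature sequence
    leader_len: int
    trailer_len: int


@dataclass
class SyntheticReference:
    """Transcript sequences plus the per-biotype structural metadata."""

    sequences: dict[str, str]
    biotypes: dict[str, str]
    mrna_segments: dict[str, tuple[int, int, int]]  # (utr5, cds, utr3) lengths
    trna_meta: dict[str, TrnaRefMeta]

    def __post_init__(self) -> None:
        for t, (u5, cds, u3) in self.mrna_segments.items():
            if cds % 3 != 0:
                raise ValueError(f"{t}: CDS length {cds} not divisible by 3")
            if u5 + cds + u3 != len(self.sequences[t]):
                raise ValueError(f"{t}: UTR/CDS lengths do not sum to transcript length")
        for t, m in self.trna_meta.items():
            if m.anticodon_start + 2 > len(self.sequences[t]):
                raise ValueError(f"{t}: anticodon extends beyond the mature sequence")

    def transcripts(self, biotype: str | None = None) -> list[str]:
        if biotype is None:
            return list(self.sequences)
        return [t for t in self.sequences if self.biotypes[t] == biotype]

    def cds_sequence(self, transcript: str) -> str:
        u5, cds, _ = self.mrna_segments[transcript]
        return self.sequences[transcript][u5:u5 + cds]

    def write_fasta(self, path: str | Path) -> None:
        from Bio.Seq import Seq
        from Bio.SeqIO import write as seqio_write
        from Bio.SeqRecord import SeqRecord

        records = [SeqRecord(Seq(s), id=t, description=self.biotypes[t])
                   for t, s in self.sequences.items()]
        seqio_write(records, str(path), "fasta")

    def write_gff3(self, path: str | Path) -> None:
        """Transcript-space GFF3 (1-based, closed intervals)."""
        type_of = {"mRNA": "mRNA", "rRNA": "rRNA", "tRNA": "tRNA", "ncRNA": "ncRNA"}
        lines = ["##gff-version 3"]
        for t, seq in self.sequences.items():
            L = len(seq)
            bt = self.biotypes[t]
            lines.append("\t".join([t, "epistress", type_of[bt], "1", str(L),
                                    ".", "+", ".", f"ID={t};biotype={bt}"]))
            if bt == "mRNA":
                u5, cds, u3 = self.mrna_segments[t]
                if u5:
                    lines.append("\t".join([t, "epistress", "five_prime_UTR", "1",
                                            str(u5), ".", "+", ".", f"Parent={t}"]))
                lines.append("\t".join([t, "epistress", "CDS", str(u5 + 1),
                                        str(u5 + cds), ".", "+", "0", f"Parent={t}"]))
                if u3:
                    lines.append("\t".join([t, "epistress", "three_prime_UTR",
                                            str(u5 + cds + 1), str(L), ".", "+", ".",
                                            f"Parent={t}"]))
        Path(path).write_text("\n".join(lines) + "\n")

    def write_utr_tsv(self, path: str | Path) -> None:
        rows = [(t, u5, cds, u3) for t, (u5, cds, u3) in self.mrna_segments.items()]
        pd.DataFrame(rows, columns=["transcript", "utr5_len", "cds_len", "utr3_len"]
                     ).to_csv(path, sep="\t", index=False)

    def write_trna_meta_tsv(self, path: str | Path) -> None:
        rows = [(t, m.anticodon_start, m.leader_len, m.trailer_len)
                for t, m in self.trna_meta.items()]
        pd.DataFrame(rows, columns=["trna", "anticodon_start", "leader_len",
                                    "trailer_len"]).to_csv(path, sep="\t", index=False)


_RRNA_LENGTHS = {"16S": 1542, "23S": 2904}


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random sense codons + stop; length = 3 * n_codons."""
    if n_codons < 3:
        raise ValueError("CDS needs at least start, one sense codon, and stop")
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = _random_seq(rng, 3)
        if c not in _STOP_CODONS:
            codons.append(c)
    codons.append("TAA")
    return "".join(codons)


def _allocate(n: int, weights: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder allocation with >= 1 per positive-weight biotype."""
    keys = [k for k in ("mRNA", "rRNA", "tRNA", "ncRNA") if weights.get(k, 0) > 0]
    raw = {k: weights[k] * n for k in keys}
    counts = {k: max(1, int(raw[k])) for k in keys}
    while sum(counts.values()) > n:
        k = max(counts, key=lambda k: (counts[k] - raw[k], counts[k]))
        if counts[k] > 1:
            counts[k] -= 1
        else:  # pragma: no cover - guarded by config validation
            break
    while sum(counts.values()) < n:
        k = max(counts, key=lambda k: (raw[k] - counts[k], raw[k]))
        counts[k] += 1
    return counts


def generate_reference(config: SyntheticConfig) -> SyntheticReference:
    """Deterministically fabricate the transcript reference for a config."""
    config.validate()
    rng = _stream(config.seed, "reference")
    counts = _allocate(config.n_transcripts, config.biotype_weights)

    sequences: dict[str, str] = {}
    biotypes: dict[str, str] = {}
    mrna_segments: dict[str, tuple[int, int, int]] = {}
    trna_meta: dict[str, TrnaRefMeta] = {}

    for i in range(counts.get("rRNA", 0)):
        name = ("16S", "23S")[i] if i < 2 else f"rRNA_{i + 1:02d}"
        L = _RRNA_LENGTHS.get(name, int(rng.integers(100, 301)))
        sequences[name] = _random_seq(rng, L)
        biotypes[name] = "rRNA"

    for i in range(counts.get("mRNA", 0)):
        name = f"mRNA_{i + 1:02d}"
        u5 = int(rng.integers(*config.mrna_utr5_range))
        u3 = int(rng.integers(*config.mrna_utr3_range))
        if config.mrna_cds_lengths is not None:
            cds_len = int(config.mrna_cds_lengths[i % len(config.mrna_cds_lengths)])
            n_codons = cds_len // 3
        else:
            n_codons = int(rng.integers(*config.mrna_cds_codons_range))
        cds = _random_cds(rng, n_codons)
        sequences[name] = _random_seq(rng, u5) + cds + _random_seq(rng, u3)
        biotypes[name] = "mRNA"
        mrna_segments[name] = (u5, len(cds), u3)

    for i in range(counts.get("tRNA", 0)):
        name = f"tRNA_{i + 1:02d}"
        mature_len = int(rng.integers(72, 96))
        leader = int(rng.integers(30, 151))
        trailer = int(rng.integers(30, 251))
        trailer = min(trailer, 500 - mature_len - leader)
        sequences[name] = _random_seq(rng, mature_len)
        biotypes[name] = "tRNA"
        trna_meta[name] = TrnaRefMeta(anticodon_start=34, leader_len=leader,
                                      trailer_len=max(trailer, 10))

    for i in range(counts.get("ncRNA", 0)):
        name = f"ncRNA_{i + 1:02d}"
        sequences[name] = _random_seq(rng, int(rng.integers(80, 301)))
        biotypes[name] = "ncRNA"

    return SyntheticReference(sequences, biotypes, mrna_segments, trna_meta)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class SyntheticTruth:
    """Long-format truth: (transcript, position, mod, condition, stoichiometry)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"transcript", "position", "mod", "condition", "stoichiometry"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"truth table must have columns {sorted(required)}")

    def for_condition(self, condition: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """{transcript: (0-based positions, stoichiometries)} for one condition."""
        out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        sub = self.table[self.table["condition"] == condition]
        for t, g in sub.groupby("transcript", sort=False):
            out[str(t)] = (g["position"].to_numpy() - 1,
                           g["stoichiometry"].to_numpy(dtype=float))
        return out

    def sites(self, biotype_of: Mapping[str, str] | None = None,
              biotype: str | None = None) -> pd.DataFrame:
        """Unique (transcript, position, mod) rows, optionally by biotype."""
        s = self.table[["transcript", "position", "mod"]].drop_duplicates()
        if biotype is not None:
            s = s[s["transcript"].map(biotype_of) == biotype]
        return s.reset_index(drop=True)

    def wobble_stoich(self, condition: str,
                      trna_meta: Mapping[str, TrnaRefMeta]) -> dict[str, float]:
        sub = self.table[(self.table["condition"] == condition)
                         & (self.table["mod"] == "wobble")]
        return {str(r.transcript): float(r.stoichiometry)
                for r in sub.itertuples(index=False)}

    def write_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def sample_truth(reference: SyntheticReference, config: SyntheticConfig) -> SyntheticTruth:
    """Draw modified positions and per-condition stoichiometries.

    rRNA transcripts named 16S/23S receive the curated known-site positions
    shipped with the package, so calibration can be run against the same
    table that real rRNA analyses use.  tRNAs get a wobble site (first
    anticodon position) plus one body site; stress conditions shift the
    wobble stoichiometry of a configurable subset of tRNAs by
    ``stress_shift`` (clipped to [0, 1]).  IVT stoichiometry is exactly 0.
    """
    config.validate()
    rng = _stream(config.seed, "truth")
    rows: list[tuple[str, int, str, float]] = []  # (transcript, pos1, mod, control stoich)

    from .detection import known_rrna_sites

    known = known_rrna_sites()
    for t in reference.transcripts("rRNA"):
        L = len(reference.sequences[t])
        sub = known[known["molecule"] == t]
        if len(sub):
            for r in sub.itertuples(index=False):
                if r.position <= L:
                    s = float(rng.uniform(*config.stoich_range))
                    rows.append((t, int(r.position), str(r.mod), s))
        else:
            for p in sorted(rng.choice(np.arange(2, L), size=min(config.sites_per_transcript, L - 2),
                                       replace=False)):
                rows.append((t, int(p), "unknown", float(rng.uniform(*config.stoich_range))))

    for t in reference.transcripts("mRNA") + reference.transcripts("ncRNA"):
        L = len(reference.sequences[t])
        k = min(config.sites_per_transcript, max(L - 2, 0))
        for p in sorted(rng.choice(np.arange(2, L), size=k, replace=False)):
            rows.append((t, int(p), "unknown", float(rng.uniform(*config.stoich_range))))

    trnas = reference.transcripts("tRNA")
    for t in trnas:
        meta = reference.trna_meta[t]
        rows.append((t, meta.anticodon_start, "wobble",
                     float(rng.uniform(*config.wobble_stoich_range))))
        body = int(rng.integers(5, 25))
        rows.append((t, body, "body", float(rng.uniform(*config.stoich_range))))

    n_shift = len(trnas) if config.n_shifted_trnas is None else config.n_shifted_trnas
    shifted = set(rng.choice(trnas, size=min(n_shift, len(trnas)), replace=False)) \
        if trnas else set()

    out = []
    for cond in config.conditions:
        for t, pos, mod, s in rows:
            if cond == config.ivt_label:
                stoich = 0.0
            elif (cond in config.stress_conditions and mod == "wobble"
                  and t in shifted):
                stoich = float(np.clip(s + config.stress_shift, 0.0, 1.0))
            else:
                stoich = s
            out.append((t, pos, mod, cond, stoich))
    df = pd.DataFrame(out, columns=["transcript", "position", "mod",
                                    "condition", "stoichiometry"])
    return SyntheticTruth(df)


# ---------------------------------------------------------------------------
# alignment simulation


def _assemble_read(seq: bytes, events: list[tuple[int, int, int]]) -> tuple[str, list[tuple[int, int]]]:
    """Build (query sequence, cigartuples) from per-position error events.

    ``events``: sorted (position, type, random draw in 0..2).  A deletion at
    the first or last reference position is emitted as a mismatch instead (a
    CIGAR cannot start or end with D).
    """
    L = len(seq)
    qparts: list[bytes] = []
    cig: list[tuple[int, int]] = []

    def add(op: int, ln: int) -> None:
        if ln <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + ln)
        else:
            cig.append((op, ln))

    prev = 0
    for pos, typ, r in events:
        if typ == DELETION and (pos == 0 or pos == L - 1):
            typ = MISMATCH
        if typ == MISMATCH:
            add(0, pos - prev)
            qparts.append(seq[prev:pos])
            ref_i = _BASES.tolist().index(seq[pos:pos + 1])
            qparts.append(_BASES[(ref_i + 1 + r % 3) % 4])
            add(0, 1)
            prev = pos + 1
        elif typ == DELETION:
            add(0, pos - prev)
            qparts.append(seq[prev:pos])
            add(2, 1)
            prev = pos + 1
        else:  # insertion after pos
            add(0, pos + 1 - prev)
            qparts.append(seq[prev:pos + 1])
            qparts.append(_BASES[r % 4])
            add(1, 1)
            prev = pos + 1
    add(0, L - prev)
    qparts.append(seq[prev:])
    query = b"".join(p if isinstance(p, bytes) else p.tobytes() for p in qparts)
    return query.decode(), cig


def _simulate_sample_reads(
    reference: SyntheticReference,
    site_map: Mapping[str, tuple[np.ndarray, np.ndarray]],
    config: SyntheticConfig,
    rng: np.random.Generator,
):
    """Yield (transcript, read name suffix, query, cigar, qual) per read."""
    e = config.baseline_error
    d = config.mod_error_boost
    m_mis, m_del, _ = config.error_mix
    for t in reference.sequences:
        seq = reference.sequences[t].encode()
        L = len(seq)
        n = config.coverage
        U = rng.random((n, L))
        err = U < e
        positions, stoich = site_map.get(t, (np.empty(0, dtype=int), np.empty(0)))
        for p, s in zip(positions, stoich):
            if s > 0:
                modified = rng.random(n) < s
                err[:, p] = U[:, p] < (e + d * modified)
        tdraw = rng.random((n, L))
        rdraw = rng.integers(0, 12, size=(n, L), dtype=np.int8)  # base choice entropy
        lowq = rng.random(n) < config.low_q_fraction
        for i in range(n):
            idx = np.nonzero(err[i])[0]
            events = []
            for pos in idx:
                x = tdraw[i, pos]
                typ = MISMATCH if x < m_mis else (DELETION if x < m_mis + m_del
                                                  else INSERTION)
                events.append((int(pos), typ, int(rdraw[i, pos])))
            query, cig = _assemble_read(seq, events)
            q = config.low_q_value if lowq[i] else config.read_q_mean
            yield t, i, query, cig, int(round(q))


def simulate_alignments(
    reference: SyntheticReference,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    outdir: str | Path,
    conditions: Sequence[str] | None = None,
) -> dict[tuple[str, int], Path]:
    """Write one coordinate-sorted, indexed BAM per condition x replicate.

    Reads span their whole transcript; per-read constant quality strings let
    the mean-Q filters be exercised.  Returns {(condition, replicate): path}.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": t, "LN": len(s)} for t, s in reference.sequences.items()],
    })
    tid_of = {t: i for i, t in enumerate(reference.sequences)}
    out: dict[tuple[str, int], Path] = {}
    for cond in (conditions or list(config.conditions)):
        site_map = truth.for_condition(cond)
        for rep in range(1, config.conditions[cond] + 1):
            rng = _stream(config.seed, "bam", cond, rep)
            path = outdir / f"{cond}_rep{rep}.bam"
            with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
                for t, i, query, cig, q in _simulate_sample_reads(
                        reference, site_map, config, rng):
                    a = pysam.AlignedSegment(header)
                    a.query_name = f"{cond}_{rep}_{t}_{i:05d}"
                    a.query_sequence = query
                    a.flag = 0
                    a.reference_id = tid_of[t]
                    a.reference_start = 0
                    a.mapping_quality = 60
                    a.cigartuples = cig
                    a.query_qualities = pysam.qualitystring_to_array(
                        chr(q + 33) * len(query))
                    bam.write(a)
            pysam.index(str(path))
            out[(cond, rep)] = path
    return out


def simulate_pileup(
    reference: SyntheticReference,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    condition: str,
    replicate: int = 1,
):
    """Direct per-position count simulation (no reads materialized).

    Error counts are Binomial(coverage, e_base + s * delta_mod), exactly the
    marginal law of the read-level model; use where only counts matter.
    Returns {transcript: PileupProfile}.
    """
    from .profiling import PileupProfile

    config.validate()
    rng = _stream(config.seed, "pileup", condition, replicate)
    site_map = truth.for_condition(condition)
    out = {}
    for t, seq in reference.sequences.items():
        L = len(seq)
        p = np.full(L, config.baseline_error)
        positions, stoich = site_map.get(t, (np.empty(0, dtype=int), np.empty(0)))
        p[positions] = config.baseline_error + stoich * config.mod_error_boost
        cov = np.full(L, config.coverage, dtype=np.int64)
        err = rng.binomial(cov, p)
        out[t] = PileupProfile(t, cov, err)
    return out


# ---------------------------------------------------------------------------
# pre-tRNA read populations


def simulate_pretrna_lengths(
    reference: SyntheticReference,
    truth: SyntheticTruth,
    config: SyntheticConfig,
    condition: str,
    replicate: int = 1,
) -> pd.DataFrame:
    """Per-read lengths and anticodon modification states for all tRNAs.

    Each tRNA's immature-read fraction is drawn once (per master seed) from
    the model's range and shared across conditions and replicates, so
    between-condition comparisons see the same processing baseline.  Mature
    reads are the mature sequence minus a small 5' truncation; immature
    reads extend into the leader/trailer.  A read's anticodon is modified
    with probability ``s`` (mature) or ``s * immaturity_factor`` (immature).
    """
    config.validate()
    model = config.read_length_model
    wobble = truth.wobble_stoich(condition, reference.trna_meta)
    rows = []
    for t in reference.transcripts("tRNA"):
        meta = reference.trna_meta[t]
        mature_len = len(reference.sequences[t])
        f_imm = float(_stream(config.seed, "maturity", t).uniform(
            *model.immature_fraction_range))
        rng = _stream(config.seed, "pretrna", condition, replicate, t)
        n = model.reads_per_trna
        immature = rng.random(n) < f_imm
        mat_lo = min(model.mature_range[0], mature_len)
        mat_hi = min(model.mature_range[1], mature_len)
        imm_lo = max(model.immature_range[0], mature_len + 1)
        imm_hi = max(min(model.immature_range[1],
                         mature_len + meta.leader_len + meta.trailer_len),
                     imm_lo + 1)
        mature_draw = rng.integers(mat_lo, mat_hi + 1, size=n)
        immature_draw = rng.integers(imm_lo, imm_hi + 1, size=n)
        lengths = np.where(immature, immature_draw, mature_draw)
        s = wobble.get(t, 0.0)
        p_mod = np.where(immature, s * model.immaturity_factor, s)
        modified = rng.random(n) < p_mod
        for ln, im, mo in zip(lengths, immature, modified):
            rows.append((t, condition, replicate, int(ln), bool(im), bool(mo)))
    return pd.DataFrame(rows, columns=["transcript", "condition", "replicate",
                                       "length", "immature", "modified"])


# ---------------------------------------------------------------------------
# translational-efficiency table


def generate_te_table(
    reference: SyntheticReference,
    config: SyntheticConfig,
    effect: float = 0.0,
) -> pd.DataFrame:
    """TE log-fold-changes and classes, optionally coupled to codon scores.

    With ``effect`` = 0 the class labels are independent of codon content;
    with ``effect`` > 0 the latent log-fold-change is shifted by
    ``effect * z``, where ``z`` is the standardized modification-dependent
    codon abundance of the CDS, so the "increased" class is enriched in
    modification-dependent codons with a known effect size.
    """
    from .codons import default_codon_sets, count_codons

    config.validate()
    mrnas = reference.transcripts("mRNA")
    if not mrnas:
        return pd.DataFrame(columns=["transcript", "te_lfc", "te_class"])
    sets = default_codon_sets()
    scores = np.array([
        (count_codons(reference.cds_sequence(t), sets).abundance or 0.0)
        for t in mrnas
    ])
    sd = scores.std()
    z = (scores - scores.mean()) / sd if sd > 0 else np.zeros_like(scores)
    rng = _stream(config.seed, "te")
    lfc = effect * z + rng.normal(0.0, 0.5, size=len(mrnas))
    te_class = np.where(lfc > 0.25, "increased",
                        np.where(lfc < -0.25, "decreased", "unchanged"))
    return pd.DataFrame({"transcript": mrnas, "te_lfc": lfc, "te_class": te_class})
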