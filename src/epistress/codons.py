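"""Modification-dependent codon abundance and translational-efficiency tests.

Wobble-position tRNA modifications from the queuosine (Q) and Mnm pathways
expand decoding: for nine synonymous codon pairs, one codon of each pair can
only be translated efficiently when the cognate anticodon carries the
modification (modification-dependent), while its partner is read by
unmodified Watson-Crick pairing (modification-independent).  For a CDS the
normalized modification-dependent codon abundance is

    abundance = n_dependent / (n_dependent + n_independent)

counted over an in-frame, non-overlapping codon scan of the 18 set codons.
Transcript ranking by abundance uses tie-aware top/bottom-n selection (every
transcript tied with the boundary score is included), and abundance
differences between translational-efficiency classes are assessed with a
two-sided Mann-Whitney U test.

The default nine sets are the standard wobble-decoding assignments (Q: Asn,
Asp, His, Tyr with the U-ending codon dependent; Mnm: Arg, Gln, Glu, Gly,
Leu with the G-ending codon dependent) and can be replaced from a TSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table
from scipy import stats

__all__ = [
    "CodonSet",
    "CodonSetTable",
    "CodonScore",
    "GroupComparison",
    "default_codon_sets",
    "load_codon_sets",
    "count_codons",
    "score_cds_records",
    "rank_select",
    "compare_te_groups",
]


def _dna(codon: str) -> str:
    return codon.upper().replace("U", "T")


@dataclass(frozen=True)
class CodonSet:
    amino_acid: str
    pathway: str       # Q | Mnm
    dependent: str     # modification-dependent codon (DNA alphabet)
    independent: str   # modification-independent synonymous codon


@dataclass(frozen=True)
class CodonSetTable:
    """Nine validated (dependent, independent) synonymous codon pairs."""

    sets: tuple[CodonSet, ...]

    def __post_init__(self) -> None:
        table = standard_dna_table.forward_table
        seen: set[str] = set()
        for s in self.sets:
            dep, ind = _dna(s.dependent), _dna(s.independent)
            for c in (dep, ind):
                if len(c) != 3 or any(b not in "ACGT" for b in c):
                    raise ValueError(f"{c!r} is not a valid codon")
                if c in standard_dna_table.stop_codons:
                    raise ValueError(f"{c!r} is a stop codon")
                if c in seen:
                    raise ValueError(f"codon {c!r} appears in two sets")
                seen.add(c)
            if table[dep] != table[ind]:
                raise ValueError(f"{dep}/{ind} are not synonymous")
            if dep[:2] != ind[:2] or dep[2] == ind[2]:
                raise ValueError(f"{dep}/{ind} must differ only at position 3")
        if len(seen) != 2 * len(self.sets):
            raise ValueError("duplicate codons across sets")

    @property
    def dependent_codons(self) -> frozenset[str]:
        return frozenset(_dna(s.dependent) for s in self.sets)

    @property
    def independent_codons(self) -> frozenset[str]:
        return frozenset(_dna(s.independent) for s in self.sets)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.amino_acid, s.pathway, s.dependent, s.independent) for s in self.sets],
            columns=["amino_acid", "pathway", "dependent", "independent"])


_DEFAULT_SETS = (
    # Q pathway: GUN anticodons; NAU codons need queuosine at position 34
    CodonSet("Asn", "Q", "AAT", "AAC"),
    CodonSet("Asp", "Q", "GAT", "GAC"),
    CodonSet("His", "Q", "CAT", "CAC"),
    CodonSet("Tyr", "Q", "TAT", "TAC"),
    # Mnm pathway: mnm5(s2)U34 anticodons; G-ending codons are wobble-read
    CodonSet("Arg", "Mnm", "AGG", "AGA"),
    CodonSet("Gln", "Mnm", "CAG", "CAA"),
    CodonSet("Glu", "Mnm", "GAG", "GAA"),
    CodonSet("Gly", "Mnm", "GGG", "GGA"),
    CodonSet("Leu", "Mnm", "TTG", "TTA"),
)


def default_codon_sets() -> CodonSetTable:
    """The shipped nine Q/Mnm codon pairs (18 codons)."""
    return CodonSetTable(_DEFAULT_SETS)


def load_codon_sets(path: str | Path) -> CodonSetTable:
    """Load replacement codon sets from a TSV
    (amino_acid, pathway, dependent, independent)."""
    df = pd.read_csv(path, sep="\t")
    sets = tuple(CodonSet(str(r.amino_acid), str(r.pathway),
                          _dna(str(r.dependent)), _dna(str(r.independent)))
                 for r in df.itertuples(index=False))
    return CodonSetTable(sets)


@dataclass(frozen=True)
class CodonScore:
    transcript: str
    count_dependent: int
    count_independent: int

    @property
    def abundance(self) -> float | None:
        """dep / (dep + ind); None (masked) when neither codon occurs."""
        denom = self.count_dependent + self.count_independent
        if denom == 0:
            return None
        return self.count_dependent / denom


def count_codons(cds: str, sets: CodonSetTable | None = None,
                 transcript: str = "") -> CodonScore:
    """In-frame, non-overlapping scan counting the 18 set codons.

    The CDS must start at a reading-frame boundary and have a length
    divisible by 3.  Codons containing ambiguity characters are skipped;
    premature stops are counted as ordinary codons (none of the 18 is a
    stop), keeping the scan purely positional.
    """
    sets = sets or default_codon_sets()
    seq = _dna(cds)
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} is not divisible by 3")
    dep_set = sets.dependent_codons
    ind_set = sets.independent_codons
    dep = ind = 0
    for i in range(0, len(seq), 3):
        codon = seq[i:i + 3]
        if codon in dep_set:
            dep += 1
        elif codon in ind_set:
            ind += 1
    return CodonScore(transcript, dep, ind)


def score_cds_records(cds_by_transcript: Mapping[str, str] | str | Path,
                      sets: CodonSetTable | None = None) -> pd.DataFrame:
    """Score every CDS in a mapping or multi-FASTA; one row per transcript.

    The ``abundance`` column is NaN for transcripts containing none of the
    18 codons (masked, not zero).
    """
    if not isinstance(cds_by_transcript, Mapping):
        from Bio import SeqIO

        cds_by_transcript = {rec.id: str(rec.seq)
                             for rec in SeqIO.parse(str(cds_by_transcript), "fasta")}
    rows = []
    for t, seq in cds_by_transcript.items():
        s = count_codons(seq, sets, transcript=t)
        rows.append((t, s.count_dependent, s.count_independent,
                     np.nan if s.abundance is None else s.abundance))
    return pd.DataFrame(rows, columns=["transcript", "count_dependent",
                                       "count_independent", "abundance"])


def rank_select(scores: pd.DataFrame, n: int,
                direction: str = "highest") -> list[str]:
    """Tie-aware top/bottom-``n`` transcripts by abundance.

    Transcripts are sorted by abundance (masked ones excluded); every
    transcript tied with the score at rank ``n`` is included, so the result
    can exceed ``n`` — e.g. a tie spanning ranks 399-403 with n = 400 yields
    403 transcripts.
    """
    if direction not in ("highest", "lowest"):
        raise ValueError("direction must be 'highest' or 'lowest'")
    df = scores.dropna(subset=["abundance"])
    if n > len(df):
        raise ValueError(f"n = {n} exceeds the {len(df)} scored transcripts")
    asc = direction == "lowest"
    df = df.sort_values(["abundance", "transcript"], ascending=[asc, True])
    boundary = df["abundance"].iloc[n - 1]
    if asc:
        sel = df[df["abundance"] <= boundary]
    else:
        sel = df[df["abundance"] >= boundary]
    return sel["transcript"].tolist()


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_te_groups(
    scores: pd.DataFrame,
    te_table: pd.DataFrame,
    classes: tuple[str, str] = ("increased", "decreased"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U on codon abundance between TE classes.

    ``te_table`` needs columns transcript and te_class.  The U statistic is
    reported for the first class; ties are handled with midranks (an exact
    null distribution is used for small tie-free samples).  Raises when a
    class is empty after removing masked abundances.
    """
    merged = scores.merge(te_table[["transcript", "te_class"]], on="transcript")
    merged = merged.dropna(subset=["abundance"])
    a = merged.loc[merged["te_class"] == classes[0], "abundance"].to_numpy()
    b = merged.loc[merged["te_class"] == classes[1], "abundance"].to_numpy()
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"a TE class is empty after masking: "
                         f"{classes[0]}={len(a)}, {classes[1]}={len(b)}")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return GroupComparison(classes[0], classes[1], len(a), len(b),
                           float(res.statistic), float(res.pvalue),
                           float(np.median(a)), float(np.median(b)))
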