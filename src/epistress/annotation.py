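"""Biotype context, metagene positions, and functional rollups for site calls.

Putative modification sites are placed into transcript context — 5'UTR, CDS,
3'UTR, ncRNA, or intergenic — and mapped onto a length-normalized metagene
axis (relative position within the segment, in [0, 1]) so that site
distributions can be compared across transcripts of different lengths.
Functional category tables (e.g. a KEGG hierarchy export) roll calls up into
per-category site and gene counts; rendering is left to the caller.

Coordinate conventions: GFF3 intervals are 1-based closed; BED is 0-based
half-open; everything internal is 1-based closed to match the GFF dialect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .detection import SiteCall

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentSpan",
    "TranscriptAnnotation",
    "AnnotatedSite",
    "load_annotation",
    "assign_biotype",
    "relative_position",
    "metagene_density",
    "functional_rollup",
]

#: label precedence when annotation intervals overlap
PRECEDENCE = ("CDS", "5'UTR", "3'UTR", "ncRNA", "intergenic")

_SEGMENT_LABELS = ("5'UTR", "CDS", "3'UTR")


@dataclass(frozen=True)
class SegmentSpan:
    """A 1-based closed interval within a transcript."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass
class TranscriptAnnotation:
    """Per-transcript biotype and UTR/CDS segmentation.

    ``segments`` maps transcript id to {label: SegmentSpan} for mRNAs;
    segments must be ordered 5'UTR < CDS < 3'UTR and non-overlapping.
    """

    lengths: dict[str, int]
    biotypes: dict[str, str]
    segments: dict[str, dict[str, SegmentSpan]]

    def __post_init__(self) -> None:
        for t, segs in self.segments.items():
            order = [segs[lbl] for lbl in _SEGMENT_LABELS if lbl in segs]
            for a, b in zip(order, order[1:]):
                if a.end >= b.start:
                    raise ValueError(
                        f"{t}: UTR/CDS segments overlap or are out of order")


_GFF_COLS = ["seqid", "source", "type", "start", "end",
             "score", "strand", "phase", "attributes"]

_GFF_TYPE_TO_LABEL = {"five_prime_UTR": "5'UTR", "CDS": "CDS",
                      "three_prime_UTR": "3'UTR"}


def load_annotation(gff3_path: str | Path,
                    utr_tsv: str | Path | None = None) -> TranscriptAnnotation:
    """Build a TranscriptAnnotation from a transcript-space GFF3.

    Transcript-level features (mRNA/rRNA/tRNA/ncRNA types) define lengths and
    biotypes; five_prime_UTR/CDS/three_prime_UTR features define segments.
    A UTR coordinate TSV (transcript, utr5_len, cds_len, utr3_len) can stand
    in for — or override — per-feature UTR rows.
    """
    df = pd.read_csv(gff3_path, sep="\t", comment="#", header=None,
                     names=_GFF_COLS)
    lengths: dict[str, int] = {}
    biotypes: dict[str, str] = {}
    segments: dict[str, dict[str, SegmentSpan]] = {}
    for row in df.itertuples(index=False):
        t = str(row.seqid)
        if row.type in ("mRNA", "rRNA", "tRNA", "ncRNA"):
            lengths[t] = int(row.end)
            biotypes[t] = str(row.type)
        elif row.type in _GFF_TYPE_TO_LABEL:
            segments.setdefault(t, {})[_GFF_TYPE_TO_LABEL[row.type]] = \
                SegmentSpan(int(row.start), int(row.end))
    if utr_tsv is not None:
        utr = pd.read_csv(utr_tsv, sep="\t")
        for r in utr.itertuples(index=False):
            t = str(r.transcript)
            u5, cds, u3 = int(r.utr5_len), int(r.cds_len), int(r.utr3_len)
            segs: dict[str, SegmentSpan] = {}
            if u5:
                segs["5'UTR"] = SegmentSpan(1, u5)
            segs["CDS"] = SegmentSpan(u5 + 1, u5 + cds)
            if u3:
                segs["3'UTR"] = SegmentSpan(u5 + cds + 1, u5 + cds + u3)
            segments[t] = segs
            lengths.setdefault(t, u5 + cds + u3)
            biotypes.setdefault(t, "mRNA")
    return TranscriptAnnotation(lengths, biotypes, segments)


@dataclass(frozen=True)
class AnnotatedSite:
    """A site call with biotype context and metagene coordinates."""

    transcript: str
    position: int
    delta: float
    label: str                      # 5'UTR | CDS | 3'UTR | ncRNA | intergenic
    relative_position: float | None  # within its segment, UTR/CDS only
    base: str | None = None          # A/C/G/U
    condition: str | None = None


def _label_position(t: str, pos: int, annotation: TranscriptAnnotation) -> str:
    biotype = annotation.biotypes.get(t)
    if biotype in ("ncRNA", "rRNA", "tRNA"):
        return "ncRNA"
    segs = annotation.segments.get(t, {})
    for label in PRECEDENCE[:3]:
        if label in segs and segs[label].contains(pos):
            return label
    if "ncRNA" in segs:  # constructed overlap case: ncRNA embedded in an mRNA record
        if segs["ncRNA"].contains(pos):
            return "ncRNA"
    return "intergenic"


def assign_biotype(
    calls: Iterable[SiteCall],
    annotation: TranscriptAnnotation,
    sequences: Mapping[str, str] | None = None,
    condition: str | None = None,
) -> list[AnnotatedSite]:
    """Give every call exactly one region label (precedence CDS > 5'UTR >
    3'UTR > ncRNA > intergenic) and, where applicable, its relative position.

    Calls outside the transcript bounds raise; unknown transcripts are
    labelled intergenic with a logged warning.
    """
    out = []
    for c in calls:
        L = annotation.lengths.get(c.transcript)
        if L is not None and not (1 <= c.position <= L):
            raise ValueError(
                f"call {c.transcript}:{c.position} lies outside the "
                f"transcript (length {L})")
        if L is None:
            logger.warning("transcript %s missing from annotation; "
                           "call labelled intergenic", c.transcript)
            label = "intergenic"
        else:
            label = _label_position(c.transcript, c.position, annotation)
        base = None
        if sequences is not None and c.transcript in sequences:
            base = sequences[c.transcript][c.position - 1].upper().replace("T", "U")
        site = AnnotatedSite(c.transcript, c.position, c.delta, label,
                             None, base, condition)
        rel = relative_position(site, annotation) if label in _SEGMENT_LABELS else None
        out.append(AnnotatedSite(c.transcript, c.position, c.delta, label,
                                 rel, base, condition))
    return out


def relative_position(site: AnnotatedSite,
                      annotation: TranscriptAnnotation) -> float | None:
    """(position − segment start + 1) / segment length, 1-based inclusive.

    Defined only for 5'UTR/CDS/3'UTR labels; zero-length segments yield None
    with a warning.
    """
    if site.label not in _SEGMENT_LABELS:
        raise ValueError(f"relative position undefined for label {site.label!r}")
    seg = annotation.segments[site.transcript][site.label]
    if seg.length <= 0:
        logger.warning("zero-length %s segment on %s; relative position masked",
                       site.label, site.transcript)
        return None
    return (site.position - seg.start + 1) / seg.length


def metagene_density(
    sites: Iterable[AnnotatedSite],
    bins: int = 50,
    base: str | None = None,
) -> pd.DataFrame:
    """Histogram of relative positions per (condition, segment[, base]).

    Each (condition, segment) group is normalized to unit area over [0, 1]
    (density values integrate to 1).  ``base`` restricts to sites with that
    nucleotide identity.
    """
    rows = [(s.condition or "", s.label, s.relative_position, s.base)
            for s in sites
            if s.relative_position is not None
            and (base is None or s.base == base)]
    df = pd.DataFrame(rows, columns=["condition", "segment", "rel", "base"])
    edges = np.linspace(0.0, 1.0, bins + 1)
    out = []
    for (cond, seg), g in df.groupby(["condition", "segment"], sort=True):
        hist, _ = np.histogram(g["rel"], bins=edges, density=True)
        centers = (edges[:-1] + edges[1:]) / 2
        for c, h in zip(centers, hist):
            out.append((cond, seg, float(c), float(h)))
    return pd.DataFrame(out, columns=["condition", "segment", "bin_center",
                                      "density"])


UNKNOWN_CATEGORY = "Function unknown"


def functional_rollup(
    sites: Iterable[AnnotatedSite | SiteCall],
    categories: Mapping[str, str] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-category counts of modified sites and distinct genes.

    ``categories`` maps gene/transcript id to a category label (or is a
    two-column DataFrame).  Genes absent from the table are counted under
    "Function unknown" with a logged notice.
    """
    if isinstance(categories, pd.DataFrame):
        cols = list(categories.columns[:2])
        categories = dict(zip(categories[cols[0]].astype(str),
                              categories[cols[1]].astype(str)))
    tally: dict[str, set[str]] = {}
    counts: dict[str, int] = {}
    missing = set()
    for s in sites:
        gene = s.transcript
        cat = categories.get(gene)
        if cat is None:
            cat = UNKNOWN_CATEGORY
            missing.add(gene)
        counts[cat] = counts.get(cat, 0) + 1
        tally.setdefault(cat, set()).add(gene)
    if missing:
        logger.info("%d genes missing from the category table; counted as %r",
                    len(missing), UNKNOWN_CATEGORY)
    rows = [(cat, counts[cat], len(tally[cat])) for cat in sorted(counts)]
    return pd.DataFrame(rows, columns=["category", "n_sites", "n_genes"])
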