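"""Putative modification-site detection from ΔBCError.

The detection logic compares a sample BCError profile against a control
(modification-free in vitro transcript, or a no-stress sample):

    ΔBCError(p)            = BCError_sample(p) - BCError_control(p)
    normalized ΔBCError(p) = ΔBCError(p) / BCError_control(p)

A classification threshold τ on ΔBCError is calibrated by sweeping a grid of
candidate thresholds and scoring precision/recall against a table of known
modification positions (the E. coli rRNA provides a dense, well-curated truth
set; a 36-site 16S+23S table ships with the package).  The calibrated — or a
user-imposed — τ then classifies unmasked positions as putative sites, which
can be intersected across biological replicates and with region calls from an
external signal-level detector to form a consensus call set.
"""

from __future__ import annotations

import importlib.resources
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiling import PileupProfile

__all__ = [
    "DeltaProfile",
    "ThresholdCalibration",
    "SiteCall",
    "delta_profile",
    "load_known_sites",
    "known_rrna_sites",
    "calibrate_threshold",
    "classify_sites",
    "consensus_sites",
    "motif_proximity_fraction",
    "load_bed_regions",
    "default_grid",
    "PAPER_TAU",
]

#: ΔBCError threshold adopted for mRNA/ncRNA site classification
PAPER_TAU = 0.02


@dataclass
class DeltaProfile:
    """Positionwise BCError difference between a sample and a control.

    ``mask`` is True wherever either input is masked (insufficient depth).
    ``normalized`` is additionally NaN where the control BCError is zero.
    Arrays are 0-based internally; tables are emitted 1-based.
    """

    transcript: str
    delta: np.ndarray
    normalized: np.ndarray
    mask: np.ndarray

    @property
    def length(self) -> int:
        return self.delta.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "transcript": self.transcript,
            "pos": np.arange(1, self.length + 1),
            "delta_bcerror": self.delta,
            "normalized_delta_bcerror": self.normalized,
            "masked": self.mask,
        })


def delta_profile(sample: PileupProfile, control: PileupProfile) -> DeltaProfile:
    """ΔBCError = sample − control, with joint masking.

    Raises on transcript length mismatch.  Antisymmetric by construction:
    ``delta_profile(a, b).delta == -delta_profile(b, a).delta`` positionwise.
    """
    if sample.length != control.length:
        raise ValueError(
            f"length mismatch for {sample.transcript!r}: "
            f"{sample.length} vs {control.length}"
        )
    b_s = sample.bcerror
    b_c = control.bcerror
    mask = sample.mask | control.mask
    delta = b_s - b_c
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized = np.where(b_c > 0, delta / np.where(b_c > 0, b_c, 1.0), np.nan)
    return DeltaProfile(sample.transcript, delta, normalized, mask)


# ---------------------------------------------------------------------------
# known modification sites


def load_known_sites(path: str | Path) -> pd.DataFrame:
    """Load a known-modification table (molecule, position [1-based], mod).

    (molecule, position) keys must be unique.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"molecule", "position", "mod"}
    if not required.issubset(df.columns):
        raise ValueError(f"known-site table must have columns {sorted(required)}")
    if df.duplicated(["molecule", "position"]).any():
        raise ValueError("duplicate (molecule, position) keys in known-site table")
    df["position"] = df["position"].astype(int)
    return df


def known_rrna_sites() -> pd.DataFrame:
    """The shipped curated table of E. coli 16S/23S rRNA modification sites."""
    ref = importlib.resources.files("epistress.data") / "known_rrna_mods.tsv"
    with importlib.resources.as_file(ref) as p:
        return load_known_sites(p)


# ---------------------------------------------------------------------------
# threshold calibration


@dataclass
class ThresholdCalibration:
    """Precision/recall sweep over a ΔBCError threshold grid.

    ``table`` has one row per grid value (tau, tp, fp, fn, precision, recall,
    f1); ``tau`` is the F1-maximizing threshold (smallest wins ties) unless an
    override was imposed; ``restriction`` records whether predictions were
    limited to externally called regions.
    """

    table: pd.DataFrame
    tau: float
    overridden: bool = False
    restriction: str = "all positions"

    def at(self, tau: float) -> pd.Series:
        i = (self.table["tau"] - tau).abs().idxmin()
        return self.table.loc[i]


def default_grid(stop: float = 0.2, step: float = 0.005) -> np.ndarray:
    """Ascending ΔBCError threshold grid, 0 to ``stop`` inclusive."""
    n = int(round(stop / step))
    return np.round(np.linspace(0.0, stop, n + 1), 10)


def load_bed_regions(path: str | Path) -> dict[str, list[tuple[int, int]]]:
    """BED (0-based half-open) → {transcript: [(start, end), ...]}."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    out: dict[str, list[tuple[int, int]]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.chrom), []).append((int(row.start), int(row.end)))
    return out


def _in_regions(transcript: str, pos1: int,
                regions: Mapping[str, Sequence[tuple[int, int]]]) -> bool:
    """1-based position against 0-based half-open intervals."""
    for start, end in regions.get(transcript, ()):
        if start <= pos1 - 1 < end:
            return True
    return False


def _predicted_positions(deltas: Mapping[str, DeltaProfile], tau: float,
                         regions=None) -> set[tuple[str, int]]:
    out: set[tuple[str, int]] = set()
    for t, d in deltas.items():
        ok = (~d.mask) & ~np.isnan(d.delta) & (d.delta >= tau)
        for i in np.nonzero(ok)[0]:
            pos1 = int(i) + 1
            if regions is not None and not _in_regions(t, pos1, regions):
                continue
            out.add((t, pos1))
    return out


def calibrate_threshold(
    deltas: Mapping[str, DeltaProfile],
    known: pd.DataFrame,
    grid: Sequence[float] | None = None,
    restriction_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
    tolerance: int = 0,
    tau_override: float | None = None,
) -> ThresholdCalibration:
    """Sweep thresholds and score against known sites.

    For each τ in the ascending grid, predicted positives are the unmasked
    positions with ΔBCError ≥ τ (optionally intersected with external region
    calls).  A prediction is a true positive when it matches a known site
    exactly, or within ``tolerance`` nt when a nonzero matching window is
    configured (modification-induced error halos can shift the error peak by
    a base or two).  Recall is counted over known sites on transcripts that
    are present and not entirely masked.  The chosen τ maximizes F1; ties go
    to the smallest (most sensitive) τ.  ``tau_override`` pins the working
    threshold without changing the sweep.
    """
    if known.empty:
        raise ValueError("known-site table is empty")
    if not (0 <= tolerance <= 2):
        raise ValueError("tolerance must be 0, 1, or 2 nt")
    covered = {t for t, d in deltas.items() if not np.all(d.mask)}
    if not covered:
        raise ValueError("all positions masked in every delta profile")
    known_sites = {
        (str(r.molecule), int(r.position))
        for r in known.itertuples(index=False)
        if str(r.molecule) in covered
    }
    if not known_sites:
        raise ValueError("no known site lies on a covered transcript")
    grid = default_grid() if grid is None else np.asarray(sorted(grid), dtype=float)

    rows = []
    for tau in grid:
        pred = _predicted_positions(deltas, float(tau), restriction_regions)
        if tolerance == 0:
            tp_pred = pred & known_sites
            matched_known = tp_pred
        else:
            tp_pred = {
                (t, p) for (t, p) in pred
                if any((t, p + o) in known_sites for o in range(-tolerance, tolerance + 1))
            }
            matched_known = {
                (t, k) for (t, k) in known_sites
                if any((t, k + o) in pred for o in range(-tolerance, tolerance + 1))
            }
        tp = len(tp_pred)
        fp = len(pred) - tp
        fn = len(known_sites) - len(matched_known)
        precision = tp / (tp + fp) if (tp + fp) else np.nan
        recall = len(matched_known) / len(known_sites)
        f1 = (2 * precision * recall / (precision + recall)
              if (tp + fp) and (precision + recall) > 0 else 0.0)
        rows.append((float(tau), tp, fp, fn, precision, recall, f1))
    table = pd.DataFrame(rows, columns=["tau", "tp", "fp", "fn",
                                        "precision", "recall", "f1"])
    if tau_override is not None:
        chosen, overridden = float(tau_override), True
    else:
        best = table["f1"].fillna(0.0)
        chosen = float(table.loc[best.idxmax(), "tau"])  # idxmax → first (smallest τ)
        overridden = False
    return ThresholdCalibration(
        table=table, tau=chosen, overridden=overridden,
        restriction="external regions only" if restriction_regions is not None
        else "all positions",
    )


# ---------------------------------------------------------------------------
# site classification and consensus


@dataclass(frozen=True)
class SiteCall:
    """A putative modification site: ΔBCError ≥ τ at an unmasked position."""

    transcript: str
    position: int  # 1-based
    delta: float
    supported_by: frozenset[str] = field(default_factory=frozenset)

    @property
    def key(self) -> tuple[str, int]:
        return (self.transcript, self.position)


def classify_sites(deltas: Mapping[str, DeltaProfile], tau: float,
                   label: str | None = None) -> list[SiteCall]:
    """All unmasked positions with ΔBCError ≥ τ, as site calls."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    support = frozenset([label]) if label else frozenset()
    calls = []
    for t, d in deltas.items():
        ok = (~d.mask) & ~np.isnan(d.delta) & (d.delta >= tau)
        for i in np.nonzero(ok)[0]:
            calls.append(SiteCall(t, int(i) + 1, float(d.delta[i]), support))
    return calls


def consensus_sites(
    calls_by_replicate: Mapping[str, Iterable[SiteCall]],
    external_regions: Mapping[str, Sequence[tuple[int, int]]] | None = None,
) -> list[SiteCall]:
    """Sites supported in every biological replicate (and external regions).

    A call survives only if the same (transcript, position) is called in all
    replicates; when external region calls are supplied, it must additionally
    fall inside at least one region.  ``supported_by`` accumulates the
    replicate labels (plus ``"region"`` when region support applies).
    """
    if not calls_by_replicate:
        raise ValueError("need at least one replicate of calls")
    per_rep = {rep: {c.key: c for c in calls} for rep, calls in calls_by_replicate.items()}
    shared = set.intersection(*(set(d) for d in per_rep.values()))
    out = []
    for key in sorted(shared):
        t, pos = key
        if external_regions is not None and not _in_regions(t, pos, external_regions):
            continue
        support = set(per_rep)
        if external_regions is not None:
            support.add("region")
        deltas = [per_rep[rep][key].delta for rep in per_rep]
        out.append(SiteCall(t, pos, float(np.mean(deltas)), frozenset(support)))
    return out


# ---------------------------------------------------------------------------
# motif proximity

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}


def _motif_regex(motif: str) -> re.Pattern[str]:
    try:
        return re.compile("".join(_IUPAC[ch] for ch in motif.upper()))
    except KeyError as e:
        raise ValueError(f"invalid IUPAC code {e.args[0]!r} in motif {motif!r}") from None


def motif_proximity_fraction(
    calls: Iterable[SiteCall],
    sequences: Mapping[str, str],
    motifs: Sequence[str],
    window: int = 4,
) -> float:
    """Fraction of calls with a sequence motif within ±``window`` nt.

    Motifs are matched on the sense strand in the RNA alphabet (U and T are
    interchangeable; IUPAC ambiguity codes allowed).  A call counts when the
    neighborhood [pos − window, pos + window] overlaps ≥ 1 motif occurrence.
    """
    if not motifs:
        raise ValueError("motif list is empty")
    calls = list(calls)
    if not calls:
        return 0.0
    patterns = [_motif_regex(m) for m in motifs]
    # precompute motif occurrence spans per transcript actually queried
    spans: dict[str, list[tuple[int, int]]] = {}
    for t in {c.transcript for c in calls}:
        seq = sequences[t].upper().replace("U", "T")
        occ = []
        for pat in patterns:
            for m in pat.finditer(seq):
                occ.append((m.start(), m.end()))  # 0-based half-open
        spans[t] = occ
    hit = 0
    for c in calls:
        lo = c.position - 1 - window
        hi = c.position - 1 + window + 1
        if any(s < hi and lo < e for s, e in spans[c.transcript]):
            hit += 1
    return hit / len(calls)
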