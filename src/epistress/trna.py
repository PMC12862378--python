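"""Anticodon-resolved differential modification and pre-tRNA maturation.

Wobble-position (nucleotide 34) and anticodon-loop modifications respond to
stress; this module quantifies that response from BCError profiles and links
it to pre-tRNA processing state inferred from read lengths:

* per-tRNA, per-position ΔBCError matrices over the anticodon loop, averaged
  across biological replicates, with a ≥ 5-read depth gate;
* a stress-responsiveness call per tRNA (|Δ| above a cutoff with consistent
  sign in every replicate);
* read-length densities over 0-500 nt in which each tRNA, replicate, and
  condition is weighted equally, so abundant species do not dominate;
* a maturity metric, log2 of the mean read length ratio between conditions
  (longer reads = earlier processing stage);
* a normality-gated correlation between maturity and cumulative anticodon
  ΔBCError: Pearson when both variables pass a Shapiro-Wilk test at
  alpha = 0.05, Spearman otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .profiling import PileupProfile

logger = logging.getLogger(__name__)

__all__ = [
    "TRNAMeta",
    "AnticodonDeltaResult",
    "CorrelationResult",
    "load_trna_meta",
    "anticodon_delta_matrix",
    "classify_stress_responsive",
    "anticodon_totals",
    "length_distributions",
    "maturity_metric",
    "correlate_with_normality_gate",
    "maturity_modification_correlation",
]

#: canonical anticodon positions (wobble = 34) and loop span, as offsets
ANTICODON_SPAN = 3
DEFAULT_LOOP = (-2, 4)  # anticodon_start + offsets -> canonical 32..38
MIN_READS = 5
ALPHA = 0.05


@dataclass(frozen=True)
class TRNAMeta:
    """Anticodon placement and modification pathway for one tRNA.

    ``anticodon_start`` is 1-based in mature-sequence coordinates (canonical
    position 34, the wobble base).  Coordinates always come from reference
    metadata rather than canonical-numbering inference, because pre-tRNA
    reads carry leaders and trailers.
    """

    trna: str
    anticodon_start: int
    pathway: str = "other"  # Q | Mnm | cmo5U | other

    def loop_positions(self, loop: tuple[int, int] = DEFAULT_LOOP) -> list[int]:
        return [self.anticodon_start + o for o in range(loop[0], loop[1] + 1)]

    def anticodon_positions(self) -> list[int]:
        return [self.anticodon_start + o for o in range(ANTICODON_SPAN)]


def load_trna_meta(path) -> dict[str, TRNAMeta]:
    df = pd.read_csv(path, sep="\t")
    out = {}
    for r in df.itertuples(index=False):
        out[str(r.trna)] = TRNAMeta(str(r.trna), int(r.anticodon_start),
                                    str(getattr(r, "pathway", "other")))
    return out


@dataclass
class AnticodonDeltaResult:
    """Replicate-averaged and per-replicate loop Δ matrices.

    ``mean`` and each per-replicate frame are indexed by tRNA with one column
    per loop offset (canonical positions 32-38 by default); ``excluded``
    lists tRNAs that failed the depth gate at any loop position.
    """

    mean: pd.DataFrame
    per_replicate: list[pd.DataFrame] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)
    loop: tuple[int, int] = DEFAULT_LOOP


def _loop_delta(stress: PileupProfile, control: PileupProfile,
                meta: TRNAMeta, loop: tuple[int, int]) -> np.ndarray | None:
    """Δ over the loop for one replicate pair, or None if depth fails."""
    positions = meta.loop_positions(loop)
    idx = np.array(positions) - 1
    if idx.min() < 0 or idx.max() >= stress.length:
        return None
    if stress.mask[idx].any() or control.mask[idx].any():
        return None
    return stress.bcerror[idx] - control.bcerror[idx]


def anticodon_delta_matrix(
    stress_profiles: Sequence[Mapping[str, PileupProfile]],
    control_profiles: Sequence[Mapping[str, PileupProfile]],
    meta: Mapping[str, TRNAMeta],
    loop: tuple[int, int] = DEFAULT_LOOP,
) -> AnticodonDeltaResult:
    """Per-tRNA, per-loop-position ΔBCError, averaged across replicates.

    ``stress_profiles[i]`` and ``control_profiles[i]`` are replicate-paired
    {tRNA: profile} maps.  tRNAs with < 5 reads at any loop position in any
    replicate are excluded and listed.  Raises when a profiled tRNA has no
    metadata entry.
    """
    if len(stress_profiles) != len(control_profiles) or not stress_profiles:
        raise ValueError("need equal, non-zero numbers of replicate profile maps")
    trnas = sorted(set().union(*[set(p) for p in stress_profiles]))
    for t in trnas:
        if t not in meta:
            raise KeyError(f"no anticodon metadata for profiled tRNA {t!r}")
    offsets = list(range(loop[0], loop[1] + 1))
    cols = [f"pos{34 + o}" for o in offsets]

    per_rep_rows: list[dict[str, np.ndarray]] = [dict() for _ in stress_profiles]
    excluded = []
    for t in trnas:
        deltas = []
        for i, (sp, cp) in enumerate(zip(stress_profiles, control_profiles)):
            if t not in sp or t not in cp:
                deltas = None
                break
            d = _loop_delta(sp[t], cp[t], meta[t], loop)
            if d is None:
                deltas = None
                break
            deltas.append(d)
        if deltas is None:
            excluded.append(t)
            continue
        for i, d in enumerate(deltas):
            per_rep_rows[i][t] = d
    kept = [t for t in trnas if t not in set(excluded)]
    per_replicate = [
        pd.DataFrame.from_dict(rows, orient="index", columns=cols).loc[kept]
        if kept else pd.DataFrame(columns=cols)
        for rows in per_rep_rows
    ]
    mean = (sum(per_replicate) / len(per_replicate)) if kept else pd.DataFrame(columns=cols)
    if excluded:
        logger.info("excluded %d tRNAs failing the %d-read depth gate: %s",
                    len(excluded), MIN_READS, ", ".join(excluded))
    return AnticodonDeltaResult(mean=mean, per_replicate=per_replicate,
                                excluded=excluded, loop=loop)


def classify_stress_responsive(
    result: AnticodonDeltaResult,
    cutoff: float = 0.1,
) -> pd.DataFrame:
    """Flag tRNAs whose loop Δ passes the magnitude + sign-consistency rule.

    Responsive iff the replicate-averaged |Δ| at its maximizing loop position
    is ≥ ``cutoff`` and every replicate agrees in sign (non-zero) there.
    ``direction`` is +1 (modification gain under stress), −1 (loss), or 0.
    """
    rows = []
    for t in result.mean.index:
        vals = result.mean.loc[t].to_numpy(dtype=float)
        j = int(np.nanargmax(np.abs(vals)))
        peak = vals[j]
        rep_vals = np.array([rep.loc[t].iloc[j] for rep in result.per_replicate])
        consistent = np.all(rep_vals > 0) or np.all(rep_vals < 0)
        responsive = bool(abs(peak) >= cutoff and consistent)
        rows.append((t, responsive,
                     int(np.sign(peak)) if responsive else 0,
                     float(peak), result.mean.columns[j]))
    return pd.DataFrame(rows, columns=["trna", "responsive", "direction",
                                       "peak_delta", "peak_position"]).set_index("trna")


def anticodon_totals(result: AnticodonDeltaResult,
                     meta: Mapping[str, TRNAMeta],
                     span: str = "anticodon") -> pd.Series:
    """Cumulative ΔBCError per tRNA: sum over the anticodon (34-36, default)
    or the whole loop (``span="loop"``)."""
    if span == "loop":
        cols = list(result.mean.columns)
    elif span == "anticodon":
        cols = [c for c in result.mean.columns
                if 34 <= int(c.removeprefix("pos")) <= 36]
    else:
        raise ValueError("span must be 'anticodon' or 'loop'")
    return result.mean[cols].sum(axis=1)


# ---------------------------------------------------------------------------
# read-length distributions and maturity


def length_distributions(
    lengths: pd.DataFrame,
    groups: Mapping[str, str],
    bin_width: int = 10,
    max_length: int = 500,
) -> pd.DataFrame:
    """Equal-weighted read-length densities per (group, condition).

    A unit-area histogram over 0-``max_length`` nt (reads beyond the limit
    clipped into the last bin) is computed per (tRNA, replicate, condition)
    and then averaged with equal weights within each (group, condition), so
    a tRNA with 10 reads counts exactly as much as one with 1000.  Empty
    groups are omitted with a warning.
    """
    edges = np.arange(0, max_length + bin_width, bin_width, dtype=float)
    df = lengths.copy()
    df["group"] = df["transcript"].map(groups)
    df = df.dropna(subset=["group"])
    out = []
    for (grp, cond), g in df.groupby(["group", "condition"], sort=True):
        densities = []
        for _, sub in g.groupby(["transcript", "replicate"], sort=False):
            vals = np.clip(sub["length"].to_numpy(dtype=float), 0, max_length - 1e-9)
            hist, _ = np.histogram(vals, bins=edges, density=True)
            densities.append(hist)
        if not densities:
            logger.warning("empty length group (%s, %s); omitted", grp, cond)
            continue
        mean_density = np.mean(densities, axis=0)
        centers = (edges[:-1] + edges[1:]) / 2
        out.extend((grp, cond, float(c), float(h))
                   for c, h in zip(centers, mean_density))
    return pd.DataFrame(out, columns=["group", "condition", "bin_center", "density"])


def maturity_metric(
    lengths: pd.DataFrame,
    condition_pair: tuple[str, str],
    min_reads: int = MIN_READS,
) -> pd.DataFrame:
    """log2 mean-read-length ratio (stress over control) per tRNA.

    Longer average reads under stress mean a shift toward earlier processing
    stages.  tRNAs with fewer than ``min_reads`` reads in either condition
    are excluded.
    """
    stress, control = condition_pair
    rows = []
    for t, g in lengths.groupby("transcript", sort=True):
        ls = g.loc[g["condition"] == stress, "length"]
        lc = g.loc[g["condition"] == control, "length"]
        if len(ls) < min_reads or len(lc) < min_reads:
            continue
        rows.append((t, float(ls.mean()), float(lc.mean()),
                     float(np.log2(ls.mean() / lc.mean()))))
    return pd.DataFrame(rows, columns=["trna", "mean_length_stress",
                                       "mean_length_control", "log2_ratio"]
                        ).set_index("trna")


# ---------------------------------------------------------------------------
# normality-gated correlation


@dataclass(frozen=True)
class CorrelationResult:
    """Correlation with the Shapiro-Wilk gate that selected the method."""

    method: str          # "pearson" | "spearman"
    statistic: float
    pvalue: float
    shapiro_w: tuple[float, float]
    shapiro_p: tuple[float, float]
    n: int


def correlate_with_normality_gate(x: Sequence[float], y: Sequence[float],
                                  alpha: float = ALPHA) -> CorrelationResult:
    """Pearson r if both variables pass Shapiro-Wilk at ``alpha``, else
    Spearman ρ; two-sided p-values throughout.  Requires ≥ 4 pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired")
    if x.size < 4:
        raise ValueError(f"need >= 4 paired observations, got {x.size}")
    swx = stats.shapiro(x)
    swy = stats.shapiro(y)
    normal = swx.pvalue > alpha and swy.pvalue > alpha
    if normal:
        r = stats.pearsonr(x, y)
        method, statistic, pvalue = "pearson", float(r.statistic), float(r.pvalue)
    else:
        r = stats.spearmanr(x, y)
        method, statistic, pvalue = "spearman", float(r.statistic), float(r.pvalue)
    return CorrelationResult(method, statistic, pvalue,
                             (float(swx.statistic), float(swy.statistic)),
                             (float(swx.pvalue), float(swy.pvalue)), int(x.size))


def maturity_modification_correlation(
    maturity: pd.DataFrame,
    totals: pd.Series,
    subset: Iterable[str] | None = None,
) -> CorrelationResult:
    """Correlate the maturity metric with cumulative anticodon ΔBCError.

    ``maturity`` comes from :func:`maturity_metric`; ``totals`` from
    :func:`anticodon_totals`.  ``subset`` restricts to e.g. the
    stress-responsive tRNAs.  The method (Pearson vs Spearman) is chosen by
    the Shapiro-Wilk gate at alpha = 0.05.
    """
    common = maturity.index.intersection(totals.index)
    if subset is not None:
        common = common.intersection(pd.Index(list(subset)))
    x = maturity.loc[common, "log2_ratio"].to_numpy()
    y = totals.loc[common].to_numpy()
    return correlate_with_normality_gate(x, y)
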