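# Methods

## Error model and BCError estimation

A modification at transcript position *p* with stoichiometry *s* (the
fraction of molecules carrying it) is modelled at the molecule level: each
read's template is drawn modified with probability *s*, and basecalling
errors are then injected per position with probability `e_base` on
unmodified templates and `e_base + delta_mod` on modified ones. Marginally
the per-read error indicator at a site is Bernoulli(`e_base + s·delta_mod`),
which makes the IVT-subtracted ΔBCError divided by `delta_mod` an unbiased
estimator of *s*. Error events are typed
mismatch : deletion : insertion = 0.6 : 0.3 : 0.1 by default (configurable);
the mix exercises all three error channels that the profiler must attribute.

BCError counting follows fixed attribution rules: a substitution is charged
to its position, a deletion to every position it spans, an insertion to the
position immediately 5′ of its opening point (insertions before the first
aligned base are discarded); a read contributes at most one error per
position, bounding BCError in [0, 1]; soft clips contribute neither
coverage nor error; coverage counts reads spanning the position with M, X,
=, or D operations. Reverse-strand alignments are dropped with a warning —
DRS reads are sense-strand in transcript space. Coordinates are 0-based
half-open internally and 1-based in all emitted tables, matching rRNA
community position names such as m4Cm1402. Replicates are pooled by summing
coverage and error counts and recomputing the proportion (count pooling,
never averaging of proportions).

Read-level filters: primary, mapped reads with mean Phred quality strictly
above the threshold (9 for mRNA-enriched libraries, 5 for tRNA libraries).
The mean is the arithmetic mean of per-base scores; the simulator emits
constant-quality reads, so the averaging rule does not interact with the
synthetic benchmarks.

## Threshold calibration

For each τ in an ascending grid (default 0 to 0.2, step 0.005), predicted
positives are the unmasked positions with ΔBCError ≥ τ, optionally
restricted to externally called regions (both restriction modes are
offered because per-position and per-region evaluation are both defensible
readings of a region-level external detector). True positives match a
known site exactly by default; a 0–2 nt tolerance window is available
because modification-induced error halos can displace the error peak.
The chosen τ maximizes F1, with ties going to the smallest (most
sensitive) value; a documented override (e.g. the conventional 0.02) pins
the working threshold without changing the sweep. Precision is undefined
(NaN) when nothing is predicted; F1 is then 0.

The shipped known-site table is curated from the published *E. coli* K-12
rRNA modification literature: 11 sites on the 16S and 25 on the 23S
(36 total), with standard short names (Y = pseudouridine, D =
dihydrouridine). Consensus calls require the same transcript/position in
every biological replicate and, when region calls are supplied, overlap
with at least one region. Motif proximity is evaluated on the sense strand
in the RNA alphabet with IUPAC codes, counting calls whose ±4 nt
neighborhood (configurable) overlaps a motif occurrence; motifs are a
required user input.

## Annotation

Biotype labels follow the precedence CDS > 5′UTR > 3′UTR > ncRNA >
intergenic when intervals overlap (the precedence order is this module's
choice; no external convention exists for transcript-space overlaps).
Relative position within a segment is (pos − start + 1) / length, 1-based
inclusive, so the first base of a 99-nt CDS maps to 1/99 and the last base
of a 3′UTR to 1.0. Metagene histograms use 50 bins by default and are
normalized to unit area per (condition, segment). GFF3 is treated as
1-based closed, BED as 0-based half-open.

## tRNA analysis

Anticodon coordinates come from reference metadata (the wobble base is the
`anticodon_start`, canonical position 34), never from canonical-numbering
inference, because pre-tRNA reads carry leaders and trailers. Loop Δ
matrices cover canonical positions 32–38 and are averaged across replicate
pairs; tRNAs with fewer than 5 reads at any loop position are excluded and
listed. Cumulative anticodon ΔBCError sums positions 34–36 by default (a
loop option sums 32–38). A tRNA is stress-responsive when its
replicate-averaged |Δ| at the maximizing loop position reaches the cutoff
(default 0.1) with the same sign in every replicate — a magnitude-plus-
consistency rule chosen because published responsive sets are described
qualitatively.

Read-length densities (0–500 nt, reads beyond clipped into the last bin)
are computed per (tRNA, replicate, condition) with unit area and then
averaged with equal weights within each group, so species abundance does
not dominate the distribution. The maturity metric is log2 of the ratio of
mean read lengths between conditions — symmetric and scale-free, preferred
over a difference because tRNA lengths span a fourfold range. The
maturity–modification correlation applies a Shapiro–Wilk gate at α = 0.05
per variable: Pearson when both pass, Spearman otherwise; at least four
pairs are required.

## Codon usage

The nine default codon sets are the standard wobble-decoding assignments:
Q-pathway pairs for Asn/Asp/His/Tyr with the U-ending codon
modification-dependent, and Mnm-pathway pairs for Arg/Gln/Glu/Gly/Leu with
the G-ending codon dependent. The table is validated against the standard
genetic code (synonymy, third-position-only difference, 18 distinct
non-stop codons) and can be replaced from a TSV, since published set
definitions vary at the margins. The scan is purely positional and
in-frame; codons containing ambiguity characters are skipped, premature
stops count as ordinary codons. Abundance is masked (not zero) when a CDS
contains none of the 18 codons. Ranking includes every transcript tied
with the boundary score, so a nominal top/bottom-400 can return more than
400. The TE comparison uses the two-sided Mann–Whitney *U* with midrank
tie handling (exact null for small tie-free samples).

## Synthetic data generator

The generator fabricates the full study design: two biological replicates
per non-IVT condition plus an IVT condition whose stoichiometry is exactly
zero; 16S/23S-length rRNAs carrying the curated known sites; mRNAs with
UTR/CDS structure (ATG…stop, CDS length a multiple of 3); tRNAs with
mature sequence plus leader/trailer metadata; and coordinate-sorted,
indexed BAMs with per-read constant quality strings so the Q filters can
be exercised. One master seed drives everything through named sub-streams
per (condition, replicate), so adding a replicate never perturbs existing
outputs and identical configurations are byte-identical. A deletion drawn
at a read's first or last reference position is emitted as a mismatch
instead (a CIGAR cannot begin or end with D); this touches only the two
boundary positions and the moment tests therefore evaluate interior
positions. A direct pileup simulator (Binomial counts at
`e_base + s·delta_mod`, the exact marginal law of the read-level model) is
provided for analyses where only counts matter.

Default conditions, chosen once as realistic for a bacterial DRS
experiment and frozen: baseline error 0.03 and modification boost 0.25
(typical of DRS at modified bases), coverage as configured per analysis,
site stoichiometries uniform on 0.2–0.9 for rRNA/mRNA sites and 0.6–0.9
for tRNA wobble sites (anticodon wobble modifications are near-
stoichiometric in vivo), a +0.3 wobble stoichiometry shift under stress by
default, mature pre-tRNA reads at 70–100 nt and immature reads at
100–500 nt with a per-tRNA immature fraction uniform on 0.1–0.6, 200 reads
per tRNA, and an immaturity factor of 0.3 damping the anticodon
modification probability of immature reads (pre-tRNAs acquire anticodon
modifications late in processing).

What the generator does not emulate — and what passing tests therefore do
not show about real data: no raw signal or basecaller behaviour, no
sequence-context-dependent error spectra (real DRS errors cluster in
5-mers around the modified base rather than at the single site), no error
halos at neighbouring positions, no coverage decay along transcripts from
truncated reads, and no between-replicate biological variability beyond
sampling noise. Calibration results on synthetic rRNA are therefore a
verification of the statistical machinery at known truth, not a claim
about detection power on any particular organism or flow cell.

## Problem sizes and numerical choices

The validation analyses run at desk scale: calibration uses 16S+23S at
coverage 500 (two replicates pooled against one IVT sample);
stoichiometry recovery uses 124 sites at coverage 1000; the maturation
coupling analysis uses 30 tRNAs × 200 reads with 100 seeded replicates for
the detection-rate and type-I estimates; the Mann–Whitney enumeration
check covers all group sizes up to 8. Degenerate inputs fail loudly:
length mismatches, empty known-site tables, all-masked profiles, empty TE
classes, and sub-minimum correlation samples all raise with specific
messages rather than returning silent defaults.
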