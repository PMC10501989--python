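# Methods

## Screen hit-calling model

The unit of evidence is the guide-level log2 fold change between the
two sorted bins. Counts are normalized by total bin depth with a
pseudocount added to both the numerator count and (scaled by the number
of guides) the denominator library size, so that doubling sequencing
depth — with the pseudocount scaled accordingly — leaves every fold
change unchanged and zero counts stay finite:

    log2FC = log2[(c_neg + pc)/(N_neg + pc·G)] − log2[(c_pos + pc)/(N_pos + pc·G)]

The orientation (reporter-negative over reporter-positive) is chosen so
that knocking out a positive regulator of the reporter gives a positive
fold change: those knockouts cannot switch the reporter on and
accumulate in the negative bin.

Gene-level inference compares a gene's guide fold changes against the
non-targeting (NT) guides that survive the same count filter, with a
two-sided Wilcoxon rank-sum test. The NT guides, not a theoretical
null, are the reference population: they absorb whatever global
distortions the infection, sorting and sequencing introduce.

### Exact rank-sum test

`EXACT` mode computes the permutation null of the rank sum over all
C(n+m, n) assignments, with midranks for ties. Rather than literal
enumeration, the null distribution is built by a generating-function
recurrence over the doubled midranks (doubling makes them integers):
`dist[j, s]` counts j-subsets of the pooled ranks summing to s. This is
algebraically identical to enumeration but polynomial-time, so the
exact test remains practical at, say, 4 guides against 100 NT
references, where C(104, 4) ≈ 4.6 million. The two-sided p doubles the
smaller tail (observed value included in both tails) and is capped at
1; a completely tied pooled sample returns p = 1. `NORMAL_APPROX`
delegates to the tie-corrected, continuity-corrected normal
approximation (scipy's asymptotic Mann–Whitney U). `AUTO` uses the
exact null while C(n+m, n) ≤ 1e5.

### Replicate combination

Per gene, enrichment scores (mean guide log2FC) are averaged across the
screens in which the gene was testable, and the per-screen p-values are
combined by Fisher's method, X = −2Σ ln pᵢ ~ χ²(2k). p-values are
floored at 1e−300 before the log so X stays finite. Direction is the
sign of the mean enrichment. Output ordering is fully deterministic:
combined p ascending, then |mean enrichment| descending, then gene
name. BH q-values are reported as an extra column but never drive the
ranking, mirroring the convention of ranking by unadjusted combined p.

### Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `count_threshold` | 20 | guide dropped per screen if below this in either bin; 20 suits genome-wide depth, 50 focused screens |
| `pseudocount` | 1.0 | count regularizer; 1 read is the natural unit |
| `min_guides` | 2 | a 1-guide gene has no within-gene evidence; it is recorded as untestable |
| `alpha` | 0.05 | hit-calling level on the combined p |
| `mode` | AUTO | exact permutation null when it has ≤ 1e5 assignments |

### Calibration caveat

All gene tests within a screen share the same NT reference sample, so
the ~500 gene-level p-values are weakly positively dependent: an
atypical NT draw shifts them coherently. Simulation shows the
Kolmogorov–Smirnov statistic of null combined p-values against
Uniform(0,1) exceeds the *iid* 1% critical value in roughly 15% of
generator seeds with the exact test (and 0% when each gene gets a fresh
reference). This is a property of the reference-population design
itself, not of the implementation; the calibration test therefore runs
at a fixed seed, and marginal error rates (fraction of genes below
0.05) remain nominal. With only 4 guides per gene the normal
approximation is additionally discrete/conservative in the tails that
Fisher's method amplifies, which is why calibration checks use the
exact mode.

## Guide quantification

Protospacers are extracted by anchoring on the leftmost match of the 5'
backbone adapter (`GACGAAACACCG`) within a Hamming budget (default 1
mismatch) and taking the following 20 bases; the 3' adapter
(`GTTTTAGAGCTA`) is expected immediately after but its absence does not
move the window. Reads without an anchor or with fewer than 20
remaining bases are tallied as unextracted. Assignment is dictionary
lookup: exact match wins; with a mismatch budget, a protospacer maps to
the unique library sequence within that Hamming distance, ties
unassigned. Alignment-free matching is sufficient because the library
is a known dictionary of 20-mers; the generator further guarantees
pairwise Hamming distance ≥ 3 so 1-mismatch assignment is unambiguous.

Library QC reports the fraction of perfectly matching reads, the
fraction of undetected guides, and a skew ratio defined as the 90th
over the 10th nearest-rank percentile of guide counts (a common
library-QC convention; the ratio is flagged as undefined when the 10th
percentile is zero). Nearest-rank percentiles keep the statistic exact
on integer counts and platform-independent.

## Interval arithmetic

Peaks use BED semantics (0-based half-open) throughout. Gene TSS/TTS
are single base coordinates (TSS > TTS on the minus strand); promoter
(±1 kb of TSS, strand-oriented) and downstream (1 kb past TTS) windows
are *inclusive base ranges*, which makes every annotation rule exactly
symmetric under genome mirroring — reversing coordinates and strands
maps PROMOTER peaks to PROMOTER peaks and DOWNSTREAM to DOWNSTREAM.

Annotation priority is fixed: PROMOTER > EXON > INTRON > DOWNSTREAM >
INTERGENIC, so each peak gets exactly one category and the counts
partition the peak set. Replicate reconciliation keeps intervals of
replicate 1 overlapping some interval of replicate 2 by ≥
`min_overlap_bp` (default 1) and merges; a symmetric variant unions
both directions. Closest-gene distance is measured to the gene span,
with adjacent features 1 bp apart (the bedtools-closest convention),
signed positive when the peak lies 3' of the gene; ties go to the
lexicographically smaller gene id. k-set overlap counts are anchored on
the first set of each label subset (peaks of set A also overlapped by B
and C), which matches how factor co-occupancy percentages are usually
quoted. Metaprofiles average per-peak binned signal over windows
centered on peak midpoints (or over the rescaled peak body with
half-width flank bins); bins are equal integer partitions of the
window's bases, windows reaching before base 0 are clipped and
contribute zeros with a warning.

## Motif scanning and enrichment

A JASPAR-style frequency matrix becomes a log2-odds PWM against a
0-order background with pseudocount smoothing:
`entry(b, j) = log2(((count + pc·bg_b)/colsum) / bg_b)`. Scores are
rescaled to [0, 1] between the matrix's worst and best attainable
scores; the default hit threshold is a relative score of 0.80, always
reported in outputs so results are self-describing (no cutoff is baked
in). Both strands are scanned, reverse-strand windows scored on their
reverse complement and reported at forward coordinates; windows with
non-ACGT characters are skipped. Enrichment counts *sequences with at
least one hit* (presence/absence, not hit counts) and computes the
one-sided cumulative binomial tail with the background rate estimated
from the background sequence set, clamped to
[1/(2·n_bg), 1 − 1/(2·n_bg)] to avoid degenerate p = 0/1 when the
background shows no (or only) hits.

## Synthetic data

`simulate_screen` emulates the sorted-bin screen: per-guide library
representation is lognormal (σ = 0.5, a typical synthesis skew giving a
90/10 skew ratio well under 10); true-regulator guides multiply their
reporter-negative : positive abundance ratio by 2^effect with per-guide
lognormal jitter (σ = 0.3 in log2 units) around the gene effect;
NT and non-regulator guides are exactly null by construction. Counts
are gamma-Poisson (negative binomial) at the configured depth
(default 500 reads/guide/bin, dispersion 0.15 — moderate overdispersion
typical of pooled amplicon sequencing); dispersion 0 degrades to
Poisson for analytic checks. Default effect −1.5 log2 units in 5% of
500 genes, 4 guides/gene, 100 NT guides, 2 screen replicates. Guide
representation and realized guide effects are shared across screens
(same physical library and biology); count noise is drawn
independently per screen and bin. Reads for the FASTQ path are emitted
as adapter + protospacer + adapter with a configurable adapter error
rate.

What the generator does **not** emulate: read-level base-call errors
inside the protospacer, PCR jackpotting beyond the gamma mixture,
guide-efficiency heterogeneity correlated with chromatin context,
cell-cycle or fitness effects that deplete guides from *both* bins, and
sorting impurity. Passing tests therefore demonstrate the statistics
behave correctly under a faithful abstraction of the design, not that
any particular biological dataset will reach the same power.

`simulate_genome` draws uniform-random chromosome sequence,
non-overlapping gene models with exon blocks, and peak sets placed with
a clearance margin so that *undesigned* overlaps are zero. The pairwise
overlap design is honored for (i, j) with i < j — the target fraction
of the earlier set i's peaks overlapped by set j — by co-locating peaks
of set j on sampled peaks of set i; simultaneous arbitrary constraint
systems (e.g. exact triple-overlap fractions) are out of scope, and
infeasible designs raise. The signal track is a uniform floor plus a
triangular bump over each peak of the first set, quantized to 10-bp
plateaus to keep emitted bedGraphs compact. Motif consensus sequences
are written at peak centers in the stated fraction of each set's
peaks; chance occurrences elsewhere in the random genome form a
realistic background.

Everything is deterministic given the seed: identical configs and seeds
yield byte-identical emitted files.

## Problem sizes

The test suite and acceptance script run at desk scale by design: null
calibration at 500 genes × 4 guides × 2 screens, recovery over 20
seeded runs at the same size, interval oracles on 100 randomized ~6 kb
genomes, motif checks on 50 + 50 sequences of 120–350 bp, and the
read-level path at ~90k reads. These sizes were chosen so every
property is exercised with comfortable statistical resolution while the
whole suite stays fast enough to run habitually.

## Known limitations

- The enrichment score is the mean guide log2FC; median or
  trimmed-mean variants are not provided (the mean is isolated behind
  `enrichment_score` if that choice is revisited).
- No negative-binomial count modeling at test time (MAGeCK-style),
  copy-number correction, or guide-efficiency priors — hit calling is
  purely rank-based against NT controls.
- `overlap_sets` handles 2–4 sets, matching Venn-style reporting.
- The 0-order background is the only motif background model; no
  higher-order Markov backgrounds or de novo discovery.
- Closest-gene distance is span-based; TSS-distance variants are not
  implemented.
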