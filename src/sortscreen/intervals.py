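"""Interval arithmetic for peak sets, gene models and signal tracks.

All peak coordinates follow the BED convention: 0-based, half-open
``[start, end)``.  Gene models carry TSS and TTS as single base
coordinates (strand-oriented, so TSS > TTS on the minus strand);
promoter and downstream windows around them are inclusive base ranges,
which keeps every rule exactly mirror-symmetric under genome
reversal.

The operations here back the standard regulatory-genomics bookkeeping:
replicate-reconciled peak lists, genomic-feature annotation with
promoter/exon/intron/downstream/intergenic priority, nearest-gene
target assignment (bedtools-closest distance convention), k-set Venn
overlap counts, and average-signal metaprofiles over peak windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

PROMOTER = "PROMOTER"
EXON = "EXON"
INTRON = "INTRON"
DOWNSTREAM = "DOWNSTREAM"
INTERGENIC = "INTERGENIC"
CATEGORIES = (PROMOTER, EXON, INTRON, DOWNSTREAM, INTERGENIC)

CENTER = "CENTER"
SCALED_BODY = "SCALED_BODY"


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


class PeakSet:
    """A labelled, sorted collection of peaks (e.g. one factor/condition)."""

    def __init__(self, label: str, intervals: Iterable[GenomicInterval]):
        self.label = label
        self.intervals = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def by_chrom(self) -> dict[str, list[GenomicInterval]]:
        out: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def tree(self) -> dict[str, IntervalTree]:
        return {
            chrom: IntervalTree.from_tuples((iv.start, iv.end) for iv in ivs)
            for chrom, ivs in self.by_chrom().items()
        }

    @classmethod
    def from_bed(cls, path, label: Optional[str] = None) -> "PeakSet":
        """Read a 3-6 column BED file."""
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                name = parts[3] if len(parts) > 3 else None
                score = float(parts[4]) if len(parts) > 4 and parts[4] != "." else None
                strand = parts[5] if len(parts) > 5 else "."
                ivs.append(GenomicInterval(chrom, start, end, name, score, strand))
        return cls(label or str(path), ivs)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, iv in enumerate(self.intervals):
                name = iv.name or f"{self.label}_{i}"
                score = 0 if iv.score is None else iv.score
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )


def merge_intervals(peaks: PeakSet) -> PeakSet:
    """Merge overlapping intervals into a maximal non-overlapping cover."""
    merged: list[GenomicInterval] = []
    for chrom, ivs in peaks.by_chrom().items():
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return PeakSet(peaks.label, merged)


def reconcile_replicates(
    rep1: PeakSet,
    rep2: PeakSet,
    min_overlap_bp: int = 1,
    symmetric: bool = False,
) -> PeakSet:
    """Replicate-reconciled peak list.

    Keeps intervals of ``rep1`` that overlap some single interval of
    ``rep2`` by at least ``min_overlap_bp`` bases, then merges.  With
    ``symmetric=True`` the union of both directions is taken before
    merging (peaks supported in both independent experiments, anchored
    on either replicate).
    """
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")

    def _supported(a: PeakSet, b: PeakSet) -> list[GenomicInterval]:
        trees = b.tree()
        out = []
        for iv in a:
            tree = trees.get(iv.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(iv.start, iv.end):
                if min(iv.end, hit.end) - max(iv.start, hit.begin) >= min_overlap_bp:
                    out.append(iv)
                    break
        return out

    kept = _supported(rep1, rep2)
    if symmetric:
        kept += _supported(rep2, rep1)
    label = f"{rep1.label}&{rep2.label}"
    if not kept:
        return PeakSet(label, [])
    return merge_intervals(PeakSet(label, kept))


@dataclass(frozen=True)
class GeneModel:
    """A gene: strand-oriented TSS/TTS base coordinates, optional exons.

    Exon blocks are half-open ``(start, end)`` pairs in genomic
    coordinates, independent of strand.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int
    exons: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.strand == "+" and not self.tss < self.tts:
            raise ValueError(f"gene {self.gene_id}: + strand requires TSS < TTS")
        if self.strand == "-" and not self.tss > self.tts:
            raise ValueError(f"gene {self.gene_id}: - strand requires TSS > TTS")
        lo, hi = self.span
        for s, e in self.exons:
            if not (lo <= s < e <= hi + 1):
                raise ValueError(f"gene {self.gene_id}: exon [{s},{e}) outside span")

    @property
    def span(self) -> tuple[int, int]:
        """Inclusive base range covered by the gene body."""
        return min(self.tss, self.tts), max(self.tss, self.tts)


def read_gene_models(path) -> list[GeneModel]:
    """Read a gene-model TSV: gene_id, chrom, strand, tss, tts, exons.

    The exons column holds comma-separated ``start-end`` half-open
    pairs, or is empty/'.' for exonless models.
    """
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            parts = line.split("\t")
            gene_id, chrom, strand = parts[0], parts[1], parts[2]
            tss, tts = int(parts[3]), int(parts[4])
            exons: tuple[tuple[int, int], ...] = ()
            if len(parts) > 5 and parts[5] not in ("", "."):
                exons = tuple(
                    (int(a), int(b))
                    for a, b in (p.split("-") for p in parts[5].split(","))
                )
            genes.append(GeneModel(gene_id, chrom, strand, tss, tts, exons))
    return genes


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\tstrand\ttss\ttts\texons\n")
        for g in genes:
            ex = ",".join(f"{s}-{e}" for s, e in g.exons) or "."
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.strand}\t{g.tss}\t{g.tts}\t{ex}\n")


def _overlaps_bases(peak: GenomicInterval, lo: int, hi: int) -> bool:
    """Peak [start, end) vs inclusive base range [lo, hi]."""
    return peak.start <= hi and peak.end - 1 >= lo


def promoter_window(gene: GeneModel, up: int, down: int) -> tuple[int, int]:
    """Inclusive base range of the strand-oriented promoter around TSS."""
    if gene.strand == "+":
        return gene.tss - up, gene.tss + down
    return gene.tss - down, gene.tss + up


def downstream_window(gene: GeneModel, window: int) -> tuple[int, int]:
    """Inclusive base range immediately 3' of the TTS."""
    if gene.strand == "+":
        return gene.tts + 1, gene.tts + window
    return gene.tts - window, gene.tts - 1


def annotate_peak(
    peak: GenomicInterval,
    genes: Sequence[GeneModel],
    promoter_up: int = 1000,
    promoter_down: int = 1000,
    downstream_bp: int = 1000,
) -> str:
    """Assign one genomic-feature category to a peak.

    Priority: PROMOTER (within 1 kb either side of a TSS,
    strand-oriented) > EXON > INTRON (inside a gene body) > DOWNSTREAM
    (within 1 kb past a TTS) > INTERGENIC.
    """
    if min(promoter_up, promoter_down, downstream_bp) < 0:
        raise ValueError("windows must be >= 0")
    here = [g for g in genes if g.chrom == peak.chrom]
    for g in here:
        if _overlaps_bases(peak, *promoter_window(g, promoter_up, promoter_down)):
            return PROMOTER
    for g in here:
        for s, e in g.exons:
            if peak.start < e and peak.end > s:
                return EXON
    for g in here:
        if _overlaps_bases(peak, *g.span):
            return INTRON
    if downstream_bp > 0:
        for g in here:
            if _overlaps_bases(peak, *downstream_window(g, downstream_bp)):
                return DOWNSTREAM
    return INTERGENIC


def annotate_peaks(
    peaks: PeakSet, genes: Sequence[GeneModel], **windows
) -> pd.DataFrame:
    """Annotate every peak; returns a tidy per-peak table."""
    rows = [
        {
            "chrom": iv.chrom,
            "start": iv.start,
            "end": iv.end,
            "category": annotate_peak(iv, genes, **windows),
        }
        for iv in peaks
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "category"])


def closest_gene(
    peak: GenomicInterval, genes: Sequence[GeneModel]
) -> Optional[tuple[str, int]]:
    """Nearest gene to a peak, with the signed base-pair distance.

    Distance is measured to the gene body (span): 0 for any overlap,
    otherwise the gap in bases plus one (adjacent features are 1 bp
    apart, the bedtools-closest convention).  The sign orients the peak
    relative to the gene's strand: positive when the peak lies 3'
    (downstream) of the gene, negative when 5' (upstream).  Ties on
    distance go to the lexicographically smaller gene id.  Returns
    ``None`` when the peak's chromosome carries no genes.
    """
    here = [g for g in genes if g.chrom == peak.chrom]
    if not here:
        return None
    best: Optional[tuple[int, str, int]] = None
    for g in here:
        lo, hi = g.span
        if _overlaps_bases(peak, lo, hi):
            dist, signed = 0, 0
        elif peak.end - 1 < lo:  # peak left of gene
            dist = lo - (peak.end - 1)
            signed = -dist if g.strand == "+" else dist
        else:  # peak right of gene
            dist = peak.start - hi
            signed = dist if g.strand == "+" else -dist
        key = (dist, g.gene_id, signed)
        if best is None or key[:2] < best[:2]:
            best = key
    return best[1], best[2]


def closest_genes(peaks: PeakSet, genes: Sequence[GeneModel]) -> pd.DataFrame:
    rows = []
    for iv in peaks:
        hit = closest_gene(iv, genes)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "gene": None if hit is None else hit[0],
                "distance": None if hit is None else hit[1],
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene", "distance"])


@dataclass
class VennCounts:
    """k-set overlap counts anchored on the first set of each subset.

    ``counts[labels]`` is the number of intervals of ``labels[0]``
    overlapping at least one interval of every other listed set;
    ``percentages`` expresses that as a share of ``labels[0]``'s peaks.
    ``membership`` is a per-set boolean table of pairwise support.
    """

    counts: dict[tuple[str, ...], int]
    percentages: dict[tuple[str, ...], float]
    set_sizes: dict[str, int]
    membership: dict[str, pd.DataFrame]

    def as_dict(self) -> dict:
        return {
            "set_sizes": self.set_sizes,
            "counts": {"|".join(k): v for k, v in self.counts.items()},
            "percentages": {"|".join(k): v for k, v in self.percentages.items()},
        }


def overlap_sets(sets: Sequence[PeakSet], min_overlap_bp: int = 1) -> VennCounts:
    """Venn-style overlap counts for 2-4 merged peak sets.

    For every non-empty subset of labels (in input order) the count is
    the number of intervals of the subset's *first* set overlapping all
    the other member sets by at least ``min_overlap_bp``.
    """
    from itertools import combinations

    if not (2 <= len(sets) <= 4):
        raise ValueError("overlap_sets takes 2-4 peak sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("peak set labels must be distinct")
    trees = {s.label: s.tree() for s in sets}

    def hits(iv: GenomicInterval, other: str) -> bool:
        tree = trees[other].get(iv.chrom)
        if tree is None:
            return False
        return any(
            min(iv.end, h.end) - max(iv.start, h.begin) >= min_overlap_bp
            for h in tree.overlap(iv.start, iv.end)
        )

    membership = {}
    for s in sets:
        rows = [[hits(iv, other) for other in labels] for iv in s]
        membership[s.label] = pd.DataFrame(
            rows, columns=labels, dtype=bool
        )

    counts: dict[tuple[str, ...], int] = {}
    percentages: dict[tuple[str, ...], float] = {}
    sizes = {s.label: len(s) for s in sets}
    for r in range(1, len(sets) + 1):
        for combo in combinations(range(len(sets)), r):
            names = tuple(labels[i] for i in combo)
            ref = names[0]
            others = list(names[1:])
            memb = membership[ref]
            if others:
                mask = memb[others].all(axis=1)
                n = int(mask.sum()) if len(memb) else 0
            else:
                n = sizes[ref]
            counts[names] = n
            percentages[names] = 100.0 * n / sizes[ref] if sizes[ref] else float("nan")
    return VennCounts(counts, percentages, sizes, membership)


class SignalTrack:
    """A sparse per-chromosome step function (bedGraph semantics).

    Steps are non-overlapping, sorted, half-open; uncovered bases read
    as 0.
    """

    def __init__(self, steps: dict[str, list[tuple[int, int, float]]]):
        self.steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, triples in steps.items():
            triples = sorted(triples)
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            vals = np.array([t[2] for t in triples], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise ValueError(f"overlapping steps on {chrom}")
            if np.any(ends <= starts):
                raise ValueError(f"empty step on {chrom}")
            self.steps[chrom] = (starts, ends, vals)

    @classmethod
    def from_bedgraph(cls, path) -> "SignalTrack":
        steps: dict[str, list[tuple[int, int, float]]] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, s, e, v = line.split("\t")[:4]
                steps.setdefault(chrom, []).append((int(s), int(e), float(v)))
        return cls(steps)

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.steps):
                starts, ends, vals = self.steps[chrom]
                for s, e, v in zip(starts, ends, vals):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")

    def values(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base signal over [start, end); bases before 0 are clipped
        to zeros on the left so the window length is preserved."""
        if end <= start:
            return np.zeros(0)
        out = np.zeros(end - start)
        if chrom not in self.steps:
            return out
        starts, ends, vals = self.steps[chrom]
        lo = int(np.searchsorted(ends, start, side="right"))
        hi = int(np.searchsorted(starts, end, side="left"))
        for i in range(lo, hi):
            a = max(starts[i], start) - start
            b = min(ends[i], end) - start
            if b > a:
                out[a:b] = vals[i]
        return out


def _bin_means(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of equal index partitions; empty partitions contribute 0."""
    edges = np.floor(np.arange(n_bins + 1) * len(values) / n_bins).astype(int)
    out = np.zeros(n_bins)
    for b in range(n_bins):
        seg = values[edges[b] : edges[b + 1]]
        if seg.size:
            out[b] = seg.mean()
    return out


def metaprofile(
    track: SignalTrack,
    peaks: PeakSet,
    flank_bp: int = 2000,
    n_bins: int = 50,
    anchor: str = CENTER,
) -> np.ndarray:
    """Average signal profile across aligned peak windows.

    CENTER: each peak contributes the signal over
    ``[center - flank_bp, center + flank_bp)`` split into ``n_bins``
    equal base partitions; the profile is the mean over peaks of the
    per-peak bin means.  SCALED_BODY: the peak body is rescaled to
    ``n_bins`` bins with each flank appended as ``n_bins // 2`` bins.
    Windows reaching before base 0 are clipped and contribute zeros.
    """
    if n_bins < 1 or flank_bp < 0:
        raise ValueError("need n_bins >= 1 and flank_bp >= 0")
    if len(peaks) == 0:
        raise ValueError("empty peak set")
    profiles = []
    clipped = 0
    for iv in peaks:
        if anchor == CENTER:
            c = iv.center
            win_s, win_e = c - flank_bp, c + flank_bp
            if win_e <= win_s:
                raise ValueError("CENTER anchor needs flank_bp >= 1")
            vals = track.values(iv.chrom, max(win_s, 0), win_e)
            if win_s < 0:
                clipped += 1
                vals = np.concatenate([np.zeros(-win_s), vals])
            profiles.append(_bin_means(vals, n_bins))
        elif anchor == SCALED_BODY:
            n_flank = n_bins // 2 if flank_bp > 0 else 0
            body = _bin_means(track.values(iv.chrom, iv.start, iv.end), n_bins)
            if n_flank:
                ls, le = iv.start - flank_bp, iv.start
                lvals = track.values(iv.chrom, max(ls, 0), le)
                if ls < 0:
                    clipped += 1
                    lvals = np.concatenate([np.zeros(-ls), lvals])
                left = _bin_means(lvals, n_flank)
                right = _bin_means(track.values(iv.chrom, iv.end, iv.end + flank_bp), n_flank)
                body = np.concatenate([left, body, right])
            profiles.append(body)
        else:
            raise ValueError(f"unknown anchor {anchor!r}")
    if clipped:
        warnings.warn(f"{clipped} peak windows clipped at chromosome start", stacklevel=2)
    return np.mean(np.vstack(profiles), axis=0)
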