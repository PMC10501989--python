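"""Synthetic data generation for the whole pipeline.

Two generators cover every input the package consumes:

* :func:`simulate_screen` emits a guide library, sorted-bin count
  tables per screen replicate and the generating ground truth for a
  reporter-sorted knockout screen.  A minority of genes are true
  regulators whose guides change the reporter-negative : positive
  abundance ratio by ``2**effect``; counts are drawn gamma-Poisson
  (negative binomial) so sequencing overdispersion is tunable, with
  ``dispersion = 0`` degrading to pure Poisson for analytic checks.
  Non-targeting and non-regulator guides share identical generative
  parameters, so the null is faithful by construction.

* :func:`simulate_genome` emits a small random genome with
  non-overlapping gene models, multi-factor peak sets with a controlled
  pairwise overlap design, a bedGraph signal track of per-peak
  triangular bumps over a uniform floor, and motif consensus sequences
  planted in a stated fraction of each set's peaks.

Both are deterministic given their seed, and both can write the exact
text formats the rest of the package reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd

from .intervals import GeneModel, GenomicInterval, PeakSet, SignalTrack, write_gene_models
from .quant import (
    BINS,
    DEFAULT_FIVE_ADAPTER,
    DEFAULT_THREE_ADAPTER,
    NON_TARGETING,
    REPORTER_NEG,
    REPORTER_POS,
    CountTable,
    GuideLibrary,
    ReadRecord,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# screen simulation
# ---------------------------------------------------------------------------

@dataclass
class ScreenSimConfig:
    """Study conditions for the simulated reporter-sorted screen.

    Defaults describe a focused library (hundreds of genes, 4 guides
    each, ~100 non-targeting controls) sequenced to ~500 reads per
    guide per bin with moderate overdispersion; 5% of genes are true
    regulators with a mean guide effect of -1.5 log2 units.
    """

    n_genes: int = 500
    guides_per_gene: int = 4
    n_nt_guides: int = 100
    n_screens: int = 2
    fraction_true_positive: float = 0.05
    effect_log2fc: float = -1.5
    guide_effect_sd: float = 0.3
    depth_per_guide: int = 500
    dispersion: float = 0.15
    abundance_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.fraction_true_positive <= 1.0:
            raise ValueError("fraction_true_positive must lie in [0, 1]")
        if min(self.n_genes, self.guides_per_gene, self.n_nt_guides,
               self.n_screens, self.depth_per_guide) < 1:
            raise ValueError("counts must be positive")
        if self.dispersion < 0 or self.guide_effect_sd < 0:
            raise ValueError("dispersion and guide_effect_sd must be >= 0")


@dataclass
class ScreenTruth:
    """Generating truth of a simulated screen."""

    regulator_genes: list[str]
    gene_effects: dict[str, float]
    guide_effects: dict[str, float]
    expected_abundance: pd.DataFrame  # guides x (screen, bin) expected counts

    def to_json(self, path) -> None:
        payload = {
            "regulator_genes": self.regulator_genes,
            "gene_effects": self.gene_effects,
            "guide_effects": self.guide_effects,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def random_guide_sequences(
    n: int, rng: np.random.Generator, min_hamming: int = 3, length: int = 20
) -> list[str]:
    """Random distinct DNA 20-mers with pairwise Hamming distance >= 3,
    so single-mismatch guide assignment is always unambiguous."""
    accepted = np.zeros((0, length), dtype=np.uint8)
    out: list[str] = []
    attempts = 0
    while len(out) < n:
        attempts += 1
        if attempts > 50 * n + 1000:
            raise RuntimeError("cannot place distinct guide sequences")
        cand = BASES[rng.integers(0, 4, size=length)]
        if len(accepted) and ((accepted != cand).sum(axis=1) < min_hamming).any():
            continue
        accepted = np.vstack([accepted, cand])
        out.append(cand.tobytes().decode())
    return out


def simulate_screen(
    config: Optional[ScreenSimConfig] = None, **overrides
) -> tuple[GuideLibrary, CountTable, ScreenTruth]:
    """Simulate guide counts for a sorted-bin screen with known truth.

    Returns the guide library, a multi-screen count table and the
    generating truth.  Reproducible bit-for-bit given the seed.
    """
    cfg = config or ScreenSimConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)

    genes = [f"GENE{i:04d}" for i in range(cfg.n_genes)]
    n_guides = cfg.n_genes * cfg.guides_per_gene + cfg.n_nt_guides
    seqs = random_guide_sequences(n_guides, rng)
    entries, guide_gene = [], []
    k = 0
    for gene in genes:
        for j in range(cfg.guides_per_gene):
            entries.append((f"{gene}_g{j}", seqs[k], gene))
            guide_gene.append(gene)
            k += 1
    for j in range(cfg.n_nt_guides):
        entries.append((f"NT_g{j}", seqs[k], NON_TARGETING))
        guide_gene.append(NON_TARGETING)
        k += 1
    library = GuideLibrary(entries)
    guide_ids = library.guide_ids

    n_reg = int(round(cfg.fraction_true_positive * cfg.n_genes))
    regulators = sorted(rng.choice(genes, size=n_reg, replace=False).tolist())
    gene_effect = {g: (cfg.effect_log2fc if g in set(regulators) else 0.0) for g in genes}
    gene_effect[NON_TARGETING] = 0.0

    # per-guide realized effect: regulator guides get lognormal jitter of
    # the abundance ratio; everything else is exactly null
    guide_effect = np.zeros(n_guides)
    for i, g in enumerate(guide_gene):
        eff = gene_effect[g]
        if eff != 0.0:
            guide_effect[i] = eff + rng.normal(0.0, cfg.guide_effect_sd)

    # library representation (shared across bins and screens)
    abundance = rng.lognormal(mean=0.0, sigma=cfg.abundance_sigma, size=n_guides)
    depth = cfg.depth_per_guide * n_guides

    columns: dict[tuple[str, str], pd.Series] = {}
    expected: dict[tuple[str, str], np.ndarray] = {}
    for s in range(cfg.n_screens):
        screen = f"S{s + 1}"
        w_pos = abundance
        w_neg = abundance * np.exp2(guide_effect)
        for bin_, w in ((REPORTER_POS, w_pos), (REPORTER_NEG, w_neg)):
            mu = depth * w / w.sum()
            if cfg.dispersion > 0:
                lam = rng.gamma(shape=1.0 / cfg.dispersion, scale=mu * cfg.dispersion)
            else:
                lam = mu
            counts = rng.poisson(lam)
            columns[(screen, bin_)] = pd.Series(counts, index=guide_ids)
            expected[(screen, bin_)] = mu
    table = CountTable.from_columns(columns, library)

    exp_df = pd.DataFrame(expected, index=guide_ids)
    exp_df.columns = pd.MultiIndex.from_tuples(exp_df.columns, names=["screen", "bin"])
    truth = ScreenTruth(
        regulator_genes=regulators,
        gene_effects={g: gene_effect[g] for g in genes},
        guide_effects=dict(zip(guide_ids, guide_effect.tolist())),
        expected_abundance=exp_df,
    )

    # warn when depth is too shallow for the count filter to retain guides
    if (table.counts.to_numpy().min(axis=None) < 1) and cfg.depth_per_guide < 50:
        import warnings

        warnings.warn("low depth: count filtering may drop many guides", stacklevel=2)
    return library, table, truth


def simulate_reads(
    library: GuideLibrary,
    counts: pd.Series,
    rng: np.random.Generator,
    five_adapter: str = DEFAULT_FIVE_ADAPTER,
    three_adapter: str = DEFAULT_THREE_ADAPTER,
    adapter_error_rate: float = 0.0,
) -> Iterator[ReadRecord]:
    """Emit amplicon reads (adapter + protospacer + adapter) realizing a
    count column, in shuffled order, with optional adapter base errors."""
    guide_of_read: list[str] = []
    for gid, c in counts.items():
        guide_of_read.extend([gid] * int(c))
    order = rng.permutation(len(guide_of_read))
    alphabet = "ACGT"
    for i, ridx in enumerate(order):
        gid = guide_of_read[ridx]
        a5, a3 = five_adapter, three_adapter
        if adapter_error_rate > 0:
            a5 = _mutate(a5, rng, adapter_error_rate, alphabet)
            a3 = _mutate(a3, rng, adapter_error_rate, alphabet)
        seq = a5 + library.sequence_of(gid) + a3
        yield ReadRecord(f"read{i}:{gid}", seq, "I" * len(seq))


def _mutate(seq: str, rng: np.random.Generator, rate: float, alphabet: str) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = alphabet[int(rng.integers(0, 4))]
    return "".join(chars)


def write_fastq(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{r.quality or 'I' * len(r.sequence)}\n")


def write_screen_dir(
    outdir,
    library: GuideLibrary,
    table: CountTable,
    truth: ScreenTruth,
) -> None:
    """Write library CSV, counts TSV and truth JSON into a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    library.to_csv(outdir / "library.csv")
    table.to_tsv(outdir / "counts.tsv")
    truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

@dataclass
class GenomeSimConfig:
    """Study conditions for the simulated genome and peak sets.

    ``overlap_design[(i, j)]`` (with set indices ``i < j``) is the target
    fraction of set ``i``'s peaks that set ``j`` must overlap;
    ``motif_plant_rate[i]`` is the fraction of set ``i``'s peaks that get
    the motif consensus written at their center.
    """

    n_chroms: int = 4
    chrom_length: int = 150_000
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (2_000, 6_000)
    exons_per_gene: int = 3
    n_peaksets: int = 3
    peaks_per_set: int = 150
    peak_width_range: tuple[int, int] = (150, 350)
    overlap_design: dict[tuple[int, int], float] = field(default_factory=dict)
    motif_plant_rate: tuple[float, ...] = ()
    motif_consensus: str = "TGACTCA"
    bump_height_range: tuple[float, float] = (5.0, 15.0)
    noise_floor: float = 0.2
    clearance: int = 500
    seed: int = 0

    def __post_init__(self):
        for (i, j), f in self.overlap_design.items():
            if not 0 <= i < j < self.n_peaksets:
                raise ValueError(f"overlap_design key ({i},{j}) must satisfy i < j")
            if not 0.0 <= f <= 1.0:
                raise ValueError("overlap fractions must lie in [0, 1]")


@dataclass
class GenomeTruth:
    """Generating truth of a simulated genome."""

    realized_overlap: dict[tuple[int, int], float]
    planted_motifs: dict[int, list[tuple[str, int]]]  # set index -> (chrom, offset)

    def to_json(self, path) -> None:
        payload = {
            "realized_overlap": {f"{i}|{j}": v for (i, j), v in self.realized_overlap.items()},
            "planted_motifs": {str(k): v for k, v in self.planted_motifs.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def _place_nonoverlapping(
    rng: np.random.Generator,
    n: int,
    chroms: list[str],
    chrom_length: int,
    width_range: tuple[int, int],
    occupied: dict[str, list[tuple[int, int]]],
    clearance: int,
) -> list[GenomicInterval]:
    """Random intervals keeping `clearance` bp away from `occupied`."""
    placed = []
    attempts = 0
    while len(placed) < n:
        attempts += 1
        if attempts > 200 * n + 2000:
            raise RuntimeError("genome too crowded: cannot place intervals")
        chrom = chroms[int(rng.integers(len(chroms)))]
        w = int(rng.integers(width_range[0], width_range[1] + 1))
        if chrom_length <= w + 2 * clearance:
            raise RuntimeError("chromosome shorter than interval + clearance")
        s = int(rng.integers(clearance, chrom_length - w - clearance))
        e = s + w
        if any(s - clearance < oe and e + clearance > os_ for os_, oe in occupied.get(chrom, [])):
            continue
        occupied.setdefault(chrom, []).append((s, e))
        placed.append(GenomicInterval(chrom, s, e))
    return placed


def simulate_genome(
    config: Optional[GenomeSimConfig] = None, **overrides
) -> tuple[dict[str, str], list[GeneModel], list[PeakSet], SignalTrack, GenomeTruth]:
    """Simulate a genome, gene models, peak sets, signal track and truth.

    Peaks of later sets are co-located on sampled peaks of earlier sets
    to realize the pairwise overlap design within +/-0.05; remaining
    peaks keep clear of all other sets so undesigned overlaps stay at 0.
    """
    cfg = config or GenomeSimConfig(**overrides)
    if config is not None and overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chroms)]

    genome = {
        c: BASES[rng.integers(0, 4, size=cfg.chrom_length)].tobytes().decode()
        for c in chroms
    }

    # --- gene models: non-overlapping spans, random strand, exon blocks
    gene_occupied: dict[str, list[tuple[int, int]]] = {}
    spans = _place_nonoverlapping(
        rng, cfg.n_genes, chroms, cfg.chrom_length, cfg.gene_length_range,
        gene_occupied, clearance=100,
    )
    genes = []
    for i, iv in enumerate(spans):
        strand = "+" if rng.random() < 0.5 else "-"
        lo, hi = iv.start, iv.end - 1
        tss, tts = (lo, hi) if strand == "+" else (hi, lo)
        n_ex = max(1, cfg.exons_per_gene)
        cuts = np.sort(rng.choice(np.arange(lo + 1, hi), size=2 * n_ex - 2, replace=False))
        bounds = [lo, *cuts.tolist(), hi + 1]
        exons = tuple(
            (bounds[2 * k], bounds[2 * k + 1]) for k in range(n_ex)
        )
        genes.append(GeneModel(f"g{i:03d}", iv.chrom, strand, tss, tts, exons))

    # --- peak sets with designed overlaps
    n_sets, n_peaks = cfg.n_peaksets, cfg.peaks_per_set
    for j in range(1, n_sets):
        need = sum(
            int(round(cfg.overlap_design.get((i, j), 0.0) * n_peaks))
            for i in range(j)
        )
        if need > n_peaks:
            raise ValueError(f"overlap design infeasible for set {j}: needs {need} peaks")

    peak_occupied: dict[str, list[tuple[int, int]]] = {}
    sets: list[list[GenomicInterval]] = []
    for j in range(n_sets):
        intervals: list[GenomicInterval] = []
        used_partners: set[tuple[int, int]] = set()
        for i in range(j):
            f = cfg.overlap_design.get((i, j), 0.0)
            m = int(round(f * len(sets[i])))
            if m == 0:
                continue
            available = [k for k in range(len(sets[i])) if (i, k) not in used_partners]
            partners = rng.choice(available, size=m, replace=False)
            for k in partners:
                used_partners.add((i, int(k)))
                ref = sets[i][int(k)]
                w = int(rng.integers(cfg.peak_width_range[0], cfg.peak_width_range[1] + 1))
                # center-jittered placement guaranteeing >= 1 bp overlap
                shift = int(rng.integers(-(min(w, len(ref)) // 2), min(w, len(ref)) // 2 + 1))
                s = max(0, ref.center + shift - w // 2)
                intervals.append(GenomicInterval(ref.chrom, s, s + w))
        fresh = _place_nonoverlapping(
            rng, n_peaks - len(intervals), chroms, cfg.chrom_length,
            cfg.peak_width_range, peak_occupied, cfg.clearance,
        )
        intervals.extend(fresh)
        sets.append(intervals)
    # register designed-overlap peaks after all placement so fresh peaks of
    # later sets also keep clear of them
    peaksets = [PeakSet(f"set{j}", ivs) for j, ivs in enumerate(sets)]

    # realized pairwise overlap fractions (fraction of set i hit by set j)
    realized: dict[tuple[int, int], float] = {}
    for i in range(n_sets):
        for j in range(n_sets):
            if i == j:
                continue
            tree = peaksets[j].tree()
            hit = sum(
                1
                for iv in peaksets[i]
                if iv.chrom in tree and tree[iv.chrom].overlaps(iv.start, iv.end)
            )
            realized[(i, j)] = hit / len(peaksets[i])

    # --- signal track: triangular bumps over set 0 peaks + uniform floor
    arrays = {c: np.full(cfg.chrom_length, cfg.noise_floor) for c in chroms}
    for iv in peaksets[0]:
        h = rng.uniform(*cfg.bump_height_range)
        w = len(iv)
        half = w / 2.0
        x = np.arange(w)
        bump = h * (1.0 - np.abs(x - half) / half)
        # quantize to 10-bp plateaus so the emitted bedGraph stays compact
        q = (np.floor(x / 10) * 10 + 5).clip(0, w - 1).astype(int)
        arrays[iv.chrom][iv.start : iv.end] += bump[q]
    track = SignalTrack({c: _rle_steps(a) for c, a in arrays.items()})

    # --- plant motif consensus at peak centers
    planted: dict[int, list[tuple[str, int]]] = {}
    motif = cfg.motif_consensus.upper()
    rates = cfg.motif_plant_rate or tuple(0.0 for _ in range(n_sets))
    for j, rate in enumerate(rates):
        planted[j] = []
        if rate <= 0:
            continue
        n_plant = int(round(rate * len(peaksets[j])))
        which = rng.choice(len(peaksets[j]), size=n_plant, replace=False)
        for k in which:
            iv = peaksets[j].intervals[int(k)]
            off = iv.center - len(motif) // 2
            g = genome[iv.chrom]
            genome[iv.chrom] = g[:off] + motif + g[off + len(motif):]
            planted[j].append((iv.chrom, off))

    truth = GenomeTruth(realized_overlap=realized, planted_motifs=planted)
    return genome, genes, peaksets, track, truth


def _rle_steps(values: np.ndarray) -> list[tuple[int, int, float]]:
    """Run-length encode a per-base value array into bedGraph steps,
    dropping zero-valued runs."""
    change = np.flatnonzero(np.diff(values)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [len(values)]])
    return [
        (int(s), int(e), float(values[s]))
        for s, e in zip(starts, ends)
        if values[s] != 0.0
    ]


def write_genome_dir(
    outdir,
    genome: dict[str, str],
    genes: Sequence[GeneModel],
    peaksets: Sequence[PeakSet],
    track: SignalTrack,
    truth: GenomeTruth,
) -> None:
    """Write FASTA, gene-model TSV, per-set BED, bedGraph and truth JSON."""
    from .motifs import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(genome, outdir / "genome.fa")
    write_gene_models(genes, outdir / "genes.tsv")
    for ps in peaksets:
        ps.to_bed(outdir / f"peaks_{ps.label}.bed")
    track.to_bedgraph(outdir / "signal.bedgraph")
    truth.to_json(outdir / "truth.json")
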