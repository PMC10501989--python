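"""Interval arithmetic against per-base and all-pairs brute-force oracles."""

import numpy as np
import pytest

from sortscreen import (
    GeneModel,
    GenomicInterval,
    PeakSet,
    SignalTrack,
    annotate_peak,
    annotate_peaks,
    closest_gene,
    merge_intervals,
    metaprofile,
    overlap_sets,
    reconcile_replicates,
)
from sortscreen.intervals import (
    CATEGORIES,
    CENTER,
    DOWNSTREAM,
    EXON,
    INTERGENIC,
    INTRON,
    PROMOTER,
    SCALED_BODY,
    read_gene_models,
    write_gene_models,
)

GENOME_LEN = 5000


def random_peaks(rng, n, label="A", max_len=GENOME_LEN, chroms=("chr1", "chr2")):
    ivs = []
    for _ in range(n):
        s = int(rng.integers(0, max_len - 60))
        w = int(rng.integers(1, 60))
        ivs.append(GenomicInterval(str(rng.choice(chroms)), s, s + w))
    return PeakSet(label, ivs)


def coverage_mask(peaks, chrom, length=GENOME_LEN):
    mask = np.zeros(length, dtype=bool)
    for iv in peaks:
        if iv.chrom == chrom:
            mask[iv.start : iv.end] = True
    return mask


class TestMerge:
    def test_overlapping_pair_merges(self):
        ps = PeakSet("A", [GenomicInterval("c", 10, 20), GenomicInterval("c", 15, 30)])
        merged = merge_intervals(ps)
        assert [(iv.start, iv.end) for iv in merged] == [(10, 30)]

    def test_disjoint_unchanged(self):
        ps = PeakSet("A", [GenomicInterval("c", 10, 20), GenomicInterval("c", 25, 30)])
        assert len(merge_intervals(ps)) == 2

    def test_coverage_identical_to_per_base_oracle(self, rng):
        ps = random_peaks(rng, 200)
        merged = merge_intervals(ps)
        for chrom in ("chr1", "chr2"):
            assert np.array_equal(
                coverage_mask(ps, chrom), coverage_mask(merged, chrom)
            )
        # merged cover is non-overlapping and sorted
        for chrom, ivs in merged.by_chrom().items():
            for a, b in zip(ivs, ivs[1:]):
                assert a.end < b.start


class TestReconcile:
    def test_unsupported_peak_absent(self):
        a = PeakSet("A", [GenomicInterval("c", 10, 20)])
        b = PeakSet("B", [GenomicInterval("c", 100, 120)])
        assert len(reconcile_replicates(a, b)) == 0

    def test_identical_replicates_idempotent(self, rng):
        a = random_peaks(rng, 50)
        out = reconcile_replicates(a, a)
        merged = merge_intervals(a)
        assert [(iv.chrom, iv.start, iv.end) for iv in out] == [
            (iv.chrom, iv.start, iv.end) for iv in merged
        ]

    def test_matches_all_pairs_oracle(self, rng):
        a, b = random_peaks(rng, 60, "A"), random_peaks(rng, 60, "B")
        for min_bp in (1, 5, 20):
            kept = [
                iv
                for iv in a
                if any(iv.overlap_bp(jv) >= min_bp for jv in b)
            ]
            expected = (
                merge_intervals(PeakSet("x", kept)) if kept else PeakSet("x", [])
            )
            got = reconcile_replicates(a, b, min_overlap_bp=min_bp)
            assert [(iv.chrom, iv.start, iv.end) for iv in got] == [
                (iv.chrom, iv.start, iv.end) for iv in expected
            ]

    def test_anti_monotone_in_min_overlap(self, rng):
        a, b = random_peaks(rng, 80, "A"), random_peaks(rng, 80, "B")
        sizes = [
            sum(len(iv) for iv in reconcile_replicates(a, b, min_overlap_bp=k))
            for k in (1, 10, 30)
        ]
        assert sizes[0] >= sizes[1] >= sizes[2]

    def test_symmetric_variant_contains_both_directions(self, rng):
        a, b = random_peaks(rng, 40, "A"), random_peaks(rng, 40, "B")
        sym = reconcile_replicates(a, b, symmetric=True)
        asym = reconcile_replicates(a, b)
        cov_sym = coverage_mask(sym, "chr1")
        cov_asym = coverage_mask(asym, "chr1")
        assert not np.any(cov_asym & ~cov_sym)


def demo_genes():
    # + strand gene 2000..3999 with two exons; - strand gene 6000..7999
    return [
        GeneModel("gp", "c", "+", 2000, 3999, ((2000, 2500), (3500, 4000))),
        GeneModel("gm", "c", "-", 7999, 6000, ((6000, 6400), (7600, 8000))),
    ]


class TestAnnotate:
    def test_peak_straddling_tss_is_promoter(self):
        assert annotate_peak(GenomicInterval("c", 1990, 2010), demo_genes()) == PROMOTER

    def test_downstream_past_tts(self):
        # 500 bp 3' of the + gene's TTS (3999), outside promoter reach
        genes = [GeneModel("g", "c", "+", 100, 3999)]
        assert annotate_peak(GenomicInterval("c", 4480, 4520), genes) == DOWNSTREAM

    def test_far_peak_is_intergenic(self):
        assert annotate_peak(GenomicInterval("c", 20000, 20100), demo_genes()) == INTERGENIC

    def test_exon_and_intron(self):
        genes = [GeneModel("g", "c", "+", 100, 9999, ((4000, 4500),))]
        assert annotate_peak(GenomicInterval("c", 4100, 4200), genes) == EXON
        assert annotate_peak(GenomicInterval("c", 5000, 5100), genes) == INTRON

    def test_promoter_priority_over_exon(self):
        # first exon overlaps the promoter window; promoter wins
        assert annotate_peak(GenomicInterval("c", 2100, 2200), demo_genes()) == PROMOTER

    def test_minus_strand_promoter_orientation(self):
        # upstream of a - strand gene means higher coordinates
        assert annotate_peak(GenomicInterval("c", 8500, 8600), demo_genes()) == PROMOTER
        assert annotate_peak(GenomicInterval("c", 5300, 5400), demo_genes()) == DOWNSTREAM

    def test_category_counts_partition_peaks(self, rng):
        genes = demo_genes()
        peaks = PeakSet(
            "A",
            [
                GenomicInterval("c", int(s), int(s) + int(w))
                for s, w in zip(
                    rng.integers(0, 12000, 300), rng.integers(1, 200, 300)
                )
            ],
        )
        df = annotate_peaks(peaks, genes)
        assert df["category"].isin(CATEGORIES).all()
        assert len(df) == len(peaks)

    def test_strand_mirror_invariance(self, rng):
        L = 20000
        genes = [
            GeneModel("g0", "c", "+", 2000, 3999, ((2000, 2400), (3000, 4000))),
            GeneModel("g1", "c", "-", 9000, 7001, ((7001, 7500), (8500, 9001))),
        ]

        def mirror_gene(g):
            strand = "-" if g.strand == "+" else "+"
            exons = tuple(sorted((L - e, L - s) for s, e in g.exons))
            return GeneModel(g.gene_id, g.chrom, strand, L - 1 - g.tss, L - 1 - g.tts, exons)

        mirrored = [mirror_gene(g) for g in genes]
        for _ in range(200):
            s = int(rng.integers(0, L - 300))
            w = int(rng.integers(1, 300))
            peak = GenomicInterval("c", s, s + w)
            mpeak = GenomicInterval("c", L - (s + w), L - s)
            assert annotate_peak(peak, genes) == annotate_peak(mpeak, mirrored)


class TestClosestGene:
    def test_overlapping_gene_distance_zero(self):
        gid, d = closest_gene(GenomicInterval("c", 2500, 2600), demo_genes())
        assert gid == "gp" and d == 0

    def test_midway_tie_prefers_lexicographic(self):
        genes = [
            GeneModel("b", "c", "+", 100, 199),
            GeneModel("a", "c", "+", 402, 500),
        ]
        # peak [296, 306) is 97 bp from b's end and 97 bp to a's start
        gid, _ = closest_gene(GenomicInterval("c", 296, 306), genes)
        assert gid == "a"

    def test_no_gene_on_chromosome(self):
        assert closest_gene(GenomicInterval("chrX", 0, 10), demo_genes()) is None

    def test_signed_distance_orientation(self):
        genes = [GeneModel("g", "c", "+", 1000, 1999), GeneModel("h", "c", "-", 5999, 5000)]
        _, d_down = closest_gene(GenomicInterval("c", 2100, 2110), [genes[0]])
        _, d_up = closest_gene(GenomicInterval("c", 900, 910), [genes[0]])
        assert d_down > 0 and d_up < 0
        # for the - strand gene the orientation flips
        _, d2 = closest_gene(GenomicInterval("c", 6100, 6110), [genes[1]])
        assert d2 < 0

    def test_matches_all_pairs_gap_oracle(self, rng):
        genes = []
        for i in range(20):
            s = int(rng.integers(0, 90000))
            e = s + int(rng.integers(100, 2000))
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tts = (s, e) if strand == "+" else (e, s)
            genes.append(GeneModel(f"g{i:02d}", "c", strand, tss, tts))
        for _ in range(100):
            s = int(rng.integers(0, 95000))
            peak = GenomicInterval("c", s, s + int(rng.integers(1, 500)))
            gid, d = closest_gene(peak, genes)
            gaps = {}
            for g in genes:
                lo, hi = g.span
                if peak.start <= hi and peak.end - 1 >= lo:
                    gaps[g.gene_id] = 0
                elif peak.end - 1 < lo:
                    gaps[g.gene_id] = lo - peak.end + 1
                else:
                    gaps[g.gene_id] = peak.start - hi
            best = min(gaps, key=lambda k: (gaps[k], k))
            assert gid == best and abs(d) == gaps[best]


class TestOverlapSets:
    def test_disjoint_sets_zero_multi_counts(self):
        a = PeakSet("A", [GenomicInterval("c", 0, 10)])
        b = PeakSet("B", [GenomicInterval("c", 100, 110)])
        venn = overlap_sets([a, b])
        assert venn.counts[("A", "B")] == 0

    def test_subset_gives_full_percentage(self):
        a = PeakSet("A", [GenomicInterval("c", i * 100, i * 100 + 10) for i in range(1, 6)])
        b = PeakSet("B", [GenomicInterval("c", i * 100 - 5, i * 100 + 20) for i in range(1, 6)])
        venn = overlap_sets([a, b])
        assert venn.counts[("A", "B")] == 5
        assert venn.percentages[("A", "B")] == 100.0

    def test_matches_triple_loop_brute_force(self, rng):
        sets = [
            merge_intervals(random_peaks(rng, 50, lab)) for lab in ("A", "B", "C")
        ]
        venn = overlap_sets(sets)
        by_label = {s.label: s for s in sets}
        from itertools import combinations

        for r in (2, 3):
            for combo in combinations("ABC", r):
                ref = by_label[combo[0]]
                n = sum(
                    all(
                        any(iv.overlap_bp(jv) >= 1 for jv in by_label[o])
                        for o in combo[1:]
                    )
                    for iv in ref
                )
                assert venn.counts[tuple(combo)] == n

    def test_wrong_cardinality_rejected(self):
        a = PeakSet("A", [GenomicInterval("c", 0, 10)])
        with pytest.raises(ValueError):
            overlap_sets([a])


def step_track(rng, length=GENOME_LEN, chrom="chr1"):
    steps, pos = [], 0
    while pos < length - 20:
        w = int(rng.integers(5, 50))
        v = float(np.round(rng.uniform(0, 10), 3))
        if v > 0:
            steps.append((pos, min(pos + w, length), v))
        pos += w + int(rng.integers(0, 10))
    return SignalTrack({chrom: steps})


class TestMetaprofile:
    def test_constant_track_gives_constant_profile(self):
        track = SignalTrack({"chr1": [(0, GENOME_LEN, 3.5)]})
        peaks = PeakSet("A", [GenomicInterval("chr1", 1000, 1200)])
        prof = metaprofile(track, peaks, flank_bp=100, n_bins=10)
        assert np.allclose(prof, 3.5)

    def test_unit_impulse_localized_to_center_bin(self):
        peaks = PeakSet("A", [GenomicInterval("chr1", 1000, 1200)])
        c = peaks.intervals[0].center
        track = SignalTrack({"chr1": [(c, c + 1, 1.0)]})
        prof = metaprofile(track, peaks, flank_bp=100, n_bins=20)
        assert prof[10] > 0 and prof[0] == 0 and prof[-1] == 0

    def test_matches_per_base_oracle(self, rng):
        track = step_track(rng)
        peaks = random_peaks(rng, 50, chroms=("chr1",), max_len=GENOME_LEN - 500)
        flank, n_bins = 200, 16
        prof = metaprofile(track, peaks, flank_bp=flank, n_bins=n_bins)
        acc = np.zeros(n_bins)
        for iv in peaks:
            c = (iv.start + iv.end) // 2
            base_vals = np.array(
                [
                    _track_value_at(track, "chr1", p)
                    for p in range(c - flank, c + flank)
                ]
            )
            edges = np.floor(np.arange(n_bins + 1) * len(base_vals) / n_bins).astype(int)
            acc += np.array(
                [base_vals[edges[b] : edges[b + 1]].mean() for b in range(n_bins)]
            )
        assert np.allclose(prof, acc / len(peaks))

    def test_additive_in_track(self, rng):
        t1, t2 = step_track(rng), step_track(rng)
        combined = {
            "chr1": _sum_tracks(t1, t2, "chr1", GENOME_LEN),
        }
        peaks = random_peaks(rng, 20, chroms=("chr1",), max_len=GENOME_LEN - 500)
        p1 = metaprofile(t1, peaks, 100, 10)
        p2 = metaprofile(t2, peaks, 100, 10)
        p12 = metaprofile(SignalTrack(combined), peaks, 100, 10)
        assert np.allclose(p12, p1 + p2)

    def test_invariant_to_peak_order(self, rng):
        track = step_track(rng)
        peaks = random_peaks(rng, 30, chroms=("chr1",))
        shuffled = PeakSet("A", list(rng.permutation(peaks.intervals)))
        assert np.allclose(
            metaprofile(track, peaks, 100, 10), metaprofile(track, shuffled, 100, 10)
        )

    def test_off_chromosome_window_clipped_with_warning(self):
        track = SignalTrack({"chr1": [(0, 1000, 2.0)]})
        peaks = PeakSet("A", [GenomicInterval("chr1", 0, 10)])
        with pytest.warns(UserWarning, match="clipped"):
            prof = metaprofile(track, peaks, flank_bp=100, n_bins=4)
        assert prof[0] < 2.0  # left flank padded with zeros

    def test_scaled_body_shape_and_constant_value(self):
        track = SignalTrack({"chr1": [(0, GENOME_LEN, 2.0)]})
        peaks = PeakSet("A", [GenomicInterval("chr1", 1000, 1400)])
        prof = metaprofile(track, peaks, flank_bp=100, n_bins=10, anchor=SCALED_BODY)
        assert len(prof) == 10 + 2 * 5
        assert np.allclose(prof, 2.0)


def _track_value_at(track, chrom, pos):
    if pos < 0:
        return 0.0
    starts, ends, vals = track.steps[chrom]
    for s, e, v in zip(starts, ends, vals):
        if s <= pos < e:
            return float(v)
    return 0.0


def _sum_tracks(t1, t2, chrom, length):
    arr = t1.values(chrom, 0, length) + t2.values(chrom, 0, length)
    steps = []
    change = np.flatnonzero(np.diff(arr)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [length]])
    for s, e in zip(starts, ends):
        if arr[s] != 0:
            steps.append((int(s), int(e), float(arr[s])))
    return steps


class TestGeneModelIO:
    def test_tsv_roundtrip(self, tmp_path):
        genes = demo_genes()
        path = tmp_path / "genes.tsv"
        write_gene_models(genes, path)
        back = read_gene_models(path)
        assert back == genes

    def test_strand_coordinate_invariants_enforced(self):
        with pytest.raises(ValueError):
            GeneModel("g", "c", "+", 100, 50)
        with pytest.raises(ValueError):
            GeneModel("g", "c", "-", 50, 100)


class TestBedIO:
    def test_bed_roundtrip(self, tmp_path, rng):
        ps = random_peaks(rng, 30)
        path = tmp_path / "peaks.bed"
        ps.to_bed(path)
        back = PeakSet.from_bed(path, "A")
        assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
            (iv.chrom, iv.start, iv.end) for iv in ps
        ]

    def test_bedgraph_roundtrip(self, tmp_path, rng):
        track = step_track(rng)
        path = tmp_path / "sig.bedgraph"
        track.to_bedgraph(path)
        back = SignalTrack.from_bedgraph(path)
        assert np.allclose(
            back.values("chr1", 0, GENOME_LEN), track.values("chr1", 0, GENOME_LEN)
        )
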