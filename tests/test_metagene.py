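import numpy as np
import pandas as pd
import pytest

from polredist.core import (
    AlignedLibrary,
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    ReadInterval,
    build_coverage,
)
from polredist.metagene import (
    body_log2fc_slope,
    expressed_genes,
    filter_intronic,
    metagene_by_quartile,
    occupancy_log2fc,
    redistribution_stat,
    scaled_metagene,
    stratify_by_length,
    tss_profile,
)


class TestFilterIntronic:
    def test_rules(self, toy_annotation):
        reads = [
            ReadInterval("chr1", 400, 450),  # fully intronic in gA -> kept
            ReadInterval("chr1", 280, 330),  # straddles exon boundary -> removed
            ReadInterval("chr1", 150, 200),  # inside exon -> removed
            ReadInterval("chr1", 5000, 5050),  # intergenic -> kept
            ReadInterval("chr2", 6100, 6150),  # blacklist -> removed
        ]
        kept = filter_intronic(reads, toy_annotation)
        assert kept == [reads[0], reads[3]]

    def test_matches_brute_force(self, toy_annotation, random_reads):
        reads = random_reads(800, toy_annotation.chrom_sizes, seed=6, read_len=60)
        kept = set(filter_intronic(reads, toy_annotation))
        forbidden = []
        for g in toy_annotation.genes.values():
            forbidden += [(g.chrom, s, e) for s, e in g.exons]
        forbidden += toy_annotation.blacklist
        naive = {
            r
            for r in reads
            if not any(c == r.chrom and r.start < e and s < r.end for c, s, e in forbidden)
        }
        assert kept == naive


class TestExpressedGenes:
    def test_boundary(self):
        m = pd.DataFrame({"a": [5, 4], "b": [5, 5]}, index=["g1", "g2"])
        assert expressed_genes(m, min_reads=10) == {"g1"}
        assert expressed_genes(pd.DataFrame(), min_reads=10) == set()

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.poisson(6, (50, 3)), index=[f"g{i}" for i in range(50)])
        prev = expressed_genes(m, 0)
        for thr in (5, 10, 20, 40):
            cur = expressed_genes(m, thr)
            assert cur <= prev
            prev = cur


class TestStratify:
    def test_published_quartile_sizes(self):
        lengths = {f"g{i}": 10_000 + i for i in range(8365)}
        a = stratify_by_length(lengths)
        assert a.sizes() == [2091, 2091, 2091, 2092]

    def test_eight_genes(self):
        lengths = {f"g{i}": 20_000 + i for i in range(8)}
        assert stratify_by_length(lengths).sizes() == [2, 2, 2, 2]

    def test_min_length_and_expression_exclusions(self):
        lengths = {"short": 5_000, "a": 20_000, "b": 30_000, "c": 40_000,
                   "d": 50_000, "silent": 60_000}
        a = stratify_by_length(lengths, expressed={"a", "b", "c", "d", "short"})
        assert a.excluded == {"short": "too_short", "silent": "not_expressed"}
        assert a.sizes() == [1, 1, 1, 1]

    def test_tie_break_is_input_order_invariant(self):
        rng = np.random.default_rng(0)
        lengths = {f"g{i}": int(rng.choice([12_000, 15_000, 20_000])) for i in range(40)}
        a = stratify_by_length(lengths)
        items = list(lengths.items())
        rng.shuffle(items)
        b = stratify_by_length(dict(items))
        assert a.assignment == b.assignment

    def test_shortest_in_group_one(self):
        lengths = {f"g{i}": 10_000 * (i + 1) for i in range(12)}
        a = stratify_by_length(lengths)
        assert a.assignment["g0"] == 1 and a.assignment["g11"] == 4


def delta_track(annotation, positions, bin_size=10):
    """Track with value 1 exactly in the bins containing given positions."""
    track = CoverageTrack(bin_size, annotation.chrom_sizes, total_mapped=len(positions))
    for chrom, pos in positions:
        track.values[chrom][pos // bin_size] += 1
    return track


class TestTssProfile:
    def test_delta_at_tss_peaks_centrally(self, toy_annotation):
        genes = toy_annotation.genes
        track = delta_track(toy_annotation, [(g.chrom, g.tss) for g in genes.values()])
        mat = tss_profile(track, genes, flank=100, out_bin=10)
        profile = mat.values[0]
        assert np.argmax(profile) == 10  # first downstream bin after the TSS
        assert profile[:9].sum() == 0

    def test_uniform_coverage_is_flat(self, toy_annotation):
        track = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=1)
        for c in track.values:
            track.values[c][:] = 3.0
        mat = tss_profile(track, toy_annotation.genes, flank=200)
        np.testing.assert_allclose(mat.values[0], 3.0)

    def test_matches_brute_force_window_average(self, random_reads):
        from polredist.simulate import simulate_annotation

        anno = simulate_annotation(50, length_log_range=(15_000, 60_000), seed=13)
        reads = random_reads(5000, anno.chrom_sizes, seed=14)
        track = build_coverage(reads, anno.chrom_sizes, 10)
        flank, ob = 500, 10
        mat = tss_profile(track, anno.genes, flank=flank, out_bin=ob)
        rows = []
        for g in anno.genes.values():
            if g.strand == "+":
                base = track.base_values(g.chrom, g.tss - flank, g.tss + flank)
            else:
                base = track.base_values(g.chrom, g.tss - flank + 1, g.tss + flank + 1)[::-1]
            with np.errstate(invalid="ignore"):
                rows.append(np.nanmean(base.reshape(-1, ob), axis=1))
        np.testing.assert_allclose(mat.values[0], np.nanmean(rows, axis=0), atol=1e-9)


class TestScaledMetagene:
    def test_uniform_coverage_flat_for_any_length(self, toy_annotation):
        track = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=1)
        for c in track.values:
            track.values[c][:] = 2.0
        prof = scaled_metagene(track, toy_annotation.genes, body_bins=20, flank=100, flank_bin=10)
        np.testing.assert_allclose(prof.matrix, 2.0)

    def test_geometric_decay_terminal_initial_ratio(self):
        # analytic track: density s^(d/1000) along one long plus-strand gene
        L, s = 100_000, 0.99
        genes = {"g": GeneModel("g", "chr1", "+", 0, L)}
        anno = GenomeAnnotation(genes, {"chr1": L})
        track = CoverageTrack(10, {"chr1": L}, total_mapped=1)
        d = np.arange(0, L, 10) + 5.0
        track.values["chr1"] = s ** (d / 1000.0)
        prof = scaled_metagene(track, genes, body_bins=100, flank=0)
        body = prof.matrix[0]
        expected = s ** (L / 1000.0 * 99 / 100)  # last vs first segment midpoint
        assert body[-1] / body[0] == pytest.approx(expected, rel=0.02)

    def test_short_gene_excluded_with_reason(self):
        genes = {"tiny": GeneModel("tiny", "chr1", "+", 0, 50)}
        track = CoverageTrack(10, {"chr1": 1000})
        prof = scaled_metagene(track, genes, body_bins=100, flank=0)
        assert prof.excluded == {"tiny": "shorter_than_body_bins"}

    def test_two_lengths_same_shape_average_equals_either(self):
        # identical scaled-space shape at different lengths: linear ramp
        genes = {
            "a": GeneModel("a", "chr1", "+", 0, 10_000),
            "b": GeneModel("b", "chr1", "+", 20_000, 60_000),
        }
        track = CoverageTrack(10, {"chr1": 100_000}, total_mapped=1)
        for g in genes.values():
            nb = g.length // 10
            track.values["chr1"][g.start // 10 : g.end // 10] = np.repeat(
                np.linspace(1, 2, 100), nb // 100
            )
        prof = scaled_metagene(track, genes, body_bins=100, flank=0)
        np.testing.assert_allclose(prof.matrix[0], prof.matrix[1], rtol=1e-6)


class TestMetageneByQuartile:
    def _setup(self):
        from polredist.simulate import (
            ConditionSpec,
            ElongationParams,
            simulate_annotation,
            simulate_elongation_reads,
        )

        anno = simulate_annotation(40, length_log_range=(12_000, 80_000), seed=21)
        cond = ConditionSpec("c", ElongationParams(reads_total=50_000))
        main, _ = simulate_elongation_reads(anno, cond, seed=22)
        return anno, main

    def test_identical_libraries_identical_matrices(self):
        anno, main = self._setup()
        track = build_coverage(main, anno.chrom_sizes)
        assign = stratify_by_length(anno.genes, min_length=0)
        prof = scaled_metagene(track, anno.genes, body_bins=20, flank=100, flank_bin=10)
        m1 = metagene_by_quartile(prof, assign)
        m2 = metagene_by_quartile(prof, assign)
        np.testing.assert_array_equal(m1.values, m2.values)
        assert m1.n_genes == assign.sizes()

    def test_cpm_invariant_to_read_duplication(self):
        anno, main = self._setup()
        dup = AlignedLibrary(main.sample_id, "main", main.reads * 2)
        assign = stratify_by_length(anno.genes, min_length=0)
        t1 = build_coverage(main, anno.chrom_sizes)
        t2 = build_coverage(dup, anno.chrom_sizes)
        p1 = scaled_metagene(t1, anno.genes, body_bins=20, flank=0)
        p2 = scaled_metagene(t2, anno.genes, body_bins=20, flank=0)
        np.testing.assert_allclose(
            metagene_by_quartile(p1, assign).values,
            metagene_by_quartile(p2, assign).values,
            rtol=1e-9,
        )


class TestOccupancyFC:
    def test_equal_tracks_give_zero_matrix(self, toy_annotation):
        track = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=100)
        for c in track.values:
            track.values[c][:] = 1.0
        genes = {k: g for k, g in toy_annotation.genes.items() if g.length >= 100}
        mat = occupancy_log2fc(track, track, genes, body_bins=10, downstream=100,
                               downstream_bin=10)
        np.testing.assert_allclose(mat.values, 0.0)
        assert mat.lengths.tolist() == sorted(mat.lengths.tolist())
        assert mat.body_end_index == 10

    def test_pseudocount_changes_only_zero_coverage_bins(self, toy_annotation):
        t = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=100)
        c = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=100)
        t.values["chr1"][:60] = 2.0
        c.values["chr1"][:60] = 1.0
        genes = {"gA": toy_annotation.genes["gA"]}
        m1 = occupancy_log2fc(t, c, genes, body_bins=10, downstream=0, pseudocount=1.0)
        m2 = occupancy_log2fc(t, c, genes, body_bins=10, downstream=0, pseudocount=2.0)
        changed = ~np.isclose(m1.values, m2.values)
        # bins past base 600 have zero coverage in both tracks -> log2FC 0 either way
        zero_both = np.isclose(m1.values, 0.0) & np.isclose(m2.values, 0.0)
        assert (changed | zero_both).all() or changed.any()
        assert np.isclose(m1.values, m2.values)[..., :5].sum() == 0  # nonzero bins move


class TestRedistribution:
    def test_identical_tracks_zero_and_swap_negates(self, toy_annotation):
        rng = np.random.default_rng(31)
        t = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=1000)
        c = CoverageTrack(10, toy_annotation.chrom_sizes, total_mapped=1000)
        for ch in t.values:
            t.values[ch][:] = rng.poisson(5, len(t.values[ch]))
            c.values[ch][:] = rng.poisson(5, len(c.values[ch]))
        assign = stratify_by_length(
            {g: m.length for g, m in toy_annotation.genes.items()},
            n_groups=3,
            min_length=0,
        )
        zero = redistribution_stat(t, t, toy_annotation.genes, assign)
        np.testing.assert_allclose(zero[["promoter_log2fc", "body_log2fc"]], 0.0, atol=1e-12)
        ab = redistribution_stat(t, c, toy_annotation.genes, assign)
        ba = redistribution_stat(c, t, toy_annotation.genes, assign)
        np.testing.assert_allclose(
            ab[["promoter_log2fc", "body_log2fc"]].to_numpy(),
            -ba[["promoter_log2fc", "body_log2fc"]].to_numpy(),
            atol=1e-12,
        )


def test_strand_mirror_invariance():
    """Reverse-complementing the genome leaves strand-aware profiles unchanged."""
    size = 50_000
    fwd_gene = {"g": GeneModel("g", "chr1", "+", 10_000, 30_000)}
    rng = np.random.default_rng(41)
    starts = rng.integers(10_000, 29_950, 2000)
    reads_fwd = [ReadInterval("chr1", int(s), int(s) + 50, "+") for s in starts]
    # mirrored genome: position x -> size - x
    rev_gene = {"g": GeneModel("g", "chr1", "-", size - 30_000, size - 10_000)}
    reads_rev = [
        ReadInterval("chr1", size - (int(s) + 50), size - int(s), "-") for s in starts
    ]
    t_fwd = build_coverage(reads_fwd, {"chr1": size}, 1)
    t_rev = build_coverage(reads_rev, {"chr1": size}, 1)
    p_fwd = scaled_metagene(t_fwd, fwd_gene, body_bins=50, flank=100, flank_bin=10)
    p_rev = scaled_metagene(t_rev, rev_gene, body_bins=50, flank=100, flank_bin=10)
    np.testing.assert_allclose(p_fwd.matrix, p_rev.matrix, atol=1e-9)
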