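import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from polpause.genome_io import (
    ChromSizes,
    GeneModel,
    GenomicInterval,
    Peak,
    filter_blacklist,
    read_bed6,
    read_chrom_sizes,
    read_genes,
    select_isolated_genes,
    write_bed6,
    write_genes_bed6,
)


class TestInterval:
    def test_rejects_inverted_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 0, 10, "x")

    def test_half_open_adjacency_is_not_overlap(self):
        a = GenomicInterval("chr1", 100, 200)
        assert not a.overlaps(GenomicInterval("chr1", 200, 300))
        assert a.overlaps(GenomicInterval("chr1", 199, 300))
        assert not a.overlaps(GenomicInterval("chr2", 100, 200))


class TestGeneModel:
    @pytest.mark.parametrize("strand,tss,tes", [("+", 1000, 5000),
                                                ("-", 5000, 1000)])
    def test_strand_aware_anchors(self, strand, tss, tes):
        g = GeneModel("g", GenomicInterval("chr1", 1000, 5000, strand))
        assert (g.tss, g.tes) == (tss, tes)

    def test_requires_strand_and_contained_exons(self):
        with pytest.raises(ValueError):
            GeneModel("g", GenomicInterval("chr1", 0, 10, "."))
        with pytest.raises(ValueError):
            GeneModel("g", GenomicInterval("chr1", 100, 200, "+"),
                      exons=[GenomicInterval("chr1", 50, 150, "+")])


class TestReaders:
    def test_read_genes_bed6(self, tmp_path):
        p = tmp_path / "genes.bed"
        p.write_text("chr1\t1000\t5000\tgeneA\t0\t+\n"
                     "chr1\t8000\t9000\tgeneB\t0\t-\n")
        genes = read_genes(p, "bed6")
        assert [g.gene_id for g in genes] == ["geneA", "geneB"]
        assert genes[0].tss == 1000 and genes[0].tes == 5000
        assert genes[1].tss == 9000 and genes[1].tes == 8000

    def test_read_genes_gtf_converts_coordinates(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1001\t5000\t.\t+\t.\tgene_id "gA";\n'
            'chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "gA";\n')
        genes = read_genes(p, "gtf")
        assert genes[0].interval.start == 1000
        assert genes[0].interval.end == 5000
        assert genes[0].exons[0].start == 1000

    def test_read_genes_bed12_blocks(self, tmp_path):
        p = tmp_path / "g.bed12"
        p.write_text("chr1\t1000\t5000\tgA\t0\t+\t1000\t5000\t0\t2\t"
                     "200,300\t0,3700\n")
        genes = read_genes(p, "bed12")
        assert len(genes[0].exons) == 2
        assert genes[0].exons[1].start == 4700
        assert genes[0].exons[1].end == 5000

    def test_malformed_line_errors_with_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\tok\t0\t+\nchr1\t500\t400\tbad\t0\t+\n")
        with pytest.raises(ValueError, match="line 2"):
            read_bed6(p)
        p.write_text("chr1\t100\t200\tok\t0\t?\n")
        with pytest.raises(ValueError, match="strand"):
            read_bed6(p)

    def test_chrom_sizes_rejects_duplicates_and_nonpositive(self, tmp_path):
        p = tmp_path / "c.sizes"
        p.write_text("chr1\t100\nchr1\t200\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_chrom_sizes(p)
        with pytest.raises(ValueError):
            ChromSizes({"chr1": 0})

    def test_clipping_to_chromosome(self):
        sizes = ChromSizes({"chr1": 1000})
        clipped = sizes.clip(GenomicInterval("chr1", 900, 1200))
        assert (clipped.start, clipped.end) == (900, 1000)

@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(
    st.tuples(st.sampled_from(["chr1", "chr2"]),
              st.integers(0, 10_000), st.integers(1, 500),
              st.sampled_from(["+", "-", "."])),
    min_size=1, max_size=30))
def test_bed6_round_trip_bit_exact(raw):
    import tempfile
    from pathlib import Path

    df = pd.DataFrame(
        [(c, s, s + l, f"iv{i}", 0, strand)
         for i, (c, s, l, strand) in enumerate(raw)],
        columns=["chrom", "start", "end", "name", "score", "strand"])
    with tempfile.TemporaryDirectory() as tmp:
        path = Path(tmp) / "rt.bed"
        write_bed6(df, path)
        back = read_bed6(path)
    pd.testing.assert_frame_equal(back, df)


def brute_force_isolated(genes, min_distance):
    """All-pairs edge-gap oracle."""
    kept = []
    for g in genes:
        ok = True
        for other in genes:
            if other is g:
                continue
            if other.chrom != g.chrom:
                continue
            if g.interval.overlaps(other.interval):
                ok = False
                break
            gap = max(other.interval.start - g.interval.end,
                      g.interval.start - other.interval.end)
            if gap < min_distance:
                ok = False
                break
        if ok:
            kept.append(g.gene_id)
    return kept


class TestIsolatedGenes:
    def _genes(self, spans, chrom="chr1"):
        return [GeneModel(f"g{i}", GenomicInterval(chrom, s, e, "+"))
                for i, (s, e) in enumerate(spans)]

    def test_single_gene_kept(self):
        genes = self._genes([(1000, 2000)])
        assert len(select_isolated_genes(genes)) == 1

    @pytest.mark.parametrize("gap,expected", [(3000, 0), (5000, 2), (4000, 2)])
    def test_gap_thresholds(self, gap, expected):
        genes = self._genes([(1000, 2000), (2000 + gap, 3000 + gap)])
        assert len(select_isolated_genes(genes, 4000)) == expected

    def test_overlapping_always_excluded(self):
        genes = self._genes([(1000, 5000), (4000, 9000)])
        assert select_isolated_genes(genes, 0) == []

    def test_matches_brute_force_oracle_and_symmetry(self):
        rng = np.random.default_rng(42)
        spans = []
        pos = 0
        for _ in range(60):
            pos += int(rng.integers(100, 9000))
            length = int(rng.integers(200, 4000))
            spans.append((pos, pos + length))
            pos += length
        genes = self._genes(spans)
        kept = {g.gene_id for g in select_isolated_genes(genes, 4000)}
        assert kept == set(brute_force_isolated(genes, 4000))
        # symmetry: exclusion is mutual, so kept genes never have an excluded
        # neighbour within range whose only conflict is the kept gene itself
        for g in genes:
            if g.gene_id in kept:
                for other in genes:
                    if other is not g:
                        assert (other.interval.start >= g.interval.end + 4000
                                or other.interval.end <= g.interval.start - 4000)

    def test_extra_annotations_disqualify(self):
        genes = self._genes([(10_000, 12_000)])
        extra = [GenomicInterval("chr1", 13_000, 13_100, ".")]
        assert select_isolated_genes(genes, 4000, extra) == []
        far = [GenomicInterval("chr1", 17_000, 17_100, ".")]
        assert len(select_isolated_genes(genes, 4000, far)) == 1


class TestBlacklist:
    def _peak(self, start, end):
        return Peak(GenomicInterval("chr1", start, end), 1.0, "p")

    def test_one_bp_overlap_removes(self):
        bl = [GenomicInterval("chr1", 150, 160)]
        assert filter_blacklist([self._peak(100, 200)], bl) == []

    def test_half_open_adjacency_keeps(self):
        bl = [GenomicInterval("chr1", 200, 300)]
        assert len(filter_blacklist([self._peak(100, 200)], bl)) == 1

    def test_planted_enumeration_and_idempotence(self):
        rng = np.random.default_rng(7)
        bl = [GenomicInterval("chr1", 50_000, 60_000)]
        peaks = []
        inside = 0
        for i in range(10):
            if i < 3:
                s = int(rng.integers(50_000, 59_000))
                inside += 1
            else:
                s = int(rng.integers(0, 40_000))
            peaks.append(Peak(GenomicInterval("chr1", s, s + 500), 1.0, f"p{i}"))
        survivors = filter_blacklist(peaks, bl)
        assert len(survivors) == 7
        assert [p.name for p in survivors] == [p.name for p in peaks[3:]]
        # subset + idempotent
        assert all(p in peaks for p in survivors)
        assert filter_blacklist(survivors, bl) == survivors


def test_write_genes_round_trip(tmp_path):
    genes = [GeneModel("a", GenomicInterval("chr1", 10, 500, "+")),
             GeneModel("b", GenomicInterval("chr2", 20, 700, "-"))]
    path = tmp_path / "g.bed"
    write_genes_bed6(genes, path)
    back = read_genes(path, "bed6")
    assert [(g.gene_id, g.interval) for g in back] == \
        [(g.gene_id, g.interval) for g in genes]
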