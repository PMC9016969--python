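"""binding_signatures: windows, %GC, differential enrichment, context, overlap tests."""

import math

import numpy as np
import pandas as pd
import pytest

from emqtlkit.core_io import CpGManifest, GeneAnnotation, GenomicInterval, TFBSCollection
from emqtlkit.signatures import (
    RegionSet,
    annotate_genomic_context,
    differential_tfbs_enrichment,
    gc_content,
    list_overlap_fisher,
    window_regions,
)


def manifest_at(positions, chrom="chr1"):
    return CpGManifest(
        pd.DataFrame(
            {"chrom": chrom, "pos": positions},
            index=pd.Index([f"cg{i}" for i in range(len(positions))], name="probe_id"),
        )
    )


class TestWindowRegions:
    def test_plain_window(self):
        rs = window_regions(["cg0"], manifest_at([1000]), flank=200)
        assert (rs.regions[0].start, rs.regions[0].end) == (800, 1201)

    def test_clipping(self):
        rs = window_regions(["cg0"], manifest_at([50]), flank=200, chrom_sizes={"chr1": 10_000})
        assert (rs.regions[0].start, rs.regions[0].end) == (0, 251)

    def test_lengths_401_unless_clipped(self, rng):
        positions = rng.choice(np.arange(300, 9000), size=100, replace=False)
        rs = window_regions(
            [f"cg{i}" for i in range(100)], manifest_at(positions), flank=200,
            chrom_sizes={"chr1": 10_000},
        )
        for region, q in zip(rs.regions, positions):
            assert (region.start, region.end) == (q - 200, q + 201)
            assert region.length == 401

    def test_unknown_probe(self):
        with pytest.raises(KeyError):
            window_regions(["nope"], manifest_at([10]))

    def test_deduplication(self):
        rs = RegionSet("x", [GenomicInterval("chr1", 1, 5)] * 3)
        assert len(rs) == 1


class TestGcContent:
    @pytest.fixture()
    def fasta(self, tmp_path):
        p = tmp_path / "toy.fa"
        p.write_text(">chr1\nAAAAGCGCGCNNA\n")
        return str(p)

    def test_known_fractions(self, fasta):
        regions = [
            GenomicInterval("chr1", 0, 4),  # AAAA
            GenomicInterval("chr1", 4, 8),  # GCGC
            GenomicInterval("chr1", 8, 13),  # GCNNA
        ]
        np.testing.assert_allclose(gc_content(regions, fasta), [0.0, 1.0, 0.4])

    def test_out_of_contig(self, fasta):
        with pytest.raises(ValueError, match="beyond contig"):
            gc_content([GenomicInterval("chr1", 0, 99)], fasta)


class TestDifferentialEnrichment:
    def _sets(self):
        fg = RegionSet("fg", [GenomicInterval("chr1", i * 1000, i * 1000 + 401) for i in range(10)])
        ot = RegionSet("ot", [GenomicInterval("chr1", 100_000 + i * 1000, 100_000 + i * 1000 + 401) for i in range(20)])
        return fg, ot

    def test_closed_form_tail(self):
        fg, ot = self._sets()
        # sites hitting 8 foreground and 2 other regions
        sites = [GenomicInterval("chr1", i * 1000 + 100, i * 1000 + 110) for i in range(8)]
        sites += [GenomicInterval("chr1", 100_000 + i * 1000 + 100, 100_000 + i * 1000 + 110) for i in range(2)]
        rows = differential_tfbs_enrichment(fg, ot, TFBSCollection({"T": sites}))
        row = rows.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (8, 2, 2, 18)
        # hypergeometric upper tail of [[8,2],[2,18]]
        expected = sum(
            math.comb(10, k) * math.comb(20, 10 - k) for k in range(8, 11)
        ) / math.comb(30, 10)
        assert row["p"] == pytest.approx(expected, rel=1e-10)

    def test_empty_overlap_haldane(self):
        fg, ot = self._sets()
        sites = [GenomicInterval("chr2", 5, 10)]
        rows = differential_tfbs_enrichment(fg, ot, TFBSCollection({"T": sites}))
        row = rows.iloc[0]
        assert row["p"] == 1.0
        assert row["odds_ratio"] == pytest.approx((0.5 * 20.5) / (10.5 * 0.5))

    def test_swap_exchanges_counts(self):
        fg, ot = self._sets()
        sites = [GenomicInterval("chr1", 100, 110), GenomicInterval("chr1", 100_100, 100_110)]
        coll = TFBSCollection({"T": sites})
        fwd = differential_tfbs_enrichment(fg, ot, coll).iloc[0]
        rev = differential_tfbs_enrichment(ot, fg, coll).iloc[0]
        assert (fwd["a"], fwd["b"]) == (rev["c"], rev["d"])
        assert (fwd["c"], fwd["d"]) == (rev["a"], rev["b"])

    def test_overlapping_sets_rejected(self):
        fg, _ = self._sets()
        with pytest.raises(ValueError, match="disjoint"):
            differential_tfbs_enrichment(fg, fg, TFBSCollection({"T": []}))


class TestGenomicContext:
    @pytest.fixture()
    def annotation(self):
        df = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [5000, 20_000],
                "end": [8000, 24_000],
                "strand": ["+", "-"],
            },
            index=pd.Index(["GENEA", "GENEB"], name="gene_id"),
        )
        exons = {
            "GENEA": [GenomicInterval("chr1", 5000, 5400), GenomicInterval("chr1", 7500, 8000)],
            "GENEB": [GenomicInterval("chr1", 20_000, 20_500), GenomicInterval("chr1", 23_500, 24_000)],
        }
        return GeneAnnotation(df, exons)

    def test_promoter_upstream_strand_aware(self, annotation):
        # 300 bp upstream of GENEA's + strand TSS at 5000
        cats, _ = annotate_genomic_context(["cg0"], manifest_at([4700]), annotation)
        assert cats["cg0"] == "promoter"
        # GENEB is - strand with TSS at 23_999; 300 bp upstream means pos 24_299
        cats, _ = annotate_genomic_context(["cg0"], manifest_at([24_299]), annotation)
        assert cats["cg0"] == "promoter"

    def test_intron_between_exons(self, annotation):
        cats, _ = annotate_genomic_context(["cg0"], manifest_at([6000]), annotation)
        assert cats["cg0"] == "intron"

    def test_intergenic_far_away(self, annotation):
        cats, dist = annotate_genomic_context(["cg0"], manifest_at([60_000]), annotation)
        assert cats["cg0"] == "intergenic"
        assert dist.loc["intergenic", "count"] == 1

    def test_matches_brute_force_classifier(self, annotation, rng):
        positions = rng.integers(0, 30_000, size=300)
        probes = [f"cg{i}" for i in range(300)]
        cats, _ = annotate_genomic_context(probes, manifest_at(positions), annotation)

        def brute(q):
            for gid, row in annotation.df.iterrows():
                off = q - row["tss"] if row["strand"] == "+" else row["tss"] - q
                if -1000 <= off <= 100:
                    return "promoter"
            for gid, row in annotation.df.iterrows():
                if row["start"] <= q < row["end"]:
                    in_exon = any(iv.start <= q < iv.end for iv in annotation.exons[gid])
                    return "exon" if in_exon else "intron"
            return "intergenic"

        expected = [brute(int(q)) for q in positions]
        assert cats.tolist() == expected


class TestListOverlap:
    def test_single_shared_element(self):
        overlap, _, p = list_overlap_fisher({"x"}, {"x"}, universe_size=10)
        assert overlap == 1
        assert p == pytest.approx(0.1)

    def test_disjoint_sets(self):
        overlap, _, p = list_overlap_fisher({"a", "b"}, {"c", "d"}, universe_size=100)
        assert overlap == 0
        assert p == 1.0

    def test_pioneer_scale_tail_oracle(self):
        # 13-item list vs 34-item list, overlap 11, universe of 231 TFs
        a = {f"a{i}" for i in range(2)} | {f"s{i}" for i in range(11)}
        b = {f"b{i}" for i in range(23)} | {f"s{i}" for i in range(11)}
        overlap, _, p = list_overlap_fisher(a, b, universe_size=231)
        assert overlap == 11
        expected = sum(
            math.comb(34, k) * math.comb(231 - 34, 13 - k) for k in range(11, 14)
        ) / math.comb(231, 13)
        assert p == pytest.approx(expected, rel=1e-10)

    def test_universe_too_small(self):
        with pytest.raises(ValueError, match="universe"):
            list_overlap_fisher({"a"}, {"b"}, universe_size=1)
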