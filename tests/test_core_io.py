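"""core_io: domain-type invariants, file round trips, interval-index oracle."""

import numpy as np
import pandas as pd
import pytest

from emqtlkit.core_io import (
    CohortBundle,
    GenomicInterval,
    IntervalIndex,
    ParseError,
    SampleMatrix,
    align_cohort,
    normalize_chrom,
    read_bed,
    read_manifest,
    read_matrix,
    read_tfbs_bed,
    write_bed,
)


class TestGenomicInterval:
    def test_valid_fields(self):
        iv = GenomicInterval("chr1", 100, 110, name="FOXA1")
        assert (iv.chrom, iv.start, iv.end, iv.name, iv.length) == ("chr1", 100, 110, "FOXA1", 10)

    @pytest.mark.parametrize("start,end", [(110, 100), (100, 100), (-1, 5)])
    def test_invalid_coordinates(self, start, end):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", start, end)

    def test_point_distance(self):
        iv = GenomicInterval("chr1", 1100, 1110)
        assert iv.distance_to(900) == 200
        assert iv.distance_to(899) == 201
        assert iv.distance_to(1105) == 0
        assert iv.distance_to(1110) == 1


class TestBed:
    def test_read_fields_and_grouping(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t110\tFOXA1\n1\t50\t60\tGATA3\n")
        ivs = read_bed(p)
        assert ivs[0] == GenomicInterval("chr1", 100, 110)
        assert ivs[0].name == "FOXA1"
        assert ivs[1].chrom == "chr1"  # dialect normalised
        coll = read_tfbs_bed(p)
        assert coll.tf_names == ["FOXA1", "GATA3"]

    @pytest.mark.parametrize("line", ["chr1\t110\t100", "chr1\tx\t100"])
    def test_parse_error_names_line(self, tmp_path, line):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t1\t2\n" + line + "\n")
        with pytest.raises(ParseError, match="line 2"):
            read_bed(p)

    def test_round_trip_byte_identical(self, tmp_path):
        content = "chr1\t100\t110\tFOXA1\nchr1\t200\t215\tFOXA1\nchr2\t5\t30\tGATA3\n"
        src = tmp_path / "in.bed"
        src.write_text(content)
        dst = tmp_path / "out.bed"
        write_bed(read_bed(src), dst)
        assert dst.read_text() == content


class TestMatrix:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[0.1, 0.2, 0.3], [0.9, 0.8, 0.7]],
            index=pd.Index(["cg1", "cg2"], name="id"),
            columns=["S1", "S2", "S3"],
        )
        m = SampleMatrix(df, kind="methylation")
        p = tmp_path / "m.tsv"
        m.to_tsv(p)
        back = read_matrix(p, kind="methylation")
        assert back.row_ids == ["cg1", "cg2"]
        assert back.sample_ids == ["S1", "S2", "S3"]
        np.testing.assert_allclose(back.values, m.values, rtol=1e-5)

    def test_duplicate_row_id(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("id\tS1\ncg1\t0.5\ncg1\t0.6\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_matrix(p)

    def test_non_numeric_cell_reports_coordinates(self, tmp_path):
        p = tmp_path / "n.tsv"
        p.write_text("id\tS1\tS2\ncg1\t0.5\toops\n")
        with pytest.raises(ParseError, match="cg1.*S2"):
            read_matrix(p)

    def test_beta_out_of_range(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("id\tS1\ncg1\t1.2\n")
        with pytest.raises(ParseError, match=r"\[0,1\]"):
            read_matrix(p, kind="methylation")

    def test_empty_cell_becomes_missing(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("id\tS1\tS2\ncg1\t0.5\t\n")
        m = read_matrix(p, kind="methylation")
        assert np.isnan(m.values[0, 1])


class TestAlignCohort:
    def _mat(self, samples, kind="expression"):
        # value depends on the sample name, not its column position
        vals = np.array([[(ord(s[0]) - ord("A") + 1) / 10.0 for s in samples]])
        return SampleMatrix(pd.DataFrame(vals, index=["TF1"], columns=samples), kind=kind)

    def test_intersection(self):
        b = align_cohort("X", self._mat(["A", "B", "C", "E"]), self._mat(["B", "C", "D", "E"], "methylation"))
        assert b.samples == ["B", "C", "E"]

    def test_disjoint_errors(self):
        with pytest.raises(ValueError, match="no shared samples"):
            align_cohort("X", self._mat(["A", "B"]), self._mat(["C", "D"], "methylation"))

    def test_order_invariance(self):
        a = align_cohort("X", self._mat(["C", "A", "B", "D"]), self._mat(["B", "D", "C", "A"], "methylation"))
        b = align_cohort("X", self._mat(["A", "B", "C", "D"]), self._mat(["A", "B", "C", "D"], "methylation"))
        assert a.samples == b.samples
        pd.testing.assert_frame_equal(
            a.expression.data.sort_index(axis=1), b.expression.data.sort_index(axis=1)
        )

    def test_too_few_samples(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            align_cohort("X", self._mat(["A", "B"]), self._mat(["A", "B"], "methylation"))


class TestManifest:
    def test_one_based_conversion_and_chrom_dialect(self, tmp_path):
        p = tmp_path / "man.tsv"
        p.write_text("probe_id\tchrom\tpos\ncg1\t1\t1000\ncg2\tchr2\t50\n")
        man = read_manifest(p, one_based=True)
        assert man.df.loc["cg1", "pos"] == 999
        assert man.df.loc["cg1", "chrom"] == "chr1"
        man0 = read_manifest(p, one_based=False)
        assert man0.df.loc["cg1", "pos"] == 1000

    def test_unknown_probe_raises(self, toy_manifest):
        with pytest.raises(KeyError):
            toy_manifest.positions(["nope"])


class TestIntervalIndex:
    def test_matches_brute_force_scan(self, rng):
        chroms = ["chr1", "chr2"]
        intervals = [
            GenomicInterval(
                rng.choice(chroms), s := int(rng.integers(0, 5000)), s + int(rng.integers(1, 60))
            )
            for _ in range(200)
        ]
        index = IntervalIndex(intervals)
        for window in (0, 25, 200):
            pts = rng.integers(0, 5200, size=1000)
            for chrom in chroms:
                got = index.overlaps_points(chrom, pts, window=window)
                expected = np.array(
                    [
                        any(iv.distance_to(int(q)) <= window for iv in intervals if iv.chrom == chrom)
                        for q in pts
                    ]
                )
                np.testing.assert_array_equal(got, expected)

    def test_region_overlap_matches_brute_force(self, rng):
        intervals = [
            GenomicInterval("chr1", s := int(rng.integers(0, 3000)), s + int(rng.integers(1, 40)))
            for _ in range(120)
        ]
        index = IntervalIndex(intervals)
        starts = rng.integers(0, 3000, size=400)
        ends = starts + rng.integers(1, 100, size=400)
        got = index.overlaps_regions("chr1", starts, ends)
        expected = np.array(
            [
                any(iv.start < e and iv.end > s for iv in intervals)
                for s, e in zip(starts, ends)
            ]
        )
        np.testing.assert_array_equal(got, expected)


def test_normalize_chrom():
    assert normalize_chrom("7") == "chr7"
    assert normalize_chrom("chrX") == "chrX"
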