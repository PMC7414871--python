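import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from founderscan.errors import (
    MapLookupError,
    ParseError,
    ValidationError,
)
from founderscan.formats_io import (
    GeneticMap,
    IBDSegment,
    MaskRegions,
    interpolate_cm,
    read_genetic_map,
    read_mask_bed,
    read_phased_vcf,
    read_segments,
    write_segments,
)

from conftest import make_segment


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------

class TestGeneticMap:
    def test_two_anchor_parse(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1\ts1\t1.0\t1000000\n1\ts2\t2.0\t2000000\n")
        gmap = read_genetic_map(p)
        bp, cm = gmap.anchors("1")
        assert bp.tolist() == [1_000_000, 2_000_000]
        assert cm.tolist() == [1.0, 2.0]

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("")
        with pytest.raises(ValidationError):
            read_genetic_map(p)

    def test_decreasing_cm_rejected(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1\ts1\t2.0\t1000000\n1\ts2\t1.0\t2000000\n")
        with pytest.raises(ValidationError):
            read_genetic_map(p)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "m.map"
        p.write_text("1\ts1\t1.0\t1000000\n1\ts2\n")
        with pytest.raises(ParseError, match="line 2"):
            read_genetic_map(p)

    def test_single_anchor_rejected(self):
        with pytest.raises(ValidationError):
            GeneticMap({"1": (np.array([5]), np.array([1.0]))})

    @pytest.mark.parametrize("query,expected", [
        (1_500_000, 1.5),     # midpoint interpolation
        (1_000_000, 1.0),     # exactly at an anchor
        (500_000, 1.0),       # before first anchor -> clamped
        (3_000_000, 2.0),     # after last anchor -> clamped
    ])
    def test_interpolation(self, query, expected):
        gmap = GeneticMap({"1": (np.array([1_000_000, 2_000_000]),
                                 np.array([1.0, 2.0]))})
        assert interpolate_cm(gmap, "1", query) == pytest.approx(expected)

    def test_unknown_chromosome(self, simple_map):
        with pytest.raises(MapLookupError):
            simple_map.interpolate("99", 1000)

    @given(st.lists(st.integers(1, 10 ** 8), min_size=2, max_size=30,
                    unique=True),
           st.lists(st.floats(0, 200), min_size=2, max_size=30),
           st.lists(st.integers(1, 10 ** 8), min_size=5, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_interpolation_monotone(self, bps, cms, queries):
        n = min(len(bps), len(cms))
        bp = np.sort(np.array(bps[:n]))
        cm = np.sort(np.array(cms[:n]))
        gmap = GeneticMap({"1": (bp, cm)})
        q = np.sort(np.array(queries))
        out = gmap.interpolate("1", q)
        assert np.all(np.diff(out) >= -1e-12)

    def test_map_roundtrip(self, tmp_path, simple_map):
        p = tmp_path / "g.map"
        simple_map.write(p)
        back = read_genetic_map(p)
        bp0, cm0 = simple_map.anchors("1")
        bp1, cm1 = back.anchors("1")
        assert np.array_equal(bp0, bp1) and np.allclose(cm0, cm1)


# ---------------------------------------------------------------------------
# Segment TSV round-trip
# ---------------------------------------------------------------------------

segment_strategy = st.builds(
    lambda sa, ha, hb, chrom, s, length, c0, cl: IBDSegment(
        sample_a=f"A{sa}", hap_a=ha, sample_b=f"B{sa}", hap_b=hb,
        chrom=str(chrom), start_bp=s, end_bp=s + length,
        start_cm=c0, end_cm=c0 + cl, length_cm=cl),
    sa=st.integers(0, 99), ha=st.integers(0, 1), hb=st.integers(0, 1),
    chrom=st.integers(1, 22), s=st.integers(1, 10 ** 8),
    length=st.integers(0, 10 ** 7),
    c0=st.floats(0, 100, allow_nan=False),
    cl=st.floats(0, 50, allow_nan=False),
)


class TestSegmentIO:
    @given(segments=st.lists(segment_strategy, max_size=20))
    @settings(max_examples=25, deadline=None)
    def test_roundtrip_identity(self, segments, tmp_path_factory):
        p = tmp_path_factory.mktemp("seg") / "s.tsv"
        write_segments(segments, p)
        assert read_segments(p) == segments

    def test_empty_list_header_only(self, tmp_path):
        p = tmp_path / "s.tsv"
        write_segments([], p)
        assert p.read_text().count("\n") == 1
        assert read_segments(p) == []

    def test_unknown_column_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("sample_a\tfoo\nA\t1\n")
        with pytest.raises(ParseError):
            read_segments(p)

    def test_corrupted_row_rejected(self, tmp_path):
        p = tmp_path / "s.tsv"
        seg = make_segment(start_bp=100, end_bp=200, start_cm=1.0, end_cm=2.0)
        write_segments([seg], p)
        text = p.read_text().replace("\t100\t200\t", "\t300\t200\t")
        p.write_text(text)
        with pytest.raises(ValidationError):
            read_segments(p)


# ---------------------------------------------------------------------------
# Mask BED
# ---------------------------------------------------------------------------

class TestMaskBed:
    def test_overlapping_rows_merged(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("chr21\t100\t200\nchr21\t150\t300\n")
        mask = read_mask_bed(p)
        assert mask.intervals == [("chr21", 100, 300)]

    def test_empty_file(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("")
        assert len(read_mask_bed(p)) == 0

    def test_degenerate_interval_rejected(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("chr21\t100\t100\n")
        with pytest.raises(ValidationError):
            read_mask_bed(p)

    @given(st.lists(st.tuples(st.integers(0, 1000), st.integers(1, 100)),
                    min_size=1, max_size=20))
    @settings(max_examples=50, deadline=None)
    def test_merged_form_is_disjoint_and_sorted(self, raw):
        mask = MaskRegions([("1", s, s + l) for s, l in raw])
        runs = mask.for_chrom("1")
        for (s0, e0), (s1, e1) in zip(runs, runs[1:]):
            assert e0 < s1  # disjoint, non-adjacent, ordered


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1,length=1000000>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\n"
)


class TestPhasedVcf:
    def test_small_phased_file(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_HEADER
                     + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0|1\t1|1\n"
                     + "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|0\n"
                     + "1\t300\t.\tG\tA\t.\tPASS\t.\tGT\t1|0\t0|1\n")
        cohort = read_phased_vcf(p)
        assert cohort.haplotypes.shape == (2, 2, 3)
        assert cohort.haplotypes[0, 0].tolist() == [0, 0, 1]
        assert cohort.haplotypes[1, 1].tolist() == [1, 0, 1]

    def test_multiallelic_record_skipped(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_HEADER
                     + "1\t100\t.\tA\tG,T\t.\tPASS\t.\tGT\t0|1\t1|1\n"
                     + "1\t200\t.\tC\tT\t.\tPASS\t.\tGT\t0|0\t1|0\n")
        cohort = read_phased_vcf(p)
        assert cohort.n_variants == 1
        assert cohort.n_skipped_records == 1

    def test_unphased_genotype_rejected(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t1|1\n")
        with pytest.raises(ValidationError, match="unphased"):
            read_phased_vcf(p)

    def test_missing_genotype_rejected(self, tmp_path):
        p = tmp_path / "t.vcf"
        p.write_text(VCF_HEADER + "1\t100\t.\tA\tG\t.\tPASS\t.\tGT\t.|.\t1|1\n")
        with pytest.raises(ValidationError, match="missing"):
            read_phased_vcf(p)
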