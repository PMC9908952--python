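"""Coordinate model and format round-trips."""

import pytest

from ticlip.core import GenomicInterval, SiteTrack, TranscriptionUnit
from ticlip.io import (
    read_alignments,
    read_annotation,
    read_bedgraph,
    write_alignments,
    write_annotation,
    write_bedgraph,
)
from ticlip.simulate import SimConfig, make_annotation, simulate_timecourse

from conftest import make_pair


class TestGenomicInterval:
    @pytest.mark.parametrize(
        "start,end,strand",
        [(-1, 5, "+"), (5, 5, "+"), (7, 5, "-"), (0, 5, "."), (0, 5, "fwd")],
    )
    def test_invalid_rejected(self, start, end, strand):
        with pytest.raises(ValueError):
            GenomicInterval("c1", start, end, strand)

    def test_length_and_containment(self):
        iv = GenomicInterval("c1", 10, 20, "+")
        assert len(iv) == 10
        assert iv.contains(10) and iv.contains(19) and not iv.contains(20)


class TestTranscriptionUnit:
    def test_intron_is_interblock_gap(self):
        tu = TranscriptionUnit(
            "t", "c1", 0, 300, "+", exons=((0, 100), (200, 300))
        )
        assert tu.introns == ((100, 200),)

    def test_bp_distance_example(self, tiny_bundle):
        # BP 20 nt upstream of the 3'SS on both strands
        assert tiny_bundle.introns["TUP.i0"].dist_bp_to_3ss == 20
        assert tiny_bundle.introns["TUM.i0"].dist_bp_to_3ss == 20

    def test_malformed_blocks_rejected(self):
        with pytest.raises(ValueError):
            TranscriptionUnit(
                "t", "c1", 0, 300, "+", exons=((0, 150), (100, 300))
            )

    def test_mature_projection_strand_symmetry(self):
        plus = TranscriptionUnit("p", "c1", 0, 300, "+", exons=((0, 100), (200, 300)))
        minus = TranscriptionUnit("m", "c1", 0, 300, "-", exons=((0, 100), (200, 300)))
        assert plus.genome_to_mature(0) == 0
        assert plus.genome_to_mature(200) == 100
        assert minus.genome_to_mature(299) == 0
        assert minus.genome_to_mature(150) is None
        assert plus.mature_length == minus.mature_length == 200


class TestBedgraph:
    def test_adjacent_equal_values_merged(self, tmp_path):
        track = SiteTrack({("c1", "+", 5): 2.0, ("c1", "+", 6): 2.0})
        plus, minus = write_bedgraph(track, tmp_path / "t")
        assert plus.read_text() == "c1\t5\t7\t2\n"
        assert minus.read_text() == ""

    def test_empty_track_gives_empty_files(self, tmp_path):
        plus, minus = write_bedgraph(SiteTrack(), tmp_path / "t")
        assert plus.read_text() == "" and minus.read_text() == ""

    def test_round_trip_identity(self, tmp_path):
        track = SiteTrack(
            {
                ("c1", "+", 5): 2.0,
                ("c1", "+", 6): 3.5,
                ("c2", "-", 0): 1.0,
                ("c1", "-", 100): 0.25,
            }
        )
        plus, minus = write_bedgraph(track, tmp_path / "t")
        back = read_bedgraph(plus, minus)
        assert back.entries == track.entries


class TestAlignmentIO:
    def test_simulator_round_trip(self, tmp_path):
        cfg = SimConfig(
            seed=2, reads_per_library=300, n_replicates=1,
            timepoints={"t30": 30.0},
        )
        ann = make_annotation(5, 2, cfg)
        libs, _ = simulate_timecourse(ann, cfg)
        pairs = libs[("t30", "rep1")]
        path = tmp_path / "lib.sam"
        write_alignments(pairs, path, ann.chrom_sizes)
        back = read_alignments(path)
        assert len(back) == len(pairs)
        by_name = {p.name: p for p in back}
        for orig in pairs:
            got = by_name[orig.name]
            assert got.read1_blocks == orig.read1_blocks
            assert got.read2_blocks == orig.read2_blocks
            assert got.strand == orig.strand
            assert got.umi == orig.umi and got.barcode == orig.barcode
            assert got.mismatches == orig.mismatches

    def test_secondary_and_unmapped_filtered(self, tmp_path):
        path = tmp_path / "mixed.sam"
        lines = [
            "@HD\tVN:1.6",
            "@SQ\tSN:c1\tLN:10000",
            # proper pair
            "a#AC#GGGG\t99\tc1\t101\t60\t30M\t=\t101\t30\t*\t*",
            "a#AC#GGGG\t147\tc1\t101\t60\t30M\t=\t101\t-30\t*\t*",
            # secondary alignment of the same pair
            "a#AC#GGGG\t355\tc1\t501\t60\t30M\t=\t501\t30\t*\t*",
            # unmapped pair
            "b#AC#TTTT\t77\t*\t0\t0\t*\t*\t0\t0\t*\t*",
            "b#AC#TTTT\t141\t*\t0\t0\t*\t*\t0\t0\t*\t*",
        ]
        path.write_text("\n".join(lines) + "\n")
        pairs = read_alignments(path)
        assert [p.name for p in pairs] == ["a"]
        assert pairs[0].read1_blocks == ((100, 130),)


class TestAnnotationIO:
    def test_round_trip(self, tmp_path):
        cfg = SimConfig(seed=3)
        ann = make_annotation(12, 3, cfg)
        write_annotation(ann, tmp_path)
        back = read_annotation(
            tmp_path / "tus.bed12",
            tmp_path / "bp.bed",
            tmp_path / "sno.bed",
            tmp_path / "rrna.bed",
            tmp_path / "chrom.sizes",
        )
        assert set(back.tus) == set(ann.tus)
        for tu_id, tu in ann.tus.items():
            got = back.tus[tu_id]
            assert (got.start, got.end, got.strand, got.exons, got.is_rrna) == (
                tu.start, tu.end, tu.strand, tu.exons, tu.is_rrna
            )
        for iid, iv in ann.introns.items():
            assert back.introns[iid].bp_pos == iv.bp_pos
        for sid, sno in ann.snornas.items():
            got = back.snornas[sid]
            assert (got.start, got.end, got.sno_class, got.host_intron_id) == (
                sno.start, sno.end, sno.sno_class, sno.host_intron_id
            )

    def test_bp_outside_introns_rejected(self, tmp_path):
        (tmp_path / "tus.bed12").write_text(
            "c1\t0\t300\tT\t0\t+\t0\t300\t0\t2\t100,100,\t0,200,\n"
        )
        (tmp_path / "bp.bed").write_text("c1\t50\t51\tT.i0\t0\t+\n")  # exonic
        with pytest.raises(ValueError, match="outside"):
            read_annotation(tmp_path / "tus.bed12", tmp_path / "bp.bed")
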