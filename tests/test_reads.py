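"""Demultiplexing, deduplication and read deconstruction rules."""

import pytest

from ticlip.reads import (
    classify_splice_status,
    crosslink_sites,
    deduplicate,
    demultiplex,
    exon_junction_table,
    three_prime_sites,
    whole_read_coverage,
)

from conftest import make_pair


class TestDemultiplex:
    def test_exact_match_and_undetermined(self):
        table = {"ACGT": "s1"}
        hit = make_pair(barcode="ACGT")
        miss = make_pair(name="r1", barcode="ACGA")
        out = demultiplex([hit, miss], table, max_mismatch=0)
        assert [p.name for p in out["s1"]] == ["r0"]
        assert [p.name for p in out["undetermined"]] == ["r1"]

    def test_one_mismatch_tolerated(self):
        out = demultiplex(
            [make_pair(barcode="ACGA")], {"ACGT": "s1", "TGCA": "s2"},
            max_mismatch=1,
        )
        assert len(out["s1"]) == 1

    def test_collision_is_configuration_error(self):
        with pytest.raises(ValueError, match="collision"):
            demultiplex([], {"ACGT": "s1", "ACGA": "s2"}, max_mismatch=1)

    def test_simulator_counts_match_ground_truth(self, intron_sim):
        _cfg, _ann, libraries, gt = intron_sim
        pooled = [p for pairs in libraries.values() for p in pairs]
        barcodes = sorted({p.barcode for p in pooled})
        table = {bc: f"sample_{bc}" for bc in barcodes}
        out = demultiplex(pooled, table)
        gt_counts = gt["barcode"].value_counts().to_dict()
        for bc in barcodes:
            assert len(out[f"sample_{bc}"]) == gt_counts[bc]
        assert not out["undetermined"]


class TestDeduplicate:
    def test_same_umi_same_start_collapsed(self):
        a = make_pair(name="a", umi="AAAA")
        b = make_pair(name="b", umi="AAAA")
        assert [p.name for p in deduplicate([a, b])] == ["a"]

    def test_distinct_umis_kept(self):
        a = make_pair(name="a", umi="AAAA")
        b = make_pair(name="b", umi="AAAT")
        assert len(deduplicate([a, b])) == 2

    def test_idempotent(self, intron_sim):
        _cfg, _ann, libraries, _gt = intron_sim
        pairs = next(iter(libraries.values()))
        once = deduplicate(pairs)
        assert deduplicate(once) == once

    def test_empty_input(self):
        assert deduplicate([]) == []


class TestCrosslinkSites:
    def test_plus_strand_one_upstream(self):
        track = crosslink_sites([make_pair(r1=((100, 130),), strand="+")])
        assert track.entries == {("c1", "+", 99): 1.0}

    def test_minus_strand_one_upstream(self):
        track = crosslink_sites([make_pair(r1=((100, 130),), strand="-")])
        assert track.entries == {("c1", "-", 130): 1.0}

    def test_site_before_origin_dropped_and_counted(self):
        track = crosslink_sites([make_pair(r1=((0, 30),), strand="+")])
        assert track.entries == {} and track.dropped == 1

    def test_site_never_inside_read1_span(self, intron_sim_pairs):
        sample = intron_sim_pairs[:2000]
        track = crosslink_sites(sample)
        spans = {
            (p.chrom, p.strand): (p.read1_blocks[0][0], p.read1_blocks[-1][1])
            for p in sample
        }
        for p in sample:
            site = p.read1_five_prime + (-1 if p.strand == "+" else 1)
            if site >= 0:
                assert not (p.read1_blocks[0][0] <= site < p.read1_blocks[-1][1])

    def test_conservation(self, intron_sim_pairs):
        track = crosslink_sites(intron_sim_pairs)
        assert track.total() + track.dropped == len(intron_sim_pairs)


class TestThreePrimeSites:
    def test_plus_rna_fragment_end(self):
        p = make_pair(r1=((100, 130),), r2=((180, 210),), strand="+")
        track = three_prime_sites([p])
        assert track.entries == {("c1", "+", 209): 1.0}

    def test_minus_rna_fragment_end(self):
        p = make_pair(r1=((180, 210),), r2=((100, 130),), strand="-")
        track = three_prime_sites([p])
        assert track.entries == {("c1", "-", 100): 1.0}

    def test_coordinate_last_convention_differs_on_minus(self):
        p = make_pair(r1=((180, 210),), r2=((100, 130),), strand="-")
        track = three_prime_sites([p], convention="coordinate_last")
        assert track.entries == {("c1", "-", 129): 1.0}

    def test_sno_extension_termini_match_ground_truth(self, intron_sim):
        _cfg, ann, libraries, gt = intron_sim
        sno_rows = gt[(gt["sno_id"] != "") & (~gt["is_pcr_duplicate"])]
        assert len(sno_rows) > 50
        pooled = [p for pairs in libraries.values() for p in pairs]
        by_name = {p.name: p for p in pooled}
        for _, row in sno_rows.head(300).iterrows():
            pair = by_name[row["name"]]
            track = three_prime_sites([pair])
            ((_, _, pos),) = track.entries
            sno = ann.snornas[row.sno_id]
            sgn = 1 if sno.strand == "+" else -1
            assert pos == sno.three_prime_end + sgn * int(row.extension_offset)


class TestWholeReadCoverage:
    def test_single_block(self):
        track = whole_read_coverage([make_pair(r1=((100, 130),))])
        assert track.total() == 30
        assert track.get("c1", "+", 100) == 1 and track.get("c1", "+", 129) == 1

    def test_gap_excluded(self):
        track = whole_read_coverage([make_pair(r1=((100, 110), (210, 220)))])
        assert track.total() == 20
        assert track.get("c1", "+", 150) == 0

    def test_mass_conserves_aligned_length(self, intron_sim_pairs):
        sample = intron_sim_pairs[:500]
        track = whole_read_coverage(sample)
        assert track.total() == sum(p.read1_length for p in sample)


class TestClassifySpliceStatus:
    ROWS = [("e0", "c1", "+", 50, 100, 200, 260, "first")]

    def _counts(self, pairs):
        df = classify_splice_status(pairs, self.ROWS)
        return int(df.spliced.iloc[0]), int(df.non_spliced.iloc[0])

    def test_junction_read_is_spliced(self):
        p = make_pair(r1=((90, 100), (200, 210)))
        assert self._counts([p]) == (1, 0)

    def test_contiguous_into_intron_is_non_spliced(self):
        p = make_pair(r1=((90, 105),))
        assert self._counts([p]) == (0, 1)

    def test_ending_at_exon_end_is_neither(self):
        p = make_pair(r1=((90, 100),))
        assert self._counts([p]) == (0, 0)

    def test_minus_strand_orientation(self):
        rows = [("e0", "c1", "-", 200, 260, 50, 100, "first")]
        spliced = make_pair(strand="-", r1=((90, 100), (200, 210)))
        non = make_pair(strand="-", r1=((195, 230),))
        df = classify_splice_status([spliced, non], rows)
        assert (int(df.spliced.iloc[0]), int(df.non_spliced.iloc[0])) == (1, 1)

    def test_simulator_junction_reads_classified(self, intron_sim):
        """Spliced-molecule reads crossing a first-exon junction must be
        called spliced, never non-spliced."""
        from ticlip.simulate import SimConfig, make_annotation, simulate_timecourse

        cfg = SimConfig(
            seed=21, reads_per_library=4000, n_replicates=1,
            factor_model="CAP_ANCHORED", timepoints={"t60": 60.0},
            rrna_fraction=0.0,
        )
        ann = make_annotation(20, 21, cfg)
        libs, gt = simulate_timecourse(ann, cfg)
        pairs = deduplicate(libs[("t60", "rep1")])
        df = classify_splice_status(pairs, exon_junction_table(ann))
        assert df.spliced.sum() > 0
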