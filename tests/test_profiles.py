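"""Metagene profiles, wave velocity, mature profiles and clustering."""

import math

import numpy as np
import pytest

from ticlip.core import SiteTrack, TranscriptionUnit
from ticlip.profiles import (
    ProfileMatrix,
    estimate_wave_velocity,
    exon_anchored_profile,
    exon_rank_density,
    junction_density_profile,
    kmeans_profile_groups,
    mature_profile,
    spatiotemporal_matrix,
    three_prime_end_histogram,
)
from ticlip.reads import crosslink_sites, deduplicate
from ticlip.simulate import SimConfig, make_annotation, simulate_timecourse


def _tu(tu_id="T", length=25_000, strand="+", exons=None, start=0):
    end = start + length
    return TranscriptionUnit(
        tu_id, "c1", start, end, strand,
        exons=tuple(exons) if exons else ((start, end),),
    )


class TestSpatiotemporalMatrix:
    def test_group_label_and_bin_count(self):
        tu = _tu(length=25_000)
        track = SiteTrack({("c1", "+", 100): 1.0})
        pm = spatiotemporal_matrix(track, [tu])
        assert pm.row_ids == ["[20,30)kb"]
        assert np.isfinite(pm.values[0]).sum() == 25

    def test_group_max_normalization(self):
        tu = _tu(length=3_000)
        entries = {}
        for b, n in ((0, 2), (1, 4), (2, 8)):
            for i in range(n):
                entries[("c1", "+", b * 1000 + i)] = 1.0
        pm = spatiotemporal_matrix(SiteTrack(entries), [tu])
        row = pm.values[0][:3]
        assert row == pytest.approx([0.25, 0.5, 1.0])
        assert pm.normalized

    def test_cap_anchored_t00_mass_in_first_bin(self):
        cfg = SimConfig(
            seed=15, reads_per_library=4000, n_replicates=1,
            factor_model="CAP_ANCHORED", rrna_fraction=0.0,
            timepoints={"t00": 0.0},
        )
        ann = make_annotation(20, 15, cfg)
        libs, _ = simulate_timecourse(ann, cfg)
        track = crosslink_sites(deduplicate(libs[("t00", "rep1")]))
        tus = [t for t in ann.tus.values() if not t.is_rrna]
        total = in_first = 0.0
        for (c, s, pos), w in track.entries.items():
            for tu in tus:
                if tu.chrom == c and tu.strand == s and tu.start <= pos < tu.end:
                    total += w
                    if tu.genome_to_premrna(pos) < 1000:
                        in_first += w
                    break
        assert total > 0 and in_first / total > 0.90

    def test_intronic_only_scope(self):
        tu = _tu(length=3_000, exons=((0, 1000), (2000, 3000)))
        track = SiteTrack({("c1", "+", 500): 1.0, ("c1", "+", 1500): 1.0})
        pm_all = spatiotemporal_matrix(track, [tu])
        pm_intron = spatiotemporal_matrix(track, [tu], read_scope="intronic_only")
        assert np.nansum(pm_all.values) > np.nansum(pm_intron.values) > 0


class TestWaveVelocity:
    @staticmethod
    def _matrix(front_bins, n_bins=120):
        vals = np.zeros((1, n_bins))
        vals[0, :front_bins] = 1.0
        return ProfileMatrix(
            row_ids=["g"], col_labels=list(range(n_bins)), values=vals,
            normalized=True,
        )

    def test_two_point_slope(self):
        mats = {
            float(m): self._matrix(round(3.5 * m))
            for m in (5, 10, 20, 30)
        }
        est = estimate_wave_velocity(mats)
        assert est.velocity_kb_per_min == pytest.approx(3.5, rel=0.05)
        assert est.r_squared > 0.99

    def test_stationary_profiles_give_zero_slope(self):
        mats = {float(m): self._matrix(40) for m in (5, 15, 30, 60)}
        est = estimate_wave_velocity(mats)
        assert est.velocity_kb_per_min == pytest.approx(0.0, abs=1e-9)

    def test_too_few_timepoints_rejected(self):
        mats = {5.0: self._matrix(17), 10.0: self._matrix(35)}
        with pytest.raises(ValueError, match="usable wave fronts"):
            estimate_wave_velocity(mats)

    def test_saturated_groups_excluded(self):
        # a fully-invaded short group carries no wave information
        mats = {
            float(m): self._matrix(min(round(3.5 * m), 120))
            for m in (5, 10, 20, 30, 45, 60)
        }
        est = estimate_wave_velocity(mats)
        assert est.velocity_kb_per_min == pytest.approx(3.5, rel=0.05)
        assert 60.0 not in est.front_kb_by_timepoint  # front hit the TES


class TestExonAnchoredProfile:
    def test_offset_orientation_plus(self):
        tu = _tu(length=2_000, exons=((0, 1001), (1500, 2000)))
        track = SiteTrack({("c1", "+", 975): 1.0})
        offsets, prof = exon_anchored_profile(track, [tu], "first", "3p")
        assert prof[list(offsets).index(-25)] == 1.0

    def test_offset_orientation_minus(self):
        tu = _tu(length=2_000, strand="-", exons=((0, 500), (999, 2000)))
        # first exon is the right-most block; its 3' end (last nt) is 999
        track = SiteTrack({("c1", "-", 1024): 1.0})
        offsets, prof = exon_anchored_profile(track, [tu], "first", "3p")
        assert prof[list(offsets).index(-25)] == 1.0

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            exon_anchored_profile(SiteTrack(), [], "first", "3p", window=200)

    def test_ejc_simulation_mode_near_minus_25(self):
        cfg = SimConfig(
            seed=16, reads_per_library=8000, n_replicates=1,
            factor_model="EXON3P_EJC", rrna_fraction=0.0,
            timepoints={"DMSO": math.inf},
        )
        ann = make_annotation(30, 16, cfg)
        libs, _ = simulate_timecourse(ann, cfg)
        track = crosslink_sites(deduplicate(libs[("DMSO", "rep1")]))
        tus = [t for t in ann.tus.values() if not t.is_rrna]
        offsets, prof = exon_anchored_profile(track, tus, "internal", "3p")
        mode_offset = offsets[int(np.argmax(prof))]
        assert abs(mode_offset - (-25)) <= 3


class TestThreePrimeEndHistogram:
    def test_all_signal_at_exon_end(self):
        tu = _tu(length=2_000, exons=((0, 1000), (1500, 2000)))
        track = SiteTrack({("c1", "+", 999): 3.0})
        offsets, prof, at_zero = three_prime_end_histogram(track, [tu])
        assert at_zero == 3.0
        assert prof.sum() == at_zero

    def test_empty_track(self):
        tu = _tu(length=2_000, exons=((0, 1000), (1500, 2000)))
        _, prof, at_zero = three_prime_end_histogram(SiteTrack(), [tu])
        assert at_zero == 0.0 and not prof.any()

    def test_first_step_signal_rises_then_falls(self):
        """First-exon-end 3'CLIP tracks the transient post-1st-step pool:
        low while splicing has not started, peaking mid-course, relaxing
        towards steady state."""
        from ticlip.reads import three_prime_sites

        cfg = SimConfig(
            seed=17, reads_per_library=12000, n_replicates=1,
            factor_model="CAP_ANCHORED", rrna_fraction=0.0,
            timepoints={"t00": 0.0, "t15": 15.0, "DMSO": math.inf},
        )
        ann = make_annotation(40, 17, cfg)
        libs, _ = simulate_timecourse(ann, cfg)
        tus = [t for t in ann.tus.values() if not t.is_rrna]
        at_zero = {}
        for tp in cfg.timepoints:
            track = three_prime_sites(deduplicate(libs[(tp, "rep1")]))
            _, _, at_zero[tp] = three_prime_end_histogram(track, tus)
        assert at_zero["t15"] > at_zero["t00"]
        assert at_zero["t15"] > at_zero["DMSO"]


class TestExonRankDensity:
    def test_uniform_track_equal_densities(self):
        tu = _tu(
            length=9_500,
            exons=tuple((i * 1000, i * 1000 + 500) for i in range(10)),
        )
        track = SiteTrack(
            {("c1", "+", p): 1.0 for s, e in tu.exons for p in range(s, e, 10)}
        )
        dens = exon_rank_density(track, [tu])
        assert dens["first4"] == pytest.approx(dens["last4"])
        assert dens["first4"] == pytest.approx(dens["internal"])

    def test_empty_track_zero(self):
        tu = _tu(length=3_000, exons=((0, 1000), (2000, 3000)))
        dens = exon_rank_density(SiteTrack(), tu and [tu])
        assert set(dens.values()) == {0.0}


class TestMatureProfile:
    def test_all_signal_in_first_bin(self):
        tu = _tu(length=1_000)
        track = SiteTrack({("c1", "+", i): 2.5 for i in range(10)})
        mp = mature_profile(track, tu)
        assert not mp.excluded
        assert mp.bin_values[0] == pytest.approx(1.0)
        assert mp.bin_values[1:].sum() == 0.0

    def test_short_tu_excluded(self):
        tu = _tu(length=150)
        mp = mature_profile(SiteTrack(), tu)
        assert mp.excluded_reason == "length"

    def test_exactly_20_reads_excluded(self):
        tu = _tu(length=1_000)
        track = SiteTrack({("c1", "+", i): 1.0 for i in range(20)})
        assert mature_profile(track, tu).excluded_reason == "reads"
        track.add("c1", "+", 25)
        assert not mature_profile(track, tu).excluded

    def test_intronic_signal_ignored(self):
        tu = _tu(length=2_000, exons=((0, 500), (1500, 2000)))
        track = SiteTrack({("c1", "+", 1000): 100.0})
        assert mature_profile(track, tu).excluded_reason == "reads"

    def test_strand_mirror_reverses_profile(self):
        length = 1_000
        plus = _tu(tu_id="P", length=length, strand="+")
        minus = _tu(tu_id="M", length=length, strand="-")
        rng = np.random.default_rng(0)
        positions = rng.integers(0, length, 500)
        t_plus = SiteTrack()
        t_minus = SiteTrack()
        for pos in positions:
            t_plus.add("c1", "+", int(pos))
            t_minus.add("c1", "-", int(length - 1 - pos))
        p = mature_profile(t_plus, plus).bin_values
        m = mature_profile(t_minus, minus).bin_values
        assert p == pytest.approx(m)


class TestKmeansGroups:
    @staticmethod
    def _planted(seed, n_each=40, n_background=120):
        rng = np.random.default_rng(seed)
        x = np.arange(100)
        arch1 = np.exp(-0.5 * ((x - 5) / 3.0) ** 2) + 0.25 * np.exp(
            -0.5 * ((x - 95) / 3.0) ** 2
        )
        arch2 = np.exp(-0.5 * ((x - 95) / 3.0) ** 2)
        profiles = {}
        truth = {}
        for i in range(n_each):
            profiles[f"A{i}"] = arch1 + rng.normal(0, 0.05, 100)
            truth[f"A{i}"] = "group1"
        for i in range(n_each):
            profiles[f"B{i}"] = arch2 + rng.normal(0, 0.05, 100)
            truth[f"B{i}"] = "group2"
        for i in range(n_background):
            profiles[f"N{i}"] = 0.1 + rng.normal(0, 0.05, 100)
        out = {}
        for k, v in profiles.items():
            v = np.clip(v, 0, None)
            out[k] = v / v.sum()
        return out, truth

    def test_identical_replicates_keep_per_replicate_clustering(self):
        profiles, _ = self._planted(1)
        groups = kmeans_profile_groups(
            {"rep1": profiles, "rep2": profiles}, k=3, seed=0,
            report_background=True,
        )
        assert sum(len(m) for m in groups.groups.values()) == len(profiles)

    def test_planted_archetypes_recovered(self):
        reps = {
            "rep1": self._planted(1)[0],
            "rep2": self._planted(2)[0],
        }
        truth = self._planted(1)[1]
        groups = kmeans_profile_groups(reps, k=3, seed=0)
        assert set(groups.groups) == {"group1", "group2"}
        correct = sum(
            1
            for tu, g in truth.items()
            if tu in groups.groups[g]
        )
        assert correct / len(truth) >= 0.95

    def test_deterministic(self):
        reps = {"rep1": self._planted(1)[0], "rep2": self._planted(2)[0]}
        a = kmeans_profile_groups(reps, k=3, seed=0)
        b = kmeans_profile_groups(reps, k=3, seed=0)
        assert a.groups == b.groups

    def test_groups_disjoint(self):
        reps = {"rep1": self._planted(1)[0], "rep2": self._planted(2)[0]}
        groups = kmeans_profile_groups(reps, k=3, seed=0).groups
        labels = list(groups)
        for i, a in enumerate(labels):
            for b in labels[i + 1 :]:
                assert not (groups[a] & groups[b])

    def test_k_larger_than_profiles_rejected(self):
        profs = {"rep1": {"a": np.ones(100)}, "rep2": {"a": np.ones(100)}}
        with pytest.raises(ValueError):
            kmeans_profile_groups(profs, k=3, seed=0)


class TestJunctionDensity:
    def test_single_junction_position(self):
        tu = _tu(length=1_000, exons=((0, 100), (500, 1000)))
        # junction at mature offset 99 of 600 -> bin 16
        prof = junction_density_profile([tu])
        assert prof[99 * 100 // 600] == 1.0
        assert prof.sum() == 1.0

    def test_mono_exonic_contributes_zeros(self):
        prof = junction_density_profile([_tu(length=1_000)])
        assert not prof.any()

    def test_short_first_exons_enrich_cap_proximal_quartile(self):
        short_first = [
            _tu(
                tu_id=f"S{i}", length=10_000,
                exons=((0, 120), (1000, 1200), (3000, 3200), (9000, 10_000)),
            )
            for i in range(3)
        ]
        long_first = [
            _tu(
                tu_id=f"L{i}", length=10_000,
                exons=((0, 5000), (7000, 7200), (9000, 10_000)),
            )
            for i in range(3)
        ]
        ps = junction_density_profile(short_first)
        pl = junction_density_profile(long_first)
        assert ps[:25].sum() > pl[:25].sum()
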