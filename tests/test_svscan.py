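"""Unit and property tests for the windowed alternate-read scanner."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cheatkit.svscan import (
    ALTERNATE,
    DISCORDANT_FLAGS,
    NORMAL,
    AlignmentObservation,
    UnmappedRecordError,
    classify_alignment,
    compare_profiles,
    flag_is_discordant,
    profiles_from_alignment_file,
    tile_windows,
    window_profiles,
)
from cheatkit.synthetic import SimulationConfig, simulate_alignments

from conftest import per_base_coverage_oracle, random_observations


class TestFlagFilter:
    def test_listed_flags_are_discordant(self):
        for flag in (67, 131, 115, 179, 81, 161, 97, 145, 65, 129, 113, 177):
            assert flag_is_discordant(flag)

    def test_proper_pair_flags_are_not(self):
        assert not flag_is_discordant(99)
        assert not flag_is_discordant(147)

    def test_exhaustive_scan_finds_exactly_twelve(self):
        hits = [f for f in range(4096) if flag_is_discordant(f)]
        assert sorted(hits) == sorted(DISCORDANT_FLAGS)
        assert len(hits) == 12

    def test_negative_flag_rejected(self):
        with pytest.raises(ValueError):
            flag_is_discordant(-1)


class TestClassification:
    @pytest.mark.parametrize(
        "cigar,flag,expected",
        [
            ((("M", 50), ("S", 10)), 99, ALTERNATE),  # soft clip
            ((("H", 5), ("M", 95)), 99, ALTERNATE),  # hard clip
            ((("M", 40), ("I", 3), ("M", 57)), 99, ALTERNATE),  # insertion
            ((("M", 40), ("D", 3), ("M", 60)), 99, ALTERNATE),  # deletion
            ((("M", 100),), 99, NORMAL),
            ((("M", 100),), 177, ALTERNATE),  # listed flag, clean CIGAR
            ((("M", 100),), 0, NORMAL),
        ],
    )
    def test_labels(self, cigar, flag, expected):
        obs = AlignmentObservation(flag=flag, contig="c", pos=0, cigar=cigar)
        assert classify_alignment(obs) == expected

    def test_unmapped_record_excluded(self):
        obs = AlignmentObservation(flag=4, contig="", pos=0, cigar=(("M", 10),))
        with pytest.raises(UnmappedRecordError):
            classify_alignment(obs)

    def test_classification_partitions_mapped_records(self, rng):
        obs = random_observations(rng, 2000, 300)
        labels = [classify_alignment(o) for o in obs]
        assert labels.count(ALTERNATE) + labels.count(NORMAL) == len(obs)


class TestTiling:
    def test_truncated_final_window(self):
        assert tile_windows(250, 100) == [(0, 100), (100, 200), (200, 250)]

    def test_single_window(self):
        assert tile_windows(100, 100) == [(0, 100)]

    def test_genome_scale_window_count(self):
        # ceil(41_102_378 / 100) — a full fungal-genome tiling
        assert len(tile_windows(41_102_378, 100)) == 411_024

    @pytest.mark.parametrize("length,window", [(0, 100), (100, 0), (-5, 100)])
    def test_invalid_inputs(self, length, window):
        with pytest.raises(ValueError):
            tile_windows(length, window)


class TestWindowProfiles:
    def test_all_normal_reads_give_zero_fraction(self):
        windows = tile_windows(100, 100)
        obs = [
            AlignmentObservation(flag=99, contig="c", pos=0, cigar=(("M", 100),))
            for _ in range(10)
        ]
        (profile,) = window_profiles(obs, windows)
        assert profile.alt_fraction == 0.0
        assert profile.total_coverage == 1000

    def test_all_alternate_reads_give_fraction_one(self):
        windows = tile_windows(100, 100)
        obs = [
            AlignmentObservation(flag=177, contig="c", pos=0, cigar=(("M", 100),))
            for _ in range(5)
        ]
        (profile,) = window_profiles(obs, windows)
        assert profile.alt_fraction == 1.0

    def test_zero_coverage_window_has_missing_fraction(self):
        windows = tile_windows(200, 100)
        obs = [AlignmentObservation(flag=99, contig="c", pos=0, cigar=(("M", 50),))]
        profiles = window_profiles(obs, windows)
        assert profiles[1].total_coverage == 0
        assert profiles[1].alt_fraction is None

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_per_base_oracle(self, seed):
        """Window totals agree with brute-force per-base depth accumulation."""
        rng = np.random.default_rng(seed)
        contig_length = 1500
        obs = random_observations(rng, contig_length, 200)
        windows = tile_windows(contig_length, 100)
        profiles = window_profiles(obs, windows)
        oracle = per_base_coverage_oracle(obs, contig_length, windows)
        for prof, (alt, total) in zip(profiles, oracle):
            assert prof.alt_coverage == alt
            assert prof.total_coverage == total

    def test_coverage_conservation(self, rng):
        """Summed window coverage equals total reference-consuming bases."""
        contig_length = 3000
        obs = random_observations(rng, contig_length, 150)
        windows = tile_windows(contig_length, 100)
        profiles = window_profiles(obs, windows)
        expected = sum(min(o.reference_end, contig_length) - o.pos for o in obs)
        assert sum(p.total_coverage for p in profiles) == expected

    def test_alt_fraction_scale_invariant(self, rng):
        """Duplicating the whole read set leaves every fraction unchanged."""
        obs = random_observations(rng, 1000, 80)
        windows = tile_windows(1000, 100)
        single = window_profiles(obs, windows)
        doubled = window_profiles(obs + obs, windows)
        for p1, p2 in zip(single, doubled):
            assert p2.total_coverage == 2 * p1.total_coverage
            assert p1.alt_fraction == p2.alt_fraction

    def test_mismatched_contig_rejected(self):
        windows = tile_windows(200, 100)
        obs = [
            AlignmentObservation(flag=99, contig="a", pos=0, cigar=(("M", 50),)),
            AlignmentObservation(flag=99, contig="b", pos=0, cigar=(("M", 50),)),
        ]
        with pytest.raises(ValueError):
            window_profiles(obs, windows)

    def test_mapq_filter_off_by_default(self, rng):
        obs = random_observations(rng, 500, 50)
        windows = tile_windows(500, 100)
        total_all = sum(p.total_coverage for p in window_profiles(obs, windows))
        total_q20 = sum(p.total_coverage for p in window_profiles(obs, windows, min_mapq=20))
        assert total_q20 <= total_all


class TestCompareProfiles:
    def test_identical_profiles_all_zero(self, rng):
        obs = random_observations(rng, 1000, 100)
        windows = tile_windows(1000, 100)
        profiles = window_profiles(obs, windows)
        table = compare_profiles(profiles, profiles)
        assert (table["abs_diff"] == 0).all()
        assert list(table["rank"]) == list(range(1, len(table) + 1))

    def test_zero_coverage_window_absent(self):
        windows = tile_windows(200, 100)
        covered = [AlignmentObservation(flag=99, contig="c", pos=0, cigar=(("M", 200),))]
        half = [AlignmentObservation(flag=99, contig="c", pos=0, cigar=(("M", 100),))]
        table = compare_profiles(window_profiles(covered, windows), window_profiles(half, windows))
        assert len(table) == 1
        assert table.iloc[0]["start"] == 0

    def test_mismatched_tilings_rejected(self):
        obs = [AlignmentObservation(flag=99, contig="c", pos=0, cigar=(("M", 100),))]
        p100 = window_profiles(obs, tile_windows(200, 100))
        p50 = window_profiles(obs, tile_windows(200, 50))
        with pytest.raises(ValueError):
            compare_profiles(p100, p50)

    def test_implanted_deletion_ranks_breakpoint_windows_first(self):
        """Ancestor/evolved comparison puts breakpoint-adjacent windows on top."""
        cfg = SimulationConfig(deletion=(1000, 300))
        obs_evo, truth = simulate_alignments(cfg, seed=11)
        obs_anc, _ = simulate_alignments(SimulationConfig(deletion=None), seed=12)
        windows = tile_windows(cfg.reference_length, cfg.window)
        table = compare_profiles(
            window_profiles(obs_anc, windows), window_profiles(obs_evo, windows)
        )
        truth_windows = set(truth["window_start"])
        top2 = set(table.head(2)["start"])
        assert top2 <= truth_windows


class TestFileInput:
    def test_sam_round_trip_matches_in_memory_profiles(self, tmp_path):
        cfg = SimulationConfig()
        sam = tmp_path / "clone.sam"
        obs, _ = simulate_alignments(cfg, seed=5, out_sam=str(sam))
        by_contig = profiles_from_alignment_file(str(sam), window=cfg.window)
        windows = tile_windows(cfg.reference_length, cfg.window)
        direct = window_profiles(obs, windows)
        assert [p.total_coverage for p in by_contig[cfg.contig]] == [
            p.total_coverage for p in direct
        ]
        assert [p.alt_coverage for p in by_contig[cfg.contig]] == [
            p.alt_coverage for p in direct
        ]


@settings(max_examples=50, deadline=None)
@given(
    flag=st.integers(min_value=0, max_value=4095),
    clip=st.integers(min_value=0, max_value=20),
)
def test_alternate_iff_clip_or_listed_flag(flag, clip):
    """The alternate set is exactly the union of clip/indel CIGARs and listed flags."""
    cigar = (("M", 80),) if clip == 0 else (("M", 80), ("S", clip))
    obs = AlignmentObservation(flag=flag, contig="c", pos=0, cigar=cigar)
    expected = ALTERNATE if (clip > 0 or flag in DISCORDANT_FLAGS) else NORMAL
    assert classify_alignment(obs) == expected
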