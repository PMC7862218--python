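"""Tests for the synthetic-data generators: determinism, inverse
relationships with the analysis stages, and the transfer-cycle dynamics."""

from __future__ import annotations

import numpy as np
import pytest

from cheatkit.svscan import ALTERNATE, classify_alignment
from cheatkit.synthetic import (
    SimulationConfig,
    load_config,
    simulate_alignments,
    simulate_competitions,
    simulate_plate_counts,
    simulate_qpcr_ct,
    simulate_transfer_series,
    success_function,
)


class TestAlignmentSimulation:
    def test_same_seed_identical_sam_bytes(self, tmp_path):
        cfg = SimulationConfig()
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        simulate_alignments(cfg, seed=7, out_sam=str(p1))
        simulate_alignments(cfg, seed=7, out_sam=str(p2))
        assert p1.read_bytes() == p2.read_bytes()

    def test_different_seed_differs(self, tmp_path):
        cfg = SimulationConfig()
        p1, p2 = tmp_path / "a.sam", tmp_path / "b.sam"
        simulate_alignments(cfg, seed=7, out_sam=str(p1))
        simulate_alignments(cfg, seed=8, out_sam=str(p2))
        assert p1.read_bytes() != p2.read_bytes()

    def test_no_deletion_means_background_alternate_only(self):
        cfg = SimulationConfig(deletion=None, background_clip_rate=0.01)
        obs, truth = simulate_alignments(cfg, seed=1)
        assert truth.empty
        alt_rate = sum(classify_alignment(o) == ALTERNATE for o in obs) / len(obs)
        assert alt_rate <= 0.05

    def test_zero_background_gives_zero_alternate(self):
        cfg = SimulationConfig(deletion=None, background_clip_rate=0.0)
        obs, _ = simulate_alignments(cfg, seed=1)
        assert all(classify_alignment(o) != ALTERNATE for o in obs)

    def test_deletion_produces_clips_and_discordant_pairs(self):
        cfg = SimulationConfig(deletion=(1000, 300), background_clip_rate=0.0)
        obs, truth = simulate_alignments(cfg, seed=2)
        clipped = [o for o in obs if any(op == "S" for op, _ in o.cigar)]
        discordant = [o for o in obs if o.flag in (97, 145)]
        assert clipped and discordant
        assert set(truth["breakpoint"]) == {1000, 1300}

    def test_depth_close_to_configured(self):
        cfg = SimulationConfig(deletion=None, mean_depth=30.0)
        obs, _ = simulate_alignments(cfg, seed=3)
        total_bases = sum(o.reference_span for o in obs)
        assert total_bases / cfg.reference_length == pytest.approx(30.0, rel=0.1)

    def test_infeasible_geometry_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(reference_length=1000, deletion=(500, 600))


class TestQpcrSimulation:
    def test_half_frequency_zero_delta(self):
        m = simulate_qpcr_ct(0.5, noise_sd=0.0, seed=1)
        assert np.mean(m.ct_so) - np.mean(m.ct_hygB) == pytest.approx(0.0, abs=1e-12)

    def test_eighty_twenty_gives_delta_two(self):
        m = simulate_qpcr_ct(0.8, efficiency=2.0, noise_sd=0.0, seed=1)
        assert np.mean(m.ct_so) - np.mean(m.ct_hygB) == pytest.approx(2.0, abs=1e-12)

    def test_boundary_frequency_censored_at_ceiling(self):
        m = simulate_qpcr_ct(0.0, noise_sd=0.0, seed=1)
        assert all(v == m.max_cycles for v in m.ct_hygB)
        m = simulate_qpcr_ct(1.0, noise_sd=0.0, seed=1)
        assert all(v == m.max_cycles for v in m.ct_so)

    def test_same_seed_reproducible(self):
        m1 = simulate_qpcr_ct(0.3, noise_sd=0.1, seed=42)
        m2 = simulate_qpcr_ct(0.3, noise_sd=0.1, seed=42)
        assert m1.ct_so == m2.ct_so and m1.ct_hygB == m2.ct_hygB


class TestPlateSimulation:
    def test_exact_mode_inverts_deconvolution(self):
        from cheatkit.platecount import deconvolve_genotypes

        truth = (0.55, 0.35, 0.10)
        t = simulate_plate_counts(truth, colonies_per_plate=400, n_plates=4, exact=True)
        f = deconvolve_genotypes(t)
        assert f.as_tuple() == pytest.approx(truth, abs=1e-12)

    def test_no_heterokaryons_no_unsupplemented_growth(self):
        t = simulate_plate_counts((0.6, 0.4, 0.0), colonies_per_plate=400, n_plates=4, seed=1)
        assert t.count_none == 0

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate_counts((0.5, 0.5, 0.5))

    def test_zero_colonies_rejected(self):
        with pytest.raises(ValueError):
            simulate_plate_counts((0.5, 0.4, 0.1), colonies_per_plate=0)


class TestTransferSeries:
    def test_neutral_infinite_population_constant(self):
        cfg = SimulationConfig(selection_strength=0.0, het_formation_rate=0.0)
        traj = simulate_transfer_series(cfg, infinite_population=True)
        assert len(traj) == cfg.n_transfers + 1
        assert np.allclose(traj["f_cheater_nuclear"], cfg.initial_cheater_frequency)

    def test_converges_to_configured_equilibrium(self):
        """Starting below the S(f) root, the trajectory stabilises near it."""
        cfg = SimulationConfig(het_formation_rate=0.0, initial_cheater_frequency=0.1)
        traj = simulate_transfer_series(cfg, infinite_population=True, n_transfers=20)
        assert traj["f_cheater_nuclear"].iloc[-1] == pytest.approx(0.30, abs=0.01)

    def test_same_seed_identical_trajectories(self):
        cfg = SimulationConfig()
        t1 = simulate_transfer_series(cfg, seed=5)
        t2 = simulate_transfer_series(cfg, seed=5)
        assert t1.equals(t2)

    def test_heterokaryons_accumulate(self):
        cfg = SimulationConfig(het_formation_rate=0.2)
        traj = simulate_transfer_series(cfg, seed=1)
        assert traj["f_heterokaryon"].iloc[-1] > 0.05

    def test_yield_declines_with_cheater_frequency(self):
        cfg = SimulationConfig(initial_cheater_frequency=0.5, het_formation_rate=0.0,
                               selection_strength=0.0)
        traj = simulate_transfer_series(cfg, infinite_population=True)
        low = SimulationConfig(initial_cheater_frequency=0.05, het_formation_rate=0.0,
                               selection_strength=0.0)
        traj_low = simulate_transfer_series(low, infinite_population=True)
        assert traj["spore_yield"].iloc[-1] < traj_low["spore_yield"].iloc[-1]

    def test_bottleneck_sampling_unbiased(self):
        """Multinomial bottleneck preserves expected frequency over 1,000 draws."""
        rng = np.random.default_rng(123)
        f = 0.27
        n = 2000
        means = [rng.binomial(n, f) / n for _ in range(1000)]
        assert float(np.mean(means)) == pytest.approx(f, abs=0.005)
        # and through the simulator: one stochastic transfer, neutral dynamics
        cfg = SimulationConfig(selection_strength=0.0, het_formation_rate=0.0,
                               initial_cheater_frequency=f, yield_decline=0.0,
                               yield_max=2.0e5)
        finals = []
        for seed in range(1000):
            traj = simulate_transfer_series(cfg, seed=seed, n_transfers=1)
            finals.append(traj["f_cheater_nuclear"].iloc[-1])
        assert float(np.mean(finals)) == pytest.approx(f, abs=0.005)


class TestCompetitionSimulation:
    def test_records_cross_one_near_equilibrium(self):
        cfg = SimulationConfig()
        recs = simulate_competitions(cfg, [0.05, 0.1, 0.2, 0.3, 0.4, 0.5], seed=3)
        below = [r.S for r in recs if r.f_initial < 0.2]
        above = [r.S for r in recs if r.f_initial > 0.4]
        assert np.mean(below) > 1.0 > np.mean(above)


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "sim.yaml"
        path.write_text(
            "seed: 3\nreference_length: 4000\ndeletion: [800, 200]\n"
            "true_frequencies: [0.5, 0.4, 0.1]\nbottleneck_fraction: 0.02\n"
        )
        cfg = load_config(str(path))
        assert cfg.deletion == (800, 200)
        assert cfg.bottleneck_fraction == 0.02
        assert cfg.reference_length == 4000

    def test_invalid_bottleneck_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(bottleneck_fraction=0.0)
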