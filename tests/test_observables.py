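"""Observable extraction: gaps, pelotons, profiles, fits, bursts."""

import math
import random

import numpy as np
import pytest

from pelotons.model import LatticeState, ModelParams
from pelotons.observables import (burst_statistics, estimate_profiles,
                                  fit_gap_distribution, fit_relaxation,
                                  gap_sizes, identify_pelotons,
                                  peloton_stats)
from pelotons.simulate import run
from pelotons.theory import predict, relative_profiles


def ring_params(**kw):
    base = dict(L=10, delta_m=1, delta_rb=1, k_ip=1.0, k_tp=0.3, k_b=0.1,
                boundary="periodic", n_motors=0)
    base.update(kw)
    return ModelParams(**base)


class TestGapSizes:
    def test_two_motors_on_ring(self):
        p = ring_params()
        s = LatticeState(0.0, motors=(0, 5), roadblocks=())
        assert [g for g, _ in gap_sizes(s, p)] == [4, 4]

    def test_single_motor_ring_gap(self):
        p = ring_params()
        s = LatticeState(0.0, motors=(3,), roadblocks=())
        assert [g for g, _ in gap_sizes(s, p)] == [p.L - p.delta_m]

    def test_classification_uniform(self):
        p = ring_params()
        s = LatticeState(0.0, motors=(0, 5), roadblocks=(2,))
        assert gap_sizes(s, p) == [(4, True), (4, False)]

    def test_classification_dyad_uses_dyad_site(self):
        # footprint 10-12, dyad 11: a gap covering only site 10 of the
        # footprint holds no dyad and stays intra-peloton
        p = ModelParams(L=40, delta_m=1, delta_rb=3, k_ip=1.0, k_tp=0.3,
                        boundary="open", interaction="dyad")
        s = LatticeState(0.0, motors=(5, 20), roadblocks=(10,))
        assert gap_sizes(s, p) == [(14, True)]
        s2 = LatticeState(0.0, motors=(5, 11), roadblocks=(10,))
        assert gap_sizes(s2, p) == [(5, False)]

    def test_random_states_match_site_scan_oracle(self):
        rnd = random.Random(21)
        p = ring_params(L=20)
        for _ in range(80):
            sites = rnd.sample(range(20), rnd.randint(2, 10))
            k = rnd.randint(2, len(sites))
            motors = tuple(sorted(sites[:k]))
            rbs = tuple(sorted(sites[k:]))
            s = LatticeState(0.0, motors, rbs)
            got = gap_sizes(s, p)
            ms = sorted(motors)
            for j, (gap, trans) in enumerate(got):
                a = ms[j]
                b = ms[(j + 1) % len(ms)]
                between = [(a + 1 + i) % 20
                           for i in range((b - a - 1) % 20)]
                assert gap == len(between)
                assert trans == any(site in rbs for site in between)


class TestPelotons:
    def test_no_roadblocks_single_peloton(self):
        p = ring_params()
        s = LatticeState(0.0, motors=(0, 2, 7), roadblocks=())
        assert identify_pelotons(s, p) == [[0, 1, 2]]

    def test_roadblock_in_every_gap_all_singletons(self):
        p = ring_params()
        s = LatticeState(0.0, motors=(0, 3, 6), roadblocks=(1, 4, 8))
        assert sorted(map(len, identify_pelotons(s, p))) == [1, 1, 1]

    def test_sizes_sum_to_motor_count(self, brm_mid_run):
        for s in brm_mid_run.snapshots[::50]:
            groups = identify_pelotons(s, brm_mid_run.params)
            assert sum(map(len, groups)) == len(s.motors)

    def test_matches_brute_force_partition(self):
        rnd = random.Random(5)
        p = ring_params(L=24)
        for _ in range(50):
            sites = rnd.sample(range(24), rnd.randint(2, 12))
            k = rnd.randint(1, len(sites))
            motors = tuple(sorted(sites[:k]))
            rbs = tuple(sorted(sites[k:]))
            s = LatticeState(0.0, motors, rbs)
            groups = identify_pelotons(s, p)
            # brute force: motors i,i+1 joined iff no roadblock between
            n = len(motors)
            joined = []
            for j in range(n if n > 1 else 0):
                a, b = motors[j], motors[(j + 1) % n]
                span = [(a + 1 + i) % 24 for i in range((b - a - 1) % 24)]
                joined.append(not any(x in rbs for x in span))
            # count groups: number of False links (or 1 if all joined)
            if n == 1:
                expected_groups = 1
            else:
                cuts = sum(1 for flag in joined if not flag)
                expected_groups = cuts if cuts > 0 else 1
            assert len(groups) == expected_groups
            assert sum(map(len, groups)) == n


class TestGapDistributionFit:
    def test_geometric_sample_recovered(self):
        rng = np.random.default_rng(2)
        gaps = rng.geometric(0.3, size=20000) - 1
        fit = fit_gap_distribution(gaps, seed=1)
        assert fit.p_single == pytest.approx(0.3, abs=0.01)
        assert fit.preferred == "single"

    def test_two_component_mixture_recovered(self):
        rng = np.random.default_rng(3)
        a = rng.geometric(0.6, size=12000) - 1
        b = rng.geometric(0.05, size=8000) - 1
        fit = fit_gap_distribution(np.concatenate([a, b]), seed=1)
        assert fit.preferred == "mixture"
        assert fit.p_intra == pytest.approx(0.6, abs=0.05)
        assert fit.p_trans == pytest.approx(0.05, abs=0.01)
        assert fit.weight_intra == pytest.approx(0.6, abs=0.05)

    def test_degenerate_sample_flagged(self):
        fit = fit_gap_distribution(np.full(500, 7), seed=1)
        assert fit.degenerate and fit.preferred == "single"

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            fit_gap_distribution([])

    def test_intra_gaps_below_trans_gaps_in_peloton_regime(self, brm_mid_run):
        intra, trans = [], []
        for s in brm_mid_run.snapshots:
            for g, is_trans in gap_sizes(s, brm_mid_run.params):
                (trans if is_trans else intra).append(g)
        assert np.mean(intra) < np.mean(trans)


class TestProfiles:
    def test_footprint_accounting(self, table1_high_run):
        """Sum of motor occupancy over sites equals delta_m times the
        time-averaged motor count."""
        traj = table1_high_run
        prof = estimate_profiles(traj)
        snaps = [s for s in traj.snapshots
                 if traj.burn_in <= s.time < traj.t_max]
        mean_count = np.mean([len(s.motors) for s in snaps])
        assert prof.rho_m.sum() == pytest.approx(
            traj.params.delta_m * mean_count, rel=1e-6)

    def test_front_time_totals_match_presence(self, table1_high_run):
        """Every motor has exactly one front: total front residence time
        equals integrated motor presence."""
        traj = table1_high_run
        prof = estimate_profiles(traj)
        snaps = [s for s in traj.snapshots
                 if traj.burn_in <= s.time < traj.t_max]
        mean_count = np.mean([len(s.motors) for s in snaps])
        span = traj.t_max - traj.burn_in
        assert prof.front_time.sum() == pytest.approx(
            mean_count * span, rel=0.02)  # snapshot vs event-log estimate

    def test_single_free_motor_flat_density(self):
        p = ModelParams(L=150, delta_m=1, delta_rb=1, k_ip=2.0, k_tp=2.0,
                        k_in=0.01, k_b=0.0, boundary="open")
        traj = run(p, t_max=100000.0, dt_sample=5.0, burn_in=1000.0, seed=3)
        prof = estimate_profiles(traj, bin_size=30)
        # occupancy flat along the lattice; velocity ~ k_ip everywhere
        assert prof.rho_m.std() / prof.rho_m.mean() < 0.1
        assert np.nanmean(prof.v_m) == pytest.approx(2.0, rel=0.05)

    def test_peloton_formation_shape(self, table1_high_run):
        """Density rises and velocity falls over the formation region."""
        traj = table1_high_run
        prof = estimate_profiles(traj, smooth=traj.params.delta_rb)
        pred = predict(traj.params)
        near = slice(30, 130)
        far = slice(1500, 2800)
        assert prof.rho_m[near].mean() < 0.75 * prof.rho_m[far].mean()
        v_near = prof.step_counts[near].sum() / prof.front_time[near].sum()
        v_far = prof.step_counts[far].sum() / prof.front_time[far].sum()
        assert v_near > 1.15 * v_far
        assert v_far == pytest.approx(pred.v_m_final, rel=0.15)


class TestRelaxationFit:
    def test_exact_curve_recovered(self):
        x = np.arange(0, 2000, dtype=float)
        y = 0.013 - 0.006 * np.exp(-x / 280.0)
        fit = fit_relaxation(x, y, x_p_guess=280.0)
        assert fit.x_p_hat == pytest.approx(280.0, rel=1e-6)
        assert fit.amplitude == pytest.approx(0.006, rel=1e-6)
        assert fit.offset == pytest.approx(0.013, rel=1e-6)

    def test_noisy_curve_recovered(self):
        rng = np.random.default_rng(4)
        x = np.arange(0, 1600, dtype=float)
        y = 1.0 - 0.5 * np.exp(-x / 300.0) + rng.normal(0, 0.01, x.size)
        fit = fit_relaxation(x, y, x_p_guess=300.0)
        assert fit.x_p_hat == pytest.approx(300.0, rel=0.1)

    def test_guess_can_be_off(self):
        x = np.arange(0, 4000, dtype=float)
        y = 2.0 - 1.0 * np.exp(-x / 500.0)
        fit = fit_relaxation(x, y, x_p_guess=800.0)
        assert fit.x_p_hat == pytest.approx(500.0, rel=1e-4)

    def test_too_few_points_raise(self):
        with pytest.raises(ValueError):
            fit_relaxation(np.arange(3.0), np.ones(3), x_p_guess=100.0)


class TestBurstStatistics:
    def test_poisson_stream_fano_near_one(self):
        rng = np.random.default_rng(6)
        times = np.cumsum(rng.exponential(2.0, size=20000))
        bs = burst_statistics(times, window=60.0)
        assert bs.fano == pytest.approx(1.0, abs=0.15)
        assert bs.mean_rate == pytest.approx(0.5, rel=0.05)

    def test_counts_reproducible_from_times(self):
        times = np.array([1.0, 2.0, 2.5, 61.0, 125.0])
        bs = burst_statistics(times, window=60.0, t0=0.0, t1=180.0)
        assert bs.counts.tolist() == [3, 1, 1]
        assert bs.interarrivals.size == 4

    def test_invalid_window_raises(self):
        with pytest.raises(ValueError):
            burst_statistics(np.arange(5.0), window=0.0)


class TestPelotonStats:
    def test_window_filters_by_leader_front(self, table1_high_run):
        traj = table1_high_run
        all_stats = peloton_stats(traj)
        end_stats = peloton_stats(traj, x_window=(2400, 2900))
        assert all_stats.sizes.size > end_stats.sizes.size > 0
        # formed pelotons near the gene end are larger than the mixture of
        # forming and formed ones over the whole gene
        assert end_stats.mean_size > all_stats.mean_size
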