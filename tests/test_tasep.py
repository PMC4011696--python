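"""Stochastic lattice simulator: exclusion, conservation, stationarity,
segment averaging, periodicity scoring, mean-field comparison."""

import numpy as np
import pytest

import periflow as pf


def constant_schedule(n, rates):
    return pf.RateSchedule(n, [pf.constant(r) for r in rates])


@pytest.fixture(scope="module")
def small_trace():
    sched = constant_schedule(5, [0.8] + [1.0] * 5)
    cfg = pf.TASEPConfig(n_sites=5, schedule=sched, dt=0.01, t_final=500.0,
                         seed=11, segment_length=10.0)
    return pf.simulate_tasep(cfg)


class TestSimulator:
    def test_vanishing_initiation_leaves_lattice_empty(self):
        # positivity of rates is enforced, so "no initiation" is probed with
        # a rate so small that no entry fits in the horizon
        sched = constant_schedule(3, [1e-9, 1.0, 1.0, 1.0])
        cfg = pf.TASEPConfig(n_sites=3, schedule=sched, dt=0.01, t_final=200.0,
                             seed=0, segment_length=10.0)
        trace = pf.simulate_tasep(cfg)
        assert trace.entries == 0
        assert trace.occupancy.sum() == 0

    def test_exclusion_invariant(self, small_trace):
        assert small_trace.occupancy.max() <= 1
        assert small_trace.occupancy.min() == 0

    def test_particle_conservation(self, small_trace):
        on_lattice = small_trace.occupancy[-1].sum()
        assert small_trace.entries - small_trace.exits == on_lattice
        # running conservation: occupancy total changes by +-1 per event
        totals = small_trace.occupancy.sum(axis=1).astype(np.int64)
        assert np.all(np.abs(np.diff(totals)) <= small_trace.config.n_sites)

    def test_single_site_two_state_stationary_law(self):
        # n = 1, constant rates: occupancy is a two-state Markov chain with
        # stationary probability lambda0 / (lambda0 + lambda1)
        lam0, lam1 = 0.7, 1.3
        sched = constant_schedule(1, [lam0, lam1])
        cfg = pf.TASEPConfig(n_sites=1, schedule=sched, dt=0.01,
                             t_final=100_000.0, seed=21, segment_length=200.0)
        trace = pf.simulate_tasep(cfg)
        burn = trace.n_slots // 4
        occ = trace.occupancy[burn:, 0]
        p_hat = occ.mean()
        p = lam0 / (lam0 + lam1)
        # standard error from segment (batch) means
        seg = trace.segment_averages(200.0)
        seg = seg[len(seg) // 4:, 0]
        se = seg.std(ddof=1) / np.sqrt(len(seg))
        assert abs(p_hat - p) < 3 * se

    def test_same_seed_bit_identical(self):
        sched = constant_schedule(3, [0.9, 1.0, 1.1, 1.0])
        cfg = pf.TASEPConfig(n_sites=3, schedule=sched, dt=0.01, t_final=300.0,
                             seed=5, segment_length=10.0)
        a = pf.simulate_tasep(cfg)
        b = pf.simulate_tasep(cfg)
        np.testing.assert_array_equal(a.occupancy, b.occupancy)
        assert a.entries == b.entries and a.exits == b.exits

    def test_footprint_blocks_close_packing(self):
        # footprint 2: simultaneous occupancies never exceed n // 2 particles
        sched = constant_schedule(6, [2.0] + [1.0] * 6)
        cfg = pf.TASEPConfig(n_sites=6, schedule=sched, dt=0.01, t_final=200.0,
                             seed=2, segment_length=10.0, footprint=2)
        trace = pf.simulate_tasep(cfg)
        assert trace.occupancy.max() <= 1
        # entries require the first two sites empty; particles cover 2 sites
        # except while sliding off the end
        assert trace.entries > 0

    def test_coarse_dt_warns(self):
        sched = constant_schedule(2, [1.0, 1.0, 1.0])
        cfg = pf.TASEPConfig(n_sites=2, schedule=sched, dt=0.5, t_final=50.0,
                             seed=1, segment_length=5.0)
        with pytest.warns(UserWarning, match="coarse"):
            pf.simulate_tasep(cfg)


class TestSegmentAverage:
    def test_full_and_empty_lattices(self, small_trace):
        n_seg = small_trace.n_slots // 1000
        ones = pf.TASEPTrace(
            config=small_trace.config,
            occupancy=np.ones_like(small_trace.occupancy),
            entries=0, exits=0, exit_slots=np.array([], dtype=np.int64),
            n_events=0,
        )
        assert np.all(pf.segment_average(ones, 10.0) == 1.0)
        zeros = pf.TASEPTrace(
            config=small_trace.config,
            occupancy=np.zeros_like(small_trace.occupancy),
            entries=0, exits=0, exit_slots=np.array([], dtype=np.int64),
            n_events=0,
        )
        assert np.all(pf.segment_average(zeros, 10.0) == 0.0)

    def test_linearity_of_doubled_segments(self, small_trace):
        a = pf.segment_average(small_trace, 10.0)
        b = pf.segment_average(small_trace, 20.0)
        paired = a[: 2 * len(b)].reshape(-1, 2, a.shape[1]).mean(axis=1)
        np.testing.assert_allclose(paired, b, atol=1e-12)

    def test_misaligned_segment_rejected(self, small_trace):
        with pytest.raises(ValueError, match="multiple"):
            pf.segment_average(small_trace, 10.005)


class TestPeriodicityScore:
    def test_exactly_periodic_series_scores_zero(self):
        series = np.tile([0.1, 0.5, 0.9, 0.5], 8)
        assert pf.periodicity_score(series, T=4.0, L=1.0) == 0.0

    def test_white_noise_scores_order_one(self):
        rng = np.random.default_rng(0)
        scores = [
            pf.periodicity_score(rng.normal(size=64), T=8.0, L=1.0)
            for _ in range(100)
        ]
        assert 0.2 < np.median(scores) < 1.0

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match="4 periods"):
            pf.periodicity_score(np.arange(6, dtype=float), T=2.0, L=1.0)

    def test_tasep_demo_beats_phase_shuffled_null(self):
        sched, _ = pf.make_scenario("tasep_demo", 8, seed=3)
        T = sched.T
        cfg = pf.TASEPConfig(n_sites=8, schedule=sched, dt=0.01,
                             t_final=100 * T, seed=1, segment_length=2.0)
        trace = pf.simulate_tasep(cfg)
        seg = trace.segment_averages(2.0)
        series = seg[len(seg) // 4:, 0]  # discard burn-in
        score = pf.periodicity_score(series, T, 2.0)
        null = pf.periodicity_null(series, T, 2.0, n_shuffles=200, seed=99)
        assert score < np.percentile(null, 5)


class TestMeanFieldComparison:
    def test_single_site_matches_closed_form(self):
        sched = constant_schedule(1, [1.0, 1.0])
        cfg = pf.TASEPConfig(n_sites=1, schedule=sched, dt=0.01,
                             t_final=20_000.0, seed=13, segment_length=100.0)
        cmp = pf.compare_tasep_rfm(cfg, replicates=3)
        assert cmp.equilibrium[0] == pytest.approx(0.5, abs=1e-10)
        assert abs(cmp.mean_occupancy[0] - 0.5) < 0.02

    def test_multi_site_positive_correlation(self):
        sched = constant_schedule(10, [0.6] + [1.0] * 10)
        cfg = pf.TASEPConfig(n_sites=10, schedule=sched, dt=0.01,
                             t_final=3000.0, seed=17, segment_length=100.0)
        cmp = pf.compare_tasep_rfm(cfg, replicates=4)
        assert cmp.correlation > 0
        assert np.isfinite(cmp.relative_flux_error)
        assert np.isfinite(cmp.flux_ci_halfwidth)

    def test_zero_replicates_rejected(self):
        sched = constant_schedule(2, [1.0, 1.0, 1.0])
        cfg = pf.TASEPConfig(n_sites=2, schedule=sched, dt=0.01, t_final=100.0,
                             seed=0, segment_length=10.0)
        with pytest.raises(ValueError):
            pf.compare_tasep_rfm(cfg, replicates=0)

    def test_periodic_rates_rejected(self):
        sched, _ = pf.make_scenario("tasep_demo", 3, seed=0)
        cfg = pf.TASEPConfig(n_sites=3, schedule=sched, dt=0.01, t_final=100.0,
                             seed=0, segment_length=10.0)
        with pytest.raises(ValueError, match="constant"):
            pf.compare_tasep_rfm(cfg, replicates=2)
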