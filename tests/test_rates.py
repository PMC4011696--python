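"""Rate primitives: evaluation conventions, period arithmetic, bounds, noise."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import periflow as pf
from periflow.rates import RateSpec


class TestEvaluation:
    def test_constant_is_flat(self):
        sched = pf.RateSchedule(2, [pf.constant(1.0)] * 3)
        assert np.allclose(pf.evaluate_rates(sched, 17.3), [1.0, 1.0, 1.0])

    def test_sinusoid_quarter_period(self):
        s = pf.sinusoid(baseline=1.0, amplitude=0.5, period=2 * np.pi)
        assert s(np.pi / 2) == pytest.approx(1.5)

    def test_square_wave_halves(self):
        s = pf.square_wave(baseline=2.0, amplitude=1.0, period=4.0)
        assert s(1.0) == 3.0  # first half-period: baseline + amplitude
        assert s(3.0) == 1.0  # second half-period: baseline - amplitude
        # half-open convention at the discontinuities
        assert s(0.0) == 3.0
        assert s(2.0) == 1.0
        assert s(4.0) == 3.0

    def test_negative_time_rejected(self):
        s = pf.sinusoid(1.0, 0.5, 2.0)
        with pytest.raises(ValueError):
            s(-0.1)
        sched = pf.RateSchedule(1, [pf.constant(1.0), pf.constant(1.0)])
        with pytest.raises(ValueError):
            pf.evaluate_rates(sched, -1.0)

    def test_values_within_schedule_bounds(self):
        sched, _ = pf.make_scenario("entrain_demo", 4, seed=7)
        for t in np.linspace(0, 3 * sched.T, 301):
            v = pf.evaluate_rates(sched, t)
            assert np.all(v >= sched.delta1 - 1e-12)
            assert np.all(v <= sched.delta2 + 1e-12)

    def test_periodicity_on_grid(self):
        sched, _ = pf.make_scenario("entrain_demo", 3, seed=2)
        T = sched.T
        ts = np.linspace(0.0, T, 57)
        for s in sched.specs:
            np.testing.assert_allclose(s(ts), s(ts + T), rtol=0, atol=1e-12)


class TestValidation:
    def test_amplitude_must_stay_below_baseline(self):
        with pytest.raises(ValueError, match="zero"):
            pf.sinusoid(baseline=1.0, amplitude=1.0, period=2.0)

    def test_constant_reports_period_none(self):
        assert pf.constant(2.7).period is None
        with pytest.raises(ValueError):
            RateSpec(kind="constant", baseline=1.0, period=3.0)

    def test_schedule_requires_positive_infimum(self):
        # built from specs the schedule bound check is redundant with the
        # per-spec check, so it can only trip through the noisy wrapper
        with pytest.raises(ValueError, match="half-width"):
            pf.make_noisy(pf.constant(0.5), half_width=0.5, refresh_step=1.0, seed=0)


class TestCommonPeriod:
    @pytest.mark.parametrize(
        "periods,expected",
        [
            ([2.0, 3.0], 6.0),
            ([5.0, None, None], 5.0),  # constants are periodic for every T
            ([None, None], None),
            ([1.5, 0.5, 1.0], 3.0),
            ([7.0], 7.0),  # idempotence
        ],
    )
    def test_least_common_multiple(self, periods, expected):
        assert pf.common_period(periods) == pytest.approx(expected)

    def test_incommensurate_pair_errors(self):
        with pytest.raises(pf.IncommensurateError):
            pf.common_period([1.0, np.sqrt(2.0)])

    def test_minimality_on_schedule(self):
        sched, _ = pf.make_scenario("entrain_demo", 5, seed=3)
        # no smaller positive period works for all specs
        assert sched.T == pytest.approx(6.0)

    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_idempotent(self, T):
        assert pf.common_period([T]) == pytest.approx(T)


class TestBounds:
    def test_sinusoid_extremes(self):
        sched = pf.RateSchedule(
            1, [pf.sinusoid(1.0, 0.5, 3.0), pf.sinusoid(1.0, 0.5, 3.0)]
        )
        assert pf.rate_bounds(sched) == pytest.approx((0.5, 1.5))

    def test_constant_bounds(self):
        sched = pf.RateSchedule(1, [pf.constant(2.7), pf.constant(2.7)])
        assert pf.rate_bounds(sched) == (2.7, 2.7)

    def test_closed_form_matches_dense_grid(self):
        # mixture of sinusoids with different phases/periods against a
        # brute-force extremum over a 1e5-point grid
        specs = [
            pf.sinusoid(1.0, 0.4, 6.0, phase=1.3),
            pf.sinusoid(0.8, 0.3, 3.0, phase=0.2),
            pf.sinusoid(1.5, 0.9, 2.0, phase=2.9),
        ]
        sched = pf.RateSchedule(2, specs)
        lo, hi = pf.rate_bounds(sched)
        ts = np.linspace(0.0, sched.T, 100_000)
        vals = np.concatenate([np.asarray(s(ts)) for s in specs])
        assert lo == pytest.approx(vals.min(), abs=1e-6)
        assert hi == pytest.approx(vals.max(), abs=1e-6)
        # grid cross-check hook agrees
        assert pf.rate_bounds(sched, grid_points=1000) == (lo, hi)


class TestNoise:
    def test_zero_half_width_is_identity(self):
        inner = pf.sinusoid(1.0, 0.3, 4.0)
        noisy = pf.make_noisy(inner, half_width=0.0, refresh_step=0.5, seed=1)
        ts = np.linspace(0, 10, 101)
        np.testing.assert_array_equal(np.asarray(noisy(ts)), np.asarray(inner(ts)))

    def test_same_seed_same_path(self):
        inner = pf.constant(1.0)
        a = pf.make_noisy(inner, 0.4, 0.25, seed=7)
        b = pf.make_noisy(inner, 0.4, 0.25, seed=7)
        ts = np.linspace(0, 20, 500)
        np.testing.assert_array_equal(np.asarray(a(ts)), np.asarray(b(ts)))
        c = pf.make_noisy(inner, 0.4, 0.25, seed=8)
        assert not np.array_equal(np.asarray(a(ts)), np.asarray(c(ts)))

    def test_noise_mean_is_centred(self):
        # CLT check: mean of (noisy - inner) over 1e4 hold windows
        inner = pf.constant(1.0)
        hw = 0.5
        noisy = pf.make_noisy(inner, hw, refresh_step=1.0, seed=3)
        ts = np.arange(10_000) + 0.5  # one sample per window
        resid = np.asarray(noisy(ts)) - 1.0
        se = hw / np.sqrt(3.0) / np.sqrt(len(ts))
        assert abs(resid.mean()) < 3 * se
        assert np.all(np.abs(resid) <= hw)

    def test_piecewise_constant_within_window(self):
        noisy = pf.make_noisy(pf.constant(1.0), 0.3, refresh_step=1.0, seed=5)
        assert noisy(0.1) == noisy(0.9)
        assert noisy(0.1) != noisy(1.1)


class TestScenarios:
    @pytest.mark.parametrize("name", pf.rates.SCENARIO_NAMES)
    def test_presets_are_valid_and_deterministic(self, name):
        s1, x1 = pf.make_scenario(name, 4, seed=9)
        s2, x2 = pf.make_scenario(name, 4, seed=9)
        assert s1.to_dict() == s2.to_dict()
        np.testing.assert_array_equal(x1, x2)
        assert s1.delta1 > 0
        assert s1.T is not None and s1.T > 0
        assert np.all((x1 >= 0) & (x1 <= 1))

    def test_rate_limited_structure(self):
        sched, _ = pf.make_scenario("rate_limited_elongation", 3, seed=0)
        lam0, rest = sched.specs[0], sched.specs[1:]
        assert lam0.period is not None
        assert all(s.kind == "constant" for s in rest)
        # transition rates sit below the initiation rate's minimum
        assert max(s.baseline for s in rest) < lam0.bounds()[0]

    def test_entrain_demo_common_period(self):
        sched, _ = pf.make_scenario("entrain_demo", 3, seed=4)
        periods = [s.period for s in sched.specs]
        assert pf.common_period(periods) == pytest.approx(sched.T)

    def test_noisy_seeds_differ_but_share_structure(self):
        a, _ = pf.make_scenario("noisy_rates", 3, seed=1)
        b, _ = pf.make_scenario("noisy_rates", 3, seed=2)
        ts = np.linspace(0, 6, 50)
        assert not np.array_equal(np.asarray(a.specs[0](ts)), np.asarray(b.specs[0](ts)))
        # identical underlying periodic components for identical seeds of
        # the base scenario
        assert a.specs[0].inner.period == b.specs[0].inner.period

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            pf.make_scenario("does_not_exist", 3, 0)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            pf.make_scenario("entrain_demo", 1, 0)


class TestSerialization:
    def test_round_trip(self):
        sched, _ = pf.make_scenario("noisy_rates", 3, seed=6)
        again = pf.RateSchedule.from_dict(sched.to_dict())
        assert again.to_dict() == sched.to_dict()
        ts = np.linspace(0, 12, 100)
        for a, b in zip(sched.specs, again.specs):
            np.testing.assert_array_equal(np.asarray(a(ts)), np.asarray(b(ts)))

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            pf.RateSpec.from_dict({"kind": "constant", "baseline": 1.0, "typo": 1})
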