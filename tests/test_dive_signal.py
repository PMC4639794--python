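"""Dive/wiggle/step/feeding detectors against hand geometry and scans."""

import numpy as np
import pytest

from divepop import dive_signal, synth
from divepop.records import DepthRecord, TemperatureRecord, Dive

from conftest import random_dive_trace


def make_record(depths, dt=2.0):
    d = np.asarray(depths, dtype=float)
    return DepthRecord(np.arange(d.size) * dt, d)


class TestDetectDives:
    def test_v_dive_hand_geometry(self):
        # 0 -> 100 m -> 0 over 160 s at 2 s sampling: rates 1.25 m/s
        down = np.arange(1, 41) * 2.5
        up = down[::-1][1:]
        depths = np.concatenate([[0.0] * 5, down, up, [0.0] * 5])
        rec = make_record(depths)
        dives = dive_signal.detect_dives(rec, min_depth=50)
        assert len(dives) == 1
        d = dives[0]
        assert d.max_depth == 100.0
        assert d.descent_rate == pytest.approx(1.25, rel=0.05)
        assert d.ascent_rate == pytest.approx(1.25, rel=0.05)

    def test_flat_surface_trace(self):
        rec = make_record(np.zeros(100))
        assert dive_signal.detect_dives(rec, min_depth=50) == []

    def test_default_generator_rates_near_observed(self):
        plan = synth.random_trip_plan(n_days=0.2, seed=0)
        rec, _ = synth.gen_dive_record(plan, 2, seed=0)
        dives = dive_signal.detect_dives(rec, min_depth=50)
        rates = [d.descent_rate for d in dives] + [d.ascent_rate for d in dives]
        assert np.nanmean(rates) == pytest.approx(1.3, abs=0.15)

    def test_phases_partition_dive(self):
        plan = synth.random_trip_plan(n_days=0.2, seed=1)
        rec, _ = synth.gen_dive_record(plan, 2, seed=1)
        for d in dive_signal.detect_dives(rec, min_depth=50):
            assert d.start <= d.bottom_start <= d.bottom_end <= d.end
            t = rec.time
            desc = t[d.bottom_start] - t[d.start]
            bott = t[d.bottom_end] - t[d.bottom_start]
            asc = t[d.end] - t[d.bottom_end]
            assert desc + bott + asc == pytest.approx(d.duration)


class TestWigglesAndSteps:
    def test_hand_example_single_wiggle(self):
        rec = make_record([100, 102, 101, 103, 104], dt=1.0)
        d = Dive(start=0, end=4, bottom_start=0, bottom_end=4, max_depth=104,
                 duration=4, descent_rate=1, ascent_rate=1,
                 post_dive_surface=np.nan)
        assert dive_signal.count_wiggles(d, rec) == 1

    def test_constant_speed_descent_no_steps(self):
        depths = np.concatenate([np.arange(0, 100, 2.6), [100] * 10,
                                 np.arange(100, 0, -2.6), [0] * 5])
        rec = make_record(depths)
        d = dive_signal.detect_dives(rec, min_depth=50)[0]
        assert dive_signal.count_steps(d, rec) == 0

    def test_descent_plateau_is_one_step(self):
        # 1.3 m/s descent with a 6 s period at 0.2 m/s
        fast1 = np.arange(1, 21) * 2.6
        plateau = fast1[-1] + np.arange(1, 4) * 0.4
        fast2 = plateau[-1] + np.arange(1, 21) * 2.6
        top = fast2[-1]
        depths = np.concatenate([[0] * 3, fast1, plateau, fast2, [top] * 10,
                                 top - np.arange(1, 41) * 2.6])
        depths = np.clip(depths, 0, None)
        rec = make_record(depths)
        d = dive_signal.detect_dives(rec, min_depth=50)[0]
        assert dive_signal.count_steps(d, rec) == 1

    def test_planted_counts_recovered(self):
        plan = synth.DiveTruth(dives=[
            synth.DivePlan(start=60, max_depth=180, n_wiggles=2, n_steps=2)])
        rec, _ = synth.gen_dive_record(plan, 2, seed=0)
        d = dive_signal.detect_dives(rec, min_depth=50)[0]
        assert dive_signal.count_wiggles(d, rec) == 2
        assert dive_signal.count_steps(d, rec) == 2

    def test_counts_match_brute_force_on_random_traces(self):
        from test_synth import brute_wiggle_scan
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(100):
            t, depth = random_dive_trace(rng)
            rec = DepthRecord(t, depth)
            for d in dive_signal.detect_dives(rec, min_depth=10):
                v = np.diff(rec.depth) / np.diff(rec.time)
                assert dive_signal.count_wiggles(d, rec) == \
                    brute_wiggle_scan(v[d.start:d.bottom_end])
                checked += 1
        assert checked > 50


class TestFeedingEvents:
    def _trace(self, temps, dt=1.0):
        T = np.asarray(temps, dtype=float)
        return TemperatureRecord(np.arange(T.size) * dt, T)

    def test_constant_trace_no_events(self):
        rec = self._trace(np.full(100, 38.0))
        assert dive_signal.detect_feeding_events(rec) == []

    def test_threshold_selects_fast_drops(self):
        # three drops at 0.10, 0.05, 0.07 degC/s -> 2 events at 0.06
        T = np.full(300, 38.0)
        for start, rate in ((50, 0.10), (150, 0.05), (250, 0.07)):
            for j in range(5):
                T[start + 1 + j] = T[start] - rate * (j + 1)
            T[start + 6:] = T[start]  # recover instantly to baseline
        rec = self._trace(T)
        events = dive_signal.detect_feeding_events(
            rec, rate_threshold=0.06, min_amplitude=0.01, max_duration=100)
        assert len(events) == 2

    def test_monotone_in_rate_threshold(self):
        rng = np.random.default_rng(3)
        T = 38.0 + np.cumsum(rng.normal(0, 0.03, 500))
        rec = self._trace(T)
        counts = [len(dive_signal.detect_feeding_events(
            rec, rate_threshold=thr, min_amplitude=0.0, max_duration=1e9))
            for thr in (0.0, 0.03, 0.06, 0.1, 0.2)]
        assert counts == sorted(counts, reverse=True)

    def test_non_uniform_sampling_names_gap(self):
        rec = TemperatureRecord(np.array([0.0, 1.0, 2.0, 5.0]),
                                np.full(4, 38.0))
        with pytest.raises(ValueError, match="non-uniform"):
            dive_signal.detect_feeding_events(rec)


class TestBouts:
    def _dive(self, start, post):
        return Dive(start=start, end=start + 10, bottom_start=start + 3,
                    bottom_end=start + 7, max_depth=100, duration=100,
                    descent_rate=1.3, ascent_rate=1.3, post_dive_surface=post)

    def test_all_small_gaps_one_bout(self):
        dives = [self._dive(100 * k, 60.0) for k in range(4)]
        bouts = dive_signal.segment_bouts(dives, gap_threshold=1800)
        assert len(bouts) == 1 and bouts[0].n_dives == 4

    def test_large_gap_splits_bouts(self):
        gaps = [60.0, 4000.0, 60.0, np.nan]
        dives = [self._dive(1000 * k, g) for k, g in enumerate(gaps)]
        bouts = dive_signal.segment_bouts(dives, gap_threshold=1800)
        assert [b.n_dives for b in bouts] == [2, 2]

    def test_covariate_columns_match_bout_table_design(self):
        plan = synth.random_trip_plan(n_days=0.2, seed=2)
        rec, _ = synth.gen_dive_record(plan, 2, seed=2)
        dives = dive_signal.detect_dives(rec, min_depth=50)
        bouts = dive_signal.segment_bouts(dives, 1800, rec=rec)
        expected = {"log_n_dives", "log_n_dives_sq", "max_depth", "n_wiggles",
                    "ascent_rate", "descent_rate", "n_steps",
                    "surface_duration"}
        assert set(bouts[0].covariates) == expected


class TestThermocline:
    def test_piecewise_profile_gradient_midpoint(self):
        z = np.arange(0, 240, 2.0)
        T = np.where(z < 150, 6.0, np.where(z > 190, 2.0,
                     6.0 - 4.0 * (z - 150) / 40.0))
        est = dive_signal.estimate_thermocline([(z, T)])
        assert est.depth == pytest.approx(170.0, abs=6.0)

    def test_tanh_profile_centre(self):
        z = np.arange(0, 240, 2.0)
        T = 4.0 - 2.0 * np.tanh((z - 120.0) / 15.0)
        est = dive_signal.estimate_thermocline([(z, T)])
        assert est.depth == pytest.approx(120.0, abs=2.5)

    def test_isothermal_returns_none(self):
        z = np.arange(0, 150, 2.0)
        with pytest.warns(UserWarning, match="isothermal"):
            est = dive_signal.estimate_thermocline([(z, np.full(z.size, 5.0))])
        assert est is None

    def test_invariant_to_temperature_offset(self):
        z = np.arange(0, 240, 2.0)
        T = 4.0 - 2.0 * np.tanh((z - 120.0) / 15.0)
        a = dive_signal.estimate_thermocline([(z, T)])
        b = dive_signal.estimate_thermocline([(z, T + 3.0)])
        assert a.depth == b.depth


class TestPhaseComparison:
    def test_exact_small_sample(self):
        u, p = dive_signal.phase_feeding_comparison([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = dive_signal.phase_feeding_comparison([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_doubled_capture_rate_detected(self):
        # per-dive capture rates ~2x higher at the front than in transit
        rng = np.random.default_rng(0)
        transit = rng.poisson(2.0, 200) / 1.0
        front = rng.poisson(4.0, 200) / 1.0
        _, p = dive_signal.phase_feeding_comparison(transit, front)
        assert p < 0.05
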