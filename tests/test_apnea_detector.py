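"""Local-range computation and the dual-threshold apnea rule."""

import numpy as np
import pytest

from lrsahs import (
    DetectorConfig,
    EventType,
    LrSeries,
    RespEvent,
    SampledSignal,
    detect_apnea,
    local_range,
    optimize_thresholds,
)


def naive_local_range(x: np.ndarray, rate: float, window_s: float, step_s: float) -> np.ndarray:
    """Brute-force per-window max - min (the oracle the fast path must equal)."""
    win = int(round(window_s * rate))
    step = int(round(step_s * rate))
    out = []
    i = 0
    while i + win <= len(x):
        w = x[i : i + win]
        out.append(w.max() - w.min())
        i += step
    return np.asarray(out)


def lr_series(values, step_s=0.5, window_s=10.0, start_s=0.0):
    return LrSeries(np.asarray(values, dtype=float), step_s, window_s, start_s)


def inv_to_lr(inv_values):
    """Build an LR grid whose 1/LR equals the given profile."""
    return lr_series([1.0 / v for v in inv_values])


class TestLocalRange:
    def test_constant_signal_gives_zero(self, cfg):
        sig = SampledSignal(np.full(200 * 60, 3.7), rate=200.0)
        lr = local_range(sig, cfg)
        assert np.all(lr.values == 0.0)
        assert len(lr) == (60 - 10) / 0.5 + 1

    @pytest.mark.parametrize("amp", [0.1, 1.0, 25.0])
    def test_sine_peak_to_peak_is_twice_amplitude(self, cfg, amp):
        t = np.arange(200 * 60) / 200.0
        sig = SampledSignal(amp * np.sin(2 * np.pi * t / 4.0), rate=200.0)
        lr = local_range(sig, cfg)
        assert lr.values == pytest.approx(2 * amp, abs=1e-6)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_naive_oracle_bit_for_bit(self, cfg, seed):
        rng = np.random.default_rng(seed)
        rate = float(rng.choice([50, 100, 200]))
        n = int(rng.integers(int(12 * rate), 10_000))
        x = rng.normal(size=n)
        lr = local_range(SampledSignal(x, rate=rate), cfg)
        assert np.array_equal(lr.values, naive_local_range(x, rate, 10.0, 0.5))

    def test_non_aligned_window_step_also_matches_oracle(self):
        # window not a whole multiple of the step exercises the strided path
        cfg = DetectorConfig(window_s=10.0, lr_step_s=3.0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=400)
        lr = local_range(SampledSignal(x, rate=10.0), cfg)
        assert np.array_equal(lr.values, naive_local_range(x, 10.0, 10.0, 3.0))

    def test_scaling_equivariance_and_offset_invariance(self, cfg):
        rng = np.random.default_rng(2)
        x = rng.normal(size=4000)
        base = local_range(SampledSignal(x, rate=100.0), cfg).values
        for c in (0.5, 2.0, 8.0):  # powers of two: scaling is exact in floats
            scaled = local_range(SampledSignal(c * x, rate=100.0), cfg).values
            assert np.array_equal(scaled, c * base)
        shifted = local_range(SampledSignal(x + 5.0, rate=100.0), cfg).values
        assert shifted == pytest.approx(base, abs=1e-12)

    def test_too_short_signal_rejected(self, cfg):
        with pytest.raises(ValueError, match="too short"):
            local_range(SampledSignal(np.zeros(100), rate=200.0), cfg)


class TestDetectApnea:
    def test_below_ta_everywhere_gives_no_events(self, cfg):
        assert detect_apnea(inv_to_lr([5.0] * 200), cfg) == []

    def test_single_run_duration_is_dwell_plus_window(self, cfg):
        # 20 s (40 grid points) of 1/LR = 50 amid 1/LR = 5
        inv = [5.0] * 100 + [50.0] * 40 + [5.0] * 100
        (ev,) = detect_apnea(inv_to_lr(inv), cfg)
        assert ev.type is EventType.APNEA
        assert ev.start_s == pytest.approx(50.0)
        assert ev.duration_s == pytest.approx(20.0 + 10.0)

    def test_two_tc_spikes_in_one_ta_run_are_one_event(self, cfg):
        inv = [5.0] * 50 + [15.0] * 10 + [50.0] * 4 + [15.0] * 20 + [50.0] * 4 + [15.0] * 10 + [5.0] * 50
        events = detect_apnea(inv_to_lr(inv), cfg)
        assert len(events) == 1

    def test_run_between_ta_and_tc_is_not_an_event(self, cfg):
        inv = [5.0] * 50 + [15.0] * 60 + [5.0] * 50
        assert detect_apnea(inv_to_lr(inv), cfg) == []

    def test_nearby_runs_with_overlapping_extensions_join(self, cfg):
        # two super-Tc runs 5 s apart: extensions (+10 s) overlap -> one event
        inv = [5.0] * 40 + [50.0] * 10 + [5.0] * 10 + [50.0] * 10 + [5.0] * 40
        events = detect_apnea(inv_to_lr(inv), cfg)
        assert len(events) == 1
        # same runs 30 s apart stay separate
        inv = [5.0] * 40 + [50.0] * 10 + [5.0] * 60 + [50.0] * 10 + [5.0] * 40
        events = detect_apnea(inv_to_lr(inv), cfg)
        assert len(events) == 2

    def test_flat_line_sensor_reads_as_apnea(self, cfg):
        # complete cessation: LR = 0 clamps to lr_floor and 1/LR is huge
        vals = [0.2] * 100 + [0.0] * 40 + [0.2] * 100
        (ev,) = detect_apnea(lr_series(vals), cfg)
        assert ev.duration_s >= 10.0

    @pytest.mark.parametrize("seed", range(3))
    def test_events_disjoint_ordered_and_long_enough(self, cfg, seed):
        rng = np.random.default_rng(seed)
        lr = lr_series(rng.uniform(0.01, 0.3, 2000))
        events = detect_apnea(lr, cfg)
        for ev in events:
            assert ev.duration_s >= cfg.window_s
        for a, b in zip(events, events[1:]):
            assert a.end_s <= b.start_s

    @pytest.mark.parametrize("seed", range(3))
    def test_raising_tc_never_adds_events(self, seed):
        rng = np.random.default_rng(100 + seed)
        lr = lr_series(rng.uniform(0.01, 0.3, 2000))
        counts = [
            len(detect_apnea(lr, DetectorConfig(ta=10.0, tc=tc)))
            for tc in (12.0, 18.0, 25.0, 40.0, 80.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestOptimizeThresholds:
    def _one_recording(self, cfg):
        inv = [5.0] * 100 + [50.0] * 40 + [5.0] * 100
        refs = [RespEvent("apnea", 50.0, 80.0)]
        return [(inv_to_lr(inv), refs)]

    def test_single_pair_grid_returns_that_pair(self, cfg):
        res = optimize_thresholds(self._one_recording(cfg), ta_grid=[10], tc_grid=[25], cfg=cfg)
        assert (res.best_ta, res.best_tc) == (10.0, 25.0)
        assert len(res.table) == 1

    def test_invalid_pairs_skipped_and_ties_break_low(self, cfg):
        res = optimize_thresholds(
            self._one_recording(cfg), ta_grid=[10, 30], tc_grid=[25, 30], cfg=cfg
        )
        # (30, 25) and (30, 30) violate Ta < Tc; both survivors score perfectly,
        # so the tie breaks toward the smaller pair
        assert (res.best_ta, res.best_tc) == (10.0, 25.0)
        assert set(map(tuple, res.table[["ta", "tc"]].values)) == {(10.0, 25.0), (10.0, 30.0)}

    def test_empty_references_are_an_error(self, cfg):
        recs = [(self._one_recording(cfg)[0][0], [])]
        with pytest.raises(ValueError, match="empty"):
            optimize_thresholds(recs, cfg=cfg)
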