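import numpy as np
import pandas as pd
import pytest

import hemisync as hs
from hemisync.core import EventStream
from hemisync.eyetracking import GazeTrace, ScreenGeometry


def drift_trace(duration=20.0, rate=500.0, seed=0, drift_sd=0.05):
    """Plain fixational drift, no saccades."""
    rng = np.random.default_rng(seed)
    n = int(duration * rate)
    dt = 1.0 / rate
    x = np.zeros(n)
    y = np.zeros(n)
    sig = drift_sd * np.sqrt(2 * dt)
    for i in range(1, n):
        x[i] = x[i - 1] * (1 - dt) + rng.standard_normal() * sig
        y[i] = y[i - 1] * (1 - dt) + rng.standard_normal() * sig
    return GazeTrace(time=np.arange(n) * dt, x=x, y=y, rate=rate)


def inject(trace, onset, amplitude, duration, direction=0.0):
    """Add a ballistic saccade profile to a copy of the trace."""
    x = trace.x.copy()
    y = trace.y.copy()
    i0 = int(onset * trace.rate)
    n_s = max(int(duration * trace.rate), 2)
    u = np.linspace(0, 1, n_s)
    prof = amplitude * (u - np.sin(2 * np.pi * u) / (2 * np.pi))
    x[i0 : i0 + n_s] += np.cos(direction) * prof
    x[i0 + n_s :] += np.cos(direction) * amplitude
    y[i0 : i0 + n_s] += np.sin(direction) * prof
    y[i0 + n_s :] += np.sin(direction) * amplitude
    return GazeTrace(time=trace.time, x=x, y=y, rate=trace.rate)


class TestDetection:
    def test_injected_saccade_found_with_precise_onset(self):
        trace = inject(drift_trace(seed=1), onset=10.0, amplitude=0.4, duration=0.02)
        table = hs.detect_microsaccades(trace)
        assert len(table) == 1
        assert table.loc[0, "onset"] == pytest.approx(10.0, abs=0.004)
        assert table.loc[0, "amplitude"] == pytest.approx(0.4, abs=0.1)

    def test_tiny_amplitude_rejected(self):
        trace = inject(drift_trace(seed=2), onset=10.0, amplitude=0.02, duration=0.02)
        table = hs.detect_microsaccades(trace)
        assert not (np.abs(table["onset"] - 10.0) < 0.02).any()

    def test_too_brief_event_rejected(self):
        # 6 ms excursion: supra-threshold but below the 10 ms duration floor
        trace = inject(drift_trace(seed=3), onset=10.0, amplitude=0.3, duration=0.006)
        table = hs.detect_microsaccades(trace)
        assert not (np.abs(table["onset"] - 10.0) < 0.02).any()

    def test_oversized_amplitude_rejected(self):
        trace = inject(drift_trace(seed=4), onset=10.0, amplitude=1.5, duration=0.03)
        table = hs.detect_microsaccades(trace)
        assert not (np.abs(table["onset"] - 10.0) < 0.03).any()

    def test_rotation_invariance(self):
        base = drift_trace(seed=5)
        t1 = inject(base, 8.0, 0.4, 0.02, direction=0.3)
        th = 0.77
        rot = GazeTrace(
            time=t1.time,
            x=np.cos(th) * t1.x - np.sin(th) * t1.y,
            y=np.sin(th) * t1.x + np.cos(th) * t1.y,
            rate=t1.rate,
        )
        n1 = len(hs.detect_microsaccades(t1))
        n2 = len(hs.detect_microsaccades(rot))
        assert n1 == n2 == 1

    def test_gain_doubles_amplitude_not_count(self):
        base = drift_trace(seed=6)
        t1 = inject(base, 8.0, 0.3, 0.02)  # away from the 0.05/1 deg bounds
        t2 = GazeTrace(time=t1.time, x=2 * t1.x, y=2 * t1.y, rate=t1.rate)
        d1 = hs.detect_microsaccades(t1)
        d2 = hs.detect_microsaccades(t2)
        assert len(d1) == len(d2) == 1
        assert d2.loc[0, "amplitude"] == pytest.approx(
            2 * d1.loc[0, "amplitude"], rel=0.05
        )

    def test_recall_and_precision_on_generated_gaze(self):
        cfg = hs.SimulationConfig(seed=13, duration=60.0)
        trace, truth = hs.generate_gaze(cfg)
        clean, _ = hs.prefilter(trace)
        table = hs.detect_microsaccades(clean)
        hits = 0
        for onset in truth["onset"]:
            if (np.abs(table["onset"] - onset) < 0.015).any():
                hits += 1
        recall = hits / len(truth)
        matched = sum(
            (np.abs(truth["onset"] - o) < 0.015).any() for o in table["onset"]
        )
        precision = matched / len(table)
        assert recall >= 0.9
        assert precision >= 0.9

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            hs.detect_microsaccades(
                GazeTrace(time=np.arange(3) / 500, x=np.zeros(3), y=np.zeros(3), rate=500.0)
            )


class TestPrefilter:
    def test_epoch_survival_threshold(self):
        trace = drift_trace(duration=10.0, seed=7)
        # blink out 25% of the first 4 s epoch and 10% of the second
        trace.blink_mask[: int(1.0 * trace.rate)] = True
        trace.blink_mask[int(4.0 * trace.rate) : int(4.4 * trace.rate)] = True
        clean, surviving = hs.prefilter(trace, epochs=[(0.0, 4.0), (4.0, 8.0)])
        assert (0.0, 4.0) not in surviving  # 75% remaining -> rejected
        assert (4.0, 8.0) in surviving  # 90% remaining -> kept

    def test_press_windows_masked(self):
        trace = drift_trace(duration=10.0, seed=8)
        ev = EventStream([(5.0, "press_horizontal")])
        clean, _ = hs.prefilter(trace, events=ev)
        sl = slice(int(4.1 * trace.rate), int(5.9 * trace.rate))
        assert not clean.valid_mask[sl].any()

    def test_clean_trace_untouched(self):
        trace = drift_trace(duration=10.0, seed=9)
        clean, surviving = hs.prefilter(trace, epochs=[(0.0, 10.0)])
        assert clean.valid_mask.all()
        assert surviving == [(0.0, 10.0)]


class TestFixationStats:
    def test_constant_offset_recovered(self):
        trace = drift_trace(seed=10)
        shifted = GazeTrace(
            time=trace.time, x=trace.x + 0.5, y=trace.y, rate=trace.rate
        )
        stats = hs.fixation_stats(shifted)
        assert stats["mean_x"] == pytest.approx(0.5, abs=0.1)
        assert stats["mean_y"] == pytest.approx(0.0, abs=0.1)

    def test_generated_rate_recovered(self):
        cfg = hs.SimulationConfig(seed=14, duration=120.0, microsaccade_rate=1.5)
        trace, truth = hs.generate_gaze(cfg)
        clean, _ = hs.prefilter(trace)
        table = hs.detect_microsaccades(clean)
        rate = hs.microsaccade_rate(table, clean)
        assert rate == pytest.approx(len(truth) / cfg.duration, abs=0.3)

    def test_empty_trace_rejected(self):
        trace = drift_trace(duration=1.0, seed=11)
        trace.valid_mask[:] = False
        with pytest.raises(ValueError):
            hs.fixation_stats(trace)


class TestScreenGeometry:
    def test_center_pixel_maps_to_origin(self):
        geo = ScreenGeometry()
        x, y = geo.px_to_deg(np.array([960.0]), np.array([540.0]))
        assert x[0] == 0.0 and y[0] == 0.0

    def test_known_offset(self):
        geo = ScreenGeometry()
        # one degree at 60 cm is ~1.047 cm ~ 37.9 px horizontally
        px = 960.0 + np.tan(np.radians(1.0)) * 60.0 / (53.1 / 1920)
        x, _ = geo.px_to_deg(np.array([px]), np.array([540.0]))
        assert x[0] == pytest.approx(1.0, abs=0.01)
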