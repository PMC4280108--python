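import numpy as np
import pandas as pd
import pytest

import hemisync as hs
from hemisync.core import EventStream
from hemisync.preprocessing import Epochs
from conftest import sine_recording


def amp_at(data_row, rate, freq):
    spec = np.abs(np.fft.rfft(data_row)) * 2 / len(data_row)
    freqs = np.fft.rfftfreq(len(data_row), 1 / rate)
    return spec[np.argmin(np.abs(freqs - freq))]


class TestBandpass:
    def test_passband_tone_preserved(self):
        rec = sine_recording([(50.0, 1.0)], rate=1000.0, duration=4.0)
        out = hs.bandpass(rec, 1.0, 100.0)
        assert amp_at(out.data[0], 1000.0, 50.0) == pytest.approx(1.0, rel=0.05)

    def test_slow_drift_attenuated(self):
        rec = sine_recording([(0.2, 1.0)], rate=1000.0, duration=20.0)
        out = hs.bandpass(rec, 1.0, 100.0)
        ratio = amp_at(out.data[0], 1000.0, 0.2) / 1.0
        assert 20 * np.log10(1 / max(ratio, 1e-12)) >= 20.0  # >= 20 dB down

    def test_impulse_response_symmetric(self, layout):
        # long signal so reflection-padding ghosts stay clear of the centre
        n = 10000
        data = np.zeros((31, n))
        data[:, n // 2] = 1.0
        rec = hs.Recording(data=data, rate=1000.0, layout=layout)
        out = hs.bandpass(rec, 1.0, 100.0)
        h = out.data[0]
        left = h[: n // 2][::-1]
        right = h[n // 2 + 1 :]
        m = 1500
        assert np.allclose(left[:m], right[:m], atol=1e-9)  # zero-phase

    def test_linearity(self, layout):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((31, 2000))
        y = rng.standard_normal((31, 2000))
        rec = lambda d: hs.Recording(data=d, rate=1000.0, layout=layout)
        fx = hs.bandpass(rec(x), 1, 100).data
        fy = hs.bandpass(rec(y), 1, 100).data
        fxy = hs.bandpass(rec(2 * x + 3 * y), 1, 100).data
        assert np.allclose(fxy, 2 * fx + 3 * fy, atol=1e-8)

    def test_invalid_corners_rejected(self, recording):
        with pytest.raises(ValueError):
            hs.bandpass(recording, 100.0, 1.0)
        with pytest.raises(ValueError):
            hs.bandpass(recording, 1.0, 600.0)


class TestNotch:
    def test_40hz_removed(self):
        # recording-length tone: residual dominated by brief edge ringing
        rec = sine_recording([(40.0, 1.0)], rate=1000.0, duration=30.0)
        out = hs.notch(rec, 35.0, 45.0)
        rms_in = np.sqrt((rec.data[0] ** 2).mean())
        assert np.sqrt((out.data[0] ** 2).mean()) < 0.01 * rms_in
        # away from the edges the suppression is essentially total
        interior = out.data[0, 1000:-1000]
        assert np.sqrt((interior**2).mean()) < 0.002 * rms_in

    @pytest.mark.parametrize("freq", [20.0, 60.0])
    def test_flanking_tones_preserved(self, freq):
        rec = sine_recording([(40.0, 1.0), (freq, 1.0)], rate=1000.0, duration=4.0)
        out = hs.notch(rec, 35.0, 45.0)
        assert amp_at(out.data[0], 1000.0, freq) == pytest.approx(1.0, rel=0.05)


class TestDownsample:
    def test_sample_count(self, layout):
        rec = sine_recording([(30.0, 1.0)], rate=5000.0, duration=10.0, layout=layout)
        out = hs.downsample(rec, 1000.0)
        assert out.n_samples == 10000 and out.rate == 1000.0

    def test_passband_preserved_alias_removed(self, layout):
        rec = sine_recording(
            [(30.0, 1.0), (900.0, 1.0)], rate=5000.0, duration=4.0, layout=layout
        )
        out = hs.downsample(rec, 1000.0)
        assert amp_at(out.data[0], 1000.0, 30.0) == pytest.approx(1.0, rel=0.05)
        # 900 Hz would alias to 100 Hz; the anti-alias filter must kill it
        assert amp_at(out.data[0], 1000.0, 100.0) < 0.02

    def test_non_integer_ratio_rejected(self, recording):
        with pytest.raises(ValueError):
            hs.downsample(recording, 333.0)


def _stream(presses, trial=(0.0, 60.0)):
    evs = [(trial[0], "trial_start")] + list(presses) + [(trial[1], "trial_end")]
    return EventStream(sorted(evs, key=lambda e: e[0]))


class TestEpochPercepts:
    def make_rec(self, duration=60.0, rate=200.0):
        layout = hs.default_layout()
        data = np.zeros((31, int(duration * rate)))
        data[:] = np.arange(data.shape[1])[None, :]  # sample index as value
        return hs.Recording(data=data, rate=rate, layout=layout)

    def test_epoch_window_placement(self):
        rec = self.make_rec()
        ev = _stream([(10.0, "press_horizontal"), (20.0, "press_vertical")])
        ep = hs.epoch_percepts(rec, ev)
        assert ep.n_epochs == 2
        # first epoch covers [10.5, 13.5) s; samples carry their index
        assert ep.data[0, 0, 0] == int(10.5 * rec.rate)
        assert ep.labels.loc[0, "percept"] == "horizontal"
        assert ep.duration == pytest.approx(3.0)

    def test_epoch_overlapping_next_switch_dropped(self):
        rec = self.make_rec()
        ev = _stream([(10.0, "press_horizontal"), (12.0, "press_vertical")])
        ep = hs.epoch_percepts(rec, ev)
        # first switch epoch would cross the 12 s switch -> dropped
        assert (ep.labels["percept"] == "horizontal").sum() == 0

    def test_epoch_crossing_trial_end_dropped(self):
        rec = self.make_rec()
        ev = _stream([(58.0, "press_horizontal")])
        ep = hs.epoch_percepts(rec, ev)
        assert ep.n_epochs == 0

    def test_no_switches_no_epochs(self):
        rec = self.make_rec()
        ep = hs.epoch_percepts(rec, _stream([]))
        assert ep.n_epochs == 0

    def test_no_samples_fabricated(self):
        rec = self.make_rec()
        ev = _stream([(10.0, "press_horizontal"), (20.0, "press_vertical")])
        ep = hs.epoch_percepts(rec, ev)
        # every epoch sample must exist in the source at the mapped time
        for e in range(ep.n_epochs):
            i0 = int(round(ep.labels.loc[e, "start"] * rec.rate))
            assert np.array_equal(ep.data[e], rec.data[:, i0 : i0 + ep.n_samples])


class TestSegmentResting:
    @pytest.mark.parametrize("duration,expected", [(10.0, 10), (1.5, 1), (0.5, 0)])
    def test_floor_rule(self, duration, expected, layout):
        data = np.zeros((31, int(duration * 100)))
        rec = hs.Recording(data=data, rate=100.0, layout=layout, condition="resting")
        ep = hs.segment_resting(rec)
        assert ep.n_epochs == expected


class TestRejectArtifacts:
    def make_epochs(self, n=5, layout=None):
        layout = layout or hs.default_layout()
        rng = np.random.default_rng(1)
        data = rng.standard_normal((n, 31, 200)) * 10.0
        labels = pd.DataFrame(
            {
                "percept": ["horizontal"] * n,
                "start": np.arange(n, dtype=float),
                "session": ["in_phase"] * n,
                "condition": ["sham"] * n,
            }
        )
        return Epochs(data=data, rate=100.0, labels=labels, layout=layout)

    def test_spike_epoch_removed(self):
        ep = self.make_epochs()
        ep.data[2, 5, 50] += 500.0
        out, report = hs.reject_artifacts(ep, threshold=200.0)
        assert report["n_dropped"] == 1
        assert out.n_epochs == 4
        assert 2.0 not in out.labels["start"].tolist()

    def test_huge_threshold_is_identity(self):
        ep = self.make_epochs()
        out, report = hs.reject_artifacts(ep, threshold=1e9)
        assert report["n_dropped"] == 0
        assert np.array_equal(out.data, ep.data)

    def test_all_contaminated_gives_empty(self):
        ep = self.make_epochs()
        ep.data += 1e6
        out, report = hs.reject_artifacts(ep, threshold=1.0)
        assert out.n_epochs == 0 and report["n_out"] == 0


class TestBalance:
    def make_epochs(self, counts):
        layout = hs.default_layout()
        rows, chunks = [], []
        for (cond, percept), k in counts.items():
            for _ in range(k):
                rows.append(
                    {
                        "percept": percept,
                        "start": float(len(rows)),
                        "session": "in_phase",
                        "condition": cond,
                    }
                )
                chunks.append(np.zeros((31, 10)))
        return Epochs(
            data=np.stack(chunks),
            rate=100.0,
            labels=pd.DataFrame(rows),
            layout=layout,
        )

    def test_cells_equalized_to_minimum(self):
        ep = self.make_epochs(
            {
                ("sham", "horizontal"): 10,
                ("sham", "vertical"): 7,
                ("stimulation", "horizontal"): 9,
                ("stimulation", "vertical"): 8,
            }
        )
        out = hs.balance_segments(ep, seed=0)
        counts = out.labels.groupby(["condition", "percept"]).size()
        assert (counts == 7).all()

    def test_equal_cells_identity_up_to_order(self):
        ep = self.make_epochs(
            {("sham", "horizontal"): 5, ("sham", "vertical"): 5}
        )
        out = hs.balance_segments(ep, seed=3)
        assert out.n_epochs == 10

    def test_empty_cell_raises_with_name(self):
        ep = self.make_epochs(
            {
                ("sham", "horizontal"): 4,
                ("sham", "vertical"): 4,
                ("stimulation", "horizontal"): 4,
            }
        )
        with pytest.raises(ValueError, match="stimulation.*vertical"):
            hs.balance_segments(ep, seed=0)

    def test_seed_determinism(self):
        ep = self.make_epochs(
            {("sham", "horizontal"): 9, ("sham", "vertical"): 5}
        )
        a = hs.balance_segments(ep, seed=1)
        b = hs.balance_segments(ep, seed=1)
        c = hs.balance_segments(ep, seed=2)
        assert a.labels.equals(b.labels)
        assert len(c.labels) == len(a.labels)  # sizes match across seeds
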