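"""Filtering, downsampling, epoching and segment balancing.

The preprocessing chain mirrors standard practice for stimulation-EEG:
a two-pass (zero-phase) FIR band-pass between 1 and 100 Hz, an eighth-order
two-pass Butterworth notch between 35 and 45 Hz to remove the 40 Hz
stimulation artifact (applied identically to sham, stimulation and post data
so the conditions stay comparable), decimation to 1 kHz, segmentation into
3 s epochs starting 500 ms after a reported perceptual switch, 1 s resting
segments, automated peak-to-peak artifact rejection, and per-cell balancing
of segment counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .core import AnalysisConfig, ChannelLayout, EventStream, Recording

__all__ = [
    "Epochs",
    "bandpass",
    "notch",
    "downsample",
    "epoch_percepts",
    "segment_resting",
    "reject_artifacts",
    "balance_segments",
]


@dataclass
class Epochs:
    """Equal-length epochs: ``data`` is epochs x channels x samples (uV)."""

    data: np.ndarray
    rate: float
    labels: pd.DataFrame  # columns: percept, start, session, condition
    layout: Optional[ChannelLayout] = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be 3-D (epochs x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label row per epoch required")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def subset(self, index) -> "Epochs":
        idx = np.asarray(index)
        return Epochs(
            data=self.data[idx],
            rate=self.rate,
            labels=self.labels.iloc[idx].reset_index(drop=True),
            layout=self.layout,
        )


def _fir_two_pass(data: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering via centred FFT convolution.

    A symmetric (linear-phase) kernel applied twice has zero net phase and
    the squared magnitude response.  Edges are padded by reflection and
    trimmed afterwards to suppress filter transients.
    """
    pad = len(taps)
    x = np.atleast_2d(data)
    padded = np.pad(x, [(0, 0), (pad, pad)], mode="reflect")
    once = signal.fftconvolve(padded, taps[None, :], mode="same", axes=1)
    twice = signal.fftconvolve(once, taps[None, :], mode="same", axes=1)
    out = twice[:, pad:-pad]
    return out if data.ndim == 2 else out[0]


def _design_bandpass(lo: float, hi: float, rate: float, order_factor: int) -> np.ndarray:
    numtaps = int(order_factor * rate / lo)
    numtaps += 1 - numtaps % 2  # odd length -> exactly linear phase, type I
    numtaps = max(numtaps, 5)
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=rate)


def bandpass(
    rec: Recording, lo: float = 1.0, hi: float = 100.0, cfg: Optional[AnalysisConfig] = None
) -> Recording:
    """Zero-phase FIR band-pass; corner frequencies in Hz."""
    cfg = cfg or AnalysisConfig()
    if not 0 < lo < hi < rec.rate / 2:
        raise ValueError(f"need 0 < lo < hi < Nyquist, got ({lo}, {hi}) at {rec.rate} Hz")
    taps = _design_bandpass(lo, hi, rec.rate, cfg.fir_order_factor)
    return rec.copy_with(_fir_two_pass(rec.data, taps))


def bandpass_array(
    data: np.ndarray, rate: float, lo: float, hi: float, order_factor: int = 3
) -> np.ndarray:
    """Zero-phase FIR band-pass on a raw array (channels x samples)."""
    if not 0 < lo < hi < rate / 2:
        raise ValueError(f"need 0 < lo < hi < Nyquist, got ({lo}, {hi}) at {rate} Hz")
    taps = _design_bandpass(lo, hi, rate, order_factor)
    return _fir_two_pass(data, taps)


def notch(
    rec: Recording, lo: float = 35.0, hi: float = 45.0, order: int = 8
) -> Recording:
    """Two-pass Butterworth band-stop, removing the stimulation artifact."""
    if not 0 < lo < hi < rec.rate / 2:
        raise ValueError("notch band must lie within (0, Nyquist)")
    sos = signal.butter(order, [lo, hi], btype="bandstop", fs=rec.rate, output="sos")
    # forward-backward application realized in the frequency domain: the
    # two-pass filter has the squared magnitude response and zero phase, and
    # evaluating |H|^2 on the FFT grid avoids the long edge transients an
    # order-8 band-stop produces under time-domain filtfilt
    pad = min(int(2 * rec.rate), rec.n_samples - 1)
    padded = np.pad(
        rec.data, [(0, 0), (pad, pad)], mode="reflect", reflect_type="odd"
    )
    # taper the pads to zero: keeps the junction smooth while removing the
    # pad's offset/wrap-around discontinuities from the FFT
    ramp = 0.5 * (1 + np.cos(np.linspace(np.pi, 0, pad)))
    padded[:, :pad] *= ramp
    padded[:, -pad:] *= ramp[::-1]
    n = padded.shape[1]
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.rate)
    _, h = signal.sosfreqz(sos, worN=2 * np.pi * freqs / rec.rate)
    spec = np.fft.rfft(padded, axis=1) * (np.abs(h) ** 2)[None, :]
    out = np.fft.irfft(spec, n=n, axis=1)[:, pad:-pad]
    return rec.copy_with(out)


def downsample(rec: Recording, target: float = 1000.0) -> Recording:
    """Anti-alias filtered decimation to ``target`` Hz (integer ratio)."""
    ratio = rec.rate / target
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(f"target {target} must divide rate {rec.rate}")
    q = int(round(ratio))
    if q == 1:
        return rec.copy_with(rec.data.copy())
    out = signal.decimate(rec.data, q, ftype="fir", axis=1, zero_phase=True)
    return rec.copy_with(out, rate=target)


def _collapse_redundant(presses):
    """Drop consecutive same-label presses, keeping the first."""
    out = []
    for t, lab in presses:
        if out and out[-1][1] == lab:
            continue
        out.append((t, lab))
    return out


def epoch_percepts(
    rec: Recording, events: EventStream, cfg: Optional[AnalysisConfig] = None
) -> Epochs:
    """3 s epochs starting 0.5 s after each reported switch.

    Each epoch covers [t + 0.5, t + 3.5) s and is labelled with the newly
    reported percept.  Epochs that would cross the next switch, a trial
    boundary, or the end of the recording are dropped, so every epoch is
    percept-pure.
    """
    cfg = cfg or AnalysisConfig()
    offset, length = cfg.epoch_offset, cfg.epoch_length
    presses = _collapse_redundant(
        [(t, lab) for t, lab in events if lab in ("press_horizontal", "press_vertical")]
    )
    trials = events.trials()
    n_len = int(round(length * rec.rate))
    rows, chunks = [], []
    for i, (t, lab) in enumerate(presses):
        start = t + offset
        end = start + length
        if end > rec.duration:
            continue
        if i + 1 < len(presses) and end > presses[i + 1][0]:
            continue  # would overlap the next percept
        if trials and not any(ts <= t and end <= te for ts, te in trials):
            continue  # switch outside a trial or epoch crossing its boundary
        i0 = int(round(start * rec.rate))
        if i0 + n_len > rec.n_samples:
            continue
        chunks.append(rec.data[:, i0 : i0 + n_len])
        rows.append(
            {
                "percept": "horizontal" if lab == "press_horizontal" else "vertical",
                "start": start,
                "session": rec.session,
                "condition": rec.condition,
            }
        )
    data = (
        np.stack(chunks)
        if chunks
        else np.empty((0, rec.n_channels, n_len))
    )
    labels = pd.DataFrame(rows, columns=["percept", "start", "session", "condition"])
    return Epochs(data=data, rate=rec.rate, labels=labels, layout=rec.layout)


def segment_resting(rec: Recording, cfg: Optional[AnalysisConfig] = None) -> Epochs:
    """Non-overlapping 1 s segments of a resting-state recording."""
    cfg = cfg or AnalysisConfig()
    seg = int(round(cfg.resting_segment * rec.rate))
    n_seg = rec.n_samples // seg
    data = rec.data[:, : n_seg * seg].reshape(rec.n_channels, n_seg, seg)
    data = np.moveaxis(data, 1, 0)
    labels = pd.DataFrame(
        {
            "percept": ["resting"] * n_seg,
            "start": np.arange(n_seg) * cfg.resting_segment,
            "session": [rec.session] * n_seg,
            "condition": [rec.condition] * n_seg,
        }
    )
    return Epochs(data=data.copy(), rate=rec.rate, labels=labels, layout=rec.layout)


def reject_artifacts(
    ep: Epochs, threshold: float = 150.0
) -> Tuple[Epochs, dict]:
    """Drop epochs whose peak-to-peak amplitude exceeds ``threshold`` uV.

    Automated stand-in for visual artifact screening.  Returns the cleaned
    epochs and a report with per-reason drop counts.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if ep.n_epochs == 0:
        return ep, {"n_in": 0, "n_dropped": 0, "n_out": 0}
    ptp = ep.data.max(axis=2) - ep.data.min(axis=2)  # epochs x channels
    keep = (ptp <= threshold).all(axis=1)
    report = {
        "n_in": int(ep.n_epochs),
        "n_dropped": int((~keep).sum()),
        "n_out": int(keep.sum()),
    }
    return ep.subset(np.flatnonzero(keep)), report


def balance_segments(ep: Epochs, seed: int, by=("condition", "percept")) -> Epochs:
    """Random subsampling so every condition x percept cell has equal count.

    Cells are the cross of the label values present in ``ep.labels``; an empty
    cell raises, since a balanced contrast is then impossible.  Deterministic
    given the seed; epochs keep their original relative order.
    """
    rng = np.random.default_rng(seed)
    labels = ep.labels
    levels = [sorted(labels[col].dropna().unique().tolist()) for col in by]
    if any(len(lv) == 0 for lv in levels):
        return ep
    from itertools import product

    cells = {}
    for combo in product(*levels):
        mask = np.ones(len(labels), dtype=bool)
        for col, val in zip(by, combo):
            mask &= (labels[col] == val).to_numpy()
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"empty cell {dict(zip(by, combo))}: cannot balance")
        cells[combo] = idx
    n_min = min(len(v) for v in cells.values())
    keep = np.sort(
        np.concatenate(
            [rng.choice(idx, size=n_min, replace=False) for idx in cells.values()]
        )
    )
    return ep.subset(keep)
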