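"""Power and cross-spectral estimation on the 1-100 Hz, 1 Hz grid.

Two estimation regimes are combined, as is common for task EEG with both
slow rhythms and broadband gamma: 1-35 Hz by sliding 500 ms Hanning windows
(50% overlap, zero-padded to 1 s for the 1 Hz grid), and 36-100 Hz by DPSS
(Slepian) multitapers with +/-10 Hz half-bandwidth.  In the default
``"epoch"`` mode the tapers span the whole segment, which with K =
floor(2*T*W) - 1 gives 59 tapers for 3 s task epochs and 19 for 1 s resting
segments.  A ``"sliding"`` mode tapers 250 ms windows instead (K = 4).

All estimates are one-sided spectral densities in uV^2/Hz; cross-spectra are
accumulated with the same windows and tapers as the auto-spectra, so the
downstream coherence is properly normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import windows

from .core import AnalysisConfig, BandScheme, ChannelLayout, default_bands
from .preprocessing import Epochs

__all__ = [
    "SpectralEstimate",
    "taper_count",
    "estimate_spectra",
    "pool_bands",
    "smooth_for_display",
]

FREQS = np.arange(1, 101)  # the analysis grid, Hz


@dataclass
class SpectralEstimate:
    """Per-channel power and per-pair cross-spectra on the 1-100 Hz grid."""

    freqs: np.ndarray  # (100,)
    power: np.ndarray  # (n_channels, 100), uV^2/Hz
    cross: np.ndarray  # (n_pairs, 100), complex
    pairs: Tuple[Tuple[int, int], ...]
    n_segments: int
    metadata: dict = field(default_factory=dict)
    layout: Optional[ChannelLayout] = None

    def __post_init__(self):
        if self.power.shape[1] != len(self.freqs):
            raise ValueError("power grid mismatch")
        if np.any(self.power < -1e-12):
            raise ValueError("power must be non-negative")


def taper_count(T: float, W: float) -> int:
    """Number of Slepian tapers for duration T (s) and half-bandwidth W (Hz).

    K = floor(2*T*W) - 1, clamped to at least one taper.
    """
    if T <= 0 or W <= 0:
        raise ValueError("T and W must be positive")
    return max(int(np.floor(2 * T * W)) - 1, 1)


def _accumulate(x_win: np.ndarray, rate: float, norm: float, nfft: int, idx: np.ndarray):
    """FFT one windowed block: returns spectra at the requested bin indices.

    ``x_win``: (n_channels, n_samples) already tapered. ``norm`` = sum(w^2).
    Density scaling: S = 2 |X|^2 / (fs * sum(w^2)).
    """
    spec = np.fft.rfft(x_win, n=nfft, axis=1)[:, idx]
    scale = 2.0 / (rate * norm)
    return spec, scale


def _sliding_starts(n: int, win: int, step: int):
    return range(0, n - win + 1, step)


def estimate_spectra(
    ep: Epochs, cfg: Optional[AnalysisConfig] = None
) -> SpectralEstimate:
    """Estimate auto- and cross-spectra for all interhemispheric pairs."""
    cfg = cfg or AnalysisConfig()
    if ep.n_epochs == 0:
        raise ValueError("no epochs to estimate from")
    rate = ep.rate
    layout = ep.layout
    pairs = layout.pairs if layout is not None else ()
    n_ch = ep.n_channels
    nfft = int(round(rate))  # 1 s zero-padded FFT -> exact 1 Hz grid
    split = cfg.low_high_split

    lo_freqs = FREQS[FREQS <= split]
    hi_freqs = FREQS[FREQS > split]
    lo_idx = lo_freqs.astype(int)  # rfft bin k = f for nfft = rate
    power = np.zeros((n_ch, len(FREQS)))
    cross = np.zeros((len(pairs), len(FREQS)), dtype=complex)
    pl = np.array([p[0] for p in pairs], dtype=int)
    pr = np.array([p[1] for p in pairs], dtype=int)

    # --- low regime: sliding Hanning windows -------------------------------
    win = int(round(cfg.hann_window * rate))
    if ep.n_samples < win:
        raise ValueError("epochs shorter than the Hanning analysis window")
    step = max(int(round(win * (1 - cfg.hann_overlap))), 1)
    w = windows.hann(win, sym=False)
    norm = float(np.sum(w**2))
    n_lo = 0
    acc_p_lo = np.zeros((n_ch, len(lo_idx)))
    acc_c_lo = np.zeros((len(pairs), len(lo_idx)), dtype=complex)
    for e in range(ep.n_epochs):
        for s0 in _sliding_starts(ep.n_samples, win, step):
            seg = ep.data[e, :, s0 : s0 + win]
            seg = seg - seg.mean(axis=1, keepdims=True)
            spec, scale = _accumulate(seg * w, rate, norm, nfft, lo_idx)
            acc_p_lo += scale * np.abs(spec) ** 2
            if len(pairs):
                acc_c_lo += scale * spec[pl] * np.conj(spec[pr])
            n_lo += 1
    power[:, : len(lo_idx)] = acc_p_lo / n_lo
    if len(pairs):
        cross[:, : len(lo_idx)] = acc_c_lo / n_lo

    # --- high regime: DPSS multitaper --------------------------------------
    if cfg.multitaper_mode == "epoch":
        T = ep.duration
        n_win = ep.n_samples
        starts = [0]
    else:  # sliding short windows
        T = cfg.mt_window
        n_win = int(round(T * rate))
        starts = list(_sliding_starts(ep.n_samples, n_win, max(n_win // 2, 1)))
    K = taper_count(T, cfg.mt_half_bandwidth)
    NW = T * cfg.mt_half_bandwidth
    tapers = windows.dpss(n_win, NW, Kmax=K)  # (K, n_win)
    t_norm = np.sum(tapers**2, axis=1)  # ~1 per taper
    # FFT long enough to contain an exact 1 Hz grid
    nfft_hi = int(np.ceil(n_win / rate)) * int(round(rate))
    nfft_hi = max(nfft_hi, int(round(rate)))
    hi_idx = (hi_freqs * nfft_hi / rate).round().astype(int)
    n_hi = 0
    acc_p_hi = np.zeros((n_ch, len(hi_idx)))
    acc_c_hi = np.zeros((len(pairs), len(hi_idx)), dtype=complex)
    for e in range(ep.n_epochs):
        for s0 in starts:
            seg = ep.data[e, :, s0 : s0 + n_win]
            seg = seg - seg.mean(axis=1, keepdims=True)
            for k in range(K):
                spec, scale = _accumulate(
                    seg * tapers[k], rate, float(t_norm[k]), nfft_hi, hi_idx
                )
                acc_p_hi += scale * np.abs(spec) ** 2
                if len(pairs):
                    acc_c_hi += scale * spec[pl] * np.conj(spec[pr])
            n_hi += K
    power[:, len(lo_idx) :] = acc_p_hi / n_hi
    if len(pairs):
        cross[:, len(lo_idx) :] = acc_c_hi / n_hi

    meta = {
        "low_regime": f"hann {cfg.hann_window*1000:.0f} ms, {cfg.hann_overlap:.0%} overlap",
        "high_regime": f"dpss K={K}, NW={NW:g}, mode={cfg.multitaper_mode}",
        "taper_count": K,
        "half_bandwidth_hz": cfg.mt_half_bandwidth,
        "split_hz": split,
        "rate": rate,
    }
    return SpectralEstimate(
        freqs=FREQS.copy(),
        power=power,
        cross=cross,
        pairs=tuple(pairs),
        n_segments=ep.n_epochs,
        metadata=meta,
        layout=layout,
    )


def pool_bands(
    sp: SpectralEstimate,
    scheme: Optional[BandScheme] = None,
    exclude_gamma1: bool = False,
) -> pd.DataFrame:
    """Arithmetic band means of channel power (channels x bands).

    With ``exclude_gamma1`` the gamma_1 band (containing the 40 Hz
    stimulation artifact) is reported as NaN so it cannot enter any pooled
    gamma summary.
    """
    scheme = scheme or default_bands()
    cols = {}
    for name in scheme.names():
        f = scheme.frequencies(name)
        vals = sp.power[:, f - 1].mean(axis=1)
        if exclude_gamma1 and name == "gamma1":
            vals = np.full_like(vals, np.nan)
        cols[name] = vals
    return pd.DataFrame(cols)


def smooth_for_display(power: np.ndarray, width_hz: int = 3) -> np.ndarray:
    """Moving-average smoother for spectra shown in figures.

    Post-hoc cosmetic smoothing only; never feeds any statistic.
    """
    kernel = np.ones(width_hz) / width_hz
    return np.apply_along_axis(
        lambda r: np.convolve(np.pad(r, width_hz, mode="edge"), kernel, mode="same")[
            width_hz:-width_hz
        ],
        -1,
        power,
    )
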