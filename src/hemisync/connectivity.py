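"""Interhemispheric coherence and phase-locking per pair and band.

Magnitude-squared coherence (MSC) is computed per 1 Hz frequency step from
averaged cross- and auto-spectra, C_xy(f) = |S_xy|^2 / (S_xx * S_yy), then
averaged over the frequencies of each band.  The phase-locking value (PLV)
is the modulus of the time- and segment-averaged unit phase-difference
vector of the band-limited analytic signals; unlike MSC it is blind to
amplitude, which makes it the natural control when amplitude correlations
could masquerade as coherence changes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from .core import AnalysisConfig, BandScheme, ChannelLayout, default_bands
from .preprocessing import Epochs, bandpass_array
from .spectral import SpectralEstimate

__all__ = ["BandConnectivity", "msc", "plv", "percept_contrast"]


@dataclass
class BandConnectivity:
    """Pair x band connectivity tables in [0, 1]; NaN marks undefined cells."""

    pairs: Tuple[Tuple[int, int], ...]
    band_names: Tuple[str, ...]
    msc: Optional[np.ndarray] = None  # (n_pairs, n_bands)
    plv: Optional[np.ndarray] = None
    n_segments: int = 0
    labels: dict = field(default_factory=dict)

    def __post_init__(self):
        for arr in (self.msc, self.plv):
            if arr is None:
                continue
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
                raise ValueError("connectivity values must lie in [0, 1]")

    def table(self, which: str = "msc") -> pd.DataFrame:
        arr = getattr(self, which)
        if arr is None:
            raise ValueError(f"{which} not computed")
        return pd.DataFrame(arr, columns=list(self.band_names))


def msc(
    sp: SpectralEstimate,
    scheme: Optional[BandScheme] = None,
    exclude_gamma1: bool = False,
) -> BandConnectivity:
    """Band-pooled magnitude-squared coherence for all pairs.

    Frequencies where either auto-spectrum vanishes are flagged undefined and
    excluded from the band mean; with ``exclude_gamma1`` the artifact band is
    reported as NaN entirely.
    """
    scheme = scheme or default_bands()
    pl = np.array([p[0] for p in sp.pairs])
    pr = np.array([p[1] for p in sp.pairs])
    sxx = sp.power[pl]  # (n_pairs, 100)
    syy = sp.power[pr]
    denom = sxx * syy
    with np.errstate(divide="ignore", invalid="ignore"):
        coh = np.abs(sp.cross) ** 2 / denom
    coh[denom <= 0] = np.nan
    coh = np.clip(coh, 0.0, 1.0)

    names = scheme.names()
    out = np.full((len(sp.pairs), len(names)), np.nan)
    for j, name in enumerate(names):
        if exclude_gamma1 and name == "gamma1":
            continue
        f = scheme.frequencies(name)
        with np.errstate(invalid="ignore"):
            out[:, j] = np.nanmean(coh[:, f - 1], axis=1)
    return BandConnectivity(
        pairs=sp.pairs,
        band_names=tuple(names),
        msc=out,
        n_segments=sp.n_segments,
        labels=dict(sp.metadata.get("labels", {})),
    )


def plv(
    ep: Epochs,
    band: Tuple[float, float],
    band_name: str = "gamma2",
    cfg: Optional[AnalysisConfig] = None,
    edge_trim: float = 0.1,
) -> BandConnectivity:
    """Phase-locking value per pair in one frequency band.

    Each epoch is zero-phase band-passed, the instantaneous phase extracted
    from the analytic signal, and PLV computed as the modulus of the mean of
    exp(i * (phi_left - phi_right)) over time and segments, after trimming
    ``edge_trim`` seconds at both epoch edges.
    """
    cfg = cfg or AnalysisConfig()
    lo, hi = band
    if not 0 < lo < hi < ep.rate / 2:
        raise ValueError("band must lie within (0, Nyquist)")
    if ep.n_epochs == 0:
        raise ValueError("no epochs")
    layout = ep.layout
    pairs = layout.pairs
    trim = int(round(edge_trim * ep.rate))
    acc = np.zeros(len(pairs), dtype=complex)
    count = 0
    for e in range(ep.n_epochs):
        filt = bandpass_array(ep.data[e], ep.rate, lo, hi, cfg.fir_order_factor)
        phase = np.angle(hilbert(filt, axis=1))
        if trim:
            phase = phase[:, trim:-trim]
        for k, (li, ri) in enumerate(pairs):
            acc[k] += np.exp(1j * (phase[li] - phase[ri])).sum()
        count += phase.shape[1]
    vals = np.abs(acc) / count
    out = np.full((len(pairs), len(default_bands().names())), np.nan)
    j = default_bands().names().index(band_name)
    out[:, j] = vals
    return BandConnectivity(
        pairs=tuple(pairs),
        band_names=tuple(default_bands().names()),
        plv=out,
        n_segments=ep.n_epochs,
    )


def percept_contrast(
    conn_h: BandConnectivity, conn_v: BandConnectivity, which: str = "msc"
) -> pd.DataFrame:
    """Relative connectivity change, horizontal vs vertical, in percent.

    (C_h - C_v) / C_v * 100 per pair and band; cells with zero or undefined
    baseline propagate as NaN.
    """
    if conn_h.pairs != conn_v.pairs or conn_h.band_names != conn_v.band_names:
        raise ValueError("connectivity tables must share pairs and bands")
    a = getattr(conn_h, which)
    b = getattr(conn_v, which)
    if a is None or b is None:
        raise ValueError(f"{which} not computed on both inputs")
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (a - b) / b * 100.0
    rel = np.where(np.isfinite(rel), rel, np.nan)
    return pd.DataFrame(rel, columns=list(conn_h.band_names))
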