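"""Core domain types shared across the pipeline.

The analysis operates on 31-channel scalp EEG arranged in a left/right
mirror-symmetric equidistant montage, with interhemispheric connectivity
evaluated over 13 homologous left-right channel pairs.  Frequencies between
1 and 100 Hz are partitioned into seven canonical bands; all band-resolved
quantities downstream (power, coherence, phase-locking, entropy) are pooled
over these bands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml
from scipy.spatial import Delaunay

__all__ = [
    "DEFAULT_BANDS",
    "EVENT_LABELS",
    "BandScheme",
    "ChannelLayout",
    "Recording",
    "EventStream",
    "AnalysisConfig",
    "default_layout",
    "default_bands",
    "bonferroni_threshold",
    "montage_contact_area_cm2",
]

# Seven-band partition of the 1-100 Hz grid (inclusive integer bounds, Hz).
DEFAULT_BANDS: Dict[str, Tuple[int, int]] = {
    "delta_theta": (1, 7),
    "alpha": (8, 12),
    "beta1": (13, 25),
    "beta2": (26, 35),
    "gamma1": (36, 45),
    "gamma2": (46, 70),
    "gamma3": (71, 100),
}

EVENT_LABELS = frozenset(
    {
        "tacs_trigger",
        "dummy_trigger",
        "press_horizontal",
        "press_vertical",
        "trial_start",
        "trial_end",
        "blink_start",
        "blink_end",
    }
)

SESSIONS = ("in_phase", "anti_phase")
CONDITIONS = ("sham", "stimulation", "post", "resting")


class BandScheme:
    """Ordered, contiguous, non-overlapping partition of 1-100 Hz into bands."""

    def __init__(self, bands: Optional[Dict[str, Tuple[int, int]]] = None):
        self.bands: Dict[str, Tuple[int, int]] = dict(bands or DEFAULT_BANDS)
        self._validate()

    def _validate(self) -> None:
        expected = list(DEFAULT_BANDS)
        if list(self.bands) != expected:
            raise ValueError(f"band scheme must define exactly {expected}")
        prev_hi = 0
        for name, (lo, hi) in self.bands.items():
            if not (isinstance(lo, int) and isinstance(hi, int)):
                raise ValueError(f"band {name}: bounds must be integers")
            if lo != prev_hi + 1:
                raise ValueError(f"band {name}: bands must be contiguous from 1 Hz")
            if hi < lo:
                raise ValueError(f"band {name}: empty band")
            prev_hi = hi
        if prev_hi != 100:
            raise ValueError("band scheme must end at 100 Hz")

    def names(self) -> List[str]:
        return list(self.bands)

    def band_of(self, freq: float) -> str:
        """Name of the band containing an integer frequency on 1-100 Hz."""
        f = int(freq)
        if not 1 <= f <= 100:
            raise ValueError(f"frequency {freq} outside the 1-100 Hz grid")
        for name, (lo, hi) in self.bands.items():
            if lo <= f <= hi:
                return name
        raise AssertionError("unreachable: bands cover 1-100 Hz")

    def frequencies(self, name: str) -> np.ndarray:
        lo, hi = self.bands[name]
        return np.arange(lo, hi + 1)

    def __eq__(self, other) -> bool:
        return isinstance(other, BandScheme) and self.bands == other.bands


def default_bands() -> BandScheme:
    return BandScheme()


@dataclass(frozen=True)
class ChannelLayout:
    """31-sensor scalp geometry with hemisphere labels and homologous pairs.

    Positions live on the unit disc viewed from above, +y anterior, +x right.
    ``pairs`` lists the 13 (left, right) channel-index pairs used for
    interhemispheric connectivity; ``pair_of_interest`` indexes into it.
    ``adjacency`` is a symmetric, irreflexive neighbour structure.
    """

    names: Tuple[str, ...]
    positions: np.ndarray  # (31, 2)
    hemispheres: Tuple[str, ...]  # "left" | "right" | "midline"
    pairs: Tuple[Tuple[int, int], ...]
    pair_of_interest: int
    adjacency: Tuple[frozenset, ...]

    def __post_init__(self):
        n = len(self.names)
        if n != 31:
            raise ValueError(f"layout must have 31 channels, got {n}")
        if self.positions.shape != (n, 2):
            raise ValueError("positions must be (n_channels, 2)")
        if len(self.pairs) != 13:
            raise ValueError("layout must declare 13 interhemispheric pairs")
        for li, ri in self.pairs:
            if self.hemispheres[li] != "left" or self.hemispheres[ri] != "right":
                raise ValueError("each pair must join one left and one right channel")
        if not 0 <= self.pair_of_interest < len(self.pairs):
            raise ValueError("pair_of_interest out of range")
        for i, nbrs in enumerate(self.adjacency):
            if i in nbrs:
                raise ValueError("adjacency must be irreflexive")
            for j in nbrs:
                if i not in self.adjacency[j]:
                    raise ValueError("adjacency must be symmetric")

    @property
    def n_channels(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def adjacency_matrix(self) -> np.ndarray:
        n = self.n_channels
        mat = np.zeros((n, n), dtype=bool)
        for i, nbrs in enumerate(self.adjacency):
            for j in nbrs:
                mat[i, j] = True
        return mat

    def pair_adjacency_matrix(self) -> np.ndarray:
        """Adjacency between interhemispheric pairs.

        Two pairs are neighbours when their left members are scalp neighbours
        or their right members are (equivalent by mirror symmetry).
        """
        m = len(self.pairs)
        mat = np.zeros((m, m), dtype=bool)
        for a in range(m):
            for b in range(m):
                if a == b:
                    continue
                la, ra = self.pairs[a]
                lb, rb = self.pairs[b]
                if lb in self.adjacency[la] or rb in self.adjacency[ra]:
                    mat[a, b] = mat[b, a] = True
        return mat


def _delaunay_adjacency(points: np.ndarray) -> Tuple[frozenset, ...]:
    tri = Delaunay(points)
    nbrs: List[set] = [set() for _ in range(len(points))]
    for simplex in tri.simplices:
        for i in simplex:
            for j in simplex:
                if i != j:
                    nbrs[int(i)].add(int(j))
    return tuple(frozenset(s) for s in nbrs)


def default_layout() -> ChannelLayout:
    """Deterministic mirror-symmetric 31-channel montage on the unit disc.

    Five midline sensors plus 13 sensors per hemisphere on three concentric
    arcs (radii 0.40, 0.70, 0.95).  Homologous left/right sensors form the 13
    interhemispheric pairs; the most posterior pair (parieto-occipital) is the
    pair of interest.  Adjacency is the Delaunay triangulation of the layout.
    """
    left: List[Tuple[float, float]] = []
    # (radius, angles from +y axis, degrees) -- angles sweep front to back
    for r, angles in (
        (0.40, (30.0, 90.0, 150.0)),
        (0.70, (22.5, 67.5, 112.5, 157.5)),
        (0.95, (15.0, 45.0, 75.0, 105.0, 135.0, 165.0)),
    ):
        for a in angles:
            th = math.radians(a)
            left.append((-r * math.sin(th), r * math.cos(th)))
    # order left channels front-to-back so pair 13 is the most posterior
    left.sort(key=lambda p: -p[1])

    names: List[str] = []
    pos: List[Tuple[float, float]] = []
    hemi: List[str] = []
    for k, y in enumerate((0.90, 0.45, 0.0, -0.45, -0.90), start=1):
        names.append(f"M{k}")
        pos.append((0.0, y))
        hemi.append("midline")
    pairs: List[Tuple[int, int]] = []
    for k, (x, y) in enumerate(left, start=1):
        li = len(names)
        names.append(f"L{k:02d}")
        pos.append((x, y))
        hemi.append("left")
        ri = len(names)
        names.append(f"R{k:02d}")
        pos.append((-x, y))
        hemi.append("right")
        pairs.append((li, ri))

    positions = np.array(pos, dtype=float)
    adjacency = _delaunay_adjacency(positions)
    return ChannelLayout(
        names=tuple(names),
        positions=positions,
        hemispheres=tuple(hemi),
        pairs=tuple(pairs),
        pair_of_interest=len(pairs) - 1,
        adjacency=adjacency,
    )


@dataclass
class Recording:
    """Multichannel EEG: ``data`` is channels x samples in microvolts."""

    data: np.ndarray
    rate: float
    layout: ChannelLayout
    session: Optional[str] = None  # in_phase | anti_phase
    condition: Optional[str] = None  # sham | stimulation | post | resting
    rs_index: Optional[int] = None  # 1-6 when condition == "resting"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        if self.layout is not None and self.data.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but layout declares "
                f"{self.layout.n_channels} channels"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite samples")
        if self.session is not None and self.session not in SESSIONS:
            raise ValueError(f"session must be one of {SESSIONS}")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        if self.rs_index is not None and not 1 <= self.rs_index <= 6:
            raise ValueError("rs_index must be in 1..6")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate

    def copy_with(self, data: np.ndarray, rate: Optional[float] = None) -> "Recording":
        return Recording(
            data=data,
            rate=self.rate if rate is None else rate,
            layout=self.layout,
            session=self.session,
            condition=self.condition,
            rs_index=self.rs_index,
        )


class EventStream:
    """Time-ordered labelled events (seconds from recording start)."""

    def __init__(self, events: Sequence[Tuple[float, str]]):
        evs = [(float(t), str(lab)) for t, lab in events]
        for t, lab in evs:
            if lab not in EVENT_LABELS:
                raise ValueError(
                    f"unknown event label {lab!r}; allowed: {sorted(EVENT_LABELS)}"
                )
        times = [t for t, _ in evs]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("event times must be non-decreasing")
        starts = sum(1 for _, lab in evs if lab == "trial_start")
        ends = sum(1 for _, lab in evs if lab == "trial_end")
        if starts != ends:
            raise ValueError("every trial_start must have a matching trial_end")
        self.events: List[Tuple[float, str]] = evs

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventStream) and self.events == other.events

    def times(self, label: Optional[str] = None) -> np.ndarray:
        if label is None:
            return np.array([t for t, _ in self.events])
        return np.array([t for t, lab in self.events if lab == label])

    def with_label(self, label: str) -> "EventStream":
        return EventStream([(t, lab) for t, lab in self.events if lab == label])

    def trials(self) -> List[Tuple[float, float]]:
        """Half-open [start, end) trial windows, in order."""
        starts = [t for t, lab in self.events if lab == "trial_start"]
        ends = [t for t, lab in self.events if lab == "trial_end"]
        out = []
        for s, e in zip(starts, ends):
            if e < s:
                raise ValueError("trial_end precedes trial_start")
            out.append((s, e))
        return out

    @staticmethod
    def merged(*streams: "EventStream") -> "EventStream":
        evs = sorted((ev for s in streams for ev in s.events), key=lambda e: e[0])
        return EventStream(evs)


@dataclass
class AnalysisConfig:
    """Numeric defaults for the whole pipeline; the seed threads everywhere."""

    seed: int = 0
    # preprocessing
    bandpass_lo: float = 1.0
    bandpass_hi: float = 100.0
    fir_order_factor: int = 3  # FIR length = factor * rate / lo_corner
    notch_lo: float = 35.0
    notch_hi: float = 45.0
    notch_order: int = 8  # Butterworth, applied forward-backward
    downsample_rate: float = 1000.0
    epoch_offset: float = 0.5  # s after a reported switch
    epoch_length: float = 3.0  # s
    resting_segment: float = 1.0  # s
    artifact_threshold_uv: float = 150.0
    # spectral
    hann_window: float = 0.5  # s, 1-35 Hz regime
    hann_overlap: float = 0.5  # fraction
    mt_half_bandwidth: float = 10.0  # Hz
    mt_window: float = 0.25  # s, used only in "sliding" mode
    multitaper_mode: str = "epoch"  # "epoch" | "sliding"
    low_high_split: float = 35.0  # Hz, Hanning below, multitaper above
    # statistics
    n_permutations: int = 1000
    cluster_alpha: float = 0.05
    corr_cluster_alpha: float = 0.20
    min_cluster_channels: int = 2
    rao_mc_draws: int = 10000
    # entrainment / entropy
    entropy_normalization: str = "across_channels"  # or "across_frequencies"
    trigger_edge: str = "rising"
    # behavior
    trial_exclusion: float = 3.0  # s excluded at trial start
    min_percept_duration: float = 1.0  # s
    short_interval_policy: str = "drop"  # "drop" | "reassign"
    # eyetracking
    velocity_lambda: float = 8.0
    velocity_estimator: str = "median"  # "median" | "mean"
    ms_min_duration: float = 0.010  # s
    ms_amp_lo: float = 0.05  # deg
    ms_amp_hi: float = 1.0  # deg
    ms_merge_gap: float = 0.020  # s

    def __post_init__(self):
        if self.multitaper_mode not in ("epoch", "sliding"):
            raise ValueError("multitaper_mode must be 'epoch' or 'sliding'")
        if self.entropy_normalization not in ("across_channels", "across_frequencies"):
            raise ValueError("invalid entropy_normalization")
        if self.short_interval_policy not in ("drop", "reassign"):
            raise ValueError("invalid short_interval_policy")

    def bands(self) -> BandScheme:
        return default_bands()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def bonferroni_threshold(alpha: float, n_comparisons: int) -> float:
    """Per-comparison alpha after Bonferroni correction (alpha / m)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    return alpha / n_comparisons


def montage_contact_area_cm2(n_electrodes: int = 10, diameter_mm: float = 12.0) -> float:
    """Combined contact area of the stimulation montage's disc electrodes."""
    if n_electrodes < 1 or diameter_mm <= 0:
        raise ValueError("need at least one electrode with positive diameter")
    r_cm = diameter_mm / 20.0
    return n_electrodes * math.pi * r_cm**2
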