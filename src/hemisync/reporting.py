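"""Figure-level summaries: effect sizes, time courses, report assembly."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .connectivity import BandConnectivity

__all__ = ["SummaryReport", "cohens_d", "resting_time_course"]


@dataclass
class SummaryReport:
    """Keyed tables assembled from module outputs, with provenance."""

    tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    effect_sizes: Dict[str, float] = field(default_factory=dict)
    provenance: Dict[str, object] = field(default_factory=dict)

    def add(self, key: str, table: pd.DataFrame) -> None:
        self.tables[key] = table

    def to_text(self) -> str:
        lines = [f"# summary ({self.provenance})"]
        for key, tab in self.tables.items():
            lines.append(f"\n## {key}\n{tab.to_string()}")
        if self.effect_sizes:
            lines.append("\n## effect sizes (Cohen's d, paired)")
            for k, v in self.effect_sizes.items():
                lines.append(f"{k}\t{v:.3f}")
        return "\n".join(lines)


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Paired-design Cohen's d: mean difference over SD of the differences.

    NaN (flagged undefined) when the differences have zero variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("need two equal-length 1-D samples with n >= 2")
    d = a - b
    sd = d.std(ddof=1)
    if sd < 1e-12:
        # identical samples are a true zero effect; a constant nonzero
        # difference has no paired-design scale and stays undefined
        return 0.0 if abs(d.mean()) < 1e-12 else float("nan")
    return float(d.mean() / sd)


def resting_time_course(
    conns: Dict[int, BandConnectivity],
    band: str = "gamma2",
    pair: Optional[int] = None,
    baseline: int = 1,
) -> pd.Series:
    """Band coherence over the six resting intervals, relative to RS1.

    ``conns`` maps resting-state index (1-6) to a connectivity result; the
    value at the pair of interest (or ``pair``) is divided by the baseline
    interval's value.  Missing intervals appear as NaN gaps.
    """
    if baseline not in conns:
        raise ValueError(f"baseline RS{baseline} missing")
    ref_conn = conns[baseline]
    j = ref_conn.band_names.index(band)
    out = {}
    for k in range(1, 7):
        if k not in conns:
            out[f"RS{k}"] = np.nan
            continue
        conn = conns[k]
        p = pair if pair is not None else len(conn.pairs) - 1
        out[f"RS{k}"] = conn.msc[p, j]
    ref = out[f"RS{baseline}"]
    if not np.isfinite(ref) or ref <= 0:
        raise ValueError("baseline coherence undefined")
    return pd.Series({k: v / ref for k, v in out.items()}, name=f"{band}_rel_coherence")
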