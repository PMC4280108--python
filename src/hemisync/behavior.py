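"""Motion-ratio and switch-rate scoring of percept report streams.

The motion ratio MR = time(horizontal) / time(total) is computed per trial
from the button-press stream after three cleaning rules: redundant
(same-label) presses are collapsed, the first 3 s of every trial are
excluded, and only percept durations longer than 1 s are accepted - shorter
interludes are, by default, removed from numerator and denominator alike
(a config switch reassigns their time to the preceding percept instead).
An interval straddling the 3 s boundary keeps its post-boundary portion if
that portion alone exceeds 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import AnalysisConfig, EventStream

__all__ = ["BehaviorSummary", "motion_ratio", "switch_rate", "summarize_behavior"]


@dataclass
class BehaviorSummary:
    per_trial: pd.DataFrame  # trial, mr, switch_rate, accepted_s, excluded_s, redundant
    mr: float  # aggregate over trials (accepted-time weighted)
    switch_rate: float  # mean per-trial rate, /min


def _accepted_intervals(
    events: EventStream, trial: Tuple[float, float], cfg: AnalysisConfig
) -> Tuple[List[Tuple[float, float, str]], dict]:
    """Accepted (start, end, percept) intervals for one trial, plus counters."""
    t0, t1 = trial
    presses = [
        (t, lab)
        for t, lab in events
        if lab in ("press_horizontal", "press_vertical") and t0 <= t < t1
    ]
    redundant = 0
    collapsed: List[Tuple[float, str]] = []
    for t, lab in presses:
        if collapsed and collapsed[-1][1] == lab:
            redundant += 1
            continue
        collapsed.append((t, lab))

    cut = t0 + cfg.trial_exclusion
    raw: List[Tuple[float, float, str]] = []
    for i, (t, lab) in enumerate(collapsed):
        end = collapsed[i + 1][0] if i + 1 < len(collapsed) else t1
        start = max(t, cut)  # keep only the portion after the exclusion window
        if end > start:
            percept = "horizontal" if lab == "press_horizontal" else "vertical"
            raw.append((start, min(end, t1), percept))

    accepted: List[Tuple[float, float, str]] = []
    for start, end, percept in raw:
        if end - start > cfg.min_percept_duration:
            accepted.append((start, end, percept))
        elif cfg.short_interval_policy == "reassign" and accepted:
            s, e, p = accepted[-1]
            accepted[-1] = (s, end, p)  # absorb into the preceding percept
        # "drop": short interval contributes to neither numerator nor denominator
    counters = {
        "redundant": redundant,
        "excluded_s": min(cfg.trial_exclusion, t1 - t0),
        "n_accepted": len(accepted),
    }
    return accepted, counters


def _resolve_trial(events: EventStream, trial) -> Tuple[float, float]:
    if trial is not None:
        return float(trial[0]), float(trial[1])
    trials = events.trials()
    if not trials:
        raise ValueError("no trial boundaries in the event stream")
    return trials[0]


def motion_ratio(
    events: EventStream,
    trial: Optional[Tuple[float, float]] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> float:
    """Fraction of accepted viewing time spent perceiving horizontal motion.

    NaN when no interval survives the exclusion rules.
    """
    cfg = cfg or AnalysisConfig()
    t0, t1 = _resolve_trial(events, trial)
    accepted, _ = _accepted_intervals(events, (t0, t1), cfg)
    total = sum(e - s for s, e, _ in accepted)
    if total <= 0:
        return float("nan")
    horiz = sum(e - s for s, e, p in accepted if p == "horizontal")
    return horiz / total


def switch_rate(
    events: EventStream,
    trial: Optional[Tuple[float, float]] = None,
    cfg: Optional[AnalysisConfig] = None,
) -> float:
    """Accepted perceptual reversals per minute of trial time.

    A reversal is a label change between consecutive accepted intervals;
    the rate is normalized by the trial duration in minutes.
    """
    cfg = cfg or AnalysisConfig()
    t0, t1 = _resolve_trial(events, trial)
    accepted, _ = _accepted_intervals(events, (t0, t1), cfg)
    switches = sum(
        1 for a, b in zip(accepted, accepted[1:]) if a[2] != b[2]
    )
    minutes = (t1 - t0) / 60.0
    if minutes <= 0:
        return float("nan")
    return switches / minutes


def summarize_behavior(
    events: EventStream, cfg: Optional[AnalysisConfig] = None
) -> BehaviorSummary:
    """Per-trial and aggregate motion ratio and switch rate."""
    cfg = cfg or AnalysisConfig()
    rows = []
    for k, (t0, t1) in enumerate(events.trials()):
        accepted, counters = _accepted_intervals(events, (t0, t1), cfg)
        total = sum(e - s for s, e, _ in accepted)
        horiz = sum(e - s for s, e, p in accepted if p == "horizontal")
        mr = horiz / total if total > 0 else np.nan
        rows.append(
            {
                "trial": k,
                "mr": mr,
                "switch_rate": switch_rate(events, (t0, t1), cfg),
                "accepted_s": total,
                "excluded_s": counters["excluded_s"],
                "redundant": counters["redundant"],
            }
        )
    per_trial = pd.DataFrame(rows)
    if len(per_trial) and per_trial["accepted_s"].sum() > 0:
        w = per_trial["accepted_s"].to_numpy()
        mr_vals = per_trial["mr"].to_numpy()
        ok = np.isfinite(mr_vals)
        agg_mr = float(np.average(mr_vals[ok], weights=w[ok])) if ok.any() else float("nan")
        agg_sw = float(per_trial["switch_rate"].mean())
    else:
        agg_mr, agg_sw = float("nan"), float("nan")
    return BehaviorSummary(per_trial=per_trial, mr=agg_mr, switch_rate=agg_sw)
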