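"""Score a percept-report stream: motion ratio and switch rate.

The motion ratio MR = time(horizontal)/time(total) after the cleaning
rules (first 3 s of each trial excluded, only >1 s percepts accepted,
redundant presses collapsed).  The default generator conditions produce a
nearly balanced sham distribution.
"""

import hemisync as hs

cfg = hs.SimulationConfig(seed=21, duration=600.0)  # ten 1-minute trials
events = hs.generate_percept_stream(cfg)
summary = hs.summarize_behavior(events)

print(summary.per_trial[["trial", "mr", "switch_rate", "accepted_s"]]
      .round(3).to_string(index=False))
print(f"\naggregate MR = {100 * summary.mr:.1f}% "
      f"(generator renewal ratio: {100 * 7.8 / (7.8 + 8.2):.1f}%)")
print(f"mean switch rate = {summary.switch_rate:.1f} reversals/min")

mi = hs.motion_index(0.52, 0.49, 0.47, 0.49)
print(f"example motion index (in-phase up, anti-phase down): {mi:+.2f}")
# MR near 48.7% reflects the slight vertical bias of the default dominance
# durations; the motion index summarizes the sham-corrected phase effect.
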