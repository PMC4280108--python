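"""Generate a synthetic stimulation session and write it to disk.

Builds a percept-report stream, a 31-channel EEG recording whose
interhemispheric gamma coupling follows the reported percept, and a 40 Hz
stimulation artifact with its trigger stream, then saves everything in the
package's on-disk formats.
"""

from pathlib import Path

import hemisync as hs

out = Path("scratch/example_session")
out.mkdir(parents=True, exist_ok=True)

cfg = hs.SimulationConfig(seed=42, duration=60.0, rate=1000.0)
events = hs.generate_percept_stream(cfg)
rec = hs.generate_recording(cfg, events, session="in_phase", condition="stimulation")
rec, triggers = hs.inject_tacs_artifact(rec, amplitude=500.0, freq=40.0)

hs.write_recording(rec, out / "recording.dat")
hs.write_events(hs.EventStream.merged(events, triggers), out / "events.tsv")
hs.write_layout(rec.layout, out / "layout.tsv")

n_press = sum(1 for _, lab in events if lab.startswith("press"))
print(f"recording: {rec.n_channels} channels x {rec.n_samples} samples at {rec.rate:g} Hz")
print(f"percept reports: {n_press}; tacs triggers: {len(triggers)}")
print(f"trigger cadence: {triggers.times('tacs_trigger')[1]:.2f} s (30 cycles of 40 Hz)")
print(f"files written to {out}/")
# The trigger cadence of 0.75 s marks every 30th rising zero crossing of the
# stimulation sine; the percept stream drives the gamma coupling over time.
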