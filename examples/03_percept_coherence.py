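"""Interhemispheric coherence split by percept: the study's central contrast.

Horizontal apparent motion requires integrating tokens across both visual
hemifields, so interhemispheric gamma coherence should be higher during
horizontal than vertical percepts.  The generator injects exactly this
structure (stronger shared-source coupling during horizontal reports).
"""

import numpy as np

import hemisync as hs

cfg = hs.SimulationConfig(
    seed=11,
    duration=300.0,
    rate=1000.0,
    kappa_horizontal=0.8,
    kappa_vertical=0.4,
    dominance_mean_horizontal=6.0,
    dominance_mean_vertical=6.0,
)
events = hs.generate_percept_stream(cfg)
rec = hs.generate_recording(cfg, events, session="in_phase", condition="sham")
rec = hs.bandpass(rec, 1.0, 100.0)

epochs = hs.epoch_percepts(rec, events)
epochs = hs.balance_segments(epochs, seed=0, by=("percept",))
is_h = (epochs.labels["percept"] == "horizontal").to_numpy()
conn_h = hs.msc(hs.estimate_spectra(epochs.subset(np.flatnonzero(is_h))))
conn_v = hs.msc(hs.estimate_spectra(epochs.subset(np.flatnonzero(~is_h))))

poi = rec.layout.pair_of_interest
contrast = hs.percept_contrast(conn_h, conn_v)
print(f"epochs per percept after balancing: {is_h.sum()}")
print(f"gamma1 coherence at pair of interest: "
      f"horizontal={conn_h.msc[poi, 4]:.3f} vertical={conn_v.msc[poi, 4]:.3f}")
print(f"relative gamma increase (horizontal vs vertical): "
      f"{contrast.loc[poi, 'gamma1']:+.1f}%")

plv_h = hs.plv(epochs.subset(np.flatnonzero(is_h)), (36.0, 45.0), "gamma1")
plv_v = hs.plv(epochs.subset(np.flatnonzero(~is_h)), (36.0, 45.0), "gamma1")
print(f"amplitude-free control (PLV): horizontal={plv_h.plv[poi, 4]:.3f} "
      f"vertical={plv_v.plv[poi, 4]:.3f}")
# A positive contrast confirmed by PLV shows the coupling difference is a
# phase effect, not an amplitude-correlation artifact.
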