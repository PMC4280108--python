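"""Alpha-amplitude x gamma-envelope correlation (three-step chain).

Band-pass 8-12 Hz -> alpha amplitude; band-pass 46-70 Hz -> gamma
amplitude; band-pass that amplitude 8-12 Hz and take its envelope: the
strength of alpha-rhythmic gamma modulation.  Correlating the two per 1 s
segment and averaging Fisher-z values quantifies alpha-gamma coupling.
"""

import hemisync as hs
from hemisync.preprocessing import segment_resting

cfg = hs.SimulationConfig(seed=3, duration=90.0, rate=1000.0, alpha_gamma_rho=-0.5)
rec = hs.generate_recording(cfg, None, condition="resting")
aec_map = hs.aec_from_epochs(segment_resting(rec))

li, ri = rec.layout.pairs[rec.layout.pair_of_interest]
print(f"segments analysed: {aec_map.n_segments}")
print(f"mean Fisher-z at posterior pair: "
      f"left={aec_map.z[li]:+.3f} right={aec_map.z[ri]:+.3f}")
print(f"back-transformed r: left={aec_map.r[li]:+.3f} right={aec_map.r[ri]:+.3f}")
print(f"generative coupling rho = {cfg.alpha_gamma_rho:+.1f} -> "
      f"recovered sign {'matches' if aec_map.z[li] < 0 else 'differs'}")
# Negative coupling (the antagonistic alpha-gamma interplay): moments of
# high alpha amplitude carry weaker alpha-rhythmic gamma modulation.  The
# chain recovers the sign; its magnitude is attenuated by envelope noise.
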