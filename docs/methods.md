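# Methods

This note documents the models, estimators, numerical choices and known
limitations of `hemisync`. It is the design record a maintainer should read
before changing defaults.

## Sensor model

Analyses assume a 31-channel scalp array with exact left–right mirror
symmetry: 5 midline sensors and 13 per hemisphere on three concentric arcs
(radii 0.40, 0.70, 0.95 on the unit disc, +y anterior). The true cap
geometry of such experiments is rarely published; the layout here is a
declared synthetic stand-in whose only load-bearing properties are the 13
homologous left–right pairs, a most-posterior (parieto-occipital) pair of
interest, and a symmetric, irreflexive adjacency (Delaunay triangulation of
the sensor positions). Cluster inference needs nothing more than a declared
adjacency; conclusions about specific scalp locations transfer to real caps
only by analogy.

## Synthetic-data generator

The generator (`hemisync.synth`) emulates the statistical structure the
analysis chain assumes, not the biophysics that produces it. Components,
all at a default 5 kHz sampling rate (tests and examples use 1 kHz; the
rate is a config field and every estimator is rate-agnostic):

- **Interhemispheric gamma coupling.** Each hemisphere's gamma signal is
  `sqrt(kappa)*common + sqrt(1-kappa)*private`, with unit-variance
  narrowband noise sources (Gaussian spectral profile centred on the 40 Hz
  carrier, 10 Hz wide). The population magnitude-squared coherence between
  hemispheres is then `kappa**2`, monotone in `kappa`, and < 1 — matching
  broadband physiological gamma rather than a sinusoid. A per-percept
  coupling (`kappa_horizontal`, `kappa_vertical`) switches instantaneously
  at report events; no reaction-time lag is modelled. An optional
  interhemispheric phase lag rotates the analytic phase of the shared
  source.
- **Alpha rhythm and alpha–gamma antagonism.** A shared slow modulator m(t)
  (band-limited to roughly 0.5–2 Hz so it is visible within 1 s analysis
  segments) drives the alpha amplitude, `A = 1 + 0.4*m`. A second
  modulator `m_g = rho*m + sqrt(1-rho^2)*m_ind` drives the depth of an
  alpha-rhythmic pulsation of the gamma envelope,
  `genv = 1 + p0*(1 + 0.4*m_g)*cos(phi_alpha)` with `p0 = 0.5`. The
  correlation between alpha amplitude and gamma-modulation strength is
  therefore `rho` by construction. Alpha and the secondary 46–70 Hz gamma
  component use frequency-modulated constant-modulus carriers (instantaneous
  frequency wandering ±~1 Hz and ±~2.5 Hz around 10 and 58 Hz): the phase of
  band-limited noise slips at envelope nulls and those slips, not the
  analysis chain, were the dominant noise in envelope readouts.
- **Background.** Per-channel 1/f noise (exponent 1.0, 8 µV RMS) by
  spectral shaping of white noise.
- **Spatial projection.** Sources project with Gaussian gains centred on
  the posterior pair of interest and are confined to their own hemisphere
  (midline sees both). Real EEG has cross-hemispheric volume conduction;
  it is deliberately absent here so that pair coherence reflects the source
  coupling and `kappa = 0` sits at the estimator's bias floor. Passing
  tests therefore demonstrate estimator correctness, not robustness to
  volume conduction — the study design addresses that by contrasting
  conditions, not the estimator.
- **Stimulation artifact.** A pure sinusoid (default 500 µV, 40 Hz) with a
  smooth posterior gain profile; a trigger marks every 30th rising zero
  crossing (0.75 s at 40 Hz).
- **Behavior.** Percept dominance durations are Gamma(shape 3) with
  percept-specific means; defaults mu_h = 7.8 s, mu_v = 8.2 s give a
  renewal-process motion ratio of 48.75%, the near-balanced sham
  distribution these experiments report. Trials are 1 minute.
- **Gaze.** Ornstein–Uhlenbeck fixational drift (0.04° SD, 1 s relaxation),
  EyeLink-grade measurement noise (0.0015° SD), Poisson microsaccades
  (default 1.5/s, amplitudes 0.1–0.6°, main-sequence-like durations
  22–34 ms, minimum-jerk displacement profile, exponential return drift),
  optional blinks. Ground truth (onset, duration, amplitude, direction,
  peak velocity) is returned alongside.

Default effect sizes were fixed once from the study conditions the pipeline
targets: `kappa_vertical = 0.55` and `kappa_horizontal = 0.5755` make the
model's coherence ratio `(kappa_h/kappa_v)^2 = 1.095`, i.e. a +9.5%
relative gamma-coherence increase for the horizontal percept;
`alpha_gamma_rho = -0.5` encodes the antagonistic alpha–gamma interplay
(sign from the physiology, magnitude a free parameter — no quantitative
generative model exists for it).

Randomness contract: all draws go through `numpy.random.default_rng(seed)`
(PCG64); a fixed seed gives bit-identical output across runs and platforms.

## Preprocessing

- Band-pass 1–100 Hz: windowed-sinc FIR (Hamming), length 3 periods of the
  low corner (odd, type I), applied twice via centred FFT convolution on
  reflection padding — zero net phase, squared magnitude response.
- Notch 35–45 Hz (stimulation artifact): order-8 Butterworth band-stop
  applied forward–backward, realized as its exact squared-magnitude
  zero-phase response on the FFT grid over tapered odd-reflection padding.
  Time-domain `filtfilt` of so sharp a stop-band rings for ~0.5 s at the
  edges regardless of padding (and Gustafsson initialization is unstable at
  this order); the frequency-domain form has the identical response with
  interior residual < 0.1%. The first/last ~0.5 s of a notched recording
  remain the least trustworthy — epoching away from recording edges (as the
  pipeline does) avoids them. Applied identically to sham, stimulation and
  post data so conditions stay comparable.
- Downsampling 5 kHz → 1 kHz: FIR anti-alias + decimation
  (`scipy.signal.decimate`, zero-phase), integer ratios only.
- Percept epochs: [t + 0.5 s, t + 3.5 s) after each reported switch,
  labelled with the new percept; epochs crossing the next switch, a trial
  boundary, or the recording end are dropped, guaranteeing percept purity
  (the stricter of the two possible readings; flagged as a design choice).
- Resting data: non-overlapping 1 s segments.
- Artifact rejection: automated peak-to-peak threshold (default 150 µV on
  any channel) standing in for visual inspection; drop counts reported.
- Balancing: random subsampling without replacement to the minimum
  condition × percept cell count, deterministic per seed; an empty cell is
  an error naming the cell.

## Spectral estimation

Two regimes on the 1–100 Hz, 1 Hz grid, both one-sided densities in
µV²/Hz with matched scaling (`2/(fs*sum(w^2))`), cross-spectra accumulated
with the same windows/tapers:

- 1–35 Hz: sliding 500 ms Hanning windows, 50% overlap (standard practice;
  the overlap is not dictated by the printed methods), zero-padded to 1 s
  for the exact 1 Hz grid.
- 36–100 Hz: DPSS multitapers, half-bandwidth W = 10 Hz, K = ⌊2TW⌋ − 1.
  Default mode tapers the whole segment: T = 3 s task epochs give K = 59,
  T = 1 s resting segments give K = 19 — the published taper counts. The
  printed "250 ms window length" is arithmetically incompatible with 59
  tapers at ±10 Hz (it implies T = 3 s); the literal short-window reading
  is available as `multitaper_mode="sliding"` (250 ms windows, K = 4) but
  is not the default.

A 3 Hz moving-average smoother exists for display only and never feeds a
statistic. Band pooling is the arithmetic mean over each band's 1 Hz bins;
with `exclude_gamma1` the 36–45 Hz band (containing the stimulation
artifact) is reported as NaN so it cannot enter pooled gamma summaries.
Undefined cells propagate as NaN, never as zero.

## Connectivity

MSC per frequency then band-averaged; frequencies with vanishing power are
flagged undefined and excluded from the mean. PLV from zero-phase
band-passed analytic phases, 100 ms edge trim per epoch. Both are invariant
to channel scaling; the coherence bias floor for independent signals is
~1/n_segments (the Hanning/multitaper averaging lowers it further). The
percept contrast is reported in percent with NaN on zero baselines.

## Circular statistics and entropy

- Rao's spacing test: U = ½·Σ|T_i − λ| over sorted circular spacings
  (degrees); p from a seeded Monte-Carlo uniform null (default 10,000
  draws) at the observed n — exact at any sample size rather than relying
  on asymptotic tables, and reproducible by seed.
- Two-sample Kuiper: V = D⁺ + D⁻ between the empirical circular CDFs over
  the pooled sample (rotation-invariant); p from the standard asymptotic
  series with effective n = n_a·n_b/(n_a+n_b). Calibration is conservative
  at small n (checked: false-positive rate ≤ nominal at n = 40).
- Group rule: significant iff >26 of 28 per-comparison tests pass the
  Bonferroni-corrected per-test alpha (0.05/31 ≈ 0.0016 across electrodes;
  0.05/4 = 0.0125 across bands). The rule is implemented verbatim with the
  general (k, n, threshold) parameterization stored in config; its
  derivation (14 subjects × 2 sessions) is plausible but not asserted.
- Dummy triggers for sham/post are laid down at exactly 0.75 s cadence from
  the first trial start; the trigger edge (rising) is configurable.
- Spectral entropy: natural log. Default normalization divides each
  frequency's power by its sum across channels and accumulates
  H = −Σ_f S·log S over each band group (δ/θ, α, β₁+β₂, γ₂+γ₃); a config
  switch normalizes per channel across frequencies instead. The wording of
  the source normalization is ambiguous; across-channels is the default and
  both are tested. Zero-power cells contribute 0 (0·log 0 := 0); all-zero
  rows are counted in `n_undefined` rather than poisoning band sums, which
  keeps the one-hot limit (H = 0) exact.

## Cross-frequency chain

Implemented exactly as the three-step operator order prescribes (envelope
of the alpha-filtered gamma amplitude), although a single demodulation
would be simpler — fidelity to the operator order is the point. Zero-phase
FIR band-passes (8–12 Hz, 46–70 Hz), 100 ms edge trim per 1 s segment,
per-segment Pearson r, Fisher z = atanh(r), z averaged and back-transformed.
Zero-variance segments are skipped and counted.

A quantitative caveat, measured on the generator: with ~1 Hz modulators and
1 s segments, the expected per-segment sample correlation is capped near
0.54 for a true ρ = 0.6 even for a perfect chain (few independent modulator
samples per window), and envelope noise (spectral leakage of the 36–45 Hz
oscillator into 46–70 Hz, in-band 1/f background) multiplies in, leaving
full-chain readouts near 0.3. The chain therefore recovers the *sign* and
*ordering* of ρ reliably — which is what the inference uses — while
magnitude recovery is validated at the level the coupling is defined:
`aec()` on generator-level envelope pairs recovers ρ within ±0.15.

## Cluster permutation inference

Element-wise dependent-samples t (or r→t via the Student transform for the
correlation variant), two-sided thresholds at the forming alpha (5% for the
t-test, 20% for correlations), positive and negative clusters formed
separately over the declared adjacency (space × frequency adjacency links
1 Hz-adjacent bins regardless of band boundaries), cluster statistic = sum
of t. The null permutes condition labels within subjects — sign flips of
the per-subject difference (or of the ΔCoh rows for the correlation test;
shuffling MI across subjects is available behind a flag) — taking the
maximum |cluster sum| per iteration over both signs. p-values include the
observed labelling: p ≥ 1/(n_perm + 1). The correlation variant reports
only clusters of ≥2 adjacent channels with p < 0.05. Degenerate-variance
elements are excluded; ties at the forming threshold use strict
inequality. Permutation t-values are computed vectorized (sign flips only
change the mean, not the sum of squares), which keeps 400-replicate
calibration runs in minutes.

Family-wise error calibration (400 null replicates, 14 subjects × 31
sensors, 500 permutations each) keeps the significant-cluster rate inside
the binomial 95% interval around 5% for both variants.

## Behavior

Interval accounting per trial: collapse redundant presses; clip the first
3 s; accept only intervals whose (clipped) duration exceeds 1 s; an
interval straddling the 3 s boundary keeps its post-boundary portion if
that portion alone qualifies. Dropped short intervals vanish from numerator
and denominator (default) or are absorbed into the preceding percept
(`short_interval_policy="reassign"`). The trailing percept counts to
trial end. Switch rate = accepted label changes per trial minute (trial
duration, matching the published definition; the accepted-time variant was
considered and rejected because the worked example divides by the trial
minute). MR respects the label-swap symmetry MR ↔ 1 − MR.

## Eye tracking

Two-step detection: prefilter masks blinks, excursions <0.05° or >1.6°,
±1 s around button presses, and drops epochs retaining <80% valid samples;
detection then computes 2-D velocity with the 5-sample moving-difference
kernel, estimates per-axis dispersion with the median-based robust
estimator (`sqrt(median(v^2) - median(v)^2)`; plain SD behind a config
flag), thresholds at λ = 8 on the elliptical criterion, merges detections
closer than 20 ms, and keeps events with run duration strictly above 10 ms
and amplitude in [0.05°, 1°]. The strict duration inequality compensates
the kernel's smear: a genuinely sub-10 ms impulse produces a run of at most
the floor itself, while true ≥10 ms saccades exceed it by at least one
sample at 500 Hz. Amplitude is the per-axis peak-to-peak extent over the
event (rotation-invariant with the elliptical threshold). The pixel→degree
conversion assumes 60 cm viewing distance and screen metadata.

## Problem sizes used in tests and acceptance

Module and acceptance tests run the generator at 1 kHz with durations of
20–600 s (chosen so coherence estimates have ~0.02 standard error where a
contrast is asserted), 400 replicates for error-rate calibration, 500–1000
permutations per test, and 10 seeds for recovery-rate claims. These sizes
are the package's own validation conditions; the full study-scale defaults
(5 kHz, 20-minute stimulation blocks) run identically but longer.

## Known limitations

- No volume conduction or common reference artifact in the generator; MSC
  here isolates source coupling.
- No entrainment dynamics: stimulation does not alter the ongoing gamma
  phase in the generator (the artifact is purely additive), so
  phase-at-trigger concentration is validated on constructed phase-locked
  signals, not emergent entrainment.
- Outlasting (post-stimulation) effects are emulated by setting
  `kappa_resting` per resting interval, not by a plasticity model.
- The EDF writer is minimal (16-bit, 1 s records, padded final record);
  it round-trips through mne within quantization but does not cover EDF+
  annotations.
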