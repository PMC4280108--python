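# hemisync

Analysis pipeline for interhemispheric EEG gamma-band coupling under
dual-site 40 Hz transcranial alternating-current stimulation (tACS), built
around bistable apparent-motion perception — together with a synthetic-data
generator that reproduces the statistical structure the analysis assumes,
so every stage can be validated against known ground truth.

## The scientific problem

When an ambiguous stroboscopic motion stimulus is perceived as *horizontal*
motion, visual information from the two hemifields must be integrated across
hemispheres; interhemispheric gamma-band synchronization over parieto-occipital
cortex is the candidate mechanism. Dual-site 40 Hz tACS applied in-phase
(0° between hemispheres) should strengthen that coupling and bias perception
toward horizontal motion; anti-phase stimulation (180°) should weaken it.
Testing this requires a chain of estimators and nonparametric statistics:

- **Spectra**: two-regime estimation on a 1–100 Hz, 1 Hz grid — sliding
  500 ms Hanning windows for 1–35 Hz, DPSS (Slepian) multitapers with
  ±10 Hz half-bandwidth above (K = ⌊2·T·W⌋ − 1: 59 tapers for 3 s task
  epochs, 19 for 1 s resting segments), pooled over seven bands
  (δ/θ 1–7, α 8–12, β₁ 13–25, β₂ 26–35, γ₁ 36–45, γ₂ 46–70, γ₃ 71–100 Hz).
- **Connectivity**: magnitude-squared coherence
  C\_xy(f) = |S\_xy|² / (S\_xx·S\_yy) over 13 homologous left–right sensor
  pairs, band-averaged; phase-locking value
  PLV = |⟨e^{i(φ\_x−φ\_y)}⟩| as the amplitude-free control. The percept
  contrast is (C\_h − C\_v)/C\_v.
- **Entrainment statistics**: instantaneous band-limited phase sampled at
  every 30th rising zero crossing of the driver (0.75 s cadence; dummy
  markers during sham), tested with Rao's spacing test (Monte-Carlo null)
  and a two-sample circular Kuiper test; group calls by the fixed binomial
  rule (>26 of 28 comparisons at Bonferroni-corrected α). Shannon spectral
  entropy H = −Σ S log S on normalized spectra tracks stimulation-induced
  regularity.
- **Cross-frequency coupling**: the three-step amplitude-envelope chain
  (α amplitude; γ₂ amplitude; envelope of the 8–12 Hz-filtered γ₂
  amplitude), Pearson-correlated per 1 s segment and Fisher-z averaged.
- **Inference**: cluster-based permutation tests (dependent-samples t and
  the permuted-correlation variant linking the behavioral motion index
  MI = (MR\_in − MR\_shamIn) − (MR\_anti − MR\_shamAnti) to coherence
  differences ΔCoh, with t = r·√(n−2)/√(1−r²), 20% forming alpha, ≥2
  adjacent channels, within-subject label permutation).
- **Controls**: motion-ratio/switch-rate scoring with the published
  exclusion rules, and two-step velocity-threshold microsaccade detection
  (λ = 8 robust SDs, ≥10 ms, 0.05–1°).

The package is a library: import `hemisync`, or run the narrative scripts
in `examples/` (one per capability).

## Worked example

`examples/03_percept_coherence.py` generates a 300 s sham session whose
interhemispheric gamma coupling is stronger during horizontal percepts
(shared-source mixing weight κ\_h = 0.8 vs κ\_v = 0.4), then runs the full
chain — band-pass, percept epoching, balancing, multitaper spectra,
coherence, contrast:

```
epochs per percept after balancing: 17
gamma1 coherence at pair of interest: horizontal=0.402 vertical=0.099
relative gamma increase (horizontal vs vertical): +307.4%
amplitude-free control (PLV): horizontal=0.594 vertical=0.253
```

The coherence at the posterior pair of interest tracks κ² (0.402 ≈
attenuated 0.64; 0.099 ≈ attenuated 0.16), the percept contrast is
recovered with the correct sign, and the PLV control confirms it is a
phase effect rather than an amplitude artifact.

`examples/06_cluster_statistics.py` seeds a posterior coupling between the
behavioral motion index and coherence-difference maps across 14 simulated
subjects and recovers it as a significant cluster:

```
correlation cluster: p = 0.001, members ['L11', 'R11', 'L12', 'L13', 'R13'], r in [0.39, 0.98]
```

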