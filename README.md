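# deltrain

Delta-band prosodic entrainment analysis on synthetic MEG-like sessions.

## The problem

When listeners hear a repetitive prosodic (pitch) contour, slow cortical
activity synchronizes with the contour's cycle rate — *entrainment* —
and the entrained rhythm can persist after the sound stops, carrying a
temporal prediction about what comes next.  In the paradigm this package
models, a delexicalized pitch contour (SLOW, 1.73 s cycles ≈ 0.6 Hz, or
FAST, 1.102 s cycles ≈ 0.9 Hz) repeats three times, then a sentence is
shown word by word at 314 ms/word.  A SLOW contour predicts a six-word
sentence; if only five words appear, the prediction is falsified at the
missing word's onset and an omission evoked field (ERF) should appear.

`deltrain` implements the full analysis chain for this paradigm —
stimulus synthesis, epoching, pitch–MEG coherence and power spectra on a
0.1 Hz grid, cluster-based sign-flip permutation statistics, the
rate-specific response (RSR) index, DICS/LCMV beamforming on a toy
forward model, and omission-ERF contrasts — together with a generative
model that simulates multichannel sessions with all three effects
planted, so every stage is testable without any recordings.  It is aimed
at methods work: validating estimator calibration (type-I error,
coherence bias), parameter recovery, and power analyses for entrainment
designs.

## The core quantities

* Pitch–MEG coherence across K trials, per channel and frequency bin:
  `C(f) = |Σₖ Xₖ(f)·conj(Yₖ(f))|² / (Σₖ|Xₖ(f)|² · Σₖ|Yₖ(f)|²)`,
  with X the interpolated F0 reference; null level ≈ 1/K.
* Cluster statistics: per-channel paired t thresholded two-tailed at
  α = 0.05, connected components over the sensor graph (≥3 channels),
  cluster mass Σt against the sign-flip permutation null of the maximal
  mass (5,000 permutations; exact enumeration for small n).
* Rate-specific response per ROI:
  `RSR = (R₀.₆,SLOW − R₀.₆,FAST) + (R₀.₉,FAST − R₀.₉,SLOW)` — positive
  when brain responses follow each condition's stimulation rate.
* DICS beamformer: `w = (LᵀC⁻¹L)⁻¹LᵀC⁻¹` from the condition-pooled
  cross-spectral density (common spatial filter), applied per condition;
  LCMV is the time-domain analog for the omission ERF.

## Worked example

```python
import numpy as np
from deltrain import simulate as sim, spectral

cfg = sim.SimConfig(n_subjects=4, n_trials=64, seed=8)
model = sim.build_sensor_model(seed=cfg.seed)
coh = 0
for s, rng in enumerate(sim.subject_seeds(cfg.seed, cfg.n_subjects)):
    rec, truth = sim.simulate_subject(cfg, sim.generate_plan_for(cfg, s), model, rng)
    ep = spectral.extract_epochs(rec, phase="entrainment", condition="SLOW")
    ref = spectral.reference_epochs(ep)
    coh = coh + spectral.coherence_spectrum(ref, ep).channel_mean()
coh /= cfg.n_subjects
grid = spectral.SpectralGrid()
print("peak:", round(spectral.peak_frequency(coh, (0.1, 1.5), grid.frequencies), 1))
print("C at 0.6 Hz:", round(coh[grid.bin_of(0.6)], 3))
```

prints

```
peak: 0.6
C at 0.6 Hz: 0.145
```

i.e. the group-averaged pitch–MEG coherence of the SLOW condition peaks
at the 0.6 Hz bin — the contour's cycle rate — with a peak coherence of
≈0.15 against a 1/K ≈ 0.03 null level.  The analogous FAST analysis
peaks at 0.9 Hz, and target-phase power spectra peak at the same rates
after the sound has ended (sustained entrainment).

## The analysis sequence

Numbered drivers under `analysis/` run the study end to end at reduced
scale and write tables under `results/`:

| script | what it shows |
| --- | --- |
| `01_simulate.py` | contour audio (WAV), F0 tracks, session timeline, one simulated session |
| `02_entrainment_coherence.py` | group coherence spectra; 0.6-vs-0.9 Hz sensor clusters |
| `03_target_power.py` | target-phase power spectra and clusters (sustained entrainment) |
| `04_source_rsr.py` | DICS ROI responses, RSR index, condition × frequency interaction |
| `05_omission_erf.py` | omission ERF contrasts (300–600, 0–120 ms) and LCMV source map |

A `deltrain` command-line interface wraps the same pipeline
(`deltrain all --smoke --seed 0 --outdir out/`).

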