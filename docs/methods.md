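# Methods

`deltrain` re-implements, as a tested pipeline over synthetic data, a
three-part MEG analysis of delta-band prosodic entrainment: (1) during
exposure to a repetitive pitch contour, sensor activity coheres with the
contour at its cycle rate; (2) during a subsequent visual sentence, power
at that rate persists; (3) when the contour's duration prediction is
falsified — a 5-word sentence after a slow contour that predicted six
words — an evoked field appears at the missing word's onset.  Because no
recordings ship with the package, a generative model plants all three
effects through a toy forward model, and every analysis stage is verified
by recovering what was planted.

## Paradigm timing

Contours last 1,570 ms (SLOW) or 942 ms (FAST) and repeat three times
with 160 ms pauses, so one cycle lasts 1.73 s (≈0.6 Hz printed; exactly
0.578 Hz) or 1.102 s (≈0.9 Hz; exactly 0.907 Hz).  A silent lead-in of
1,884 ms before FAST contours equalizes the entrainment phase at 5.19 s
across conditions (the per-repetition reading, 628 ms, is selectable via
`lead_mode="per_repetition"`).  Words appear at 314 ms; SHORT sentences
have 5 words (1.57 s), LONG 6 (1.884 s).  The omission point of a SHORT
sentence is 1,570 ms after sentence onset.  A delay of 500 + U(0, 250) ms
(quantized to the 4 ms sample grid) follows each sentence.  The computed
FAST entrainment duration is 3 × 1.102 = 3.306 s; a printed value of
3.32 s exists in the literature for this window, but the arithmetic value
is used throughout.

## Stimuli

Contours are delexicalized by the PURR rule: a sine at F0 plus the second
harmonic at 1/4 and the third at 1/16 amplitude, with phase accumulated
as 2π∫f0 dt so glides are continuous.  The synthetic F0 contour is a
two-accent rise–fall (main accent a third of the way in, smaller late
accent) spanning 116–267 Hz, the range of the recordings the paradigm
was built from; contours are lowered by 55 Hz before synthesis.  Loudness
calibration (dB SPL) has no software counterpart; waveforms are
peak-normalized.  Pauses are unvoiced; cubic-spline interpolation fills
them when a continuous F0 reference is needed.

## Generative model

A 102-sensor array on the unit sphere observes 90 source nodes through
an inverse-square-distance, fixed-orientation leadfield whose columns
are norm-normalized (depth-bias removal).  Sixteen named areas
(EAC, STG, IFG, FOP, BA4, BA6, DLPFC, TPOJ × hemisphere) occupy
stereotyped positions with two nodes each; nodes of one area share an
orientation up to a small scatter, as dipoles of a cortical patch do —
without this, simultaneously active nodes of an area have near-orthogonal
field patterns and a beamformer sees phantom sources between them.
Remaining nodes are randomly placed, randomly oriented fillers.

Planted effects, per trial:

* **Entrained response** (rEAC/rSTG): one kernel per contour cycle, the
  cycle's interpolated F0 modulation low-passed at 1.2 Hz (zero-phase;
  the neural response follows the slow pitch modulation), unit RMS,
  amplitude `entrain_amp`; the whole train shifts by a per-trial jitter
  of 0.3 rad (≈80 ms at the SLOW rate).  Being cycle-locked but
  non-sinusoidal, the response carries the cycle rate and its harmonics.
* **Sustained oscillation** (lFOP/lEAC): a sinusoid at the trial's cycle
  rate spanning the sentence phase, amplitude `sustain_amp`.  Its phase
  is redrawn uniformly per trial: an endogenous continued rhythm keeps
  the *rate*, not the stimulus phase.  This choice is forced by the
  analysis geometry — the target epoch is exactly one period, and a
  Hann-windowed single period of a phase-locked sinusoid has a spectral
  argmax that swings a full bin with the start phase, so a strictly
  phase-locked source cannot reproduce a stable peak at the stimulation
  rate; a uniform phase makes the trial-averaged spectrum peak at the
  rate, and also keeps the oscillation out of trial-averaged evoked
  fields.
* **Omission response** (lIFG/lFOP/lDLPFC/rTPOJ), SLOW×SHORT trials
  only: a biphasic deflection at the omission point (early lobe peaking
  ≈60 ms, late lobe 250–550 ms peaking ≈400 ms), amplitude
  `omission_amp`.
* Optional word-evoked impulses (100 ms lobes at each word onset,
  ≈3.18 Hz; posterior filler nodes), default off.

Sensor noise is spectrally shaped Gaussian noise with a 1/f^0.8
amplitude-squared profile plus a white component (0.8 : 0.6 amplitude
mix), unit sd in arbitrary units.  The exponent deserves a note: with an
exponent of exactly 1.0, the noise-power ratio between the 0.9 and 1.0 Hz
bins (1.11) coincides numerically with the Hann-leakage ratio of the
3-cycle FAST response train (1.13), and the group FAST coherence argmax
becomes a coin flip at *any* source amplitude — no trial-stochastic
mechanism can separate neighboring bins that sample the same spectral
line, because leakage inherits the line's phase ramp.  An exponent of
0.8, still well within the range reported for MEG background spectra,
breaks the coincidence and yields a stable ≈2% margin for the 0.9 Hz
bin.

Default amplitudes (entrain 0.6, sustain 8.0, omission 1.5, in units of
the noise sd through unit-norm leadfield columns) were calibrated once so
that a 20-subject cohort reproduces the qualitative group results: peak
group coherence ≈0.15, clearly significant sensor clusters, and a
target-phase power argmax at the stimulation rate (the sustained source
must dominate the window-shaped noise maximum at ≈1.2/T, which is why
its amplitude is large).  Effect sizes in physical units are not
recoverable from published text; these are simulation choices, not
reported values.

## Sensor-space analysis

Entrainment epochs span the three cycles from contour onset (5.19 s SLOW
/ 3.306 s FAST), target epochs one cycle from sentence onset (1.73 /
1.102 s), sample counts floored (5.19 s → 1,297 samples at 250 Hz), each
epoch demeaned.  Spectra are estimated by Hann-tapering the data length,
zero-padding to 10 s, and evaluating the DFT on the 0–3 Hz grid at
0.1 Hz (31 bins); 0.6, 0.9 and 1.2 Hz fall exactly on bins.  Pitch–MEG
coherence is magnitude-squared coherence across trials against the
interpolated repeated-contour F0 track (resampled to 250 Hz, demeaned
per epoch); its null level is 1/K for K trials.  Target-phase power is
the trial-averaged squared magnitude.  The true first harmonic of the
SLOW cycle (2/1.73 = 1.156 Hz) lies midway between the 1.1 and 1.2 Hz
bins; the generator reproduces a secondary harmonic hump over that bin
pair, and which of the two bins carries its maximum is sub-resolution,
so checks assert a local maximum over {1.1, 1.2} rather than bin parity.

## Statistics

Condition contrasts use cluster-based sign-flip permutation tests:
paired t per channel, two-tailed threshold at the cluster-forming α
(default 0.05, i.e. 0.025 per tail), connected suprathreshold components
over the k-nearest sensor graph (k = 6), clusters of fewer than 3
channels discarded, cluster mass = Σt, and a per-polarity null of the
maximal mass over 5,000 sign flips (full enumeration when 2ⁿ ≤ n_perm,
making the test exact; otherwise Monte-Carlo with the +1 correction).
Clusters are evaluated at 0.025 per tail; comparison at 0.05 is a
configuration switch.  Type-I calibration on pure-noise cohorts at the
102-channel scale gives a family-wise rate of ≈0.04.

ROI-level rate specificity uses
RSR = (R₀.₆,SLOW − R₀.₆,FAST) + (R₀.₉,FAST − R₀.₉,SLOW), positive when
responses follow the stimulation rate; the condition × frequency
interaction is the within-subject difference-of-differences tested by
sign-flip permutation, with within-condition 0.6-vs-0.9 paired tests as
post-hocs.  Mixed-effects modelling is intentionally not re-implemented;
the permutation contrast answers the same within-subject hypothesis.

## Source space

Cross-spectral density matrices over all sensors plus the pitch
reference are computed at 0.6 / 0.9 Hz with Hann tapering and 20 s
padding.  DICS filters w = (LᵀC⁻¹L)⁻¹LᵀC⁻¹ use the real part of the
condition-pooled CSD, regularized by λ·mean(diag) with λ = 0.05
(common-filter strategy: filters from pooled data applied to each
condition's CSD, avoiding single-condition bias).  Node power is wCwᵀ,
node–reference coherence |w c_ref|²/(power·S_ref).  The time-domain
analog (LCMV) uses the covariance of pooled SHORT-trial ERF epochs and
projects per-condition ERFs to node time courses, averaged over the
300–600 ms window.  ROI values are node means per area × hemisphere.
The leadfield is scalar (no orientation optimization) and the inversion
uses the real CSD; both are configuration-exposed dialects.

## Omission ERF

SHORT trials are epoched −250…+1000 ms around the omission point and
baseline-corrected by the pre-onset 250 ms.  Per-subject condition
averages enter a space-only cluster test on window-mean amplitudes
(a-priori windows 300–600 ms and 0–120 ms).  Cluster polarity is never
interpreted as effect direction — MEG polarity depends on source
orientation — direction is read from the condition-mean amplitudes over
the cluster channels.  An optional per-trial SNR (post-onset RMS /
baseline RMS) is provided as a heuristic QC metric only; the estimator
behind published per-epoch SNR figures is not specified.

## Trial QC

Three rules, thresholds in simulation units: an absolute-amplitude bound
(default 25, the analog of a recording hardware field limit), a jump rule
(z > 75 on |d/dt| of ninth-order median-filtered data — a clean step is
tracked exactly by a running median, so the derivative, not the residual,
carries the artifact), and a muscle analog (110–124 Hz band power,
z > 20, computed on zero-padded trials to avoid filter edge artifacts).

## Problem sizes

The default cohort is 20 subjects × 160 trials (40 per condition cell).
The test suite shares one simulated cohort of 8 subjects × 96 trials and
uses reduced permutation counts (500–1,000) and 10–20 seed repetitions
for calibration and recovery checks; the acceptance script simulates the
full 20 × 160 cohort.  These sizes are the package's choices for a
single-workstation run; all scale parameters are exposed in `SimConfig`
and `RunConfig`.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analyses assume —
cycle-locked delta coherence, a sustained narrowband rhythm, a biphasic
omission deflection, 1/f-plus-white sensor noise, linear mixing, and a
balanced counterbalanced design — with known ground truth.  It does not
emulate head movement, SQUID physics, ocular/cardiac components,
realistic anatomy or volume conduction, inter-subject anatomical
variability, or behavioral responses.  Passing tests therefore establish
that the pipeline's estimators and tests recover planted effects and
hold their error rates under this model; they do not validate the
neuroscientific claims on real recordings.
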