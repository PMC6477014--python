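# Methods

This note records the modelling assumptions, default parameters and design
choices behind `prevoid`, and what the synthetic experiments do and do not
demonstrate.

## Units and conventions

Depths in mm, times in µs, velocities in m/s, frequencies in MHz, gains and
levels in dB.  Confusion matrices are oriented rows = predicted state,
columns = true state, states ordered empty < 1/2 < 3/4 < full.

## Acoustic model

The physics layer is deliberately closed-form:

- **Time of flight** T = 2D/c; inversion recovers depth exactly.
- **Attenuation** scales linearly with frequency: soft tissue 0.7 dB/cm per
  MHz; urine is taken as 0.00014 dB/cm per MHz.  The urine figure is
  ambiguous in its source (units unstated); treating it as a per-MHz
  coefficient makes urine effectively lossless, which is the physically
  salient property.
- The coefficient is interpreted **per cm of depth** (the clinical
  round-trip convention), so the TGC gain that restores an echo arriving at
  time T is simply coefficient × one-way path length: 6.16 dB at
  T = 51.61 µs (4 cm of tissue) for a 2.2 MHz pulse.  Simulator absorption
  and TGC use the same convention, so they cancel exactly on soft-tissue
  paths.
- **Penetration** vs frequency follows floor(40/f) cm, tabulated at
  {1, 2, 3, 5, 10, 20} MHz; off-table queries snap to the nearest tabulated
  frequency (ties to the lower, deeper-penetrating one).
- **Wall thickness** interpolates linearly, 5 mm (empty) → 3 mm (full).
- **Anterior reflection** interpolates linearly between the two physically
  pinned endpoints, 99.9% of incident energy (empty) and 5% (full).  Only
  the endpoints are established; the linear bridge is a modelling choice
  and is isolated in one function should a better curve become available.

## Echo simulator

Each interface contributes one echo: a Gaussian-windowed sinusoid at the
pulse frequency (envelope σ = 1/f µs, ≈2 carrier cycles; the sub-25 ns
electrical excitation is stored as metadata — the simulated pulse width
represents transducer ringing).  Echo amplitudes are square roots of energy
fractions: the anterior echo √R(fill), the posterior echo
(1 − R) × 0.9 — the transmitted energy fraction after crossing the anterior
interface twice, times a near-total posterior interface reflectivity.  The
0.9 keeps the empty-bladder posterior echo at ≤0.001 of the anterior peak
(energy budget with R = 0.999) while giving a filling bladder a strong
distal echo, as observed when TGC tuned for tissue meets a lossless lumen.

Defaults: 2.2 MHz pulse, 10 MHz sampling, 20 cm region of interest, layer
stack = 40 mm of muscle (anterior wall at 4 cm), lumen depth extent =
60 mm × fill fraction.  The fill→depth gain is an assumption — voided
volumes are known (210–335 ml) but no volume→depth mapping is — chosen so
the full-bladder posterior wall (≈103 mm) stays comfortably inside the ROI.

Multiplicative speckle (sd 0.05) perturbs echo amplitudes; additive
Gaussian receiver noise (sd 0.05 relative to unit incident amplitude) is
added **after** TGC, modelling post-amplifier digitiser noise.  Adding it
before TGC would amplify far-field noise by >30 dB and make a stated noise
level meaningless.  Every stochastic call takes an explicit seed; there is
no hidden global state.

Not modelled: pubic-bone shadowing, probe angulation (the 15° placement is
metadata only), motion artefacts, nonlinear/harmonic propagation, B-mode
imaging.

## Collection protocol

A simulated day is one filling session: fill rises monotonically 0 → 1 over
160 min with acquisitions every 10 min (16 acquisitions) of 19 traces each
(≈304 samples/day; five days ≈ 1520 per wearer — the order of the reference
collection).  Labels are the nearest of the four reference fills
{0, 0.5, 0.75, 1} with ties rounding up.  The acquisition grid is mapped
through the class-boundary quantiles so the four states are sampled
equally, mirroring the roughly balanced class counts of the reference
protocol; the schedule is monotone and hits 0 and 1 exactly.  The two
default wearers are boys aged 6 (BMI 18.9) and 9 (BMI 23.4).

## Feature extraction

- Gate A default window [20, 60] mm at the body velocity, threshold 0.05 of
  full scale; gate B opens 2 mm beyond the detected anterior echo (mapped
  through the urine velocity) out to 200 mm, threshold 0.2.  Two
  deliberate asymmetries: the anterior threshold is low because the
  anterior reflection fades to ≈5% of incident energy at high fill while
  TGC boosts the posterior echo past it; and the anterior window stops at
  60 mm because a mid-fill posterior wall (depth 45 + 58·fill mm) would
  otherwise enter the anterior gate and win the maximum-amplitude rule.
- Detection picks the maximum-amplitude local peak of |trace| above
  threshold × A-scan height (the trace's maximum absolute amplitude, which
  is also the reference for the H percentages).
- s(A) uses T(A) with the body velocity; s(B) adds the inter-echo interval
  at the urine velocity (piecewise media).
- Body velocity interpolates 1550 m/s at BMI ≤ 18.5 down to 1436 m/s at
  BMI ≥ 30 — standard BMI category endpoints bridging the muscle and fat
  sound speeds, since only the velocity range is established.
- No-echo sentinels: a silent gate B writes empty fields on disk and
  (t_b, s_b, h_b) = 0, v_b = −120 dB, Δ = 0 in memory — the empty-bladder
  signature the classifiers learn.  V thresholds are configuration values
  with per-subject override; −120 dB is the below-floor sentinel of the
  relative level for non-positive amplitudes.
- A silent gate A marks the vector "misplaced"; the garment check consumes
  this.

## Classifiers and voting

- SVC, linear kernel by default (RBF exposed), one-vs-one multiclass, C = 1,
  features standardised in-pipeline.
- Stepwise regression: forward selection on AIC = n·ln(RSS/n) + 2(k+1),
  prediction rounded half-up to the nearest ordinal index and clipped to
  [0, 3].  The rounding/clipping map is our choice for ordinal consistency.
- Bagging: 10 bootstrap replicates of a decision tree (configurable).
- Voting: strict (weighted) majority; on three-way disagreement the
  weighted mean index is rounded, half-way ties towards the higher state —
  a missed pre-void alarm (wet bed) costs more than a spurious one.
- Cross-validation: stratified seeded folds for holdout and k-fold (k = 10
  default), leave-one-out for small sets.  Ties in stratification follow
  the class order.  For a 90/10 protocol, split first (per-class test
  counts = nearest integer, half up), run 10-fold inside the 90%.

## Evaluation

At trigger g, a sample is positive when its true state ≥ g and a prediction
alarms when the predicted state ≥ g; Se = alarmed positives / positives,
Sp = non-alarmed negatives / negatives.  Summary values are reported
rounded half-up to 2 dp (raw rates retained).  Applied to the packaged
reference matrices this reproduces the published summary at 2 dp in 15 of
16 cells; the remaining cell (stepwise-regression specificity at the 1/2
trigger) computes 657/743 = 0.8843 → 0.88 from its own matrix against a
printed 0.89 — an upstream rounding slip we do not replicate.  The packaged
matrices themselves derive from unreleased volunteer recordings and are
fixtures, not outputs.

## Alarm policy

Trigger default 3/4 (the imminent-voiding point); modalities (sound,
vibration, speech) with an escalation index; third-party notification is a
log event only.  Self-tuning is one-step: moisture with no pre-void alarm
in the preceding 15 min lowers the trigger one step (floor 1/2); moisture
despite an alarm escalates the modality (capped).  A 10 min refractory
period spaces alarms.  The refractory and lookback windows are our
choices — unspecified upstream — sized to a child's sleep/void timescales.

## What the synthetic experiments show

On the simulator's terms the pipeline is close to perfect: 10-fold voting
accuracy ≈0.98 at noise sd 0.05, wall separation recovered to ≈0.2 mm on
noiseless traces, one first alarm at the first 3/4 estimate on a filling
night.  That validates the *machinery* — gating, feature identities,
ensemble plumbing, alarm logic — not field performance: real traces carry
bone shadowing, probe motion, inter-subject anatomy and coupling loss that
the simulator omits, and real labels are noisier than nearest-reference-fill.
The reference study's own summary (voting Se 0.89 / Sp 0.93 at 3/4) is the
realistic benchmark, and it is reproduced here from its confusion matrices,
not regenerated.

## Numerical details

- Peak timing resolution is one sample (0.1 µs at 10 MHz ≈ 0.08 mm in
  urine); carrier-phase offsets mostly cancel in Δs, leaving a ≈0.2 mm
  systematic bias, well inside the 1 mm recovery tolerance.
- Degenerate inputs: empty traces raise; all-zero traces are "no echo";
  single-class training raises a degenerate-training error; Se/Sp with an
  empty positive or negative class raises an undefined-rate error.
- Seeds: protocol simulation spawns per-trace seeds from a seed sequence
  (kept below 2³¹); scikit-learn components receive the same integer seed.
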