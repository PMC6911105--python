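# Methods

This note records the model, the tunable constants, the design choices made
where the design was genuinely open, and what the synthetic test bed does
and does not show about real recordings.

## Signal model and units

The package operates on a uniformly sampled single-lead voltage series in
millivolts with sampling frequency `fs` ≥ 250 Hz.  All duration constants
are specified in milliseconds and converted per record as
`round(ms·fs/1000)`; symmetric windows are forced to an odd sample count
(even counts round up), so a 40 ms median window is 15 samples at 360 Hz
and 11 at 250 Hz.  Sample indices are 0-based everywhere; tools that print
1-based WFDB times need a +1 shift.

## Phasor transform

Each sample maps to the phasor y(n) = R_V + j·x(n):

* magnitude M(n) = sqrt(R_V² + x(n)²) — bounded below by R_V;
* phase φ(n) = arctan(x(n)/R_V), normalised onto [0, π/2].

R_V controls the enhancement: the smaller R_V is relative to the deflection
of interest, the closer that deflection's phase sits to π/2, which
equalises the apparent amplitude of P, T and QRS waves.  Normalisation is
|arctan| by default, so negative and biphasic deflections rank exactly as
high as positive ones — required for negative/biphasic P waves.  An affine
alternative (rescaling the signed phase onto (0, π/2)) is exposed through
`phasor_transform(..., normalization="affine")` for comparison; it favours
positive deflections only.

**Unit convention per stage.**  R_V only discriminates when it is
commensurate with the deflections being ranked.  The P and T stages
(R_V = 0.05 and 0.1) run on the millivolt-scale signal, where P ≈ 0.1–0.3 mV
and T ≈ 0.2–0.5 mV give mid-range phases while QRS complexes saturate.  The
QRS stage (R_V = 0.001) runs on the bandpassed signal expressed in volts:
after 12–19 Hz bandpassing a 1 mV R wave retains ≈ 3·10⁻⁴ V, so R_V = 0.001
sits at the QRS scale and the arctangent keeps dynamic range.  On a
millivolt scale the same R_V would push *every* visible deflection to
φ ≈ π/2 and the adaptive threshold could no longer separate attenuated
beats from full ones (the rolling standard deviation of a {0, π/2}-valued
signal is bounded by π/4, so a threshold of 2σ can never sit between two
saturated phase values).

## Filtering

* **Baseline removal** — subtract-the-running-mean high-pass (Lynn
  family).  The moving-average length N solves sin(u)/u = 1 − 1/√2 with
  u = π·f_c·N/fs, placing the half-power point at f_c = 0.67 Hz
  (N ≈ 1.02 s of samples, forced odd).  DC is rejected exactly; the
  centred window gives zero group delay.
* **QRS bandpass** — Hamming-window FIR, 12–19 Hz, about fs taps (odd),
  applied as a centred convolution.  Pass-band gain at 15 Hz ≥ 0.7 and
  stop-band gain at 2 Hz ≤ 0.1 by construction of the window/order pair.
* **Median smoother** — 40 ms sliding median with symmetric shrinking
  windows at the edges.  A median filter plateaus narrow peaks (the peak
  sample still attains the maximum) and is only approximately idempotent;
  both properties are tested as such.

**Isoelectric re-referencing.**  A zero-DC high-passed periodic ECG keeps
its inter-beat baseline *below* zero by the mean wave area per cycle
(≈ 0.1 mV for typical morphology).  Under the sign-symmetric |arctan|
phase, that offset would outrank a genuine P deflection.  Before P/T
detection the package therefore subtracts a 600 ms rolling-median estimate
of the isoelectric line (a window longer than twice the support of any
single wave tracks the baseline, not the waves) from both the smoothed and
the unsmoothed detection signals.  Amplitude measurements (U_P, U_QRS) are
taken on the re-referenced voltage signal.

## QRS detection

Phase candidates come from chained 300 ms maximum-search windows (each
window begins one sample past the previously discovered maximum; ties break
toward the earlier sample).  A candidate is kept when its phase exceeds
2× the rolling standard deviation of the phase over a centred 2 s window
(population σ, edge windows shrink) *and* an absolute floor of 0.01 rad
(≈ 0.01 mV of bandpassed deflection).  The floor exists because in a
synthetic noise-free stretch the rolling σ collapses to numerical-ripple
scale and would otherwise admit femtovolt "beats"; real recordings sit far
above it on both sides.  A 200 ms refractory rule resolves near-coincident
acceptances in favour of the larger phase value — this is also what removes
the P wave's own phase peak, which always lies within 200 ms of its R.

Accepted beats are refined to the extremum of the isoelectric-referenced
voltage within ±60 ms: the phase maximum of the *bandpassed* signal sits on
the sharpest QRS component (for a slurred PVC that is its narrow terminal
S wave), while downstream windows must be anchored on the dominant
deflection.

**Backward search.**  For every interval with RR(i) ≥ 1.75 × RR(i−1) the
magnitude M(n) is searched inside the gap (200 ms guard around both
neighbours) and the maximum is added as a beat iff its deflection component
sqrt(M² − R_V²) = |x| exceeds 0.3× the deflection at the previous R.  The
deflection, not raw M, carries the comparison because M ≥ R_V makes the raw
ratio vacuous near the floor.  The pass iterates to convergence and never
removes beats.

## PVC classification

Seven features per beat (index ≥ 2; the first two beats of a record default
to "other"): AUC = Σ|x|·Δt over R ± 50 ms (mV·ms) on the baseline-removed
signal, ΔAUC, RR(i), RR(i−1), ΔRR, U_QRS = max|x| over the same window, and
ΔU_QRS.  Any subset can be selected.  Classification is 1-NN on z-scored
features (they mix mV and ms scales; unscaled distance would be
RR-dominated).  The neighbour search is a direct distance computation so
the tie rule — equidistant training points resolve to the lowest training
index — is deterministic; scikit-learn's 1-NN serves as an independent
cross-check in the tests.  Models serialise to JSON.  A default model
trains on synthetic presets (bigeminy, trigeminy, sinus, SVES mix) so the
pipeline works with no external data; any user feature/label table is
accepted.

## T and P detection, decision rules

T(i) is the phase maximum (R_V = 0.1) of the smoothed signal in
[R(i) + 0.16·RR(i+1), R(i) + 0.57·RR(i+1)]; the last beat substitutes
RR(i).  The pre-QRS P candidate (R_V = 0.05) is the **highest interior
local maximum** of the phase in [R(i) − 0.70·RR(i), R(i) − 0.07·RR(i)]; a
maximum attained at the window boundary is the truncated flank of the
previous T wave (at ~70 bpm the window starts almost exactly on the T
peak) and is not a candidate.  The first beat substitutes RR(1) for its
undefined RR, mirroring the last-beat T surrogate.

The rules run a→e per beat with skip semantics; every firing is logged:

* **a** PVC beat → delete candidate, skip b–e.
* **b** candidate ≤ T(i−1) + 80 ms → delete, skip c–e.  The 80 ms guard
  covers the phase/voltage quantisation between the T estimate and the
  candidate — with a 0 ms guard a candidate sitting *on* the T peak can
  trivially pass by one sample.  Deletion is final (no second-chance
  search): this is deliberately conservative, trading sensitivity for
  precision when the window is dominated by the previous T.
* **c** RR(i) > 1.6 × RR(i−1) and beat i−1 not PVC → search
  [T(i−1) + 200 ms, R(i) − 300 ms] for a dissociated P with the normal-P
  settings (interior peak, R_V = 0.05); at most one per gap.
* **d** RR(i−1) < 0.85 × RR(i−2) → supraventricular extrasystole assumed;
  the gap search is suppressed.
* **e** accept iff U_P > 0.1 × U_QRS(i) (strict), both on the
  isoelectric-referenced voltage; applied to normal and dissociated
  candidates alike.

Peaks are refined to argmax |voltage| within ±20 ms of the phase maximum.
In an AV-block gap the pre-QRS window spans the whole gap, so both searches
can latch onto the same blocked P; when an accepted dissociated P and the
pre-QRS candidate refine to within 40 ms of each other, the pre-QRS search
repeats with ±100 ms around the dissociated P masked, recovering the
conducted P of the beat that ends the gap.

## Evaluation

Detected and reference fiducials are matched one-to-one within a tolerance
(defaults: ±50 ms for R, ±100 ms for P/T; every entry point takes the
tolerance explicitly).  An O(n·m) dynamic program over the sorted lists
maximises the pair count and then minimises total distance; for points on a
line with an interval constraint an optimal non-crossing matching always
exists, so the DP is globally optimal (verified against the Hungarian
algorithm in tests — greedy nearest-first matching is *not* cardinality-
optimal and is not used).  Se = 100·TP/(TP+FN), PP = 100·TP/(TP+FP); with
nothing detected PP is defined as 0 (100 if the reference is empty too).
Per-rhythm aggregation is the unweighted mean of per-record Se/PP.

## Synthetic test bed

Waves are Gaussian kernels (QRS a Q/R/S triplet); defaults are typical MLII
magnitudes: P 0.15 mV/σ25 ms at −160 ms, Q −0.10/6 at −26, R 1.00/12,
S −0.20/7 at +26, T 0.30/50 at +250; PVC: Q −0.20/12 at −60, R 1.30/30,
S −0.90/10 at +50, inverted T −0.35/60 at +300, no P.  The PVC's sharp deep
S is deliberate: a lone σ-30 ms Gaussian carries almost no 12–19 Hz energy,
a property no real ventricular beat has, and it would make the beat
invisible to any QRS-band detector.  Presets: normal sinus, AVB II (regular
atrial clock, every 4th P blocked — 4:3 conduction), bigeminy (two-beat
sinus run-in, then alternating normal/PVC with a 0.55·RR coupling interval
and full compensatory pause), trigeminy, nodal rhythm (QRS-T without P) and
a sinus/SVES mix (every 5th beat early at 0.65·RR).  Disturbances default
to 0.02 mV white noise plus a 0.1 mV/0.3 Hz baseline-wander sinusoid;
controlled experiments set both to zero.  Generation is bit-deterministic
for a given script (seeded `default_rng`); ground truth is the scheduled
peak samples, so tolerances in tests measure the detector, not the
generator.

What this does **not** emulate: beat-to-beat morphology variability, QRS
notching, atrial fibrillation/flutter waves, muscle artefact, electrode
motion, or P waves hidden inside QRS/T complexes.  Passing the synthetic
suite therefore demonstrates the mechanics of the windows, thresholds and
rules under known truth — not field performance on clinical recordings.

## Numerical choices and degenerate inputs

* ms→samples: `round(ms·fs/1000)`; odd-forcing for symmetric windows.
* Ties in maxima break toward the earlier sample throughout.
* Collapsed windows (< 3 samples) yield "no T"/"no candidate" with a
  warning rather than an error.
* Records shorter than twice the 2 s threshold window are rejected by the
  QRS stage; flat-zero records yield an empty beat set.
* Feature windows that would leave the record skip the beat with a warning.
* Duplicate/conflicting 1-NN training points resolve to the earlier index;
  non-finite query vectors are labelled "other" with a warning.

## Problem sizes

The test suite and the acceptance script run on 30–60 s records at 360 Hz
(40–180 bpm), 1000-instance matcher comparisons, and single train/test
splits — sizes chosen so the full cycle reruns in seconds while every
rhythm preset and rule path is exercised.

## Known limitations

* Rule b's delete-and-stop semantics cost sensitivity under noise: a noise
  bump on the previous T's flank can become the candidate and be deleted,
  losing a P that is plainly present later in the window.  Precision is
  unaffected (deletions cannot create false positives).
* One dissociated P per RR gap: higher-grade block with several blocked
  beats in one gap is out of scope.
* Nodal rhythm yields no P detections by design; an algorithm cannot
  currently distinguish "no P present" from "P hidden in QRS/T".
* Fibrillation/flutter and hidden P waves are out of scope.
* Threshold constants (0.67 Hz, 12–19 Hz, R_V values, window fractions,
  1.75/1.6/0.85/0.1/0.3 ratios) are fixed defaults exposed through
  `FilterSpec`, `QrsConfig` and `DelineationConfig` and the CLI YAML
  config; they were not re-fitted here.
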