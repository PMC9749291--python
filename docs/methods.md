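# Methods

## Signal model and cleaning rules

An FHR trace x(i), i = 1…N, is a 4 Hz series in beats per minute. A value of
exactly 0 encodes a missing sample; no NaNs appear in raw input. Cleaning is
a fixed-order chain, and its outputs are only defined for this order:

1. **Long-gap deletion.** Maximal zero-runs strictly longer than 15 s
   (> 60 samples at 4 Hz) are excised and the series concatenated; a run of
   exactly 15 s is kept for interpolation. Deletion reindexes the time axis —
   downstream transforms treat the cleaned series as contiguous, which is
   what keeps the fixed-length labor-stage windows meaningful.
2. **Edge trimming.** Remaining zero-runs touching either end are removed
   entirely, regardless of length, so the series starts and ends at a stable
   beat.
3. **Linear interpolation.** Samples that are 0 (short gaps) or outside
   [50, 200] bpm (outliers; the bounds themselves are physiologic and kept)
   are replaced by straight-line interpolation between the nearest valid
   neighbours. An invalid sample at an edge — possible when an out-of-range
   value survives trimming, which only strips zeros — is extended constantly
   from the nearest valid sample rather than treated as an error.
4. **Spike removal.** Scanning left to right with the first sample taken as
   stable, a jump of more than 25 bpm from the last stable sample opens an
   unstable run; the run closes at the first sample back within 25 bpm of
   that stable level. The run is replaced by a natural cubic spline through
   up to 4 stable anchor samples on each side (values kept inside [50, 200]);
   a run reaching the end of the signal is extended linearly from the left
   anchors. The scan repeats (bounded at 10 passes; exceeding the bound
   raises) because a replacement can expose a residual jump at its
   boundaries. The anchor count, the run-termination rule and the natural
   boundary conditions are this package's choices, made for locality and
   spline stability; only the 25-bpm trigger is fixed by the method.
5. **Segmentation.** Stage 1 takes the first 20 min (4800 samples), stage 2
   the last 15 min (3600 samples), measured on the cleaned (shortened)
   series. Signals shorter than the window are rejected, never padded —
   padding would fabricate physiology.

After step 4 the signal provably contains no zeros, lies in [50, 200] bpm
and has no adjacent delta above 25 bpm; `check_invariants` re-verifies this
by brute-force scan and the cleaning provenance counts every altered sample.
Re-running the chain on its own output is the identity.

## Slicing augmentation

The distressed minority is oversampled ×3 by window slicing: the base
labor-stage window plus two windows shifted backward by 300 s. A stage-1
base window starts at sample 0, so backward shifts would leave the
recording; the base is therefore anchored at 2 shifts (2400 samples) and
slid back toward 0 — offsets {2400, 1200, 0}. For stage 2 the base is the
final window and shifts move its start earlier. Slices that do not fit are
dropped with a warning; samples are never fabricated. Every slice is an
exact contiguous sub-window of the cleaned signal, so the dataset size
follows |D| = n_major + n_minor·(1 + n_slices) per labor stage.

Augmentation before splitting mirrors the dataset bookkeeping that produces
the 1556 = 878 + 678 item counts, but slices of one recording may then span
train and test. The `by_record` split option groups items by recording to
eliminate that leakage; it is off by default and used by the end-to-end
sanity checks (see below).

## Generalized Morse wavelet

Frequency-domain definition ψ̂(ω) = U(ω)·α·ω^β·e^(−ω^γ), β = P²/γ. The
implementation evaluates it in log space, so large β never overflows, and
it is exactly zero (not merely small) for ω ≤ 0.

* **Normalisation.** α = 2(eγ/β)^(β/γ), the peak-value-2 convention of
  analytic-CWT practice: a unit-amplitude real tone at a filter's center
  frequency then has unit coefficient magnitude.
* **Peak frequency.** ω_p = (β/γ)^(1/γ), the argmax of ω^β e^(−ω^γ).
* **Demodulate skewness.** Shifting the spectrum down by ω_p makes
  ψ̂(ω_p + ν) — non-negative and integrable — act as the characteristic
  function of the demodulated wavelet's time variable, so the cumulants are
  derivatives of L = log ψ̂ at ω_p: variance −L″(ω_p) = βγ/ω_p², and
  standardized third cumulant L‴(ω_p)/(−L″(ω_p))^{3/2}. It is computed by
  Richardson-extrapolated central differences with step 5·10⁻³·ω_p (error
  O(h⁴), ~10⁻¹⁰ in practice); analytically L‴(ω_p) =
  β(2−(γ−1)(γ−2))/ω_p³, which vanishes exactly at γ = 3 — the Airy family —
  and tests cross-check the numeric value against that closed form.
* **Filter bank.** Centers descend geometrically at 2^(1/12) (12 voices per
  octave). Endpoints are this package's contract: the top center frequency
  puts the wavelet peak two frequency standard deviations (σ_ω ≈ ω_p/P)
  below Nyquist, ω_hi(1 + 2/P) = π; the bottom requires two time-domain
  standard deviations (σ_t ≈ P/ω_c samples) to fit the signal on each side,
  ω_lo = 4P/N. The bottom endpoint therefore scales with the signal length:
  4800- and 3600-sample banks share their top endpoint but differ at the
  bottom by log₂(4/3) ≈ 0.4 octave, as any support-based cutoff must.
* **Transform.** FFT-based with periodic boundary handling; the segment mean
  is removed first (analytic filters carry no DC, so a constant signal maps
  to zero). Ridge measurements in tests exclude the outer quarter of the
  time axis to avoid wrap-around bins. Magnitudes are linear in positive
  signal scaling.
* **Rendering.** Magnitude is min–max normalized per image, quantized
  through a 256-level colormap ("jet" by default, matching common
  scalogram plotting practice; configurable), and bilinearly resized to
  224×224 RGB — deterministic down to the PNG bytes. Per-image
  normalization makes the image invariant to overall signal amplitude; class
  information must come from the *shape* of the time-frequency content.
  A flat scalogram renders as the lowest colormap color with a warning.
* One image is emitted per (segment, P²); the default P² is 60, with 55 the
  supported alternative. γ = 3 is used for all representation.

## Classifier

Transfer learning here means a frozen feature extractor plus a freshly
initialized two-class softmax head. The backbone is a protocol
(`transform(images) -> features` on 224×224×3 uint8), so a pretrained deep
network can be plugged in unchanged; the bundled `TinyConvBackbone`
(block-mean downsample → 8 fixed random 5×5×3 convolutions → ReLU →
block-mean pooling) is *not* pretrained and exists so the pipeline and its
tests run deterministically with no external weights. The head is trained
with minibatch Adam: learning rate 0.001, minibatch 30, default 15 epochs,
validation loss/accuracy recorded every 15 iterations (configurable; both
15 and 20 are plausible conventions) on a per-class 10% draw from the
training pool. All arithmetic is numpy, so fixed seeds give bit-identical
learning curves.

Splits are stratified per class: round(0.10·n) items to test (never fewer
than 1, never the whole class), validation carved from the remainder. The
90/10 train/test reading is used because the worked item counts
(790/610 train pool, 88/68 test from 878/678) are only reproducible that
way. Reported metrics are Acc = (tp+tn)/total, Se = tp/(tp+fn),
Sp = tn/(tn+fp), as percentages rounded half-up to one decimal; a
zero-denominator metric is reported as `None` and flagged, not raised.

## Synthetic FHR generator

Each record is baseline + slow wander (σ = 5 bpm, ~2 min correlation) +
band-limited short-term variability (Gaussian noise smoothed with σ = 0.75 s,
scaled to half the variability amplitude) + Gaussian-bump accelerations
(+15 bpm) and decelerations (−30 bpm and deeper), clipped to [55, 195] bpm
pre-defect. Defaults: 40 min at 4 Hz, baseline 140 bpm, variability 10 bpm,
4 accelerations — long enough for both labor-stage windows plus slicing
after cleaning losses. The distressed signature at `class_separation = 1`
is baseline −20 bpm, variability −5 bpm, +6 decelerations and +10 bpm
deceleration depth — the qualitative CTG correlates of fetal compromise; at
0 the classes are draws from one distribution. pH is drawn consistent with
the label (≤ 7.15 iff distressed).

Injected defects (Poisson counts at ~1 per 10 min each, non-overlapping
with a 10 s margin): zero-runs (70% ≤ 15 s to exercise interpolation, 30%
longer to exercise deletion), 1–3-sample outliers in (20, 45) or (205, 230)
bpm, 1–3-sample spikes offset 35–50 bpm from the local level, and optional
short zero-runs touching the edges. Long gaps are only placed where the
splice left by their deletion stays under the 25-bpm spike trigger —
otherwise gap deletion would manufacture spikes and the defect ledger could
not predict the cleaner's provenance exactly. With that constraint, ledger
→ provenance is an exact oracle, and the test suite verifies it on 200
seeded records.

What the generator does **not** emulate: real CTG morphology statistics
(deceleration timing relative to contractions, sinusoidal patterns,
baseline drift pathology), sensor-specific noise spectra, or any
distributional match to a clinical database. Passing tests therefore show
the pipeline's mechanics are correct and that it can exploit a plausible
distress signature — not clinical-grade performance on real recordings,
which additionally requires a genuinely pretrained backbone and the
clinical data itself.

## Scaled-down study conditions

The end-to-end sanity checks run 88 normal + 22 distressed synthetic
recordings (→ 88/66 items after slicing) — the minority:majority ratio of a
439/113 cohort at reduced size — with the record-grouped split, leaving 15
held-out test items. At full class separation the classifier must exceed
90% test accuracy; at zero separation it must stay within a ~3σ binomial
band of 50%. The record-grouped split is essential for the null check: with
item-level splitting, near-duplicate slices of one recording appear on both
sides and memorization alone lifts accuracy above chance even when the
classes are identical.

## Known limitations

* The PhysioNet reader covers text headers + 16-bit little-endian signal
  files with gain/baseline scaling and `#pH` comments — enough for
  CTU-UHB-style records, not a general waveform-format implementation.
* The bundled backbone is random, not pretrained; headline clinical
  accuracies require a real pretrained 224×224×3 backbone plugged into the
  same protocol and the clinical database itself.
* Spike-removal convergence is bounded at 10 passes; pathological inputs
  (sustained oscillation > 25 bpm per sample) raise rather than loop.
* Stage windows are measured on the cleaned, reindexed series; recordings
  losing too many samples to gap deletion are rejected at segmentation.
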