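# Methods

## Model

An EEG epoch is a matrix **A** ∈ ℝ^{H×W} (H electrodes, W time points).
The model has two stages.

**Dual attention fusion.** A 1×1 convolution produces a feature map
**B** ∈ ℝ^{H×W×1} (identity-initialised, so B starts equal to A).  Two
compression convolutions whose kernels span the collapsed axis summarise
B per channel, c ∈ ℝ^H (kernel (1, W)), and per time point, d ∈ ℝ^W
(kernel (H, 1)).  Trainable attention vectors v ∈ ℝ^H and w ∈ ℝ^W pair
elementwise with the summaries, and a softmax over the index produces the
spatial attention map a₁ = softmax(c ⊙ v) and the temporal attention map
a₂ = softmax(d ⊙ w); each is nonnegative and sums to one.  Their outer
product a = a₁ a₂ᵀ is a rank-1, normalised spatial-temporal weight
matrix.  It multiplies B elementwise (E = a ⊙ B) and a single learnable
residual scalar γ blends the recoding with the original map:

    Z = γ·E + B.

With the per-index pairing, the logit form c_i·v_i is exact for a single
feature map (C = 1); we do not implement multi-map attention (C > 1) or
key/query/value attention — the interaction between the two axes happens
only through the outer product.

**Classification head.** An EEGNet-style compact CNN consumes Z:
temporal convolution (1, K1)×F1 with 'same' padding → BatchNorm →
depthwise spatial convolution (H, 1) with depth multiplier D (collapses
the electrode axis) → BatchNorm → ELU → average pooling (1, P1) → dropout
→ separable convolution (1, K2)×F2 → BatchNorm → ELU → average pooling
(1, P2) → dropout → flatten → dense → softmax.  Convolutions carry no
biases (each is followed by BatchNorm); the first convolution is not
followed by an activation.  Two-class problems use the same 2-unit
softmax head with cross-entropy, which is mathematically identical to a
sigmoid unit with binary cross-entropy.

The whole network — attention front-end and head — is implemented in
NumPy with hand-derived gradients.  Temporal convolutions run as FFT
correlations (exact to rounding; the kernels are long relative to the
epochs, so the frequency domain is substantially faster than im2col on
one CPU).  Every gradient is verified against central finite differences
in the test-suite.

## Parameters and defaults

| parameter | meaning | default |
|---|---|---|
| F1 / F2 | temporal / separable filter counts | 8 / 16 |
| K1 | temporal kernel length (samples) | 72 (speller), 64 (MI) |
| K2 | separable kernel length | 16 |
| P1, P2 | pooling lengths | 4, 8 |
| D | depthwise depth multiplier | 2 |
| γ init | residual scalar | 0 |
| v, w init | zero-mean Gaussian, scale 0.1 | — |
| optimiser | Adam (β₁ 0.9, β₂ 0.999, ε 1e-7) | lr 0.001 |
| MI protocol | batch 16, dropout 0.2, ≤1000 epochs | |
| P300 protocol | batch 150, dropout 0.5, ≤300 epochs, balanced class weights | |

γ starts at 0 so the untrained module is an exact identity on B.  That
gives a clean ablation: the "without attention" arm is the same network
with γ frozen at 0 (then Z ≡ B and the attention parameters receive zero
gradient), so both arms share one code path, draw identical initial
weights for a given seed, and the identity is bitwise exact.

Benchmark geometries: speller epochs are 10 electrodes × 144 samples
(600 ms at 240 Hz, electrodes Fz, Cz, Pz, Oz, C3, C4, P3, P4, PO7, PO8);
motor-imagery epochs are 22×1000 or 3×1000 (4 s at 250 Hz).

**Pooling and the flatten length.**  With floor ('valid') pooling the
flattened feature length is ⌊W/P1/P2⌋·F2: 496 for W=1000 and 64 for
W=144.  The idealised algebra (W·F2)/(P1·P2) gives 500 and 72, but those
lengths are unattainable with integer pooling (the pooled widths 250 and
36 are not divisible by P2=8; 500 is not even a multiple of F2=16).  The
config exposes both `flatten_length` (what the network actually builds)
and `flatten_length_formula` (the idealised value); 'same'-padded pooling
would give 512/80 and was rejected as it changes the receptive geometry.

## Preprocessing

Filtering is a zero-phase 4th-order Butterworth band-pass applied
forward-backward (effective 8th-order magnitude, no phase distortion, so
ERP latencies are preserved).  Default bands: 0.5–40 Hz for P300, 4–38 Hz
for motor imagery — each encloses the physiological band of interest
(P300 energy below ~10 Hz; mu/beta 8–30 Hz) inside the acquisition bands
of the standard recordings.  Epoching slices the filtered signal without
resampling; windows are half-open [start, start+W) with 0-based sample
indices.  MI windows start at cue onset (configurable offset, since the
cue-to-imagery interval varies between protocols); P300 windows are the
600 ms after flash onset.  No artifact rejection, re-referencing or
per-trial normalisation is applied by default (optional z-scoring flag).

## Synthetic data

The generators produce the statistical structure the model exploits, not
realistic EEG:

* **Background**: 1/f (pink) noise, independently generated per channel
  by FFT spectral shaping, standardised to zero mean and unit variance.
  Real EEG has volume-conducted cross-channel correlation, alpha peaks
  and artifacts; none are simulated.
* **P300**: per character, 15 repetitions of 12 row/column flashes in
  random order; the two target flashes per repetition add a positive
  half-sine deflection, 300 ms wide, peaking 300 ms after flash onset,
  with a parieto-central topography (largest at Pz/Cz).  Target fraction
  is exactly 1/6.  The epoch-level generator treats flashes as
  independent; the continuous-recording generator flashes every 175 ms
  (~5.7 Hz), so analysis windows overlap as in real sessions.
* **Motor imagery**: class c adds a 10–12 Hz oscillation of random
  frequency and phase with amplitude `snr` on a class-specific channel
  group (the outermost channels for two classes, mimicking C3/C4
  lateralisation).  This is an amplitude-modulation stylisation of
  event-related (de)synchronisation; real ERD is a *decrease* relative
  to a baseline rhythm, which the classifier is equally indifferent to.

`snr` is the class-signal amplitude relative to the unit noise standard
deviation; at snr=0 the class label is independent of the data by
construction, giving an exact chance-level control.

Because the generators are caricatures, passing the learnability tests
shows that the pipeline can discover exactly the class of pattern it was
designed for (a localised spatio-temporal deflection; a lateralised band
power difference) — it says nothing about accuracy on real recordings,
where noise is structured and effect sizes are far smaller.

## Test and acceptance problem sizes

The synthetic study conditions are: P300 — 600 training / 180 test
epochs (exactly 50 / 15 repetitions' worth of flashes), snr 2 for the
learnability check, snr 0 for the chance control, 100 training epochs,
seed 42; motor imagery — 400/100 trials of 3×1000, same snr pair, batch
16, 100 training epochs.  These sizes give stable results (the snr=2
runs saturate near 100% accuracy) while keeping a full acceptance run in
minutes on one CPU.  Chance controls are judged within 3 binomial
standard errors of 1/2.  Speller decoding is demonstrated on 20
characters at snr 1.

## Numerical choices

* Softmax with max-subtraction (stable on unnormalised microvolt
  amplitudes).
* BatchNorm: ε 1e-3, running-statistics momentum 0.99; inference uses
  running statistics only, so evaluation is deterministic (two passes are
  bitwise identical).
* Training in float32; gradient checks in float64.
* Glorot-style weight initialisation throughout, from one seeded
  generator consumed in a fixed order — two fits with the same seed and
  data are bitwise identical (single-threaded NumPy).
* Speller decoding sums target probabilities per flash code (monotone
  equivalent to averaging); ties break to the lowest code,
  deterministically.  Decoding is provably equivalent to exhaustive
  36-cell search because the row/column objective is separable; the
  test-suite still checks this against brute force.
* Max-norm weight constraints from the original EEGNet are not applied
  (available nowhere in this implementation); no early stopping or
  validation split by default — models are evaluated at the final epoch.
* Class imbalance in oddball training (1:5) is handled by
  inverse-frequency sample weights in the loss ('balanced'), optional.

## Known limitations

* Single feature map attention only (C = 1); no multi-head variants.
* No GPU path; the NumPy implementation targets desk-scale experiments
  (thousands of epochs), not large-scale training.
* The EDF writer covers the plain 16-bit subset only (no EDF+
  annotations); GDF is read-only, via MNE.
* Character-level speller accuracy and trial-level flash accuracy are
  different quantities and are reported separately; we never convert one
  into the other.
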