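# eegfusion

Dual spatial-temporal attention fusion for EEG-based brain-computer
interfaces: P300 / oddball speller detection and motor-imagery decoding.

EEG classification is hard because the discriminative signal — an
event-related potential a few microvolts high, or a band-power shift on a
couple of electrodes — is buried in noise that dominates both the spatial
and the temporal dimension.  This package implements a model that learns
*where* and *when* to look before classifying.  An epoch
**A** ∈ ℝ^{H×W} (H electrodes × W time points) is recoded by an
interactive attention module:

- a₁ = softmax(c ⊙ v) — spatial attention over electrodes, from a
  time-collapsed summary c and a trainable vector v;
- a₂ = softmax(d ⊙ w) — temporal attention over time points, from a
  channel-collapsed summary d and a trainable vector w;
- a = a₁ a₂ᵀ — a rank-1, normalised spatial-temporal weight map;
- Z = γ·(a ⊙ B) + B — the attentive recoding blended with the original
  feature map B through a learnable residual scalar γ.

Z feeds an EEGNet-style compact CNN (temporal convolution → depthwise
spatial convolution → separable convolution, with batch-norm, ELU,
average pooling and dropout) ending in a softmax over classes.  The whole
network, including gradients and the Adam optimiser, is pure NumPy, and
everything is seeded and bitwise reproducible.  See `docs/methods.md`
for the model, its assumptions and the numerical choices.

It is aimed at BCI researchers who want a transparent, dependency-light
reference implementation of interactive dual attention with a testable
synthetic-data harness, not a GPU training framework.

## Worked example

Train on synthetic oddball epochs (10 electrodes × 144 samples at
240 Hz; targets carry a half-sine deflection peaking 300 ms after flash
onset at twice the noise amplitude) and decode speller characters:

```python
import numpy as np
from eegfusion import (SimulationSpec, TrainConfig, evaluate,
                       simulate_p300_epochs, simulate_p300_session, train)
from eegfusion.speller import character_accuracy, score_session

train_set = simulate_p300_epochs(600, snr=2.0, seed=42)
test_set  = simulate_p300_epochs(180, snr=2.0, seed=43)
clf = train(train_set,
            TrainConfig(batch_size=150, max_epochs=100,
                        class_weight="balanced", seed=42),
            model_config="speller-ii")

report = evaluate(clf, test_set)
print("trial accuracy:", report.accuracy)
print("confusion:\n", report.confusion)

maps = clf.attention_maps(test_set.epochs)
peak = np.argmax(maps.a2[test_set.labels == 1].mean(axis=0)) / 240.0
print("temporal attention peak (s):", peak)

spec = SimulationSpec(task="P300", H=10, W=144, sfreq=240.0,
                      snr=1.0, n_characters=20, seed=7)
epochs, session = simulate_p300_session(spec)
acc, curve = character_accuracy(score_session(clf, epochs, session))
print("character accuracy (15 reps):", acc)
```

Output:

```
trial accuracy: 1.0
confusion:
 [[150   0]
 [  0  30]]
temporal attention peak (s): 0.3
character accuracy (15 reps): 1.0
```

The trained model separates target from non-target flashes perfectly at
this signal-to-noise ratio (150 non-targets and 30 targets in the test
session), its temporal attention concentrates exactly on the injected
300 ms deflection, and summing per-flash target probabilities over
row/column codes spells all 20 characters correctly.  At `snr=0` the
same pipeline stays at chance — the null control for the harness.

A command-line interface mirrors the library
(`eegfusion simulate|epoch|train|evaluate|spell --help`).

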