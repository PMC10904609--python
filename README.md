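# hemonet

Decoding individual finger tapping from fNIRS hemodynamics.

Functional near-infrared spectroscopy (fNIRS) measures cortical
oxygenated (ΔHbO) and deoxygenated (ΔHbR) hemoglobin changes from
dual-wavelength light attenuation. Classifying *which finger* a person
tapped from motor-cortex fNIRS is a hard five-class brain–computer
interface problem: the signal is slow, noisy, and spatially blurred.
`hemonet` implements the full decoding path for this task — for BCI
researchers who want a tested, reproducible reference pipeline, and for
method developers who need a synthetic testbed with known ground truth:

- **simulate** — block-design paradigms (30 s baseline + 3 sessions ×
  5 fingers × (10 s rest + 10 s tap) + terminal rest = 350 s at
  3.9063 Hz) and synthetic dual-wavelength recordings: double-gamma
  hemodynamic responses with class-dependent amplitudes, forward
  Beer–Lambert optics, cardiac/respiratory/Mayer-wave noise, and seeded
  spike/baseline-shift motion artifacts with logged ground truth.
- **preprocess** — truncation, spike interpolation, coefficient-of-
  variation channel rejection (7.5 %), optical density, modified
  Beer–Lambert inversion to ΔHbO/ΔHbR/ΔHbT (µM), zero-phase 0.01–0.5 Hz
  Butterworth band-pass, temporal-derivative distribution repair (TDDR)
  motion correction, and z-normalisation.
- **features** — stimulus-locked epochs from −5 s to +15 s (77 samples),
  per-condition event averages, and an N × 77 labelled feature matrix in
  which every (channel, chromophore) average is one training example:

  P(Y = yᵢ | X = xᵢ) = f(xᵢ; w),  xᵢ ∈ ℝ^77,  yᵢ ∈ {thumb, …, little}.

- **models** — ten classifiers under one scikit-learn contract: LDA
  (scatter matrices S_W, S_B and the eigenproblem S_W⁻¹S_B v = λv exposed),
  QDA, multinomial logistic regression (reference-class softmax), random
  forest and XGBoost with 5-fold grid search over the protocol grids, and
  five deep networks on an in-package NumPy autodiff engine — dense
  baseline, LSTM, bidirectional LSTM, CNN-LSTM hybrid, and **Hemo-Net**,
  an inception-style time-series network (three multi-scale blocks with
  kernel lengths 10/20/40, residual connection, global average pooling,
  softmax head).
- **evaluate** — stratified and run-held-out splits, confusion matrices,
  accuracy = Σ I(y_pred = y_true)/N, per-class precision Tp/(Tp+Fp) and
  recall Tp/(Tp+Fn), F1, macro/weighted averages, and an end-to-end
  experiment runner.

See `docs/methods.md` for the model details, generator design, and
numerical choices.

## Worked example

```python
import numpy as np
from hemonet import build_paradigm, preset_config, simulate_recording
from hemonet import run_pipeline, extract_epochs, event_average
from hemonet import build_feature_matrix, split, SplitPlan, standard_scale
from hemonet.evaluate import simulate_feature_runs, evaluate_predictions
from hemonet.models import RandomForestFingerClassifier

# four synthetic participants, 16 channels, clearly decodable conditions
fm = simulate_feature_runs(preset="high_snr", n_runs=4,
                           montage_channels=16, seed=2)
print(fm.X.shape)                       # (960, 77): 16 ch x 3 chromophores
                                        # x 5 conditions x 4 runs
train, test = split(fm, SplitPlan(test_fraction=0.2, seed=2))
Xtr, scaler = standard_scale(train.X)
model = RandomForestFingerClassifier(random_state=0).fit(Xtr, train.y)
rep = evaluate_predictions(test.y, model.predict(scaler.transform(test.X)))
print(f"test accuracy {rep.accuracy:.3f}")
print(rep.as_frame().head(3).to_string(index=False))
```

```
(960, 77)
test accuracy 0.995
 class  precision   recall       f1  support
 index        1.0 1.000000 1.000000       39
little        1.0 0.973684 0.986667       38
middle        1.0 1.000000 1.000000       38
```

At high signal-to-noise the evenly spaced class amplitudes are cleanly
decodable from a single channel's event average, so held-out accuracy sits
near ceiling; the `mid_snr` preset yields the more interesting regime where
Hemo-Net ≥ random forest ≥ multinomial regression, and the `null` preset
(equal amplitudes) drives every model to the 20 % chance floor.

The same pipeline is scriptable from the shell:

```bash
hemonet simulate --preset high_snr --channels 16 --seed 7 \
    --out run.snirf --events-out events.tsv
hemonet features run.snirf events.tsv --out features.csv
hemonet train features.csv --model hemonet --seed 7 --out report.json
```

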