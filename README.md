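# bulbulvox

Detection and repertoire analysis of passerine vocalizations, built around the
call structure of the White Spectacled Bulbul (*Pycnonotus xanthopygos*).

Field recordings of songbirds are long, noisy, and accumulate far faster than
anyone can annotate by hand. `bulbulvox` is an end-to-end toolkit for turning
such recordings into quantitative repertoire data:

- **Detection** — a small convolutional network scores overlapping 1-s
  segments of a recording from cleaned 50×60 log-mel images; consecutive
  positive segments are merged into call events.
- **Syllable analysis** — the fundamental-frequency (F0) contour of a vocal
  base unit is estimated by zero-crossing analysis and modeled as a degree-3
  Legendre series `p(t) = a₀ + a₁L₁(t) + a₂L₂(t) + a₃L₃(t)` on the rescaled
  time axis [−1, 1]; `a₀…a₃` encode the contour's mean, slope, quadratic
  trend and wave-like shape. Each syllable becomes an 8-vector: duration,
  spectral flatness, spectral centroid, bandwidth, and the four coefficients.
- **Word analysis** — a whole multi-syllable vocalization ("word") becomes a
  fixed-size 35×34 mel image over the 700–3,900 Hz call band, denoised by
  median clipping (keep cells above `F·max(row median, col median)`, `F=3.5`)
  and small-object removal, then flattened to a 1,190-D vector.
- **Repertoire classification** — PCA reduces word/syllable vectors;
  nearest-centroid, KNN (K=3) or RBF-SVM classifiers label new detections,
  with open-set rejection: anything farther from every class centroid than
  any training item was from its own centroid is marked `REJECTED`.
- **Synthesis** — any coefficient vector can be re-rendered as a
  phase-continuous frequency-modulated sinusoid, which both validates the
  analysis (analysis-by-synthesis) and powers a synthetic-fixture generator
  (syllable/word templates, noisy scenes with known ground truth) so the
  whole pipeline is testable without field data.

## Worked example

```python
import numpy as np
from bulbulvox import (LegendreModel, synthesize_from_coeffs,
                       resynthesize_syllable, syllable_features)

# a chirp-like syllable whose F0 contour is a known Legendre series
true = np.array([2000.0, -400.0, 150.0, 80.0])   # Hz
sig = synthesize_from_coeffs(LegendreModel(true, (0.0, 0.5)), duration=0.5)

# analysis-by-synthesis: band-pass -> ZCR contour -> degree-3 fit
_, model = resynthesize_syllable(sig)
print(np.round(model.coeffs, 1))
print(np.round(100 * np.abs(model.coeffs - true) / np.abs(true), 2))
```

prints

```
[2000.2 -400.4  150.    80.1]
[0.01 0.1  0.01 0.06]
```

— the four generating coefficients are recovered to well under 1% from the
rendered waveform alone, which is the core claim behind using this tiny
parameterization as a syllable descriptor.

A synthetic scene with ground truth, from the shell:

```
vox simulate --scene scene.json --out rec.wav --ann rec.tsv --seed 1
vox synth --coeffs 2000,-400,150,80 --dur 0.5 --out syll.wav
```

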