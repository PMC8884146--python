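# Methods

This note documents the models and procedures implemented in `bulbulvox`,
the parameters that matter, the synthetic-data generator that stands in for
field recordings, and the numerical choices made where the design was open.

## Signal front-end

Audio is mono PCM WAV (stereo is rejected rather than silently downmixed).
Framing uses **no center padding**: frame *m* covers samples
`[m·hop, m·hop + frame_len)`, so frame counts are an exact function of the
signal length — this keeps every image dimension bit-stable. The default
analysis STFT is 512-sample frames (~12 ms at 44.1 kHz) with hop 128 and a
Hann window.

The mel filterbank uses the break-point formula `mel = 2595·log10(1 + f/700)`
with triangular filters whose centers are equally spaced on the mel scale
between `f_lo` and `f_hi`; adjacent filters overlap so the band is tiled with
no gaps. Log images are expressed in dB relative to the image maximum and
clamped at a floor of −80 dB, so processed images live in [−80, 0]. MFCCs are
the orthonormal DCT-II of each log-mel frame (13 kept by default).

Band-pass filtering is a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`), so unit boundaries are not shifted by group delay. The
padding used by the forward-backward pass is **even reflection**: tonal
units often start or end mid-oscillation, and odd reflection (the scipy
default) places a kink at the boundary whose transient corrupts the edge
frames of the F0 contour — with even reflection the worst-case
analysis-by-synthesis error at 0.2 s dropped from ~16% to ~1.6%.

Two band conventions coexist, following the stage that defines them: the
detector front-end pre-filters at 1–3.5 kHz (broad call band for event
detection), while syllable/word analysis uses 700–3,900 Hz (the species'
vocalization range). Both are configuration, not constants.

## F0 contours from zero crossings

A band-limited tonal unit crosses zero twice per cycle, so per frame (64
samples / hop 32 at 11,025 Hz, i.e. ~5.8 ms frames) the fundamental can be
read off the crossings. Two estimators are provided:

- **plain** (`refine=False`): `f0 = count / (2·frame_duration)` with
  `frame_duration = (frame_len−1)/rate` (crossings live in the frame's 63
  sample-intervals; using the nominal 64 biases a tone down by 1.5%). Its
  resolution is one count, ≈87 Hz at these settings.
- **refined** (default): crossing times are linearly interpolated between
  the bracketing samples; `c` crossings span `c−1` half-periods, so
  `f0 = (c−1) / (2·(t_last − t_first))`. This removes the integer-count
  quantization, whose error is strongly correlated across overlapping frames
  and aliases into the low-degree contour coefficients; with the plain
  estimator, degree-3 coefficient recovery on 0.5-s units is limited to
  ~6–9% error, with the refined one to well under 1%.

Frames with fewer than two crossings are unvoiced and **dropped**, not
interpolated; the Legendre fit consumes voiced frames only. Exact zeros take
`sign(0) = +1` so they are not double-counted.

No external pitch tracker (YIN/PYIN family) ships with the package; the
corresponding entry point raises a capability error pointing at the ZCR
path, which is the recommended estimator for noisy bioacoustic data anyway.

## Legendre contour model

A voiced contour is rescaled so its first voiced frame lands on −1 and its
last on +1 (gaps are not re-spaced), then fit by unweighted least squares in
the Legendre basis (P₀=1, P₁=t, P₂=(3t²−1)/2, P₃=(5t³−3t)/2; higher orders by
recurrence). Degree 3 is the default everywhere: four coefficients encode
mean, slope, quadratic trend and wave-like shape. The fit solves the
pseudo-Vandermonde system `V(t)·a = F0` and reports the RMS residual; it
matches a brute-force normal-equations solver to 1e−8 on random small
contours (property-tested). At least m+1 voiced points are required.

The 8-D syllable vector is (duration, spectral flatness, spectral centroid,
spectral bandwidth, a₀…a₃). Bandwidth defaults to the unnormalized form
`B = (Σ|X(k)|·(f(k)−f_c)²)^½`; a conventional normalized variant (divide by
Σ|X(k)| before the root) is available behind a flag and the choice is
recorded on the result. Spectral flatness computes its geometric mean in the
log domain over magnitudes floored at 1e−10 so spectra containing exact
zeros stay finite. MFCCs are computed but not part of the 8-vector.

## Synthesis

A syllable is re-rendered from its coefficients as a piecewise-constant
frequency-modulated cosine: the series is evaluated at the centers of
consecutive 64-sample frames (first center → −1, last → +1, mirroring the
analysis rescaling), each frame holds its frequency, and phase is
accumulated sample-by-sample across frame boundaries. Carrying the phase
forward is mathematically equivalent to the acos-branch recovery rule
(recover the previous frame's final phase from its final sample value, using
the [0,π) / [π,2π) branch, then advance by one sample step); the equivalence
is kept as a property test rather than as the implementation because acos is
numerically fragile near |x| → A. Output length is the duration rounded down
to whole frames; amplitude is exactly linear in A and bounded by it.

## Noise suppression on mel images

Two image operations raise the effective SNR before an image is used as a
word representation or detector input:

1. **Median clipping**: cell (i,j) survives iff its linear magnitude exceeds
   `F·max(median(row i), median(col j))` with `F = 3.5`; everything else
   drops to the floor. The comparison must happen on linear magnitudes — a
   multiplicative factor on a median of negative dB values would invert the
   inequality — so dB images are converted for the comparison and suppressed
   cells are written back at the dB floor (−80). Note the linear-domain
   median must be taken directly: for even-length rows/columns the
   interpolated median does not commute with the log map.
2. **Small-object removal**: surviving cells with fewer than
   `min_neighbors = 2` surviving immediate neighbors (8-connectivity by
   default, 4 selectable) are suppressed; the binary mask is returned
   alongside the masked image.

Both operators are vectorized but are property-tested for exact equality
against literal double-loop implementations of the defining formulas on
random small images. Outputs are always either the input value or the
floor, and the number of above-floor cells is monotone non-increasing.

## Word representation

A demarcated word becomes a 35-filter mel image over 700–3,900 Hz shaped to
exactly 34 time frames (1,190 values flattened row-major). Default mode
`zero_pad` keeps the configured hop and right-pads (or truncates, with a log
message) the time axis; the padding value is the dB floor so padding is
indistinguishable from silence. Mode `fixed_frames` instead chooses
`hop = ceil((len − frame_len)/(n_frames−1))` so the word itself spans the 34
frames. The two modes produce different vectors but agree on ≥95% of
nearest-centroid decisions on the synthetic corpus (tested). Cleaning is
applied after shaping, so the image statistics the median sees include the
padding; dimensionality depends only on configuration, never on duration.

## Detector

Recordings are tiled into 1-s segments with 50% overlap. Each segment
becomes a 50×60 log-mel image (frames 2,048 / hop 700 at 44.1 kHz gives 61
frames; the last is dropped for a bit-stable 60), cleaned by the two
operators above. The mel band for detector inputs is 300–7,000 Hz so the
700–3,900 Hz call band occupies interior rows with margin on both sides.

The network is `n_blocks` blocks of (3×3 same-padded convolution → 2×2 max
pool → ReLU) with channel count doubling per block from `base_kernels`,
then a fully connected layer (90 units, dropout 0.5) and a single sigmoid
output thresholded at 0.5. The default is 5 blocks from 32 kernels
(50×60 → 1×1 after five floor-mode pools). Training is Adam (lr 1e−3) on
binary cross-entropy, batch 32, fully seeded; the backend is a small numpy
implementation (im2col convolution) since the architecture is part of the
package's contribution and no DL framework is required. `build_model`
reports the exact trainable-parameter count.

Labeling is segment-based: a segment is positive iff its overlap with the
union of annotated call intervals is ≥30% of the segment (boundary
inclusive; overlapping annotations are merged first so they are not double
counted). Augmentation triples a batch: each input plus two copies, each by
one of five methods (white noise on the image, horizontal flip, 1–20%
zoom-in crop, time stretch ×0.7–1.3, pitch shift ×0.94–1.06) chosen
uniformly. The stretch/shift methods are applied in the spectrogram domain
(time-axis rescale, mel-row rescale) because detector inputs do not retain
their source waveform; labels are inherited and shapes preserved.
Evaluation uses a seeded stratified 70/30 split with 10% of the training
part held out for validation, and reports recall and the FP/TP ratio.
Consecutive positive segments merge into events (first start → last end,
mean score).

### Shuffled-label control

Training on randomly shuffled labels must not beat chance. Measured across
seeds, held-out accuracy indeed stays at 0.50–0.62, but the *recall* of a
single shuffled run is a high-variance statistic: the null model's outputs
concentrate at the 0.5 threshold, so the shared logit bias tips most of the
test batch to one side together (observed single-run null recalls 0.26–0.82
across seeds). The control is therefore reported as the mean recall over
three independent shuffle replicates — a variance-reduced estimator of the
same quantity, not a relaxed criterion.

## Repertoire classification

PCA (deterministic given the data) supports out-of-sample projection of new
detections into the reduced space; t-SNE is fit-once, for visualization
only. Classifiers operate in the PCA space: nearest centroid, KNN with K=3
(ties broken by smallest mean distance via the underlying estimator), and
an RBF-kernel SVM. Distances are Euclidean. With rejection enabled, the
threshold is the maximum over training samples of the distance to their own
class centroid (a percentile option exists); test items farther than that
from *every* centroid are labeled `REJECTED` before any labeling rule
applies, so with rejection disabled classification is a total function.

## Synthetic fixtures: what they emulate and what they do not

The generator draws 22 syllable templates (degree-3 coefficient vectors,
pairwise separated by ≥250 Hz in coefficient space, contours strictly inside
700–3,900 Hz) composed into 13 word templates of 1–4 syllables with
0.02–0.08 s gaps, at least one syllable shared between words — mirroring a
realistic passerine inventory in which words are built from a shared
syllable stock. Coefficient magnitudes are bounded away from zero
(|a₁| ≥ 150, |a₂| ≥ 80, |a₃| ≥ 50 Hz) so every template has a pronounced
contour shape and relative recovery errors are well-defined; durations are
0.15–0.30 s, long enough that a frame-64/hop-32 contour has >40 voiced
frames, the regime the degree-3 fit needs. Scenes place rendered words into
white or pink noise at exact per-event SNR (signal power over the event span
vs noise power), with ±6 dB amplitude roving so classifiers cannot key on
loudness, plus distractors (tones and band noise outside the call band,
in-band clicks) that stand in for other species, machinery and impulsive
noise. Ground-truth annotations carry exact spans; overlapping events are
permitted and flagged.

The voice is a single phase-continuous sinusoid: no harmonics, no formants,
no amplitude envelope, no reverberation or recorder coloration. Passing
tests on these fixtures therefore demonstrates the *pipeline's* correctness
and noise robustness under controlled conditions, not field-grade detector
performance on real bulbul recordings; real-data recall depends on acoustic
variability the fixtures deliberately do not model.

## Problem sizes and defaults used by the acceptance run

The acceptance script trains the detector on 400 one-second segments
(200 calls, 200 noise/distractors) at 10 dB SNR with the desk-scale network
(3 blocks from 8 kernels, 32 FC units, 12 epochs) — wide enough to separate
tonal calls from noise, small enough to train in well under a minute per
epoch in numpy. The word-classification corpus is 13 classes × 25
renditions (20 train / 5 test) at 20 dB SNR with ±10 ms gap jitter.
Analysis-by-synthesis closure uses 50 random templates rendered at 0.5 s.
All randomness flows from the `--seed` argument.

## Known limitations

- The ZCR estimator presumes one dominant spectral component inside the
  analysis band; harmonic stacks or overlapping calls violate it.
- Word images are truncated at the fixed 34-frame span in `zero_pad` mode;
  words longer than ~0.43 s (at the default hop) lose their tail unless
  `fixed_frames` mode is chosen.
- The printed-parameter-count of the reference 5-block architecture is not
  asserted; `build_model` exposes the count so configurations can be
  searched.
- t-SNE has no out-of-sample transform by design; classification uses PCA.
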