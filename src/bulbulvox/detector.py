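"""CNN segment classifier for call detection.

Long recordings are tiled into 1-s segments with 50% overlap; each segment
becomes a cleaned 50 x 60 log-mel image and a small convolutional network
scores it as call / non-call.  Consecutive positive segments are merged into
call events.  Evaluation is segment-based: a segment counts as a call if at
least 30% of it overlaps an annotated call interval.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import scipy.ndimage

from ._nn import Conv2D, Dense, Dropout, Flatten, MaxPool2, ReLU, Sequential, adam_step
from .audio_core import AudioSignal, MelConfig, Segment, StftConfig, \
    mel_spectrogram
from .errors import InvalidConfiguration, StratificationError
from .spectrogram_clean import CleanConfig, clean_image

log = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig", "DetectorInput", "DetectionEvent", "EvalReport", "CnnModel",
    "detector_input", "label_segments", "build_model", "augment", "train_detector",
    "merge_events", "evaluate", "hflip",
]


@dataclass(frozen=True)
class DetectorConfig:
    seg_len: float = 1.0
    overlap: float = 0.5
    frame_len: int = 2048
    hop: int = 700
    n_mels: int = 50
    n_time_bins: int = 60
    mel_lo: float = 300.0
    mel_hi: float = 7000.0
    n_blocks: int = 5
    base_kernels: int = 32
    kernel_size: int = 3
    fc_units: int = 90
    dropout: float = 0.5
    threshold: float = 0.5
    lr: float = 1e-3
    epochs: int = 15
    batch_size: int = 32

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise InvalidConfiguration("n_blocks must be >= 1")
        if not (0 < self.threshold < 1):
            raise InvalidConfiguration("threshold must be in (0, 1)")

    @property
    def kernels_per_block(self) -> tuple[int, ...]:
        # channel count doubles at each block
        return tuple(self.base_kernels * 2 ** b for b in range(self.n_blocks))

    @classmethod
    def small(cls, **kw) -> "DetectorConfig":
        """Desk-scale variant (narrow net) for quick experiments and tests."""
        defaults = dict(n_blocks=3, base_kernels=8, fc_units=32, epochs=12)
        defaults.update(kw)
        return cls(**defaults)


@dataclass
class DetectorInput:
    image: np.ndarray          # n_mels x n_time_bins, floored dB
    segment: Segment
    label: int | None = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float64)
        if self.image.ndim != 2:
            raise InvalidConfiguration("detector input image must be 2-D")


@dataclass(frozen=True)
class DetectionEvent:
    start: float
    end: float
    score: float
    n_segments: int

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise InvalidConfiguration("event must have positive duration")
        if self.n_segments < 1:
            raise InvalidConfiguration("event needs at least one segment")


@dataclass(frozen=True)
class EvalReport:
    recall: float
    false_positive_ratio: float   # FP count / TP count
    tp: int
    fp: int
    tn: int
    fn: int


# ---------------------------------------------------------------------------
# Input preparation and labeling

def detector_input(
    signal: AudioSignal,
    seg: Segment,
    cfg: DetectorConfig = DetectorConfig(),
    clean: CleanConfig = CleanConfig(),
) -> DetectorInput:
    """Cleaned fixed-shape log-mel image for one segment.

    With no center padding, 1 s at 44.1 kHz under frame 2048 / hop 700
    yields 61 frames; the time axis is truncated (or floor-padded) to exactly
    ``n_time_bins`` so the shape is bit-stable.
    """
    piece = signal.slice(seg.start, seg.end)
    expect = int(round(cfg.seg_len * signal.rate))
    if abs(piece.samples.size - expect) > 2:
        raise InvalidConfiguration(
            f"segment [{seg.start}, {seg.end}) yields {piece.samples.size} samples; "
            f"expected ~{expect} (seg_len={cfg.seg_len} s)"
        )
    stft_cfg = StftConfig(frame_len=cfg.frame_len, hop=cfg.hop)
    mel_cfg = MelConfig(n_filters=cfg.n_mels, f_lo=cfg.mel_lo,
                        f_hi=min(cfg.mel_hi, signal.rate / 2), log_floor=clean.floor_db)
    img = mel_spectrogram(piece, stft_cfg, mel_cfg, log_output=True)
    cleaned = clean_image(img, clean)
    v = cleaned.values
    if v.shape[1] > cfg.n_time_bins:
        v = v[:, : cfg.n_time_bins]
    elif v.shape[1] < cfg.n_time_bins:
        v = np.pad(v, ((0, 0), (0, cfg.n_time_bins - v.shape[1])),
                   constant_values=clean.floor_db)
    return DetectorInput(v, seg)


def label_segments(
    segments: list[Segment],
    annotations: list[tuple[float, float, str]],
    min_overlap_frac: float = 0.3,
    target_labels: set[str] | None = None,
) -> list[int]:
    """Label 1 iff a segment's overlap with target intervals is >= 30% of it.

    ``annotations`` are (start, end, label) triples; when ``target_labels``
    is given only those labels count as calls.  Overlaps are summed over the
    union of the (per-label merged) intervals so overlapping annotations are
    not double-counted; the threshold is boundary-inclusive.
    """
    ivals = sorted(
        (s, e) for s, e, lab in annotations
        if target_labels is None or lab in target_labels
    )
    merged: list[list[float]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    labels = []
    for seg in segments:
        overlap = sum(max(0.0, min(seg.end, e) - max(seg.start, s)) for s, e in merged)
        labels.append(int(overlap >= min_overlap_frac * seg.duration - 1e-9))
    return labels


# ---------------------------------------------------------------------------
# Model

class CnnModel:
    """Convolution/max-pool blocks with doubling channels, FC head, sigmoid out.

    Images (floored dB in [floor, 0]) are rescaled to [0, 1] before entering
    the network.  All randomness (init, dropout, batching) flows from the
    seed given at construction.
    """

    def __init__(self, cfg: DetectorConfig, seed: int = 0, floor_db: float = -80.0) -> None:
        self.cfg = cfg
        self.floor_db = floor_db
        self.rng = np.random.default_rng(seed)
        h, w = cfg.n_mels, cfg.n_time_bins
        layers: list = []
        c_in = 1
        for b, c_out in enumerate(cfg.kernels_per_block):
            layers += [Conv2D(c_in, c_out, cfg.kernel_size, self.rng), MaxPool2(), ReLU()]
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise InvalidConfiguration(
                    f"block {b + 1}: pooled feature map collapses to {h}x{w}; "
                    f"input {cfg.n_mels}x{cfg.n_time_bins} supports fewer blocks"
                )
            c_in = c_out
        layers += [Flatten(), Dense(h * w * c_in, cfg.fc_units, self.rng), ReLU(),
                   Dropout(cfg.dropout), Dense(cfg.fc_units, 1, self.rng)]
        self.net = Sequential(layers)
        self._adam: dict = {}

    @property
    def n_params(self) -> int:
        return self.net.n_params

    def _prep(self, images: np.ndarray) -> np.ndarray:
        x = (np.asarray(images, dtype=np.float64) - self.floor_db) / (-self.floor_db)
        return x[:, None, :, :]

    def predict_proba(self, images: np.ndarray, batch_size: int = 64) -> np.ndarray:
        x = self._prep(images)
        out = []
        for i in range(0, x.shape[0], batch_size):
            z = self.net.forward(x[i:i + batch_size], train=False, rng=self.rng)
            out.append(1.0 / (1.0 + np.exp(-z[:, 0])))
        return np.concatenate(out) if out else np.empty(0)

    def predict(self, images: np.ndarray) -> np.ndarray:
        return (self.predict_proba(images) >= self.cfg.threshold).astype(int)

    def fit(self, images: np.ndarray, labels: np.ndarray,
            val: tuple[np.ndarray, np.ndarray] | None = None) -> list[float]:
        """Adam / binary cross-entropy training; returns per-epoch mean loss."""
        x = self._prep(images)
        y = np.asarray(labels, dtype=np.float64)
        history = []
        for epoch in range(self.cfg.epochs):
            order = self.rng.permutation(x.shape[0])
            losses = []
            for i in range(0, x.shape[0], self.cfg.batch_size):
                idx = order[i:i + self.cfg.batch_size]
                xb, yb = x[idx], y[idx]
                z = self.net.forward(xb, train=True, rng=self.rng)[:, 0]
                p = 1.0 / (1.0 + np.exp(-z))
                eps = 1e-12
                losses.append(float(-np.mean(
                    yb * np.log(p + eps) + (1 - yb) * np.log(1 - p + eps))))
                dz = ((p - yb) / xb.shape[0])[:, None]
                self.net.backward(dz)
                adam_step(self._adam, self.net.parameters(), lr=self.cfg.lr)
            history.append(float(np.mean(losses)))
            if val is not None:
                acc = float(np.mean(self.predict(val[0]) == val[1]))
                log.info("epoch %d: loss %.4f, val acc %.3f", epoch + 1, history[-1], acc)
        return history

    def save(self, path: str | Path) -> None:
        arrays = {f"p{i}": p for i, (p, _) in enumerate(self.net.parameters())}
        np.savez(path, **arrays)
        Path(str(path) + ".config.json").write_text(json.dumps(asdict(self.cfg)))

    @classmethod
    def load(cls, path: str | Path, seed: int = 0) -> "CnnModel":
        cfg = DetectorConfig(**json.loads(Path(str(path) + ".config.json").read_text()))
        model = cls(cfg, seed=seed)
        data = np.load(str(path) if str(path).endswith(".npz") else str(path) + ".npz")
        for i, (p, _) in enumerate(model.net.parameters()):
            p[...] = data[f"p{i}"]
        return model


def build_model(cfg: DetectorConfig = DetectorConfig(), seed: int = 0) -> tuple[CnnModel, int]:
    """Construct the configured network; returns (model, trainable parameter count)."""
    model = CnnModel(cfg, seed=seed)
    return model, model.n_params


# ---------------------------------------------------------------------------
# Augmentation

def hflip(image: np.ndarray) -> np.ndarray:
    """Horizontal (time-axis) flip of a mel image."""
    return image[:, ::-1].copy()


def _aug_noise(img: np.ndarray, rng: np.random.Generator, floor: float) -> np.ndarray:
    out = img + rng.normal(0.0, 2.0, size=img.shape)  # ~2 dB white perturbation
    return np.clip(out, floor, 0.0)


def _aug_zoom(img: np.ndarray, rng: np.random.Generator, floor: float) -> np.ndarray:
    # zoom in by 1-20%: crop then rescale back to the fixed shape
    frac = rng.uniform(0.01, 0.20)
    h, w = img.shape
    ch, cw = max(1, int(round(h * (1 - frac)))), max(1, int(round(w * (1 - frac))))
    i0 = (h - ch) // 2
    j0 = (w - cw) // 2
    crop = img[i0:i0 + ch, j0:j0 + cw]
    out = scipy.ndimage.zoom(crop, (h / ch, w / cw), order=1, mode="nearest")[:h, :w]
    if out.shape != img.shape:
        out = np.pad(out, ((0, h - out.shape[0]), (0, w - out.shape[1])), constant_values=floor)
    return np.clip(out, floor, 0.0)


def _aug_time_stretch(img: np.ndarray, rng: np.random.Generator, floor: float) -> np.ndarray:
    factor = rng.uniform(0.7, 1.3)
    h, w = img.shape
    stretched = scipy.ndimage.zoom(img, (1.0, factor), order=1, mode="nearest")
    if stretched.shape[1] >= w:
        out = stretched[:, :w]
    else:
        out = np.pad(stretched, ((0, 0), (0, w - stretched.shape[1])), constant_values=floor)
    return np.clip(out, floor, 0.0)


def _aug_pitch_shift(img: np.ndarray, rng: np.random.Generator, floor: float) -> np.ndarray:
    factor = rng.uniform(0.94, 1.06)
    h, w = img.shape
    shifted = scipy.ndimage.zoom(img, (factor, 1.0), order=1, mode="nearest")
    if shifted.shape[0] >= h:
        out = shifted[:h]
    else:
        out = np.pad(shifted, ((0, h - shifted.shape[0]), (0, 0)), constant_values=floor)
    return np.clip(out, floor, 0.0)


_AUG_METHODS = ("noise", "flip", "zoom", "time_stretch", "pitch_shift")


def augment(batch: list[DetectorInput], seed: int = 0,
            floor_db: float = -80.0) -> list[DetectorInput]:
    """Triple a batch: each input plus two copies, each transformed by one of
    five methods (white noise, horizontal flip, zoom-in, time stretch, pitch
    shift) chosen uniformly.  Labels are inherited; shapes preserved."""
    rng = np.random.default_rng(seed)
    out: list[DetectorInput] = []
    for inp in batch:
        out.append(inp)
        for _ in range(2):
            method = _AUG_METHODS[rng.integers(len(_AUG_METHODS))]
            if method == "flip":
                img = hflip(inp.image)
            elif method == "noise":
                img = _aug_noise(inp.image, rng, floor_db)
            elif method == "zoom":
                img = _aug_zoom(inp.image, rng, floor_db)
            elif method == "time_stretch":
                img = _aug_time_stretch(inp.image, rng, floor_db)
            else:
                img = _aug_pitch_shift(inp.image, rng, floor_db)
            out.append(DetectorInput(img, inp.segment, inp.label))
    return out


# ---------------------------------------------------------------------------
# Training and evaluation

def _confusion(pred: np.ndarray, truth: np.ndarray) -> EvalReport:
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    recall = tp / (tp + fn) if tp + fn else 0.0
    fp_ratio = fp / tp if tp else float("inf") if fp else 0.0
    return EvalReport(recall, fp_ratio, tp, fp, tn, fn)


def evaluate(model: CnnModel, inputs: list[DetectorInput]) -> EvalReport:
    images = np.stack([i.image for i in inputs])
    truth = np.asarray([i.label for i in inputs])
    return _confusion(model.predict(images), truth)


def train_detector(
    inputs: list[DetectorInput],
    cfg: DetectorConfig = DetectorConfig(),
    seed: int = 0,
    test_frac: float = 0.3,
    val_frac: float = 0.1,
    augment_train: bool = True,
) -> tuple[CnnModel, EvalReport]:
    """Train on a labeled corpus with a seeded stratified 70/30 split
    (10% of the training part held out for validation) and report segment-wise
    recall and false-positive ratio on the test part."""
    from sklearn.model_selection import train_test_split

    labels = np.asarray([i.label for i in inputs])
    if labels.min() == labels.max():
        raise StratificationError("both classes must be present")
    idx = np.arange(len(inputs))
    train_idx, test_idx = train_test_split(
        idx, test_size=test_frac, random_state=seed, stratify=labels)
    if labels[train_idx].min() == labels[train_idx].max() or \
            labels[test_idx].min() == labels[test_idx].max():
        raise StratificationError("split left a single-class partition")
    tr_idx, val_idx = train_test_split(
        train_idx, test_size=val_frac, random_state=seed, stratify=labels[train_idx])

    train_inputs = [inputs[i] for i in tr_idx]
    if augment_train:
        train_inputs = augment(train_inputs, seed=seed)
    x_train = np.stack([i.image for i in train_inputs])
    y_train = np.asarray([i.label for i in train_inputs])
    x_val = np.stack([inputs[i].image for i in val_idx])
    y_val = labels[val_idx]

    model = CnnModel(cfg, seed=seed)
    model.fit(x_train, y_train, val=(x_val, y_val))
    report = evaluate(model, [inputs[i] for i in test_idx])
    return model, report


# ---------------------------------------------------------------------------
# Event merging

def merge_events(
    segments: list[Segment],
    predictions: list[int] | np.ndarray,
    scores: list[float] | np.ndarray | None = None,
) -> list[DetectionEvent]:
    """Merge maximal runs of consecutive positive segments into call events.

    Each event spans the first positive segment's start to the last one's
    end; its score is the mean segment score over the run.
    """
    preds = np.asarray(predictions, dtype=int)
    if scores is None:
        scores = preds.astype(float)
    scores = np.asarray(scores, dtype=float)
    events: list[DetectionEvent] = []
    run: list[int] = []
    for i, p in enumerate(preds):
        if p == 1:
            run.append(i)
        elif run:
            events.append(DetectionEvent(segments[run[0]].start, segments[run[-1]].end,
                                         float(scores[run].mean()), len(run)))
            run = []
    if run:
        events.append(DetectionEvent(segments[run[0]].start, segments[run[-1]].end,
                                     float(scores[run].mean()), len(run)))
    return events
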