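"""Fixed-size feature vector for a whole word.

A word (several syllables plus gaps) of variable duration is represented by
a 35-filter mel image over the 700-3900 Hz call band, noise-suppressed, then
shaped to a fixed number of time frames and flattened row-major — by default
35 x 34 = 1190 values, the input to dimensionality reduction and
classification.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .audio_core import AudioSignal, MelConfig, MelImage, StftConfig, mel_spectrogram
from .errors import RepresentationError
from .spectrogram_clean import CleanConfig, clean_image

log = logging.getLogger(__name__)

__all__ = ["WordVector", "PadMode", "word_vector", "unflatten", "save_word_vectors",
           "load_word_vectors"]


class PadMode(str, Enum):
    ZERO_PAD = "zero_pad"          # fixed hop; pad/truncate the time axis
    FIXED_FRAMES = "fixed_frames"  # variable hop chosen to yield the frame count


@dataclass
class WordVector:
    values: np.ndarray   # length n_filters * n_frames_fixed, row-major
    word_id: str
    label: str | None = None
    n_filters: int = 35
    n_frames: int = 34

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size != self.n_filters * self.n_frames:
            raise RepresentationError(
                f"vector length {self.values.size} != {self.n_filters}x{self.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise RepresentationError("word vector contains non-finite values")


def unflatten(vec: WordVector) -> np.ndarray:
    """Inverse of the row-major flattening: the n_filters x n_frames image."""
    return vec.values.reshape(vec.n_filters, vec.n_frames)


def _shape_time_axis(img: MelImage, n_frames_fixed: int, word_id: str) -> MelImage:
    v, t = img.values, img.frame_times
    if v.shape[1] > n_frames_fixed:
        log.debug("word %s: %d frames truncated to %d", word_id, v.shape[1], n_frames_fixed)
        v, t = v[:, :n_frames_fixed], t[:n_frames_fixed]
    elif v.shape[1] < n_frames_fixed:
        pad = n_frames_fixed - v.shape[1]
        fill = img.log_floor if img.db else 0.0
        v = np.pad(v, ((0, 0), (0, pad)), constant_values=fill)
        dt = t[1] - t[0] if t.size > 1 else 1.0
        t = np.concatenate([t, t[-1] + dt * np.arange(1, pad + 1)])
    return MelImage(v, t, img.stage, db=img.db, log_floor=img.log_floor,
                    filter_freqs=img.filter_freqs)


def word_vector(
    signal: AudioSignal,
    cfg: StftConfig = StftConfig(frame_len=512, hop=128),
    mel: MelConfig = MelConfig(n_filters=35, f_lo=700.0, f_hi=3900.0),
    clean: CleanConfig = CleanConfig(),
    n_frames_fixed: int = 34,
    mode: PadMode = PadMode.ZERO_PAD,
    word_id: str = "",
    label: str | None = None,
) -> WordVector:
    """Represent one demarcated word as a fixed-length cleaned mel vector.

    ``zero_pad`` keeps the configured hop and right-pads (or truncates) the
    time axis to ``n_frames_fixed`` at the floor value — padding is
    indistinguishable from silence in the floored-dB domain.  ``fixed_frames``
    instead picks ``hop = ceil((len - frame_len) / (n_frames_fixed - 1))`` so
    the word itself spans the fixed frame count.
    """
    if signal.samples.size < cfg.frame_len:
        raise RepresentationError(
            f"word {word_id or signal.source_id!r} shorter than one frame "
            f"({signal.samples.size} < {cfg.frame_len} samples)"
        )
    if mode == PadMode.FIXED_FRAMES:
        span = signal.samples.size - cfg.frame_len
        hop = max(1, int(np.ceil(span / max(1, n_frames_fixed - 1)))) if span > 0 else 1
        cfg = StftConfig(frame_len=cfg.frame_len, hop=min(hop, cfg.frame_len),
                         window=cfg.window, dft_size=cfg.dft_size)
    img = mel_spectrogram(signal, cfg, mel, log_output=True)
    img = _shape_time_axis(img, n_frames_fixed, word_id or signal.source_id)
    cleaned = clean_image(img, clean)
    return WordVector(cleaned.values.reshape(-1), word_id or signal.source_id, label,
                      n_filters=mel.n_filters, n_frames=n_frames_fixed)


def save_word_vectors(path: str | Path, vectors: list[WordVector],
                      sidecar: str | Path | None = None) -> None:
    """Persist vectors as CSV plus a JSON sidecar with the dimensionality config."""
    if not vectors:
        raise RepresentationError("nothing to save")
    df = pd.DataFrame([v.values for v in vectors])
    df.insert(0, "word_id", [v.word_id for v in vectors])
    df.insert(1, "label", [v.label for v in vectors])
    df.to_csv(path, index=False)
    side = Path(sidecar) if sidecar else Path(path).with_suffix(".config.json")
    side.write_text(json.dumps({
        "n_filters": vectors[0].n_filters,
        "n_frames": vectors[0].n_frames,
        "length": int(vectors[0].values.size),
    }, indent=2))


def load_word_vectors(path: str | Path) -> list[WordVector]:
    df = pd.read_csv(path)
    feat_cols = [c for c in df.columns if c not in ("word_id", "label")]
    side = Path(path).with_suffix(".config.json")
    meta = json.loads(side.read_text()) if side.exists() else {
        "n_filters": 35, "n_frames": len(feat_cols) // 35}
    out = []
    for _, row in df.iterrows():
        label = row["label"] if isinstance(row["label"], str) else None
        out.append(WordVector(row[feat_cols].to_numpy(dtype=float), str(row["word_id"]),
                              label, meta["n_filters"], meta["n_frames"]))
    return out
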