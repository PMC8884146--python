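"""Noise suppression on mel-spectrogram images: median clipping + small-object removal.

Field recordings carry broadband and impulsive background noise; these two
image-processing steps raise the effective SNR of a mel image before it is
used as a word representation or a detector input.

Median clipping keeps a time-frequency cell only if its magnitude exceeds a
factor ``F`` times the larger of its row median and column median; everything
else drops to the image floor ``S_L``.  Small-object removal then deletes
surviving cells with too few surviving immediate neighbors (isolated specks),
yielding a binary mask and the masked image.

The threshold is meaningful on linear magnitudes (a multiplicative factor on
a median of negative dB values would invert the comparison), so dB images
are converted to linear magnitudes for the comparison; suppressed cells are
written back at the image's own floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage

from .audio_core import MelImage, Stage
from .errors import InvalidConfiguration

__all__ = ["CleanConfig", "BinaryMask", "median_clip", "small_object_removal", "clean_image"]


@dataclass(frozen=True)
class CleanConfig:
    clip_factor: float = 3.5      # F: multiplier on the row/column median
    floor_db: float = -80.0       # S_L for dB images
    min_neighbors: int = 2        # surviving-neighbor count required to keep a cell
    connectivity: int = 8         # 4 or 8

    def __post_init__(self) -> None:
        if self.clip_factor <= 0:
            raise InvalidConfiguration("clip_factor must be positive")
        if self.min_neighbors < 0:
            raise InvalidConfiguration("min_neighbors must be >= 0")
        if self.connectivity not in (4, 8):
            raise InvalidConfiguration("connectivity must be 4 or 8")


@dataclass
class BinaryMask:
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise InvalidConfiguration("mask entries must be 0 or 1")


def _floor_of(img: MelImage, cfg: CleanConfig) -> float:
    # dB images floor at S_L; linear magnitudes floor at zero
    return cfg.floor_db if img.db else 0.0


def median_clip(img: MelImage, cfg: CleanConfig = CleanConfig()) -> MelImage:
    """Suppress cells not exceeding ``F`` times their row/column median.

    Requires a raw-stage image; returns a clipped-stage image in the same
    (dB or linear) domain, with suppressed cells at the floor.
    """
    if img.stage != Stage.RAW:
        raise InvalidConfiguration(f"median_clip expects a raw image, got {img.stage}")
    v = img.values
    lin = 10.0 ** (v / 20.0) if img.db else v
    row_med = np.median(lin, axis=1, keepdims=True)
    col_med = np.median(lin, axis=0, keepdims=True)
    keep = lin > cfg.clip_factor * np.maximum(row_med, col_med)
    out = np.where(keep, v, _floor_of(img, cfg))
    return MelImage(out, img.frame_times, Stage.CLIPPED, db=img.db,
                    log_floor=img.log_floor, filter_freqs=img.filter_freqs)


def _neighbor_kernel(connectivity: int) -> np.ndarray:
    k = np.ones((3, 3))
    k[1, 1] = 0
    if connectivity == 4:
        k[0, 0] = k[0, 2] = k[2, 0] = k[2, 2] = 0
    return k


def small_object_removal(
    img: MelImage, cfg: CleanConfig = CleanConfig()
) -> tuple[MelImage, BinaryMask]:
    """Zero above-floor cells whose above-floor neighbor count is too small.

    Requires a clipped-stage image.  Returns the masked image (suppressed
    cells at the floor) and the binary mask that was applied.
    """
    if img.stage != Stage.CLIPPED:
        raise InvalidConfiguration(f"small_object_removal expects a clipped image, got {img.stage}")
    floor = _floor_of(img, cfg)
    binary = (img.values > floor).astype(np.int64)
    counts = scipy.ndimage.convolve(binary, _neighbor_kernel(cfg.connectivity),
                                    mode="constant", cval=0)
    mask = (binary == 1) & (counts >= cfg.min_neighbors)
    out = np.where(mask, img.values, floor)
    return (
        MelImage(out, img.frame_times, Stage.MASKED, db=img.db,
                 log_floor=img.log_floor, filter_freqs=img.filter_freqs),
        BinaryMask(mask.astype(np.int8)),
    )


def clean_image(img: MelImage, cfg: CleanConfig = CleanConfig()) -> MelImage:
    """Convenience: median clip then small-object removal."""
    out, _ = small_object_removal(median_clip(img, cfg), cfg)
    return out
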