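"""Shared signal front-end: audio I/O, filtering, segmentation, STFT, mel, MFCC.

All downstream stages (syllable features, word images, detector inputs) are
built on the operations here.  Framing uses no center padding: frame ``m``
covers samples ``[m*hop, m*hop + frame_len)``, so frame counts are exactly
reproducible from the signal length.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import scipy.io.wavfile
import scipy.signal
from scipy.fft import dct, rfft

from .errors import InvalidConfiguration

log = logging.getLogger(__name__)

__all__ = [
    "AudioSignal",
    "StftConfig",
    "MelConfig",
    "MelImage",
    "Stage",
    "Segment",
    "read_wav",
    "write_wav",
    "read_annotations",
    "write_annotations",
    "bandpass",
    "segment_fixed",
    "stft",
    "mel_filterbank",
    "mel_spectrogram",
    "mfcc",
    "hz_to_mel",
    "mel_to_hz",
]


@dataclass
class AudioSignal:
    """A mono sampled waveform.

    Parameters
    ----------
    samples : ndarray
        Dimensionless amplitude, finite everywhere.
    rate : float
        Sampling rate in samples/second.
    source_id : str
        Opaque provenance tag (file name, scene id, ...).
    """

    samples: np.ndarray
    rate: float
    source_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise InvalidConfiguration("AudioSignal requires a 1-D (mono) sample array")
        if self.samples.size < 1:
            raise InvalidConfiguration("AudioSignal requires at least one sample")
        if self.rate <= 0:
            raise InvalidConfiguration("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidConfiguration("amplitude must be finite everywhere")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def nyquist(self) -> float:
        return self.rate / 2.0

    def slice(self, start: float, end: float) -> "AudioSignal":
        """Extract [start, end) seconds as a new signal."""
        i0 = max(0, int(round(start * self.rate)))
        i1 = min(self.samples.size, int(round(end * self.rate)))
        return AudioSignal(self.samples[i0:i1], self.rate, self.source_id)


@dataclass(frozen=True)
class StftConfig:
    """Short-time Fourier transform framing parameters (samples)."""

    frame_len: int = 512
    hop: int = 128
    window: str = "hann"
    dft_size: int | None = None

    def __post_init__(self) -> None:
        dft = self.dft_size if self.dft_size is not None else self.frame_len
        if not (0 < self.hop <= self.frame_len <= dft):
            raise InvalidConfiguration(
                f"need 0 < hop <= frame_len <= dft_size, got hop={self.hop}, "
                f"frame_len={self.frame_len}, dft_size={dft}"
            )

    @property
    def n_fft(self) -> int:
        return self.dft_size if self.dft_size is not None else self.frame_len


@dataclass(frozen=True)
class MelConfig:
    """Triangular mel filterbank between ``f_lo`` and ``f_hi`` Hz.

    The mel mapping is the HTK-style formula ``mel = 2595 log10(1 + f/700)``
    (recorded here as the package's single mel variant; there is a second
    common break-point formula which is not used).
    """

    n_filters: int = 35
    f_lo: float = 700.0
    f_hi: float = 3900.0
    log_floor: float = -80.0  # dB relative to image max
    scale: str = "htk"

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise InvalidConfiguration("n_filters must be >= 1")
        if not (0 <= self.f_lo < self.f_hi):
            raise InvalidConfiguration("need 0 <= f_lo < f_hi")


class Stage(str, Enum):
    RAW = "raw"
    CLIPPED = "clipped"
    MASKED = "masked"


@dataclass
class MelImage:
    """A mel spectrogram with its axes and processing provenance.

    ``values`` is ``n_filters x n_frames``; ``db`` flags whether values are
    decibels (floored at ``log_floor``) or linear filterbank magnitudes.
    """

    values: np.ndarray
    frame_times: np.ndarray
    stage: Stage = Stage.RAW
    db: bool = False
    log_floor: float = -80.0
    filter_freqs: np.ndarray | None = None  # center frequency of each mel row, Hz

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise InvalidConfiguration("MelImage requires a 2-D matrix with >= 1 frame")
        if self.stage != Stage.RAW and self.db and np.any(self.values < self.log_floor - 1e-9):
            raise InvalidConfiguration("processed image has values below the floor")

    @property
    def n_filters(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class Segment:
    """A [start, end) interval in seconds within one recording."""

    start: float
    end: float
    source_id: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InvalidConfiguration(f"need 0 <= start < end, got [{self.start}, {self.end})")

    @property
    def duration(self) -> float:
        return self.end - self.start


# ---------------------------------------------------------------------------
# I/O

def read_wav(path: str | Path, source_id: str | None = None) -> AudioSignal:
    """Read a mono PCM WAV file (16/24/32-bit int or 32/64-bit float).

    Stereo input raises rather than silently downmixing.
    """
    rate, data = scipy.io.wavfile.read(str(path))
    if data.ndim != 1:
        raise InvalidConfiguration(f"{path}: stereo/multichannel WAV not supported; supply mono")
    if np.issubdtype(data.dtype, np.integer):
        info = np.iinfo(data.dtype)
        data = data.astype(np.float64) / max(abs(info.min), info.max)
    else:
        data = data.astype(np.float64)
    return AudioSignal(data, float(rate), source_id or Path(path).name)


def write_wav(path: str | Path, signal: AudioSignal) -> None:
    """Write a mono 16-bit PCM WAV."""
    peak = np.max(np.abs(signal.samples))
    x = signal.samples / peak if peak > 1.0 else signal.samples
    scipy.io.wavfile.write(str(path), int(round(signal.rate)), (x * 32767).astype(np.int16))


def read_annotations(path: str | Path) -> list[tuple[float, float, str]]:
    """Read interval annotations: ``start<TAB>end<TAB>label`` per line."""
    out: list[tuple[float, float, str]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("\\"):  # Audacity writes "\" frequency lines
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        label = parts[2] if len(parts) > 2 else ""
        out.append((float(parts[0]), float(parts[1]), label))
    return out


def write_annotations(path: str | Path, intervals: list[tuple[float, float, str]]) -> None:
    lines = [f"{s:.6f}\t{e:.6f}\t{lab}" for s, e, lab in intervals]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# Filtering and segmentation

def bandpass(signal: AudioSignal, f_lo: float, f_hi: float, order: int = 4) -> AudioSignal:
    """Zero-phase Butterworth band-pass between ``f_lo`` and ``f_hi`` Hz.

    Forward-backward filtering (sosfiltfilt) so unit boundaries are not
    shifted by group delay.
    """
    if not (0 < f_lo < f_hi < signal.nyquist):
        raise InvalidConfiguration(
            f"band ({f_lo}, {f_hi}) must lie strictly inside (0, {signal.nyquist}) Hz"
        )
    sos = scipy.signal.butter(order, [f_lo, f_hi], btype="bandpass", fs=signal.rate, output="sos")
    # even-reflection padding keeps the edge values continuous, which matters
    # for tonal units that start or end mid-oscillation (odd reflection puts a
    # kink at the boundary and the resulting transient corrupts edge frames)
    y = scipy.signal.sosfiltfilt(sos, signal.samples, padtype="even")
    return AudioSignal(y, signal.rate, signal.source_id)


def segment_fixed(signal: AudioSignal, seg_len: float, overlap_frac: float = 0.5) -> list[Segment]:
    """Tile a recording with fixed-length segments at the given overlap.

    Segments start at multiples of ``seg_len * (1 - overlap_frac)`` and lie
    fully inside the signal.  A signal shorter than ``seg_len`` yields an
    empty list (with a warning log).
    """
    if not (0 <= overlap_frac < 1):
        raise InvalidConfiguration("overlap_frac must be in [0, 1)")
    dur = signal.duration
    if dur < seg_len - 1e-12:
        log.warning("signal %s (%.3f s) shorter than segment length %.3f s",
                    signal.source_id, dur, seg_len)
        return []
    step = seg_len * (1.0 - overlap_frac)
    n = int(np.floor((dur - seg_len) / step + 1e-9)) + 1
    return [Segment(i * step, i * step + seg_len, signal.source_id) for i in range(n)]


# ---------------------------------------------------------------------------
# Spectral transforms

def _frame(x: np.ndarray, frame_len: int, hop: int) -> np.ndarray:
    """Frame matrix (n_frames x frame_len); frame m covers [m*hop, m*hop+frame_len)."""
    n = 1 + (x.size - frame_len) // hop
    if n < 1:
        raise InvalidConfiguration("signal shorter than one frame")
    idx = np.arange(frame_len)[None, :] + hop * np.arange(n)[:, None]
    return x[idx]


def stft(signal: AudioSignal, cfg: StftConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Discrete STFT of a signal.

    Returns ``(spec, freqs, times)`` where ``spec`` is a complex
    ``(n_fft//2 + 1) x n_frames`` matrix, ``freqs`` the bin center
    frequencies in Hz and ``times`` the frame-center times in seconds.
    """
    frames = _frame(signal.samples, cfg.frame_len, cfg.hop)
    win = scipy.signal.get_window(cfg.window, cfg.frame_len, fftbins=True)
    spec = rfft(frames * win, n=cfg.n_fft, axis=1).T
    freqs = np.arange(cfg.n_fft // 2 + 1) * signal.rate / cfg.n_fft
    times = (np.arange(frames.shape[0]) * cfg.hop + cfg.frame_len / 2) / signal.rate
    return spec, freqs, times


def hz_to_mel(f: np.ndarray | float) -> np.ndarray | float:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def mel_to_hz(m: np.ndarray | float) -> np.ndarray | float:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(mel: MelConfig, rate: float, n_fft: int) -> np.ndarray:
    """Overlapping triangular filters, ``n_filters x (n_fft//2 + 1)``.

    Filter centers are equally spaced on the mel scale between ``f_lo`` and
    ``f_hi``; each filter's support runs from the previous center to the
    next, so the filters tile the band with no gap.
    """
    if mel.f_hi > rate / 2 + 1e-9:
        raise InvalidConfiguration(f"f_hi={mel.f_hi} above Nyquist {rate / 2}")
    edges_hz = mel_to_hz(np.linspace(hz_to_mel(mel.f_lo), hz_to_mel(mel.f_hi), mel.n_filters + 2))
    freqs = np.arange(n_fft // 2 + 1) * rate / n_fft
    fb = np.zeros((mel.n_filters, freqs.size))
    for i in range(mel.n_filters):
        lo, c, hi = edges_hz[i], edges_hz[i + 1], edges_hz[i + 2]
        up = (freqs - lo) / (c - lo)
        down = (hi - freqs) / (hi - c)
        fb[i] = np.maximum(0.0, np.minimum(up, down))
    return fb


def filter_centers(mel: MelConfig) -> np.ndarray:
    """Center frequency (Hz) of each mel filter."""
    edges = mel_to_hz(np.linspace(hz_to_mel(mel.f_lo), hz_to_mel(mel.f_hi), mel.n_filters + 2))
    return np.asarray(edges[1:-1])


def mel_spectrogram(
    signal: AudioSignal,
    cfg: StftConfig,
    mel: MelConfig,
    log_output: bool = True,
) -> MelImage:
    """Mel spectrogram of a signal; optionally in dB floored at ``log_floor``.

    The dB conversion is relative to the image maximum, then clamped at the
    floor, so a processed image's values always lie in [log_floor, 0].
    """
    spec, freqs, times = stft(signal, cfg)
    fb = mel_filterbank(mel, signal.rate, cfg.n_fft)
    melspec = fb @ np.abs(spec)
    if not log_output:
        return MelImage(melspec, times, Stage.RAW, db=False,
                        log_floor=mel.log_floor, filter_freqs=filter_centers(mel))
    ref = melspec.max()
    if ref <= 0:
        vals = np.full_like(melspec, mel.log_floor)
    else:
        with np.errstate(divide="ignore"):
            vals = 20.0 * np.log10(np.maximum(melspec, 1e-300) / ref)
        vals = np.maximum(vals, mel.log_floor)
    return MelImage(vals, times, Stage.RAW, db=True,
                    log_floor=mel.log_floor, filter_freqs=filter_centers(mel))


def mfcc(mel_img: MelImage, n_coeffs: int = 13) -> np.ndarray:
    """Mel-frequency cepstral coefficients via DCT-II of each log-mel frame.

    Returns an ``n_coeffs x n_frames`` matrix.  Coefficient 0 is proportional
    to the frame's summed log energy.
    """
    if not mel_img.db:
        raise InvalidConfiguration("mfcc requires a log-domain (dB) MelImage")
    if n_coeffs > mel_img.n_filters:
        raise InvalidConfiguration(
            f"n_coeffs={n_coeffs} exceeds n_filters={mel_img.n_filters}"
        )
    coeffs = dct(mel_img.values, type=2, axis=0, norm="ortho")
    return coeffs[:n_coeffs]
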