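"""Per-unit acoustic descriptors and ZCR-based fundamental-frequency estimation.

Spectral descriptors follow the unnormalized-bandwidth convention by default
(``B = (sum |X(k)| (f(k)-f_c)^2)^(1/2)``); a normalized variant (divide the
weighted variance by the total magnitude before the square root) is available
behind a flag and the choice is recorded on the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .audio_core import AudioSignal
from .errors import CapabilityError, FeatureError

log = logging.getLogger(__name__)

__all__ = [
    "SpectralDescriptors",
    "TimeDescriptors",
    "F0Contour",
    "F0Method",
    "zero_crossing_rate",
    "spectral_descriptors",
    "estimate_f0_zcr",
    "estimate_f0_external",
]

_FLATNESS_FLOOR = 1e-10  # magnitude floor for the log-domain geometric mean


@dataclass(frozen=True)
class SpectralDescriptors:
    centroid: float       # Hz, center of mass of the magnitude spectrum
    flatness: float       # in [0,1]; ~0 tonal, ~1 noise-like
    bandwidth: float      # weighted spread around the centroid
    bandwidth_normalized: bool = False


@dataclass(frozen=True)
class TimeDescriptors:
    zcr: int              # sign-change count over the whole unit
    energy: float         # sum of squared amplitude
    duration: float       # seconds


class F0Method(str, Enum):
    ZCR = "zcr"
    EXTERNAL = "external_pitch_tracker"


@dataclass
class F0Contour:
    """Frame-center times (s) and fundamental-frequency estimates (Hz)."""

    times: np.ndarray
    values: np.ndarray
    method: F0Method = F0Method.ZCR

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.times.size != self.values.size:
            raise FeatureError("times and values must have equal length")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise FeatureError("contour times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _signs(x: np.ndarray) -> np.ndarray:
    # sign(0) := +1 so exact zeros do not double-count crossings
    return np.where(x >= 0, 1.0, -1.0)


def zero_crossing_rate(signal: AudioSignal | np.ndarray) -> int:
    """Number of sign changes: ``1/2 * sum |sign x(n) - sign x(n-1)|``."""
    x = signal.samples if isinstance(signal, AudioSignal) else np.asarray(signal)
    if x.size < 2:
        raise FeatureError("need at least two samples for a zero-crossing count")
    s = _signs(x)
    return int(round(0.5 * np.sum(np.abs(s[1:] - s[:-1]))))


def spectral_descriptors(
    magnitudes: np.ndarray,
    freqs: np.ndarray,
    normalized_bandwidth: bool = False,
) -> SpectralDescriptors:
    """Centroid, flatness and bandwidth of a non-negative magnitude spectrum.

    Flatness is the ratio of the geometric to the arithmetic mean of the
    energy spectrum, with the geometric mean taken in the log domain over
    floored magnitudes so spectra containing exact zeros stay finite.
    """
    mag = np.asarray(magnitudes, dtype=np.float64)
    f = np.asarray(freqs, dtype=np.float64)
    if mag.shape != f.shape:
        raise FeatureError("magnitudes and freqs must align")
    if np.any(mag < 0):
        raise FeatureError("magnitudes must be non-negative")
    total = mag.sum()
    if total <= 0:
        raise FeatureError("all-zero spectrum: descriptors undefined")
    centroid = float((f * mag).sum() / total)
    power = np.maximum(mag, _FLATNESS_FLOOR) ** 2
    flatness = float(np.exp(np.mean(np.log(power))) / np.mean(power))
    var = float((mag * (f - centroid) ** 2).sum())
    bandwidth = float(np.sqrt(var / total)) if normalized_bandwidth else float(np.sqrt(var))
    return SpectralDescriptors(centroid, min(flatness, 1.0), bandwidth, normalized_bandwidth)


def time_descriptors(signal: AudioSignal) -> TimeDescriptors:
    return TimeDescriptors(
        zcr=zero_crossing_rate(signal),
        energy=float(np.sum(signal.samples ** 2)),
        duration=signal.duration,
    )


def estimate_f0_zcr(
    signal: AudioSignal,
    frame_len: int = 64,
    hop: int = 32,
    refine: bool = True,
) -> F0Contour:
    """Fundamental-frequency contour from per-frame zero-crossing analysis.

    For a band-limited signal with one dominant component, a sinusoid of
    frequency f crosses zero 2f times per second.  With ``refine`` (default)
    each frame's estimate uses the linearly interpolated crossing times: c
    crossings span c-1 half-periods, so ``f0 = (c-1) / (2 * (t_last -
    t_first))``, which removes the one-count quantization (~1/(2*frame_dur),
    about 87 Hz at frame 64 / 11.025 kHz) of the plain count.  With
    ``refine=False`` the plain ratio ``f0 = count / (2 * frame_duration)`` is
    used.  Frames with fewer than two crossings are marked unvoiced and
    dropped (not interpolated); the caller should band-pass first.
    """
    x = signal.samples
    if frame_len > x.size:
        log.warning("frame_len %d exceeds signal length %d; empty contour", frame_len, x.size)
        return F0Contour(np.empty(0), np.empty(0), F0Method.ZCR)
    n = 1 + (x.size - frame_len) // hop
    s = _signs(x)
    times, values = [], []
    # crossings lie in the frame's frame_len-1 sample intervals, so that is
    # the effective frame duration for the plain count estimate
    frame_dur = (frame_len - 1) / signal.rate
    for m in range(n):
        fr = x[m * hop: m * hop + frame_len]
        sf = s[m * hop: m * hop + frame_len]
        idx = np.nonzero(sf[1:] != sf[:-1])[0]
        if idx.size < 2:
            continue
        if refine:
            denom = fr[idx] - fr[idx + 1]
            frac = np.where(np.abs(denom) > 0, fr[idx] / np.where(denom == 0, 1.0, denom), 0.5)
            tau = idx + frac
            span = (tau[-1] - tau[0]) / signal.rate
            if span <= 0:
                continue
            values.append((idx.size - 1) / (2.0 * span))
        else:
            values.append(idx.size / (2.0 * frame_dur))
        times.append((m * hop + frame_len / 2) / signal.rate)
    return F0Contour(np.asarray(times), np.asarray(values), F0Method.ZCR)


def estimate_f0_external(signal: AudioSignal, f_lo: float = 700.0, f_hi: float = 3900.0):
    """Contour via an external pitch tracker (YIN/PYIN family).

    No pitch-tracking backend ships with this package; the native estimator
    is :func:`estimate_f0_zcr`, which is the recommended path for noisy
    bioacoustic data anyway.
    """
    raise CapabilityError(
        "no external pitch-tracking backend is available; "
        "use estimate_f0_zcr (band-pass the signal first)"
    )
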