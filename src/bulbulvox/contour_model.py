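"""Legendre-series modeling of F0 contours and the 8-D syllable feature vector.

A syllable's fundamental-frequency contour is modeled as a low-degree
Legendre series ``p(t) = a0 + a1 L1(t) + ... + am Lm(t)`` after rescaling
its time axis to [-1, 1].  The first four coefficients encode the contour's
mean, slope, quadratic trend and wave-like shape, so a handful of numbers
captures the intonation pattern that distinguishes syllable types.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from numpy.polynomial import legendre as npleg

from .audio_core import AudioSignal, StftConfig, bandpass, stft
from .errors import FeatureError, UnderdeterminedFit, VoxError
from .features import F0Contour, estimate_f0_zcr, spectral_descriptors

__all__ = [
    "LegendreModel",
    "SyllableFeatures",
    "legendre_basis",
    "fit_contour",
    "evaluate_series",
    "syllable_features",
]


@dataclass
class LegendreModel:
    """Fitted Legendre-series coefficients with their time-domain scaling.

    ``coeffs[j]`` (Hz) multiplies the degree-j Legendre polynomial on the
    rescaled axis; ``t_span`` is the original (start, end) time interval that
    maps to [-1, 1]; ``fit_residual`` is the RMS error of the fit in Hz.
    """

    coeffs: np.ndarray
    t_span: tuple[float, float]
    fit_residual: float = 0.0

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=np.float64)
        if self.coeffs.ndim != 1 or self.coeffs.size < 1:
            raise VoxError("coeffs must be a non-empty 1-D vector")
        if not self.t_span[1] > self.t_span[0]:
            raise VoxError("t_span must be non-degenerate")
        if self.fit_residual < 0:
            raise VoxError("fit_residual must be >= 0")

    @property
    def degree(self) -> int:
        return self.coeffs.size - 1

    def to_json(self) -> str:
        d = asdict(self)
        d["coeffs"] = self.coeffs.tolist()
        d["t_span"] = list(self.t_span)
        return json.dumps(d)

    @classmethod
    def from_json(cls, s: str) -> "LegendreModel":
        d = json.loads(s)
        return cls(np.asarray(d["coeffs"]), tuple(d["t_span"]), d["fit_residual"])


@dataclass
class SyllableFeatures:
    """The 8-D descriptor of one syllable: duration, three spectral shape
    statistics, and four Legendre contour coefficients."""

    duration: float
    flatness: float
    centroid: float
    bandwidth: float
    legendre: np.ndarray  # (a0, a1, a2, a3)

    def vector(self) -> np.ndarray:
        v = np.concatenate([
            [self.duration, self.flatness, self.centroid, self.bandwidth],
            np.asarray(self.legendre, dtype=np.float64),
        ])
        if not np.all(np.isfinite(v)):
            raise FeatureError("syllable feature vector contains non-finite values")
        return v


def legendre_basis(degree: int, t: float | np.ndarray) -> np.ndarray:
    """Legendre polynomial values ``(P_0(t) ... P_degree(t))`` for |t| <= 1.

    P0 = 1, P1 = t, P2 = (3t^2 - 1)/2, P3 = (5t^3 - 3t)/2; higher orders by
    the three-term recurrence (via numpy's Legendre backend).
    """
    t_arr = np.asarray(t, dtype=np.float64)
    if np.any(np.abs(t_arr) > 1 + 1e-12):
        raise ValueError("Legendre basis is defined on [-1, 1]")
    return np.stack([npleg.legval(t_arr, np.eye(degree + 1)[j]) for j in range(degree + 1)])


def _rescale(times: np.ndarray, t_span: tuple[float, float]) -> np.ndarray:
    t0, t1 = t_span
    return 2.0 * (times - t0) / (t1 - t0) - 1.0


def fit_contour(contour: F0Contour, degree: int = 3) -> LegendreModel:
    """Unweighted least-squares Legendre fit to a voiced contour.

    The time axis is mapped affinely so the first voiced frame lands on -1
    and the last on +1 (gaps are not re-spaced); the coefficients solve the
    pseudo-Vandermonde system ``V(t) a = F0`` in the least-squares sense.
    """
    n = len(contour)
    if n < degree + 1:
        raise UnderdeterminedFit(
            f"contour has {n} voiced points; need at least {degree + 1} for degree {degree}"
        )
    t_span = (float(contour.times[0]), float(contour.times[-1]))
    if not t_span[1] > t_span[0]:
        raise UnderdeterminedFit("contour spans zero time")
    x = _rescale(contour.times, t_span)
    coeffs = npleg.legfit(x, contour.values, degree)
    resid = float(np.sqrt(np.mean((npleg.legval(x, coeffs) - contour.values) ** 2)))
    return LegendreModel(coeffs, t_span, resid)


def evaluate_series(model: LegendreModel, times: np.ndarray) -> np.ndarray:
    """Evaluate the fitted series p(t) at times given in original seconds."""
    times = np.asarray(times, dtype=np.float64)
    x = _rescale(times, model.t_span)
    if np.any(np.abs(x) > 1 + 1e-9):
        import warnings
        warnings.warn("evaluating Legendre series outside the fitted span (extrapolation)")
    return npleg.legval(x, model.coeffs)


def syllable_features(
    signal: AudioSignal,
    band: tuple[float, float] = (700.0, 3900.0),
    degree: int = 3,
    frame_len: int = 64,
    hop: int = 32,
    stft_cfg: StftConfig | None = None,
) -> SyllableFeatures:
    """8-D feature vector of one demarcated syllable.

    Spectral flatness/centroid/bandwidth come from the mean magnitude
    spectrum of the band-passed syllable; the Legendre part from a degree-3
    fit to the ZCR contour (frame 64 / hop 32 convention at the signal's
    rate).
    """
    filt = bandpass(signal, *band)
    contour = estimate_f0_zcr(filt, frame_len=frame_len, hop=hop)
    if len(contour) < degree + 1:
        raise FeatureError(
            f"syllable {signal.source_id!r}: contour too short "
            f"({len(contour)} voiced frames) for a degree-{degree} fit"
        )
    model = fit_contour(contour, degree=degree)

    cfg = stft_cfg
    if cfg is None:
        frame = min(512, signal.samples.size)
        cfg = StftConfig(frame_len=frame, hop=max(1, frame // 4))
    spec, freqs, _ = stft(filt, cfg)
    mean_mag = np.abs(spec).mean(axis=1)
    sd = spectral_descriptors(mean_mag, freqs)
    return SyllableFeatures(
        duration=signal.duration,
        flatness=sd.flatness,
        centroid=sd.centroid,
        bandwidth=sd.bandwidth,
        legendre=model.coeffs[: degree + 1].copy(),
    )
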