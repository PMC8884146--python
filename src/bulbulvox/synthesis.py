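"""Phase-continuous sinusoidal re-synthesis of syllables from Legendre coefficients.

A syllable is rendered as a frequency-modulated sinusoid: the fitted Legendre
series is evaluated at consecutive frame centers, each frame holds its
frequency constant, and the per-frame sinusoids are concatenated with the
phase carried across frame boundaries so the waveform is continuous.  This
provides both a validation oracle (analysis-by-synthesis) and the voice of
the synthetic fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import scipy.signal
from numpy.polynomial import legendre as npleg

from .audio_core import AudioSignal
from .contour_model import LegendreModel, fit_contour
from .errors import FeatureError, InvalidConfiguration, SynthesisRangeError
from .features import estimate_f0_zcr

__all__ = ["SynthConfig", "synthesize_from_coeffs", "resynthesize_syllable"]


@dataclass(frozen=True)
class SynthConfig:
    rate: float = 11025.0
    frame_len: int = 64       # samples per synthesis frame (held-frequency span)
    hop: int = 32             # analysis step for the F0 contour
    amplitude: float = 1.0
    band: tuple[float, float] = (700.0, 3900.0)

    def __post_init__(self) -> None:
        if self.hop > self.frame_len:
            raise InvalidConfiguration("hop must not exceed frame_len")
        if self.rate <= 2 * self.band[1]:
            raise InvalidConfiguration("rate must exceed twice the band's upper edge")


def synthesize_from_coeffs(
    model: LegendreModel,
    duration: float,
    cfg: SynthConfig = SynthConfig(),
) -> AudioSignal:
    """Render a chirp-like syllable whose F0 follows the Legendre series.

    The series' span is mapped onto [0, duration].  Each frame of
    ``cfg.frame_len`` samples is a constant-frequency sinusoid; phase is
    accumulated sample by sample (equivalent to correcting each frame's
    initial phase from the previous frame's final sample), so there is no
    discontinuity at frame boundaries.  Output length is ``duration * rate``
    rounded down to whole frames.
    """
    n_frames = int(np.floor(duration * cfg.rate / cfg.frame_len))
    if n_frames < 1:
        raise SynthesisRangeError("duration shorter than one synthesis frame")
    # frame centers map onto the series' full domain (first -> -1, last -> +1),
    # mirroring the analysis convention that rescales first-to-last voiced
    # frame centers to [-1, 1]
    u = np.linspace(-1.0, 1.0, n_frames) if n_frames > 1 else np.zeros(1)
    freqs = npleg.legval(u, model.coeffs)
    if np.any(freqs <= 0) or np.any(freqs >= cfg.rate / 2):
        raise SynthesisRangeError(
            f"contour leaves (0, {cfg.rate / 2}) Hz: range "
            f"[{freqs.min():.1f}, {freqs.max():.1f}]"
        )
    inst = np.repeat(freqs, cfg.frame_len)
    # phi[n] = phi[n-1] + 2*pi*f(frame of n-1)*Ts ; phi[0] = 0
    phase = 2.0 * np.pi / cfg.rate * np.concatenate([[0.0], np.cumsum(inst)[:-1]])
    x = cfg.amplitude * np.cos(phase)
    return AudioSignal(x, cfg.rate, "synth")


def _downsample(signal: AudioSignal, rate: float) -> AudioSignal:
    if abs(signal.rate - rate) < 1e-9:
        return signal
    frac = Fraction(int(round(rate)), int(round(signal.rate))).limit_denominator(1000)
    y = scipy.signal.resample_poly(signal.samples, frac.numerator, frac.denominator)
    return AudioSignal(y, signal.rate * frac.numerator / frac.denominator, signal.source_id)


def resynthesize_syllable(
    signal: AudioSignal,
    cfg: SynthConfig = SynthConfig(),
    degree: int = 3,
) -> tuple[AudioSignal, LegendreModel]:
    """Analyze one syllable and re-render it from its fitted coefficients.

    Pipeline: polyphase downsample to ``cfg.rate`` -> band-pass to
    ``cfg.band`` -> ZCR contour (frame ``cfg.frame_len`` / hop ``cfg.hop``)
    -> degree-3 Legendre fit -> phase-continuous synthesis.  Returns both the
    re-synthesized audio and the model it was rendered from.
    """
    from .audio_core import bandpass

    low = _downsample(signal, cfg.rate)
    filt = bandpass(low, *cfg.band)
    contour = estimate_f0_zcr(filt, frame_len=cfg.frame_len, hop=cfg.hop)
    if len(contour) < degree + 1:
        raise FeatureError(
            f"syllable {signal.source_id!r}: contour too short for a degree-{degree} fit"
        )
    model = fit_contour(contour, degree=degree)
    audio = synthesize_from_coeffs(model, low.duration, cfg)
    return audio, model
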