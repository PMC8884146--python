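"""Labeled synthetic corpora for every pipeline stage.

Syllable templates are degree-3 Legendre coefficient vectors whose contours
stay inside the 700-3900 Hz call band; word templates are ordered syllable
sequences with silent gaps; scenes are long recordings with words placed at
known onsets over broadband noise and out-of-band/impulsive distractors.
Because the voice is the package's own phase-continuous synthesizer, every
ground truth (coefficients, spans, SNR) is known exactly, which is what makes
analysis-by-synthesis and detector/classifier health checks possible without
any field data.

Default repertoire size mirrors a realistic passerine inventory: 22 syllable
types composed into 13 word types, with syllables shared across words.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.signal
from numpy.polynomial import legendre as npleg

from .audio_core import AudioSignal
from .contour_model import LegendreModel
from .errors import VoxError
from .synthesis import SynthConfig, synthesize_from_coeffs, _downsample

log = logging.getLogger(__name__)

__all__ = [
    "SyllableTemplate", "WordTemplate", "SceneSpec", "default_repertoire",
    "render_syllable", "render_word", "render_scene", "make_word_corpus",
    "make_detector_corpus", "noise_signal",
]

BAND = (700.0, 3900.0)


@dataclass(frozen=True)
class SyllableTemplate:
    name: str
    coeffs: tuple[float, float, float, float]   # (a0..a3), Hz
    duration: float                             # seconds
    amplitude: float = 1.0

    def contour_range(self) -> tuple[float, float]:
        u = np.linspace(-1, 1, 201)
        p = npleg.legval(u, np.asarray(self.coeffs))
        return float(p.min()), float(p.max())


@dataclass(frozen=True)
class WordTemplate:
    name: str
    syllables: tuple[str, ...]
    gaps: tuple[float, ...]                     # between consecutive syllables

    def __post_init__(self) -> None:
        if len(self.syllables) < 1:
            raise VoxError("a word needs at least one syllable")
        if len(self.gaps) != max(0, len(self.syllables) - 1):
            raise VoxError("need one gap per adjacent syllable pair")
        if any(g < 0 for g in self.gaps):
            raise VoxError("gaps must be >= 0")


@dataclass
class SceneSpec:
    duration: float
    events: list[tuple[str, float]]             # (word name, onset s), onsets sorted
    snr_db: float | list[float] = 10.0
    noise_kind: str = "white"                   # white | pink
    distractors: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [t for _, t in self.events]
        if any(t < 0 or t > self.duration for t in onsets):
            raise VoxError("event onsets must lie within the scene")
        if onsets != sorted(onsets):
            raise VoxError("event onsets must be sorted")


# ---------------------------------------------------------------------------
# Repertoire generation

# Coefficient magnitude ranges: means near the band center, and shape
# coefficients bounded away from zero so each template has a pronounced,
# identifiable contour (and relative errors on recovered coefficients are
# meaningful).
_A0 = (1700.0, 3000.0)
_A1 = (150.0, 450.0)
_A2 = (80.0, 250.0)
_A3 = (50.0, 150.0)
_DUR = (0.15, 0.30)


def _draw_syllable(rng: np.random.Generator, name: str) -> SyllableTemplate:
    for _ in range(200):
        coeffs = (
            rng.uniform(*_A0),
            rng.choice([-1, 1]) * rng.uniform(*_A1),
            rng.choice([-1, 1]) * rng.uniform(*_A2),
            rng.choice([-1, 1]) * rng.uniform(*_A3),
        )
        tpl = SyllableTemplate(name, coeffs, float(rng.uniform(*_DUR)))
        lo, hi = tpl.contour_range()
        if BAND[0] + 50 < lo and hi < BAND[1] - 50:
            return tpl
    raise VoxError("could not draw an in-band syllable contour")


def default_repertoire(
    n_syllables: int = 22,
    n_words: int = 13,
    seed: int = 0,
    min_coeff_distance: float = 250.0,
) -> tuple[dict[str, SyllableTemplate], dict[str, WordTemplate]]:
    """Seeded repertoire: pairwise-separated syllables composed into words.

    Every word uses 1-4 syllables drawn from the shared pool, and at least
    one syllable is guaranteed to appear in two or more words.
    """
    if n_words < 2 or n_syllables < 2:
        raise VoxError("need at least 2 syllables and 2 words")
    rng = np.random.default_rng(seed)
    syllables: dict[str, SyllableTemplate] = {}
    for i in range(n_syllables):
        name = f"syl{i:02d}"
        for attempt in range(50):
            tpl = _draw_syllable(rng, name)
            d = [np.linalg.norm(np.subtract(tpl.coeffs, s.coeffs)) for s in syllables.values()]
            if not d or min(d) >= min_coeff_distance:
                syllables[name] = tpl
                break
        else:
            raise VoxError(
                f"could not separate {n_syllables} syllable templates by "
                f"{min_coeff_distance}; try fewer templates"
            )
    names = list(syllables)
    words: dict[str, WordTemplate] = {}
    for w in range(n_words):
        k = int(rng.integers(1, 5))
        chosen = tuple(rng.choice(names, size=k, replace=True))
        gaps = tuple(float(g) for g in rng.uniform(0.02, 0.08, size=max(0, k - 1)))
        words[f"word{w:02d}"] = WordTemplate(f"word{w:02d}", chosen, gaps)
    # guarantee a shared syllable across words
    used = [s for wt in words.values() for s in set(wt.syllables)]
    if len(used) == len(set(used)):
        w0, w1 = list(words)[:2]
        wt = words[w1]
        words[w1] = WordTemplate(wt.name, (words[w0].syllables[0],) + wt.syllables[1:], wt.gaps)
    return syllables, words


# ---------------------------------------------------------------------------
# Rendering

def render_syllable(tpl: SyllableTemplate, cfg: SynthConfig = SynthConfig()) -> AudioSignal:
    model = LegendreModel(np.asarray(tpl.coeffs), (0.0, tpl.duration))
    sig = synthesize_from_coeffs(model, tpl.duration, cfg)
    return AudioSignal(sig.samples * tpl.amplitude, sig.rate, tpl.name)


def render_word(
    word: WordTemplate,
    syllables: dict[str, SyllableTemplate],
    cfg: SynthConfig = SynthConfig(),
    gap_jitter: float = 0.0,
    rng: np.random.Generator | None = None,
) -> AudioSignal:
    """Concatenate a word's syllables with (optionally jittered) silent gaps."""
    rng = rng or np.random.default_rng(0)
    parts: list[np.ndarray] = []
    for i, name in enumerate(word.syllables):
        parts.append(render_syllable(syllables[name], cfg).samples)
        if i < len(word.syllables) - 1:
            gap = word.gaps[i]
            if gap_jitter > 0:
                gap = max(0.0, gap + rng.uniform(-gap_jitter, gap_jitter))
            parts.append(np.zeros(int(round(gap * cfg.rate))))
    return AudioSignal(np.concatenate(parts), cfg.rate, word.name)


def noise_signal(duration: float, rate: float, kind: str = "white",
                 rng: np.random.Generator | None = None) -> AudioSignal:
    """Unit-variance broadband noise, white or pink (1/f amplitude)."""
    rng = rng or np.random.default_rng(0)
    n = int(round(duration * rate))
    x = rng.standard_normal(n)
    if kind == "pink":
        spec = np.fft.rfft(x)
        f = np.fft.rfftfreq(n, 1 / rate)
        spec[1:] /= np.sqrt(f[1:])
        x = np.fft.irfft(spec, n)
        x /= x.std()
    return AudioSignal(x, rate, f"{kind}-noise")


def _distractor(kind: str, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Non-target sounds: tones and noise outside the call band, in-band clicks."""
    dur = rng.uniform(0.1, 0.4)
    n = int(dur * rate)
    t = np.arange(n) / rate
    if kind == "low_tone":
        return np.sin(2 * np.pi * rng.uniform(100, 500) * t)
    if kind == "high_tone":
        f = rng.uniform(5000, min(8000, rate / 2 * 0.9))
        return np.sin(2 * np.pi * f * t)
    if kind == "band_noise":
        x = rng.standard_normal(n)
        sos = scipy.signal.butter(4, min(600, rate / 2 * 0.5), btype="lowpass",
                                  fs=rate, output="sos")
        y = scipy.signal.sosfiltfilt(sos, x)
        return y / (np.abs(y).max() + 1e-12)
    if kind == "clicks":
        x = np.zeros(n)
        for i in rng.integers(0, max(1, n - 1), size=5):
            x[i] = rng.choice([-1, 1])
        return x
    raise VoxError(f"unknown distractor kind {kind!r}")


DISTRACTOR_KINDS = ("low_tone", "high_tone", "band_noise", "clicks")


def _resample_to(sig: AudioSignal, rate: float) -> AudioSignal:
    return _downsample(sig, rate)  # polyphase; works in either direction


def render_scene(
    spec: SceneSpec,
    syllables: dict[str, SyllableTemplate],
    words: dict[str, WordTemplate],
    rate: float = 44100.0,
    seed: int = 0,
    synth_cfg: SynthConfig = SynthConfig(),
    amplitude_rove_db: float = 6.0,
) -> tuple[AudioSignal, list[tuple[float, float, str]]]:
    """Mix words into noise at per-event SNR; return audio + ground truth.

    SNR is the ratio of event signal power to noise power over the event
    span.  Event amplitudes additionally rove by up to +/-``amplitude_rove_db``
    (after SNR is fixed the rove is part of the per-event SNR draw) so a
    classifier cannot key on loudness; per-event SNR reported in annotations
    is exact by construction.  Overlapping events are permitted; the later
    event's label is prefixed ``overlap:``.
    """
    rng = np.random.default_rng(seed)
    noise = noise_signal(spec.duration, rate, spec.noise_kind, rng)
    mix = noise.samples.copy()
    snrs = (spec.snr_db if isinstance(spec.snr_db, (list, tuple))
            else [spec.snr_db] * len(spec.events))
    annotations: list[tuple[float, float, str]] = []
    prev_end = -1.0
    for (wname, onset), snr in zip(spec.events, snrs):
        w = render_word(words[wname], syllables, synth_cfg)
        w = _resample_to(w, rate)
        i0 = int(round(onset * rate))
        seg = w.samples[: max(0, mix.size - i0)]
        if seg.size == 0:
            continue
        p_noise = float(np.mean(noise.samples[i0:i0 + seg.size] ** 2))
        p_sig = float(np.mean(seg ** 2))
        gain = np.sqrt(p_noise / p_sig * 10.0 ** (snr / 10.0))
        rove = 10.0 ** (rng.uniform(-amplitude_rove_db, amplitude_rove_db) / 20.0)
        mix[i0:i0 + seg.size] += gain * rove * seg
        end = onset + seg.size / rate
        label = wname if onset >= prev_end else f"overlap:{wname}"
        if onset < prev_end:
            log.warning("events overlap at %.2f s", onset)
        annotations.append((onset, end, label))
        prev_end = max(prev_end, end)
    for kind, onset in spec.distractors:
        d = _distractor(kind, rate, rng)
        i0 = int(round(onset * rate))
        seg = d[: max(0, mix.size - i0)]
        p_noise = float(np.mean(noise.samples[i0:i0 + seg.size] ** 2)) if seg.size else 0.0
        if seg.size and np.mean(seg ** 2) > 0:
            gain = np.sqrt(p_noise / np.mean(seg ** 2) * 10.0 ** (1.0))  # ~10 dB
            mix[i0:i0 + seg.size] += gain * seg
    return AudioSignal(mix, rate, "scene"), annotations


# ---------------------------------------------------------------------------
# Ready-made corpora

def make_word_corpus(
    syllables: dict[str, SyllableTemplate],
    words: dict[str, WordTemplate],
    n_per_class: int = 25,
    snr_db: float = 20.0,
    gap_jitter: float = 0.010,
    amplitude_rove_db: float = 6.0,
    seed: int = 0,
    synth_cfg: SynthConfig = SynthConfig(),
) -> tuple[list[AudioSignal], list[str]]:
    """Noisy, timing-jittered renditions of every word template.

    Each rendition re-draws its gap lengths (+/-``gap_jitter`` s), roves its
    amplitude and sits in fresh white noise at ``snr_db``; labels are the
    word template names.
    """
    rng = np.random.default_rng(seed)
    signals, labels = [], []
    for name, wt in words.items():
        for _ in range(n_per_class):
            w = render_word(wt, syllables, synth_cfg, gap_jitter=gap_jitter, rng=rng)
            rove = 10.0 ** (rng.uniform(-amplitude_rove_db, amplitude_rove_db) / 20.0)
            x = w.samples * rove
            p_sig = float(np.mean(x ** 2))
            noise = rng.standard_normal(x.size)
            noise *= np.sqrt(p_sig / 10.0 ** (snr_db / 10.0))
            signals.append(AudioSignal(x + noise, synth_cfg.rate, name))
            labels.append(name)
    return signals, labels


def make_detector_corpus(
    n_pos: int = 200,
    n_neg: int = 200,
    snr_db: float = 10.0,
    rate: float = 44100.0,
    seed: int = 0,
    repertoire_seed: int = 0,
) -> tuple[list[AudioSignal], list[int]]:
    """Balanced 1-s segments: words in noise (label 1) vs noise/distractors (0)."""
    rng = np.random.default_rng(seed)
    syls, words = default_repertoire(seed=repertoire_seed)
    wnames = list(words)
    segs, labels = [], []
    n_samp = int(rate)
    for i in range(n_pos):
        noise = rng.standard_normal(n_samp)
        w = _resample_to(render_word(words[wnames[i % len(wnames)]], syls,
                                     gap_jitter=0.01, rng=rng), rate)
        x = w.samples[:n_samp]
        i0 = int(rng.integers(0, max(1, n_samp - x.size + 1)))
        p_sig = float(np.mean(x ** 2))
        gain = np.sqrt(np.mean(noise[i0:i0 + x.size] ** 2) / p_sig * 10 ** (snr_db / 10.0))
        rove = 10.0 ** (rng.uniform(-6, 6) / 20.0)
        noise[i0:i0 + x.size] += gain * rove * x
        segs.append(AudioSignal(noise, rate, f"pos{i}"))
        labels.append(1)
    for i in range(n_neg):
        noise = rng.standard_normal(n_samp)
        if i % 2 == 1:  # half the negatives carry a distractor
            d = _distractor(DISTRACTOR_KINDS[i % len(DISTRACTOR_KINDS)], rate, rng)
            i0 = int(rng.integers(0, max(1, n_samp - d.size + 1)))
            if np.mean(d ** 2) > 0:
                gain = np.sqrt(np.mean(noise[i0:i0 + d.size] ** 2) /
                               np.mean(d ** 2) * 10 ** (snr_db / 10.0))
                noise[i0:i0 + d.size] += gain * d
        segs.append(AudioSignal(noise, rate, f"neg{i}"))
        labels.append(0)
    return segs, labels
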