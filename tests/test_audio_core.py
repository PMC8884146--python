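import numpy as np
import pytest

from bulbulvox import (
    AudioSignal, StftConfig, MelConfig, Segment,
    bandpass, segment_fixed, stft, mel_filterbank, mel_spectrogram, mfcc,
    read_wav, write_wav, read_annotations, write_annotations,
)
from bulbulvox.audio_core import filter_centers
from bulbulvox.errors import InvalidConfiguration

from conftest import tone


class TestBandpass:
    def test_passband_tone_preserved(self):
        sig = tone(2000.0)
        out = bandpass(sig, 700.0, 3900.0)
        rms_in = np.sqrt(np.mean(sig.samples ** 2))
        rms_out = np.sqrt(np.mean(out.samples ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_stopband_tone_attenuated(self):
        sig = tone(100.0)
        out = bandpass(sig, 700.0, 3900.0)
        atten_db = 20 * np.log10(
            np.sqrt(np.mean(out.samples ** 2)) / np.sqrt(np.mean(sig.samples ** 2)))
        assert atten_db < -20

    def test_zero_signal_maps_to_zero(self):
        sig = AudioSignal(np.zeros(1000), 44100.0)
        assert np.allclose(bandpass(sig, 700, 3900).samples, 0.0)

    def test_band_outside_nyquist_rejected(self):
        sig = tone(2000.0, rate=8000.0)
        with pytest.raises(InvalidConfiguration):
            bandpass(sig, 700.0, 5000.0)

    def test_preserves_length_and_rate(self):
        sig = tone(1500.0, duration=0.123)
        out = bandpass(sig, 700, 3900)
        assert out.samples.size == sig.samples.size and out.rate == sig.rate


class TestSegmentFixed:
    @pytest.mark.parametrize("dur, seg_len, overlap, expected_starts", [
        (3.0, 1.0, 0.5, [0.0, 0.5, 1.0, 1.5, 2.0]),
        (1.0, 1.0, 0.5, [0.0]),
        (2.0, 0.5, 0.0, [0.0, 0.5, 1.0, 1.5]),
    ])
    def test_enumerated_grids(self, dur, seg_len, overlap, expected_starts):
        sig = AudioSignal(np.zeros(int(dur * 1000)), 1000.0)
        segs = segment_fixed(sig, seg_len, overlap)
        assert [round(s.start, 6) for s in segs] == expected_starts
        assert all(s.end <= dur + 1e-9 for s in segs)

    def test_too_short_gives_empty(self):
        sig = AudioSignal(np.zeros(900), 1000.0)
        assert segment_fixed(sig, 1.0, 0.5) == []

    @pytest.mark.parametrize("dur", [1.0, 1.7, 3.25, 10.0])
    @pytest.mark.parametrize("overlap", [0.0, 0.25, 0.5])
    def test_count_formula(self, dur, overlap):
        # floor((T - L)/(L(1-o))) + 1 against direct enumeration
        sig = AudioSignal(np.zeros(int(dur * 1000)), 1000.0)
        segs = segment_fixed(sig, 1.0, overlap)
        expected = int(np.floor((dur - 1.0) / (1.0 * (1 - overlap)) + 1e-9)) + 1
        assert len(segs) == expected


class TestStft:
    def test_zero_input_zero_magnitude(self):
        sig = AudioSignal(np.zeros(2048), 44100.0)
        spec, _, _ = stft(sig, StftConfig())
        assert np.allclose(np.abs(spec), 0.0)

    def test_tone_peaks_at_its_bin(self):
        rate, n_fft = 44100.0, 512
        k = 24  # bin-centered frequency
        freq = k * rate / n_fft
        sig = tone(freq, duration=0.2, rate=rate)
        spec, freqs, _ = stft(sig, StftConfig(frame_len=512, hop=128))
        assert np.all(np.abs(spec).argmax(axis=0) == k)

    def test_parseval_per_frame(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        sig = AudioSignal(x, 44100.0)
        cfg = StftConfig(frame_len=512, hop=512)
        spec, _, _ = stft(sig, cfg)
        import scipy.signal
        win = scipy.signal.get_window("hann", 512, fftbins=True)
        time_energy = np.sum((x * win) ** 2)
        mags2 = np.abs(spec[:, 0]) ** 2
        # rfft: double the non-DC/non-Nyquist bins
        spec_energy = (mags2[0] + mags2[-1] + 2 * mags2[1:-1].sum()) / 512
        assert abs(spec_energy - time_energy) / time_energy < 1e-6

    def test_frame_count_no_centering(self):
        sig = AudioSignal(np.zeros(44100), 44100.0)
        spec, _, _ = stft(sig, StftConfig(frame_len=2048, hop=700))
        assert spec.shape[1] == 1 + (44100 - 2048) // 700 == 61


class TestMel:
    def test_tone_maximal_in_nearest_filter(self):
        mel = MelConfig(n_filters=35, f_lo=700.0, f_hi=3900.0)
        sig = tone(2000.0)
        img = mel_spectrogram(sig, StftConfig(), mel, log_output=False)
        centers = filter_centers(mel)
        assert img.values.sum(axis=1).argmax() == np.abs(centers - 2000.0).argmin()

    def test_silence_log_output_is_floor(self):
        mel = MelConfig()
        sig = AudioSignal(np.zeros(4096), 44100.0)
        img = mel_spectrogram(sig, StftConfig(), mel, log_output=True)
        assert np.all(img.values == mel.log_floor)

    def test_white_noise_covers_all_rows(self, rng):
        sig = AudioSignal(rng.standard_normal(44100), 44100.0)
        img = mel_spectrogram(sig, StftConfig(), MelConfig(), log_output=True)
        assert not np.any(np.all(img.values == img.log_floor, axis=1))

    def test_filterbank_tiles_band_without_gaps(self):
        mel = MelConfig(n_filters=35, f_lo=700.0, f_hi=3900.0)
        fb = mel_filterbank(mel, 44100.0, 512)
        freqs = np.arange(257) * 44100.0 / 512
        inside = (freqs > 760) & (freqs < 3840)  # interior of the band
        assert np.all(fb[:, inside].sum(axis=0) > 0)
        assert np.all(fb.sum(axis=1) > 0)

    def test_pipeline_deterministic(self, rng):
        x = rng.standard_normal(22050)
        a = mel_spectrogram(AudioSignal(x, 44100.0), StftConfig(), MelConfig())
        b = mel_spectrogram(AudioSignal(x.copy(), 44100.0), StftConfig(), MelConfig())
        assert np.array_equal(a.values, b.values)

    def test_f_hi_above_nyquist_rejected(self):
        sig = tone(1000.0, rate=6000.0)
        with pytest.raises(InvalidConfiguration):
            mel_spectrogram(sig, StftConfig(), MelConfig(f_hi=3900.0))


class TestMfcc:
    def test_thirteen_coefficients_default(self, rng):
        sig = AudioSignal(rng.standard_normal(22050), 44100.0)
        img = mel_spectrogram(sig, StftConfig(), MelConfig())
        assert mfcc(img).shape[0] == 13

    def test_constant_frame_only_dc(self):
        from bulbulvox.audio_core import MelImage
        img = MelImage(np.full((35, 4), -20.0), np.arange(4) * 0.01, db=True)
        c = mfcc(img, 13)
        assert np.allclose(c[1:], 0.0, atol=1e-12)
        assert np.all(c[0] != 0)

    def test_identical_frames_identical_columns(self, rng):
        from bulbulvox.audio_core import MelImage
        col = rng.uniform(-60, 0, size=35)
        img = MelImage(np.stack([col, col], axis=1), np.array([0.0, 0.01]), db=True)
        c = mfcc(img)
        assert np.array_equal(c[:, 0], c[:, 1])

    def test_too_many_coeffs_rejected(self, rng):
        sig = AudioSignal(rng.standard_normal(22050), 44100.0)
        img = mel_spectrogram(sig, StftConfig(), MelConfig(n_filters=10))
        with pytest.raises(InvalidConfiguration):
            mfcc(img, 13)


class TestIO:
    def test_wav_roundtrip(self, tmp_path, rng):
        sig = AudioSignal(rng.uniform(-0.5, 0.5, 4410), 44100.0, "x")
        write_wav(tmp_path / "x.wav", sig)
        back = read_wav(tmp_path / "x.wav")
        assert back.rate == 44100.0
        assert np.max(np.abs(back.samples - sig.samples)) < 1e-3  # 16-bit quantization

    def test_stereo_rejected(self, tmp_path):
        import scipy.io.wavfile
        scipy.io.wavfile.write(tmp_path / "s.wav", 44100,
                               np.zeros((100, 2), dtype=np.int16))
        with pytest.raises(InvalidConfiguration):
            read_wav(tmp_path / "s.wav")

    def test_annotation_roundtrip(self, tmp_path):
        ivals = [(0.5, 1.25, "word01"), (2.0, 2.75, "word02")]
        write_annotations(tmp_path / "a.tsv", ivals)
        back = read_annotations(tmp_path / "a.tsv")
        assert [(round(s, 6), round(e, 6), l) for s, e, l in back] == ivals
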