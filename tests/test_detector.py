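import numpy as np
import pytest

from bulbulvox import (
    AudioSignal, Segment, DetectorConfig, DetectorInput,
    detector_input, label_segments, build_model, augment, merge_events,
)
from bulbulvox.detector import CnnModel, hflip, evaluate, _confusion
from bulbulvox.errors import InvalidConfiguration, StratificationError

from conftest import tone


def seg_grid(n, seg_len=1.0, overlap=0.5):
    step = seg_len * (1 - overlap)
    return [Segment(i * step, i * step + seg_len) for i in range(n)]


class TestDetectorInput:
    def test_shape_50x60(self):
        sig = tone(2000.0, duration=1.0)
        di = detector_input(sig, Segment(0.0, 1.0), DetectorConfig())
        assert di.image.shape == (50, 60)

    def test_silence_all_floor(self):
        sig = AudioSignal(np.zeros(44100), 44100.0)
        di = detector_input(sig, Segment(0.0, 1.0), DetectorConfig())
        assert np.all(di.image == -80.0)

    def test_call_energy_in_band_rows(self, repertoire):
        from bulbulvox.synthetic_fixtures import render_word
        from bulbulvox.synthesis import _downsample
        from bulbulvox.audio_core import MelConfig
        from bulbulvox.audio_core import mel_to_hz, hz_to_mel
        syls, words = repertoire
        w = _downsample(render_word(next(iter(words.values())), syls), 44100.0)
        x = np.zeros(44100)
        n = min(w.samples.size, 30000)
        x[5000:5000 + n] = w.samples[:n]
        cfg = DetectorConfig()
        di = detector_input(AudioSignal(x, 44100.0), Segment(0.0, 1.0), cfg)
        centers = mel_to_hz(np.linspace(hz_to_mel(cfg.mel_lo), hz_to_mel(cfg.mel_hi), 52))[1:-1]
        hot_rows = np.where((di.image > -80).any(axis=1))[0]
        assert hot_rows.size > 0
        assert np.all(centers[hot_rows] > 600) and np.all(centers[hot_rows] < 4100)

    def test_wrong_segment_length_rejected(self):
        sig = tone(2000.0, duration=1.0)
        with pytest.raises(InvalidConfiguration):
            detector_input(sig, Segment(0.0, 0.5), DetectorConfig())


class TestLabelSegments:
    def test_thirty_percent_boundary_inclusive(self):
        segs = [Segment(0.0, 1.0)]
        assert label_segments(segs, [(0.70, 1.5, "w")]) == [1]   # overlap exactly 0.30
        assert label_segments(segs, [(0.71, 1.5, "w")]) == [0]   # overlap 0.29

    def test_no_annotations_all_zero(self):
        assert label_segments(seg_grid(4), []) == [0, 0, 0, 0]

    def test_monotone_in_threshold(self, rng):
        segs = seg_grid(10)
        anns = [(float(s), float(s) + 0.4, "w") for s in rng.uniform(0, 4, size=5)]
        prev = None
        for frac in (0.1, 0.3, 0.5, 0.9):
            lab = np.array(label_segments(segs, anns, min_overlap_frac=frac))
            if prev is not None:
                assert np.all(lab <= prev)  # raising threshold never flips 0 -> 1
            prev = lab

    def test_overlapping_annotations_not_double_counted(self):
        segs = [Segment(0.0, 1.0)]
        # two annotations covering the same 0.2 s: union is 0.2 < 0.3
        assert label_segments(segs, [(0.0, 0.2, "a"), (0.05, 0.2, "b")]) == [0]


class TestBuildModel:
    def test_tiny_net_parameter_count_by_hand(self):
        cfg = DetectorConfig(n_blocks=1, base_kernels=1, fc_units=1)
        model, n = build_model(cfg)
        # conv: (1*3*3)*1 + 1 = 10; feature map 25x30 -> flatten 750
        # fc: 750*1 + 1 = 751; out: 1*1 + 1 = 2
        assert n == 10 + 751 + 2

    def test_default_architecture_parameter_count_formula(self):
        cfg = DetectorConfig()
        model, n = build_model(cfg)
        expect = 0
        c_in = 1
        for c in (32, 64, 128, 256, 512):
            expect += (c_in * 9 + 1) * c
            c_in = c
        expect += (1 * 1 * 512 + 1) * 90 + (90 + 1) * 1
        assert n == expect

    def test_untrained_output_is_probability(self, rng):
        cfg = DetectorConfig.small()
        model, _ = build_model(cfg, seed=0)
        p = model.predict_proba(rng.uniform(-80, 0, size=(3, 50, 60)))
        assert np.all((p >= 0) & (p <= 1))

    def test_same_seed_same_build(self):
        a, na = build_model(DetectorConfig.small(), seed=3)
        b, nb = build_model(DetectorConfig.small(), seed=3)
        assert na == nb
        x = np.full((2, 50, 60), -40.0)
        assert np.array_equal(a.predict_proba(x), b.predict_proba(x))

    def test_too_many_blocks_rejected(self):
        with pytest.raises(InvalidConfiguration, match="block"):
            build_model(DetectorConfig(n_blocks=7, base_kernels=2))

    def test_save_load_roundtrip(self, tmp_path, rng):
        model, _ = build_model(DetectorConfig.small(), seed=1)
        model.save(tmp_path / "m.npz")
        back = CnnModel.load(tmp_path / "m.npz")
        x = rng.uniform(-80, 0, size=(2, 50, 60))
        assert np.allclose(model.predict_proba(x), back.predict_proba(x))


class TestAugment:
    def _batch(self, rng, n=4):
        return [DetectorInput(rng.uniform(-80, 0, size=(50, 60)), Segment(i, i + 1.0), i % 2)
                for i in range(n)]

    def test_triples_batch(self, rng):
        out = augment(self._batch(rng), seed=0)
        assert len(out) == 12

    def test_labels_and_shapes_inherited(self, rng):
        batch = self._batch(rng)
        out = augment(batch, seed=0)
        for i, inp in enumerate(out):
            assert inp.image.shape == (50, 60)
            assert inp.label == batch[i // 3].label

    def test_flip_is_involution(self, rng):
        img = rng.uniform(-80, 0, size=(50, 60))
        assert np.array_equal(hflip(hflip(img)), img)

    def test_noise_perturbs_but_keeps_range(self, rng):
        from bulbulvox.detector import _aug_noise
        img = rng.uniform(-80, 0, size=(50, 60))
        out = _aug_noise(img, np.random.default_rng(0), -80.0)
        assert out.shape == img.shape
        assert np.mean(np.abs(out - img)) > 0
        assert out.min() >= -80.0 and out.max() <= 0.0


class TestMergeEvents:
    def test_enumerated_merge(self):
        segs = seg_grid(4)  # starts 0, .5, 1, 1.5
        events = merge_events(segs, [1, 1, 0, 1], [0.9, 0.7, 0.1, 0.6])
        assert len(events) == 2
        assert events[0].start == 0.0 and events[0].end == 1.5
        assert events[0].score == pytest.approx(0.8)
        assert events[0].n_segments == 2
        assert events[1].start == 1.5 and events[1].end == 2.5

    def test_all_negative_empty(self):
        assert merge_events(seg_grid(5), [0] * 5) == []

    def test_all_positive_single_event(self):
        segs = seg_grid(5)
        events = merge_events(segs, [1] * 5)
        assert len(events) == 1
        assert events[0].start == 0.0 and events[0].end == segs[-1].end

    def test_no_overlapping_events(self, rng):
        segs = seg_grid(30)
        preds = (rng.random(30) > 0.5).astype(int)
        events = merge_events(segs, preds)
        for a, b in zip(events, events[1:]):
            assert b.start >= a.end


class TestEvalBookkeeping:
    def test_confusion_recount(self, rng):
        pred = (rng.random(200) > 0.5).astype(int)
        truth = (rng.random(200) > 0.5).astype(int)
        r = _confusion(pred, truth)
        assert r.tp + r.fp + r.tn + r.fn == 200
        assert r.recall == pytest.approx(r.tp / max(1, r.tp + r.fn))
        assert r.false_positive_ratio == pytest.approx(r.fp / max(1, r.tp))

    def test_single_class_split_rejected(self, rng):
        from bulbulvox.detector import train_detector
        inputs = [DetectorInput(rng.uniform(-80, 0, size=(50, 60)), Segment(i, i + 1), 1)
                  for i in range(10)]
        with pytest.raises(StratificationError):
            train_detector(inputs, DetectorConfig.small())
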