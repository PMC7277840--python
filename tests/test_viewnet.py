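"""View classifier: folds, model contracts, training protocol, ensembling."""

from __future__ import annotations

import numpy as np
import pytest

import echoview as ev
from echoview.core import FrameSet, ViewLabel, mean_uint8
from echoview import nn
from echoview.viewnet import (
    ModelConfig,
    Sample,
    build_model,
    combine_probabilities,
    ensemble_predict,
    make_folds,
    predict_avgimage,
    predict_frames,
    train,
)

TINY = dict(channels=(4, 4), n_conv_layers=2, input_size=32, dense_units=8,
            epochs=2, batch_size=8)


def tiny_config(**kw):
    with pytest.warns(UserWarning, match="64-128"):
        return ModelConfig(**{**TINY, **kw})


def make_fs(img: np.ndarray, pid="P0") -> FrameSet:
    frames = np.repeat(img[None], 10, axis=0)
    return FrameSet(frames=frames, source_indices=np.arange(10),
                    averaged=mean_uint8(frames), patient_id=pid)


@pytest.fixture(scope="module")
def tiny_samples(rng_mod=None):
    """24 patients x 5 views of 32x32 crops of view-specific phantoms."""
    rng = np.random.default_rng(77)
    samples = []
    for i in range(24):
        pid = f"T{i:02d}"
        for view in ev.VIEW_ORDER:
            mask = ev.chamber_mask(view, (32, 32), 1.0)
            img = np.where(mask, 30, 180).astype(np.uint8)
            img = np.clip(img + rng.normal(0, 12, (32, 32)), 0, 255).astype(np.uint8)
            frames = np.clip(img[None] + rng.normal(0, 6, (10, 32, 32)), 0,
                             255).astype(np.uint8)
            fs = FrameSet(frames=frames, source_indices=np.arange(10),
                          averaged=mean_uint8(frames), patient_id=pid)
            samples.append(Sample(pid, fs, view))
    return samples


class TestFolds:
    def test_340_patients_give_3400_images_per_fold(self):
        ids = [f"P{i:04d}" for i in range(340)]
        folds = make_folds(ids, k=5, seed=1)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.tolist() == [68] * 5
        # 68 patients x 5 views x 10 frames
        assert all(s * 5 * 10 == 3400 for s in sizes)

    def test_singleton_folds(self):
        folds = make_folds(["a", "b", "c", "d", "e"], k=5, seed=0)
        assert sorted(folds.values()) == [0, 1, 2, 3, 4]

    def test_deterministic_given_seed(self):
        ids = [f"P{i}" for i in range(37)]
        assert make_folds(ids, 5, seed=9) == make_folds(ids, 5, seed=9)

    def test_sizes_differ_by_at_most_one(self):
        folds = make_folds([f"P{i}" for i in range(23)], k=5, seed=3)
        sizes = np.bincount(list(folds.values()), minlength=5)
        assert sizes.max() - sizes.min() <= 1

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], k=1, seed=0)


class TestModelContracts:
    def test_output_is_probability_vector(self, rng):
        model = build_model(tiny_config(seed=3))
        p = model.predict_proba(rng.random((2, 32, 32)).astype(np.float32))
        assert p.shape == (2, 5)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert (p >= 0).all()

    def test_seeded_init_is_reproducible(self):
        a = build_model(tiny_config(seed=3))
        b = build_model(tiny_config(seed=3))
        for pa, pb in zip(a.net.params, b.net.params):
            assert np.array_equal(pa, pb)

    def test_wrong_input_size_rejected(self, rng):
        model = build_model(tiny_config(seed=3))
        with pytest.raises(ValueError, match="expected 32x32"):
            model.forward_logits(rng.random((1, 31, 31)))

    def test_default_config_has_study_protocol_values(self):
        cfg = ModelConfig()
        assert cfg.n_conv_layers == 5
        assert cfg.epochs == 50
        assert cfg.n_classes == 5
        assert all(64 <= c <= 128 for c in cfg.channels)


class TestTraining:
    def test_stored_loss_is_min_of_history(self, tiny_samples):
        cfg = tiny_config(seed=5, epochs=3)
        tr = [s for s in tiny_samples if s.patient_id < "T16"]
        va = [s for s in tiny_samples if s.patient_id >= "T16"]
        ws = train(build_model(cfg), tr, va, cfg)
        assert ws.val_loss == pytest.approx(min(v for _, v in ws.history))
        assert len(ws.history) == 3

    def test_train_as_val_loss_not_above_first_epoch(self, tiny_samples):
        cfg = tiny_config(seed=5, epochs=2)
        tr = tiny_samples[:40]
        ws = train(build_model(cfg), tr, tr, cfg, allow_overlap=True)
        assert ws.val_loss <= ws.history[0][1] + 1e-9

    def test_patient_overlap_rejected(self, tiny_samples):
        cfg = tiny_config(seed=5)
        with pytest.raises(ValueError, match="leakage"):
            train(build_model(cfg), tiny_samples, tiny_samples[:5], cfg)

    def test_empty_sets_rejected(self, tiny_samples):
        cfg = tiny_config(seed=5)
        with pytest.raises(ValueError, match="non-empty"):
            train(build_model(cfg), [], tiny_samples, cfg)

    def test_phantoms_are_learnable(self, tiny_samples):
        """Training on separable phantoms reaches high training accuracy —
        the classification task is learnable by this architecture."""
        cfg = tiny_config(seed=5, epochs=12, input_mode="averaged",
                          channels=(8, 12), dense_units=16)
        tr = [s for s in tiny_samples if s.patient_id < "T20"]
        va = [s for s in tiny_samples if s.patient_id >= "T20"]
        ws = train(build_model(cfg), tr, va, cfg)
        model = ws.model()
        x = np.stack([s.frameset.averaged for s in tr]).astype(np.float32) / 255
        acc = np.mean(model.predict_proba(x).argmax(axis=1) ==
                      [s.label.index for s in tr])
        assert acc > 0.9


class TestPrediction:
    def test_identical_frames_equal_single_frame_prediction(self, tiny_samples):
        cfg = tiny_config(seed=6, epochs=1)
        tr = [s for s in tiny_samples if s.patient_id < "T16"]
        va = [s for s in tiny_samples if s.patient_id >= "T16"]
        ws = train(build_model(cfg), tr, va, cfg)
        img = tiny_samples[0].frameset.averaged
        fs = make_fs(img)
        per_frame = predict_frames(ws, fs)
        single = ws.model().predict_proba(img.astype(np.float32) / 255.0)[0]
        assert np.allclose(per_frame, single, atol=1e-6)
        avg = predict_avgimage(ws, fs)
        assert np.allclose(avg, single, atol=1e-6)

    def test_linear_model_frame_average_commutes(self, rng):
        """For a linear map, averaging inputs equals averaging outputs —
        the two input strategies coincide before any nonlinearity."""
        dense = nn.Dense(16, 5, rng)
        frames = rng.random((10, 16)).astype(np.float32)
        mean_of_logits = dense.forward(frames).mean(axis=0)
        logits_of_mean = dense.forward(frames.mean(axis=0, keepdims=True))[0]
        assert np.allclose(mean_of_logits, logits_of_mean, atol=1e-5)


class TestEnsemble:
    def test_agreeing_models_return_same_vector(self):
        v = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        mean, label = combine_probabilities([v, v, v, v, v])
        assert np.allclose(mean, v)
        assert label is ViewLabel.AP3  # index 2 in canonical order

    def test_three_two_split_averages(self):
        a = np.array([1.0, 0, 0, 0, 0])
        b = np.array([0, 1.0, 0, 0, 0])
        mean, label = combine_probabilities([a, a, a, b, b])
        assert np.allclose(mean, [0.6, 0.4, 0, 0, 0])
        assert label is ev.VIEW_ORDER[0]

    def test_exact_tie_broken_by_canonical_order(self):
        t = np.array([0.5, 0.5, 0, 0, 0])
        _, label = combine_probabilities([t])
        assert label is ViewLabel.PLAX

    def test_empty_ensemble_rejected(self):
        with pytest.raises(ValueError):
            combine_probabilities([])

    def test_permutation_invariance_over_weight_sets(self, tiny_samples):
        cfg = tiny_config(seed=8, epochs=1)
        tr = [s for s in tiny_samples if s.patient_id < "T16"]
        va = [s for s in tiny_samples if s.patient_id >= "T16"]
        w1 = train(build_model(cfg), tr, va, cfg)
        cfg2 = tiny_config(seed=9, epochs=1)
        w2 = train(build_model(cfg2), tr, va, cfg2)
        fs = tiny_samples[-1].frameset
        p_ab, l_ab = ensemble_predict([w1, w2], fs)
        p_ba, l_ba = ensemble_predict([w2, w1], fs)
        assert np.allclose(p_ab, p_ba, atol=1e-7)
        assert l_ab is l_ba
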