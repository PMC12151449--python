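import numpy as np
import pytest

from posmov import (
    ConfigurationError,
    ModelSpec,
    RecordingConfig,
    TrainingConfig,
    augment_sequence,
    build_model,
    cohen_kappa,
    confusion_from_labels,
    predict_frames,
    train_cross_validated,
)
from posmov.nn import Adam, weighted_cross_entropy
from posmov.preprocess import preprocess_recording
from posmov.vocab import POSTURES


@pytest.fixture(scope="module")
def acc_gyro_tensor(tiny_cohort):
    cfg = RecordingConfig(n_arm=2, n_leg=2, modality="acc_gyro")
    return preprocess_recording(tiny_cohort[0].recording, cfg)


class TestArchitecture:
    def test_acc_gyro_has_three_input_heads(self, acc_gyro_tensor):
        model = build_model(acc_gyro_tensor, n_classes=7)
        assert len(model.heads) == 3

    def test_raw_acc_has_one_input_head(self, tiny_cohort):
        cfg = RecordingConfig(n_arm=2, n_leg=2, modality="raw_acc")
        tensor = preprocess_recording(tiny_cohort[0].recording, cfg)
        model = build_model(tensor, n_classes=7)
        assert len(model.heads) == 1

    def test_softmax_rows_sum_to_one(self, acc_gyro_tensor):
        model = build_model(acc_gyro_tensor, n_classes=7)
        probs = model(acc_gyro_tensor.frames[:16])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_reference_scale_latent_and_receptive_field(self):
        ref = ModelSpec.reference()
        assert ref.latent_dim == 160
        assert abs(ref.receptive_field_frames - 30) <= 1
        assert ref.receptive_field_frames * 60 / 52 == pytest.approx(34.6, abs=1.5)

    def test_parameter_count_deterministic(self, acc_gyro_tensor):
        a = build_model(acc_gyro_tensor, 7, seed=0)
        b = build_model(acc_gyro_tensor, 7, seed=0)
        assert a.n_parameters() == b.n_parameters()
        for (pa, _), (pb, _) in zip(a.params(), b.params()):
            np.testing.assert_array_equal(pa, pb)

    def test_stream_mismatch_rejected(self, acc_gyro_tensor):
        model = build_model((1, 6), n_classes=7)
        with pytest.raises(ConfigurationError):
            model.forward(acc_gyro_tensor.frames[:4])

    def test_receptive_field_locality(self, acc_gyro_tensor):
        """Perturbing one frame may not affect predictions beyond +-15 frames."""
        model = build_model(acc_gyro_tensor, n_classes=7, seed=2)
        frames = acc_gyro_tensor.frames[:80].copy()
        base = model.forward(frames)
        j = 40
        frames[j] += 5.0
        pert = model.forward(frames)
        changed = np.nonzero(np.abs(pert - base).max(axis=1) > 1e-9)[0]
        half = (model.spec.receptive_field_frames - 1) // 2
        assert changed.size > 0
        assert np.abs(changed - j).max() <= half


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Analytic gradients agree with central differences on a tiny model."""
        rng = np.random.default_rng(0)
        spec = ModelSpec(head_width=4, latent_dim=6, temporal_width=6, dilations=(1, 2))
        model = build_model((2, 3), n_classes=3, spec=spec, seed=1)
        frames = rng.normal(size=(7, 2, 3, 120))
        targets = rng.integers(0, 3, size=7)
        weights = np.ones(3)

        def loss_value():
            logits = model.forward(frames)
            loss, _ = weighted_cross_entropy(logits, targets, weights)
            return loss

        logits = model.forward(frames)
        _, dlogits = weighted_cross_entropy(logits, targets, weights)
        model.backward(dlogits)
        checked = 0
        for p, g in model.params():
            flat_p, flat_g = p.ravel(), g.ravel()
            for idx in (0, flat_p.size // 2):
                orig = flat_p[idx]
                eps = 1e-5
                flat_p[idx] = orig + eps
                up = loss_value()
                flat_p[idx] = orig - eps
                down = loss_value()
                flat_p[idx] = orig
                numeric = (up - down) / (2 * eps)
                assert numeric == pytest.approx(flat_g[idx], rel=2e-2, abs=1e-6)
                checked += 1
        assert checked >= 10


class TestAugmentation:
    def _frames(self, rng, n_sensors=4):
        return rng.normal(size=(6, 3, 3 * n_sensors, 120))

    def test_zero_probabilities_identity(self, rng):
        frames = self._frames(rng)
        cfg = TrainingConfig(p_sensor_dropout=0, p_sample_dropout=0, p_rotation=0)
        np.testing.assert_array_equal(augment_sequence(frames, cfg, rng), frames)

    def test_rotation_preserves_vector_norms(self, rng):
        frames = self._frames(rng)
        cfg = TrainingConfig(p_sensor_dropout=0, p_sample_dropout=0, p_rotation=1.0)
        out = augment_sequence(frames, cfg, rng)
        for s in range(4):
            seg_in = frames[:, :, 3 * s : 3 * s + 3, :]
            seg_out = out[:, :, 3 * s : 3 * s + 3, :]
            np.testing.assert_allclose(
                np.linalg.norm(seg_out, axis=2), np.linalg.norm(seg_in, axis=2), atol=1e-6
            )
        assert not np.allclose(out, frames)

    def test_sensor_dropout_zeroes_exactly_one_sensor(self, rng):
        frames = self._frames(rng)
        cfg = TrainingConfig(p_sensor_dropout=1.0, p_sample_dropout=0, p_rotation=0)
        out = augment_sequence(frames, cfg, rng)
        zeroed = [
            s for s in range(4) if np.all(out[:, :, 3 * s : 3 * s + 3, :] == 0)
        ]
        assert len(zeroed) == 1

    def test_sensor_dropout_skipped_for_single_sensor(self, rng):
        frames = self._frames(rng, n_sensors=1)
        cfg = TrainingConfig(p_sensor_dropout=1.0, p_sample_dropout=0, p_rotation=0)
        np.testing.assert_array_equal(augment_sequence(frames, cfg, rng), frames)

    def test_sample_dropout_rate(self, rng):
        frames = np.ones((20, 2, 6, 120))
        cfg = TrainingConfig(p_sensor_dropout=0, p_sample_dropout=1.0, p_rotation=0)
        out = augment_sequence(frames, cfg, rng)
        assert np.mean(out == 0) == pytest.approx(0.3, abs=0.02)


class TestLossWeighting:
    def test_inverse_prior_weights_recover_minority_class(self):
        """9:1 imbalance: weighted training yields minority recall >= 0.7
        and beats unweighted training at the same budget."""
        rng = np.random.default_rng(7)
        n = 400
        targets = (rng.random(n) < 0.1).astype(int)
        frames = rng.normal(0, 1, size=(n, 1, 3, 120))
        frames[targets == 1, :, 0, :] += 0.8  # weak minority signature

        def train(weights):
            spec = ModelSpec(head_width=4, latent_dim=8, temporal_width=8, dilations=(1,))
            model = build_model((1, 3), n_classes=2, spec=spec, seed=3)
            opt = Adam(model.params(), lr=3e-3)
            for _ in range(30):
                for s in range(0, n, 100):
                    logits = model.forward(frames[s : s + 100])
                    _, d = weighted_cross_entropy(logits, targets[s : s + 100], weights)
                    model.backward(d)
                    opt.step()
            pred = np.argmax(model.forward(frames), axis=1)
            return (pred[targets == 1] == 1).mean()

        priors = np.array([0.9, 0.1])
        weighted_recall = train(1.0 / priors)
        unweighted_recall = train(np.ones(2))
        assert weighted_recall >= 0.7
        assert weighted_recall > unweighted_recall


class TestTraining:
    @pytest.fixture(scope="class")
    def tensors(self, tiny_cohort):
        cfg = RecordingConfig(n_arm=2, n_leg=2, modality="acc_gyro")
        return [preprocess_recording(c.recording, cfg) for c in tiny_cohort]

    def test_fold_partition_and_determinism(self, tensors, tiny_labels):
        tc = TrainingConfig.desk_scale(epochs=2, folds=3, seed=5)
        preds1, folds1 = train_cross_validated(tensors, tiny_labels, "posture", 7, training=tc)
        preds2, _ = train_cross_validated(tensors, tiny_labels, "posture", 7, training=tc)
        tested = sorted(i for f in folds1 for i in f.test_recordings)
        assert tested == list(range(len(tensors)))  # exact partition
        assert sorted(preds1) == tested
        for i in preds1:
            np.testing.assert_array_equal(preds1[i].onehot, preds2[i].onehot)

    def test_shuffled_labels_give_chance_kappa(self, tensors, tiny_labels, tiny_truth):
        rng = np.random.default_rng(0)
        shuffled = []
        for lab in tiny_labels:
            import copy

            lab2 = copy.deepcopy(lab)
            perm = rng.permutation(lab2.targets["posture"].shape[0])
            lab2.targets["posture"] = lab2.targets["posture"][perm]
            shuffled.append(lab2)
        tc = TrainingConfig.desk_scale(epochs=3, folds=3, seed=1)
        preds, _ = train_cross_validated(tensors, shuffled, "posture", 7, training=tc)
        cm = np.zeros((7, 7), dtype=np.int64)
        for i, p in preds.items():
            cm += confusion_from_labels(p.labels, shuffled[i].targets["posture"], 7)
        assert abs(cohen_kappa(cm)) < 0.1

    def test_prediction_invariant_to_trailing_padding(self, tensors, tiny_labels):
        model = build_model(tensors[0], n_classes=len(POSTURES), seed=4)
        frames = tensors[0].frames
        valid = np.ones(frames.shape[0], dtype=bool)
        base = predict_frames(model, tensors[0], valid)
        from posmov.preprocess import FrameTensor, frame_times

        padded_frames = np.concatenate([frames, np.zeros_like(frames[:20])], axis=0)
        padded = FrameTensor(
            padded_frames, tensors[0].stream_labels, frame_times(frames.shape[0] + 20)
        )
        out = predict_frames(model, padded, np.ones(padded_frames.shape[0], dtype=bool))
        half = (model.spec.receptive_field_frames - 1) // 2
        np.testing.assert_array_equal(
            out.onehot[: frames.shape[0] - half], base.onehot[: frames.shape[0] - half]
        )

    def test_too_few_recordings_rejected(self, tensors, tiny_labels):
        tc = TrainingConfig.desk_scale(epochs=1, folds=10)
        with pytest.raises(ConfigurationError):
            train_cross_validated(tensors, tiny_labels, "posture", 7, training=tc)
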