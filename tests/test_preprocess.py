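import numpy as np
import pytest
from scipy import signal as sp_signal

import posmov
from posmov import ConfigurationError, IntegrityError, RecordingConfig
from posmov.io import AnnotationTrack
from posmov.preprocess import (
    HOP_SAMPLES,
    WINDOW_SAMPLES,
    assemble_streams,
    assign_frame_labels,
    frame_count,
    frame_times,
    make_frames,
    preprocess_recording,
    reduce_sampling_rate,
    remove_gyro_bias,
    select_placement,
    split_accelerometer,
)

FS = 52.0


class TestPlacementSelection:
    def test_full_placement_is_identity(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        out = select_placement(rec, RecordingConfig(n_arm=2, n_leg=2))
        assert list(out.sensors) == ["left_arm", "right_arm", "left_leg", "right_leg"]

    def test_singletons_default_to_left(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        out = select_placement(rec, RecordingConfig(n_arm=1, n_leg=1))
        assert list(out.sensors) == ["left_arm", "left_leg"]

    def test_missing_sensor_is_configuration_error(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        partial = posmov.Recording(
            recording_id="p",
            sample_rate=rec.sample_rate,
            sensors={"left_leg": rec.sensors["left_leg"]},
        )
        with pytest.raises(ConfigurationError):
            select_placement(partial, RecordingConfig(n_arm=1, n_leg=1))


class TestRateReduction:
    def test_factor_one_is_identity(self, rng):
        x = rng.normal(size=(520, 3))
        np.testing.assert_array_equal(reduce_sampling_rate(x, 1), x)

    def test_constant_preserved(self):
        x = np.full((1040, 2), 3.7)
        out = reduce_sampling_rate(x, 4)
        np.testing.assert_allclose(out, x, atol=1e-6)

    @pytest.mark.parametrize("freq,factor", [(2.0, 4), (20.0, 4)])
    def test_sine_attenuation_matches_butterworth_oracle(self, freq, factor):
        # Oracle: two zero-phase passes of the 6th-order low-pass at
        # 0.5 * decimated rate, i.e. |H|^4 amplitude gain.
        t = np.arange(int(FS * 60)) / FS
        x = np.sin(2 * np.pi * freq * t)[:, None]
        out = reduce_sampling_rate(x, factor)
        core = slice(260, -260)  # avoid edge transients
        ratio = np.sqrt(np.mean(out[core] ** 2) / np.mean(x[core] ** 2))
        b, a = sp_signal.butter(6, 0.5 * FS / factor, btype="lowpass", fs=FS)
        _, h = sp_signal.freqz(b, a, worN=[freq], fs=FS)
        expected = np.abs(h[0]) ** 4
        if freq < 0.5 * FS / factor:
            assert 0.95 <= ratio <= 1.05
            assert ratio == pytest.approx(expected, abs=0.05)
        else:
            assert ratio < 0.05

    def test_idempotent_at_fixed_factor(self):
        # multisine well inside the retained passband (cutoff 6.5 Hz)
        t = np.arange(int(FS * 60)) / FS
        x = (
            np.sin(2 * np.pi * 0.5 * t)
            + 0.5 * np.sin(2 * np.pi * 1.5 * t)
            + 0.3 * np.sin(2 * np.pi * 3.0 * t)
        )[:, None]
        once = reduce_sampling_rate(x, 4)
        twice = reduce_sampling_rate(once, 4)
        rms = np.sqrt(np.mean((twice - once) ** 2))
        assert rms < 1e-3 * np.sqrt(np.mean(once**2))

    def test_invalid_factor_rejected(self):
        with pytest.raises(ConfigurationError):
            reduce_sampling_rate(np.zeros((200, 1)), 0)
        with pytest.raises(ConfigurationError):
            reduce_sampling_rate(np.zeros((200, 1)), 2.5)


class TestGravitySplit:
    def test_constant_gravity_goes_to_lowpass(self):
        acc = np.tile([0.0, 0.0, 9.81], (1040, 1))
        low, high = split_accelerometer(acc, FS)
        np.testing.assert_allclose(low, acc, atol=1e-9)
        np.testing.assert_allclose(high, 0.0, atol=1e-9)

    def test_additive_identity(self, rng):
        acc = rng.normal(0, 3, size=(1560, 3))
        low, high = split_accelerometer(acc, FS)
        np.testing.assert_allclose(low + high, acc, atol=1e-9)

    def test_fast_oscillation_goes_to_highpass(self):
        t = np.arange(int(FS * 30)) / FS
        acc = np.sin(2 * np.pi * 5.0 * t)[:, None]
        _, high = split_accelerometer(acc, FS)
        core = slice(120, -120)
        assert np.sqrt(np.mean(high[core] ** 2) / np.mean(acc[core] ** 2)) > 0.99

    def test_non_finite_rejected(self):
        acc = np.zeros((600, 3))
        acc[10, 1] = np.nan
        with pytest.raises(IntegrityError):
            split_accelerometer(acc, FS)


class TestGyroBias:
    def test_constant_offset_removed(self):
        gyro = np.tile([2.0, -1.5, 0.7], (600, 1))
        np.testing.assert_allclose(remove_gyro_bias(gyro), 0.0, atol=1e-9)

    def test_zero_median_signal_unchanged(self):
        t = np.arange(1040)
        gyro = np.sin(2 * np.pi * t / 52.0)[:, None] * np.array([[10.0, 5.0, 1.0]])
        np.testing.assert_allclose(remove_gyro_bias(gyro), gyro, atol=1e-9)

    def test_sine_plus_offset_recentered(self, rng):
        t = np.arange(int(FS * 120)) / FS
        gyro = np.sin(2 * np.pi * 1.3 * t)[:, None] * 20 + 3.0
        out = remove_gyro_bias(gyro)
        assert np.abs(np.median(out, axis=0)).max() < 0.05


class TestStreamAssembly:
    def test_acc_gyro_full_placement(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        streams, labels = assemble_streams(rec, RecordingConfig(n_arm=2, n_leg=2))
        assert labels == ("acc_low", "acc_high", "gyro")
        assert streams.shape[1:] == (3, 12)

    def test_raw_acc_two_sensors(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        cfg = RecordingConfig(n_arm=1, n_leg=1, modality="raw_acc")
        streams, labels = assemble_streams(rec, cfg)
        assert labels == ("acc",)
        assert streams.shape[1:] == (1, 6)

    def test_preproc_streams_reconstruct_raw(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        cfg = RecordingConfig(n_arm=0, n_leg=2, modality="preproc_acc")
        streams, _ = assemble_streams(rec, cfg)
        raw = np.concatenate([rec.sensors["left_leg"].acc, rec.sensors["right_leg"].acc], axis=1)
        np.testing.assert_allclose(streams[:, 0] + streams[:, 1], raw, atol=1e-9)


class TestFraming:
    @pytest.mark.parametrize("n,expected", [(119, 0), (120, 1), (179, 1), (180, 2), (600, 9)])
    def test_frame_count_examples(self, n, expected):
        assert frame_count(n) == expected

    def test_frame_count_matches_brute_force(self):
        for n in np.random.default_rng(0).integers(120, 5000, size=50):
            brute = sum(
                1 for start in range(0, n, HOP_SAMPLES) if start + WINDOW_SAMPLES <= n
            )
            assert frame_count(int(n)) == brute

    def test_frame_rate(self):
        times = frame_times(3)
        assert np.diff(times)[0] == pytest.approx(HOP_SAMPLES / FS)
        assert FS / HOP_SAMPLES == pytest.approx(0.87, abs=0.005)

    def test_short_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            tensor = make_frames(np.zeros((100, 1, 3)), ("acc",))
        assert tensor.n_frames == 0

    def test_pipeline_shapes(self, tiny_cohort):
        rec = tiny_cohort[0].recording
        cfg = RecordingConfig(n_arm=1, n_leg=1, modality="acc_gyro", sample_rate=13)
        tensor = preprocess_recording(rec, cfg)
        assert tensor.frames.shape[1:] == (3, 6, WINDOW_SAMPLES)
        assert tensor.n_frames == frame_count(rec.n_samples)


class TestFrameLabelAssignment:
    def test_frame_inside_one_segment(self):
        tracks = [
            AnnotationTrack("A1", "posture", [(0, 30, "prone")]),
            AnnotationTrack("A1", "movement", [(0, 30, "still")]),
        ]
        labs = assign_frame_labels(tracks, frame_times(10))
        assert (labs.targets["posture"] == 0).all()

    def test_majority_overlap_wins(self):
        # window [3.46, 5.77] s split 60/40 between supine and prone
        boundary = 3.46 + 0.6 * (WINDOW_SAMPLES / FS)
        tracks = [
            AnnotationTrack(
                "A1", "posture", [(0, boundary, "supine"), (boundary, 30, "prone")]
            )
        ]
        labs = assign_frame_labels(tracks, np.array([4.615]))
        assert labs.targets["posture"][0] == 1  # supine

    def test_any_auxiliary_overlap_masks_frame(self):
        tracks = [AnnotationTrack("A1", "posture", [(0, 60, "prone")])]
        aux = AnnotationTrack("shared", "auxiliary", [(10.0, 12.0, "carried")])
        times = frame_times(frame_count(int(60 * FS)))
        labs = assign_frame_labels(tracks, times, auxiliary=aux)
        half = WINDOW_SAMPLES / 2 / FS
        overlapping = (times + half > 10.0) & (times - half < 12.0)
        assert (~labs.valid[overlapping]).all()
        assert labs.valid[~overlapping].all()
        assert (labs.targets["posture"][overlapping] == -1).all()

    def test_vote_tie_breaks_to_first_annotator(self):
        tracks = [
            AnnotationTrack("A1", "posture", [(0, 30, "sitting")]),
            AnnotationTrack("A2", "posture", [(0, 30, "standing")]),
        ]
        labs = assign_frame_labels(tracks, frame_times(5))
        assert (labs.targets["posture"] == 5).all()  # sitting = A1's label
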