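import numpy as np
import pytest

from posmov import (
    AnnotatorErrorModel,
    BehaviorModel,
    CohortSpec,
    ModelError,
    cohen_kappa,
    generate_cohort,
    interrater_confusion,
    sample_cohort,
    sample_state_sequence,
    simulate_annotators,
    synthesize_imu,
)
from posmov.io import AnnotationTrack
from posmov.preprocess import assign_frame_labels, frame_count, frame_times, split_accelerometer
from posmov.vocab import MOVEMENTS, POSTURES


@pytest.fixture(scope="module")
def model():
    return BehaviorModel()


class TestStateSequences:
    def test_tracks_cover_duration_without_gaps(self, model, rng):
        posture, movement = sample_state_sequence(model, 8.0, 600.0, rng)
        for track in (posture, movement):
            assert track.segments[0][0] == 0.0
            assert track.segments[-1][1] == pytest.approx(600.0)
            for (_, e1, _), (s2, _, _) in zip(track.segments, track.segments[1:]):
                assert e1 == pytest.approx(s2)

    def test_young_infant_spends_most_time_lying(self, model):
        # Monte-Carlo occupancy at age 5 months over repeated draws
        rng = np.random.default_rng(0)
        lying = total = 0.0
        for _ in range(100):
            posture, _ = sample_state_sequence(model, 5.0, 600.0, rng)
            for s, e, cat in posture.segments:
                total += e - s
                if cat in ("prone", "supine"):
                    lying += e - s
        assert lying / total > 0.5

    def test_movement_bouts_shorter_than_posture_bouts(self, model, rng):
        posture, movement = sample_state_sequence(model, 10.0, 1200.0, rng)
        mean_p = np.mean([e - s for s, e, _ in posture.segments])
        mean_m = np.mean([e - s for s, e, _ in movement.segments])
        assert mean_m < mean_p

    @pytest.mark.parametrize("age", [5.0, 10.0, 16.0])
    def test_short_bout_fractions_match_study_structure(self, model, age):
        rng = np.random.default_rng(int(age))
        durations_m, durations_p = [], []
        for _ in range(20):
            posture, movement = sample_state_sequence(model, age, 900.0, rng)
            durations_m += [e - s for s, e, _ in movement.segments]
            durations_p += [e - s for s, e, _ in posture.segments]
        durations_m, durations_p = np.array(durations_m), np.array(durations_p)
        assert 0.10 <= np.mean(durations_m < 2.0) <= 0.40
        assert np.mean(durations_m < 1.0) < 0.02
        assert np.mean(durations_p < 1.0) < 0.02

    def test_unreachable_posture_is_model_error(self):
        delta = {p: (1.0 if p == "prone" else 0.0) for p in POSTURES}
        bad = BehaviorModel(occupancy_young=dict(delta), occupancy_old=dict(delta))
        with pytest.raises(ModelError):
            sample_state_sequence(bad, 5.0, 120.0, np.random.default_rng(0))

    def test_minimum_duration_enforced(self, model, rng):
        with pytest.raises(ModelError):
            sample_state_sequence(model, 8.0, 30.0, rng)


class TestImuSynthesis:
    def test_still_prone_noiseless_gives_gravity_and_bias(self):
        quiet = BehaviorModel(
            sensor_noise_std=0.0, gyro_noise_std=0.0, arm_wander_std=0.0,
            leg_wander_std=0.0, arm_motor_noise=0.0, arm_motor_gyro=0.0, gyro_bias_std=0.0,
        )
        posture = AnnotationTrack("truth", "posture", [(0, 120, "prone")])
        movement = AnnotationTrack("truth", "movement", [(0, 120, "still")])
        rec = synthesize_imu(posture, movement, quiet, np.random.default_rng(0))
        leg = rec.sensors["left_leg"]
        expected = 9.81 * quiet.gravity_map("left_leg")["prone"]
        np.testing.assert_allclose(leg.acc.mean(axis=0), expected, atol=0.05)
        # gyro carries only the (zero) bias plus still-category micro-activity
        assert np.abs(leg.gyro.mean(axis=0)).max() < 0.5

    def test_acc_magnitude_near_gravity_when_still(self, model, rng):
        posture = AnnotationTrack("truth", "posture", [(0, 300, "supine")])
        movement = AnnotationTrack("truth", "movement", [(0, 300, "still")])
        rec = synthesize_imu(posture, movement, model, rng)
        mags = np.linalg.norm(rec.sensors["right_leg"].acc, axis=1)
        assert abs(mags.mean() - 9.81) / 9.81 < 0.02

    def test_fluent_has_more_highpass_energy_than_still(self, model, rng):
        posture = AnnotationTrack("truth", "posture", [(0, 240, "crawl")])
        movement = AnnotationTrack(
            "truth", "movement", [(0, 120, "still"), (120, 240, "fluent")]
        )
        rec = synthesize_imu(posture, movement, model, rng)
        _, high = split_accelerometer(rec.sensors["left_leg"].acc, 52.0)
        n = high.shape[0]
        rms_still = np.sqrt(np.mean(high[: n // 2 - 60] ** 2))
        rms_fluent = np.sqrt(np.mean(high[n // 2 + 60 :] ** 2))
        assert rms_fluent > 3 * rms_still

    def test_signals_within_hardware_ranges(self, tiny_cohort):
        for item in tiny_cohort:
            for block in item.recording.sensors.values():
                assert np.abs(block.acc).max() <= 8 * 9.81 + 1e-9
                assert np.abs(block.gyro).max() <= 500 + 1e-9


class TestAnnotators:
    def _frame_labels(self, item):
        n = frame_count(int(round(item.duration_s * 52)))
        labs = assign_frame_labels(item.annotations, frame_times(n), auxiliary=item.auxiliary)
        out = {}
        for tr in ("posture", "movement"):
            m = labs.per_annotator[tr].copy()
            m[~labs.valid] = -1
            out[tr] = m
        return out

    def test_errorless_annotators_reproduce_truth(self, model, rng):
        posture, movement = sample_state_sequence(model, 9.0, 600.0, rng)
        perfect = AnnotatorErrorModel(0.0, 0.0, 0.0, 0.0)
        tracks, _ = simulate_annotators(posture, movement, perfect, 3, rng, carrying_fraction=0.0)
        for t in tracks:
            truth = posture if t.track == "posture" else movement
            assert t.segments == truth.segments
        labels = np.stack(
            [self._labels_for(t, 600.0) for t in tracks if t.track == "posture"], axis=1
        )
        cm = interrater_confusion([labels], len(POSTURES))
        assert cohen_kappa(cm) == pytest.approx(1.0)

    @staticmethod
    def _labels_for(track, duration):
        n = frame_count(int(round(duration * 52)))
        labs = assign_frame_labels([track], frame_times(n))
        return labs.per_annotator[track.track][:, 0]

    def test_total_uniform_confusion_gives_chance_agreement(self, model):
        rng = np.random.default_rng(5)
        posture, movement = sample_state_sequence(model, 9.0, 1200.0, rng)
        worst = AnnotatorErrorModel(1.0, 1.0, 0.0, 0.0)
        tracks, _ = simulate_annotators(
            posture, movement, worst, 3, rng, carrying_fraction=0.0, uniform_kernel=True
        )
        labels = np.stack(
            [self._labels_for(t, 1200.0) for t in tracks if t.track == "posture"], axis=1
        )
        kappa = cohen_kappa(interrater_confusion([labels], len(POSTURES)))
        assert abs(kappa) < 0.1

    def test_auxiliary_track_shared_and_sized(self, model, rng):
        posture, movement = sample_state_sequence(model, 9.0, 1800.0, rng)
        _, aux = simulate_annotators(
            posture, movement, AnnotatorErrorModel(), 2, rng, carrying_fraction=0.15
        )
        covered = sum(e - s for s, e, _ in aux.segments)
        assert 0.10 * 1800 <= covered <= 0.25 * 1800
        assert all(c in ("carried", "out_of_camera") for _, _, c in aux.segments)


class TestCohorts:
    def test_same_seed_reproduces_cohort_exactly(self):
        spec = CohortSpec(n_recordings=2, session_minutes=(2.0, 3.0), seed=3)
        a = sample_cohort(spec, signals=True)
        b = sample_cohort(spec, signals=True)
        for x, y in zip(a, b):
            assert x.age_months == y.age_months
            assert x.truth_posture.segments == y.truth_posture.segments
            for s in x.recording.sensors:
                np.testing.assert_array_equal(
                    x.recording.sensors[s].acc, y.recording.sensors[s].acc
                )

    def test_generate_cohort_writes_byte_identical_outputs(self, tmp_path):
        spec = CohortSpec(n_recordings=2, session_minutes=(2.0, 3.0), seed=3)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(spec, d1, signals=True)
        generate_cohort(spec, d2, signals=True)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()

    def test_generate_cohort_refuses_overwrite(self, tmp_path):
        spec = CohortSpec(n_recordings=1, session_minutes=(2.0, 2.5), seed=4)
        generate_cohort(spec, tmp_path, signals=False)
        from posmov import IntegrityError

        with pytest.raises(IntegrityError):
            generate_cohort(spec, tmp_path, signals=False)

    def test_manifest_rows_and_age_range(self, tmp_path):
        spec = CohortSpec(n_recordings=12, session_minutes=(2.0, 3.0), seed=9)
        manifest = generate_cohort(spec, tmp_path, signals=False)
        assert len(manifest) == 12
        assert manifest["age_months"].between(4.5, 16.6).all()
        assert (tmp_path / "manifest.csv").exists()

    def test_cohort_spec_validation(self):
        with pytest.raises(ModelError):
            CohortSpec(n_recordings=0)
        with pytest.raises(ModelError):
            CohortSpec(n_annotators=4)
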