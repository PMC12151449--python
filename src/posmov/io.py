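"""Domain types and on-disk formats.

Recordings are stored as long-format CSV (one row per timestamp per sensor),
which tolerates missing sensors naturally; annotations as TSV interval lists;
grid results as a flat CSV.  Timestamps are seconds from recording start and
must be uniform — non-uniformity is an error, never silently resampled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError, RangeError, VocabularyError
from .vocab import TRACK_VOCAB

# Canonical sensor order: left arm, right arm, left leg, right leg.
SENSOR_CODES: tuple[str, ...] = ("LA", "RA", "LL", "RL")
SENSOR_PLACEMENTS: dict[str, str] = {
    "LA": "left_arm",
    "RA": "right_arm",
    "LL": "left_leg",
    "RL": "right_leg",
}
PLACEMENT_CODES = {v: k for k, v in SENSOR_PLACEMENTS.items()}

G = 9.81  # m/s^2
ACC_RANGE = 8 * G  # +-8 g accelerometer sensitivity
GYRO_RANGE = 500.0  # +-500 deg/s

REFERENCE_RATE = 52.0  # Hz

_RECORDING_COLUMNS = ["t_s", "sensor", "acc_x", "acc_y", "acc_z", "gyro_x", "gyro_y", "gyro_z"]
_ANNOTATION_COLUMNS = ["annotator", "track", "category", "start_s", "end_s"]
_RESULTS_COLUMNS = [
    "config_id",
    "placement",
    "modality",
    "sample_rate_hz",
    "track",
    "fold",
    "kappa",
    "ci_lo",
    "ci_hi",
]


@dataclass
class SensorBlock:
    """Triaxial accelerometer (m/s^2) and gyroscope (deg/s) of one sensor."""

    acc: np.ndarray  # (N, 3)
    gyro: np.ndarray  # (N, 3)

    def __post_init__(self) -> None:
        self.acc = np.asarray(self.acc, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        if self.acc.shape != self.gyro.shape or self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise IntegrityError("acc and gyro must both have shape (N, 3)")

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]


@dataclass
class Recording:
    """A multi-sensor IMU recording on a shared uniform time base."""

    recording_id: str
    sample_rate: float
    sensors: dict[str, SensorBlock]  # keyed by placement label, canonical order
    age_months: float | None = None

    def __post_init__(self) -> None:
        if not self.sensors:
            raise IntegrityError("recording must contain at least one sensor")
        lengths = {b.n_samples for b in self.sensors.values()}
        if len(lengths) != 1:
            raise IntegrityError(f"sensor blocks have unequal lengths: {sorted(lengths)}")
        for label in self.sensors:
            if label not in PLACEMENT_CODES:
                raise VocabularyError(f"unknown sensor placement {label!r}")
        # Canonical order regardless of construction order.
        order = [SENSOR_PLACEMENTS[c] for c in SENSOR_CODES]
        self.sensors = {k: self.sensors[k] for k in order if k in self.sensors}
        for label, block in self.sensors.items():
            if np.abs(block.acc).max(initial=0.0) > ACC_RANGE * (1 + 1e-9):
                raise RangeError(f"accelerometer out of +-8 g range on sensor {label}")
            if np.abs(block.gyro).max(initial=0.0) > GYRO_RANGE * (1 + 1e-9):
                raise RangeError(f"gyroscope out of +-500 deg/s range on sensor {label}")
        if self.age_months is not None and not (0 < self.age_months < 36):
            raise RangeError(f"age {self.age_months} months outside (0, 36)")

    @property
    def n_samples(self) -> int:
        return next(iter(self.sensors.values())).n_samples

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate


@dataclass
class AnnotationTrack:
    """Interval annotation of one track by one annotator."""

    annotator_id: str
    track: str  # posture | movement | auxiliary
    segments: list[tuple[float, float, str]]  # (start_s, end_s, category), sorted

    def __post_init__(self) -> None:
        if self.track not in TRACK_VOCAB:
            raise VocabularyError(f"unknown track {self.track!r}")
        vocab = TRACK_VOCAB[self.track]
        self.segments = sorted(
            [(float(a), float(b), str(c)) for a, b, c in self.segments], key=lambda s: s[0]
        )
        prev_end = -np.inf
        for start, end, cat in self.segments:
            if cat not in vocab:
                raise VocabularyError(f"category {cat!r} not in {self.track} vocabulary")
            if end <= start:
                raise IntegrityError(f"segment ({start}, {end}) has end <= start")
            if start < prev_end - 1e-9:
                raise IntegrityError(f"overlapping segments in {self.track} track at {start}")
            prev_end = end

    @property
    def duration_s(self) -> float:
        return self.segments[-1][1] if self.segments else 0.0


@dataclass(frozen=True)
class RecordingConfig:
    """A studied recording configuration: placement, modality, sampling rate.

    ``n_arm``/``n_leg`` count sensors per limb type; singletons are resolved
    by ``side`` (default left).  ``modality`` selects the input streams fed
    to the classifier, ``sample_rate`` the simulated sampling frequency.
    """

    n_arm: int
    n_leg: int
    modality: str = "acc_gyro"  # acc_gyro | raw_acc | preproc_acc
    sample_rate: float = REFERENCE_RATE
    side: str = "left"

    def __post_init__(self) -> None:
        from .errors import ConfigurationError

        if self.n_arm not in (0, 1, 2) or self.n_leg not in (0, 1, 2):
            raise ConfigurationError("sensor counts must be in {0, 1, 2}")
        if self.n_arm + self.n_leg < 1:
            raise ConfigurationError("at least one sensor required")
        if self.modality not in ("acc_gyro", "raw_acc", "preproc_acc"):
            raise ConfigurationError(f"unknown modality {self.modality!r}")
        if self.side not in ("left", "right"):
            raise ConfigurationError(f"side policy must be left or right, got {self.side!r}")
        if not 0 < self.sample_rate <= REFERENCE_RATE:
            raise ConfigurationError(
                f"sample rate {self.sample_rate} must be in (0, {REFERENCE_RATE}] Hz"
            )

    @property
    def decimation_factor(self) -> int:
        """Integer decimation factor realizing the (nominal) sample rate.

        Exact for rates dividing 52 Hz; nominal 6 and 3 Hz are realized by
        the nearest integer factors (8 -> 6.5 Hz, 16 -> 3.25 Hz).
        """
        return max(int(round(REFERENCE_RATE / self.sample_rate)), 1)

    @property
    def placement_name(self) -> str:
        parts = []
        if self.n_arm:
            parts.append(f"{self.n_arm}Arm")
        if self.n_leg:
            parts.append(f"{self.n_leg}Leg")
        return "".join(parts)

    @property
    def n_sensors(self) -> int:
        return self.n_arm + self.n_leg

    @property
    def sensor_labels(self) -> tuple[str, ...]:
        arms = {1: (f"{self.side}_arm",), 2: ("left_arm", "right_arm"), 0: ()}[self.n_arm]
        legs = {1: (f"{self.side}_leg",), 2: ("left_leg", "right_leg"), 0: ()}[self.n_leg]
        return arms + legs

    @property
    def config_id(self) -> str:
        return f"{self.placement_name}_{self.modality}_{self.sample_rate:g}Hz"


@dataclass
class FramePredictions:
    """Per-frame one-hot classification output with a validity mask."""

    frame_times: np.ndarray  # (N_frames,), window-center seconds
    onehot: np.ndarray  # (N_frames, N_cats) in {0, 1}
    valid_mask: np.ndarray  # (N_frames,), False where auxiliary/carrying

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.onehot = np.asarray(self.onehot)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        n = self.frame_times.shape[0]
        if self.onehot.shape[0] != n or self.valid_mask.shape != (n,):
            raise IntegrityError("frame grid shapes disagree")
        sums = self.onehot.sum(axis=1)
        if not np.all(sums[self.valid_mask] == 1):
            raise IntegrityError("valid rows must be exactly one-hot")
        if not np.all(sums[~self.valid_mask] == 0):
            raise IntegrityError("invalid rows must be all-zero")

    @property
    def labels(self) -> np.ndarray:
        """Argmax label per frame; -1 on masked frames."""
        lab = np.argmax(self.onehot, axis=1)
        return np.where(self.valid_mask, lab, -1)


@dataclass
class RecordingSummary:
    """Recording-level aggregates: distributions and BIMS score."""

    recording_id: str
    posture_dist: np.ndarray  # 7-vector
    movement_dist: np.ndarray  # 9-vector
    conditioned_dist: np.ndarray  # 27-vector over sensible combinations
    bims: float | None = None
    age_months: float | None = None

    def __post_init__(self) -> None:
        for name, vec, size in (
            ("posture_dist", self.posture_dist, 7),
            ("movement_dist", self.movement_dist, 9),
            ("conditioned_dist", self.conditioned_dist, 27),
        ):
            vec = np.asarray(vec, dtype=float)
            setattr(self, name, vec)
            if vec.shape != (size,):
                raise IntegrityError(f"{name} must have length {size}")
            if vec.min() < -1e-12 or abs(vec.sum() - 1.0) > 1e-9:
                raise IntegrityError(f"{name} must be a probability vector")
        if self.bims is not None and not (0 <= self.bims <= 100):
            raise RangeError(f"bims {self.bims} outside [0, 100]")

    @property
    def features(self) -> np.ndarray:
        """34-dim feature vector: posture distribution + conditioned distribution."""
        return np.concatenate([self.posture_dist, self.conditioned_dist])


# ---------------------------------------------------------------------------
# Recording CSV


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as long-format CSV (one row per timestamp per sensor)."""
    frames = []
    t = recording.times
    for label, block in recording.sensors.items():
        df = pd.DataFrame(
            {
                "t_s": t,
                "sensor": PLACEMENT_CODES[label],
                "acc_x": block.acc[:, 0],
                "acc_y": block.acc[:, 1],
                "acc_z": block.acc[:, 2],
                "gyro_x": block.gyro[:, 0],
                "gyro_y": block.gyro[:, 1],
                "gyro_z": block.gyro[:, 2],
            }
        )
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.10g")


def read_recording(
    path: str | Path,
    recording_id: str | None = None,
    age_months: float | None = None,
    sample_rate: float = REFERENCE_RATE,
) -> Recording:
    """Read a long-format recording CSV, validating schema and uniformity.

    The sampling rate is not stored in the file; it defaults to the 52 Hz
    hardware reference and is checked against the observed timestamp step.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(_RECORDING_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    sensors: dict[str, SensorBlock] = {}
    for code in SENSOR_CODES:
        sub = df[df["sensor"] == code]
        if sub.empty:
            continue
        sub = sub.sort_values("t_s")
        t = sub["t_s"].to_numpy(dtype=float)
        if len(t) > 1:
            gaps = np.diff(t)
            if gaps.max() > 1.5 / sample_rate:
                raise IntegrityError(
                    f"{path.name}: timestamp gap {gaps.max():.3f} s on sensor {code}"
                )
        acc = sub[["acc_x", "acc_y", "acc_z"]].to_numpy(dtype=float)
        gyro = sub[["gyro_x", "gyro_y", "gyro_z"]].to_numpy(dtype=float)
        sensors[SENSOR_PLACEMENTS[code]] = SensorBlock(acc=acc, gyro=gyro)
    if not sensors:
        raise FormatError(f"{path.name}: no sensor rows found")
    return Recording(
        recording_id=recording_id or path.stem,
        sample_rate=sample_rate,
        sensors=sensors,
        age_months=age_months,
    )


# ---------------------------------------------------------------------------
# Annotation TSV


def write_annotations(tracks: list[AnnotationTrack], path: str | Path) -> None:
    rows = [
        {
            "annotator": tr.annotator_id,
            "track": tr.track,
            "category": cat,
            "start_s": start,
            "end_s": end,
        }
        for tr in tracks
        for start, end, cat in tr.segments
    ]
    pd.DataFrame(rows, columns=_ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_annotations(path: str | Path) -> list[AnnotationTrack]:
    """Read annotation TSV into one AnnotationTrack per (annotator, track)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(_ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path.name}: missing columns {sorted(missing)}")
    tracks = []
    for (annotator, track), sub in df.groupby(["annotator", "track"], sort=True):
        segments = list(
            zip(
                sub["start_s"].astype(float),
                sub["end_s"].astype(float),
                sub["category"].astype(str),
            )
        )
        tracks.append(AnnotationTrack(annotator_id=str(annotator), track=str(track), segments=segments))
    return tracks


# ---------------------------------------------------------------------------
# Results table


def write_results_table(results: pd.DataFrame, path: str | Path) -> None:
    """Write grid results with deterministic column order; keys must be unique."""
    df = results.copy()
    missing = set(_RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"results table missing columns {sorted(missing)}")
    if len(df) and df.duplicated(subset=["config_id", "track", "fold"]).any():
        raise IntegrityError("duplicate (config_id, track, fold) keys in results")
    df[_RESULTS_COLUMNS].to_csv(path, index=False, float_format="%.12g")


def read_results_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_RESULTS_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{Path(path).name}: missing columns {sorted(missing)}")
    if len(df):
        df["sample_rate_hz"] = df["sample_rate_hz"].astype(float)
        df["fold"] = df["fold"].astype(int)
    return df
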