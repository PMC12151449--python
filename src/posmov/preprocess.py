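"""Reduce a reference-configuration recording to any studied configuration.

All reduced sampling rates are simulated on the 52 Hz grid (decimate,
linearly upsample back, zero-phase low-pass) so that every classifier
variant sees identical 120-sample frames.  The accelerometer can be split
into a gravity-dominated low-pass component (absolute orientation) and a
high-pass component (instantaneous movement) with an exact additive
identity low + high == raw.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .errors import ConfigurationError, IntegrityError
from .io import REFERENCE_RATE, AnnotationTrack, Recording, RecordingConfig, SensorBlock
from .vocab import TRACK_VOCAB

WINDOW_SAMPLES = 120  # 2.3 s at 52 Hz
HOP_SAMPLES = 60  # 50 % overlap
GRAVITY_CUTOFF_HZ = 0.5  # low/high accelerometer split
DECIMATION_ORDER = 6  # Butterworth order for rate reduction
GRAVITY_ORDER = 8  # Butterworth order for the gravity split


@dataclass
class FrameTensor:
    """Model-ready frames: (N_frames, N_streams, channels, 120 samples)."""

    frames: np.ndarray
    stream_labels: tuple[str, ...]
    frame_times: np.ndarray  # window-center seconds

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[3] != WINDOW_SAMPLES:
            raise IntegrityError(
                f"frames must have shape (F, S, C, {WINDOW_SAMPLES}), got {self.frames.shape}"
            )
        if self.frames.shape[1] != len(self.stream_labels):
            raise IntegrityError("stream labels do not match stream axis")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class FrameLabels:
    """Per-frame targets and per-annotator labels for one recording."""

    frame_times: np.ndarray
    targets: dict[str, np.ndarray]  # track -> (F,) int, -1 where masked
    per_annotator: dict[str, np.ndarray]  # track -> (F, n_annotators) int
    annotator_ids: tuple[str, ...]
    valid: np.ndarray  # (F,) bool, False where auxiliary overlaps


def select_placement(recording: Recording, config: RecordingConfig) -> Recording:
    """Restrict a recording to the sensors of ``config`` (deterministic order)."""
    wanted = config.sensor_labels
    missing = [s for s in wanted if s not in recording.sensors]
    if missing:
        raise ConfigurationError(f"sensors {missing} not present in recording")
    return Recording(
        recording_id=recording.recording_id,
        sample_rate=recording.sample_rate,
        sensors={s: recording.sensors[s] for s in wanted},
        age_months=recording.age_months,
    )


def reduce_sampling_rate(x: np.ndarray, factor: int, fs: float = REFERENCE_RATE) -> np.ndarray:
    """Simulate a lower sampling rate on the original grid (length-preserving).

    Anti-alias low-pass (zero-phase 6th-order Butterworth at half the
    decimated rate), drop samples, upsample back to the original grid
    (Fourier method, exact for band-limited content), then apply the same
    zero-phase low-pass once more.
    """
    if not float(factor).is_integer() or factor <= 0:
        raise ConfigurationError(f"decimation factor must be a positive integer, got {factor}")
    factor = int(factor)
    x = np.asarray(x, dtype=float)
    if factor == 1:
        return x.copy()
    n = x.shape[0]
    cutoff = 0.5 * fs / factor
    sos = signal.butter(DECIMATION_ORDER, cutoff, btype="lowpass", fs=fs, output="sos")
    padlen = min(n - 1, int(3 * fs))
    low = signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    n_pad = (-n) % factor
    if n_pad:
        low = np.concatenate([low, np.repeat(low[-1:], n_pad, axis=0)], axis=0)
    decimated = low[::factor]
    up = signal.resample(decimated, low.shape[0], axis=0)[:n]
    return signal.sosfiltfilt(sos, up, axis=0, padlen=padlen)


def split_accelerometer(acc: np.ndarray, fs: float = REFERENCE_RATE) -> tuple[np.ndarray, np.ndarray]:
    """Split acceleration into gravity (low-pass) and movement (high-pass).

    Zero-phase 8th-order Butterworth at 0.5 Hz; the high-pass part is the
    subtraction residual, so low + high reconstructs the input exactly.
    """
    acc = np.asarray(acc, dtype=float)
    if not np.all(np.isfinite(acc)):
        raise IntegrityError("non-finite accelerometer samples")
    sos = signal.butter(GRAVITY_ORDER, GRAVITY_CUTOFF_HZ, btype="lowpass", fs=fs, output="sos")
    padlen = min(acc.shape[0] - 1, int(6 * fs))
    low = signal.sosfiltfilt(sos, acc, axis=0, padlen=padlen)
    return low, acc - low


def remove_gyro_bias(gyro: np.ndarray) -> np.ndarray:
    """Subtract the per-channel whole-recording median (robust constant-offset estimate)."""
    gyro = np.asarray(gyro, dtype=float)
    return gyro - np.median(gyro, axis=0, keepdims=True)


def assemble_streams(recording: Recording, config: RecordingConfig) -> tuple[np.ndarray, tuple[str, ...]]:
    """Stack modality streams: (N_samples, N_streams, 3 * n_sensors).

    raw_acc -> {acc}; preproc_acc -> {acc_low, acc_high};
    acc_gyro -> {acc_low, acc_high, gyro (bias removed)}.
    Channels are concatenated across sensors within each stream, in the
    deterministic sensor order of the configuration.
    """
    labels = config.sensor_labels
    missing = [s for s in labels if s not in recording.sensors]
    if missing:
        raise ConfigurationError(f"modality/sensor mismatch: missing sensors {missing}")
    acc = np.concatenate([recording.sensors[s].acc for s in labels], axis=1)
    if config.modality == "raw_acc":
        streams = np.stack([acc], axis=1)
        return streams, ("acc",)
    low, high = split_accelerometer(acc, recording.sample_rate)
    if config.modality == "preproc_acc":
        return np.stack([low, high], axis=1), ("acc_low", "acc_high")
    gyro = np.concatenate([recording.sensors[s].gyro for s in labels], axis=1)
    gyro = remove_gyro_bias(gyro)
    return np.stack([low, high, gyro], axis=1), ("acc_low", "acc_high", "gyro")


def frame_count(n_samples: int) -> int:
    if n_samples < WINDOW_SAMPLES:
        return 0
    return (n_samples - WINDOW_SAMPLES) // HOP_SAMPLES + 1


def frame_times(n_frames: int, fs: float = REFERENCE_RATE) -> np.ndarray:
    """Window-center times of the frame grid (hop 60 samples)."""
    starts = np.arange(n_frames) * HOP_SAMPLES
    return (starts + WINDOW_SAMPLES / 2) / fs


def make_frames(
    streams: np.ndarray,
    stream_labels: tuple[str, ...],
    fs: float = REFERENCE_RATE,
) -> FrameTensor:
    """Window streams into 120-sample frames with 50 % overlap.

    The trailing remainder shorter than one hop is discarded; an input
    shorter than one window yields an empty tensor with a warning.
    """
    streams = np.asarray(streams, dtype=float)
    n = streams.shape[0]
    f = frame_count(n)
    if f == 0:
        warnings.warn("input shorter than one 120-sample window; empty frame tensor")
        empty = np.empty((0, streams.shape[1], streams.shape[2], WINDOW_SAMPLES))
        return FrameTensor(empty, stream_labels, np.empty(0))
    idx = np.arange(f)[:, None] * HOP_SAMPLES + np.arange(WINDOW_SAMPLES)[None, :]
    frames = streams[idx]  # (F, 120, S, C)
    frames = np.transpose(frames, (0, 2, 3, 1))  # (F, S, C, 120)
    return FrameTensor(np.ascontiguousarray(frames), stream_labels, frame_times(f, fs))


def preprocess_recording(recording: Recording, config: RecordingConfig) -> FrameTensor:
    """Full reduction pipeline: placement -> rate -> modality streams -> frames."""
    rec = select_placement(recording, config)
    factor = config.decimation_factor
    if factor != 1:
        sensors = {}
        for label, block in rec.sensors.items():
            sensors[label] = SensorBlock(
                acc=reduce_sampling_rate(block.acc, factor, rec.sample_rate),
                gyro=reduce_sampling_rate(block.gyro, factor, rec.sample_rate),
            )
        rec = Recording(
            recording_id=rec.recording_id,
            sample_rate=rec.sample_rate,
            sensors=sensors,
            age_months=rec.age_months,
        )
    streams, labels = assemble_streams(rec, config)
    return make_frames(streams, labels, rec.sample_rate)


# ---------------------------------------------------------------------------
# Frame labels


def _overlap_counts(
    track: AnnotationTrack,
    times: np.ndarray,
    n_cats: int,
    index: dict[str, int],
    fs: float,
) -> np.ndarray:
    """Per-frame per-category overlap (in samples) with the 2.3 s window."""
    duration = track.duration_s
    n = max(int(np.ceil(duration * fs)), 1)
    codes = np.full(n, -1, dtype=np.int32)
    grid = (np.arange(n) + 0.5) / fs
    for start, end, cat in track.segments:
        lo = np.searchsorted(grid, start)
        hi = np.searchsorted(grid, end)
        codes[lo:hi] = index[cat]
    onehot = np.zeros((n + 1, n_cats), dtype=np.int64)
    covered = codes >= 0
    onehot[1:][covered, codes[covered]] = 1
    cum = np.cumsum(onehot, axis=0)
    half = WINDOW_SAMPLES / 2 / fs
    lo = np.clip(np.round((times - half) * fs).astype(int), 0, n)
    hi = np.clip(np.round((times + half) * fs).astype(int), 0, n)
    return cum[hi] - cum[lo]


def _aux_mask(auxiliary: AnnotationTrack | None, times: np.ndarray, fs: float) -> np.ndarray:
    """True where the frame window has no overlap with any auxiliary segment."""
    valid = np.ones(times.shape[0], dtype=bool)
    if auxiliary is None:
        return valid
    half = WINDOW_SAMPLES / 2 / fs
    for start, end, _ in auxiliary.segments:
        valid &= (times + half <= start) | (times - half >= end)
    return valid


def assign_frame_labels(
    tracks: list[AnnotationTrack],
    times: np.ndarray,
    auxiliary: AnnotationTrack | None = None,
    fs: float = REFERENCE_RATE,
) -> FrameLabels:
    """Assign per-frame labels by largest temporal overlap with the window.

    For each annotator and track the frame label is the category with the
    largest overlap with the 2.3 s window (ties broken toward the
    lower-indexed category); frames with no covering segment get -1.  The
    training target is the majority vote across annotators, with ties
    resolved to the first annotator's label.  Frames overlapping an
    auxiliary segment by any amount are masked on all tracks.
    """
    times = np.asarray(times, dtype=float)
    valid = _aux_mask(auxiliary, times, fs)
    annotators = sorted({t.annotator_id for t in tracks if t.track != "auxiliary"})
    per_annotator: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    for track_name in ("posture", "movement"):
        vocab = TRACK_VOCAB[track_name]
        index = {c: i for i, c in enumerate(vocab)}
        labels = np.full((times.shape[0], len(annotators)), -1, dtype=np.int32)
        for j, ann in enumerate(annotators):
            match = [t for t in tracks if t.annotator_id == ann and t.track == track_name]
            if not match:
                continue
            counts = _overlap_counts(match[0], times, len(vocab), index, fs)
            lab = np.argmax(counts, axis=1).astype(np.int32)
            lab[counts.sum(axis=1) == 0] = -1
            labels[:, j] = lab
        per_annotator[track_name] = labels
        # majority vote; ties -> first annotator's label
        votes = np.zeros((times.shape[0], len(vocab)), dtype=np.int32)
        for j in range(labels.shape[1]):
            ok = labels[:, j] >= 0
            votes[np.nonzero(ok)[0], labels[ok, j]] += 1
        target = np.argmax(votes, axis=1).astype(np.int32)
        top = votes.max(axis=1)
        tied = (votes == top[:, None]).sum(axis=1) > 1
        first = labels[:, 0]
        target[tied & (first >= 0)] = first[tied & (first >= 0)]
        target[top == 0] = -1
        target[~valid] = -1
        targets[track_name] = target
    return FrameLabels(
        frame_times=times,
        targets=targets,
        per_annotator=per_annotator,
        annotator_ids=tuple(annotators),
        valid=valid,
    )
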