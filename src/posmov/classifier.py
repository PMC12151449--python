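"""End-to-end frame classifier and its training protocol.

The network is an encoder + temporal-convolution classifier: one input head
per modality stream (stacked strided 1-D convolutions over the 120-sample
frame, mean-pooled to a head embedding), head embeddings concatenated and
projected to the frame latent, then stacked residual blocks of symmetric
(non-causal) dilated convolutions over the frame axis and a per-track
softmax output.  At reference scale the latent is 160-dimensional and the
dilation stack (1, 2, 4, 8) with kernel 3 gives a receptive field of
31 frames (~±15 frames, i.e. ~34.6 s of context).

Training follows the study protocol: recording-level k-fold
cross-validation with a fixed seed, Adam on weighted categorical
cross-entropy (weights = inverse class priors of the training split),
batches of 100 consecutive frames, augmentation by sensor dropout, sample
dropout and small random rotations, and model selection by validation
Cohen kappa.  A reduced ("desk-scale") variant trains on CPU in minutes.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .agreement import cohen_kappa, confusion_from_labels
from .errors import ConfigurationError
from .io import FramePredictions
from .preprocess import FrameLabels, FrameTensor


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters; ``reference()`` matches the study scale."""

    head_width: int = 8
    latent_dim: int = 16
    temporal_width: int = 16
    head_kernel: int = 5
    head_stride: int = 2
    head_layers: int = 3
    temporal_kernel: int = 3
    dilations: tuple[int, ...] = (1, 2, 4, 8)

    @classmethod
    def reference(cls) -> "ModelSpec":
        return cls(head_width=64, latent_dim=160, temporal_width=160)

    @property
    def receptive_field_frames(self) -> int:
        """Total temporal receptive field in frames (31 at the default dilations)."""
        return 1 + (self.temporal_kernel - 1) * sum(self.dilations)


@dataclass
class TrainingConfig:
    """Optimization protocol; defaults follow the reference protocol."""

    learning_rate: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    epochs: int = 200
    folds: int = 10
    val_fraction: float = 0.20
    batch_frames: int = 100
    p_sensor_dropout: float = 0.3
    p_sample_dropout: float = 0.3
    sample_dropout_rate: float = 0.3
    p_rotation: float = 0.3
    rotation_deg: float = 15.0
    seed: int = 0

    @classmethod
    def desk_scale(cls, epochs: int = 20, folds: int = 3, seed: int = 0) -> "TrainingConfig":
        """Reduced protocol that trains the reduced model on CPU in minutes.

        The larger learning rate compensates for the much smaller epoch
        budget of the reduced model; all other settings are inherited.
        """
        return cls(learning_rate=3e-3, epochs=epochs, folds=folds, seed=seed)


# Fixed input normalization per stream kind: accelerometer streams are
# scaled to gravity units, gyroscope streams to ~full-scale-fraction units.
_STREAM_SCALES = {"acc": 1 / 9.81, "acc_low": 1 / 9.81, "acc_high": 1 / 9.81, "gyro": 1 / 100.0}


class FrameClassifier:
    """Callable network mapping a FrameTensor to per-frame class scores."""

    def __init__(
        self,
        n_streams: int,
        channels_per_stream: int,
        n_classes: int,
        spec: ModelSpec,
        rng: np.random.Generator,
        stream_labels: tuple[str, ...] | None = None,
    ) -> None:
        if n_streams < 1 or channels_per_stream < 3:
            raise ConfigurationError("need at least one stream of >= 3 channels")
        self.n_streams = n_streams
        self.channels = channels_per_stream
        self.n_classes = n_classes
        self.spec = spec
        if stream_labels is not None and len(stream_labels) != n_streams:
            raise ConfigurationError("stream labels do not match stream count")
        self.stream_scales = np.array(
            [
                _STREAM_SCALES.get(lbl, 1.0)
                for lbl in (stream_labels or ("acc",) * n_streams)
            ]
        )
        self.heads: list[list[nn.Layer]] = []
        for _ in range(n_streams):
            layers: list[nn.Layer] = []
            in_ch = channels_per_stream
            for li in range(spec.head_layers):
                conv = nn.Conv1D(
                    in_ch, spec.head_width, spec.head_kernel, rng, stride=spec.head_stride
                )
                if li == 0:
                    conv.compute_dx = False  # first layer: no input gradient needed
                layers += [conv, nn.ReLU()]
                in_ch = spec.head_width
            layers.append(nn.MeanPoolTime())
            self.heads.append(layers)
        self.merge = nn.Dense(n_streams * spec.head_width, spec.latent_dim, rng)
        self.merge_relu = nn.ReLU()
        self.temporal_in = nn.Conv1D(spec.latent_dim, spec.temporal_width, 1, rng, pad="valid")
        self.blocks = [
            nn.ResidualDilatedBlock(spec.temporal_width, spec.temporal_kernel, d, rng)
            for d in spec.dilations
        ]
        self.out = nn.Conv1D(spec.temporal_width, n_classes, 1, rng, pad="valid")

    # -- parameters ---------------------------------------------------------
    def params(self):
        ps = []
        for head in self.heads:
            for layer in head:
                ps += layer.params()
        ps += self.merge.params() + self.temporal_in.params() + self.out.params()
        for block in self.blocks:
            ps += block.params()
        return ps

    def n_parameters(self) -> int:
        return sum(p.size for p, _ in self.params())

    def state_dict(self) -> list[np.ndarray]:
        return [p.copy() for p, _ in self.params()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        for (p, _), saved in zip(self.params(), state):
            p[...] = saved

    # -- forward / backward -------------------------------------------------
    def forward(self, frames: np.ndarray) -> np.ndarray:
        """frames: (F, S, C, 120) -> logits (F, K)."""
        if frames.shape[1] != self.n_streams or frames.shape[2] != self.channels:
            raise ConfigurationError(
                f"stream layout {frames.shape[1:3]} does not match model "
                f"({self.n_streams}, {self.channels})"
            )
        embeddings = []
        for s, head in enumerate(self.heads):
            h = frames[:, s] * self.stream_scales[s]  # (F, C, 120), normalized units
            for layer in head:
                h = layer.forward(h)
            embeddings.append(h)  # (F, head_width)
        merged = np.concatenate(embeddings, axis=1)
        latent = self.merge_relu.forward(self.merge.forward(merged))  # (F, L)
        seq = latent.T[None]  # (1, L, F)
        h = self.temporal_in.forward(seq)
        for block in self.blocks:
            h = block.forward(h)
        logits = self.out.forward(h)[0].T  # (F, K)
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        grad = self.out.backward(dlogits.T[None])
        for block in reversed(self.blocks):
            grad = block.backward(grad)
        grad = self.temporal_in.backward(grad)  # (1, L, F)
        grad = self.merge_relu.backward(grad[0].T)  # (F, L)
        grad = self.merge.backward(grad)  # (F, S*h)
        width = self.spec.head_width
        for s in range(self.n_streams - 1, -1, -1):
            g = grad[:, s * width : (s + 1) * width]
            for layer in reversed(self.heads[s]):
                g = layer.backward(g)

    def __call__(self, frames: np.ndarray) -> np.ndarray:
        return nn.softmax(self.forward(frames), axis=1)


def build_model(
    tensor_or_layout: FrameTensor | tuple[int, int],
    n_classes: int,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> FrameClassifier:
    """Build a classifier matching a FrameTensor's stream layout."""
    labels = None
    if isinstance(tensor_or_layout, FrameTensor):
        n_streams, channels = tensor_or_layout.frames.shape[1:3]
        labels = tensor_or_layout.stream_labels
    else:
        n_streams, channels = tensor_or_layout
    spec = spec or ModelSpec()
    return FrameClassifier(
        n_streams, channels, n_classes, spec, np.random.default_rng(seed), stream_labels=labels
    )


# ---------------------------------------------------------------------------
# Augmentation


def _rotation_matrix(angles_rad: np.ndarray) -> np.ndarray:
    ax, ay, az = angles_rad
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def augment_sequence(
    frames: np.ndarray, config: TrainingConfig, rng: np.random.Generator
) -> np.ndarray:
    """Training-time augmentation of one (F, S, C, 120) frame sequence.

    With P_sensor_dropout one sensor's channels are zeroed for the whole
    sequence (never the only sensor); with P_sample_dropout individual
    samples are zeroed independently at the dropout rate; with P_rotation a
    single random Euler rotation (each angle uniform within ±15°) is applied
    to every acc/gyro 3-vector of every sensor.
    """
    out = frames.copy()
    n_sensors = frames.shape[2] // 3
    if n_sensors > 1 and rng.random() < config.p_sensor_dropout:
        drop = int(rng.integers(n_sensors))
        out[:, :, 3 * drop : 3 * drop + 3, :] = 0.0
    if rng.random() < config.p_rotation:
        angles = np.deg2rad(rng.uniform(-config.rotation_deg, config.rotation_deg, size=3))
        rot = _rotation_matrix(angles)
        for s in range(n_sensors):
            seg = out[:, :, 3 * s : 3 * s + 3, :]
            out[:, :, 3 * s : 3 * s + 3, :] = np.einsum("ij,fsjt->fsit", rot, seg)
    if rng.random() < config.p_sample_dropout:
        keep = rng.random(out.shape) >= config.sample_dropout_rate
        out *= keep
    return out


# ---------------------------------------------------------------------------
# Prediction and cross-validated training


def predict_frames(model: FrameClassifier, tensor: FrameTensor, valid: np.ndarray) -> FramePredictions:
    """Deterministic argmax one-hot predictions with the validity mask applied."""
    logits = model.forward(tensor.frames)
    labels = np.argmax(logits, axis=1)
    onehot = np.zeros((tensor.n_frames, model.n_classes), dtype=np.int8)
    valid = np.asarray(valid, dtype=bool)
    idx = np.nonzero(valid)[0]
    onehot[idx, labels[idx]] = 1
    return FramePredictions(frame_times=tensor.frame_times, onehot=onehot, valid_mask=valid)


def _fold_assignment(n: int, folds: int, rng: np.random.Generator) -> np.ndarray:
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for pos, rec in enumerate(order):
        assignment[rec] = pos % folds
    return assignment


def _class_weights(targets: list[np.ndarray], n_classes: int) -> np.ndarray:
    counts = np.zeros(n_classes)
    for t in targets:
        ok = t >= 0
        counts += np.bincount(t[ok], minlength=n_classes)
    total = counts.sum()
    weights = np.zeros(n_classes)
    present = counts > 0
    weights[present] = total / counts[present]
    if not present.all():
        absent = [int(i) for i in np.nonzero(~present)[0]]
        warnings.warn(f"classes {absent} absent from training split; weight clamped to 0")
    # normalize to mean weight 1 over present classes
    weights[present] /= weights[present].mean()
    return weights


@dataclass
class FoldResult:
    fold: int
    test_recordings: list[int]
    best_epoch: int
    val_kappa_history: list[float]
    model_state: list[np.ndarray] = field(repr=False, default_factory=list)


def train_cross_validated(
    tensors: list[FrameTensor],
    labels: list[FrameLabels],
    track: str,
    n_classes: int,
    model_spec: ModelSpec | None = None,
    training: TrainingConfig | None = None,
) -> tuple[dict[int, FramePredictions], list[FoldResult]]:
    """Recording-level k-fold cross-validated training.

    Every recording is predicted exactly once, by the fold model that never
    saw it.  Within each fold, 20 % of the training recordings are held out
    for validation and the epoch checkpoint with the best validation Cohen
    kappa is kept.  Returns out-of-fold predictions per recording index and
    per-fold training diagnostics.
    """
    spec = model_spec or ModelSpec()
    cfg = training or TrainingConfig()
    n = len(tensors)
    if n < cfg.folds:
        raise ConfigurationError(f"need >= {cfg.folds} recordings for {cfg.folds}-fold CV")
    rng = np.random.default_rng(cfg.seed)
    assignment = _fold_assignment(n, cfg.folds, rng)
    targets = [lab.targets[track] for lab in labels]
    predictions: dict[int, FramePredictions] = {}
    fold_results: list[FoldResult] = []

    for fold in range(cfg.folds):
        fold_rng = np.random.default_rng(cfg.seed * 100_003 + fold + 1)
        test_ids = [i for i in range(n) if assignment[i] == fold]
        train_pool = [i for i in range(n) if assignment[i] != fold]
        fold_rng.shuffle(train_pool)
        n_val = max(1, int(round(cfg.val_fraction * len(train_pool))))
        val_ids = sorted(train_pool[:n_val])
        train_ids = sorted(train_pool[n_val:])
        weights = _class_weights([targets[i] for i in train_ids], n_classes)

        model = FrameClassifier(
            tensors[0].frames.shape[1],
            tensors[0].frames.shape[2],
            n_classes,
            spec,
            fold_rng,
            stream_labels=tensors[0].stream_labels,
        )
        optimizer = nn.Adam(
            model.params(), lr=cfg.learning_rate, beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps
        )
        best_state = model.state_dict()
        best_kappa = -np.inf
        best_epoch = -1
        history: list[float] = []

        for epoch in range(cfg.epochs):
            order = list(train_ids)
            fold_rng.shuffle(order)
            for rec in order:
                frames = tensors[rec].frames
                tgt = targets[rec]
                n_frames = frames.shape[0]
                starts = np.arange(0, n_frames, cfg.batch_frames)
                for s in starts:
                    chunk = slice(s, min(s + cfg.batch_frames, n_frames))
                    batch = augment_sequence(frames[chunk], cfg, fold_rng)
                    logits = model.forward(batch)
                    _, dlogits = nn.weighted_cross_entropy(logits, tgt[chunk], weights)
                    model.backward(dlogits)
                    optimizer.step()
            # validation kappa for model selection
            cm = np.zeros((n_classes, n_classes), dtype=np.int64)
            for rec in val_ids:
                logits = model.forward(tensors[rec].frames)
                pred = np.argmax(logits, axis=1)
                pred = np.where(targets[rec] >= 0, pred, -1)
                cm += confusion_from_labels(pred, targets[rec], n_classes)
            kappa = cohen_kappa(cm) if cm.sum() else float("nan")
            history.append(kappa)
            if np.isfinite(kappa) and kappa > best_kappa:
                best_kappa = kappa
                best_epoch = epoch
                best_state = model.state_dict()

        model.load_state_dict(best_state)
        for rec in test_ids:
            valid = labels[rec].valid & (targets[rec] >= 0)
            predictions[rec] = predict_frames(model, tensors[rec], valid)
        fold_results.append(
            FoldResult(
                fold=fold,
                test_recordings=test_ids,
                best_epoch=best_epoch,
                val_kappa_history=history,
                model_state=best_state,
            )
        )
    return predictions, fold_results
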