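"""Orchestrate the recording-configuration grid and its report structures.

The reference study grid crosses 8 sensor placements x 3 sampling
frequencies x 3 modalities (72 configurations), trains a cross-validated
classifier pair per configuration, and compares configurations with paired
t tests matched on the two held-constant attributes.  A desk-scale grid
(fewer rates/modalities, reduced model) exercises the same machinery on a
synthetic cohort in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .agreement import bootstrap_ci, cohen_kappa, compound_confusion, paired_t
from .classifier import ModelSpec, TrainingConfig, train_cross_validated
from .errors import ConfigurationError, IntegrityError
from .io import FramePredictions, RecordingConfig
from .preprocess import FrameLabels, assign_frame_labels, frame_count, frame_times, preprocess_recording
from .synth import SyntheticRecording
from .vocab import MOVEMENTS, POSTURES

# Descending mean-performance order of the 8 placements observed on the
# reference data; enumerate_placements() follows it canonically.
PLACEMENT_ORDER: tuple[tuple[int, int], ...] = (
    (2, 2),  # 2Arm2Leg
    (1, 2),  # 1Arm2Leg
    (2, 1),  # 2Arm1Leg
    (1, 1),  # 1Arm1Leg
    (0, 2),  # 2Leg
    (0, 1),  # 1Leg
    (2, 0),  # 2Arm
    (1, 0),  # 1Arm
)

REFERENCE_RATES = (52.0, 26.0, 13.0)
EXTREME_RATES = (13.0, 6.0, 3.0, 2.0, 1.0)
MODALITIES = ("acc_gyro", "raw_acc", "preproc_acc")


def enumerate_placements() -> list[tuple[int, int]]:
    """All 8 (n_arm, n_leg) placements, in the canonical performance order."""
    return list(PLACEMENT_ORDER)


def placement_name(n_arm: int, n_leg: int) -> str:
    return RecordingConfig(n_arm=n_arm, n_leg=n_leg).placement_name


def data_rate(config: RecordingConfig, bytes_per_number: int = 4) -> tuple[float, float]:
    """(numbers per second, kilobytes per second) of the raw sensor stream.

    Hardware channels per sensor: 6 with the gyroscope (acc_gyro), 3 for the
    accelerometer-only modalities (the pre-processed variant is derived from
    the same 3 recorded channels).  kilobyte = 1000 bytes.
    """
    if config.n_sensors < 1:
        raise ConfigurationError("configuration has no sensors")
    channels = 6 if config.modality == "acc_gyro" else 3
    numbers = config.n_sensors * channels * config.sample_rate
    return numbers, numbers * bytes_per_number / 1000.0


@dataclass
class GridSpec:
    """A configuration grid to train and evaluate."""

    placements: tuple[tuple[int, int], ...] = PLACEMENT_ORDER
    rates: tuple[float, ...] = REFERENCE_RATES
    modalities: tuple[str, ...] = MODALITIES
    tracks: tuple[str, ...] = ("posture", "movement")
    model: ModelSpec = field(default_factory=ModelSpec)
    training: TrainingConfig = field(default_factory=TrainingConfig.desk_scale)
    seed: int = 0

    @property
    def grid_size(self) -> int:
        return len(self.placements) * len(self.rates) * len(self.modalities)

    def configs(self) -> list[RecordingConfig]:
        return [
            RecordingConfig(n_arm=a, n_leg=l, modality=m, sample_rate=r)
            for (a, l), r, m in product(self.placements, self.rates, self.modalities)
        ]


def reference_grid_size() -> int:
    """8 placements x 3 rates x 3 modalities = 72 trained classifier pairs."""
    return len(PLACEMENT_ORDER) * len(REFERENCE_RATES) * len(MODALITIES)


# ---------------------------------------------------------------------------
# Cohort plumbing


def load_cohort(cohort_dir: str | Path) -> list[SyntheticRecording]:
    """Load a generated cohort (manifest + recordings + annotations) from disk."""
    cohort_dir = Path(cohort_dir)
    manifest = pd.read_csv(cohort_dir / "manifest.csv")
    out: list[SyntheticRecording] = []
    for row in manifest.itertuples():
        rec_id = str(row.recording_id)
        tracks = pio.read_annotations(cohort_dir / f"{rec_id}_annotations.tsv")
        truth_p = next(t for t in tracks if t.annotator_id == "truth" and t.track == "posture")
        truth_m = next(t for t in tracks if t.annotator_id == "truth" and t.track == "movement")
        aux = next(t for t in tracks if t.track == "auxiliary")
        annotations = [t for t in tracks if t.annotator_id not in ("truth", "shared")]
        rec_path = cohort_dir / f"{rec_id}.csv"
        recording = None
        if rec_path.exists():
            recording = pio.read_recording(
                rec_path, recording_id=rec_id, age_months=float(row.age_months)
            )
        out.append(
            SyntheticRecording(
                recording_id=rec_id,
                age_months=float(row.age_months),
                duration_s=float(row.duration_s),
                truth_posture=truth_p,
                truth_movement=truth_m,
                annotations=annotations,
                auxiliary=aux,
                recording=recording,
            )
        )
    return out


def cohort_frame_labels(cohort: list[SyntheticRecording]) -> list[FrameLabels]:
    """Frame-grid labels per recording (shared by all configurations).

    The frame grid depends only on recording length, which no configuration
    transform changes, so labels are assigned once per recording.
    """
    labels = []
    for item in cohort:
        if item.recording is None:
            raise IntegrityError(f"recording {item.recording_id} has no signals")
        n = frame_count(item.recording.n_samples)
        times = frame_times(n, item.recording.sample_rate)
        labels.append(
            assign_frame_labels(item.annotations, times, auxiliary=item.auxiliary)
        )
    return labels


def truth_frame_labels(cohort: list[SyntheticRecording]) -> list[FrameLabels]:
    """Frame labels taken from the generator's ground-truth tracks."""
    labels = []
    for item in cohort:
        n = frame_count(item.recording.n_samples)
        times = frame_times(n, item.recording.sample_rate)
        truth = [item.truth_posture, item.truth_movement]
        labels.append(assign_frame_labels(truth, times, auxiliary=item.auxiliary))
    return labels


# ---------------------------------------------------------------------------
# Grid runs


def evaluate_config(
    cohort: list[SyntheticRecording],
    labels: list[FrameLabels],
    config: RecordingConfig,
    tracks: tuple[str, ...],
    model: ModelSpec,
    training: TrainingConfig,
) -> tuple[list[dict], dict[str, dict[int, FramePredictions]]]:
    """Train one configuration and measure per-fold kappa against annotators."""
    tensors = [preprocess_recording(item.recording, config) for item in cohort]
    rows: list[dict] = []
    predictions: dict[str, dict[int, FramePredictions]] = {}
    for track in tracks:
        n_cats = len(POSTURES) if track == "posture" else len(MOVEMENTS)
        preds, folds = train_cross_validated(
            tensors, labels, track, n_cats, model_spec=model, training=training
        )
        predictions[track] = preds
        for fr in folds:
            recs = fr.test_recordings
            pred_list = [preds[i].labels for i in recs]
            ann_list = [labels[i].per_annotator[track] for i in recs]
            cm = compound_confusion(pred_list, ann_list, n_cats)
            kappa = cohen_kappa(cm)
            if len(recs) >= 2:
                per_rec = [
                    compound_confusion([p], [a], n_cats) for p, a in zip(pred_list, ann_list)
                ]
                ci_lo, ci_hi = bootstrap_ci(
                    per_rec,
                    statistic=lambda mats: cohen_kappa(np.sum(mats, axis=0)),
                    n_iter=500,
                    rng=np.random.default_rng(training.seed),
                )
            else:
                ci_lo = ci_hi = float("nan")
            rows.append(
                {
                    "config_id": config.config_id,
                    "placement": config.placement_name,
                    "modality": config.modality,
                    "sample_rate_hz": config.sample_rate,
                    "track": track,
                    "fold": fr.fold,
                    "kappa": kappa,
                    "ci_lo": ci_lo,
                    "ci_hi": ci_hi,
                }
            )
    return rows, predictions


def run_grid(
    spec: GridSpec,
    cohort: list[SyntheticRecording],
    out_path: str | Path | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str], dict[int, FramePredictions]]]:
    """Train and evaluate every configuration of the grid.

    Results are a pure function of (cohort, spec); when ``out_path`` exists,
    configurations already present in it are skipped (idempotent resume)
    and the merged table is rewritten.
    """
    configs = spec.configs()
    ids = [c.config_id for c in configs]
    if len(set(ids)) != len(ids):
        raise IntegrityError("duplicate configuration ids in grid")
    existing = pd.DataFrame()
    done: set[str] = set()
    if out_path is not None and Path(out_path).exists():
        existing = pio.read_results_table(out_path)
        done = set(existing["config_id"].unique())
    labels = cohort_frame_labels(cohort)
    all_rows: list[dict] = []
    predictions: dict[tuple[str, str], dict[int, FramePredictions]] = {}
    for config in configs:
        if config.config_id in done:
            continue
        rows, preds = evaluate_config(
            cohort, labels, config, spec.tracks, spec.model, spec.training
        )
        all_rows.extend(rows)
        for track, p in preds.items():
            predictions[(config.config_id, track)] = p
    results = pd.concat([existing, pd.DataFrame(all_rows)], ignore_index=True)
    if out_path is not None:
        pio.write_results_table(results, out_path)
    return results, predictions


def config_pair_tests(results: pd.DataFrame, attribute: str) -> pd.DataFrame:
    """Paired t tests between attribute levels, matched on the other attributes.

    For each pair of levels of ``attribute`` (placement, modality or
    sample_rate_hz) and each track, the per-configuration mean kappas of
    systems with otherwise equivalent parameters are compared pairwise.
    """
    others = [a for a in ("placement", "modality", "sample_rate_hz") if a != attribute]
    mean_kappa = (
        results.groupby(["track", attribute] + others)["kappa"].mean().reset_index()
    )
    rows = []
    for track, sub in mean_kappa.groupby("track"):
        pivot = sub.pivot_table(index=others, columns=attribute, values="kappa")
        for a, b in combinations(pivot.columns, 2):
            paired = pivot[[a, b]].dropna()
            if len(paired) < 3:
                continue
            res = paired_t(paired[a].to_numpy(), paired[b].to_numpy())
            rows.append(
                {
                    "track": track,
                    "attribute": attribute,
                    "level_a": a,
                    "level_b": b,
                    "mean_a": paired[a].mean(),
                    "mean_b": paired[b].mean(),
                    "t": res.statistic,
                    "p": res.p_value,
                    "stars": res.stars,
                    "n": res.n,
                    "gaussian_ok": res.gaussian_ok,
                }
            )
    return pd.DataFrame(rows)


def placement_ranking(results: pd.DataFrame, track: str = "posture") -> list[str]:
    """Placements ordered by descending mean kappa."""
    sub = results[results["track"] == track]
    means = sub.groupby("placement")["kappa"].mean().sort_values(ascending=False)
    return list(means.index)


def extreme_decimation_report(
    cohort: list[SyntheticRecording],
    rates: tuple[float, ...] = EXTREME_RATES,
    placements: tuple[tuple[int, int], ...] = ((2, 2), (1, 1)),
    modalities: tuple[str, ...] = ("acc_gyro", "preproc_acc"),
    tracks: tuple[str, ...] = ("posture",),
    model: ModelSpec | None = None,
    training: TrainingConfig | None = None,
) -> pd.DataFrame:
    """Kappa versus sampling rate for the candidate systems (4 x 5 by default)."""
    spec = GridSpec(
        placements=placements,
        rates=rates,
        modalities=modalities,
        tracks=tracks,
        model=model or ModelSpec(),
        training=training or TrainingConfig.desk_scale(),
    )
    results, _ = run_grid(spec, cohort)
    return results


def markdown_summary(results: pd.DataFrame) -> str:
    """Compact markdown report: per-track placement ranking and pair tests."""
    lines = ["# Configuration grid summary", ""]
    for track in sorted(results["track"].unique()):
        lines.append(f"## {track}")
        sub = results[results["track"] == track]
        means = (
            sub.groupby(["placement", "modality", "sample_rate_hz"])["kappa"]
            .mean()
            .sort_values(ascending=False)
        )
        lines.append("")
        lines.append("| placement | modality | rate (Hz) | mean kappa |")
        lines.append("|---|---|---|---|")
        for (pl, mo, ra), k in means.items():
            lines.append(f"| {pl} | {mo} | {ra:g} | {k:.3f} |")
        lines.append("")
        lines.append(f"Placement ranking: {' > '.join(placement_ranking(results, track))}")
        lines.append("")
    for attribute in ("placement", "modality", "sample_rate_hz"):
        tests = config_pair_tests(results, attribute)
        if tests.empty:
            continue
        lines.append(f"## Paired t tests: {attribute}")
        lines.append("")
        lines.append("| track | A | B | mean A | mean B | t | p | sig |")
        lines.append("|---|---|---|---|---|---|---|---|")
        for row in tests.itertuples():
            lines.append(
                f"| {row.track} | {row.level_a} | {row.level_b} | {row.mean_a:.3f} "
                f"| {row.mean_b:.3f} | {row.t:.2f} | {row.p:.2g} | {row.stars} |"
            )
        lines.append("")
    return "\n".join(lines)
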