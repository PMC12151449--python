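"""Recording-level summaries: category distributions and the BIMS score.

A recording's second-by-second one-hot classifications are collapsed, after
carrying-mask filtering, into per-track category distributions and a
posture-conditioned movement distribution over the 27 sensible
posture x movement combinations.  The BIMS motor-maturity score is the
Gaussian-process-regression expectation of age given the 34-dimensional
distribution feature vector (7 posture shares + 27 conditioned shares),
normalized linearly onto [0, 100] over the training age span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel

from .agreement import StatResult, pearson_r
from .errors import ConfigurationError, IntegrityError, ModelError
from .io import FramePredictions, RecordingSummary
from .vocab import MOVEMENTS, POSTURES, default_sensibility

N_FEATURES = 34  # 7 posture + 27 conditioned-distribution entries


def category_distribution(onehot: np.ndarray, mask: np.ndarray) -> np.ndarray | None:
    """Mean of the mask-filtered one-hot matrix along the frame axis.

    Returns None (undefined marker) when no frame is retained.
    """
    onehot = np.asarray(onehot, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if onehot.shape[0] != mask.shape[0]:
        raise IntegrityError("mask length does not match frame count")
    kept = onehot[mask]
    if kept.shape[0] == 0:
        return None
    dist = kept.mean(axis=0)
    total = dist.sum()
    if total <= 0:
        return None
    return dist / total


def conditioned_distribution(
    posture_onehot: np.ndarray,
    movement_onehot: np.ndarray,
    mask: np.ndarray,
    sensibility: np.ndarray | None = None,
) -> np.ndarray | None:
    """Distribution over the sensible posture x movement combinations.

    Each retained frame maps to its (posture, movement) pair; frames whose
    pair is not sensible are dropped and the distribution renormalized over
    the sensible mass.  Output length equals the number of True cells (27
    for the default matrix).  Returns None when no retained frame is
    sensible.
    """
    sens = default_sensibility() if sensibility is None else np.asarray(sensibility, bool)
    posture_onehot = np.asarray(posture_onehot, dtype=float)
    movement_onehot = np.asarray(movement_onehot, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (posture_onehot.shape[0] == movement_onehot.shape[0] == mask.shape[0]):
        raise IntegrityError("frame grids misaligned between tracks")
    keep = mask & (posture_onehot.sum(axis=1) > 0) & (movement_onehot.sum(axis=1) > 0)
    if not np.any(keep):
        return None
    p = np.argmax(posture_onehot[keep], axis=1)
    m = np.argmax(movement_onehot[keep], axis=1)
    joint = np.zeros(sens.shape, dtype=float)
    np.add.at(joint, (p, m), 1.0)
    sensible_counts = joint[sens]
    total = sensible_counts.sum()
    if total <= 0:
        return None
    return sensible_counts / total


def summarize_recording(
    recording_id: str,
    posture_pred: FramePredictions,
    movement_pred: FramePredictions,
    carrying_mask: np.ndarray | None = None,
    sensibility: np.ndarray | None = None,
    age_months: float | None = None,
) -> RecordingSummary | None:
    """Build a RecordingSummary from per-track one-hot predictions.

    The retained-frame mask is the AND of both tracks' validity masks and
    the carrying mask.  Returns None when any distribution is undefined.
    """
    mask = posture_pred.valid_mask & movement_pred.valid_mask
    if carrying_mask is not None:
        mask = mask & np.asarray(carrying_mask, dtype=bool)
    p_dist = category_distribution(posture_pred.onehot, mask)
    m_dist = category_distribution(movement_pred.onehot, mask)
    c_dist = conditioned_distribution(
        posture_pred.onehot, movement_pred.onehot, mask, sensibility
    )
    if p_dist is None or m_dist is None or c_dist is None:
        return None
    return RecordingSummary(
        recording_id=recording_id,
        posture_dist=p_dist,
        movement_dist=m_dist,
        conditioned_dist=c_dist,
        age_months=age_months,
    )


def distribution_correlations(
    summaries_pred: list[RecordingSummary],
    summaries_ref: list[RecordingSummary],
    track: str = "posture",
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict[str, StatResult | None]:
    """Per-category Pearson r between predicted and reference shares.

    The per-recording share of each category is concatenated across
    recordings for both variants and correlated; categories with zero
    variance in either variant get None (undefined marker).
    """
    if len(summaries_pred) != len(summaries_ref):
        raise IntegrityError("prediction and reference summaries cover different recordings")
    attr = {"posture": "posture_dist", "movement": "movement_dist"}[track]
    vocab = POSTURES if track == "posture" else MOVEMENTS
    pred = np.array([getattr(s, attr) for s in summaries_pred])
    ref = np.array([getattr(s, attr) for s in summaries_ref])
    out: dict[str, StatResult | None] = {}
    for j, cat in enumerate(vocab):
        if pred[:, j].std() == 0 or ref[:, j].std() == 0:
            out[cat] = None
            continue
        out[cat] = pearson_r(ref[:, j], pred[:, j], n_iter=n_iter, rng=rng)
    return out


# ---------------------------------------------------------------------------
# BIMS


@dataclass
class BimsModel:
    """GP regressor from distribution features to age, normalized to [0, 100]."""

    gp: GaussianProcessRegressor
    age_lo: float
    age_hi: float

    def normalize(self, age_months: np.ndarray) -> np.ndarray:
        span = self.age_hi - self.age_lo
        return np.clip((np.asarray(age_months) - self.age_lo) / span * 100.0, 0.0, 100.0)

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.atleast_2d(np.asarray(features, dtype=float))
        if features.shape[1] != N_FEATURES:
            raise ConfigurationError(
                f"BIMS features must have length {N_FEATURES}, got {features.shape[1]}"
            )
        age = self.gp.predict(features)
        return self.normalize(age)


def fit_bims(features: np.ndarray, ages_months: np.ndarray) -> BimsModel:
    """Fit the BIMS Gaussian-process regressor on reference distributions.

    Kernel: constant * RBF + white noise, hyperparameters by marginal
    likelihood.  Requires >= 10 recordings spanning >= 6 months of age.
    """
    features = np.asarray(features, dtype=float)
    ages = np.asarray(ages_months, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ConfigurationError(f"features must be (n, {N_FEATURES})")
    if features.shape[0] < 10:
        raise ModelError("BIMS fit requires at least 10 recordings")
    if ages.max() - ages.min() < 6.0:
        raise ModelError("BIMS fit requires >= 6 months of age span")
    if np.allclose(features.std(axis=0), 0):
        raise ModelError("degenerate features: zero variance")
    # Length-scale and noise floors keep the marginal-likelihood optimum away
    # from the interpolation collapse (tiny length scale + tiny noise) that
    # otherwise makes held-out predictions revert to the prior mean.
    kernel = ConstantKernel(1.0, (1e-3, 1e3)) * RBF(
        length_scale=1.0, length_scale_bounds=(0.2, 1e2)
    ) + WhiteKernel(noise_level=1.0, noise_level_bounds=(0.5, 1e2))
    gp = GaussianProcessRegressor(
        kernel=kernel, normalize_y=True, n_restarts_optimizer=3, random_state=0
    )
    gp.fit(features, ages)
    return BimsModel(gp=gp, age_lo=float(ages.min()), age_hi=float(ages.max()))


def predict_bims(model: BimsModel, features: np.ndarray) -> np.ndarray:
    """BIMS scores in [0, 100] for one or more feature vectors."""
    return model.predict(features)


def delta_bims(bims_ref: np.ndarray, bims_pred: np.ndarray) -> np.ndarray:
    """Reference minus predicted BIMS (positive = prediction too low)."""
    return np.asarray(bims_ref, dtype=float) - np.asarray(bims_pred, dtype=float)


def crossvalidated_bims(
    features: np.ndarray,
    ages_months: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    predict_features: np.ndarray | None = None,
) -> np.ndarray:
    """Recording-level cross-validated BIMS.

    The GP is always fitted on the (annotation-derived) reference
    ``features``; each recording is scored by a model not trained on it.
    When ``predict_features`` is given (classifier-derived distributions),
    the held-out recordings are scored from those instead, yielding
    BIMS_pred; otherwise the reference features themselves are scored,
    yielding BIMS_ref.  The normalization span is taken from the full age
    range so scores are comparable across folds.
    """
    features = np.asarray(features, dtype=float)
    ages = np.asarray(ages_months, dtype=float)
    eval_features = features if predict_features is None else np.asarray(predict_features, float)
    if eval_features.shape != features.shape:
        raise ConfigurationError("predict_features must match the reference feature shape")
    n = features.shape[0]
    folds = min(folds, n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = np.empty(n, dtype=int)
    for pos, rec in enumerate(order):
        assignment[rec] = pos % folds
    out = np.empty(n)
    lo, hi = float(ages.min()), float(ages.max())
    for fold in range(folds):
        test = assignment == fold
        model = fit_bims(features[~test], ages[~test])
        model.age_lo, model.age_hi = lo, hi
        out[test] = model.predict(eval_features[test])
    return out
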