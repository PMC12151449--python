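"""Frame-level agreement metrics and the study's statistical tests.

Performance is computed from a compound confusion matrix: every individual
human annotation is compared with the classifier output (or, for
inter-rater agreement, annotators are compared with each other in all
pair combinations), and the per-recording matrices are summed before the
chance-corrected agreement (Cohen kappa) is taken.  Confidence intervals
come from recording-level percentile bootstrap; configuration contrasts use
two-tailed paired t tests with a Kolmogorov-Smirnov Gaussianity pre-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from .errors import IntegrityError

# Both significance legends printed in the study; the figure legend is the
# default, the methods-section variant is available by name.
SIGNIFICANCE_LEGENDS = {
    "figure": (0.05, 0.005, 0.001),
    "methods": (0.05, 0.001, 0.0001),
}


@dataclass
class StatResult:
    """A statistic with p-value, 95 % CI, significance tier and sample size."""

    statistic: float
    p_value: float | None
    n: int
    ci_lo: float | None = None
    ci_hi: float | None = None
    stars: str = ""
    gaussian_ok: bool | None = None

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.statistic)


def significance_stars(p: float | None, legend: str = "figure") -> str:
    if p is None or not np.isfinite(p):
        return ""
    t1, t2, t3 = SIGNIFICANCE_LEGENDS[legend]
    if p < t3:
        return "***"
    if p < t2:
        return "**"
    if p < t1:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# Confusion matrices and kappa


def confusion_from_labels(a: np.ndarray, b: np.ndarray, n_cats: int) -> np.ndarray:
    """K x K confusion counts over frames where both labelings are >= 0."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise IntegrityError(f"frame grids misaligned: {a.shape} vs {b.shape}")
    ok = (a >= 0) & (b >= 0)
    return np.bincount(
        a[ok].astype(np.int64) * n_cats + b[ok].astype(np.int64), minlength=n_cats * n_cats
    ).reshape(n_cats, n_cats)


def compound_confusion(
    predictions: Sequence[np.ndarray],
    annotator_labels: Sequence[np.ndarray],
    n_cats: int,
) -> np.ndarray:
    """Sum classifier-vs-annotator confusion over recordings and annotators.

    ``predictions[i]`` is the (F_i,) predicted label vector of recording i
    (-1 on masked frames); ``annotator_labels[i]`` is the matching
    (F_i, n_annotators) matrix.  One comparison per (frame, annotator) pair.
    """
    if len(predictions) != len(annotator_labels):
        raise IntegrityError("predictions and annotations cover different recordings")
    total = np.zeros((n_cats, n_cats), dtype=np.int64)
    for pred, ann in zip(predictions, annotator_labels):
        ann = np.atleast_2d(np.asarray(ann).T).T
        if pred.shape[0] != ann.shape[0]:
            raise IntegrityError("frame grids misaligned between predictions and annotations")
        for j in range(ann.shape[1]):
            total += confusion_from_labels(pred, ann[:, j], n_cats)
    return total


def interrater_confusion(annotator_labels: Sequence[np.ndarray], n_cats: int) -> np.ndarray:
    """Sum annotator-vs-annotator confusion over all pair combinations."""
    total = np.zeros((n_cats, n_cats), dtype=np.int64)
    for ann in annotator_labels:
        ann = np.asarray(ann)
        for j, k in combinations(range(ann.shape[1]), 2):
            total += confusion_from_labels(ann[:, j], ann[:, k], n_cats)
    return total


def cohen_kappa(cm: np.ndarray) -> float:
    """Multiclass Cohen kappa from a confusion matrix.

    Observed agreement versus the chance agreement implied by the marginals.
    Returns NaN (undefined) when the marginals are degenerate (all mass in a
    single row-and-column cell, so chance agreement is 1).
    """
    cm = np.asarray(cm, dtype=float)
    total = cm.sum()
    if total <= 0:
        raise IntegrityError("empty confusion matrix")
    po = np.trace(cm) / total
    pe = float(np.dot(cm.sum(axis=1), cm.sum(axis=0))) / total**2
    if pe >= 1.0 - 1e-15:
        return float("nan")
    return (po - pe) / (1.0 - pe)


def binary_kappa(tp: float, fp: float, fn: float, tn: float) -> float:
    """The printed 2x2 closed form: k = 2(tp tn - fn fp) / ((tp+fp)(fp+tn) + (tp+fn)(fn+tn))."""
    denom = (tp + fp) * (fp + tn) + (tp + fn) * (fn + tn)
    if denom == 0:
        return float("nan")
    return 2.0 * (tp * tn - fn * fp) / denom


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_ci(
    items: Sequence,
    statistic: Callable | None = None,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    ci: float = 95.0,
) -> tuple[float, float]:
    """Recording-level percentile bootstrap CI of a compound statistic.

    ``items`` holds one entry per recording (scalar, array, or confusion
    matrix); ``statistic`` maps a resampled list of entries to a scalar and
    defaults to the mean of scalar entries.  Compound statistics are
    recomputed on each resample.
    """
    n = len(items)
    if n < 2:
        raise IntegrityError("bootstrap requires at least 2 recordings")
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} is very low for a bootstrap CI")
    rng = np.random.default_rng() if rng is None else rng
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2
    idx = rng.integers(0, n, size=(n_iter, n))
    arr = np.asarray(items, dtype=float) if statistic is None else None
    if arr is not None and arr.ndim == 1:
        # vectorized mean bootstrap for plain per-recording scalars
        samples = arr[idx].mean(axis=1)
    else:
        stat = statistic if statistic is not None else (lambda xs: float(np.mean(xs)))
        samples = np.array([stat([items[i] for i in row]) for row in idx])
    return float(np.percentile(samples, lo_q)), float(np.percentile(samples, hi_q))


# ---------------------------------------------------------------------------
# Paired t and Pearson r


def paired_t(x: Sequence[float], y: Sequence[float], legend: str = "figure") -> StatResult:
    """Two-tailed paired t test for equal performance of two matched systems.

    Gaussianity of the differences is pre-checked with a one-sample
    Kolmogorov-Smirnov test on the mean/std-standardized differences
    (``gaussian_ok``); a failed pre-check flags the result but the test is
    still reported.  All-zero differences yield an undefined marker.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise IntegrityError("paired_t needs two equal-length vectors of length >= 3")
    d = x - y
    n = d.size
    if np.all(d == 0):
        return StatResult(float("nan"), None, n, gaussian_ok=None)
    sd = d.std(ddof=1)
    gaussian_ok = None
    if sd > 0:
        ks = stats.kstest((d - d.mean()) / sd, "norm")
        gaussian_ok = bool(ks.pvalue > 0.05)
    t_res = stats.ttest_rel(x, y)
    se = sd / np.sqrt(n)
    half = stats.t.ppf(0.975, n - 1) * se
    return StatResult(
        statistic=float(t_res.statistic),
        p_value=float(t_res.pvalue),
        n=n,
        ci_lo=float(d.mean() - half),
        ci_hi=float(d.mean() + half),
        stars=significance_stars(float(t_res.pvalue), legend),
        gaussian_ok=gaussian_ok,
    )


def pearson_r(
    a: Sequence[float],
    b: Sequence[float],
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
    legend: str = "figure",
) -> StatResult:
    """Pearson correlation with a recording-level bootstrap 95 % CI."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise IntegrityError("pearson_r needs two equal-length vectors of length >= 3")
    if a.std() == 0 or b.std() == 0:
        return StatResult(float("nan"), None, a.size)
    res = stats.pearsonr(a, b)

    def _stat(items):
        xs = np.array([p[0] for p in items])
        ys = np.array([p[1] for p in items])
        if xs.std() == 0 or ys.std() == 0:
            return float("nan")
        return float(np.corrcoef(xs, ys)[0, 1])

    pairs = list(zip(a, b))
    rng = np.random.default_rng() if rng is None else rng
    idx = rng.integers(0, len(pairs), size=(n_iter, len(pairs)))
    samples = np.array([_stat([pairs[i] for i in row]) for row in idx])
    samples = samples[np.isfinite(samples)]
    lo, hi = (np.percentile(samples, 2.5), np.percentile(samples, 97.5)) if samples.size else (None, None)
    return StatResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n=a.size,
        ci_lo=None if lo is None else float(lo),
        ci_hi=None if hi is None else float(hi),
        stars=significance_stars(float(res.pvalue), legend),
    )
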