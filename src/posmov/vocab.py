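"""Closed category vocabularies for the posture / movement / auxiliary tracks.

The annotation scheme describes infant gross motor behavior on three parallel
tracks: a 7-category posture track (body configuration), a 9-category
movement track (ongoing motor activity) and an auxiliary track marking
segments where independent movement cannot be assessed (infant carried or
out of camera view).  The vocabularies are closed: unknown labels are errors.
"""

from __future__ import annotations

import numpy as np

POSTURES: tuple[str, ...] = (
    "prone",
    "supine",
    "side_left",
    "side_right",
    "crawl",
    "sitting",
    "standing",
)

MOVEMENTS: tuple[str, ...] = (
    "still",
    "proto",
    "elementary",
    "fluent",
    "transition",
    "roll_left",
    "roll_right",
    "pivot_left",
    "pivot_right",
)

AUXILIARY: tuple[str, ...] = ("carried", "out_of_camera")

TRACKS: tuple[str, ...] = ("posture", "movement", "auxiliary")

TRACK_VOCAB: dict[str, tuple[str, ...]] = {
    "posture": POSTURES,
    "movement": MOVEMENTS,
    "auxiliary": AUXILIARY,
}

POSTURE_INDEX = {c: i for i, c in enumerate(POSTURES)}
MOVEMENT_INDEX = {c: i for i, c in enumerate(MOVEMENTS)}

# Which posture x movement combinations are physically sensible.  Exactly 27
# pairs are marked: rolls only from lying postures, pivots only in prone,
# fluent locomotion only in crawl/sitting/standing, "still" everywhere, and
# proto/elementary/transition over the floor-based repertoire.  Downstream
# code treats this as a default that callers may override.
_SENSIBLE_PAIRS: tuple[tuple[str, str], ...] = tuple(
    [(p, "still") for p in POSTURES]
    + [(p, "fluent") for p in ("crawl", "sitting", "standing")]
    + [("prone", "pivot_left"), ("prone", "pivot_right")]
    + [
        (p, r)
        for p in ("prone", "supine", "side_left", "side_right")
        for r in ("roll_left", "roll_right")
    ]
    + [(p, "transition") for p in ("prone", "supine", "crawl", "sitting")]
    + [(p, "proto") for p in ("prone", "supine")]
    + [("prone", "elementary")]
)


def default_sensibility() -> np.ndarray:
    """Return the default 7x9 boolean sensibility matrix (27 True cells)."""
    mat = np.zeros((len(POSTURES), len(MOVEMENTS)), dtype=bool)
    for p, m in _SENSIBLE_PAIRS:
        mat[POSTURE_INDEX[p], MOVEMENT_INDEX[m]] = True
    return mat


def sensible_pairs(sensibility: np.ndarray | None = None) -> list[tuple[str, str]]:
    """List (posture, movement) names of the True cells, row-major order."""
    mat = default_sensibility() if sensibility is None else np.asarray(sensibility, bool)
    if mat.shape != (len(POSTURES), len(MOVEMENTS)):
        raise ValueError(f"sensibility matrix must be {len(POSTURES)}x{len(MOVEMENTS)}")
    return [
        (POSTURES[i], MOVEMENTS[j])
        for i in range(mat.shape[0])
        for j in range(mat.shape[1])
        if mat[i, j]
    ]
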