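"""Movement scoring, occupancy classification and death calling.

The vitality logic is the heart of the platform.  Object centroids in
adjacent frames of the same arena are matched greedily by distance; a
matched object counts as moving when its (frameshift-compensated) centroid
displacement strictly exceeds the movement threshold (7 px by default —
about 55 um at 3200 dpi), and any appearance or disappearance also counts
as movement, since a worm crossing pillar shadows can fragment or merge.

Because a physical disturbance of the chip translates every arena at once
(a global frameshift), displacement vectors are pooled across the array for
each frame pair: when most populated arenas agree on a common translation,
that median vector is subtracted before thresholding.

Death is called from the per-arena series of moving counts: the death time
is the last timepoint with observed movement before the first quiescent run
spanning at least ``quiescent_h`` hours (4 by default).  Movement appearing
after such a run resets the call only when confirmed over at least
``confirm_m`` consecutive frames; an isolated blip is treated as spurious
(detector noise, drifting debris), which is the multiple-observation guard
that prevents false late death calls.  Animals still moving at the end of
the recording are censored.  The scan is implemented backward from the
final frame — when the experiment ends every resident animal should be
still — and is provably equivalent to the forward definition above.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .detect import WormObject

__all__ = [
    "MatchResult",
    "ArenaTimeline",
    "DeathCall",
    "OccupancyClass",
    "match_objects",
    "compensate_global_shift",
    "moving_count",
    "movement_table",
    "classify_occupancy",
    "call_death",
    "compute_yield",
    "occupancy_breakdown",
]

MOVE_THRESHOLD_PX = 7.0
QUIESCENT_H = 4.0
CONFIRM_M = 2
OCCUPANCY_WINDOW_H = 10.0


@dataclass
class MatchResult:
    """Greedy nearest-centroid matching of one adjacent frame pair."""

    pairs: list[tuple[int, int]]  # (index in prev, index in curr)
    vectors: np.ndarray  # (n_pairs, 2) displacement vectors (row, col)
    disappeared: list[int]  # prev indices with no partner
    appeared: list[int]  # curr indices with no partner
    n_prev: int
    n_curr: int

    @property
    def displacements(self) -> np.ndarray:
        if len(self.vectors) == 0:
            return np.zeros(0)
        return np.linalg.norm(self.vectors, axis=1)


def match_objects(prev: list[WormObject], curr: list[WormObject]) -> MatchResult:
    """Match objects across adjacent frames by smallest centroid distance.

    Greedy: the globally closest unmatched pair is taken first, each object
    used at most once.  Unmatched leftovers are reported as disappearances
    (prev only) and appearances (curr only).
    """
    n_p, n_c = len(prev), len(curr)
    if n_p and n_c:
        pc = np.array([o.centroid for o in prev], dtype=float)
        cc = np.array([o.centroid for o in curr], dtype=float)
        d = np.linalg.norm(pc[:, None, :] - cc[None, :, :], axis=2)
        order = np.dstack(np.unravel_index(np.argsort(d, axis=None), d.shape))[0]
        used_p: set[int] = set()
        used_c: set[int] = set()
        pairs = []
        for i, j in order:
            if i in used_p or j in used_c:
                continue
            used_p.add(int(i))
            used_c.add(int(j))
            pairs.append((int(i), int(j)))
            if len(pairs) == min(n_p, n_c):
                break
        vectors = np.array([np.subtract(curr[j].centroid, prev[i].centroid) for i, j in pairs])
    else:
        pairs, vectors, used_p, used_c = [], np.zeros((0, 2)), set(), set()
    return MatchResult(
        pairs=pairs,
        vectors=vectors,
        disappeared=[i for i in range(n_p) if i not in used_p],
        appeared=[j for j in range(n_c) if j not in used_c],
        n_prev=n_p,
        n_curr=n_c,
    )


def compensate_global_shift(
    matches: list[MatchResult],
    agree_frac: float = 0.5,
    min_shift: float = 3.0,
) -> tuple[list[MatchResult], bool, np.ndarray]:
    """Detect and remove a whole-array translation from one frame pair.

    ``matches`` holds every arena's :class:`MatchResult` for the same frame
    pair.  The pooled median of all matched displacement vectors estimates
    the candidate shift (objects that are genuinely still — dead animals,
    debris — sit exactly on it, while live movement scatters isotropically
    and medians out).  If that median's magnitude is at least ``min_shift``
    px and more than ``agree_frac`` of the arenas with matched objects have
    a displacement within ``min_shift`` px of it — an arena with any static
    object is direct evidence of the shift — the median vector is
    subtracted from every matched displacement and the pair is flagged as a
    global frameshift.  Fewer than 3 populated arenas: no compensation (no
    quorum).
    """
    populated = [m for m in matches if len(m.pairs) > 0]
    if len(populated) < 3:
        return matches, False, np.zeros(2)
    all_vecs = np.concatenate([m.vectors for m in populated])
    median_vec = np.median(all_vecs, axis=0)
    if np.linalg.norm(median_vec) < min_shift:
        return matches, False, np.zeros(2)
    agree = np.array(
        [
            np.linalg.norm(m.vectors - median_vec, axis=1).min() < min_shift
            for m in populated
        ]
    )
    if agree.mean() <= agree_frac:
        return matches, False, np.zeros(2)
    corrected = []
    for m in matches:
        vectors = m.vectors - median_vec if len(m.vectors) else m.vectors
        corrected.append(
            MatchResult(m.pairs, vectors, m.disappeared, m.appeared, m.n_prev, m.n_curr)
        )
    return corrected, True, median_vec


def moving_count(match: MatchResult, move_threshold: float = MOVE_THRESHOLD_PX) -> int:
    """Number of moving worms seen across one frame pair.

    A matched object moves when its displacement is strictly greater than
    the threshold; every appearance or disappearance counts as one moving
    worm (topology change implies motion).  Capped at the larger object
    count of the pair.
    """
    n = int(np.sum(match.displacements > move_threshold))
    n += len(match.appeared) + len(match.disappeared)
    return min(n, max(match.n_prev, match.n_curr))


@dataclass
class ArenaTimeline:
    """Per-arena object timeline with per-frame-pair movement calls.

    ``counts[i]`` is the moving-worm count for the frame pair ending at
    ``times[i + 1]``; ``excluded_frames`` marks timepoints removed by QC or
    user exclusion windows.
    """

    arena: int
    times: np.ndarray
    objects: list[list[WormObject]]
    counts: np.ndarray  # length len(times) - 1
    excluded_frames: np.ndarray = field(default=None)  # bool, per frame

    def __post_init__(self) -> None:
        if self.excluded_frames is None:
            self.excluded_frames = np.zeros(len(self.times), dtype=bool)


def movement_table(
    objects_per_arena: list[list[list[WormObject]]],
    times: np.ndarray,
    move_threshold: float = MOVE_THRESHOLD_PX,
    compensate: bool = True,
    agree_frac: float = 0.5,
    min_shift: float = 3.0,
) -> tuple[list[ArenaTimeline], np.ndarray]:
    """Score movement for every arena and frame pair of one array.

    ``objects_per_arena[a][f]`` is the object list of arena ``a`` at frame
    ``f``.  Returns one :class:`ArenaTimeline` per arena plus a boolean
    per-frame-pair flag of detected global frameshifts.  Per-arena results
    are independent of arena order (matching is per arena; compensation uses
    an order-free pooled median).
    """
    n_arenas = len(objects_per_arena)
    n_frames = len(times)
    counts = np.zeros((n_arenas, n_frames - 1), dtype=int)
    shift_flags = np.zeros(n_frames - 1, dtype=bool)
    for f in range(n_frames - 1):
        matches = [
            match_objects(objects_per_arena[a][f], objects_per_arena[a][f + 1])
            for a in range(n_arenas)
        ]
        if compensate:
            matches, flagged, _ = compensate_global_shift(
                matches, agree_frac=agree_frac, min_shift=min_shift
            )
            shift_flags[f] = flagged
        for a in range(n_arenas):
            counts[a, f] = moving_count(matches[a], move_threshold)
    timelines = [
        ArenaTimeline(
            arena=a,
            times=np.asarray(times, dtype=float),
            objects=objects_per_arena[a],
            counts=counts[a],
        )
        for a in range(n_arenas)
    ]
    return timelines, shift_flags


@dataclass
class OccupancyClass:
    """Resident object count class over the initial assessment window."""

    label: str  # "0", "1", "2", "3" or "4+"
    window_h: float
    excluded: bool  # True for 4+ (bubbles/debris)


def classify_occupancy(
    object_counts: np.ndarray,
    times: np.ndarray,
    window_h: float = OCCUPANCY_WINDOW_H,
) -> OccupancyClass:
    """Modal detected-object count over the first ``window_h`` hours.

    Ties break toward the larger count (a transiently merged pair should not
    demote a double).  Four or more objects mark the arena as bubbles or
    debris and exclude it from analysis.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(object_counts)
    in_window = times <= times[0] + window_h
    if times[-1] - times[0] < window_h:
        warnings.warn(
            f"assessment window {window_h} h longer than series; using all frames",
            stacklevel=2,
        )
        in_window[:] = True
    window_counts = [min(int(c), 4) for c in counts[in_window]]
    tally = Counter(window_counts)
    best = max(tally.items(), key=lambda kv: (kv[1], kv[0]))[0]
    if best >= 4:
        return OccupancyClass("4+", window_h, excluded=True)
    return OccupancyClass(str(best), window_h, excluded=False)


@dataclass
class DeathCall:
    """Per-arena outcome of the vitality analysis."""

    arena: int
    status: str  # "dead" | "censored" | "excluded" | "empty"
    time_h: float | None = None  # death time (dead) or censor time (censored)
    occupancy: str = "1"
    multi_occupancy: bool = False
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.status in ("dead", "censored") and self.time_h is None:
            raise ValueError(f"status {self.status!r} requires a time")
        if self.status in ("excluded", "empty") and self.time_h is not None:
            raise ValueError(f"status {self.status!r} must not carry a time")


def _runs(values: np.ndarray) -> list[tuple[bool, int, int]]:
    """Maximal runs of a boolean series as (value, start, stop) half-open."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((bool(values[start]), start, i))
            start = i
    return runs


def call_death(
    times: np.ndarray,
    counts: np.ndarray,
    quiescent_h: float = QUIESCENT_H,
    confirm_m: int = CONFIRM_M,
    arena: int = 0,
    occupancy: OccupancyClass | None = None,
) -> DeathCall:
    """Translate a moving-count series into a death call.

    Death time = last timepoint with movement before the first quiescent run
    of at least ``quiescent_h`` hours; movement after a qualifying run resets
    the call only when sustained over >= ``confirm_m`` consecutive frames.
    No qualifying run surviving to the end of the series means the animal is
    censored at the last timepoint.  ``quiescent_h`` is converted to frames
    with the series' actual sampling interval (ceil), so sub-hourly series
    work.

    Implemented as a single backward pass from the final frame: locate the
    last confirmed movement run, then the first qualifying quiet run after
    it; the death anchor is the last movement before that quiet run.  This
    is equivalent to the forward scan-and-reset definition (the property
    suite checks the equivalence against a brute-force forward oracle).
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(counts)
    if len(times) != len(counts):
        raise ValueError("times and counts must have equal length")
    if occupancy is not None and occupancy.excluded:
        return DeathCall(arena, "excluded", occupancy=occupancy.label)
    if occupancy is not None and occupancy.label == "0":
        return DeathCall(arena, "empty", occupancy="0")
    if len(times) == 0:
        return DeathCall(arena, "empty", occupancy="0")
    if confirm_m < 1:
        raise ValueError("confirm_m must be >= 1")

    dt = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    if times[-1] - times[0] < quiescent_h:
        warnings.warn(
            f"series span {times[-1] - times[0]:.1f} h shorter than the "
            f"{quiescent_h} h quiescence rule; censoring",
            stacklevel=2,
        )
        return _finish(arena, None, times, occupancy)
    needed = max(1, math.ceil(quiescent_h / dt))

    moving = counts > 0
    runs = _runs(moving)

    # Backward pass: last confirmed movement run, if any.
    last_confirmed_stop = 0
    for value, start, stop in reversed(runs):
        if value and (stop - start) >= confirm_m:
            last_confirmed_stop = stop
            break
    # First qualifying quiet run at/after the last confirmed movement.
    quiet = next(
        (
            (start, stop)
            for value, start, stop in runs
            if not value and (stop - start) >= needed and start >= last_confirmed_stop
        ),
        None,
    )
    if quiet is None:
        return _finish(arena, None, times, occupancy)
    # Death anchor: last movement strictly before the quiet run.
    before = np.nonzero(moving[: quiet[0]])[0]
    anchor_time = float(times[before[-1]]) if len(before) else float(times[0])
    return _finish(arena, anchor_time, times, occupancy)


def _finish(
    arena: int,
    death_time: float | None,
    times: np.ndarray,
    occupancy: OccupancyClass | None,
) -> DeathCall:
    occ_label = occupancy.label if occupancy is not None else "1"
    multi = occ_label in ("2", "3")
    if death_time is None:
        return DeathCall(
            arena, "censored", time_h=float(times[-1]), occupancy=occ_label,
            multi_occupancy=multi,
        )
    return DeathCall(
        arena, "dead", time_h=death_time, occupancy=occ_label, multi_occupancy=multi
    )


def compute_yield(calls: list[DeathCall], total_capacity: int) -> float:
    """Fraction of arena capacity producing a usable endpoint.

    Usable = a death call or a censored-alive call; excluded (4+ objects)
    and empty arenas do not count.  ``total_capacity`` is arenas per array
    (50) times the number of arrays.
    """
    if total_capacity <= 0:
        raise ValueError("total_capacity must be positive")
    scored = sum(1 for c in calls if c.status in ("dead", "censored"))
    return scored / total_capacity


def occupancy_breakdown(labels: list[str]) -> dict[str, float]:
    """Percent of arenas per occupancy class, to one decimal."""
    if not labels:
        return {}
    tally = Counter(labels)
    return {k: round(100.0 * v / len(labels), 1) for k, v in sorted(tally.items())}
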