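"""Arena-grid segmentation of aligned frames.

A chip array holds a fixed rectangular grid of arenas (50 by default, two
columns of 25).  The user supplies the array's bounding rectangle on the
aligned frame plus the layout; each arena is a rectangle in half-open pixel
intervals, so the regions tile the bounds exactly with no overlap.  Arenas
(or arena time-windows) can be excluded from analysis, e.g. when a channel
clogs; an automatic QC flag catches arena-frames whose mean intensity jumps
far from that arena's typical value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "ArenaRegion", "build_grid", "crop_arena", "auto_qc_mask"]


@dataclass
class ArenaRegion:
    """One arena's rectangle: half-open pixel intervals [r0, r1) x [c0, c1)."""

    index: int
    r0: int
    r1: int
    c0: int
    c1: int
    excluded: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return (self.r1 - self.r0, self.c1 - self.c0)


@dataclass
class GridSpec:
    """Grid of arenas over an aligned frame.

    ``bounds`` is (r0, c0, r1, c1) half-open; ``rows * cols`` arenas are laid
    out row-major from the top-left.  ``excluded`` lists arena indices the
    user dropped; ``time_exclusions`` are (arena, t_start_h, t_end_h)
    windows masked before vitality analysis.
    """

    bounds: tuple[int, int, int, int]
    rows: int
    cols: int
    excluded: tuple[int, ...] = ()
    time_exclusions: tuple[tuple[int, float, float], ...] = ()

    def __post_init__(self) -> None:
        r0, c0, r1, c1 = self.bounds
        if r1 <= r0 or c1 <= c0:
            raise ValueError("grid bounds rectangle is empty")
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("rows and cols must be positive")
        n = self.n_arenas
        for idx in self.excluded:
            if not 0 <= idx < n:
                raise ValueError(f"excluded arena index {idx} out of range 0..{n - 1}")
        for idx, t0, t1 in self.time_exclusions:
            if not 0 <= idx < n:
                raise ValueError(f"time-exclusion arena index {idx} out of range")
            if t1 <= t0:
                raise ValueError(f"empty time-exclusion window ({t0}, {t1})")

    @property
    def n_arenas(self) -> int:
        return self.rows * self.cols


def _edges(start: int, stop: int, n: int) -> list[int]:
    """Split [start, stop) into n near-equal intervals, widths differing by
    at most 1 px; the remainder goes to the last cells."""
    span = stop - start
    base, rem = divmod(span, n)
    if base == 0:
        raise ValueError(f"cannot split {span} px into {n} arenas")
    widths = [base] * (n - rem) + [base + 1] * rem
    edges = [start]
    for w in widths:
        edges.append(edges[-1] + w)
    return edges


def build_grid(spec: GridSpec) -> list[ArenaRegion]:
    """Tile the bounds into ``rows x cols`` arena rectangles, row-major.

    Pure: the same spec always yields the same regions.  Excluded arenas are
    flagged, not removed, so arena indices stay stable.
    """
    r0, c0, r1, c1 = spec.bounds
    row_edges = _edges(r0, r1, spec.rows)
    col_edges = _edges(c0, c1, spec.cols)
    excluded = set(spec.excluded)
    regions = []
    for i in range(spec.rows):
        for j in range(spec.cols):
            idx = i * spec.cols + j
            regions.append(
                ArenaRegion(
                    index=idx,
                    r0=row_edges[i],
                    r1=row_edges[i + 1],
                    c0=col_edges[j],
                    c1=col_edges[j + 1],
                    excluded=idx in excluded,
                )
            )
    return regions


def crop_arena(frame: np.ndarray, region: ArenaRegion) -> np.ndarray:
    """Extract exactly the region's extent from a frame."""
    h, w = frame.shape[:2]
    if region.r0 < 0 or region.c0 < 0 or region.r1 > h or region.c1 > w:
        raise ValueError(
            f"arena {region.index} region [{region.r0}:{region.r1}, "
            f"{region.c0}:{region.c1}] outside frame {frame.shape}"
        )
    return frame[region.r0 : region.r1, region.c0 : region.c1]


def auto_qc_mask(
    frames: np.ndarray,
    regions: list[ArenaRegion],
    n_sd: float = 5.0,
    min_dev_frac: float = 0.05,
) -> np.ndarray:
    """Flag arena-frames whose mean intensity is anomalous.

    Returns a boolean (n_arenas, n_frames) array, True where the arena-frame
    mean deviates more than ``n_sd`` standard deviations from that arena's
    series median — the signature of a transient acquisition fault (clog,
    bubble sweep, light leak).  The scale is estimated robustly (1.4826x the
    median absolute deviation) so the fault itself cannot mask the flag, and
    the deviation must also exceed ``min_dev_frac`` of the median intensity:
    acquisition faults change brightness grossly, whereas a worm shifting
    posture perturbs the arena mean by well under a percent and must not
    trip QC.  Arenas with an essentially constant series are never flagged.
    """
    n_frames = len(frames)
    flags = np.zeros((len(regions), n_frames), dtype=bool)
    for k, region in enumerate(regions):
        means = np.array(
            [float(crop_arena(frames[i], region).mean()) for i in range(n_frames)]
        )
        med = np.median(means)
        sd = 1.4826 * np.median(np.abs(means - med))
        if sd < 1e-12:
            continue
        dev = np.abs(means - med)
        flags[k] = (dev > n_sd * sd) & (dev > min_dev_frac * max(abs(med), 1.0))
    if flags.any():
        warnings.warn(f"auto-QC flagged {int(flags.sum())} arena-frames", stacklevel=2)
    return flags
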