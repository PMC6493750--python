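"""Synthetic scanner-stack generator with ground truth.

Emulates the observable phenomenology of a flatbed-scanner worm-chip run:
hourly grayscale frames of a 2-column array of arenas, each holding 0-4 dark
elongated worm-like objects.  Live worms displace their centroid between
frames; at a ground-truth death time drawn from a configurable survival
distribution the centroid freezes (rod-like death), optionally followed by a
progressive loss of opacity (the "bagging" phenotype).  Static debris (below
the detection size filter) and bubbles (above it), additive Gaussian noise,
and whole-frame translations (global frameshifts, a physically disturbed
chip) can all be injected.

Default geometry approximates a 3200 dpi scan (~7.9 um/px), so a ~1 mm
adult worm covers ~1000 px and the 300-px detection size filter is
meaningful.  Default occupancy probabilities follow the loading statistics
of a real 50-arena chip run (~39% empty, ~51% single worm, ~9% double,
~1% triple, ~0.3% bubbles/debris counted as 4+ objects).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

from .imaging import FrameSeries

__all__ = [
    "SimConfig",
    "GroundTruth",
    "sample_death_times",
    "render_arena_frame",
    "generate_experiment",
    "write_experiment",
]

logger = logging.getLogger(__name__)

#: occupancy distribution over {0, 1, 2, 3, 4+} resident objects,
#: matching observed chip-loading frequencies
DEFAULT_OCCUPANCY = (0.3879, 0.5055, 0.0924, 0.0116, 0.0026)


@dataclass
class SimConfig:
    """Parameters of a synthetic chip run.

    All lengths are in pixels, times in hours, gray levels in 8-bit units
    with worms darker than the background (transillumination).
    """

    n_arenas: int = 50
    arena_px: tuple[int, int] = (126, 456)  # (height, width); ~1 x 3.6 mm at 3200 dpi
    frames: int = 72
    frame_interval: float = 1.0
    occupancy_probs: tuple[float, ...] = DEFAULT_OCCUPANCY
    survival_dist: tuple = ("exponential", {"mean": 40.0})
    movement_px: tuple[float, float] = (12.0, 2.0)  # live centroid step (mean, sd)
    worm_area_px: int = 1000
    fade_after_death: float = 0.0  # contrast decay rate per hour; 0 = rod-like death
    debris_rate: float = 0.0  # expected static sub-threshold objects per arena
    bubble_rate: float = 0.0  # expected static supra-threshold objects per arena
    global_shift_events: tuple[tuple[int, int, int], ...] = ()  # (frame, drow, dcol)
    noise_sd: float = 4.0
    background_level: float = 200.0
    worm_level: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        probs = np.asarray(self.occupancy_probs, dtype=float)
        if len(probs) != 5 or np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-6:
            raise ValueError("occupancy_probs must be 5 non-negative values summing to 1")
        if self.n_arenas <= 0 or self.frames <= 0 or self.worm_area_px <= 0:
            raise ValueError("counts must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if not self.worm_level < self.background_level:
            raise ValueError("worm_level must be darker than background_level")
        if min(self.arena_px) < 16:
            raise ValueError("arena_px too small to render objects")
        for ev in self.global_shift_events:
            f, dr, dc = ev
            if not (0 <= int(f) < self.frames):
                raise ValueError(f"global shift event frame {f} outside stack")

    def to_dict(self) -> dict:
        return {
            "n_arenas": self.n_arenas,
            "arena_px": list(self.arena_px),
            "frames": self.frames,
            "frame_interval": self.frame_interval,
            "occupancy_probs": list(self.occupancy_probs),
            "survival_dist": [self.survival_dist[0], dict(self.survival_dist[1])],
            "movement_px": list(self.movement_px),
            "worm_area_px": self.worm_area_px,
            "fade_after_death": self.fade_after_death,
            "debris_rate": self.debris_rate,
            "bubble_rate": self.bubble_rate,
            "global_shift_events": [list(e) for e in self.global_shift_events],
            "noise_sd": self.noise_sd,
            "background_level": self.background_level,
            "worm_level": self.worm_level,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        """Build from a plain mapping (e.g. a YAML/JSON section); keys left
        out keep their defaults."""
        d = dict(d)
        for key in ("arena_px", "occupancy_probs", "movement_px"):
            if key in d:
                d[key] = tuple(d[key])
        if "survival_dist" in d:
            name, params = d["survival_dist"]
            d["survival_dist"] = (name, dict(params))
        if "global_shift_events" in d:
            d["global_shift_events"] = tuple(tuple(e) for e in d["global_shift_events"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Per-animal death times, per-arena occupancy and per-frame shifts.

    ``death_times[a]`` lists one entry per animal in arena ``a``: the death
    time in hours, or ``None`` for an animal still alive at the last frame.
    """

    occupancy: list[int]
    death_times: list[list[float | None]]
    frame_shifts: list[tuple[int, int]]  # cumulative (drow, dcol) per frame
    end_time: float

    @property
    def n_animals(self) -> int:
        return sum(self.occupancy)

    def arena_last_death(self, arena: int) -> float | None:
        """Time the last resident animal stops moving, None if any survive
        (or the arena is empty)."""
        deaths = self.death_times[arena]
        if not deaths or any(d is None for d in deaths):
            return None
        return max(deaths)

    def to_dict(self) -> dict:
        return {
            "occupancy": self.occupancy,
            "death_times": self.death_times,
            "frame_shifts": [list(s) for s in self.frame_shifts],
            "end_time": self.end_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            occupancy=list(d["occupancy"]),
            death_times=[list(v) for v in d["death_times"]],
            frame_shifts=[tuple(s) for s in d["frame_shifts"]],
            end_time=float(d["end_time"]),
        )


def sample_death_times(n: int, dist: tuple, seed: int) -> list[float]:
    """Draw ``n`` non-negative death times (hours) from a named distribution.

    ``dist`` is ``(name, params)`` with name one of ``exponential`` (param
    ``mean``), ``weibull`` (``shape``, ``scale``) or ``fixed`` (``times``, a
    list cycled through in order).
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    name, params = dist
    rng = np.random.default_rng(seed)
    if name == "exponential":
        mean = float(params["mean"])
        if mean <= 0:
            raise ValueError("exponential mean must be positive")
        return list(rng.exponential(mean, size=n))
    if name == "weibull":
        shape, scale = float(params["shape"]), float(params["scale"])
        if shape <= 0 or scale <= 0:
            raise ValueError("weibull shape and scale must be positive")
        return list(scale * rng.weibull(shape, size=n))
    if name == "fixed":
        times = [float(t) for t in params["times"]]
        if any(t < 0 for t in times):
            raise ValueError("fixed death times must be non-negative")
        if n and not times:
            raise ValueError("fixed distribution needs at least one time")
        return [times[i % len(times)] for i in range(n)]
    raise ValueError(f"unknown survival distribution {name!r}")


def _worm_mask(area_px: int, rng: np.random.Generator, curl: float = 0.18) -> np.ndarray:
    """Rasterize one worm posture as a thickened random-walk polyline.

    Disks of fixed radius are stamped along a unit-step random walk until the
    painted area reaches the target, so bounding-box dimensions vary with
    posture while area stays within a few percent of ``area_px``.
    """
    # half-width from a ~10:1 length:width aspect
    r = max(2, int(round(math.sqrt(area_px / 10.0) / 2)))
    max_len = int(3 * area_px / (2 * r)) + 8
    size = 2 * max_len + 4 * r + 4
    canvas = np.zeros((size, size), dtype=bool)
    dd, cc = np.ogrid[-r : r + 1, -r : r + 1]
    disk = (dd * dd + cc * cc) <= r * r

    pos = np.array([size / 2, size / 2])
    heading = rng.uniform(0, 2 * math.pi)
    painted = 0
    for _ in range(max_len):
        heading += rng.normal(0.0, curl)
        pos = pos + np.array([math.sin(heading), math.cos(heading)])
        i, j = int(round(pos[0])), int(round(pos[1]))
        view = canvas[i - r : i + r + 1, j - r : j + r + 1]
        view |= disk
        painted = int(canvas.sum())
        if painted >= area_px:
            break
    rows, cols = np.nonzero(canvas)
    return canvas[rows.min() : rows.max() + 1, cols.min() : cols.max() + 1]


def _mask_centroid(mask: np.ndarray) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.array([rows.mean(), cols.mean()])


@dataclass
class _WormState:
    centroid: np.ndarray  # (row, col), float
    mask: np.ndarray
    death_time: float | None  # hours; None = never dies in-window
    anchor: np.ndarray | None = None  # mask pixel centroid, set on mask assignment

    def set_mask(self, mask: np.ndarray) -> None:
        self.mask = mask
        self.anchor = _mask_centroid(mask)


@dataclass
class _ArenaState:
    worms: list[_WormState]
    debris: list[tuple[np.ndarray, np.ndarray]]  # (centroid, mask), static
    bubbles: list[tuple[np.ndarray, np.ndarray]]


def _stamp(
    img: np.ndarray,
    centroid: np.ndarray,
    mask: np.ndarray,
    level: float,
    anchor: np.ndarray | None = None,
) -> None:
    """Paint ``mask`` so its pixel centroid (``anchor`` within the mask)
    lands on ``centroid``, clipped to arena bounds."""
    h, w = img.shape
    mh, mw = mask.shape
    if anchor is None:
        anchor = np.array([mh / 2, mw / 2])
    r0 = int(round(centroid[0] - anchor[0]))
    c0 = int(round(centroid[1] - anchor[1]))
    rs, cs = max(r0, 0), max(c0, 0)
    re, ce = min(r0 + mh, h), min(c0 + mw, w)
    if rs >= re or cs >= ce:
        return
    if r0 < 0 or c0 < 0 or r0 + mh > h or c0 + mw > w:
        logger.warning("object at %s clipped by arena bounds", tuple(centroid))
    sub = mask[rs - r0 : re - r0, cs - c0 : ce - c0]
    region = img[rs:re, cs:ce]
    region[sub] = np.minimum(region[sub], level)


def render_arena_frame(
    state: _ArenaState,
    t: float,
    cfg: SimConfig,
    noise_rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one arena at time ``t`` hours as a float grayscale image.

    Worms past their death time fade toward the background at rate
    ``cfg.fade_after_death`` (contrast times ``exp(-rate * hours_dead)``);
    noise is added last.
    """
    h, w = cfg.arena_px
    img = np.full((h, w), cfg.background_level, dtype=float)
    for centroid, mask in state.debris + state.bubbles:
        _stamp(img, centroid, mask, cfg.worm_level)
    contrast = cfg.background_level - cfg.worm_level
    for worm in state.worms:
        level = cfg.worm_level
        if worm.death_time is not None and t >= worm.death_time and cfg.fade_after_death > 0:
            fade = math.exp(-cfg.fade_after_death * (t - worm.death_time))
            level = cfg.background_level - contrast * fade
        _stamp(img, worm.centroid, worm.mask, level, anchor=worm.anchor)
    if noise_rng is not None and cfg.noise_sd > 0:
        img += noise_rng.normal(0.0, cfg.noise_sd, size=img.shape)
    return img


def _static_blob(
    rng: np.random.Generator, area_range: tuple[int, int], arena_px: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """A static circular blob (debris or bubble) of area within the range."""
    area = rng.integers(*area_range)
    r = max(1, int(round(math.sqrt(area / math.pi))))
    dd, cc = np.ogrid[-r : r + 1, -r : r + 1]
    mask = (dd * dd + cc * cc) <= r * r
    h, w = arena_px
    margin = r + 2
    centroid = np.array(
        [rng.uniform(margin, h - margin), rng.uniform(margin, w - margin)]
    )
    return centroid, mask


def _layout(n_arenas: int, arena_px: tuple[int, int]) -> tuple[tuple[int, int], list[tuple[int, int]]]:
    """2-column array layout; returns frame shape and per-arena origins
    (row-major order, matching downstream arena indexing)."""
    cols = 2 if n_arenas > 1 else 1
    rows = math.ceil(n_arenas / cols)
    ah, aw = arena_px
    origins = [((i // cols) * ah, (i % cols) * aw) for i in range(n_arenas)]
    return (rows * ah, cols * aw), origins


def _translate(frame: np.ndarray, shift: tuple[int, int], fill: float) -> np.ndarray:
    dr, dc = shift
    if dr == 0 and dc == 0:
        return frame
    out = np.full_like(frame, fill)
    h, w = frame.shape
    rs_src = slice(max(0, -dr), min(h, h - dr))
    cs_src = slice(max(0, -dc), min(w, w - dc))
    rs_dst = slice(max(0, dr), min(h, h + dr))
    cs_dst = slice(max(0, dc), min(w, w + dc))
    out[rs_dst, cs_dst] = frame[rs_src, cs_src]
    return out


def generate_experiment(cfg: SimConfig) -> tuple[FrameSeries, GroundTruth]:
    """Simulate a full chip run: a frame stack plus its ground truth.

    Live worms take a centroid step of ``movement_px`` (mean, sd) pixels in a
    uniform random direction each frame and re-sample their posture; from the
    first frame at or past the death time the posture and position freeze, so
    displacement is zero for every frame pair whose earlier frame is at or
    past the death time.  Centroids are reflected off an interior margin so
    worms stay inside their arena.  Fully reproducible for a fixed config.
    """
    ss = np.random.SeedSequence(cfg.seed)
    s_occ, s_death, s_worm, s_noise, s_debris = ss.spawn(5)
    occ_rng = np.random.default_rng(s_occ)
    worm_rng = np.random.default_rng(s_worm)
    noise_rng = np.random.default_rng(s_noise)
    debris_rng = np.random.default_rng(s_debris)

    probs = np.asarray(cfg.occupancy_probs, dtype=float)
    occupancy = list(occ_rng.choice(5, size=cfg.n_arenas, p=probs / probs.sum()))
    occupancy = [int(o) for o in occupancy]

    end_time = (cfg.frames - 1) * cfg.frame_interval
    death_seed = int(np.random.default_rng(s_death).integers(2**31))
    all_deaths = sample_death_times(sum(occupancy), cfg.survival_dist, death_seed)

    ah, aw = cfg.arena_px
    # keep centroids away from arena walls so postures rarely clip
    margin = min(int(round(1.2 * math.sqrt(cfg.worm_area_px))), min(ah, aw) // 3)

    arenas: list[_ArenaState] = []
    death_times: list[list[float | None]] = []
    k = 0
    for a in range(cfg.n_arenas):
        worms: list[_WormState] = []
        arena_deaths: list[float | None] = []
        for _ in range(occupancy[a]):
            d = all_deaths[k]
            k += 1
            death: float | None = float(d) if d <= end_time else None
            arena_deaths.append(None if death is None else round(death, 6))
            centroid = np.array(
                [
                    worm_rng.uniform(margin, ah - margin),
                    worm_rng.uniform(margin, aw - margin),
                ]
            )
            state = _WormState(centroid, None, death)
            state.set_mask(_worm_mask(cfg.worm_area_px, worm_rng))
            worms.append(state)
        n_debris = int(debris_rng.poisson(cfg.debris_rate))
        n_bubbles = int(debris_rng.poisson(cfg.bubble_rate))
        debris = [_static_blob(debris_rng, (40, 200), cfg.arena_px) for _ in range(n_debris)]
        bubbles = [_static_blob(debris_rng, (400, 1200), cfg.arena_px) for _ in range(n_bubbles)]
        arenas.append(_ArenaState(worms, debris, bubbles))
        death_times.append(arena_deaths)

    move_mean, move_sd = cfg.movement_px
    frame_shape, origins = _layout(cfg.n_arenas, cfg.arena_px)
    shift_by_frame: dict[int, np.ndarray] = {}
    for f, dr, dc in cfg.global_shift_events:
        shift_by_frame[int(f)] = shift_by_frame.get(int(f), np.zeros(2, int)) + np.array(
            [int(dr), int(dc)]
        )

    stack = np.empty((cfg.frames,) + frame_shape, dtype=np.uint8)
    frame_shifts: list[tuple[int, int]] = []
    cum_shift = np.zeros(2, dtype=int)
    for fi in range(cfg.frames):
        t = fi * cfg.frame_interval
        if fi > 0:
            t_prev = (fi - 1) * cfg.frame_interval
            for arena in arenas:
                for worm in arena.worms:
                    alive_pair = worm.death_time is None or t_prev < worm.death_time
                    if alive_pair:
                        step = abs(worm_rng.normal(move_mean, move_sd))
                        # resample direction until the step stays inside the
                        # interior, so the step magnitude is always realized
                        for _ in range(30):
                            theta = worm_rng.uniform(0, 2 * math.pi)
                            new = worm.centroid + step * np.array(
                                [math.sin(theta), math.cos(theta)]
                            )
                            if (
                                margin <= new[0] <= ah - margin
                                and margin <= new[1] <= aw - margin
                            ):
                                break
                        else:
                            center = np.array([ah / 2, aw / 2])
                            u = center - worm.centroid
                            u = u / max(np.linalg.norm(u), 1e-9)
                            new = worm.centroid + step * u
                        worm.centroid = new
                        worm.set_mask(_worm_mask(cfg.worm_area_px, worm_rng))
        frame = np.full(frame_shape, cfg.background_level, dtype=float)
        for a, (r0, c0) in enumerate(origins):
            frame[r0 : r0 + ah, c0 : c0 + aw] = render_arena_frame(
                arenas[a], t, cfg, noise_rng=None
            )
        if cfg.noise_sd > 0:
            frame += noise_rng.normal(0.0, cfg.noise_sd, size=frame.shape)
        if fi in shift_by_frame:
            cum_shift = cum_shift + shift_by_frame[fi]
        frame = _translate(frame, tuple(cum_shift), cfg.background_level)
        frame_shifts.append((int(cum_shift[0]), int(cum_shift[1])))
        stack[fi] = np.clip(np.round(frame), 0, 255).astype(np.uint8)

    times = np.arange(cfg.frames) * cfg.frame_interval
    series = FrameSeries(stack, times, source_id=f"synthetic-seed{cfg.seed}")
    truth = GroundTruth(occupancy, death_times, frame_shifts, float(end_time))
    return series, truth


def write_experiment(cfg: SimConfig, out_dir: str | Path) -> tuple[Path, Path]:
    """Generate a run and write ``stack.tif`` plus a JSON sidecar manifest
    holding the config, ground truth and frame times."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    series, truth = generate_experiment(cfg)
    tif_path = out / "stack.tif"
    tifffile.imwrite(tif_path, series.frames)
    manifest = {
        "config": cfg.to_dict(),
        "ground_truth": truth.to_dict(),
        "times_h": [float(t) for t in series.times],
        "layout": {
            "rows": math.ceil(cfg.n_arenas / (2 if cfg.n_arenas > 1 else 1)),
            "cols": 2 if cfg.n_arenas > 1 else 1,
            "frame_shape": list(series.shape),
        },
    }
    man_path = out / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=1))
    return tif_path, man_path
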