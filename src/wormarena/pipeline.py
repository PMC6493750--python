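"""End-to-end orchestration: stack -> alignment -> arenas -> objects ->
movement -> death calls -> survival outputs, with a checksummed manifest.

Every stage writes the documented plain-text files so stages can also be
run (and tested) independently through the CLI.  Numeric formatting is
fixed (hours to 1 decimal, fractions to 3 decimals) so identical runs
produce byte-identical outputs.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .config import RunConfig
from .detect import WormObject, binarize, detect_objects
from .grid import ArenaRegion, GridSpec, auto_qc_mask, build_grid, crop_arena
from .imaging import FrameSeries, apply_transform, estimate_rigid_transform, load_frame_series
from .survival import SurvivalDataset, km_curve, summarize
from .vitality import (
    ArenaTimeline,
    DeathCall,
    OccupancyClass,
    call_death,
    classify_occupancy,
    compute_yield,
    movement_table,
    occupancy_breakdown,
)

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "detect_stack", "analyze_objects"]


@dataclass
class RunManifest:
    """Record of one pipeline run: config, inputs, stage counts, outputs."""

    config: dict
    version: str = __version__
    started: str = ""
    input_checksums: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)  # filename -> sha256
    valid: bool = True

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "version": self.version,
            "started": self.started,
            "input_checksums": self.input_checksums,
            "counts": self.counts,
            "outputs": self.outputs,
            "valid": self.valid,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _load_input(cfg: RunConfig) -> tuple[FrameSeries, dict | None]:
    """Load the frame stack; a synthetic-run manifest supplies times/layout."""
    manifest = None
    if cfg.paths.manifest:
        manifest = json.loads(Path(cfg.paths.manifest).read_text())
        frames = tifffile.imread(cfg.paths.stack)
        if frames.ndim == 2:
            frames = frames[None]
        times = np.asarray(manifest["times_h"], dtype=float)
        series = FrameSeries(frames, times - times[0], source_id=cfg.paths.stack)
    else:
        series = load_frame_series(cfg.paths.stack, sidecar=cfg.paths.sidecar or None)
    return series, manifest


def _read_reference_points(path: Path) -> tuple[np.ndarray, np.ndarray]:
    rows = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or not row[0].strip().replace("-", "").replace(".", "").isdigit():
                continue
            rows.append([float(v) for v in row[:4]])
    arr = np.asarray(rows)
    return arr[:, :2], arr[:, 2:]


def _grid_spec(cfg: RunConfig, series: FrameSeries, manifest: dict | None) -> GridSpec:
    if manifest is not None:
        layout = manifest["layout"]
        rows, cols = int(layout["rows"]), int(layout["cols"])
        bounds = (0, 0, *series.shape)
    else:
        rows, cols = cfg.grid.rows, cfg.grid.cols
        bounds = tuple(cfg.grid.bounds) if cfg.grid.bounds else (0, 0, *series.shape)
    time_excl = []
    if cfg.grid.time_exclusions:
        with open(cfg.grid.time_exclusions, newline="") as fh:
            for row in csv.reader(fh):
                if not row or row[0].strip().lower().startswith("arena"):
                    continue
                time_excl.append((int(row[0]), float(row[1]), float(row[2])))
    return GridSpec(
        bounds=bounds,
        rows=rows,
        cols=cols,
        excluded=tuple(int(i) for i in cfg.grid.excluded),
        time_exclusions=tuple(time_excl),
    )


def detect_stack(
    series: FrameSeries, regions: list[ArenaRegion], cfg: RunConfig
) -> list[list[list[WormObject]]]:
    """Detect objects in every arena of every frame.

    Returns ``objects[arena][frame]``; binarization is per arena per frame
    (per-crop Otsu tolerates the scanner's exposure gradient).
    """
    det = cfg.detection
    out: list[list[list[WormObject]]] = [[] for _ in regions]
    for f in range(len(series)):
        frame = series.frames[f]
        t = float(series.times[f])
        for region in regions:
            crop = crop_arena(frame, region)
            mask = binarize(
                crop,
                method=det.method,
                threshold=det.threshold,
                polarity=det.polarity,
                min_contrast=det.min_contrast,
            )
            out[region.index].append(
                detect_objects(
                    mask,
                    min_area=det.min_area,
                    intensity_image=crop,
                    arena=region.index,
                    time_h=t,
                )
            )
    return out


def _frame_exclusion_masks(
    spec: GridSpec, times: np.ndarray, qc_flags: np.ndarray | None
) -> np.ndarray:
    n_arenas = spec.n_arenas
    masks = np.zeros((n_arenas, len(times)), dtype=bool)
    if qc_flags is not None:
        masks |= qc_flags
    for arena, t0, t1 in spec.time_exclusions:
        masks[arena] |= (times >= t0) & (times <= t1)
    return masks


def analyze_objects(
    objects_per_arena: list[list[list[WormObject]]],
    times: np.ndarray,
    cfg: RunConfig,
    spec: GridSpec,
    qc_flags: np.ndarray | None = None,
) -> tuple[list[ArenaTimeline], np.ndarray, list[DeathCall], list[OccupancyClass]]:
    """Movement scoring, occupancy classing and death calling for one array."""
    vit = cfg.vitality
    timelines, shift_flags = movement_table(
        objects_per_arena,
        times,
        move_threshold=vit.move_threshold,
        compensate=vit.compensate_shifts,
        agree_frac=vit.agree_frac,
        min_shift=vit.min_shift,
    )
    frame_masks = _frame_exclusion_masks(spec, np.asarray(times, dtype=float), qc_flags)
    user_excluded = set(spec.excluded)
    calls: list[DeathCall] = []
    occupancies: list[OccupancyClass] = []
    for tl in timelines:
        n_objects = np.array([len(objs) for objs in tl.objects])
        occ = classify_occupancy(n_objects, tl.times, window_h=vit.occupancy_window_h)
        occupancies.append(occ)
        if tl.arena in user_excluded:
            calls.append(
                DeathCall(tl.arena, "excluded", occupancy=occ.label, flags=("user_excluded",))
            )
            logger.info("arena %d excluded: user exclusion list", tl.arena)
            continue
        if occ.excluded:
            calls.append(
                DeathCall(tl.arena, "excluded", occupancy=occ.label, flags=("occupancy_4plus",))
            )
            logger.info("arena %d excluded: occupancy 4+ (bubbles/debris)", tl.arena)
            continue
        if occ.label == "0":
            calls.append(DeathCall(tl.arena, "empty", occupancy="0"))
            continue
        mask = frame_masks[tl.arena]
        pair_keep = ~(mask[:-1] | mask[1:])
        pair_times = tl.times[1:][pair_keep]
        pair_counts = tl.counts[pair_keep]
        flags = ("qc_frames_dropped",) if not pair_keep.all() else ()
        if not pair_keep.all():
            logger.info(
                "arena %d: %d frame pairs dropped by QC/exclusion windows",
                tl.arena,
                int((~pair_keep).sum()),
            )
        call = call_death(
            pair_times,
            pair_counts,
            quiescent_h=vit.quiescent_h,
            confirm_m=vit.confirm_m,
            arena=tl.arena,
            occupancy=occ,
        )
        call.flags = call.flags + flags
        calls.append(call)
    return timelines, shift_flags, calls, occupancies


def _fmt_h(t: float | None) -> str:
    return "" if t is None else f"{t:.1f}"


def _write_moving_counts(path: Path, timelines: list[ArenaTimeline]) -> None:
    times = timelines[0].times[1:]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["arena"] + [f"{t:.1f}" for t in times])
        for tl in timelines:
            w.writerow([tl.arena] + [int(c) for c in tl.counts])


def _write_death_calls(path: Path, calls: list[DeathCall]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["arena", "status", "time_h", "occupancy", "multi_occupancy", "flags"])
        for c in calls:
            w.writerow(
                [
                    c.arena,
                    c.status,
                    _fmt_h(c.time_h),
                    c.occupancy,
                    int(c.multi_occupancy),
                    ";".join(c.flags),
                ]
            )


def read_death_calls(path: str | Path) -> list[DeathCall]:
    calls = []
    df = pd.read_csv(path, dtype={"occupancy": str}, keep_default_na=False)
    for row in df.itertuples(index=False):
        time_h = float(row.time_h) if str(row.time_h) != "" else None
        calls.append(
            DeathCall(
                arena=int(row.arena),
                status=row.status,
                time_h=time_h,
                occupancy=str(row.occupancy),
                multi_occupancy=bool(int(row.multi_occupancy)),
                flags=tuple(f for f in str(row.flags).split(";") if f),
            )
        )
    return calls


def write_objects(path: Path, objects_per_arena: list[list[list[WormObject]]], times) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["arena", "frame", "time_h", "area", "centroid_r", "centroid_c",
             "bbox_h", "bbox_w", "mean_intensity"]
        )
        for arena_objs in objects_per_arena:
            for f, objs in enumerate(arena_objs):
                for o in objs:
                    w.writerow(
                        [o.arena, f, f"{o.time_h:.1f}", o.area,
                         f"{o.centroid[0]:.3f}", f"{o.centroid[1]:.3f}",
                         o.bbox_height, o.bbox_width, f"{o.mean_intensity:.3f}"]
                    )


def read_objects(path: str | Path, n_arenas: int, times: np.ndarray) -> list[list[list[WormObject]]]:
    out: list[list[list[WormObject]]] = [
        [[] for _ in range(len(times))] for _ in range(n_arenas)
    ]
    df = pd.read_csv(path)
    for row in df.itertuples(index=False):
        out[int(row.arena)][int(row.frame)].append(
            WormObject(
                arena=int(row.arena),
                time_h=float(row.time_h),
                area=int(row.area),
                centroid=(float(row.centroid_r), float(row.centroid_c)),
                bbox_height=int(row.bbox_h),
                bbox_width=int(row.bbox_w),
                mean_intensity=float(row.mean_intensity),
            )
        )
    return out


def _write_survival_outputs(
    out_dir: Path, calls: list[DeathCall], cfg: RunConfig
) -> dict:
    scored = [c for c in calls if c.status in ("dead", "censored")]
    results: dict = {}
    if not scored:
        return results
    data = SurvivalDataset.from_death_calls(
        calls, group=cfg.survival.group, include_multi=cfg.survival.include_multi
    )
    curve = km_curve(data)
    with open(out_dir / "survival_curve.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["time_h", "n_risk", "n_event", "survival"])
        for t, nr, ne, s in zip(curve.times, curve.at_risk, curve.deaths, curve.survival):
            w.writerow([f"{t:.1f}", int(nr), int(ne), f"{s:.3f}"])
    summary = summarize(data, lethality_at=[float(t) for t in cfg.survival.lethality_at])
    summary["group"] = cfg.survival.group
    (out_dir / "summary.json").write_text(_stable_json(summary))
    results["median_h"] = curve.median
    results["n_scored"] = len(data)
    return results


def _stable_json(obj) -> str:
    def clean(v):
        if isinstance(v, dict):
            return {str(k): clean(x) for k, x in v.items()}
        if isinstance(v, (list, tuple)):
            return [clean(x) for x in v]
        if isinstance(v, float):
            return None if np.isnan(v) else round(v, 6)
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return clean(float(v))
        return v

    return json.dumps(clean(obj), indent=1, sort_keys=True)


def run_pipeline(cfg: RunConfig) -> RunManifest:
    """Execute the full image-to-survival pipeline for one run config.

    Writes moving_counts.tsv, death_calls.csv, survival outputs, a yield
    report and manifest.json into ``paths.out_dir``; returns the manifest.
    Identical config + inputs give byte-identical result files.
    """
    out_dir = Path(cfg.paths.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config=cfg.to_dict(),
        started=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    try:
        series, sim_manifest = _load_input(cfg)
        manifest.input_checksums[str(cfg.paths.stack)] = _sha256(Path(cfg.paths.stack))

        if cfg.alignment.reference_points:
            src, dst = _read_reference_points(Path(cfg.alignment.reference_points))
            t = estimate_rigid_transform(src, dst, allow_scale=cfg.alignment.allow_scale)
            logger.info(
                "alignment: rotation %.4f rad, translation (%.2f, %.2f), RMS %.3f px",
                t.rotation, *t.translation, t.residual_rms,
            )
            aligned = np.stack([apply_transform(f, t) for f in series.frames])
            series = FrameSeries(aligned, series.times, source_id=series.source_id)

        spec = _grid_spec(cfg, series, sim_manifest)
        regions = build_grid(spec)
        qc = auto_qc_mask(series.frames, regions, n_sd=cfg.grid.auto_qc_sd)
        objects = detect_stack(series, regions, cfg)
        timelines, shift_flags, calls, occupancies = analyze_objects(
            objects, series.times, cfg, spec, qc_flags=qc
        )

        _write_moving_counts(out_dir / "moving_counts.tsv", timelines)
        _write_death_calls(out_dir / "death_calls.csv", calls)
        surv = _write_survival_outputs(out_dir, calls, cfg)

        capacity = spec.n_arenas
        yield_frac = compute_yield(calls, capacity)
        status_counts = {
            s: sum(1 for c in calls if c.status == s)
            for s in ("dead", "censored", "excluded", "empty")
        }
        report = {
            "arenas": capacity,
            "scored": status_counts["dead"] + status_counts["censored"],
            "yield_percent": round(100.0 * yield_frac, 1),
            "status_counts": status_counts,
            "occupancy_percent": occupancy_breakdown([o.label for o in occupancies]),
            "global_frameshift_pairs": int(shift_flags.sum()),
        }
        report.update(surv)
        (out_dir / "yield.json").write_text(_stable_json(report))

        manifest.counts = report
        for name in ("moving_counts.tsv", "death_calls.csv", "survival_curve.csv",
                     "summary.json", "yield.json"):
            p = out_dir / name
            if p.exists():
                manifest.outputs[name] = _sha256(p)
    except Exception:
        manifest.valid = False
        (out_dir / "manifest.json").write_text(_stable_json(manifest.to_dict()))
        raise
    (out_dir / "manifest.json").write_text(_stable_json(manifest.to_dict()))
    return manifest
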