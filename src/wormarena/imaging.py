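"""Frame-series loading and rigid alignment.

A scanner run produces one grayscale frame per hourly scan of a 50-arena
array.  This module turns TIFF files (one multi-page stack or a directory of
single-frame files) into a :class:`FrameSeries` with times in hours, and
aligns frames to a common coordinate system from user-supplied reference
points.

Coordinate convention: pixel indices are 0-based ``(row, col)``, origin at
the top-left.  All centroids and reference points use this frame.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import tifffile
from skimage import transform as sktransform

__all__ = [
    "FrameSeries",
    "RigidTransform",
    "load_frame_series",
    "estimate_rigid_transform",
    "apply_transform",
]


@dataclass
class FrameSeries:
    """Ordered grayscale frames with acquisition times in hours.

    ``times[0]`` is always 0 (hours since the first frame) and times are
    strictly increasing.
    """

    frames: np.ndarray  # (n_frames, height, width)
    times: np.ndarray  # hours since first frame
    source_id: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.times = np.asarray(self.times, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) stack")
        if len(self.times) != len(self.frames):
            raise ValueError(
                f"{len(self.frames)} frames but {len(self.times)} timestamps"
            )
        if len(self.times) and abs(self.times[0]) > 1e-9:
            raise ValueError("times must be relative to the first frame (times[0] == 0)")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def interval(self) -> float:
        """Median inter-frame interval in hours (1.0 for hourly scans)."""
        if len(self.times) < 2:
            return 1.0
        return float(np.median(np.diff(self.times)))


@dataclass
class RigidTransform:
    """Rotation + translation (optionally uniform scale) in (row, col) space.

    Maps a point ``p = (r, c)`` to ``scale * R(rotation) @ p + translation``
    with the standard counter-clockwise rotation matrix
    ``[[cos, -sin], [sin, cos]]`` acting on (row, col) axes.
    """

    rotation: float = 0.0
    translation: tuple[float, float] = (0.0, 0.0)
    scale: float = 1.0
    residual_rms: float = field(default=0.0, compare=False)

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply_points(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        return pts @ self.matrix.T + np.asarray(self.translation)

    def inverse(self) -> "RigidTransform":
        inv_mat = np.linalg.inv(self.matrix)
        t = -inv_mat @ np.asarray(self.translation)
        return RigidTransform(
            rotation=-self.rotation, translation=(t[0], t[1]), scale=1.0 / self.scale
        )


_ISO_RE = re.compile(r"(\d{4})[-_]?(\d{2})[-_]?(\d{2})[T_\- ](\d{2})[-:_]?(\d{2})[-:_]?(\d{2})")
_HOUR_RE = re.compile(r"t(\d+(?:\.\d+)?)h", re.IGNORECASE)


def _parse_time_token(token: str, path: str) -> float:
    """Parse a timestamp token into absolute hours.

    Accepts ISO-8601-like datetimes or plain floats (hours).
    """
    token = token.strip()
    try:
        return float(token)
    except ValueError:
        pass
    for fmt in ("%Y-%m-%dT%H:%M:%S", "%Y-%m-%d %H:%M:%S", "%Y:%m:%d %H:%M:%S"):
        try:
            dt = datetime.strptime(token, fmt)
            return dt.timestamp() / 3600.0
        except ValueError:
            continue
    raise ValueError(f"unparseable timestamp {token!r} for {path}")


def _time_from_filename(path: Path) -> float | None:
    m = _HOUR_RE.search(path.stem)
    if m:
        return float(m.group(1))
    m = _ISO_RE.search(path.stem)
    if m:
        y, mo, d, h, mi, s = (int(g) for g in m.groups())
        return datetime(y, mo, d, h, mi, s).timestamp() / 3600.0
    return None


def _time_from_tiff_tag(path: Path) -> float | None:
    with tifffile.TiffFile(path) as tf:
        tag = tf.pages[0].tags.get("DateTime")
        if tag is None:
            return None
        return _parse_time_token(str(tag.value), str(path))


def _read_sidecar(sidecar: Path) -> dict[str, float]:
    times: dict[str, float] = {}
    with open(sidecar, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].strip().lower() in ("frame", "filename", "page"):
                continue
            key, token = row[0].strip(), row[1]
            if key in times:
                raise ValueError(f"duplicate timestamp entry for {key!r} in {sidecar}")
            times[key] = _parse_time_token(token, key)
    return times


def load_frame_series(
    path_spec: str | Path, sidecar: str | Path | None = None, source_id: str = ""
) -> FrameSeries:
    """Load a frame series from a multi-page TIFF or a directory of TIFFs.

    Timestamp precedence: sidecar table, then filename pattern
    (``...t<hours>h...`` or an ISO-8601 datetime), then the TIFF ``DateTime``
    tag.  Frames are sorted by time and times converted to hours relative to
    the first frame.

    Parameters
    ----------
    path_spec:
        A multi-page TIFF file or a directory containing ``.tif``/``.tiff``
        files (one frame each).
    sidecar:
        Optional two-column CSV ``(filename-or-page, time)`` where time is an
        ISO-8601 datetime or a float in hours.  Defaults to ``times.csv``
        next to the input if present.
    """
    path = Path(path_spec)
    if not path.exists():
        raise FileNotFoundError(f"no such file or directory: {path}")

    if sidecar is None:
        candidate = (path.parent if path.is_file() else path) / "times.csv"
        sidecar = candidate if candidate.exists() else None
    sidecar_times = _read_sidecar(Path(sidecar)) if sidecar is not None else {}

    frames: list[np.ndarray] = []
    times: list[float] = []

    if path.is_file():
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        for i in range(len(stack)):
            t = sidecar_times.get(str(i), sidecar_times.get(f"{path.name}:{i}"))
            if t is None:
                raise ValueError(
                    f"no timestamp for page {i} of {path}; supply a sidecar table"
                )
            frames.append(stack[i])
            times.append(t)
    else:
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FileNotFoundError(f"no TIFF files in {path}")
        for f in files:
            t = sidecar_times.get(f.name)
            if t is None:
                t = _time_from_filename(f)
            if t is None:
                t = _time_from_tiff_tag(f)
            if t is None:
                raise ValueError(f"no timestamp found for {f}")
            img = tifffile.imread(f)
            if img.ndim != 2:
                raise ValueError(f"expected a single grayscale frame in {f}")
            frames.append(img)
            times.append(t)

    shapes = {f.shape for f in frames}
    if len(shapes) > 1:
        raise ValueError(f"unequal frame shapes {sorted(shapes)} under {path}")
    order = np.argsort(times, kind="stable")
    times_arr = np.asarray(times, dtype=float)[order]
    if np.any(np.diff(times_arr) == 0):
        raise ValueError(f"duplicate timestamps under {path}")
    stack_arr = np.stack([frames[i] for i in order])
    return FrameSeries(stack_arr, times_arr - times_arr[0], source_id=source_id or str(path))


def estimate_rigid_transform(
    src_pts: np.ndarray, dst_pts: np.ndarray, allow_scale: bool = False
) -> RigidTransform:
    """Least-squares rigid (or similarity) transform mapping src to dst.

    Solves the 2-D orthogonal Procrustes problem for >= 2 non-coincident
    point pairs given in (row, col); reports the RMS residual of the fit.
    """
    src = np.atleast_2d(np.asarray(src_pts, dtype=float))
    dst = np.atleast_2d(np.asarray(dst_pts, dtype=float))
    if src.shape != dst.shape or src.shape[1] != 2:
        raise ValueError("src and dst must be matching (n, 2) arrays")
    if len(src) < 2:
        raise ValueError("at least 2 point pairs are required")
    if np.allclose(src, src[0]) or np.allclose(dst, dst[0]):
        raise ValueError("degenerate (coincident) reference points")

    # skimage works in (x, y) = (col, row); a CCW angle there is a CW angle
    # in (row, col) axes, hence the sign flip below.
    cls = sktransform.SimilarityTransform if allow_scale else sktransform.EuclideanTransform
    tf = cls.from_estimate(src[:, ::-1], dst[:, ::-1])
    if not tf:
        raise ValueError("transform estimation failed (degenerate points)")
    rotation = -float(tf.rotation)
    tx, ty = (float(v) for v in tf.translation)
    scale = float(tf.scale) if allow_scale else 1.0
    result = RigidTransform(rotation=rotation, translation=(ty, tx), scale=scale)
    resid = result.apply_points(src) - dst
    result.residual_rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return result


def apply_transform(image: np.ndarray, t: RigidTransform) -> np.ndarray:
    """Resample ``image`` under transform ``t`` (bilinear, same shape).

    Out-of-bounds regions are filled with the median border intensity so no
    spurious dark objects appear at frame edges.
    """
    image = np.asarray(image)
    border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    fill = float(np.median(border))
    c, s = np.cos(t.rotation), np.sin(t.rotation)
    dr, dc = t.translation
    # (row, col) rotation angle maps to the opposite sign in skimage's (x, y)
    sk = sktransform.SimilarityTransform(
        scale=t.scale, rotation=-t.rotation, translation=(dc, dr)
    )
    out = sktransform.warp(
        image.astype(float), sk.inverse, order=1, cval=fill, preserve_range=True
    )
    return out.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else out
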