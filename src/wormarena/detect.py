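"""Worm-like object detection in arena sub-images.

Each arena crop is binarized (Otsu by default, computed per arena per frame
because flatbed scanners leave a residual exposure gradient across the bed)
and its connected components measured.  Components smaller than ``min_area``
(300 px by default, the footprint of objects too small to be adult worms at
3200 dpi) are discarded; the boundary is kept (area >= min_area survives).
Components use 8-connectivity so thin diagonal worm segments do not
fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import measure
from skimage.filters import threshold_otsu

__all__ = ["WormObject", "binarize", "detect_objects", "DEFAULT_MIN_AREA"]

DEFAULT_MIN_AREA = 300


@dataclass
class WormObject:
    """A measured worm-candidate connected component in arena coordinates."""

    arena: int
    time_h: float
    area: int
    centroid: tuple[float, float]  # (row, col)
    bbox_height: int
    bbox_width: int
    mean_intensity: float = float("nan")


def binarize(
    image: np.ndarray,
    method: str = "otsu",
    threshold: float | None = None,
    polarity: str = "dark_objects",
    min_contrast: float = 20.0,
) -> np.ndarray:
    """Convert a grayscale arena crop to a worm-candidate mask.

    ``method`` is ``"otsu"`` or ``"fixed"`` (requires ``threshold``);
    ``polarity`` selects whether foreground pixels are darker
    (transillumination, the default) or lighter than the threshold.
    A constant image yields an empty mask: no contrast, no evidence of an
    object.  With Otsu, the two classes must additionally differ by at least
    ``min_contrast`` gray levels in mean — Otsu always finds *a* threshold,
    and without this floor an empty arena containing only scanner noise
    would binarize into a large spurious foreground; worms are far darker
    than the background, so the floor costs nothing on real objects.
    """
    image = np.asarray(image)
    if polarity not in ("dark_objects", "light_objects"):
        raise ValueError(f"unknown polarity {polarity!r}")
    if method == "otsu":
        lo, hi = float(image.min()), float(image.max())
        if hi - lo < 1e-12 or hi - lo < min_contrast:
            return np.zeros(image.shape, dtype=bool)
        thr = float(threshold_otsu(image))
        # Otsu partitions classes as (<= thr, > thr)
        fg = image <= thr if polarity == "dark_objects" else image > thr
        if not fg.any() or fg.all():
            return np.zeros(image.shape, dtype=bool)
        if abs(float(image[fg].mean()) - float(image[~fg].mean())) < min_contrast:
            return np.zeros(image.shape, dtype=bool)
        return fg
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = float(threshold)
        lo, hi = float(image.min()), float(image.max())
        if thr < lo or thr > hi:
            warnings.warn(
                f"fixed threshold {thr} outside image range [{lo}, {hi}]",
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return image < thr if polarity == "dark_objects" else image > thr


def detect_objects(
    mask: np.ndarray,
    min_area: int = DEFAULT_MIN_AREA,
    intensity_image: np.ndarray | None = None,
    arena: int = 0,
    time_h: float = 0.0,
) -> list[WormObject]:
    """Measure 8-connected components of area >= ``min_area``.

    Objects are returned sorted by centroid (row, then col).  The centroid is
    the mean of member pixel coordinates; bounding-box height/width come from
    the component extent.  An empty mask yields an empty list.
    """
    if min_area < 1:
        raise ValueError("min_area must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    objects = []
    for prop in measure.regionprops(labels, intensity_image=intensity_image):
        if prop.area < min_area:
            continue
        r0, c0, r1, c1 = prop.bbox
        mean_int = float(prop.intensity_mean) if intensity_image is not None else float("nan")
        objects.append(
            WormObject(
                arena=arena,
                time_h=time_h,
                area=int(prop.area),
                centroid=(float(prop.centroid[0]), float(prop.centroid[1])),
                bbox_height=r1 - r0,
                bbox_width=c1 - c0,
                mean_intensity=mean_int,
            )
        )
    objects.sort(key=lambda o: o.centroid)
    return objects
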