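"""Shared fixtures: small synthetic runs and independent measurement oracles.

Oracles deliberately use a different code path than the package (scipy's
flood fill instead of skimage labeling, direct pixel arithmetic instead of
regionprops) so the checks stay independent.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage

from wormarena.simulate import SimConfig, generate_experiment


def oracle_components(mask: np.ndarray) -> list[dict]:
    """Brute-force 8-connected component measurement via scipy flood fill."""
    labels, n = ndimage.label(np.asarray(mask, bool), structure=np.ones((3, 3)))
    out = []
    for i in range(1, n + 1):
        rows, cols = np.nonzero(labels == i)
        out.append(
            {
                "area": len(rows),
                "centroid": (rows.mean(), cols.mean()),
                "bbox": (rows.min(), cols.min(), rows.max() + 1, cols.max() + 1),
            }
        )
    return out


def oracle_centroids(frame: np.ndarray, cutoff: float = 130.0) -> list[np.ndarray]:
    """Centroids of dark objects in a rendered frame, measured independently."""
    mask = np.asarray(frame) < cutoff
    labels, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return [np.array(ndimage.center_of_mass(labels == i)) for i in range(1, n + 1)]


@pytest.fixture(scope="session")
def single_worm_run():
    """1 arena, 1 worm dying at 5 h, noiseless, vigorous movement."""
    cfg = SimConfig(
        n_arenas=1,
        frames=12,
        occupancy_probs=(0, 1, 0, 0, 0),
        survival_dist=("fixed", {"times": [5.0]}),
        movement_px=(12.0, 0.5),
        noise_sd=0.0,
        debris_rate=0.0,
        bubble_rate=0.0,
        seed=11,
    )
    return cfg, *generate_experiment(cfg)


@pytest.fixture(scope="session")
def small_array_run():
    """6 arenas (3x2), one worm each, staggered fixed deaths, mild noise."""
    cfg = SimConfig(
        n_arenas=6,
        arena_px=(110, 200),
        frames=24,
        occupancy_probs=(0, 1, 0, 0, 0),
        survival_dist=("fixed", {"times": [5.2, 9.7, 14.1, 3.4, 30.0, 18.6]}),
        movement_px=(12.0, 1.5),
        worm_area_px=700,
        noise_sd=3.0,
        seed=23,
    )
    return cfg, *generate_experiment(cfg)
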