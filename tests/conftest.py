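"""Shared fixtures: small rendered scenes and parameter sets.

All fixtures are generated programmatically with fixed seeds; nothing is
read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from endopos.segmentation import SegmentationParams
from endopos.synthetic import GrapeSpec, PopulationSpec, SceneSpec, render_cell


def small_scene_spec(seed: int = 0, **overrides) -> SceneSpec:
    """A quick-to-render 256 px scene with modest populations."""
    defaults = dict(
        image_size_px=256,
        cell_center=(128.0, 128.0),
        cell_semi_axes=(112.0, 88.0),
        nucleus_center=(128.0, 128.0),
        nucleus_radius_px=24.0,
        ee=PopulationSpec(count=20),
        le=PopulationSpec(
            count=8, radius_log_mu=float(np.log(4.0)), radius_min_px=3.0,
            peak_intensity=120.0,
        ),
        grapes=GrapeSpec(count=0),
        noise_sigma=8.0,
        seed=seed,
    )
    defaults.update(overrides)
    return SceneSpec(**defaults)


@pytest.fixture(scope="session")
def small_scene():
    """Rendered small scene plus its ground truth (seed 0)."""
    return render_cell(small_scene_spec(seed=0))


@pytest.fixture(scope="session")
def default_params() -> SegmentationParams:
    return SegmentationParams()


@pytest.fixture(scope="session")
def calibrated_params() -> SegmentationParams:
    """Threshold multiplier matched to the generator's noise regime."""
    return SegmentationParams(n_sigma_endosome=3.0)


def flood_fill_count(mask: np.ndarray, connectivity: int = 8) -> int:
    """Brute-force connected-component count by BFS flood fill.

    Independent oracle for labeling: no scipy/skimage involvement.
    """
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        neighbours = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
                      (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        neighbours = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    rows, cols = mask.shape
    for r in range(rows):
        for c in range(cols):
            if mask[r, c] and not seen[r, c]:
                count += 1
                stack = [(r, c)]
                seen[r, c] = True
                while stack:
                    rr, cc = stack.pop()
                    for dr, dc in neighbours:
                        nr, nc = rr + dr, cc + dc
                        if (0 <= nr < rows and 0 <= nc < cols
                                and mask[nr, nc] and not seen[nr, nc]):
                            seen[nr, nc] = True
                            stack.append((nr, nc))
    return count


def two_hole_grape_mask() -> tuple[np.ndarray, int, int]:
    """Hand-traced fixture: two fused rectangular rings with 15 px and 2 px holes.

    Returns (mask, large_hole_area, small_hole_area). Ring A is a 7x9
    rectangle ring with a 5x7 = 35 ... scaled so the enclosed holes measure
    exactly 15 px (5x3) and 2 px (2x1); the rings share a wall so the object
    is one 8-connected component.
    """
    mask = np.zeros((20, 24), dtype=bool)
    # large ring: outer rows 4..10, cols 4..10 (7x7), hole rows 6..8, cols 5..9
    mask[4:11, 4:11] = True
    mask[6:9, 5:10] = False   # hole: 3 rows x 5 cols = 15 px
    # small ring fused on the right: outer rows 5..9, cols 10..14, hole 2 px
    mask[5:10, 10:15] = True
    mask[7:8, 11:13] = False  # hole: 1 row x 2 cols = 2 px
    return mask, 15, 2
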