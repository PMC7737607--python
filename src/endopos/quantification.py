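"""Per-cell endosome metrics: number, size, and distance to nucleus.

All metrics are normalized on cell size so that cells of different footprints
can be pooled:

* **distance** — Euclidean distance between the endosome centroid and the
  nucleus centroid, divided by the cell's equivalent circular diameter
  ``2 sqrt(area / pi)`` (a length, commensurate with a distance);
* **size** — endosome area divided by cell area;
* **number** — endosome count divided by cell area.

The raw (unnormalized) values are always retained alongside, so either
convention can be re-plotted. Pearson colocalization between two channels is
computed over the cell mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import PixelGrid
from .segmentation import CellSegment, EndosomeObject, NucleusSegment

__all__ = [
    "CellFrame",
    "EndosomeMetrics",
    "CellSummary",
    "distance_to_nucleus",
    "normalize_metrics",
    "metrics_table",
    "pearson_colocalization",
]


@dataclass(frozen=True)
class CellFrame:
    """The per-cell analysis unit: one nucleus, one cell mask, its vesicles."""

    nucleus: NucleusSegment
    cell: CellSegment
    endosomes: tuple[EndosomeObject, ...]
    pixel_size: float  # nm

    def __post_init__(self) -> None:
        object.__setattr__(self, "endosomes", tuple(self.endosomes))


@dataclass(frozen=True)
class EndosomeMetrics:
    """Positioning and size metrics for one vesicle."""

    endosome_id: int
    channel: Literal["EE", "LE"]
    distance_um: float      # centroid-to-nucleus-centroid, micrometres
    distance_norm: float    # distance / cell equivalent diameter
    area_um2: float
    size_norm: float        # endosome area / cell area


@dataclass(frozen=True)
class CellSummary:
    """Per-cell aggregate of one channel's vesicle population."""

    channel: Literal["EE", "LE"]
    n_endosomes: int
    n_endosomes_norm: float       # count per um^2 of cell area
    mean_size_norm: float         # nan when the cell has no endosomes
    mean_distance_norm: float     # nan when the cell has no endosomes
    distances_norm: tuple[float, ...]
    cell_area_um2: float
    cell_diameter_um: float


def distance_to_nucleus(
    endosome: EndosomeObject, nucleus: NucleusSegment, pixel_size: float
) -> float:
    """Euclidean centroid-to-centroid distance in micrometres."""
    dr = endosome.centroid[0] - nucleus.centroid[0]
    dc = endosome.centroid[1] - nucleus.centroid[1]
    return float(np.hypot(dr, dc) * pixel_size / 1000.0)


def normalize_metrics(
    frame: CellFrame, channel: Literal["EE", "LE"] | None = None
) -> tuple[list[EndosomeMetrics], CellSummary]:
    """Compute normalized per-endosome metrics and the per-cell summary.

    Distances are normalized by the cell equivalent diameter; sizes and
    counts by cell area. ``channel`` restricts the population (None pools
    both channels; the summary is then labeled with the first channel seen
    or "EE" for an empty frame).
    """
    if frame.cell.area_um2 <= 0:
        raise ValueError("cell area must be positive")
    diameter = frame.cell.equivalent_diameter_um
    population = [
        e for e in frame.endosomes if channel is None or e.channel == channel
    ]
    metrics = [
        EndosomeMetrics(
            endosome_id=e.id,
            channel=e.channel,
            distance_um=(d := distance_to_nucleus(e, frame.nucleus, frame.pixel_size)),
            distance_norm=d / diameter,
            area_um2=e.area_um2,
            size_norm=e.area_um2 / frame.cell.area_um2,
        )
        for e in population
    ]
    label = channel or (population[0].channel if population else "EE")
    distances = tuple(m.distance_norm for m in metrics)
    summary = CellSummary(
        channel=label,
        n_endosomes=len(metrics),
        n_endosomes_norm=len(metrics) / frame.cell.area_um2,
        mean_size_norm=(
            float(np.mean([m.size_norm for m in metrics])) if metrics else float("nan")
        ),
        mean_distance_norm=float(np.mean(distances)) if distances else float("nan"),
        distances_norm=distances,
        cell_area_um2=frame.cell.area_um2,
        cell_diameter_um=diameter,
    )
    return metrics, summary


def metrics_table(
    metrics: Sequence[EndosomeMetrics], cell_id: str = "cell"
) -> pd.DataFrame:
    """One row per endosome, ready for CSV export and statistics."""
    return pd.DataFrame(
        {
            "cell_id": cell_id,
            "channel": [m.channel for m in metrics],
            "endosome_id": [m.endosome_id for m in metrics],
            "distance_um": [m.distance_um for m in metrics],
            "distance_norm": [m.distance_norm for m in metrics],
            "area_um2": [m.area_um2 for m in metrics],
            "size_norm": [m.size_norm for m in metrics],
        }
    )


def pearson_colocalization(
    ch1: PixelGrid | np.ndarray, ch2: PixelGrid | np.ndarray, mask: np.ndarray
) -> float:
    """Pearson correlation of two channels' intensities over a cell mask.

    Raises if either channel has zero variance inside the mask (the
    coefficient is undefined there).
    """
    v1 = ch1.values if isinstance(ch1, PixelGrid) else np.asarray(ch1, dtype=float)
    v2 = ch2.values if isinstance(ch2, PixelGrid) else np.asarray(ch2, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if v1.shape != v2.shape or v1.shape != mask.shape:
        raise ValueError("channel and mask shapes must match")
    x = v1[mask]
    y = v2[mask]
    if x.size < 2:
        raise ValueError("need at least 2 pixels in the mask")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined: zero variance in a channel")
    r = np.corrcoef(x, y)[0, 1]
    return float(r)
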