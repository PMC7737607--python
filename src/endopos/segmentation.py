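"""Three-stage segmentation: nucleus, whole cell, and endosome objects.

The pipeline mirrors a per-cell confocal analysis of maximum-intensity
projections:

1. **Nucleus** — threshold the nuclear stain at ``mean(positive pixels) +
   n·SD``, connect nearby pixels by morphological closing, keep the largest
   8-connected object, record its mask and centroid.
2. **Cell** — average the two endosome channels, take every pixel with any
   signal (threshold zero), close and fill holes to obtain a single solid
   object whose pixel count gives the cell area.
3. **Endosomes** — threshold the EE or LE channel, blank the nucleus area,
   label 8-connected objects, optionally split merged spots by watershed on
   the distance transform, discard objects below the channel's minimum size
   ``s_min``, fill ring-like objects, and — for late endosomes — decompose
   "grape-like" clusters of fused rings via hole analysis and keep only
   objects whose circularity lies in a configured band.

Holes are 4-connected background regions not connected to the image border
(the complementary connectivity to the 8-connected foreground). The Euler
number of a labeled set is (number of 8-connected objects) minus (number of
such holes).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import pi
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, segmentation as skseg
from skimage.feature import peak_local_max

from .io import PixelGrid, RunConfig

__all__ = [
    "SegmentationParams",
    "LabeledObjects",
    "NucleusSegment",
    "CellSegment",
    "EndosomeObject",
    "threshold_mask",
    "label8",
    "segment_nucleus",
    "segment_cell",
    "fill_rings",
    "euler_number",
    "decompose_grapes",
    "chain_code_perimeter",
    "circularity_from_geometry",
    "circularity",
    "filter_circularity",
    "split_merged_objects",
    "detect_endosomes",
]

_STRUCT8 = np.ones((3, 3), bool)     # 8-connectivity (foreground)
_STRUCT4 = ndi.generate_binary_structure(2, 1)  # 4-connectivity (holes)


class SegmentationError(ValueError):
    """Raised when a required structure (nucleus, cell) cannot be found."""


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable segmentation parameters.

    ``n_sigma_*`` are the threshold multipliers (no published value; adjusted
    per experiment). ``s_min_ee``/``s_min_le`` are the minimum object sizes in
    pixels (published: 3 for EEs; 10, alternatively 20, for LEs). The
    circularity band default is the published [0.6, 1.5].
    """

    n_sigma_nucleus: float = 2.0
    n_sigma_endosome: float = 2.0
    s_min_ee: int = 3
    s_min_le: int = 10
    circularity_range: tuple[float, float] = (0.6, 1.5)
    closing_radius_px: int = 2
    split_merged: bool = True
    split_area_factor: float = 4.0
    split_min_seed_separation_px: int = 4
    circularity_on_ee: bool = False
    circularity_four_a: bool = False

    def __post_init__(self) -> None:
        if self.s_min_ee < 1 or self.s_min_le < 1:
            raise ValueError("s_min must be >= 1")
        lo, hi = self.circularity_range
        if not 0 < lo < hi:
            raise ValueError("circularity_range must satisfy 0 < lo < hi")

    def s_min(self, kind: Literal["EE", "LE"]) -> int:
        return self.s_min_ee if kind == "EE" else self.s_min_le

    @classmethod
    def from_config(cls, config: RunConfig) -> "SegmentationParams":
        return cls(
            n_sigma_nucleus=config.n_sigma_nucleus,
            n_sigma_endosome=config.n_sigma_endosome,
            s_min_ee=config.s_min_ee,
            s_min_le=config.s_min_le,
            circularity_range=(config.circularity_lo, config.circularity_hi),
            closing_radius_px=config.closing_radius_px,
            split_merged=config.split_merged,
            split_area_factor=config.split_area_factor,
            split_min_seed_separation_px=config.split_min_seed_separation_px,
            circularity_on_ee=config.circularity_on_ee,
            circularity_four_a=config.circularity_four_a,
        )


@dataclass(frozen=True)
class LabeledObjects:
    """8-connected components of a binary mask, labeled 1..K.

    Labels follow raster-scan order of each object's first pixel, so the
    labeling is deterministic and ties (e.g. "largest object" with equal
    areas) resolve reproducibly.
    """

    label_grid: np.ndarray
    objects: tuple[np.ndarray, ...]  # per object: (N, 2) row/col coordinates

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    def mask_of(self, index: int) -> np.ndarray:
        """Boolean mask of object ``index`` (0-based)."""
        return self.label_grid == index + 1

    def areas(self) -> np.ndarray:
        return np.array([len(o) for o in self.objects], dtype=int)


@dataclass(frozen=True)
class NucleusSegment:
    mask: np.ndarray           # boolean, one connected object
    centroid: tuple[float, float]  # (row, col), pixel units


@dataclass(frozen=True)
class CellSegment:
    mask: np.ndarray   # boolean, single solid object
    area_um2: float

    @property
    def equivalent_diameter_um(self) -> float:
        """Diameter of the circle with the same area, in micrometres."""
        return 2.0 * np.sqrt(self.area_um2 / pi)


@dataclass(frozen=True)
class EndosomeObject:
    """One segmented vesicle."""

    id: int
    pixels: np.ndarray          # (N, 2) row/col coordinates
    area_px: int
    area_um2: float
    centroid: tuple[float, float]
    circularity: float
    channel: Literal["EE", "LE"]


def _values(grid: PixelGrid | np.ndarray) -> np.ndarray:
    return grid.values if isinstance(grid, PixelGrid) else np.asarray(grid, dtype=float)


def threshold_mask(grid: PixelGrid | np.ndarray, n_sigma: float) -> np.ndarray:
    """Binarize at ``T = mean(positive pixels) + n_sigma * SD(positive pixels)``.

    "Positive" means strictly greater than zero; the SD is the population
    standard deviation of those pixels. A pixel is foreground iff its
    intensity strictly exceeds ``T``. A grid with no positive pixel yields an
    all-false mask.
    """
    if n_sigma < 0:
        raise ValueError("n_sigma must be >= 0")
    values = _values(grid)
    positive = values[values > 0]
    if positive.size == 0:
        return np.zeros(values.shape, dtype=bool)
    threshold = positive.mean() + n_sigma * positive.std()
    return values > threshold


def label8(mask: np.ndarray) -> LabeledObjects:
    """Label maximal 8-connected components in raster-scan order."""
    mask = np.asarray(mask, dtype=bool)
    raw = measure.label(mask, connectivity=2)
    n = int(raw.max())
    if n == 0:
        return LabeledObjects(np.zeros(mask.shape, dtype=np.int32), ())
    # Re-order labels by the raster position of each object's first pixel.
    flat = raw.ravel()
    first = np.full(n + 1, flat.size, dtype=np.int64)
    nz = np.flatnonzero(flat)
    # reversed so earlier raster positions overwrite later ones
    first[flat[nz[::-1]]] = nz[::-1]
    order = np.argsort(first[1:], kind="stable")  # old label -> rank
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    label_grid = remap[raw]
    objects = []
    for k in range(1, n + 1):
        coords = np.argwhere(label_grid == k)
        objects.append(coords)
    return LabeledObjects(label_grid, tuple(objects))


def _relabel(label_grid: np.ndarray) -> LabeledObjects:
    labels = [int(v) for v in np.unique(label_grid) if v > 0]
    flat = label_grid.ravel()
    firsts = {}
    for lab in labels:
        firsts[lab] = np.flatnonzero(flat == lab)[0]
    ordered = sorted(labels, key=lambda lab: firsts[lab])
    out = np.zeros(label_grid.shape, dtype=np.int32)
    objects = []
    for new, old in enumerate(ordered, start=1):
        sel = label_grid == old
        out[sel] = new
        objects.append(np.argwhere(sel))
    return LabeledObjects(out, tuple(objects))


def _largest_object(objs: LabeledObjects) -> int:
    """Index of the largest object; raster-order of first pixel breaks ties."""
    areas = objs.areas()
    return int(np.argmax(areas))  # argmax returns first max -> raster tie-break


def segment_nucleus(
    nucleus: PixelGrid | np.ndarray, params: SegmentationParams
) -> NucleusSegment:
    """Segment the nucleus and locate its centroid.

    Threshold, connect spatially near pixels by closing, label, keep the
    biggest object. The centroid is the arithmetic mean of the mask's pixel
    coordinates.
    """
    mask = threshold_mask(nucleus, params.n_sigma_nucleus)
    if params.closing_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius_px))
    objs = label8(mask)
    if objs.n_objects == 0:
        raise SegmentationError("no nucleus found (empty mask after thresholding)")
    best = _largest_object(objs)
    nucleus_mask = objs.mask_of(best)
    coords = objs.objects[best]
    centroid = (float(coords[:, 0].mean()), float(coords[:, 1].mean()))
    return NucleusSegment(mask=nucleus_mask, centroid=centroid)


def segment_cell(
    ee: PixelGrid | np.ndarray,
    le: PixelGrid | np.ndarray | None,
    params: SegmentationParams,
    pixel_size: float | None = None,
) -> CellSegment:
    """Segment the whole cell footprint from the endosome channels.

    The average of the EE and LE channels is thresholded at zero (any signal
    counts, maximizing the area covered), then closed and hole-filled to a
    single solid object. The pixel count converted to micrometres squared
    gives the cell area.
    """
    ee_vals = _values(ee)
    if pixel_size is None:
        if not isinstance(ee, PixelGrid):
            raise ValueError("pixel_size required when passing bare arrays")
        pixel_size = ee.pixel_size
    mean_signal = ee_vals if le is None else (ee_vals + _values(le)) / 2.0
    mask = mean_signal > 0
    if not mask.any():
        raise SegmentationError("no cell found (all-zero channels)")
    if params.closing_radius_px > 0:
        mask = morphology.closing(mask, morphology.disk(params.closing_radius_px))
    mask = ndi.binary_fill_holes(mask, structure=_STRUCT4)
    objs = label8(mask)
    cell_mask = objs.mask_of(_largest_object(objs))
    area_um2 = float(cell_mask.sum()) * (pixel_size / 1000.0) ** 2
    return CellSegment(mask=cell_mask, area_um2=area_um2)


def _holes_of(obj_mask: np.ndarray) -> LabeledObjects:
    """Enclosed holes of one object: 4-connected background regions that
    vanish under hole filling."""
    filled = ndi.binary_fill_holes(obj_mask, structure=_STRUCT4)
    holes = filled & ~obj_mask
    raw = measure.label(holes, connectivity=1)
    return _relabel(raw) if raw.max() > 0 else LabeledObjects(raw.astype(np.int32), ())


def fill_rings(
    objs: LabeledObjects, s_min: int, max_hole_area: int | None = None
) -> LabeledObjects:
    """Fill ring-like objects and drop objects below the minimum size.

    Objects with area >= ``s_min`` have their enclosed holes converted to
    foreground; objects smaller than ``s_min`` are removed. If
    ``max_hole_area`` is given, only holes strictly smaller than that many
    pixels are filled — used on the LE channel so that large holes survive
    for grape decomposition.
    """
    out = np.zeros(objs.label_grid.shape, dtype=np.int32)
    next_label = 0
    for coords in objs.objects:
        if len(coords) < s_min:
            continue
        obj_mask = np.zeros(out.shape, dtype=bool)
        obj_mask[coords[:, 0], coords[:, 1]] = True
        if max_hole_area is None:
            obj_mask = ndi.binary_fill_holes(obj_mask, structure=_STRUCT4)
        else:
            for hole in _holes_of(obj_mask).objects:
                if len(hole) < max_hole_area:
                    obj_mask[hole[:, 0], hole[:, 1]] = True
        next_label += 1
        out[obj_mask] = next_label
    return _relabel(out) if next_label else LabeledObjects(out, ())


def euler_number(objs: LabeledObjects | np.ndarray) -> int:
    """Euler number: 8-connected objects minus 4-connected enclosed holes."""
    mask = (
        objs.label_grid > 0 if isinstance(objs, LabeledObjects)
        else np.asarray(objs, dtype=bool)
    )
    n_obj = int(measure.label(mask, connectivity=2).max())
    filled = ndi.binary_fill_holes(mask, structure=_STRUCT4)
    n_holes = int(measure.label(filled & ~mask, connectivity=1).max())
    return n_obj - n_holes


def decompose_grapes(objs: LabeledObjects, s_min: int) -> LabeledObjects:
    """Decompose grape-like clusters of fused rings via hole analysis.

    An object is grape-like iff it contains at least one enclosed hole
    (per-object Euler number < 1). Each hole smaller than ``s_min`` is filled
    into the body. Each hole of at least ``s_min`` pixels is extracted as a
    new object — the hole's pixels plus the immediately surrounding ring of
    object pixels, filled solid — and once any extraction happens the
    unassigned remainder of the grape is discarded. Hole-free objects pass
    through unchanged. Output is re-labeled 1..K in raster order.
    """
    shape = objs.label_grid.shape
    out = np.zeros(shape, dtype=np.int32)
    next_label = 0
    for coords in objs.objects:
        obj_mask = np.zeros(shape, dtype=bool)
        obj_mask[coords[:, 0], coords[:, 1]] = True
        holes = _holes_of(obj_mask)
        if holes.n_objects == 0:  # Euler >= 1: not grape-like
            next_label += 1
            out[obj_mask] = next_label
            continue
        body = obj_mask.copy()
        extracted: list[np.ndarray] = []
        for hole in holes.objects:
            hole_mask = np.zeros(shape, dtype=bool)
            hole_mask[hole[:, 0], hole[:, 1]] = True
            if len(hole) < s_min:
                body |= hole_mask  # small hole: absorbed into the grape body
            else:
                ring = ndi.binary_dilation(hole_mask, structure=_STRUCT8) & obj_mask
                new_obj = ndi.binary_fill_holes(hole_mask | ring, structure=_STRUCT4)
                extracted.append(new_obj)
        if extracted:
            for new_obj in extracted:  # remainder of the grape is discarded
                next_label += 1
                out[new_obj] = next_label
        else:
            next_label += 1
            out[body] = next_label
    return _relabel(out) if next_label else LabeledObjects(out, ())


# --------------------------------------------------------------------------
# Circularity
# --------------------------------------------------------------------------

_MOORE = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


_SQRT2 = float(np.sqrt(2.0))


def chain_code_perimeter(obj_mask: np.ndarray) -> float:
    """Freeman chain-code perimeter of an object's outer boundary.

    Moore-neighbour boundary tracing; axial steps count 1 and diagonal steps
    sqrt(2). Tracing stops when the walk is about to repeat its first move
    from the start pixel, so the accumulated length covers exactly one loop.
    Objects too small to trace (1-2 pixels) fall back to the
    bounding-rectangle perimeter.
    """
    obj_mask = np.asarray(obj_mask, dtype=bool)
    coords = np.argwhere(obj_mask)
    if len(coords) == 0:
        raise ValueError("empty object")
    if len(coords) <= 2:
        h = int(coords[:, 0].max() - coords[:, 0].min()) + 1
        w = int(coords[:, 1].max() - coords[:, 1].min()) + 1
        return float(2 * (h + w))
    padded = np.zeros((obj_mask.shape[0] + 2, obj_mask.shape[1] + 2), dtype=bool)
    padded[1:-1, 1:-1] = obj_mask
    start = (int(coords[0, 0]) + 1, int(coords[0, 1]) + 1)
    current = start
    # start is the raster-first pixel, so its west neighbour is background
    backtrack = (start[0], start[1] - 1)
    first_state: tuple[tuple[int, int], int] | None = None
    perim = 0.0
    for _ in range(8 * len(coords) + 8):
        bi = _MOORE.index((backtrack[0] - current[0], backtrack[1] - current[1]))
        prev_bg = backtrack
        found = None
        for k in range(1, 9):
            d = (bi + k) % 8
            cand = (current[0] + _MOORE[d][0], current[1] + _MOORE[d][1])
            if padded[cand]:
                found = (d, cand)
                break
            prev_bg = cand
        if found is None:  # isolated pixel (unreachable for area >= 3 components)
            return 4.0
        d, nxt = found
        state = (current, d)
        if first_state is None:
            first_state = state
        elif state == first_state:
            return perim
        perim += 1.0 if d % 2 == 0 else _SQRT2
        backtrack = prev_bg
        current = nxt
    return perim


def circularity_from_geometry(
    perimeter: float, area: float, four_a: bool = False
) -> float:
    """Circularity ``c = P^2 / (4 pi A)`` (or ``P^2 / (4 A)`` if ``four_a``).

    Calibrated so an analytic circle (P = 2 pi r, A = pi r^2) scores exactly
    1; the un-normalized ``four_a`` variant is the literal
    perimeter-squared-over-four-area reading, larger by a factor pi.
    """
    if area <= 0:
        raise ValueError("area must be positive")
    denom = 4.0 * area if four_a else 4.0 * pi * area
    return float(perimeter**2 / denom)


def circularity(obj_mask: np.ndarray, four_a: bool = False) -> float:
    """Circularity of a pixelated object from its traced perimeter and area."""
    area = float(np.count_nonzero(obj_mask))
    return circularity_from_geometry(chain_code_perimeter(obj_mask), area, four_a)


def filter_circularity(
    objs: Sequence[EndosomeObject], c_range: tuple[float, float]
) -> list[EndosomeObject]:
    """Keep objects whose circularity lies in [c_lo, c_hi] (inclusive)."""
    lo, hi = c_range
    return [o for o in objs if lo <= o.circularity <= hi]


# --------------------------------------------------------------------------
# Merged-object splitting and full endosome detection
# --------------------------------------------------------------------------

def split_merged_objects(
    objs: LabeledObjects,
    area_factor: float = 4.0,
    min_seed_separation_px: int = 2,
) -> LabeledObjects:
    """Split merged spots by watershed on the Euclidean distance transform.

    Only objects larger than ``area_factor`` times the median object area are
    candidates; seeds are local maxima of the distance transform at least
    ``min_seed_separation_px`` apart. Objects with a single seed are left
    untouched.
    """
    if objs.n_objects == 0:
        return objs
    areas = objs.areas()
    cutoff = area_factor * float(np.median(areas))
    out = np.zeros(objs.label_grid.shape, dtype=np.int32)
    next_label = 0
    for i, coords in enumerate(objs.objects):
        obj_mask = objs.mask_of(i)
        if len(coords) <= cutoff:
            next_label += 1
            out[obj_mask] = next_label
            continue
        distance = ndi.distance_transform_edt(obj_mask)
        peaks = peak_local_max(
            distance, min_distance=min_seed_separation_px, labels=obj_mask,
            exclude_border=False,
        )
        if len(peaks) < 2:
            next_label += 1
            out[obj_mask] = next_label
            continue
        markers = np.zeros(obj_mask.shape, dtype=np.int32)
        markers[peaks[:, 0], peaks[:, 1]] = np.arange(1, len(peaks) + 1)
        ws = skseg.watershed(-distance, markers, mask=obj_mask)
        for lab in range(1, len(peaks) + 1):
            piece = ws == lab
            if piece.any():
                next_label += 1
                out[piece] = next_label
    return _relabel(out)


def detect_endosomes(
    channel: PixelGrid | np.ndarray,
    kind: Literal["EE", "LE"],
    nucleus: NucleusSegment,
    params: SegmentationParams,
    pixel_size: float | None = None,
) -> list[EndosomeObject]:
    """Detect early or late endosomes in one channel of a fixed image.

    Threshold the channel, blank the nucleus footprint, label 8-connected
    objects, split merged spots, apply the minimum-size filter, fill rings
    and — for LEs — decompose grape-like clusters and apply the circularity
    test. Returns the final vesicle population with per-object geometry.
    """
    if pixel_size is None:
        if not isinstance(channel, PixelGrid):
            raise ValueError("pixel_size required when passing bare arrays")
        pixel_size = channel.pixel_size
    mask = threshold_mask(channel, params.n_sigma_endosome)
    mask &= ~nucleus.mask
    objs = label8(mask)
    # splitting targets merged diffraction-limited EE spots; LE clusters are
    # handled by the grape decomposition instead and must not be shredded
    if params.split_merged and kind == "EE" and objs.n_objects:
        objs = split_merged_objects(
            objs, params.split_area_factor, params.split_min_seed_separation_px
        )
    s_min = params.s_min(kind)
    if kind == "LE":
        # fill only sub-s_min holes so grape decomposition still sees large ones
        objs = fill_rings(objs, s_min, max_hole_area=s_min)
        objs = decompose_grapes(objs, s_min)
    else:
        objs = fill_rings(objs, s_min)
    px_um2 = (pixel_size / 1000.0) ** 2
    endosomes: list[EndosomeObject] = []
    for i, coords in enumerate(objs.objects):
        obj_mask = objs.mask_of(i)
        c = circularity(obj_mask, four_a=params.circularity_four_a)
        endosomes.append(
            EndosomeObject(
                id=i + 1,
                pixels=coords,
                area_px=len(coords),
                area_um2=len(coords) * px_um2,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                circularity=c,
                channel=kind,
            )
        )
    apply_c = kind == "LE" or params.circularity_on_ee
    if apply_c:
        endosomes = filter_circularity(endosomes, params.circularity_range)
        for new_id, obj in enumerate(endosomes, start=1):
            endosomes[new_id - 1] = EndosomeObject(
                id=new_id, pixels=obj.pixels, area_px=obj.area_px,
                area_um2=obj.area_um2, centroid=obj.centroid,
                circularity=obj.circularity, channel=obj.channel,
            )
    return endosomes
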