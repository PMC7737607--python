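"""Synthetic confocal scenes and live movies with full ground truth.

The generator emulates the imaging regime the analysis assumes: one adherent
cell per field with a single nucleus, 8-bit intensities (0-255), pixel sizes
around 90 nm for fixed imaging and 170 nm for live imaging, 0.5 s frames.
Early endosomes are rendered as small Gaussian spots (sigma = radius/2,
truncated at 3 sigma), late endosomes as larger spots plus optional
"grape-like" clusters of fused annular rings with enclosed holes. Spot
positions follow a radial Beta(a, b) law scaled to the corridor between the
nucleus edge and the cell edge, so ``a < b`` produces a perinuclear
population and ``a > b`` a peripheral one. Movies move particles by radial
drift (negative speed = toward the nucleus) plus isotropic diffusion.

Everything is deterministic given the spec seed, and every render returns
the ground truth (true centers, radii, cluster structure, or per-frame
positions and drift speeds) that recovery tests compare against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .io import Movie, MultiChannelImage, PixelGrid

__all__ = [
    "PopulationSpec",
    "GrapeSpec",
    "SceneSpec",
    "MotionSpec",
    "SpotTruth",
    "SceneGroundTruth",
    "ParticleTruth",
    "MovieGroundTruth",
    "render_cell",
    "render_grape",
    "render_movie",
]


@dataclass(frozen=True)
class PopulationSpec:
    """One vesicle population: how many, how big, where along the radius."""

    count: int = 50
    radius_log_mu: float = float(np.log(2.5))  # lognormal radius, px
    radius_log_sigma: float = 0.2
    radius_min_px: float = 2.0
    radial_a: float = 2.0   # Beta(a, b) over [nucleus edge, cell edge]
    radial_b: float = 2.0
    peak_intensity: float = 100.0


@dataclass(frozen=True)
class GrapeSpec:
    """Grape-like LE clusters: fused annular rings with enclosed holes."""

    count: int = 0
    rings_per_grape: int = 2
    ring_radius_px: float = 4.0
    hole_radius_px: float = 2.0
    intensity: float = 150.0


@dataclass(frozen=True)
class SceneSpec:
    """Geometry, populations and noise of one synthetic fixed-cell field."""

    image_size_px: int = 512
    pixel_size_nm: float = 90.0
    cell_center: tuple[float, float] = (256.0, 256.0)
    cell_semi_axes: tuple[float, float] = (220.0, 170.0)  # (row, col) px
    nucleus_center: tuple[float, float] = (256.0, 256.0)
    nucleus_radius_px: float = 45.0
    ee: PopulationSpec = field(default_factory=PopulationSpec)
    le: PopulationSpec = field(
        default_factory=lambda: PopulationSpec(
            count=25, radius_log_mu=float(np.log(4.0)), radius_log_sigma=0.2,
            radius_min_px=3.0, peak_intensity=120.0,
        )
    )
    grapes: GrapeSpec = field(default_factory=GrapeSpec)
    nucleus_intensity: float = 180.0
    nucleus_haze_intensity: float = 10.0  # dim out-of-nucleus staining
    haze_intensity: float = 10.0   # cytoplasmic haze, ~10% of spot peak
    noise_sigma: float = 4.0       # additive Gaussian background noise
    min_spot_separation_factor: float = 3.0
    seed: int = 0


@dataclass(frozen=True)
class MotionSpec:
    """Particle kinetics for live movies."""

    n_particles: int = 10
    drift_speed_um_per_s: float = -0.05  # negative = toward the nucleus
    diffusion_um2_per_s: float = 0.0
    lifetime_mean_s: float | None = None  # None = immortal
    frame_interval_s: float = 0.5
    n_frames: int = 121
    spot_radius_px: float = 3.0
    peak_intensity: float = 180.0
    noise_sigma: float = 2.0
    nucleus_centroid_px: tuple[float, float] | None = None  # overrides the scene
    init_margin_px: float = 16.0
    min_initial_separation_px: float = 12.0
    seed: int = 0


@dataclass(frozen=True)
class SpotTruth:
    center: tuple[float, float]  # (row, col) px
    radius_px: float
    channel: str                 # EE | LE | grape
    cluster_id: int | None = None


@dataclass(frozen=True)
class SceneGroundTruth:
    spots: tuple[SpotTruth, ...]
    nucleus_center: tuple[float, float]
    nucleus_radius_px: float
    cell_center: tuple[float, float]
    cell_semi_axes: tuple[float, float]
    cell_area_px: int
    grape_hole_areas: tuple[tuple[int, ...], ...]  # per grape, measured px


@dataclass(frozen=True)
class ParticleTruth:
    id: int
    drift_um_per_s: float
    start_frame: int
    positions_px: np.ndarray  # (n_alive, 2)


@dataclass(frozen=True)
class MovieGroundTruth:
    particles: tuple[ParticleTruth, ...]
    nucleus_centroid_px: tuple[float, float]
    pixel_size_nm: float
    frame_interval_s: float


# --------------------------------------------------------------------------
# Fixed-cell scene
# --------------------------------------------------------------------------

def _ellipse_radius(theta: np.ndarray, semi_axes: tuple[float, float]) -> np.ndarray:
    """Distance from the ellipse center to its boundary along ``theta``."""
    a, b = semi_axes  # row, col semi-axes
    return (a * b) / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)


def _inside_ellipse(rows, cols, center, semi_axes):
    a, b = semi_axes
    return ((rows - center[0]) / a) ** 2 + ((cols - center[1]) / b) ** 2 <= 1.0


def _add_gaussian_spot(
    image: np.ndarray, center: tuple[float, float], radius_px: float, peak: float
) -> None:
    """Add a Gaussian spot (sigma = radius/2, truncated at 3 sigma) in place."""
    sigma = radius_px / 2.0
    half = int(np.ceil(3.0 * sigma))
    r0 = int(np.floor(center[0])) - half
    c0 = int(np.floor(center[1])) - half
    r1, c1 = r0 + 2 * half + 1, c0 + 2 * half + 1
    rr, cc = np.mgrid[max(r0, 0):min(r1, image.shape[0]),
                      max(c0, 0):min(c1, image.shape[1])]
    if rr.size == 0:
        return
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    spot = peak * np.exp(-d2 / (2.0 * sigma**2))
    spot[d2 > (3.0 * sigma) ** 2] = 0.0
    image[rr, cc] += spot


def _sample_positions(
    rng: np.random.Generator,
    spec: SceneSpec,
    pop: PopulationSpec,
    radii: np.ndarray,
    occupied: list[tuple[float, float, float]],
) -> np.ndarray:
    """Sample spot centers along the Beta radial law, rejecting overlaps.

    Centers stay clear of the nucleus (by 3 sigma of the spot profile) and of
    the cell edge, and keep ``min_spot_separation_factor`` times the summed
    radii from previously placed spots so rendered spots stay resolvable.
    """
    centers = np.empty((len(radii), 2))
    sep = spec.min_spot_separation_factor
    for i, radius in enumerate(radii):
        margin = 1.5 * radius  # 3 sigma with sigma = radius/2
        for _ in range(10_000):
            theta = rng.uniform(0.0, 2.0 * np.pi)
            u = rng.beta(pop.radial_a, pop.radial_b)
            r_cell = _ellipse_radius(np.array([theta]), spec.cell_semi_axes)[0]
            lo = spec.nucleus_radius_px + margin
            hi = r_cell - margin
            if hi <= lo:
                continue
            dist = lo + u * (hi - lo)
            pos = (
                spec.nucleus_center[0] + dist * np.sin(theta),
                spec.nucleus_center[1] + dist * np.cos(theta),
            )
            if not (0 <= pos[0] < spec.image_size_px and 0 <= pos[1] < spec.image_size_px):
                continue
            ok = all(
                np.hypot(pos[0] - orow, pos[1] - ocol) >= sep * (radius + oradius) / 2.0 + 2.0
                for orow, ocol, oradius in occupied
            )
            if ok:
                break
        else:
            raise ValueError(
                "could not place all spots without overlapping the nucleus "
                "or each other; reduce counts or sizes"
            )
        centers[i] = pos
        occupied.append((pos[0], pos[1], float(radius)))
    return centers


def render_grape(
    center: tuple[float, float],
    ring_radii: Sequence[float],
    hole_radii: Sequence[float],
    intensity: float = 150.0,
    shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, dict]:
    """Render fused annular rings ("grape") into a patch, with ground truth.

    Rings are placed side by side along the column axis at center distances
    ``0.9 * (r_i + r_(i+1))`` so their annuli fuse into one 8-connected
    object while each hole stays an enclosed background region. Returns the
    intensity patch and a truth dict with the ring centers and the measured
    pixel area of every enclosed hole.
    """
    if len(ring_radii) != len(hole_radii):
        raise ValueError("ring_radii and hole_radii must have equal length")
    if any(h >= r for r, h in zip(ring_radii, hole_radii)):
        raise ValueError("each hole radius must be smaller than its ring radius")
    if len(ring_radii) == 0:
        empty = np.zeros(shape or (16, 16))
        return empty, {"ring_centers": [], "hole_areas_px": []}
    # ring centers along the column axis
    centers = [np.array(center, dtype=float)]
    for i in range(1, len(ring_radii)):
        offset = 0.9 * (ring_radii[i - 1] + ring_radii[i])
        centers.append(centers[-1] + np.array([0.0, offset]))
    if shape is None:
        max_r = max(ring_radii)
        extent = int(np.ceil(centers[-1][1] + max_r + 3))
        shape = (int(np.ceil(center[0] + max_r + 3)) + 1, extent + 1)
    patch = np.zeros(shape)
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    annulus_any = np.zeros(shape, dtype=bool)
    for (cr, ccol), ring_r, hole_r in zip(centers, ring_radii, hole_radii):
        d = np.hypot(rr - cr, cc - ccol)
        annulus_any |= (d <= ring_r) & (d > hole_r)
    patch[annulus_any] = intensity
    # measure the enclosed holes of the rendered object
    filled = ndi.binary_fill_holes(annulus_any)
    holes = measure.label(filled & ~annulus_any, connectivity=1)
    hole_areas = [int((holes == k).sum()) for k in range(1, holes.max() + 1)]
    truth = {
        "ring_centers": [tuple(c) for c in centers],
        "hole_areas_px": hole_areas,
    }
    return patch, truth


def render_cell(spec: SceneSpec) -> tuple[MultiChannelImage, SceneGroundTruth]:
    """Render one synthetic multi-channel fixed-cell field.

    Nucleus channel: filled disc plus noise. EE/LE channels: Gaussian spots
    at Beta-law radial positions, plus a diffuse cytoplasmic haze filling the
    cell ellipse (so the zero-threshold cell segmentation has support), plus
    noise. The noiseless render is capped at 255 before noise is added, and
    the final images are clipped to [0, 255]. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    rr, cc = np.mgrid[0:size, 0:size]
    # nucleus must fit inside the cell
    for theta in np.linspace(0, 2 * np.pi, 64):
        edge = _ellipse_radius(np.array([theta]), spec.cell_semi_axes)[0]
        if spec.nucleus_radius_px >= edge:
            raise ValueError("nucleus does not fit inside the cell ellipse")

    cell_mask = _inside_ellipse(rr, cc, spec.cell_center, spec.cell_semi_axes)
    # nuclear dyes leave dim cytoplasmic staining; the threshold statistic
    # relies on those dim positives to land between background and nucleus
    nucleus = np.zeros((size, size))
    nucleus[cell_mask] = spec.nucleus_haze_intensity
    nucleus_mask = (
        np.hypot(rr - spec.nucleus_center[0], cc - spec.nucleus_center[1])
        <= spec.nucleus_radius_px
    )
    nucleus[nucleus_mask] = spec.nucleus_intensity
    ee = np.zeros((size, size))
    le = np.zeros((size, size))
    ee[cell_mask] = spec.haze_intensity
    le[cell_mask] = spec.haze_intensity

    occupied: list[tuple[float, float, float]] = []
    spots: list[SpotTruth] = []

    ee_radii = np.maximum(
        rng.lognormal(spec.ee.radius_log_mu, spec.ee.radius_log_sigma, spec.ee.count),
        spec.ee.radius_min_px,
    )
    ee_centers = _sample_positions(rng, spec, spec.ee, ee_radii, occupied)
    for center, radius in zip(ee_centers, ee_radii):
        _add_gaussian_spot(ee, tuple(center), radius, spec.ee.peak_intensity)
        spots.append(SpotTruth(tuple(center), float(radius), "EE"))

    le_radii = np.maximum(
        rng.lognormal(spec.le.radius_log_mu, spec.le.radius_log_sigma, spec.le.count),
        spec.le.radius_min_px,
    )
    le_centers = _sample_positions(rng, spec, spec.le, le_radii, occupied)
    for center, radius in zip(le_centers, le_radii):
        _add_gaussian_spot(le, tuple(center), radius, spec.le.peak_intensity)
        spots.append(SpotTruth(tuple(center), float(radius), "LE"))

    grape_hole_areas: list[tuple[int, ...]] = []
    if spec.grapes.count > 0:
        g = spec.grapes
        extent = g.rings_per_grape * 2.2 * g.ring_radius_px
        grape_radii = np.full(g.count, extent / 2.0)
        grape_centers = _sample_positions(rng, spec, spec.le, grape_radii, occupied)
        patch_size = int(np.ceil(extent)) + 8
        for gid, center in enumerate(grape_centers):
            patch, truth = render_grape(
                (patch_size / 2.0, g.ring_radius_px + 4.0),
                [g.ring_radius_px] * g.rings_per_grape,
                [g.hole_radius_px] * g.rings_per_grape,
                g.intensity,
                shape=(patch_size, patch_size),
            )
            # paste the patch centered on the sampled position
            pr = int(round(center[0] - patch.shape[0] / 2))
            pc = int(round(center[1] - extent / 2))
            r0, c0 = max(pr, 0), max(pc, 0)
            r1 = min(pr + patch.shape[0], size)
            c1 = min(pc + patch.shape[1], size)
            le[r0:r1, c0:c1] += patch[r0 - pr:r1 - pr, c0 - pc:c1 - pc]
            grape_hole_areas.append(tuple(truth["hole_areas_px"]))
            for ring_center in truth["ring_centers"]:
                spots.append(
                    SpotTruth(
                        (ring_center[0] + pr, ring_center[1] + pc),
                        g.ring_radius_px, "grape", cluster_id=gid,
                    )
                )

    channels = []
    for img in (nucleus, ee, le):
        img = np.minimum(img, 255.0)  # noiseless render stays within 8-bit range
        if spec.noise_sigma > 0:
            # photon-counting detectors: noise rides on signal, true background
            # stays at zero counts (this is what makes the zero-threshold cell
            # segmentation meaningful)
            noise = rng.normal(0.0, spec.noise_sigma, img.shape)
            img = np.where(img > 0, img + noise, 0.0)
        channels.append(np.clip(img, 0.0, 255.0))

    image = MultiChannelImage(
        nucleus=PixelGrid(channels[0], spec.pixel_size_nm),
        ee=PixelGrid(channels[1], spec.pixel_size_nm),
        le=PixelGrid(channels[2], spec.pixel_size_nm),
    )
    truth = SceneGroundTruth(
        spots=tuple(spots),
        nucleus_center=spec.nucleus_center,
        nucleus_radius_px=spec.nucleus_radius_px,
        cell_center=spec.cell_center,
        cell_semi_axes=spec.cell_semi_axes,
        cell_area_px=int(cell_mask.sum()),
        grape_hole_areas=tuple(grape_hole_areas),
    )
    return image, truth


# --------------------------------------------------------------------------
# Live movie
# --------------------------------------------------------------------------

def render_movie(
    scene: SceneSpec | None, motion: MotionSpec
) -> tuple[Movie, MovieGroundTruth]:
    """Render a single-channel time-lapse of drifting/diffusing particles.

    Geometry (image size, pixel size, nucleus position) comes from ``scene``
    when given; ``motion.nucleus_centroid_px`` overrides the nucleus position
    (it may lie outside the frame, as for wide cells whose nucleus is out of
    the field). Initial positions follow the scene's EE radial law when the
    nucleus is in-frame, otherwise a uniform draw over the frame inset by
    ``init_margin_px``. Per frame each particle takes a radial step
    ``drift_speed * dt`` (negative = toward the nucleus) plus an isotropic
    Gaussian diffusion step of variance ``2 D dt`` per axis. Deaths follow a
    per-frame geometric law with mean lifetime ``lifetime_mean_s``; each
    death triggers a birth at a fresh position, keeping the population size
    constant. Ground truth records every true position.
    """
    rng = np.random.default_rng(motion.seed)
    if scene is not None:
        size = scene.image_size_px
        pixel_size = scene.pixel_size_nm
        nucleus = motion.nucleus_centroid_px or scene.nucleus_center
    else:
        size = 256
        pixel_size = 170.0
        if motion.nucleus_centroid_px is None:
            raise ValueError("nucleus_centroid_px required without a scene")
        nucleus = motion.nucleus_centroid_px
    nucleus = (float(nucleus[0]), float(nucleus[1]))
    dt = motion.frame_interval_s
    px_per_um = 1000.0 / pixel_size
    drift_px = motion.drift_speed_um_per_s * dt * px_per_um
    diff_sigma_px = np.sqrt(2.0 * motion.diffusion_um2_per_s * dt) * px_per_um
    p_death = (
        0.0 if motion.lifetime_mean_s is None else min(1.0, dt / motion.lifetime_mean_s)
    )

    nucleus_in_frame = (
        scene is not None
        and 0 <= nucleus[0] < size
        and 0 <= nucleus[1] < size
        and motion.nucleus_centroid_px is None
    )

    def sample_position(existing: list[np.ndarray]) -> np.ndarray:
        for _ in range(10_000):
            if nucleus_in_frame:
                theta = rng.uniform(0.0, 2.0 * np.pi)
                u = rng.beta(scene.ee.radial_a, scene.ee.radial_b)
                r_cell = _ellipse_radius(np.array([theta]), scene.cell_semi_axes)[0]
                lo = scene.nucleus_radius_px + 3.0 * motion.spot_radius_px
                hi = r_cell - 3.0 * motion.spot_radius_px
                if hi <= lo:
                    continue
                dist = lo + u * (hi - lo)
                pos = np.array(
                    [nucleus[0] + dist * np.sin(theta), nucleus[1] + dist * np.cos(theta)]
                )
            else:
                m = motion.init_margin_px
                pos = rng.uniform([m, m], [size - m, size - m])
            if not (0 <= pos[0] < size and 0 <= pos[1] < size):
                continue
            if all(
                np.hypot(*(pos - q)) >= motion.min_initial_separation_px
                for q in existing
            ):
                return pos
        raise ValueError("could not place particles with the requested separation")

    # state
    positions: list[np.ndarray] = []
    for _ in range(motion.n_particles):
        positions.append(sample_position(positions))
    ids = list(range(motion.n_particles))
    next_id = motion.n_particles
    history: dict[int, list] = {i: [(0, positions[k].copy())] for k, i in enumerate(ids)}
    start_frames = {i: 0 for i in ids}

    frames = []
    for frame_index in range(motion.n_frames):
        img = np.zeros((size, size))
        for pos in positions:
            _add_gaussian_spot(
                img, (pos[0], pos[1]), motion.spot_radius_px, motion.peak_intensity
            )
        img = np.minimum(img, 255.0)
        if motion.noise_sigma > 0:
            img = img + rng.normal(0.0, motion.noise_sigma, img.shape)
        frames.append(PixelGrid(np.clip(img, 0.0, 255.0), pixel_size))
        if frame_index == motion.n_frames - 1:
            break
        # advance particles
        new_positions = []
        new_ids = []
        for pid, pos in zip(ids, positions):
            dies = p_death > 0 and rng.uniform() < p_death
            out_of_frame = not (0 <= pos[0] < size and 0 <= pos[1] < size)
            if dies or out_of_frame:
                fresh = sample_position(new_positions)
                new_positions.append(fresh)
                new_ids.append(next_id)
                history[next_id] = [(frame_index + 1, fresh.copy())]
                start_frames[next_id] = frame_index + 1
                next_id += 1
                continue
            radial = pos - np.array(nucleus)
            norm = np.hypot(*radial)
            step = (
                drift_px * radial / norm if norm > 0 else np.zeros(2)
            )
            if diff_sigma_px > 0:
                step = step + rng.normal(0.0, diff_sigma_px, 2)
            nxt = pos + step
            new_positions.append(nxt)
            new_ids.append(pid)
            history[pid].append((frame_index + 1, nxt.copy()))
        positions, ids = new_positions, new_ids

    particles = tuple(
        ParticleTruth(
            id=pid,
            drift_um_per_s=motion.drift_speed_um_per_s,
            start_frame=start_frames[pid],
            positions_px=np.array([p for _, p in records]),
        )
        for pid, records in sorted(history.items())
    )
    movie = Movie(tuple(frames), dt, nucleus)
    truth = MovieGroundTruth(
        particles=particles,
        nucleus_centroid_px=nucleus,
        pixel_size_nm=pixel_size,
        frame_interval_s=dt,
    )
    return movie, truth
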