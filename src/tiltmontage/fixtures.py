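"""Deterministic synthetic-data generators for the whole toolkit.

Everything downstream — stitching, drift metrics, reconstruction, dose
annotation, fringe calibration — is exercised on data produced here, so every
generator is a pure function of ``(seed, config)``.

The generators emulate the geometry of a montage acquisition, not its imaging
physics: a flat specimen phantom is foreshortened by cos(alpha) about the x
tilt axis, camera frames are windows cut from the projection at the tile
targets (plus any injected registration error), optionally masked by the beam
footprint, decorated with synthetic edge fringes and degraded with Poisson
counting noise.  No contrast transfer function, multislice scattering or
detector MTF is modeled.

Desk-scale defaults (128 x 96 px tiles, 21 tilts, 3 x 3 pattern) keep full
pipeline runs fast; the phantom spans 10 x 10 um with a high-contrast central
region of 5 x 4 um, mirroring the reference simulation canvas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .dose import DoseMap, StageCanvas
from .geometry import CameraFrame, MontagePattern, TiltScheme, generate_tilt_angles, tile_grid
from .particles import TileGeometry
from .pipeline import MontageDataset, TileSeries
from .serialem import MdocDocument

__all__ = [
    "FixtureConfig",
    "DESK",
    "BENCHMARK",
    "make_phantom",
    "foreshorten",
    "render_tile",
    "make_montage_dataset",
    "make_tile_series",
    "make_fringed_beam",
    "make_particle_table",
    "canvas_tile_geometry",
]


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for the synthetic acquisition.

    ``jitter_px`` adds per-frame integer registration error (uniform in
    +/- jitter_px) to the true tile positions while the nominal piece
    coordinates stay ideal — the stitcher has to recover it.
    ``noise_mean_counts`` switches on Poisson counting noise at that mean
    count per pixel (the reference detector ran at 10 e-/px/s).
    """

    seed: int = 0
    camera: CameraFrame = field(
        default_factory=lambda: CameraFrame(width_px=128, height_px=96, pixel_size_A=166.0)
    )
    pattern: MontagePattern = field(
        default_factory=lambda: MontagePattern(m=3, n=3, overlap_x_px=24, overlap_y_px=24)
    )
    scheme: TiltScheme = field(
        default_factory=lambda: TiltScheme(max_angle_deg=30.0, increment_deg=3.0, group_size=3)
    )
    phantom_px: int = 600
    phantom_extent_um: float = 10.0
    roi_um: tuple[float, float] = (5.0, 4.0)
    n_point_features: int = 40
    background_amplitude: float = 0.3
    jitter_px: int = 0
    noise_mean_counts: float | None = None
    beam_mask: bool = False
    beam_diameter_um: float | None = None


#: Desk-scale default conditions (fast full-pipeline runs).
DESK = FixtureConfig()

#: Benchmark-geometry conditions: full K3-format frames at 4.603 A/px with
#: the printed piece-coordinate overlaps (1152 px in x, 576 px in y) and the
#: +/-60 deg, 3 deg, group-of-three tilt scheme.  Geometry only — rendering
#: frames at this size is supported but not a test default.
BENCHMARK = FixtureConfig(
    camera=CameraFrame(width_px=5760, height_px=4092, pixel_size_A=4.603),
    pattern=MontagePattern(m=3, n=3, overlap_x_px=1152, overlap_y_px=576),
    scheme=TiltScheme(max_angle_deg=60.0, increment_deg=3.0, group_size=3),
)


def make_phantom(config: FixtureConfig = DESK) -> tuple[np.ndarray, pd.DataFrame]:
    """Square stage phantom with a high-contrast central ROI and point features.

    Returns ``(image, features)`` where ``features`` lists the (x, y) pixel
    coordinates of the point features.  The central ROI (default 5 x 4 um on
    a 10 um canvas) is a checker-like high-contrast block; point features are
    small Gaussian spots scattered over the whole canvas.  Deterministic in
    ``(seed, config)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.phantom_px
    px_per_um = n / config.phantom_extent_um
    img = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (n, n)), 8.0)
    img = config.background_amplitude * img / max(img.std(), 1e-12)

    # central ROI block with internal structure
    rw = int(config.roi_um[0] * px_per_um)
    rh = int(config.roi_um[1] * px_per_um)
    y0, x0 = (n - rh) // 2, (n - rw) // 2
    yy, xx = np.mgrid[0:rh, 0:rw]
    checker = np.sin(2 * np.pi * xx / 24.0) * np.sin(2 * np.pi * yy / 24.0)
    img[y0 : y0 + rh, x0 : x0 + rw] += 1.0 + 0.8 * checker

    rows = []
    if config.n_point_features:
        coords = rng.uniform(0.08 * n, 0.92 * n, size=(config.n_point_features, 2))
        yy, xx = np.mgrid[0:n, 0:n]
        for fx, fy in coords:
            img += 1.5 * np.exp(-(((xx - fx) ** 2 + (yy - fy) ** 2) / (2 * 2.0**2)))
            rows.append({"x_px": fx, "y_px": fy})
    return img, pd.DataFrame(rows, columns=["x_px", "y_px"])


def foreshorten(phantom: np.ndarray, alpha_deg: float) -> np.ndarray:
    """Project the flat phantom at tilt ``alpha_deg``: content compresses by
    cos(alpha) along y about the phantom center; x is untouched."""
    c = math.cos(math.radians(alpha_deg))
    if c == 1.0:
        return phantom.astype(np.float64, copy=True)
    cy = (phantom.shape[0] - 1) / 2.0
    # output row y samples input row (y - cy)/c + cy
    matrix = np.array([1.0 / c, 1.0])
    offset = np.array([cy * (1.0 - 1.0 / c), 0.0])
    return ndimage.affine_transform(
        phantom.astype(np.float64), matrix, offset=offset, order=1, mode="constant", cval=0.0
    )


def render_tile(
    projected: np.ndarray,
    center_px: tuple[int, int],
    frame_shape: tuple[int, int],
    beam_radius_px: float | None = None,
    fringe: tuple[float, float, float] | None = None,
    noise_mean_counts: float | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Cut one camera frame from a projected phantom.

    ``center_px`` is the (x, y) window center in projected-phantom pixels;
    ``frame_shape`` is (height, width).  Optional decorations: a circular
    top-hat beam mask, synthetic x-edge fringes ``(depth_fraction,
    amplitude, period_px)``, and Poisson counting noise at
    ``noise_mean_counts`` per pixel.  Raises if the window leaves the phantom.
    """
    h, w = frame_shape
    cx, cy = int(round(center_px[0])), int(round(center_px[1]))
    y0, x0 = cy - h // 2, cx - w // 2
    if y0 < 0 or x0 < 0 or y0 + h > projected.shape[0] or x0 + w > projected.shape[1]:
        raise ValueError("tile window falls outside the phantom")
    frame = projected[y0 : y0 + h, x0 : x0 + w].copy()
    if beam_radius_px is not None:
        yy, xx = np.mgrid[0:h, 0:w]
        mask = ((xx - (w - 1) / 2) ** 2 + (yy - (h - 1) / 2) ** 2) <= beam_radius_px**2
        frame *= mask
    if fringe is not None:
        depth_frac, amplitude, period_px = fringe
        depth = int(depth_frac * w)
        if depth > 0:
            d = np.arange(depth)
            wave = amplitude * np.cos(2 * np.pi * d / period_px)
            frame[:, :depth] += wave[::-1]
            frame[:, w - depth :] += wave
    if noise_mean_counts is not None:
        if rng is None:
            raise ValueError("noise requested without an rng")
        lo = frame.min()
        span = max(frame.max() - lo, 1e-9)
        rate = noise_mean_counts * (0.5 + (frame - lo) / span)
        frame = rng.poisson(rate).astype(np.float64)
    return frame


def make_montage_dataset(
    config: FixtureConfig = DESK,
    beam_offsets_px: np.ndarray | None = None,
    drop: tuple[tuple[int, int], ...] = (),
) -> MontageDataset:
    """Full synthetic montage tilt series with per-tilt metadata.

    The content of tile j at tilt alpha is windowed around the projected
    position of its specimen target: pattern-relative x shift unchanged,
    y shift scaled by cos(alpha) (plus any per-tilt ``beam_offsets_px`` and
    the per-frame jitter).  Nominal piece coordinates are emitted per tilt
    with the same cosine-contracted y spacing — the jitter is what the
    stitcher must recover.  ``drop`` removes (tilt_index, tile_index)
    exposures to emulate failed acquisitions.
    """
    rng = np.random.default_rng(config.seed + 1)
    phantom, _ = make_phantom(config)
    grid = tile_grid(config.pattern, config.camera)
    angles = np.asarray(generate_tilt_angles(config.scheme))
    n_tiles = config.pattern.n_tiles
    if beam_offsets_px is None:
        beam_offsets_px = np.zeros((len(angles), 2))
    h, w = config.camera.height_px, config.camera.width_px
    pc = (phantom.shape[1] // 2, phantom.shape[0] // 2)
    sx, sy = grid.spacing_px
    cxt, cyt = config.pattern.center_tile

    frames, etilt, etile = [], [], []
    piece = np.zeros((len(angles), n_tiles, 2))
    truth_rows = []
    beam_radius_px = None
    if config.beam_mask:
        dia = config.beam_diameter_um or 1.25 * config.camera.px_to_um(w)
        beam_radius_px = dia / 2.0 / (config.camera.pixel_size_A * 1e-4)
    for ti, ang in enumerate(angles):
        c = math.cos(math.radians(ang))
        projected = foreshorten(phantom, ang)
        for tile in range(n_tiles):
            ix, iy = tile % config.pattern.m, tile // config.pattern.m
            piece[ti, tile] = (ix * sx, round(iy * sy * c))
            if (ti, tile) in drop:
                continue
            jit = (
                rng.integers(-config.jitter_px, config.jitter_px + 1, size=2)
                if config.jitter_px
                else np.zeros(2, dtype=int)
            )
            cx = pc[0] + (ix - cxt) * sx + beam_offsets_px[ti, 0] + jit[0]
            cy = pc[1] + ((iy - cyt) * sy + beam_offsets_px[ti, 1]) * c + jit[1]
            frame = render_tile(
                projected,
                (int(round(cx)), int(round(cy))),
                (h, w),
                beam_radius_px=beam_radius_px,
                noise_mean_counts=config.noise_mean_counts,
                rng=rng,
            )
            frames.append(frame)
            etilt.append(ti)
            etile.append(tile)
            truth_rows.append(
                {
                    "tilt_index": ti,
                    "tile_index": tile,
                    "angle_deg": float(ang),
                    "true_cx_px": int(round(cx)),
                    "true_cy_px": int(round(cy)),
                    "jitter_x_px": int(jit[0]),
                    "jitter_y_px": int(jit[1]),
                }
            )

    mdoc = MdocDocument()
    mdoc.set_header("PixelSpacing", config.camera.pixel_size_A)
    mdoc.set_header("ImageSize", (w, h))
    z = 0
    for row in truth_rows:
        ti, tile = row["tilt_index"], row["tile_index"]
        shift = grid.image_shifts_um[tile]
        mdoc.add_section(
            z,
            TiltAngle=row["angle_deg"],
            PieceCoordinates=(int(piece[ti, tile, 0]), int(piece[ti, tile, 1]), ti),
            ImageShift=(float(shift[0]), float(shift[1])),
            ExposureDose=1.0,
        )
        z += 1

    return MontageDataset(
        frames=np.stack(frames),
        tilt_angles=angles,
        exposure_tilt=np.asarray(etilt),
        exposure_tile=np.asarray(etile),
        pattern=config.pattern,
        camera=config.camera,
        piece_coords_px=piece,
        mdoc=mdoc,
        ground_truth={"frames": pd.DataFrame(truth_rows)},
    )


def make_tile_series(
    config: FixtureConfig = DESK,
    roi_offset_um: tuple[float, float] = (0.0, 0.0),
    tracking_error_px: np.ndarray | None = None,
) -> TileSeries:
    """One compensated tile tilt series following an off-axis ROI.

    The window tracks the projected ROI position at every tilt (perfect
    beam-image-shift compensation), except for optional per-tilt
    ``tracking_error_px`` (n_tilts, 2) displacements — the drift metric
    should read back exactly those errors.  Angles are returned sorted.
    """
    phantom, _ = make_phantom(config)
    angles = np.sort(np.asarray(generate_tilt_angles(config.scheme)))
    if tracking_error_px is None:
        tracking_error_px = np.zeros((len(angles), 2))
    h, w = config.camera.height_px, config.camera.width_px
    pc = (phantom.shape[1] // 2, phantom.shape[0] // 2)
    s = config.camera.pixel_size_A * 1e-4
    roi_px = (roi_offset_um[0] / s, roi_offset_um[1] / s)
    frames = []
    for k, ang in enumerate(angles):
        c = math.cos(math.radians(ang))
        projected = foreshorten(phantom, ang)
        cx = pc[0] + roi_px[0] + tracking_error_px[k, 0]
        cy = pc[1] + roi_px[1] * c + tracking_error_px[k, 1]
        frames.append(render_tile(projected, (int(round(cx)), int(round(cy))), (h, w)))
    return TileSeries(
        tile_index=0,
        angles_deg=angles,
        stack=np.stack(frames),
        complete=True,
    )


def make_fringed_beam(
    depth_fraction: float = 0.04,
    amplitude: float = 0.3,
    period_px: float = 24.0,
    shape: tuple[int, int] = (512, 1536),
    pixel_size_A: float = 4.603,
    noise_sigma: float = 0.03,
    seed: int = 0,
) -> np.ndarray:
    """Gain-normalized beam image with fringes of known x depth.

    A flat unit background with Gaussian read noise; sinusoidal ringing of
    the given amplitude is superposed over the outer ``depth_fraction`` of x
    on both edges, phased so the envelope peaks at the inner boundary of the
    fringe zone (the quantity the calibration should recover).
    """
    rng = np.random.default_rng(seed)
    h, w = shape
    img = 1.0 + rng.normal(0.0, noise_sigma, (h, w))
    depth = int(depth_fraction * w)
    if depth > 0:
        d = np.arange(depth)  # distance from the edge
        wave = amplitude * np.cos(2 * np.pi * (depth - 1 - d) / period_px)
        img[:, :depth] += wave
        img[:, w - depth :] += wave[::-1]
    return img


def canvas_tile_geometry(canvas: StageCanvas) -> TileGeometry:
    """Identity mapping: one 'tomogram' whose pixel grid is the dose canvas
    (pixel (i, j) center = voxel (i, j) center)."""
    vx, vy, _ = canvas.voxel_size_um
    origin = (-canvas.extent_um[0] / 2 + vx / 2, -canvas.extent_um[1] / 2 + vy / 2)
    return TileGeometry({0: origin}, pixel_size_A=vx * 1e4)


def make_particle_table(
    dose_map: DoseMap,
    n_total: int,
    n_overdosed: int,
    threshold_e_per_A2: float = 130.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Particle table with a prescribed overdose split.

    ``n_overdosed`` particles are placed in voxels at or above the threshold
    and the remainder in exposed voxels below it (sampling voxels with
    replacement), so the overdose filter partitions the table exactly as
    constructed.  Coordinates are in canvas-pixel units of the identity
    :func:`canvas_tile_geometry`.
    """
    if n_overdosed > n_total:
        raise ValueError("n_overdosed cannot exceed n_total")
    rng = np.random.default_rng(seed)
    plane = dose_map.dose[:, :, dose_map.canvas.nz // 2]
    over = plane >= threshold_e_per_A2
    under = (plane > 0) & ~over
    if not over.any() or not under.any():
        raise ValueError("dose map lacks voxels on one side of the threshold")
    oj, oi = np.nonzero(over)
    uj, ui = np.nonzero(under)
    ko = rng.integers(0, len(oi), size=n_overdosed)
    ku = rng.integers(0, len(ui), size=n_total - n_overdosed)
    x = np.concatenate([oi[ko], ui[ku]]).astype(np.float64)
    y = np.concatenate([oj[ko], uj[ku]]).astype(np.float64)
    df = pd.DataFrame(
        {
            "id": np.arange(1, n_total + 1),
            "tile": 0,
            "x_px": x,
            "y_px": y,
            "z_px": 0.0,
        }
    )
    return df.sample(frac=1.0, random_state=int(rng.integers(0, 2**31))).reset_index(drop=True)
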