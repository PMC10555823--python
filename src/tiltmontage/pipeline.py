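"""Two-path processing of montage tilt series.

A montage acquisition yields ``m*n`` overlapping camera frames per tilt.  Two
complementary products are built from the same raw frames:

* **path 1 (stitched)** — for each tilt, tiles are registered with their
  nominal piece coordinates as priors, refined by cross-correlation over the
  overlap bands, globally reconciled by least squares over the tile adjacency
  graph, and blended with linear feathering; the per-tilt montages are then
  cropped to their common region and stacked into one large-field tilt
  series, reconstructed into a single tomogram.
* **path 2 (per-tile)** — frames are sorted into ``m*n`` individual tile tilt
  series and each is reconstructed on its own, giving small tomograms suited
  to sub-tomogram averaging.

A 3 x 3 acquisition therefore yields ten volumes in total.

Because off-axis content forshortens as y*cos(alpha) while the camera frame
is fixed, y-adjacent tiles overlap more at high tilt and the stitched montage
shrinks along y; the assembled stack is cropped to the minimum y extent over
tilts.  The drift metric quantifies ROI retention within one tile series:
each tilted frame is stretched by 1/cos(alpha) along y and cross-correlated
against the 0-degree frame, reporting the residual displacement in nm.

The reconstruction here is a minimal deterministic filtered back-projector
about the x tilt axis, intended for synthetic-data validation; real data
should go through an established tomography package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import CameraFrame, MontagePattern

__all__ = [
    "MontageDataset",
    "TileSeries",
    "StitchResult",
    "TwoPathResult",
    "sort_tiles",
    "stitch_tilt",
    "assemble_montage_stack",
    "drift_metric",
    "reconstruct",
    "run_two_paths",
]


@dataclass
class MontageDataset:
    """Raw montage tilt-series data plus the metadata needed to process it.

    ``frames[i]`` is the 2D image of exposure ``i``; ``exposure_tilt[i]`` /
    ``exposure_tile[i]`` give its (tilt index, tile index).  Tilt indices
    refer to ``tilt_angles`` (acquisition order); tile indices are row-major
    over the pattern.  ``piece_coords_px[t, j]`` is the nominal (x, y) piece
    coordinate of tile ``j`` at tilt ``t`` — nominal coordinates are per tilt
    because y spacings contract with cos(alpha).
    """

    frames: np.ndarray  # (n_exposures, h, w)
    tilt_angles: np.ndarray  # (n_tilts,)
    exposure_tilt: np.ndarray  # (n_exposures,)
    exposure_tile: np.ndarray  # (n_exposures,)
    pattern: MontagePattern
    camera: CameraFrame
    piece_coords_px: np.ndarray  # (n_tilts, n_tiles, 2)
    mdoc: object | None = None
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = list(zip(self.exposure_tilt.tolist(), self.exposure_tile.tolist()))
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate (tilt, tile) exposure in dataset")

    @property
    def n_tilts(self) -> int:
        return len(self.tilt_angles)

    @property
    def is_complete(self) -> bool:
        return len(self.frames) == self.n_tilts * self.pattern.n_tiles

    def frame_for(self, tilt_index: int, tile_index: int) -> np.ndarray | None:
        hit = np.flatnonzero(
            (self.exposure_tilt == tilt_index) & (self.exposure_tile == tile_index)
        )
        return self.frames[hit[0]] if hit.size else None


@dataclass
class TileSeries:
    """One tile's tilt series, ordered by tilt angle."""

    tile_index: int
    angles_deg: np.ndarray
    stack: np.ndarray  # (n_present, h, w)
    complete: bool
    missing_tilts: tuple[int, ...] = ()


@dataclass
class StitchResult:
    """One tilt's stitched montage and registration diagnostics."""

    image: np.ndarray
    positions_px: np.ndarray  # (n_tiles, 2) refined (x, y)
    nominal_px: np.ndarray
    scores: np.ndarray  # per-tile mean correlation peak score
    flagged: np.ndarray  # tiles that fell back to nominal coordinates
    angle_deg: float = 0.0


@dataclass
class TwoPathResult:
    stitched_volume: np.ndarray
    tile_volumes: dict[int, np.ndarray]
    stitched_stack: np.ndarray
    incomplete_tiles: tuple[int, ...] = ()

    @property
    def n_volumes(self) -> int:
        return 1 + len(self.tile_volumes)


def sort_tiles(dataset: MontageDataset) -> dict[int, TileSeries]:
    """Sort exposures into per-tile tilt series ordered by angle.

    The union of outputs is exactly the input frame set.  A tile with one or
    more missing tilts is marked incomplete (such series are discarded from
    reconstruction, mirroring practice with inadequate projections).
    """
    order = np.argsort(dataset.tilt_angles, kind="stable")
    out: dict[int, TileSeries] = {}
    for tile in range(dataset.pattern.n_tiles):
        frames, angles, missing = [], [], []
        for ti in order:
            fr = dataset.frame_for(int(ti), tile)
            if fr is None:
                missing.append(int(ti))
            else:
                frames.append(fr)
                angles.append(dataset.tilt_angles[ti])
        out[tile] = TileSeries(
            tile_index=tile,
            angles_deg=np.asarray(angles, dtype=np.float64),
            stack=np.stack(frames) if frames else np.empty((0, 0, 0)),
            complete=not missing,
            missing_tilts=tuple(missing),
        )
    return out


def _overlap_ncc(a: np.ndarray, b: np.ndarray, sx: int, sy: int) -> float:
    """Pearson correlation of the pixels where ``b`` (displaced by (sx, sy)
    in ``a``'s frame) actually overlaps ``a``; 0 if degenerate or empty."""
    h, w = a.shape
    ay0, ay1 = max(sy, 0), min(h, b.shape[0] + sy)
    ax0, ax1 = max(sx, 0), min(w, b.shape[1] + sx)
    if ay1 - ay0 < 2 or ax1 - ax0 < 2:
        return 0.0
    ra = a[ay0:ay1, ax0:ax1]
    rb = b[ay0 - sy : ay1 - sy, ax0 - sx : ax1 - sx]
    sa, sb = ra.std(), rb.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(((ra - ra.mean()) * (rb - rb.mean())).mean() / (sa * sb))


def _xcorr_shift(
    a: np.ndarray,
    b: np.ndarray,
    max_shift: int,
    center: tuple[int, int] = (0, 0),
) -> tuple[float, float, float]:
    """Translation of ``b`` relative to ``a`` by linear FFT cross-correlation.

    The peak is searched within ``max_shift`` pixels of ``center`` (the
    coordinate prior); zero padding makes the correlation linear, so large
    priors such as full tile spacings are handled.  Returns ``(dx, dy,
    score)`` where the score is the Pearson correlation of the overlapping
    pixels at the refined shift (0 for featureless inputs).  Ties break
    toward the smallest displacement from the prior.
    """
    am = a - a.mean()
    bm = b - b.mean()
    if np.linalg.norm(am) == 0 or np.linalg.norm(bm) == 0:
        return float(center[0]), float(center[1]), 0.0
    H = a.shape[0] + b.shape[0]
    W = a.shape[1] + b.shape[1]
    corr = np.fft.irfft2(
        np.fft.rfft2(am, s=(H, W)) * np.conj(np.fft.rfft2(bm, s=(H, W))), s=(H, W)
    )
    cx, cy = int(round(center[0])), int(round(center[1]))
    sy = np.arange(cy - max_shift, cy + max_shift + 1)
    sx = np.arange(cx - max_shift, cx + max_shift + 1)
    cand = corr[np.ix_(sy % H, sx % W)]
    peak = cand.max()
    ties = np.argwhere(cand >= peak - 1e-12 * abs(peak))
    d2 = (sy[ties[:, 0]] - cy) ** 2 + (sx[ties[:, 1]] - cx) ** 2
    iy, ix = ties[int(np.argmin(d2))]
    dy, dx = int(sy[iy]), int(sx[ix])
    return float(dx), float(dy), _overlap_ncc(a, b, dx, dy)


def _pair_offset(
    a: np.ndarray, b: np.ndarray, rel: np.ndarray, margin: int
) -> tuple[np.ndarray, float] | None:
    """Refined relative position of tile ``b`` w.r.t. tile ``a``.

    The nominal overlap band of ``a`` is matched as a normalized
    cross-correlation template over a search window of ``b`` grown by
    ``margin`` pixels, so the measurement is unbiased by overlap area.
    Returns ``(rel_measured, score)`` or None when the nominal layout leaves
    no usable overlap; ties break toward the nominal offset.
    """
    from skimage.feature import match_template

    h, w = a.shape
    rx, ry = int(round(rel[0])), int(round(rel[1]))
    ax0, ax1 = max(rx, 0), min(w, w + rx)
    ay0, ay1 = max(ry, 0), min(h, h + ry)
    if ax1 - ax0 < 4 or ay1 - ay0 < 4:
        return None
    # contract the template inside the overlap band so the search window can
    # move by up to `margin` in both dimensions
    cx = min(margin, max(0, (ax1 - ax0 - 4) // 2))
    cy = min(margin, max(0, (ay1 - ay0 - 4) // 2))
    ax0, ax1 = ax0 + cx, ax1 - cx
    ay0, ay1 = ay0 + cy, ay1 - cy
    template = a[ay0:ay1, ax0:ax1]
    bx0, by0 = ax0 - rx, ay0 - ry
    sx0, sy0 = max(bx0 - margin, 0), max(by0 - margin, 0)
    sx1 = min(bx0 + template.shape[1] + margin, w)
    sy1 = min(by0 + template.shape[0] + margin, h)
    image = b[sy0:sy1, sx0:sx1]
    if image.shape[0] < template.shape[0] or image.shape[1] < template.shape[1]:
        return None
    if template.std() == 0 or image.std() == 0:
        return ( np.array([float(rx), float(ry)]), 0.0)
    cc = match_template(image, template)
    peak = cc.max()
    ties = np.argwhere(cc >= peak - 1e-9)
    nom = np.array([by0 - sy0, bx0 - sx0])
    d2 = ((ties - nom) ** 2).sum(axis=1)
    py, px = ties[int(np.argmin(d2))]
    # template found at b-frame position (sx0+px, sy0+py): pB + tb = pA + a0
    rel_meas = np.array([ax0 - (sx0 + px), ay0 - (sy0 + py)], dtype=float)
    return rel_meas, float(peak)


def _neighbor_pairs(pattern: MontagePattern) -> list[tuple[int, int]]:
    pairs = []
    for iy in range(pattern.n):
        for ix in range(pattern.m):
            t = iy * pattern.m + ix
            if ix + 1 < pattern.m:
                pairs.append((t, t + 1))
            if iy + 1 < pattern.n:
                pairs.append((t, t + pattern.m))
    return pairs


def stitch_tilt(
    tiles: dict[int, np.ndarray],
    nominal_coords_px: np.ndarray,
    refine: bool = True,
    search_radius_px: int = 10,
    score_threshold: float = 0.1,
    pattern: MontagePattern | None = None,
    angle_deg: float = 0.0,
) -> StitchResult:
    """Stitch one tilt's tiles with coordinate priors plus cross-correlation.

    Pairwise offsets between adjacent tiles are refined over their nominal
    overlap bands, constrained to ``search_radius_px`` of the prior; global
    tile positions are solved by least squares over the adjacency graph,
    anchored at tile 0.  Tiles whose every pairwise score falls below
    ``score_threshold`` keep their nominal coordinates and are flagged.
    Overlaps are blended by linear feathering.
    """
    if pattern is None:
        raise ValueError("pattern is required to define tile adjacency")
    n = pattern.n_tiles
    nominal = np.asarray(nominal_coords_px, dtype=np.float64)[:, :2]
    h, w = next(iter(tiles.values())).shape
    # pairwise measurements over nominal overlap bands
    measurements = []  # (i, j, rel_xy, score)
    scores = np.zeros(n)
    counts = np.zeros(n)
    n_pairs = 0
    n_usable = 0
    if refine:
        for i, j in _neighbor_pairs(pattern):
            if i not in tiles or j not in tiles:
                continue
            n_pairs += 1
            rel = nominal[j] - nominal[i]
            meas = _pair_offset(tiles[i], tiles[j], rel, search_radius_px)
            if meas is None:
                continue
            n_usable += 1
            rel_meas, score = meas
            scores[i] += score
            scores[j] += score
            counts[i] += 1
            counts[j] += 1
            if score >= score_threshold:
                measurements.append((i, j, rel_meas, score))
    if refine and n_pairs > 0 and n_usable == 0:
        raise ValueError("nominal layout leaves no usable overlap between adjacent tiles")
    with np.errstate(invalid="ignore"):
        mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1), 0.0)
    positions = _solve_positions(n, nominal, measurements)
    flagged = np.array(
        [counts[t] == 0 or mean_scores[t] < score_threshold for t in range(n)]
    )
    # any tile not connected to the anchor by accepted measurements stays nominal
    image = _blend(tiles, positions, pattern, (h, w))
    return StitchResult(
        image=image,
        positions_px=positions,
        nominal_px=nominal,
        scores=mean_scores,
        flagged=flagged,
        angle_deg=angle_deg,
    )


def _solve_positions(n, nominal, measurements):
    """Least-squares global positions from pairwise offsets, anchored at
    tile 0; tiles untouched by measurements keep their nominal positions."""
    positions = nominal.copy()
    if not measurements:
        return positions
    # union-find connectivity to the anchor
    idx = {0}
    changed = True
    accepted = [(i, j, rel) for i, j, rel, _ in measurements]
    while changed:
        changed = False
        for i, j, _ in accepted:
            if (i in idx) != (j in idx):
                idx |= {i, j}
                changed = True
    nodes = sorted(idx)
    col = {t: k for k, t in enumerate(nodes)}
    rows = []
    rhs = []
    for i, j, rel in accepted:
        if i in idx and j in idx:
            r = np.zeros(len(nodes))
            r[col[j]] += 1
            r[col[i]] -= 1
            rows.append(r)
            rhs.append(rel)
    # anchor
    r0 = np.zeros(len(nodes))
    r0[col[0]] = 1
    rows.append(r0)
    rhs.append(nominal[0])
    A = np.asarray(rows)
    B = np.asarray(rhs)
    sol, *_ = np.linalg.lstsq(A, B, rcond=None)
    for t in nodes:
        positions[t] = sol[col[t]]
    return positions


def _feather_weight(h, w, ramp_x, ramp_y):
    wx = np.minimum((np.arange(w) + 1) / ramp_x, (w - np.arange(w)) / ramp_x)
    wy = np.minimum((np.arange(h) + 1) / ramp_y, (h - np.arange(h)) / ramp_y)
    return np.clip(wy, 0, 1)[:, None] * np.clip(wx, 0, 1)[None, :]


def _blend(tiles, positions, pattern, tile_shape):
    h, w = tile_shape
    pos = np.round(positions).astype(int)
    x0, y0 = pos.min(axis=0)
    x1, y1 = pos.max(axis=0) + (w, h)
    H, W = y1 - y0, x1 - x0
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    ramp_x = max(pattern.overlap_x_px, 1)
    ramp_y = max(pattern.overlap_y_px, 1)
    weight = _feather_weight(h, w, ramp_x, ramp_y)
    for t, tile in tiles.items():
        px, py = pos[t] - (x0, y0)
        acc[py : py + h, px : px + w] += tile * weight
        wacc[py : py + h, px : px + w] += weight
    out = np.zeros_like(acc)
    np.divide(acc, wacc, out=out, where=wacc > 0)
    return out


def assemble_montage_stack(results: list[StitchResult]) -> np.ndarray:
    """Stack per-tilt stitched montages, cropped (centered) to the common
    region: the minimum x and y extents over tilts.  With foreshortened
    content the y extent is set by the highest tilts."""
    if not results:
        raise ValueError("no stitch results to assemble")
    Hs = [r.image.shape[0] for r in results]
    Ws = [r.image.shape[1] for r in results]
    H, W = min(Hs), min(Ws)
    if H == 0 or W == 0:
        raise ValueError("empty common region")
    out = np.zeros((len(results), H, W))
    for k, r in enumerate(results):
        h, w = r.image.shape
        y0 = (h - H) // 2
        x0 = (w - W) // 2
        out[k] = r.image[y0 : y0 + H, x0 : x0 + W]
    return out


def drift_metric(
    series: TileSeries, pixel_size_A: float, max_shift_px: int | None = None
) -> np.ndarray:
    """ROI displacement (nm) at each tilt relative to the 0-degree frame.

    Each tilted frame is stretched by 1/cos(alpha) along y (undoing
    foreshortening), then cross-correlated against the 0-degree frame; the
    radial displacement of the correlation peak is converted to nm.
    """
    if series.stack.size == 0:
        raise ValueError("empty tile series")
    i0 = int(np.argmin(np.abs(series.angles_deg)))
    ref = series.stack[i0]
    h, w = ref.shape
    if max_shift_px is None:
        max_shift_px = min(h, w) // 3
    out = np.zeros(len(series.angles_deg))
    for k, ang in enumerate(series.angles_deg):
        img = series.stack[k]
        if float(np.ptp(img)) == 0 or float(np.ptp(ref)) == 0:
            raise ValueError("degenerate (constant) frame in drift metric")
        c = math.cos(math.radians(ang))
        stretched = ndimage.zoom(img, (1.0 / c, 1.0), order=1, mode="nearest", grid_mode=False)
        hs = stretched.shape[0]
        y0 = (hs - h) // 2
        stretched = stretched[y0 : y0 + h, :]
        dx, dy, _ = _xcorr_shift(ref, stretched, max_shift_px)
        out[k] = math.hypot(dx, dy) * pixel_size_A / 10.0
    return out


def _ramp_filter(proj: np.ndarray) -> np.ndarray:
    """Ramp-filter a (ny, nx) projection along the detector (y) axis."""
    ny = proj.shape[0]
    n = int(2 ** np.ceil(np.log2(2 * ny)))
    freqs = np.fft.rfftfreq(n)
    filt = 2.0 * freqs
    padded = np.zeros((n, proj.shape[1]))
    padded[:ny] = proj
    out = np.fft.irfft(np.fft.rfft(padded, axis=0) * filt[:, None], n=n, axis=0)
    return out[:ny]


def reconstruct(
    stack: np.ndarray,
    angles_deg,
    thickness: int,
    filtered: bool = True,
) -> np.ndarray:
    """Back-project an aligned tilt stack about the x tilt axis.

    ``stack`` is (n_tilts, ny, nx); the result is (thickness, ny, nx) with z
    centered on the projection plane.  ``filtered=True`` applies a ramp
    filter along y (standard FBP weighting pi/(2 n_angles)); ``False`` gives
    the plain back-projection sum, under which a single 0-degree projection
    reproduces itself exactly in the central slice.
    """
    stack = np.asarray(stack, dtype=np.float64)
    angles = np.asarray(angles_deg, dtype=np.float64)
    if len(stack) != len(angles):
        raise ValueError("stack length and angle list length differ")
    n_tilts, ny, nx = stack.shape
    nz = int(thickness)
    y = np.arange(ny) - (ny - 1) / 2.0
    z = np.arange(nz) - (nz - 1) / 2.0
    Z, Y = np.meshgrid(z, y, indexing="ij")  # (nz, ny)
    vol = np.zeros((nz, ny, nx))
    for proj, ang in zip(stack, angles):
        p = _ramp_filter(proj) if filtered else proj
        rad = math.radians(ang)
        u = Y * math.cos(rad) + Z * math.sin(rad) + (ny - 1) / 2.0
        u0 = np.floor(u).astype(int)
        f = u - u0
        valid0 = (u0 >= 0) & (u0 <= ny - 1)
        valid1 = (u0 + 1 >= 0) & (u0 + 1 <= ny - 1)
        c0 = np.clip(u0, 0, ny - 1)
        c1 = np.clip(u0 + 1, 0, ny - 1)
        contrib = (
            p[c0] * ((1 - f) * valid0)[..., None]
            + p[c1] * (f * valid1)[..., None]
        )
        vol += contrib
    if filtered:
        vol *= math.pi / (2.0 * len(angles))
    return vol


def run_two_paths(
    dataset: MontageDataset,
    thickness: int = 16,
    search_radius_px: int = 10,
    filtered: bool = True,
) -> TwoPathResult:
    """Run both processing paths on a montage dataset.

    Path 1 stitches each tilt and reconstructs one large tomogram; path 2
    reconstructs every complete individual tile series.  A complete m x n
    dataset yields ``m*n + 1`` volumes.
    """
    order = np.argsort(dataset.tilt_angles, kind="stable")
    results = []
    for ti in order:
        tiles = {
            t: dataset.frame_for(int(ti), t)
            for t in range(dataset.pattern.n_tiles)
            if dataset.frame_for(int(ti), t) is not None
        }
        results.append(
            stitch_tilt(
                tiles,
                dataset.piece_coords_px[int(ti)],
                search_radius_px=search_radius_px,
                pattern=dataset.pattern,
                angle_deg=float(dataset.tilt_angles[ti]),
            )
        )
    stack = assemble_montage_stack(results)
    sorted_angles = dataset.tilt_angles[order]
    stitched_vol = reconstruct(stack, sorted_angles, thickness, filtered=filtered)
    series = sort_tiles(dataset)
    tile_vols = {}
    incomplete = []
    for tile, s in series.items():
        if s.complete:
            tile_vols[tile] = reconstruct(s.stack, s.angles_deg, thickness, filtered=filtered)
        else:
            incomplete.append(tile)
    return TwoPathResult(
        stitched_volume=stitched_vol,
        tile_volumes=tile_vols,
        stitched_stack=stack,
        incomplete_tiles=tuple(incomplete),
    )
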