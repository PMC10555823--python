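"""Per-voxel electron-dose accumulation over a montage tilt acquisition.

The simulator mirrors a simple physical picture: the stage canvas is a fixed
voxel grid in the xy plane, the beam arrives along z, and each exposure
illuminates an elliptical stage footprint — a circle of the beam diameter at
0 degrees, elongated along y by 1/cos(alpha) at tilt alpha.  Every voxel whose
center falls inside the footprint has its accumulated dose incremented once
per exposure by that exposure's dose.  A top-hat beam profile is assumed
(parallel illumination); rasterization is a voxel-center-inside-ellipse test,
validated in the test suite against a supersampled-ray oracle.

Beam-frame offsets (tile image shifts, spiral offsets, ROI compensation) map
to stage-plane positions as x unchanged, y divided by cos(alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import (
    BeamIllumination,
    CameraFrame,
    MontagePattern,
    TiltScheme,
    footprint_at_tilt,
    generate_tilt_angles,
    tile_grid,
)
from .spiral import OffsetTable

__all__ = [
    "StageCanvas",
    "Exposure",
    "ExposurePlan",
    "DoseMap",
    "build_exposure_plan",
    "simulate",
    "dose_stats",
    "montage_regions",
    "overdose_mask",
    "export_dose_csv",
    "read_dose_csv",
]


@dataclass(frozen=True)
class StageCanvas:
    """Voxelized stage region: ``nx * ny * nz`` voxels spanning
    ``extent_um = (ex, ey, ez)`` micrometres, centered on the origin.

    The default matches the simulator's reference canvas: 150 x 150 x 1
    voxels over 10 x 10 x 0.2 um.
    """

    nx: int = 150
    ny: int = 150
    nz: int = 1
    extent_um: tuple[float, float, float] = (10.0, 10.0, 0.2)

    def __post_init__(self) -> None:
        if min(self.nx, self.ny, self.nz) < 1:
            raise ValueError("voxel counts must be >= 1")
        if min(self.extent_um) <= 0:
            raise ValueError("extent must be positive")

    @property
    def voxel_size_um(self) -> tuple[float, float, float]:
        return (
            self.extent_um[0] / self.nx,
            self.extent_um[1] / self.ny,
            self.extent_um[2] / self.nz,
        )

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Voxel-center coordinate vectors (x, y) in um, origin-centered."""
        vx, vy, _ = self.voxel_size_um
        x = (np.arange(self.nx) + 0.5) * vx - self.extent_um[0] / 2.0
        y = (np.arange(self.ny) + 0.5) * vy - self.extent_um[1] / 2.0
        return x, y


@dataclass(frozen=True)
class Exposure:
    """One beam exposure: tilt, tile, stage-plane footprint center and dose."""

    tilt_index: int
    angle_deg: float
    tile_index: int
    center_x_um: float
    center_y_um: float
    semi_x_um: float
    semi_y_um: float
    dose_e_A2: float = 1.0


@dataclass(frozen=True)
class ExposurePlan:
    """Ordered exposures of a full (montage) tilt acquisition, grouped by
    tilt in acquisition order."""

    exposures: tuple[Exposure, ...]

    def __len__(self) -> int:
        return len(self.exposures)

    def __iter__(self):
        return iter(self.exposures)


@dataclass
class DoseMap:
    """Accumulated dose per voxel, shape ``(ny, nx, nz)``, plus its canvas."""

    dose: np.ndarray
    canvas: StageCanvas

    @property
    def total(self) -> float:
        return float(self.dose.sum())


def build_exposure_plan(
    frame: CameraFrame,
    beam: BeamIllumination,
    pattern: MontagePattern,
    scheme: TiltScheme,
    offsets: OffsetTable | None = None,
    dose_per_exposure: float = 1.0,
) -> ExposurePlan:
    """Assemble the exposure list for a montage tilt series.

    Each tilt exposes all ``m*n`` tiles; the beam-frame position of a tile is
    its image-shift vector (relative to the pattern center) plus the per-tilt
    pattern offset, mapped to the stage plane by dividing y by cos(alpha).
    With ``offsets=None`` a regular (no-shift) array acquisition is produced.
    """
    if dose_per_exposure <= 0:
        raise ValueError("dose per exposure must be positive")
    grid = tile_grid(pattern, frame)
    angles = generate_tilt_angles(scheme)
    if offsets is not None and len(offsets.table) != len(angles):
        raise ValueError("offset table length must match the tilt count")
    beam_off = (
        offsets.beam_offsets() if offsets is not None else np.zeros((len(angles), 2))
    )
    exposures = []
    for ti, ang in enumerate(angles):
        c = np.cos(np.radians(ang))
        sa, sb = footprint_at_tilt(beam, ang)
        for tile in range(pattern.n_tiles):
            bx = grid.image_shifts_um[tile, 0] + beam_off[ti, 0]
            by = grid.image_shifts_um[tile, 1] + beam_off[ti, 1]
            exposures.append(
                Exposure(
                    tilt_index=ti,
                    angle_deg=ang,
                    tile_index=tile,
                    center_x_um=bx,
                    center_y_um=by / c,
                    semi_x_um=sa,
                    semi_y_um=sb,
                    dose_e_A2=dose_per_exposure,
                )
            )
    return ExposurePlan(tuple(exposures))


def simulate(plan: ExposurePlan, canvas: StageCanvas | None = None) -> DoseMap:
    """Accumulate dose on the canvas, once per beam per intersected voxel.

    A voxel is intersected when its center lies inside the exposure's
    elliptical stage footprint.  An exposure whose footprint misses the
    canvas entirely contributes nothing (a warning is emitted).
    """
    canvas = canvas or StageCanvas()
    x, y = canvas.centers()
    X, Y = np.meshgrid(x, y)  # (ny, nx)
    dose = np.zeros((canvas.ny, canvas.nx), dtype=np.float64)
    for exp in plan:
        u = (X - exp.center_x_um) / exp.semi_x_um
        v = (Y - exp.center_y_um) / exp.semi_y_um
        inside = (u * u + v * v) <= 1.0
        if not inside.any():
            warnings.warn(
                f"exposure (tilt {exp.tilt_index}, tile {exp.tile_index}) "
                "falls entirely off the canvas",
                stacklevel=2,
            )
            continue
        dose[inside] += exp.dose_e_A2
    full = np.repeat(dose[:, :, None], canvas.nz, axis=2)
    return DoseMap(full, canvas)


def montage_regions(
    frame: CameraFrame,
    pattern: MontagePattern,
    canvas: StageCanvas,
) -> dict[str, np.ndarray]:
    """Region masks on the canvas for the 0-degree montage layout.

    Returns boolean ``(ny, nx)`` masks: ``roi`` (union of all tile frames),
    ``interior`` (covered by exactly one tile frame), ``overlap_x`` /
    ``overlap_y`` (bands shared by x- / y-adjacent frames).
    """
    grid = tile_grid(pattern, frame)
    fx, fy = frame.fov_um
    x, y = canvas.centers()
    X, Y = np.meshgrid(x, y)
    count = np.zeros_like(X, dtype=np.int32)
    overlap_x = np.zeros_like(X, dtype=bool)
    overlap_y = np.zeros_like(X, dtype=bool)
    rects = []
    for t in range(pattern.n_tiles):
        cx, cy = grid.image_shifts_um[t]
        m = (np.abs(X - cx) <= fx / 2) & (np.abs(Y - cy) <= fy / 2)
        rects.append(m)
        count += m
    for iy in range(pattern.n):
        for ix in range(pattern.m):
            t = grid.tile_index(ix, iy)
            if ix + 1 < pattern.m:
                overlap_x |= rects[t] & rects[grid.tile_index(ix + 1, iy)]
            if iy + 1 < pattern.n:
                overlap_y |= rects[t] & rects[grid.tile_index(ix, iy + 1)]
    roi = count > 0
    interior = count == 1
    return {"roi": roi, "interior": interior, "overlap_x": overlap_x, "overlap_y": overlap_y}


def dose_stats(
    dose_map: DoseMap, regions: dict[str, np.ndarray], bins: int = 32
) -> pd.DataFrame:
    """Min/mean/max/std of accumulated dose per region, with histograms.

    Region masks are 2D ``(ny, nx)`` booleans; statistics are taken over the
    central z slice (dose is uniform along z in this thin-canvas model).
    """
    plane = dose_map.dose[:, :, dose_map.canvas.nz // 2]
    rows = []
    hists = {}
    for name, mask in regions.items():
        vals = plane[mask]
        if vals.size == 0:
            raise ValueError(f"region {name!r} is empty on this canvas")
        rows.append(
            {
                "region": name,
                "n_voxels": int(vals.size),
                "min": float(vals.min()),
                "mean": float(vals.mean()),
                "max": float(vals.max()),
                "std": float(vals.std()),
            }
        )
        hists[name] = np.histogram(vals, bins=bins)
    df = pd.DataFrame(rows).set_index("region")
    df.attrs["histograms"] = hists
    return df


def overdose_mask(dose_map: DoseMap, threshold_e_per_A2: float) -> np.ndarray:
    """Boolean mask of voxels at or above the overdose threshold
    (e.g. 130 e-/A^2, about twice a typical dose tolerance)."""
    if threshold_e_per_A2 <= 0:
        raise ValueError("threshold must be positive")
    return dose_map.dose >= threshold_e_per_A2


def export_dose_csv(dose_map: DoseMap, path) -> None:
    """Write one row per voxel: i, j, k (x, y, z voxel indices) and dose."""
    c = dose_map.canvas
    jj, ii, kk = np.meshgrid(np.arange(c.ny), np.arange(c.nx), np.arange(c.nz), indexing="ij")
    df = pd.DataFrame(
        {
            "i": ii.ravel(),
            "j": jj.ravel(),
            "k": kk.ravel(),
            "dose": dose_map.dose.ravel(),
        }
    )
    df.to_csv(path, index=False)


def read_dose_csv(path, canvas: StageCanvas) -> DoseMap:
    """Inverse of :func:`export_dose_csv`."""
    df = pd.read_csv(path)
    dose = np.zeros((canvas.ny, canvas.nx, canvas.nz), dtype=np.float64)
    dose[df["j"].to_numpy(), df["i"].to_numpy(), df["k"].to_numpy()] = df["dose"].to_numpy()
    return DoseMap(dose, canvas)
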