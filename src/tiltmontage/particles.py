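"""Dose annotation and overdose filtering of sub-tomogram particle tables.

Montage overlap bands accumulate roughly twice the interior dose; particles
picked there carry degraded high-resolution signal and drag down sub-tomogram
averages.  Given the simulator's dose map for the matching acquisition plan,
each particle is annotated with the accumulated dose of the voxel containing
its stage position, and particles at or above an overdose threshold
(default 130 e-/A^2, at least twofold a typical dose tolerance) are removed.

Tables are plain comma-separated text with columns ``id, tile, x_px, y_px,
z_px, dose_e_A2, kept`` (plus whatever extra columns the caller carries,
e.g. orientations or correlation scores).  A convenience writer emits a
35-column Dynamo-style table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dose import DoseMap
from .pipeline import StitchResult

__all__ = [
    "OverdoseRule",
    "TileGeometry",
    "annotate_dose",
    "filter_overdosed",
    "map_to_montage",
    "write_dynamo_table",
]

REQUIRED_COLUMNS = ("id", "tile", "x_px", "y_px", "z_px")


@dataclass(frozen=True)
class OverdoseRule:
    """Removal threshold in e-/A^2; particles with dose >= threshold go."""

    threshold_e_per_A2: float = 130.0

    def __post_init__(self) -> None:
        if self.threshold_e_per_A2 <= 0:
            raise ValueError("threshold must be positive")


@dataclass(frozen=True)
class TileGeometry:
    """Mapping from tile-frame pixels to stage micrometres.

    ``tile_origins_um[tile]`` is the stage position of the tile's pixel
    (0, 0); a particle at pixel (x, y) of that tile sits at
    ``origin + (x, y) * pixel_size_A * 1e-4`` um.
    """

    tile_origins_um: dict[int, tuple[float, float]]
    pixel_size_A: float

    def stage_position_um(self, tile: int, x_px: float, y_px: float) -> tuple[float, float]:
        if tile not in self.tile_origins_um:
            raise KeyError(f"unknown tile id: {tile}")
        ox, oy = self.tile_origins_um[tile]
        s = self.pixel_size_A * 1e-4
        return (ox + x_px * s, oy + y_px * s)


def _validate(particles: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in particles.columns]
    if missing:
        raise ValueError(f"particle table missing columns: {missing}")
    if particles["id"].duplicated().any():
        raise ValueError("particle ids must be unique")


def annotate_dose(
    particles: pd.DataFrame, dose_map: DoseMap, geometry: TileGeometry
) -> pd.DataFrame:
    """Fill ``dose_e_A2`` with the dose of the voxel containing each particle.

    Lookup is nearest-voxel (particle extents are ignored; they are small
    relative to overlap bands).  Particles falling outside the canvas are
    flagged ``off_canvas=True`` with undefined (NaN) dose.
    """
    _validate(particles)
    out = particles.copy()
    c = dose_map.canvas
    vx, vy, _ = c.voxel_size_um
    doses = np.full(len(out), np.nan)
    off = np.zeros(len(out), dtype=bool)
    plane = dose_map.dose[:, :, c.nz // 2]
    for k, row in enumerate(out.itertuples()):
        sx, sy = geometry.stage_position_um(int(row.tile), float(row.x_px), float(row.y_px))
        i = int(np.floor((sx + c.extent_um[0] / 2) / vx))
        j = int(np.floor((sy + c.extent_um[1] / 2) / vy))
        if 0 <= i < c.nx and 0 <= j < c.ny:
            doses[k] = plane[j, i]
        else:
            off[k] = True
    out["dose_e_A2"] = doses
    out["off_canvas"] = off
    return out


def filter_overdosed(
    particles: pd.DataFrame, rule: OverdoseRule = OverdoseRule()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split an annotated table into (kept, removed) by the overdose rule.

    ``removed`` holds particles with dose >= threshold; the two outputs
    partition the input exactly.  Raises if any particle is unannotated.
    """
    if "dose_e_A2" not in particles.columns:
        raise ValueError("particles must be dose-annotated before filtering")
    if particles["dose_e_A2"].isna().any():
        raise ValueError("particle table contains unannotated (NaN) doses")
    over = particles["dose_e_A2"] >= rule.threshold_e_per_A2
    kept = particles.loc[~over].copy()
    removed = particles.loc[over].copy()
    kept["kept"] = True
    removed["kept"] = False
    return kept, removed


def map_to_montage(
    x_px: float, y_px: float, tile: int, stitch: StitchResult
) -> tuple[float, float]:
    """Tile-frame particle coordinates -> montage-frame coordinates.

    The montage coordinate is the tile coordinate plus the tile's refined
    stitch offset; :func:`map_from_montage` inverts it within rounding.
    """
    if not 0 <= tile < len(stitch.positions_px):
        raise KeyError(f"unknown tile id: {tile}")
    px, py = stitch.positions_px[tile]
    return (x_px + px, y_px + py)


def map_from_montage(
    mx_px: float, my_px: float, tile: int, stitch: StitchResult
) -> tuple[float, float]:
    """Inverse of :func:`map_to_montage`."""
    if not 0 <= tile < len(stitch.positions_px):
        raise KeyError(f"unknown tile id: {tile}")
    px, py = stitch.positions_px[tile]
    return (mx_px - px, my_px - py)


def write_dynamo_table(particles: pd.DataFrame, path) -> None:
    """Convenience writer: 35-column Dynamo-style table (space separated).

    Column 1 is the particle tag, columns 24-26 carry x/y/z coordinates;
    all other columns are zero.  Provided for downstream interoperability
    only — alignment and averaging are out of scope here.
    """
    _validate(particles)
    n = len(particles)
    tbl = np.zeros((n, 35))
    tbl[:, 0] = particles["id"].to_numpy()
    tbl[:, 23] = particles["x_px"].to_numpy()
    tbl[:, 24] = particles["y_px"].to_numpy()
    tbl[:, 25] = particles["z_px"].to_numpy()
    np.savetxt(path, tbl, fmt="%g")
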