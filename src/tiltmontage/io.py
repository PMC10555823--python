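"""On-disk layout for synthetic montage datasets.

A dataset directory holds ``frames.tif`` (one page per exposure),
``metadata.mdoc``, ``exposures.csv`` (tilt/tile index per page, angles) and
``piece_coords.csv`` (per-tilt nominal coordinates).  TIFF is used as the
stack container throughout the toolkit.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .geometry import CameraFrame, MontagePattern
from .pipeline import MontageDataset
from .serialem import read_mdoc, write_mdoc

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(dataset: MontageDataset, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(out / "frames.tif", dataset.frames.astype(np.float32))
    if dataset.mdoc is not None:
        (out / "metadata.mdoc").write_text(write_mdoc(dataset.mdoc))
    pd.DataFrame(
        {
            "exposure": np.arange(len(dataset.frames)),
            "tilt_index": dataset.exposure_tilt,
            "tile_index": dataset.exposure_tile,
            "angle_deg": dataset.tilt_angles[dataset.exposure_tilt],
        }
    ).to_csv(out / "exposures.csv", index=False)
    nt, ntile, _ = dataset.piece_coords_px.shape
    rows = []
    for t in range(nt):
        for j in range(ntile):
            rows.append(
                {
                    "tilt_index": t,
                    "angle_deg": dataset.tilt_angles[t],
                    "tile_index": j,
                    "x_px": dataset.piece_coords_px[t, j, 0],
                    "y_px": dataset.piece_coords_px[t, j, 1],
                }
            )
    pd.DataFrame(rows).to_csv(out / "piece_coords.csv", index=False)
    geom = pd.DataFrame(
        [
            {
                "width_px": dataset.camera.width_px,
                "height_px": dataset.camera.height_px,
                "pixel_size_A": dataset.camera.pixel_size_A,
                "m": dataset.pattern.m,
                "n": dataset.pattern.n,
                "overlap_x_px": dataset.pattern.overlap_x_px,
                "overlap_y_px": dataset.pattern.overlap_y_px,
            }
        ]
    )
    geom.to_csv(out / "geometry.csv", index=False)
    for name, df in dataset.ground_truth.items():
        if isinstance(df, pd.DataFrame):
            df.to_csv(out / f"truth_{name}.csv", index=False)
    return out


def load_dataset(in_dir) -> MontageDataset:
    d = Path(in_dir)
    frames = tifffile.imread(d / "frames.tif").astype(np.float64)
    if frames.ndim == 2:
        frames = frames[None]
    exp = pd.read_csv(d / "exposures.csv")
    geom = pd.read_csv(d / "geometry.csv").iloc[0]
    camera = CameraFrame(int(geom.width_px), int(geom.height_px), float(geom.pixel_size_A))
    pattern = MontagePattern(
        int(geom.m), int(geom.n), int(geom.overlap_x_px), int(geom.overlap_y_px)
    )
    pc = pd.read_csv(d / "piece_coords.csv")
    n_tilts = pc["tilt_index"].max() + 1
    n_tiles = pattern.n_tiles
    piece = np.zeros((n_tilts, n_tiles, 2))
    piece[pc["tilt_index"], pc["tile_index"], 0] = pc["x_px"]
    piece[pc["tilt_index"], pc["tile_index"], 1] = pc["y_px"]
    angles = (
        pc.drop_duplicates("tilt_index").sort_values("tilt_index")["angle_deg"].to_numpy()
    )
    mdoc_path = d / "metadata.mdoc"
    mdoc = read_mdoc(mdoc_path.read_text()) if mdoc_path.exists() else None
    return MontageDataset(
        frames=frames,
        tilt_angles=angles,
        exposure_tilt=exp["tilt_index"].to_numpy(),
        exposure_tile=exp["tile_index"].to_numpy(),
        pattern=pattern,
        camera=camera,
        piece_coords_px=piece,
        mdoc=mdoc,
    )
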