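"""Per-tilt translational offsets along an Archimedean spiral.

A montage acquisition re-exposes tile-overlap bands at every tilt, so those
bands accumulate roughly twice the interior dose.  Displacing the whole tile
pattern by a small, slowly growing spiral offset at each tilt spreads that
extra dose over a wider area.  The spiral is sampled in acquisition order,
starting at the origin so the 0-degree reference exposure is unshifted, and
is clamped so the largest radial offset stays within a set fraction of the
camera field of view (30% by default) and the ROI is retained across the
whole tilt range.

Offsets can be applied in two modes.  In *unadjusted* mode the beam-frame
offset equals the design point, so the stage-plane trajectory stretches along
y by 1/cos(alpha) at tilt alpha (larger physical displacements at high tilt).
In *adjusted* mode ("Adjust Shifts by Tilt Angle") the beam-frame y offset is
scaled by cos(alpha) so the stage-plane trajectory is identical at every tilt
to the 0-degree design.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import CameraFrame

__all__ = [
    "SpiralParams",
    "OffsetTable",
    "archimedean_points",
    "clamp_offsets",
    "offsets_for_tilts",
]

MODES = ("adjusted", "unadjusted")


@dataclass(frozen=True)
class SpiralParams:
    """Archimedean-spiral design parameters.

    ``A_final`` is the terminal amplitude in micrometres reached after
    ``turns`` spiral samples; ``revolutions`` is the total number of angular
    revolutions spread over those samples; ``period`` is the number of
    consecutive exposures that share one spiral sample (echoing grouped
    dose-symmetric tilting).  Defaults follow the benchmarked setting
    A_final=1.5, period=3, turns=50, revolutions=15.
    """

    A_final: float = 1.5
    period: int = 3
    turns: int = 50
    revolutions: float = 15.0

    def __post_init__(self) -> None:
        if self.A_final < 0:
            raise ValueError("A_final must be >= 0")
        if self.period < 1 or self.turns < 1:
            raise ValueError("period and turns must be >= 1")
        if self.revolutions < 0:
            raise ValueError("revolutions must be >= 0")


@dataclass(frozen=True)
class OffsetTable:
    """Per-tilt pattern offsets in acquisition order.

    ``table`` columns: ``tilt_index``, ``angle_deg``, ``dx_um``, ``dy_um``
    (the beam-frame offsets actually applied), plus ``stage_dx_um`` /
    ``stage_dy_um`` (the resulting stage-plane displacement at that tilt).
    """

    table: pd.DataFrame
    mode: str
    max_offset_um: float

    def beam_offsets(self) -> np.ndarray:
        return self.table[["dx_um", "dy_um"]].to_numpy()

    def stage_offsets(self) -> np.ndarray:
        return self.table[["stage_dx_um", "stage_dy_um"]].to_numpy()

    def to_csv(self, path) -> None:
        out = self.table[["tilt_index", "angle_deg", "dx_um", "dy_um"]].copy()
        out["mode"] = self.mode
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, max_offset_um: float = np.inf) -> "OffsetTable":
        df = pd.read_csv(path)
        mode = str(df["mode"].iloc[0])
        df = df.drop(columns=["mode"])
        c = np.cos(np.radians(df["angle_deg"].to_numpy()))
        df["stage_dx_um"] = df["dx_um"]
        df["stage_dy_um"] = df["dy_um"].to_numpy() / c if mode == "unadjusted" else df["dy_um"]
        return cls(df, mode, max_offset_um)


def archimedean_points(params: SpiralParams, n_tilts: int) -> np.ndarray:
    """Design offsets (dx, dy) in um at 0 degrees for ``n_tilts`` exposures.

    Exposure k uses spiral sample ``s_k = floor(k / period)`` with radius
    ``A_final * s_k / turns`` and angle ``2*pi*revolutions*s_k / turns``; the
    first point is the origin and the radius is non-decreasing in k.
    """
    if n_tilts < 1:
        raise ValueError("n_tilts must be >= 1")
    k = np.arange(n_tilts)
    s = k // params.period
    r = params.A_final * s / params.turns
    phi = 2.0 * np.pi * params.revolutions * s / params.turns
    return np.column_stack([r * np.cos(phi), r * np.sin(phi)])


def clamp_offsets(
    points: np.ndarray, frame: CameraFrame, fraction: float = 0.30
) -> tuple[np.ndarray, float]:
    """Scale offsets so the largest radial magnitude is at most
    ``fraction`` of the long-axis field of view.

    Returns ``(clamped_points, max_offset_um)`` where ``max_offset_um`` is
    the clamp radius actually enforced.  With a 5760-px long axis at
    4.603 A/px and the default 30% fraction the clamp is 0.795 um (~0.8 um).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    points = np.asarray(points, dtype=np.float64)
    long_fov_um = max(frame.fov_um)
    clamp = fraction * long_fov_um
    radii = np.hypot(points[:, 0], points[:, 1])
    rmax = radii.max() if len(radii) else 0.0
    if rmax > clamp:
        points = points * (clamp / rmax)
    return points, clamp


def offsets_for_tilts(
    points: np.ndarray,
    angles: list[float] | np.ndarray,
    mode: str = "adjusted",
    max_offset_um: float = np.inf,
) -> OffsetTable:
    """Turn 0-degree design points into per-tilt applied offsets.

    ``points`` must hold one design point per tilt, in acquisition order
    matching ``angles``.  See the module docstring for the two modes; x
    offsets are identical in both (the tilt axis is x).
    """
    if mode not in MODES:
        raise ValueError(f"unknown offset mode: {mode!r}")
    points = np.asarray(points, dtype=np.float64)
    angles = np.asarray(angles, dtype=np.float64)
    if points.shape[0] != angles.shape[0]:
        raise ValueError("need exactly one design point per tilt")
    c = np.cos(np.radians(angles))
    dx = points[:, 0]
    if mode == "adjusted":
        dy_beam = points[:, 1] * c
    else:
        dy_beam = points[:, 1].copy()
    stage_dy = dy_beam / c
    df = pd.DataFrame(
        {
            "tilt_index": np.arange(len(angles)),
            "angle_deg": angles,
            "dx_um": dx,
            "dy_um": dy_beam,
            "stage_dx_um": dx,
            "stage_dy_um": stage_dy,
        }
    )
    return OffsetTable(df, mode, float(max_offset_um))
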