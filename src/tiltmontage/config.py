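"""YAML acquisition-configuration loading.

Expected keys::

    camera:  {width_px, height_px, pixel_size_A}
    beam:    {diameter_um, fringe_fraction_x}
    pattern: {m, n, overlap_x_px, overlap_y_px}
    tilt:    {max_deg, increment_deg, group_size, style}
    spiral:  {A_final, period, turns, revolutions}    # optional
    dose_per_exposure: 1.0                            # optional, e-/A^2
    canvas:  {nx, ny, nz, extent_um: [x, y, z]}       # optional
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .dose import StageCanvas
from .geometry import BeamIllumination, CameraFrame, MontagePattern, TiltScheme
from .spiral import SpiralParams

__all__ = ["AcquisitionConfig", "load_config"]


@dataclass(frozen=True)
class AcquisitionConfig:
    camera: CameraFrame
    beam: BeamIllumination
    pattern: MontagePattern
    tilt: TiltScheme
    spiral: SpiralParams | None = None
    dose_per_exposure: float = 1.0
    canvas: StageCanvas = field(default_factory=StageCanvas)


def load_config(path) -> AcquisitionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    try:
        cam = CameraFrame(**raw["camera"])
        beam = BeamIllumination(**raw["beam"])
        pat = MontagePattern(**raw["pattern"])
        t = raw["tilt"]
        tilt = TiltScheme(
            max_angle_deg=t["max_deg"],
            increment_deg=t["increment_deg"],
            group_size=t.get("group_size", 1),
            style=t.get("style", "dose-symmetric"),
        )
    except KeyError as exc:
        raise ValueError(f"configuration missing required key: {exc}") from exc
    spiral = SpiralParams(**raw["spiral"]) if "spiral" in raw else None
    canvas = StageCanvas(
        nx=raw["canvas"]["nx"],
        ny=raw["canvas"]["ny"],
        nz=raw["canvas"].get("nz", 1),
        extent_um=tuple(raw["canvas"]["extent_um"]),
    ) if "canvas" in raw else StageCanvas()
    return AcquisitionConfig(
        camera=cam,
        beam=beam,
        pattern=pat,
        tilt=tilt,
        spiral=spiral,
        dose_per_exposure=float(raw.get("dose_per_exposure", 1.0)),
        canvas=canvas,
    )
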