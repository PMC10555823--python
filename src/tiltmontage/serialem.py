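"""Readers/writers for the acquisition-metadata dialects the workflow touches.

Three text formats:

* **mdoc** — SerialEM's per-exposure metadata sidecar: a global header of
  ``Key = value`` lines followed by ``[ZValue = n]`` sections, one per
  exposure, carrying TiltAngle, ImageShift, PieceCoordinates, ExposureDose
  and whatever else the acquisition software wrote.  Unknown keys are
  preserved verbatim on write.
* **piece lists** — IMOD-style ``x y z`` integer triples, one line per tile,
  one file per tilt; consumed by montage blending tools.
* **macros** — a descriptive SerialEM-like batch script enumerating per-tilt
  pattern offsets, tile image shifts, tracking thresholds and focus
  placement.  The macro encodes the plan faithfully and round-trips through
  :func:`parse_macro`, but is not guaranteed runnable on a microscope
  unmodified.

All writers are deterministic: identical inputs give byte-identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import CameraFrame, MontagePattern, TiltScheme, tile_grid
from .spiral import OffsetTable

__all__ = [
    "MdocSection",
    "MdocDocument",
    "read_mdoc",
    "write_mdoc",
    "export_macro",
    "parse_macro",
    "write_piece_lists",
    "read_piece_list",
]

MACRO_DIALECTS = ("3.8", "4.1")


def _fmt(value) -> str:
    """Deterministic mdoc/macro number formatting: ints as ints, floats with
    up to 6 significant digits in fixed notation."""
    if isinstance(value, str):
        return value
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        s = f"{value:.6g}"
        return s
    if isinstance(value, (tuple, list, np.ndarray)):
        return " ".join(_fmt(v) for v in value)
    return str(value)


@dataclass
class MdocSection:
    """One ``[ZValue = n]`` section: ordered key -> raw string value."""

    z_value: int
    entries: dict[str, str] = field(default_factory=dict)

    def get_floats(self, key: str) -> tuple[float, ...]:
        return tuple(float(v) for v in self.entries[key].split())

    def get_ints(self, key: str) -> tuple[int, ...]:
        return tuple(int(round(float(v))) for v in self.entries[key].split())

    @property
    def tilt_angle(self) -> float:
        return self.get_floats("TiltAngle")[0]

    @property
    def piece_coordinates(self) -> tuple[int, int, int]:
        x, y, z = self.get_ints("PieceCoordinates")
        return x, y, z

    @property
    def image_shift(self) -> tuple[float, float]:
        x, y = self.get_floats("ImageShift")
        return x, y


@dataclass
class MdocDocument:
    """Global header plus acquisition-ordered exposure sections."""

    header: dict[str, str] = field(default_factory=dict)
    sections: list[MdocSection] = field(default_factory=list)

    @property
    def pixel_spacing_A(self) -> float:
        return float(self.header["PixelSpacing"])

    def set_header(self, key: str, value) -> None:
        self.header[key] = _fmt(value)

    def add_section(self, z_value: int, **entries) -> MdocSection:
        sec = MdocSection(z_value, {k: _fmt(v) for k, v in entries.items()})
        self.sections.append(sec)
        return sec


MANDATORY_SECTION_KEYS = ("TiltAngle",)


def read_mdoc(text: str) -> MdocDocument:
    """Parse mdoc text.  Values are kept as raw strings so that unknown keys
    round-trip byte-identically; typed accessors live on the section."""
    doc = MdocDocument()
    current: dict[str, str] | None = doc.header
    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            inner = line[1:-1].strip()
            key, _, val = inner.partition("=")
            if key.strip() != "ZValue":
                raise ValueError(f"unsupported mdoc bracket section: {line!r}")
            sec = MdocSection(int(val.strip()))
            doc.sections.append(sec)
            current = sec.entries
            continue
        key, sep, val = line.partition("=")
        if not sep:
            raise ValueError(f"malformed mdoc line: {line!r}")
        current[key.strip()] = val.strip()
    for sec in doc.sections:
        for key in MANDATORY_SECTION_KEYS:
            if key not in sec.entries:
                raise ValueError(f"mdoc section [ZValue = {sec.z_value}] missing {key}")
    return doc


def write_mdoc(doc: MdocDocument) -> str:
    """Serialize; ``write_mdoc(read_mdoc(t))`` is stable on the retained keys."""
    out = io.StringIO()
    for key, val in doc.header.items():
        out.write(f"{key} = {val}\n")
    if doc.header:
        out.write("\n")
    for sec in doc.sections:
        out.write(f"[ZValue = {sec.z_value}]\n")
        for key, val in sec.entries.items():
            out.write(f"{key} = {val}\n")
        out.write("\n")
    return out.getvalue()


def export_macro(
    frame: CameraFrame,
    pattern: MontagePattern,
    scheme: TiltScheme,
    offsets: OffsetTable,
    dialect: str = "4.1",
    focus_offset_um: float = 1.3,
) -> str:
    """Emit a batch montage tilt-series macro.

    One block per tilt with the pattern's translational offset; a preamble
    records the tile image-shift vectors, the tracking thresholds (5% of the
    FOV below 30 degrees, 10% above, pause after 5 alignment iterations) and
    the autofocus/tracking placement along the tilt axis.
    """
    if dialect not in MACRO_DIALECTS:
        raise ValueError(f"unknown macro dialect: {dialect!r}")
    grid = tile_grid(pattern, frame)
    lines = [
        f"MacroName MontageTiltSeries_{dialect.replace('.', '_')}",
        f"# dialect {dialect}",
        f"SetMontage {pattern.m} {pattern.n} "
        f"{pattern.overlap_x_px} {pattern.overlap_y_px}",
        f"SetCamera {frame.width_px} {frame.height_px} {_fmt(frame.pixel_size_A)}",
        f"SetTiltScheme {_fmt(scheme.max_angle_deg)} {_fmt(scheme.increment_deg)} "
        f"{scheme.group_size} {scheme.style}",
        f"SetOffsetMode {offsets.mode}",
        "TrackingThreshold low 0.05",
        "TrackingThreshold high 0.10",
        "TrackingPauseAfter 5",
        f"FocusPositionAlongTiltAxis {_fmt(focus_offset_um)}",
    ]
    if dialect == "4.1":
        lines.append("MultipleRecordMontage 1")
    else:
        lines.append("MultishotParams FromSettingsFile")
    for t in range(pattern.n_tiles):
        sx, sy = grid.image_shifts_um[t]
        lines.append(f"TileImageShift {t} {float(sx)!r} {float(sy)!r}")
    for row in offsets.table.itertuples():
        lines.append(f"TiltBlock {int(row.tilt_index)} {float(row.angle_deg)!r}")
        lines.append(f"PatternOffset {float(row.dx_um)!r} {float(row.dy_um)!r}")
        lines.append("MultipleRecord" if dialect == "4.1" else "RunMultishot")
    lines.append("EndMacro")
    return "\n".join(lines) + "\n"


def parse_macro(text: str) -> dict:
    """Recover the plan encoded by :func:`export_macro`.

    Returns a dict with ``pattern``, ``scheme_fields``, ``mode``,
    ``tile_shifts_um`` and an :class:`OffsetTable`-compatible offsets frame
    (``tilt_index``, ``angle_deg``, ``dx_um``, ``dy_um``).
    """
    import pandas as pd

    out: dict = {"tile_shifts_um": {}}
    rows = []
    pending_tilt = None
    for line in text.splitlines():
        parts = line.split()
        if not parts or parts[0].startswith("#"):
            continue
        cmd = parts[0]
        if cmd == "SetMontage":
            m, n, ox, oy = (int(p) for p in parts[1:5])
            out["pattern"] = MontagePattern(m, n, ox, oy)
        elif cmd == "SetCamera":
            out["frame"] = CameraFrame(int(parts[1]), int(parts[2]), float(parts[3]))
        elif cmd == "SetTiltScheme":
            out["scheme_fields"] = {
                "max_angle_deg": float(parts[1]),
                "increment_deg": float(parts[2]),
                "group_size": int(parts[3]),
                "style": parts[4],
            }
        elif cmd == "SetOffsetMode":
            out["mode"] = parts[1]
        elif cmd == "TileImageShift":
            out["tile_shifts_um"][int(parts[1])] = (float(parts[2]), float(parts[3]))
        elif cmd == "TiltBlock":
            pending_tilt = (int(parts[1]), float(parts[2]))
        elif cmd == "PatternOffset":
            ti, ang = pending_tilt
            rows.append(
                {"tilt_index": ti, "angle_deg": ang, "dx_um": float(parts[1]), "dy_um": float(parts[2])}
            )
    out["offsets"] = pd.DataFrame(rows)
    return out


def write_piece_lists(
    piece_coords_px: np.ndarray,
    tilt_angles: list[float],
    out_dir,
    stem: str = "tilt",
) -> list[Path]:
    """One IMOD-style piece-list file per tilt, ordered by tilt angle.

    ``piece_coords_px`` is the ``(n_tiles, 3)`` integer array from the tile
    grid; the z column is overwritten with the section index of the tilt.
    """
    coords = np.asarray(piece_coords_px)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError("piece coordinates must be an (n_tiles, 3) array")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    order = np.argsort(np.asarray(tilt_angles), kind="stable")
    paths = []
    for rank, ti in enumerate(order):
        path = out_dir / f"{stem}_{rank:03d}.pl"
        with open(path, "w") as fh:
            for row in coords:
                fh.write(f"{int(row[0])} {int(row[1])} {int(ti)}\n")
        paths.append(path)
    return paths


def read_piece_list(path) -> np.ndarray:
    """Read an ``x y z`` piece-list file back into an (n, 3) int array."""
    return np.loadtxt(path, dtype=np.int64, ndmin=2)
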