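"""CSV dialects for FOF grids, ESS-sweep tables, readings, and profiles.

All files are UTF-8 CSV with decimal points; ``#``-prefixed lines carry
metadata as ``# key=value`` and may appear before the header.

Grid CSV mirrors the conventional printed layout of a 7 x 7 output-factor
table: the first header cell is ``X\\Y [cm]``, the remaining header cells
are the Y sides, and each data row starts with an X side — i.e. rows run
along the leaf-motion axis and columns along the leaf-side axis, while the
in-memory :class:`~smallfield.fof.FOFGrid` is indexed ``[y][x]``.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Mapping, TextIO

import numpy as np

from .fof import FOFGrid, ReadingSet
from .geometry import FieldSpec
from .profiles import Profile

__all__ = [
    "write_fof_grid",
    "read_fof_grid",
    "write_sweep_table",
    "read_sweep_table",
    "read_readings",
    "write_readings",
    "write_profile",
    "read_profile",
]

GRID_CORNER = "X\\Y [cm]"
SWEEP_CORNER = "ESSy\\ESSx"


def _fmt(v: float) -> str:
    return f"{v:g}"


def _split_meta(lines: list[str]) -> tuple[dict[str, str], list[str]]:
    meta: dict[str, str] = {}
    body: list[str] = []
    for line in lines:
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            payload = stripped.lstrip("#").strip()
            if "=" in payload:
                key, _, value = payload.partition("=")
                meta[key.strip()] = value.strip()
        else:
            body.append(line)
    return meta, body


def _open_lines(source) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text(encoding="utf-8").splitlines()


def write_fof_grid(grid: FOFGrid, destination, extra_meta: Mapping[str, str] | None = None) -> None:
    """Write a grid in the printed-table layout (rows = X, columns = Y)."""
    buf = _io.StringIO()
    meta = {"beam_quality": grid.beam_quality, "kind": grid.kind}
    if grid.convention:
        meta["convention"] = grid.convention
    meta.update(extra_meta or {})
    for key, value in meta.items():
        buf.write(f"# {key}={value}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([GRID_CORNER] + [_fmt(y) for y in grid.y_sides_cm])
    for ix, x in enumerate(grid.x_sides_cm):
        row = [_fmt(x)]
        for iy in range(len(grid.y_sides_cm)):
            v = grid.values[iy, ix]
            row.append("" if np.isnan(v) else repr(float(v)))
        writer.writerow(row)
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def read_fof_grid(source) -> FOFGrid:
    """Read a grid CSV written by :func:`write_fof_grid` (bit-exact round trip)."""
    meta, body = _split_meta(_open_lines(source))
    rows = list(csv.reader(body))
    if not rows or rows[0][0] != GRID_CORNER:
        raise ValueError(f"grid CSV must start with a {GRID_CORNER!r} header")
    y_sides = tuple(float(v) for v in rows[0][1:])
    x_sides = []
    values = np.full((len(y_sides), len(rows) - 1), np.nan)
    for ix, row in enumerate(rows[1:]):
        x_sides.append(float(row[0]))
        for iy, cell in enumerate(row[1:]):
            if cell.strip():
                values[iy, ix] = float(cell)
    kind = meta.get("kind", "measured")
    return FOFGrid(
        y_sides,
        tuple(x_sides),
        values,
        kind,  # type: ignore[arg-type]
        beam_quality=meta.get("beam_quality", "6X"),
        convention=meta.get("convention"),
    )


def write_sweep_table(
    table: "SweepTable", destination, extra_meta: Mapping[str, str] | None = None
) -> None:
    """Write a sparse ESS-sweep difference table (rows = ESSy, cols = ESSx)."""
    buf = _io.StringIO()
    meta = {
        "beam_quality": table.beam_quality,
        "field": table.field_label,
        "kind": "ess_sweep_difference_percent",
    }
    meta.update(extra_meta or {})
    for key, value in meta.items():
        buf.write(f"# {key}={value}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow([SWEEP_CORNER] + [_fmt(x) for x in table.essx_values])
    for y in table.essy_values:
        row = [_fmt(y)]
        for x in table.essx_values:
            v = table.entries.get((y, x))
            row.append("" if v is None else repr(float(v)))
        writer.writerow(row)
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def read_sweep_table(source) -> "SweepTable":
    from .benchmark import SweepTable

    meta, body = _split_meta(_open_lines(source))
    rows = list(csv.reader(body))
    if not rows or rows[0][0] != SWEEP_CORNER:
        raise ValueError(f"sweep CSV must start with a {SWEEP_CORNER!r} header")
    essx = tuple(float(v) for v in rows[0][1:])
    essy = []
    entries: dict[tuple[float, float], float] = {}
    for row in rows[1:]:
        y = float(row[0])
        essy.append(y)
        for x, cell in zip(essx, row[1:]):
            if cell.strip():
                entries[(y, x)] = float(cell)
    return SweepTable(
        field_label=meta.get("field", "?"),
        beam_quality=meta.get("beam_quality", "6X"),
        essy_values=tuple(essy),
        essx_values=essx,
        entries=entries,
    )


def read_readings(source, beam_quality: str = "6X") -> list[ReadingSet]:
    """Read a readings CSV: ``y_cm,x_cm,mean_reading,n_repeats,reading_sd``."""
    meta, body = _split_meta(_open_lines(source))
    beam_quality = meta.get("beam_quality", beam_quality)
    rows = list(csv.DictReader(body))
    out = []
    for row in rows:
        out.append(
            ReadingSet(
                field=FieldSpec(
                    float(row["y_cm"]), float(row["x_cm"]), beam_quality=beam_quality
                ),
                mean_reading=float(row["mean_reading"]),
                n_repeats=int(row.get("n_repeats") or 1),
                reading_sd=float(row.get("reading_sd") or 0.0),
            )
        )
    return out


def write_readings(readings: list[ReadingSet], destination) -> None:
    buf = _io.StringIO()
    if readings:
        buf.write(f"# beam_quality={readings[0].field.beam_quality.value}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["y_cm", "x_cm", "mean_reading", "n_repeats", "reading_sd"])
    for r in readings:
        writer.writerow(
            [_fmt(r.field.y_cm), _fmt(r.field.x_cm), repr(r.mean_reading), r.n_repeats, repr(r.reading_sd)]
        )
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def write_profile(profile: Profile, destination) -> None:
    """Write a profile CSV: ``position_mm,value`` with axis/field metadata."""
    buf = _io.StringIO()
    buf.write(f"# axis={profile.axis}\n")
    for key, value in profile.meta.items():
        buf.write(f"# {key}={value}\n")
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(["position_mm", "value"])
    for p, v in zip(profile.positions_mm, profile.values):
        writer.writerow([repr(float(p)), repr(float(v))])
    text = buf.getvalue()
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        Path(destination).write_text(text, encoding="utf-8")


def read_profile(source) -> Profile:
    meta, body = _split_meta(_open_lines(source))
    rows = list(csv.DictReader(body))
    pos = np.array([float(r["position_mm"]) for r in rows])
    val = np.array([float(r["value"]) for r in rows])
    axis = meta.pop("axis", "X")
    return Profile(positions_mm=pos, values=val, axis=axis, meta=meta)  # type: ignore[arg-type]
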