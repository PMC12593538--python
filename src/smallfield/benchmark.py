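"""Published TrueBeam HD-MLC small-field benchmark data (transcribed).

These tables transcribe a published commissioning benchmark for small
square and rectangular MLC fields on a Varian TrueBeam with HD-MLC
(fields 0.5–4 cm per side, jaws fixed at 4.4 x 4.4 cm^2, isocenter,
10 cm depth):

* measured field output factors (microDiamond, TRS-483 corrected) for the
  6X and 6FFF beams over the full 7 x 7 field matrix;
* calculated-minus-measured FOF percent differences for the same matrix
  with the dose engine configured at its optimal spot-size setting;
* spot-size sweep tables: FOF percent difference for the three most
  sensitive fields (4 x 0.5, 0.5 x 4, 0.5 x 0.5 cm^2, 6X) as a function of
  the ESSx/ESSy setting, sparse over the swept combinations.

They serve as reference fixtures: summary statistics, the optimizer
replayed against the sweep tables, and the fixture CSVs written by
:func:`emit_fixtures` all derive from them.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np

from .fof import DEFAULT_SIDES_CM, FOFGrid

__all__ = [
    "SweepTable",
    "measured_fof_grid",
    "fof_difference_grid",
    "sweep_table",
    "OPTIMAL_ESS_MM",
    "emit_fixtures",
]

_PROVENANCE = "published TrueBeam HD-MLC small-field benchmark (transcribed)"

# Printed layout: rows = X side, columns = Y side (0.5, 1, 1.5, 2, 2.5, 3, 4 cm).
_MEASURED_FOF_ROWS_X = {
    "6X": [
        [0.636, 0.686, 0.700, 0.705, 0.708, 0.710, 0.711],
        [0.737, 0.819, 0.845, 0.857, 0.865, 0.868, 0.872],
        [0.763, 0.858, 0.892, 0.908, 0.918, 0.924, 0.930],
        [0.773, 0.872, 0.912, 0.931, 0.943, 0.951, 0.958],
        [0.777, 0.880, 0.920, 0.945, 0.957, 0.965, 0.975],
        [0.779, 0.883, 0.927, 0.950, 0.965, 0.973, 0.984],
        [0.782, 0.888, 0.933, 0.959, 0.975, 0.985, 1.000],
    ],
    "6FFF": [
        [0.662, 0.705, 0.718, 0.723, 0.726, 0.727, 0.729],
        [0.757, 0.828, 0.852, 0.863, 0.869, 0.873, 0.877],
        [0.779, 0.863, 0.894, 0.907, 0.916, 0.922, 0.929],
        [0.787, 0.875, 0.910, 0.929, 0.938, 0.946, 0.955],
        [0.792, 0.882, 0.920, 0.940, 0.953, 0.960, 0.972],
        [0.794, 0.887, 0.926, 0.948, 0.962, 0.971, 0.983],
        [0.797, 0.893, 0.934, 0.958, 0.973, 0.984, 1.000],
    ],
}

# Calculated (optimal-ESS) minus measured FOF, percent; same layout.
_DIFF_ROWS_X = {
    "6X": [
        [0.2, 0.4, 0.2, 0.1, 0.1, 0.0, 0.0],
        [0.5, 0.7, 0.7, 0.5, 0.2, 0.1, 0.1],
        [0.2, 0.6, 0.5, 0.4, 0.1, 0.0, -0.1],
        [0.1, 0.6, 0.5, 0.4, 0.2, 0.0, 0.1],
        [0.1, 0.6, 0.6, 0.2, 0.2, 0.1, 0.0],
        [0.0, 0.6, 0.5, 0.4, 0.2, 0.2, 0.2],
        [0.0, 0.6, 0.6, 0.4, 0.2, 0.1, 0.0],
    ],
    "6FFF": [
        [1.0, 1.1, 0.9, 0.7, 0.6, 0.6, 0.5],
        [0.9, 1.0, 0.9, 0.6, 0.5, 0.3, 0.3],
        [0.7, 0.8, 0.7, 0.6, 0.4, 0.2, 0.2],
        [0.6, 0.8, 0.8, 0.6, 0.5, 0.3, 0.2],
        [0.4, 0.8, 0.7, 0.5, 0.3, 0.3, 0.1],
        [0.3, 0.7, 0.7, 0.5, 0.3, 0.2, 0.1],
        [0.2, 0.6, 0.6, 0.4, 0.3, 0.1, 0.0],
    ],
}

#: Benchmark-estimated optimal spot sizes (mm) per beam quality, as
#: (essx_interval, essy_interval).
OPTIMAL_ESS_MM: Mapping[str, tuple[tuple[float, float], tuple[float, float]]] = {
    "6X": ((0.7, 0.8), (0.7, 0.8)),
    "6FFF": ((0.7, 0.8), (0.7, 0.8)),
    "10X": ((0.6, 0.6), (0.7, 0.8)),
    "10FFF": ((0.3, 0.3), (0.4, 0.5)),
}

_ESS_AXIS = (0.0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.5)


@dataclass(frozen=True)
class SweepTable:
    """Sparse table of FOF percent differences over (ESSy, ESSx) settings.

    `entries` maps ``(essy_mm, essx_mm)`` to the calculated-minus-measured
    percent difference for one field; combinations that were not swept are
    absent.
    """

    field_label: str
    beam_quality: str
    essy_values: tuple[float, ...]
    essx_values: tuple[float, ...]
    entries: Mapping[tuple[float, float], float]

    def get(self, essy_mm: float, essx_mm: float) -> float:
        try:
            return self.entries[(essy_mm, essx_mm)]
        except KeyError:
            raise KeyError(
                f"no swept entry at (ESSy={essy_mm:g}, ESSx={essx_mm:g}) mm for "
                f"field {self.field_label} ({self.beam_quality})"
            ) from None

    def row(self, essy_mm: float) -> dict[float, float]:
        """All swept (essx -> difference) entries at a fixed ESSy."""
        return {x: v for (y, x), v in self.entries.items() if y == essy_mm}

    def column(self, essx_mm: float) -> dict[float, float]:
        """All swept (essy -> difference) entries at a fixed ESSx."""
        return {y: v for (y, x), v in self.entries.items() if x == essx_mm}


def _sweep(field_label: str, rows: dict[float, dict[float, float]]) -> SweepTable:
    entries = {(y, x): v for y, row in rows.items() for x, v in row.items()}
    return SweepTable(
        field_label=field_label,
        beam_quality="6X",
        essy_values=_ESS_AXIS,
        essx_values=_ESS_AXIS,
        entries=entries,
    )


_SWEEP_Y4_X05 = _sweep(
    "4 x 0.5",
    {
        0.0: {0.0: 1.10, 0.7: 1.11, 1.5: 1.17},
        0.4: {0.5: 0.75, 0.7: 0.76, 0.8: 0.76, 0.9: 0.77},
        0.5: {0.4: 0.75, 0.5: 0.75, 0.6: 0.75, 0.7: 0.76, 0.8: 0.76, 0.9: 0.77, 1.0: 0.72},
        0.6: {0.5: 0.60, 0.6: 0.60, 0.7: 0.61, 0.8: 0.61, 0.9: 0.61, 1.0: 0.56},
        0.7: {0.0: 0.03, 0.5: 0.03, 0.6: 0.03, 0.7: 0.01, 0.8: 0.01, 0.9: 0.01, 1.0: 0.02, 1.5: 0.07},
        0.8: {0.5: 0.03, 0.6: 0.03, 0.7: 0.01, 0.8: 0.01, 0.9: 0.01, 1.0: 0.02},
        0.9: {0.4: -0.83, 0.5: -0.83, 0.6: -0.83, 0.7: -0.84, 0.8: -0.84, 0.9: -0.84, 1.0: -0.84},
        1.0: {0.5: -0.85, 0.6: -0.85, 0.7: -0.85, 0.8: -0.85, 0.9: -0.85, 1.0: -0.87, 1.5: -0.80},
        1.5: {0.0: -6.11, 0.7: -6.09, 1.5: -1.55},
    },
)

_SWEEP_Y05_X4 = _sweep(
    "0.5 x 4",
    {
        0.0: {0.0: 2.60, 0.7: -0.03, 1.5: -11.29},
        0.4: {0.5: 1.42, 0.7: -0.03, 0.8: -0.03, 0.9: -1.90},
        0.5: {0.4: 1.42, 0.5: 1.42, 0.6: 1.18, 0.7: -0.03, 0.8: -0.03, 0.9: -1.90, 1.0: -1.96},
        0.6: {0.5: 1.42, 0.6: 1.18, 0.7: -0.03, 0.8: -0.03, 0.9: -1.90, 1.0: -1.96},
        0.7: {0.0: 2.65, 0.5: 1.45, 0.6: 1.21, 0.7: -0.02, 0.8: -0.02, 0.9: -1.90, 1.0: -1.91, 1.5: -11.29},
        0.8: {0.5: 1.45, 0.6: 1.21, 0.7: -0.02, 0.8: -0.02, 0.9: -1.90, 1.0: -1.91},
        0.9: {0.4: 1.45, 0.5: 1.45, 0.6: 1.21, 0.7: -0.02, 0.8: -0.02, 0.9: -1.91, 1.0: -1.91},
        1.0: {0.5: 1.43, 0.6: 1.19, 0.7: -0.04, 0.8: -0.04, 0.9: -1.92, 1.0: -1.93, 1.5: -11.30},
        1.5: {0.0: 2.69, 0.7: 0.05, 1.5: -11.20},
    },
)

_SWEEP_Y05_X05 = _sweep(
    "0.5 x 0.5",
    {
        0.0: {0.0: 4.06, 0.7: 1.39, 1.5: -10.52},
        0.4: {0.5: 2.30, 0.7: 0.84, 0.8: 0.84, 0.9: -1.09},
        0.5: {0.4: 2.30, 0.5: 2.30, 0.6: 2.07, 0.7: 0.84, 0.8: 0.84, 0.9: -1.09, 1.0: -1.16},
        0.6: {0.5: 2.51, 0.6: 1.95, 0.7: 0.73, 0.8: 0.73, 0.9: -1.20, 1.0: -1.27},
        0.7: {0.0: 3.12, 0.5: 1.94, 0.6: 1.70, 0.7: 0.19, 0.8: 0.19, 0.9: -1.72, 1.0: -1.73, 1.5: -11.56},
        0.8: {0.5: 1.94, 0.6: 1.70, 0.7: 0.19, 0.8: 0.19, 0.9: -1.72, 1.0: -1.73},
        0.9: {0.4: 1.04, 0.5: 1.04, 0.6: 0.81, 0.7: -0.63, 0.8: -0.63, 0.9: -2.53, 1.0: -2.54},
        1.0: {0.5: 1.03, 0.6: 0.80, 0.7: -0.64, 0.8: -0.64, 0.9: -2.55, 1.0: -2.56},
        1.5: {0.0: -3.58, 0.7: -6.01, 1.5: -16.94},
    },
)

_SWEEPS = {
    "4 x 0.5": _SWEEP_Y4_X05,
    "0.5 x 4": _SWEEP_Y05_X4,
    "0.5 x 0.5": _SWEEP_Y05_X05,
}


def _rows_to_grid(rows_x: list[list[float]], kind: str, quality: str, convention=None) -> FOFGrid:
    # printed rows run along X, columns along Y; FOFGrid is indexed [y][x]
    values = np.asarray(rows_x, dtype=float).T
    return FOFGrid(
        DEFAULT_SIDES_CM, DEFAULT_SIDES_CM, values, kind,  # type: ignore[arg-type]
        beam_quality=quality, convention=convention,
    )


def measured_fof_grid(beam_quality: str = "6X") -> FOFGrid:
    """Benchmark measured FOF grid (microDiamond, TRS-483 corrected)."""
    try:
        rows = _MEASURED_FOF_ROWS_X[beam_quality]
    except KeyError:
        raise KeyError(
            f"no transcribed measured grid for {beam_quality!r}; available: "
            f"{sorted(_MEASURED_FOF_ROWS_X)}"
        ) from None
    return _rows_to_grid(rows, "measured", beam_quality)


def fof_difference_grid(beam_quality: str = "6X") -> FOFGrid:
    """Benchmark calculated-minus-measured difference grid at optimal ESS (%)."""
    try:
        rows = _DIFF_ROWS_X[beam_quality]
    except KeyError:
        raise KeyError(
            f"no transcribed difference grid for {beam_quality!r}; available: "
            f"{sorted(_DIFF_ROWS_X)}"
        ) from None
    return _rows_to_grid(rows, "difference_percent", beam_quality, convention="printed")


def sweep_table(field_label: str) -> SweepTable:
    """Benchmark ESS-sweep difference table for one of the three sensitive fields.

    `field_label` is one of ``"4 x 0.5"``, ``"0.5 x 4"``, ``"0.5 x 0.5"`` (6X).
    """
    try:
        return _SWEEPS[field_label]
    except KeyError:
        raise KeyError(
            f"no sweep table for field {field_label!r}; available: {sorted(_SWEEPS)}"
        ) from None


def emit_fixtures(destination) -> list[Path]:
    """Write every transcribed benchmark table as CSV under `destination`.

    Files: ``measured_fof_{6x,6fff}.csv``, ``fof_diff_optimal_ess_{6x,6fff}.csv``,
    and ``ess_sweep_diff_6x_{y4_x05,y05_x4,y05_x05}.csv``.  Returns the
    written paths.
    """
    from .gridio import write_fof_grid, write_sweep_table

    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    meta = {"source": _PROVENANCE}
    written = []
    for quality in ("6X", "6FFF"):
        tag = quality.lower()
        path = dest / f"measured_fof_{tag}.csv"
        write_fof_grid(measured_fof_grid(quality), path, extra_meta=meta)
        written.append(path)
        path = dest / f"fof_diff_optimal_ess_{tag}.csv"
        write_fof_grid(fof_difference_grid(quality), path, extra_meta=meta)
        written.append(path)
    tags = {"4 x 0.5": "y4_x05", "0.5 x 4": "y05_x4", "0.5 x 0.5": "y05_x05"}
    for label, tag in tags.items():
        path = dest / f"ess_sweep_diff_6x_{tag}.csv"
        write_sweep_table(sweep_table(label), path, extra_meta=meta)
        written.append(path)
    return written
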