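"""Field-output-factor (FOF) computation and grid analysis.

The FOF of a clinical test field relative to a machine-specific reference
(msr) field — here the intermediate 4 x 4 cm^2 MLC field — is the corrected
reading ratio

.. math:: \\Omega = \\frac{M_{clin}}{M_{msr}} \\, k

where k is the detector's output correction factor at the equivalent
square side of the test field.  Grids of FOFs over the 7 x 7 matrix of
rectangular fields (sides 0.5–4 cm), calculated-minus-measured difference
grids, and their summary statistics are the working objects of the
effective-spot-size tuning procedure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

from .geometry import EquivalentSquare, FieldSpec

__all__ = [
    "DEFAULT_SIDES_CM",
    "MSR_SIDE_CM",
    "ReadingSet",
    "FOFMeasurement",
    "FOFGrid",
    "DiffSummary",
    "compute_fof",
    "build_fof_grid",
    "difference_grid",
    "summarize_diff",
    "extreme_field_differences",
    "round_half_away",
]

#: The field sides (cm) of the benchmark design: 7 x 7 = 49 settings.
DEFAULT_SIDES_CM: tuple[float, ...] = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)

#: Machine-specific reference (intermediate) field side, cm.
MSR_SIDE_CM = 4.0

GridKind = Literal["measured", "calculated", "difference_percent"]


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (display convention for percent tables)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)


@dataclass(frozen=True)
class ReadingSet:
    """Repeated detector readings for one field (mean, count, spread)."""

    field: FieldSpec
    mean_reading: float
    n_repeats: int = 3
    reading_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mean_reading <= 0:
            raise ValueError(f"mean reading must be > 0, got {self.mean_reading}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.reading_sd < 0:
            raise ValueError("reading_sd must be >= 0")


@dataclass(frozen=True)
class FOFMeasurement:
    """One field output factor with the correction that produced it."""

    field: FieldSpec
    fof: float
    esf: EquivalentSquare | None = None
    ocf_applied: float = 1.0

    def __post_init__(self) -> None:
        if self.fof <= 0:
            raise ValueError(f"FOF must be > 0, got {self.fof}")


@dataclass(frozen=True)
class FOFGrid:
    """Matrix of output factors (or percent differences) over Y x X sides.

    `values` is indexed ``[iy, ix]`` following the Y-then-X field naming;
    gaps are NaN.  For measured/calculated grids all values lie in (0, 1.2]
    and the msr cell (when on the axes) equals 1 by normalization.
    """

    y_sides_cm: tuple[float, ...]
    x_sides_cm: tuple[float, ...]
    values: np.ndarray
    kind: GridKind
    beam_quality: str = "6X"
    convention: str | None = None  # for difference grids: 'relative' | 'absolute'
    msr_side_cm: float = MSR_SIDE_CM

    def __post_init__(self) -> None:
        y = np.asarray(self.y_sides_cm, float)
        x = np.asarray(self.x_sides_cm, float)
        if not (np.all(np.diff(y) > 0) and np.all(np.diff(x) > 0)):
            raise ValueError("grid axes must be strictly increasing")
        vals = np.asarray(self.values, float)
        if vals.shape != (len(y), len(x)):
            raise ValueError(
                f"values shape {vals.shape} does not match axes ({len(y)}, {len(x)})"
            )
        object.__setattr__(self, "values", vals)
        if self.kind not in ("measured", "calculated", "difference_percent"):
            raise ValueError(f"unknown grid kind {self.kind!r}")
        if self.kind != "difference_percent":
            filled = vals[~np.isnan(vals)]
            if filled.size and not ((filled > 0).all() and (filled <= 1.2).all()):
                raise ValueError("output factors must lie in (0, 1.2]")
            iy, ix = self._msr_index()
            if iy is not None and not np.isnan(vals[iy, ix]):
                if abs(vals[iy, ix] - 1.0) > 1e-9:
                    raise ValueError(
                        f"msr cell ({self.msr_side_cm} x {self.msr_side_cm}) must equal "
                        f"1.0 by normalization, got {vals[iy, ix]}"
                    )

    def _msr_index(self) -> tuple[int | None, int | None]:
        try:
            iy = self.y_sides_cm.index(self.msr_side_cm)
            ix = self.x_sides_cm.index(self.msr_side_cm)
        except ValueError:
            return None, None
        return iy, ix

    @property
    def is_complete(self) -> bool:
        return not np.isnan(self.values).any()

    @property
    def n_cells(self) -> int:
        return self.values.size

    def cell(self, y_cm: float, x_cm: float) -> float:
        """Value at the (y, x) cell; KeyError if the sides are off-axis."""
        try:
            iy = self.y_sides_cm.index(y_cm)
            ix = self.x_sides_cm.index(x_cm)
        except ValueError as exc:
            raise KeyError(f"field ({y_cm} x {x_cm}) cm not on the grid axes") from exc
        return float(self.values[iy, ix])

    def gaps(self) -> list[tuple[float, float]]:
        """(y, x) sides of unfilled cells."""
        iy, ix = np.nonzero(np.isnan(self.values))
        return [(self.y_sides_cm[i], self.x_sides_cm[j]) for i, j in zip(iy, ix)]


@dataclass(frozen=True)
class DiffSummary:
    """Mean +/- SD and range of a percent-difference grid."""

    mean_pct: float
    sd_pct: float
    min_pct: float
    max_pct: float
    n_cells: int
    excluded_msr: bool = False

    def rounded(self, ndigits: int = 1) -> "DiffSummary":
        return DiffSummary(
            round_half_away(self.mean_pct, ndigits),
            round_half_away(self.sd_pct, ndigits),
            round_half_away(self.min_pct, ndigits),
            round_half_away(self.max_pct, ndigits),
            self.n_cells,
            self.excluded_msr,
        )

    def __str__(self) -> str:
        return (
            f"{self.mean_pct:+.1f}% ± {self.sd_pct:.1f}% "
            f"[{self.min_pct:+.1f}%, {self.max_pct:+.1f}%] (n={self.n_cells})"
        )


def compute_fof(
    reading_clin: ReadingSet,
    reading_msr: ReadingSet,
    ocf: float = 1.0,
    esf: EquivalentSquare | None = None,
) -> FOFMeasurement:
    """FOF of a test field: corrected reading ratio (M_clin / M_msr) * OCF.

    The correction factor must lie within the 5%-from-unity validity band;
    out-of-band factors are rejected rather than applied.
    """
    if reading_msr.mean_reading <= 0:
        raise ValueError("msr reading must be > 0")
    if not 0.95 <= ocf <= 1.05:
        raise ValueError(
            f"OCF {ocf} outside the validity band [0.95, 1.05]; factors further "
            "from unity are not used"
        )
    fof = reading_clin.mean_reading / reading_msr.mean_reading * ocf
    return FOFMeasurement(field=reading_clin.field, fof=fof, esf=esf, ocf_applied=ocf)


def build_fof_grid(
    measurements: Iterable[FOFMeasurement],
    y_sides_cm: Sequence[float] = DEFAULT_SIDES_CM,
    x_sides_cm: Sequence[float] = DEFAULT_SIDES_CM,
    kind: GridKind = "measured",
    beam_quality: str | None = None,
) -> tuple[FOFGrid, list[tuple[float, float]]]:
    """Place measurements on a (Y, X) grid; returns the grid and its gap list.

    Each measurement must map to a unique on-axis cell; duplicates and
    off-axis sides are errors.  Missing cells are NaN and reported.
    """
    y_sides = tuple(float(v) for v in y_sides_cm)
    x_sides = tuple(float(v) for v in x_sides_cm)
    values = np.full((len(y_sides), len(x_sides)), np.nan)
    quality = beam_quality
    for m in measurements:
        try:
            iy = y_sides.index(m.field.y_cm)
            ix = x_sides.index(m.field.x_cm)
        except ValueError as exc:
            raise ValueError(
                f"field {m.field.label} cm is not on the grid axes"
            ) from exc
        if not np.isnan(values[iy, ix]):
            raise ValueError(f"duplicate measurement for cell {m.field.label} cm")
        values[iy, ix] = m.fof
        if quality is None:
            quality = m.field.beam_quality.value
    grid = FOFGrid(y_sides, x_sides, values, kind, beam_quality=quality or "6X")
    return grid, grid.gaps()


def difference_grid(
    calc: FOFGrid,
    meas: FOFGrid,
    convention: Literal["relative", "absolute"] = "relative",
) -> FOFGrid:
    """Cellwise percent difference between a calculated and a measured grid.

    ``relative`` (default): 100 * (calc - meas) / meas.
    ``absolute``: 100 * (calc - meas), i.e. percentage points of the msr dose.
    """
    if calc.y_sides_cm != meas.y_sides_cm or calc.x_sides_cm != meas.x_sides_cm:
        raise ValueError("calculated and measured grids have different axes")
    if not (calc.is_complete and meas.is_complete):
        raise ValueError("difference requires complete grids")
    if calc.kind != "calculated" or meas.kind != "measured":
        raise ValueError(
            f"expected kinds (calculated, measured), got ({calc.kind}, {meas.kind})"
        )
    if convention == "relative":
        diff = 100.0 * (calc.values - meas.values) / meas.values
    elif convention == "absolute":
        diff = 100.0 * (calc.values - meas.values)
    else:
        raise ValueError(f"unknown percent-difference convention {convention!r}")
    return FOFGrid(
        calc.y_sides_cm,
        calc.x_sides_cm,
        diff,
        "difference_percent",
        beam_quality=calc.beam_quality,
        convention=convention,
    )


def summarize_diff(diff: FOFGrid, exclude_msr: bool = False) -> DiffSummary:
    """Mean, sample SD (n-1), min and max of a percent-difference grid.

    With `exclude_msr` the trivially-zero reference cell is left out of the
    statistics (the reference field is identically self-normalized, so its
    difference carries no information).
    """
    if diff.kind != "difference_percent":
        raise ValueError("summary requires a difference_percent grid")
    if not diff.is_complete:
        raise ValueError("summary requires a complete grid")
    vals = diff.values.copy()
    excluded = False
    if exclude_msr:
        iy, ix = diff._msr_index()
        if iy is not None:
            vals[iy, ix] = np.nan
            excluded = True
    flat = vals[~np.isnan(vals)]
    if flat.size == 0:
        raise ValueError("no cells to summarize")
    sd = float(np.std(flat, ddof=1)) if flat.size > 1 else 0.0
    return DiffSummary(
        mean_pct=float(np.mean(flat)),
        sd_pct=sd,
        min_pct=float(np.min(flat)),
        max_pct=float(np.max(flat)),
        n_cells=int(flat.size),
        excluded_msr=excluded,
    )


def extreme_field_differences(diff: FOFGrid) -> tuple[float, float]:
    """Differences at the two extreme elongated fields.

    Returns ``(d(4 x 0.5), d(0.5 x 4))`` in Y-times-X naming: first the
    field narrow along the leaf-motion X axis (most sensitive to the X
    spot size), then the field narrow along the leaf-side Y axis (most
    sensitive to the Y spot size).  These two cells drive the spot-size
    optimization objective.
    """
    lo, hi = 0.5, 4.0
    try:
        d_x = diff.cell(hi, lo)  # y = 4, x = 0.5
        d_y = diff.cell(lo, hi)  # y = 0.5, x = 4
    except KeyError as exc:
        raise ValueError(f"extreme field missing from the grid: {exc}") from exc
    if math.isnan(d_x) or math.isnan(d_y):
        raise ValueError("extreme field cell is an unfilled gap")
    return d_x, d_y
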