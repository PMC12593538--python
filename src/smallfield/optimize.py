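"""Sequential and joint effective-spot-size (ESS) optimization.

The spot sizes are tuned against the two extreme elongated fields of the
7 x 7 matrix: the 4 x 0.5 cm^2 field (narrow along the leaf-motion X axis,
most sensitive to ESSx) and the 0.5 x 4 cm^2 field (narrow along the
leaf-side Y axis, most sensitive to ESSy).  The sequential procedure:

1. start from the vendor suggestion (ESSx = 0.5 mm, ESSy = 0.7 mm);
2. vary ESSx with ESSy fixed — the ESSx with the smallest absolute
   calculated-minus-measured FOF difference for the 4 x 0.5 field is ESSx';
3. vary ESSy with ESSx = ESSx' — the ESSy minimizing the 0.5 x 4 field
   difference is ESSy'.

Candidates whose objective lies within a tie tolerance of the minimum are
reported as an interval (dose engines quantize the spot size internally,
so adjacent candidates can give identical dose), and an exhaustive joint
grid search is available as a cross-check of the sequential result.

The calculation engine behind the optimizer is abstract: the synthetic
forward model, a set of precomputed per-ESS FOF grids exported from a real
planning system, or a transcribed sweep table can all drive it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Protocol, Sequence

import numpy as np

from .benchmark import SweepTable
from .engine import DEFAULT_GEOMETRY, DEFAULT_KERNEL, BeamGeometry, ESSPair, ScatterKernel, simulate_fof_grid
from .fof import FOFGrid, difference_grid, extreme_field_differences

__all__ = [
    "DEFAULT_CANDIDATES_MM",
    "VENDOR_START_MM",
    "ESSGridSpec",
    "TraceRow",
    "SweepResult",
    "OptimizationResult",
    "OptimizationError",
    "ExtremeFieldEvaluator",
    "SyntheticEvaluator",
    "SweepTableEvaluator",
    "PrecomputedGridEvaluator",
    "sweep_extreme_fields",
    "optimize_sequential",
    "optimize_joint",
    "sign_diagnosis",
    "SignReport",
]

log = logging.getLogger(__name__)

#: Candidate spot sizes (mm): 0–1.5 with finer 0.1 mm increments between
#: 0.5 and 1.0 mm.
DEFAULT_CANDIDATES_MM: tuple[float, ...] = (0.0, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.5)

#: Vendor-suggested starting point (ESSx, ESSy) in mm, MLC in field.
VENDOR_START_MM: tuple[float, float] = (0.5, 0.7)


class OptimizationError(RuntimeError):
    """No candidate could be evaluated, or the optimum is undefined."""


@dataclass(frozen=True)
class ESSGridSpec:
    """Candidate grid and the objective-space tie tolerance.

    `tie_tolerance_pct` (percentage points of FOF difference) declares two
    candidates equivalent when their objectives are this close; tied
    candidates are reported as an interval.
    """

    values_mm: tuple[float, ...] = DEFAULT_CANDIDATES_MM
    tie_tolerance_pct: float = 0.02

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values_mm)
        if len(vals) < 2 or any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("candidate values must be strictly increasing (>= 2 values)")
        if not all(0.0 <= v <= 5.0 for v in vals):
            raise ValueError("candidates must lie within [0, 5] mm")
        if self.tie_tolerance_pct < 0:
            raise ValueError("tie tolerance must be >= 0")
        object.__setattr__(self, "values_mm", vals)

    def step_of(self, value_mm: float) -> int:
        return self.values_mm.index(value_mm)


@dataclass(frozen=True)
class TraceRow:
    """One evaluated (ESSx, ESSy) with its two extreme-field differences."""

    essx_mm: float
    essy_mm: float
    diff_4x05_pct: float | None  # calc-meas at the (y=4, x=0.5) cell
    diff_05x4_pct: float | None  # calc-meas at the (y=0.5, x=4) cell
    failed: bool = False
    note: str = ""


@dataclass(frozen=True)
class SweepResult:
    """Rows of one axis sweep, ordered by the varied candidate."""

    axis: Literal["x", "y"]
    fixed_mm: float
    rows: tuple[TraceRow, ...]

    def varied(self, row: TraceRow) -> float:
        return row.essx_mm if self.axis == "x" else row.essy_mm

    def objective(self, row: TraceRow) -> float | None:
        d = row.diff_4x05_pct if self.axis == "x" else row.diff_05x4_pct
        return None if d is None else abs(d)


@dataclass(frozen=True)
class OptimizationResult:
    """Optimal spot sizes, possibly interval-valued, with the full trace."""

    essx_mm: tuple[float, float]
    essy_mm: tuple[float, float]
    essx_best: float
    essy_best: float
    residual_4x05_pct: float
    residual_05x4_pct: float
    trace: tuple[TraceRow, ...]
    objective: Literal["sequential", "joint_max_abs", "joint_sum_abs"]

    def as_dict(self) -> dict:
        return {
            "essx_mm": list(self.essx_mm),
            "essy_mm": list(self.essy_mm),
            "essx_best": self.essx_best,
            "essy_best": self.essy_best,
            "residual_4x05_pct": self.residual_4x05_pct,
            "residual_05x4_pct": self.residual_05x4_pct,
            "objective": self.objective,
            "trace": [
                {
                    "essx_mm": r.essx_mm,
                    "essy_mm": r.essy_mm,
                    "diff_4x05_pct": r.diff_4x05_pct,
                    "diff_05x4_pct": r.diff_05x4_pct,
                    "failed": r.failed,
                    "note": r.note,
                }
                for r in self.trace
            ],
        }


class ExtremeFieldEvaluator(Protocol):
    """Anything that maps an ESS pair to the two extreme-field differences."""

    def extreme_differences(self, ess: ESSPair) -> tuple[float, float]:
        """Return (diff at 4 x 0.5, diff at 0.5 x 4) in percent."""
        ...


class SyntheticEvaluator:
    """Drives the optimizer with the synthetic forward model.

    Differences are computed against a fixed measured grid using the
    relative percent convention.
    """

    def __init__(
        self,
        measured: FOFGrid,
        kernel: ScatterKernel = DEFAULT_KERNEL,
        geometry: BeamGeometry = DEFAULT_GEOMETRY,
    ):
        if not measured.is_complete:
            raise ValueError("measured grid must be complete")
        self.measured = measured
        self.kernel = kernel
        self.geometry = geometry

    def calculated_grid(self, ess: ESSPair) -> FOFGrid:
        return simulate_fof_grid(
            ess, self.kernel, self.geometry,
            self.measured.y_sides_cm, self.measured.x_sides_cm,
            self.measured.msr_side_cm, self.measured.beam_quality,
        )

    def extreme_differences(self, ess: ESSPair) -> tuple[float, float]:
        diff = difference_grid(self.calculated_grid(ess), self.measured)
        return extreme_field_differences(diff)


class SweepTableEvaluator:
    """Drives the optimizer with precomputed sweep difference tables.

    Takes the table for the 4 x 0.5 field and the table for the 0.5 x 4
    field; combinations absent from a table raise KeyError, which the
    sweep records as a failed row.
    """

    def __init__(self, table_4x05: SweepTable, table_05x4: SweepTable):
        self.table_4x05 = table_4x05
        self.table_05x4 = table_05x4

    def extreme_differences(self, ess: ESSPair) -> tuple[float, float]:
        return (
            self.table_4x05.get(ess.essy_mm, ess.essx_mm),
            self.table_05x4.get(ess.essy_mm, ess.essx_mm),
        )


class PrecomputedGridEvaluator:
    """Drives the optimizer with per-ESS calculated grids stored on disk.

    Looks for files named ``ess_<essx>_<essy>.csv`` (grid CSV dialect)
    under `directory`, as exported from a planning system, and compares
    each against the measured grid.
    """

    def __init__(self, directory, measured: FOFGrid):
        self.directory = Path(directory)
        self.measured = measured

    def extreme_differences(self, ess: ESSPair) -> tuple[float, float]:
        from .gridio import read_fof_grid

        path = self.directory / f"ess_{ess.essx_mm:g}_{ess.essy_mm:g}.csv"
        if not path.exists():
            raise FileNotFoundError(f"no precomputed grid for {path.name}")
        calc = read_fof_grid(path)
        diff = difference_grid(calc, self.measured)
        return extreme_field_differences(diff)


def _evaluate(engine: ExtremeFieldEvaluator, essx: float, essy: float) -> TraceRow:
    try:
        d_x, d_y = engine.extreme_differences(ESSPair(essx, essy))
    except Exception as exc:  # failed candidates are recorded, not fatal
        return TraceRow(essx, essy, None, None, failed=True, note=str(exc))
    return TraceRow(essx, essy, d_x, d_y)


def sweep_extreme_fields(
    engine: ExtremeFieldEvaluator,
    candidates: ESSGridSpec,
    vary: Literal["x", "y"],
    fixed_mm: float,
) -> SweepResult:
    """Evaluate every candidate of one axis with the other axis fixed.

    A pure function of its inputs: re-running with the same engine and
    candidates yields an identical trace.  Engine failures become failed
    rows; the sweep continues.
    """
    rows = []
    for v in candidates.values_mm:
        essx, essy = (v, fixed_mm) if vary == "x" else (fixed_mm, v)
        rows.append(_evaluate(engine, essx, essy))
    return SweepResult(axis=vary, fixed_mm=fixed_mm, rows=tuple(rows))


def _tied_interval(
    sweep: SweepResult, tie_tolerance_pct: float
) -> tuple[tuple[float, float], float, float]:
    """(interval, best value, best objective) of one completed sweep."""
    scored = [
        (sweep.objective(r), sweep.varied(r)) for r in sweep.rows if not r.failed
    ]
    if not scored:
        raise OptimizationError(
            f"every candidate failed in the ESS{sweep.axis} sweep at "
            f"{sweep.fixed_mm:g} mm fixed"
        )
    best_obj, best_val = min(scored)
    tied = [v for obj, v in scored if obj <= best_obj + tie_tolerance_pct]
    return (min(tied), max(tied)), best_val, best_obj


def optimize_sequential(
    engine: ExtremeFieldEvaluator,
    candidates: ESSGridSpec = ESSGridSpec(),
    start_mm: tuple[float, float] = VENDOR_START_MM,
) -> OptimizationResult:
    """Two-step sequential spot-size determination.

    Step 1 fixes ESSy at the starting value and picks the ESSx minimizing
    the absolute difference at the 4 x 0.5 field; step 2 fixes that ESSx
    and picks the ESSy minimizing the 0.5 x 4 field difference.  Tied
    candidates (within the tie tolerance) form the reported intervals; the
    tie-break for the value carried into step 2 is the smallest objective,
    then the smaller candidate.
    """
    sweep_x = sweep_extreme_fields(engine, candidates, "x", start_mm[1])
    ix, essx_best, _ = _tied_interval(sweep_x, candidates.tie_tolerance_pct)
    sweep_y = sweep_extreme_fields(engine, candidates, "y", essx_best)
    iy, essy_best, _ = _tied_interval(sweep_y, candidates.tie_tolerance_pct)

    opt_row = next(
        r for r in sweep_y.rows if not r.failed and r.essy_mm == essy_best
    )
    return OptimizationResult(
        essx_mm=ix,
        essy_mm=iy,
        essx_best=essx_best,
        essy_best=essy_best,
        residual_4x05_pct=opt_row.diff_4x05_pct,
        residual_05x4_pct=opt_row.diff_05x4_pct,
        trace=sweep_x.rows + sweep_y.rows,
        objective="sequential",
    )


def optimize_joint(
    engine: ExtremeFieldEvaluator,
    candidates: ESSGridSpec = ESSGridSpec(),
    objective: Literal["max_abs", "sum_abs"] = "max_abs",
) -> OptimizationResult:
    """Exhaustive search over the candidate product grid.

    Minimizes ``max(|d1|, |d2|)`` or ``|d1| + |d2|`` of the two extreme
    fields; the bounding intervals of the tied set are reported.  Serves
    as a cross-check of the sequential procedure.
    """
    if objective not in ("max_abs", "sum_abs"):
        raise ValueError(f"unknown joint objective {objective!r}")
    rows = [
        _evaluate(engine, x, y)
        for y in candidates.values_mm
        for x in candidates.values_mm
    ]
    scalar = {
        "max_abs": lambda r: max(abs(r.diff_4x05_pct), abs(r.diff_05x4_pct)),
        "sum_abs": lambda r: abs(r.diff_4x05_pct) + abs(r.diff_05x4_pct),
    }[objective]
    scored = [(scalar(r), r) for r in rows if not r.failed]
    if not scored:
        raise OptimizationError("every candidate pair failed in the joint search")
    best_obj, best_row = min(scored, key=lambda t: (t[0], t[1].essx_mm, t[1].essy_mm))
    tied = [r for obj, r in scored if obj <= best_obj + candidates.tie_tolerance_pct]
    if len(tied) == len(scored) and len(scored) > 1:
        log.warning(
            "joint search is degenerate: all %d evaluated pairs are tied "
            "within %.3g%%", len(scored), candidates.tie_tolerance_pct,
        )
    return OptimizationResult(
        essx_mm=(min(r.essx_mm for r in tied), max(r.essx_mm for r in tied)),
        essy_mm=(min(r.essy_mm for r in tied), max(r.essy_mm for r in tied)),
        essx_best=best_row.essx_mm,
        essy_best=best_row.essy_mm,
        residual_4x05_pct=best_row.diff_4x05_pct,
        residual_05x4_pct=best_row.diff_05x4_pct,
        trace=tuple(rows),
        objective=f"joint_{objective}",  # type: ignore[arg-type]
    )


@dataclass(frozen=True)
class SignReport:
    """Monotonicity and side-of-optimum diagnosis of one sweep.

    A too-small spot size lets too much fluence through the narrow
    aperture and overestimates the calculated dose (positive difference);
    a too-large one underestimates it.  The difference should therefore
    fall monotonically along the sweep; noisy measurements can violate
    this near the zero crossing, which is reported, not fatal.
    """

    axis: str
    checked_field: str
    labels: tuple[tuple[float, str], ...]  # (candidate, below/above/at optimum)
    violations: tuple[tuple[float, float, float, float], ...]  # (v1, d1, v2, d2)

    @property
    def monotone(self) -> bool:
        return not self.violations


def sign_diagnosis(
    sweep: SweepResult,
    checked_field: Literal["4 x 0.5", "0.5 x 4"] | None = None,
    zero_band_pct: float = 0.02,
) -> SignReport:
    """Verify the difference is non-increasing along a sweep and label sides.

    By default the field matched to the swept axis is checked (ESSx sweep
    against the 4 x 0.5 field, ESSy sweep against 0.5 x 4); either field
    can be requested explicitly.  Candidates are labelled ``below`` /
    ``above`` the optimum by the difference sign (within `zero_band_pct`
    of zero: ``at``).
    """
    if checked_field is None:
        checked_field = "4 x 0.5" if sweep.axis == "x" else "0.5 x 4"
    pick = {
        "4 x 0.5": lambda r: r.diff_4x05_pct,
        "0.5 x 4": lambda r: r.diff_05x4_pct,
    }[checked_field]
    seq = [
        (sweep.varied(r), pick(r)) for r in sweep.rows if not r.failed and pick(r) is not None
    ]
    seq.sort()
    labels = tuple(
        (v, "at" if abs(d) <= zero_band_pct else ("below" if d > 0 else "above"))
        for v, d in seq
    )
    violations = tuple(
        (v1, d1, v2, d2)
        for (v1, d1), (v2, d2) in zip(seq, seq[1:])
        if d2 > d1
    )
    return SignReport(
        axis=sweep.axis, checked_field=checked_field, labels=labels, violations=violations
    )
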