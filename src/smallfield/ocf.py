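"""Detector metadata and output-correction-factor (OCF) tables.

The TRS-483 formalism converts a small-field detector reading ratio into a
dose ratio through a detector- and field-size-specific output correction
factor k.  OCF tables map the equivalent square field side (cm) to the
factor; per the code of practice, factors more than 5% from unity are not
used.  Tables are user-supplied CSV (``field_side_cm,ocf`` with ``# key=value``
metadata comments); this package ships only synthetic example tables, since
the published tables are copyrighted reference data.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry import BeamQuality, OutOfValidityError

__all__ = [
    "DetectorSpec",
    "OCFTable",
    "BUILTIN_DETECTORS",
    "VALIDITY_THRESHOLD",
    "load_ocf_table",
    "filter_ocf_validity",
    "ocf_lookup",
]

log = logging.getLogger(__name__)

#: OCFs more than this far from unity are excluded from use.
VALIDITY_THRESHOLD = 0.05


@dataclass(frozen=True)
class DetectorSpec:
    """A small-field detector and the smallest field side with a published OCF.

    `min_field_cm_by_quality` maps a beam quality to the smallest equivalent
    square side (cm) for which an OCF is available; queries below it are
    out of the detector's validity domain, never extrapolated.
    """

    name: str
    min_field_cm_by_quality: Mapping[BeamQuality, float] = field(default_factory=dict)
    notes: str = ""

    def __post_init__(self) -> None:
        for q, v in self.min_field_cm_by_quality.items():
            if v <= 0:
                raise ValueError(f"minimum field side for {q} must be > 0, got {v}")

    def min_field_cm(self, beam_quality: BeamQuality | str) -> float | None:
        return self.min_field_cm_by_quality.get(BeamQuality(beam_quality))


def _minmap(mv6: float, mv10: float) -> dict[BeamQuality, float]:
    return {
        BeamQuality.X6: mv6,
        BeamQuality.FFF6: mv6,
        BeamQuality.X10: mv10,
        BeamQuality.FFF10: mv10,
    }


#: Detectors used for small-field output measurements, with the smallest
#: field side (cm) carrying a published OCF per beam energy.
BUILTIN_DETECTORS: dict[str, DetectorSpec] = {
    "microDiamond": DetectorSpec(
        "microDiamond",
        _minmap(0.4, 0.4),
        notes="synthetic single-crystal diamond; OCFs down to 0.4 cm for 6 and 10 MV",
    ),
    "PinPoint3D": DetectorSpec(
        "PinPoint3D",
        _minmap(0.8, 1.0),
        notes="vented micro ion chamber; OCFs down to 0.8 cm (6 MV) / 1.0 cm (10 MV)",
    ),
    "DiodeE": DetectorSpec(
        "DiodeE",
        _minmap(0.5, 0.6),
        notes="unshielded silicon diode; OCFs down to 0.5 cm (6 MV) / 0.6 cm (10 MV)",
    ),
}


@dataclass(frozen=True)
class OCFTable:
    """Ordered (field side, correction factor) pairs for one detector/quality."""

    detector: DetectorSpec
    beam_quality: BeamQuality
    sides_cm: tuple[float, ...]
    factors: tuple[float, ...]

    def __post_init__(self) -> None:
        sides = np.asarray(self.sides_cm, dtype=float)
        if len(sides) != len(self.factors):
            raise ValueError("sides and factors must have equal length")
        if len(sides) and not np.all(np.diff(sides) > 0):
            raise ValueError("field sides must be strictly increasing with no duplicates")

    def __len__(self) -> int:
        return len(self.sides_cm)

    @property
    def domain(self) -> tuple[float, float]:
        return self.sides_cm[0], self.sides_cm[-1]


def load_ocf_table(
    source,
    detector: DetectorSpec,
    beam_quality: BeamQuality | str,
) -> OCFTable:
    """Load an OCF table from CSV (path, file-like, or DataFrame).

    Expects columns ``field_side_cm`` and ``ocf``; ``#``-prefixed lines are
    metadata comments.  Rows are sorted ascending by field side; duplicate
    sides, non-numeric cells, or fewer than 2 rows are errors.
    """
    beam_quality = BeamQuality(beam_quality)
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, comment="#")
    missing = {"field_side_cm", "ocf"} - set(df.columns)
    if missing:
        raise ValueError(f"OCF table missing required column(s): {sorted(missing)}")
    df = df[["field_side_cm", "ocf"]]
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in OCF table: {exc}") from exc
    if df.isna().any().any():
        raise ValueError("non-numeric or missing cell in OCF table")
    if len(df) < 2:
        raise ValueError(f"OCF table needs at least 2 rows, got {len(df)}")
    if df["field_side_cm"].duplicated().any():
        dups = sorted(df.loc[df["field_side_cm"].duplicated(), "field_side_cm"])
        raise ValueError(f"duplicate field side(s) in OCF table: {dups}")
    df = df.sort_values("field_side_cm")
    return OCFTable(
        detector=detector,
        beam_quality=beam_quality,
        sides_cm=tuple(df["field_side_cm"]),
        factors=tuple(df["ocf"]),
    )


def filter_ocf_validity(table: OCFTable, threshold: float = VALIDITY_THRESHOLD) -> OCFTable:
    """Drop entries whose factor is more than `threshold` from unity.

    Idempotent.  Removed entries are logged; an empty result is returned
    with a warning rather than raised.
    """
    keep_s, keep_f = [], []
    for s, f in zip(table.sides_cm, table.factors):
        if abs(f - 1.0) <= threshold:
            keep_s.append(s)
            keep_f.append(f)
        else:
            log.info(
                "dropping OCF entry (side %.3g cm, factor %.4f) for %s/%s: "
                "more than %.0f%% from unity",
                s, f, table.detector.name, table.beam_quality.value, 100 * threshold,
            )
    if not keep_s:
        log.warning(
            "OCF validity filter removed every entry for %s/%s",
            table.detector.name, table.beam_quality.value,
        )
    return OCFTable(table.detector, table.beam_quality, tuple(keep_s), tuple(keep_f))


def ocf_lookup(table: OCFTable, esf_cm: float) -> float:
    """Output correction factor at equivalent square side `esf_cm`.

    Piecewise-linear interpolation between tabulated nodes; exact node hits
    return the node value.  Queries below the smallest tabulated side are
    out of the detector's validity domain.  Queries above the largest side
    return 1.0 only when the table explicitly ends at unity (the factor has
    converged), otherwise they are out of domain too.
    """
    if len(table) < 2:
        raise ValueError("OCF lookup requires a table with at least 2 entries")
    lo, hi = table.domain
    if esf_cm < lo:
        raise OutOfValidityError(
            f"equivalent square side {esf_cm:.4g} cm is below the smallest tabulated "
            f"side ({lo:g} cm) for {table.detector.name}/{table.beam_quality.value}; "
            "no OCF is published for smaller fields"
        )
    if esf_cm > hi:
        if table.factors[-1] == 1.0:
            return 1.0
        raise OutOfValidityError(
            f"equivalent square side {esf_cm:.4g} cm is above the largest tabulated "
            f"side ({hi:g} cm) for {table.detector.name}/{table.beam_quality.value}"
        )
    return float(np.interp(esf_cm, table.sides_cm, table.factors))
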