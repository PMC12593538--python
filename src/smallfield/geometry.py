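"""Field definitions and equivalent-square-field computations.

Small rectangular fields shaped by a multileaf collimator (MLC) are named
``Y x X`` where X is the leaf-motion (leaf-end) direction and Y the
leaf-side direction.  The TRS-483 output-correction-factor tables are
indexed by the side of the *equivalent square field* (ESF), the square
field dosimetrically equivalent to the rectangle.  Three estimators are
provided:

``eq_empirical``
    The empirical elongated-field formula

    .. math:: \\mathrm{ESF} = \\frac{2\\,\\min(A,B)^a \\max(A,B)^{2-a}}{A+B}

    with exponent ``a = 1.12`` by default.  At ``a = 1`` it reduces to the
    Sterling form; at ``a = 2`` to twice the harmonic-mean-like limit.

``sterling``
    Four times the area over the perimeter, ``2AB/(A+B)``.

``area``
    The equivalent-area square root ``sqrt(A*B)``, valid only for nearly
    square fields (aspect ratio within the open interval (0.7, 1.4)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Literal

__all__ = [
    "BeamQuality",
    "FieldSpec",
    "DosimetricSize",
    "EquivalentSquare",
    "AREA_RATIO_WINDOW",
    "DEFAULT_EXPONENT",
    "MIN_SIDE_CM",
    "equivalent_square_field",
    "sterling_square",
    "area_equivalent_square",
    "OutOfValidityError",
]

#: Empirically determined exponent of the elongated-field formula.
DEFAULT_EXPONENT = 1.12

#: Open validity window for the equivalent-area method (aspect ratio A/B).
AREA_RATIO_WINDOW = (0.7, 1.4)

#: Sides below this are rejected: below any OCF table domain.
MIN_SIDE_CM = 0.01


class BeamQuality(str, Enum):
    """Beam qualities of a TrueBeam-class linac (flattened / FFF)."""

    X6 = "6X"
    FFF6 = "6FFF"
    X10 = "10X"
    FFF10 = "10FFF"


class OutOfValidityError(ValueError):
    """A quantity falls outside the validity window of a method or table."""


def _check_sides(a_cm: float, b_cm: float) -> None:
    for s in (a_cm, b_cm):
        if not math.isfinite(s) or s < MIN_SIDE_CM:
            raise ValueError(
                f"field side {s} cm is invalid: sides must be finite and >= {MIN_SIDE_CM} cm"
            )


@dataclass(frozen=True)
class FieldSpec:
    """A symmetric rectangular MLC field centered on the beam axis.

    Parameters
    ----------
    y_cm, x_cm
        Field sides (cm) along the leaf-side (Y) and leaf-motion (X)
        directions.  Fields are named in Y-then-X order.
    beam_quality
        One of 6X, 6FFF, 10X, 10FFF.
    jaw_y_cm, jaw_x_cm
        Jaw openings (cm); fixed larger than the MLC field so that the MLC
        is the collimating device and jaw scatter is constant.
    depth_cm
        Measurement depth in water (cm).
    """

    y_cm: float
    x_cm: float
    beam_quality: BeamQuality = BeamQuality.X6
    jaw_y_cm: float = 4.4
    jaw_x_cm: float = 4.4
    depth_cm: float = 10.0

    def __post_init__(self) -> None:
        _check_sides(self.y_cm, self.x_cm)
        if self.jaw_y_cm <= self.y_cm or self.jaw_x_cm <= self.x_cm:
            raise ValueError(
                f"jaw opening ({self.jaw_y_cm} x {self.jaw_x_cm} cm) must strictly "
                f"exceed the MLC-defined field ({self.y_cm} x {self.x_cm} cm)"
            )
        object.__setattr__(self, "beam_quality", BeamQuality(self.beam_quality))

    @property
    def label(self) -> str:
        """Display name, sides in Y-then-X order (e.g. ``'0.5 x 4'``)."""

        def fmt(v: float) -> str:
            return f"{v:g}"

        return f"{fmt(self.y_cm)} x {fmt(self.x_cm)}"


@dataclass(frozen=True)
class DosimetricSize:
    """Measured (or nominal/simulated) field sides along the two axes.

    The dosimetric field size is the FWHM of the profile at the measuring
    depth; the `source` field records whether the sides fed to the
    equivalent-square formula were nominal settings, FWHM measurements,
    or simulated-profile FWHMs.
    """

    a_cm: float
    b_cm: float
    source: Literal["nominal", "measured", "simulated"] = "nominal"

    def __post_init__(self) -> None:
        _check_sides(self.a_cm, self.b_cm)
        if self.source not in ("nominal", "measured", "simulated"):
            raise ValueError(f"unknown size source {self.source!r}")


@dataclass(frozen=True)
class EquivalentSquare:
    """Equivalent square field side together with the method that produced it."""

    esf_cm: float
    method: Literal["eq_empirical", "sterling", "area"]
    exponent_a: float | None = None

    def __post_init__(self) -> None:
        if (self.method == "eq_empirical") != (self.exponent_a is not None):
            raise ValueError("exponent_a must be given iff method is 'eq_empirical'")


def equivalent_square_field(
    a_side: float, b_side: float, exponent: float = DEFAULT_EXPONENT
) -> EquivalentSquare:
    """Equivalent square side of an elongated rectangular field.

    Computes ``2 * min^a * max^(2-a) / (min + max)`` (sides in cm).  The
    formula is symmetric under side swap, bounded by the two sides, and
    returns the side itself for square input at any exponent.

    Parameters
    ----------
    a_side, b_side
        Field sides in cm (order immaterial).
    exponent
        Dimensionless exponent ``a`` in [1, 2]; 1.12 by default
        (empirically determined).  ``a = 1`` reduces to the Sterling form.
    """
    _check_sides(a_side, b_side)
    if not 1.0 <= exponent <= 2.0:
        raise ValueError(f"exponent {exponent} outside the allowed range [1, 2]")
    lo, hi = min(a_side, b_side), max(a_side, b_side)
    esf = 2.0 * lo**exponent * hi ** (2.0 - exponent) / (lo + hi)
    return EquivalentSquare(esf_cm=esf, method="eq_empirical", exponent_a=exponent)


def sterling_square(a_side: float, b_side: float) -> EquivalentSquare:
    """Sterling equivalent square: four times the area over the perimeter."""
    _check_sides(a_side, b_side)
    esf = 2.0 * a_side * b_side / (a_side + b_side)
    return EquivalentSquare(esf_cm=esf, method="sterling")


def area_equivalent_square(
    a_side: float, b_side: float, enforce_range: bool = True
) -> EquivalentSquare:
    """Equivalent-area square ``sqrt(A*B)``.

    Valid only for aspect ratios in the open window (0.7, 1.4); with
    ``enforce_range`` set (the default) an out-of-window ratio raises
    :class:`OutOfValidityError` instead of returning a value.
    """
    _check_sides(a_side, b_side)
    ratio = a_side / b_side
    lo, hi = AREA_RATIO_WINDOW
    if enforce_range and not (lo < ratio < hi):
        raise OutOfValidityError(
            f"aspect ratio A/B = {ratio:.4g} outside the equivalent-area validity "
            f"window ({lo}, {hi}); use the elongated-field formula instead"
        )
    return EquivalentSquare(esf_cm=math.sqrt(a_side * b_side), method="area")
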