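"""Beam-profile metrics: center, FWHM field size, and 20–80% penumbra.

A profile is a 1-D scan of dose (or detector signal) across the beam along
one collimation axis.  The dosimetric field size is the full width at half
maximum (FWHM); the penumbra is the lateral distance between the 20% and
80% dose levels on each shoulder of the normalized profile.  All level
crossings are located by linear interpolation between samples; no
smoothing is applied unless explicitly requested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping

import numpy as np
from scipy.signal import medfilt

__all__ = [
    "Profile",
    "ProfileMetrics",
    "normalize_profile",
    "beam_center",
    "fwhm",
    "penumbra_20_80",
    "profile_metrics",
    "ProfileShapeError",
]

log = logging.getLogger(__name__)


class ProfileShapeError(ValueError):
    """The profile does not have the expected two-shoulder field shape."""


@dataclass(frozen=True)
class Profile:
    """Sampled 1-D dose profile along one collimation axis.

    Positions are millimeters at the isocenter plane, strictly increasing,
    at least 8 samples; values are non-negative with a positive maximum.
    `axis` is ``"X"`` (leaf-motion / leaf-end direction) or ``"Y"``
    (leaf-side direction).
    """

    positions_mm: np.ndarray
    values: np.ndarray
    axis: Literal["X", "Y"] = "X"
    meta: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_mm, float)
        val = np.asarray(self.values, float)
        if pos.ndim != 1 or pos.size < 8:
            raise ValueError("profile needs at least 8 samples on a 1-D axis")
        if val.shape != pos.shape:
            raise ValueError("positions and values must have the same shape")
        if not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(val < 0) or not np.isfinite(val).all():
            raise ValueError("values must be finite and non-negative")
        if val.max() <= 0:
            raise ValueError("profile maximum must be positive")
        if self.axis not in ("X", "Y"):
            raise ValueError(f"axis must be 'X' or 'Y', got {self.axis!r}")
        object.__setattr__(self, "positions_mm", pos)
        object.__setattr__(self, "values", val)


@dataclass(frozen=True)
class ProfileMetrics:
    """Extracted profile metrics (all lengths in mm)."""

    center_mm: float
    fwhm_mm: float
    penumbra_left_mm: float
    penumbra_right_mm: float
    normalization_value: float

    @property
    def penumbra_mean_mm(self) -> float:
        return 0.5 * (self.penumbra_left_mm + self.penumbra_right_mm)


def normalize_profile(
    profile: Profile, reference: Literal["max", "center"] = "max"
) -> Profile:
    """Scale values so the reference (maximum, or value at x=0) equals 100.

    The maximum is the default reference: it matches the practice of
    positioning the detector at the maximum reading of each profile, and
    for small centered fields the two references coincide.
    """
    if reference == "max":
        ref = float(profile.values.max())
    elif reference == "center":
        ref = float(np.interp(0.0, profile.positions_mm, profile.values))
    else:
        raise ValueError(f"unknown normalization reference {reference!r}")
    if ref <= 0:
        raise ValueError("cannot normalize: reference value is not positive")
    return replace(profile, values=profile.values * (100.0 / ref))


def median_filter_profile(profile: Profile, window: int = 3) -> Profile:
    """Optional median filter for noisy measured profiles (choice is logged)."""
    if window % 2 == 0 or window < 3:
        raise ValueError("median filter window must be an odd integer >= 3")
    log.info("applying median filter (window %d) before metric extraction", window)
    return replace(profile, values=medfilt(profile.values, kernel_size=window))


def _crossings(pos: np.ndarray, val: np.ndarray, level: float) -> list[float]:
    """Positions where the piecewise-linear profile crosses `level`."""
    s = val - level
    out: list[float] = []
    for i in range(len(s) - 1):
        a, b = s[i], s[i + 1]
        if a == 0.0:
            if not out or out[-1] != pos[i]:
                out.append(float(pos[i]))
        elif a * b < 0:
            out.append(float(pos[i] + (pos[i + 1] - pos[i]) * a / (a - b)))
    if s[-1] == 0.0 and (not out or out[-1] != pos[-1]):
        out.append(float(pos[-1]))
    return out


def _half_crossings(profile: Profile) -> tuple[float, float]:
    norm = normalize_profile(profile)
    cross = _crossings(norm.positions_mm, norm.values, 50.0)
    if len(cross) != 2:
        raise ProfileShapeError(
            f"expected exactly two 50% crossings, found {len(cross)}; the profile "
            "does not look like a single centered field"
        )
    return cross[0], cross[1]


def beam_center(profile: Profile) -> float:
    """Midpoint of the two 50%-of-maximum crossings (mm)."""
    left, right = _half_crossings(profile)
    return 0.5 * (left + right)


def fwhm(profile: Profile) -> float:
    """Dosimetric field size: distance between the two 50% crossings (mm)."""
    left, right = _half_crossings(profile)
    return right - left


def _shoulder_crossing(
    pos: np.ndarray, val: np.ndarray, level: float, side: str, edge_mm: float
) -> float:
    cross = _crossings(pos, val, level)
    if not cross:
        raise ProfileShapeError(f"profile never crosses the {level:g}% level on the {side} side")
    if len(cross) > 1:
        log.warning(
            "%d crossings of the %g%% level on the %s shoulder; using the one "
            "nearest the field edge", len(cross), level, side,
        )
    return min(cross, key=lambda c: abs(c - edge_mm))


def penumbra_20_80(profile: Profile) -> tuple[float, float]:
    """Left and right 20–80% penumbra widths (mm).

    Crossings are located moving outward from the beam center on each
    shoulder; non-monotone shoulders use the crossing nearest the field
    edge (with a warning).
    """
    norm = normalize_profile(profile)
    left_edge, right_edge = _half_crossings(norm)
    center = 0.5 * (left_edge + right_edge)
    pos, val = norm.positions_mm, norm.values
    left_mask = pos <= center
    right_mask = pos >= center
    widths = []
    for mask, side, edge in ((left_mask, "left", left_edge), (right_mask, "right", right_edge)):
        p, v = pos[mask], val[mask]
        p80 = _shoulder_crossing(p, v, 80.0, side, edge)
        p20 = _shoulder_crossing(p, v, 20.0, side, edge)
        widths.append(abs(p80 - p20))
    return widths[0], widths[1]


def profile_metrics(profile: Profile) -> ProfileMetrics:
    """All standard metrics of one profile in a single pass."""
    left, right = _half_crossings(profile)
    pen_l, pen_r = penumbra_20_80(profile)
    return ProfileMetrics(
        center_mm=0.5 * (left + right),
        fwhm_mm=right - left,
        penumbra_left_mm=pen_l,
        penumbra_right_mm=pen_r,
        normalization_value=float(profile.values.max()),
    )
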