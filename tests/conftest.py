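"""Shared fixtures and the independent numerical dose oracle."""

from __future__ import annotations

import math

import numpy as np
import pytest
from scipy.signal import fftconvolve

from smallfield import BeamGeometry, ESSPair, FieldSpec, ScatterKernel


def numeric_central_dose(
    field: FieldSpec,
    ess: ESSPair,
    kernel: ScatterKernel,
    geometry: BeamGeometry,
    grid_mm: float = 0.05,
) -> float:
    """Brute-force central dose: 2-D aperture x source Gaussian x kernel.

    Independent of the closed-form engine: the aperture is rasterized with
    area-weighted edge pixels, convolved (2-D FFT) with the sampled source
    Gaussian, and integrated against each sampled kernel component.
    """
    p = geometry.projection_factor
    wx, wy = field.x_cm * 10.0, field.y_cm * 10.0
    sx_src, sy_src = p * ess.sigma_x_mm, p * ess.sigma_y_mm
    smax = max(max(kx, ky) for _, kx, ky in kernel.components)
    half = 0.5 * max(wx, wy) + 5.0 * (max(sx_src, sy_src) + smax) + 1.0
    n = int(math.ceil(half / grid_mm))
    ax = np.arange(-n, n + 1) * grid_mm

    def coverage(w: float) -> np.ndarray:
        lo = np.maximum(ax - grid_mm / 2, -w / 2)
        hi = np.minimum(ax + grid_mm / 2, w / 2)
        return np.clip(hi - lo, 0.0, None) / grid_mm

    def gauss1(s: float) -> np.ndarray:
        if s <= 0:
            d = np.zeros_like(ax)
            d[n] = 1.0
            return d
        g = np.exp(-0.5 * (ax / s) ** 2)
        return g / g.sum()

    aperture = np.outer(coverage(wx), coverage(wy))
    if sx_src == 0 and sy_src == 0:
        fluence = aperture
    else:
        fluence = fftconvolve(
            aperture, np.outer(gauss1(sx_src), gauss1(sy_src)), mode="same"
        )
    dose = 0.0
    for w, kx, ky in kernel.components:
        dose += w * float((fluence * np.outer(gauss1(kx), gauss1(ky))).sum())
    return dose


@pytest.fixture(scope="session")
def dose_oracle():
    return numeric_central_dose
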