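"""Ocular magnification correction and fovea-centered annulus construction.

An OCT-A instrument acquires a scan of nominal side length ``s`` (here 3.0 mm)
assuming an emmetropic eye.  The physical length actually imaged depends on the
ocular magnification, which Bennett's formula expresses through the axial
length (AL) of the eye::

    s_actual = p * q * s,     q = 0.01306 * (AL - 1.82)

``p`` is the camera (instrument) magnification factor and ``q`` the
magnification factor of the eye.  Region-of-interest analysis is performed on a
fovea-centered annulus of fixed *physical* size (inner diameter 1.0 mm, outer
diameter 2.5 mm); rather than resampling the image, the annulus radii are
rescaled into pixels with the eye-specific mm/pixel scale, so the analyzed
region covers the same retinal area in every eye.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "EyeBiometry",
    "AnnulusSpec",
    "bennett_actual_scan_length",
    "pixel_scale",
    "annulus_mask",
    "DEFAULT_CAMERA_FACTOR",
]

#: Camera magnification factor calibrated so a nominal emmetropic eye with
#: AL = 24.46 mm is magnification neutral (s_actual == s).  The instrument
#: vendor does not publish p; this calibration is the conventional choice.
DEFAULT_CAMERA_FACTOR = 3.382

_BENNETT_SLOPE = 0.01306
_BENNETT_OFFSET = 1.82


@dataclass(frozen=True)
class EyeBiometry:
    """Per-eye biometry needed for magnification correction.

    Parameters
    ----------
    axial_length_mm
        Ocular axial length in millimetres.  Values outside the plausible
        adult range [20, 30] mm are rejected.
    camera_factor_p
        Instrument magnification factor (dimensionless).
    nominal_scan_mm
        Nominal scan side length ``s`` of the acquisition protocol.
    """

    axial_length_mm: float
    camera_factor_p: float = DEFAULT_CAMERA_FACTOR
    nominal_scan_mm: float = 3.0

    def __post_init__(self) -> None:
        if not (20.0 <= self.axial_length_mm <= 30.0):
            raise ValueError(
                f"implausible axial length {self.axial_length_mm!r} mm "
                "(expected 20-30 mm)"
            )
        if self.camera_factor_p <= 0:
            raise ValueError("camera_factor_p must be positive")
        if self.nominal_scan_mm <= 0:
            raise ValueError("nominal_scan_mm must be positive")


@dataclass(frozen=True)
class AnnulusSpec:
    """Fovea-centered annulus: physical inner/outer diameters in mm.

    ``center_px`` is the annulus center in 0-based ``(x, y)`` pixel
    coordinates; ``None`` means the geometric image center, appropriate for
    fovea-centered scans.
    """

    inner_diameter_mm: float = 1.0
    outer_diameter_mm: float = 2.5
    center_px: Optional[Tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.inner_diameter_mm < 0:
            raise ValueError("inner diameter must be non-negative")
        if self.outer_diameter_mm < self.inner_diameter_mm:
            raise ValueError("outer diameter must be >= inner diameter")


def bennett_actual_scan_length(biometry: EyeBiometry) -> float:
    """Physical scan side length (mm) via Bennett's formula.

    Returns ``p * (0.01306 * (AL - 1.82)) * s`` exactly.
    """
    q = _BENNETT_SLOPE * (biometry.axial_length_mm - _BENNETT_OFFSET)
    return biometry.camera_factor_p * q * biometry.nominal_scan_mm


def pixel_scale(actual_scan_mm: float, n_px: int) -> float:
    """Millimetres per pixel for a square scan of ``n_px`` pixels per side."""
    if n_px <= 0:
        raise ValueError("n_px must be positive")
    if actual_scan_mm <= 0:
        raise ValueError("actual_scan_mm must be positive")
    return actual_scan_mm / n_px


def annulus_mask(
    shape: Tuple[int, int],
    spec: AnnulusSpec,
    scale_mm_per_px: float,
) -> np.ndarray:
    """Boolean annulus mask on a pixel grid.

    A pixel belongs to the annulus when its center lies at a distance ``d``
    from the annulus center with ``inner_radius <= d < outer_radius``, radii
    converted to pixels with the eye-specific scale.

    Raises
    ------
    ValueError
        If the outer radius (in pixels) does not fit within the grid
        half-width.
    """
    if scale_mm_per_px <= 0:
        raise ValueError("scale must be positive")
    ny, nx = shape
    if ny <= 0 or nx <= 0:
        raise ValueError("grid must be non-empty")
    r_in = (spec.inner_diameter_mm / 2.0) / scale_mm_per_px
    r_out = (spec.outer_diameter_mm / 2.0) / scale_mm_per_px
    if spec.center_px is None:
        cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    else:
        cx, cy = spec.center_px
    if r_out > min(nx, ny) / 2.0:
        raise ValueError(
            f"annulus outer radius {r_out:.1f} px exceeds grid half-width "
            f"{min(nx, ny) / 2.0:.1f} px"
        )
    yy, xx = np.mgrid[0:ny, 0:nx]
    d = np.hypot(xx - cx, yy - cy)
    return (d >= r_in) & (d < r_out)
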