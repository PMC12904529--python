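"""Vessel and imaging-system geometry.

The instrument images the curved surface of a cylindrical bioreactor
vessel from three viewpoints: a direct front view, plus two mirror views
that together cover the rear surface.  All downstream processing happens
on an "unwrapped" representation of that surface, as if it were peeled
off the cylinder and laid flat.

Coordinate conventions (package-wide)
-------------------------------------
* All lengths are millimetres; attenuation coefficients are mm^-1.
* ``height`` is measured downward from the top of the scan window, so
  height increases with image row index.
* The angular coordinate ``theta`` (radians) is measured around the
  vessel axis with ``theta = 0`` on the front camera axis and the range
  ``[-pi, pi)``; the seam at ``theta = +/-pi`` is on the rear surface.
* The arc-length coordinate ``s = R * (theta + pi)`` runs over
  ``[0, 2*pi*R)`` so the front camera axis sits at ``s = pi*R``, the
  middle of an unwrapped image.
* Pixels use 0-based indices, origin top-left, with pixel ``(i, j)``
  covering the half-open square ``[i-1/2, i+1/2) x [j-1/2, j+1/2)`` in
  continuous index coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = [
    "ImagingSystemSpec",
    "VesselGeometry",
    "rayleigh_resolution",
    "default_geometry",
    "wrap_angle",
]

TWO_PI = 2.0 * math.pi


def wrap_angle(theta):
    """Wrap an angle (or array of angles) into ``[-pi, pi)``."""
    return (np.asarray(theta) + math.pi) % TWO_PI - math.pi


@dataclass(frozen=True)
class ImagingSystemSpec:
    """Diffraction-relevant parameters of the imaging optics.

    Parameters
    ----------
    wavelength_nm:
        Illumination wavelength in nanometres.  The default, 473 nm, is
        a common blue CW laser line well matched to cell-culture
        scattering work.
    numerical_aperture:
        Numerical aperture of the collection lens, dimensionless.  Long
        working-distance machine-vision lenses have very small NA; the
        default 0.0174 corresponds to an 8 mm focal-length lens focused
        near infinity.
    """

    wavelength_nm: float = 473.0
    numerical_aperture: float = 0.0174

    def __post_init__(self):
        if not self.wavelength_nm > 0:
            raise ValidationError("wavelength_nm must be positive")
        if not 0.0 < self.numerical_aperture < 1.0:
            raise ValidationError("numerical_aperture must lie in (0, 1)")


def rayleigh_resolution(spec: ImagingSystemSpec) -> float:
    """Diffraction-limited resolution of the imaging system, in microns.

    Uses the full Airy-diameter convention ``1.22 * lambda / NA``.  For
    the default optics (473 nm, NA 0.0174) this evaluates to ~33 um,
    which is far finer than the millimetre-scale diffuse-scattering
    profiles the instrument actually analyses, so diffraction never
    limits the measurement.
    """
    return 1.22 * spec.wavelength_nm / spec.numerical_aperture * 1e-3


@dataclass(frozen=True)
class VesselGeometry:
    """Geometry of the cylindrical vessel and its three-view imaging.

    Parameters
    ----------
    radius_mm:
        Cylinder radius.  The default 65 mm matches a 2.5 L
        single-use stirred vessel.
    scan_window_height_mm:
        Vertical extent of the imaged band of the vessel surface.
    liquid_top_mm:
        Height coordinate of the liquid surface.  Rows above it (smaller
        height values) image air, which scatters nothing and renders as
        a dark band.
    baffles:
        Static mixing vanes of the internal manifold, each given as
        ``(angular position rad, angular width rad)``.  They sit close
        to the wall and cast vertical dark bands on the images.
    front_sector, mirror_view_sectors:
        Angular intervals ``(lo, hi)`` in radians observed by the direct
        front view and by the two mirror views (``rear_left`` covers the
        positive-theta side).  Together they must cover the full
        circumference; overlap is permitted and resolved at stitch time.
    camera_pixel_pitch_mm:
        Sampling pitch on the vessel surface, mm per pixel, shared by
        rendered raw frames and unwrapped images.
    dark_attenuation:
        Multiplicative intensity factor applied to baffle shadows and
        the air band above the liquid when synthesising scenes.
    """

    radius_mm: float = 65.0
    scan_window_height_mm: float = 140.0
    liquid_top_mm: float = 8.0
    baffles: tuple[tuple[float, float], ...] = (
        (math.radians(100.0), math.radians(8.0)),
        (math.radians(-100.0), math.radians(8.0)),
        (math.pi, math.radians(8.0)),
    )
    front_sector: tuple[float, float] = (-1.15, 1.15)
    mirror_view_sectors: tuple[tuple[float, float], tuple[float, float]] = (
        (1.05, math.pi),
        (-math.pi, -1.05),
    )
    camera_pixel_pitch_mm: float = 0.5
    dark_attenuation: float = 0.05

    def __post_init__(self):
        if not self.radius_mm > 0:
            raise ValidationError("radius_mm must be positive")
        if not self.scan_window_height_mm > 0:
            raise ValidationError("scan_window_height_mm must be positive")
        if not self.camera_pixel_pitch_mm > 0:
            raise ValidationError("camera_pixel_pitch_mm must be positive")
        if not 0.0 <= self.dark_attenuation <= 1.0:
            raise ValidationError("dark_attenuation must lie in [0, 1]")
        for lo, hi in (self.front_sector, *self.mirror_view_sectors):
            if not (-math.pi - 1e-12 <= lo < hi <= math.pi + 1e-12):
                raise ValidationError(
                    f"sector ({lo}, {hi}) must be an increasing interval within [-pi, pi]"
                )

    # ------------------------------------------------------------------
    # derived scalars
    # ------------------------------------------------------------------
    @property
    def circumference_mm(self) -> float:
        return TWO_PI * self.radius_mm

    @property
    def n_arc(self) -> int:
        """Number of columns of the unwrapped grid."""
        return max(1, round(self.circumference_mm / self.camera_pixel_pitch_mm))

    @property
    def n_rows(self) -> int:
        """Number of rows of the unwrapped grid (and of rendered views)."""
        return max(1, round(self.scan_window_height_mm / self.camera_pixel_pitch_mm))

    @property
    def arc_pitch_mm(self) -> float:
        """Effective column pitch; the grid spans exactly one circumference."""
        return self.circumference_mm / self.n_arc

    @property
    def row_pitch_mm(self) -> float:
        return self.scan_window_height_mm / self.n_rows

    @property
    def front_arc_mm(self) -> float:
        """Arc coordinate of the front camera axis (theta = 0)."""
        return math.pi * self.radius_mm

    # ------------------------------------------------------------------
    # coordinate grids
    # ------------------------------------------------------------------
    def arc_centers(self) -> np.ndarray:
        return (np.arange(self.n_arc) + 0.5) * self.arc_pitch_mm

    def height_centers(self) -> np.ndarray:
        return (np.arange(self.n_rows) + 0.5) * self.row_pitch_mm

    def theta_centers(self) -> np.ndarray:
        return self.arc_centers() / self.radius_mm - math.pi

    def arc_of_theta(self, theta) -> np.ndarray | float:
        return (np.asarray(theta) + math.pi) * self.radius_mm

    def theta_of_arc(self, arc) -> np.ndarray | float:
        return np.asarray(arc) / self.radius_mm - math.pi

    # ------------------------------------------------------------------
    # sectors
    # ------------------------------------------------------------------
    def sectors(self) -> dict[str, tuple[float, float]]:
        """Angular interval observed by each view, keyed by view label."""
        return {
            "front": self.front_sector,
            "rear_left": self.mirror_view_sectors[0],
            "rear_right": self.mirror_view_sectors[1],
        }

    def angular_gaps(self, tol: float = 1e-9) -> list[tuple[float, float]]:
        """Sub-intervals of ``[-pi, pi)`` not covered by any view sector."""
        intervals = sorted(
            (max(lo, -math.pi), min(hi, math.pi)) for lo, hi in self.sectors().values()
        )
        gaps: list[tuple[float, float]] = []
        cursor = -math.pi
        for lo, hi in intervals:
            if lo > cursor + tol:
                gaps.append((cursor, lo))
            cursor = max(cursor, hi)
        if cursor < math.pi - tol:
            gaps.append((cursor, math.pi))
        return gaps

    def circular_arc_difference(self, arc, arc0) -> np.ndarray:
        """Signed arc separation on the closed circumference."""
        half = 0.5 * self.circumference_mm
        return (np.asarray(arc) - arc0 + half) % self.circumference_mm - half


def default_geometry(**overrides) -> VesselGeometry:
    """The reference 2.5 L vessel geometry with optional field overrides."""
    return VesselGeometry(**overrides)
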