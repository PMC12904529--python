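"""Cylindrical-surface unwrapping of raw three-view camera frames.

A raw frame holds three disjoint regions: the direct front view of the
vessel and two mirror views of the rear surface.  Each region is an
orthographic (parallel-ray) projection of the curved surface, so a
surface point at angle ``theta`` within a view of sector centre
``theta_c`` appears at lateral position ``x = R * sin(theta - theta_c)``
(mirror views are additionally flipped, ``x' = -x``).  Unwrapping
inverts these projections column-by-column, removes the mirror flips,
and stitches the three flat fragments into a single image indexed by
``(height, arc length)``.

Radiometry: the projection is treated as radiance-preserving -- a pixel
reports the surface radiance of the point it images, with no limb
foreshortening factor -- so unwrapping only resamples geometry and
leaves intensities untouched for the downstream attenuation fit.
Interpolation is bilinear with a nearest-neighbour fallback at polygon
borders; seams between views are hard switches with no blending.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import LineString
from skimage.draw import polygon2mask

from .errors import AngularCoverageError, ValidationError
from .geometry import VesselGeometry, wrap_angle

__all__ = [
    "VIEW_LABELS",
    "VIEW_CODES",
    "RegionPolygon",
    "UnwrappedImage",
    "ViewFragment",
    "project_view",
    "stitch",
    "unwrap",
]

VIEW_LABELS = ("front", "rear_left", "rear_right")
#: integer provenance codes; -1 marks pixels no view claims
VIEW_CODES = {"none": -1, "front": 0, "rear_left": 1, "rear_right": 2}
CODE_VIEWS = {v: k for k, v in VIEW_CODES.items()}


@dataclass(frozen=True)
class RegionPolygon:
    """Predefined polygon isolating one view region in the raw frame.

    ``vertices`` are ``(row, col)`` corner points in continuous 0-based
    pixel coordinates.  The polygon's bounding box defines the region's
    coordinate frame: its horizontal extent maps linearly onto the
    view's projected lateral range and its vertical extent onto
    ``[0, scan_window_height]``.  ``mirrored`` is true for the two rear
    views, which are imaged via a mirror and therefore horizontally
    reversed.
    """

    view_label: str
    vertices: tuple[tuple[float, float], ...]
    mirrored: bool

    def __post_init__(self):
        if self.view_label not in VIEW_LABELS:
            raise ValidationError(f"unknown view label {self.view_label!r}")
        if len(self.vertices) < 3:
            raise ValidationError("polygon needs at least 3 vertices")
        if self.mirrored != (self.view_label != "front"):
            raise ValidationError("mirrored must be true exactly for rear views")
        ring = LineString(list(self.vertices) + [self.vertices[0]])
        if not ring.is_simple:
            raise ValidationError("polygon is self-intersecting")

    # bounding box in continuous pixel coordinates
    @property
    def bbox(self) -> tuple[float, float, float, float]:
        rows = [v[0] for v in self.vertices]
        cols = [v[1] for v in self.vertices]
        return min(rows), max(rows), min(cols), max(cols)

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        return polygon2mask(shape, np.asarray(self.vertices, dtype=float))

    def within_frame(self, shape: tuple[int, int]) -> bool:
        r0, r1, c0, c1 = self.bbox
        return r0 >= -0.5 and c0 >= -0.5 and r1 <= shape[0] - 0.5 and c1 <= shape[1] - 0.5

    @staticmethod
    def rectangle(view_label: str, row0: int, col0: int, n_rows: int, n_cols: int) -> "RegionPolygon":
        """Axis-aligned rectangle covering pixels [row0, row0+n_rows) x [col0, col0+n_cols)."""
        r0, r1 = row0 - 0.5, row0 + n_rows - 0.5
        c0, c1 = col0 - 0.5, col0 + n_cols - 0.5
        return RegionPolygon(
            view_label=view_label,
            vertices=((r0, c0), (r0, c1), (r1, c1), (r1, c0)),
            mirrored=view_label != "front",
        )


@dataclass
class UnwrappedImage:
    """Flat intensity map of the cylinder surface.

    ``values`` has shape ``(n_rows, n_arc)``; row ``i`` is height
    ``height_mm[i]`` (increasing downward) and column ``j`` is arc
    length ``arc_mm[j]``; the columns span exactly one circumference.
    ``provenance`` stores the VIEW_CODES label of the view each pixel
    was taken from.  NaNs mark pixels invalid upstream (e.g. saturated
    in every exposure).
    """

    values: np.ndarray
    arc_mm: np.ndarray
    height_mm: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.arc_mm = np.asarray(self.arc_mm, dtype=float)
        self.height_mm = np.asarray(self.height_mm, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be 2-D")
        if self.values.shape != (self.height_mm.size, self.arc_mm.size):
            raise ValidationError("values shape does not match coordinate axes")
        if self.arc_mm.size > 1 and np.any(np.diff(self.arc_mm) <= 0):
            raise ValidationError("arc_mm must be strictly increasing")
        if self.height_mm.size > 1 and np.any(np.diff(self.height_mm) <= 0):
            raise ValidationError("height_mm must increase with row index")
        if self.provenance is None:
            self.provenance = np.full(self.values.shape, VIEW_CODES["none"], dtype=np.int8)
        with np.errstate(invalid="ignore"):
            if np.any(self.values[np.isfinite(self.values)] < 0):
                raise ValidationError("intensities must be non-negative")

    @property
    def arc_pitch_mm(self) -> float:
        return float(self.arc_mm[1] - self.arc_mm[0]) if self.arc_mm.size > 1 else float("nan")

    @property
    def row_pitch_mm(self) -> float:
        return float(self.height_mm[1] - self.height_mm[0]) if self.height_mm.size > 1 else float("nan")

    @property
    def width_mm(self) -> float:
        """Total circumferential extent represented by the columns."""
        return self.arc_mm.size * self.arc_pitch_mm


@dataclass
class ViewFragment:
    """One view's contribution to the unwrapped plane.

    ``values`` is a full-size ``(n_rows, n_arc)`` grid; only the columns
    whose angle lies inside ``sector`` are populated (``covered`` marks
    them), the rest are NaN.
    """

    values: np.ndarray
    view_label: str
    sector: tuple[float, float]
    covered: np.ndarray  # boolean per column

    @property
    def sector_center(self) -> float:
        return 0.5 * (self.sector[0] + self.sector[1])


def _sample(raw_masked: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear sample with nearest-neighbour fallback where bilinear
    touches masked (NaN) pixels, e.g. at polygon borders."""
    vals = map_coordinates(raw_masked, [rows, cols], order=1, mode="nearest")
    bad = ~np.isfinite(vals)
    if np.any(bad):
        vals[bad] = map_coordinates(raw_masked, [rows[bad], cols[bad]], order=0, mode="nearest")
    return vals


def project_view(
    raw: np.ndarray,
    polygon: RegionPolygon,
    geometry: VesselGeometry,
) -> ViewFragment:
    """Invert one view's cylindrical projection onto the unwrapped plane."""
    raw = np.asarray(raw, dtype=float)
    if not polygon.within_frame(raw.shape):
        raise ValidationError(f"{polygon.view_label} polygon extends outside the raw frame")

    lo, hi = geometry.sectors()[polygon.view_label]
    theta_c = 0.5 * (lo + hi)
    half_width = 0.5 * (hi - lo)
    if half_width >= math.pi / 2:
        raise ValidationError("view sector wider than pi cannot be imaged orthographically")
    R = geometry.radius_mm

    theta = geometry.theta_centers()
    covered = (theta >= lo) & (theta <= hi)
    n_rows, n_arc = geometry.n_rows, geometry.n_arc
    out = np.full((n_rows, n_arc), np.nan)
    if np.any(covered):
        x = R * np.sin(theta[covered] - theta_c)
        xp = -x if polygon.mirrored else x
        r0, r1, c0, c1 = polygon.bbox
        x_half = R * math.sin(half_width)
        # lateral position -> continuous pixel column within the polygon bbox
        cols = c0 + (xp + x_half) / (2.0 * x_half) * (c1 - c0)
        heights = geometry.height_centers()
        rows = r0 + heights / geometry.scan_window_height_mm * (r1 - r0)
        # keep strictly inside the bbox so border rounding cannot escape it
        cols = np.clip(cols, c0 + 1e-6, c1 - 1e-6)
        rows = np.clip(rows, r0 + 1e-6, r1 - 1e-6)
        rr, cc = np.meshgrid(rows, cols, indexing="ij")
        raw_masked = np.where(polygon.mask(raw.shape), raw, np.nan)
        out[:, covered] = _sample(raw_masked, rr.ravel(), cc.ravel()).reshape(rr.shape)
    return ViewFragment(values=out, view_label=polygon.view_label, sector=(lo, hi), covered=covered)


def stitch(fragments: list[ViewFragment], geometry: VesselGeometry) -> UnwrappedImage:
    """Combine partially-covering fragments into one unwrapped image.

    Where fragments overlap, each column is taken whole from the view
    whose sector centre is angularly closest -- a hard switch, no
    blending, so intensities stay radiometrically unmodified.
    """
    if not fragments:
        raise ValidationError("no fragments to stitch")
    theta = geometry.theta_centers()
    n_rows, n_arc = fragments[0].values.shape
    values = np.full((n_rows, n_arc), np.nan)
    provenance = np.full((n_rows, n_arc), VIEW_CODES["none"], dtype=np.int8)

    distance = np.full((len(fragments), n_arc), np.inf)
    for i, frag in enumerate(fragments):
        dist = np.abs(wrap_angle(theta - frag.sector_center))
        distance[i, frag.covered] = dist[frag.covered]
    any_cover = np.isfinite(distance).any(axis=0)
    if not np.all(any_cover):
        uncovered = theta[~any_cover]
        raise AngularCoverageError([(float(uncovered.min()), float(uncovered.max()))])
    winner = np.argmin(distance, axis=0)
    for i, frag in enumerate(fragments):
        take = winner == i
        values[:, take] = frag.values[:, take]
        provenance[:, take] = VIEW_CODES[frag.view_label]
    return UnwrappedImage(
        values=values,
        arc_mm=geometry.arc_centers(),
        height_mm=geometry.height_centers(),
        provenance=provenance,
    )


def unwrap(
    raw: np.ndarray,
    polygons: list[RegionPolygon],
    geometry: VesselGeometry,
) -> UnwrappedImage:
    """Transform a raw three-view frame into an unwrapped surface image.

    Steps: (1) isolate each view with its predefined polygon; (2)
    resample each by the inverse orthographic projection
    ``s = R * arcsin(x / R)`` per column; (3) un-flip the mirror views;
    (4) stitch the fragments at their angular sectors.

    Raises
    ------
    AngularCoverageError
        If the views' sectors leave part of the circumference uncovered.
    ValidationError
        If a polygon lies outside the raw frame.
    """
    gaps = geometry.angular_gaps()
    if gaps:
        raise AngularCoverageError(gaps)
    fragments = [project_view(raw, poly, geometry) for poly in polygons]
    return stitch(fragments, geometry)
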