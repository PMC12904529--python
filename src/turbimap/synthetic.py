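"""Forward simulator for laser-illuminated turbid-vessel imaging.

Generates ground-truth surface intensity fields, rendered three-view
camera frames with sensor noise, and full time-series growth datasets,
so every downstream stage (HDR merge, unwrapping, attenuation fitting,
calibration, growth mapping) can be exercised and validated without
any real instrument data.

The surface model is the semi-infinite diffusion approximation: the
intensity on the vessel surface a distance ``d`` from the laser spot is
``A * exp(-mu_eff * d) / d**2``, with ``d`` the Euclidean distance in
the unwrapped (arc, height) plane -- an approximation to the 3-D chord
distance that matches how profiles are analysed (along a straight
horizontal image line).  Baffle shadows and the air band above the
liquid are multiplicative dark masks.  The camera model is
shot-noise-limited with Gaussian read noise, a black-level offset and
hard full-well clipping.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Iterator

import numpy as np
from scipy.ndimage import map_coordinates

from .calibration import PAPER_CALIBRATION, CalibrationModel, mueff_from_density
from .errors import ValidationError
from .geometry import (  # noqa: F401  (re-exported module surface)
    ImagingSystemSpec,
    VesselGeometry,
    default_geometry,
    rayleigh_resolution,
)
from .growth import GrowthMap
from .hdr import ExposureStack, RawFrame
from .scattering import mueff_from_coefficients, scan_plan
from .unwrapping import RegionPolygon, UnwrappedImage

__all__ = [
    "OpticalProperties",
    "GrowthScenario",
    "CameraModel",
    "SceneLayout",
    "SceneRender",
    "ViewRegion",
    "surface_intensity",
    "view_layout",
    "render_views",
    "apply_camera",
    "SimulatedGrowthDataset",
    "simulate_growth_series",
    "fermentation_scenario",
    "banded_scenario",
    "antibiotic_scenario",
    "DEFAULT_EXPOSURES",
    "DEFAULT_AMPLITUDE",
    "INITIAL_FERMENTATION_DENSITY",
]

#: exposure times (arbitrary units) of the default HDR stack; the 8x
#: ratio keeps every fit-window pixel within a frame's linear range
DEFAULT_EXPOSURES = (0.5, 4.0, 32.0, 256.0)
#: laser amplitude (photo-events per unit exposure) placing the 5-30 mm
#: window in the well-exposed part of the default stack
DEFAULT_AMPLITUDE = 1.0e6
#: starting density of the default growth scenarios, one third of the
#: highest calibration density (16 aliquots x 1.82e8 cells/mL)
INITIAL_FERMENTATION_DENSITY = 16 * 1.82e8 / 3.0


@dataclass(frozen=True)
class OpticalProperties:
    """Bulk optical properties of the vessel contents.

    ``mu_eff`` is the cell-suspension contribution;
    ``background_mu_eff`` is the vessel's own scattering floor (internal
    plastic manifold, wall imperfections), added so that zero-cell
    scenes still show the non-zero attenuation a real vessel does.
    All coefficients are mm^-1.
    """

    mu_eff: float
    background_mu_eff: float = 0.0
    mu_a: float | None = None
    mu_s_prime: float | None = None

    def __post_init__(self):
        for name in ("mu_eff", "background_mu_eff"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if (self.mu_a is None) != (self.mu_s_prime is None):
            raise ValidationError("mu_a and mu_s_prime must be given together")
        if self.mu_a is not None:
            if self.mu_a < 0 or self.mu_s_prime < 0:
                raise ValidationError("optical coefficients must be non-negative")
            expected = mueff_from_coefficients(self.mu_a, self.mu_s_prime)
            if not math.isclose(self.mu_eff, expected, rel_tol=1e-9, abs_tol=1e-12):
                raise ValidationError(
                    f"mu_eff={self.mu_eff} inconsistent with sqrt(3*mu_a*mu_s')={expected}"
                )

    @classmethod
    def from_coefficients(
        cls, mu_a: float, mu_s_prime: float, background_mu_eff: float = 0.0
    ) -> "OpticalProperties":
        return cls(
            mu_eff=mueff_from_coefficients(mu_a, mu_s_prime),
            background_mu_eff=background_mu_eff,
            mu_a=mu_a,
            mu_s_prime=mu_s_prime,
        )

    @property
    def total_mu_eff(self) -> float:
        """Suspension plus vessel-background attenuation."""
        return self.mu_eff + self.background_mu_eff


@dataclass(frozen=True)
class CameraModel:
    """Sensor parameters of the simulated monochrome camera."""

    gain: float = 2.0  # counts per photo-event
    read_noise_sd: float = 3.0  # counts
    black_level: float = 100.0  # counts
    full_well: float = 65535.0  # counts (16-bit sensor)

    def __post_init__(self):
        if not self.gain > 0:
            raise ValidationError("gain must be positive")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be non-negative")
        if not self.full_well > self.black_level:
            raise ValidationError("full_well must exceed black_level")


# ----------------------------------------------------------------------
# surface intensity field
# ----------------------------------------------------------------------
def _dark_mask(geometry: VesselGeometry) -> np.ndarray:
    """Multiplicative mask: air band above the liquid and baffle shadows."""
    mask = np.ones((geometry.n_rows, geometry.n_arc))
    mask[geometry.height_centers() < geometry.liquid_top_mm, :] = geometry.dark_attenuation
    theta = geometry.theta_centers()
    for center, width in geometry.baffles:
        hit = np.abs((theta - center + math.pi) % (2 * math.pi) - math.pi) <= width / 2
        mask[:, hit] = np.minimum(mask[:, hit], geometry.dark_attenuation)
    return mask


def surface_intensity(
    geometry: VesselGeometry,
    optics: OpticalProperties,
    laser_spot: tuple[float, float],
    amplitude: float = DEFAULT_AMPLITUDE,
) -> UnwrappedImage:
    """Ground-truth surface intensity field around one laser spot.

    Intensity at surface point ``p`` is
    ``amplitude * exp(-mu_eff * d) / d**2`` with
    ``d = distance(p, laser_spot)`` (Euclidean in the unwrapped plane,
    circular in arc, clamped below by one pixel pitch so the spot pixel
    stays finite).  Baffle sectors and the region above the liquid line
    are attenuated to the geometry's dark level.
    """
    if not amplitude > 0:
        raise ValidationError("amplitude must be positive")
    s0, h0 = laser_spot
    if h0 <= geometry.liquid_top_mm:
        raise ValidationError(
            f"laser height {h0} mm is above the liquid line ({geometry.liquid_top_mm} mm)"
        )
    if not 0 <= h0 <= geometry.scan_window_height_mm:
        raise ValidationError("laser spot lies outside the scan window")
    ds = geometry.circular_arc_difference(geometry.arc_centers(), s0)
    dh = geometry.height_centers() - h0
    d = np.hypot(dh[:, None], ds[None, :])
    np.maximum(d, geometry.camera_pixel_pitch_mm, out=d)
    values = amplitude * np.exp(-optics.total_mu_eff * d) / d**2
    values *= _dark_mask(geometry)
    return UnwrappedImage(
        values=values,
        arc_mm=geometry.arc_centers(),
        height_mm=geometry.height_centers(),
    )


# ----------------------------------------------------------------------
# three-view rendering
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ViewRegion:
    """Placement of one rendered view inside the flat raw frame."""

    label: str
    sector: tuple[float, float]
    mirrored: bool
    row0: int
    col0: int
    n_rows: int
    n_cols: int
    x_half_mm: float  # lateral half-extent R*sin(sector half-width)


@dataclass(frozen=True)
class SceneLayout:
    """Raw-frame layout of the three view regions (disjoint, padded)."""

    regions: tuple[ViewRegion, ...]
    shape: tuple[int, int]

    def polygons(self) -> list[RegionPolygon]:
        return [
            RegionPolygon.rectangle(r.label, r.row0, r.col0, r.n_rows, r.n_cols)
            for r in self.regions
        ]


@dataclass
class SceneRender:
    """A rendered raw three-view frame plus its layout."""

    values: np.ndarray
    layout: SceneLayout


def view_layout(geometry: VesselGeometry, pad_cols: int = 4) -> SceneLayout:
    """Compute the raw-frame layout for the given geometry.

    Views are placed side by side (rear-left mirror, front, rear-right
    mirror) separated by ``pad_cols`` dark columns, mimicking a camera
    frame that sees the vessel flanked by its two mirrors.
    """
    gaps = geometry.angular_gaps()
    if gaps:
        from .errors import AngularCoverageError

        raise AngularCoverageError(gaps)
    regions = []
    col = 0
    n_rows = geometry.n_rows
    for label in ("rear_left", "front", "rear_right"):
        lo, hi = geometry.sectors()[label]
        half_width = 0.5 * (hi - lo)
        x_half = geometry.radius_mm * math.sin(half_width)
        n_cols = max(1, round(2.0 * x_half / geometry.camera_pixel_pitch_mm))
        regions.append(
            ViewRegion(
                label=label,
                sector=(lo, hi),
                mirrored=label != "front",
                row0=0,
                col0=col,
                n_rows=n_rows,
                n_cols=n_cols,
                x_half_mm=x_half,
            )
        )
        col += n_cols + pad_cols
    return SceneLayout(regions=tuple(regions), shape=(n_rows, col - pad_cols))


def render_views(
    unwrapped: UnwrappedImage | np.ndarray,
    geometry: VesselGeometry,
    layout: SceneLayout | None = None,
) -> SceneRender:
    """Render the three camera views of an unwrapped surface field.

    Each region applies the forward orthographic projection
    ``x = R * sin(theta - theta_c)`` of its sector (mirror views are
    horizontally flipped), i.e. exactly the inverse of the unwrapping
    transform.  The mapping is radiance-preserving: pixel values are
    sampled, not re-weighted, so unwrap(render(U)) recovers U away from
    seams.
    """
    values = unwrapped.values if isinstance(unwrapped, UnwrappedImage) else np.asarray(unwrapped)
    if values.shape != (geometry.n_rows, geometry.n_arc):
        raise ValidationError(
            "unwrapped field must cover the full circumference on the geometry grid"
        )
    if layout is None:
        layout = view_layout(geometry)
    out = np.zeros(layout.shape)
    R = geometry.radius_mm
    for reg in layout.regions:
        theta_c = 0.5 * (reg.sector[0] + reg.sector[1])
        j = np.arange(reg.n_cols)
        xp = -reg.x_half_mm + (j + 0.5) * (2.0 * reg.x_half_mm / reg.n_cols)
        x = -xp if reg.mirrored else xp
        theta = theta_c + np.arcsin(np.clip(x / R, -1.0, 1.0))
        arc = (theta + math.pi) * R % geometry.circumference_mm
        cols = arc / geometry.arc_pitch_mm - 0.5
        rows = np.arange(reg.n_rows, dtype=float)
        rr = np.repeat(rows, reg.n_cols)
        cc = np.tile(cols, reg.n_rows)
        sampled = map_coordinates(values, [rr, cc], order=1, mode="grid-wrap")
        out[reg.row0 : reg.row0 + reg.n_rows, reg.col0 : reg.col0 + reg.n_cols] = (
            sampled.reshape(reg.n_rows, reg.n_cols)
        )
    return SceneRender(values=out, layout=layout)


# ----------------------------------------------------------------------
# camera
# ----------------------------------------------------------------------
def apply_camera(
    scene: np.ndarray,
    exposure: float,
    *,
    gain: float = 2.0,
    read_noise_sd: float = 3.0,
    black_level: float = 100.0,
    full_well: float = 65535.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RawFrame:
    """Expose a noiseless scene through the simulated sensor.

    Pixel value = ``clip(black_level + gain * Poisson(scene * exposure)
    + Gaussian(0, read_noise_sd), 0, full_well)`` quantised to integers.
    ``scene`` is in photo-events per unit exposure.  Deterministic for a
    given ``seed`` (or supplied generator).
    """
    scene = np.asarray(scene, dtype=float)
    if np.any(scene < 0):
        raise ValidationError("scene intensities must be non-negative")
    if not exposure > 0:
        raise ValidationError("exposure must be positive")
    if not full_well > black_level:
        raise ValidationError("full_well must exceed black_level")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = black_level + gain * rng.poisson(scene * exposure).astype(float)
    if read_noise_sd > 0:
        counts += rng.normal(0.0, read_noise_sd, size=scene.shape)
    quantised = np.clip(np.rint(counts), 0, full_well)
    dtype = np.uint16 if full_well <= np.iinfo(np.uint16).max else np.int64
    return RawFrame(
        values=quantised.astype(dtype),
        exposure=exposure,
        black_level=black_level,
        full_well=full_well,
    )


def expose_stack(
    scene: np.ndarray,
    exposures=DEFAULT_EXPOSURES,
    camera: CameraModel = CameraModel(),
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> ExposureStack:
    """Capture a full HDR exposure stack of one scene."""
    if rng is None:
        rng = np.random.default_rng(seed)
    frames = [
        apply_camera(
            scene,
            e,
            gain=camera.gain,
            read_noise_sd=camera.read_noise_sd,
            black_level=camera.black_level,
            full_well=camera.full_well,
            rng=rng,
        )
        for e in exposures
    ]
    return ExposureStack(frames=tuple(frames))


# ----------------------------------------------------------------------
# growth scenarios
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class GrowthScenario:
    """A ground-truth culture history to simulate.

    ``density_profile(height_mm, time_h)`` returns cells/mL and stands
    in for the live culture; ``laser_heights_mm`` is the vertical scan
    plan and ``timepoints_h`` the acquisition schedule.
    """

    density_profile: Callable[[float, float], float]
    timepoints_h: tuple[float, ...]
    laser_heights_mm: tuple[float, ...]
    rng_seed: int = 0
    name: str = "custom"

    def __post_init__(self):
        t = np.asarray(self.timepoints_h)
        if t.size == 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("timepoints must be non-empty and strictly increasing")
        if len(self.laser_heights_mm) == 0:
            raise ValidationError("at least one laser height required")

    def density_grid(self) -> np.ndarray:
        """Ground-truth density at every (laser height, timepoint)."""
        grid = np.array(
            [
                [self.density_profile(h, t) for t in self.timepoints_h]
                for h in self.laser_heights_mm
            ],
            dtype=float,
        )
        if np.any(grid < 0):
            raise ValidationError("density_profile must be non-negative everywhere")
        return grid

    def truth_map(self) -> GrowthMap:
        """The generator's stored truth: density normalised at T = 0."""
        grid = self.density_grid()
        return GrowthMap(
            growth=grid / grid[:, :1],
            heights_mm=np.asarray(self.laser_heights_mm),
            times_h=np.asarray(self.timepoints_h),
        )


def _default_scan(geometry: VesselGeometry) -> tuple[float, ...]:
    # 25 positions at 5 mm spacing over 125 mm, offset below the liquid line
    return tuple(scan_plan(5.0, 125.0, start_mm=10.0))


def _logistic_ramp(t: float, t_mid: float = 7.0, tau: float = 2.0) -> float:
    """Smooth 0 -> 1 ramp pinned to 0 at t = 0 and ~1 at late times."""
    raw0 = 1.0 / (1.0 + math.exp(t_mid / tau))
    raw = 1.0 / (1.0 + math.exp(-(t - t_mid) / tau))
    return (raw - raw0) / (1.0 - raw0)


def fermentation_scenario(
    *,
    n_timepoints: int = 12,
    duration_h: float = 23.0,
    timepoints_h=None,
    laser_heights_mm=None,
    rho0: float = INITIAL_FERMENTATION_DENSITY,
    fold: float = 2.0,
    geometry: VesselGeometry | None = None,
    rng_seed: int = 0,
) -> GrowthScenario:
    """Uniform logistic growth reaching ``fold`` (default 2x) at 23 h,
    emulating a typical stirred-vessel batch culture."""
    geometry = geometry or default_geometry()
    times = tuple(timepoints_h) if timepoints_h is not None else tuple(
        np.linspace(0.0, duration_h, n_timepoints)
    )
    heights = (
        tuple(laser_heights_mm) if laser_heights_mm is not None else _default_scan(geometry)
    )

    def profile(h: float, t: float) -> float:
        return rho0 * (1.0 + (fold - 1.0) * _logistic_ramp(t))

    return GrowthScenario(
        density_profile=profile,
        timepoints_h=times,
        laser_heights_mm=heights,
        rng_seed=rng_seed,
        name="fermentation",
    )


def banded_scenario(
    *,
    n_timepoints: int = 12,
    duration_h: float = 23.0,
    timepoints_h=None,
    laser_heights_mm=None,
    rho0: float = INITIAL_FERMENTATION_DENSITY,
    folds: tuple[float, float, float] = (2.5, 1.5, 2.5),
    band_edges_mm: tuple[float, float] = (45.0, 80.0),
    geometry: VesselGeometry | None = None,
    rng_seed: int = 0,
) -> GrowthScenario:
    """Height-dependent growth with bands of distinct final fold change.

    Emulates the spatial heterogeneity seen in real vessels: a
    high-growth band near the top, reduced growth in the middle and
    renewed growth below, with a smooth logistic ramp in time.
    """
    geometry = geometry or default_geometry()
    times = tuple(timepoints_h) if timepoints_h is not None else tuple(
        np.linspace(0.0, duration_h, n_timepoints)
    )
    heights = (
        tuple(laser_heights_mm) if laser_heights_mm is not None else _default_scan(geometry)
    )
    e0, e1 = band_edges_mm

    def fold_of(h: float) -> float:
        if h < e0:
            return folds[0]
        if h < e1:
            return folds[1]
        return folds[2]

    def profile(h: float, t: float) -> float:
        return rho0 * (1.0 + (fold_of(h) - 1.0) * _logistic_ramp(t))

    return GrowthScenario(
        density_profile=profile,
        timepoints_h=times,
        laser_heights_mm=heights,
        rng_seed=rng_seed,
        name="banded",
    )


def antibiotic_scenario(
    *,
    n_timepoints: int = 12,
    duration_h: float = 23.0,
    timepoints_h=None,
    laser_heights_mm=None,
    rho0: float = INITIAL_FERMENTATION_DENSITY,
    geometry: VesselGeometry | None = None,
    rng_seed: int = 0,
) -> GrowthScenario:
    """Negative control: growth suppressed, density constant in time."""
    geometry = geometry or default_geometry()
    times = tuple(timepoints_h) if timepoints_h is not None else tuple(
        np.linspace(0.0, duration_h, n_timepoints)
    )
    heights = (
        tuple(laser_heights_mm) if laser_heights_mm is not None else _default_scan(geometry)
    )
    return GrowthScenario(
        density_profile=lambda h, t: rho0,
        timepoints_h=times,
        laser_heights_mm=heights,
        rng_seed=rng_seed,
        name="antibiotic",
    )


# ----------------------------------------------------------------------
# full dataset simulation
# ----------------------------------------------------------------------
@dataclass
class SimulatedGrowthDataset:
    """Lazily-rendered exposure stacks plus the generator's stored truth.

    ``stacks()`` yields ``(time_index, laser_index, ExposureStack)``;
    frames are rendered on demand so a full scan series never needs to
    sit in memory at once.  Per-frame RNG streams are spawned from the
    scenario seed and the (time, laser) indices, so the dataset is
    reproducible and iteration-order independent.
    """

    scenario: GrowthScenario
    geometry: VesselGeometry
    camera: CameraModel
    calibration: CalibrationModel
    amplitude: float
    exposures: tuple[float, ...]
    layout: SceneLayout
    truth: GrowthMap
    mueff_grid: np.ndarray  # ground-truth mu_eff at (height, time)

    def stack_for(self, time_index: int, laser_index: int) -> ExposureStack:
        mu = float(self.mueff_grid[laser_index, time_index])
        optics = OpticalProperties(mu_eff=mu)
        spot = (self.geometry.front_arc_mm, self.scenario.laser_heights_mm[laser_index])
        field_ = surface_intensity(self.geometry, optics, spot, self.amplitude)
        scene = render_views(field_, self.geometry, self.layout).values
        ss = np.random.SeedSequence(
            entropy=self.scenario.rng_seed, spawn_key=(time_index, laser_index)
        )
        return expose_stack(
            scene, self.exposures, self.camera, rng=np.random.default_rng(ss)
        )

    def stacks(self) -> Iterator[tuple[int, int, ExposureStack]]:
        for ti in range(len(self.scenario.timepoints_h)):
            for li in range(len(self.scenario.laser_heights_mm)):
                yield ti, li, self.stack_for(ti, li)


def simulate_growth_series(
    scenario: GrowthScenario,
    geometry: VesselGeometry | None = None,
    calibration: CalibrationModel = PAPER_CALIBRATION,
    camera: CameraModel = CameraModel(),
    *,
    amplitude: float = DEFAULT_AMPLITUDE,
    exposures=DEFAULT_EXPOSURES,
    opacity_bound: float = 5.0,
    min_fit_distance_mm: float = 5.0,
) -> SimulatedGrowthDataset:
    """Simulate a complete spatially-resolved growth monitoring run.

    For each (timepoint, laser position) the scenario density is mapped
    to ``mu_eff`` through the calibration model (background floor =
    model intercept), a surface intensity field is synthesised, rendered
    to three views and captured as an HDR exposure stack.  The ground
    truth growth map is the density profile normalised at the first
    timepoint.

    Warns when the medium is so opaque that
    ``mu_eff * min_fit_distance > opacity_bound`` -- the fit window
    would then be photon-starved and underdetermined.
    """
    geometry = geometry or default_geometry()
    if not calibration.slope > 0:
        raise ValidationError("calibration slope must be positive")
    density = scenario.density_grid()
    mueff_grid = np.asarray(mueff_from_density(density, calibration))
    if np.any(mueff_grid * min_fit_distance_mm > opacity_bound):
        warnings.warn(
            "medium opacity exceeds the configured bound inside the fit window; "
            "the attenuation fit may be underdetermined",
            stacklevel=2,
        )
    return SimulatedGrowthDataset(
        scenario=scenario,
        geometry=geometry,
        camera=camera,
        calibration=calibration,
        amplitude=amplitude,
        exposures=tuple(exposures),
        layout=view_layout(geometry),
        truth=scenario.truth_map(),
        mueff_grid=mueff_grid,
    )
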