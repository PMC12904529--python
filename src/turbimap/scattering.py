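"""Effective-scattering-parameter extraction from unwrapped images.

In the diffusion approximation for a semi-infinite turbid medium, the
surface intensity a distance ``d`` from a pencil-beam illumination spot
decays as ``I(d) = A * exp(-mu_eff * d) / d**2``, where ``mu_eff`` is
the effective scattering (attenuation) parameter of the medium.  Taking
the natural logarithm linearises the model,

    ln(I * d**2) = -mu_eff * d + k,

so an ordinary least-squares fit of ``ln(I d^2)`` against ``d`` yields
``mu_eff`` as minus the slope; the intercept ``k`` absorbs the source
amplitude and is not used further.  Profiles are taken along the
horizontal image row through the laser spot, within a fit window that
excludes the saturated region near the spot (default 5 mm) and the
low-signal far field (default beyond 30 mm).

``mu_eff`` relates to the absorption coefficient ``mu_a`` and reduced
scattering coefficient ``mu_s'`` through the diffusion-theory form
``mu_eff = sqrt(3 * mu_a * mu_s')`` (default convention here; a literal
product ``3 * mu_a * mu_s'`` is selectable).  All distances are mm and
all coefficients mm^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, InsufficientSamplesError, ValidationError
from .unwrapping import UnwrappedImage

__all__ = [
    "IntensityProfile",
    "ScatteringFit",
    "extract_profile",
    "linearize",
    "fit_mueff",
    "fit_spot",
    "mueff_from_coefficients",
    "scan_plan",
    "acquisition_schedule",
    "DEFAULT_FIT_WINDOW",
]

#: distance window (mm) of the attenuation fit; below 5 mm the sensor
#: saturates around the spot, beyond 30 mm the signal nears the floor
DEFAULT_FIT_WINDOW = (5.0, 30.0)


@dataclass(frozen=True)
class IntensityProfile:
    """Intensity-versus-distance samples along one horizontal line."""

    distances: np.ndarray  # mm from the laser spot, strictly increasing
    intensities: np.ndarray  # linear radiance values
    laser_spot: tuple[float, float]  # (arc mm, height mm)
    window: tuple[float, float] = DEFAULT_FIT_WINDOW
    side: str = "right"  # which side of the spot the samples came from

    def __post_init__(self):
        d = np.asarray(self.distances, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "distances", d)
        object.__setattr__(self, "intensities", i)
        if d.shape != i.shape or d.ndim != 1:
            raise ValidationError("distances and intensities must be matching 1-D arrays")
        if d.size and (np.any(np.diff(d) <= 0)):
            raise ValidationError("distances must be strictly increasing")
        lo, hi = self.window
        if d.size and (d.min() < lo - 1e-9 or d.max() > hi + 1e-9):
            raise ValidationError("distances must lie within the fit window")
        if np.any(~np.isfinite(i)) or np.any(i <= 0):
            raise ValidationError("retained intensities must be positive and finite")

    def __len__(self) -> int:
        return self.distances.size


@dataclass(frozen=True)
class ScatteringFit:
    """Result of the linearised attenuation fit for one profile."""

    mu_eff: float  # mm^-1; may be <= 0 in near-clear media (flagged, not an error)
    k: float  # intercept of ln(I d^2) = -mu_eff d + k
    r_squared: float
    stderr_mu_eff: float
    n_points: int

    def __post_init__(self):
        if self.n_points < 3:
            raise ValidationError("a fit needs at least 3 points")
        if not (0.0 <= self.r_squared <= 1.0 or math.isnan(self.r_squared)):
            raise ValidationError("r_squared must lie in [0, 1]")

    @property
    def scattering_detected(self) -> bool:
        """False in near-clear media where the fitted slope is <= 0."""
        return self.mu_eff > 0


def _side_samples(unwrapped, row_values, spot_arc, window, side):
    """Distances/intensities of one side's in-window, valid samples and
    whether the geometric window fully fits inside the image."""
    arc = unwrapped.arc_mm
    lo, hi = window
    if side == "right":
        d = arc - spot_arc
        full = spot_arc + hi <= arc[-1] + 0.5 * unwrapped.arc_pitch_mm + 1e-9
    else:
        d = spot_arc - arc
        full = spot_arc - hi >= arc[0] - 0.5 * unwrapped.arc_pitch_mm - 1e-9
    in_win = (d >= lo) & (d <= hi)
    d = d[in_win]
    vals = row_values[in_win]
    if side == "left":  # restore increasing distance order
        d = d[::-1]
        vals = vals[::-1]
    ok = np.isfinite(vals) & (vals > 0)
    return d[ok], vals[ok], full


def extract_profile(
    unwrapped: UnwrappedImage,
    laser_spot: tuple[float, float],
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    *,
    side: str = "auto",
    row_halfwidth: int = 0,
) -> IntensityProfile:
    """Extract intensity vs distance along the row through the laser spot.

    Samples are taken at pixel resolution along the horizontal row at
    the spot's height (optionally averaged over ``+/- row_halfwidth``
    neighbouring rows); pixels flagged invalid upstream or non-positive
    are dropped, and the region nearer than ``window[0]`` -- where the
    sensor saturates around the spot -- is excluded by construction.

    ``side='auto'`` prefers a side whose full window fits inside the
    image (relevant when the spot sits near the arc seam); when both
    qualify the right side is returned -- use :func:`fit_spot` to
    combine both sides.
    """
    if side not in ("auto", "left", "right"):
        raise ValidationError("side must be 'auto', 'left' or 'right'")
    spot_arc, spot_height = laser_spot
    heights = unwrapped.height_mm
    if not (heights[0] - 0.5 * unwrapped.row_pitch_mm <= spot_height
            <= heights[-1] + 0.5 * unwrapped.row_pitch_mm):
        raise ValidationError("laser spot height lies outside the image")
    row = int(np.argmin(np.abs(heights - spot_height)))
    r0 = max(0, row - row_halfwidth)
    r1 = min(heights.size, row + row_halfwidth + 1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        row_values = np.nanmean(unwrapped.values[r0:r1], axis=0)

    candidates = {}
    for s in ("left", "right"):
        if side in ("auto", s):
            candidates[s] = _side_samples(unwrapped, row_values, spot_arc, window, s)
    if side == "auto":
        full_sides = [s for s, (_, _, full) in candidates.items() if full]
        if full_sides:
            chosen = "right" if "right" in full_sides else "left"
        else:  # neither side complete: take the better-sampled one
            chosen = max(candidates, key=lambda s: candidates[s][0].size)
    else:
        chosen = side
    d, vals, _ = candidates[chosen]
    if d.size < 3:
        raise InsufficientSamplesError(
            f"only {d.size} valid samples in the {chosen} window; need >= 3"
        )
    return IntensityProfile(
        distances=d, intensities=vals, laser_spot=laser_spot, window=window, side=chosen
    )


def linearize(profile: IntensityProfile) -> tuple[np.ndarray, np.ndarray]:
    """Return ``(d, ln(I * d**2))`` pairs in increasing distance order."""
    if np.any(profile.intensities <= 0):
        raise ValidationError("non-positive intensity: upstream masking failed")
    d = profile.distances
    return d, np.log(profile.intensities * d**2)


def fit_mueff(profile: IntensityProfile) -> ScatteringFit:
    """Ordinary least-squares fit of the linearised attenuation model.

    Returns ``mu_eff = -slope`` with the intercept ``k``, the coefficient
    of determination and the slope's standard error.  A non-positive
    ``mu_eff`` (near-clear media) is reported, not raised.
    """
    d, y = linearize(profile)
    if d.size < 3:
        raise InsufficientSamplesError("need at least 3 points after linearization")
    if np.ptp(d) == 0:
        raise DegenerateDataError("degenerate profile: all distances equal")
    res = stats.linregress(d, y)
    return ScatteringFit(
        mu_eff=float(-res.slope),
        k=float(res.intercept),
        r_squared=float(res.rvalue**2),
        stderr_mu_eff=float(res.stderr),
        n_points=int(d.size),
    )


def fit_spot(
    unwrapped: UnwrappedImage,
    laser_spot: tuple[float, float],
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    *,
    row_halfwidth: int = 0,
) -> ScatteringFit:
    """Fit ``mu_eff`` at one laser spot, combining both profile sides.

    Each horizontal side that admits the full fit window is fitted
    separately and the estimates are averaged with inverse-variance
    weights; if only one side fits (spot near the arc seam) that side
    alone is used.
    """
    fits = []
    for s in ("left", "right"):
        try:
            prof = extract_profile(
                unwrapped, laser_spot, window, side=s, row_halfwidth=row_halfwidth
            )
        except (InsufficientSamplesError, ValidationError):
            continue
        fits.append(fit_mueff(prof))
    if not fits:
        raise InsufficientSamplesError("no side of the spot admits a usable profile")
    if len(fits) == 1:
        return fits[0]
    w = np.array([1.0 / max(f.stderr_mu_eff, 1e-30) ** 2 for f in fits])
    mu = float(np.sum(w * [f.mu_eff for f in fits]) / np.sum(w))
    best = fits[int(np.argmax(w))]
    return ScatteringFit(
        mu_eff=mu,
        k=best.k,
        r_squared=best.r_squared,
        stderr_mu_eff=float(1.0 / math.sqrt(np.sum(w))),
        n_points=sum(f.n_points for f in fits),
    )


def mueff_from_coefficients(
    mu_a: float, mu_s_prime: float, convention: str = "sqrt"
) -> float:
    """Effective scattering parameter from ``mu_a`` and ``mu_s'``.

    ``convention='sqrt'`` (default) uses the diffusion-theory form
    ``sqrt(3 * mu_a * mu_s')``; ``convention='product'`` uses the
    literal product ``3 * mu_a * mu_s'``.
    """
    if mu_a < 0 or mu_s_prime < 0:
        raise ValidationError("optical coefficients must be non-negative")
    if convention == "sqrt":
        return math.sqrt(3.0 * mu_a * mu_s_prime)
    if convention == "product":
        return 3.0 * mu_a * mu_s_prime
    raise ValidationError(f"unknown convention {convention!r}")


def scan_plan(spacing_mm: float, span_mm: float, start_mm: float = 0.0) -> np.ndarray:
    """Vertical laser positions covering ``span_mm`` at ``spacing_mm`` steps.

    Returns ``floor(span / spacing)`` heights (mm, downward from the top
    of the scan window), each centred in its coverage cell, so 5 mm
    spacing over 125 mm yields 25 positions.  A span that is not an
    integer multiple of the spacing is floored with a warning.
    """
    if not spacing_mm > 0:
        raise ValidationError("spacing must be positive")
    if span_mm < spacing_mm:
        raise ValidationError("span must be at least one spacing")
    ratio = span_mm / spacing_mm
    n = int(math.floor(ratio + 1e-9))
    if abs(ratio - round(ratio)) > 1e-9:
        warnings.warn(
            f"span {span_mm} mm is not a multiple of spacing {spacing_mm} mm; "
            f"using {n} positions",
            stacklevel=2,
        )
    return start_mm + spacing_mm * (np.arange(n) + 0.5)


def acquisition_schedule(interval_min: float, duration_h: float) -> np.ndarray:
    """Acquisition times (hours) for repeated scans over a monitoring run.

    One dataset per interval across the duration, starting at T = 0:
    ``floor(duration / interval)`` datasets, so 10-minute intervals over
    23 hours yield 138.
    """
    if not interval_min > 0 or not duration_h > 0:
        raise ValidationError("interval and duration must be positive")
    n = int(math.floor(duration_h * 60.0 / interval_min + 1e-9))
    return np.arange(n) * interval_min / 60.0
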