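"""HDR exposure-stack merging and photon-transfer camera characterisation.

The scattered-light signal spans several orders of magnitude between
pixels near the laser spot and pixels 30 mm away, far exceeding a
single frame's dynamic range.  Each (timepoint, laser position) is
therefore captured as a stack of frames at increasing exposure times
and merged into one linear radiance map.

Merge rule: per pixel, take the longest exposure that stayed below the
saturation margin and scale it to counts per unit exposure.  This keeps
the estimator radiometrically linear and maximises per-pixel SNR
without the bias bookkeeping of weighted averaging.  Pixels saturated
in every frame are flagged invalid (NaN) and excluded downstream.

Sensor gain and read noise are estimated by the temporal-variance
(photon-transfer) method: for pairs of frames under identical
illumination, the temporal variance ``var(A - B) / 2`` is regressed on
the mean signal above black level; the slope is the gain in counts per
photo-event and the intercept is the read-noise variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "RawFrame",
    "ExposureStack",
    "CameraNoiseModel",
    "MergedRadiance",
    "hdr_merge",
    "estimate_noise_model",
]


@dataclass(frozen=True)
class RawFrame:
    """One camera frame in integer counts at a known exposure time."""

    values: np.ndarray
    exposure: float
    black_level: float
    full_well: float

    def __post_init__(self):
        values = np.asarray(self.values)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValidationError("frame values must be 2-D")
        if not self.exposure > 0:
            raise ValidationError("exposure must be positive")
        if not self.full_well > self.black_level:
            raise ValidationError("full_well must exceed black_level")
        if values.size and (values.min() < 0 or values.max() > self.full_well):
            raise ValidationError("counts must lie in [0, full_well]")


@dataclass(frozen=True)
class ExposureStack:
    """Co-registered frames of one scene at strictly increasing exposures."""

    frames: tuple[RawFrame, ...]
    saturation_margin: float = 0.95

    def __post_init__(self):
        object.__setattr__(self, "frames", tuple(self.frames))
        if not self.frames:
            raise ValidationError("exposure stack is empty")
        shapes = {f.values.shape for f in self.frames}
        if len(shapes) != 1:
            raise ValidationError(f"frames have mismatched shapes: {sorted(shapes)}")
        exposures = [f.exposure for f in self.frames]
        if any(b <= a for a, b in zip(exposures, exposures[1:])):
            raise ValidationError("exposures must be strictly increasing")
        if not 0.0 < self.saturation_margin <= 1.0:
            raise ValidationError("saturation_margin must lie in (0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames[0].values.shape


@dataclass(frozen=True)
class CameraNoiseModel:
    """Photon-transfer sensor model: gain, read noise, black level."""

    gain: float  # counts per photo-event
    read_noise_sd: float  # counts
    black_level: float  # counts
    valid: bool = True
    r_squared: float = float("nan")
    levels: tuple[tuple[float, float], ...] = ()  # fitted (mean, variance) points

    def __post_init__(self):
        if self.gain < 0:
            raise ValidationError("negative gain signals invalid data")
        if self.read_noise_sd < 0:
            raise ValidationError("read_noise_sd must be non-negative")


@dataclass
class MergedRadiance:
    """Linear radiance map in counts per unit exposure.

    ``values`` is NaN wherever ``valid`` is False (saturated in every
    exposure)."""

    values: np.ndarray
    valid: np.ndarray
    exposure_index: np.ndarray  # which frame supplied each pixel


def hdr_merge(stack: ExposureStack) -> MergedRadiance:
    """Merge an exposure stack into a linear radiance map.

    Per pixel the longest unsaturated exposure is selected and scaled by
    ``(value - black_level) / exposure``, floored at zero.  Raises
    :class:`DegenerateDataError` if every pixel saturates in every frame.
    """
    cube = np.stack([f.values.astype(float) for f in stack.frames])
    exposures = np.array([f.exposure for f in stack.frames])
    blacks = np.array([f.black_level for f in stack.frames])
    thresholds = np.array([stack.saturation_margin * f.full_well for f in stack.frames])

    unsaturated = cube < thresholds[:, None, None]
    any_ok = unsaturated.any(axis=0)
    if not any_ok.any():
        raise DegenerateDataError("every pixel is saturated in every exposure")
    # index of the longest (= last, exposures increase) unsaturated frame
    idx = cube.shape[0] - 1 - np.argmax(unsaturated[::-1], axis=0)
    picked = np.take_along_axis(cube, idx[None], axis=0)[0]
    values = np.maximum(picked - blacks[idx], 0.0) / exposures[idx]
    values[~any_ok] = np.nan
    return MergedRadiance(values=values, valid=any_ok, exposure_index=idx)


def estimate_noise_model(
    frame_pairs: list[tuple[RawFrame, RawFrame]],
    *,
    min_signal: float = 1.0,
) -> CameraNoiseModel:
    """Fit gain and read noise from same-illumination frame pairs.

    Each pair contributes one photon-transfer point: mean signal
    ``m = mean((A + B) / 2) - black_level`` and temporal variance
    ``v = var(A - B) / 2``.  Points with ``m < min_signal`` carry no
    photon signal and are discarded; at least three informative levels
    must remain.  ``v = gain * m + read_noise_sd**2`` is then fit by
    ordinary least squares.
    """
    if not frame_pairs:
        raise DegenerateDataError("no frame pairs supplied")
    means, variances = [], []
    black = frame_pairs[0][0].black_level
    for a, b in frame_pairs:
        if a.values.shape != b.values.shape:
            raise ValidationError("frame pair is not co-registered (shape mismatch)")
        av = a.values.astype(float)
        bv = b.values.astype(float)
        means.append(float(np.mean(0.5 * (av + bv))) - black)
        variances.append(float(np.var(av - bv) / 2.0))
    m = np.array(means)
    v = np.array(variances)
    keep = m >= min_signal
    if np.unique(np.round(m[keep], 6)).size < 3:
        raise DegenerateDataError(
            "fewer than 3 levels of signal available for the photon-transfer fit"
        )
    fit = stats.linregress(m[keep], v[keep])
    if fit.slope < -1e-12:
        raise ValidationError("negative fitted gain signals invalid data")
    gain = max(float(fit.slope), 0.0)
    read_noise_sd = float(np.sqrt(max(fit.intercept, 0.0)))
    return CameraNoiseModel(
        gain=gain,
        read_noise_sd=read_noise_sd,
        black_level=black,
        valid=gain > 0,
        r_squared=float(fit.rvalue**2),
        levels=tuple(zip(m[keep].tolist(), v[keep].tolist())),
    )
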