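"""Growth-factor maps and curves from per-(time, height) scattering fits.

Each fitted ``mu_eff(height, time)`` is converted to a cell density via
the vessel calibration, then every height row is normalised by its own
T = 0 density to give a dimensionless growth factor (fold change).
Rows known to produce spurious readings -- e.g. specular glints from
the vessel surface at particular laser heights -- can be masked
manually or flagged automatically by a robust outlier rule; masked rows
keep their values for auditability but are excluded from all summary
statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import median_abs_deviation

from .calibration import CalibrationModel, density_from_mueff
from .errors import DegenerateDataError, ValidationError

__all__ = [
    "GrowthMap",
    "GrowthCurve",
    "assemble_growth_map",
    "mean_growth_curve",
    "flag_spurious_rows",
    "replicate_growth_stats",
]

MASK_MANUAL = "specular"
MASK_AUTO = "auto-specular"
MASK_BASELINE = "nonpositive-baseline"


@dataclass
class GrowthMap:
    """Time-by-height grid of growth factors with a per-row validity mask.

    ``growth[i, j]`` is the fold change at height ``heights_mm[i]`` and
    time ``times_h[j]`` relative to the first timepoint of that row.
    ``row_reason[i]`` is ``None`` for valid rows, else a reason code
    (``"specular"``, ``"auto-specular"``, ``"nonpositive-baseline"``).
    """

    growth: np.ndarray
    heights_mm: np.ndarray
    times_h: np.ndarray
    row_reason: list[str | None] = field(default_factory=list)

    def __post_init__(self):
        self.growth = np.asarray(self.growth, dtype=float)
        self.heights_mm = np.asarray(self.heights_mm, dtype=float)
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.growth.shape != (self.heights_mm.size, self.times_h.size):
            raise ValidationError("growth grid shape must be (n_heights, n_times)")
        if not self.row_reason:
            self.row_reason = [None] * self.heights_mm.size
        if len(self.row_reason) != self.heights_mm.size:
            raise ValidationError("one mask entry per height row required")

    @property
    def row_valid(self) -> np.ndarray:
        return np.array([r is None for r in self.row_reason])

    def unmasked(self) -> np.ndarray:
        return self.growth[self.row_valid]


@dataclass(frozen=True)
class GrowthCurve:
    """Per-timepoint mean and sample SD of growth factors."""

    times_h: np.ndarray
    mean_growth: np.ndarray
    sd_growth: np.ndarray
    n: int  # heights or replicates averaged

    def __post_init__(self):
        if np.any(np.asarray(self.sd_growth) < 0):
            raise ValidationError("sd_growth must be non-negative")


def _mueff_grid(fits) -> np.ndarray:
    grid = np.asarray(fits)
    if grid.dtype == object:  # grid of ScatteringFit objects
        grid = np.vectorize(lambda f: f.mu_eff, otypes=[float])(grid)
    return grid.astype(float)


def assemble_growth_map(
    fits,
    heights_mm,
    times_h,
    model: CalibrationModel,
    mask_heights=(),
    *,
    mask_tolerance_mm: float | None = None,
) -> GrowthMap:
    """Build a growth map from a ``(height, time)`` grid of fits.

    ``fits`` is a 2-D array of ``mu_eff`` values or ScatteringFit
    objects with the T = 0 column first.  Densities come from the
    calibration model; each row is divided by its own T = 0 density.
    Rows whose height matches an entry of ``mask_heights`` (within
    ``mask_tolerance_mm``, default half the row spacing) are flagged
    ``"specular"``; rows with a non-positive baseline density are
    auto-masked ``"nonpositive-baseline"``.
    """
    mu = _mueff_grid(fits)
    heights = np.asarray(heights_mm, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if mu.shape != (heights.size, times.size):
        raise ValidationError("fit grid shape must be (n_heights, n_times)")
    density = density_from_mueff(mu, model)
    baseline = density[:, 0]
    reasons: list[str | None] = [None] * heights.size

    if mask_tolerance_mm is None:
        spacing = np.median(np.diff(heights)) if heights.size > 1 else 1.0
        mask_tolerance_mm = 0.5 * float(spacing)
    for h in mask_heights:
        hits = np.nonzero(np.abs(heights - h) <= mask_tolerance_mm + 1e-9)[0]
        for i in hits:
            reasons[i] = MASK_MANUAL

    with np.errstate(divide="ignore", invalid="ignore"):
        growth = density / baseline[:, None]
    for i in range(heights.size):
        if baseline[i] <= 0 and reasons[i] is None:
            reasons[i] = MASK_BASELINE
    return GrowthMap(growth=growth, heights_mm=heights, times_h=times, row_reason=reasons)


def mean_growth_curve(gmap: GrowthMap) -> GrowthCurve:
    """Vessel-average growth curve over unmasked height rows."""
    rows = gmap.unmasked()
    if rows.shape[0] == 0:
        raise DegenerateDataError("all height rows are masked")
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=1) if rows.shape[0] > 1 else np.zeros(rows.shape[1])
    return GrowthCurve(times_h=gmap.times_h, mean_growth=mean, sd_growth=sd, n=rows.shape[0])


def flag_spurious_rows(gmap: GrowthMap, z_threshold: float = 3.5) -> GrowthMap:
    """Flag outlier rows by a robust (MAD-based) z-score.

    Each unmasked row is summarised by its median growth over time; rows
    deviating from the cross-row median by more than ``z_threshold``
    robust z-scores (1.4826 x median absolute deviation scale) are
    flagged ``"auto-specular"``.  Manual masks take precedence and at
    least 4 unmasked rows are required.
    """
    valid = gmap.row_valid
    if valid.sum() < 4:
        raise DegenerateDataError("need at least 4 unmasked rows to flag outliers")
    summary = np.median(gmap.growth[valid], axis=1)
    center = np.median(summary)
    scale = median_abs_deviation(summary, scale="normal")
    deviation = np.abs(summary - center)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(deviation > 0, deviation / scale if scale > 0 else np.inf, 0.0)
    reasons = list(gmap.row_reason)
    for idx, zi in zip(np.nonzero(valid)[0], z):
        if zi > z_threshold:
            reasons[idx] = MASK_AUTO
    return replace(gmap, growth=gmap.growth.copy(), row_reason=reasons)


def replicate_growth_stats(times_h, replicate_curves) -> GrowthCurve:
    """Mean and sample SD of growth factors across repeated experiments.

    ``replicate_curves`` is ``(n_replicates, n_times)`` of raw signals
    (OD600 or optically-derived density) on a common time grid; each
    replicate is normalised to its own T = 0 value first.
    """
    curves = np.asarray(replicate_curves, dtype=float)
    times = np.asarray(times_h, dtype=float)
    if curves.ndim != 2 or curves.shape[1] != times.size:
        raise ValidationError("replicate_curves must be (n_replicates, n_times)")
    if curves.shape[0] < 2:
        raise DegenerateDataError("need at least 2 replicates")
    baseline = curves[:, 0]
    if np.any(baseline <= 0):
        raise ValidationError("every replicate needs a positive T = 0 value")
    normalised = curves / baseline[:, None]
    return GrowthCurve(
        times_h=times,
        mean_growth=normalised.mean(axis=0),
        sd_growth=normalised.std(axis=0, ddof=1),
        n=curves.shape[0],
    )
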