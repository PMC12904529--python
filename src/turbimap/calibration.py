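"""Calibration between the effective scattering parameter and cell density.

At low concentrations both absorption and reduced scattering grow
linearly with the number of suspended cells, so ``mu_eff`` is an affine
function of density: ``mu_eff = intercept + slope * rho``.  The
intercept is non-zero even at zero cells because the vessel's internal
plastic manifold and surface imperfections scatter on their own; it is
a fixed property of the vessel.  Inverting the fit gives

    rho [cells/mL] = (mu_eff - intercept) / slope.

The calibration experiment steps the vessel density by adding equal
aliquots of a harvested culture whose total cell count is estimated
from an OD600 reading, then measures ``mu_eff`` at each step.  The
regression runs ``mu_eff`` on density because density is the
controlled variable; the lowest-concentration points are excluded
(default: the two lowest) since the method needs a scattering medium to
be applicable at all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "CalibrationModel",
    "ODMeasurement",
    "AliquotPlan",
    "od600_to_density",
    "plan_aliquots",
    "fit_calibration",
    "density_from_mueff",
    "mueff_from_density",
    "PAPER_CALIBRATION",
    "DEFAULT_OD600_FACTOR",
]

#: cells/mL per OD600 unit in the linear regime (E. coli convention)
DEFAULT_OD600_FACTOR = 8.0e8


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map ``mu_eff = intercept + slope * density``.

    slope is in mm^-1 per (cells/mL); intercept (mm^-1) is the
    zero-cell scattering floor of the vessel itself.
    """

    slope: float
    intercept: float
    r_squared: float = float("nan")
    excluded_points: tuple[int, ...] = ()
    n_points: int = 0
    stderr_slope: float = float("nan")

    def __post_init__(self):
        if not self.slope > 0:
            raise ValidationError("calibration slope must be positive")

    def density(self, mu_eff):
        return density_from_mueff(mu_eff, self)

    def mueff(self, rho):
        return mueff_from_density(rho, self)


#: the reference vessel calibration shipped with the package, so the
#: published conversion can be applied without refitting
PAPER_CALIBRATION = CalibrationModel(
    slope=8.23e-12, intercept=7.58e-2, r_squared=0.9322, n_points=14
)


@dataclass(frozen=True)
class ODMeasurement:
    """A spectrophotometer OD600 reading of a cell suspension."""

    od600: float
    volume_ml: float = 1.0
    conversion_factor: float = DEFAULT_OD600_FACTOR  # cells/mL per OD unit

    def __post_init__(self):
        if self.od600 < 0:
            raise ValidationError("od600 must be non-negative")
        if not self.volume_ml > 0:
            raise ValidationError("volume must be positive")
        if not self.conversion_factor > 0:
            raise ValidationError("conversion_factor must be positive")


@dataclass(frozen=True)
class AliquotPlan:
    """Splitting a harvested culture into equal density-step aliquots."""

    total_cells: float
    n_aliquots: int
    vessel_volume_ml: float
    cells_per_aliquot: float
    density_increment: float  # cells/mL added to the vessel per aliquot

    def __post_init__(self):
        if abs(self.cells_per_aliquot - self.total_cells / self.n_aliquots) > 1e-6 * max(
            1.0, self.cells_per_aliquot
        ):
            raise ValidationError("cells_per_aliquot must equal total_cells / n_aliquots")
        if abs(
            self.density_increment - self.cells_per_aliquot / self.vessel_volume_ml
        ) > 1e-6 * max(1.0, self.density_increment):
            raise ValidationError("density_increment must equal cells_per_aliquot / vessel_volume")


def od600_to_density(m: ODMeasurement) -> float:
    """Cell density (cells/mL) implied by an OD600 reading.

    Assumes the linear low-concentration regime, where an OD600 of 1.0
    corresponds to ``conversion_factor`` cells/mL (default 8e8, under
    which an OD600 of 9.1 maps to 7.28e9 cells/mL).
    """
    return m.od600 * m.conversion_factor


def plan_aliquots(
    od600: float,
    culture_volume_ml: float,
    n_aliquots: int,
    vessel_volume_ml: float,
    conversion_factor: float = DEFAULT_OD600_FACTOR,
) -> AliquotPlan:
    """Plan the calibration-experiment density steps from one OD reading."""
    if n_aliquots <= 0:
        raise ValidationError("n_aliquots must be positive")
    if culture_volume_ml <= 0 or vessel_volume_ml <= 0:
        raise ValidationError("volumes must be positive")
    density = od600_to_density(ODMeasurement(od600, conversion_factor=conversion_factor))
    total = density * culture_volume_ml
    per_aliquot = total / n_aliquots
    return AliquotPlan(
        total_cells=total,
        n_aliquots=n_aliquots,
        vessel_volume_ml=vessel_volume_ml,
        cells_per_aliquot=per_aliquot,
        density_increment=per_aliquot / vessel_volume_ml,
    )


def fit_calibration(
    densities,
    mu_effs,
    *,
    exclude_lowest: int = 2,
    exclude_indices=None,
) -> CalibrationModel:
    """Ordinary least-squares fit of ``mu_eff`` on cell density.

    The exclusion rule is either an explicit index list or "drop the
    ``exclude_lowest`` lowest densities" (default 2): the lowest
    concentrations carry no usable scattering signal.  At least three
    points must remain.  A non-positive fitted slope signals a
    non-scattering regime and raises :class:`DegenerateDataError`.
    """
    rho = np.asarray(densities, dtype=float)
    mu = np.asarray(mu_effs, dtype=float)
    if rho.shape != mu.shape or rho.ndim != 1:
        raise ValidationError("densities and mu_effs must be matching 1-D sequences")
    if exclude_indices is not None:
        excluded = tuple(sorted(int(i) for i in exclude_indices))
    else:
        excluded = tuple(sorted(np.argsort(rho, kind="stable")[:exclude_lowest].tolist()))
    keep = np.setdiff1d(np.arange(rho.size), excluded)
    if keep.size < 3:
        raise DegenerateDataError("fewer than 3 calibration points after exclusion")
    res = stats.linregress(rho[keep], mu[keep])
    if not res.slope > 0:
        raise DegenerateDataError(
            "non-positive calibration slope: non-scattering regime or bad data"
        )
    return CalibrationModel(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        excluded_points=excluded,
        n_points=int(keep.size),
        stderr_slope=float(res.stderr),
    )


def density_from_mueff(mu_eff, model: CalibrationModel):
    """Cell density from a measured ``mu_eff``.

    May be negative when ``mu_eff`` drifts below the vessel's zero-cell
    scattering floor; negative values are returned unclamped so the
    caller can detect and flag them.
    """
    return (np.asarray(mu_eff, dtype=float) - model.intercept) / model.slope


def mueff_from_density(rho, model: CalibrationModel):
    """Exact inverse of :func:`density_from_mueff`."""
    return model.intercept + model.slope * np.asarray(rho, dtype=float)
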