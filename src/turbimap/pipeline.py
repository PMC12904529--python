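"""End-to-end processing: exposure stacks -> growth map.

Chains the measurement stages exactly as they run on instrument data:
HDR-merge each stack, unwrap the merged frame to the flat vessel
surface, fit the effective scattering parameter around the commanded
laser spot, convert to cell density through the calibration, and
normalise per height to growth factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationModel
from .geometry import VesselGeometry
from .growth import GrowthMap, assemble_growth_map
from .hdr import ExposureStack, hdr_merge
from .scattering import DEFAULT_FIT_WINDOW, ScatteringFit, fit_spot
from .unwrapping import RegionPolygon, unwrap

__all__ = ["process_stack", "recover_fits", "recover_growth_map"]


def process_stack(
    stack: ExposureStack,
    polygons: list[RegionPolygon],
    geometry: VesselGeometry,
    laser_spot: tuple[float, float],
    *,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    row_halfwidth: int = 2,
) -> ScatteringFit:
    """Merge, unwrap and fit one (timepoint, laser position) stack.

    The laser spot is taken from the commanded scan plan (the spot
    pixel itself saturates); the profile is averaged over
    ``+/- row_halfwidth`` rows and both horizontal sides are combined,
    which suppresses shot noise without biasing the slope.
    """
    merged = hdr_merge(stack)
    unwrapped = unwrap(merged.values, polygons, geometry)
    return fit_spot(unwrapped, laser_spot, window, row_halfwidth=row_halfwidth)


def recover_fits(
    dataset,
    *,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    row_halfwidth: int = 2,
) -> np.ndarray:
    """Fit every stack of a simulated/loaded dataset.

    ``dataset`` needs ``geometry``, ``layout``, a ``scenario`` carrying
    ``laser_heights_mm`` / ``timepoints_h``, and a ``stacks()``
    iterator -- the interface of
    :class:`~turbimap.synthetic.SimulatedGrowthDataset` and of datasets
    loaded from disk.  Returns an object array of
    :class:`~turbimap.scattering.ScatteringFit` shaped (height, time).
    """
    n_h = len(dataset.scenario.laser_heights_mm)
    n_t = len(dataset.scenario.timepoints_h)
    polygons = dataset.layout.polygons()
    front_arc = dataset.geometry.front_arc_mm
    fits = np.empty((n_h, n_t), dtype=object)
    for ti, li, stack in dataset.stacks():
        spot = (front_arc, dataset.scenario.laser_heights_mm[li])
        fits[li, ti] = process_stack(
            stack,
            polygons,
            dataset.geometry,
            spot,
            window=window,
            row_halfwidth=row_halfwidth,
        )
    return fits


def recover_growth_map(
    dataset,
    calibration: CalibrationModel | None = None,
    mask_heights=(),
    *,
    window: tuple[float, float] = DEFAULT_FIT_WINDOW,
    row_halfwidth: int = 2,
) -> GrowthMap:
    """Run the full pipeline on a dataset and assemble the growth map."""
    calibration = calibration or dataset.calibration
    fits = recover_fits(dataset, window=window, row_halfwidth=row_halfwidth)
    return assemble_growth_map(
        fits,
        np.asarray(dataset.scenario.laser_heights_mm),
        np.asarray(dataset.scenario.timepoints_h),
        calibration,
        mask_heights,
    )
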