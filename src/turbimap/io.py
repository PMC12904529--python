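"""File formats: datasets of exposure stacks, unwrapped images, fit
tables, calibration models and growth maps.

Frames are 16-bit grayscale TIFF (PNG accepted on read); tables are CSV
with a JSON metadata sidecar recording units, seed, package version and
a configuration hash, so a written artifact can be re-read bit-exactly
and traced back to the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__ as _version
from .calibration import CalibrationModel
from .errors import ValidationError
from .geometry import VesselGeometry
from .growth import GrowthMap
from .hdr import ExposureStack, RawFrame
from .synthetic import CameraModel, SimulatedGrowthDataset, view_layout
from .unwrapping import UnwrappedImage

__all__ = [
    "config_hash",
    "read_frames",
    "write_dataset",
    "read_dataset",
    "write_unwrapped",
    "read_unwrapped",
    "write_fits",
    "read_fits",
    "write_calibration",
    "read_calibration",
    "write_growth_map",
    "read_growth_map",
    "DiskGrowthDataset",
]


def config_hash(obj) -> str:
    """Stable sha256 of a JSON-serialisable configuration object."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _sidecar(path: Path, payload: dict) -> None:
    payload = {"package_version": _version, **payload}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _read_image(path: Path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    if path.suffix.lower() == ".png":
        import imageio.v3 as iio

        return np.asarray(iio.imread(path))
    raise ValidationError(f"unsupported image format: {path.suffix}")


# ----------------------------------------------------------------------
# exposure stacks / datasets
# ----------------------------------------------------------------------
def read_frames(
    stack_dir,
    exposures,
    black_level: float,
    full_well: float,
) -> ExposureStack:
    """Read one exposure stack from ``{exposure_index}.tif`` files."""
    stack_dir = Path(stack_dir)
    frames = []
    for ei, exposure in enumerate(exposures):
        candidates = [stack_dir / f"{ei}.tif", stack_dir / f"{ei}.png"]
        path = next((p for p in candidates if p.exists()), None)
        if path is None:
            raise ValidationError(f"missing frame {ei} in {stack_dir}")
        values = _read_image(path)
        if values.ndim != 2:
            raise ValidationError(f"malformed frame {path}: expected 2-D grayscale")
        frames.append(
            RawFrame(values=values, exposure=exposure, black_level=black_level, full_well=full_well)
        )
    return ExposureStack(frames=tuple(frames))


def _geometry_to_dict(geometry: VesselGeometry) -> dict:
    return dataclasses.asdict(geometry)


def _geometry_from_dict(d: dict) -> VesselGeometry:
    d = dict(d)
    d["baffles"] = tuple(tuple(b) for b in d["baffles"])
    d["front_sector"] = tuple(d["front_sector"])
    d["mirror_view_sectors"] = tuple(tuple(s) for s in d["mirror_view_sectors"])
    return VesselGeometry(**d)


def write_dataset(dataset: SimulatedGrowthDataset, outdir, extra_metadata: dict | None = None) -> Path:
    """Write a simulated dataset as a directory tree.

    Frames go to ``frames/{time_index}/{laser_index}/{exposure_index}.tif``
    (16-bit grayscale); geometry, optics, exposures and seed to a single
    ``metadata.json`` sidecar; the ground-truth growth map to
    ``truth_growth.csv`` (rows = heights mm, columns = timepoints h).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {
        "seed": dataset.scenario.rng_seed,
        "scenario": dataset.scenario.name,
        "timepoints_h": list(dataset.scenario.timepoints_h),
        "laser_heights_mm": list(dataset.scenario.laser_heights_mm),
        "exposures": list(dataset.exposures),
        "amplitude": dataset.amplitude,
        "geometry": _geometry_to_dict(dataset.geometry),
        "camera": dataclasses.asdict(dataset.camera),
        "calibration": {
            "slope": dataset.calibration.slope,
            "intercept": dataset.calibration.intercept,
        },
        "units": {"length": "mm", "mu_eff": "1/mm", "time": "h", "density": "cells/mL"},
    }
    meta["config_hash"] = config_hash(meta)
    if extra_metadata:
        meta.update(extra_metadata)
    _sidecar(outdir / "metadata.json", meta)

    truth = dataset.truth
    df = pd.DataFrame(
        truth.growth,
        index=pd.Index(truth.heights_mm, name="height_mm"),
        columns=[f"t={t:g}h" for t in truth.times_h],
    )
    df.to_csv(outdir / "truth_growth.csv")

    for ti, li, stack in dataset.stacks():
        stack_dir = outdir / "frames" / str(ti) / str(li)
        stack_dir.mkdir(parents=True, exist_ok=True)
        for ei, frame in enumerate(stack.frames):
            tifffile.imwrite(stack_dir / f"{ei}.tif", frame.values.astype(np.uint16))
    return outdir


@dataclass
class _DatasetIndex:
    """Scenario-shaped index of a dataset loaded from disk."""

    timepoints_h: tuple
    laser_heights_mm: tuple
    rng_seed: int
    name: str


@dataclass
class DiskGrowthDataset:
    """A dataset directory exposing the in-memory dataset interface."""

    root: Path
    scenario: _DatasetIndex
    geometry: VesselGeometry
    camera: CameraModel
    calibration: CalibrationModel
    exposures: tuple
    layout: object

    def stack_for(self, time_index: int, laser_index: int) -> ExposureStack:
        return read_frames(
            self.root / "frames" / str(time_index) / str(laser_index),
            self.exposures,
            self.camera.black_level,
            self.camera.full_well,
        )

    def stacks(self):
        for ti in range(len(self.scenario.timepoints_h)):
            for li in range(len(self.scenario.laser_heights_mm)):
                yield ti, li, self.stack_for(ti, li)


def read_dataset(root) -> DiskGrowthDataset:
    root = Path(root)
    meta_path = root / "metadata.json"
    if not meta_path.exists():
        raise ValidationError(f"missing metadata sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    geometry = _geometry_from_dict(meta["geometry"])
    return DiskGrowthDataset(
        root=root,
        scenario=_DatasetIndex(
            timepoints_h=tuple(meta["timepoints_h"]),
            laser_heights_mm=tuple(meta["laser_heights_mm"]),
            rng_seed=meta["seed"],
            name=meta.get("scenario", "unknown"),
        ),
        geometry=geometry,
        camera=CameraModel(**meta["camera"]),
        calibration=CalibrationModel(
            slope=meta["calibration"]["slope"], intercept=meta["calibration"]["intercept"]
        ),
        exposures=tuple(meta["exposures"]),
        layout=view_layout(geometry),
    )


# ----------------------------------------------------------------------
# unwrapped images
# ----------------------------------------------------------------------
def write_unwrapped(image: UnwrappedImage, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image.values.astype(np.float32))
    tifffile.imwrite(path.with_suffix(".prov.tif"), image.provenance.astype(np.int8))
    _sidecar(
        path.with_suffix(".json"),
        {
            "arc_mm": image.arc_mm.tolist(),
            "height_mm": image.height_mm.tolist(),
            "units": {"length": "mm"},
        },
    )
    return path


def read_unwrapped(path) -> UnwrappedImage:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    prov_path = path.with_suffix(".prov.tif")
    return UnwrappedImage(
        values=tifffile.imread(path).astype(float),
        arc_mm=np.array(meta["arc_mm"]),
        height_mm=np.array(meta["height_mm"]),
        provenance=tifffile.imread(prov_path) if prov_path.exists() else None,
    )


# ----------------------------------------------------------------------
# fit tables and models
# ----------------------------------------------------------------------
def write_fits(table: pd.DataFrame, path, metadata: dict | None = None) -> Path:
    """Write a per-(time, height) fit table as CSV plus JSON sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    _sidecar(
        path.with_suffix(".json"),
        {"units": {"mu_eff": "1/mm", "height_mm": "mm", "time_h": "h"}, **(metadata or {})},
    )
    return path


def read_fits(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


def write_calibration(model: CalibrationModel, path, metadata: dict | None = None) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "slope": model.slope,
        "intercept": model.intercept,
        "r_squared": model.r_squared,
        "excluded_points": list(model.excluded_points),
        "n_points": model.n_points,
        "units": {"slope": "mm^-1 per cells/mL", "intercept": "mm^-1"},
        **(metadata or {}),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_calibration(path) -> CalibrationModel:
    d = json.loads(Path(path).read_text())
    return CalibrationModel(
        slope=d["slope"],
        intercept=d["intercept"],
        r_squared=d.get("r_squared", float("nan")),
        excluded_points=tuple(d.get("excluded_points", ())),
        n_points=d.get("n_points", 0),
    )


# ----------------------------------------------------------------------
# growth maps
# ----------------------------------------------------------------------
def write_growth_map(gmap: GrowthMap, path, metadata: dict | None = None) -> Path:
    """CSV with one row per height; masked rows carry their reason string."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(gmap.growth, columns=[f"t={t:g}h" for t in gmap.times_h])
    df.insert(0, "height_mm", gmap.heights_mm)
    df.insert(1, "mask_reason", ["" if r is None else r for r in gmap.row_reason])
    df.to_csv(path, index=False)
    _sidecar(
        path.with_suffix(".json"),
        {
            "times_h": gmap.times_h.tolist(),
            "units": {"height_mm": "mm", "growth": "fold change vs T=0"},
            **(metadata or {}),
        },
    )
    return path


def read_growth_map(path) -> GrowthMap:
    path = Path(path)
    df = pd.read_csv(path, keep_default_na=False, float_precision="round_trip")
    meta = json.loads(path.with_suffix(".json").read_text())
    time_cols = [c for c in df.columns if c.startswith("t=")]
    return GrowthMap(
        growth=df[time_cols].to_numpy(dtype=float),
        heights_mm=df["height_mm"].to_numpy(dtype=float),
        times_h=np.array(meta["times_h"], dtype=float),
        row_reason=[r if r else None for r in df["mask_reason"].tolist()],
    )
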