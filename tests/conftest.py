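"""Shared fixtures: compact geometries and noiseless optics that keep
unit tests fast while exercising the same code paths as full-size runs."""

import numpy as np
import pytest

from turbimap.geometry import VesselGeometry
from turbimap.synthetic import CameraModel, OpticalProperties, surface_intensity


@pytest.fixture()
def geometry():
    """Full-size reference vessel grid (280 x 817 at 0.5 mm pitch)."""
    return VesselGeometry()


@pytest.fixture()
def small_geometry():
    """A compact vessel for cheap tests: 120 x 503 grid at 0.5 mm pitch."""
    return VesselGeometry(radius_mm=40.0, scan_window_height_mm=60.0, liquid_top_mm=6.0)


@pytest.fixture()
def camera():
    return CameraModel()


@pytest.fixture()
def centered_spot(small_geometry):
    """Laser spot on the front axis, exactly on a row centre."""
    h = small_geometry.height_centers()[len(small_geometry.height_centers()) // 2]
    return (small_geometry.front_arc_mm, float(h))


@pytest.fixture()
def noiseless_scene(small_geometry, centered_spot):
    """Noise-free forward-model field at mu_eff = 0.1 mm^-1."""
    return surface_intensity(
        small_geometry, OpticalProperties(mu_eff=0.1), centered_spot, amplitude=1e6
    )


def seam_margin_mask(provenance, margin=2):
    """Boolean mask of columns within ``margin`` pixels of a stitch seam."""
    prov = np.asarray(provenance)
    row = prov[0].astype(int)
    seam = np.zeros(row.size, dtype=bool)
    change = np.nonzero(np.diff(row) != 0)[0]
    for c in change:
        seam[max(0, c - margin + 1) : c + margin + 1] = True
    seam[:margin] = True  # wrap-around seam at arc = 0
    seam[-margin:] = True
    return np.broadcast_to(seam, prov.shape)
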