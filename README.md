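# turbimap

Spatially-resolved optical monitoring of biomass in cylindrical
bioreactors, using the diffuse scattering of a scanned laser as a proxy
for local cell density.

## The problem

Cell cultures in stirred bioreactors are usually monitored by drawing
aliquots and reading OD₆₀₀ in a spectrophotometer — a single-point,
manual measurement that says nothing about spatial heterogeneity inside
the vessel. Yet stirred vessels are known to develop height-dependent
gradients in mixing, oxygen, and growth. Direct imaging through a dense
culture is impossible precisely because the cells scatter light; this
toolkit turns that parasitic scattering into the measurement itself.

A laser is stepped down the front of the vessel; a camera (plus two
flanking mirrors covering the rear surface) records the diffuse glow
emerging around each illumination spot. In the diffusion approximation
for a semi-infinite turbid medium, the surface intensity a distance *d*
from the spot follows

    I(d) ∝ exp(−μ_eff · d) / d²      ⇔      ln(I·d²) = −μ_eff·d + k

so an ordinary least-squares fit of ln(I·d²) against *d* over a 5–30 mm
window yields the **effective scattering parameter μ_eff** (mm⁻¹) as
minus the slope. At low concentrations μ_eff is affine in cell density,

    ρ [cells/mL] = (μ_eff − 7.58×10⁻²) / 8.23×10⁻¹²

(the shipped reference calibration; the intercept is the vessel's own
scattering floor). Repeating the fit at 25 laser heights every few
minutes and normalising each height by its T = 0 density produces
time × height maps of the cell growth factor.

The package contains the full measurement chain plus a forward
simulator, so every stage is testable without instrument data:

| module | role |
|---|---|
| `turbimap.synthetic` | forward simulator: surface intensity fields, three-view rendering, sensor noise, growth scenarios |
| `turbimap.unwrapping` | raw three-view frame → flat (arc, height) surface image |
| `turbimap.hdr` | exposure-stack merging; photon-transfer gain/read-noise estimation |
| `turbimap.scattering` | profile extraction and the μ_eff estimator; scan/schedule planning |
| `turbimap.calibration` | μ_eff ↔ cell density fits, OD₆₀₀ conversions, aliquot planning |
| `turbimap.growth` | growth-factor maps, masking of specular rows, replicate statistics |
| `turbimap.io` / `turbimap.cli` | TIFF/CSV/JSON formats and the `turbimap` command |

## Worked example

Simulate one laser spot in a culture of 1.5×10⁹ cells/mL, push it
through the complete pipeline, and recover the density:

```python
import numpy as np
from turbimap import (
    PAPER_CALIBRATION, OpticalProperties, VesselGeometry,
    surface_intensity, render_views, expose_stack, hdr_merge, unwrap,
    fit_spot, density_from_mueff,
)

geometry = VesselGeometry()                       # 2.5 L vessel, 0.5 mm pitch
rho_true = 1.5e9                                  # cells/mL
mu_true = PAPER_CALIBRATION.mueff(rho_true)       # forward calibration
spot = (geometry.front_arc_mm, 60.25)             # front axis, 60 mm depth

scene = surface_intensity(geometry, OpticalProperties(mu_eff=float(mu_true)), spot)
raw = render_views(scene, geometry)               # three-view camera frame
stack = expose_stack(raw.values, seed=1)          # HDR exposure stack
merged = hdr_merge(stack)                         # linear radiance map
image = unwrap(merged.values, raw.layout.polygons(), geometry)

fit = fit_spot(image, spot, row_halfwidth=2)
rho_est = density_from_mueff(fit.mu_eff, PAPER_CALIBRATION)
print(f"true mu_eff      : {float(mu_true):.4f} mm^-1")
print(f"fitted mu_eff    : {fit.mu_eff:.4f} mm^-1  (r^2 = {fit.r_squared:.4f})")
print(f"estimated density: {float(rho_est):.3e} cells/mL  (truth 1.500e+09)")
```

prints

```
true mu_eff      : 0.0881 mm^-1
fitted mu_eff    : 0.0876 mm^-1  (r^2 = 1.0000)
estimated density: 1.438e+09 cells/mL  (truth 1.500e+09)
```

The fitted slope sits within half a percent of the truth; the remaining
density error (~4%) comes from resampling during rendering/unwrapping
and largely cancels when densities are normalised into growth factors
— full growth maps are recovered with a median error below 3%
(see `docs/methods.md`).

The same flow is available from the shell:

```bash
turbimap simulate --config scenario.yaml --out run/
turbimap unwrap   --in run/ --out run-unwrapped/
turbimap fit      --in run-unwrapped/ --window 5 30 --out fits.csv
turbimap map      --fits fits.csv --model paper-default --mask 55 70 --out growth.csv
turbimap report   --growth growth.csv --out report/
```

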