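# msbptomo

3D refractive-index (RI) tomography by multi-slice beam-propagation
(MSBP) inverse scattering — for microscopists and computational-imaging
researchers who want label-free, quantitative volumetric contrast of
scattering samples (cells, organoids, embryos, calibration phantoms)
from angle-scanned holographic measurements.

A sample's RI map is itself the image: it provides endogenous
morphological contrast and is the physical parameter that governs
scattering. `msbptomo` implements the full pipeline on synthetic or
experimental data: off-axis hologram demodulation, background
normalization, digital refocusing, a weak-scattering (Rytov) warm
start, and the iterative MSBP inversion with analytic adjoint
gradients — plus phantom generators so every stage is testable
end-to-end without laboratory data.

## The model

The sample volume is M thin phase screens at spacing Δz in a background
of index n0. Illumination E₀ (a tilted plane wave) propagates through
the stack by the angular-spectrum recursion

    E′_m = h_Δz ⊗ E_{m−1},      E_m = T_m · E′_m,
    T_m(r) = exp(j·k·Δz·Δn_m(r)),

with h_Δz the free-space kernel exp(+j2π·Δz·√(κ² − |ν|²)), κ = n0/λ.
The imaging-plane prediction back-propagates the exit field by the
focus offset ẑ, applies the detection pupil, and divides by the
empty-volume background field. The RI contrast is estimated by

    n̂ = argmin_n (1/2L) Σ_ℓ ‖y⁽ℓ⁾ − G⁽ℓ⁾{n}‖² + τ·TV(Δn),

where y⁽ℓ⁾ are complex-field or amplitude-only records at illumination
angle/defocus ℓ, G is the MSBP prediction of matching kind, and the
gradient is computed by exact error back-propagation through the
layers. All the acquisition/reconstruction strategies the package
compares — field vs. amplitude cost, Rytov initialization, lateral
volume padding, angular + defocus measurement diversity — are reachable
through `SolverConfig` and the CLI.

## Worked example

Recover a 2.5 μm calibration bead (Δn = 0.01) from 8 illumination
angles × 3 digital defocus planes of amplitude-only data:

```python
import numpy as np
from msbptomo import (Grid2D, OpticalConfig, SolverConfig, TomographyModel,
                      bead_phantom, illumination_ring, simulate_measurements,
                      sphere_mask)

grid = Grid2D(48, 48, 0.125)                    # 6 um field of view
optics = OpticalConfig(wavelength=0.635, n0=1.336, na_detect=1.2, na_illum=1.0)
n_layers, dz = 16, 0.25                         # 4 um deep, 16 slices

truth = bead_phantom(diameter=2.5, delta_n=0.01, grid=grid,
                     n_layers=n_layers, dz=dz, n0=optics.n0)
angles = illumination_ring(8, optics, radius_fraction=0.9, grid=grid)
measurements = simulate_measurements(truth, angles, [-2.0, 0.0, 2.0],
                                     "amplitude", optics, seed=0)

model = TomographyModel(measurements, n_layers, dz,
                        SolverConfig(n_epochs=60, nonneg=True, batch_size=8))
results = model.fit()
print(results.summary())

mask = sphere_mask(grid, n_layers, dz, diameter=2.5, fraction=0.7)
est = results.volume.delta_n[mask].mean()
print(f"interior mean delta_n: {est:.5f}")
```

Output:

```
MSBP Tomography Results
================================================
grid                 48 x 48 @ 0.125 um
layers               16 x 0.25 um (4 um thick)
background RI        1.336
measurements         24
cost kind            amplitude
init / pad           zero / 0
step size / tau      0.05 / 0.0001
epochs               60 (batch 8, momentum 0)
------------------------------------------------
final data term      1.6422e-04
final TV             1.1779e+01
delta_n range        [+0.0000, +0.0115]
delta_n mean         +0.00078
interior mean delta_n: 0.01018
```

The interior mean 0.01018 recovers the true contrast 0.01 to 1.8% —
the quantitative-accuracy figure the bead-calibration procedure
(`calibrate_hyperparameters`) optimizes when selecting the default step
size and TV strength. The final data term (mean ½‖residual‖² per
record) and the TV value are the two columns of
`results.cost_trace`.

The same pipeline runs from the shell:

```bash
msbp-tomo simulate-phantom --kind bead --spec bead.yaml --seed 1 --out truth.tif
msbp-tomo simulate-measurements --volume truth.tif --angles 16 --kind field --out set.h5
msbp-tomo init-rytov --measurements set.h5 --n-layers 16 --dz 0.25 --out warm.tif
msbp-tomo reconstruct --measurements set.h5 --cost field --init rytov \
    --pad 0.3 --n-layers 16 --dz 0.25 --out recon.tif
msbp-tomo evaluate --recon recon.tif --truth truth.tif --out metrics.json
```

or as one configured pipeline (`msbp-tomo run --config pipeline.yaml
--outdir out --seed 1`), which is byte-reproducible under a fixed seed.

## Package layout

| module        | contents |
|---------------|----------|
| `optics`      | grids, transfer functions, propagation, pupils, plane waves |
| `forward`     | `RIVolume`, MSBP forward model, measurement simulation |
| `inverse`     | cost terms, adjoint gradients, TV prox, SGD driver, calibration |
| `rytov`       | phase unwrapping, Ewald-cap accumulation, weak-scattering recon |
| `holography`  | interferogram simulation/demodulation, defocus-set synthesis |
| `phantoms`    | beads, rod-scattering cubes, cell targets, RI-error metrics |
| `model`       | `TomographyModel` / `TomographyResults` front end |
| `io`, `cli`   | HDF5/TIFF round trips, `msbp-tomo` subcommands |

See `docs/methods.md` for the numerical conventions, the calibration
protocol, and known limitations.

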