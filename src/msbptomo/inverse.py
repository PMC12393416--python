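"""Regularized least-squares inversion of the MSBP forward model.

The reconstruction solves

    n̂ = argmin_n  (1/2L) Σ_ℓ ‖y⁽ℓ⁾ − G⁽ℓ⁾{n}‖² + τ·TV(Δn)

over the layered RI contrast Δn, where G is the background-normalized
MSBP prediction for either complex-field or amplitude-only records.
Gradients are computed by the exact adjoint of the layer recursion
(error back-propagation through the phase screens), validated against
finite differences rather than trusted by derivation.  The amplitude
cost reuses the field machinery: the measured amplitude is paired with
the predicted field's phase, forming the synthetic complex measurement
y_amp·exp(j∠G_field).

Optimization is Nesterov-accelerated stochastic gradient descent over
shuffled per-angle mini-batches, with an isotropic 3D total-variation
proximal step after each update and optional non-negativity projection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np

from .optics import Field2D, Grid2D, OpticalConfig, plane_wave, propagate, pupil_filter
from .forward import (
    Measurement,
    MeasurementSet,
    RIVolume,
    _background_image,
    resolve_focus_offset,
)

__all__ = [
    "SolverConfig",
    "ReconResult",
    "data_term",
    "gradient_field",
    "gradient_amplitude",
    "synthetic_field_measurement",
    "tv_prox",
    "total_variation",
    "reconstruct",
    "calibrate_hyperparameters",
    "artifact_energy",
    "DEFAULT_BEAD_FIXTURES",
]

# Calibrated on the shipped bead fixtures via calibrate_hyperparameters
# (see docs/methods.md); not hand-picked numbers.
DEFAULT_STEP_SIZE = 0.05
DEFAULT_TAU = 1e-4


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings.

    step_size is in RI units per unit gradient; tau is the TV strength τ;
    pad_fraction is the total lateral zero-padding added to the
    reconstruction volume as a fraction of the FOV (0.3 → 30% extra,
    split half per side).  batch_size counts illumination angles per
    stochastic step (all defocus records of an angle travel together).
    """

    step_size: float = DEFAULT_STEP_SIZE
    tau: float = DEFAULT_TAU
    n_epochs: int = 40
    batch_size: int = 1
    pad_fraction: float = 0.0
    init: Literal["zero", "rytov", "given"] = "zero"
    cost_kind: Literal["field", "amplitude"] = "amplitude"
    # Plain (momentum-free) descent by default: accelerated iterates
    # systematically overshoot interior RI under the non-negativity
    # projection; set momentum > 0 for Nesterov acceleration w/ restart.
    momentum: float = 0.0
    seed: int = 0
    nonneg: bool = False
    restart: bool = True
    tv_iters: int = 20

    def __post_init__(self) -> None:
        if not self.step_size > 0:
            raise ValueError("step_size must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if not 0 <= self.pad_fraction <= 2:
            raise ValueError("pad_fraction must be in [0, 2]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")


@dataclass
class ReconResult:
    """Reconstruction output: n̂ cropped to the FOV plus diagnostics.

    ``cost_trace`` has one row per epoch: (mean data term, TV value).
    """

    volume: RIVolume
    cost_trace: np.ndarray
    config_used: SolverConfig


# ---------------------------------------------------------------------------
# forward with cached layer fields, shared by cost and adjoint


def _crop_slices(big: Grid2D, small: Grid2D) -> tuple[slice, slice]:
    if big.nx < small.nx or big.ny < small.ny or big.pitch != small.pitch:
        raise ValueError("measurement grid must be a centered sub-grid of the volume")
    oy = (big.ny - small.ny) // 2
    ox = (big.nx - small.nx) // 2
    return slice(oy, oy + small.ny), slice(ox, ox + small.nx)


def _forward_cached(
    volume: RIVolume,
    k_lat: Sequence[float],
    defocus: float,
    config: OpticalConfig,
    store: bool,
):
    """MSBP forward pass returning (imaging field, background field, caches)."""
    grid = volume.grid
    kmask = config.mask_k
    E = plane_wave(grid, k_lat, config)
    eprimes: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    for m in range(volume.n_layers):
        E = propagate(E, volume.dz, config)
        T = np.exp(1j * kmask * volume.dz * volume.delta_n[m])
        if store:
            eprimes.append(E.values)
            masks.append(T)
        E = Field2D(T * E.values, grid)
    zhat = resolve_focus_offset(config, volume.n_layers, volume.dz)
    img = pupil_filter(propagate(E, -zhat + defocus, config), config)
    bg = _background_image(grid, volume.n_layers, volume.dz, k_lat, defocus, config)
    return img, bg, eprimes, masks


def _phase_of(G: np.ndarray) -> np.ndarray:
    """Unit phasor e^{j∠G}, defined as 0 at exact zeros of |G|."""
    phase = np.exp(1j * np.angle(G))
    return np.where(np.abs(G) > 0, phase, 0.0 + 0.0j)


def _residual(G: np.ndarray, measurement: Measurement) -> np.ndarray:
    """Complex residual feeding the adjoint; |r|² is the pointwise data misfit."""
    if measurement.kind == "field":
        return G - measurement.data
    return G - measurement.data * _phase_of(G)


def synthetic_field_measurement(
    volume: RIVolume, measurement: Measurement, config: OpticalConfig
) -> Measurement:
    """Pair an amplitude record with the predicted field's phase.

    Returns the synthetic complex measurement y_amp·exp(j∠G_field) whose
    field gradient is identical to the amplitude gradient of the input.
    """
    if measurement.kind != "amplitude":
        raise ValueError("expected an amplitude measurement")
    img, bg, _, _ = _forward_cached(
        volume, measurement.k_lat, measurement.defocus, config, store=False
    )
    sy, sx = _crop_slices(volume.grid, Grid2D(*measurement.data.shape[::-1], volume.grid.pitch))
    G = (img.values / bg.values)[sy, sx]
    return Measurement(
        measurement.data * _phase_of(G),
        "field",
        measurement.k_lat,
        measurement.defocus,
        measurement.index,
    )


def data_term(
    volume: RIVolume, measurement: Measurement, config: OpticalConfig
) -> float:
    """½‖y − G{n}‖² for one record, with G matched to the record kind."""
    img, bg, _, _ = _forward_cached(
        volume, measurement.k_lat, measurement.defocus, config, store=False
    )
    mgrid = Grid2D(measurement.data.shape[1], measurement.data.shape[0], volume.grid.pitch)
    sy, sx = _crop_slices(volume.grid, mgrid)
    G = (img.values / bg.values)[sy, sx]
    if measurement.kind == "amplitude":
        G = np.abs(G)
    return float(0.5 * np.sum(np.abs(measurement.data - G) ** 2))


def _gradient(
    volume: RIVolume, measurement: Measurement, config: OpticalConfig
) -> tuple[np.ndarray, float]:
    """Adjoint gradient of the data term w.r.t. Δn, plus the cost value.

    The residual is divided by the conjugate background, zero-embedded
    into the (possibly padded) volume grid, pupil-filtered, propagated
    forward by ẑ − defocus, and swept backward through the layers; at
    layer m the gradient is Re{conj(j·k·Δz·T_m·E'_m)·A}, and A picks up
    conj(T_m) and a −Δz propagation between layers.
    """
    grid = volume.grid
    img, bg, eprimes, masks = _forward_cached(
        volume, measurement.k_lat, measurement.defocus, config, store=True
    )
    mgrid = Grid2D(measurement.data.shape[1], measurement.data.shape[0], grid.pitch)
    sy, sx = _crop_slices(grid, mgrid)
    G = (img.values / bg.values)[sy, sx]
    r = _residual(G, measurement)
    cost = float(0.5 * np.sum(np.abs(r) ** 2))

    A = np.zeros(grid.shape, dtype=np.complex128)
    A[sy, sx] = r / np.conj(bg.values[sy, sx])
    Af = pupil_filter(Field2D(A, grid), config)
    zhat = resolve_focus_offset(config, volume.n_layers, volume.dz)
    Af = propagate(Af, zhat - measurement.defocus, config)

    kfac = 1j * config.mask_k * volume.dz
    grad = np.empty_like(volume.delta_n)
    Av = Af.values
    for m in range(volume.n_layers - 1, -1, -1):
        grad[m] = np.real(np.conj(kfac * masks[m] * eprimes[m]) * Av)
        if m > 0:
            Av = propagate(
                Field2D(np.conj(masks[m]) * Av, grid), -volume.dz, config
            ).values
    return grad, cost


def gradient_field(
    volume: RIVolume, measurement: Measurement, config: OpticalConfig
) -> np.ndarray:
    """Analytic gradient of the field data term ½‖y_field − G_field‖²."""
    if measurement.kind != "field":
        raise ValueError("gradient_field requires a field-kind measurement")
    return _gradient(volume, measurement, config)[0]


def gradient_amplitude(
    volume: RIVolume, measurement: Measurement, config: OpticalConfig
) -> np.ndarray:
    """Analytic gradient of the amplitude data term ½‖y_amp − |G_field|‖²."""
    if measurement.kind != "amplitude":
        raise ValueError("gradient_amplitude requires an amplitude-kind measurement")
    return _gradient(volume, measurement, config)[0]


# ---------------------------------------------------------------------------
# total variation


def _grad3(u: np.ndarray) -> np.ndarray:
    """Forward differences along each axis, zero at the far boundary."""
    g = np.zeros((3,) + u.shape, dtype=u.dtype)
    g[0, :-1] = u[1:] - u[:-1]
    g[1, :, :-1] = u[:, 1:] - u[:, :-1]
    g[2, :, :, :-1] = u[:, :, 1:] - u[:, :, :-1]
    return g


def _div3(p: np.ndarray) -> np.ndarray:
    """Negative adjoint of :func:`_grad3`."""
    d = np.zeros(p.shape[1:], dtype=p.dtype)
    d[0] += p[0, 0]
    d[1:] += p[0, 1:] - p[0, :-1]
    d[:, 0] += p[1, :, 0]
    d[:, 1:] += p[1, :, 1:] - p[1, :, :-1]
    d[:, :, 0] += p[2, :, :, 0]
    d[:, :, 1:] += p[2, :, :, 1:] - p[2, :, :, :-1]
    return d


def total_variation(delta_n: np.ndarray) -> float:
    """Isotropic 3D TV: Σ_voxels sqrt(Σ_axes (forward difference)²)."""
    g = _grad3(np.asarray(delta_n, dtype=np.float64))
    return float(np.sum(np.sqrt(np.sum(g**2, axis=0))))


def _tv_prox_array(x: np.ndarray, weight: float, n_iters: int) -> np.ndarray:
    # Chambolle's dual projection for argmin_u 1/2||u - x||^2 + weight*TV(u);
    # step 1/12 satisfies the 3D contraction bound tau <= 1/(4·ndim).
    tau = 1.0 / 12.0
    p = np.zeros((3,) + x.shape, dtype=np.float64)
    for _ in range(n_iters):
        g = _grad3(_div3(p) - x / weight)
        mag = np.sqrt(np.sum(g**2, axis=0))
        p = (p + tau * g) / (1.0 + tau * mag)
    return x - weight * _div3(p)


def tv_prox(volume: RIVolume, weight: float, n_iters: int = 20) -> RIVolume:
    """Proximal operator of weight·TV3D applied to the contrast map.

    ``weight = 0`` returns the input unchanged; the output TV never
    exceeds the input TV (up to iteration tolerance).
    """
    if weight < 0:
        raise ValueError("TV prox weight must be non-negative")
    if weight == 0:
        return volume
    out = _tv_prox_array(volume.delta_n, weight, n_iters)
    return RIVolume(out, volume.dz, volume.n0, volume.grid)


# ---------------------------------------------------------------------------
# reconstruction driver


def artifact_energy(volume: RIVolume, border_fraction: float) -> float:
    """Mean Δn² over the lateral border band of the given fractional width.

    Quantifies edge artifacts: energy parked near the FOV boundary that
    padding is expected to suppress.
    """
    if not 0 < border_fraction < 0.5:
        raise ValueError("border_fraction must be in (0, 0.5)")
    ny, nx = volume.grid.shape
    wy = max(1, int(round(border_fraction * ny)))
    wx = max(1, int(round(border_fraction * nx)))
    band = np.zeros((ny, nx), dtype=bool)
    band[:wy] = band[-wy:] = True
    band[:, :wx] = band[:, -wx:] = True
    vals = volume.delta_n[:, band]
    return float(np.mean(vals**2))


def _angle_groups(measurements: MeasurementSet) -> list[list[int]]:
    """Indices grouped by illumination angle, in first-appearance order."""
    groups: dict[tuple[float, float], list[int]] = {}
    for i, m in enumerate(measurements):
        groups.setdefault(m.k_lat, []).append(i)
    return list(groups.values())


def _embed_lateral(delta_n: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Zero-embed (M, ny, nx) layers into larger centered lateral shape."""
    M, ny, nx = delta_n.shape
    out = np.zeros((M, shape[0], shape[1]), dtype=np.float64)
    oy = (shape[0] - ny) // 2
    ox = (shape[1] - nx) // 2
    out[:, oy : oy + ny, ox : ox + nx] = delta_n
    return out


def reconstruct(
    measurements: MeasurementSet,
    config: SolverConfig,
    n_layers: int,
    dz: float,
    init_volume: RIVolume | None = None,
) -> ReconResult:
    """Run the full MSBP inverse-scattering reconstruction.

    Pads the volume laterally by ``pad_fraction`` of the FOV, embeds the
    initialization, runs ``n_epochs`` of Nesterov-accelerated stochastic
    gradient descent over shuffled per-angle mini-batches (predictions
    cropped to the measurement FOV before residual formation, residuals
    zero-embedded for the adjoint), applies the TV prox after every
    step, and returns the FOV-cropped estimate with a per-epoch cost
    trace.  Fully deterministic under a fixed seed.
    """
    if len(measurements) == 0:
        raise ValueError("empty measurement set")
    opt = measurements.config
    fov = measurements.grid
    # freeze the focus offset so padded/unpadded geometry agree
    opt = opt.with_focus(resolve_focus_offset(opt, n_layers, dz))

    pad_x = int(round(fov.nx * config.pad_fraction / 2.0))
    pad_y = int(round(fov.ny * config.pad_fraction / 2.0))
    pgrid = fov.padded(pad_x, pad_y)

    if config.init == "given":
        if init_volume is None:
            raise ValueError("init='given' requires init_volume")
        if init_volume.delta_n.shape[0] != n_layers:
            raise ValueError("init_volume layer count does not match geometry")
        x = _embed_lateral(init_volume.delta_n, pgrid.shape)
    elif config.init == "rytov":
        from .rytov import rytov_reconstruct

        field_set = measurements.of_kind("field")
        if len(field_set) == 0:
            raise ValueError("init='rytov' requires field-kind measurements")
        warm = rytov_reconstruct(field_set, n_layers, dz)
        x = _embed_lateral(warm.delta_n, pgrid.shape)
    elif config.init == "zero":
        x = np.zeros((n_layers,) + pgrid.shape, dtype=np.float64)
    else:
        raise ValueError(f"unknown init {config.init!r}")

    groups = _angle_groups(measurements)
    rng = np.random.default_rng(config.seed)
    L = len(measurements)

    x_prev = x.copy()
    trace = np.zeros((config.n_epochs, 2), dtype=np.float64)
    prev_epoch_cost = np.inf
    for epoch in range(config.n_epochs):
        order = rng.permutation(len(groups))
        epoch_cost = 0.0
        for start in range(0, len(order), config.batch_size):
            batch = [j for gi in order[start : start + config.batch_size] for j in groups[gi]]
            if not np.all(np.isfinite(x)):
                raise RuntimeError(
                    f"reconstruction diverged (non-finite estimate) at epoch {epoch}"
                )
            # Nesterov look-ahead point
            v = x + config.momentum * (x - x_prev)
            vol = RIVolume(v, dz, opt.n0, pgrid)
            g = np.zeros_like(x)
            for j in batch:
                try:
                    gj, cj = _gradient(vol, measurements[j], opt)
                except ValueError as exc:
                    raise RuntimeError(
                        f"non-finite field encountered at epoch {epoch} "
                        f"(measurement {j}): {exc}"
                    ) from exc
                g += gj
                epoch_cost += cj
            g /= len(batch)
            x_prev = x
            x_new = v - config.step_size * g
            if config.tau > 0:
                x_new = _tv_prox_array(
                    x_new, config.step_size * config.tau, config.tv_iters
                )
            if config.nonneg:
                np.maximum(x_new, 0.0, out=x_new)
            x = x_new
        epoch_cost /= L
        if not np.isfinite(epoch_cost):
            raise RuntimeError(f"cost diverged (non-finite) at epoch {epoch}")
        trace[epoch, 0] = epoch_cost
        trace[epoch, 1] = total_variation(x)
        if config.restart and epoch_cost > prev_epoch_cost:
            x_prev = x.copy()  # kill momentum after an uphill epoch
        prev_epoch_cost = epoch_cost

    sy, sx = _crop_slices(pgrid, fov)
    volume = RIVolume(x[:, sy, sx], dz, opt.n0, fov)
    return ReconResult(volume, trace, config)


# ---------------------------------------------------------------------------
# hyperparameter calibration on synthetic calibration beads

# (diameter um, delta_n) spanning typical polystyrene/PMMA/silica-in-oil
# contrasts; fixtures for calibration, not reproductions of any dataset.
DEFAULT_BEAD_FIXTURES: tuple[tuple[float, float], ...] = ((2.5, 0.01), (2.5, 0.04))


def calibrate_hyperparameters(
    bead_specs: Sequence[tuple[float, float]],
    step_grid: Sequence[float],
    tau_grid: Sequence[float],
    config: SolverConfig | None = None,
    optical: OpticalConfig | None = None,
    grid: Grid2D | None = None,
    n_layers: int = 16,
    dz: float = 0.25,
    n_angles: int = 8,
    seed: int = 0,
):
    """Grid-search step size and TV strength on synthetic calibration beads.

    For every (step, τ) pair and every bead, simulates defocus-diverse
    amplitude measurements, reconstructs, and scores the interior
    mean-RI relative error.  Returns the pair minimizing the worst-case
    (max over beads) error plus the full error table; divergent runs
    score ``inf``.  The calibration protocol enforces Δn ≥ 0 (bead
    contrast is known positive) and full-batch, momentum-free descent
    for quantitative accuracy unless a base ``config`` overrides it.
    """
    import pandas as pd

    from .phantoms import bead_phantom, sphere_mask

    if not bead_specs or not len(step_grid) or not len(tau_grid):
        raise ValueError("bead_specs, step_grid and tau_grid must be non-empty")
    base = config or SolverConfig(
        nonneg=True, momentum=0.0, batch_size=n_angles, n_epochs=60
    )
    opt = optical or OpticalConfig(
        wavelength=0.635, n0=1.336, na_detect=1.2, na_illum=1.0
    )
    g = grid or Grid2D(48, 48, 0.125)

    from .optics import illumination_ring
    from .forward import simulate_measurements

    angles = illumination_ring(n_angles, opt, radius_fraction=0.9, grid=g)
    T = n_layers * dz
    defocus = [-T / 2.0, 0.0, T / 2.0]
    sims = []
    for diameter, dn_true in bead_specs:
        truth = bead_phantom(diameter, dn_true, g, n_layers, dz, n0=opt.n0)
        mset = simulate_measurements(truth, angles, defocus, "amplitude", opt, seed=seed)
        mask = sphere_mask(g, n_layers, dz, diameter, fraction=0.7)
        sims.append((diameter, dn_true, mset, mask))

    rows = []
    for step in step_grid:
        for tau in tau_grid:
            for diameter, dn_true, mset, mask in sims:
                trial = replace(base, step_size=float(step), tau=float(tau))
                try:
                    res = reconstruct(mset, trial, n_layers, dz)
                    est = float(np.mean(res.volume.delta_n[mask]))
                    err = abs(est - dn_true) / abs(dn_true)
                    if not np.isfinite(err):
                        err = np.inf
                except (RuntimeError, FloatingPointError):
                    err = np.inf
                rows.append(
                    {
                        "step_size": float(step),
                        "tau": float(tau),
                        "bead_diameter": diameter,
                        "bead_delta_n": dn_true,
                        "error": err,
                    }
                )
    table = pd.DataFrame(rows)
    worst = table.groupby(["step_size", "tau"])["error"].max().reset_index()
    best = worst.loc[worst["error"].idxmin()]
    return float(best["step_size"]), float(best["tau"]), table
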