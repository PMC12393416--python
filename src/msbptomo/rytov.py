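"""Weak-scattering (Rytov) reconstruction via the Fourier diffraction theorem.

For a weakly scattering object under tilted plane-wave illumination,
the complex Rytov phase of the background-normalized field at the
object plane,

    u_R = ln|E/E_bg| + j·unwrap(arg(E/E_bg)),

maps (after a 2D Fourier transform) onto a spherical Ewald-sphere cap
of the object's 3D scattering-potential spectrum, displaced by the
illumination wavevector:

    V̂(ν⊥ − ν⊥0, νz − νz0) = −j·4π·νz · Ψ̂(ν⊥ − ν⊥0),

with νz = sqrt(κ² − |ν⊥|²), κ = n0/λ (cycles/μm), and V = 2k̄²·Δn/n0
the linearized scattering potential (k̄ = 2πn0/λ).  Accumulating caps
over many angles fills k-space; an inverse 3D FFT and count-averaging
yield the Δn estimate.  The missing cone is left empty — this serves as
a warm start for the iterative MSBP solver, not a final reconstruction.

Phase unwrapping is DCT-based least squares (Ghiglia–Romero): exact for
residue-free wrapped phases, deterministic and parameter-free.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.fft import dctn, idctn

from .optics import Field2D, Grid2D, OpticalConfig, plane_wave, propagate
from .forward import MeasurementSet, RIVolume, resolve_focus_offset

__all__ = [
    "KSpaceAccumulator",
    "unwrap_phase_lstsq",
    "rytov_complex_phase",
    "map_to_ewald",
    "rytov_reconstruct",
]


@dataclass
class KSpaceAccumulator:
    """Scattering-potential spectrum accumulated on the target 3D grid.

    ``spectrum`` and ``counts`` are indexed (νz, νy, νx) in DFT-native
    order on the frequency lattice of an (M, ny, nx) volume with voxel
    (dz, pitch, pitch).
    """

    spectrum: np.ndarray
    counts: np.ndarray
    grid: Grid2D
    n_layers: int
    dz: float

    @classmethod
    def empty(cls, grid: Grid2D, n_layers: int, dz: float) -> "KSpaceAccumulator":
        shape = (n_layers,) + grid.shape
        return cls(
            np.zeros(shape, dtype=np.complex128),
            np.zeros(shape, dtype=np.int64),
            grid,
            n_layers,
            dz,
        )

    def normalized(self) -> np.ndarray:
        """Count-averaged spectrum; zero where no shell contributed."""
        out = np.zeros_like(self.spectrum)
        hit = self.counts > 0
        out[hit] = self.spectrum[hit] / self.counts[hit]
        return out


def _wrap(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2 * np.pi) - np.pi


def unwrap_phase_lstsq(psi: np.ndarray) -> np.ndarray:
    """Least-squares 2D phase unwrapping via a DCT Poisson solve.

    Integrates the wrapped phase gradients in the least-squares sense
    under Neumann boundaries; the unwrapped surface is anchored so that
    its mean offset from the wrapped input is zero (mod 2π consistent).
    """
    psi = np.asarray(psi, dtype=np.float64)
    ny, nx = psi.shape
    dx = _wrap(np.diff(psi, axis=1))
    dy = _wrap(np.diff(psi, axis=0))
    rho = np.zeros_like(psi)
    rho[:, :-1] += dx
    rho[:, 1:] -= dx
    rho[:-1, :] += dy
    rho[1:, :] -= dy
    # Neumann Laplacian eigenvalues on the DCT-II basis
    wy = 2.0 * (np.cos(np.pi * np.arange(ny) / ny) - 1.0)
    wx = 2.0 * (np.cos(np.pi * np.arange(nx) / nx) - 1.0)
    denom = wy[:, None] + wx[None, :]
    denom[0, 0] = 1.0
    coeff = dctn(rho, type=2, norm="ortho")
    coeff /= denom
    coeff[0, 0] = 0.0
    phi = idctn(coeff, type=2, norm="ortho")
    return phi + np.mean(_wrap(psi - phi))


def rytov_complex_phase(normalized_field: Field2D) -> np.ndarray:
    """Complex Rytov phase u_R = ln|E| + j·unwrap(arg E) of a normalized field."""
    E = normalized_field.values
    mag = np.abs(E)
    if np.any(mag == 0):
        iy, ix = np.argwhere(mag == 0)[0]
        raise ValueError(
            f"normalized field has |E| = 0 at pixel (y={iy}, x={ix}); the Rytov "
            "log-amplitude is undefined there"
        )
    return np.log(mag) + 1j * unwrap_phase_lstsq(np.angle(E))


def map_to_ewald(
    u_R: np.ndarray,
    k_lat: Sequence[float],
    acc: KSpaceAccumulator,
    config: OpticalConfig,
    weighting: str = "paraxial",
) -> KSpaceAccumulator:
    """Scatter one angle's Rytov spectrum onto its displaced Ewald cap.

    The 2D spectrum of ``u_R`` is weighted by the diffraction-theorem
    factor −j·4π·w and written to the nearest 3D frequency voxel at
    (ν⊥ − ν⊥0, νz(ν⊥) − νz0); frequencies outside the medium band, the
    detection pupil, or the target lattice are skipped.  Counts are
    incremented at every voxel touched.  Modifies and returns ``acc``.

    ``weighting="paraxial"`` (default) evaluates the obliquity at the
    band centre, w = κ — the exact linearization of the paraxial MSBP
    forward model, so the warm start is consistent with the solver it
    initializes.  ``weighting="obliquity"`` uses the Helmholtz-exact
    w = νz of each detected plane wave.
    """
    kx0, ky0 = float(k_lat[0]), float(k_lat[1])
    if np.hypot(kx0, ky0) > config.illum_cutoff * (1 + 1e-12):
        raise ValueError("illumination frequency outside the illumination NA")
    grid = acc.grid
    if u_R.shape != grid.shape:
        raise ValueError("u_R shape does not match accumulator grid")
    kappa = config.medium_cutoff
    fx, fy = grid.freqs()
    # The Rytov spectrum lattice frequency f is the *difference* frequency
    # q_lat = nu_lat - k_lat0 of the object's spectrum; the physically
    # detected plane wave has transverse frequency nu_lat = f + k_lat0,
    # which sets the obliquity factor and the band/pupil admission.
    det_sq = (fx + kx0) ** 2 + (fy + ky0) ** 2
    band = det_sq <= min(kappa, config.pupil_cutoff) ** 2
    nuz = np.sqrt(np.maximum(kappa**2 - det_sq, 0.0))
    nuz0 = float(np.sqrt(max(kappa**2 - kx0**2 - ky0**2, 0.0)))

    if weighting == "paraxial":
        w = kappa
    elif weighting == "obliquity":
        w = nuz
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    psi_hat = np.fft.fft2(np.asarray(u_R, dtype=np.complex128)) * grid.pitch**2
    value = -4j * np.pi * w * psi_hat

    # lateral bins are already on the target lattice; only the axial shell
    # offset needs nearest-voxel rounding and a range check
    bx = np.rint(fx * grid.nx * grid.pitch).astype(np.int64)
    by = np.rint(fy * grid.ny * grid.pitch).astype(np.int64)
    bz = np.rint((nuz - nuz0) * acc.n_layers * acc.dz).astype(np.int64)
    bx = np.broadcast_to(bx, grid.shape)
    by = np.broadcast_to(by, grid.shape)
    ok = (
        band
        & (bz >= -(acc.n_layers // 2))
        & (bz < (acc.n_layers + 1) // 2)
    )
    iz = bz[ok] % acc.n_layers
    iy = by[ok] % grid.ny
    ix = bx[ok] % grid.nx
    np.add.at(acc.spectrum, (iz, iy, ix), value[ok])
    np.add.at(acc.counts, (iz, iy, ix), 1)
    return acc


def _refocus_normalized(
    data: np.ndarray,
    k_lat: Sequence[float],
    distance: float,
    grid: Grid2D,
    config: OpticalConfig,
) -> Field2D:
    """Digitally refocus a background-normalized field by ``distance`` μm.

    The tilt carrier is restored before propagation and divided out
    after, so refocusing commutes with background normalization.
    """
    E0 = plane_wave(grid, k_lat, config)
    total = Field2D(np.asarray(data, dtype=np.complex128) * E0.values, grid)
    moved = propagate(total, distance, config)
    bg = propagate(E0, distance, config)
    return Field2D(moved.values / bg.values, grid)


def rytov_reconstruct(
    measurements: MeasurementSet,
    n_layers: int,
    dz: float,
    return_accumulator: bool = False,
) -> RIVolume:
    """Closed-form weak-scattering Δn estimate from field measurements.

    Every field-kind record is refocused to the first-layer plane,
    converted to its complex Rytov phase, and scattered onto its Ewald
    cap; the count-averaged spectrum is inverse-transformed and
    converted to RI contrast via Δn = V·λ²/(8π²·n0).  The missing cone
    stays zero-filled.  Hermitian symmetry (real Δn) is enforced by
    taking the real part after the inverse transform.
    """
    field_set = [m for m in measurements if m.kind == "field"]
    if not field_set:
        raise ValueError("rytov_reconstruct requires at least one field-kind record")
    config = measurements.config
    grid = measurements.grid
    zhat = resolve_focus_offset(config, n_layers, dz)
    acc = KSpaceAccumulator.empty(grid, n_layers, dz)
    # Phase-reference the spectrum to the volume centre: for a roughly
    # centred object the referenced spectrum varies slowly in q_z, so the
    # nearest-voxel shell rounding commits only small phase errors.
    z_ref = (n_layers - 1) * dz / 2.0
    for m in field_set:
        # imaging plane sits (M−1)·Δz − ẑ + defocus past the first layer
        z_img = (n_layers - 1) * dz - zhat + m.defocus
        y0 = _refocus_normalized(m.data, m.k_lat, z_ref - z_img, grid, config)
        u_R = rytov_complex_phase(y0)
        map_to_ewald(u_R, m.k_lat, acc, config)
    spec = acc.normalized()
    # re-reference the axial phase origin from the centre to the first layer
    qz = np.fft.fftfreq(n_layers, dz)[:, None, None]
    spec = spec * np.exp(-2j * np.pi * qz * z_ref)
    V = np.real(np.fft.ifftn(spec)) / (grid.pitch**2 * dz)
    delta_n = V * config.wavelength**2 / (8.0 * np.pi**2 * config.n0)
    # match the wavenumber convention of the solver's phase masks
    delta_n *= (2.0 * np.pi / config.wavelength) / config.mask_k
    vol = RIVolume(delta_n, dz, config.n0, grid)
    if return_accumulator:
        return vol, acc
    return vol
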