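"""Scalar-field optics primitives: grids, angular-spectrum propagation, pupils.

All lengths are micrometres and all spatial frequencies are cycles/μm.
Fields are sampled on regular 2D grids with the DFT-native frequency
ordering (ν = 0 at the first sample).  Propagation follows the angular
spectrum method: the field is decomposed into plane waves by a 2D FFT,
each component is multiplied by the free-space transfer function

    H_dz(ν) = exp(+j·2π·dz·sqrt(κ² − |ν|²)),   κ = n0/λ,

and the field is re-assembled by an inverse FFT.  Evanescent components
(|ν| > κ) are zeroed so that propagation is unitary on the travelling
band and back-propagation (negative dz) is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np


@dataclass(frozen=True)
class Grid2D:
    """Regular transverse sampling grid.

    Parameters
    ----------
    nx, ny : int
        Pixel counts along x (fast axis) and y.  Arrays are ``(ny, nx)``.
    pitch : float
        Transverse sampling interval in μm/pixel.
    """

    nx: int
    ny: int
    pitch: float

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise ValueError(f"grid must be at least 2x2, got {self.nx}x{self.ny}")
        if not (self.pitch > 0 and np.isfinite(self.pitch)):
            raise ValueError(f"pitch must be positive and finite, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def extent(self) -> tuple[float, float]:
        """Physical field-of-view (Lx, Ly) in μm."""
        return (self.nx * self.pitch, self.ny * self.pitch)

    def coords(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable physical coordinates (x, y) in μm, origin at pixel (0, 0)."""
        x = np.arange(self.nx) * self.pitch
        y = np.arange(self.ny) * self.pitch
        return x[None, :], y[:, None]

    def freqs(self) -> tuple[np.ndarray, np.ndarray]:
        """Broadcastable DFT frequencies (νx, νy) in cycles/μm, DFT-native order."""
        fx = np.fft.fftfreq(self.nx, self.pitch)
        fy = np.fft.fftfreq(self.ny, self.pitch)
        return fx[None, :], fy[:, None]

    def freq_sq(self) -> np.ndarray:
        fx, fy = self.freqs()
        return fx**2 + fy**2

    def padded(self, pad_x: int, pad_y: int) -> "Grid2D":
        return Grid2D(self.nx + 2 * pad_x, self.ny + 2 * pad_y, self.pitch)


@dataclass(frozen=True)
class OpticalConfig:
    """Acquisition geometry and medium parameters.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength λ in μm.
    n0 : float
        Background (immersion medium) refractive index.
    na_detect : float
        Detection numerical aperture; sets the pupil cutoff na_detect/λ.
    na_illum : float
        Maximum illumination numerical aperture.
    focus_offset : float or None
        ẑ, distance from the last sample layer back to the conjugate
        imaging plane (μm).  ``None`` means "mid-volume": resolved to
        M·Δz/2 wherever the layer geometry is known.
    kernel : {"standard", "paper"}
        Angular-spectrum kernel variant.  "standard" is the exact
        homogeneous-medium kernel sqrt((n0/λ)² − |ν|²); "paper" keeps n0
        outside the square root, n0·sqrt(1/λ² − |ν|²), which agrees in
        the paraxial limit.
    mask_wavenumber : {"vacuum", "medium"}
        Wavenumber used in the slice transmittance exp(j·k·Δz·Δn):
        vacuum 2π/λ (reproduces the optical-path-length projection
        limit) or medium 2π·n0/λ.
    """

    wavelength: float
    n0: float
    na_detect: float
    na_illum: float
    focus_offset: float | None = None
    kernel: Literal["standard", "paper"] = "standard"
    mask_wavenumber: Literal["vacuum", "medium"] = "vacuum"

    def __post_init__(self) -> None:
        if not self.wavelength > 0:
            raise ValueError("wavelength must be positive")
        if self.n0 < 1:
            raise ValueError("background RI must be >= 1")
        if not (0 < self.na_detect <= self.n0):
            raise ValueError("na_detect must satisfy 0 < NA <= n0")
        if not (0 <= self.na_illum <= self.n0):
            raise ValueError("na_illum must satisfy 0 <= NA <= n0")
        if self.kernel not in ("standard", "paper"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.mask_wavenumber not in ("vacuum", "medium"):
            raise ValueError(f"unknown mask_wavenumber {self.mask_wavenumber!r}")

    @property
    def medium_cutoff(self) -> float:
        """κ = n0/λ, the propagating-band limit in cycles/μm."""
        return self.n0 / self.wavelength

    @property
    def pupil_cutoff(self) -> float:
        """Detection band limit na_detect/λ in cycles/μm."""
        return self.na_detect / self.wavelength

    @property
    def illum_cutoff(self) -> float:
        """Maximum illumination transverse frequency na_illum/λ in cycles/μm."""
        return self.na_illum / self.wavelength

    @property
    def mask_k(self) -> float:
        """Wavenumber (rad/μm) used in the slice phase mask."""
        k = 2.0 * np.pi / self.wavelength
        return k * self.n0 if self.mask_wavenumber == "medium" else k

    def with_focus(self, focus_offset: float) -> "OpticalConfig":
        return replace(self, focus_offset=focus_offset)


@dataclass
class Field2D:
    """A complex scalar field sampled on a :class:`Grid2D`."""

    values: np.ndarray
    grid: Grid2D

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field contains non-finite samples")

    @property
    def power(self) -> float:
        """Total power Σ|E|²."""
        return float(np.sum(np.abs(self.values) ** 2))

    def copy(self) -> "Field2D":
        return Field2D(self.values.copy(), self.grid)


def transfer_function(grid: Grid2D, dz: float, config: OpticalConfig) -> np.ndarray:
    """Free-space transfer function H_dz(ν) on the DFT frequency grid.

    Returns exp(+j·2π·dz·k_z(ν)) on the propagating band and exactly 0
    beyond the cutoff.  |H| = 1 on the band for any real dz, so
    propagation is unitary and invertible there.
    """
    if not np.isfinite(dz):
        raise ValueError(f"propagation distance must be finite, got {dz}")
    rho_sq = grid.freq_sq()
    if config.kernel == "standard":
        kappa = config.medium_cutoff
        band = rho_sq <= kappa**2
        kz = np.sqrt(np.maximum(kappa**2 - rho_sq, 0.0))
    else:  # literal printed form: n0 outside the root, vacuum cutoff
        inv_lam = 1.0 / config.wavelength
        band = rho_sq <= inv_lam**2
        kz = config.n0 * np.sqrt(np.maximum(inv_lam**2 - rho_sq, 0.0))
    H = np.exp(2j * np.pi * dz * kz)
    H[~band] = 0.0
    return H


def propagate(field: Field2D, dz: float, config: OpticalConfig) -> Field2D:
    """Angular-spectrum propagation of ``field`` by signed distance ``dz`` μm."""
    H = transfer_function(field.grid, dz, config)
    spec = np.fft.fft2(field.values)
    out = np.fft.ifft2(spec * H)
    return Field2D(out, field.grid)


def pupil_mask(grid: Grid2D, config: OpticalConfig) -> np.ndarray:
    """Boolean frequency-domain mask of the hard circular detection pupil."""
    return grid.freq_sq() <= config.pupil_cutoff**2


def pupil_filter(field: Field2D, config: OpticalConfig) -> Field2D:
    """Hard low-pass at the detection NA: |ν| > na_detect/λ is zeroed.

    Models the system PSF as an ideal circular pupil; idempotent.
    """
    mask = pupil_mask(field.grid, config)
    spec = np.fft.fft2(field.values)
    spec[~mask] = 0.0
    return Field2D(np.fft.ifft2(spec), field.grid)


def plane_wave(grid: Grid2D, k_lat: Sequence[float], config: OpticalConfig) -> Field2D:
    """Unit-magnitude tilted plane wave exp(j·2π·k_lat·r).

    ``k_lat`` is the transverse spatial frequency (cycles/μm) of the
    illumination; it must lie within the illumination NA.
    """
    kx, ky = float(k_lat[0]), float(k_lat[1])
    if np.hypot(kx, ky) > config.illum_cutoff * (1 + 1e-12):
        raise ValueError(
            f"|k_lat| = {np.hypot(kx, ky):.4f} cycles/um exceeds the illumination "
            f"NA limit {config.illum_cutoff:.4f}"
        )
    x, y = grid.coords()
    return Field2D(np.exp(2j * np.pi * (kx * x + ky * y)), grid)


def snap_frequency(k_lat: Sequence[float], grid: Grid2D) -> tuple[float, float]:
    """Round a transverse frequency onto the grid's DFT frequency lattice.

    On-lattice illumination keeps a plane wave strictly periodic on the
    FOV, avoiding spectral leakage in FFT-based propagation.
    """
    kx = round(float(k_lat[0]) * grid.nx * grid.pitch) / (grid.nx * grid.pitch)
    ky = round(float(k_lat[1]) * grid.ny * grid.pitch) / (grid.ny * grid.pitch)
    return (kx, ky)


def illumination_ring(
    n_angles: int,
    config: OpticalConfig,
    radius_fraction: float = 1.0,
    grid: Grid2D | None = None,
) -> list[tuple[float, float]]:
    """Transverse illumination frequencies equally spaced on a circle.

    The ring radius is ``radius_fraction``·na_illum/λ; if ``grid`` is
    given each frequency is snapped onto its DFT lattice.
    """
    if n_angles < 1:
        raise ValueError("need at least one illumination angle")
    if not 0 <= radius_fraction <= 1:
        raise ValueError("radius_fraction must be in [0, 1]")
    r = radius_fraction * config.illum_cutoff
    out = []
    for i in range(n_angles):
        th = 2 * np.pi * i / n_angles
        k = (r * np.cos(th), r * np.sin(th))
        if grid is not None:
            k = snap_frequency(k, grid)
        out.append(k)
    return out
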