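"""Off-axis holography: interferogram simulation, sideband demodulation,
background normalization, and synthesis of defocus-diverse amplitude sets.

Off-axis recording interferes the sample field with a tilted reference
wave; the complex field is recovered from one intensity image by
cropping the +1-order sideband around the carrier frequency in Fourier
space, recentering it, and dividing by the reference amplitude.
Background correction is a complex division by an empty-FOV field
(dividing amplitudes, subtracting phases), which cancels system-induced
wavefront errors.  Defocus-diverse amplitude records are synthesized by
digitally propagating normalized fields and taking the modulus.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .optics import Field2D, Grid2D, OpticalConfig, plane_wave, propagate
from .forward import Measurement, MeasurementSet

__all__ = [
    "simulate_interferogram",
    "demodulate",
    "normalize_background",
    "synthesize_defocus_set",
    "default_defocus_planes",
]


def simulate_interferogram(
    sample_field: Field2D,
    carrier: Sequence[float],
    ref_amplitude: float = 1.0,
) -> np.ndarray:
    """Intensity of sample + tilted reference: I = |E_s + a·e^{j2πc·r}|²."""
    cx, cy = float(carrier[0]), float(carrier[1])
    grid = sample_field.grid
    nyq = 1.0 / (2.0 * grid.pitch)
    if abs(cx) > nyq or abs(cy) > nyq:
        raise ValueError(
            f"carrier ({cx:.3f}, {cy:.3f}) cycles/um exceeds the grid Nyquist "
            f"frequency {nyq:.3f}"
        )
    x, y = grid.coords()
    ref = ref_amplitude * np.exp(2j * np.pi * (cx * x + cy * y))
    return np.abs(sample_field.values + ref) ** 2


def demodulate(
    interferogram: np.ndarray,
    grid: Grid2D,
    carrier: Sequence[float],
    bandwidth: float,
    ref_amplitude: float = 1.0,
) -> Field2D:
    """Recover the complex sample field from an off-axis interferogram.

    Crops the sideband of radius ``bandwidth`` (cycles/μm) that carries
    E_s·conj(ref) — centred at −carrier for a reference tilt
    exp(+j2π·carrier·r) — recenters it to baseband, inverse-transforms,
    and divides by the reference amplitude.  Exact for fields whose
    spectrum fits inside the sideband with the carrier well separated
    from the DC term.
    """
    cx, cy = float(carrier[0]), float(carrier[1])
    if np.hypot(cx, cy) <= bandwidth:
        raise ValueError(
            "carrier separation from DC must exceed the sideband bandwidth; "
            f"got |carrier| = {np.hypot(cx, cy):.3f} <= bandwidth = {bandwidth:.3f}"
        )
    interferogram = np.asarray(interferogram, dtype=np.float64)
    if interferogram.shape != grid.shape:
        raise ValueError("interferogram shape does not match grid")
    spec = np.fft.fft2(interferogram)
    # recenter: integer roll by the nearest on-lattice carrier bins
    # (the E_s sideband sits at -carrier)
    sx = round(cx * grid.nx * grid.pitch)
    sy = round(cy * grid.ny * grid.pitch)
    spec = np.roll(spec, (sy, sx), axis=(0, 1))
    fx, fy = grid.freqs()
    spec[fx**2 + fy**2 > bandwidth**2] = 0.0
    return Field2D(np.fft.ifft2(spec) / ref_amplitude, grid)


def normalize_background(sample: Field2D, background: Field2D) -> Field2D:
    """Complex division sample/background (divide amplitudes, subtract phases)."""
    if sample.grid != background.grid:
        raise ValueError("sample and background grids differ")
    zero = np.abs(background.values) == 0
    if np.any(zero):
        iy, ix = np.argwhere(zero)[0]
        raise ValueError(
            f"background field is zero at pixel (y={iy}, x={ix}); division undefined"
        )
    return Field2D(sample.values / background.values, sample.grid)


def default_defocus_planes(n_layers: int, dz: float) -> list[float]:
    """Symmetric defocus spread over the sample thickness T = M·Δz."""
    T = n_layers * dz
    return [-T / 2.0, -T / 4.0, 0.0, T / 4.0, T / 2.0]


def synthesize_defocus_set(
    fields: Sequence[tuple[Field2D, Sequence[float]]],
    defocus_list: Sequence[float],
    config: OpticalConfig,
) -> MeasurementSet:
    """Amplitude records at multiple digital defocus planes.

    ``fields`` is a list of (normalized field, k_lat) pairs.  For each
    field and each defocus z_d, the illumination carrier is restored,
    the field is propagated by z_d, and the modulus is taken — so every
    record stays in the normalized space the solver's forward model
    predicts.  ``defocus_list = [0]`` reduces to plain amplitude
    extraction.  Output order is (field-major, defocus-minor).
    """
    defocus_list = [float(z) for z in defocus_list]
    if not fields or not defocus_list:
        raise ValueError("fields and defocus_list must be non-empty")
    for z in defocus_list:
        if not np.isfinite(z):
            raise ValueError(f"defocus distance must be finite, got {z}")
    grid = fields[0][0].grid
    records: list[Measurement] = []
    idx = 0
    for fld, k_lat in fields:
        if fld.grid != grid:
            raise ValueError("all fields must share one grid")
        k = (float(k_lat[0]), float(k_lat[1]))
        carrier = plane_wave(grid, k, config)
        total = Field2D(fld.values * carrier.values, grid)
        for zd in defocus_list:
            if zd == 0.0:
                amp = np.abs(fld.values)
            else:
                moved = propagate(total, zd, config)
                amp = np.abs(moved.values)
            records.append(Measurement(amp, "amplitude", k, zd, index=idx))
            idx += 1
    return MeasurementSet(records, config, grid)
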