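"""Multi-slice beam-propagation (MSBP) forward model.

A 3D sample with refractive-index contrast Δn(x, y, m) is modelled as M
thin phase screens separated by Δz of homogeneous background medium.
The illumination E_0 is defined one Δz before the first layer and is
pushed through the stack by the recursion

    E'_m = h_Δz ⊗ E_{m-1}        (angular-spectrum propagation)
    E_m  = T_m · E'_m            (phase modulation)

with the unit-modulus slice transmittance T_m = exp(j·k·Δz·Δn_m).  The
exit field E_M is then back-propagated by the focus offset ẑ (plus any
record-specific defocus) and low-passed by the detection pupil to form
the imaging-plane field.  Model predictions are background-normalized:
the same pipeline run on Δn ≡ 0 defines the background field and the
sample prediction is complex-divided by it, so predictions live in the
same normalized space as preprocessed measurements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Literal, Sequence

import numpy as np

from .optics import Field2D, Grid2D, OpticalConfig, plane_wave, propagate, pupil_filter

MeasurementKind = Literal["field", "amplitude"]


@dataclass
class RIVolume:
    """Layered refractive-index contrast map Δn(m, y, x).

    ``delta_n`` is indexed ``(m, y, x)`` for layers m = 1…M (axis 0),
    with inter-layer spacing ``dz`` μm in a background of index ``n0``.
    """

    delta_n: np.ndarray
    dz: float
    n0: float
    grid: Grid2D

    def __post_init__(self) -> None:
        self.delta_n = np.asarray(self.delta_n, dtype=np.float64)
        if self.delta_n.ndim != 3 or self.delta_n.shape[0] < 1:
            raise ValueError("delta_n must be a 3D (M, ny, nx) array with M >= 1")
        if self.delta_n.shape[1:] != self.grid.shape:
            raise ValueError(
                f"delta_n lateral shape {self.delta_n.shape[1:]} does not match "
                f"grid {self.grid.shape}"
            )
        if not self.dz > 0:
            raise ValueError("layer spacing dz must be positive")
        if not np.all(np.isfinite(self.delta_n)):
            raise ValueError("delta_n contains non-finite values")
        peak = float(np.max(np.abs(self.delta_n))) if self.delta_n.size else 0.0
        if peak > 0.2:
            warnings.warn(
                f"peak |delta_n| = {peak:.3f} exceeds 0.2; the thin-screen model "
                "degrades at high contrast",
                stacklevel=2,
            )

    @property
    def n_layers(self) -> int:
        return self.delta_n.shape[0]

    @property
    def thickness(self) -> float:
        """Total modelled thickness M·Δz in μm."""
        return self.n_layers * self.dz

    def copy(self) -> "RIVolume":
        return RIVolume(self.delta_n.copy(), self.dz, self.n0, self.grid)


@dataclass
class Measurement:
    """One 2D scattering record: complex field or real amplitude.

    Tagged with the illumination transverse wavevector ``k_lat``
    (cycles/μm) and the defocus distance ``defocus`` (μm) of the record.
    """

    data: np.ndarray
    kind: MeasurementKind
    k_lat: tuple[float, float]
    defocus: float = 0.0
    index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.kind not in ("field", "amplitude"):
            raise ValueError(f"unknown measurement kind {self.kind!r}")
        if self.kind == "amplitude":
            self.data = np.asarray(self.data, dtype=np.float64)
            if np.any(self.data < 0):
                raise ValueError("amplitude data must be non-negative")
        else:
            self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 2:
            raise ValueError("measurement data must be 2D")
        self.k_lat = (float(self.k_lat[0]), float(self.k_lat[1]))
        self.defocus = float(self.defocus)


@dataclass
class MeasurementSet:
    """Indexed collection of measurements sharing one grid and config."""

    measurements: list[Measurement]
    config: OpticalConfig
    grid: Grid2D

    def __post_init__(self) -> None:
        for m in self.measurements:
            if m.data.shape != self.grid.shape:
                raise ValueError(
                    f"measurement {m.index} shape {m.data.shape} does not match "
                    f"grid {self.grid.shape}"
                )

    def __len__(self) -> int:
        return len(self.measurements)

    def __iter__(self) -> Iterator[Measurement]:
        return iter(self.measurements)

    def __getitem__(self, i: int) -> Measurement:
        return self.measurements[i]

    def of_kind(self, kind: MeasurementKind) -> "MeasurementSet":
        return MeasurementSet(
            [m for m in self.measurements if m.kind == kind], self.config, self.grid
        )


def resolve_focus_offset(config: OpticalConfig, n_layers: int, dz: float) -> float:
    """ẑ used for imaging: configured value, or M·Δz/2 (mid-volume) if unset."""
    if config.focus_offset is None:
        return n_layers * dz / 2.0
    return float(config.focus_offset)


def check_sampling(grid: Grid2D, config: OpticalConfig) -> None:
    """Warn when the grid cannot hold the steepest modelled ray angles.

    A marginal illumination ray scattered to the pupil edge carries a
    transverse frequency up to (na_illum + na_detect)/λ; pitch beyond
    λ/(2·(na_illum + na_detect)) aliases it and silently corrupts MSBP.
    """
    limit = config.wavelength / (2.0 * (config.na_illum + config.na_detect))
    if grid.pitch > limit * (1 + 1e-12):
        warnings.warn(
            f"pixel pitch {grid.pitch:.3f} um exceeds the Nyquist limit "
            f"{limit:.3f} um for NA_illum={config.na_illum}, "
            f"NA_detect={config.na_detect}; expect aliasing",
            stacklevel=2,
        )


def slice_transmittance(volume: RIVolume, m: int, config: OpticalConfig) -> np.ndarray:
    """Unit-modulus phase mask T_m = exp(j·k·Δz·Δn_m) of layer m (0-based)."""
    return np.exp(1j * config.mask_k * volume.dz * volume.delta_n[m])


def msbp_exit_field(
    volume: RIVolume, illumination: Field2D, config: OpticalConfig
) -> Field2D:
    """Propagate an illumination field through the layer stack; returns E_M."""
    if illumination.grid != volume.grid:
        raise ValueError("illumination grid does not match volume grid")
    E = illumination
    for m in range(volume.n_layers):
        E = propagate(E, volume.dz, config)
        E = Field2D(slice_transmittance(volume, m, config) * E.values, E.grid)
    return E


def image_field(
    exit_field: Field2D,
    volume: RIVolume,
    defocus: float,
    config: OpticalConfig,
) -> Field2D:
    """Imaging-plane field: back-propagate by ẑ − defocus, then pupil-filter.

    With ẑ = defocus = 0 and a full-aperture pupil this is the identity.
    """
    zhat = resolve_focus_offset(config, volume.n_layers, volume.dz)
    out = propagate(exit_field, -zhat + defocus, config)
    return pupil_filter(out, config)


def _background_image(
    grid: Grid2D,
    n_layers: int,
    dz: float,
    k_lat: Sequence[float],
    defocus: float,
    config: OpticalConfig,
) -> Field2D:
    """The Δn ≡ 0 prediction: illumination through M·Δz of background, imaged."""
    if np.hypot(*k_lat) > config.pupil_cutoff * (1 + 1e-12):
        raise ValueError(
            "illumination frequency lies outside the detection pupil; the "
            "background field would be rejected and normalization undefined"
        )
    E = plane_wave(grid, k_lat, config)
    E = propagate(E, n_layers * dz, config)
    zhat = resolve_focus_offset(config, n_layers, dz)
    E = propagate(E, -zhat + defocus, config)
    return pupil_filter(E, config)


def forward_field(
    volume: RIVolume,
    k_lat: Sequence[float],
    defocus: float,
    config: OpticalConfig,
) -> Field2D:
    """Background-normalized complex field prediction G_field for one record."""
    illum = plane_wave(volume.grid, k_lat, config)
    exit_f = msbp_exit_field(volume, illum, config)
    img = image_field(exit_f, volume, defocus, config)
    bg = _background_image(volume.grid, volume.n_layers, volume.dz, k_lat, defocus, config)
    return Field2D(img.values / bg.values, volume.grid)


def forward(
    volume: RIVolume,
    k_lat: Sequence[float],
    defocus: float,
    kind: MeasurementKind,
    config: OpticalConfig,
) -> np.ndarray:
    """Predict one normalized 2D measurement.

    ``kind="field"`` returns the complex field G_field; ``"amplitude"``
    returns its elementwise modulus |G_field|.
    """
    G = forward_field(volume, k_lat, defocus, config)
    if kind == "field":
        return G.values
    if kind == "amplitude":
        return np.abs(G.values)
    raise ValueError(f"unknown measurement kind {kind!r}")


def simulate_measurements(
    volume: RIVolume,
    angle_list: Iterable[Sequence[float]],
    defocus_list: Iterable[float],
    kind: MeasurementKind,
    config: OpticalConfig,
    snr_db: float | None = None,
    seed: int = 0,
) -> MeasurementSet:
    """Generate one measurement per (angle, defocus) pair via the forward model.

    Optional additive circular complex Gaussian noise of the stated SNR
    (dB, signal-power / noise-power on the normalized field) is applied
    before the modulus for amplitude records.  Deterministic under a
    fixed seed.
    """
    angle_list = [tuple(a) for a in angle_list]
    defocus_list = [float(d) for d in defocus_list]
    if not angle_list or not defocus_list:
        raise ValueError("angle_list and defocus_list must be non-empty")
    if snr_db is not None and not np.isfinite(snr_db):
        raise ValueError(f"snr_db must be finite, got {snr_db}")
    check_sampling(volume.grid, config)
    rng = np.random.default_rng(seed)
    records: list[Measurement] = []
    idx = 0
    for k_lat in angle_list:
        for zd in defocus_list:
            G = forward_field(volume, k_lat, zd, config).values
            if snr_db is not None:
                sig = np.sqrt(np.mean(np.abs(G) ** 2))
                sigma = sig * 10.0 ** (-snr_db / 20.0)
                noise = sigma / np.sqrt(2.0) * (
                    rng.standard_normal(G.shape) + 1j * rng.standard_normal(G.shape)
                )
                G = G + noise
            data = G if kind == "field" else np.abs(G)
            records.append(Measurement(data, kind, k_lat, zd, index=idx))
            idx += 1
    return MeasurementSet(records, config, volume.grid)
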