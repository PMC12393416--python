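"""Model/Results front end for MSBP tomography.

`TomographyModel` binds a measurement set to a reconstruction geometry;
`fit()` runs the regularized inverse solver and returns a
`TomographyResults` carrying the RI estimate, the cost trace, and a
text `summary()`.  Simulation (forward prediction from the fitted
volume) and slice plotting hang off the results object.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np

from .forward import MeasurementSet, RIVolume, forward
from .inverse import ReconResult, SolverConfig, reconstruct, total_variation

__all__ = ["TomographyModel", "TomographyResults"]


class TomographyModel:
    """MSBP inverse-scattering model for a measurement set.

    Parameters
    ----------
    measurements : MeasurementSet
        Normalized scattering records (field and/or amplitude kind).
    n_layers : int
        Number of axial slices M of the reconstruction volume.
    dz : float
        Inter-layer spacing Δz in μm.
    config : SolverConfig, optional
        Solver settings; unset fields keep calibrated defaults.
    """

    def __init__(
        self,
        measurements: MeasurementSet,
        n_layers: int,
        dz: float,
        config: SolverConfig | None = None,
    ) -> None:
        if n_layers < 1 or not dz > 0:
            raise ValueError("need n_layers >= 1 and dz > 0")
        self.measurements = measurements
        self.n_layers = int(n_layers)
        self.dz = float(dz)
        self.config = config or SolverConfig()

    def fit(self, init_volume: RIVolume | None = None, **overrides) -> "TomographyResults":
        """Run the reconstruction; keyword overrides patch the solver config."""
        cfg = replace(self.config, **overrides) if overrides else self.config
        result = reconstruct(
            self.measurements, cfg, self.n_layers, self.dz, init_volume=init_volume
        )
        return TomographyResults(self, result)


class TomographyResults:
    """Fitted RI volume with diagnostics."""

    def __init__(self, model: TomographyModel, result: ReconResult) -> None:
        self.model = model
        self._result = result

    @property
    def volume(self) -> RIVolume:
        """The reconstructed RI-contrast map n̂ − n0, cropped to the FOV."""
        return self._result.volume

    @property
    def cost_trace(self) -> np.ndarray:
        """(n_epochs, 2) array of per-epoch mean data term and TV value."""
        return self._result.cost_trace

    @property
    def config_used(self) -> SolverConfig:
        return self._result.config_used

    def simulate(self, kind: str | None = None) -> list[np.ndarray]:
        """Forward-predict every measurement record from the fitted volume."""
        out = []
        for m in self.model.measurements:
            out.append(
                forward(
                    self.volume,
                    m.k_lat,
                    m.defocus,
                    kind or m.kind,  # type: ignore[arg-type]
                    self.model.measurements.config,
                )
            )
        return out

    def residual_norm(self) -> float:
        """Relative L2 misfit between data and fitted predictions."""
        num = 0.0
        den = 0.0
        for m, pred in zip(self.model.measurements, self.simulate()):
            num += float(np.sum(np.abs(m.data - pred) ** 2))
            den += float(np.sum(np.abs(m.data) ** 2))
        return float(np.sqrt(num / den))

    def summary(self) -> str:
        vol = self.volume
        cfg = self.config_used
        trace = self.cost_trace
        lines = [
            "MSBP Tomography Results",
            "=" * 48,
            f"grid                 {vol.grid.ny} x {vol.grid.nx} @ {vol.grid.pitch:g} um",
            f"layers               {vol.n_layers} x {vol.dz:g} um "
            f"({vol.thickness:g} um thick)",
            f"background RI        {vol.n0:g}",
            f"measurements         {len(self.model.measurements)}",
            f"cost kind            {cfg.cost_kind}",
            f"init / pad           {cfg.init} / {cfg.pad_fraction:g}",
            f"step size / tau      {cfg.step_size:g} / {cfg.tau:g}",
            f"epochs               {cfg.n_epochs} (batch {cfg.batch_size}, "
            f"momentum {cfg.momentum:g})",
            "-" * 48,
            f"final data term      {trace[-1, 0]:.4e}",
            f"final TV             {trace[-1, 1]:.4e}",
            f"delta_n range        [{vol.delta_n.min():+.4f}, {vol.delta_n.max():+.4f}]",
            f"delta_n mean         {vol.delta_n.mean():+.5f}",
        ]
        return "\n".join(lines)

    def plot_slices(self, axis: int = 0, indices: Sequence[int] | None = None, ax=None):
        """Quick-look slice montage of the reconstructed Δn (matplotlib)."""
        import matplotlib.pyplot as plt

        dn = np.moveaxis(self.volume.delta_n, axis, 0)
        if indices is None:
            indices = np.linspace(0, dn.shape[0] - 1, min(4, dn.shape[0])).astype(int)
        if ax is None:
            _, axes = plt.subplots(1, len(indices), figsize=(3 * len(indices), 3))
        else:
            axes = np.atleast_1d(ax)
        vmax = np.max(np.abs(dn)) or 1.0
        for a, i in zip(np.atleast_1d(axes), indices):
            im = a.imshow(dn[i], cmap="magma", vmin=-0.1 * vmax, vmax=vmax)
            a.set_title(f"slice {i}")
            a.axis("off")
        plt.colorbar(im, ax=np.atleast_1d(axes).tolist(), shrink=0.8, label="Δn")
        return axes
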