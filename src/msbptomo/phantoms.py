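"""Synthetic ground-truth phantoms and reconstruction-quality metrics.

Stand-ins for physical calibration targets: index-contrast microspheres
(as used to calibrate step size and regularization against known RI)
and a two-photon-polymerization-style scattering cube — layers of
parallel polymer rods with randomized lateral gaps, orientation
alternating 90° between successive layers — optionally hosting a
compact cell-like target with multi-scale internal features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from .forward import RIVolume
from .optics import Grid2D


@dataclass(frozen=True)
class RodCubeSpec:
    """Geometry of the pseudo-random rod-scattering cube.

    Defaults mirror the fabricated design: 0.5 μm × 1.8 μm rods, lateral
    edge-to-edge gaps drawn uniformly from 0.7–3 μm, layers stacked
    every 1.4 μm with orientation alternating between x and y.
    """

    cube_size: float = 20.0
    rod_width: float = 0.5
    rod_height: float = 1.8
    layer_pitch: float = 1.4
    spacing_range: tuple[float, float] = (0.7, 3.0)
    delta_n: float = 0.04
    alternate_orientation: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.spacing_range
        if lo > hi:
            raise ValueError("spacing_range must be (min, max) with min <= max")
        for name in ("cube_size", "rod_width", "rod_height", "layer_pitch"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def _axial_centers(n_layers: int, dz: float) -> np.ndarray:
    """Physical z of each layer plane; layer m (0-based) sits at m·Δz."""
    return np.arange(n_layers) * dz


def bead_phantom(
    diameter: float,
    delta_n: float,
    grid: Grid2D,
    n_layers: int,
    dz: float,
    center: tuple[float, float, float] | None = None,
    n0: float = 1.336,
) -> RIVolume:
    """Uniform-contrast sphere with a partial-volume antialiased boundary.

    ``center`` is (x, y, z) in μm; default is the volume centre.  Voxels
    strictly inside the sphere carry exactly ``delta_n``; boundary
    voxels are weighted linearly by their signed distance to the
    surface over one voxel diagonal.
    """
    R = diameter / 2.0
    x, y = grid.coords()
    z = _axial_centers(n_layers, dz)
    if center is None:
        center = (
            (grid.nx - 1) * grid.pitch / 2.0,
            (grid.ny - 1) * grid.pitch / 2.0,
            (n_layers - 1) * dz / 2.0,
        )
    cx, cy, cz = center
    if R > min(grid.extent[0], grid.extent[1], n_layers * dz) / 2.0:
        raise ValueError("bead does not fit inside the volume")
    r = np.sqrt(
        (x[None] - cx) ** 2 + (y[None] - cy) ** 2 + (z[:, None, None] - cz) ** 2
    )
    h = min(grid.pitch, dz)  # transition width: one (finest) voxel
    w = np.clip(0.5 + (R - r) / h, 0.0, 1.0)
    return RIVolume(delta_n * w, dz, n0, grid)


def sphere_mask(
    grid: Grid2D,
    n_layers: int,
    dz: float,
    diameter: float,
    center: tuple[float, float, float] | None = None,
    fraction: float = 0.7,
) -> np.ndarray:
    """Boolean interior mask: r ≤ fraction·radius of the stated sphere.

    Shrinking away from the boundary excludes partial-volume and
    resolution-limited shell voxels from interior-mean RI scoring.
    """
    R = fraction * diameter / 2.0
    x, y = grid.coords()
    z = _axial_centers(n_layers, dz)
    if center is None:
        center = (
            (grid.nx - 1) * grid.pitch / 2.0,
            (grid.ny - 1) * grid.pitch / 2.0,
            (n_layers - 1) * dz / 2.0,
        )
    cx, cy, cz = center
    r = np.sqrt(
        (x[None] - cx) ** 2 + (y[None] - cy) ** 2 + (z[:, None, None] - cz) ** 2
    )
    return r <= R


def rod_cube(
    spec: RodCubeSpec,
    grid: Grid2D,
    n_layers: int,
    dz: float,
    n0: float = 1.512,
) -> tuple[RIVolume, float]:
    """Pseudo-random rod-scattering cube; returns (volume, fill factor).

    Rod layers sit every ``layer_pitch`` μm starting at the cube bottom;
    each layer holds parallel rods of the stated cross-section spanning
    the cube, with edge-to-edge lateral gaps drawn uniformly from
    ``spacing_range``.  Successive layers alternate orientation by 90°
    when requested.  Overlapping rods (the 1.8 μm height exceeds the
    1.4 μm stacking pitch) take the single rod contrast — the physical
    polymer has one RI.  The fill factor is the fraction of cube voxels
    with Δn above half the rod contrast.  Bit-reproducible under
    ``spec.seed``.
    """
    S = spec.cube_size
    Lx, Ly = grid.extent
    Lz = n_layers * dz
    if S > Lx or S > Ly:
        raise ValueError("cube does not fit laterally in the grid")
    rng = np.random.default_rng(spec.seed)
    xv = np.arange(grid.nx) * grid.pitch
    yv = np.arange(grid.ny) * grid.pitch
    z = _axial_centers(n_layers, dz)

    # cube bounding box, centered laterally, clipped axially to the volume
    x0, x1 = (Lx - S) / 2.0, (Lx + S) / 2.0
    y0, y1 = (Ly - S) / 2.0, (Ly + S) / 2.0
    height = min(S, Lz)
    z0 = (Lz - height) / 2.0
    z1 = z0 + height

    dn = np.zeros((n_layers,) + grid.shape, dtype=np.float64)
    in_x = (xv >= x0) & (xv < x1)
    in_y = (yv >= y0) & (yv < y1)

    zc = z0 + spec.rod_height / 2.0
    layer = 0
    half_h = spec.rod_height / 2.0
    half_w = spec.rod_width / 2.0
    while zc + half_h <= z1 + 1e-9:
        axial = np.abs(z - zc) <= half_h
        along_x = (layer % 2 == 0) or not spec.alternate_orientation
        # rod centres across the axis perpendicular to the rod direction
        perp0, perp1 = (y0, y1) if along_x else (x0, x1)
        u = perp0 - rng.uniform(0.0, spec.rod_width + spec.spacing_range[1])
        centers = []
        while u < perp1:
            if u + spec.rod_width > perp0:
                centers.append(u + half_w)
            u += spec.rod_width + rng.uniform(*spec.spacing_range)
        perp = yv if along_x else xv
        pmask = np.zeros(perp.shape, dtype=bool)
        for c in centers:
            pmask |= np.abs(perp - c) <= half_w
        if along_x:  # rods run along x, stacked across y
            lat2d = (pmask & in_y)[:, None] & in_x[None, :]
        else:  # rods run along y, stacked across x
            lat2d = in_y[:, None] & (pmask & in_x)[None, :]
        dn[axial] = np.maximum(dn[axial], spec.delta_n * lat2d[None])
        zc += spec.layer_pitch
        layer += 1

    cube_mask = np.zeros_like(dn, dtype=bool)
    in_z = (z >= z0) & (z < z1)
    cube_mask[in_z] = (in_y[:, None] & in_x[None, :])[None]
    n_cube = int(cube_mask.sum())
    fill = float(np.count_nonzero(dn[cube_mask] > spec.delta_n / 2.0) / max(n_cube, 1))
    return RIVolume(dn, dz, n0, grid), fill


@dataclass(frozen=True)
class Feature:
    """One geometric feature of the cell-like target."""

    kind: Literal["sphere", "shell", "bar"]
    center: tuple[float, float, float]
    size: float  # sphere/shell diameter or bar width, μm
    delta_n: float
    length: float = 2.0  # bar length, μm
    thickness: float = 0.4  # shell wall thickness, μm
    axis: Literal["x", "y"] = "x"
    label: int = 1


def default_cell_features(
    center: tuple[float, float, float], min_feature: float = 0.3
) -> list[Feature]:
    """A compact multi-scale test target: a shell plus bars down to min_feature."""
    cx, cy, cz = center
    feats = [
        Feature("shell", (cx, cy, cz), size=4.0, thickness=0.5, delta_n=0.02, label=1),
        Feature("sphere", (cx + 0.8, cy - 0.6, cz), size=1.2, delta_n=0.03, label=2),
    ]
    widths = [1.0, 0.5, min_feature]
    for i, w in enumerate(widths):
        feats.append(
            Feature(
                "bar",
                (cx - 1.0, cy + 1.0 - 0.7 * i, cz),
                size=w,
                length=2.0,
                delta_n=0.025,
                axis="x",
                label=3 + i,
            )
        )
    return feats


def cell_target(
    features: Sequence[Feature],
    grid: Grid2D,
    n_layers: int,
    dz: float,
    n0: float = 1.512,
) -> tuple[RIVolume, np.ndarray]:
    """Voxelize a list of features; returns (volume, integer label mask).

    Later features overwrite earlier ones where they overlap.  The
    smallest feature must span at least two voxels of the grid.
    """
    for f in features:
        if f.size < 2 * min(grid.pitch, dz):
            raise ValueError(
                f"feature with size {f.size} um is below two voxels at this sampling"
            )
    x, y = grid.coords()
    z = _axial_centers(n_layers, dz)
    dn = np.zeros((n_layers,) + grid.shape, dtype=np.float64)
    labels = np.zeros_like(dn, dtype=np.int32)
    for f in features:
        cx, cy, cz = f.center
        if f.kind in ("sphere", "shell"):
            r = np.sqrt(
                (x[None] - cx) ** 2
                + (y[None] - cy) ** 2
                + (z[:, None, None] - cz) ** 2
            )
            R = f.size / 2.0
            mask = r <= R if f.kind == "sphere" else (np.abs(r - R) <= f.thickness / 2.0)
        elif f.kind == "bar":
            half_w = f.size / 2.0
            half_l = f.length / 2.0
            dx = np.abs(x[None] - cx)
            dy = np.abs(y[None] - cy)
            du, dv = (dx, dy) if f.axis == "x" else (dy, dx)
            mask = (
                (du <= half_l)
                & (dv <= half_w)
                & (np.abs(z[:, None, None] - cz) <= half_w)
            )
        else:
            raise ValueError(f"unknown feature kind {f.kind!r}")
        dn[mask] = f.delta_n
        labels[mask] = f.label
    return RIVolume(dn, dz, n0, grid), labels


def embed(target: RIVolume, host: RIVolume, offset: tuple[int, int, int]) -> RIVolume:
    """Place ``target`` into ``host`` at the given voxel offset (m, y, x).

    Overlapping voxels take the maximum contrast (the target carves out
    rods); host voxels outside the overlap are unchanged.
    """
    om, oy, ox = offset
    tm, ty, tx = target.delta_n.shape
    hm, hy, hx = host.delta_n.shape
    if om < 0 or oy < 0 or ox < 0 or om + tm > hm or oy + ty > hy or ox + tx > hx:
        raise ValueError("target does not fit in host at the given offset")
    out = host.delta_n.copy()
    sl = (slice(om, om + tm), slice(oy, oy + ty), slice(ox, ox + tx))
    out[sl] = np.maximum(out[sl], target.delta_n)
    return RIVolume(out, host.dz, host.n0, host.grid)


def ri_error(
    recon: RIVolume, truth: RIVolume, mask: np.ndarray | None = None
) -> dict[str, float]:
    """Voxelwise RI-accuracy metrics over an optional boolean mask."""
    if recon.delta_n.shape != truth.delta_n.shape:
        raise ValueError("reconstruction and truth shapes differ")
    if mask is None:
        mask = np.ones_like(truth.delta_n, dtype=bool)
    d = recon.delta_n[mask] - truth.delta_n[mask]
    mean_true = float(np.mean(truth.delta_n[mask]))
    mean_rec = float(np.mean(recon.delta_n[mask]))
    rel = abs(mean_rec - mean_true) / abs(mean_true) if mean_true != 0 else (
        0.0 if mean_rec == 0 else np.inf
    )
    return {
        "mean_bias": float(np.mean(d)),
        "rmse": float(np.sqrt(np.mean(d**2))),
        "interior_mean_relative_error": float(rel),
    }
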