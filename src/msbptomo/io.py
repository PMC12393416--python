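"""Readers/writers: measurement sets as HDF5, volumes and fields as TIFF+JSON.

HDF5 layout for a measurement set::

    /measurements/000/data      complex64 or float32 dataset
                      .attrs    kind, k_lat, defocus, index
    /.attrs                     wavelength, n0, na_detect, na_illum,
                                focus_offset, kernel, mask_wavenumber,
                                pitch, version

Volumes are multi-page 32-bit TIFF (one page per layer) with a JSON
sidecar ``<name>.json`` holding {dz, n0, pitch}.  Round trips are
lossless at the stored precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .optics import Field2D, Grid2D, OpticalConfig
from .forward import Measurement, MeasurementSet, RIVolume

FORMAT_VERSION = "msbptomo-1"

_CONFIG_ATTRS = ("wavelength", "n0", "na_detect", "na_illum")


def write_measurement_set(path: str | Path, mset: MeasurementSet) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        for name in _CONFIG_ATTRS:
            f.attrs[name] = getattr(mset.config, name)
        if mset.config.focus_offset is not None:
            f.attrs["focus_offset"] = mset.config.focus_offset
        f.attrs["kernel"] = mset.config.kernel
        f.attrs["mask_wavenumber"] = mset.config.mask_wavenumber
        f.attrs["pitch"] = mset.grid.pitch
        grp = f.create_group("measurements")
        for i, m in enumerate(mset):
            if m.kind == "field":
                data = m.data.astype(np.complex64)
            else:
                data = m.data.astype(np.float32)
            d = grp.create_dataset(f"{i:03d}", data=data)
            d.attrs["kind"] = m.kind
            d.attrs["k_lat"] = np.asarray(m.k_lat, dtype=np.float64)
            d.attrs["defocus"] = m.defocus
            d.attrs["index"] = m.index


def _require_attr(obj, name: str, path) -> object:
    if name not in obj.attrs:
        raise KeyError(f"{path}: missing required attribute {name!r}")
    return obj.attrs[name]


def read_measurement_set(path: str | Path) -> MeasurementSet:
    with h5py.File(path, "r") as f:
        version = _require_attr(f, "version", path)
        if version != FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported format version {version!r}")
        kwargs = {name: float(_require_attr(f, name, path)) for name in _CONFIG_ATTRS}
        if "focus_offset" in f.attrs:
            kwargs["focus_offset"] = float(f.attrs["focus_offset"])
        kwargs["kernel"] = str(f.attrs.get("kernel", "standard"))
        kwargs["mask_wavenumber"] = str(f.attrs.get("mask_wavenumber", "vacuum"))
        config = OpticalConfig(**kwargs)
        pitch = float(_require_attr(f, "pitch", path))
        records = []
        grp = f["measurements"]
        grid = None
        for key in sorted(grp.keys()):
            d = grp[key]
            kind = str(_require_attr(d, "kind", path))
            k_lat = tuple(np.asarray(_require_attr(d, "k_lat", path), dtype=float))
            data = d[...]
            data = data.astype(np.complex128 if kind == "field" else np.float64)
            if grid is None:
                grid = Grid2D(data.shape[1], data.shape[0], pitch)
            records.append(
                Measurement(
                    data,
                    kind,  # type: ignore[arg-type]
                    k_lat,
                    float(_require_attr(d, "defocus", path)),
                    int(d.attrs.get("index", len(records))),
                )
            )
        if grid is None:
            raise ValueError(f"{path}: measurement set is empty")
    return MeasurementSet(records, config, grid)


def write_volume(path: str | Path, volume: RIVolume) -> None:
    """Multi-page float32 TIFF (one page per layer) plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, volume.delta_n.astype(np.float32))
    sidecar = {
        "version": FORMAT_VERSION,
        "dz": volume.dz,
        "n0": volume.n0,
        "pitch": volume.grid.pitch,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_volume(path: str | Path) -> RIVolume:
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    for name in ("dz", "n0", "pitch"):
        if name not in meta:
            raise KeyError(f"{sidecar_path}: missing required attribute {name!r}")
    data = tifffile.imread(path).astype(np.float64)
    if data.ndim == 2:
        data = data[None]
    grid = Grid2D(data.shape[2], data.shape[1], float(meta["pitch"]))
    return RIVolume(data, float(meta["dz"]), float(meta["n0"]), grid)


def write_accumulator(path: str | Path, acc) -> None:
    """HDF5 export of a k-space accumulator (spectrum + counts) for inspection."""
    with h5py.File(path, "w") as f:
        f.attrs["version"] = FORMAT_VERSION
        f.attrs["pitch"] = acc.grid.pitch
        f.attrs["dz"] = acc.dz
        f.create_dataset("spectrum", data=acc.spectrum.astype(np.complex64))
        f.create_dataset("counts", data=acc.counts)


def read_accumulator(path: str | Path):
    from .rytov import KSpaceAccumulator

    with h5py.File(path, "r") as f:
        if _require_attr(f, "version", path) != FORMAT_VERSION:
            raise ValueError(f"{path}: unsupported format version")
        spectrum = f["spectrum"][...].astype(np.complex128)
        counts = f["counts"][...]
        grid = Grid2D(spectrum.shape[2], spectrum.shape[1], float(f.attrs["pitch"]))
        return KSpaceAccumulator(spectrum, counts, grid, spectrum.shape[0],
                                 float(f.attrs["dz"]))


def write_field(path: str | Path, field: Field2D, config: OpticalConfig) -> None:
    """2-page TIFF (real, imaginary) with wavelength/n0/pitch metadata."""
    path = Path(path)
    pages = np.stack([field.values.real, field.values.imag]).astype(np.float32)
    tifffile.imwrite(path, pages)
    sidecar = {
        "version": FORMAT_VERSION,
        "wavelength": config.wavelength,
        "n0": config.n0,
        "pitch": field.grid.pitch,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_field(path: str | Path) -> tuple[Field2D, dict]:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    pages = tifffile.imread(path).astype(np.float64)
    grid = Grid2D(pages.shape[2], pages.shape[1], float(meta["pitch"]))
    return Field2D(pages[0] + 1j * pages[1], grid), meta
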