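"""Reading and writing raw records, cubes, slices and spectra.

Raw acquisitions travel as NPZ or HDF5 with datasets ``raman``,
``trigger`` and ``transmission`` (plus the configuration and optional
ground truth), or as a 3-page TIFF (one page per channel, in that
order) accompanied by a YAML/JSON configuration.  Hypercubes persist as
NPZ/HDF5 with ``hypercube``, ``wavenumber_axis`` and ``pixel_mask``;
frequency-slice images export as TIFF and spectra as two-column CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .physics import AcquisitionConfig
from .simulate import GroundTruth, RawAcquisition
from .spectral import HyperCube, Spectrum

__all__ = [
    "write_fixture",
    "read_fixture",
    "load_channels",
    "write_hypercube",
    "read_hypercube",
    "write_slice_tiff",
    "write_spectrum_csv",
    "read_spectrum_csv",
]

_CHANNELS = ("raman", "trigger", "transmission")
_GT_KEYS = ("raman_cube", "transmission_cube", "transient")


def _io_error(path, exc):
    return OSError(f"while accessing {path}: {exc}")


def write_fixture(raw: RawAcquisition, path: str | Path) -> None:
    """Persist an acquisition losslessly (``.npz`` or ``.h5``/``.hdf5``)."""
    path = Path(path)
    arrays = {ch: getattr(raw, ch) for ch in _CHANNELS}
    if raw.ground_truth is not None:
        arrays.update(
            {f"gt_{k}": getattr(raw.ground_truth, k) for k in _GT_KEYS}
        )
    config_json = json.dumps(raw.config.to_dict())
    try:
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "w") as f:
                for k, v in arrays.items():
                    f.create_dataset(k, data=v)
                f.attrs["config"] = config_json
                f.attrs["truncated_samples"] = raw.truncated_samples
        elif path.suffix == ".npz":
            np.savez(
                path,
                **arrays,
                config=np.bytes_(config_json),
                truncated_samples=raw.truncated_samples,
            )
        else:
            raise ValueError(f"unsupported fixture format: {path.suffix}")
    except OSError as exc:  # pragma: no cover - filesystem dependent
        raise _io_error(path, exc) from exc


def read_fixture(path: str | Path) -> RawAcquisition:
    """Load an acquisition written by :func:`write_fixture`."""
    path = Path(path)
    try:
        if path.suffix in (".h5", ".hdf5"):
            with h5py.File(path, "r") as f:
                arrays = {k: f[k][...] for k in f}
                config = AcquisitionConfig.from_dict(json.loads(f.attrs["config"]))
                truncated = int(f.attrs.get("truncated_samples", 0))
        elif path.suffix == ".npz":
            with np.load(path) as f:
                arrays = {k: f[k] for k in f.files if k not in ("config", "truncated_samples")}
                config = AcquisitionConfig.from_dict(
                    json.loads(bytes(f["config"]).decode())
                )
                truncated = int(f["truncated_samples"])
        else:
            raise ValueError(f"unsupported fixture format: {path.suffix}")
    except OSError as exc:
        raise _io_error(path, exc) from exc
    gt = None
    if all(f"gt_{k}" in arrays for k in _GT_KEYS):
        gt = GroundTruth(**{k: arrays[f"gt_{k}"] for k in _GT_KEYS})
    return RawAcquisition(
        raman=arrays["raman"],
        trigger=arrays["trigger"],
        transmission=arrays["transmission"],
        config=config,
        ground_truth=gt,
        truncated_samples=truncated,
    )


def load_channels(
    path: str | Path, config: AcquisitionConfig | None = None
) -> RawAcquisition:
    """Load the three raw channels from NPZ/HDF5 (self-describing) or a
    3-page TIFF (needs an explicit configuration)."""
    path = Path(path)
    if path.suffix in (".npz", ".h5", ".hdf5"):
        raw = read_fixture(path)
        if config is not None:
            raw.config = config
        return raw
    if path.suffix in (".tif", ".tiff"):
        if config is None:
            raise ValueError("TIFF input requires an explicit AcquisitionConfig")
        pages = tifffile.imread(path)
        if pages.ndim != 3 or pages.shape[0] != 3:
            raise ValueError(
                f"{path}: expected 3 pages (raman, trigger, transmission), "
                f"got shape {pages.shape}"
            )
        return RawAcquisition(
            raman=np.asarray(pages[0], dtype=float),
            trigger=np.asarray(pages[1], dtype=float),
            transmission=np.asarray(pages[2], dtype=float),
            config=config,
        )
    raise ValueError(f"unsupported raw format: {path.suffix}")


def write_hypercube(hcube: HyperCube, path: str | Path) -> None:
    """Persist a hypercube with its axis, pixel mask and parameters."""
    path = Path(path)
    params = hcube.metadata.get("params")
    params_json = json.dumps(vars(params) if params is not None else {})
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("hypercube", data=hcube.data)
            f.create_dataset("wavenumber_axis", data=hcube.wavenumbers)
            f.create_dataset("pixel_mask", data=hcube.pixel_valid)
            f.attrs["params"] = params_json
    elif path.suffix == ".npz":
        np.savez(
            path,
            hypercube=hcube.data,
            wavenumber_axis=hcube.wavenumbers,
            pixel_mask=hcube.pixel_valid,
            params=np.bytes_(params_json),
        )
    else:
        raise ValueError(f"unsupported cube format: {path.suffix}")


def read_hypercube(path: str | Path) -> HyperCube:
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            return HyperCube(
                data=f["hypercube"][...],
                wavenumbers=f["wavenumber_axis"][...],
                pixel_valid=f["pixel_mask"][...].astype(bool),
                metadata={"params_json": f.attrs.get("params", "{}")},
            )
    if path.suffix == ".npz":
        with np.load(path) as f:
            return HyperCube(
                data=f["hypercube"],
                wavenumbers=f["wavenumber_axis"],
                pixel_valid=f["pixel_mask"].astype(bool),
                metadata={"params_json": bytes(f["params"]).decode()},
            )
    raise ValueError(f"unsupported cube format: {path.suffix}")


def write_slice_tiff(image: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, dtype=np.float32))


def write_spectrum_csv(spectrum: Spectrum, path: str | Path) -> None:
    """Two-column CSV: wavenumber (cm^-1), magnitude."""
    arr = np.column_stack([spectrum.wavenumbers, spectrum.magnitude])
    np.savetxt(
        Path(path), arr, delimiter=",", header="wavenumber_cm-1,magnitude", comments=""
    )


def read_spectrum_csv(path: str | Path) -> Spectrum:
    arr = np.loadtxt(Path(path), delimiter=",", skiprows=1)
    return Spectrum(wavenumbers=arr[:, 0], magnitude=arr[:, 1])
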