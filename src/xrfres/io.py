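"""Reading and writing elemental maps, radial spectra, and analysis reports.

Three on-disk map layouts are supported, all carrying the same metadata
(pixel pitch dx/dy in µm, element symbol, dwell time in s):

* HDF5 — one 2-D dataset (default path ``"map"``) with the metadata as
  dataset attributes.  This is a simple documented layout, not the internal
  schema of any particular spectrum-fitting program.
* TIFF — single-page 32-bit float image plus a YAML sidecar
  (``<file>.yaml``) holding the metadata.
* CSV — comma-delimited pixel values plus the same YAML sidecar.

Missing pixel-pitch metadata is an error, never a silent default: a map
without a physical scale cannot yield a resolution in physical units.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .maps import ElementalMap, InvalidMapError
from .psd import RadialPSD

__all__ = [
    "read_map",
    "write_map",
    "write_radial_psd",
    "read_radial_psd",
    "write_report",
    "file_digest",
]

_REQUIRED_META = ("dx", "dy")
_DEFAULT_DATASET = "map"


class MapReadError(IOError):
    """A map file is unreadable, has the wrong dimensionality, or lacks metadata."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def _check_meta(meta: dict, source: str) -> None:
    missing = [k for k in _REQUIRED_META if k not in meta]
    if missing:
        raise MapReadError(
            f"{source}: missing required pixel-pitch metadata {missing}; "
            "a map without a physical scale cannot be analyzed"
        )


def _build_map(values: np.ndarray, meta: dict, source: str) -> ElementalMap:
    if values.ndim != 2:
        raise MapReadError(
            f"{source}: expected a 2-D dataset, got {values.ndim}-D shape {values.shape}"
        )
    _check_meta(meta, source)
    try:
        return ElementalMap(
            values=np.asarray(values, dtype=float),
            dx=float(meta["dx"]),
            dy=float(meta["dy"]),
            element=str(meta.get("element", "")),
            dwell=float(meta.get("dwell", 1.0)),
        )
    except InvalidMapError as exc:
        raise MapReadError(f"{source}: {exc}") from exc


def read_map(path: str | Path, dataset: str = _DEFAULT_DATASET) -> ElementalMap:
    """Read an elemental map from HDF5, TIFF(+sidecar), or CSV(+sidecar).

    The format is chosen by extension (.h5/.hdf5, .tif/.tiff, .csv).
    ``dataset`` selects the HDF5 dataset path and is ignored elsewhere.
    """
    path = Path(path)
    if not path.exists():
        raise MapReadError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if dataset not in f:
                raise MapReadError(f"{path}: no dataset {dataset!r}")
            ds = f[dataset]
            values = np.asarray(ds)
            meta = dict(ds.attrs)
        return _build_map(values, meta, str(path))
    if suffix in (".tif", ".tiff"):
        values = tifffile.imread(path)
        meta = _read_sidecar(path)
        return _build_map(values, meta, str(path))
    if suffix == ".csv":
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        meta = _read_sidecar(path)
        return _build_map(values, meta, str(path))
    raise MapReadError(f"{path}: unrecognized map format {suffix!r}")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MapReadError(f"{path}: metadata sidecar {sidecar.name} not found")
    with open(sidecar) as f:
        meta = yaml.safe_load(f)
    if not isinstance(meta, dict):
        raise MapReadError(f"{sidecar}: sidecar must be a YAML mapping")
    return meta


def write_map(emap: ElementalMap, path: str | Path, dataset: str = _DEFAULT_DATASET) -> None:
    """Write an elemental map in the layout implied by the file extension."""
    path = Path(path)
    meta = {"dx": emap.dx, "dy": emap.dy, "element": emap.element, "dwell": emap.dwell}
    suffix = path.suffix.lower()
    if suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(dataset, data=emap.values)
            for k, v in meta.items():
                ds.attrs[k] = v
        return
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, emap.values.astype(np.float32))
    elif suffix == ".csv":
        np.savetxt(path, emap.values, delimiter=",")
    else:
        raise ValueError(f"unrecognized map format {suffix!r}")
    with open(_sidecar_path(path), "w") as f:
        yaml.safe_dump(meta, f)


def write_radial_psd(psd: RadialPSD, path: str | Path) -> None:
    """Export a radial PSD as CSV with columns u_r, S, n."""
    with open(path, "w", newline="") as f:
        writer = csv.writer(f)
        writer.writerow(["u_r", "S", "n"])
        for u, s, n in zip(psd.u_r, psd.S, psd.n):
            writer.writerow([repr(float(u)), repr(float(s)), int(n)])


def read_radial_psd(path: str | Path) -> RadialPSD:
    """Read back a radial PSD written by :func:`write_radial_psd`."""
    data = np.genfromtxt(path, delimiter=",", names=True)
    return RadialPSD(
        u_r=np.atleast_1d(data["u_r"]),
        S=np.atleast_1d(data["S"]),
        n=np.atleast_1d(data["n"]).astype(int),
    )


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path: str | Path | None) -> str:
    """Serialize an analysis report to JSON; return the JSON text.

    ``path=None`` skips writing and just returns the serialized text.
    """
    text = json.dumps(_jsonable(report), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def file_digest(path: str | Path) -> str:
    """SHA-256 digest of a file, for report provenance."""
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
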