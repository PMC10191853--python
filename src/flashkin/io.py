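"""File I/O for flash-series spectro-kinetic matrices.

Two on-disk layouts are supported:

* ``delimited`` — a directory holding one tab-separated file per flash
  (first column time in us, one further column per wavenumber, header row
  ``time_us`` followed by the wavenumber values) plus a ``manifest.json``
  with axes metadata.  Mirrors the per-flash averaged time-course layout of
  deposited step-scan data.
* ``binary`` — a single HDF5 container with named datasets ``data``,
  ``time_us`` and ``wavenumbers_cm1`` and metadata attributes.

Readers normalize descending wavenumber axes to ascending (reordering the
data accordingly) and reject non-finite cells.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .dataset import FlashSeriesDataset, TimeGrid, WavenumberGrid
from .exceptions import DimensionError, ParseError, ValidationError

FORMATS = ("delimited", "binary")
_MANIFEST = "manifest.json"
_MAGIC = "flashkin-delimited-v1"


def write_flash_series(dataset: FlashSeriesDataset, path, format="delimited"):
    """Write a dataset; returns the path written.

    ``delimited`` writes a directory, ``binary`` a single HDF5 file.  Values
    are stored at full double precision so a read-back is bit-identical.
    """
    path = Path(path)
    if format == "delimited":
        return _write_delimited(dataset, path)
    if format == "binary":
        return _write_hdf5(dataset, path)
    raise ValidationError(f"unknown format {format!r}; expected one of {FORMATS}")


def read_flash_series(path, format=None) -> FlashSeriesDataset:
    """Read a dataset; ``format`` is inferred from the path when omitted."""
    path = Path(path)
    if format is None:
        format = "delimited" if path.is_dir() else "binary"
    if format == "delimited":
        return _read_delimited(path)
    if format == "binary":
        return _read_hdf5(path)
    raise ValidationError(f"unknown format {format!r}; expected one of {FORMATS}")


# --- delimited --------------------------------------------------------------

def _write_delimited(dataset: FlashSeriesDataset, path: Path):
    path.mkdir(parents=True, exist_ok=True)
    files = []
    times = dataset.time.times
    header = "time_us\t" + "\t".join(
        format(w, ".17g") for w in dataset.wavenumbers.values
    )
    for n in range(dataset.n_flashes):
        name = f"flash_{n + 1:02d}.tsv"
        files.append(name)
        block = np.column_stack([times, dataset.data[n]])
        np.savetxt(path / name, block, delimiter="\t", header=header,
                   comments="", fmt="%.17g")
    manifest = {
        "format": _MAGIC,
        "n_flashes": dataset.n_flashes,
        "dt_us": dataset.time.dt,
        "n_samples": dataset.time.n_samples,
        "t0_index": dataset.time.t0_index,
        "flash_spacing_ms": dataset.flash_spacing,
        "files": files,
    }
    if dataset.metadata:
        manifest["metadata"] = _jsonable(dataset.metadata)
    (path / _MANIFEST).write_text(json.dumps(manifest, indent=1))
    return path


def _jsonable(meta: dict) -> dict:
    out = {}
    for k, v in meta.items():
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        out[str(k)] = v
    return out


def _read_delimited(path: Path) -> FlashSeriesDataset:
    manifest_path = path / _MANIFEST
    if not manifest_path.exists():
        raise ParseError(f"no {_MANIFEST} in {path}")
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{manifest_path}: invalid JSON at line {exc.lineno}") from exc
    if manifest.get("format") != _MAGIC:
        raise ParseError(f"{manifest_path}: unknown format tag {manifest.get('format')!r}")
    time = TimeGrid(dt=float(manifest["dt_us"]),
                    n_samples=int(manifest["n_samples"]),
                    t0_index=int(manifest["t0_index"]))
    blocks = []
    wavenumbers = None
    order = None
    for name in manifest["files"]:
        fpath = path / name
        if not fpath.exists():
            raise ParseError(f"manifest names missing file {name!r}")
        with open(fpath) as fh:
            header = fh.readline().strip()
        cols = header.split("\t")
        if not cols or cols[0] != "time_us":
            raise ParseError(f"{fpath}, line 1: header must start with 'time_us'")
        try:
            wn = np.array([float(c) for c in cols[1:]])
        except ValueError:
            raise ParseError(f"{fpath}, line 1: non-numeric wavenumber in header")
        block = np.loadtxt(fpath, delimiter="\t", skiprows=1, ndmin=2)
        if block.shape[1] != wn.size + 1:
            raise DimensionError(
                f"{fpath}: {block.shape[1] - 1} data columns but "
                f"{wn.size} wavenumbers in header"
            )
        if block.shape[0] != time.n_samples:
            raise DimensionError(
                f"{fpath}: {block.shape[0]} rows but manifest declares "
                f"{time.n_samples} samples"
            )
        if wavenumbers is None:
            grid, order = WavenumberGrid.from_values(wn)
            wavenumbers = grid
        elif not np.array_equal(wn[order], wavenumbers.values):
            raise DimensionError(f"{fpath}: wavenumber axis differs between flashes")
        values = block[:, 1:][:, order]
        bad = np.argwhere(~np.isfinite(values))
        if bad.size:
            raise ValidationError(
                f"{fpath}: non-finite cells at (row, col) "
                f"{[(int(r), int(c)) for r, c in bad[:5]]}"
            )
        blocks.append(values)
    if not blocks:
        raise ParseError(f"{manifest_path}: manifest lists no files")
    return FlashSeriesDataset(
        data=np.stack(blocks),
        time=time,
        wavenumbers=wavenumbers,
        flash_spacing=float(manifest.get("flash_spacing_ms", 700.0)),
        metadata=dict(manifest.get("metadata", {})),
    )


# --- binary (HDF5) ----------------------------------------------------------

def _write_hdf5(dataset: FlashSeriesDataset, path: Path):
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("data", data=dataset.data)
        fh.create_dataset("time_us", data=dataset.time.times)
        fh.create_dataset("wavenumbers_cm1", data=dataset.wavenumbers.values)
        fh.attrs["dt_us"] = dataset.time.dt
        fh.attrs["t0_index"] = dataset.time.t0_index
        fh.attrs["flash_spacing_ms"] = dataset.flash_spacing
        if dataset.metadata:
            fh.attrs["metadata_json"] = json.dumps(_jsonable(dataset.metadata))
    return path


def _read_hdf5(path: Path) -> FlashSeriesDataset:
    if not Path(path).exists():
        raise ParseError(f"no such file: {path}")
    with h5py.File(path, "r") as fh:
        for key in ("data", "time_us", "wavenumbers_cm1"):
            if key not in fh:
                raise ParseError(f"{path}: missing dataset {key!r}")
        data = fh["data"][...]
        wn = fh["wavenumbers_cm1"][...]
        dt = float(fh.attrs["dt_us"])
        t0 = int(fh.attrs["t0_index"])
        spacing = float(fh.attrs.get("flash_spacing_ms", 700.0))
        meta = json.loads(fh.attrs.get("metadata_json", "{}"))
    if data.ndim != 3:
        raise DimensionError(f"{path}: data must be 3D, got shape {data.shape}")
    grid, order = WavenumberGrid.from_values(wn)
    data = data[:, :, order]
    bad = np.argwhere(~np.isfinite(data))
    if bad.size:
        raise ValidationError(
            f"{path}: non-finite cells at {[tuple(ix) for ix in bad[:5]]}"
        )
    time = TimeGrid(dt=dt, n_samples=data.shape[1], t0_index=t0)
    return FlashSeriesDataset(data=data, time=time, wavenumbers=grid,
                              flash_spacing=spacing, metadata=meta)
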