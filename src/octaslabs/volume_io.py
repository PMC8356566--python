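"""Readers and writers for volumes, boundary surfaces and en face images.

Two volume containers are supported:

* **HDF5** — a single 4-D ``intensities`` dataset with the geometry stored in
  dataset attributes (``track_times`` disabled so identical data give
  byte-identical files);
* **multi-page TIFF** — one page per (repeat, B-scan) pair in the order
  declared by a JSON sidecar (``<path>.json``), which also carries the
  geometry.

On-disk axis order is free: ``load_volume`` takes a four-letter layout
string over ``r`` (repeat), ``b`` (B-scan), ``z`` (depth), ``a`` (A-scan)
and permutes to the canonical ``(repeat, bscan, depth, ascan)`` order.

Boundary surfaces travel as long-format CSV (``junction,bscan,ascan,
depth_px``) or an equivalent JSON document; depth positions are fractional
pixels and round-trip exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .angiography import FlowVolume
from .compositing import CompositeImage
from .geometry import CANONICAL_AXES, AcquisitionGeometry, AcquisitionVolume
from .layer_boundaries import JUNCTIONS, BoundarySet
from .slab_engine import EnFaceSlab

_H5_DATASET = "intensities"


def _layout_permutation(layout: str) -> tuple[int, ...]:
    layout = layout.lower()
    if sorted(layout) != sorted(CANONICAL_AXES):
        raise ValueError(
            f"layout must name each of '{CANONICAL_AXES}' exactly once, got {layout!r}"
        )
    return tuple(layout.index(ax) for ax in CANONICAL_AXES)


def save_volume(volume: AcquisitionVolume, path: str | Path) -> Path:
    """Write a volume as HDF5 (.h5/.hdf5) or multi-page TIFF (+ JSON sidecar)."""
    path = Path(path)
    meta = volume.geometry.to_dict()
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            ds = f.create_dataset(_H5_DATASET, data=volume.intensities, track_times=False)
            for k, v in meta.items():
                ds.attrs[k] = v
            ds.attrs["layout"] = CANONICAL_AXES
    elif path.suffix.lower() in (".tif", ".tiff"):
        nr, nb, nz, nx = volume.intensities.shape
        pages = volume.intensities.reshape(nr * nb, nz, nx)
        tifffile.imwrite(path, pages.astype(np.float32))
        sidecar = dict(meta, layout=CANONICAL_AXES, page_order="repeat_major")
        Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=1))
    else:
        raise ValueError(f"unsupported volume container {path.suffix!r}")
    return path


def load_volume(path: str | Path, layout: str = CANONICAL_AXES) -> AcquisitionVolume:
    """Read a volume and canonicalise its axes to (repeat, bscan, depth, ascan).

    ``layout`` describes the on-disk axis order for HDF5 files; TIFF stacks
    are always page-major ``(repeat*bscan, depth, ascan)`` with the split
    declared in the sidecar.  A JSON sidecar, when present, overrides any
    embedded geometry (explicit user intent wins).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sidecar_path = Path(str(path) + ".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else None

    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            ds = f[_H5_DATASET]
            arr = ds[()]
            meta = {k: ds.attrs[k] for k in ds.attrs}
        if sidecar:
            meta.update(sidecar)
        layout = str(meta.get("layout", layout))
        if arr.ndim != 4:
            raise ValueError(f"expected a 4-D dataset, got ndim={arr.ndim}")
        arr = np.transpose(arr, _layout_permutation(layout))
        geometry = AcquisitionGeometry.from_dict(_geometry_fields(meta, arr))
    elif path.suffix.lower() in (".tif", ".tiff"):
        if sidecar is None:
            raise ValueError(f"TIFF volume requires a sidecar at {sidecar_path}")
        pages = tifffile.imread(path)
        geometry = AcquisitionGeometry.from_dict(sidecar)
        nr, nb = geometry.n_repeats, geometry.n_bscans
        if pages.shape[0] != nr * nb:
            raise ValueError(
                f"TIFF has {pages.shape[0]} pages, sidecar implies {nr * nb}"
            )
        arr = pages.reshape(nr, nb, pages.shape[1], pages.shape[2])
    else:
        raise ValueError(f"unsupported volume container {path.suffix!r}")

    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path} contains non-finite voxels")
    return AcquisitionVolume(geometry=geometry, intensities=np.asarray(arr, dtype=np.float64))


def _geometry_fields(meta: dict, arr: np.ndarray) -> dict:
    out = dict(meta)
    out.setdefault("n_repeats", arr.shape[0])
    out.setdefault("n_bscans", arr.shape[1])
    out.setdefault("n_ascans", arr.shape[3])
    return out


def save_flow(flow: "FlowVolume", path: str | Path) -> Path:
    """Write a flow volume as HDF5 with geometry and provenance attributes."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("flow", data=flow.flow, track_times=False)
        for k, v in flow.geometry.to_dict().items():
            ds.attrs[k] = v
        ds.attrs["provenance"] = json.dumps(flow.provenance, sort_keys=True)
    return path


def load_flow(path: str | Path) -> "FlowVolume":
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        ds = f["flow"]
        arr = ds[()]
        meta = {k: ds.attrs[k] for k in ds.attrs if k != "provenance"}
        prov = json.loads(ds.attrs.get("provenance", "{}"))
    geometry = AcquisitionGeometry.from_dict(meta)
    return FlowVolume(geometry=geometry, flow=arr, provenance=prov)


# ---------------------------------------------------------------------------
# boundary surfaces
# ---------------------------------------------------------------------------

def save_boundaries(boundaries: BoundarySet, path: str | Path) -> Path:
    """Write junction surfaces as long-format CSV or JSON."""
    path = Path(path)
    records = []
    for junction, surf in boundaries.surfaces.items():
        nb, nx = surf.shape
        bb, aa = np.meshgrid(np.arange(nb), np.arange(nx), indexing="ij")
        records.append(pd.DataFrame({
            "junction": junction,
            "bscan": bb.ravel(),
            "ascan": aa.ravel(),
            "depth_px": surf.ravel(),
        }))
    table = pd.concat(records, ignore_index=True)
    if path.suffix.lower() == ".csv":
        table.to_csv(path, index=False, float_format="%.17g")
    elif path.suffix.lower() == ".json":
        payload = {
            j: {"shape": list(s.shape), "depth_px": s.ravel().tolist()}
            for j, s in boundaries.surfaces.items()
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unsupported boundary format {path.suffix!r}")
    return path


def load_boundaries(path: str | Path, depth_extent: int | None = None) -> BoundarySet:
    """Read junction surfaces written by :func:`save_boundaries` (lossless)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    surfaces: dict[str, np.ndarray] = {}
    if path.suffix.lower() == ".csv":
        table = pd.read_csv(path, float_precision="round_trip")
        required = {"junction", "bscan", "ascan", "depth_px"}
        if not required.issubset(table.columns):
            raise ValueError(f"boundary CSV must have columns {sorted(required)}")
        for junction, grp in table.groupby("junction", sort=False):
            if junction not in JUNCTIONS:
                raise ValueError(f"unknown junction name {junction!r}")
            nb = int(grp["bscan"].max()) + 1
            nx = int(grp["ascan"].max()) + 1
            if (grp["bscan"].min() < 0) or (grp["ascan"].min() < 0):
                raise ValueError("negative lateral index in boundary table")
            surf = np.full((nb, nx), np.nan)
            surf[grp["bscan"].to_numpy(), grp["ascan"].to_numpy()] = grp["depth_px"].to_numpy()
            if np.isnan(surf).any():
                raise ValueError(f"junction {junction!r} has missing lateral positions")
            surfaces[junction] = surf
    elif path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        for junction, entry in payload.items():
            if junction not in JUNCTIONS:
                raise ValueError(f"unknown junction name {junction!r}")
            surfaces[junction] = np.asarray(entry["depth_px"]).reshape(entry["shape"])
    else:
        raise ValueError(f"unsupported boundary format {path.suffix!r}")
    return BoundarySet(surfaces=surfaces, depth_extent=depth_extent)


# ---------------------------------------------------------------------------
# en face images
# ---------------------------------------------------------------------------

def save_enface(image, path: str | Path, bit_depth: int = 8) -> Path:
    """Quantise an en face slab or RGB composite to 8/16-bit PNG or TIFF.

    Quantisation is round-to-nearest onto ``[0, 2**bit_depth - 1]``; pixel
    values must already lie in [0, 1].
    """
    path = Path(path)
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    if isinstance(image, EnFaceSlab):
        arr = image.image
    elif isinstance(image, CompositeImage):
        arr = image.rgb
    else:
        arr = np.asarray(image, dtype=np.float64)
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError("pixel values must lie in [0, 1] before quantisation")
    arr = np.clip(arr, 0.0, 1.0)
    scale = 2 ** bit_depth - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    quant = np.floor(arr * scale + 0.5).astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, quant)
    elif path.suffix.lower() == ".png":
        if bit_depth == 16 and quant.ndim == 3:
            raise ValueError("16-bit RGB is only supported as TIFF; use .tif")
        iio.imwrite(path, quant)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")
    return path


def load_enface(path: str | Path) -> np.ndarray:
    """Read a saved en face image back to float64 in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path) if path.suffix.lower() == ".png" else tifffile.imread(path)
    info = np.iinfo(arr.dtype)
    return arr.astype(np.float64) / info.max
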