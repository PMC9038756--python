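"""Image-volume and reconstruction I/O, and the coordinate convention.

Conventions used by every module in this package:

* Arrays are indexed ``data[i, j, k]`` with axes ``(x, y, z)`` and voxel
  indices 0-based.
* Physical coordinates are voxel *centers* in micrometres:
  ``physical = origin + index * spacing`` (elementwise).
* Multi-page TIFF pages are interpreted as z-planes; in-memory arrays are
  transposed so the package-level ``(x, y, z)`` order always holds.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "read_swc",
    "write_swc",
    "voxel_to_physical",
    "physical_to_voxel",
]


def voxel_to_physical(index, spacing, origin=(0.0, 0.0, 0.0)):
    """Map voxel indices (i,j,k) to physical voxel-center coordinates in μm.

    ``index`` may be a single triple or an (N, 3) array.
    """
    index = np.asarray(index, dtype=float)
    return np.asarray(origin, dtype=float) + index * np.asarray(spacing, dtype=float)


def physical_to_voxel(point, spacing, origin=(0.0, 0.0, 0.0)):
    """Map physical μm coordinates to the nearest voxel index (rounded)."""
    point = np.asarray(point, dtype=float)
    cont = (point - np.asarray(origin, dtype=float)) / np.asarray(spacing, dtype=float)
    # floor(x + 0.5): deterministic half-up rounding, unlike banker's rounding
    return np.floor(cont + 0.5).astype(np.int64)


@dataclass
class ImageVolume:
    """A 3D scalar intensity lattice with anisotropic physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Intensities in arbitrary non-negative units (any scalar dtype).
    spacing : tuple of 3 floats
        Per-axis voxel size in μm, same (x, y, z) order as the array axes.
    origin : tuple of 3 floats
        Physical offset in μm of voxel (0, 0, 0); defaults to the origin.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 4 and 1 in self.data.shape:
            self.data = np.squeeze(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_to_physical(self, index):
        return voxel_to_physical(index, self.spacing, self.origin)

    def physical_to_voxel(self, point):
        return physical_to_voxel(point, self.spacing, self.origin)

    def contains_point(self, point) -> bool:
        idx = self.physical_to_voxel(point)
        return bool(np.all(idx >= 0) and np.all(idx < np.array(self.shape)))


@dataclass
class LabelVolume(ImageVolume):
    """Integer-labelled volume: 0 = background, k > 0 = component/fragment id."""

    def __post_init__(self):
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.allclose(self.data, np.round(self.data)):
                raise ValueError("label volume requires integer labels")
            self.data = self.data.astype(np.int32)
        if self.data.size and self.data.min() < 0:
            raise ValueError("labels must be nonnegative")


def _guess_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt.lower()
    lower = str(path).lower()
    if lower.endswith((".tif", ".tiff")):
        return "tiff"
    if lower.endswith((".zarr", ".zarr/")):
        return "zarr"
    if lower.endswith((".nrrd", ".nhdr")):
        return "nrrd"
    raise ValueError(f"cannot infer volume format from path: {path!r}")


def read_volume(path, fmt: str | None = None, spacing=None, origin=(0.0, 0.0, 0.0)) -> ImageVolume:
    """Read a 3D volume from TIFF, Zarr or NRRD.

    Spacing is taken from file metadata when present; an explicit ``spacing``
    argument overrides/supplies it (default (1,1,1) μm if neither exists).
    Intensities are preserved bit-exactly at the native dtype.
    """
    fmt = _guess_format(path, fmt)
    meta_spacing = None
    if fmt == "tiff":
        import tifffile

        if not os.path.exists(path):
            raise IOError(f"cannot read volume: no such file {path!r}")
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            try:
                md = tf.imagej_metadata or {}
                page = tf.pages[0]
                xres = page.tags.get("XResolution")
                yres = page.tags.get("YResolution")
                if xres and yres and "spacing" in md:
                    sx = xres.value[1] / xres.value[0]
                    sy = yres.value[1] / yres.value[0]
                    meta_spacing = (sx, sy, float(md["spacing"]))
            except Exception:
                meta_spacing = None
        if data.ndim == 2:
            data = data[None]
        if data.ndim != 3:
            raise ValueError(f"unsupported TIFF layout (shape {data.shape}): multi-channel data is not supported")
        data = np.ascontiguousarray(data.transpose(2, 1, 0))  # (z,y,x) pages -> (x,y,z)
    elif fmt == "zarr":
        import zarr

        if not os.path.exists(path):
            raise IOError(f"cannot read volume: no such path {path!r}")
        arr = zarr.open_array(path, mode="r")
        data = np.asarray(arr[:])
        if "spacing" in arr.attrs:
            meta_spacing = tuple(arr.attrs["spacing"])
        if data.ndim != 3:
            raise ValueError(f"unsupported zarr array (shape {data.shape})")
    elif fmt == "nrrd":
        import SimpleITK as sitk

        if not os.path.exists(path):
            raise IOError(f"cannot read volume: no such file {path!r}")
        img = sitk.ReadImage(str(path))
        if img.GetNumberOfComponentsPerPixel() != 1:
            raise ValueError("multi-channel volumes are not supported")
        data = sitk.GetArrayFromImage(img)  # (z, y, x)
        data = np.ascontiguousarray(data.transpose(2, 1, 0))
        sp = img.GetSpacing()  # already (x, y, z)
        meta_spacing = tuple(float(s) for s in sp)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected tiff, zarr or nrrd")

    if spacing is None:
        spacing = meta_spacing if meta_spacing is not None else (1.0, 1.0, 1.0)
    return ImageVolume(data=data, spacing=tuple(spacing), origin=origin)


def write_volume(volume: ImageVolume, path, fmt: str | None = None) -> None:
    """Write a volume to TIFF (ImageJ-style spacing metadata), Zarr or NRRD."""
    fmt = _guess_format(path, fmt)
    if fmt == "tiff":
        import tifffile

        pages = np.ascontiguousarray(volume.data.transpose(2, 1, 0))  # (x,y,z) -> (z,y,x)
        sx, sy, sz = volume.spacing
        tifffile.imwrite(
            path,
            pages,
            imagej=True,
            resolution=(1.0 / sx, 1.0 / sy),
            metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
        )
    elif fmt == "zarr":
        import zarr

        arr = zarr.open_array(path, mode="w", shape=volume.data.shape, dtype=volume.data.dtype)
        arr[:] = volume.data
        arr.attrs["spacing"] = list(volume.spacing)
    elif fmt == "nrrd":
        import SimpleITK as sitk

        img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
        img.SetSpacing(tuple(float(s) for s in volume.spacing))
        sitk.WriteImage(img, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_swc(polyline, path, node_type: int = 2, radius: float = 1.0) -> None:
    """Write an ordered physical-space curve as a 7-column SWC chain.

    Columns: id, type, x, y, z, radius, parent — coordinates in μm, node 1
    has parent −1 and node k has parent k−1. Type code defaults to 2 (axon).
    """
    points = np.asarray(getattr(polyline, "points", polyline), dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 1:
        raise ValueError("polyline must contain at least one 3D point")
    with open(path, "w") as fh:
        fh.write("# SWC written by axonhmm; coordinates in micrometres\n")
        fh.write("# id type x y z radius parent\n")
        for k, (x, y, z) in enumerate(points, start=1):
            parent = -1 if k == 1 else k - 1
            fh.write(f"{k} {node_type} {x:.6f} {y:.6f} {z:.6f} {radius:.6f} {parent}\n")


def read_swc(path) -> np.ndarray:
    """Read a non-branching SWC file back as an (N, 3) μm coordinate array.

    Rows are returned in node-id order; branching files are rejected.
    """
    ids, rows, parents = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            ids.append(int(parts[0]))
            rows.append([float(parts[2]), float(parts[3]), float(parts[4])])
            parents.append(int(parts[6]))
    if not rows:
        raise ValueError(f"no nodes found in SWC file {path!r}")
    nonroot = [p for p in parents if p != -1]
    if len(set(nonroot)) != len(nonroot):
        raise ValueError("branching SWC files are not supported")
    order = np.argsort(ids)
    return np.asarray(rows, dtype=float)[order]
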