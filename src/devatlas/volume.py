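"""Volumes, slice series, file I/O and resampling.

Every other module works on :class:`ImageVolume`: a dense 3-D scalar array
with per-axis voxel spacing, a world origin and a 3-letter orientation code.
The toolkit-wide convention, stated once here and relied on everywhere:

* voxel indices are 0-based and node-centered — the world coordinate of
  index ``i`` along an axis is ``origin + i * spacing``;
* the canonical internal orientation is RAS (axis 0 left→right, axis 1
  posterior→anterior, axis 2 inferior→superior); loaders reorient on entry;
* the internal length unit is mm; µm inputs are converted at load and the
  original unit tag is carried along.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

log = logging.getLogger(__name__)

_VALID_UNITS = ("mm", "um")
_AXIS_LETTERS = {"R": 0, "L": 0, "A": 1, "P": 1, "S": 2, "I": 2}


def _as_spacing(spacing) -> tuple[float, float, float]:
    s = tuple(float(x) for x in np.atleast_1d(spacing))
    if len(s) == 1:
        s = s * 3
    if len(s) != 3:
        raise ValueError(f"spacing must have 3 components, got {spacing!r}")
    if any(x <= 0 for x in s):
        raise ValueError(f"spacing must be strictly positive, got {s}")
    return s


@dataclass
class ImageVolume:
    """Dense 3-D scalar image with geometry.

    Parameters
    ----------
    data:
        3-D array; intensity or integer labels.
    spacing:
        Per-axis voxel size. Scalar broadcasts to all three axes.
    origin:
        World coordinate of voxel (0, 0, 0).
    orientation:
        3-letter axis code; canonical is ``"RAS"``.
    unit:
        ``"mm"`` (canonical) or ``"um"``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    orientation: str = "RAS"
    unit: str = "mm"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be rank 3, got rank {self.data.ndim}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(x) for x in self.origin)
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unit must be one of {_VALID_UNITS}, got {self.unit!r}")
        if len(self.orientation) != 3 or any(c not in _AXIS_LETTERS for c in self.orientation):
            raise ValueError(f"bad orientation code {self.orientation!r}")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing_arr(self) -> np.ndarray:
        return np.asarray(self.spacing, dtype=float)

    @property
    def origin_arr(self) -> np.ndarray:
        return np.asarray(self.origin, dtype=float)

    def world_extent(self) -> np.ndarray:
        """Node-centered world length spanned per axis: (n-1) * spacing."""
        return (np.asarray(self.shape) - 1) * self.spacing_arr

    def index_to_world(self, idx) -> np.ndarray:
        return self.origin_arr + np.asarray(idx, dtype=float) * self.spacing_arr

    def world_to_index(self, pt) -> np.ndarray:
        return (np.asarray(pt, dtype=float) - self.origin_arr) / self.spacing_arr

    def to_mm(self) -> "ImageVolume":
        if self.unit == "mm":
            return self
        return replace(
            self,
            spacing=tuple(s * 1e-3 for s in self.spacing),
            origin=tuple(o * 1e-3 for o in self.origin),
            unit="mm",
        )

    def same_grid(self, other: "ImageVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def copy(self, data: np.ndarray | None = None) -> "ImageVolume":
        return replace(self, data=self.data.copy() if data is None else data)


@dataclass
class SliceSeries:
    """Ordered 2-D sections with per-slice world z positions.

    ``present_mask`` flags which nominal slice indices carry data; the
    ``slices`` list holds only present slices, in order.  ``channel_of_slice``
    optionally labels each present slice (e.g. with a gene name).
    """

    slices: list[np.ndarray]
    z_positions: np.ndarray
    present_mask: np.ndarray
    channel_of_slice: list[str] | None = None
    in_plane_spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.z_positions = np.asarray(self.z_positions, dtype=float)
        self.present_mask = np.asarray(self.present_mask, dtype=bool)
        if np.any(np.diff(self.z_positions) <= 0):
            raise ValueError("z_positions must be strictly increasing")
        if len(self.slices) != int(self.present_mask.sum()):
            raise ValueError(
                f"{len(self.slices)} slices but {int(self.present_mask.sum())} present flags"
            )
        if self.channel_of_slice is not None and len(self.channel_of_slice) != len(self.slices):
            raise ValueError("channel_of_slice length must match slices")

    @property
    def n_nominal(self) -> int:
        return len(self.present_mask)

    @property
    def present_indices(self) -> np.ndarray:
        return np.flatnonzero(self.present_mask)

    @property
    def present_z(self) -> np.ndarray:
        return self.z_positions[self.present_mask]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def load_volume(path, format_hint: str | None = None, orientation: str | None = None) -> ImageVolume:
    """Read a NIfTI-1, multi-page TIFF, or zarr volume.

    TIFF and zarr stores without geometry metadata get spacing 1.0 mm and a
    logged warning; a JSON sidecar written by :func:`save_volume` restores the
    full geometry.  ``orientation`` overrides the assumed axis code for
    sources that do not record one.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    fmt = format_hint or _guess_format(path)
    if fmt == "nifti":
        vol = _load_nifti(path)
    elif fmt == "tiff":
        vol = _load_tiff(path)
    elif fmt == "zarr":
        vol = _load_zarr(path)
    else:
        raise IOError(f"cannot determine format of {path}")
    if orientation is not None:
        vol = replace(vol, orientation=orientation)
    return vol.to_mm()


def _guess_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff"
    if path.is_dir():
        return "zarr"
    raise IOError(f"unsupported file type: {path}")


def _load_nifti(path: Path) -> ImageVolume:
    import nibabel as nib

    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)  # reorient to RAS
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected rank-3 volume, got rank {data.ndim} in {path}")
    zooms = img.header.get_zooms()[:3]
    origin = img.affine[:3, 3]
    vol = ImageVolume(data, spacing=zooms, origin=tuple(origin), orientation="RAS", unit="mm")
    return _apply_sidecar(vol, path)


def _load_tiff(path: Path) -> ImageVolume:
    import tifffile

    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        raise ValueError(f"{path} is a single 2-D image, not a volume")
    if arr.ndim != 3:
        raise ValueError(f"expected rank-3 TIFF stack, got rank {arr.ndim}")
    # pages are z; transpose to (x, y, z)
    data = np.ascontiguousarray(arr.transpose(2, 1, 0))
    side = _sidecar(path)
    if not side.exists():
        log.warning("TIFF %s has no geometry metadata; assuming 1.0 mm spacing", path)
    vol = ImageVolume(data, spacing=1.0)
    return _apply_sidecar(vol, path)


def _load_zarr(path: Path) -> ImageVolume:
    import zarr

    arr = np.asarray(zarr.open_array(str(path), mode="r")[:])
    if arr.ndim != 3:
        raise ValueError(f"expected rank-3 zarr array, got rank {arr.ndim}")
    side = _sidecar(path)
    if not side.exists():
        log.warning("zarr %s has no geometry metadata; assuming 1.0 mm spacing", path)
    vol = ImageVolume(arr, spacing=1.0)
    return _apply_sidecar(vol, path)


def _apply_sidecar(vol: ImageVolume, path: Path) -> ImageVolume:
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        vol = replace(
            vol,
            spacing=tuple(meta.get("spacing", vol.spacing)),
            origin=tuple(meta.get("origin", vol.origin)),
            orientation=meta.get("orientation", vol.orientation),
            unit=meta.get("unit", vol.unit),
        )
    return vol


def save_volume(vol: ImageVolume, path) -> None:
    """Write a volume to NIfTI-1, TIFF or zarr, chosen by extension.

    NIfTI headers are always written in mm; a µm unit tag is preserved in a
    JSON sidecar so that ``load(save(v))`` round-trips geometry exactly.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"directory does not exist: {path.parent}")
    name = path.name.lower()
    mm = vol.to_mm()
    if name.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag(list(mm.spacing) + [1.0])
        affine[:3, 3] = mm.origin
        nib.save(nib.Nifti1Image(np.asarray(mm.data), affine), str(path))
    elif name.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.ascontiguousarray(mm.data.transpose(2, 1, 0)))
    elif name.endswith(".zarr"):
        import zarr

        z = zarr.open_array(str(path), mode="w", shape=mm.data.shape, dtype=mm.data.dtype)
        z[:] = mm.data
    else:
        raise ValueError(f"unsupported output extension: {path.name}")
    meta = {
        "spacing": list(vol.spacing),
        "origin": list(vol.origin),
        "orientation": vol.orientation,
        "unit": vol.unit,
    }
    _sidecar(path).write_text(json.dumps(meta))


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_ORDERS = {"nearest": 0, "linear": 1, "bspline": 3}


def resample_volume(
    vol: ImageVolume,
    target_spacing,
    interpolation: str = "linear",
) -> ImageVolume:
    """Resample onto an isotropic-or-not grid with the given voxel size.

    ``interpolation`` is one of ``nearest`` (labels; never invents values),
    ``linear``, ``bspline``, or ``sum`` — integer-factor block summation used
    for count volumes, where each coarse voxel is the sum of its fine-voxel
    block (total conserved exactly).
    """
    target = _as_spacing(target_spacing)
    if interpolation == "sum":
        factor = np.asarray(target) / vol.spacing_arr
        ifactor = np.rint(factor).astype(int)
        if not np.allclose(factor, ifactor) or np.any(ifactor < 1):
            raise ValueError("sum resampling requires integer downsampling factors")
        data = block_sum(vol.data, tuple(ifactor))
        return ImageVolume(data, spacing=target, origin=vol.origin,
                           orientation=vol.orientation, unit=vol.unit)
    if interpolation not in _ORDERS:
        raise ValueError(f"unknown interpolation {interpolation!r}")
    if np.allclose(target, vol.spacing):
        return vol.copy()

    from scipy import ndimage

    extent = vol.world_extent()
    new_shape = np.maximum(1, np.floor(extent / np.asarray(target) + 0.5).astype(int) + 1)
    idx = [np.arange(n) * target[a] / vol.spacing[a] for a, n in enumerate(new_shape)]
    grid = np.meshgrid(*idx, indexing="ij")
    order = _ORDERS[interpolation]
    data = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=float if order > 0 else vol.data.dtype),
        np.stack([g.ravel() for g in grid]),
        order=order,
        mode="nearest",
    ).reshape(tuple(new_shape))
    if order == 0:
        data = data.astype(vol.data.dtype)
    return ImageVolume(data, spacing=target, origin=vol.origin,
                       orientation=vol.orientation, unit=vol.unit)


def block_sum(data: np.ndarray, factor: Sequence[int]) -> np.ndarray:
    """Sum over non-overlapping blocks; trailing partial blocks are zero-padded."""
    factor = tuple(int(f) for f in factor)
    if any(f < 1 for f in factor):
        raise ValueError(f"factors must be >= 1, got {factor}")
    shape = data.shape
    padded = [int(np.ceil(s / f)) * f for s, f in zip(shape, factor)]
    if padded != list(shape):
        out = np.zeros(padded, dtype=np.result_type(data.dtype, np.int64)
                       if np.issubdtype(data.dtype, np.integer) else float)
        out[: shape[0], : shape[1], : shape[2]] = data
        data = out
    view = data.reshape(
        padded[0] // factor[0], factor[0],
        padded[1] // factor[1], factor[1],
        padded[2] // factor[2], factor[2],
    )
    return view.sum(axis=(1, 3, 5))
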