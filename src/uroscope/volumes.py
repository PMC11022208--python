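"""Volume and label-map containers, NIfTI I/O, and CT preprocessing.

Conventions
-----------
Arrays are indexed ``(z, y, x)``.  ``spacing`` holds the voxel size in mm
*in the same axis order as the array*, i.e. ``(sz, sy, sx)``, and ``origin``
is the physical position (mm) of the centre of voxel ``(0, 0, 0)``.  On
disk the NIfTI convention (fastest axis = x) is used; arrays are transposed
transparently on read/write so the round trip is bit exact.

Preprocessing follows the delayed-phase CT recipe used for collecting-system
segmentation: resample to an isotropic-count grid (e.g. 256^3 voxels, which
also tames highly anisotropic scans such as 0.8x0.8x5 mm), then clip
intensities to a fixed Hounsfield window (default [-256, 512] HU, bracketing
soft tissue and pooled contrast) and rescale to [0, 1].
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "LabelMap",
    "LABEL_SEMANTICS",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "resample_to_shape",
    "clip_normalize",
]

#: Canonical label roles for kidney phantoms and segmentations.
LABEL_SEMANTICS = {0: "background", 1: "kidney", 2: "collecting_system"}


def _validate_grid(data: np.ndarray, spacing, name: str) -> None:
    if data.ndim != 3:
        raise ValueError(f"{name} requires a 3D array, got ndim={data.ndim}")
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"{name} spacing must be 3 strictly positive values, got {spacing!r}")


@dataclasses.dataclass
class Volume:
    """A 3D scalar grid (CT intensities in HU, or normalized values).

    Parameters
    ----------
    data : (nz, ny, nx) ndarray
        Scalar field, finite everywhere.
    spacing : (sz, sy, sx) floats
        Voxel size in mm per array axis.
    origin : (3,) floats
        Physical coordinate (mm) of voxel (0, 0, 0), same axis order.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _validate_grid(self.data, self.spacing, type(self).__name__)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if np.issubdtype(self.data.dtype, np.floating) and not np.isfinite(self.data).all():
            raise ValueError("volume data must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def physical_extent(self) -> np.ndarray:
        """Physical size (mm) per axis: shape * spacing."""
        return np.asarray(self.shape, dtype=float) * np.asarray(self.spacing)


@dataclasses.dataclass
class LabelMap(Volume):
    """Integer grid aligned to a companion :class:`Volume`.

    Labels must be drawn from :data:`LABEL_SEMANTICS` (0=background,
    1=kidney, 2=collecting system); binary masks use {0, 1}.
    """

    label_semantics: dict[int, str] = dataclasses.field(
        default_factory=lambda: dict(LABEL_SEMANTICS)
    )

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.issubdtype(self.data.dtype, np.bool_):
                self.data = self.data.astype(np.uint8)
            else:
                rounded = np.rint(self.data)
                if not np.array_equal(rounded, self.data):
                    raise ValueError("label map requires integer values")
                self.data = rounded.astype(np.int32)
        super().__post_init__()
        present = np.unique(self.data)
        unknown = set(int(v) for v in present) - set(self.label_semantics)
        if unknown:
            raise ValueError(f"labels {sorted(unknown)} not in declared semantics "
                             f"{sorted(self.label_semantics)}")


def _affine(spacing, origin) -> np.ndarray:
    # spacing/origin are (z, y, x); NIfTI affine columns are (x, y, z).
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing[2], spacing[1], spacing[0]
    aff[:3, 3] = origin[::-1]
    return aff


def write_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume (or label map) to NIfTI (.nii / .nii.gz)."""
    path = Path(path)
    if path.suffix not in {".nii", ".gz"}:
        raise ValueError(f"expected .nii or .nii.gz, got {path.name!r}")
    data = vol.data
    if data.dtype == np.int64:  # NIfTI-1 has no 64-bit integer type
        data = data.astype(np.int32)
    img = nib.Nifti1Image(np.transpose(data, (2, 1, 0)), _affine(vol.spacing, vol.origin))
    img.header.set_data_dtype(data.dtype)
    nib.save(img, str(path))


write_labelmap = write_volume


def _load(path: str | Path):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume file: {path}")
    img = nib.load(str(path))
    arr = np.asanyarray(img.dataobj)
    if arr.ndim == 4 and arr.shape[3] == 1:
        arr = arr[..., 0]
    if arr.ndim != 3:
        raise ValueError(f"{path.name}: expected a 3D image, got shape {arr.shape}")
    zooms = img.header.get_zooms()[:3]  # (x, y, z)
    spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    origin = tuple(float(v) for v in img.affine[:3, 3][::-1])
    return np.transpose(arr, (2, 1, 0)), spacing, origin


def read_volume(path: str | Path) -> Volume:
    """Read a NIfTI file as a :class:`Volume`."""
    data, spacing, origin = _load(path)
    return Volume(data, spacing, origin)


def read_labelmap(path: str | Path) -> LabelMap:
    """Read a NIfTI file as a :class:`LabelMap` (integer-valued)."""
    data, spacing, origin = _load(path)
    return LabelMap(data, spacing, origin)


def resample_to_shape(vol: Volume, target_shape: tuple[int, int, int]) -> Volume:
    """Resample a volume to a fixed voxel-count grid, preserving physical extent.

    Output spacing is ``input extent / target_shape`` per axis (corner-aligned
    grids; voxel centres at ``(i + 0.5) * spacing``).  Intensities are
    interpolated trilinearly; :class:`LabelMap` inputs use nearest-neighbour
    so label semantics are preserved.
    """
    target_shape = tuple(int(n) for n in target_shape)
    if len(target_shape) != 3 or any(n < 2 for n in target_shape):
        raise ValueError(f"target_shape must be 3 ints >= 2, got {target_shape!r}")
    is_labels = isinstance(vol, LabelMap)
    old_shape = np.asarray(vol.shape, dtype=float)
    new_shape = np.asarray(target_shape, dtype=float)
    scale = old_shape / new_shape
    new_spacing = tuple(np.asarray(vol.spacing) * scale)
    # Map output voxel-centre j to input index space: (j + .5) * scale - .5
    coords = np.meshgrid(
        *[(np.arange(n) + 0.5) * s - 0.5 for n, s in zip(target_shape, scale)],
        indexing="ij",
    )
    order = 0 if is_labels else 1
    out = ndimage.map_coordinates(
        vol.data.astype(vol.data.dtype if is_labels else np.float64),
        np.stack(coords), order=order, mode="nearest",
    )
    # Voxel-centre origin shifts so the physical corner stays put.
    new_origin = tuple(
        o + 0.5 * (ns - s) for o, s, ns in zip(vol.origin, vol.spacing, new_spacing)
    )
    if is_labels:
        return LabelMap(out, new_spacing, new_origin, dict(vol.label_semantics))
    return Volume(out, new_spacing, new_origin)


def clip_normalize(vol: Volume, lo: float = -256.0, hi: float = 512.0) -> Volume:
    """Clip intensities to ``[lo, hi]`` HU and rescale to ``[0, 1]``.

    ``v -> (clamp(v, lo, hi) - lo) / (hi - lo)``; the default window
    [-256, 512] HU brackets soft tissue and pooled urographic contrast.
    """
    if lo >= hi:
        raise ValueError(f"clip window requires lo < hi, got [{lo}, {hi}]")
    out = (np.clip(vol.data.astype(np.float64), lo, hi) - lo) / (hi - lo)
    return Volume(out, vol.spacing, vol.origin)
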