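"""Volume data model, world-coordinate geometry, and NIfTI/MetaImage I/O.

Grids are axis-aligned: a voxel index ``(i, j, k)`` maps to the world point
``origin + index * spacing`` (mm).  Oblique direction matrices are out of
scope; files carrying a non-identity direction are rejected.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

__all__ = [
    "ImageVolume",
    "LabelVolume",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "match_fov",
    "FormatError",
]

#: Pad value used for CT volumes (air on the Hounsfield scale).
CT_PAD_HU = -1000.0
#: Pad value for PET / other modalities.
DEFAULT_PAD = 0.0

_MODALITIES = ("CT", "PET", "OTHER")


class FormatError(ValueError):
    """Unreadable file or unsupported image format."""


def _as_tuple3(x, name: str) -> tuple[float, float, float]:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValueError(f"{name} must have 3 components, got {arr.size}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass
class ImageVolume:
    """A 3-D scalar image on a regular axis-aligned grid.

    Parameters
    ----------
    data : ndarray, shape (ni, nj, nk)
        Scalar intensities, indexed ``(i, j, k)``.
    spacing : 3-tuple of float
        Per-axis voxel size in mm, all strictly positive.
    origin : 3-tuple of float
        World position (mm) of the centre of voxel ``(0, 0, 0)``.
    modality : {"CT", "PET", "OTHER"}
        Governs the out-of-field pad value (CT: -1000 HU, else 0).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    modality: str = "OTHER"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3-D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every axis must have length >= 1")
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_tuple3(self.origin, "origin")
        if self.modality not in _MODALITIES:
            raise ValueError(f"modality must be one of {_MODALITIES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def pad_value(self) -> float:
        return CT_PAD_HU if self.modality == "CT" else DEFAULT_PAD

    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """World-space bounding box (voxel-edge to voxel-edge), each endpoint in mm."""
        sp = np.asarray(self.spacing)
        lo = np.asarray(self.origin) - 0.5 * sp
        hi = lo + np.asarray(self.shape) * sp
        return lo, hi

    def same_grid(self, other: "ImageVolume | LabelVolume", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )

    def with_data(self, data: np.ndarray, modality: str | None = None) -> "ImageVolume":
        return ImageVolume(data, self.spacing, self.origin, modality or self.modality)


@dataclass
class LabelVolume:
    """A 3-D integer label map with a region table.

    Labels are exclusive (one ID per voxel); 0 is background.  Every nonzero
    value present in ``data`` must appear in ``region_table``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    region_table: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label data must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            if np.any(self.data != np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int32)
        self.spacing = _as_tuple3(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")
        self.origin = _as_tuple3(self.origin, "origin")
        present = set(int(v) for v in np.unique(self.data)) - {0}
        if not self.region_table:
            self.region_table = {v: f"region_{v}" for v in sorted(present)}
        missing = present - set(self.region_table)
        if missing:
            raise ValueError(f"labels present but not in region_table: {sorted(missing)}")

    shape = ImageVolume.shape
    voxel_volume_mm3 = ImageVolume.voxel_volume_mm3
    extent = ImageVolume.extent
    same_grid = ImageVolume.same_grid

    def id_of(self, region: str) -> int:
        for rid, name in self.region_table.items():
            if name == region:
                return rid
        raise KeyError(f"unknown region {region!r}")

    def mask(self, region: str | int) -> np.ndarray:
        rid = region if isinstance(region, int) else self.id_of(region)
        return self.data == rid


# ---------------------------------------------------------------------------
# Geometry

def voxel_to_world(volume, index) -> np.ndarray:
    """Map (fractional) voxel indices to world mm: ``origin + index * spacing``.

    ``index`` may be a single triple or an (N, 3) array; indices outside the
    grid are mapped by the same affine rule.
    """
    idx = np.asarray(index, dtype=float)
    return np.asarray(volume.origin) + idx * np.asarray(volume.spacing)


def world_to_voxel(volume, point) -> np.ndarray:
    """Inverse of :func:`voxel_to_world` (exact for positive spacing)."""
    pt = np.asarray(point, dtype=float)
    return (pt - np.asarray(volume.origin)) / np.asarray(volume.spacing)


# ---------------------------------------------------------------------------
# I/O

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mhd", ".mha")


def _check_ext(path: str) -> None:
    p = path.lower()
    if not (p.endswith(_NIFTI_EXT) or p.endswith(_META_EXT)):
        raise FormatError(
            f"unsupported format for {path!r}; expected .nii/.nii.gz/.mhd/.mha"
        )


def _sidecar_path(path: str) -> str:
    p = path
    for ext in (".nii.gz", ".nii", ".mhd", ".mha"):
        if p.lower().endswith(ext):
            return p[: -len(ext)] + ".labels.txt"
    return p + ".labels.txt"


def read_volume(path: str, as_labels: bool = False, modality: str = "OTHER"):
    """Read a NIfTI or MetaImage volume.

    With ``as_labels`` the data are validated as integers and a
    :class:`LabelVolume` is returned; region names come from a ``.labels.txt``
    sidecar when present, else default to ``region_<id>``.
    """
    _check_ext(path)
    if not os.path.exists(path):
        raise FormatError(f"file not found: {path}")
    try:
        img = sitk.ReadImage(path)
    except Exception as exc:  # pragma: no cover - backend-specific message
        raise FormatError(f"unreadable image {path!r}: {exc}") from exc
    if img.GetDimension() != 3:
        raise FormatError(f"expected a 3-D volume, got {img.GetDimension()}-D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise FormatError("oblique/non-identity direction matrices are not supported")
    # SimpleITK arrays come back indexed (z, y, x); transpose to (i, j, k) = (x, y, z).
    data = sitk.GetArrayFromImage(img).T
    spacing = tuple(float(s) for s in img.GetSpacing())
    origin = tuple(float(o) for o in img.GetOrigin())
    if as_labels:
        if not np.issubdtype(data.dtype, np.integer) and np.any(data != np.round(data)):
            raise ValueError(f"{path!r}: non-integer data cannot be read as labels")
        table = _read_sidecar(_sidecar_path(path))
        return LabelVolume(data.astype(np.int32), spacing, origin, table)
    return ImageVolume(np.asarray(data, dtype=np.float64), spacing, origin, modality)


def write_volume(volume, path: str) -> str:
    """Write a volume to NIfTI or MetaImage; returns the path.

    Label volumes are written with an unsigned-integer dtype plus a
    ``.labels.txt`` sidecar mapping ``id: name``.
    """
    _check_ext(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    is_labels = isinstance(volume, LabelVolume)
    data = volume.data.astype(np.uint16 if is_labels else np.float64)
    img = sitk.GetImageFromArray(data.T)
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, path)
    if is_labels:
        _write_sidecar(_sidecar_path(path), volume.region_table)
    return path


def _read_sidecar(path: str) -> dict[int, str]:
    table: dict[int, str] = {}
    if os.path.exists(path):
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, name = line.partition(":")
                table[int(key)] = name.strip()
    return table


def _write_sidecar(path: str, table: dict[int, str]) -> None:
    with open(path, "w") as fh:
        for rid in sorted(table):
            fh.write(f"{rid}: {table[rid]}\n")


# ---------------------------------------------------------------------------
# Field-of-view matching

def match_fov(reference: ImageVolume, subject):
    """Crop/zero-pad ``subject`` so its world extent matches ``reference``.

    Spacing is unchanged; the subject grid is shifted by whole voxels only, so
    the output extent matches the reference extent to within one voxel per
    axis.  Pad values: CT -1000 HU, labels 0, PET/other 0.
    """
    ref_lo, ref_hi = reference.extent()
    sub_lo, sub_hi = subject.extent()
    if np.any(ref_lo >= sub_hi) or np.any(ref_hi <= sub_lo):
        raise ValueError("subject and reference extents do not overlap")
    sp = np.asarray(subject.spacing)
    start = np.round((ref_lo - sub_lo) / sp).astype(int)
    n_new = np.maximum(1, np.round((ref_hi - ref_lo) / sp).astype(int))
    if np.array_equal(start, [0, 0, 0]) and tuple(n_new) == subject.shape:
        return subject

    pad = 0 if isinstance(subject, LabelVolume) else subject.pad_value
    out = np.full(tuple(n_new), pad, dtype=subject.data.dtype)
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(start + n_new, subject.shape)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    if np.any(src_hi <= src_lo):
        raise ValueError("no voxel overlap between subject and reference extents")
    out[dst_lo[0]:dst_hi[0], dst_lo[1]:dst_hi[1], dst_lo[2]:dst_hi[2]] = subject.data[
        src_lo[0]:src_hi[0], src_lo[1]:src_hi[1], src_lo[2]:src_hi[2]
    ]
    new_origin = tuple(np.asarray(subject.origin) + start * sp)
    if isinstance(subject, LabelVolume):
        return LabelVolume(out, subject.spacing, new_origin, dict(subject.region_table))
    return ImageVolume(out, subject.spacing, new_origin, subject.modality)
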