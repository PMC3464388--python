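"""Spatial transform models and resampling.

Transforms map *fixed-space* world points (mm) into *moving-space* world
points — the standard backward-resampling convention: to warp a moving image
onto the fixed grid, each fixed voxel centre is pushed through the transform
and the moving image is interpolated there.

Models
------
* :class:`AffineTransform` — 12-parameter (translation, rotation, scale,
  shear) linear map about a centre point.
* :class:`BSplineTransform` — cubic B-spline free-form deformation on a
  regular control-point lattice; identity outside the lattice support.
* :class:`CompositeTransform` — ordered composition, applied first-to-last.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

from .volumes import ImageVolume, LabelVolume, world_to_voxel

__all__ = [
    "AffineTransform",
    "BSplineTransform",
    "CompositeTransform",
    "affine_matrix",
    "cubic_bspline_weight",
    "displacement_at",
    "apply_point",
    "resample",
    "resample_labels",
    "write_transform",
    "read_transform",
    "invert_points",
    "TransformParseError",
]


class TransformParseError(ValueError):
    """Malformed transform parameter file."""


# ---------------------------------------------------------------------------
# Affine

@dataclass
class AffineTransform:
    """12-DOF affine map: 3 translations (mm), 3 rotations (rad, applied as
    Rz*Ry*Rx), 3 scales, 3 shears (xy, xz, yz), about ``center`` (world mm)."""

    translation: tuple = (0.0, 0.0, 0.0)
    rotation: tuple = (0.0, 0.0, 0.0)
    scale: tuple = (1.0, 1.0, 1.0)
    shear: tuple = (0.0, 0.0, 0.0)
    center: tuple = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        for name in ("translation", "rotation", "scale", "shear", "center"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            setattr(self, name, tuple(v))
        if any(s <= 0 for s in self.scale):
            raise ValueError(f"scale factors must be strictly positive: {self.scale}")

    @property
    def params(self) -> np.ndarray:
        """Flat 12-vector (translation, rotation, scale, shear)."""
        return np.concatenate([self.translation, self.rotation, self.scale, self.shear])

    @classmethod
    def from_params(cls, theta, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        t = np.asarray(theta, dtype=float).reshape(12)
        return cls(tuple(t[0:3]), tuple(t[3:6]), tuple(t[6:9]), tuple(t[9:12]), tuple(center))

    def matrix(self) -> np.ndarray:
        return affine_matrix(self)

    @classmethod
    def from_matrix(cls, m: np.ndarray, center=(0.0, 0.0, 0.0)) -> "AffineTransform":
        """Decompose a homogeneous 4x4 map into canonical 12 parameters.

        Uses A = R*K with K = chol(A^T A)^T upper-triangular (positive
        diagonal), so scale = diag(K), shear from K's off-diagonal, and Euler
        angles extracted from R in the Rz*Ry*Rx convention.  Requires
        det(A) > 0.
        """
        m = np.asarray(m, dtype=float)
        a = m[:3, :3]
        if np.linalg.det(a) <= 0:
            raise ValueError("cannot decompose a matrix with non-positive determinant")
        k = np.linalg.cholesky(a.T @ a).T  # upper triangular, positive diag
        r = a @ np.linalg.inv(k)
        sx, sy, sz = np.diag(k)
        shear = (k[0, 1] / sy, k[0, 2] / sz, k[1, 2] / sz)
        ry = -np.arcsin(np.clip(r[2, 0], -1.0, 1.0))
        if abs(np.cos(ry)) > 1e-9:
            rx = np.arctan2(r[2, 1], r[2, 2])
            rz = np.arctan2(r[1, 0], r[0, 0])
        else:  # gimbal lock
            rx = np.arctan2(-r[1, 2], r[1, 1])
            rz = 0.0
        c = np.asarray(center, dtype=float)
        # m(x) = a x + offset ; with this centre the translation parameter is
        # offset - c + a c.
        translation = m[:3, 3] - c + a @ c
        return cls(tuple(translation), (rx, ry, rz), (sx, sy, sz), shear, tuple(c))

    def inverted(self) -> "AffineTransform":
        return AffineTransform.from_matrix(np.linalg.inv(self.matrix()), self.center)


def _rot_zyx(angles) -> np.ndarray:
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def affine_matrix(t: AffineTransform) -> np.ndarray:
    """Homogeneous 4x4 matrix: translate(center) . R . Shear . Scale .
    translate(-center), plus the translation vector."""
    r = _rot_zyx(t.rotation)
    sh = np.array(
        [[1.0, t.shear[0], t.shear[1]], [0.0, 1.0, t.shear[2]], [0.0, 0.0, 1.0]]
    )
    sc = np.diag(t.scale)
    a = r @ sh @ sc
    c = np.asarray(t.center)
    m = np.eye(4)
    m[:3, :3] = a
    m[:3, 3] = np.asarray(t.translation) + c - a @ c
    if abs(np.linalg.det(a)) < 1e-15:
        raise ValueError("affine matrix is singular")
    return m


# ---------------------------------------------------------------------------
# Cubic B-spline FFD

def cubic_bspline_weight(u):
    """The cubic B-spline kernel beta^3(u): 2/3 at 0, 1/6 at +-1, 0 for |u|>=2."""
    u = np.abs(np.asarray(u, dtype=float))
    out = np.zeros_like(u)
    near = u < 1.0
    mid = (u >= 1.0) & (u < 2.0)
    out[near] = 2.0 / 3.0 - u[near] ** 2 + 0.5 * u[near] ** 3
    out[mid] = (2.0 - u[mid]) ** 3 / 6.0
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BSplineTransform:
    """Free-form deformation: displacement (mm) interpolated from a regular
    control-point lattice with tensor-product cubic B-splines.

    ``coefficients`` has shape (nx, ny, nz, 3); control point ``(l, m, n)``
    sits at ``grid_origin + (l, m, n) * grid_spacing`` in world mm.  The
    lattice should include a one-point border beyond the image domain for
    full cubic support; displacement decays to zero off-lattice (identity).
    """

    grid_origin: tuple
    grid_spacing: tuple
    coefficients: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.grid_origin = tuple(np.asarray(self.grid_origin, dtype=float).reshape(3))
        self.grid_spacing = tuple(np.asarray(self.grid_spacing, dtype=float).reshape(3))
        if any(s <= 0 for s in self.grid_spacing):
            raise ValueError("grid_spacing must be strictly positive")
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if self.coefficients.ndim != 4 or self.coefficients.shape[3] != 3:
            raise ValueError("coefficients must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("coefficients must be finite")

    def lattice_coords(self, points: np.ndarray) -> np.ndarray:
        """Continuous lattice indices of world points, shape (N, 3)."""
        return (np.asarray(points, dtype=float) - self.grid_origin) / self.grid_spacing


def displacement_at(t: BSplineTransform, points) -> np.ndarray:
    """Displacement vectors (mm) at world points; (N, 3) in -> (N, 3) out.

    Evaluates sum_l beta^3(u - l) c_l per component.  Implemented with
    ``map_coordinates(order=3, prefilter=False)``, which performs exactly this
    tensor-product sum treating the array as spline coefficients; coefficients
    beyond the lattice are zero, so the field decays smoothly to identity
    off-grid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    u = t.lattice_coords(pts).T  # (3, N)
    out = np.empty((pts.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            t.coefficients[..., c], u, order=3, prefilter=False,
            mode="grid-constant", cval=0.0,
        )
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


@dataclass
class CompositeTransform:
    """Ordered composition, applied first-to-last (fixed -> moving)."""

    transforms: list

    def __post_init__(self) -> None:
        self.transforms = list(self.transforms)
        if not self.transforms:
            raise ValueError("composite transform must contain at least one transform")


def apply_point(t, points) -> np.ndarray:
    """Map fixed-space world points (mm) through a transform.

    Accepts a single 3-vector or an (N, 3) array; returns the same shape.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(t, AffineTransform):
        m = t.matrix()
        out = pts @ m[:3, :3].T + m[:3, 3]
    elif isinstance(t, BSplineTransform):
        out = pts + displacement_at(t, pts)
    elif isinstance(t, CompositeTransform):
        out = pts
        for sub in t.transforms:
            out = apply_point(sub, out)
        out = np.atleast_2d(out)
    else:
        raise TypeError(f"unsupported transform type {type(t).__name__}")
    if np.asarray(points).ndim == 1:
        return out[0]
    return out


def invert_points(t, points, n_iter: int = 30, tol: float = 1e-9) -> np.ndarray:
    """Numerically solve ``t(x) = y`` for each y in ``points``.

    Damped fixed-point iteration, preconditioned by the exact inverse of the
    leading affine when the transform is (or starts with) one.  Intended for
    small, non-folding deformations (e.g. phantom ground-truth warps).
    """
    y = np.atleast_2d(np.asarray(points, dtype=float))
    if isinstance(t, AffineTransform):
        out = apply_point(t.inverted(), y)
        return out if np.asarray(points).ndim > 1 else np.atleast_2d(out)[0]
    pre = None
    if isinstance(t, CompositeTransform) and isinstance(t.transforms[0], AffineTransform):
        pre = t.transforms[0].inverted()
    x = apply_point(pre, y) if pre is not None else y.copy()
    x = np.atleast_2d(x)
    for _ in range(n_iter):
        resid = apply_point(t, x) - y
        x = x - 0.8 * resid
        if np.max(np.abs(resid)) < tol:
            break
    if np.asarray(points).ndim == 1:
        return x[0]
    return x


# ---------------------------------------------------------------------------
# Resampling

def _transform_grid_points(t, reference) -> np.ndarray:
    """World coordinates of every reference voxel centre pushed through t,
    returned as an (N, 3) array in C order of the reference grid."""
    shape = reference.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1).astype(float)
    world = np.asarray(reference.origin) + idx * np.asarray(reference.spacing)
    if t is None:
        return world
    return apply_point(t, world)


def resample(moving: ImageVolume, t, reference, order: int = 3,
             cval: float | None = None) -> ImageVolume:
    """Warp ``moving`` onto the ``reference`` grid by backward mapping.

    For each reference voxel centre x the output value is the moving image
    interpolated at ``t(x)``; ``order`` 0/1/3 selects nearest, trilinear, or
    prefiltered cubic B-spline interpolation (cubic genuinely interpolates the
    samples).  Out-of-domain values take ``cval`` (default: the moving
    image's modality pad: CT -1000 HU, else 0).
    """
    if order not in (0, 1, 3):
        raise ValueError(f"order must be 0, 1 or 3, got {order}")
    if cval is None:
        cval = moving.pad_value
    pts = _transform_grid_points(t, reference)
    coords = world_to_voxel(moving, pts).T  # (3, N)
    vals = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), coords, order=order,
        mode="grid-constant", cval=cval, prefilter=(order > 1),
    )
    return ImageVolume(
        vals.reshape(reference.shape), reference.spacing, reference.origin,
        moving.modality,
    )


def resample_labels(moving: LabelVolume, t, reference) -> LabelVolume:
    """Nearest-neighbour backward mapping of a label map; background 0 outside."""
    pts = _transform_grid_points(t, reference)
    coords = world_to_voxel(moving, pts).T
    vals = ndimage.map_coordinates(
        moving.data, coords, order=0, mode="grid-constant", cval=0, prefilter=False,
    )
    return LabelVolume(
        vals.reshape(reference.shape).astype(moving.data.dtype),
        reference.spacing, reference.origin, dict(moving.region_table),
    )


# ---------------------------------------------------------------------------
# ASCII transform files
#
# Format: one "[type]" section header per transform, then "key = v1 v2 ..."
# lines; a composite is the ordered concatenation of sections.  B-spline
# coefficients are stored in an accompanying MetaImage vector volume
# referenced by (relative) path.

_FMT = "%.17g"  # full float64 precision (comfortably beyond 12 significant digits)


def _fmt_vec(v) -> str:
    return " ".join(_FMT % x for x in np.asarray(v, dtype=float).reshape(-1))


def write_transform(t, path: str) -> str:
    """Write a transform to an ASCII parameter file (12-significant-digit
    round trip); B-spline coefficient lattices go to a sibling ``.coeff.mhd``
    vector volume."""
    lines: list[str] = []
    coeff_count = [0]

    def emit(tr):
        if isinstance(tr, CompositeTransform):
            for sub in tr.transforms:
                emit(sub)
        elif isinstance(tr, AffineTransform):
            lines.append("[affine]")
            for key in ("translation", "rotation", "scale", "shear", "center"):
                lines.append(f"{key} = {_fmt_vec(getattr(tr, key))}")
        elif isinstance(tr, BSplineTransform):
            coeff_count[0] += 1
            base = os.path.basename(path)
            stem = base.rsplit(".", 1)[0]
            coeff_name = f"{stem}.coeff{coeff_count[0]}.mhd"
            img = sitk.GetImageFromArray(
                np.ascontiguousarray(tr.coefficients.transpose(2, 1, 0, 3)),
                isVector=True,
            )
            img.SetSpacing(tr.grid_spacing)
            img.SetOrigin(tr.grid_origin)
            sitk.WriteImage(img, os.path.join(os.path.dirname(path) or ".", coeff_name))
            lines.append("[bspline]")
            lines.append(f"grid_origin = {_fmt_vec(tr.grid_origin)}")
            lines.append(f"grid_spacing = {_fmt_vec(tr.grid_spacing)}")
            lines.append(f"grid_shape = {' '.join(str(n) for n in tr.coefficients.shape[:3])}")
            lines.append(f"coefficients = {coeff_name}")
        else:
            raise TypeError(f"cannot serialize transform type {type(tr).__name__}")

    emit(t)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def read_transform(path: str):
    """Read a transform parameter file written by :func:`write_transform`.

    A file with a single section returns that transform; multiple sections
    return a :class:`CompositeTransform` in file order.
    """
    if not os.path.exists(path):
        raise TransformParseError(f"transform file not found: {path}")
    sections: list[tuple[str, dict]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("[") and line.endswith("]"):
                sections.append((line[1:-1], {}))
            elif "=" in line:
                if not sections:
                    raise TransformParseError(f"{path}:{lineno}: key before any section")
                key, _, val = line.partition("=")
                sections[-1][1][key.strip()] = val.strip()
            else:
                raise TransformParseError(f"{path}:{lineno}: unparseable line {line!r}")
    if not sections:
        raise TransformParseError(f"{path}: no transform sections found")

    out = []
    for kind, kv in sections:
        try:
            if kind == "affine":
                out.append(AffineTransform(
                    tuple(float(x) for x in kv["translation"].split()),
                    tuple(float(x) for x in kv["rotation"].split()),
                    tuple(float(x) for x in kv["scale"].split()),
                    tuple(float(x) for x in kv["shear"].split()),
                    tuple(float(x) for x in kv["center"].split()),
                ))
            elif kind == "bspline":
                shape = tuple(int(x) for x in kv["grid_shape"].split())
                coeff_path = os.path.join(os.path.dirname(path) or ".", kv["coefficients"])
                img = sitk.ReadImage(coeff_path)
                arr = sitk.GetArrayFromImage(img)  # (nz, ny, nx, 3)
                coeff = np.asarray(arr, dtype=float).transpose(2, 1, 0, 3)
                if coeff.shape[:3] != shape:
                    raise TransformParseError(
                        f"{coeff_path}: lattice shape {coeff.shape[:3]} != header {shape}")
                out.append(BSplineTransform(
                    tuple(float(x) for x in kv["grid_origin"].split()),
                    tuple(float(x) for x in kv["grid_spacing"].split()),
                    coeff,
                ))
            else:
                raise TransformParseError(f"{path}: unknown section [{kind}]")
        except (KeyError, ValueError) as exc:
            raise TransformParseError(f"{path}: bad [{kind}] section: {exc}") from exc
    return out[0] if len(out) == 1 else CompositeTransform(out)
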