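"""Synthetic mouse phantom generation.

Builds co-registered CT/PET/label studies with known ground truth, standing
in for a Digimouse-like atlas and Moby-like subject simulations.  The body is
a smooth superellipsoidal tube (quartic taper along the cephalad-caudad axis,
elliptical cross-section) whose cross-section is sized so the whole-body
volume equals the sum of the organ volume targets.  Organs are ellipsoids (or
paired ellipsoids, or cylinder unions for the skeleton) at fixed anatomical
stations, each scaled analytically to its target volume; labels are painted
exclusively, later-listed organs winning where shapes would overlap.

Subjects are generated by warping the atlas through a known random transform
(small 12-DOF affine composed with a bounded cubic B-spline displacement) and
re-painting CT/PET from the warped label map with per-subject activity draws
and fresh noise — so every subject carries an exact ground-truth transform
and exact ground-truth activity concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    apply_point,
    displacement_at,
)
from .volumes import ImageVolume, LabelVolume

__all__ = [
    "OrganSpec",
    "PhantomSpec",
    "PhantomStudy",
    "default_phantom_spec",
    "generate_atlas_phantom",
    "sample_subject",
    "region_activity_truth",
    "GenerationError",
]


class GenerationError(RuntimeError):
    """Phantom could not be generated under the requested constraints."""


@dataclass
class OrganSpec:
    """One organ: target volume (ml), CT intensity (HU), and the normal
    distribution of its PET activity concentration across subjects."""

    name: str
    target_volume_ml: float
    ct_hu: float
    activity_mean: float
    activity_sd: float

    def __post_init__(self) -> None:
        if self.target_volume_ml <= 0:
            raise ValueError(f"{self.name}: target_volume_ml must be > 0")
        if self.activity_mean < 0 or self.activity_sd < 0:
            raise ValueError(f"{self.name}: activity mean/sd must be >= 0")


@dataclass
class PhantomSpec:
    """Phantom study conditions.

    ``length_mm``/``ventral_dorsal_mm``/``lateral_mm`` are bounding body
    dimensions of the animal; the trunk tube's elliptical cross-section is
    derived from the total volume target (sum of organ targets) with the
    ventral-dorsal : lateral aspect ratio, since the bounding box of a real
    mouse (limbs included) is larger than its trunk.
    """

    length_mm: float = 92.640
    ventral_dorsal_mm: float = 25.310
    lateral_mm: float = 32.120
    spacing_mm: float = 0.4
    margin_mm: float = 3.2
    ct_noise_hu: float = 20.0
    pet_noise_frac: float = 0.10
    background_hu: float = -1000.0
    organs: list = field(default_factory=list)
    tumour_volume_ml: float = 0.0  # optional surface xenograft analogue, off by default

    def __post_init__(self) -> None:
        if not self.organs:
            self.organs = _default_organs()
        names = [o.name for o in self.organs]
        if len(names) != len(set(names)):
            raise ValueError("duplicate organ names in spec")

    @property
    def total_volume_ml(self) -> float:
        return sum(o.target_volume_ml for o in self.organs)

    def organ(self, name: str) -> OrganSpec:
        for o in self.organs:
            if o.name == name:
                return o
        raise KeyError(f"no organ named {name!r}")


def _default_organs() -> list[OrganSpec]:
    # Volume targets (ml): experimental-group means.  HU palette gives
    # bone/lung/soft-tissue contrast comparable to real mouse CT.  Activity
    # means (arbitrary concentration units) are a plausible FDG-like
    # biodistribution: hottest in bladder, then kidneys, cold lungs.
    return [
        OrganSpec("brain", 0.344, 35.0, 2.5, 0.40),
        OrganSpec("lungs", 0.380, -500.0, 1.0, 0.20),
        OrganSpec("heart", 0.267, 45.0, 3.0, 0.50),
        OrganSpec("kidneys", 0.291, 45.0, 6.0, 1.00),
        OrganSpec("bladder", 0.172, 10.0, 18.0, 3.00),
        OrganSpec("skeleton", 1.697, 700.0, 1.2, 0.20),
        OrganSpec("remaining", 17.843, 40.0, 1.8, 0.30),
    ]


@dataclass
class PhantomStudy:
    """A co-registered CT/PET/label triple plus ground truth.

    ``truth_transform`` maps atlas (fixed) world points to subject (moving)
    world points; absent (None) for the atlas itself.  ``truth_activities``
    records the activity concentration painted into each organ.
    """

    ct: ImageVolume
    pet: ImageVolume
    labels: LabelVolume
    truth_transform: object = None
    truth_activities: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.ct.same_grid(self.pet) and self.ct.same_grid(self.labels)):
            raise ValueError("ct, pet and labels must share one grid")


def default_phantom_spec(spacing_mm: float = 0.4) -> PhantomSpec:
    return PhantomSpec(spacing_mm=spacing_mm)


# ---------------------------------------------------------------------------
# Geometry helpers (mm, body frame: x cephalad->caudad, y ventral-dorsal,
# z lateral; origin at the head end on the tube axis)

def _grid(spec: PhantomSpec):
    sp = spec.spacing_mm
    m = spec.margin_mm
    ry, rz = _cross_section(spec)
    nx = int(np.ceil((spec.length_mm + 2 * m) / sp))
    ny = int(np.ceil((2 * ry + 2 * m) / sp))
    nz = int(np.ceil((2 * rz + 2 * m) / sp))
    origin = (-m + sp / 2.0, -(ry + m) + sp / 2.0, -(rz + m) + sp / 2.0)
    return (nx, ny, nz), origin


def _cross_section(spec: PhantomSpec) -> tuple[float, float]:
    """Semi-axes (ry, rz) of the trunk cross-section, from the total volume.

    V = pi * ry * rz * (L/2) * Int_{-1}^{1} (1 - u^4) du = 1.6 pi ry rz L/2.
    """
    total_mm3 = spec.total_volume_ml * 1000.0
    aspect = spec.ventral_dorsal_mm / spec.lateral_mm
    prod = total_mm3 / (np.pi * (spec.length_mm / 2.0) * 1.6)
    rz = float(np.sqrt(prod / aspect))
    return rz * aspect, rz


def _world_axes(shape, origin, sp):
    x = origin[0] + sp * np.arange(shape[0])
    y = origin[1] + sp * np.arange(shape[1])
    z = origin[2] + sp * np.arange(shape[2])
    return np.meshgrid(x, y, z, indexing="ij", sparse=True)


def _body_mask(spec, xx, yy, zz) -> np.ndarray:
    ry, rz = _cross_section(spec)
    u = 2.0 * (xx - spec.length_mm / 2.0) / spec.length_mm
    return u ** 4 + (yy / ry) ** 2 + (zz / rz) ** 2 <= 1.0


def _ellipsoid(xx, yy, zz, center, semi) -> np.ndarray:
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _rod(xx, yy, zz, p0, p1, radius) -> np.ndarray:
    """Capsule-free cylinder: distance to the segment axis <= radius, with
    the axial coordinate clamped to the segment (flat end caps)."""
    p0 = np.asarray(p0, dtype=float)
    d = np.asarray(p1, dtype=float) - p0
    length = float(np.linalg.norm(d))
    d = d / length
    px, py, pz = xx - p0[0], yy - p0[1], zz - p0[2]
    t = px * d[0] + py * d[1] + pz * d[2]
    inside_axial = (t >= 0) & (t <= length)
    r2 = (px - t * d[0]) ** 2 + (py - t * d[1]) ** 2 + (pz - t * d[2]) ** 2
    return inside_axial & (r2 <= radius ** 2)


def _semi_from_volume(volume_mm3: float, aspect) -> tuple[float, float, float]:
    aspect = np.asarray(aspect, dtype=float)
    r = (3.0 * volume_mm3 / (4.0 * np.pi * np.prod(aspect))) ** (1.0 / 3.0)
    return tuple(r * aspect)


# Anatomical stations: x as a fraction of body length; y/z offsets in mm from
# the tube axis (ventral negative y, dorsal positive y).  Paired organs list
# two mirrored centres.  Tuned for the default body; the volume calibration
# check below guards any respec.
_STATIONS = {
    "brain": dict(fx=0.090, dy=0.5, dz=0.0, aspect=(1.05, 0.92, 0.92)),
    "lungs": dict(fx=0.250, dy=-0.5, dz=4.2, aspect=(1.35, 0.85, 0.90), paired=True),
    "heart": dict(fx=0.360, dy=-1.5, dz=0.0, aspect=(1.0, 1.0, 1.0)),
    "kidneys": dict(fx=0.560, dy=1.0, dz=5.0, aspect=(1.3, 0.9, 0.9), paired=True),
    "bladder": dict(fx=0.840, dy=-2.5, dz=0.0, aspect=(1.0, 1.0, 1.0)),
}
_SPINE = dict(fx0=0.155, fx1=0.850, dy=4.5)
_LIMBS = [  # (fx_start, fx_end, z_sign) for front and hind pairs
    (0.300, 0.340, +1.0), (0.300, 0.340, -1.0),
    (0.720, 0.760, +1.0), (0.720, 0.760, -1.0),
]
_LIMB_RADIUS = 1.1
_LIMB_START = (2.5, 3.0)   # (dy, |dz|) at the spine end
_LIMB_END = (-4.5, 6.5)    # at the ventral-lateral end


def _paint_labels(spec: PhantomSpec, shape, origin) -> tuple[np.ndarray, dict]:
    sp = spec.spacing_mm
    xx, yy, zz = _world_axes(shape, origin, sp)
    body = _body_mask(spec, xx, yy, zz)
    L = spec.length_mm

    organ_names = [o.name for o in spec.organs]
    ids = {name: i + 1 for i, name in enumerate(organ_names)}
    labels = np.zeros(shape, dtype=np.int32)
    if "remaining" in ids:
        labels[body] = ids["remaining"]

    for organ in spec.organs:
        if organ.name == "remaining":
            continue
        if organ.name == "skeleton":
            mask = _skeleton_mask(spec, xx, yy, zz)
        elif organ.name in _STATIONS:
            st = _STATIONS[organ.name]
            vol = organ.target_volume_ml * 1000.0
            if st.get("paired"):
                semi = _semi_from_volume(vol / 2.0, st["aspect"])
                mask = _ellipsoid(xx, yy, zz, (st["fx"] * L, st["dy"], st["dz"]), semi)
                mask |= _ellipsoid(xx, yy, zz, (st["fx"] * L, st["dy"], -st["dz"]), semi)
            else:
                semi = _semi_from_volume(vol, st["aspect"])
                mask = _ellipsoid(xx, yy, zz, (st["fx"] * L, st["dy"], st["dz"]), semi)
        else:
            raise GenerationError(f"no anatomical station defined for {organ.name!r}")
        labels[mask & body] = ids[organ.name]  # later-listed organ wins; clipped to body

    if spec.tumour_volume_ml > 0:
        ry, _ = _cross_section(spec)
        semi = _semi_from_volume(spec.tumour_volume_ml * 1000.0, (1.0, 1.0, 1.0))
        centre = (0.62 * L, -0.9 * ry, 0.0)  # attached at the ventral surface
        ids["tumour"] = max(ids.values()) + 1
        labels[_ellipsoid(xx, yy, zz, centre, semi)] = ids["tumour"]

    table = {rid: name for name, rid in ids.items()}
    _check_calibration(spec, labels, ids, sp)
    return labels, table


def _skeleton_mask(spec, xx, yy, zz) -> np.ndarray:
    """Spine cylinder plus four limb rods; the spine radius is solved so the
    total skeleton volume hits its target."""
    L = spec.length_mm
    target = spec.organ("skeleton").target_volume_ml * 1000.0
    limb_vol = 0.0
    masks = np.zeros(np.broadcast(xx, yy, zz).shape, dtype=bool)
    for fx0, fx1, zsig in _LIMBS:
        p0 = (fx0 * L, _LIMB_START[0], zsig * _LIMB_START[1])
        p1 = (fx1 * L, _LIMB_END[0], zsig * _LIMB_END[1])
        limb_vol += np.pi * _LIMB_RADIUS ** 2 * float(
            np.linalg.norm(np.subtract(p1, p0)))
        masks |= _rod(xx, yy, zz, p0, p1, _LIMB_RADIUS)
    spine_len = (_SPINE["fx1"] - _SPINE["fx0"]) * L
    spine_vol = target - limb_vol
    if spine_vol <= 0:
        raise GenerationError("skeleton target volume too small for the limb rods")
    radius = float(np.sqrt(spine_vol / (np.pi * spine_len)))
    masks |= _rod(
        xx, yy, zz,
        (_SPINE["fx0"] * L, _SPINE["dy"], 0.0),
        (_SPINE["fx1"] * L, _SPINE["dy"], 0.0),
        radius,
    )
    return masks


def _check_calibration(spec, labels, ids, sp) -> None:
    vox_ml = sp ** 3 / 1000.0
    for organ in spec.organs:
        got = int((labels == ids[organ.name]).sum()) * vox_ml
        if got == 0:
            raise GenerationError(f"organ {organ.name!r} occupies no voxels")
        err = abs(got - organ.target_volume_ml) / organ.target_volume_ml
        if err > 0.05:
            raise GenerationError(
                f"organ {organ.name!r} volume {got:.4f} ml misses target "
                f"{organ.target_volume_ml:.4f} ml by {100 * err:.1f} % "
                "(cannot fit in the body at the requested volumes/spacing)"
            )


def _paint_images(spec: PhantomSpec, labels: np.ndarray, table: dict,
                  activities: dict, rng) -> tuple[np.ndarray, np.ndarray]:
    max_id = max(table) if table else 0
    hu = np.full(max_id + 1, spec.background_hu)
    act = np.zeros(max_id + 1)
    for rid, name in table.items():
        organ = spec.organ(name) if name != "tumour" else None
        hu[rid] = organ.ct_hu if organ else 45.0
        act[rid] = activities.get(name, 0.0)
    ct = hu[labels] + rng.normal(0.0, spec.ct_noise_hu, labels.shape)
    pet = act[labels] * (1.0 + rng.normal(0.0, spec.pet_noise_frac, labels.shape))
    return ct, np.maximum(pet, 0.0)


# ---------------------------------------------------------------------------
# Public operations

def generate_atlas_phantom(spec: PhantomSpec, seed: int) -> PhantomStudy:
    """Generate the atlas study: exact-mean activities, known segmentation.

    Deterministic for a given (spec, seed).  Raises :class:`GenerationError`
    if any organ cannot reach its target volume within 5 % inside the body.
    """
    rng = np.random.default_rng(seed)
    shape, origin = _grid(spec)
    labels, table = _paint_labels(spec, shape, origin)
    activities = {o.name: o.activity_mean for o in spec.organs}
    if spec.tumour_volume_ml > 0:
        activities["tumour"] = 4.0 * max(o.activity_mean for o in spec.organs
                                         if o.name != "bladder")
    ct, pet = _paint_images(spec, labels, table, activities, rng)
    sp3 = (spec.spacing_mm,) * 3
    return PhantomStudy(
        ct=ImageVolume(ct, sp3, origin, "CT"),
        pet=ImageVolume(pet, sp3, origin, "PET"),
        labels=LabelVolume(labels, sp3, origin, dict(table)),
        truth_transform=None,
        truth_activities=activities,
    )


def _random_affine(rng, center, translation_mm, rotation_deg, scale_range, shear_max):
    return AffineTransform(
        translation=tuple(rng.uniform(-translation_mm, translation_mm, 3)),
        rotation=tuple(np.deg2rad(rng.uniform(-rotation_deg, rotation_deg, 3))),
        scale=tuple(rng.uniform(scale_range[0], scale_range[1], 3)),
        shear=tuple(rng.uniform(-shear_max, shear_max, 3)),
        center=tuple(center),
    )


def _random_bspline(rng, atlas: PhantomStudy, magnitude: float,
                    lattice_spacing_mm: float = 12.0) -> BSplineTransform:
    lo, hi = atlas.ct.extent()
    spacing = np.full(3, lattice_spacing_mm)
    n = np.ceil((hi - lo) / spacing).astype(int) + 1 + 2  # +2: one-point border
    origin = lo - spacing
    coeff = rng.normal(0.0, 1.0, size=(*n, 3))
    t = BSplineTransform(tuple(origin), tuple(spacing), coeff)
    if magnitude <= 0:
        t.coefficients[:] = 0.0
        return t
    # rescale so the maximum displacement over the body is the requested one
    body_idx = np.argwhere(atlas.labels.data != 0)[::7]
    pts = np.asarray(atlas.ct.origin) + body_idx * np.asarray(atlas.ct.spacing)
    mags = np.linalg.norm(displacement_at(t, pts), axis=1)
    peak = float(mags.max())
    if peak <= 0:
        raise GenerationError("degenerate zero displacement draw")
    t.coefficients *= magnitude / peak
    return t


def _min_jacobian(transform: CompositeTransform, atlas: PhantomStudy,
                  h: float = 0.5) -> float:
    """Minimum Jacobian determinant of the warp over body voxels (strided),
    by central finite differences."""
    body_idx = np.argwhere(atlas.labels.data != 0)[::11]
    pts = np.asarray(atlas.ct.origin) + body_idx * np.asarray(atlas.ct.spacing)
    jac = np.empty((pts.shape[0], 3, 3))
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = h
        jac[:, :, ax] = (apply_point(transform, pts + e)
                         - apply_point(transform, pts - e)) / (2 * h)
    return float(np.linalg.det(jac).min())


def _invert_on_grid(transform: CompositeTransform, reference) -> np.ndarray:
    """Solve transform(x) = y for every reference voxel centre y.

    Exploits the affine-then-B-spline structure: with T(x) = w + D(w),
    w = A(x), the displacement equation w + D(w) = y is solved by fixed-point
    iteration (contractive for non-folding fields), then x = A^{-1}(w).
    """
    affine, bspline = transform.transforms
    shape = reference.shape
    ii, jj, kk = np.meshgrid(*(np.arange(s) for s in shape), indexing="ij")
    y = (np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) *
         np.asarray(reference.spacing) + np.asarray(reference.origin))
    w = y.copy()
    for _ in range(12):
        resid = w + displacement_at(bspline, w) - y
        w -= resid
        if np.max(np.abs(resid)) < 1e-6:
            break
    return apply_point(affine.inverted(), w)


def sample_subject(atlas: PhantomStudy, spec: PhantomSpec, deform_magnitude: float,
                   seed: int, translation_mm: float = 5.0, rotation_deg: float = 10.0,
                   scale_range=(0.9, 1.1), shear_max: float = 0.05) -> PhantomStudy:
    """Draw one simulated subject from the atlas.

    Per-organ activities are drawn from Normal(mean, sd) truncated at 0; the
    ground-truth transform is a random 12-DOF affine (bounds given by the
    keyword arguments) composed with a random cubic B-spline displacement of
    maximum magnitude ``deform_magnitude`` mm over the body.  The atlas label
    map is resampled through the inverse warp onto the atlas grid
    (nearest-neighbour) and subject CT/PET are painted from the warped labels
    with the drawn activities and fresh noise.

    A draw whose warp folds (non-positive Jacobian in the body) is retried
    with damped magnitude, up to 10 attempts.
    """
    if deform_magnitude < 0:
        raise ValueError("deform_magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    activities = {
        o.name: float(max(0.0, rng.normal(o.activity_mean, o.activity_sd)))
        for o in spec.organs
    }
    lo, hi = atlas.ct.extent()
    center = 0.5 * (lo + hi)

    magnitude = deform_magnitude
    transform = None
    for _ in range(10):
        affine = _random_affine(rng, center, translation_mm, rotation_deg,
                                scale_range, shear_max)
        bspline = _random_bspline(rng, atlas, magnitude)
        candidate = CompositeTransform([affine, bspline])
        if _min_jacobian(candidate, atlas) > 0.05:
            transform = candidate
            break
        magnitude *= 0.7
    if transform is None:
        raise GenerationError("could not draw a non-folding deformation in 10 attempts")

    x = _invert_on_grid(transform, atlas.ct)
    coords = ((x - np.asarray(atlas.labels.origin)) /
              np.asarray(atlas.labels.spacing)).T
    from scipy import ndimage
    warped = ndimage.map_coordinates(atlas.labels.data, coords, order=0,
                                     mode="grid-constant", cval=0, prefilter=False)
    warped = warped.reshape(atlas.labels.shape).astype(np.int32)
    table = dict(atlas.labels.region_table)
    ct, pet = _paint_images(spec, warped, table, activities, rng)
    sp = atlas.ct.spacing
    origin = atlas.ct.origin
    return PhantomStudy(
        ct=ImageVolume(ct, sp, origin, "CT"),
        pet=ImageVolume(pet, sp, origin, "PET"),
        labels=LabelVolume(warped, sp, origin, table),
        truth_transform=transform,
        truth_activities=activities,
    )


def region_activity_truth(study: PhantomStudy, region: str) -> float:
    """The ground-truth activity concentration painted into ``region``."""
    if region not in study.truth_activities:
        raise KeyError(f"no ground-truth activity recorded for region {region!r}")
    return study.truth_activities[region]
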