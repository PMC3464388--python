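"""Multi-resolution intensity-based registration.

Implements the three-step protocol — affine pre-alignment, free-form cubic
B-spline refinement, then a masked B-spline step on a finer control lattice —
driven by the normalized correlation coefficient (NCC) evaluated on 2,500
random sample points redrawn every iteration, and optimized with adaptive
stochastic gradient descent (ASGD).

The default image pyramid uses down-sampling factors (32, 16, 8, 4, 2) with
per-level iteration budgets (4096, 4096, 2048, 2048, 1024); levels that would
leave any axis shorter than 4 voxels are skipped, and budgets are multiplied
by ``iteration_scale`` (default 1/8) for desk-scale grids.  During
optimization the moving image is interpolated trilinearly with analytic
chain-rule gradients; third-order B-spline interpolation is reserved for the
final resampling of outputs.  All computation is floating point.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .transforms import (
    AffineTransform,
    BSplineTransform,
    CompositeTransform,
    apply_point,
)
from .volumes import ImageVolume, world_to_voxel

__all__ = [
    "PyramidLevel",
    "PyramidSchedule",
    "RegistrationConfig",
    "RegistrationResult",
    "build_pyramid",
    "ncc",
    "sample_points",
    "optimize_asgd",
    "register_affine",
    "register_bspline",
    "three_step_register",
    "body_mask_from_ct",
    "OptimizationError",
]

log = logging.getLogger(__name__)


class OptimizationError(RuntimeError):
    """Non-finite objective or gradient encountered during optimization."""


@dataclass
class PyramidLevel:
    factor: int
    max_iterations: int
    smoothing: bool = True


@dataclass
class PyramidSchedule:
    levels: list

    @classmethod
    def default(cls) -> "PyramidSchedule":
        factors = (32, 16, 8, 4, 2)
        iters = (4096, 4096, 2048, 2048, 1024)
        return cls([PyramidLevel(f, n) for f, n in zip(factors, iters)])

    def __post_init__(self) -> None:
        facs = [lv.factor for lv in self.levels]
        if any(b >= a for a, b in zip(facs, facs[1:])):
            raise ValueError("pyramid factors must be strictly decreasing")
        if facs and facs[-1] < 1:
            raise ValueError("final pyramid factor must be >= 1")


@dataclass
class RegistrationConfig:
    """Engine configuration.

    ``a``, ``A``, ``alpha`` parameterize the ASGD gain sequence
    gamma(t) = a_eff / (A + t)^alpha; ``a`` multiplies an auto-calibrated
    gain chosen so the first step moves about half a level-voxel.
    ``iteration_scale`` scales the per-level iteration budgets.
    """

    schedule: PyramidSchedule = field(default_factory=PyramidSchedule.default)
    n_samples: int = 2500
    a: float = 1.0
    A: float = 50.0
    alpha: float = 0.602
    adaptive: bool = True
    seed: int = 0
    iteration_scale: float = 1.0 / 8.0
    gain_floor: float = 1e-8
    tail_average_frac: float = 0.25  # iterate averaging over the final fraction
    bspline_spacing_mm: float = 8.0  # unmasked step; the masked step halves this

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.a <= 0 or not (0.0 < self.alpha <= 1.0):
            raise ValueError("require a > 0 and alpha in (0, 1]")


@dataclass
class RegistrationResult:
    transform: object
    final_metric: float
    trace: list
    converged: bool


# ---------------------------------------------------------------------------
# Pyramid

def build_pyramid(v: ImageVolume, schedule: PyramidSchedule) -> list:
    """Smoothed/subsampled image pyramid, coarse to fine.

    Each level Gaussian-smooths with sigma = factor/2 voxels then subsamples
    by the factor; spacing scales by the factor and the origin stays at the
    first retained voxel centre.  Levels that would reduce any axis below 4
    voxels are skipped with a log notice.
    """
    out = []
    for lv in schedule.levels:
        f = int(lv.factor)
        if f < 1:
            raise ValueError("pyramid factor must be >= 1")
        if f > 1 and min(s // f for s in v.shape) < 4:
            log.info("skipping pyramid level factor=%d (axis would fall below 4 voxels)", f)
            continue
        if f == 1:
            data = ndimage.gaussian_filter(v.data.astype(float), 0.5, mode="nearest") \
                if lv.smoothing else v.data.astype(float)
            level_img = ImageVolume(data, v.spacing, v.origin, v.modality)
        else:
            data = v.data.astype(float)
            if lv.smoothing:
                data = ndimage.gaussian_filter(data, sigma=f / 2.0, mode="nearest")
            data = data[::f, ::f, ::f]
            level_img = ImageVolume(
                data, tuple(np.asarray(v.spacing) * f), v.origin, v.modality)
        out.append((lv, level_img))
    if not out:
        raise ValueError("no usable pyramid levels for this volume")
    return out


# ---------------------------------------------------------------------------
# Metric and sampling

def ncc(fixed_samples, moving_samples) -> float:
    """Pearson correlation of paired intensity samples, in [-1, 1].

    Invariant to positive affine rescaling of either input; returns 0 with a
    warning when either sample list has zero variance.
    """
    f = np.asarray(fixed_samples, dtype=float)
    m = np.asarray(moving_samples, dtype=float)
    if f.shape != m.shape or f.size < 2:
        raise ValueError("sample lists must have equal length >= 2")
    fc = f - f.mean()
    mc = m - m.mean()
    sf = np.sqrt((fc * fc).sum())
    sm = np.sqrt((mc * mc).sum())
    if sf == 0.0 or sm == 0.0:
        warnings.warn("degenerate (zero-variance) samples; NCC set to 0", stacklevel=2)
        return 0.0
    return float(np.clip((fc * mc).sum() / (sf * sm), -1.0, 1.0))


def _neg_ncc_and_dm(f, m):
    """(-NCC, d(-NCC)/dm_i) for paired samples; None gradient if degenerate."""
    fc = f - f.mean()
    mc = m - m.mean()
    sf = np.sqrt((fc * fc).sum())
    sm = np.sqrt((mc * mc).sum())
    if sf == 0.0 or sm == 0.0:
        return 0.0, None
    rho = (fc * mc).sum() / (sf * sm)
    dm = -(fc / (sf * sm) - rho * mc / (sm * sm))
    return -rho, dm


def sample_points(domain: ImageVolume, n: int, rng, mask: np.ndarray | None = None
                  ) -> np.ndarray:
    """Draw n uniform random world points (mm) within the fixed domain.

    With a boolean ``mask`` (same grid as ``domain``), points are drawn inside
    masked voxels only (voxel choice + uniform in-voxel jitter).  Deterministic
    for a given generator state.
    """
    shape = np.asarray(domain.shape)
    if mask is not None:
        cand = np.argwhere(mask)
        if cand.size == 0:
            raise ValueError("masked sampling domain is empty")
        pick = cand[rng.integers(0, len(cand), size=n)]
        idx = pick + rng.uniform(-0.5, 0.5, size=(n, 3))
        idx = np.clip(idx, 0.0, shape - 1.0)
    else:
        idx = rng.uniform(np.zeros(3), shape - 1.0, size=(n, 3))
    return np.asarray(domain.origin) + idx * np.asarray(domain.spacing)


# ---------------------------------------------------------------------------
# ASGD

def optimize_asgd(objective, init, n_iter: int, config: RegistrationConfig,
                  a_eff: float | None = None, max_step: float | None = None):
    """Adaptive stochastic gradient descent.

    Iterates theta <- theta - gamma(t_k) g_k with gamma(t) = a_eff/(A + t)^alpha.
    With the adaptive flag the artificial time advances by a bounded sigmoid of
    the cosine similarity of successive gradients — by more (toward 2/iter)
    when they agree (inner product > 0), by less (toward 0.5/iter) when they
    oppose — and never decreases; without it, t_k = k.  ``max_step`` bounds
    the norm of a single update (trust region against rare gradient spikes).
    Stops at ``n_iter`` or when the gain falls below ``gain_floor``.
    Returns (theta, trace of (iteration, objective value)).
    """
    theta = np.array(init, dtype=float)
    if a_eff is None:
        a_eff = config.a
    t = 0.0
    g_prev = None
    trace = []
    total = np.zeros_like(theta)
    n_tail = max(1, int(np.ceil(config.tail_average_frac * n_iter)))
    tail_count = 0
    for k in range(n_iter):
        value, grad = objective(theta)
        grad = np.asarray(grad, dtype=float)
        if not np.isfinite(value) or not np.all(np.isfinite(grad)):
            raise OptimizationError(
                f"non-finite objective/gradient at iteration {k}: theta={theta}")
        trace.append((k, -value))  # record the metric (NCC), not the loss
        gamma = a_eff / (config.A + t) ** config.alpha
        if gamma < config.gain_floor:
            break
        step = gamma * grad
        if max_step is not None:
            norm = float(np.linalg.norm(step))
            if norm > max_step:
                step = step * (max_step / norm)
        theta = theta - step
        if config.adaptive:
            if g_prev is not None:
                denom = np.linalg.norm(grad) * np.linalg.norm(g_prev)
                cos = float(grad @ g_prev) / denom if denom > 0 else 0.0
                # in (0.5, 2.0): faster decay on agreement, slower on opposition
                t += 0.5 + 1.5 / (1.0 + np.exp(-5.0 * cos))
            else:
                t += 1.0
        else:
            t = float(k + 1)
        g_prev = grad
        if k >= n_iter - n_tail:
            total += theta
            tail_count += 1
    if tail_count > 0:
        theta = total / tail_count
    return theta, trace


# ---------------------------------------------------------------------------
# Shared machinery

class _Level:
    """Per-level sampling/interpolation context for one (fixed, moving) pair."""

    def __init__(self, fixed_lv: ImageVolume, moving_lv: ImageVolume,
                 mask_lv: np.ndarray | None, n_samples: int, rng):
        self.fixed = fixed_lv
        self.moving = moving_lv
        self.mask = mask_lv
        self.n = n_samples
        self.rng = rng
        sp = np.asarray(moving_lv.spacing)
        g = np.gradient(moving_lv.data.astype(float), *sp)
        self.moving_grad = g  # d(intensity)/d(world mm), per axis

    def draw(self) -> tuple[np.ndarray, np.ndarray]:
        pts = sample_points(self.fixed, self.n, self.rng, self.mask)
        f = ndimage.map_coordinates(
            self.fixed.data.astype(float), world_to_voxel(self.fixed, pts).T,
            order=1, mode="nearest")
        return pts, f

    def moving_values_and_grad(self, world_pts):
        c = world_to_voxel(self.moving, world_pts).T
        inside = np.all((c >= 0.0) & (c <= (np.asarray(self.moving.shape) - 1.0)[:, None]),
                        axis=0)
        m = ndimage.map_coordinates(self.moving.data.astype(float), c, order=1,
                                    mode="nearest")
        grad = np.stack([
            ndimage.map_coordinates(gv, c, order=1, mode="nearest")
            for gv in self.moving_grad
        ], axis=1)  # (N, 3)
        return m, grad, inside


def _calibrate_gain(objective, theta0, config, step_mm: float, n_probe: int = 5):
    """Auto-scale the ASGD gain so the first step is about ``step_mm`` long
    (parameters are scaled to mm-equivalents).  A zero probe gradient means
    the metric is already stationary; returns 0 to freeze the level."""
    norms = []
    for _ in range(n_probe):
        _, g = objective(theta0)
        norms.append(np.linalg.norm(g))
    g0 = float(np.median(norms))
    if g0 < 1e-14:
        return 0.0
    return config.a * step_mm * config.A ** config.alpha / g0


def _level_step_mm(level_spacing: np.ndarray) -> float:
    return float(np.clip(0.5 * np.mean(level_spacing), 0.2, 3.0))


def _dense_metric(fixed: ImageVolume, moving: ImageVolume, transform, seed: int,
                  n: int = 20000, mask=None) -> float:
    """NCC over a dense seeded sample at full resolution (for reporting)."""
    rng = np.random.default_rng(seed)
    pts = sample_points(fixed, n, rng, mask)
    f = ndimage.map_coordinates(fixed.data.astype(float),
                                world_to_voxel(fixed, pts).T, order=1, mode="nearest")
    warped = apply_point(transform, pts) if transform is not None else pts
    c = world_to_voxel(moving, warped).T
    inside = np.all((c >= 0.0) & (c <= (np.asarray(moving.shape) - 1.0)[:, None]), axis=0)
    m = ndimage.map_coordinates(moving.data.astype(float), c, order=1, mode="nearest")
    if inside.sum() < 2:
        return 0.0
    return ncc(f[inside], m[inside])


def _downsample_mask(mask: np.ndarray | None, fixed: ImageVolume,
                     level_img: ImageVolume) -> np.ndarray | None:
    if mask is None:
        return None
    f = int(round(level_img.spacing[0] / fixed.spacing[0]))
    return mask[::f, ::f, ::f] if f > 1 else mask


# ---------------------------------------------------------------------------
# Affine registration

def _affine_param_jacobians(theta, center, h: float = 1e-6):
    """d(matrix)/d(theta_j) for the 12 parameters, by central differences of
    the (cheap, exact) matrix construction."""
    jacs = []
    for j in range(12):
        tp = np.array(theta)
        tm = np.array(theta)
        tp[j] += h
        tm[j] -= h
        mp = AffineTransform.from_params(tp, center).matrix()
        mm = AffineTransform.from_params(tm, center).matrix()
        jacs.append((mp - mm) / (2 * h))
    return jacs


def register_affine(fixed: ImageVolume, moving: ImageVolume,
                    config: RegistrationConfig,
                    init: AffineTransform | None = None,
                    mask: np.ndarray | None = None) -> RegistrationResult:
    """Optimize the 12 affine parameters over the image pyramid.

    Each level warm-starts from the previous; the -NCC gradient is computed
    analytically by the chain rule through trilinear interpolation at the
    sample points.  Rotation/scale/shear parameters are rescaled so a unit
    optimizer step moves comparable millimetres in every parameter class.
    """
    lo, hi = fixed.extent()
    center = tuple(0.5 * (lo + hi))
    if init is None:
        init = AffineTransform(center=center)
    theta = init.params
    # automatic parameter scaling: equalize the RMS point displacement a unit
    # step in each parameter produces over the fixed domain, so the optimizer
    # sees mm-equivalent coordinates in every parameter class (this also
    # strengthens weakly constrained directions, e.g. rotation about the long
    # axis of an elongated body)
    probe_rng = np.random.default_rng(config.seed + 17)
    probe_pts = sample_points(fixed, 1000, probe_rng,
                              mask if mask is not None else None)
    jacs0 = _affine_param_jacobians(theta, center)
    scale_vec = np.empty(12)
    for j in range(12):
        dy = probe_pts @ jacs0[j][:3, :3].T + jacs0[j][:3, 3]
        rms = float(np.sqrt((dy ** 2).sum(axis=1).mean()))
        scale_vec[j] = 1.0 / max(rms, 1e-6)

    rng = np.random.default_rng(config.seed)
    fixed_pyr = build_pyramid(fixed, config.schedule)
    moving_pyr = build_pyramid(moving, config.schedule)
    trace = []
    improved_any = False
    for (lv, f_img), (_, m_img) in zip(fixed_pyr, moving_pyr):
        ctx = _Level(f_img, m_img, _downsample_mask(mask, fixed, f_img),
                     config.n_samples, rng)
        jac_cache = {}

        def objective(phi):
            th = theta_ref + scale_vec * (phi - phi0)
            pts, f_s = ctx.draw()
            m_mat = AffineTransform.from_params(th, center).matrix()
            warped = pts @ m_mat[:3, :3].T + m_mat[:3, 3]
            m_s, m_grad, inside = ctx.moving_values_and_grad(warped)
            if inside.sum() < 10:
                return 0.0, np.zeros(12)
            loss, dm = _neg_ncc_and_dm(f_s[inside], m_s[inside])
            if dm is None:
                return loss, np.zeros(12)
            key = tuple(np.round(th, 12))
            if key not in jac_cache:
                jac_cache.clear()
                jac_cache[key] = _affine_param_jacobians(th, center)
            jacs = jac_cache[key]
            p_in = pts[inside]
            g_in = m_grad[inside]
            grad = np.empty(12)
            for j in range(12):
                dy = p_in @ jacs[j][:3, :3].T + jacs[j][:3, 3]
                grad[j] = (dm * np.einsum("ij,ij->i", g_in, dy)).sum()
            return loss, grad * scale_vec

        theta_ref = theta
        phi0 = np.zeros(12)
        n_iter = max(1, int(round(lv.max_iterations * config.iteration_scale)))
        metric_before = -objective(phi0)[0]
        step_mm = _level_step_mm(np.asarray(f_img.spacing))
        a_eff = _calibrate_gain(objective, phi0, config, step_mm)
        if a_eff == 0.0:
            trace.append((lv.factor, [(0, metric_before)]))
            continue
        phi, lv_trace = optimize_asgd(objective, phi0, n_iter, config, a_eff=a_eff,
                                      max_step=2.0 * step_mm)
        theta = theta_ref + scale_vec * (phi - phi0)
        metric_after = float(np.mean([m for _, m in lv_trace[-20:]]))
        improved_any = improved_any or metric_after > metric_before
        trace.append((lv.factor, lv_trace))

    result_t = AffineTransform.from_params(theta, center)
    final = _dense_metric(fixed, moving, result_t, config.seed + 101, mask=mask)
    return RegistrationResult(result_t, final, trace, converged=True if improved_any
                              else _near_stationary(trace))


def _near_stationary(trace) -> bool:
    # no level improved: either already aligned (fine) or genuinely stuck
    return all(len(t) <= 1 for _, t in trace)


# ---------------------------------------------------------------------------
# B-spline registration

def _make_lattice(domain_lo, domain_hi, spacing_mm: float) -> BSplineTransform:
    spacing = np.full(3, float(spacing_mm))
    n = np.ceil((np.asarray(domain_hi) - domain_lo) / spacing).astype(int) + 1 + 2
    origin = np.asarray(domain_lo) - spacing
    return BSplineTransform(tuple(origin), tuple(spacing),
                            np.zeros((*n, 3)))


def _bspline_weights(t: BSplineTransform, pts: np.ndarray):
    """Indices and tensor weights of the 4x4x4 support of each point.

    Returns (flat control indices (N, 64), weights (N, 64), in_support mask).
    Out-of-lattice neighbours are dropped (their coefficients are zero by
    definition of the finite lattice)."""
    from .transforms import cubic_bspline_weight

    u = t.lattice_coords(pts)  # (N, 3)
    base = np.floor(u).astype(int) - 1
    shape = np.asarray(t.coefficients.shape[:3])
    offs = np.arange(4)
    w_ax = []
    idx_ax = []
    for ax in range(3):
        nodes = base[:, ax, None] + offs[None, :]
        w_ax.append(cubic_bspline_weight(u[:, ax, None] - nodes))
        idx_ax.append(nodes)
    w = (w_ax[0][:, :, None, None] * w_ax[1][:, None, :, None]
         * w_ax[2][:, None, None, :]).reshape(len(pts), 64)
    ii = idx_ax[0][:, :, None, None]
    jj = idx_ax[1][:, None, :, None]
    kk = idx_ax[2][:, None, None, :]
    valid = ((ii >= 0) & (ii < shape[0]) & (jj >= 0) & (jj < shape[1])
             & (kk >= 0) & (kk < shape[2]))
    flat = (np.clip(ii, 0, shape[0] - 1) * shape[1] + np.clip(jj, 0, shape[1] - 1)) \
        * shape[2] + np.clip(kk, 0, shape[2] - 1)
    flat = np.broadcast_to(flat, (len(pts), 4, 4, 4)).reshape(len(pts), 64)
    valid = np.broadcast_to(valid, (len(pts), 4, 4, 4)).reshape(len(pts), 64)
    w = np.where(valid, w, 0.0)
    return flat, w


def register_bspline(fixed: ImageVolume, moving: ImageVolume, init,
                     config: RegistrationConfig,
                     mask: np.ndarray | None = None,
                     grid_spacing_mm: float | None = None) -> RegistrationResult:
    """Optimize a cubic B-spline FFD composed after ``init``.

    The control lattice covers the ``init``-image of the fixed domain plus a
    one-point border; its displacements (mm) are the optimization variables.
    With ``mask``, metric samples are drawn only inside it (the masked third
    step of the protocol).  Returns a composite (init then B-spline).
    """
    if grid_spacing_mm is None:
        grid_spacing_mm = config.bspline_spacing_mm
    lo, hi = fixed.extent()
    corners = np.array([[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1])
                        for z in (lo[2], hi[2])])
    warped_corners = apply_point(init, corners) if init is not None else corners
    bspline = _make_lattice(warped_corners.min(axis=0), warped_corners.max(axis=0),
                            grid_spacing_mm)
    n_params = bspline.coefficients.size
    shape_c = bspline.coefficients.shape

    rng = np.random.default_rng(config.seed + 7)
    fixed_pyr = build_pyramid(fixed, config.schedule)
    moving_pyr = build_pyramid(moving, config.schedule)
    theta = np.zeros(n_params)
    trace = []
    for (lv, f_img), (_, m_img) in zip(fixed_pyr, moving_pyr):
        ctx = _Level(f_img, m_img, _downsample_mask(mask, fixed, f_img),
                     config.n_samples, rng)

        def objective(th):
            coeff = th.reshape(shape_c)
            pts, f_s = ctx.draw()
            base_pts = apply_point(init, pts) if init is not None else pts
            flat, w = _bspline_weights(bspline, base_pts)
            cf = coeff.reshape(-1, 3)
            disp = np.einsum("nk,nkc->nc", w, cf[flat])
            m_s, m_grad, inside = ctx.moving_values_and_grad(base_pts + disp)
            if inside.sum() < 10:
                return 0.0, np.zeros(n_params)
            loss, dm = _neg_ncc_and_dm(f_s[inside], m_s[inside])
            if dm is None:
                return loss, np.zeros(n_params)
            grad = np.zeros((cf.shape[0], 3))
            contrib = w[inside] * dm[:, None]  # (Nin, 64)
            flat_in = flat[inside].ravel()
            for c in range(3):
                vals = (contrib * m_grad[inside][:, c, None]).ravel()
                grad[:, c] += np.bincount(flat_in, weights=vals,
                                          minlength=cf.shape[0])
            return loss, grad.ravel()

        n_iter = max(1, int(round(lv.max_iterations * config.iteration_scale)))
        metric_before = -objective(theta)[0]
        step_mm = _level_step_mm(np.asarray(f_img.spacing))
        a_eff = _calibrate_gain(objective, theta, config, step_mm)
        if a_eff == 0.0:
            trace.append((lv.factor, [(0, metric_before)]))
            continue
        theta, lv_trace = optimize_asgd(objective, theta, n_iter, config, a_eff=a_eff,
                                        max_step=2.0 * step_mm)
        trace.append((lv.factor, lv_trace))

    bspline = replace(bspline, coefficients=theta.reshape(shape_c))
    parts = list(init.transforms) if isinstance(init, CompositeTransform) \
        else ([init] if init is not None else [])
    result_t = CompositeTransform(parts + [bspline])
    final = _dense_metric(fixed, moving, result_t, config.seed + 103, mask=mask)
    return RegistrationResult(result_t, final, trace, converged=True)


# ---------------------------------------------------------------------------
# Three-step protocol

def body_mask_from_ct(ct: ImageVolume, threshold_hu: float = -400.0,
                      dilate_voxels: int = 2) -> np.ndarray:
    """Binary body mask from a CT: threshold, keep the largest component,
    fill holes, dilate."""
    raw = ct.data > threshold_hu
    lab, n = ndimage.label(raw)
    if n == 0:
        raise ValueError("no voxels above the body threshold")
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    body = lab == (1 + int(np.argmax(sizes)))
    body = ndimage.binary_fill_holes(body)
    if dilate_voxels > 0:
        body = ndimage.binary_dilation(body, iterations=dilate_voxels)
    return body


def three_step_register(atlas_ct: ImageVolume, subject_ct: ImageVolume,
                        config: RegistrationConfig,
                        body_mask: np.ndarray | None = None):
    """Affine -> B-spline -> masked B-spline (finer lattice) registration.

    ``atlas_ct`` is the fixed image, ``subject_ct`` the moving one; the
    returned composite maps atlas-space world points into subject space.  The
    mask for step 3 is a binary body mask in fixed space (derived from the
    fixed CT when not supplied, dilated 2 voxels).  Returns
    (CompositeTransform, [RegistrationResult per step]).
    """
    results = []
    try:
        step1 = register_affine(atlas_ct, subject_ct, config)
        results.append(step1)
    except Exception as exc:
        raise RuntimeError(f"three-step registration failed at step 1 (affine): {exc}") \
            from exc
    try:
        step2 = register_bspline(atlas_ct, subject_ct, step1.transform, config,
                                 grid_spacing_mm=config.bspline_spacing_mm)
        results.append(step2)
    except Exception as exc:
        raise RuntimeError(f"three-step registration failed at step 2 (B-spline): {exc}") \
            from exc
    if body_mask is None:
        body_mask = body_mask_from_ct(atlas_ct)
    try:
        step3 = register_bspline(atlas_ct, subject_ct, step2.transform, config,
                                 mask=body_mask,
                                 grid_spacing_mm=config.bspline_spacing_mm / 2.0)
        results.append(step3)
    except Exception as exc:
        raise RuntimeError(
            f"three-step registration failed at step 3 (masked B-spline): {exc}") from exc
    # re-evaluate every step's metric on one common (unmasked) domain so the
    # per-step values are comparable
    for r in results:
        r.final_metric = _dense_metric(atlas_ct, subject_ct, r.transform,
                                       config.seed + 101)
    log.info("three-step NCC: affine %.4f -> B-spline %.4f -> masked %.4f",
             step1.final_metric, step2.final_metric, step3.final_metric)
    return step3.transform, results
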