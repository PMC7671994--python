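"""Masked rigid + deformable registration of ultrasound volume pairs.

The distance measure is the normalized gradient field (NGF): it scores the
local alignment of image gradients, which makes it robust to the intensity
non-stationarity of ultrasound. For a reference R and warped template T,

    D(R, T) = 1/2 * sum_{x in mask} h * (1 - r(x)^2),
    r(x) = (<grad R, grad T> + eps^2) / (|grad R|_eps * |grad T|_eps),
    |g|_eps = sqrt(|g|^2 + eps^2),

with central differences scaled by the voxel spacing and h the voxel
volume. The edge parameter eps decides which gradients count as edges
rather than noise. Crucially, the sum runs only over a mask: the beam
cones of both volumes intersected, minus the resection cavity — the cavity
has no counterpart in the pre-resection volume, so letting it contribute
drags the optimum away from the true tissue alignment.

Deformations are penalized by the curvature regularizer, the squared
Laplacian of each displacement component; affine transforms cost nothing.
Both stages are optimized with limited-memory BFGS, coarse-to-fine for the
deformable stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage, optimize

from .grids import BinaryMask, DeformationField, LandmarkSet, Volume3D

# The optimized objective is the masked-mean NGF residual plus the
# mean curvature penalty, expressed in percent. The published stopping
# tolerances (0.001) are meaningful for objectives of order 1-10; the
# per-voxel means are of order 0.01-0.5, so they are scaled by 100.
OBJECTIVE_SCALE = 100.0

__all__ = [
    "RegistrationConfig", "RigidTransform",
    "estimate_beam_mask", "combine_masks",
    "ngf_distance", "curvature_energy", "estimate_ngf_epsilon",
    "rigid_register", "deformable_register", "transform_landmarks",
]


@dataclass
class RegistrationConfig:
    """Tunables of both registration stages.

    Stopping tolerances follow the convention: minimal progress is
    ``|J_k - J_{k-1}| / max(1, |J_k|)``, the relative gradient is
    ``||g_k|| / ||g_0||`` at the current level, and the step length is the
    parameter-space norm of the last accepted step.
    """

    ngf_epsilon: float | None = None   # None -> intensity-adaptive per level
    regularizer_weight: float = 0.3
    image_smoothing: float = 3.0       # Gaussian sigma, finest-level voxels
    rigid_smoothing: float = 2.5       # same convention, rigid stage only
    levels_deformable: int = 3         # coarse-to-fine, finest = original
    rigid_level_offset: int = 1        # rigid runs this many levels coarser
    max_iterations: int = 100
    min_progress: float = 0.001
    min_gradient: float = 0.001
    min_relative_gradient: float = 0.001
    min_step_length: float = 0.001
    use_cavity_mask: bool = True
    use_beam_mask: bool = True

    def __post_init__(self):
        for name in ("min_progress", "min_gradient", "min_relative_gradient",
                     "min_step_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.levels_deformable < 1 or self.max_iterations < 1:
            raise ValueError("levels and max_iterations must be >= 1")


@dataclass
class RigidTransform:
    """World-space rigid map ``phi(x) = R (x - c) + c + t`` (mm)."""

    rotation: np.ndarray = dfield(default_factory=lambda: np.eye(3))
    translation: np.ndarray = dfield(default_factory=lambda: np.zeros(3))
    center: np.ndarray = dfield(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation matrix must have determinant +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - self.center) @ self.rotation.T + self.center \
            + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()


def euler_to_matrix(angles) -> np.ndarray:
    """Rotation matrix from extrinsic x-y-z Euler angles (radians)."""
    ax, ay, az = angles
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


# ---------------------------------------------------------------------------
# masks

def estimate_beam_mask(volume: Volume3D) -> BinaryMask:
    """Mask of the insonified cone: nonzero voxels, closed, largest component."""
    raw = volume.data > 0
    if not raw.any():
        warnings.warn("volume is identically zero; beam mask is empty")
        return BinaryMask.on_grid(volume, raw)
    if raw.all():
        return BinaryMask.on_grid(volume, raw)
    closed = ndimage.binary_closing(raw, structure=np.ones((3, 3, 3)),
                                    iterations=2)
    closed |= raw
    labels, n = ndimage.label(closed, structure=np.ones((3, 3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n + 1))
        closed = labels == (1 + int(np.argmax(sizes)))
    return BinaryMask.on_grid(volume, closed)


def combine_masks(beam_fixed: BinaryMask, beam_moving_warped: BinaryMask,
                  cavity: BinaryMask | None = None) -> BinaryMask:
    """Evaluation mask: beam intersection minus the resection cavity."""
    if beam_fixed.shape != beam_moving_warped.shape or (
            cavity is not None and cavity.shape != beam_fixed.shape):
        raise ValueError("masks must share one grid")
    data = beam_fixed.data & beam_moving_warped.data
    if cavity is not None:
        data = data & ~cavity.data
    if not data.any():
        raise ValueError("no overlap to register: combined mask is empty")
    return BinaryMask(data, beam_fixed.spacing, beam_fixed.origin,
                      beam_fixed.direction)


# ---------------------------------------------------------------------------
# differential operators (central differences, replicate boundary)

def _diff(f: np.ndarray, axis: int, s: float) -> np.ndarray:
    fp = np.concatenate([f.take(np.arange(1, f.shape[axis]), axis=axis),
                         f.take([-1], axis=axis)], axis=axis)
    fm = np.concatenate([f.take([0], axis=axis),
                         f.take(np.arange(0, f.shape[axis] - 1), axis=axis)],
                        axis=axis)
    return (fp - fm) / (2.0 * s)


def _diff_adjoint(w: np.ndarray, axis: int, s: float) -> np.ndarray:
    """Exact transpose of :func:`_diff` (tested to machine precision)."""
    out = np.zeros_like(w)
    wv = np.moveaxis(w, axis, 0)
    ov = np.moveaxis(out, axis, 0)
    # +w/(2s) scattered to index i+1 (clamped), -w/(2s) to index i-1 (clamped)
    ov[1:] += wv[:-1]
    ov[-1] += wv[-1]
    ov[:-1] -= wv[1:]
    ov[0] -= wv[0]
    return out / (2.0 * s)


def image_gradient(data: np.ndarray, spacing) -> np.ndarray:
    """Spacing-scaled central-difference gradient, shape (3,) + data.shape."""
    return np.stack([_diff(data, ax, spacing[ax]) for ax in range(3)])


def _ngf_core(gR, nR, data_T, mask, spacing, eps, h):
    """NGF value and its gradient w.r.t. the template intensities."""
    gT = image_gradient(data_T, spacing)
    nT2 = (gT ** 2).sum(axis=0) + eps ** 2
    nT = np.sqrt(nT2)
    dot = (gR * gT).sum(axis=0) + eps ** 2
    r = dot / (nR * nT)
    value = 0.5 * h * float(((1.0 - r ** 2) * mask).sum())
    # d value / d gT_k = -h r (gR_k/(nR nT) - r gT_k / nT^2), inside mask
    pref = -h * r * mask
    grad_T = np.zeros_like(data_T)
    for k in range(3):
        wk = pref * (gR[k] / (nR * nT) - r * gT[k] / nT2)
        grad_T += _diff_adjoint(wk, k, spacing[k])
    return value, grad_T


def ngf_distance(reference: Volume3D, template_warped: Volume3D,
                 mask: BinaryMask, epsilon: float) -> dict:
    """Masked NGF distance between a reference and an already-warped template.

    Returns ``{"value": float, "gradient": array}`` where the gradient is
    taken with respect to the warped template's intensities; the deformable
    stage chains it through the warp to obtain the displacement gradient.
    """
    if reference.shape != template_warped.shape or mask.shape != reference.shape:
        raise ValueError("reference, template and mask must share one grid")
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    m = mask.data.astype(float)
    if not mask.data.any():
        warnings.warn("empty mask: NGF distance is 0")
        return {"value": 0.0, "gradient": np.zeros(reference.shape)}
    sp = reference.spacing
    h = reference.voxel_volume
    R = reference.data.astype(np.float64)
    gR = image_gradient(R, sp)
    nR = np.sqrt((gR ** 2).sum(axis=0) + epsilon ** 2)
    value, grad_T = _ngf_core(gR, nR, template_warped.data.astype(np.float64),
                              m, sp, epsilon, h)
    return {"value": value, "gradient": grad_T}


def estimate_ngf_epsilon(reference: Volume3D, template: Volume3D,
                         mask: BinaryMask) -> float:
    """Edge parameter: 10% of the masked median absolute gradient magnitude."""
    mags = []
    for vol in (reference, template):
        g = image_gradient(vol.data.astype(np.float64), vol.spacing)
        mags.append(np.sqrt((g ** 2).sum(axis=0))[mask.data])
    med = float(np.median(np.concatenate(mags)))
    return max(0.1 * med, 1e-6)


def curvature_energy(field: DeformationField) -> dict:
    """Curvature regularizer: 1/2 sum_l sum_x h (Laplacian u_l)^2.

    The Laplacian uses spacing-scaled central second differences and is
    accumulated over interior voxels only, so affine fields have exactly
    zero energy. Returns value and analytic gradient w.r.t. displacements.
    """
    u = field.displacements
    sp = field.spacing
    h = float(np.prod(sp))
    value = 0.0
    grad = np.zeros_like(u)
    inner = (slice(1, -1),) * 3
    for l in range(3):
        lap = np.zeros(u.shape[1:])
        for ax in range(3):
            lap += (np.roll(u[l], -1, axis=ax) - 2 * u[l]
                    + np.roll(u[l], 1, axis=ax)) / sp[ax] ** 2
        v = np.zeros_like(lap)
        v[inner] = lap[inner]
        value += 0.5 * h * float((v ** 2).sum())
        # symmetric stencil: gradient = h * L^T v with v zero outside interior
        g = np.zeros_like(lap)
        for ax in range(3):
            g += (np.roll(v, -1, axis=ax) - 2 * v
                  + np.roll(v, 1, axis=ax)) / sp[ax] ** 2
        grad[l] = h * g
    return {"value": value, "gradient": grad}


# ---------------------------------------------------------------------------
# trilinear sampling with analytic derivative

def _trilinear(data: np.ndarray, coords: np.ndarray):
    """Sample ``data`` at fractional indices with replicate boundary.

    coords: (3,) + S. Returns (values with shape S, derivative (3,) + S in
    index units). Coordinates outside the domain clamp to the edge, which
    keeps the sampled value continuous in the coordinates; the derivative
    along a clamped axis is zero. (The zero-outside convention of plain
    warping would make the registration objective discontinuous wherever a
    boundary voxel crosses the domain edge.)
    """
    shape = np.array(data.shape)
    clamped = [(coords[ax] < 0) | (coords[ax] > shape[ax] - 1)
               for ax in range(3)]
    coords = np.stack([np.clip(coords[ax], 0.0, shape[ax] - 1.0)
                       for ax in range(3)])
    base = np.floor(coords).astype(np.int64)
    for ax in range(3):
        np.clip(base[ax], 0, shape[ax] - 2, out=base[ax])
    frac = coords - base
    i0, j0, k0 = base
    c = {}
    for a in (0, 1):
        for b in (0, 1):
            for d in (0, 1):
                c[(a, b, d)] = data[i0 + a, j0 + b, k0 + d]
    fx, fy, fz = frac
    wx = (1 - fx, fx)
    wy = (1 - fy, fy)
    wz = (1 - fz, fz)
    val = np.zeros(coords.shape[1:])
    dx = np.zeros_like(val)
    dy = np.zeros_like(val)
    dz = np.zeros_like(val)
    for a in (0, 1):
        sa = 1.0 if a else -1.0
        for b in (0, 1):
            sb = 1.0 if b else -1.0
            for d in (0, 1):
                sd = 1.0 if d else -1.0
                cv = c[(a, b, d)]
                val += cv * wx[a] * wy[b] * wz[d]
                dx += cv * sa * wy[b] * wz[d]
                dy += cv * wx[a] * sb * wz[d]
                dz += cv * wx[a] * wy[b] * sd
    deriv = np.stack([dx, dy, dz])
    for ax in range(3):
        deriv[ax][clamped[ax]] = 0.0
    return val, deriv


# ---------------------------------------------------------------------------
# multilevel helpers

def _downsample_volume(vol: Volume3D) -> Volume3D:
    sm = ndimage.gaussian_filter(vol.data.astype(np.float64), 1.0)
    return Volume3D(sm[::2, ::2, ::2], vol.spacing * 2, vol.origin,
                    vol.direction)


def _downsample_mask(mask: BinaryMask) -> BinaryMask:
    sm = ndimage.gaussian_filter(mask.data.astype(np.float64), 1.0)
    return BinaryMask(sm[::2, ::2, ::2] > 0.5, mask.spacing * 2, mask.origin,
                      mask.direction)


def _pyramid(vol: Volume3D, levels: int) -> list[Volume3D]:
    out = [vol]
    for _ in range(levels - 1):
        out.append(_downsample_volume(out[-1]))
    return out[::-1]  # coarse first


def _mask_pyramid(mask: BinaryMask, levels: int) -> list[BinaryMask]:
    out = [mask]
    for _ in range(levels - 1):
        out.append(_downsample_mask(out[-1]))
    return out[::-1]


def _erode_mask(mask: BinaryMask, iterations: int) -> BinaryMask:
    """Erode, but never to emptiness (fall back to the original)."""
    if iterations <= 0:
        return mask
    er = ndimage.binary_erosion(mask.data, iterations=iterations)
    if not er.any():
        return mask
    return BinaryMask(er, mask.spacing, mask.origin, mask.direction)


def _prolong(u: np.ndarray, fine_shape) -> np.ndarray:
    """Trilinear field prolongation; displacement values stay in mm.

    The coarse grid is the fine grid subsampled by 2 (coarse node c sits
    at fine node 2c), so fine index i maps to coarse coordinate i/2.
    """
    coords = np.indices(fine_shape, dtype=float) * 0.5
    return np.stack([
        ndimage.map_coordinates(u[c], coords, order=1, mode="nearest")
        for c in range(3)])


class _StopTracker:
    """Implements the four extra stopping rules on top of L-BFGS-B."""

    def __init__(self, config: RegistrationConfig):
        self.cfg = config
        self.values: list[float] = []
        self.grad_norms: list[float] = []
        self.g0: float | None = None
        self.prev_x: np.ndarray | None = None
        self.reason = "max_iterations"

    def record_eval(self, J: float, gnorm: float):
        self.last_eval = (J, gnorm)

    def callback(self, xk):
        J, gnorm = self.last_eval
        if self.g0 is None:
            self.g0 = max(gnorm, 1e-300)
        stop = None
        if self.values and abs(J - self.values[-1]) / max(1.0, abs(J)) \
                < self.cfg.min_progress:
            stop = "min_progress"
        elif self.prev_x is not None and float(
                np.linalg.norm(xk - self.prev_x)) < self.cfg.min_step_length:
            stop = "min_step_length"
        elif gnorm < self.cfg.min_gradient:
            stop = "min_gradient"
        elif gnorm / self.g0 < self.cfg.min_relative_gradient:
            stop = "min_relative_gradient"
        self.values.append(J)
        self.grad_norms.append(gnorm)
        self.prev_x = np.asarray(xk).copy()
        if stop is not None:
            self.reason = stop
            raise StopIteration


def _minimize(fun, x0, config: RegistrationConfig, jac=True):
    tracker = _StopTracker(config)

    def wrapped(x):
        if jac:
            J, g = fun(x)
            tracker.record_eval(float(J), float(np.linalg.norm(g)))
            return J, g
        J = fun(x)
        tracker.record_eval(float(J), np.inf)
        return J

    try:
        res = optimize.minimize(
            wrapped, x0, jac=True if jac else None, method="L-BFGS-B",
            callback=tracker.callback,
            options=dict(maxiter=config.max_iterations, maxcor=10,
                         ftol=1e-15, gtol=1e-15))
        x = res.x
    except StopIteration:  # our own stopping rules fired
        x = tracker.prev_x if tracker.prev_x is not None else x0
    return np.asarray(x), dict(iterations=len(tracker.values),
                               values=tracker.values,
                               grad_norms=tracker.grad_norms,
                               stop_reason=tracker.reason)


# ---------------------------------------------------------------------------
# rigid stage

def rigid_register(fixed: Volume3D, moving: Volume3D, masks=None,
                   config: RegistrationConfig | None = None) -> RigidTransform:
    """Rigid alignment by masked NGF at one coarse level.

    Parameters
    ----------
    masks : optional (beam_fixed, beam_moving[, cavity]) tuple of BinaryMask.
        Beam masks are estimated from the volumes when omitted. The cavity
        mask is ignored by default at this stage.
    """
    config = config or RegistrationConfig()
    if masks is None:
        masks = (estimate_beam_mask(fixed), estimate_beam_mask(moving))
    beam_f, beam_m = masks[0], masks[1]

    n_down = max(config.rigid_level_offset, 0)
    f, m = fixed, moving
    bf, bm = beam_f, beam_m
    for _ in range(n_down):
        f, m = _downsample_volume(f), _downsample_volume(m)
        bf, bm = _downsample_mask(bf), _downsample_mask(bm)

    mask = bf.data & bm.data
    if not mask.any():
        warnings.warn("rigid stage: empty mask, returning identity")
        return RigidTransform.identity()
    sigma = config.rigid_smoothing * 0.5 ** n_down
    # the beam boundary's huge intensity step bleeds ~sigma voxels inward
    # on the smoothed images; keep the support clear of it
    eroded = ndimage.binary_erosion(mask,
                                    iterations=int(np.ceil(sigma)) + 1)
    if eroded.any():
        mask = eroded
    maskf = mask.astype(float)

    # the distance is evaluated on band-limited images: speckle decorrelates
    # between acquisitions, so its gradients carry no alignment signal.
    # sigma shrinks with the level so the bandwidth is constant in mm.
    if sigma > 0:
        f = f.with_data(ndimage.gaussian_filter(
            f.data.astype(np.float64), sigma))
        m = m.with_data(ndimage.gaussian_filter(
            m.data.astype(np.float64), sigma))
    eps = config.ngf_epsilon or estimate_ngf_epsilon(
        f, m, BinaryMask.on_grid(f, mask))
    sp = f.spacing
    h = f.voxel_volume
    R = f.data.astype(np.float64)
    gR = image_gradient(R, sp)
    nR = np.sqrt((gR ** 2).sum(axis=0) + eps ** 2)
    Nm = maskf.sum() * h

    idx = np.indices(f.shape, dtype=float)
    world = np.einsum("ab,b...->a...", f.index_to_world, idx) \
        + f.origin[:, None, None, None]
    ctr = (world * maskf[None]).sum(axis=(1, 2, 3)) / maskf.sum()
    Ainv_m = m.world_to_index
    Mdata = m.data.astype(np.float64)

    # translations in mm, angles scaled so 1 unit ~ 1 radian
    def objective(p):
        Rm = euler_to_matrix(p[:3])
        t = p[3:]
        pts = np.einsum("ab,b...->a...", Rm,
                        world - ctr[:, None, None, None]) \
            + (ctr + t)[:, None, None, None]
        coords = np.einsum("ab,b...->a...", Ainv_m,
                           pts - m.origin[:, None, None, None])
        T, _ = _trilinear(Mdata, coords)
        val, _ = _ngf_core(gR, nR, T, maskf, sp, eps, h)
        return OBJECTIVE_SCALE * val / Nm

    # two starts: identity, and the beam-centroid shift (robust against
    # coarse-level local minima when a large translation is present)
    mwld = np.einsum("ab,b...->a...", m.index_to_world,
                     np.indices(m.shape, dtype=float)) \
        + m.origin[:, None, None, None]
    bmf = bm.data.astype(float)
    ctr_m = (mwld * bmf[None]).sum(axis=(1, 2, 3)) / max(bmf.sum(), 1.0)
    bff = bf.data.astype(float)
    ctr_f = (world * bff[None]).sum(axis=(1, 2, 3)) / max(bff.sum(), 1.0)
    starts = [np.zeros(6),
              np.concatenate([np.zeros(3), ctr_m - ctr_f])]

    best = (np.inf, np.zeros(6))
    for x0 in starts:
        tracker = _StopTracker(config)

        def wrapped(p):
            J = objective(p)
            tracker.record_eval(J, np.inf)
            return J

        try:
            res = optimize.minimize(
                wrapped, x0, method="L-BFGS-B", jac="3-point",
                callback=lambda xk: _rigid_cb(tracker, xk),
                options=dict(maxiter=config.max_iterations,
                             eps=1e-4, ftol=1e-15, gtol=1e-15))
            x = res.x
        except StopIteration:
            x = tracker.prev_x
        except Exception as exc:  # never crash the pipeline
            warnings.warn(f"rigid optimization failed ({exc}); "
                          "skipping this start")
            continue
        if x is None:
            continue
        J = objective(x)
        if J < best[0]:
            best = (J, np.asarray(x))
    x = best[1]
    return RigidTransform(rotation=euler_to_matrix(x[:3]), translation=x[3:],
                          center=ctr)


def _rigid_cb(tracker: _StopTracker, xk):
    J, _ = tracker.last_eval
    if tracker.values:
        if abs(J - tracker.values[-1]) / max(1.0, abs(J)) \
                < tracker.cfg.min_progress:
            tracker.values.append(J)
            tracker.prev_x = np.asarray(xk).copy()
            raise StopIteration
    tracker.values.append(J)
    tracker.prev_x = np.asarray(xk).copy()


# ---------------------------------------------------------------------------
# deformable stage

def _resample_through_rigid(moving: Volume3D, grid: Volume3D,
                            rig: RigidTransform, order=1) -> np.ndarray:
    idx = np.indices(grid.shape, dtype=float)
    world = np.einsum("ab,b...->a...", grid.index_to_world, idx) \
        + grid.origin[:, None, None, None]
    pts = np.einsum("ab,b...->a...", rig.rotation,
                    world - rig.center[:, None, None, None]) \
        + (rig.center + rig.translation)[:, None, None, None]
    coords = np.einsum("ab,b...->a...", moving.world_to_index,
                       pts - moving.origin[:, None, None, None])
    return ndimage.map_coordinates(moving.data.astype(np.float64), coords,
                                   order=order, mode="constant", cval=0.0)


def deformable_register(fixed: Volume3D, moving: Volume3D,
                        cavity_mask: BinaryMask | None = None,
                        init: RigidTransform | None = None,
                        config: RegistrationConfig | None = None):
    """Coarse-to-fine curvature-regularized NGF registration.

    Returns ``(DeformationField, report)``. The returned field lives on the
    fixed grid and already composes the rigid initialization: applying it
    to fixed-grid points (or warping the *original* moving volume with it)
    reproduces the full two-stage alignment.
    """
    config = config or RegistrationConfig()
    rig = init or RigidTransform.identity()

    if config.use_beam_mask:
        beam_f = estimate_beam_mask(fixed)
        beam_m = estimate_beam_mask(moving)
        bm_warped = BinaryMask.on_grid(fixed, _resample_through_rigid(
            beam_m.to_volume(), fixed, rig, order=0) > 0.5)
    else:
        beam_f = BinaryMask.on_grid(fixed, np.ones(fixed.shape, bool))
        bm_warped = beam_f
    cav = cavity_mask if (config.use_cavity_mask and cavity_mask is not None) \
        else None
    if cav is not None and config.image_smoothing > 0:
        # the distance sees band-limited images, so the cavity's (spurious)
        # edges bleed ~sigma voxels beyond the segmentation: dilate the
        # exclusion a little past the smoothing scale
        dil = int(np.ceil(config.image_smoothing)) + 1
        cav = BinaryMask.on_grid(fixed, ndimage.binary_dilation(
            cav.data, iterations=dil))
    try:
        mask = combine_masks(beam_f, bm_warped, cav)
    except ValueError as exc:
        raise ValueError(f"no common content: {exc}") from exc
    # noise-level (epsilon) estimation uses the beam intersection without
    # cavity exclusion, so masked and unmasked runs share one edge
    # parameter and differ only in the distance's support
    eps_mask = combine_masks(beam_f, bm_warped)

    moving_r = fixed.with_data(_resample_through_rigid(moving, fixed, rig))

    L = config.levels_deformable
    fix_pyr = _pyramid(fixed, L)
    mov_pyr = _pyramid(moving_r, L)
    mask_pyr = _mask_pyramid(mask, L)
    eps_mask_pyr = _mask_pyramid(eps_mask, L)

    u = np.zeros((3,) + tuple(fix_pyr[0].shape))
    report = []
    for lev in range(L):
        f, m, msk = fix_pyr[lev], mov_pyr[lev], mask_pyr[lev]
        if u.shape[1:] != tuple(f.shape):
            u = _prolong(u, tuple(f.shape))
        sigma = config.image_smoothing * 0.5 ** (L - 1 - lev)
        # beam-boundary gradients bleed ~sigma voxels inward on the
        # smoothed images: keep the distance's support clear of them
        ero = int(np.ceil(sigma)) + 1
        msk = _erode_mask(msk, ero)
        emsk = _erode_mask(eps_mask_pyr[lev], ero)
        if not msk.data.any():
            report.append(dict(level=lev, skipped="empty mask at this level"))
            continue
        u, info = _optimize_level(f, m, msk, u, config.ngf_epsilon, config,
                                  sigma, eps_mask=emsk)
        info["level"] = lev
        report.append(info)

    # compose with the rigid initialization on the fixed grid
    idx = np.indices(fixed.shape, dtype=float)
    world = np.einsum("ab,b...->a...", fixed.index_to_world, idx) \
        + fixed.origin[:, None, None, None]
    pts = world + u
    mapped = np.einsum("ab,b...->a...", rig.rotation,
                       pts - rig.center[:, None, None, None]) \
        + (rig.center + rig.translation)[:, None, None, None]
    u_total = mapped - world
    field = DeformationField.on_grid(fixed, u_total)
    return field, report


def _optimize_level(f: Volume3D, m: Volume3D, msk: BinaryMask,
                    u0: np.ndarray, eps: float | None,
                    config: RegistrationConfig, sigma: float = 0.0,
                    eps_mask: BinaryMask | None = None):
    if sigma > 0:
        f = f.with_data(ndimage.gaussian_filter(
            f.data.astype(np.float64), sigma))
        m = m.with_data(ndimage.gaussian_filter(
            m.data.astype(np.float64), sigma))
    if eps is None:
        eps = estimate_ngf_epsilon(f, m, eps_mask if eps_mask is not None
                                   and eps_mask.data.any() else msk)
    sp = f.spacing
    h = f.voxel_volume
    maskf = msk.data.astype(float)
    Nm = maskf.sum() * h
    Nv = np.prod(f.shape) * h
    R = f.data.astype(np.float64)
    gR = image_gradient(R, sp)
    nR = np.sqrt((gR ** 2).sum(axis=0) + eps ** 2)
    Mdata = m.data.astype(np.float64)
    Ainv = f.world_to_index
    base = np.indices(f.shape, dtype=float)
    shape = tuple(f.shape)
    w = config.regularizer_weight

    def fun(x):
        uu = x.reshape((3,) + shape)
        coords = base + np.einsum("ab,b...->a...", Ainv, uu)
        T, dT = _trilinear(Mdata, coords)
        Dval, qT = _ngf_core(gR, nR, T, maskf, sp, eps, h)
        fld = DeformationField.on_grid(f, uu)
        curv = curvature_energy(fld)
        J = Dval / Nm + w * curv["value"] / Nv
        # chain d D/d T through the trilinear warp to displacements (mm)
        gD = np.einsum("j...,ja->a...", dT * qT[None], Ainv)
        grad = gD / Nm + w * curv["gradient"] / Nv
        return OBJECTIVE_SCALE * J, OBJECTIVE_SCALE * grad.ravel()

    x, info = _minimize(fun, u0.ravel(), config, jac=True)
    info["epsilon"] = eps
    return x.reshape((3,) + shape), info


def transform_landmarks(points: LandmarkSet,
                        field: DeformationField) -> LandmarkSet:
    """Map fixed-volume landmarks through the field: ``p -> p + u(p)``."""
    grid = Volume3D(np.zeros((1, 1, 1), np.float32), field.spacing,
                    field.origin, field.direction)
    idx = (points.points_fixed - grid.origin) @ grid.world_to_index.T
    shape = np.array(field.shape)
    bad = [lab for lab, ix in zip(points.labels, idx)
           if np.any(ix < 0) or np.any(ix > shape - 1)]
    if bad:
        raise ValueError(f"landmarks outside the field domain: {bad}")
    u = np.stack([
        ndimage.map_coordinates(field.displacements[c], idx.T, order=1,
                                mode="nearest") for c in range(3)], axis=1)
    return LandmarkSet(points.points_fixed + u, points.points_moving.copy(),
                       list(points.labels))
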