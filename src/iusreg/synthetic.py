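"""Ultrasound-like phantom pairs with known deformation, cavity, and landmarks.

The generator emulates the situation this package targets: two 3D ultrasound
volumes of the same brain taken at successive resection stages. The
"moving" volume plays the pre-resection acquisition; the "fixed" volume is
the same tissue deformed by a known smooth field, with a resection cavity
carved in -- a hypoechoic (dark) interior surrounded by a hyperechoic
(bright) rim -- that has no counterpart in the moving volume. Both volumes
are zero outside a cone-shaped beam region, and speckle is re-sampled
independently per volume so the pair never matches voxel-for-voxel.

This is deliberately not a physical ultrasound simulation: there is no
point-spread function, attenuation or reverberation. Speckle is
multiplicative log-normal texture, enough to exercise a gradient-based
distance measure.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield

import numpy as np
from scipy import ndimage

from .grids import BinaryMask, DeformationField, LandmarkSet, Volume3D

__all__ = ["PhantomSpec", "PhantomPair", "make_deformation", "warp_volume",
           "warp_mask", "make_pair"]


@dataclass
class PhantomSpec:
    """All tunables of the phantom generator.

    Distances are mm. The beam cone opens along +x (axis 0) from an apex
    sitting above the volume, mimicking a probe at the top surface.
    """

    shape: tuple = (64, 64, 64)
    spacing: tuple = (0.5, 0.5, 0.5)
    n_blobs: int = 12
    base_intensity: float = 40.0
    speckle_sigma: float = 0.25
    # beam cone
    cone_apex: tuple = (-4.0, 16.0, 16.0)
    cone_half_angle_deg: float = 30.0
    # resection cavity (fixed volume only); radius 0 disables it entirely
    cavity_center: tuple = (18.0, 16.0, 16.0)
    cavity_radius: float = 4.0
    rim_thickness: float = 1.5
    rim_gain: float = 2.5
    cavity_gain: float = 0.12
    # ground-truth deformation
    control_grid: int = 5
    max_displacement: float = 3.0
    n_landmarks: int = 10
    seed: int = 0

    def __post_init__(self):
        self.shape = tuple(int(s) for s in self.shape)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.cavity_radius < 0 or self.rim_thickness < 0:
            raise ValueError("cavity radius and rim thickness must be >= 0")
        if self.cavity_radius > 0:
            if self.max_displacement >= self.cavity_radius:
                raise ValueError(
                    "max displacement must be smaller than the cavity radius "
                    "(landmarks must not cross into the cavity)")
            grid = _reference_grid(self)
            cav = _cavity_dist(grid, self) <= self.cavity_radius + self.rim_thickness
            if not np.all(_cone_mask_array(grid, self)[cav]):
                raise ValueError("beam cone does not contain the cavity entirely")


def _reference_grid(spec: PhantomSpec) -> Volume3D:
    return Volume3D(np.zeros(spec.shape, dtype=np.float32),
                    spacing=spec.spacing)


def _world_coords(grid: Volume3D) -> np.ndarray:
    """(3, nx, ny, nz) world coordinates of every voxel."""
    idx = np.indices(grid.shape, dtype=float)
    A = grid.index_to_world
    return np.einsum("ab,b...->a...", A, idx) + grid.origin[:, None, None, None]


def _cone_mask_array(grid: Volume3D, spec: PhantomSpec) -> np.ndarray:
    w = _world_coords(grid)
    apex = np.asarray(spec.cone_apex, dtype=float)
    v = w - apex[:, None, None, None]
    axial = v[0]
    radial = np.sqrt(v[1] ** 2 + v[2] ** 2)
    half = np.deg2rad(spec.cone_half_angle_deg)
    return (axial > 0) & (radial <= np.tan(half) * axial)


def _cavity_dist(grid: Volume3D, spec: PhantomSpec) -> np.ndarray:
    w = _world_coords(grid)
    c = np.asarray(spec.cavity_center, dtype=float)
    return np.sqrt(((w - c[:, None, None, None]) ** 2).sum(axis=0))


def make_deformation(spec: PhantomSpec) -> DeformationField:
    """Synthesize a smooth random deformation with known maximum magnitude.

    Random displacements are drawn on a coarse control grid whose boundary
    nodes are pinned to zero, cubically upsampled to the full grid, and
    rescaled so the maximum magnitude equals ``spec.max_displacement``
    exactly. Deterministic for a given seed.
    """
    rng = np.random.default_rng(spec.seed)
    g = max(int(spec.control_grid), 3)
    ctrl = rng.standard_normal((3, g, g, g))
    ctrl[:, [0, -1], :, :] = 0.0
    ctrl[:, :, [0, -1], :] = 0.0
    ctrl[:, :, :, [0, -1]] = 0.0
    if spec.max_displacement == 0:
        u = np.zeros((3,) + spec.shape)
        return DeformationField.on_grid(_reference_grid(spec), u)
    u = np.empty((3,) + spec.shape)
    zoom = [n / g for n in spec.shape]
    for c in range(3):
        u[c] = ndimage.zoom(ctrl[c], zoom, order=3, mode="nearest",
                            grid_mode=True)
    # pin the field to exactly zero on the boundary with a smooth taper
    taper = np.ones(spec.shape)
    for ax, n in enumerate(spec.shape):
        ramp = np.minimum(np.arange(n), np.arange(n)[::-1]) / 3.0
        shape1 = [1, 1, 1]
        shape1[ax] = n
        taper = taper * np.minimum(ramp, 1.0).reshape(shape1)
    u *= taper
    mag = np.sqrt((u ** 2).sum(axis=0))
    peak = mag.max()
    if peak > 0:
        u *= spec.max_displacement / peak
    return DeformationField.on_grid(_reference_grid(spec), u)


def _index_displacement(field: DeformationField) -> np.ndarray:
    """Convert mm world displacements to fractional index displacements."""
    grid = Volume3D(np.zeros((1, 1, 1), np.float32), field.spacing,
                    field.origin, field.direction)
    Ainv = grid.world_to_index
    return np.einsum("ab,b...->a...", Ainv, field.displacements)


def warp_volume(volume: Volume3D, field: DeformationField,
                interpolation: str = "linear") -> Volume3D:
    """Pull-back warp: ``out(x) = in(x + u(x))``, out-of-domain samples -> 0."""
    if tuple(volume.shape) != tuple(field.shape):
        raise ValueError(
            f"field grid {field.shape} does not match volume {volume.shape}")
    order = {"linear": 1, "nearest": 0}[interpolation]
    d_idx = _index_displacement(field)
    coords = np.indices(volume.shape, dtype=float) + d_idx
    out = ndimage.map_coordinates(volume.data.astype(np.float64), coords,
                                  order=order, mode="constant", cval=0.0)
    return volume.with_data(out)


def warp_mask(mask: BinaryMask, field: DeformationField) -> BinaryMask:
    vol = mask.to_volume()
    warped = warp_volume(vol, field, interpolation="nearest")
    return BinaryMask(warped.data > 0.5, mask.spacing, mask.origin,
                      mask.direction)


def _speckle(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    if sigma == 0:
        return np.ones(shape)
    g = ndimage.gaussian_filter(rng.standard_normal(shape), 0.8)
    g /= g.std()
    return np.exp(sigma * g - 0.5 * sigma ** 2)


def _tissue(rng: np.random.Generator, grid: Volume3D,
            spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free tissue intensities plus the blob centers (world mm)."""
    w = _world_coords(grid)
    tex = np.full(grid.shape, spec.base_intensity)
    half = np.deg2rad(spec.cone_half_angle_deg)
    apex = np.asarray(spec.cone_apex)
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    centers = []
    tries = 0
    while len(centers) < spec.n_blobs and tries < 200 * spec.n_blobs:
        tries += 1
        depth = rng.uniform(0.25 * extent[0], 0.9 * extent[0])
        r_max = np.tan(half) * (depth - apex[0])
        ang = rng.uniform(0, 2 * np.pi)
        rad = rng.uniform(0, 0.75 * r_max)
        c = np.array([depth, apex[1] + rad * np.cos(ang),
                      apex[2] + rad * np.sin(ang)])
        if np.any(c < 1.5) or np.any(c > extent - 1.5):
            continue
        centers.append(c)
    centers = np.array(centers) if centers else np.zeros((0, 3))
    for c in centers:
        sig = rng.uniform(1.5, 3.5)
        amp = rng.uniform(25.0, 70.0)
        d2 = ((w - c[:, None, None, None]) ** 2).sum(axis=0)
        tex += amp * np.exp(-0.5 * d2 / sig ** 2)
    return tex, centers


@dataclass
class PhantomPair:
    fixed: Volume3D
    moving: Volume3D
    cavity_mask: BinaryMask
    beam_mask: BinaryMask
    true_field: DeformationField
    landmarks: LandmarkSet
    spec: PhantomSpec = dfield(repr=False, default=None)


def _sample_field_at(field: DeformationField, points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of the field at (N, 3) world points -> (N, 3) mm."""
    grid = Volume3D(np.zeros((1, 1, 1), np.float32), field.spacing,
                    field.origin, field.direction)
    idx = (np.atleast_2d(points_mm) - grid.origin) @ grid.world_to_index.T
    out = np.stack([
        ndimage.map_coordinates(field.displacements[c], idx.T, order=1,
                                mode="nearest")
        for c in range(3)], axis=1)
    return out


def make_pair(spec: PhantomSpec) -> PhantomPair:
    """Generate one fixed/moving phantom pair with full ground truth.

    The moving volume is the pre-resection phantom. The fixed volume is the
    same tissue pulled back through ``true_field`` (so a fixed-grid point x
    corresponds to moving-space point x + u(x)), with the cavity carved in
    and speckle drawn independently. Landmark pairs satisfy
    ``p_moving = p_fixed + u(p_fixed)`` by construction.
    """
    rng = np.random.default_rng(spec.seed)
    grid = _reference_grid(spec)
    cone = _cone_mask_array(grid, spec)

    tissue, blob_centers = _tissue(rng, grid, spec)
    moving_data = tissue * _speckle(rng, spec.shape, spec.speckle_sigma)
    moving_data[~cone] = 0.0
    moving = grid.with_data(moving_data)

    true_field = make_deformation(
        PhantomSpec(**{**spec.__dict__, "seed": spec.seed + 7919}))

    fixed_tissue = warp_volume(grid.with_data(tissue), true_field).data
    fixed_data = fixed_tissue * _speckle(rng, spec.shape, spec.speckle_sigma)

    dist = _cavity_dist(grid, spec)
    if spec.cavity_radius > 0:
        interior = dist <= spec.cavity_radius
        rim = (dist > spec.cavity_radius) & (
            dist <= spec.cavity_radius + spec.rim_thickness)
        fixed_data[interior] *= spec.cavity_gain
        fixed_data[rim] *= spec.rim_gain
        cavity = interior | rim
    else:
        cavity = np.zeros(spec.shape, dtype=bool)
    fixed_data[~cone] = 0.0
    fixed = grid.with_data(fixed_data)

    landmarks = _place_landmarks(spec, grid, true_field, blob_centers, dist)

    return PhantomPair(
        fixed=fixed,
        moving=moving,
        cavity_mask=BinaryMask.on_grid(grid, cavity),
        beam_mask=BinaryMask.on_grid(grid, cone),
        true_field=true_field,
        landmarks=landmarks,
        spec=spec,
    )


def _place_landmarks(spec, grid, true_field, blob_centers, cavity_dist):
    """Landmarks at blob centers, outside the cavity, exact under the field.

    A blob lives at moving-space point c; the corresponding fixed-grid point
    p solves p + u(p) = c, found by fixed-point iteration. The moving point
    is then *defined* as p + u(p), so the pair is exact under trilinear
    interpolation of the field.
    """
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    keep_margin = spec.cavity_radius + spec.rim_thickness + 1.0
    cav_c = np.asarray(spec.cavity_center)
    fixed_pts, moving_pts = [], []
    for c in blob_centers:
        p = c.copy()
        for _ in range(20):
            u = _sample_field_at(true_field, p[None])[0]
            p_new = c - u
            if np.linalg.norm(p_new - p) < 1e-10:
                p = p_new
                break
            p = p_new
        if np.any(p < 1.0) or np.any(p > extent - 1.0):
            continue
        if spec.cavity_radius > 0 and np.linalg.norm(p - cav_c) < keep_margin:
            continue
        u = _sample_field_at(true_field, p[None])[0]
        fixed_pts.append(p)
        moving_pts.append(p + u)
        if len(fixed_pts) >= spec.n_landmarks:
            break
    if not fixed_pts:
        raise ValueError("could not place any landmark outside the cavity; "
                         "relax the phantom spec")
    return LandmarkSet(np.array(fixed_pts), np.array(moving_pts))
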