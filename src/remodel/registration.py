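"""Rigid 3D registration, mask generation, and common-region computation.

The later scan is aligned to the earlier one by minimizing the mean squared
intensity error over a 3-level image pyramid (downsampling factor 2), with
the six rigid parameters scaled so a unit step moves a peripheral point by
roughly one voxel.  Compartment masks come from threshold + morphology
segmentation; all remodeling and mechanics are restricted to the overlap of
the two scans' bone masks (the common region).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .images import (BoneMasks, DensityImage, RigidTransform3D, domain_mask,
                     index_affine, resample, resample_mask, warp_values)

__all__ = ["RegistrationResult", "register_rigid", "align_to_axis",
           "generate_masks", "common_region"]


@dataclass
class RegistrationResult:
    transform: RigidTransform3D
    final_mse: float
    pyramid_levels: int
    converged: bool

    def __post_init__(self) -> None:
        if self.final_mse < 0:
            raise ValueError("MSE cannot be negative")


def _correlation_shift(fixed: DensityImage, moving: DensityImage,
                       smooth: float = 0.0) -> np.ndarray:
    """Integer-voxel translation estimate by FFT cross-correlation.

    Returns the physical (x, y, z) displacement of the moving image content
    relative to the fixed image, i.e. the translation of the resampling
    transform that re-aligns it.  With ``smooth`` > 0 both images are
    low-passed first so the peak reflects the large-scale (cortical shell)
    alignment rather than a trabecular-lattice period; the sharp and the
    smoothed estimate are complementary initializations.
    """
    f, m = fixed.values, moving.values
    if smooth > 0:
        f = ndimage.gaussian_filter(f, smooth)
        m = ndimage.gaussian_filter(m, smooth)
    f = f - f.mean()
    m = m - m.mean()
    cc = np.fft.ifftn(np.fft.fftn(m) * np.conj(np.fft.fftn(f))).real
    peak = np.array(np.unravel_index(np.argmax(cc), cc.shape), dtype=float)
    shape = np.array(cc.shape, dtype=float)
    peak[peak > shape / 2] -= shape[peak > shape / 2]   # wrap to signed shift
    return peak[::-1] * fixed.voxel_size                # (z,y,x) -> (x,y,z) mm


def _downsample(img: DensityImage) -> DensityImage:
    smoothed = ndimage.gaussian_filter(img.values, 1.0)
    return DensityImage(smoothed[::2, ::2, ::2], img.voxel_size * 2, img.origin)


def _mse(fixed: np.ndarray, moving: DensityImage,
         transform: RigidTransform3D) -> float:
    warped = warp_values(moving, transform, order=1, cval=np.nan)
    valid = ~np.isnan(warped)
    if not valid.any():
        return float(np.mean(fixed ** 2))
    diff = (fixed - warped)[valid]
    return float(np.mean(diff * diff))


class _SampledMSE:
    """MSE over a strided subset of fixed voxels (linear interpolation).

    Point sampling makes one metric evaluation O(n_points) instead of
    O(n_voxels); sample points whose transformed position leaves the moving
    image domain are excluded from the mean.
    """

    def __init__(self, fixed: DensityImage, moving: DensityImage, stride: int,
                 order: int = 1):
        nz, ny, nx = fixed.shape
        grid = np.mgrid[0:nz:stride, 0:ny:stride, 0:nx:stride]
        self.points = grid.reshape(3, -1).astype(float)   # (3, n) index coords
        self.fvals = fixed.values[::stride, ::stride, ::stride].ravel().astype(float)
        self.moving = moving
        self.order = order
        if order > 1:
            self._data = ndimage.spline_filter(moving.values.astype(float),
                                               order=order)
        else:
            self._data = moving.values.astype(float)

    def __call__(self, transform: RigidTransform3D) -> float:
        M, off = index_affine(self.moving, transform)
        coords = M @ self.points + off[:, None]
        sampled = ndimage.map_coordinates(self._data, coords,
                                          order=self.order, mode="constant",
                                          cval=np.nan, prefilter=False)
        valid = ~np.isnan(sampled)
        # guard against overlap collapse: shrinking the overlap into an
        # air-only corner would otherwise yield a spurious near-zero MSE
        if valid.mean() < 0.4:
            return float(np.mean(self.fvals ** 2))
        diff = self.fvals[valid] - sampled[valid]
        return float(np.mean(diff * diff))


def register_rigid(fixed: DensityImage, moving: DensityImage, levels: int = 3,
                   init: RigidTransform3D | None = None) -> RegistrationResult:
    """Recover the rigid transform mapping ``moving`` into ``fixed``'s frame.

    The returned transform is a resampling transform: ``resample(moving, T)``
    is aligned with ``fixed``.  Optimization runs coarse to fine; MSE is
    evaluated only where the warped moving image is in-domain.  Convergence
    failure is reported via ``converged=False``, never an exception.
    """
    if abs(fixed.voxel_size - moving.voxel_size) > 1e-9:
        raise ValueError("images must share a voxel size")
    if np.ptp(fixed.values) == 0 or np.ptp(moving.values) == 0:
        raise ValueError("no gradient information: constant image")

    center = tuple(fixed.center_physical())

    pyr_fixed, pyr_moving = [fixed], [moving]
    for _ in range(levels - 1):
        pyr_fixed.append(_downsample(pyr_fixed[-1]))
        pyr_moving.append(_downsample(pyr_moving[-1]))

    # scale: one parameter unit ~ one fine-level voxel of peripheral motion
    extent = 0.5 * max(fixed.shape) * fixed.voxel_size
    rot_scale = fixed.voxel_size / extent     # rad per unit
    trans_scale = fixed.voxel_size            # mm per unit

    def to_params(T: RigidTransform3D) -> np.ndarray:
        return np.concatenate([np.asarray(T.rotation) / rot_scale,
                               np.asarray(T.translation) / trans_scale])

    def to_transform(p: np.ndarray) -> RigidTransform3D:
        return RigidTransform3D(tuple(p[:3] * rot_scale),
                                tuple(p[3:] * trans_scale), center)

    init_from_correlation = init is None
    if init is not None:
        starts = [to_params(init)]
    else:
        # multi-start: FFT cross-correlation translation seeds, sharp (exact
        # under small rotation, but a quasi-periodic trabecular lattice can
        # alias it by one period) and low-passed (tracks the large-scale
        # cortical alignment); the coarsest pyramid level is cheap enough to
        # optimize from every candidate and keep the best basin
        init = RigidTransform3D.identity(center=center)
        cands = [_correlation_shift(fixed, moving),
                 _correlation_shift(fixed, moving, smooth=4.0)]
        starts = []
        for shift in cands:
            p0 = np.concatenate([np.zeros(3), shift / trans_scale])
            if not any(np.abs(p0 - s).max() < 1.0 for s in starts):
                starts.append(p0)

    converged = True
    candidates = list(starts)
    for lvl in range(levels - 1, -1, -1):
        f, m = pyr_fixed[lvl], pyr_moving[lvl]
        metric = _SampledMSE(f, m, stride=2 if lvl <= 1 else 1)

        def cost(p):
            return metric(to_transform(p))

        optimized = []
        for p0 in candidates:
            # rotations first with translation held: the rotational cost has
            # no lattice-period local minima, and translation refinement
            # from a good rotation is reliable
            if lvl == levels - 1:
                t_hold = p0[3:].copy()
                rot_res = optimize.minimize(
                    lambda q: cost(np.concatenate([q, t_hold])), p0[:3],
                    method="Powell", options={"xtol": 1e-3, "ftol": 1e-9,
                                              "maxiter": 20})
                if rot_res.fun <= cost(p0):
                    p0 = np.concatenate([rot_res.x, t_hold])
            res = optimize.minimize(cost, p0, method="Powell",
                                    options={"xtol": 1e-4, "ftol": 1e-9,
                                             "maxiter": 30})
            p1, f1 = (res.x, res.fun) if res.fun <= cost(p0) else (p0, cost(p0))
            ok = bool(res.success or res.fun <= cost(p0))
            optimized.append((p1, f1, ok))
        # every candidate is carried through (and optimized at) the finest
        # level before one is chosen: the downsampled levels shrink a
        # quasi-periodic lattice's basin spacing and can strand or misrank
        # the true basin, while full resolution has the widest basins
        if lvl == 0:
            p1, _, level_ok = min(optimized, key=lambda t: t[1])
            candidates = [p1]
            converged = converged and level_ok
        else:
            candidates = [t[0] for t in optimized]

    # translational slip rescue: a quasi-periodic trabecular lattice offers
    # period-shifted basins along every lattice axis, and z-end clipping of
    # a section-type specimen biases the correlation seeds.  Exhaustive 1-D
    # probes over integer voxel offsets along each axis are cheap at the
    # sampled fine metric; re-polish only when a probe finds a substantially
    # better basin.
    metric0 = _SampledMSE(pyr_fixed[0], pyr_moving[0], stride=2)

    def cost0(p):
        return metric0(to_transform(p))

    params = candidates[0]
    base_cost = cost0(params)
    best_probe, best_cost = None, base_cost
    for axis in (3, 4, 5):
        for dv in range(-12, 13):
            if dv == 0:
                continue
            probe = params.copy()
            probe[axis] += dv
            c = cost0(probe)
            if c < best_cost:
                best_probe, best_cost = probe, c
    if best_probe is not None and best_cost < 0.8 * base_cost:
        res = optimize.minimize(cost0, best_probe, method="Powell",
                                options={"xtol": 1e-4, "ftol": 1e-9,
                                         "maxiter": 30})
        if res.fun < base_cost:
            params = res.x

    transform = to_transform(params)
    final_mse = _mse(fixed.values.astype(np.float64), moving, transform)
    init_mse = _mse(fixed.values.astype(np.float64), moving, init)
    return RegistrationResult(transform=transform, final_mse=final_mse,
                              pyramid_levels=levels,
                              converged=converged and final_mse <= init_mse)


def align_to_axis(image: DensityImage,
                  bone_threshold: float = 320.0) -> tuple[DensityImage, RigidTransform3D]:
    """Rotate the bone's principal (longitudinal) axis onto the grid z-axis.

    The longitudinal axis is the inertia-tensor eigenvector with the smallest
    moment of the thresholded bone voxel cloud; it is invariant to uniform
    density rescaling.  Raises if no dominant axis exists.
    """
    bone = image.values >= bone_threshold
    if not bone.any():
        raise ValueError("no bone voxels above threshold")
    idx = np.argwhere(bone).astype(float)          # (z, y, x)
    pts = idx[:, ::-1] * image.voxel_size          # (x, y, z) mm
    pts = pts + np.asarray(image.origin)
    centroid = pts.mean(axis=0)
    d = pts - centroid
    cov = d.T @ d / len(d)
    # inertia tensor of unit point masses
    inertia = np.trace(cov) * np.eye(3) - cov
    w, v = np.linalg.eigh(inertia)
    if (w[1] - w[0]) < 0.05 * w[2]:
        raise ValueError("no dominant longitudinal axis (nearly isotropic)")
    axis = v[:, 0]
    if axis[2] < 0:
        axis = -axis
    zhat = np.array([0.0, 0.0, 1.0])
    # rotation taking `axis` onto z
    cross = np.cross(axis, zhat)
    s, c = np.linalg.norm(cross), float(axis @ zhat)
    if s < 1e-12:
        R = np.eye(3)
    else:
        R = Rotation.from_rotvec(cross / s * np.arctan2(s, c)).as_matrix()
    A = np.eye(4)
    # resampling transform samples the input at T(p): invert the alignment
    A[:3, :3] = R.T
    T = RigidTransform3D.from_affine(A, center=tuple(centroid))
    return resample(image, T, interpolation="cubic"), T


def generate_masks(image: DensityImage, bone_threshold: float = 320.0,
                   cortical_threshold: float = 450.0,
                   transition_voxels: int = 2) -> BoneMasks:
    """Segment whole-bone, cortical and trabecular compartments.

    Threshold + morphology stand-in for contour-based segmentation: the whole
    mask is the filled largest connected component of the smoothed bone
    segmentation; cortical voxels exceed a density criterion and connect to
    the periosteal surface; trabecular is the remainder minus a transition
    band around the cortex.
    """
    from .morphometry import denoise

    smoothed = denoise(image).values
    bone = smoothed >= bone_threshold
    if not bone.any():
        raise ValueError("empty segmentation: no voxels above bone threshold")
    dense = smoothed >= cortical_threshold
    seed = dense if dense.any() else bone
    labels, nlab = ndimage.label(seed)
    largest = np.argmax(ndimage.sum_labels(seed, labels, range(1, nlab + 1))) + 1
    comp = _closing(labels == largest, 2)
    # fill the medullary cavity slice-wise: the cavity is open at both z
    # ends, so 3D hole filling would miss it
    whole = _fill2d(comp)

    # the medullary cavity is the largest sub-cortical-density region inside
    # the whole mask; closing bridges over trabecular struts (which touch
    # the endosteal surface, so pure connectivity cannot separate them from
    # the cortex) to recover the full lumen
    cavity = whole & ~dense
    lab2, n2 = ndimage.label(cavity)
    if n2 == 0:
        lumen = np.zeros_like(whole)
    else:
        largest2 = np.argmax(ndimage.sum_labels(cavity, lab2,
                                                range(1, n2 + 1))) + 1
        lumen = _fill2d(_closing(lab2 == largest2, 4,
                                 structure=np.ones((3, 3, 3), bool))) & whole
    cortical = dense & whole & ~lumen
    cortical = _closing(cortical, 1) & whole & ~lumen

    band = ndimage.binary_dilation(cortical, iterations=transition_voxels)
    trabecular = lumen & ~band
    return BoneMasks(whole=whole, cortical=cortical, trabecular=trabecular)


def _closing(mask: np.ndarray, iterations: int,
             structure: np.ndarray | None = None) -> np.ndarray:
    """Binary closing with edge padding (avoids border erosion artifacts)."""
    pad = iterations + 1
    padded = np.pad(mask, pad, mode="edge")
    closed = ndimage.binary_closing(padded, structure=structure,
                                    iterations=iterations, border_value=0)
    return closed[pad:-pad, pad:-pad, pad:-pad]


def _fill2d(mask: np.ndarray) -> np.ndarray:
    return np.stack([ndimage.binary_fill_holes(sl) for sl in mask])


def common_region(fixed_masks: BoneMasks, moving_masks: BoneMasks,
                  transform: RigidTransform3D,
                  image_like: DensityImage) -> np.ndarray:
    """Overlap region on which all downstream analysis is defined.

    Intersection of the fixed whole mask, the transformed moving whole mask,
    and the in-domain region of the resampling.
    """
    moved = resample_mask(moving_masks.whole, image_like, transform)
    valid = domain_mask(image_like, transform)
    region = fixed_masks.whole & moved & valid
    if not region.any():
        raise ValueError("empty common region: registration overlap is void")
    return region
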