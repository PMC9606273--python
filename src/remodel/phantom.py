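"""Synthetic paired-scan phantoms with known remodeling and misalignment.

Real repeat HR-pQCT scans of patients are not publicly available, so every
pipeline stage is validated against phantoms: a cortical shell plus a regular
trabecular rod lattice, imaged twice.  The follow-up differs from baseline by
(i) surface remodeling driven by a known strain-threshold rule, (ii) a rigid
repositioning misalignment, and (iii) fresh additive noise.  The generator
records ground truth (transform, per-voxel labels, rule) so registration,
dynamic morphometry and mechanoregulation recovery can all be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .images import (DEFAULT_VOXEL_SIZE, BoneMasks, DensityImage,
                     RigidTransform3D, resample)

__all__ = ["PhantomParams", "MechanoregRule", "PhantomTruth", "make_phantom",
           "simulate_followup", "surrogate_strain", "add_noise"]

#: Standardized mineral density threshold separating bone from background.
STANDARD_THRESHOLD = 320.0

#: Density written into remodeled voxels (newly mineralized packet / marrow).
FORMED_DENSITY = 650.0
RESORBED_DENSITY = 50.0

# 6-connectivity structuring element (face neighbours)
FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

# lexicographic (z, y, x) face-neighbour offsets, fixed for tie-breaking
FACE_OFFSETS = ((-1, 0, 0), (0, -1, 0), (0, 0, -1),
                (0, 0, 1), (0, 1, 0), (1, 0, 0))


@dataclass
class PhantomParams:
    """Geometry, density and noise parameters of the phantom.

    Densities are mg HA/cm^3; lengths are mm.  Defaults emulate a distal
    radius section at desk scale: a dense cortical annulus around a cubic
    rod lattice of trabecular bone in low-density marrow.
    """

    shape: tuple[int, int, int] = (48, 96, 96)  # air margin fits <=20 vx misalignment
    voxel_size: float = DEFAULT_VOXEL_SIZE
    outer_radius: float = 1.45
    inner_radius: float = 1.05
    cortical_density: float = 900.0
    trabecular_density: float = 650.0
    marrow_density: float = 50.0
    strut_spacing: float = 0.55
    strut_thickness: float = 0.18
    taper: float = 0.15   # fractional narrowing of the lumen toward z-max
    undulation: float = 0.05  # fractional radius modulation along z
    aspect: tuple[float, float] = (1.05, 0.85)  # (x, y) ellipse factors
    noise_sd: float = 60.0
    blur_sd: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.inner_radius < self.outer_radius:
            raise ValueError("inner radius must be smaller than outer radius")
        for d in (self.cortical_density, self.trabecular_density,
                  self.marrow_density):
            if not 0 <= d <= 1200:
                raise ValueError(f"density {d} outside [0, 1200] mg HA/cm^3")
        if self.strut_thickness < 2 * self.voxel_size:
            raise ValueError(
                f"strut thickness {self.strut_thickness} mm is below two "
                f"voxels ({2 * self.voxel_size} mm): unresolvable structure")


@dataclass
class MechanoregRule:
    """Strain-threshold remodeling rule used to generate the follow-up.

    Surface sites below ``resorption_threshold_true`` (normalized strain)
    resorb, sites above ``formation_threshold_true`` add bone; between the
    two lies the lazy zone (quiescence).  ``event_rate`` is the fraction of
    surface voxels active over the interval; an active site follows the rule
    with probability ``obedience`` and otherwise takes one of the two other
    outcomes at random.
    """

    resorption_threshold_true: float = 0.08
    formation_threshold_true: float = 0.23
    obedience: float = 0.9
    event_rate: float = 0.7

    def __post_init__(self) -> None:
        if not 0 <= self.resorption_threshold_true < self.formation_threshold_true <= 1:
            raise ValueError("need 0 <= Tr* < Tf* <= 1")
        if not (0 <= self.obedience <= 1 and 0 <= self.event_rate <= 1):
            raise ValueError("obedience and event_rate must lie in [0, 1]")


@dataclass
class PhantomTruth:
    """Ground truth of a simulated follow-up (on the baseline grid)."""

    applied_transform: RigidTransform3D
    formed: np.ndarray
    resorbed: np.ndarray
    quiescent: np.ndarray
    rule: MechanoregRule

    def counts(self) -> dict[str, int]:
        return {"formed": int(self.formed.sum()),
                "resorbed": int(self.resorbed.sum()),
                "quiescent": int(self.quiescent.sum())}


def lattice_volume_fraction(params: PhantomParams) -> float:
    """Analytic volume fraction of the 3-axis square-rod lattice.

    Three orthogonal families of square rods (side t) on a cubic lattice of
    pitch s, by inclusion-exclusion: 3(t/s)^2 - 2(t/s)^3.
    """
    a = params.strut_thickness / params.strut_spacing
    return 3 * a**2 - 2 * a**3


def _geometry(params: PhantomParams, z_lo: int = 0, nz_total: int | None = None):
    """Noise-free density field and exact compartment masks.

    ``z_lo`` and ``nz_total`` evaluate the same continuous geometry on an
    axially extended window (the bone continues beyond the scanned section).
    """
    nz, ny, nx = params.shape
    if nz_total is not None:
        nz = nz_total
    vs = params.voxel_size
    yy, xx = np.meshgrid(np.arange(ny, dtype=float), np.arange(nx, dtype=float),
                         indexing="ij")
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # elliptical cross-section (a long bone is not circular); the anisotropy
    # also makes in-plane rotation identifiable for registration
    ax, ay = params.aspect
    r = np.hypot((yy - cy) * vs / ay, (xx - cx) * vs / ax)
    # the cortex thickens toward z-max (metaphyseal-to-diaphyseal taper) and
    # the whole cross-section undulates gently along the shaft, as real
    # diaphyses do; this longitudinal structure is what makes z-registration
    # well-posed — without it a periodic lattice leaves period-shifted
    # alignments nearly as good as the true one
    z_coords = np.arange(z_lo, z_lo + nz, dtype=float)
    zfrac = z_coords / max(params.shape[0] - 1, 1)
    wobble = 1.0 + params.undulation * np.cos(2 * np.pi * 1.5 * zfrac + 0.7)
    inner_z = params.inner_radius * (1.0 - params.taper * zfrac) * wobble
    outer_z = params.outer_radius * wobble
    lumen = r[None, :, :] < inner_z[:, None, None]
    annulus = (r[None, :, :] <= outer_z[:, None, None]) & ~lumen

    # rod lattice: struts along each axis on a cubic grid of pitch s
    s_vx = params.strut_spacing / vs
    t_vx = params.strut_thickness / vs
    half = t_vx / 2.0

    def on_grid(coord: np.ndarray) -> np.ndarray:
        # distance of voxel center to nearest lattice plane, in voxels
        d = np.abs((coord + half) % s_vx - half)
        return d <= half

    gz = on_grid(z_coords)[:, None, None]
    gy = on_grid(np.arange(ny, dtype=float))[None, :, None]
    gx = on_grid(np.arange(nx, dtype=float))[None, None, :]
    rods = (gy & gx) | (gz & gx) | (gz & gy)  # rods along z, y, x

    density = np.zeros((nz, ny, nx), dtype=np.float32)
    density[lumen] = params.marrow_density
    density[lumen & rods] = params.trabecular_density
    density[annulus] = params.cortical_density

    whole = annulus | lumen
    masks = BoneMasks(whole=whole, cortical=annulus.copy(),
                      trabecular=lumen.copy())
    return density, masks


_EXT_CACHE: dict = {}


def _extended_clean(params: PhantomParams, pad: int) -> np.ndarray:
    """Blurred clean geometry on a z-padded grid (cached; transform-free)."""
    key = (tuple(sorted(vars(params).items())), pad)
    if key not in _EXT_CACHE:
        ext, _ = _geometry(params, z_lo=-pad,
                           nz_total=params.shape[0] + 2 * pad)
        if params.blur_sd > 0:
            ext = ndimage.gaussian_filter(ext, params.blur_sd)
        if len(_EXT_CACHE) > 8:
            _EXT_CACHE.clear()
        _EXT_CACHE[key] = ext
    return _EXT_CACHE[key]


def add_noise(image: DensityImage, sd: float, rng: np.random.Generator) -> DensityImage:
    """Additive Gaussian image noise (mg HA/cm^3)."""
    if sd == 0:
        return image.like(image.values.copy())
    return image.like(image.values + rng.normal(0.0, sd, image.shape))


def make_phantom(params: PhantomParams | None = None) -> tuple[DensityImage, BoneMasks]:
    """Generate the baseline phantom image and its ground-truth masks.

    The noise-free geometry is blurred with a Gaussian of ``blur_sd`` voxels
    (partial-volume emulation at the surfaces), then Gaussian noise of
    ``noise_sd`` is added.  Masks come from the unblurred geometry.
    """
    params = params or PhantomParams()
    density, masks = _geometry(params)
    if params.blur_sd > 0:
        density = ndimage.gaussian_filter(density, params.blur_sd)
    img = DensityImage(density, params.voxel_size)
    rng = np.random.default_rng(params.seed)
    return add_noise(img, params.noise_sd, rng), masks


def surface_voxels(bone: np.ndarray) -> np.ndarray:
    """Bone voxels with at least one face neighbour outside bone."""
    interior = ndimage.binary_erosion(bone, structure=FACE_STRUCT,
                                      border_value=0)
    return bone & ~interior


def surrogate_strain(masks: BoneMasks, mode: str = "depth_ramp",
                     image: DensityImage | None = None) -> np.ndarray:
    """Per-voxel normalized strain field standing in for a micro-FE solve.

    ``depth_ramp`` increases linearly along z (higher strain distally),
    mirroring the axial gradient a compression test produces in a long bone;
    ``fe`` runs the voxel FE solver on ``image`` and uses its effective
    strain field.  Either way the output is normalized so its 99th
    percentile over whole-mask voxels equals 1.
    """
    if mode == "depth_ramp":
        nz, ny, nx = masks.whole.shape
        ramp = np.arange(nz, dtype=float) / max(nz - 1, 1)
        # mild radial modulation (periosteal fibers are loaded slightly more
        # than the core in bending-free compression of a tapered tube); keeps
        # strain linear in z at every (y, x) while spreading values
        # continuously across bins instead of one discrete value per slice
        yy, xx = np.meshgrid(np.arange(ny, dtype=float),
                             np.arange(nx, dtype=float), indexing="ij")
        r = np.hypot(yy - (ny - 1) / 2.0, xx - (nx - 1) / 2.0)
        rfrac = r / max(r.max(), 1.0)
        field = ramp[:, None, None] * (0.9 + 0.2 * rfrac)[None, :, :]
    elif mode == "fe":
        if image is None:
            raise ValueError("fe mode requires the density image")
        from .fe import MaterialLaw, build_mesh, solve_compression

        mesh = build_mesh(image, masks, MaterialLaw())
        result = solve_compression(mesh)
        grid = result.eff_strain_grid
        norm = np.percentile(grid[~np.isnan(grid)], 99)
        return np.nan_to_num(grid, nan=0.0) / norm
    else:
        raise ValueError(f"unknown strain mode {mode!r}")
    norm = np.percentile(field[masks.whole], 99)
    return field / norm


def simulate_followup(baseline: DensityImage, masks: BoneMasks,
                      strain_field: np.ndarray, rule: MechanoregRule,
                      misalignment: RigidTransform3D | None = None,
                      seed: int = 0, noise_sd: float = 0.0,
                      bone_threshold: float = STANDARD_THRESHOLD,
                      params: PhantomParams | None = None,
                      ) -> tuple[DensityImage, PhantomTruth]:
    """Apply mechanoregulated surface remodeling, misalign, and re-noise.

    Remodeling is one voxel deep: active surface voxels with normalized
    strain below Tr* lose their density to marrow; active surface voxels
    above Tf* deposit bone (trabecular density) into a face-adjacent
    background voxel.  Ground-truth labels are recorded on the baseline grid
    BEFORE the misalignment resample and noise.

    When ``params`` is given, the misaligned follow-up is produced as a
    scanner would produce it: the bone continues beyond the scanned section,
    so the image is resampled from an axially extended version of the
    geometry and cropped back to the window — the z-ends then contain real
    structure rather than a zero-fill band no repeat scan would show.
    """
    if strain_field.shape != baseline.shape:
        raise ValueError("strain_field is not congruent with the baseline grid")
    misalignment = misalignment or RigidTransform3D.identity()
    rng = np.random.default_rng(seed)

    bone = baseline.values >= bone_threshold
    surf = surface_voxels(bone)
    surf_idx = np.argwhere(surf)  # lexicographic (z, y, x) order
    n = len(surf_idx)

    active = rng.random(n) < rule.event_rate
    obeys = rng.random(n) < rule.obedience
    alt = rng.random(n)  # picks between the two non-rule outcomes

    values = baseline.values.copy()
    formed = np.zeros(baseline.shape, dtype=bool)
    resorbed = np.zeros(baseline.shape, dtype=bool)
    nz, ny, nx = baseline.shape

    for i, (z, y, x) in enumerate(surf_idx):
        if not active[i]:
            continue
        g = strain_field[z, y, x]
        if g < rule.resorption_threshold_true:
            action = "R"
        elif g > rule.formation_threshold_true:
            action = "F"
        else:
            action = "Q"
        if not obeys[i]:
            others = [a for a in ("R", "Q", "F") if a != action]
            action = others[0] if alt[i] < 0.5 else others[1]
        if action == "R":
            values[z, y, x] = RESORBED_DENSITY
            resorbed[z, y, x] = True
        elif action == "F":
            for dz, dy, dx in FACE_OFFSETS:
                zz, yy, xx = z + dz, y + dy, x + dx
                if not (0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx):
                    continue
                if not bone[zz, yy, xx] and not formed[zz, yy, xx]:
                    values[zz, yy, xx] = FORMED_DENSITY
                    formed[zz, yy, xx] = True
                    break
            # no free background neighbour: the action degrades to quiescence

    quiescent = bone & ~resorbed
    truth = PhantomTruth(applied_transform=misalignment, formed=formed,
                         resorbed=resorbed, quiescent=quiescent, rule=rule)
    followup = baseline.like(values)
    if params is not None:
        pad = 24
        ext = _extended_clean(params, pad).copy()
        ext[pad:pad + nz] = values
        ext_img = DensityImage(ext, baseline.voxel_size,
                               origin=(baseline.origin[0], baseline.origin[1],
                                       baseline.origin[2] - pad * baseline.voxel_size))
        warped = resample(ext_img, misalignment, interpolation="cubic")
        followup = baseline.like(warped.values[pad:pad + nz])
    else:
        followup = resample(followup, misalignment, interpolation="cubic")
    followup = add_noise(followup, noise_sd, rng)
    return followup, truth
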