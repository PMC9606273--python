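"""Calibrated 3D density images, binary compartment masks, and rigid transforms.

The common currency of the pipeline is a :class:`DensityImage`: a 3D grid of
volumetric bone mineral density (mg HA/cm^3) on isotropic voxels.  Arrays are
indexed ``(z, y, x)`` with ``z`` the longitudinal / loading axis; physical
coordinates are ``(x, y, z)`` in mm with the voxel-center convention
``p = origin + index * voxel_size``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

__all__ = [
    "DensityImage",
    "BoneMasks",
    "RigidTransform3D",
    "read_image",
    "write_image",
    "resample",
]

#: Default HR-pQCT voxel edge length in mm (second-generation scanner protocol).
DEFAULT_VOXEL_SIZE = 0.0607


@dataclass
class DensityImage:
    """A calibrated volumetric BMD image.

    Parameters
    ----------
    values :
        3D float array, axis order ``(z, y, x)``, in mg HA/cm^3.
    voxel_size :
        Isotropic voxel edge length in mm.
    origin :
        Physical ``(x, y, z)`` position of voxel ``(0, 0, 0)`` in mm.
    """

    values: np.ndarray
    voxel_size: float = DEFAULT_VOXEL_SIZE
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.values.ndim}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("density values must be finite")
        if not self.voxel_size > 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        self.origin = tuple(float(c) for c in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def center_physical(self) -> np.ndarray:
        """Physical (x, y, z) coordinate of the grid center, mm."""
        nz, ny, nx = self.shape
        idx_center = (np.array([nx, ny, nz], dtype=float) - 1) / 2.0
        return np.asarray(self.origin) + idx_center * self.voxel_size

    def like(self, values: np.ndarray) -> "DensityImage":
        """New image with the same grid metadata and different values."""
        return DensityImage(values, self.voxel_size, self.origin)


@dataclass
class BoneMasks:
    """Whole-bone, cortical, and trabecular binary masks on one grid.

    Invariants: cortical and trabecular are disjoint and both contained in
    the whole mask (a transition band between compartments may belong to
    whole only).
    """

    whole: np.ndarray
    cortical: np.ndarray
    trabecular: np.ndarray

    def __post_init__(self) -> None:
        self.whole = np.asarray(self.whole, dtype=bool)
        self.cortical = np.asarray(self.cortical, dtype=bool)
        self.trabecular = np.asarray(self.trabecular, dtype=bool)
        if not (self.whole.shape == self.cortical.shape == self.trabecular.shape):
            raise ValueError("mask grids must be congruent")
        if np.any(self.cortical & self.trabecular):
            raise ValueError("cortical and trabecular masks overlap")
        if np.any(self.cortical & ~self.whole) or np.any(self.trabecular & ~self.whole):
            raise ValueError("compartment masks must lie inside the whole mask")

    def compartment(self, name: str) -> np.ndarray:
        try:
            return {"whole": self.whole, "cortical": self.cortical,
                    "trabecular": self.trabecular}[name]
        except KeyError:
            raise KeyError(f"unknown compartment {name!r}") from None


@dataclass
class RigidTransform3D:
    """Rigid transform: rotation (Euler angles), translation, rotation center.

    ``rotation`` holds fixed-axis Euler angles ``(rz, ry, rx)`` in radians;
    the rotation matrix is ``R = Rz(rz) @ Ry(ry) @ Rx(rx)`` acting on
    physical ``(x, y, z)`` coordinates.  A point maps as
    ``p' = R @ (p - center) + center + translation``.
    """

    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.rotation = tuple(float(a) for a in self.rotation)
        self.translation = tuple(float(t) for t in self.translation)
        self.center = tuple(float(c) for c in self.center)
        if not all(np.isfinite(self.rotation + self.translation + self.center)):
            raise ValueError("transform parameters must be finite")

    @classmethod
    def identity(cls, center=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        return cls(center=center)

    def matrix(self) -> np.ndarray:
        """3x3 rotation matrix on (x, y, z) physical coordinates."""
        rz, ry, rx = self.rotation
        # scipy extrinsic 'xyz': R = Rz(rz) @ Ry(ry) @ Rx(rx)
        return Rotation.from_euler("xyz", [rx, ry, rz]).as_matrix()

    def affine(self) -> np.ndarray:
        """Homogeneous 4x4 matrix equivalent to apply()."""
        R = self.matrix()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        A = np.eye(4)
        A[:3, :3] = R
        A[:3, 3] = c + t - R @ c
        return A

    @classmethod
    def from_affine(cls, A: np.ndarray, center=(0.0, 0.0, 0.0)) -> "RigidTransform3D":
        R = np.asarray(A)[:3, :3]
        rx, ry, rz = Rotation.from_matrix(R).as_euler("xyz")
        c = np.asarray(center, dtype=float)
        t = (A[:3, :3] @ c + A[:3, 3]) - c
        return cls(rotation=(rz, ry, rx), translation=tuple(t), center=tuple(c))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map physical (x, y, z) points (..., 3) through the transform."""
        p = np.asarray(points, dtype=float)
        R = self.matrix()
        c = np.asarray(self.center)
        t = np.asarray(self.translation)
        return (p - c) @ R.T + c + t

    def compose(self, other: "RigidTransform3D") -> "RigidTransform3D":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        A = self.affine() @ other.affine()
        return RigidTransform3D.from_affine(A, center=self.center)

    def inverse(self) -> "RigidTransform3D":
        R = self.matrix()
        rx, ry, rz = Rotation.from_matrix(R.T).as_euler("xyz")
        t = -R.T @ np.asarray(self.translation)
        return RigidTransform3D(rotation=(rz, ry, rx), translation=tuple(t),
                                center=self.center)

    def parameters(self) -> np.ndarray:
        """(rz, ry, rx, tx, ty, tz) parameter vector."""
        return np.array(self.rotation + self.translation, dtype=float)

    def to_dict(self) -> dict:
        return {"rotation_zyx_rad": list(self.rotation),
                "translation_xyz_mm": list(self.translation),
                "center_xyz_mm": list(self.center)}

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform3D":
        return cls(tuple(d["rotation_zyx_rad"]), tuple(d["translation_xyz_mm"]),
                   tuple(d["center_xyz_mm"]))


# ---------------------------------------------------------------------------
# Resampling

_ORDER = {"cubic": 3, "linear": 1, "nearest": 0}


def resample(image: DensityImage, transform: RigidTransform3D,
             interpolation: str = "cubic", fill: float = 0.0) -> DensityImage:
    """Resample an image through a rigid transform onto its own grid.

    The output value at physical point ``p`` is the input sampled at
    ``transform(p)`` (the transform maps the fixed/output frame into the
    moving/input frame, as in ITK resampling).  Points falling outside the
    input domain take ``fill`` (default 0 mg HA/cm^3 = air/marrow, neutral
    under all analysis thresholds).
    """
    try:
        order = _ORDER[interpolation]
    except KeyError:
        raise ValueError(f"unknown interpolation {interpolation!r}") from None
    return image.like(warp_values(image, transform, order, fill))


def index_affine(image: DensityImage,
                 transform: RigidTransform3D) -> tuple[np.ndarray, np.ndarray]:
    """Index-space (z, y, x) affine ``idx_in = M @ idx_out + off`` of a transform."""
    R = transform.matrix()
    c = np.asarray(transform.center)
    t = np.asarray(transform.translation)
    origin = np.asarray(image.origin)
    vs = image.voxel_size
    P = np.eye(3)[::-1]  # (z,y,x) <-> (x,y,z) axis reversal
    M = P @ R @ P
    off = P @ ((R @ (origin - c) + c + t - origin) / vs)
    return M, off


def warp_values(image: DensityImage, transform: RigidTransform3D,
                order: int, cval: float) -> np.ndarray:
    """Raw resampled value array (allows NaN fill; no validation)."""
    M, off = index_affine(image, transform)
    return ndimage.affine_transform(
        image.values.astype(np.float64), M, offset=off, order=order,
        mode="constant", cval=cval, prefilter=(order > 1))


def resample_mask(mask: np.ndarray, image_like: DensityImage,
                  transform: RigidTransform3D) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask (fill = background)."""
    img = DensityImage(mask.astype(np.float32), image_like.voxel_size,
                       image_like.origin)
    return resample(img, transform, interpolation="nearest").values > 0.5


def domain_mask(image: DensityImage, transform: RigidTransform3D) -> np.ndarray:
    """Voxels of the output grid whose sample point lies inside the input."""
    ones = image.like(np.ones(image.shape, dtype=np.float32))
    return resample(ones, transform, interpolation="nearest").values > 0.5


# ---------------------------------------------------------------------------
# MetaImage / NIfTI I/O

_MHA_DTYPES = {"MET_FLOAT": np.float32, "MET_DOUBLE": np.float64,
               "MET_UCHAR": np.uint8, "MET_SHORT": np.int16,
               "MET_USHORT": np.uint16, "MET_INT": np.int32}
_MHA_NAMES = {np.dtype(np.float32): "MET_FLOAT", np.dtype(np.float64): "MET_DOUBLE",
              np.dtype(np.uint8): "MET_UCHAR", np.dtype(np.int16): "MET_SHORT",
              np.dtype(np.uint16): "MET_USHORT", np.dtype(np.int32): "MET_INT"}


def _format_from_path(path: str) -> str:
    p = str(path).lower()
    if p.endswith((".mha", ".mhd")):
        return "MetaImage"
    if p.endswith((".nii", ".nii.gz")):
        return "NIfTI"
    raise ValueError(f"cannot infer image format from path {path!r}")


def _check_isotropic(spacing) -> float:
    spacing = np.asarray(spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=1e-5, atol=1e-9):
        raise ValueError(f"anisotropic voxels are not supported: "
                         f"spacings {tuple(spacing)}")
    return float(spacing[0])


def read_image(path: str, format: str | None = None) -> DensityImage:
    """Read a MetaImage (.mha) or NIfTI (.nii/.nii.gz) density image.

    Values are returned as stored (mg HA/cm^3 for density images, {0,1} for
    masks).  Anisotropic spacing raises a ValueError naming the spacings.
    """
    fmt = format or _format_from_path(path)
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    if fmt == "MetaImage":
        return _read_mha(path)
    if fmt == "NIfTI":
        return _read_nifti(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_image(image: DensityImage, path: str, format: str | None = None,
                dtype=np.float32) -> None:
    """Write an image losslessly (32-bit float by default, 8-bit for masks)."""
    fmt = format or _format_from_path(path)
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise IOError(f"parent directory does not exist: {parent}")
    data = np.ascontiguousarray(image.values.astype(dtype))
    if fmt == "MetaImage":
        _write_mha(data, image, path)
    elif fmt == "NIfTI":
        _write_nifti(data, image, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_mask(mask: np.ndarray, image_like: DensityImage, path: str) -> None:
    """Write a binary mask as an 8-bit image with values {0, 1}."""
    img = DensityImage(mask.astype(np.float32), image_like.voxel_size,
                       image_like.origin)
    write_image(img, path, dtype=np.uint8)


def _read_mha(path: str):
    header: dict[str, str] = {}
    with open(path, "rb") as fh:
        while True:
            line = fh.readline()
            if not line:
                raise IOError(f"truncated MetaImage header in {path}")
            key, _, val = line.decode("ascii").partition("=")
            key, val = key.strip(), val.strip()
            header[key] = val
            if key == "ElementDataFile":
                break
        if header.get("ObjectType", "Image") != "Image":
            raise IOError(f"not a MetaImage image: {path}")
        if int(header.get("NDims", 3)) != 3:
            raise IOError("only 3D MetaImage files are supported")
        dims = [int(v) for v in header["DimSize"].split()]  # x y z
        dtype = _MHA_DTYPES[header["ElementType"]]
        spacing = [float(v) for v in header.get("ElementSpacing", "1 1 1").split()]
        offset = [float(v) for v in header.get("Offset", "0 0 0").split()]
        if header["ElementDataFile"] == "LOCAL":
            raw = fh.read()
        else:
            raw_path = os.path.join(os.path.dirname(path), header["ElementDataFile"])
            with open(raw_path, "rb") as rf:
                raw = rf.read()
    if header.get("CompressedData", "False").lower() == "true":
        raise IOError("compressed MetaImage data is not supported")
    n = dims[0] * dims[1] * dims[2]
    arr = np.frombuffer(raw, dtype=np.dtype(dtype).newbyteorder("<"), count=n)
    arr = arr.reshape(dims[2], dims[1], dims[0])  # (z, y, x), x fastest
    vs = _check_isotropic(spacing)
    return DensityImage(arr.astype(np.float32), vs, tuple(offset))


def _write_mha(data: np.ndarray, image: DensityImage, path: str) -> None:
    nz, ny, nx = data.shape
    vs = image.voxel_size
    ox, oy, oz = image.origin
    header = (
        "ObjectType = Image\n"
        "NDims = 3\n"
        "BinaryData = True\n"
        "BinaryDataByteOrderMSB = False\n"
        "CompressedData = False\n"
        f"DimSize = {nx} {ny} {nz}\n"
        f"ElementSpacing = {vs!r} {vs!r} {vs!r}\n"
        f"Offset = {ox!r} {oy!r} {oz!r}\n"
        f"ElementType = {_MHA_NAMES[data.dtype]}\n"
        "ElementDataFile = LOCAL\n"
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(data.astype(data.dtype.newbyteorder("<"), copy=False).tobytes())


def _read_nifti(path: str) -> DensityImage:
    import nibabel as nib

    img = nib.load(path)
    zooms = img.header.get_zooms()[:3]
    vs = _check_isotropic(zooms)
    arr = np.asanyarray(img.dataobj)
    if arr.ndim != 3:
        raise IOError("only 3D NIfTI files are supported")
    # nibabel axis order (x, y, z) -> internal (z, y, x)
    arr = np.transpose(arr, (2, 1, 0))
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return DensityImage(arr.astype(np.float32), vs, origin)


def _write_nifti(data: np.ndarray, image: DensityImage, path: str) -> None:
    import nibabel as nib

    vs = image.voxel_size
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = image.origin
    arr = np.transpose(data, (2, 1, 0))
    nib.save(nib.Nifti1Image(arr, affine), path)
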