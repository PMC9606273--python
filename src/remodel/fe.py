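"""Voxel-based micro-finite-element analysis of a density image.

Each bone voxel becomes an 8-node hexahedral element with trilinear shape
functions and a linear-elastic, density-scaled tissue modulus (Poisson's
ratio 0.3).  A high-friction uniaxial compression of 1% of the model height
is applied along z: bottom-face nodes fully fixed, top-face nodes displaced
axially with lateral motion suppressed (bonded platens).  Outputs are the
apparent stiffness (kN/mm), per-element strain energy density, and the
effective strain

    eps_eff = sqrt(2 * SED / E)

which is the mechanical signal of the mechanoregulation analysis.
Units: mm, MPa, N internally; stiffness reported in kN/mm, strain in
microstrain where noted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg

from .images import BoneMasks, DensityImage

__all__ = ["MaterialLaw", "FEMesh", "FEResult", "build_mesh",
           "solve_compression", "effective_strain", "strain_percentiles"]

# local node order: bits (dz, dy, dx); node k at offset _NODE_OFFSETS[k]
_NODE_OFFSETS = np.array([(dz, dy, dx)
                          for dz in (0, 1) for dy in (0, 1) for dx in (0, 1)])
_GAUSS = [(sx / np.sqrt(3), sy / np.sqrt(3), sz / np.sqrt(3))
          for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]


@dataclass
class MaterialLaw:
    """Density -> isotropic tissue modulus mapping.

    ``E(rho) = E_max * (clamp(rho, 0, rho_ref) / rho_ref) ** exponent`` —
    linear scaling by default, reaching ``E_max`` (10 GPa) at fully
    mineralized tissue (1200 mg HA/cm^3).  Voxels below ``rho_min`` are not
    meshed.
    """

    E_max: float = 10000.0       # MPa
    rho_ref: float = 1200.0      # mg HA/cm^3
    exponent: float = 1.0
    rho_min: float = 130.0       # mg HA/cm^3 inclusion cutoff
    nu: float = 0.3

    def modulus(self, rho: np.ndarray) -> np.ndarray:
        rho = np.clip(np.asarray(rho, dtype=float), 0.0, self.rho_ref)
        return self.E_max * (rho / self.rho_ref) ** self.exponent


@dataclass
class FEMesh:
    """Voxel hexahedral mesh: element voxel indices, moduli, node numbering."""

    element_voxels: np.ndarray      # (n_el, 3) int (z, y, x)
    moduli: np.ndarray              # (n_el,) MPa
    node_ids: np.ndarray            # (n_el, 8) indices into node table
    node_coords: np.ndarray         # (n_nodes, 3) float (z, y, x) voxel units
    voxel_size: float               # mm
    nu: float
    shape: tuple[int, int, int]     # grid shape the voxels live on

    @property
    def n_elements(self) -> int:
        return len(self.element_voxels)

    @property
    def n_nodes(self) -> int:
        return len(self.node_coords)

    def bottom_top_nodes(self) -> tuple[np.ndarray, np.ndarray]:
        z = self.node_coords[:, 0]
        return np.flatnonzero(z == z.min()), np.flatnonzero(z == z.max())

    @property
    def height_mm(self) -> float:
        z = self.node_coords[:, 0]
        return float(z.max() - z.min()) * self.voxel_size


@dataclass
class FEResult:
    """Solution of the compression test."""

    displacements: np.ndarray        # (n_nodes, 3) mm, dof order (x, y, z)
    sed: np.ndarray                  # (n_el,) MPa
    eff_strain: np.ndarray           # (n_el,) dimensionless
    eff_strain_grid: np.ndarray      # 3D, NaN outside the mesh
    apparent_stiffness: float        # kN/mm
    reaction_force: float            # kN (axial, top face, magnitude)
    reaction_top: float              # kN, signed axial reaction on top face
    reaction_bottom: float           # kN, signed axial reaction on bottom face
    iterations: int
    residual: float
    mesh: FEMesh

    def __post_init__(self) -> None:
        if np.any(self.eff_strain < 0):
            raise ValueError("effective strain must be non-negative")
        if not self.apparent_stiffness > 0:
            raise ValueError("apparent stiffness must be positive")


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    """6x6 isotropic D, strain order (xx, yy, zz, xy, yz, zx), engineering shear."""
    lam = E * nu / ((1 + nu) * (1 - 2 * nu))
    mu = E / (2 * (1 + nu))
    D = np.zeros((6, 6))
    D[:3, :3] = lam
    D[np.arange(3), np.arange(3)] = lam + 2 * mu
    D[np.arange(3, 6), np.arange(3, 6)] = mu
    return D


def _b_matrix(xi: tuple[float, float, float], h: float) -> np.ndarray:
    """Strain-displacement matrix (6 x 24) at natural coords xi=(x,y,z)."""
    # node sign vectors in (x, y, z)
    signs = np.stack([2 * _NODE_OFFSETS[:, 2] - 1,
                      2 * _NODE_OFFSETS[:, 1] - 1,
                      2 * _NODE_OFFSETS[:, 0] - 1], axis=1).astype(float)
    x, y, z = xi
    dN = np.empty((8, 3))
    for k in range(8):
        sx, sy, sz = signs[k]
        dN[k, 0] = sx * (1 + sy * y) * (1 + sz * z) / 8.0
        dN[k, 1] = (1 + sx * x) * sy * (1 + sz * z) / 8.0
        dN[k, 2] = (1 + sx * x) * (1 + sy * y) * sz / 8.0
    dN *= 2.0 / h  # d/dx = (2/h) d/dxi
    B = np.zeros((6, 24))
    for k in range(8):
        c = 3 * k
        dx, dy, dz = dN[k]
        B[0, c] = dx
        B[1, c + 1] = dy
        B[2, c + 2] = dz
        B[3, c] = dy
        B[3, c + 1] = dx
        B[4, c + 1] = dz
        B[4, c + 2] = dy
        B[5, c] = dz
        B[5, c + 2] = dx
    return B


def element_stiffness(E: float, nu: float, h: float) -> np.ndarray:
    """24x24 stiffness of a cube element, full 2x2x2 Gauss integration."""
    D = _elasticity_matrix(E, nu)
    detJ = (h / 2.0) ** 3
    Ke = np.zeros((24, 24))
    for xi in _GAUSS:
        B = _b_matrix(xi, h)
        Ke += B.T @ D @ B * detJ
    return Ke


def build_mesh(image: DensityImage, masks: BoneMasks | None = None,
               law: MaterialLaw | None = None) -> FEMesh:
    """Mesh every voxel above the inclusion cutoff inside the whole mask.

    Only the largest face-connected component that spans the model from its
    bottom to its top slice carries load and is kept; floating fragments
    cannot transmit force to the platens.
    """
    law = law or MaterialLaw()
    candidate = image.values >= law.rho_min
    if masks is not None:
        candidate &= masks.whole
    if not candidate.any():
        raise ValueError("model cannot carry load: no voxels above rho_min")
    zs = np.flatnonzero(candidate.any(axis=(1, 2)))
    z_lo, z_hi = zs[0], zs[-1]
    labels, nlab = ndimage.label(candidate,
                                 structure=ndimage.generate_binary_structure(3, 1))
    spanning, sizes = [], []
    lo_labels = set(np.unique(labels[z_lo])) - {0}
    hi_labels = set(np.unique(labels[z_hi])) - {0}
    for lab in lo_labels & hi_labels:
        spanning.append(lab)
    if not spanning:
        raise ValueError("model cannot carry load: no bottom-to-top "
                         "spanning component")
    sizes = ndimage.sum_labels(candidate, labels, spanning)
    keep = spanning[int(np.argmax(sizes))]
    mask = labels == keep

    vox = np.argwhere(mask)                        # (n_el, 3) z, y, x
    moduli = law.modulus(image.values[mask])
    nz, ny, nx = image.shape
    # global node key on the (nz+1, ny+1, nx+1) node grid
    stride_y, stride_x = nx + 1, 1
    stride_z = (ny + 1) * (nx + 1)
    corner = vox[:, None, :] + _NODE_OFFSETS[None, :, :]   # (n_el, 8, 3)
    keys = (corner[..., 0] * stride_z + corner[..., 1] * stride_y
            + corner[..., 2] * stride_x)
    uniq, inv = np.unique(keys, return_inverse=True)
    node_ids = inv.reshape(keys.shape)
    node_coords = np.stack([uniq // stride_z,
                            (uniq % stride_z) // stride_y,
                            uniq % stride_y], axis=1).astype(float)
    return FEMesh(element_voxels=vox, moduli=moduli, node_ids=node_ids,
                  node_coords=node_coords, voxel_size=image.voxel_size,
                  nu=law.nu, shape=image.shape)


def _assemble(mesh: FEMesh) -> sparse.csr_matrix:
    h = mesh.voxel_size
    Ke1 = element_stiffness(1.0, mesh.nu, h)
    ndof = 3 * mesh.n_nodes
    dofs = (3 * mesh.node_ids[:, :, None]
            + np.arange(3)[None, None, :]).reshape(mesh.n_elements, 24)
    K = sparse.csr_matrix((ndof, ndof))
    chunk = 20000
    for s in range(0, mesh.n_elements, chunk):
        e = min(s + chunk, mesh.n_elements)
        d = dofs[s:e]
        data = mesh.moduli[s:e, None, None] * Ke1[None, :, :]
        rows = np.repeat(d, 24, axis=1).ravel()
        cols = np.tile(d, (1, 24)).ravel()
        K = K + sparse.coo_matrix((data.ravel(), (rows, cols)),
                                  shape=(ndof, ndof)).tocsr()
    return K


def solve_compression(mesh: FEMesh, applied_strain: float = 0.01,
                      tolerance: float = 1e-6, high_friction: bool = True,
                      method: str = "cg", max_iter: int = 20000) -> FEResult:
    """Uniaxial compression by ``applied_strain`` of the model height.

    Bottom nodes are fixed; top nodes move down by the prescribed amount,
    with lateral displacements fixed too when ``high_friction`` (bonded
    platens).  ``method='dense'`` solves the reduced system directly with
    LAPACK (oracle for small meshes); the default is Jacobi-preconditioned
    conjugate gradients converged to a relative residual of ``tolerance``.
    """
    K = _assemble(mesh)
    ndof = K.shape[0]
    bottom, top = mesh.bottom_top_nodes()
    height = mesh.height_mm
    delta = applied_strain * height

    u = np.zeros(ndof)
    fixed = np.zeros(ndof, dtype=bool)
    for n in bottom:
        if high_friction:
            fixed[3 * n:3 * n + 3] = True
        else:
            fixed[3 * n + 2] = True
    for n in top:
        if high_friction:
            fixed[3 * n:3 * n + 3] = True
        else:
            fixed[3 * n + 2] = True
        u[3 * n + 2] = -delta
    if not high_friction:
        # pin in-plane rigid-body modes at one bottom corner node (test-only
        # BC; the uniform-stress solution has zero lateral motion there only
        # up to a rigid shift, so pinning does not perturb strains)
        n0 = int(bottom[0])
        fixed[3 * n0] = fixed[3 * n0 + 1] = True

    free = ~fixed
    rhs = -K[free][:, fixed] @ u[fixed]
    Kff = K[free][:, free].tocsr()

    iterations = 0
    if Kff.shape[0] == 0:
        u_free = np.zeros(0)
        residual = 0.0
    elif method == "dense":
        u_free = np.linalg.solve(Kff.toarray(), rhs)
        residual = float(np.linalg.norm(Kff @ u_free - rhs)
                         / max(np.linalg.norm(rhs), 1e-300))
    elif method == "cg":
        diag = Kff.diagonal()
        diag[diag == 0] = 1.0
        M = sparse.diags(1.0 / diag)

        count = [0]

        def cb(_):
            count[0] += 1

        u_free, info = cg(Kff, rhs, rtol=tolerance, atol=0.0, M=M,
                          maxiter=max_iter, callback=cb)
        iterations = count[0]
        residual = float(np.linalg.norm(Kff @ u_free - rhs)
                         / max(np.linalg.norm(rhs), 1e-300))
        if info != 0:
            raise RuntimeError(f"solver did not converge within {max_iter} "
                               f"iterations (relative residual {residual:.3e})")
    else:
        raise ValueError(f"unknown method {method!r}")
    u[free] = u_free

    # reactions on constrained faces
    r = K @ u
    top_dofs_z = 3 * np.asarray(top) + 2
    bottom_dofs_z = 3 * np.asarray(bottom) + 2
    F_top = float(r[top_dofs_z].sum())        # N
    F_bottom = float(r[bottom_dofs_z].sum())
    stiffness = abs(F_top) / delta / 1000.0   # kN/mm

    sed, eff = _recover_sed(mesh, u)
    grid = np.full(mesh.shape, np.nan)
    vz, vy, vx = mesh.element_voxels.T
    grid[vz, vy, vx] = eff

    return FEResult(displacements=u.reshape(-1, 3), sed=sed, eff_strain=eff,
                    eff_strain_grid=grid, apparent_stiffness=stiffness,
                    reaction_force=abs(F_top) / 1000.0,
                    reaction_top=F_top / 1000.0, reaction_bottom=F_bottom / 1000.0,
                    iterations=iterations, residual=residual, mesh=mesh)


def _recover_sed(mesh: FEMesh, u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Element SED and effective strain at the element centroid."""
    B0 = _b_matrix((0.0, 0.0, 0.0), mesh.voxel_size)
    D1 = _elasticity_matrix(1.0, mesh.nu)
    dofs = (3 * mesh.node_ids[:, :, None]
            + np.arange(3)[None, None, :]).reshape(mesh.n_elements, 24)
    ue = u[dofs]                              # (n_el, 24)
    eps = ue @ B0.T                           # (n_el, 6)
    sed = 0.5 * mesh.moduli * np.einsum("ij,jk,ik->i", eps, D1, eps)
    sed = np.maximum(sed, 0.0)
    eff = effective_strain(sed, mesh.moduli)
    return sed, eff


def effective_strain(sed: np.ndarray, E: np.ndarray) -> np.ndarray:
    """eps_eff = sqrt(2 * SED / E); dimensionless (multiply by 1e6 for microstrain)."""
    sed = np.asarray(sed, dtype=float)
    E = np.asarray(E, dtype=float)
    if np.any(sed < 0):
        raise ValueError("SED must be non-negative")
    if np.any(E <= 0):
        raise ValueError("modulus must be positive")
    return np.sqrt(2.0 * sed / E)


def strain_percentiles(result: FEResult, masks: BoneMasks,
                       percentiles=(5, 10, 25, 50, 75, 99)) -> dict[str, dict[int, float]]:
    """Effective-strain percentiles (microstrain) per bone compartment.

    Linear interpolation between order statistics; raises on an empty
    compartment.
    """
    out: dict[str, dict[int, float]] = {}
    vz, vy, vx = result.mesh.element_voxels.T
    for name in ("cortical", "trabecular"):
        comp = masks.compartment(name)
        sel = comp[vz, vy, vx]
        if not sel.any():
            raise ValueError(f"no elements in {name} compartment")
        vals = result.eff_strain[sel] * 1e6
        pct = {int(q): float(np.percentile(vals, q, method="linear"))
               for q in percentiles}
        if list(pct.values()) != sorted(pct.values()):
            raise AssertionError("percentiles must be non-decreasing")
        out[name] = pct
    return out
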