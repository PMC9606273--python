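"""Voxel micro-FE: meshing, compression solve, SED and effective strain."""

import numpy as np
import pytest

import remodel as rm
from remodel.fe import (MaterialLaw, build_mesh, effective_strain,
                        solve_compression, strain_percentiles)


def _block_image(shape, density=1200.0, voxel_size=0.0607):
    return rm.DensityImage(np.full(shape, density, np.float32), voxel_size)


def test_material_law_scaling():
    law = MaterialLaw()
    assert law.modulus(1200.0) == pytest.approx(10000.0)
    assert law.modulus(600.0) == pytest.approx(5000.0)
    assert law.modulus(0.0) == 0.0
    assert law.modulus(2400.0) == pytest.approx(10000.0)   # clamped


def test_solid_block_meshes_every_voxel():
    mesh = build_mesh(_block_image((10, 10, 10)), None, MaterialLaw())
    assert mesh.n_elements == 1000
    np.testing.assert_allclose(mesh.moduli, 10000.0)


def test_floating_cluster_is_excluded():
    vals = np.zeros((12, 8, 8), np.float32)
    vals[2:10, 2:6, 2:6] = 1200.0
    vals[5, 0, 0] = 1200.0               # floating voxel, no load path
    img = rm.DensityImage(vals)
    mesh = build_mesh(img, None, MaterialLaw())
    assert mesh.n_elements == 8 * 4 * 4


def test_no_spanning_component_raises():
    vals = np.zeros((10, 6, 6), np.float32)
    vals[0:3] = 1200.0
    vals[7:10] = 1200.0                   # two slabs, a gap between
    with pytest.raises(ValueError, match="carry load"):
        build_mesh(rm.DensityImage(vals), None, MaterialLaw())


def test_homogeneous_prism_nu0_analytic_limit():
    law = MaterialLaw(nu=0.0)
    img = _block_image((12, 6, 6))
    res = solve_compression(build_mesh(img, None, law), tolerance=1e-12)
    h = img.voxel_size
    expected = 10000.0 * (6 * h) ** 2 / (12 * h) / 1000.0   # E*A/L, kN/mm
    assert res.apparent_stiffness == pytest.approx(expected, rel=1e-9)
    np.testing.assert_allclose(res.eff_strain, 0.01, rtol=1e-9)


def test_frictionless_prism_nu03_analytic_limit():
    """Test-only boundary condition: only axial displacement prescribed on
    the end faces; the uniform uniaxial-stress solution is then exact even
    at nu = 0.3."""
    law = MaterialLaw(nu=0.3)
    img = _block_image((10, 5, 5))
    res = solve_compression(build_mesh(img, None, law), tolerance=1e-12,
                            high_friction=False)
    h = img.voxel_size
    expected = 10000.0 * (5 * h) ** 2 / (10 * h) / 1000.0
    assert res.apparent_stiffness == pytest.approx(expected, rel=1e-8)
    np.testing.assert_allclose(res.eff_strain, 0.01, rtol=1e-7)


def test_single_element_matches_dense_solve():
    img = _block_image((1, 1, 1), density=800.0)
    mesh = build_mesh(img, None, MaterialLaw())
    a = solve_compression(mesh, tolerance=1e-14)
    b = solve_compression(mesh, method="dense")
    np.testing.assert_allclose(a.displacements, b.displacements, atol=1e-10)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_random_density_mesh_matches_dense_oracle(seed):
    rng = np.random.default_rng(seed)
    img = rm.DensityImage(rng.uniform(200, 1200, (5, 5, 5)).astype(np.float32))
    mesh = build_mesh(img, None, MaterialLaw())
    it = solve_compression(mesh, tolerance=1e-12)
    direct = solve_compression(mesh, method="dense")
    err = (np.linalg.norm(it.displacements - direct.displacements)
           / np.linalg.norm(direct.displacements))
    assert err < 1e-8


def test_equilibrium_of_reactions():
    rng = np.random.default_rng(3)
    img = rm.DensityImage(rng.uniform(300, 1200, (8, 5, 5)).astype(np.float32))
    res = solve_compression(build_mesh(img, None, MaterialLaw()),
                            tolerance=1e-10)
    assert abs(res.reaction_top + res.reaction_bottom) <= 1e-6 * abs(res.reaction_top)


def test_stiffness_monotone_in_modulus():
    rng = np.random.default_rng(4)
    vals = rng.uniform(400, 1000, (4, 4, 4)).astype(np.float32)
    soft = solve_compression(build_mesh(rm.DensityImage(vals), None,
                                        MaterialLaw()), tolerance=1e-12)
    vals2 = vals.copy()
    vals2[2, 2, 2] = 1200.0               # stiffen one element
    stiff = solve_compression(build_mesh(rm.DensityImage(vals2), None,
                                         MaterialLaw()), tolerance=1e-12)
    assert stiff.apparent_stiffness >= soft.apparent_stiffness


def test_effective_strain_formula():
    assert effective_strain(np.array([5000.0]), np.array([10000.0]))[0] == 1.0
    val = effective_strain(np.array([0.05]), np.array([10000.0]))[0]
    assert val * 1e6 == pytest.approx(3162.27766, rel=1e-6)
    double = effective_strain(np.array([0.10]), np.array([10000.0]))[0]
    assert double == pytest.approx(val * np.sqrt(2), rel=1e-12)
    assert effective_strain(np.array([0.0]), np.array([1.0]))[0] == 0.0
    with pytest.raises(ValueError):
        effective_strain(np.array([1.0]), np.array([0.0]))
    with pytest.raises(ValueError):
        effective_strain(np.array([-1.0]), np.array([1.0]))


def test_strain_percentiles_order_statistics():
    img = _block_image((10, 4, 4))
    mesh = build_mesh(img, None, MaterialLaw(nu=0.0))
    res = solve_compression(mesh, tolerance=1e-12)
    # overwrite with a known set: 1..n_elements microstrain; elements are
    # ordered lexicographically (z, y, x), so z < 5 holds elements 1..80
    res.eff_strain = np.arange(1, mesh.n_elements + 1, dtype=float) / 1e6
    cort = np.zeros(img.shape, bool)
    cort[:5] = True
    masks = rm.BoneMasks(whole=np.ones(img.shape, bool), cortical=cort,
                         trabecular=~cort)
    pct = strain_percentiles(res, masks, percentiles=(25, 50, 75))
    assert pct["cortical"][50] == pytest.approx(40.5, rel=1e-12)
    assert pct["cortical"][25] == pytest.approx(1 + 79 * 0.25, rel=1e-12)
    # uniform field: all percentiles equal
    res.eff_strain = np.full(mesh.n_elements, 123e-6)
    pct2 = strain_percentiles(res, masks, percentiles=(5, 50, 99))
    for v in pct2["cortical"].values():
        assert v == pytest.approx(123.0)


def test_empty_compartment_rejected():
    img = _block_image((6, 4, 4))
    mesh = build_mesh(img, None, MaterialLaw())
    res = solve_compression(mesh, tolerance=1e-10)
    ones = np.ones(img.shape, bool)
    masks = rm.BoneMasks(whole=ones, cortical=ones.copy(),
                         trabecular=np.zeros_like(ones))
    with pytest.raises(ValueError, match="trabecular"):
        strain_percentiles(res, masks)
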