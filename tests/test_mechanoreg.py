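"""Surface-event extraction, CP curves, thresholds and classification rate."""

import numpy as np
import pytest

import remodel as rm
from remodel.mechanoreg import SurfaceEvents, predict_types
from remodel.morphometry import RemodelingLabels


def _events(types, strains, normalized=True):
    ev = SurfaceEvents(types=np.asarray(types, dtype=str),
                       eff_strain=np.asarray(strains, dtype=float),
                       normalized=None,
                       voxels=np.zeros((len(types), 3), int))
    return rm.normalize_strains(ev, 1.0) if normalized else ev


def _cube_labels(k=5, pad=1, resorbed_at=None):
    n = k + 2 * pad
    bone = np.zeros((n, n, n), bool)
    bone[pad:pad + k, pad:pad + k, pad:pad + k] = True
    quiescent = bone.copy()
    resorbed = np.zeros_like(bone)
    if resorbed_at is not None:
        quiescent[resorbed_at] = False
        resorbed[resorbed_at] = True
    labels = RemodelingLabels(formed=np.zeros_like(bone), resorbed=resorbed,
                              quiescent=quiescent, threshold=320.0,
                              region=np.ones_like(bone))
    return bone, labels


def test_solid_cube_surface_events_match_closed_form():
    k = 5
    bone, labels = _cube_labels(k)
    strain = np.full(bone.shape, 1000.0)
    ev = rm.extract_surface_events(labels, bone, strain)
    assert len(ev) == 6 * k ** 2 - 12 * k + 8      # cube surface voxels
    assert set(ev.types) == {"quiescent"}


def test_single_resorbed_face_voxel_is_one_event():
    bone, labels = _cube_labels(5, resorbed_at=(1, 3, 3))
    strain = np.zeros(bone.shape)
    strain[1, 3, 3] = 777.0
    ev = rm.extract_surface_events(labels, bone, strain)
    res = ev.types == "resorbed"
    assert res.sum() == 1
    assert ev.eff_strain[res][0] == 777.0


def test_formed_voxel_inherits_adjacent_surface_strain():
    bone, labels = _cube_labels(5)
    formed = np.zeros_like(bone)
    formed[0, 3, 3] = True                 # sits on top of surface (1, 3, 3)
    labels = RemodelingLabels(formed=formed, resorbed=labels.resorbed,
                              quiescent=labels.quiescent, threshold=320.0,
                              region=labels.region)
    strain = np.full(bone.shape, 100.0)
    strain[1, 3, 3] = 555.0
    ev = rm.extract_surface_events(labels, bone, strain)
    f = ev.types == "formed"
    assert f.sum() == 1
    assert ev.eff_strain[f][0] == 555.0
    # the parent surface voxel is part of the formation site, not a
    # quiescence event
    assert not np.any((ev.types == "quiescent")
                      & (ev.voxels == [1, 3, 3]).all(axis=1))


def test_normalization_scale_invariance():
    ev = _events(["formed", "resorbed"], [100.0, 200.0], normalized=False)
    a = rm.normalize_strains(ev, 100.0)
    b = rm.normalize_strains(SurfaceEvents(ev.types, ev.eff_strain / 2, None,
                                           ev.voxels), 50.0)
    np.testing.assert_allclose(a.normalized, b.normalized)
    with pytest.raises(ValueError):
        rm.normalize_strains(ev, 0.0)


def test_cp_single_bin_arithmetic():
    types = ["formed"] * 2 + ["quiescent"] * 5 + ["resorbed"] * 3
    ev = _events(types, [0.155] * 10)
    cp = rm.cp_curves(ev, min_bin_count=1)
    row = cp.probabilities.iloc[15]
    assert row.p_F == pytest.approx(0.2)
    assert row.p_Q == pytest.approx(0.5)
    assert row.p_R == pytest.approx(0.3)


def test_cp_all_formation_gives_unit_probability(rng):
    ev = _events(["formed"] * 500, rng.uniform(0, 1, 500))
    cp = rm.cp_curves(ev, min_bin_count=1)
    occ = cp.counts.sum(axis=1) > 0
    assert np.all(cp.probabilities.loc[occ, "p_F"] == 1.0)


def test_cp_probabilities_sum_to_one_in_occupied_bins(rng):
    types = rng.choice(["formed", "quiescent", "resorbed"], size=5000)
    ev = _events(types, rng.uniform(0, 1.2, 5000))
    cp = rm.cp_curves(ev)
    occ = cp.counts.sum(axis=1) > 0
    sums = cp.probabilities.loc[occ].sum(axis=1)
    np.testing.assert_allclose(sums, 1.0, atol=1e-12)


def test_strain_independent_types_stay_within_binomial_bounds(rng):
    """With types drawn independently of strain, every occupied bin's
    conditional probabilities sit inside wide binomial confidence bounds
    around the marginal rates."""
    n = 100_000
    marginals = {"formed": 0.3, "quiescent": 0.5, "resorbed": 0.2}
    types = rng.choice(list(marginals), size=n, p=list(marginals.values()))
    ev = _events(types, rng.uniform(0, 1, n))
    cp = rm.cp_curves(ev)
    occ = np.flatnonzero(cp.occupied())
    counts = cp.counts.to_numpy()[occ]
    probs = cp.probabilities.to_numpy()[occ]
    for (p_hat, n_bin), p in zip(zip(probs.T, [counts.sum(axis=1)] * 3),
                                 marginals.values()):
        se = np.sqrt(p * (1 - p) / n_bin)
        assert np.all(np.abs(p_hat - p) < 4.5 * se)


def test_step_function_thresholds_recovered_exactly():
    """Resorption dominant below 0.08, formation above 0.23, quiescence in
    the lazy zone: Tr and Tf equal the construction exactly."""
    types, strains = [], []
    for b in range(40):
        g = b * 0.01 + 0.005
        if g < 0.08:
            mix = ["resorbed"] * 12 + ["quiescent"] * 5 + ["formed"] * 3
        elif g > 0.23:
            mix = ["formed"] * 12 + ["quiescent"] * 5 + ["resorbed"] * 3
        else:
            mix = ["quiescent"] * 12 + ["formed"] * 5 + ["resorbed"] * 3
        types += mix
        strains += [g] * len(mix)
    cp = rm.cp_curves(_events(types, strains))
    Tr, Tf = rm.derive_thresholds(cp)
    assert Tr == pytest.approx(0.08)
    assert Tf == pytest.approx(0.23)
    assert rm.ccr(_events(types, strains), (Tr, Tf)) == pytest.approx(12 / 20)


def test_all_quiescent_thresholds_undefined():
    ev = _events(["quiescent"] * 200, np.linspace(0, 1, 200))
    cp = rm.cp_curves(ev)
    Tr, Tf = rm.derive_thresholds(cp)
    assert Tr is None and Tf is None
    with pytest.raises(ValueError, match="undefined"):
        rm.ccr(ev, (Tr, Tf))


def test_ccr_of_uniform_random_types_is_chance(rng):
    n = 100_000
    types = rng.choice(["formed", "quiescent", "resorbed"], size=n)
    ev = _events(types, rng.uniform(0, 1, n))
    rate = rm.ccr(ev, (0.1, 0.3))
    assert rate == pytest.approx(1 / 3, abs=0.01)


def test_predict_types_threshold_conventions():
    pred = predict_types(np.array([0.05, 0.1, 0.2, 0.35]), 0.1, 0.3)
    assert list(pred) == ["resorbed", "quiescent", "quiescent", "formed"]


def test_monotone_association_on_mechanoregulated_phantom():
    """p_F should rise and p_R fall across occupied bins (one-bin violation
    tolerance) when events were generated by a strain-threshold rule."""
    p = rm.PhantomParams(noise_sd=0, seed=11)
    img, masks = rm.make_phantom(p)
    s = rm.surrogate_strain(masks)
    fu, _ = rm.simulate_followup(img, masks, s, rm.MechanoregRule(), seed=12)
    region = np.ones(img.shape, bool)
    region[:3] = region[-3:] = False
    b = rm.binarize(img, 320)
    labels = rm.classify_remodeling(b, rm.binarize(fu, 320), region)
    ev = rm.normalize_strains(rm.extract_surface_events(labels, b, s), 1.0)
    cp = rm.cp_curves(ev)
    occ = np.flatnonzero(cp.occupied())
    p_F = cp.probabilities.to_numpy()[occ, 0]
    p_R = cp.probabilities.to_numpy()[occ, 2]

    def blocks(x, size=8):
        n = len(x) // size * size
        return x[:n].reshape(-1, size).mean(axis=1)

    bF, bR = blocks(p_F), blocks(p_R)
    tol = 0.08   # block averaging suppresses, not removes, the spatially
    # correlated per-bin sampling noise of lattice surfaces
    f_viol = np.sum(bF[1:] < np.maximum.accumulate(bF)[:-1] - tol)
    r_viol = np.sum(bR[1:] > np.minimum.accumulate(bR)[:-1] + tol)
    assert f_viol <= 1
    assert r_viol <= 1
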