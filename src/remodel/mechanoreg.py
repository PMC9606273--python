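"""Mechanoregulation analysis: linking surface remodeling to local strain.

Remodeling events on the baseline bone surface are paired with the effective
strain of the underlying tissue, strains are normalized (by the cohort
average 99th percentile, or any injected constant), and binned at 1% steps.
Conditional probability (CP) curves give, per bin, the probability that an
event is formation, quiescence or resorption.  From the curves come the
resorption threshold Tr (upper edge of the strain range where resorption
dominates), the formation threshold Tf (lower edge of the range where
formation dominates), and the correct classification rate (CCR) of
predicting event types from strain alone.

Event bookkeeping is site-based: each baseline surface voxel contributes one
outcome.  A surface voxel face-adjacent to newly formed bone is part of a
formation site — the formed voxel is the formation event and the parent
surface voxel is not additionally counted as quiescent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .fe import FEResult
from .morphometry import RemodelingLabels
from .phantom import FACE_OFFSETS, FACE_STRUCT, surface_voxels

__all__ = ["SurfaceEvents", "CPAnalysis", "extract_surface_events",
           "normalize_strains", "cp_curves", "derive_thresholds", "ccr"]

_TYPES = ("formed", "quiescent", "resorbed")


@dataclass
class SurfaceEvents:
    """Remodeling events with their local mechanical environment."""

    types: np.ndarray             # (n,) str in {formed, quiescent, resorbed}
    eff_strain: np.ndarray        # (n,) microstrain
    normalized: np.ndarray | None # (n,) strain / normalization constant
    voxels: np.ndarray            # (n, 3) int (z, y, x)
    normalization_constant: float | None = None

    def __len__(self) -> int:
        return len(self.types)


@dataclass
class CPAnalysis:
    """Binned conditional probabilities of remodeling vs normalized strain."""

    bin_edges: np.ndarray         # (n_bins + 1,) multiples of bin width
    counts: pd.DataFrame          # columns n_F, n_Q, n_R, one row per bin
    probabilities: pd.DataFrame   # columns p_F, p_Q, p_R (NaN in empty bins)
    normalization_constant: float
    Tr: float | None = None
    Tf: float | None = None
    ccr: float | None = None
    min_bin_count: int = 10

    def occupied(self) -> np.ndarray:
        return (self.counts.sum(axis=1) >= self.min_bin_count).to_numpy()

    def table(self) -> pd.DataFrame:
        out = pd.DataFrame({"bin_lower": self.bin_edges[:-1],
                            "bin_upper": self.bin_edges[1:]})
        out = pd.concat([out, self.counts.reset_index(drop=True),
                         self.probabilities.reset_index(drop=True)], axis=1)
        return out


def extract_surface_events(labels: RemodelingLabels, baseline_bone: np.ndarray,
                           fe: FEResult | np.ndarray) -> SurfaceEvents:
    """Collect remodeling events on the baseline bone surface.

    The surface is the set of baseline bone voxels with a face neighbour
    outside bone (6-connectivity).  Resorbed surface voxels are resorption
    events; formed voxels face-adjacent to the surface are formation events
    and inherit the effective strain of their adjacent surface voxel
    (lexicographically first neighbour if several); remaining surface voxels
    not adjacent to formed bone are quiescence events.  Strain for bone
    voxels comes from the FE effective-strain field (microstrain); voxels
    without an element take the nearest element's value along the face
    neighbourhood, else 0.
    """
    if isinstance(fe, FEResult):
        strain = fe.eff_strain_grid * 1e6
    else:
        strain = np.asarray(fe, dtype=float)
    if strain is None or strain.shape != baseline_bone.shape:
        raise ValueError("FE result missing a congruent effective-strain field")
    surf = surface_voxels(baseline_bone)

    # fill NaN (no element) with a face-neighbourhood mean so every surface
    # voxel has a defined mechanical environment
    if np.isnan(strain).any():
        filled = strain.copy()
        nanmask = np.isnan(filled)
        filled[nanmask] = 0.0
        weight = ndimage.correlate((~nanmask).astype(float), FACE_STRUCT.astype(float),
                                   mode="constant")
        total = ndimage.correlate(filled, FACE_STRUCT.astype(float), mode="constant")
        with np.errstate(invalid="ignore", divide="ignore"):
            neighbor_mean = np.where(weight > 0, total / weight, 0.0)
        strain = np.where(nanmask, neighbor_mean, strain)

    formed_adjacent = ndimage.binary_dilation(labels.formed, structure=FACE_STRUCT)

    types, strains, voxels = [], [], []
    # resorption and quiescence events are surface voxels; surface voxels
    # face-adjacent to new bone belong to formation sites, not independent
    # quiescence events
    res_idx = np.argwhere(surf & labels.resorbed)
    qui_idx = np.argwhere(surf & labels.quiescent & ~formed_adjacent)
    for idx, t in ((res_idx, "resorbed"), (qui_idx, "quiescent")):
        if len(idx):
            types.extend([t] * len(idx))
            strains.extend(strain[idx[:, 0], idx[:, 1], idx[:, 2]])
            voxels.extend(idx)

    # formation events: formed voxels face-adjacent to the surface,
    # inheriting the lexicographically first adjacent surface voxel's strain
    nz, ny, nx = baseline_bone.shape
    for z, y, x in np.argwhere(labels.formed):
        for dz, dy, dx in FACE_OFFSETS:
            zz, yy, xx = z + dz, y + dy, x + dx
            if 0 <= zz < nz and 0 <= yy < ny and 0 <= xx < nx and surf[zz, yy, xx]:
                types.append("formed")
                strains.append(strain[zz, yy, xx])
                voxels.append((z, y, x))
                break

    if not types:
        raise ValueError("no surface events found")
    return SurfaceEvents(types=np.array(types), eff_strain=np.array(strains, dtype=float),
                         normalized=None, voxels=np.array(voxels, dtype=int))


def normalize_strains(events: SurfaceEvents,
                      normalization_constant: float) -> SurfaceEvents:
    """Divide event strains by a normalization constant (microstrain).

    The canonical constant is the cohort average of subjects' 99th-percentile
    effective strain, but any positive value may be injected.
    """
    if not normalization_constant > 0:
        raise ValueError("normalization constant must be positive")
    return SurfaceEvents(types=events.types, eff_strain=events.eff_strain,
                         normalized=events.eff_strain / normalization_constant,
                         voxels=events.voxels,
                         normalization_constant=float(normalization_constant))


def cp_curves(events: SurfaceEvents, bin_width: float = 0.01,
              min_bin_count: int = 10) -> CPAnalysis:
    """Bin normalized strains at 1% steps and condition event type on bin.

    ``p_t(b) = n_t(b) / (n_F(b) + n_Q(b) + n_R(b))``; bins with no events
    carry NaN probabilities and bins under ``min_bin_count`` are excluded
    from the threshold search.  Pool events across subjects before calling
    for group-wise curves.
    """
    if events.normalized is None:
        raise ValueError("normalize_strains must be applied first")
    if len(events) == 0:
        raise ValueError("no events")
    g = events.normalized
    n_bins = int(np.ceil(max(g.max(), bin_width) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    which = np.minimum((g / bin_width).astype(int), n_bins - 1)
    counts = pd.DataFrame(0, index=range(n_bins), columns=["n_F", "n_Q", "n_R"])
    for t, col in (("formed", "n_F"), ("quiescent", "n_Q"), ("resorbed", "n_R")):
        sel = which[events.types == t]
        if len(sel):
            counts[col] = np.bincount(sel, minlength=n_bins)
    total = counts.sum(axis=1).to_numpy().astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = counts.to_numpy() / total[:, None]
    probabilities = pd.DataFrame(probs, columns=["p_F", "p_Q", "p_R"])
    occupied = total > 0
    p = probabilities.to_numpy()[occupied]
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12), \
        "conditional probabilities must sum to 1 in every occupied bin"
    return CPAnalysis(bin_edges=edges, counts=counts, probabilities=probabilities,
                      normalization_constant=events.normalization_constant,
                      min_bin_count=min_bin_count)


def derive_thresholds(cp: CPAnalysis) -> tuple[float | None, float | None]:
    """(Tr, Tf): where resorption / formation become the dominant outcome.

    Dominance uses a persistence rule against single-bin noise: Tf is the
    lower edge of the first occupied bin from which formation has the
    strictly largest probability in every remaining occupied bin; Tr is the
    upper edge of the last bin of the initial run of occupied bins in which
    resorption strictly dominates.  A missing dominance region yields None.
    """
    occ = np.flatnonzero(cp.occupied())
    if len(occ) == 0:
        return None, None
    p = cp.probabilities.to_numpy()
    f_dom = (p[occ, 0] > p[occ, 1]) & (p[occ, 0] > p[occ, 2])
    r_dom = (p[occ, 2] > p[occ, 0]) & (p[occ, 2] > p[occ, 1])

    Tf = None
    for i in range(len(occ)):
        if f_dom[i:].all():
            Tf = float(cp.bin_edges[occ[i]])
            break
    Tr = None
    k = 0
    while k < len(occ) and r_dom[k]:
        k += 1
    if k > 0:
        Tr = float(cp.bin_edges[occ[k - 1] + 1])
    cp.Tr, cp.Tf = Tr, Tf
    return Tr, Tf


def predict_types(normalized: np.ndarray, Tr: float, Tf: float) -> np.ndarray:
    """Predicted event type from normalized strain and the two thresholds."""
    pred = np.full(len(normalized), "quiescent", dtype=object)
    pred[normalized < Tr] = "resorbed"
    pred[normalized > Tf] = "formed"
    return pred.astype(str)


def ccr(events: SurfaceEvents, thresholds: tuple[float | None, float | None]) -> float:
    """Correct classification rate of event types predicted from strain."""
    Tr, Tf = thresholds
    if Tr is None or Tf is None:
        raise ValueError("thresholds undefined: widen the event sample before "
                         "computing a classification rate")
    if events.normalized is None:
        raise ValueError("normalize_strains must be applied first")
    pred = predict_types(events.normalized, Tr, Tf)
    rate = float(np.mean(pred == events.types))
    assert 0.0 <= rate <= 1.0
    return rate
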