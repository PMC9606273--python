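# Methods

`remodel` quantifies time-lapse bone remodeling and its mechanical regulation
from paired HR-pQCT-style density images.  This note records the models,
parameter choices, and numerical decisions the package makes, and what its
synthetic validation does and does not establish.

## Pipeline

For one subject (two calibrated BMD images, baseline and follow-up):

1. **Rigid registration.** The follow-up (moving) image is aligned to the
   baseline (fixed) by minimizing mean squared intensity error over a
   3-level image pyramid (factor-2 downsampling, Gaussian antialiasing).
   The six rigid parameters are scaled so one optimizer unit moves a
   peripheral point about one voxel; optimization is Powell's method with
   linear interpolation during the search and cubic interpolation for the
   final resampling.  Two translation seeds come from FFT cross-correlation
   — one sharp, one low-passed (σ = 4 voxels) — because a quasi-periodic
   trabecular lattice can alias the sharp estimate by one lattice period.
   Both seeds are refined through the coarse and middle levels; the basins
   are compared with the full-resolution metric before the finest-level
   polish, where the over-smoothed coarse metric is unreliable.  At the
   coarsest level rotations are optimized first with the translation held,
   since the rotational landscape has no lattice-period minima.
2. **Masks and common region.** Whole-bone, cortical and trabecular masks
   come from threshold-plus-morphology segmentation (see below).  All
   remodeling quantities are computed inside the intersection of the two
   scans' whole masks and the resampling domain.
3. **Dynamic morphometry.** Both images are denoised with the constrained
   Gaussian filter (σ = 1.2, truncate = 0.8, support = 1.0), binarized at a
   ladder of thresholds (200–920 mg HA/cm³ in steps of 120; trabecular rows
   stop at 680; 320 is the standardized threshold), and compared voxel-wise:
   formed = bone only at follow-up, resorbed = bone only at baseline,
   quiescent = bone at both.  Formation and resorption volume fractions are
   relative to baseline bone volume at the same threshold, per compartment.
4. **Micro-FE.** Each voxel at or above the inclusion cutoff becomes an
   8-node hexahedral element (trilinear shape functions, full 2×2×2 Gauss
   integration) with isotropic modulus `E(ρ) = E_max·(ρ/ρ_ref)` and
   ν = 0.3.  A high-friction compression of 1 % of the model height is
   applied along z (bottom face fully fixed; top face laterally fixed and
   displaced axially).  Apparent stiffness is the axial top-face reaction
   over the applied displacement.  Strain energy density is recovered at
   each element centroid and converted to the effective strain
   `ε_eff = sqrt(2·SED/E)`.
5. **Mechanoregulation.** Remodeling events on the baseline bone surface are
   paired with ε_eff, normalized (per-subject 99th percentile by default, a
   cohort mean in cohort mode), binned at 1 % steps, and conditioned bin-wise
   to give CP curves.  Tr is the upper edge of the initial run of occupied
   bins where resorption has the strictly largest probability; Tf is the
   lower edge of the first occupied bin from which formation dominates in
   every remaining occupied bin (persistence guards against single-bin
   noise).  The correct classification rate (CCR) scores prediction of event
   types from normalized strain alone with those two thresholds.

## Parameters that matter

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| voxel size | 0.0607 | mm | second-generation HR-pQCT protocol |
| threshold ladder | 200…920 step 120 | mg HA/cm³ | density range of mineralized tissue |
| standardized threshold | 320 | mg HA/cm³ | common trabecular segmentation threshold |
| filter (σ, truncate, support) | 1.2, 0.8, 1.0 | voxels | kernel half-width of one voxel; constants are fixed points |
| E_max at ρ_ref | 10 000 at 1200 | MPa, mg HA/cm³ | common linear density–modulus scaling for voxel micro-FE |
| ρ_min inclusion cutoff | 130 | mg HA/cm³ | excludes marrow/soft tissue from the mesh |
| ν | 0.3 | – | standard for mineralized tissue |
| applied strain | 0.01 | – | 1 % axial compression |
| CP bin width | 0.01 | – | 1 % of the normalization constant |
| min bin occupancy | 10 | events | CP estimates from fewer events are noise |
| event-region margin | 3 | slices | cut surfaces and platen contact are artifacts, excluded from events |

The solver converges Jacobi-preconditioned conjugate gradients to a relative
residual of 1e-6 by default (1e-12 in oracle tests); results are independent
of thread count because assembly and the solve are single-threaded and
deterministic in element order.

## Synthetic phantom: the stated world

No patient scans are available, so validation runs on phantoms with known
ground truth: an elliptical cortical shell (peak 900 mg HA/cm³, aspect
1.05 : 0.85, lumen tapering 15 % toward z-max, radius undulating ±5 % along
the shaft) around a cubic lattice of
square trabecular rods (650 mg HA/cm³, pitch 0.55 mm, thickness 0.18 mm) in
marrow (50 mg HA/cm³), blurred by a Gaussian of 0.8 voxels (partial volume)
with additive Gaussian noise of sd 60 mg HA/cm³.  The default grid is
48×96×96 voxels: the air margin is sized so a repositioning misalignment up
to 10° / 20 voxels never clips bone, as with an operator-centered scan.
The taper, the radius undulation and the elliptical cross-section are
anatomically motivated (metaphyseal flare; shaft cross-sections vary along
their length; non-circular diaphysis) and they are what makes longitudinal
translation and in-plane rotation identifiable — a perfectly periodic,
axisymmetric phantom leaves a lattice-period-shifted alignment nearly as
good as the true one (with a z-clipped section, sometimes better), which no
real, aperiodic bone does.

The follow-up is generated by a strain-threshold rule on the baseline bone
surface: active sites (event rate 0.7 per interval) resorb below Tr* = 0.08
normalized strain, add one voxel of bone above Tf* = 0.23, and otherwise
stay quiescent; a site disobeys with probability 0.1 and takes one of the
other two outcomes at random.  Remodeling is one voxel deep, keeping ground
truth exactly countable.  The event rate reflects that over a 9–12 month
interval a large fraction of the surface remodels; it is also the regime in
which formation can dominate a strain bin at all — with site-based event
counting, formation dominance requires `event_rate · obedience` above
roughly one half, so a sparse-remodeling phantom could never exhibit the
behavior the analysis is designed to detect.  The strain field driving the
rule is either the package's own micro-FE solve of the baseline (default;
the analysis then measures the same physical field it was generated from) or
an analytic depth ramp, linear in z with a mild radial modulation so strain
values fill bins continuously.

The misaligned follow-up is produced the way a repeat scan is: the bone
continues beyond the scanned section, so the generator resamples an axially
extended version of the geometry and crops back to the 48-slice window.  A
plain resample would leave zero-fill bands at the z-ends that no real
follow-up shows, and those bands measurably displace the registration
optimum (about half a voxel in z on this phantom).

Event bookkeeping is site-based: each baseline surface voxel carries one
outcome.  A formed voxel face-adjacent to the surface is a formation event
inheriting its first (lexicographic) surface neighbour's strain; surface
voxels adjacent to formed bone belong to those formation sites and are not
additionally counted as quiescent events.  Counting them as quiescent would
make `p_F > p_Q` mathematically impossible in any bin (every formation would
bring a quiescent parent along), so thresholds could never be recovered.

### What a green phantom test does not establish

The phantom has no beam hardening, motion artifacts, plate-like trabeculae,
cortical porosity, or anatomically realistic geometry; its noise is i.i.d.
Gaussian, its remodeling exactly one voxel deep.  Recovery results on the
phantom therefore validate the pipeline's bookkeeping and numerics, not its
accuracy on clinical scans.  Two regimes are worth naming explicitly:

- The constrained Gaussian denoiser blends isolated single-voxel remodeling
  events below the standardized threshold, and cubic resampling under a
  misalignment does the same; exact label recovery holds (and is tested) on
  noise-free, identity-aligned inputs with denoising off.  On noisy inputs
  denoising is indispensable and label recovery is necessarily approximate —
  the same trade real longitudinal studies face.
- With realistic noise (sd 60) the CP curves flatten and the generating
  thresholds are not recoverable to one bin end-to-end; threshold-recovery
  claims are made for the noise-free pipeline and for the module-level chain.

## Numerical choices

- Threshold boundary is `≥` (a voxel exactly at a threshold is bone).
- "Constrained Gaussian" = truncated, renormalized separable Gaussian; the
  kernel half-width is `floor(min(truncate·σ, support) + 0.5)` voxels, and
  boundary handling is nearest-edge replication, so constants are exact
  fixed points.
- Order of operations: register → resample follow-up (cubic) → denoise both
  → binarize → classify.  Resampling before thresholding avoids interpolating
  binary images.
- Mask segmentation: the whole mask is the filled, closed largest connected
  component of the denoised image at the cortical density criterion
  (450 mg HA/cm³ — the half-maximum of the periosteal edge, which is where
  smoothing leaves a step edge's level set unmoved).  The medullary cavity
  is recovered as the largest sub-criterion component closed over the
  trabecular struts (struts touch the endosteal surface, so connectivity
  alone cannot separate the compartments); cortical = dense voxels outside
  the cavity, trabecular = cavity minus a 2-voxel transition band.  All
  morphological closings pad with edge replication so the open z-ends of the
  scanned section are not eroded.
- Element SED is evaluated at the single centroid point, checked against a
  dense-assembly oracle; negative round-off SED is clamped to zero.
- No minimum-cluster filtering of remodeling events by default.
- Formed voxels may lie one voxel outside the baseline whole mask
  (periosteal apposition), so the event region is the common region dilated
  by 2 voxels, minus 3 end slices on each side.
- Ties in threshold derivation: dominance requires strict inequality;
  missing dominance regions yield `None`, never a guess.

## Known limitations

- Rigid registration only; no deformable motion compensation.
- The density–modulus law constants are conventional, not calibrated to the
  source cohort; apparent stiffness is therefore comparable within runs of
  this package, not across instruments.
- The lattice-slip failure mode of MSE registration on quasi-periodic
  structures is mitigated (multi-start, fine-metric basin comparison) but
  not eliminated; the recovery guarantee is on the median over transforms.
- Marrow is excluded from the FE mesh rather than meshed with a low modulus.
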