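"""End-to-end orchestration: phantom -> registration -> morphometry -> FE ->
mechanoregulation, from a single TOML-serializable configuration.

The stage order is fixed: register the follow-up to the baseline, resample
it (cubic), denoise both images, binarize and classify across the threshold
ladder, solve the baseline micro-FE compression, then correlate surface
remodeling events with effective strain.  All artifacts are deterministic
under a fixed seed; wall-clock timings go to stderr only so output files are
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import sys
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .fe import MaterialLaw, build_mesh, solve_compression, strain_percentiles
from .images import DensityImage, RigidTransform3D, read_image, resample, write_image, write_mask
from .mechanoreg import (SurfaceEvents, ccr, cp_curves, derive_thresholds,
                         extract_surface_events, normalize_strains)
from .morphometry import ThresholdLadder, binarize, classify_remodeling, denoise, \
    static_summaries, threshold_sweep
from .phantom import (MechanoregRule, PhantomParams, make_phantom,
                      simulate_followup, surrogate_strain)
from .registration import common_region, generate_masks, register_rigid

__all__ = ["RunConfig", "SubjectReport", "run_subject", "run_cohort"]


@dataclass
class RunConfig:
    """One subject's run: inputs (or phantom parameters) plus all stage knobs."""

    # inputs: either a phantom specification or two image paths
    use_phantom: bool = True
    baseline_path: str | None = None
    followup_path: str | None = None
    phantom: PhantomParams = field(default_factory=PhantomParams)
    rule: MechanoregRule = field(default_factory=MechanoregRule)
    misalignment_deg: tuple[float, float, float] = (3.0, 1.5, -2.0)
    misalignment_voxels: tuple[float, float, float] = (4.0, -3.0, 5.0)
    strain_mode: str = "fe"

    # stage parameters
    ladder: ThresholdLadder = field(default_factory=ThresholdLadder)
    filter_sigma: float = 1.2
    filter_truncate: float = 0.8
    filter_support: float = 1.0
    apply_denoise: bool = True
    law: MaterialLaw = field(default_factory=MaterialLaw)
    applied_strain: float = 0.01
    fe_tolerance: float = 1e-6
    bin_width: float = 0.01
    min_bin_count: int = 10
    mechreg_exclude_slices: int = 3   # cut-surface/platen artifact margin
    normalization: float | str = "auto"   # microstrain constant or "auto"
    seed: int = 0
    out_dir: str = "run_out"
    save_images: bool = False

    def to_dict(self) -> dict:
        # JSON round-trip normalizes tuples to lists so serialized and
        # reconstructed configurations compare equal
        return json.loads(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "phantom" in d:
            p = dict(d["phantom"])
            p["shape"] = tuple(p.get("shape", PhantomParams.shape))
            if "aspect" in p:
                p["aspect"] = tuple(p["aspect"])
            d["phantom"] = PhantomParams(**p)
        if "rule" in d:
            d["rule"] = MechanoregRule(**d["rule"])
        if "ladder" in d:
            lad = dict(d["ladder"])
            lad["thresholds"] = tuple(lad.get("thresholds",
                                              ThresholdLadder.thresholds))
            d["ladder"] = ThresholdLadder(**lad)
        if "law" in d:
            d["law"] = MaterialLaw(**d["law"])
        for key in ("misalignment_deg", "misalignment_voxels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("out_dir", None)       # output location is not part of the
        d.pop("save_images", None)   # scientific configuration
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def misalignment(self, image: DensityImage) -> RigidTransform3D:
        rot = tuple(np.deg2rad(a) for a in self.misalignment_deg)
        trans = tuple(v * image.voxel_size for v in self.misalignment_voxels)
        return RigidTransform3D(rotation=rot, translation=trans,
                                center=tuple(image.center_physical()))


@dataclass
class SubjectReport:
    """All per-subject outputs plus enough state for cohort re-normalization."""

    fractions: pd.DataFrame
    stiffness_kn_mm: float
    strain_percentiles: dict
    percentile99: float
    Tr: float | None
    Tf: float | None
    ccr: float | None
    normalization_constant: float
    statics: dict
    registration_mse: float
    config_hash: str
    events: SurfaceEvents | None = None
    cp_table: pd.DataFrame | None = None

    def summary(self) -> dict:
        return {
            "software_version": __version__,
            "config_hash": self.config_hash,
            "stiffness_kn_mm": self.stiffness_kn_mm,
            "strain_percentiles_ue": self.strain_percentiles,
            "percentile99_ue": self.percentile99,
            "Tr": self.Tr, "Tf": self.Tf, "ccr": self.ccr,
            "normalization_constant_ue": self.normalization_constant,
            "statics": self.statics,
            "registration_mse": self.registration_mse,
        }


def _log(stage: str, note: str, t0: float) -> None:
    print(f"[remodel] {stage}: {note} ({time.perf_counter() - t0:.1f}s)",
          file=sys.stderr)


def run_subject(config: RunConfig, write_outputs: bool = True) -> SubjectReport:
    """Execute every stage for one subject and write its report artifacts."""
    t0 = time.perf_counter()
    out = config.out_dir
    if write_outputs:
        os.makedirs(out, exist_ok=True)
    log_lines: list[str] = []

    def log(stage: str, note: str) -> None:
        _log(stage, note, t0)
        log_lines.append(f"{stage}: {note}")

    truth = None
    if config.use_phantom:
        baseline, true_masks = make_phantom(config.phantom)
        strain_for_rule = surrogate_strain(true_masks, mode=config.strain_mode,
                                           image=baseline)
        mis = config.misalignment(baseline)
        followup, truth = simulate_followup(
            baseline, true_masks, strain_for_rule, config.rule,
            misalignment=mis, seed=config.seed + 1,
            noise_sd=config.phantom.noise_sd, params=config.phantom)
        log("phantom", f"seed={config.phantom.seed} "
                       f"truth={truth.counts()}")
    else:
        if not (config.baseline_path and config.followup_path):
            raise ValueError("either phantom parameters or two image paths "
                             "must be provided")
        baseline = read_image(config.baseline_path)
        followup = read_image(config.followup_path)
        log("load", f"{config.baseline_path} / {config.followup_path}")

    reg = register_rigid(baseline, followup)
    log("register", f"mse={reg.final_mse:.3f} converged={reg.converged}")
    followup_aligned = resample(followup, reg.transform, interpolation="cubic")

    masks = generate_masks(baseline)
    moving_masks = generate_masks(followup)
    region = common_region(masks, moving_masks, reg.transform, baseline)
    log("masks", f"region={int(region.sum())} voxels")

    if config.apply_denoise:
        base_d = denoise(baseline, config.filter_sigma, config.filter_truncate,
                         config.filter_support)
        foll_d = denoise(followup_aligned, config.filter_sigma,
                         config.filter_truncate, config.filter_support)
    else:
        base_d, foll_d = baseline, followup_aligned

    fractions = threshold_sweep(base_d, foll_d, masks, region=region,
                                ladder=config.ladder, apply_denoise=False)
    t_std = config.ladder.standardized
    baseline_bone = binarize(base_d, t_std)   # full grid: surface topology
    followup_bone = binarize(foll_d, t_std)
    labels = classify_remodeling(baseline_bone, followup_bone, region,
                                 threshold=t_std)
    statics = static_summaries(base_d, masks, threshold=t_std)
    log("morphometry", f"labels={labels.counts()}")

    mesh = build_mesh(base_d, masks, config.law)
    fe_result = solve_compression(mesh, applied_strain=config.applied_strain,
                                  tolerance=config.fe_tolerance)
    pct = strain_percentiles(fe_result, masks)
    p99 = float(np.percentile(fe_result.eff_strain * 1e6, 99))
    log("fe", f"elements={mesh.n_elements} "
              f"stiffness={fe_result.apparent_stiffness:.2f} kN/mm "
              f"iters={fe_result.iterations}")

    # events are restricted away from the axial ends (cut surfaces are not
    # biological remodeling surfaces and platen contact distorts the local
    # strain field) but include a small periosteal margin: apposition puts
    # new bone one voxel outside the baseline surface, which a tight whole
    # mask would otherwise clip
    from scipy import ndimage as _ndi

    k = config.mechreg_exclude_slices
    ev_region = _ndi.binary_dilation(region, iterations=2)
    if k > 0:
        ev_region[:k] = False
        ev_region[-k:] = False
    ev_labels = classify_remodeling(baseline_bone, followup_bone, ev_region,
                                    threshold=t_std)
    events = extract_surface_events(ev_labels, baseline_bone, fe_result)
    norm_const = p99 if config.normalization == "auto" else float(config.normalization)
    events = normalize_strains(events, norm_const)
    cp = cp_curves(events, bin_width=config.bin_width,
                   min_bin_count=config.min_bin_count)
    Tr, Tf = derive_thresholds(cp)
    rate = ccr(events, (Tr, Tf)) if (Tr is not None and Tf is not None) else None
    cp.ccr = rate
    log("mechanoreg", f"events={len(events)} Tr={Tr} Tf={Tf} ccr={rate}")

    report = SubjectReport(
        fractions=fractions, stiffness_kn_mm=fe_result.apparent_stiffness,
        strain_percentiles=pct, percentile99=p99, Tr=Tr, Tf=Tf, ccr=rate,
        normalization_constant=norm_const, statics=statics,
        registration_mse=reg.final_mse, config_hash=config.config_hash(),
        events=events, cp_table=cp.table())

    if write_outputs:
        fractions.to_csv(os.path.join(out, "fractions.csv"), index=False)
        cp.table().to_csv(os.path.join(out, "cp.csv"), index=False)
        rows = [{"compartment": comp, "percentile": q, "eff_strain_ue": v}
                for comp, d in pct.items() for q, v in d.items()]
        pd.DataFrame(rows).to_csv(os.path.join(out, "strain_percentiles.csv"),
                                  index=False)
        with open(os.path.join(out, "report.json"), "w") as fh:
            json.dump(report.summary(), fh, indent=2, sort_keys=True)
        with open(os.path.join(out, "run.log"), "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
        with open(os.path.join(out, "transform.json"), "w") as fh:
            json.dump(reg.transform.to_dict(), fh, indent=2)
        if config.save_images:
            write_image(baseline, os.path.join(out, "baseline.mha"))
            write_image(followup, os.path.join(out, "followup.mha"))
            write_mask(labels.formed, baseline, os.path.join(out, "formed.mha"))
            write_mask(labels.resorbed, baseline, os.path.join(out, "resorbed.mha"))
    if truth is not None:
        report_truth = truth  # exposed for callers that need ground truth
        report.truth = report_truth  # type: ignore[attr-defined]
    return report


def run_cohort(configs: list[RunConfig], grouping: dict[int, str] | None = None,
               out_dir: str | None = None) -> dict:
    """Run a cohort and redo mechanoregulation with the cohort constant.

    The cohort normalization constant is the arithmetic mean of every
    subject's 99th-percentile effective strain.  Group CP curves pool events
    across the group's subjects before conditioning.
    """
    if not configs:
        raise ValueError("empty cohort")
    grouping = grouping or {i: "all" for i in range(len(configs))}
    reports = [run_subject(c, write_outputs=False) for c in configs]
    cohort_constant = float(np.mean([r.percentile99 for r in reports]))

    groups: dict[str, dict] = {}
    rows = []
    for i, rep in enumerate(reports):
        ev = normalize_strains(rep.events, cohort_constant)
        cp = cp_curves(ev)
        Tr, Tf = derive_thresholds(cp)
        rate = ccr(ev, (Tr, Tf)) if (Tr is not None and Tf is not None) else None
        g = grouping.get(i, "all")
        groups.setdefault(g, {"events": [], "Tr": [], "Tf": [], "ccr": []})
        groups[g]["events"].append(ev)
        if Tr is not None:
            groups[g]["Tr"].append(Tr)
        if Tf is not None:
            groups[g]["Tf"].append(Tf)
        if rate is not None:
            groups[g]["ccr"].append(rate)
        rows.append({"subject": i, "group": g, "Tr": Tr, "Tf": Tf, "ccr": rate,
                     "percentile99_ue": reports[i].percentile99,
                     "stiffness_kn_mm": reports[i].stiffness_kn_mm})

    summary_rows = []
    group_cp: dict[str, pd.DataFrame] = {}
    for g, data in groups.items():
        pooled = _pool_events(data["events"], cohort_constant)
        cp = cp_curves(pooled)
        derive_thresholds(cp)
        group_cp[g] = cp.table()
        summary_rows.append({
            "group": g, "n_subjects": len(data["events"]),
            "mean_Tr": float(np.mean(data["Tr"])) if data["Tr"] else None,
            "mean_Tf": float(np.mean(data["Tf"])) if data["Tf"] else None,
            "mean_ccr": float(np.mean(data["ccr"])) if data["ccr"] else None,
            "pooled_Tr": cp.Tr, "pooled_Tf": cp.Tf,
        })
    result = {"normalization_constant_ue": cohort_constant,
              "subjects": pd.DataFrame(rows),
              "summary": pd.DataFrame(summary_rows),
              "group_cp": group_cp}
    if out_dir:
        os.makedirs(out_dir, exist_ok=True)
        result["subjects"].to_csv(os.path.join(out_dir, "cohort_subjects.csv"),
                                  index=False)
        result["summary"].to_csv(os.path.join(out_dir, "cohort_summary.csv"),
                                 index=False)
        for g, tbl in group_cp.items():
            tbl.to_csv(os.path.join(out_dir, f"cohort_cp_{g}.csv"), index=False)
    return result


def _pool_events(event_sets: list[SurfaceEvents], constant: float) -> SurfaceEvents:
    types = np.concatenate([e.types for e in event_sets])
    strains = np.concatenate([e.eff_strain for e in event_sets])
    voxels = np.concatenate([e.voxels for e in event_sets])
    pooled = SurfaceEvents(types=types, eff_strain=strains, normalized=None,
                           voxels=voxels)
    return normalize_strains(pooled, constant)
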