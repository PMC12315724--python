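"""End-to-end orchestration: simulate -> physio -> design -> fit -> group.

The pipeline runs one of five first-level model variants:

``blockwise_hr``
    task boxcar + parametric modulator of per-block mean HR (the main model)
``volumewise_hr``
    task boxcar + scan-wise HR modulator
``phasewise_hr``
    per-phase task boxcars + per-phase HR modulators (within-phase centering)
``hf_hrv``
    task boxcar + per-block HF-HRV power modulator
``task_only``
    per-phase task boxcars, Stress-vs-surround contrast [-1 +2 -1]

Every variant shares the nuisance chain (residualization against motion /
trend / spikes, CompCor components, 256 s DCT high-pass) and forwards the
modulator (or task-contrast) effect map to a random-effects group test.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behav, grouplevel, physio, roistats, synthdata
from .firstlevel import (Mask3D, NuisanceSet, Volume4D, compcor, dvars,
                         fit_glm, framewise_displacement, residualize,
                         smooth_gaussian, t_contrast)
from .paradigm import (HRFParams, TaskDesign, assemble_design,
                       build_block_modulator, build_onset_control,
                       build_phasewise_regressors, build_task_regressor,
                       build_volume_modulator, dct_highpass_basis,
                       trim_block_onsets)

__all__ = ["RunConfig", "VARIANTS", "PhysioResult", "SubjectOutput",
           "process_physio", "build_variant_design", "run_subject_arrays",
           "run_group_maps", "run_cohort_dir", "effect_size_table"]

VARIANTS = ("blockwise_hr", "volumewise_hr", "phasewise_hr", "hf_hrv",
            "task_only")

_CONFIG_FIELDS = {
    "variant", "alpha", "extent_k", "fd_limit_mm", "highpass_s", "n_compcor",
    "compcor_per_tissue", "fwhm_mm", "onset_head_s", "hf_window_s",
    "hf_shift_s", "seed",
}


@dataclass
class RunConfig:
    """Validated pipeline settings; defaults are the study's analysis choices."""

    variant: str = "blockwise_hr"
    alpha: float = 0.05
    extent_k: int = 25
    fd_limit_mm: float = 1.5
    highpass_s: float = 256.0
    n_compcor: int = 5
    compcor_per_tissue: bool = False   # True: n per tissue; False: n combined
    fwhm_mm: float = 6.0
    onset_head_s: float | None = None  # exclude first N s of blocks as control
    hf_window_s: float = 300.0
    hf_shift_s: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"choose from {VARIANTS}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.extent_k < 1 or self.n_compcor < 0 or self.fwhm_mm < 0:
            raise ValueError("thresholds must be non-negative (extent_k >= 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Physio stage
# ---------------------------------------------------------------------------

@dataclass
class PhysioResult:
    quality: physio.QualityReport
    ibis: physio.IBISeries
    hr_block: physio.BlockTrace | None
    hr_volume: physio.VolumeTrace | None
    hf_block: physio.BlockTrace | None


def process_physio(rec: physio.PhysioRecording, design: TaskDesign,
                   cfg: RunConfig | None = None,
                   compute_hf: bool = True) -> PhysioResult:
    """Raw PPG -> quality report + blockwise/volumewise HR + blockwise HF-HRV.

    Unusable recordings (quality rating 3) return early with empty traces.
    """
    cfg = cfg or RunConfig()
    if abs(rec.fs - 100.0) > 1e-9:
        rec = physio.resample(rec, 100.0)
    beats, quality = physio.detect_beats(rec)
    if not quality.usable:
        return PhysioResult(quality, physio.IBISeries(
            np.empty(0), np.empty(0), np.empty(0, dtype=bool)),
            None, None, None)
    ibis = physio.filter_ibis(beats)
    hr_block = physio.hr_block_means(ibis, design)
    hr_volume = physio.hr_volume_means(ibis, design)
    hf_block = None
    if compute_hf:
        sliding = physio.hf_hrv(ibis, window_s=cfg.hf_window_s,
                                shift_s=cfg.hf_shift_s)
        hf_block = physio.block_average_windows(sliding, design)
    return PhysioResult(quality, ibis, hr_block, hr_volume, hf_block)


# ---------------------------------------------------------------------------
# Design construction per variant
# ---------------------------------------------------------------------------

def build_variant_design(design: TaskDesign, variant: str,
                         traces: PhysioResult, nuisance: NuisanceSet,
                         cfg: RunConfig | None = None,
                         hrf: HRFParams | None = None):
    """Assemble the first-level design for one model variant.

    Returns ``(DesignMatrix, contrast_weights)`` where the weights name the
    column(s) whose effect goes to the group level.
    """
    cfg = cfg or RunConfig()
    hrf = hrf or HRFParams()
    regs = []
    eff_design = design
    if cfg.onset_head_s:
        regs.append(build_onset_control(design, cfg.onset_head_s, hrf))
        eff_design = trim_block_onsets(design, cfg.onset_head_s)
    if variant == "blockwise_hr":
        regs += [build_task_regressor(eff_design, hrf),
                 build_block_modulator(eff_design, traces.hr_block, hrf)]
        weights = {"task_x_hr": 1.0}
    elif variant == "volumewise_hr":
        regs += [build_task_regressor(eff_design, hrf),
                 build_volume_modulator(eff_design, traces.hr_volume, hrf)]
        weights = {"task_x_hr_vol": 1.0}
    elif variant == "phasewise_hr":
        regs += build_phasewise_regressors(eff_design, traces.hr_block, hrf)
        phases = eff_design.phases
        weights = {f"task_{ph}_x_hr": 1.0 / len(phases) for ph in phases}
    elif variant == "hf_hrv":
        mod = build_block_modulator(eff_design, traces.hf_block, hrf,
                                    name="task_x_hf")
        regs += [build_task_regressor(eff_design, hrf), mod]
        weights = {"task_x_hf": 1.0}
    elif variant == "task_only":
        regs += build_phasewise_regressors(eff_design, None, hrf)
        weights = {"task_PreStress": -1.0, "task_Stress": 2.0,
                   "task_PostStress": -1.0}
    else:
        raise ValueError(f"unknown variant {variant!r}")
    regs += dct_highpass_basis(design.n_scans, design.tr, cfg.highpass_s)
    X = assemble_design(regs, nuisance, tr=design.tr)
    return X, weights


# ---------------------------------------------------------------------------
# First level
# ---------------------------------------------------------------------------

@dataclass
class SubjectOutput:
    subject: str
    excluded: str | None                 # machine-readable reason or None
    effect_maps: dict = field(default_factory=dict)   # variant -> 3D array
    t_maps: dict = field(default_factory=dict)
    mean_fd: float = float("nan")
    physio_rating: int = 0
    hr_block: physio.BlockTrace | None = None


def _compcor_columns(vol: Volume4D, wm: Mask3D, csf: Mask3D,
                     cfg: RunConfig) -> np.ndarray:
    if cfg.compcor_per_tissue:
        return np.hstack([compcor(vol, wm, cfg.n_compcor),
                          compcor(vol, csf, cfg.n_compcor)])
    both = Mask3D(wm.data | csf.data, wm.affine)
    return compcor(vol, both, cfg.n_compcor)


def run_subject_arrays(sb: synthdata.SubjectBold, design: TaskDesign,
                       traces: PhysioResult, cfg: RunConfig | None = None,
                       variants: tuple[str, ...] = ("blockwise_hr",),
                       subject: str = "") -> SubjectOutput:
    """Full first-level chain on in-memory arrays for the given variants.

    QC gates first: mean FD above the limit or physio rating 3 marks the
    subject excluded and skips fitting.
    """
    cfg = cfg or RunConfig()
    fd = framewise_displacement(sb.motion, exclude_mm=cfg.fd_limit_mm)
    out = SubjectOutput(subject, None, mean_fd=fd.mean_fd,
                        physio_rating=traces.quality.rating,
                        hr_block=traces.hr_block)
    if fd.excluded:
        out.excluded = "motion"
        return out
    if not traces.quality.usable:
        out.excluded = "physio_quality"
        return out
    dv = dvars(sb.vol, sb.brain)
    nuis = NuisanceSet(motion=sb.motion,
                       motion_diff=np.vstack([np.zeros(6),
                                              np.diff(sb.motion, axis=0)]),
                       spike_flags=dv.spike_flags, fd_series=fd.fd)
    resid = residualize(sb.vol, nuis)
    nuis.compcor = _compcor_columns(resid, sb.wm, sb.csf, cfg)
    smoothed = smooth_gaussian(resid, cfg.fwhm_mm)
    for variant in variants:
        X, weights = build_variant_design(design, variant, traces, nuis, cfg)
        fit = fit_glm(smoothed, X, sb.brain)
        cmap = t_contrast(fit, X.contrast_vector(weights))
        out.effect_maps[variant] = cmap.effect_volume()
        out.t_maps[variant] = cmap.t_volume()
    return out


# ---------------------------------------------------------------------------
# Group level
# ---------------------------------------------------------------------------

def run_group_maps(effect_maps: list[np.ndarray], mask: Mask3D,
                   direction: int, cfg: RunConfig | None = None
                   ) -> grouplevel.GroupResult:
    """One-sample t in one direction + Bonferroni FWE + cluster extraction."""
    cfg = cfg or RunConfig()
    res = grouplevel.one_sample_t(np.stack(effect_maps), mask, direction)
    grouplevel.fwe_voxel_threshold(res, cfg.alpha)
    grouplevel.clusterize(res, cfg.extent_k)
    return res


def effect_size_table(per_variant_maps: dict, rois: dict,
                      main: str = "blockwise_hr") -> pd.DataFrame:
    """Cohen's d of the main variant vs each control per ROI (Table-2 style).

    ``per_variant_maps``: variant -> list of per-subject 3D effect maps;
    ``rois``: roi name -> Mask3D.
    """
    rows = []
    main_stack = np.stack(per_variant_maps[main])
    for roi_name, roi in rois.items():
        betas_main = roistats.extract_roi_betas(main_stack, roi)
        for variant, maps in per_variant_maps.items():
            if variant == main:
                continue
            betas_ctrl = roistats.extract_roi_betas(np.stack(maps), roi)
            entry = roistats.cohens_d_models(betas_main, betas_ctrl,
                                             roi=roi_name, model_a=main,
                                             model_b=variant)
            rows.append({"roi": roi_name, "comparison": f"{main}_vs_{variant}",
                         "d": entry.d, "p": entry.p, "stars": entry.stars})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# File-based cohort run
# ---------------------------------------------------------------------------

def _load_subject(cohort: Path, sid: str, design: TaskDesign):
    func = cohort / sid / "func"
    rec = physio.read_physio(func / f"{sid}_task-stress_physio")
    vol = Volume4D.from_nifti(func / f"{sid}_task-stress_bold.nii.gz",
                              tr=design.tr)
    motion = np.loadtxt(func / f"{sid}_task-stress_motion.tsv")
    tdir = cohort / "derivatives" / "truth" / sid
    masks = {name: Mask3D.from_nifti(tdir / f"{name}_mask.nii.gz")
             for name in ("brain", "wm", "csf", "insula_like",
                          "amygdala_like", "dmn_like")}
    rois = {k: masks[k] for k in ("insula_like", "amygdala_like", "dmn_like")}
    sb = synthdata.SubjectBold(vol, masks["brain"], masks["wm"], masks["csf"],
                               rois, motion, np.empty(0, dtype=int),
                               np.zeros(vol.data.shape[:3]),
                               np.zeros(vol.data.shape[:3]))
    return sb, rec


def run_cohort_dir(cohort_dir, outdir, cfg: RunConfig | None = None,
                   variants: tuple[str, ...] | None = None) -> dict:
    """Analyze a simulated cohort directory end to end; write a report.

    Runs first level for the configured variant (plus any extra ``variants``
    for effect-size comparison), group maps in both directions with cluster
    tables, the Table-2-style effect-size TSV, and the behavioral
    correlation TSV.  Excluded subjects are listed once with a reason.
    """
    cfg = cfg or RunConfig()
    cohort = Path(cohort_dir)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(cohort / "manifest.json") as fh:
        manifest = json.load(fh)
    d = manifest["design"]
    design = synthdata.default_design(
        phases=d["phases"], blocks_per_phase=d["blocks_per_phase"],
        active_s=d["active_s"], rest_s=d["rest_s"], tr=d["tr"],
        n_dummy=d["n_dummy"])
    subjects = sorted(manifest["subject_seeds"])
    variants = variants or (cfg.variant,)
    outputs: list[SubjectOutput] = []
    for sid in subjects:
        sb, rec = _load_subject(cohort, sid, design)
        traces = process_physio(rec, design, cfg,
                                compute_hf="hf_hrv" in variants)
        outputs.append(run_subject_arrays(sb, design, traces, cfg, variants,
                                          subject=sid))
    included = [o for o in outputs if o.excluded is None]
    excluded = [{"subject": o.subject, "reason": o.excluded}
                for o in outputs if o.excluded]
    if len(included) < 3:
        raise ValueError(f"only {len(included)} usable subjects; need >= 3")
    mask = _load_subject(cohort, subjects[0], design)[0].brain
    report: dict = {"config": asdict(cfg), "config_hash": cfg.hash(),
                    "n_included": len(included), "excluded": excluded}
    for direction, tag in ((1, "pos"), (-1, "neg")):
        res = run_group_maps([o.effect_maps[cfg.variant] for o in included],
                             mask, direction, cfg)
        grouplevel.cluster_table(res.clusters).to_csv(
            out / f"group_{cfg.variant}_{tag}_clusters.tsv", sep="\t",
            index=False)
        report[f"n_clusters_{tag}"] = len(res.clusters)
    if len(variants) > 1:
        rois = _load_subject(cohort, subjects[0], design)[0].rois
        per_variant = {v: [o.effect_maps[v] for o in included]
                       for v in variants}
        effect_size_table(per_variant, rois, main=cfg.variant).to_csv(
            out / "effect_sizes.tsv", sep="\t", index=False)
    # behavioral correlations on included subjects with usable HR traces
    ratings = pd.read_csv(cohort / "ratings.tsv", sep="\t")
    idx = [subjects.index(o.subject) for o in included]
    swings = [behav.swing_metrics(o.hr_block, design, subject=o.subject)
              for o in included]
    deltas = synthdata.rating_deltas(ratings.iloc[idx].reset_index(drop=True))
    if len(swings) >= 10:
        corr = behav.corr_with_ratings(swings, deltas)
        pd.DataFrame([asdict(c) for c in corr]).to_csv(
            out / "behavioral_correlations.tsv", sep="\t", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
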