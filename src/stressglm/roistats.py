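"""Region-of-interest summaries: PC1 timecourses, block-locked averages,
and effect-size comparison of model variants on ROI betas.

The first principal component of an ROI's voxel timeseries serves as its
representative timecourse (sign-aligned with the ROI mean so "activation"
keeps its direction).  Block-locked averages show the mean response over the
100 s active+rest cycle per task phase with across-subject 95% confidence
bands.  Model variants are compared by Cohen's d on per-subject mean ROI
betas with a paired t-test, since the same subjects underlie every variant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .firstlevel import Mask3D, Volume4D
from .paradigm import TaskDesign

__all__ = ["ROITimecourse", "BlockLockedAverage", "EffectSizeEntry",
           "roi_first_pc", "block_locked_average", "extract_roi_betas",
           "cohens_d_models"]


@dataclass
class ROITimecourse:
    """Z-scored representative series of one ROI for one subject."""

    series: np.ndarray
    roi_id: str = ""
    subject: str = ""


@dataclass
class BlockLockedAverage:
    time: np.ndarray        # s relative to active-block onset
    mean: np.ndarray
    ci_halfwidth: np.ndarray
    phase: str
    n_blocks: int
    n_subjects: int


@dataclass
class EffectSizeEntry:
    roi: str
    model_a: str
    model_b: str
    d: float
    p: float
    n: int

    @property
    def stars(self) -> str:
        if not np.isfinite(self.p):
            return ""
        for thr, s in ((0.001, "***"), (0.01, "**"), (0.05, "*")):
            if self.p < thr:
                return s
        return "n.s."


def roi_first_pc(vol: Volume4D, roi: Mask3D, roi_id: str = "",
                 subject: str = "") -> ROITimecourse:
    """First principal component of the in-ROI voxel x time matrix.

    Voxel series are temporally centered; the leading right singular vector
    (length n_scans) is sign-aligned to correlate positively with the ROI
    mean series and z-scored.
    """
    Y = vol.data[roi.data].astype(np.float64)      # voxels x t
    Yc = Y - Y.mean(axis=1, keepdims=True)
    if not np.any(Yc.std(axis=1) > 0):
        raise ValueError("ROI has zero temporal variance")
    _, _, Vt = np.linalg.svd(Yc, full_matrices=False)
    pc = Vt[0]
    mean_series = Yc.mean(axis=0)
    if mean_series.std() > 0 and np.corrcoef(pc, mean_series)[0, 1] < 0:
        pc = -pc
    pc = (pc - pc.mean()) / pc.std()
    return ROITimecourse(pc, roi_id=roi_id, subject=subject)


def block_locked_average(tcs: list[ROITimecourse], design: TaskDesign,
                         phase: str) -> BlockLockedAverage:
    """Across-subject mean and 95% t-CI of the block-locked ROI response.

    Per subject, the segments starting at each of the phase's active-block
    onsets (covering the active block plus the following rest, e.g. 100 s)
    are averaged; across subjects a pointwise mean and t-based 95%
    confidence half-width are computed.
    """
    if len(tcs) < 2:
        raise ValueError("need at least 2 subjects")
    actives = [b for b in design.active_blocks if b.phase == phase]
    if not actives:
        raise ValueError(f"phase {phase!r} not present in design")
    rests = {b.onset: b for b in design.blocks if b.kind == "rest"}
    cycle_s = actives[0].duration
    follow = rests.get(actives[0].offset)
    if follow is not None:
        cycle_s += follow.duration
    n_seg = int(round(cycle_s / design.tr))
    subj_means = []
    for tc in tcs:
        segs = []
        for b in actives:
            i0 = int(round(b.onset / design.tr))
            seg = tc.series[i0:i0 + n_seg]
            if seg.size == n_seg:
                segs.append(seg)
        subj_means.append(np.mean(segs, axis=0))
    stack = np.asarray(subj_means)
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sd = stack.std(axis=0, ddof=1)
    hw = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
    return BlockLockedAverage(np.arange(n_seg) * design.tr, mean, hw,
                              phase, len(actives), n)


def extract_roi_betas(effect_maps: np.ndarray, roi: Mask3D) -> np.ndarray:
    """Per-subject mean effect inside the (bilateral-union) ROI mask.

    ``effect_maps`` stacks per-subject effect volumes along axis 0; NaN
    voxels (outside a subject's analysis mask) are ignored.
    """
    maps = np.asarray(effect_maps, dtype=np.float64)
    vals = maps[:, roi.data]
    if np.all(np.isnan(vals)):
        raise ValueError("ROI does not intersect the effect-map support")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(vals, axis=1)


def cohens_d_models(betas_a: np.ndarray, betas_b: np.ndarray,
                    roi: str = "", model_a: str = "a", model_b: str = "b",
                    paired: bool = True) -> EffectSizeEntry:
    """Cohen's d between two model variants' ROI betas, pooled-SD units.

    ``d = (mean_a - mean_b) / sqrt((var_a + var_b) / 2)``; the accompanying
    p-value is a paired t-test on the per-subject differences (the same
    subjects underlie both models).  Antisymmetric under swapping a and b.
    """
    a = np.asarray(betas_a, dtype=float)
    b = np.asarray(betas_b, dtype=float)
    if a.size != b.size:
        raise ValueError("beta vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 subjects")
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        warnings.warn("zero pooled SD; effect size undefined")
        d = 0.0 if np.allclose(a, b) else np.inf
        return EffectSizeEntry(roi, model_a, model_b, d, np.nan, a.size)
    d = float((a.mean() - b.mean()) / pooled)
    if paired:
        if np.allclose(a, b):
            p = np.nan
        else:
            p = float(sps.ttest_rel(a, b).pvalue)
    else:
        p = float(sps.ttest_ind(a, b).pvalue)
    return EffectSizeEntry(roi, model_a, model_b, d, p, a.size)
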