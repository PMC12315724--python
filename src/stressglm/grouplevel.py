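"""Random-effects group inference on first-level contrast maps.

One-sample t-tests across subjects per voxel, one direction at a time
(positive and negative coupling are tested separately), voxel-level
family-wise-error control by Bonferroni over in-mask voxels, and reporting
of suprathreshold clusters (18-connectivity, extent threshold 25 voxels)
with peak statistics in mm coordinates.

Bonferroni replaces random-field-theory FWE: it needs no smoothness
estimation, is exact-or-conservative under any dependence, and its
error-rate guarantee is directly testable by simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy import stats as sps

from .firstlevel import Mask3D

__all__ = ["GroupResult", "ClusterRow", "one_sample_t", "fwe_voxel_threshold",
           "clusterize", "label_clusters", "cluster_table"]

#: SPM-convention connectivity (faces + edges) for cluster formation.
CONNECTIVITY_18 = ndimage.generate_binary_structure(3, 2)
#: Default cluster extent threshold in voxels.
EXTENT_K = 25


@dataclass
class GroupResult:
    """Voxelwise one-sample t-test results for one tested direction."""

    t: np.ndarray                  # 3D, NaN outside mask
    p: np.ndarray                  # 3D, one-sided in the tested direction
    df: int
    direction: int                 # +1 or -1
    mask: Mask3D
    zero_variance: np.ndarray      # 3D bool: voxels with no across-subject spread
    alpha: float | None = None
    voxel_p_threshold: float | None = None
    suprathreshold: np.ndarray | None = None
    clusters: list["ClusterRow"] = field(default_factory=list)


@dataclass
class ClusterRow:
    label: int
    k: int
    peak_t: float
    peak_ijk: tuple[int, int, int]
    peak_mm: tuple[float, float, float]
    peak_p: float
    region_labels: list[tuple[str, float]] = field(default_factory=list)


def one_sample_t(effect_maps: np.ndarray, mask: Mask3D,
                 direction: int = 1) -> GroupResult:
    """Voxelwise t = mean / (sd / sqrt(N)) across subjects, df = N - 1.

    ``effect_maps`` stacks per-subject effect volumes along axis 0.  The
    one-sided p-value is computed in the requested direction; voxels with
    zero across-subject variance are flagged and excluded from thresholding.
    """
    maps = np.asarray(effect_maps, dtype=np.float64)
    n = maps.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    if direction not in (1, -1):
        raise ValueError("direction must be +1 or -1")
    m = mask.data
    vals = maps[:, m]                      # subjects x voxels
    mean = vals.mean(axis=0)
    sd = vals.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[zero_var] = np.sign(mean[zero_var]) * np.inf
    df = n - 1
    p = sps.t.sf(direction * t, df)
    t3 = np.full(m.shape, np.nan)
    p3 = np.full(m.shape, np.nan)
    zv3 = np.zeros(m.shape, dtype=bool)
    t3[m], p3[m], zv3[m] = t, p, zero_var
    return GroupResult(t3, p3, df, direction, mask, zv3)


def fwe_voxel_threshold(result: GroupResult, alpha: float = 0.05,
                        method: str = "bonferroni") -> GroupResult:
    """Apply voxel-level FWE control; sets the suprathreshold mask in place.

    Bonferroni: per-voxel p threshold = alpha / (number of in-mask voxels).
    Zero-variance voxels never enter the suprathreshold set.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if method != "bonferroni":
        raise ValueError(f"unknown FWE method {method!r}")
    n_vox = result.mask.n_voxels
    thr = alpha / n_vox
    supra = np.zeros(result.mask.data.shape, dtype=bool)
    m = result.mask.data
    supra[m] = (result.p[m] < thr) & ~result.zero_variance[m]
    result.alpha = alpha
    result.voxel_p_threshold = thr
    result.suprathreshold = supra
    return result


def clusterize(result: GroupResult, extent_k: int = EXTENT_K,
               connectivity: np.ndarray = CONNECTIVITY_18,
               affine: np.ndarray | None = None) -> list[ClusterRow]:
    """Connected components of the suprathreshold mask, small ones dropped.

    Components are formed under 18-connectivity; only clusters with
    k >= ``extent_k`` voxels are reported, each with its max-|direction| t
    peak and mm coordinates via the mask affine.
    """
    if extent_k < 1:
        raise ValueError("extent_k must be >= 1")
    if result.suprathreshold is None:
        raise ValueError("run fwe_voxel_threshold first")
    aff = affine if affine is not None else result.mask.affine
    labels, n_lab = ndimage.label(result.suprathreshold, structure=connectivity)
    rows: list[ClusterRow] = []
    signed_t = result.direction * result.t
    for lab in range(1, n_lab + 1):
        sel = labels == lab
        k = int(sel.sum())
        if k < extent_k:
            continue
        tvals = np.where(sel, signed_t, -np.inf)
        peak_flat = np.nanargmax(tvals)
        ijk = np.unravel_index(peak_flat, sel.shape)
        mm = tuple(np.asarray(aff @ np.array([*ijk, 1.0]))[:3])
        rows.append(ClusterRow(
            label=lab, k=k,
            peak_t=float(result.t[ijk]),
            peak_ijk=tuple(int(i) for i in ijk),
            peak_mm=tuple(float(x) for x in mm),
            peak_p=float(result.p[ijk])))
    rows.sort(key=lambda r: -r.k)
    result.clusters = rows
    return rows


def label_clusters(rows: list[ClusterRow], result: GroupResult,
                   atlas: np.ndarray | None = None,
                   atlas_names: dict[int, str] | None = None,
                   min_fraction: float = 0.05) -> list[ClusterRow]:
    """Annotate clusters with atlas-label fractions (labels >= 5% of k kept).

    ``atlas`` is an integer label volume on the same grid; without one the
    rows keep coordinates only.
    """
    if atlas is None:
        return rows
    atlas = np.asarray(atlas)
    if atlas.shape != result.mask.data.shape:
        raise ValueError("atlas grid does not match the result grid")
    labels, _ = ndimage.label(result.suprathreshold, structure=CONNECTIVITY_18)
    for row in rows:
        sel = labels == row.label
        in_labels = atlas[sel]
        fracs = []
        for val in np.unique(in_labels):
            frac = float((in_labels == val).sum()) / row.k
            if frac >= min_fraction:
                name = (atlas_names or {}).get(int(val), str(int(val)))
                fracs.append((name, frac))
        row.region_labels = sorted(fracs, key=lambda x: -x[1])
    return rows


def cluster_table(rows: list[ClusterRow]) -> pd.DataFrame:
    """Cluster rows as a tidy table: x, y, z, label, k, %k, p, t."""
    recs = []
    for r in rows:
        if r.region_labels:
            for name, frac in r.region_labels:
                recs.append({"x": r.peak_mm[0], "y": r.peak_mm[1],
                             "z": r.peak_mm[2], "label": name, "k": r.k,
                             "pct_k": 100 * frac, "p": r.peak_p, "t": r.peak_t})
        else:
            recs.append({"x": r.peak_mm[0], "y": r.peak_mm[1], "z": r.peak_mm[2],
                         "label": "", "k": r.k, "pct_k": 100.0,
                         "p": r.peak_p, "t": r.peak_t})
    return pd.DataFrame(recs,
                        columns=["x", "y", "z", "label", "k", "pct_k", "p", "t"])
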