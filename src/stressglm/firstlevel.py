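"""Single-subject nuisance construction and mass-univariate GLM fitting.

The volumes entering this stage are assumed motion-corrected and spatially
normalized already.  The stage reproduces the within-subject statistical
chain: motion quality control (framewise displacement, dvars spikes),
residualization against motion/trend/spikes, anatomical CompCor components
from WM/CSF compartments, Gaussian smoothing, and ordinary-least-squares
fitting of the assembled design with t-contrasts.

Noise model is plain OLS (no AR(1) prewhitening); group inference below is
random-effects across subjects, which is robust to within-subject
autocorrelation misspecification.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np
from scipy import ndimage

from .paradigm import DesignMatrix, Regressor

__all__ = [
    "Volume4D",
    "Mask3D",
    "NuisanceSet",
    "GLMFit",
    "ContrastMap",
    "framewise_displacement",
    "dvars",
    "residualize",
    "compcor",
    "smooth_gaussian",
    "fit_glm",
    "t_contrast",
]

#: Rotation-to-translation radius for framewise displacement, mm.
FD_RADIUS_MM = 50.0
#: Mean-FD subject exclusion threshold, mm.
FD_EXCLUDE_MM = 1.5

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class Volume4D:
    """4D BOLD grid with affine and repetition time."""

    data: np.ndarray          # x, y, z, t
    affine: np.ndarray        # 4x4 voxel -> mm
    tr: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("expected a 4D array")
        if abs(np.linalg.det(np.asarray(self.affine))) < 1e-12:
            raise ValueError("affine is singular")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data, self.affine)
        img.header.set_zooms((*self.voxel_sizes, self.tr))
        return img

    @classmethod
    def from_nifti(cls, img_or_path, tr: float | None = None) -> "Volume4D":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) \
            else nib.load(str(img_or_path))
        if tr is None:
            tr = float(img.header.get_zooms()[3])
        return cls(np.asarray(img.dataobj, dtype=np.float32), img.affine, tr)


@dataclass
class Mask3D:
    """Boolean 3D mask sharing the grid of a companion Volume4D."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("expected a 3D array")
        if not self.data.any():
            raise ValueError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.uint8), self.affine)

    @classmethod
    def from_nifti(cls, img_or_path, threshold: float = 0.5) -> "Mask3D":
        img = img_or_path if isinstance(img_or_path, nib.Nifti1Image) \
            else nib.load(str(img_or_path))
        return cls(np.asarray(img.dataobj) > threshold, img.affine)


@dataclass
class NuisanceSet:
    """Per-scan nuisance series entering the first-level design."""

    motion: np.ndarray | None = None        # n x 6: translations mm, rotations rad
    motion_diff: np.ndarray | None = None
    spike_flags: np.ndarray | None = None   # boolean per scan
    fd_series: np.ndarray | None = None
    compcor: np.ndarray | None = None       # n x k components

    def columns(self) -> list[Regressor]:
        """CompCor components and spike one-hots as design regressors.

        Motion is handled in the residualization stage only, but spike
        scans must be re-excluded in the final model: residualization
        replaces their values with the voxel mean, and that notch would
        otherwise bleed into task/modulator betas.
        """
        out = []
        if self.compcor is not None:
            for k in range(self.compcor.shape[1]):
                out.append(Regressor(f"compcor{k + 1:02d}",
                                     self.compcor[:, k], "nuisance"))
        if self.spike_flags is not None:
            for idx in np.flatnonzero(self.spike_flags):
                onehot = np.zeros(self.spike_flags.size)
                onehot[idx] = 1.0
                out.append(Regressor(f"spike{idx:04d}", onehot, "nuisance"))
        return out


@dataclass
class GLMFit:
    """Per-voxel OLS estimates on an in-mask voxel table."""

    beta: np.ndarray       # voxels x columns
    sigma2: np.ndarray     # voxels
    dof: int
    design: DesignMatrix
    mask: Mask3D | None = None

    def beta_map(self, column: str) -> np.ndarray:
        """Scatter one beta column back into the 3D grid (NaN outside mask)."""
        if self.mask is None:
            raise ValueError("fit carries no mask")
        out = np.full(self.mask.data.shape, np.nan)
        out[self.mask.data] = self.beta[:, self.design.column_index(column)]
        return out


@dataclass
class ContrastMap:
    effect: np.ndarray     # voxels
    t: np.ndarray          # voxels
    contrast: np.ndarray
    dof: int
    mask: Mask3D | None = None

    def effect_volume(self) -> np.ndarray:
        out = np.full(self.mask.data.shape, np.nan)
        out[self.mask.data] = self.effect
        return out

    def t_volume(self) -> np.ndarray:
        out = np.full(self.mask.data.shape, np.nan)
        out[self.mask.data] = self.t
        return out


# ---------------------------------------------------------------------------
# Motion QC
# ---------------------------------------------------------------------------

@dataclass
class FDResult:
    fd: np.ndarray
    mean_fd: float
    excluded: bool


def framewise_displacement(motion: np.ndarray, radius: float = FD_RADIUS_MM,
                           exclude_mm: float = FD_EXCLUDE_MM) -> FDResult:
    """Power-style framewise displacement from 6 rigid-body parameters.

    ``FD_t = sum |d translation| + radius * sum |d rotation|``; the first
    scan gets FD 0.  A subject is flagged for exclusion when mean FD exceeds
    ``exclude_mm`` (default 1.5 mm).
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"expected an n x 6 motion array, got {motion.shape}")
    if radius <= 0:
        raise ValueError("rotation radius must be positive")
    d = np.diff(motion, axis=0)
    fd = np.concatenate([[0.0],
                         np.abs(d[:, :3]).sum(axis=1)
                         + radius * np.abs(d[:, 3:]).sum(axis=1)])
    mean_fd = float(fd.mean())
    return FDResult(fd, mean_fd, mean_fd > exclude_mm)


@dataclass
class DvarsResult:
    series: np.ndarray
    spike_flags: np.ndarray


def dvars(vol: Volume4D, mask: Mask3D,
          spike_iqr_factor: float = 1.5) -> DvarsResult:
    """RMS temporal intensity change over in-mask voxels, median-scaled.

    Spikes are frames whose dvars exceeds median + ``spike_iqr_factor``*IQR
    of the series (frame 0 is 0 by convention and never a spike).
    """
    Y = vol.data[mask.data]                      # voxels x t
    diff = np.diff(Y.astype(np.float64), axis=1)
    series = np.concatenate([[0.0], np.sqrt((diff ** 2).mean(axis=0))])
    med_int = np.median(Y)
    if med_int != 0:
        series = series / abs(med_int)
    rest = series[1:]
    q75, q25 = np.percentile(rest, [75, 25])
    thr = np.median(rest) + spike_iqr_factor * (q75 - q25)
    flags = series > thr
    flags[0] = False
    return DvarsResult(series, flags)


# ---------------------------------------------------------------------------
# Stage-1 residualization and CompCor
# ---------------------------------------------------------------------------

def _drop_dependent_columns(X: np.ndarray, names: list[str]) -> tuple[np.ndarray, list[str]]:
    keep: list[int] = []
    for j in range(X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(f"dropping linearly dependent nuisance column {names[j]!r}")
    return X[:, keep], [names[j] for j in keep]


def residualize(vol: Volume4D, nuisance: NuisanceSet) -> Volume4D:
    """Remove motion, differential motion, spikes, and a linear trend.

    Per-voxel OLS residuals against [constant, linear trend, motion,
    motion_diff, spike one-hots], with the voxel temporal mean re-added so
    percent-signal scaling downstream stays meaningful.
    """
    n = vol.n_scans
    cols = [np.ones(n), np.linspace(-1, 1, n)]
    names = ["constant", "trend"]
    if nuisance.motion is not None:
        for j in range(6):
            cols.append(nuisance.motion[:, j])
            names.append(f"motion{j + 1}")
    if nuisance.motion_diff is not None:
        for j in range(6):
            cols.append(nuisance.motion_diff[:, j])
            names.append(f"motion_diff{j + 1}")
    if nuisance.spike_flags is not None:
        for idx in np.flatnonzero(nuisance.spike_flags):
            onehot = np.zeros(n)
            onehot[idx] = 1.0
            cols.append(onehot)
            names.append(f"spike{idx}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        X, names = _drop_dependent_columns(X, names)
    shape = vol.data.shape
    Y = vol.data.reshape(-1, n).T.astype(np.float64)     # t x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = (resid + Y.mean(axis=0)).T.reshape(shape)
    return Volume4D(out.astype(vol.data.dtype), vol.affine, vol.tr)


def compcor(vol: Volume4D, mask: Mask3D, n_components: int = 5) -> np.ndarray:
    """Anatomical CompCor: top temporal components of noise-tissue voxels.

    Voxel series are variance-normalized; the first ``n_components`` left
    singular vectors of the scans x voxels matrix are returned as unit-norm
    columns, each sign-fixed to correlate positively with its top-loading
    voxel.
    """
    Y = vol.data[mask.data].T.astype(np.float64)   # t x voxels
    if Y.shape[1] <= n_components:
        raise ValueError(
            f"mask has {Y.shape[1]} voxels; need more than {n_components}")
    Y = Y - Y.mean(axis=0)
    sd = Y.std(axis=0)
    ok = sd > 0
    if not ok.any():
        raise ValueError("mask contains only zero-variance voxels")
    Y = Y[:, ok] / sd[ok]
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    comps = U[:, :n_components].copy()
    for k in range(n_components):
        top = np.argmax(np.abs(Vt[k]))
        if Vt[k, top] < 0:
            comps[:, k] = -comps[:, k]
    return comps


def smooth_gaussian(vol: Volume4D, fwhm: float | tuple = 6.0) -> Volume4D:
    """Separable spatial Gaussian smoothing, FWHM given in mm per axis.

    Sigma per axis is converted to voxel units through the affine scales.
    Periodic boundary handling keeps the global mean exactly conserved.
    """
    fwhm_arr = np.broadcast_to(np.asarray(fwhm, dtype=float), (3,))
    if np.any(fwhm_arr < 0):
        raise ValueError("fwhm must be non-negative")
    if np.all(fwhm_arr == 0):
        return vol
    sigma_vox = fwhm_arr * _FWHM_TO_SIGMA / vol.voxel_sizes
    out = ndimage.gaussian_filter(vol.data.astype(np.float64),
                                  sigma=(*sigma_vox, 0.0), mode="wrap")
    return Volume4D(out.astype(vol.data.dtype), vol.affine, vol.tr)


# ---------------------------------------------------------------------------
# GLM
# ---------------------------------------------------------------------------

def fit_glm(vol: Volume4D | np.ndarray, X: DesignMatrix,
            mask: Mask3D | None = None) -> GLMFit:
    """Mass-univariate OLS: beta = (X'X)^-1 X'y per in-mask voxel.

    ``vol`` may also be a plain (scans x voxels) matrix for testing.
    Refuses rank-deficient designs, naming the dependent columns.
    """
    if not X.full_rank:
        dep = _dependent_column_names(X)
        raise ValueError(f"design is rank-deficient; dependent columns: {dep}")
    if isinstance(vol, Volume4D):
        if vol.n_scans != X.n_scans:
            raise ValueError("time dimension does not match design")
        if mask is None:
            raise ValueError("a mask is required for volume input")
        Y = vol.data[mask.data].T.astype(np.float64)
    else:
        Y = np.asarray(vol, dtype=np.float64)
    M = X.matrix
    beta, *_ = np.linalg.lstsq(M, Y, rcond=None)
    resid = Y - M @ beta
    dof = X.n_scans - X.rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    return GLMFit(beta.T, sigma2, dof, X, mask)


def _dependent_column_names(X: DesignMatrix) -> list[str]:
    dep = []
    keep: list[int] = []
    for j in range(X.n_columns):
        if np.linalg.matrix_rank(X.matrix[:, keep + [j]]) == len(keep) + 1:
            keep.append(j)
        else:
            dep.append(X.names[j])
    return dep


def t_contrast(fit: GLMFit, c: np.ndarray) -> ContrastMap:
    """t-statistic map for contrast ``c``: t = c'b / sqrt(s2 * c'(X'X)^-1 c)."""
    c = np.asarray(c, dtype=float)
    if c.size != fit.design.n_columns:
        raise ValueError(
            f"contrast length {c.size} != {fit.design.n_columns} design columns")
    if not np.any(c):
        raise ValueError("contrast vector is all zero")
    M = fit.design.matrix
    xtx_inv = np.linalg.inv(M.T @ M)
    effect = fit.beta @ c
    var_scale = float(c @ xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fit.sigma2 * var_scale)
    return ContrastMap(effect, t, c, fit.dof, fit.mask)
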