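"""Synthetic cohort generator with known ground truth.

Every pipeline stage is exercised on data this module generates: a
continuous heart-rate process with a Stress-phase elevation and
respiratory sinus arrhythmia (RSA) whose amplitude falls with rising HR
(inducing the negative HR <-> HF-HRV coupling seen empirically), beats
placed by time-rescaling, a PPG waveform rendered from the beats, BOLD
volumes with spherical blobs of known task and HR-coupling coefficients,
WM/CSF compartments carrying shared structured noise for CompCor, motion
series with optional spikes, and subjective ratings generated at a known
correlation with the HR upswing.

Defaults emulate the study conditions: 3 phases x 5 blocks of 60 s task +
40 s rest at TR 2 s (750 retained scans), PreStress baseline near 74.6 bpm
with a +7 bpm Stress elevation (observed 81.4 vs 74.6 bpm), pooled
HR <-> HF-HRV correlation near -0.5, and an upswing <-> arousal-change
correlation of 0.3.  The grid is a 24 mm-cube desk-scale stand-in for a
whole brain: it keeps end-to-end runs fast while preserving the full
statistical structure.
"""

from __future__ import annotations

import gzip
import json
import shutil
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as ss
from scipy import stats as sps

from .firstlevel import Mask3D, Volume4D
from .paradigm import TaskDesign, build_task_design, write_events_tsv
from .physio import PhysioRecording, write_physio

__all__ = [
    "GroundTruth",
    "HRProcess",
    "SubjectBold",
    "simulate_hr_process",
    "inject_ectopics",
    "render_ppg",
    "render_bold",
    "simulate_ratings",
    "simulate_cohort",
    "default_design",
]

RATING_VARS = ("scale_positive", "scale_negative", "item_arousal", "item_relaxation")


@dataclass
class GroundTruth:
    """All simulator parameters; the parameter-recovery oracle.

    HR parameters are in bpm unless noted; BOLD coefficients are in percent
    signal change units (baseline 100) per unit regressor, HR coupling per
    bpm of centered blockwise HR.
    """

    # --- heart rate process ---
    hr_baseline_mean: float = 74.0
    hr_baseline_sd: float = 8.0          # between subjects
    stress_elevation: float = 7.0        # added in Stress active blocks
    active_increase: float = 2.0         # added in every active block
    onset_ramp_bpm: float = 1.0          # transient at active onsets
    onset_ramp_tau_s: float = 8.0
    hr_smooth_tau_s: float = 6.0         # first-order lag of HR adjustments
    ou_sd: float = 2.5                   # slow HR wander, stationary sd
    ou_tau_s: float = 60.0
    # --- respiratory sinus arrhythmia (drives HF-HRV) ---
    rsa_freq_hz: float = 0.25
    rsa_amp0: float = 3.0                # bpm at 70 bpm slow HR
    rsa_amp_slope: float = 0.027         # fractional amplitude loss per bpm
    rsa_amp_subject_sd: float = 0.30     # between-subject amplitude factor sd
    # --- BOLD ---
    task_beta_gray: float = 0.5          # % signal per unit task regressor
    task_beta_dmn: float = -0.5
    hr_beta_pos: float = 0.08            # % signal per bpm, "insula-like" blob
    hr_beta_neg: float = -0.08           # "amygdala/hippocampus-like" blob
    bold_noise_sd: float = 1.0           # % signal
    bold_ar1: float = 0.3
    drift_amp: float = 0.5
    structured_noise_amp: float = 1.0    # WM/CSF shared-component amplitude
    gray_structured_frac: float = 0.15   # leakage of shared noise into gray
    onset_transient_amp: float = 0.0     # % signal, Stress-block onsets, neg blob
    # --- motion ---
    motion_step_mm: float = 0.01
    motion_step_rad: float = 2e-4
    spike_prob: float = 0.004
    # --- ratings ---
    rating_upswing_r: float = 0.3        # true corr of item_arousal with upswing
    rating_shared_loading: float = 0.5   # common factor among rating deltas
    # --- bookkeeping ---
    master_seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def default_design(**overrides) -> TaskDesign:
    """The 3 x 5-block, 60 s + 40 s, TR 2 s paradigm (750 retained scans)."""
    kw = dict(phases=3, blocks_per_phase=5, active_s=60.0, rest_s=40.0,
              tr=2.0, n_dummy=5)
    kw.update(overrides)
    return build_task_design(**kw)


# ---------------------------------------------------------------------------
# Heart-rate process and beats
# ---------------------------------------------------------------------------

@dataclass
class HRProcess:
    t: np.ndarray            # s
    hr: np.ndarray           # bpm, includes RSA
    hr_slow: np.ndarray      # bpm, without RSA
    beat_times: np.ndarray   # s
    baseline: float          # this subject's baseline, bpm

    def block_means(self, design: TaskDesign) -> np.ndarray:
        """True mean HR (incl. RSA) per active block — the recovery target."""
        out = np.empty(len(design.active_blocks))
        for j, b in enumerate(design.active_blocks):
            sel = (self.t >= b.onset) & (self.t < b.offset)
            out[j] = self.hr[sel].mean()
        return out


def _ou_process(n: int, dt: float, tau: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    a = np.exp(-dt / tau)
    innov_sd = sd * np.sqrt(1.0 - a * a)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    eps = rng.normal(0.0, innov_sd, size=n - 1)
    for k in range(1, n):
        x[k] = a * x[k - 1] + eps[k - 1]
    return x


def _lag_smooth(x: np.ndarray, dt: float, tau: float) -> np.ndarray:
    """First-order (exponential) lag, modelling sluggish HR adjustment."""
    if tau <= 0:
        return x
    a = np.exp(-dt / tau)
    return ss.lfilter([1.0 - a], [1.0, -a], x, zi=[a * x[0]])[0]


def simulate_hr_process(design: TaskDesign, truth: GroundTruth,
                        seed_or_rng) -> HRProcess:
    """Continuous HR with Stress elevation, onset ramps, OU wander, and RSA.

    Beats are drawn by time-rescaling: the instantaneous rate HR(t)/60 is
    integrated and beats placed at unit increments of the integral (exact
    and invertible).
    """
    rng = np.random.default_rng(seed_or_rng) \
        if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    dt = 0.25
    t = np.arange(0.0, design.duration, dt)
    # truncated at 2.5 sd: a screened cohort has no extreme resting HR
    baseline = rng.normal(truth.hr_baseline_mean, truth.hr_baseline_sd)
    while abs(baseline - truth.hr_baseline_mean) > 2.5 * truth.hr_baseline_sd:
        baseline = rng.normal(truth.hr_baseline_mean, truth.hr_baseline_sd)
    drive = np.zeros(t.size)
    for b in design.active_blocks:
        sel = (t >= b.onset) & (t < b.offset)
        drive[sel] += truth.active_increase
        if b.phase == "Stress":
            drive[sel] += truth.stress_elevation
        drive += truth.onset_ramp_bpm * np.where(
            t >= b.onset, np.exp(-(t - b.onset) / truth.onset_ramp_tau_s), 0.0) \
            * (t >= b.onset) * (t < b.offset)
    drive = _lag_smooth(drive, dt, truth.hr_smooth_tau_s)
    wander = _ou_process(t.size, dt, truth.ou_tau_s, truth.ou_sd, rng)
    hr_slow = baseline + drive + wander
    if np.any(hr_slow <= 30) or np.any(hr_slow >= 200):
        raise ValueError("simulated HR left the physiological range 30-200 bpm")
    # bounded linear amplitude-HR relation: higher HR -> weaker RSA, with a
    # floor/ceiling so HF power stays within a physiological dynamic range
    subj_amp = max(0.3, 1.0 + rng.normal(0.0, truth.rsa_amp_subject_sd))
    amp = truth.rsa_amp0 * subj_amp * np.clip(
        1.0 - truth.rsa_amp_slope * (hr_slow - 70.0), 0.25, 2.0)
    # RSA swing stays below ~5% of HR, keeping beat-to-beat changes
    # physiological (and within artifact-filter tolerance on clean data)
    amp = np.minimum(amp, 0.05 * hr_slow)
    phase0 = rng.uniform(0, 2 * np.pi)
    hr = hr_slow + amp * np.sin(2 * np.pi * truth.rsa_freq_hz * t + phase0)
    # time-rescaling: beats at unit increments of the integrated rate
    cum = np.concatenate([[0.0], np.cumsum((hr[:-1] + hr[1:]) / 2.0) * dt / 60.0])
    n_beats = int(np.floor(cum[-1]))
    beat_times = np.interp(np.arange(1, n_beats + 1), cum, t)
    return HRProcess(t, hr, hr_slow, beat_times, baseline)


def inject_ectopics(beat_times: np.ndarray, n: int,
                    rng: np.random.Generator,
                    shift_fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Shift ``n`` interior beats by +/- ``shift_fraction`` of the local interval.

    Returns the corrupted series and the indices of the shifted beats.
    """
    bt = np.asarray(beat_times, dtype=float).copy()
    if bt.size < n + 4:
        raise ValueError("too few beats to inject ectopics")
    idx = rng.choice(np.arange(2, bt.size - 2), size=n, replace=False)
    for i in sorted(idx):
        local = bt[i] - bt[i - 1]
        bt[i] += rng.choice([-1.0, 1.0]) * shift_fraction * local
    bt = np.sort(bt)
    return bt, np.sort(idx)


# ---------------------------------------------------------------------------
# PPG rendering
# ---------------------------------------------------------------------------

def _pulse_template(fs: float, width_s: float = 0.45) -> np.ndarray:
    """Gamma-shaped systolic pulse, peak-normalized."""
    tt = np.arange(0.0, width_s, 1.0 / fs)
    shape, scale = 3.0, width_s / 9.0
    w = sps.gamma.pdf(tt, shape, scale=scale)
    return w / w.max()


def render_ppg(beat_times: np.ndarray, fs: float = 100.0,
               snr_db: float = 20.0, seed_or_rng=0,
               duration: float | None = None,
               dropout: tuple[float, float] | None = None) -> PhysioRecording:
    """Place a pulse template at each beat, add wander and white noise.

    ``snr_db`` is the ratio of pulse-component variance to noise variance;
    ``dropout`` zeroes the pulse component over (start_s, duration_s).
    """
    if fs < 50:
        raise ValueError("PPG rendering needs fs >= 50 Hz")
    rng = np.random.default_rng(seed_or_rng) \
        if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    beat_times = np.asarray(beat_times, dtype=float)
    if duration is None:
        duration = beat_times[-1] + 1.0
    n = int(round(duration * fs))
    sig = np.zeros(n)
    tpl = _pulse_template(fs)
    # center so the template's systolic peak falls exactly on the beat time
    peak_off = int(np.argmax(tpl))
    for bt in beat_times:
        i0 = int(round(bt * fs)) - peak_off
        lo = max(0, -i0)
        if i0 + lo < n:
            seg = tpl[lo: n - i0]
            sig[i0 + lo:i0 + lo + seg.size] += seg
    if dropout is not None:
        a, d = dropout
        sig[int(a * fs):int((a + d) * fs)] = 0.0
    t = np.arange(n) / fs
    wander = 0.4 * np.sin(2 * np.pi * 0.2 * t + rng.uniform(0, 2 * np.pi))
    noise_sd = np.sqrt(sig.var() / (10.0 ** (snr_db / 10.0)))
    noise = rng.normal(0.0, noise_sd, size=n)
    return PhysioRecording(sig + wander + noise, fs=fs, channel="ppg")


# ---------------------------------------------------------------------------
# BOLD rendering
# ---------------------------------------------------------------------------

@dataclass
class SubjectBold:
    vol: Volume4D
    brain: Mask3D
    wm: Mask3D
    csf: Mask3D
    rois: dict                       # blob name -> Mask3D
    motion: np.ndarray               # n_scans x 6
    spike_frames: np.ndarray         # indices
    hr_beta_map: np.ndarray          # 3D, % signal per bpm
    task_beta_map: np.ndarray        # 3D, % signal


def _sphere(grid: int, center, radius: float) -> np.ndarray:
    idx = np.indices((grid, grid, grid))
    d2 = sum((idx[i] - center[i]) ** 2 for i in range(3))
    return d2 <= radius ** 2


def _smooth_noise_series(n: int, tr: float, rng: np.random.Generator,
                         cutoff_hz: float = 0.05) -> np.ndarray:
    """Unit-variance low-frequency series (shared 'physiological' component)."""
    w = rng.normal(size=n)
    b, a = ss.butter(2, cutoff_hz * 2 * tr)
    x = ss.filtfilt(b, a, w)
    return (x - x.mean()) / x.std()


def render_bold(design: TaskDesign, hr_block_values: np.ndarray,
                truth: GroundTruth, seed_or_rng=0, grid: int = 24,
                voxel_mm: float = 2.0) -> SubjectBold:
    """Render one subject's 4D BOLD with planted task and HR coupling.

    Geometry (voxel units, ``grid`` cube): a radius-10 "gray" sphere at the
    center containing three radius-3 blobs — positive HR coupling
    ("insula-like"), negative HR coupling ("amygdala/hippocampus-like"),
    and negative task coupling ("DMN-like") — plus disjoint WM and CSF
    spheres carrying shared structured noise for CompCor.

    Voxel model: ``100 + task_beta * conv(task boxcar) + hr_beta *
    conv(centered-HR-weighted boxcar) + drift + structured noise + AR(1)
    noise``, all in percent-signal units.
    """
    from .paradigm import (HRFParams, build_block_modulator,
                           build_task_regressor)

    if grid < 16:
        raise ValueError("grid must be at least 16 voxels per axis")
    rng = np.random.default_rng(seed_or_rng) \
        if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    c = grid // 2
    r_gray = grid * 10.0 / 24.0
    r_blob = max(2.0, grid * 3.0 / 24.0)
    gray = _sphere(grid, (c, c, c), r_gray)
    off = int(round(grid * 5.0 / 24.0))
    blob_pos = _sphere(grid, (c - off, c, c), r_blob)
    blob_neg = _sphere(grid, (c + off, c, c), r_blob)
    blob_dmn = _sphere(grid, (c, c + off, c), r_blob)
    for a_m, b_m in [(blob_pos, blob_neg), (blob_pos, blob_dmn),
                     (blob_neg, blob_dmn)]:
        if np.any(a_m & b_m):
            raise ValueError("ROI blobs overlap; enlarge the grid")
    corner = int(round(grid * 4.0 / 24.0))
    r_tissue = max(2.0, grid * 3.0 / 24.0)
    wm = _sphere(grid, (corner, corner, corner), r_tissue)
    csf = _sphere(grid, (grid - 1 - corner,) * 3, r_tissue)
    wm &= ~gray
    csf &= ~gray

    n = design.n_scans
    hrf = HRFParams()
    task_reg = build_task_regressor(design, hrf).values
    mod_reg = build_block_modulator(design, np.asarray(hr_block_values), hrf).values

    task_map = np.zeros((grid,) * 3)
    task_map[gray] = truth.task_beta_gray
    task_map[blob_dmn] = truth.task_beta_dmn
    hr_map = np.zeros((grid,) * 3)
    hr_map[blob_pos] = truth.hr_beta_pos
    hr_map[blob_neg] = truth.hr_beta_neg

    support = gray | wm | csf
    nv = int(support.sum())
    flat_task = task_map[support]
    flat_hr = hr_map[support]

    # AR(1) noise, voxelwise
    white = rng.normal(0.0, truth.bold_noise_sd, size=(n, nv))
    noise = ss.lfilter([1.0], [1.0, -truth.bold_ar1], white, axis=0)
    noise *= np.sqrt(1.0 - truth.bold_ar1 ** 2)

    # slow drift below the high-pass cutoff
    tsec = design.scan_times()
    drift_series = np.cos(2 * np.pi * tsec / 800.0 + rng.uniform(0, 2 * np.pi)) \
        + 0.5 * np.cos(2 * np.pi * tsec / 400.0 + rng.uniform(0, 2 * np.pi))
    drift_amp = rng.normal(truth.drift_amp, 0.2 * abs(truth.drift_amp), size=nv)

    # shared structured noise: strong in WM/CSF, weak leakage into gray
    comp1 = _smooth_noise_series(n, design.tr, rng)
    comp2 = _smooth_noise_series(n, design.tr, rng)
    tissue_flat = (wm | csf)[support]
    load1 = np.where(tissue_flat, rng.normal(1.0, 0.3, nv),
                     rng.normal(truth.gray_structured_frac, 0.05, nv))
    load2 = np.where(tissue_flat, rng.normal(1.0, 0.3, nv),
                     rng.normal(truth.gray_structured_frac, 0.05, nv))
    structured = truth.structured_noise_amp * (
        np.outer(comp1, load1) + np.outer(comp2, load2))

    Y = (100.0
         + np.outer(task_reg, flat_task)
         + np.outer(mod_reg, flat_hr)
         + np.outer(drift_series, drift_amp)
         + structured
         + noise)

    if truth.onset_transient_amp:
        trans = np.zeros(n)
        for b in design.active_blocks:
            if b.phase != "Stress":
                continue
            i0 = int(round(b.onset / design.tr))
            length = int(round(8.0 / design.tr))
            trans[i0:i0 + length] = 1.0
        from .paradigm import canonical_hrf
        k = canonical_hrf(hrf, design.tr)
        trans = np.convolve(trans, k)[:n]
        Y[:, blob_neg[support]] += truth.onset_transient_amp * trans[:, None]

    # motion random walk + spikes
    steps = np.concatenate([
        rng.normal(0.0, truth.motion_step_mm, size=(n, 3)),
        rng.normal(0.0, truth.motion_step_rad, size=(n, 3))], axis=1)
    motion = np.cumsum(steps, axis=0)
    spikes = np.flatnonzero(rng.random(n) < truth.spike_prob)
    for s in spikes:
        motion[s:, :3] += rng.normal(0.0, 0.3, size=3)
        Y[s] *= 1.03

    data = np.zeros((grid, grid, grid, n), dtype=np.float32)
    data[support] = Y.T.astype(np.float32)
    aff = np.diag([voxel_mm] * 3 + [1.0])
    aff[:3, 3] = -voxel_mm * c
    vol = Volume4D(data, aff, tr=design.tr)
    rois = {"insula_like": Mask3D(blob_pos, aff),
            "amygdala_like": Mask3D(blob_neg, aff),
            "dmn_like": Mask3D(blob_dmn, aff)}
    return SubjectBold(vol, Mask3D(gray, aff), Mask3D(wm, aff), Mask3D(csf, aff),
                       rois, motion, spikes, hr_map, task_map)


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def simulate_ratings(upswings: np.ndarray, truth: GroundTruth,
                     seed_or_rng=0) -> pd.DataFrame:
    """Pre/post rating scores with a planted upswing correlation.

    ``item_arousal`` change correlates ``rating_upswing_r`` with the HR
    upswing (``item_relaxation`` at the negated value); the two scale sums
    are essentially upswing-independent.  All deltas share a common factor
    so the rating correlation matrix is non-diagonal and m_eff < M.
    Scores are continuous analogs of Likert-sum scales.
    """
    rng = np.random.default_rng(seed_or_rng) \
        if not isinstance(seed_or_rng, np.random.Generator) else seed_or_rng
    up = np.asarray(upswings, dtype=float)
    z = (up - up.mean()) / up.std()
    n = up.size
    shared = rng.normal(size=n)
    c = truth.rating_shared_loading
    rho = {"scale_positive": 0.05, "scale_negative": -0.05,
           "item_arousal": truth.rating_upswing_r,
           "item_relaxation": -truth.rating_upswing_r}
    rows = {}
    for name in RATING_VARS:
        r = rho[name]
        resid_sd = np.sqrt(max(1e-9, 1.0 - r * r))
        e = c * shared + np.sqrt(1.0 - c * c) * rng.normal(size=n)
        delta = r * z + resid_sd * e
        pre = rng.normal(3.5, 0.7, size=n)
        rows[f"{name}_pre"] = pre
        rows[f"{name}_post"] = pre + delta
    df = pd.DataFrame(rows)
    df.insert(0, "subject", [f"sub-{i + 1:02d}" for i in range(n)])
    return df


def rating_deltas(ratings: pd.DataFrame) -> pd.DataFrame:
    """Post-minus-pre change per rating variable."""
    return pd.DataFrame({v: ratings[f"{v}_post"] - ratings[f"{v}_pre"]
                         for v in RATING_VARS})


# ---------------------------------------------------------------------------
# Cohort on disk
# ---------------------------------------------------------------------------

def _write_nifti_gz(img_bytes: bytes, path: Path) -> None:
    with open(path, "wb") as fh:
        with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(img_bytes)


def simulate_cohort(n_subjects: int, outdir, design: TaskDesign | None = None,
                    truth: GroundTruth | None = None, master_seed: int = 0,
                    grid: int = 24, snr_db: float = 20.0,
                    n_low_snr: int = 0, low_snr_db: float = -20.0,
                    physio_only: bool = False, force: bool = False) -> dict:
    """Write a BIDS-like synthetic cohort and its ground-truth manifest.

    Per subject: ``sub-XX/func/`` with BOLD NIfTI (unless ``physio_only``),
    events TSV, physio TSV.GZ + JSON, motion TSV; cohort-level ratings TSV
    and ``manifest.json`` recording every truth parameter and per-subject
    seed (``master_seed + i``).  Deterministic: the same seed reproduces
    byte-identical output.  The last ``n_low_snr`` subjects get unusable
    (very low SNR) physio traces, emulating quality-based exclusions.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    design = design or default_design()
    truth = truth or GroundTruth(master_seed=master_seed)
    out = Path(outdir)
    if out.exists() and any(out.iterdir()):
        if not force:
            raise FileExistsError(f"{out} exists and is not empty (use force)")
        shutil.rmtree(out)
    out.mkdir(parents=True, exist_ok=True)

    upswings = np.empty(n_subjects)
    subject_seeds = {}
    for i in range(n_subjects):
        sid = f"sub-{i + 1:02d}"
        seed = int(master_seed + i)
        subject_seeds[sid] = seed
        rng = np.random.default_rng(seed)
        func = out / sid / "func"
        func.mkdir(parents=True)
        proc = simulate_hr_process(design, truth, rng)
        tm = proc.block_means(design)
        phases = np.array([b.phase for b in design.active_blocks])
        upswings[i] = tm[phases == "Stress"].mean() - tm[phases == "PreStress"].mean()
        this_snr = low_snr_db if i >= n_subjects - n_low_snr else snr_db
        rec = render_ppg(proc.beat_times, fs=100.0, snr_db=this_snr,
                         seed_or_rng=rng, duration=design.duration)
        write_physio(rec, func / f"{sid}_task-stress_physio")
        write_events_tsv(design, func / f"{sid}_task-stress_events.tsv")
        if not physio_only:
            sb = render_bold(design, tm, truth, seed_or_rng=rng, grid=grid)
            _write_nifti_gz(sb.vol.to_nifti().to_bytes(),
                            func / f"{sid}_task-stress_bold.nii.gz")
            np.savetxt(func / f"{sid}_task-stress_motion.tsv", sb.motion,
                       delimiter="\t", fmt="%.6f")
            tdir = out / "derivatives" / "truth" / sid
            tdir.mkdir(parents=True)
            for name, m in [("brain", sb.brain), ("wm", sb.wm), ("csf", sb.csf),
                            *[(k, v) for k, v in sb.rois.items()]]:
                _write_nifti_gz(m.to_nifti().to_bytes(),
                                tdir / f"{name}_mask.nii.gz")
            import nibabel as nib
            _write_nifti_gz(nib.Nifti1Image(sb.hr_beta_map, sb.vol.affine
                                            ).to_bytes(),
                            tdir / "hr_beta_map.nii.gz")
        else:
            np.savetxt(func / f"{sid}_task-stress_motion.tsv",
                       np.zeros((design.n_scans, 6)), delimiter="\t", fmt="%.6f")

    ratings = simulate_ratings(upswings, truth,
                               np.random.default_rng(master_seed + 10_000))
    ratings.to_csv(out / "ratings.tsv", sep="\t", index=False,
                   float_format="%.6f")
    manifest = {
        "n_subjects": n_subjects,
        "master_seed": int(master_seed),
        "grid": grid,
        "snr_db": snr_db,
        "n_low_snr": n_low_snr,
        "physio_only": physio_only,
        "subject_seeds": subject_seeds,
        "truth": truth.to_dict(),
        "design": {"phases": len(design.phases),
                   "blocks_per_phase":
                       len(design.active_blocks) // len(design.phases),
                   "active_s": design.active_blocks[0].duration,
                   "rest_s": design.blocks[1].duration,
                   "tr": design.tr, "n_scans": design.n_scans,
                   "n_dummy": design.n_dummy},
        "true_upswings": [float(u) for u in upswings],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
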