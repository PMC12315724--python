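"""Pulse plethysmography processing: beats, inter-beat intervals, HR, HF-HRV.

The chain mirrors a standard PPG pipeline: resample the raw trace to 100 Hz,
detect pulse peaks on the band-passed signal, filter the resulting inter-beat
intervals (IBIs) against a running-mean heart rate with a relative tolerance
(default 12% against the last 50 accepted beats, the RHRV convention), then
average instantaneous HR per active task block and per scan, and integrate
high-frequency (0.15-0.40 Hz) heart-rate-variability power in 300 s sliding
windows shifted by 30 s.

Visual quality rating of the original workflow is replaced by an automated
3-point surrogate driven by the rejected-interval fraction and the longest
beat gap; recordings rated 3 are excluded, mirroring the ">2 excluded" rule.
"""

from __future__ import annotations

import gzip
import json
import warnings
from collections import deque
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal as ss
from scipy.interpolate import CubicSpline

from .paradigm import TaskDesign

__all__ = [
    "PhysioRecording",
    "BeatSeries",
    "IBISeries",
    "QualityReport",
    "BlockTrace",
    "VolumeTrace",
    "SlidingTrace",
    "resample",
    "detect_beats",
    "filter_ibis",
    "hr_block_means",
    "hr_volume_means",
    "hf_hrv",
    "block_average_windows",
    "hr_hf_correlation",
    "read_physio",
    "write_physio",
]

#: Physiological IBI bounds in ms (30-200 bpm).
IBI_BOUNDS_MS = (300.0, 2000.0)
#: Minimum inter-peak distance in s (refractory period).
REFRACTORY_S = 0.3


@dataclass
class PhysioRecording:
    """A continuous physiological channel with sampling metadata."""

    samples: np.ndarray
    fs: float                  # Hz
    start_offset: float = 0.0  # s relative to first retained scan
    channel: str = "ppg"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        if self.samples.size == 0:
            raise ValueError("recording is empty")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_offset + np.arange(self.samples.size) / self.fs


@dataclass
class BeatSeries:
    """Detected pulse-peak times in seconds, strictly increasing."""

    beat_times: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if self.beat_times.size > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    def __len__(self) -> int:
        return self.beat_times.size


@dataclass
class QualityReport:
    rating: int                # 1 (good) .. 3 (unusable)
    rejected_fraction: float
    longest_gap_s: float

    @property
    def usable(self) -> bool:
        return self.rating < 3


@dataclass
class IBISeries:
    """Successive inter-beat intervals with per-interval accept flags.

    Rejected intervals are flagged, never deleted, so downstream averaging
    can honour only the accepted subset while the full series stays
    inspectable.
    """

    beat_times: np.ndarray
    interval_ms: np.ndarray
    accepted: np.ndarray

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.interval_ms = np.asarray(self.interval_ms, dtype=float)
        self.accepted = np.asarray(self.accepted, dtype=bool)

    @property
    def midpoints(self) -> np.ndarray:
        """Interval midpoints in s, the time stamp used for block assignment."""
        return self.beat_times[:-1] + self.interval_ms / 2000.0

    @property
    def instantaneous_hr(self) -> np.ndarray:
        """bpm per interval."""
        return 60000.0 / self.interval_ms

    @property
    def rejected_fraction(self) -> float:
        return 1.0 - self.accepted.mean() if self.accepted.size else 1.0


@dataclass
class BlockTrace:
    """One physiological value per active task block."""

    values: np.ndarray
    units: str = "bpm"
    block_ids: np.ndarray | None = None
    phases: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.block_ids is None:
            self.block_ids = np.arange(self.values.size)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"block_id": self.block_ids, "value": self.values,
                      "units": self.units}).to_csv(path, sep="\t", index=False)


@dataclass
class VolumeTrace:
    """One physiological value per retained scan."""

    values: np.ndarray
    units: str = "bpm"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"scan_index": np.arange(self.values.size),
                      "value": self.values, "units": self.units}
                     ).to_csv(path, sep="\t", index=False)


@dataclass
class SlidingTrace:
    """Values on sliding-window centers (HF-HRV convention: 300 s / 30 s)."""

    times: np.ndarray   # s, window centers
    values: np.ndarray
    units: str = "bpm^2"


# ---------------------------------------------------------------------------
# Resampling and beat detection
# ---------------------------------------------------------------------------

def resample(rec: PhysioRecording, fs_target: float) -> PhysioRecording:
    """Polyphase resampling with anti-aliasing at 0.45 * fs_target.

    Identity when the target rate equals the current rate.
    """
    if fs_target <= 0:
        raise ValueError("target rate must be positive")
    if abs(fs_target - rec.fs) < 1e-12:
        return rec
    frac = Fraction(fs_target / rec.fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    if down > up:  # downsampling: FIR low-pass at 0.45 * fs_target
        numtaps = 2 * 10 * down + 1
        h = ss.firwin(numtaps, 0.45 * fs_target, fs=rec.fs * up) * up
        out = ss.resample_poly(rec.samples, up, down, window=h)
    else:
        out = ss.resample_poly(rec.samples, up, down)
    return PhysioRecording(out, fs=fs_target, start_offset=rec.start_offset,
                           channel=rec.channel)


def _rolling_iqr(x: np.ndarray, fs: float, window_s: float = 10.0) -> np.ndarray:
    """Per-sample IQR estimated in non-overlapping windows, step-interpolated."""
    w = max(1, int(round(window_s * fs)))
    n_win = max(1, int(np.ceil(x.size / w)))
    iqr = np.empty(n_win)
    centers = np.empty(n_win)
    for i in range(n_win):
        seg = x[i * w:(i + 1) * w]
        q75, q25 = np.percentile(seg, [75, 25])
        iqr[i] = q75 - q25
        centers[i] = (i * w + min((i + 1) * w, x.size)) / 2.0
    return np.interp(np.arange(x.size), centers, iqr)


def detect_beats(rec: PhysioRecording,
                 band: tuple[float, float] = (0.5, 8.0),
                 prominence_factor: float = 0.4,
                 refractory_s: float = REFRACTORY_S,
                 ibi_tolerance: float = 0.12,
                 ibi_window: int = 50) -> tuple[BeatSeries, QualityReport]:
    """Detect pulse peaks and rate recording quality.

    Peaks are local maxima of the zero-phase band-passed signal whose
    prominence exceeds ``prominence_factor`` times a rolling 10 s IQR, at
    least ``refractory_s`` apart.  The quality surrogate re-runs the IBI
    filter internally: rating 1 if <5% rejected and longest gap <3 s,
    rating 2 if <15% and <10 s, else 3 (unusable).
    """
    x = rec.samples
    if np.ptp(x) < 1e-12:
        return (BeatSeries(np.empty(0)),
                QualityReport(3, 1.0, rec.duration))
    nyq = rec.fs / 2.0
    hi = min(band[1], 0.95 * nyq)
    sos = ss.butter(3, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    filt = ss.sosfiltfilt(sos, x)
    iqr = _rolling_iqr(filt, rec.fs)
    # floor at 30% of the global IQR so signal dropouts (where the local IQR
    # collapses) do not let pure noise through as "beats"
    q75, q25 = np.percentile(filt, [75, 25])
    iqr = np.maximum(iqr, 0.3 * (q75 - q25))
    thr = np.maximum(prominence_factor * iqr, 1e-6 * np.ptp(filt))
    peaks, _ = ss.find_peaks(filt, prominence=thr,
                             distance=max(1, int(round(refractory_s * rec.fs))))
    beat_times = rec.start_offset + peaks / rec.fs
    beats = BeatSeries(beat_times)
    if len(beats) < 2:
        return beats, QualityReport(3, 1.0, rec.duration)
    gaps = np.diff(beat_times)
    edge = max(beat_times[0] - rec.start_offset,
               rec.start_offset + rec.duration - beat_times[-1])
    longest_gap = float(max(gaps.max(), edge))
    ibis = filter_ibis(beats, tolerance=ibi_tolerance, window=ibi_window)
    rf = ibis.rejected_fraction
    if rf < 0.05 and longest_gap < 3.0:
        rating = 1
    elif rf < 0.15 and longest_gap < 10.0:
        rating = 2
    else:
        rating = 3
    return beats, QualityReport(rating, float(rf), longest_gap)


def filter_ibis(beats: BeatSeries, tolerance: float = 0.12,
                window: int = 50, reacquire_n: int = 10) -> IBISeries:
    """Flag artifactual inter-beat intervals against a running-mean HR.

    An interval is accepted iff its implied instantaneous HR lies within
    ``tolerance`` (relative) of the mean HR over the last ``window`` accepted
    beats AND the interval is physiologically plausible (300-2000 ms).  The
    first in-bounds interval seeds the running mean.

    A pure running-mean rule can self-lock: after a sustained genuine HR
    shift the stale reference rejects every subsequent beat.  When
    ``reacquire_n`` consecutive in-bounds rejections are mutually consistent
    (each within ``tolerance`` of their own mean) the reference re-seeds
    from them.  Isolated ectopics produce alternating short/long intervals
    that are never mutually consistent, so they stay fully rejected.
    """
    if not 0 < tolerance < 1:
        raise ValueError("tolerance must lie in (0, 1)")
    if window < 1:
        raise ValueError("window must be >= 1")
    t = beats.beat_times
    if t.size < 2:
        return IBISeries(t, np.empty(0), np.empty(0, dtype=bool))
    ibi_ms = np.diff(t) * 1000.0
    accepted = np.zeros(ibi_ms.size, dtype=bool)
    recent: deque[float] = deque(maxlen=window)
    rejected_run: deque[float] = deque(maxlen=reacquire_n)
    lo, hi = IBI_BOUNDS_MS
    for i, ms in enumerate(ibi_ms):
        if not lo <= ms <= hi:
            rejected_run.clear()
            continue
        hr = 60000.0 / ms
        if not recent:
            accepted[i] = True
            recent.append(hr)
            continue
        mean_hr = sum(recent) / len(recent)
        if abs(hr - mean_hr) <= tolerance * mean_hr:
            accepted[i] = True
            recent.append(hr)
            rejected_run.clear()
            continue
        rejected_run.append(hr)
        if len(rejected_run) == reacquire_n:
            m = sum(rejected_run) / reacquire_n
            if all(abs(h - m) <= tolerance * m for h in rejected_run):
                recent.clear()
                recent.extend(rejected_run)
                accepted[i] = True        # current beat survives re-seeding
                rejected_run.clear()
    return IBISeries(t, ibi_ms, accepted)


# ---------------------------------------------------------------------------
# HR traces
# ---------------------------------------------------------------------------

def hr_block_means(ibis: IBISeries, design: TaskDesign) -> BlockTrace:
    """Mean instantaneous HR (bpm) over accepted intervals per active block.

    An interval belongs to the block containing its midpoint.  Blocks with no
    accepted interval get NaN and a warning; the exclusion decision is left
    to the pipeline.
    """
    mids = ibis.midpoints[ibis.accepted]
    hrs = ibis.instantaneous_hr[ibis.accepted]
    actives = design.active_blocks
    values = np.full(len(actives), np.nan)
    for j, b in enumerate(actives):
        sel = (mids >= b.onset) & (mids < b.offset)
        if sel.any():
            values[j] = hrs[sel].mean()
        else:
            warnings.warn(f"active block {j} has no accepted intervals")
    return BlockTrace(values, units="bpm",
                      phases=tuple(b.phase for b in actives))


def hr_volume_means(ibis: IBISeries, design: TaskDesign) -> VolumeTrace:
    """Instantaneous HR linearly interpolated to scan midtimes (edge-held)."""
    mids = ibis.midpoints[ibis.accepted]
    hrs = ibis.instantaneous_hr[ibis.accepted]
    if mids.size < 2:
        raise ValueError("need at least two accepted intervals")
    scan_t = design.scan_midtimes()
    if scan_t[0] < mids[0] or scan_t[-1] > mids[-1]:
        warnings.warn("scan times extend beyond beat coverage; edge values held")
    return VolumeTrace(np.interp(scan_t, mids, hrs), units="bpm")


# ---------------------------------------------------------------------------
# HF-HRV
# ---------------------------------------------------------------------------

def hf_hrv(ibis: IBISeries, band: tuple[float, float] = (0.15, 0.40),
           window_s: float = 300.0, shift_s: float = 30.0,
           resample_hz: float = 4.0) -> SlidingTrace:
    """High-frequency HRV power in sliding windows.

    Instantaneous HR at accepted-interval midpoints is cubic-interpolated to
    a uniform ``resample_hz`` grid; each window is linearly detrended, its
    FFT periodogram integrated over ``band``; the value is stamped at the
    window center.
    """
    mids = ibis.midpoints[ibis.accepted]
    hrs = ibis.instantaneous_hr[ibis.accepted]
    if mids.size < 4:
        raise ValueError("too few accepted intervals for spectral analysis")
    coverage = mids[-1] - mids[0]
    if coverage < window_s:
        raise ValueError(
            f"recording covers {coverage:.0f} s; at least {window_s:.0f} s required")
    grid = np.arange(mids[0], mids[-1], 1.0 / resample_hz)
    hr_u = CubicSpline(mids, hrs)(grid)
    n_w = int(round(window_s * resample_hz))
    step = int(round(shift_s * resample_hz))
    centers, power = [], []
    for start in range(0, hr_u.size - n_w + 1, step):
        seg = ss.detrend(hr_u[start:start + n_w], type="linear")
        f, psd = ss.periodogram(seg, fs=resample_hz, window="boxcar",
                                detrend=False)
        sel = (f >= band[0]) & (f <= band[1])
        df = f[1] - f[0]
        power.append(psd[sel].sum() * df)
        centers.append(grid[start] + window_s / 2.0)
    return SlidingTrace(np.asarray(centers), np.asarray(power), units="bpm^2")


def block_average_windows(trace: SlidingTrace, design: TaskDesign) -> BlockTrace:
    """Average sliding-window values whose centers fall within each active block.

    Blocks shorter than the window shift may contain no center; those are
    filled from the nearest window center so the HF-HRV modulator stays
    defined for every block.
    """
    actives = design.active_blocks
    values = np.full(len(actives), np.nan)
    for j, b in enumerate(actives):
        sel = (trace.times >= b.onset) & (trace.times < b.offset)
        if sel.any():
            values[j] = trace.values[sel].mean()
        else:
            mid = b.onset + b.duration / 2.0
            values[j] = trace.values[np.argmin(np.abs(trace.times - mid))]
    return BlockTrace(values, units=trace.units,
                      phases=tuple(b.phase for b in actives))


def hr_hf_correlation(hr_traces: list[BlockTrace],
                      hf_traces: list[BlockTrace]) -> float:
    """Pearson r between HR and HF-HRV pooled over subject x block pairs."""
    hr = np.concatenate([t.values for t in hr_traces])
    hf = np.concatenate([t.values for t in hf_traces])
    if hr.size != hf.size:
        raise ValueError("paired traces must pool to equal length")
    ok = np.isfinite(hr) & np.isfinite(hf)
    hr, hf = hr[ok], hf[ok]
    if hr.std() == 0 or hf.std() == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan")
    return float(np.corrcoef(hr, hf)[0, 1])


# ---------------------------------------------------------------------------
# BIDS physio IO
# ---------------------------------------------------------------------------

def write_physio(rec: PhysioRecording, path) -> None:
    """Write a BIDS-style physio pair: <path>.tsv.gz + <path>.json.

    The gzip member carries mtime 0 so identical data give identical bytes.
    """
    base = str(path)
    if base.endswith(".tsv.gz"):
        base = base[:-7]
    body = "\n".join(f"{v:.6f}" for v in rec.samples) + "\n"
    with open(base + ".tsv.gz", "wb") as fh:
        with gzip.GzipFile(filename="", fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(body.encode())
    sidecar = {"SamplingFrequency": rec.fs, "StartTime": rec.start_offset,
               "Columns": [rec.channel]}
    with open(base + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)


def read_physio(path) -> PhysioRecording:
    base = str(path)
    if base.endswith(".tsv.gz"):
        base = base[:-7]
    with open(base + ".json") as fh:
        meta = json.load(fh)
    samples = pd.read_csv(base + ".tsv.gz", sep="\t", header=None).to_numpy().ravel()
    return PhysioRecording(samples, fs=float(meta["SamplingFrequency"]),
                           start_offset=float(meta.get("StartTime", 0.0)),
                           channel=(meta.get("Columns") or ["ppg"])[0])
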