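"""Task timing and design-matrix construction for the block stress paradigm.

The paradigm is a Montreal-Imaging-Stress-Task variant: three phases
(PreStress, Stress, PostStress), each five blocks of 60 s mental arithmetic
followed by 40 s rest.  All regressors are built at microtime resolution
(``microtime_bins`` per TR), convolved with a canonical double-gamma
hemodynamic response function, and sampled at scan onsets.

Heart rate (or HF-HRV power) enters the model as a *parametric modulator*:
a boxcar restricted to the active blocks whose height per block (or per
scan, for the volumewise variant) is the mean-centered physiological value.
Mean-centering is the only orthogonalization applied, so the task beta keeps
its interpretation as the response at the average heart rate.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "Block",
    "TaskDesign",
    "HRFParams",
    "Regressor",
    "DesignMatrix",
    "build_task_design",
    "canonical_hrf",
    "build_task_regressor",
    "build_block_modulator",
    "build_volume_modulator",
    "build_phasewise_regressors",
    "build_onset_control",
    "trim_block_onsets",
    "dct_highpass_basis",
    "assemble_design",
    "read_events_tsv",
    "write_events_tsv",
]

#: Canonical phase labels of the three-phase design, in task order.
PHASES = ("PreStress", "Stress", "PostStress")

_PHASE_TSV = {"PreStress": "pre", "Stress": "stress", "PostStress": "post"}
_TSV_PHASE = {v: k for k, v in _PHASE_TSV.items()}


@dataclass(frozen=True)
class Block:
    """One task block: ``kind`` is ``"active"`` or ``"rest"``."""

    onset: float      # s, relative to first retained scan
    duration: float   # s
    kind: str
    phase: str

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class TaskDesign:
    """Full block timing plus acquisition parameters.

    Onsets are expressed relative to the first *retained* scan; the
    ``n_dummy`` leading volumes discarded for T1 equilibration are counted
    separately and never appear in regressors.
    """

    blocks: tuple[Block, ...]
    tr: float
    n_scans: int
    n_dummy: int = 0
    microtime_bins: int = 16

    def __post_init__(self) -> None:
        prev_end = -np.inf
        for b in self.blocks:
            if b.onset < prev_end - 1e-9:
                raise ValueError(f"blocks overlap or are unordered at onset {b.onset}")
            prev_end = b.offset
        if self.tr <= 0 or self.n_scans <= 0:
            raise ValueError("tr and n_scans must be positive")

    @property
    def active_blocks(self) -> tuple[Block, ...]:
        return tuple(b for b in self.blocks if b.kind == "active")

    @property
    def phases(self) -> tuple[str, ...]:
        seen: list[str] = []
        for b in self.blocks:
            if b.phase not in seen:
                seen.append(b.phase)
        return tuple(seen)

    @property
    def duration(self) -> float:
        return self.n_scans * self.tr

    @property
    def n_acquired(self) -> int:
        """Total acquired volumes including discarded dummies."""
        return self.n_scans + self.n_dummy

    def scan_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr

    def scan_midtimes(self) -> np.ndarray:
        return (np.arange(self.n_scans) + 0.5) * self.tr


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma hemodynamic response parameters (SPM-convention defaults)."""

    peak_delay: float = 6.0          # s
    undershoot_delay: float = 16.0   # s
    peak_dispersion: float = 1.0     # s
    undershoot_dispersion: float = 1.0  # s
    ratio: float = 6.0               # peak:undershoot amplitude ratio
    length: float = 32.0             # s

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")
        if self.length < self.undershoot_delay:
            raise ValueError("HRF kernel length must cover the undershoot delay")


@dataclass(frozen=True)
class Regressor:
    """A named design-matrix column, one value per retained scan."""

    name: str
    values: np.ndarray
    kind: str  # task | modulator | drift | nuisance | control | constant

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1:
            raise ValueError("regressor values must be one-dimensional")


@dataclass
class DesignMatrix:
    """scans x columns matrix with per-column metadata."""

    matrix: np.ndarray
    names: list[str]
    kinds: list[str]
    tr: float
    rank: int = field(init=False)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[1] != len(self.names):
            raise ValueError("column metadata does not match matrix width")
        self.rank = int(np.linalg.matrix_rank(self.matrix))

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    @property
    def full_rank(self) -> bool:
        return self.rank == self.n_columns

    def column_index(self, name: str) -> int:
        return self.names.index(name)

    def contrast_vector(self, weights: dict[str, float]) -> np.ndarray:
        """Full-length contrast vector from per-column weights, zero elsewhere."""
        c = np.zeros(self.n_columns)
        for name, w in weights.items():
            c[self.column_index(name)] = w
        return c

    def to_tsv(self, path, sidecar: dict | None = None) -> None:
        pd.DataFrame(self.matrix, columns=self.names).to_csv(path, sep="\t", index=False)
        meta = {"tr": self.tr, "kinds": dict(zip(self.names, self.kinds))}
        if sidecar:
            meta.update(sidecar)
        with open(str(path).replace(".tsv", "") + ".json", "w") as fh:
            json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# Task timing
# ---------------------------------------------------------------------------

def build_task_design(phases: int = 3, blocks_per_phase: int = 5,
                      active_s: float = 60.0, rest_s: float = 40.0,
                      tr: float = 2.0, n_dummy: int = 5,
                      microtime_bins: int = 16) -> TaskDesign:
    """Build the alternating active/rest block design.

    The first active block starts at t = 0 of the retained scan series;
    every active block is followed by one rest block.  Total task duration
    must tile exactly into TRs.
    """
    if min(phases, blocks_per_phase) < 1 or min(active_s, rest_s, tr) <= 0 or n_dummy < 0:
        raise ValueError("all design arguments must be positive (n_dummy >= 0)")
    total = phases * blocks_per_phase * (active_s + rest_s)
    remainder = total % tr
    if remainder > 1e-9:
        raise ValueError(
            f"task duration {total} s does not tile into TR={tr} s "
            f"(remainder {remainder} s)")
    phase_names = (PHASES if phases == 3
                   else tuple(f"Phase{i + 1}" for i in range(phases)))
    blocks: list[Block] = []
    t = 0.0
    for ph in phase_names:
        for _ in range(blocks_per_phase):
            blocks.append(Block(t, active_s, "active", ph))
            t += active_s
            blocks.append(Block(t, rest_s, "rest", ph))
            t += rest_s
    return TaskDesign(tuple(blocks), tr=tr, n_scans=int(round(total / tr)),
                      n_dummy=n_dummy, microtime_bins=microtime_bins)


def trim_block_onsets(design: TaskDesign, head_s: float) -> TaskDesign:
    """Shorten every active block by its first ``head_s`` seconds.

    Used with :func:`build_onset_control`: the excised head is modelled by a
    separate regressor of no interest while the main task (and modulator)
    regressors are rebuilt over the remaining block portion.
    """
    active_dur = design.active_blocks[0].duration
    if not 0 < head_s < active_dur:
        raise ValueError(f"head_s must lie in (0, {active_dur})")
    blocks = tuple(
        replace(b, onset=b.onset + head_s, duration=b.duration - head_s)
        if b.kind == "active" else b
        for b in design.blocks)
    return replace(design, blocks=blocks)


# ---------------------------------------------------------------------------
# HRF and convolution machinery
# ---------------------------------------------------------------------------

def canonical_hrf(params: HRFParams | None = None, dt: float = 0.125) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``dt``, normalized to peak 1.

    ``h(t) = Gamma(peak_delay/disp, disp).pdf(t)
             - ratio^-1 * Gamma(undershoot_delay/disp, disp).pdf(t)``
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.length, dt)
    peak = sps.gamma.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = sps.gamma.pdf(t, p.undershoot_delay / p.undershoot_dispersion,
                          scale=p.undershoot_dispersion)
    kernel = peak - under / p.ratio
    return kernel / kernel.max()


def _resolve_kernel(hrf, dt: float) -> np.ndarray:
    """Accept HRFParams, an explicit kernel array, or None (delta kernel)."""
    if hrf is None:
        return np.array([1.0])
    if isinstance(hrf, HRFParams):
        return canonical_hrf(hrf, dt)
    return np.asarray(hrf, dtype=float)


def _microtime_grid(design: TaskDesign) -> tuple[np.ndarray, float]:
    dt = design.tr / design.microtime_bins
    n = design.n_scans * design.microtime_bins
    return np.arange(n) * dt, dt


def _convolve_downsample(box: np.ndarray, kernel: np.ndarray,
                         design: TaskDesign) -> np.ndarray:
    # unit-sum kernel normalization: a sustained unit boxcar converges to a
    # plateau of 1, so betas read as signal change per unit boxcar height
    full = np.convolve(box, kernel / kernel.sum())[: box.size]
    return full[:: design.microtime_bins]


def _active_support(design: TaskDesign, grid: np.ndarray) -> list[np.ndarray]:
    """Boolean microtime support of each active block, half-open [onset, offset)."""
    return [(grid >= b.onset - 1e-9) & (grid < b.offset - 1e-9)
            for b in design.active_blocks]


def build_task_regressor(design: TaskDesign, hrf=HRFParams(),
                         name: str = "task") -> Regressor:
    """Unit boxcar over all active blocks, HRF-convolved, sampled per scan."""
    grid, dt = _microtime_grid(design)
    box = np.zeros(grid.size)
    for sup in _active_support(design, grid):
        box[sup] = 1.0
    return Regressor(name, _convolve_downsample(box, _resolve_kernel(hrf, dt), design),
                     "task")


def build_block_modulator(design: TaskDesign, trace, hrf=HRFParams(),
                          name: str = "task_x_hr") -> Regressor:
    """Parametric modulator: per-active-block heights, mean-centered across blocks.

    ``trace`` is a BlockTrace or plain sequence with one value per active
    block.  Centering across the 15 active blocks happens *before*
    convolution, so a constant trace yields an identically zero column.
    """
    values = np.asarray(getattr(trace, "values", trace), dtype=float)
    grid, dt = _microtime_grid(design)
    supports = _active_support(design, grid)
    if values.size != len(supports):
        raise ValueError(
            f"trace has {values.size} values for {len(supports)} active blocks")
    centered = values - values.mean()
    box = np.zeros(grid.size)
    for sup, h in zip(supports, centered):
        box[sup] = h
    return Regressor(name, _convolve_downsample(box, _resolve_kernel(hrf, dt), design),
                     "modulator")


def build_volume_modulator(design: TaskDesign, trace, hrf=HRFParams(),
                           name: str = "task_x_hr_vol") -> Regressor:
    """Scan-wise parametric modulator restricted to active-block scans.

    The trace (one value per retained scan) is centered over active-block
    scans only; rest scans carry no support, matching a modulator that rides
    on the task boxcar.
    """
    values = np.asarray(getattr(trace, "values", trace), dtype=float)
    if values.size != design.n_scans:
        raise ValueError(f"trace length {values.size} != n_scans {design.n_scans}")
    grid, dt = _microtime_grid(design)
    scan_of_bin = (np.arange(grid.size) // design.microtime_bins)
    active = np.zeros(grid.size, dtype=bool)
    for sup in _active_support(design, grid):
        active |= sup
    active_scans = np.unique(scan_of_bin[active])
    centered = values - values[active_scans].mean()
    box = np.where(active, centered[scan_of_bin], 0.0)
    return Regressor(name, _convolve_downsample(box, _resolve_kernel(hrf, dt), design),
                     "modulator")


def build_phasewise_regressors(design: TaskDesign, trace=None,
                               hrf=HRFParams()) -> list[Regressor]:
    """One task regressor per phase; with a trace, one per-phase modulator.

    Modulator heights are centered *within* phase, mirroring the phasewise
    model's contrast scope.  The three task columns support the
    [-1 +2 -1] Stress-versus-surround contrast of the task-regressor model.
    """
    if not design.phases:
        raise ValueError("design has no phases")
    grid, dt = _microtime_grid(design)
    kernel = _resolve_kernel(hrf, dt)
    values = None
    if trace is not None:
        values = np.asarray(getattr(trace, "values", trace), dtype=float)
        if values.size != len(design.active_blocks):
            raise ValueError("trace must have one value per active block")
    out: list[Regressor] = []
    actives = design.active_blocks
    supports = _active_support(design, grid)
    for ph in design.phases:
        idx = [i for i, b in enumerate(actives) if b.phase == ph]
        box = np.zeros(grid.size)
        for i in idx:
            box[supports[i]] = 1.0
        out.append(Regressor(f"task_{ph}",
                             _convolve_downsample(box, kernel, design), "task"))
    if values is not None:
        for ph in design.phases:
            idx = [i for i, b in enumerate(actives) if b.phase == ph]
            centered = values[idx] - values[idx].mean()
            box = np.zeros(grid.size)
            for i, h in zip(idx, centered):
                box[supports[i]] = h
            out.append(Regressor(f"task_{ph}_x_hr",
                                 _convolve_downsample(box, kernel, design),
                                 "modulator"))
    return out


def build_onset_control(design: TaskDesign, head_s: float,
                        hrf=HRFParams()) -> Regressor:
    """Regressor of no interest covering the first ``head_s`` of each active block.

    Controls for onset transients: pair with :func:`trim_block_onsets` so the
    main task/modulator regressors cover only the remaining block portion.
    """
    active_dur = design.active_blocks[0].duration
    if not 0 < head_s < active_dur:
        raise ValueError(f"head_s must lie in (0, {active_dur})")
    grid, dt = _microtime_grid(design)
    box = np.zeros(grid.size)
    for b in design.active_blocks:
        box[(grid >= b.onset - 1e-9) & (grid < b.onset + head_s - 1e-9)] = 1.0
    return Regressor(f"onset_head_{head_s:g}s",
                     _convolve_downsample(box, _resolve_kernel(hrf, dt), design),
                     "control")


# ---------------------------------------------------------------------------
# Drift basis and assembly
# ---------------------------------------------------------------------------

def dct_highpass_basis(n_scans: int, tr: float, cutoff_s: float = 256.0) -> list[Regressor]:
    """Discrete-cosine drift columns with periods >= ``cutoff_s``.

    K = floor(2 * n_scans * tr / cutoff_s) columns; the constant term is not
    included here (it is added by :func:`assemble_design`).
    """
    if cutoff_s <= 2 * tr:
        raise ValueError(f"cutoff {cutoff_s} s must exceed 2*TR = {2 * tr} s")
    K = int(np.floor(2 * n_scans * tr / cutoff_s))
    n = np.arange(n_scans)
    cols = []
    for k in range(1, K + 1):
        c = np.sqrt(2.0 / n_scans) * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans))
        cols.append(Regressor(f"drift_dct{k:02d}", c, "drift"))
    return cols


def assemble_design(regressors: list[Regressor], nuisance=None,
                    tr: float | None = None) -> DesignMatrix:
    """Assemble columns in canonical order and append the constant.

    Order: task, modulator, control, nuisance, drift, constant.  ``nuisance``
    may be a NuisanceSet (its ``columns()`` are used) or a list of Regressor.
    """
    if not regressors:
        raise ValueError("no regressors given")
    extra: list[Regressor] = []
    if nuisance is not None:
        extra = list(nuisance.columns()) if hasattr(nuisance, "columns") else list(nuisance)
    pool = list(regressors) + extra
    order = {"task": 0, "modulator": 1, "control": 2, "nuisance": 3, "drift": 4}
    pool.sort(key=lambda r: order.get(r.kind, 3))
    n = pool[0].values.size
    for r in pool:
        if r.values.size != n:
            raise ValueError(f"column {r.name!r} has length {r.values.size}, expected {n}")
        if r.kind != "modulator" and not np.any(r.values):
            warnings.warn(f"column {r.name!r} is identically zero")
    names = [r.name for r in pool] + ["constant"]
    if len(set(names)) != len(names):
        dupes = sorted({x for x in names if names.count(x) > 1})
        raise ValueError(f"duplicate column names: {dupes}")
    mat = np.column_stack([r.values for r in pool] + [np.ones(n)])
    kinds = [r.kind for r in pool] + ["constant"]
    return DesignMatrix(mat, names, kinds, tr=tr if tr is not None else np.nan)


# ---------------------------------------------------------------------------
# BIDS-style events IO
# ---------------------------------------------------------------------------

def write_events_tsv(design: TaskDesign, path) -> None:
    rows = [{"onset": b.onset, "duration": b.duration, "trial_type": b.kind,
             "phase": _PHASE_TSV.get(b.phase, b.phase)} for b in design.blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path, tr: float, n_scans: int, n_dummy: int = 0,
                    microtime_bins: int = 16) -> TaskDesign:
    df = pd.read_csv(path, sep="\t")
    blocks = tuple(
        Block(float(r.onset), float(r.duration), str(r.trial_type),
              _TSV_PHASE.get(str(r.phase), str(r.phase)))
        for r in df.itertuples())
    return TaskDesign(blocks, tr=tr, n_scans=n_scans, n_dummy=n_dummy,
                      microtime_bins=microtime_bins)
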