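"""Heart-rate dynamics versus subjective ratings.

Per subject, three swing metrics summarize the blockwise-HR trajectory
across the three task phases: the upswing (mean Stress-phase HR minus mean
PreStress HR), the downswing (mean Stress minus mean PostStress), and the
proportional downswing (downswing normalized by the upswing).  These are
correlated with pre-to-post changes in subjective rating scales; multiple
comparisons are handled by dividing alpha by the effective number of tests
(Nyholt's eigenvalue-based m_eff) computed from the correlation matrix of
the rating variables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .paradigm import TaskDesign
from .physio import BlockTrace

__all__ = ["SwingMetrics", "CorrResult", "swing_metrics", "meff",
           "corr_with_ratings"]

#: Below this |upswing| (bpm) the proportional downswing is undefined.
UPSWING_EPS_BPM = 0.1


@dataclass
class SwingMetrics:
    upswing: float                 # bpm
    downswing: float               # bpm
    proportional_downswing: float  # unitless, NaN when |upswing| < eps
    subject: str = ""


@dataclass
class CorrResult:
    swing_var: str
    rating_var: str
    r: float
    p: float
    meff: float
    adjusted_alpha: float
    significant: bool


def _phase_means(trace: BlockTrace, design: TaskDesign) -> dict[str, float]:
    phases = trace.phases or tuple(b.phase for b in design.active_blocks)
    if len(phases) != trace.values.size:
        raise ValueError("trace length does not match active blocks")
    out: dict[str, float] = {}
    for ph in dict.fromkeys(phases):
        sel = [i for i, p in enumerate(phases) if p == ph]
        out[ph] = float(np.nanmean(trace.values[sel]))
    return out


def swing_metrics(trace: BlockTrace, design: TaskDesign,
                  subject: str = "") -> SwingMetrics:
    """HR upswing/downswing across the PreStress -> Stress -> PostStress arc."""
    means = _phase_means(trace, design)
    try:
        pre, stress, post = (means["PreStress"], means["Stress"],
                             means["PostStress"])
    except KeyError as exc:
        raise ValueError(f"trace does not cover phase {exc}") from exc
    up = stress - pre
    down = stress - post
    if abs(up) < UPSWING_EPS_BPM:
        warnings.warn("upswing below 0.1 bpm; proportional downswing undefined")
        prop = float("nan")
    else:
        prop = down / up
    return SwingMetrics(up, down, prop, subject=subject)


def meff(corr_matrix: np.ndarray, method: str = "nyholt",
         tol: float = 1e-8) -> float:
    """Effective number of tests from a correlation matrix.

    ``nyholt`` (default): ``m_eff = 1 + (M - 1) * (1 - Var(lambda) / M)``
    over the eigenvalues lambda of the M x M correlation matrix (sample
    variance, ddof = 1).  Equals M for independent variables and 1 for
    perfectly collinear ones.  Note the Nyholt estimate is not monotone
    under duplicating a single variable; the ``liji`` (Li & Ji) alternative
    ``sum_i [I(lambda_i >= 1) + frac(lambda_i)]`` is better behaved there.
    """
    R = np.asarray(corr_matrix, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=tol):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=tol):
        raise ValueError("correlation matrix must have unit diagonal")
    lam = np.linalg.eigvalsh(R)
    if lam.min() < -1e-6:
        raise ValueError(f"matrix is not positive semidefinite (min eig {lam.min():.3g})")
    M = R.shape[0]
    if M == 1:
        return 1.0
    if method == "nyholt":
        return float(1.0 + (M - 1) * (1.0 - lam.var(ddof=1) / M))
    if method == "liji":
        lam = np.clip(lam, 0.0, None)
        return float(np.sum((lam >= 1.0) + (lam - np.floor(lam))))
    raise ValueError(f"unknown meff method {method!r}")


def corr_with_ratings(swings: list[SwingMetrics], deltas: pd.DataFrame,
                      alpha: float = 0.05) -> list[CorrResult]:
    """Pearson correlations of swing metrics with rating changes, m_eff-adjusted.

    ``deltas`` holds one row per subject (same order as ``swings``) and one
    column per rating variable (post-minus-pre change).  The adjusted alpha
    is ``alpha / m_eff`` with m_eff from the rating-variable correlation
    matrix (unrounded).
    """
    if len(swings) < 10:
        raise ValueError("need at least 10 subjects for stable correlations")
    if len(swings) != len(deltas):
        raise ValueError("swings and rating rows must pair one-to-one")
    swing_cols = {
        "upswing": np.array([s.upswing for s in swings]),
        "downswing": np.array([s.downswing for s in swings]),
        "proportional_downswing":
            np.array([s.proportional_downswing for s in swings]),
    }
    rating_cols = [c for c in deltas.columns if deltas[c].std() > 0]
    for c in deltas.columns:
        if c not in rating_cols:
            warnings.warn(f"rating column {c!r} is constant; skipped")
    m = meff(deltas[rating_cols].corr().to_numpy())
    adj = alpha / m
    out: list[CorrResult] = []
    for sname, svals in swing_cols.items():
        ok = np.isfinite(svals)
        if ok.sum() < 3 or svals[ok].std() == 0:
            warnings.warn(f"swing metric {sname!r} degenerate; skipped")
            continue
        for rname in rating_cols:
            rvals = deltas[rname].to_numpy(dtype=float)
            sel = ok & np.isfinite(rvals)
            r, p = sps.pearsonr(svals[sel], rvals[sel])
            out.append(CorrResult(sname, rname, float(r), float(p), m, adj,
                                  bool(p < adj)))
    return out
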