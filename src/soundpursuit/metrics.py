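"""Behavioural pursuit metrics.

* `optimal_alignment` — brute-force search for the head-trace lead that
  minimises the mean absolute pursuit error (MAE) against the stimulus.
* `velocity_trace` — zero-phase low-pass differentiation of a trace.
* `error_regressions` — pooled regressions of instantaneous head position /
  velocity on the (aligned) position and velocity errors, the dissociation
  analysis that separates position-error from velocity-error drive.
* `static_localization_regression` — the baseline stimulus-response
  regression for static sound localisation (azimuth and elevation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt
from scipy.stats import linregress

from .stimulus import TrajectoryTrace

__all__ = [
    "PursuitErrorResult",
    "LocalizationRegression",
    "optimal_alignment",
    "velocity_trace",
    "error_regressions",
    "static_localization_regression",
]


@dataclass(frozen=True)
class PursuitErrorResult:
    """Optimal alignment lead ``t_opt`` (s), the MAE it attains (deg), and the
    correlation between stimulus and optimally shifted head trace."""

    t_opt: float
    mae: float
    r_aligned: float
    shift_samples: int


def _aligned_pair(stim: np.ndarray, head: np.ndarray, shift: int) -> tuple[np.ndarray, np.ndarray]:
    # advance the head by `shift` samples; overlap shrinks by the shift
    if shift == 0:
        return stim, head
    return stim[:-shift], head[shift:]


def optimal_alignment(
    trial,
    search: tuple[float, float] = (0.0, 0.6),
) -> PursuitErrorResult:
    """Brute-force delay-optimised mean absolute pursuit error of one trial.

    For every candidate lead on the sample grid within ``search`` (seconds),
    the head trace is advanced and the mean absolute stimulus-head difference
    over the overlapping samples computed; the minimising lead is returned
    (ties break toward the smallest lead).
    """
    stim = trial.stimulus.position
    head = trial.head.position
    dt = trial.stimulus.dt
    lo, hi = search
    if lo < 0 or hi <= lo:
        raise ValueError("search window must satisfy 0 <= lo < hi")
    duration = stim.size * dt
    if hi > duration / 2:
        raise ValueError("search range must not exceed half the trial duration")
    shifts = np.arange(int(round(lo / dt)), int(round(hi / dt)) + 1)
    maes = np.empty(shifts.size)
    for i, s in enumerate(shifts):
        a, b = _aligned_pair(stim, head, int(s))
        maes[i] = np.mean(np.abs(a - b))
    best = int(np.argmin(maes))  # argmin returns the first (smallest) tie
    shift = int(shifts[best])
    a, b = _aligned_pair(stim, head, shift)
    if np.std(a) == 0 or np.std(b) == 0:
        r = np.nan
    else:
        r = float(np.corrcoef(a, b)[0, 1])
    return PursuitErrorResult(
        t_opt=shift * dt, mae=float(maes[best]), r_aligned=r, shift_samples=shift
    )


def velocity_trace(trace: TrajectoryTrace, cutoff_hz: float = 5.0) -> TrajectoryTrace:
    """Angular velocity (deg/s) by central differences after zero-phase low-pass.

    The default 5 Hz cutoff sits far above the stimulus band (<= 1.05 Hz) and
    far below the Nyquist frequency, so it suppresses measurement noise
    without touching pursuit content.  Endpoints use one-sided differences.
    """
    pos = trace.position
    if pos.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    fs = trace.sample_rate
    if 0 < cutoff_hz < fs / 2:
        b, a = butter(4, cutoff_hz / (fs / 2))
        pos = filtfilt(b, a, pos)
    vel = np.gradient(pos, trace.dt)
    return TrajectoryTrace(
        time=trace.time.copy(),
        position=vel,
        trial_id=trace.trial_id,
        role=trace.role,
        units="deg/s",
        meta={**trace.meta, "derivative": True},
    )


def error_regressions(
    trials: Sequence,
    subsample_step: int = 15,
    alignments: Sequence[PursuitErrorResult] | None = None,
    velocity_cutoff_hz: float = 5.0,
) -> pd.DataFrame:
    """Pooled OLS of head position/velocity on position/velocity errors.

    For each trial the head trace (and its velocity) is advanced by the
    trial's optimal lead; position error dE = m - H_aligned and velocity
    error dEdot = mdot - Hdot_aligned are formed, every ``subsample_step``-th
    sample pooled across trials, and four regressions run: each response
    (H, Hdot) on each error (dE, dEdot).

    Returns a DataFrame with rows ``H~dE``, ``Hdot~dEdot``, ``H~dEdot``,
    ``Hdot~dE`` and columns ``offset``, ``slope``, ``correlation``,
    ``degenerate``.
    """
    if alignments is None:
        alignments = [optimal_alignment(tr) for tr in trials]
    pooled: dict[str, list[np.ndarray]] = {k: [] for k in ("H", "Hdot", "dE", "dEdot")}
    for trial, al in zip(trials, alignments):
        s = al.shift_samples
        m = trial.stimulus.position
        h = trial.head.position
        mdot = velocity_trace(trial.stimulus, velocity_cutoff_hz).position
        hdot = velocity_trace(trial.head, velocity_cutoff_hz).position
        m_a, h_a = _aligned_pair(m, h, s)
        md_a, hd_a = _aligned_pair(mdot, hdot, s)
        sl = slice(None, None, subsample_step)
        pooled["H"].append(h_a[sl])
        pooled["Hdot"].append(hd_a[sl])
        pooled["dE"].append((m_a - h_a)[sl])
        pooled["dEdot"].append((md_a - hd_a)[sl])
    data = {k: np.concatenate(v) for k, v in pooled.items()}
    n = data["H"].size
    if n < 100:
        raise ValueError(f"only {n} pooled samples; need >= 100 for the regressions")
    rows = []
    for resp, pred in (("H", "dE"), ("Hdot", "dEdot"), ("H", "dEdot"), ("Hdot", "dE")):
        x, y = data[pred], data[resp]
        if np.std(x) == 0 or np.std(y) == 0:
            rows.append((f"{resp}~{pred}", np.nan, np.nan, np.nan, True))
            continue
        fit = linregress(x, y)
        rows.append((f"{resp}~{pred}", fit.intercept, fit.slope, fit.rvalue, False))
    return pd.DataFrame(
        rows, columns=["regression", "offset", "slope", "correlation", "degenerate"]
    ).set_index("regression")


@dataclass(frozen=True)
class LocalizationRegression:
    """Per-axis stimulus-response regression of static localisation."""

    azimuth_bias: float
    azimuth_gain: float
    azimuth_r: float
    azimuth_mae: float
    azimuth_residual_sd: float
    elevation_bias: float
    elevation_gain: float
    elevation_r: float
    elevation_mae: float
    elevation_residual_sd: float


def _axis_regression(target: np.ndarray, response: np.ndarray) -> tuple[float, float, float, float, float]:
    if target.size < 3:
        raise ValueError("need at least 3 points per axis")
    if np.std(target) == 0:
        raise ValueError("degenerate target set: zero variance")
    fit = linregress(target, response)
    resid = response - (fit.intercept + fit.slope * target)
    return (
        float(fit.intercept),
        float(fit.slope),
        float(fit.rvalue),
        float(np.mean(np.abs(resid))),
        float(np.std(resid, ddof=1)),
    )


def static_localization_regression(
    target_az, response_az, target_el, response_el
) -> LocalizationRegression:
    """Least-squares stimulus-response fits per axis: response = gain * target + bias.

    Normal listeners show azimuth/elevation gains close to 1 and biases close
    to 0 deg; this serves as the validation gate for imported recordings.
    """
    az = _axis_regression(np.asarray(target_az, float), np.asarray(response_az, float))
    el = _axis_regression(np.asarray(target_el, float), np.asarray(response_el, float))
    return LocalizationRegression(*az, *el)
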