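"""Synthetic pursuit subjects: ground-truth responses for parameter recovery.

A synthetic subject is a second-order-plus-delay system with a fixed,
idiosyncratic delay (drawn uniformly from 10-98 ms), a fixed resonance
frequency near 0.6 Hz, and a quality factor that drifts linearly across the
session from ~1.5 (underdamped, resonant) toward ~0.6 (near-critically
damped), with lognormal trial-to-trial jitter.  Head responses are the
discrete convolution of the motor stimulus with the subject's impulse
response plus additive Gaussian measurement noise (default 1 deg SD, of the
same order as search-coil residuals).  No corrective head saccades are
generated: none were present in the behaviour this emulates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .identify import predict_response
from .lti import APSParameters
from .stimulus import SumOfSinesSpec, TrajectoryTrace

__all__ = [
    "SyntheticSubjectConfig",
    "TrialRecord",
    "q_schedule",
    "simulate_trial",
    "simulate_session",
]

DELAY_RANGE_S = (0.010, 0.098)


@dataclass(frozen=True)
class SyntheticSubjectConfig:
    """Ground-truth description of one synthetic subject.

    ``t_d=None`` draws the subject's fixed delay uniformly from 10-98 ms.
    The quality factor interpolates linearly from ``q_start`` at trial 1 to
    ``q_end`` at the last trial, optionally jittered multiplicatively
    (lognormal, ``q_jitter_sd`` in log units).
    """

    subject_id: str = "S1"
    f_c: float = 0.6
    t_d: float | None = None
    q_start: float = 1.5
    q_end: float = 0.6
    q_jitter_sd: float = 0.15
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.f_c <= 0 or self.q_start <= 0 or self.q_end <= 0:
            raise ValueError("f_c, q_start and q_end must be positive")
        if self.t_d is not None and self.t_d < 0:
            raise ValueError("t_d must be non-negative")
        if self.noise_sd < 0 or self.q_jitter_sd < 0:
            raise ValueError("noise_sd and q_jitter_sd must be non-negative")


@dataclass
class TrialRecord:
    """One trial: paired stimulus and head traces plus optional ground truth.

    ``ground_truth`` is the generating parameter set for synthetic data and
    ``None`` for imported recordings.
    """

    subject_id: str
    trial_number: int
    stimulus: TrajectoryTrace
    head: TrajectoryTrace
    ground_truth: APSParameters | None = None
    spec: SumOfSinesSpec | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trial_number < 1:
            raise ValueError("trial_number must be >= 1")
        if self.stimulus.position.shape != self.head.position.shape:
            raise ValueError("stimulus and head traces must share the time grid")
        if not np.allclose(self.stimulus.time, self.head.time):
            raise ValueError("stimulus and head traces must share the time grid")


def q_schedule(
    config: SyntheticSubjectConfig,
    n: int,
    n_trials: int,
    rng: np.random.Generator | None = None,
) -> float:
    """Quality factor of trial ``n`` out of ``n_trials``.

    Linear interpolation q_start -> q_end over the session; when an ``rng``
    is supplied and ``q_jitter_sd > 0``, multiplies by lognormal jitter to
    mimic trial-to-trial scatter.
    """
    if not 1 <= n <= n_trials:
        raise ValueError(f"trial index {n} outside 1..{n_trials}")
    if n_trials == 1:
        q = config.q_start
    else:
        frac = (n - 1) / (n_trials - 1)
        q = config.q_start + frac * (config.q_end - config.q_start)
    if rng is not None and config.q_jitter_sd > 0:
        q *= float(np.exp(rng.normal(0.0, config.q_jitter_sd)))
    return float(q)


def simulate_trial(
    stimulus: TrajectoryTrace,
    params: APSParameters,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    subject_id: str = "S1",
    trial_number: int | None = None,
    spec: SumOfSinesSpec | None = None,
    warmup_periods: int = 0,
) -> TrialRecord:
    """Head response of a model subject to one stimulus trace.

    The head trace is the discrete convolution of the stimulus with the
    subject's sampled impulse response (stimulus zero before onset) plus
    i.i.d. Gaussian measurement noise.  Sub-sample delays need no rounding:
    the kernel is sampled from the analytic delay-shifted formula.

    ``warmup_periods > 0`` prepends that many periods of the (periodic)
    stimulus before convolving and discards them again, yielding the settled
    response of a subject already tracking; the default starts from rest,
    which leaves the onset transient in the trace as in a real trial.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if warmup_periods > 0:
        n = stimulus.position.size
        tiled = np.tile(stimulus.position, warmup_periods + 1)
        t_ext = np.arange(tiled.size) * stimulus.dt
        ext_trace = TrajectoryTrace(
            t_ext, tiled, trial_id=stimulus.trial_id, role=stimulus.role, meta=stimulus.meta
        )
        head0 = predict_response(params, ext_trace).position[-n:]
        pred = stimulus.with_position(head0, role="predicted")
    else:
        pred = predict_response(params, stimulus)
    head = pred.position
    if noise_sd > 0:
        head = head + rng.normal(0.0, noise_sd, size=head.size)
    head_trace = stimulus.with_position(head, role="head")
    return TrialRecord(
        subject_id=subject_id,
        trial_number=trial_number if trial_number is not None else stimulus.trial_id,
        stimulus=stimulus,
        head=head_trace,
        ground_truth=params,
        spec=spec,
    )


def simulate_session(
    config: SyntheticSubjectConfig,
    stimuli: list[TrajectoryTrace],
    seed: int | np.random.Generator | None = None,
    spec: SumOfSinesSpec | None = None,
) -> list[TrialRecord]:
    """Simulate one subject's full session over a list of stimulus traces.

    The delay (drawn once if unset) and resonance frequency are fixed for the
    subject; the quality factor follows `q_schedule`.  Deterministic for a
    fixed seed.
    """
    if not stimuli:
        raise ValueError("need at least one stimulus")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t_d = config.t_d if config.t_d is not None else float(rng.uniform(*DELAY_RANGE_S))
    records = []
    for i, stim in enumerate(stimuli, start=1):
        q = q_schedule(config, i, len(stimuli), rng=rng)
        params = APSParameters.from_quality(config.f_c, q, t_d=t_d)
        records.append(
            simulate_trial(
                stim,
                params,
                noise_sd=config.noise_sd,
                seed=rng,
                subject_id=config.subject_id,
                trial_number=i,
                spec=spec,
            )
        )
    return records
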