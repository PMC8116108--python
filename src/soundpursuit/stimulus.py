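"""Sum-of-sines sound-motion stimuli and the robot-arm distortion of them.

A pursuit stimulus is a linear combination of five sines at fixed integer
multiples of a common fundamental (default 0.05 Hz with multipliers
[2, 3, 7, 13, 21], i.e. 0.10, 0.15, 0.35, 0.65 and 1.05 Hz), with phases
drawn uniformly at random per trial and the whole waveform rescaled to a
fixed peak excursion (default 30 deg).  Harmonics of one fundamental whose
period equals the trial length make the motion spectrally fixed but
unpredictable in the time domain.

The robot arm that physically moves the speaker introduces small extra
harmonics (e.g. at multipliers [1, 5, 15]) and a mild low-pass smoothing;
`apply_motor_distortion` emulates that transformation.  Downstream analysis
always treats the *motor* trace as the true stimulus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SumOfSinesSpec",
    "TrajectoryTrace",
    "MotorDistortion",
    "generate_stimulus",
    "apply_motor_distortion",
    "trial_set",
]


@dataclass(frozen=True)
class SumOfSinesSpec:
    """Specification of a sum-of-sines pursuit stimulus."""

    f0: float = 0.05
    multipliers: tuple[int, ...] = (2, 3, 7, 13, 21)
    duration: float = 20.0
    sample_rate: float = 110.0
    peak: float = 30.0

    def __post_init__(self) -> None:
        if self.f0 <= 0 or self.duration <= 0 or self.sample_rate <= 0 or self.peak <= 0:
            raise ValueError("f0, duration, sample_rate and peak must all be positive")
        mult = tuple(int(m) for m in self.multipliers)
        if len(set(mult)) != len(mult) or any(m <= 0 for m in mult):
            raise ValueError("multipliers must be distinct positive integers")
        object.__setattr__(self, "multipliers", mult)
        n_periods = self.duration * self.f0
        if abs(n_periods - round(n_periods)) > 1e-9 or round(n_periods) < 1:
            raise ValueError(
                "duration must span an integer number of fundamental periods "
                f"(duration*f0 = {n_periods})"
            )
        if self.sample_rate <= 2 * max(self.frequencies):
            raise ValueError("sample_rate must exceed twice the highest harmonic")

    @property
    def frequencies(self) -> np.ndarray:
        """Harmonic frequencies in Hz."""
        return self.f0 * np.asarray(self.multipliers, dtype=float)

    @property
    def n_samples(self) -> int:
        n = self.duration * self.sample_rate
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration*sample_rate must be an integer sample count")
        return int(round(n))

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate


@dataclass
class TrajectoryTrace:
    """A uniformly sampled angular trajectory.

    ``role`` distinguishes the programmed command, the measured motor
    movement, a head response and a model prediction.  ``meta`` carries
    bookkeeping such as realized per-harmonic amplitudes and phases.
    """

    time: np.ndarray
    position: np.ndarray
    trial_id: int = 1
    role: str = "command"
    units: str = "deg"
    meta: dict = field(default_factory=dict)

    _ROLES = ("command", "motor", "head", "predicted")

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.position = np.asarray(self.position, dtype=float)
        if self.time.shape != self.position.shape or self.time.ndim != 1:
            raise ValueError("time and position must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("position contains non-finite samples")
        # the azimuth bound applies to angular positions, not derived velocities
        if self.units == "deg" and np.any(np.abs(self.position) > 90.0 + 1e-9):
            raise ValueError("azimuth positions must stay within +/-90 deg")
        if self.role not in self._ROLES:
            raise ValueError(f"role must be one of {self._ROLES}, got {self.role!r}")
        if self.trial_id < 1:
            raise ValueError("trial_id must be >= 1")

    @property
    def sample_rate(self) -> float:
        return 1.0 / self.dt

    @property
    def dt(self) -> float:
        if self.time.size < 2:
            raise ValueError("trace too short to define a sampling interval")
        return float(self.time[1] - self.time[0])

    def with_position(self, position: np.ndarray, role: str | None = None, **meta) -> "TrajectoryTrace":
        """Copy of this trace with new samples (and optionally a new role)."""
        return TrajectoryTrace(
            time=self.time.copy(),
            position=np.asarray(position, dtype=float),
            trial_id=self.trial_id,
            role=role or self.role,
            meta={**self.meta, **meta},
        )


def _time_grid(spec: SumOfSinesSpec) -> np.ndarray:
    return np.arange(spec.n_samples) / spec.sample_rate


def generate_stimulus(
    spec: SumOfSinesSpec,
    seed: int | np.random.Generator | None = None,
    phases: Sequence[float] | None = None,
    trial_id: int = 1,
) -> TrajectoryTrace:
    """Generate one command stimulus trajectory.

    Phases are drawn uniformly on [0, 2 pi) unless given explicitly.  The sum
    of unit-amplitude sines is rescaled so that the sampled peak excursion
    equals ``spec.peak`` exactly; the realized per-harmonic amplitudes
    ``A_k = peak / max|raw|`` are stored in ``meta["amplitudes"]``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    freqs = spec.frequencies
    if phases is None:
        phi = rng.uniform(0.0, 2.0 * np.pi, size=len(freqs))
    else:
        phi = np.asarray(phases, dtype=float)
        if phi.shape != freqs.shape:
            raise ValueError("need one phase per harmonic")
    t = _time_grid(spec)
    raw = np.sum(np.sin(2.0 * np.pi * freqs[:, None] * t[None, :] + phi[:, None]), axis=0)
    peak_raw = np.max(np.abs(raw))
    if peak_raw == 0.0:
        raise ValueError("degenerate all-zero stimulus realization")
    scale = spec.peak / peak_raw
    return TrajectoryTrace(
        time=t,
        position=scale * raw,
        trial_id=trial_id,
        role="command",
        meta={
            "phases": phi,
            "amplitudes": np.full(len(freqs), scale),
            "frequencies": freqs,
            "peak": spec.peak,
        },
    )


@dataclass(frozen=True)
class MotorDistortion:
    """Robot-arm input-output transformation: extra harmonics + low-pass smoothing.

    ``extra_multipliers`` are additional harmonics of the stimulus fundamental
    injected at ``extra_rel_amplitude`` times the command peak (random phases);
    ``smoothing_cutoff`` (Hz) is the corner of a first-order low-pass applied
    to the whole trace.  Must lie above the highest stimulus harmonic.
    """

    extra_multipliers: tuple[int, ...] = (1, 5, 15)
    extra_rel_amplitude: float = 0.03
    smoothing_cutoff: float = 5.0


def apply_motor_distortion(
    trace: TrajectoryTrace,
    spec: SumOfSinesSpec,
    distortion: MotorDistortion = MotorDistortion(),
    seed: int | np.random.Generator | None = None,
) -> TrajectoryTrace:
    """Transform a command trace into the motor trace the speaker actually follows.

    The low-pass is applied in the frequency domain (steady-state filtering of
    the periodic trace); the realized post-distortion peak is re-measured and
    stored in ``meta["realized_peak"]`` rather than re-normalised.
    """
    if distortion.smoothing_cutoff <= max(spec.frequencies):
        raise ValueError(
            "smoothing cutoff must lie above the highest stimulus harmonic "
            f"({max(spec.frequencies)} Hz)"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    t = trace.time
    pos = trace.position.astype(float).copy()
    extra = np.asarray(distortion.extra_multipliers, dtype=float) * spec.f0
    if distortion.extra_rel_amplitude > 0 and extra.size:
        phi = rng.uniform(0.0, 2.0 * np.pi, size=extra.size)
        amp = distortion.extra_rel_amplitude * spec.peak
        pos = pos + amp * np.sum(
            np.sin(2.0 * np.pi * extra[:, None] * t[None, :] + phi[:, None]), axis=0
        )
    if np.isfinite(distortion.smoothing_cutoff):
        spec_f = np.fft.rfft(pos)
        f = np.fft.rfftfreq(pos.size, d=trace.dt)
        spec_f *= 1.0 / (1.0 + 1j * f / distortion.smoothing_cutoff)
        pos = np.fft.irfft(spec_f, n=pos.size)
    return trace.with_position(pos, role="motor", realized_peak=float(np.max(np.abs(pos))))


def trial_set(
    n_trials: int,
    spec: SumOfSinesSpec = SumOfSinesSpec(),
    seed: int | np.random.Generator | None = None,
    distortion: MotorDistortion | None = MotorDistortion(),
) -> list[TrajectoryTrace]:
    """Generate a session's worth of independent motor stimulus traces.

    Each trial draws fresh phases; the whole set is deterministic for a fixed
    seed.  Pass ``distortion=None`` to return undistorted command traces.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    traces = []
    for n in range(1, n_trials + 1):
        cmd = generate_stimulus(spec, seed=rng, trial_id=n)
        if distortion is not None:
            traces.append(apply_motor_distortion(cmd, spec, distortion, seed=rng))
        else:
            traces.append(cmd)
    return traces
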