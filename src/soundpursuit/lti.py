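"""Second-order-plus-delay model of the auditory pursuit system (APS).

The APS transfer characteristic is a second-order low-pass filter in series
with a pure sensorimotor delay::

    H(s) = G0 * exp(-T_D s) * w_C^2 / (w_C^2 + 2 zeta w_C s + s^2)

with ``w_C = 2 pi f_C`` the undamped (resonance) angular frequency, ``zeta``
the damping ratio and ``T_D`` the delay.  The quality factor ``Q = 1/(2 zeta)``
is the field's usual damping descriptor: Q > 0.5 is underdamped (overshoot,
possible resonant peak), Q = 0.5 critically damped, Q < 0.5 overdamped.

Everything here is analytic and stateless: transfer function, impulse and
step responses, resonance-peak location, and the two movement-effort
functionals (time-integrated squared step-response velocity, and
band-averaged gain magnitude).  The impulse response is normalised to unit
DC gain, i.e. its time integral equals ``G0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid

__all__ = [
    "APSParameters",
    "FrequencyResponse",
    "transfer_function",
    "impulse_response",
    "step_response",
    "peak_gain",
    "kinetic_energy",
    "spectral_effort",
    "q_to_zeta",
    "zeta_to_q",
]

# |zeta - 1| below this switches to the critically-damped limit form to
# avoid catastrophic cancellation in the overdamped difference of exponentials
_CRITICAL_TOL = 1e-6


def q_to_zeta(q: float) -> float:
    """Convert quality factor Q to damping ratio zeta = 1/(2Q)."""
    if not np.isfinite(q) or q <= 0:
        raise ValueError(f"quality factor must be positive and finite, got {q!r}")
    return 1.0 / (2.0 * q)


def zeta_to_q(zeta: float) -> float:
    """Convert damping ratio zeta to quality factor Q = 1/(2 zeta)."""
    if not np.isfinite(zeta) or zeta <= 0:
        raise ValueError(f"damping ratio must be positive and finite, got {zeta!r}")
    return 1.0 / (2.0 * zeta)


@dataclass(frozen=True)
class APSParameters:
    """Parameter triple of the second-order-plus-delay pursuit model.

    Attributes
    ----------
    f_c : float
        Undamped resonance frequency in Hz (> 0).
    zeta : float
        Damping ratio, dimensionless (> 0).
    t_d : float
        Pure delay in seconds (>= 0).
    g0 : float
        Steady-state gain; clamped to 1.0 for pursuit fits.
    """

    f_c: float
    zeta: float
    t_d: float = 0.0
    g0: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.f_c) and self.f_c > 0):
            raise ValueError(f"f_c must be positive and finite, got {self.f_c!r}")
        if not (np.isfinite(self.zeta) and self.zeta > 0):
            raise ValueError(f"zeta must be positive and finite, got {self.zeta!r}")
        if not (np.isfinite(self.t_d) and self.t_d >= 0):
            raise ValueError(f"t_d must be non-negative, got {self.t_d!r}")
        if not np.isfinite(self.g0):
            raise ValueError("g0 must be finite")

    @classmethod
    def from_quality(cls, f_c: float, q: float, t_d: float = 0.0, g0: float = 1.0) -> "APSParameters":
        """Build parameters from a quality factor instead of a damping ratio."""
        return cls(f_c=f_c, zeta=q_to_zeta(q), t_d=t_d, g0=g0)

    @property
    def q(self) -> float:
        """Quality factor Q = 1/(2 zeta)."""
        return zeta_to_q(self.zeta)

    @property
    def omega_c(self) -> float:
        """Angular resonance frequency, rad/s."""
        return 2.0 * np.pi * self.f_c


@dataclass(frozen=True)
class FrequencyResponse:
    """Gain and phase sampled on a frequency grid.

    ``frequencies`` (Hz) are strictly increasing; ``gain`` is the dimensionless
    magnitude and ``phase`` the unwrapped phase in degrees (<= 0 at low
    frequency for a causal lag).
    """

    frequencies: np.ndarray
    gain: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, float)
        g = np.asarray(self.gain, float)
        p = np.asarray(self.phase, float)
        if not (f.shape == g.shape == p.shape):
            raise ValueError("frequencies, gain and phase must have matching shapes")
        if f.size > 1 and np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        if np.any(g < 0):
            raise ValueError("gain must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "gain", g)
        object.__setattr__(self, "phase", p)


def transfer_function(params: APSParameters, f):
    """Complex frequency response H(i 2 pi f) of the model.

    Parameters
    ----------
    params : APSParameters
    f : float or array_like
        Frequency in Hz, >= 0.

    Returns
    -------
    complex or ndarray of complex
    """
    f = np.asarray(f, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("frequencies must be finite")
    if np.any(f < 0):
        raise ValueError("frequencies must be non-negative")
    wc = params.omega_c
    s = 1j * 2.0 * np.pi * f
    h = params.g0 * np.exp(-s * params.t_d) * wc**2 / (wc**2 + 2.0 * params.zeta * wc * s + s**2)
    return h if h.ndim else complex(h)


def frequency_response(params: APSParameters, frequencies) -> FrequencyResponse:
    """Gain/phase curves of the model on a frequency grid (phase unwrapped, degrees)."""
    h = np.atleast_1d(transfer_function(params, frequencies))
    phase = np.degrees(np.unwrap(np.angle(h)))
    return FrequencyResponse(np.atleast_1d(np.asarray(frequencies, float)), np.abs(h), phase)


def impulse_response(params: APSParameters, t_grid) -> np.ndarray:
    """Analytic impulse response h(t) sampled on ``t_grid`` (deg/s per unit-deg impulse).

    Zero for t < T_D.  Underdamped, overdamped and critically damped branches
    are handled, with the critical limit used in a narrow band around
    zeta = 1 for numerical stability.  Normalised so that the time integral of
    h equals the steady-state gain G0.
    """
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_grid must be non-negative")
    zeta, wc = params.zeta, params.omega_c
    tau = t - params.t_d
    active = tau > 0
    taua = np.where(active, tau, 0.0)
    out = np.zeros_like(t)
    if abs(zeta - 1.0) < _CRITICAL_TOL:
        out[active] = (wc**2 * taua * np.exp(-wc * taua))[active]
    elif zeta < 1.0:
        beta = np.sqrt(1.0 - zeta**2)
        out[active] = ((wc / beta) * np.exp(-zeta * wc * taua) * np.sin(beta * wc * taua))[active]
    else:
        gamma = np.sqrt(zeta**2 - 1.0)
        e_slow = np.exp(-wc * (zeta - gamma) * taua)
        e_fast = np.exp(-wc * (zeta + gamma) * taua)
        out[active] = ((wc / (2.0 * gamma)) * (e_slow - e_fast))[active]
    return params.g0 * out


def step_response(params: APSParameters, t_grid) -> np.ndarray:
    """Unit-step response: cumulative integral of the impulse response.

    Converges to G0; overshoots above G0 iff the system is underdamped.
    """
    t = np.asarray(t_grid, dtype=float)
    h = impulse_response(params, t)
    return cumulative_trapezoid(h, t, initial=0.0)


def peak_gain(params: APSParameters) -> tuple[float, float]:
    """Location and height of the maximum of the gain characteristic |H(i w)|.

    For zeta < 1/sqrt(2) (Q > 1/sqrt(2)) the gain has an interior resonant
    peak at ``w_max = w_C sqrt(1 - 2 zeta^2)`` of height
    ``G0 / (2 zeta sqrt(1 - zeta^2))``; otherwise the maximum is the DC gain,
    returned as ``(0.0, G0)``.  In the high-Q limit the peak approaches
    (w_C, Q * G0).

    Returns
    -------
    (omega_max, g_max) : rad/s, dimensionless
    """
    zeta = params.zeta
    if zeta >= 1.0 / np.sqrt(2.0):
        return 0.0, params.g0
    w_max = params.omega_c * np.sqrt(1.0 - 2.0 * zeta**2)
    g_max = params.g0 / (2.0 * zeta * np.sqrt(1.0 - zeta**2))
    return float(w_max), float(g_max)


def _converging_trapezoid(func, lo: float, hi: float, n0: int = 2049, rtol: float = 1e-3) -> float:
    # refine by grid halving until the relative change drops below rtol
    n = n0
    x = np.linspace(lo, hi, n)
    val = np.trapezoid(func(x), x)
    for _ in range(8):
        n = 2 * n - 1
        x = np.linspace(lo, hi, n)
        new = np.trapezoid(func(x), x)
        if abs(new - val) <= rtol * abs(new):
            return float(new)
        val = new
    return float(val)


def kinetic_energy(params: APSParameters, duration: float) -> float:
    """Rotational kinetic-energy proxy of a unit-step head movement.

    Integrates the squared step-response velocity (the impulse response)
    over ``[0, duration]`` seconds, per unit angular momentum.  The delay is
    ignored (set to zero): a pure delay only shifts the velocity profile and
    for durations well beyond T_D does not change the integral.

    For an underdamped system and long durations this converges to the
    closed form ``w_C / (4 zeta)``.
    """
    if not (np.isfinite(duration) and duration > 0):
        raise ValueError(f"duration must be positive, got {duration!r}")
    p = replace(params, t_d=0.0)
    return _converging_trapezoid(lambda t: impulse_response(p, t) ** 2, 0.0, duration)


def spectral_effort(params: APSParameters, band: tuple[float, float] = (0.05, 1.05)) -> float:
    """Band-averaged gain magnitude: mean of |H(i w)| over ``band`` (Hz).

    A frequency-domain movement-effort proxy; for the degenerate wide-band
    limit where the gain is constant it reduces to that constant.
    """
    f_lo, f_hi = band
    if not (0 <= f_lo < f_hi):
        raise ValueError(f"band must satisfy 0 <= f_lo < f_hi, got {band!r}")
    w_lo, w_hi = 2.0 * np.pi * f_lo, 2.0 * np.pi * f_hi
    integral = _converging_trapezoid(
        lambda w: np.abs(transfer_function(params, w / (2.0 * np.pi))), w_lo, w_hi
    )
    return integral / (w_hi - w_lo)
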