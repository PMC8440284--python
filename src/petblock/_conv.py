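"""Shared numerics: exponential convolution and frame averaging on a fine grid.

The compartment-model solutions are convolutions of decaying exponentials
with the plasma input. On a uniform fine grid with the input treated as
piecewise linear, the convolution integral has an exact one-pole recursion,
evaluated here with :func:`scipy.signal.lfilter` (C speed, no ODE stepping).
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .frames import FrameSchedule

DEFAULT_DT = 0.005  # minutes; divides the 15-s frame boundary grid


def fine_grid(total_minutes: float, dt: float = DEFAULT_DT) -> np.ndarray:
    n = int(round(total_minutes / dt))
    return np.linspace(0.0, n * dt, n + 1)


def exp_conv(u: np.ndarray, dt: float, theta: float) -> np.ndarray:
    """Exact ``y(t) = int_0^t exp(-theta (t-s)) u(s) ds`` for piecewise-linear u.

    Works for theta >= 0, including theta == 0 (running integral).
    """
    if theta < 0 or not np.isfinite(theta):
        raise ValueError("theta must be finite and non-negative")
    x = theta * dt
    if x < 1e-6:
        # series limit: trapezoidal running integral with exp correction O(x^2)
        a = 1.0 - x
        b0 = b1 = 0.5 * dt
    else:
        a = np.exp(-x)
        A = (1.0 - a) / theta
        B = dt / theta - (1.0 - a) / theta**2
        b0 = B / dt
        b1 = A - B / dt
    y = lfilter([b0, b1], [1.0, -a], u)
    if u[0] != 0.0:
        # lfilter starts the recursion at y0 = b0*u0; the true initial value is 0
        y = y - (b0 * u[0]) * a ** np.arange(u.size)
    else:
        y[0] = 0.0
    return y


def cumulative_trapezoid_grid(values: np.ndarray, dt: float) -> np.ndarray:
    out = np.empty_like(values)
    out[0] = 0.0
    np.cumsum(0.5 * dt * (values[1:] + values[:-1]), out=out[1:])
    return out


def frame_average(values: np.ndarray, dt: float, schedule: FrameSchedule) -> np.ndarray:
    """Average a fine-grid curve over each frame interval (exact trapezoid)."""
    cum = cumulative_trapezoid_grid(values, dt)
    i0 = np.rint(schedule.frame_start / dt).astype(int)
    i1 = np.rint(schedule.frame_end / dt).astype(int)
    if i1[-1] >= cum.size:
        raise ValueError("fine grid does not cover the frame schedule")
    return (cum[i1] - cum[i0]) / (schedule.frame_duration)
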