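"""Minimum-jerk point-to-point profiles and threshold-crossing solutions.

The quintic minimum-jerk shape s(tau) = 10 tau^3 - 15 tau^4 + 6 tau^5 moves
from 0 to 1 over tau in [0, 1] with zero boundary velocity and acceleration.
Its speed profile admits a closed-form solution for crossings of a constant
speed threshold, which is what the velocity-gated step definition operates on.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import brentq


def mj_shape(tau):
    """Position shape s(tau) in [0, 1]."""
    tau = np.clip(tau, 0.0, 1.0)
    return tau**3 * (10.0 + tau * (-15.0 + 6.0 * tau))


def mj_shape_rate(tau):
    """ds/dtau = 30 tau^2 (1 - tau)^2."""
    tau = np.clip(tau, 0.0, 1.0)
    return 30.0 * tau**2 * (1.0 - tau) ** 2


def mj_eval(t, t0: float, T: float, x0: float, x1: float):
    """Evaluate a minimum-jerk segment from x0 at t0 to x1 at t0+T."""
    return x0 + (x1 - x0) * mj_shape((np.asarray(t) - t0) / T)


def mj_peak_speed(displacement: float, T: float) -> float:
    """Peak speed of a minimum-jerk move: 30/16 * |d| / T."""
    return 1.875 * abs(displacement) / T


def mj_speed_crossings(displacement: float, T: float, v_thr: float):
    """Times (relative to segment start) at which |v| crosses ``v_thr``.

    Returns ``(t_rise, t_fall)`` or ``None`` when the peak speed never
    reaches the threshold.  Closed form: |v| = 30|d|/T tau^2(1-tau)^2 = v_thr
    gives tau(1-tau) = sqrt(v_thr T / (30 |d|)).
    """
    d = abs(displacement)
    if d == 0 or T <= 0:
        return None
    c = v_thr * T / (30.0 * d)
    disc = 1.0 - 4.0 * np.sqrt(c)
    if disc <= 0:
        return None
    tau1 = 0.5 * (1.0 - np.sqrt(disc))
    return tau1 * T, (1.0 - tau1) * T


def mj_level_crossing(level: float, x0: float, x1: float, T: float) -> float | None:
    """Time (relative to start) at which the segment crosses ``level``.

    Monotone segment, so at most one crossing; None when the level is outside
    (x0, x1).
    """
    if x0 == x1:
        return None
    s = (level - x0) / (x1 - x0)
    if not 0.0 < s < 1.0:
        return None
    tau = brentq(lambda t: mj_shape(t) - s, 0.0, 1.0, xtol=1e-12)
    return float(tau * T)
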