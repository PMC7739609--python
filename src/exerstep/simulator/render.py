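"""Render a movement plan into 22-marker trajectories plus exact ground truth.

The kinematic model is deliberately simple: upper-body markers ride on the
sternum path, foot markers execute the commanded minimum-jerk steps, and the
wrists execute commanded raise/hold/lower profiles.  Because every profile is
analytic, the threshold crossings that define steps and arm lifts can be
solved exactly, giving ground truth that an event detector applied to the
noise-free render must reproduce to within one frame.
"""

from __future__ import annotations

import numpy as np

from .._profiles import mj_eval, mj_level_crossing, mj_shape, mj_speed_crossings
from ..detection import derive_single_support, StepEvent
from ..errors import ConfigError
from ..gamelog import GameEventLog
from ..mocap_io import TrialMeta, TrialRecording
from ..markers import MarkerSet
from .settings import Anthropometry, GroundTruth, MovementPlan, PlayerPolicy

RATE = 120.0


def _times(plan: MovementPlan, rate: float) -> np.ndarray:
    n = max(2, int(round(plan.duration * rate)))
    return np.arange(n) / rate


def _step_profile(t: np.ndarray, commands, component: str, half: bool) -> np.ndarray:
    """Sum of commanded minimum-jerk displacements sampled on ``t``."""
    out = np.zeros_like(t)
    scale = 0.5 if half else 1.0
    for cmd in commands:
        d = getattr(cmd, component)
        if d == 0.0:
            continue
        i0 = np.searchsorted(t, cmd.t0)
        i1 = np.searchsorted(t, cmd.t0 + cmd.duration)
        out[i0:i1] += scale * d * mj_shape((t[i0:i1] - cmd.t0) / cmd.duration)
        out[i1:] += scale * d
    return out


def body_trajectory(plan: MovementPlan, rate: float = RATE) -> np.ndarray:
    """Sternum (X, Y) over the capture, from step commands and drift."""
    t = _times(plan, rate)
    x = plan.start_x + _step_profile(t, plan.steps, "dx", half=True)
    y = plan.start_y + _step_profile(t, plan.steps, "dy", half=True) + plan.drift_at(t)
    return np.column_stack([x, y])


def synthesize_markers(
    plan: MovementPlan,
    policy: PlayerPolicy,
    anthropometry: Anthropometry = Anthropometry(),
    noise_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    meta: TrialMeta | None = None,
    rate: float = RATE,
) -> TrialRecording:
    """Render the full 22-marker recording for one movement plan."""
    if noise_sd < 0:
        raise ConfigError("noise_sd must be non-negative")
    a = anthropometry
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t = _times(plan, rate)
    n = len(t)

    body = body_trajectory(plan, rate)
    bx, by = body[:, 0], body[:, 1]
    drift = plan.drift_at(t)

    feet: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for foot, tag, sign in (("left", "L", -1.0), ("right", "R", 1.0)):
        cmds = [c for c in plan.steps if c.foot == foot]
        fx = (plan.start_x + sign * a.stance_half_width
              + _step_profile(t, cmds, "dx", half=False))
        fy = plan.start_y + drift + _step_profile(t, cmds, "dy", half=False)
        feet[tag] = (fx, fy)

    wrist_z: dict[str, np.ndarray] = {
        "L": np.full(n, a.wrist_rest_z), "R": np.full(n, a.wrist_rest_z)}
    for cmd in plan.arms:
        for side in cmd.sides:
            tag = "L" if side == "left" else "R"
            z = wrist_z[tag]
            up0, up1 = cmd.t0, cmd.t0 + cmd.t_raise
            dn0, dn1 = up1 + cmd.t_hold, cmd.end
            i = (t >= up0) & (t < up1)
            z[i] = mj_eval(t[i], up0, cmd.t_raise, a.wrist_rest_z, a.wrist_peak_z)
            i = (t >= up1) & (t < dn0)
            z[i] = a.wrist_peak_z
            i = (t >= dn0) & (t < dn1)
            z[i] = mj_eval(t[i], dn0, cmd.t_lower, a.wrist_peak_z, a.wrist_rest_z)

    H = a.height
    positions: dict[str, np.ndarray] = {}

    def put(name, x, y, z):
        arr = np.column_stack([
            np.broadcast_to(x, n).astype(float),
            np.broadcast_to(y, n).astype(float),
            np.broadcast_to(z, n).astype(float),
        ])
        positions[name] = arr

    hz = a.head_z
    put("head_ant_L", bx - 0.07, by + 0.09, hz + 0.01)
    put("head_ant_R", bx + 0.07, by + 0.09, hz + 0.01)
    put("head_post_L", bx - 0.07, by - 0.09, hz - 0.01)
    put("head_post_R", bx + 0.07, by - 0.09, hz - 0.01)
    put("sternum", bx, by, a.sternum_z)
    for tag, sign in (("L", -1.0), ("R", 1.0)):
        put(f"acromion_{tag}", bx + sign * a.shoulder_half_width, by, 0.82 * H)
        put(f"elbow_{tag}", bx + sign * (a.shoulder_half_width + 0.05), by, 0.63 * H)
        put(f"wrist_{tag}", bx + sign * (a.shoulder_half_width + 0.07), by + 0.05,
            wrist_z[tag])
        put(f"psis_{tag}", bx + sign * a.hip_half_width, by - 0.10, 0.58 * H)
        put(f"asis_{tag}", bx + sign * a.hip_half_width, by + 0.10, 0.58 * H)
        fx, fy = feet[tag]
        put(f"knee_{tag}", fx, fy - 0.05, 0.28 * H)
        put(f"ankle_{tag}", fx, fy - 0.15, 0.05 * H)
        put(f"toe_{tag}", fx, fy, 0.02 * H)
    put("thigh_R", bx + a.hip_half_width + 0.03, by + 0.02, 0.45 * H)

    if noise_sd > 0:
        for name in positions:
            positions[name] = positions[name] + rng.normal(0, noise_sd, (n, 3))

    return TrialRecording(positions=positions, rate=rate,
                          meta=meta or TrialMeta(), markers=MarkerSet())


def ground_truth_from_plan(
    plan: MovementPlan,
    log: GameEventLog,
    anthropometry: Anthropometry = Anthropometry(),
    stationary_speed: float = 0.1,
    lift_hysteresis: float = 0.02,
) -> GroundTruth:
    """Exact operational event annotations for a rendered plan.

    Step boundaries are the closed-form times at which each commanded
    minimum-jerk profile crosses the stationary-speed band; arm-lift
    boundaries are the analytic head-level crossings of the wrist profile
    (release level lowered by the detector's hysteresis).
    """
    a = anthropometry
    steps: list[tuple[str, float, float, float]] = []
    for cmd in plan.steps:
        cross = mj_speed_crossings(cmd.displacement, cmd.duration, stationary_speed)
        if cross is None:
            continue
        t1, t2 = cross
        size = cmd.displacement * (mj_shape(t2 / cmd.duration)
                                   - mj_shape(t1 / cmd.duration))
        steps.append((cmd.foot, cmd.t0 + t1, cmd.t0 + t2, float(size)))

    lifts: list[tuple[str, float, float]] = []
    head_z = a.head_z  # four head markers average to head_z exactly
    for cmd in plan.arms:
        up = mj_level_crossing(head_z, a.wrist_rest_z, a.wrist_peak_z, cmd.t_raise)
        down = mj_level_crossing(head_z - lift_hysteresis,
                                 a.wrist_peak_z, a.wrist_rest_z, cmd.t_lower)
        if up is None or down is None:
            continue
        start = cmd.t0 + up
        end = cmd.t0 + cmd.t_raise + cmd.t_hold + down
        side = "both" if len(cmd.sides) == 2 else cmd.sides[0]
        lifts.append((side, start, end))

    by_foot = {
        foot: [StepEvent(foot, s, e, sz) for f, s, e, sz in steps if f == foot]
        for foot in ("left", "right")
    }
    support_iv = derive_single_support(by_foot, plan.duration)
    support = {
        foot: [(iv.start, iv.end) for iv in ivs]
        for foot, ivs in support_iv.items()
    }

    return GroundTruth(
        steps=steps,
        arm_lifts=lifts,
        support=support,
        error_messages=[(e.time, e.duration, e.direction) for e in log.errors],
        game=log,
    )
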