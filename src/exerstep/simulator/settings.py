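"""Configuration and plan/ground-truth data types for the game simulator."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..errors import ConfigError
from ..gamelog import GameEventLog, ScoreWeights


@dataclass(frozen=True)
class GameSettings:
    """Game parameters for one speed x obstacles condition.

    Higher game speed raises the number of simultaneously falling grapes
    (1-3 -> 3-5) and branches (1-2 -> 1-3) and shortens their time on screen
    (8-10 s -> 6-9 s).  The number of chickens (11 per trial) and their 7 s
    catch window do not depend on speed.
    """

    speed: str = "low"                  # "low" / "high"
    obstacles: str = "without"          # "without" / "with"
    trial_duration: float = 120.0       # s of game time
    area_half_width: float = 1.0        # active area is 2*half_width square
    grape_concurrency: tuple[int, int] = (1, 3)
    branch_concurrency: tuple[int, int] = (1, 2)
    fall_time_range: tuple[float, float] = (8.0, 10.0)
    chickens_per_trial: int = 11
    chicken_window: float = 7.0
    branch_width: float = 0.57
    catch_half_width: float = 0.15
    score_weights: ScoreWeights = field(default_factory=ScoreWeights)

    def __post_init__(self) -> None:
        for lo, hi in (self.grape_concurrency, self.branch_concurrency):
            if not (0 < lo <= hi):
                raise ConfigError("concurrency ranges must be non-empty and positive")
        lo, hi = self.fall_time_range
        if not (0 < lo <= hi):
            raise ConfigError("fall_time_range must be positive and ordered")
        if self.chicken_window <= 0:
            raise ConfigError("chicken_window must be positive")
        if self.branch_width >= 2 * self.area_half_width:
            raise ConfigError("branch wider than the play area")

    @classmethod
    def for_condition(cls, speed: str, obstacles: str, **overrides) -> "GameSettings":
        if speed == "low":
            base = dict(grape_concurrency=(1, 3), branch_concurrency=(1, 2),
                        fall_time_range=(8.0, 10.0))
        elif speed == "high":
            base = dict(grape_concurrency=(3, 5), branch_concurrency=(1, 3),
                        fall_time_range=(6.0, 9.0))
        else:
            raise ConfigError(f"speed must be 'low' or 'high', got {speed!r}")
        if obstacles not in ("without", "with"):
            raise ConfigError(f"obstacles must be 'without' or 'with', got {obstacles!r}")
        base.update(overrides)
        return cls(speed=speed, obstacles=obstacles, **base)


@dataclass
class GameObject:
    kind: str                  # grape / chicken / branch
    spawn_time: float          # game-clock s
    lateral: float             # center, m
    half_width: float          # lateral half extent (0 for grapes/chickens)
    fall_time: float           # time on screen (grapes/branches) or window (chickens)
    outcome: str = "pending"   # caught / missed / hit / avoided / pending

    @property
    def arrival(self) -> float:
        return self.spawn_time + self.fall_time


@dataclass(frozen=True)
class PlayerPolicy:
    """Behavior model for one simulated participant."""

    reaction_delay: float = 0.4          # s before a commanded sequence starts
    step_size_preference: float = 0.25   # m per foot step
    cadence_preference: float = 110.0    # foot steps per minute while moving
    step_duration: float = 0.30          # s per foot step
    arm_lift_probability: float = 0.9    # per chicken
    arm_style: str = "both_arms"         # one_arm / both_arms / never
    forward_drift_rate: float = 0.25     # m per minute toward the screen
    lateral_noise: float = 0.05          # sd of target placement error, m
    jump_catch: bool = False             # exploit: catch grapes during jumps
    error_resolution_median: float = 2.0 # s, median pause to step back inside

    def __post_init__(self) -> None:
        if not 0.0 <= self.arm_lift_probability <= 1.0:
            raise ConfigError("arm_lift_probability must be in [0, 1]")
        for name in ("reaction_delay", "step_size_preference", "cadence_preference",
                     "step_duration", "forward_drift_rate", "lateral_noise"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.arm_style not in ("one_arm", "both_arms", "never"):
            raise ConfigError(f"unknown arm_style {self.arm_style!r}")

    @property
    def dwell(self) -> float:
        """Pause between consecutive foot steps, from the cadence preference."""
        period = 60.0 / max(self.cadence_preference, 1.0)
        return max(0.08, period - self.step_duration)


@dataclass(frozen=True)
class PolicyPopulation:
    """Between-participant distribution over :class:`PlayerPolicy`.

    One policy per participant induces the participant-level random intercept
    that the mixed-effects analysis assumes.
    """

    reaction_delay: tuple[float, float] = (0.4, 0.1)
    step_size_preference: tuple[float, float] = (0.25, 0.05)
    cadence_preference: tuple[float, float] = (110.0, 15.0)
    arm_lift_probability: tuple[float, float] = (0.9, 0.08)
    forward_drift_rate: tuple[float, float] = (0.35, 0.3)
    lateral_noise: tuple[float, float] = (0.05, 0.02)
    # roughly matches the observed mix of playing styles, including one
    # participant in fifteen who never raised the arms
    arm_style_probs: tuple[float, float, float] = (0.50, 0.43, 0.07)  # both/one/never

    def sample(self, rng: np.random.Generator) -> PlayerPolicy:
        def pos(mu_sd, lo=0.01):
            mu, sd = mu_sd
            return max(lo, float(rng.normal(mu, sd)))

        style = rng.choice(["both_arms", "one_arm", "never"], p=self.arm_style_probs)
        return PlayerPolicy(
            reaction_delay=pos(self.reaction_delay, 0.05),
            step_size_preference=pos(self.step_size_preference, 0.12),
            cadence_preference=pos(self.cadence_preference, 40.0),
            arm_lift_probability=float(np.clip(rng.normal(*self.arm_lift_probability), 0, 1)),
            arm_style=str(style),
            forward_drift_rate=pos(self.forward_drift_rate, 0.0),
            lateral_noise=pos(self.lateral_noise, 0.0),
        )


@dataclass(frozen=True)
class StepCommand:
    """One commanded foot step.

    The foot marker moves by ``(dx, dy)`` along a minimum-jerk profile over
    ``[t0, t0 + duration]``; the body (sternum) concurrently moves by half
    that displacement, so a lead-step/close-step pair shifts the body by one
    step size with the stance width restored.
    """

    foot: str          # "left" / "right"
    t0: float          # wall-clock s
    duration: float
    dx: float
    dy: float

    @property
    def displacement(self) -> float:
        return float(np.hypot(self.dx, self.dy))


@dataclass(frozen=True)
class ArmCommand:
    """One commanded arm raise: up, hold above the head, down."""

    sides: tuple[str, ...]      # ("left",), ("right",) or ("left", "right")
    t0: float                   # wall-clock s
    t_raise: float = 0.35
    t_hold: float = 0.6
    t_lower: float = 0.35

    @property
    def end(self) -> float:
        return self.t0 + self.t_raise + self.t_hold + self.t_lower

    @property
    def above(self) -> tuple[float, float]:
        """Interval during which the wrist is guaranteed at its apex."""
        return (self.t0 + self.t_raise, self.t0 + self.t_raise + self.t_hold)


@dataclass
class MovementPlan:
    """Commanded kinematics for one trial, in wall-clock time."""

    duration: float                      # wall s (recording length)
    start_x: float
    start_y: float
    steps: list[StepCommand] = field(default_factory=list)
    arms: list[ArmCommand] = field(default_factory=list)
    #: cumulative forward drift d(t) as (time, displacement) breakpoints;
    #: piecewise linear, frozen while the game is paused
    drift_breakpoints: list[tuple[float, float]] = field(default_factory=list)

    def drift_at(self, t) -> np.ndarray:
        if not self.drift_breakpoints:
            return np.zeros_like(np.asarray(t, dtype=float))
        bp = np.asarray(self.drift_breakpoints)
        return np.interp(t, bp[:, 0], bp[:, 1])


@dataclass(frozen=True)
class Anthropometry:
    """Marker placement heights/offsets for rendering, all in meters."""

    height: float = 1.71
    shoulder_half_width: float = 0.18
    hip_half_width: float = 0.12
    stance_half_width: float = 0.12
    arm_down_z: float | None = None     # default 0.49 * height

    def __post_init__(self) -> None:
        if self.height <= 0 or self.shoulder_half_width <= 0 or \
                self.hip_half_width <= 0 or self.stance_half_width <= 0:
            raise ConfigError("anthropometry lengths must be positive")
        if self.arm_down_z is not None and self.arm_down_z <= 0:
            raise ConfigError("arm_down_z must be positive")

    @property
    def head_z(self) -> float:
        return 0.936 * self.height

    @property
    def sternum_z(self) -> float:
        return 0.72 * self.height

    @property
    def wrist_rest_z(self) -> float:
        return self.arm_down_z if self.arm_down_z is not None else 0.49 * self.height

    @property
    def wrist_peak_z(self) -> float:
        return self.head_z + 0.15


@dataclass
class GroundTruth:
    """Exact event annotations for one synthesized trial.

    Step and arm-lift boundaries are *operational*: the analytic times at
    which the commanded minimum-jerk profiles cross the detector's stationary
    band (0.1 m/s) and head-height levels, so that a detector applied to the
    noise-free render recovers them to within one frame.
    """

    steps: list[tuple[str, float, float, float]]        # foot, start, end, size
    arm_lifts: list[tuple[str, float, float]]           # side(s), start, end
    support: dict[str, list[tuple[float, float]]]       # stance foot -> intervals
    error_messages: list[tuple[float, float, str]]      # start, duration, direction
    game: GameEventLog

    def support_total(self, foot: str) -> float:
        return sum(e - s for s, e in self.support.get(foot, []))
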