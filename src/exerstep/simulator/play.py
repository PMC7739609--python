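"""Gameplay simulation: a policy-driven player in front of the falling fruit.

The loop runs on the capture clock (wall time).  The game clock advances with
it except while the simulated sternum is outside the 2 x 2 m active area, when
the game pauses, an error message is logged and the player steps back inside.
The avatar mirrors the player's lateral (sternum) position.  All body motion
is expressed as commanded foot steps: each step moves the stepping foot's
markers by its displacement and the body by half of it, so a lead/close pair
shifts the body by one step size.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np

from .._profiles import mj_shape
from ..gamelog import ErrorMessage, GameEventLog, ObjectRecord
from ..mocap_io import TrialMeta
from .settings import (
    ArmCommand,
    GameObject,
    GameSettings,
    MovementPlan,
    PlayerPolicy,
    StepCommand,
)

DT = 1.0 / 120.0

#: Player start: centered laterally, 0.5 m behind the area center.
START_X = 0.0
START_Y = -0.5

_EVADE_LOOKAHEAD = 3.5     # s of game time
_MIN_STEP = 0.06           # m; smaller moves are skipped (well inside catch tolerance)
_WINDDOWN_MARGIN = 0.2     # s


class _Player:
    """Mutable gameplay state shared by the frame loop and the controller."""

    def __init__(self, policy: PlayerPolicy, rng: np.random.Generator):
        self.policy = policy
        self.rng = rng
        self.base_x = START_X
        self.base_y = 0.0            # commanded y contribution (drift separate)
        self.queue: list[StepCommand] = []
        self.active: StepCommand | None = None
        self.arm_queue: list[ArmCommand] = []
        self.arm_active: ArmCommand | None = None
        self.planned_x = START_X     # body x once the queue empties
        self.planned_y_cmd = 0.0
        self.queue_end = 0.0         # wall time when all queued steps finish
        self.busy_until = 0.0
        self.steps_done: list[StepCommand] = []
        self.arms_done: list[ArmCommand] = []

    # -- kinematic evaluation -------------------------------------------------

    def position(self, t: float, drift: float) -> tuple[float, float]:
        while self.active is None and self.queue and self.queue[0].t0 <= t:
            self.active = self.queue.pop(0)
        if self.active is not None and t >= self.active.t0 + self.active.duration:
            self.base_x += self.active.dx / 2.0
            self.base_y += self.active.dy / 2.0
            self.steps_done.append(self.active)
            self.active = None
            return self.position(t, drift)
        x, y = self.base_x, self.base_y
        if self.active is not None and t >= self.active.t0:
            frac = mj_shape((t - self.active.t0) / self.active.duration)
            x += self.active.dx / 2.0 * frac
            y += self.active.dy / 2.0 * frac
        return x, START_Y + y + drift

    def arm_above(self, t: float) -> bool:
        while self.arm_active is None and self.arm_queue and self.arm_queue[0].t0 <= t:
            self.arm_active = self.arm_queue.pop(0)
        if self.arm_active is not None and t >= self.arm_active.end:
            self.arms_done.append(self.arm_active)
            self.arm_active = None
            return self.arm_above(t)
        if self.arm_active is None or t < self.arm_active.t0:
            return False
        lo, hi = self.arm_active.above
        return lo <= t <= hi

    # -- command construction -------------------------------------------------

    def move_time(self, dx_body: float) -> float:
        """Wall time needed to shift the body by ``dx_body``, incl. reaction."""
        if abs(dx_body) < _MIN_STEP:
            return self.policy.reaction_delay
        pairs = self._n_pairs(dx_body)
        return (self.policy.reaction_delay
                + 2 * pairs * (self.policy.step_duration + self.policy.dwell))

    def _n_pairs(self, dx_body: float) -> int:
        pairs = max(1, round(abs(dx_body) / self.policy.step_size_preference))
        while pairs > 1 and abs(dx_body) / pairs < _MIN_STEP:
            pairs -= 1
        return pairs

    def queue_lateral_move(self, target_x: float, t_from: float,
                           urgent: bool = False) -> float:
        """Queue a lead/close step sequence toward ``target_x``; return end time."""
        dx_body = target_x - self.planned_x
        reaction = self.policy.reaction_delay * (0.5 if urgent else 1.0)
        dwell = max(0.08, self.policy.dwell * (0.5 if urgent else 1.0))
        t0 = max(t_from, self.queue_end) + reaction
        if abs(dx_body) < _MIN_STEP:
            return t0
        d = dx_body / self._n_pairs(dx_body)     # per foot step, per pair
        lead, trail = ("right", "left") if d > 0 else ("left", "right")
        tc = t0
        for _ in range(self._n_pairs(dx_body)):
            for foot in (lead, trail):
                self.queue.append(StepCommand(foot, tc, self.policy.step_duration, d, 0.0))
                tc += self.policy.step_duration + dwell
        self.planned_x += d * self._n_pairs(dx_body)
        self.queue_end = tc
        return tc

    def queue_y_correction(self, dy_body: float, t_from: float) -> float:
        """Queue backward/forward shuffle steps shifting the body by ``dy_body``."""
        t0 = max(t_from, self.queue_end) + 0.1
        d = dy_body / 2.0                         # 4 steps, body moves 2 d
        tc = t0
        for foot in ("right", "left", "right", "left"):
            self.queue.append(StepCommand(foot, tc, self.policy.step_duration, 0.0, d))
            tc += self.policy.step_duration + 0.08
        self.planned_y_cmd += dy_body
        self.queue_end = tc
        return tc

    def queue_arm_lift(self, sides: tuple[str, ...], t_from: float) -> float:
        cmd = ArmCommand(sides=sides, t0=max(t_from, self.queue_end) + 0.05)
        self.arm_queue.append(cmd)
        return cmd.end

    def all_commands_done(self, t: float) -> bool:
        return (not self.queue and self.active is None
                and not self.arm_queue and self.arm_active is None)

    def feet_idle(self) -> bool:
        return not self.queue and self.active is None


def simulate_play(
    schedule: list[GameObject],
    policy: PlayerPolicy,
    settings: GameSettings,
    seed: int | np.random.Generator,
    meta: TrialMeta | None = None,
) -> tuple[np.ndarray, GameEventLog, MovementPlan]:
    """Play one trial; return (avatar XY trajectory, event log, movement plan).

    The avatar trajectory is the sternum's (X, Y) sampled at 120 Hz over the
    full capture duration.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    meta = meta or TrialMeta(speed=settings.speed, obstacles=settings.obstacles)
    player = _Player(policy, rng)
    half = settings.area_half_width
    drift_rate = policy.forward_drift_rate / 60.0

    falling = sorted((o for o in schedule if o.kind in ("grape", "branch")),
                     key=lambda o: o.arrival)
    chickens = sorted((o for o in schedule if o.kind == "chicken"),
                      key=lambda o: o.spawn_time)
    fall_ptr = 0
    chick_ptr = 0
    active_chicken: GameObject | None = None
    chicken_caught = False
    chicken_handled = False
    chicken_wants: bool | None = None

    errors: list[ErrorMessage] = []
    drift_bp: list[tuple[float, float]] = [(0.0, 0.0)]
    drift = 0.0
    paused = False
    pause_end = 0.0

    t = 0.0
    t_game = 0.0
    duration = settings.trial_duration
    max_wall = 3.0 * duration + 120.0

    def unresolved_grapes():
        return [o for o in falling[fall_ptr:fall_ptr + 12]
                if o.kind == "grape" and o.outcome == "pending"]

    def branch_threat(x_now: float):
        for o in falling[fall_ptr:fall_ptr + 16]:
            if (o.kind == "branch" and o.outcome == "pending"
                    and o.arrival <= t_game + _EVADE_LOOKAHEAD
                    and abs(player.planned_x - o.lateral) < o.half_width + 0.08):
                return o
        return None

    def blocked(pos: float, until_game: float) -> bool:
        """Will a branch arriving before ``until_game`` cover ``pos``?"""
        for o in falling[fall_ptr:fall_ptr + 16]:
            if (o.kind == "branch" and o.outcome == "pending"
                    and o.arrival <= until_game
                    and abs(pos - o.lateral) <= o.half_width + 0.12):
                return True
        return False

    while t_game < duration and t < max_wall:
        x, y = player.position(t, drift)

        if paused:
            if t >= pause_end:
                paused = False
                drift_bp.append((t, drift))
                player.busy_until = t + 0.1
        else:
            # --- boundary exits ------------------------------------------------
            direction = None
            if y > half:
                direction = "front"
            elif y < -half:
                direction = "back"
            elif x > half:
                direction = "right"
            elif x < -half:
                direction = "left"
            if direction is not None:
                resolution = float(np.exp(rng.normal(
                    math.log(policy.error_resolution_median), 0.35)))
                if direction in ("front", "back"):
                    target_y = 0.3 if direction == "front" else -0.3
                    end = player.queue_y_correction(
                        (target_y - y) + 0.0, t)
                else:
                    target_x = 0.75 if direction == "right" else -0.75
                    end = player.queue_lateral_move(target_x, t)
                min_pause = (end - t) + 0.15
                resolution = max(resolution, min_pause)
                paused = True
                pause_end = t + resolution
                player.busy_until = pause_end
                drift_bp.append((t, drift))
                errors.append(ErrorMessage(
                    time=t, game_time=t_game, direction=direction,
                    duration=resolution))
                t += DT
                continue

            drift += drift_rate * DT
            t_game += DT

            # --- resolve falling objects --------------------------------------
            while fall_ptr < len(falling) and falling[fall_ptr].arrival <= t_game:
                obj = falling[fall_ptr]
                tol = settings.catch_half_width
                if obj.kind == "grape":
                    if policy.jump_catch and player.arm_above(t):
                        tol *= 1.6
                    obj.outcome = "caught" if abs(x - obj.lateral) <= tol else "missed"
                else:
                    obj.outcome = ("hit" if abs(x - obj.lateral) <= obj.half_width
                                   else "avoided")
                fall_ptr += 1

            # --- chickens ------------------------------------------------------
            if active_chicken is not None:
                if t_game >= active_chicken.arrival:
                    active_chicken.outcome = "caught" if chicken_caught else "missed"
                    active_chicken = None
                elif (not chicken_caught and player.arm_above(t)
                        and abs(x - active_chicken.lateral) <= settings.catch_half_width):
                    chicken_caught = True
            if active_chicken is None and chick_ptr < len(chickens) \
                    and chickens[chick_ptr].spawn_time <= t_game:
                active_chicken = chickens[chick_ptr]
                chick_ptr += 1
                chicken_caught = False
                chicken_handled = False
                chicken_wants = None

            # --- controller ----------------------------------------------------
            # idle waiting (no queued commands) may be preempted by a branch
            # threat or a newly appeared chicken; committed step sequences may
            # not.
            idle = player.feet_idle()
            threat = branch_threat(x) if (t >= player.busy_until or idle) else None
            preempt = idle and t < player.busy_until and (
                threat is not None
                or (active_chicken is not None and not chicken_handled
                    and player.all_commands_done(t)))
            if t >= player.busy_until or preempt:
                remaining = duration - t_game - _WINDDOWN_MARGIN
                if active_chicken is not None and not chicken_handled \
                        and not chicken_caught:
                    if chicken_wants is None:
                        chicken_wants = (policy.arm_style != "never"
                                         and rng.random() < policy.arm_lift_probability)
                    tgt = active_chicken.lateral + rng.normal(0, policy.lateral_noise / 2)
                    tgt = float(np.clip(tgt, -0.95 * half, 0.95 * half))
                    est = player.move_time(tgt - player.planned_x) + 1.6
                    window_left = active_chicken.arrival - t_game
                    if not chicken_wants or est > remaining:
                        chicken_handled = True
                        player.busy_until = t + 0.3
                    elif blocked(tgt, t_game + est) and window_left > est + 1.0:
                        # a branch will sweep the chicken's spot: wait it out
                        player.busy_until = t + 0.4
                    else:
                        chicken_handled = True
                        move_end = player.queue_lateral_move(tgt, t)
                        sides = (("left", "right") if policy.arm_style == "both_arms"
                                 else (str(rng.choice(["left", "right"])),))
                        lift_end = player.queue_arm_lift(sides, move_end)
                        player.busy_until = lift_end + 0.1
                elif threat is not None:
                    # step out of the branch interval, toward the play center
                    # unless that side is itself about to be swept
                    away = -1.0 if threat.lateral > 0 else 1.0
                    candidates = [
                        float(np.clip(threat.lateral + s * (threat.half_width + 0.22),
                                      -0.95 * half, 0.95 * half))
                        for s in (away, -away)
                    ]
                    tgt = next(
                        (c for c in candidates
                         if not blocked(c, threat.arrival + 0.6)),
                        candidates[0])
                    if player.move_time(tgt - player.planned_x) <= remaining:
                        end = player.queue_lateral_move(tgt, t, urgent=True)
                        player.busy_until = end + 0.05
                    else:
                        player.busy_until = t + 0.15
                elif preempt:
                    pass   # chicken was just handled above; keep waiting otherwise
                else:
                    best = None
                    best_arrival = None
                    for o in unresolved_grapes():
                        dx_body = o.lateral - player.planned_x
                        eta = t + player.move_time(dx_body)
                        arrival_wall = t + (o.arrival - t_game)
                        if (eta <= arrival_wall - 0.05
                                and o.arrival <= t_game + remaining
                                and not blocked(o.lateral, o.arrival + 0.6)):
                            best = o
                            best_arrival = arrival_wall
                            break   # falling[] is arrival-sorted: first is soonest
                    if best is not None and t_game < duration - _WINDDOWN_MARGIN:
                        tgt = best.lateral + rng.normal(0, policy.lateral_noise)
                        end = player.queue_lateral_move(
                            float(np.clip(tgt, -0.95 * half, 0.95 * half)), t)
                        # stay under the grape until it lands
                        player.busy_until = max(end, best_arrival) + 0.05
                    else:
                        player.busy_until = t + 0.15

        t += DT

    # flush any command still marked active (loop guarantees completion times
    # are inside the capture window)
    end_t = t
    player.position(end_t + 10 * DT, drift)
    player.arm_above(end_t + 10 * DT)
    drift_bp.append((end_t, drift))

    plan = MovementPlan(
        duration=end_t,
        start_x=START_X,
        start_y=START_Y,
        steps=sorted(player.steps_done, key=lambda c: c.t0),
        arms=sorted(player.arms_done, key=lambda c: c.t0),
        drift_breakpoints=drift_bp,
    )

    score = sum(
        settings.score_weights.grape * (o.kind == "grape" and o.outcome == "caught")
        + settings.score_weights.chicken * (o.kind == "chicken" and o.outcome == "caught")
        + settings.score_weights.branch * (o.kind == "branch" and o.outcome == "hit")
        for o in schedule
    )
    log = GameEventLog(
        meta=meta,
        objects=[ObjectRecord(o.kind, o.spawn_time, o.lateral, o.half_width,
                              o.fall_time, o.outcome) for o in schedule],
        errors=errors,
        score=int(score),
        duration_game=min(t_game, duration),
        duration_wall=end_t,
    )

    from .render import body_trajectory
    avatar = body_trajectory(plan)
    return avatar, log, plan
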