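"""Object schedules: falling grapes/branches and stationary chickens.

Spawning maintains the configured concurrency band: whenever a landing would
drop the number of simultaneously falling objects below the band minimum, a
replacement spawns at that instant; occasional extra spawns fill toward the
maximum.  Chickens get non-overlapping catch windows spread over the trial.
"""

from __future__ import annotations

import heapq

import numpy as np

from ..errors import ScheduleInfeasible
from .settings import GameObject, GameSettings

#: Lateral band for object centers, as a fraction of the area half width.
SPAWN_MARGIN = 0.85
#: Probability of an extra spawn (toward the concurrency maximum) per landing.
EXTRA_SPAWN_P = 0.35


def _falling_kind(kind: str, settings: GameSettings,
                  concurrency: tuple[int, int], half_width: float,
                  rng: np.random.Generator) -> list[GameObject]:
    lo, hi = concurrency
    duration = settings.trial_duration
    span = SPAWN_MARGIN * settings.area_half_width - half_width
    if span <= 0:
        raise ScheduleInfeasible(f"{kind} wider than the spawn band")

    def spawn(t: float) -> GameObject:
        return GameObject(
            kind=kind,
            spawn_time=t,
            lateral=float(rng.uniform(-span, span)),
            half_width=half_width,
            fall_time=float(rng.uniform(*settings.fall_time_range)),
        )

    objects: list[GameObject] = []
    landings: list[float] = []   # heap of arrival times of active objects
    n_initial = int(rng.integers(lo, hi + 1))
    for _ in range(n_initial):
        obj = spawn(0.0)
        objects.append(obj)
        heapq.heappush(landings, obj.arrival)
    while landings and landings[0] < duration:
        t = heapq.heappop(landings)
        # active count just dropped by one; top back up to the band minimum
        while len(landings) < lo:
            obj = spawn(t)
            objects.append(obj)
            heapq.heappush(landings, obj.arrival)
        if len(landings) < hi and rng.random() < EXTRA_SPAWN_P:
            obj = spawn(t)
            objects.append(obj)
            heapq.heappush(landings, obj.arrival)
    return objects


def _chickens(settings: GameSettings, rng: np.random.Generator) -> list[GameObject]:
    n = settings.chickens_per_trial
    window = settings.chicken_window
    slack = settings.trial_duration - n * window
    if slack < 0:
        raise ScheduleInfeasible(
            f"{n} chickens with {window} s windows do not fit in "
            f"{settings.trial_duration} s")
    cuts = np.sort(rng.uniform(0.0, slack, size=n))
    span = SPAWN_MARGIN * settings.area_half_width
    return [
        GameObject(
            kind="chicken",
            spawn_time=float(cuts[i] + i * window),
            lateral=float(rng.uniform(-span, span)),
            half_width=0.0,
            fall_time=window,
        )
        for i in range(n)
    ]


def generate_object_schedule(
    settings: GameSettings, seed: int | np.random.Generator
) -> list[GameObject]:
    """Generate all game objects for one trial, sorted by spawn time.

    Raises :class:`ScheduleInfeasible` when the trial is too short to place
    all chickens.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if settings.trial_duration <= 0:
        raise ScheduleInfeasible("trial_duration must be positive")
    objects = _chickens(settings, rng)
    objects += _falling_kind("grape", settings, settings.grape_concurrency, 0.0, rng)
    if settings.obstacles == "with":
        objects += _falling_kind(
            "branch", settings, settings.branch_concurrency,
            settings.branch_width / 2.0, rng)
    return sorted(objects, key=lambda o: (o.spawn_time, o.kind, o.lateral))


def concurrency_profile(objects: list[GameObject], kind: str,
                        duration: float, dt: float = 0.05) -> np.ndarray:
    """Sampled count of simultaneously falling objects of one kind."""
    t = np.arange(0.0, duration, dt)
    count = np.zeros_like(t)
    for obj in objects:
        if obj.kind != kind:
            continue
        count += (t >= obj.spawn_time) & (t < obj.arrival)
    return count
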