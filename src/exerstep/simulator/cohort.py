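"""Cohort generation: participants x counterbalanced conditions x repetitions."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ..gamelog import GameEventLog
from ..mocap_io import TrialMeta, TrialRecording
from .play import simulate_play
from .render import ground_truth_from_plan, synthesize_markers
from .schedule import generate_object_schedule
from .settings import (
    Anthropometry,
    GameSettings,
    GroundTruth,
    MovementPlan,
    PlayerPolicy,
    PolicyPopulation,
)

CONDITIONS: tuple[tuple[str, str], ...] = (
    ("low", "without"), ("low", "with"), ("high", "without"), ("high", "with"))


@dataclass
class CohortTrial:
    recording: TrialRecording
    truth: GroundTruth
    log: GameEventLog
    plan: MovementPlan
    policy: PlayerPolicy


def condition_order(participant_index: int) -> tuple[tuple[str, str], ...]:
    """Latin-square rotation of the four conditions across participants."""
    k = participant_index % len(CONDITIONS)
    return CONDITIONS[k:] + CONDITIONS[:k]


def assign_genders(n: int) -> list[str]:
    """Deterministic gender assignment; 7 female / 8 male at n = 15."""
    n_female = round(7 * n / 15)
    return ["female"] * n_female + ["male"] * (n - n_female)


def iter_cohort(
    n_participants: int,
    seed: int,
    population: PolicyPopulation = PolicyPopulation(),
    trial_duration: float = 120.0,
    noise_sd: float = 0.002,
    anthropometry: Anthropometry = Anthropometry(),
    settings_overrides: dict | None = None,
) -> Iterator[CohortTrial]:
    """Lazily generate all trials of a synthetic cohort.

    Eight trials per participant: the four speed x obstacles conditions in a
    Latin-square counterbalanced order, each played twice (repetition 1 then
    2 in the same order).  The participant's policy is drawn once, inducing
    the between-participant variation the mixed model attributes to its
    random intercept.
    """
    if n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    root = np.random.SeedSequence(seed)
    genders = assign_genders(n_participants)
    for i, pseq in enumerate(root.spawn(n_participants)):
        p_rng = np.random.default_rng(pseq)
        policy = population.sample(p_rng)
        order = condition_order(i)
        pid = f"P{i + 1:02d}"
        for repetition in (1, 2):
            for speed, obstacles in order:
                settings = GameSettings.for_condition(
                    speed, obstacles, trial_duration=trial_duration,
                    **(settings_overrides or {}))
                meta = TrialMeta(participant=pid, gender=genders[i],
                                 speed=speed, obstacles=obstacles,
                                 repetition=repetition)
                trial_rng = np.random.default_rng(pseq.spawn(1)[0])
                schedule = generate_object_schedule(settings, trial_rng)
                _, log, plan = simulate_play(schedule, policy, settings,
                                             trial_rng, meta=meta)
                rec = synthesize_markers(plan, policy, anthropometry,
                                         noise_sd=noise_sd, seed=trial_rng,
                                         meta=meta)
                truth = ground_truth_from_plan(plan, log, anthropometry)
                yield CohortTrial(recording=rec, truth=truth, log=log,
                                  plan=plan, policy=policy)


def make_cohort(
    n_participants: int,
    seed: int,
    population: PolicyPopulation = PolicyPopulation(),
    **kwargs,
) -> list[CohortTrial]:
    """Materialize a full cohort (prefer :func:`iter_cohort` for large n)."""
    return list(iter_cohort(n_participants, seed, population, **kwargs))
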