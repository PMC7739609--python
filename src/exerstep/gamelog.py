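"""Structured game event logs: scoring, error-message tallies, chi-square.

These logs replace screen-capture OCR: the simulator (or an instrumented
game) writes one JSON record per event, and this module recounts outcomes,
builds the speed x obstacles error-message table and computes the associated
independence test.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.stats import chi2_contingency

from .errors import DegenerateTable, LogParseError, UndefinedRate
from .mocap_io import TrialMeta


@dataclass(frozen=True)
class ScoreWeights:
    grape: int = 1
    chicken: int = 3
    branch: int = -2


@dataclass
class ObjectRecord:
    kind: str                    # grape / chicken / branch
    spawn_time: float            # game-clock s
    lateral: float               # center position, m
    half_width: float            # 0 for points, branch_width/2 for branches
    fall_time: float             # s on screen (grapes/branches) or window (chickens)
    outcome: str                 # caught / missed / hit / avoided / pending


@dataclass
class ErrorMessage:
    time: float                  # wall-clock s at trigger
    game_time: float             # game-clock s at trigger
    direction: str               # front / back / left / right
    duration: float              # s until resolved


@dataclass
class GameEventLog:
    meta: TrialMeta
    objects: list[ObjectRecord] = field(default_factory=list)
    errors: list[ErrorMessage] = field(default_factory=list)
    score: int = 0
    duration_game: float = 0.0
    duration_wall: float = 0.0
    valid: bool = True

    def counts(self, kind: str) -> dict[str, int]:
        recs = [o for o in self.objects if o.kind == kind]
        out = {"presented": len(recs)}
        for o in recs:
            out[o.outcome] = out.get(o.outcome, 0) + 1
        return out


@dataclass(frozen=True)
class GameScoreSummary:
    score: int
    grapes_presented: int
    grapes_caught: int
    chickens_presented: int
    chickens_caught: int
    branches_presented: int
    branches_hit: int

    @property
    def pct_grapes_caught(self) -> float:
        return _pct(self.grapes_caught, self.grapes_presented)

    @property
    def pct_chickens_caught(self) -> float:
        return _pct(self.chickens_caught, self.chickens_presented)

    @property
    def pct_branches_hit(self) -> float:
        return _pct(self.branches_hit, self.branches_presented)


def _pct(num: int, den: int) -> float:
    return 100.0 * num / den if den else math.nan


@dataclass
class ErrorMessageTally:
    cells: dict[tuple[str, str], int]            # (speed, obstacles) -> count
    by_direction: dict[str, list[float]]         # direction -> resolution times
    valid_trials: int

    @property
    def total(self) -> int:
        return sum(self.cells.values())

    def table(self) -> np.ndarray:
        """2x2 array: rows speed (low, high), columns obstacles (without, with)."""
        return np.array([
            [self.cells.get(("low", "without"), 0), self.cells.get(("low", "with"), 0)],
            [self.cells.get(("high", "without"), 0), self.cells.get(("high", "with"), 0)],
        ])

    def mean_resolution(self) -> dict[str, float]:
        return {
            d: float(np.mean(ts)) if ts else math.nan
            for d, ts in self.by_direction.items()
        }


# ---------------------------------------------------------------------------
# serialization (JSON lines, one event per line)
# ---------------------------------------------------------------------------

def write_log(log: GameEventLog, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        header = {
            "record": "trial",
            **log.meta.as_dict(),
            "score": log.score,
            "duration_game": log.duration_game,
            "duration_wall": log.duration_wall,
            "valid": log.valid,
        }
        fh.write(json.dumps(header) + "\n")
        for obj in log.objects:
            fh.write(json.dumps({"record": "object", **asdict(obj)}) + "\n")
        for err in log.errors:
            fh.write(json.dumps({"record": "error", **asdict(err)}) + "\n")


def read_log(path: str | os.PathLike) -> GameEventLog:
    meta = TrialMeta()
    log = GameEventLog(meta=meta)
    try:
        lines = Path(path).read_text().splitlines()
    except OSError as exc:
        raise LogParseError(str(exc)) from exc
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        try:
            rec = json.loads(line)
            kind = rec.pop("record")
            if kind == "trial":
                log.meta = TrialMeta(
                    participant=rec["participant"], gender=rec.get("gender", ""),
                    speed=rec["speed"], obstacles=rec["obstacles"],
                    repetition=int(rec.get("repetition", 0)))
                log.score = int(rec["score"])
                log.duration_game = float(rec["duration_game"])
                log.duration_wall = float(rec["duration_wall"])
                log.valid = bool(rec.get("valid", True))
            elif kind == "object":
                log.objects.append(ObjectRecord(**rec))
            elif kind == "error":
                log.errors.append(ErrorMessage(**rec))
            else:
                raise KeyError(kind)
        except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
            raise LogParseError(f"{path}:{i + 1}: {exc}") from exc
    return log


# ---------------------------------------------------------------------------
# analysis operations
# ---------------------------------------------------------------------------

def score_trial(log: GameEventLog, weights: ScoreWeights = ScoreWeights()) -> GameScoreSummary:
    """Recount outcomes and compute the score from the weights.

    The returned summary satisfies the score identity
    ``score = w_grape * grapes_caught + w_chicken * chickens_caught +
    w_branch * branches_hit`` by construction.
    """
    for obj in log.objects:
        if obj.kind not in ("grape", "chicken", "branch"):
            raise LogParseError(f"unknown object kind {obj.kind!r}")
        if obj.outcome not in ("caught", "missed", "hit", "avoided", "pending"):
            raise LogParseError(f"unknown outcome {obj.outcome!r}")
    g = log.counts("grape")
    c = log.counts("chicken")
    b = log.counts("branch")
    score = (weights.grape * g.get("caught", 0)
             + weights.chicken * c.get("caught", 0)
             + weights.branch * b.get("hit", 0))
    return GameScoreSummary(
        score=score,
        grapes_presented=g["presented"], grapes_caught=g.get("caught", 0),
        chickens_presented=c["presented"], chickens_caught=c.get("caught", 0),
        branches_presented=b["presented"], branches_hit=b.get("hit", 0),
    )


def tally_errors(logs: list[GameEventLog]) -> ErrorMessageTally:
    """2x2 (speed x obstacles) error-message counts plus per-direction stats.

    Trials flagged invalid contribute neither messages nor to the valid-trial
    denominator, mirroring the handling of trials without usable captures.
    """
    cells: dict[tuple[str, str], int] = {}
    by_dir: dict[str, list[float]] = {}
    valid = 0
    for log in logs:
        if not log.valid:
            continue
        valid += 1
        key = (log.meta.speed, log.meta.obstacles)
        cells[key] = cells.get(key, 0) + len(log.errors)
        for err in log.errors:
            by_dir.setdefault(err.direction, []).append(err.duration)
    return ErrorMessageTally(cells=cells, by_direction=by_dir, valid_trials=valid)


def mean_errors_per_trial(tally: ErrorMessageTally) -> float:
    """Total error messages divided by the number of valid trials."""
    if tally.valid_trials <= 0:
        raise UndefinedRate("no valid trials")
    return tally.total / tally.valid_trials


def chi_square_2x2(table) -> tuple[float, int, float]:
    """Pearson chi-squared test on a 2x2 table, no continuity correction.

    Returns ``(statistic, df, p)`` with df = 1.
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DegenerateTable("zero row or column margin")
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)
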