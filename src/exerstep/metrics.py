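"""Per-trial movement characteristics.

All rates use the full motion-capture duration as denominator: the game clock
pauses during error messages but the capture does not, which is why ratios and
frequencies rather than raw totals are the comparable quantities across
trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detection import ArmLiftEvent, StepEvent, SupportInterval
from .errors import InsufficientData, MarkerSetMismatch
from .mocap_io import TrialMeta, TrialRecording

#: Default heatmap extent: 3 x 3 m centered on the play area -- player
#: positions outside the 2 x 2 m active square still appear in the figure.
DEFAULT_EXTENT = ((-1.5, 1.5), (-1.5, 1.5))


@dataclass(frozen=True)
class Heatmap:
    grid: np.ndarray                       # (bins, bins) counts, X rows, Y cols
    extent: tuple[tuple[float, float], tuple[float, float]]
    total: int                             # frames with valid sternum data

    @property
    def in_extent(self) -> int:
        return int(self.grid.sum())

    @property
    def out_of_extent(self) -> int:
        return self.total - self.in_extent


@dataclass
class TrialMetrics:
    """One trial's movement characteristics (NaN where undefined)."""

    meta: TrialMeta
    trial_time: float
    mean_single_support: dict[str, float]    # per stance foot, s
    single_support_ratio: dict[str, float]   # per stance foot, unitless
    mean_step_size: dict[str, float]         # per foot, m
    cadence: dict[str, float]                # per foot, steps/min
    arm_lift_frequency: dict[str, float]     # left/right/combined, lifts/min
    anterior_drift: float = math.nan         # m
    heatmap: Heatmap | None = None


def step_metrics(
    steps: dict[str, list[StepEvent]], trial_time: float
) -> dict[str, tuple[float, float]]:
    """Per foot: (mean step size in m, cadence in steps/min).

    Mean step size is NaN when the foot took no steps; cadence is then 0.
    """
    if trial_time <= 0:
        raise ValueError("trial_time must be positive")
    out = {}
    for foot, events in steps.items():
        n = len(events)
        mean_size = float(np.mean([e.size for e in events])) if n else math.nan
        out[foot] = (mean_size, 60.0 * n / trial_time)
    return out


def support_metrics(
    support: dict[str, list[SupportInterval]], trial_time: float
) -> dict[str, tuple[float, float]]:
    """Per stance foot: (mean single-support duration in s, support ratio)."""
    if trial_time <= 0:
        raise ValueError("trial_time must be positive")
    out = {}
    for foot, intervals in support.items():
        durations = [iv.duration for iv in intervals]
        mean_dur = float(np.mean(durations)) if durations else math.nan
        out[foot] = (mean_dur, float(np.sum(durations)) / trial_time)
    return out


def arm_lift_frequency(
    lifts: list[ArmLiftEvent], trial_time: float
) -> dict[str, float]:
    """Lifts per minute: per side and combined.

    A ``both`` event counts toward each side and once toward the combined
    rate.  ``trial_time`` is the full recording duration.
    """
    if trial_time <= 0:
        raise ValueError("trial_time must be positive")
    n_left = sum(1 for e in lifts if e.side in ("left", "both"))
    n_right = sum(1 for e in lifts if e.side in ("right", "both"))
    return {
        "left": 60.0 * n_left / trial_time,
        "right": 60.0 * n_right / trial_time,
        "combined": 60.0 * len(lifts) / trial_time,
    }


def position_heatmap(
    rec: TrialRecording,
    extent: tuple[tuple[float, float], tuple[float, float]] = DEFAULT_EXTENT,
    bins: int = 30,
) -> Heatmap:
    """2D occupancy histogram of the sternum marker over the floor plane."""
    if "sternum" not in rec.positions:
        raise MarkerSetMismatch("sternum marker required for heatmap")
    xy = rec["sternum"][:, :2]
    valid = ~np.isnan(xy).any(axis=1)
    xy = xy[valid]
    grid, _, _ = np.histogram2d(
        xy[:, 0], xy[:, 1], bins=bins, range=[list(extent[0]), list(extent[1])])
    return Heatmap(grid=grid.astype(int), extent=extent, total=int(valid.sum()))


def anterior_drift(rec: TrialRecording, window: float = 10.0) -> float:
    """Mean sternum Y over the final window minus over the initial window.

    Positive values mean the player ended closer to the screen.
    """
    if rec.duration <= 2 * window:
        raise InsufficientData(
            f"trial of {rec.duration:.2f} s too short for {window} s windows")
    y = rec["sternum"][:, 1]
    n = int(round(window * rec.rate))
    head = np.nanmean(y[:n])
    tail = np.nanmean(y[-n:])
    return float(tail - head)


def compute_trial_metrics(
    rec: TrialRecording,
    steps: dict[str, list[StepEvent]],
    support: dict[str, list[SupportInterval]],
    lifts: list[ArmLiftEvent],
    heatmap_extent=DEFAULT_EXTENT,
    drift_window: float = 10.0,
) -> TrialMetrics:
    """Bundle all per-trial movement characteristics."""
    t = rec.duration
    sm = step_metrics(steps, t)
    sup = support_metrics(support, t)
    try:
        drift = anterior_drift(rec, drift_window)
    except InsufficientData:
        drift = math.nan
    return TrialMetrics(
        meta=rec.meta,
        trial_time=t,
        mean_single_support={f: v[0] for f, v in sup.items()},
        single_support_ratio={f: v[1] for f, v in sup.items()},
        mean_step_size={f: v[0] for f, v in sm.items()},
        cadence={f: v[1] for f, v in sm.items()},
        arm_lift_frequency=arm_lift_frequency(lifts, t),
        anterior_drift=drift,
        heatmap=position_heatmap(rec, heatmap_extent),
    )
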