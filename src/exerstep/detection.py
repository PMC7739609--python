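"""Detection of steps, arm lifts and single-leg support from marker data.

A step is a >= 0.03 m net horizontal displacement of the foot marker lasting
>= 0.05 s, delimited by the foot-marker horizontal speed leaving/re-entering
the stationary band (speed < 0.1 m/s).  An arm lift is the interval during
which a wrist marker's vertical position exceeds the mean vertical position of
the four head markers.  Single-leg support on one foot is the time the other
foot spends in swing while that foot is stationary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import InsufficientData, MarkerSetMismatch
from .mocap_io import TrialRecording


@dataclass(frozen=True)
class DetectionConfig:
    min_displacement: float = 0.03   # m, net horizontal step displacement
    min_duration: float = 0.05       # s, minimum step duration
    stationary_speed: float = 0.1    # m/s, half-width of the zero-velocity band
    foot_marker: str = "toe"         # "toe" or "ankle"
    filter_cutoff: float = 6.0       # Hz, zero-lag low-pass before differencing
    min_lift_duration: float = 0.1   # s, discard shorter arm-lift chatter
    lift_hysteresis: float = 0.02    # m, release level below mean head height

    def __post_init__(self) -> None:
        for name in ("min_displacement", "min_duration", "stationary_speed",
                     "filter_cutoff", "min_lift_duration", "lift_hysteresis"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.foot_marker not in ("toe", "ankle"):
            raise ValueError("foot_marker must be 'toe' or 'ankle'")


@dataclass(frozen=True)
class StepEvent:
    foot: str        # "left" / "right"
    start: float     # s
    end: float       # s
    size: float      # m, net horizontal displacement

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class ArmLiftEvent:
    side: str        # "left" / "right" / "both"
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class SupportInterval:
    foot: str        # stance foot
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def _lowpass(series: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Zero-lag 4th-order Butterworth low-pass along axis 0."""
    if cutoff >= rate / 2:
        raise ValueError("cutoff must be below the Nyquist frequency")
    b, a = butter(4, cutoff / (rate / 2))
    padlen = 3 * (max(len(a), len(b)) - 1)
    if series.shape[0] <= padlen:
        raise InsufficientData(
            f"need more than {padlen} samples for filtering, got {series.shape[0]}")
    return filtfilt(b, a, series, axis=0)


def estimate_speed(
    series: np.ndarray, rate: float, cutoff: float = 6.0,
    return_filtered: bool = False,
):
    """Horizontal speed of a 3D position series (low-pass + central differences).

    Returns an array of the same length as the input; endpoints use one-sided
    differences.  With ``return_filtered=True`` the filtered positions are
    returned as well (used to measure step sizes on the same signal the
    velocity gate saw).
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] != 3:
        raise ValueError("series must be (n, 3)")
    if series.shape[0] < 3:
        raise InsufficientData("need at least 3 samples")
    filt = _lowpass(series, rate, cutoff)
    vel = np.gradient(filt[:, :2], 1.0 / rate, axis=0)
    speed = np.hypot(vel[:, 0], vel[:, 1])
    if return_filtered:
        return speed, filt
    return speed


def _runs_above(mask: np.ndarray):
    """(start, stop) index pairs of maximal True runs; stop is inclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.astype(int), [0]))))
    return [(int(s), int(e) - 1) for s, e in zip(idx[::2], idx[1::2])]


def detect_steps(
    rec: TrialRecording, cfg: DetectionConfig = DetectionConfig()
) -> dict[str, list[StepEvent]]:
    """Detect steps per foot from the configured foot marker.

    Candidate intervals are maximal runs where the marker's horizontal speed
    is at or above the stationary band; a candidate becomes a step iff its net
    horizontal displacement is >= ``min_displacement`` and its duration is
    >= ``min_duration``.  The step size is the horizontal Euclidean distance
    between the (filtered) positions at the run boundaries, capturing both
    sideways and forward components.
    """
    out: dict[str, list[StepEvent]] = {}
    for side, foot in (("left", f"{cfg.foot_marker}_L"), ("right", f"{cfg.foot_marker}_R")):
        if foot not in rec.positions:
            raise MarkerSetMismatch(f"foot marker {foot!r} not present")
        speed, filt = estimate_speed(
            rec[foot], rec.rate, cfg.filter_cutoff, return_filtered=True)
        events = []
        for i0, i1 in _runs_above(speed >= cfg.stationary_speed):
            duration = (i1 - i0) / rec.rate
            if duration < cfg.min_duration:
                continue
            size = float(np.hypot(*(filt[i1, :2] - filt[i0, :2])))
            if size < cfg.min_displacement:
                continue
            events.append(StepEvent(side, i0 / rec.rate, i1 / rec.rate, size))
        out[side] = events
    return out


def _lift_intervals(z: np.ndarray, head_z: np.ndarray, rate: float,
                    hysteresis: float, min_duration: float):
    """Hysteresis state machine: on when z > head, off when z < head - hyst."""
    above_on = z > head_z
    below_off = z < head_z - hysteresis
    events = []
    state = False
    start = 0
    for i in range(len(z)):
        if not state and above_on[i]:
            state, start = True, i
        elif state and below_off[i]:
            state = False
            events.append((start, i))
    if state:
        events.append((start, len(z) - 1))
    return [
        (s / rate, e / rate)
        for s, e in events
        if (e - s) / rate >= min_duration
    ]


def detect_arm_lifts(
    rec: TrialRecording, cfg: DetectionConfig = DetectionConfig()
) -> list[ArmLiftEvent]:
    """Detect arm lifts: wrist above mean head height, with hysteresis.

    Per side, a lift starts when the wrist Z rises above the mean head-marker
    Z and ends when it falls below that level minus ``lift_hysteresis``.
    Events shorter than ``min_lift_duration`` are discarded; overlapping
    left/right events are merged into a single ``side='both'`` event spanning
    their union.
    """
    head = rec.markers.head
    rec.require(*head, "wrist_L", "wrist_R")
    head_z = np.mean([rec[h][:, 2] for h in head], axis=0)
    per_side = {
        side: _lift_intervals(rec[f"wrist_{tag}"][:, 2], head_z, rec.rate,
                              cfg.lift_hysteresis, cfg.min_lift_duration)
        for side, tag in (("left", "L"), ("right", "R"))
    }
    events: list[ArmLiftEvent] = []
    left = list(per_side["left"])
    right = list(per_side["right"])
    used_r = [False] * len(right)
    for ls, le in left:
        merged = False
        for j, (rs, re) in enumerate(right):
            if not used_r[j] and ls < re and rs < le:  # overlap
                events.append(ArmLiftEvent("both", min(ls, rs), max(le, re)))
                used_r[j] = True
                merged = True
                break
        if not merged:
            events.append(ArmLiftEvent("left", ls, le))
    for j, (rs, re) in enumerate(right):
        if not used_r[j]:
            events.append(ArmLiftEvent("right", rs, re))
    return sorted(events, key=lambda e: e.start)


def _subtract_intervals(base: list[tuple[float, float]],
                        cut: list[tuple[float, float]]):
    """Set difference of unions of intervals, result as maximal intervals."""
    out = []
    for s, e in base:
        pieces = [(s, e)]
        for cs, ce in cut:
            next_pieces = []
            for ps, pe in pieces:
                if ce <= ps or cs >= pe:
                    next_pieces.append((ps, pe))
                else:
                    if cs > ps:
                        next_pieces.append((ps, cs))
                    if ce < pe:
                        next_pieces.append((ce, pe))
            pieces = next_pieces
        out.extend(pieces)
    return sorted((s, e) for s, e in out if e > s)


def derive_single_support(
    steps: dict[str, list[StepEvent]], duration: float
) -> dict[str, list[SupportInterval]]:
    """Single-leg support per stance foot from the per-foot step events.

    For stance foot F, single support is the union of the contralateral foot's
    step intervals minus any overlap with F's own steps (double-swing time is
    excluded).
    """
    out: dict[str, list[SupportInterval]] = {}
    for stance, swing in (("left", "right"), ("right", "left")):
        swing_iv = [(s.start, s.end) for s in steps.get(swing, [])]
        own_iv = [(s.start, s.end) for s in steps.get(stance, [])]
        clipped = [(max(0.0, s), min(duration, e)) for s, e in swing_iv]
        clipped = [(s, e) for s, e in clipped if e > s]
        out[stance] = [
            SupportInterval(stance, s, e)
            for s, e in _subtract_intervals(clipped, own_iv)
        ]
    return out
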