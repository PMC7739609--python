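"""Shared fixtures and independent oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest

from exerstep.markers import CANONICAL_MARKERS
from exerstep.mocap_io import TrialMeta, TrialRecording

RATE = 120.0


def static_positions(n_frames: int, rng=None) -> dict[str, np.ndarray]:
    """A full 22-marker standing posture, constant over time."""
    base = {
        "head_ant_L": (-0.07, 0.09, 1.61), "head_ant_R": (0.07, 0.09, 1.61),
        "head_post_L": (-0.07, -0.09, 1.59), "head_post_R": (0.07, -0.09, 1.59),
        "sternum": (0.0, -0.5, 1.23), "thigh_R": (0.15, -0.48, 0.77),
    }
    for tag, sign in (("L", -1), ("R", 1)):
        base[f"wrist_{tag}"] = (sign * 0.25, -0.45, 0.84)
        base[f"elbow_{tag}"] = (sign * 0.23, -0.5, 1.08)
        base[f"acromion_{tag}"] = (sign * 0.18, -0.5, 1.40)
        base[f"psis_{tag}"] = (sign * 0.12, -0.6, 0.99)
        base[f"asis_{tag}"] = (sign * 0.12, -0.4, 0.99)
        base[f"knee_{tag}"] = (sign * 0.12, -0.55, 0.48)
        base[f"ankle_{tag}"] = (sign * 0.12, -0.65, 0.09)
        base[f"toe_{tag}"] = (sign * 0.12, -0.5, 0.03)
    assert set(base) == set(CANONICAL_MARKERS)
    return {k: np.tile(np.asarray(v, float), (n_frames, 1)) for k, v in base.items()}


def make_recording(n_frames: int = 240, rate: float = RATE,
                   meta: TrialMeta | None = None) -> TrialRecording:
    return TrialRecording(positions=static_positions(n_frames), rate=rate,
                          meta=meta or TrialMeta(participant="P01"))


def minjerk_shape(tau: np.ndarray) -> np.ndarray:
    """Independent quintic shape (re-derived, not imported from the package)."""
    tau = np.clip(tau, 0.0, 1.0)
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def add_step(rec: TrialRecording, marker: str, t0: float, duration: float,
             dx: float, dy: float = 0.0) -> None:
    """Superimpose a minimum-jerk displacement on one marker in place."""
    t = np.arange(rec.n_frames) / rec.rate
    prof = minjerk_shape((t - t0) / duration)
    rec.positions[marker] = rec.positions[marker].copy()
    rec.positions[marker][:, 0] += dx * prof
    rec.positions[marker][:, 1] += dy * prof


def brute_force_steps(speed: np.ndarray, horizontal: np.ndarray, rate: float,
                      stationary_speed: float = 0.1,
                      min_displacement: float = 0.03,
                      min_duration: float = 0.05):
    """Exhaustive per-frame threshold scan (the independent step oracle).

    Walks the speed series sample by sample, collecting maximal runs at or
    above the stationary band, then applies the displacement and duration
    thresholds to each run.
    """
    events = []
    i = 0
    n = len(speed)
    while i < n:
        if speed[i] >= stationary_speed:
            j = i
            while j + 1 < n and speed[j + 1] >= stationary_speed:
                j += 1
            duration = (j - i) / rate
            disp = float(np.hypot(horizontal[j, 0] - horizontal[i, 0],
                                  horizontal[j, 1] - horizontal[i, 1]))
            if duration >= min_duration and disp >= min_displacement:
                events.append((i / rate, j / rate, disp))
            i = j + 1
        else:
            i += 1
    return events


@pytest.fixture
def static_recording() -> TrialRecording:
    return make_recording(600)


@pytest.fixture
def small_settings_overrides() -> dict:
    """Shrunk game settings for fast trials (chickens fit in short trials)."""
    return {"chickens_per_trial": 4}
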