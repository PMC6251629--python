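"""Running-speed estimation and run/rest state segmentation.

The analysis window is divided into periods of running (speed >= 7 cm/s)
and resting (speed < 0.5 cm/s, with each rest bout limited to its first
20 s); intermediate speeds belong to neither state.  Gamma-band measures
are made during running, ripple measures during rest.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Interval",
    "PositionTrace",
    "StateSegments",
    "VelocityTrace",
    "compute_velocity",
    "restrict_to_window",
    "segment_states",
]

RUN_MIN_CM_S = 7.0
REST_MAX_CM_S = 0.5
REST_CAP_S = 20.0
MIN_BOUT_S = 1.0


@dataclass(frozen=True)
class Interval:
    """Half-open labeled time interval [start_s, end_s)."""

    start_s: float
    end_s: float
    label: str

    def __post_init__(self) -> None:
        if not self.end_s > self.start_s:
            raise ValueError(f"empty interval [{self.start_s}, {self.end_s})")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PositionTrace:
    """Animal x/y position sampled at the tracking rate (nominally 30 Hz)."""

    time_s: np.ndarray
    x_cm: np.ndarray
    y_cm: np.ndarray
    rate: float = 30.0

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.x_cm = np.asarray(self.x_cm, dtype=np.float64)
        self.y_cm = np.asarray(self.y_cm, dtype=np.float64)
        if not (self.time_s.size == self.x_cm.size == self.y_cm.size):
            raise ValueError("time/x/y must have equal lengths")
        if self.rate <= 0:
            raise ValueError("tracking rate must be positive")
        if self.time_s.size >= 2 and np.any(np.diff(self.time_s) <= 0):
            raise ValueError("position timestamps must be strictly increasing")


@dataclass
class VelocityTrace:
    """Instantaneous speed on the position grid."""

    time_s: np.ndarray
    speed_cm_s: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=np.float64)
        self.speed_cm_s = np.asarray(self.speed_cm_s, dtype=np.float64)


@dataclass
class StateSegments:
    """Non-overlapping run/rest intervals with the thresholds that made them."""

    intervals: list[Interval]
    run_min_cm_s: float = RUN_MIN_CM_S
    rest_max_cm_s: float = REST_MAX_CM_S
    rest_cap_s: float = REST_CAP_S

    def __post_init__(self) -> None:
        ivs = sorted(self.intervals, key=lambda iv: iv.start_s)
        for a, b in zip(ivs, ivs[1:]):
            if b.start_s < a.end_s - 1e-9:
                raise ValueError(f"overlapping intervals {a} and {b}")
        self.intervals = ivs

    def by_label(self, label: str) -> list[Interval]:
        return [iv for iv in self.intervals if iv.label == label]

    def total_s(self, label: str | None = None) -> float:
        return sum(iv.duration_s for iv in self.intervals
                   if label is None or iv.label == label)


def compute_velocity(pos: PositionTrace, smooth_s: float = 0.5) -> VelocityTrace:
    """Speed from position: smooth x/y, then central finite differences.

    Position jitter from tracking (a few mm) turns into large spurious
    velocities at 30 Hz, so the coordinates are smoothed with a Gaussian
    kernel of full width ``smooth_s`` (sigma = smooth_s/4) before
    differentiating.  Boundary samples use one-sided differences.
    """
    if pos.time_s.size < 2:
        raise ValueError("need at least 2 position samples")
    if np.any(np.diff(pos.time_s) == 0):
        raise ValueError("duplicate position timestamps")
    sigma = max(smooth_s * pos.rate / 4.0, 1e-9)
    x = gaussian_filter1d(pos.x_cm, sigma, mode="nearest")
    y = gaussian_filter1d(pos.y_cm, sigma, mode="nearest")
    vx = np.gradient(x, pos.time_s)
    vy = np.gradient(y, pos.time_s)
    return VelocityTrace(time_s=pos.time_s.copy(),
                         speed_cm_s=np.hypot(vx, vy), rate=pos.rate)


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open index ranges of maximal True runs."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment_states(vel: VelocityTrace,
                   run_min_cm_s: float = RUN_MIN_CM_S,
                   rest_max_cm_s: float = REST_MAX_CM_S,
                   rest_cap_s: float = REST_CAP_S,
                   min_bout_s: float = MIN_BOUT_S) -> StateSegments:
    """Divide time into run (speed >= 7 cm/s) and rest (< 0.5 cm/s) bouts.

    Maximal supra/sub-threshold intervals at least ``min_bout_s`` long
    become segments; speeds between the two thresholds belong to neither
    state.  Each rest bout is truncated to its first ``rest_cap_s`` seconds
    (long immobility beyond 20 s may reflect sleep rather than quiet rest).
    A speed exactly at the run threshold counts as running.
    """
    if vel.time_s.size == 0:
        raise ValueError("empty velocity trace")
    if not rest_max_cm_s < run_min_cm_s:
        raise ValueError("rest_max_cm_s must be below run_min_cm_s")
    dt = 1.0 / vel.rate
    intervals: list[Interval] = []
    for label, mask in (("run", vel.speed_cm_s >= run_min_cm_s),
                        ("rest", vel.speed_cm_s < rest_max_cm_s)):
        for i0, i1 in _true_runs(mask):
            start = vel.time_s[i0]
            end = vel.time_s[i1 - 1] + dt
            if end - start < min_bout_s:
                continue
            if label == "rest" and end - start > rest_cap_s:
                end = start + rest_cap_s
            intervals.append(Interval(start, end, label))
    return StateSegments(intervals=intervals, run_min_cm_s=run_min_cm_s,
                         rest_max_cm_s=rest_max_cm_s, rest_cap_s=rest_cap_s)


def restrict_to_window(segments: StateSegments,
                       window: tuple[float, float]) -> StateSegments:
    """Clip segments to a half-open analysis window [start, end).

    Typically the 30-60 min post-treatment window; an empty result is valid.
    """
    w0, w1 = window
    if not w1 > w0:
        raise ValueError(f"invalid analysis window [{w0}, {w1})")
    clipped = [
        Interval(max(iv.start_s, w0), min(iv.end_s, w1), iv.label)
        for iv in segments.intervals
        if min(iv.end_s, w1) - max(iv.start_s, w0) > 1e-12
    ]
    return StateSegments(intervals=clipped,
                         run_min_cm_s=segments.run_min_cm_s,
                         rest_max_cm_s=segments.rest_max_cm_s,
                         rest_cap_s=segments.rest_cap_s)
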