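"""Sharp-wave ripple detection from the pyramidal-layer LFP during rest.

Detection pipeline on the z-scored rest-state signal: 60/180 Hz notch ->
order-69 zero-phase FIR band-pass 100-300 Hz -> Hilbert envelope -> 50-ms
moving-average smoothing -> threshold at (envelope mean + 3 SD), with the
mean/SD computed once over all analyzed rest samples.  Supra-threshold
excursions longer than 30 ms become candidate events; a candidate starting
within 200 ms of the previous accepted event's offset is excluded, and
events touching bout edges (where the envelope is filter-contaminated)
are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

from lfpkit.conditioning import StateSignal, notch_array

__all__ = ["RippleEvent", "RippleParams", "RippleStats", "detect_ripples",
           "ripple_stats"]

log = logging.getLogger("lfpkit.ripples")


@dataclass(frozen=True)
class RippleParams:
    notch_freqs: tuple[float, ...] = (60.0, 180.0)
    band_low_hz: float = 100.0
    band_high_hz: float = 300.0
    fir_order: int = 69
    smooth_window_ms: float = 50.0
    threshold_sd: float = 3.0
    min_duration_ms: float = 30.0
    refractory_ms: float = 200.0
    edge_margin_ms: float = 100.0

    def __post_init__(self) -> None:
        if not (0 < self.band_low_hz < self.band_high_hz):
            raise ValueError("invalid ripple band")
        for name in ("fir_order", "smooth_window_ms", "threshold_sd",
                     "min_duration_ms", "refractory_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class RippleEvent:
    onset_s: float
    offset_s: float
    peak_s: float
    amplitude_sd: float  # peak smoothed-envelope height in SD units above the mean

    def __post_init__(self) -> None:
        if not (self.onset_s < self.peak_s <= self.offset_s):
            raise ValueError("ripple event must satisfy onset < peak <= offset")

    @property
    def duration_ms(self) -> float:
        return (self.offset_s - self.onset_s) * 1000.0


@dataclass
class RippleStats:
    event_rate_hz: float
    mean_amplitude_sd: float  # NaN when no events
    n_events: int
    analyzed_time_s: float


def _ripple_envelope(piece: np.ndarray, rate: float, p: RippleParams) -> np.ndarray:
    """Notch -> zero-phase FIR band-pass -> Hilbert envelope -> 50-ms smoothing."""
    if p.band_high_hz >= rate / 2.0:
        raise ValueError("ripple band reaches Nyquist; sampling rate too low")
    y = notch_array(piece, rate, p.notch_freqs)
    taps = sps.firwin(p.fir_order + 1, [p.band_low_hz, p.band_high_hz],
                      fs=rate, pass_zero=False)
    y = sps.filtfilt(taps, [1.0], y)
    env = np.abs(sps.hilbert(y))
    win = max(1, int(round(p.smooth_window_ms * rate / 1000.0)))
    return uniform_filter1d(env, win, mode="reflect")


def detect_ripples(rest: StateSignal, params: RippleParams | None = None
                   ) -> list[RippleEvent]:
    """Detect ripple events in the z-scored rest-state LFP.

    The threshold statistics are computed once over the concatenated
    envelope of all rest bouts (not per bout), which stabilizes the
    operating point when individual bouts are short.

    Raises
    ------
    ValueError
        If less than 10 s of rest data is available (threshold unstable).
    """
    p = params or RippleParams()
    if rest.total_s < 10.0:
        raise ValueError(
            f"only {rest.total_s:.1f} s of rest data; need >= 10 s for a "
            "stable ripple threshold"
        )
    rate = rest.rate
    envs = [_ripple_envelope(piece, rate, p) for piece in rest.pieces]
    allenv = np.concatenate(envs)
    mu = float(allenv.mean())
    sd = float(allenv.std())
    thr = mu + p.threshold_sd * sd
    min_len = p.min_duration_ms / 1000.0
    margin = int(round(p.edge_margin_ms * rate / 1000.0))

    candidates: list[RippleEvent] = []
    n_edge_dropped = 0
    for env, t0 in zip(envs, rest.piece_starts_s):
        above = env > thr
        padded = np.concatenate(([False], above, [False]))
        d = np.diff(padded.astype(np.int8))
        for i0, i1 in zip(np.flatnonzero(d == 1), np.flatnonzero(d == -1)):
            if (i1 - i0) / rate <= min_len:
                continue
            if i0 < margin or i1 > env.size - margin:
                n_edge_dropped += 1
                continue
            k = i0 + int(np.argmax(env[i0:i1]))
            candidates.append(RippleEvent(
                onset_s=t0 + i0 / rate,
                offset_s=t0 + i1 / rate,
                peak_s=t0 + k / rate,
                amplitude_sd=(float(env[k]) - mu) / sd,
            ))
    if n_edge_dropped:
        log.info("dropped %d candidate ripple(s) overlapping bout-edge margins",
                 n_edge_dropped)
    candidates.sort(key=lambda e: e.onset_s)
    accepted: list[RippleEvent] = []
    for ev in candidates:
        if accepted and ev.onset_s - accepted[-1].offset_s < p.refractory_ms / 1000.0:
            continue
        accepted.append(ev)
    return accepted


def ripple_stats(events: list[RippleEvent], analyzed_time_s: float) -> RippleStats:
    """Event rate over the analyzed rest time and mean event amplitude.

    An empty event list gives rate 0 with amplitude NaN (undefined).
    """
    if analyzed_time_s <= 0:
        raise ValueError("analyzed rest time must be positive")
    n = len(events)
    amp = float(np.mean([e.amplitude_sd for e in events])) if n else float("nan")
    return RippleStats(event_rate_hz=n / analyzed_time_s, mean_amplitude_sd=amp,
                       n_events=n, analyzed_time_s=float(analyzed_time_s))
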