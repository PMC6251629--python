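"""Putative pyramidal-cell vs interneuron classification of sorted units.

Criteria: pyramidal cells have broad waveforms (peak-to-valley spike width
> 300 us), low baseline firing rates (< 5 Hz), and bursty autocorrelograms
(peak within 10 ms); narrow, fast-firing units are putative interneurons.
Units meeting neither full set of criteria stay unclassified.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeTrain", "UnitClass", "classify_unit", "firing_rate_timecourse"]

SPIKE_WIDTH_US = 300.0
RATE_HZ = 5.0
BURST_LAG_MS = 10.0
MIN_SPIKES = 50


@dataclass
class SpikeTrain:
    """Sorted spike times plus the unit's mean waveform."""

    spike_times_s: np.ndarray
    waveform: np.ndarray          # mean spike shape, largest-amplitude electrode
    waveform_rate: float          # waveform sample rate, Hz
    baseline_interval: tuple[float, float] = (0.0, np.inf)

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=np.float64)
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.spike_times_s.size >= 2 and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError("spike times must be strictly increasing")


@dataclass
class UnitClass:
    label: str                     # pyramidal | interneuron | unclassified
    spike_width_us: float
    mean_rate_hz: float
    burst_lag_ms: float            # lag of the autocorrelogram peak
    reason: str = ""


def _spike_width_us(waveform: np.ndarray, rate: float) -> float:
    """Peak-to-valley width: time from the waveform peak to the following valley."""
    i_peak = int(np.argmax(waveform))
    after = waveform[i_peak:]
    if after.size < 2:
        return 0.0
    i_valley = i_peak + int(np.argmin(after))
    return (i_valley - i_peak) / rate * 1e6


def autocorrelogram(times: np.ndarray, bin_ms: float = 1.0,
                    max_lag_ms: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Spike-time autocorrelogram on positive lags (1-ms bins to +-50 ms)."""
    edges = np.arange(0.0, max_lag_ms + bin_ms, bin_ms) / 1000.0
    counts = np.zeros(edges.size - 1)
    max_lag = edges[-1]
    j = 0
    for i in range(times.size):
        for j in range(i + 1, times.size):
            d = times[j] - times[i]
            if d > max_lag:
                break
            counts[min(int(d / (bin_ms / 1000.0)), counts.size - 1)] += 1
    centers = (edges[:-1] + edges[1:]) / 2.0 * 1000.0
    return centers, counts


def _burst_lag_ms(times: np.ndarray, refractory_ms: float = 1.5) -> float:
    """Lag of the autocorrelogram's global peak, excluding refractory bins."""
    centers, counts = autocorrelogram(times)
    valid = centers >= refractory_ms
    if not counts[valid].any():
        return np.inf
    c = counts.copy()
    c[~valid] = -1.0
    return float(centers[int(np.argmax(c))])


def classify_unit(train: SpikeTrain) -> UnitClass:
    """Classify a unit by spike width, baseline rate, and burstiness.

    Classification is deterministic and invariant to waveform amplitude
    scaling (widths are measured on extrema positions only).
    """
    b0, b1 = train.baseline_interval
    t = train.spike_times_s
    in_base = t[(t >= b0) & (t < b1)]
    width = _spike_width_us(train.waveform, train.waveform_rate)
    if in_base.size < MIN_SPIKES:
        return UnitClass("unclassified", width, float("nan"), float("nan"),
                         reason=f"only {in_base.size} baseline spikes (<{MIN_SPIKES})")
    span = (min(b1, float(t[-1])) - b0) if np.isinf(b1) else (b1 - b0)
    rate = in_base.size / span if span > 0 else float("inf")
    burst = _burst_lag_ms(in_base)
    if width > SPIKE_WIDTH_US and rate < RATE_HZ and burst <= BURST_LAG_MS:
        label = "pyramidal"
    elif width <= SPIKE_WIDTH_US and rate >= RATE_HZ:
        label = "interneuron"
    else:
        label = "unclassified"
    return UnitClass(label, width, rate, burst)


def firing_rate_timecourse(train: SpikeTrain, bin_s: float,
                           t_start: float = 0.0,
                           t_end: float | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Firing rate per time bin (spike count / bin width), in Hz."""
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    t = train.spike_times_s
    if t_end is None:
        t_end = float(t[-1]) if t.size else t_start + bin_s
    edges = np.arange(t_start, t_end + bin_s, bin_s)
    counts, _ = np.histogram(t, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return centers, counts / bin_s
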