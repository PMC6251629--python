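"""Signal containers, per-state z-scoring, zero-phase filtering, analytic signal.

Every downstream stage (spectra, coupling, coherence, ripples) consumes the
outputs of this module.  Conventions:

* times are seconds from session start, double precision;
* band filters are zero-phase (forward-backward), so filtered traces stay
  peak-aligned with the raw LFP;
* per-state z-scoring normalizes each behavioral state's concatenated
  samples with that subset's own mean/SD, which makes power comparable
  across sessions recorded days apart at the cost of absolute units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

__all__ = [
    "BANDS",
    "AnalyticSignal",
    "BandDefinition",
    "LfpSignal",
    "StateSignal",
    "analytic",
    "bandpass_array",
    "bandpass_zero_phase",
    "notch",
    "notch_array",
    "zscore_by_state",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, 0 < low < high."""

    name: str
    low_hz: float
    high_hz: float

    def __post_init__(self) -> None:
        if not (0.0 < self.low_hz < self.high_hz):
            raise ValueError(f"invalid band {self.name}: {self.low_hz}-{self.high_hz} Hz")

    def check_rate(self, rate: float) -> None:
        if self.high_hz >= rate / 2.0:
            raise ValueError(
                f"band {self.name} ({self.low_hz}-{self.high_hz} Hz) exceeds "
                f"Nyquist for rate {rate} Hz"
            )


#: Canonical analysis bands.  The coupling analysis uses a slightly narrower
#: low-gamma band (30-55 Hz) than the power/coherence analyses (30-60 Hz).
BANDS: dict[str, BandDefinition] = {
    "theta": BandDefinition("theta", 5.0, 10.0),
    "low_gamma": BandDefinition("low_gamma", 30.0, 60.0),
    "high_gamma": BandDefinition("high_gamma", 65.0, 100.0),
    "cfc_low_gamma": BandDefinition("cfc_low_gamma", 30.0, 55.0),
    "ripple": BandDefinition("ripple", 100.0, 300.0),
}


@dataclass
class LfpSignal:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    samples
        Voltage samples (microvolts for raw data, unitless after z-scoring).
    rate
        Sampling rate in Hz.
    role
        Which electrode the trace comes from: ``"hpc"`` (hippocampal
        pyramidal layer) or ``"pfc"`` (prefrontal cortex).
    start_time_s
        Session time of the first sample.
    """

    samples: np.ndarray
    rate: float
    role: str = "hpc"
    start_time_s: float = 0.0
    units: str = "uV"
    zscored: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("LfpSignal samples must be one-dimensional")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.role not in ("hpc", "pfc"):
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    def times(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.n_samples) / self.rate


@dataclass
class StateSignal:
    """Z-scored LFP samples from one behavioral state.

    The samples of all same-state bouts are concatenated for statistics,
    but the bout structure is retained (``pieces``): filtering and
    windowed spectral estimation must never cross a concatenation seam,
    because adjacent bouts are not contiguous in time.
    """

    label: str
    pieces: list[np.ndarray]
    piece_starts_s: list[float]
    rate: float
    role: str = "hpc"

    @property
    def samples(self) -> np.ndarray:
        if not self.pieces:
            return np.empty(0)
        return np.concatenate(self.pieces)

    @property
    def total_s(self) -> float:
        return sum(p.size for p in self.pieces) / self.rate

    def map_pieces(self, fn) -> "StateSignal":
        """Apply ``fn(array) -> array`` independently to every bout."""
        return StateSignal(
            label=self.label,
            pieces=[fn(p) for p in self.pieces],
            piece_starts_s=list(self.piece_starts_s),
            rate=self.rate,
            role=self.role,
        )


@dataclass
class AnalyticSignal:
    """Envelope/phase of a band-limited trace via the Hilbert transform.

    ``edge_valid`` is False within the edge margin (default 100 ms) where
    the analytic extension is contaminated by boundary effects.
    """

    envelope: np.ndarray
    phase: np.ndarray
    rate: float
    band: BandDefinition | None = None
    edge_valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.edge_valid is None:
            self.edge_valid = np.ones(self.envelope.size, dtype=bool)


def _segment_sample_bounds(start_s: float, end_s: float, rate: float,
                           origin_s: float = 0.0) -> tuple[int, int]:
    """Half-open [start, end) interval -> sample index range, rounded inward."""
    i0 = int(np.ceil(round((start_s - origin_s) * rate, 9)))
    i1 = int(np.floor(round((end_s - origin_s) * rate, 9)))
    return i0, i1


def zscore_by_state(lfp: LfpSignal, segments) -> dict[str, StateSignal]:
    """Z-score the LFP separately within each behavioral state.

    For every state label present in ``segments``, the within-state samples
    are concatenated and transformed to mean 0, SD 1 using that subset's own
    statistics; the bout-aligned pieces are preserved.

    Raises
    ------
    ValueError
        If a state's concatenated samples are shorter than 1 s or have zero
        variance.
    """
    out: dict[str, StateSignal] = {}
    for label in sorted({iv.label for iv in segments.intervals}):
        pieces: list[np.ndarray] = []
        starts: list[float] = []
        for iv in segments.intervals:
            if iv.label != label:
                continue
            i0, i1 = _segment_sample_bounds(iv.start_s, iv.end_s, lfp.rate,
                                            lfp.start_time_s)
            i0 = max(i0, 0)
            i1 = min(i1, lfp.n_samples)
            if i1 - i0 < 2:
                continue
            pieces.append(lfp.samples[i0:i1])
            starts.append(lfp.start_time_s + i0 / lfp.rate)
        if not pieces:
            continue
        concat = np.concatenate(pieces)
        if concat.size < lfp.rate:
            raise ValueError(
                f"state {label!r} has only {concat.size / lfp.rate:.2f} s of "
                "data; need at least 1 s to z-score"
            )
        mu = concat.mean()
        sd = concat.std()
        if sd == 0:
            raise ValueError(f"state {label!r} samples have zero variance")
        out[label] = StateSignal(
            label=label,
            pieces=[(p - mu) / sd for p in pieces],
            piece_starts_s=starts,
            rate=lfp.rate,
            role=lfp.role,
        )
    return out


def bandpass_array(x: np.ndarray, band: BandDefinition, rate: float,
                   order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass (forward-backward squared magnitude).

    The 4th-order Butterworth response is applied as ``|H(f)|^2`` in the
    frequency domain on a reflect-padded copy of the signal: this is the
    exact forward-backward (filtfilt) response with no residual edge
    transient asymmetry, so the output is strictly zero-phase, strictly
    linear, and commutes with time reversal.
    """
    band.check_rate(rate)
    x = np.asarray(x, dtype=np.float64)
    sos = sps.butter(order, [band.low_hz, band.high_hz], btype="bandpass",
                     fs=rate, output="sos")
    # reflect-pad by ~3 cycles of the band's low edge to kill wraparound
    pad = min(x.size - 1, int(round(3.0 * rate / band.low_hz)))
    xp = np.pad(x, pad, mode="reflect") if pad > 0 else x
    freqs = np.fft.rfftfreq(xp.size, 1.0 / rate)
    _, h = sps.sosfreqz(sos, worN=freqs, fs=rate)
    y = np.fft.irfft(np.fft.rfft(xp) * (np.abs(h) ** 2), n=xp.size)
    return y[pad:pad + x.size] if pad > 0 else y


def bandpass_zero_phase(lfp: LfpSignal, band: BandDefinition | str,
                        order: int = 4) -> LfpSignal:
    """Band-pass an LFP with zero group delay.

    A 4th-order Butterworth applied forward and backward (effective 8th
    order, squared magnitude response), so narrowband components stay
    peak-aligned with the input.
    """
    if isinstance(band, str):
        band = BANDS[band]
    return replace(lfp, samples=bandpass_array(lfp.samples, band, lfp.rate, order))


def notch_array(x: np.ndarray, rate: float, freqs=(60.0, 180.0),
                q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at each frequency (line noise and harmonic)."""
    y = np.asarray(x, dtype=np.float64)
    for f0 in freqs:
        if f0 >= rate / 2:
            raise ValueError(f"notch frequency {f0} Hz at or above Nyquist")
        b, a = sps.iirnotch(f0, q, fs=rate)
        y = sps.filtfilt(b, a, y)
    return y


def notch(lfp: LfpSignal, freqs=(60.0, 180.0), q: float = 30.0) -> LfpSignal:
    """Remove line noise (60 Hz and its 180 Hz harmonic) with zero-phase notches."""
    return replace(lfp, samples=notch_array(lfp.samples, lfp.rate, freqs, q))


def analytic(x: np.ndarray | LfpSignal, rate: float | None = None,
             band: BandDefinition | None = None,
             edge_ms: float = 100.0) -> AnalyticSignal:
    """Envelope and instantaneous phase of a band-limited signal.

    The first and last ``edge_ms`` milliseconds are flagged edge-invalid;
    downstream consumers (coupling, phase-lag, ripple detection) must not
    use samples there.
    """
    if isinstance(x, LfpSignal):
        rate = x.rate
        x = x.samples
    if rate is None:
        raise ValueError("rate is required for array input")
    z = sps.hilbert(np.asarray(x, dtype=np.float64))
    margin = int(round(edge_ms * rate / 1000.0))
    valid = np.ones(z.size, dtype=bool)
    if margin > 0:
        valid[:margin] = False
        valid[z.size - margin:] = False
    return AnalyticSignal(envelope=np.abs(z), phase=np.angle(z), rate=rate,
                          band=band, edge_valid=valid)
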