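"""Multitaper power spectral estimation and peak band power.

Spectra are estimated with 5 DPSS tapers (time-bandwidth NW = 3, the
K = 2NW - 1 convention) on 2-s windows with 50% overlap inside each
behavioral bout; bouts shorter than a window but at least 1 s long are
analyzed whole with tapers re-fit to their length.  Because input traces
are z-scored per state, power is in arbitrary units; the integral of the
spectrum over [0, Nyquist] equals the signal variance (one for z-scored
input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import windows

from lfpkit.conditioning import BandDefinition, StateSignal

__all__ = [
    "PeakPower",
    "PowerSpectrum",
    "multitaper_psd",
    "peak_band_power",
    "smooth_spectrum",
    "spectrogram",
]

DEFAULT_WINDOW_S = 2.0
DEFAULT_OVERLAP = 0.5
MIN_WINDOW_S = 1.0


@dataclass
class PowerSpectrum:
    freqs_hz: np.ndarray
    power: np.ndarray
    n_tapers: int
    time_bandwidth: float
    n_windows: int
    rate: float

    @property
    def df(self) -> float:
        return float(self.freqs_hz[1] - self.freqs_hz[0])

    def integral(self, low_hz: float | None = None,
                 high_hz: float | None = None) -> float:
        """Riemann integral of power over [low, high] (defaults: full range)."""
        m = np.ones(self.freqs_hz.size, dtype=bool)
        if low_hz is not None:
            m &= self.freqs_hz >= low_hz
        if high_hz is not None:
            m &= self.freqs_hz <= high_hz
        return float(self.power[m].sum() * self.df)


@dataclass
class PeakPower:
    band: BandDefinition
    peak_power: float
    peak_freq_hz: float


def _taper_psd(seg: np.ndarray, rate: float, n_tapers: int,
               nw: float, n_out: int) -> np.ndarray:
    """Average one-sided PSD over DPSS tapers for one window, on an
    ``n_out``-point rfft grid (zero-padded/evaluated at the standard grid
    length when the segment is shorter)."""
    m = seg.size
    tapers = windows.dpss(m, nw, Kmax=n_tapers)  # rows have unit energy
    # zero-padding to the common grid changes resolution, not total power
    spec = np.fft.rfft(tapers * seg[None, :], n=max(m, 2 * (n_out - 1)), axis=1)
    psd = (np.abs(spec) ** 2).mean(axis=0) / rate
    # one-sided scaling: double everything except DC and Nyquist
    psd[1:-1] *= 2.0
    return psd[:n_out]


def _gather_windows(pieces: list[np.ndarray], rate: float, window_s: float,
                    overlap: float, min_window_s: float) -> list[np.ndarray]:
    nwin = int(round(window_s * rate))
    nmin = int(round(min_window_s * rate))
    step = max(1, int(round(nwin * (1.0 - overlap))))
    out: list[np.ndarray] = []
    for p in pieces:
        if p.size >= nwin:
            for i0 in range(0, p.size - nwin + 1, step):
                out.append(p[i0:i0 + nwin])
        elif p.size >= nmin:
            out.append(p)
    return out


def multitaper_psd(x: StateSignal | np.ndarray | list[np.ndarray],
                   rate: float | None = None,
                   n_tapers: int = 5,
                   window_s: float = DEFAULT_WINDOW_S,
                   overlap: float = DEFAULT_OVERLAP,
                   min_window_s: float = MIN_WINDOW_S) -> PowerSpectrum:
    """Multitaper PSD averaged over tapers and windows, duration-weighted.

    Accepts a :class:`StateSignal` (windows never cross bout seams), a
    single array, or a list of arrays (one per bout).

    Raises
    ------
    ValueError
        If no bout is at least ``min_window_s`` long.
    """
    if isinstance(x, StateSignal):
        pieces = x.pieces
        rate = x.rate
    elif isinstance(x, np.ndarray):
        pieces = [np.asarray(x, dtype=np.float64)]
    else:
        pieces = [np.asarray(p, dtype=np.float64) for p in x]
    if rate is None:
        raise ValueError("rate is required for array input")
    if n_tapers < 1:
        raise ValueError("need at least one taper")
    nw = (n_tapers + 1) / 2.0  # K = 2NW - 1
    segs = _gather_windows(pieces, rate, window_s, overlap, min_window_s)
    if not segs:
        raise ValueError(
            f"no segment is at least {min_window_s} s long; cannot estimate PSD"
        )
    nwin = int(round(window_s * rate))
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate)
    acc = np.zeros(freqs.size)
    wsum = 0.0
    for seg in segs:
        w = seg.size / rate
        acc += w * _taper_psd(seg, rate, n_tapers, nw, freqs.size)
        wsum += w
    return PowerSpectrum(freqs_hz=freqs, power=acc / wsum, n_tapers=n_tapers,
                         time_bandwidth=nw, n_windows=len(segs), rate=rate)


def smooth_spectrum(spec: PowerSpectrum, bw_hz: float = 1.0) -> PowerSpectrum:
    """Moving-average smoothing over ``bw_hz``; conserves integrated power.

    Reflective edge handling keeps a constant spectrum exactly unchanged.
    """
    if bw_hz < spec.df:
        raise ValueError("smoothing bandwidth below frequency resolution")
    nbins = max(1, int(round(bw_hz / spec.df)))
    nbins += 1 - nbins % 2  # centered (odd) kernel
    return PowerSpectrum(freqs_hz=spec.freqs_hz.copy(),
                         power=uniform_filter1d(spec.power, nbins, mode="reflect"),
                         n_tapers=spec.n_tapers,
                         time_bandwidth=spec.time_bandwidth,
                         n_windows=spec.n_windows, rate=spec.rate)


def peak_band_power(spec: PowerSpectrum, band: BandDefinition) -> PeakPower:
    """Maximum power within the band and its frequency (ties -> lowest freq)."""
    m = (spec.freqs_hz >= band.low_hz) & (spec.freqs_hz <= band.high_hz)
    if not m.any():
        raise ValueError(f"band {band.name} outside the spectrum's grid")
    idx = np.flatnonzero(m)
    k = idx[np.argmax(spec.power[idx])]
    return PeakPower(band=band, peak_power=float(spec.power[k]),
                     peak_freq_hz=float(spec.freqs_hz[k]))


def spectrogram(x: np.ndarray, rate: float, window_s: float = 2.0,
                step_s: float = 0.5, n_tapers: int = 5
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sliding-window multitaper spectrogram (report figures only).

    Returns ``(times_s, freqs_hz, power)`` with ``power`` shaped
    (n_freqs, n_windows); window times are window centers.
    """
    if step_s > window_s:
        raise ValueError("step must not exceed window length")
    x = np.asarray(x, dtype=np.float64)
    nwin = int(round(window_s * rate))
    step = int(round(step_s * rate))
    if x.size < nwin:
        raise ValueError("signal shorter than one window")
    nw = (n_tapers + 1) / 2.0
    freqs = np.fft.rfftfreq(nwin, 1.0 / rate)
    starts = range(0, x.size - nwin + 1, step)
    cols = [_taper_psd(x[i0:i0 + nwin], rate, n_tapers, nw, freqs.size)
            for i0 in starts]
    times = np.array([(i0 + nwin / 2.0) / rate for i0 in starts])
    return times, freqs, np.column_stack(cols) if cols else np.empty((freqs.size, 0))
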