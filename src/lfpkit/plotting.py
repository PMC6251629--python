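"""Report figures: PSD overlays, spectrograms, ripple rasters.

Figures are side effects of the pipeline, never inputs to any metric.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from lfpkit.ripples import RippleEvent
from lfpkit.spectral import PowerSpectrum

__all__ = ["plot_psd_overlay", "plot_ripple_raster", "plot_spectrogram"]


def plot_psd_overlay(specs: dict[str, PowerSpectrum], path: str | Path,
                     fmax_hz: float = 100.0) -> Path:
    """Overlay per-state (or per-condition) power spectra up to ``fmax_hz``."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, spec in specs.items():
        m = spec.freqs_hz <= fmax_hz
        ax.semilogy(spec.freqs_hz[m], np.maximum(spec.power[m], 1e-12),
                    label=label, lw=1.2)
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power (a.u.)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_spectrogram(times_s: np.ndarray, freqs_hz: np.ndarray,
                     power: np.ndarray, path: str | Path,
                     fmax_hz: float = 100.0) -> Path:
    """Time-frequency power (log scale), as in session overview figures."""
    m = freqs_hz <= fmax_hz
    fig, ax = plt.subplots(figsize=(6, 3))
    pm = ax.pcolormesh(times_s, freqs_hz[m],
                       10 * np.log10(np.maximum(power[m], 1e-12)),
                       shading="auto", cmap="magma")
    fig.colorbar(pm, ax=ax, label="power (dB)")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_ripple_raster(events_by_session: dict[str, list[RippleEvent]],
                       path: str | Path) -> Path:
    """One row per session; a tick at each ripple peak time."""
    fig, ax = plt.subplots(figsize=(6, 0.6 + 0.4 * len(events_by_session)))
    labels = list(events_by_session)
    for i, label in enumerate(labels):
        peaks = [e.peak_s for e in events_by_session[label]]
        ax.eventplot(peaks, lineoffsets=i, linelengths=0.8, color="k")
    ax.set_yticks(range(len(labels)), labels)
    ax.set_xlabel("time (s)")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
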