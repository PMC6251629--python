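"""Readers/writers for the package's native formats, session config, logging.

Native formats (language-agnostic, diffable metadata):

* LFP signals: little-endian float32 ``.bin`` with a JSON sidecar
  (``<name>.json``) carrying rate, start time, units, and channel role;
  a plain two-column ``t,v`` CSV is also accepted for small traces.
* Positions: CSV with columns ``time_s,x_cm,y_cm``.
* Ripple events: CSV with columns
  ``onset_s,offset_s,peak_s,amplitude_sd,duration_ms``.
* Session config: YAML or JSON mirroring :class:`SessionConfig`.
* Ground truth and results: JSON.

All times are seconds from session start; intervals are half-open.
Round trips preserve full float precision.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lfpkit.behavior import PositionTrace
from lfpkit.conditioning import LfpSignal
from lfpkit.ripples import RippleEvent

__all__ = [
    "FormatError",
    "SessionConfig",
    "ValidationError",
    "get_logger",
    "load_config",
    "read_events",
    "read_position",
    "read_signal",
    "write_events",
    "write_position",
    "write_signal",
]

EVENT_COLUMNS = ["onset_s", "offset_s", "peak_s", "amplitude_sd", "duration_ms"]


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(ValueError):
    """A file parses but its contents are internally inconsistent."""


def get_logger(stage: str) -> logging.Logger:
    """Stage-scoped logger with ``timestamp stage message`` lines."""
    logger = logging.getLogger(f"lfpkit.{stage}")
    if not logging.getLogger("lfpkit").handlers:
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
        logging.getLogger("lfpkit").addHandler(h)
    return logger


@dataclass(frozen=True)
class SessionConfig:
    """Experiment metadata plus the analysis window for one session."""

    session_id: str
    genotype: str = "cre_pos"             # cre_pos | cre_neg
    treatment: str = "vehicle"            # vehicle | cno
    dose_mg_per_kg: float = 0.0
    analysis_window_s: tuple[float, float] = (1800.0, 3600.0)
    channel_roles: dict = field(default_factory=lambda: {"ch0": "hpc"})
    sampling_rate_lfp: float = 1000.0
    sampling_rate_pos: float = 30.0

    def __post_init__(self) -> None:
        if self.genotype not in ("cre_pos", "cre_neg"):
            raise ValidationError(f"unknown genotype {self.genotype!r}")
        if self.treatment not in ("vehicle", "cno"):
            raise ValidationError(f"unknown treatment {self.treatment!r}")
        if self.dose_mg_per_kg < 0:
            raise ValidationError("dose must be non-negative")
        w0, w1 = self.analysis_window_s
        if not w0 < w1:
            raise ValidationError("analysis window start must precede its end")
        # ripple band tops out at 300 Hz -> need > 600 Hz sampling
        if self.sampling_rate_lfp < 600.0:
            raise ValidationError(
                "LFP rate below 600 Hz cannot support ripple-band analysis")
        for ch, role in self.channel_roles.items():
            if role not in ("hpc", "pfc"):
                raise ValidationError(f"channel {ch}: unknown role {role!r}")


def load_config(path: str | Path) -> SessionConfig:
    """Load a YAML/JSON session config."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "session_id" not in data:
        raise FormatError(f"{path}: not a session config (missing session_id)")
    if "analysis_window_s" in data:
        data["analysis_window_s"] = tuple(data["analysis_window_s"])
    try:
        return SessionConfig(**data)
    except TypeError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# signals

_REQUIRED_HEADER = ("rate", "n_samples", "start_time_s", "units", "role")


def write_signal(lfp: LfpSignal, path: str | Path) -> Path:
    """Write an LFP trace (float32 .bin + JSON sidecar, or CSV)."""
    path = Path(path)
    if path.suffix == ".csv":
        t = lfp.times()
        with open(path, "w") as fh:
            fh.write("t,v\n")
            for ti, vi in zip(t, lfp.samples):
                fh.write(f"{float(ti)!r},{float(vi)!r}\n")
        return path
    path.write_bytes(lfp.samples.astype("<f4").tobytes())
    header = {
        "rate": lfp.rate,
        "n_samples": int(lfp.n_samples),
        "start_time_s": lfp.start_time_s,
        "units": lfp.units,
        "role": lfp.role,
        "zscored": lfp.zscored,
        "dtype": "<f4",
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))
    return path


def read_signal(path: str | Path, channel: str | None = None) -> LfpSignal:
    """Read an LFP trace written by :func:`write_signal`.

    Raises :class:`FormatError` on missing header fields and
    :class:`ValidationError` on NaN samples or sample-count mismatches.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".csv":
        df = pd.read_csv(path, float_precision="round_trip")
        if list(df.columns) != ["t", "v"]:
            raise FormatError(f"{path}: expected columns t,v")
        t = df["t"].to_numpy(dtype=np.float64)
        if t.size < 2:
            raise FormatError(f"{path}: need at least 2 samples")
        dts = np.diff(t)
        if np.any(dts <= 0):
            raise ValidationError(f"{path}: non-monotonic timestamps")
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ValidationError(f"{path}: non-uniform sampling")
        samples = df["v"].to_numpy(dtype=np.float64)
        _check_nan(samples, path)
        return LfpSignal(samples=samples, rate=1.0 / dts[0],
                         start_time_s=float(t[0]),
                         role=channel or "hpc")
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar.name}")
    header = json.loads(sidecar.read_text())
    missing = [k for k in _REQUIRED_HEADER if k not in header]
    if missing:
        raise FormatError(f"{path}: header missing fields {missing}")
    samples = np.frombuffer(path.read_bytes(),
                            dtype=header.get("dtype", "<f4")).astype(np.float64)
    if samples.size != header["n_samples"]:
        raise ValidationError(
            f"{path}: header declares {header['n_samples']} samples but file "
            f"holds {samples.size}")
    _check_nan(samples, path)
    return LfpSignal(samples=samples, rate=float(header["rate"]),
                     role=header["role"], start_time_s=float(header["start_time_s"]),
                     units=header["units"], zscored=bool(header.get("zscored", False)))


def _check_nan(samples: np.ndarray, path: Path) -> None:
    bad = np.flatnonzero(~np.isfinite(samples))
    if bad.size:
        shown = ", ".join(map(str, bad[:10]))
        raise ValidationError(
            f"{path}: {bad.size} non-finite sample(s) at indices [{shown}"
            + ("...]" if bad.size > 10 else "]"))


# ---------------------------------------------------------------------------
# positions

def write_position(pos: PositionTrace, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("time_s,x_cm,y_cm\n")
        for t, x, y in zip(pos.time_s, pos.x_cm, pos.y_cm):
            fh.write(f"{float(t)!r},{float(x)!r},{float(y)!r}\n")
    return path


def read_position(path: str | Path) -> PositionTrace:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != ["time_s", "x_cm", "y_cm"]:
        raise FormatError(f"{path}: expected columns time_s,x_cm,y_cm")
    t = df["time_s"].to_numpy(dtype=np.float64)
    if t.size >= 2 and np.any(np.diff(t) <= 0):
        raise ValidationError(f"{path}: non-monotonic timestamps")
    rate = 1.0 / float(np.median(np.diff(t))) if t.size >= 2 else 30.0
    return PositionTrace(time_s=t, x_cm=df["x_cm"].to_numpy(np.float64),
                         y_cm=df["y_cm"].to_numpy(np.float64), rate=rate)


# ---------------------------------------------------------------------------
# ripple events

def write_events(events: list[RippleEvent], path: str | Path) -> Path:
    """Write time-sorted ripple events as CSV; errors on unsorted input."""
    onsets = [e.onset_s for e in events]
    if any(b < a for a, b in zip(onsets, onsets[1:])):
        raise ValidationError("events must be sorted by onset time")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(",".join(EVENT_COLUMNS) + "\n")
        for e in events:
            fh.write(f"{float(e.onset_s)!r},{float(e.offset_s)!r},"
                     f"{float(e.peak_s)!r},{float(e.amplitude_sd)!r},"
                     f"{float(e.duration_ms)!r}\n")
    return path


def read_events(path: str | Path) -> list[RippleEvent]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns) != EVENT_COLUMNS:
        raise FormatError(f"{path}: expected columns {EVENT_COLUMNS}")
    return [RippleEvent(onset_s=r.onset_s, offset_s=r.offset_s, peak_s=r.peak_s,
                        amplitude_sd=r.amplitude_sd)
            for r in df.itertuples()]
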