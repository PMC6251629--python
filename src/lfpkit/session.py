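"""Per-session orchestration and vehicle-vs-treatment comparison.

``analyze_session`` runs the full pipeline on one session: velocity and
run/rest segmentation inside the analysis window, per-state z-scoring,
multitaper peak band powers (theta / low-gamma / high-gamma), theta-phase
low-gamma-amplitude coupling during running, hippocampal-prefrontal
coherence and phase lag when a PFC channel is present, and ripple
detection during rest.  ``compare_conditions`` reduces paired results to
per-metric ratios and signed differences; it deliberately computes no
hypothesis tests (effect sizes only).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

import lfpkit
from lfpkit.behavior import (
    PositionTrace,
    compute_velocity,
    restrict_to_window,
    segment_states,
)
from lfpkit.conditioning import BANDS, LfpSignal, analytic, bandpass_array, zscore_by_state
from lfpkit.coupling import mi_surrogate_threshold, modulation_index
from lfpkit.io import SessionConfig, get_logger
from lfpkit.ripples import RippleParams, detect_ripples, ripple_stats
from lfpkit.spectral import multitaper_psd, peak_band_power, smooth_spectrum
from lfpkit.synchrony import band_coherence, coherence, phase_lag

__all__ = ["SessionResult", "analyze_session", "compare_conditions"]

log = get_logger("session")

POWER_BANDS = ("theta", "low_gamma", "high_gamma")


@dataclass
class SessionResult:
    """Nested per-session metrics; absent channels/states yield absent keys."""

    data: dict

    def to_json(self) -> str:
        return json.dumps(self.data, sort_keys=True, indent=1)

    def get(self, *path, default=None):
        node = self.data
        for key in path:
            if not isinstance(node, dict) or key not in node:
                return default
            node = node[key]
        return node


def _config_hash(config: SessionConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _collect_cfc_inputs(run_state):
    """Theta phase and low-gamma (30-55 Hz) envelope on edge-valid run samples."""
    phases, envs = [], []
    for piece in run_state.pieces:
        if piece.size < 2 * run_state.rate:  # need >= 2 s per bout for edges
            continue
        th = analytic(bandpass_array(piece, BANDS["theta"], run_state.rate),
                      run_state.rate, BANDS["theta"])
        lg = analytic(bandpass_array(piece, BANDS["cfc_low_gamma"], run_state.rate),
                      run_state.rate, BANDS["cfc_low_gamma"])
        valid = th.edge_valid & lg.edge_valid
        phases.append(th.phase[valid])
        envs.append(lg.envelope[valid])
    if not phases:
        return None, None
    return np.concatenate(phases), np.concatenate(envs)


def analyze_session(config: SessionConfig, hpc: LfpSignal, position: PositionTrace,
                    pfc: LfpSignal | None = None, seed: int = 0,
                    ripple_params: RippleParams | None = None) -> SessionResult:
    """Run the full pipeline on one session; deterministic given config + seed."""
    out: dict = {
        "session_id": config.session_id,
        "genotype": config.genotype,
        "treatment": config.treatment,
        "dose_mg_per_kg": config.dose_mg_per_kg,
        "provenance": {
            "config_hash": _config_hash(config),
            "seed": int(seed),
            "package_version": lfpkit.__version__,
        },
        "missing": [],
    }
    window = tuple(config.analysis_window_s)
    vel = compute_velocity(position)
    segments = restrict_to_window(segment_states(vel), window)

    # locomotion summary
    run_time = segments.total_s("run")
    run_mask = np.zeros(vel.time_s.size, dtype=bool)
    for iv in segments.by_label("run"):
        run_mask |= (vel.time_s >= iv.start_s) & (vel.time_s < iv.end_s)
    out["locomotion"] = {
        "percent_time_running": 100.0 * run_time / (window[1] - window[0]),
        "mean_run_speed_cm_s": (float(vel.speed_cm_s[run_mask].mean())
                                if run_mask.any() else float("nan")),
        "n_run_bouts": len(segments.by_label("run")),
        "n_rest_bouts": len(segments.by_label("rest")),
        "window_s": list(window),
    }

    try:
        states = zscore_by_state(hpc, segments)
    except ValueError as exc:
        raise RuntimeError(f"stage zscore: {exc}") from exc
    pfc_states = zscore_by_state(pfc, segments) if pfc is not None else {}

    # per-state spectral peaks
    out["power"] = {}
    for label in ("run", "rest"):
        if label not in states:
            out["missing"].append(f"power.{label}")
            continue
        try:
            spec = smooth_spectrum(multitaper_psd(states[label]))
        except ValueError as exc:
            out["missing"].append(f"power.{label}")
            log.info("power stage skipped for %s: %s", label, exc)
            continue
        out["power"][label] = {
            band: {
                "peak_power": peak_band_power(spec, BANDS[band]).peak_power,
                "peak_freq_hz": peak_band_power(spec, BANDS[band]).peak_freq_hz,
            }
            for band in POWER_BANDS
        }

    # theta-phase / low-gamma-amplitude coupling during running
    if "run" in states:
        phase, env = _collect_cfc_inputs(states["run"])
        if phase is not None and phase.size >= 10 * states["run"].rate / 7.0:
            mod = modulation_index(phase, env)
            thr = mi_surrogate_threshold(phase, env, seed=seed)
            out["coupling"] = {
                "mi": mod.mi,
                "preferred_phase_rad": mod.preferred_phase_rad,
                "mi_surrogate_p95": thr,
                "significant": bool(mod.mi > thr),
            }
        else:
            out["missing"].append("coupling")
    else:
        out["missing"].append("coupling")

    # hippocampal-prefrontal synchrony (only when a PFC channel exists)
    if pfc is not None:
        out["synchrony"] = {}
        for label in ("run", "rest"):
            if label not in states or label not in pfc_states:
                continue
            try:
                coh = coherence(states[label], pfc_states[label])
            except ValueError as exc:
                log.info("coherence skipped for %s: %s", label, exc)
                continue
            entry = {"lowgamma_coherence": band_coherence(coh, BANDS["low_gamma"])}
            if label == "run":
                try:
                    lag = phase_lag(states[label], pfc_states[label],
                                    BANDS["low_gamma"])
                    entry["phase_lag"] = {
                        "mean_phase_diff_rad": lag.mean_phase_diff_rad,
                        "resultant_length": lag.resultant_length,
                        "p_vs_zero": lag.p_vs_zero,
                        "p_vs_2pi": lag.p_vs_2pi,
                        "n": lag.n,
                    }
                except ValueError as exc:
                    log.info("phase lag skipped: %s", exc)
            out["synchrony"][label] = entry

    # ripple detection during rest
    if "rest" in states:
        try:
            events = detect_ripples(states["rest"], ripple_params)
            stats = ripple_stats(events, states["rest"].total_s)
            out["ripples"] = {
                "event_rate_hz": stats.event_rate_hz,
                "mean_amplitude_sd": stats.mean_amplitude_sd,
                "n_events": stats.n_events,
                "analyzed_time_s": stats.analyzed_time_s,
            }
        except ValueError as exc:
            out["missing"].append("ripples")
            log.info("ripple stage skipped: %s", exc)
    else:
        out["missing"].append("ripples")

    return SessionResult(data=out)


#: metric paths compared across conditions (positive scalars -> ratios valid)
COMPARISON_METRICS = {
    "lowgamma_power_run": ("power", "run", "low_gamma", "peak_power"),
    "lowgamma_power_rest": ("power", "rest", "low_gamma", "peak_power"),
    "theta_power_run": ("power", "run", "theta", "peak_power"),
    "highgamma_power_run": ("power", "run", "high_gamma", "peak_power"),
    "mi": ("coupling", "mi"),
    "lowgamma_coherence_run": ("synchrony", "run", "lowgamma_coherence"),
    "ripple_rate_hz": ("ripples", "event_rate_hz"),
    "ripple_amplitude_sd": ("ripples", "mean_amplitude_sd"),
}


def compare_conditions(pairs: list[tuple[SessionResult, SessionResult]]) -> dict:
    """Effect sizes for paired (vehicle, treatment) session results.

    For every metric present in both members of a pair the treatment/vehicle
    ratio and signed difference are reported, along with group means and a
    direction flag (``"up"``/``"down"``).  No hypothesis tests are computed.
    """
    if not pairs:
        raise ValueError("need at least one (vehicle, treatment) pair")
    per_metric: dict[str, dict] = {}
    for name, path in COMPARISON_METRICS.items():
        ratios, diffs = [], []
        for veh, trt in pairs:
            a = veh.get(*path)
            b = trt.get(*path)
            if a is None or b is None or not np.isfinite(a) or not np.isfinite(b):
                continue
            diffs.append(b - a)
            if a > 0:
                ratios.append(b / a)
        if not diffs:
            continue
        entry = {
            "n_pairs": len(diffs),
            "mean_difference": float(np.mean(diffs)),
        }
        if ratios:
            mean_ratio = float(np.mean(ratios))
            entry["mean_ratio"] = mean_ratio
            entry["direction"] = ("up" if mean_ratio > 1.0
                                  else "down" if mean_ratio < 1.0 else "unchanged")
        per_metric[name] = entry
    return {"metrics": per_metric, "n_pairs": len(pairs)}
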