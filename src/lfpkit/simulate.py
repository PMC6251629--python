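"""Ground-truthed two-channel LFP + position session simulator.

Generates synthetic sessions with the statistical structure the analysis
pipeline assumes: a two-state (run/rest) locomotion Markov chain tracked at
30 Hz; a 1 kHz hippocampal LFP composed of 1/f background, state-gated
theta (7 Hz), theta-phase-coupled low-gamma (42 Hz) whose amplitude scales
with a condition gain (modeling the chemogenetic manipulation of CA2
output), high-gamma (80 Hz), rest-only Poisson ripple bursts (150 Hz), and
60/180 Hz line noise; and a prefrontal channel sharing the low-gamma
component at a fixed lag plus independent background.

The low-gamma instantaneous amplitude follows

    A(t) = a * g * (1 - k/2 + (k/2) * cos(theta_phase(t) - phi0))

with coupling depth k in [0, 1] and preferred theta phase phi0, so the
coupling ground truth is exact (theta phase is taken from the generated
oscillator, never re-estimated).  Ripple burst amplitude is parameterized
in units of the rest-state ripple-band background SD, which makes detector
operating points controllable.  Identical seeds give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from lfpkit.behavior import Interval, PositionTrace
from lfpkit.conditioning import LfpSignal

__all__ = [
    "GroundTruth",
    "SimulatedSession",
    "SimulationParams",
    "simulate_condition_pair",
    "simulate_lfp",
    "simulate_position",
    "simulate_session",
]


@dataclass(frozen=True)
class SimulationParams:
    """Session generator parameters (amplitudes in background-SD-ish a.u.)."""

    duration_s: float = 600.0
    seed: int = 0
    fs_lfp: float = 1000.0
    fs_pos: float = 30.0
    # theta
    theta_freq: float = 7.0
    theta_amp_run: float = 1.0
    theta_amp_rest: float = 0.3
    # low-gamma and its theta-phase coupling
    lowgamma_freq: float = 42.0
    lowgamma_amp: float = 0.3
    coupling_strength: float = 0.5          # k, depth of phase modulation
    preferred_phase: float = np.pi / 2.0    # phi0
    # high-gamma
    highgamma_freq: float = 80.0
    highgamma_amp: float = 0.15
    # ripples (rest only)
    ripple_rate_hz: float = 0.3
    ripple_freq: float = 150.0
    ripple_dur_ms: float = 60.0
    ripple_amp_sd: float = 6.0
    # nuisance components
    line_noise_amp: float = 0.1
    pink_noise_sd: float = 1.0
    # condition / inter-areal structure
    condition_gain: float = 1.0             # g, multiplies lowgamma_amp
    interareal_lag_ms: float = 5.0
    # locomotion
    run_to_rest_hz: float = 0.125           # per-second switch rates
    rest_to_run_hz: float = 0.1
    min_bout_s: float = 2.0
    run_speed_cm_s: float = 10.0
    rest_speed_cm_s: float = 0.1
    arena_cm: float = 80.0

    def __post_init__(self) -> None:
        for name in ("theta_amp_run", "theta_amp_rest", "lowgamma_amp",
                     "highgamma_amp", "ripple_amp_sd", "line_noise_amp",
                     "pink_noise_sd", "condition_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.ripple_freq >= self.fs_lfp / 2.0:
            raise ValueError("ripple frequency at or above Nyquist")


@dataclass
class GroundTruth:
    """Everything a test needs to score the pipeline against the generator."""

    state_intervals: list[Interval]
    ripple_onsets_s: list[float]
    ripple_peaks_s: list[float]
    kappa: float
    preferred_phase_rad: float
    lag_ms: float
    condition_gain: float
    lowgamma_power_ratio: float             # vs a gain-1 baseline: g**2
    theta_phase: np.ndarray | None = None   # unwrapped oscillator phase at fs_lfp

    def to_dict(self) -> dict:
        return {
            "state_intervals": [[iv.start_s, iv.end_s, iv.label]
                                for iv in self.state_intervals],
            "ripple_onsets_s": list(self.ripple_onsets_s),
            "ripple_peaks_s": list(self.ripple_peaks_s),
            "kappa": self.kappa,
            "preferred_phase_rad": self.preferred_phase_rad,
            "lag_ms": self.lag_ms,
            "condition_gain": self.condition_gain,
            "lowgamma_power_ratio": self.lowgamma_power_ratio,
        }


@dataclass
class SimulatedSession:
    hpc: LfpSignal
    pfc: LfpSignal
    position: PositionTrace
    truth: GroundTruth
    params: SimulationParams


def _draw_state_intervals(params: SimulationParams,
                          rng: np.random.Generator) -> list[Interval]:
    """Alternating run/rest bouts with exponential dwell times.

    A minimum dwell of ``min_bout_s`` keeps bouts resolvable by a velocity
    estimator operating with 0.5-s smoothing on a 30 Hz grid.
    """
    means = {"run": 1.0 / params.run_to_rest_hz if params.run_to_rest_hz > 0 else np.inf,
             "rest": 1.0 / params.rest_to_run_hz if params.rest_to_run_hz > 0 else np.inf}
    # start state by stationary occupancy
    p_run = (means["run"] / (means["run"] + means["rest"])
             if np.isfinite(means["run"]) or np.isfinite(means["rest"]) else 0.5)
    if np.isinf(means["run"]):
        p_run = 1.0
    if np.isinf(means["rest"]):
        p_run = 0.0
    state = "run" if rng.random() < p_run else "rest"
    t = 0.0
    out: list[Interval] = []
    while t < params.duration_s:
        dwell = (params.duration_s - t if np.isinf(means[state])
                 else max(params.min_bout_s, rng.exponential(means[state])))
        end = min(t + dwell, params.duration_s)
        out.append(Interval(t, end, state))
        t = end
        state = "rest" if state == "run" else "run"
    return out


def _state_mask(intervals: list[Interval], n: int, rate: float,
                label: str) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for iv in intervals:
        if iv.label != label:
            continue
        i0 = int(np.floor(iv.start_s * rate))
        i1 = min(n, int(np.ceil(iv.end_s * rate)))
        mask[i0:i1] = True
    return mask


def simulate_position(params: SimulationParams, seed: int | None = None
                      ) -> tuple[PositionTrace, list[Interval]]:
    """30 Hz x/y tracking from the two-state locomotion chain.

    During run bouts the animal moves at ``run_speed_cm_s`` with a slowly
    wandering heading, reflecting off the arena walls; during rest it
    jitters in place at ``rest_speed_cm_s``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    intervals = _draw_state_intervals(params, rng)
    n = int(round(params.duration_s * params.fs_pos))
    dt = 1.0 / params.fs_pos
    run = _state_mask(intervals, n, params.fs_pos, "run")
    speed = np.where(run, params.run_speed_cm_s, params.rest_speed_cm_s)
    # heading wanders slowly during running (so the 0.5-s-smoothed finite
    # difference preserves the path speed) and is isotropic jitter at rest
    turn = rng.normal(0.0, 0.05, size=n)
    rest_heading = rng.uniform(0.0, 2.0 * np.pi, size=n)
    x = np.empty(n)
    y = np.empty(n)
    x[0] = params.arena_cm / 2.0
    y[0] = params.arena_cm / 2.0
    lo, hi = 2.0, params.arena_cm - 2.0
    cx, cy = x[0], y[0]
    h = rng.uniform(0.0, 2.0 * np.pi)
    center = params.arena_cm / 2.0
    wall_margin = 10.0
    max_steer = 0.12  # rad/sample: full turnaround in ~0.9 s, gentle enough
    # that the smoothed finite-difference speed stays above the run threshold
    for i in range(1, n):
        h += turn[i]
        near_wall = (cx < lo + wall_margin or cx > hi - wall_margin
                     or cy < lo + wall_margin or cy > hi - wall_margin)
        if run[i] and near_wall:
            # steer smoothly toward the arena center instead of bouncing
            want = np.arctan2(center - cy, center - cx)
            dh = np.angle(np.exp(1j * (want - h)))
            h += np.clip(dh, -max_steer, max_steer)
        hi_now = h if run[i] else rest_heading[i]
        cx += speed[i] * dt * np.cos(hi_now)
        cy += speed[i] * dt * np.sin(hi_now)
        cx = min(max(cx, lo), hi)
        cy = min(max(cy, lo), hi)
        x[i] = cx
        y[i] = cy
    pos = PositionTrace(time_s=np.arange(n) * dt, x_cm=x, y_cm=y,
                        rate=params.fs_pos)
    return pos, intervals


def _pink_noise(n: int, fs: float, sd: float, rng: np.random.Generator
                ) -> np.ndarray:
    """1/f-amplitude background: spectrally shaped white noise, flat below 1 Hz."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    shape = 1.0 / np.maximum(f, 1.0)
    spec *= shape
    out = np.fft.irfft(spec, n=n)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def _slow_drift(n: int, fs: float, cutoff_hz: float, sd: float,
                rng: np.random.Generator) -> np.ndarray:
    """Smooth random drift: white noise low-passed below ``cutoff_hz``."""
    white = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec[f > cutoff_hz] = 0.0
    out = np.fft.irfft(spec, n=n)
    s = out.std()
    return out * (sd / s) if s > 0 else out


def _draw_ripple_times(intervals: list[Interval], rate_hz: float,
                       dur_s: float, rng: np.random.Generator,
                       margin_s: float = 0.15,
                       min_gap_s: float = 0.2) -> list[float]:
    """Poisson ripple centers within rest bouts, with a minimum spacing.

    The margin keeps whole bursts inside their bout; spacing is enforced
    peak-to-peak at ``min_gap_s + dur_s`` so consecutive true events are
    separable by a detector honoring the 200-ms exclusion rule.
    """
    centers: list[float] = []
    for iv in intervals:
        if iv.label != "rest":
            continue
        lo = iv.start_s + margin_s + dur_s / 2.0
        hi = iv.end_s - margin_s - dur_s / 2.0
        if hi <= lo:
            # a zero draw must still consume one Poisson variate for
            # reproducibility across parameter variants
            rng.poisson(0.0)
            continue
        k = rng.poisson(rate_hz * (hi - lo))
        ts = np.sort(rng.uniform(lo, hi, size=k))
        kept: list[float] = []
        for t in ts:
            if not kept or t - kept[-1] >= min_gap_s + dur_s:
                kept.append(float(t))
        centers.extend(kept)
    return centers


def simulate_lfp(params: SimulationParams, state_intervals: list[Interval],
                 seed: int | None = None
                 ) -> tuple[LfpSignal, LfpSignal, GroundTruth]:
    """Two-channel LFP with full ground truth for the given state intervals."""
    total = sum(iv.duration_s for iv in state_intervals)
    if abs(total - params.duration_s) > 1.0 / params.fs_pos:
        raise ValueError("state intervals must tile [0, duration)")
    entropy = params.seed if seed is None else seed
    ss = entropy if isinstance(entropy, np.random.SeedSequence) \
        else np.random.SeedSequence(entropy)
    rng_hpc, rng_pfc, rng_rip, rng_phase = [np.random.default_rng(c)
                                            for c in ss.spawn(4)]
    fs = params.fs_lfp
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs
    run = _state_mask(state_intervals, n, fs, "run")

    # theta frequency wanders slowly (as in vivo); without drift the gamma
    # envelope would be strictly periodic and circular-shift surrogates
    # could never decohere it from theta phase
    f_inst = params.theta_freq + _slow_drift(n, fs, 0.2, 0.4, rng_phase)
    theta_phase = (2.0 * np.pi * np.cumsum(f_inst) / fs
                   + rng_phase.uniform(0, 2 * np.pi))
    theta_amp = np.where(run, params.theta_amp_run, params.theta_amp_rest)
    theta = theta_amp * np.cos(theta_phase)

    a = params.lowgamma_amp * params.condition_gain
    k = params.coupling_strength
    env = a * (1.0 - k / 2.0 + (k / 2.0) * np.cos(theta_phase - params.preferred_phase))
    lg_carrier_phase = 2.0 * np.pi * params.lowgamma_freq * t + rng_phase.uniform(0, 2 * np.pi)
    lowgamma = env * np.cos(lg_carrier_phase)

    highgamma = params.highgamma_amp * np.cos(
        2.0 * np.pi * params.highgamma_freq * t + rng_phase.uniform(0, 2 * np.pi))
    line = params.line_noise_amp * (
        np.sin(2.0 * np.pi * 60.0 * t + rng_phase.uniform(0, 2 * np.pi))
        + 0.5 * np.sin(2.0 * np.pi * 180.0 * t + rng_phase.uniform(0, 2 * np.pi)))

    pink_hpc = _pink_noise(n, fs, params.pink_noise_sd, rng_hpc)
    pink_pfc = _pink_noise(n, fs, params.pink_noise_sd, rng_pfc)

    # ripple bursts, calibrated against the rest-state ripple-band background SD
    dur_s = params.ripple_dur_ms / 1000.0
    centers = _draw_ripple_times(state_intervals, params.ripple_rate_hz,
                                 dur_s, rng_rip)
    ripples = np.zeros(n)
    if centers and params.ripple_amp_sd > 0:
        rest = ~run
        if params.pink_noise_sd > 0 and rest.any():
            sos = sps.butter(4, [100.0, 300.0], btype="bandpass", fs=fs,
                             output="sos")
            band_bg = sps.sosfiltfilt(sos, pink_hpc)
            sigma_band = float(band_bg[rest].std())
        else:
            sigma_band = 1.0
        amp = params.ripple_amp_sd * sigma_band
        sigma_t = dur_s / 4.0  # +-2 sigma spans the nominal duration
        half = int(round(3 * sigma_t * fs))
        for c in centers:
            i0 = int(round(c * fs)) - half
            idx = np.arange(i0, i0 + 2 * half + 1)
            idx = idx[(idx >= 0) & (idx < n)]
            tt = idx / fs - c
            ripples[idx] += amp * np.exp(-tt ** 2 / (2 * sigma_t ** 2)) * np.sin(
                2.0 * np.pi * params.ripple_freq * tt)

    hpc = pink_hpc + theta + lowgamma + highgamma + ripples + line

    lag = int(round(params.interareal_lag_ms * fs / 1000.0))
    lowgamma_delayed = np.roll(lowgamma, lag)
    pfc = pink_pfc + lowgamma_delayed + line

    truth = GroundTruth(
        state_intervals=list(state_intervals),
        ripple_onsets_s=[c - dur_s / 2.0 for c in centers],
        ripple_peaks_s=list(centers),
        kappa=k,
        preferred_phase_rad=float(params.preferred_phase),
        lag_ms=params.interareal_lag_ms,
        condition_gain=params.condition_gain,
        lowgamma_power_ratio=params.condition_gain ** 2,
        theta_phase=theta_phase,
    )
    hpc_sig = LfpSignal(samples=hpc, rate=fs, role="hpc", units="au")
    pfc_sig = LfpSignal(samples=pfc, rate=fs, role="pfc", units="au")
    return hpc_sig, pfc_sig, truth


def simulate_session(params: SimulationParams, seed: int | None = None
                     ) -> SimulatedSession:
    """Position + two-channel LFP + ground truth in one call."""
    base = np.random.SeedSequence(params.seed if seed is None else seed)
    pos_seed, lfp_seed = base.spawn(2)
    pos, intervals = simulate_position(params, seed=pos_seed)
    hpc, pfc, truth = simulate_lfp(params, intervals, seed=lfp_seed)
    return SimulatedSession(hpc=hpc, pfc=pfc, position=pos, truth=truth,
                            params=params)


def simulate_condition_pair(params: SimulationParams, seed: int,
                            gain: float, ripple_rate_factor: float
                            ) -> tuple[SimulatedSession, SimulatedSession]:
    """A vehicle/treatment session pair isolating the condition effect.

    Both sessions share the same locomotion (same state seed), as in a
    within-animal design; LFP noise is drawn independently per session.
    Only the low-gamma gain and the ripple rate differ: ``gain > 1`` with
    ``ripple_rate_factor < 1`` emulates excitatory-DREADD activation of
    CA2 (gamma up, ripples down) and the converse emulates inhibition.
    """
    base = np.random.SeedSequence(seed)
    pos_seed, veh_seed, trt_seed = base.spawn(3)
    p_veh = replace(params, condition_gain=1.0)
    p_trt = replace(params, condition_gain=gain,
                    ripple_rate_hz=params.ripple_rate_hz * ripple_rate_factor)
    pos, intervals = simulate_position(params, seed=pos_seed)
    hv, pv, tv = simulate_lfp(p_veh, intervals, seed=veh_seed)
    ht, pt, tt_ = simulate_lfp(p_trt, intervals, seed=trt_seed)
    vehicle = SimulatedSession(hpc=hv, pfc=pv, position=pos, truth=tv,
                               params=p_veh)
    treated = SimulatedSession(hpc=ht, pfc=pt, position=pos, truth=tt_,
                               params=p_trt)
    return vehicle, treated
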