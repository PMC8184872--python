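"""Synthetic 300 Hz gaze traces with known ground truth.

The generator emulates one session of the tool-viewing cueing experiment:
each trial holds fixation at screen centre, then (for blue/green cues)
executes a 12-degree horizontal saccade a latency draw after the colour
cue, followed by a return saccade during the post-trial phase.  Saccade
kinematics follow the main sequence (duration linear in amplitude, peak
velocity saturating with amplitude); latencies follow an ex-Gaussian whose
condition and SOA terms default to the grand means observed in the
experiment this pipeline reanalyses.  Position noise, brief dropouts and
blinks (runs of missing samples, optionally flanked by eyelid artefact
spikes) can be layered on top.

Ground truth (true saccade onset, landing point, SRT, blink intervals) is
recorded per trial so every downstream stage can be validated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignParams, TrialSpec, build_schedule
from .gaze_io import GazeTrace, ScreenGeometry, deg_to_px, px_to_deg

__all__ = [
    "KinematicsParams",
    "LatencyModel",
    "NoiseAndArtifactParams",
    "SubjectData",
    "main_sequence",
    "saccade_displacement",
    "simulate_trial",
    "simulate_subject",
    "simulate_cohort",
]

PROFILES = ("flat_top", "gaussian", "minimum_jerk")


@dataclass(frozen=True)
class KinematicsParams:
    """Main-sequence saccade kinematics.

    ``duration = d0 + d1 * A`` (ms) and ``peak_velocity = vmax * (1 -
    exp(-A / a0))`` (deg/s) with conventional oculomotor constants as
    defaults.  ``profile`` selects the velocity waveform; the default
    ``flat_top`` (cosine-ramped plateau) is the only shape that can honour
    the main-sequence duration, peak velocity and amplitude simultaneously
    -- for a 12 deg saccade the main sequence implies a mean/peak velocity
    ratio near 0.88, which no bell-shaped profile reaches.  ``gaussian``
    preserves amplitude and duration but overshoots the main-sequence peak;
    ``minimum_jerk`` preserves amplitude and duration with peak
    ``1.875 * A / d``.
    """

    sample_rate: float = 300.0
    d0: float = 21.0        # ms
    d1: float = 2.2         # ms/deg
    vmax: float = 500.0     # deg/s
    a0: float = 14.0        # deg
    profile: str = "flat_top"

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.d0 <= 0 or self.d1 < 0:
            raise ValueError("saccade duration must stay positive")
        if self.profile not in PROFILES:
            raise ValueError(f"profile must be one of {PROFILES}")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate


def main_sequence(amplitude: float, k: KinematicsParams) -> tuple[float, float]:
    """(duration_ms, peak_velocity_deg_s) for a saccade of given amplitude."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    duration = k.d0 + k.d1 * amplitude
    peak = k.vmax * (1.0 - math.exp(-amplitude / k.a0))
    return duration, peak


def _flat_top_params(A: float, d_ms: float, vp: float) -> tuple[float, float]:
    """Ramp time tau (ms) and effective plateau velocity for the flat-top
    profile: cosine rise over tau, constant plateau, cosine fall over tau.

    The plateau velocity solves ``v_eff * (d - tau) = A``; tau is chosen so
    v_eff matches the main-sequence peak when feasible, clipped to
    [0.1 d, 0.5 d] so the waveform stays smooth for extreme amplitudes.
    """
    d_s = d_ms / 1000.0
    if vp > 0:
        tau = d_s - A / vp
    else:
        tau = d_s / 2
    tau = min(max(tau, 0.1 * d_s), 0.5 * d_s)
    v_eff = A / (d_s - tau) if d_s > tau else 0.0
    return tau, v_eff


def saccade_displacement(t_ms: np.ndarray, amplitude: float,
                         k: KinematicsParams) -> tuple[np.ndarray, float]:
    """Scalar displacement along the saccade axis at times ``t_ms``
    (relative to saccade onset), plus the profile's true peak velocity.

    The displacement is 0 before onset and ``amplitude`` after the
    main-sequence duration has elapsed.
    """
    d_ms, vp = main_sequence(amplitude, k)
    t = np.asarray(t_ms, dtype=float) / 1000.0
    d = d_ms / 1000.0
    s = np.zeros_like(t)
    if amplitude == 0:
        return s, 0.0
    if k.profile == "flat_top":
        tau, v = _flat_top_params(amplitude, d_ms, vp)
        rise = (t > 0) & (t < tau)
        mid = (t >= tau) & (t <= d - tau)
        fall = (t > d - tau) & (t < d)
        s[rise] = 0.5 * v * (t[rise] - (tau / math.pi)
                             * np.sin(math.pi * t[rise] / tau))
        s[mid] = 0.5 * v * tau + v * (t[mid] - tau)
        td = d - t[fall]
        s[fall] = amplitude - 0.5 * v * (td - (tau / math.pi)
                                         * np.sin(math.pi * td / tau))
        s[t >= d] = amplitude
        return s, v
    if k.profile == "minimum_jerk":
        u = np.clip(t / d, 0.0, 1.0)
        s = amplitude * (10 * u**3 - 15 * u**4 + 6 * u**5)
        return s, 1.875 * amplitude / d
    # gaussian velocity profile truncated to the main-sequence duration
    from scipy.stats import norm
    sig = d / 6.0
    lo = norm.cdf(-0.5 * d / sig)
    hi = norm.cdf(0.5 * d / sig)
    u = np.clip(t, 0.0, d)
    s = amplitude * (norm.cdf((u - 0.5 * d) / sig) - lo) / (hi - lo)
    s[t >= d] = amplitude
    peak = amplitude / (sig * math.sqrt(2 * math.pi) * (hi - lo))
    return s, peak


@dataclass(frozen=True)
class LatencyModel:
    """Ex-Gaussian saccadic-latency generator.

    Per-trial latency = condition mean + SOA term + subject offset +
    N(0, trial_sd) + Exp(tau) - tau, floored at ``min_latency``.  The
    subtraction of tau keeps the expectation at the additive mean.
    Defaults are calibrated so the generated grand means reproduce the
    per-condition and per-SOA mean SRTs of the tool-viewing experiment
    (head saccades ~9 ms faster than handle/control; latencies shortening
    with SOA); trial- and subject-level spreads are conventional SRT
    values, chosen once as realistic for a 300 Hz cueing task.
    """

    mu_by_condition: tuple[tuple[str, float], ...] = (
        ("head", 393.0), ("handle", 402.1), ("control", 402.66))
    soa_effect: tuple[tuple[int, float], ...] = (
        (100, 33.75), (200, 8.75), (400, -16.25), (600, -26.25))
    subject_sd: float = 52.0
    trial_sd: float = 35.0
    exgauss_tau: float = 50.0
    min_latency: float = 80.0

    @property
    def mu(self) -> dict[str, float]:
        return dict(self.mu_by_condition)

    @property
    def soa(self) -> dict[int, float]:
        return dict(self.soa_effect)

    def draw(self, tool_end: str, soa_ms: int, subject_offset: float,
             rng: np.random.Generator) -> float:
        mean = (self.mu.get(tool_end, 400.0) + self.soa.get(int(soa_ms), 0.0)
                + subject_offset)
        lat = mean
        if self.trial_sd > 0:
            lat += rng.normal(0.0, self.trial_sd)
        if self.exgauss_tau > 0:
            lat += rng.exponential(self.exgauss_tau) - self.exgauss_tau
        return max(lat, self.min_latency)

    @classmethod
    def null(cls, mean: float = 400.0, **kw) -> "LatencyModel":
        """A no-effect model: identical means in every condition and SOA."""
        return cls(
            mu_by_condition=(("head", mean), ("handle", mean),
                             ("control", mean)),
            soa_effect=((100, 0.0), (200, 0.0), (400, 0.0), (600, 0.0)),
            **kw)


@dataclass(frozen=True)
class NoiseAndArtifactParams:
    """Measurement noise and artefacts layered on the ideal trace.

    ``position_noise_rms`` is white per-axis noise in degrees (remote
    300 Hz trackers sit around 0.05 deg RMS); ``blink_rate`` is events per
    minute; blink durations are uniform within ``blink_duration_ms`` (the
    minimum stays above 10 samples so every generated blink is detectable
    by the 10-continuous-missing-samples rule); ``dropout_rate`` is the
    per-sample probability of an isolated 1-sample loss; ``overshoot_amp``
    adds a decaying post-saccadic oscillation to exercise the 9-sample
    landing average; ``blink_spikes`` adds eyelid-closure position
    excursions just before/after each blink to exercise the +-20-sample
    padding rule; ``landing_sd`` scatters the saccade endpoint around the
    target.
    """

    position_noise_rms: float = 0.05   # deg per axis
    blink_rate: float = 3.0            # per minute
    blink_duration_ms: tuple[float, float] = (100.0, 250.0)
    dropout_rate: float = 0.002        # per sample
    overshoot_amp: float = 0.15        # deg
    blink_spikes: bool = True
    landing_sd: float = 0.5            # deg
    quantize_px: bool = False

    def __post_init__(self) -> None:
        if min(self.position_noise_rms, self.blink_rate,
               self.dropout_rate, self.overshoot_amp, self.landing_sd) < 0:
            raise ValueError("noise parameters must be non-negative")
        if self.blink_rate > 0 and self.blink_duration_ms[0] < 10 * 1000 / 300:
            raise ValueError(
                "minimum blink duration must cover >= 10 samples at 300 Hz "
                "so generated blinks satisfy the blink-detection rule")

    @classmethod
    def clean(cls) -> "NoiseAndArtifactParams":
        """Noise-free settings for ground-truth validation."""
        return cls(position_noise_rms=0.0, blink_rate=0.0, dropout_rate=0.0,
                   overshoot_amp=0.0, blink_spikes=False, landing_sd=0.0)


def _add_saccade(x, y, t_ms, onset_ms, start_xy, end_xy, k):
    """Superimpose one saccade from start_xy to end_xy; returns (end_ms, vp)."""
    dx = end_xy[0] - start_xy[0]
    dy = end_xy[1] - start_xy[1]
    amp = math.hypot(dx, dy)
    d_ms, _ = main_sequence(amp, k)
    s, vp = saccade_displacement(t_ms - onset_ms, amp, k)
    if amp > 0:
        x += s * (dx / amp)
        y += s * (dy / amp)
    return onset_ms + d_ms, vp


def simulate_trial(
    spec: TrialSpec,
    params: DesignParams,
    k: KinematicsParams,
    lat: LatencyModel,
    noise: NoiseAndArtifactParams,
    rng: np.random.Generator,
    subject_offset: float = 0.0,
    latency_override: float | None = None,
) -> tuple[GazeTrace, dict]:
    """Simulate one trial; returns the trace (degrees) and its ground truth.

    Red (no-saccade) trials hold fixation throughout.  A latency draw that
    would not leave room for the saccade before the trial ends is recorded
    as an omission (``true_srt_ms`` absent), not an error.
    """
    dt = k.dt_ms
    n = int(round(spec.trial_end / dt))
    t = np.arange(n) * dt
    x = np.zeros(n)
    y = np.zeros(n)
    truth: dict = {
        "trial_id": spec.trial_id,
        "tool_end": spec.tool_end,
        "soa_ms": spec.soa_ms,
        "direction": spec.saccade_direction,
        "true_onset_ms": np.nan,
        "true_srt_ms": np.nan,
        "true_landing_x": np.nan,
        "true_landing_y": np.nan,
        "true_peak_vel": np.nan,
        "omitted": False,
        "blink_intervals": "",
    }

    if not spec.is_red:
        if latency_override is not None:
            latency = latency_override
        else:
            latency = lat.draw(spec.tool_end, spec.soa_ms, subject_offset, rng)
        onset = spec.cue_on + latency
        sign = 1.0 if spec.saccade_direction == "right" else -1.0
        landing = np.array([sign * params.target_ecc_deg, 0.0])
        if noise.landing_sd > 0:
            landing = landing + rng.normal(0.0, noise.landing_sd, 2)
        amp = float(np.hypot(*landing))
        d_ms, _ = main_sequence(amp, k)
        if onset + d_ms >= spec.trial_end:
            truth["omitted"] = True
        else:
            end_ms, vp = _add_saccade(x, y, t, onset, (0.0, 0.0), landing, k)
            truth.update(true_onset_ms=onset, true_srt_ms=latency,
                         true_landing_x=landing[0], true_landing_y=landing[1],
                         true_peak_vel=vp)
            if noise.overshoot_amp > 0:
                tp = t - end_ms
                ring = (noise.overshoot_amp * np.exp(-np.maximum(tp, 0) / 12.0)
                        * np.sin(2 * math.pi * 40.0 * np.maximum(tp, 0) / 1000.0))
                ring[tp < 0] = 0.0
                ux, uy = landing / amp
                x += ring * ux
                y += ring * uy
            # return saccade to centre during the post-trial phase
            ret_lat = max(rng.normal(230.0, 30.0), 120.0)
            ret_on = max(spec.image_off, end_ms + 80.0) + ret_lat
            ret_d, _ = main_sequence(amp, k)
            if ret_on + ret_d < spec.trial_end:
                _add_saccade(x, y, t, ret_on, tuple(landing), (0.0, 0.0), k)

    if noise.position_noise_rms > 0:
        x += rng.normal(0.0, noise.position_noise_rms, n)
        y += rng.normal(0.0, noise.position_noise_rms, n)

    missing = np.zeros(n, dtype=bool)
    if noise.blink_rate > 0:
        n_blinks = rng.poisson(noise.blink_rate * spec.trial_end / 60000.0)
        intervals = []
        for _ in range(n_blinks):
            dur = rng.uniform(*noise.blink_duration_ms)
            start = rng.uniform(0.0, max(spec.trial_end - dur, 0.0))
            i0 = int(start / dt)
            i1 = min(int((start + dur) / dt) + 1, n)
            if i1 - i0 < 10:
                i1 = min(i0 + 10, n)
                i0 = i1 - 10
            missing[i0:i1] = True
            intervals.append((i0, i1))
            if noise.blink_spikes:
                for j, sgn in ((i0 - 2, 1.0), (i0 - 1, 1.0),
                               (i1, -1.0), (i1 + 1, -1.0)):
                    if 0 <= j < n:
                        y[j] += sgn * 3.0  # eyelid excursion, deg
        truth["blink_intervals"] = ";".join(f"{a}:{b}" for a, b in intervals)
    if noise.dropout_rate > 0:
        missing |= rng.random(n) < noise.dropout_rate

    x[missing] = np.nan
    y[missing] = np.nan
    trace = GazeTrace(t, x, y, missing, unit="deg", sample_rate=k.sample_rate)
    if noise.quantize_px:
        geom = ScreenGeometry()
        px, py = deg_to_px(trace.x, trace.y, geom)
        trace.x, trace.y = px_to_deg(np.round(px), np.round(py), geom)
    return trace, truth


@dataclass
class SubjectData:
    """One simulated subject: schedule, continuous trace, per-trial truth."""

    subject_id: int
    schedule: list[TrialSpec]
    trace: GazeTrace
    truth: pd.DataFrame
    subject_offset: float


def simulate_subject(
    subject_id: int,
    params: DesignParams,
    k: KinematicsParams,
    lat: LatencyModel,
    noise: NoiseAndArtifactParams,
    rng: np.random.Generator,
    subject_offset: float | None = None,
    schedule: list[TrialSpec] | None = None,
) -> SubjectData:
    """Simulate a whole session as one continuous 300 Hz recording."""
    if schedule is None:
        sched_seed = int(rng.integers(0, 2**31 - 1))
        schedule = build_schedule(
            DesignParams(**{**params.__dict__, "rng_seed": sched_seed}))
    if subject_offset is None:
        subject_offset = (rng.normal(0.0, lat.subject_sd)
                          if lat.subject_sd > 0 else 0.0)
    xs, ys, ms, ts, ids = [], [], [], [], []
    truths = []
    offset_ms = 0.0
    for spec in schedule:
        trace, truth = simulate_trial(spec, params, k, lat, noise, rng,
                                      subject_offset=subject_offset)
        xs.append(trace.x)
        ys.append(trace.y)
        ms.append(trace.missing)
        ts.append(trace.t_ms + offset_ms)
        ids.append(np.full(len(trace), spec.trial_id))
        truths.append(truth)
        offset_ms += spec.trial_end
    full = GazeTrace(
        np.concatenate(ts), np.concatenate(xs), np.concatenate(ys),
        np.concatenate(ms), unit="deg", sample_rate=k.sample_rate,
        trial_id=np.concatenate(ids))
    return SubjectData(subject_id, schedule, full, pd.DataFrame(truths),
                       subject_offset)


def simulate_cohort(
    n_subjects: int,
    params: DesignParams | None = None,
    k: KinematicsParams | None = None,
    lat: LatencyModel | None = None,
    noise: NoiseAndArtifactParams | None = None,
    master_seed: int = 0,
):
    """Yield :class:`SubjectData` for each subject.

    Child seeds are spawned deterministically from ``master_seed`` so each
    subject's data is reproducible independently of iteration order.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    params = params or DesignParams()
    params.validate()
    k = k or KinematicsParams()
    lat = lat or LatencyModel()
    noise = noise if noise is not None else NoiseAndArtifactParams()
    children = np.random.SeedSequence(master_seed).spawn(n_subjects)
    for sid, ss in enumerate(children):
        rng = np.random.default_rng(ss)
        yield simulate_subject(sid, params, k, lat, noise, rng)
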