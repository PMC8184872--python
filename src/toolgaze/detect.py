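"""Velocity-based saccade detection with dual thresholds and persistence.

Combined-axis eye speed is computed by central differences.  A saccade
onset is the first sample of a run of at least 3 consecutive samples at or
above the 50 deg/s threshold; the offset is reached when speed stays below
threshold for 3 consecutive samples (the offset index is the last
above-threshold sample).  Events whose peak speed reaches 100 deg/s are
flagged as the "large" saccades of interest (the 12-degree target
responses); sub-threshold dips shorter than the persistence never split an
event, and events never span missing samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gaze_io import GazeTrace, ScreenGeometry

__all__ = [
    "DetectionParams",
    "VelocityTrace",
    "SaccadeEvent",
    "velocity",
    "detect_saccades",
    "landing_point",
    "extract_saccades",
]

JITTER_TOL = 0.01


@dataclass(frozen=True)
class DetectionParams:
    """Detection thresholds (deg/s), persistence and landing window."""

    theta_all: float = 50.0     # detects all saccades
    theta_big: float = 100.0    # classifies the big saccades of interest
    persistence: int = 3        # consecutive samples for onset/offset
    landing_avg_samples: int = 9
    onset_at_big: bool = False  # sensitivity mode: detect at theta_big

    def __post_init__(self) -> None:
        if not 0 < self.theta_all <= self.theta_big:
            raise ValueError("need 0 < theta_all <= theta_big")
        if self.persistence < 1:
            raise ValueError("persistence must be >= 1")


@dataclass
class VelocityTrace:
    """Non-negative combined-axis speed per sample; NaN where undefined."""

    v: np.ndarray
    dt_ms: float

    def __len__(self) -> int:
        return len(self.v)


@dataclass
class SaccadeEvent:
    """One detected saccade.

    ``onset_idx``..``offset_idx`` is inclusive of both above-threshold
    endpoints; landing/amplitude/direction are filled by
    :func:`extract_saccades` from the position trace.
    """

    onset_idx: int
    offset_idx: int
    peak_velocity: float
    is_large: bool
    onset_ms: float = np.nan
    landing_x: float = np.nan
    landing_y: float = np.nan
    landing_n: int = 0
    amplitude: float = np.nan
    direction: str = ""


def velocity(trace: GazeTrace, geometry: ScreenGeometry | None = None,
             ) -> VelocityTrace:
    """Central-difference combined (x, y) speed in deg/s.

    The speed at sample i uses samples i-1 and i+1; it is undefined
    (NaN) wherever any contributing sample is missing.  Trace edges fall
    back to one-sided differences.  Requires uniform sampling.
    """
    tr = trace if trace.unit == "deg" else trace.to_deg(geometry)
    t = tr.t_ms
    if len(t) >= 2:
        dt = np.diff(t)
        nominal = tr.dt_ms
        if np.max(np.abs(dt - nominal)) / nominal > JITTER_TOL:
            raise ValueError("non-uniform timestamps exceed jitter tolerance")
    n = len(tr)
    v = np.full(n, np.nan)
    if n >= 3:
        dx = tr.x[2:] - tr.x[:-2]
        dy = tr.y[2:] - tr.y[:-2]
        dts = (t[2:] - t[:-2]) / 1000.0
        v[1:-1] = np.hypot(dx, dy) / dts
    if n >= 2:
        v[0] = np.hypot(tr.x[1] - tr.x[0], tr.y[1] - tr.y[0]) / (
            (t[1] - t[0]) / 1000.0)
        v[-1] = np.hypot(tr.x[-1] - tr.x[-2], tr.y[-1] - tr.y[-2]) / (
            (t[-1] - t[-2]) / 1000.0)
    v[tr.missing] = np.nan  # speed is undefined at a lost sample itself
    return VelocityTrace(v=v, dt_ms=tr.dt_ms)


def _runs(mask: np.ndarray):
    """Half-open (start, stop) ranges of True runs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False]))
                                 .astype(np.int8)))
    return list(zip(idx[::2], idx[1::2]))


def detect_saccades(vel: VelocityTrace, p: DetectionParams | None = None,
                    ) -> list[SaccadeEvent]:
    """Dual-threshold, persistence-based event segmentation.

    Candidate onsets are runs of >= ``persistence`` samples at or above
    ``theta_all``; an open event absorbs later above-threshold runs (of
    any length) separated by fewer than ``persistence`` finite
    below-threshold samples.  A missing sample or a long-enough
    below-threshold run closes the event at its last above-threshold
    sample.  ``is_large`` is set from the peak speed against ``theta_big``.
    """
    p = p or DetectionParams()
    thr = p.theta_big if p.onset_at_big else p.theta_all
    v = vel.v
    finite = np.isfinite(v)
    above = finite & (v >= thr)
    events: list[SaccadeEvent] = []
    cur: list[int] | None = None  # [onset, offset]

    def close(cur):
        peak = float(np.nanmax(v[cur[0]:cur[1] + 1]))
        events.append(SaccadeEvent(
            onset_idx=cur[0], offset_idx=cur[1], peak_velocity=peak,
            is_large=bool(peak >= p.theta_big)))

    for start, stop in _runs(above):
        if cur is not None:
            gap = slice(cur[1] + 1, start)
            gap_ok = (start - cur[1] - 1 < p.persistence
                      and bool(np.all(finite[gap])))
            if gap_ok:
                cur[1] = stop - 1
                continue
            close(cur)
            cur = None
        if stop - start >= p.persistence:
            cur = [int(start), int(stop - 1)]
    if cur is not None:
        close(cur)
    return events


def landing_point(trace: GazeTrace, event: SaccadeEvent,
                  p: DetectionParams | None = None,
                  ) -> tuple[float, float, int]:
    """Mean gaze position over up to ``landing_avg_samples`` finite samples
    after the saccade offset (compensates post-filtering overshoot ringing).

    Returns (x_deg, y_deg, n_samples_used); NaNs if no finite sample
    follows the offset within the window.
    """
    p = p or DetectionParams()
    lo = event.offset_idx + 1
    hi = min(lo + p.landing_avg_samples, len(trace))
    xs = trace.x[lo:hi]
    ys = trace.y[lo:hi]
    ok = np.isfinite(xs) & np.isfinite(ys)
    if not np.any(ok):
        return np.nan, np.nan, 0
    return float(xs[ok].mean()), float(ys[ok].mean()), int(ok.sum())


def extract_saccades(
    trace: GazeTrace,
    p: DetectionParams | None = None,
    geometry: ScreenGeometry | None = None,
) -> list[SaccadeEvent]:
    """velocity -> detect -> annotate each event with timing, landing point,
    amplitude (Euclidean onset-to-landing) and horizontal direction."""
    p = p or DetectionParams()
    tr = trace if trace.unit == "deg" else trace.to_deg(geometry)
    events = detect_saccades(velocity(tr), p)
    for ev in events:
        ev.onset_ms = float(tr.t_ms[ev.onset_idx])
        ev.landing_x, ev.landing_y, ev.landing_n = landing_point(tr, ev, p)
        x0, y0 = tr.x[ev.onset_idx], tr.y[ev.onset_idx]
        if np.isfinite(ev.landing_x) and np.isfinite(x0):
            ev.amplitude = float(np.hypot(ev.landing_x - x0,
                                          ev.landing_y - y0))
            dx = ev.landing_x - x0
            ev.direction = "right" if dx > 0 else ("left" if dx < 0 else "")
    return events
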