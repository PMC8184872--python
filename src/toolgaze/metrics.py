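"""Per-trial saccadic reaction time and error, exclusions, aggregation.

The response saccade of a trial is the first large (peak speed >=
100 deg/s) saccade starting after the colour cue; its SRT is the onset
latency from cue onset.  Saccadic error is the Euclidean distance in
degrees between the averaged landing point and the target cross at
(+-12, 0).  Trials are classified into a status taxonomy (valid /
anticipatory / wrong_direction / blink_contaminated / no_saccade /
red_excluded); only valid trials enter condition means.  Subject-average
errors are rounded to multiples of 0.03 deg (about one pixel of the
recording display).  Subjects whose recording lost too large a fraction
of samples are excluded for poor data quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignParams, TrialSpec
from .detect import DetectionParams, SaccadeEvent, extract_saccades
from .gaze_io import GazeTrace
from .preprocess import BlinkParams, FilterParams, preprocess_trace

__all__ = [
    "MetricsParams",
    "TrialResult",
    "SubjectSummary",
    "select_response_saccade",
    "compute_error",
    "score_trial",
    "process_subject_trace",
    "aggregate_subject",
    "apply_subject_exclusions",
    "round_to_multiple",
]

STATUSES = ("valid", "no_saccade", "anticipatory", "wrong_direction",
            "blink_contaminated", "red_excluded")


@dataclass(frozen=True)
class MetricsParams:
    """Trial scoring rules.

    ``srt_min_ms`` rejects anticipatory saccades (launched before the cue
    could have been processed); ``direction_check`` rejects saccades away
    from the cued side; ``error_round_deg`` is the pixel-scale rounding
    applied to subject-average errors; ``subject_missing_exclusion_frac``
    operationalises "poor data quality" as the tolerated fraction of
    missing samples per recording.
    """

    srt_min_ms: float = 80.0
    direction_check: bool = True
    error_round_deg: float = 0.03
    target_ecc_deg: float = 12.0
    subject_missing_exclusion_frac: float = 0.3

    def __post_init__(self) -> None:
        if self.srt_min_ms < 0 or self.error_round_deg <= 0:
            raise ValueError("invalid MetricsParams")


@dataclass
class TrialResult:
    """Outcome of scoring one trial."""

    trial_id: int
    tool_end: str
    orientation: str
    soa_ms: int
    status: str
    srt_ms: float = np.nan
    error_deg: float = np.nan
    landing_x: float = np.nan
    landing_y: float = np.nan
    peak_velocity: float = np.nan


def select_response_saccade(
    events: list[SaccadeEvent],
    spec: TrialSpec,
    p: MetricsParams | None = None,
) -> tuple[SaccadeEvent | None, str]:
    """Pick the trial's response saccade, or explain why there is none.

    Events carry ``onset_ms`` relative to trial start.  The response is
    the first large event with onset after cue onset and before trial end
    whose latency is at least ``srt_min_ms`` and (when checked) whose
    direction matches the cue.  The first disqualifying large event
    determines the failure status.
    """
    p = p or MetricsParams()
    for ev in events:
        if not ev.is_large:
            continue
        if not np.isfinite(ev.onset_ms) or ev.onset_ms <= spec.cue_on:
            continue
        if ev.onset_ms >= spec.trial_end:
            break
        latency = ev.onset_ms - spec.cue_on
        if latency < p.srt_min_ms:
            return None, "anticipatory"
        if p.direction_check and ev.direction and (
                ev.direction != spec.saccade_direction):
            return None, "wrong_direction"
        return ev, "valid"
    return None, "no_saccade"


def compute_error(landing_xy, spec: TrialSpec,
                  p: MetricsParams | None = None) -> float:
    """Euclidean distance (deg) from landing point to the cued target cross.

    Targets sit on the horizontal axis at +-``target_ecc_deg`` regardless
    of stimulus orientation.
    """
    p = p or MetricsParams()
    if spec.saccade_direction not in ("left", "right"):
        raise ValueError("saccadic error is undefined for no-saccade trials")
    sign = 1.0 if spec.saccade_direction == "right" else -1.0
    tx, ty = sign * p.target_ecc_deg, 0.0
    return float(np.hypot(landing_xy[0] - tx, landing_xy[1] - ty))


def _has_blink_gap(missing: np.ndarray, min_gap: int) -> bool:
    from .preprocess import _runs
    return any(b - a >= min_gap for a, b in _runs(missing))


def score_trial(
    trace: GazeTrace,
    events: list[SaccadeEvent],
    spec: TrialSpec,
    p: MetricsParams | None = None,
    bp: BlinkParams | None = None,
) -> TrialResult:
    """Score one preprocessed trial segment (trial-relative timestamps)."""
    p = p or MetricsParams()
    bp = bp or BlinkParams()
    base = dict(trial_id=spec.trial_id, tool_end=spec.tool_end,
                orientation=spec.orientation, soa_ms=spec.soa_ms)
    if spec.is_red:
        return TrialResult(status="red_excluded", **base)
    ev, status = select_response_saccade(events, spec, p)
    if ev is None:
        if status == "no_saccade":
            i0 = int(spec.cue_on / trace.dt_ms)
            if _has_blink_gap(trace.missing[i0:], bp.min_gap_samples):
                status = "blink_contaminated"
        return TrialResult(status=status, **base)
    err = (compute_error((ev.landing_x, ev.landing_y), spec, p)
           if np.isfinite(ev.landing_x) else np.nan)
    return TrialResult(
        status="valid", srt_ms=float(ev.onset_ms - spec.cue_on),
        error_deg=err, landing_x=ev.landing_x, landing_y=ev.landing_y,
        peak_velocity=ev.peak_velocity, **base)


def process_subject_trace(
    trace: GazeTrace,
    schedule: list[TrialSpec],
    fp: FilterParams | None = None,
    bp: BlinkParams | None = None,
    dp: DetectionParams | None = None,
    mp: MetricsParams | None = None,
) -> tuple[list[TrialResult], float]:
    """Preprocess a continuous recording, detect saccades per trial, and
    score every trial.  Returns (results, missing-sample fraction).

    The trace must carry per-sample ``trial_id`` matching the schedule.
    """
    if trace.trial_id is None:
        raise ValueError("continuous trace needs per-sample trial_id")
    mp = mp or MetricsParams()
    clean, _ = preprocess_trace(trace, fp, bp)
    missing_frac = float(clean.missing.mean())
    results = []
    bounds = _trial_bounds(clean.trial_id)
    for spec in schedule:
        start, stop = bounds[spec.trial_id]
        seg = clean.segment(start, stop)
        seg.t_ms = seg.t_ms - seg.t_ms[0]
        events = extract_saccades(seg, dp)
        results.append(score_trial(seg, events, spec, mp, bp))
    return results, missing_frac


def _trial_bounds(trial_id: np.ndarray) -> dict[int, tuple[int, int]]:
    change = np.flatnonzero(np.diff(trial_id)) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [len(trial_id)]))
    return {int(trial_id[a]): (int(a), int(b)) for a, b in zip(starts, stops)}


def round_to_multiple(x, step: float):
    """Round to the nearest multiple of ``step``, ties away from zero."""
    x = np.asarray(x, dtype=float)
    return np.where(np.isfinite(x),
                    np.floor(np.abs(x) / step + 0.5) * step * np.sign(x),
                    x)


@dataclass
class SubjectSummary:
    """Per-cell means for one subject plus data-quality bookkeeping."""

    subject_id: int
    cells: pd.DataFrame       # tool_end, soa_ms, orientation, mean_srt_ms,
                              # mean_error_deg, n_valid
    status_counts: dict[str, int]
    missing_frac: float


def aggregate_subject(
    results: list[TrialResult],
    p: MetricsParams | None = None,
    subject_id: int = 0,
    missing_frac: float = 0.0,
) -> SubjectSummary:
    """Condition-cell means over valid trials.

    Red trials are excluded before aggregation; subject-average errors are
    rounded to the nearest multiple of ``error_round_deg``.
    """
    p = p or MetricsParams()
    df = pd.DataFrame([r.__dict__ for r in results])
    counts = {s: 0 for s in STATUSES}
    if len(df):
        counts.update(df["status"].value_counts().to_dict())
    valid = df[df["status"] == "valid"] if len(df) else df
    if len(valid):
        cells = (valid.groupby(["tool_end", "soa_ms", "orientation"],
                               as_index=False)
                 .agg(mean_srt_ms=("srt_ms", "mean"),
                      mean_error_deg=("error_deg", "mean"),
                      n_valid=("trial_id", "size")))
        cells["mean_error_deg"] = round_to_multiple(
            cells["mean_error_deg"].to_numpy(), p.error_round_deg)
    else:
        cells = pd.DataFrame(columns=["tool_end", "soa_ms", "orientation",
                                      "mean_srt_ms", "mean_error_deg",
                                      "n_valid"])
    return SubjectSummary(subject_id=subject_id, cells=cells,
                          status_counts=counts, missing_frac=missing_frac)


def apply_subject_exclusions(
    summaries: list[SubjectSummary],
    p: MetricsParams | None = None,
) -> tuple[list[SubjectSummary], list[str]]:
    """Drop subjects whose missing-sample fraction exceeds the data-quality
    threshold; the log records each exclusion with its reason."""
    p = p or MetricsParams()
    kept, logbook = [], []
    for s in summaries:
        if s.missing_frac > p.subject_missing_exclusion_frac:
            logbook.append(
                f"subject {s.subject_id}: excluded, missing fraction "
                f"{s.missing_frac:.3f} > {p.subject_missing_exclusion_frac}")
        else:
            kept.append(s)
    return kept, logbook


def summaries_to_long(summaries: list[SubjectSummary],
                      dv: str = "mean_srt_ms",
                      collapse: tuple[str, ...] = ()) -> pd.DataFrame:
    """Stack per-subject cell means into a long table for inference.

    ``collapse`` lists factor columns to average over (e.g. collapse
    orientation for the tool_end x SOA analysis).  Cell means are weighted
    equally, matching a subject-level cell-means analysis.
    """
    frames = []
    for s in summaries:
        df = s.cells.copy()
        df.insert(0, "subject", s.subject_id)
        frames.append(df)
    long = pd.concat(frames, ignore_index=True)
    factors = [c for c in ("tool_end", "soa_ms", "orientation")
               if c not in collapse]
    return (long.groupby(["subject", *factors], as_index=False)[dv]
            .mean().rename(columns={dv: "dv"}))
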