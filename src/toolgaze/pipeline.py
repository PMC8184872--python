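"""One-call orchestration: simulate -> preprocess -> detect -> metrics ->
infer, with a checksummed manifest for reproducibility.

Every stage writes plain delimited text (plus one JSON manifest); a rerun
with the same config and master seed reproduces byte-identical numeric
outputs.  ``describe_run`` summarises a finished run from its files alone
and verifies checksums without recomputing anything.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .design import schedule_to_frame, write_schedule
from .gaze_io import write_gaze_table
from .metrics import (aggregate_subject, apply_subject_exclusions,
                      process_subject_trace, summaries_to_long)
from .preprocess import detect_blinks
from .simulate import simulate_cohort
from .stats import effects_to_frame, pairwise_t, rm_anova

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "describe_run"]

STAGES = ("design", "simulate", "preprocess", "metrics", "infer")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and return the run directory.

    Failure in any stage halts with an error naming the stage; outputs
    and their SHA-256 checksums are listed in ``manifest.json``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    files: dict[str, list[str]] = {s: [] for s in STAGES}

    def emit(stage: str, name: str) -> Path:
        files[stage].append(name)
        return out / name

    summaries = []
    trial_frames = []
    stage = "simulate"
    try:
        for sub in simulate_cohort(
                config.n_subjects, config.design, config.kinematics,
                config.latency, config.noise, master_seed=config.master_seed):
            sid = sub.subject_id
            stage = "design"
            write_schedule(sub.schedule, emit(stage, f"schedule_{sid:03d}.csv"))
            stage = "simulate"
            if config.write_gaze:
                write_gaze_table(sub.trace,
                                 emit(stage, f"gaze_{sid:03d}.csv"))
            sub.truth.to_csv(emit(stage, f"truth_{sid:03d}.csv"), index=False)
            stage = "preprocess"
            blinks = detect_blinks(sub.trace, config.blink)
            pd.DataFrame(blinks, columns=["start", "stop"]).to_csv(
                emit(stage, f"blinks_{sid:03d}.csv"), index=False)
            stage = "metrics"
            results, missing_frac = process_subject_trace(
                sub.trace, sub.schedule, config.filter, config.blink,
                config.detection, config.metrics)
            df = pd.DataFrame([r.__dict__ for r in results])
            df.insert(0, "subject", sid)
            trial_frames.append(df)
            summaries.append(aggregate_subject(
                results, config.metrics, subject_id=sid,
                missing_frac=missing_frac))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "metrics"
    try:
        pd.concat(trial_frames, ignore_index=True).to_csv(
            emit(stage, "trials.csv"), index=False)
        kept, exclusion_log = apply_subject_exclusions(summaries,
                                                       config.metrics)
        cells = pd.concat(
            [s.cells.assign(subject=s.subject_id) for s in kept],
            ignore_index=True)
        cells.to_csv(emit(stage, "subjects.csv"), index=False)
        (out / "exclusions.txt").write_text("\n".join(exclusion_log) + "\n")
        files[stage].append("exclusions.txt")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "infer"
    try:
        dv_col = "mean_srt_ms" if config.dv == "srt" else "mean_error_deg"
        long = summaries_to_long(kept, dv=dv_col, collapse=("orientation",))
        if len(kept) >= 2:
            try:
                effects = rm_anova(long, within=["tool_end", "soa_ms"])
            except ValueError as exc:
                # tiny demo designs may not fill every cell; inference is
                # then skipped rather than fabricated
                log.warning("inference skipped: %s", exc)
            else:
                effects_to_frame(effects).to_csv(
                    emit(stage, "effects.csv"), index=False)
                pairs = pairwise_t(long, factor="tool_end")
                pd.DataFrame([p.__dict__ for p in pairs]).to_csv(
                    emit(stage, "pairwise.csv"), index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest = {
        "master_seed": config.master_seed,
        "n_subjects": config.n_subjects,
        "stages": files,
        "checksums": {name: _sha256(out / name)
                      for names in files.values() for name in names},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out


def recover_condition_effect(
    n_subjects: int = 26,
    master_seed: int = 0,
    config: PipelineConfig | None = None,
) -> dict:
    """End-to-end recovery of the tool-end latency effect, in memory.

    Simulates a cohort under the configured latency model, runs
    preprocessing, saccade detection and SRT extraction, aggregates to
    subject x condition means (cells weighted equally), and returns the
    per-condition grand means plus the handle-minus-head mean SRT
    difference averaged across subjects.
    """
    cfg = config or PipelineConfig()
    summaries = []
    for sub in simulate_cohort(n_subjects, cfg.design, cfg.kinematics,
                               cfg.latency, cfg.noise,
                               master_seed=master_seed):
        results, missing_frac = process_subject_trace(
            sub.trace, sub.schedule, cfg.filter, cfg.blink,
            cfg.detection, cfg.metrics)
        summaries.append(aggregate_subject(
            results, cfg.metrics, subject_id=sub.subject_id,
            missing_frac=missing_frac))
    kept, _ = apply_subject_exclusions(summaries, cfg.metrics)
    long = summaries_to_long(kept, dv="mean_srt_ms",
                             collapse=("orientation",))
    cond = (long.groupby(["subject", "tool_end"])["dv"].mean()
            .unstack("tool_end"))
    diffs = cond["handle"] - cond["head"]
    return {
        "n_subjects": int(len(kept)),
        "condition_means_ms": cond.mean().to_dict(),
        "handle_minus_head_ms": float(diffs.mean()),
        "subject_diffs_ms": diffs.to_numpy(),
        "summaries": kept,
    }


def describe_run(run_dir) -> dict:
    """Read-only summary of a finished run; verifies checksums.

    Never recomputes: all numbers come from the stage output files.
    """
    run_dir = Path(run_dir)
    mpath = run_dir / "manifest.json"
    if not mpath.exists():
        raise FileNotFoundError(f"no manifest in {run_dir}")
    manifest = json.loads(mpath.read_text())
    mismatches = [name for name, digest in manifest["checksums"].items()
                  if not (run_dir / name).exists()
                  or _sha256(run_dir / name) != digest]
    summary: dict = {
        "n_subjects": manifest["n_subjects"],
        "master_seed": manifest["master_seed"],
        "stages": {s: len(v) for s, v in manifest["stages"].items()},
        "checksum_mismatches": mismatches,
    }
    trials = run_dir / "trials.csv"
    if trials.exists() and "trials.csv" not in mismatches:
        df = pd.read_csv(trials)
        summary["n_trials"] = int(len(df))
        summary["status_counts"] = df["status"].value_counts().to_dict()
    subjects = run_dir / "subjects.csv"
    if subjects.exists():
        cells = pd.read_csv(subjects)
        summary["condition_means"] = (
            cells.groupby("tool_end")["mean_srt_ms"].mean().round(2)
            .to_dict())
    effects = run_dir / "effects.csv"
    if effects.exists():
        summary["effects"] = pd.read_csv(effects).to_dict("records")
    return summary
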