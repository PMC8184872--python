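"""Randomised trial schedule for the 3 x 4 within-subject cueing design.

One session crosses Tool-end congruency (saccade toward the tool's head,
toward its handle, or toward a no-handle control object) with the stimulus
onset asynchrony (SOA) between image onset and the colour go-cue
(100/200/400/600 ms).  A small number of "red" catch trials (no saccade,
SOA fixed at 400 ms) maintain attention and are excluded from analysis.

Trial timeline (ms from trial start): fixation 0-500, image on at 500,
colour cue at 500+SOA, image off at 1500, return phase until 2000.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

__all__ = [
    "DesignParams",
    "TrialSpec",
    "DesignError",
    "build_schedule",
    "validate_schedule",
    "epoch_times",
    "schedule_to_frame",
    "frame_to_schedule",
    "write_schedule",
    "read_schedule",
]

TOOL_ENDS = ("head", "handle", "control", "red")
ORIENTATIONS = ("horizontal", "oblique", "none")
DIRECTIONS = ("left", "right", "none")


class DesignError(ValueError):
    """A design parameterisation violates one of its count identities."""


@dataclass(frozen=True)
class DesignParams:
    """Session structure and per-condition trial counts.

    Defaults reproduce the 10-block, 840-trial session: 320 head-congruent,
    320 handle-congruent, 160 control and 40 red (no-saccade) trials, SOAs
    100/200/400/600 ms, red trials always at 400 ms, and 12 deg lateral
    targets.
    """

    n_blocks: int = 10
    trials_per_block: int = 84
    n_head: int = 320
    n_handle: int = 320
    n_control: int = 160
    n_red: int = 40
    soas: tuple[int, ...] = (100, 200, 400, 600)
    red_soa: int = 400
    fixation_ms: int = 500
    image_ms: int = 1000
    return_ms: int = 500
    target_ecc_deg: float = 12.0
    cue_map: tuple[tuple[str, str], ...] = (
        ("blue", "left"), ("green", "right"), ("red", "none"))
    oblique_fraction: float = 0.5  # horizontal/oblique split for head+handle
    per_block_balance: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        total = self.n_head + self.n_handle + self.n_control + self.n_red
        if total != self.n_blocks * self.trials_per_block:
            raise DesignError(
                "n_head + n_handle + n_control + n_red "
                f"({total}) != n_blocks * trials_per_block "
                f"({self.n_blocks * self.trials_per_block})")
        if not self.soas or any(s <= 0 or s >= self.image_ms for s in self.soas):
            raise DesignError(
                "every SOA must be strictly positive and < image_ms")
        if self.n_red and self.red_soa not in self.soas:
            raise DesignError("red_soa must be one of soas")
        colors = [c for c, _ in self.cue_map]
        dirs = [d for _, d in self.cue_map]
        if sorted(colors) != ["blue", "green", "red"] or sorted(dirs) != [
                "left", "none", "right"]:
            raise DesignError(
                "cue_map must be a bijection {blue,green,red} -> "
                "{left,right,none}")
        if not 0.0 <= self.oblique_fraction <= 1.0:
            raise DesignError("oblique_fraction must lie in [0, 1]")

    @property
    def direction_to_color(self) -> dict[str, str]:
        return {d: c for c, d in self.cue_map}

    @property
    def trial_ms(self) -> int:
        return self.fixation_ms + self.image_ms + self.return_ms

    @classmethod
    def from_dict(cls, d: dict) -> "DesignParams":
        d = dict(d)
        if "soas" in d:
            d["soas"] = tuple(d["soas"])
        if "cue_map" in d and isinstance(d["cue_map"], dict):
            d["cue_map"] = tuple(d["cue_map"].items())
        return cls(**d)


@dataclass(frozen=True)
class TrialSpec:
    """One trial's design cell plus its epoch timestamps (ms, trial-relative)."""

    trial_id: int
    block: int
    tool_end: str
    orientation: str
    soa_ms: int
    cue_color: str
    saccade_direction: str
    image_on: int = 500
    cue_on: int = 0
    image_off: int = 1500
    trial_end: int = 2000

    @property
    def is_red(self) -> bool:
        return self.tool_end == "red"


def epoch_times(soa_ms: int, params: DesignParams) -> dict[str, int]:
    """The five trial epochs implied by a SOA under the session timing."""
    image_on = params.fixation_ms
    return {
        "fixation_on": 0,
        "image_on": image_on,
        "cue_on": image_on + soa_ms,
        "image_off": image_on + params.image_ms,
        "trial_end": image_on + params.image_ms + params.return_ms,
    }


def _condition_cells(params: DesignParams) -> list[tuple[str, str, int, str]]:
    """Expand per-condition totals into per-trial (tool_end, orientation,
    soa, direction) cells, deterministically round-robining any remainder."""
    cells: list[tuple[str, str, int, str]] = []

    def spread(n: int, slots: list[tuple[str, str, int, str]]):
        base, rem = divmod(n, len(slots))
        for i, slot in enumerate(slots):
            cells.extend([slot] * (base + (1 if i < rem else 0)))

    for tool_end, n in (("head", params.n_head), ("handle", params.n_handle)):
        n_obl = int(round(n * params.oblique_fraction))
        for orient, n_or in (("oblique", n_obl), ("horizontal", n - n_obl)):
            slots = [(tool_end, orient, soa, d)
                     for soa in params.soas for d in ("left", "right")]
            spread(n_or, slots)
    spread(params.n_control,
           [("control", "horizontal", soa, d)
            for soa in params.soas for d in ("left", "right")])
    cells.extend([("red", "none", params.red_soa, "none")] * params.n_red)
    return cells


def build_schedule(params: DesignParams | None = None) -> list[TrialSpec]:
    """Build the randomised session schedule.

    Per-condition counts match ``params`` exactly and left/right cues are
    balanced within each non-red tool-end x SOA x orientation cell.  Order
    is a uniform shuffle over the session (or within each block when
    ``per_block_balance`` is set), deterministic given ``rng_seed``.
    """
    params = params or DesignParams()
    params.validate()
    cells = _condition_cells(params)
    rng = np.random.default_rng(params.rng_seed)
    order = rng.permutation(len(cells))
    if params.per_block_balance:
        # deal conditions round-robin into blocks, then shuffle each block
        shuffled = [cells[i] for i in order]
        blocks: list[list] = [[] for _ in range(params.n_blocks)]
        for i, cell in enumerate(shuffled):
            blocks[i % params.n_blocks].append(cell)
        ordered = []
        for b in blocks:
            ordered.extend(b[i] for i in rng.permutation(len(b)))
    else:
        ordered = [cells[i] for i in order]

    d2c = params.direction_to_color
    schedule = []
    for tid, (tool_end, orient, soa, direction) in enumerate(ordered):
        ep = epoch_times(soa, params)
        schedule.append(TrialSpec(
            trial_id=tid,
            block=tid // params.trials_per_block,
            tool_end=tool_end,
            orientation=orient,
            soa_ms=soa,
            cue_color=d2c[direction],
            saccade_direction=direction,
            image_on=ep["image_on"],
            cue_on=ep["cue_on"],
            image_off=ep["image_off"],
            trial_end=ep["trial_end"],
        ))
    return schedule


def validate_schedule(schedule: list[TrialSpec],
                      params: DesignParams | None = None) -> list[str]:
    """Check a schedule against every per-trial and global invariant.

    Violations are returned as data (a list of human-readable strings),
    never raised -- a report is empty iff the schedule is consistent.
    """
    params = params or DesignParams()
    report: list[str] = []
    if not schedule:
        return ["schedule is empty"]
    d2c = params.direction_to_color
    counts = {te: 0 for te in TOOL_ENDS}
    for spec in schedule:
        tag = f"trial {spec.trial_id}"
        ep = epoch_times(spec.soa_ms, params)
        if (spec.image_on, spec.cue_on, spec.image_off, spec.trial_end) != (
                ep["image_on"], ep["cue_on"], ep["image_off"], ep["trial_end"]):
            report.append(f"{tag}: epoch timestamps inconsistent with "
                          f"soa={spec.soa_ms}")
        if spec.tool_end not in TOOL_ENDS:
            report.append(f"{tag}: unknown tool_end {spec.tool_end!r}")
            continue
        counts[spec.tool_end] += 1
        if spec.is_red:
            if spec.saccade_direction != "none":
                report.append(f"{tag}: red trial with a saccade direction")
            if spec.soa_ms != params.red_soa:
                report.append(f"{tag}: red trial with soa {spec.soa_ms} != "
                              f"{params.red_soa}")
        else:
            if spec.soa_ms not in params.soas:
                report.append(f"{tag}: soa {spec.soa_ms} not in design")
            if spec.saccade_direction not in ("left", "right"):
                report.append(f"{tag}: non-red trial without direction")
        if spec.tool_end == "control" and spec.orientation != "horizontal":
            report.append(f"{tag}: control trial must be horizontal")
        if d2c.get(spec.saccade_direction) != spec.cue_color:
            report.append(f"{tag}: cue color {spec.cue_color!r} does not map "
                          f"to direction {spec.saccade_direction!r}")
    expected = {"head": params.n_head, "handle": params.n_handle,
                "control": params.n_control, "red": params.n_red}
    for te, n in expected.items():
        if counts[te] != n:
            report.append(f"count mismatch: {counts[te]} {te} trials, "
                          f"expected {n}")
    n_total = params.n_blocks * params.trials_per_block
    if len(schedule) != n_total:
        report.append(f"count mismatch: {len(schedule)} trials, expected "
                      f"{n_total}")
    # left/right balance within each non-red cell
    lr: dict[tuple, int] = {}
    for spec in schedule:
        if spec.saccade_direction in ("left", "right"):
            key = (spec.tool_end, spec.orientation, spec.soa_ms)
            lr[key] = lr.get(key, 0) + (1 if spec.saccade_direction == "left"
                                        else -1)
    for key, imbalance in lr.items():
        if abs(imbalance) > 1:  # odd cell sizes allow a 1-trial imbalance
            report.append(f"left/right imbalance of {imbalance} in cell {key}")
    return report


_COLUMNS = ["trial_id", "block", "tool_end", "orientation", "soa_ms",
            "cue_color", "direction", "image_on_ms", "cue_on_ms",
            "image_off_ms", "trial_end_ms"]


def schedule_to_frame(schedule: list[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.trial_id, s.block, s.tool_end, s.orientation, s.soa_ms,
          s.cue_color, s.saccade_direction, s.image_on, s.cue_on,
          s.image_off, s.trial_end) for s in schedule],
        columns=_COLUMNS)


def frame_to_schedule(df: pd.DataFrame) -> list[TrialSpec]:
    return [TrialSpec(
        trial_id=int(r.trial_id), block=int(r.block), tool_end=r.tool_end,
        orientation=r.orientation, soa_ms=int(r.soa_ms), cue_color=r.cue_color,
        saccade_direction=r.direction, image_on=int(r.image_on_ms),
        cue_on=int(r.cue_on_ms), image_off=int(r.image_off_ms),
        trial_end=int(r.trial_end_ms)) for r in df.itertuples(index=False)]


def write_schedule(schedule: list[TrialSpec], path) -> None:
    schedule_to_frame(schedule).to_csv(path, index=False)


def read_schedule(path) -> list[TrialSpec]:
    return frame_to_schedule(pd.read_csv(path))
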