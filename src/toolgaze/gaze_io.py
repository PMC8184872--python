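"""Raw gaze-sample I/O and screen-geometry conversions.

Conventions used throughout the package:

* pixel coordinates are 0-based indices with the origin at the top-left
  corner and y increasing downward (screen convention);
* visual degrees are measured from the screen centre with right/up
  positive, using a per-axis tangent model about the centre (not the
  small-angle linearisation -- at the 12 deg eccentricities used here the
  linearisation error is not negligible);
* a gaze trace is a uniformly sampled time series; samples where the
  tracker lost the eye carry no finite position and are flagged missing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "ScreenGeometry",
    "GazeTrace",
    "px_to_deg",
    "deg_to_px",
    "read_gaze_table",
    "write_gaze_table",
]


@dataclass(frozen=True)
class ScreenGeometry:
    """Display panel and viewing geometry of the recording setup.

    Defaults describe a 23-inch 1920x1080 panel viewed from 670 mm, the
    class of remote tracker this pipeline targets.  The physical panel
    size is configurable because the degree-per-pixel scale depends on it.
    """

    width_px: int = 1920
    height_px: int = 1080
    width_mm: float = 509.0
    height_mm: float = 286.0
    viewing_distance_mm: float = 670.0
    small_angle: bool = False  # linearised conversion instead of tangent

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm",
                     "viewing_distance_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be positive")

    @property
    def center_px(self) -> tuple[float, float]:
        return ((self.width_px - 1) / 2.0, (self.height_px - 1) / 2.0)

    @property
    def mm_per_px(self) -> tuple[float, float]:
        return (self.width_mm / self.width_px, self.height_mm / self.height_px)


def px_to_deg(x_px, y_px, geometry: ScreenGeometry):
    """Convert screen-pixel coordinates to visual degrees from centre.

    Per-axis: ``deg = atan((p - center) * mm_per_px / distance)``.
    y is flipped so that up is positive.
    """
    cx, cy = geometry.center_px
    mmx, mmy = geometry.mm_per_px
    d = geometry.viewing_distance_mm
    tx = (np.asarray(x_px, dtype=float) - cx) * mmx / d
    ty = (cy - np.asarray(y_px, dtype=float)) * mmy / d
    if geometry.small_angle:
        return np.degrees(tx), np.degrees(ty)
    return np.degrees(np.arctan(tx)), np.degrees(np.arctan(ty))


def deg_to_px(x_deg, y_deg, geometry: ScreenGeometry):
    """Inverse of :func:`px_to_deg` (exact up to floating point)."""
    cx, cy = geometry.center_px
    mmx, mmy = geometry.mm_per_px
    d = geometry.viewing_distance_mm
    if geometry.small_angle:
        tx = np.radians(np.asarray(x_deg, dtype=float))
        ty = np.radians(np.asarray(y_deg, dtype=float))
    else:
        tx = np.tan(np.radians(np.asarray(x_deg, dtype=float)))
        ty = np.tan(np.radians(np.asarray(y_deg, dtype=float)))
    return cx + tx * d / mmx, cy - ty * d / mmy


@dataclass
class GazeTrace:
    """Uniformly sampled cyclopean gaze position with missing-sample flags.

    ``x``/``y`` are NaN wherever ``missing`` is True.  ``unit`` is either
    ``"px"`` or ``"deg"``.  ``trial_id`` is optional per-sample trial
    membership for continuous recordings.
    """

    t_ms: np.ndarray
    x: np.ndarray
    y: np.ndarray
    missing: np.ndarray
    unit: str = "deg"
    sample_rate: float = 300.0
    trial_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        n = len(self.t_ms)
        if not (len(self.x) == len(self.y) == len(self.missing) == n):
            raise ValueError("GazeTrace arrays must have equal length")
        # missing samples must not carry positions
        self.x[self.missing] = np.nan
        self.y[self.missing] = np.nan
        self.missing = self.missing | ~np.isfinite(self.x) | ~np.isfinite(self.y)

    def __len__(self) -> int:
        return len(self.t_ms)

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sample_rate

    def copy(self) -> "GazeTrace":
        return replace(
            self,
            t_ms=self.t_ms.copy(),
            x=self.x.copy(),
            y=self.y.copy(),
            missing=self.missing.copy(),
            trial_id=None if self.trial_id is None else self.trial_id.copy(),
        )

    def to_deg(self, geometry: ScreenGeometry) -> "GazeTrace":
        if self.unit == "deg":
            return self
        out = self.copy()
        out.x, out.y = px_to_deg(self.x, self.y, geometry)
        out.unit = "deg"
        return out

    def to_px(self, geometry: ScreenGeometry) -> "GazeTrace":
        if self.unit == "px":
            return self
        out = self.copy()
        out.x, out.y = deg_to_px(self.x, self.y, geometry)
        out.unit = "px"
        return out

    def segment(self, start: int, stop: int) -> "GazeTrace":
        """Slice [start, stop) keeping metadata."""
        return GazeTrace(
            t_ms=self.t_ms[start:stop],
            x=self.x[start:stop].copy(),
            y=self.y[start:stop].copy(),
            missing=self.missing[start:stop].copy(),
            unit=self.unit,
            sample_rate=self.sample_rate,
            trial_id=None if self.trial_id is None
            else self.trial_id[start:stop],
        )


DEFAULT_COLUMNS = {
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "validity": "validity",
    "trial_id": "trial_id",
}

JITTER_TOL = 0.01  # fractional deviation of the sampling step


def _check_timing(t_ms: np.ndarray, sample_rate: float) -> None:
    dt = np.diff(t_ms)
    if len(dt) == 0:
        return
    if np.any(dt <= 0):
        raise ValueError("gaze table timestamps are not strictly increasing")
    nominal = 1000.0 / sample_rate
    worst = np.max(np.abs(dt - nominal)) / nominal
    if worst > JITTER_TOL:
        warnings.warn(
            f"sampling jitter {worst:.1%} exceeds {JITTER_TOL:.0%} of the "
            f"nominal {nominal:.3f} ms step",
            stacklevel=3,
        )


def read_gaze_table(
    path,
    column_map: dict[str, str] | None = None,
    geometry: ScreenGeometry | None = None,
    unit: str = "px",
    sample_rate: float = 300.0,
    sep: str = ",",
) -> GazeTrace:
    """Read a delimited raw gaze table into a :class:`GazeTrace`.

    The table needs timestamp, x, y and validity columns (names remappable
    through ``column_map``).  Binocular exports may instead provide
    ``x_left/y_left/validity_left`` and ``x_right/...`` pairs, which are
    averaged into one cyclopean trace; a single valid eye is used when the
    other is lost.  Validity follows the tracker convention: 0 = valid,
    anything else = lost.  Timestamps are normalised to ms from the first
    sample.  If ``geometry`` is given and ``unit == "px"`` the positions
    are converted to degrees.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, sep=sep)

    binocular = f"{cols['x']}_left" in df.columns
    required = [cols["timestamp"]]
    if binocular:
        required += [f"{cols[c]}_{eye}" for c in ("x", "y", "validity")
                     for eye in ("left", "right")]
    else:
        required += [cols["x"], cols["y"], cols["validity"]]
    for c in required:
        if c not in df.columns:
            raise ValueError(f"gaze table is missing required column {c!r}")
    known = set(required) | {cols["trial_id"]}
    extra = [c for c in df.columns if c not in known]
    if extra:
        log.warning("ignoring unknown gaze-table columns: %s", extra)

    t = df[cols["timestamp"]].to_numpy(dtype=float)
    t = t - t[0]
    _check_timing(t, sample_rate)

    if binocular:
        x, y, miss = _combine_eyes(df, cols)
    else:
        x = df[cols["x"]].to_numpy(dtype=float)
        y = df[cols["y"]].to_numpy(dtype=float)
        miss = (df[cols["validity"]].to_numpy() != 0) | ~np.isfinite(x) | ~np.isfinite(y)

    trial_id = None
    if cols["trial_id"] in df.columns:
        trial_id = df[cols["trial_id"]].to_numpy()

    trace = GazeTrace(t, x, y, miss, unit=unit, sample_rate=sample_rate,
                      trial_id=trial_id)
    if geometry is not None and unit == "px":
        trace = trace.to_deg(geometry)
    return trace


def _combine_eyes(df: pd.DataFrame, cols: dict[str, str]):
    """Average both eyes where valid; use the single valid eye otherwise."""
    out = {}
    valid = {}
    for eye in ("left", "right"):
        xe = df[f"{cols['x']}_{eye}"].to_numpy(dtype=float)
        ye = df[f"{cols['y']}_{eye}"].to_numpy(dtype=float)
        ve = (df[f"{cols['validity']}_{eye}"].to_numpy() == 0)
        ve &= np.isfinite(xe) & np.isfinite(ye)
        out[eye] = (xe, ye)
        valid[eye] = ve
    both = valid["left"] & valid["right"]
    left_only = valid["left"] & ~valid["right"]
    right_only = valid["right"] & ~valid["left"]
    n = len(df)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    x[both] = 0.5 * (out["left"][0][both] + out["right"][0][both])
    y[both] = 0.5 * (out["left"][1][both] + out["right"][1][both])
    x[left_only] = out["left"][0][left_only]
    y[left_only] = out["left"][1][left_only]
    x[right_only] = out["right"][0][right_only]
    y[right_only] = out["right"][1][right_only]
    return x, y, ~(both | left_only | right_only)


def write_gaze_table(trace: GazeTrace, path, sep: str = ",") -> None:
    """Write a trace back to the delimited raw format (validity 0/4)."""
    df = pd.DataFrame(
        {
            "timestamp": trace.t_ms,
            "x": trace.x,
            "y": trace.y,
            "validity": np.where(trace.missing, 4, 0),
        }
    )
    if trace.trial_id is not None:
        df["trial_id"] = trace.trial_id
    df.to_csv(path, sep=sep, index=False)
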