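"""Logan graphical reference-tissue quantification of BP_ND.

The classic Logan plot linearizes reversible-tracer kinetics: with
cumulative trapezoid integrals anchored at zero activity at t=0,

    y(t) = int_0^t C_target / C_target(t)
    x(t) = int_0^t C_ref    / C_target(t)

becomes linear at late times with slope equal to the distribution volume
ratio (DVR); the binding potential is ``BP_ND = DVR - 1``. The k2'
correction term is omitted (the conventional choice for raclopride with a
cerebellar reference at late fit windows); the fit start ``t_star`` is
configuration, default 18 min.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    DivisionByZeroActivityError,
    EmptyRoiError,
    InsufficientFramesError,
    InvalidSpecError,
)
from .frames import FrameSchedule
from .regions import REGIONS

logger = logging.getLogger(__name__)

__all__ = ["TimeActivityCurve", "logan_bp", "logan_points", "roi_median_bp",
           "read_tac_csv", "write_tac_csv"]


@dataclass
class TimeActivityCurve:
    """Regional tracer concentration per frame.

    ``activity`` is in kBq/mL at the frames of ``schedule``; negative frame
    values (noise) are clamped to zero before any integration, and the clamp
    is logged.
    """

    activity: np.ndarray
    schedule: FrameSchedule
    label: str = ""
    n_clamped: int = field(init=False, default=0)

    def __post_init__(self) -> None:
        act = np.asarray(self.activity, dtype=float)
        if act.ndim != 1 or act.size != self.schedule.n_frames:
            raise InvalidSpecError(
                f"activity length {act.size} != schedule frames {self.schedule.n_frames}"
            )
        neg = act < 0
        if neg.any():
            logger.info("TAC %r: clamped %d negative frame value(s) to 0", self.label, int(neg.sum()))
            act = np.where(neg, 0.0, act)
        self.n_clamped = int(neg.sum())
        self.activity = act

    @property
    def mid_times_min(self) -> np.ndarray:
        return self.schedule.mid_times_min


def _cumtrapz_from_zero(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Cumulative trapezoid of y(t) anchored at (t=0, y=0)."""
    tt = np.concatenate([[0.0], t])
    yy = np.concatenate([[0.0], y])
    return np.cumsum(np.diff(tt) * (yy[1:] + yy[:-1]) / 2.0)


def logan_points(
    target: TimeActivityCurve, reference: TimeActivityCurve
) -> tuple[np.ndarray, np.ndarray]:
    """Transformed (x, y) Logan coordinates at every frame mid-time.

    Frames where the target activity is zero are returned as NaN; the fit
    routine raises on them only if they fall inside the fit window.
    """
    t = target.mid_times_min
    ct = target.activity
    cr = reference.activity
    int_ct = _cumtrapz_from_zero(ct, t)
    int_cr = _cumtrapz_from_zero(cr, t)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(ct > 0, int_cr / ct, np.nan)
        y = np.where(ct > 0, int_ct / ct, np.nan)
    return x, y


def logan_bp(
    target: TimeActivityCurve,
    reference: TimeActivityCurve,
    schedule: FrameSchedule | None = None,
    t_star: float = 18.0,
) -> float:
    """Estimate BP_ND (= DVR - 1) by OLS on the Logan transform after ``t_star`` minutes.

    Raises
    ------
    InsufficientFramesError
        Fewer than 3 frames have mid-time >= t_star.
    DivisionByZeroActivityError
        A fit-window frame has zero target activity (names the frame index).
    """
    schedule = schedule or target.schedule
    t = schedule.mid_times_min
    window = t >= t_star
    if window.sum() < 3:
        raise InsufficientFramesError(
            f"need >=3 frames with mid-time >= {t_star} min, got {int(window.sum())}"
        )
    if not np.any(reference.activity[window] > 0):
        raise InvalidSpecError("reference TAC is identically zero on the fit window")
    zero = window & (target.activity <= 0)
    if zero.any():
        idx = int(np.flatnonzero(zero)[0])
        raise DivisionByZeroActivityError(f"zero target activity at frame {idx} in fit window")
    x, y = logan_points(target, reference)
    xw, yw = x[window], y[window]
    slope = np.polyfit(xw, yw, 1)[0]
    return float(slope - 1.0)


def roi_median_bp(
    voxel_bp: Mapping[int, float] | np.ndarray,
    labels: Mapping[int, str] | np.ndarray,
    regions: tuple[str, ...] = REGIONS,
) -> pd.Series:
    """Reduce a voxelwise BP_ND map to per-region medians.

    ``voxel_bp`` maps voxel index to BP estimate; ``labels`` maps voxel index
    to region name (unlabeled voxels — absent or empty label — are ignored).
    Every requested region must own at least one voxel.
    """
    if isinstance(voxel_bp, np.ndarray):
        voxel_bp = dict(enumerate(voxel_bp.ravel()))
    if isinstance(labels, np.ndarray):
        labels = dict(enumerate(labels.ravel()))
    per_region: dict[str, list[float]] = {r: [] for r in regions}
    for vox, region in labels.items():
        if region in per_region and vox in voxel_bp:
            per_region[region].append(float(voxel_bp[vox]))
    out = {}
    for region in regions:
        if not per_region[region]:
            raise EmptyRoiError(f"region {region!r} has no labelled voxels")
        out[region] = float(np.median(per_region[region]))
    return pd.Series(out, name="bp_nd")


def write_tac_csv(path, schedule: FrameSchedule, tacs: Mapping[str, np.ndarray]) -> None:
    """Write TACs as CSV: frame, start_s, duration_s, then one column per region."""
    df = pd.DataFrame(
        {
            "frame": np.arange(schedule.n_frames),
            "start_s": schedule.frame_starts,
            "duration_s": schedule.frame_durations,
        }
    )
    for name, act in tacs.items():
        df[name] = np.asarray(act, dtype=float)
    df.to_csv(path, index=False)


def read_tac_csv(path) -> tuple[FrameSchedule, dict[str, TimeActivityCurve]]:
    """Read the TAC CSV written by :func:`write_tac_csv`."""
    df = pd.read_csv(path)
    schedule = FrameSchedule(df["start_s"].to_numpy(), df["duration_s"].to_numpy())
    curves = {}
    for col in df.columns:
        if col in ("frame", "start_s", "duration_s"):
            continue
        curves[col] = TimeActivityCurve(df[col].to_numpy(), schedule, label=col)
    return schedule, curves
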