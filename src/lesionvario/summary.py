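"""Pattern-level summaries in ln(a)-ln(c) space.

Each pattern yields three (range, sill) pairs, one per grid axis.  On
natural-log axes both marginals are close to normal across realistic
cohorts, so the pattern is summarized by the mean center (the per-coordinate
arithmetic mean of the three points) and the standard distance

    SD = sqrt( mean_i (a_i - a_bar)^2 + mean_i (c_i - c_bar)^2 ),

the bivariate analog of a standard deviation: 0 for a perfectly isotropic
pattern, growing with geometric anisotropy.

The sill doubles as a total-lesion-load (TLL) nomogram.  For a binary
pattern with foreground fraction p the theoretical sill is the indicator
variance p(1-p) ~ p at small p, so V ~ c_bar * N_voxels * voxel_volume; a
cohort-calibrated linear mapping can replace this analytic default.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .masks import GridSpec
from .models import VariogramModelFit

Point = tuple[float, float]


@dataclass(frozen=True)
class PatternSummary:
    """Mean center, standard distance and TLL estimate for one pattern."""

    id: str
    mean_ln_a: float
    mean_ln_c: float
    sd: float
    tll_estimate_mm3: float
    per_axis: tuple[Point, Point, Point]
    sd_class: int | None = None
    exam_date: _dt.date | None = None


def _check_triple(points: Sequence[Point]) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.shape != (3, 2):
        raise ValueError(f"expected exactly three (x, y) points, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates in summary points")
    return pts


def mean_center(points: Sequence[Point]) -> Point:
    """Per-coordinate arithmetic mean of three points."""
    pts = _check_triple(points)
    center = pts.mean(axis=0)
    return float(center[0]), float(center[1])


def standard_distance(points: Sequence[Point]) -> float:
    """Root of the summed per-coordinate mean squared deviations.

    Zero exactly when the three points coincide.
    """
    pts = _check_triple(points)
    if (pts == pts[0]).all():  # coincident triple: exactly zero, no roundoff
        return 0.0
    dev = pts - pts.mean(axis=0)
    return float(np.sqrt(np.mean(dev[:, 0] ** 2) + np.mean(dev[:, 1] ** 2)))


def tll_from_sill(
    c_bar: float,
    grid: GridSpec,
    calibration: tuple[float, float] | None = None,
) -> float:
    """Total lesion load (mm³) from a mean sill.

    Default analytic mapping: V ~ c_bar * N_voxels * voxel_volume, from the
    small-p indicator-variance identity c ~ p(1-p) ~ p.  With
    ``calibration = (slope, intercept)`` from a cohort regression of volume
    on sill, the linear mapping slope * c_bar + intercept is used instead
    (clipped at zero).
    """
    if c_bar < 0:
        raise ValueError(f"mean sill must be nonnegative, got {c_bar}")
    if calibration is not None:
        slope, intercept = calibration
        return max(0.0, slope * c_bar + intercept)
    return c_bar * grid.n_voxels * grid.voxel_volume_mm3


def calibrate_tll(
    sills: Iterable[float], volumes_mm3: Iterable[float]
) -> tuple[tuple[float, float], float]:
    """Least-squares line of volume on mean sill over a cohort.

    Returns ((slope, intercept), r2) — the empirical-nomogram analog of the
    analytic mapping.
    """
    c = np.asarray(list(sills), dtype=float)
    v = np.asarray(list(volumes_mm3), dtype=float)
    if c.size < 2:
        raise ValueError("calibration needs at least two patterns")
    slope, intercept = np.polyfit(c, v, 1)
    pred = slope * c + intercept
    ss_res = float(np.sum((v - pred) ** 2))
    ss_tot = float(np.sum((v - v.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return (float(slope), float(intercept)), r2


def classify_sd(sd: float, thresholds: Sequence[float]) -> int:
    """Ordinal anisotropy class: 1 (most isotropic) .. len(thresholds)+1."""
    ts = sorted(thresholds)
    return 1 + int(np.searchsorted(ts, sd, side="right"))


def sd_quartile_thresholds(sds: Iterable[float]) -> tuple[float, float, float]:
    """Batch-quartile class boundaries (4 classes) for SD symbols."""
    arr = np.asarray(list(sds), dtype=float)
    if arr.size == 0:
        raise ValueError("no SD values to classify")
    q1, q2, q3 = np.percentile(arr, [25, 50, 75])
    return float(q1), float(q2), float(q3)


def summarize(
    fits: Sequence[VariogramModelFit],
    grid: GridSpec,
    pattern_id: str = "",
    log_space: bool = True,
    sd_thresholds: Sequence[float] | None = None,
    calibration: tuple[float, float] | None = None,
    exam_date: _dt.date | None = None,
) -> PatternSummary:
    """Reduce three per-axis fits to a :class:`PatternSummary`.

    With ``log_space`` (the default) the mean center and SD are computed on
    (ln a, ln c), the coordinates of the a-c plot and LDP.  All three fits
    must have converged.
    """
    if len(fits) != 3:
        raise ValueError(f"expected three directional fits, got {len(fits)}")
    bad = [f.axis for f in fits if not f.converged]
    if bad:
        raise ValueError(f"pattern {pattern_id!r}: non-converged fit(s) on axes {bad}")
    if log_space:
        points = tuple((f.ln_a, f.ln_c) for f in fits)
    else:
        points = tuple((f.a, f.c) for f in fits)
    a_bar, c_bar = mean_center(points)
    sd = standard_distance(points)
    mean_sill = float(np.mean([f.c for f in fits]))
    tll = tll_from_sill(mean_sill, grid, calibration)
    sd_class = classify_sd(sd, sd_thresholds) if sd_thresholds is not None else None
    return PatternSummary(pattern_id, a_bar, c_bar, sd, tll, points, sd_class, exam_date)


def summaries_to_frame(summaries: Iterable[PatternSummary]) -> pd.DataFrame:
    rows = [
        {
            "id": s.id,
            "date": s.exam_date.isoformat() if s.exam_date else "",
            "mean_ln_a": s.mean_ln_a,
            "mean_ln_c": s.mean_ln_c,
            "sd": s.sd,
            "sd_class": s.sd_class if s.sd_class is not None else "",
            "tll_estimate_mm3": s.tll_estimate_mm3,
        }
        for s in summaries
    ]
    return pd.DataFrame(rows)
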