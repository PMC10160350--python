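"""Percentile-based size estimation and its calibration.

A video of one free-swimming animal yields many per-frame length estimates.
Because the animal rotates freely in three dimensions, most projected
lengths undershoot the true body length (the silhouette is foreshortened
whenever the long axis tilts out of the image plane), while occasional
overshoots come from segmentation failures such as an unremoved spine.  The
distribution is therefore skewed and neither the mean nor the median tracks
the true length; a high percentile does.

Calibration finds, for a set of individuals with paired manual measurements,
the integer percentile in [50, 100] whose per-video value minimises the
summed absolute difference to the manual lengths.  That percentile is then
fixed per taxon (and per mounted set-up) and reported as the size estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "SizeDistribution",
    "CalibrationPair",
    "CalibrationResult",
    "SummarySizeRow",
    "percentile",
    "summarize_video",
    "find_optimal_percentile",
    "assess",
]

PERCENTILE_GRID = range(50, 101)


@dataclass(frozen=True)
class SizeDistribution:
    """All accepted per-frame lengths (mm) for one video."""

    video_name: str
    lengths_mm: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths_mm):
            raise ValueError("lengths must be positive")
        object.__setattr__(self, "lengths_mm", tuple(float(v) for v in self.lengths_mm))

    @property
    def n_frames(self) -> int:
        return len(self.lengths_mm)


@dataclass(frozen=True)
class CalibrationPair:
    """One individual: manual length (mm) + its video length distribution."""

    manual_mm: float
    distribution: SizeDistribution

    def __post_init__(self) -> None:
        if self.manual_mm <= 0:
            raise ValueError("manual_mm must be positive")
        if self.distribution.n_frames == 0:
            raise ValueError("distribution must be non-empty")


@dataclass(frozen=True)
class CalibrationResult:
    """Outcome of the percentile scan.

    ``objective_by_percentile`` maps each integer percentile in [50, 100]
    to the summed absolute difference (mm) between manual lengths and that
    percentile of each video distribution; ``optimal_percentile`` is its
    argmin (ties broken toward the lower percentile).
    """

    optimal_percentile: int
    objective_by_percentile: dict[int, float]
    n_pairs: int

    def summary(self) -> str:
        lines = [
            f"Percentile calibration on {self.n_pairs} paired individuals",
            f"optimal percentile: {self.optimal_percentile}",
            f"objective at optimum: {self.objective_by_percentile[self.optimal_percentile]:.4f} mm",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class SummarySizeRow:
    """One video's final size estimate."""

    video_name: str
    species: str
    percentile_used: int
    length_mm: float | None
    n_frames: int
    width_mm: float | None = None
    low_support: bool = False


def percentile(values, p: float, mode: str = "linear") -> float:
    """Percentile of a multiset by linear interpolation of order statistics.

    With sorted values v(1..n) and h = (n-1)p/100, the result is
    v(floor(h)+1) + frac(h) * (v(floor(h)+2) - v(floor(h)+1)); p=100 gives
    the maximum.  ``mode='nearest'`` switches to nearest-rank for
    sensitivity checks.
    """
    vals = sorted(float(v) for v in values)
    n = len(vals)
    if n == 0:
        raise ValueError("percentile of an empty multiset is undefined")
    if not (0 <= p <= 100):
        raise ValueError("percentile must lie in [0, 100]")
    h = (n - 1) * p / 100.0
    lo = math.floor(h)
    if mode == "linear":
        if lo + 1 >= n:
            return vals[-1]
        frac = h - lo
        return vals[lo] + frac * (vals[lo + 1] - vals[lo])
    if mode == "nearest":
        return vals[min(n - 1, round(h))]
    raise ValueError(f"unknown percentile mode: {mode!r}")


def summarize_video(
    dist: SizeDistribution,
    profile,
    min_support: int = 10,
    include_width: bool = False,
    widths_mm=None,
) -> SummarySizeRow:
    """Collapse a per-video length distribution to one summary row.

    The estimate is the profile's calibrated percentile of the accepted
    lengths.  Videos with fewer than ``min_support`` accepted frames are
    flagged low-support but still reported; empty distributions give a row
    with a missing length.
    """
    if dist.n_frames == 0:
        return SummarySizeRow(
            video_name=dist.video_name,
            species=profile.name,
            percentile_used=profile.optimal_percentile,
            length_mm=None,
            n_frames=0,
            low_support=True,
        )
    length = percentile(dist.lengths_mm, profile.optimal_percentile)
    width = None
    if include_width and widths_mm:
        width = percentile(widths_mm, profile.optimal_percentile)
    return SummarySizeRow(
        video_name=dist.video_name,
        species=profile.name,
        percentile_used=profile.optimal_percentile,
        length_mm=length,
        n_frames=dist.n_frames,
        width_mm=width,
        low_support=dist.n_frames < min_support,
    )


def find_optimal_percentile(pairs: list[CalibrationPair]) -> CalibrationResult:
    """Exhaustive scan of integer percentiles 50..100.

    For each candidate p the objective is sum_i |manual_i - Q_p(lengths_i)|;
    the returned optimum is the exact argmin with ties broken toward the
    lower percentile, so results are deterministic.
    """
    if not pairs:
        raise ValueError("calibration requires at least one pair")
    objective: dict[int, float] = {}
    for p in PERCENTILE_GRID:
        objective[p] = float(
            sum(abs(pair.manual_mm - percentile(pair.distribution.lengths_mm, p)) for pair in pairs)
        )
    optimal = min(PERCENTILE_GRID, key=lambda p: (objective[p], p))
    return CalibrationResult(
        optimal_percentile=optimal, objective_by_percentile=objective, n_pairs=len(pairs)
    )


#: size-class edges (mm) used in accuracy reporting: small (<2), medium
#: (2-3), large (>3)
ASSESS_BIN_EDGES = (2.0, 3.0)


@dataclass(frozen=True)
class AssessmentReport:
    """Agreement statistics between manual and video size estimates."""

    pearson_r: float | None
    r_squared: float | None
    n: int
    bins: dict[str, dict[str, float]] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Assessment on {self.n} paired estimates"]
        r = "undefined" if self.pearson_r is None else f"{self.pearson_r:.3f}"
        r2 = "undefined" if self.r_squared is None else f"{self.r_squared:.3f}"
        lines.append(f"Pearson r = {r}; linear-fit R^2 = {r2}")
        for name, b in self.bins.items():
            lines.append(
                f"  {name}: n={int(b['n'])}, mean |diff| = {b['mean_abs_diff_mm']:.3f} mm "
                f"({b['relative_pct_diff']:.2f}% of mean size)"
            )
        return "\n".join(lines)


def assess(manual_mm, estimate_mm) -> AssessmentReport:
    """Compare video estimates with manual measurements.

    Reports the Pearson correlation, the R^2 of a linear fit of estimate on
    manual length, and per-size-class mean absolute difference plus the
    relative percentage difference (mean difference / mean size x 100) for
    the <2 mm, 2-3 mm and >3 mm classes.
    """
    manual = np.asarray(manual_mm, dtype=float)
    est = np.asarray(estimate_mm, dtype=float)
    if manual.shape != est.shape or manual.ndim != 1:
        raise ValueError("manual and estimate must be 1D arrays of equal length")
    if manual.size < 3:
        raise ValueError("assessment requires at least 3 pairs")
    if np.ptp(manual) == 0 or np.ptp(est) == 0:
        pearson = None
        r2 = None
    else:
        pearson = float(stats.pearsonr(manual, est).statistic)
        fit = stats.linregress(manual, est)
        r2 = float(fit.rvalue**2)
    lo, hi = ASSESS_BIN_EDGES
    masks = {
        "<2 mm": manual < lo,
        "2-3 mm": (manual >= lo) & (manual <= hi),
        ">3 mm": manual > hi,
    }
    bins: dict[str, dict[str, float]] = {}
    for name, sel in masks.items():
        if not sel.any():
            continue
        diffs = np.abs(manual[sel] - est[sel])
        mean_size = float(manual[sel].mean())
        bins[name] = {
            "n": float(sel.sum()),
            "mean_size_mm": mean_size,
            "mean_abs_diff_mm": float(diffs.mean()),
            "relative_pct_diff": float(diffs.mean() / mean_size * 100.0),
        }
    return AssessmentReport(pearson_r=pearson, r_squared=r2, n=int(manual.size), bins=bins)
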