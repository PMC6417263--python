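"""Presence-only evaluation of suitability rasters.

Occurrence records for invasive mosquitoes come without verified
absences, so standard discrimination metrics (AUC/ROC) would require
fabricating pseudo-absences; that is deliberately not done here.
Instead two presence-only measures are computed:

``exactness``
    the mean predicted suitability at the collection sites -- a fit
    measure: a good model predicts high values where the species was
    actually found.

``selectivity``
    take the threshold below which the lowest 10% of point predictions
    fall, and report the fraction of the study area (non-nodata cells)
    predicted strictly below that threshold -- a discrimination measure:
    a good model keeps most of the map "unsuitable" while still covering
    nearly all occurrences.

Supporting diagnostics: value histograms at points vs the whole area
(used to shape membership functions) and cumulative gain curves for
comparing models at the same points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from fuzzyhab.raster_core import GridRaster, require_aligned

__all__ = [
    "PresencePoints",
    "EvaluationReport",
    "sample_raster_at_points",
    "exactness",
    "selectivity",
    "value_histograms",
    "cumulative_gain",
    "evaluate",
    "EmptySampleError",
]


class EmptySampleError(ValueError):
    """No usable presence point falls on a data cell of the raster."""


@dataclass(frozen=True)
class PresencePoints:
    """Species collection coordinates (x, y) in the analysis CRS.

    ``source`` optionally tags each record (e.g. active vs passive
    monitoring); it is carried through but not used by the metrics.
    """

    x: np.ndarray
    y: np.ndarray
    source: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return self.x.size

    @classmethod
    def from_csv(cls, path: str) -> "PresencePoints":
        df = pd.read_csv(path)
        if not {"x", "y"} <= set(df.columns):
            raise ValueError(f"{path}: need columns 'x' and 'y'")
        source = tuple(df["source"]) if "source" in df.columns else None
        return cls(df["x"].to_numpy(), df["y"].to_numpy(), source)

    def to_csv(self, path: str) -> None:
        df = pd.DataFrame({"x": self.x, "y": self.y})
        if self.source is not None:
            df["source"] = list(self.source)
        df.to_csv(path, index=False)


def sample_raster_at_points(r: GridRaster, pts: PresencePoints,
                            return_info: bool = False):
    """Value of the containing cell for each point.

    The containing cell follows the package's half-open convention (a
    point on a shared vertical edge belongs to the right cell, on a
    shared horizontal edge to the cell above).  Points outside the
    raster extent or on nodata cells are excluded; their counts are
    available with ``return_info=True``.  Raises
    :class:`EmptySampleError` when nothing remains.
    """
    rows, cols = r.index_of(pts.x, pts.y)
    nrows, ncols = r.shape
    inside = (rows >= 0) & (rows < nrows) & (cols >= 0) & (cols < ncols)
    n_outside = int((~inside).sum())
    values = r.values[rows[inside], cols[inside]]
    nodata = r.nodata_mask()[rows[inside], cols[inside]]
    n_nodata = int(nodata.sum())
    sampled = np.asarray(values[~nodata], dtype=float)
    if sampled.size == 0:
        raise EmptySampleError(
            f"no usable point: {n_outside} outside the extent, "
            f"{n_nodata} on nodata cells"
        )
    if return_info:
        return sampled, {"n_outside": n_outside, "n_nodata": n_nodata,
                         "n_used": int(sampled.size)}
    return sampled


def exactness(r: GridRaster, pts: PresencePoints) -> float:
    """Mean predicted value at the presence points."""
    return float(np.mean(sample_raster_at_points(r, pts)))


def _lower_quantile(values: np.ndarray, q: float) -> float:
    """Type-1 (inverse empirical CDF, no interpolation) lower quantile."""
    v = np.sort(np.asarray(values, dtype=float))
    k = max(1, math.ceil(q * v.size))
    return float(v[k - 1])


def selectivity(r: GridRaster, pts: PresencePoints,
                lowest_fraction: float = 0.10,
                return_threshold: bool = False):
    """Fraction of the study area strictly below the point-quantile threshold.

    The threshold is the type-1 empirical ``lowest_fraction`` quantile of
    the predictions at the points; the study area is the set of
    non-nodata cells.  Strictly-below is used, so a constant raster has
    selectivity 0 regardless of the points.
    """
    values = sample_raster_at_points(r, pts)
    if lowest_fraction <= 0 or lowest_fraction >= 1:
        raise ValueError("lowest_fraction must be in (0, 1)")
    t = _lower_quantile(values, lowest_fraction)
    area = r.data_values()
    frac = float((area < t).mean())
    if return_threshold:
        return frac, t
    return frac


def value_histograms(r: GridRaster, pts: PresencePoints,
                     bins: int = 20) -> dict:
    """Normalised value distributions: whole study area vs presence points.

    Both histograms share one bin grid covering [min, max] of the
    raster's data cells, so the curves are directly comparable (the
    diagnostic from which the membership functions were shaped).
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    area = r.data_values()
    points = sample_raster_at_points(r, pts)
    lo, hi = float(area.min()), float(area.max())
    if hi <= lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, bins + 1)
    h_area, _ = np.histogram(area, bins=edges)
    h_pts, _ = np.histogram(np.clip(points, lo, hi), bins=edges)
    return {
        "bin_edges": edges,
        "area": h_area / max(h_area.sum(), 1),
        "points": h_pts / max(h_pts.sum(), 1),
    }


def cumulative_gain(rasters: dict[str, GridRaster],
                    pts: PresencePoints) -> dict[str, np.ndarray]:
    """Descending sorted point predictions per raster, for model comparison.

    A model whose curve dominates another's predicts uniformly higher
    values at the occurrence sites.  All rasters must share one grid.
    """
    rs = list(rasters.values())
    if len(rs) > 1:
        require_aligned(*rs)
    return {
        name: np.sort(sample_raster_at_points(r, pts))[::-1]
        for name, r in rasters.items()
    }


@dataclass
class EvaluationReport:
    """Bundle of the presence-only metrics for one prediction raster."""

    exactness: float
    selectivity: float
    threshold: float
    n_points_used: int
    n_points_outside: int
    n_points_nodata: int
    histograms: dict = field(default_factory=dict)
    gain: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "exactness": self.exactness,
            "selectivity": self.selectivity,
            "threshold": self.threshold,
            "n_points_used": self.n_points_used,
            "n_points_outside": self.n_points_outside,
            "n_points_nodata": self.n_points_nodata,
        }


def plot_report(report: EvaluationReport, path: str,
                title: str | None = None) -> None:
    """Write the report's histogram and gain-curve diagnostics as a figure.

    Left panel: value distribution over the study area vs at the
    presence points (the curves whose divergence justifies each model
    input).  Right panel: the cumulative gain curve of sorted point
    predictions.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    h = report.histograms
    centers = 0.5 * (h["bin_edges"][:-1] + h["bin_edges"][1:])
    ax1.plot(centers, h["area"], color="tab:red", label="study area")
    ax1.plot(centers, h["points"], color="black", label="presence sites")
    ax1.set_xlabel("predicted suitability")
    ax1.set_ylabel("relative frequency")
    ax1.legend(frameon=False)
    ax2.plot(np.arange(1, report.gain.size + 1), report.gain, color="black")
    ax2.set_xlabel("sites (sorted by prediction)")
    ax2.set_ylabel("prediction")
    ax2.set_ylim(-0.02, 1.02)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def evaluate(r: GridRaster, pts: PresencePoints,
             lowest_fraction: float = 0.10,
             bins: int = 20) -> EvaluationReport:
    """Full presence-only evaluation of one suitability raster."""
    values, info = sample_raster_at_points(r, pts, return_info=True)
    sel, t = selectivity(r, pts, lowest_fraction, return_threshold=True)
    return EvaluationReport(
        exactness=float(values.mean()),
        selectivity=sel,
        threshold=t,
        n_points_used=info["n_used"],
        n_points_outside=info["n_outside"],
        n_points_nodata=info["n_nodata"],
        histograms=value_histograms(r, pts, bins),
        gain=np.sort(values)[::-1],
    )
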