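"""Mean center and standard deviational ellipse (SDE) of planar point clouds.

The mean center (MC) is the (optionally weighted) average coordinate of a
point set; the SDE summarizes dispersion and orientation with two standard
-distance axes and a rotation angle.  Axis lengths are root-mean-square
deviations along the principal axes with denominator m (no m-2 correction and
no sqrt(2) inflation; both are exposed as options for compatibility with GIS
products that apply them).

Angle convention: theta is measured counterclockwise from the positive
x-axis and reduced mod 180 degrees.  Use :func:`theta_to_gis` for the
clockwise-from-north convention that desktop GIS tools report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .panel import STREAM_OVERLAP, subseeded_rng

_ISO_TOL = 1e-12


@dataclass(frozen=True)
class MeanCenter:
    x: float
    y: float
    year: Optional[int] = None
    n_points: int = 0


@dataclass(frozen=True)
class Ellipse:
    """Standard deviational ellipse: center, major/minor standard distances
    (``sde_x >= sde_y``), and major-axis angle in degrees within [0, 180)."""

    center: MeanCenter
    sde_x: float
    sde_y: float
    theta: float
    degenerate: bool = False

    @property
    def area(self) -> float:
        return float(np.pi * self.sde_x * self.sde_y)


def _as_xyw(points, weights=None) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        x = points["x"].to_numpy(dtype=float)
        y = points["y"].to_numpy(dtype=float)
        if weights is None and "weight" in points.columns:
            weights = points["weight"].to_numpy(dtype=float)
    else:
        arr = np.asarray(points, dtype=float)
        if arr.ndim != 2 or arr.shape[1] < 2:
            raise DomainError("points must be an (n, 2) array or a DataFrame with x, y")
        x, y = arr[:, 0], arr[:, 1]
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != x.shape:
        raise DomainError("weights must match the number of points")
    if np.any(w < 0):
        raise DomainError("weights must be >= 0")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DomainError("coordinates must be finite")
    return x, y, w


def mean_center(points, weights=None, year: Optional[int] = None) -> MeanCenter:
    """Weight-averaged coordinates of a point set."""
    x, y, w = _as_xyw(points, weights)
    if x.size == 0 or w.sum() <= 0:
        raise DomainError("mean center needs at least one point with positive total weight")
    W = w.sum()
    return MeanCenter(float((x * w).sum() / W), float((y * w).sum() / W), year, int(x.size))


def standard_deviational_ellipse(
    points,
    weights=None,
    year: Optional[int] = None,
    ddof: int = 0,
    inflation: float = 1.0,
) -> Ellipse:
    """Fit the SDE of a point cloud.

    Orientation and axes come from the eigendecomposition of the weighted
    second-moment matrix of deviations from the mean center, which is the
    closed-form tan-theta solution in a numerically robust form (exact at the
    Sum(xy) = 0 branch point).  ``ddof`` shifts the RMS denominator (0 -> m);
    ``inflation`` scales both axes (1 -> none; some GIS tools use sqrt(2)).

    An isotropic cloud (equal moments, zero cross-moment) has no defined
    orientation; theta = 0 is returned with ``degenerate=True``.
    """
    x, y, w = _as_xyw(points, weights)
    if x.size < 1 or w.sum() <= 0:
        raise DomainError("SDE needs at least one point with positive total weight")
    mc = mean_center(np.column_stack([x, y]), w, year)
    xt = x - mc.x
    yt = y - mc.y
    W = w.sum()
    denom = W - ddof
    if denom <= 0:
        raise DomainError("ddof leaves a non-positive denominator")
    sxx = float((w * xt * xt).sum()) / denom
    syy = float((w * yt * yt).sum()) / denom
    sxy = float((w * xt * yt).sum()) / denom
    scale = max(sxx, syy, 1.0)
    degenerate = abs(sxy) <= _ISO_TOL * scale and abs(sxx - syy) <= _ISO_TOL * scale
    if degenerate:
        s = float(np.sqrt(max(sxx, 0.0)))
        return Ellipse(mc, inflation * s, inflation * s, 0.0, degenerate=True)
    evals, evecs = np.linalg.eigh(np.array([[sxx, sxy], [sxy, syy]]))
    # eigh sorts ascending: column 1 is the major axis
    major, minor = float(evals[1]), float(evals[0])
    vx, vy = evecs[0, 1], evecs[1, 1]
    theta = float(np.degrees(np.arctan2(vy, vx)) % 180.0)
    return Ellipse(
        mc,
        inflation * float(np.sqrt(max(major, 0.0))),
        inflation * float(np.sqrt(max(minor, 0.0))),
        theta,
        degenerate=False,
    )


def theta_to_gis(theta: float) -> float:
    """Convert a counterclockwise-from-east angle to clockwise-from-north."""
    return (90.0 - theta) % 180.0


def _ellipse_bbox(e: Ellipse) -> Tuple[float, float, float, float]:
    t = np.radians(e.theta)
    hw = np.sqrt((e.sde_x * np.cos(t)) ** 2 + (e.sde_y * np.sin(t)) ** 2)
    hh = np.sqrt((e.sde_x * np.sin(t)) ** 2 + (e.sde_y * np.cos(t)) ** 2)
    return e.center.x - hw, e.center.x + hw, e.center.y - hh, e.center.y + hh


def _inside(e: Ellipse, px: np.ndarray, py: np.ndarray) -> np.ndarray:
    t = np.radians(e.theta)
    dx = px - e.center.x
    dy = py - e.center.y
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / e.sde_x) ** 2 + (v / e.sde_y) ** 2 <= 1.0


def ellipse_overlap_fraction(
    e1: Ellipse, e2: Ellipse, n_samples: int = 100_000, seed: int = 0
) -> float:
    """Monte-Carlo intersection-over-union of two ellipses.

    Uniform samples over the joint bounding box are classified against both
    ellipses; the estimate is #(in both) / #(in either).  Seeded and
    symmetric in its arguments.  Overlap near 1 means the two annual case
    distributions occupy the same ground; near 0, spatial segregation.
    """
    if n_samples < 1:
        raise DomainError("n_samples must be >= 1")
    if min(e1.sde_x, e1.sde_y) <= 0 or min(e2.sde_x, e2.sde_y) <= 0:
        warnings.warn("degenerate (zero-area) ellipse; overlap reported as 0")
        return 0.0
    b1, b2 = _ellipse_bbox(e1), _ellipse_bbox(e2)
    xmin, xmax = min(b1[0], b2[0]), max(b1[1], b2[1])
    ymin, ymax = min(b1[2], b2[2]), max(b1[3], b2[3])
    rng = subseeded_rng(seed, STREAM_OVERLAP)
    px = rng.uniform(xmin, xmax, n_samples)
    py = rng.uniform(ymin, ymax, n_samples)
    in1 = _inside(e1, px, py)
    in2 = _inside(e2, px, py)
    union = int(np.sum(in1 | in2))
    if union == 0:
        return 0.0
    return float(np.sum(in1 & in2) / union)


def center_trajectory(
    points_by_year: Mapping[int, object],
    weights_by_year: Optional[Mapping[int, Sequence[float]]] = None,
) -> List[MeanCenter]:
    """Mean center per year, ordered by year.  For population trajectories,
    pass district centroids as points and populations as weights."""
    if not points_by_year:
        raise DomainError("need at least one year of points")
    out = []
    for year in sorted(points_by_year):
        w = None if weights_by_year is None else weights_by_year.get(year)
        out.append(mean_center(points_by_year[year], w, year=int(year)))
    return out


def annual_ellipses(case_points: pd.DataFrame) -> List[Ellipse]:
    """SDE of the case point cloud of each year present, ordered by year."""
    out = []
    for year, grp in case_points.groupby("year"):
        if len(grp) >= 1:
            out.append(standard_deviational_ellipse(grp, year=int(year)))
    return out


def ellipse_to_polygon(e: Ellipse, n_vertices: int = 64) -> List[Tuple[float, float]]:
    """Discretize an ellipse boundary (closed ring) for GeoJSON output."""
    t = np.radians(e.theta)
    ang = np.linspace(0.0, 2.0 * np.pi, n_vertices + 1)
    u = e.sde_x * np.cos(ang)
    v = e.sde_y * np.sin(ang)
    xs = e.center.x + u * np.cos(t) - v * np.sin(t)
    ys = e.center.y + u * np.sin(t) + v * np.cos(t)
    return [(float(a), float(b)) for a, b in zip(xs, ys)]
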