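"""Hospitalization rates, indirect standardization, and rank classification.

The incidence rate (IR) of a district is its admissions per 1,000 residents.
The standardized ratio (SR) is observed admissions divided by expected
admissions, where the expectation applies the city-wide general rate (G_IR)
to the district's population.  SR > 1 marks above-average relative risk.

Average IRs are graded into four ranks by z-score against the cross-district
mean; SRs into five ranks by fixed breakpoints (regenerable from the data
with a one-dimensional k-means).
"""

from __future__ import annotations

import warnings
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError

#: z-score cut points separating the four IR ranks (left-open, right-closed).
DEFAULT_IR_ZBREAKS = (-0.29, 0.61, 1.5)

#: Upper bounds of the five SR ranks (rank 1: [0, 0.580], ..., rank 5:
#: (1.840, 2.500]); values above the last bound fall in rank 5 with a warning.
DEFAULT_SR_BREAKPOINTS = (0.580, 0.890, 1.270, 1.840, 2.500)

CHANGE_HIGHER = "higher"
CHANGE_LOWER = "lower"
CHANGE_INVARIANT = "invariant"


def incidence_rate(admissions, population):
    """Admissions per 1,000 residents.  Vectorizes over array inputs."""
    admissions = np.asarray(admissions, dtype=float)
    population = np.asarray(population, dtype=float)
    if np.any(population <= 0):
        raise DomainError("population must be > 0")
    out = 1000.0 * admissions / population
    return float(out) if out.ndim == 0 else out


def general_rate(panel: pd.DataFrame, year: int) -> float:
    """City-wide crude admission rate (per person) for one year:
    total admissions over total population of the districts present."""
    cut = panel[panel["year"] == year]
    if cut.empty:
        raise DomainError(f"no districts present in year {year}")
    return float(cut["admissions"].sum() / cut["population"].sum())


def expected_cases(general_rate_value: float, population) -> float:
    """Expected admissions under the city-wide rate: ``G_IR * N_i``."""
    if general_rate_value < 0:
        raise DomainError("general rate must be >= 0")
    population = np.asarray(population, dtype=float)
    if np.any(population < 0):
        raise DomainError("population must be >= 0")
    out = general_rate_value * population
    return float(out) if out.ndim == 0 else out


def standardized_ratio(observed, expected):
    """Observed over expected admissions."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise DomainError("expected cases must be > 0")
    out = observed / expected
    return float(out) if out.ndim == 0 else out


def classify_ir_rank(
    values: Sequence[float], zbreaks: Sequence[float] = DEFAULT_IR_ZBREAKS
) -> np.ndarray:
    """Grade district average IRs into ranks 1..len(zbreaks)+1 by z-score.

    The z-score uses the population (divide-by-n) standard deviation across
    districts.  Intervals are left-open/right-closed at the cut points, e.g.
    with the default breaks rank 2 is -0.29 < z <= 0.61.  A zero-variance
    input puts every district in the interval containing z = 0 (rank 2 under
    the defaults), with a warning.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise DomainError("need at least 2 districts to rank IRs")
    zbreaks = np.asarray(zbreaks, dtype=float)
    sd = float(values.std())  # population convention
    if sd == 0.0:
        warnings.warn("zero variance across districts; all IR ranks default to the z=0 interval")
        rank0 = int(np.searchsorted(zbreaks, 0.0, side="left")) + 1
        return np.full(values.shape, rank0, dtype=int)
    z = (values - values.mean()) / sd
    # left-open/right-closed: z exactly at a cut point stays in the lower rank
    return (np.searchsorted(zbreaks, z, side="left") + 1).astype(int)


def classify_sr_rank(
    sr, breakpoints: Sequence[float] = DEFAULT_SR_BREAKPOINTS
) -> np.ndarray:
    """Grade SRs into ranks 1..len(breakpoints) against ordered upper bounds.

    Rank = 1 + number of breakpoints strictly below the value; values above
    the last bound are capped at the top rank with a warning.  Monotone
    non-decreasing in ``sr``.
    """
    bp = np.asarray(breakpoints, dtype=float)
    if bp.size < 1 or np.any(np.diff(bp) <= 0):
        raise DomainError("breakpoints must be strictly increasing and non-empty")
    arr = np.atleast_1d(np.asarray(sr, dtype=float))
    if np.any(arr < 0):
        raise DomainError("SR must be >= 0")
    if np.any(arr > bp[-1]):
        warnings.warn(
            f"SR value(s) above the top breakpoint {bp[-1]}; assigned the highest rank"
        )
    ranks = np.minimum(np.searchsorted(bp, arr, side="left") + 1, bp.size)
    return int(ranks[0]) if np.ndim(sr) == 0 else ranks.astype(int)


def kmeans_1d(values: Sequence[float], k: int, seed: int = 0) -> List[float]:
    """One-dimensional Lloyd's k-means; returns the k-1 class boundaries.

    Centers start at the (i+0.5)/k quantiles and iterate to an assignment
    fixpoint (deterministic; ``seed`` is accepted for interface symmetry).
    Boundaries are midpoints between the maximum of one sorted cluster and
    the minimum of the next.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    n_distinct = np.unique(values).size
    if k > n_distinct:
        raise DomainError(f"k={k} exceeds the {n_distinct} distinct values")
    if k == 1:
        return []
    centers = np.quantile(values, (np.arange(k) + 0.5) / k)
    centers = np.unique(centers)
    while centers.size < k:  # duplicates collapse; re-seed from distinct values
        extra = np.setdiff1d(np.unique(values), centers)[: k - centers.size]
        centers = np.sort(np.concatenate([centers, extra]))
    assign = None
    for _ in range(1000):
        new_assign = np.argmin(np.abs(values[:, None] - centers[None, :]), axis=1)
        if assign is not None and np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            sel = values[assign == j]
            if sel.size:
                centers[j] = sel.mean()
        order = np.argsort(centers)
        centers = centers[order]
    boundaries = []
    for j in range(k - 1):
        hi = values[assign == j].max()
        lo = values[assign == j + 1].min()
        boundaries.append(float((hi + lo) / 2.0))
    return boundaries


def sr_change_pattern(rank_start: int, rank_end: int) -> str:
    """Direction of SR rank movement over an interval."""
    for r in (rank_start, rank_end):
        if not 1 <= r <= 5:
            raise DomainError(f"rank {r} outside 1..5")
    if rank_end > rank_start:
        return CHANGE_HIGHER
    if rank_end < rank_start:
        return CHANGE_LOWER
    return CHANGE_INVARIANT


def rates_table(
    panel: pd.DataFrame,
    sr_breakpoints: Sequence[float] = DEFAULT_SR_BREAKPOINTS,
    ir_zbreaks: Sequence[float] = DEFAULT_IR_ZBREAKS,
) -> pd.DataFrame:
    """Per district-year IR, expected cases, SR, and both rank gradings.

    The general rate is computed per year (SR maps are annual); the IR rank
    grades each district's study-period *average* IR and is replicated down
    that district's rows.
    """
    out = panel.copy().sort_values(["year", "district"], kind="stable")
    out["ir"] = incidence_rate(out["admissions"], out["population"])
    expected = np.empty(len(out))
    for year, idx in out.groupby("year").groups.items():
        g = general_rate(panel, int(year))
        expected[out.index.get_indexer(idx)] = expected_cases(
            g, out.loc[idx, "population"]
        )
    out["expected"] = expected
    out["sr"] = standardized_ratio(out["admissions"], out["expected"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["sr_rank"] = classify_sr_rank(out["sr"].to_numpy(), sr_breakpoints)
        avg_ir = out.groupby("district")["ir"].mean()
        ir_ranks = pd.Series(
            classify_ir_rank(avg_ir.to_numpy(), ir_zbreaks), index=avg_ir.index
        )
    out["ir_rank"] = out["district"].map(ir_ranks).astype(int)
    return out.reset_index(drop=True)[
        ["district", "year", "population", "admissions", "ir", "expected", "sr", "ir_rank", "sr_rank"]
    ]


def change_pattern_table(
    rates: pd.DataFrame, step: int = 3, include_full: bool = True
) -> pd.DataFrame:
    """SR rank movement per district over fixed-step year intervals (default
    every 3 years) plus the full study period.

    Returns columns ``district, interval, rank_start, rank_end, pattern``.
    """
    years = sorted(rates["year"].unique())
    endpoints = list(range(0, len(years), step))
    if endpoints[-1] != len(years) - 1:
        endpoints.append(len(years) - 1)
    intervals = [(years[a], years[b]) for a, b in zip(endpoints[:-1], endpoints[1:])]
    if include_full and (years[0], years[-1]) not in intervals:
        intervals.append((years[0], years[-1]))
    by = rates.set_index(["district", "year"])["sr_rank"]
    rows = []
    for d in sorted(rates["district"].unique()):
        for y0, y1 in intervals:
            r0, r1 = int(by[(d, y0)]), int(by[(d, y1)])
            rows.append((d, f"{y0}-{y1}", r0, r1, sr_change_pattern(r0, r1)))
    return pd.DataFrame(
        rows, columns=["district", "interval", "rank_start", "rank_end", "pattern"]
    )
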