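"""Retrospective space-time scan statistic on the district panel.

Kulldorff's discrete-Poisson scan with cylindrical windows: a circular
geographic base (districts whose centroids fall within a radius of a center
district) crossed with a contiguous year interval.  For each window the
log-likelihood ratio

    LLR = O ln(O/E) + (C-O) ln((C-O)/(C-E))   if O > E, else 0

compares the admission rate inside the window with outside, where O and E
are observed and expected cases in the window, C the study total, and
expected counts apply the whole-study general rate to district-year
populations (purely population-proportional).  Only high-rate windows score
(the one-sided convention).  Significance comes from Monte-Carlo replication
conditional on C: replicate totals are redistributed multinomially with
probabilities proportional to the expected counts, and each window's p-value
is the rank of its LLR among the replicate maxima.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import DomainError
from .panel import STREAM_SCAN_MC, subseeded_rng


@dataclass(frozen=True)
class Cylinder:
    """One scanning window: circular base around a center district crossed
    with an inclusive year interval."""

    center_district: str
    radius: float
    member_districts: frozenset
    year_start: int
    year_end: int

    def __post_init__(self):
        if not self.member_districts or self.center_district not in self.member_districts:
            raise DomainError("member_districts must be non-empty and contain the center")
        if self.year_start > self.year_end:
            raise DomainError("year interval is empty")


@dataclass
class ClusterResult:
    cylinder: Cylinder
    observed: float
    expected: float
    llr: float
    relative_risk: float
    p_value: Optional[float] = None

    @property
    def districts(self) -> Tuple[str, ...]:
        return tuple(sorted(self.cylinder.member_districts))


@dataclass(frozen=True)
class ScanParams:
    max_pop_fraction: float = 0.5
    max_time_fraction: float = 0.5
    n_replicates: int = 999
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.max_pop_fraction <= 1:
            raise DomainError("max_pop_fraction must be in (0, 1]")
        if not 0 < self.max_time_fraction <= 1:
            raise DomainError("max_time_fraction must be in (0, 1]")
        if self.n_replicates < 1:
            raise DomainError("n_replicates must be >= 1")
        if not 0 < self.alpha <= 1:
            raise DomainError("alpha must be in (0, 1]")


def expected_counts(panel: pd.DataFrame) -> pd.Series:
    """Expected admissions per district-year under the whole-study general
    rate: E_{i,t} = (total cases / total person-years) * N_{i,t}."""
    total_cases = panel["admissions"].sum()
    total_pop = panel["population"].sum()
    if total_pop <= 0:
        raise DomainError("panel has no population")
    return panel["population"] * (total_cases / total_pop)


def max_interval_length(n_years: int, max_time_fraction: float) -> int:
    """Longest admissible year interval: floor(fraction * study length),
    clamped to at least one year."""
    return max(1, int(np.floor(max_time_fraction * n_years + 1e-9)))


def enumerate_cylinders(
    district_info: pd.DataFrame,
    panel: pd.DataFrame,
    max_pop_fraction: float = 0.5,
    max_time_fraction: float = 0.5,
) -> List[Cylinder]:
    """All candidate windows for the scan.

    For every center district the radius sweeps the sorted centroid-to
    -centroid distances (including 0, the single-district base); a base is
    retained iff its share of the study-average population is at most
    ``max_pop_fraction`` (boundary districts included: centroid-in-circle,
    inclusive).  Bases are crossed with every contiguous year interval no
    longer than ``max_time_fraction`` of the study length; duplicate
    (member-set x interval) windows are dropped, keeping the smallest radius.
    """
    if panel.empty:
        raise DomainError("empty panel")
    years = sorted(int(y) for y in panel["year"].unique())
    max_len = max_interval_length(len(years), max_time_fraction)
    avg_pop = panel.groupby("district")["population"].mean()
    total_avg = avg_pop.sum()
    names = list(district_info["district"])
    coords = district_info[["x", "y"]].to_numpy(dtype=float)
    dist = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))

    bases: Dict[frozenset, Tuple[str, float]] = {}
    for ci, center in enumerate(names):
        order = np.argsort(dist[ci], kind="stable")
        for radius in np.unique(dist[ci]):
            members = frozenset(names[j] for j in order if dist[ci, j] <= radius)
            if avg_pop[list(members)].sum() / total_avg > max_pop_fraction:
                break  # larger radii only add population
            prev = bases.get(members)
            if prev is None or radius < prev[1]:
                bases[members] = (center, float(radius))

    intervals = [
        (years[a], years[b])
        for a in range(len(years))
        for b in range(a, min(a + max_len, len(years)))
    ]
    out = []
    for members in sorted(bases, key=lambda m: (len(m), tuple(sorted(m)))):
        center, radius = bases[members]
        for ys, ye in intervals:
            out.append(Cylinder(center, radius, members, ys, ye))
    return out


def _llr_terms(O: np.ndarray, E: np.ndarray, C: float) -> np.ndarray:
    """Vectorized one-sided Poisson LLR with the 0*ln(0) = 0 convention."""
    O = np.asarray(O, dtype=float)
    E = np.asarray(E, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(O > 0, O * np.log(np.where(O > 0, O / E, 1.0)), 0.0)
        rem_o = C - O
        rem_e = C - E
        t2 = np.where(
            rem_o > 0,
            rem_o * np.log(np.where(rem_o > 0, rem_o / np.where(rem_e > 0, rem_e, 1.0), 1.0)),
            0.0,
        )
    return np.where(O > E, t1 + t2, 0.0)


def window_stats(
    cylinder: Cylinder, panel: pd.DataFrame, expected: Optional[pd.Series] = None
) -> Tuple[float, float, float, float]:
    """(O_in, E_in, LLR, relative risk) for one window."""
    if expected is None:
        expected = expected_counts(panel)
    mask = panel["district"].isin(cylinder.member_districts) & panel["year"].between(
        cylinder.year_start, cylinder.year_end
    )
    O = float(panel.loc[mask, "admissions"].sum())
    E = float(expected[mask].sum())
    C = float(panel["admissions"].sum())
    if E <= 0:
        raise DomainError("window has zero expected cases")
    llr = float(_llr_terms(np.array(O), np.array(E), C))
    rem_o, rem_e = C - O, C - E
    if rem_e <= 0:
        raise DomainError("window expectation covers the whole study")
    rr = np.inf if rem_o <= 0 else (O / E) / (rem_o / rem_e)
    return O, E, llr, float(rr)


def _cell_index(panel: pd.DataFrame) -> Tuple[pd.DataFrame, Dict[Tuple[str, int], int]]:
    cells = panel.reset_index(drop=True)
    idx = {(d, int(y)): i for i, (d, y) in enumerate(zip(cells["district"], cells["year"]))}
    return cells, idx


def _indicator_matrix(
    cylinders: Sequence[Cylinder], cells: pd.DataFrame
) -> np.ndarray:
    d = cells["district"].to_numpy()
    y = cells["year"].to_numpy()
    M = np.zeros((len(cylinders), len(cells)), dtype=bool)
    for k, cyl in enumerate(cylinders):
        M[k] = np.isin(d, list(cyl.member_districts)) & (y >= cyl.year_start) & (y <= cyl.year_end)
    return M


def monte_carlo_pvalues(
    panel: pd.DataFrame,
    cylinders: Sequence[Cylinder],
    n_replicates: int = 999,
    seed: int = 0,
    observed_llr: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Monte-Carlo p-value per candidate window.

    Replicate panels redistribute the observed case total over district-year
    cells multinomially with probabilities proportional to expected counts
    (the standard conditioning for the discrete-Poisson scan).  Each
    window's p is (1 + #{replicate max LLR >= window LLR}) / (1 + R) —
    invariant to the enumeration order of the windows.
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    cells, _ = _cell_index(panel)
    expected = expected_counts(cells).to_numpy(dtype=float)
    counts = cells["admissions"].to_numpy(dtype=float)
    C = counts.sum()
    M = _indicator_matrix(cylinders, cells)
    E_in = M @ expected
    if observed_llr is None:
        observed_llr = _llr_terms(M @ counts, E_in, C)
    if C == 0:
        return np.ones(len(cylinders))
    rng = subseeded_rng(seed, STREAM_SCAN_MC)
    probs = expected / expected.sum()
    draws = rng.multinomial(int(C), probs, size=n_replicates).astype(float)
    O_rep = draws @ M.T  # (R, n_cyl)
    rep_llr = _llr_terms(O_rep, E_in[None, :], C)
    rep_max = rep_llr.max(axis=1)
    exceed = (rep_max[:, None] >= observed_llr[None, :] - 1e-12).sum(axis=0)
    return (1.0 + exceed) / (1.0 + n_replicates)


def _order_key(cyl: Cylinder, llr: float):
    """Sort key: LLR descending, then fewer members, then lexicographic
    district ids, then earlier/shorter interval."""
    return (-llr, len(cyl.member_districts), tuple(sorted(cyl.member_districts)),
            cyl.year_start, cyl.year_end)


def detect_clusters(
    panel: pd.DataFrame,
    district_info: pd.DataFrame,
    params: ScanParams = ScanParams(),
    cylinders: Optional[Sequence[Cylinder]] = None,
) -> List[ClusterResult]:
    """Most-likely and secondary clusters of the panel.

    The first result maximizes the LLR (ties broken by smaller member count,
    then lexicographic district ids).  Secondary clusters are significant
    windows (p <= alpha) sharing no district with any better-ranked reported
    cluster.  A panel with no admissions returns an empty list.
    """
    if panel["admissions"].sum() == 0:
        return []
    if cylinders is None:
        cylinders = enumerate_cylinders(
            district_info, panel, params.max_pop_fraction, params.max_time_fraction
        )
    if not cylinders:
        return []
    cells, _ = _cell_index(panel)
    expected = expected_counts(cells).to_numpy(dtype=float)
    counts = cells["admissions"].to_numpy(dtype=float)
    C = counts.sum()
    M = _indicator_matrix(cylinders, cells)
    O_in = M @ counts
    E_in = M @ expected
    llr = _llr_terms(O_in, E_in, C)
    pvals = monte_carlo_pvalues(
        panel, cylinders, params.n_replicates, params.seed, observed_llr=llr
    )

    order = sorted(range(len(cylinders)), key=lambda k: _order_key(cylinders[k], llr[k]))
    results: List[ClusterResult] = []
    used: set = set()
    for rank, k in enumerate(order):
        cyl = cylinders[k]
        if rank > 0:
            if pvals[k] > params.alpha or (cyl.member_districts & used):
                continue
        rem_o, rem_e = C - O_in[k], C - E_in[k]
        rr = np.inf if rem_o <= 0 else (O_in[k] / E_in[k]) / (rem_o / rem_e)
        results.append(
            ClusterResult(cyl, float(O_in[k]), float(E_in[k]), float(llr[k]), float(rr),
                          float(pvals[k]))
        )
        used |= cyl.member_districts
    return results


def clusters_to_frame(results: Sequence[ClusterResult]) -> pd.DataFrame:
    rows = [
        {
            "rank": i + 1,
            "districts": ";".join(r.districts),
            "year_start": r.cylinder.year_start,
            "year_end": r.cylinder.year_end,
            "observed": r.observed,
            "expected": r.expected,
            "llr": r.llr,
            "rr": r.relative_risk,
            "p": r.p_value,
        }
        for i, r in enumerate(results)
    ]
    return pd.DataFrame(
        rows,
        columns=["rank", "districts", "year_start", "year_end", "observed", "expected",
                 "llr", "rr", "p"],
    )
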