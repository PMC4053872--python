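"""Seeded generator for district-level hospitalization panels.

Emulates a ten-district, ten-year urban study design: populations of order
1e5-1e6 with secular growth, annual admission counts Poisson-distributed
around population x a rising baseline rate (order 0.3-3 per 1,000
person-years), a slow northward centroid drift, per-district case point
clouds, and an optional embedded space-time cluster with a known rate
multiplier.  Poisson counts on top of a log-linear rate surface are the
minimal generative model consistent with the discrete-Poisson scan statistic,
which makes the scan's null hypothesis exact when rates are homogeneous.

All draws are reproducible: a fixed master seed yields byte-identical output,
and each operation consumes its own sub-seeded stream.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError, PanelLookupError
from .panel import (
    POINT_COLUMNS,
    STREAM_INJECT,
    STREAM_PANEL,
    STREAM_POINTS,
    ClusterSpec,
    PanelConfig,
    SyntheticPanel,
    subseeded_rng,
)

#: Default ten-district study design (projected meters, admissions per
#: person-year).  Populations span ~1e5-1e6 with 5%/yr growth; baseline rates
#: span 0.3-2.4 per 1,000 and rise 8%/yr; centroids scatter over a ~40x20 km
#: coastal strip and drift 200 m/yr northward.
DEFAULT_DISTRICTS = tuple(f"D{i:02d}" for i in range(1, 11))
DEFAULT_POPULATIONS = (
    950_000.0, 780_000.0, 620_000.0, 540_000.0, 470_000.0,
    390_000.0, 310_000.0, 250_000.0, 180_000.0, 120_000.0,
)
DEFAULT_RATES = tuple(
    r / 1000.0 for r in (2.4, 2.0, 1.6, 1.4, 1.1, 0.9, 0.8, 0.6, 0.45, 0.3)
)
DEFAULT_CENTROIDS = (
    (5_000.0, 8_000.0), (12_000.0, 6_000.0), (20_000.0, 9_000.0),
    (27_000.0, 7_000.0), (34_000.0, 10_000.0), (8_000.0, 14_000.0),
    (16_000.0, 15_000.0), (24_000.0, 16_000.0), (31_000.0, 15_000.0),
    (38_000.0, 12_000.0),
)
DEFAULT_HOSPITALS = (45, 38, 30, 25, 20, 16, 12, 9, 7, 5)


def default_config(seed: int = 0, cluster_spec: Optional[ClusterSpec] = None) -> PanelConfig:
    """The heterogeneous study design: per-district baseline rates with a
    rising secular trend, growing populations, northward drift."""
    return PanelConfig(
        districts=DEFAULT_DISTRICTS,
        year_start=2003,
        year_end=2012,
        base_populations=DEFAULT_POPULATIONS,
        baseline_rates=DEFAULT_RATES,
        centroids=DEFAULT_CENTROIDS,
        hospitals=DEFAULT_HOSPITALS,
        pop_growth_rate=0.05,
        rate_trend=1.08,
        centroid_drift=(0.0, 200.0),
        dispersion=2500.0,
        cluster_spec=cluster_spec,
        seed=seed,
    )


def null_config(seed: int = 0, cluster_spec: Optional[ClusterSpec] = None) -> PanelConfig:
    """A scan-null study design: one common baseline rate, no secular trend,
    so the expected count of every cell is exactly proportional to its
    population.  Used for scan calibration and power studies, where
    rate heterogeneity would itself be a true cluster signal."""
    return PanelConfig(
        districts=DEFAULT_DISTRICTS,
        year_start=2003,
        year_end=2012,
        base_populations=DEFAULT_POPULATIONS,
        baseline_rates=(1.0 / 1000.0,) * 10,
        centroids=DEFAULT_CENTROIDS,
        hospitals=DEFAULT_HOSPITALS,
        pop_growth_rate=0.05,
        rate_trend=1.0,
        centroid_drift=(0.0, 200.0),
        dispersion=2500.0,
        cluster_spec=cluster_spec,
        seed=seed,
    )


def _cell_means(config: PanelConfig) -> pd.DataFrame:
    """Deterministic per-cell populations and Poisson means, ordered by
    (district index, year)."""
    rows = []
    t0 = config.year_start
    for i, d in enumerate(config.districts):
        for year in config.years:
            dt = year - t0
            pop = config.base_populations[i] * (1.0 + config.pop_growth_rate) ** dt
            mean = pop * config.baseline_rates[i] * config.rate_trend**dt
            if config.cluster_spec is not None and config.cluster_spec.contains(d, year):
                mean *= config.cluster_spec.multiplier
            rows.append((d, year, pop, mean))
    return pd.DataFrame(rows, columns=["district", "year", "population", "mean"])


def generate_panel(config: PanelConfig, with_points: bool = True) -> SyntheticPanel:
    """Draw a full synthetic panel from the study design.

    Parameters
    ----------
    config
        Validated study design (:class:`PanelConfig` raises
        :class:`~greyscan.errors.ConfigError` on construction otherwise).
    with_points
        Also draw per-case point locations (may be ~1e5 points for the
        default design); pass ``False`` when only counts are needed.
    """
    cells = _cell_means(config)
    rng = subseeded_rng(config.seed, STREAM_PANEL)
    admissions = rng.poisson(cells["mean"].to_numpy())
    records = pd.DataFrame(
        {
            "district": cells["district"],
            "year": cells["year"].astype(int),
            "population": np.maximum(np.rint(cells["population"]), 1).astype(int),
            "admissions": admissions.astype(int),
        }
    )
    district_info = pd.DataFrame(
        {
            "district": list(config.districts),
            "x": [c[0] for c in config.centroids],
            "y": [c[1] for c in config.centroids],
            "hospitals": list(config.hospitals),
        }
    )
    panel = SyntheticPanel(
        records=records,
        district_info=district_info,
        means=cells["mean"],
        centroid_drift=config.centroid_drift,
        year_start=config.year_start,
    )
    if with_points:
        panel.case_points = generate_case_points(panel, config.dispersion, config.seed)
    return panel


def generate_case_points(
    panel: SyntheticPanel, dispersion: float, seed: int
) -> pd.DataFrame:
    """Sample one planar point per admission, isotropic bivariate normal with
    standard deviation ``dispersion`` around the district's year-t centroid.

    The within-district spatial law of real cases is unknown; the isotropic
    normal is an explicit modelling assumption of this generator.
    """
    if dispersion <= 0:
        raise ConfigError(f"dispersion must be > 0, got {dispersion}")
    rng = subseeded_rng(seed, STREAM_POINTS)
    rec = panel.records.sort_values(["district", "year"], kind="stable")
    base = panel.district_info.set_index("district")
    t0 = panel.year_start if panel.year_start is not None else 0
    dx, dy = panel.centroid_drift

    counts = rec["admissions"].to_numpy()
    total = int(counts.sum())
    cx = base.loc[rec["district"], "x"].to_numpy() + dx * (rec["year"].to_numpy() - t0)
    cy = base.loc[rec["district"], "y"].to_numpy() + dy * (rec["year"].to_numpy() - t0)

    centers_x = np.repeat(cx, counts)
    centers_y = np.repeat(cy, counts)
    noise = rng.normal(0.0, dispersion, size=(total, 2))
    return pd.DataFrame(
        {
            "district": np.repeat(rec["district"].to_numpy(), counts),
            "year": np.repeat(rec["year"].to_numpy(), counts),
            "x": centers_x + noise[:, 0],
            "y": centers_y + noise[:, 1],
        }
    )


def inject_cluster(
    panel: SyntheticPanel,
    districts: Iterable[str],
    year_interval: Sequence[int],
    multiplier: float,
    seed: int,
    dispersion: Optional[float] = None,
) -> SyntheticPanel:
    """Redraw the admissions of a district-subset x year-span window with the
    generative Poisson mean scaled by ``multiplier``; all other cells keep
    their original draws.  Returns a new panel (the input is unchanged).

    Requires a panel produced by :func:`generate_panel` (it carries the
    per-cell means).  If the panel holds case points they are regenerated for
    the whole panel (seeded) so the points stay consistent with the counts.
    """
    if multiplier < 0:
        raise ConfigError(f"multiplier must be >= 0, got {multiplier}")
    if panel.means is None:
        raise ConfigError("panel carries no generative means; inject into a generated panel")
    districts = tuple(districts)
    years = range(int(min(year_interval)), int(max(year_interval)) + 1)
    known_d = set(panel.records["district"])
    known_y = set(int(y) for y in panel.records["year"])
    missing_d = [d for d in districts if d not in known_d]
    missing_y = [y for y in years if y not in known_y]
    if missing_d or missing_y:
        raise PanelLookupError(
            f"unknown districts {missing_d} / years {missing_y} for this panel"
        )

    out = panel.copy()
    out.means = panel.means.copy()
    mask = out.records["district"].isin(districts) & out.records["year"].isin(list(years))
    rng = subseeded_rng(seed, STREAM_INJECT)
    new_means = panel.means[mask] * multiplier
    out.records.loc[mask, "admissions"] = rng.poisson(new_means.to_numpy()).astype(int)
    out.means.loc[mask] = new_means
    if len(panel.case_points):
        disp = dispersion if dispersion is not None else _infer_dispersion(panel)
        out.case_points = generate_case_points(out, disp, seed)
    return out


def _infer_dispersion(panel: SyntheticPanel) -> float:
    """Fallback dispersion when re-generating points: RMS distance of the
    existing points from their district-year centroids."""
    pts = panel.case_points
    base = panel.district_info.set_index("district")
    t0 = panel.year_start if panel.year_start is not None else 0
    dxv = pts["x"].to_numpy() - (
        base.loc[pts["district"], "x"].to_numpy()
        + panel.centroid_drift[0] * (pts["year"].to_numpy() - t0)
    )
    dyv = pts["y"].to_numpy() - (
        base.loc[pts["district"], "y"].to_numpy()
        + panel.centroid_drift[1] * (pts["year"].to_numpy() - t0)
    )
    return float(np.sqrt(np.mean(dxv**2 + dyv**2) / 2.0))
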