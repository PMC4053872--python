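"""Core data containers for district-level annual hospitalization panels.

The in-memory lingua franca is the :class:`pandas.DataFrame`:

* **panel records** — one row per (district, year) with columns
  ``district, year, population, admissions``;
* **district info** — one row per district with columns
  ``district, x, y, hospitals`` (projected planar centroid, map units);
* **case points** — one row per case with columns ``district, year, x, y``.

:class:`SyntheticPanel` bundles the three together with the generative
metadata (per-cell Poisson means, centroid drift) that the simulator and the
cluster injector need but the CSV interchange formats do not carry.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigError

PANEL_COLUMNS = ["district", "year", "population", "admissions"]
DISTRICT_COLUMNS = ["district", "x", "y", "hospitals"]
POINT_COLUMNS = ["district", "year", "x", "y"]


@dataclass(frozen=True)
class ClusterSpec:
    """A ground-truth space-time cluster: a district subset crossed with a
    contiguous year span, whose Poisson means are scaled by ``multiplier``."""

    districts: Tuple[str, ...]
    year_start: int
    year_end: int
    multiplier: float

    def __post_init__(self):
        if self.multiplier < 0:
            raise ConfigError(f"cluster_spec.multiplier must be >= 0, got {self.multiplier}")
        if self.year_start > self.year_end:
            raise ConfigError(
                f"cluster_spec year interval is empty: {self.year_start}..{self.year_end}"
            )
        if not self.districts:
            raise ConfigError("cluster_spec.districts must be non-empty")

    def contains(self, district: str, year: int) -> bool:
        return district in self.districts and self.year_start <= year <= self.year_end


@dataclass(frozen=True)
class PanelConfig:
    """Study design for the synthetic district panel.

    Populations follow ``base * (1 + pop_growth_rate)**(t - t0)``; admissions
    for district *i* in year *t* are Poisson with mean
    ``population * baseline_rate_i * rate_trend**(t - t0)``, times the cluster
    multiplier inside ``cluster_spec`` if one is given.  District centroids
    translate by ``centroid_drift`` map units per year.
    """

    districts: Tuple[str, ...]
    year_start: int
    year_end: int
    base_populations: Tuple[float, ...]
    baseline_rates: Tuple[float, ...]  # admissions per person-year
    centroids: Tuple[Tuple[float, float], ...]
    hospitals: Tuple[int, ...]
    pop_growth_rate: float = 0.0
    rate_trend: float = 1.0
    centroid_drift: Tuple[float, float] = (0.0, 0.0)
    dispersion: float = 2500.0  # case-point scatter (map units)
    cluster_spec: Optional[ClusterSpec] = None
    seed: int = 0

    def __post_init__(self):
        n = len(self.districts)
        if n < 2:
            raise ConfigError(f"districts: need at least 2, got {n}")
        if len(set(self.districts)) != n:
            raise ConfigError("districts: duplicate identifiers")
        if self.year_end - self.year_start + 1 < 4:
            raise ConfigError(
                f"year range {self.year_start}..{self.year_end} too short: "
                "at least 4 annual observations are required"
            )
        for name, seq in (
            ("base_populations", self.base_populations),
            ("baseline_rates", self.baseline_rates),
            ("centroids", self.centroids),
            ("hospitals", self.hospitals),
        ):
            if len(seq) != n:
                raise ConfigError(f"{name}: expected {n} entries, got {len(seq)}")
        if any(p <= 0 for p in self.base_populations):
            raise ConfigError("base_populations: all values must be > 0")
        if any(r < 0 for r in self.baseline_rates):
            raise ConfigError("baseline_rates: all values must be >= 0")
        if any(h < 0 for h in self.hospitals):
            raise ConfigError("hospitals: all values must be >= 0")
        if self.dispersion <= 0:
            raise ConfigError(f"dispersion must be > 0, got {self.dispersion}")
        if self.cluster_spec is not None:
            unknown = set(self.cluster_spec.districts) - set(self.districts)
            if unknown:
                raise ConfigError(f"cluster_spec.districts: unknown districts {sorted(unknown)}")
            if not (
                self.year_start <= self.cluster_spec.year_start
                and self.cluster_spec.year_end <= self.year_end
            ):
                raise ConfigError("cluster_spec: year interval outside the study period")

    @property
    def years(self) -> range:
        return range(self.year_start, self.year_end + 1)

    @property
    def n_districts(self) -> int:
        return len(self.districts)

    def with_seed(self, seed: int) -> "PanelConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticPanel:
    """A generated panel: records, district info, case points, and the
    generative Poisson means needed to re-draw windows (cluster injection)."""

    records: pd.DataFrame
    district_info: pd.DataFrame
    case_points: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=POINT_COLUMNS)
    )
    means: Optional[pd.Series] = None  # aligned with ``records`` rows
    centroid_drift: Tuple[float, float] = (0.0, 0.0)
    year_start: Optional[int] = None

    def __post_init__(self):
        if self.year_start is None and len(self.records):
            self.year_start = int(self.records["year"].min())

    @property
    def years(self) -> Sequence[int]:
        return sorted(self.records["year"].unique())

    @property
    def districts(self) -> Sequence[str]:
        return list(self.district_info["district"])

    def centroids_for_year(self, year: int) -> pd.DataFrame:
        """District centroids translated by the drift accumulated since the
        first study year."""
        dt = year - (self.year_start if self.year_start is not None else year)
        out = self.district_info[["district", "x", "y"]].copy()
        out["x"] = out["x"] + self.centroid_drift[0] * dt
        out["y"] = out["y"] + self.centroid_drift[1] * dt
        return out

    def copy(self) -> "SyntheticPanel":
        return SyntheticPanel(
            records=self.records.copy(),
            district_info=self.district_info.copy(),
            case_points=self.case_points.copy(),
            means=None if self.means is None else self.means.copy(),
            centroid_drift=self.centroid_drift,
            year_start=self.year_start,
        )


def subseeded_rng(seed: int, stream: int) -> np.random.Generator:
    """One independent RNG stream per operation, derived from the master seed
    by stable sub-seeding, so adding an operation never perturbs another's
    draws."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# stable stream ids; append-only so existing draws never shift
STREAM_PANEL = 0
STREAM_POINTS = 1
STREAM_INJECT = 2
STREAM_SCAN_MC = 3
STREAM_OVERLAP = 4
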