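"""End-to-end orchestration: simulate/load -> rates -> spatial -> scan ->
grey forecast -> hospital burden, with validated I/O and a reproducible
report tree.

The report is deterministic given the seed: identical configurations produce
byte-identical output files (no timestamps enter the artifacts).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .errors import ConfigError, GreyscanError, ValidationError
from .grey import burden as grey_burden
from .grey import fit_and_validate, forecast
from .io import (
    ellipses_to_geojson,
    read_district_csv,
    read_panel_csv,
    read_points_csv,
    write_panel,
)
from .panel import PanelConfig, SyntheticPanel
from .rates import (
    DEFAULT_IR_ZBREAKS,
    DEFAULT_SR_BREAKPOINTS,
    change_pattern_table,
    rates_table,
)
from .scan import ScanParams, clusters_to_frame, detect_clusters
from .spatial import annual_ellipses, center_trajectory
from .synthetic import generate_panel

log = logging.getLogger("greyscan")


@dataclass
class AnalysisConfig:
    """Exactly one of ``simulation`` or (``panel_csv`` + ``district_csv``)
    selects the input; ``points_csv`` is optional for file-based runs."""

    simulation: Optional[PanelConfig] = None
    panel_csv: Optional[str] = None
    district_csv: Optional[str] = None
    points_csv: Optional[str] = None
    scan: ScanParams = field(default_factory=ScanParams)
    horizon: int = 3  # forecast years, the study's 2013-2015 design
    sr_breakpoints: Sequence[float] = DEFAULT_SR_BREAKPOINTS
    ir_zbreaks: Sequence[float] = DEFAULT_IR_ZBREAKS
    change_step: int = 3
    out_dir: Optional[str] = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        file_mode = self.panel_csv is not None
        if file_mode == (self.simulation is not None):
            raise ConfigError(
                "supply exactly one of `simulation` or `panel_csv`/`district_csv`"
            )
        if file_mode and self.district_csv is None:
            raise ConfigError("district_csv is required with panel_csv")
        if self.horizon < 1:
            raise ConfigError(f"horizon must be >= 1, got {self.horizon}")


@dataclass
class AnalysisReport:
    rates: pd.DataFrame
    change_patterns: pd.DataFrame
    centers: pd.DataFrame
    ellipses: pd.DataFrame
    ellipse_objects: list
    clusters: pd.DataFrame
    forecasts: pd.DataFrame
    validation: pd.DataFrame
    burden: pd.DataFrame
    metadata: dict
    skipped: Dict[str, str] = field(default_factory=dict)


def load_and_validate(
    config: AnalysisConfig,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Load or simulate the inputs and enforce referential integrity.

    Every violation found is reported (not only the first):
    non-positive populations, negative admissions, duplicate district-years,
    case points referencing unknown districts, and non-rectangular panels
    (missing cells are listed, not silently dropped).
    """
    if config.simulation is not None:
        panel_obj = generate_panel(config.simulation.with_seed(config.seed))
        panel, districts, points = (
            panel_obj.records,
            panel_obj.district_info,
            panel_obj.case_points,
        )
    else:
        panel = read_panel_csv(config.panel_csv)
        districts = read_district_csv(config.district_csv)
        points = (
            read_points_csv(config.points_csv)
            if config.points_csv is not None
            else pd.DataFrame(columns=["district", "year", "x", "y"])
        )

    violations: List[str] = []
    dup = panel.duplicated(subset=["district", "year"], keep=False)
    for d, y in sorted(set(map(tuple, panel.loc[dup, ["district", "year"]].values))):
        violations.append(f"duplicate district-year ({d}, {y})")
    bad_pop = panel["population"] <= 0
    for r in panel.loc[bad_pop].itertuples():
        violations.append(f"non-positive population for ({r.district}, {r.year})")
    bad_adm = panel["admissions"] < 0
    for r in panel.loc[bad_adm].itertuples():
        violations.append(f"negative admissions for ({r.district}, {r.year})")
    known = set(districts["district"])
    for d in sorted(set(panel["district"]) - known):
        violations.append(f"panel district '{d}' absent from district info")
    unknown_pts = points.loc[~points["district"].isin(known | set(panel["district"]))]
    for i, r in zip(unknown_pts.index, unknown_pts.itertuples()):
        violations.append(f"case point row {i} references unknown district '{r.district}'")
    years = sorted(panel["year"].unique())
    missing_cells = [
        (d, y)
        for d in sorted(set(panel["district"]))
        for y in years
        if not ((panel["district"] == d) & (panel["year"] == y)).any()
    ]
    for d, y in missing_cells:
        log.warning("panel is missing cell (%s, %s)", d, y)
    if violations:
        raise ValidationError(violations)
    log.info(
        "validated panel: %d districts x %d years, %d case points",
        panel["district"].nunique(), len(years), len(points),
    )
    return panel, districts, points


def run_full_analysis(config: AnalysisConfig) -> AnalysisReport:
    """Run every stage on validated inputs; deterministic given the seed.

    Stage failures abort with the stage name and cause.  Districts whose
    series cannot support a grey fit (non-positive values) are skipped with
    a recorded reason, never silently dropped.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    panel, districts, points = _stage("load", load_and_validate, config)

    rates = _stage("rates", rates_table, panel, config.sr_breakpoints, config.ir_zbreaks)
    changes = _stage("rates", change_pattern_table, rates, config.change_step)

    centers_df, ellipses_df, ellipse_objs = _stage(
        "spatial", _spatial_section, panel, districts, points
    )

    scan_params = ScanParams(
        max_pop_fraction=config.scan.max_pop_fraction,
        max_time_fraction=config.scan.max_time_fraction,
        n_replicates=config.scan.n_replicates,
        alpha=config.scan.alpha,
        seed=config.seed,
    )
    results = _stage("scan", detect_clusters, panel, districts, scan_params)
    clusters = clusters_to_frame(results)
    log.info("scan: %d reported cluster(s)", len(clusters))

    skipped: Dict[str, str] = {}
    forecasts, validation, burden_df = _stage(
        "forecast", _grey_section, panel, districts, config.horizon, skipped
    )

    metadata = {
        "seed": config.seed,
        "version": __version__,
        "horizon": config.horizon,
        "scan": {
            "max_pop_fraction": scan_params.max_pop_fraction,
            "max_time_fraction": scan_params.max_time_fraction,
            "n_replicates": scan_params.n_replicates,
            "alpha": scan_params.alpha,
        },
        "sr_breakpoints": list(config.sr_breakpoints),
        "ir_zbreaks": list(config.ir_zbreaks),
        "n_districts": int(panel["district"].nunique()),
        "years": [int(panel["year"].min()), int(panel["year"].max())],
        "total_admissions": int(panel["admissions"].sum()),
        "skipped": skipped,
    }
    return AnalysisReport(
        rates=rates, change_patterns=changes, centers=centers_df,
        ellipses=ellipses_df, ellipse_objects=ellipse_objs, clusters=clusters,
        forecasts=forecasts, validation=validation, burden=burden_df,
        metadata=metadata, skipped=skipped,
    )


def _stage(name, fn, *args):
    try:
        return fn(*args)
    except GreyscanError:
        raise
    except Exception as exc:  # pragma: no cover - defensive
        raise GreyscanError(f"stage '{name}' failed: {exc}") from exc


def _spatial_section(panel, districts, points):
    rows_c, ellipse_objs = [], []
    if len(points):
        by_year = {int(y): grp for y, grp in points.groupby("year")}
        for mc in center_trajectory(by_year):
            rows_c.append(("cases", mc.year, mc.x, mc.y, mc.n_points))
        ellipse_objs = annual_ellipses(points)
    # population mean centers from district centroids weighted by population
    coords = districts.set_index("district")[["x", "y"]]
    pop_by_year = {}
    w_by_year = {}
    for y, grp in panel.groupby("year"):
        pop_by_year[int(y)] = coords.loc[grp["district"]].to_numpy()
        w_by_year[int(y)] = grp["population"].to_numpy(dtype=float)
    for mc in center_trajectory(pop_by_year, w_by_year):
        rows_c.append(("population", mc.year, mc.x, mc.y, mc.n_points))
    centers_df = pd.DataFrame(rows_c, columns=["series", "year", "x", "y", "n"])
    ellipses_df = pd.DataFrame(
        [
            {
                "year": e.center.year, "cx": e.center.x, "cy": e.center.y,
                "sde_x": e.sde_x, "sde_y": e.sde_y, "theta_deg": e.theta,
            }
            for e in ellipse_objs
        ],
        columns=["year", "cx", "cy", "sde_x", "sde_y", "theta_deg"],
    )
    return centers_df, ellipses_df, ellipse_objs


def _grey_section(panel, districts, horizon, skipped):
    years = sorted(int(y) for y in panel["year"].unique())
    future = [years[-1] + h for h in range(1, horizon + 1)]
    hospitals = districts.set_index("district")["hospitals"].to_dict()
    f_rows, v_rows = [], []
    admissions_fc: Dict[str, np.ndarray] = {}
    for d, grp in panel.sort_values("year").groupby("district"):
        ir_series = 1000.0 * grp["admissions"].to_numpy() / grp["population"].to_numpy()
        adm_series = grp["admissions"].to_numpy(dtype=float)
        for kind, series in (("ir", ir_series), ("admissions", adm_series)):
            if np.any(series <= 0):
                skipped[f"{d}:{kind}"] = "series has non-positive values; grey fit skipped"
                log.warning("grey: skipping %s %s (non-positive values)", d, kind)
                continue
            model = fit_and_validate(series, label=f"{d}:{kind}")
            fc = forecast(model, horizon)
            if kind == "admissions":
                admissions_fc[d] = fc
            for y, v in zip(future, fc):
                f_rows.append((d, kind, y, float(v)))
            v_rows.append(
                (d, kind, model.s1, model.s2, model.c, model.p, model.degree,
                 model.alpha, model.mu)
            )
    forecasts = pd.DataFrame(f_rows, columns=["district", "series", "year", "value"])
    validation = pd.DataFrame(
        v_rows, columns=["district", "series", "s1", "s2", "c", "p", "degree", "alpha", "mu"]
    )
    burden_map = grey_burden(admissions_fc, hospitals)
    b_rows = [
        (d, y, float(v))
        for d in sorted(burden_map)
        for y, v in zip(future, burden_map[d])
    ]
    burden_df = pd.DataFrame(b_rows, columns=["district", "year", "burden"])
    return forecasts, validation, burden_df


def write_report(report: AnalysisReport, out_dir) -> Dict[str, str]:
    """Write the report tree (CSV/JSON/GeoJSON) and return a manifest of
    sha256 checksums; the manifest itself is saved as ``manifest.json``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    float_fmt = "%.10g"

    files = {
        "rates.csv": lambda p: report.rates.to_csv(p, index=False, float_format=float_fmt),
        "change_patterns.csv": lambda p: report.change_patterns.to_csv(p, index=False),
        "centers.csv": lambda p: report.centers.to_csv(p, index=False, float_format=float_fmt),
        "ellipses.csv": lambda p: report.ellipses.to_csv(p, index=False, float_format=float_fmt),
        "clusters.csv": lambda p: report.clusters.to_csv(p, index=False, float_format=float_fmt),
        "forecasts.csv": lambda p: report.forecasts.to_csv(p, index=False, float_format=float_fmt),
        "validation.csv": lambda p: report.validation.to_csv(p, index=False, float_format=float_fmt),
        "burden.csv": lambda p: report.burden.to_csv(p, index=False, float_format=float_fmt),
        "clusters.json": lambda p: Path(p).write_text(
            json.dumps(report.clusters.to_dict(orient="records"), indent=2, sort_keys=True)
        ),
        "ellipses.geojson": lambda p: Path(p).write_text(
            json.dumps(ellipses_to_geojson(report.ellipse_objects), sort_keys=True)
        ),
        "metadata.json": lambda p: Path(p).write_text(
            json.dumps(report.metadata, indent=2, sort_keys=True)
        ),
    }
    manifest: Dict[str, str] = {}
    for name, writer in files.items():
        path = out / name
        writer(path)
        manifest[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    log.info("report written to %s (%d files)", out, len(manifest) + 1)
    return manifest
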