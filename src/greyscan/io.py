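"""CSV / GeoJSON / YAML interchange for panels, points, and configs."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from .errors import ConfigError
from .panel import (
    DISTRICT_COLUMNS,
    PANEL_COLUMNS,
    POINT_COLUMNS,
    ClusterSpec,
    PanelConfig,
    SyntheticPanel,
)

PathLike = Union[str, Path]


def _require_columns(df: pd.DataFrame, columns, what: str, path) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ConfigError(f"{what} file {path} lacks columns {missing}")
    return df[list(columns)]


def read_panel_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _require_columns(df, PANEL_COLUMNS, "panel", path)
    return df.astype({"year": int, "population": int, "admissions": int})


def write_panel_csv(records: pd.DataFrame, path: PathLike) -> None:
    records[PANEL_COLUMNS].to_csv(path, index=False)


def read_district_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _require_columns(df, DISTRICT_COLUMNS, "district info", path)
    return df.astype({"x": float, "y": float, "hospitals": int})


def write_district_csv(district_info: pd.DataFrame, path: PathLike) -> None:
    district_info[DISTRICT_COLUMNS].to_csv(path, index=False)


def read_points_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    df = _require_columns(df, POINT_COLUMNS, "case points", path)
    return df.astype({"year": int, "x": float, "y": float})


def write_points_csv(points: pd.DataFrame, path: PathLike) -> None:
    points[POINT_COLUMNS].to_csv(path, index=False)


def points_to_geojson(points: pd.DataFrame) -> dict:
    """Case points as a GeoJSON FeatureCollection of Points."""
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [float(r.x), float(r.y)]},
            "properties": {"district": r.district, "year": int(r.year)},
        }
        for r in points.itertuples()
    ]
    return {"type": "FeatureCollection", "features": features}


def read_points_geojson(path: PathLike) -> pd.DataFrame:
    with open(path) as fh:
        obj = json.load(fh)
    rows = []
    for feat in obj.get("features", []):
        geom = feat.get("geometry", {})
        props = feat.get("properties", {})
        if geom.get("type") != "Point":
            continue
        x, y = geom["coordinates"][:2]
        rows.append((props.get("district"), int(props.get("year")), float(x), float(y)))
    return pd.DataFrame(rows, columns=POINT_COLUMNS)


def ellipses_to_geojson(ellipses, n_vertices: int = 64) -> dict:
    """Annual SDEs as GeoJSON Polygon features (64-gon discretization)."""
    from .spatial import ellipse_to_polygon

    features = []
    for e in ellipses:
        ring = [[x, y] for x, y in ellipse_to_polygon(e, n_vertices)]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": [ring]},
                "properties": {
                    "year": e.center.year,
                    "cx": e.center.x,
                    "cy": e.center.y,
                    "sde_x": e.sde_x,
                    "sde_y": e.sde_y,
                    "theta_deg": e.theta,
                },
            }
        )
    return {"type": "FeatureCollection", "features": features}


def panel_config_from_dict(d: dict) -> PanelConfig:
    """Build a :class:`PanelConfig` from plain key-value data (YAML/JSON)."""
    d = dict(d)
    cluster = d.pop("cluster_spec", None)
    if cluster is not None:
        cluster = ClusterSpec(
            districts=tuple(cluster["districts"]),
            year_start=int(cluster["year_start"]),
            year_end=int(cluster["year_end"]),
            multiplier=float(cluster["multiplier"]),
        )
    try:
        return PanelConfig(
            districts=tuple(d["districts"]),
            year_start=int(d["year_start"]),
            year_end=int(d["year_end"]),
            base_populations=tuple(float(v) for v in d["base_populations"]),
            baseline_rates=tuple(float(v) for v in d["baseline_rates"]),
            centroids=tuple((float(a), float(b)) for a, b in d["centroids"]),
            hospitals=tuple(int(v) for v in d["hospitals"]),
            pop_growth_rate=float(d.get("pop_growth_rate", 0.0)),
            rate_trend=float(d.get("rate_trend", 1.0)),
            centroid_drift=tuple(d.get("centroid_drift", (0.0, 0.0))),
            dispersion=float(d.get("dispersion", 2500.0)),
            cluster_spec=cluster,
            seed=int(d.get("seed", 0)),
        )
    except KeyError as exc:
        raise ConfigError(f"panel config missing field {exc}") from exc


def read_panel_config(path: PathLike) -> PanelConfig:
    with open(path) as fh:
        return panel_config_from_dict(yaml.safe_load(fh))


def write_panel(panel: SyntheticPanel, out_dir: PathLike, prefix: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_panel_csv(panel.records, out / f"{prefix}panel.csv")
    write_district_csv(panel.district_info, out / f"{prefix}districts.csv")
    if len(panel.case_points):
        write_points_csv(panel.case_points, out / f"{prefix}case_points.csv")
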