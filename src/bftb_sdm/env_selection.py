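"""Calibration regions (buffered MCP) and collinearity pruning of predictors.

Each species' calibration/background extent is the minimum convex polygon
(MCP) of its occurrences buffered by a great-circle threshold (default
400 km), intersected with land.  Predictor pruning follows standard SDM
practice: Pearson correlations over the region's land cells; for every
pair with |r| >= 0.8 the member with the lower exploratory jackknife AUC
(a single-variable model with default settings) is dropped, greedily from
the most correlated pair down.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint

from .maxent import (
    env_at_points,
    evaluate_auc,
    expand_features,
    extract_region_env,
    fit_maxent,
    predict_raw,
)
from .occurrences import EARTH_RADIUS_KM, OccurrenceSet
from .raster import RasterGrid

__all__ = [
    "CalibrationRegion",
    "VariableSelection",
    "build_mcp",
    "build_calibration_region",
    "select_variables",
]

log = logging.getLogger(__name__)

_KM_PER_DEG = np.pi * EARTH_RADIUS_KM / 180.0


@dataclass
class CalibrationRegion:
    """A species' calibration extent: MCP + buffer, masked to land."""

    species: str
    mcp: shapely.Geometry
    region_mask: RasterGrid = field(repr=False)  # 1 inside, 0 outside, NaN off land
    threshold_km: float = 400.0

    @property
    def n_cells(self) -> int:
        return int(np.nansum(self.region_mask.values > 0))


def build_mcp(points: np.ndarray) -> shapely.Geometry:
    """Convex hull of lon/lat points (degenerate inputs give point/segment)."""
    pts = np.asarray(points, float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("need at least one point")
    return MultiPoint([tuple(p) for p in pts]).convex_hull


def _distance_km_to_geometry(lons: np.ndarray, lats: np.ndarray, geom: shapely.Geometry) -> np.ndarray:
    """Approximate great-circle distance from points to a lon/lat geometry.

    Uses a local equirectangular metric per point (lon scaled by
    cos(latitude)), accurate to well under a percent at the few-hundred-km
    scales of calibration buffers.  Points inside the geometry get 0.
    """
    lons = np.asarray(lons, float)
    lats = np.asarray(lats, float)
    dist = np.full(lons.shape, np.inf)
    inside = shapely.contains_xy(geom, lons, lats) if geom.area > 0 else np.zeros(lons.shape, bool)
    # boundary vertices as segments
    if geom.geom_type == "Point":
        verts = np.asarray(geom.coords)
        segs = [(verts[0], verts[0])]
    elif geom.geom_type == "LineString":
        verts = np.asarray(geom.coords)
        segs = [(verts[i], verts[i + 1]) for i in range(len(verts) - 1)]
    else:
        verts = np.asarray(geom.exterior.coords)
        segs = [(verts[i], verts[i + 1]) for i in range(len(verts) - 1)]
    coslat = np.cos(np.radians(lats))
    for (ax, ay), (bx, by) in segs:
        dxa = (ax - lons) * coslat * _KM_PER_DEG
        dya = (ay - lats) * _KM_PER_DEG
        dxb = (bx - lons) * coslat * _KM_PER_DEG
        dyb = (by - lats) * _KM_PER_DEG
        ex = dxb - dxa
        ey = dyb - dya
        denom = ex * ex + ey * ey
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(denom > 0, -(dxa * ex + dya * ey) / denom, 0.0)
        t = np.clip(t, 0.0, 1.0)
        px = dxa + t * ex
        py = dya + t * ey
        dist = np.minimum(dist, np.hypot(px, py))
    dist[inside] = 0.0
    return dist


def build_calibration_region(
    occ: OccurrenceSet,
    land_mask: RasterGrid,
    threshold_km: float = 400.0,
) -> CalibrationRegion:
    """Land cells whose centers lie in the MCP or within ``threshold_km`` of it."""
    coords = occ.coords
    if len(coords) == 0:
        raise ValueError(f"{occ.species}: no retained occurrences")
    if threshold_km < 0:
        raise ValueError("threshold_km must be >= 0")
    mcp = build_mcp(coords)
    grid = land_mask.grid
    lon2d, lat2d = grid.center_arrays()
    dist = _distance_km_to_geometry(lon2d.ravel(), lat2d.ravel(), mcp).reshape(grid.shape)
    land = land_mask.values > 0
    in_region = land & (dist <= threshold_km)
    if not in_region.any():
        raise ValueError(f"{occ.species}: calibration region contains no land cells")
    vals = np.where(land, in_region.astype(float), np.nan)
    return CalibrationRegion(
        species=occ.species,
        mcp=mcp,
        region_mask=RasterGrid(name=f"{occ.species}_region", grid=grid, values=vals),
        threshold_km=threshold_km,
    )


@dataclass
class VariableSelection:
    """Result of collinearity pruning over one calibration region."""

    candidate_names: tuple[str, ...]
    retained_names: tuple[str, ...]
    pearson: pd.DataFrame = field(repr=False)
    jackknife_auc: pd.Series = field(repr=False)
    dropped_because_of: dict[str, str] = field(default_factory=dict)

    def report(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variable": list(self.candidate_names),
                "jackknife_auc": [self.jackknife_auc[v] for v in self.candidate_names],
                "retained": [v in self.retained_names for v in self.candidate_names],
                "dropped_because_of": [
                    self.dropped_because_of.get(v, "") for v in self.candidate_names
                ],
            }
        )


def select_variables(
    layers: dict[str, RasterGrid],
    occ: OccurrenceSet,
    region: CalibrationRegion,
    candidate_names: tuple[str, ...] | None = None,
    r_threshold: float = 0.8,
    seed: int = 0,
) -> VariableSelection:
    """Prune collinear predictors by jackknife AUC.

    Each candidate gets an exploratory training AUC from a single-variable
    model with default settings (feature class LQ, RM 1).  While any
    retained pair has |Pearson r| >= ``r_threshold`` over region cells, the
    pair with the largest |r| is resolved by dropping its lower-AUC member
    (AUC ties drop the alphabetically later name, logged).
    """
    if candidate_names is None:
        candidate_names = tuple(layers)
    if len(candidate_names) < 2:
        return VariableSelection(
            candidate_names=tuple(candidate_names),
            retained_names=tuple(candidate_names),
            pearson=pd.DataFrame(),
            jackknife_auc=pd.Series(dtype=float),
        )
    bg_env, _ = extract_region_env(layers, candidate_names, region, seed=seed)
    pr_env, _ = env_at_points(layers, candidate_names, occ.coords)
    pr_env = pr_env[np.all(np.isfinite(pr_env), axis=1)]
    if len(pr_env) == 0:
        raise ValueError(f"{occ.species}: no occurrences with valid environment")

    aucs = {}
    for j, name in enumerate(candidate_names):
        env_all = np.concatenate([bg_env[:, j], pr_env[:, j]])[:, None]
        bg_rows = np.arange(len(bg_env))
        pr_rows = np.arange(len(bg_env), len(env_all))
        fs, F = expand_features(env_all, {"L", "Q"}, background_rows=bg_rows, variable_names=(name,))
        model = fit_maxent(pr_rows, bg_rows, F, rm=1.0, features=fs)
        aucs[name] = evaluate_auc(predict_raw(model, F[pr_rows]), predict_raw(model, F[bg_rows]))
    jack = pd.Series(aucs)

    corr = pd.DataFrame(
        np.corrcoef(bg_env, rowvar=False), index=candidate_names, columns=candidate_names
    )
    retained = list(candidate_names)
    dropped: dict[str, str] = {}
    while True:
        worst = None
        worst_r = r_threshold
        for i, a in enumerate(retained):
            for b in retained[i + 1:]:
                r = abs(corr.loc[a, b])
                if r >= worst_r and (worst is None or r > worst_r):
                    worst, worst_r = (a, b), r
        if worst is None:
            break
        a, b = worst
        if jack[a] > jack[b]:
            drop, keep = b, a
        elif jack[b] > jack[a]:
            drop, keep = a, b
        else:
            drop, keep = max(a, b), min(a, b)
            log.info("AUC tie between %s and %s: dropping %s (alphabetical rule)", a, b, drop)
        retained.remove(drop)
        dropped[drop] = keep
        log.info("dropping %s (|r|=%.3f with %s, AUC %.3f < %.3f)", drop, worst_r, keep, jack[drop], jack[keep])
    return VariableSelection(
        candidate_names=tuple(candidate_names),
        retained_names=tuple(retained),
        pearson=corr,
        jackknife_auc=jack,
        dropped_because_of=dropped,
    )
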