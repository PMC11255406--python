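"""Low-sample-size distribution estimators and tier dispatch.

Species are routed by occurrence count: n >= 5 goes to the MaxEnt tier
(falling back here if tuning fails or mean test AUC < 0.8); 2-4
occurrences use MCP-AT (20-km-buffered minimum convex polygon intersected
with the annual-temperature range observed at the occurrences); a single
occurrence maps to exactly the grid cell containing it (point-to-grid).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .env_selection import CalibrationRegion, _distance_km_to_geometry, build_mcp
from .maxent import DEFAULT_FC_GRID, DEFAULT_RM_GRID, run_replicates, tune_maxent
from .occurrences import OccurrenceSet
from .raster import RasterGrid
from .stacking import binarize, classify_suitability

__all__ = [
    "SpeciesDistribution",
    "mcp_at_distribution",
    "point_to_grid",
    "dispatch_species",
]

log = logging.getLogger(__name__)


@dataclass
class SpeciesDistribution:
    """Final per-species range estimate with its method tag."""

    species: str
    method: str  # "maxent" | "mcp_at" | "point"
    binary_map: RasterGrid = field(repr=False)
    suitability_map: RasterGrid | None = field(default=None, repr=False)
    three_class_map: RasterGrid | None = field(default=None, repr=False)
    metrics: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return int(np.nansum(self.binary_map.values > 0))


def mcp_at_distribution(
    occ: OccurrenceSet,
    at_layer: RasterGrid,
    land_mask: RasterGrid,
    buffer_km: float = 20.0,
) -> SpeciesDistribution:
    """MCP-AT range: buffered occurrence hull clipped to the observed
    annual-temperature (AT) interval.

    The binary map marks land cells within ``buffer_km`` (great-circle) of
    the occurrence MCP whose AT value lies inside the inclusive
    [min, max] range of AT at the occurrence cells.  Occurrences on nodata
    AT cells are excluded from the range; all-nodata is an error.
    """
    coords = occ.coords
    if len(coords) < 1:
        raise ValueError(f"{occ.species}: no occurrences")
    grid = at_layer.grid
    at_vals = []
    for lon, lat in coords:
        try:
            r, c = grid.cell_of(lon, lat)
        except ValueError:
            continue
        v = at_layer.values[r, c]
        if np.isfinite(v):
            at_vals.append(v)
    if not at_vals:
        raise ValueError(f"{occ.species}: all occurrences on nodata AT cells")
    at_min, at_max = float(min(at_vals)), float(max(at_vals))

    mcp = build_mcp(coords)
    lon2d, lat2d = grid.center_arrays()
    dist = _distance_km_to_geometry(lon2d.ravel(), lat2d.ravel(), mcp).reshape(grid.shape)
    land = land_mask.values > 0
    mask1 = land & (dist <= buffer_km)
    at_ok = np.isfinite(at_layer.values) & (at_layer.values >= at_min) & (at_layer.values <= at_max)
    binary = np.where(land, (mask1 & at_ok).astype(float), np.nan)
    return SpeciesDistribution(
        species=occ.species,
        method="mcp_at",
        binary_map=RasterGrid(name=f"{occ.species}_range", grid=grid, values=binary),
        metrics={"at_min": at_min, "at_max": at_max, "buffer_km": buffer_km},
    )


def point_to_grid(occ: OccurrenceSet, land_mask: RasterGrid) -> SpeciesDistribution:
    """Single-occurrence range: the one grid cell containing the record.

    Uses the half-open cell convention (a point on a shared edge belongs
    to the east/north cell).  A point off the grid or on a sea cell is an
    error.
    """
    coords = occ.coords
    if len(coords) != 1:
        raise ValueError(f"point-to-grid requires exactly 1 occurrence, got {len(coords)}")
    grid = land_mask.grid
    lon, lat = coords[0]
    r, c = grid.cell_of(lon, lat)  # raises off-grid
    land = land_mask.values > 0
    if not land[r, c]:
        raise ValueError(f"{occ.species}: occurrence cell ({r}, {c}) is not land")
    binary = np.where(land, 0.0, np.nan)
    binary[r, c] = 1.0
    return SpeciesDistribution(
        species=occ.species,
        method="point",
        binary_map=RasterGrid(name=f"{occ.species}_range", grid=grid, values=binary),
    )


def dispatch_species(
    occ: OccurrenceSet,
    layers: dict[str, RasterGrid],
    region: CalibrationRegion,
    land_mask: RasterGrid,
    variable_names: tuple[str, ...],
    at_layer_name: str = "annual_temp",
    fc_grid: tuple[str, ...] = DEFAULT_FC_GRID,
    rm_grid: tuple[float, ...] = DEFAULT_RM_GRID,
    n_rep: int = 10,
    train_frac: float = 0.8,
    auc_gate: float = 0.8,
    buffer_km: float = 20.0,
    knots_per_var: int = 10,
    max_background: int = 10_000,
    seed: int = 0,
) -> SpeciesDistribution | None:
    """Route one species through the three-tier scheme.

    n >= 5: MaxEnt tuning + replicates, binarized at P10 with a
    three-class (unsuitable / moderate / high) map; on tuning failure or a
    mean test AUC below ``auc_gate`` the species re-enters MCP-AT with all
    its occurrences.  2 <= n <= 4: MCP-AT.  n == 1: point-to-grid.
    n == 0: skipped with a warning (returns None).
    """
    n = occ.n_retained
    at_layer = layers[at_layer_name]
    if n == 0:
        log.warning("%s: no occurrences after cleaning/thinning; skipped", occ.species)
        return None
    if n == 1:
        return point_to_grid(occ, land_mask)
    if n <= 4:
        return mcp_at_distribution(occ, at_layer, land_mask, buffer_km)

    try:
        fc, rm, table = tune_maxent(
            occ, layers, region, variable_names, fc_grid, rm_grid,
            knots_per_var, max_background, seed,
        )
        tuned = run_replicates(
            occ, layers, region, variable_names, fc, rm, n_rep, train_frac,
            knots_per_var, max_background, seed, auc_gate,
        )
    except (RuntimeError, ValueError) as exc:
        log.warning("%s: MaxEnt tier failed (%s); falling back to MCP-AT", occ.species, exc)
        sd = mcp_at_distribution(occ, at_layer, land_mask, buffer_km)
        sd.metrics["maxent_failure"] = str(exc)
        return sd
    if not tuned.success:
        log.info(
            "%s: mean test AUC %.3f below gate %.2f; falling back to MCP-AT",
            occ.species, tuned.mean_test_auc, auc_gate,
        )
        sd = mcp_at_distribution(occ, at_layer, land_mask, buffer_km)
        sd.metrics["mean_test_auc"] = tuned.mean_test_auc
        return sd

    binary = binarize(tuned.suitability, tuned.p10_threshold, land_mask)
    binary.name = f"{occ.species}_range"
    three = classify_suitability(tuned.suitability, tuned.mtp_threshold, tuned.p10_threshold)
    return SpeciesDistribution(
        species=occ.species,
        method="maxent",
        binary_map=binary,
        suitability_map=tuned.suitability,
        three_class_map=three,
        metrics={
            "mean_test_auc": tuned.mean_test_auc,
            "best_fc": fc,
            "best_rm": rm,
            "mtp": tuned.mtp_threshold,
            "p10": tuned.p10_threshold,
        },
    )
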