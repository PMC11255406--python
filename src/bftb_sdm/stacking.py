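"""Stacked-SDM richness surfaces and biodiversity-hotspot delineation.

Per-species binary range maps (thresholded MaxEnt suitability, MCP-AT or
point-to-grid maps) are stacked cellwise into a species-richness surface;
hotspots are the top 5% of land cells by richness, with ties at the cutoff
broken by deterministic row-major cell order so runs are reproducible.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .raster import Grid, RasterGrid

__all__ = [
    "RichnessMap",
    "HotspotMask",
    "binarize",
    "classify_suitability",
    "stack_richness",
    "delineate_hotspots",
]

log = logging.getLogger(__name__)


@dataclass
class RichnessMap:
    """Integer species richness per land cell (NaN off land)."""

    richness: RasterGrid
    n_species_stacked: int

    @property
    def grid(self) -> Grid:
        return self.richness.grid


@dataclass
class HotspotMask:
    """Boolean hotspot raster with its defining fraction and cutoff."""

    mask: RasterGrid  # 1 = hotspot, 0 = other land, NaN off land
    fraction: float
    cutoff_richness: int
    n_hotspot_cells: int


def binarize(suitability: RasterGrid, threshold: float, land_mask: RasterGrid | None = None) -> RasterGrid:
    """Binary map: 1 where suitability >= threshold (on land), else 0.

    Cells that are nodata in ``suitability`` (or off ``land_mask`` when
    given) stay NaN.
    """
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    vals = suitability.values
    out = np.where(np.isfinite(vals), (vals >= threshold).astype(float), np.nan)
    if land_mask is not None:
        out = np.where(land_mask.values > 0, out, np.nan)
    return RasterGrid(name=f"{suitability.name}_bin", grid=suitability.grid, values=out)


def classify_suitability(suitability: RasterGrid, mtp: float, p10: float) -> RasterGrid:
    """Three-class habitat map: 2 highly suitable (s >= p10), 1 moderately
    suitable (mtp <= s < p10), 0 unsuitable (s < mtp)."""
    if mtp > p10:
        raise ValueError(f"mtp ({mtp}) must not exceed p10 ({p10})")
    s = suitability.values
    cls = np.full(s.shape, np.nan)
    ok = np.isfinite(s)
    cls[ok] = 0.0
    cls[ok & (s >= mtp)] = 1.0
    cls[ok & (s >= p10)] = 2.0
    return RasterGrid(name=f"{suitability.name}_3class", grid=suitability.grid, values=cls)


def stack_richness(binary_maps: list[RasterGrid]) -> RichnessMap:
    """Cellwise count of species present; maps must share one grid.

    A cell is land (finite richness) if it is valid in at least one input
    map; nodata cells of an individual map count as absence elsewhere.
    """
    if not binary_maps:
        raise ValueError("no maps to stack")
    grid = binary_maps[0].grid
    for m in binary_maps[1:]:
        if m.grid != grid:
            raise ValueError(f"grid mismatch: {m.name} not on the shared grid")
    total = np.zeros(grid.shape)
    any_valid = np.zeros(grid.shape, bool)
    for m in binary_maps:
        ok = np.isfinite(m.values)
        any_valid |= ok
        total += np.where(ok, m.values > 0, 0.0)
    total[~any_valid] = np.nan
    return RichnessMap(
        richness=RasterGrid(name="richness", grid=grid, values=total),
        n_species_stacked=len(binary_maps),
    )


def delineate_hotspots(richness: RichnessMap | RasterGrid, fraction: float = 0.05) -> HotspotMask:
    """Select the top ``fraction`` of land cells by richness as hotspots.

    ``k = round(fraction * n_land)`` (half away from zero); cells are ranked
    by richness descending with row-major index as the deterministic
    tie-break, and exactly k cells are selected.  ``cutoff_richness`` is the
    richness of the last selected cell.  A uniform (e.g. all-zero) surface
    still yields k cells, with a warning.
    """
    layer = richness.richness if isinstance(richness, RichnessMap) else richness
    vals = layer.values
    flat = vals.ravel()
    land = np.flatnonzero(np.isfinite(flat))
    n_land = land.size
    if n_land < 20:
        raise ValueError(f"need >= 20 land cells, got {n_land}")
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    k = int(math.floor(fraction * n_land + 0.5))
    k = max(k, 1)
    # sort land cells by (richness desc, row-major index asc)
    order = land[np.lexsort((land, -flat[land]))]
    top = order[:k]
    cutoff = flat[top[-1]]
    if np.all(flat[land] == flat[land[0]]):
        log.warning("uniform richness surface: hotspot selection is order-driven")
    mask = np.full(vals.shape, np.nan).ravel()
    mask[land] = 0.0
    mask[top] = 1.0
    return HotspotMask(
        mask=RasterGrid(name="hotspots", grid=layer.grid, values=mask.reshape(vals.shape)),
        fraction=fraction,
        cutoff_richness=int(cutoff),
        n_hotspot_cells=k,
    )


def stack_summary(richness: RichnessMap, hotspots: HotspotMask) -> pd.DataFrame:
    """One-row summary table (n species stacked, cutoff, hotspot cells)."""
    return pd.DataFrame(
        [
            {
                "n_species_stacked": richness.n_species_stacked,
                "cutoff_richness": hotspots.cutoff_richness,
                "n_hotspot_cells": hotspots.n_hotspot_cells,
                "hotspot_fraction": hotspots.fraction,
            }
        ]
    )
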