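"""Occurrence-record handling: validation, cleaning and spatial thinning.

Records are presence coordinates (WGS84 decimal degrees) per species.
Cleaning removes rows with missing/invalid coordinates, exact duplicate
coordinates within a species, and points off the land mask.  Thinning
enforces a minimum great-circle nearest-neighbour distance (default 20 km)
with the classic randomized max-neighbour-removal heuristic: repeatedly
delete a point with the most neighbours closer than the threshold (ties
broken uniformly at random), repeat the whole procedure several times and
keep a largest retained set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid

__all__ = [
    "EARTH_RADIUS_KM",
    "OccurrenceSet",
    "haversine_km",
    "pairwise_haversine_km",
    "clean_occurrences",
    "thin_occurrences",
]

log = logging.getLogger(__name__)

#: IUGG mean Earth radius.
EARTH_RADIUS_KM = 6371.0088

# Per-point provenance flags.
FLAG_RETAINED = "retained"
FLAG_DUPLICATE = "duplicate_removed"
FLAG_OFF_LAND = "off_land"
FLAG_INVALID = "invalid_coordinate"
FLAG_THINNED = "thinned_out"


def _check_lonlat(lon, lat) -> None:
    lon = np.asarray(lon, float)
    lat = np.asarray(lat, float)
    if np.any(~np.isfinite(lon)) or np.any(~np.isfinite(lat)):
        raise ValueError("non-finite coordinate")
    if np.any(np.abs(lon) > 180) or np.any(np.abs(lat) > 90):
        raise ValueError("coordinate out of range: lon in [-180,180], lat in [-90,90]")


def haversine_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Great-circle distance in km between two (lon, lat) points."""
    _check_lonlat([p1[0], p2[0]], [p1[1], p2[1]])
    lon1, lat1, lon2, lat2 = map(np.radians, (p1[0], p1[1], p2[0], p2[1]))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def pairwise_haversine_km(points: np.ndarray) -> np.ndarray:
    """Symmetric matrix of great-circle distances, ``points`` = (n, 2) lon/lat."""
    pts = np.asarray(points, float)
    _check_lonlat(pts[:, 0], pts[:, 1])
    lon = np.radians(pts[:, 0])[:, None]
    lat = np.radians(pts[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    a = np.sin(dlat / 2) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


@dataclass
class OccurrenceSet:
    """One species' occurrence points with per-point provenance flags.

    ``points`` holds every point ever seen for the species (in input order);
    ``flags`` marks each as retained / duplicate_removed / off_land /
    invalid_coordinate / thinned_out.  ``coords`` gives the retained
    (n, 2) lon/lat array used by downstream modelling.
    """

    species: str
    points: np.ndarray = field(repr=False)  # (n, 2) lon/lat, all points
    flags: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, float).reshape(-1, 2)
        if not self.flags:
            self.flags = [FLAG_RETAINED] * len(self.points)
        if len(self.flags) != len(self.points):
            raise ValueError("flags and points length mismatch")

    @property
    def coords(self) -> np.ndarray:
        """Retained (n, 2) lon/lat coordinates."""
        keep = [i for i, f in enumerate(self.flags) if f == FLAG_RETAINED]
        return self.points[keep] if keep else np.empty((0, 2))

    @property
    def n_retained(self) -> int:
        return sum(f == FLAG_RETAINED for f in self.flags)

    def to_frame(self) -> pd.DataFrame:
        """Table with species, lon, lat, retained, flag columns."""
        return pd.DataFrame(
            {
                "species": self.species,
                "lon": self.points[:, 0],
                "lat": self.points[:, 1],
                "retained": [f == FLAG_RETAINED for f in self.flags],
                "flag": self.flags,
            }
        )


def clean_occurrences(
    raw: pd.DataFrame, land_mask: RasterGrid | None = None
) -> dict[str, OccurrenceSet]:
    """Validate and deduplicate raw occurrence rows per species.

    Drops rows with missing or out-of-range coordinates, exact duplicate
    coordinates within a species, and (when ``land_mask`` is given) points
    that fall off the grid or on non-land cells.  Exclusion counts are
    logged per reason; an empty result is allowed.
    """
    for col in ("species", "lon", "lat"):
        if col not in raw.columns:
            raise ValueError(f"occurrence table lacks required column {col!r}")
    out: dict[str, OccurrenceSet] = {}
    for species, sub in raw.groupby("species", sort=True):
        pts: list[tuple[float, float]] = []
        flags: list[str] = []
        seen: set[tuple[float, float]] = set()
        counts = {FLAG_INVALID: 0, FLAG_DUPLICATE: 0, FLAG_OFF_LAND: 0}
        for lon, lat in zip(sub["lon"], sub["lat"]):
            try:
                lon = float(lon)
                lat = float(lat)
                _check_lonlat(lon, lat)
            except (TypeError, ValueError):
                pts.append((np.nan, np.nan))
                flags.append(FLAG_INVALID)
                counts[FLAG_INVALID] += 1
                continue
            if (lon, lat) in seen:
                pts.append((lon, lat))
                flags.append(FLAG_DUPLICATE)
                counts[FLAG_DUPLICATE] += 1
                continue
            if land_mask is not None:
                try:
                    r, c = land_mask.grid.cell_of(lon, lat)
                    on_land = bool(land_mask.values[r, c] > 0)
                except ValueError:
                    on_land = False
                if not on_land:
                    pts.append((lon, lat))
                    flags.append(FLAG_OFF_LAND)
                    counts[FLAG_OFF_LAND] += 1
                    continue
            seen.add((lon, lat))
            pts.append((lon, lat))
            flags.append(FLAG_RETAINED)
        occ = OccurrenceSet(
            species=str(species),
            points=np.array(pts, float).reshape(-1, 2),
            flags=flags,
        )
        log.info(
            "clean %s: %d retained (%d invalid, %d duplicate, %d off land)",
            species, occ.n_retained, counts[FLAG_INVALID],
            counts[FLAG_DUPLICATE], counts[FLAG_OFF_LAND],
        )
        if occ.n_retained == 0:
            log.warning("species %s: no valid occurrences after cleaning", species)
        out[str(species)] = occ
    return out


def _thin_once(dist: np.ndarray, thin_km: float, rng: np.random.Generator) -> np.ndarray:
    """One randomized run of max-neighbour removal; returns a keep mask."""
    n = dist.shape[0]
    keep = np.ones(n, bool)
    close = (dist < thin_km) & ~np.eye(n, dtype=bool)
    while True:
        counts = np.where(keep, (close & keep[None, :]).sum(axis=1), -1)
        worst = counts.max()
        if worst <= 0:
            break
        candidates = np.flatnonzero(counts == worst)
        keep[rng.choice(candidates)] = False
    return keep


def thin_occurrences(
    occ: OccurrenceSet,
    thin_km: float = 20.0,
    seed: int = 0,
    n_repeats: int = 10,
) -> OccurrenceSet:
    """Spatially thin retained points to a minimum spacing of ``thin_km``.

    Runs the randomized removal heuristic ``n_repeats`` times with seeds
    derived from ``seed`` and keeps a solution with the most retained
    points (first such run on ties), so results are deterministic for a
    fixed seed.  Already-thinned input is returned unchanged (idempotent).
    """
    if thin_km <= 0:
        raise ValueError("thin_km must be positive")
    coords = occ.coords
    if len(coords) <= 1:
        return occ
    dist = pairwise_haversine_km(coords)
    off = ~np.eye(len(coords), dtype=bool)
    if dist[off].min() >= thin_km:
        return occ
    rng = np.random.default_rng(seed)
    best: np.ndarray | None = None
    for _ in range(n_repeats):
        keep = _thin_once(dist, thin_km, rng)
        if best is None or keep.sum() > best.sum():
            best = keep
    assert best is not None
    # map the keep decisions back onto the full flag list
    flags = list(occ.flags)
    retained_idx = [i for i, f in enumerate(flags) if f == FLAG_RETAINED]
    for j, i in enumerate(retained_idx):
        if not best[j]:
            flags[i] = FLAG_THINNED
    log.info(
        "thin %s: %d -> %d points at %.0f km", occ.species,
        len(coords), int(best.sum()), thin_km,
    )
    return OccurrenceSet(species=occ.species, points=occ.points.copy(), flags=flags)
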