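"""Aggregation of 1° occurrence cells into ~equal-area regional cells.

Intra-regional beta diversity needs a set of regions of comparable area so
that dissimilarity is computed among a comparable number of 1° cells
everywhere on the globe.  Because the area of a 1°x1° cell shrinks with the
cosine of latitude, regions are built as latitude bands of fixed height
whose longitudinal width grows poleward so that every block stays close to a
target area (250,000 km² by default).

Cells are identified by the integer (lat, lon) of their lower-left corner;
the cell covers the half-open box [lat, lat+1) x [lon, lon+1) and its
centre sits at (lat + 0.5, lon + 0.5).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_DEG_KM",
    "OccurrenceGrid",
    "RegionAssignment",
    "cell_area",
    "build_regions",
    "filter_regions",
    "aggregate_environment",
]

#: km per degree of a great circle on the mean-radius sphere (R = 6371.0088 km)
EARTH_DEG_KM = 2.0 * math.pi * 6371.0088 / 360.0

ENV_COLUMNS = ("t_pres", "t_past", "pet", "prec", "elev", "glaciated")


@dataclass
class OccurrenceGrid:
    """Species presence/absence on integer-degree grid cells.

    Attributes
    ----------
    cells : ndarray, shape (n_cells, 2)
        Integer (lat, lon) lower-left corners, no duplicates.
    species : list of str
        Species identifiers; every species occurs in at least one cell.
    presence : ndarray, shape (n_cells, n_species), uint8
        0/1 occupancy.  All-zero *rows* (occupancy-free cells) are allowed —
        they record surveyed but unoccupied cells.
    groups : list of str, optional
        One taxonomic group label per species (e.g. an order).
    """

    cells: np.ndarray
    species: list
    presence: np.ndarray
    groups: list | None = None

    def __post_init__(self):
        self.cells = np.asarray(self.cells, dtype=int)
        self.presence = np.asarray(self.presence)
        if self.cells.ndim != 2 or self.cells.shape[1] != 2:
            raise ValueError("cells must be an (n, 2) array of integer (lat, lon)")
        if len({tuple(c) for c in self.cells.tolist()}) != len(self.cells):
            raise ValueError("duplicate cells in occurrence grid")
        if self.presence.shape != (len(self.cells), len(self.species)):
            raise ValueError("presence shape must be (n_cells, n_species)")
        if not np.isin(np.unique(self.presence), (0, 1)).all():
            raise ValueError("presence must be strictly 0/1")
        self.presence = self.presence.astype(np.uint8)
        if len(self.species) and (self.presence.sum(axis=0) == 0).any():
            missing = [s for s, tot in zip(self.species, self.presence.sum(axis=0)) if tot == 0]
            raise ValueError(f"species never observed: {missing[:5]}")
        if self.groups is not None and len(self.groups) != len(self.species):
            raise ValueError("groups must align with species")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_species(self) -> int:
        return len(self.species)

    def cell_index(self) -> dict:
        """Mapping (lat, lon) -> row index."""
        return {(int(la), int(lo)): i for i, (la, lo) in enumerate(self.cells)}

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table with one row per (species, occupied cell)."""
        rows, cols = np.nonzero(self.presence)
        frame = pd.DataFrame(
            {
                "species": [self.species[c] for c in cols],
                "lat": self.cells[rows, 0],
                "lon": self.cells[rows, 1],
            }
        )
        if self.groups is not None:
            frame["group"] = [self.groups[c] for c in cols]
        return frame


@dataclass
class RegionAssignment:
    """Partition of grid cells into regional blocks.

    ``cell_table`` has one row per 1° cell (lat, lon, region_id);
    ``region_table`` is indexed by region_id with columns n_cells,
    area_km2, centroid_lat, centroid_lon, centroid_abs_lat and area_ok
    (False for polar/edge remainders outside the area tolerance band).
    """

    cell_table: pd.DataFrame
    region_table: pd.DataFrame
    target_area_km2: float
    band_height_deg: int
    members: dict = field(repr=False, default_factory=dict)

    def region_of(self) -> dict:
        return {
            (int(r.lat), int(r.lon)): int(r.region_id)
            for r in self.cell_table.itertuples(index=False)
        }


def cell_area(lat_edge: float) -> float:
    """Area in km² of the 1°x1° cell whose lower latitude edge is ``lat_edge``.

    Spherical-cap geometry is approximated by ``L² · cos(lat_mid)`` with
    L = one degree of great circle (~111.195 km) and ``lat_mid`` the cell
    centre; exact enough for equal-area blocking and strictly decreasing in
    \\|lat_mid\\|.
    """
    if abs(lat_edge) > 90.0:
        raise ValueError(f"latitude edge {lat_edge} outside [-90, 90]")
    lat_mid = lat_edge + 0.5
    return EARTH_DEG_KM**2 * abs(math.cos(math.radians(lat_mid)))


def build_regions(
    lat_min: int,
    lat_max: int,
    lon_min: int,
    lon_max: int,
    target_area_km2: float = 250_000.0,
    band_height_deg: int = 5,
    area_tol: float = 0.25,
) -> RegionAssignment:
    """Tile an integer-degree extent into ~equal-area regional blocks.

    Latitude is cut into bands of ``band_height_deg``; within each band the
    longitudinal block width is chosen so the block area is as close as
    possible to ``target_area_km2``.  Remainder blocks at the eastern edge
    or truncated polar bands can fall outside the ±``area_tol`` band and are
    flagged ``area_ok = False`` (the inclusion filters drop most of them via
    the minimum-cell rule anyway).
    """
    if lat_min >= lat_max or lon_min >= lon_max:
        raise ValueError("empty extent")
    if target_area_km2 < cell_area(0):
        raise ValueError("target area smaller than a single equatorial cell")
    h = int(band_height_deg)
    if h < 1:
        raise ValueError("band height must be >= 1 degree")

    cell_rows = []
    region_rows = []
    members: dict[int, list[tuple[int, int]]] = {}
    region_id = 0
    lon_span = lon_max - lon_min
    for band_lo in range(lat_min, lat_max, h):
        band_hi = min(band_lo + h, lat_max)
        rows = range(band_lo, band_hi)
        col_area = sum(cell_area(r) for r in rows)  # area of a 1°-wide column
        width = max(1, round(target_area_km2 / col_area))
        width = min(width, lon_span)
        for block_lo in range(lon_min, lon_max, width):
            block_hi = min(block_lo + width, lon_max)
            block_cells = [(r, c) for r in rows for c in range(block_lo, block_hi)]
            area = col_area * (block_hi - block_lo)
            lats = np.array([r + 0.5 for r, _ in block_cells])
            lons = np.array([c + 0.5 for _, c in block_cells])
            region_rows.append(
                {
                    "region_id": region_id,
                    "n_cells": len(block_cells),
                    "area_km2": area,
                    "centroid_lat": lats.mean(),
                    "centroid_lon": lons.mean(),
                    "centroid_abs_lat": abs(lats.mean()),
                    "area_ok": abs(area - target_area_km2) <= area_tol * target_area_km2,
                }
            )
            members[region_id] = block_cells
            for r, c in block_cells:
                cell_rows.append((r, c, region_id))
            region_id += 1

    cell_table = pd.DataFrame(cell_rows, columns=["lat", "lon", "region_id"])
    region_table = pd.DataFrame(region_rows).set_index("region_id")
    return RegionAssignment(cell_table, region_table, float(target_area_km2), h, members)


def filter_regions(
    assignment: RegionAssignment,
    occurrence: OccurrenceGrid,
    min_cells: int = 15,
    min_species: int = 5,
) -> pd.DataFrame:
    """Apply the inclusion filters and report regional (gamma) richness.

    A region is retained iff it contributes at least ``min_cells`` 1° cells
    that exist in the occurrence grid AND its pooled species richness over
    those cells (gamma diversity) is at least ``min_species``.

    Returns a DataFrame indexed by region_id with columns ``n_cells``,
    ``gamma`` and ``retained``.
    """
    index = occurrence.cell_index()
    out = []
    for rid, cells in assignment.members.items():
        rows = [index[c] for c in cells if c in index]
        if rows:
            gamma = int(occurrence.presence[rows].any(axis=0).sum())
        else:
            gamma = 0
        out.append(
            {
                "region_id": rid,
                "n_cells": len(rows),
                "gamma": gamma,
                "retained": len(rows) >= min_cells and gamma >= min_species,
            }
        )
    return pd.DataFrame(out).set_index("region_id")


def aggregate_environment(
    assignment: RegionAssignment,
    cell_env: pd.DataFrame,
    elevation_sd_ddof: int = 0,
) -> pd.DataFrame:
    """Summarize per-cell environment to the regional scale.

    Climate variables are unweighted means over member cells; altitudinal
    variability (``a_range``) is the standard deviation of member-cell
    elevations (population SD by default, ``elevation_sd_ddof=1`` for the
    sample convention); ``t_dif`` is the regional present-minus-past
    temperature difference; ``glaciated`` is True if any member cell was.

    ``cell_env`` must carry columns lat, lon, t_pres, t_past, pet, prec,
    elev, glaciated; a member cell of the assignment missing from
    ``cell_env`` raises a KeyError naming it.
    """
    for col in ("lat", "lon", *ENV_COLUMNS):
        if col not in cell_env.columns:
            raise ValueError(f"cell_env missing column {col!r}")
    env_index = {
        (int(r.lat), int(r.lon)): i
        for i, r in enumerate(cell_env[["lat", "lon"]].itertuples(index=False))
    }
    vals = cell_env[list(ENV_COLUMNS)].to_numpy()
    rows = []
    for rid, cells in assignment.members.items():
        idx = []
        for c in cells:
            if c not in env_index:
                raise KeyError(f"no environmental data for member cell {c} of region {rid}")
            idx.append(env_index[c])
        block = vals[idx]
        t_pres, t_past, pet, prec = block[:, 0].mean(), block[:, 1].mean(), block[:, 2].mean(), block[:, 3].mean()
        a_range = float(np.std(block[:, 4], ddof=elevation_sd_ddof)) if len(idx) > elevation_sd_ddof else 0.0
        rows.append(
            {
                "region_id": rid,
                "t_pres": t_pres,
                "t_past": t_past,
                "t_dif": t_pres - t_past,
                "pet": pet,
                "prec": prec,
                "a_range": a_range,
                "glaciated": bool(block[:, 5].any()),
            }
        )
    table = pd.DataFrame(rows).set_index("region_id")
    table["centroid_abs_lat"] = assignment.region_table["centroid_abs_lat"]
    return table
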