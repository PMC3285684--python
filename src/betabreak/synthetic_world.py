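"""Synthetic gridded worlds with a known latitudinal regime breakpoint.

The generator builds the two ingredients of the study design with full
ground truth:

**Species ranges.**  Two layers combine into a beta-diversity profile that
is high-turnover equatorward of an absolute-latitude breakpoint and slides
continuously into nestedness dominance poleward of it — a kink at the
breakpoint rather than a cliff, which is the latitudinal shape the fitted
broken sticks of the motivating analysis describe.

* A *local* layer of small axis-aligned rectangular ranges tiled
  edge-to-edge, so neighbouring tiles share no species (mutual replacement).
  Tile species richness is constant equatorward of the breakpoint and decays
  linearly to zero across the zone poleward of it (``transition_deg``
  degrees, the full zone by default; 0 reproduces a sharp regime switch).
* A *widespread nested pool* confined poleward of the breakpoint: each pool
  species ranges from a species-specific onset latitude to the polar edge
  and spans a longitudinal *prefix* of the extent (all ranges share the
  western anchor), so along any row the pool composition of eastern cells is
  a subset of western cells, and poleward rows accumulate pool species as
  local species thin out.  Ordered species loss — nestedness — therefore
  dominates dissimilarity where the local layer has faded.

Both hemispheres are handled symmetrically.

**Climate surfaces.**  Present temperature, potential evapotranspiration and
precipitation are linear in absolute latitude (plus optional Gaussian
noise) — smooth gradients with no breakpoint.  The present-minus-glacial
temperature difference T_DIF is continuous piecewise-linear in absolute
latitude with a slope change exactly at the breakpoint (the default slopes
0.09 equatorward / 0.24 poleward echo the magnitude of glacial-age
temperature anomalies at mid latitudes); T_PAST = T_PRES − T_DIF.  Elevation
is flat apart from configured mountain blocks, inside which cell elevations
are drawn with a block-specific standard deviation, giving those areas high
regional altitudinal variability.  Cells poleward of ``glaciation_lat`` are
flagged glaciated.

Every stochastic component draws from its own stream keyed on the master
seed, so e.g. adding species never perturbs the climate noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .regional_grid import OccurrenceGrid

__all__ = [
    "MountainBlock",
    "WorldConfig",
    "WorldBundle",
    "generate_climate_fields",
    "generate_species_ranges",
    "generate_world",
]


@dataclass(frozen=True)
class MountainBlock:
    """Axis-aligned box of cells with elevated topographic variability (m)."""

    lat_min: int
    lat_max: int
    lon_min: int
    lon_max: int
    elev_sd: float = 800.0


@dataclass
class WorldConfig:
    """Full parameterization of a synthetic world.

    Latitudes/longitudes are integer degrees bounding the grid of 1° cells;
    ``breakpoint_lat`` is the absolute latitude separating the turnover
    regime (equatorward) from the nested regime (poleward).  Temperatures in
    °C, PET/PREC in arbitrary mm-like units, elevations in m.
    """

    lat_min: int = 2
    lat_max: int = 62
    lon_min: int = -40
    lon_max: int = 40
    n_species: int = 4000
    breakpoint_lat: int = 37
    turnover_range_cells: int = 4       # footprint of one local-layer range
    nested_max_range_cells: int = 2000  # footprint of the largest pool range
    nested_pool_size: int = 64          # widespread nested species per polar zone
    nested_prefix_classes: int = 8      # distinct longitudinal prefix widths
    transition_deg: float | None = None  # local-layer decay span; None = whole zone
    # climate trends vs absolute latitude
    t_pres_intercept: float = 28.0
    t_pres_slope: float = -0.45         # °C per degree
    pet_intercept: float = 1600.0
    pet_slope: float = -18.0
    prec_intercept: float = 1800.0
    prec_slope: float = -20.0
    t_dif_intercept: float = 2.0
    t_dif_slope_below: float = 0.09     # °C per degree equatorward of the breakpoint
    t_dif_slope_above: float = 0.24     # °C per degree poleward of it
    # noise standard deviations (0 = deterministic surfaces)
    t_noise_sd: float = 0.5
    pet_noise_sd: float = 40.0
    prec_noise_sd: float = 80.0
    t_dif_noise_sd: float = 0.3
    elev_noise_sd: float = 20.0
    mountain_blocks: list = field(
        default_factory=lambda: [
            MountainBlock(8, 20, -35, -27, 900.0),
            MountainBlock(40, 52, 10, 20, 700.0),
        ]
    )
    glaciation_lat: float = 50.0
    group_names: list = field(default_factory=lambda: ["anura", "caudata", "gymnophiona"])
    seed: int = 0

    def __post_init__(self):
        if self.lat_min >= self.lat_max or self.lon_min >= self.lon_max:
            raise ValueError("empty grid extent")
        max_abs = max(abs(self.lat_min), abs(self.lat_max))
        if not 0 < self.breakpoint_lat:
            raise ValueError("breakpoint_lat must be positive (absolute latitude)")
        if self.breakpoint_lat > max_abs:
            raise ValueError("breakpoint_lat outside the grid extent")
        if self.n_species < 1:
            raise ValueError("need at least one species")
        if self.turnover_range_cells < 1 or self.nested_max_range_cells < 1:
            raise ValueError("range sizes must be positive cell counts")
        if self.nested_pool_size < 0 or self.nested_prefix_classes < 1:
            raise ValueError("invalid nested-pool parameters")
        if self.transition_deg is not None and self.transition_deg < 0:
            raise ValueError("transition_deg must be >= 0")
        for name in (
            "t_noise_sd", "pet_noise_sd", "prec_noise_sd",
            "t_dif_noise_sd", "elev_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        params = [
            self.t_pres_intercept, self.t_pres_slope, self.pet_intercept,
            self.pet_slope, self.prec_intercept, self.prec_slope,
            self.t_dif_intercept, self.t_dif_slope_below, self.t_dif_slope_above,
            self.glaciation_lat,
        ]
        if not all(math.isfinite(p) for p in params):
            raise ValueError("non-finite climate parameter")
        if not 0.0 <= self.glaciation_lat <= max_abs:
            raise ValueError("glaciation_lat outside the grid extent")
        self.mountain_blocks = [
            b if isinstance(b, MountainBlock) else MountainBlock(**b)
            for b in self.mountain_blocks
        ]

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "WorldConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class WorldBundle:
    """A generated world: occupancy, per-cell environment and its truth."""

    occurrence: OccurrenceGrid
    cell_env: pd.DataFrame
    truth: WorldConfig


def _grid_cells(cfg: WorldConfig) -> np.ndarray:
    lats = np.arange(cfg.lat_min, cfg.lat_max)
    lons = np.arange(cfg.lon_min, cfg.lon_max)
    la, lo = np.meshgrid(lats, lons, indexing="ij")
    return np.column_stack([la.ravel(), lo.ravel()])


def generate_climate_fields(config: WorldConfig) -> pd.DataFrame:
    """Per-cell environmental table (lat, lon, t_pres, t_past, pet, prec,
    elev, glaciated).

    T_PRES/PET/PREC are linear in absolute cell-centre latitude plus noise;
    T_DIF is continuous piecewise-linear with its kink at
    ``breakpoint_lat``; T_PAST = T_PRES − T_DIF.  Deterministic given the
    config seed.
    """
    cells = _grid_cells(config)
    abs_lat = np.abs(cells[:, 0] + 0.5)
    n = len(cells)
    rng_climate = np.random.default_rng([config.seed, 11])
    rng_elev = np.random.default_rng([config.seed, 13])

    def noisy(sd):
        return rng_climate.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)

    t_pres = config.t_pres_intercept + config.t_pres_slope * abs_lat + noisy(config.t_noise_sd)
    pet = config.pet_intercept + config.pet_slope * abs_lat + noisy(config.pet_noise_sd)
    prec = config.prec_intercept + config.prec_slope * abs_lat + noisy(config.prec_noise_sd)
    bp = config.breakpoint_lat
    t_dif = (
        config.t_dif_intercept
        + config.t_dif_slope_below * np.minimum(abs_lat, bp)
        + config.t_dif_slope_above * np.maximum(abs_lat - bp, 0.0)
        + noisy(config.t_dif_noise_sd)
    )
    elev = (
        rng_elev.normal(0.0, config.elev_noise_sd, size=n)
        if config.elev_noise_sd > 0
        else np.zeros(n)
    )
    for block in config.mountain_blocks:
        inside = (
            (cells[:, 0] >= block.lat_min)
            & (cells[:, 0] < block.lat_max)
            & (cells[:, 1] >= block.lon_min)
            & (cells[:, 1] < block.lon_max)
        )
        elev = elev + np.where(inside, rng_elev.normal(0.0, block.elev_sd, size=n), 0.0)
    glaciated = abs_lat >= config.glaciation_lat

    return pd.DataFrame(
        {
            "lat": cells[:, 0],
            "lon": cells[:, 1],
            "t_pres": t_pres,
            "t_past": t_pres - t_dif,
            "pet": pet,
            "prec": prec,
            "elev": elev,
            "glaciated": glaciated,
        }
    )


def _local_density(abs_lat: float, bp: float, transition: float) -> float:
    """Relative richness of the local tiled layer at one absolute latitude:
    1 equatorward of the breakpoint, decaying linearly to 0 over
    ``transition`` degrees poleward of it (0 = sharp switch)."""
    if abs_lat <= bp:
        return 1.0
    if transition <= 0:
        return 0.0
    return max(0.0, 1.0 - (abs_lat - bp) / transition)


def _contiguous_runs(rows: list) -> list:
    runs = []
    for r in rows:
        if runs and r == runs[-1][-1] + 1:
            runs[-1].append(r)
        else:
            runs.append([r])
    return runs


def generate_species_ranges(config: WorldConfig) -> OccurrenceGrid:
    """Occupancy grid realizing the turnover-to-nestedness gradient.

    The *local layer* tiles the whole extent with ``turnover_range_cells``
    rectangles; per-tile species counts follow the latitude-dependent
    density (constant equatorward of the breakpoint, linear decay poleward
    of it), with counts dithered along each tile row so the decay is smooth
    rather than a rounding staircase.  The *nested pool* places, per polar
    zone, ``nested_pool_size`` widespread species whose ranges run from an
    onset latitude (onsets spread evenly across the zone) to the polar edge
    and cover a western longitudinal prefix whose width cycles through
    ``nested_prefix_classes`` values up to
    ``nested_max_range_cells / zone_depth`` columns.

    Which species identity lands on which tile/prefix slot is the only
    random choice (keyed on the seed); the occupied structure itself is
    fixed by the config.
    """
    cells = _grid_cells(config)
    lats = np.arange(config.lat_min, config.lat_max)
    lon_span = config.lon_max - config.lon_min
    bp = float(config.breakpoint_lat)

    polar_rows = [int(r) for r in lats if abs(r + 0.5) > bp]
    zones = _contiguous_runs(polar_rows)

    # --- local layer: tiled rectangular ranges with graded density -------
    side = max(1, round(math.sqrt(config.turnover_range_cells)))
    tile_h, tile_w = side, max(1, round(config.turnover_range_cells / side))
    tile_rows = []  # (mean_abs_lat, [tile cell lists ordered along the row])
    for r0 in range(config.lat_min, config.lat_max, tile_h):
        rs = [r for r in range(r0, min(r0 + tile_h, config.lat_max))]
        mean_abs = float(np.mean([abs(r + 0.5) for r in rs]))
        row_tiles = []
        for c0 in range(config.lon_min, config.lon_max, tile_w):
            cs = range(c0, min(c0 + tile_w, config.lon_max))
            row_tiles.append([(r, c) for r in rs for c in cs])
        tile_rows.append((mean_abs, row_tiles))

    n_local = max(0, config.n_species - config.nested_pool_size * len(zones))
    default_transition = (
        max((len(z) for z in zones), default=1.0)
        if config.transition_deg is None
        else float(config.transition_deg)
    )
    weights = [
        _local_density(mean_abs, bp, default_transition) for mean_abs, _ in tile_rows
    ]
    total_weight = sum(w * len(rt) for w, (_, rt) in zip(weights, tile_rows))
    per_unit = n_local / total_weight if total_weight > 0 else 0.0

    tile_counts = []  # aligned with a flat tile list
    flat_tiles = []
    for w, (_, row_tiles) in zip(weights, tile_rows):
        mu = per_unit * w
        # Bresenham dithering along the row keeps the latitudinal decay
        # smooth even when the per-tile mean is below one species
        prev = 0
        for i, tile in enumerate(row_tiles, start=1):
            count = math.floor(mu * i + 1e-9) - prev
            prev += count
            flat_tiles.append(tile)
            tile_counts.append(count)

    # --- nested pool: poleward ranges with western prefix structure ------
    pool_ranges = []
    for zone in zones:
        depth = len(zone)
        northern = zone[0] >= 0
        q_max = max(1, min(lon_span, config.nested_max_range_cells // depth))
        q_classes = [
            max(1, round((j + 1) * q_max / config.nested_prefix_classes))
            for j in range(config.nested_prefix_classes)
        ]
        for i in range(config.nested_pool_size):
            onset = min(depth - 1, math.floor((i + 0.5) * depth / config.nested_pool_size))
            rows = zone[onset:] if northern else zone[: depth - onset]
            width = q_classes[i % len(q_classes)]
            cols = range(config.lon_min, config.lon_min + width)
            pool_ranges.append([(r, c) for r in rows for c in cols])

    # species identity assignment is the only seeded choice
    rng = np.random.default_rng([config.seed, 17])
    slots = [(0, i) for i, c in enumerate(tile_counts) for _ in range(c)]
    slots += [(1, i) for i in range(len(pool_ranges))]
    if not slots:
        raise ValueError("extent/species budget too small to host a single range")
    order = rng.permutation(len(slots))

    cell_index = {(int(la), int(lo)): i for i, (la, lo) in enumerate(cells)}
    presence = np.zeros((len(cells), len(slots)), dtype=np.uint8)
    species = []
    groups = []
    n_groups = max(1, len(config.group_names))
    for sp, slot_idx in enumerate(order):
        layer, idx = slots[slot_idx]
        footprint = flat_tiles[idx] if layer == 0 else pool_ranges[idx]
        for cell in footprint:
            presence[cell_index[cell], sp] = 1
        species.append(("turn_" if layer == 0 else "nest_") + f"{sp:05d}")
        groups.append(config.group_names[sp % n_groups] if config.group_names else "all")

    keep = presence.sum(axis=0) > 0
    presence = presence[:, keep]
    species = [s for s, k in zip(species, keep) if k]
    groups = [g for g, k in zip(groups, keep) if k]
    if not species:
        raise ValueError("extent too small to host a single range")
    return OccurrenceGrid(cells=cells, species=species, presence=presence, groups=groups)


def generate_world(config: WorldConfig) -> WorldBundle:
    """Generate occupancy and environment for one config (deterministic)."""
    occurrence = generate_species_ranges(config)
    cell_env = generate_climate_fields(config)
    return WorldBundle(occurrence=occurrence, cell_env=cell_env, truth=config)
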