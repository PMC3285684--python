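"""Reading and writing the pipeline's tabular artifacts.

Occurrence data travels as a long-format CSV with columns ``species, lat,
lon`` (plus an optional ``group`` column); coordinates are snapped to the
integer-degree grid by flooring, duplicates collapse to a single presence.
Environment tables are plain per-cell CSVs as produced by
:func:`betabreak.synthetic_world.generate_climate_fields`.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .regional_grid import ENV_COLUMNS, OccurrenceGrid

__all__ = [
    "read_occurrence_table",
    "write_occurrence_table",
    "read_env_table",
    "write_env_table",
]


def read_occurrence_table(path) -> OccurrenceGrid:
    """Load a long-format occurrence CSV into an :class:`OccurrenceGrid`.

    Raises ``ValueError`` naming the first offending row (1-based, header
    excluded) on non-numeric coordinates or latitudes outside [-90, 90].
    """
    frame = pd.read_csv(path)
    for col in ("species", "lat", "lon"):
        if col not in frame.columns:
            raise ValueError(f"occurrence table missing column {col!r}")
    lats = pd.to_numeric(frame["lat"], errors="coerce")
    lons = pd.to_numeric(frame["lon"], errors="coerce")
    bad = lats.isna() | lons.isna()
    if bad.any():
        row = int(np.flatnonzero(bad)[0]) + 1
        raise ValueError(f"non-numeric coordinate at row {row}")
    out_of_range = (lats.abs() > 90) | (lons.abs() > 360)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range)[0]) + 1
        raise ValueError(f"coordinate out of range at row {row}")

    cell_lat = np.floor(lats.to_numpy()).astype(int)
    cell_lon = np.floor(lons.to_numpy()).astype(int)
    species_names = sorted(frame["species"].astype(str).unique())
    sp_index = {s: j for j, s in enumerate(species_names)}
    cell_keys = sorted({(int(a), int(b)) for a, b in zip(cell_lat, cell_lon)})
    cell_pos = {c: i for i, c in enumerate(cell_keys)}
    presence = np.zeros((len(cell_keys), len(species_names)), dtype=np.uint8)
    for s, la, lo in zip(frame["species"].astype(str), cell_lat, cell_lon):
        presence[cell_pos[(int(la), int(lo))], sp_index[s]] = 1

    groups = None
    if "group" in frame.columns:
        by_species = frame.groupby(frame["species"].astype(str))["group"].first()
        groups = [str(by_species[s]) for s in species_names]
    return OccurrenceGrid(
        cells=np.array(cell_keys), species=species_names, presence=presence, groups=groups
    )


def write_occurrence_table(grid: OccurrenceGrid, path) -> None:
    grid.to_long_frame().to_csv(path, index=False)


def read_env_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("lat", "lon", *ENV_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"environment table missing columns {missing}")
    frame["glaciated"] = frame["glaciated"].astype(bool)
    return frame


def write_env_table(cell_env: pd.DataFrame, path) -> None:
    cell_env.to_csv(path, index=False)


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonable(v) for k, v in vars(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        if math.isinf(f):
            return "inf" if f > 0 else "-inf"
        if math.isnan(f):
            return None
        return f
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    return obj


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")
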