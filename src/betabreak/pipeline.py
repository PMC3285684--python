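"""End-to-end orchestration of the intra-regional beta-diversity study.

The full analysis runs the three stages of the study design in order:

1. **Regionalize** — aggregate the 1° occurrence grid into ~250,000 km²
   regional cells, apply the inclusion filters (>= 15 cells and gamma
   richness >= 5 by default) and compute each region's resampled
   beta_SOR/beta_SIM/beta_NES triple and environmental summary.
2. **Breakpoints** — piecewise-regress each response (the three beta
   components and the climate variables T_DIF, T_PRES, PET) on absolute
   centroid latitude, compare against the linear fit by ANOVA, and
   summarize segment means ± 95% CI.
3. **Drivers** — Dutilleul-corrected correlations between beta components
   and environmental variables (total and split at the beta_SIM
   breakpoint), partial-regression variance partitions, the glaciated vs
   non-glaciated Mann-Whitney contrasts above the breakpoint, and the
   richness–beta Spearman correlations.

Everything is deterministic under the master seed; per-region resampling
draws from a stream keyed on (seed, region id) so region order is
irrelevant.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as bio
from .beta_partition import resampled_beta
from .breakpoint_regression import (
    ModelComparison,
    PiecewiseFit,
    compare_to_linear,
    search_breakpoint,
    segment_summary,
)
from .regional_grid import (
    OccurrenceGrid,
    RegionAssignment,
    aggregate_environment,
    build_regions,
    filter_regions,
)
from .spatial_stats import dutilleul_correlation, mann_whitney, spearman
from .synthetic_world import WorldConfig, generate_world
from .variance_partition import partition_variation

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "AnalysisReport",
    "compute_region_beta",
    "subset_by_group",
    "run_full_analysis",
    "write_report",
]

ENV_VARS = ("t_pres", "t_past", "t_dif", "pet", "prec", "a_range")
BETA_VARS = ("beta_sim", "beta_nes")
DEFAULT_RESPONSES = ("beta_sor", "beta_sim", "beta_nes", "t_dif", "t_pres", "pet")
DEFAULT_VARPART_GROUPS = {
    "beta_sim": {"A": ["a_range"], "B": ["t_pres", "t_past"]},
    "beta_nes": {"A": ["pet"], "B": ["t_pres", "t_past"]},
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Configuration of a full run (synthetic world or user files)."""

    world: WorldConfig | None = field(default_factory=WorldConfig)
    occurrence_path: str | None = None
    env_path: str | None = None
    target_area_km2: float = 250_000.0
    band_height_deg: int = 1
    min_cells: int = 15
    min_species: int = 5
    resample_k: int = 15
    resample_reps: int = 10
    breakpoint_mode: str = "continuous"
    min_seg: int = 5
    responses: tuple = DEFAULT_RESPONSES
    n_distance_classes: int = 10
    varpart_groups: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_VARPART_GROUPS.items()})
    elevation_sd_ddof: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.world is not None and isinstance(self.world, dict):
            self.world = WorldConfig(**self.world)
        if self.world is None and (self.occurrence_path is None or self.env_path is None):
            raise ValueError("config needs either a synthetic world or occurrence+env paths")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = asdict(self)
        raw["responses"] = list(self.responses)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass
class AnalysisReport:
    region_beta: pd.DataFrame
    region_env: pd.DataFrame
    merged: pd.DataFrame
    fits: dict                      # response -> {fit, comparison, segments}
    correlations: pd.DataFrame
    varpart: pd.DataFrame
    contrasts: dict                 # Mann-Whitney glaciated contrasts
    richness_correlations: dict     # Spearman gamma vs beta components
    metadata: dict
    log: list = field(default_factory=list)


def subset_by_group(occurrence: OccurrenceGrid, label: str) -> OccurrenceGrid:
    """Restrict an occurrence grid to one species group (e.g. one order).

    Cells left with no species are dropped; downstream filters re-apply.
    """
    if occurrence.groups is None:
        raise ValueError("occurrence grid carries no group labels")
    labels = sorted(set(occurrence.groups))
    if label not in labels:
        raise ValueError(f"unknown group {label!r}; available: {labels}")
    keep_sp = np.array([g == label for g in occurrence.groups])
    presence = occurrence.presence[:, keep_sp]
    keep_cells = presence.any(axis=1)
    return OccurrenceGrid(
        cells=occurrence.cells[keep_cells],
        species=[s for s, k in zip(occurrence.species, keep_sp) if k],
        presence=presence[keep_cells],
        groups=[label] * int(keep_sp.sum()),
    )


def compute_region_beta(
    occurrence: OccurrenceGrid,
    assignment: RegionAssignment,
    min_cells: int = 15,
    min_species: int = 5,
    k: int = 15,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Resampled beta partition for every retained region.

    Occupancy-free member cells are dropped before sampling (multiple-site
    dissimilarity is undefined on empty sites); a region must retain at
    least ``k`` non-empty cells to be scored.
    """
    stats = filter_regions(assignment, occurrence, min_cells=min_cells, min_species=min_species)
    index = occurrence.cell_index()
    rows = []
    for rid in stats.index[stats["retained"]]:
        cell_rows = [index[c] for c in assignment.members[rid] if c in index]
        mat = occurrence.presence[cell_rows]
        mat = mat[mat.any(axis=1)]  # empty sites carry no compositional signal
        if mat.shape[0] < k:
            continue
        mat = mat[:, mat.any(axis=0)]
        rng = np.random.default_rng([seed, 23, int(rid)])
        triple = resampled_beta(mat, k=k, reps=reps, seed=rng)
        rows.append(
            {
                "region_id": rid,
                "n_cells": int(stats.loc[rid, "n_cells"]),
                "gamma": int(stats.loc[rid, "gamma"]),
                "beta_sor": triple.beta_sor,
                "beta_sim": triple.beta_sim,
                "beta_nes": triple.beta_nes,
                "centroid_abs_lat": float(assignment.region_table.loc[rid, "centroid_abs_lat"]),
            }
        )
    return pd.DataFrame(rows).set_index("region_id") if rows else pd.DataFrame(
        columns=["n_cells", "gamma", "beta_sor", "beta_sim", "beta_nes", "centroid_abs_lat"]
    )


def _correlation_grid(merged: pd.DataFrame, split_bp: float, n_classes: int) -> pd.DataFrame:
    """Table-1-shaped grid: env variable x beta component x subset."""
    coords = merged[["centroid_lat", "centroid_lon"]].to_numpy()
    rows = []
    subsets = {
        "total": np.ones(len(merged), dtype=bool),
        "above": merged["centroid_abs_lat"].to_numpy() > split_bp,
        "below": merged["centroid_abs_lat"].to_numpy() <= split_bp,
    }
    for var in ENV_VARS:
        for comp in BETA_VARS:
            for sub_name, mask in subsets.items():
                n = int(mask.sum())
                if n < 10:
                    rows.append(
                        {"variable": var, "component": comp, "subset": sub_name,
                         "r": np.nan, "p": np.nan, "m_hat": np.nan, "n": n}
                    )
                    continue
                x = merged.loc[mask, var].to_numpy()
                y = merged.loc[mask, comp].to_numpy()
                if np.std(x) == 0 or np.std(y) == 0:
                    rows.append(
                        {"variable": var, "component": comp, "subset": sub_name,
                         "r": np.nan, "p": np.nan, "m_hat": np.nan, "n": n}
                    )
                    continue
                res = dutilleul_correlation(x, y, coords[mask], n_classes=n_classes)
                rows.append(
                    {"variable": var, "component": comp, "subset": sub_name,
                     "r": res.r, "p": res.p_value, "m_hat": res.m_hat, "n": n}
                )
    return pd.DataFrame(rows)


def _varpart_tables(merged: pd.DataFrame, groups: dict, split_bp: float, log=None) -> pd.DataFrame:
    frames = []
    subsets = {
        "total": np.ones(len(merged), dtype=bool),
        "above": merged["centroid_abs_lat"].to_numpy() > split_bp,
        "below": merged["centroid_abs_lat"].to_numpy() <= split_bp,
    }
    for response, spec in groups.items():
        (label_a, cols_a), (label_b, cols_b) = list(spec.items())
        for sub_name, mask in subsets.items():
            sub = merged.loc[mask]
            if len(sub) <= len(cols_a) + len(cols_b) + 2:
                continue
            try:
                part = partition_variation(
                    sub[response].to_numpy(),
                    sub[list(cols_a)].to_numpy(),
                    sub[list(cols_b)].to_numpy(),
                    labels=("+".join(cols_a), "+".join(cols_b)),
                )
            except ValueError as exc:
                # e.g. exactly collinear predictors in a noise-free world
                if log is not None:
                    log.append(f"           varpart[{response}/{sub_name}] skipped: {exc}")
                continue
            frame = part.to_frame()
            frame.insert(0, "response", response)
            frame.insert(1, "subset", sub_name)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def run_full_analysis(config: PipelineConfig) -> AnalysisReport:
    """Execute the complete study design and assemble the report."""
    log = []
    t0 = time.perf_counter()

    def stage(msg):
        log.append(f"[{time.perf_counter() - t0:8.2f}s] {msg}")

    if config.world is not None:
        bundle = generate_world(config.world)
        occurrence, cell_env = bundle.occurrence, bundle.cell_env
        stage(
            f"generated synthetic world: {occurrence.n_cells} cells, "
            f"{occurrence.n_species} species, breakpoint {config.world.breakpoint_lat}"
        )
    else:
        occurrence = bio.read_occurrence_table(config.occurrence_path)
        cell_env = bio.read_env_table(config.env_path)
        stage(f"loaded {occurrence.n_cells} cells / {occurrence.n_species} species from files")

    lat_min = int(occurrence.cells[:, 0].min())
    lat_max = int(occurrence.cells[:, 0].max()) + 1
    lon_min = int(occurrence.cells[:, 1].min())
    lon_max = int(occurrence.cells[:, 1].max()) + 1
    assignment = build_regions(
        lat_min, lat_max, lon_min, lon_max,
        target_area_km2=config.target_area_km2,
        band_height_deg=config.band_height_deg,
    )
    stage(f"built {len(assignment.region_table)} candidate regions "
          f"(target {config.target_area_km2:.0f} km2, bands {config.band_height_deg} deg)")

    region_beta = compute_region_beta(
        occurrence, assignment,
        min_cells=config.min_cells, min_species=config.min_species,
        k=config.resample_k, reps=config.resample_reps, seed=config.seed,
    )
    stage(f"retained {len(region_beta)} regions after filters "
          f"(min_cells={config.min_cells}, min_species={config.min_species}) "
          f"and resampling (k={config.resample_k}, reps={config.resample_reps})")
    if len(region_beta) < 10:
        raise PipelineError(
            f"only {len(region_beta)} regions retained (need >= 10); "
            "relax the filters or enlarge the extent"
        )

    region_env = aggregate_environment(
        assignment, cell_env, elevation_sd_ddof=config.elevation_sd_ddof
    )
    merged = region_beta.join(region_env.drop(columns=["centroid_abs_lat"]), how="inner")
    merged = merged.join(assignment.region_table[["centroid_lat", "centroid_lon"]])
    stage("aggregated regional environment")

    fits = {}
    for response in config.responses:
        x = merged["centroid_abs_lat"].to_numpy()
        y = merged[response].to_numpy()
        fit = search_breakpoint(x, y, mode=config.breakpoint_mode, min_seg=config.min_seg)
        comparison = compare_to_linear(x, y, fit)
        segments = segment_summary(y, x, fit.breakpoint)
        fits[response] = {"fit": fit, "comparison": comparison, "segments": segments}
        stage(f"breakpoint[{response}] = {fit.breakpoint:.0f} "
              f"(RSE {fit.residual_se:.4g}, F={comparison.f_statistic:.3g})")

    split_bp = fits["beta_sim"]["fit"].breakpoint if "beta_sim" in fits else float(
        np.median(merged["centroid_abs_lat"])
    )
    correlations = _correlation_grid(merged, split_bp, config.n_distance_classes)
    stage(f"correlation grid at split breakpoint {split_bp:.0f}")

    varpart = _varpart_tables(merged, config.varpart_groups, split_bp, log=log)
    stage("variance partitions")

    above = merged[merged["centroid_abs_lat"] > split_bp]
    contrasts = {}
    glaciated = above[above["glaciated"]]
    unglaciated = above[~above["glaciated"]]
    if len(glaciated) >= 2 and len(unglaciated) >= 2:
        for comp in BETA_VARS:
            u, p = mann_whitney(glaciated[comp].to_numpy(), unglaciated[comp].to_numpy())
            contrasts[comp] = {
                "U": u, "p": p,
                "n_glaciated": len(glaciated), "n_unglaciated": len(unglaciated),
                "mean_glaciated": float(glaciated[comp].mean()),
                "mean_unglaciated": float(unglaciated[comp].mean()),
            }
        stage(f"glaciated contrast above {split_bp:.0f}: "
              f"{len(glaciated)} glaciated vs {len(unglaciated)} non-glaciated")
    else:
        stage("glaciated contrast skipped (a group has < 2 regions)")

    richness = {}
    for comp in BETA_VARS:
        rho, p = spearman(merged["gamma"].to_numpy(), merged[comp].to_numpy())
        richness[comp] = {"rho": rho, "p": p, "n": len(merged)}
    stage("richness-beta rank correlations")

    metadata = {
        "seed": config.seed,
        "n_regions": len(merged),
        "split_breakpoint": split_bp,
        "target_area_km2": config.target_area_km2,
        "band_height_deg": config.band_height_deg,
        "min_cells": config.min_cells,
        "min_species": config.min_species,
        "resample_k": config.resample_k,
        "resample_reps": config.resample_reps,
        "breakpoint_mode": config.breakpoint_mode,
        "min_seg": config.min_seg,
        "n_distance_classes": config.n_distance_classes,
        "elevation_sd_ddof": config.elevation_sd_ddof,
        "world": None if config.world is None else asdict(config.world),
    }
    return AnalysisReport(
        region_beta=region_beta,
        region_env=region_env,
        merged=merged,
        fits=fits,
        correlations=correlations,
        varpart=varpart,
        contrasts=contrasts,
        richness_correlations=richness,
        metadata=metadata,
        log=log,
    )


def write_report(report: AnalysisReport, outdir) -> None:
    """Write every report table/record to ``outdir`` (CSV + JSON + log)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.region_beta.to_csv(out / "region_beta.csv")
    report.region_env.to_csv(out / "region_env.csv")
    report.merged.to_csv(out / "region_merged.csv")
    report.correlations.to_csv(out / "correlations.csv", index=False)
    report.varpart.to_csv(out / "variance_partition.csv", index=False)
    bio.write_json(report.fits, out / "breakpoint_fits.json")
    bio.write_json(
        {"glaciation_contrasts": report.contrasts, "richness_correlations": report.richness_correlations},
        out / "group_tests.json",
    )
    bio.write_json(report.metadata, out / "metadata.json")
    (out / "run_log.txt").write_text("\n".join(report.log) + "\n")
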