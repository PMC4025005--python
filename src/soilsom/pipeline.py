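"""End-to-end orchestration: risk scoring → kriging/zonal → SOM → clusters → stats.

Stage order follows the analysis design: score point samples with the
Hakanson indices; krige each per-metal contamination factor and RI onto a
grid and average within town polygons; assemble the 20-variable town matrix
(19 covariates + town RI); scan map sizes (optional) and train the SOM;
cluster the codebook with k-means selected by minimum DBI and project
cluster labels to towns; and characterize the clusters with summary,
metal, and correlation tables.

Every stage writes its artifacts under the output directory and records a
SHA-256 checksum in ``manifest.json``; a single master seed is fanned out
to per-stage child seeds (CRC of the stage name) so stages are individually
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import project_labels, select_k
from .errors import ConfigError, DataError, SoilSomError
from .risk import METALS, MetalPanel, score_samples
from .som import (DEFAULT_SIZE_CANDIDATES, SOMConfig, component_planes,
                  map_size_scan, train, u_matrix)
from .spatial import (Grid, GridSpec, UnitPolygon, empirical_variogram,
                      fit_variogram, krige_grid, units_from_geojson, zonal_mean)
from .stats import cluster_summary, correlation_table, format_correlation_table
from .synthetic import COVARIATES

logger = logging.getLogger("soilsom")

STAGES = ("ri", "interpolate", "som-scan", "train", "cluster", "stats")

_KNOWN_KEYS = {
    "samples", "towns", "covariates", "panel", "out_dir", "seed",
    "grid_cell_size", "variogram_family", "n_lags",
    "map_size", "candidate_sizes", "rough_epochs", "finetune_epochs",
    "lattice", "init", "k_range", "n_restarts", "posthoc_method", "alpha",
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration.

    Paths may be filesystem paths or pre-loaded objects (DataFrame / list of
    :class:`UnitPolygon` / :class:`MetalPanel`), which keeps the library
    surface usable without touching disk.
    """

    samples: object                      # path or DataFrame
    towns: object                        # path or list[UnitPolygon]
    covariates: object                   # path or DataFrame
    panel: object                        # path or MetalPanel
    out_dir: Path
    seed: int = 0
    grid_cell_size: float = 0.01
    variogram_family: str = "spherical"
    n_lags: int = 12
    map_size: tuple[int, int] | None = None
    candidate_sizes: Sequence[tuple[int, int]] = DEFAULT_SIZE_CANDIDATES
    rough_epochs: int = 10
    finetune_epochs: int = 20
    lattice: str = "hexagonal"
    init: str = "linear"
    k_range: Sequence[int] = tuple(range(2, 11))
    n_restarts: int = 10
    posthoc_method: str = "tukey"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        if self.grid_cell_size <= 0:
            raise ConfigError("grid_cell_size must be positive")
        if self.variogram_family not in ("spherical", "exponential"):
            raise ConfigError(f"unknown variogram family {self.variogram_family!r}")
        if self.posthoc_method not in ("tukey", "duncan"):
            raise ConfigError(f"unknown posthoc method {self.posthoc_method!r}")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        missing = {"samples", "towns", "covariates", "panel", "out_dir"} - set(d)
        if missing:
            raise ConfigError(f"missing config keys: {sorted(missing)}")
        d = dict(d)
        if "map_size" in d and d["map_size"] is not None:
            d["map_size"] = tuple(d["map_size"])
        if "candidate_sizes" in d:
            d["candidate_sizes"] = [tuple(s) for s in d["candidate_sizes"]]
        if "k_range" in d:
            kr = d["k_range"]
            d["k_range"] = tuple(range(kr[0], kr[1] + 1)) if len(kr) == 2 else tuple(kr)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage child seed (CRC-32 of the stage name, below 2^31)."""
    return (int(master_seed) * 1000003 + zlib.crc32(stage.encode())) % (2 ** 31)


def _load_samples(src) -> pd.DataFrame:
    return src if isinstance(src, pd.DataFrame) else pd.read_csv(src)


def _load_towns(src) -> list[UnitPolygon]:
    if isinstance(src, (list, tuple)):
        return list(src)
    return units_from_geojson(json.loads(Path(src).read_text()))


def _load_covariates(src) -> pd.DataFrame:
    if isinstance(src, pd.DataFrame):
        return src
    return pd.read_csv(src, index_col="unit_id")


def _load_panel(src) -> MetalPanel:
    if isinstance(src, MetalPanel):
        return src
    return MetalPanel.from_dict(yaml.safe_load(Path(src).read_text()))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def assemble_feature_matrix(covariates: pd.DataFrame, town_ri: pd.Series) -> pd.DataFrame:
    """Join the 19 covariates with town RI into the cases x 20 SOM matrix.

    Towns missing RI (no grid coverage) are dropped with a warning; an id
    mismatch above 5% is a hard error.
    """
    town_ri = town_ri.dropna()
    common = covariates.index.intersection(town_ri.index)
    mismatch = 1.0 - len(common) / max(len(covariates), 1)
    if mismatch > 0.05:
        raise DataError(f"{mismatch:.0%} of towns lack RI values (> 5%)")
    dropped = covariates.index.difference(common)
    if len(dropped):
        logger.warning("dropping %d town(s) without RI coverage: %s",
                       len(dropped), list(dropped[:5]))
    cols = [c for c in COVARIATES if c in covariates.columns]
    cols += [c for c in covariates.columns if c not in cols]
    mat = covariates.loc[common.sort_values(), cols].copy()
    mat["RI"] = town_ri.loc[mat.index]
    return mat


def interpolate_to_towns(
    scored: pd.DataFrame,
    samples: pd.DataFrame,
    towns: Sequence[UnitPolygon],
    cell_size: float = 0.01,
    family: str = "spherical",
    n_lags: int = 12,
    fields: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, dict[str, Grid]]:
    """Krige each requested field and aggregate to town means.

    ``fields`` defaults to every per-metal contamination factor plus RI.
    Returns the towns x fields table and the kriged grids.
    """
    if fields is None:
        fields = [f"cf_{m}" for m in METALS] + ["ri"]
    lon = samples["lon"].to_numpy(float)
    lat = samples["lat"].to_numpy(float)
    all_x = np.concatenate([lon, [b for t in towns for b in t.geometry.bounds[0::2]]])
    all_y = np.concatenate([lat, [b for t in towns for b in t.geometry.bounds[1::2]]])
    spec = GridSpec.cover(all_x, all_y, cell_size)
    grids: dict[str, Grid] = {}
    out: dict[str, dict[str, float]] = {}
    for f in fields:
        vals = scored[f].to_numpy(float)
        lag_table = empirical_variogram(lon, lat, vals, n_lags=n_lags)
        model = fit_variogram(lag_table, family=family)
        grid = krige_grid(lon, lat, vals, model, spec)
        grids[f] = grid
        out[f] = zonal_mean(grid, towns)
    table = pd.DataFrame(out)
    table.index.name = "unit_id"
    return table, grids


def run_pipeline(config: PipelineConfig, stages: Sequence[str] | None = None) -> dict:
    """Run the pipeline (or a prefix-closed subset of stages) and write artifacts.

    Returns the run manifest: seed, package version, per-stage output
    checksums, and headline numbers (selected map size, selected k).
    Partial outputs from completed stages are retained on failure.
    """
    stages = list(stages) if stages is not None else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ConfigError(f"unknown stages: {sorted(unknown)}")
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "version": __version__,
                      "stages": {}, "checksums": {}}

    def record(stage: str, *paths: Path) -> None:
        manifest["stages"][stage] = "ok"
        for p in paths:
            manifest["checksums"][str(p.relative_to(out))] = _checksum(p)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    current = "setup"
    try:
        samples = _load_samples(config.samples)
        towns = _load_towns(config.towns)
        covariates = _load_covariates(config.covariates)
        panel = _load_panel(config.panel)

        scored = None
        if "ri" in stages:
            current = "ri"
            scored = score_samples(samples, panel)
            p = out / "risk.csv"
            scored.to_csv(p, index=False)
            record("ri", p)

        town_table = None
        if "interpolate" in stages:
            current = "interpolate"
            if scored is None:
                scored = pd.read_csv(out / "risk.csv")
            town_table, grids = interpolate_to_towns(
                scored, samples, towns, cell_size=config.grid_cell_size,
                family=config.variogram_family, n_lags=config.n_lags)
            p = out / "town_indices.csv"
            town_table.sort_index().to_csv(p)
            gpaths = []
            for name, grid in grids.items():
                gp = out / f"grid_{name}.csv"
                grid.to_frame().to_csv(gp, index=False)
                gpaths.append(gp)
            record("interpolate", p, *gpaths)

        matrix = None
        if {"som-scan", "train", "cluster", "stats"} & set(stages):
            if town_table is None:
                town_table = pd.read_csv(out / "town_indices.csv", index_col="unit_id")
            matrix = assemble_feature_matrix(covariates, town_table["ri"])
            p = out / "feature_matrix.csv"
            matrix.to_csv(p)

        som_seed = stage_seed(config.seed, "train")
        map_size = config.map_size
        if "som-scan" in stages:
            current = "som-scan"
            cfg = SOMConfig(n_rows=2, n_cols=2, lattice=config.lattice,
                            init=config.init, rough_epochs=config.rough_epochs,
                            finetune_epochs=config.finetune_epochs, seed=som_seed)
            records, selected = map_size_scan(matrix, config.candidate_sizes, cfg)
            scan = pd.DataFrame([{"n_rows": r.n_rows, "n_cols": r.n_cols,
                                  "units": r.n_rows * r.n_cols,
                                  "qe": r.qe, "te": r.te} for r in records])
            p = out / "map_quality.csv"
            scan.to_csv(p, index=False)
            record("som-scan", p)
            manifest["selected_map_size"] = list(selected)
            if map_size is None:
                map_size = selected
        if map_size is None:
            map_size = (12, 7)

        model = None
        if "train" in stages:
            current = "train"
            cfg = SOMConfig(n_rows=map_size[0], n_cols=map_size[1],
                            lattice=config.lattice, init=config.init,
                            rough_epochs=config.rough_epochs,
                            finetune_epochs=config.finetune_epochs, seed=som_seed)
            model = train(matrix, cfg)
            cb = pd.DataFrame(model.denormalized_codebook(),
                              columns=model.variable_names)
            cb.index.name = "unit"
            p1 = out / "codebook.csv"
            cb.to_csv(p1)
            umat, edges = u_matrix(model)
            p2 = out / "umatrix.csv"
            pd.DataFrame(umat).to_csv(p2, index=False)
            p3 = out / "umatrix_edges.csv"
            edges.to_csv(p3, index=False)
            planes = component_planes(model)
            p4 = out / "component_planes.csv"
            pd.concat({k: pd.DataFrame(v) for k, v in planes.items()},
                      names=["variable", "row"]).to_csv(p4)
            meta = {"config": {"n_rows": cfg.n_rows, "n_cols": cfg.n_cols,
                               "lattice": cfg.lattice, "init": cfg.init,
                               "rough_epochs": cfg.rough_epochs,
                               "finetune_epochs": cfg.finetune_epochs,
                               "seed": cfg.seed},
                    "variable_names": model.variable_names,
                    "norm_mean": model.norm_params.mean.tolist(),
                    "norm_sd": model.norm_params.sd.tolist()}
            p5 = out / "som_model.json"
            p5.write_text(json.dumps(meta, indent=2))
            record("train", p1, p2, p3, p4, p5)

        town_labels = None
        if "cluster" in stages:
            current = "cluster"
            if model is None:
                raise ConfigError("cluster stage requires the train stage")
            best, scan = select_k(model.codebook, config.k_range,
                                  seed=stage_seed(config.seed, "cluster"),
                                  n_restarts=config.n_restarts)
            p1 = out / "dbi_scan.csv"
            scan.to_csv(p1, index=False)
            ul = pd.DataFrame({"unit": np.arange(model.n_units),
                               "cluster": best.labels + 1})
            p2 = out / "unit_labels.csv"
            ul.to_csv(p2, index=False)
            town_labels = pd.Series(
                project_labels(model, best.labels, matrix) + 1,
                index=matrix.index, name="cluster")
            p3 = out / "town_clusters.csv"
            town_labels.to_csv(p3)
            record("cluster", p1, p2, p3)
            manifest["selected_k"] = int(best.k)
            manifest["dbi"] = float(best.dbi)

        if "stats" in stages:
            current = "stats"
            if town_labels is None:
                raise ConfigError("stats stage requires the cluster stage")
            all_clusters = sorted(town_labels.unique().tolist())
            summary = cluster_summary(matrix, town_labels.to_numpy(),
                                      method=config.posthoc_method,
                                      alpha=config.alpha,
                                      all_clusters=all_clusters)
            p1 = out / "cluster_summary.csv"
            summary["formatted"].to_csv(p1)

            sample_clusters = town_labels.reindex(samples["town_id"]).to_numpy()
            keep = ~pd.isna(sample_clusters)
            metal_summary = cluster_summary(
                samples.loc[keep, list(METALS)],
                sample_clusters[keep].astype(int),
                method=config.posthoc_method, alpha=config.alpha,
                all_clusters=all_clusters)
            p2 = out / "metal_summary.csv"
            metal_summary["formatted"].to_csv(p2)

            corr = correlation_table(matrix.drop(columns=["RI"]),
                                     matrix["RI"], town_labels.to_numpy())
            p3 = out / "correlation_table.csv"
            format_correlation_table(corr).to_csv(p3)
            record("stats", p1, p2, p3)

        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except SoilSomError:
        logger.error("pipeline failed in stage %r", current)
        raise
    except Exception as e:
        logger.error("pipeline failed in stage %r: %s", current, e)
        raise SoilSomError(f"stage {current!r} failed: {e}") from e
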