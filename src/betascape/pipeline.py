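"""End-to-end pipeline: rasterize -> fields -> turnover -> .dif -> PCNM ->
filter selection -> partial regression, model selection and latitude /
longitude correlations, with a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import beta as beta_mod
from . import io as io_mod
from . import spatial as spatial_mod
from . import stats as stats_mod
from .exceptions import ConfigError, InvalidSpecError
from .grid import CellField, Grid, PAMatrix, clade_subset, restricted_range_subset, richness

logger = logging.getLogger("betascape")

__all__ = ["PipelineConfig", "run_pipeline", "analysis_cells", "aligned_predictors"]


@dataclass
class PipelineConfig:
    """Declarative description of one full analysis run.

    Unknown keys are rejected up front; every field has a documented
    default, and a config written with :meth:`to_yaml` reads back
    identically.
    """

    grid: str = "grid.json"  # grid-definition JSON
    input_mode: str = "polygons"  # polygons | pam
    ranges: str | None = None  # GeoJSON (polygons mode)
    pam: str | None = None  # PAM CSV (pam mode)
    env_layers: dict = field(default_factory=dict)  # name -> gridded CSV path
    clades: list = field(default_factory=list)  # clade labels analyzed separately
    restricted_quantile: float | None = 0.25
    coverage_threshold: float = 0.5
    adjacency: str = "queen"  # queen | rook
    diff_mode: str = "absolute"  # absolute | signed
    sqrt_turnover: bool = True
    distance_metric: str = "greatcircle"  # greatcircle | degrees
    pcnm_beyond_factor: float = 4.0
    filter_alpha: float = 0.05
    filter_select_on: str = "residual"  # residual | response
    filter_min_improvement: float = 0.05
    filter_permutations: int = 199
    max_filters: int | None = 12
    max_filter_candidates: int | None = 60
    out_dir: str = "betascape_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**doc)
        if cfg.input_mode not in ("polygons", "pam"):
            raise ConfigError("input_mode must be 'polygons' or 'pam'")
        if cfg.adjacency not in ("queen", "rook"):
            raise ConfigError("adjacency must be 'queen' or 'rook'")
        if cfg.diff_mode not in ("absolute", "signed"):
            raise ConfigError("diff_mode must be 'absolute' or 'signed'")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(doc, dict):
            raise ConfigError(f"config {path} is not a mapping")
        return cls.from_dict(doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def analysis_cells(rich: CellField, layers: list[CellField]) -> np.ndarray:
    """Boolean mask of land cells used in regressions: richness >= 1 and
    every layer defined.  A fixed cell set keeps AICc comparable across
    models."""
    ok = (~rich.missing) & (rich.values >= 1)
    for lay in layers:
        ok &= ~lay.missing
    return ok


def aligned_predictors(
    layers: list[CellField],
    mask: np.ndarray,
    filters: np.ndarray | None,
) -> stats_mod.PredictorSet:
    names = [lay.name for lay in layers]
    X = np.column_stack([lay.values[mask] for lay in layers])
    F = filters[mask] if filters is not None else None
    return stats_mod.PredictorSet(names=names, values=X, filters=F)


def _partial_table(res: stats_mod.PartialRegressionResult) -> pd.DataFrame:
    rows = [
        {
            "term": "global",
            "r2": res.global_r2,
            "r2_partial": res.global_r2_partial,
            "f": res.global_f,
            "p": res.global_p,
        }
    ]
    for name in res.predictor_names:
        rows.append(
            {
                "term": name,
                "r2": res.semipartial_r2[name],
                "r2_partial": np.nan,
                "f": res.f_values[name],
                "p": res.p_values[name],
            }
        )
    return pd.DataFrame(rows)


def _selection_table(rows: list[stats_mod.ModelSelectionRow], names: list[str]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = {name: r.coefficients.get(name, np.nan) for name in names}
        rec.update({"r2": r.r2, "aicc": r.aicc, "delta_aicc": r.delta_aicc, "weight": r.weight})
        recs.append(rec)
    return pd.DataFrame(recs)


def _write_table(df: pd.DataFrame, path: Path, cfg_hash: str, n: int) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg_hash} n={n}\n")
        df.to_csv(fh, index=False)


@dataclass
class StageResult:
    """Per-response statistical outputs of one pipeline run."""

    name: str
    n: int
    partial: stats_mod.PartialRegressionResult
    selection: list[stats_mod.ModelSelectionRow]
    vif: dict[str, float]
    pearson_lat: float
    pearson_lon: float
    n_filters: int


@dataclass
class RunResult:
    config: PipelineConfig
    grid: Grid
    pam: PAMatrix
    fields: dict
    stages: dict
    manifest: dict
    out_dir: Path


def _analyze_response(
    name: str,
    response: CellField,
    layers: list[CellField],
    grid: Grid,
    filters: spatial_mod.SpatialFilterSet,
    weights: spatial_mod.SpatialWeights,
    cfg: PipelineConfig,
    rich: CellField,
    rng_seed: int,
) -> StageResult:
    mask = analysis_cells(rich, layers) & (~response.missing)
    n = int(mask.sum())
    if n <= len(layers) + 5:
        raise InvalidSpecError(f"analysis cell set for {name!r} is too small (n={n})")
    y = response.values[mask]
    sub_w = weights.restrict(mask)
    sub_filters = spatial_mod.SpatialFilterSet(
        truncation_t=filters.truncation_t,
        eigenvalues=filters.eigenvalues,
        eigenvectors=filters.eigenvectors[mask],
        metric=filters.metric,
    )
    target = y
    if cfg.filter_select_on == "residual":
        Xp = np.column_stack([np.ones(n)] + [lay.values[mask] for lay in layers])
        beta_hat, *_ = np.linalg.lstsq(Xp, y, rcond=None)
        target = y - Xp @ beta_hat
    sel = spatial_mod.select_filters(
        target,
        sub_filters,
        sub_w,
        alpha=cfg.filter_alpha,
        seed=rng_seed,
        n_permutations=cfg.filter_permutations,
        max_k=cfg.max_filters,
        max_candidates=cfg.max_filter_candidates,
        min_improvement=cfg.filter_min_improvement,
    )
    F = sel.vectors if sel.vectors is not None and sel.vectors.shape[1] else None
    pred = stats_mod.PredictorSet(
        names=[lay.name for lay in layers],
        values=np.column_stack([lay.values[mask] for lay in layers]),
        filters=F,
    )
    partial = stats_mod.partial_regression(y, pred)
    selection = stats_mod.model_selection(y, pred)
    vifs = stats_mod.vif(pred)
    centers = grid.land_centers()[mask]
    p_lat = stats_mod.pearson(y, centers[:, 0])
    p_lon = stats_mod.pearson(y, centers[:, 1])
    return StageResult(
        name=name,
        n=n,
        partial=partial,
        selection=selection,
        vif=vifs,
        pearson_lat=p_lat,
        pearson_lon=p_lon,
        n_filters=0 if F is None else F.shape[1],
    )


def run_pipeline(config: PipelineConfig) -> RunResult:
    """Execute the full analysis described by ``config`` and write all
    tables, fields and a run manifest to ``config.out_dir``."""
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()
    t0 = time.perf_counter()
    timings: dict[str, float] = {}

    def _tick(stage: str, start: float) -> None:
        timings[stage] = round(time.perf_counter() - start, 4)
        logger.info("stage %s done in %.2fs", stage, timings[stage])

    # --- inputs -------------------------------------------------------------
    t = time.perf_counter()
    grid = io_mod.read_grid(cfg.grid)
    if cfg.input_mode == "polygons":
        if not cfg.ranges:
            raise ConfigError("polygons mode requires 'ranges'")
        from .rasterize import build_pam

        ranges = io_mod.read_ranges_geojson(cfg.ranges)
        pam = build_pam(ranges, grid, cfg.coverage_threshold)
    else:
        if not cfg.pam:
            raise ConfigError("pam mode requires 'pam'")
        pam = io_mod.read_pam(cfg.pam, grid)
    layers = [
        io_mod.read_field(path, grid, name=name) for name, path in cfg.env_layers.items()
    ]
    if not layers:
        raise ConfigError("env_layers must name at least one layer")
    _tick("inputs", t)

    # --- diversity fields ----------------------------------------------------
    t = time.perf_counter()
    fields: dict[str, CellField] = {}
    groups: dict[str, PAMatrix] = {"all": pam}
    for label in cfg.clades:
        groups[label] = clade_subset(pam, label)
    for label, sub in groups.items():
        fields[f"richness_{label}"] = richness(sub)
    if cfg.restricted_quantile:
        fields["richness_restricted"] = richness(
            restricted_range_subset(pam, cfg.restricted_quantile)
        )
    turnovers: dict[str, CellField] = {}
    for label, sub in groups.items():
        tf = beta_mod.neighborhood_turnover(sub, adjacency=cfg.adjacency)
        if cfg.sqrt_turnover:
            tf = beta_mod.sqrt_transform(tf)
        turnovers[label] = tf
        fields[f"turnover_{label}"] = tf
    dif_layers = [
        beta_mod.neighborhood_env_diff(lay, adjacency=cfg.adjacency, mode=cfg.diff_mode)
        for lay in layers
    ]
    for lay in dif_layers:
        fields[lay.name] = lay
    _tick("fields", t)

    # --- spatial filters ------------------------------------------------------
    t = time.perf_counter()
    coords = grid.land_centers()
    t_trunc = spatial_mod.mst_truncation(coords, cfg.distance_metric)
    filters = spatial_mod.pcnm(
        coords, t_trunc, metric=cfg.distance_metric, beyond_factor=cfg.pcnm_beyond_factor
    )
    weights = spatial_mod.queen_weights(grid, cfg.adjacency)
    _tick("pcnm", t)

    # --- statistics -----------------------------------------------------------
    t = time.perf_counter()
    stages: dict[str, StageResult] = {}
    rich_all = fields["richness_all"]
    for label in groups:
        stages[f"richness_{label}"] = _analyze_response(
            f"richness_{label}", fields[f"richness_{label}"], layers, grid,
            filters, weights, cfg, rich_all, cfg.seed,
        )
        stages[f"turnover_{label}"] = _analyze_response(
            f"turnover_{label}", turnovers[label], dif_layers, grid,
            filters, weights, cfg, rich_all, cfg.seed,
        )
    _tick("stats", t)

    # --- outputs --------------------------------------------------------------
    t = time.perf_counter()
    io_mod.write_grid(grid, out / "grid.json")
    io_mod.write_pam(pam, out / "pam.csv")
    for name, f in fields.items():
        io_mod.write_field(f, out / f"{name.replace('.', '_')}.csv")
    corr_rows = []
    for sname, st in stages.items():
        base = sname.replace(".", "_")
        _write_table(_partial_table(st.partial), out / f"partial_{base}.csv", cfg_hash, st.n)
        _write_table(
            _selection_table(st.selection, st.partial.predictor_names),
            out / f"modelsel_{base}.csv",
            cfg_hash,
            st.n,
        )
        corr_rows.append(
            {"response": sname, "r_latitude": st.pearson_lat, "r_longitude": st.pearson_lon}
        )
    _write_table(pd.DataFrame(corr_rows), out / "correlations.csv", cfg_hash, grid.n_land)
    manifest = {
        "package": "betascape",
        "config": cfg.to_dict(),
        "config_hash": cfg_hash,
        "seed": cfg.seed,
        "n_land_cells": grid.n_land,
        "n_species": pam.n_species,
        "species_with_empty_ranges": pam.empty_species,
        "pcnm": {"truncation_t": filters.truncation_t, "k": filters.k, "metric": filters.metric},
        "stages": {
            s: {"n": st.n, "n_filters": st.n_filters} for s, st in stages.items()
        },
        "timings_s": timings,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    _tick("outputs", t)
    manifest["total_s"] = round(time.perf_counter() - t0, 4)

    return RunResult(
        config=cfg, grid=grid, pam=pam, fields=fields, stages=stages,
        manifest=manifest, out_dir=out,
    )
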