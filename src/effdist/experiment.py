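"""Simulation experiments and comparative statistics.

Two experiment designs mirror the study conditions:

* fixed-size: landscapes share one dimension (1000 x 1000 in the reference
  design); the autocorrelation range is drawn uniformly from [1, 1000] map
  units (resampled until range <= dim); 15 focal nodes give 105 pairs per
  landscape.  Each landscape is additionally degraded once by a random
  spatial factor and once by a random thematic class count, both uniform
  integers in [2, 20], applied independently.
* variable-size: the dimension itself is a uniform integer in [100, 1000]
  (10,000 to 1,000,000 pixels), with range <= dim enforced and no duplicate
  (dim, range) draws; no aggregation treatments.

Agreement between effective-distance metrics is measured per landscape by
Spearman rank correlation; aggregation effects by the drop in that
correlation (delta-rho) and by each metric's before/after self-correlation.
Pooled pair tables feed the OLS regressions (raw scale against Euclidean
distance; log-log against pixel count).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .aggregate import remap_nodes, spatial_aggregate, thematic_aggregate
from .distance import compute_pair_table
from .errors import EffdistError, NodePlacementError
from .graph import build_graph
from .landscape import (
    CostRaster,
    FocalNodes,
    VariogramSpec,
    place_nodes,
    rescale_to_cost,
    simulate_grf,
)

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "run_fixed_size",
    "run_variable_size",
    "spearman_rho",
    "ols_fit",
    "pct_increase_per_doubling",
    "delta_rho",
    "method_self_correlation",
    "summarize",
]


# ---------------------------------------------------------------- statistics


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for constant input")
    return float(scipy.stats.spearmanr(x, y).statistic)


def ols_fit(y, x, transform: str = "raw") -> tuple[np.ndarray, float]:
    """OLS of y on one or more predictors; returns (slopes, r_squared).

    ``transform``: 'raw', 'log_y' (log response only) or 'log_both'
    (natural log of response and every predictor).  An intercept is always
    included; slopes exclude it.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(x, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if transform not in ("raw", "log_y", "log_both"):
        raise ValueError(f"unknown transform {transform!r}")
    if transform in ("log_y", "log_both"):
        y = np.log(y)
    if transform == "log_both":
        X = np.log(X)
    if len(y) <= X.shape[1] + 1:
        raise ValueError("not enough observations for the number of predictors")
    design = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear predictors: design matrix is rank-deficient")
    fit = sm.OLS(y, design).fit()
    return np.asarray(fit.params[1:]), float(fit.rsquared)


def pct_increase_per_doubling(loglog_slope: float) -> float:
    """Percent change in the response per doubling of the predictor.

    For a log-log slope b, doubling x multiplies y by 2**b, i.e. a
    100*(2**b - 1) percent change.
    """
    return 100.0 * (2.0**loglog_slope - 1.0)


def delta_rho(baseline: float, treated: float) -> float:
    """Drop in rank correlation due to a treatment: baseline - treated."""
    return baseline - treated


def method_self_correlation(
    before: pd.DataFrame, after: pd.DataFrame, metric: str
) -> float:
    """Spearman rho between one metric's pairwise values before/after a treatment."""
    keys = ["node_a", "node_b"]
    if metric not in before.columns or metric not in after.columns:
        raise ValueError(f"metric {metric!r} missing from a pair table")
    merged = before[keys + [metric]].merge(
        after[keys + [metric]], on=keys, suffixes=("_before", "_after"), how="outer"
    )
    if merged.isna().any().any() or len(merged) != len(before):
        raise ValueError("pair tables do not cover the same node pairs")
    return spearman_rho(merged[f"{metric}_before"], merged[f"{metric}_after"])


# ------------------------------------------------------------- configuration


@dataclass(frozen=True)
class ExperimentConfig:
    """Study conditions for one batch of simulated landscapes."""

    n_landscapes: int = 30
    dim: int = 1000  # fixed-size experiments
    dim_range: tuple[int, int] = (100, 1000)  # variable-size experiments
    sill: float = 0.025
    range_bounds: tuple[float, float] = (1.0, 1000.0)
    n_nodes: int = 15
    buffer_frac: float = 0.10
    seed: int = 0
    solver_tol: float = 1e-8
    metrics: tuple[str, ...] = ("lcd", "resistance", "commute")
    treatments: bool = True
    factor_bounds: tuple[int, int] = (2, 20)
    class_bounds: tuple[int, int] = (2, 20)
    max_retries: int = 5
    neighbourhood: int = 8
    averaging: str = "resistance"
    diagonal_correction: bool = False

    def __post_init__(self):
        if self.n_landscapes < 1:
            raise ValueError("n_landscapes must be >= 1")
        if self.range_bounds[0] > self.range_bounds[1]:
            raise ValueError("range_bounds must be ordered")
        if self.dim_range[0] > self.dim_range[1]:
            raise ValueError("dim_range must be ordered")


@dataclass
class ExperimentResult:
    """Per-landscape summaries plus the pooled pairwise-distance archives."""

    landscapes: pd.DataFrame
    pairs: pd.DataFrame
    treated_pairs: pd.DataFrame | None
    config: ExperimentConfig
    failures: list[str] = field(default_factory=list)

    @property
    def n_ok(self) -> int:
        return len(self.landscapes)


# ------------------------------------------------------------------ plumbing


def _draw_range(rng: np.random.Generator, bounds, dim: int) -> float:
    lo, hi = bounds
    for _ in range(100_000):
        r = rng.uniform(lo, hi)
        if r <= dim:
            return r
    raise EffdistError(f"could not draw a range <= dim={dim} from U{bounds}")


def _one_landscape(
    cfg: ExperimentConfig, dim: int, range_param: float, rng: np.random.Generator
) -> tuple[CostRaster, FocalNodes]:
    spec = VariogramSpec(sill=cfg.sill, range_param=range_param)
    field_ = simulate_grf(spec, dim, rng)
    raster = rescale_to_cost(field_)
    nodes = place_nodes(raster, n=cfg.n_nodes, buffer_frac=cfg.buffer_frac, seed=rng)
    return raster, nodes


def _pairs(cfg, raster, nodes, lid):
    return compute_pair_table(
        raster,
        nodes,
        landscape_id=lid,
        metrics=cfg.metrics,
        tol=cfg.solver_tol,
        neighbourhood=cfg.neighbourhood,
        averaging=cfg.averaging,
        diagonal_correction=cfg.diagonal_correction,
    )


def _apply_spatial(cfg, raster, nodes, rng):
    """Draw a spatial factor, retrying (bounded) on node collision."""
    last = None
    for _ in range(cfg.max_retries):
        f = int(rng.integers(cfg.factor_bounds[0], cfg.factor_bounds[1] + 1))
        agg = spatial_aggregate(raster, f)
        try:
            coarse = remap_nodes(nodes, f, agg.dim)
        except NodePlacementError as exc:
            last = exc
            continue
        return f, agg, coarse
    raise NodePlacementError(
        f"no collision-free spatial factor in {cfg.max_retries} draws: {last}"
    )


def _apply_thematic(cfg, raster, rng):
    last = None
    for _ in range(cfg.max_retries):
        k = int(rng.integers(cfg.class_bounds[0], cfg.class_bounds[1] + 1))
        try:
            return k, thematic_aggregate(raster, k)
        except ValueError as exc:  # fewer distinct values than classes
            last = exc
    raise EffdistError(f"no feasible class count in {cfg.max_retries} draws: {last}")


def _landscape_record(cfg, lid, dim, range_param, table):
    rec = {
        "landscape_id": lid,
        "dim": dim,
        "n_pixels": dim * dim,
        "range_param": range_param,
    }
    if {"least_cost", "resistance"} <= set(table.columns):
        rec["rho_lcd_resistance"] = spearman_rho(
            table["least_cost"], table["resistance"]
        )
    if {"commute", "resistance"} <= set(table.columns):
        rec["rho_ct_resistance"] = spearman_rho(table["commute"], table["resistance"])
    return rec


def _annotate(table, dim, range_param):
    table = table.copy()
    table["dim"] = dim
    table["n_pixels"] = dim * dim
    table["range_param"] = range_param
    return table


def _run(cfg: ExperimentConfig, variable_size: bool) -> ExperimentResult:
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_landscapes)
    land_rows, base_tables, treated_tables, failures = [], [], [], []
    seen: set[tuple[int, float]] = set()
    for lid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        try:
            if variable_size:
                for _ in range(100_000):
                    dim = int(rng.integers(cfg.dim_range[0], cfg.dim_range[1] + 1))
                    range_param = _draw_range(rng, cfg.range_bounds, dim)
                    if (dim, range_param) not in seen:
                        seen.add((dim, range_param))
                        break
            else:
                dim = cfg.dim
                range_param = _draw_range(rng, cfg.range_bounds, dim)
            raster, nodes = _one_landscape(cfg, dim, range_param, rng)
            base = _pairs(cfg, raster, nodes, lid)
            rec = _landscape_record(cfg, lid, dim, range_param, base)
            base_tables.append(_annotate(base, dim, range_param))

            if cfg.treatments and not variable_size:
                f, agg_s, coarse = _apply_spatial(cfg, raster, nodes, rng)
                t_spatial = _pairs(cfg, agg_s, coarse, lid)
                k, agg_t = _apply_thematic(cfg, raster, rng)
                t_them = _pairs(cfg, agg_t, nodes, lid)
                rec["spatial_factor"] = f
                rec["n_classes"] = k
                for name, tbl in (("spatial", t_spatial), ("thematic", t_them)):
                    if "rho_lcd_resistance" in rec:
                        treated_rho = spearman_rho(tbl["least_cost"], tbl["resistance"])
                        rec[f"rho_{name}"] = treated_rho
                        rec[f"delta_rho_{name}"] = delta_rho(
                            rec["rho_lcd_resistance"], treated_rho
                        )
                    for metric in ("least_cost", "resistance"):
                        if metric in tbl.columns:
                            rec[f"self_{metric}_{name}"] = method_self_correlation(
                                base, tbl, metric
                            )
                    tbl = _annotate(tbl, dim, range_param)
                    tbl["treatment"] = name
                    tbl["degree"] = f if name == "spatial" else 22 - k
                    treated_tables.append(tbl)
            land_rows.append(rec)
        except EffdistError as exc:
            failures.append(f"landscape {lid}: {exc}")
    if not land_rows:
        raise EffdistError(f"every landscape failed; first error: {failures[0]}")
    return ExperimentResult(
        landscapes=pd.DataFrame(land_rows),
        pairs=pd.concat(base_tables, ignore_index=True),
        treated_pairs=(
            pd.concat(treated_tables, ignore_index=True) if treated_tables else None
        ),
        config=cfg,
        failures=failures,
    )


def run_fixed_size(config: ExperimentConfig) -> ExperimentResult:
    """Run the fixed-dimension experiment (with aggregation treatments)."""
    return _run(config, variable_size=False)


def run_variable_size(config: ExperimentConfig) -> ExperimentResult:
    """Run the variable-dimension experiment (no treatments)."""
    cfg = replace(config, treatments=False)
    return _run(cfg, variable_size=True)


# ------------------------------------------------------------------ summary


def summarize(result: ExperimentResult) -> dict:
    """Pooled statistics of an experiment run, keyed by what they measure."""
    pairs = result.pairs
    land = result.landscapes
    out: dict[str, float] = {
        "n_landscapes": int(result.n_ok),
        "n_pairs": int(len(pairs)),
        "n_failures": len(result.failures),
    }
    if "rho_lcd_resistance" in land:
        out["mean_rho_lcd_resistance"] = float(land["rho_lcd_resistance"].mean())
        out["sd_rho_lcd_resistance"] = float(land["rho_lcd_resistance"].std())
    if "rho_ct_resistance" in land:
        out["mean_rho_ct_resistance"] = float(land["rho_ct_resistance"].mean())
    for metric, key in (("least_cost", "lcd"), ("resistance", "resistance")):
        if metric in pairs.columns:
            slopes, r2 = ols_fit(pairs[metric], pairs["euclidean"], "raw")
            out[f"euclid_slope_{key}"] = float(slopes[0])
            out[f"euclid_r2_pct_{key}"] = 100.0 * r2
    if land["dim"].nunique() > 1:  # variable-size statistics
        for metric, key in (("least_cost", "lcd"), ("resistance", "resistance")):
            if metric in pairs.columns:
                slopes, r2 = ols_fit(pairs[metric], pairs["n_pixels"], "log_both")
                out[f"pixel_loglog_slope_{key}"] = float(slopes[0])
                out[f"pixel_loglog_r2_pct_{key}"] = 100.0 * r2
                out[f"pixel_pct_per_doubling_{key}"] = pct_increase_per_doubling(
                    slopes[0]
                )
                slopes2, r2_2 = ols_fit(
                    pairs[metric],
                    np.column_stack([pairs["n_pixels"], pairs["euclidean"]]),
                    "log_both",
                )
                out[f"pixel_euclid_loglog_r2_pct_{key}"] = 100.0 * r2_2
    for name in ("spatial", "thematic"):
        col = f"delta_rho_{name}"
        if col in land.columns:
            out[f"mean_abs_delta_rho_{name}"] = float(land[col].abs().mean())
        for metric in ("least_cost", "resistance"):
            scol = f"self_{metric}_{name}"
            if scol in land.columns:
                out[f"mean_self_{metric}_{name}"] = float(land[scol].mean())
    if "range_param" in land.columns and "rho_lcd_resistance" in land.columns:
        if len(land) >= 3 and land["range_param"].nunique() > 2:
            out["rho_range_vs_agreement"] = spearman_rho(
                land["range_param"], land["rho_lcd_resistance"]
            )
    return out
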