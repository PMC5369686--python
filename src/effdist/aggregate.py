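"""Data-degradation treatments: spatial and thematic aggregation.

Spatial aggregation coarsens the raster by replacing each f x f block with
its arithmetic mean (trailing rows/columns that do not fill a block are
dropped), emulating a resolution reduction by factor f.  Thematic
aggregation discretizes cell values into k equal-frequency (quantile)
classes and replaces every cell by its class mean, emulating a categorical
land-cover costing with k levels.  The two treatments are applied
independently, never composed.  The "degree" of a treatment puts both on a
common axis: f for spatial, 22 - k for thematic (so 2 classes, the
patch-matrix extreme, is degree 20).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NodeCollisionError, NodePlacementError
from .landscape import COST_MAX, COST_MIN, CostRaster, FocalNodes

__all__ = [
    "AggregationSpec",
    "spatial_aggregate",
    "thematic_aggregate",
    "remap_nodes",
]


@dataclass(frozen=True)
class AggregationSpec:
    """One treatment: kind 'spatial' with block factor, or 'thematic' with n_classes."""

    kind: str
    factor: int | None = None
    n_classes: int | None = None

    def __post_init__(self):
        if self.kind == "spatial":
            if self.factor is None or not 1 <= self.factor <= 20:
                raise ValueError("spatial factor must be an integer in [1, 20]")
        elif self.kind == "thematic":
            if self.n_classes is None or not 2 <= self.n_classes <= 20:
                raise ValueError("n_classes must be an integer in [2, 20]")
        else:
            raise ValueError(f"unknown aggregation kind {self.kind!r}")

    @property
    def degree(self) -> int:
        """Common aggregation axis: f for spatial, 22 - k for thematic."""
        if self.kind == "spatial":
            return int(self.factor)
        return 22 - int(self.n_classes)


def spatial_aggregate(raster: CostRaster, f: int) -> CostRaster:
    """Coarsen by block-averaging f x f cells; output side is floor(dim/f).

    Block means are rounded half-to-even and clamped to the cost range; the
    output raster keeps the input's physical extent per pixel scaled by f
    (resolution multiplied by f).
    """
    if f < 1 or int(f) != f:
        raise ValueError("aggregation factor must be a positive integer")
    f = int(f)
    if f == 1:
        return raster
    new_dim = raster.dim // f
    if new_dim < 2:
        raise ValueError(
            f"factor {f} would leave a {new_dim}x{new_dim} raster (< 2x2)"
        )
    v = raster.values[: new_dim * f, : new_dim * f].astype(float)
    block = v.reshape(new_dim, f, new_dim, f).mean(axis=(1, 3))
    out = np.clip(np.rint(block), COST_MIN, COST_MAX).astype(np.int64)
    return CostRaster(out, resolution=raster.resolution * f)


def thematic_aggregate(raster: CostRaster, k: int) -> CostRaster:
    """Quantile-discretize cell values into k classes, valued at class means.

    Break points are the i/k quantiles of the cell-value distribution; each
    cell is replaced by the rounded arithmetic mean of the original values
    in its class.  The class map is monotone: a costlier cell never lands in
    a cheaper class.
    """
    if k < 2 or int(k) != k:
        raise ValueError("number of classes must be an integer >= 2")
    k = int(k)
    v = raster.values
    n_distinct = len(np.unique(v))
    if n_distinct < k:
        raise ValueError(
            f"raster has {n_distinct} distinct values, fewer than {k} classes"
        )
    flat = v.ravel().astype(float)
    breaks = np.quantile(flat, np.arange(1, k) / k)
    cls = np.searchsorted(breaks, flat, side="left")
    sums = np.bincount(cls, weights=flat, minlength=k)
    counts = np.bincount(cls, minlength=k)
    means = np.zeros(k)
    nonempty = counts > 0
    means[nonempty] = sums[nonempty] / counts[nonempty]
    out = np.rint(means[cls]).astype(np.int64).reshape(v.shape)
    out = np.clip(out, COST_MIN, COST_MAX)
    return CostRaster(out, resolution=raster.resolution)


def remap_nodes(nodes: FocalNodes, f: int, new_dim: int) -> FocalNodes:
    """Map focal nodes onto the f-aggregated raster by integer division.

    Raises :class:`NodeCollisionError` if two nodes fall in the same coarse
    cell, and :class:`NodePlacementError` if a node lies in a dropped
    partial block (coordinate >= new_dim after division).
    """
    if f < 1 or int(f) != f:
        raise ValueError("aggregation factor must be a positive integer")
    f = int(f)
    if f == 1:
        return nodes
    coarse = nodes.coords // f
    if coarse.max() >= new_dim:
        raise NodePlacementError(
            "a focal node lies in a trailing partial block dropped by "
            f"aggregation (coarse coord >= {new_dim})"
        )
    uniq = np.unique(coarse, axis=0)
    if len(uniq) != len(coarse):
        raise NodeCollisionError(
            f"focal nodes collide after aggregation by factor {f}"
        )
    return FocalNodes(coarse, buffer_frac=nodes.buffer_frac)
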