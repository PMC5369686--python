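"""Synthetic landscape generation.

Cost surfaces are realizations of a stationary, zero-mean Gaussian random
field with an exponential covariance

    C(h) = sill * exp(-h / range_param),

simulated on the pixel-centre lattice by exact circulant embedding (FFT),
then min-max rescaled to integer movement costs in [1, 1000].  ``range_param``
is the exponential *scale* parameter (the conventional "Exp" model
parameterization; the effective range, where correlation drops to ~5%, is
about three times larger).  Focal nodes are placed uniformly at random in
the raster interior, excluding a buffer of 10% of the dimension at each
edge to limit edge effects on circuit-based distances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.fft import fft2, next_fast_len

from .errors import CapacityError, ConstantFieldError, NodePlacementError

__all__ = [
    "VariogramSpec",
    "CostRaster",
    "FocalNodes",
    "simulate_grf",
    "rescale_to_cost",
    "place_nodes",
    "empirical_variogram",
]

COST_MIN = 1
COST_MAX = 1000

#: largest embedding grid side the FFT simulator will attempt
_MAX_EMBED = 8192


@dataclass(frozen=True)
class VariogramSpec:
    """Exponential variogram / covariance model of a stationary field.

    Semivariance: gamma(h) = nugget + sill * (1 - exp(-h / range_param)).
    """

    sill: float = 0.025
    range_param: float = 1.0
    nugget: float = 0.0
    model: str = "exponential"

    def __post_init__(self):
        if self.model != "exponential":
            raise ValueError(f"unsupported variogram model {self.model!r}")
        if not self.sill > 0:
            raise ValueError("sill must be positive")
        if not self.range_param >= 1:
            raise ValueError("range_param must be >= 1 map unit")
        if self.nugget < 0:
            raise ValueError("nugget must be non-negative")

    def covariance(self, h):
        """Covariance C(h) at lag distance h (map units)."""
        h = np.asarray(h, dtype=float)
        c = self.sill * np.exp(-h / self.range_param)
        return np.where(h == 0, c + self.nugget, c)

    def semivariance(self, h):
        """Model semivariance gamma(h)."""
        h = np.asarray(h, dtype=float)
        g = self.sill * (1.0 - np.exp(-h / self.range_param))
        return np.where(h == 0, 0.0, g + self.nugget)


@dataclass(frozen=True)
class CostRaster:
    """Square integer grid of movement costs in [1, 1000].

    ``resolution`` is the edge length of a pixel in map units.
    """

    values: np.ndarray
    resolution: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"cost raster must be square 2-D, got shape {v.shape}")
        if not np.issubdtype(v.dtype, np.integer):
            raise ValueError("cost raster values must be integers")
        if v.min() < COST_MIN or v.max() > COST_MAX:
            n_bad = int(((v < COST_MIN) | (v > COST_MAX)).sum())
            raise ValueError(
                f"{n_bad} cell(s) outside the cost range [{COST_MIN}, {COST_MAX}]"
            )
        object.__setattr__(self, "values", v)

    @property
    def dim(self) -> int:
        return self.values.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class FocalNodes:
    """Panel of focal-node pixel coordinates, 0-based (row, col) from top-left."""

    coords: np.ndarray  # (n, 2) int
    buffer_frac: float = 0.10

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=np.int64)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("coords must be an (n, 2) array of (row, col)")
        if c.shape[0] < 2:
            raise ValueError("need at least 2 focal nodes")
        if len(np.unique(c, axis=0)) != len(c):
            raise ValueError("focal nodes must be distinct")
        object.__setattr__(self, "coords", c)

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    def ids(self, dim: int) -> np.ndarray:
        """Row-major node ids on a dim x dim lattice."""
        return self.coords[:, 0] * dim + self.coords[:, 1]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_grf(
    spec: VariogramSpec, dim: int, seed, *, pad: float = 2.0
) -> np.ndarray:
    """Simulate a dim x dim Gaussian random field with covariance ``spec``.

    Uses circulant embedding: the covariance is laid out on a torus of side
    N >= pad*dim, diagonalized by the 2-D FFT, and the field is synthesized
    from complex white noise.  Negative embedding eigenvalues (which occur
    for the exponential model when the range approaches the domain size) are
    clipped to zero and the spectrum renormalized to preserve the total
    variance; the clipped mass is at most ~2% for range <= dim at pad=2.

    Deterministic for a fixed integer seed.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    N = next_fast_len(max(int(np.ceil(dim * pad)), dim + 1))
    if N > _MAX_EMBED:
        raise CapacityError(
            f"embedding grid {N}x{N} exceeds the FFT simulator capacity "
            f"({_MAX_EMBED}); reduce dim or pad"
        )
    # torus (wrap-around) lag distances on the embedding grid
    ax = np.minimum(np.arange(N), N - np.arange(N)).astype(float)
    h = np.hypot(ax[:, None], ax[None, :])
    cov = spec.covariance(h)
    lam = fft2(cov).real
    total = lam.sum()
    lam = np.clip(lam, 0.0, None)
    lam *= total / lam.sum()  # preserve C(0) = sill exactly
    rng = _as_rng(seed)
    z = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
    field = (fft2(z * np.sqrt(lam)) / N).real
    return np.ascontiguousarray(field[:dim, :dim])


def rescale_to_cost(field: np.ndarray, resolution: float = 1.0) -> CostRaster:
    """Affine min-max rescale of a real field onto integer costs [1, 1000].

    The minimum cell maps to 1 and the maximum to 1000; intermediate values
    are rounded half-to-even (numpy's rint), so rank order is preserved up
    to rounding ties.  A constant field has no defined scaling and raises.
    """
    f = np.asarray(field, dtype=float)
    lo, hi = f.min(), f.max()
    if hi == lo:
        raise ConstantFieldError("cannot rescale a constant field to costs")
    scaled = COST_MIN + (f - lo) * (COST_MAX - COST_MIN) / (hi - lo)
    return CostRaster(np.rint(scaled).astype(np.int64), resolution=resolution)


def interior_bounds(dim: int, buffer_frac: float) -> tuple[int, int]:
    """Inclusive (low, high) index bounds of the interior after the edge buffer."""
    b = int(np.floor(buffer_frac * dim))
    return b, dim - 1 - b


def place_nodes(
    raster: CostRaster, n: int = 15, buffer_frac: float = 0.10, seed=None
) -> FocalNodes:
    """Sample n distinct focal pixels uniformly from the buffered interior."""
    dim = raster.dim
    lo, hi = interior_bounds(dim, buffer_frac)
    side = hi - lo + 1
    if side < 1 or side * side < n:
        raise NodePlacementError(
            f"interior after a {buffer_frac:.0%} buffer is {max(side, 0)}x"
            f"{max(side, 0)} pixels; cannot place {n} distinct nodes"
        )
    rng = _as_rng(seed)
    flat = rng.choice(side * side, size=n, replace=False)
    coords = np.column_stack((lo + flat // side, lo + flat % side))
    return FocalNodes(coords, buffer_frac=buffer_frac)


def empirical_variogram(
    field: np.ndarray,
    max_lag: float,
    *,
    n_bins: int = 20,
    n_samples: int = 3000,
    seed=0,
) -> pd.DataFrame:
    """Isotropic method-of-moments semivariogram of a 2-D field.

    Randomly subsamples up to ``n_samples`` cells, forms all pairs, and bins
    half the mean squared difference by lag distance.  Returns a DataFrame
    with columns (lag, semivariance, n_pairs); ``lag`` is the bin midpoint.
    """
    f = np.asarray(field, dtype=float)
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    if f.max() == f.min():
        raise ConstantFieldError("variogram of a constant field is undefined")
    rng = _as_rng(seed)
    n_cells = f.size
    take = min(n_samples, n_cells)
    flat = rng.choice(n_cells, size=take, replace=False)
    rows, cols = np.divmod(flat, f.shape[1])
    z = f[rows, cols]
    dr = rows[:, None] - rows[None, :]
    dc = cols[:, None] - cols[None, :]
    iu = np.triu_indices(take, k=1)
    d = np.hypot(dr[iu], dc[iu])
    sq = 0.5 * (z[:, None] - z[None, :])[iu] ** 2
    keep = d <= max_lag
    d, sq = d[keep], sq[keep]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sq, minlength=n_bins)
    ok = counts > 0
    mid = 0.5 * (edges[:-1] + edges[1:])
    return pd.DataFrame(
        {
            "lag": mid[ok],
            "semivariance": sums[ok] / counts[ok],
            "n_pairs": counts[ok],
        }
    )
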