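# effdist

Least-cost distance and circuit-theory resistance distance are the two
standard "effective distances" used to model animal movement and gene flow
across cost surfaces. They formalize different movement assumptions — a
single optimal path versus a random walk over all paths — and they are
**not** interchangeable: their relationship is curvilinear, their agreement
degrades as a landscape is represented by more pixels, and data aggregation
(coarsening resolution, or discretizing costs into land-cover-like classes)
degrades it further, hitting resistance distance hardest.

`effdist` is a simulation pipeline for studying these effects from first
principles. It generates spatially autocorrelated cost landscapes, computes
pairwise effective distances between random focal nodes, applies spatial
and thematic aggregation treatments, and reproduces the comparative
statistics: rank correlations between metrics, regressions on Euclidean
distance and pixel count, and aggregation-induced correlation changes. It
is aimed at landscape geneticists and connectivity modellers who want a
fast, fully scriptable test bench rather than a GIS workflow.

## The quantities

On an 8-neighbour pixel graph with edge resistances r_ij = (c_i + c_j)/2
(average of the two cell costs):

- **least-cost distance** LCD(a,b) = min over paths of Σ r_ij — the
  accumulated cost of the cheapest path (Dijkstra), *not* its geometric
  length;
- **resistance distance** R(a,b) = (e_a − e_b)ᵀ L⁺ (e_a − e_b), the
  effective resistance of the whole network, with L the Laplacian built
  from conductances g_ij = 1/r_ij; computed by one sparse linear solve per
  focal node, never by forming L⁺;
- **commute time** CT(a,b) = vol(G) · R(a,b), the expected round-trip steps
  of a random walk; proportional to R within a landscape;
- **redundancy** = LCD/R ≥ 1, a coarse count of independent pathways (1 on
  a chain; k for k identical disjoint paths).

Landscapes are Gaussian random fields with exponential covariance
C(h) = 0.025·exp(−h/range), simulated by exact circulant embedding (FFT)
and min–max rescaled to integer costs in [1, 1000]; 15 focal nodes are
placed uniformly inside a 10%-of-dimension edge buffer.

## Worked example

```python
import effdist as ed

spec = ed.VariogramSpec(sill=0.025, range_param=120)
field = ed.simulate_grf(spec, 256, seed=7)
raster = ed.rescale_to_cost(field)
nodes = ed.place_nodes(raster, n=15, seed=7)
table = ed.compute_pair_table(raster, nodes)

rho = ed.spearman_rho(table.least_cost, table.resistance)
print(f"rho(LCD, R) = {rho:.3f}")
print(f"rho(CT, R)  = {ed.spearman_rho(table.commute, table.resistance):.3f}")
print(f"median redundancy = {table.redundancy.median():.1f}")

agg = ed.spatial_aggregate(raster, 8)
coarse = ed.remap_nodes(nodes, 8, agg.dim)
treated = ed.compute_pair_table(agg, coarse)
rho_t = ed.spearman_rho(treated.least_cost, treated.resistance)
print(f"rho after 8x spatial aggregation = {rho_t:.3f}")
```

prints

```
rho(LCD, R) = 0.699
rho(CT, R)  = 1.000
median redundancy = 109.3
rho after 8x spatial aggregation = 0.884
```

On this strongly autocorrelated 256×256 landscape the two metrics agree
only moderately in rank (ρ = 0.70), commute time ranks identically to
resistance distance (it is a scalar multiple of it within a landscape), and
the median pair has ~109 "independent pathways" worth of redundancy.
Coarsening the raster 8-fold collapses many alternative pathways, and here
the two metrics agree *more* afterwards (ρ = 0.88) — a single treated
landscape can move either way, which is why the aggregation effect is
reported as a mean |Δρ| over many landscapes.

There is also a CLI for shell pipelines — `effdist simulate`,
`effdist distances`, `effdist aggregate`, `effdist experiment`,
`effdist stats` — writing ESRI ASCII/TIFF rasters, CSV pair tables, and a
JSON manifest for every run (see `effdist --help`).

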