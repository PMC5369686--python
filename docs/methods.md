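# Methods

## The question

Landscape ecologists and landscape geneticists model movement or gene flow
across a cost surface with two families of effective distance: least-cost
distance (the accumulated cost of the single cheapest path, computed with
Dijkstra's algorithm) and circuit-theoretic resistance distance (the
effective electrical resistance of the whole lattice, equivalently the
scaled commute time of a random walk). `effdist` implements both from first
principles on simulated landscapes and measures how strongly they agree, how
each responds to Euclidean separation and to the number of pixels
representing a landscape, and how raster aggregation degrades their
agreement.

## Landscape model

Cost surfaces are realizations of a stationary zero-mean Gaussian random
field with exponential covariance C(h) = s·exp(−h/r), sill s = 0.025 and
scale parameter r drawn uniformly from [1, 1000] map units (resampled until
r ≤ dim). `range_param` is the exponential *scale*; the effective range —
the lag at which correlation has decayed to ~5% — is about 3r. This is the
conventional "Exp" model parameterization of geostatistics packages. The
field is min–max rescaled to integer movement costs in [1, 1000]
(round-half-to-even, fixed for cross-platform determinism), which makes the
cost raster invariant to the sill; only the correlation shape matters.

Simulation is by exact circulant embedding: the covariance is laid on a
torus of side ≥ 2·dim, diagonalized with a 2-D FFT, and the field
synthesized from complex white noise. For ranges approaching the domain
size the embedding develops a small negative eigenvalue mass (≤ ~2% at
r = dim = 1000); it is clipped to zero and the spectrum renormalized so the
variance is preserved exactly. The distortion of the correlation shape is
far below the variogram-recovery tolerance we test (25%).

Fifteen focal nodes are placed uniformly at random, excluding a buffer of
10% of the dimension at each edge (edge effects bias circuit distances).
No minimum separation is enforced; sampling without replacement guarantees
distinctness.

## Graph construction

Each pixel is a node of an 8-neighbour lattice. An edge between adjacent
pixels i, j carries resistance r_ij = (c_i + c_j)/2 (average resistance, the
default; average conductance g_ij = (1/c_i + 1/c_j)/2 is retained as an
option). The same edge resistances feed both engines: least-cost distance
minimizes the summed r_ij along a path, and the circuit engine uses
conductances g_ij = 1/r_ij.

Diagonal edges are **not** scaled by √2 by default. The raster connectivity
of the standard circuit and cost-distance toolchains connects diagonal
neighbours with plain averaged resistances, and the replication targets
decide the question empirically: with the √2 geometric correction the
pooled least-cost-vs-Euclidean slope comes out near 435 and r² near 81%,
both far above the reference values (345, 71%); without it they land at
~340 and ~72%. The correction is available as `diagonal_correction=True`
for workflows that want geometrically consistent accumulated costs.

## Distance engines

*Least-cost*: `scipy.sparse.csgraph.dijkstra` from the 15 focal nodes
(15 single-source runs per landscape, 10⁶-node graphs in ~0.4 s/source).

*Resistance*: R(a,b) = (e_a − e_b)ᵀ L⁺ (e_a − e_b) with L the conductance
Laplacian. One focal node is grounded (row/column deleted — equivalent to
deflating the constant nullspace) and L_g v_a = e_a is solved for each of
the other 14 nodes; all 105 pairwise resistances follow from
R(a,b) = v_a[a] − v_a[b] − v_b[a] + v_b[b]. Up to 4×10⁵ nodes the grounded
system is factorized once with sparse LU (SuperLU) and solved for all
right-hand sides; larger grids fall back to conjugate gradient with an
incomplete-LU preconditioner. Every solve path verifies the relative
residual against `tol` (default 1e−8, orders of magnitude below the
statistical noise of any reported quantity) and raises with the achieved
residual on failure.

*Commute time*: CT = vol(G)·R with vol(G) the total weighted degree; it is
computed from the resistance matrix, so its per-landscape rank correlation
with R is exactly 1 — the quantity reported per landscape. (Pooling pairs
across landscapes breaks the proportionality because vol(G) differs per
landscape; the pairs archive supports that analysis but it is not a
headline statistic.)

*Redundancy*: LCD/R ≥ 1, a coarse count of independent pathways (1 on a
chain, k for k identical node-disjoint paths — both reproduced exactly in
tests). The linearized variants √LCD/R and LCD/R² are provided. The
curvilinearity of LCD against R — and its straightening under a square
root of LCD — is a property of the pair cloud *pooled across landscapes*,
where between-landscape differences in redundancy drive the curvature;
within a single landscape the curvature is weak relative to the noise of
105 pairs, and the transform does not systematically raise the
per-landscape correlation.

## Aggregation treatments

Spatial: f×f block arithmetic mean (f ∈ [2, 20]), rounded half-to-even,
trailing partial blocks dropped; focal nodes remap by integer division, and
a factor that makes two nodes collide is redrawn (bounded retries) so the
15-node panel is identical across treatments. Thematic: k equal-frequency
(quantile) classes (k ∈ [2, 20]), each cell replaced by its class mean —
the class mean (rather than midpoint or index) keeps the cost scale
comparable before/after so distances remain on one scale. The two
treatments are always applied independently, never composed. The common
"degree" axis is f for spatial and 22 − k for thematic.

## Statistics

Per landscape: Spearman ρ (average ranks on ties) between LCD and R, and
between CT and R; Δρ = ρ_baseline − ρ_treated per treatment; before/after
self-correlation of each metric under each treatment. Pooled across
landscapes: OLS of LCD and R on Euclidean distance (raw scale), and of
log distance on log pixel count (and log Euclidean distance) for the
variable-size design. A log-log slope b is reported as a percent increase
per doubling, 100·(2^b − 1). OLS goes through statsmodels; Spearman through
scipy — both are cross-checked against closed-form oracles in the test
suite.

## Problem sizes

The full study design (1,000 landscapes of 10⁶ pixels) is hours-scale on
one CPU. The package's replication scripts use reduced batch sizes chosen
so that each statistic's sampling error is well inside its comparison
band: 50 landscapes at 316² (~100k pixels) for the rank-agreement level,
30 landscapes at 1000² for the pooled Euclidean regressions (the
per-landscape ρ has σ ≈ 0.1, so means over n landscapes carry standard
errors of ≈ 0.1/√n), and 60 variable-size landscapes for the pixel-count
regressions. The test suite uses further-reduced counts at the same
dimensions, plus qualitative batches at 256².

## What the generator does and does not emulate

The generator reproduces the study conditions: stationary isotropic
exponential autocorrelation, uniform range, full-range integer cost
rescaling, uniform node placement with an edge buffer. Real cost surfaces
are not stationary or isotropic, have landcover-like categorical structure,
barriers and NoData holes, and focal sites are not uniform in space.
Passing tests therefore validate the *relationships between the metrics
under controlled heterogeneity*, not any claim about a particular real
landscape. Reference values for this kind of analysis are commonly
produced with sequential Gaussian simulation from a geostatistics package;
circulant embedding realizes the same covariance model exactly, but the
small numerical artifacts of sequential simulation on 10⁶-pixel grids
(finite search neighbourhoods add unstructured noise) are deliberately not
reproduced, which can shift size-scaling statistics by a few points.

## Numerical choices and degenerate inputs

- Rounding is half-to-even everywhere a real value becomes an integer cost.
- Constant fields cannot be rescaled or variogram-estimated (explicit
  errors); rasters with fewer distinct values than classes reject thematic
  aggregation.
- A disconnected focal pair (impossible with positive finite costs) raises
  rather than returning infinity.
- Landscape-level failures inside an experiment batch (e.g., no
  collision-free aggregation factor after 5 draws) abort that landscape,
  are logged in the result, and do not abort the batch.
- All randomness flows from one master seed through
  `numpy.random.SeedSequence.spawn`, so every batch is bit-reproducible and
  landscapes are independent of each other's retry behaviour.

## Known limitations

- No NoData/barrier masking, anisotropy, or conditional simulation.
- TIFF output is a plain single-band uint16 image without CRS or
  geotransform tags; the ESRI ASCII grid writer covers interchange with GIS
  tools for the unit-resolution rasters used here.
- The CG fallback above 4×10⁵ nodes is substantially slower than the
  direct factorization and is exercised only by reduced-size tests.
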