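# Methods

## The analysis grid

All layers live on one rectified grid: a regular, axis-aligned raster in a
projected CRS with square cells of edge `resolution` meters.  The grid shape
is `ceil(extent / resolution)` rows × columns; the origin is the top-left
corner, cells are row-major and pixel-is-area with half-open intervals
`[x, x + res)`.  Geographic (degree-unit) CRSs are rejected outright — the
models are metric (propagation distances, cell areas) and there is
deliberately no reprojection engine; inputs must arrive in the analysis CRS.
The CRS is otherwise treated as an opaque identifier: a small table of
well-known geographic EPSG codes is the only geodetic knowledge in the
package.

Nodata is NaN in memory and `-9999` in written GeoTIFFs.  Nodata is treated
as zero inside convolutions and sums and excluded from maxima and
statistics.  Rasters are written as float64 GeoTIFFs (ModelPixelScale /
ModelTiepoint / GeoKeyDirectory / GDAL_NODATA tags) so model outputs reload
bit-exactly.

### Rasterization

Polygons cover a cell when the **cell center** falls inside them — a
deterministic, resolution-consistent rule with no partial-coverage
weighting.  Lines and points burn every cell whose box they intersect.
Presence mode yields binary layers; burn-value mode sums each feature's
attribute into the cells it covers (additive on overlapping features).
Vector input is GeoJSON; a declared CRS that differs from the grid's is an
error rather than a silent reinterpretation.

### Gaussian propagation

`gaussian_convolve(layer, d)` interprets `d` as the *effective propagation
radius*: σ = d/3, so ≈99.7% of the kernel mass falls within the stated
distance.  The kernel is truncated at 4σ and renormalized to unit sum
(scipy's separable Gaussian filter does exactly this), which makes total
mass conserved to better than 1e-6 relative for sources ≥4σ from every
boundary; mass crossing the extent boundary is lost by construction
(`mode="constant"`).  `d = 0` is the identity.  Tiny negative values from
floating-point cancellation are clipped to zero.

### Other operators

- `normalize`: divide by the maximum non-nodata value.  An all-zero layer
  is returned unchanged rather than erroring — zero layers legitimately
  arise from empty use subsets — and the operator is idempotent.
- `log_scale`: cellwise `log1p`, requiring non-negative input.
- `reclassify`: left-closed, right-open intervals `[bᵢ, bᵢ₊₁)`; values
  below the first break take the first class.
- `apply_mask`: cells outside the mask become nodata.
- "Aggregation" is exposed only as the cellwise `sum/mean/min/max`
  functions of the expression language over aligned layers.

## The expression language

Pre-processing expressions are the auditable record of how each raw dataset
became a model input.  The grammar is deliberately minimal: identifiers,
numeric literals, `+ - * /`, comparisons (yielding 0/1 mask layers so they
compose with arithmetic), parentheses, and a closed function whitelist
(`norm`, `log1p`, `gaussian`, `rescale`, `where`, `min`, `max`, `sum`,
`mean`).  Evaluation is a tree-walking interpreter; the raw string is never
handed to the host language, so nothing outside the whitelist is
expressible.

One grammar decision worth knowing: layer codes may contain hyphens
(`mpa-zones`), and identifiers lex with maximal munch, so `a-b` is **one
identifier** — subtraction requires surrounding whitespace (`a - b`).
Division by zero and comparisons against nodata both yield nodata rather
than propagating infinities or silently treating missing data as false.

## MUC: rule-set reconstruction

The pairwise scoring uses a vertical-overlap gate times three additive
components (mobility, spatial domain, temporal domain), each scoring 2 when
both uses take the high-conflict value (fixed / large / year-round), 1 when
mixed, 0 when both take the low value.  This preserves the documented 0–6
range, symmetry, and the qualitative COEXIST logic — persistent, extensive,
immobile co-located uses conflict most.  It is a *reconstruction*, not the
published COEXIST calibration tables, and `RuleSet` is a plain
configuration object (JSON-loadable via `inputs/ruleset.json`) precisely so
published tables can be substituted verbatim.

Presence is strict: a use occupies a cell iff its intensity is > 0 (or a
caller-chosen threshold); nodata counts as absent.  Self-pairs are
excluded and multiple features of one use in a cell count once.  Cells
outside the area of analysis are nodata in the score map, and the
pair-contribution table counts in-area cells only, so its totals match the
map total exactly.

## CEA: scale conventions

Pressure fields are normalized to [0, 1] after the weighted sum of
propagated use layers.  This keeps sensitivities the only scale carrier,
consistent with weights being *relative*; it can be disabled
(`rescale_pressures=False`) for absolute-intensity studies.  Convolution
and weighting are linear and commute; the implementation convolves first,
then weights.  Environmental layers are normalized once at load time;
`cea_map` asserts the [0, 1] range rather than silently rescaling, so a
mis-scaled receptor fails loudly.  "Effects" and "impacts" are treated as a
single quantity — no separate impact transformation is applied.  An
optional log-scaling of pressures, where a study calls for it, is expressed
through the pre-processing expression of a directly supplied pressure layer
rather than hard-coded in the model.

Because of pressure renormalization, removing a *use* can raise the
normalized pressure field elsewhere; cellwise monotonicity under subsetting
is therefore guaranteed only for selections that remove whole terms of the
sum — receptors, pressures or sensitivity entries — and that is what the
subsetting tests check.

## Case-study bundles

A directory with `casestudy.json` (metadata, grid definition, per-layer
entries `{name, role, file?, expression?}`), a `layers/` directory (GeoTIFF
rasters and/or GeoJSON vectors) and `inputs/` CSV tables.  Layers may
arrive pre-gridded or as vectors plus an expression; both paths converge to
aligned grid layers at load time.  Loading is two-stage (layers, then
inputs), sorts every registry by name so manifest order is irrelevant, and
ends with full validation.  Weights outside [0, 1] are warnings (data
smells); negative distances or sensitivities and dangling identifiers are
errors.

`save_case_study` writes evaluated layers as rasters, so `load(save(cs))`
reproduces every layer bit-exactly for any case study that came through the
loader (env normalization is idempotent: a normalized layer re-normalizes
to itself).  A non-trivial area-of-analysis mask is persisted as a binary
raster alongside the layers.

## Synthetic generator

`SyntheticSpec` defaults describe a 10 km × 10 km area at 500 m resolution
(20 × 20 cells — the resolution used by regional case-study setups), three
uses, two receptors, two pressures, and 15% footprint density per use.  Use
footprints are unions of random disks (radius 3 cells) and equal-area
rectangles; the shape count k solves the independent-placement coverage
equation 1 − (1 − a)^k = density, so realized density is honored in
expectation (boundary clipping biases it slightly low, well within the
±20% the tests allow).  Receptor fields are Gaussian-smoothed white noise
rescaled to [0, 1].  Links are reference-closed (every pressure has at
least one source use) with weights in [0.2, 1] and distances in
{0, 1, 2, 5} km; sensitivities are uniform in [0, 3].  One
`numpy.random.default_rng(seed)` stream drives everything; the same spec
and seed write byte-identical bundles.

The generator targets *structural* validity, not Adriatic realism: real use
footprints are spatially autocorrelated along coasts and corridors, real
sensitivity tables are expert-elicited and sparse, and real receptor fields
have habitat structure.  Passing tests therefore demonstrate correctness of
the machinery, not calibration of any real sea area.

The shipped demo (`examples/demo_case/`) exercises the *other* input path:
hand-written GeoJSON footprints with pre-processing expressions, plain-text
throughout.

## Numerical choices

- Percentiles: linear interpolation between order statistics (numpy's
  `method="linear"`), fixed so report numbers are deterministic.
- Histograms: edges span [min, max] exactly; a constant layer produces a
  single bin `[c, c]` holding every cell.
- Grid shape uses a tolerance of 1e-9 cells in the ceiling so an extent
  reconstructed as `n · res` from a written raster yields exactly n.
- Reports never embed timestamps in data files (only in `run.json`).

## Problem sizes

Tests and the acceptance script run on grids between 3 × 3 and 30 × 30
cells with up to five uses, three pressures and two receptors — sizes at
which brute-force per-cell oracles are exact and fast while exercising
every code path.  The operators are vectorized numpy/scipy throughout and
scale to case-study grids of millions of cells.

## Known limitations

- No reprojection: all inputs must share the analysis CRS.
- Vector input is GeoJSON only; rasters are single-band GeoTIFF.
- Cell-center coverage ignores partial overlap of footprints with cells;
  at coarse resolutions thin features (cables, corridors) should be
  supplied as lines, which burn by intersection instead.
- The linear sensitivity model has no receptor response saturation or
  interaction between pressures; pressure extents beyond ~4σ are truncated.
- The default rule set is a documented reconstruction of the COEXIST
  logic, not its published calibration.
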