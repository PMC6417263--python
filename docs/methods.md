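# Methods

## The model

`fuzzyhab` computes a habitat-suitability ("occurrence probability") map
for a container-breeding invasive mosquito by combining three gridded
inputs through an explicit linguistic fuzzy system:

* **landscape suitability** in [0, 1] — expert scores per land-use class,
  focal-mean smoothed;
* **mean wind speed** in m/s — a flight-limiting factor;
* **climate suitability** in [0, 1] — the score of a niche classifier
  trained to separate the target species' climate niche from that of
  native reference species.

Each input is fuzzified over a piecewise-linear Ruspini partition (term
memberships sum to 1 at every domain point; at most two adjacent terms
are active).  The partitions are parametrised by one *node* per term:
membership is 1 at the term's node, falls linearly to 0 at the
neighbouring nodes, and the first/last terms extend flat to the domain
edges.  This construction guarantees the partition property by design.

All 4 × 3 × 4 = 48 rules `(landscape term, wind term, climate term) →
output label` fire on every evaluation.  Rule strength is the t-norm of
the three antecedent degrees; each of the nine ordered output labels
(`bbbb` … `m` … `gggg`) is a crisp singleton on [0, 1] (default: evenly
spaced 0, 0.125, …, 1).  The output is the strength-weighted average of
the singletons (zero-order Takagi–Sugeno defuzzification).  It is
continuous, bounded in [0, 1], and equals a singleton exactly whenever
all three inputs sit in term cores.

### Choice of t-norm

The default t-norm is the **product**.  With Ruspini partitions the
per-variable memberships sum to 1, so the 48 product strengths sum to
exactly 1 and the output is the multilinear interpolation of the rule
table's singletons over the term grid.  Because the shipped rule table
is monotone along each input's term order (conclusions never worsen
with better landscape or climate, never improve with stronger wind),
multilinear interpolation is provably monotone in each input — a
property we verify exhaustively on a 50×50×50 input grid.  The minimum
t-norm is available as an option (`tnorm="min"`); it produces the same
48 core outputs and the same wind cap, but weighted-average
defuzzification under `min` is *not* monotonicity-preserving in general
and measurably violates monotonicity between cores, which is why it is
not the default.

### Membership calibration

The published description fixes the wind behaviour at two anchors: the
species was never recorded where mean wind exceeds 4.7 m/s, suitability
is "significantly reduced" around 3.7 m/s, and at 4.7 m/s the model caps
output at 25%.  The shipped wind partition encodes exactly that:
`comfortable` core up to 3.0 m/s, `high` peaking at 3.7 m/s, `too high`
reaching full membership at 4.7 m/s (domain [0, 12] m/s; values beyond
are clamped with edge memberships persisting).  The cap then follows
structurally: once `too high` has membership 1, every firing rule
concludes at most `bb` = 0.25, so the output cannot exceed 25% whatever
the other inputs — `scripts/acceptance.py` recomputes this maximum over
a dense 101×101 landscape × climate grid.

Landscape and climate partitions default to uniform nodes (0, 1/3, 2/3,
1), the neutral choice in the absence of published breakpoints.  All
nodes, singletons, rules and the t-norm live in one YAML document
(`fuzzyhab/data/japonicus_de.yaml`) and are user-overridable; the
shipped values are a documented reconstruction anchored to the printed
behavioural facts, not a recovered original.

## Landscape module

Land-use codes are reclassified through lookup tables; the shipped
tables carry the published expert scores (36 scored CORINE-style
classes; 5 finer override classes such as cemeteries and gardens at
suitability 1.0).  Classes judged not applicable are absent from the
table and become nodata.  Unknown codes raise by default (a permissive
flag maps them to nodata); they are never silently scored 0, which
would bias the landscape input downward.

A finer override layer overwrites the base layer where it has data
(idempotent, overwrite-biased).  Vector categories are gridded by area
fill: a cell is claimed from a 51% fill level onwards (coverage exactly
at the threshold counts); competing categories that both reach the
threshold require an explicit priority order.

The focal (sliding-window) mean uses an odd window edge; at raster
borders the window truncates to its in-bounds part, and nodata cells
are excluded from every mean (nodata is absence of information, not
zero suitability).  A cell that is itself nodata stays nodata.  The
implementation (uniform-filter numerator/denominator) is tested for
exact agreement with a brute-force double-loop oracle on 100+ seeded
instances including nodata and borders.

**Window-size selection.**  The original choice of a 700 m window was
made by inspecting how the histogram of smoothed suitability at
occurrence sites changes with window size: from bimodal (raw) to
unimodal and left-skewed (well-chosen) to bell-shaped (too large).
`select_window_size` formalises this: for each candidate edge length it
smooths, samples at the points, and reports a 10-bin histogram, sample
skewness, and a mode count.  Because raw bin-to-bin noise of a few
hundred points reads as spurious modes, the mode count smooths the
histogram with a 3-bin moving average and counts peaks with a 2%
prominence floor.  The recommendation — the smallest window with a
unimodal, negatively skewed point histogram — is reported, never
silently applied.

## Climate module

Feature scaling follows the original protocol exactly: the centred
feature is divided by its **variance**, `s(x) = (x − x̄)/σ²`, not by the
standard deviation.  The variance convention is the sample variance
(ddof = 1); this is fixed so the worked examples are deterministic.  A
conventional z-score mode exists behind `use_std=True`, default off.
The transform is affine and invertible per feature; constant columns
raise an error naming the column.

The niche classifier is an RBF support-vector machine (target species
= 1 vs native reference = 0) fitted on scaled training rows only.
Decision values are mapped to [0, 1] scores by a monotone logistic link
fitted on the training outputs (Platt scaling); monotonicity in the SVM
margin is the contract, the logistic link is the documented choice.
Validation is a seeded, stratified 90/10 holdout repeated R times
(default 40), reported as mean ± SD accuracy — the repeated-training
protocol of the original study.  The exact fold structure of the
original ("k-fold" with 10% reserved) is underdetermined in the source;
the seeded repeated holdout reproduces the reported protocol's shape
(R repeats, 10% held out, mean ± SD).

Scenario projection perturbs tagged feature rasters: additive offsets
for temperatures (default summer +1.4 K), multiplicative factors for
precipitation (default summer ×0.96, winter ×1.05), nodata preserved.

## Evaluation module

Presence-only records preclude AUC/ROC without fabricating
pseudo-absences, which is deliberately not done.  Two metrics are
computed:

* **exactness** — mean prediction at the presence points;
* **selectivity** — with threshold *t* = the type-1 (inverse empirical
  CDF, no interpolation) 10% quantile of the point predictions, the
  fraction of non-nodata study-area cells **strictly below** *t*.

Strictly-below makes a constant raster score 0 regardless of the
points; the quantile type and the strict inequality only matter at ties
and are frozen here because selectivity depends on them.  Selectivity
is rank-based and therefore invariant under any strictly monotone
transform applied to the raster (property-tested).

Point-in-cell lookup follows one convention used package-wide: the grid
origin is the upper-left corner, cell (i, j) covers the half-open
square [x0+jc, x0+(j+1)c) × (y0−(i+1)c, y0−ic], so a point on a shared
vertical edge belongs to the right cell and a point on a shared
horizontal edge to the cell above.

## Synthetic data

The generators emulate the statistical structure of the real inputs so
the whole pipeline is testable without licensed geodata:

* **Land use** — seed cells grown by nearest-seed (Voronoi) assignment
  plus one 3×3 majority pass.  Category area weights default to an
  unsuitable-dominated composition (cropland/conifer/pasture analogues
  ≈ 2/3 of the area) with many small suitable pockets, because that is
  the composition a temperate study area presents and it is what makes
  focal smoothing informative: with 400 patches on the default 200×200
  grid and the 700 m window, the smoothed-suitability histogram at
  presence sites becomes unimodal and left-skewed with essentially no
  mass at 1.0 — the qualitative signature the window-selection
  diagnostic looks for.
* **Wind** — base level (2.0 m/s) plus a quadratic cross-row gradient
  (up to +3.2 m/s, strongest at one map edge, emulating a windy coastal
  band over a limited area fraction) plus smooth noise (±0.8 m/s,
  Gaussian filter σ = 8 cells), clipped to [1.5, 6.0] m/s.  Most of the
  area stays flight-friendly while the windy band straddles both
  behavioural anchors (3.7, 4.7 m/s), so every wind rule fires
  somewhere.  A plain min–max mapping of smoothed noise was rejected:
  it concentrates nearly all cells mid-range, i.e. almost the whole
  map in the flight-restricted zone, which no temperate study area
  shows.
* **Climate** — Gaussian-filtered noise rank-transformed to a uniform
  marginal on [0, 1].  Filtered noise alone leaves almost no mass near
  0 or 1, whereas a niche score over a real region includes strongly
  suitable and strongly unsuitable subregions; equalisation preserves
  the spatial pattern while exercising all four climate terms.
* **Presences** — cells drawn with probability ∝ truth^β (β = 3 by
  default: strong but not deterministic concentration on suitable
  habitat), jittered uniformly within the cell, drawn with replacement.
  β = 0 is uniform background sampling.

The "truth" raster of the end-to-end scenario is the shipped fuzzy
model applied to the synthetic inputs — a deliberately self-consistent
fixture.  Passing end-to-end tests therefore demonstrate pipeline
correctness and metric behaviour (e.g. that the combined model's
exactness exceeds each single-input model's on presences drawn from the
combined truth), **not** ecological realism or transferability to real
occurrence data.  Features of real data the generators do not emulate:
sampling bias toward populated areas, spatial autocorrelation of
occurrence beyond habitat effects, class frequencies of any particular
land-cover product, and correlation between wind and land use.

All randomness flows through `numpy.random.default_rng` seeded from the
scenario seed plus a CRC32 stream tag, so identical scenarios reproduce
bit-for-bit across processes; no global random state is touched.

## Numerical choices and degenerate inputs

* Nodata: one sentinel per raster; any operation with a nodata operand
  yields nodata.  NaN cells count as nodata.
* Out-of-domain fuzzy inputs are clamped to the domain edge (edge-term
  membership persists); non-finite inputs raise.
* Mean resampling aggregates source-cell centers falling in each target
  cell; target cells receiving no center fall back to nearest-neighbour.
  Nearest resampling never invents values (output value set ⊆ input
  value set); constant fields are fixed points of both methods.
* The focal mean clips its output to the input data range to guard
  against floating-point drift at the 1e-16 level.
* A single projected metric CRS is assumed per run; there is no
  reprojection.  Problem sizes in the shipped tests (200×200 default
  scenario, 50³ monotonicity grid, 100+ small oracle instances) keep the
  full suite in the low seconds on one CPU.

## Known limitations

* The membership breakpoints and output singletons are reconstructions
  anchored to the printed behavioural facts; real-data predictions from
  the original study are not reproducible without the licensed inputs.
* `grid_polygons` is a straightforward per-cell intersection loop,
  adequate for override layers of moderate polygon counts, not a
  country-scale rasteriser.
* The GeoTIFF reader/writer handles single-band rasters with the three
  standard geo tags (pixel scale, tiepoint, nodata); it is not a general
  GeoTIFF implementation.
* Exactness rewards uniformly high predictions; it is only meaningful
  alongside selectivity, which penalises models that are high
  everywhere.
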