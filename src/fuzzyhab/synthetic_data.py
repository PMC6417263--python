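"""Seeded synthetic geodata emulating the statistical structure of the inputs.

Real runs of the model consume licensed national geodata (categorical
land-cover grids, a statistical wind-field grid, climate normals) and a
mosquito occurrence database, none of which can ship with the package.
These generators produce stand-ins with the features the pipeline
actually exercises:

* a patchy categorical land-use field (random category seeds grown by
  nearest-seed assignment plus one majority-smoothing pass) with a known
  ground-truth suitability lookup;
* smooth positive wind and climate fields (filtered noise mapped to a
  target range; the default wind range [1.5, 6.0] m/s straddles the
  behaviourally critical 3.7 and 4.7 m/s anchors so every wind rule
  fires somewhere);
* presence points sampled cell-wise with probability proportional to
  ``truth**beta`` and jittered within the cell -- ``beta`` controls how
  strongly collections concentrate on suitable habitat, ``beta = 0`` is
  uniform background sampling.

Everything is a pure function of (scenario, seed): identical inputs give
bit-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from fuzzyhab.raster_core import GridRaster, GridSpec
from fuzzyhab.landscape import SuitabilityLookup, sliding_window_mean, \
    suitability_from_landuse
from fuzzyhab.evaluation import PresencePoints
from fuzzyhab.fuzzy_engine import FuzzyModel, default_model

__all__ = [
    "SyntheticScenario",
    "generate_landuse",
    "generate_smooth_field",
    "sample_presences",
    "build_end_to_end_scenario",
]


@dataclass(frozen=True)
class SyntheticScenario:
    """Parameters of one synthetic study area.

    Defaults describe a 200 x 200 grid of 100 m cells with 8 land-use
    categories spanning the suitability scale, wind in [1.5, 6.0] m/s,
    climate suitability spanning [0, 1], and 500 presence points drawn
    with sharpness ``beta = 3`` (strong but not deterministic
    concentration on suitable cells, as citizen-science collections
    show).
    """

    seed: int = 42
    nrows: int = 200
    ncols: int = 200
    cell_size: float = 100.0
    origin: tuple[float, float] = (0.0, 20000.0)
    n_categories: int = 8
    category_suitabilities: tuple[float, ...] = (
        0.0, 0.1, 0.2, 0.3, 0.5, 0.8, 0.9, 1.0)
    #: relative area share per category; the default is dominated by
    #: unsuitable matrix (cropland/conifer/pasture analogues) with
    #: concentrated suitable pockets (settlement/broadleaf analogues),
    #: the composition any temperate study area presents
    category_weights: tuple[float, ...] = (
        0.30, 0.15, 0.18, 0.05, 0.04, 0.08, 0.10, 0.10)
    n_patches: int = 400
    wind_base: float = 2.0
    wind_gradient: float = 3.2
    wind_noise: float = 0.8
    wind_range: tuple[float, float] = (1.5, 6.0)
    wind_smoothness: float = 8.0
    climate_range: tuple[float, float] = (0.0, 1.0)
    climate_smoothness: float = 12.0
    n_presences: int = 500
    beta: float = 3.0
    window_px: int = 7

    def __post_init__(self) -> None:
        if self.n_categories < 2:
            raise ValueError("need at least 2 land-use categories")
        if len(self.category_suitabilities) != self.n_categories:
            raise ValueError("one suitability per category required")
        if len(self.category_weights) != self.n_categories:
            raise ValueError("one weight per category required")
        if any(w <= 0 for w in self.category_weights):
            raise ValueError("category weights must be positive")
        if self.n_patches > self.nrows * self.ncols:
            raise ValueError("more patches than grid cells")
        if self.wind_range[0] < 0 or self.wind_range[1] <= self.wind_range[0]:
            raise ValueError("invalid wind range")
        if not (0 <= self.climate_range[0] < self.climate_range[1] <= 1):
            raise ValueError("climate range must be within [0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")

    @property
    def grid(self) -> GridSpec:
        x0, y0 = self.origin
        return GridSpec(
            self.cell_size,
            (x0, y0 - self.nrows * self.cell_size,
             x0 + self.ncols * self.cell_size, y0),
        )


def _rng(scn: SyntheticScenario, stream: str) -> np.random.Generator:
    """Independent, reproducible substream per generator.

    Uses a process-independent stream hash (CRC32), so identical
    (scenario, seed) pairs give bit-identical output in any session.
    """
    return np.random.default_rng([scn.seed, zlib.crc32(stream.encode())])


def generate_landuse(scn: SyntheticScenario
                     ) -> tuple[GridRaster, SuitabilityLookup]:
    """Patchy categorical land-use raster plus its ground-truth lookup.

    ``n_patches`` seed cells are placed at random; patch categories are
    allotted in proportion to ``category_weights`` (largest-remainder
    apportionment with at least one patch per category, so every
    category occurs when ``n_patches >= n_categories``).  Each cell
    takes the category of its nearest seed (Voronoi growth) and one 3x3
    majority pass smooths ragged patch edges without inventing codes.
    """
    if scn.n_patches < scn.n_categories:
        raise ValueError("n_patches must be >= n_categories so every "
                         "category can occur")
    rng = _rng(scn, "landuse")
    nr, nc = scn.nrows, scn.ncols
    seeds = rng.choice(nr * nc, size=scn.n_patches, replace=False)
    seed_rc = np.column_stack(np.unravel_index(seeds, (nr, nc)))
    # largest-remainder apportionment of patches to categories
    weights = np.asarray(scn.category_weights, dtype=float)
    quota = weights / weights.sum() * scn.n_patches
    counts = np.maximum(1, np.floor(quota).astype(int))
    while counts.sum() > scn.n_patches:
        counts[np.argmax(counts)] -= 1
    rem = quota - np.floor(quota)
    while counts.sum() < scn.n_patches:
        k = int(np.argmax(rem))
        counts[k] += 1
        rem[k] = -1
    seed_cat = np.repeat(np.arange(scn.n_categories), counts)
    rng.shuffle(seed_cat)
    rows, cols = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    cells = np.column_stack([rows.ravel(), cols.ravel()])
    _, nearest = cKDTree(seed_rc).query(cells, k=1)
    codes = seed_cat[nearest].reshape(nr, nc)

    # one-hot majority filter; ties resolved toward the lower code for
    # determinism
    counts = np.stack([
        ndimage.uniform_filter((codes == k).astype(float), size=3,
                               mode="nearest")
        for k in range(scn.n_categories)
    ])
    codes = np.argmax(counts, axis=0)

    raster = GridRaster(codes.astype(float), scn.cell_size, scn.origin,
                        nodata=-9999.0, semantics="categorical")
    lut = SuitabilityLookup(
        {k: float(s) for k, s in enumerate(scn.category_suitabilities)},
        name="synthetic-truth",
    )
    return raster, lut


def _smoothed_unit_noise(scn: SyntheticScenario, stream: str,
                         sigma: float) -> np.ndarray:
    """Seeded filtered white noise rescaled to span exactly [0, 1]."""
    rng = _rng(scn, stream)
    noise = rng.standard_normal((scn.nrows, scn.ncols))
    if sigma > 0:
        noise = ndimage.gaussian_filter(noise, sigma=sigma, mode="nearest")
    span = noise.max() - noise.min()
    if span <= 0:
        return np.full_like(noise, 0.5)
    return (noise - noise.min()) / span


def generate_smooth_field(scn: SyntheticScenario, kind: str) -> GridRaster:
    """Smooth random field for ``kind`` in {"wind", "climate"}.

    The climate field is Gaussian-filtered white noise affinely mapped
    onto ``climate_range``; larger smoothness gives stronger spatial
    autocorrelation.

    The wind field emulates the geography of a temperate study area with
    a windy coastal band: ``base`` plus a quadratic cross-row gradient
    (strongest at the northern edge, so high winds stay a limited
    fraction of the area) plus smooth noise of amplitude ``wind_noise``,
    clipped to ``wind_range``.  Under the defaults most of the area is
    flight-friendly while the windy band comfortably straddles the 3.7
    and 4.7 m/s behavioural anchors, so every wind rule fires somewhere.
    With zero noise amplitude and zero gradient the field is constant at
    the base level.
    """
    if kind == "wind":
        if scn.wind_smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        rowfrac = np.linspace(0.0, 1.0, scn.nrows)[:, None]
        profile = scn.wind_base + scn.wind_gradient * (1.0 - rowfrac) ** 2
        unit = _smoothed_unit_noise(scn, "wind", scn.wind_smoothness)
        vals = profile + scn.wind_noise * (2.0 * unit - 1.0)
        vals = np.broadcast_to(vals, (scn.nrows, scn.ncols)).copy()
        lo, hi = scn.wind_range
        field_vals = np.clip(vals, lo, hi)
        semantics = "wind"
    elif kind == "climate":
        if scn.climate_smoothness < 0:
            raise ValueError("smoothness must be >= 0")
        lo, hi = scn.climate_range
        unit = _smoothed_unit_noise(scn, "climate", scn.climate_smoothness)
        # rank-transform to a uniform marginal: filtered Gaussian noise
        # alone leaves almost no mass near the extremes, whereas niche
        # scores over a real study area include strongly suitable and
        # strongly unsuitable regions; equalising spreads cells evenly
        # over the range while preserving the spatial pattern
        order = unit.ravel().argsort().argsort()
        uniform = (order + 0.5) / order.size
        field_vals = (lo + uniform * (hi - lo)).reshape(unit.shape)
        semantics = "suitability"
    else:
        raise ValueError(f"unknown field kind: {kind!r}")
    return GridRaster(field_vals, scn.cell_size, scn.origin,
                      nodata=-9999.0, semantics=semantics)


def sample_presences(truth: GridRaster, n: int, beta: float,
                     seed: int) -> PresencePoints:
    """Draw ``n`` presence points with cell probability ~ ``truth**beta``.

    ``beta = 0`` samples the background uniformly (over data cells);
    higher sharpness concentrates collections on suitable habitat.
    Points are jittered uniformly within their cell.  Cells are drawn
    with replacement, as several collections can fall in one cell.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    rng = np.random.default_rng(seed)
    mask = truth.nodata_mask()
    weights = np.where(mask, 0.0, truth.values.astype(float)) ** beta
    weights = np.where(mask, 0.0, weights)
    total = weights.sum()
    if total <= 0:
        raise ValueError("truth raster gives zero sampling mass "
                         "(all-zero suitability with beta > 0)")
    p = weights.ravel() / total
    chosen = rng.choice(weights.size, size=n, replace=True, p=p)
    rows, cols = np.unravel_index(chosen, truth.shape)
    x0, y0 = truth.origin
    c = truth.cell_size
    jx = rng.uniform(0.0, 1.0, size=n)
    jy = rng.uniform(0.0, 1.0, size=n)
    xs = x0 + (cols + jx) * c
    ys = y0 - (rows + jy) * c
    return PresencePoints(xs, ys)


def build_end_to_end_scenario(scn: SyntheticScenario | None = None,
                              model: FuzzyModel | None = None) -> dict:
    """Compose all generators into one self-consistent test scenario.

    The landscape input is the reclassified land-use field smoothed with
    the scenario's focal window; wind and climate are smooth fields; the
    "true" occurrence-probability raster is the shipped fuzzy model
    applied to those inputs, and presences are sampled from that truth.
    Returns a dict with every intermediate product.
    """
    scn = scn or SyntheticScenario()
    model = model or default_model()
    landuse, lut = generate_landuse(scn)
    land_suit = suitability_from_landuse(landuse, lut)
    land_smooth = sliding_window_mean(land_suit, scn.window_px)
    wind = generate_smooth_field(scn, "wind")
    climate = generate_smooth_field(scn, "climate")
    truth = model.apply(land_smooth, wind, climate)
    presences = sample_presences(
        truth, scn.n_presences, scn.beta,
        seed=int(_rng(scn, "presences").integers(0, 2**31 - 1)))
    return {
        "scenario": scn,
        "landuse": landuse,
        "lookup": lut,
        "landscape": land_smooth,
        "wind": wind,
        "climate": climate,
        "truth": truth,
        "presences": presences,
        "model": model,
    }
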