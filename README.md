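# fuzzyhab

Fuzzy rule-based habitat suitability modelling for invasive
container-breeding mosquitoes (developed around the Asian bush mosquito
*Aedes japonicus japonicus* in a temperate study area).

Climate-only species distribution models predict where an invasive
mosquito *could* persist, but at km-scale resolution they cannot guide
local surveillance or control.  `fuzzyhab` implements a nested approach
that combines, at 100 m resolution:

1. a **landscape suitability** raster — expert scores per land-use class
   (gardens and cemeteries ~1.0, broad-leaved forest 0.9, arable land
   0.0, …), focal-mean smoothed at the mosquito's flight-range scale;
2. a **mean wind speed** raster — wind suppresses host-seeking flight;
3. a **climate suitability** raster — the [0, 1] score of a
   support-vector niche classifier separating the target species'
   climate niche from that of native reference species, with the
   protocol-specific feature scaling s(x) = (x − x̄)/σ² (variance, not
   SD, in the denominator).

The combination is an explicit 48-rule linguistic fuzzy system.  Each
input is fuzzified over a piecewise-linear Ruspini partition
(landscape: *low / medium low / medium high / high*; wind: *comfortable
/ high / too high*; climate: *bad / medium bad / medium good / good*).
Every rule `(landscape, wind, climate) → label` concludes one of nine
ordered output singletons `bbbb … m … gggg` on [0, 1], and the
occurrence probability is the firing-strength-weighted average of the
singletons:

    P(x) = Σᵣ wᵣ(x) · sᵣ / Σᵣ wᵣ(x),   wᵣ(x) = μₗ(x₁) · μ_w(x₂) · μ_c(x₃)

The rules encode the ecological reasoning directly: very suitable land
use (gardens, cemeteries — irrigated containers) partially compensates
a dry climate, an unsuitable landscape is never rescued by good
climate, and once mean wind reaches 4.7 m/s — above which the species
has not been recorded — every rule concludes at most `bb`, capping
suitability at 25% regardless of the other inputs.

Presence-only evaluation ships with the package: **exactness** (mean
prediction at collection sites) and **selectivity** (fraction of the
study area below the 10%-lowest point-prediction threshold), plus the
histogram and cumulative-gain diagnostics used to shape memberships and
compare models.  A seeded synthetic-geodata module generates patchy
land use, wind and climate fields, and presence points, so the entire
pipeline is testable without any licensed geodata.

## Worked example

```python
from fuzzyhab import default_model
from fuzzyhab.fuzzy_engine import sensitivity_surface
from fuzzyhab.synthetic_data import SyntheticScenario, build_end_to_end_scenario
from fuzzyhab.evaluation import evaluate, exactness

model = default_model()

# one cell: good landscape (0.8), calm wind (2.5 m/s), good climate (0.9)
print(model.infer(0.8, 2.5, 0.9))        # 0.9775

# the wind cap: maximum output over all landscape x climate combinations
for w in (3.0, 3.7, 4.2, 4.7):
    print(w, sensitivity_surface(model, w, grid_n=101)["max"])
# 3.0 1.0      unrestricted flight: full suitability reachable
# 3.7 0.875    already significantly reduced
# 4.2 0.5625
# 4.7 0.25     the cap: at most 25% everywhere

# end-to-end on synthetic geodata (200x200 grid, 500 presences)
bundle = build_end_to_end_scenario(SyntheticScenario(seed=42))
report = evaluate(bundle["truth"], bundle["presences"])
print(report.exactness, report.selectivity)   # 0.736 0.658
print(exactness(bundle["landscape"], bundle["presences"]))  # 0.673
print(exactness(bundle["climate"], bundle["presences"]))    # 0.637
```

The last three numbers reproduce the study's qualitative headline on
synthetic data: the combined fuzzy model explains the presence points
better (exactness 0.736) than the landscape-only (0.673) or
climate-only (0.637) inputs on their own.

The same pipeline is available from the shell:

```bash
fuzzyhab synth make --seed 42 --size 200 --outdir scenario/
fuzzyhab fuzzy apply --landscape scenario/landscape.asc \
    --wind scenario/wind.asc --climate scenario/climate.asc \
    --out scenario/prediction.asc
fuzzyhab evaluate --prediction scenario/prediction.asc \
    --points scenario/presences.csv --report report.json
fuzzyhab fuzzy surface --wind 4.7 --n 101
```

The model definition (membership nodes, rules, singletons, t-norm)
lives in a single YAML document; the shipped
`fuzzyhab/data/japonicus_de.yaml` encodes the published rule table and
the wind anchors, and any part of it can be overridden.  See
`docs/methods.md` for the model's assumptions, calibration and
limitations.

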