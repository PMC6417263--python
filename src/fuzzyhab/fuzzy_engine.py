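"""The 48-rule linguistic fuzzy system combining landscape, wind and climate.

Three inputs are fuzzified over piecewise-linear Ruspini partitions
(term memberships sum to 1 at every domain point):

* landscape suitability in [0, 1]: ``low``, ``medium low``, ``medium high``,
  ``high``;
* mean wind speed in m/s: ``comfortable`` (unrestricted flight), ``high``
  (moderate flight restriction), ``too high`` (strong restriction);
* climate suitability in [0, 1]: ``bad``, ``medium bad``, ``medium good``,
  ``good``.

All 4 x 3 x 4 = 48 rules fire with strength = t-norm of the three
antecedent degrees; each rule concludes one of nine ordered output labels
``bbbb`` (worst) .. ``m`` .. ``gggg`` (best), represented by crisp
singletons on the occurrence-probability scale.  Defuzzification is the
strength-weighted average of the singletons (zero-order Takagi-Sugeno),
so the output is continuous, lies in [0, 1], and equals a singleton
exactly whenever every input sits in a term core.

The shipped default model anchors the wind partition to the field
evidence for *Aedes japonicus japonicus* in Germany: the species was not
recorded above 4.7 m/s mean wind speed, so ``too high`` reaches full
membership at 4.7 m/s -- at that point every firing rule concludes at
most ``bb`` (0.25) and the model caps habitat suitability at 25%.
``comfortable`` holds up to 3.0 m/s and suitability is already markedly
reduced by 3.7 m/s, where ``high`` peaks.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml

from fuzzyhab.raster_core import GridRaster, require_aligned

__all__ = [
    "FuzzyVariable",
    "OutputScale",
    "RuleBase",
    "FuzzyModel",
    "load_model",
    "save_model",
    "default_model",
    "validate_rulebase",
    "sensitivity_surface",
]

LANDSCAPE_TERMS = ("low", "medium low", "medium high", "high")
WIND_TERMS = ("comfortable", "high", "too high")
CLIMATE_TERMS = ("bad", "medium bad", "medium good", "good")
OUTPUT_LABELS = ("bbbb", "bbb", "bb", "b", "m", "g", "gg", "ggg", "gggg")


@dataclass(frozen=True)
class FuzzyVariable:
    """One fuzzy input: ordered terms with a piecewise-linear partition.

    The partition is parametrised by one strictly increasing ``node`` per
    term: term *k* has membership 1 at ``nodes[k]``, falls linearly to 0
    at the neighbouring nodes, and the first/last terms stay at 1 out to
    the domain edges.  This construction is a Ruspini partition by
    design: at every point of the domain the memberships sum to exactly 1
    and at most two adjacent terms are active.
    """

    name: str
    terms: tuple[str, ...]
    nodes: tuple[float, ...]
    domain: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.terms) != len(self.nodes):
            raise ValueError(f"{self.name}: one node per term required")
        if len(self.terms) < 2:
            raise ValueError(f"{self.name}: at least two terms required")
        if any(b <= a for a, b in zip(self.nodes, self.nodes[1:])):
            raise ValueError(f"{self.name}: nodes must be strictly increasing")
        lo, hi = self.domain
        if not (lo <= self.nodes[0] and self.nodes[-1] <= hi):
            raise ValueError(f"{self.name}: nodes must lie inside the domain")

    def clamp(self, value: np.ndarray | float) -> np.ndarray:
        return np.clip(value, self.domain[0], self.domain[1])

    def memberships(self, value: np.ndarray | float) -> np.ndarray:
        """Degrees of membership, shape ``value.shape + (n_terms,)``.

        Values outside the declared domain are clamped to its edge (the
        edge terms keep full membership there).  Non-finite input raises.
        """
        value = np.asarray(value, dtype=float)
        if not np.all(np.isfinite(value)):
            raise ValueError(f"{self.name}: non-finite input value")
        v = self.clamp(value)
        out = np.empty(v.shape + (len(self.terms),))
        nodes = self.nodes
        for k in range(len(self.terms)):
            xs = [self.domain[0]]
            ys = [1.0 if k == 0 else 0.0]
            for m, node in enumerate(nodes):
                xs.append(node)
                ys.append(1.0 if m == k else 0.0)
            xs.append(self.domain[1])
            ys.append(1.0 if k == len(nodes) - 1 else 0.0)
            # drop duplicate abscissae introduced when a node sits on an edge
            xs_a, ys_a = [], []
            for x, yv in zip(xs, ys):
                if xs_a and x == xs_a[-1]:
                    continue
                xs_a.append(x)
                ys_a.append(yv)
            out[..., k] = np.interp(v, xs_a, ys_a)
        return out

    def membership_dict(self, value: float) -> dict[str, float]:
        """Term -> degree mapping for a single value."""
        deg = self.memberships(float(value))
        return {t: float(d) for t, d in zip(self.terms, deg)}


@dataclass(frozen=True)
class OutputScale:
    """Nine ordered output labels and their singleton values in [0, 1]."""

    labels: tuple[str, ...] = OUTPUT_LABELS
    singletons: tuple[float, ...] = tuple(np.linspace(0.0, 1.0, 9))

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.singletons):
            raise ValueError("one singleton per label required")
        if any(b <= a for a, b in zip(self.singletons, self.singletons[1:])):
            raise ValueError("singleton values must be strictly increasing")
        if self.singletons[0] != 0.0 or self.singletons[-1] != 1.0:
            raise ValueError("the scale must span [0, 1] exactly")

    def value(self, label: str) -> float:
        return self.singletons[self.labels.index(label)]


# Table of linguistic rules: (landscape, wind, climate) -> output label.
# An unsuitable landscape is never rescued by good climate, while very
# suitable land use partially compensates a bad climate; wind only ever
# pushes the conclusion down, to at most `bb` once it is `too high`.
DEFAULT_RULES: dict[tuple[str, str, str], str] = {}
_RULE_SPEC = """
low          comfortable bbbb bbb  bb   b
low          high        bbbb bbbb bbb  bbb
low          too high    bbbb bbbb bbbb bbb
medium low   comfortable bb   b    m    g
medium low   high        bbb  bb   m    m
medium low   too high    bbbb bbbb bbb  bbb
medium high  comfortable m    gg   ggg  gggg
medium high  high        bb   m    g    gg
medium high  too high    bbbb bbb  bb   bb
high         comfortable m    gg   gggg gggg
high         high        bb   m    gg   ggg
high         too high    bbbb bbb  bb   bb
"""
for _line in _RULE_SPEC.strip().splitlines():
    _parts = _line.split()
    _k = 2 if _parts[0] == "medium" else 1
    _land = " ".join(_parts[:_k])
    _wk = 2 if _parts[_k] == "too" else 1
    _wind = " ".join(_parts[_k:_k + _wk])
    for _climate, _label in zip(CLIMATE_TERMS, _parts[_k + _wk:]):
        DEFAULT_RULES[(_land, _wind, _climate)] = _label


@dataclass(frozen=True)
class RuleBase:
    """Complete rule set over the cross-product of antecedent terms."""

    rules: dict[tuple[str, str, str], str] = field(
        default_factory=lambda: dict(DEFAULT_RULES)
    )

    def conclusion(self, landscape: str, wind: str, climate: str) -> str:
        return self.rules[(landscape, wind, climate)]


def validate_rulebase(rb: RuleBase,
                      landscape: FuzzyVariable,
                      wind: FuzzyVariable,
                      climate: FuzzyVariable,
                      scale: OutputScale | None = None) -> dict:
    """Machine-readable consistency report for a rule base.

    Checks full cross-product coverage (48 premises for the default
    variables), unknown terms or labels, and monotonicity of the
    conclusions along each input's term order (non-decreasing in
    landscape and climate, non-increasing in wind).
    """
    scale = scale or OutputScale()
    expected = {
        (l, w, c)
        for l in landscape.terms for w in wind.terms for c in climate.terms
    }
    present = set(rb.rules)
    missing = sorted(expected - present)
    unknown_premises = sorted(present - expected)
    unknown_labels = sorted(
        {lab for lab in rb.rules.values() if lab not in scale.labels}
    )

    def rank(label: str) -> int:
        return scale.labels.index(label)

    violations: list[dict] = []
    covered = expected & present
    ok_labels = {p for p in covered if rb.rules[p] not in unknown_labels}

    def check(axis: str, order: tuple[str, ...], key, increasing: bool) -> None:
        for a, b in zip(order, order[1:]):
            for premise in ok_labels:
                if key(premise) != a:
                    continue
                other = tuple(b if v == a and i == _axis_index(axis) else v
                              for i, v in enumerate(premise))
                if other not in ok_labels:
                    continue
                lo, hi = rank(rb.rules[premise]), rank(rb.rules[other])
                bad = hi < lo if increasing else hi > lo
                if bad:
                    violations.append({
                        "axis": axis, "from": premise, "to": other,
                        "labels": (rb.rules[premise], rb.rules[other]),
                    })

    def _axis_index(axis: str) -> int:
        return {"landscape": 0, "wind": 1, "climate": 2}[axis]

    check("landscape", landscape.terms, lambda p: p[0], increasing=True)
    check("wind", wind.terms, lambda p: p[1], increasing=False)
    check("climate", climate.terms, lambda p: p[2], increasing=True)

    return {
        "n_rules": len(rb.rules),
        "n_expected": len(expected),
        "complete": not missing and not unknown_premises,
        "missing_premises": missing,
        "unknown_premises": unknown_premises,
        "unknown_labels": unknown_labels,
        "monotonicity_violations": violations,
        "ok": (not missing and not unknown_premises and not unknown_labels
               and not violations),
    }


def _default_variables() -> tuple[FuzzyVariable, FuzzyVariable, FuzzyVariable]:
    landscape = FuzzyVariable(
        "landscape", LANDSCAPE_TERMS,
        nodes=(0.0, 1 / 3, 2 / 3, 1.0), domain=(0.0, 1.0))
    wind = FuzzyVariable(
        "wind", WIND_TERMS, nodes=(3.0, 3.7, 4.7), domain=(0.0, 12.0))
    climate = FuzzyVariable(
        "climate", CLIMATE_TERMS,
        nodes=(0.0, 1 / 3, 2 / 3, 1.0), domain=(0.0, 1.0))
    return landscape, wind, climate


@dataclass
class FuzzyModel:
    """Fuzzification + rule base + defuzzification, scalar or raster-wise."""

    landscape: FuzzyVariable
    wind: FuzzyVariable
    climate: FuzzyVariable
    rules: RuleBase = field(default_factory=RuleBase)
    scale: OutputScale = field(default_factory=OutputScale)
    tnorm: Literal["min", "prod"] = "prod"

    def __post_init__(self) -> None:
        report = validate_rulebase(self.rules, self.landscape, self.wind,
                                   self.climate, self.scale)
        if not report["complete"] or report["unknown_labels"]:
            raise ValueError(
                "rule base does not cover the variables exactly: "
                f"missing={report['missing_premises'][:3]}... "
                f"unknown={report['unknown_premises'][:3]}"
            )
        if self.tnorm not in ("min", "prod"):
            raise ValueError(f"unknown t-norm: {self.tnorm!r}")
        # cache rule index arrays for the vectorised path
        idx = np.array(
            [
                (self.landscape.terms.index(l), self.wind.terms.index(w),
                 self.climate.terms.index(c))
                for (l, w, c) in self.rules.rules
            ],
            dtype=int,
        )
        self._rule_idx = idx
        self._rule_out = np.array(
            [self.scale.value(lab) for lab in self.rules.rules.values()]
        )

    # -- inference ----------------------------------------------------------
    def infer_array(self, landscape: np.ndarray, wind: np.ndarray,
                    climate: np.ndarray) -> np.ndarray:
        """Vectorised inference; inputs broadcast to a common shape."""
        l, w, c = np.broadcast_arrays(
            np.asarray(landscape, dtype=float),
            np.asarray(wind, dtype=float),
            np.asarray(climate, dtype=float),
        )
        mu_l = self.landscape.memberships(l)
        mu_w = self.wind.memberships(w)
        mu_c = self.climate.memberships(c)
        num = np.zeros(l.shape)
        den = np.zeros(l.shape)
        for (il, iw, ic), out in zip(self._rule_idx, self._rule_out):
            a, b, d = mu_l[..., il], mu_w[..., iw], mu_c[..., ic]
            if self.tnorm == "min":
                strength = np.minimum(np.minimum(a, b), d)
            else:
                strength = a * b * d
            num += strength * out
            den += strength
        if np.any(den <= 0):
            raise RuntimeError(
                "no rule fired for some input; the partitions do not cover "
                "the domain"
            )
        return num / den

    def infer(self, landscape: float, wind: float, climate: float) -> float:
        """Occurrence probability in [0, 1] for one input triple."""
        for name, v in (("landscape", landscape), ("wind", wind),
                        ("climate", climate)):
            if not np.isfinite(v):
                raise ValueError(f"non-finite {name} input")
        return float(self.infer_array(landscape, wind, climate))

    def apply(self, landscape: GridRaster, wind: GridRaster,
              climate: GridRaster, verbose: bool = False) -> GridRaster:
        """Cellwise inference over aligned rasters; nodata in -> nodata out."""
        require_aligned(landscape, wind, climate)
        mask = (landscape.nodata_mask() | wind.nodata_mask()
                | climate.nodata_mask())
        l = np.where(mask, 0.0, landscape.values.astype(float))
        w = np.where(mask, 0.0, wind.values.astype(float))
        c = np.where(mask, 0.0, climate.values.astype(float))
        if verbose:  # pragma: no cover - logging only
            total = mask.size
            print(f"applying fuzzy model to {total} cells "
                  f"({int(mask.sum())} nodata)")
        out = self.infer_array(l, w, c)
        out = np.where(mask, landscape.nodata, out)
        return GridRaster(out, landscape.cell_size, landscape.origin,
                          nodata=landscape.nodata, semantics="suitability")


def sensitivity_surface(model: FuzzyModel, wind: float,
                        grid_n: int = 101) -> dict:
    """Model output over a grid_n x grid_n landscape x climate grid at
    fixed wind speed; reports the surface and its maximum.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    axis = np.linspace(0.0, 1.0, grid_n)
    l, c = np.meshgrid(axis, axis, indexing="ij")
    surface = model.infer_array(l, np.full_like(l, wind), c)
    return {
        "axis": axis,
        "surface": surface,
        "max": float(surface.max()),
        "wind": float(wind),
    }


# ---------------------------------------------------------------------------
# (De)serialisation
# ---------------------------------------------------------------------------

def _model_to_dict(model: FuzzyModel) -> dict:
    return {
        "variables": [
            {
                "name": var.name,
                "terms": list(var.terms),
                "nodes": [float(n) for n in var.nodes],
                "domain": [float(v) for v in var.domain],
            }
            for var in (model.landscape, model.wind, model.climate)
        ],
        "output": {
            "labels": list(model.scale.labels),
            "singletons": [float(s) for s in model.scale.singletons],
        },
        "rules": [
            {"landscape": l, "wind": w, "climate": c, "then": lab}
            for (l, w, c), lab in model.rules.rules.items()
        ],
        "tnorm": model.tnorm,
    }


def save_model(model: FuzzyModel, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_model_to_dict(model), fh, sort_keys=False)


def _model_from_dict(doc: dict) -> FuzzyModel:
    variables = {}
    for vdoc in doc["variables"]:
        variables[vdoc["name"]] = FuzzyVariable(
            vdoc["name"], tuple(vdoc["terms"]), tuple(vdoc["nodes"]),
            tuple(vdoc["domain"]))
    rules = {
        (r["landscape"], r["wind"], r["climate"]): r["then"]
        for r in doc["rules"]
    }
    if len(rules) != len(doc["rules"]):
        raise ValueError("duplicate rule premises in model document")
    scale = OutputScale(tuple(doc["output"]["labels"]),
                        tuple(doc["output"]["singletons"]))
    return FuzzyModel(
        landscape=variables["landscape"],
        wind=variables["wind"],
        climate=variables["climate"],
        rules=RuleBase(rules),
        scale=scale,
        tnorm=doc.get("tnorm", "prod"),
    )


def load_model(path: str) -> FuzzyModel:
    """Load a fuzzy model definition from a YAML document."""
    with open(path) as fh:
        return _model_from_dict(yaml.safe_load(fh))


def default_model(tnorm: Literal["min", "prod"] = "prod") -> FuzzyModel:
    """The shipped model for *Ae. j. japonicus* in Germany.

    Identical to the packaged ``japonicus_de.yaml`` definition.
    """
    landscape, wind, climate = _default_variables()
    return FuzzyModel(landscape, wind, climate, tnorm=tnorm)


def packaged_model_path() -> str:
    """Filesystem path of the shipped ``japonicus_de.yaml``."""
    ref = importlib.resources.files("fuzzyhab") / "data" / "japonicus_de.yaml"
    return str(ref)
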