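"""Climate suitability: feature scaling, niche classifier, scenario deltas.

The climate input of the fuzzy model is the continuous [0, 1] score of a
binary classifier trained to separate the climate niche of the target
species from that of native reference species, on gridded climate
features (monthly precipitation sums, drought index, mean temperatures).

Two idiosyncrasies of the original protocol are reproduced exactly:

* feature scaling divides the centred feature by its **variance**, not
  its standard deviation, ``s(x) = (x - mean(x)) / var(x)``.  A
  conventional z-score mode is available behind ``use_std=True`` but is
  off by default;
* validation is a seeded stratified 90/10 holdout repeated R times
  (default 40), reported as mean +/- SD accuracy.

For future-climate projection the trained model is re-applied to feature
rasters perturbed by scenario deltas: additive offsets for temperatures
(K) and multiplicative factors for precipitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import train_test_split
from sklearn.svm import SVC

from fuzzyhab.raster_core import GridRaster, require_aligned

__all__ = [
    "FeatureScaler",
    "NicheClassifier",
    "ScenarioDeltas",
    "fit_scaler",
    "train_niche_classifier",
    "repeated_training_accuracy",
    "predict_suitability",
    "apply_scenario_deltas",
    "DegenerateFeatureError",
]


class DegenerateFeatureError(ValueError):
    """A feature column has zero variance and cannot be scaled."""


@dataclass(frozen=True)
class FeatureScaler:
    """Per-feature affine scaling ``s(x) = (x - mean) / var``.

    The variance (sample variance, ddof=1) in the denominator follows
    the original training protocol; set ``use_std`` for a conventional
    z-score.  The transform is invertible per feature.
    """

    mean: np.ndarray
    var: np.ndarray
    use_std: bool = False

    @property
    def denom(self) -> np.ndarray:
        return np.sqrt(self.var) if self.use_std else self.var

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.mean) / self.denom

    def inverse_transform(self, s: np.ndarray) -> np.ndarray:
        return np.asarray(s, dtype=float) * self.denom + self.mean


def fit_scaler(features: np.ndarray, use_std: bool = False) -> FeatureScaler:
    """Fit the scaler on a (n_samples, n_features) matrix.

    Raises :class:`DegenerateFeatureError` naming any constant column.
    """
    x = np.asarray(features, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        raise DegenerateFeatureError(
            f"zero-variance feature column(s): {bad.tolist()}"
        )
    return FeatureScaler(mean, var, use_std=use_std)


@dataclass
class NicheClassifier:
    """Margin-based presence-vs-reference classifier with [0, 1] scores.

    Wraps a support vector machine trained on scaled features; decision
    values are mapped to suitability scores through a monotone logistic
    link fitted on the training outputs (Platt scaling), so scores are
    always in [0, 1] and ordered like the SVM margins.
    """

    scaler: FeatureScaler
    svm: SVC
    link: LogisticRegression
    holdout_accuracy: float
    n_features: int
    meta: dict = field(default_factory=dict)

    def decision_values(self, features: np.ndarray) -> np.ndarray:
        x = np.asarray(features, dtype=float)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[1]}"
            )
        return self.svm.decision_function(self.scaler.transform(x))

    def score(self, features: np.ndarray) -> np.ndarray:
        """Suitability in [0, 1]; monotone in the SVM decision value."""
        d = self.decision_values(features)
        return self.link.predict_proba(d[:, None])[:, 1]


def _fit_once(presence: np.ndarray, reference: np.ndarray,
              holdout_fraction: float, seed: int,
              use_std: bool) -> NicheClassifier:
    x = np.vstack([presence, reference])
    y = np.concatenate([np.ones(len(presence)), np.zeros(len(reference))])
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=holdout_fraction, random_state=seed, stratify=y)
    scaler = fit_scaler(x_tr, use_std=use_std)
    svm = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    svm.fit(scaler.transform(x_tr), y_tr)
    d_tr = svm.decision_function(scaler.transform(x_tr))
    link = LogisticRegression()
    link.fit(d_tr[:, None], y_tr)
    acc = float((svm.predict(scaler.transform(x_te)) == y_te).mean())
    return NicheClassifier(scaler=scaler, svm=svm, link=link,
                           holdout_accuracy=acc, n_features=x.shape[1])


def train_niche_classifier(presence_features: np.ndarray,
                           reference_features: np.ndarray,
                           holdout_fraction: float = 0.10,
                           seed: int = 0,
                           use_std: bool = False) -> NicheClassifier:
    """Train the presence-vs-reference niche classifier.

    Fits the feature scaler on the training rows only, trains an RBF
    support vector machine (target species = 1, native reference = 0)
    and evaluates accuracy on a seeded stratified holdout of
    ``holdout_fraction`` (default 10%).
    """
    presence = np.asarray(presence_features, dtype=float)
    reference = np.asarray(reference_features, dtype=float)
    if presence.ndim != 2 or reference.ndim != 2:
        raise ValueError("feature matrices must be 2-D")
    if presence.shape[1] != reference.shape[1]:
        raise ValueError("presence and reference must share feature columns")
    if len(presence) < 10 or len(reference) < 10:
        raise ValueError("each class needs at least 10 rows")
    if not (0.0 < holdout_fraction < 1.0):
        raise ValueError("holdout_fraction must be in (0, 1)")
    return _fit_once(presence, reference, holdout_fraction, seed, use_std)


def repeated_training_accuracy(presence_features: np.ndarray,
                               reference_features: np.ndarray,
                               repeats: int = 40,
                               holdout_fraction: float = 0.10,
                               seed: int = 0,
                               use_std: bool = False) -> dict:
    """Repeat training over R seeded holdout splits; report mean +/- SD.

    This mirrors the repeated-training validation protocol (default 40
    repeats with a 10% stratified holdout).  Returns the per-repeat
    accuracies plus their mean and standard deviation, and the
    classifier from the first repeat.
    """
    rng = np.random.default_rng(seed)
    accs = []
    model = None
    for _ in range(repeats):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        fitted = train_niche_classifier(
            presence_features, reference_features,
            holdout_fraction=holdout_fraction, seed=sub_seed,
            use_std=use_std)
        if model is None:
            model = fitted
        accs.append(fitted.holdout_accuracy)
    accs_arr = np.asarray(accs)
    return {
        "accuracies": accs_arr,
        "mean": float(accs_arr.mean()),
        "sd": float(accs_arr.std(ddof=1)) if repeats > 1 else 0.0,
        "repeats": repeats,
        "holdout_fraction": holdout_fraction,
        "model": model,
    }


def predict_suitability(model: NicheClassifier,
                        feature_rasters: list[GridRaster]) -> GridRaster:
    """Cellwise classifier score over aligned feature rasters.

    One raster per trained feature, in training column order; nodata in
    any feature makes the output cell nodata.
    """
    if len(feature_rasters) != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} feature rasters, "
            f"got {len(feature_rasters)}"
        )
    require_aligned(*feature_rasters)
    first = feature_rasters[0]
    mask = np.zeros(first.shape, dtype=bool)
    for r in feature_rasters:
        mask |= r.nodata_mask()
    stack = np.stack([r.values.astype(float) for r in feature_rasters],
                     axis=-1)
    flat = stack.reshape(-1, model.n_features)
    ok = ~mask.ravel()
    scores = np.full(flat.shape[0], first.nodata, dtype=float)
    if ok.any():
        scores[ok] = model.score(flat[ok])
    out = scores.reshape(first.shape)
    return GridRaster(out, first.cell_size, first.origin,
                      nodata=first.nodata, semantics="suitability")


@dataclass(frozen=True)
class ScenarioDeltas:
    """Mean climate-change deltas applied to the feature rasters.

    Temperatures shift additively (K); precipitation scales
    multiplicatively.  The default values are the multi-scenario means
    used for the 2021-2050 projection: summer temperature +1.4 K, summer
    precipitation -4%, winter precipitation +5%.
    """

    temperature_offsets: dict[str, float] = field(
        default_factory=lambda: {"summer": 1.4})
    precipitation_factors: dict[str, float] = field(
        default_factory=lambda: {"summer": 0.96, "winter": 1.05})

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.precipitation_factors.values()):
            raise ValueError("precipitation factors must be positive")


def apply_scenario_deltas(feature_rasters: list[GridRaster],
                          deltas: ScenarioDeltas) -> list[GridRaster]:
    """Perturb feature rasters by scenario deltas; nodata is preserved.

    Each raster must be tagged through ``meta['feature_group']`` as
    ``"temperature:<season>"`` or ``"precipitation:<season>"``; an
    untagged raster raises.  Applying an additive delta twice equals
    applying its doubled value once (and likewise multiplicatively).
    """
    out: list[GridRaster] = []
    for r in feature_rasters:
        group = r.meta.get("feature_group")
        if not group or ":" not in group:
            raise ValueError(
                "feature raster lacks a 'feature_group' tag of the form "
                "'temperature:<season>' or 'precipitation:<season>'"
            )
        kind, season = group.split(":", 1)
        mask = r.nodata_mask()
        vals = r.values.astype(float)
        if kind == "temperature":
            offset = deltas.temperature_offsets.get(season, 0.0)
            new = vals + offset
        elif kind == "precipitation":
            factor = deltas.precipitation_factors.get(season, 1.0)
            new = vals * factor
        else:
            raise ValueError(f"unknown feature group kind: {kind!r}")
        new = np.where(mask, r.nodata, new)
        out.append(r.with_values(new))
    return out
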