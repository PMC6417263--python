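import numpy as np
import pytest
import yaml

from fuzzyhab.fuzzy_engine import (
    DEFAULT_RULES,
    FuzzyModel,
    FuzzyVariable,
    OutputScale,
    RuleBase,
    default_model,
    load_model,
    packaged_model_path,
    save_model,
    sensitivity_surface,
    validate_rulebase,
)
from fuzzyhab.raster_core import GridAlignmentError, GridRaster

MODEL = default_model()

CORES = {
    "landscape": dict(zip(MODEL.landscape.terms, MODEL.landscape.nodes)),
    "wind": dict(zip(MODEL.wind.terms, MODEL.wind.nodes)),
    "climate": dict(zip(MODEL.climate.terms, MODEL.climate.nodes)),
}


class TestMembership:
    @pytest.mark.parametrize("var", [MODEL.landscape, MODEL.wind,
                                     MODEL.climate])
    def test_ruspini_partition_sums_to_one(self, var):
        rng = np.random.default_rng(17)
        values = rng.uniform(var.domain[0], var.domain[1], size=10_000)
        sums = var.memberships(values).sum(axis=-1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_core_membership_is_crisp(self):
        deg = MODEL.wind.membership_dict(2.0)  # inside the comfortable core
        assert deg == {"comfortable": 1.0, "high": 0.0, "too high": 0.0}

    def test_crossover_midpoint_splits_half_half(self):
        mid = (3.0 + 3.7) / 2
        deg = MODEL.wind.membership_dict(mid)
        assert deg["comfortable"] == pytest.approx(0.5)
        assert deg["high"] == pytest.approx(0.5)

    def test_out_of_domain_values_clamp_to_edge(self):
        deg = MODEL.wind.membership_dict(50.0)
        assert deg["too high"] == 1.0

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            MODEL.wind.memberships(np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            MODEL.infer(0.5, np.inf, 0.5)

    def test_nodes_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            FuzzyVariable("x", ("a", "b"), (1.0, 1.0), (0.0, 2.0))


class TestOutputScale:
    def test_default_scale_spans_unit_interval(self):
        s = OutputScale()
        assert s.value("bbbb") == 0.0
        assert s.value("m") == 0.5
        assert s.value("gggg") == 1.0

    def test_non_increasing_singletons_rejected(self):
        with pytest.raises(ValueError):
            OutputScale(("a", "b"), (0.5, 0.5))


class TestRuleBase:
    def test_default_rulebase_complete(self):
        report = validate_rulebase(MODEL.rules, MODEL.landscape, MODEL.wind,
                                   MODEL.climate, MODEL.scale)
        assert report["n_rules"] == 48
        assert report["complete"]
        assert not report["unknown_labels"]
        assert not report["monotonicity_violations"]
        assert report["ok"]

    def test_missing_premise_flagged_by_name(self):
        rules = dict(DEFAULT_RULES)
        removed = ("low", "comfortable", "bad")
        del rules[removed]
        report = validate_rulebase(RuleBase(rules), MODEL.landscape,
                                   MODEL.wind, MODEL.climate, MODEL.scale)
        assert not report["complete"]
        assert removed in report["missing_premises"]

    def test_unknown_term_flagged(self):
        rules = dict(DEFAULT_RULES)
        rules[("low", "breezy", "bad")] = "m"
        report = validate_rulebase(RuleBase(rules), MODEL.landscape,
                                   MODEL.wind, MODEL.climate, MODEL.scale)
        assert ("low", "breezy", "bad") in report["unknown_premises"]

    def test_non_monotone_conclusion_flagged(self):
        rules = dict(DEFAULT_RULES)
        rules[("high", "comfortable", "good")] = "bbbb"  # break ordering
        report = validate_rulebase(RuleBase(rules), MODEL.landscape,
                                   MODEL.wind, MODEL.climate, MODEL.scale)
        assert report["monotonicity_violations"]

    def test_incomplete_rulebase_rejected_by_model(self):
        rules = dict(DEFAULT_RULES)
        del rules[("low", "comfortable", "bad")]
        with pytest.raises(ValueError, match="cover"):
            FuzzyModel(MODEL.landscape, MODEL.wind, MODEL.climate,
                       RuleBase(rules))


class TestInference:
    @pytest.mark.parametrize("tnorm", ["prod", "min"])
    def test_all_48_rule_cores_return_exact_singletons(self, tnorm):
        model = default_model(tnorm)
        for (lt, wt, ct), label in model.rules.rules.items():
            out = model.infer(CORES["landscape"][lt], CORES["wind"][wt],
                              CORES["climate"][ct])
            assert out == pytest.approx(model.scale.value(label), abs=1e-12), \
                f"rule ({lt}, {wt}, {ct}) -> {label}"

    def test_output_monotone_in_each_input(self):
        ls = np.linspace(0, 1, 25)
        ws = np.linspace(0, 6, 25)
        cs = np.linspace(0, 1, 25)
        L, W, C = np.meshgrid(ls, ws, cs, indexing="ij")
        out = MODEL.infer_array(L, W, C)
        assert (np.diff(out, axis=0) >= -1e-12).all(), "landscape"
        assert (np.diff(out, axis=1) <= 1e-12).all(), "wind"
        assert (np.diff(out, axis=2) >= -1e-12).all(), "climate"

    def test_output_continuous_in_each_input(self):
        # finite differences on a fine grid stay bounded by a Lipschitz-like
        # constant (piecewise-linear memberships, weighted-average output)
        n = 601
        xs = np.linspace(0, 1, n)
        step = xs[1] - xs[0]
        out_l = MODEL.infer_array(xs, 2.0, 0.6)
        assert np.abs(np.diff(out_l)).max() < 10 * step
        ws = np.linspace(0, 6, n)
        out_w = MODEL.infer_array(0.8, ws, 0.6)
        assert np.abs(np.diff(out_w)).max() < 10 * (ws[1] - ws[0])

    def test_output_in_unit_interval_everywhere(self):
        rng = np.random.default_rng(23)
        out = MODEL.infer_array(rng.random(500), rng.uniform(0, 12, 500),
                                rng.random(500))
        assert (out >= 0).all() and (out <= 1).all()


class TestSensitivitySurface:
    def test_comfortable_wind_reaches_full_suitability(self):
        res = sensitivity_surface(MODEL, 2.0, grid_n=21)
        assert res["max"] == pytest.approx(1.0)

    def test_wind_cap_at_4_7(self):
        res = sensitivity_surface(MODEL, 4.7, grid_n=101)
        assert res["max"] <= 0.25 + 1e-12

    def test_5ms_surface_dominated_by_3ms_surface(self):
        s3 = sensitivity_surface(MODEL, 3.0, grid_n=41)["surface"]
        s5 = sensitivity_surface(MODEL, 5.0, grid_n=41)["surface"]
        assert (s5 <= s3 + 1e-12).all()

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            sensitivity_surface(MODEL, 3.0, grid_n=1)


class TestRasterApplication:
    def _const(self, value, semantics):
        return GridRaster(np.full((4, 5), value), 100.0, (0.0, 400.0),
                          nodata=-9999.0, semantics=semantics)

    def test_constant_rasters_at_cores_give_singleton(self):
        out = MODEL.apply(self._const(1.0, "suitability"),
                          self._const(2.0, "wind"),
                          self._const(1.0, "suitability"))
        np.testing.assert_allclose(out.values, 1.0)
        out2 = MODEL.apply(self._const(0.0, "suitability"),
                           self._const(5.5, "wind"),
                           self._const(0.0, "suitability"))
        np.testing.assert_allclose(out2.values, 0.0)

    def test_nodata_in_any_input_propagates(self):
        wind = self._const(2.0, "wind")
        wind.values[1, 2] = -9999.0
        out = MODEL.apply(self._const(0.8, "suitability"), wind,
                          self._const(0.9, "suitability"))
        assert out.values[1, 2] == -9999.0
        assert (out.values != -9999.0).sum() == 19

    def test_misaligned_rasters_rejected(self):
        shifted = GridRaster(np.full((4, 5), 2.0), 100.0, (50.0, 400.0),
                             semantics="wind")
        with pytest.raises(GridAlignmentError):
            MODEL.apply(self._const(0.5, "suitability"), shifted,
                        self._const(0.5, "suitability"))

    def test_raster_application_equals_cellwise_loop(self):
        rng = np.random.default_rng(6)
        shape = (12, 9)
        l = GridRaster(rng.random(shape), 100.0, (0.0, 1200.0),
                       semantics="suitability")
        w = GridRaster(rng.uniform(0, 6, shape), 100.0, (0.0, 1200.0),
                       semantics="wind")
        c = GridRaster(rng.random(shape), 100.0, (0.0, 1200.0),
                       semantics="suitability")
        out = MODEL.apply(l, w, c)
        for i in range(shape[0]):
            for j in range(shape[1]):
                want = MODEL.infer(l.values[i, j], w.values[i, j],
                                   c.values[i, j])
                assert out.values[i, j] == pytest.approx(want, abs=1e-12)


class TestSerialisation:
    def test_yaml_roundtrip_preserves_model(self, tmp_path):
        path = str(tmp_path / "model.yaml")
        save_model(MODEL, path)
        back = load_model(path)
        assert back.rules.rules == MODEL.rules.rules
        assert back.scale.singletons == MODEL.scale.singletons
        assert back.tnorm == MODEL.tnorm
        assert back.wind.nodes == MODEL.wind.nodes

    def test_packaged_model_matches_default(self):
        shipped = load_model(packaged_model_path())
        assert shipped.rules.rules == MODEL.rules.rules
        assert shipped.wind.nodes == MODEL.wind.nodes
        assert shipped.scale.singletons == MODEL.scale.singletons

    def test_duplicate_rule_premises_rejected_on_load(self, tmp_path):
        with open(packaged_model_path()) as fh:
            doc = yaml.safe_load(fh)
        doc["rules"].append(dict(doc["rules"][0]))
        path = tmp_path / "dup.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ValueError, match="duplicate"):
            load_model(str(path))
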