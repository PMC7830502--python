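import numpy as np
import pandas as pd
import pytest

from rangeshift.ensemble import (
    FAMILIES,
    EnsembleModel,
    FittedModel,
    ModelSpec,
    average_stacks,
    build_ensemble,
    evaluate_ensemble,
    evaluate_member,
    fit_member,
    marginal_response,
    predict_surface,
    sample_pseudo_absences,
    split_train_test,
)
from rangeshift.exceptions import GridAlignmentError, MissingLayerError
from rangeshift.grids import PredictorStack, RasterGrid
from rangeshift.metrics import EvaluationResult
from rangeshift.occurrences import OccurrenceSet

FAST = {
    "RF": {"n_trees": 50},
    "BRT": {"n_trees": 100, "learning_rate": 0.05},
    "GLM": {},
    "GAM": {},
}


def _spec(family, seed=0):
    return ModelSpec(family=family, hyperparameters=FAST[family], seed=seed)


@pytest.fixture
def separable_table():
    """Linearly separable toy data with a little label noise-free margin."""
    rng = np.random.default_rng(0)
    n = 120
    x1 = np.concatenate([rng.normal(-2, 0.5, n // 2), rng.normal(2, 0.5, n // 2)])
    x2 = rng.standard_normal(n)
    label = (x1 > 0).astype(int)
    return pd.DataFrame({"x1": x1, "x2": x2, "label": label})


class TestPseudoAbsences:
    def test_ratio_times_presences(self, default_world):
        stack, _, _, occ, _, _ = default_world
        pts = occ.points[:20]
        background = sample_pseudo_absences(stack, pts, ratio=10, seed=1)
        assert len(background) == 200

    def test_no_background_on_presence_cells(self, default_world):
        stack, _, _, occ, _, _ = default_world
        background = sample_pseudo_absences(stack, occ, ratio=10, seed=2)
        pres_cells = {tuple(c) for c in stack.grid.cells_of(occ.points)}
        bg_cells = {tuple(c) for c in stack.grid.cells_of(background)}
        assert not (pres_cells & bg_cells)

    def test_seed_reproducible(self, default_world):
        stack, _, _, occ, _, _ = default_world
        a = sample_pseudo_absences(stack, occ, ratio=5, seed=3)
        b = sample_pseudo_absences(stack, occ, ratio=5, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_insufficient_cells_warns_and_returns_all(self, tiny_stack):
        occ = OccurrenceSet("sp", [tiny_stack.grid.cell_center(0, 0)])
        with pytest.warns(UserWarning, match="eligible"):
            background = sample_pseudo_absences(tiny_stack, occ, ratio=200, seed=0)
        assert len(background) == 99  # all cells except the presence cell


class TestSplit:
    def test_seventy_thirty(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame({
            "x": rng.standard_normal(100),
            "label": np.repeat([1, 0], 50),
        })
        train, test = split_train_test(table, seed=0)
        assert len(train) == 70 and len(test) == 30

    def test_stratification_arithmetic(self):
        table = pd.DataFrame({
            "x": np.arange(110.0),
            "label": np.array([1] * 10 + [0] * 100),
        })
        train, _ = split_train_test(table, seed=1)
        assert (train["label"] == 1).sum() == 7

    def test_union_is_input(self):
        rng = np.random.default_rng(2)
        table = pd.DataFrame({
            "x": rng.standard_normal(40), "label": np.tile([0, 1], 20)
        })
        train, test = split_train_test(table, seed=2)
        merged = pd.concat([train, test]).sort_values("x").reset_index(drop=True)
        expected = table.sort_values("x").reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, expected)

    def test_tiny_class_errors(self):
        table = pd.DataFrame({"x": [1.0, 2.0, 3.0], "label": [1, 0, 0]})
        with pytest.raises(ValueError):
            split_train_test(table, seed=0)


class TestFitMember:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_data_high_auc(self, family, separable_table):
        train, test = split_train_test(separable_table, seed=3)
        member = evaluate_member(fit_member(_spec(family), train), test)
        assert member.evaluation.auc > 0.9

    @pytest.mark.parametrize("family", FAMILIES)
    def test_no_signal_predicts_prevalence(self, family):
        rng = np.random.default_rng(4)
        table = pd.DataFrame({
            "x": np.ones(100) + rng.normal(0, 1e-9, 100),
            "label": np.array([1] * 20 + [0] * 80),
        })
        member = fit_member(_spec(family), table)
        preds = member.predict(table)
        assert np.mean(preds) == pytest.approx(0.2, abs=0.1)

    def test_same_spec_same_predictions(self, separable_table):
        train, test = split_train_test(separable_table, seed=5)
        for family in ("RF", "BRT"):
            a = fit_member(_spec(family, seed=7), train).predict(test)
            b = fit_member(_spec(family, seed=7), train).predict(test)
            np.testing.assert_array_equal(a, b)

    def test_predictions_are_probabilities(self, separable_table):
        member = fit_member(_spec("GLM"), separable_table)
        preds = member.predict(separable_table)
        assert np.all((preds >= 0) & (preds <= 1))


def _stub_member(tss_value, constant=0.5, family="GLM"):
    member = FittedModel(
        spec=ModelSpec(family=family), variables=["x"], pipeline=None
    )
    member.evaluation = EvaluationResult(
        auc=0.9, tss=tss_value, sensitivity=0.9, specificity=0.9,
        threshold_mtss=0.5, threshold_mtp=0.1,
    )
    member.predict = lambda table: np.full(len(table), constant)  # type: ignore
    return member


class TestBuildEnsemble:
    def test_weights_proportional_to_tss(self):
        ens = build_ensemble([_stub_member(0.6), _stub_member(0.2)])
        np.testing.assert_allclose(ens.weights, [0.75, 0.25])

    def test_single_member_weight_one(self):
        ens = build_ensemble([_stub_member(0.4)])
        np.testing.assert_allclose(ens.weights, [1.0])

    def test_negative_tss_floored_to_zero(self):
        ens = build_ensemble([_stub_member(0.5), _stub_member(-0.2)])
        np.testing.assert_allclose(ens.weights, [1.0, 0.0])

    def test_all_non_positive_tss_equal_weights(self):
        with pytest.warns(UserWarning, match="equal weights"):
            ens = build_ensemble([_stub_member(-0.1), _stub_member(0.0)])
        np.testing.assert_allclose(ens.weights, [0.5, 0.5])

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            build_ensemble([])

    def test_weights_sum_to_one(self):
        ens = build_ensemble([_stub_member(t) for t in (0.3, 0.5, 0.1, 0.7)])
        assert ens.weights.sum() == pytest.approx(1.0)


class TestPredictSurface:
    @pytest.fixture
    def fitted(self, separable_table):
        train, test = split_train_test(separable_table, seed=6)
        members = [
            evaluate_member(fit_member(_spec(f, seed=1), train), test)
            for f in ("GLM", "RF")
        ]
        return build_ensemble(members)

    @pytest.fixture
    def surface_stack(self, small_grid):
        rng = np.random.default_rng(7)
        stack = PredictorStack()
        stack.add("x1", RasterGrid(rng.normal(0, 2, (10, 10)), small_grid))
        stack.add("x2", RasterGrid(rng.standard_normal((10, 10)), small_grid))
        return stack

    def test_convex_combination_of_members(self, fitted, surface_stack):
        ens_surface = predict_surface(fitted, surface_stack).values
        member_surfaces = [
            predict_surface(
                EnsembleModel([m], np.array([1.0]), fitted.retained_variables),
                surface_stack,
            ).values
            for m in fitted.members
        ]
        lo = np.minimum.reduce(member_surfaces)
        hi = np.maximum.reduce(member_surfaces)
        assert np.all(ens_surface >= lo - 1e-12)
        assert np.all(ens_surface <= hi + 1e-12)

    def test_nodata_propagates(self, fitted, surface_stack):
        surface_stack["x1"].values[0, 0] = np.nan
        out = predict_surface(fitted, surface_stack)
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[1:, :]).all()

    def test_missing_layer_errors(self, fitted, small_grid):
        stack = PredictorStack({"x1": RasterGrid(np.zeros((10, 10)), small_grid)})
        with pytest.raises(MissingLayerError):
            predict_surface(fitted, stack)


class TestMarginalResponse:
    def test_flat_curve_for_ignored_variable(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({
            "used": rng.standard_normal(100), "unused": rng.standard_normal(100)
        })
        member = _stub_member(0.5)
        ens = EnsembleModel([member], np.array([1.0]), ["used", "unused"])
        curve = marginal_response(ens, "unused", 20, table)
        probs = [p for _, p in curve]
        assert max(probs) - min(probs) < 1e-12

    def test_values_in_unit_interval(self, separable_table):
        train, test = split_train_test(separable_table, seed=9)
        member = evaluate_member(fit_member(_spec("GLM"), train), test)
        ens = build_ensemble([member])
        curve = marginal_response(ens, "x1", 30, train)
        assert all(0.0 <= p <= 1.0 for _, p in curve)

    def test_unknown_variable_errors(self):
        ens = EnsembleModel([_stub_member(0.5)], np.array([1.0]), ["x"])
        with pytest.raises(ValueError):
            marginal_response(ens, "zzz", 10, pd.DataFrame({"x": [0.0, 1.0]}))


class TestAverageStacks:
    def test_average_with_itself_is_identity(self, tiny_stack):
        out = average_stacks([tiny_stack, tiny_stack])
        for name in tiny_stack.names:
            np.testing.assert_allclose(out[name].values, tiny_stack[name].values)

    def test_constant_layers_average(self, small_grid):
        a = PredictorStack({"L": RasterGrid(np.full((10, 10), 10.0), small_grid)})
        b = PredictorStack({"L": RasterGrid(np.full((10, 10), 20.0), small_grid)})
        out = average_stacks([a, b])
        np.testing.assert_allclose(out["L"].values, 15.0)

    def test_order_invariant(self, small_grid):
        rng = np.random.default_rng(10)
        stacks = [
            PredictorStack({"L": RasterGrid(rng.random((10, 10)), small_grid)})
            for _ in range(3)
        ]
        fwd = average_stacks(stacks)
        rev = average_stacks(stacks[::-1])
        np.testing.assert_allclose(fwd["L"].values, rev["L"].values)

    def test_mismatched_grids_error(self, small_grid):
        from rangeshift.grids import GridDefinition

        other = GridDefinition(10, 10, 0.0, 10.0, 1.0, 1.0)
        a = PredictorStack({"L": RasterGrid(np.zeros((10, 10)), small_grid)})
        b = PredictorStack({"L": RasterGrid(np.zeros((10, 10)), other)})
        with pytest.raises(GridAlignmentError):
            average_stacks([a, b])

    def test_mismatched_names_error(self, small_grid):
        a = PredictorStack({"L": RasterGrid(np.zeros((10, 10)), small_grid)})
        b = PredictorStack({"M": RasterGrid(np.zeros((10, 10)), small_grid)})
        with pytest.raises(ValueError):
            average_stacks([a, b])


def test_ensemble_evaluation_populates_metrics(separable_table):
    train, test = split_train_test(separable_table, seed=11)
    members = [
        evaluate_member(fit_member(_spec(f), train), test) for f in ("GLM", "RF")
    ]
    ens = evaluate_ensemble(build_ensemble(members), test)
    ev = ens.evaluation
    assert 0.9 < ev.auc <= 1.0
    assert ev.tss == pytest.approx(ev.sensitivity + ev.specificity - 1.0)
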