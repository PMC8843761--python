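import warnings

import numpy as np
import pandas as pd
import pytest

from kernelscape.covariates import CovariateStack
from kernelscape.model import (HabitatSelectionModel, collinearity_screen,
                               ensemble_predict, evaluate_auc,
                               mir_model_selection, mir_subsets,
                               partial_dependence, rank_auc,
                               univariate_scale_selection)

from conftest import make_grid


def auc_pair_count(scores, labels):
    """Brute-force AUC: fraction of presence/absence pairs correctly
    ordered, ties counted half."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels).astype(int)
    pos = s[lab == 1]
    neg = s[lab == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else (0.5 if p == q else 0.0)
    return wins / (len(pos) * len(neg))


class TestRankAuc:
    def test_perfect_separation_is_one(self):
        assert rank_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_reversed_separation_is_zero(self):
        assert rank_auc([0.1, 0.2, 0.8, 0.9], [1, 1, 0, 0]) == 0.0

    def test_all_tied_scores_give_half(self):
        assert rank_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == 0.5

    def test_matches_pair_count_oracle(self, rng):
        scores = rng.choice(np.linspace(0, 1, 20), size=60)  # forces ties
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]  # both classes present
        assert rank_auc(scores, labels) == pytest.approx(
            auc_pair_count(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rank_auc([0.1, 0.2], [1, 1])


class TestMirSubsets:
    def test_threshold_arithmetic(self):
        mir = pd.Series({"a": 1.0, "b": 0.5, "c": 0.1})
        subs = mir_subsets(mir, step=0.1)
        assert subs[0.0] == ["a", "b", "c"]
        assert subs[0.3] == ["a", "b"]
        assert subs[0.5] == ["a", "b"]
        assert subs[0.6] == ["a"]
        assert subs[0.9] == ["a"]
        assert len(subs) == 10

    def test_normalization_by_maximum(self):
        # raw importances (0.5, 0.25, 0.05) normalize to MIR (1, 0.5, 0.1)
        raw = pd.Series({"a": 0.5, "b": 0.25, "c": 0.05})
        mir = raw / raw.max()
        assert mir.tolist() == [1.0, 0.5, 0.1]
        assert mir_subsets(mir)[0.3] == ["a", "b"]


def _two_scale_stack(rng, n=40, cs=100.0):
    """Stack where A discriminates (x-gradient) and B is noise; A present at
    two scales with the 1000-m layer informative and the 2000-m layer
    degraded by noise."""
    x = np.tile(np.linspace(0, 1, n), (n, 1))
    stack = CovariateStack()
    stack.add("A_1000", make_grid(x, cs))
    stack.add("A_2000", make_grid(x + rng.normal(0, 2.0, (n, n)), cs))
    stack.add("B_1000", make_grid(rng.normal(size=(n, n)), cs))
    stack.add("B_2000", make_grid(rng.normal(size=(n, n)), cs))
    return stack


def _points(stack, rng, n_pts=25):
    """Presences on the east (high A), absences on the west."""
    tmpl = stack.template
    xmin, ymin, xmax, ymax = tmpl.bounds
    pres = pd.DataFrame({
        "x": rng.uniform(0.75 * xmax, xmax - 1, n_pts),
        "y": rng.uniform(ymin + 1, ymax - 1, n_pts)})
    absn = pd.DataFrame({
        "x": rng.uniform(xmin + 1, 0.25 * xmax, n_pts),
        "y": rng.uniform(ymin + 1, ymax - 1, n_pts)})
    return pres, absn


class TestScaleSelection:
    def test_informative_scale_recovered(self, rng):
        stack = _two_scale_stack(rng)
        pres, absn = _points(stack, rng)
        ds = pd.concat([pres.assign(label="presence"),
                        absn.assign(label="pseudo_absence")],
                       ignore_index=True)
        prof = univariate_scale_selection([ds, ds], stack, trees=50, seed=1)
        assert prof.chosen["A"] == 1000
        assert prof.frequency["A"] == 2
        assert set(prof.oob_errors["variable"]) == {"A", "B"}

    def test_unbalanced_dataset_rejected(self, rng):
        stack = _two_scale_stack(rng)
        pres, absn = _points(stack, rng)
        ds = pd.concat([pres.assign(label="presence"),
                        absn.iloc[:-3].assign(label="pseudo_absence")],
                       ignore_index=True)
        with pytest.raises(ValueError):
            univariate_scale_selection([ds], stack, trees=20, seed=0)

    def test_empty_dataset_list_rejected(self, rng):
        with pytest.raises(ValueError):
            univariate_scale_selection([], _two_scale_stack(rng))


class TestCollinearityScreen:
    def test_duplicate_layer_dropped_by_ranking(self, rng):
        vals = rng.normal(size=(20, 20))
        stack = CovariateStack()
        stack.add("a", make_grid(vals))
        stack.add("b", make_grid(vals.copy()))          # r = 1 with a
        stack.add("c", make_grid(rng.normal(size=(20, 20))))
        retained, removals = collinearity_screen(
            stack, ["a", "b", "c"], 0.85, ranking={"a": 0.4, "b": 0.1})
        assert retained == ["b", "c"]                   # a is worse, dropped
        assert removals[0][0] == "a" and removals[0][1] == "b"
        assert removals[0][2] == pytest.approx(1.0)

    def test_without_ranking_later_layer_dropped(self, rng):
        vals = rng.normal(size=(20, 20))
        stack = CovariateStack()
        stack.add("a", make_grid(vals))
        stack.add("b", make_grid(vals * 2.0 + 1.0))     # r = 1, later-listed
        retained, removals = collinearity_screen(stack, ["a", "b"], 0.85)
        assert retained == ["a"]
        assert removals[0][0] == "b"

    def test_uncorrelated_layers_all_retained(self, rng):
        stack = CovariateStack()
        stack.add("a", make_grid(rng.normal(size=(30, 30))))
        stack.add("b", make_grid(rng.normal(size=(30, 30))))
        retained, removals = collinearity_screen(stack, ["a", "b"], 0.85)
        assert retained == ["a", "b"] and removals == []

    def test_constant_layer_retained_with_warning(self, rng):
        stack = CovariateStack()
        stack.add("a", make_grid(rng.normal(size=(10, 10))))
        stack.add("flat", make_grid(np.full((10, 10), 7.0)))
        with pytest.warns(UserWarning, match="constant"):
            retained, _ = collinearity_screen(stack, ["a", "flat"], 0.85)
        assert "flat" in retained


class TestMirModelSelection:
    def test_informative_variable_survives(self, rng):
        x = np.concatenate([rng.normal(2, 0.3, 30), rng.normal(-2, 0.3, 30)])
        X = pd.DataFrame({"signal": x, "noise": rng.normal(size=60)})
        y = np.r_[np.ones(30), np.zeros(30)]
        member = mir_model_selection(X, y, trees=100, seed=4)
        assert "signal" in member.variables
        top = member.mir_table.iloc[0]
        assert top["variable"] == "signal"
        assert top["mir"] == pytest.approx(1.0)
        assert 0.0 <= member.oob_error <= 0.2

    def test_pure_noise_rejected(self, rng):
        X = pd.DataFrame({"n1": np.zeros(40), "n2": np.zeros(40)})
        y = np.r_[np.ones(20), np.zeros(20)]
        with pytest.raises(ValueError, match="importance"):
            mir_model_selection(X, y, trees=30, seed=0)

    def test_unbalanced_labels_rejected(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=30)})
        y = np.r_[np.ones(20), np.zeros(10)]
        with pytest.raises(ValueError, match="equal-sampling"):
            mir_model_selection(X, y, trees=20, seed=0)


class TestEnsemblePredict:
    def test_learned_gradient_reproduced(self, rng):
        stack = _two_scale_stack(rng)
        pres, absn = _points(stack, rng)
        X = stack.sample(np.r_[pres["x"], absn["x"]],
                         np.r_[pres["y"], absn["y"]],
                         names=["A_1000"])
        y = np.r_[np.ones(len(pres)), np.zeros(len(absn))]
        member = mir_model_selection(X, y, trees=100, seed=2)
        surface = ensemble_predict([member], stack)
        vals = surface.values
        assert np.nanmin(vals) >= 0 and np.nanmax(vals) <= 1
        # east edge (high A, presence side) scores above the west edge
        assert np.nanmean(vals[:, -5:]) > np.nanmean(vals[:, :5]) + 0.5

    def test_empty_ensemble_rejected(self, rng):
        with pytest.raises(ValueError):
            ensemble_predict([], _two_scale_stack(rng))


class TestEvaluateAuc:
    def test_separable_data_scores_high(self, rng):
        x = np.concatenate([rng.normal(3, 0.3, 30), rng.normal(-3, 0.3, 30)])
        X = pd.DataFrame({"v": x})
        y = np.r_[np.ones(30), np.zeros(30)]
        mean, sd, per_rep = evaluate_auc([X], [y], reps=3, trees=50, seed=1)
        assert mean > 0.95
        assert len(per_rep) == 3
        assert sd >= 0.0

    def test_label_noise_scores_near_half(self, rng):
        X = pd.DataFrame({"v": rng.normal(size=80)})
        y = np.r_[np.ones(40), np.zeros(40)]
        mean, _, _ = evaluate_auc([X], [y], reps=5, trees=50, seed=1)
        assert 0.25 < mean < 0.75

    def test_invalid_split_rejected(self, rng):
        X = pd.DataFrame({"v": rng.normal(size=10)})
        y = np.r_[np.ones(5), np.zeros(5)]
        with pytest.raises(ValueError):
            evaluate_auc([X], [y], split=1.5)


class TestPartialDependence:
    def test_monotone_response_recovered(self, rng):
        x = np.concatenate([rng.normal(2, 0.4, 40), rng.normal(-2, 0.4, 40)])
        X = pd.DataFrame({"v": x, "noise": rng.normal(size=80)})
        y = np.r_[np.ones(40), np.zeros(40)]
        member = mir_model_selection(X, y, trees=100, seed=3)
        pd_curve = partial_dependence([member], "v", grid_points=20)
        assert list(pd_curve.columns[:2]) == ["value", "model_1"]
        assert {"mean", "lo", "hi"} <= set(pd_curve.columns)
        assert pd_curve["mean"].iloc[-1] > pd_curve["mean"].iloc[0] + 0.5
        assert (pd_curve["lo"] <= pd_curve["mean"]).all()
        assert (pd_curve["hi"] >= pd_curve["mean"]).all()

    def test_unknown_variable_rejected(self, rng):
        x = np.concatenate([rng.normal(2, 0.4, 20), rng.normal(-2, 0.4, 20)])
        X = pd.DataFrame({"v": x})
        y = np.r_[np.ones(20), np.zeros(20)]
        member = mir_model_selection(X, y, trees=30, seed=0)
        with pytest.raises(KeyError):
            partial_dependence([member], "absent")


class TestModelResultsApi:
    def test_fit_predict_summary(self, rng):
        stack = _two_scale_stack(rng)
        pres, absn = _points(stack, rng, n_pts=20)
        absn2 = absn.copy()
        absn2["y"] = absn2["y"].iloc[::-1].to_numpy()
        model = HabitatSelectionModel(pres, [absn, absn2], stack, trees=60)
        res = model.fit(seed=7)
        assert len(res.members) == 2
        assert res.scale_profile.chosen["A"] in (1000, 2000)
        surface = res.predict()
        assert surface.shape == stack.template.shape
        assert np.nanmax(surface.values) <= 1.0
        mean, sd = res.evaluate_auc(reps=2)
        assert mean > 0.8                      # spatially separable by design
        text = res.summary()
        assert "Optimal scales" in text and "OOB" in text and "AUC" in text

    def test_fit_is_seed_deterministic(self, rng):
        stack = _two_scale_stack(rng)
        pres, absn = _points(stack, rng, n_pts=15)
        model = HabitatSelectionModel(pres, [absn], stack, trees=40)
        a = model.fit(seed=3).predict().values
        b = model.fit(seed=3).predict().values
        assert np.array_equal(a, b, equal_nan=True)

    def test_mismatched_absence_count_rejected(self, rng):
        stack = _two_scale_stack(rng)
        pres, absn = _points(stack, rng, n_pts=15)
        with pytest.raises(ValueError):
            HabitatSelectionModel(pres, [absn.iloc[:-1]], stack)
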