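"""Fusion weighting, age gating and stacking behaviour."""

import numpy as np
import pytest
from scipy.special import expit, logit

from conftest import make_card, make_dataset
from riskfusion import metrics
from riskfusion.ensembles import (
    ApplicationContext,
    WeightVector,
    age_mixture_gate,
    apply_age_mixture,
    apply_fusion,
    compute_fusion_weights,
    fit_stacking,
    member_predictions,
    predict_stacking,
)
from riskfusion.exceptions import AlignmentError, DegenerateWeightsError, NoEventsError


def ctx(mean_age=50.0, feature_means=None, ages=None):
    return ApplicationContext(
        feature_means=feature_means or {}, mean_age=mean_age,
        patient_ages=None if ages is None else np.asarray(ages, float),
    )


class TestFusionWeights:
    def test_auc1_scales_relative_to_half(self):
        cards = [make_card(f"db{i}", auroc=a) for i, a in enumerate((0.75, 0.65, 0.55))]
        w = compute_fusion_weights("auc1", cards)
        assert w.weights["db0"] == pytest.approx(5 / 9)
        assert w.weights["db1"] == pytest.approx(3 / 9)
        assert w.weights["db2"] == pytest.approx(1 / 9)

    @pytest.mark.parametrize("auroc,expected", [(0.75, 0.5), (0.5, 0.0), (1.0, 1.0)])
    def test_auc2_unnormalized(self, auroc, expected):
        cards = [make_card("db0", auroc=auroc), make_card("db1", auroc=0.6)]
        w = compute_fusion_weights("auc2", cards)
        assert w.weights["db0"] == pytest.approx(expected)

    def test_age_inverse_distance(self):
        cards = [make_card("db0", dev_mean_age=41.0), make_card("db1", dev_mean_age=75.0)]
        w = compute_fusion_weights("age", cards, ctx(mean_age=41.0))
        # unnormalized (1, 1/35) -> (35/36, 1/36)
        assert w.weights["db0"] == pytest.approx(35 / 36)
        assert w.weights["db1"] == pytest.approx(1 / 36)

    def test_sim_cosine_selects_matching_population(self):
        cards = [
            make_card("db0", dev_feature_means={"feat_000": 1.0, "feat_001": 0.0},
                      coefficients=[1.0, 1.0]),
            make_card("db1", dev_feature_means={"feat_000": 0.0, "feat_001": 1.0},
                      coefficients=[1.0, 1.0]),
        ]
        c = ctx(feature_means={"feat_000": 1.0, "feat_001": 0.0})
        w = compute_fusion_weights("sim", cards, c)
        assert w.weights["db0"] == pytest.approx(1.0)
        assert w.weights["db1"] == pytest.approx(0.0, abs=1e-12)

    def test_mean_uniform(self):
        cards = [make_card(f"db{i}") for i in range(4)]
        w = compute_fusion_weights("mean", cards)
        assert all(v == pytest.approx(0.25) for v in w.weights.values())

    @pytest.mark.parametrize("scheme", ["mean", "auc1", "sim", "age"])
    def test_normalized_schemes_sum_to_one(self, scheme):
        cards = [
            make_card(f"db{i}", auroc=0.55 + 0.05 * i, dev_mean_age=40.0 + 10 * i,
                      dev_feature_means={"feat_000": 0.2 + 0.1 * i, "feat_001": 0.5})
            for i in range(4)
        ]
        c = ctx(mean_age=52.0, feature_means={"feat_000": 0.4, "feat_001": 0.5})
        w = compute_fusion_weights(scheme, cards, c)
        assert sum(w.weights.values()) == pytest.approx(1.0, abs=1e-9)

    def test_auc1_permutation_equivariant(self):
        cards = [make_card(f"db{i}", auroc=a) for i, a in enumerate((0.8, 0.6, 0.7))]
        w1 = compute_fusion_weights("auc1", cards)
        w2 = compute_fusion_weights("auc1", cards[::-1])
        assert w1.weights == w2.weights

    def test_all_uninformative_members_degenerate(self):
        cards = [make_card("db0", auroc=0.5), make_card("db1", auroc=0.5)]
        with pytest.raises(DegenerateWeightsError) as exc:
            compute_fusion_weights("auc1", cards)
        assert exc.value.fallback.weights == {"db0": 0.5, "db1": 0.5}

    def test_sim_scale_invariance(self):
        base = {"feat_000": 0.2, "feat_001": 0.4}
        cards = [
            make_card("db0", dev_feature_means=base, coefficients=[1.0, 1.0]),
            make_card("db1", dev_feature_means={"feat_000": 0.4, "feat_001": 0.1},
                      coefficients=[1.0, 1.0]),
        ]
        c1 = ctx(feature_means={"feat_000": 0.3, "feat_001": 0.3})
        w1 = compute_fusion_weights("sim", cards, c1)
        # scale both the application and development vectors by the same constant
        scaled_cards = [
            make_card("db0", dev_feature_means={k: v / 2 for k, v in base.items()},
                      coefficients=[1.0, 1.0]),
            make_card("db1", dev_feature_means={"feat_000": 0.2, "feat_001": 0.05},
                      coefficients=[1.0, 1.0]),
        ]
        c2 = ctx(feature_means={"feat_000": 0.15, "feat_001": 0.15})
        w2 = compute_fusion_weights("sim", scaled_cards, c2)
        for k in w1.weights:
            assert w1.weights[k] == pytest.approx(w2.weights[k])

    def test_requires_two_distinct_members(self):
        with pytest.raises(ValueError):
            compute_fusion_weights("mean", [make_card("db0")])
        with pytest.raises(ValueError):
            compute_fusion_weights("mean", [make_card("db0"), make_card("db0")])


class TestApplyFusion:
    def test_mean_of_two_members(self):
        w = WeightVector({"a": 0.5, "b": 0.5}, "mean")
        out = apply_fusion(w, {"a": np.array([0.2]), "b": np.array([0.4])})
        assert out[0] == pytest.approx(0.3)

    def test_point_mass_returns_member(self):
        w = WeightVector({"a": 1.0, "b": 0.0}, "mean")
        pa = np.array([0.1, 0.9, 0.5])
        out = apply_fusion(w, {"a": pa, "b": np.array([0.7, 0.7, 0.7])})
        assert np.array_equal(out, pa)

    def test_auc2_total_weight_changes_scale(self):
        both = {"a": np.array([0.9]), "b": np.array([0.9])}
        w1 = WeightVector({"a": 0.5, "b": 0.5}, "auc2")
        w2 = WeightVector({"a": 0.5, "b": 0.1}, "auc2")
        assert apply_fusion(w1, both)[0] == pytest.approx(0.9)
        assert apply_fusion(w2, both)[0] == pytest.approx(0.54)

    def test_key_mismatch_rejected(self):
        w = WeightVector({"a": 0.5, "b": 0.5}, "mean")
        with pytest.raises(AlignmentError):
            apply_fusion(w, {"a": np.array([0.2]), "c": np.array([0.4])})

    def test_identity_property_identical_members(self):
        members = {f"db{i}": np.array([0.12, 0.5, 0.9]) for i in range(3)}
        w = WeightVector({k: 1 / 3 for k in members}, "mean")
        assert np.allclose(apply_fusion(w, members), [0.12, 0.5, 0.9])


class TestAgeGate:
    def test_patient_aged_70_selects_75_model(self):
        cards = [make_card(f"db{i}", dev_mean_age=a)
                 for i, a in enumerate((41.0, 35.0, 75.0, 50.0))]
        gate, order = age_mixture_gate(cards, [70.0])
        assert order[int(np.argmax(gate[0]))] == "db2"

    def test_exact_match_selected(self):
        cards = [make_card("db0", dev_mean_age=41.0), make_card("db1", dev_mean_age=75.0)]
        gate, order = age_mixture_gate(cards, [75.0])
        assert order[int(np.argmax(gate[0]))] == "db1"

    def test_tie_broken_lexicographically(self):
        cards = [make_card("dbB", dev_mean_age=50.0), make_card("dbA", dev_mean_age=50.0)]
        gate, order = age_mixture_gate(cards, [60.0])
        assert order[int(np.argmax(gate[0]))] == "dbA"

    def test_rows_one_hot_and_prediction_matches_one_member(self):
        cards = [make_card(f"db{i}", dev_mean_age=a) for i, a in enumerate((30.0, 60.0))]
        ages = np.array([25.0, 44.0, 46.0, 80.0])
        gate, order = age_mixture_gate(cards, ages)
        assert np.array_equal(gate.sum(axis=1), np.ones(4))
        preds = {"db0": np.array([0.1, 0.2, 0.3, 0.4]), "db1": np.array([0.5, 0.6, 0.7, 0.8])}
        out = apply_age_mixture(cards, preds, ages)
        for i in range(4):
            assert out[i] in (preds["db0"][i], preds["db1"][i])
        assert np.allclose(out, [0.1, 0.2, 0.7, 0.8])

    def test_missing_ages_rejected(self):
        cards = [make_card("db0"), make_card("db1")]
        with pytest.raises(ValueError):
            age_mixture_gate(cards, None)


def _stacking_setup(n=2_000, seed=5, event_rate=0.3):
    ds = make_dataset(n=n, n_features=2, event_rate=event_rate, seed=seed)
    cards = [
        make_card("db0", coefficients=[0.8, 0.0], intercept=-1.0),
        make_card("db1", coefficients=[0.0, -0.5], intercept=-0.5),
    ]
    return ds, cards


class TestStacking:
    def test_constant_members_yield_event_rate(self):
        ds, _ = _stacking_setup(n=1_000, seed=9)
        cards = [
            make_card("db0", coefficients=[0.0, 0.0], intercept=0.0),
            make_card("db1", coefficients=[0.0, 0.0], intercept=0.0),
        ]
        stack = fit_stacking(cards, ds, n_labels=None, seed=0)
        preds = predict_stacking(stack, member_predictions(cards, ds.features))
        rate = ds.labels["y"].mean()
        assert np.allclose(preds, rate, atol=1e-6)

    def test_mle_zero_citl_on_fitting_sample(self):
        ds, cards = _stacking_setup()
        stack = fit_stacking(cards, ds, n_labels=None, seed=1)
        preds = predict_stacking(stack, member_predictions(cards, ds.features))
        sp = metrics.ScoredPredictions(preds, ds.labels["y"])
        assert abs(metrics.calibration_in_the_large(sp)) < 1e-8

    def test_informed_member_recovered(self):
        # one member already outputs the true generating risk; with many
        # labels the stacker should reproduce near-calibrated predictions
        rng = np.random.default_rng(17)
        n = 20_000
        import pandas as pd

        x = rng.integers(0, 2, size=(n, 2)).astype(np.uint8)
        p_true = expit(-1.5 + 1.2 * x[:, 0])
        y = (rng.random(n) < p_true).astype(np.uint8)
        from riskfusion.simdata import LabelledDataset

        ds = LabelledDataset(
            db_id="gen",
            features=pd.DataFrame(x, columns=["feat_000", "feat_001"]),
            age_years=np.full(n, 50.0),
            labels={"y": y},
        )
        cards = [
            make_card("oracle", coefficients=[1.2, 0.0], intercept=-1.5),
            make_card("noise", coefficients=[0.0, 0.1], intercept=-1.0),
        ]
        stack = fit_stacking(cards, ds, n_labels=None, seed=2)
        preds = predict_stacking(stack, member_predictions(cards, ds.features))
        # predictions track the generating risks closely
        assert np.max(np.abs(preds - p_true)) < 0.05
        assert abs(stack.coefficients["noise"]) < abs(stack.coefficients["oracle"])

    def test_subsample_seeded_and_sized(self):
        ds, cards = _stacking_setup()
        a = fit_stacking(cards, ds, n_labels=500, seed=3)
        b = fit_stacking(cards, ds, n_labels=500, seed=3)
        assert a.coefficients == b.coefficients
        assert a.n_labels_used == 500

    def test_no_events_in_subsample(self):
        ds, cards = _stacking_setup(event_rate=0.0)
        ds.labels["y"][-1] = 1  # one event, never sampled below
        with pytest.raises(NoEventsError):
            fit_stacking(cards, ds, n_labels=100, seed=0)

    def test_budget_exceeding_sample_rejected(self):
        ds, cards = _stacking_setup(n=300)
        with pytest.raises(ValueError):
            fit_stacking(cards, ds, n_labels=301, seed=0)


class TestPredictStacking:
    def test_zero_model_predicts_half(self):
        from riskfusion.ensembles import StackingModel

        stack = StackingModel({"a": 0.0, "b": 0.0}, intercept=0.0, n_labels_used=10)
        out = predict_stacking(stack, {"a": np.array([0.2]), "b": np.array([0.9])})
        assert out[0] == pytest.approx(0.5)

    def test_intercept_only_rate(self):
        from riskfusion.ensembles import StackingModel

        stack = StackingModel({"a": 0.0}, intercept=float(logit(0.03)), n_labels_used=10)
        out = predict_stacking(stack, {"a": np.array([0.1, 0.9])})
        assert np.allclose(out, 0.03)

    def test_round_trip_consistency(self):
        ds, cards = _stacking_setup()
        stack = fit_stacking(cards, ds, n_labels=800, seed=4)
        preds = member_predictions(cards, ds.features)
        p1 = predict_stacking(stack, preds)
        p2 = predict_stacking(stack, preds)
        assert np.array_equal(p1, p2)
        assert np.all((p1 > 0) & (p1 < 1))
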