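import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from staplr.data import ViewHierarchy, make_folds
from staplr.glm import PenaltySpec
from staplr.stacking import (
    PredictionMatrix,
    StackedClassifier,
    StaplrConfig,
    coefficient_table,
    cross_validated_predictions,
    fit_staplr,
    predict_stacked,
)
from staplr.synthetic import SyntheticConfig, generate_dataset, three_scan_type_preset

NNL = PenaltySpec(alpha=1.0, nonnegative=True, standardize=False)


class TestCrossValidatedPredictions:
    def test_range_and_length(self, tiny_dataset):
        ds, _, _ = tiny_dataset
        plan = make_folds(ds.y, 5, seed=0)
        z = cross_validated_predictions(
            ds.view_matrix("v1"), ds.y.astype(float), PenaltySpec(alpha=0.0), plan,
            lambda_folds=3, n_lambda=15, seed=1,
        )
        assert z.shape == (ds.n_subjects,)
        assert np.all((z >= 0) & (z <= 1))

    def test_held_out_labels_cannot_influence_own_predictions(self, tiny_dataset):
        """Shuffling the held-out fold's outcomes must leave that fold's
        predictions unchanged (the out-of-sample contract of stacking)."""
        ds, _, _ = tiny_dataset
        X = ds.view_matrix("v1")
        y = ds.y.astype(float)
        plan = make_folds(ds.y, 4, seed=3)
        z = cross_validated_predictions(X, y, PenaltySpec(alpha=0.0), plan,
                                        lambda_folds=3, n_lambda=10, seed=2)
        rng = np.random.default_rng(0)
        for f in range(4):
            y_mod = y.copy()
            te = plan.test_rows(f)
            y_mod[te] = rng.permutation(y_mod[te])
            z_mod = cross_validated_predictions(X, y_mod, PenaltySpec(alpha=0.0), plan,
                                                lambda_folds=3, n_lambda=10, seed=2)
            np.testing.assert_array_equal(z[te], z_mod[te])

    def test_intercept_only_learner_predicts_training_prevalence(self):
        """A constant feature forces the null model, so each fold's prediction
        equals the class-1 proportion of the other folds."""
        y = np.array([0] * 12 + [1] * 8, dtype=float)
        X = np.ones((20, 1))
        plan = make_folds(y.astype(int), 4, seed=5)
        z = cross_validated_predictions(X, y, PenaltySpec(alpha=0.0), plan,
                                        lambda_folds=2, n_lambda=5, seed=0)
        for f in range(4):
            expected = y[plan.train_rows(f)].mean()
            np.testing.assert_allclose(z[plan.test_rows(f)], expected, atol=1e-6)


class TestFitStaplr:
    def test_three_scan_type_preset_structure(self):
        """The 3-branch / 5+4+31-leaf hierarchy yields exactly 40 base models,
        3 intermediate combiners and 1 meta model."""
        cfg = three_scan_type_preset(n_subjects=100, seed=3)
        ds, h, _ = generate_dataset(cfg)
        widths = [len(ds.view_columns(v)) for v in h.leaves]
        assert len(h.leaves) == 40 and min(widths) == 5
        model = fit_staplr(ds, h, StaplrConfig(prediction_folds=3, lambda_folds=3, n_lambda=15, seed=1))
        assert len(model.base_models) == 40
        assert len(model.node_models) == 4  # 3 intermediate + meta
        assert coefficient_table(model, "meta").shape[0] == 3
        assert coefficient_table(model, "intermediate").shape[0] == 40
        assert (coefficient_table(model, "all").query("level != 'base'")["coefficient"] >= 0).all()

    def test_depth_two_reduces_to_single_combiner(self, fast_staplr_config):
        cfg = SyntheticConfig(
            n_subjects=70, views={"v1": 4, "v2": 3, "v3": 5},
            signal_views=("v1",), effect_size=2.0, seed=4,
        )
        ds, h, _ = generate_dataset(cfg)
        assert h.depth == 2
        model = fit_staplr(ds, h, fast_staplr_config)
        assert list(model.node_models) == ["root"]
        assert model.node_models["root"].coefficients.shape == (3,)

    def test_determinism_bitwise(self, tiny_dataset, fast_staplr_config):
        ds, h, _ = tiny_dataset
        t1 = coefficient_table(fit_staplr(ds, h, fast_staplr_config), "all")
        t2 = coefficient_table(fit_staplr(ds, h, fast_staplr_config), "all")
        pd.testing.assert_frame_equal(t1, t2)

    def test_mixed_depth_leaf_under_root(self, fast_staplr_config):
        cfg = SyntheticConfig(
            n_subjects=70, views={"a": {"v1": 4, "v2": 3}, "v3": 5},
            signal_views=("v1",), effect_size=2.0, seed=5,
        )
        ds, h, _ = generate_dataset(cfg)
        model = fit_staplr(ds, h, fast_staplr_config)
        assert model.node_models["root"].feature_names == ["a", "v3"]
        assert "v3" in model.base_models


class TestPredictStacked:
    def test_composition_matches_hand_evaluation(self, toy_depth3_model):
        m = toy_depth3_model
        rng = np.random.default_rng(0)
        X = rng.standard_normal((20, 6))
        cols = [f"{leaf}_f{j}" for leaf in ["v11", "v12", "v21"] for j in (1, 2)]
        frame = pd.DataFrame(X, columns=cols)
        out = predict_stacked(m, frame)
        for i in range(20):
            leaf_p = {
                leaf: expit(m.base_models[leaf].intercept
                            + frame.loc[i, [f"{leaf}_f1", f"{leaf}_f2"]].to_numpy(dtype=float)
                            @ m.base_models[leaf].coefficients)
                for leaf in ["v11", "v12", "v21"]
            }
            s1 = expit(-1.0 + 3.0 * leaf_p["v11"] + 1.0 * leaf_p["v12"])
            s2 = expit(-0.5 + 2.0 * leaf_p["v21"])
            manual = expit(-1.0 + 2.0 * s1 + 1.0 * s2)
            assert abs(out[i] - manual) < 1e-12

    def test_published_style_meta_weights_example(self, toy_depth3_model):
        """ψ(ω̂0 + Σ ω̂s·z_s) with weights (5.12, 1.02, 1.25), intercept −4 and
        branch outputs (0.9, 0.5, 0.5) gives ψ(1.743) ≈ 0.8511."""
        z = np.array([0.9, 0.5, 0.5])
        w = np.array([5.12, 1.02, 1.25])
        val = expit(-4.0 + w @ z)
        assert val == pytest.approx(0.85108, abs=1e-4)

    def test_all_zero_slopes_give_constant_output(self, toy_depth3_model):
        m = toy_depth3_model
        for node in m.node_models.values():
            node.coefficients = np.zeros_like(node.coefficients)
        X = pd.DataFrame(np.random.default_rng(1).standard_normal((5, 6)),
                         columns=[f"{l}_f{j}" for l in ["v11", "v12", "v21"] for j in (1, 2)])
        np.testing.assert_allclose(predict_stacked(m, X), expit(-1.0), atol=1e-14)

    def test_monotone_in_any_leaf_output_under_nonnegative_weights(self, toy_depth3_model):
        m = toy_depth3_model
        X = pd.DataFrame(np.zeros((1, 6)),
                         columns=[f"{l}_f{j}" for l in ["v11", "v12", "v21"] for j in (1, 2)])
        base = predict_stacked(m, X)[0]
        # raising v11's own prediction (via its positive feature) cannot lower the output
        X2 = X.copy()
        X2.loc[0, "v11_f1"] = 3.0
        assert predict_stacked(m, X2)[0] >= base

    def test_zero_coefficient_child_is_inert(self, tiny_dataset, fast_staplr_config):
        """A child whose combiner coefficient is 0 contributes nothing: its
        feature block can be scrambled without changing predictions."""
        ds, h, _ = tiny_dataset
        model = fit_staplr(ds, h, fast_staplr_config)
        table = coefficient_table(model, "all").query("level != 'base'")
        zero_leaves = [
            r["child"] for _, r in table.iterrows()
            if r["coefficient"] == 0.0 and r["child"] in h.leaves
        ]
        if not zero_leaves:
            pytest.skip("no zero-coefficient leaf in this fit")
        leaf = zero_leaves[0]
        frame = ds.to_frame().drop(columns="outcome")
        base = predict_stacked(model, frame)
        scrambled = frame.copy()
        scrambled[ds.view_feature_ids(leaf)] = np.random.default_rng(0).standard_normal(
            (len(frame), len(ds.view_feature_ids(leaf)))
        )
        # identical up to BLAS summation-order noise from the frame copy
        np.testing.assert_allclose(predict_stacked(model, scrambled), base, atol=1e-12)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, tiny_dataset, fast_staplr_config, tmp_path):
        ds, h, _ = tiny_dataset
        model = fit_staplr(ds, h, fast_staplr_config)
        model.save(tmp_path / "m.json")
        back = StackedClassifier.load(tmp_path / "m.json")
        frame = ds.to_frame().drop(columns="outcome")
        np.testing.assert_allclose(predict_stacked(back, frame), predict_stacked(model, frame), atol=1e-15)
        assert back.ybar == model.ybar
        assert set(back.cv_predictions) == set(model.cv_predictions)


def test_prediction_matrix_validates_range():
    with pytest.raises(ValueError, match=r"\[0, 1\]"):
        PredictionMatrix("root", ["a"], np.array([[1.2]]))
    with pytest.raises(ValueError, match="one column per child"):
        PredictionMatrix("root", ["a", "b"], np.ones((3, 1)))
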