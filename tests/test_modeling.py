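import logging

import numpy as np
import pytest
from sklearn.naive_bayes import GaussianNB

from frailwear import ModelSpec, grid_for, predict, train, tune
from frailwear.errors import ConfigurationError, ContractError
from frailwear.modeling import NaiveBayes, build_estimator, load_model, save_model

from conftest import matrix_from_arrays


def _gaussian_matrix(n_per_class=30, spread=0.3, seed=0, n_features=4):
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for i, cls in enumerate(("non-frail", "pre-frail", "frail")):
        centre = np.full(n_features, 3.0 * i)
        blocks.append(rng.normal(centre, spread, size=(n_per_class, n_features)))
        labels += [cls] * n_per_class
    return matrix_from_arrays(np.vstack(blocks), labels)


class TestGrids:
    def test_knn_grid_odd_k_up_to_sqrt_rows(self):
        ks = [s.params["k"] for s in grid_for("knn", 100)]
        assert ks == [1, 3, 5, 7, 9]

    def test_svm_grid_is_full_product_of_48(self):
        grid = grid_for("svm", 100)
        assert len(grid) == 48
        assert len({(s.params["cost"], s.params["gamma"], s.params["kernel"])
                    for s in grid}) == 48

    def test_rf_grid_is_15(self):
        assert len(grid_for("rf", 100)) == 15

    def test_nb_grid_is_4(self):
        assert len(grid_for("nb", 100)) == 4

    def test_tiny_n_still_offers_k_1(self):
        assert [s.params["k"] for s in grid_for("knn", 1)] == [1]

    def test_unknown_algorithm_rejected(self):
        with pytest.raises(ConfigurationError):
            grid_for("mlp", 100)

    def test_even_k_rejected(self):
        with pytest.raises(ConfigurationError):
            ModelSpec("knn", {"k": 4})


class TestTrainPredict:
    def test_1nn_resubstitution_is_perfect(self, small_matrix):
        model = train(small_matrix, ModelSpec("knn", {"k": 1}), seed=0)
        preds = predict(model, small_matrix)
        assert (preds == small_matrix.y).all()

    @pytest.mark.parametrize("algorithm", ["knn", "svm", "rf", "nb"])
    def test_separable_gaussians_tuned_heldout_accuracy(self, algorithm):
        train_m = _gaussian_matrix(n_per_class=20, seed=0)
        test_m = _gaussian_matrix(n_per_class=10, seed=99)
        spec = tune(train_m, algorithm, k=5, seed=0)
        model = train(train_m, spec, seed=0)
        acc = (predict(model, test_m) == test_m.y).mean()
        assert acc > 0.95

    def test_feature_name_mismatch_rejected(self, small_matrix):
        model = train(small_matrix, ModelSpec("knn", {"k": 1}), seed=0)
        other = small_matrix.select_features(small_matrix.feature_names[:10])
        with pytest.raises(ContractError):
            predict(model, other)

    def test_persistence_roundtrip_identical_predictions(self, small_matrix, tmp_path):
        model = train(small_matrix, ModelSpec("rf", {"n_trees": 50, "n_vars_sampled": 10}),
                      seed=0)
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        np.testing.assert_array_equal(predict(back, small_matrix),
                                      predict(model, small_matrix))
        assert back.spec == model.spec

    def test_rf_vars_sampled_clamped_to_feature_count(self):
        m = _gaussian_matrix(n_per_class=10, n_features=3)
        model = train(m, ModelSpec("rf", {"n_trees": 20, "n_vars_sampled": 50}), seed=0)
        assert model.estimator.max_features == 3


class TestTune:
    def test_singleton_grid_returned(self):
        m = _gaussian_matrix(n_per_class=10)
        spec = tune(m, "nb", k=5, seed=0)
        assert spec.algorithm == "nb"

    def test_separable_data_small_k_near_perfect(self):
        m = _gaussian_matrix(n_per_class=30, spread=0.1)
        spec = tune(m, "knn", k=5, seed=0)
        assert spec.params["k"] <= 5

    def test_deterministic_given_seed(self):
        m = _gaussian_matrix(n_per_class=15)
        assert tune(m, "knn", k=5, seed=4) == tune(m, "knn", k=5, seed=4)

    def test_class_smaller_than_k_advises_stratification(self):
        m = _gaussian_matrix(n_per_class=3)
        from frailwear.errors import StratificationError
        with pytest.raises(StratificationError, match="[Ss]tratification"):
            tune(m, "knn", k=5, seed=0)


class TestNaiveBayes:
    def test_plain_variant_matches_sklearn_gaussian_nb(self):
        m = _gaussian_matrix(n_per_class=25, seed=3)
        ours = NaiveBayes(use_kernel=False, use_poisson=False).fit(m.X, m.y)
        theirs = GaussianNB(var_smoothing=1e-9).fit(m.X, m.y)
        agree = (ours.predict(m.X) == theirs.predict(m.X)).mean()
        assert agree > 0.98

    def test_poisson_honoured_only_for_integer_features(self, caplog):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.poisson(5, 60).astype(float), rng.normal(size=60)])
        y = np.array(["frail", "non-frail"])[np.arange(60) % 2]
        with caplog.at_level(logging.WARNING, logger="frailwear.modeling"):
            nb = NaiveBayes(use_poisson=True).fit(X, y)
        assert list(nb._poisson_ok) == [True, False]
        assert any("use_poisson ignored" in r.message for r in caplog.records)
        assert len(nb.predict(X)) == 60

    def test_kernel_variant_separates_bimodal_class(self):
        # one class is a symmetric two-mode mixture: a single Gaussian sees
        # the wrong (inflated) density at the centre, a KDE does not
        rng = np.random.default_rng(1)
        a = np.concatenate([rng.normal(-4, 0.3, 100), rng.normal(4, 0.3, 100)])
        b = rng.normal(0, 0.5, 200)
        X = np.concatenate([a, b])[:, None]
        y = np.array(["frail"] * 200 + ["non-frail"] * 200)
        kde_nb = NaiveBayes(use_kernel=True).fit(X, y)
        acc = (kde_nb.predict(X) == y).mean()
        assert acc > 0.95


class TestScalingIsolation:
    def test_scaler_fit_on_training_fold_only(self):
        # manual 2-fold CV: a sentinel outlier in the held-out fold must not
        # influence the scaler fitted on the training fold
        from frailwear.evaluation import cross_validate
        from frailwear.features import FeatureMatrix

        m = _gaussian_matrix(n_per_class=10, seed=5)
        rec = m.records.copy()
        rec.loc[len(rec) - 1, m.feature_names] = 1e6  # sentinel in fold 1
        m_out = FeatureMatrix(rec, m.feature_names)
        folds = np.array([0, 1] * (len(rec) // 2))
        spec = ModelSpec("knn", {"k": 1})
        report = cross_validate(m_out, spec, seed=0, folds=folds)

        # oracle: fit scaler+1NN on fold 0 only, predict fold 1
        est = build_estimator(spec, n_features=len(m.feature_names), seed=0)
        tr, te = folds == 0, folds == 1
        est.fit(m_out.X[tr], m_out.y[tr])
        expected = est.predict(m_out.X[te])
        got_conf = report.confusion.to_numpy().sum()
        assert got_conf == len(rec)
        # training-fold scaler stats equal the training fold's own moments
        np.testing.assert_allclose(est.named_steps["scale"].mean_,
                                   m_out.X[tr].mean(axis=0), rtol=1e-12)
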