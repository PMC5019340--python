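"""The penalized classifier: solver correctness, path, CV, prediction, weights."""

import numpy as np
import pytest

from desilasso import _solver
from desilasso.io import CLASSES, MassAxis, MSISample
from desilasso.model import MultinomialLassoClassifier
from desilasso.preprocess import bin_features
from desilasso.synthetic import (
    NoiseModel,
    SyntheticCohortConfig,
    banded_layout,
    generate_cohort,
)
from desilasso.experiments import cohort_feature_arrays


def _toy_problem(rng, n=60, p=5, K=3, spread=2.0):
    X = rng.normal(size=(n, p))
    beta = spread * rng.normal(size=(p, K))
    Z = X @ beta
    P = np.exp(Z - Z.max(axis=1, keepdims=True))
    P /= P.sum(axis=1, keepdims=True)
    y = np.array([rng.choice(K, p=row) for row in P])
    labels = np.array([f"c{k}" for k in y], dtype=object)
    return X, labels


@pytest.fixture(scope="module")
def small_cohort_model():
    """A small synthetic cohort pooled into a fitted-ready classifier."""
    axis = MassAxis(np.linspace(100.0, 160.0, 360))
    from desilasso.synthetic import ClassProfile, Peak

    profiles = {
        "cancer": ClassProfile("cancer", (Peak(110.0, 1.0), Peak(130.0, 0.7))),
        "glands": ClassProfile("glands", (Peak(120.0, 1.0), Peak(150.0, 0.5))),
        "stroma": ClassProfile("stroma", (Peak(140.0, 0.8), Peak(120.0, 0.4)),
                               total_abundance_scale=0.5),
    }
    layout = banded_layout((10, 10), {"glands": 0.5, "cancer": 0.3, "stroma": 0.2})
    cfg = SyntheticCohortConfig(
        n_patients=4, layouts=[layout], seed=5, axis=axis, profiles=profiles,
        noise=NoiseModel(multiplicative_cv=0.2, baseline_level=0.5,
                         patient_effect_sd=0.1),
    )
    cohort, _ = generate_cohort(cfg)
    fm, labels, groups = cohort_feature_arrays(cohort)
    model = MultinomialLassoClassifier(fm, labels, groups=groups)
    planted = {
        "cancer": {110.0, 130.0},
        "glands": {150.0},  # 120 is shared with stroma
        "stroma": {140.0},
    }
    return model, planted


class TestPenaltySaturation:
    def test_lambda_max_gives_zero_weights_and_prior_probs(self, rng):
        X, labels = _toy_problem(rng)
        model = MultinomialLassoClassifier(X, labels)
        fit = model.fit(model.lambda_max * 1.5)
        assert fit.nonzero_count == 0
        probs = fit.predict(X).probabilities
        freqs = np.array([(labels == c).mean() for c in model.classes])
        assert np.allclose(probs, freqs[None, :], atol=1e-6)

    def test_objective_not_worse_than_zero_model(self, rng):
        X, labels = _toy_problem(rng)
        model = MultinomialLassoClassifier(X, labels)
        lam = 0.3 * model.lambda_max
        fit = model.fit(lam)
        Y = model.Y
        zero_obj = _solver.objective(
            X, Y, np.zeros_like(fit.weights), _solver.null_intercepts(Y),
            lam, model.mean_, model.scale_,
        )
        assert fit.objective_value() <= zero_obj + 1e-12

    def test_separable_toy_perfect_training_accuracy(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
        labels = np.array(["a", "a", "b", "b"], dtype=object)
        model = MultinomialLassoClassifier(X, labels)
        fit = model.fit(1e-4 * model.lambda_max)
        assert (fit.predict(X).labels == labels).all()


class TestSolverCorrectness:
    def test_matches_convex_oracle_and_kkt(self, rng):
        for _ in range(5):
            X, labels = _toy_problem(rng, n=40, p=4)
            model = MultinomialLassoClassifier(X, labels)
            lam = float(rng.uniform(0.05, 0.5)) * model.lambda_max
            fit = model.fit(lam, tol=1e-9)
            _, _, obj_oracle = _solver.oracle_fit(
                X, model.Y, lam, model.mean_, model.scale_
            )
            assert fit.objective_value() <= obj_oracle * (1 + 1e-6)
            assert fit.kkt_violation() <= 1e-5

    def test_screening_agrees_with_direct_solve(self, rng):
        # wide problem so the working-set path actually engages
        X = rng.normal(size=(80, 300))
        beta = np.zeros((300, 3))
        beta[:4] = 3.0 * rng.normal(size=(4, 3))
        y = np.argmax(X @ beta + rng.normal(size=(80, 3)), axis=1)
        labels = np.array([CLASSES[k] for k in y], dtype=object)
        model = MultinomialLassoClassifier(X, labels)
        lam = 0.2 * model.lambda_max
        f_screen = model.fit(lam, tol=1e-9, screen=True)
        f_direct = model.fit(lam, tol=1e-9, screen=False)
        assert f_screen.objective_value() == pytest.approx(
            f_direct.objective_value(), rel=1e-6
        )

    def test_feature_permutation_equivariance(self, rng):
        X, labels = _toy_problem(rng, n=50, p=6)
        model = MultinomialLassoClassifier(X, labels)
        lam = 0.2 * model.lambda_max
        W = model.fit(lam, tol=1e-9).weights
        perm = rng.permutation(6)
        W_perm = MultinomialLassoClassifier(X[:, perm], labels).fit(
            lam, tol=1e-9
        ).weights
        assert np.allclose(W_perm, W[perm], atol=1e-6)

    def test_single_class_rejected(self):
        X = np.ones((5, 2))
        with pytest.raises(ValueError, match="degenerate|two classes"):
            MultinomialLassoClassifier(X, np.array(["a"] * 5, dtype=object))

    def test_non_finite_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            MultinomialLassoClassifier(X, np.array(["a", "a", "b", "b"], dtype=object))


class TestPath:
    def test_first_model_all_zero_and_sparsity_grows(self, small_cohort_model):
        model, _ = small_cohort_model
        path = model.fit_path(n_lambdas=12, lambda_min_ratio=1e-3)
        counts = path.nonzero_counts()
        assert counts[0] == 0
        # monotone up to tolerance-level violations
        assert np.all(np.diff(counts) >= -1)
        assert counts[-1] > 0

    def test_planted_bins_enter_before_null_bins(self, small_cohort_model):
        model, planted = small_cohort_model
        path = model.fit_path(n_lambdas=12, lambda_min_ratio=1e-3)
        mid = next(f for f in path.fits if 0 < f.nonzero_count <= 8)
        tbl = mid.weight_table()
        planted_mz = sorted(set().union(*planted.values()))
        for mz in tbl["mz"]:
            assert any(abs(mz - p) < 0.6 for p in planted_mz), (
                f"feature {mz} selected early but no peak was planted there"
            )

    def test_warm_and_cold_fits_agree(self, small_cohort_model):
        model, _ = small_cohort_model
        path = model.fit_path(n_lambdas=6, lambda_min_ratio=1e-2, tol=1e-8)
        lam = path.lambdas[-1]
        cold = model.fit(lam, tol=1e-8)
        assert path.fits[-1].objective_value() == pytest.approx(
            cold.objective_value(), rel=1e-6
        )


class TestCrossValidation:
    def test_one_fold_per_patient(self, small_cohort_model):
        model, _ = small_cohort_model
        cv = model.fit_cv(n_lambdas=6, lambda_min_ratio=1e-2)
        assert cv.n_folds == len(set(model.groups))
        assert set(cv.fold_patients) == set(model.groups)
        # fold sizes sum to the pixel count
        assert int(cv.fold_sizes.sum()) == len(model.labels)

    def test_single_lambda_grid_is_chosen(self, small_cohort_model):
        model, _ = small_cohort_model
        cv = model.fit_cv(lambdas=[0.01])
        assert cv.chosen_lambda == pytest.approx(0.01)

    def test_tie_breaks_to_larger_lambda(self, rng):
        # a strongly separable problem where several penalties reach zero errors
        X = np.vstack([rng.normal(0, 0.1, (30, 3)) + [5, 0, 0],
                       rng.normal(0, 0.1, (30, 3)) + [0, 5, 0]])
        labels = np.array(["a"] * 30 + ["b"] * 30, dtype=object)
        groups = np.tile(np.repeat(["p1", "p2", "p3"], 10), 2)
        model = MultinomialLassoClassifier(X, labels, groups=groups)
        cv = model.fit_cv(n_lambdas=8, lambda_min_ratio=1e-3)
        zero_lams = cv.lambdas[cv.total_errors == cv.total_errors.min()]
        assert cv.chosen_lambda == pytest.approx(zero_lams.max())

    def test_requires_groups(self, rng):
        X, labels = _toy_problem(rng)
        with pytest.raises(ValueError, match="groups"):
            MultinomialLassoClassifier(X, labels).fit_cv()

    def test_grouped_cv_is_not_optimistic(self):
        """With strong patient effects, patient-grouped CV error at small
        penalty is at least the error of pixel-random fold assignment."""
        axis = MassAxis(np.linspace(100.0, 120.0, 120))
        from desilasso.synthetic import ClassProfile, Peak

        profiles = {
            "cancer": ClassProfile("cancer", (Peak(104.0, 1.0),)),
            "glands": ClassProfile("glands", (Peak(110.0, 1.0),)),
            "stroma": ClassProfile("stroma", (Peak(116.0, 1.0),), total_abundance_scale=0.6),
        }
        layout = banded_layout((8, 8), {"glands": 0.4, "cancer": 0.3, "stroma": 0.3})
        cfg = SyntheticCohortConfig(
            n_patients=6, layouts=[layout], seed=17, axis=axis, profiles=profiles,
            noise=NoiseModel(multiplicative_cv=0.5, baseline_level=1.0,
                             patient_effect_sd=0.8),
        )
        cohort, _ = generate_cohort(cfg)
        fm, labels, groups = cohort_feature_arrays(cohort)
        lambdas = [1e-3]
        grouped = MultinomialLassoClassifier(fm, labels, groups=groups).fit_cv(
            lambdas=lambdas
        )
        rng = np.random.default_rng(0)
        random_groups = groups[rng.permutation(len(groups))]
        random_cv = MultinomialLassoClassifier(fm, labels, groups=random_groups).fit_cv(
            lambdas=lambdas
        )
        assert grouped.total_errors[0] >= random_cv.total_errors[0]


class TestPrediction:
    def test_probabilities_sum_to_one(self, small_cohort_model):
        model, _ = small_cohort_model
        fit = model.fit(0.05 * model.lambda_max)
        probs = fit.predict(model.X).probabilities
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-12)
        assert (probs >= 0).all()

    def test_dimension_mismatch(self, small_cohort_model):
        model, _ = small_cohort_model
        fit = model.fit(model.lambda_max)
        with pytest.raises(ValueError, match="feature count"):
            fit.predict(np.ones((3, 7)))

    def test_equal_probabilities_break_to_first_class(self, rng):
        X = rng.normal(size=(40, 3))
        labels = np.array((["cancer", "glands"] * 20), dtype=object)
        model = MultinomialLassoClassifier(X, labels)
        fit = model.fit(model.lambda_max * 2)  # zero weights, equal priors
        assert (fit.predict(X).labels == "cancer").all()


class TestWeightTable:
    def test_zero_model_empty_table(self, small_cohort_model):
        model, _ = small_cohort_model
        fit = model.fit(model.lambda_max)
        assert len(fit.weight_table()) == 0

    def test_row_count_equals_nonzero_features(self, small_cohort_model):
        model, _ = small_cohort_model
        fit = model.fit(0.1 * model.lambda_max)
        tbl = fit.weight_table()
        assert len(tbl) == fit.nonzero_count > 0
        assert (np.diff(tbl["mz"]) > 0).all()

    def test_planted_bins_have_expected_signs(self, small_cohort_model):
        """An ion abundant in a class gets a positive weight for that class."""
        model, planted = small_cohort_model
        fit = model.fit(0.05 * model.lambda_max)
        tbl = fit.weight_table()
        for cls, mzs in planted.items():
            for mz in mzs:
                rows = tbl[np.abs(tbl["mz"] - mz) < 0.6]
                assert len(rows), f"planted {cls} bin at {mz} not selected"
                assert rows[cls].max() > 0, f"{cls} weight at {mz} not positive"

    def test_summary_mentions_key_facts(self, small_cohort_model):
        model, _ = small_cohort_model
        fit = model.fit(0.1 * model.lambda_max)
        text = fit.summary()
        assert "lambda" in text and "cancer" in text
        assert str(model.X.shape[1]) in text
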