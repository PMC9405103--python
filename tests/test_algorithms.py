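"""Adapter layer: envelope, distance, density and classifier scorers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichetransfer.algorithms import (
    ensemble_predict,
    fit_bioclim,
    fit_classifier,
    fit_domain,
    fit_kde,
    sample_background,
)
from nichetransfer.containers import SuitabilityMap
from nichetransfer.errors import DataError
from nichetransfer.evaluation_metrics import auc
from nichetransfer.synthetic_world import sample_occurrences, true_suitability
from nichetransfer.containers import VirtualSpeciesSpec
from tests.conftest import make_env


class TestBioclim:
    def test_median_vector_scores_one(self):
        X = np.column_stack([np.arange(1.0, 11.0), np.arange(11.0, 21.0)])
        model = fit_bioclim(X)
        assert model.predict([[5.5, 15.5]])[0] == pytest.approx(1.0)

    def test_outside_training_range_scores_zero(self):
        X = np.random.default_rng(0).random((20, 3))
        model = fit_bioclim(X)
        q = X[0].copy()
        q[1] = 2.0  # beyond max
        assert model.predict([q])[0] == 0.0

    def test_quarter_percentile_scores_half(self):
        X = np.column_stack([np.arange(1.0, 11.0), np.arange(1.0, 11.0)])
        model = fit_bioclim(X)
        # first variable at its 25th percentile (midpoint convention:
        # (2 + 0.5)/10), second at the median
        assert model.predict([[3.0, 5.5]])[0] == pytest.approx(0.5)

    def test_too_few_presences_raise(self):
        with pytest.raises(DataError):
            fit_bioclim(np.zeros((4, 2)))

    @settings(max_examples=25, derandomize=True)
    @given(shift=st.floats(-50, 50, allow_nan=False))
    def test_shift_invariance(self, shift):
        rng = np.random.default_rng(3)
        X = rng.random((15, 2))
        Q = rng.random((8, 2))
        base = fit_bioclim(X).predict(Q)
        shifted = fit_bioclim(X + [shift, 0.0]).predict(Q + [shift, 0.0])
        assert np.allclose(base, shifted, atol=1e-12)


class TestDomain:
    def test_training_presence_scores_one(self):
        X = np.random.default_rng(0).random((10, 3))
        assert fit_domain(X).predict([X[4]])[0] == pytest.approx(1.0)

    def test_hand_gower_example(self):
        X = np.array([[0.0, 0.0], [10.0, 2.0]])  # ranges (10, 2)
        model = fit_domain(X)
        # candidate (5, 1): mean(|5|/10, |1|/2) = 0.5 to either presence
        assert model.predict([[5.0, 1.0]])[0] == pytest.approx(0.5)

    def test_distance_beyond_one_clamps_to_zero(self):
        X = np.array([[0.0], [1.0]])
        assert fit_domain(X).predict([[5.0]])[0] == 0.0

    def test_shift_invariance(self):
        rng = np.random.default_rng(1)
        X, Q = rng.random((12, 2)), rng.random((6, 2))
        assert np.allclose(
            fit_domain(X).predict(Q), fit_domain(X + 7.0).predict(Q + 7.0), atol=1e-12
        )


class TestKde:
    def test_argmax_presence_scores_one(self):
        X = np.random.default_rng(0).normal(size=(30, 2))
        model = fit_kde(X)
        assert model.predict(X).max() == pytest.approx(1.0)

    def test_mirror_symmetry(self):
        X = np.array([[-2.0], [-1.0], [1.0], [2.0]])
        model = fit_kde(X)
        q = np.array([[0.5], [-0.5]])
        s = model.predict(q)
        assert s[0] == pytest.approx(s[1], abs=1e-10)

    def test_kernel_sum_hand_oracle(self):
        """1D presences {0, 1, 2}: density at 0 equals the hand-computed
        three-kernel Gaussian sum in standardized space."""
        X = np.array([[0.0], [1.0], [2.0]])
        model = fit_kde(X)
        sd = np.std([0.0, 1.0, 2.0], ddof=1)
        z = (np.array([0.0, 1.0, 2.0]) - 1.0) / sd  # standardized presences
        h = (4.0 / 3.0) ** 0.2 * 3 ** (-0.2)  # Silverman, d=1, n=3, unit sd
        zq = (0.0 - 1.0) / sd
        dens = np.mean(np.exp(-0.5 * ((zq - z) / h) ** 2)) / (h * np.sqrt(2 * np.pi))
        assert model.density([[0.0]])[0] == pytest.approx(dens, rel=1e-10)

    def test_zero_variance_dimension_raises(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        with pytest.raises(DataError):
            fit_kde(X)


ALL_LEARNERS = [
    "glm_logistic", "maxent_surrogate", "discriminant", "tree", "forest",
    "svm", "neuralnet", "gam",
]


class TestClassifier:
    def _separable(self, rng, gap=5.0, n=60):
        pres = rng.normal(size=(n, 1)) + gap
        contr = rng.normal(size=(n, 1))
        return pres, contr

    @pytest.mark.parametrize("learner", ALL_LEARNERS)
    def test_separable_data_training_auc(self, learner):
        rng = np.random.default_rng(0)
        pres, contr = self._separable(rng)
        model = fit_classifier(pres, contr, learner=learner, seed=1)
        scores = np.concatenate([model.predict(pres), model.predict(contr)])
        assert scores.min() >= 0.0 and scores.max() <= 1.0
        assert auc(model.predict(pres), model.predict(contr)) >= 0.99

    def test_native_glm_matches_unpenalized_reference(self):
        """The IRLS logistic (ridge 1e-6) agrees with an (effectively)
        unpenalized reference fit on the same quadratic basis."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(2)
        pres = rng.normal(loc=1.2, size=(80, 2))
        contr = rng.normal(size=(200, 2))
        model = fit_classifier(pres, contr, learner="glm_logistic")
        X = np.vstack([pres, contr])
        y = np.concatenate([np.ones(80), np.zeros(200)])
        Z = (X - X.mean(axis=0)) / X.std(axis=0)
        ref = LogisticRegression(C=1e8, max_iter=5000).fit(
            np.hstack([Z, Z**2]), y
        )
        q = rng.normal(size=(50, 2))
        Zq = (q - X.mean(axis=0)) / X.std(axis=0)
        assert np.allclose(
            model.predict(q), ref.predict_proba(np.hstack([Zq, Zq**2]))[:, 1], atol=2e-3
        )

    def test_permuted_labels_give_null_auc(self):
        """With exchangeable classes and permuted labels, the AUC against the
        original grouping is a symmetric null: its mean over 100 seeds stays
        within 99% Monte Carlo bounds of 1/2."""
        rng = np.random.default_rng(3)
        pres = rng.normal(size=(40, 1))
        contr = rng.normal(size=(40, 1))
        aucs = []
        for s in range(100):
            m = fit_classifier(pres, contr, learner="glm_logistic", seed=s,
                               permute_labels=True)
            aucs.append(auc(m.predict(pres), m.predict(contr)))
        assert abs(np.mean(aucs) - 0.5) < 2.576 * np.std(aucs) / np.sqrt(100) + 1e-9

    def test_empty_class_raises(self):
        with pytest.raises(DataError):
            fit_classifier(np.zeros((0, 2)), np.zeros((5, 2)))

    def test_prediction_is_deterministic(self):
        rng = np.random.default_rng(4)
        pres, contr = self._separable(rng)
        m = fit_classifier(pres, contr, learner="forest", seed=7)
        q = rng.normal(size=(20, 1))
        assert np.array_equal(m.predict(q), m.predict(q))


class TestTruthCorrelation:
    @pytest.mark.parametrize("proc", ["bioclim", "domain", "kde", "glm_logistic",
                                      "maxent_surrogate", "discriminant", "svm"])
    def test_adapters_recover_a_gaussian_niche(self, proc):
        """With abundant presences every adapter's scores correlate positively
        with the true suitability over the study area."""
        from scipy.stats import spearmanr

        rng = np.random.default_rng(0)
        env = make_env(
            np.stack([
                np.add.outer(np.linspace(-2, 2, 45), np.zeros(50)) + 0.2 * rng.normal(size=(45, 50)),
                np.add.outer(np.zeros(45), np.linspace(-2, 2, 50)) + 0.2 * rng.normal(size=(45, 50)),
            ])
        )
        spec = VirtualSpeciesSpec("v", np.array([0.3, -0.2]), 0.4 * np.eye(2))
        truth = true_suitability(spec, env)
        occ = sample_occurrences(truth, 500, "modern", seed=1)
        X = env.values_at(occ.ys, occ.xs)
        if proc in ("bioclim", "domain", "kde"):
            model = {"bioclim": fit_bioclim, "domain": fit_domain, "kde": fit_kde}[proc](X)
        else:
            contrast = sample_background(env, n=1000, seed=2)
            model = fit_classifier(X, contrast, learner=proc, seed=3)
        vals, cells = env.table()
        rho = spearmanr(model.predict(vals), truth.values[cells[:, 0], cells[:, 1]]).statistic
        assert rho > 0.5


class TestSampleBackground:
    def test_fixed_n_on_full_grid(self):
        env = make_env(np.random.default_rng(0).random((2, 100, 100)))
        assert sample_background(env, n=1000, seed=0).shape == (1000, 2)

    def test_presences_x10(self):
        env = make_env(np.random.default_rng(0).random((1, 40, 40)))
        cells = np.column_stack([np.arange(37), np.arange(37)])
        out = sample_background(env, seed=0, rule="presences_x10", presence_cells=cells)
        assert out.shape == (370, 1)

    def test_seeding_contract(self):
        env = make_env(np.random.default_rng(0).random((1, 30, 30)))
        a = sample_background(env, n=200, seed=5)
        assert np.array_equal(a, sample_background(env, n=200, seed=5))

    def test_exceeding_valid_cells_raises(self):
        env = make_env(np.zeros((1, 10, 10)))
        with pytest.raises(DataError):
            sample_background(env, n=101, seed=0)

    def test_pseudoabsences_exclude_presence_cells(self):
        vals = np.arange(100.0).reshape(1, 10, 10)
        env = make_env(vals)
        pres = np.column_stack([np.repeat(np.arange(5), 10), np.tile(np.arange(10), 5)])
        out = sample_background(
            env, n=50, seed=1, rule="fixed_n", presence_cells=pres, exclude_presences=True
        )
        assert np.all(out[:, 0] >= 50.0)  # only cells from rows 5..9 remain


class TestEnsemblePredict:
    def _map(self, value):
        return SuitabilityMap(values=np.full((4, 4), value), mask=np.ones((4, 4), bool))

    def test_identical_members_passthrough(self):
        out = ensemble_predict([self._map(0.3), self._map(0.3)], weights=np.array([1, 1]))
        assert np.allclose(out.values, 0.3)

    def test_degenerate_weights_select_first(self):
        out = ensemble_predict([self._map(0.2), self._map(0.9)], weights=np.array([1, 0]))
        assert np.allclose(out.values, 0.2)

    def test_hand_mean(self):
        out = ensemble_predict([self._map(0.2), self._map(0.6)], weights=np.array([1, 1]))
        assert np.allclose(out.values, 0.4)

    def test_auc_floor_drops_weak_members(self):
        out = ensemble_predict(
            [self._map(0.2), self._map(0.9)], weights="auc_weighted",
            aucs=np.array([0.95, 0.55]),
        )
        assert np.allclose(out.values, 0.2)

    def test_grid_mismatch_raises(self):
        a = self._map(0.2)
        b = SuitabilityMap(values=np.zeros((5, 5)), mask=np.ones((5, 5), bool))
        with pytest.raises(DataError):
            ensemble_predict([a, b], weights=np.array([1, 1]))
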