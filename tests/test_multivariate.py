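import json

import numpy as np
import pytest

from metabrisk.multivariate import (
    OPLSDA,
    OPLSDAResults,
    OplsDaSpec,
    fit_oplsda,
    fit_pca,
    fit_plsda,
    min_components_at_max,
    select_components,
)


def naive_pls1(x, y01, scaling=True):
    """Independent one-component NIPALS PLS oracle (textbook construction)."""
    x = np.asarray(x, dtype=float)
    mu, sd = x.mean(0), x.std(0, ddof=1)
    if not scaling:
        sd = np.ones_like(sd)
    sd = np.where(sd == 0, 1.0, sd)
    xs = (x - mu) / sd
    yc = y01 - y01.mean()
    w = xs.T @ yc
    w = w / np.linalg.norm(w)
    t = xs @ w
    q = (yc @ t) / (t @ t)

    def predict_response(xn):
        return (((np.asarray(xn, dtype=float) - mu) / sd) @ w) * q + y01.mean()

    return predict_response


class TestPCA:
    def test_collinear_data_one_component(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=20)
        x = np.outer(t, [1.0, -2.0, 0.5])
        res = fit_pca(x, 2)
        assert res.explained_variance_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_reconstruction_at_full_rank(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 6))
        res = fit_pca(x, 6)
        recon = res.scores @ res.loadings.T + x.mean(axis=0)
        np.testing.assert_allclose(recon, x, atol=1e-8)

    def test_invariants_and_sign_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 8))
        a = fit_pca(x, 5)
        b = fit_pca(x, 5)
        np.testing.assert_array_equal(a.loadings, b.loadings)
        np.testing.assert_allclose(a.loadings.T @ a.loadings, np.eye(5), atol=1e-8)
        evr = a.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12) and evr.sum() <= 1 + 1e-12
        # fixed sign convention: the largest-|loading| entry is positive
        for i in range(5):
            assert a.loadings[np.argmax(np.abs(a.loadings[:, i])), i] > 0

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            fit_pca(np.zeros((5, 3)), 5)


class TestOplsDa:
    def test_separable_training_accuracy(self, separable_xy):
        # a fixed 0.5 threshold on the regression response does not guarantee
        # perfect training separation, so allow one borderline sample in 40
        x, y = separable_xy
        res = fit_oplsda(x, y, k_ortho=0)
        assert (res.predict(x) == y).mean() >= 0.95

    @pytest.mark.parametrize("seed,n,m", [(0, 20, 5), (1, 35, 12), (2, 50, 61)])
    def test_zero_ortho_equals_one_component_pls(self, seed, n, m):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(n, m))
        y = rng.integers(0, 2, size=n)
        while len(np.unique(y)) < 2:
            y = rng.integers(0, 2, size=n)
        res = fit_oplsda(x, y, k_ortho=0)
        oracle = naive_pls1(x, y.astype(float))
        np.testing.assert_allclose(res.decision_function(x), oracle(x), atol=1e-8)

    def test_orthogonal_filtering_improves_score_correlation(self):
        # planted structure: x1 carries y plus a strong confound shared with x2
        rng = np.random.default_rng(3)
        n = 60
        y = np.repeat([0.0, 1.0], n // 2)
        confound = rng.normal(scale=4.0, size=n)
        x = np.column_stack([
            y + confound + rng.normal(scale=0.2, size=n),
            confound + rng.normal(scale=0.2, size=n),
            rng.normal(size=n),
        ])
        plain = fit_oplsda(x, y, k_ortho=0)
        opls = fit_oplsda(x, y, k_ortho=1)
        def corr(t):
            return abs(np.corrcoef(t, y)[0, 1])
        assert corr(opls.predictive_scores(x)) >= corr(plain.predictive_scores(x))

    def test_scores_orthogonality_invariant(self, separable_xy):
        x, y = separable_xy
        res = fit_oplsda(x, y, k_ortho=3)
        for j in range(res.k_ortho):
            assert abs(res.scores @ res.ortho_scores[:, j]) < 1e-8
        gram = res.ortho_scores.T @ res.ortho_scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_deflation_never_hurts_training_accuracy(self, separable_xy):
        x, y = separable_xy
        rng = np.random.default_rng(4)
        x = x + np.outer(rng.normal(scale=3, size=len(y)), rng.normal(size=x.shape[1]))
        accs = []
        for k in range(4):
            res = fit_oplsda(x, y, k_ortho=k)
            accs.append((res.predict(x) == y).mean())
        assert all(b >= a - 1e-12 for a, b in zip(accs, accs[1:]))

    def test_tie_at_threshold_goes_to_first_class(self):
        res = fit_oplsda(np.array([[0.0, 1], [1, 0], [2, 1], [3, 0]]),
                         np.array(["A", "A", "B", "B"]), k_ortho=0)
        res.threshold = float(res.decision_function(np.array([[1.5, 0.5]]))[0])
        assert res.predict(np.array([[1.5, 0.5]]))[0] == "A"

    def test_training_sample_prediction_consistency(self, separable_xy):
        x, y = separable_xy
        res = fit_oplsda(x, y, k_ortho=1)
        train_pred = res.predict(x)
        assert res.predict(x[7][None, :])[0] == train_pred[7]

    def test_column_mismatch_rejected(self, separable_xy):
        import pandas as pd
        x, y = separable_xy
        df = pd.DataFrame(x, columns=[f"m{j}" for j in range(x.shape[1])])
        res = fit_oplsda(df, y, k_ortho=0)
        wrong = df.rename(columns={"m0": "other"})
        with pytest.raises(ValueError, match="column"):
            res.predict(wrong)
        with pytest.raises(ValueError, match="metabolites"):
            res.predict(np.zeros((2, x.shape[1] + 1)))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="class"):
            OPLSDA(np.zeros((4, 2)), np.array(["A", "A", "A", "A"]))

    def test_json_round_trip_preserves_predictions(self, separable_xy):
        x, y = separable_xy
        res = fit_oplsda(x, y, k_ortho=2)
        back = OPLSDAResults.from_json(res.to_json())
        np.testing.assert_allclose(back.decision_function(x),
                                   res.decision_function(x), atol=1e-12)
        assert (back.predict(x) == res.predict(x)).all()

    def test_summary_mentions_components(self, separable_xy):
        x, y = separable_xy
        text = fit_oplsda(x, y, k_ortho=2).summary()
        assert "1 predictive + 2 orthogonal" in text


class TestPlsDa:
    def test_component_scores_mutually_orthogonal(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(30, 10))
        y = np.array(["a", "b", "c"] * 10)
        res = fit_plsda(x, y, n_components=4)
        gram = res.scores.T @ res.scores
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0, atol=1e-8)

    def test_three_class_separable_prediction(self):
        rng = np.random.default_rng(6)
        centers = np.array([[5, 0, 0], [0, 5, 0], [0, 0, 5]], dtype=float)
        y = np.repeat(["a", "b", "c"], 15)
        x = np.vstack([centers[i] + rng.normal(scale=0.3, size=(15, 3))
                       for i in range(3)])
        res = fit_plsda(x, y, n_components=2)
        assert (res.predict(x) == y).mean() == 1.0


class TestComponentSelection:
    def test_minimum_at_maximum_rule(self):
        assert min_components_at_max([0.7, 0.9, 0.9, 0.85]) == 2

    def test_flat_profile_returns_one(self):
        assert min_components_at_max([0.8, 0.8, 0.8]) == 1

    def test_separable_one_direction_selects_one(self):
        # class shift along every metabolite: one predictive component already
        # reaches maximal CV accuracy, so the min-at-max rule must return 1
        rng = np.random.default_rng(1)
        x = rng.normal(size=(40, 6))
        y = np.array(["A"] * 20 + ["B"] * 20)
        x[:20] -= 2.0
        x[20:] += 2.0
        assert select_components(x, y, max_total=3, seed=0, n_iterations=10) == 1
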