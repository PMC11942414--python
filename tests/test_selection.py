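"""Unit and property tests for the deflation-based forward selection."""

import numpy as np
import pytest

from fspls import (
    FitOptions,
    FsplsModel,
    Outcome,
    center,
    deflate,
    fit,
    fit_univariate,
    lrt_pvalue,
    null_loglik,
    predict,
    select_model_size,
    select_next,
)
from fspls.selection import linear_predictor

from conftest import forward_ols_path, gram_schmidt_deflate


def _random_problem(rng, family, m=40, p=8):
    X = rng.normal(size=(m, p))
    if family == "gaussian":
        yv = X[:, 0] * 0.8 + rng.normal(size=m)
    elif family == "binomial":
        yv = (rng.random(m) < 1 / (1 + np.exp(-X[:, 0]))).astype(float)
        yv[:2] = [0, 1]
    else:
        yv = rng.integers(0, 3, m).astype(float)
        yv[:3] = [0, 1, 2]
    return X, Outcome(yv, family)


class TestCenter:
    def test_records_means(self):
        fm = center(np.array([[1.0], [2.0], [3.0]]))
        assert np.allclose(fm.data[:, 0], [-1, 0, 1])
        assert fm.feature_means[0] == 2.0

    def test_already_centered_unchanged(self):
        col = np.array([[-1.0], [0.0], [1.0]])
        fm = center(col)
        assert np.allclose(fm.data, col)
        assert fm.feature_means[0] == 0.0

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        X = rng.normal(5.0, 2.0, (15, 6))
        once = center(X)
        twice = center(once.data)
        assert np.allclose(once.data, twice.data, atol=1e-12)
        assert np.allclose(twice.feature_means, 0.0, atol=1e-12)

    def test_nonfinite_names_feature(self):
        X = np.ones((4, 3))
        X[2, 1] = np.inf
        with pytest.raises(ValueError, match="geneB"):
            center(X, feature_ids=["geneA", "geneB", "geneC"])

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            center(np.ones((3, 2)), feature_ids=["a", "a"])


class TestDeflate:
    def test_empty_selection_is_identity(self):
        rng = np.random.default_rng(1)
        X = center(rng.normal(size=(10, 5))).data
        assert np.array_equal(deflate(X, X[:, []]), X)

    def test_own_column_becomes_zero(self):
        rng = np.random.default_rng(2)
        X = center(rng.normal(size=(12, 6))).data
        R = deflate(X, X[:, [2]])
        assert np.linalg.norm(R[:, 2]) <= 1e-10

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_gram_schmidt_and_is_orthogonal(self, seed):
        rng = np.random.default_rng(seed)
        X = center(rng.normal(size=(20, 8))).data
        sel = X[:, [1, 4, 6]]
        R = deflate(X, sel)
        assert np.abs(sel.T @ R).max() <= 1e-8
        assert np.allclose(R, gram_schmidt_deflate(X, sel), atol=1e-8)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            deflate(np.ones((5, 3)), np.ones((4, 1)))


class TestSelectNext:
    def test_planted_column_found(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(100, 12))
            y = Outcome(3.0 * X[:, 7] + 0.1 * rng.normal(size=100), "gaussian")
            j, _ = select_next(center(X).data, y)
            hits += j == 7
        assert hits >= 19

    def test_tie_breaks_to_lowest_index(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        X = np.column_stack([rng.normal(size=30), x, x])
        y = Outcome(2 * x + 0.1 * rng.normal(size=30), "gaussian")
        j, _ = select_next(center(X).data, y)
        assert j == 1

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "multinomial"])
    def test_matches_exhaustive_enumeration(self, family):
        rng = np.random.default_rng(17)
        X, y = _random_problem(rng, family, m=30, p=10)
        Xc = center(X).data
        j, f = select_next(Xc, y)
        lls = [fit_univariate(Xc[:, k], y).loglik for k in range(10)]
        assert j == int(np.argmax(lls))
        assert f.loglik == pytest.approx(max(lls), abs=1e-7)

    def test_all_degenerate_signals_stop(self):
        from fspls import DegenerateOutcomeError

        y = Outcome(np.array([0.0, 1.0, 0.0, 1.0]), "binomial")
        with pytest.raises(DegenerateOutcomeError):
            select_next(np.zeros((4, 3)), y)


class TestFit:
    def test_exact_two_feature_recovery(self):
        rng = np.random.default_rng(5)
        Q, _ = np.linalg.qr(rng.normal(size=(30, 10)))
        X = Q * 3.0
        y = Outcome(2.0 * X[:, 3] - 1.0 * X[:, 7], "gaussian")
        m = fit(X, y, FitOptions(ridge_lambda=0.0))
        assert m.selected_indices == [3, 7] or m.selected_indices == [7, 3]
        assert np.abs(predict(m, X) - y.values).max() < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_fitted_values_equal_ols_on_selected(self, seed):
        rng = np.random.default_rng(30 + seed)
        m_, p = 40, 12
        Q, _ = np.linalg.qr(rng.normal(size=(m_, p)))
        y = Outcome(Q[:, 2] * 2 + Q[:, 9] + 0.3 * rng.normal(size=m_), "gaussian")
        model = fit(Q, y, FitOptions(ridge_lambda=0.0, max_features=4, force_to_max=True))
        sel = model.selected_indices
        D = np.column_stack([np.ones(m_), Q[:, sel]])
        beta, *_ = np.linalg.lstsq(D, y.values, rcond=None)
        assert np.allclose(predict(model, Q), D @ beta, atol=1e-8)

    def test_pure_noise_first_step_pvalue_matches_enumeration(self):
        """fit() declines to select iff the smallest enumerated univariate
        likelihood-ratio p-value is above the threshold."""
        agree = 0
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            X = rng.normal(size=(60, 50))
            y = Outcome(rng.normal(size=60), "gaussian")
            model = fit(X, y, FitOptions(pvalue_threshold=0.05))
            Xc = center(X).data
            ll0 = null_loglik(y)
            pmin = min(
                lrt_pvalue(fit_univariate(Xc[:, j], y).loglik, ll0, 1)
                for j in range(50)
            )
            agree += (len(model.steps) == 0) == (pmin >= 0.05)
        assert agree == 20

    @pytest.mark.parametrize("family", ["gaussian", "binomial", "multinomial"])
    @pytest.mark.parametrize("seed", range(5))
    def test_no_reselection_and_monotone_loglik(self, family, seed):
        rng = np.random.default_rng(1000 + seed)
        X, y = _random_problem(rng, family, m=50, p=10)
        model = fit(X, y, FitOptions(max_features=6, force_to_max=True))
        sel = model.selected_indices
        assert len(sel) == len(set(sel))
        lls = [model.null_loglik] + [s.loglik for s in model.steps]
        assert all(a <= b + 1e-7 for a, b in zip(lls, lls[1:]))

    def test_orthogonality_maintained_each_iteration(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(40, 15))
        y = Outcome(X[:, 1] - X[:, 5] + 0.5 * rng.normal(size=40), "gaussian")
        model = fit(X, y, FitOptions(max_features=5, force_to_max=True))
        Xc = center(X).data
        for k in range(1, len(model.steps) + 1):
            sel = Xc[:, model.selected_indices[:k]]
            R = deflate(Xc, sel)
            assert np.abs(sel.T @ R).max() <= 1e-8 * np.abs(Xc).max() * 40

    def test_correlated_block_contributes_at_most_one_feature(self):
        """With a tight block (r >= 0.95) holding one associated feature,
        deflation keeps the block's redundant twins out, and the selected
        set is less internally correlated than the top-k marginal ranking."""
        rng = np.random.default_rng(12)
        m_, p = 150, 30
        X = rng.normal(size=(m_, p))
        shared = rng.normal(size=m_)
        block = [4, 9, 14, 19, 24]
        for j in block:
            X[:, j] = shared + 0.15 * rng.normal(size=m_)
        y = Outcome(
            1.5 * X[:, 4] + 1.0 * X[:, 0] - 1.0 * X[:, 11] + 0.7 * rng.normal(size=m_),
            "gaussian",
        )
        C = np.corrcoef(X[:, block].T)
        assert np.abs(C[np.triu_indices_from(C, 1)]).min() >= 0.95
        model = fit(X, y, FitOptions())
        sel = model.selected_indices
        assert len(set(sel) & set(block)) <= 1
        # marginal top-k ranking, same k
        Xc = center(X).data
        lls = [fit_univariate(Xc[:, j], y).loglik for j in range(p)]
        topk = np.argsort(lls)[::-1][: len(sel)]

        def mean_abs_r(idx):
            Cm = np.corrcoef(X[:, idx].T)
            return np.abs(Cm[np.triu_indices_from(Cm, 1)]).mean()

        assert mean_abs_r(sel) < mean_abs_r(topk)

    def test_stop_reasons(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(30, 5))
        y = Outcome(X[:, 2] + 0.1 * rng.normal(size=30), "gaussian")
        m1 = fit(X, y, FitOptions(pvalue_threshold=1.0, max_features=2))
        assert len(m1.steps) == 2 and m1.stop_reason == "max_features"
        m2 = fit(X, y, FitOptions(pvalue_threshold=1.0))
        assert m2.stop_reason == "loglik_degenerate"
        assert len(m2.steps) == 5


class TestPredict:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "multinomial"])
    def test_training_replay_and_single_sample(self, family):
        rng = np.random.default_rng(40)
        X, y = _random_problem(rng, family, m=45, p=9)
        model = fit(X, y, FitOptions(max_features=4, force_to_max=True))
        assert model.steps
        batch = predict(model, X)
        singles = np.stack([predict(model, X[i : i + 1])[0] for i in range(10)])
        assert np.abs(singles - batch[:10]).max() <= 1e-12
        # replay of the training linear predictor is exact
        eta = linear_predictor(model, X)
        eta2 = linear_predictor(model, X)
        assert np.abs(eta - eta2).max() == 0.0

    def test_zero_step_model_predicts_null(self):
        rng = np.random.default_rng(41)
        X = rng.normal(size=(30, 6))
        y = Outcome(rng.normal(size=30), "gaussian")
        model = fit(X, y, FitOptions(pvalue_threshold=1e-12))
        assert len(model.steps) == 0
        assert np.allclose(predict(model, X), y.values.mean())

    def test_through_step_truncation_matches_truncate(self):
        rng = np.random.default_rng(42)
        X, y = _random_problem(rng, "gaussian", m=40, p=8)
        model = fit(X, y, FitOptions(max_features=3, force_to_max=True))
        assert np.allclose(
            predict(model, X, through_step=2), predict(model.truncate(2), X)
        )

    def test_missing_feature_is_named(self):
        rng = np.random.default_rng(43)
        X, y = _random_problem(rng, "gaussian", m=30, p=5)
        model = fit(X, y, FitOptions(max_features=1, force_to_max=True),
                    feature_ids=list("abcde"))
        needed = model.selected_ids[0]
        with pytest.raises(ValueError, match=needed):
            predict(model, np.ones((2, 2)), feature_ids=["zz", "ww"])

    def test_prediction_needs_only_selected_features(self):
        rng = np.random.default_rng(44)
        X, y = _random_problem(rng, "binomial", m=50, p=12)
        model = fit(X, y, FitOptions(max_features=3, force_to_max=True))
        sel = model.selected_indices
        ids = [model.feature_ids[j] for j in sel]
        sub = predict(model, X[:, sel], feature_ids=ids)
        assert np.allclose(sub, predict(model, X), atol=1e-12)


class TestSerialization:
    @pytest.mark.parametrize("family", ["gaussian", "binomial", "multinomial"])
    def test_roundtrip_preserves_predictions(self, family):
        rng = np.random.default_rng(60)
        X, y = _random_problem(rng, family, m=40, p=10)
        model = fit(X, y, FitOptions(max_features=3, force_to_max=True))
        restored = FsplsModel.from_json(model.to_json())
        sel = model.selected_indices
        ids = [model.feature_ids[j] for j in sel]
        assert np.allclose(
            predict(restored, X[:, sel], feature_ids=ids),
            predict(model, X),
            atol=1e-12,
        )

    def test_unknown_version_rejected(self):
        rng = np.random.default_rng(61)
        X, y = _random_problem(rng, "gaussian")
        model = fit(X, y, FitOptions(max_features=1, force_to_max=True))
        import json

        doc = json.loads(model.to_json())
        doc["version"] = 99
        with pytest.raises(ValueError, match="version"):
            FsplsModel.from_json(json.dumps(doc))


class TestSelectModelSize:
    def test_min_rule(self):
        assert select_model_size([5, 3, 2, 2.1], rule="min") == 3

    def test_min_ties_take_smallest(self):
        assert select_model_size([5, 2, 2], rule="min") == 2

    def test_one_se_rule(self):
        assert select_model_size([5, 3, 2], rule="one_se", se=[1, 1, 1]) == 2

    def test_one_se_zero_se_equals_min(self):
        losses = [9, 5, 3, 1]
        assert select_model_size(losses, "one_se", se=[0, 0, 0, 0]) == select_model_size(
            losses, "min"
        )

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            select_model_size([], "min")


class TestFitOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            FitOptions(pvalue_threshold=0.0)
        with pytest.raises(ValueError):
            FitOptions(max_features=0)
        with pytest.raises(ValueError):
            FitOptions(ridge_lambda=-1.0)
        with pytest.raises(ValueError):
            FitOptions(force_to_max=True)
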