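"""Shrunken-centroid machinery against independent brute-force oracles."""

import numpy as np
import pytest

from dynsig.core_io import ValidationError
from dynsig.pam_classifier import (
    cross_validate_pam,
    default_delta_grid,
    fit_shrunken_centroids,
    pam_discriminant,
    pam_predict,
    pam_signature_scores,
)


def oracle_diagonal_predict(X, y, x_new):
    """Independent nearest-centroid rule with the same standardisation:
    diagonal discriminant on unshrunken class centroids, empirical priors."""
    classes = sorted(np.unique(y).tolist())
    n = len(y)
    cents = {c: X[:, y == c].mean(axis=1) for c in classes}
    ss = np.zeros(X.shape[0])
    for c in classes:
        resid = X[:, y == c] - cents[c][:, None]
        ss += (resid**2).sum(axis=1)
    s = np.sqrt(ss / (n - len(classes)))
    s0 = np.median(s)
    best, best_score = None, np.inf
    for c in classes:
        score = np.sum((x_new - cents[c]) ** 2 / (s + s0) ** 2) - 2 * np.log(np.mean(y == c))
        if score < best_score:
            best, best_score = c, score
    return best


class TestFit:
    def test_two_class_symmetry_of_standardised_differences(self):
        # one gene, equal class sizes: d_g1 = -d_g2 because m_k and the
        # centroid offsets are symmetric
        X = np.array([[0.0, 0.1, -0.1, 2.0, 1.9, 2.1]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_shrunken_centroids(X, y, delta=0.0)
        assert model.d_unshrunken[0, 0] == pytest.approx(-model.d_unshrunken[1, 0])

    def test_full_shrinkage_collapses_to_overall_centroid(self, rng):
        X = rng.normal(size=(20, 12))
        y = np.array([0] * 6 + [1] * 6)
        big = float(np.max(np.abs(fit_shrunken_centroids(X, y).d_unshrunken))) + 1.0
        model = fit_shrunken_centroids(X, y, delta=big)
        np.testing.assert_allclose(
            model.class_centroids_shrunken, np.tile(model.overall_centroid, (2, 1))
        )
        assert model.selected_genes == []
        # predictions become prior-driven: the larger class wins everywhere
        y_skew = np.array([0] * 8 + [1] * 4)
        m2 = fit_shrunken_centroids(X, y_skew, delta=1e6)
        assert np.all(pam_predict(m2, X) == 0)

    def test_small_class_rejected(self):
        with pytest.raises(ValidationError, match="fewer than 2"):
            fit_shrunken_centroids(np.zeros((3, 3)) + np.eye(3), np.array([0, 1, 1]))

    def test_selected_genes_monotone_in_delta(self, rng):
        X = rng.normal(size=(50, 30))
        X[:10, :15] += 1.0
        y = np.array([0] * 15 + [1] * 15)
        base = fit_shrunken_centroids(X, y)
        grid = default_delta_grid(X, y, n_points=15)
        counts = [len(base.at_delta(d).selected_genes) for d in grid]
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 50  # delta = 0 keeps everything (generic data)


class TestDiscriminant:
    def test_delta_zero_matches_diagonal_oracle_on_random_datasets(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            g = int(rng.integers(3, 12))
            n0, n1 = int(rng.integers(3, 8)), int(rng.integers(3, 8))
            X = rng.normal(size=(g, n0 + n1))
            X[: g // 2, n0:] += rng.normal(0, 1.5)
            y = np.array([0] * n0 + [1] * n1)
            model = fit_shrunken_centroids(X, y, delta=0.0)
            x_new = rng.normal(size=g)
            assert pam_discriminant(model, x_new)["predicted"] == oracle_diagonal_predict(X, y, x_new)

    def test_scores_match_quadratic_form_oracle(self, rng):
        X = rng.normal(size=(8, 10))
        y = np.array([0] * 5 + [1] * 5)
        model = fit_shrunken_centroids(X, y, delta=0.4)
        x_new = rng.normal(size=8)
        out = pam_discriminant(model, x_new)
        for i, c in enumerate(model.classes):
            brute = sum(
                (x_new[j] - model.class_centroids_shrunken[i, j]) ** 2
                / (model.pooled_sd[j] + model.s0) ** 2
                for j in range(8)
            ) - 2 * np.log(model.priors[i])
            assert out["scores"][c] == pytest.approx(brute, rel=1e-12)

    def test_profile_at_centroid_wins_with_equal_priors(self, rng):
        X = rng.normal(size=(5, 8))
        y = np.array([0] * 4 + [1] * 4)
        model = fit_shrunken_centroids(X, y, delta=0.1, priors="uniform")
        out = pam_discriminant(model, model.class_centroids_shrunken[1])
        assert out["predicted"] == 1

    def test_equidistant_profile_ties_flagged_and_label_ordered(self):
        X = np.array([[0.0, 0.2, -0.2, 2.0, 2.2, 1.8]])
        y = np.array([0, 0, 0, 1, 1, 1])
        model = fit_shrunken_centroids(X, y, delta=0.0, priors="uniform")
        midpoint = model.class_centroids_shrunken.mean(axis=0)
        out = pam_discriminant(model, midpoint)
        assert out["tie"] and out["predicted"] == 0

    def test_dict_profile_imputes_missing_genes_at_overall_centroid(self, rng):
        from dynsig.core_io import ExpressionMatrix

        vals = rng.normal(size=(4, 8))
        X = ExpressionMatrix([f"g{i}" for i in range(4)], [f"s{j}" for j in range(8)], vals)
        y = np.array([0] * 4 + [1] * 4)
        model = fit_shrunken_centroids(X, y, delta=0.0)
        full = {g: model.overall_centroid[i] for i, g in enumerate(model.gene_ids)}
        assert (
            pam_discriminant(model, {})["scores"] == pam_discriminant(model, full)["scores"]
        )

    def test_predictions_invariant_to_gene_and_sample_order(self, rng):
        from dynsig.core_io import ExpressionMatrix

        vals = rng.normal(size=(6, 12))
        vals[:3, 6:] += 2.0
        genes = [f"g{i}" for i in range(6)]
        y = np.array([0] * 6 + [1] * 6)
        X = ExpressionMatrix(genes, [f"s{j}" for j in range(12)], vals)
        model = fit_shrunken_centroids(X, y, delta=0.0)

        gperm = rng.permutation(6)
        sperm = rng.permutation(12)
        X2 = ExpressionMatrix(
            [genes[i] for i in gperm], [f"s{j}" for j in sperm], vals[np.ix_(gperm, sperm)]
        )
        model2 = fit_shrunken_centroids(X2, y[sperm], delta=0.0)
        pred1 = pam_predict(model, X)
        pred2 = pam_predict(model2, X)  # X realigned to model2's gene order internally
        np.testing.assert_array_equal(pred1, pred2)


class TestCrossValidation:
    def test_separable_data_reaches_zero_cv_error(self, rng):
        X = rng.normal(size=(10, 40))
        X[:, 20:] += 4.0
        y = np.array([0] * 20 + [1] * 20)
        cv = cross_validate_pam(X, y, n_folds=5, seed=0)
        assert cv.cv_error.min() == 0.0
        assert cv.cv_error[0] == 0.0  # small delta already separates

    def test_permuted_labels_error_near_majority_rate(self):
        # with labels carrying no information, the best CV error should sit
        # near the majority-class rate
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 40))
            y = np.array([0] * 24 + [1] * 16)
            rng.shuffle(y)
            cv = cross_validate_pam(X, y, n_folds=5, seed=seed)
            errs.append(cv.cv_error.min())
        assert abs(np.mean(errs) - 0.4) < 0.1

    def test_chosen_delta_in_grid_and_folds_stratified(self, rng):
        X = rng.normal(size=(15, 60))
        X[:5, 30:] += 1.5
        y = np.array([0] * 30 + [1] * 30)
        cv = cross_validate_pam(X, y, n_folds=10, seed=3)
        assert cv.chosen_delta in cv.delta_grid
        for f in range(10):
            fold_labels = y[cv.fold_assignments == f]
            assert set(fold_labels) == {0, 1}

    def test_too_small_class_for_folds_errors(self, rng):
        X = rng.normal(size=(5, 12))
        y = np.array([0] * 9 + [1] * 3)
        with pytest.raises(ValidationError, match="fewer folds|too small"):
            cross_validate_pam(X, y, n_folds=10)

    def test_one_se_never_selects_empty_model(self, rng):
        # noisy labels push one-SE toward heavy shrinkage; the chosen model
        # must still carry at least one gene
        X = rng.normal(size=(40, 30))
        y = np.array([0] * 20 + [1] * 10)
        cv = cross_validate_pam(X, y, n_folds=5, seed=1)
        assert len(cv.model.selected_genes) >= 1

    def test_signature_score_orientation(self, rng):
        X = rng.normal(size=(12, 60))
        X[:6, 30:] += 2.0  # class 1 shifted up
        y = np.array([0] * 30 + [1] * 30)
        model = fit_shrunken_centroids(X, y, delta=0.5)
        scores = pam_signature_scores(model, X, positive_class=1)
        assert scores[y == 1].mean() > scores[y == 0].mean()
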