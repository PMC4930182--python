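"""Dimensionality reduction, ANN scoring, cross-validation, cohort statistics."""

import numpy as np
import pandas as pd
import pytest

from fmscore.errors import ContractError, RankError, ValidationError
from fmscore.features import FeatureVector, feature_names
from fmscore.motion_io import CohortTable, FMAItem
from fmscore.scoring import (
    balance_classes,
    cross_validate,
    evaluate_cohort,
    fit_reduction,
    ItemScoreModel,
    predict_item_score,
    select_k,
    summed_score,
    train_item_model,
)


def _clustered_data(rng, n_per_class=30, n_features=20, spread=0.15):
    """Three well-separated Gaussian clusters, one per score class."""
    centers = rng.normal(0, 2.0, size=(3, n_features))
    X = np.vstack([centers[c] + spread * rng.normal(size=(n_per_class, n_features))
                   for c in range(3)])
    y = np.repeat([0, 1, 2], n_per_class)
    return X, y, centers


class TestReduction:
    def test_exact_subspace_reconstructs_with_no_error(self, rng):
        basis = rng.normal(size=(3, 12))
        coords = rng.normal(size=(40, 3))
        X = coords @ basis + rng.normal(size=12)  # affine 3-dim subspace
        red = fit_reduction(X, 3)
        Z = red.transform(X)
        X_std = (X - red.mean) / red.scale
        recon = Z @ red.components
        assert np.allclose(recon, X_std, atol=1e-8)

    def test_explained_variance_matches_eigendecomposition_oracle(self, rng):
        X = rng.normal(size=(60, 8)) @ rng.normal(size=(8, 8))
        red = fit_reduction(X, 5)
        Z = (X - red.mean) / red.scale
        eigvals = np.linalg.eigvalsh(np.cov(Z, rowvar=False))[::-1]
        assert np.allclose(red.explained_variance, eigvals[:5], rtol=1e-8)

    def test_column_mean_projects_to_zero(self, rng):
        X = rng.normal(size=(30, 10))
        red = fit_reduction(X, 4)
        assert np.allclose(red.transform(X.mean(axis=0)[None, :]), 0.0, atol=1e-9)

    def test_component_sign_convention_is_deterministic(self, rng):
        X = rng.normal(size=(50, 9))
        red = fit_reduction(X, 4)
        for comp in red.components:
            assert comp[np.argmax(np.abs(comp))] > 0

    def test_rank_deficient_data_raises(self, rng):
        low = rng.normal(size=(30, 3)) @ rng.normal(size=(3, 10))
        with pytest.raises(RankError):
            fit_reduction(low, 5)


class TestBalance:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.repeat([0, 1, 2], 10)
        Xb, yb = balance_classes(X, y, seed=0)
        assert np.array_equal(Xb, X) and np.array_equal(yb, y)

    def test_minorities_oversampled_to_majority_count(self, rng):
        X = rng.normal(size=(17, 4))
        y = np.array([0] * 2 + [1] * 5 + [2] * 10)
        _, yb = balance_classes(X, y, seed=0)
        _, counts = np.unique(yb, return_counts=True)
        assert counts.tolist() == [10, 10, 10]

    def test_resampled_rows_all_come_from_the_input(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 2 + [1] * 4 + [2] * 6)
        Xb, yb = balance_classes(X, y, seed=1)
        originals = {tuple(row) for row in X}
        assert all(tuple(row) in originals for row in Xb)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            balance_classes(np.empty((0, 3)), np.empty(0))


class TestSelectK:
    def test_recovers_known_intrinsic_dimension(self, rng):
        # class signal confined to 4 latent dimensions + tiny isotropic noise
        latent_centers = rng.normal(0, 3.0, size=(3, 4))
        loadings = rng.normal(size=(4, 30))
        X, y = [], []
        for c in range(3):
            z = latent_centers[c] + 0.1 * rng.normal(size=(25, 4))
            X.append(z @ loadings + 0.01 * rng.normal(size=(25, 30)))
            y.extend([c] * 25)
        k = select_k(np.vstack(X), np.array(y), seed=0)
        assert k == 4  # saturated accuracy beyond 4 -> tie-break to smallest

    def test_result_always_inside_grid(self, rng):
        X, y, _ = _clustered_data(rng)
        assert 4 <= select_k(X, y, seed=0) <= 10

    def test_single_class_data_rejected(self, rng):
        X = rng.normal(size=(20, 10))
        with pytest.raises(ValidationError):
            select_k(X, np.zeros(20, dtype=int))


class TestItemModel:
    def test_single_class_training_predicts_that_class(self, rng):
        X = rng.normal(size=(15, 10))
        model = train_item_model(X, np.full(15, 2), FMAItem.ELBOW_FLEXION,
                                 [f"f{i}" for i in range(10)])
        assert model.predict_matrix(rng.normal(size=(7, 10))).tolist() == [2] * 7

    def test_separable_clusters_reach_full_training_accuracy(self, rng):
        X, y, _ = _clustered_data(rng)
        model = train_item_model(X, y, FMAItem.ELBOW_FLEXION,
                                 [f"f{i}" for i in range(X.shape[1])], n_components=5)
        assert np.mean(model.predict_matrix(X) == y) == 1.0

    def test_cluster_centroid_predicts_its_class(self, rng):
        X, y, centers = _clustered_data(rng)
        names = [f"f{i}" for i in range(X.shape[1])]
        model = train_item_model(X, y, FMAItem.ELBOW_FLEXION, names, n_components=5)
        fv = FeatureVector(item=FMAItem.ELBOW_FLEXION, names=tuple(names),
                           values=centers[2])
        assert predict_item_score(model, fv) == 2

    def test_save_load_round_trip_preserves_predictions(self, rng, tmp_path):
        X, y, _ = _clustered_data(rng)
        names = [f"f{i}" for i in range(X.shape[1])]
        model = train_item_model(X, y, FMAItem.SHOULDER_ABDUCTION, names, n_components=4)
        probe = rng.normal(size=(25, X.shape[1]))
        path = tmp_path / "model.pkl"
        model.save(path)
        loaded = ItemScoreModel.load(path)
        assert np.array_equal(loaded.predict_matrix(probe), model.predict_matrix(probe))
        assert loaded.metadata["n_components"] == 4

    def test_feature_name_mismatch_is_a_contract_error(self, rng):
        X, y, _ = _clustered_data(rng)
        names = [f"f{i}" for i in range(X.shape[1])]
        model = train_item_model(X, y, FMAItem.ELBOW_FLEXION, names, n_components=4)
        fv = FeatureVector(item=FMAItem.ELBOW_FLEXION,
                           names=tuple(feature_names()[: X.shape[1]]),
                           values=np.zeros(X.shape[1]))
        with pytest.raises(ContractError):
            predict_item_score(model, fv)

    def test_prediction_is_deterministic(self, rng):
        X, y, _ = _clustered_data(rng)
        names = [f"f{i}" for i in range(X.shape[1])]
        m1 = train_item_model(X, y, FMAItem.ELBOW_FLEXION, names, n_components=5, seed=42)
        m2 = train_item_model(X, y, FMAItem.ELBOW_FLEXION, names, n_components=5, seed=42)
        probe = rng.normal(size=(10, X.shape[1]))
        assert np.array_equal(m1.predict_matrix(probe), m2.predict_matrix(probe))


class TestCrossValidation:
    def test_folds_partition_every_record_exactly_once(self, rng):
        X, y, _ = _clustered_data(rng, n_per_class=20)
        report = cross_validate(X, y, k_folds=10, seed=0, n_components=4)
        seen = np.concatenate(report.fold_test_indices)
        assert sorted(seen.tolist()) == list(range(len(y)))

    def test_mean_accuracy_equals_recomputed_fold_mean(self, rng):
        X, y, _ = _clustered_data(rng, n_per_class=20)
        report = cross_validate(X, y, k_folds=8, seed=1, n_components=4)
        manual = sum(report.fold_accuracies) / len(report.fold_accuracies)
        assert report.mean_accuracy == pytest.approx(manual, abs=1e-12)

    def test_separable_cohort_scores_above_95_percent(self, rng):
        X, y, _ = _clustered_data(rng, n_per_class=25)
        report = cross_validate(X, y, k_folds=10, seed=0, n_components=5)
        assert report.mean_accuracy >= 0.95

    def test_confusion_counts_sum_to_cohort_size(self, rng):
        X, y, _ = _clustered_data(rng, n_per_class=15)
        report = cross_validate(X, y, k_folds=9, seed=0, n_components=4)
        assert report.confusion.sum() == len(y)

    def test_fold_count_outside_study_range_needs_explicit_override(self, rng):
        X, y, _ = _clustered_data(rng, n_per_class=10)
        with pytest.raises(ValidationError):
            cross_validate(X, y, k_folds=5, seed=0)
        report = cross_validate(X, y, k_folds=5, seed=0, allow_any_k=True, n_components=4)
        assert report.k_folds == 5

    def test_deterministic_given_seed(self, rng):
        X, y, _ = _clustered_data(rng, n_per_class=15)
        r1 = cross_validate(X, y, k_folds=8, seed=7, n_components=4)
        r2 = cross_validate(X, y, k_folds=8, seed=7, n_components=4)
        assert r1.fold_accuracies == r2.fold_accuracies
        assert np.array_equal(r1.predictions, r2.predictions)


class TestSummedScore:
    def test_all_twos_reach_the_26_point_maximum(self):
        assert summed_score([2] * 13) == 26

    def test_all_zeros_is_the_floor(self):
        assert summed_score([0] * 13) == 0

    def test_mixed_scores_sum_correctly(self):
        assert summed_score([2] * 6 + [1] * 4 + [0] * 3) == 16

    @pytest.mark.parametrize("bad", [[2] * 12, [2] * 14, [3] + [0] * 12])
    def test_contract_violations_rejected(self, bad):
        with pytest.raises(ContractError):
            summed_score(bad)


def _toy_cohort(stages, sums=None, totals=None):
    n = len(stages)
    sums = sums if sums is not None else [2 * i for i in range(n)]
    totals = totals if totals is not None else [min(66, 2 * s + 5) for s in sums]
    rows = []
    for i in range(n):
        per_item = [2] * (sums[i] // 2) + ([1] if sums[i] % 2 else [])
        per_item += [0] * (13 - len(per_item))
        row = {"subject_id": f"P{i}", "side": "left", "hemiplegic": True,
               "brunnstrom_arm": stages[i], "sum_13": sums[i], "total_66": totals[i]}
        for item, score in zip(FMAItem, per_item):
            row[item.value] = score
        rows.append(row)
    return CohortTable(df=pd.DataFrame(rows))


class TestCohortEvaluation:
    def test_perfect_predictions_give_unit_correlation(self):
        cohort = _toy_cohort(stages=[3, 4, 5, 6, 3, 4])
        predicted = {f"P{i}": int(cohort.df.loc[i, "sum_13"]) for i in range(6)}
        ev = evaluate_cohort(predicted, cohort)
        assert ev.pearson_sum13 == pytest.approx(1.0)

    def test_pearson_and_spearman_match_textbook_oracles(self):
        sums = [4, 10, 7, 20, 15, 3]
        cohort = _toy_cohort(stages=[3, 4, 5, 6, 5, 3], sums=sums)
        predicted = {f"P{i}": v for i, v in enumerate([5, 9, 9, 18, 16, 2])}
        jerk = {f"P{i}": (lj, 1.2) for i, lj in enumerate([2.5, 2.0, 1.9, 1.4, 1.6, 2.6])}
        ev = evaluate_cohort(predicted, cohort, jerk)

        x = np.array([predicted[f"P{i}"] for i in range(6)], float)
        y = np.array(sums, float)
        r_oracle = (np.mean(x * y) - x.mean() * y.mean()) / (x.std() * y.std())
        assert ev.pearson_sum13 == pytest.approx(r_oracle, abs=1e-12)

        stages = np.array([3, 4, 5, 6, 5, 3], float)
        lj = np.array([2.5, 2.0, 1.9, 1.4, 1.6, 2.6])
        # average ranks for ties via pandas (independent of scipy's path)
        r_s = pd.Series(stages).rank().to_numpy()
        r_j = pd.Series(lj).rank().to_numpy()
        rho_oracle = ((r_s - r_s.mean()) @ (r_j - r_j.mean())) / (
            np.sqrt(((r_s - r_s.mean()) ** 2).sum() * ((r_j - r_j.mean()) ** 2).sum())
        )
        assert ev.spearman_stage == pytest.approx(rho_oracle, abs=1e-12)

    def test_stage_filter_counts_3_to_6_subgroup(self):
        cohort = _toy_cohort(stages=[2, 3, 4, 6, 6, 1])
        predicted = {f"P{i}": 5 + i for i in range(6)}
        jerk = {f"P{i}": (2.0 + 0.1 * i, 1.2) for i in range(6)}
        ev = evaluate_cohort(predicted, cohort, jerk)
        assert ev.stage_subgroup_n == 4

    def test_unmatched_subjects_are_listed_and_excluded(self):
        cohort = _toy_cohort(stages=[3, 4, 5, 6])
        predicted = {f"P{i}": 5 + i for i in range(4)}
        predicted["GHOST"] = 7
        with pytest.warns(UserWarning, match="GHOST"):
            ev = evaluate_cohort(predicted, cohort)
        assert ev.unmatched_subjects == ["GHOST"]
        assert ev.n_subjects == 4
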