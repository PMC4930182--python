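"""Per-item FMA score prediction and cohort-level evaluation.

Each of the 13 items gets its own predictor with an identical architecture:
per-feature standardization, PCA down to 4-10 components (chosen per item),
and a small feed-forward neural network with one 16-unit logistic hidden
layer and a 3-way softmax output for scores 0/1/2.  Therapist scores are
heavily imbalanced in real cohorts, so minority classes are randomly
oversampled with replacement - inside training folds only, never in test
folds.  Validation is 8- to 10-fold cross-validation with per-fold refits of
the standardization and PCA (no leakage); item accuracy is the fraction of
exact agreements with the reference score.

Cohort evaluation sums the 13 item predictions per subject (0-26), correlates
them with the therapist sums and with the full 66-point upper-extremity
total (Pearson), compares hemiplegic vs non-hemiplegic log jerk scores with
a paired t-test, and correlates hemiplegic log jerk with the Brunnstrom arm
stage (Spearman) in the stage-3-6 subgroup.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .errors import ContractError, RankError, ValidationError
from .motion_io import CohortTable, FMAItem, N_ITEMS
from .features import FeatureVector, ROSTER_VERSION

SCORES = (0, 1, 2)
K_GRID = tuple(range(4, 11))
FOLD_RANGE = (8, 10)


@dataclass
class ANNConfig:
    """Shared network architecture applied identically to every item."""

    hidden_layer_sizes: tuple[int, ...] = (16,)
    activation: str = "logistic"
    alpha: float = 1e-3  # L2 penalty
    max_iter: int = 2000
    solver: str = "lbfgs"


@dataclass
class Reduction:
    """Standardization statistics plus a sign-fixed PCA basis."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray  # (k, n_features)
    explained_variance: np.ndarray

    @property
    def k(self) -> int:
        return self.components.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        return ((np.asarray(X, float) - self.mean) / self.scale) @ self.components.T


def fit_reduction(X: np.ndarray, k: int) -> Reduction:
    """Standardize columns, then fit the top-``k`` principal components.

    Component signs are fixed by convention (largest-magnitude loading
    positive) so the basis is deterministic.  Raises :class:`RankError` when
    ``k`` exceeds the rank of the standardized data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < k + 1:
        raise ValidationError(f"need at least {k + 1} rows to fit {k} components")
    if np.isnan(X).any():
        raise ValidationError("feature matrix contains NaN")
    scaler = StandardScaler().fit(X)
    scaler.scale_[scaler.scale_ == 0] = 1.0  # constant columns carry no signal
    Z = (X - scaler.mean_) / scaler.scale_
    rank = np.linalg.matrix_rank(Z - Z.mean(axis=0))
    if k > rank:
        raise RankError(f"requested {k} components but data rank is {rank}")
    pca = PCA(n_components=k, svd_solver="full").fit(Z)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return Reduction(
        mean=scaler.mean_.copy(),
        scale=scaler.scale_.copy(),
        components=comps,
        explained_variance=pca.explained_variance_.copy(),
    )


def balance_classes(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Random oversampling with replacement of minority classes to the majority count.

    Returns the original rows followed by the resampled extras; intended for
    training folds only.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if len(y) == 0:
        raise ValidationError("cannot balance an empty data set")
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    target = counts.max()
    extra_idx: list[np.ndarray] = []
    for cls, count in zip(classes, counts):
        if count < target:
            pool = np.flatnonzero(y == cls)
            extra_idx.append(rng.choice(pool, size=target - count, replace=True))
    if not extra_idx:
        return X.copy(), y.copy()
    extras = np.concatenate(extra_idx)
    return np.concatenate([X, X[extras]]), np.concatenate([y, y[extras]])


def _make_ann(config: ANNConfig, seed: int) -> MLPClassifier:
    return MLPClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        activation=config.activation,
        alpha=config.alpha,
        max_iter=config.max_iter,
        solver=config.solver,
        random_state=seed,
    )


@dataclass
class ItemScoreModel:
    """Trained per-item predictor: standardization + PCA basis + ANN weights."""

    item: FMAItem
    feature_names: tuple[str, ...]
    reduction: Reduction | None
    ann: MLPClassifier | None
    constant_class: int | None = None  # degenerate single-class training set
    metadata: dict = field(default_factory=dict)

    def _check_names(self, names: Sequence[str]) -> None:
        if tuple(names) != tuple(self.feature_names):
            raise ContractError("feature names do not match the trained model")

    def predict_matrix(self, X: np.ndarray) -> np.ndarray:
        if self.constant_class is not None:
            return np.full(len(X), self.constant_class, dtype=int)
        Z = self.reduction.transform(X)
        proba = self.ann.predict_proba(Z)
        full = np.zeros((len(Z), len(SCORES)))
        for j, cls in enumerate(self.ann.classes_):
            full[:, int(cls)] = proba[:, j]
        # argmax returns the first maximum: ties resolve to the lower score
        return np.argmax(full, axis=1)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "ItemScoreModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, ItemScoreModel):
            raise ContractError(f"{path} does not contain an ItemScoreModel")
        return model


def train_item_model(
    X: np.ndarray,
    y: np.ndarray,
    item: FMAItem,
    feature_names: Sequence[str],
    n_components: int = 8,
    config: ANNConfig | None = None,
    seed: int = 0,
) -> ItemScoreModel:
    """Fit one item model (standardize -> PCA -> ANN), deterministic per seed.

    Resampling for class balance is the caller's responsibility (it belongs
    inside training folds only).  A single-class training set produces a
    constant predictor.  Non-convergence at ``max_iter`` is recorded in the
    metadata rather than raised.
    """
    config = config or ANNConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if not np.isin(y, SCORES).all():
        raise ContractError("labels must be item scores in {0, 1, 2}")
    classes, counts = np.unique(y, return_counts=True)
    meta = {
        "seed": seed,
        "n_components": n_components,
        "config": config,
        "class_counts": dict(zip(classes.tolist(), counts.tolist())),
        "roster_version": ROSTER_VERSION,
        "converged": True,
    }
    if len(classes) == 1:
        return ItemScoreModel(
            item=item, feature_names=tuple(feature_names), reduction=None,
            ann=None, constant_class=int(classes[0]), metadata=meta,
        )
    reduction = fit_reduction(X, n_components)
    ann = _make_ann(config, seed)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        ann.fit(reduction.transform(X), y)
    if any(issubclass(w.category, ConvergenceWarning) for w in caught):
        meta["converged"] = False
        warnings.warn(
            f"{item.value}: ANN did not converge within {config.max_iter} iterations",
            ConvergenceWarning,
            stacklevel=2,
        )
    return ItemScoreModel(
        item=item, feature_names=tuple(feature_names),
        reduction=reduction, ann=ann, metadata=meta,
    )


def predict_item_score(model: ItemScoreModel, fv: FeatureVector) -> int:
    """Score one feature vector with a trained model; output in {0, 1, 2}."""
    model._check_names(fv.names)
    return int(model.predict_matrix(fv.values[None, :])[0])


def _folds(y: np.ndarray, k_folds: int, seed: int):
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k_folds:
        splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        return list(splitter.split(np.zeros(len(y)), y))
    splitter = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    return list(splitter.split(np.zeros(len(y))))


@dataclass
class CVReport:
    """Cross-validation outcome for one item."""

    item: FMAItem | None
    k_folds: int
    fold_accuracies: list[float]
    mean_accuracy: float
    confusion: np.ndarray  # (3, 3), rows = reference score, cols = predicted
    fold_test_indices: list[np.ndarray]
    selected_components: int
    predictions: np.ndarray | None = None  # out-of-fold predictions, input order


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    n_components: int = 8,
    config: ANNConfig | None = None,
    item: FMAItem | None = None,
    allow_any_k: bool = False,
) -> CVReport:
    """Stratified k-fold cross-validation of one item predictor.

    Folds partition every record exactly once (stratified when every class
    has at least ``k_folds`` members, plain shuffled otherwise).  Inside each
    training fold the classes are rebalanced by oversampling and the
    standardization + PCA are refit; the test fold is never touched.  Fold
    accuracy is the fraction of exact score agreements.
    """
    if not allow_any_k and not (FOLD_RANGE[0] <= k_folds <= FOLD_RANGE[1]):
        raise ValidationError(
            f"k_folds must lie in [{FOLD_RANGE[0]}, {FOLD_RANGE[1]}] "
            "(pass allow_any_k=True to override)"
        )
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(y) < k_folds:
        raise ValidationError("need at least one record per fold")
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    folds = _folds(y, k_folds, seed)
    accs: list[float] = []
    test_sets: list[np.ndarray] = []
    oof = np.full(len(y), -1, dtype=int)
    confusion = np.zeros((len(SCORES), len(SCORES)), dtype=int)
    for fold_i, (train_idx, test_idx) in enumerate(folds):
        Xb, yb = balance_classes(X[train_idx], y[train_idx], seed=seed + fold_i)
        model = train_item_model(
            Xb, yb, item or FMAItem.ELBOW_FLEXION, names,
            n_components=n_components, config=config, seed=seed,
        )
        pred = model.predict_matrix(X[test_idx])
        oof[test_idx] = pred
        accs.append(float(np.mean(pred == y[test_idx])))
        for true, p in zip(y[test_idx], pred):
            confusion[true, p] += 1
        test_sets.append(test_idx)
    return CVReport(
        item=item,
        k_folds=k_folds,
        fold_accuracies=accs,
        mean_accuracy=float(np.mean(accs)),
        confusion=confusion,
        fold_test_indices=test_sets,
        selected_components=n_components,
        predictions=oof,
    )


def select_k(
    X: np.ndarray,
    y: np.ndarray,
    grid: Sequence[int] = K_GRID,
    seed: int = 0,
    inner_folds: int = 3,
    config: ANNConfig | None = None,
) -> int:
    """Pick the component count maximizing inner-CV accuracy; ties to smaller k."""
    y = np.asarray(y, dtype=int)
    if np.unique(y).size < 2:
        raise ValidationError("component selection needs at least two classes")
    best_k, best_acc = None, -np.inf
    for k in sorted(grid):
        try:
            report = cross_validate(
                X, y, k_folds=inner_folds, seed=seed, n_components=k,
                config=config, allow_any_k=True,
            )
        except RankError:
            continue
        if report.mean_accuracy > best_acc:
            best_k, best_acc = k, report.mean_accuracy
    if best_k is None:
        raise ValidationError("no component count in the grid was feasible")
    return best_k


def summed_score(predictions: Sequence[int]) -> int:
    """Sum of the 13 item scores; lies in [0, 26]."""
    if len(predictions) != N_ITEMS:
        raise ContractError(f"expected exactly {N_ITEMS} item scores")
    if any(p not in SCORES for p in predictions):
        raise ContractError("every item score must be 0, 1 or 2")
    return int(sum(predictions))


@dataclass
class CohortEvaluation:
    """Cohort-level agreement and smoothness statistics."""

    n_subjects: int
    pearson_sum13: float  # predicted 13-item sum vs therapist 13-item sum
    pearson_sum13_p: float
    pearson_total66: float  # predicted 13-item sum vs 66-point therapist total
    pearson_total66_p: float
    hemiplegic_log_jerk_mean: float
    hemiplegic_log_jerk_sd: float
    nonhemiplegic_log_jerk_mean: float
    nonhemiplegic_log_jerk_sd: float
    paired_t: float
    paired_t_p: float
    spearman_stage: float  # hemiplegic log jerk vs Brunnstrom stage, stages 3-6
    spearman_stage_p: float
    stage_subgroup_n: int
    unmatched_subjects: list[str] = field(default_factory=list)


def evaluate_cohort(
    predicted_sums: Mapping[str, int],
    cohort: CohortTable,
    log_jerk_pairs: Mapping[str, tuple[float, float]] | None = None,
) -> CohortEvaluation:
    """Compare predicted sums with therapist scores and analyze smoothness.

    ``predicted_sums`` maps subject id to the predicted 13-item sum for the
    hemiplegic side; ``log_jerk_pairs`` maps subject id to
    ``(hemiplegic, non-hemiplegic)`` log jerk scores.  Subjects missing on
    either side of a comparison are listed in ``unmatched_subjects`` and
    excluded from that comparison with a warning.
    """
    hemi = cohort.hemiplegic_rows().set_index("subject_id")
    matched = [s for s in predicted_sums if s in hemi.index]
    unmatched = sorted(set(predicted_sums) - set(matched))
    if unmatched:
        warnings.warn(f"subjects without cohort rows excluded: {unmatched}", stacklevel=2)
    if len(matched) < 3:
        raise ValidationError("need at least 3 matched subjects for correlations")

    pred = np.array([predicted_sums[s] for s in matched], dtype=float)
    real13 = hemi.loc[matched, "sum_13"].to_numpy(dtype=float)
    total66 = hemi.loc[matched, "total_66"].to_numpy(dtype=float)
    r13, p13 = stats.pearsonr(pred, real13)
    r66, p66 = stats.pearsonr(pred, total66)

    hj = nhj = np.array([])
    t = tp = rho = rho_p = float("nan")
    sub_n = 0
    if log_jerk_pairs:
        jm = [s for s in matched if s in log_jerk_pairs]
        hj = np.array([log_jerk_pairs[s][0] for s in jm])
        nhj = np.array([log_jerk_pairs[s][1] for s in jm])
        t, tp = stats.ttest_rel(hj, nhj)
        stage = hemi.loc[jm, "brunnstrom_arm"].to_numpy(dtype=int)
        mask = (stage >= 3) & (stage <= 6)
        sub_n = int(mask.sum())
        if sub_n >= 3:
            rho, rho_p = stats.spearmanr(hj[mask], stage[mask])

    return CohortEvaluation(
        n_subjects=len(matched),
        pearson_sum13=float(r13),
        pearson_sum13_p=float(p13),
        pearson_total66=float(r66),
        pearson_total66_p=float(p66),
        hemiplegic_log_jerk_mean=float(hj.mean()) if hj.size else float("nan"),
        hemiplegic_log_jerk_sd=float(hj.std(ddof=1)) if hj.size > 1 else float("nan"),
        nonhemiplegic_log_jerk_mean=float(nhj.mean()) if nhj.size else float("nan"),
        nonhemiplegic_log_jerk_sd=float(nhj.std(ddof=1)) if nhj.size > 1 else float("nan"),
        paired_t=float(t),
        paired_t_p=float(tp),
        spearman_stage=float(rho),
        spearman_stage_p=float(rho_p),
        stage_subgroup_n=sub_n,
        unmatched_subjects=unmatched,
    )
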