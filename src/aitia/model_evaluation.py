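"""Repeated nested stratified cross-validation over a classifier battery.

Protocol: the processed matrix is split into 5 stratified outer folds; each
fold in turn is held out as a test set while a 4-fold stratified inner loop
grid-searches hyperparameters by mean validation AUC.  The winning
configuration is retrained on all non-test data and evaluated on the held
out fold.  The whole procedure repeats 30 times with fresh outer splits,
yielding 150 held-out evaluations per classifier.  Fold assignments depend
only on (seed, repeat), never on the model, so every classifier sees
identical train/test partitions and paired statistical comparison is valid.

Class imbalance is handled by SMOTE applied strictly to training
partitions (outer-train for the final fit, inner-train inside the grid
search); held-out rows are never resampled or rescaled with their own
statistics.  Synthetic minority rows are convex combinations of a minority
record and one of its k minority neighbours on the ordinal encodings,
rounded back to the nearest valid level.

Metrics: accuracy, sensitivity and specificity from the confusion counts
at probability threshold 0.5; AUC from the trapezoidal ROC; and the
FPR/TPR at the optimal operating point, defined as the ROC threshold where
the true positive rate meets 1 minus the false positive rate.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import BaggingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier, NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort_stats import FeatureSet
from .preprocessing import PROCESSED_FEATURES

__all__ = [
    "ModelSpec",
    "CVConfig",
    "CVResult",
    "DEFAULT_GRIDS",
    "default_battery",
    "stratified_folds",
    "smote_upsample",
    "nested_cv",
    "compute_metrics",
    "compare_models",
]

METRIC_NAMES = ["accuracy", "sensitivity", "specificity", "auc", "fpr", "tpr"]

#: Default hyperparameter grids, deliberately small; all configurable.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "logistic_regression": {"C": [0.01, 0.1, 1.0, 10.0]},
    "svm_linear": {"C": [0.01, 0.1, 1.0, 10.0]},
    "knn": {"n_neighbors": [3, 5, 7, 9]},
    "random_forest": {"n_estimators": [100, 300]},
    "xgboost": {"n_estimators": [100], "max_depth": [2, 3]},
    "ensembled_svm": {"C": [0.1, 1.0]},
    "ensembled_knn": {"n_neighbors": [3, 5]},
    "sequential_nn": {"hidden_layer_sizes": [(8,), (16,)]},
}

_KNOWN_CLASSIFIERS = tuple(DEFAULT_GRIDS)


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    classifier_id: str
    grid: Mapping[str, list] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.classifier_id not in _KNOWN_CLASSIFIERS:
            raise ValueError(f"unknown classifier: {self.classifier_id!r}")
        if self.grid is None:
            object.__setattr__(self, "grid", DEFAULT_GRIDS[self.classifier_id])
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    def param_combinations(self) -> list[dict]:
        keys = sorted(self.grid)
        return [dict(zip(keys, vals))
                for vals in itertools.product(*(self.grid[k] for k in keys))]


def default_battery(reduced: bool = True) -> list[ModelSpec]:
    """Reduced battery (logistic, linear SVM, KNN) or the full 8 models."""
    ids = (["logistic_regression", "svm_linear", "knn"] if reduced
           else list(_KNOWN_CLASSIFIERS))
    return [ModelSpec(i) for i in ids]


@dataclasses.dataclass(frozen=True)
class CVConfig:
    outer_folds: int = 5
    inner_folds: int = 4
    repeats: int = 30
    seed: int = 0
    smote: bool = True
    imputation_mode: str = "faithful"

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if self.imputation_mode not in ("faithful", "hygienic"):
            raise ValueError("imputation_mode must be faithful or hygienic")


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold id per record from a shuffled stratified k-fold split."""
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) has fewer members "
                         f"than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(y.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(y.size), y)):
        assignment[test_idx] = fold
    return assignment


def smote_upsample(train_matrix: np.ndarray, train_labels: np.ndarray,
                   k_neighbours: int = 5, seed: int = 0,
                   level_max: np.ndarray | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """SMOTE on ordinal encodings with rounding to the nearest valid level.

    Raises on a singleton minority; reduces k with a warning when the
    minority class is too small for the requested neighbour count.
    """
    X = np.asarray(train_matrix, dtype=float)
    y = np.asarray(train_labels)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("SMOTE requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == 1:
        raise ValueError("cannot SMOTE a singleton minority class")
    if n_min == n_maj:
        return X, y
    k = k_neighbours
    if n_min <= k:
        k = n_min - 1
        warnings.warn(f"minority class of {n_min} <= k; reducing k to {k}")
    rng = np.random.default_rng(seed)
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
    _, idx = nn.kneighbors(Xm)
    idx = idx[:, 1:]
    n_new = n_maj - n_min
    base = rng.integers(0, Xm.shape[0], size=n_new)
    pick = rng.integers(0, k, size=n_new)
    u = rng.random((n_new, 1))
    synth = Xm[base] + u * (Xm[idx[base, pick]] - Xm[base])
    synth = np.round(synth)
    lo = X.min(axis=0)
    hi = X.max(axis=0) if level_max is None else np.asarray(level_max, float)
    synth = np.clip(synth, lo, hi)
    X_out = np.vstack([X, synth])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


def compute_metrics(probabilities: np.ndarray, labels: np.ndarray) -> dict:
    """Metric bundle from per-record scores of the positive class.

    Accuracy/sensitivity/specificity at threshold 0.5, trapezoidal AUC,
    and FPR/TPR at the optimal operating point (TPR = 1 - FPR crossing,
    realised as the threshold minimising |TPR - (1 - FPR)|, ties broken
    toward higher TPR).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    if np.unique(y).size < 2:
        raise ValueError("AUC is undefined with a single class present")
    pred = (p >= 0.5).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    auc = roc_auc_score(y, p)
    fpr_curve, tpr_curve, _ = roc_curve(y, p)
    gap = np.abs(tpr_curve - (1.0 - fpr_curve))
    best = np.lexsort((-tpr_curve, gap))[0]
    return {
        "accuracy": (tp + tn) / (tp + tn + fp + fn),
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
        "auc": float(auc),
        "fpr": float(fpr_curve[best]),
        "tpr": float(tpr_curve[best]),
        "confusion": {"tp": tp, "fp": fp, "tn": tn, "fn": fn},
    }


# --- classifier construction ---------------------------------------------

def _build_model(classifier_id: str, params: dict, seed: int):
    if classifier_id == "logistic_regression":
        return LogisticRegression(max_iter=2000, **params)
    if classifier_id == "svm_linear":
        return SVC(kernel="linear", **params)
    if classifier_id == "knn":
        return KNeighborsClassifier(**params)
    if classifier_id == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    if classifier_id == "xgboost":
        from xgboost import XGBClassifier
        return XGBClassifier(random_state=seed, eval_metric="logloss",
                             n_jobs=1, **params)
    if classifier_id == "ensembled_svm":
        return BaggingClassifier(SVC(kernel="linear", **params),
                                 n_estimators=25, random_state=seed)
    if classifier_id == "ensembled_knn":
        return BaggingClassifier(KNeighborsClassifier(**params),
                                 n_estimators=25, random_state=seed)
    if classifier_id == "sequential_nn":
        return MLPClassifier(max_iter=500, random_state=seed, **params)
    raise ValueError(classifier_id)


def _predict_proba(model, X: np.ndarray) -> np.ndarray:
    """Positive-class score in [0, 1].

    Hard-margin classifiers expose only a decision score; it is mapped
    through a logistic link, which is monotone, so ranking metrics (AUC,
    ROC) are unaffected by the choice.
    """
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    s = model.decision_function(X)
    return 1.0 / (1.0 + np.exp(-s))


def _fit_scaled(model_spec: ModelSpec, params: dict, X_tr: np.ndarray,
                y_tr: np.ndarray, config: CVConfig, seed: int):
    """SMOTE (optional) + train-fold min-max scaling + fit; returns (model, scaler)."""
    if config.smote:
        X_tr, y_tr = smote_upsample(X_tr, y_tr, seed=seed)
    lo = X_tr.min(axis=0)
    rng_ = X_tr.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0
    model = _build_model(model_spec.classifier_id, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence chatter
        model.fit((X_tr - lo) / rng_, y_tr)
    return model, (lo, rng_)


def _scale(X: np.ndarray, scaler: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    lo, rng_ = scaler
    return (X - lo) / rng_


@dataclasses.dataclass
class CVResult:
    metrics: pd.DataFrame               # model,repeat,fold,split + metric cols
    chosen_params: pd.DataFrame         # model,repeat,fold,params(json-ish str)
    oof: dict                           # model -> (n_records, repeats) array
    mean_oof: pd.DataFrame              # record x model mean OOF probability
    fold_assignment: np.ndarray         # (repeats, n_records) outer fold ids
    test_row_checksums: dict            # (repeat, fold) -> sha256 hex
    config: CVConfig

    def to_csv(self, metrics_path, oof_path) -> None:
        self.metrics.to_csv(metrics_path, index=False)
        self.mean_oof.to_csv(oof_path, index=True)


def _row_checksum(X: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()


def nested_cv(matrix: pd.DataFrame, labels: np.ndarray,
              models: Sequence[ModelSpec], feature_set: FeatureSet | Sequence[str],
              config: CVConfig) -> CVResult:
    """Run the repeated nested stratified cross-validation protocol.

    ``matrix`` is the processed design matrix (features only or including
    ``outcome``); ``labels`` the binary outcome (1 = good).  In hygienic
    imputation mode the matrix may still contain missing FAAM/EILP groups,
    which are imputed inside each outer-train partition; in faithful mode
    the matrix must be complete.
    """
    features = list(feature_set.features if isinstance(feature_set, FeatureSet)
                    else feature_set)
    missing_cols = set(features) - set(matrix.columns)
    if missing_cols:
        raise ValueError(f"feature set not in matrix schema: {sorted(missing_cols)}")
    y = np.asarray(labels).astype(int)
    n = y.size

    work = matrix.reset_index(drop=True)
    if config.imputation_mode == "faithful":
        if work[features].isna().any().any():
            raise ValueError("faithful mode requires a pre-imputed matrix")
    X_all = work[features].to_numpy(dtype=float)

    metric_rows, param_rows = [], []
    oof = {m.classifier_id: np.full((n, config.repeats), np.nan) for m in models}
    fold_assignment = np.empty((config.repeats, n), dtype=int)
    checksums: dict[tuple[int, int], str] = {}

    for r in range(config.repeats):
        repeat_seed = (config.seed * 1009 + r) % (2**31 - 1)
        outer = stratified_folds(y, config.outer_folds, repeat_seed)
        fold_assignment[r] = outer
        for fold in range(config.outer_folds):
            test_idx = np.where(outer == fold)[0]
            train_idx = np.where(outer != fold)[0]
            if np.unique(y[test_idx]).size < 2 or np.unique(y[train_idx]).size < 2:
                raise RuntimeError(
                    f"degenerate single-class fold (repeat {r}, fold {fold})")
            if config.imputation_mode == "hygienic":
                from .preprocessing import impute_missing
                imputed = impute_missing(work, mode="hygienic",
                                         train_index=train_idx)
                X = imputed[features].to_numpy(dtype=float)
            else:
                X = X_all
            X_tr, y_tr = X[train_idx], y[train_idx]
            X_te, y_te = X[test_idx], y[test_idx]
            checksums[(r, fold)] = _row_checksum(X_te)
            fold_seed = (repeat_seed * 31 + fold) % (2**31 - 1)
            inner = stratified_folds(y_tr, config.inner_folds, fold_seed)

            for spec in models:
                combos = spec.param_combinations()
                val_store: list[list[tuple[np.ndarray, np.ndarray]]] = []
                mean_aucs = []
                for params in combos:
                    fold_probs = []
                    for ifold in range(config.inner_folds):
                        iv = inner == ifold
                        model, scaler = _fit_scaled(
                            spec, params, X_tr[~iv], y_tr[~iv], config,
                            seed=fold_seed)
                        pv = _predict_proba(model, _scale(X_tr[iv], scaler))
                        fold_probs.append((pv, y_tr[iv]))
                    val_store.append(fold_probs)
                    mean_aucs.append(np.mean(
                        [roc_auc_score(yv, pv) for pv, yv in fold_probs]))
                best_i = int(np.argmax(mean_aucs))
                best_params = combos[best_i]

                model, scaler = _fit_scaled(spec, best_params, X_tr, y_tr,
                                            config, seed=fold_seed)
                p_train = _predict_proba(model, _scale(X_tr, scaler))
                p_test = _predict_proba(model, _scale(X_te, scaler))
                oof[spec.classifier_id][test_idx, r] = p_test

                for split, (pp, yy) in (("train", (p_train, y_tr)),
                                        ("test", (p_test, y_te))):
                    m = compute_metrics(pp, yy)
                    metric_rows.append(dict(model=spec.classifier_id,
                                            repeat=r, fold=fold, split=split,
                                            **{k: m[k] for k in METRIC_NAMES}))
                val_metrics = [compute_metrics(pv, yv)
                               for pv, yv in val_store[best_i]
                               if np.unique(yv).size > 1]
                agg = {k: float(np.mean([vm[k] for vm in val_metrics]))
                       for k in METRIC_NAMES}
                metric_rows.append(dict(model=spec.classifier_id, repeat=r,
                                        fold=fold, split="validation", **agg))
                param_rows.append(dict(model=spec.classifier_id, repeat=r,
                                       fold=fold, params=str(best_params)))

    mean_oof = pd.DataFrame(
        {mid: np.nanmean(arr, axis=1) for mid, arr in oof.items()})
    return CVResult(
        metrics=pd.DataFrame(metric_rows),
        chosen_params=pd.DataFrame(param_rows),
        oof=oof,
        mean_oof=mean_oof,
        fold_assignment=fold_assignment,
        test_row_checksums=checksums,
        config=config,
    )


def compare_models(result: CVResult, metrics: Sequence[str] = ("accuracy", "auc"),
                   alpha: float = 0.05) -> dict:
    """Friedman test across models per metric, Wilcoxon post hoc if significant.

    Operates on the paired per-(repeat, fold) test-set metric vectors; the
    post-hoc threshold is Bonferroni-adjusted to alpha / C(n_models, 2).
    """
    test = result.metrics[result.metrics["split"] == "test"]
    models = sorted(test["model"].unique())
    if len(models) < 2:
        raise ValueError("model comparison needs at least two models")
    report: dict = {}
    n_pairs = len(models) * (len(models) - 1) // 2
    for metric in metrics:
        vectors = {}
        for m in models:
            sub = test[test["model"] == m].sort_values(["repeat", "fold"])
            vectors[m] = sub[metric].to_numpy()
        lengths = {len(v) for v in vectors.values()}
        if len(lengths) != 1:
            raise ValueError("models were not evaluated on identical test sets")
        cols = [vectors[m] for m in models]
        if all(np.allclose(cols[0], c) for c in cols[1:]):
            report[metric] = dict(friedman_stat=0.0, friedman_p=1.0,
                                  posthoc={})
            continue
        stat, p = stats.friedmanchisquare(*cols)
        entry = dict(friedman_stat=float(stat), friedman_p=float(p), posthoc={})
        if p < alpha:
            threshold = alpha / n_pairs
            for a, b in itertools.combinations(models, 2):
                diff = vectors[a] - vectors[b]
                if np.allclose(diff, 0):
                    wp = 1.0
                else:
                    _, wp = stats.wilcoxon(vectors[a], vectors[b])
                entry["posthoc"][f"{a} vs {b}"] = dict(
                    p=float(wp), significant=bool(wp < threshold),
                    threshold=threshold)
        report[metric] = entry
    return report
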