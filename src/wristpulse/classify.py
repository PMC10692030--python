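"""Dataset assembly, SMOTE balancing, and DT/RF cross-validated classification.

Three feature blocks feed the models: Dataset1 = the 21 time-domain features
plus general information (age, sex, BMI); Dataset2 = the 5 MSE features plus
general information; Dataset3 = everything. Class sizes (249, 85, 85) are
equalised with SMOTE before stratified fivefold cross-validation — that
ordering mirrors the published procedure and is the default here, but it
lets synthetic minority samples share neighbours across folds, so
``smote_within_folds=True`` offers the leakage-free variant (SMOTE applied
to each training fold only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.tree import DecisionTreeClassifier

from wristpulse.synthetic import GENERAL_INFO, MSE_FEATURES, TIME_DOMAIN_FEATURES

__all__ = ["DATASET_COLUMNS", "assemble", "smote_balance", "run_cv", "CVResult"]

CLASS_ORDER = (1, 2, 3)

DATASET_COLUMNS: dict[int, list[str]] = {
    1: TIME_DOMAIN_FEATURES + GENERAL_INFO,
    2: MSE_FEATURES + GENERAL_INFO,
    3: TIME_DOMAIN_FEATURES + MSE_FEATURES + GENERAL_INFO,
}

# unstated in the source study; conventional defaults, all overridable
RF_PARAMS = dict(n_estimators=100, max_features="sqrt", max_depth=None)
DT_PARAMS = dict(criterion="gini", max_depth=None)


@dataclass
class CVResult:
    """Aggregated cross-validation outcome for one model/dataset pairing.

    ``matrix`` is indexed [predicted class][actual class] with classes in
    order (1, 2, 3), matching the layout of published confusion tables.
    """

    matrix: np.ndarray
    fold_matrices: list[np.ndarray]
    algorithm: str
    dataset: int | None
    seed: int | None
    labels: tuple[int, ...] = CLASS_ORDER
    extra: dict = field(default_factory=dict)


def assemble(table: pd.DataFrame, dataset: int) -> tuple[np.ndarray, np.ndarray]:
    """Select the feature block of ``dataset`` (1, 2 or 3) as (X, y).

    Column order follows :data:`DATASET_COLUMNS`; sex must already be coded
    0/1. Raises on a missing or incomplete column.
    """
    if dataset not in DATASET_COLUMNS:
        raise ValueError(f"dataset must be 1, 2 or 3, got {dataset}")
    cols = DATASET_COLUMNS[dataset]
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    block = table[cols]
    if block.isna().any().any():
        bad = block.columns[block.isna().any()].tolist()
        raise ValueError(f"missing values in columns: {bad}")
    y = table["group"].to_numpy()
    if not np.isin(y, CLASS_ORDER).all():
        raise ValueError("group labels must be in {1, 2, 3}")
    return block.to_numpy(dtype=float), y.astype(int)


def smote_balance(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Equalise class counts by synthetic-minority oversampling.

    Every minority class is upsampled to the majority count. Each synthetic
    row lies uniformly on the segment between a random minority sample and
    one of its ``k_neighbors`` nearest same-class neighbours (Euclidean);
    original rows are retained unchanged, synthetic rows are appended.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    n_max = counts.max()
    xs = [X]
    ys = [y]
    for cls, cnt in zip(classes, counts):
        deficit = n_max - cnt
        if deficit == 0:
            continue
        if cnt <= k_neighbors:
            raise ValueError(
                f"class {cls} has {cnt} samples, too few for k={k_neighbors} SMOTE"
            )
        Xc = X[y == cls]
        nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, cnt, deficit)
        pick = neigh[base, rng.integers(0, k_neighbors, deficit)]
        gap = rng.uniform(size=(deficit, 1))
        xs.append(Xc[base] + gap * (Xc[pick] - Xc[base]))
        ys.append(np.full(deficit, cls, dtype=y.dtype))
    return np.concatenate(xs), np.concatenate(ys)


def _make_classifier(algorithm: str, seed: int | None):
    algo = algorithm.lower()
    if algo in ("dt", "tree", "decision_tree"):
        return DecisionTreeClassifier(random_state=seed, **DT_PARAMS)
    if algo in ("rf", "forest", "random_forest"):
        return RandomForestClassifier(random_state=seed, **RF_PARAMS)
    raise ValueError(f"unknown algorithm {algorithm!r} (use 'dt' or 'rf')")


def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    """3x3 counts indexed [predicted][actual], classes in CLASS_ORDER."""
    k = len(CLASS_ORDER)
    cm = np.zeros((k, k), dtype=int)
    for p, a in zip(y_pred, y_true):
        cm[CLASS_ORDER.index(p), CLASS_ORDER.index(a)] += 1
    return cm


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    algorithm: str = "rf",
    n_folds: int = 5,
    seed: int | None = 0,
    smote_within_folds: bool = False,
    k_neighbors: int = 5,
    dataset: int | None = None,
) -> CVResult:
    """Stratified k-fold cross-validation; returns the aggregated confusion matrix.

    With the default ordering the caller passes an already SMOTE-balanced
    (X, y); with ``smote_within_folds=True`` pass the raw imbalanced data
    and balancing is applied inside each training fold only, leaving test
    folds untouched.
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_matrices = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        X_tr, y_tr = X[tr], y[tr]
        if smote_within_folds:
            X_tr, y_tr = smote_balance(
                X_tr, y_tr, k_neighbors=k_neighbors,
                seed=None if seed is None else seed + fold,
            )
        clf = _make_classifier(algorithm, seed)
        clf.fit(X_tr, y_tr)
        fold_matrices.append(_confusion(y[te], clf.predict(X[te])))
    total = np.sum(fold_matrices, axis=0)
    return CVResult(
        matrix=total, fold_matrices=fold_matrices,
        algorithm=algorithm, dataset=dataset, seed=seed,
        extra={"smote_within_folds": smote_within_folds, "n_folds": n_folds},
    )
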