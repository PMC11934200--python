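"""Imbalance handling, splitting, CV, randomized search and forest training.

The default protocol oversamples the minority class *before* the 80/20
split, which leaks duplicated minority rows across the split and yields
optimistic internal validation scores; a leakage-safe after-split mode is
provided and `resampling_protocol_auc` measures the optimism directly.
Hyperparameters (number of trees in [50, 500], maximum depth in [1, 20])
are tuned by randomized search scored with mean stratified k-fold ROC-AUC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.utils import resample, shuffle

from .metrics import roc_auc


def upsample_indices(y: np.ndarray, seed: int = 0) -> np.ndarray:
    """Row indices realising minority upsampling to equal class counts.

    Minority rows are resampled with replacement until both classes match
    the majority count; the combined index list is then reshuffled with the
    given seed.  Returning indices (rather than rows) keeps the mapping back
    to the underlying molecules, which the explanation stage needs.
    """
    y = np.asarray(y).astype(int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("upsampling requires both classes present")
    minority = classes[np.argmin(counts)]
    n_major = int(counts.max())
    min_idx = np.flatnonzero(y == minority)
    maj_idx = np.flatnonzero(y != minority)
    up_idx = resample(min_idx, replace=True, n_samples=n_major, random_state=seed)
    return shuffle(np.concatenate([maj_idx, up_idx]), random_state=seed)


def upsample_minority(X: np.ndarray, y: np.ndarray, seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Resample the minority class with replacement to equal class counts."""
    idx = upsample_indices(y, seed=seed)
    y = np.asarray(y).astype(int)
    return X[idx], y[idx]


@dataclass
class SearchSpace:
    """Randomized-search domain for the forest."""

    n_estimators_range: tuple[int, int] = (50, 500)
    max_depth_range: tuple[int, int] = (1, 20)
    n_draws: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def draw(self, rng: np.random.Generator) -> dict[str, int]:
        lo_e, hi_e = self.n_estimators_range
        lo_d, hi_d = self.max_depth_range
        return {
            "n_estimators": int(rng.integers(lo_e, hi_e + 1)),
            "max_depth": int(rng.integers(lo_d, hi_d + 1)),
        }

    def contains(self, params: dict[str, int]) -> bool:
        return (self.n_estimators_range[0] <= params["n_estimators"] <= self.n_estimators_range[1]
                and self.max_depth_range[0] <= params["max_depth"] <= self.max_depth_range[1])


@dataclass
class SplitPlan:
    train_indices: np.ndarray
    validation_indices: np.ndarray
    k: int
    seed: int


def split_train_validation(y: Sequence[int], seed: int = 0, validation_fraction: float = 0.2,
                           k: int = 5) -> SplitPlan:
    """Stratified random split; validation holds ~20% of rows by default."""
    y = np.asarray(y).astype(int)
    idx = np.arange(len(y))
    train_idx, val_idx = train_test_split(idx, test_size=validation_fraction,
                                          random_state=seed, stratify=y)
    return SplitPlan(train_indices=train_idx, validation_indices=val_idx, k=k, seed=seed)


def _new_forest(params: dict[str, int], seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(n_estimators=params["n_estimators"],
                                  max_depth=params["max_depth"],
                                  random_state=seed, n_jobs=1)


def cv_scores(X: np.ndarray, y: np.ndarray, params: dict[str, int], k: int,
              seed: int = 0) -> tuple[list[float], list[float]]:
    """Per-fold validation (ROC-AUC, Brier) of one configuration, stratified k-fold."""
    y = np.asarray(y).astype(int)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs: list[float] = []
    briers: list[float] = []
    for fold, (tr, va) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < 2 or len(np.unique(y[va])) < 2:
            raise ValueError(f"fold {fold} is degenerate (single class)")
        clf = _new_forest(params, seed)
        clf.fit(X[tr], y[tr])
        proba = clf.predict_proba(X[va])[:, list(clf.classes_).index(1)]
        aucs.append(roc_auc(proba, y[va]))
        briers.append(float(np.mean((proba - y[va]) ** 2)))
    return aucs, briers


def cv_roc_auc(X: np.ndarray, y: np.ndarray, params: dict[str, int], k: int,
               seed: int = 0) -> list[float]:
    """Per-fold validation ROC-AUC of one configuration under stratified k-fold."""
    return cv_scores(X, y, params, k, seed)[0]


@dataclass
class SearchResult:
    best_params: dict[str, int]
    best_score: float
    draws: list[dict]  # each: {"params": ..., "fold_scores": [...], "mean": ...}


def search_hyperparameters(X: np.ndarray, y: np.ndarray, space: SearchSpace,
                           k: int = 5) -> SearchResult:
    """Randomized search: ``space.n_draws`` configurations scored by mean CV ROC-AUC.

    Exact ties on the rank-based ROC-AUC (routine on well-separated data)
    are broken by the lower mean cross-validated Brier score, since the
    downstream confidence filter consumes the forest's probabilities and a
    well-ranked but poorly calibrated configuration would starve it.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(space.seed)
    draws = []
    for _ in range(space.n_draws):
        params = space.draw(rng)
        aucs, briers = cv_scores(X, y, params, k=k, seed=space.seed)
        draws.append({"params": params, "fold_scores": aucs, "mean": float(np.mean(aucs)),
                      "mean_brier": float(np.mean(briers))})
    best = max(draws, key=lambda d: (d["mean"], -d["mean_brier"]))
    return SearchResult(best_params=best["params"], best_score=best["mean"], draws=draws)


@dataclass
class ModelHandle:
    """A fitted forest plus the metadata needed to reproduce it."""

    classifier: RandomForestClassifier
    params: dict[str, int]
    seed: int
    train_roc_auc: float = float("nan")
    fold_scores: list[float] = field(default_factory=list)

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        """Class-1 probability (forest vote fraction) per row."""
        proba = self.classifier.predict_proba(X)
        return proba[:, list(self.classifier.classes_).index(1)]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba1(X) >= threshold).astype(int)

    def save(self, path: str | Path) -> None:
        joblib.dump({"classifier": self.classifier, "params": self.params,
                     "seed": self.seed, "train_roc_auc": self.train_roc_auc,
                     "fold_scores": self.fold_scores}, path)

    @classmethod
    def load(cls, path: str | Path) -> "ModelHandle":
        d = joblib.load(path)
        return cls(classifier=d["classifier"], params=d["params"], seed=d["seed"],
                   train_roc_auc=d["train_roc_auc"], fold_scores=d["fold_scores"])


def fit(X: np.ndarray, y: np.ndarray, params: dict[str, int], seed: int = 0,
        space: Optional[SearchSpace] = None,
        fold_scores: Sequence[float] = ()) -> ModelHandle:
    """Fit the forest with the chosen hyperparameters; records training ROC-AUC."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes present")
    if space is not None and not space.contains(params):
        raise ValueError(f"params {params} outside search space")
    clf = _new_forest(params, seed)
    clf.fit(X, y)
    proba = clf.predict_proba(X)[:, list(clf.classes_).index(1)]
    return ModelHandle(classifier=clf, params=params, seed=seed,
                       train_roc_auc=roc_auc(proba, y), fold_scores=list(fold_scores))


def resampling_protocol_auc(X: np.ndarray, y: np.ndarray, seed: int,
                            order: str = "before",
                            params: Optional[dict[str, int]] = None,
                            validation_fraction: float = 0.2) -> float:
    """Internal validation ROC-AUC under one resampling protocol.

    ``order="before"`` upsamples the minority class first and then splits
    (duplicated minority rows can land on both sides — the optimistic,
    leaky protocol); ``order="after"`` splits first and upsamples only the
    training portion.
    """
    params = params or {"n_estimators": 100, "max_depth": 10}
    y = np.asarray(y).astype(int)
    if order == "before":
        Xb, yb = upsample_minority(X, y, seed=seed)
        plan = split_train_validation(yb, seed=seed, validation_fraction=validation_fraction)
        X_tr, y_tr = Xb[plan.train_indices], yb[plan.train_indices]
        X_va, y_va = Xb[plan.validation_indices], yb[plan.validation_indices]
    elif order == "after":
        plan = split_train_validation(y, seed=seed, validation_fraction=validation_fraction)
        X_tr, y_tr = upsample_minority(X[plan.train_indices], y[plan.train_indices], seed=seed)
        X_va, y_va = X[plan.validation_indices], y[plan.validation_indices]
    else:
        raise ValueError("order must be 'before' or 'after'")
    model = fit(X_tr, y_tr, params, seed=seed)
    return roc_auc(model.predict_proba1(X_va), y_va)
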