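"""Feature selection and RBF-SVM classification of cluster feature vectors.

Pipeline: mRMR ranking (MID variant: mutual information relevance minus
mean redundancy over equal-frequency bins), forward stepwise selection on
repeated 4:1 train/validation splits scored by MCC, then a final RBF-SVM
fitted with standardization and a 10-fold cross-validated grid search over
C and gamma in {0.0001, 0.001, 0.01, 0.1, 1, 10, 100, 1000}. Models are
serialized as plain JSON (scaler statistics, kernel parameters, support
data) and evaluated without unpickling anything.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import matthews_corrcoef, mutual_info_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

PARAM_GRID = (0.0001, 0.001, 0.01, 0.1, 1.0, 10.0, 100.0, 1000.0)


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    c_grid: tuple[float, ...] = PARAM_GRID
    gamma_grid: tuple[float, ...] = PARAM_GRID
    cv_folds: int = 10
    split_fraction: float = 0.2  # validation share of the 4:1 split
    split_replicates: int = 10
    selection_epsilon: float = 0.005
    seed: int = 0


@dataclass
class LabeledDataset:
    features: pd.DataFrame
    labels: np.ndarray  # 1 = miRNA, 0 = non-miRNA

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ModelError("feature matrix and labels disagree in length")

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)


def mcc(tp: int, fp: int, tn: int, fn: int) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    if min(tp, fp, tn, fn) < 0:
        raise ModelError("confusion-matrix counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def _discretize(column: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-frequency binning; constant columns collapse to one bin."""
    ranks = rankdata(column, method="average")
    quantile = (ranks - 0.5) / len(column)
    return np.minimum((quantile * n_bins).astype(int), n_bins - 1)


def mrmr_rank(
    dataset: LabeledDataset, n_bins: int = 10
) -> list[tuple[str, float]]:
    """Greedy mRMR (MID) ranking: relevance minus mean redundancy.

    Deterministic: ties break on feature name.
    """
    names = dataset.feature_names
    if len(names) < 2:
        raise ModelError("mRMR needs at least 2 features")
    binned = {
        name: _discretize(dataset.features[name].to_numpy(dtype=float), n_bins)
        for name in names
    }
    y = dataset.labels
    relevance = {name: mutual_info_score(y, binned[name]) for name in names}

    selected: list[tuple[str, float]] = []
    remaining = sorted(names)
    redundancy_sum = {name: 0.0 for name in names}
    while remaining:
        best_name, best_score = None, -np.inf
        for name in remaining:
            redundancy = redundancy_sum[name] / len(selected) if selected else 0.0
            score = relevance[name] - redundancy
            if score > best_score + 1e-15:
                best_name, best_score = name, score
        selected.append((best_name, best_score))
        remaining.remove(best_name)
        for name in remaining:
            redundancy_sum[name] += mutual_info_score(binned[best_name], binned[name])
    return selected


def _split_mcc(
    X: np.ndarray, y: np.ndarray, seed: int, split_fraction: float
) -> float | None:
    """Validation MCC of a standardized default RBF-SVM on one 4:1 split."""
    X_tr, X_va, y_tr, y_va = train_test_split(
        X, y, test_size=split_fraction, random_state=seed, stratify=y
    )
    if len(set(y_tr)) < 2 or len(set(y_va)) < 2:
        logger.warning("degenerate single-class split (seed %d) skipped", seed)
        return None
    scaler = StandardScaler().fit(X_tr)
    clf = SVC(kernel="rbf", C=1.0, gamma="scale", random_state=seed)
    clf.fit(scaler.transform(X_tr), y_tr)
    return matthews_corrcoef(y_va, clf.predict(scaler.transform(X_va)))


def forward_select(
    dataset: LabeledDataset,
    ranked: Sequence[str],
    config: ModelConfig | None = None,
) -> tuple[int, list[str], pd.DataFrame]:
    """Smallest k whose mean validation MCC is within epsilon of the best."""
    config = config or ModelConfig()
    y = dataset.labels
    table = []
    for k in range(1, len(ranked) + 1):
        X = dataset.features[list(ranked[:k])].to_numpy(dtype=float)
        scores = []
        for rep in range(config.split_replicates):
            score = _split_mcc(X, y, config.seed * 1009 + rep, config.split_fraction)
            if score is not None:
                scores.append(score)
        table.append(
            {
                "k": k,
                "mean_mcc": float(np.mean(scores)) if scores else 0.0,
                "sd_mcc": float(np.std(scores)) if scores else 0.0,
            }
        )
    report = pd.DataFrame(table)
    best = report["mean_mcc"].max()
    chosen = int(report.loc[report["mean_mcc"] >= best - config.selection_epsilon, "k"].iloc[0])
    return chosen, list(ranked[:chosen]), report


@dataclass
class TrainedModel:
    feature_names: list[str]  # selected, in order
    all_feature_names: list[str]
    means: np.ndarray
    scales: np.ndarray
    C: float
    gamma: float
    support_vectors: np.ndarray  # standardized space
    dual_coef: np.ndarray
    intercept: float
    seed: int
    training_mcc: float = float("nan")
    cv_mcc: float = float("nan")

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.means) / self.scales
        d2 = (
            (Z * Z).sum(axis=1)[:, None]
            + (self.support_vectors * self.support_vectors).sum(axis=1)[None, :]
            - 2.0 * Z @ self.support_vectors.T
        )
        K = np.exp(-self.gamma * np.maximum(d2, 0.0))
        return K @ self.dual_coef + self.intercept

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "mirquant-svm-1",
            "feature_names": self.feature_names,
            "all_feature_names": self.all_feature_names,
            "means": self.means.tolist(),
            "scales": self.scales.tolist(),
            "C": self.C,
            "gamma": self.gamma,
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "seed": self.seed,
            "training_mcc": self.training_mcc,
            "cv_mcc": self.cv_mcc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "mirquant-svm-1":
            raise ModelError(f"unrecognized model file format in {path}")
        return cls(
            feature_names=payload["feature_names"],
            all_feature_names=payload["all_feature_names"],
            means=np.asarray(payload["means"]),
            scales=np.asarray(payload["scales"]),
            C=payload["C"],
            gamma=payload["gamma"],
            support_vectors=np.asarray(payload["support_vectors"]),
            dual_coef=np.asarray(payload["dual_coef"]),
            intercept=payload["intercept"],
            seed=payload["seed"],
            training_mcc=payload["training_mcc"],
            cv_mcc=payload["cv_mcc"],
        )


def train(
    dataset: LabeledDataset,
    selected: Sequence[str],
    config: ModelConfig | None = None,
) -> TrainedModel:
    """Standardize, grid-search C/gamma by 10-fold CV on MCC, refit."""
    config = config or ModelConfig()
    y = dataset.labels
    if len(set(y)) < 2:
        raise ModelError("training requires both classes")
    X = dataset.features[list(selected)].to_numpy(dtype=float)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    folds = config.cv_folds
    min_class = min(np.bincount(y))
    if min_class < folds:
        logger.warning("reducing CV folds from %d to %d (small class)", folds, min_class)
        folds = max(2, min_class)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=config.seed)
    search = GridSearchCV(
        SVC(kernel="rbf", random_state=config.seed),
        param_grid={"C": list(config.c_grid), "gamma": list(config.gamma_grid)},
        scoring="matthews_corrcoef",
        cv=cv,
        n_jobs=1,
    )
    search.fit(Z, y)
    clf: SVC = search.best_estimator_
    # with classes {0, 1}, sklearn's decision_function is already >0 for class 1
    model = TrainedModel(
        feature_names=list(selected),
        all_feature_names=dataset.feature_names,
        means=scaler.mean_.copy(),
        scales=scaler.scale_.copy(),
        C=float(clf.C),
        gamma=float(clf.gamma),
        support_vectors=clf.support_vectors_.copy(),
        dual_coef=clf.dual_coef_[0].copy(),
        intercept=float(clf.intercept_[0]),
        seed=config.seed,
        cv_mcc=float(search.best_score_),
    )
    model.training_mcc = float(
        matthews_corrcoef(y, (model.decision_function(X) > 0).astype(int))
    )
    return model


def predict(
    model: TrainedModel, vectors: Sequence[dict[str, float]]
) -> list[tuple[float, int]]:
    """(decision value, label) per feature vector; deterministic.

    Unknown feature names are an error; missing selected features are
    imputed as 0 (the convention used for zero-coverage flank features).
    """
    known = set(model.all_feature_names)
    unknown = sorted({k for v in vectors for k in v} - known)
    if unknown:
        raise ModelError(f"unknown feature names: {unknown}")
    X = np.array(
        [[v.get(name, 0.0) for name in model.feature_names] for v in vectors],
        dtype=float,
    )
    if len(X) == 0:
        return []
    decisions = model.decision_function(X)
    return [(float(d), int(d > 0)) for d in decisions]


def quality_score(decision_values: Sequence[float]) -> list[float]:
    """1 - rank percentile, ranked by decision value descending.

    Ties share the mean of their ranks.
    """
    n = len(decision_values)
    if n == 0:
        return []
    ranks = rankdata([-d for d in decision_values], method="average")
    return [1.0 - r / n for r in ranks]
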