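"""Deep/radiomics feature fusion and the six downstream classifiers.

The CNN yields a 4 x 200 feature block per case (one 200-vector per
slice); the block is aggregated to one 200-vector by the per-feature
mean over slices.  Deep features are ranked by mean decrease in
impurity (MDI) averaged over 100 random-forest fits with distinct
seeds, and the top 20 are concatenated with the selected radiomics
features into the 1 x 30 hybrid vector (10 + 20 at the defaults).

Six classifiers are trained on the fused table: KNN, random forest,
logistic regression, RBF support vector machine, one-hidden-layer MLP,
and AdaBoost on decision stumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "MdiRanking",
    "HybridFeatureVector",
    "aggregate_case_features",
    "mdi_rank",
    "fuse",
    "make_classifiers",
    "train_classifiers",
    "CLASSIFIER_NAMES",
]

CLASSIFIER_NAMES = ("KNN", "RF", "LR", "SVM", "MLP", "AdaBoost")
DEEP_DIM = 200
DEFAULT_TOP_K = 20


@dataclass
class MdiRanking:
    mean_importance: np.ndarray  # (200,)
    rank_order: np.ndarray  # feature indices, descending importance
    n_runs: int

    def top(self, k: int) -> np.ndarray:
        return self.rank_order[:k]


@dataclass
class HybridFeatureVector:
    case_id: str
    radiomics_part: dict[str, float]
    deep_part: dict[str, float]
    label: str | int | None = None

    @property
    def values(self) -> dict[str, float]:
        return {**self.radiomics_part, **self.deep_part}

    def __len__(self) -> int:
        return len(self.radiomics_part) + len(self.deep_part)


def aggregate_case_features(deep: np.ndarray) -> np.ndarray:
    """Collapse the (4, 200) slice-wise block to 200 values (mean over slices)."""
    deep = np.asarray(deep, dtype=float)
    if deep.shape != (4, DEEP_DIM):
        raise ValueError(f"expected (4, {DEEP_DIM}), got {deep.shape}")
    return deep.mean(axis=0)


def mdi_rank(X, y, n_runs: int = 100, seed: int = 0,
             n_estimators: int = 100) -> MdiRanking:
    """Average random-forest MDI importance over `n_runs` refits.

    Each forest uses a distinct seed derived from the master seed; the
    per-forest importances are already normalized to sum to 1, and the
    average keeps that normalization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if np.all(X.std(axis=0) == 0):
        raise ValueError("constant feature matrix")
    seeds = np.random.SeedSequence(seed).generate_state(n_runs) % (2**31)
    total = np.zeros(X.shape[1])
    for s in seeds:
        forest = RandomForestClassifier(n_estimators=n_estimators, random_state=int(s))
        forest.fit(X, y)
        total += forest.feature_importances_
    mean_imp = total / n_runs
    order = np.argsort(-mean_imp, kind="stable")
    return MdiRanking(mean_imp, order, n_runs)


def fuse(
    radiomics_selected: dict[str, float],
    deep_ranked: np.ndarray,
    ranking: MdiRanking,
    k: int = DEFAULT_TOP_K,
    case_id: str = "",
    label=None,
) -> HybridFeatureVector:
    """Concatenate selected radiomics features with the top-k deep features."""
    deep_ranked = np.asarray(deep_ranked, dtype=float)
    if deep_ranked.shape != (DEEP_DIM,):
        raise ValueError(f"expected {DEEP_DIM} aggregated deep features")
    if k > DEEP_DIM:
        raise ValueError(f"k={k} exceeds the {DEEP_DIM} deep features")
    deep_part = {f"deep_{int(i):03d}": float(deep_ranked[i]) for i in ranking.top(k)}
    return HybridFeatureVector(case_id, dict(radiomics_selected), deep_part, label)


def fused_table(vectors: list[HybridFeatureVector]) -> pd.DataFrame:
    df = pd.DataFrame([v.values for v in vectors], index=[v.case_id for v in vectors])
    df.index.name = "case_id"
    return df


def make_classifiers(seed: int = 0) -> dict[str, object]:
    """The six models with the package's fixed default hyperparameters."""
    return {
        "KNN": KNeighborsClassifier(n_neighbors=5),
        "RF": RandomForestClassifier(n_estimators=100, random_state=seed),
        "LR": LogisticRegression(max_iter=5000, random_state=seed),
        "SVM": SVC(kernel="rbf", probability=True, random_state=seed),
        "MLP": MLPClassifier(hidden_layer_sizes=(64,), max_iter=2000,
                             random_state=seed),
        "AdaBoost": AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1),
            n_estimators=50, random_state=seed,
        ),
    }


def train_classifiers(X, y, seed: int = 0) -> dict[str, object]:
    """Fit all six classifiers on the (standardized) fused table."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    models = make_classifiers(seed)
    for model in models.values():
        model.fit(X, y)
    return models
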