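"""Feature reproducibility filtering and sparse selection.

Two stages reduce the 1781-column radiomics table to a compact
signature:

1. **ICC filter** — for the subset of subjects delineated by two raters,
   each feature's two-way random-effects, absolute-agreement,
   single-measurement intraclass correlation ICC(2,1) is computed from
   the ANOVA mean squares; features with ICC > 0.8 survive.
2. **LASSO** — L1-penalized logistic regression on the standardized
   surviving features, with the penalty chosen by cross-validated
   deviance (the lambda.min convention); features with nonzero
   coefficients at the chosen penalty are selected.

Standardization statistics are always fit on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "FeatureScaler",
    "SelectionResult",
    "icc",
    "icc_filter",
    "lasso_select",
]


@dataclass
class FeatureScaler:
    """Per-feature zero-mean/unit-variance scaler fit on training rows."""

    mean: pd.Series
    sd: pd.Series

    @classmethod
    def fit(cls, table: pd.DataFrame) -> "FeatureScaler":
        sd = table.std(ddof=0).replace(0.0, 1.0)
        return cls(table.mean(), sd)

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        return (table[self.mean.index] - self.mean) / self.sd


@dataclass
class SelectionResult:
    icc_per_feature: dict[str, float]
    retained_after_icc: list[str]
    lasso_path: list[tuple[float, np.ndarray]]  # (lambda, mean-fold coefficients)
    selected_features: list[str]
    coefficients: dict[str, float]
    scaler: FeatureScaler | None = None


def icc(ratings_rater1, ratings_rater2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA decomposition of the n-subjects x
    2-raters table.  Raises on zero total variance (ICC undefined).
    """
    r1 = np.asarray(ratings_rater1, dtype=float)
    r2 = np.asarray(ratings_rater2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("paired 1D rating vectors required")
    n = r1.size
    if n < 3:
        raise ValueError("need at least 3 subjects")
    data = np.column_stack([r1, r2])
    k = 2
    grand = data.mean()
    if np.allclose(data, grand):
        raise ValueError("zero total variance: ICC undefined")
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    msr = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((rater_means - grand) ** 2) / (k - 1)
    resid = data - subj_means[:, None] - rater_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    return float((msr - mse) / denom)


def icc_filter(
    table_r1: pd.DataFrame, table_r2: pd.DataFrame, threshold: float = 0.8
) -> tuple[list[str], dict[str, float]]:
    """Feature names whose two-rater ICC exceeds `threshold` (strict).

    A column pair that is bit-identical is perfectly reproducible and
    scores 1 even when constant; a non-identical pair with no subject
    variance scores 0.
    """
    if list(table_r1.columns) != list(table_r2.columns):
        raise ValueError("feature columns of the two rater tables differ")
    if list(table_r1.index) != list(table_r2.index):
        raise ValueError("subject rows of the two rater tables differ")
    values: dict[str, float] = {}
    for name in table_r1.columns:
        a = table_r1[name].to_numpy(dtype=float)
        b = table_r2[name].to_numpy(dtype=float)
        if np.array_equal(a, b):
            values[name] = 1.0
            continue
        try:
            values[name] = icc(a, b)
        except ValueError:
            values[name] = 0.0
    # bit-identical columns (value exactly 1) survive any threshold <= 1
    retained = [
        name for name, v in values.items()
        if v > threshold or (v == 1.0 and threshold <= 1.0)
    ]
    return retained, values


def lasso_select(
    X: pd.DataFrame,
    y,
    n_folds: int = 5,
    seed: int = 0,
    cap_to_k: int | None = None,
    Cs: np.ndarray | None = None,
) -> SelectionResult:
    """L1-logistic selection with penalty chosen by CV deviance.

    `X` must already be standardized.  The regularization path is
    reported as (lambda, coefficient-vector) pairs with lambda = 1/C,
    coefficients averaged over CV folds.  With `cap_to_k`, the
    signature is forced to exactly k features: trimmed by |coefficient|
    when the CV optimum selects more, topped up along the path (largest
    maximal |coefficient| first) when it selects fewer.
    """
    X = pd.DataFrame(X)
    y = np.asarray(y, dtype=int)
    if X.isna().to_numpy().any():
        raise ValueError("X contains NaN")
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    if Cs is None:
        Cs = np.logspace(-3, 2, 40)
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    clf = LogisticRegressionCV(
        Cs=Cs,
        cv=cv,
        penalty="l1",
        solver="liblinear",
        scoring="neg_log_loss",
        max_iter=5000,
        refit=True,
        random_state=seed,
    )
    clf.fit(X.to_numpy(), y)
    coef = clf.coef_[0]
    names = list(X.columns)

    fold_paths = next(iter(clf.coefs_paths_.values()))  # (folds, Cs, features+1)
    mean_path = fold_paths.mean(axis=0)[:, : len(names)]
    path = [(1.0 / c, mean_path[i].copy()) for i, c in enumerate(Cs)]
    path.sort(key=lambda t: t[0])  # ascending lambda

    selected = [n for n, c in zip(names, coef) if c != 0.0]
    if cap_to_k is not None:
        order = np.argsort(-np.abs(coef), kind="stable")
        if len(selected) > cap_to_k:
            selected = [names[i] for i in order[:cap_to_k]]
        elif len(selected) < cap_to_k:
            max_abs = np.abs(mean_path).max(axis=0)
            extras = [
                names[i]
                for i in np.argsort(-max_abs, kind="stable")
                if names[i] not in selected
            ]
            selected = selected + extras[: cap_to_k - len(selected)]
    return SelectionResult(
        icc_per_feature={},
        retained_after_icc=names,
        lasso_path=path,
        selected_features=selected,
        coefficients={n: float(c) for n, c in zip(names, coef)},
    )
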