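"""Domestication classifier: standardized OLS on grain length/width/depth.

The model regresses domestication status (wild = 0, domesticated = 1) on
z-score-standardized grain dimensions,

    y = β₀ + β₁·length + β₂·width + β₃·depth + ε,

fit by ordinary least squares on a stratified random 20% training split
and scored on the held-out 80% by

    R² = 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)².

A grain is classified as domesticated when its prediction crosses 0.5.
Standardization parameters come from the training data only, so no
information leaks from the test set.  The ablation experiment refits the
model on every feature subset over one shared split, quantifying how much
of the classification signal each dimension (notably depth) carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import train_test_split

FEATURES = ["length_um", "width_um", "depth_um"]
STATUS_CODES = {"wild": 0, "domesticated": 1}


def encode_status(table: pd.DataFrame) -> np.ndarray:
    """Map the status column to the 0/1 response (wild → 0, domesticated → 1)."""
    status = table["status"]
    unknown = sorted(set(status) - set(STATUS_CODES))
    if unknown:
        raise ValueError(f"unknown status value(s): {unknown}")
    return status.map(STATUS_CODES).to_numpy(dtype=float)


def split_train_test(
    table: pd.DataFrame, train_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random split stratified by status; default 20% train / 80% test."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    counts = table["status"].value_counts()
    if (counts < 2).any():
        small = counts[counts < 2].index.tolist()
        raise ValueError(f"status class(es) with < 2 records: {small}")
    encode_status(table)  # validates the labels
    train, test = train_test_split(
        table,
        train_size=train_fraction,
        random_state=seed,
        stratify=table["status"],
        shuffle=True,
    )
    return train.copy(), test.copy()


@dataclass
class DomesticationFit:
    """A fitted standardized-OLS domestication model."""

    features: list[str]
    coefficients: dict[str, float]  # includes "intercept"
    train_means: np.ndarray
    train_sds: np.ndarray
    train_index: pd.Index
    seed: int | None = None
    model: object = field(default=None, repr=False)

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.features if f not in table.columns]
        if missing:
            raise ValueError(f"missing feature column(s): {missing}")
        x = (np.asarray(table[self.features], float) - self.train_means) / self.train_sds
        beta = np.array([self.coefficients[f] for f in self.features])
        return self.coefficients["intercept"] + x @ beta


def fit(
    train: pd.DataFrame,
    features=FEATURES,
    seed: int | None = None,
    response: np.ndarray | None = None,
) -> DomesticationFit:
    """Fit the standardized OLS model on a training table.

    Features are z-scored with training means/SDs; the response is the 0/1
    status encoding unless an explicit ``response`` vector is given.
    Constant or collinear features are an error.
    """
    features = list(features)
    if not set(features) <= set(FEATURES):
        raise ValueError(f"features must be a subset of {FEATURES}")
    if len(train) < len(features) + 2:
        raise ValueError("too few training records")
    y = encode_status(train) if response is None else np.asarray(response, dtype=float)
    x = np.asarray(train[features], dtype=float)
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    constant = [f for f, s in zip(features, sds) if s == 0]
    if constant:
        raise ValueError(f"constant feature(s): {constant}")
    xs = (x - means) / sds
    design = sm.add_constant(xs, has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        for drop in range(len(features)):
            cols = np.delete(xs, drop, axis=1)
            if np.linalg.matrix_rank(sm.add_constant(cols)) == cols.shape[1] + 1:
                raise ValueError(f"collinear feature: {features[drop]}")
        raise ValueError("collinear features")
    ols = sm.OLS(y, design).fit()
    coeffs = {"intercept": float(ols.params[0])}
    coeffs.update({f: float(b) for f, b in zip(features, ols.params[1:])})
    return DomesticationFit(
        features=features,
        coefficients=coeffs,
        train_means=means,
        train_sds=sds,
        train_index=train.index,
        seed=seed,
        model=ols,
    )


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination: 1 − Σ(yᵢ − ŷᵢ)² / Σ(yᵢ − ȳ)²."""
    y = np.asarray(y_true, dtype=float)
    p = np.asarray(y_pred, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 values")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("constant y_true: R² undefined")
    return 1.0 - float(np.sum((y - p) ** 2)) / sst


@dataclass
class Evaluation:
    r_squared: float
    accuracy: float
    predictions: np.ndarray
    classifications: np.ndarray
    misclassified: pd.DataFrame  # grain rows with boundary distance


def evaluate(
    fitted: DomesticationFit, test: pd.DataFrame, threshold: float = 0.5
) -> Evaluation:
    """Score a fitted model on held-out records.

    R² is computed against the 0/1 status labels; classification is
    ŷ ≥ threshold.  Misclassified records are reported with their distance
    from the decision boundary (they tend to sit close to it).  Test
    records overlapping the training set are an error.
    """
    overlap = fitted.train_index.intersection(test.index)
    if len(overlap):
        raise ValueError(f"test set overlaps training set ({len(overlap)} records)")
    y = encode_status(test)
    preds = fitted.predict(test)
    classes = (preds >= threshold).astype(int)
    wrong = classes != y
    mis = test.loc[wrong, [c for c in ("grain_id", "status") if c in test.columns]].copy()
    mis["prediction"] = preds[wrong]
    mis["boundary_distance"] = np.abs(preds[wrong] - threshold)
    return Evaluation(
        r_squared=r_squared(y, preds),
        accuracy=float((classes == y).mean()),
        predictions=preds,
        classifications=classes,
        misclassified=mis,
    )


@dataclass
class AblationReport:
    """Held-out R² (and accuracy) per feature subset, on one shared split."""

    r_squared: dict[tuple[str, ...], float]
    accuracy: dict[tuple[str, ...], float]
    train_fraction: float
    seed: int
    test_index: pd.Index


def ablation(
    table: pd.DataFrame, seed: int = 0, train_fraction: float = 0.2
) -> AblationReport:
    """Refit and score the model on every non-empty feature subset.

    One stratified split is drawn once and reused across subsets, so the
    R² values are directly comparable.
    """
    train, test = split_train_test(table, train_fraction, seed)
    r2: dict[tuple[str, ...], float] = {}
    acc: dict[tuple[str, ...], float] = {}
    for k in range(len(FEATURES), 0, -1):
        for subset in combinations(FEATURES, k):
            ev = evaluate(fit(train, list(subset), seed=seed), test)
            r2[subset] = ev.r_squared
            acc[subset] = ev.accuracy
    return AblationReport(
        r_squared=r2,
        accuracy=acc,
        train_fraction=train_fraction,
        seed=seed,
        test_index=test.index,
    )
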