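"""Two-feature (ΔΔG, RSA) regularized logistic classifier.

Protocol: classes are balanced by a seeded subsample of the majority class;
the balanced set is split 80/20 (stratified); the regularization strength c
is selected on the training portion by repeated stratified 5-fold
cross-validation (fold assignments reshuffled each repetition), scored by
mean validation AUC, ties broken toward the smaller c (stronger
regularization); the final model is refit on the full training portion at
the selected c.

Features are standardized with training-portion statistics only, so the
kcal/mol ΔΔG scale and the [0,1] RSA scale are comparable under the shared
L2 penalty; the standardization constants are stored on the model so
prediction is self-contained.  The fit itself is scikit-learn's lbfgs
L2-penalized logistic regression (tol 1e-8), which maximizes the
log-likelihood minus ‖w‖²/(2c).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .evaluate import ConfusionCounts, auc_concordance, mcc

__all__ = ["LogisticModel", "SplitProtocol", "FeatureSpec", "fit_logistic",
           "select_c", "train_eval"]


def _default_c_grid() -> tuple[float, ...]:
    return tuple(np.logspace(-3, 3, 13))


@dataclass(frozen=True)
class LogisticModel:
    """A fitted standardized logistic model.

    ``weights`` and ``intercept`` act on standardized features
    (x − mean) / sd; predicted probability is the logistic function of the
    linear score.
    """

    feature_names: tuple[str, ...]
    weights: np.ndarray
    intercept: float
    c: float
    feature_mean: np.ndarray
    feature_sd: np.ndarray

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        z = (X - self.feature_mean) / self.feature_sd
        t = z @ self.weights + self.intercept
        return 1.0 / (1.0 + np.exp(-t))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(X) >= threshold).astype(int)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "weights": self.weights.tolist(),
            "intercept": self.intercept,
            "c": self.c,
            "feature_mean": self.feature_mean.tolist(),
            "feature_sd": self.feature_sd.tolist(),
        }


@dataclass(frozen=True)
class SplitProtocol:
    """Split and hyperparameter-selection protocol.

    Defaults mirror the full study protocol: 80/20 train/test split,
    stratified 5-fold cross-validation repeated 100 times per candidate c,
    13-point log-spaced c grid over [1e−3, 1e3].
    """

    train_fraction: float = 0.8
    cv_folds: int = 5
    cv_repeats: int = 100
    c_grid: tuple[float, ...] = field(default_factory=_default_c_grid)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.cv_repeats < 1:
            raise ValueError("cv_repeats must be >= 1")
        if len(self.c_grid) == 0:
            raise ValueError("c_grid must be non-empty")


@dataclass(frozen=True)
class FeatureSpec:
    """Which ΔΔG source feeds the model and whether RSA is included.

    ``ddg_predictors`` of length > 1 means the ensemble average of those
    columns is used as the single ΔΔG feature.
    """

    ddg_predictors: tuple[str, ...] = ("ddg_p1",)
    include_rsa: bool = True

    def build(self, df: pd.DataFrame) -> tuple[np.ndarray, tuple[str, ...]]:
        cols = []
        names = []
        ddg = df[list(self.ddg_predictors)].mean(axis=1).to_numpy()
        cols.append(ddg)
        names.append("ddg:" + "+".join(self.ddg_predictors))
        if self.include_rsa:
            cols.append(df["rsa"].to_numpy())
            names.append("rsa")
        return np.column_stack(cols), tuple(names)


def fit_logistic(
    X, labels, c: float, feature_names: tuple[str, ...] | None = None
) -> LogisticModel:
    """Fit an L2-regularized logistic model at regularization strength c."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    if c <= 0:
        raise ValueError("c must be > 0")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature value")
    if y.min() == y.max():
        raise ValueError("need both classes to fit")

    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mean) / sd
    est = LogisticRegression(C=c, solver="lbfgs", tol=1e-8, max_iter=10_000)
    est.fit(Z, y)
    names = feature_names or tuple(f"x{i}" for i in range(X.shape[1]))
    return LogisticModel(
        feature_names=names,
        weights=est.coef_[0].copy(),
        intercept=float(est.intercept_[0]),
        c=float(c),
        feature_mean=mean,
        feature_sd=sd,
    )


def select_c(X, labels, protocol: SplitProtocol) -> tuple[float, dict[float, float]]:
    """Choose c by repeated stratified k-fold CV, scored by mean validation
    AUC; ties break toward smaller c.  Returns (best_c, {c: mean AUC})."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels, dtype=int)
    if y.min() == y.max():
        raise ValueError("need both classes")
    rng = np.random.default_rng(protocol.seed)

    # one fold plan per repetition, shared across the c grid so the
    # comparison between c values is paired
    plans = []
    for _ in range(protocol.cv_repeats):
        skf = StratifiedKFold(
            n_splits=protocol.cv_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        plans.append(list(skf.split(X, y)))

    mean_auc: dict[float, float] = {}
    for c in protocol.c_grid:
        aucs = []
        for plan in plans:
            for train_idx, val_idx in plan:
                model = fit_logistic(X[train_idx], y[train_idx], c)
                p = model.predict_proba(X[val_idx])
                aucs.append(
                    auc_concordance(p, y[val_idx], higher_is_pathogenic=True)
                )
        mean_auc[float(c)] = float(np.mean(aucs))

    best = max(sorted(mean_auc), key=lambda c: (mean_auc[c], -c))
    return best, mean_auc


def _balance(df: pd.DataFrame, label_col: str, rng: np.random.Generator) -> pd.DataFrame:
    pos = df[df[label_col] == 1]
    neg = df[df[label_col] == 0]
    n = min(len(pos), len(neg))
    if n == 0:
        raise ValueError("need both classes to balance")
    take_pos = pos.iloc[np.sort(rng.choice(len(pos), size=n, replace=False))]
    take_neg = neg.iloc[np.sort(rng.choice(len(neg), size=n, replace=False))]
    return pd.concat([take_neg, take_pos])


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train_parts, test_parts = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        k = int(round(train_fraction * len(idx)))
        train_parts.append(idx[:k])
        test_parts.append(idx[k:])
    return np.sort(np.concatenate(train_parts)), np.sort(np.concatenate(test_parts))


def train_eval(
    dataset: pd.DataFrame,
    feature_spec: FeatureSpec,
    protocol: SplitProtocol,
    label_col: str = "label",
) -> dict:
    """Balance → 80/20 stratified split → select c on the training portion →
    final fit → report train/test AUC and MCC at probability threshold 0.5.

    Returns a report dict with keys train_auc, test_auc, train_mcc,
    test_mcc, c, n_train, n_test and the fitted ``model``.
    """
    rng = np.random.default_rng(protocol.seed)
    balanced = _balance(dataset, label_col, rng)
    X, names = feature_spec.build(balanced)
    y = balanced[label_col].to_numpy()
    if len(np.unique(y)) < 2 or min((y == 0).sum(), (y == 1).sum()) < protocol.cv_folds:
        raise ValueError("insufficient data after balancing")

    train_idx, test_idx = _stratified_split(y, protocol.train_fraction, rng)
    best_c, cv_scores = select_c(X[train_idx], y[train_idx], protocol)
    model = fit_logistic(X[train_idx], y[train_idx], best_c, names)

    report: dict = {"c": best_c, "cv_mean_auc": cv_scores, "model": model,
                    "n_train": int(len(train_idx)), "n_test": int(len(test_idx))}
    for part, idx in (("train", train_idx), ("test", test_idx)):
        p = model.predict_proba(X[idx])
        pred = (p >= 0.5).astype(int)
        yy = y[idx]
        counts = ConfusionCounts(
            tp=int(((pred == 1) & (yy == 1)).sum()),
            tn=int(((pred == 0) & (yy == 0)).sum()),
            fp=int(((pred == 1) & (yy == 0)).sum()),
            fn=int(((pred == 0) & (yy == 1)).sum()),
        )
        report[f"{part}_auc"] = auc_concordance(p, yy, higher_is_pathogenic=True)
        report[f"{part}_mcc"] = mcc(counts)
    return report
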