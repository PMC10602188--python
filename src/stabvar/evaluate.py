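"""Threshold classification, MCC, ROC/AUC and balanced resampling.

Score orientation
-----------------
Both scores used in this pipeline point the same way: pathogenicity rises
as the score *falls* (more negative ΔΔG = more destabilizing; lower RSA =
more buried).  Threshold rules therefore default to ``pathogenic_if_le``:
a variant is called pathogenic when its score is less than or equal to the
cutoff (the boundary itself predicts pathogenic).  ROC/AUC functions take
an explicit ``higher_is_pathogenic`` flag instead, defaulting to False.

AUC is computed two ways that are algebraically identical and are asserted
against each other in the test suite: the pairwise-concordance
(Mann–Whitney) estimator — the fraction of (pathogenic, benign) pairs
ranked correctly, ties counting half — and the trapezoidal area under the
ROC curve swept over the unique score values.

The Matthews correlation coefficient uses the standard form
MCC = (tp·tn − fp·fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)), with the
convention that a zero denominator factor yields MCC = 0.

The MCC-optimal threshold is found by exhaustive scan over midpoints of
consecutive sorted unique scores plus below-min and above-max sentinels;
ties are broken toward the smallest |threshold|, then the smaller
threshold.  The optimal threshold is calibrated on the full dataset and
then reused inside balanced resampling — a deliberate (and documented)
reproduction of the upstream protocol, including its information leakage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "RocResult",
    "ResamplingSummary",
    "confusion",
    "mcc",
    "auc_concordance",
    "roc_curve",
    "optimal_threshold",
    "balanced_resample_evaluate",
    "stratified_auc",
]

RULES = ("pathogenic_if_le", "pathogenic_if_ge")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def tpr(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def fpr(self) -> float:
        return self.fp / (self.fp + self.tn) if self.fp + self.tn else float("nan")

    @property
    def fnr(self) -> float:
        return 1.0 - self.tpr

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else float("nan")


@dataclass(frozen=True)
class RocResult:
    """Operating points sorted by threshold (descending pathogenicity
    stringency) plus the trapezoidal AUC."""

    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "tpr": self.tpr, "fpr": self.fpr}
        )


@dataclass(frozen=True)
class ResamplingSummary:
    """Mean ± sd of TPR/FPR/FNR/accuracy over balanced resampling repeats."""

    mean: dict[str, float]
    sd: dict[str, float]
    n_repeats: int
    n_per_class: int

    def to_dict(self) -> dict:
        return {
            "mean": self.mean,
            "sd": self.sd,
            "n_repeats": self.n_repeats,
            "n_per_class": self.n_per_class,
        }


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-D arrays of equal length")
    if s.size == 0:
        raise ValueError("empty input")
    if not np.isfinite(s).all():
        raise ValueError("scores must be finite")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be 0/1")
    return s, y


def _predict(scores: np.ndarray, threshold: float, rule: str) -> np.ndarray:
    if rule == "pathogenic_if_le":
        return scores <= threshold
    if rule == "pathogenic_if_ge":
        return scores >= threshold
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


def confusion(
    scores, labels, threshold: float, rule: str = "pathogenic_if_le"
) -> ConfusionCounts:
    """Confusion counts under a threshold rule.

    With ``pathogenic_if_le`` a variant is predicted pathogenic iff its
    score ≤ threshold; true positives are pathogenic variants predicted
    pathogenic, true negatives benign variants predicted benign.
    """
    s, y = _validate_scores_labels(scores, labels)
    pred = _predict(s, threshold, rule)
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any denominator factor is 0."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def auc_concordance(scores, labels, higher_is_pathogenic: bool = False) -> float:
    """Pairwise-concordance (Mann–Whitney) AUC estimator.

    Mean over all (pathogenic, benign) pairs of 1 if the pathogenic case is
    ranked more pathogenic, 0.5 on a tie.  Computed via midranks, so it is
    O(n log n) and exact under ties.
    """
    s, y = _validate_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need at least one case of each class")
    oriented = s if higher_is_pathogenic else -s
    ranks = rankdata(oriented)  # midranks handle ties as 0.5 per pair
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores, labels, higher_is_pathogenic: bool = False) -> RocResult:
    """ROC sweep over the unique score values plus sentinels.

    The returned AUC is the trapezoidal area, which agrees with
    :func:`auc_concordance` to floating-point precision (an invariant the
    test suite asserts).
    """
    s, y = _validate_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC undefined: need at least one case of each class")
    oriented = s if higher_is_pathogenic else -s

    order = np.argsort(-oriented, kind="mergesort")
    so = oriented[order]
    yo = y[order]
    # collapse tied scores into single operating points
    distinct = np.r_[np.diff(so) != 0, True]
    ctp = np.cumsum(yo)[distinct]
    cfp = np.cumsum(1 - yo)[distinct]
    tpr = np.r_[0.0, ctp / n_pos]
    fpr = np.r_[0.0, cfp / n_neg]
    thresholds = np.r_[np.inf, so[distinct]]
    if not higher_is_pathogenic:
        thresholds = -thresholds  # back to the original score scale
    auc = float(np.trapezoid(tpr, fpr))
    return RocResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def _candidate_thresholds(scores: np.ndarray) -> np.ndarray:
    """Midpoints between consecutive sorted unique scores plus sentinels
    strictly below the minimum and above the maximum."""
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.r_[u[0] - 1.0, mids, u[-1] + 1.0]


def optimal_threshold(
    scores, labels, rule: str = "pathogenic_if_le"
) -> tuple[float, float]:
    """Exhaustive MCC-maximizing threshold scan.

    Returns (threshold, best_mcc).  Ties on MCC break toward the smallest
    absolute threshold, then toward the smaller threshold value.
    """
    s, y = _validate_scores_labels(scores, labels)
    if y.min() == y.max():
        raise ValueError("optimal_threshold: need both classes present")
    if rule not in RULES:
        raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")

    candidates = _candidate_thresholds(s)
    # vectorized confusion counts over all candidates
    pos = s[y == 1]
    neg = s[y == 0]
    n_pos, n_neg = pos.size, neg.size
    pos_sorted = np.sort(pos)
    neg_sorted = np.sort(neg)
    if rule == "pathogenic_if_le":
        tp = np.searchsorted(pos_sorted, candidates, side="right")
        fp = np.searchsorted(neg_sorted, candidates, side="right")
    else:
        tp = n_pos - np.searchsorted(pos_sorted, candidates, side="left")
        fp = n_neg - np.searchsorted(neg_sorted, candidates, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    num = tp * tn - fp * fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore", divide="ignore"):
        mccs = np.where(denom > 0, num / np.sqrt(denom.astype(float)), 0.0)

    best = mccs.max()
    tied = np.flatnonzero(np.isclose(mccs, best, rtol=0, atol=1e-12))
    tied = tied[np.lexsort((candidates[tied], np.abs(candidates[tied])))]
    idx = tied[0]
    return float(candidates[idx]), float(mccs[idx])


def balanced_resample_evaluate(
    labels,
    predictions=None,
    *,
    scores=None,
    threshold: float | None = None,
    rule: str = "pathogenic_if_le",
    n_repeats: int = 100,
    seed: int | np.random.Generator = 0,
) -> ResamplingSummary:
    """Repeated evaluation on balanced benign/pathogenic subsamples.

    Per repeat, N benign and N pathogenic variants are drawn uniformly
    without replacement with N = floor(0.5 · min(n_benign, n_pathogenic)),
    and TPR, FPR, FNR and accuracy are computed on the subsample; the
    summary reports their means and standard deviations over ``n_repeats``.

    The classifier is supplied either as a 0/1 ``predictions`` array
    aligned with ``labels`` (e.g. from a fitted model) or as a fixed
    ``scores`` + ``threshold`` rule.  Because the threshold is calibrated
    once on the full dataset, per-variant predictions are constant across
    repeats, so precomputing them is exact.
    """
    y = np.asarray(labels, dtype=int)
    if predictions is None:
        if scores is None or threshold is None:
            raise ValueError("provide either predictions or scores+threshold")
        pred = _predict(np.asarray(scores, dtype=float), threshold, rule)
    else:
        pred = np.asarray(predictions).astype(bool)
    if pred.shape != y.shape:
        raise ValueError("predictions and labels must align")

    pos_idx = np.flatnonzero(y == 1)
    neg_idx = np.flatnonzero(y == 0)
    n = min(pos_idx.size, neg_idx.size) // 2
    if n == 0:
        raise ValueError("insufficient data: balanced sample size N is 0")

    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    stats = {k: np.empty(n_repeats) for k in ("tpr", "fpr", "fnr", "accuracy")}
    for r in range(n_repeats):
        take_pos = rng.choice(pos_idx, size=n, replace=False)
        take_neg = rng.choice(neg_idx, size=n, replace=False)
        tp = int(pred[take_pos].sum())
        fp = int(pred[take_neg].sum())
        stats["tpr"][r] = tp / n
        stats["fpr"][r] = fp / n
        stats["fnr"][r] = (n - tp) / n
        stats["accuracy"][r] = (tp + (n - fp)) / (2 * n)

    return ResamplingSummary(
        mean={k: float(v.mean()) for k, v in stats.items()},
        sd={k: float(v.std(ddof=1)) if n_repeats > 1 else 0.0 for k, v in stats.items()},
        n_repeats=n_repeats,
        n_per_class=n,
    )


def stratified_auc(
    variants: pd.DataFrame,
    grouping: str,
    score: str,
    label_col: str = "label",
    min_count: int = 100,
    higher_is_pathogenic: bool = False,
) -> pd.DataFrame:
    """Per-group AUC table for groups with n strictly greater than
    ``min_count`` and both classes present.

    ``grouping`` is a column name (a substitution-category axis such as
    ``cat_hydropathy``, or ``functional_class``); ``score`` is the score
    column.  Returns a DataFrame with columns (group, n, auc), possibly
    empty.
    """
    if grouping not in variants.columns:
        raise ValueError(f"grouping column {grouping!r} not present")
    rows = []
    for group, grp in variants.dropna(subset=[grouping]).groupby(grouping, sort=True):
        if len(grp) <= min_count:
            continue
        y = grp[label_col].to_numpy()
        if y.min() == y.max():
            continue
        rows.append(
            {
                "group": group,
                "n": len(grp),
                "auc": auc_concordance(
                    grp[score].to_numpy(), y, higher_is_pathogenic
                ),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "auc"])
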