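"""Supervised edge weighting: c-edge / nc-edge labels, CV, and the LE-PIN.

An interaction is a *c-edge* when its two proteins co-occur in at least
one gold-standard complex, an *nc-edge* when both proteins belong to the
gold-standard universe but never share a complex, and *unlabeled*
otherwise.  A probabilistic classifier trained on labeled edges assigns
every edge the probability of being a c-edge; those probabilities become
the weights of the labeled-edge PIN (LE-PIN) that complex detection
consumes.

Because nc-edges vastly outnumber c-edges, cross-validation uses a
sub-sampling strategy: each training round pairs nine c-edge subsets with
an equal-size random draw from the nine nc-edge subsets (1:1 balance),
and everything else is tested on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .complexes import ComplexSet
from .pin_core import WeightedPIN

logger = logging.getLogger(__name__)

C_EDGE, NC_EDGE, UNLABELED = "c-edge", "nc-edge", "unlabeled"


@dataclass(frozen=True)
class EdgeLabel:
    u: str
    v: str
    label: str


class ClassifierContract(Protocol):
    """Anything with fit / predict_probability of being a c-edge."""

    def fit(self, features: np.ndarray, labels: np.ndarray) -> "ClassifierContract": ...

    def predict_probability(self, features: np.ndarray) -> np.ndarray: ...


class GradientBoostedEdgeClassifier:
    """Default edge classifier: a gradient-boosted tree ensemble (LightGBM).

    Deterministic given ``seed``: single-threaded, deterministic
    histogram construction.
    """

    def __init__(self, seed: int = 0, n_estimators: int = 200, **kwargs):
        from lightgbm import LGBMClassifier
        self._model = LGBMClassifier(
            n_estimators=n_estimators, random_state=seed, n_jobs=1,
            deterministic=True, force_row_wise=True, verbosity=-1, **kwargs)

    def fit(self, features, labels):
        self._model.fit(np.asarray(features), np.asarray(labels))
        return self

    def predict_probability(self, features) -> np.ndarray:
        import warnings
        with warnings.catch_warnings():
            # lightgbm's sklearn wrapper warns about feature names even
            # when both fit and predict receive plain arrays
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names")
            return self._model.predict_proba(np.asarray(features))[:, 1]


@dataclass
class ConfusionCounts:
    """Positives are c-edges."""

    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_prob: np.ndarray,
                         threshold: float = 0.5) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(bool)
        pred = np.asarray(y_prob) > threshold
        return cls(TP=int(np.sum(pred & y_true)),
                   FP=int(np.sum(pred & ~y_true)),
                   TN=int(np.sum(~pred & ~y_true)),
                   FN=int(np.sum(~pred & y_true)))


@dataclass
class ClassificationReport:
    ACC: float
    SEN: float
    SPE: float
    PRE: float
    F1: float
    MCC: float
    AUC: float | None = None

    def as_dict(self) -> dict[str, float]:
        d = {"ACC": self.ACC, "SEN": self.SEN, "SPE": self.SPE,
             "PRE": self.PRE, "F1": self.F1, "MCC": self.MCC}
        if self.AUC is not None:
            d["AUC"] = self.AUC
        return d


def label_edges(pin: WeightedPIN, gold: ComplexSet) -> list[EdgeLabel]:
    """Label every PIN edge as c-edge, nc-edge or unlabeled.

    Uses the gold universe (union of complex members) and pairwise
    co-membership; class counts are logged.
    """
    universe = gold.proteins()
    co_member: set[frozenset[str]] = set()
    for c in gold:
        members = sorted(c.members)
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                co_member.add(frozenset((a, b)))
    out = []
    counts = {C_EDGE: 0, NC_EDGE: 0, UNLABELED: 0}
    for u, v in pin.edges():
        pair = frozenset((u, v))
        if pair in co_member:
            lab = C_EDGE
        elif u in universe and v in universe:
            lab = NC_EDGE
        else:
            lab = UNLABELED
        counts[lab] += 1
        out.append(EdgeLabel(u, v, lab))
    logger.info("edge labels: %d c-edges, %d nc-edges, %d unlabeled",
                counts[C_EDGE], counts[NC_EDGE], counts[UNLABELED])
    return out


def rank_auc(y_true: Sequence[int] | np.ndarray,
             scores: Sequence[float] | np.ndarray) -> float:
    """AUC via the rank-sum (Mann–Whitney) formulation; ties share ranks."""
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def classification_metrics(cc: ConfusionCounts,
                           y_true: np.ndarray | None = None,
                           scores: np.ndarray | None = None
                           ) -> ClassificationReport:
    """Accuracy, sensitivity, specificity, precision, F1, MCC (and AUC).

    Degenerate denominators (no predicted positives for PRE, zero MCC
    denominator) yield 0 with a warning.  AUC is computed from ``scores``
    against ``y_true`` when both are given.
    """
    if cc.total == 0:
        raise ValueError("empty confusion table")
    tp, fp, tn, fn = cc.TP, cc.FP, cc.TN, cc.FN
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("sensitivity/specificity need both classes present")
    acc = (tp + tn) / cc.total
    sen = tp / (tp + fn)
    spe = tn / (tn + fp)
    if tp + fp == 0:
        logger.warning("no predicted positives; PRE set to 0")
        pre = 0.0
    else:
        pre = tp / (tp + fp)
    f1 = 2 * sen * pre / (sen + pre) if (sen + pre) > 0 else 0.0
    denom = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if denom == 0:
        logger.warning("MCC denominator is 0; MCC set to 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / denom
    auc = None
    if scores is not None and y_true is not None:
        auc = rank_auc(y_true, scores)
    return ClassificationReport(acc, sen, spe, pre, f1, float(mcc), auc)


@dataclass
class CVResult:
    """Per-edge held-out probabilities plus per-fold confusion counts."""

    heldout_probability: np.ndarray  # aligned with the input rows
    fold_of_row: np.ndarray
    fold_counts: list[ConfusionCounts]
    aggregate: ConfusionCounts
    report: ClassificationReport


def subsampled_cv(features: np.ndarray | pd.DataFrame,
                  labels: Sequence[bool] | np.ndarray,
                  folds: int = 10, seed: int = 0,
                  classifier_factory=None,
                  threshold: float = 0.5) -> CVResult:
    """Class-balanced k-fold cross-validation for imbalanced edge labels.

    c-edges and nc-edges are each split into ``folds`` subsets.  Round i
    trains on the other ``folds - 1`` c-edge subsets plus an equal-size
    random draw from the other nc-edge subsets (1:1 balance) and tests on
    every remaining edge.  Each edge's *held-out* probability comes from
    the round in which its own subset was held out, so every edge is held
    out exactly once.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(bool)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    if len(pos_idx) < folds or len(neg_idx) < folds:
        raise ValueError(
            f"each class needs at least {folds} edges for {folds}-fold CV; "
            f"got {len(pos_idx)} c-edges and {len(neg_idx)} nc-edges — "
            "use fewer folds")
    rng = np.random.default_rng(seed)
    pos_perm = rng.permutation(pos_idx)
    neg_perm = rng.permutation(neg_idx)
    pos_folds = np.array_split(pos_perm, folds)
    neg_folds = np.array_split(neg_perm, folds)

    if classifier_factory is None:
        classifier_factory = lambda s: GradientBoostedEdgeClassifier(seed=s)

    heldout = np.full(len(y), np.nan)
    fold_of_row = np.full(len(y), -1, dtype=int)
    fold_counts = []
    for i in range(folds):
        train_pos = np.concatenate([pos_folds[j] for j in range(folds) if j != i])
        pool_neg = np.concatenate([neg_folds[j] for j in range(folds) if j != i])
        draw = rng.choice(pool_neg, size=len(train_pos), replace=False) \
            if len(pool_neg) >= len(train_pos) else pool_neg
        train_idx = np.concatenate([train_pos, draw])
        test_mask = np.ones(len(y), dtype=bool)
        test_mask[train_idx] = False
        test_idx = np.flatnonzero(test_mask)

        clf = classifier_factory(seed + i)
        clf.fit(X[train_idx], y[train_idx].astype(int))
        prob = clf.predict_probability(X[test_idx])
        fold_counts.append(ConfusionCounts.from_predictions(
            y[test_idx], prob, threshold))

        held_rows = np.concatenate([pos_folds[i], neg_folds[i]])
        pos_in_test = {r: p for r, p in zip(test_idx, prob)}
        for r in held_rows:
            heldout[r] = pos_in_test[r]
            fold_of_row[r] = i

    aggregate = ConfusionCounts.from_predictions(y, heldout, threshold)
    report = classification_metrics(aggregate, y_true=y, scores=heldout)
    return CVResult(heldout, fold_of_row, fold_counts, aggregate, report)


def build_lepin(pin: WeightedPIN, classifier: ClassifierContract,
                features: pd.DataFrame,
                pin_training_labels: dict[frozenset[str], bool] | None = None
                ) -> WeightedPIN:
    """Reweight every edge with its predicted c-edge probability.

    ``features`` must be indexed by the (u, v) MultiIndex of sorted pairs
    covering every PIN edge.  When ``pin_training_labels`` is given,
    those edges are pinned to 1/0 instead of the model's probability
    (default: model predictions everywhere, so all edges are treated
    uniformly).
    """
    pairs = [(u, v) if u <= v else (v, u) for u, v in pin.edges()]
    missing = [p for p in pairs if p not in features.index]
    if missing:
        raise ValueError(
            f"{len(missing)} edges lack feature rows, e.g. {missing[:5]}")
    mat = features.loc[pairs].to_numpy(dtype=float)
    prob = np.clip(classifier.predict_probability(mat), 0.0, 1.0)
    out = pin.copy()
    for (u, v), p in zip(pairs, prob):
        if pin_training_labels is not None:
            lab = pin_training_labels.get(frozenset((u, v)))
            if lab is not None:
                p = 1.0 if lab else 0.0
        out.set_weight(u, v, float(p))
    return out
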