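"""Complex-prediction quality metrics against a gold standard.

The overlap statistic between a predicted complex P and a gold complex G
is the matching rate |P∩G|^2 / (|P|·|G|): 1 exactly when the sets are
equal, 0 when disjoint.  A matching rate >= 0.2 is the conventional
"successful match"; 1.0 is an exact match.

Set-level metrics:

* Recall / Precision / F-measure — fractions of gold (resp. predicted)
  complexes with at least one successful match, and their harmonic mean.
* MMR — maximum matching ratio: total weight of the optimal one-to-one
  gold–prediction assignment (edge weights = matching rates) divided by
  the number of gold complexes.
* GACC — geometric accuracy: sqrt of the clustering-wise sensitivity
  (protein-level coverage of gold complexes) times the positive
  predictive value.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .complexes import ComplexSet

logger = logging.getLogger(__name__)

__all__ = ["matching_rate", "match_matrix", "precision_recall_f", "mmr",
           "gacc", "EvaluationReport", "evaluate"]


def matching_rate(pc: frozenset[str] | set[str],
                  gc: frozenset[str] | set[str]) -> float:
    """|pc ∩ gc|^2 / (|pc| * |gc|); symmetric, in [0, 1]."""
    if not pc or not gc:
        raise ValueError("matching_rate is undefined for empty sets")
    inter = len(set(pc) & set(gc))
    return inter * inter / (len(pc) * len(gc))


def match_matrix(pred: ComplexSet, gold: ComplexSet) -> np.ndarray:
    """Matching-rate matrix, rows = gold complexes, columns = predicted."""
    mat = np.zeros((len(gold), len(pred)))
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            mat[i, j] = matching_rate(p.members, g.members)
    return mat


def precision_recall_f(pred: ComplexSet, gold: ComplexSet,
                       threshold: float = 0.2
                       ) -> tuple[float, float, float]:
    """(Recall, Precision, F-measure) at a matching-rate threshold.

    Recall is the fraction of gold complexes matched by some prediction;
    Precision the fraction of predictions matching some gold complex; a
    threshold of 1.0 counts exact matches only.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    if len(pred) == 0:
        logger.warning("empty prediction set; Precision set to 0")
        return 0.0, 0.0, 0.0
    mat = match_matrix(pred, gold)
    hit = mat >= threshold
    recall = float(hit.any(axis=1).mean())
    precision = float(hit.any(axis=0).mean())
    f = (2 * recall * precision / (recall + precision)
         if recall + precision > 0 else 0.0)
    return recall, precision, f


def mmr(pred: ComplexSet, gold: ComplexSet) -> float:
    """Maximum matching ratio via an exact assignment solve.

    Bipartite edges carry the matching rate (zero-rate pairs excluded);
    the optimal one-to-one matching weight is normalised by the number
    of gold complexes.
    """
    if len(gold) == 0:
        raise ValueError("gold standard is empty")
    if len(pred) == 0:
        return 0.0
    mat = match_matrix(pred, gold)
    row, col = linear_sum_assignment(mat, maximize=True)
    return float(mat[row, col].sum() / len(gold))


def gacc(pred: ComplexSet, gold: ComplexSet) -> tuple[float, float, float]:
    """(SN_GM, PPV, GACC) — protein-level sensitivity, positive predictive
    value, and their geometric mean.

    t[g, p] = shared proteins between gold complex g and prediction p.
    SN_GM sums each gold complex's best coverage over its size; PPV sums
    each prediction's best overlap over all its gold overlaps.  A zero
    PPV denominator (no prediction touches any gold complex) yields
    PPV = 0 with a warning.
    """
    if len(gold) == 0 or len(pred) == 0:
        raise ValueError("both complex sets must be non-empty")
    t = np.zeros((len(gold), len(pred)))
    for i, g in enumerate(gold):
        for j, p in enumerate(pred):
            t[i, j] = len(g.members & p.members)
    n_g = np.array([len(g.members) for g in gold], dtype=float)
    sn_gm = float(t.max(axis=1).sum() / n_g.sum())
    denom = t.sum()
    if denom == 0:
        logger.warning("no gold-prediction protein overlap; PPV set to 0")
        ppv = 0.0
    else:
        ppv = float(t.max(axis=0).sum() / denom)
    return sn_gm, ppv, math.sqrt(sn_gm * ppv)


@dataclass
class EvaluationReport:
    Recall: float
    Precision: float
    F_measure: float
    MMR: float
    SN_GM: float
    PPV: float
    GACC: float
    n_successful_matches: int
    n_exact_matches: int

    def as_dict(self) -> dict[str, float]:
        return {"Recall": self.Recall, "Precision": self.Precision,
                "F-measure": self.F_measure, "MMR": self.MMR,
                "SN_GM": self.SN_GM, "PPV": self.PPV, "GACC": self.GACC,
                "successful_matches": self.n_successful_matches,
                "exact_matches": self.n_exact_matches}


def evaluate(pred: ComplexSet, gold: ComplexSet,
             threshold: float = 0.2) -> EvaluationReport:
    """All five metrics plus successful / exact match counts."""
    recall, precision, f = precision_recall_f(pred, gold, threshold)
    sn_gm, ppv, g = (0.0, 0.0, 0.0)
    m = 0.0
    n_succ = n_exact = 0
    if len(pred) > 0:
        sn_gm, ppv, g = gacc(pred, gold)
        m = mmr(pred, gold)
        mat = match_matrix(pred, gold)
        n_succ = int((mat.max(axis=0) >= threshold).sum())
        n_exact = int((mat.max(axis=0) >= 1.0).sum())
    return EvaluationReport(recall, precision, f, m, sn_gm, ppv, g,
                            n_succ, n_exact)
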