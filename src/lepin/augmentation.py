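"""Interactome augmentation: recovering likely false-negative interactions.

Two complementary link predictors are provided:

* **WMM** (weighted matrix model): a pair of proteins observed together
  ``k`` times, with ``n`` and ``m`` total interactions each in a network
  of ``N`` interactions, is scored by the upper-tail hypergeometric
  probability of seeing at least ``k`` co-occurrences by chance.  Small
  p-values flag pairs whose co-occurrence is unlikely under random
  assortment — candidate missed interactions in AP-MS data.

* **L3**: degree-normalised length-3 path counts.  Interacting proteins
  tend to have complementary interfaces, so partners of a protein's
  partners' partners are good candidates; each path X-U-V-Y contributes
  1/sqrt(deg(U)*deg(V)).  Suited to Y2H-style binary networks.

Augmented networks are merged with :func:`integrate_networks`.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

from scipy.stats import hypergeom

from .pin_core import WeightedPIN

logger = logging.getLogger(__name__)

__all__ = ["InteractionEvidence", "CandidateEdge", "wmm_pvalue", "wmm_augment",
           "calibrate_wmm_threshold", "l3_scores", "integrate_networks",
           "edge_overlap_ratio"]


@dataclass(frozen=True)
class InteractionEvidence:
    """Co-occurrence evidence for one protein pair.

    k: observed interactions between the pair; n, m: total interactions
    of each protein; N: total interactions in the network.  k may exceed
    1 for replicated AP-MS evidence.
    """

    u: str
    v: str
    k: int
    n: int
    m: int
    N: int

    def __post_init__(self):
        if min(self.k, self.n, self.m, self.N) < 0:
            raise ValueError("evidence counts must be non-negative")
        if self.k > min(self.n, self.m):
            raise ValueError(f"k={self.k} exceeds min(n, m)={min(self.n, self.m)}")
        if max(self.n, self.m) > self.N:
            raise ValueError("per-protein totals cannot exceed network total")


@dataclass(frozen=True)
class CandidateEdge:
    u: str
    v: str
    score: float

    @property
    def pair(self) -> frozenset[str]:
        return frozenset((self.u, self.v))


def wmm_pvalue(k: int, n: int, m: int, N: int) -> float:
    """P(#co-occurrences >= k | n, m, N) under the hypergeometric null.

    Equals sum_{i=k}^{min(n,m)} C(n,i) C(N-n, m-i) / C(N,m).  Population
    size N, n "marked" draws, m trials; computed in log space by scipy.
    """
    InteractionEvidence("_a", "_b", k, n, m, N)  # validate
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, n, m))


def wmm_augment(evidence: list[InteractionEvidence], p_threshold: float,
                source: WeightedPIN | None = None) -> list[CandidateEdge]:
    """Candidate pairs with p-value strictly below the threshold.

    Pairs already present as edges of ``source`` are excluded; results
    are sorted ascending by p-value (most significant first), ties broken
    by pair id for determinism.
    """
    if not 0.0 <= p_threshold <= 1.0:
        raise ValueError("p_threshold must be in [0, 1]")
    cands = []
    for ev in evidence:
        if source is not None and source.has_edge(ev.u, ev.v):
            continue
        p = wmm_pvalue(ev.k, ev.n, ev.m, ev.N)
        if p < p_threshold:
            cands.append(CandidateEdge(ev.u, ev.v, p))
    cands.sort(key=lambda c: (c.score, min(c.u, c.v), max(c.u, c.v)))
    return cands


def calibrate_wmm_threshold(candidates: list[CandidateEdge],
                            reference: WeightedPIN,
                            fallback: float = 0.05) -> float:
    """Largest p-value among candidates confirmed by the reference network.

    Predicted pairs that are real edges of the reference define how lax
    the cutoff may be; the loosest confirmed p-value is returned.  With no
    confirmed candidate the configured fallback is returned with a warning.
    """
    matched = [c.score for c in candidates if reference.has_edge(c.u, c.v)]
    if not matched:
        logger.warning(
            "no candidate matched the reference network; "
            "falling back to threshold %g", fallback)
        return fallback
    return max(matched)


def l3_scores(pin: WeightedPIN, top_k: int | None = None,
              normalized: bool = True) -> list[CandidateEdge]:
    """Length-3 path link prediction on the unweighted skeleton.

    For every non-adjacent pair (X, Y), sums 1/sqrt(deg(U)*deg(V)) over
    simple length-3 paths X-U-V-Y (plain path counts when
    ``normalized=False``).  Returns candidates in descending score order,
    ties broken by pair id; ``top_k`` keeps only the strongest
    predictions (the usual operating point is a few thousand).
    """
    g = pin.graph
    deg = dict(g.degree())
    scores: dict[tuple[str, str], float] = {}
    for u, v in g.edges():
        contrib = 1.0 / math.sqrt(deg[u] * deg[v]) if normalized else 1.0
        for a, b in ((u, v), (v, u)):
            for x in g.neighbors(a):
                if x == b:
                    continue
                for y in g.neighbors(b):
                    if y == a or y == x or g.has_edge(x, y):
                        continue
                    key = (x, y) if x < y else (y, x)
                    scores[key] = scores.get(key, 0.0) + contrib
    # each undirected path was visited once per orientation
    cands = [CandidateEdge(x, y, s / 2.0) for (x, y), s in scores.items()]
    cands.sort(key=lambda c: (-c.score, c.u, c.v))
    if top_k is not None:
        cands = cands[:top_k]
    return cands


def integrate_networks(pins: list[WeightedPIN],
                       extra_edges: list[CandidateEdge] | None = None,
                       predicted_weight: float = 1.0) -> WeightedPIN:
    """Union of several PINs plus predicted edges.

    Node set is the union; conflicting weights resolve to the maximum.
    Predicted edges enter with a provisional ``predicted_weight`` — the
    supervised reweighting step is expected to overwrite every weight
    before detection runs.
    """
    out = WeightedPIN()
    for pin in pins:
        for n in pin.nodes:
            out.add_node(n)
        for u, v, d in pin.edges(data=True):
            out.add_edge(u, v, d["weight"])
    for cand in extra_edges or []:
        out.add_edge(cand.u, cand.v, predicted_weight)
    return out


def edge_overlap_ratio(pin_a: WeightedPIN, pin_b: WeightedPIN) -> float:
    """Fraction of pin_a's edges also present in pin_b (|A∩B| / |A|)."""
    if pin_a.number_of_edges() == 0:
        return 0.0
    shared = sum(1 for u, v in pin_a.edges() if pin_b.has_edge(u, v))
    return shared / pin_a.number_of_edges()


def evidence_from_cooccurrence(groups: list[set[str]]) -> list[InteractionEvidence]:
    """Build WMM evidence from co-occurrence groups (e.g. purifications).

    Each group contributes C(size, 2) pairwise observations; k counts the
    groups a pair shares, n/m count each protein's total pairwise
    observations, N the total observations in the collection.
    """
    pair_k: dict[tuple[str, str], int] = {}
    prot_n: dict[str, int] = {}
    N = 0
    for grp in groups:
        for a, b in itertools.combinations(sorted(grp), 2):
            pair_k[(a, b)] = pair_k.get((a, b), 0) + 1
            prot_n[a] = prot_n.get(a, 0) + 1
            prot_n[b] = prot_n.get(b, 0) + 1
            N += 1
    return [InteractionEvidence(a, b, k, prot_n[a], prot_n[b], N)
            for (a, b), k in sorted(pair_k.items())]
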