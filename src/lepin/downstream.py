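"""Downstream calls on a detected complex atlas.

Covers score-based filtering of likely-real complexes, construction of a
limited-overlap complex set, multifunctional-protein identification, and
selection of complexes affected by an interactor list (e.g. proteins
binding a viral proteome) with optional drug-target annotation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .complexes import Complex, ComplexSet
from .evaluation import matching_rate

__all__ = ["select_real_complexes", "calibrate_score_threshold",
           "subcomplex_index", "limited_overlap_set", "find_multifunctional",
           "AffectedComplexReport", "affected_complexes"]


def select_real_complexes(complexes: ComplexSet,
                          score_threshold: float = 0.5) -> ComplexSet:
    """Keep complexes with score >= threshold (inclusive), descending.

    High-scoring complexes have strong cohesion and weak coupling and are
    treated as real; the default cutoff is 0.5.
    """
    kept = [c for c in complexes if c.score is not None
            and c.score >= score_threshold]
    return ComplexSet(sorted(kept, key=lambda c: (-c.score, c.sorted_members())))


def calibrate_score_threshold(complexes: ComplexSet,
                              independent_gold: ComplexSet) -> float:
    """Lowest score among predictions exactly matching an independent set.

    Exact match means matching rate 1.0 (identical member sets).  Raises
    when no prediction matches exactly — set the threshold manually then.
    """
    gold_sets = {g.members for g in independent_gold}
    matched = [c.score for c in complexes
               if c.score is not None and c.members in gold_sets]
    if not matched:
        raise ValueError(
            "no predicted complex exactly matches the independent set; "
            "choose a score threshold manually")
    return min(matched)


def subcomplex_index(cp_i: frozenset[str] | set[str],
                     cp_j: frozenset[str] | set[str]) -> float:
    """|CP_i ∩ CP_j| / |CP_i| — fraction of complex i inside complex j.

    Asymmetric: a small complex fully contained in a large one has index
    1 in this direction but a small index the other way.
    """
    if not cp_i:
        raise ValueError("first complex must be non-empty")
    return len(set(cp_i) & set(cp_j)) / len(cp_i)


def limited_overlap_set(complexes: ComplexSet,
                        idx_threshold: float = 0.5) -> ComplexSet:
    """Greedy construction of a complex set with limited pairwise overlap.

    Complexes are visited in descending score order; a candidate is kept
    only if, against every already-kept complex, both directional
    sub-complex indices are strictly below the threshold.  Taking the
    maximum of both directions removes containment in either direction
    and keeps the result deterministic.
    """
    kept: list[Complex] = []
    for cand in complexes.sorted_canonical():
        ok = all(max(subcomplex_index(cand.members, k.members),
                     subcomplex_index(k.members, cand.members)) < idx_threshold
                 for k in kept)
        if ok:
            kept.append(cand)
    return ComplexSet(kept)


def find_multifunctional(limited: ComplexSet) -> dict[str, list[Complex]]:
    """Proteins belonging to two or more complexes of a limited-overlap set.

    Membership in several well-separated complexes is the operational
    signature of a multifunctional (potentially moonlighting) protein.
    """
    membership: dict[str, list[Complex]] = {}
    for c in limited:
        for p in sorted(c.members):
            membership.setdefault(p, []).append(c)
    return {p: cs for p, cs in sorted(membership.items()) if len(cs) >= 2}


@dataclass
class AffectedComplexReport:
    complex: Complex
    interactor_members: frozenset[str]
    target_members: frozenset[str]
    all_members_interact: bool

    @property
    def interactor_count(self) -> int:
        return len(self.interactor_members)


def affected_complexes(complexes: ComplexSet, interactors: set[str],
                       targets: set[str] | None = None
                       ) -> list[AffectedComplexReport]:
    """Complexes containing at least one protein from ``interactors``.

    Reports each affected complex's interacting members, whether *every*
    member interacts, and (when given) which members are known drug
    targets.  Monotone in the interactor set.
    """
    if not interactors:
        raise ValueError("interactor set must be non-empty")
    targets = targets or set()
    out = []
    for c in complexes:
        hit = frozenset(c.members & interactors)
        if hit:
            out.append(AffectedComplexReport(
                complex=c,
                interactor_members=hit,
                target_members=frozenset(c.members & targets),
                all_members_interact=(hit == c.members)))
    return out
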