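"""Protein-complex detection on the LE-PIN: density+modularity search.

A candidate complex is a subgraph SG of the weighted network.  Its
quality combines cohesion and coupling:

    D(SG) = sum of internal weights / C(|V_SG|, 2)        (density)
    M(SG) = d_in / (d_in + d_out)                         (modularity)
    F(SG) = 1 / (1/D + 1/M) + (D + M) / 2

F is 0 for singletons or zero internal weight, and attains its maximum
1.5 only on an isolated clique of weight-1 edges.  Starting from each
seed in k-shell order, the search alternates an *inflate* phase (greedily
add the neighbor maximising F among those passing the c-edge weight gate
and the expected-edges criterion) and a *shrink* phase (greedily remove
the boundary node maximising F), until F stops improving.  Duplicates
(identical member sets) are discarded and the output is canonically
sorted, so results do not depend on scheduling.
"""

from __future__ import annotations

from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field, replace

from .complexes import Complex, ComplexSet
from .pin_core import SeedQueue, WeightedPIN, build_seed_queue

__all__ = ["DetectionParams", "CandidateComplex", "complex_score",
           "inflate", "shrink", "detect_complexes", "deduplicate"]


@dataclass(frozen=True)
class DetectionParams:
    """Knobs of the detection search.

    c_edge_threshold: minimum edge weight for a connection to count as a
    c-edge at the inflate gate (strictly greater-than).
    high_shell_threshold: k-shell value from which a seed is "high" and
    gets its own work batch.
    min_size: smallest complex emitted.
    shrink_requires_eq29: whether removal candidates must also satisfy
    the expected-edges criterion against the remaining subgraph.
    """

    c_edge_threshold: float = 0.5
    high_shell_threshold: int = 20
    min_size: int = 2
    shrink_requires_eq29: bool = True

    def __post_init__(self):
        if not 0.0 < self.c_edge_threshold < 1.0:
            raise ValueError("c_edge_threshold must be in (0, 1)")


@dataclass
class CandidateComplex:
    """A subgraph under construction, with cached weight sums.

    d_in is the total internal edge weight, d_out the total weight of
    edges leaving the member set; D, M, F are derived.
    """

    members: set[str]
    d_in: float = 0.0
    d_out: float = 0.0

    @property
    def D(self) -> float:
        n = len(self.members)
        if n < 2:
            return 0.0
        return self.d_in / (n * (n - 1) / 2)

    @property
    def M(self) -> float:
        if self.d_in <= 0.0:
            return 0.0
        return self.d_in / (self.d_in + self.d_out)

    @property
    def F(self) -> float:
        return _f_score(self.D, self.M)

    @classmethod
    def from_members(cls, pin: WeightedPIN, members: set[str]) -> "CandidateComplex":
        for m in members:
            if m not in pin:
                raise KeyError(f"node {m!r} not in network")
        d_in = d_out = 0.0
        for u in members:
            for v in pin.neighbors(u):
                w = pin.weight(u, v)
                if v in members:
                    d_in += w / 2.0  # each internal edge visited twice
                else:
                    d_out += w
        return cls(set(members), d_in, d_out)


def _f_score(D: float, M: float) -> float:
    if D <= 0.0 or M <= 0.0:
        return 0.0
    return 1.0 / (1.0 / D + 1.0 / M) + (D + M) / 2.0


def complex_score(pin: WeightedPIN, members: set[str]) -> tuple[float, float, float]:
    """(density, modularity, F) of a member set in the network.

    Modularity is 1 when there is internal weight but no outgoing weight
    (isolated subgraph); F is 0 for singletons or zero internal weight.
    """
    cc = CandidateComplex.from_members(pin, members)
    return cc.D, cc.M, cc.F


def _delta_add(pin: WeightedPIN, cc: CandidateComplex, node: str
               ) -> tuple[float, float, float, int]:
    """(new_d_in, new_d_out, new_F, internal links) after adding ``node``."""
    w_in = 0.0
    w_ext = 0.0
    links = 0
    for nb in pin.neighbors(node):
        w = pin.weight(node, nb)
        if nb in cc.members:
            w_in += w
            links += 1
        else:
            w_ext += w
    d_in = cc.d_in + w_in
    d_out = cc.d_out - w_in + w_ext
    n = len(cc.members) + 1
    D = d_in / (n * (n - 1) / 2) if n >= 2 else 0.0
    M = d_in / (d_in + d_out) if d_in > 0 else 0.0
    return d_in, d_out, _f_score(D, M), links


def _delta_remove(pin: WeightedPIN, cc: CandidateComplex, node: str
                  ) -> tuple[float, float, float]:
    """(new_d_in, new_d_out, new_F) after removing ``node``."""
    w_in = 0.0
    w_ext = 0.0
    for nb in pin.neighbors(node):
        w = pin.weight(node, nb)
        if nb in cc.members:
            w_in += w
        else:
            w_ext += w
    d_in = cc.d_in - w_in
    d_out = cc.d_out - w_ext + w_in
    n = len(cc.members) - 1
    D = d_in / (n * (n - 1) / 2) if n >= 2 else 0.0
    M = d_in / (d_in + d_out) if d_in > 0 else 0.0
    return d_in, d_out, _f_score(D, M)


def inflate(pin: WeightedPIN, cc: CandidateComplex,
            params: DetectionParams = DetectionParams()) -> CandidateComplex:
    """Greedy growth phase.

    Repeatedly adds the candidate neighbor that maximises F among nodes
    passing all of: (1) at least one edge into the subgraph with weight
    strictly above the c-edge threshold; (2) number of links into the
    subgraph >= F(SG) * |V_SG| (expected-edges criterion, evaluated on
    the current subgraph); (3) F strictly increases.  The chosen node is
    removed from the candidate pool whether or not more growth follows;
    the pool is not replenished with the new member's neighbors' already
    rejected picks — new neighbors do join the pool.  Ties break on the
    lexicographically smallest node id.
    """
    cc = replace(cc, members=set(cc.members))
    pool: set[str] = set()
    for m in cc.members:
        for nb in pin.neighbors(m):
            if nb not in cc.members:
                pool.add(nb)
    while pool:
        f_cur = cc.F
        expectation = f_cur * len(cc.members)
        best = None
        for node in sorted(pool):
            has_strong = any(
                nb in cc.members and pin.weight(node, nb) > params.c_edge_threshold
                for nb in pin.neighbors(node))
            if not has_strong:
                continue
            d_in, d_out, f_new, links = _delta_add(pin, cc, node)
            if links < expectation:
                continue
            if f_new <= f_cur:
                continue
            if best is None or f_new > best[1]:
                best = (node, f_new, d_in, d_out)
        if best is None:
            break
        node, _, d_in, d_out = best
        pool.discard(node)
        cc.members.add(node)
        cc.d_in, cc.d_out = d_in, d_out
        for nb in pin.neighbors(node):
            if nb not in cc.members:
                pool.add(nb)
    return cc


def shrink(pin: WeightedPIN, cc: CandidateComplex,
           params: DetectionParams = DetectionParams()) -> CandidateComplex:
    """Greedy pruning phase.

    Repeatedly removes, among boundary nodes (members with at least one
    edge to a non-member), the node whose removal maximises F, requiring
    that F strictly increase and — when ``shrink_requires_eq29`` — that
    the removed node satisfy the expected-edges criterion against the
    remaining subgraph.  Stops when no removal improves F.
    """
    cc = replace(cc, members=set(cc.members))
    while len(cc.members) > 1:
        f_cur = cc.F
        boundary = [m for m in cc.members
                    if any(nb not in cc.members for nb in pin.neighbors(m))]
        best = None
        for node in sorted(boundary):
            d_in, d_out, f_new = _delta_remove(pin, cc, node)
            if f_new <= f_cur:
                continue
            if params.shrink_requires_eq29:
                remaining = cc.members - {node}
                links = sum(1 for nb in pin.neighbors(node) if nb in remaining)
                if links < f_new * len(remaining):
                    continue
            if best is None or f_new > best[1]:
                best = (node, f_new, d_in, d_out)
        if best is None:
            break
        node, _, d_in, d_out = best
        cc.members.discard(node)
        cc.d_in, cc.d_out = d_in, d_out
    return cc


def _search_from_seed(pin: WeightedPIN, seed: str,
                      params: DetectionParams) -> CandidateComplex:
    cc = CandidateComplex.from_members(pin, {seed})
    f_old = -1.0
    while cc.F > f_old:
        f_old = cc.F
        cc = inflate(pin, cc, params)
        cc = shrink(pin, cc, params)
    return cc


def _seed_batches(queue: SeedQueue, workers: int) -> list[list[str]]:
    """Load-balancing batches: one–two high-shell seeds per batch, larger
    batches of low-shell seeds."""
    if workers <= 1:
        return [list(queue.order)]
    high = [n for n in queue.order if queue.is_high(n)]
    low = [n for n in queue.order if not queue.is_high(n)]
    batches = [high[i:i + 2] for i in range(0, len(high), 2)]
    chunk = max(1, -(-len(low) // max(workers * 4, 1)))
    batches += [low[i:i + chunk] for i in range(0, len(low), chunk)]
    return [b for b in batches if b]


def detect_complexes(pin: WeightedPIN,
                     params: DetectionParams = DetectionParams(),
                     workers: int = 1) -> ComplexSet:
    """Run the seeded inflate/shrink search from every node of the LE-PIN.

    Seeds are visited in descending k-shell order (isolated nodes are
    skipped); candidates below ``min_size`` are dropped, exact duplicates
    removed, and the result canonically sorted (descending F, then
    lexicographic members) — so output is independent of worker count
    and scheduling.
    """
    queue = build_seed_queue(pin, params.high_shell_threshold)

    def run_batch(batch: list[str]) -> list[CandidateComplex]:
        return [_search_from_seed(pin, s, params)
                for s in batch if pin.degree(s) >= 1]

    batches = _seed_batches(queue, workers)
    if workers <= 1 or len(batches) <= 1:
        results = [cc for b in batches for cc in run_batch(b)]
    else:
        with ThreadPoolExecutor(max_workers=workers) as pool:
            results = [cc for out in pool.map(run_batch, batches) for cc in out]

    found = ComplexSet([Complex(frozenset(cc.members), cc.F)
                        for cc in results if len(cc.members) >= params.min_size])
    return deduplicate(found)


def deduplicate(complexes: ComplexSet) -> ComplexSet:
    """Drop exact duplicates (matching rate 1.0 means identical member
    sets) and canonically sort: descending F, then lexicographic members."""
    seen: set[frozenset[str]] = set()
    unique = []
    for c in complexes.sorted_canonical():
        if c.members not in seen:
            seen.add(c.members)
            unique.append(c)
    return ComplexSet(unique)
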