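"""Weighted protein-interaction network (PIN) data model and seed ordering.

The central container is :class:`WeightedPIN`, a thin validated wrapper
around an undirected :class:`networkx.Graph` whose edge weights lie in
[0, 1].  In the labeled-edge PIN (LE-PIN) a weight is the predicted
probability that the interaction lies within a protein complex.

Seeds for complex detection are ordered by k-shell decomposition of the
unweighted skeleton: nodes in deeper cores are expanded first.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["WeightedPIN", "SeedQueue", "load_edge_list", "save_edge_list",
           "k_shell", "build_seed_queue"]


class WeightedPIN:
    """Undirected simple graph of proteins with edge weights in [0, 1].

    Invariants: no self-loops, each unordered pair at most once,
    symmetric weights, isolated nodes permitted.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g = nx.Graph()
        if graph is not None:
            for n in graph.nodes:
                self.add_node(n)
            for u, v, d in graph.edges(data=True):
                self.add_edge(u, v, d.get("weight", 1.0))

    # -- construction -------------------------------------------------

    def add_node(self, node: str) -> None:
        self._g.add_node(str(node))

    def add_edge(self, u: str, v: str, weight: float = 1.0) -> None:
        """Add (or update) an undirected edge; keeps the maximum weight
        when the pair is already present."""
        u, v = str(u), str(v)
        if u == v:
            raise ValueError(f"self-loop not allowed: {u!r}")
        w = float(weight)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight {w} outside [0, 1] for edge ({u}, {v})")
        if self._g.has_edge(u, v):
            w = max(w, self._g[u][v]["weight"])
        self._g.add_edge(u, v, weight=w)

    def set_weight(self, u: str, v: str, weight: float) -> None:
        """Overwrite the weight of an existing edge."""
        w = float(weight)
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"weight {w} outside [0, 1]")
        if not self._g.has_edge(u, v):
            raise KeyError(f"no edge ({u}, {v})")
        self._g[u][v]["weight"] = w

    @classmethod
    def from_edges(cls, edges: Iterable[tuple]) -> "WeightedPIN":
        """Build from (u, v) or (u, v, weight) tuples."""
        pin = cls()
        for e in edges:
            if len(e) == 2:
                pin.add_edge(e[0], e[1], 1.0)
            else:
                pin.add_edge(e[0], e[1], e[2])
        return pin

    def copy(self) -> "WeightedPIN":
        other = WeightedPIN()
        other._g = self._g.copy()
        return other

    # -- queries ------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying networkx graph (mutate at your own risk)."""
        return self._g

    @property
    def nodes(self):
        return self._g.nodes

    def edges(self, data: bool = False):
        return self._g.edges(data=data)

    def number_of_nodes(self) -> int:
        return self._g.number_of_nodes()

    def number_of_edges(self) -> int:
        return self._g.number_of_edges()

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def weight(self, u: str, v: str) -> float:
        return self._g[u][v]["weight"]

    def neighbors(self, node: str) -> Iterator[str]:
        return self._g.neighbors(node)

    def degree(self, node: str) -> int:
        return self._g.degree(node)

    def __contains__(self, node: str) -> bool:
        return node in self._g

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __repr__(self) -> str:
        return (f"WeightedPIN({self.number_of_nodes()} proteins, "
                f"{self.number_of_edges()} interactions)")


@dataclass
class SeedQueue:
    """Detection seed order: every node once, descending k-shell.

    ``high`` marks nodes whose shell is at or above the high-shell
    threshold; the detector gives such seeds their own work batches.
    """

    order: list[str] = field(default_factory=list)
    shells: dict[str, int] = field(default_factory=dict)
    high_shell_threshold: int = 20

    def is_high(self, node: str) -> bool:
        return self.shells[node] >= self.high_shell_threshold

    def __iter__(self) -> Iterator[str]:
        return iter(self.order)

    def __len__(self) -> int:
        return len(self.order)


def load_edge_list(path: str | Path, weighted: bool = True) -> WeightedPIN:
    """Read a TSV edge list (protein_a, protein_b[, weight]) into a PIN.

    Unweighted files get weight 1.0 on every edge.  Duplicate rows for the
    same unordered pair are collapsed keeping the maximum weight; self-loop
    rows are dropped with a warning.  A ``#``-prefixed header is permitted.
    """
    pin = WeightedPIN()
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if weighted and len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 columns "
                    f"(protein_a, protein_b, weight), got {len(parts)}")
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, got {len(parts)}")
            u, v = parts[0].strip(), parts[1].strip()
            if not u or not v:
                raise ValueError(f"{path}:{lineno}: empty protein identifier")
            if u == v:
                logger.warning("%s:%d: dropping self-loop on %r", path, lineno, u)
                pin.add_node(u)
                continue
            if weighted:
                try:
                    w = float(parts[2])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: malformed weight {parts[2]!r}") from exc
                if not 0.0 <= w <= 1.0:
                    raise ValueError(
                        f"{path}:{lineno}: weight {w} outside [0, 1]")
            else:
                w = 1.0
            pin.add_edge(u, v, w)
    return pin


def save_edge_list(pin: WeightedPIN, path: str | Path) -> None:
    """Write a PIN as a canonical 3-column TSV (sorted pairs, u < v)."""
    rows = sorted(
        (min(u, v), max(u, v), d["weight"]) for u, v, d in pin.edges(data=True))
    with Path(path).open("w") as fh:
        for u, v, w in rows:
            fh.write(f"{u}\t{v}\t{w:g}\n")


def k_shell(pin: WeightedPIN) -> dict[str, int]:
    """k-shell (core number) of every node on the unweighted skeleton.

    Weights are ignored: the decomposition is purely topological.
    Isolated nodes get shell 0.
    """
    return nx.core_number(pin.graph)


def build_seed_queue(pin: WeightedPIN, high_shell_threshold: int = 20) -> SeedQueue:
    """Order all nodes by descending k-shell for seeded detection.

    Ties within a shell are broken by ascending lexicographic node id so
    that detection output is deterministic.
    """
    shells = k_shell(pin)
    order = sorted(shells, key=lambda n: (-shells[n], n))
    return SeedQueue(order=order, shells=shells,
                     high_shell_threshold=high_shell_threshold)
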