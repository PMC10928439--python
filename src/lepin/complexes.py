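"""Protein-complex containers and CORUM-style membership file I/O.

A complex is a set of at least two protein identifiers, optionally with a
detection score.  A :class:`ComplexSet` is an ordered list of complexes;
order matters downstream (greedy overlap filtering is score-descending).

File format: one complex per line, members tab-separated; an optional
leading numeric column carries the score (written by ``save_complexes``
when scores are present, auto-detected on read).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator


@dataclass(frozen=True)
class Complex:
    members: frozenset[str]
    score: float | None = None

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("complex must have at least one member")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, protein: str) -> bool:
        return protein in self.members

    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class ComplexSet:
    complexes: list[Complex] = field(default_factory=list)

    @classmethod
    def from_iterable(cls, sets: Iterable[Iterable[str]],
                      scores: Iterable[float] | None = None) -> "ComplexSet":
        sets = [frozenset(map(str, s)) for s in sets]
        if scores is None:
            return cls([Complex(s) for s in sets])
        return cls([Complex(s, float(f)) for s, f in zip(sets, scores, strict=True)])

    def __iter__(self) -> Iterator[Complex]:
        return iter(self.complexes)

    def __len__(self) -> int:
        return len(self.complexes)

    def __getitem__(self, i):
        return self.complexes[i]

    def append(self, c: Complex) -> None:
        self.complexes.append(c)

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c.members
        return out

    def filter_min_size(self, min_size: int = 2) -> "ComplexSet":
        return ComplexSet([c for c in self.complexes if len(c) >= min_size])

    def sorted_canonical(self) -> "ComplexSet":
        """Descending score (None last), then lexicographic member list."""
        return ComplexSet(sorted(
            self.complexes,
            key=lambda c: (-(c.score if c.score is not None else float("-inf")),
                           c.sorted_members())))


def load_complexes(path: str | Path, min_size: int = 2) -> ComplexSet:
    """Read a one-complex-per-line membership file.

    A leading column that parses as a float and is not a plausible protein
    id is treated as the complex score.  Complexes smaller than
    ``min_size`` after member deduplication are dropped.
    """
    out = ComplexSet()
    with Path(path).open() as fh:
        for line in fh:
            parts = [p for p in line.rstrip("\n").split("\t") if p]
            if not parts or parts[0].startswith("#"):
                continue
            score = None
            try:
                score = float(parts[0])
                members = parts[1:]
            except ValueError:
                members = parts
            mset = frozenset(members)
            if len(mset) >= min_size:
                out.append(Complex(mset, score))
    return out


def save_complexes(cs: ComplexSet, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for c in cs:
            cols = list(c.sorted_members())
            if c.score is not None:
                cols = [f"{c.score:.6g}"] + cols
            fh.write("\t".join(cols) + "\n")
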