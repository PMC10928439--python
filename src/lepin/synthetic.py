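"""Deterministic synthetic fixtures: planted complexes and separable features.

The planted-network generator emulates the structure of a labeled-edge
PIN: complexes are realised as cliques whose internal weights are drawn
from a high-mean distribution (c-edge-like, mean 0.9), while sparse
background edges between complexes carry low weights (nc-edge-like, mean
0.1).  The default size distribution favours 2–3-member complexes, the
regime that dominates real atlases.  The feature generator produces
class-conditional Gaussian feature vectors with a controllable mean
separation, so classifier plumbing can be tested from the no-signal null
up to near-separability.

All randomness flows from an explicit seed; global random state is never
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .complexes import Complex, ComplexSet
from .pin_core import WeightedPIN

__all__ = ["PlantedNetworkSpec", "PlantedTruth", "generate_planted_pin",
           "generate_edge_feature_data", "split_gold_standard"]

# sizes 2..10, weighted toward small complexes
DEFAULT_SIZES = tuple(range(2, 11))
DEFAULT_SIZE_PROBS = (0.25, 0.25, 0.12, 0.10, 0.08, 0.07, 0.05, 0.04, 0.04)


@dataclass
class PlantedNetworkSpec:
    """Parameters of a planted-complex weighted network.

    Within-complex weights ~ Beta(18, 2) (mean 0.9, rarely below 0.5);
    background weights ~ Beta(2, 18) (mean 0.1, rarely above 0.5); the
    generator warns when the two means do not straddle the 0.5 c-edge
    threshold, since such an instance is unresolvable for detection.
    """

    n_complexes: int = 20
    sizes: tuple[int, ...] = DEFAULT_SIZES
    size_probs: tuple[float, ...] = DEFAULT_SIZE_PROBS
    within_beta: tuple[float, float] = (18.0, 2.0)
    background_edge_probability: float = 0.01
    background_beta: tuple[float, float] = (2.0, 18.0)
    overlap_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.sizes) < 2:
            raise ValueError("complex sizes must be >= 2")
        if len(self.sizes) != len(self.size_probs):
            raise ValueError("sizes and size_probs must align")
        a, b = self.within_beta
        c, d = self.background_beta
        if a / (a + b) <= 0.5 or c / (c + d) >= 0.5:
            import warnings
            warnings.warn(
                "within/background weight means do not straddle 0.5; "
                "the instance may be unresolvable at the default threshold")


@dataclass
class PlantedTruth:
    """A generated network together with its ground truth."""

    pin: WeightedPIN
    complexes: ComplexSet
    edge_labels: dict[frozenset[str], bool] = field(default_factory=dict)

    def c_edges(self) -> list[frozenset[str]]:
        return [p for p, is_c in self.edge_labels.items() if is_c]

    def nc_edges(self) -> list[frozenset[str]]:
        return [p for p, is_c in self.edge_labels.items() if not is_c]


def generate_planted_pin(spec: PlantedNetworkSpec) -> PlantedTruth:
    """Realise the spec: clique complexes plus sparse weak background.

    With ``overlap_fraction`` > 0, that fraction of complexes (after the
    first) shares one member with a previously planted complex.
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    probs = np.asarray(spec.size_probs, dtype=float)
    probs = probs / probs.sum()
    sizes = rng.choice(spec.sizes, size=spec.n_complexes, p=probs)

    pin = WeightedPIN()
    planted: list[frozenset[str]] = []
    next_id = 0

    def new_node() -> str:
        nonlocal next_id
        node = f"P{next_id:05d}"
        next_id += 1
        return node

    a_w, b_w = spec.within_beta
    for ci, size in enumerate(sizes):
        members: list[str] = []
        if ci > 0 and spec.overlap_fraction > 0 and \
                rng.random() < spec.overlap_fraction:
            prev = planted[int(rng.integers(len(planted)))]
            members.append(sorted(prev)[int(rng.integers(len(prev)))])
        while len(members) < size:
            members.append(new_node())
        planted.append(frozenset(members))

    truth_edges: dict[frozenset[str], bool] = {}
    for members in planted:
        mem = sorted(members)
        for i, u in enumerate(mem):
            for v in mem[i + 1:]:
                w = float(rng.beta(a_w, b_w))
                pin.add_edge(u, v, w)
                truth_edges[frozenset((u, v))] = True

    # weak background edges between proteins of different complexes
    a_b, b_b = spec.background_beta
    nodes = sorted(pin.nodes)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1:]:
            pair = frozenset((u, v))
            if pair in truth_edges:
                continue
            if rng.random() < spec.background_edge_probability:
                w = float(rng.beta(a_b, b_b))
                pin.add_edge(u, v, w)
                truth_edges[pair] = False

    return PlantedTruth(pin=pin,
                        complexes=ComplexSet([Complex(m) for m in planted]),
                        edge_labels=truth_edges)


def generate_edge_feature_data(n_c: int, n_nc: int, separation: float,
                               seed: int = 0, n_features: int = 16,
                               n_informative: int = 4, noise_sd: float = 0.1
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Class-conditional Gaussian features for classifier tests.

    ``separation`` is the between-class mean difference in units of the
    noise standard deviation, applied to the first ``n_informative``
    slots; the remaining slots are pure noise.  Values are clipped to
    [0, 1] (pre-scaled).  Returns (features, labels) with labels True
    for the c-edge class; class counts are honoured exactly.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    rng = np.random.default_rng(seed)
    delta = separation * noise_sd / 2.0
    y = np.concatenate([np.ones(n_c, bool), np.zeros(n_nc, bool)])
    X = rng.normal(0.5, noise_sd, size=(n_c + n_nc, n_features))
    X[:n_c, :n_informative] += delta
    X[n_c:, :n_informative] -= delta
    perm = rng.permutation(len(y))
    return np.clip(X[perm], 0.0, 1.0), y[perm]


def split_gold_standard(gold: ComplexSet, fraction: float, seed: int = 0
                        ) -> tuple[ComplexSet, ComplexSet]:
    """Random complex-level partition into (train, test).

    ``fraction`` is the training share; the split is deterministic given
    the seed.  Pair-level redundancy between the halves is handled
    downstream by the edge-labeling step, which deduplicates protein
    pairs.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(gold))
    n_train = int(round(fraction * len(gold)))
    train = ComplexSet([gold[i] for i in sorted(idx[:n_train])])
    test = ComplexSet([gold[i] for i in sorted(idx[n_train:])])
    return train, test
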