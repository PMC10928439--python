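"""Per-pair feature computation for the featured-edge PIN (FE-PIN).

Five feature groups describe each interacting pair: subcellular
localization overlap (4 features), domain composition and domain–domain
interaction support (5), chain-length difference (1), GO semantic
similarity (1, behind a pluggable provider), and an optional externally
precomputed sequence-profile block (420 summed profile dimensions plus a
Euclidean-distance scalar).  All features are min–max scaled to [0, 1]
with parameters fit on the training edges only.

Missing annotations are carried as NaN and masked; after scaling they are
imputed as 0 and the mask is available to the classifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LOCALIZATION_COLUMNS = ["overlap_sl", "equality_sl", "jaccard_sl", "inclusion_sl"]
DOMAIN_COLUMNS = ["overlap_pd", "interaction_pd", "total_pd",
                  "similarity_overlap_pd", "similarity_interaction_pd"]
SCALAR_COLUMNS = ["chain_length_diff", "go_similarity"]
PSSM_BLOCK_SIZE = 421  # 420 summed profile dims + Euclidean distance


@dataclass
class ProteinAnnotation:
    """Annotation bundle for one protein; any block may be absent."""

    protein: str
    localization: set[str] | None = None
    domains: set[str] | None = None
    chain_length: int | None = None
    go_terms: set[str] | None = None

    def __post_init__(self):
        if self.chain_length is not None and self.chain_length < 1:
            raise ValueError("chain_length must be >= 1")


class DomainInteractionSet:
    """Symmetric set of interacting domain pairs (Pfam-style DDI list)."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs: set[frozenset[str]] = set()
        for d1, d2 in pairs:
            self.add(d1, d2)

    def add(self, d1: str, d2: str) -> None:
        self._pairs.add(frozenset((d1, d2)))

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DomainInteractionSet":
        out = cls()
        with Path(path).open() as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2 and parts[0] and not parts[0].startswith("#"):
                    out.add(parts[0], parts[1])
        return out


def localization_features(sl_i: set[str] | None,
                          sl_j: set[str] | None) -> tuple[float, float, float, float]:
    """(overlap, equality, Jaccard, inclusion) of two localization sets.

    Conventions for empty sets: two empty sets are equal (equality=1) and
    trivially mutually inclusive (inclusion=1); Jaccard of two empty sets
    is 0.
    """
    if sl_i is None or sl_j is None:
        return (np.nan,) * 4
    inter = len(sl_i & sl_j)
    union = len(sl_i | sl_j)
    overlap = float(inter)
    equality = 1.0 if sl_i == sl_j else 0.0
    jaccard = inter / union if union else 0.0
    inclusion = 1.0 if (sl_i <= sl_j or sl_j <= sl_i) else 0.0
    return overlap, equality, jaccard, inclusion


def domain_features(pd_i: set[str] | None, pd_j: set[str] | None,
                    ddi: DomainInteractionSet) -> tuple[float, ...]:
    """(overlap, interaction, total, similarity_overlap, similarity_interaction).

    ``interaction`` counts ordered domain pairs (d_i from protein i, d_j
    from protein j) supported by the domain-interaction set; both ratio
    features are 0 when the domain union is empty.
    """
    if pd_i is None or pd_j is None:
        return (np.nan,) * 5
    overlap = float(len(pd_i & pd_j))
    total = float(len(pd_i | pd_j))
    interaction = float(sum(1 for di in pd_i for dj in pd_j if (di, dj) in ddi))
    sim_overlap = overlap / total if total else 0.0
    sim_interaction = interaction / total if total else 0.0
    return overlap, interaction, total, sim_overlap, sim_interaction


def chain_length_feature(len_i: int | None, len_j: int | None) -> float:
    """Absolute difference of the two chain lengths (amino acids)."""
    if len_i is None or len_j is None:
        return np.nan
    return float(abs(len_i - len_j))


GoProvider = Callable[[set[str], set[str]], float]


def jaccard_go_provider(go_i: set[str], go_j: set[str]) -> float:
    """Fallback GO similarity: Jaccard index over annotated term sets."""
    union = go_i | go_j
    return len(go_i & go_j) / len(union) if union else 0.0


def go_similarity(provider: GoProvider | None,
                  go_i: set[str] | None, go_j: set[str] | None) -> float:
    """Single semantic-similarity scalar in [0, 1] from a pluggable provider.

    Provider failures degrade to a masked missing value with a warning;
    ontology-aware providers (e.g. Wang/Resnik via an external package)
    plug in through the same two-set callable contract.
    """
    if go_i is None or go_j is None:
        return np.nan
    provider = provider or jaccard_go_provider
    try:
        val = float(provider(go_i, go_j))
    except Exception as exc:  # provider contract: any failure -> masked
        logger.warning("GO similarity provider failed (%s); masking value", exc)
        return np.nan
    if not 0.0 <= val <= 1.0:
        logger.warning("GO similarity %g outside [0, 1]; masking value", val)
        return np.nan
    return val


def featurize_edges(pairs: Iterable[tuple[str, str]],
                    annotations: Mapping[str, ProteinAnnotation],
                    ddi: DomainInteractionSet | None = None,
                    go_provider: GoProvider | None = None,
                    pssm_block: Mapping[frozenset[str], np.ndarray] | None = None,
                    ) -> pd.DataFrame:
    """Assemble the per-pair feature matrix (rows indexed by sorted pair).

    Unknown proteins yield fully masked rows for the affected blocks; the
    optional precomputed profile block is joined by pair, never computed
    here.
    """
    ddi = ddi or DomainInteractionSet()
    empty = ProteinAnnotation("_missing")
    rows = []
    index = []
    for u, v in pairs:
        u, v = (u, v) if u <= v else (v, u)
        ai = annotations.get(u, empty)
        aj = annotations.get(v, empty)
        row = list(localization_features(ai.localization, aj.localization))
        row += list(domain_features(ai.domains, aj.domains, ddi))
        row.append(chain_length_feature(ai.chain_length, aj.chain_length))
        row.append(go_similarity(go_provider, ai.go_terms, aj.go_terms))
        if pssm_block is not None:
            blk = pssm_block.get(frozenset((u, v)))
            if blk is None:
                row += [np.nan] * PSSM_BLOCK_SIZE
            else:
                blk = np.asarray(blk, dtype=float)
                if blk.shape != (PSSM_BLOCK_SIZE,):
                    raise ValueError(
                        f"profile block for ({u}, {v}) has shape {blk.shape}, "
                        f"expected ({PSSM_BLOCK_SIZE},)")
                row += blk.tolist()
        rows.append(row)
        index.append((u, v))
    columns = LOCALIZATION_COLUMNS + DOMAIN_COLUMNS + SCALAR_COLUMNS
    if pssm_block is not None:
        columns = columns + [f"pssm_{i:03d}" for i in range(PSSM_BLOCK_SIZE)]
    return pd.DataFrame(rows, columns=columns,
                        index=pd.MultiIndex.from_tuples(index, names=["u", "v"]))


@dataclass
class FeatureScaler:
    """Per-column min–max scaler with clamping to [0, 1].

    Fit on the training partition only; at transform time values outside
    the fitted range clamp to the boundary, constant columns map to 0,
    and NaNs (masked missing annotations) impute to 0.
    """

    mins: pd.Series | None = field(default=None)
    maxs: pd.Series | None = field(default=None)

    def fit(self, df: pd.DataFrame) -> "FeatureScaler":
        if len(df) < 1:
            raise ValueError("need at least one record to fit the scaler")
        self.mins = df.min(axis=0, skipna=True)
        self.maxs = df.max(axis=0, skipna=True)
        return self

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.mins is None:
            raise RuntimeError("scaler is not fitted")
        span = (self.maxs - self.mins).replace(0.0, np.nan)
        scaled = (df - self.mins) / span
        scaled = scaled.clip(lower=0.0, upper=1.0)
        return scaled.fillna(0.0)

    def fit_transform(self, df: pd.DataFrame) -> pd.DataFrame:
        return self.fit(df).transform(df)


def scale_features(train: pd.DataFrame,
                   *others: pd.DataFrame) -> tuple[pd.DataFrame, ...]:
    """Scale feature frames with parameters fit on ``train`` only."""
    scaler = FeatureScaler().fit(train)
    return tuple(scaler.transform(df) for df in (train, *others))


# -- annotation table I/O ---------------------------------------------

def _read_two_col(path: str | Path) -> dict[str, str]:
    out = {}
    with Path(path).open() as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0] and not parts[0].startswith("#"):
                out[parts[0]] = parts[1]
    return out


def load_annotations(localization_path: str | Path | None = None,
                     domains_path: str | Path | None = None,
                     chain_length_path: str | Path | None = None,
                     go_path: str | Path | None = None,
                     ) -> dict[str, ProteinAnnotation]:
    """Read the TSV annotation tables (protein \\t ;-separated terms).

    Each table is optional; proteins appearing in any table get a record.
    """
    ann: dict[str, ProteinAnnotation] = {}

    def rec(p: str) -> ProteinAnnotation:
        if p not in ann:
            ann[p] = ProteinAnnotation(p)
        return ann[p]

    if localization_path:
        for p, terms in _read_two_col(localization_path).items():
            rec(p).localization = {t for t in terms.split(";") if t}
    if domains_path:
        for p, terms in _read_two_col(domains_path).items():
            rec(p).domains = {t for t in terms.split(";") if t}
    if chain_length_path:
        for p, val in _read_two_col(chain_length_path).items():
            rec(p).chain_length = int(val)
    if go_path:
        for p, terms in _read_two_col(go_path).items():
            rec(p).go_terms = {t for t in terms.split(";") if t}
    return ann
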