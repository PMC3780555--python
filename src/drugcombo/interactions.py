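"""Drug targets, pairwise confidence-score tables and pathway annotations.

Confidence scores follow the zero-default convention used by large
interaction databases: a pair absent from the table scores exactly 0.
Scores are kept on their raw input scale (e.g. 0-999 integers); nothing
downstream requires normalization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Pair = Tuple[str, str]


def canonical_pair(a: str, b: str) -> Pair:
    """Order-independent key for an unordered id pair."""
    return (a, b) if a <= b else (b, a)


class ConfigurationError(ValueError):
    """Raised when an input file does not match its declared dialect."""


@dataclass(frozen=True)
class DrugRecord:
    """A drug and the union of its annotated protein targets."""

    drug_id: str
    targets: FrozenSet[str]

    def __post_init__(self) -> None:
        if not self.targets:
            raise ValueError(
                f"drug {self.drug_id!r} has no targets; drugs without "
                "target information are excluded"
            )


class ScoreTable:
    """Symmetric sparse map from unordered id pairs to positive confidence scores.

    Lookup of an absent pair (and of any self-pair) returns 0. Only
    strictly positive scores are stored; duplicate orientations collapse
    to the maximum.
    """

    def __init__(self, kind: str, entries: Mapping[Pair, float] | None = None):
        if kind not in ("chemical", "protein"):
            raise ValueError(f"unknown score table kind {kind!r}")
        self.kind = kind
        self._entries: Dict[Pair, float] = {}
        if entries:
            for (a, b), s in entries.items():
                self.add(a, b, s)

    def add(self, a: str, b: str, score: float) -> None:
        """Record score(a,b), collapsing duplicates by max; drops self pairs and scores <= 0."""
        if a == b or score <= 0:
            return
        key = canonical_pair(a, b)
        prev = self._entries.get(key)
        if prev is None or score > prev:
            self._entries[key] = float(score)

    def score(self, a: str, b: str) -> float:
        if a == b:
            return 0.0
        return self._entries.get(canonical_pair(a, b), 0.0)

    def neighbors(self, node: str) -> Set[str]:
        """All ids with a positive score against ``node``."""
        return self._adjacency().get(node, set())

    def _adjacency(self) -> Dict[str, Set[str]]:
        adj = getattr(self, "_adj_cache", None)
        if adj is None or len(adj) != getattr(self, "_adj_n", -1):
            adj: Dict[str, Set[str]] = {}
            for a, b in self._entries:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
            self._adj_cache = adj
            self._adj_n = len(adj)
        return self._adj_cache

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(sorted(self._entries.items()))

    def items(self) -> List[Tuple[Pair, float]]:
        return sorted(self._entries.items())


@dataclass
class PathwayAnnotation:
    """Ordered pathway -> gene-set map over a gene universe of known size.

    Pathway order is lexicographic by id, fixing downstream feature-column
    order.
    """

    pathways: Dict[str, FrozenSet[str]]
    universe_size: int

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        ordered = {}
        for pid in sorted(self.pathways):
            genes = frozenset(self.pathways[pid])
            if not genes:
                raise ValueError(f"pathway {pid!r} has an empty gene set")
            if len(genes) > self.universe_size:
                raise ValueError(
                    f"pathway {pid!r} has {len(genes)} genes, more than the "
                    f"universe size {self.universe_size}"
                )
            ordered[pid] = genes
        self.pathways = ordered

    @property
    def pathway_ids(self) -> List[str]:
        return list(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)


@dataclass(frozen=True)
class CombinationLabelSet:
    """Positive and negative unordered drug-id pairs, disjoint by construction."""

    positives: FrozenSet[Pair]
    negatives: FrozenSet[Pair]

    def __post_init__(self) -> None:
        for name, pairs in (("positives", self.positives), ("negatives", self.negatives)):
            for a, b in pairs:
                if a == b:
                    raise ValueError(f"self-pair ({a},{b}) in {name}")
                if (a, b) != canonical_pair(a, b):
                    raise ValueError(f"non-canonical pair ({a},{b}) in {name}")
        overlap = self.positives & self.negatives
        if overlap:
            raise ValueError(f"{len(overlap)} pairs are both positive and negative")

    def validate_drugs(self, drug_ids: Iterable[str]) -> None:
        known = set(drug_ids)
        for a, b in itertools.chain(self.positives, self.negatives):
            if a not in known or b not in known:
                raise ValueError(f"pair ({a},{b}) references an unknown drug")


# ---------------------------------------------------------------------------
# Loaders


def load_score_table(path, kind: str, score_column: str = "combined_score") -> ScoreTable:
    """Load a STITCH/STRING-style TSV into a :class:`ScoreTable`.

    The file must be tab-separated with a header naming ``score_column``.
    Rows with non-positive scores are dropped; duplicate orientations of a
    pair collapse to the maximum score; malformed rows are logged and
    skipped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if score_column not in df.columns:
        raise ConfigurationError(
            f"column {score_column!r} not found in {path}; "
            f"available: {list(df.columns)}"
        )
    id1_col, id2_col = df.columns[0], df.columns[1]
    table = ScoreTable(kind)
    skipped = 0
    scores = pd.to_numeric(df[score_column], errors="coerce")
    for a, b, s in zip(df[id1_col], df[id2_col], scores):
        if not isinstance(a, str) or not isinstance(b, str) or not np.isfinite(s):
            skipped += 1
            continue
        table.add(a, b, s)
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    return table


def load_drug_targets(path) -> Dict[str, DrugRecord]:
    """Read a two-column drug_id / protein_id TSV into DrugRecords.

    One row per (drug, target); the per-drug target set is the union of
    its rows. Drugs never listed with a target simply do not appear.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns (drug_id, protein_id)")
    targets: Dict[str, Set[str]] = {}
    for drug, prot in zip(df.iloc[:, 0], df.iloc[:, 1]):
        if not isinstance(drug, str) or not isinstance(prot, str):
            continue
        targets.setdefault(drug, set()).add(prot)
    return {d: DrugRecord(d, frozenset(t)) for d, t in sorted(targets.items())}


def load_gmt(path, universe_size: int) -> PathwayAnnotation:
    """Read a GMT file (pathway_id <tab> description <tab> gene ...)."""
    pathways: Dict[str, FrozenSet[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ConfigurationError(
                    f"{path}:{lineno}: GMT rows need id, description and >=1 gene"
                )
            pathways[fields[0]] = frozenset(g for g in fields[2:] if g)
    return PathwayAnnotation(pathways, universe_size)


def load_pair_list(path) -> Set[Pair]:
    """Read a two-column TSV of drug-id pairs into a canonical pair set."""
    df = pd.read_csv(path, sep="\t", dtype=str, header=0)
    if df.shape[1] < 2:
        raise ConfigurationError(f"{path}: expected two columns of drug ids")
    return {canonical_pair(a, b) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])}


# ---------------------------------------------------------------------------
# Negative sampling


def all_pairs(drugs: Sequence[str]) -> List[Pair]:
    """All unordered non-self pairs over ``drugs``, in deterministic order."""
    ordered = sorted(set(drugs))
    return [canonical_pair(a, b) for a, b in itertools.combinations(ordered, 2)]


def sample_negatives(
    drugs: Sequence[str],
    positives: Iterable[Pair],
    ratio: int,
    seed: int,
) -> CombinationLabelSet:
    """Draw ``ratio * |positives|`` negative pairs uniformly without replacement.

    Candidates are all unordered drug pairs that are not positives. The
    draw is deterministic for a fixed seed.
    """
    if ratio < 1:
        raise ValueError("ratio must be a positive integer")
    pos = frozenset(canonical_pair(a, b) for a, b in positives)
    candidates = [p for p in all_pairs(drugs) if p not in pos]
    needed = ratio * len(pos)
    if needed > len(candidates):
        raise ValueError(
            f"cannot sample {needed} negatives: only {len(candidates)} "
            f"non-positive pairs available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=needed, replace=False)
    negatives = frozenset(candidates[i] for i in idx)
    return CombinationLabelSet(positives=pos, negatives=negatives)
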