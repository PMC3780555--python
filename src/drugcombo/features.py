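"""Symmetric feature encoding of a drug pair.

Each pair maps to a 7 + 2P vector: the pair's chemical confidence score,
two cross-target-group interaction statistics, four within-group
statistics, then P pathway-score sums and P absolute differences. Every
component is a symmetric function of the two drugs, so the encoding is
invariant under swapping them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .enrichment import EnrichmentProfile
from .interactions import (
    CombinationLabelSet,
    DrugRecord,
    ScoreTable,
    canonical_pair,
)

BASE_FEATURE_NAMES = (
    "chem",
    "ppi_cross_max",
    "ppi_cross_mean",
    "ppi_within_sum_max",
    "ppi_within_sum_mean",
    "ppi_within_absdiff_max",
    "ppi_within_absdiff_mean",
)


@dataclass(frozen=True)
class PairFeatureVector:
    pair: Tuple[str, str]
    names: Tuple[str, ...]
    values: np.ndarray
    label: str = "unlabeled"

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValueError("names and values differ in length")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("feature values must be finite and non-negative")


def chemical_feature(d1: str, d2: str, chem: ScoreTable) -> float:
    """Chemical interaction confidence score of the pair; 0 when absent."""
    return chem.score(d1, d2)


def cross_group_features(
    t1: FrozenSet[str], t2: FrozenSet[str], ppi: ScoreTable
) -> Tuple[float, float]:
    """Max and mean confidence score over all cross pairs between two target sets.

    Cross pairs whose two proteins are the identical shared target are
    excluded (a protein has no self-interaction score); the mean divides
    by the number of evaluated pairs.
    """
    if not t1 or not t2:
        raise ValueError("target sets must be non-empty")
    scores = [ppi.score(a, b) for a in t1 for b in t2 if a != b]
    if not scores:
        return 0.0, 0.0
    return float(max(scores)), float(np.mean(scores))


def _within_stats(targets: FrozenSet[str], ppi: ScoreTable) -> Tuple[float, float]:
    # Singleton sets have no within pairs; both stats default to 0,
    # consistent with the zero-default score convention.
    pairs = list(itertools.combinations(sorted(targets), 2))
    if not pairs:
        return 0.0, 0.0
    scores = [ppi.score(a, b) for a, b in pairs]
    return float(max(scores)), float(np.mean(scores))


def within_group_features(
    t1: FrozenSet[str], t2: FrozenSet[str], ppi: ScoreTable
) -> Tuple[float, float, float, float]:
    """Order-free combination of each drug's within-target-set max and mean.

    Returns (max1+max2, mean1+mean2, |max1-max2|, |mean1-mean2|).
    """
    if not t1 or not t2:
        raise ValueError("target sets must be non-empty")
    v1_max, v1_mean = _within_stats(t1, ppi)
    v2_max, v2_mean = _within_stats(t2, ppi)
    return (
        v1_max + v2_max,
        v1_mean + v2_mean,
        abs(v1_max - v2_max),
        abs(v1_mean - v2_mean),
    )


def pathway_features(e1: EnrichmentProfile, e2: EnrichmentProfile) -> np.ndarray:
    """P sums then P absolute differences of two enrichment profiles."""
    if e1.pathway_ids != e2.pathway_ids:
        raise ValueError(
            f"profiles for {e1.drug_id} and {e2.drug_id} have mismatched pathway order"
        )
    return np.concatenate([e1.scores + e2.scores, np.abs(e1.scores - e2.scores)])


def feature_names(pathway_ids: Sequence[str]) -> Tuple[str, ...]:
    """Stable column names for the full 7 + 2P encoding."""
    return (
        BASE_FEATURE_NAMES
        + tuple(f"sum:{p}" for p in pathway_ids)
        + tuple(f"absdiff:{p}" for p in pathway_ids)
    )


def build_pair_vector(
    d1: str,
    d2: str,
    drugs: Dict[str, DrugRecord],
    chem: ScoreTable,
    ppi: ScoreTable,
    profiles: Dict[str, EnrichmentProfile],
    label: str = "unlabeled",
) -> PairFeatureVector:
    for d in (d1, d2):
        if d not in drugs:
            raise KeyError(f"pair ({d1},{d2}): drug {d!r} has no target record")
        if d not in profiles:
            raise KeyError(f"pair ({d1},{d2}): drug {d!r} has no enrichment profile")
    t1, t2 = drugs[d1].targets, drugs[d2].targets
    cross_max, cross_mean = cross_group_features(t1, t2, ppi)
    within = within_group_features(t1, t2, ppi)
    base = np.array(
        [chemical_feature(d1, d2, chem), cross_max, cross_mean, *within]
    )
    values = np.concatenate([base, pathway_features(profiles[d1], profiles[d2])])
    names = feature_names(profiles[d1].pathway_ids)
    return PairFeatureVector(
        pair=canonical_pair(d1, d2), names=names, values=values, label=label
    )


def build_matrix(
    labels: CombinationLabelSet,
    drugs: Dict[str, DrugRecord],
    chem: ScoreTable,
    ppi: ScoreTable,
    profiles: Dict[str, EnrichmentProfile],
) -> pd.DataFrame:
    """Labelled feature matrix: positives first, then negatives, sorted within class.

    Columns: drug1, drug2, label (1/0), then the feature columns.
    """
    rows = []
    for pair_set, y in ((labels.positives, 1), (labels.negatives, 0)):
        for d1, d2 in sorted(pair_set):
            vec = build_pair_vector(
                d1, d2, drugs, chem, ppi, profiles,
                label="positive" if y else "negative",
            )
            rows.append((d1, d2, y, vec))
    if not rows:
        raise ValueError("no pairs to encode")
    names = rows[0][3].names
    data = np.stack([r[3].values for r in rows])
    df = pd.DataFrame(data, columns=list(names))
    df.insert(0, "label", [r[2] for r in rows])
    df.insert(0, "drug2", [r[1] for r in rows])
    df.insert(0, "drug1", [r[0] for r in rows])
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def split_matrix(df: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray, List[str]]:
    """(X, y, feature names) from a matrix frame with drug1/drug2/label columns."""
    names = [c for c in df.columns if c not in ("drug1", "drug2", "label")]
    return df[names].to_numpy(dtype=float), df["label"].to_numpy(dtype=int), names
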