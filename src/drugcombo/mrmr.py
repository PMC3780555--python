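"""Minimum-redundancy maximum-relevance feature ranking.

Continuous columns are discretized into three states at mean +/- one
sample standard deviation. Relevance and redundancy are plug-in mutual
information (base 2) on the discretized data. Two orderings are
produced: MaxRel (relevance only) and mRMR (greedy, relevance minus mean
redundancy with the already-selected set by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd


def discretize(column: np.ndarray) -> np.ndarray:
    """Map a numeric column to {-1, 0, 1} at mean +/- sample standard deviation.

    Values below mean - sd map to -1, above mean + sd to +1, else 0.
    Constant columns (sd = 0) map entirely to 0.
    """
    x = np.asarray(column, dtype=float)
    if x.ndim != 1:
        raise ValueError("discretize expects a 1-D column")
    if not np.all(np.isfinite(x)):
        raise ValueError("column must be finite")
    mean = x.mean()
    sd = x.std(ddof=1) if len(x) > 1 else 0.0
    out = np.zeros(len(x), dtype=np.int8)
    if sd > 0:
        out[x < mean - sd] = -1
        out[x > mean + sd] = 1
    return out


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information of two discrete vectors, in bits."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = len(x)
    if n == 0:
        raise ValueError("vectors must be non-empty")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    kx, ky = xi.max() + 1, yi.max() + 1
    joint = np.bincount(xi * ky + yi, minlength=kx * ky).reshape(kx, ky) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    mi = float(np.sum(joint[nz] * np.log2(joint[nz] / np.outer(px, py)[nz])))
    return max(mi, 0.0)


@dataclass
class RankedFeatureLists:
    """MaxRel and mRMR orderings plus the per-step greedy trace."""

    maxrel: List[str]
    mrmr: List[str]
    relevance: Dict[str, float]
    selection_trace: List[Tuple[str, float, float, float]] = field(default_factory=list)

    def to_frames(self) -> Tuple[pd.DataFrame, pd.DataFrame]:
        maxrel_df = pd.DataFrame(
            {
                "rank": np.arange(1, len(self.maxrel) + 1),
                "feature": self.maxrel,
                "relevance": [self.relevance[f] for f in self.maxrel],
            }
        )
        mrmr_df = pd.DataFrame(
            [
                (i + 1, f, rel, red, obj)
                for i, (f, rel, red, obj) in enumerate(self.selection_trace)
            ],
            columns=["rank", "feature", "relevance", "redundancy", "objective"],
        )
        return maxrel_df, mrmr_df


def rank_features(
    X: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
    variant: str = "MID",
    n_select: int | None = None,
) -> RankedFeatureLists:
    """Rank all features by MaxRel and by greedy mRMR.

    ``variant`` selects the greedy objective: "MID" (relevance minus mean
    redundancy, the cited program's default) or "MIQ" (relevance divided
    by mean redundancy). Ties break toward the lower original column
    index, making the ordering fully deterministic. ``n_select`` stops
    the greedy pass after that many features (the mrmr list is then a
    prefix); by default every feature is ranked and both lists are full
    permutations of the feature set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per label")
    if X.shape[1] < 2:
        raise ValueError("need at least 2 features")
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if variant not in ("MID", "MIQ"):
        raise ValueError(f"unknown mRMR variant {variant!r}")

    n_feat = X.shape[1]
    disc = np.stack([discretize(X[:, j]) for j in range(n_feat)], axis=1)
    y_disc = np.asarray(y)

    relevance = np.array(
        [mutual_information(disc[:, j], y_disc) for j in range(n_feat)]
    )

    # Stable sort on (-relevance, index) implements the tie rule.
    maxrel_idx = np.lexsort((np.arange(n_feat), -relevance))

    selected: List[int] = []
    remaining = list(range(n_feat))
    redundancy_sum = np.zeros(n_feat)
    trace: List[Tuple[str, float, float, float]] = []

    first = int(maxrel_idx[0])
    selected.append(first)
    remaining.remove(first)
    trace.append((names[first], float(relevance[first]), 0.0, float(relevance[first])))

    if n_select is None:
        n_select = n_feat
    if not 1 <= n_select <= n_feat:
        raise ValueError(f"n_select={n_select} out of range")

    while remaining and len(selected) < n_select:
        last = selected[-1]
        for j in remaining:
            redundancy_sum[j] += mutual_information(disc[:, j], disc[:, last])
        k = len(selected)
        best_j, best_obj = -1, -np.inf
        # remaining is ascending, so strict > keeps the lowest index on ties
        for j in remaining:
            red = redundancy_sum[j] / k
            if variant == "MID":
                obj = relevance[j] - red
            else:
                obj = relevance[j] / max(red, 1e-12)
            if obj > best_obj:
                best_j, best_obj = j, obj
        red = redundancy_sum[best_j] / k
        trace.append((names[best_j], float(relevance[best_j]), float(red), float(best_obj)))
        selected.append(best_j)
        remaining.remove(best_j)

    rel_map = {names[j]: float(relevance[j]) for j in range(n_feat)}
    return RankedFeatureLists(
        maxrel=[names[j] for j in maxrel_idx],
        mrmr=[names[j] for j in selected],
        relevance=rel_map,
        selection_trace=trace,
    )


def write_ranked_lists(lists: RankedFeatureLists, maxrel_path, mrmr_path) -> None:
    maxrel_df, mrmr_df = lists.to_frames()
    maxrel_df.to_csv(maxrel_path, sep="\t", index=False, float_format="%.10g")
    mrmr_df.to_csv(mrmr_path, sep="\t", index=False, float_format="%.10g")
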