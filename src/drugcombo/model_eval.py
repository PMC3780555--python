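"""Random-forest evaluation: confusion metrics, 5-fold CV, incremental feature selection.

The forest follows the classical configuration: bootstrap-resampled,
fully grown trees, a small random candidate-feature count per split
(floor(log2 M) + 1 by default), majority vote, with the positive-vote
fraction as the ranking score for the ROC curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score


def default_mtry(n_features: int) -> int:
    """floor(log2 M) + 1 candidate features per split."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return int(math.floor(math.log2(n_features))) + 1


@dataclass(frozen=True)
class ForestConfig:
    n_trees: int = 10
    m_try: Optional[int] = None  # None -> floor(log2 M) + 1 at fit time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")

    def resolve_mtry(self, n_features: int) -> int:
        m = self.m_try if self.m_try is not None else default_mtry(n_features)
        if not (1 <= m <= n_features):
            raise ValueError(f"m_try={m} out of range for {n_features} features")
        return m


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sp: float
    sn: float
    mcc: float
    auc: float  # NaN when undefined (single-class labels)

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> Dict[str, float]:
        return {
            "tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
            "acc": self.acc, "sp": self.sp, "sn": self.sn,
            "mcc": self.mcc, "auc": self.auc,
        }


def compute_metrics(
    labels: np.ndarray, predictions: np.ndarray, scores: Optional[np.ndarray] = None
) -> ConfusionMetrics:
    """Confusion counts, ACC/SP/SN, MCC (0 when its denominator is 0) and AUC.

    AUC is the trapezoid-convention area under the ROC traced over all
    thresholds of ``scores``; it is NaN when scores are omitted or labels
    contain a single class.
    """
    y = np.asarray(labels).astype(int)
    p = np.asarray(predictions).astype(int)
    if y.shape != p.shape or y.ndim != 1:
        raise ValueError("labels and predictions must be 1-D and equal length")
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    n = tp + tn + fp + fn
    acc = (tp + tn) / n if n else float("nan")
    sp = tn / (tn + fp) if (tn + fp) else float("nan")
    sn = tp / (tp + fn) if (tp + fn) else float("nan")
    denom = math.sqrt(
        float(tn + fn) * float(tn + fp) * float(tp + fn) * float(tp + fp)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    if scores is not None and len(np.unique(y)) == 2:
        s = np.asarray(scores, dtype=float)
        if s.shape != y.shape:
            raise ValueError("scores must match labels in length")
        auc = float(roc_auc_score(y, s))
    else:
        auc = float("nan")
    return ConfusionMetrics(tp, tn, fp, fn, acc, sp, sn, mcc, auc)


def make_folds(n: int, folds: int, seed: int) -> List[np.ndarray]:
    """Unstratified random partition into near-equal folds (sizes differ by <= 1)."""
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > n:
        raise ValueError(f"cannot split {n} rows into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, folds)]


def _fold_seed(master: int, fold: int) -> int:
    # Counter scheme: each fold draws its forest seed from an independent
    # stream keyed by (master, fold), so adding evaluations never
    # perturbs earlier ones.
    return int(np.random.SeedSequence([master, fold]).generate_state(1)[0])


def _vote_fraction(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting for the positive class."""
    votes = np.zeros(X.shape[0])
    for tree in forest.estimators_:
        pred = forest.classes_.take(np.argmax(tree.predict_proba(X), axis=1))
        votes += (pred == 1)
    return votes / len(forest.estimators_)


def crossval(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    feature_subset: Sequence[str],
    folds: int = 5,
    config: ForestConfig = ForestConfig(),
    cv_seed: int = 0,
) -> ConfusionMetrics:
    """k-fold cross-validated forest metrics on a feature subset.

    Each row is predicted exactly once; metrics are pooled over all rows.
    The per-row score is the fraction of trees voting positive.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    name_to_col = {nm: j for j, nm in enumerate(feature_names)}
    missing = [f for f in feature_subset if f not in name_to_col]
    if missing:
        raise KeyError(f"features not in matrix: {missing[:5]}")
    cols = [name_to_col[f] for f in feature_subset]
    Xs = X[:, cols]
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    n = len(y)
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    mtry = config.resolve_mtry(len(cols))
    for i, test_idx in enumerate(make_folds(n, folds, cv_seed)):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=mtry,
            bootstrap=True,
            oob_score=False,
            random_state=_fold_seed(config.seed, i),
        )
        forest.fit(Xs[mask], y[mask])
        frac = _vote_fraction(forest, Xs[test_idx])
        preds[test_idx] = (frac > 0.5).astype(int)
        scores[test_idx] = frac
    return compute_metrics(y, preds, scores)


@dataclass
class IFSResult:
    """Metric rows for each mRMR-prefix size and the MCC-optimal prefix."""

    rows: List[Tuple[int, ConfusionMetrics]]
    optimal_k: int
    optimal_features: List[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"k": k, **m.as_dict()} for k, m in self.rows]
        )


def run_ifs(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: Sequence[str],
    mrmr_list: Sequence[str],
    k_max: Optional[int] = None,
    folds: int = 5,
    config: ForestConfig = ForestConfig(),
    cv_seed: int = 0,
    progress: bool = False,
) -> IFSResult:
    """Evaluate nested prefixes of the mRMR list and pick the MCC-optimal size.

    Every prefix size k = 1..k_max is cross-validated with the same fold
    partition (``cv_seed``); the forest seed for each (k, fold) derives
    from (config.seed, k, fold) so extending k_max never changes earlier
    rows. Ties on MCC resolve to the smallest k.
    """
    if k_max is None:
        k_max = len(mrmr_list)
    if k_max > len(mrmr_list):
        raise ValueError(f"k_max={k_max} exceeds list length {len(mrmr_list)}")
    rows: List[Tuple[int, ConfusionMetrics]] = []
    for k in range(1, k_max + 1):
        k_master = int(np.random.SeedSequence([config.seed, k]).generate_state(1)[0])
        k_config = ForestConfig(
            n_trees=config.n_trees, m_try=config.m_try, seed=k_master
        )
        metrics = crossval(
            X, y, feature_names, mrmr_list[:k],
            folds=folds, config=k_config, cv_seed=cv_seed,
        )
        rows.append((k, metrics))
        if progress and k % 25 == 0:
            print(f"  IFS k={k}/{k_max} mcc={metrics.mcc:.4f}", flush=True)
    mccs = np.array([m.mcc for _, m in rows])
    optimal_k = int(np.argmax(mccs)) + 1  # argmax returns first max -> smallest k
    return IFSResult(
        rows=rows,
        optimal_k=optimal_k,
        optimal_features=list(mrmr_list[:optimal_k]),
    )


def write_ifs_table(result: IFSResult, path) -> None:
    df = result.to_frame()[["k", "acc", "sp", "sn", "mcc", "auc"]]
    df.columns = ["k", "ACC", "SP", "SN", "MCC", "AUC"]
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_optimal_features(result: IFSResult, path) -> None:
    """Optimal feature list: rank, name, kind flag, pathway id (if any)."""
    rows = []
    for rank, name in enumerate(result.optimal_features, 1):
        if name.startswith("sum:"):
            kind, pw = "+", name.split(":", 1)[1]
        elif name.startswith("absdiff:"):
            kind, pw = "-", name.split(":", 1)[1]
        else:
            kind, pw = ".", ""
        rows.append((rank, name, kind, pw))
    pd.DataFrame(rows, columns=["rank", "feature", "kind", "pathway"]).to_csv(
        path, sep="\t", index=False
    )


def plot_ifs_curve(result: IFSResult, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.to_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(df["k"], df["mcc"], lw=1)
    ax.axvline(result.optimal_k, color="red", ls="--", lw=0.8)
    ax.set_xlabel("number of features")
    ax.set_ylabel("MCC (cross-validated)")
    ax.set_title(f"IFS curve (optimal k={result.optimal_k})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
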