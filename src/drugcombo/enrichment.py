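"""Per-drug pathway enrichment scores.

A drug's gene set is its target set expanded by direct neighbors in the
protein-interaction network. For each pathway the enrichment score is
the -log10 upper-tail hypergeometric probability of the overlap between
that gene set and the pathway's gene set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence

import numpy as np
from scipy import stats

from .interactions import DrugRecord, PathwayAnnotation, ScoreTable

#: Saturation for -log10(p); tail probabilities below 1e-300 hit the
#: double-precision underflow floor.
SCORE_CAP = 300.0


@dataclass(frozen=True)
class GeneSet:
    """Network-expanded gene set attributed to one drug."""

    source_drug: str
    genes: FrozenSet[str]


@dataclass(frozen=True)
class EnrichmentProfile:
    """One enrichment score per pathway, in fixed pathway order."""

    drug_id: str
    pathway_ids: tuple
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pathway_ids) != len(self.scores):
            raise ValueError("scores and pathway_ids differ in length")
        if not np.all(np.isfinite(self.scores)) or np.any(self.scores < 0):
            raise ValueError("enrichment scores must be finite and non-negative")


def expand_targets(
    drug: DrugRecord, ppi: ScoreTable, threshold: float = 0.0
) -> GeneSet:
    """Targets plus every protein interacting with a target above ``threshold``.

    One hop only; a neighbor's neighbors are not included. The default
    threshold 0 counts any positive confidence score as an interaction.
    """
    genes = set(drug.targets)
    for t in drug.targets:
        for p in ppi.neighbors(t):
            if ppi.score(t, p) > threshold:
                genes.add(p)
    return GeneSet(source_drug=drug.drug_id, genes=frozenset(genes))


def enrichment_score(
    n_overlap: int,
    gene_set_size: int,
    pathway_size: int,
    universe_size: int,
    cap: float = SCORE_CAP,
) -> float:
    """-log10 of P[X >= m] with X ~ Hypergeometric(N, M, n).

    Parameters follow the test convention: ``n_overlap`` = m genes shared
    by the gene set and the pathway, ``gene_set_size`` = n draws,
    ``pathway_size`` = M marked genes, ``universe_size`` = N. Returns 0
    when m = 0 (the tail probability is 1) and saturates at ``cap``.
    """
    m, n, M, N = n_overlap, gene_set_size, pathway_size, universe_size
    if not (0 < M <= N):
        raise ValueError(f"pathway size M={M} must satisfy 0 < M <= N={N}")
    if not (0 < n <= N):
        raise ValueError(f"gene set size n={n} must satisfy 0 < n <= N={N}")
    if not (0 <= m <= min(M, n)):
        raise ValueError(f"overlap m={m} out of range for M={M}, n={n}")
    if m == 0:
        return 0.0
    # Survival function at m-1 gives P[X >= m] without naive summation.
    tail = stats.hypergeom.sf(m - 1, N, M, n)
    tail = min(max(float(tail), 0.0), 1.0)
    if tail <= 0.0:
        return cap
    return min(-np.log10(tail), cap)


def score_gene_set(
    gene_set: GeneSet,
    annotation: PathwayAnnotation,
    universe: Optional[FrozenSet[str]] = None,
) -> EnrichmentProfile:
    """Enrichment scores of one gene set against every pathway.

    When a membership ``universe`` is given, both the gene set and the
    pathway sets are intersected with it; otherwise the annotation's
    declared universe size is trusted and only counts are used.
    """
    genes = set(gene_set.genes)
    if universe is not None:
        genes &= universe
    N = annotation.universe_size
    n = len(genes)
    pids = annotation.pathway_ids
    scores = np.zeros(len(pids))
    if n > 0:
        for j, pid in enumerate(pids):
            pw = annotation.pathways[pid]
            if universe is not None:
                pw = pw & universe
            if not pw:
                continue
            m = len(genes & pw)
            scores[j] = enrichment_score(m, n, len(pw), N)
    return EnrichmentProfile(
        drug_id=gene_set.source_drug, pathway_ids=tuple(pids), scores=scores
    )


def profile_all(
    drugs: Iterable[DrugRecord],
    ppi: ScoreTable,
    annotation: PathwayAnnotation,
    threshold: float = 0.0,
    universe: Optional[FrozenSet[str]] = None,
) -> Dict[str, EnrichmentProfile]:
    """One enrichment profile per drug, identical pathway order throughout."""
    if len(annotation) == 0:
        raise ValueError("annotation must contain at least one pathway")
    profiles = {}
    for drug in drugs:
        gs = expand_targets(drug, ppi, threshold=threshold)
        profiles[drug.drug_id] = score_gene_set(gs, annotation, universe=universe)
    return profiles


def write_profiles(profiles: Dict[str, EnrichmentProfile], path) -> None:
    """Persist profiles as TSV: rows = drugs, columns = pathway ids."""
    drug_ids = sorted(profiles)
    if not drug_ids:
        raise ValueError("no profiles to write")
    pids = profiles[drug_ids[0]].pathway_ids
    with open(path, "w") as fh:
        fh.write("drug_id\t" + "\t".join(pids) + "\n")
        for d in drug_ids:
            prof = profiles[d]
            if prof.pathway_ids != pids:
                raise ValueError(f"profile for {d} has mismatched pathway order")
            row = "\t".join("%.10g" % v for v in prof.scores)
            fh.write(f"{d}\t{row}\n")


def read_profiles(path) -> Dict[str, EnrichmentProfile]:
    """Inverse of :func:`write_profiles`."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    pids = tuple(df.columns)
    return {
        str(d): EnrichmentProfile(str(d), pids, df.loc[d].to_numpy(dtype=float))
        for d in df.index
    }
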