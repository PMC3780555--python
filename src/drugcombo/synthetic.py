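"""Synthetic interaction-database-shaped inputs with a plantable pair signal.

Generates drug target tables, sparse symmetric chemical and protein
score tables (0-999 integer scale), pathway gene sets over a large gene
universe, and labelled positive/negative drug pairs. Signal is injected
at the data layer only — boosted chemical scores, extra cross-target
protein edges, and pathway co-membership for positive pairs — so the
full enrichment/featurization path is exercised end-to-end.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Set, Tuple

import numpy as np

from .interactions import (
    CombinationLabelSet,
    DrugRecord,
    PathwayAnnotation,
    ScoreTable,
    all_pairs,
    canonical_pair,
    sample_negatives,
)

SCORE_LOW, SCORE_HIGH = 150, 999


@dataclass(frozen=True)
class SignalConfig:
    """Planted differences between positive and negative pairs."""

    chem_shift: int = 0  # additive chemical-score boost for positive pairs
    cross_ppi_boost: float = 0.0  # prob. of an extra cross-target protein edge
    n_signal_pathways: int = 0  # pathways co-enriched within positive pairs

    def __post_init__(self) -> None:
        if self.chem_shift < 0 or self.n_signal_pathways < 0:
            raise ValueError("signal magnitudes must be non-negative")
        if not 0.0 <= self.cross_ppi_boost <= 1.0:
            raise ValueError("cross_ppi_boost must be a probability")


@dataclass(frozen=True)
class SynthConfig:
    n_drugs: int = 169
    n_proteins: int = 2000
    universe_size: int = 20000
    n_pathways: int = 229
    targets_min: int = 1
    targets_max: int = 8
    chem_density: float = 0.05
    ppi_density: float = 0.002
    pathway_size_min: int = 20
    pathway_size_max: int = 150
    pathway_protein_fraction: float = 0.3
    n_positives: int = 121
    negative_ratio: int = 5
    signal: SignalConfig = field(default_factory=SignalConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_drugs, self.n_proteins, self.universe_size,
               self.n_pathways, self.n_positives, self.negative_ratio) < 1:
            raise ValueError("all counts must be positive")
        if not (1 <= self.targets_min <= self.targets_max <= self.n_proteins):
            raise ValueError("invalid targets_per_drug range")
        for d in (self.chem_density, self.ppi_density, self.pathway_protein_fraction):
            if not 0.0 <= d <= 1.0:
                raise ValueError("densities must be in [0, 1]")
        if self.n_proteins > self.universe_size:
            raise ValueError("proteins must fit inside the gene universe")
        n_pairs = self.n_drugs * (self.n_drugs - 1) // 2
        if self.n_positives * (1 + self.negative_ratio) > n_pairs:
            raise ValueError(
                f"{self.n_positives} positives at ratio {self.negative_ratio} "
                f"exceed the {n_pairs} available pairs"
            )
        if self.signal.n_signal_pathways > self.n_pathways:
            raise ValueError("more signal pathways than pathways")


@dataclass
class SynthDataset:
    config: SynthConfig
    drugs: Dict[str, DrugRecord]
    chem: ScoreTable
    ppi: ScoreTable
    annotation: PathwayAnnotation
    labels: CombinationLabelSet
    signal_pathways: List[str]


def _gene_id(i: int) -> str:
    return f"G{i:06d}"


def _random_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(SCORE_LOW, SCORE_HIGH + 1, size=n)


def _sample_pairs(rng: np.random.Generator, n_items: int, density: float):
    """Bernoulli(density) subset of all unordered index pairs, as (i, j) arrays."""
    iu, ju = np.triu_indices(n_items, k=1)
    n_pairs = len(iu)
    n_edges = rng.binomial(n_pairs, density)
    if n_edges == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    chosen = rng.choice(n_pairs, size=n_edges, replace=False)
    chosen.sort()
    return iu[chosen], ju[chosen]


def generate(config: SynthConfig) -> SynthDataset:
    """Deterministically generate the full input bundle for one seed."""
    ss = np.random.SeedSequence(config.seed)
    (s_targets, s_chem, s_ppi, s_pw, s_pairs, s_neg, s_signal) = [
        np.random.default_rng(child) for child in ss.spawn(7)
    ]
    sig = config.signal

    drug_ids = [f"D{i:04d}" for i in range(1, config.n_drugs + 1)]
    protein_ids = [_gene_id(i) for i in range(1, config.n_proteins + 1)]

    # Target sets: uniform size in the configured range, uniform proteins.
    drugs: Dict[str, DrugRecord] = {}
    for d in drug_ids:
        size = int(s_targets.integers(config.targets_min, config.targets_max + 1))
        idx = s_targets.choice(config.n_proteins, size=size, replace=False)
        drugs[d] = DrugRecord(d, frozenset(protein_ids[i] for i in idx))

    # Labelled pairs: uniform positives, then seeded negative sampling.
    candidates = all_pairs(drug_ids)
    pos_idx = s_pairs.choice(len(candidates), size=config.n_positives, replace=False)
    positives = frozenset(candidates[i] for i in pos_idx)
    neg_seed = int(np.random.SeedSequence([config.seed, 0xFEED]).generate_state(1)[0])
    labels = sample_negatives(
        drug_ids, positives, config.negative_ratio, seed=neg_seed
    )

    # Background chemical scores.
    chem = ScoreTable("chemical")
    ci, cj = _sample_pairs(s_chem, config.n_drugs, config.chem_density)
    for i, j, s in zip(ci, cj, _random_scores(s_chem, len(ci))):
        chem.add(drug_ids[i], drug_ids[j], int(s))
    # Planted chemical shift for positive pairs (clamped to the score scale).
    if sig.chem_shift > 0:
        for a, b in sorted(positives):
            boosted = min(chem.score(a, b) + sig.chem_shift, SCORE_HIGH)
            chem.add(a, b, boosted)

    # Background protein-protein scores.
    ppi = ScoreTable("protein")
    pi, pj = _sample_pairs(s_ppi, config.n_proteins, config.ppi_density)
    for i, j, s in zip(pi, pj, _random_scores(s_ppi, len(pi))):
        ppi.add(protein_ids[i], protein_ids[j], int(s))
    # Planted cross-target edges for positive pairs.
    if sig.cross_ppi_boost > 0:
        for a, b in sorted(positives):
            for t1 in sorted(drugs[a].targets):
                for t2 in sorted(drugs[b].targets):
                    if t1 != t2 and s_signal.random() < sig.cross_ppi_boost:
                        ppi.add(t1, t2, int(_random_scores(s_signal, 1)[0]))

    # Pathways: a fraction of each gene set drawn from the protein range so
    # background overlaps (and hence nonzero enrichment scores) occur.
    pathway_sets: Dict[str, Set[str]] = {}
    pathway_ids = [f"pw{j:04d}" for j in range(1, config.n_pathways + 1)]
    for pid in pathway_ids:
        size = int(s_pw.integers(config.pathway_size_min, config.pathway_size_max + 1))
        n_prot = int(round(size * config.pathway_protein_fraction))
        genes: Set[str] = set()
        if n_prot > 0:
            idx = s_pw.choice(config.n_proteins, size=n_prot, replace=False)
            genes.update(protein_ids[i] for i in idx)
        n_rest = size - len(genes)
        if n_rest > 0:
            idx = s_pw.choice(
                config.universe_size - config.n_proteins, size=n_rest, replace=False
            )
            genes.update(_gene_id(config.n_proteins + 1 + i) for i in idx)
        pathway_sets[pid] = genes

    # Pathway co-membership signal: each positive pair is assigned one
    # signal pathway (round robin) that absorbs both drugs' expanded gene
    # sets (targets plus network neighbors), so both partners become
    # strongly enriched in the same pathway.
    signal_pathways = pathway_ids[: sig.n_signal_pathways]
    if signal_pathways:
        from .enrichment import expand_targets

        for i, (a, b) in enumerate(sorted(positives)):
            pid = signal_pathways[i % len(signal_pathways)]
            pathway_sets[pid].update(expand_targets(drugs[a], ppi).genes)
            pathway_sets[pid].update(expand_targets(drugs[b], ppi).genes)

    annotation = PathwayAnnotation(
        {pid: frozenset(g) for pid, g in pathway_sets.items()},
        universe_size=config.universe_size,
    )
    return SynthDataset(
        config=config,
        drugs=drugs,
        chem=chem,
        ppi=ppi,
        annotation=annotation,
        labels=labels,
        signal_pathways=signal_pathways,
    )


# ---------------------------------------------------------------------------
# File output, matching the dialects the loaders read.

STITCH_COLUMNS = (
    "chemical1", "chemical2", "similarity", "experimental",
    "database", "textmining", "combined_score",
)


def write_inputs(data: SynthDataset, outdir) -> Dict[str, str]:
    """Write the five input files; returns a name -> path map."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "targets": os.path.join(outdir, "drug_targets.tsv"),
        "chem": os.path.join(outdir, "chemical_links.tsv"),
        "ppi": os.path.join(outdir, "protein_links.tsv"),
        "pathways": os.path.join(outdir, "pathways.gmt"),
        "positives": os.path.join(outdir, "positive_pairs.tsv"),
        "negatives": os.path.join(outdir, "negative_pairs.tsv"),
    }
    with open(paths["targets"], "w") as fh:
        fh.write("drug_id\tprotein_id\n")
        for d in sorted(data.drugs):
            for t in sorted(data.drugs[d].targets):
                fh.write(f"{d}\t{t}\n")
    with open(paths["chem"], "w") as fh:
        fh.write("\t".join(STITCH_COLUMNS) + "\n")
        for (a, b), s in data.chem.items():
            fh.write(f"{a}\t{b}\t0\t0\t0\t0\t{int(s)}\n")
    with open(paths["ppi"], "w") as fh:
        fh.write("protein1\tprotein2\tcombined_score\n")
        for (a, b), s in data.ppi.items():
            fh.write(f"{a}\t{b}\t{int(s)}\n")
    with open(paths["pathways"], "w") as fh:
        for pid, genes in data.annotation.pathways.items():
            fh.write(pid + "\tsynthetic pathway\t" + "\t".join(sorted(genes)) + "\n")
    for key, pair_set in (
        ("positives", data.labels.positives),
        ("negatives", data.labels.negatives),
    ):
        with open(paths[key], "w") as fh:
            fh.write("drug1\tdrug2\n")
            for a, b in sorted(pair_set):
                fh.write(f"{a}\t{b}\n")
    return paths
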