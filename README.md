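# drugcombo

Classify drug pairs as effective/ineffective combinations from three data
layers: chemical-chemical interaction scores, protein-protein interactions
between and within the drugs' target sets, and pathway enrichment of the
network-expanded target sets. Features are ranked by minimum-redundancy
maximum-relevance (mRMR) mutual information, and a random forest under
5-fold cross-validation drives incremental feature selection (IFS) to an
MCC-optimal feature subset.

## Method outline

Each unordered drug pair is encoded as a `7 + 2P` feature vector
(`P` = number of pathways; 465 dimensions at `P = 229`):

1. **chem** — the pair's chemical interaction confidence score (0 when absent);
2. **ppi_cross_max / ppi_cross_mean** — max and mean protein confidence score
   over all cross pairs between the two target sets;
3. four **ppi_within_*** features — order-free sums and absolute differences
   of each drug's within-target-set max and mean;
4. `P` sums and `P` absolute differences of the two drugs' pathway
   enrichment scores, where a drug's enrichment score for a pathway is the
   `-log10` upper-tail hypergeometric probability of the overlap between the
   pathway's gene set and the drug's targets plus their direct network
   neighbors.

Features are discretized at mean ± one sample standard deviation into three
states; plug-in mutual information (bits) yields a MaxRel list (relevance
only) and an mRMR list (greedy, relevance minus mean redundancy — MID; MIQ
available). IFS evaluates every prefix of the mRMR list with a 10-tree
random forest (`m_try = ⌊log2 M⌋ + 1` candidate features per split,
bootstrap, unpruned, majority vote) under seeded unstratified 5-fold CV and
reports ACC, SP, SN, MCC and AUC per prefix, selecting the smallest prefix
with maximal MCC.

Note: relevance and the feature lists are computed once on the full labelled
matrix, not per CV fold. This mirrors the original workflow but means the
IFS curve carries selection bias; treat the reported CV metrics accordingly.

## CLI

The `drugcombo` command runs the pipeline stages — `synth`, `enrich`,
`featurize`, `rank`, `ifs`, `report` — individually or end to end:

```bash
# full run on default synthetic data (169 drugs, 121/605 pairs, 229
# pathways -> a 726 x 465 matrix), all randomness tied to one seed
drugcombo all --outdir run1 --seed 7

# or from a YAML config with explicit input files
drugcombo all --config config.yaml
```

Config keys mirror `drugcombo.pipeline.RunConfig`; either a `synth:` block
(see `drugcombo.synthetic.SynthConfig`) or explicit `targets_path`,
`chem_path`, `ppi_path`, `gmt_path`, `positives_path` (TSV/GMT dialects
described below). Every stage persists its outputs in the run directory
(`enrichment.tsv`, `feature_matrix.tsv`, `maxrel_list.tsv`, `mrmr_list.tsv`,
`ifs_table.tsv`, `ifs_curve.svg`, `optimal_features.tsv`) plus a
`manifest.json` recording the config hash, all seeds and per-stage counts;
identical configs reproduce byte-identical artifacts.

Input dialects: chemical links as STITCH-style TSV (`chemical1`,
`chemical2`, ..., `combined_score`; gzip or plain; score column
configurable), protein links as STRING-style TSV (`protein1`, `protein2`,
`combined_score`), drug targets as two-column TSV, pathways as GMT plus a
configured gene-universe size, pair lists as two-column TSV. Scores stay
on their raw 0–999 scale; absent pairs score exactly 0.

## Synthetic data

`drugcombo.synthetic` generates all five input files with a configurable
planted signal — a chemical-score shift for positive pairs, extra
cross-target protein edges, and pathway co-membership of positive-pair
partners — injected at the data layer only, so the entire enrichment and
featurization path is exercised. The defaults reproduce the study-scale
matrix shape (726 × 465).

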