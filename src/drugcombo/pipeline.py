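"""Stage orchestration: generate/ingest -> enrich -> featurize -> rank -> ifs -> report.

Every stage reads declared inputs from the run directory and persists
its outputs there, so stages are individually re-runnable. A manifest
records the config hash, every seed, and per-stage row/column counts;
identical configs reproduce identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import enrichment as enr
from . import features as feat
from . import interactions as ia
from . import model_eval as me
from . import mrmr
from . import synthetic as synth

logger = logging.getLogger(__name__)

STAGES = ("synth", "enrich", "featurize", "rank", "ifs", "report")


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    outdir: str = "run"
    # Either synthetic generation...
    synth: Optional[synth.SynthConfig] = field(default_factory=synth.SynthConfig)
    # ...or pre-existing input files (paths override synth when all set).
    targets_path: Optional[str] = None
    chem_path: Optional[str] = None
    ppi_path: Optional[str] = None
    gmt_path: Optional[str] = None
    positives_path: Optional[str] = None
    negatives_path: Optional[str] = None

    universe_size: int = 20000
    chem_score_column: str = "combined_score"
    ppi_score_column: str = "combined_score"
    neighbor_threshold: float = 0.0
    negative_ratio: int = 5
    mrmr_variant: str = "MID"
    folds: int = 5
    n_trees: int = 10
    m_try: Optional[int] = None
    k_max: Optional[int] = None
    sampling_seed: int = 0
    cv_seed: int = 0
    forest_seed: int = 0

    @classmethod
    def from_dict(cls, d: Dict) -> "RunConfig":
        d = dict(d)
        if "synth" in d and d["synth"] is not None and not isinstance(d["synth"], synth.SynthConfig):
            sd = dict(d["synth"])
            if "signal" in sd and sd["signal"] is not None:
                sd["signal"] = synth.SignalConfig(**sd["signal"])
            d["synth"] = synth.SynthConfig(**sd)
        return cls(**d)

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        # outdir is excluded: it names where results go, not what they are.
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _path(cfg: RunConfig, name: str) -> str:
    return os.path.join(cfg.outdir, name)


ARTIFACTS = {
    "enrichment": "enrichment.tsv",
    "matrix": "feature_matrix.tsv",
    "maxrel": "maxrel_list.tsv",
    "mrmr": "mrmr_list.tsv",
    "ifs_table": "ifs_table.tsv",
    "ifs_curve": "ifs_curve.svg",
    "optimal_features": "optimal_features.tsv",
    "manifest": "manifest.json",
}


class PipelineRun:
    """Holds config plus the manifest being accumulated across stages."""

    def __init__(self, config: RunConfig):
        self.config = config
        os.makedirs(config.outdir, exist_ok=True)
        self.manifest_path = _path(config, ARTIFACTS["manifest"])
        if os.path.exists(self.manifest_path):
            with open(self.manifest_path) as fh:
                self.manifest = json.load(fh)
            if self.manifest.get("config_hash") != config.config_hash():
                # Config changed: stale stage records no longer apply.
                self.manifest = self._fresh_manifest()
        else:
            self.manifest = self._fresh_manifest()

    def _fresh_manifest(self) -> Dict:
        return {
            "config_hash": self.config.config_hash(),
            "config": self.config.to_dict(),
            "seeds": {
                "sampling": self.config.sampling_seed,
                "cv": self.config.cv_seed,
                "forest": self.config.forest_seed,
                "synth": self.config.synth.seed if self.config.synth else None,
            },
            "stages": {},
        }

    def _record(self, stage: str, **counts) -> None:
        self.manifest["stages"][stage] = counts
        self.manifest["manifest_hash"] = hashlib.sha256(
            json.dumps(
                {k: self.manifest[k] for k in ("config_hash", "seeds", "stages")},
                sort_keys=True,
            ).encode()
        ).hexdigest()[:16]
        with open(self.manifest_path, "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def _input_paths(self) -> Dict[str, str]:
        cfg = self.config
        explicit = {
            "targets": cfg.targets_path,
            "chem": cfg.chem_path,
            "ppi": cfg.ppi_path,
            "pathways": cfg.gmt_path,
            "positives": cfg.positives_path,
            "negatives": cfg.negatives_path,
        }
        if all(v for k, v in explicit.items() if k != "negatives"):
            return {k: v for k, v in explicit.items() if v}
        synth_dir = _path(cfg, "inputs")
        names = {
            "targets": "drug_targets.tsv",
            "chem": "chemical_links.tsv",
            "ppi": "protein_links.tsv",
            "pathways": "pathways.gmt",
            "positives": "positive_pairs.tsv",
            "negatives": "negative_pairs.tsv",
        }
        return {k: os.path.join(synth_dir, v) for k, v in names.items()}

    # -- stages ------------------------------------------------------------

    def stage_synth(self) -> None:
        cfg = self.config
        if cfg.synth is None:
            raise StageError("synth", "no_config", "no synthetic config supplied")
        t0 = time.perf_counter()
        data = synth.generate(cfg.synth)
        synth.write_inputs(data, _path(cfg, "inputs"))
        logger.info("synth: %.2fs", time.perf_counter() - t0)
        self._record(
            "synth",
            n_drugs=len(data.drugs),
            chem_entries=len(data.chem),
            ppi_entries=len(data.ppi),
            n_pathways=len(data.annotation),
            n_positives=len(data.labels.positives),
            n_negatives=len(data.labels.negatives),
        )

    def stage_enrich(self) -> None:
        cfg = self.config
        paths = self._input_paths()
        t0 = time.perf_counter()
        try:
            drugs = ia.load_drug_targets(paths["targets"])
            ppi = ia.load_score_table(
                paths["ppi"], "protein", cfg.ppi_score_column
            )
            annotation = ia.load_gmt(paths["pathways"], cfg.universe_size)
        except (OSError, ia.ConfigurationError) as e:
            raise StageError("enrich", "bad_input", str(e)) from e
        profiles = enr.profile_all(
            drugs.values(), ppi, annotation, threshold=cfg.neighbor_threshold
        )
        enr.write_profiles(profiles, _path(cfg, ARTIFACTS["enrichment"]))
        logger.info("enrich: %.2fs", time.perf_counter() - t0)
        self._record(
            "enrich", n_drugs=len(profiles), n_pathways=len(annotation)
        )

    def stage_featurize(self) -> None:
        cfg = self.config
        paths = self._input_paths()
        t0 = time.perf_counter()
        try:
            drugs = ia.load_drug_targets(paths["targets"])
            chem = ia.load_score_table(paths["chem"], "chemical", cfg.chem_score_column)
            ppi = ia.load_score_table(paths["ppi"], "protein", cfg.ppi_score_column)
            profiles = enr.read_profiles(_path(cfg, ARTIFACTS["enrichment"]))
            positives = ia.load_pair_list(paths["positives"])
        except (OSError, ia.ConfigurationError) as e:
            raise StageError("featurize", "bad_input", str(e)) from e
        if "negatives" in paths and os.path.exists(paths["negatives"]):
            negatives = ia.load_pair_list(paths["negatives"])
            labels = ia.CombinationLabelSet(
                frozenset(positives), frozenset(negatives)
            )
        else:
            labels = ia.sample_negatives(
                sorted(drugs), positives, cfg.negative_ratio, cfg.sampling_seed
            )
        labels.validate_drugs(drugs)
        try:
            df = feat.build_matrix(labels, drugs, chem, ppi, profiles)
        except KeyError as e:
            raise StageError("featurize", "unresolvable_drug", str(e)) from e
        feat.write_matrix(df, _path(cfg, ARTIFACTS["matrix"]))
        logger.info("featurize: %.2fs", time.perf_counter() - t0)
        self._record(
            "featurize", n_rows=len(df), n_features=df.shape[1] - 3
        )

    def stage_rank(self) -> None:
        cfg = self.config
        t0 = time.perf_counter()
        try:
            df = feat.read_matrix(_path(cfg, ARTIFACTS["matrix"]))
        except OSError as e:
            raise StageError("rank", "missing_matrix", str(e)) from e
        X, y, names = feat.split_matrix(df)
        lists = mrmr.rank_features(X, y, names, variant=cfg.mrmr_variant)
        mrmr.write_ranked_lists(
            lists, _path(cfg, ARTIFACTS["maxrel"]), _path(cfg, ARTIFACTS["mrmr"])
        )
        logger.info("rank: %.2fs", time.perf_counter() - t0)
        self._record("rank", n_features=len(lists.mrmr))

    def stage_ifs(self) -> None:
        import pandas as pd

        cfg = self.config
        t0 = time.perf_counter()
        try:
            df = feat.read_matrix(_path(cfg, ARTIFACTS["matrix"]))
            mrmr_df = pd.read_csv(_path(cfg, ARTIFACTS["mrmr"]), sep="\t")
        except OSError as e:
            raise StageError("ifs", "missing_input", str(e)) from e
        X, y, names = feat.split_matrix(df)
        mrmr_list = list(mrmr_df["feature"])
        forest = me.ForestConfig(
            n_trees=cfg.n_trees, m_try=cfg.m_try, seed=cfg.forest_seed
        )
        result = me.run_ifs(
            X, y, names, mrmr_list,
            k_max=cfg.k_max, folds=cfg.folds, config=forest, cv_seed=cfg.cv_seed,
        )
        me.write_ifs_table(result, _path(cfg, ARTIFACTS["ifs_table"]))
        me.write_optimal_features(result, _path(cfg, ARTIFACTS["optimal_features"]))
        me.plot_ifs_curve(result, _path(cfg, ARTIFACTS["ifs_curve"]))
        logger.info("ifs: %.2fs", time.perf_counter() - t0)
        best = dict(result.rows)[result.optimal_k]
        self._record(
            "ifs",
            k_evaluated=len(result.rows),
            optimal_k=result.optimal_k,
            optimal_mcc=round(best.mcc, 10),
        )

    def stage_report(self) -> None:
        # The manifest is maintained incrementally; report just re-seals it.
        self._record("report", stages_complete=sorted(self.manifest["stages"]))

    def run(self, stages: Optional[List[str]] = None) -> Dict:
        if stages is None:
            stages = [s for s in STAGES if s != "synth" or self.config.synth]
        dispatch = {
            "synth": self.stage_synth,
            "enrich": self.stage_enrich,
            "featurize": self.stage_featurize,
            "rank": self.stage_rank,
            "ifs": self.stage_ifs,
            "report": self.stage_report,
        }
        for s in stages:
            if s not in dispatch:
                raise StageError(s, "unknown_stage", f"valid stages: {STAGES}")
            dispatch[s]()
        return self.manifest


def run_pipeline(config: RunConfig, stages: Optional[List[str]] = None) -> Dict:
    return PipelineRun(config).run(stages)
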