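"""End-to-end orchestration: simulate -> preprocess -> mine -> cross-validate
-> verify -> network, with a reproducible run manifest."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import evaluation, mining, network, preprocessing, verification
from .records import load_records, write_records
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("comorbnet")


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs; loadable from YAML."""

    input_csv: str | None = None          # existing diagnosis table, or None to simulate
    simulate: bool = True
    n_patients: int = 1488
    min_sup: float = 0.001
    min_conf: float = 0.0
    min_lift: float = 1.0
    min_items: int = 2
    k: int = 10
    c_grid: Sequence[float] = tuple(round(0.1 * i, 1) for i in range(11))
    seed: int = 0
    cache_csv: str | None = "builtin"  # shipped synthetic snapshot; None skips
    literature_csv: str | None = None
    mapping_overrides_csv: str | None = None
    block_table_csv: str | None = None
    out_dir: str = "comorbnet_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if not 0 < self.min_sup <= 1:
            raise ValueError("min_sup must be in (0,1]")
        if not 0 <= self.min_conf <= 1:
            raise ValueError("min_conf must be in [0,1]")
        if self.min_lift < 0:
            raise ValueError("min_lift must be non-negative")
        if any(not 0 <= c <= 1 for c in self.c_grid):
            raise ValueError("C grid values must lie in [0,1]")
        for attr in ("input_csv", "cache_csv", "literature_csv",
                     "mapping_overrides_csv", "block_table_csv"):
            p = getattr(self, attr)
            if p is not None and p != "builtin" and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage in order and write all artifacts plus a manifest.

    Returns the manifest dict.  Identical config+seed produce identical
    artifacts byte for byte.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed,
                      "thresholds": {"min_sup": config.min_sup,
                                     "min_conf": config.min_conf,
                                     "min_lift": config.min_lift},
                      "stages": {}}

    def stage(name):
        def wrap(fn):
            try:
                result = fn()
            except Exception as exc:  # abort with stage name and cause
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                with open(out / "manifest.json", "w") as fh:
                    json.dump(manifest, fh, indent=2, sort_keys=True)
                raise StageError(name, exc) from exc
            return result
        return wrap

    # -- input ------------------------------------------------------------
    if config.input_csv:
        records = stage("load")(lambda: load_records(config.input_csv))
    else:
        def simulate():
            cc = CohortConfig(n_patients=config.n_patients, seed=config.seed)
            recs = generate_cohort(cc)
            write_records(recs, out / "cohort.csv")
            return recs
        records = stage("simulate")(simulate)
    manifest["stages"]["input"] = {"records": len(records)}
    log.info("input: %d diagnosis records", len(records))

    # -- preprocess --------------------------------------------------------
    def preprocess():
        kept = preprocessing.exclude_chapters(records)
        block_table = (preprocessing.load_block_table(config.block_table_csv)
                       if config.block_table_csv else preprocessing.DEFAULT_BLOCK_TABLE)
        overrides = (preprocessing.load_mapping_overrides(config.mapping_overrides_csv)
                     if config.mapping_overrides_csv else None)
        gmap = preprocessing.build_generalization_map(
            {r.icd10_code for r in kept}, block_table, overrides=overrides)
        db = preprocessing.build_transactions(kept, gmap)
        db = preprocessing.filter_patients(db, min_items=config.min_items)
        summary = preprocessing.summarize_cohort(kept, db)
        summary.to_csv(out / "cohort_summary.csv", index=False)
        return kept, gmap, db
    kept, gmap, db = stage("preprocess")(preprocess)
    manifest["stages"]["preprocess"] = {
        "records_after_exclusion": len(kept),
        "excluded_records": len(records) - len(kept),
        "patients_after_filter": db.n_patients,
        "distinct_items": len(db.items),
    }
    log.info("preprocess: %d records kept, %d patients, %d items",
             len(kept), db.n_patients, len(db.items))

    # -- mine --------------------------------------------------------------
    thresholds = mining.Thresholds(config.min_sup, config.min_conf, config.min_lift)
    rulebase = stage("mine")(lambda: mining.mine_rules(db, thresholds))
    mining.write_rules(rulebase, out / "rules.csv")
    manifest["stages"]["mine"] = {"rules": len(rulebase)}
    log.info("mine: %d rules", len(rulebase))

    # -- cross-validate ----------------------------------------------------
    def crossval():
        report = evaluation.cross_validate(
            db, k=config.k, C_grid=config.c_grid, seed=config.seed,
            miner=lambda train: mining.mine_rules(train, thresholds))
        report.to_csv(out / "cv_report.csv", index=False)
        return report
    report = stage("crossval")(crossval)
    manifest["stages"]["crossval"] = {"k": config.k, "c_values": len(report)}

    # -- verify ------------------------------------------------------------
    block_members: dict[str, list[str]] = {}
    for code, (level, label) in gmap.entries.items():
        if level == 2:
            block_members.setdefault(label, []).append(code)
    if config.cache_csv:
        cache_path = (verification.builtin_cache_path()
                      if config.cache_csv == "builtin" else config.cache_csv)

        def verify():
            cache = verification.load_cache(cache_path)
            literature = (verification.load_literature(config.literature_csv)
                          if config.literature_csv else None)
            recs = verification.verify_rules(rulebase.rules, cache, literature,
                                             block_members)
            verification.write_annotated_rules(recs, out / "rules_annotated.csv")
            agreement = verification.tabulate_agreement(recs)
            agreement.to_csv(out / "agreement.csv")
            return recs
        vrecords = stage("verify")(verify)
        manifest["stages"]["verify"] = {
            "rules": len(vrecords),
            "cohd_significant": sum(r.cohd_status == verification.SIGNIFICANT
                                    for r in vrecords),
            "unverified": sum(r.final_class == "unverified" for r in vrecords),
        }
        net_input: Sequence = vrecords
    else:
        net_input = rulebase.rules
        manifest["stages"]["verify"] = {"skipped": True}

    # -- network -----------------------------------------------------------
    def build():
        g = network.build_network(net_input)
        network.export_network(g, out / "disease_network")
        stats = network.node_statistics(g, anchor="F84")
        stats.to_csv(out / "node_statistics.csv", index=False)
        return g
    g = stage("network")(build)
    manifest["stages"]["network"] = {"nodes": g.number_of_nodes(),
                                     "edges": g.number_of_edges()}
    log.info("network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
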