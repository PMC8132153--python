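"""Top-level pipeline: simulate/load -> enrich -> screen -> select -> build -> evaluate.

The two-step study design (discovery then validation) is mirrored
directly: a candidate gene set is derived on the training cohort by
mutation-enrichment filtering, optionally intersected with CRISPR
screen hits (the C-classifier path) or an external driver-gene list
(the D-classifier path) — with neither restriction the full filtered
set is used (the W-classifier path) — reduced by the penalized cascade
and co-occurrence checks, fit by the greedy AUC forward build, and
evaluated on both cohorts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .evaluation import evaluate_cohort
from .feature_selection import SelectionConfig, run_cascade
from .model_build import GreedyConfig, cooccurrence_prune, greedy_forward_auc
from .mutation_enrichment import enrichment_filter, gene_stats
from .crispr_screen import gene_enrichment_all, hit_genes, select_hits
from .synthetic_data import CohortSpec, ScreenSpec, generate_cohort, generate_screen

log = logging.getLogger("nactrisk")

_COHORT_KEYS = {"simulate", "matrix", "labels", "clinical"}
_TOP_KEYS = {"seed", "training", "validation", "screen", "candidates_file",
             "enrichment", "selection", "build", "reduced"}


@dataclass
class PipelineConfig:
    """Declarative configuration of one end-to-end run.

    ``training`` / ``validation`` are either ``{"simulate": {...CohortSpec
    fields...}}`` or ``{"matrix": path, "labels": path, "clinical": path}``.
    ``screen`` likewise holds ``{"simulate": {...ScreenSpec fields...}}`` or
    ``{"counts": path}``; omitting it selects the W-classifier path.
    Unknown keys are rejected.
    """

    seed: int = 0
    training: dict = field(default_factory=dict)
    validation: dict | None = None
    screen: dict | None = None
    candidates_file: str | None = None
    enrichment: dict = field(default_factory=lambda: {"min_diff": 2, "p_max": 0.25})
    selection: dict = field(default_factory=dict)
    build: dict = field(default_factory=dict)
    reduced: bool = False

    def __post_init__(self) -> None:
        for name, block, allowed in (
            ("training", self.training, _COHORT_KEYS),
            ("validation", self.validation or {}, _COHORT_KEYS),
            ("screen", self.screen or {}, {"simulate", "counts"}),
        ):
            unknown = set(block) - allowed
            if unknown:
                raise ValueError(f"unknown keys in {name!r}: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _load_cohort(block: dict, seed: int, cohort: str):
    if "simulate" in block:
        spec = CohortSpec(**{**block["simulate"], "seed": seed})
        return generate_cohort(spec, cohort=cohort)
    matrix = nio.read_mutation_matrix(block["matrix"], block.get("labels"))
    clinical = nio.read_clinical(block["clinical"]) if block.get("clinical") else None
    return matrix, clinical


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every configured stage, writing artifacts under ``outdir``.

    Returns a summary dict (also written as ``report.json``); rerunning
    with the same config and seed reproduces all numeric outputs exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    seeds = {name: int(rng.integers(0, 2**31 - 1))
             for name in ("training", "validation", "screen", "selection", "build")}
    prov = nio.provenance_block(config.seed, config.to_dict())
    t0 = time.time()

    train, train_clin = _load_cohort(config.training, seeds["training"], "training")
    log.info("training cohort: %d samples x %d genes [%.1fs]",
             len(train.samples), len(train.genes), time.time() - t0)

    stats = gene_stats(train)
    nio.write_gene_stats(stats, outdir / "gene_stats.tsv")
    candidates = enrichment_filter(stats, **config.enrichment)
    log.info("enrichment filter: %d candidate genes", len(candidates))

    if config.screen is not None:
        if "simulate" in config.screen:
            screen = generate_screen(
                ScreenSpec(**{**config.screen["simulate"], "seed": seeds["screen"]}))
        else:
            screen = nio.read_screen_counts(config.screen["counts"])
        hits = select_hits(gene_enrichment_all(screen))
        hits.to_csv(outdir / "screen_hits.tsv", sep="\t", index=False)
        candidates = [g for g in candidates if g in set(hit_genes(hits))]
        log.info("screen hits restrict candidates to %d genes", len(candidates))
    if config.candidates_file is not None:
        allowed = set(nio.read_gene_list(config.candidates_file))
        candidates = [g for g in candidates if g in allowed]
        log.info("candidate list restricts candidates to %d genes", len(candidates))

    sel_cfg = SelectionConfig(**{**config.selection, "seed": seeds["selection"]})
    if config.reduced:
        sel_cfg = sel_cfg.reduced()
    cascade = run_cascade(train, None, sel_cfg, candidates=candidates)
    for res in cascade.stages:
        res.table.to_csv(outdir / f"stage_{res.stage}.tsv", sep="\t", index=False)
    log.info("cascade: %s -> %s genes", len(candidates),
             [len(r.retained_genes) for r in cascade.stages])

    lasso_scores = cascade.stages[-1].scores()
    pruned, drop_log = cooccurrence_prune(
        train, cascade.final_genes, lasso_scores,
        threshold=sel_cfg.spearman_threshold,
        rounds=config.build.get("cooccurrence_rounds", 2))
    drop_log.to_csv(outdir / "cooccurrence_drops.tsv", sep="\t", index=False)

    greedy = GreedyConfig(cv_folds=config.build.get("cv_folds", 10),
                          seed=seeds["build"])
    model = greedy_forward_auc(train, None, pruned, greedy,
                               lasso_ranks=cascade.lasso_ranks)
    model.provenance.update(prov)
    model.save(outdir / "model.json")
    log.info("model: %d genes, cutoff %.3f", len(model.genes), model.cutoff)

    summary = {"provenance": prov,
               "n_candidates": len(candidates),
               "stage_sizes": [len(r.retained_genes) for r in cascade.stages],
               "model_genes": model.genes,
               "cutoff": model.cutoff}
    report = evaluate_cohort(model, train, clinical=train_clin)
    report.to_json(outdir / "training_report.json")
    summary["training_auc"] = report.auc.auc
    summary["training_accuracy_pct"] = report.metrics.accuracy.pct
    if config.validation is not None:
        val, val_clin = _load_cohort(config.validation, seeds["validation"],
                                     "validation")
        vreport = evaluate_cohort(model, val, clinical=val_clin)
        vreport.to_json(outdir / "validation_report.json")
        summary["validation_auc"] = vreport.auc.auc
        summary["validation_accuracy_pct"] = vreport.metrics.accuracy.pct
        summary["validation_odds_ratio"] = vreport.odds_ratio.odds_ratio
    (outdir / "report.json").write_text(json.dumps(summary, indent=2, default=str))
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return summary
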