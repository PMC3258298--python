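"""End-to-end pipeline driver: screen → enrich → RE score → seed words →
network RD test → TF layer.

Each stage reads the typed tables of :mod:`coldmir.io`, writes its result
table into the output directory, and contributes to a JSON summary. Stages
whose optional inputs (UTRs, annotations) are absent are marked skipped.
A fixed seed makes the whole bundle reproducible byte-for-byte.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from . import __version__
from .regnet import build_network, classify_edges, rd_null_test, regulatory_density
from .response import bh_fdr, fisher_target_enrichment, re_score_test
from .screen import estimate_norm_factor, screen_differential
from .seedword import build_seed_index, default_cutoffs, top_words, word_enrichment_profile, word_presence
from .tflayer import (
    DEFAULT_TF_TERMS,
    mirna_tf_coherent_pairs,
    select_tfs,
    tf_expression_comparison,
    tf_underrepresentation_test,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("coldmir")


@dataclass
class PipelineConfig:
    """File paths, thresholds and run parameters of one pipeline run."""

    counts: str
    expression: str
    gene_status: str
    targets: str
    outdir: str
    utrs: str | None = None
    annotations: str | None = None
    fold_threshold: float = 2.0
    mean_threshold: float = 64.0
    fdr_threshold: float = 0.05
    n_null: int = 1000
    n_cutoffs: int = 20
    norm_method: str = "total"
    pseudocount: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fold_threshold", "mean_threshold", "fdr_threshold", "pseudocount"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_null < 1 or self.n_cutoffs < 1:
            raise ValueError("n_null and n_cutoffs must be positive")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _sample_conditions(expr: pd.DataFrame) -> dict[str, str]:
    return {c: ("NC" if c.startswith("NC") else "WC") for c in expr.columns}


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and return the JSON-serializable summary."""
    os.makedirs(cfg.outdir, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(name)s %(levelname)s: %(message)s")
    fh = logging.FileHandler(os.path.join(cfg.outdir, "pipeline.log"), mode="w")
    fh.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(fh)
    summary: dict = {"version": __version__, "seed": cfg.seed, "parameters": asdict(cfg), "stages": {}}
    head = cio.provenance_header(seed=cfg.seed, config=json.dumps(asdict(cfg), sort_keys=True))

    def _stage(name):
        log.info("stage %s", name)

    try:
        # --- differential miRNA screen -------------------------------------
        _stage("screen")
        counts = cio.read_counts(cfg.counts)
        f = estimate_norm_factor(counts, method=cfg.norm_method).factor_f
        screened = screen_differential(
            counts, f,
            fold_threshold=cfg.fold_threshold,
            mean_threshold=cfg.mean_threshold,
            pseudocount=cfg.pseudocount,
        )
        cio.write_counts(screened, os.path.join(cfg.outdir, "mirna_screen.tsv"), head)
        diff_mirnas = screened[screened["passes_screen"]]
        summary["stages"]["screen"] = {
            "norm_factor": f,
            "n_mirnas": int(len(counts)),
            "n_differential": int(len(diff_mirnas)),
            "n_up": int((diff_mirnas["direction"] == "up").sum()),
            "n_down": int((diff_mirnas["direction"] == "down").sum()),
        }

        # --- shared inputs --------------------------------------------------
        expr = cio.read_expression(cfg.expression)
        status = cio.read_gene_status(cfg.gene_status)
        target_map = cio.read_targets(cfg.targets)
        background = set(expr.index)
        gene_dir = dict(zip(status["gene_id"], status["direction"]))
        up_set = {g for g, d in gene_dir.items() if d == "up"} & background
        down_set = {g for g, d in gene_dir.items() if d == "down"} & background

        # --- per-miRNA target-set enrichment -------------------------------
        _stage("enrich")
        rows = []
        for mirna, tset in sorted(target_map.targets_by_mirna().items()):
            for set_name, dset in (("up", up_set), ("down", down_set)):
                if not dset:
                    continue
                res = fisher_target_enrichment(tset, dset, background)
                res.update(mirna_id=mirna, gene_set=set_name)
                rows.append(res)
        enrich = pd.DataFrame(rows)
        if len(enrich):
            enrich["q_value"] = bh_fdr(enrich["p_value"])
            enrich["significant"] = enrich["q_value"] < cfg.fdr_threshold
        cio.write_counts(enrich, os.path.join(cfg.outdir, "target_enrichment.tsv"), head)
        summary["stages"]["enrich"] = {
            "n_tests": int(len(enrich)),
            "n_significant": int(enrich["significant"].sum()) if len(enrich) else 0,
        }

        # --- regulatory-effect score test ----------------------------------
        _stage("rescore")
        re_table = re_score_test(expr, target_map, _sample_conditions(expr), cfg.fdr_threshold)
        cio.write_counts(re_table, os.path.join(cfg.outdir, "re_score.tsv"), head)
        summary["stages"]["rescore"] = {
            "n_mirnas": int(len(re_table)),
            "n_significant": int(re_table["significant"].sum()),
        }

        # --- seed-word landscape -------------------------------------------
        if cfg.utrs:
            _stage("sylamer")
            utrs = cio.read_fasta(cfg.utrs)
            delta = expr[[c for c in expr.columns if c.startswith("WC")]].mean(axis=1) - expr[
                [c for c in expr.columns if c.startswith("NC")]
            ].mean(axis=1)
            ranked = list(delta.sort_values(ascending=False).index)
            presence = word_presence(utrs, ranked)
            profile = word_enrichment_profile(presence, default_cutoffs(len(presence), cfg.n_cutoffs))
            seed_index = None
            if "sequence" in counts.columns:
                seqs = dict(zip(diff_mirnas["mirna_id"], diff_mirnas["sequence"]))
                if seqs:
                    seed_index = build_seed_index(seqs)
            tops = top_words(profile, k=10, seed_index=seed_index)
            cio.write_counts(profile, os.path.join(cfg.outdir, "word_profile.tsv"), head)
            cio.write_counts(tops, os.path.join(cfg.outdir, "top_words.tsv"), head)
            summary["stages"]["sylamer"] = {
                "n_genes": int(len(presence)),
                "n_words": int(profile["word"].nunique()),
                "top_word": tops["word"].iloc[0] if len(tops) else None,
                "top_peak_score": float(tops["peak_score"].iloc[0]) if len(tops) else None,
            }
        else:
            summary["stages"]["sylamer"] = {"skipped": True}

        # --- network RD test ------------------------------------------------
        _stage("network")
        mirna_dirs = dict(zip(diff_mirnas["mirna_id"], diff_mirnas["direction"]))
        diff_gene_dirs = {g: d for g, d in gene_dir.items() if d in ("up", "down") and g in background}
        tf_genes: set[str] | None = None
        if cfg.annotations:
            tf_genes = select_tfs(cio.read_annotations(cfg.annotations), DEFAULT_TF_TERMS)
        net = build_network(mirna_dirs, diff_gene_dirs, target_map.pairs, tf_genes)
        edges = pd.DataFrame(classify_edges(net))
        cio.write_counts(edges, os.path.join(cfg.outdir, "network_edges.tsv"), head)
        if net.n_edges >= 2:
            null = rd_null_test(net, n=cfg.n_null, seed=cfg.seed)
            rd_block = {
                "observed_rd": null.observed_rd,
                "empirical_p": null.empirical_p,
                "q95": null.q95,
                "q99": null.q99,
                "n_replicates": null.n_replicates,
                "significant": bool(null.significant),
            }
        elif net.n_edges == 1:
            rd_block = {"observed_rd": regulatory_density(net), "empirical_p": None}
        else:
            rd_block = {"observed_rd": None, "note": "network has no edges"}
        rd_block.update(net.nonisolated_counts())
        summary["stages"]["network"] = rd_block

        # --- TF layer ---------------------------------------------------------
        if cfg.annotations:
            _stage("tf_layer")
            diff_genes = up_set | down_set
            tf_test = tf_underrepresentation_test(diff_genes, tf_genes, background)
            tf_edges, tf_summary = mirna_tf_coherent_pairs(net)
            cio.write_counts(tf_edges, os.path.join(cfg.outdir, "tf_edges.tsv"), head)
            expr_cmp = tf_expression_comparison(expr.mean(axis=1), tf_genes)
            summary["stages"]["tf_layer"] = {
                "n_tfs": len(tf_genes),
                "n_diff_tfs": tf_test["n_overlap"],
                "fisher_p": tf_test["p_value"],
                "direction": tf_test["direction"],
                "pairs": tf_summary,
                "expression_comparison": expr_cmp,
            }
        else:
            summary["stages"]["tf_layer"] = {"skipped": True}
    except Exception as exc:  # annotate which stage failed, then re-raise
        done = list(summary["stages"])
        log.error("pipeline aborted after stages %s: %s", done, exc)
        raise RuntimeError(f"pipeline failed after stages {done}: {exc}") from exc
    finally:
        log.removeHandler(fh)
        fh.close()

    with open(os.path.join(cfg.outdir, "summary.json"), "w") as out:
        json.dump(summary, out, indent=2, sort_keys=True, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
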