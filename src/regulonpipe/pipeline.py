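"""End-to-end orchestration of the regulon pipeline on synthetic data.

``run_pipeline`` executes the full analysis in the order of the study
design: QC → meta-cells → co-expression GRN → regulon assembly → AUCell
activity → ANOVA → CSI modules → module activity contrast → regulon∩DE
signature → bulk-cohort consensus subtyping → subtype survival →
univariate-Cox screening → model grid → risk stratification. Every
stage writes a deterministic TSV/JSON artifact into the output
directory and logs its input/output dimensions; a stage failure aborts
the run naming the stage, keeping partial outputs.

The bulk cohorts are generated *after* the single-cell stages so their
planted prognostic signature lies inside the analysis-selected regulon,
mirroring a study where one regulon's condition-responsive targets
drive patient subtypes and survival.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
import time as _time
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import __version__
from .activity import group_specific_regulons, score_all
from .config import PipelineConfig
from .csi import compute_csi, cut_modules, module_activity
from .datatypes import ExpressionMatrix
from .grn import assemble_regulons, build_metacells, infer_coexpression
from .io import write_expression, write_gmt, write_regulons
from .prognosis import (
    build_input_geneset,
    cox_screen,
    fit_model_grid,
    stratify_and_evaluate,
)
from .qc import annotate_cells, filter_cells, lognormalize, normalize_and_select_hvg
from .subtyping import (
    build_signature,
    compare_subtypes,
    consensus_cluster,
    differential_expression,
    filter_de,
)
from .synthetic import SimConfig, make_gene_sets, make_prior, simulate_bulk_cohort, simulate_single_cell
from .enrichment import ssgsea_score

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "artifact_checksums"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = _time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as err:
                raise StageError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %s done in %.1fs", name, _time.perf_counter() - t0)
            return out
        return inner
    return wrap


def artifact_checksums(outdir: str | Path) -> Dict[str, str]:
    """SHA-256 of every artifact file, keyed by relative path."""
    outdir = Path(outdir)
    sums = {}
    for f in sorted(outdir.rglob("*")):
        if f.is_file():
            sums[str(f.relative_to(outdir))] = hashlib.sha256(f.read_bytes()).hexdigest()
    return sums


def run_pipeline(
    config: PipelineConfig,
    sim: Optional[SimConfig] = None,
) -> dict:
    """Run every stage on freshly simulated data; return a report dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": []}

    sim = sim or SimConfig(seed=config.sim_seed_sc)

    # --- simulate single-cell -----------------------------------------
    @_stage("simulate")
    def s_sim():
        m, truth = simulate_single_cell(sim)
        logger.info("simulated %d genes x %d cells", m.n_genes, m.n_cells)
        return m, truth

    matrix, truth = s_sim()
    report["stages"].append("simulate")

    # --- QC ------------------------------------------------------------
    @_stage("qc")
    def s_qc():
        filtered, qc_table = filter_cells(
            matrix, config.min_genes, config.max_genes, config.max_ribo_frac
        )
        qc_table.to_csv(out / "qc_cells.tsv", sep="\t")
        hvg = normalize_and_select_hvg(filtered, config.n_hvg)
        norm_full = lognormalize(filtered)
        labels = annotate_cells(norm_full)
        norm_full.cell_meta["cell_type_called"] = labels
        hvg.cell_meta["cell_type_called"] = labels
        props = (
            labels.groupby(norm_full.cell_meta["condition"])
            .value_counts(normalize=True)
            .rename("proportion")
        )
        props.to_csv(out / "cell_type_proportions.tsv", sep="\t")
        write_expression(filtered, out / "filtered_counts", format="mtx")
        return filtered, hvg, norm_full

    filtered, hvg, norm_full = s_qc()
    report["stages"].append("qc")

    # --- meta-cells + GRN ----------------------------------------------
    @_stage("metacells")
    def s_meta():
        n_mc = max(20, hvg.n_cells // config.cells_per_metacell)
        # cluster in HVG space, aggregate raw counts (pseudo-bulk profiles)
        mc = build_metacells(
            filtered, n_metacells=n_mc, n_pcs=config.n_pcs, seed=config.seed,
            cluster_on=hvg,
        )
        mc.membership.rename("metacell").to_csv(out / "metacell_membership.tsv", sep="\t")
        return mc

    mc = s_meta()
    report["stages"].append("metacells")

    tfs = [tf for tf in truth.regulons if tf in mc.values.index]

    @_stage("grn")
    def s_grn():
        edges = infer_coexpression(
            mc, tfs, method=config.grn_method,
            n_estimators=config.grn_n_estimators, seed=config.seed,
        )
        edges.to_csv(out / "edges.tsv", sep="\t", index=False)
        prior = make_prior(truth, seed=config.seed)
        regulons = assemble_regulons(edges, prior, config.min_regulon_size)
        write_regulons(regulons, out / "regulons.json")
        if not regulons:
            raise ValueError("no regulon survived assembly")
        return edges, regulons

    edges, regulons = s_grn()
    report["stages"].append("grn")

    # --- activity + ANOVA ----------------------------------------------
    @_stage("activity")
    def s_act():
        act = score_all(norm_full, regulons, top_frac=config.aucell_top_frac)
        act.values.to_csv(out / "ras.tsv", sep="\t")
        anova = group_specific_regulons(act, act.cell_meta["cell_type_called"])
        anova.to_csv(out / "anova_cell_type.tsv", sep="\t", index=False)
        return act

    act = s_act()
    report["stages"].append("activity")

    # --- CSI modules -----------------------------------------------------
    @_stage("modules")
    def s_csi():
        csi = compute_csi(act, delta=config.csi_delta)
        csi.values.to_csv(out / "csi.tsv", sep="\t")
        modules = cut_modules(csi, height=config.csi_cut_height)
        modules.labels.to_csv(out / "modules.tsv", sep="\t")
        mod_act, summary = module_activity(act, modules)
        summary.to_csv(out / "module_activity_summary.tsv", sep="\t")
        return modules, summary

    modules, mod_summary = s_csi()
    report["stages"].append("modules")
    report["n_modules"] = len(modules.modules)
    top_module = mod_summary["diff_WT_minus_MUT"].abs().idxmax()
    report["top_module"] = str(top_module)

    # --- signature -------------------------------------------------------
    @_stage("signature")
    def s_sig():
        de = differential_expression(
            norm_full.values, norm_full.cell_meta["condition"], "WT", "MUT"
        )
        de.to_csv(out / "de_condition.tsv", sep="\t", index=False)
        de_hits = filter_de(de, adj_p=config.de_adj_p, logfc=config.de_logfc)
        members = modules.labels.index[modules.labels == top_module]
        member_regs = [r for r in regulons if r.tf in set(members)]
        cond = act.cell_meta["condition"]
        diffs = {
            r.tf: abs(
                act.values.loc[r.tf, cond == "WT"].mean()
                - act.values.loc[r.tf, cond == "MUT"].mean()
            )
            for r in member_regs
        }
        top_tf = max(diffs, key=diffs.get)
        top_reg = next(r for r in member_regs if r.tf == top_tf)
        sig = build_signature(top_reg, de_hits)
        (out / "signature.txt").write_text("\n".join(sig) + "\n")
        return de_hits, top_reg, sig

    de_hits, top_regulon, signature = s_sig()
    report["stages"].append("signature")
    report["top_regulon"] = top_regulon.tf
    report["signature_size"] = len(signature)

    # --- bulk cohorts ---------------------------------------------------
    @_stage("cohorts")
    def s_cohorts():
        pool = list(top_regulon.targets)
        cohorts = {}
        for i, name in enumerate(["train", "test1", "test2"]):
            cohort, bulk_truth = simulate_bulk_cohort(
                sim, truth=truth, seed=config.sim_seed_bulk + i, name=name,
                signature_pool=pool,
            )
            cohorts[name] = (cohort, bulk_truth)
        sets = make_gene_sets(
            cohorts["train"][1], n_sets=13, set_size=50, overlap=0.5,
            seed=config.sim_seed_bulk,
        )
        write_gmt(sets, out / "gene_sets.gmt")
        return cohorts, sets

    cohorts, gene_sets = s_cohorts()
    report["stages"].append("cohorts")
    train, train_truth = cohorts["train"]
    tests = [cohorts["test1"][0], cohorts["test2"][0]]

    # --- subtyping -------------------------------------------------------
    @_stage("subtype")
    def s_subtype():
        feats = [g for g in signature if g in train.genes]
        cons = consensus_cluster(
            train.expression[feats],
            k_range=config.consensus_k_range,
            n_resamples=config.consensus_resamples,
            sample_frac=config.consensus_sample_frac,
            seed=config.seed,
        )
        cons.labels.to_csv(out / "subtype_labels.tsv", sep="\t")
        cons.consensus[cons.selected_k].to_csv(out / "consensus_matrix.tsv", sep="\t")
        scores = ssgsea_score(train.expression.T, gene_sets)
        cmp = compare_subtypes(train, cons.labels, scores)
        cmp["set_comparison"].to_csv(out / "subtype_set_scores.tsv", sep="\t", index=False)
        (out / "subtype_survival.json").write_text(
            json.dumps(
                {
                    "selected_k": cons.selected_k,
                    "logrank_stat": cmp["logrank_stat"],
                    "logrank_p": cmp["logrank_p"],
                },
                indent=1, sort_keys=True,
            )
        )
        return cons, cmp

    cons, subtype_cmp = s_subtype()
    report["stages"].append("subtype")
    report["selected_k"] = cons.selected_k
    report["subtype_logrank_p"] = subtype_cmp["logrank_p"]

    # --- prognosis -------------------------------------------------------
    @_stage("prognosis")
    def s_prog():
        cox = cox_screen(train, p_thresh=config.cox_p)
        cox.to_csv(out / "cox_screen.tsv", sep="\t", index=False)
        de_sub = differential_expression(train.expression.T, cons.labels)
        sub_hits = filter_de(de_sub, adj_p=config.de_adj_p, logfc=0.5)
        geneset = build_input_geneset(cox["gene"], sub_hits["gene"], signature)
        (out / "model_geneset.txt").write_text("\n".join(geneset) + "\n")
        leaderboard, best, _ = fit_model_grid(train, tests, geneset, seed=config.seed)
        leaderboard.to_csv(out / "model_leaderboard.tsv", sep="\t", index=False)
        reports = {}
        for cohort in [train, *tests]:
            rep = stratify_and_evaluate(best, cohort)
            rep["scores"].to_csv(out / f"risk_scores_{cohort.name}.tsv", sep="\t")
            reports[cohort.name] = {
                "logrank_p": rep.get("logrank_p"),
                "roc_auc": rep["roc_auc"],
            }
        (out / "risk_evaluation.json").write_text(
            json.dumps(reports, indent=1, sort_keys=True, default=float)
        )
        return leaderboard, best, reports

    leaderboard, best_model, risk_reports = s_prog()
    report["stages"].append("prognosis")
    report["best_model"] = best_model.algorithm
    report["best_cindex_train"] = best_model.cindex_train
    report["best_cindex_test"] = best_model.cindex_test

    # --- manifest --------------------------------------------------------
    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config_hash": config.config_hash(),
        "config": config.params(),
        "sim": sim.to_dict(),
        "report": {
            k: v for k, v in report.items() if k not in ("stages",)
        },
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    report["outdir"] = str(out)
    return report
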