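"""End-to-end orchestration of the synthetic-truth pipeline.

``run_all`` generates a seeded synthetic study, runs differential
methylation and expression, classifies quadrants, screens the TF array,
intersects the knockdown panels and quantifies the validation assays,
writing every artifact plus a manifest and planted-truth recovery
metrics to an output directory.  Each stage writes only its own
outputs; inputs are never mutated.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__, differential, enrich, integrate, io, simulate, \
    tf_screen, validate

log = logging.getLogger("mepact")

__all__ = ["run_all", "recovery_metrics", "write_manifest"]


def recovery_metrics(records: pd.DataFrame, truth: pd.DataFrame,
                     quadrant: str = "hyper_up") -> dict:
    """Sensitivity and false-discovery proportion for a planted quadrant."""
    called = set(records.index[records["quadrant"] == quadrant])
    planted = set(truth.index[truth["planted_quadrant"] == quadrant])
    tp = len(called & planted)
    sens = tp / len(planted) if planted else float("nan")
    fdp = (len(called) - tp) / len(called) if called else 0.0
    return {"quadrant": quadrant, "n_planted": len(planted),
            "n_called": len(called), "sensitivity": sens, "fdp": fdp}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_manifest(outdir: Path, cfg: dict, inputs: list[Path]) -> None:
    io.write_json({
        "package": "mepact",
        "version": __version__,
        "parameters": cfg,
        "inputs": {str(p): _sha256(p) for p in sorted(inputs) if p.exists()},
    }, outdir / "manifest.json")


def run_all(cfg: dict, outdir) -> dict:
    """Run every stage on synthetic data; returns the summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # --- simulate -----------------------------------------------------
    sim_cfg = simulate.SimConfig(seed=seed, **cfg["simulate"])
    beta, expr, annot, truth = simulate.gen_methylome_transcriptome(sim_cfg)
    io.write_beta(beta, outdir / "sim")
    io.write_expression(expr, outdir / "sim")
    io.write_annotation(annot, outdir / "sim.tss.tsv")
    io.write_promoter_bed(annot, outdir / "sim.promoters.bed")
    truth.to_csv(outdir / "sim.truth.tsv", sep="\t")
    log.info("simulated %d genes x %d samples", sim_cfg.n_genes,
             2 * sim_cfg.n_per_group)

    # --- differential -------------------------------------------------
    meth, dropped = differential.diff_methylation(
        beta, annot, p_adj_cut=cfg["methylation"]["p_adj"],
        min_abs_delta=cfg["methylation"]["min_abs_delta_beta"])
    expr_table = differential.diff_expression(
        expr, p_adj_cut=cfg["expression"]["p_adj"],
        min_abs_lfc=cfg["expression"]["min_abs_log2fc"])
    io.write_matrix(meth, outdir / "diff_methylation.tsv")
    io.write_matrix(expr_table, outdir / "diff_expression.tsv")
    if dropped:
        (outdir / "diff_methylation.dropped.txt").write_text(
            "\n".join(dropped) + "\n")

    # --- integration --------------------------------------------------
    records = integrate.classify_quadrants(meth, expr_table)
    counts = integrate.quadrant_counts(records)
    io.write_matrix(records, outdir / "integration.tsv", "gene_id")
    records[["delta_beta", "log2fc"]].to_csv(
        outdir / "integration.scatter.tsv", sep="\t")
    metrics = recovery_metrics(records, truth)
    log.info("quadrant counts: %s", counts)

    # --- TF screen ----------------------------------------------------
    scan, binders = simulate.gen_tf_array(
        n_tf=100, n_neg=16, n_methyl_binders=5, seed=seed + 1)
    scan.to_csv(outdir / "tf_scan.tsv", sep="\t", index=False)
    result = tf_screen.screen(
        scan, ratio_cutoff=cfg["tf_screen"]["ratio_cutoff"],
        expression_floor=cfg["tf_screen"]["expression_floor"],
        top_k=cfg["tf_screen"]["top_k"])
    io.write_matrix(result, outdir / "tf_screen.tsv", "tf_id")
    top = result[result["class"] == "methyl_preferring"].nsmallest(
        len(binders), "rank")
    tf_recovered = len(set(top.index) & set(binders)) / len(binders)

    # --- knockdown panels + intersection ------------------------------
    panels, kd_truth = simulate.gen_knockdown_panel(
        seed=seed + 2, **cfg["knockdown"])
    panel_tables = [differential.diff_expression(p) for p in panels]
    consistent = integrate.knockdown_intersection(panel_tables)
    targets = integrate.candidate_direct_targets(consistent, meth)
    (outdir / "knockdown_consistent_down.txt").write_text(
        "\n".join(sorted(consistent)) + "\n")
    planted_kd = set(kd_truth.index[kd_truth["planted_kd_down"]])

    # --- GSEA on the first knockdown panel ----------------------------
    ranked = panel_tables[0]["t_mod"]
    collection = {"planted_down": planted_kd}
    gsea_res = enrich.gsea(ranked.mul(-1), collection,
                           weight=cfg["gsea"]["weight"],
                           n_perm=cfg["gsea"]["n_perm"], seed=seed + 3)
    io.write_matrix(gsea_res, outdir / "gsea.tsv", "set_id")

    # --- validation assays --------------------------------------------
    clones, conv, ct, chip, luc = simulate.gen_validation_data({}, seed=seed + 4)
    per_cpg, overall = validate.clone_methylation_summary(clones)
    folds = validate.ddct(ct, housekeeping="HPRT1",
                          reference_condition="control",
                          replicate_combine=cfg["validation"]["replicate_combine"])
    chip_pct = validate.percent_input(chip)
    luc_rel = validate.luciferase_relative(luc)

    summary = {
        "quadrant_counts": counts,
        "hyper_up_recovery": metrics,
        "tf_screen": {"planted_binders": sorted(binders),
                      "recovered_fraction": tf_recovered},
        "knockdown": {"n_consistent_down": len(consistent),
                      "n_planted": len(planted_kd),
                      "recovered": sorted(consistent & planted_kd),
                      "candidate_direct_targets": sorted(targets)},
        "gsea": json.loads(gsea_res.to_json(orient="index")),
        "validation": {
            "clone_overall_pct": overall,
            "clone_per_cpg_pct": per_cpg.tolist(),
            "ddct_folds": {f"{g}|{c}": v for (g, c), v in folds.items()},
            "percent_input": {f"{r}|{a}": v for (r, a), v in chip_pct.items()},
            "luciferase_relative": luc_rel.to_dict(),
        },
    }
    io.write_json(summary, outdir / "summary.json")
    write_manifest(outdir, cfg, list(outdir.glob("sim.*")))
    return summary
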