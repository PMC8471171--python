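"""Synthetic data with planted ground truth for every pipeline stage.

The generators emulate the structure of the study data — two-group CpG
beta matrices with promoter-level methylation shifts, two-group log2
expression with planted fold changes and a planted hypermethylated/
up-regulated gene set, TF-microarray scans with planted
methyl-preferring binders, knockdown/control expression panels from
several cell lines with a planted consistently-down set, and the
validation-assay tables (bisulfite clones, qPCR Ct, ChIP Ct,
luciferase readings) — so the whole pipeline is testable offline
against known truth.

All randomness flows through an explicit seed; identical configuration
yields bit-identical outputs.  Beta noise is applied on the logit scale
and back-transformed (clamped to [1e-4, 1-1e-4]) so values stay in the
open interval with array-like mean-dependent variance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import (BetaMatrix, ExpressionMatrix, GeneAnnotation,
                           promoter_windows)

__all__ = [
    "SimConfig", "gen_methylome_transcriptome", "gen_tf_array",
    "gen_knockdown_panel", "gen_validation_data", "clone_matrix_from_counts",
]

BETA_CLAMP = 1e-4


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimConfig:
    """Study-condition parameters for the methylome/transcriptome generator.

    Defaults mirror the planted-signal conditions the pipeline is
    benchmarked under: promoter delta-beta 0.3, log2FC 1.5, 20 samples
    per group, moderate noise, 10% of genes in the hypermethylated/
    up-regulated quadrant and 5% in each other quadrant (remainder
    null).
    """

    n_genes: int = 200
    n_cpg_per_promoter: int = 8
    n_per_group: int = 20
    delta_beta_effect: float = 0.3
    log2fc_effect: float = 1.5
    beta_noise_sd: float = 0.5   # logit scale
    expr_noise_sd: float = 0.5   # log2 scale
    quadrant_proportions: dict = field(default_factory=lambda: {
        "hyper_up": 0.10, "hyper_down": 0.05,
        "hypo_up": 0.05, "hypo_down": 0.05})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cpg_per_promoter", "n_per_group"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.beta_noise_sd < 0 or self.expr_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if sum(self.quadrant_proportions.values()) > 1 + 1e-12:
            raise ValueError("quadrant proportions must sum to <= 1")
        unknown = set(self.quadrant_proportions) - {
            "hyper_up", "hyper_down", "hypo_up", "hypo_down"}
        if unknown:
            raise ValueError(f"unknown quadrants: {sorted(unknown)}")


def _assign_quadrants(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    counts = {q: int(round(f * cfg.n_genes))
              for q, f in cfg.quadrant_proportions.items()}
    labels = []
    for q in ("hyper_up", "hyper_down", "hypo_up", "hypo_down"):
        labels += [q] * counts.get(q, 0)
    labels += ["null"] * (cfg.n_genes - len(labels))
    labels = np.array(labels, dtype=object)
    rng.shuffle(labels)
    return labels


_SIGNS = {"hyper_up": (1, 1), "hyper_down": (1, -1),
          "hypo_up": (-1, 1), "hypo_down": (-1, -1), "null": (0, 0)}


def gen_methylome_transcriptome(config: SimConfig):
    """Two-group beta and expression matrices with planted quadrant truth.

    Returns ``(BetaMatrix, ExpressionMatrix, GeneAnnotation, truth)``.
    Each gene gets one TSS on an alternating strand and
    ``n_cpg_per_promoter`` probes evenly spaced inside its -1500/+500
    promoter window; per CpG and sample, beta = logistic(logit(group
    promoter mean) + probe offset + noise).  Case promoter means are
    shifted by the planted delta-beta, case expression by the planted
    log2FC.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    quadrant = _assign_quadrants(cfg, rng)
    gene_ids = [f"g{i:04d}" for i in range(cfg.n_genes)]
    strands = np.where(np.arange(cfg.n_genes) % 2 == 0, "+", "-")
    tss = 10_000 + 5_000 * np.arange(cfg.n_genes)
    annot = GeneAnnotation(pd.DataFrame({
        "gene_id": gene_ids, "chrom": "chr1", "strand": strands, "tss": tss}))

    signs = np.array([_SIGNS[q] for q in quadrant], dtype=float)
    delta_beta = signs[:, 0] * cfg.delta_beta_effect
    log2fc = signs[:, 1] * cfg.log2fc_effect

    n = cfg.n_per_group
    samples = [f"ctrl{i:02d}" for i in range(n)] + [f"case{i:02d}" for i in range(n)]
    groups = pd.Series(["control"] * n + ["case"] * n, index=samples)

    # promoter baseline methylation; case mean shifted by delta-beta
    base = rng.uniform(0.2, 0.5, size=cfg.n_genes)
    mean_ctrl = np.clip(base, 0.05, 0.95)
    mean_case = np.clip(base + delta_beta, 0.05, 0.95)

    windows = promoter_windows(annot)
    probe_rows, values = [], []
    for gi, gid in enumerate(gene_ids):
        w = windows.loc[gid]
        pos = np.linspace(w["start"], w["end"] - 1, cfg.n_cpg_per_promoter,
                          dtype=int)
        probe_offset = rng.normal(0.0, 0.3, size=cfg.n_cpg_per_promoter)
        for pj in range(cfg.n_cpg_per_promoter):
            probe_rows.append((f"{gid}_cg{pj:02d}", "chr1", int(pos[pj])))
            mu = np.concatenate([
                np.full(n, _logit(mean_ctrl[gi])),
                np.full(n, _logit(mean_case[gi]))]) + probe_offset[pj]
            noise = rng.normal(0.0, cfg.beta_noise_sd, size=2 * n)
            values.append(np.clip(_expit(mu + noise), BETA_CLAMP, 1 - BETA_CLAMP))
    probes = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos"]) \
        .set_index("probe_id")
    beta = BetaMatrix(values=pd.DataFrame(values, index=probes.index,
                                          columns=samples),
                      probes=probes, groups=groups)

    base_expr = rng.normal(8.0, 1.5, size=cfg.n_genes)
    mu = np.tile(base_expr[:, None], (1, 2 * n))
    mu[:, n:] += log2fc[:, None]
    expr_vals = mu + rng.normal(0.0, cfg.expr_noise_sd, size=mu.shape)
    expr = ExpressionMatrix(
        values=pd.DataFrame(expr_vals, index=gene_ids, columns=samples),
        groups=groups)

    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "planted_delta_beta": delta_beta,
        "planted_log2fc": log2fc,
        "planted_quadrant": quadrant,
        "planted_kd_down": False,
    }).set_index("gene_id")
    return beta, expr, annot, truth


def gen_tf_array(n_tf: int, n_neg: int, n_methyl_binders: int,
                 preference_fold: float = 8.0, noise_cv: float = 0.1,
                 seed: int = 0, n_replicates: int = 2,
                 background_mfi: float = 100.0, binder_mfi: float = 800.0,
                 tag_mfi: float = 3000.0):
    """TF-microarray scan with planted methyl-preferring binders.

    Returns ``(scan, binders)`` where ``scan`` is a spot table (columns
    spot_id, tf_id, construct, replicate, mfi_meth, mfi_unmeth, tag_n,
    tag_c) and ``binders`` the planted methyl-preferring tf_ids.
    Planted binders bind the unmethylated fragment at ``binder_mfi`` and
    the methylated fragment ``preference_fold`` times stronger; all
    other factors sit at background on both DNA channels.  Noise is
    multiplicative with coefficient of variation ``noise_cv``.
    """
    if n_methyl_binders > n_tf:
        raise ValueError("more planted binders than TFs")
    if preference_fold < 1:
        raise ValueError("preference_fold must be >= 1")
    if n_neg < 2:
        raise ValueError("need >= 2 negative-control spots (SD undefined)")
    rng = np.random.default_rng(seed)
    tf_ids = [f"TF{i:03d}" for i in range(n_tf)]
    binders = sorted(rng.choice(tf_ids, size=n_methyl_binders, replace=False))

    def noisy(level, size):
        return np.clip(level * (1.0 + noise_cv * rng.standard_normal(size)),
                       0.0, None)

    rows = []
    spot = 0
    for rep in range(n_replicates):
        for tf in tf_ids:
            meth = binder_mfi * preference_fold if tf in binders else background_mfi
            unmeth = binder_mfi if tf in binders else background_mfi
            rows.append((f"s{spot:05d}", tf, "dbd", rep,
                         float(noisy(meth, 1)[0]), float(noisy(unmeth, 1)[0]),
                         float(noisy(tag_mfi, 1)[0]), float(noisy(tag_mfi, 1)[0])))
            spot += 1
        for j in range(n_neg):
            rows.append((f"s{spot:05d}", f"NEG{j:03d}", "negative_control", rep,
                         float(noisy(background_mfi, 1)[0]),
                         float(noisy(background_mfi, 1)[0]),
                         float(noisy(background_mfi, 1)[0]),
                         float(noisy(background_mfi, 1)[0])))
            spot += 1
    scan = pd.DataFrame(rows, columns=["spot_id", "tf_id", "construct",
                                       "replicate", "mfi_meth", "mfi_unmeth",
                                       "tag_n", "tag_c"])
    return scan, list(binders)


def gen_knockdown_panel(n_cell_lines: int = 3, n_genes: int = 200,
                        n_down_consistent: int = 10, per_line_extra_down: int = 5,
                        log2fc_effect: float = 1.5, seed: int = 0,
                        n_per_group: int = 5, noise_sd: float = 0.3,
                        consistent_genes=None):
    """Knockdown/control expression panels with a planted consistent set.

    Returns ``(panels, truth)``: one ExpressionMatrix per cell line
    (knockdown samples are the "case" group) in which the consistent set
    is down-shifted by ``log2fc_effect`` in every line and each line
    additionally has its own disjoint extra down set.  The consistent
    set is drawn at random unless ``consistent_genes`` pins specific
    gene ids (they override ``n_down_consistent``).
    """
    if n_down_consistent > n_genes:
        raise ValueError("consistent set larger than the gene universe")
    rng = np.random.default_rng(seed)
    gene_ids = [f"g{i:04d}" for i in range(n_genes)]
    if consistent_genes is not None:
        consistent = set(consistent_genes)
        if not consistent <= set(gene_ids):
            raise ValueError("consistent_genes outside the gene universe")
        remaining = [g for g in gene_ids if g not in consistent]
        pool = list(rng.permutation(remaining))
    else:
        perm = list(rng.permutation(n_genes))
        consistent = set(np.array(gene_ids)[perm[:n_down_consistent]])
        pool = [gene_ids[i] for i in perm[n_down_consistent:]]
    extras = []
    for _ in range(n_cell_lines):
        if len(pool) < per_line_extra_down:
            raise ValueError("not enough genes for disjoint per-line extra sets")
        extras.append(set(pool[:per_line_extra_down]))
        pool = pool[per_line_extra_down:]

    n = n_per_group
    panels = []
    for line in range(n_cell_lines):
        samples = [f"L{line}_ctrl{i}" for i in range(n)] + \
            [f"L{line}_kd{i}" for i in range(n)]
        groups = pd.Series(["control"] * n + ["case"] * n, index=samples)
        base = rng.normal(8.0, 1.5, size=n_genes)
        mu = np.tile(base[:, None], (1, 2 * n))
        down = np.array([g in consistent or g in extras[line] for g in gene_ids])
        mu[down, n:] -= abs(log2fc_effect)
        vals = mu + rng.normal(0.0, noise_sd, size=mu.shape)
        panels.append(ExpressionMatrix(
            values=pd.DataFrame(vals, index=gene_ids, columns=samples),
            groups=groups))
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "planted_kd_down": [g in consistent for g in gene_ids],
    }).set_index("gene_id")
    return panels, truth


def clone_matrix_from_counts(per_site_methylated: list[int],
                             n_clones: int) -> pd.DataFrame:
    """Deterministic clone x CpG call matrix with exact per-site counts.

    Site j carries ``per_site_methylated[j]`` methylated calls among
    ``n_clones`` clones (methylated calls fill the top rows).  Useful
    for reconstructing published lollipop diagrams whose per-site counts
    are known.
    """
    cols = {}
    for j, k in enumerate(per_site_methylated):
        if not 0 <= k <= n_clones:
            raise ValueError("per-site count outside [0, n_clones]")
        cols[f"cpg{j + 1}"] = [1] * k + [0] * (n_clones - k)
    return pd.DataFrame(cols, index=[f"clone{i + 1}" for i in range(n_clones)])


def gen_validation_data(spec: dict, seed: int = 0):
    """Validation-assay inputs encoding known truth.

    ``spec`` keys (all optional, sensible defaults):

    * ``cpg_fractions``: per-CpG true methylation fractions
    * ``n_clones`` (default 10), ``conversion_prob`` (default 0.995),
      ``n_non_cpg`` (default 20)
    * ``fold_changes``: gene -> true expression fold (case over control)
    * ``chip_percent``: (region, antibody) -> true percent-input fraction
      in (0, 1]
    * ``activities``: (construct, condition) -> true promoter activity
    * ``ct_noise_sd`` (default 0.0), ``n_ct_replicates`` (default 3)

    Returns ``(clone_calls, conversion, ct_table, chip_table, luc_table)``.
    """
    rng = np.random.default_rng(seed)
    fractions = np.asarray(spec.get("cpg_fractions", [0.6, 0.6, 0.6, 0.5, 0.6]),
                           dtype=float)
    if ((fractions < 0) | (fractions > 1)).any():
        raise ValueError("cpg_fractions must lie in [0, 1]")
    n_clones = int(spec.get("n_clones", 10))
    clone_calls = pd.DataFrame(
        rng.binomial(1, fractions, size=(n_clones, len(fractions))),
        index=[f"clone{i + 1}" for i in range(n_clones)],
        columns=[f"cpg{j + 1}" for j in range(len(fractions))])
    n_non_cpg = int(spec.get("n_non_cpg", 20))
    conversion = pd.DataFrame({
        "converted": rng.binomial(n_non_cpg, float(spec.get("conversion_prob", 0.995)),
                                  size=n_clones),
        "total": n_non_cpg,
    }, index=clone_calls.index)

    ct_noise = float(spec.get("ct_noise_sd", 0.0))
    n_rep = int(spec.get("n_ct_replicates", 3))
    hk_ct, base_ct = 20.0, 25.0
    rows = []
    for gene, fold in dict(spec.get("fold_changes", {"target": 2.0})).items():
        for cond, abundance in (("control", 1.0), ("case", float(fold))):
            for r in range(n_rep):
                rows.append((f"{cond}_s1", cond, gene,
                             base_ct - np.log2(abundance) + rng.normal(0, ct_noise)))
    for cond in ("control", "case"):
        for r in range(n_rep):
            rows.append((f"{cond}_s1", cond, "HPRT1",
                         hk_ct + rng.normal(0, ct_noise)))
    ct_table = pd.DataFrame(rows, columns=["sample", "condition", "gene", "ct"])

    chip_spec = dict(spec.get("chip_percent", {
        ("promoter", "specific"): 0.30, ("promoter", "igg"): 0.01,
        ("upstream_5kb_control", "specific"): 0.01,
        ("upstream_5kb_control", "igg"): 0.01}))
    input_fraction = float(spec.get("input_fraction", 0.01))
    chip_rows = []
    ct_input = 25.0
    adj = ct_input - np.log2(1.0 / input_fraction)
    for (region, antibody), frac in chip_spec.items():
        if not 0 < frac <= 1:
            raise ValueError("chip percent-input fractions must lie in (0, 1]")
        for r in range(n_rep):
            chip_rows.append((region, antibody,
                              adj - np.log2(frac) + rng.normal(0, ct_noise),
                              ct_input + rng.normal(0, ct_noise), input_fraction))
    chip_table = pd.DataFrame(chip_rows, columns=[
        "target_region", "antibody", "ct_ip", "ct_input", "input_fraction"])

    activities = dict(spec.get("activities", {
        ("promoter", "control"): 5.0, ("promoter", "kd"): 2.5,
        ("empty_control", "control"): 1.0, ("empty_control", "kd"): 1.0}))
    luc_noise = float(spec.get("luc_noise_cv", 0.0))
    luc_rows = []
    for (construct, cond), act in activities.items():
        for r in range(n_rep):
            renilla = 1000.0 * (1.0 + luc_noise * rng.standard_normal())
            firefly = act * renilla * (1.0 + luc_noise * rng.standard_normal())
            luc_rows.append((construct, cond, firefly, renilla))
    luc_table = pd.DataFrame(luc_rows, columns=["construct", "condition",
                                                "firefly", "renilla"])
    return clone_calls, conversion, ct_table, chip_table, luc_table
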