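"""Gene-set analysis: Fisher overrepresentation and GSEA.

``fisher_overrep`` tests a study set against a gene-set collection with
one-sided Fisher's exact tests (overrepresentation), BH-adjusted.

``gsea`` is a weighted Kolmogorov-Smirnov running-sum enrichment
analysis: genes are ranked by a score (here typically the moderated t
from a knockdown-vs-control comparison), the running sum increments by
|score|^weight (normalised) at set members and decrements by 1/(N - Nh)
elsewhere, and the enrichment score ES is the extremum.  The null is a
gene-label permutation; NES normalises ES by the mean same-sign null
magnitude.  Significance follows the study rule NES > 1, p <= 0.05 and
FDR q <= 0.25.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .differential import bh_adjust

__all__ = ["fisher_overrep", "gsea", "running_sum_es",
           "GSEA_MIN_NES", "GSEA_MAX_P", "GSEA_MAX_Q"]

GSEA_MIN_NES = 1.0
GSEA_MAX_P = 0.05
GSEA_MAX_Q = 0.25


def fisher_overrep(study: set, universe: set,
                   collection: dict[str, set],
                   p_adj_cut: float = 0.05) -> pd.DataFrame:
    """One-sided Fisher overrepresentation of ``study`` in each set.

    For each set S the 2x2 table (study&S, study-S, S-study, neither)
    over the universe is tested with alternative='greater'.  Returns a
    DataFrame with columns n_overlap, n_study, n_set, odds_ratio, p,
    p_adj, significant.
    """
    study, universe = set(study), set(universe)
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    rows = []
    for set_id, members in collection.items():
        members = set(members) & universe
        a = len(study & members)
        b = len(study - members)
        c = len(members - study)
        d = len(universe) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append((set_id, a, len(study), len(members), odds, p))
    out = pd.DataFrame(rows, columns=["set_id", "n_overlap", "n_study",
                                      "n_set", "odds_ratio", "p"]).set_index("set_id")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = out["p_adj"] <= p_adj_cut
    return out


def running_sum_es(ranked_genes: list[str], scores: np.ndarray,
                   members: set, weight: float = 1.0) -> float:
    """Enrichment score: extremum of the weighted KS running sum.

    ``ranked_genes``/``scores`` must already be sorted by decreasing
    score.  Hits step up by |score|^weight / sum(|hit scores|^weight);
    misses step down by 1/(N - Nh).
    """
    hit = np.fromiter((g in members for g in ranked_genes), dtype=bool,
                      count=len(ranked_genes))
    nh = int(hit.sum())
    n = len(ranked_genes)
    if nh == 0 or nh == n:
        raise ValueError("gene set must hit a strict subset of the ranking")
    w = np.abs(scores) ** weight
    hit_sum = w[hit].sum()
    if hit_sum == 0:  # all member scores zero: fall back to unweighted steps
        steps_hit = np.full(n, 1.0 / nh)
    else:
        steps_hit = w / hit_sum
    delta = np.where(hit, steps_hit, -1.0 / (n - nh))
    running = np.cumsum(delta)
    return float(running[np.argmax(np.abs(running))])


def _rank(ranked: pd.Series) -> tuple[list[str], np.ndarray]:
    if ranked.index.has_duplicates:
        raise ValueError("ranked list must have unique gene ids")
    ordered = ranked.sort_values(ascending=False)
    return list(ordered.index), ordered.to_numpy(dtype=float)


def gsea(ranked: pd.Series, collection: dict[str, set],
         weight: float = 1.0, n_perm: int = 1000,
         seed: int = 0) -> pd.DataFrame:
    """Gene-set enrichment over a ranked gene->score series.

    The permutation null shuffles gene labels (equivalently: random
    same-size member subsets of ranking positions), so results are
    deterministic for a fixed seed at any sample size.  p uses the +1
    correction: p >= 1/(n_same_sign + 1).  q is the standard NES-based
    FDR computed separately within the positive and negative pools:
    q(S) = [fraction of pooled null NES at least as extreme] /
    [fraction of observed NES at least as extreme], capped at 1.

    Returns a DataFrame indexed by set_id with columns es, nes, p, q,
    direction, significant.
    """
    genes, scores = _rank(ranked)
    rng = np.random.default_rng(seed)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    results = []
    null_nes: list[np.ndarray] = []
    for set_id, members in collection.items():
        in_list = {g for g in members if g in gene_pos}
        if not in_list or len(in_list) == n:
            warnings.warn(f"set {set_id!r} skipped: no usable members in ranking",
                          stacklevel=2)
            continue
        es = running_sum_es(genes, scores, in_list, weight=weight)
        k = len(in_list)
        null = np.empty(n_perm)
        for j in range(n_perm):
            perm = set(rng.choice(n, size=k, replace=False))
            null[j] = running_sum_es(genes, scores,
                                     {genes[i] for i in perm}, weight=weight)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = float(np.mean(np.abs(same_sign))) if same_sign.size else 0.0
        nes = es / denom if denom > 0 else 0.0
        p = (1.0 + np.sum(np.abs(same_sign) >= abs(es))) / (1.0 + same_sign.size)
        results.append((set_id, es, nes, p))
        null_nes.append(null / denom if denom > 0 else np.zeros_like(null))

    out = pd.DataFrame(results, columns=["set_id", "es", "nes", "p"]).set_index("set_id")
    out["q"] = _nes_fdr(out["nes"].to_numpy(),
                        np.concatenate(null_nes) if null_nes else np.array([]))
    out["direction"] = np.where(out["es"] >= 0, "enriched_in_control",
                                "enriched_in_kd")
    out["significant"] = (out["nes"] > GSEA_MIN_NES) & (out["p"] <= GSEA_MAX_P) \
        & (out["q"] <= GSEA_MAX_Q)
    return out


def _nes_fdr(obs: np.ndarray, null: np.ndarray) -> np.ndarray:
    """NES-based FDR within positive/negative pools (capped at 1)."""
    q = np.ones_like(obs, dtype=float)
    for sign in (1, -1):
        sel = obs * sign > 0
        pool_null = null[null * sign > 0] * sign
        pool_obs = obs[sel] * sign
        if not sel.any():
            continue
        for i, idx in enumerate(np.where(sel)[0]):
            nes = pool_obs[i]
            num = np.mean(pool_null >= nes) if pool_null.size else 1.0
            den = np.mean(pool_obs >= nes)
            q[idx] = min(1.0, num / den) if den > 0 else 1.0
    return q
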