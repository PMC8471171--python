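"""Joint classification of promoter methylation and expression changes.

Each gene measured in both layers is placed in one of the four
methylation-expression quadrants (hyper/hypo-methylated x up/down-
regulated) when significant in both, mirroring the delta-beta vs log2FC
scatter used to find genes whose promoter hypermethylation coincides
with transcriptional activation.  Knockdown panels from several cell
lines are intersected to nominate genes consistently down-regulated on
transcription-factor depletion, and those are crossed with the
hypermethylated set to yield candidate direct targets.
"""

from __future__ import annotations

import warnings

import pandas as pd

__all__ = [
    "QUADRANTS",
    "classify_quadrants",
    "quadrant_counts",
    "knockdown_intersection",
    "candidate_direct_targets",
]

QUADRANTS = ("hyper_up", "hyper_down", "hypo_up", "hypo_down")


def _quadrant(delta_beta: float, log2fc: float, meth_sig: bool, expr_sig: bool) -> str:
    if not (meth_sig and expr_sig) or delta_beta == 0 or log2fc == 0:
        # zero effect with a significance flag can only arise under
        # user-supplied thresholds; the sign (hence quadrant) is undefined
        return "none"
    meth = "hyper" if delta_beta > 0 else "hypo"
    expr = "up" if log2fc > 0 else "down"
    return f"{meth}_{expr}"


def classify_quadrants(meth: pd.DataFrame, expr: pd.DataFrame) -> pd.DataFrame:
    """Inner-join the two differential tables and assign quadrants.

    ``meth`` and ``expr`` are DifferentialTables indexed by gene with
    columns effect / p_adj / significant (delta-beta and log2FC effects
    respectively).  Returns one row per shared gene with columns
    delta_beta, log2fc, meth_significant, expr_significant, quadrant.
    """
    shared = meth.index.intersection(expr.index)
    if len(shared) == 0:
        warnings.warn("no genes shared between methylation and expression tables",
                      stacklevel=2)
    out = pd.DataFrame({
        "delta_beta": meth.loc[shared, "effect"],
        "log2fc": expr.loc[shared, "effect"],
        "meth_significant": meth.loc[shared, "significant"].astype(bool),
        "expr_significant": expr.loc[shared, "significant"].astype(bool),
    })
    out["quadrant"] = [
        _quadrant(db, fc, ms, es)
        for db, fc, ms, es in zip(out["delta_beta"], out["log2fc"],
                                  out["meth_significant"], out["expr_significant"])
    ]
    out.index.name = "gene_id"
    return out


def quadrant_counts(records: pd.DataFrame) -> dict[str, int]:
    """Per-quadrant gene counts plus the total with both layers significant."""
    counts = {q: int((records["quadrant"] == q).sum()) for q in QUADRANTS}
    counts["total"] = sum(counts.values())
    return counts


def knockdown_intersection(panels: list[pd.DataFrame]) -> set[str]:
    """Genes significantly down-regulated in every knockdown panel.

    Each panel is a DifferentialTable of knockdown vs control for one
    cell line (effect = log2FC).  A gene qualifies in a panel when it is
    flagged significant with a negative effect.
    """
    if not panels:
        raise ValueError("need at least one knockdown panel")
    down_sets = [
        set(p.index[p["significant"] & (p["effect"] < 0)]) for p in panels
    ]
    return set.intersection(*down_sets)


def candidate_direct_targets(consistent_down: set[str], meth: pd.DataFrame) -> set[str]:
    """Consistently down-regulated genes with hypermethylated promoters.

    Intersects the knockdown-consistent set with genes flagged
    significant in the methylation table with delta-beta > 0.
    """
    hyper = set(meth.index[meth["significant"] & (meth["effect"] > 0)])
    return set(consistent_down) & hyper
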