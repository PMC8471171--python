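"""Protein-microarray screen for methylation-preferring DNA binders.

Spotted transcription factors (DNA-binding domains or full-length
constructs) are incubated with a fluorescently labelled promoter
fragment in fully methylated and fully unmethylated form.  Per channel,
a spot is called positive when its median fluorescence intensity (MFI)
exceeds the mean of the negative-control spots plus four sample
standard deviations.  The methylated/unmethylated signal ratio — with
each channel floored at its positivity threshold so sub-background
denominators cannot inflate it — classifies each factor, and the
methyl-preferring factors are ranked by descending ratio.

Protein expression is QC'd via N- and C-terminal tag stains: a factor
counts as expressed at full length only when both tags exceed their own
negative-control-derived thresholds.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["positivity_threshold", "screen", "expression_qc",
           "SD_MULTIPLIER", "DEFAULT_RATIO_CUTOFF", "DEFAULT_TOP_K"]

SD_MULTIPLIER = 4.0
DEFAULT_RATIO_CUTOFF = 2.0
DEFAULT_TOP_K = 15

CHANNELS = ("mfi_meth", "mfi_unmeth", "tag_n", "tag_c")


def positivity_threshold(neg_mfis, sd_multiplier: float = SD_MULTIPLIER) -> float:
    """Positive-signal threshold: mean of negative controls + 4 sample SD."""
    x = np.asarray(neg_mfis, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 negative-control values (SD undefined)")
    return float(x.mean() + sd_multiplier * x.std(ddof=1))


def _collapse(scan: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Median-collapse replicates per TF and compute per-channel thresholds."""
    neg = scan[scan["construct"] == "negative_control"]
    if len(neg) < 2:
        raise ValueError("scan must contain >= 2 negative-control spots")
    thresholds = {ch: positivity_threshold(neg[ch]) for ch in CHANNELS}
    tf = scan[scan["construct"] != "negative_control"]
    collapsed = tf.groupby("tf_id", sort=True)[list(CHANNELS)].median()
    return collapsed, thresholds


def screen(scan: pd.DataFrame,
           ratio_cutoff: float = DEFAULT_RATIO_CUTOFF,
           expression_floor: float = 1.0,
           top_k: int = DEFAULT_TOP_K) -> pd.DataFrame:
    """Classify and rank TFs by methylation preference.

    ``scan`` columns: spot_id, tf_id, construct, replicate, mfi_meth,
    mfi_unmeth, tag_n, tag_c; negative-control spots carry
    construct == "negative_control".

    Classes: ``not_expressed`` (both tag stains below
    ``expression_floor`` x their thresholds), ``non_binder`` (neither
    DNA channel positive), ``methyl_preferring`` (methylated channel
    positive, floored ratio >= cutoff), ``unmethyl_preferring``
    (symmetric) or ``non_discriminating``.  Methyl-preferring factors
    get ranks 1..k by descending ratio (ties: descending mfi_meth, then
    tf_id); the top ``top_k`` are marked in ``in_top_k``.
    """
    collapsed, thr = _collapse(scan)
    m = collapsed["mfi_meth"].to_numpy()
    u = collapsed["mfi_unmeth"].to_numpy()
    pos_m = m > thr["mfi_meth"]
    pos_u = u > thr["mfi_unmeth"]
    m_floor = np.maximum(m, thr["mfi_meth"])
    u_floor = np.maximum(u, thr["mfi_unmeth"])
    ratio = m_floor / u_floor

    not_expressed = (
        (collapsed["tag_n"] < expression_floor * thr["tag_n"])
        & (collapsed["tag_c"] < expression_floor * thr["tag_c"])
    ).to_numpy()

    cls = np.full(len(collapsed), "non_discriminating", dtype=object)
    cls[pos_m & (ratio >= ratio_cutoff)] = "methyl_preferring"
    cls[pos_u & (1.0 / ratio >= ratio_cutoff)] = "unmethyl_preferring"
    cls[~pos_m & ~pos_u] = "non_binder"
    cls[not_expressed] = "not_expressed"

    out = pd.DataFrame({
        "tf_id": collapsed.index,
        "mfi_meth": m, "mfi_unmeth": u,
        "threshold_meth": thr["mfi_meth"], "threshold_unmeth": thr["mfi_unmeth"],
        "positive_meth": pos_m, "positive_unmeth": pos_u,
        "ratio_meth_over_unmeth": ratio,
        "class": cls,
    }).set_index("tf_id")

    mp = out[out["class"] == "methyl_preferring"]
    order = mp.reset_index().sort_values(
        ["ratio_meth_over_unmeth", "mfi_meth", "tf_id"],
        ascending=[False, False, True])["tf_id"]
    out["rank"] = pd.Series(np.arange(1, len(order) + 1), index=order)
    out["in_top_k"] = out["rank"].le(top_k).fillna(False)
    return out


def expression_qc(scan: pd.DataFrame, expression_floor: float = 1.0) -> pd.DataFrame:
    """Full-length expression calls from the two terminal tag stains."""
    collapsed, thr = _collapse(scan)
    return pd.DataFrame({
        "tag_n": collapsed["tag_n"],
        "tag_c": collapsed["tag_c"],
        "expressed_full_length": (
            (collapsed["tag_n"] > expression_floor * thr["tag_n"])
            & (collapsed["tag_c"] > expression_floor * thr["tag_c"])
        ),
    })
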