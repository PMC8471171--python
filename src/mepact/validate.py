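"""Quantification of the wet-lab validation assays.

* bisulfite clone sequencing: per-CpG and overall percent methylation,
  plus the per-clone conversion rate over non-CpG cytosines as a
  quality gate;
* qPCR relative expression by the delta-delta-Ct method against a
  housekeeping gene;
* ChIP-qPCR enrichment by the percent-input method with log2 dilution
  adjustment;
* dual-luciferase promoter activity, firefly normalised by Renilla,
  relative to the empty-vector control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "clone_methylation_summary", "conversion_rate", "ddct",
    "percent_input", "luciferase_relative",
    "DEFAULT_CONVERSION_PASS_PCT",
]

DEFAULT_CONVERSION_PASS_PCT = 95.0


def clone_methylation_summary(calls: pd.DataFrame):
    """Percent methylation per CpG site and overall.

    ``calls`` is clone x CpG-site with entries in {0, 1} (1 =
    methylated).  Returns ``(per_cpg_percent, overall_percent)``; the
    overall value averages every call, e.g. 29 methylated of 50 calls ->
    58.0.
    """
    if calls.size == 0:
        raise ValueError("clone matrix is empty")
    vals = calls.to_numpy(dtype=float)
    if not np.isin(vals, (0.0, 1.0)).all():
        raise ValueError("clone calls must be 0 or 1")
    per_cpg = 100.0 * vals.mean(axis=0)
    overall = 100.0 * vals.mean()
    return pd.Series(per_cpg, index=calls.columns, name="percent_methylated"), \
        float(overall)


def conversion_rate(conv: pd.DataFrame,
                    pass_threshold_pct: float = DEFAULT_CONVERSION_PASS_PCT
                    ) -> pd.DataFrame:
    """Per-clone bisulfite conversion rate over non-CpG cytosines.

    ``conv`` has columns ``converted`` and ``total`` per clone.  Returns
    rate_pct and a pass flag (rate >= threshold); callers may exclude
    failing clones before summarising.
    """
    if (conv["total"] <= 0).any():
        raise ValueError("total non-CpG cytosine count must be > 0")
    if (conv["converted"] > conv["total"]).any():
        raise ValueError("converted count exceeds total")
    rate = 100.0 * conv["converted"] / conv["total"]
    return pd.DataFrame({"rate_pct": rate, "passed": rate >= pass_threshold_pct})


def _combine(x: pd.Series, how: str) -> float:
    return float(x.median() if how == "median" else x.mean())


def ddct(ct: pd.DataFrame, housekeeping: str, reference_condition: str,
         replicate_combine: str = "mean") -> pd.Series:
    """Relative expression fold changes by the delta-delta-Ct method.

    ``ct`` columns: sample, condition, gene, ct.  Per condition,
    replicate (and sample) Cts are combined per gene; dCt = Ct_target -
    Ct_housekeeping; ddCt = dCt_condition - dCt_reference; fold =
    2^(-ddCt).  Returns a Series indexed by (gene, condition) for the
    non-reference conditions.
    """
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    mean_ct = ct.groupby(["condition", "gene"])["ct"].apply(
        lambda x: _combine(x, replicate_combine))
    conditions = ct["condition"].unique()
    if reference_condition not in conditions:
        raise ValueError(f"reference condition {reference_condition!r} absent")
    folds = {}
    for cond in conditions:
        if (cond, housekeeping) not in mean_ct.index:
            raise ValueError(f"housekeeping gene {housekeeping!r} missing "
                             f"in condition {cond!r}")
    ref_hk = mean_ct[(reference_condition, housekeeping)]
    for cond in conditions:
        if cond == reference_condition:
            continue
        hk = mean_ct[(cond, housekeeping)]
        for gene in mean_ct.loc[cond].index:
            if gene == housekeeping:
                continue
            if (reference_condition, gene) not in mean_ct.index:
                continue
            dct_case = mean_ct[(cond, gene)] - hk
            dct_ref = mean_ct[(reference_condition, gene)] - ref_hk
            folds[(gene, cond)] = 2.0 ** (-(dct_case - dct_ref))
    out = pd.Series(folds, name="fold_change")
    out.index.names = ["gene", "condition"]
    return out


def percent_input(chip: pd.DataFrame) -> pd.Series:
    """ChIP enrichment as percent of input chromatin.

    ``chip`` columns: target_region, antibody, ct_ip, ct_input,
    input_fraction.  The input Ct is adjusted for the dilution
    (ct_input - log2(1/input_fraction), i.e. the Ct the full input would
    have shown), then percent = 100 * 2^(adjusted_input - ct_ip),
    averaged over replicate rows per (target_region, antibody).
    """
    if (chip["input_fraction"] <= 0).any() or (chip["input_fraction"] > 1).any():
        raise ValueError("input_fraction must lie in (0, 1]")
    adj = chip["ct_input"] - np.log2(1.0 / chip["input_fraction"])
    pct = 100.0 * 2.0 ** (adj - chip["ct_ip"])
    out = pct.groupby([chip["target_region"], chip["antibody"]]).mean()
    out.name = "percent_input"
    return out


def luciferase_relative(luc: pd.DataFrame) -> pd.Series:
    """Promoter activity relative to the empty-vector control.

    ``luc`` columns: construct (promoter / empty_control), condition,
    firefly, renilla.  Per well, activity = firefly / renilla; per
    condition, fold = mean promoter activity / mean empty-control
    activity.
    """
    if (luc["renilla"] <= 0).any():
        raise ValueError("Renilla readings must be > 0")
    luc = luc.assign(activity=luc["firefly"] / luc["renilla"])
    folds = {}
    for cond, grp in luc.groupby("condition"):
        ctrl = grp.loc[grp["construct"] == "empty_control", "activity"]
        prom = grp.loc[grp["construct"] == "promoter", "activity"]
        if ctrl.empty:
            raise ValueError(f"no empty-control wells in condition {cond!r}")
        folds[cond] = float(prom.mean() / ctrl.mean())
    out = pd.Series(folds, name="relative_activity")
    out.index.name = "condition"
    return out
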