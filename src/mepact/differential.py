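"""Differential promoter methylation and differential expression.

Both data layers are tested with the same empirical-Bayes moderated
two-sample t-statistic: per-feature sample variances are shrunk toward a
pooled prior variance fitted across all features, which stabilises the
denominator of the t-statistic when per-group sample sizes are small.
Multiple testing is controlled with the Benjamini-Hochberg step-up
procedure.

Significance calls follow the study defaults:

* methylation: BH-adjusted p <= 0.05 and absolute promoter delta-beta >= 0.1
* expression:  BH-adjusted p <= 0.01 and absolute log2 fold change >= 0.5
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import polygamma
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BetaMatrix",
    "ExpressionMatrix",
    "GeneAnnotation",
    "promoter_windows",
    "promoter_mean_beta",
    "moderated_t_test",
    "bh_adjust",
    "diff_methylation",
    "diff_expression",
    "METH_P_ADJ",
    "METH_MIN_ABS_DELTA",
    "EXPR_P_ADJ",
    "EXPR_MIN_ABS_LFC",
]

# study significance thresholds
METH_P_ADJ = 0.05
METH_MIN_ABS_DELTA = 0.1
EXPR_P_ADJ = 0.01
EXPR_MIN_ABS_LFC = 0.5

PROMOTER_UPSTREAM = 1500
PROMOTER_DOWNSTREAM = 500


@dataclass
class BetaMatrix:
    """CpG-probe x sample methylation fractions with probe coordinates.

    ``values`` is probes x samples with entries in [0, 1]; ``probes`` maps
    probe_id -> (chrom, pos) with 0-based positions; ``groups`` maps sample
    id -> {"case", "control"}.
    """

    values: pd.DataFrame
    probes: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("beta values must lie in [0, 1]")
        missing = self.values.index.difference(self.probes.index)
        if len(missing):
            raise ValueError(f"probes without coordinates: {list(missing)[:5]}")


@dataclass
class ExpressionMatrix:
    """Gene x sample log2 abundances plus a sample->group mapping."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression values must be finite")


@dataclass
class GeneAnnotation:
    """Per-gene TSS annotation. ``table`` columns: gene_id, chrom, strand, tss."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "strand", "tss"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"annotation needs columns {sorted(required)}")
        bad = ~self.table["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError("strand must be '+' or '-'")


def promoter_windows(annot: GeneAnnotation,
                     upstream: int = PROMOTER_UPSTREAM,
                     downstream: int = PROMOTER_DOWNSTREAM) -> pd.DataFrame:
    """Strand-oriented promoter intervals, 0-based half-open.

    For a plus-strand gene the window is [tss-upstream, tss+downstream);
    for a minus-strand gene it is [tss-downstream, tss+upstream) in genome
    coordinates, i.e. the same window in transcription orientation.
    """
    t = annot.table
    plus = t["strand"].eq("+")
    start = np.where(plus, t["tss"] - upstream, t["tss"] - downstream)
    end = np.where(plus, t["tss"] + downstream, t["tss"] + upstream)
    return pd.DataFrame(
        {"gene_id": t["gene_id"], "chrom": t["chrom"],
         "start": start.astype(int), "end": end.astype(int),
         "strand": t["strand"]}).set_index("gene_id")


def promoter_mean_beta(beta: BetaMatrix, annot: GeneAnnotation):
    """Average beta over the probes inside each gene's promoter window.

    Returns ``(means, dropped)`` where ``means`` is a gene x sample
    DataFrame of arithmetic means and ``dropped`` lists genes whose
    promoter contains no probe (omitted from ``means``).  Window
    membership is half-open: a probe at exactly the window end is
    excluded.
    """
    windows = promoter_windows(annot)
    rows = []
    dropped: list[str] = []
    probes = beta.probes
    for gene_id, w in windows.iterrows():
        on_chrom = probes["chrom"] == w["chrom"]
        inside = on_chrom & (probes["pos"] >= w["start"]) & (probes["pos"] < w["end"])
        ids = probes.index[inside]
        if len(ids) == 0:
            dropped.append(gene_id)
            continue
        rows.append(pd.Series(beta.values.loc[ids].mean(axis=0), name=gene_id))
    if not rows:
        raise ValueError("no gene promoter contains any probe")
    means = pd.DataFrame(rows)
    means.index.name = "gene_id"
    return means, dropped


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y += dif
        if abs(dif) / y < 1e-8:
            break
    return float(y)


def _fit_variance_prior(s2: np.ndarray, df: int,
                        d0: float | None = None) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior (d0, s0^2) to the
    observed per-feature variances.

    Under the hierarchical model, log s^2 has mean log s0^2 + psi(d/2)
    - log(d/2) - psi(d0/2) + log(d0/2) and variance psi'(d/2) + psi'(d0/2);
    d0 comes from inverting the trigamma, s0^2 from the digamma identity.
    Returns d0 = 0 (no moderation) when the inversion is infeasible, which
    happens when the observed log-variances are nearly constant.  A fixed
    ``d0`` skips the trigamma step and fits only s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return (d0 or 0.0), float(np.median(s2[ok])) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - polygamma(0, df / 2.0) + np.log(df / 2.0)
    if d0 is None:
        evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
        if evar <= 0:
            return 0.0, float(np.exp(np.mean(e)))
        d0 = 2.0 * _trigamma_inverse(evar)
    if np.isinf(d0):
        return float(d0), float(np.exp(np.mean(e)))
    s02 = float(np.exp(np.mean(e) + polygamma(0, d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s02


def moderated_t_test(values: pd.DataFrame, groups: pd.Series,
                     prior_df: float | None = None) -> pd.DataFrame:
    """Empirical-Bayes moderated two-sample t-test, case minus control.

    Per feature the pooled sample variance s^2 (d = n1 + n2 - 2 df) is
    shrunk toward a prior s0^2 fitted across features:
    s2_post = (d0*s0^2 + d*s^2) / (d0 + d), and
    t = effect / (s_post * sqrt(1/n1 + 1/n2)) with d0 + d degrees of
    freedom.  ``prior_df`` overrides the estimated d0 (0 recovers the
    ordinary pooled-variance t).

    Returns a DataFrame indexed by feature with columns effect, t_mod, p.
    """
    groups = groups.reindex(values.columns)
    case = values.loc[:, groups.eq("case").to_numpy()].to_numpy(dtype=float)
    ctrl = values.loc[:, groups.eq("control").to_numpy()].to_numpy(dtype=float)
    n1, n2 = case.shape[1], ctrl.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 samples per group")
    if values.shape[0] < 2:
        raise ValueError("need >= 2 features to fit the variance prior")
    df = n1 + n2 - 2
    effect = case.mean(axis=1) - ctrl.mean(axis=1)
    ss = case.var(axis=1, ddof=1) * (n1 - 1) + ctrl.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df

    if prior_df is None:
        if not (s2 > 0).any():
            warnings.warn("all features have zero variance; "
                          "falling back to the ordinary t-test (t undefined -> p = 1 "
                          "where the effect is also zero)", stacklevel=2)
            d0, s02 = 0.0, 0.0
        else:
            d0, s02 = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        if d0 > 0:
            _, s02 = _fit_variance_prior(s2, df, d0=d0)
        else:
            s02 = 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = np.inf
    else:
        s2_post = (d0 * s02 + df * s2) / (d0 + df)
        df_total = d0 + df

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / se
    # constant features with no effect: define t = 0 (p = 1)
    t[(se == 0) & (effect == 0)] = 0.0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return pd.DataFrame({"effect": effect, "t_mod": t, "p": p}, index=values.index)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _finalise(table: pd.DataFrame, p_adj_cut: float, effect_cut: float) -> pd.DataFrame:
    table = table.copy()
    table["p_adj"] = bh_adjust(table["p"].to_numpy())
    table["significant"] = (table["p_adj"] <= p_adj_cut) & \
        (table["effect"].abs() >= effect_cut)
    table.index.name = "feature_id"
    return table


def diff_methylation(beta: BetaMatrix, annot: GeneAnnotation,
                     p_adj_cut: float = METH_P_ADJ,
                     min_abs_delta: float = METH_MIN_ABS_DELTA,
                     prior_df: float | None = None):
    """Per-gene differential promoter methylation (effect = delta-beta).

    Promoter-mean beta values are compared case vs control with the
    moderated t; genes whose promoter holds no probe are dropped and
    returned in the QC list.  Returns ``(DifferentialTable, dropped)``.
    """
    means, dropped = promoter_mean_beta(beta, annot)
    table = moderated_t_test(means, beta.groups, prior_df=prior_df)
    return _finalise(table, p_adj_cut, min_abs_delta), dropped


def diff_expression(expr: ExpressionMatrix,
                    p_adj_cut: float = EXPR_P_ADJ,
                    min_abs_lfc: float = EXPR_MIN_ABS_LFC,
                    prior_df: float | None = None) -> pd.DataFrame:
    """Per-gene differential expression (effect = log2 fold change)."""
    table = moderated_t_test(expr.values, expr.groups, prior_df=prior_df)
    return _finalise(table, p_adj_cut, min_abs_lfc)
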