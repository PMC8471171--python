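"""Methylation-aware PWM scanning of promoter sequences.

Motifs are position weight matrices over the extended alphabet
{A, C, G, T, M}, where M denotes 5-methylcytosine in CpG context.  A
promoter is a plain DNA sequence plus a mask of methylated CpG
cytosines; encoding rewrites masked cytosines to M on the scanned
strand, and — because CpG methylation is symmetric — the complementary
cytosine of each masked CpG is likewise M on the reverse strand.

Windows on both strands are scored as the log2 likelihood ratio of the
motif emissions over a background distribution (bits), and each score
gets an exact p-value P(score >= s) under the background model,
computed by dynamic programming over integerised per-position score
distributions.  Benjamini-Hochberg q-values are taken over all windows
tested in a scan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .differential import bh_adjust

__all__ = [
    "ALPHABET", "MethylPromoter", "MethylPWM", "PValueTable",
    "encode_methylation", "scan", "exact_pvalue_table",
    "DEFAULT_P_THRESHOLD", "DEFAULT_GRANULARITY",
]

ALPHABET = "ACGTM"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
# M pairs with G; its complement on the other strand is the partner CpG
# cytosine, which symmetric methylation also marks as M
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "M": "G"}

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_GRANULARITY = 1e-3


@dataclass
class MethylPromoter:
    """Promoter sequence with methylated-CpG position mask (0-based)."""

    gene_id: str
    sequence: str
    methyl_mask: frozenset = field(default_factory=frozenset)
    coordinate_offset: int = 0

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if set(self.sequence) - set("ACGT"):
            raise ValueError("sequence must be over {A, C, G, T}")
        self.methyl_mask = frozenset(int(p) for p in self.methyl_mask)
        for p in self.methyl_mask:
            if not (0 <= p < len(self.sequence) - 1) \
                    or self.sequence[p] != "C" or self.sequence[p + 1] != "G":
                raise ValueError(
                    f"masked position {p} is not a CpG cytosine in {self.gene_id}")


@dataclass
class MethylPWM:
    """PWM over {A, C, G, T, M} with a background distribution.

    ``emissions`` is width x 5; rows must sum to 1.  A motif without an
    M column (M emission equal to C, background M mass folded into C)
    behaves exactly like a standard 4-letter PWM.
    """

    name: str
    emissions: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.full(5, 0.2))
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.emissions.ndim != 2 or self.emissions.shape[1] != 5:
            raise ValueError("emissions must be width x 5 (A, C, G, T, M)")
        if self.pseudocount:
            self.emissions = self.emissions + self.pseudocount
            self.emissions /= self.emissions.sum(axis=1, keepdims=True)
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("each PWM position must sum to 1")
        if (self.background <= 0).any():
            raise ValueError("background must be strictly positive")

    @property
    def width(self) -> int:
        return self.emissions.shape[0]

    def score_matrix(self) -> np.ndarray:
        """Per-position per-letter log2-odds scores (bits); -inf allowed."""
        with np.errstate(divide="ignore"):
            return np.log2(self.emissions / self.background)


def _revcomp(encoded: str) -> str:
    return "".join(_COMPLEMENT[c] for c in reversed(encoded))


def encode_methylation(promoter: MethylPromoter) -> tuple[str, str]:
    """Extended-alphabet strings for the plus and minus strands.

    On the plus strand every masked cytosine becomes M; the minus-strand
    string is the reverse complement in which the cytosine pairing each
    masked CpG's guanine is also M (symmetric CpG methylation).  The
    minus string is written 5'->3'; its index i corresponds to plus
    position len - 1 - i.
    """
    seq = list(promoter.sequence)
    for p in promoter.methyl_mask:
        seq[p] = "M"
    plus = "".join(seq)
    minus = list(_revcomp(plus))
    for p in promoter.methyl_mask:
        # plus-strand G at p+1 pairs the minus-strand methyl-C
        minus[len(plus) - 1 - (p + 1)] = "M"
    return plus, "".join(minus)


@dataclass
class PValueTable:
    """Exact null distribution of integerised window scores.

    ``scores`` are achievable integer scores (ascending, units of
    ``granularity`` bits); ``tail[i]`` = P(score >= scores[i]) under the
    background model.
    """

    scores: np.ndarray
    tail: np.ndarray
    granularity: float

    def pvalue(self, score_bits: float) -> float:
        """P(window score >= score_bits); score integerised consistently
        with the DP so table lookups match scanned windows exactly."""
        k = int(round(score_bits / self.granularity))
        idx = np.searchsorted(self.scores, k, side="left")
        if idx >= len(self.scores):
            return 0.0
        return float(min(1.0, self.tail[idx]))


def exact_pvalue_table(pwm: MethylPWM,
                       granularity: float = DEFAULT_GRANULARITY) -> PValueTable:
    """Exact PWM p-values by DP convolution under the background model.

    Per position the per-letter log2-odds scores are rounded to integer
    multiples of ``granularity``; the distributions are convolved across
    positions, giving P(score >= s) for every achievable score.  Letters
    with zero emission (score -inf) contribute their background mass to
    an 'unreachable' bucket, so p-values stay a proper tail.
    """
    if granularity <= 0:
        raise ValueError("granularity must be > 0")
    sm = pwm.score_matrix()
    dist: dict[int, float] = {0: 1.0}
    p_unreachable = 0.0
    for i in range(pwm.width):
        new: dict[int, float] = {}
        reachable_mass = 0.0
        for a in range(5):
            s = sm[i, a]
            bg = pwm.background[a]
            if not np.isfinite(s):
                continue
            k = int(round(s / granularity))
            reachable_mass += bg
            for cur, prob in dist.items():
                new[cur + k] = new.get(cur + k, 0.0) + prob * bg
        p_unreachable += sum(dist.values()) * (1.0 - reachable_mass)
        dist = new
    scores = np.array(sorted(dist))
    probs = np.array([dist[k] for k in scores])
    tail = probs[::-1].cumsum()[::-1]
    return PValueTable(scores=scores, tail=tail, granularity=granularity)


def _window_scores(encoded: str, int_scores: np.ndarray) -> np.ndarray:
    """Integerised score of every window of the encoded strand.

    Windows containing a zero-emission letter score minus infinity and
    are reported but never significant.
    """
    w = int_scores.shape[0]
    idx = np.array([_INDEX[c] for c in encoded])
    n = len(encoded) - w + 1
    out = np.empty(n)
    for start in range(n):
        out[start] = int_scores[np.arange(w), idx[start:start + w]].sum()
    return out


def scan(promoter: MethylPromoter, pwm: MethylPWM,
         p_threshold: float = DEFAULT_P_THRESHOLD,
         granularity: float = DEFAULT_GRANULARITY) -> pd.DataFrame:
    """Score every window on both strands; report hits with p <= threshold.

    Returns a DataFrame with columns gene_id, start, end, strand, score
    (bits), p, q — starts are 0-based plus-strand coordinates (offset by
    the promoter's genomic start), q is BH over all tested windows.
    Sorted by p then start.
    """
    L = len(promoter.sequence)
    if pwm.width > L:
        warnings.warn(f"motif wider than sequence for {promoter.gene_id}; "
                      "no windows to scan", stacklevel=2)
        return pd.DataFrame(
            columns=["gene_id", "start", "end", "strand", "score", "p", "q"])
    plus, minus = encode_methylation(promoter)
    table = exact_pvalue_table(pwm, granularity=granularity)
    sm = pwm.score_matrix()
    with np.errstate(invalid="ignore"):
        int_scores = np.where(np.isfinite(sm),
                              np.round(sm / granularity), -np.inf)

    rows = []
    w = pwm.width
    for strand, encoded in (("+", plus), ("-", minus)):
        ints = _window_scores(encoded, int_scores)
        for i, k in enumerate(ints):
            if np.isfinite(k):
                p = table.pvalue(k * granularity)
                score = k * granularity
            else:
                p, score = 1.0, -np.inf
            start = i if strand == "+" else L - i - w
            rows.append((promoter.gene_id, promoter.coordinate_offset + start,
                         promoter.coordinate_offset + start + w, strand, score, p))
    df = pd.DataFrame(rows, columns=["gene_id", "start", "end", "strand",
                                     "score", "p"])
    df["q"] = bh_adjust(df["p"].to_numpy())
    hits = df[df["p"] <= p_threshold].sort_values(
        ["p", "start", "strand"]).reset_index(drop=True)
    return hits
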