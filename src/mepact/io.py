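"""Readers and writers for the pipeline's on-disk formats.

Matrices travel as TSV (features x samples, header row of sample IDs),
annotation as a TSS table plus 6-column BED promoter windows (0-based,
half-open), sequences as FASTA (Biopython), methyl masks as BED,
gene-set collections as GMT, PWMs as a MEME-like probability matrix
with an optional fifth M column, and summaries as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .differential import BetaMatrix, ExpressionMatrix, GeneAnnotation, \
    promoter_windows
from .motif import MethylPromoter, MethylPWM

__all__ = [
    "write_matrix", "read_matrix", "write_groups", "read_groups",
    "write_beta", "read_beta", "write_expression", "read_expression",
    "write_annotation", "read_annotation", "write_promoter_bed",
    "read_fasta_promoters", "read_methyl_mask_bed", "read_gmt",
    "read_meme_pwm", "write_meme_pwm", "write_json",
]


def write_matrix(df: pd.DataFrame, path, index_label="feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_groups(groups: pd.Series, path) -> None:
    groups.rename("group").to_csv(path, sep="\t", index_label="sample")


def read_groups(path) -> pd.Series:
    return pd.read_csv(path, sep="\t", index_col=0)["group"]


def write_beta(beta: BetaMatrix, prefix) -> None:
    prefix = Path(prefix)
    write_matrix(beta.values, Path(f"{prefix}.beta.tsv"), "probe_id")
    beta.probes.to_csv(Path(f"{prefix}.probes.tsv"), sep="\t",
                       index_label="probe_id")
    write_groups(beta.groups, Path(f"{prefix}.groups.tsv"))


def read_beta(prefix) -> BetaMatrix:
    prefix = Path(prefix)
    return BetaMatrix(
        values=read_matrix(Path(f"{prefix}.beta.tsv")),
        probes=pd.read_csv(Path(f"{prefix}.probes.tsv"), sep="\t",
                           index_col=0),
        groups=read_groups(Path(f"{prefix}.groups.tsv")))


def write_expression(expr: ExpressionMatrix, prefix) -> None:
    prefix = Path(prefix)
    write_matrix(expr.values, Path(f"{prefix}.expr.tsv"), "gene_id")
    write_groups(expr.groups, Path(f"{prefix}.groups.tsv"))


def read_expression(prefix) -> ExpressionMatrix:
    prefix = Path(prefix)
    return ExpressionMatrix(
        values=read_matrix(Path(f"{prefix}.expr.tsv")),
        groups=read_groups(Path(f"{prefix}.groups.tsv")))


def write_annotation(annot: GeneAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index=False)


def read_annotation(path) -> GeneAnnotation:
    return GeneAnnotation(pd.read_csv(path, sep="\t"))


def write_promoter_bed(annot: GeneAnnotation, path) -> None:
    """Promoter windows as 6-column BED (name=gene_id, score=0)."""
    w = promoter_windows(annot).reset_index()
    bed = w[["chrom", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = w["strand"]
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_methyl_mask_bed(path) -> dict[str, set]:
    """BED of methylated-CpG cytosines: chrom column = gene/sequence id,
    positions 0-based relative to that sequence."""
    masks: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            name, start = fields[0], int(fields[1])
            masks.setdefault(name, set()).add(start)
    return masks


def read_fasta_promoters(fasta_path, mask_bed_path=None) -> list[MethylPromoter]:
    masks = read_methyl_mask_bed(mask_bed_path) if mask_bed_path else {}
    return [
        MethylPromoter(gene_id=rec.id, sequence=str(rec.seq),
                       methyl_mask=frozenset(masks.get(rec.id, set())))
        for rec in SeqIO.parse(fasta_path, "fasta")
    ]


def read_gmt(path) -> dict[str, set]:
    collection: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            collection[fields[0]] = set(g for g in fields[2:] if g)
    return collection


def read_meme_pwm(path) -> list[MethylPWM]:
    """MEME-like probability matrices, optionally with a fifth M column.

    When the M column is absent, the M emission is set equal to the C
    emission (the motif is indifferent to methylation) and the default
    uniform 5-letter background applies.
    """
    motifs = []
    name, rows = None, []
    background = None

    def _extend(mat: np.ndarray) -> np.ndarray:
        # split the C mass between C and M: log-odds of C are unchanged
        # and M scores like C (methylation-indifferent motif)
        mat = np.atleast_2d(mat)
        return np.column_stack([mat[:, 0], mat[:, 1] / 2, mat[:, 2],
                                mat[:, 3], mat[:, 1] / 2])

    def flush():
        nonlocal name, rows
        if name is not None and rows:
            em = np.array(rows, dtype=float)
            if em.shape[1] == 4:
                em = _extend(em)
            bg = background
            if bg is not None and len(bg) == 4:
                bg = _extend(bg)[0]
            kwargs = {"background": bg} if bg is not None else {}
            motifs.append(MethylPWM(name=name, emissions=em, **kwargs))
        name, rows = None, []

    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if s.startswith("MOTIF"):
                flush()
                name = s.split()[1]
            elif s.startswith("background:"):
                background = np.array(s.split()[1:], dtype=float)
            elif name is not None and s and (s[0].isdigit() or s[0] == "."):
                rows.append([float(x) for x in s.split()])
    flush()
    return motifs


def write_meme_pwm(motifs: list[MethylPWM], path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME-like extended alphabet A C G T M\n")
        for m in motifs:
            fh.write(f"\nMOTIF {m.name}\n")
            fh.write(f"background: {' '.join(f'{b:.6f}' for b in m.background)}\n")
            for row in m.emissions:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
        fh.write("\n")
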