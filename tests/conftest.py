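import numpy as np
import pandas as pd
import pytest

from mepact.differential import BetaMatrix, ExpressionMatrix, GeneAnnotation


@pytest.fixture
def small_annotation():
    return GeneAnnotation(pd.DataFrame({
        "gene_id": ["gA", "gB"],
        "chrom": ["chr1", "chr1"],
        "strand": ["+", "-"],
        "tss": [10_000, 50_000],
    }))


@pytest.fixture
def toy_expression():
    """3 case vs 3 control, one shifted gene, one null gene, one constant."""
    values = pd.DataFrame(
        {
            "c1": [5.0, 7.0, 3.0], "c2": [5.2, 6.9, 3.0], "c3": [4.8, 7.1, 3.0],
            "t1": [7.0, 7.05, 3.0], "t2": [7.2, 6.95, 3.0], "t3": [6.9, 7.0, 3.0],
        },
        index=["shifted", "flat", "constant"])
    groups = pd.Series(
        ["control"] * 3 + ["case"] * 3,
        index=["c1", "c2", "c3", "t1", "t2", "t3"])
    return ExpressionMatrix(values=values, groups=groups)


def make_beta(probe_pos, values, groups, chrom="chr1"):
    probes = pd.DataFrame(
        {"chrom": chrom, "pos": list(probe_pos.values())},
        index=pd.Index(probe_pos.keys(), name="probe_id"))
    return BetaMatrix(values=pd.DataFrame(values, index=probes.index,
                                          columns=groups.index),
                      probes=probes, groups=groups)
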