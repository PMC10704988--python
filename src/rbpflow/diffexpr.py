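"""Differential expression on replicate count matrices.

The pipeline consumes a DESeq2-style result table (gene, fold change,
p-value).  When only raw counts are available, this module produces that
table by fitting the negative-binomial GLM through pydeseq2 (a DESeq2
reimplementation), then converting the log2 fold change to linear scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .reads import ExpressionMatrix
from .splicing import CONTROL, KNOCKDOWN


def differential_expression(counts: ExpressionMatrix) -> pd.DataFrame:
    """DESeq2-style Wald test, knockdown vs control.

    Returns a table with columns gene_id, fold_change (linear,
    knockdown/control), p_value (raw Wald p), padj (BH).  Genes with no
    reads in any sample are reported with fold_change 1 and p 1.
    """
    from pydeseq2.dds import DeseqDataSet
    from pydeseq2.ds import DeseqStats

    mat = counts.values.T  # samples x genes
    meta = pd.DataFrame(
        {"condition": [counts.groups[s] for s in counts.samples]},
        index=counts.samples,
    )
    if set(meta["condition"]) != {CONTROL, KNOCKDOWN}:
        raise ValueError("need both control and knockdown samples")
    nonzero = mat.columns[(mat.sum(axis=0) > 0)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dds = DeseqDataSet(
            counts=mat[nonzero], metadata=meta, design="~condition", quiet=True
        )
        dds.deseq2()
        st = DeseqStats(
            dds, contrast=["condition", KNOCKDOWN, CONTROL], quiet=True
        )
        st.summary()
    res = st.results_df
    table = pd.DataFrame(
        {
            "gene_id": res.index.astype(str),
            "fold_change": 2.0 ** res["log2FoldChange"].to_numpy(),
            "p_value": res["pvalue"].fillna(1.0).to_numpy(),
            "padj": res["padj"].fillna(1.0).to_numpy(),
        }
    )
    dropped = [g for g in counts.genes if g not in set(nonzero)]
    if dropped:
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    {
                        "gene_id": dropped,
                        "fold_change": 1.0,
                        "p_value": 1.0,
                        "padj": 1.0,
                    }
                ),
            ],
            ignore_index=True,
        )
    order = {g: i for i, g in enumerate(counts.genes)}
    return (
        table.assign(_o=table["gene_id"].map(order))
        .sort_values("_o")
        .drop(columns="_o")
        .reset_index(drop=True)
    )
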