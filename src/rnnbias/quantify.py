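"""Gene-level FPKM with and without bias reweighting, plus evaluation
metrics and expression-shift diagnostics.

Raw expression of a gene is

    FPKM = 1e9 * sum_i n_i / (length(gene) * N)

over the gene's exonic read-start positions i, with N the total number of
counted (mapped, exonic) reads.  Bias correction replaces n_i by
n_i / bias_i while keeping the same denominator N.
"""

from __future__ import annotations

from intervaltree import IntervalTree

import numpy as np
import pandas as pd
from scipy import stats

from .bias import BiasTable
from .genome_io import GeneModel
from .sampling import PositionCounts

__all__ = [
    "quantify",
    "correlation_metrics",
    "expression_shift",
]


def quantify(
    counts: PositionCounts,
    gene_models: list[GeneModel],
    bias_table: BiasTable | None = None,
) -> pd.DataFrame:
    """Per-gene expression table.

    Columns: ``gene_id, raw_count, effective_count, raw_fpkm`` and, when a
    bias table is supplied, ``corrected_fpkm``.  A position inside several
    genes' exons contributes to each of them.
    """
    if counts.total_mapped <= 0:
        raise ValueError("total_mapped must be > 0")
    trees: dict[str, IntervalTree] = {}
    for gi, g in enumerate(gene_models):
        tree = trees.setdefault(g.contig, IntervalTree())
        for start, end in g.exons:
            tree.addi(start, end, gi)
    raw = np.zeros(len(gene_models))
    eff = np.zeros(len(gene_models))
    for key, n in counts.counts.items():
        contig, pos, _strand = key
        tree = trees.get(contig)
        if tree is None:
            continue
        b = bias_table.get(key) if bias_table is not None else 1.0
        for iv in tree[pos]:
            raw[iv.data] += n
            eff[iv.data] += n / b
    lengths = np.array([g.length for g in gene_models], dtype=float)
    n_total = float(counts.total_mapped)
    table = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in gene_models],
            "raw_count": raw,
            "effective_count": eff,
            "raw_fpkm": 1e9 * raw / (lengths * n_total),
        }
    )
    if bias_table is not None:
        table["corrected_fpkm"] = 1e9 * eff / (lengths * n_total)
    return table


def correlation_metrics(pred, ref, min_pairs: int = 3) -> dict:
    """Log-adjusted Pearson, Spearman and r2 between predicted and reference
    expression values.

    Pairs where either value is <= 0 are dropped (mirroring evaluation
    against non-zero reference measurements); Pearson is computed on log10
    of both, Spearman on the raw filtered values, and r2 is the squared
    log-Pearson.
    """
    pred = np.asarray(pred, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pred.shape != ref.shape:
        raise ValueError("pred and ref must have the same length")
    mask = (pred > 0) & (ref > 0)
    n = int(mask.sum())
    if n < min_pairs:
        raise ValueError(f"only {n} positive pairs; need at least {min_pairs}")
    lp, lr = np.log10(pred[mask]), np.log10(ref[mask])
    pearson = float(stats.pearsonr(lp, lr).statistic)
    spearman = float(stats.spearmanr(pred[mask], ref[mask]).statistic)
    return {
        "pearson_log": pearson,
        "spearman": spearman,
        "r2": pearson**2,
        "n": n,
    }


def expression_shift(raw, corrected, epsilon: float = 1e-6) -> dict:
    """How far bias correction moved the expression estimates.

    Per-gene ``logfold = log10((corrected + eps)/(raw + eps))``; the
    Euclidean distance is reported as the root-mean-square of the logfolds
    (gene-count independent), alongside counts of increased (> 0) and
    decreased (< 0) genes.
    """
    if isinstance(raw, pd.Series) and isinstance(corrected, pd.Series):
        if not raw.index.equals(corrected.index):
            if set(raw.index) != set(corrected.index):
                raise ValueError("raw and corrected tables cover different genes")
            corrected = corrected.reindex(raw.index)
    raw = np.asarray(raw, dtype=float)
    corrected = np.asarray(corrected, dtype=float)
    if raw.shape != corrected.shape:
        raise ValueError("raw and corrected tables cover different genes")
    logfold = np.log10((corrected + epsilon) / (raw + epsilon))
    return {
        "euclidean": float(np.sqrt(np.mean(logfold**2))),
        "n_increased": int((logfold > 0).sum()),
        "n_decreased": int((logfold < 0).sum()),
        "logfold": logfold,
    }
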