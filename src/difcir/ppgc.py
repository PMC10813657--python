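"""Produced-per-gene-circle (PpGC) quantification.

A circle contributes its full split-read count to every gene it
overlaps by at least one base pair (bedtools-intersect semantics on
half-open intervals; no apportioning between genes).  The per-gene,
per-sample sums form the unscaled PpGC matrix.  Each gene's sum is then
multiplied by the scale factor L_Max / L_i — L_Max being the length of
the longest gene found in the dataset, by default the longest gene with
any split-read support — and equalized as log2(x + 1) to give the
final PpGC values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io_circ import EccDnaRecord, GeneModel


@dataclass
class PpGCMatrix:
    """Genes × samples PpGC matrix.

    ``raw`` holds the unscaled per-gene split-read sums; ``values``
    holds log2(raw · L_Max/L_i + 1).  Gene order and sample order are
    shared between the two frames.  All-zero gene rows are retained and
    listed in ``zero_genes`` so callers may drop them.
    """

    genes: list[str]
    samples: list[str]
    raw: pd.DataFrame
    values: pd.DataFrame
    gene_lengths: pd.Series
    l_max: int
    zero_genes: list[str] = field(default_factory=list)

    def drop_zero_genes(self) -> "PpGCMatrix":
        keep = [g for g in self.genes if g not in set(self.zero_genes)]
        return PpGCMatrix(
            genes=keep,
            samples=list(self.samples),
            raw=self.raw.loc[keep],
            values=self.values.loc[keep],
            gene_lengths=self.gene_lengths.loc[keep],
            l_max=self.l_max,
            zero_genes=[],
        )


def annotate_overlaps(cohort: Mapping[str, Sequence[EccDnaRecord]],
                      genes: Sequence[GeneModel]) -> pd.DataFrame:
    """Sum split reads of all circles overlapping each gene, per sample.

    Overlap is ≥ 1 bp on half-open intervals, so abutting intervals do
    not overlap.  A circle spanning several genes contributes its full
    split-read count to each of them.  Returns an integer genes ×
    samples frame (gene symbols as index, sample ids as columns).
    """
    symbols = [g.symbol for g in genes]
    if len(set(symbols)) != len(symbols):
        raise ValueError("gene symbols must be unique")
    trees: dict[str, IntervalTree] = {}
    for idx, g in enumerate(genes):
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end, idx)
    samples = list(cohort)
    raw = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for s_idx, sample in enumerate(samples):
        for rec in cohort[sample]:
            tree = trees.get(rec.chrom)
            if tree is None:
                continue
            for hit in tree.overlap(rec.start, rec.end):
                raw[hit.data, s_idx] += rec.split_reads
    return pd.DataFrame(raw, index=symbols, columns=samples)


def ppgc_matrix(raw: pd.DataFrame, genes: Sequence[GeneModel],
                l_max_over_all_genes: bool = False) -> PpGCMatrix:
    """Scale unscaled per-gene sums by L_Max/L_i and equalize as log2(x+1).

    ``l_max`` is the longest gene with at least one split read in the
    dataset; pass ``l_max_over_all_genes=True`` to take the maximum over
    every annotated gene instead.  Values are therefore comparable only
    within one run; the run manifest records the L_Max used.
    """
    by_symbol = {g.symbol: g for g in genes}
    missing = [s for s in raw.index if s not in by_symbol]
    if missing:
        raise ValueError(f"raw matrix rows without a gene model: {missing[:5]}")
    lengths = pd.Series({s: by_symbol[s].length for s in raw.index}, name="length")
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"gene {bad} has non-positive length")
    if (raw.to_numpy() < 0).any():
        raise ValueError("raw PpGC sums must be non-negative")
    nonzero = raw.sum(axis=1) > 0
    if l_max_over_all_genes or not nonzero.any():
        l_max = int(lengths.max())
    else:
        l_max = int(lengths[nonzero].max())
    scale = l_max / lengths.to_numpy(dtype=float)
    values = np.log2(raw.to_numpy(dtype=float) * scale[:, None] + 1.0)
    return PpGCMatrix(
        genes=list(raw.index),
        samples=list(raw.columns),
        raw=raw.copy(),
        values=pd.DataFrame(values, index=raw.index, columns=raw.columns),
        gene_lengths=lengths,
        l_max=l_max,
        zero_genes=list(raw.index[~nonzero]),
    )


def quantify(cohort: Mapping[str, Sequence[EccDnaRecord]],
             genes: Sequence[GeneModel],
             l_max_over_all_genes: bool = False) -> PpGCMatrix:
    """annotate_overlaps followed by ppgc_matrix."""
    raw = annotate_overlaps(cohort, genes)
    return ppgc_matrix(raw, genes, l_max_over_all_genes=l_max_over_all_genes)
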