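"""Differential-expression screening, min-max normalization, sample shuffling.

The screen is rank-based and nonparametric: per gene, a two-sided
Mann-Whitney U test between the normal and tumor groups, Benjamini-Hochberg
correction across all genes, and a log2 fold-change filter on class means.
A gene survives when |log2FC| > logfc_min and FDR < fdr_max. Screening runs
on raw expression; normalization is applied to the survivors afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .data import ExpressionDataset

__all__ = ["DEGRecord", "screen_degs", "minmax_normalize", "shuffle_samples"]

#: pseudocount guarding the fold-change ratio against zero class means
LOGFC_EPS = 1e-9


@dataclass(frozen=True)
class DEGRecord:
    """One differentially expressed gene surviving the screen."""

    gene_id: str
    logfc: float
    p_value: float
    fdr: float

    @property
    def direction(self) -> str:
        return "up" if self.logfc > 0 else "down"


def screen_degs(
    ds: ExpressionDataset,
    logfc_min: float = 1.0,
    fdr_max: float = 0.05,
    eps: float = LOGFC_EPS,
) -> list[DEGRecord]:
    """Screen genes differentially expressed between the two phenotypes.

    Per gene: two-sided Mann-Whitney U p-value (normal approximation with
    tie correction), BH FDR across all genes, and
    logfc = log2((mean_tumor + eps) / (mean_normal + eps)).
    Returns the records of genes with |logfc| > logfc_min and fdr < fdr_max,
    in input gene order.
    """
    n_neg, n_pos = ds.class_counts()
    if n_neg < 2 or n_pos < 2:
        raise ValueError(f"each class needs >= 2 samples (have {n_neg} vs {n_pos})")
    pos = ds.values[ds.labels == 1]
    neg = ds.values[ds.labels == 0]
    # vectorized over genes; "auto" picks the exact distribution for small
    # tie-free groups and the tie-corrected normal approximation otherwise
    res = mannwhitneyu(pos, neg, alternative="two-sided", axis=0, method="auto")
    pvals = np.atleast_1d(res.pvalue)
    _, fdrs, _, _ = multipletests(pvals, method="fdr_bh")
    logfc = np.log2((pos.mean(axis=0) + eps) / (neg.mean(axis=0) + eps))
    keep = (np.abs(logfc) > logfc_min) & (fdrs < fdr_max)
    return [
        DEGRecord(gene_id=g, logfc=float(logfc[j]), p_value=float(pvals[j]),
                  fdr=float(fdrs[j]))
        for j, g in enumerate(ds.gene_ids) if keep[j]
    ]


def minmax_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Scale each gene to [0, 1]: x' = (x - min) / (max - min).

    A constant gene maps to all zeros rather than NaN, so downstream
    classifiers never see non-finite input.
    """
    mins = ds.values.min(axis=0)
    spans = ds.values.max(axis=0) - mins
    out = np.zeros_like(ds.values)
    nz = spans > 0
    out[:, nz] = (ds.values[:, nz] - mins[nz]) / spans[nz]
    return ExpressionDataset(ds.sample_ids, ds.gene_ids, out, ds.labels)


def shuffle_samples(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """Permute rows and labels together with a seeded uniform permutation."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    return ExpressionDataset(
        [ds.sample_ids[i] for i in perm], ds.gene_ids,
        ds.values[perm], ds.labels[perm],
    )
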