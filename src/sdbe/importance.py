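"""Random-forest importance ranking and top-K gene cuts.

A forest trained on the full dataset scores every gene by mean impurity
decrease; genes are sorted by importance descending and a top-K cut keeps
the strongest. Permutation importance is available behind a flag for users
wary of impurity bias with many-valued features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .crossval import ClassifierSpec
from .data import ExpressionDataset

__all__ = ["ImportanceRanking", "rank_by_importance", "take_top"]


@dataclass(frozen=True)
class ImportanceRanking:
    """Genes sorted by importance descending; importances sum to 1."""

    gene_ids: tuple[str, ...]
    importances: np.ndarray

    def __post_init__(self):
        imp = np.asarray(self.importances, dtype=float)
        if len(imp) != len(self.gene_ids):
            raise ValueError("importances misaligned with gene_ids")
        if np.any(np.diff(imp) > 1e-12):
            raise ValueError("importances must be non-increasing")
        if abs(imp.sum() - 1.0) > 1e-9:
            raise ValueError("importances must sum to 1")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "importances", imp)

    def __len__(self) -> int:
        return len(self.gene_ids)


def rank_by_importance(
    ds: ExpressionDataset,
    spec: ClassifierSpec | None = None,
    seed: int = 0,
    permutation: bool = False,
    n_repeats: int = 5,
) -> ImportanceRanking:
    """Train on the full dataset and rank genes by variable importance.

    Ties break by gene id lexicographically so rankings are deterministic
    given a seed. ``permutation=True`` swaps impurity-decrease importances
    for permutation importances (slower, unbiased for cardinality).
    """
    spec = spec or ClassifierSpec("rf")
    if not spec.has_importances and not permutation:
        raise ValueError(f"classifier {spec.name!r} exposes no importances; "
                         f"use an importance-capable model or permutation=True")
    model = spec.build(seed=seed)
    model.fit(ds.values, ds.labels)
    if permutation:
        from sklearn.inspection import permutation_importance
        r = permutation_importance(model, ds.values, ds.labels,
                                   n_repeats=n_repeats, random_state=seed)
        imp = np.maximum(r.importances_mean, 0.0)
    else:
        imp = np.asarray(model.feature_importances_, dtype=float)
    total = imp.sum()
    imp = imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))
    # sort by (-importance, gene_id): deterministic under ties
    order = sorted(range(len(imp)), key=lambda j: (-imp[j], ds.gene_ids[j]))
    return ImportanceRanking(
        gene_ids=[ds.gene_ids[j] for j in order],
        importances=imp[order],
    )


def take_top(ranking: ImportanceRanking, k: int) -> list[str]:
    """First k gene ids of the ranking, order preserved."""
    if not 1 <= k <= len(ranking):
        raise ValueError(f"k={k} out of range 1..{len(ranking)}")
    return list(ranking.gene_ids[:k])
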