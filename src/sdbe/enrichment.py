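"""Lightweight gene-set enrichment: ranking, running-sum ES, leading edge.

The classic weighted Kolmogorov-Smirnov statistic: genes are ranked by a
signal-to-noise contrast between the two phenotypes; walking down the
ranked list, set members ("hits") push a running sum up in proportion to
|stat|^p while non-members pull it down by a constant; the enrichment score
(ES) is the running-sum value of maximal absolute deviation from zero. The
"leading edge" (core enrichment) is the members at or before the extremum —
the genes that actually carry the enrichment signal, and the ones this
pipeline forwards to backward elimination.

Significance comes from permutation: phenotype permutation (re-rank the
genes under shuffled labels) where the cohort is large enough, otherwise
random member sets of equal size. NES normalizes ES by the mean |null ES|
of matching sign; FDR q-values follow the sign-stratified convention of
comparing the pooled null NES distribution with the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import ExpressionDataset, GeneSet

__all__ = ["RankedList", "EnrichmentResult", "rank_genes", "enrichment_score",
           "permutation_significance", "enrichment_report", "select_core_genes",
           "read_rnk"]


@dataclass(frozen=True)
class RankedList:
    """Gene ids sorted by a contrast statistic, non-increasing."""

    gene_ids: tuple[str, ...]
    stats: np.ndarray

    def __post_init__(self):
        stats = np.asarray(self.stats, dtype=float)
        if len(stats) != len(self.gene_ids):
            raise ValueError("stats misaligned with gene_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("ranked gene ids must be unique")
        if np.any(np.diff(stats) > 1e-12):
            raise ValueError("stats must be non-increasing")
        object.__setattr__(self, "gene_ids", tuple(self.gene_ids))
        object.__setattr__(self, "stats", stats)

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    es: float
    leading_edge: tuple[str, ...]
    running_sum: np.ndarray
    nes: float = float("nan")
    nom_p: float = float("nan")
    fdr_q: float = float("nan")
    null_es: np.ndarray | None = field(default=None, repr=False)


def rank_genes(ds: ExpressionDataset, sigma_floor_frac: float = 0.2,
               sigma_floor_abs: float = 0.2) -> RankedList:
    """Rank genes by the signal-to-noise contrast between phenotypes.

    s = (mu_tumor - mu_normal) / (sigma_tumor + sigma_normal), with each
    class sigma floored at max(sigma_floor_frac * |mu|, sigma_floor_abs) to
    avoid division blow-ups on near-constant genes. Sorted descending; ties
    break by gene id.
    """
    n_neg, n_pos = ds.class_counts()
    if n_neg < 3 or n_pos < 3:
        raise ValueError(f"each class needs >= 3 samples (have {n_neg} vs {n_pos})")
    pos = ds.values[ds.labels == 1]
    neg = ds.values[ds.labels == 0]
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    sd_p = np.maximum.reduce([pos.std(axis=0, ddof=1),
                              sigma_floor_frac * np.abs(mu_p),
                              np.full_like(mu_p, sigma_floor_abs)])
    sd_n = np.maximum.reduce([neg.std(axis=0, ddof=1),
                              sigma_floor_frac * np.abs(mu_n),
                              np.full_like(mu_n, sigma_floor_abs)])
    stats = (mu_p - mu_n) / (sd_p + sd_n)
    order = sorted(range(len(stats)), key=lambda j: (-stats[j], ds.gene_ids[j]))
    return RankedList(gene_ids=[ds.gene_ids[j] for j in order], stats=stats[order])


def _running_sum(stats: np.ndarray, is_hit: np.ndarray, p: float) -> np.ndarray:
    n = len(stats)
    n_hits = int(is_hit.sum())
    if n_hits == 0 or n_hits == n and n == 0:
        raise ValueError("need at least one hit")
    weights = np.abs(stats) ** p
    hit_total = weights[is_hit].sum()
    steps = np.empty(n)
    if hit_total > 0:
        steps[is_hit] = weights[is_hit] / hit_total
    else:  # all member stats zero: equal hit weighting
        steps[is_hit] = 1.0 / n_hits
    if n > n_hits:
        steps[~is_hit] = -1.0 / (n - n_hits)
    return np.cumsum(steps)


def enrichment_score(rl: RankedList, gs: GeneSet, p: float = 1.0) -> EnrichmentResult:
    """Weighted KS running sum, ES and leading edge of one gene set.

    ES is the running-sum value of maximal |deviation|; the leading edge is
    the members at positions <= argmax for positive ES and >= argmin for
    negative ES.
    """
    is_hit = np.array([g in gs.members for g in rl.gene_ids])
    if not is_hit.any():
        raise ValueError(f"gene set {gs.name!r} has no overlap with the ranked list")
    rs = _running_sum(rl.stats, is_hit, p)
    peak = int(np.argmax(np.abs(rs)))
    es = float(rs[peak])
    if es >= 0:
        edge_mask = is_hit & (np.arange(len(rs)) <= peak)
    else:
        edge_mask = is_hit & (np.arange(len(rs)) >= peak)
    leading = tuple(g for g, m in zip(rl.gene_ids, edge_mask) if m)
    return EnrichmentResult(set_name=gs.name, es=es, leading_edge=leading,
                            running_sum=rs)


def _null_es(
    ds: ExpressionDataset | None,
    rl: RankedList,
    gs: GeneSet,
    n_perm: int,
    mode: str,
    rng: np.random.Generator,
    p: float,
) -> np.ndarray:
    size = sum(g in gs.members for g in rl.gene_ids)
    out = np.empty(n_perm)
    if mode == "geneset":
        ids = np.array(rl.gene_ids)
        for i in range(n_perm):
            members = rng.choice(ids, size=size, replace=False)
            fake = GeneSet(name=gs.name, members=frozenset(members))
            out[i] = enrichment_score(rl, fake, p=p).es
    elif mode == "phenotype":
        for i in range(n_perm):
            labels = rng.permutation(ds.labels)
            perm_ds = ExpressionDataset(ds.sample_ids, ds.gene_ids, ds.values, labels)
            out[i] = enrichment_score(rank_genes(perm_ds), gs, p=p).es
    else:
        raise ValueError(f"unknown permutation mode {mode!r}")
    return out


def _normalize(es: float, null: np.ndarray) -> tuple[float, float]:
    """(nes, nom_p) against a null ES sample, sign-stratified."""
    same_sign = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same_sign) == 0:
        return float("nan"), 1.0
    denom = np.abs(same_sign).mean()
    nes = es / denom if denom > 0 else float("nan")
    nom_p = float(np.mean(np.abs(same_sign) >= abs(es)))
    return nes, nom_p


def permutation_significance(
    ds: ExpressionDataset | None,
    rl: RankedList,
    gs: GeneSet,
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int = 0,
    p: float = 1.0,
) -> EnrichmentResult:
    """Fill nes / nom_p (and a single-set fdr_q) by permutation.

    Phenotype mode permutes labels and re-ranks each time (needs >= 7
    samples per class, else it falls back to geneset mode with a warning);
    geneset mode draws random member sets of equal size from the ranked
    list.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100 for stable p-values")
    if mode == "phenotype":
        if ds is None:
            raise ValueError("phenotype mode requires the dataset")
        n_neg, n_pos = ds.class_counts()
        if min(n_neg, n_pos) < 7:
            import warnings
            warnings.warn("fewer than 7 samples per class; switching to "
                          "geneset permutation", stacklevel=2)
            mode = "geneset"
    rng = np.random.default_rng(seed)
    base = enrichment_score(rl, gs, p=p)
    null = _null_es(ds, rl, gs, n_perm, mode, rng, p)
    nes, nom_p = _normalize(base.es, null)
    return replace(base, nes=nes, nom_p=nom_p, fdr_q=nom_p, null_es=null)


def enrichment_report(
    ds: ExpressionDataset | None,
    rl: RankedList,
    sets: list[GeneSet],
    n_perm: int = 1000,
    mode: str = "phenotype",
    seed: int = 0,
    p: float = 1.0,
) -> list[EnrichmentResult]:
    """Run permutation significance for every set and fill pooled FDR q.

    q(set) compares the pooled null NES distribution with the observed NES
    of the evaluated sets, stratified by sign and clipped to [0, 1].
    """
    results = [
        permutation_significance(ds, rl, gs, n_perm=n_perm, mode=mode,
                                 seed=seed + i, p=p)
        for i, gs in enumerate(sets)
    ]
    null_nes = []
    for r in results:
        pos = r.null_es[r.null_es >= 0]
        neg = r.null_es[r.null_es < 0]
        if len(pos):
            null_nes.append(pos / pos.mean())
        if len(neg):
            null_nes.append(neg / np.abs(neg).mean())
    null_nes = np.concatenate(null_nes) if null_nes else np.array([])
    obs = np.array([r.nes for r in results])
    out = []
    for r in results:
        if np.isnan(r.nes) or len(null_nes) == 0:
            out.append(r)
            continue
        if r.nes >= 0:
            p_null = np.mean(null_nes[null_nes >= 0] >= r.nes) if (null_nes >= 0).any() else 0.0
            p_obs = np.mean(obs[obs >= 0] >= r.nes) if (obs >= 0).any() else 1.0
        else:
            p_null = np.mean(null_nes[null_nes < 0] <= r.nes) if (null_nes < 0).any() else 0.0
            p_obs = np.mean(obs[obs < 0] <= r.nes) if (obs < 0).any() else 1.0
        q = min(1.0, float(p_null / p_obs)) if p_obs > 0 else 1.0
        out.append(replace(r, fdr_q=q))
    return out


def select_core_genes(results: list[EnrichmentResult],
                      chosen_sets: list[str]) -> list[str]:
    """Union of leading edges of the chosen sets, first occurrence kept.

    Which sets are "strongly related" to the disease is a human call; this
    function only merges the leading edges of an explicit selection.
    """
    by_name = {r.set_name: r for r in results}
    unknown = [s for s in chosen_sets if s not in by_name]
    if unknown:
        raise ValueError(f"unknown set name(s): {unknown}")
    seen: set[str] = set()
    out: list[str] = []
    for s in chosen_sets:
        for g in by_name[s].leading_edge:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def read_rnk(path) -> RankedList:
    """Read a two-column pre-ranked (.rnk) file: gene_id TAB statistic."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["gene_id", "stat"])
    df = df.sort_values("stat", ascending=False, kind="stable")
    return RankedList(gene_ids=list(df["gene_id"].astype(str)),
                      stats=df["stat"].to_numpy(float))
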