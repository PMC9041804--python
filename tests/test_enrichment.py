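"""Enrichment: running-sum oracle, leading edge, permutation calibration."""

import numpy as np
import pytest

from sdbe.data import ExpressionDataset, GeneSet
from sdbe.enrichment import (RankedList, enrichment_report, enrichment_score,
                             permutation_significance, rank_genes, read_rnk,
                             select_core_genes)


def brute_force_es(gene_ids, stats, members, p=1.0):
    """Independent oracle: walk the list accumulating the weighted KS sum."""
    hits = [g in members for g in gene_ids]
    nr = sum(abs(s) ** p for g, s in zip(gene_ids, stats) if g in members)
    n_miss = len(gene_ids) - sum(hits)
    total, path = 0.0, []
    for g, s in zip(gene_ids, stats):
        if g in members:
            total += (abs(s) ** p) / nr if nr > 0 else 1.0 / sum(hits)
        else:
            total -= 1.0 / n_miss
        path.append(total)
    best_idx = 0
    for i, v in enumerate(path):
        if abs(v) > abs(path[best_idx]):
            best_idx = i
    return path[best_idx], path


def _random_ranked(rng, n=50):
    stats = np.sort(rng.normal(0, 1.5, n))[::-1]
    return RankedList([f"g{j}" for j in range(n)], stats)


def test_es_matches_brute_force_oracle():
    rng = np.random.default_rng(123)
    for _ in range(50):
        rl = _random_ranked(rng)
        members = frozenset(rng.choice(rl.gene_ids, size=6, replace=False))
        gs = GeneSet("S", members=members)
        res = enrichment_score(rl, gs)
        es_oracle, path = brute_force_es(rl.gene_ids, rl.stats, members)
        assert res.es == pytest.approx(es_oracle, abs=1e-12)
        np.testing.assert_allclose(res.running_sum, path, atol=1e-12)


def test_leading_edge_positions_follow_argmax_rule():
    rng = np.random.default_rng(5)
    for _ in range(20):
        rl = _random_ranked(rng, n=40)
        members = frozenset(rng.choice(rl.gene_ids, size=5, replace=False))
        res = enrichment_score(rl, GeneSet("S", members=members))
        peak = int(np.argmax(np.abs(res.running_sum)))
        pos = {g: i for i, g in enumerate(rl.gene_ids)}
        if res.es >= 0:
            expect = [g for g in rl.gene_ids if g in members and pos[g] <= peak]
        else:
            expect = [g for g in rl.gene_ids if g in members and pos[g] >= peak]
        assert list(res.leading_edge) == expect
        assert set(res.leading_edge) <= members


def test_es_limit_behaviors():
    rl = RankedList([f"g{j}" for j in range(30)],
                    np.linspace(3, -3, 30))
    top = GeneSet("TOP", members=frozenset(["g0", "g1", "g2"]))
    assert enrichment_score(rl, top).es > 0.9
    whole = GeneSet("ALL", members=frozenset(rl.gene_ids))
    res = enrichment_score(rl, whole)
    assert res.running_sum[-1] == pytest.approx(1.0)
    with pytest.raises(ValueError, match="MISSING"):
        enrichment_score(rl, GeneSet("MISSING", members=frozenset(["zzz"])))


def test_unweighted_running_sum_ends_at_zero():
    rng = np.random.default_rng(2)
    rl = _random_ranked(rng, n=25)
    gs = GeneSet("S", members=frozenset(rng.choice(rl.gene_ids, 7, replace=False)))
    res = enrichment_score(rl, gs, p=0.0)
    assert res.running_sum[-1] == pytest.approx(0.0, abs=1e-9)


def test_signal_to_noise_ranking_hand_fixture():
    """3v3 fixture with round numbers: stat matches hand arithmetic."""
    # gene A: tumor {3,4,5} mu=4 sd=1; normal {1,2,3} mu=2 sd=1
    #   floors: max(1, .2*4, .2)=1 each -> s = 2/2 = 1
    # gene B: tumor {10,10,10} sd=0 -> floor .2*10=2; normal {5,5,5} floor 1
    #   s = 5/3
    values = np.array([
        [1, 5], [2, 5], [3, 5],      # normals
        [3, 10], [4, 10], [5, 10],   # tumors
    ], dtype=float)
    ds = ExpressionDataset([f"s{i}" for i in range(6)], ["A", "B"],
                           values, [0, 0, 0, 1, 1, 1])
    rl = rank_genes(ds)
    assert rl.gene_ids == ("B", "A")
    assert rl.stats[0] == pytest.approx(5 / 3)
    assert rl.stats[1] == pytest.approx(1.0)
    # direction and noise monotonicity
    assert rl.stats[0] > 0
    with pytest.raises(ValueError):
        rank_genes(ExpressionDataset(["a", "b"], ["g"], [[1], [2]], [0, 1]))


def test_permutation_deterministic_and_powered():
    rng = np.random.default_rng(0)
    n = 60
    labels = np.r_[np.zeros(30, dtype=int), np.ones(30, dtype=int)]
    vals = rng.uniform(0, 1, (n, 40))
    vals[labels == 1, :5] += 1.2  # strong tumor-up block
    ds = ExpressionDataset([f"s{i}" for i in range(n)],
                           [f"g{j}" for j in range(40)], vals, labels)
    rl = rank_genes(ds)
    gs = GeneSet("UP", members=frozenset(f"g{j}" for j in range(5)))
    a = permutation_significance(ds, rl, gs, n_perm=150, mode="geneset", seed=7)
    b = permutation_significance(ds, rl, gs, n_perm=150, mode="geneset", seed=7)
    assert (a.nes, a.nom_p, a.fdr_q) == (b.nes, b.nom_p, b.fdr_q)
    assert a.es > 0.5 and a.nom_p <= 0.05


def test_small_cohort_falls_back_to_geneset_mode():
    rng = np.random.default_rng(1)
    ds = ExpressionDataset([f"s{i}" for i in range(8)],
                           [f"g{j}" for j in range(20)],
                           rng.uniform(0, 1, (8, 20)),
                           [0, 0, 0, 0, 1, 1, 1, 1])
    rl = rank_genes(ds)
    gs = GeneSet("S", members=frozenset(["g0", "g1", "g2"]))
    with pytest.warns(UserWarning, match="geneset"):
        permutation_significance(ds, rl, gs, n_perm=100, mode="phenotype", seed=0)


def test_select_core_genes_union_dedup():
    from sdbe.enrichment import EnrichmentResult
    mk = lambda name, edge: EnrichmentResult(
        set_name=name, es=0.5, leading_edge=tuple(edge),
        running_sum=np.zeros(1))
    results = [mk("S1", ["a", "b", "c"]), mk("S2", ["b", "c", "d"])]
    assert select_core_genes(results, ["S1", "S2"]) == ["a", "b", "c", "d"]
    assert select_core_genes(results, ["S2"]) == ["b", "c", "d"]
    with pytest.raises(ValueError, match="NOPE"):
        select_core_genes(results, ["NOPE"])
    # 72 leading-edge slots with 12 repeats collapse to 60 unique ids
    edges = [[f"u{j}" for j in range(20)],
             [f"d{j}" for j in range(17)],
             [f"d{j}" for j in range(6)] + [f"e{j}" for j in range(5)],
             [f"d{j}" for j in range(6, 12)] + [f"f{j}" for j in range(18)]]
    results = [mk(f"P{i}", e) for i, e in enumerate(edges)]
    assert sum(len(e) for e in edges) == 72
    merged = select_core_genes(results, [f"P{i}" for i in range(4)])
    assert len(merged) == 60


def test_enrichment_report_fills_fdr(tmp_path):
    rng = np.random.default_rng(3)
    rl = _random_ranked(rng, n=60)
    sets = [GeneSet(f"S{i}", members=frozenset(
        rng.choice(rl.gene_ids, 8, replace=False))) for i in range(3)]
    results = enrichment_report(None, rl, sets, n_perm=100, mode="geneset", seed=0)
    for r in results:
        assert 0.0 <= r.fdr_q <= 1.0
        assert not np.isnan(r.nes)
    # RNK round trip
    p = tmp_path / "x.rnk"
    p.write_text("\n".join(f"{g}\t{s}" for g, s in
                           zip(rl.gene_ids, rl.stats)) + "\n")
    back = read_rnk(p)
    assert back.gene_ids == rl.gene_ids
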