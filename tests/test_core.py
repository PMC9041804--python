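"""SDBE stage primitives, reference-iteration equivalence, selection rule."""

import numpy as np
import pytest

from sdbe.core import (GeneOrdering, IterationRecord, MetricTrace, SDBE,
                       advance_st, diff_list, run_sdbe, select_min_gene_set,
                       split_sort_merge, stage1_importance_elimination,
                       stage7_trace)
from sdbe.crossval import ClassifierSpec


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def test_diff_list_examples():
    np.testing.assert_allclose(diff_list(MetricTrace("mcc", [0.80, 0.85, 0.84])),
                               [0.05, -0.01])
    np.testing.assert_allclose(diff_list(np.full(5, 0.7)), np.zeros(4))
    assert len(diff_list(np.arange(7.0))) == 6
    with pytest.raises(ValueError):
        diff_list(MetricTrace("mcc", [0.5]))


@pytest.mark.parametrize("dm,st,expected", [
    ([0.02, -0.01, 0.03], 0, 1),
    ([0.1, 0.0, 0.2], 0, 3),       # no negative element -> end of list
    ([-0.5, 0.1], 0, 0),
    ([-0.5, -0.1], 1, 1),          # search starts at st
    ([0.1, 0.1], 2, 2),            # st at end stays
])
def test_advance_st(dm, st, expected):
    assert advance_st(np.array(dm), st) == expected


def test_split_sort_merge_worked_example_both_orientations():
    """dm (0.1, -0.2, 0.3) on [g0,g1,g2,g3] with ST=1: part1=[g1],
    part2 sorted desc=[g3,g2]."""
    o = GeneOrdering(["g0", "g1", "g2", "g3"])
    dm = np.array([0.1, -0.2, 0.3])
    st = advance_st(dm, 0)
    assert st == 1
    # default: anchor first, parts kept in descending-difference order
    assert split_sort_merge(o, dm, st).genes == ("g0", "g1", "g3", "g2")
    # word-for-word append-then-reverse reading
    assert split_sort_merge(o, dm, st, orientation="reverse").genes == \
        ("g0", "g2", "g3", "g1")


def test_split_sort_merge_ties_and_degenerate():
    o = GeneOrdering(["g0", "g1", "g2", "g3"])
    equal = np.zeros(3)
    # stable sort: equal differences preserve current order
    assert split_sort_merge(o, equal, 1).genes == ("g0", "g1", "g2", "g3")
    assert split_sort_merge(o, equal, 1, orientation="reverse").genes == \
        ("g0", "g3", "g2", "g1")
    two = GeneOrdering(["g0", "g1"])
    assert split_sort_merge(two, np.array([0.4]), 0).genes == ("g0", "g1")
    with pytest.raises(ValueError):
        split_sort_merge(o, np.zeros(2), 0)  # misaligned
    with pytest.raises(ValueError):
        split_sort_merge(o, equal, 4)


# ---------------------------------------------------------------------------
# elimination stages with the deterministic stub
# ---------------------------------------------------------------------------

def test_stage1_ordering_and_trace_alignment(stub_world):
    genes = list(stub_world.family_of)
    rec = stage1_importance_elimination(stub_world, genes, seed=0)
    assert sorted(rec.ordering.genes) == sorted(genes)   # permutation
    # anchor = highest stub importance
    best = max(genes, key=lambda g: stub_world.importance_of[g])
    assert rec.ordering.anchor == best
    # trace[i] must equal the stub metric of the prefix {g_0..g_i}
    for i in range(len(genes)):
        prefix = list(rec.ordering.genes[:i + 1])
        assert rec.traces["mcc"].values[i] == pytest.approx(
            stub_world.metric(prefix))
    # descending stub importance along the whole ordering
    imps = [stub_world.importance_of[g] for g in rec.ordering.genes]
    assert imps == sorted(imps, reverse=True)


def test_stage1_single_gene_degenerate(stub_world):
    rec = stage1_importance_elimination(stub_world, ["F0_0"], seed=0)
    assert rec.ordering.genes == ("F0_0",)
    assert len(rec.traces["mcc"]) == 1
    with pytest.raises(ValueError):
        diff_list(rec.traces["mcc"])


def test_stage7_trace_matches_prefix_metrics(stub_world):
    ordering = GeneOrdering(["F0_0", "N0", "F1_0", "N1"])
    traces = stage7_trace(stub_world, ordering, seed=0)
    assert len(traces["mcc"]) == 4
    for i in range(4):
        assert traces["mcc"].values[i] == pytest.approx(
            stub_world.metric(list(ordering.genes[:i + 1])))
    # prefix-1 value equals evaluating the anchor alone
    assert traces["mcc"].values[0] == pytest.approx(
        stub_world.metric(["F0_0"]))


# ---------------------------------------------------------------------------
# one full iteration vs an independently coded reference (stages 3-6)
# ---------------------------------------------------------------------------

def reference_iteration(genes, metric_of, st, orientation):
    """Hand-coded stages 3-6, written against the prose, not the library:
    compute prefix metrics, difference them, advance the split index to the
    first negative at/after st, split (st element into the right part),
    sort both parts descending by difference keeping ties in place, map to
    genes, and put the anchor back in front."""
    m = [metric_of(genes[:i + 1]) for i in range(len(genes))]
    dm = [m[i] - m[i - 1] for i in range(1, len(m))]
    j = st
    while j < len(dm) and dm[j] >= 0:
        j += 1
    new_st = j
    pairs = list(zip(dm, genes[1:]))
    left = [pairs[i] for i in range(new_st)]
    right = [pairs[i] for i in range(new_st, len(pairs))]
    key = lambda p: -p[0]
    left = [g for _, g in sorted(left, key=key)]
    right = [g for _, g in sorted(right, key=key)]
    if orientation == "rotate":
        return [genes[0]] + left + right, new_st
    out = left + right + [genes[0]]
    out.reverse()
    return out, new_st


@pytest.mark.parametrize("orientation", ["rotate", "reverse"])
@pytest.mark.parametrize("n_genes", [2, 3, 4, 5])
def test_full_iteration_equals_reference(orientation, n_genes, stub_world):
    rng = np.random.default_rng(n_genes * 7 + (orientation == "rotate"))
    pool = list(stub_world.family_of)
    for _ in range(25):
        genes = list(rng.choice(pool, size=n_genes, replace=False))
        st0 = int(rng.integers(0, n_genes))  # any legal starting split
        traces = stage7_trace(stub_world, GeneOrdering(genes), seed=0)
        dm = diff_list(traces["mcc"])
        st = advance_st(dm, min(st0, len(dm)))
        got = split_sort_merge(GeneOrdering(genes), dm, st,
                               orientation=orientation)
        want, want_st = reference_iteration(
            genes, stub_world.metric, min(st0, len(dm)), orientation)
        assert st == want_st
        assert list(got.genes) == want


# ---------------------------------------------------------------------------
# full runs on the stub: invariants and determinism
# ---------------------------------------------------------------------------

def test_run_sdbe_history_and_invariants(stub_world):
    genes = list(stub_world.family_of)
    history = run_sdbe(genes, "mcc", stub_world, n_iterations=5, seed=0)
    assert len(history) == 6  # stage-1 record + 5 iterations
    anchor = history[0].ordering.anchor
    sts = []
    for rec in history:
        assert sorted(rec.ordering.genes) == sorted(genes)  # permutation
        assert rec.ordering.anchor == anchor                # g0 fixed
        if rec.st is not None:
            sts.append(rec.st)
    assert all(b >= a for a, b in zip(sts, sts[1:]))        # ST monotone
    # deterministic stub -> identical rerun
    again = run_sdbe(genes, "mcc", stub_world, n_iterations=5, seed=0)
    assert [r.ordering.genes for r in again] == \
        [r.ordering.genes for r in history]


def test_run_sdbe_concentrates_stub_families_left(stub_world):
    genes = list(stub_world.family_of)
    history = run_sdbe(genes, "mcc", stub_world, n_iterations=6, seed=0)
    final = history[-1].ordering.genes
    pos = {g: i for i, g in enumerate(final)}
    fam_best = [min(pos[f"F{f}_{c}"] for c in range(2)) for f in range(3)]
    assert max(fam_best) <= 3  # one member of each family in the left 4


def test_run_sdbe_validates_inputs(stub_world):
    with pytest.raises(ValueError):
        run_sdbe(["a"], "mcc", stub_world)
    with pytest.raises(ValueError):
        run_sdbe(["a", "b"], "accuracy", stub_world)
    with pytest.raises(ValueError):
        run_sdbe(["a", "b"], "mcc", stub_world, n_iterations=0)


# ---------------------------------------------------------------------------
# smallest-gene-set rule
# ---------------------------------------------------------------------------

def _hist_from_trace(vals, genes=None):
    genes = genes or [f"g{i}" for i in range(len(vals))]
    return [IterationRecord(GeneOrdering(genes),
                            {"mcc": MetricTrace("mcc", vals)}, 0)]


def test_selection_tolerance_rule():
    sel = select_min_gene_set(_hist_from_trace([0.50, 0.95, 0.953, 0.951]),
                              "mcc", tolerance=0.005)
    assert len(sel.genes) == 2  # 0.95 is within 0.005 of the 0.953 max


def test_selection_edge_traces():
    inc = select_min_gene_set(_hist_from_trace([0.1, 0.2, 0.3, 0.4]), "mcc",
                              tolerance=0.0)
    assert len(inc.genes) == 4  # strictly increasing, zero tolerance
    flat = select_min_gene_set(_hist_from_trace([0.7, 0.7, 0.7]), "mcc")
    assert len(flat.genes) == 1


def test_selection_requires_stability_across_window():
    genes_a = ["x", "y", "z"]
    genes_b = ["x", "z", "y"]  # same 2-prefix set? no: {x,y} vs {x,z}
    trace = MetricTrace("mcc", [0.9, 0.91, 0.2])
    hist = [
        IterationRecord(GeneOrdering(genes_b), {"mcc": trace}, 0),
        IterationRecord(GeneOrdering(genes_a), {"mcc": trace}, 0),
        IterationRecord(GeneOrdering(genes_a), {"mcc": trace}, 0),
    ]
    sel = select_min_gene_set(hist, "mcc", tolerance=0.02, stability_window=3)
    # 1-prefix {x} is stable everywhere -> chosen over the unstable 2-prefix
    assert sel.genes == ("x",) and sel.stable
    sel2 = select_min_gene_set(hist, "mcc", tolerance=0.0, stability_window=3)
    assert sel2.genes == ("x", "y") and not sel2.stable


# ---------------------------------------------------------------------------
# the Model/Results surface on a real (tiny) dataset
# ---------------------------------------------------------------------------

def test_sdbe_model_on_separable_data(separable_ds):
    model = SDBE(separable_ds, metric_object="mcc",
                 model=ClassifierSpec("rf", {"n_estimators": 15}),
                 n_iterations=2, k=4)
    res = model.fit(seed=0)
    assert res.anchor == "SEP"
    assert sorted(res.final_ordering.genes) == sorted(separable_ds.gene_ids)
    sel = res.selection()
    assert "SEP" in sel.genes
    assert res.trace("mcc").values[0] == 1.0  # SEP alone is perfect
    text = res.summary()
    assert "SEP" in text and "mcc" in text
    # determinism of the whole fit
    res2 = model.fit(seed=0)
    assert [r.ordering.genes for r in res2.history] == \
        [r.ordering.genes for r in res.history]


def test_sdbe_results_to_dir(tmp_path, separable_ds):
    model = SDBE(separable_ds, model=ClassifierSpec("rf", {"n_estimators": 10}),
                 n_iterations=1, k=4)
    res = model.fit(seed=1)
    res.to_dir(tmp_path / "run")
    assert (tmp_path / "run" / "manifest.json").exists()
    assert (tmp_path / "run" / "ordering_stage1.tsv").exists()
    assert (tmp_path / "run" / "selected_genes.txt").read_text().strip()
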