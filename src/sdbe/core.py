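"""Sort Difference Backward Elimination (SDBE).

SDBE reorders a gene list so that the smallest set of relevant genes can be
read off its left end while redundant genes accumulate on the right. It
never discards a gene — every iteration emits a permutation of the input.

The machinery, in stages:

1. *Importance elimination.* Backward elimination driven by random-forest
   variable importance: cross-validate on the current gene set, delete the
   least-important gene, repeat down to a single gene. Collecting the
   deletions in reverse order yields the initial ordering
   ``G = [g_0, ..., g_n]`` (descending importance) together with metric
   traces aligned so ``trace[i]`` is the CV metric of the prefix
   ``{g_0..g_i}``. The anchor ``g_0`` — the lone survivor — keeps position
   0 forever after.
2. Choose the *metric object* (MCC or ROC AUC) and set the split index
   ``ST = 0``.
3. *Differences.* ``dm_i = m_i - m_{i-1}`` for ``i = 1..n``: the change in
   the metric caused by adding gene ``g_i`` to the prefix (equivalently,
   minus the change caused by deleting it). A near-zero ``dm_i`` marks
   ``g_i`` as redundant given the genes to its left.
4. *Advance ST* forward to the first difference below zero at or after the
   current ST (end of list if none) — the left-of-ST region is the part
   that has stopped hurting the metric.
5./6. *Split, sort, merge.* Split the difference list at ST (the ST element
   goes to part2), sort each part descending by difference (stable), map
   differences back to their genes, merge, and restore ``g_0`` to position
   0. Genes whose addition helps drift left; redundant ones drift right.
   Two orientations of the final merge are supported (see
   :func:`split_sort_merge`); the default keeps each part in descending
   difference order after the anchor, which is what actually concentrates
   relevant genes on the left.
7. *Re-trace.* Backward elimination over the new, fixed order with the
   chosen classifier (any registered model — importances are not needed
   here) to obtain fresh traces; loop back to stage 3 until the configured
   iteration count is reached.
8. *Read off the answer:* the shortest stable prefix whose metric is within
   tolerance of the best prefix metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from .crossval import ClassifierSpec, kfold_cv
from .data import ExpressionDataset, write_ordering, write_run_manifest
from .metrics import METRIC_NAMES, MetricVector, metric_vector

__all__ = [
    "GeneOrdering", "MetricTrace", "IterationRecord", "SelectionResult",
    "SDBE", "SDBEResults", "CVEvaluator",
    "diff_list", "advance_st", "split_sort_merge",
    "stage1_importance_elimination", "stage7_trace", "run_sdbe",
    "select_min_gene_set",
]

# An evaluator maps a gene subset to (MetricVector, importances-or-None),
# importances aligned to the subset order. The CV-backed one below is the
# production implementation; tests may plug in deterministic stubs.
Evaluator = Callable[[Sequence[str], int], tuple[MetricVector, np.ndarray | None]]


@dataclass(frozen=True)
class GeneOrdering:
    """An ordered gene list g_0..g_n produced by one SDBE stage."""

    genes: tuple[str, ...]
    iteration: int = 0

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ordering contains duplicate genes")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def anchor(self) -> str:
        return self.genes[0]


@dataclass(frozen=True)
class MetricTrace:
    """Per-prefix metric values: values[i] = metric of prefix {g_0..g_i}."""

    metric_name: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class IterationRecord:
    """State after one SDBE stage: ordering, aligned traces, split index."""

    ordering: GeneOrdering
    traces: Mapping[str, MetricTrace]
    st: int | None  # None for the stage-1 record (ST not yet defined)


@dataclass(frozen=True)
class SelectionResult:
    """Output of the smallest-gene-set rule."""

    genes: tuple[str, ...]
    metric_value: float
    stable: bool


class CVEvaluator:
    """Evaluate gene subsets by k-fold CV on a fixed dataset and classifier."""

    def __init__(self, ds: ExpressionDataset, spec: ClassifierSpec,
                 k: int = 10, stratified: bool = True):
        self.ds = ds
        self.spec = spec
        self.k = k
        self.stratified = stratified

    def __call__(self, genes: Sequence[str], seed: int):
        sub = self.ds.subset_genes(list(genes))
        cv = kfold_cv(sub, self.spec, k=self.k, seed=seed,
                      stratified=self.stratified)
        mv = metric_vector(cv.y_true, cv.y_pred, cv.scores)
        return mv, cv.mean_importances


# ---------------------------------------------------------------------------
# Stage primitives
# ---------------------------------------------------------------------------

def diff_list(trace: MetricTrace | np.ndarray) -> np.ndarray:
    """dm_i = m_i - m_{i-1} for i = 1..n (length = trace length - 1)."""
    values = trace.values if isinstance(trace, MetricTrace) else np.asarray(trace, float)
    if len(values) < 2:
        raise ValueError("trace must have length >= 2 to form differences")
    return np.diff(values)


def advance_st(dm: np.ndarray, st: int) -> int:
    """Smallest index j >= st with dm_j < 0; len(dm) if no such element."""
    dm = np.asarray(dm, dtype=float)
    if not 0 <= st <= len(dm):
        raise ValueError(f"st={st} out of range 0..{len(dm)}")
    neg = np.nonzero(dm[st:] < 0)[0]
    return int(st + neg[0]) if len(neg) else len(dm)


def split_sort_merge(ordering: GeneOrdering, dm: np.ndarray, st: int,
                     orientation: str = "rotate") -> GeneOrdering:
    """Stages 5-6: split the difference list at ST, sort each part
    descending by difference (stable), map differences back to their genes,
    merge, and put the anchor back at position 0.

    ``orientation`` fixes an ambiguity in how the anchor returns to the
    front:

    * ``"rotate"`` (default): new order = [g_0] + part1 + part2, each part
      in descending difference order. Genes whose addition raised the
      metric move toward the anchor; this is the orientation under which
      relevant genes assemble on the left and the pre-ST region acts as the
      stabilizing left part.
    * ``"reverse"``: append g_0 to the merged list and reverse the whole
      list — the word-for-word reading of the procedure. The anchor still
      lands first, but each part ends up in ascending order after it and
      part2 precedes part1.
    """
    dm = np.asarray(dm, dtype=float)
    genes = ordering.genes
    if len(dm) != len(genes) - 1:
        raise ValueError(f"dm length {len(dm)} misaligned with ordering of "
                         f"{len(genes)} genes")
    if not 0 <= st <= len(dm):
        raise ValueError(f"st={st} out of range 0..{len(dm)}")
    if orientation not in ("rotate", "reverse"):
        raise ValueError(f"unknown orientation {orientation!r}")
    tail = list(genes[1:])  # genes g_1..g_n aligned with dm_1..dm_n

    def sort_desc(idx: list[int]) -> list[int]:
        # stable descending: ties keep current order
        return sorted(idx, key=lambda j: -dm[j])

    part1 = [tail[j] for j in sort_desc(list(range(0, st)))]
    part2 = [tail[j] for j in sort_desc(list(range(st, len(dm))))]
    if orientation == "rotate":
        ng = [genes[0]] + part1 + part2
    else:
        ng = part1 + part2 + [genes[0]]
        ng.reverse()
    return GeneOrdering(genes=ng, iteration=ordering.iteration + 1)


# ---------------------------------------------------------------------------
# Elimination stages (evaluator-driven)
# ---------------------------------------------------------------------------

def _least_important(genes: list[str], importances: np.ndarray) -> int:
    """Index of the gene to delete: minimum importance, ties broken so the
    lexicographically last gene id goes first (mirrors the descending
    importance sort with gene-id tie-break)."""
    order = sorted(range(len(genes)),
                   key=lambda j: (-importances[j], genes[j]))
    return order[-1]


def _records_to_traces(records: list[MetricVector]) -> dict[str, MetricTrace]:
    """Reverse deletion-ordered records into prefix-aligned traces."""
    return {
        name: MetricTrace(name, [getattr(mv, name) for mv in reversed(records)])
        for name in METRIC_NAMES
    }


def stage1_importance_elimination(
    evaluator: Evaluator,
    genes: Sequence[str],
    seed: int = 0,
) -> IterationRecord:
    """Importance-driven backward elimination producing the initial ordering.

    Importances are recomputed on every loop (dynamic re-ranking); the
    deleted genes, collected in reverse, plus the final survivor give the
    descending-importance ordering with the anchor g_0 first.
    """
    current = list(genes)
    if len(current) < 1:
        raise ValueError("need at least one gene")
    deleted: list[str] = []
    records: list[MetricVector] = []
    while len(current) > 1:
        mv, imp = evaluator(current, seed)
        if imp is None:
            raise ValueError("stage-1 evaluator must supply importances")
        records.append(mv)
        drop = _least_important(current, np.asarray(imp, dtype=float))
        deleted.append(current.pop(drop))
    mv, _ = evaluator(current, seed)
    records.append(mv)  # m_0: the single-gene model
    ordering = GeneOrdering(genes=[current[0], *reversed(deleted)], iteration=0)
    return IterationRecord(ordering=ordering, traces=_records_to_traces(records),
                           st=None)


def stage7_trace(
    evaluator: Evaluator,
    ordering: GeneOrdering,
    seed: int = 0,
) -> dict[str, MetricTrace]:
    """Backward elimination over a fixed order: CV metrics on every prefix."""
    records: list[MetricVector] = []
    for i in range(len(ordering) - 1, -1, -1):
        mv, _ = evaluator(ordering.genes[:i + 1], seed)
        records.append(mv)
    records.reverse()  # deletion order is n..0; reverse to prefix order 0..n
    return {
        name: MetricTrace(name, [getattr(mv, name) for mv in records])
        for name in METRIC_NAMES
    }


def run_sdbe(
    genes: Sequence[str],
    metric_object: str,
    evaluator: Evaluator,
    importance_evaluator: Evaluator | None = None,
    n_iterations: int = 19,
    seed: int = 0,
    strict_stage3: bool = False,
    stop_when_stable: bool = False,
    stage1_record: IterationRecord | None = None,
    merge_orientation: str = "rotate",
) -> list[IterationRecord]:
    """Run the full SDBE loop and return the per-iteration history.

    ``evaluator`` drives the stage-7 traces (any classifier);
    ``importance_evaluator`` (defaults to ``evaluator``) drives stage 1 and
    must supply importances. ``strict_stage3`` recomputes the difference
    trace with the importance evaluator each iteration instead of reusing
    the stage-7 trace of the chosen classifier. A precomputed
    ``stage1_record`` may be passed in — stage 1 depends only on the
    importance model, so one record can seed many metric/classifier
    combinations.
    """
    if metric_object not in ("mcc", "roc_auc"):
        raise ValueError("metric_object must be 'mcc' or 'roc_auc'")
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if len(genes) < 2:
        raise ValueError("SDBE needs at least 2 genes")
    imp_eval = importance_evaluator or evaluator

    if stage1_record is not None:
        if set(stage1_record.ordering.genes) != set(genes):
            raise ValueError("stage1_record does not cover the requested genes")
        first = stage1_record
    else:
        first = stage1_importance_elimination(imp_eval, genes, seed=seed)
    history = [first]
    st = 0
    ordering, traces = first.ordering, first.traces
    for _ in range(n_iterations):
        if strict_stage3:
            diff_traces = stage7_trace(imp_eval, ordering, seed=seed)
        else:
            diff_traces = traces
        dm = diff_list(diff_traces[metric_object])
        st = advance_st(dm, st)
        new_ordering = split_sort_merge(ordering, dm, st,
                                        orientation=merge_orientation)
        traces = stage7_trace(evaluator, new_ordering, seed=seed)
        history.append(IterationRecord(ordering=new_ordering, traces=traces, st=st))
        stable = new_ordering.genes == ordering.genes
        ordering = new_ordering
        if stop_when_stable and stable:
            break
    return history


def select_min_gene_set(
    history: list[IterationRecord],
    metric_object: str,
    tolerance: float = 0.005,
    stability_window: int = 3,
) -> SelectionResult:
    """Smallest stable prefix within tolerance of the best prefix metric.

    Candidates are prefix lengths whose final-iteration metric is at least
    (max over prefixes - tolerance); a candidate is *stable* when its gene
    set is identical across the last ``stability_window`` orderings. The
    shortest stable candidate wins; if none is stable, the shortest
    candidate is returned flagged unstable.
    """
    if not history:
        raise ValueError("empty history")
    final = history[-1]
    values = final.traces[metric_object].values
    best = values.max()
    candidates = [i + 1 for i in range(len(values)) if values[i] >= best - tolerance]
    window = history[-stability_window:]
    for length in sorted(candidates):
        prefix = set(final.ordering.genes[:length])
        if all(set(rec.ordering.genes[:length]) == prefix for rec in window):
            return SelectionResult(genes=final.ordering.genes[:length],
                                   metric_value=float(values[length - 1]),
                                   stable=True)
    length = min(candidates)
    return SelectionResult(genes=final.ordering.genes[:length],
                           metric_value=float(values[length - 1]),
                           stable=False)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SDBE:
    """Smallest-relevant-gene-set selection by Sort Difference Backward
    Elimination on a labeled expression dataset.

    Parameters
    ----------
    dataset : ExpressionDataset
        Samples x genes matrix with binary phenotype labels (1 = tumor).
    genes : sequence of str, optional
        Genes to run on (default: all genes of the dataset).
    metric_object : {"mcc", "roc_auc"}
        The metric whose elimination differences drive the sort.
    model : ClassifierSpec
        Classifier for the per-iteration traces (stage 7). Any registered
        model; MCC + random forest is the recommended pairing for
        imbalanced cohorts.
    importance_model : ClassifierSpec, optional
        Importance-capable model for stage 1; defaults to ``model`` when
        that exposes importances, else a random forest with the same
        hyperparameters where applicable.
    n_iterations : int
        Number of sort/re-trace iterations after stage 1.
    k : int
        Cross-validation folds.

    Examples
    --------
    >>> model = SDBE(ds, metric_object="mcc", model=ClassifierSpec("rf"),
    ...              n_iterations=6)
    >>> res = model.fit(seed=7)
    >>> res.selection().genes
    ('GENE_R0', 'GENE_R1', 'GENE_R2')
    """

    def __init__(
        self,
        dataset: ExpressionDataset,
        genes: Sequence[str] | None = None,
        metric_object: str = "mcc",
        model: ClassifierSpec | None = None,
        importance_model: ClassifierSpec | None = None,
        n_iterations: int = 19,
        k: int = 10,
        stratified: bool = True,
        strict_stage3: bool = False,
        stop_when_stable: bool = False,
        merge_orientation: str = "rotate",
    ):
        if metric_object not in ("mcc", "roc_auc"):
            raise ValueError("metric_object must be 'mcc' or 'roc_auc'")
        self.dataset = dataset
        self.genes = tuple(genes) if genes is not None else dataset.gene_ids
        dataset.gene_index(self.genes)  # validate early
        self.metric_object = metric_object
        self.model = model or ClassifierSpec("rf")
        if importance_model is None:
            if self.model.has_importances:
                importance_model = self.model
            else:
                importance_model = ClassifierSpec(
                    "rf", hyperparameters={
                        k_: v for k_, v in self.model.hyperparameters.items()
                        if k_ == "n_estimators"})
        self.importance_model = importance_model
        self.n_iterations = n_iterations
        self.k = k
        self.stratified = stratified
        self.strict_stage3 = strict_stage3
        self.stop_when_stable = stop_when_stable
        if merge_orientation not in ("rotate", "reverse"):
            raise ValueError("merge_orientation must be 'rotate' or 'reverse'")
        self.merge_orientation = merge_orientation

    @classmethod
    def from_dataframe(cls, frame, labels, **kwargs) -> "SDBE":
        """Build from a samples x genes DataFrame plus per-sample labels."""
        return cls(ExpressionDataset.from_frame(frame, labels), **kwargs)

    def _evaluators(self) -> tuple[CVEvaluator, CVEvaluator]:
        ev = CVEvaluator(self.dataset, self.model, k=self.k,
                         stratified=self.stratified)
        imp = CVEvaluator(self.dataset, self.importance_model, k=self.k,
                          stratified=self.stratified)
        return ev, imp

    def fit(self, seed: int = 0,
            stage1_record: IterationRecord | None = None) -> "SDBEResults":
        """Run stage 1 plus ``n_iterations`` sort/re-trace iterations."""
        ev, imp = self._evaluators()
        history = run_sdbe(
            self.genes, self.metric_object, ev, importance_evaluator=imp,
            n_iterations=self.n_iterations, seed=seed,
            strict_stage3=self.strict_stage3,
            stop_when_stable=self.stop_when_stable,
            stage1_record=stage1_record,
            merge_orientation=self.merge_orientation,
        )
        return SDBEResults(model=self, history=history, seed=seed)

    def stage1(self, seed: int = 0) -> IterationRecord:
        """Run only the importance-elimination stage (reusable across fits)."""
        _, imp = self._evaluators()
        return stage1_importance_elimination(imp, self.genes, seed=seed)


@dataclass
class SDBEResults:
    """Fitted SDBE run: per-iteration orderings, traces and the selection."""

    model: SDBE
    history: list[IterationRecord]
    seed: int

    @property
    def final_ordering(self) -> GeneOrdering:
        return self.history[-1].ordering

    @property
    def anchor(self) -> str:
        return self.history[0].ordering.anchor

    @property
    def st_path(self) -> list[int]:
        """The split index after each iteration (stage-1 entry excluded)."""
        return [rec.st for rec in self.history[1:]]

    def trace(self, metric: str | None = None, iteration: int = -1) -> MetricTrace:
        return self.history[iteration].traces[metric or self.model.metric_object]

    def selection(self, tolerance: float = 0.005,
                  stability_window: int = 3) -> SelectionResult:
        """Smallest stable gene prefix within tolerance of the best metric."""
        return select_min_gene_set(self.history, self.model.metric_object,
                                   tolerance=tolerance,
                                   stability_window=stability_window)

    def summary(self, tolerance: float = 0.005) -> str:
        """Human-readable run report."""
        sel = self.selection(tolerance=tolerance)
        final = self.history[-1]
        lines = [
            "Sort Difference Backward Elimination",
            "=" * 52,
            f"genes in play:        {len(self.model.genes)}",
            f"metric object:        {self.model.metric_object}",
            f"classifier:           {self.model.model.name}"
            f" (k={self.model.k}-fold CV)",
            f"iterations:           {len(self.history) - 1}",
            f"seed:                 {self.seed}",
            f"anchor gene g0:       {self.anchor}",
            f"ST path:              {self.st_path}",
            "-" * 52,
            f"selected genes ({len(sel.genes)}, "
            f"{'stable' if sel.stable else 'UNSTABLE'}): "
            + ", ".join(sel.genes),
            f"{self.model.metric_object} at selection: {sel.metric_value:.4f}",
            "-" * 52,
            "final ordering (left = most relevant):",
        ]
        tr = final.traces[self.model.metric_object].values
        for i, g in enumerate(final.ordering.genes[:min(10, len(tr))]):
            lines.append(f"  {i:3d}  {g:<20s} {self.model.metric_object}"
                         f"[prefix]={tr[i]:.4f}")
        if len(tr) > 10:
            lines.append(f"  ... {len(tr) - 10} more genes to the right")
        return "\n".join(lines)

    def plot_traces(self, metrics: Sequence[str] = ("mcc", "roc_auc"),
                    path=None):
        """Polyline plot of per-prefix metrics across iterations."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, len(metrics), figsize=(6 * len(metrics), 4),
                                 squeeze=False)
        for ax, metric in zip(axes[0], metrics):
            for it, rec in enumerate(self.history):
                vals = rec.traces[metric].values
                label = "stage 1" if it == 0 else f"iter {it}"
                ax.plot(range(1, len(vals) + 1), vals, alpha=0.5, label=label)
            ax.set_xlabel("prefix length (genes)")
            ax.set_ylabel(metric)
            ax.set_title(f"{metric} across iterations")
            if len(self.history) <= 8:
                ax.legend(fontsize=7)
        fig.tight_layout()
        if path is not None:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return fig

    def to_dir(self, out_dir) -> None:
        """Write per-iteration orderings/traces and a JSON run manifest."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for it, rec in enumerate(self.history):
            name = "stage1" if it == 0 else f"iter{it:02d}"
            write_ordering(rec.ordering, rec.traces, out / f"ordering_{name}.tsv")
        sel = self.selection()
        (out / "selected_genes.txt").write_text("\n".join(sel.genes) + "\n")
        write_run_manifest(
            out / "manifest.json",
            seed=self.seed,
            metric_object=self.model.metric_object,
            classifier=self.model.model.name,
            classifier_hyperparameters=self.model.model.hyperparameters,
            n_iterations=len(self.history) - 1,
            k=self.model.k,
            n_genes=len(self.model.genes),
            anchor=self.anchor,
            st_path=self.st_path,
            selected_genes=list(sel.genes),
            selection_stable=sel.stable,
        )
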