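"""Shared fixtures: tiny datasets and deterministic stub evaluators."""

from __future__ import annotations

import numpy as np
import pytest

from sdbe.data import ExpressionDataset
from sdbe.metrics import MetricVector


@pytest.fixture
def separable_ds() -> ExpressionDataset:
    """40 samples, one perfectly separating gene plus three noise genes.

    Class-0 values of SEP are < 0.1 and class-1 values > 0.9, so a
    threshold at 0.5 classifies perfectly (verified below in
    test_crossval by the threshold oracle).
    """
    rng = np.random.default_rng(42)
    n = 40
    labels = np.r_[np.zeros(20, dtype=int), np.ones(20, dtype=int)]
    sep = np.where(labels == 1, 0.95, 0.05) + rng.uniform(-0.04, 0.04, n)
    noise = rng.uniform(0, 1, size=(n, 3))
    values = np.column_stack([sep, noise])
    return ExpressionDataset([f"s{i}" for i in range(n)],
                             ["SEP", "N1", "N2", "N3"], values, labels)


@pytest.fixture
def tiny_ds() -> ExpressionDataset:
    return ExpressionDataset(
        ["a", "b", "c"], ["g1", "g2"],
        [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]], [0, 1, 1])


class StubEvaluator:
    """Deterministic subset evaluator for exercising the elimination logic.

    The metric of a gene subset is a fixed function: a base value per
    number of distinct planted "families" covered, minus a small size
    penalty, plus a per-gene deterministic offset. Importances are fixed
    per-gene weights. No randomness, no classifier — pure bookkeeping, so
    reference traces can be checked exactly.
    """

    def __init__(self, family_of: dict[str, str | None],
                 base: dict[int, float] | None = None,
                 size_penalty: float = 0.001,
                 jitter_scale: float = 0.01,
                 importance_of: dict[str, float] | None = None):
        self.family_of = family_of
        self.base = base or {0: 0.1, 1: 0.5, 2: 0.75, 3: 0.9, 4: 0.95, 5: 0.97}
        self.size_penalty = size_penalty
        self.jitter_scale = jitter_scale
        self.importance_of = importance_of or {}
        self.calls = 0

    def _jitter(self, gene: str) -> float:
        # deterministic pseudo-noise from the gene name
        return ((hash(gene) % 1000) / 1000 - 0.5) * self.jitter_scale

    def metric(self, genes) -> float:
        fams = {self.family_of[g] for g in genes if self.family_of.get(g)}
        base = self.base[min(len(fams), max(self.base))]
        return base - self.size_penalty * len(genes) + sum(
            self._jitter(g) for g in genes)

    def __call__(self, genes, seed):
        self.calls += 1
        m = self.metric(genes)
        mv = MetricVector(acc=m, re=m, pr=m, f1=m, fpr=1 - m, mcc=m, roc_auc=m)
        imp = np.array([self.importance_of.get(g, self._jitter(g) + 0.5)
                        for g in genes])
        return mv, imp


@pytest.fixture
def stub_world():
    """A 12-gene stub universe: 3 families x 2 copies + 6 nulls."""
    family_of = {}
    for f in range(3):
        for c in range(2):
            family_of[f"F{f}_{c}"] = f"fam{f}"
    for j in range(6):
        family_of[f"N{j}"] = None
    importance = {g: (0.9 - 0.1 * i if fam else 0.05)
                  for i, (g, fam) in enumerate(family_of.items())}
    return StubEvaluator(family_of, importance_of=importance)
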