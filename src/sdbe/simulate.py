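"""Synthetic expression data with planted relevant, redundant and null genes.

The generator emulates the shape of an imbalanced tumor-vs-normal
transcriptome cohort: a few informative genes whose mean shifts between
classes, correlated redundant copies of those genes, and many pure-noise
genes. It is the test bed for every selection stage — ground truth is known
by construction, so recovery can be scored exactly.

Model: on a latent Gaussian scale, a relevant gene is
``label * effect_size + Normal(0, base_noise_sd)``; a redundant copy is
``rho * parent + sqrt(1 - rho^2) * Normal(0, base_noise_sd)`` (within-class
correlation rho with its parent, class shift attenuated to rho * effect);
null genes are pure noise. Values are shifted per gene to be nonnegative;
an optional log-normal transform gives multiplicative, count-like data.

Two named presets frame the benchmarks:

* ``S-easy`` — balanced 50 vs 50, 5 relevant genes among 100, no
  redundancy, effect 2 SD. The easy planted-signal recovery regime.
* ``S-redundant`` — imbalanced 20 vs 200 (the ~1:10 normal:tumor ratio of
  real cohorts), 3 relevant genes each with 2 correlated copies
  (rho = 0.9) plus 51 nulls, 60 genes total: the redundancy-elimination
  regime the backward-elimination sort is meant to solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import ExpressionDataset

__all__ = ["SyntheticSpec", "PRESETS", "generate", "generate_preset",
           "RecoveryCounts", "truth_eval", "fold_change_dataset"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic cohort."""

    n_neg: int = 20
    n_pos: int = 200
    n_relevant: int = 3
    n_redundant_per_relevant: int = 0
    redundancy_rho: float = 0.9
    effect_size: float = 2.0
    n_null: int = 50
    base_noise_sd: float = 1.0
    lognormal: bool = False
    seed: int = 0

    def __post_init__(self):
        if min(self.n_neg, self.n_pos, self.n_relevant, self.n_null,
               self.n_redundant_per_relevant) < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_relevant + self.n_null == 0:
            raise ValueError("spec generates no genes")
        if not 0 < self.redundancy_rho < 1 and self.n_redundant_per_relevant:
            raise ValueError("redundancy_rho must be in (0, 1)")
        if self.base_noise_sd <= 0:
            raise ValueError("base_noise_sd must be positive")

    @property
    def n_genes(self) -> int:
        return self.n_relevant * (1 + self.n_redundant_per_relevant) + self.n_null


PRESETS: dict[str, SyntheticSpec] = {
    "S-easy": SyntheticSpec(n_neg=50, n_pos=50, n_relevant=5,
                            n_redundant_per_relevant=0, redundancy_rho=0.9,
                            effect_size=2.0, n_null=95),
    "S-redundant": SyntheticSpec(n_neg=20, n_pos=200, n_relevant=3,
                                 n_redundant_per_relevant=2, redundancy_rho=0.9,
                                 effect_size=2.0, n_null=51),
}


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, dict[str, str]]:
    """Generate a dataset and its truth map.

    Truth values: ``"relevant"``, ``"redundant-of:<parent id>"`` or
    ``"null"``. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_neg + spec.n_pos
    labels = np.r_[np.zeros(spec.n_neg, dtype=int), np.ones(spec.n_pos, dtype=int)]
    sd, rho, eff = spec.base_noise_sd, spec.redundancy_rho, spec.effect_size

    columns: list[np.ndarray] = []
    gene_ids: list[str] = []
    truth: dict[str, str] = {}
    for j in range(spec.n_relevant):
        parent_id = f"REL{j}"
        parent = labels * eff * sd + rng.normal(0.0, sd, size=n)
        columns.append(parent)
        gene_ids.append(parent_id)
        truth[parent_id] = "relevant"
        for c in range(spec.n_redundant_per_relevant):
            copy = rho * parent + np.sqrt(1 - rho**2) * rng.normal(0.0, sd, size=n)
            cid = f"RED{j}_{c}"
            columns.append(copy)
            gene_ids.append(cid)
            truth[cid] = f"redundant-of:{parent_id}"
    for j in range(spec.n_null):
        nid = f"NUL{j:03d}"
        columns.append(rng.normal(0.0, sd, size=n))
        gene_ids.append(nid)
        truth[nid] = "null"

    values = np.column_stack(columns)
    if spec.lognormal:
        values = np.exp(values)
    else:
        values = values - values.min(axis=0, keepdims=True)  # per-gene shift >= 0
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return ExpressionDataset(sample_ids, gene_ids, values, labels), truth


def generate_preset(name: str, seed: int = 0) -> tuple[ExpressionDataset, dict[str, str]]:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return generate(replace(PRESETS[name], seed=seed))


@dataclass(frozen=True)
class RecoveryCounts:
    """Selection scored against the truth map, family-level."""

    n_relevant_recovered: int   # families with original OR any copy selected
    n_redundant_selected: int
    n_null_selected: int
    n_families: int


def truth_eval(selected, truth: dict[str, str]) -> RecoveryCounts:
    """Score a selected gene list against the generator's truth map.

    A relevant *family* counts as recovered if its original or any of its
    redundant copies is selected — at high correlation the copies are
    statistically exchangeable with their parent.
    """
    unknown = [g for g in selected if g not in truth]
    if unknown:
        raise KeyError(f"unknown gene id(s): {unknown}")
    families = {g for g, t in truth.items() if t == "relevant"}
    recovered: set[str] = set()
    n_red = n_null = 0
    for g in selected:
        t = truth[g]
        if t == "relevant":
            recovered.add(g)
        elif t.startswith("redundant-of:"):
            recovered.add(t.split(":", 1)[1])
            n_red += 1
        else:
            n_null += 1
    return RecoveryCounts(n_relevant_recovered=len(recovered),
                          n_redundant_selected=n_red,
                          n_null_selected=n_null,
                          n_families=len(families))


def fold_change_dataset(
    n_neg: int = 60,
    n_pos: int = 60,
    n_signal: int = 10,
    n_null: int = 40,
    fold: float = 4.0,
    base_mean: float = 5.0,
    log_sd: float = 0.25,
    seed: int = 0,
) -> tuple[ExpressionDataset, dict[str, str]]:
    """Multiplicative cohort for fold-change screening tests.

    Every gene is log-normal around ``base_mean``; the planted genes are
    multiplied by ``fold`` in the tumor class, so their expected log2 fold
    change is exactly log2(fold).
    """
    rng = np.random.default_rng(seed)
    n = n_neg + n_pos
    labels = np.r_[np.zeros(n_neg, dtype=int), np.ones(n_pos, dtype=int)]
    base = rng.lognormal(np.log(base_mean), log_sd, size=(n, n_signal + n_null))
    base[labels == 1, :n_signal] *= fold
    gene_ids = [f"SIG{j:02d}" for j in range(n_signal)] + \
               [f"NUL{j:03d}" for j in range(n_null)]
    truth = {g: ("relevant" if g.startswith("SIG") else "null") for g in gene_ids}
    sample_ids = [f"S{i:04d}" for i in range(n)]
    return ExpressionDataset(sample_ids, gene_ids, base, labels), truth
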