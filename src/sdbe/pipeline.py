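"""End-to-end selection workflows and the metric x classifier comparison grid.

Two published workflows are wired here:

* **gsea_sdbe** — screen DEGs, min-max normalize the survivors, shuffle,
  rank by random-forest importance and keep the top K (default 2000), run
  the enrichment stage and keep the core-enrichment (leading edge) genes of
  explicitly chosen sets, then hand those genes to SDBE.
* **pre_sdbe** — the simplified variant that skips enrichment: the top K
  (default 50) importance-ranked genes go straight into SDBE.

Gene counts entering and leaving every stage are recorded in the report so
the funnel is auditable; a run manifest captures every seed and parameter
needed for an exact re-run.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import SDBE, IterationRecord, SDBEResults, SelectionResult
from .crossval import ClassifierSpec
from .data import ExpressionDataset, GeneSet, read_gmt, write_run_manifest
from .enrichment import enrichment_report, rank_genes, select_core_genes
from .importance import rank_by_importance, take_top
from .metrics import MetricVector
from .preprocess import minmax_normalize, screen_degs, shuffle_samples

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline",
           "metric_model_grid"]

_MODE_TOP_K = {"gsea_sdbe": 2000, "pre_sdbe": 50}


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one selection run (all seeds recorded on output)."""

    mode: str = "pre_sdbe"                 # {"gsea_sdbe", "pre_sdbe"}
    logfc_min: float = 1.0
    fdr_max: float = 0.05
    top_k: int | None = None               # default 2000 / 50 by mode
    # enrichment stage (gsea_sdbe only)
    gene_sets: Sequence[GeneSet] | None = None
    gmt_path: str | None = None
    chosen_sets: Sequence[str] | None = None
    gsea_n_perm: int = 1000
    gsea_mode: str = "phenotype"
    # SDBE stage
    metric_object: str = "mcc"
    model: ClassifierSpec = field(default_factory=lambda: ClassifierSpec("rf"))
    n_iterations: int = 19
    k: int = 10
    tolerance: float = 0.005
    stability_window: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in _MODE_TOP_K:
            raise ValueError(f"mode must be one of {sorted(_MODE_TOP_K)}")
        if self.mode == "gsea_sdbe":
            if self.gene_sets is None and self.gmt_path is None:
                raise ValueError("gsea_sdbe mode needs gene_sets or gmt_path")
            if not self.chosen_sets:
                raise ValueError("gsea_sdbe mode needs an explicit chosen_sets "
                                 "list (set selection is a human decision)")

    @property
    def effective_top_k(self) -> int:
        return self.top_k if self.top_k is not None else _MODE_TOP_K[self.mode]


@dataclass
class PipelineReport:
    """Everything a run produced, stage by stage."""

    config: PipelineConfig
    stage_gene_counts: dict[str, int]
    degs: list
    sdbe_input_genes: list[str]
    sdbe_results: SDBEResults
    selection: SelectionResult
    final_metrics: MetricVector
    enrichment: list | None = None

    def manifest(self) -> dict:
        cfg = dataclasses.asdict(self.config)
        cfg["model"] = {"name": self.config.model.name,
                        "hyperparameters": dict(self.config.model.hyperparameters)}
        cfg.pop("gene_sets", None)
        return {
            "config": cfg,
            "stage_gene_counts": self.stage_gene_counts,
            "selected_genes": list(self.selection.genes),
            "selection_stable": self.selection.stable,
            "final_metrics": self.final_metrics.as_dict(),
        }

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sdbe_results.to_dir(out / "sdbe")
        (out / "selected_genes.txt").write_text(
            "\n".join(self.selection.genes) + "\n")
        write_run_manifest(out / "manifest.json", **self.manifest())
        pd.DataFrame(
            [{"gene_id": d.gene_id, "logfc": d.logfc, "p": d.p_value,
              "fdr": d.fdr, "direction": d.direction} for d in self.degs]
        ).to_csv(out / "degs.tsv", sep="\t", index=False)
        self.sdbe_results.plot_traces(path=out / "traces.png")


def run_pipeline(cfg: PipelineConfig, ds: ExpressionDataset,
                 out_dir=None) -> PipelineReport:
    """Execute the configured workflow on a dataset.

    Stage order: DEG screen (raw values) -> min-max normalize survivors ->
    shuffle samples -> importance rank / top-K -> [enrichment core genes]
    -> SDBE -> smallest-stable-prefix selection. The final metrics are the
    cross-validated metrics of the selected prefix under the configured
    classifier.
    """
    counts: dict[str, int] = {"input": ds.n_genes}
    stage = "deg_screen"
    try:
        degs = screen_degs(ds, logfc_min=cfg.logfc_min, fdr_max=cfg.fdr_max)
        if len(degs) < 2:
            raise ValueError(f"only {len(degs)} genes survive the DEG screen; "
                             f"nothing to select from")
        counts["deg_screen"] = len(degs)

        stage = "normalize_shuffle"
        work = ds.subset_genes([d.gene_id for d in degs])
        work = minmax_normalize(work)
        work = shuffle_samples(work, seed=cfg.seed)

        stage = "importance_top_k"
        ranking = rank_by_importance(work, ClassifierSpec(
            "rf", hyperparameters=dict(cfg.model.hyperparameters)
            if cfg.model.name == "rf" else {}), seed=cfg.seed)
        top_k = min(cfg.effective_top_k, len(ranking))
        genes = take_top(ranking, top_k)
        counts["importance_top_k"] = len(genes)

        enrichment = None
        if cfg.mode == "gsea_sdbe":
            stage = "enrichment"
            sets = list(cfg.gene_sets) if cfg.gene_sets is not None \
                else read_gmt(cfg.gmt_path)
            rl = rank_genes(work.subset_genes(genes))
            in_play = set(rl.gene_ids)
            sets = [s for s in sets if s.members & in_play]  # skip no-overlap sets
            enrichment = enrichment_report(
                work.subset_genes(genes), rl, sets, n_perm=cfg.gsea_n_perm,
                mode=cfg.gsea_mode, seed=cfg.seed)
            genes = select_core_genes(enrichment, list(cfg.chosen_sets))
            if len(genes) < 2:
                raise ValueError("fewer than 2 core-enrichment genes selected")
            counts["enrichment_core"] = len(genes)

        stage = "sdbe"
        model = SDBE(work, genes=genes, metric_object=cfg.metric_object,
                     model=cfg.model, n_iterations=cfg.n_iterations, k=cfg.k)
        results = model.fit(seed=cfg.seed)
        selection = results.selection(tolerance=cfg.tolerance,
                                      stability_window=cfg.stability_window)
        counts["selected"] = len(selection.genes)

        final_trace_idx = len(selection.genes) - 1
        final = results.history[-1]
        final_metrics = MetricVector(**{
            name: float(final.traces[name].values[final_trace_idx])
            for name in final.traces})
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    report = PipelineReport(config=cfg, stage_gene_counts=counts, degs=degs,
                            sdbe_input_genes=list(genes), sdbe_results=results,
                            selection=selection, final_metrics=final_metrics,
                            enrichment=enrichment)
    if out_dir is not None:
        report.write(out_dir)
    return report


def metric_model_grid(
    ds: ExpressionDataset,
    genes: Sequence[str],
    metric_objects: Sequence[str] = ("mcc", "roc_auc"),
    model_names: Sequence[str] = ("rf", "svm", "knn", "gbt", "extratrees"),
    model_params: Mapping[str, Mapping] | None = None,
    n_iterations: int = 19,
    k: int = 10,
    seed: int = 0,
    tolerance: float = 0.005,
    importance_model: ClassifierSpec | None = None,
) -> pd.DataFrame:
    """Cross-compare SDBE over metric objects x classifiers.

    Every cell runs SDBE with that metric object driving the sort and that
    classifier producing the traces, then reports the cross-validated
    metrics of the smallest selected prefix. Stage 1 depends only on the
    random-forest importance model, so it is computed once per call and
    shared across all cells.

    Returns a tidy frame with one row per cell: metric_object, model,
    n_selected, selected_genes, and the six metrics of the selection.
    """
    model_params = dict(model_params or {})
    importance_model = importance_model or ClassifierSpec(
        "rf", hyperparameters=dict(model_params.get("rf", {})))
    base = SDBE(ds, genes=genes, metric_object="mcc", model=importance_model,
                n_iterations=n_iterations, k=k)
    stage1 = base.stage1(seed=seed)

    rows = []
    for metric_object in metric_objects:
        for name in model_names:
            spec = ClassifierSpec(name, hyperparameters=dict(model_params.get(name, {})))
            model = SDBE(ds, genes=genes, metric_object=metric_object,
                         model=spec, importance_model=importance_model,
                         n_iterations=n_iterations, k=k)
            res = model.fit(seed=seed, stage1_record=stage1)
            sel = res.selection(tolerance=tolerance)
            final = res.history[-1]
            idx = len(sel.genes) - 1
            row = {"metric_object": metric_object, "model": name,
                   "n_selected": len(sel.genes),
                   "selected_genes": ",".join(sel.genes),
                   "stable": sel.stable}
            row.update({m: float(final.traces[m].values[idx])
                        for m in final.traces})
            rows.append(row)
    return pd.DataFrame(rows)
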