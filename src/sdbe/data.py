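"""Core containers and text-format I/O.

The pipeline's substrate is a labeled expression matrix: samples in rows,
genes in columns, nonnegative expression values, and a binary phenotype per
sample (0 = normal = negative class, 1 = tumor = positive class). Gene sets
are exchanged in the standard GMT format (one set per line:
``name<TAB>description<TAB>member<TAB>member...``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "GeneSet",
    "read_expression",
    "read_gmt",
    "write_gmt",
    "write_ordering",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass(frozen=True)
class ExpressionDataset:
    """A samples x genes expression matrix with binary phenotype labels.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``values``.
    gene_ids : list of str
        Unique gene identifiers, one per column of ``values``.
    values : ndarray, shape (n_samples, n_genes)
        Nonnegative expression values (any unit: counts, FPKM, TPM...).
    labels : ndarray of {0, 1}
        Per-sample phenotype; 1 is the positive (tumor) class.
    """

    sample_ids: tuple[str, ...]
    gene_ids: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    def __init__(self, sample_ids, gene_ids, values, labels):
        sample_ids = tuple(str(s) for s in sample_ids)
        gene_ids = tuple(str(g) for g in gene_ids)
        _check_unique(sample_ids, "sample")
        _check_unique(gene_ids, "gene")
        values = np.asarray(values, dtype=float)
        labels = np.asarray(labels)
        if values.ndim != 2 or values.shape != (len(sample_ids), len(gene_ids)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({len(sample_ids)} samples, {len(gene_ids)} genes)"
            )
        if not np.isfinite(values).all():
            raise ValueError("expression matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("expression values must be nonnegative")
        if labels.shape != (len(sample_ids),):
            raise ValueError("labels must have one entry per sample")
        labels = labels.astype(int)
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary 0/1 (0=normal, 1=tumor)")
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "gene_ids", gene_ids)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def class_counts(self) -> tuple[int, int]:
        """(n_negative, n_positive) sample counts."""
        n_pos = int(self.labels.sum())
        return self.n_samples - n_pos, n_pos

    def gene_index(self, gene_ids: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in gene_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown gene id: {e.args[0]!r}") from None

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionDataset":
        idx = self.gene_index(gene_ids)
        return ExpressionDataset(
            self.sample_ids, [self.gene_ids[i] for i in idx],
            self.values[:, idx], self.labels,
        )

    def matrix_for(self, gene_ids: Sequence[str]) -> np.ndarray:
        """View of ``values`` restricted to the given genes, in given order."""
        return self.values[:, self.gene_index(gene_ids)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.sample_ids),
                            columns=list(self.gene_ids))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, labels) -> "ExpressionDataset":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(), labels)


@dataclass(frozen=True)
class GeneSet:
    """A named collection of gene ids (one GMT line)."""

    name: str
    description: str = ""
    members: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} has no members")

    def __len__(self) -> int:
        return len(self.members)


def _delimiter_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression(
    path,
    orientation: str = "samples_as_rows",
    labels=None,
    label_row: str | None = None,
    label_map: Mapping[str, int] | None = None,
) -> ExpressionDataset:
    """Read a delimited expression matrix plus labels into a dataset.

    Parameters
    ----------
    path : path-like
        TSV or CSV file (delimiter auto-detected from the extension) with a
        header line and row ids in the first column.
    orientation : {"samples_as_rows", "genes_as_rows"}
        Layout of the file; TCGA-style genes-as-rows matrices are transposed
        on read so the in-memory layout is always samples x genes.
    labels : path-like or sequence, optional
        Either a two-column sidecar file (sample_id, label) or an explicit
        per-sample label sequence.
    label_row : str, optional
        Name of a row (genes_as_rows) or column (samples_as_rows) holding the
        labels inside the matrix file itself.
    label_map : mapping, optional
        Vocabulary mapping label tokens to {0, 1}, e.g. {"normal": 0,
        "tumor": 1}. By default tokens must already be 0/1 or the literal
        strings "normal"/"tumor".
    """
    path = Path(path)
    sep = _delimiter_for(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)[1:]
    dups = pd.Index(header)[pd.Index(header).duplicated()]
    if len(dups):  # pandas would silently rename duplicated header ids
        raise ValueError(f"duplicate "
                         f"{'gene' if orientation == 'samples_as_rows' else 'sample'}"
                         f" id: {dups[0]!r}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation not in ("samples_as_rows", "genes_as_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")

    label_series = None
    if label_row is not None:
        if orientation == "genes_as_rows":
            if label_row not in df.index:
                raise ValueError(f"label row {label_row!r} not found")
            label_series = df.loc[label_row]
            df = df.drop(index=label_row)
        else:
            if label_row not in df.columns:
                raise ValueError(f"label column {label_row!r} not found")
            label_series = df[label_row]
            df = df.drop(columns=label_row)

    if orientation == "genes_as_rows":
        df = df.T

    # df is now samples x genes
    for axis, what in ((df.index, "sample"), (df.columns, "gene")):
        dup = axis[axis.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate {what} id: {dup[0]!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"non-numeric or missing cell at sample {df.index[bad[0]]!r}, "
            f"gene {df.columns[bad[1]]!r}"
        )

    if label_series is None:
        if labels is None:
            raise ValueError("labels must be supplied (sidecar file, sequence, or label_row)")
        if isinstance(labels, (str, Path)):
            lab_path = Path(labels)
            lab = pd.read_csv(lab_path, sep=_delimiter_for(lab_path), header=None,
                              comment="#", dtype=str)
            if lab.shape[1] < 2:
                raise ValueError("label sidecar must have two columns: sample_id, label")
            lab_map = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1]))
            missing = [s for s in numeric.index if str(s) not in lab_map]
            if missing:
                raise ValueError(f"label missing for sample {missing[0]!r}")
            label_series = pd.Series([lab_map[str(s)] for s in numeric.index],
                                     index=numeric.index)
        else:
            label_series = pd.Series(list(labels), index=numeric.index)

    enc = _encode_labels(label_series, label_map)
    return ExpressionDataset(list(numeric.index), list(numeric.columns),
                             numeric.to_numpy(), enc)


_DEFAULT_VOCAB = {"0": 0, "1": 1, "normal": 0, "tumor": 1}


def _encode_labels(series: pd.Series, label_map: Mapping[str, int] | None) -> np.ndarray:
    vocab = {str(k).lower(): int(v) for k, v in (label_map or _DEFAULT_VOCAB).items()}
    out = []
    for s, v in series.items():
        key = str(v).strip().lower()
        try:
            key = str(int(float(key)))  # "1.0" -> "1"
        except ValueError:
            pass
        if key not in vocab:
            raise ValueError(f"unmappable label {v!r} for sample {s!r}; "
                             f"supply an explicit label_map")
        out.append(vocab[key])
    return np.array(out, dtype=int)


def write_expression(ds: ExpressionDataset, path, orientation: str = "samples_as_rows",
                     label_path=None) -> None:
    """Write a dataset as TSV/CSV; labels go to a two-column sidecar if given."""
    path = Path(path)
    df = ds.to_frame()
    if orientation == "genes_as_rows":
        df = df.T
    df.to_csv(path, sep=_delimiter_for(path))
    if label_path is not None:
        pd.DataFrame({"sample_id": list(ds.sample_ids), "label": ds.labels}).to_csv(
            label_path, sep="\t", header=False, index=False)


def read_gmt(path) -> list[GeneSet]:
    """Parse a GMT gene-set file; within-set duplicates collapse silently."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line {lineno}: expected at least 3 "
                                 f"tab-separated fields, got {len(fields)}")
            name, desc, *members = fields
            members = [m for m in members if m]
            sets.append(GeneSet(name=name, description=desc, members=frozenset(members)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, gs.description, *sorted(gs.members)]) + "\n")


def write_ordering(ordering, traces: Mapping[str, object], path) -> None:
    """Write a gene ordering and aligned metric traces as TSV.

    Columns: position, gene_id, then one column per metric in sorted name
    order; row i holds the metric of the model trained on the prefix ending
    at that gene.
    """
    genes = list(getattr(ordering, "genes", ordering))
    cols: dict[str, list] = {
        "position": list(range(len(genes))),
        "gene_id": genes,
    }
    for name in sorted(traces):
        vals = list(getattr(traces[name], "values", traces[name]))
        if len(vals) != len(genes):
            raise ValueError(f"trace {name!r} has length {len(vals)}, "
                             f"expected {len(genes)}")
        cols[name] = vals
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def write_run_manifest(path, **fields) -> None:
    """JSON sidecar recording seeds/config so a run can be reproduced."""
    with open(path, "w") as fh:
        json.dump(fields, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
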