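"""Longitudinal expression containers and on-disk formats.

The canonical input is a pair of plain text tables:

* an expression table (TSV or CSV), genes in rows and sample columns,
  first column holding gene identifiers, header row holding sample ids;
* a design table mapping each sample column to ``(subject_id,
  time_index, phenotype)``.

Samples are aligned into a dense ``gene x subject x time`` tensor with an
explicit boolean mask: a subject that was not measured at some time point
simply has ``mask = False`` there, and every downstream statistic is
computed available-case per (gene, time) cell.  Expression values are
assumed to be already normalized/summarized (log scale); no normalization
is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LongitudinalExpressionSet",
    "DesignTable",
    "read_expression_table",
    "read_design_table",
    "assemble_dataset",
    "disassemble",
]


class DataValidationError(ValueError):
    """Raised when an input table or tensor violates a structural invariant."""


@dataclass
class DesignTable:
    """Sample-to-(subject, time, phenotype) mapping.

    Parameters
    ----------
    frame : pandas.DataFrame
        Columns ``sample_id``, ``subject_id``, ``time_index`` (1-based
        integers) and ``phenotype`` (0/1; constant within a subject).
    """

    frame: pd.DataFrame

    REQUIRED = ("sample_id", "subject_id", "time_index", "phenotype")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise DataValidationError(f"design table missing columns: {missing}")
        f = self.frame
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise DataValidationError(f"duplicate sample_id in design table: {dup!r}")
        pairs = f[["subject_id", "time_index"]]
        if pairs.duplicated().any():
            row = pairs.loc[pairs.duplicated()].iloc[0]
            raise DataValidationError(
                f"duplicate (subject_id, time_index) pair: "
                f"({row['subject_id']!r}, {row['time_index']!r})"
            )
        t = f["time_index"].to_numpy()
        if not np.issubdtype(t.dtype, np.integer):
            if not np.all(t == t.astype(int)):
                raise DataValidationError("time_index must be integer")
            t = t.astype(int)
        if (t < 1).any():
            raise DataValidationError("time_index must be 1-based (>= 1)")
        ph = f["phenotype"].to_numpy()
        if not np.isin(ph, (0, 1)).all():
            raise DataValidationError("phenotype must be coded 0/1")
        # phenotype must be a subject-level constant
        per_subj = f.groupby("subject_id")["phenotype"].nunique()
        bad = per_subj[per_subj > 1]
        if len(bad):
            raise DataValidationError(
                f"subject {bad.index[0]!r} has inconsistent phenotype labels"
            )


@dataclass
class LongitudinalExpressionSet:
    """Aligned ``G x n x T`` expression tensor with phenotype labels.

    Attributes
    ----------
    expr : ndarray of shape (G, n, T)
        Log-scale expression values; undefined where ``mask`` is False.
    mask : bool ndarray of shape (G, n, T)
        True where a measurement exists.
    labels : ndarray of shape (n,) or None
        Subject-level binary phenotype: 1 = diseased/complicated,
        0 = control/uncomplicated.  ``None`` for an unlabeled base pool
        (e.g. a simulator draw before outcomes are attached).
    gene_ids, subject_ids, time_ids : lists of identifiers.
    """

    expr: np.ndarray
    mask: np.ndarray
    labels: np.ndarray | None
    gene_ids: list = field(default_factory=list)
    subject_ids: list = field(default_factory=list)
    time_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.expr = np.asarray(self.expr, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.expr.ndim != 3:
            raise DataValidationError("expr must be a (gene, subject, time) tensor")
        if self.mask.shape != self.expr.shape:
            raise DataValidationError("mask shape must match expr shape")
        G, n, T = self.expr.shape
        if G < 1 or T < 1:
            raise DataValidationError("need at least one gene and one time point")
        if not self.gene_ids:
            self.gene_ids = [f"gene_{i}" for i in range(G)]
        if not self.subject_ids:
            self.subject_ids = [f"subject_{i}" for i in range(n)]
        if not self.time_ids:
            self.time_ids = list(range(1, T + 1))
        if len(self.gene_ids) != G or len(self.subject_ids) != n or len(self.time_ids) != T:
            raise DataValidationError("identifier lists do not match tensor shape")
        if not np.isfinite(self.expr[self.mask]).all():
            raise DataValidationError("non-finite expression value where mask is True")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (n,):
                raise DataValidationError("labels must be one value per subject")
            if not np.isin(self.labels, (0, 1)).all():
                raise DataValidationError("labels must be coded 0/1")

    def validate_for_analysis(self) -> None:
        """Check statistical adequacy: >= 2 measured subjects per class at
        every time point (required for a pooled SD).  Called by the SAM
        layer; plain container construction allows degenerate shapes."""
        if self.labels is None:
            raise DataValidationError("dataset has no phenotype labels")
        if self.n_subjects < 4:
            raise DataValidationError("need at least 4 subjects (2 per class)")
        present = self.mask.any(axis=0)  # (n, T): subject measured at t
        for cls in (0, 1):
            counts = present[self.labels == cls].sum(axis=0)
            if (counts < 2).any():
                t_bad = int(np.argmax(counts < 2))
                raise DataValidationError(
                    f"class {cls} has fewer than 2 measured subjects at "
                    f"time point {self.time_ids[t_bad]!r}"
                )

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_subjects(self) -> int:
        return self.expr.shape[1]

    @property
    def n_times(self) -> int:
        return self.expr.shape[2]

    def with_labels(self, labels: np.ndarray) -> "LongitudinalExpressionSet":
        """Return a copy of the dataset with (new) subject labels attached."""
        return LongitudinalExpressionSet(
            self.expr, self.mask, np.asarray(labels, dtype=int),
            list(self.gene_ids), list(self.subject_ids), list(self.time_ids),
        )

    def subset_subjects(self, idx: np.ndarray) -> "LongitudinalExpressionSet":
        """Restrict to the subjects at positions ``idx`` (order preserved)."""
        idx = np.asarray(idx)
        return LongitudinalExpressionSet(
            self.expr[:, idx, :], self.mask[:, idx, :],
            None if self.labels is None else self.labels[idx],
            list(self.gene_ids),
            [self.subject_ids[i] for i in idx],
            list(self.time_ids),
        )


def read_expression_table(path, dialect: str = "tsv") -> pd.DataFrame:
    """Read a genes-by-samples expression table.

    ``NA`` / empty cells are allowed and become NaN (masked downstream);
    any other non-numeric cell is a parse error that names the offending
    row and column.  Duplicate gene identifiers are rejected.
    """
    sep = {"tsv": "\t", "csv": ","}.get(dialect)
    if sep is None:
        raise ValueError(f"unknown dialect {dialect!r} (expected 'tsv' or 'csv')")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise DataValidationError(f"{path}: no genes (header only)")
    if raw.index.duplicated().any():
        dup = raw.index[raw.index.duplicated()][0]
        raise DataValidationError(f"{path}: duplicate gene ID {dup!r}")
    out = raw.apply(pd.to_numeric, errors="coerce")
    # distinguish genuine NA tokens from parse failures
    na_tokens = {"", "na", "nan", "null"}
    bad = out.isna() & ~raw.isna().to_numpy() & ~raw.map(
        lambda v: isinstance(v, str) and v.strip().lower() in na_tokens
    ).to_numpy()
    if bad.to_numpy().any():
        g, s = np.argwhere(bad.to_numpy())[0]
        raise DataValidationError(
            f"{path}: non-numeric value {raw.iat[g, s]!r} at gene "
            f"{raw.index[g]!r}, sample {raw.columns[s]!r}"
        )
    return out


def read_design_table(path) -> DesignTable:
    """Read a design table TSV (columns sample_id, subject_id, time_index, phenotype)."""
    return DesignTable(pd.read_csv(path, sep="\t"))


def assemble_dataset(raw: pd.DataFrame, design: DesignTable) -> LongitudinalExpressionSet:
    """Align a raw genes-by-samples matrix into a (gene, subject, time) tensor.

    Time points are ordered by their 1-based ``time_index`` (never by a
    lexical sort of labels).  Subjects keep their order of first appearance
    in the design table.  A (subject, time) pair absent from the design, or
    a NaN cell, yields ``mask = False``.
    """
    f = design.frame
    unknown = set(f["sample_id"]) - set(raw.columns)
    if unknown:
        raise DataValidationError(f"design sample(s) not in expression header: {sorted(unknown)[:3]}")
    subjects = list(dict.fromkeys(f["subject_id"]))
    T = int(f["time_index"].max())
    G = raw.shape[0]
    n = len(subjects)
    expr = np.zeros((G, n, T))
    mask = np.zeros((G, n, T), dtype=bool)
    labels = np.zeros(n, dtype=int)
    subj_pos = {s: i for i, s in enumerate(subjects)}
    for row in f.itertuples(index=False):
        i = subj_pos[row.subject_id]
        t = int(row.time_index) - 1
        col = raw[row.sample_id].to_numpy(dtype=float)
        ok = np.isfinite(col)
        expr[:, i, t] = np.where(ok, col, 0.0)
        mask[:, i, t] = ok
        labels[i] = int(row.phenotype)
    return LongitudinalExpressionSet(
        expr, mask, labels,
        gene_ids=list(raw.index), subject_ids=subjects,
        time_ids=list(range(1, T + 1)),
    )


def disassemble(ds: LongitudinalExpressionSet) -> tuple[pd.DataFrame, DesignTable]:
    """Inverse of :func:`assemble_dataset` for a labeled dataset.

    Emits one sample column per (subject, time) pair that has at least one
    measured gene; cells masked within such a column become NaN.
    """
    if ds.labels is None:
        raise DataValidationError("cannot disassemble an unlabeled dataset")
    cols, rows = {}, []
    for i, subj in enumerate(ds.subject_ids):
        for t in range(ds.n_times):
            if not ds.mask[:, i, t].any():
                continue
            sid = f"{subj}__t{t + 1}"
            col = ds.expr[:, i, t].copy()
            col[~ds.mask[:, i, t]] = np.nan
            cols[sid] = col
            rows.append((sid, subj, t + 1, int(ds.labels[i])))
    raw = pd.DataFrame(cols, index=pd.Index(ds.gene_ids, name="gene_id"))
    design = DesignTable(pd.DataFrame(
        rows, columns=["sample_id", "subject_id", "time_index", "phenotype"]))
    return raw, design
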