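"""Model/Results interface tying the pipeline together.

``LongitudinalSAMGSR`` is constructed from a labeled
:class:`~longsamgsr.data.LongitudinalExpressionSet` (or the TSV pair via
:meth:`LongitudinalSAMGSR.from_files`); ``fit`` runs screening, optional
cutoff tuning and reduction, and returns a :class:`SAMGSRResults` holding
the selection table, the tuned cutoff with its CV curve, the final
(gene, time point) feature table, and a ``summary()`` text report.
Evaluation against a held-out dataset and plotting hang off the results
object.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (LongitudinalExpressionSet, assemble_dataset,
                   read_design_table, read_expression_table)
from .evaluation import PerformanceReport, evaluate
from .reduction import (DEFAULT_CK_GRID, ReducedGene, TuningResult,
                        features_by_timepoint, reduce_all, tune_ck)
from .selection import SelectionResult, select_genes

__all__ = ["LongitudinalSAMGSR", "SAMGSRResults"]


class LongitudinalSAMGSR:
    """Longitudinal SAMGSR feature-selection model.

    Parameters
    ----------
    dataset : LongitudinalExpressionSet
        Labeled training data.
    n_permutations : int
        Subject-label permutations for the null (exhaustive enumeration
        kicks in automatically for small samples).
    q_cutoff : float
        FDR screening threshold for step 1.
    c_cutoff : float or None
        Fixed reduction cutoff; ``None`` tunes it on ``ck_grid`` by
        ``cv_folds``-fold cross-validated misclassification error.
    s0_policy : {"median", "percentile"}
        Fudge-constant estimator.
    qvalue_method : {"bh", "storey"}
        FDR adjustment.
    """

    def __init__(
        self,
        dataset: LongitudinalExpressionSet,
        n_permutations: int = 1000,
        q_cutoff: float = 0.05,
        c_cutoff: float | None = None,
        ck_grid=DEFAULT_CK_GRID,
        cv_folds: int = 5,
        s0_policy: str = "median",
        qvalue_method: str = "bh",
        svm_C: float = 1.0,
    ) -> None:
        if dataset.labels is None:
            raise ValueError("model needs a labeled dataset")
        self.dataset = dataset
        self.n_permutations = n_permutations
        self.q_cutoff = q_cutoff
        self.c_cutoff = c_cutoff
        self.ck_grid = tuple(ck_grid)
        self.cv_folds = cv_folds
        self.s0_policy = s0_policy
        self.qvalue_method = qvalue_method
        self.svm_C = svm_C

    @classmethod
    def from_files(cls, expr_path, design_path, dialect: str = "tsv", **kwargs):
        raw = read_expression_table(expr_path, dialect=dialect)
        design = read_design_table(design_path)
        return cls(assemble_dataset(raw, design), **kwargs)

    def config(self) -> dict:
        return {
            "n_permutations": self.n_permutations,
            "q_cutoff": self.q_cutoff,
            "c_cutoff": self.c_cutoff,
            "ck_grid": list(self.ck_grid),
            "cv_folds": self.cv_folds,
            "s0_policy": self.s0_policy,
            "qvalue_method": self.qvalue_method,
            "svm_C": self.svm_C,
        }

    def fit(self, seed: int = 0) -> "SAMGSRResults":
        """Run screening → (tuning) → reduction on the full dataset."""
        t0 = time.perf_counter()
        sel = select_genes(
            self.dataset, B=self.n_permutations, q_cutoff=self.q_cutoff,
            seed=seed, s0_policy=self.s0_policy,
            qvalue_method=self.qvalue_method)
        tuning = None
        cutoff = self.c_cutoff
        if cutoff is None:
            tuning = tune_ck(
                self.dataset, grid=self.ck_grid, folds=self.cv_folds,
                seed=seed, B=self.n_permutations, q_cutoff=self.q_cutoff,
                s0_policy=self.s0_policy, qvalue_method=self.qvalue_method,
                svm_C=self.svm_C)
            cutoff = tuning.best_cutoff
        reduced, table = reduce_all(sel, self.dataset, cutoff)
        return SAMGSRResults(
            model=self, selection=sel, tuning=tuning, reduced=reduced,
            feature_table=table, c_cutoff=float(cutoff), seed=seed,
            fit_seconds=time.perf_counter() - t0)


@dataclass
class SAMGSRResults:
    """Fitted longitudinal SAMGSR selection."""

    model: LongitudinalSAMGSR
    selection: SelectionResult
    tuning: TuningResult | None
    reduced: list[ReducedGene]
    feature_table: pd.DataFrame
    c_cutoff: float
    seed: int
    fit_seconds: float

    @property
    def selected_gene_ids(self) -> list:
        ds = self.model.dataset
        return [ds.gene_ids[g] for g in self.selection.selected]

    def selection_frame(self) -> pd.DataFrame:
        return self.selection.to_frame(self.model.dataset.gene_ids)

    def features(self) -> list[np.ndarray]:
        """Per-timepoint gene index lists for classifier fitting."""
        return features_by_timepoint(self.feature_table, self.model.dataset.n_times)

    def evaluate(self, test: LongitudinalExpressionSet) -> PerformanceReport:
        """Fit per-timepoint SVMs on the training data, score ``test``."""
        return evaluate(self.model.dataset, test, self.features(),
                        C=self.model.svm_C)

    def summary(self) -> str:
        ds = self.model.dataset
        n1 = int(ds.labels.sum())
        lines = [
            "Longitudinal SAMGSR selection",
            "=" * 64,
            f"genes: {ds.n_genes}   subjects: {ds.n_subjects} "
            f"({n1} diseased / {ds.n_subjects - n1} control)   "
            f"time points: {ds.n_times}",
            f"permutations: {self.selection.permutations.shape[0]}   "
            f"q-cutoff: {self.model.q_cutoff}   seed: {self.seed}",
            f"c_k cutoff: {self.c_cutoff}"
            + ("" if self.tuning is None else
               f" (tuned, CV error {self.tuning.cv_error.min():.3f})"),
            f"selected genes: {len(self.selection.selected)}   "
            f"(gene, time) features: {len(self.feature_table)}",
            "-" * 64,
        ]
        sf = self.selection_frame()
        sf = sf[sf["selected"]].sort_values("qvalue")
        core = {rg.gene: [int(t) + 1 for t in rg.core_timepoints]
                for rg in self.reduced}
        idx_of = {gid: i for i, gid in enumerate(ds.gene_ids)}
        for _, row in sf.head(25).iterrows():
            gi = idx_of[row["gene_id"]]
            lines.append(
                f"{row['gene_id']:>16}  SAMGS={row['samgs']:8.3f}  "
                f"q={row['qvalue']:.4f}  core times={core.get(gi, [])}")
        if len(sf) > 25:
            lines.append(f"... and {len(sf) - 25} more selected genes")
        return "\n".join(lines)

    def plot_tuning(self, ax=None):
        """CV error across the c_k grid (requires matplotlib)."""
        if self.tuning is None:
            raise ValueError("model was fit with a fixed c_cutoff; no tuning curve")
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.tuning.grid, self.tuning.cv_error, marker="o")
        ax.axvline(self.tuning.best_cutoff, ls="--", color="grey")
        ax.set_xlabel("c_k cutoff")
        ax.set_ylabel("5-fold CV misclassification error")
        return ax

    def save(self, outdir, config_extra: dict | None = None) -> None:
        """Write selection/tuning/feature tables and a reproducibility manifest."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.selection_frame().to_csv(out / "selection.tsv", sep="\t", index=False)
        self.feature_table.to_csv(out / "feature_table.tsv", sep="\t", index=False)
        if self.tuning is not None:
            self.tuning.to_frame().to_csv(out / "tuning.tsv", sep="\t", index=False)
        manifest = {
            "package_version": __version__,
            "seed": self.seed,
            "c_cutoff": self.c_cutoff,
            "config": self.model.config(),
            "n_selected": int(len(self.selection.selected)),
            "n_features": int(len(self.feature_table)),
            "fit_seconds": round(self.fit_seconds, 3),
        }
        if config_extra:
            manifest.update(config_extra)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
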