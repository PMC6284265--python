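"""Core time-point reduction (step 2) and tuning of its cutoff.

For each screened gene, time points are ranked by |d_t| (descending) and
gradually moved into a reduced core subset R_k.  After the top k time
points enter, c_k is the permutation p-value of the residual subset's
SAMGS statistic (sum of d_t² over the time points NOT in R_k), computed
against the same stored permutations used for screening.  The core size
k* is the smallest k whose residual is no longer significant (c_k above a
cutoff); if every residual stays significant the whole trajectory is kept.

The cutoff on c_k is the algorithm's tuning parameter: over the grid
0.05, 0.10, ..., 0.50 it is chosen by minimum 5-fold cross-validated
misclassification error of the averaged-posterior classifier, with ties
broken toward the smallest cutoff (fewer features).  Selection is re-run
inside each training fold so CV error is not contaminated by selection
bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .data import LongitudinalExpressionSet
from .selection import SelectionResult, select_genes

__all__ = [
    "ReducedGene",
    "TuningResult",
    "DEFAULT_CK_GRID",
    "reduce_gene",
    "reduce_all",
    "features_by_timepoint",
    "tune_ck",
]

log = logging.getLogger(__name__)

DEFAULT_CK_GRID = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


@dataclass
class ReducedGene:
    """Reduction outcome for one gene.

    ``ordering`` holds 0-based time indices sorted by decreasing |d_t|
    (ties: smaller time index first; unavailable cells last).  ``c`` holds
    the residual-subset p-values c_1..c_{T-1}.  ``core_timepoints`` is the
    first ``k_star`` of ``ordering``.
    """

    gene: int
    ordering: np.ndarray
    c: np.ndarray
    k_star: int
    core_timepoints: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        assert 1 <= self.k_star <= self.ordering.size
        self.core_timepoints = self.ordering[: self.k_star]


def _rank_timepoints(d_row: np.ndarray) -> np.ndarray:
    """Time indices by decreasing |d|, ties to the smaller index,
    unavailable (NaN) cells last."""
    key = np.abs(d_row)
    key = np.where(np.isfinite(key), key, -np.inf)
    # stable sort on -|d| keeps ascending time order among ties
    return np.argsort(-key, kind="stable")


def reduce_gene(
    gene: int,
    sel: SelectionResult,
    c_cutoff: float,
) -> ReducedGene:
    """Reduce one selected gene's trajectory to its core time points."""
    if not 0 < c_cutoff < 1:
        raise ValueError("c_cutoff must lie in (0, 1)")
    d_row = sel.sam.d[gene]
    avail = sel.sam.available[gene]
    T = d_row.size
    n_avail = int(avail.sum())
    if n_avail == 0:
        raise ValueError(f"gene {gene} has no available time point")
    ordering = _rank_timepoints(d_row)
    c = np.full(max(T - 1, 0), np.nan)
    if T == 1:
        return ReducedGene(gene=gene, ordering=ordering, c=c, k_star=1)

    null_sq = np.nan_to_num(sel.null_d[:, gene, :] ** 2)   # (B, T)
    obs_sq = np.nan_to_num(d_row**2)
    B = null_sq.shape[0]
    for k in range(1, T):
        residual = ordering[k:]
        obs_resid = obs_sq[residual].sum()
        null_resid = null_sq[:, residual].sum(axis=1)
        c[k - 1] = (1.0 + (null_resid >= obs_resid).sum()) / (B + 1.0)
    above = np.flatnonzero(c > c_cutoff)
    k_star = int(above[0]) + 1 if above.size else T
    # unavailable time points are ranked last and can never enter the core
    k_star = min(k_star, n_avail)
    return ReducedGene(gene=gene, ordering=ordering, c=c, k_star=k_star)


def reduce_all(
    sel: SelectionResult,
    ds: LongitudinalExpressionSet,
    c_cutoff: float,
) -> tuple[list[ReducedGene], pd.DataFrame]:
    """Reduce every selected gene; return the final feature table.

    The feature table has one row per (gene, core time point):
    columns gene_index, gene_id, time_index (1-based), d_value,
    rank_within_gene.  A gene is "selected at time t" iff t is in its
    core subset.
    """
    reduced: list[ReducedGene] = []
    rows = []
    if sel.selected.size == 0:
        log.warning("no genes selected; feature table is empty")
    for g in sel.selected:
        rg = reduce_gene(int(g), sel, c_cutoff)
        reduced.append(rg)
        for rank, t in enumerate(rg.core_timepoints, start=1):
            rows.append((int(g), ds.gene_ids[g], int(t) + 1,
                         float(sel.sam.d[g, t]), rank))
    table = pd.DataFrame(
        rows, columns=["gene_index", "gene_id", "time_index", "d_value",
                       "rank_within_gene"])
    return reduced, table


def features_by_timepoint(table: pd.DataFrame, T: int) -> list[np.ndarray]:
    """Per-timepoint gene index lists from a feature table."""
    out = []
    for t in range(1, T + 1):
        out.append(table.loc[table["time_index"] == t, "gene_index"]
                   .to_numpy(dtype=int))
    return out


@dataclass
class TuningResult:
    grid: np.ndarray
    cv_error: np.ndarray
    best_cutoff: float
    fold_assignments: np.ndarray
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"cutoff": self.grid, "cv_error": self.cv_error})


def tune_ck(
    ds: LongitudinalExpressionSet,
    grid=DEFAULT_CK_GRID,
    folds: int = 5,
    seed: int = 0,
    B: int = 1000,
    q_cutoff: float = 0.05,
    s0_policy: str = "median",
    qvalue_method: str = "bh",
    svm_C: float = 1.0,
) -> TuningResult:
    """Choose the c_k cutoff by stratified subject-level cross-validation.

    Within each fold, screening is re-run on the training subjects only;
    each candidate cutoff then reduces that fold's selection, per-timepoint
    classifiers are fit on the training subjects, and the held-out error of
    the averaged posteriors is recorded.  A fold whose training selection
    is empty contributes an uninformative 0.5.
    """
    from .evaluation import (average_posteriors, fit_timepoint_classifiers,
                             misclassification_error, predict_posteriors)

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty cutoff grid")
    labels = ds.labels
    if labels is None:
        raise ValueError("dataset has no phenotype labels")
    if min((labels == 0).sum(), (labels == 1).sum()) < folds:
        raise ValueError("both classes need at least `folds` subjects")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_of = np.empty(ds.n_subjects, dtype=int)
    errors = np.zeros((folds, grid.size))
    for f, (train_idx, val_idx) in enumerate(skf.split(np.zeros(ds.n_subjects), labels)):
        fold_of[val_idx] = f
        train = ds.subset_subjects(train_idx)
        val = ds.subset_subjects(val_idx)
        sel = select_genes(train, B=B, q_cutoff=q_cutoff, seed=seed + 1 + f,
                           s0_policy=s0_policy, qvalue_method=qvalue_method)
        for j, cutoff in enumerate(grid):
            _, table = reduce_all(sel, train, cutoff)
            if table.empty:
                log.warning("fold %d, cutoff %.2f: empty feature table; "
                            "scoring 0.5", f, cutoff)
                errors[f, j] = 0.5
                continue
            feats = features_by_timepoint(table, ds.n_times)
            clfs = fit_timepoint_classifiers(train, feats, C=svm_C)
            probs, pmask = predict_posteriors(clfs, val)
            post = average_posteriors(probs, pmask)
            ok = np.isfinite(post)
            errors[f, j] = misclassification_error(post[ok], val.labels[ok])
        log.info("fold %d/%d done", f + 1, folds)
    cv_error = errors.mean(axis=0)
    best = float(grid[int(np.argmin(cv_error))])  # argmin takes the first
    return TuningResult(grid=grid, cv_error=cv_error, best_cutoff=best,
                        fold_assignments=fold_of, seed=seed)
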