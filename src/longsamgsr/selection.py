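"""Gene screening by the longitudinal SAMGS statistic (reduction step 1).

Each gene's trajectory across the T time points is treated as a gene set:
the set statistic is SAMGS_g = Σ_t d_t², the sum of squared per-timepoint
SAM statistics.  Its null distribution comes from permuting the
subject-level phenotype labels — a subject's whole trajectory moves
between classes as a unit, which preserves the within-subject temporal
correlation the method exists to exploit.  Genes are screened at an FDR
(q-value) cutoff.  The permuted-label SAM matrices are retained so the
reduction step can reuse exactly the same permutations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .data import LongitudinalExpressionSet
from .sam import SamMatrix, sam_matrix

__all__ = [
    "SelectionResult",
    "samgs_statistic",
    "generate_permutations",
    "permutation_pvalue",
    "compute_qvalues",
    "sam_fdr_qvalues",
    "select_genes",
]

log = logging.getLogger(__name__)


def samgs_statistic(d_row: np.ndarray) -> float:
    """SAMGS statistic of one gene: sum of squared SAM statistics over the
    available time points (NaN entries are unavailable cells and contribute 0)."""
    d_row = np.asarray(d_row, dtype=float)
    if not np.isfinite(d_row).any():
        raise ValueError("gene has no available time point")
    return float(np.nansum(d_row**2))


def generate_permutations(labels, B: int, seed: int) -> np.ndarray:
    """B subject-level relabelings preserving the class counts.

    Returns a (B_eff, n) 0/1 array.  If ``B`` is at least the number of
    distinct relabelings C(n, n1), falls back to exhaustive enumeration
    (B_eff = C(n, n1)), which makes small-sample p-values exact.
    """
    labels = np.asarray(labels, dtype=int)
    n = labels.size
    n1 = int(labels.sum())
    if B < 1:
        raise ValueError("B must be >= 1")
    if n1 == 0 or n1 == n:
        raise ValueError("both classes must be present")
    n_distinct = comb(n, n1)
    if B >= n_distinct:
        log.info("B=%d >= %d distinct relabelings; enumerating exhaustively",
                 B, n_distinct)
        out = np.zeros((n_distinct, n), dtype=int)
        for b, ones in enumerate(combinations(range(n), n1)):
            out[b, list(ones)] = 1
        return out
    rng = np.random.default_rng(seed)
    out = np.zeros((B, n), dtype=int)
    for b in range(B):
        out[b, rng.choice(n, size=n1, replace=False)] = 1
    return out


def permutation_pvalue(observed: float, null_row) -> float:
    """Add-one permutation p-value (1 + #{null ≥ observed}) / (B + 1).

    Never returns 0, which keeps the downstream q-value machinery
    well-behaved; ties count against significance.
    """
    null_row = np.asarray(null_row, dtype=float)
    return (1.0 + float((null_row >= observed).sum())) / (null_row.size + 1.0)


def compute_qvalues(pvalues, method: str = "bh") -> np.ndarray:
    """FDR-adjusted q-values.

    ``"bh"`` is Benjamini–Hochberg step-up (default; monotone,
    parameter-free).  ``"storey"`` rescales BH by Storey's π0 estimate at
    λ = 0.5, clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    q = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return q
    if method == "storey":
        lam = 0.5
        pi0 = min(1.0, (p > lam).mean() / (1.0 - lam))
        return np.minimum(q * pi0, 1.0)
    raise ValueError(f"unknown q-value method {method!r}")


def sam_fdr_qvalues(stats, null_stats, pi0: float = 1.0) -> np.ndarray:
    """SAM-style q-values from the permutation null.

    For the threshold set at the i-th largest observed statistic, the
    false discovery rate is estimated as the *median over permutations*
    of the number of null statistics (pooled over genes) at or above the
    threshold, divided by the number of genes called.  The q-value of a
    gene is the smallest such FDR over all thresholds that call it.
    The median (rather than the mean) is robust to the occasional
    permutation whose label split inflates every statistic at once.
    """
    stats = np.asarray(stats, dtype=float)
    G = stats.size
    order = np.argsort(-stats)
    thresholds = stats[order]
    null_sorted = np.sort(null_stats, axis=0)        # per permutation column
    B = null_sorted.shape[1]
    counts = np.empty((G, B))
    for b in range(B):
        counts[:, b] = null_sorted.shape[0] - np.searchsorted(
            null_sorted[:, b], thresholds, side="left")
    med = np.median(counts, axis=1)
    fdr = np.minimum(pi0 * med / np.arange(1, G + 1), 1.0)
    q_sorted = np.minimum.accumulate(fdr[::-1])[::-1]
    q = np.empty(G)
    q[order] = q_sorted
    return q


@dataclass
class SelectionResult:
    """Screened genes with the permutation machinery retained for reduction.

    ``null_stats`` is the G x B matrix of permuted SAMGS statistics and
    ``null_d`` the B x G x T tensor of permuted SAM statistics; keeping
    the latter lets the reduction step score residual time-point subsets
    against exactly the same permutations.
    """

    sam: SamMatrix
    samgs: np.ndarray
    pvalues: np.ndarray
    qvalues: np.ndarray
    selected: np.ndarray
    null_stats: np.ndarray
    null_d: np.ndarray
    permutations: np.ndarray
    q_cutoff: float

    def to_frame(self, gene_ids=None) -> pd.DataFrame:
        G = self.samgs.size
        ids = gene_ids if gene_ids is not None else list(range(G))
        flag = np.zeros(G, dtype=bool)
        flag[self.selected] = True
        return pd.DataFrame({
            "gene_id": ids,
            "samgs": self.samgs,
            "pvalue": self.pvalues,
            "qvalue": self.qvalues,
            "selected": flag,
        })


def select_genes(
    ds: LongitudinalExpressionSet,
    B: int = 1000,
    q_cutoff: float = 0.05,
    seed: int = 0,
    s0_policy: str = "median",
    qvalue_method: str = "sam",
    null_pooling: str = "pooled",
) -> SelectionResult:
    """Run SAMGS screening: observed statistics, B-permutation null, q-values.

    The fudge constants s0_t are recomputed within every permutation (the
    literal reading of the statistic applied to permuted labels).  Genes
    with no available time point at all get p = q = 1 and are never
    selected.

    ``null_pooling="pooled"`` (default) ranks each observed SAMGS against
    the permuted statistics of *all* genes.  Every longitudinal gene set
    has the same size T, so the permuted statistics are exchangeable
    across genes, and pooling gives p-value granularity 1/(B·G) — without
    it, FDR control at q ≤ α could never select anything unless
    B ≥ G/α.  ``"per_gene"`` ranks each gene only against its own
    permutations (granularity 1/(B+1)).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if ds.labels is None:
        raise ValueError("dataset has no phenotype labels")
    obs = sam_matrix(ds, s0_policy=s0_policy)
    G = ds.n_genes
    with np.errstate(invalid="ignore"):
        samgs = np.nansum(obs.d**2, axis=1)
    dead = ~obs.available.any(axis=1)

    perms = generate_permutations(ds.labels, B, seed)
    B_eff = perms.shape[0]
    null_d = np.empty((B_eff, G, ds.n_times))
    for b in range(B_eff):
        null_d[b] = sam_matrix(ds, labels=perms[b], s0_policy=s0_policy,
                               warn_unavailable=False).d
        if (b + 1) % 200 == 0:
            log.info("permutation %d/%d", b + 1, B_eff)
    with np.errstate(invalid="ignore"):
        null_stats = np.nansum(null_d**2, axis=2).T  # (G, B_eff)

    if null_pooling == "pooled":
        # rank each observed statistic within the pooled null of all genes
        pool = np.sort(null_stats[~dead].ravel())
        n_ge = pool.size - np.searchsorted(pool, samgs, side="left")
        pvalues = (1.0 + n_ge) / (pool.size + 1.0)
    elif null_pooling == "per_gene":
        pvalues = (1.0 + (null_stats >= samgs[:, None]).sum(axis=1)) / (B_eff + 1.0)
    else:
        raise ValueError(f"unknown null_pooling {null_pooling!r}")
    pvalues[dead] = 1.0
    if qvalue_method == "sam":
        qvalues = sam_fdr_qvalues(samgs, null_stats)
        qvalues[dead] = 1.0
    else:
        qvalues = compute_qvalues(pvalues, method=qvalue_method)
    selected = np.flatnonzero((qvalues <= q_cutoff) & ~dead)
    log.info("selected %d/%d genes at q <= %g (B_eff=%d)",
             selected.size, G, q_cutoff, B_eff)
    return SelectionResult(
        sam=obs, samgs=samgs, pvalues=pvalues, qvalues=qvalues,
        selected=selected, null_stats=null_stats, null_d=null_d,
        permutations=perms, q_cutoff=q_cutoff,
    )
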