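"""Synthetic longitudinal case/control expression studies.

The generator emulates the structure the selection algorithm needs: G
genes measured on n subjects at T ordered time points, with within-gene
AR(1) temporal correlation, gene-specific means and variances, and a
binary phenotype generated from a logistic model on a few causal
(gene, time) covariates:

    logit_i = intercept + Σ_j β_j · X_{gene_j, time_j, i},
    p_i = exp(logit_i) / (1 + exp(logit_i)),   Y_i ~ Bernoulli(p_i).

Two study designs are anchored to the trauma-injury application: a
scenario with one gene whose association accumulates over time points
1–4 plus one gene acting only at time 3 (β = 0.18, 0.57, 0.29, 0.41 and
1.02), and a scenario with two genes acting at single time points in
opposite directions (β = 0.56 at time 1 and −0.91 at time 5).  Each uses
2 causal genes plus 998 noise genes and 43 subjects over T = 5.  With a
synthetic base pool the causal covariates are standardized before the
logit so the printed coefficients give comparable effect sizes; with a
user-supplied real expression base, raw values are used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import LongitudinalExpressionSet

__all__ = [
    "SimulationDesign",
    "ReplicateSummary",
    "generate_base_expression",
    "simulate_outcome",
    "build_scenario1",
    "build_scenario2",
    "build_mean_shift_dataset",
    "build_mean_shift_study",
    "run_replicates",
]

log = logging.getLogger(__name__)

SCENARIO1_TERMS = (("causal_joint", 1, 0.18), ("causal_joint", 2, 0.57),
                   ("causal_joint", 3, 0.29), ("causal_joint", 4, 0.41),
                   ("causal_single", 3, 1.02))
SCENARIO2_TERMS = (("causal_up", 1, 0.56), ("causal_down", 5, -0.91))


@dataclass
class SimulationDesign:
    """Causal structure of one simulated study."""

    causal_terms: list  # (gene_id, 1-based time_index, beta)
    n_noise: int
    n_subjects: int
    T: int
    intercept: float = 0.0
    base_source: str = "synthetic"
    standardize: bool = True

    def __post_init__(self) -> None:
        for g, t, b in self.causal_terms:
            if not np.isfinite(b) or b == 0:
                raise ValueError(f"coefficient for ({g}, {t}) must be finite, nonzero")
            if not 1 <= t <= self.T:
                raise ValueError(f"time index {t} outside 1..{self.T}")

    @property
    def causal_genes(self) -> list:
        return list(dict.fromkeys(g for g, _, _ in self.causal_terms))


def generate_base_expression(
    G: int,
    n: int,
    T: int,
    rho: float = 0.5,
    seed: int = 0,
    block_size: int | None = None,
    block_rho: float = 0.0,
) -> LongitudinalExpressionSet:
    """Unlabeled base pool: AR(1) subject trajectories per gene.

    Gene-level means and SDs are drawn from log-normal hyperpriors (means
    around 7 on the log2 microarray scale, SDs around 0.5).  ``rho`` is the
    lag-1 autocorrelation of a subject's trajectory.  Optional
    ``block_size``/``block_rho`` make consecutive genes share a common
    AR(1) latent factor, injecting inter-gene correlation blocks (the
    redundancy structure that inflates selection on real arrays).
    Deterministic given ``seed``.
    """
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mean_g = rng.lognormal(mean=np.log(7.0), sigma=0.15, size=G)
    sd_g = rng.lognormal(mean=np.log(0.5), sigma=0.3, size=G)

    def _ar1(shape_head, seed_rng):
        z = np.empty(shape_head + (T,))
        z[..., 0] = seed_rng.standard_normal(shape_head)
        innov_sd = np.sqrt(1.0 - rho**2)
        for t in range(1, T):
            z[..., t] = rho * z[..., t - 1] + innov_sd * seed_rng.standard_normal(shape_head)
        return z

    z = _ar1((G, n), rng)
    if block_size and block_rho > 0:
        n_blocks = int(np.ceil(G / block_size))
        f = _ar1((n_blocks, n), rng)                       # shared factors
        blocks = np.repeat(np.arange(n_blocks), block_size)[:G]
        z = np.sqrt(block_rho) * f[blocks] + np.sqrt(1 - block_rho) * z
    expr = mean_g[:, None, None] + sd_g[:, None, None] * z
    return LongitudinalExpressionSet(
        expr, np.ones_like(expr, dtype=bool), labels=None)


def simulate_outcome(
    base: LongitudinalExpressionSet,
    design: SimulationDesign,
    seed: int = 0,
    max_retries: int = 20,
) -> np.ndarray:
    """Bernoulli phenotype labels from the logistic model on causal covariates.

    With ``design.standardize`` each causal covariate is centered/scaled
    across subjects before entering the logit.  A degenerate draw (either
    class with fewer than 2 subjects) is resampled with the next seed, up
    to ``max_retries`` times.
    """
    gene_pos = {g: i for i, g in enumerate(base.gene_ids)}
    logit = np.full(base.n_subjects, design.intercept, dtype=float)
    for g, t, beta in design.causal_terms:
        if g not in gene_pos:
            raise ValueError(f"causal gene {g!r} not in base pool")
        x = base.expr[gene_pos[g], :, t - 1].astype(float)
        if design.standardize:
            x = (x - x.mean()) / x.std()
        logit += beta * x
    p = expit(logit)
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        y = rng.binomial(1, p)
        if 2 <= y.sum() <= base.n_subjects - 2:
            if attempt:
                log.info("degenerate outcome draw; succeeded on retry %d", attempt)
            return y
    raise RuntimeError(f"could not draw a non-degenerate outcome in {max_retries} tries")


def _scenario(
    terms,
    seed: int,
    n_subjects: int,
    n_noise: int,
    T: int,
    rho: float,
    base_pool: LongitudinalExpressionSet | None,
    beta_scale: float = 1.0,
    block_size: int | None = None,
    block_rho: float = 0.0,
) -> tuple[LongitudinalExpressionSet, SimulationDesign]:
    terms = [(g, t, b * beta_scale) for g, t, b in terms]
    causal_ids = list(dict.fromkeys(g for g, _, _ in terms))
    rng = np.random.default_rng(seed)
    if base_pool is None:
        base = generate_base_expression(
            n_noise + len(causal_ids), n_subjects, T, rho=rho,
            seed=int(rng.integers(2**31 - 1)),
            block_size=block_size, block_rho=block_rho)
        ids = causal_ids + [f"noise_{i:04d}" for i in range(n_noise)]
        base = LongitudinalExpressionSet(
            base.expr, base.mask, None, gene_ids=ids,
            subject_ids=base.subject_ids, time_ids=base.time_ids)
        standardize, source = True, "synthetic"
    else:
        # draw the noise genes from the pool, never touching the causal ones
        for g in causal_ids:
            if g not in base_pool.gene_ids:
                raise ValueError(f"causal gene {g!r} missing from base pool")
        pool_ids = np.array(base_pool.gene_ids)
        noise_candidates = np.flatnonzero(~np.isin(pool_ids, causal_ids))
        chosen = rng.choice(noise_candidates, size=n_noise, replace=False)
        keep = [base_pool.gene_ids.index(g) for g in causal_ids] + list(chosen)
        base = LongitudinalExpressionSet(
            base_pool.expr[keep], base_pool.mask[keep], None,
            gene_ids=[base_pool.gene_ids[i] for i in keep],
            subject_ids=base_pool.subject_ids, time_ids=base_pool.time_ids)
        standardize, source = False, "real_matrix"
    design = SimulationDesign(
        causal_terms=terms, n_noise=n_noise, n_subjects=base.n_subjects,
        T=T, base_source=source, standardize=standardize)
    labels = simulate_outcome(base, design, seed=int(rng.integers(2**31 - 1)))
    return base.with_labels(labels), design


def build_scenario1(
    seed: int = 0,
    n_subjects: int = 43,
    n_noise: int = 998,
    T: int = 5,
    rho: float = 0.5,
    base_pool: LongitudinalExpressionSet | None = None,
    beta_scale: float = 1.0,
    **kw,
) -> tuple[LongitudinalExpressionSet, SimulationDesign]:
    """Joint-effect scenario: one gene acting over times 1–4, one at time 3."""
    return _scenario(SCENARIO1_TERMS, seed, n_subjects, n_noise, T, rho,
                     base_pool, beta_scale, **kw)


def build_scenario2(
    seed: int = 0,
    n_subjects: int = 43,
    n_noise: int = 998,
    T: int = 5,
    rho: float = 0.5,
    base_pool: LongitudinalExpressionSet | None = None,
    beta_scale: float = 1.0,
    **kw,
) -> tuple[LongitudinalExpressionSet, SimulationDesign]:
    """Opposite-sign scenario: single-timepoint effects at times 1 and 5."""
    return _scenario(SCENARIO2_TERMS, seed, n_subjects, n_noise, T, rho,
                     base_pool, beta_scale, **kw)


def build_mean_shift_dataset(
    G: int = 200,
    n_cases: int = 18,
    n_controls: int = 25,
    T: int = 5,
    causal_gene: int = 0,
    causal_time: int = 3,
    shift_sd: float = 2.0,
    rho: float = 0.5,
    seed: int = 0,
) -> tuple[LongitudinalExpressionSet, tuple[int, int]]:
    """Single-timepoint causal design by direct mean shift.

    Labels are fixed (n_cases ones, n_controls zeros) and the causal gene's
    expression at ``causal_time`` is raised by ``shift_sd`` gene-level SDs
    in the cases.  Returns the labeled dataset and the causal
    (gene_index, 1-based time_index) pair.
    """
    n = n_cases + n_controls
    base = generate_base_expression(G, n, T, rho=rho, seed=seed)
    labels = np.zeros(n, dtype=int)
    labels[:n_cases] = 1
    expr = base.expr.copy()
    t = causal_time - 1
    sd = expr[causal_gene, :, t].std()
    expr[causal_gene, labels == 1, t] += shift_sd * sd
    ds = LongitudinalExpressionSet(expr, base.mask, labels,
                                   gene_ids=list(base.gene_ids))
    return ds, (causal_gene, causal_time)


def build_mean_shift_study(
    G: int = 200,
    n_cases: int = 18,
    n_controls: int = 25,
    n_test_cases: int = 23,
    n_test_controls: int = 50,
    T: int = 5,
    causal_gene: int = 0,
    causal_time: int = 3,
    shift_sd: float = 2.0,
    rho: float = 0.5,
    seed: int = 0,
):
    """Mean-shift design with a held-out test cohort from the same base.

    All subjects are drawn from one base pool (so gene-level means and
    variances agree between cohorts, as they would within one experiment)
    and split into a training and a test dataset.  Returns
    ``(train, test, (gene_index, time_index))``.
    """
    n = n_cases + n_controls + n_test_cases + n_test_controls
    base = generate_base_expression(G, n, T, rho=rho, seed=seed)
    labels = np.zeros(n, dtype=int)
    labels[:n_cases] = 1
    start = n_cases + n_controls
    labels[start:start + n_test_cases] = 1
    expr = base.expr.copy()
    t = causal_time - 1
    sd = expr[causal_gene, :, t].std()
    expr[causal_gene, labels == 1, t] += shift_sd * sd
    ds = LongitudinalExpressionSet(expr, base.mask, labels,
                                   gene_ids=list(base.gene_ids))
    train = ds.subset_subjects(np.arange(start))
    test = ds.subset_subjects(np.arange(start, n))
    return train, test, (causal_gene, causal_time)


@dataclass
class ReplicateSummary:
    """Selection-frequency summary over replicate studies.

    ``freq`` is a (causal gene x time point) table of selection
    percentages; ``genes_per_time`` the average number of genes selected
    at each time point; ``avg_union`` the average number of distinct
    selected genes; ``n_effective`` the replicates that completed.
    """

    freq: pd.DataFrame
    genes_per_time: pd.Series
    avg_union: float
    n_effective: int
    n_requested: int
    failures: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        out = pd.concat([pd.DataFrame([self.genes_per_time.rename("# genes")]),
                         self.freq])
        out.index.name = f"avg_union={self.avg_union:.2f} (R={self.n_effective})"
        return out


def run_replicates(
    builder,
    R: int = 50,
    seed: int = 0,
    B: int = 1000,
    q_cutoff: float = 0.05,
    c_cutoff: float = 0.05,
    s0_policy: str = "median",
    qvalue_method: str = "bh",
    builder_kwargs: dict | None = None,
) -> ReplicateSummary:
    """Replicate a scenario R times through the full selection pipeline.

    Each replicate gets its own derived seed, so the summary is
    independent of execution order.  A replicate that fails is recorded
    and excluded, and the summary reports the effective R.
    """
    from .reduction import reduce_all
    from .selection import select_genes

    builder_kwargs = builder_kwargs or {}
    probe_ds, probe_design = builder(seed=seed, **builder_kwargs)
    T = probe_design.T
    causal = probe_design.causal_genes
    hits = {g: np.zeros(T) for g in causal}
    per_time_counts = np.zeros(T)
    union_sizes = []
    failures = []
    n_done = 0
    for r in range(R):
        rep_seed = (seed + 1000003 * (r + 1)) % (2**31 - 1)
        try:
            ds, design = builder(seed=rep_seed, **builder_kwargs)
            sel = select_genes(ds, B=B, q_cutoff=q_cutoff, seed=rep_seed,
                               s0_policy=s0_policy, qvalue_method=qvalue_method)
            _, table = reduce_all(sel, ds, c_cutoff)
        except Exception as exc:  # noqa: BLE001 - a failed replicate is data
            log.warning("replicate %d failed: %s", r, exc)
            failures.append((r, repr(exc)))
            continue
        n_done += 1
        for t in range(1, T + 1):
            at_t = set(table.loc[table["time_index"] == t, "gene_id"])
            per_time_counts[t - 1] += len(at_t)
            for g in causal:
                if g in at_t:
                    hits[g][t - 1] += 1
        union_sizes.append(table["gene_id"].nunique())
        log.info("replicate %d/%d: %d features", r + 1, R, len(table))
    if n_done == 0:
        raise RuntimeError("every replicate failed")
    cols = [f"time_{t}" for t in range(1, T + 1)]
    freq = pd.DataFrame(
        {g: 100.0 * hits[g] / n_done for g in causal}, index=cols).T
    return ReplicateSummary(
        freq=freq,
        genes_per_time=pd.Series(per_time_counts / n_done, index=cols),
        avg_union=float(np.mean(union_sizes)),
        n_effective=n_done,
        n_requested=R,
        failures=failures,
    )
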