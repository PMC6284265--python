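# Methods

## The model

`longsamgsr` selects phenotype-associated genes from longitudinal
case/control expression experiments by treating each gene's trajectory
across the T time points as a gene set and applying a two-step gene-set
reduction.

**Step 1 — screening.** For gene g at time point t the moderated
statistic is

    d_t = (x̄_d(t) − x̄_c(t)) / (s(t) + s0_t)

with x̄_d, x̄_c the class means (label 1 = diseased in the numerator's
positive direction), s(t) the two-sample pooled standard deviation

    s = sqrt(a (Σ_d (x − x̄_d)² + Σ_c (x − x̄_c)²)),
    a = (1/n_d + 1/n_c) / (n_d + n_c − 2),

and s0_t a small positive fudge constant.  Both s(t) and s0_t are
time-point specific because measurement variability may drift over time.
The gene-set statistic is SAMGS_g = Σ_t d_t².  Its null distribution
comes from permuting the subject-level phenotype labels: a subject's
whole trajectory moves between classes as one unit, which preserves the
within-subject temporal correlation under the null.  When the requested
number of permutations B reaches the number of distinct relabelings
C(n, n1), enumeration becomes exhaustive and small-sample p-values are
exact.  Genes are screened at a false-discovery cutoff (default
q ≤ 0.05).

**Step 2 — reduction.** For each screened gene, time points are ranked
by |d_t| (descending; ties broken toward the earlier time point;
time points without a valid statistic rank last and can never enter the
core).  After the top k time points enter the reduced set, c_k is the
permutation p-value of the *residual* subset's SAMGS statistic (the sum
of d_t² over the remaining time points), evaluated against the same
stored permutations as step 1.  The core size k\* is the smallest k with
c_k above a cutoff; if no residual ever becomes null the whole
trajectory is kept.  This enforces the monotone-entry property: a time
point can enter the core only after every time point with a larger |d|.

**Tuning.** The c_k cutoff is the algorithm's tuning parameter.  Over
the grid 0.05, 0.10, …, 0.50 it is chosen by minimum 5-fold
cross-validated misclassification error of the averaged-posterior
classifier described below; ties break toward the smallest cutoff
(fewer features).  Folds are stratified by phenotype at the subject
level, and screening is re-run inside each training fold so selection
bias does not leak into the CV error.  After tuning, one full-data run
with the chosen cutoff produces the final feature table.

## Evaluation scheme

Per-timepoint evaluation would be unfair to a method built to find
effects that are weak at any single time point, so performance is
computed on time-averaged posteriors: a linear SVM (C = 1 by default) is
fit per time point on that time point's expression restricted to its
selected genes; posterior probabilities of the diseased class come from
a Platt-style sigmoid fit to the training decision values; a subject's
posteriors are averaged over their available time points (time points
with no selected genes contribute an uninformative 0.5).  Four summary
statistics are reported: misclassification error at threshold 0.5 and
the generalized Brier score (both 0-optimal), and the belief confusion
metric and area under the precision-recall curve (both 1-optimal).  GBS
and BCM are reconstructions — the literature that names them states
only their [0, 1] ranges and optimum directions — implemented as the
binary Brier score and the mean posterior probability of the true
class, which satisfy every stated property.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `n_permutations` (B) | 1000 | subject-label permutations; exhaustive below C(n, n1) |
| `q_cutoff` | 0.05 | FDR screening level, step 1 |
| `c_cutoff` | tuned on 0.05–0.50 | residual-significance cutoff, step 2 |
| `cv_folds` | 5 | folds for cutoff tuning |
| `s0_policy` | `median` | fudge constant: median pooled SD, or `percentile` search |
| `qvalue_method` | `sam` | FDR machinery (see below); `bh`, `storey` available |
| `svm_C` | 1.0 | linear-SVM regularization in the evaluation scheme |

## Numerical and design choices

- **Fudge constant.** The literature calls s0 only "a small positive
  constant".  Default is the median of the pooled SDs at that time point
  — parameter-free and scale-equivariant, so d is invariant to rescaling
  the expression matrix.  The classic percentile search (minimizing the
  coefficient of variation of d across SD bins over percentile
  candidates of s) is available as `s0_policy="percentile"`.  This is
  the largest numeric-reproducibility unknown of the whole procedure.
- **Screening p-values** are ranked against the permutation null pooled
  across genes (granularity 1/(B·G)).  Pooling is justified here because
  every longitudinal gene set has the same size T, making the permuted
  statistics exchangeable across genes; without it, a p-value floor of
  1/(B+1) makes FDR selection impossible unless B ≥ G/α.  Per-gene
  ranking (the floor-limited estimator) remains available
  (`null_pooling="per_gene"`) and is what the reduction step's c_k uses,
  where no multiplicity correction is applied.
- **q-values.** Default is the SAM-heritage estimator: for a calling
  threshold, FDR = (median over permutations of the pooled count of
  null statistics at or above the threshold) / (number called); a
  gene's q is the minimum FDR over thresholds that call it.  The median
  is essential: with temporally correlated trajectories, an occasional
  permutation inflates every gene's d_t at once, and a mean-based (or
  BH-on-p) rule is dominated by those rare splits.  Benjamini–Hochberg
  and Storey's λ = 0.5 estimator are available as `"bh"`/`"storey"`.
- **Permutation reuse.** Step 2 evaluates c_k against the permutations
  stored in step 1 rather than fresh draws, so the whole run is
  deterministic given one seed and the two steps are mutually
  consistent.  s0_t is recomputed inside every permutation.
- **Missing data** are carried as an explicit mask and handled
  available-case per (gene, time) cell.  A cell with fewer than two
  measured samples in either class is flagged unavailable: it
  contributes 0 to SAMGS sums, ranks last in the reduction ordering,
  and is excluded from classifier features.  Tie-breaks and degenerate
  inputs (T = 1, empty selections, single-class training slices) follow
  the rules asserted in the test suite.

## The synthetic-data generator

The generator emulates the structure the algorithm consumes, not any
particular microarray platform: gene-level means and SDs drawn from
log-normal hyperpriors (means near 7 on a log2-like scale, SDs near
0.5), subject trajectories with AR(1) autocorrelation (default
ρ = 0.5, a realistic persistence for day-scale clinical sampling), and
an optional block-factor structure that injects inter-gene correlation.
Phenotypes follow a logistic model on a few causal (gene, time)
covariates; the two anchored scenarios use the coefficient sets
(0.18, 0.57, 0.29, 0.41 over times 1–4 plus 1.02 at time 3) and
(0.56 at time 1, −0.91 at time 5), with 998 noise genes and 43 subjects
by default.  With a synthetic base the causal covariates are
standardized before the logit so the printed coefficients have
comparable meaning regardless of the base scale; with a user-supplied
real expression pool, raw values are used.  Noise genes are re-drawn
independently per replicate.

What the generator does **not** reproduce: the dense inter-gene
correlation of real arrays (except through the explicit block knob),
probe-level artifacts, batch effects, or heavy-tailed expression noise.
Consequently the scenario replicate studies select far fewer redundant
genes than the same designs run on real expression bases, and passing
tests demonstrate correctness of the machinery and calibration under
the stated generative model, not field performance on any particular
platform.

## Study sizes used by `scripts/acceptance.py`

The script reruns the pipeline at desk scale on one CPU: null
calibration at G = 500, n = 20/20, T = 3, B = 500 over 50 seeds;
single-timepoint recovery at G = 200, n = 18/25, T = 5, B = 200 over 20
replicates; scenario replicate studies at the full G = 1000 with
B = 300 and R = 20 (instead of R = 50); and a 43-train / 73-test
demonstration study with a 3-SD single-timepoint effect for the four
performance statistics.

## Known limitations

- Power for effects concentrated at a single time point is bounded by
  the heavy tail of the permutation null under strong within-subject
  correlation: a lucky label split inflates a noise gene's d_t at every
  time point simultaneously, so null SAMGS is much heavier-tailed than
  a χ²_T.  This is intrinsic to the statistic, and it is also why the
  method's comparative advantage is for *joint* trajectories.
- Like any marginal filter, the method cannot exclude genes merely
  correlated with causal ones; on correlated bases the selected union
  inflates (demonstrated by the block-correlation knob).
- The method assumes expression is already normalized/summarized; no
  normalization, probe collapsing or annotation is performed.
- GBS/BCM are reconstructions as flagged above.
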