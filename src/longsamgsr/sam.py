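"""Per-gene, per-time-point SAM statistics.

The moderated statistic for gene g at time point t is

    d_t = (x̄_d(t) − x̄_c(t)) / (s(t) + s0_t)

where x̄_d and x̄_c are the class means (diseased = label 1 in the
numerator's positive direction), s(t) is the two-sample pooled standard
deviation estimated from the samples at that time point, and s0_t is a
small positive "fudge" constant that keeps low-variance genes from
dominating.  Both s(t) and s0_t are time-point specific because the
measurement variability may differ over time.

Missing measurements are handled available-case per (gene, time) cell: a
cell with fewer than two samples in either class has no pooled SD and is
flagged unavailable (NaN in ``d``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data import LongitudinalExpressionSet

__all__ = ["SamMatrix", "pooled_sd", "fudge_factor", "sam_statistic", "sam_matrix"]

# absolute floor for the fudge constant when every pooled SD is zero
_S0_FLOOR = 1e-9


class InsufficientDataError(ValueError):
    """A (gene, time) cell has fewer than 2 samples in one of the classes."""


@dataclass
class SamMatrix:
    """SAM statistics and their nuisance quantities for a whole dataset.

    ``d``, ``s``, ``mean_d``, ``mean_c`` are G x T (NaN where unavailable);
    ``s0`` is length T; ``available`` is a G x T boolean matrix, True where
    both classes had >= 2 measured samples.
    """

    d: np.ndarray
    s: np.ndarray
    s0: np.ndarray
    mean_d: np.ndarray
    mean_c: np.ndarray
    available: np.ndarray

    def __post_init__(self) -> None:
        assert (self.s0 > 0).all(), "fudge constants must be strictly positive"
        assert np.all(self.s[self.available] >= 0)
        assert np.isfinite(self.d[self.available]).all()


def pooled_sd(values_d, values_c) -> float:
    """Two-sample pooled standard deviation of the SAM statistic.

    s = sqrt(a * (SS_d + SS_c)),  a = (1/n_d + 1/n_c) / (n_d + n_c − 2)
    """
    xd = np.asarray(values_d, dtype=float)
    xc = np.asarray(values_c, dtype=float)
    nd, nc = len(xd), len(xc)
    if nd < 2 or nc < 2:
        raise InsufficientDataError(
            f"pooled SD needs >= 2 samples per class (got {nd} and {nc})")
    a = (1.0 / nd + 1.0 / nc) / (nd + nc - 2)
    ss = np.sum((xd - xd.mean()) ** 2) + np.sum((xc - xc.mean()) ** 2)
    return float(np.sqrt(a * ss))


def fudge_factor(s_column, d_numerators=None, policy: str = "median") -> float:
    """Fudge constant s0 for one time point, from that time point's pooled SDs.

    ``policy="median"`` (default) returns the median pooled SD — simple,
    parameter-free and scale-equivariant.  ``policy="percentile"`` runs the
    classic percentile search: among candidate percentiles of the SD
    distribution, pick the s0 that minimizes the coefficient of variation
    of the resulting d values across SD bins (requires ``d_numerators``,
    the per-gene mean differences at this time point).  Always strictly
    positive: floored at a tiny constant when all SDs are zero.
    """
    s = np.asarray(s_column, dtype=float)
    s = s[np.isfinite(s)]
    if s.size == 0:
        raise ValueError("no finite pooled SDs to estimate s0 from")
    if policy == "median":
        return max(float(np.median(s)), _S0_FLOOR)
    if policy == "percentile":
        if d_numerators is None:
            raise ValueError("percentile policy needs the per-gene mean differences")
        num = np.asarray(d_numerators, dtype=float)
        ok = np.isfinite(num)
        num, sv = num[ok], np.asarray(s_column, dtype=float)[ok]
        if num.size < 10:  # too few genes to bin; fall back
            return max(float(np.median(s)), _S0_FLOOR)
        candidates = np.percentile(sv, np.arange(0, 101, 5))
        n_bins = min(10, max(2, num.size // 5))
        bins = np.quantile(sv, np.linspace(0, 1, n_bins + 1))
        which = np.clip(np.searchsorted(bins, sv, side="right") - 1, 0, n_bins - 1)
        best, best_cv = None, np.inf
        for s0 in candidates:
            if s0 + sv.min() <= 0:
                continue
            d = num / (sv + s0)
            mads = np.array([
                np.median(np.abs(d[which == b] - np.median(d[which == b]))) / 0.64
                for b in range(n_bins) if (which == b).any()
            ])
            if mads.mean() == 0:
                continue
            cv = mads.std() / mads.mean()
            if cv < best_cv:
                best, best_cv = s0, cv
        if best is None or best <= 0:
            return max(float(np.median(s)), _S0_FLOOR)
        return float(best)
    raise ValueError(f"unknown s0 policy {policy!r}")


def sam_statistic(values_d, values_c, s0: float) -> float:
    """SAM statistic (mean(d) − mean(c)) / (pooled SD + s0) for one cell."""
    xd = np.asarray(values_d, dtype=float)
    xc = np.asarray(values_c, dtype=float)
    s = pooled_sd(xd, xc)
    return float((xd.mean() - xc.mean()) / (s + s0))


def sam_matrix(
    ds: LongitudinalExpressionSet,
    labels: np.ndarray | None = None,
    s0_policy: str = "median",
    warn_unavailable: bool = True,
) -> SamMatrix:
    """Vectorized SAM statistics for every (gene, time) cell.

    ``labels`` defaults to ``ds.labels``; passing permuted labels
    explicitly is what makes permutation-test reuse possible.  Cells where
    either class has fewer than 2 measured samples are NaN and flagged in
    ``available`` (a count is warned once per call).
    """
    if labels is None:
        ds.validate_for_analysis()
        labels = ds.labels
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (ds.n_subjects,):
        raise ValueError("labels must give one 0/1 value per subject")

    def _class_moments(cls: int):
        sel = labels == cls
        x = ds.expr[:, sel, :]
        m = ds.mask[:, sel, :]
        n = m.sum(axis=1)                                 # (G, T)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.where(n > 0, (x * m).sum(axis=1) / np.maximum(n, 1), np.nan)
            ss = (m * (x - mean[:, None, :]) ** 2).sum(axis=1)
        return n, mean, ss

    nd, mean_d, ss_d = _class_moments(1)
    nc, mean_c, ss_c = _class_moments(0)
    available = (nd >= 2) & (nc >= 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (1.0 / nd + 1.0 / nc) / (nd + nc - 2)
        s = np.sqrt(a * (ss_d + ss_c))
    s = np.where(available, s, np.nan)

    T = ds.n_times
    s0 = np.empty(T)
    for t in range(T):
        col = s[:, t]
        if not np.isfinite(col).any():
            raise InsufficientDataError(
                f"no (gene, time) cell at time point {ds.time_ids[t]!r} has "
                "2 samples per class")
        s0[t] = fudge_factor(col[np.isfinite(col)],
                             d_numerators=(mean_d - mean_c)[:, t][np.isfinite(col)],
                             policy=s0_policy)

    with np.errstate(invalid="ignore"):
        d = (mean_d - mean_c) / (s + s0[None, :])
    d = np.where(available, d, np.nan)

    n_missing = int((~available).sum())
    if n_missing and warn_unavailable:
        warnings.warn(
            f"{n_missing} (gene, time) cells lack 2 samples per class and are "
            "excluded from SAM statistics", stacklevel=2)
    return SamMatrix(d=d, s=s, s0=s0, mean_d=mean_d, mean_c=mean_c,
                     available=available)
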