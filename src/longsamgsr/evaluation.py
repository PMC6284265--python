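"""Per-timepoint SVM classifiers, averaged posteriors and the four metrics.

A selected feature table is turned into one linear SVM per time point
(trained on that time point's expression restricted to its selected
genes).  Posterior probabilities of the diseased class are obtained by a
Platt-style sigmoid fit on the training decision values, averaged over a
subject's available time points, and summarized by four statistics:

* misclassification error (0 optimal),
* GBS, the generalized Brier score: mean squared probability error
  (0 optimal),
* BCM, the belief confusion metric: mean posterior probability assigned
  to the true class (1 optimal),
* AUPR, area under the precision-recall curve with the diseased class
  as positive (1 optimal).

GBS and BCM are reconstructions: the source literature states only their
[0, 1] ranges and optimum directions, and the definitions here are the
standard probability-scoring quantities matching those properties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score
from sklearn.svm import SVC

from .data import LongitudinalExpressionSet

__all__ = [
    "PerformanceReport",
    "fit_timepoint_classifiers",
    "predict_posteriors",
    "average_posteriors",
    "gbs",
    "bcm",
    "aupr",
    "misclassification_error",
    "evaluate",
]

# direction metadata: True means larger is better
METRIC_DIRECTIONS = {"error": False, "gbs": False, "bcm": True, "aupr": True}


@dataclass
class TimepointClassifier:
    """Linear SVM + sigmoid calibration for one time point's gene panel."""

    genes: np.ndarray
    svm: SVC
    calibrator: LogisticRegression

    def posterior(self, X: np.ndarray) -> np.ndarray:
        dec = self.svm.decision_function(X)
        return self.calibrator.predict_proba(dec.reshape(-1, 1))[:, 1]


def fit_timepoint_classifiers(
    train: LongitudinalExpressionSet,
    features: list[np.ndarray],
    C: float = 1.0,
) -> list[TimepointClassifier | None]:
    """Fit one probability-calibrated linear SVM per time point.

    ``features[t]`` is the gene index list selected at time point t; a time
    point with an empty list gets ``None`` (it will contribute a constant,
    uninformative posterior of 0.5).  Training at t uses the subjects whose
    selected genes are all measured at t.
    """
    out: list[TimepointClassifier | None] = []
    for t in range(train.n_times):
        genes = np.asarray(features[t], dtype=int)
        if genes.size == 0:
            out.append(None)
            continue
        subj_ok = train.mask[np.ix_(genes, np.arange(train.n_subjects), [t])][:, :, 0].all(axis=0)
        y = train.labels[subj_ok]
        if np.unique(y).size < 2:
            raise ValueError(f"time point {t + 1}: training slice has one class")
        X = train.expr[np.ix_(genes, np.flatnonzero(subj_ok), [t])][:, :, 0].T
        svm = SVC(kernel="linear", C=C)
        svm.fit(X, y)
        dec = svm.decision_function(X).reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            cal = LogisticRegression(C=1e6).fit(dec, y)
        out.append(TimepointClassifier(genes=genes, svm=svm, calibrator=cal))
    return out


def predict_posteriors(
    classifiers: list[TimepointClassifier | None],
    ds: LongitudinalExpressionSet,
) -> tuple[np.ndarray, np.ndarray]:
    """Class-1 posterior per (subject, time); second array flags availability.

    Time points beyond ``len(classifiers)`` (or without a classifier) give
    0.5; a subject missing any of the panel genes at t is unavailable
    there.
    """
    n, T = ds.n_subjects, ds.n_times
    probs = np.full((n, T), 0.5)
    avail = np.zeros((n, T), dtype=bool)
    for t in range(T):
        clf = classifiers[t] if t < len(classifiers) else None
        if clf is None:
            # uninformative but defined wherever the subject was measured
            avail[:, t] = ds.mask[:, :, t].any(axis=0)
            continue
        ok = ds.mask[np.ix_(clf.genes, np.arange(n), [t])][:, :, 0].all(axis=0)
        if ok.any():
            X = ds.expr[np.ix_(clf.genes, np.flatnonzero(ok), [t])][:, :, 0].T
            probs[ok, t] = clf.posterior(X)
        avail[:, t] = ok
    return probs, avail


def average_posteriors(probs: np.ndarray, avail: np.ndarray) -> np.ndarray:
    """Mean posterior over each subject's available time points.

    Subjects with no available time point get NaN and a warning; callers
    exclude them.
    """
    counts = avail.sum(axis=1)
    if (counts == 0).any():
        warnings.warn(f"{int((counts == 0).sum())} subject(s) have no available "
                      "posterior and are excluded", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = (probs * avail).sum(axis=1) / counts
    return np.where(counts > 0, out, np.nan)


def gbs(posterior, labels) -> float:
    """Generalized Brier score: mean over subjects of (p − y)²; 0 optimal."""
    p = np.asarray(posterior, dtype=float)
    y = np.asarray(labels, dtype=float)
    return float(np.mean((p - y) ** 2))


def bcm(posterior, labels) -> float:
    """Belief confusion metric: mean probability assigned to the true class;
    1 optimal."""
    p = np.asarray(posterior, dtype=float)
    y = np.asarray(labels, dtype=float)
    return float(np.mean(y * p + (1 - y) * (1 - p)))


def aupr(posterior, labels) -> float:
    """Area under the precision-recall curve (step-wise sum), class 1 positive."""
    return float(average_precision_score(np.asarray(labels), np.asarray(posterior)))


def misclassification_error(posterior, labels, threshold: float = 0.5) -> float:
    """Fraction of subjects whose thresholded posterior disagrees with the label."""
    p = np.asarray(posterior, dtype=float)
    y = np.asarray(labels, dtype=int)
    return float(np.mean((p >= threshold).astype(int) != y))


@dataclass
class PerformanceReport:
    error: float
    gbs: float
    bcm: float
    aupr: float
    per_sample_posterior: pd.Series = field(repr=False)
    directions: dict = field(default_factory=lambda: dict(METRIC_DIRECTIONS),
                             repr=False)

    def to_dict(self) -> dict:
        return {"error": self.error, "gbs": self.gbs,
                "bcm": self.bcm, "aupr": self.aupr}


def evaluate(
    train: LongitudinalExpressionSet,
    test: LongitudinalExpressionSet,
    features: list[np.ndarray],
    C: float = 1.0,
) -> PerformanceReport:
    """Fit per-timepoint classifiers on ``train``, score ``test``.

    The test set may observe fewer time points than the training set
    (subjects discharged early); averaging simply runs over the time
    points the test set has.
    """
    clfs = fit_timepoint_classifiers(train, features, C=C)
    probs, avail = predict_posteriors(clfs, test)
    post = average_posteriors(probs, avail)
    ok = np.isfinite(post)
    y = test.labels[ok]
    p = post[ok]
    return PerformanceReport(
        error=misclassification_error(p, y),
        gbs=gbs(p, y),
        bcm=bcm(p, y),
        aupr=aupr(p, y),
        per_sample_posterior=pd.Series(
            post, index=pd.Index(test.subject_ids, name="subject_id"),
            name="posterior"),
    )
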