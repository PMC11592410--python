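"""Diagnostic-accuracy statistics for non-invasive fibrosis tests.

Everything a diagnostic-accuracy table needs, implemented on the empirical
(nonparametric) ROC model:

* confusion-matrix metrics (sensitivity, specificity, PPV, NPV, accuracy)
  and prevalence-based predictive values via Bayes' theorem;
* the empirical ROC curve with tie handling, where the AUROC equals the
  Mann–Whitney statistic — the probability that a random diseased subject
  outscores a random non-diseased one, ties counted 1/2;
* the Youden-optimal operating cutoff (maximising J = sens + spec − 1);
* the DeLong variance estimator for a single AUROC (normal-approximation
  CI) and the paired DeLong z-test for comparing two correlated AUROCs;
* tie-aware Spearman rank correlation of a score with ordinal fibrosis
  stage.

Orientation is fixed throughout as "higher score = more diseased", which
holds for all the serum indices handled here (APRI, FIB-4, NFS, ELF). An
AUROC below 0.5 is reported as-is with a warning, never auto-flipped.

Undefined ratios (empty margins) are reported as NaN, never coerced to 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import DomainError
from .scores import stage_index

__all__ = [
    "ConfusionMatrix",
    "DiagnosticSummary",
    "ROCResult",
    "summarize",
    "predictive_values",
    "auroc_mann_whitney",
    "empirical_auroc",
    "youden_cutoff",
    "delong",
    "delong_compare",
    "spearman",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/FP/FN/TN counts for a binary test against binary truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise DomainError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @classmethod
    def from_predictions(cls, truth: Sequence[bool], predicted: Sequence[bool]) -> "ConfusionMatrix":
        truth = np.asarray(truth, dtype=bool)
        predicted = np.asarray(predicted, dtype=bool)
        if truth.shape != predicted.shape:
            raise DomainError("truth and predicted must have the same length")
        return cls(
            tp=int(np.sum(truth & predicted)),
            fp=int(np.sum(~truth & predicted)),
            fn=int(np.sum(truth & ~predicted)),
            tn=int(np.sum(~truth & ~predicted)),
        )


@dataclass(frozen=True)
class DiagnosticSummary:
    """Derived accuracy metrics; undefined ratios are NaN."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    prevalence: float


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else float("nan")


def summarize(cm: ConfusionMatrix) -> DiagnosticSummary:
    """Standard accuracy metrics from a confusion matrix.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
    NPV = TN/(TN+FN), accuracy = (TP+TN)/total, prevalence = (TP+FN)/total.
    A metric whose margin is empty is NaN; an all-zero matrix is a domain
    error.
    """
    if cm.total == 0:
        raise DomainError("confusion matrix is all zero; no subjects to summarize")
    return DiagnosticSummary(
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
        accuracy=(cm.tp + cm.tn) / cm.total,
        prevalence=(cm.tp + cm.fn) / cm.total,
    )


def predictive_values(sensitivity: float, specificity: float, prevalence: float) -> Tuple[float, float]:
    """PPV and NPV at a given prevalence, by Bayes' theorem.

    ppv = s*p / (s*p + (1-spec)(1-p));
    npv = spec*(1-p) / (spec*(1-p) + (1-s)*p).
    A zero denominator yields NaN for that value.
    """
    for name, v in (("sensitivity", sensitivity), ("specificity", specificity), ("prevalence", prevalence)):
        if not (0.0 <= v <= 1.0):
            raise DomainError(f"{name} must lie in [0, 1], got {v}")
    ppv_den = sensitivity * prevalence + (1 - specificity) * (1 - prevalence)
    npv_den = specificity * (1 - prevalence) + (1 - sensitivity) * prevalence
    ppv = sensitivity * prevalence / ppv_den if ppv_den > 0 else float("nan")
    npv = specificity * (1 - prevalence) / npv_den if npv_den > 0 else float("nan")
    return ppv, npv


@dataclass(frozen=True)
class ROCResult:
    """Empirical ROC curve with its AUROC, DeLong CI and Youden cutoff.

    ``points`` is an (n, 3) array of (threshold, sensitivity, 1-specificity)
    rows sorted by descending threshold; the curve runs from (0, 0) at
    threshold +inf to (1, 1) below the minimum score, and its trapezoidal
    area equals ``auroc`` exactly (ties produce diagonal segments).
    """

    points: np.ndarray
    auroc: float
    delong_variance: float
    ci_low: float
    ci_high: float
    youden_cutoff: float
    youden_j: float

    @property
    def ci95(self) -> Tuple[float, float]:
        return (self.ci_low, self.ci_high)


def _validate_scores_labels(scores, labels, min_per_class: int = 1):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise DomainError("scores and labels must be 1-D of equal length")
    if np.any(np.isnan(scores)):
        raise DomainError("scores contain NaN")
    m = int(labels.sum())
    n = int((~labels).sum())
    if m < min_per_class or n < min_per_class:
        raise DomainError(
            f"need at least {min_per_class} subject(s) per class, got {m} positive / {n} negative"
        )
    return scores, labels, m, n


def auroc_mann_whitney(scores, labels) -> float:
    """AUROC as the tie-corrected Mann–Whitney statistic (rank formula)."""
    scores, labels, m, n = _validate_scores_labels(scores, labels)
    ranks = stats.rankdata(scores)  # midranks
    return (ranks[labels].sum() - m * (m + 1) / 2) / (m * n)


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components via midranks.

    Returns (V10, V01, auc): V10[i] is the mean kernel psi of positive i
    against all negatives (psi = 1 if pos > neg, 1/2 if tied, 0 otherwise);
    V01[j] likewise per negative. Both have mean equal to the AUROC.
    """
    pos = scores[labels]
    neg = scores[~labels]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(scores)
    v10 = (all_ranks[labels] - stats.rankdata(pos)) / n
    v01 = 1.0 - (all_ranks[~labels] - stats.rankdata(neg)) / m
    auc = v10.mean()
    return v10, v01, auc


def delong(scores, labels) -> Tuple[float, float, Tuple[float, float]]:
    """AUROC with DeLong variance and a 95% normal-approximation CI.

    variance = var(V10)/m + var(V01)/n with unbiased (n−1 denominator)
    sample variances of the placement values; ci95 = auroc ± 1.96*sqrt(var),
    clipped to [0, 1]. Requires at least two subjects per class.
    """
    scores, labels, m, n = _validate_scores_labels(scores, labels, min_per_class=2)
    v10, v01, auc = _placements(scores, labels)
    variance = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    half = 1.959963984540054 * math.sqrt(variance)
    ci = (max(0.0, auc - half), min(1.0, auc + half))
    return float(auc), float(variance), ci


def empirical_auroc(scores, labels) -> ROCResult:
    """Full empirical ROC analysis of one score against binary truth.

    Operating points are evaluated at every observed score value with the
    positivity rule "score > threshold" (plus the degenerate all-negative
    point at +inf), so the stored curve is the exact empirical step function
    and its trapezoidal area equals the Mann–Whitney AUROC with ties
    counted 1/2.
    """
    scores, labels, m, n = _validate_scores_labels(scores, labels)
    thresholds = np.unique(scores)[::-1]  # descending
    sens = np.empty(len(thresholds) + 1)
    fpr = np.empty(len(thresholds) + 1)
    sens[0] = 0.0
    fpr[0] = 0.0
    pos = scores[labels]
    neg = scores[~labels]
    for i, t in enumerate(thresholds, start=1):
        sens[i] = np.mean(pos > t)
        fpr[i] = np.mean(neg > t)
    # trapezoid over the tie-corrected curve; with a final implicit (1,1)
    # vertex below the minimum observed score
    # the rank (Mann–Whitney) formula gives exact tie semantics; the
    # trapezoid over the stored points agrees with it up to float roundoff
    auc = float(auroc_mann_whitney(scores, labels))
    if auc < 0.5:
        warnings.warn(
            f"AUROC {auc:.3f} < 0.5 under the fixed 'higher score = diseased' orientation; "
            "reported as-is (no auto-flip)",
            stacklevel=2,
        )
    if m >= 2 and n >= 2:
        _, variance, ci = delong(scores, labels)
    else:
        variance, ci = float("nan"), (float("nan"), float("nan"))
    cutoff, j = youden_cutoff(scores, labels)
    points = np.column_stack([np.concatenate([[np.inf], thresholds]), sens, fpr])
    return ROCResult(
        points=points,
        auroc=auc,
        delong_variance=variance,
        ci_low=ci[0],
        ci_high=ci[1],
        youden_cutoff=cutoff,
        youden_j=j,
    )


def youden_cutoff(scores, labels, candidates: str = "observed") -> Tuple[float, float]:
    """Cutoff maximising the Youden index J = sensitivity + specificity − 1.

    Candidate cutoffs are the observed score values (``candidates="observed"``,
    the default, matching the convention of quoting a published cutoff as
    "positive if score > c") or the midpoints between consecutive distinct
    values (``candidates="midpoint"``). Ties in J are broken toward the
    higher sensitivity, then toward the smaller cutoff.
    """
    scores, labels, m, n = _validate_scores_labels(scores, labels)
    values = np.unique(scores)
    if candidates == "observed":
        cands = values
    elif candidates == "midpoint":
        cands = (values[:-1] + values[1:]) / 2 if len(values) > 1 else values
    else:
        raise DomainError(f"candidates must be 'observed' or 'midpoint', got {candidates!r}")
    pos = scores[labels]
    neg = scores[~labels]
    best = None
    for c in cands:
        s = float(np.mean(pos > c))
        sp = float(np.mean(neg <= c))
        j = s + sp - 1.0
        key = (j, s, -c)
        if best is None or key > best[0]:
            best = (key, float(c), j)
    return best[1], best[2]


def delong_compare(scores_a, scores_b, labels) -> Tuple[float, float, float]:
    """Paired DeLong test for the difference of two correlated AUROCs.

    Both score vectors must be measured on the same subjects. Returns
    (delta_auroc, z, p) with z = (A_a − A_b)/sqrt(var_a + var_b − 2 cov),
    the covariance estimated from the paired placement values, and a
    two-sided p from the standard normal. Identical score vectors give
    delta 0 and p = 1; a zero-variance difference with nonzero delta is
    reported as p = 0 with a warning.
    """
    scores_a, labels_arr, m, n = _validate_scores_labels(scores_a, labels, min_per_class=2)
    scores_b, _, _, _ = _validate_scores_labels(scores_b, labels, min_per_class=2)
    v10_a, v01_a, auc_a = _placements(scores_a, labels_arr)
    v10_b, v01_b, auc_b = _placements(scores_b, labels_arr)
    delta = float(auc_a - auc_b)
    var_a = v10_a.var(ddof=1) / m + v01_a.var(ddof=1) / n
    var_b = v10_b.var(ddof=1) / m + v01_b.var(ddof=1) / n
    cov = float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / m + float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) / n
    var_diff = var_a + var_b - 2.0 * cov
    if delta == 0.0:
        return 0.0, 0.0, 1.0
    if var_diff <= 0.0:
        warnings.warn(
            "zero estimated variance of the AUROC difference with nonzero delta; p reported as 0",
            stacklevel=2,
        )
        return delta, math.copysign(math.inf, delta), 0.0
    z = delta / math.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return delta, float(z), float(p)


def spearman(scores, stages) -> Tuple[float, float]:
    """Tie-aware Spearman rank correlation of a score with ordinal stage.

    ``stages`` may be CRN tokens (F0…F4) or numbers. rho is the Pearson
    correlation of midranks; the two-sided p comes from the t approximation
    with n − 2 degrees of freedom. Zero rank variance on either side gives
    (NaN, NaN).
    """
    scores = np.asarray(scores, dtype=float)
    stage_vals = np.asarray(
        [stage_index(s) if isinstance(s, str) else float(s) for s in stages], dtype=float
    )
    if scores.shape != stage_vals.shape or scores.ndim != 1:
        raise DomainError("scores and stages must be 1-D of equal length")
    n = len(scores)
    if n < 3:
        raise DomainError(f"need at least 3 subjects for a rank correlation, got {n}")
    rx = stats.rankdata(scores)
    ry = stats.rankdata(stage_vals)
    sx = rx.std(ddof=1)
    sy = ry.std(ddof=1)
    if sx == 0.0 or sy == 0.0:
        return float("nan"), float("nan")
    rho = float(np.cov(rx, ry, ddof=1)[0, 1] / (sx * sy))
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return rho, float(p)
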