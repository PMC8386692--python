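"""Diagnostic-accuracy statistics.

Cohort assembly for the two analysis endpoints (MS vs non-MS; OCB positive
vs negative), 2x2 contingency metrics with Wilson score confidence
intervals, the empirical ROC curve with tie-corrected AUC, Youden-optimal
cutoff selection and the Mann-Whitney two-sample comparison.

Conventions
-----------
* Classification rule for a score s at threshold t is strictly ``s > t``,
  matching the clinical cutoff notation ">3.045", ">6.6", ">12.58".
* ROC candidate thresholds are the midpoints between adjacent distinct
  score values plus one sentinel below the minimum and one above the
  maximum, so the curve always contains the (1, 0) and (0, 1) corners.
* AUC is the tie-corrected probabilistic statistic
  ``P(score_pos > score_neg) + 0.5 * P(score_pos = score_neg)``,
  identical to U / (n_pos * n_neg) with midrank ties.
* Confidence intervals are Wilson score without continuity correction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core import (
    DegenerateSetError,
    Diagnosis,
    DomainError,
    InvalidRecordError,
    PatientRecord,
    ocb_positive,
)


class Endpoint(str, Enum):
    """Analysis endpoint defining the reference (label) classes."""

    MS_VS_NONMS = "MS_vs_nonMS"
    OCB_POS_VS_NEG = "OCB_pos_vs_neg"


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Point estimates with Wilson CIs for one classifier on one endpoint.

    ``ppv``/``npv`` are ``None`` (undefined, flagged) when no predicted
    positives / negatives exist.  ``lr_pos`` is ``math.inf`` at perfect
    specificity.
    """

    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    ppv: Optional[float]
    ppv_ci: Optional[tuple[float, float]]
    npv: Optional[float]
    npv_ci: Optional[tuple[float, float]]
    lr_pos: float
    n: int


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float

    @property
    def youden_j(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class RocCurve:
    """Threshold-ordered operating points (rule: score > threshold)."""

    points: tuple[RocPoint, ...]
    auc: float


def assemble_analysis_set(
    cohort: Sequence[PatientRecord], endpoint: Endpoint | str
) -> list[tuple[PatientRecord, bool]]:
    """Select records and reference labels for an endpoint.

    MS endpoint: only definitive diagnoses enter (MS and OTHER); CIS, RIS
    and inconclusive cases are excluded.  OCB endpoint: all records enter
    and every record must carry an OCB result.
    """
    endpoint = Endpoint(endpoint)
    pairs: list[tuple[PatientRecord, bool]] = []
    if endpoint is Endpoint.MS_VS_NONMS:
        for r in cohort:
            if r.diagnosis in (Diagnosis.MS, Diagnosis.OTHER):
                pairs.append((r, r.diagnosis is Diagnosis.MS))
    else:
        for r in cohort:
            if not r.ocb_tested:
                raise InvalidRecordError(
                    f"record {r.id}: OCB untested; required for the OCB endpoint"
                )
            pairs.append((r, ocb_positive(r.ocb_bands)))
    n_pos = sum(1 for _, lab in pairs if lab)
    if n_pos == 0 or n_pos == len(pairs):
        raise DegenerateSetError(
            f"endpoint {endpoint.value}: analysis set lacks one of the two classes "
            f"({n_pos} positives of {len(pairs)})"
        )
    return pairs


def confusion(
    labels: Sequence[bool], predictions: Sequence[bool]
) -> ConfusionMatrix:
    """2x2 counts from parallel boolean sequences."""
    if len(labels) != len(predictions):
        raise DomainError(
            f"labels ({len(labels)}) and predictions ({len(predictions)}) differ in length"
        )
    if len(labels) == 0:
        raise DomainError("empty input")
    tp = fp = fn = tn = 0
    for lab, pred in zip(labels, predictions):
        if lab and pred:
            tp += 1
        elif lab:
            fn += 1
        elif pred:
            fp += 1
        else:
            tn += 1
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def wilson_interval(
    successes: int, n: int, confidence: float = 0.95
) -> tuple[float, float]:
    """Two-sided Wilson score interval (no continuity correction)."""
    if not (0 < confidence < 1):
        raise DomainError(f"confidence must be in (0, 1), got {confidence}")
    if n < 1 or not (0 <= successes <= n):
        raise DomainError(f"invalid counts: {successes}/{n}")
    lo, hi = proportion_confint(successes, n, alpha=1 - confidence, method="wilson")
    # clamp away sub-epsilon excursions outside [0, 1] at the boundaries
    return max(0.0, float(lo)), min(1.0, float(hi))


def diagnostic_metrics(
    cm: ConfusionMatrix, confidence: float = 0.95
) -> DiagnosticMetrics:
    """Sensitivity/specificity/PPV/NPV with Wilson CIs, and LR+.

    Each CI uses the proportion's own denominator.  LR+ is
    sensitivity/(1-specificity), +inf at specificity 1.
    """
    if cm.positives < 1 or cm.negatives < 1:
        raise DegenerateSetError("both reference classes must be represented")
    sens = cm.tp / cm.positives
    spec = cm.tn / cm.negatives
    pred_pos = cm.tp + cm.fp
    pred_neg = cm.tn + cm.fn
    ppv = cm.tp / pred_pos if pred_pos else None
    npv = cm.tn / pred_neg if pred_neg else None
    lr_pos = math.inf if spec == 1.0 else sens / (1.0 - spec)
    return DiagnosticMetrics(
        sensitivity=sens,
        sensitivity_ci=wilson_interval(cm.tp, cm.positives, confidence),
        specificity=spec,
        specificity_ci=wilson_interval(cm.tn, cm.negatives, confidence),
        ppv=ppv,
        ppv_ci=wilson_interval(cm.tp, pred_pos, confidence) if pred_pos else None,
        npv=npv,
        npv_ci=wilson_interval(cm.tn, pred_neg, confidence) if pred_neg else None,
        lr_pos=lr_pos,
        n=cm.n,
    )


def _validated_scores_labels(
    scores: Sequence[float], labels: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise DomainError("scores and labels must be 1-d sequences of equal length")
    if y.all() or not y.any():
        raise DegenerateSetError("both classes must be present")
    return s, y


def auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Tie-corrected probabilistic AUC via the rank-sum identity.

    Equals the mean over all (positive, negative) score pairs of
    1 / 0.5 / 0 for pos > / = / < neg.
    """
    s, y = _validated_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    ranks = stats.rankdata(s)  # midranks
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """Empirical ROC with rule score > threshold.

    Candidate thresholds: midpoints between adjacent distinct scores, plus
    sentinels below the minimum (everyone positive) and above the maximum
    (everyone negative).
    """
    s, y = _validated_scores_labels(scores, labels)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    distinct = np.unique(s)
    thresholds = np.concatenate(
        [
            [distinct[0] - 1.0],
            (distinct[:-1] + distinct[1:]) / 2.0,
            [distinct[-1] + 1.0],
        ]
    )
    points = []
    for t in thresholds:
        pred = s > t
        sens = float((pred & y).sum() / n_pos)
        spec = float((~pred & ~y).sum() / n_neg)
        points.append(RocPoint(threshold=float(t), sensitivity=sens, specificity=spec))
    return RocCurve(points=tuple(points), auc=auc(s, y))


def optimal_cutoff(curve: RocCurve, criterion: str = "youden") -> RocPoint:
    """Operating point maximising Youden J = sens + spec - 1.

    Ties break toward higher sensitivity (screening intent: a missed case
    costs more than a reflexed test), then toward the lower threshold.
    """
    if criterion != "youden":
        raise DomainError(f"unknown cutoff criterion: {criterion!r}")
    if not curve.points:
        raise DomainError("empty ROC curve")
    return max(
        curve.points,
        key=lambda p: (p.youden_j, p.sensitivity, -p.threshold),
    )


#: Largest total sample size for which the exact Mann-Whitney null
#: distribution is enumerated; above it (or with ties) the normal
#: approximation with tie and continuity corrections is used.
MANN_WHITNEY_EXACT_LIMIT = 12


def mann_whitney(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Mann-Whitney U (for x) with a two-sided p-value.

    Exact enumeration when ``len(x) + len(y) <= 12`` and there are no
    ties; otherwise normal approximation with midrank tie correction and
    continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise DomainError("both samples must be nonempty")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= MANN_WHITNEY_EXACT_LIMIT and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        xa, ya, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))
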