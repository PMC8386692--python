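"""Two-tier reflex-testing algorithm for suspected MS.

Tier 1: CSF K-FLC below the detection limit (0.03 mg/dl) -> report "no
evidence of intrathecal immunoglobulin synthesis", skip oligoclonal-band
(OCB) testing.  Tier 2: detectable K-FLC but K-Index at or below the
screening cutoff (3.045) -> likewise skip OCB.  Otherwise OCB testing is
reflexed and decides the final result.

Strategy evaluation follows the study conventions: spared-test counts are
taken over the whole cohort, while the strategy confusion matrix and its
metrics are computed on the definitive-diagnosis subset (MS vs OTHER),
because CIS/RIS/inconclusive cases have no reference label.  A reflexed
patient without an OCB result is counted as pending and excluded from the
confusion matrix (logged, never imputed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .accuracy import (
    ConfusionMatrix,
    DiagnosticMetrics,
    confusion,
    diagnostic_metrics,
)
from .core import (
    DEFAULT_IMPUTATION,
    DEFAULT_KINDEX_CUTOFF,
    Diagnosis,
    DomainError,
    PatientRecord,
    kappa_index,
    ocb_positive,
)

logger = logging.getLogger(__name__)


class Tier(str, Enum):
    TIER1_STOP = "TIER1_STOP"    # CSF K-FLC undetectable
    TIER2_STOP = "TIER2_STOP"    # detectable, K-Index <= cutoff
    REFLEX_OCB = "REFLEX_OCB"    # K-Index > cutoff, OCB decides


class Strategy(str, Enum):
    """Testing strategies compared at cohort level."""

    OCB_ONLY = "ocb_only"                       # OCB on everyone (status quo)
    TIER1_ONLY = "tier1_only"                   # skip OCB when K-FLC undetectable
    TIER1_PLUS_KINDEX = "tier1_plus_kindex"     # full two-tier algorithm


@dataclass(frozen=True)
class ScreeningDecision:
    """Per-patient outcome of the reflex algorithm.

    ``final_positive`` is False on a tier stop, the OCB result when the
    patient was reflexed and tested, and None (pending) when reflexed but
    untested.
    """

    tier: Tier
    rationale: str
    final_positive: Optional[bool]


@dataclass(frozen=True)
class CostConfig:
    """Per-OCB-test labor time (hours) and reagent cost (currency units).

    No defaults are shipped: reported aggregate savings in the source
    setting do not pin down a single consistent per-test rate, so rates
    are always explicit configuration.
    """

    ocb_labor_hours_per_test: float
    ocb_reagent_cost_per_test: float

    def __post_init__(self) -> None:
        if self.ocb_labor_hours_per_test < 0 or self.ocb_reagent_cost_per_test < 0:
            raise DomainError("cost parameters must be >= 0")


@dataclass(frozen=True)
class StrategyReport:
    strategy: Strategy
    decisions: tuple[ScreeningDecision, ...]
    spared_tier1: int
    spared_tier2: int
    reflexed: int
    pending_ocb: int
    spared_fraction: float
    strategy_cm: ConfusionMatrix
    metrics: DiagnosticMetrics
    savings_hours: Optional[float]
    savings_cost: Optional[float]

    @property
    def spared_total(self) -> int:
        return self.spared_tier1 + self.spared_tier2


def classify(
    r: PatientRecord,
    kindex_cutoff: float = DEFAULT_KINDEX_CUTOFF,
    imputation_value: float = DEFAULT_IMPUTATION,
) -> ScreeningDecision:
    """Route one patient through the two-tier algorithm.

    The tier-2 rule is "K-Index <= cutoff stops"; OCB is reflexed only
    when the K-Index is strictly higher than the cutoff.
    """
    if not kindex_cutoff > 0:
        raise DomainError(f"kindex_cutoff must be > 0, got {kindex_cutoff}")
    res = kappa_index(r, imputation_value=imputation_value)
    if not res.csf_detectable:
        return ScreeningDecision(
            tier=Tier.TIER1_STOP,
            rationale=(
                f"CSF K-FLC < {r.csf_kflc.lod} mg/dl: no evidence of intrathecal "
                "immunoglobulin synthesis; OCB testing not required"
            ),
            final_positive=False,
        )
    if res.k_index <= kindex_cutoff:
        return ScreeningDecision(
            tier=Tier.TIER2_STOP,
            rationale=(
                f"K-Index {res.k_index:.4g} <= {kindex_cutoff}: "
                "OCB testing not required"
            ),
            final_positive=False,
        )
    final: Optional[bool]
    final = ocb_positive(r.ocb_bands) if r.ocb_tested else None
    return ScreeningDecision(
        tier=Tier.REFLEX_OCB,
        rationale=(
            f"K-Index {res.k_index:.4g} > {kindex_cutoff}: reflex to OCB testing"
        ),
        final_positive=final,
    )


def savings(spared_count: int, costs: CostConfig) -> tuple[float, float]:
    """(labor hours, reagent cost) saved by skipping ``spared_count`` OCB tests."""
    if spared_count < 0:
        raise DomainError("spared_count must be >= 0")
    return (
        spared_count * costs.ocb_labor_hours_per_test,
        spared_count * costs.ocb_reagent_cost_per_test,
    )


def evaluate_strategy(
    cohort: Sequence[PatientRecord],
    strategy: Strategy | str = Strategy.TIER1_PLUS_KINDEX,
    kindex_cutoff: float = DEFAULT_KINDEX_CUTOFF,
    imputation_value: float = DEFAULT_IMPUTATION,
    costs: Optional[CostConfig] = None,
) -> StrategyReport:
    """Cohort-level evaluation of a testing strategy.

    A patient is strategy-positive when the strategy reflexes them to OCB
    and the OCB result is positive; tier-stopped patients are strategy-
    negative.  Spared counts use the full cohort; the confusion matrix and
    metrics use only MS/OTHER records (reference label = MS).
    """
    strategy = Strategy(strategy)
    if not cohort:
        raise DomainError("cohort must be nonempty")

    decisions: list[ScreeningDecision] = []
    spared_t1 = spared_t2 = reflexed = pending = 0
    labels: list[bool] = []
    predictions: list[bool] = []

    for r in cohort:
        d = classify(r, kindex_cutoff=kindex_cutoff, imputation_value=imputation_value)
        # Map the full two-tier decision onto the requested strategy.
        if strategy is Strategy.OCB_ONLY:
            tier = Tier.REFLEX_OCB
        elif strategy is Strategy.TIER1_ONLY:
            tier = Tier.TIER1_STOP if d.tier is Tier.TIER1_STOP else Tier.REFLEX_OCB
        else:
            tier = d.tier
        if tier is not d.tier:
            final = (ocb_positive(r.ocb_bands) if r.ocb_tested else None) if (
                tier is Tier.REFLEX_OCB
            ) else False
            d = ScreeningDecision(tier=tier, rationale=d.rationale, final_positive=final)
        decisions.append(d)

        if d.tier is Tier.TIER1_STOP:
            spared_t1 += 1
        elif d.tier is Tier.TIER2_STOP:
            spared_t2 += 1
        else:
            reflexed += 1
            if d.final_positive is None:
                pending += 1

        if r.diagnosis in (Diagnosis.MS, Diagnosis.OTHER):
            if d.tier is Tier.REFLEX_OCB and d.final_positive is None:
                continue  # pending: excluded from the confusion matrix
            labels.append(r.diagnosis is Diagnosis.MS)
            predictions.append(bool(d.final_positive))

    if pending:
        logger.warning(
            "strategy %s: %d reflexed patient(s) lack an OCB result; "
            "excluded from the confusion matrix",
            strategy.value,
            pending,
        )

    n = len(cohort)
    cm = confusion(labels, predictions)
    metrics = diagnostic_metrics(cm)
    spared_total = spared_t1 + spared_t2
    hours = cost = None
    if costs is not None:
        hours, cost = savings(spared_total, costs)
    logger.info(
        "strategy %s: spared %d/%d (tier1 %d, tier2 %d), reflexed %d, pending %d",
        strategy.value, spared_total, n, spared_t1, spared_t2, reflexed, pending,
    )
    return StrategyReport(
        strategy=strategy,
        decisions=tuple(decisions),
        spared_tier1=spared_t1,
        spared_tier2=spared_t2,
        reflexed=reflexed,
        pending_ocb=pending,
        spared_fraction=spared_total / n,
        strategy_cm=cm,
        metrics=metrics,
        savings_hours=hours,
        savings_cost=cost,
    )
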