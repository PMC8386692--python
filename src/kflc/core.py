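"""Kappa free-light-chain quotients and the kappa index (K-Index).

In multiple sclerosis (MS), inflammation of the central nervous system is
usually accompanied by intrathecal immunoglobulin synthesis.  Free kappa
light chains (K-FLC) leak into the cerebrospinal fluid (CSF) alongside
intact immunoglobulin; because the blood–CSF barrier also passes albumin in
proportion to its permeability, intrathecal K-FLC production is quantified
by the dimensionless **kappa index**

    K-Index = (CSF K-FLC / serum K-FLC) / (CSF albumin / serum albumin)
            = (CSF K-FLC × serum albumin) / (serum K-FLC × CSF albumin)

i.e. the kappa CSF/serum quotient normalised by the albumin quotient
(Qalb), a proxy for barrier permeability.

CSF K-FLC concentrations sit near the turbidimetric assay's detection limit
(0.03 mg/dl); below-limit measurements are censored and replaced by a small
empirical constant (0.0001 mg/dl) so that the K-Index remains defined and
far below every clinically used cutoff.  All concentrations are mg/dl.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

# ---------------------------------------------------------------------------
# Configuration constants (all overridable through function arguments /
# RunConfig; defaults are the values used on the Optilite platform workflow
# this package models).
# ---------------------------------------------------------------------------

#: Detection limit of the CSF K-FLC turbidimetric assay, mg/dl.
DEFAULT_LOD = 0.03

#: Empirical near-zero value assigned to censored CSF K-FLC, mg/dl.
DEFAULT_IMPUTATION = 0.0001

#: Screening K-Index cutoff (reflex to OCB testing when exceeded).
DEFAULT_KINDEX_CUTOFF = 3.045

#: K-Index cutoffs evaluated in the contingency report: the in-house
#: screening cutoff, the large-multicentre-study cutoff, and the
#: OCB-status-optimised cutoff.
REPORT_CUTOFFS = (3.045, 6.6, 12.58)

#: Default two-sided confidence level for proportion intervals.
DEFAULT_CONFIDENCE = 0.95

#: Minimum number of CSF-exclusive bands for a positive oligoclonal-band
#: (OCB) result.
OCB_POSITIVITY_MIN_BANDS = 2


class DomainError(ValueError):
    """Input outside the mathematical/physiologic domain of an operation."""


class InvalidRecordError(DomainError):
    """A patient record is internally inconsistent."""


class ConfigurationError(DomainError):
    """A required configuration value is absent or invalid."""


class DegenerateSetError(DomainError):
    """An analysis set lost one of its two classes after filtering."""


class Diagnosis(str, Enum):
    """Final diagnosis label attached to a patient record.

    ``CIS`` (clinically isolated syndrome), ``RIS`` (radiologically isolated
    syndrome) and ``INCONCLUSIVE`` are pre-/non-diagnoses excluded from the
    MS-vs-non-MS accuracy analysis but retained for OCB-status analyses.
    """

    MS = "MS"
    CIS = "CIS"
    RIS = "RIS"
    INCONCLUSIVE = "INCONCLUSIVE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class CensoredConcentration:
    """A concentration (mg/dl) that may be censored at a detection limit.

    ``below_lod=True`` means the assay reported "< lod"; ``value`` is then
    typically absent.  A measured value exactly equal to ``lod`` is
    detectable (the censoring rule is strictly "<").
    """

    value: Optional[float]
    below_lod: bool
    lod: float = DEFAULT_LOD

    def __post_init__(self) -> None:
        if not self.lod > 0:
            raise DomainError(f"detection limit must be > 0, got {self.lod}")
        if self.below_lod and self.value is not None and self.value >= self.lod:
            raise InvalidRecordError(
                f"value {self.value} flagged below LOD but >= LOD {self.lod}"
            )
        if self.value is not None and self.value <= 0:
            raise DomainError(f"concentration must be > 0, got {self.value}")


@dataclass(frozen=True)
class PatientRecord:
    """One subject's paired serum/CSF measurements and diagnosis.

    All concentrations in mg/dl.  ``ocb_bands`` is the count of
    CSF-exclusive IgG bands on isoelectric focusing, ``None`` if OCB
    testing was not performed.
    """

    id: str
    diagnosis: Diagnosis
    serum_kflc: float
    csf_kflc: CensoredConcentration
    serum_alb: float
    csf_alb: float
    ocb_bands: Optional[int] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "diagnosis", Diagnosis(self.diagnosis))
        for name in ("serum_kflc", "serum_alb", "csf_alb"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v > 0):
                raise InvalidRecordError(f"{self.id}: {name} must be a positive number, got {v!r}")
        if self.ocb_bands is not None and self.ocb_bands < 0:
            raise DomainError(f"{self.id}: ocb_bands must be >= 0, got {self.ocb_bands}")
        if self.csf_alb >= self.serum_alb:
            # Physiologically CSF albumin is far below serum albumin; an
            # inversion is suspicious but not fatal (could be a unit slip).
            warnings.warn(
                f"record {self.id}: CSF albumin ({self.csf_alb}) >= serum albumin "
                f"({self.serum_alb}); check units",
                stacklevel=2,
            )

    @property
    def ocb_tested(self) -> bool:
        return self.ocb_bands is not None


@dataclass(frozen=True)
class KappaResult:
    """Derived quotients for one patient.

    ``imputed`` flags that the CSF K-FLC entering ``q_kappa``/``k_index``
    was the censoring substitute, so downstream reports can count imputed
    records.
    """

    q_alb: float
    q_kappa: float
    k_index: float
    csf_detectable: bool
    imputed: bool


@dataclass(frozen=True)
class HyperbolicParams:
    """Constants (a, b, c) of a barrier-dependent upper reference curve
    ``Qlim(kappa) = a * sqrt(q_alb^2 + b^2) - c``.

    There is no built-in default: the published K-FLC constants must be
    supplied by the caller (configuration), with q_alb-scale units.
    """

    a: float
    b: float
    c: float


def impute_censored(
    c: CensoredConcentration, imputation_value: float = DEFAULT_IMPUTATION
) -> float:
    """Effective concentration after censoring policy.

    Returns the measured value for detectable input and ``imputation_value``
    for below-LOD input.  A value exactly at the detection limit is
    detectable and returned unchanged (strict "<" rule).
    """
    if not imputation_value > 0:
        raise DomainError(f"imputation_value must be > 0, got {imputation_value}")
    if c.below_lod:
        return imputation_value
    if c.value is None:
        raise InvalidRecordError("concentration flagged detectable but no value present")
    return c.value


def albumin_quotient(csf_alb: float, serum_alb: float) -> float:
    """Albumin quotient Qalb = CSF albumin / serum albumin (dimensionless).

    Both inputs must be positive and in identical units (mg/dl internally).
    """
    if not (csf_alb > 0 and serum_alb > 0):
        raise DomainError(
            f"albumin concentrations must be > 0, got csf={csf_alb}, serum={serum_alb}"
        )
    return csf_alb / serum_alb


def kappa_index(
    r: PatientRecord, imputation_value: float = DEFAULT_IMPUTATION
) -> KappaResult:
    """Compute Qalb, the kappa quotient and the K-Index for one record.

    Censored CSF K-FLC is first passed through :func:`impute_censored`;
    the result is flagged ``imputed`` (and ``csf_detectable=False``) in
    that case.  Algebraically ``k_index == q_kappa / q_alb``.
    """
    kflc_eff = impute_censored(r.csf_kflc, imputation_value)
    q_alb = albumin_quotient(r.csf_alb, r.serum_alb)
    q_kappa = kflc_eff / r.serum_kflc
    k_index = (kflc_eff * r.serum_alb) / (r.serum_kflc * r.csf_alb)
    return KappaResult(
        q_alb=q_alb,
        q_kappa=q_kappa,
        k_index=k_index,
        csf_detectable=not r.csf_kflc.below_lod,
        imputed=r.csf_kflc.below_lod,
    )


def ocb_positive(band_count: int) -> bool:
    """Positivity rule for oligoclonal bands: at least two CSF-exclusive bands."""
    if band_count is None:
        raise InvalidRecordError("OCB band count absent (untested)")
    if band_count < 0:
        raise DomainError(f"band count must be >= 0, got {band_count}")
    return band_count >= OCB_POSITIVITY_MIN_BANDS


def reiber_kflc_limit(q_alb: float, params: Optional[HyperbolicParams]) -> float:
    """Upper reference limit of the kappa quotient as a hyperbolic function
    of the albumin quotient: ``Qlim = a*sqrt(q_alb**2 + b**2) - c``.

    An intrathecal K-FLC fraction is present when the observed ``q_kappa``
    exceeds this limit.  The K-FLC constants (a, b, c) are not bundled with
    the package and must be provided explicitly.
    """
    if params is None:
        raise ConfigurationError(
            "hyperbolic reference-curve constants (a, b, c) for K-FLC are required; "
            "they are not bundled and must be supplied from the published "
            "barrier-function reference"
        )
    if not q_alb > 0:
        raise DomainError(f"q_alb must be > 0, got {q_alb}")
    return params.a * math.sqrt(q_alb * q_alb + params.b * params.b) - params.c


def intrathecal_fraction_positive(
    q_kappa: float, q_alb: float, params: Optional[HyperbolicParams]
) -> bool:
    """True when q_kappa lies above the hyperbolic reference limit."""
    return q_kappa > reiber_kflc_limit(q_alb, params)
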