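"""Synthetic patient cohorts.

Two sources of data let the whole pipeline run without access to patient
records:

* :func:`generate` draws a random cohort from a parametric model of a
  suspected-MS referral population (log-normal concentration marginals, a
  latent intrathecal-synthesis state coupling CSF K-FLC to OCB status,
  detection-limit censoring at 0.03 mg/dl).
* :func:`count_fixture` deterministically reconstructs a 252-patient
  cohort from the published stratum counts of the clinical validation
  cohort this package models (45 MS, 160 below-LOD CSF K-FLC, 65 OCB+,
  ...), so every reported contingency figure is recomputable.  Individual
  numeric values within a stratum are synthetic representative constants;
  only stratum membership is meaningful.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DEFAULT_IMPUTATION,
    DEFAULT_LOD,
    CensoredConcentration,
    Diagnosis,
    DomainError,
    PatientRecord,
    kappa_index,
    ocb_positive,
)

# ---------------------------------------------------------------------------
# Random-cohort generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneratorConfig:
    """Parametric model of a suspected-MS referral cohort.

    Concentration-like quantities are log-normal (strictly positive,
    heavy right tail): each is parameterised by its *median* (mg/dl or
    dimensionless for q_alb) and the log-scale sigma.  A latent
    intrathecal-synthesis state S is drawn per patient with a
    diagnosis-dependent probability; S selects the high or low CSF K-FLC
    component and drives OCB positivity, so OCB and K-Index are
    correlated but can disagree (e.g. OCB+ with censored K-FLC).

    Defaults emulate the modelled study cohort: n=252, 45/252 MS
    prevalence, ~63.5% of CSF K-FLC censored at 0.03 mg/dl, MS median
    CSF K-FLC ~0.26 mg/dl, albumin quotient median ~0.004.
    """

    n: int = 252
    prevalence_ms: float = 45 / 252
    frac_cis: float = 1 / 252
    frac_ris: float = 2 / 252
    frac_inconclusive: float = 7 / 252
    seed: int = 0
    lod: float = DEFAULT_LOD
    # CSF K-FLC mixture components (mg/dl), selected by the latent state
    csf_kflc_high_median: float = 0.26
    csf_kflc_high_sigma: float = 1.1
    csf_kflc_low_median: float = 0.006
    csf_kflc_low_sigma: float = 1.3
    # serum compartments
    serum_kflc_median: float = 1.1
    serum_kflc_sigma: float = 0.35
    q_alb_median: float = 0.004
    q_alb_sigma: float = 0.45
    serum_alb_mean: float = 4400.0
    serum_alb_sd: float = 350.0
    # latent intrathecal-synthesis probability per diagnosis class
    synthesis_prob_ms: float = 0.93
    synthesis_prob_cis: float = 1.0
    synthesis_prob_ris: float = 1.0
    synthesis_prob_inconclusive: float = 0.6
    synthesis_prob_other: float = 0.12
    # OCB model: P(>=2 bands | S), false-positive rate, mean extra bands,
    # and the rate of a single (sub-threshold) band in OCB- patients
    ocb_pos_given_synthesis: float = 0.9
    ocb_false_positive_rate: float = 0.02
    ocb_extra_band_rate: float = 3.0
    ocb_single_band_rate: float = 0.08

    def __post_init__(self) -> None:
        if self.n < 0:
            raise DomainError("n must be >= 0")
        fracs = (
            self.prevalence_ms,
            self.frac_cis,
            self.frac_ris,
            self.frac_inconclusive,
        )
        if any(not (0.0 <= f <= 1.0) for f in fracs) or sum(fracs) > 1.0 + 1e-12:
            raise DomainError("class fractions must lie in [0, 1] and sum to <= 1")
        for name in (
            "csf_kflc_high_sigma", "csf_kflc_low_sigma", "serum_kflc_sigma",
            "q_alb_sigma", "csf_kflc_high_median", "csf_kflc_low_median",
            "serum_kflc_median", "q_alb_median", "lod",
        ):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be > 0")

    def synthesis_prob(self, diagnosis: Diagnosis) -> float:
        return {
            Diagnosis.MS: self.synthesis_prob_ms,
            Diagnosis.CIS: self.synthesis_prob_cis,
            Diagnosis.RIS: self.synthesis_prob_ris,
            Diagnosis.INCONCLUSIVE: self.synthesis_prob_inconclusive,
            Diagnosis.OTHER: self.synthesis_prob_other,
        }[diagnosis]


def generate(config: GeneratorConfig) -> list[PatientRecord]:
    """Draw a random cohort; identical config (incl. seed) -> identical cohort."""
    rng = np.random.default_rng(config.seed)
    class_probs = [
        config.prevalence_ms,
        config.frac_cis,
        config.frac_ris,
        config.frac_inconclusive,
    ]
    class_probs.append(max(0.0, 1.0 - sum(class_probs)))
    classes = [
        Diagnosis.MS,
        Diagnosis.CIS,
        Diagnosis.RIS,
        Diagnosis.INCONCLUSIVE,
        Diagnosis.OTHER,
    ]
    records: list[PatientRecord] = []
    for i in range(config.n):
        diagnosis = classes[rng.choice(len(classes), p=class_probs)]
        synthesis = rng.random() < config.synthesis_prob(diagnosis)
        if synthesis:
            mu, sigma = np.log(config.csf_kflc_high_median), config.csf_kflc_high_sigma
        else:
            mu, sigma = np.log(config.csf_kflc_low_median), config.csf_kflc_low_sigma
        csf_val = float(rng.lognormal(mu, sigma))
        if csf_val < config.lod:
            csf = CensoredConcentration(value=None, below_lod=True, lod=config.lod)
        else:
            csf = CensoredConcentration(value=csf_val, below_lod=False, lod=config.lod)
        serum_kflc = float(
            rng.lognormal(np.log(config.serum_kflc_median), config.serum_kflc_sigma)
        )
        q_alb = float(rng.lognormal(np.log(config.q_alb_median), config.q_alb_sigma))
        serum_alb = float(
            max(rng.normal(config.serum_alb_mean, config.serum_alb_sd), 2000.0)
        )
        p_band = (
            config.ocb_pos_given_synthesis
            if synthesis
            else config.ocb_false_positive_rate
        )
        if rng.random() < p_band:
            bands = 2 + int(rng.poisson(config.ocb_extra_band_rate))
        else:
            bands = 1 if rng.random() < config.ocb_single_band_rate else 0
        records.append(
            PatientRecord(
                id=f"S{i + 1:04d}",
                diagnosis=diagnosis,
                serum_kflc=serum_kflc,
                csf_kflc=csf,
                serum_alb=serum_alb,
                csf_alb=q_alb * serum_alb,
                ocb_bands=bands,
            )
        )
    return records


# ---------------------------------------------------------------------------
# Deterministic count fixture
# ---------------------------------------------------------------------------

# Each stratum: (count, diagnosis, k_index or None for censored, ocb_bands,
# serum_kflc mg/dl, q_alb).  CSF K-FLC is back-computed from the target
# K-Index so that kappa_index() lands exactly on the stratum value; the
# K-Index constants are synthetic stratum representatives except for the
# three individually reported MS patients (K-Index 4.48 with CSF K-FLC
# 0.07, and 0.12/(4.6*0.008)=3.26 with CSF K-FLC 0.12).
_FIXTURE_STRATA: tuple[tuple[int, Diagnosis, Optional[float], int, float, float], ...] = (
    # --- MS (45): 1 censored OCB-, 2 in (3.045, 6.6], 1 in (6.6, 12.58],
    #     41 above 12.58 (38 OCB+, 3 OCB-)
    (1, Diagnosis.MS, None, 0, 1.5, 0.004),
    (1, Diagnosis.MS, 4.48, 0, 2.5, 0.00625),
    (1, Diagnosis.MS, 0.12 / (4.6 * 0.008), 2, 4.6, 0.008),
    (1, Diagnosis.MS, 9.0, 2, 1.5, 0.004),
    (38, Diagnosis.MS, 60.0, 3, 1.5, 0.004),
    (3, Diagnosis.MS, 60.0, 0, 1.5, 0.004),
    # --- CIS (1) and RIS (2): detectable, OCB+, very high K-Index
    (1, Diagnosis.CIS, 150.0, 2, 1.5, 0.004),
    (2, Diagnosis.RIS, 150.0, 2, 1.5, 0.004),
    # --- inconclusive (7): 2 censored OCB-, 4 OCB+ very high,
    #     1 OCB- at 8.49
    (2, Diagnosis.INCONCLUSIVE, None, 0, 1.5, 0.004),
    (4, Diagnosis.INCONCLUSIVE, 150.0, 2, 1.5, 0.004),
    (1, Diagnosis.INCONCLUSIVE, 8.49, 0, 1.5, 0.004),
    # --- other diagnoses (197):
    # censored: 157 (3 OCB+, 154 OCB-)
    (3, Diagnosis.OTHER, None, 2, 1.5, 0.004),
    (154, Diagnosis.OTHER, None, 0, 1.5, 0.004),
    # detectable <= 3.045: 13 (1 OCB+, 12 OCB-)
    (1, Diagnosis.OTHER, 2.0, 2, 2.5, 0.008),
    (12, Diagnosis.OTHER, 2.0, 0, 2.5, 0.008),
    # (3.045, 6.6]: 2 (1 OCB+, 1 OCB-)
    (1, Diagnosis.OTHER, 4.5, 2, 1.5, 0.005),
    (1, Diagnosis.OTHER, 4.5, 0, 1.5, 0.005),
    # (6.6, 12.58]: 6, all OCB-
    (6, Diagnosis.OTHER, 9.0, 0, 1.5, 0.004),
    # > 12.58: 19 (13 OCB+, 6 OCB-)
    (13, Diagnosis.OTHER, 50.0, 2, 1.5, 0.004),
    (6, Diagnosis.OTHER, 50.0, 0, 1.5, 0.004),
)

_FIXTURE_SERUM_ALB = 4000.0  # mg/dl


def count_fixture(lod: float = DEFAULT_LOD) -> list[PatientRecord]:
    """Deterministic 252-patient cohort matching every published marginal.

    Joint strata (diagnosis x censoring x OCB x K-Index interval) were
    derived by hand from the reported counts: 45 MS / 1 CIS / 2 RIS /
    7 inconclusive / 197 other; 160 censored (157 other, 2 inconclusive,
    1 MS); 92 detectable (62 OCB+, 30 OCB-); 65 OCB+ (40 MS, 2 RIS, 1 CIS,
    4 inconclusive, 18 other; 3 censored, none MS); 44 MS with K-Index
    > 3.045, 42 > 6.6, 41 > 12.58; 27/25/19 false positives among the 197
    at the three cutoffs; 13 detectable patients at or below 3.045.
    """
    records: list[PatientRecord] = []
    i = 0
    for count, diagnosis, k, bands, serum_kflc, q_alb in _FIXTURE_STRATA:
        for _ in range(count):
            i += 1
            if k is None:
                csf = CensoredConcentration(value=None, below_lod=True, lod=lod)
            else:
                csf_val = k * serum_kflc * q_alb
                if csf_val < lod:  # pragma: no cover - stratum constants preclude this
                    raise DomainError("fixture stratum produced a sub-LOD detectable value")
                csf = CensoredConcentration(value=csf_val, below_lod=False, lod=lod)
            records.append(
                PatientRecord(
                    id=f"P{i:03d}",
                    diagnosis=diagnosis,
                    serum_kflc=serum_kflc,
                    csf_kflc=csf,
                    serum_alb=_FIXTURE_SERUM_ALB,
                    csf_alb=q_alb * _FIXTURE_SERUM_ALB,
                    ocb_bands=bands,
                )
            )
    return records


# ---------------------------------------------------------------------------
# Calibration summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationSummary:
    """Cohort descriptives in the shape of a patient-characteristics table."""

    n: int
    class_counts: dict[str, int]
    censored_fraction: float
    groups: pd.DataFrame  # index: group; columns: n, kflc_*, kindex_*


def calibration_summary(
    cohort: Sequence[PatientRecord],
    imputation_value: float = DEFAULT_IMPUTATION,
) -> CalibrationSummary:
    """Per-group medians/ranges of (imputed) CSF K-FLC and K-Index.

    Groups: all, MS, non-MS (definitive non-MS diagnoses only), OCB+ and
    OCB- (tested patients).  Censored values enter at the imputation
    constant, mirroring the reporting convention of the modelled study.
    """
    if not cohort:
        raise DomainError("cohort must be nonempty")
    rows = []
    for r in cohort:
        res = kappa_index(r, imputation_value=imputation_value)
        rows.append(
            {
                "diagnosis": r.diagnosis.value,
                "kflc": imputation_value if res.imputed else r.csf_kflc.value,
                "kindex": res.k_index,
                "censored": res.imputed,
                "ocb_pos": ocb_positive(r.ocb_bands) if r.ocb_tested else None,
            }
        )
    df = pd.DataFrame(rows)

    def _stats(sub: pd.DataFrame) -> dict[str, float]:
        return {
            "n": len(sub),
            "kflc_median": sub["kflc"].median(),
            "kflc_min": sub["kflc"].min(),
            "kflc_max": sub["kflc"].max(),
            "kindex_median": sub["kindex"].median(),
            "kindex_min": sub["kindex"].min(),
            "kindex_max": sub["kindex"].max(),
        }

    groups = {"all": _stats(df)}
    ms = df[df["diagnosis"] == "MS"]
    non_ms = df[df["diagnosis"] == "OTHER"]
    if len(ms):
        groups["MS"] = _stats(ms)
    if len(non_ms):
        groups["non_MS"] = _stats(non_ms)
    tested = df[df["ocb_pos"].notna()]
    if len(tested):
        pos = tested[tested["ocb_pos"] == True]  # noqa: E712 - pandas mask
        neg = tested[tested["ocb_pos"] == False]  # noqa: E712
        if len(pos):
            groups["OCB_pos"] = _stats(pos)
        if len(neg):
            groups["OCB_neg"] = _stats(neg)
    return CalibrationSummary(
        n=len(df),
        class_counts=df["diagnosis"].value_counts().to_dict(),
        censored_fraction=float(df["censored"].mean()),
        groups=pd.DataFrame(groups).T,
    )
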