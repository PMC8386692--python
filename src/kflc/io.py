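"""Cohort CSV input/output, run configuration and report emission.

Cohort CSV schema (header mandatory, decimal point, UTF-8), one row per
patient::

    id, diagnosis, serum_kflc_mg_dl, csf_kflc_mg_dl, csf_kflc_below_lod,
    serum_alb_mg_dl, csf_alb_mg_dl, ocb_bands

``csf_kflc_mg_dl`` may be empty when ``csf_kflc_below_lod`` is true;
``ocb_bands`` empty means OCB untested.  All concentrations are mg/dl; the
reader rejects rows rather than guessing units.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Any, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .accuracy import (
    DiagnosticMetrics,
    Endpoint,
    RocCurve,
    assemble_analysis_set,
    auc,
    confusion,
    diagnostic_metrics,
    optimal_cutoff,
    roc_curve,
)
from .core import (
    DEFAULT_CONFIDENCE,
    DEFAULT_IMPUTATION,
    DEFAULT_KINDEX_CUTOFF,
    DEFAULT_LOD,
    REPORT_CUTOFFS,
    CensoredConcentration,
    Diagnosis,
    DomainError,
    PatientRecord,
    kappa_index,
    ocb_positive,
)

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "id",
    "diagnosis",
    "serum_kflc_mg_dl",
    "csf_kflc_mg_dl",
    "csf_kflc_below_lod",
    "serum_alb_mg_dl",
    "csf_alb_mg_dl",
    "ocb_bands",
]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


class SchemaError(DomainError):
    """The CSV header does not match the cohort schema."""


class CohortValidationError(DomainError):
    """One or more rows failed validation; ``errors`` lists (line, message)."""

    def __init__(self, errors: list[tuple[int, str]]):
        self.errors = errors
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in errors[:10])
        more = "" if len(errors) <= 10 else f" (+{len(errors) - 10} more)"
        super().__init__(f"{len(errors)} invalid row(s): {detail}{more}")


@dataclass(frozen=True)
class RunConfig:
    """Run-level constants; defaults are the modelled workflow's values."""

    lod: float = DEFAULT_LOD
    imputation_value: float = DEFAULT_IMPUTATION
    kindex_cutoff: float = DEFAULT_KINDEX_CUTOFF
    report_cutoffs: tuple[float, ...] = REPORT_CUTOFFS
    confidence: float = DEFAULT_CONFIDENCE
    ocb_labor_hours_per_test: Optional[float] = None
    ocb_reagent_cost_per_test: Optional[float] = None
    seed: int = 0


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML mapping into a :class:`RunConfig` (unknown keys rejected)."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise DomainError(f"config file {path} must contain a mapping")
    known = {f.name for f in dataclass_fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise DomainError(f"unknown config keys: {sorted(unknown)}")
    if "report_cutoffs" in raw:
        raw["report_cutoffs"] = tuple(float(c) for c in raw["report_cutoffs"])
    return RunConfig(**raw)


def _parse_bool(x: Any) -> bool:
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"not a boolean: {x!r}")


def read_cohort(path: str | Path, lod: float = DEFAULT_LOD) -> list[PatientRecord]:
    """Read and validate a cohort CSV.

    Row-level problems are collected with CSV line numbers and raised
    together as :class:`CohortValidationError`; a wrong header raises
    :class:`SchemaError` immediately.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    records: list[PatientRecord] = []
    errors: list[tuple[int, str]] = []
    n_censored = n_untested = 0
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        try:
            diagnosis = Diagnosis(row["diagnosis"].strip().upper())
            below = _parse_bool(row["csf_kflc_below_lod"])
            raw_csf = row["csf_kflc_mg_dl"].strip()
            value = float(raw_csf) if raw_csf else None
            if below and value is not None and value >= lod:
                raise ValueError(
                    f"csf_kflc_below_lod is true but value {value} >= LOD {lod}"
                )
            if not below and value is None:
                raise ValueError("csf_kflc_below_lod is false but value is empty")
            raw_bands = row["ocb_bands"].strip()
            bands = int(float(raw_bands)) if raw_bands else None
            rec = PatientRecord(
                id=row["id"].strip(),
                diagnosis=diagnosis,
                serum_kflc=float(row["serum_kflc_mg_dl"]),
                csf_kflc=CensoredConcentration(value=value, below_lod=below, lod=lod),
                serum_alb=float(row["serum_alb_mg_dl"]),
                csf_alb=float(row["csf_alb_mg_dl"]),
                ocb_bands=bands,
            )
        except (ValueError, DomainError) as exc:
            errors.append((line, str(exc)))
            continue
        if below:
            n_censored += 1
        if bands is None:
            n_untested += 1
        records.append(rec)
    if errors:
        raise CohortValidationError(errors)
    logger.info(
        "read %d records from %s: %d censored CSF K-FLC, %d OCB untested",
        len(records), path, n_censored, n_untested,
    )
    return records


def cohort_to_frame(cohort: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a schema-shaped DataFrame (censored cells empty)."""
    rows = []
    for r in cohort:
        rows.append(
            {
                "id": r.id,
                "diagnosis": r.diagnosis.value,
                # repr of builtin floats round-trips losslessly through CSV
                "serum_kflc_mg_dl": repr(float(r.serum_kflc)),
                "csf_kflc_mg_dl": "" if r.csf_kflc.value is None else repr(float(r.csf_kflc.value)),
                "csf_kflc_below_lod": "true" if r.csf_kflc.below_lod else "false",
                "serum_alb_mg_dl": repr(float(r.serum_alb)),
                "csf_alb_mg_dl": repr(float(r.csf_alb)),
                "ocb_bands": "" if r.ocb_bands is None else r.ocb_bands,
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


def write_cohort(cohort: Sequence[PatientRecord], path: str | Path) -> None:
    """Write the cohort CSV (lossless round-trip with :func:`read_cohort`)."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def annotate_kindex(
    cohort: Sequence[PatientRecord], imputation_value: float = DEFAULT_IMPUTATION
) -> pd.DataFrame:
    """Cohort frame with derived q_alb / q_kappa / k_index / csf_detectable columns."""
    df = cohort_to_frame(cohort)
    derived = [kappa_index(r, imputation_value=imputation_value) for r in cohort]
    df["q_alb"] = [d.q_alb for d in derived]
    df["q_kappa"] = [d.q_kappa for d in derived]
    df["k_index"] = [d.k_index for d in derived]
    df["csf_detectable"] = [d.csf_detectable for d in derived]
    return df


# ---------------------------------------------------------------------------
# Contingency report (the per-classifier metric blocks)
# ---------------------------------------------------------------------------


def _metrics_block(m: DiagnosticMetrics) -> dict[str, Any]:
    def ci(pair: Optional[tuple[float, float]]):
        return None if pair is None else [pair[0], pair[1]]

    return {
        "sensitivity": m.sensitivity,
        "sensitivity_ci": ci(m.sensitivity_ci),
        "specificity": m.specificity,
        "specificity_ci": ci(m.specificity_ci),
        "ppv": m.ppv,
        "ppv_ci": ci(m.ppv_ci),
        "npv": m.npv,
        "npv_ci": ci(m.npv_ci),
        "lr_pos": m.lr_pos,
        "n": m.n,
    }


def evaluate_cohort(
    cohort: Sequence[PatientRecord],
    cutoffs: Sequence[float] = REPORT_CUTOFFS,
    confidence: float = DEFAULT_CONFIDENCE,
    imputation_value: float = DEFAULT_IMPUTATION,
) -> dict[str, Any]:
    """Full contingency report: per-endpoint blocks for OCB (MS endpoint
    only) and each K-Index cutoff, plus ROC AUC and the Youden-optimal
    operating point per endpoint.
    """
    report: dict[str, Any] = {}
    kindex = {r.id: kappa_index(r, imputation_value=imputation_value).k_index for r in cohort}
    for endpoint in (Endpoint.MS_VS_NONMS, Endpoint.OCB_POS_VS_NEG):
        pairs = assemble_analysis_set(cohort, endpoint)
        labels = [lab for _, lab in pairs]
        classifiers: dict[str, list[bool]] = {}
        if endpoint is Endpoint.MS_VS_NONMS:
            if all(r.ocb_tested for r, _ in pairs):
                classifiers["OCB"] = [ocb_positive(r.ocb_bands) for r, _ in pairs]
        for c in cutoffs:
            classifiers[f"K-Index > {c:g}"] = [kindex[r.id] > c for r, _ in pairs]
        block: dict[str, Any] = {}
        for name, preds in classifiers.items():
            block[name] = _metrics_block(
                diagnostic_metrics(confusion(labels, preds), confidence)
            )
        scores = [kindex[r.id] for r, _ in pairs]
        curve = roc_curve(scores, labels)
        best = optimal_cutoff(curve)
        block["roc"] = {
            "auc": curve.auc,
            "optimal_threshold": best.threshold,
            "optimal_sensitivity": best.sensitivity,
            "optimal_specificity": best.specificity,
        }
        report[endpoint.value] = block
    return report


def roc_points_frame(curve: RocCurve) -> pd.DataFrame:
    """Tidy frame of ROC operating points (threshold, sensitivity, specificity)."""
    return pd.DataFrame(
        [
            {
                "threshold": p.threshold,
                "sensitivity": p.sensitivity,
                "specificity": p.specificity,
            }
            for p in curve.points
        ]
    )


# ---------------------------------------------------------------------------
# JSON report emission
# ---------------------------------------------------------------------------


def _render(obj: Any) -> Any:
    """4-decimal rendering of floats; infinities become strings."""
    if isinstance(obj, dict):
        return {k: _render(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_render(v) for v in obj]
    if isinstance(obj, float):
        if math.isinf(obj):
            return "Infinity" if obj > 0 else "-Infinity"
        return round(obj, 4)
    return obj


def emit_report(
    results: dict[str, Any],
    path: str | Path,
    config: Optional[RunConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """Write a JSON report: metric blocks (floats at 4 decimals) plus run
    metadata (package version, seed, configuration echo)."""
    meta: dict[str, Any] = {"package": "kflc", "version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if config is not None:
        meta["config"] = {
            f.name: getattr(config, f.name) for f in dataclass_fields(RunConfig)
        }
        meta["config"]["report_cutoffs"] = list(config.report_cutoffs)
    doc = {"metadata": _render(meta), "results": _render(results)}
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")
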