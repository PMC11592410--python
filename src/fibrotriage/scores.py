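"""Serum-based non-invasive fibrosis indices and histology-derived labels.

The three routine serum indices used to triage fibrosis in steatotic liver
disease are implemented here from their published formulas:

* APRI  — AST-to-Platelet Ratio Index: ``(AST / ULN) / platelets * 100``.
* FIB-4 — Fibrosis-4 index: ``age * AST / (platelets * sqrt(ALT))``.
* NFS   — NAFLD Fibrosis Score, a linear index over age, BMI, glycemic
  status, AST/ALT ratio, platelet count and albumin.

The ELF (Enhanced Liver Fibrosis) test is a proprietary combination of three
matrix-turnover analytes; it is consumed as a given number on the patient
record, never computed.

Histological ground truth uses the NASH CRN staging F0–F4; *advanced*
fibrosis is F3–F4 and *significant* fibrosis is F2–F4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .errors import DomainError

__all__ = [
    "FIBROSIS_STAGES",
    "PatientRecord",
    "ReferenceRanges",
    "MASLDCriteria",
    "apri",
    "fib4",
    "nfs",
    "fibrosis_labels",
    "masld_eligible",
    "stage_index",
    "score_cohort",
]

#: Ordered NASH CRN fibrosis stages, least to most severe.
FIBROSIS_STAGES = ("F0", "F1", "F2", "F3", "F4")

_SEXES = ("male", "female")


def stage_index(stage: str) -> int:
    """Return the ordinal position (0–4) of a CRN stage token.

    Raises
    ------
    DomainError
        If ``stage`` is not one of F0…F4.
    """
    try:
        return FIBROSIS_STAGES.index(stage)
    except ValueError:
        raise DomainError(
            f"unknown fibrosis stage {stage!r}; allowed values: {', '.join(FIBROSIS_STAGES)}"
        ) from None


@dataclass(frozen=True)
class ReferenceRanges:
    """Laboratory reference values entering score formulas.

    Parameters
    ----------
    ast_uln : float
        Upper limit of normal for AST in U/L. The default of 40 U/L is the
        conventional reference used with APRI; other laboratories differ, so
        it is carried as configuration rather than a constant.
    """

    ast_uln: float = 40.0

    def __post_init__(self):
        if not self.ast_uln > 0:
            raise DomainError(f"ast_uln must be positive, got {self.ast_uln}")


@dataclass(frozen=True)
class MASLDCriteria:
    """The five cardiometabolic criteria; MASLD eligibility needs at least one.

    Flags follow the consensus definition: overweight/obesity (BMI >= 23 kg/m^2
    in Asian populations), fasting glucose >= 100 mg/dL, blood pressure
    >= 130/85 mmHg or antihypertensive use, triglycerides >= 150 mg/dL or
    lipid-lowering therapy, and low HDL (<40 men / <50 women) or therapy.
    """

    overweight: bool = False
    high_fasting_glucose: bool = False
    high_blood_pressure: bool = False
    high_triglycerides: bool = False
    low_hdl: bool = False

    def any(self) -> bool:
        return (
            self.overweight
            or self.high_fasting_glucose
            or self.high_blood_pressure
            or self.high_triglycerides
            or self.low_hdl
        )


def masld_eligible(criteria: MASLDCriteria) -> bool:
    """True iff at least one of the five cardiometabolic criteria is met."""
    return criteria.any()


@dataclass
class PatientRecord:
    """One subject's clinical variables, biomarkers and histological stage.

    Missing optional biomarkers (``elf``, ``arfi``) are ``None``, never a
    sentinel number; operations that need them fail loudly.
    ``fibrosis_stage`` is optional for scoring but required for any
    evaluation against histology.
    """

    id: str
    age: float
    sex: str
    ast: float
    alt: float
    platelets: float
    albumin: float
    bmi: float
    ifg_or_diabetes: bool
    elf: Optional[float] = None
    arfi: Optional[float] = None
    fibrosis_stage: Optional[str] = None

    def __post_init__(self):
        for name in ("age", "ast", "alt", "platelets", "albumin", "bmi"):
            value = getattr(self, name)
            if not (isinstance(value, (int, float)) and math.isfinite(value) and value > 0):
                raise DomainError(f"{name} must be a finite positive number, got {value!r} (id={self.id})")
        if self.sex not in _SEXES:
            raise DomainError(f"sex must be one of {_SEXES}, got {self.sex!r} (id={self.id})")
        if self.fibrosis_stage is not None:
            stage_index(self.fibrosis_stage)


def apri(ast: float, ranges: ReferenceRanges, platelets: float) -> float:
    """AST-to-Platelet Ratio Index.

    ``((AST / ULN) / platelets) * 100`` with AST in U/L and platelets in
    10^9/L. Zero AST gives a zero score; non-positive platelets or ULN are a
    domain error.
    """
    if not platelets > 0:
        raise DomainError(f"platelets must be positive, got {platelets}")
    if ast < 0:
        raise DomainError(f"ast must be non-negative, got {ast}")
    return (ast / ranges.ast_uln) / platelets * 100.0


def fib4(age: float, ast: float, alt: float, platelets: float) -> float:
    """Fibrosis-4 index: ``age * AST / (platelets * sqrt(ALT))``.

    Undefined (domain error) for non-positive ALT or platelets — it never
    silently returns infinity.
    """
    if not alt > 0:
        raise DomainError(f"alt must be positive for FIB-4, got {alt}")
    if not platelets > 0:
        raise DomainError(f"platelets must be positive for FIB-4, got {platelets}")
    return age * ast / (platelets * math.sqrt(alt))


def nfs(
    age: float,
    bmi: float,
    ifg_or_diabetes: bool,
    ast: float,
    alt: float,
    platelets: float,
    albumin: float,
) -> float:
    """NAFLD Fibrosis Score.

    ``-1.675 + 0.037*age + 0.094*BMI + 1.13*[IFG/diabetes] + 0.99*(AST/ALT)
    - 0.013*platelets - 0.66*albumin`` with albumin in g/dL. Unbounded in
    both directions; only ALT must be positive (it divides the AST/ALT term).
    """
    if not alt > 0:
        raise DomainError(f"alt must be positive for NFS, got {alt}")
    return (
        -1.675
        + 0.037 * age
        + 0.094 * bmi
        + 1.13 * (1.0 if ifg_or_diabetes else 0.0)
        + 0.99 * (ast / alt)
        - 0.013 * platelets
        - 0.66 * albumin
    )


def fibrosis_labels(stage: str) -> dict:
    """Binary classification targets from a CRN stage.

    ``advanced`` is true for F3–F4, ``significant`` for F2–F4; advanced
    always implies significant.
    """
    idx = stage_index(stage)
    return {"advanced": idx >= 3, "significant": idx >= 2}


def score_cohort(records, ranges: ReferenceRanges | None = None) -> pd.DataFrame:
    """Compute all serum indices for a cohort of :class:`PatientRecord`.

    Returns a DataFrame indexed by subject id with columns ``apri``,
    ``fib4``, ``nfs``, ``elf``, ``arfi``, ``fibrosis_stage``, ``advanced``
    and ``significant``. Optional biomarkers and stages appear as NA when
    absent; the three computed indices are always present because the record
    invariants guarantee their inputs.
    """
    ranges = ranges or ReferenceRanges()
    rows = []
    for r in records:
        labels = fibrosis_labels(r.fibrosis_stage) if r.fibrosis_stage is not None else {}
        rows.append(
            {
                "id": r.id,
                "apri": apri(r.ast, ranges, r.platelets),
                "fib4": fib4(r.age, r.ast, r.alt, r.platelets),
                "nfs": nfs(r.age, r.bmi, r.ifg_or_diabetes, r.ast, r.alt, r.platelets, r.albumin),
                "elf": r.elf,
                "arfi": r.arfi,
                "fibrosis_stage": r.fibrosis_stage,
                "advanced": labels.get("advanced"),
                "significant": labels.get("significant"),
            }
        )
    frame = pd.DataFrame(rows)
    if not frame.empty:
        frame = frame.set_index("id")
    return frame
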