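"""Sequential diagnostic algorithms with indeterminate zones.

A triage pathway is an ordered list of :class:`StageRule`. Each stage reads
one marker (a computed index such as FIB-4 or a measured biomarker such as
ELF or ARFI shear-wave speed) and routes each subject to one of three
outcomes: *rule out* (below the low cutoff), *rule in* (at or above the
high cutoff), or *advance* to the next stage (the indeterminate zone in
between). Subjects still indeterminate after the last stage fall to the
pathway's residual policy.

The two pathways of primary clinical interest:

* **Two-step** — FIB-4 < 1.30 rules out, FIB-4 > 2.67 rules in, and the
  1.30–2.67 indeterminate zone is resolved by ELF at a single cutoff
  (>= 9.8 rules in).
* **Three-step** — as above, but ELF itself has an indeterminate zone
  (7.7–9.8) that is resolved by ARFI elastography at a device-specific
  cutoff. No consensus ARFI cutoff exists, so it must be supplied
  explicitly.

Boundary conventions are explicit ``low_inclusive`` / ``high_inclusive``
flags on every rule so that either reading of a published threshold
(``>=`` vs ``>``) is reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import yaml

from .errors import ConfigError, DataError
from .scores import PatientRecord, ReferenceRanges, apri, fib4, nfs

__all__ = [
    "RULE_OUT",
    "RULE_IN",
    "ADVANCE",
    "INDETERMINATE",
    "EXCLUDED",
    "StageRule",
    "SequentialAlgorithm",
    "TriageDecision",
    "StageFlow",
    "FlowCounts",
    "make_two_step",
    "make_three_step",
    "make_single_test",
    "marker_value",
    "apply_algorithm",
    "flow_counts",
    "algorithm_to_dict",
    "algorithm_from_dict",
    "algorithm_to_yaml",
    "algorithm_from_yaml",
]

RULE_OUT = "rule_out"
RULE_IN = "rule_in"
ADVANCE = "advance"
INDETERMINATE = "indeterminate"
EXCLUDED = "excluded"

_RESIDUAL_POLICIES = ("treat_as_negative", "treat_as_positive", "keep_indeterminate")
_MISSING_POLICIES = ("error", "exclude", "treat_as_indeterminate")

#: Computed serum indices resolvable from a record's laboratory values.
_COMPUTED_MARKERS = ("fib4", "apri", "nfs")


@dataclass(frozen=True)
class StageRule:
    """One stage of a sequential pathway.

    ``low_inclusive`` controls whether a value exactly at ``low_cutoff``
    belongs to the indeterminate zone (True, e.g. FIB-4 >= 1.30 enters the
    pathway) or rules out (False). ``high_inclusive`` controls whether a
    value exactly at ``high_cutoff`` rules in (True, e.g. ELF >= 9.8) or
    stays in the zone (False, e.g. rule-in only above FIB-4 2.67).

    A single-threshold rule collapses the zone with ``low == high``;
    there ``high_inclusive`` decides the boundary (``>=`` vs ``>``) and
    values below the threshold rule out.
    """

    marker: str
    low_cutoff: float
    high_cutoff: float
    low_inclusive: bool = True
    high_inclusive: bool = True

    def __post_init__(self):
        if math.isnan(self.low_cutoff) or math.isnan(self.high_cutoff):
            raise ConfigError(f"stage {self.marker!r}: cutoffs must not be NaN")
        if self.low_cutoff > self.high_cutoff:
            raise ConfigError(
                f"stage {self.marker!r}: low_cutoff {self.low_cutoff} exceeds high_cutoff {self.high_cutoff}"
            )

    def decide(self, value: float) -> str:
        """Route a marker value: RULE_IN, RULE_OUT or ADVANCE."""
        if value > self.high_cutoff or (value == self.high_cutoff and self.high_inclusive):
            return RULE_IN
        if value < self.low_cutoff or (value == self.low_cutoff and not self.low_inclusive):
            return RULE_OUT
        return ADVANCE


@dataclass(frozen=True)
class SequentialAlgorithm:
    """Ordered stages plus policies for residual indeterminates and missing markers."""

    stages: tuple
    residual_policy: str = "keep_indeterminate"
    missing_policy: str = "error"
    name: str = "sequential"

    def __post_init__(self):
        if len(self.stages) < 1:
            raise ConfigError("an algorithm needs at least one stage")
        object.__setattr__(self, "stages", tuple(self.stages))
        if self.residual_policy not in _RESIDUAL_POLICIES:
            raise ConfigError(f"residual_policy must be one of {_RESIDUAL_POLICIES}")
        if self.missing_policy not in _MISSING_POLICIES:
            raise ConfigError(f"missing_policy must be one of {_MISSING_POLICIES}")

    @property
    def markers(self) -> tuple:
        return tuple(s.marker for s in self.stages)


@dataclass(frozen=True)
class TriageDecision:
    """Final routing for one subject.

    ``stage_reached`` is the zero-based index of the last stage whose marker
    was actually read. ``biopsy_recommended`` is true exactly when the
    pathway rules the subject in — rule-in is the trigger for biopsy or
    specialist referral.
    """

    subject_id: str
    final: str
    stage_reached: int
    biopsy_recommended: bool


@dataclass(frozen=True)
class StageFlow:
    """Subject counts through one stage; they always sum to ``entering``."""

    marker: str
    entering: int
    rule_out: int
    advance: int
    rule_in: int


@dataclass(frozen=True)
class FlowCounts:
    """Per-stage flow plus the indeterminate-zone avoidance accounting.

    ``avoided_within_indeterminate`` counts subjects who entered the
    indeterminate zone after stage 1 and were eventually ruled out by later
    stages — the biopsies the extra test(s) avoided within that zone.
    """

    stages: tuple
    n_subjects: int
    n_excluded: int
    n_indeterminate_final: int
    indeterminate_fraction_after_stage1: float
    avoided_within_indeterminate: int
    avoided_within_indeterminate_fraction: float


def make_two_step(
    fib4_low: float = 1.30,
    fib4_high: float = 2.67,
    elf_cutoff: float = 9.8,
    variant: str = "elf_on_indeterminate_only",
    missing_policy: str = "error",
) -> SequentialAlgorithm:
    """FIB-4 then ELF.

    Default variant ``elf_on_indeterminate_only``: FIB-4 < 1.30 rules out,
    FIB-4 > 2.67 rules in directly (ELF never consulted), and the
    indeterminate zone gets ELF with rule-in at >= ``elf_cutoff``. Variant
    ``elf_on_all_fib4_positive`` instead routes every subject with
    FIB-4 >= 1.30 to the ELF stage, so a positive call requires both tests.
    """
    if not (math.isfinite(fib4_low) and math.isfinite(fib4_high)):
        raise ConfigError("FIB-4 cutoffs must be finite")
    if variant == "elf_on_indeterminate_only":
        first = StageRule("fib4", fib4_low, fib4_high, low_inclusive=True, high_inclusive=False)
    elif variant == "elf_on_all_fib4_positive":
        first = StageRule("fib4", fib4_low, math.inf, low_inclusive=True, high_inclusive=False)
    else:
        raise ConfigError(f"unknown two-step variant {variant!r}")
    second = StageRule("elf", elf_cutoff, elf_cutoff, low_inclusive=True, high_inclusive=True)
    return SequentialAlgorithm(
        stages=(first, second),
        missing_policy=missing_policy,
        name=f"two_step[{variant}]",
    )


def make_three_step(
    fib4_low: float = 1.30,
    fib4_high: float = 2.67,
    elf_low: float = 7.7,
    elf_high: float = 9.8,
    arfi_cutoff: float | None = None,
    missing_policy: str = "error",
) -> SequentialAlgorithm:
    """FIB-4, then ELF with its own indeterminate zone, then ARFI.

    ELF < ``elf_low`` rules out, ELF >= ``elf_high`` rules in, and the
    ``elf_low``–``elf_high`` zone goes to ARFI with rule-in at or above
    ``arfi_cutoff``. ARFI shear-wave cutoffs vary between devices and no
    consensus value exists, so ``arfi_cutoff`` has no default and must be
    supplied explicitly (in m/s).
    """
    if arfi_cutoff is None:
        raise ConfigError(
            "arfi_cutoff is required: ARFI shear-wave cutoffs are device-specific "
            "and no consensus value exists — supply one explicitly (m/s)"
        )
    first = StageRule("fib4", fib4_low, fib4_high, low_inclusive=True, high_inclusive=False)
    second = StageRule("elf", elf_low, elf_high, low_inclusive=True, high_inclusive=True)
    third = StageRule("arfi", arfi_cutoff, arfi_cutoff, low_inclusive=True, high_inclusive=True)
    return SequentialAlgorithm(
        stages=(first, second, third),
        missing_policy=missing_policy,
        name="three_step",
    )


def make_single_test(
    marker: str, cutoff: float, inclusive: bool = False, missing_policy: str = "error"
) -> SequentialAlgorithm:
    """A one-stage rule: positive strictly above (or at, if ``inclusive``) the cutoff."""
    rule = StageRule(marker, cutoff, cutoff, low_inclusive=False, high_inclusive=inclusive)
    return SequentialAlgorithm(stages=(rule,), missing_policy=missing_policy, name=f"single[{marker}]")


def marker_value(
    record: PatientRecord,
    marker: str,
    scores: Optional[Mapping[str, float]] = None,
    ranges: ReferenceRanges | None = None,
) -> Optional[float]:
    """Resolve a marker for one subject.

    Resolution order: an explicit ``scores`` mapping (used when indices are
    simulated directly rather than derived from labs), then a record
    attribute (``elf``, ``arfi``, raw labs), then on-the-fly computation for
    the serum indices. Returns ``None`` when the marker is unresolvable.
    """
    if scores is not None and marker in scores:
        v = scores[marker]
        if v is not None and not (isinstance(v, float) and math.isnan(v)):
            return float(v)
        return None
    if hasattr(record, marker):
        v = getattr(record, marker)
        return None if v is None else float(v)
    ranges = ranges or ReferenceRanges()
    if marker == "fib4":
        return fib4(record.age, record.ast, record.alt, record.platelets)
    if marker == "apri":
        return apri(record.ast, ranges, record.platelets)
    if marker == "nfs":
        return nfs(
            record.age, record.bmi, record.ifg_or_diabetes,
            record.ast, record.alt, record.platelets, record.albumin,
        )
    return None


def _decide_one(
    record: PatientRecord,
    algorithm: SequentialAlgorithm,
    scores: Optional[Mapping[str, float]],
    ranges: ReferenceRanges | None,
) -> TriageDecision:
    stage_reached = -1
    for i, rule in enumerate(algorithm.stages):
        value = marker_value(record, rule.marker, scores=scores, ranges=ranges)
        if value is None:
            if algorithm.missing_policy == "error":
                raise DataError(
                    f"subject {record.id!r}: marker {rule.marker!r} needed at stage {i + 1} is missing"
                )
            if algorithm.missing_policy == "exclude":
                return TriageDecision(record.id, EXCLUDED, stage_reached, False)
            return TriageDecision(record.id, INDETERMINATE, stage_reached, False)
        stage_reached = i
        outcome = rule.decide(value)
        if outcome == RULE_IN:
            return TriageDecision(record.id, RULE_IN, i, True)
        if outcome == RULE_OUT:
            return TriageDecision(record.id, RULE_OUT, i, False)
    # still indeterminate after the last stage
    if algorithm.residual_policy == "treat_as_negative":
        return TriageDecision(record.id, RULE_OUT, stage_reached, False)
    if algorithm.residual_policy == "treat_as_positive":
        return TriageDecision(record.id, RULE_IN, stage_reached, True)
    return TriageDecision(record.id, INDETERMINATE, stage_reached, False)


def apply_algorithm(
    cohort: Iterable[PatientRecord] | PatientRecord,
    algorithm: SequentialAlgorithm,
    scores: Optional[Mapping[str, Mapping[str, float]]] = None,
    ranges: ReferenceRanges | None = None,
):
    """Run a pathway over one record or a cohort.

    ``scores``, when given, maps subject id to a marker->value mapping that
    takes precedence over record-derived values (e.g. directly simulated
    indices). Returns a single :class:`TriageDecision` for a single record,
    else a list in cohort order. Decisions are deterministic.
    """
    if isinstance(cohort, PatientRecord):
        per_subject = scores.get(cohort.id) if scores else None
        return _decide_one(cohort, algorithm, per_subject, ranges)
    decisions = []
    for record in cohort:
        per_subject = scores.get(record.id) if scores else None
        decisions.append(_decide_one(record, algorithm, per_subject, ranges))
    return decisions


def flow_counts(
    cohort: Sequence[PatientRecord],
    algorithm: SequentialAlgorithm,
    scores: Optional[Mapping[str, Mapping[str, float]]] = None,
    ranges: ReferenceRanges | None = None,
    decisions: Optional[Sequence[TriageDecision]] = None,
) -> FlowCounts:
    """Tally subject flow through every stage of a pathway.

    At each stage the rule-out, advance and rule-in counts sum to the number
    entering; residual indeterminates leave the last stage as "advance".
    Fractions are exact count ratios at full precision (NaN when the
    denominator is empty).
    """
    if decisions is None:
        decisions = apply_algorithm(cohort, algorithm, scores=scores, ranges=ranges)
    n_stages = len(algorithm.stages)
    entering = [0] * n_stages
    out = [0] * n_stages
    ruled_in = [0] * n_stages
    n_excluded = 0
    n_residual = 0
    avoided_in_zone = 0
    for d in decisions:
        if d.final == EXCLUDED:
            n_excluded += 1
            continue
        last = d.stage_reached
        if last < 0:  # missing marker at stage 1 under treat_as_indeterminate
            n_residual += 1
            continue
        for i in range(last + 1):
            entering[i] += 1
        if d.final == RULE_OUT:
            out[last] += 1
            if last >= 1:
                avoided_in_zone += 1
        elif d.final == RULE_IN:
            ruled_in[last] += 1
        else:
            n_residual += 1
    stages = []
    for i, rule in enumerate(algorithm.stages):
        # advance = whoever entered but was not classified here; at the last
        # stage these are the residual indeterminates
        advanced = entering[i] - out[i] - ruled_in[i]
        stages.append(StageFlow(rule.marker, entering[i], out[i], advanced, ruled_in[i]))
    n_subjects = len(decisions)
    zone = entering[1] if n_stages > 1 else 0
    frac_zone = zone / entering[0] if n_stages > 1 and entering[0] else float("nan")
    frac_avoided = avoided_in_zone / zone if zone else float("nan")
    return FlowCounts(
        stages=tuple(stages),
        n_subjects=n_subjects,
        n_excluded=n_excluded,
        n_indeterminate_final=n_residual,
        indeterminate_fraction_after_stage1=frac_zone,
        avoided_within_indeterminate=avoided_in_zone,
        avoided_within_indeterminate_fraction=frac_avoided,
    )


# -- configuration round-trip -------------------------------------------------

def algorithm_to_dict(algorithm: SequentialAlgorithm) -> dict:
    return {
        "name": algorithm.name,
        "residual_policy": algorithm.residual_policy,
        "missing_policy": algorithm.missing_policy,
        "stages": [
            {
                "marker": s.marker,
                "low": s.low_cutoff,
                "high": s.high_cutoff,
                "low_inclusive": s.low_inclusive,
                "high_inclusive": s.high_inclusive,
            }
            for s in algorithm.stages
        ],
    }


def algorithm_from_dict(data: Mapping) -> SequentialAlgorithm:
    try:
        stages = tuple(
            StageRule(
                marker=s["marker"],
                low_cutoff=float(s["low"]),
                high_cutoff=float(s["high"]),
                low_inclusive=bool(s.get("low_inclusive", True)),
                high_inclusive=bool(s.get("high_inclusive", True)),
            )
            for s in data["stages"]
        )
    except KeyError as exc:
        raise ConfigError(f"algorithm config missing key {exc}") from None
    return SequentialAlgorithm(
        stages=stages,
        residual_policy=data.get("residual_policy", "keep_indeterminate"),
        missing_policy=data.get("missing_policy", "error"),
        name=data.get("name", "sequential"),
    )


def algorithm_to_yaml(algorithm: SequentialAlgorithm) -> str:
    return yaml.safe_dump(algorithm_to_dict(algorithm), sort_keys=False)


def algorithm_from_yaml(text: str) -> SequentialAlgorithm:
    return algorithm_from_dict(yaml.safe_load(text))
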