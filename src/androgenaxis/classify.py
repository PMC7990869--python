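"""Three-step diagnostic classification of gonadal status.

The diagnostic work-up proceeds in three nested steps mirroring data
availability in clinical practice:

* **Step A** — total testosterone only: hypogonadal when TT is below the
  lower reference limit (strict ``<``).
* **Step B** — TT plus SHBG and calculated free testosterone: *overt*
  hypogonadism when TT is low and/or cFT is low (cFT boundary inclusive,
  ``<=``).
* **Step C** — full profile including LH: overt cases are split by LH into
  primary (high LH), secondary (low LH) and normogonadotropic (LH in
  range); non-overt cases with high LH are *compensated* hypogonadism —
  a normal free level maintained only by an elevated pituitary set point.

A clinical hypogonadism label additionally requires the patient to be
symptomatic; the classification functions themselves operate on hormone
values alone, and the cohort-level entry point enforces the symptomatic
gate.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .hormones import (
    DEFAULT_CONSTANTS,
    BindingConstants,
    HormonePanel,
    PatientRecord,
    calc_free_testosterone,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceLimits",
    "GonadalClass",
    "StepACall",
    "StepBCall",
    "GonadalStatus",
    "ClassifiedRecord",
    "PrevalenceTable",
    "MisdiagnosisReport",
    "ShbgSubgroupReport",
    "DEFAULT_LIMITS",
    "classify_step_a",
    "is_overt",
    "classify_step_c",
    "classify_panel",
    "classify_cohort",
    "tabulate_prevalence",
    "misdiagnosis_analysis",
    "shbg_subgroup",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching printed clinical tables."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ReferenceLimits:
    """Laboratory reference limits used by all three classification steps.

    Defaults: TT lower limit 3.46 ng/ml, cFT low when <= 65 pg/ml, LH normal
    range 1.5-9.4 mUI/ml, SHBG high when > 70 nmol/l.
    """

    tt_lower: float = 3.46     # ng/ml, hypogonadal when strictly below
    cft_lower: float = 65.0    # pg/ml, low when <= (inclusive)
    lh_lower: float = 1.5      # mUI/ml
    lh_upper: float = 9.4      # mUI/ml
    shbg_upper: float = 70.0   # nmol/l, high when strictly above

    def __post_init__(self) -> None:
        if not (0 < self.lh_lower < self.lh_upper):
            raise ValueError("LH range must satisfy 0 < lh_lower < lh_upper")
        for name in ("tt_lower", "cft_lower", "shbg_upper"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


DEFAULT_LIMITS = ReferenceLimits()


class StepACall(str, enum.Enum):
    EUGONADAL = "eugonadal"
    HYPOGONADAL = "hypogonadal"


class StepBCall(str, enum.Enum):
    EUGONADAL = "eugonadal"
    OVERT = "overt"


class GonadalClass(str, enum.Enum):
    """Five-way gonadal status from the full hormonal profile."""

    EUGONADAL = "eugonadal"
    PRIMARY = "primary"
    SECONDARY = "secondary"
    NORMOGONADOTROPIC = "normogonadotropic"
    COMPENSATED = "compensated"


#: step-C classes that constitute overt hypogonadism
OVERT_CLASSES = frozenset(
    {GonadalClass.PRIMARY, GonadalClass.SECONDARY,
     GonadalClass.NORMOGONADOTROPIC}
)


@dataclass(frozen=True)
class GonadalStatus:
    """Per-step diagnostic calls plus advisory flags."""

    step_a: Optional[StepACall] = None
    step_b: Optional[StepBCall] = None
    step_c: Optional[GonadalClass] = None
    flags: frozenset = field(default_factory=frozenset)

    @property
    def overt(self) -> Optional[bool]:
        if self.step_c is not None:
            return self.step_c in OVERT_CLASSES
        if self.step_b is not None:
            return self.step_b is StepBCall.OVERT
        return None


class ClassificationError(ValueError):
    """A required measurement for the requested step is missing."""


def classify_step_a(tt: Optional[float],
                    limits: ReferenceLimits = DEFAULT_LIMITS) -> StepACall:
    """TT-only call: hypogonadal iff TT is strictly below the lower limit."""
    if tt is None:
        raise ClassificationError("total testosterone is required for step A")
    if tt < 0:
        raise ValueError("tt must be non-negative")
    return StepACall.HYPOGONADAL if tt < limits.tt_lower else StepACall.EUGONADAL


def is_overt(tt: Optional[float], cft: Optional[float],
             limits: ReferenceLimits = DEFAULT_LIMITS) -> bool:
    """Overt hypogonadism: low TT (strict) and/or low cFT (inclusive)."""
    if tt is None:
        raise ClassificationError("total testosterone is required")
    if cft is None:
        raise ClassificationError(
            "cFT is missing; run calc_free_testosterone on the panel first")
    return tt < limits.tt_lower or cft <= limits.cft_lower


def classify_step_c(panel: HormonePanel,
                    limits: ReferenceLimits = DEFAULT_LIMITS) -> GonadalStatus:
    """Full-profile classification into the five gonadal-status classes.

    Overt cases split by LH: primary (LH > upper), secondary (LH < lower),
    normogonadotropic (LH in range, inclusive at both ends).  Non-overt
    cases with LH above the upper limit are compensated; non-overt with low
    LH remain eugonadal but receive an ``isolated_low_lh`` flag.  SHBG above
    its cutoff adds a ``high_shbg`` flag at any class.
    """
    step_a = classify_step_a(panel.tt, limits)
    overt = is_overt(panel.tt, panel.cft, limits)
    step_b = StepBCall.OVERT if overt else StepBCall.EUGONADAL

    flags = set()
    if panel.shbg is not None and panel.shbg > limits.shbg_upper:
        flags.add("high_shbg")

    if panel.lh is None:
        logger.debug("LH missing: downgrading to the TT+SHBG+cFT (step B) "
                     "call; compensated hypogonadism cannot be assessed")
        flags.add("lh_missing")
        return GonadalStatus(step_a=step_a, step_b=step_b,
                             flags=frozenset(flags))

    if overt:
        if panel.lh > limits.lh_upper:
            cls = GonadalClass.PRIMARY
        elif panel.lh < limits.lh_lower:
            cls = GonadalClass.SECONDARY
        else:
            cls = GonadalClass.NORMOGONADOTROPIC
    else:
        if panel.lh > limits.lh_upper:
            cls = GonadalClass.COMPENSATED
        else:
            cls = GonadalClass.EUGONADAL
            if panel.lh < limits.lh_lower:
                flags.add("isolated_low_lh")

    return GonadalStatus(step_a=step_a, step_b=step_b, step_c=cls,
                         flags=frozenset(flags))


def classify_panel(panel: HormonePanel,
                   limits: ReferenceLimits = DEFAULT_LIMITS,
                   constants: BindingConstants = DEFAULT_CONSTANTS
                   ) -> GonadalStatus:
    """Classify one panel at the deepest step its measurements allow.

    cFT is (re)computed from TT/SHBG/albumin whenever SHBG is available;
    a panel with TT only gets a step-A call alone.
    """
    if panel.shbg is None:
        return GonadalStatus(step_a=classify_step_a(panel.tt, limits))
    if panel.cft is None:
        panel = panel.with_cft(constants)
    return classify_step_c(panel, limits)


@dataclass(frozen=True)
class ClassifiedRecord:
    record: PatientRecord
    status: GonadalStatus

    @property
    def panel(self) -> HormonePanel:
        return self.record.panel


def classify_cohort(records: Sequence[PatientRecord],
                    limits: ReferenceLimits = DEFAULT_LIMITS,
                    constants: BindingConstants = DEFAULT_CONSTANTS
                    ) -> list[ClassifiedRecord]:
    """Classify every record; cFT recomputed where SHBG is present.

    Asymptomatic records are excluded with a logged count — biochemical
    findings alone do not establish clinical hypogonadism.
    """
    eligible = [r for r in records if r.symptomatic]
    dropped = len(records) - len(eligible)
    if dropped:
        logger.warning("excluded %d asymptomatic record(s) from "
                       "classification", dropped)
    out = []
    for rec in eligible:
        panel = rec.panel
        if panel.shbg is not None and panel.cft is None:
            panel = panel.with_cft(constants)
            rec = PatientRecord(
                id=rec.id, panel=panel, age=rec.age, bmi=rec.bmi,
                hiv_duration=rec.hiv_duration,
                cart_duration=rec.cart_duration, cd4_nadir=rec.cd4_nadir,
                cd4_nadir_pct=rec.cd4_nadir_pct, symptomatic=rec.symptomatic)
        out.append(ClassifiedRecord(rec, classify_panel(panel, limits,
                                                        constants)))
    n_no_lh = sum(1 for c in out
                  if c.status.step_b is not None and c.status.step_c is None)
    if n_no_lh:
        logger.warning("%d record(s) lack LH: downgraded to the "
                       "TT+SHBG+cFT (step B) call; compensated "
                       "hypogonadism not assessable for them", n_no_lh)
    return out


@dataclass(frozen=True)
class PrevalenceTable:
    """Counts and one-decimal percentages per diagnostic category."""

    step: str
    n_total: int
    counts: dict
    percentages: dict
    any_alteration: Optional[int] = None       # overt + compensated (step C)
    any_alteration_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_total:
            raise ValueError("category counts must sum to n_total")


def _pct(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 1)


def tabulate_prevalence(cohort: Sequence[ClassifiedRecord],
                        step: str = "C") -> PrevalenceTable:
    """Prevalence table at the requested step ('A', 'B' or 'C')."""
    if not cohort:
        raise ValueError("cannot tabulate an empty cohort")
    step = step.upper()
    n = len(cohort)
    if step == "A":
        keys = [c.value for c in StepACall]
        calls = [c.status.step_a for c in cohort]
    elif step == "B":
        keys = [c.value for c in StepBCall]
        calls = [c.status.step_b for c in cohort]
    elif step == "C":
        keys = [c.value for c in GonadalClass]
        calls = [c.status.step_c for c in cohort]
    else:
        raise ValueError(f"unknown step {step!r}")
    if any(c is None for c in calls):
        raise ClassificationError(
            f"cohort contains records not classified at step {step}")
    counts = {k: 0 for k in keys}
    for c in calls:
        counts[c.value] += 1
    pcts = {k: _pct(v, n) for k, v in counts.items()}
    any_alt = any_alt_pct = None
    if step == "C":
        any_alt = sum(counts[c.value] for c in OVERT_CLASSES)
        any_alt += counts[GonadalClass.COMPENSATED.value]
        any_alt_pct = _pct(any_alt, n)
    return PrevalenceTable(step=step, n_total=n, counts=counts,
                           percentages=pcts, any_alteration=any_alt,
                           any_alteration_pct=any_alt_pct)


@dataclass(frozen=True)
class MisdiagnosisReport:
    """What reliance on TT alone would have missed.

    ``diagnosis_ratio`` is the full-profile overt count over the TT-alone
    count, one decimal — the factor by which adding cFT raises the
    diagnosis rate.
    """

    n_total: int
    tt_alone_diagnoses: int
    full_profile_diagnoses: int
    missed_by_tt_alone: tuple        # record ids: normal TT but low cFT
    diagnosis_ratio: Optional[float]
    missed_step_c_classes: dict      # where the missed records land at step C


def misdiagnosis_analysis(cohort: Sequence[ClassifiedRecord]
                          ) -> MisdiagnosisReport:
    """Compare TT-only diagnoses with full-profile overt diagnoses."""
    if not cohort:
        raise ValueError("cannot analyse an empty cohort")
    tt_alone = [c for c in cohort if c.status.step_a is StepACall.HYPOGONADAL]
    if any(c.status.overt is None for c in cohort):
        raise ClassificationError("cohort must be classified at step B or C")
    full = [c for c in cohort if c.status.overt]
    missed = [c for c in full if c.status.step_a is StepACall.EUGONADAL]
    ratio = (round_half_up(len(full) / len(tt_alone), 1)
             if tt_alone else None)
    landed: dict = {}
    for c in missed:
        key = c.status.step_c.value if c.status.step_c else "overt"
        landed[key] = landed.get(key, 0) + 1
    return MisdiagnosisReport(
        n_total=len(cohort),
        tt_alone_diagnoses=len(tt_alone),
        full_profile_diagnoses=len(full),
        missed_by_tt_alone=tuple(c.record.id for c in missed),
        diagnosis_ratio=ratio,
        missed_step_c_classes=landed,
    )


@dataclass(frozen=True)
class ShbgSubgroupReport:
    n_total: int
    n_high_shbg: int
    pct_high_shbg: float
    n_eugonadal_within: int
    pct_eugonadal_within: Optional[float]  # undefined when no high-SHBG record


def shbg_subgroup(cohort: Sequence[ClassifiedRecord],
                  limits: ReferenceLimits = DEFAULT_LIMITS
                  ) -> ShbgSubgroupReport:
    """High-SHBG subgroup size and the eugonadal fraction within it."""
    if any(c.panel.shbg is None for c in cohort):
        raise ClassificationError("SHBG must be present for every record")
    high = [c for c in cohort if c.panel.shbg > limits.shbg_upper]
    eug = [c for c in high if c.status.step_c is GonadalClass.EUGONADAL]
    return ShbgSubgroupReport(
        n_total=len(cohort),
        n_high_shbg=len(high),
        pct_high_shbg=_pct(len(high), len(cohort)) if cohort else 0.0,
        n_eugonadal_within=len(eug),
        pct_eugonadal_within=(_pct(len(eug), len(high)) if high else None),
    )
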