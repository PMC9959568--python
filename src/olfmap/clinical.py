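"""Anthropometric, metabolic and dietary scoring rules.

Implements the clinical classification layer used throughout the package:

* body-mass index and its weight-excess classes (overweight >= 25 kg/m^2,
  obesity >= 30 kg/m^2);
* the IDF-style component flags for a European adult population —
  sex-specific waist-circumference cut-offs (80 cm women, 94 cm men,
  strictly exceeded), raised fasting glucose (>= 100 mg/dL or treatment),
  raised triglycerides (>= 150 mg/dL), reduced HDL cholesterol (< 50 mg/dL
  women, < 40 mg/dL men, or treatment), and raised blood pressure
  (>= 130 systolic or >= 85 diastolic, or treatment);
* the metabolic-syndrome rule: elevated waist circumference plus at least
  two of the four remaining component flags;
* the 0-55 Mediterranean Diet Score (MDS): eleven food-group components
  each scored 0-5, summed; adherence is called high at a configurable
  reference value (default 30).

All thresholds live in module-level constants so the provenance of every
comparison is visible at a glance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .errors import ParameterError

#: Sex-specific waist-circumference cut-offs (cm); elevation is strict (">").
WC_CUTOFF_CM = {"F": 80.0, "M": 94.0}
#: Sex-specific HDL-cholesterol cut-offs (mg/dL); reduction is strict ("<").
HDL_CUTOFF_MG_DL = {"F": 50.0, "M": 40.0}
FPG_CUTOFF_MG_DL = 100.0   # inclusive (">=")
TG_CUTOFF_MG_DL = 150.0    # inclusive
SBP_CUTOFF_MMHG = 130.0    # inclusive
DBP_CUTOFF_MMHG = 85.0     # inclusive

OVERWEIGHT_BMI = 25.0
OBESITY_BMI = 30.0

N_MDS_COMPONENTS = 11
MDS_MAX = 55
MDS_DEFAULT_CUTOFF = 30.0


@dataclass(frozen=True)
class IdfFlags:
    """Component flags of the metabolic-syndrome definition."""

    wc_elevated: bool
    high_bp: bool
    high_gly: bool
    high_tg: bool
    low_hdl: bool


def compute_bmi(weight_kg: float, height_m: float) -> tuple[float, Optional[str]]:
    """Return (BMI, weight-excess class).

    The class is ``"overweight"`` for 25 <= BMI < 30, ``"obesity"`` for
    BMI >= 30, and ``None`` for BMI < 25 — an out-of-cohort signal for a
    weight-excess study population; the caller decides whether to exclude.
    """
    if weight_kg <= 0 or height_m <= 0:
        raise ParameterError(
            f"weight and height must be positive, got {weight_kg} kg, {height_m} m"
        )
    bmi = weight_kg / height_m**2
    if bmi >= OBESITY_BMI:
        return bmi, "obesity"
    if bmi >= OVERWEIGHT_BMI:
        return bmi, "overweight"
    return bmi, None


def classify_idf_flags(record, bp_both_required: bool = False) -> IdfFlags:
    """Compute the five IDF component flags for one patient record.

    ``record`` is any object exposing ``sex`` ("F"/"M"), ``wc``, ``sbp``,
    ``dbp``, ``fpg``, ``hdl``, ``tg`` and the treatment flags
    ``treated_diabetes``, ``treated_dyslipidemia``, ``treated_hypertension``.

    ``bp_both_required`` switches the blood-pressure rule from the default
    either-or reading (systolic >= 130 OR diastolic >= 85) to the stricter
    conjunctive one; treatment for hypertension raises the flag either way.
    """
    sex = getattr(record, "sex", None)
    if sex not in WC_CUTOFF_CM:
        raise ParameterError(f"unknown sex {sex!r}; expected 'F' or 'M'")
    bp_raised = (
        (record.sbp >= SBP_CUTOFF_MMHG and record.dbp >= DBP_CUTOFF_MMHG)
        if bp_both_required
        else (record.sbp >= SBP_CUTOFF_MMHG or record.dbp >= DBP_CUTOFF_MMHG)
    )
    return IdfFlags(
        wc_elevated=record.wc > WC_CUTOFF_CM[sex],
        high_bp=bool(bp_raised or record.treated_hypertension),
        high_gly=bool(record.fpg >= FPG_CUTOFF_MG_DL or record.treated_diabetes),
        high_tg=bool(record.tg >= TG_CUTOFF_MG_DL),
        low_hdl=bool(record.hdl < HDL_CUTOFF_MG_DL[sex] or record.treated_dyslipidemia),
    )


def classify_mets(flags: IdfFlags) -> bool:
    """Metabolic syndrome: elevated waist circumference plus >= 2 of the
    four remaining component flags."""
    n_components = sum(
        (flags.high_bp, flags.high_gly, flags.high_tg, flags.low_hdl)
    )
    return bool(flags.wc_elevated and n_components >= 2)


def alcohol_score(ml_per_day: float) -> int:
    """Score daily alcohol volume on the 0-5 MDS component scale.

    Decreasing scores 5..1 correspond to consumption below 300, 400, 500,
    600 and 700 mL/day respectively (the 600-700 band, boundary included,
    scores 1); zero consumption or more than 700 mL/day scores 0.
    """
    if ml_per_day < 0:
        raise ParameterError(f"alcohol volume must be >= 0, got {ml_per_day}")
    if ml_per_day == 0 or ml_per_day > 700:
        return 0
    for score, upper in ((5, 300), (4, 400), (3, 500), (2, 600)):
        if ml_per_day < upper:
            return score
    return 1


def score_mds(
    components: Sequence[float],
    *,
    alcohol_ml: Optional[float] = None,
    cutoff: float = MDS_DEFAULT_CUTOFF,
) -> tuple[int, bool]:
    """Sum the 11 Mediterranean Diet Score components.

    ``components`` holds pre-binned 0-5 scores. By default all 11 items
    (including the already-scored alcohol item) are given; alternatively
    pass the 10 food components plus ``alcohol_ml`` in mL/day and the
    alcohol component is scored here.

    Returns ``(total, high_adherence)`` where adherence is high when the
    total reaches ``cutoff`` (default 30, a sample-derived reference value
    rather than a validated threshold).
    """
    comps = list(components)
    if alcohol_ml is not None:
        if len(comps) != N_MDS_COMPONENTS - 1:
            raise ParameterError(
                f"expected 10 food components with alcohol_ml, got {len(comps)}"
            )
        comps.append(alcohol_score(alcohol_ml))
    if len(comps) != N_MDS_COMPONENTS:
        raise ParameterError(f"expected 11 MDS components, got {len(comps)}")
    for i, c in enumerate(comps):
        if not (0 <= c <= 5):
            raise ParameterError(f"MDS component {i} out of range [0, 5]: {c}")
    total = int(round(sum(comps)))
    return total, total >= cutoff
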