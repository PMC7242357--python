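"""Progression class definition for knee-OA periods.

A period (one patient, two visits at least two years apart) is assigned one
of four classes from its raw outcome measurements:

* **P** (pain progression) -- the WOMAC pain subscale (0-100) shows either a
  progressive increase of at least 5 points/year ending at substantial pain
  (p_e >= 40), a rapid increase of at least 10 points/year ending at p_e >=
  35, or substantial sustained pain (p_s >= 40 and p_e >= 40).
* **S** (structural progression) -- the minimum joint-space width of the most
  affected knee narrows by at least 0.3 mm/year.
* **P+S** -- both criteria hold; **N** -- neither holds.

Per-knee resolution: the structural quantities come from the knee with the
greater JSW narrowing, while pain at each endpoint is the maximum over the
knees that reported it.  Periods whose required measurements are missing, or
that end at/after a knee replacement, are excluded -- the class is never
computed from imputed values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import CLASSES, CohortTable, Period

# Pain criterion thresholds (WOMAC points on the 0-100 scale).
PAIN_RATE_MIN = 5.0          # points/year, progressive increase
PAIN_RATE_RAPID = 10.0       # points/year, rapid increase
PAIN_END_MIN = 40.0          # substantial end-of-period pain
PAIN_END_RAPID = 35.0        # relaxed end pain for rapid increase
PAIN_SUSTAINED = 40.0        # sustained pain at both endpoints

# Structural criterion threshold (mm of minimum JSW lost per year).
JSW_RATE_MIN = 0.3

EXCLUDE_UNMEASURABLE = "unmeasurable"
EXCLUDE_POST_REPLACEMENT = "post_replacement"


class InvalidPeriodError(ValueError):
    """Raised for non-positive period durations."""


@dataclass(frozen=True)
class PeriodOutcome:
    """Resolved outcome measurements of one period.

    All pain values are on the 0-100 WOMAC scale (maximum over knees at each
    endpoint); JSW values are in mm and come from the most affected knee.
    ``measurable`` is False iff a required raw measurement is missing.
    """

    p_s: float
    p_e: float
    delta_p: float
    jsw_s: float
    jsw_e: float
    jsw_rate: float
    most_affected_knee: str | None
    measurable: bool


@dataclass(frozen=True)
class ProgressionLabel:
    p_label: bool
    s_label: bool

    @property
    def class_(self) -> str:
        if self.p_label and self.s_label:
            return "P+S"
        if self.p_label:
            return "P"
        if self.s_label:
            return "S"
        return "N"


def annualized_change(start_value: float, end_value: float,
                      duration_years: float, *, narrowing: bool = False) -> float:
    """Annualized change; ``narrowing=True`` flips the sign so that a
    decrease (JSW loss) is positive, matching the worsening convention."""
    if duration_years <= 0:
        raise InvalidPeriodError(f"period duration must be positive, got {duration_years}")
    if narrowing:
        return (start_value - end_value) / duration_years
    return (end_value - start_value) / duration_years


def rescale_womac(raw_score: float | np.ndarray, max_raw: float = 20.0):
    """Rescale a raw WOMAC pain subscale (default 0-20) to the 0-100 scale."""
    return np.asarray(raw_score, dtype=float) * (100.0 / max_raw)


def _require_measurable(outcome: PeriodOutcome) -> None:
    if not outcome.measurable:
        raise ValueError("outcome is unmeasurable; the period must be excluded, "
                         "never decided from imputed values")


def is_pain_progressive(outcome: PeriodOutcome) -> bool:
    """Pain criterion: progressive, rapid, or sustained substantial pain.

    All threshold comparisons are inclusive (>=).
    """
    _require_measurable(outcome)
    progressive = outcome.delta_p >= PAIN_RATE_MIN and outcome.p_e >= PAIN_END_MIN
    rapid = outcome.delta_p >= PAIN_RATE_RAPID and outcome.p_e >= PAIN_END_RAPID
    sustained = outcome.p_s >= PAIN_SUSTAINED and outcome.p_e >= PAIN_SUSTAINED
    return progressive or rapid or sustained


def is_structure_progressive(outcome: PeriodOutcome) -> bool:
    """Structural criterion: minimum JSW loss of at least 0.3 mm/year."""
    _require_measurable(outcome)
    return outcome.jsw_rate >= JSW_RATE_MIN


def assign_label(p: bool, s: bool) -> ProgressionLabel:
    return ProgressionLabel(p_label=bool(p), s_label=bool(s))


def resolve_knees(left: dict, right: dict, duration_years: float) -> PeriodOutcome:
    """Resolve per-knee measurements into a single period outcome.

    Each knee dict carries ``pain_s``, ``pain_e``, ``jsw_s``, ``jsw_e``
    (NaN/None for missing).  Pain endpoints take the per-timepoint maximum
    over reporting knees; JSW comes from the knee with greater narrowing
    (ties broken towards the smaller end-of-period JSW).
    """
    if duration_years <= 0:
        raise InvalidPeriodError(f"period duration must be positive, got {duration_years}")

    def _get(d: dict, key: str) -> float:
        v = d.get(key)
        return float(v) if v is not None and not (isinstance(v, float) and math.isnan(v)) else math.nan

    def _max_reported(values: list[float]) -> float:
        reported = [v for v in values if not math.isnan(v)]
        return max(reported) if reported else math.nan

    knees = {"left": left, "right": right}
    p_s = _max_reported([_get(d, "pain_s") for d in knees.values()])
    p_e = _max_reported([_get(d, "pain_e") for d in knees.values()])

    best_knee, best_rate, best_s, best_e = None, -math.inf, math.nan, math.nan
    for name, d in knees.items():
        js, je = _get(d, "jsw_s"), _get(d, "jsw_e")
        if math.isnan(js) or math.isnan(je):
            continue
        rate = annualized_change(js, je, duration_years, narrowing=True)
        better = rate > best_rate or (rate == best_rate and je < best_e)
        if best_knee is None or better:
            best_knee, best_rate, best_s, best_e = name, rate, js, je

    measurable = not (math.isnan(p_s) or math.isnan(p_e)) and best_knee is not None
    delta_p = (
        annualized_change(p_s, p_e, duration_years) if measurable else math.nan
    )
    return PeriodOutcome(
        p_s=float(p_s), p_e=float(p_e), delta_p=float(delta_p),
        jsw_s=best_s, jsw_e=best_e,
        jsw_rate=best_rate if best_knee is not None else math.nan,
        most_affected_knee=best_knee, measurable=measurable,
    )


def period_outcome(cohort: CohortTable, period: Period,
                   visits: pd.DataFrame | None = None) -> PeriodOutcome:
    """Build the PeriodOutcome of one period from raw cohort measurements."""
    if visits is None:
        visits = cohort.indexed_visits()
    knees = {}
    for knee in ("left", "right"):
        d = {}
        for tag, t in (("s", period.start), ("e", period.end)):
            try:
                row = visits.loc[(period.patient_id, t)]
            except KeyError:
                row = None
            d[f"pain_{tag}"] = row.get(f"womac_pain_{knee}", math.nan) if row is not None else math.nan
            d[f"jsw_{tag}"] = row.get(f"min_jsw_{knee}", math.nan) if row is not None else math.nan
        knees[knee] = d
    return resolve_knees(knees["left"], knees["right"], period.duration)


def label_periods(cohort: CohortTable, periods: list[Period]) -> pd.DataFrame:
    """Label each period or record its exclusion reason.

    Returns a frame with one row per period: patient_id, start, end,
    duration, p_s, p_e, delta_p, jsw_rate, class, exclusion_reason.  The
    class is computed only from raw outcome columns; covariates never enter.
    """
    visits = cohort.indexed_visits()
    first_repl = {pid: cohort.first_replacement(pid) for pid in cohort.patients()}
    rows = []
    for period in periods:
        base = {
            "patient_id": period.patient_id, "start": period.start,
            "end": period.end, "duration": period.duration,
            "p_s": math.nan, "p_e": math.nan, "delta_p": math.nan,
            "jsw_rate": math.nan, "class": None, "exclusion_reason": None,
        }
        if period.end >= first_repl.get(period.patient_id, math.inf):
            base["exclusion_reason"] = EXCLUDE_POST_REPLACEMENT
            rows.append(base)
            continue
        outcome = period_outcome(cohort, period, visits=visits)
        base.update(p_s=outcome.p_s, p_e=outcome.p_e, delta_p=outcome.delta_p,
                    jsw_rate=outcome.jsw_rate)
        if not outcome.measurable:
            base["exclusion_reason"] = EXCLUDE_UNMEASURABLE
        else:
            label = assign_label(is_pain_progressive(outcome),
                                 is_structure_progressive(outcome))
            base["class"] = label.class_
        rows.append(base)
    frame = pd.DataFrame(rows)
    frame["class"] = frame["class"].astype(object)
    return frame
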