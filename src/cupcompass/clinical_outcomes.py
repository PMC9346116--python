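"""Clinical-benefit analytics for molecularly guided therapy.

Progression-free survival (PFS) per therapy line, the PFS2/PFS1 ratio
(PFSr) comparing the first molecularly recommended therapy against the
last prior systemic therapy, the modified ratio (mPFSr) with an optional
denominator floor and ratio cap, Kaplan-Meier estimation and the
log-rank test.  PFSr > 1.3 flags clinical benefit; a ratio is undefined
when the prior line did not end in progression or death.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .io_formats import SurvivalRecord, TherapyLine

__all__ = [
    "DAYS_PER_MONTH",
    "BENEFIT_THRESHOLD",
    "PfsOutcome",
    "RatioResult",
    "MpfsrRule",
    "compute_pfs",
    "pfs_ratio",
    "modified_pfs_ratio",
    "km_estimate",
    "logrank_test",
    "cohort_summary",
    "patient_ratios",
]

DAYS_PER_MONTH = 30.4375  # mean Gregorian month
BENEFIT_THRESHOLD = 1.3


@dataclass
class PfsOutcome:
    patient_id: str
    pfs_months: float
    event: str  # progression | death | censored

    @property
    def had_event(self) -> bool:
        return self.event in ("progression", "death")


@dataclass
class RatioResult:
    patient_id: str
    pfs2: float
    pfs1: Optional[float] = None
    pfsr: Optional[float] = None
    mpfsr: Optional[float] = None
    benefit: Optional[bool] = None
    undefined_reason: Optional[str] = None  # no_progression_on_prior | missing_prior


@dataclass(frozen=True)
class MpfsrRule:
    """Parameters of the modified PFS ratio: floor on PFS1, cap on the ratio.

    With no floor and no cap the modified ratio equals the plain PFSr.
    """

    pfs1_floor_months: Optional[float] = None
    ratio_cap: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pfs1_floor_months is not None and self.pfs1_floor_months <= 0:
            raise ValueError("pfs1_floor_months must be positive")
        if self.ratio_cap is not None and self.ratio_cap <= 0:
            raise ValueError("ratio_cap must be positive")


def compute_pfs(line: TherapyLine, cutoff_date: _dt.date) -> PfsOutcome:
    """PFS of a therapy line in months (30.4375 days each).

    Progression and death are events; anything else is censored at the
    earlier of the recorded date and the cutoff.
    """
    if line.event_date is not None and line.event_type in ("progression", "death"):
        end, event = line.event_date, line.event_type
        if end > cutoff_date:
            end, event = cutoff_date, "censored"
    else:
        end = min(line.event_date, cutoff_date) if line.event_date else cutoff_date
        event = "censored"
    days = (end - line.start_date).days
    if days <= 0:
        raise ValueError(
            f"nonpositive PFS duration for {line.patient_id} ({line.start_date} .. {end})"
        )
    return PfsOutcome(line.patient_id, days / DAYS_PER_MONTH, event)


def pfs_ratio(prior: Optional[PfsOutcome], recommended: PfsOutcome) -> RatioResult:
    """PFSr = PFS2 / PFS1; defined only when the prior line ended in an event."""
    if prior is None:
        return RatioResult(
            patient_id=recommended.patient_id,
            pfs2=recommended.pfs_months,
            undefined_reason="missing_prior",
        )
    if prior.patient_id != recommended.patient_id:
        raise ValueError("prior and recommended outcomes belong to different patients")
    if not prior.had_event:
        return RatioResult(
            patient_id=recommended.patient_id,
            pfs2=recommended.pfs_months,
            pfs1=prior.pfs_months,
            undefined_reason="no_progression_on_prior",
        )
    if prior.pfs_months <= 0:
        raise ValueError("PFS1 must be positive")
    ratio = recommended.pfs_months / prior.pfs_months
    return RatioResult(
        patient_id=recommended.patient_id,
        pfs2=recommended.pfs_months,
        pfs1=prior.pfs_months,
        pfsr=ratio,
        mpfsr=ratio,
        benefit=ratio > BENEFIT_THRESHOLD,
    )


def modified_pfs_ratio(
    prior: PfsOutcome, recommended: PfsOutcome, rule: MpfsrRule = MpfsrRule()
) -> RatioResult:
    """PFS ratio with the denominator floored and/or the ratio capped."""
    result = pfs_ratio(prior, recommended)
    if result.pfsr is None:
        return result
    pfs1 = result.pfs1
    if rule.pfs1_floor_months is not None:
        pfs1 = max(pfs1, rule.pfs1_floor_months)
    mpfsr = result.pfs2 / pfs1
    if rule.ratio_cap is not None:
        mpfsr = min(mpfsr, rule.ratio_cap)
    result.mpfsr = mpfsr
    return result


def km_estimate(
    records: Sequence[SurvivalRecord],
) -> tuple[pd.DataFrame, Optional[float]]:
    """Kaplan-Meier survival curve and median.

    Returns the step function as a DataFrame (time, survival, at_risk)
    and the median survival time — the smallest event time where S(t)
    drops to 0.5 or below, or None when the curve never reaches 0.5.
    """
    if not records:
        raise ValueError("no survival records")
    times = np.array([r.time_months for r in records], dtype=float)
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    events = np.array([r.event for r in records], dtype=bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    curve = pd.DataFrame(
        {
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
            "at_risk": kmf.event_table["at_risk"].reindex(
                kmf.survival_function_.index
            ).to_numpy(),
        }
    )
    median = float(kmf.median_survival_time_)
    return curve, (None if np.isinf(median) else median)


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-sided 1-df log-rank chi-square comparing two survival groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ta = [r.time_months for r in group_a]
    tb = [r.time_months for r in group_b]
    ea = [r.event for r in group_a]
    eb = [r.event for r in group_b]
    if not any(ea) and not any(eb):
        return 0.0, 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.test_statistic), float(res.p_value)


def patient_ratios(
    lines: Sequence[TherapyLine],
    cutoff_date: _dt.date,
    rule: MpfsrRule = MpfsrRule(),
) -> list[RatioResult]:
    """Per-patient PFS ratios from raw therapy lines.

    Pairs each patient's first recommended line (PFS2) with the last
    pre-recommendation line (PFS1); patients without a recommended line
    are skipped.
    """
    by_patient: dict[str, dict[str, TherapyLine]] = {}
    for line in lines:
        by_patient.setdefault(line.patient_id, {})[line.line_role] = line
    results = []
    for patient_id in sorted(by_patient):
        roles = by_patient[patient_id]
        rec = roles.get("recommended_first")
        if rec is None:
            continue
        recommended = compute_pfs(rec, cutoff_date)
        prior_line = roles.get("pre_mtb_last")
        prior = compute_pfs(prior_line, cutoff_date) if prior_line else None
        if prior is None:
            results.append(pfs_ratio(None, recommended))
        else:
            results.append(modified_pfs_ratio(prior, recommended, rule))
    return results


def cohort_summary(ratios: Sequence[RatioResult]) -> pd.DataFrame:
    """Aggregate PFS1/PFS2/PFSr/mPFSr statistics and benefit counts.

    Patients whose ratio is undefined contribute to the PFS2 aggregates
    but not to the ratio aggregates, so the two statistics can carry
    different n.
    """
    if not ratios:
        return pd.DataFrame(
            columns=["n", "mean", "median", "min", "max"],
            index=pd.Index([], name="measure"),
        )
    defined = [r for r in ratios if r.pfsr is not None]

    def row(values):
        values = [v for v in values if v is not None]
        if not values:
            return {"n": 0, "mean": np.nan, "median": np.nan, "min": np.nan, "max": np.nan}
        arr = np.asarray(values, dtype=float)
        return {
            "n": len(arr),
            "mean": float(arr.mean()),
            "median": float(np.median(arr)),
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    table = pd.DataFrame(
        {
            "PFS1": row([r.pfs1 for r in defined]),
            "PFS2": row([r.pfs2 for r in ratios]),
            "PFSr": row([r.pfsr for r in defined]),
            "mPFSr": row([r.mpfsr for r in defined]),
        }
    ).T
    table.index.name = "measure"
    table["n"] = table["n"].astype(int)
    table.attrs["n_benefit"] = sum(bool(r.benefit) for r in defined)
    table.attrs["n_defined"] = len(defined)
    table.attrs["n_undefined"] = len(ratios) - len(defined)
    return table
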