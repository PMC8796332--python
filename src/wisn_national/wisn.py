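"""Facility-level WISN (Workload Indicators of Staffing Needs) arithmetic.

The WISN method converts a facility's annual activity volumes and per-activity
time standards into the number of staff of a cadre the workload requires:

    AWT  = [A - (B + C + D + E)] * F          available working time, h/year
    HSA  = sum_s volume_s / (AWT / unit_time_s)   staff for health services
    CAF  = 1 / (1 - total_CAS% / 100)         support-activity multiplier
    IAF  = total_IAS / AWT                    staff for additional activities
    WISN = HSA * CAF + IAF

Raw WISN values are rounded to integer staff counts; facilities are then
filtered by the study's exclusion rules (partial facilities, null WISN, and
nurse records with no individual-allowance component).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Sequence

NURSE_CADRES = frozenset({("PHC", "nurses"), ("CHC", "nurses")})

#: Weekly hours below which a facility is considered to run on a partial
#: basis (half of the standard 48 h workweek) and is excluded.
MIN_WEEKLY_HOURS = 24.0


class RoundingRule(str, Enum):
    HALF_UP = "half_up"
    CEILING = "ceiling"


class ExclusionReason(str, Enum):
    NONE = "none"
    UNDER_HALF_WORKWEEK = "under_half_workweek"
    NULL_WISN = "null_wisn"
    NULL_IAF_NURSE = "null_iaf_nurse"


class InvalidPolicyError(ValueError):
    """Leave policy leaves no available working time."""


class MissingStandardError(KeyError):
    """A service with nonzero volume has no activity standard."""


@dataclass(frozen=True)
class LeavePolicy:
    """Annual working-time parameters.

    ``working_days_A`` is days worked per year before leave; ``annual_leave_B``,
    ``sick_leave_C``, ``public_holidays_D`` and ``other_leave_E`` are days of
    leave; ``hours_per_day_F`` is the working day length in hours.  Defaults
    follow the leave allotment commonly used in Indian public-sector WISN
    studies (313 working days under a 6-day week, 49 leave days, 8 h days),
    giving 2112 h of available working time per year.
    """

    working_days_A: float = 313.0
    annual_leave_B: float = 12.0
    sick_leave_C: float = 10.0
    public_holidays_D: float = 17.0
    other_leave_E: float = 10.0
    hours_per_day_F: float = 8.0

    def total_leave(self) -> float:
        return (
            self.annual_leave_B
            + self.sick_leave_C
            + self.public_holidays_D
            + self.other_leave_E
        )


@dataclass(frozen=True)
class FacilityActivityRecord:
    """One facility x year x cadre activity observation."""

    facility_id: str
    state: str
    year: int
    centre_type: str  # "PHC" or "CHC"
    cadre: str
    service_volumes: Mapping[str, float]
    support_time_shares: Mapping[str, float] = field(default_factory=dict)
    #: activity -> (hours per year, number of staff involved)
    additional_activity_times: Mapping[str, tuple[float, float]] = field(
        default_factory=dict
    )
    weekly_hours: float = 48.0

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


@dataclass(frozen=True)
class FacilityWISNResult:
    facility_id: str
    state: str
    year: int
    centre_type: str
    cadre: str
    awt_hours: float
    hsa_requirement: float
    total_cas_pct: float
    caf: float
    total_ias_hours: float
    iaf: float
    wisn_raw: float
    wisn_rounded: int
    excluded: bool = False
    exclusion_reason: ExclusionReason = ExclusionReason.NONE

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


def compute_awt(policy: LeavePolicy) -> float:
    """Annual available working time in hours: ``[A - (B+C+D+E)] * F``."""
    leave = policy.total_leave()
    if leave < 0 or policy.hours_per_day_F <= 0:
        raise InvalidPolicyError("leave days must be >= 0 and hours/day > 0")
    awt = (policy.working_days_A - leave) * policy.hours_per_day_F
    if awt <= 0:
        raise InvalidPolicyError(
            f"leave ({leave} d) consumes all working days ({policy.working_days_A} d)"
        )
    return awt


def compute_standard_workload(awt_hours: float, unit_time_minutes: float) -> float:
    """Annual service units one worker can deliver: AWT / unit time."""
    if awt_hours <= 0 or unit_time_minutes <= 0:
        raise ValueError("AWT and unit time must be positive")
    return awt_hours / (unit_time_minutes / 60.0)


def compute_hsa_requirement(
    service_volumes: Mapping[str, float],
    unit_times: Mapping[str, float],
    awt_hours: float,
) -> float:
    """Staff required for direct health-service activities.

    Sum over services of annual workload divided by the standard workload
    derived from each service's unit time (minutes per unit).
    """
    total = 0.0
    for service, volume in service_volumes.items():
        if volume < 0:
            raise ValueError(f"negative volume for service {service!r}")
        if volume == 0:
            continue
        if service not in unit_times:
            raise MissingStandardError(
                f"no activity standard for service {service!r}"
            )
        total += volume / compute_standard_workload(awt_hours, unit_times[service])
    return total


def compute_caf(support_time_shares: Mapping[str, float]) -> tuple[float, float]:
    """Total category allowance (percent of AWT) and the CAF multiplier."""
    shares = list(support_time_shares.values())
    if any(s < 0 for s in shares):
        raise ValueError("support time shares must be >= 0")
    total = math.fsum(shares)
    if total >= 1.0:
        raise ValueError(
            f"support activities consume all working time (total share {total:.3f})"
        )
    return 100.0 * total, 1.0 / (1.0 - total)


def compute_iaf(
    additional_activity_times: Mapping[str, tuple[float, float]],
    awt_hours: float,
) -> tuple[float, float]:
    """Total individual allowance (hours x staff) and IAF = total IAS / AWT."""
    if awt_hours <= 0:
        raise ValueError("AWT must be positive")
    total_ias = 0.0
    for activity, (hours, staff) in additional_activity_times.items():
        if hours < 0 or staff < 0:
            raise ValueError(f"negative time or staff for activity {activity!r}")
        total_ias += hours * staff
    return total_ias, total_ias / awt_hours


def round_wisn(wisn_raw: float, rule: RoundingRule = RoundingRule.HALF_UP) -> int:
    if wisn_raw < 0:
        raise ValueError("raw WISN must be >= 0")
    if rule is RoundingRule.CEILING:
        return int(math.ceil(wisn_raw))
    # half-up: .5 always rounds away from zero (not banker's rounding)
    return int(math.floor(wisn_raw + 0.5))


def compute_wisn(
    hsa: float,
    caf: float,
    iaf: float,
    rule: RoundingRule = RoundingRule.HALF_UP,
) -> tuple[float, int]:
    """``WISN = HSA * CAF + IAF``, raw and rounded."""
    if hsa < 0 or caf < 1 or iaf < 0:
        raise ValueError("require hsa >= 0, caf >= 1, iaf >= 0")
    raw = hsa * caf + iaf
    return raw, round_wisn(raw, rule)


def compute_facility_wisn(
    record: FacilityActivityRecord,
    unit_times: Mapping[str, float],
    policy: LeavePolicy,
    rule: RoundingRule = RoundingRule.HALF_UP,
) -> FacilityWISNResult:
    """Full WISN computation for one facility observation (no exclusions)."""
    try:
        awt = compute_awt(policy)
        hsa = compute_hsa_requirement(record.service_volumes, unit_times, awt)
        total_cas_pct, caf = compute_caf(record.support_time_shares)
        total_ias, iaf = compute_iaf(record.additional_activity_times, awt)
        raw, rounded = compute_wisn(hsa, caf, iaf, rule)
    except (ValueError, KeyError) as exc:
        raise type(exc)(
            f"facility {record.facility_id} ({record.combo}, {record.year}): {exc}"
        ) from exc
    return FacilityWISNResult(
        facility_id=record.facility_id,
        state=record.state,
        year=record.year,
        centre_type=record.centre_type,
        cadre=record.cadre,
        awt_hours=awt,
        hsa_requirement=hsa,
        total_cas_pct=total_cas_pct,
        caf=caf,
        total_ias_hours=total_ias,
        iaf=iaf,
        wisn_raw=raw,
        wisn_rounded=rounded,
    )


class ActivityStandardTable:
    """Unit-time standards in minutes per service unit, keyed by
    (centre_type, cadre, service)."""

    def __init__(self, unit_times: Mapping[tuple[str, str, str], float]):
        for key, minutes in unit_times.items():
            if minutes <= 0:
                raise ValueError(f"unit time must be positive for {key}")
        self._unit_times = dict(unit_times)

    def for_combo(self, centre_type: str, cadre: str) -> dict[str, float]:
        return {
            service: minutes
            for (ct, cd, service), minutes in self._unit_times.items()
            if ct == centre_type and cd == cadre
        }

    def items(self):
        return self._unit_times.items()


def compute_panel(
    records: Sequence[FacilityActivityRecord],
    standards: ActivityStandardTable,
    policy: LeavePolicy,
    rule: RoundingRule = RoundingRule.HALF_UP,
) -> list[FacilityWISNResult]:
    """Compute WISN for every record and apply the exclusion filters."""
    results = [
        compute_facility_wisn(
            rec, standards.for_combo(rec.centre_type, rec.cadre), policy, rule
        )
        for rec in records
    ]
    return apply_exclusions(results, records)


def apply_exclusions(
    results: Sequence[FacilityWISNResult],
    records: Sequence[FacilityActivityRecord],
) -> list[FacilityWISNResult]:
    """Flag excluded observations; precedence partial-workweek > null WISN >
    nurse with no individual-allowance component.

    Returns all results with ``excluded``/``exclusion_reason`` set; the caller
    filters on ``excluded`` to obtain the retained panel.
    """
    by_key = {
        (r.facility_id, r.year, r.centre_type, r.cadre): r for r in records
    }
    out: list[FacilityWISNResult] = []
    for res in results:
        rec = by_key.get((res.facility_id, res.year, res.centre_type, res.cadre))
        if rec is None:
            raise KeyError(
                f"no activity record for result {res.facility_id}/{res.year}/{res.combo}"
            )
        reason = ExclusionReason.NONE
        if rec.weekly_hours < MIN_WEEKLY_HOURS:
            reason = ExclusionReason.UNDER_HALF_WORKWEEK
        elif res.wisn_rounded == 0:
            reason = ExclusionReason.NULL_WISN
        elif (
            res.centre_type,
            res.cadre,
        ) in NURSE_CADRES and res.total_ias_hours == 0:
            reason = ExclusionReason.NULL_IAF_NURSE
        if reason is not ExclusionReason.NONE:
            res = FacilityWISNResult(
                **{
                    **res.__dict__,
                    "excluded": True,
                    "exclusion_reason": reason,
                }
            )
        out.append(res)
    return out


def retained(results: Sequence[FacilityWISNResult]) -> list[FacilityWISNResult]:
    return [r for r in results if not r.excluded]
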