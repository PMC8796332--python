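"""State and national staffing-gap projections.

Given a modelled per-centre requirement threshold ``WISN`` for each
centre-cadre combination and state-level staffing counts (in-position P,
sanctioned S, functional centres N), compute

    WISN ratio                  = P / (WISN x N)
    WISN difference per centre  = P/N - WISN
    WISN difference overall     = P - WISN x N
    sanctioning differences     = same with S in place of P

and their categorical interpretations: workforce problem (balance / surplus
/ shortage by the sign of the WISN difference), workload pressure (binned
WISN ratio: [0,0.25) very high, [0.25,0.5) high, [0.5,0.75) medium,
[0.75,1) low, 1 normal, >1 none) and sanctioning problem (under / optimal /
over by the sign of the sanctioning difference).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Absolute tolerance for the ratio = 1 and difference = 0 boundary cases.
DEFAULT_TOLERANCE = 1e-9

NATIONAL_LABEL = "India"


@dataclass(frozen=True)
class StateStaffingRecord:
    """State-level staffing for one centre-cadre combination."""

    state: str
    centre_type: str
    cadre: str
    in_position_P: int
    sanctioned_S: int
    n_centres_N: int

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


@dataclass(frozen=True)
class ProjectionResult:
    state: str
    centre_type: str
    cadre: str
    in_position_P: int
    sanctioned_S: int
    n_centres_N: int
    wisn_threshold: int
    wisn_ratio: float
    diff_per_centre: float
    diff_overall: float
    sanct_diff_per_centre: float
    sanct_diff_overall: float
    workforce_problem: str
    workload_pressure: str
    sanctioning_problem: str

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


def wisn_ratio(p: float, n: int, threshold: float) -> float:
    if threshold <= 0:
        raise ValueError("WISN threshold must be positive")
    if n < 1:
        raise ValueError("need at least one functional centre")
    return p / (threshold * n)


def wisn_differences(p: float, n: int, threshold: float) -> tuple[float, float]:
    """(per-centre, overall) staffing difference; overall = N x per-centre."""
    if threshold <= 0:
        raise ValueError("WISN threshold must be positive")
    if n < 1:
        raise ValueError("need at least one functional centre")
    return p / n - threshold, p - threshold * n


def sanctioning_differences(s: float, n: int, threshold: float) -> tuple[float, float]:
    return wisn_differences(s, n, threshold)


def categorise(
    ratio: float,
    diff: float,
    sanct_diff: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> tuple[str, str, str]:
    """Categorical labels for a projection row.

    Ratio bins are half-open on the left; a ratio within ``tolerance`` of 1
    is "normal" pressure, above 1 is "none".  Differences within
    ``tolerance`` of 0 are balance/optimal.
    """
    if ratio < 0:
        raise ValueError("WISN ratio must be >= 0")

    if abs(diff) <= tolerance:
        workforce = "balance"
    elif diff > 0:
        workforce = "surplus"
    else:
        workforce = "shortage"

    if abs(ratio - 1.0) <= tolerance:
        pressure = "normal"
    elif ratio > 1.0:
        pressure = "none"
    elif ratio < 0.25:
        pressure = "very_high"
    elif ratio < 0.5:
        pressure = "high"
    elif ratio < 0.75:
        pressure = "medium"
    else:
        pressure = "low"

    if abs(sanct_diff) <= tolerance:
        sanctioning = "optimal"
    elif sanct_diff > 0:
        sanctioning = "over"
    else:
        sanctioning = "under"

    return workforce, pressure, sanctioning


def project_record(
    record: StateStaffingRecord,
    threshold: int,
    tolerance: float = DEFAULT_TOLERANCE,
) -> ProjectionResult:
    ratio = wisn_ratio(record.in_position_P, record.n_centres_N, threshold)
    d_pc, d_all = wisn_differences(record.in_position_P, record.n_centres_N, threshold)
    s_pc, s_all = sanctioning_differences(
        record.sanctioned_S, record.n_centres_N, threshold
    )
    workforce, pressure, sanctioning = categorise(ratio, d_all, s_all, tolerance)
    return ProjectionResult(
        state=record.state,
        centre_type=record.centre_type,
        cadre=record.cadre,
        in_position_P=record.in_position_P,
        sanctioned_S=record.sanctioned_S,
        n_centres_N=record.n_centres_N,
        wisn_threshold=threshold,
        wisn_ratio=ratio,
        diff_per_centre=d_pc,
        diff_overall=d_all,
        sanct_diff_per_centre=s_pc,
        sanct_diff_overall=s_all,
        workforce_problem=workforce,
        workload_pressure=pressure,
        sanctioning_problem=sanctioning,
    )


def project_all(
    state_table: Sequence[StateStaffingRecord],
    thresholds: Mapping[tuple[str, str], int],
    tolerance: float = DEFAULT_TOLERANCE,
) -> list[ProjectionResult]:
    """Project every state row plus one national row per combo.

    The national row uses P, S and N summed over the states present for the
    combo.  Rows whose combo lacks a threshold raise; rows with invalid
    counts are skipped with a logged reason (mirroring the exclusion of
    states with incomplete staffing data).
    """
    results: list[ProjectionResult] = []
    totals: dict[tuple[str, str], list[int]] = {}
    for rec in state_table:
        key = (rec.centre_type, rec.cadre)
        if key not in thresholds:
            raise KeyError(f"no WISN threshold for combo {rec.combo}")
        if rec.n_centres_N < 1 or rec.in_position_P < 0 or rec.sanctioned_S < 0:
            logger.warning(
                "skipping %s / %s: invalid counts (P=%s, S=%s, N=%s)",
                rec.state, rec.combo, rec.in_position_P, rec.sanctioned_S,
                rec.n_centres_N,
            )
            continue
        results.append(project_record(rec, thresholds[key], tolerance))
        t = totals.setdefault(key, [0, 0, 0])
        t[0] += rec.in_position_P
        t[1] += rec.sanctioned_S
        t[2] += rec.n_centres_N
    for key in sorted(totals):
        p, s, n = totals[key]
        national = StateStaffingRecord(
            state=NATIONAL_LABEL,
            centre_type=key[0],
            cadre=key[1],
            in_position_P=p,
            sanctioned_S=s,
            n_centres_N=n,
        )
        results.append(project_record(national, thresholds[key], tolerance))
    return results


def projection_frame(results: Sequence[ProjectionResult]) -> pd.DataFrame:
    """Wide table, one row per state x combo (plus national rows)."""
    return pd.DataFrame([r.__dict__ for r in results])


def long_frame(results: Sequence[ProjectionResult]) -> pd.DataFrame:
    """Long state-metric table (state, combo, metric, value, category),
    suitable for mapping tools."""
    rows = []
    for r in results:
        combo = r.combo
        rows.extend(
            [
                (r.state, combo, "wisn_ratio", r.wisn_ratio, r.workload_pressure),
                (r.state, combo, "diff_per_centre", r.diff_per_centre,
                 r.workforce_problem),
                (r.state, combo, "diff_overall", r.diff_overall,
                 r.workforce_problem),
                (r.state, combo, "sanct_diff_per_centre", r.sanct_diff_per_centre,
                 r.sanctioning_problem),
                (r.state, combo, "sanct_diff_overall", r.sanct_diff_overall,
                 r.sanctioning_problem),
            ]
        )
    return pd.DataFrame(
        rows, columns=["state", "combo", "metric", "value", "category"]
    )
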