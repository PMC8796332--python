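"""CSV and config-file formats.

Facility panel CSV (one row per facility x year x cadre):
  facility_id, state, year, centre_type, cadre, weekly_hours, cas_units,
  vol_<service> ...   annual service volumes (units/year)
  cas_<activity> ...  support-activity time, as a fraction of AWT when
                      cas_units == "fraction", or annual hours when
                      cas_units == "hours_per_year"
  ias_<activity>_hours, ias_<activity>_staff ...  additional activities

Activity standards CSV: centre_type, cadre, service, unit_time_minutes.
State staffing CSV: state, centre_type, cadre, in_position, sanctioned,
n_centres.  Threshold CSV is the output of the national model stage.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .projection import StateStaffingRecord
from .wisn import (
    ActivityStandardTable,
    FacilityActivityRecord,
    FacilityWISNResult,
    LeavePolicy,
    compute_awt,
)

STATE_TABLE_COLUMNS = [
    "state", "centre_type", "cadre", "in_position", "sanctioned", "n_centres",
]


def panel_to_frame(records: Sequence[FacilityActivityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row: dict = {
            "facility_id": r.facility_id,
            "state": r.state,
            "year": r.year,
            "centre_type": r.centre_type,
            "cadre": r.cadre,
            "weekly_hours": r.weekly_hours,
            "cas_units": "fraction",
        }
        for s, v in r.service_volumes.items():
            row[f"vol_{s}"] = v
        for a, share in r.support_time_shares.items():
            row[f"cas_{a}"] = share
        for a, (hours, staff) in r.additional_activity_times.items():
            row[f"ias_{a}_hours"] = hours
            row[f"ias_{a}_staff"] = staff
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_panel(
    frame: pd.DataFrame, policy: LeavePolicy | None = None
) -> list[FacilityActivityRecord]:
    """Inverse of :func:`panel_to_frame`.

    Rows flagged ``cas_units == "hours_per_year"`` have their support times
    converted to fractions of AWT, which requires ``policy``.
    """
    records = []
    vol_cols = [c for c in frame.columns if c.startswith("vol_")]
    cas_cols = [c for c in frame.columns if c.startswith("cas_") and c != "cas_units"]
    ias_hour_cols = [
        c for c in frame.columns if c.startswith("ias_") and c.endswith("_hours")
    ]
    for _, row in frame.iterrows():
        cas_units = row.get("cas_units", "fraction")
        shares = {}
        for c in cas_cols:
            val = row[c]
            if pd.isna(val):
                continue
            if cas_units == "hours_per_year":
                if policy is None:
                    raise ValueError(
                        "cas_units == 'hours_per_year' needs a leave policy"
                    )
                val = float(val) / compute_awt(policy)
            shares[c[len("cas_"):]] = float(val)
        additional = {}
        for c in ias_hour_cols:
            if pd.isna(row[c]):
                continue
            activity = c[len("ias_"):-len("_hours")]
            staff = row.get(f"ias_{activity}_staff", 1.0)
            additional[activity] = (
                float(row[c]),
                1.0 if pd.isna(staff) else float(staff),
            )
        records.append(
            FacilityActivityRecord(
                facility_id=str(row["facility_id"]),
                state=str(row["state"]),
                year=int(row["year"]),
                centre_type=str(row["centre_type"]),
                cadre=str(row["cadre"]),
                service_volumes={
                    c[len("vol_"):]: float(row[c])
                    for c in vol_cols
                    if not pd.isna(row[c])
                },
                support_time_shares=shares,
                additional_activity_times=additional,
                weekly_hours=float(row["weekly_hours"]),
            )
        )
    return records


def standards_to_frame(standards: ActivityStandardTable) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "centre_type": ct,
                "cadre": cadre,
                "service": service,
                "unit_time_minutes": minutes,
            }
            for (ct, cadre, service), minutes in sorted(standards.items())
        ]
    )


def frame_to_standards(frame: pd.DataFrame) -> ActivityStandardTable:
    return ActivityStandardTable(
        {
            (row.centre_type, row.cadre, row.service): float(row.unit_time_minutes)
            for row in frame.itertuples()
        }
    )


def results_to_frame(results: Sequence[FacilityWISNResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        d = dict(r.__dict__)
        d["exclusion_reason"] = r.exclusion_reason.value
        rows.append(d)
    return pd.DataFrame(rows)


def state_table_to_frame(records: Sequence[StateStaffingRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "state": r.state,
                "centre_type": r.centre_type,
                "cadre": r.cadre,
                "in_position": r.in_position_P,
                "sanctioned": r.sanctioned_S,
                "n_centres": r.n_centres_N,
            }
            for r in records
        ]
    )


def frame_to_state_table(frame: pd.DataFrame) -> list[StateStaffingRecord]:
    records = []
    for row in frame.itertuples():
        records.append(
            StateStaffingRecord(
                state=str(row.state),
                centre_type=str(row.centre_type),
                cadre=str(row.cadre),
                in_position_P=int(row.in_position),
                sanctioned_S=int(row.sanctioned),
                n_centres_N=int(row.n_centres),
            )
        )
    return records


def load_config_file(path: str | Path) -> dict:
    """YAML or JSON run configuration."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".json",):
        return json.loads(text)
    return yaml.safe_load(text)
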