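#!/usr/bin/env python
"""Compute facility-level WISN staffing requirements with exclusion audit.

Reads results/facility_panel.csv and results/activity_standards.csv, applies
the AWT/HSA/CAF/IAF composition and the exclusion filters (partial
workweek, null WISN, nurse records without an individual-allowance
component), and writes results/facility_wisn.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wisn_national import io as wio
from wisn_national.wisn import LeavePolicy, compute_panel, retained

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

policy = LeavePolicy()
records = wio.frame_to_panel(
    pd.read_csv(args.results / "facility_panel.csv"), policy
)
standards = wio.frame_to_standards(
    pd.read_csv(args.results / "activity_standards.csv")
)
results = compute_panel(records, standards, policy)
wio.results_to_frame(results).to_csv(
    args.results / "facility_wisn.csv", index=False
)

kept = retained(results)
tally = pd.Series([r.exclusion_reason.value for r in results]).value_counts()
print(f"{len(kept)}/{len(results)} observations retained")
print("exclusions:", tally.drop("none", errors="ignore").to_dict())
frame = wio.results_to_frame(kept)
means = frame.groupby(["centre_type", "cadre"])["wisn_rounded"].agg(
    ["count", "mean", "std"]
)
print("rounded WISN by combo (facility-level, unmodelled):")
print(means.round(1).to_string())
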