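#!/usr/bin/env python
"""Project the modelled thresholds against state staffing.

Combines the integer thresholds with state-level in-position staff P,
sanctioned posts S and functional centre counts N to compute WISN ratios,
per-centre and overall WISN differences, sanctioning differences, and their
category labels for every state plus the national aggregate.  Writes
results/projection.csv and results/state_metrics_long.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wisn_national import io as wio
from wisn_national.projection import long_frame, project_all, projection_frame

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

records = wio.frame_to_state_table(
    pd.read_csv(args.results / "state_staffing.csv").dropna()
)
tf = pd.read_csv(args.results / "national_thresholds.csv")
thresholds = {
    (r.centre_type, r.cadre): int(r.wisn_threshold) for r in tf.itertuples()
}
results = project_all(records, thresholds)
projection_frame(results).to_csv(args.results / "projection.csv", index=False)
long_frame(results).to_csv(
    args.results / "state_metrics_long.csv", index=False
)

national = projection_frame([r for r in results if r.state == "India"])
print("national projections:")
cols = ["centre_type", "cadre", "wisn_ratio", "diff_per_centre",
        "diff_overall", "workforce_problem", "workload_pressure",
        "sanctioning_problem"]
print(national[cols].round(3).to_string(index=False))
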