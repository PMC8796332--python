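#!/usr/bin/env python
"""Workload-pressure co-occurrence and sanctioning concordance.

From the state-level projections: Spearman correlations between cadres'
WISN ratios across states (pairwise for PHC's two cadres, partial for the
six CHC cadres), and Lin's concordance between sanctioned posts and
WISN-based requirements per combo.  Writes
results/workload_correlation_<centre>.csv and
results/sanctioning_agreement.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wisn_national.agreement import (
    agreement_frame,
    correlation_matrix,
    ratio_matrix,
    sanctioning_agreement,
)

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

proj = pd.read_csv(args.results / "projection.csv")
for ct in sorted(proj["centre_type"].unique()):
    ratios = ratio_matrix(proj, ct)
    cadres = [c for c in ratios.columns if ratios[c].notna().any()]
    if len(cadres) < 2:
        continue
    method = "partial" if len(cadres) > 2 else "pairwise"
    rho, pval = correlation_matrix(ratios, cadres, method)
    rho.to_csv(args.results / f"workload_correlation_{ct}.csv")
    print(f"{ct} ({method} Spearman rho across states):")
    print(rho.round(2).to_string())

agreement = sanctioning_agreement(proj)
frame = agreement_frame(agreement)
frame.to_csv(args.results / "sanctioning_agreement.csv", index=False)
poor = frame[frame["poor_agreement"]]
print(
    f"concordance: {len(poor)}/{len(frame)} combos below the 0.90 "
    "poor-agreement line"
)
print(frame[["centre_type", "cadre", "n_states", "ccc", "bias_correction"]]
      .round(3).to_string(index=False))
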