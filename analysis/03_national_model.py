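#!/usr/bin/env python
"""Model nationally representative per-centre WISN thresholds.

For each centre-cadre combination: check across-state heterogeneity of the
raw WISN values (Kruskal-Wallis), fit the log-link Poisson GEE with
independence / exchangeable / AR(1) working correlations clustered on
facility, select by Pan's QIC, and report the marginal mean over the
observed state x year design with a 95% CI plus the raw-value model's mean
and SE.  Writes results/national_thresholds.csv and
results/state_heterogeneity.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from wisn_national.national import (
    kruskal_wallis_by_state,
    select_and_predict,
    thresholds_frame,
)

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

frame = pd.read_csv(args.results / "facility_wisn.csv")
panel = frame[~frame["excluded"]][
    ["facility_id", "state", "year", "centre_type", "cadre",
     "wisn_raw", "wisn_rounded"]
]

het_rows, thresholds = [], []
for ct, cadre in sorted(
    panel[["centre_type", "cadre"]].drop_duplicates().itertuples(index=False)
):
    h, p = kruskal_wallis_by_state(panel, ct, cadre)
    het_rows.append({"centre_type": ct, "cadre": cadre, "H": h, "p": p})
    t = select_and_predict(panel, ct, cadre)
    thresholds.append(t)
    print(
        f"{t.combo}: threshold {t.wisn_threshold} "
        f"(mean {t.mean_rounded_model:.2f} [{t.ci_low:.2f}, {t.ci_high:.2f}], "
        f"raw {t.mean_raw:.3f} +/- {t.se_raw:.3f}, {t.chosen_structure}, "
        f"KW p = {p:.3g})"
    )

pd.DataFrame(het_rows).to_csv(
    args.results / "state_heterogeneity.csv", index=False
)
thresholds_frame(thresholds).to_csv(
    args.results / "national_thresholds.csv", index=False
)
sig = sum(1 for r in het_rows if r["p"] < 0.05)
print(f"{sig}/{len(het_rows)} combos show significant across-state differences")
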