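#!/usr/bin/env python
"""Generate the study-condition inputs: a facility activity panel (5 states
x 8 years x 8 centre-cadre combos, unbalanced), the matching activity
standards, and a 30-state staffing table with systematic under-sanctioning
and partial post-filling.

Writes facility_panel.csv, activity_standards.csv, state_staffing.csv under
results/.
"""

import argparse
from pathlib import Path

from wisn_national import io as wio
from wisn_national.synthetic import (
    SimulationConfig,
    default_scenario,
    generate_facility_panel,
    generate_state_table,
    standards_for,
)

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()
args.out.mkdir(parents=True, exist_ok=True)

config = SimulationConfig(seed=args.seed)
records = generate_facility_panel(config)
wio.panel_to_frame(records).to_csv(args.out / "facility_panel.csv", index=False)
wio.standards_to_frame(standards_for(config)).to_csv(
    args.out / "activity_standards.csv", index=False
)

scenario = default_scenario(dict(config.profiles), seed=args.seed)
table = generate_state_table(scenario, seed=args.seed)
wio.state_table_to_frame(table).to_csv(
    args.out / "state_staffing.csv", index=False
)

states = {r.state for r in records}
print(
    f"panel: {len(records)} facility-year-cadre records across "
    f"{len(states)} states and {len(set(config.years))} years"
)
print(f"state table: {len(table)} rows ({len(scenario.n_centres_by_state)} states)")
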