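"""End-to-end orchestration: simulate/load -> facility WISN -> national
thresholds -> projections -> agreement, with a JSON run manifest.

All randomness flows from the single run seed; stage-level seeds are derived
from it deterministically, so identical configuration and seed reproduce
identical outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .agreement import agreement_frame, correlation_matrix, ratio_matrix, sanctioning_agreement
from .national import kruskal_wallis_by_state, panel_frame, select_and_predict, thresholds_frame
from .projection import long_frame, project_all, projection_frame
from .synthetic import (
    SimulationConfig,
    default_scenario,
    generate_facility_panel,
    generate_state_table,
    standards_for,
)
from .wisn import LeavePolicy, RoundingRule, compute_panel

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Run configuration: either the three input CSV paths or an inline
    simulation config, plus analysis options."""

    output_dir: str = "results"
    seed: int = 0
    panel_csv: str | None = None
    standards_csv: str | None = None
    state_table_csv: str | None = None
    simulate: SimulationConfig | None = None
    scenario_kwargs: dict = field(default_factory=dict)
    leave_policy: LeavePolicy = field(default_factory=LeavePolicy)
    rounding_rule: RoundingRule = RoundingRule.HALF_UP
    marginal_weighting: str = "equal_cell"
    tolerance: float = 1e-9

    def validate(self) -> None:
        has_paths = all(
            p is not None
            for p in (self.panel_csv, self.standards_csv, self.state_table_csv)
        )
        if has_paths == (self.simulate is not None):
            raise ValueError(
                "provide either all three input CSV paths or a simulation "
                "config, not both"
            )


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    excluded_states: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_inputs(
    panel_csv: str | Path,
    standards_csv: str | Path,
    state_table_csv: str | Path,
) -> ValidationReport:
    """Check input files for structural problems without mutating them."""
    report = ValidationReport()
    panel = pd.read_csv(panel_csv)
    standards = pd.read_csv(standards_csv)
    state = pd.read_csv(state_table_csv)

    for col in ("facility_id", "state", "year", "centre_type", "cadre",
                "weekly_hours"):
        if col not in panel.columns:
            report.errors.append(f"panel: missing column {col!r}")
    for col in ("centre_type", "cadre", "service", "unit_time_minutes"):
        if col not in standards.columns:
            report.errors.append(f"standards: missing column {col!r}")
    for col in wio.STATE_TABLE_COLUMNS:
        if col not in state.columns:
            report.errors.append(f"state table: missing column {col!r}")
    if report.errors:
        return report

    vol_cols = [c for c in panel.columns if c.startswith("vol_")]
    for c in vol_cols:
        if (panel[c].dropna() < 0).any():
            report.errors.append(f"panel: negative values in {c!r}")
    known = {
        (r.centre_type, r.cadre, r.service) for r in standards.itertuples()
    }
    for c in vol_cols:
        service = c[len("vol_"):]
        used = panel.loc[panel[c].fillna(0) > 0, ["centre_type", "cadre"]]
        for ct, cadre in used.drop_duplicates().itertuples(index=False):
            if (ct, cadre, service) not in known:
                report.errors.append(
                    f"standards: no unit time for {ct}-{cadre} service {service!r}"
                )
    bad = state[
        state[["in_position", "sanctioned", "n_centres"]].isna().any(axis=1)
        | (state["n_centres"].fillna(0) < 1)
    ]
    for st in sorted(bad["state"].unique()):
        report.excluded_states.append(str(st))
        report.warnings.append(
            f"state table: {st} has missing/invalid staffing counts; "
            "its rows will be excluded"
        )
    return report


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def write(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        frame.to_csv(path, index=False)
        written.append(path)

    stage = "inputs"
    try:
        if config.simulate is not None:
            sim = config.simulate
            sim.seed = int(np.random.SeedSequence(config.seed).generate_state(1)[0] % 2**31)
            records = generate_facility_panel(sim)
            standards = standards_for(sim)
            scenario_seed = int(
                np.random.SeedSequence((config.seed, 1)).generate_state(1)[0] % 2**31
            )
            scenario = default_scenario(
                profiles=dict(sim.profiles),
                **{"seed": scenario_seed, **config.scenario_kwargs},
            )
            state_records = generate_state_table(scenario, scenario_seed)
            write(wio.panel_to_frame(records), "facility_panel.csv")
            write(wio.standards_to_frame(standards), "activity_standards.csv")
            write(wio.state_table_to_frame(state_records), "state_staffing.csv")
            policy = sim.leave_policy
        else:
            records = wio.frame_to_panel(
                pd.read_csv(config.panel_csv), config.leave_policy
            )
            standards = wio.frame_to_standards(pd.read_csv(config.standards_csv))
            state_records = wio.frame_to_state_table(
                pd.read_csv(config.state_table_csv).dropna()
            )
            policy = config.leave_policy

        stage = "wisn"
        results = compute_panel(records, standards, policy, config.rounding_rule)
        write(wio.results_to_frame(results), "facility_wisn.csv")
        panel = panel_frame(results)
        exclusions = (
            pd.Series([r.exclusion_reason.value for r in results])
            .value_counts()
            .to_dict()
        )

        stage = "model"
        combos = sorted(
            panel[["centre_type", "cadre"]].drop_duplicates().itertuples(index=False)
        )
        het_rows, thresholds = [], []
        for ct, cadre in combos:
            sub = panel[(panel.centre_type == ct) & (panel.cadre == cadre)]
            if sub["state"].nunique() >= 2:
                h, p = kruskal_wallis_by_state(panel, ct, cadre)
                het_rows.append(
                    {"centre_type": ct, "cadre": cadre, "H": h, "p": p}
                )
            thresholds.append(
                select_and_predict(
                    panel, ct, cadre,
                    weighting=config.marginal_weighting,
                    rounding=config.rounding_rule,
                )
            )
        write(pd.DataFrame(het_rows), "state_heterogeneity.csv")
        write(thresholds_frame(thresholds), "national_thresholds.csv")
        threshold_map = {
            (t.centre_type, t.cadre): t.wisn_threshold for t in thresholds
        }

        stage = "project"
        state_records = [
            r for r in state_records if (r.centre_type, r.cadre) in threshold_map
        ]
        projections = project_all(state_records, threshold_map, config.tolerance)
        proj = projection_frame(projections)
        write(proj, "projection.csv")
        write(long_frame(projections), "state_metrics_long.csv")

        stage = "agree"
        corr_payload = {}
        for ct in sorted(proj["centre_type"].unique()):
            ratios = ratio_matrix(proj, ct)
            cadres = [c for c in ratios.columns if ratios[c].notna().any()]
            if len(cadres) < 2:
                continue
            method = "partial" if len(cadres) > 2 else "pairwise"
            rho, pval = correlation_matrix(ratios, cadres, method)
            write(rho.reset_index().rename(columns={"index": "cadre"}),
                  f"workload_correlation_{ct}.csv")
            corr_payload[ct] = {
                "method": method,
                "cadres": list(map(str, cadres)),
                "rho": rho.round(6).to_dict(),
                "p": pval.round(6).to_dict(),
            }
        agreement = sanctioning_agreement(proj)
        write(agreement_frame(agreement), "sanctioning_agreement.csv")
        corr_path = outdir / "workload_correlations.json"
        corr_path.write_text(json.dumps(corr_payload, indent=2, sort_keys=True))
        written.append(corr_path)

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "mode": "simulate" if config.simulate is not None else "files",
            "rounding_rule": config.rounding_rule.value,
            "marginal_weighting": config.marginal_weighting,
            "n_activity_records": len(records),
            "n_retained": int((~pd.Series([r.excluded for r in results])).sum()),
            "exclusion_tallies": exclusions,
            "n_thresholds": len(thresholds),
            "n_projection_rows": len(projections),
            "outputs": [p.name for p in written],
            "versions": _versions(),
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:  # mark partial outputs, then surface the stage
        for path in written:
            if path.exists():
                path.rename(path.with_suffix(path.suffix + ".partial"))
        raise PipelineError(stage, exc) from exc


def _versions() -> dict:
    import scipy
    import statsmodels

    from . import __version__

    return {
        "python": platform.python_version(),
        "wisn_national": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }
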