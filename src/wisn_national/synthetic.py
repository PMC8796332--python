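"""Synthetic facility activity panels and state staffing tables.

The generator emulates the data layout the analysis expects: facility
observations clustered within states over several years for a set of
centre-cadre combinations (an unbalanced panel, as real facility surveys
are), plus a state-level staffing table of in-position staff P, sanctioned
posts S and functional centre counts N with configurable under- or
over-sanctioning.

Service volumes are drawn per service from a negative-binomial distribution
(Poisson when ``overdispersion`` is 0) whose mean is a base volume scaled by
multiplicative state effects and a per-year trend.  Combo profiles are
constructed by inversion: given a target per-centre requirement ``w``, base
volumes are chosen so that the analytic WISN of the mean facility equals
``w`` exactly, which makes end-to-end recovery checks possible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .wisn import FacilityActivityRecord, LeavePolicy, compute_awt

#: The eight centre-cadre combinations analysed in the study.
DEFAULT_COMBOS: tuple[tuple[str, str], ...] = (
    ("PHC", "nurses"),
    ("PHC", "doctors"),
    ("CHC", "nurses"),
    ("CHC", "GDMOs"),
    ("CHC", "physicians"),
    ("CHC", "surgeons"),
    ("CHC", "OBGYNs"),
    ("CHC", "paediatricians"),
)

#: Default per-centre raw requirement targets per combo (staff/centre),
#: resembling the scale separation between nurse and doctor cadres at rural
#: PHCs/CHCs (nurses tens of staff, doctor cadres a few).
DEFAULT_REQUIREMENTS: dict[tuple[str, str], float] = {
    ("PHC", "nurses"): 14.9,
    ("PHC", "doctors"): 1.8,
    ("CHC", "nurses"): 45.1,
    ("CHC", "GDMOs"): 3.3,
    ("CHC", "physicians"): 1.6,
    ("CHC", "surgeons"): 1.3,
    ("CHC", "OBGYNs"): 1.1,
    ("CHC", "paediatricians"): 1.3,
}


class ConfigError(ValueError):
    """Invalid simulation configuration; names the offending field."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass(frozen=True)
class ComboProfile:
    """Activity structure of one centre-cadre combination.

    ``services`` maps service name to (mean annual volume, unit time in
    minutes).  ``support_share`` is the total category allowance as a
    fraction of AWT; the additional activity contributes
    ``additional_hours * additional_staff`` IAS hours per year.
    """

    centre_type: str
    cadre: str
    services: Mapping[str, tuple[float, float]]
    support_share: float = 0.15
    additional_hours: float = 120.0
    additional_staff: float = 2.0

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"

    def analytic_wisn(self, awt_hours: float) -> float:
        """Raw WISN of the mean facility under neutral state/year effects."""
        hsa = sum(
            vol * minutes / 60.0 / awt_hours
            for vol, minutes in self.services.values()
        )
        caf = 1.0 / (1.0 - self.support_share)
        iaf = self.additional_hours * self.additional_staff / awt_hours
        return hsa * caf + iaf


def make_profile(
    centre_type: str,
    cadre: str,
    target_wisn: float,
    awt_hours: float = 2112.0,
    support_share: float = 0.15,
    additional_hours: float = 120.0,
    additional_staff: float = 2.0,
    service_weights: Mapping[str, float] | None = None,
    unit_times: Mapping[str, float] | None = None,
) -> ComboProfile:
    """Build a profile whose analytic WISN equals ``target_wisn`` exactly.

    The direct-service staff requirement implied by the target (after
    removing the allowance components) is split across services according to
    ``service_weights`` and converted to mean annual volumes via the unit
    times (minutes per unit).
    """
    if target_wisn <= 0:
        raise ConfigError("target_wisn", "must be positive")
    caf = 1.0 / (1.0 - support_share)
    iaf = additional_hours * additional_staff / awt_hours
    hsa_target = (target_wisn - iaf) / caf
    if hsa_target <= 0:
        raise ConfigError(
            "target_wisn", "allowances alone exceed the target requirement"
        )
    if service_weights is None:
        service_weights = {"outpatient": 0.6, "inpatient": 0.25, "procedures": 0.15}
    if unit_times is None:
        unit_times = {"outpatient": 10.0, "inpatient": 30.0, "procedures": 45.0}
    wsum = math.fsum(service_weights.values())
    services = {
        s: (
            hsa_target * (w / wsum) * awt_hours * 60.0 / unit_times[s],
            unit_times[s],
        )
        for s, w in service_weights.items()
    }
    return ComboProfile(
        centre_type=centre_type,
        cadre=cadre,
        services=services,
        support_share=support_share,
        additional_hours=additional_hours,
        additional_staff=additional_staff,
    )


def default_profiles(
    requirements: Mapping[tuple[str, str], float] | None = None,
    awt_hours: float = 2112.0,
) -> dict[tuple[str, str], ComboProfile]:
    reqs = dict(DEFAULT_REQUIREMENTS if requirements is None else requirements)
    return {
        (ct, cd): make_profile(ct, cd, w, awt_hours=awt_hours)
        for (ct, cd), w in reqs.items()
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters for the facility-panel generator.

    Defaults mirror the study's panel geometry: facilities in 5 states
    followed over 8 survey years for the 8 centre-cadre combinations, with
    roughly half the facility-year cells unobserved.
    """

    n_states: int = 5
    years: Sequence[int] = tuple(range(2007, 2015))
    facilities_per_state_centretype: int = 6
    profiles: Mapping[tuple[str, str], ComboProfile] = field(
        default_factory=default_profiles
    )
    state_effects: Sequence[float] = (0.8, 0.9, 1.0, 1.1, 1.2)
    year_trend: float = 1.0
    overdispersion: float = 0.1
    #: sd (log scale) of a lognormal per-facility size multiplier on service
    #: volumes, shared across that facility's years; induces the
    #: within-facility correlation the GEE clusters on.  Mean 1.
    facility_effect_sd: float = 0.2
    missing_rate: float = 0.5
    partial_facility_rate: float = 0.05
    zero_ias_rate: float = 0.05
    leave_policy: LeavePolicy = field(default_factory=LeavePolicy)
    seed: int = 0

    def validate(self) -> None:
        if self.n_states < 1:
            raise ConfigError("n_states", "need at least one state")
        if len(self.years) < 1:
            raise ConfigError("years", "need at least one year")
        if self.facilities_per_state_centretype < 1:
            raise ConfigError(
                "facilities_per_state_centretype", "need at least one facility"
            )
        if not self.profiles:
            raise ConfigError("profiles", "need at least one centre-cadre combo")
        if len(self.state_effects) != self.n_states:
            raise ConfigError(
                "state_effects", f"need exactly {self.n_states} factors"
            )
        if any(e <= 0 for e in self.state_effects):
            raise ConfigError("state_effects", "factors must be positive")
        if self.year_trend <= 0:
            raise ConfigError("year_trend", "must be positive")
        if self.overdispersion < 0:
            raise ConfigError("overdispersion", "must be >= 0")
        if self.facility_effect_sd < 0:
            raise ConfigError("facility_effect_sd", "must be >= 0")
        for name in ("missing_rate", "partial_facility_rate", "zero_ias_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(name, "must be a probability in [0, 1]")
        for key, profile in self.profiles.items():
            for s, (vol, minutes) in profile.services.items():
                if vol <= 0 or minutes <= 0:
                    raise ConfigError(
                        "profiles", f"{key} service {s!r}: nonpositive volume/unit time"
                    )

    @property
    def state_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_states)]


def _draw_counts(
    rng: np.random.Generator, mean: float, overdispersion: float, size: int
) -> np.ndarray:
    """Negative binomial with var = m + a m^2 (gamma-Poisson mixture);
    Poisson when overdispersion a = 0."""
    if overdispersion == 0:
        return rng.poisson(mean, size)
    shape = 1.0 / overdispersion
    lam = rng.gamma(shape, overdispersion * mean, size)
    return rng.poisson(lam)


def generate_facility_panel(config: SimulationConfig) -> list[FacilityActivityRecord]:
    """Draw an unbalanced facility x year x cadre activity panel."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    awt = compute_awt(config.leave_policy)
    records: list[FacilityActivityRecord] = []
    centre_types = sorted({ct for ct, _ in config.profiles})
    year0 = min(config.years)
    for ct in centre_types:
        combos = [(c, p) for c, p in config.profiles.items() if c[0] == ct]
        for s_idx, state in enumerate(config.state_names):
            effect = config.state_effects[s_idx]
            for f_idx in range(config.facilities_per_state_centretype):
                fid = f"{state}-{ct}-{f_idx + 1:03d}"
                fac_mult = (
                    float(
                        rng.lognormal(
                            -0.5 * config.facility_effect_sd**2,
                            config.facility_effect_sd,
                        )
                    )
                    if config.facility_effect_sd > 0
                    else 1.0
                )
                partial = rng.random() < config.partial_facility_rate
                weekly = (
                    float(rng.uniform(8.0, 23.9)) if partial else 48.0
                )
                for year in config.years:
                    trend = config.year_trend ** (year - year0)
                    for (ct2, cadre), profile in combos:
                        if rng.random() < config.missing_rate:
                            continue
                        volumes = {}
                        for service, (base, _minutes) in profile.services.items():
                            m = base * effect * trend * fac_mult
                            volumes[service] = float(
                                _draw_counts(rng, m, config.overdispersion, 1)[0]
                            )
                        zero_ias = rng.random() < config.zero_ias_rate
                        additional = (
                            {}
                            if zero_ias
                            else {
                                "outreach_and_meetings": (
                                    profile.additional_hours,
                                    profile.additional_staff,
                                )
                            }
                        )
                        records.append(
                            FacilityActivityRecord(
                                facility_id=fid,
                                state=state,
                                year=int(year),
                                centre_type=ct2,
                                cadre=cadre,
                                service_volumes=volumes,
                                support_time_shares={
                                    "support": profile.support_share
                                },
                                additional_activity_times=additional,
                                weekly_hours=weekly,
                            )
                        )
    return records


def standards_for(config: SimulationConfig):
    """Activity-standard table matching the generator's profiles."""
    from .wisn import ActivityStandardTable

    unit_times = {
        (ct, cadre, service): minutes
        for (ct, cadre), profile in config.profiles.items()
        for service, (_vol, minutes) in profile.services.items()
    }
    return ActivityStandardTable(unit_times)


@dataclass
class SanctioningScenario:
    """State staffing-table generator parameters.

    ``sanction_bias`` scales the workload-based requirement to produce
    sanctioned posts S (``< 1`` emulates under-sanctioning); ``fill_rate`` is
    the fraction of sanctioned posts actually in position.  ``state_fill_sd``
    adds a lognormal per-state staffing multiplier shared across cadres
    (states that under-staff one cadre under-staff the others), and
    ``combo_fill_sd`` adds independent per-state-cadre jitter.
    """

    true_requirement_per_centre: Mapping[tuple[str, str], float]
    n_centres_by_state: Mapping[str, Mapping[str, int]]
    sanction_bias: float | Mapping[tuple[str, str], float] = 1.0
    fill_rate: float = 1.0
    state_fill_sd: float = 0.0
    combo_fill_sd: float = 0.0

    def validate(self) -> None:
        if not 0.0 <= self.fill_rate <= 1.0:
            raise ConfigError("fill_rate", "must be in [0, 1]")
        for combo, w in self.true_requirement_per_centre.items():
            if w <= 0:
                raise ConfigError(
                    "true_requirement_per_centre", f"{combo}: must be positive"
                )
        for state, by_ct in self.n_centres_by_state.items():
            for ct, n in by_ct.items():
                if n < 1:
                    raise ConfigError(
                        "n_centres_by_state", f"{state}/{ct}: need N >= 1"
                    )

    def bias_for(self, combo: tuple[str, str]) -> float:
        if isinstance(self.sanction_bias, Mapping):
            return float(self.sanction_bias[combo])
        return float(self.sanction_bias)


def recovery_config(
    target_wisn: float,
    seed: int,
    centre_type: str = "PHC",
    cadre: str = "doctors",
    n_states: int = 5,
    years: Sequence[int] = (2007, 2008),
    facilities: int = 10,
    overdispersion: float = 0.0,
    facility_effect_sd: float = 0.0,
) -> SimulationConfig:
    """Balanced no-effect panel whose analytic per-centre WISN equals
    ``target_wisn`` — the ground truth for parameter-recovery checks.

    Defaults give 5 states x 2 years x 10 facilities = 100 facility-years
    with neutral state/year effects and Poisson volumes.
    """
    profile = make_profile(centre_type, cadre, target_wisn)
    return SimulationConfig(
        n_states=n_states,
        years=tuple(years),
        facilities_per_state_centretype=facilities,
        profiles={(centre_type, cadre): profile},
        state_effects=tuple(1.0 for _ in range(n_states)),
        year_trend=1.0,
        overdispersion=overdispersion,
        facility_effect_sd=facility_effect_sd,
        missing_rate=0.0,
        partial_facility_rate=0.0,
        zero_ias_rate=0.0,
        seed=seed,
    )


def default_scenario(
    profiles: Mapping[tuple[str, str], ComboProfile] | None = None,
    n_states: int = 30,
    sanction_bias: float | Mapping[tuple[str, str], float] = 0.6,
    fill_rate: float = 0.85,
    state_fill_sd: float = 0.3,
    combo_fill_sd: float = 0.15,
    awt_hours: float = 2112.0,
    seed: int = 12345,
) -> SanctioningScenario:
    """Study-condition sanctioning scenario for the simulated country.

    Emulates a national staffing table: ~30 states with widely varying
    centre counts, systematic under-sanctioning relative to the workload
    requirement (``sanction_bias < 1``), and partially filled posts with a
    shared per-state staffing level so that workload pressure co-occurs
    across cadres within a state.  True requirements are the analytic WISN
    of each combo profile.
    """
    if profiles is None:
        profiles = default_profiles()
    rng = np.random.default_rng(seed)
    n_centres = {
        f"ST{i + 1:02d}": {
            "PHC": int(rng.integers(80, 2000)),
            "CHC": int(rng.integers(15, 400)),
        }
        for i in range(n_states)
    }
    return SanctioningScenario(
        true_requirement_per_centre={
            combo: p.analytic_wisn(awt_hours) for combo, p in profiles.items()
        },
        n_centres_by_state=n_centres,
        sanction_bias=sanction_bias,
        fill_rate=fill_rate,
        state_fill_sd=state_fill_sd,
        combo_fill_sd=combo_fill_sd,
    )


def generate_state_table(scenario: SanctioningScenario, seed: int):
    """Draw a state staffing table (one row per state x combo).

    S = round(requirement x sanction_bias x N); P = round(effective fill x S),
    clipped so P <= S.  Returns a list of
    :class:`~wisn_national.projection.StateStaffingRecord`.
    """
    from .projection import StateStaffingRecord

    scenario.validate()
    rng = np.random.default_rng(seed)
    states = sorted(scenario.n_centres_by_state)
    state_mult = {
        s: (
            float(rng.lognormal(-0.5 * scenario.state_fill_sd**2, scenario.state_fill_sd))
            if scenario.state_fill_sd > 0
            else 1.0
        )
        for s in states
    }
    records = []
    for state in states:
        for (ct, cadre), w in sorted(scenario.true_requirement_per_centre.items()):
            n_by_ct = scenario.n_centres_by_state[state]
            if ct not in n_by_ct:
                continue
            n = int(n_by_ct[ct])
            s_posts = int(round(w * scenario.bias_for((ct, cadre)) * n))
            fill = scenario.fill_rate * state_mult[state]
            if scenario.combo_fill_sd > 0:
                fill *= float(
                    rng.lognormal(
                        -0.5 * scenario.combo_fill_sd**2, scenario.combo_fill_sd
                    )
                )
            fill = min(max(fill, 0.0), 1.0)
            p = int(round(fill * s_posts))
            records.append(
                StateStaffingRecord(
                    state=state,
                    centre_type=ct,
                    cadre=cadre,
                    in_position_P=p,
                    sanctioned_S=s_posts,
                    n_centres_N=n,
                )
            )
    return records
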