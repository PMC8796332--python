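"""Facility-level WISN arithmetic, rounding and exclusion rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wisn_national.wisn import (
    ActivityStandardTable,
    ExclusionReason,
    FacilityActivityRecord,
    InvalidPolicyError,
    LeavePolicy,
    MissingStandardError,
    RoundingRule,
    apply_exclusions,
    compute_awt,
    compute_caf,
    compute_facility_wisn,
    compute_hsa_requirement,
    compute_iaf,
    compute_panel,
    compute_standard_workload,
    compute_wisn,
    retained,
)


@pytest.mark.parametrize(
    "policy, expected",
    [
        (LeavePolicy(300, 0, 0, 0, 0, 8), 2400.0),
        (LeavePolicy(313, 12, 10, 17, 10, 8), 2112.0),
    ],
)
def test_awt_arithmetic(policy, expected):
    assert compute_awt(policy) == expected


def test_awt_all_leave_is_invalid():
    with pytest.raises(InvalidPolicyError):
        compute_awt(LeavePolicy(100, 100, 0, 0, 0, 8))


@pytest.mark.parametrize(
    "awt, minutes, expected",
    [(2000, 10, 12000), (2000, 60, 2000), (2112, 15, 8448)],
)
def test_standard_workload(awt, minutes, expected):
    assert compute_standard_workload(awt, minutes) == expected


def test_hsa_requirement_sums_service_ratios():
    # volume 12000 at standard workload 12000 -> 1.0
    assert compute_hsa_requirement({"opd": 12000}, {"opd": 10}, 2000) == pytest.approx(1.0)
    # two services each contributing 0.75 staff
    hsa = compute_hsa_requirement(
        {"a": 9000, "b": 1500}, {"a": 10, "b": 60}, 2000
    )
    assert hsa == pytest.approx(1.5)
    assert compute_hsa_requirement({"a": 0, "b": 0}, {}, 2000) == 0.0


def test_hsa_missing_standard_names_service():
    with pytest.raises(MissingStandardError, match="deliveries"):
        compute_hsa_requirement({"deliveries": 5}, {"opd": 10}, 2000)


@pytest.mark.parametrize(
    "shares, cas_pct, caf",
    [
        ({"x": 0.1, "y": 0.1}, 20.0, 1.25),
        ({}, 0.0, 1.0),
        ({"x": 0.5}, 50.0, 2.0),
    ],
)
def test_caf(shares, cas_pct, caf):
    got_pct, got_caf = compute_caf(shares)
    assert got_pct == pytest.approx(cas_pct)
    assert got_caf == pytest.approx(caf)


def test_caf_shares_consuming_all_time_error():
    with pytest.raises(ValueError):
        compute_caf({"x": 0.7, "y": 0.35})


@pytest.mark.parametrize(
    "activities, awt, ias, iaf",
    [
        ({"m": (240, 2)}, 2400, 480.0, 0.2),
        ({}, 2400, 0.0, 0.0),
        ({"m": (2400, 1)}, 2400, 2400.0, 1.0),
    ],
)
def test_iaf(activities, awt, ias, iaf):
    got_ias, got_iaf = compute_iaf(activities, awt)
    assert got_ias == pytest.approx(ias)
    assert got_iaf == pytest.approx(iaf)


@pytest.mark.parametrize(
    "hsa, caf, iaf, raw, rounded",
    [(2.0, 1.25, 0.5, 3.0, 3), (0.0, 1.0, 0.0, 0.0, 0)],
)
def test_wisn_formula(hsa, caf, iaf, raw, rounded):
    got_raw, got_rounded = compute_wisn(hsa, caf, iaf)
    assert got_raw == pytest.approx(raw)
    assert got_rounded == rounded


def test_rounding_rules_differ_on_fraction():
    raw, half_up = compute_wisn(1.0, 1.0, 0.45)
    assert (raw, half_up) == (pytest.approx(1.45), 1)
    _, ceil = compute_wisn(1.0, 1.0, 0.45, RoundingRule.CEILING)
    assert ceil == 2
    # .5 rounds up, not to even
    assert compute_wisn(2.5, 1.0, 0.0)[1] == 3


def _random_record(rng, i):
    n_services = rng.integers(1, 5)
    services = {f"s{j}": float(rng.integers(0, 20000)) for j in range(n_services)}
    shares = {
        f"sup{j}": float(rng.uniform(0, 0.2)) for j in range(rng.integers(0, 4))
    }
    additional = {
        f"add{j}": (float(rng.uniform(0, 400)), float(rng.integers(1, 5)))
        for j in range(rng.integers(0, 3))
    }
    record = FacilityActivityRecord(
        facility_id=f"F{i}", state="S1", year=2010, centre_type="PHC",
        cadre="doctors", service_volumes=services, support_time_shares=shares,
        additional_activity_times=additional,
    )
    unit_times = {s: float(rng.uniform(2, 120)) for s in services}
    return record, unit_times


def test_wisn_matches_single_expression_oracle():
    """1,000 random facility records agree with an independently coded
    one-line WISN expression to 1e-9."""
    rng = np.random.default_rng(2024)
    policy = LeavePolicy()
    awt = compute_awt(policy)
    for i in range(1000):
        record, unit_times = _random_record(rng, i)
        res = compute_facility_wisn(record, unit_times, policy)
        # independent single-expression oracle
        expected = (
            sum(
                v * unit_times[s] / 60.0 / awt
                for s, v in record.service_volumes.items()
            )
            / (1.0 - sum(record.support_time_shares.values()))
            + sum(h * k for h, k in record.additional_activity_times.values()) / awt
        )
        assert res.wisn_raw == pytest.approx(expected, abs=1e-9)


def test_doubling_volumes_doubles_wisn_without_allowances():
    rng = np.random.default_rng(7)
    policy = LeavePolicy()
    record, unit_times = _random_record(rng, 0)
    base = FacilityActivityRecord(
        **{**record.__dict__, "support_time_shares": {},
           "additional_activity_times": {}}
    )
    doubled = FacilityActivityRecord(
        **{**base.__dict__,
           "service_volumes": {s: 2 * v for s, v in base.service_volumes.items()}}
    )
    r1 = compute_facility_wisn(base, unit_times, policy)
    r2 = compute_facility_wisn(doubled, unit_times, policy)
    assert r2.wisn_raw == pytest.approx(2 * r1.wisn_raw, rel=1e-12)


@settings(deadline=None, max_examples=50)
@given(
    vol=st.floats(0, 1e5),
    bump=st.floats(0, 1e4),
    share=st.floats(0, 0.5),
    dshare=st.floats(0, 0.3),
    hours=st.floats(0, 500),
    dhours=st.floats(0, 500),
)
def test_wisn_monotone_in_volumes_shares_and_times(
    vol, bump, share, dshare, hours, dhours
):
    policy = LeavePolicy()
    unit_times = {"opd": 12.0}

    def raw(v, s, h):
        rec = FacilityActivityRecord(
            facility_id="F", state="S", year=2010, centre_type="PHC",
            cadre="doctors", service_volumes={"opd": v},
            support_time_shares={"sup": s},
            additional_activity_times={"add": (h, 2.0)},
        )
        return compute_facility_wisn(rec, unit_times, policy).wisn_raw

    base = raw(vol, share, hours)
    assert raw(vol + bump, share, hours) >= base
    assert raw(vol, share + dshare, hours) >= base
    assert raw(vol, share, hours + dhours) >= base


def test_unit_normalisation_hours_equals_minutes():
    """Standards given in hours (converted to minutes) give identical WISN."""
    rng = np.random.default_rng(11)
    policy = LeavePolicy()
    record, unit_times_min = _random_record(rng, 0)
    unit_times_from_hours = {s: (m / 60.0) * 60.0 for s, m in unit_times_min.items()}
    r1 = compute_facility_wisn(record, unit_times_min, policy)
    r2 = compute_facility_wisn(record, unit_times_from_hours, policy)
    assert r1.wisn_raw == pytest.approx(r2.wisn_raw, rel=1e-12)


def _fixture_record(fid, cadre="doctors", centre="PHC", volume=12000.0,
                    weekly=48.0, with_ias=True):
    return FacilityActivityRecord(
        facility_id=fid, state="S1", year=2010, centre_type=centre,
        cadre=cadre, service_volumes={"opd": volume},
        support_time_shares={"sup": 0.1},
        additional_activity_times={"m": (100.0, 2.0)} if with_ias else {},
        weekly_hours=weekly,
    )


def test_exclusion_rules_and_precedence():
    """One record per exclusion reason plus retained controls: exactly the
    intended rows are dropped, with the right recorded reason."""
    records = [
        _fixture_record("keep_doctor"),
        _fixture_record("keep_nurse", cadre="nurses"),
        _fixture_record("partial", weekly=20.0),
        _fixture_record("null", volume=0.0, with_ias=False),
        _fixture_record("nurse_no_ias", cadre="nurses", with_ias=False),
        # partial workweek wins over the nurse-IAF reason
        _fixture_record("partial_nurse", cadre="nurses", weekly=10.0,
                        with_ias=False),
    ]
    standards = ActivityStandardTable(
        {("PHC", "doctors", "opd"): 10.0, ("PHC", "nurses", "opd"): 10.0}
    )
    results = compute_panel(records, standards, LeavePolicy())
    reasons = {r.facility_id: r.exclusion_reason for r in results}
    assert reasons["keep_doctor"] is ExclusionReason.NONE
    assert reasons["keep_nurse"] is ExclusionReason.NONE
    assert reasons["partial"] is ExclusionReason.UNDER_HALF_WORKWEEK
    assert reasons["null"] is ExclusionReason.NULL_WISN
    assert reasons["nurse_no_ias"] is ExclusionReason.NULL_IAF_NURSE
    assert reasons["partial_nurse"] is ExclusionReason.UNDER_HALF_WORKWEEK
    assert {r.facility_id for r in retained(results)} == {
        "keep_doctor", "keep_nurse"
    }
    assert all(r.excluded == (r.exclusion_reason is not ExclusionReason.NONE)
               for r in results)


def test_panel_mean_matches_generator_expectation(study_config, study_results):
    """Mean raw WISN over the retained synthetic panel is close to the
    generator's analytic per-centre requirement for each combo."""
    kept = retained(study_results)
    for (ct, cadre), profile in study_config.profiles.items():
        vals = [r.wisn_raw for r in kept
                if r.centre_type == ct and r.cadre == cadre]
        target = profile.analytic_wisn(2112.0)
        mean = np.mean(vals)
        se = np.std(vals) / math.sqrt(len(vals))
        assert abs(mean - target) < max(4 * se, 0.05 * target)
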