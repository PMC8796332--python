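"""Across-state heterogeneity checks and the GEE national-threshold model."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats
import statsmodels.api as sm

from wisn_national.national import (
    ModelError,
    fit_gee,
    kruskal_wallis_by_state,
    marginal_mean,
    panel_frame,
    qic,
    select_and_predict,
)
from wisn_national.synthetic import (
    generate_facility_panel,
    recovery_config,
    standards_for,
)
from wisn_national.wisn import compute_panel


def _panel(values_by_state, cadre="doctors", centre="PHC"):
    rows = []
    for state, values in values_by_state.items():
        for i, v in enumerate(values):
            rows.append(
                {
                    "facility_id": f"{state}-F{i}",
                    "state": state,
                    "year": 2010,
                    "centre_type": centre,
                    "cadre": cadre,
                    "wisn_raw": float(v),
                    "wisn_rounded": int(round(v)),
                }
            )
    return pd.DataFrame(rows)


def _hand_kruskal(groups):
    """Independent tie-corrected H: rank everything, sum of squared rank-sum
    deviations, divided by the tie-correction factor."""
    all_vals = np.concatenate(groups)
    n = len(all_vals)
    ranks = scipy.stats.rankdata(all_vals)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        start += len(g)
        h += r.sum() ** 2 / len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, counts = np.unique(all_vals, return_counts=True)
    tie = 1 - np.sum(counts**3 - counts) / (n**3 - n)
    return h / tie


def test_kruskal_identical_groups_gives_zero_h():
    panel = _panel({"A": [1.0, 2.0, 3.0], "B": [1.0, 2.0, 3.0]})
    h, p = kruskal_wallis_by_state(panel, "PHC", "doctors")
    assert h == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0)


def test_kruskal_matches_hand_formula_and_detects_separation():
    rng = np.random.default_rng(8)
    groups = {
        "A": rng.normal(2, 0.3, 40),
        "B": rng.normal(5, 0.3, 40),
        "C": rng.normal(9, 0.3, 40),
    }
    panel = _panel(groups)
    h, p = kruskal_wallis_by_state(panel, "PHC", "doctors")
    assert h == pytest.approx(_hand_kruskal(list(groups.values())), rel=1e-10)
    assert p < 0.001


def test_kruskal_is_rank_invariant():
    rng = np.random.default_rng(3)
    groups = {s: rng.normal(i, 1, 25) for i, s in enumerate("ABC")}
    h1, _ = kruskal_wallis_by_state(_panel(groups), "PHC", "doctors")
    all_vals = np.concatenate(list(groups.values()))
    ranks = scipy.stats.rankdata(all_vals)
    ranked = {}
    start = 0
    for s, g in groups.items():
        ranked[s] = ranks[start:start + len(g)]
        start += len(g)
    h2, _ = kruskal_wallis_by_state(_panel(ranked), "PHC", "doctors")
    assert h1 == pytest.approx(h2, rel=1e-10)


def test_kruskal_single_state_errors():
    with pytest.raises(ValueError):
        kruskal_wallis_by_state(_panel({"A": [1, 2, 3]}), "PHC", "doctors")


def _two_cluster_panel(values):
    rows = []
    for i, v in enumerate(values):
        rows.append(
            {
                "facility_id": f"F{i % 2}",
                "state": "A",
                "year": 2010 + i // 2,
                "centre_type": "PHC",
                "cadre": "doctors",
                "wisn_raw": float(v),
                "wisn_rounded": int(v),
            }
        )
    return pd.DataFrame(rows)


def test_constant_outcome_fits_constant_marginal_mean():
    panel = _two_cluster_panel([7] * 10)
    fit = fit_gee(panel, "PHC", "doctors", "independence")
    mu, se = marginal_mean(fit, panel)
    assert mu == pytest.approx(7.0, rel=1e-6)
    assert se == pytest.approx(0.0, abs=1e-6)


def test_single_state_year_marginal_mean_is_sample_mean():
    """With one state and one year the model is intercept-only and the
    Poisson marginal mean reduces to the sample mean."""
    rng = np.random.default_rng(0)
    y = rng.poisson(6, 30)
    rows = [
        {
            "facility_id": f"F{i}", "state": "A", "year": 2010,
            "centre_type": "PHC", "cadre": "doctors",
            "wisn_raw": float(v), "wisn_rounded": int(v),
        }
        for i, v in enumerate(y)
    ]
    panel = pd.DataFrame(rows)
    fit = fit_gee(panel, "PHC", "doctors", "independence")
    mu, _ = marginal_mean(fit, panel)
    assert mu == pytest.approx(y.mean(), rel=1e-8)


def test_independence_on_singleton_clusters_equals_glm():
    """Independence GEE with cluster size 1 is ordinary Poisson regression."""
    rng = np.random.default_rng(5)
    rows = []
    for i in range(120):
        state = "ABC"[i % 3]
        year = 2010 + (i % 2)
        mu = np.exp(1.0 + 0.3 * (state == "B") + 0.2 * (year == 2011))
        rows.append(
            {
                "facility_id": f"F{i}", "state": state, "year": year,
                "centre_type": "PHC", "cadre": "doctors",
                "wisn_raw": 0.0, "wisn_rounded": int(rng.poisson(mu)),
            }
        )
    panel = pd.DataFrame(rows)
    fit = fit_gee(panel, "PHC", "doctors", "independence")
    glm = sm.GLM.from_formula(
        "wisn_rounded ~ C(state) + C(year)", data=panel,
        family=sm.families.Poisson(),
    ).fit()
    np.testing.assert_allclose(
        fit.params.to_numpy(), glm.params.to_numpy(), rtol=1e-6
    )


def test_qic_is_deterministic_and_penalises_parameters():
    """QIC of the same fit is reproducible, and on correctly specified
    independent data the Pan penalty is close to twice the parameter count."""
    rng = np.random.default_rng(12)
    rows = []
    for i in range(600):
        state = "ABCDE"[i % 5]
        mu = np.exp(1.5 + 0.2 * "ABCDE".index(state) / 4)
        rows.append(
            {
                "facility_id": f"F{i}", "state": state, "year": 2010,
                "centre_type": "PHC", "cadre": "doctors",
                "wisn_raw": 0.0, "wisn_rounded": int(rng.poisson(mu)),
            }
        )
    panel = pd.DataFrame(rows)
    fit = fit_gee(panel, "PHC", "doctors", "independence")
    assert qic(fit.result) == pytest.approx(fit.qic, rel=1e-12)
    # penalty = QIC - (-2 * quasi-likelihood at the fit)
    y = fit.result.model.endog
    mu_hat = fit.result.fittedvalues
    quasi = np.sum(np.where(y > 0, y * np.log(mu_hat), 0.0) - mu_hat)
    penalty = fit.qic + 2 * quasi
    p = len(fit.params)
    assert penalty == pytest.approx(2 * p, rel=0.25)


def test_select_reports_min_qic_structure_and_single_structure_degenerate(
    study_panel,
):
    t_all = select_and_predict(study_panel, "PHC", "nurses")
    fits = {
        s: fit_gee(study_panel, "PHC", "nurses", s).qic
        for s in ("independence", "exchangeable", "ar1")
    }
    assert t_all.chosen_structure == min(fits, key=fits.get)
    assert t_all.qic == pytest.approx(min(fits.values()))
    t_one = select_and_predict(study_panel, "PHC", "nurses", structures=("ar1",))
    assert t_one.chosen_structure == "ar1"
    assert t_all.ci_low <= t_all.mean_rounded_model <= t_all.ci_high


def test_threshold_invariant_to_state_relabeling(study_panel):
    t1 = select_and_predict(study_panel, "CHC", "GDMOs")
    relabeled = study_panel.copy()
    mapping = {"S01": "Z9", "S02": "A1", "S03": "M5", "S04": "B2", "S05": "Q7"}
    relabeled["state"] = relabeled["state"].map(mapping)
    t2 = select_and_predict(relabeled, "CHC", "GDMOs")
    assert t2.mean_rounded_model == pytest.approx(t1.mean_rounded_model, rel=1e-6)
    assert t2.wisn_threshold == t1.wisn_threshold


def test_balanced_panel_weightings_agree():
    cfg = recovery_config(4.0, seed=6)  # balanced: no missingness
    panel = panel_frame(
        compute_panel(generate_facility_panel(cfg), standards_for(cfg),
                      cfg.leave_policy)
    )
    assert len(panel) == 100
    t_eq = select_and_predict(panel, "PHC", "doctors", weighting="equal_cell")
    t_ob = select_and_predict(panel, "PHC", "doctors", weighting="observation")
    assert t_eq.mean_rounded_model == pytest.approx(
        t_ob.mean_rounded_model, rel=1e-9
    )


def test_recovery_of_known_requirement():
    """Balanced no-effect panels with known per-centre requirement recover it
    after rounding."""
    for w in (2, 15):
        hits = 0
        for seed in range(5):
            cfg = recovery_config(float(w), seed=seed)
            panel = panel_frame(
                compute_panel(generate_facility_panel(cfg), standards_for(cfg),
                              cfg.leave_policy)
            )
            t = select_and_predict(panel, "PHC", "doctors")
            hits += t.wisn_threshold == w
            assert t.ci_low <= t.mean_rounded_model <= t.ci_high
        assert hits >= 4


def test_missing_combo_raises():
    panel = _two_cluster_panel([3, 4, 5, 4])
    with pytest.raises(ModelError):
        select_and_predict(panel, "CHC", "surgeons")
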