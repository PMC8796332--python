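"""Nationally representative per-centre WISN thresholds.

Facility WISN values are clustered (repeated yearly measurements within a
facility, facilities within states).  Across-state heterogeneity is first
assessed with a Kruskal-Wallis one-way ANOVA on the raw (unrounded) WISN
values.  A population-averaged log-link Poisson model,

    log E[WISN_ij] = b0 + b1 State + b2 Year,

is then fitted by generalized estimating equations (GEE) with facility as
the cluster, under independence, exchangeable and AR(1) working
correlations; the structure with the lowest QIC (Pan's quasi-likelihood
information criterion) is selected.  The national threshold is the marginal
mean of the selected fit averaged over the observed state x year design,
with an asymptotic 95% CI obtained by the delta method on the log scale.
A companion quasi-Poisson fit on the raw (non-integer) values supplies the
raw mean and its standard error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.stats
import statsmodels.api as sm

from .wisn import FacilityWISNResult, RoundingRule, round_wisn

STRUCTURES = ("independence", "exchangeable", "ar1")

_FORMULA = "outcome ~ C(state) + C(year)"


class ModelError(RuntimeError):
    pass


@dataclass(frozen=True)
class GEEFitResult:
    centre_type: str
    cadre: str
    structure: str
    params: pd.Series
    cov_params: pd.DataFrame
    qic: float
    converged: bool
    n_obs: int
    n_clusters: int
    result: object  # underlying statsmodels GEEResults

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


@dataclass(frozen=True)
class NationalThreshold:
    centre_type: str
    cadre: str
    n_obs: int
    mean_rounded_model: float
    ci_low: float
    ci_high: float
    mean_raw: float
    se_raw: float
    wisn_threshold: int
    chosen_structure: str
    qic: float

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


def panel_frame(results: Sequence[FacilityWISNResult]) -> pd.DataFrame:
    """Retained WISN panel as a tidy frame (excluded rows are dropped)."""
    rows = [
        {
            "facility_id": r.facility_id,
            "state": r.state,
            "year": r.year,
            "centre_type": r.centre_type,
            "cadre": r.cadre,
            "wisn_raw": r.wisn_raw,
            "wisn_rounded": r.wisn_rounded,
        }
        for r in results
        if not r.excluded
    ]
    return pd.DataFrame(rows)


def kruskal_wallis_by_state(
    panel: pd.DataFrame, centre_type: str, cadre: str
) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and chi-square p value for across-state
    differences in raw WISN values of one combo."""
    sub = panel[(panel.centre_type == centre_type) & (panel.cadre == cadre)]
    groups = [g["wisn_raw"].to_numpy() for _, g in sub.groupby("state") if len(g)]
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least two states with data")
    h, p = scipy.stats.kruskal(*groups)
    return float(h), float(p)


def _cov_struct(structure: str):
    if structure == "independence":
        return sm.cov_struct.Independence()
    if structure == "exchangeable":
        return sm.cov_struct.Exchangeable()
    if structure == "ar1":
        return sm.cov_struct.Autoregressive(grid=True)
    raise ValueError(f"unknown working correlation structure {structure!r}")


def qic(res) -> float:
    """Pan's quasi-likelihood information criterion for a Poisson log-link
    GEE fit:

        QIC = -2 Q(beta; independence) + 2 trace(A_I V_robust),

    where Q = sum(y log mu - mu) is the Poisson quasi-likelihood at the
    fitted coefficients evaluated under working independence (scale 1) and
    A_I = X' diag(mu) X is the independence-model information.  Lower is
    better; only differences between structures on the same data are
    meaningful.

    ``res`` is a fitted statsmodels GEEResults (or GLMResults with the same
    attributes).  Raises on a singular information matrix.
    """
    X = np.asarray(res.model.exog, dtype=float)
    y = np.asarray(res.model.endog, dtype=float)
    mu = np.exp(X @ np.asarray(res.params, dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogmu = np.where(y > 0, y * np.log(mu), 0.0)
    quasi = float(np.sum(ylogmu - mu))
    a_ind = (X * mu[:, None]).T @ X
    if not np.isfinite(np.linalg.cond(a_ind)) or np.linalg.cond(a_ind) > 1e12:
        raise np.linalg.LinAlgError("singular independence information matrix")
    v_rob = np.asarray(res.cov_params(), dtype=float)
    return float(-2.0 * quasi + 2.0 * np.trace(a_ind @ v_rob))


def fit_gee(
    panel: pd.DataFrame,
    centre_type: str,
    cadre: str,
    structure: str,
    outcome: str = "wisn_rounded",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> GEEFitResult:
    """Population-averaged Poisson fit for one combo and working structure.

    Clusters on facility; within-cluster observations are ordered by year so
    the AR(1) structure sees equally spaced repeats.  Robust (sandwich)
    covariances are used throughout.
    """
    sub = panel[(panel.centre_type == centre_type) & (panel.cadre == cadre)].copy()
    if sub.empty:
        raise ModelError(f"no data for {centre_type}-{cadre}")
    if sub["facility_id"].nunique() < 2:
        raise ModelError("GEE needs at least two facility clusters")
    sub = sub.sort_values(["facility_id", "year"]).reset_index(drop=True)
    sub["outcome"] = sub[outcome]
    sub["time"] = sub.groupby("facility_id").cumcount()
    # degenerate categorical levels: patsy drops nothing, statsmodels handles
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GEE.from_formula(
            _FORMULA,
            groups="facility_id",
            data=sub,
            time=sub["time"].to_numpy(),
            family=sm.families.Poisson(),
            cov_struct=_cov_struct(structure),
        )
        try:
            res = model.fit(maxiter=maxiter, ctol=tol)
            qic_value = qic(res)
            converged = bool(getattr(res, "converged", True)) and np.all(
                np.isfinite(res.params)
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            raise ModelError(
                f"GEE fit failed for {centre_type}-{cadre} [{structure}]: {exc}"
            ) from exc
    return GEEFitResult(
        centre_type=centre_type,
        cadre=cadre,
        structure=structure,
        params=res.params,
        cov_params=pd.DataFrame(
            res.cov_params(), index=res.params.index, columns=res.params.index
        ),
        qic=qic_value,
        converged=converged,
        n_obs=len(sub),
        n_clusters=sub["facility_id"].nunique(),
        result=res,
    )


def marginal_mean(
    fit: GEEFitResult,
    panel: pd.DataFrame,
    weighting: str = "equal_cell",
) -> tuple[float, float]:
    """Marginal mean over the observed state x year design and its
    delta-method standard error.

    ``equal_cell`` gives each observed state x year cell equal weight (the
    estimate is an average over states and years); ``observation`` weights
    cells by their observation counts.
    """
    sub = panel[
        (panel.centre_type == fit.centre_type) & (panel.cadre == fit.cadre)
    ]
    cells = (
        sub.groupby(["state", "year"], as_index=False)
        .size()
        .rename(columns={"size": "n"})
    )
    if weighting == "equal_cell":
        w = np.ones(len(cells)) / len(cells)
    elif weighting == "observation":
        w = cells["n"].to_numpy() / cells["n"].sum()
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    design_info = fit.result.model.data.design_info
    X = np.asarray(patsy.dmatrix(design_info, cells))
    beta = fit.params.to_numpy()
    mu_cells = np.exp(X @ beta)
    mu = float(w @ mu_cells)
    grad = (w * mu_cells) @ X
    var = float(grad @ fit.cov_params.to_numpy() @ grad)
    return mu, float(np.sqrt(max(var, 0.0)))


def select_and_predict(
    panel: pd.DataFrame,
    centre_type: str,
    cadre: str,
    structures: Sequence[str] = STRUCTURES,
    weighting: str = "equal_cell",
    rounding: RoundingRule = RoundingRule.HALF_UP,
    alpha: float = 0.05,
) -> NationalThreshold:
    """Fit all working structures, select by QIC, and report the national
    per-centre threshold with 95% CI.

    The CI is computed on the log scale (log mu +/- z * se/mu) and
    exponentiated.  The integer threshold used downstream is the rounded
    marginal mean of the count-outcome model.
    """
    fits: list[GEEFitResult] = []
    errors: list[str] = []
    for structure in structures:
        try:
            fit = fit_gee(panel, centre_type, cadre, structure)
        except ModelError as exc:
            errors.append(str(exc))
            continue
        if fit.converged:
            fits.append(fit)
    if not fits:
        raise ModelError(
            f"no converged GEE fit for {centre_type}-{cadre}: {'; '.join(errors)}"
        )
    best = min(fits, key=lambda f: f.qic)
    mu, se = marginal_mean(best, panel, weighting)
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    if mu > 0 and se > 0:
        ci_low = float(mu * np.exp(-z * se / mu))
        ci_high = float(mu * np.exp(z * se / mu))
    else:
        ci_low = ci_high = mu
    raw_fit = fit_gee(
        panel, centre_type, cadre, best.structure, outcome="wisn_raw"
    )
    mu_raw, se_raw = marginal_mean(raw_fit, panel, weighting)
    return NationalThreshold(
        centre_type=centre_type,
        cadre=cadre,
        n_obs=best.n_obs,
        mean_rounded_model=mu,
        ci_low=ci_low,
        ci_high=ci_high,
        mean_raw=mu_raw,
        se_raw=se_raw,
        wisn_threshold=round_wisn(mu, rounding),
        chosen_structure=best.structure,
        qic=best.qic,
    )


def thresholds_frame(thresholds: Sequence[NationalThreshold]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "centre_type": t.centre_type,
                "cadre": t.cadre,
                "n": t.n_obs,
                "mean_rounded_model": t.mean_rounded_model,
                "ci_low": t.ci_low,
                "ci_high": t.ci_high,
                "mean_raw": t.mean_raw,
                "se_raw": t.se_raw,
                "wisn_threshold": t.wisn_threshold,
                "chosen_structure": t.chosen_structure,
                "qic": t.qic,
            }
            for t in thresholds
        ]
    )
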