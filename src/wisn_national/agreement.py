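"""Workload-pressure co-occurrence and sanctioning-agreement statistics.

Two questions about the state-level projections are answered here:

* Do states that overload one cadre also overload another?  Spearman rank
  correlations between state-level WISN ratios answer this for cadre pairs;
  for centre types with many cadres, partial Spearman correlations isolate
  each pair while controlling for the remaining cadres.

* Do sanctioned posts agree with workload-based requirements?  Lin's
  concordance correlation coefficient (CCC) measures agreement of sanctioned
  posts S with the requirement WISN x N across states against the 45-degree
  identity line; the bias-correction factor C_b = CCC / r isolates the
  location/scale departure from that line.  CCC below 0.90 is conventionally
  read as poor agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats


@dataclass(frozen=True)
class AgreementResult:
    centre_type: str
    cadre: str
    n_states: int
    ccc: float
    ci_low: float
    ci_high: float
    bias_correction: float
    pearson_r: float
    poor_agreement: bool

    @property
    def combo(self) -> str:
        return f"{self.centre_type}-{self.cadre}"


def spearman_pairwise(x, y) -> tuple[float, float]:
    """Tie-corrected Spearman rho (Pearson on mid-ranks) with t-based p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need paired 1-d samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant sample")
    rho, p = scipy.stats.spearmanr(x, y)
    return float(rho), float(p)


def _rank(a: np.ndarray) -> np.ndarray:
    return scipy.stats.rankdata(a, axis=0)


def spearman_partial(
    data: pd.DataFrame, x: str, y: str, controls: Sequence[str] = ()
) -> tuple[float, float]:
    """Partial Spearman correlation of ``x`` and ``y`` given ``controls``.

    Columns are rank-transformed (mid-ranks); the partial correlation is the
    Pearson correlation of the residuals of the ranks of x and y after OLS
    regression on the ranks of the controls (with intercept).  With no
    controls this reduces to the pairwise Spearman rho.  The p value uses
    the t approximation with n - 2 - k degrees of freedom.
    """
    cols = [x, y, *controls]
    sub = data[cols].dropna()
    n, k = len(sub), len(controls)
    if n <= k + 2:
        raise ValueError("need n > number of controls + 2 complete rows")
    ranks = _rank(sub.to_numpy(dtype=float))
    rx, ry, rz = ranks[:, 0], ranks[:, 1], ranks[:, 2:]
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("partial correlation undefined for a constant sample")
    z = np.column_stack([np.ones(n), rz])
    # explicit solve so rank deficiency in the controls surfaces as an error
    if np.linalg.matrix_rank(z) < z.shape[1]:
        raise np.linalg.LinAlgError("control matrix is singular (collinear controls)")
    coef_x, *_ = np.linalg.lstsq(z, rx, rcond=None)
    coef_y, *_ = np.linalg.lstsq(z, ry, rcond=None)
    ex, ey = rx - z @ coef_x, ry - z @ coef_y
    denom = math.sqrt(float(ex @ ex) * float(ey @ ey))
    if denom == 0:
        raise ValueError("zero residual variance in partial correlation")
    rho = float(ex @ ey / denom)
    df = n - 2 - k
    rho_c = min(max(rho, -1.0), 1.0)
    if abs(rho_c) == 1.0:
        p = 0.0
    else:
        t = rho_c * math.sqrt(df / (1 - rho_c**2))
        p = float(2 * scipy.stats.t.sf(abs(t), df))
    return rho, p


def spearman_partial_inverse(
    data: pd.DataFrame, x: str, y: str, controls: Sequence[str] = ()
) -> float:
    """Same partial correlation via the inverse of the rank-correlation
    matrix (precision-matrix formulation); cross-check for the residual
    algorithm."""
    cols = [x, y, *controls]
    sub = data[cols].dropna()
    ranks = _rank(sub.to_numpy(dtype=float))
    corr = np.corrcoef(ranks, rowvar=False)
    prec = np.linalg.inv(corr)
    return float(-prec[0, 1] / math.sqrt(prec[0, 0] * prec[1, 1]))


def correlation_matrix(
    data: pd.DataFrame,
    variables: Sequence[str],
    method: str = "pairwise",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric rho and p matrices over ``variables``.

    ``pairwise`` computes plain Spearman correlations; ``partial`` computes,
    for each pair, the partial Spearman correlation controlling for all the
    other variables (rows with any missing value are dropped listwise).
    """
    if method not in ("pairwise", "partial"):
        raise ValueError(f"unknown method {method!r}")
    sub = data[list(variables)].dropna()
    k = len(variables)
    rho = pd.DataFrame(np.eye(k), index=variables, columns=variables)
    pval = pd.DataFrame(np.zeros((k, k)), index=variables, columns=variables)
    for a, b in combinations(variables, 2):
        if method == "pairwise":
            r, p = spearman_pairwise(sub[a], sub[b])
        else:
            controls = [v for v in variables if v not in (a, b)]
            r, p = spearman_partial(sub, a, b, controls)
        rho.loc[a, b] = rho.loc[b, a] = r
        pval.loc[a, b] = pval.loc[b, a] = p
    return rho, pval


def lin_ccc(
    x,
    y,
    alpha: float = 0.05,
    moments: str = "population",
) -> tuple[float, tuple[float, float], float, float]:
    """Lin's concordance correlation coefficient.

    Returns (CCC, (ci_low, ci_high), bias_correction_Cb, pearson_r).
    ``moments='population'`` uses 1/n variances and covariance (Lin's
    original estimator); ``'sample'`` uses 1/(n-1).  The CI is a Fisher-type
    z interval with Lin's asymptotic variance for the z-transformed CCC.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if x.shape != y.shape or x.ndim != 1 or n < 3:
        raise ValueError("need paired 1-d samples with n >= 3")
    ddof = 0 if moments == "population" else 1
    sx2 = float(np.var(x, ddof=ddof))
    sy2 = float(np.var(y, ddof=ddof))
    if sx2 == 0 or sy2 == 0:
        raise ValueError("CCC undefined for zero-variance sample")
    sxy = float(np.cov(x, y, ddof=ddof)[0, 1])
    dmean = float(np.mean(x) - np.mean(y))
    ccc = 2 * sxy / (sx2 + sy2 + dmean**2)
    r = sxy / math.sqrt(sx2 * sy2)
    cb = ccc / r if r != 0 else math.nan

    # Fisher z CI with Lin (1989) variance of the transformed estimate
    if abs(ccc) >= 1.0:
        ci = (ccc, ccc)
    else:
        u = dmean / (sx2 * sy2) ** 0.25
        z = math.atanh(ccc)
        r2 = r**2 if r != 0 else 1e-300
        var_z = (
            (1 - r**2) * ccc**2 / ((1 - ccc**2) * r2)
            + 2 * ccc**3 * (1 - ccc) * u**2 / (r * (1 - ccc**2) ** 2 if r != 0 else 1e-300)
            - ccc**4 * u**4 / (2 * r2 * (1 - ccc**2) ** 2)
        ) / (n - 2)
        half = scipy.stats.norm.ppf(1 - alpha / 2) * math.sqrt(max(var_z, 0.0))
        ci = (math.tanh(z - half), math.tanh(z + half))
    return float(ccc), (float(ci[0]), float(ci[1])), float(cb), float(r)


def sanctioning_agreement(
    projection: pd.DataFrame,
    poor_threshold: float = 0.90,
) -> list[AgreementResult]:
    """Per-combo agreement between sanctioned posts and WISN-based
    requirements across states.

    ``projection`` is the wide per-state projection table; national rows
    (state == "India") are ignored.  x = sanctioned posts S by state,
    y = threshold x N by state.
    """
    from .projection import NATIONAL_LABEL

    results = []
    states_only = projection[projection["state"] != NATIONAL_LABEL]
    for (ct, cadre), g in states_only.groupby(["centre_type", "cadre"]):
        x = g["sanctioned_S"].to_numpy(dtype=float)
        y = (g["wisn_threshold"] * g["n_centres_N"]).to_numpy(dtype=float)
        ccc, (lo, hi), cb, r = lin_ccc(x, y)
        results.append(
            AgreementResult(
                centre_type=ct,
                cadre=cadre,
                n_states=len(g),
                ccc=ccc,
                ci_low=lo,
                ci_high=hi,
                bias_correction=cb,
                pearson_r=r,
                poor_agreement=ccc < poor_threshold,
            )
        )
    return results


def ratio_matrix(projection: pd.DataFrame, centre_type: str) -> pd.DataFrame:
    """State x cadre matrix of WISN ratios for one centre type."""
    from .projection import NATIONAL_LABEL

    sub = projection[
        (projection["centre_type"] == centre_type)
        & (projection["state"] != NATIONAL_LABEL)
    ]
    return sub.pivot(index="state", columns="cadre", values="wisn_ratio")


def agreement_frame(results: Sequence[AgreementResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
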