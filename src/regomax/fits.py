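"""Least-squares laws relating summed sensitivity to PageRank, plus tables.

The summed sensitivity Ds(u/d)(b) of the up/down group to a protein b is, to
a good approximation, proportional to b's local PageRank probability Pr(b)
(the rank-1 background makes D[a, b] ~ Pr(b)).  Two fits quantify this:

* a one-parameter linear law through the origin, y = eta * x;
* a two-parameter power law, y = eta_tilde * x**kappa, fitted by ordinary
  least squares on the log-log scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "FitResult",
    "fit_linear_through_origin",
    "fit_powerlaw_loglog",
    "make_report_tables",
]


@dataclass
class FitResult:
    model: str                   # linear_origin | powerlaw_loglog
    params: dict                 # eta, or eta_tilde and kappa
    stderr: dict
    n_points: int
    residual_rms: float

    def __str__(self) -> str:
        terms = ", ".join(
            f"{k}={v:.4f}+-{self.stderr[k]:.4f}" for k, v in self.params.items()
        )
        return f"{self.model}: {terms} (n={self.n_points})"


def fit_linear_through_origin(pairs) -> FitResult:
    """Least squares for y = eta * x with zero intercept.

    eta = sum(xy)/sum(x^2); the standard error comes from the residual
    variance of the one-parameter model (n - 1 degrees of freedom).
    """
    x, y = _as_xy(pairs)
    if np.all(x == 0):
        raise ValueError("all x values are zero")
    res = sm.OLS(y, x).fit()
    eta = float(res.params[0])
    resid = y - eta * x
    return FitResult(
        model="linear_origin",
        params={"eta": eta},
        stderr={"eta": float(res.bse[0])},
        n_points=len(x),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def fit_powerlaw_loglog(pairs) -> FitResult:
    """OLS of ln y on ln x: kappa = slope, eta_tilde = exp(intercept)."""
    x, y = _as_xy(pairs)
    if len(x) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    lx, ly = np.log(x), np.log(y)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    intercept, kappa = float(res.params[0]), float(res.params[1])
    eta_tilde = float(np.exp(intercept))
    resid = ly - (intercept + kappa * lx)
    return FitResult(
        model="powerlaw_loglog",
        params={"eta_tilde": eta_tilde, "kappa": kappa},
        # delta method on exp(intercept) for the prefactor error
        stderr={"eta_tilde": eta_tilde * float(res.bse[0]),
                "kappa": float(res.bse[1])},
        n_points=len(x),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
    )


def _as_xy(pairs):
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def make_report_tables(aggregates, top_pairs: int = 40) -> dict[str, pd.DataFrame]:
    """Publication-style report tables from aggregated sensitivities.

    Returns the top-``top_pairs`` cut of the ranked (a, b, Dab) pair list, the
    ranked summed-sensitivity table with PageRank, and the TGF-beta influence
    ranking, all as ready-to-write DataFrames.
    """
    return {
        "top_pairs": aggregates.pair_ranking.head(top_pairs).reset_index(drop=True),
        "ds_ud": aggregates.Ds_ud.copy(),
        "ds_tgfbeta": aggregates.Ds_TGFbeta.sort_values("Ks_TGFbeta").reset_index(drop=True),
    }
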