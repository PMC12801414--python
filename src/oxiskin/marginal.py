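"""Marginal (standardised) prediction with delta-method uncertainty.

A grid point fixes some covariates (device, ITA, SaO2); the remaining ones
(haemoglobin, site, and any grid covariate not fixed) are taken from each
row of a standardisation sample.  The prediction is the average of the
per-row response-scale predictions, its standard error is propagated by the
delta method through that average, and 95% limits are Wald intervals on the
link scale transformed back to the response scale.

Works for both engines: fractional probit (response Phi(x'b)) and the
patient random-intercept logistic, where the per-row prediction is the
population-averaged probability integrating over the random effect.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtr

from .design import FittedDesign
from .fracprobit import FitResult
from .relogit import population_averaged_grad, population_averaged_prob

__all__ = ["MarginalPrediction", "MarginalResult", "marginal_predict"]

_NORM_PDF_C = 1.0 / np.sqrt(2.0 * np.pi)


def _phi(x):
    return _NORM_PDF_C * np.exp(-0.5 * x * x)


@dataclass(frozen=True)
class MarginalPrediction:
    """One standardised estimate at a grid point."""

    grid_point: dict
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    extrapolated: bool = False


class MarginalResult(NamedTuple):
    """Gridded predictions plus the delta-method machinery for contrasts."""

    table: pd.DataFrame          # grid columns + estimate/se/ci_low/ci_high
    grads: np.ndarray            # (n_grid, n_params) gradients of estimates
    vcov: np.ndarray             # parameter covariance matching grads
    param_names: list[str]

    def predictions(self) -> list[MarginalPrediction]:
        grid_cols = [c for c in self.table.columns
                     if c not in ("estimate", "se", "ci_low", "ci_high",
                                  "extrapolated")]
        return [MarginalPrediction(
            grid_point={c: row[c] for c in grid_cols},
            estimate=row["estimate"], se=row["se"],
            ci_low=row["ci_low"], ci_high=row["ci_high"],
            extrapolated=bool(row.get("extrapolated", False)))
            for _, row in self.table.iterrows()]


def _link_ci(est: float, se: float, link: str, z: float):
    eps = 1e-12
    p = min(max(est, eps), 1 - eps)
    if link == "probit":
        from scipy.special import ndtri
        l = ndtri(p)
        dldp = 1.0 / max(_phi(np.asarray(l)), eps)
    else:
        l = logit(p)
        dldp = 1.0 / (p * (1 - p))
    se_l = se * dldp
    lo, hi = l - z * se_l, l + z * se_l
    if link == "probit":
        return float(ndtr(lo)), float(ndtr(hi))
    return float(expit(lo)), float(expit(hi))


def marginal_predict(fit: FitResult, design: FittedDesign,
                     grid: pd.DataFrame, standardisation_sample: pd.DataFrame,
                     alpha: float = 0.05) -> MarginalResult:
    """Standardised predictions over a grid.

    Parameters
    ----------
    fit
        A fractional-probit or random-intercept-logistic :class:`FitResult`.
    design
        The fitted design used for ``fit``; rebuilt for each grid point.
    grid
        One row per grid point; its columns (e.g. ``device_model``,
        ``ita_degrees``, ``sao2_pct``) override the standardisation rows.
    standardisation_sample
        Rows supplying the averaged-over covariates.
    """
    if len(standardisation_sample) == 0:
        raise ValueError("standardisation sample is empty")
    from scipy.stats import norm
    zcrit = float(norm.ppf(1 - alpha / 2))

    re_model = fit.link == "logit-re"
    if re_model:
        beta = fit.extra["params_full"].to_numpy()[:-1]
        sigma = fit.random_effect_sd
        vcov = fit.extra["vcov_full"].to_numpy()
        param_names = list(fit.extra["vcov_full"].columns)
    else:
        beta = fit.params.to_numpy()
        vcov = fit.vcov.to_numpy()
        param_names = list(fit.params.index)

    extrap = design.flag_extrapolation(grid).to_numpy()
    rows_out, grads = [], []
    base = standardisation_sample.reset_index(drop=True)
    for g_idx, (_, gpoint) in enumerate(grid.iterrows()):
        rows = base.copy()
        for col, val in gpoint.items():
            rows[col] = val
        X = design.build(rows).to_numpy(float)
        eta = X @ beta
        if re_model:
            p = population_averaged_prob(eta, sigma)
            d_eta, d_lsig = population_averaged_grad(eta, sigma)
            grad = np.append((d_eta[:, None] * X).mean(axis=0),
                             d_lsig.mean())
        else:
            p = ndtr(eta)
            grad = (_phi(eta)[:, None] * X).mean(axis=0)
        est = float(np.mean(p))
        se = float(np.sqrt(max(grad @ vcov @ grad, 0.0)))
        link = "logit" if re_model else "probit"
        lo, hi = _link_ci(est, se, link, zcrit)
        rows_out.append(dict(gpoint) | {
            "estimate": est, "se": se, "ci_low": lo, "ci_high": hi,
            "extrapolated": bool(extrap[g_idx])})
        grads.append(grad)

    return MarginalResult(table=pd.DataFrame(rows_out),
                          grads=np.array(grads), vcov=vcov,
                          param_names=param_names)
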