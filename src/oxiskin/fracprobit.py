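"""Fractional probit regression with cluster-robust covariance.

The mean model is E[y | x] = Phi(x'beta) for a response y in [0, 1]
(boundary values allowed), estimated by Bernoulli quasi-maximum likelihood
— exactly a binomial GLM with probit link fitted to fractional outcomes.
Repeated measures within patients are handled by a cluster-level sandwich
covariance.  Estimation is delegated to statsmodels' GLM (IRLS / Fisher
scoring); this module owns validation, rank diagnostics and the FitResult
contract shared with the random-intercept fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import DomainWarning, PerfectSeparationWarning

__all__ = ["FitResult", "fit_fractional_probit"]


@dataclass
class FitResult:
    """Coefficients plus cluster-robust covariance for any fitted model."""

    params: pd.Series
    vcov: pd.DataFrame
    n_obs: int
    n_clusters: int
    converged: bool
    objective: float
    link: str = "probit"
    random_effect_sd: float | None = None
    extra: dict = field(default_factory=dict)

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.vcov)), index=self.params.index)

    def wald_z(self, term: str) -> float:
        return float(self.params[term] / self.se[term])


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(arr)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(
            f"design matrix is rank deficient ({rank}/{arr.shape[1]}); "
            f"suspect columns: {bad}")


def fit_fractional_probit(y, X: pd.DataFrame, cluster_ids) -> FitResult:
    """Quasi-ML fractional probit with a cluster sandwich covariance.

    Parameters
    ----------
    y
        Response on the fraction scale, values in [0, 1].
    X
        Model matrix with named columns (include the constant).
    cluster_ids
        One label per row; scores are aggregated within clusters before the
        sandwich is assembled, giving standard errors robust to arbitrary
        within-cluster correlation.
    """
    y = np.asarray(y, dtype=float)
    if y.min() < -1e-12 or y.max() > 1 + 1e-12:
        raise ValueError("fractional response must lie in [0, 1]")
    y = np.clip(y, 0.0, 1.0)
    if len(y) != len(X):
        raise ValueError("y and X have different lengths")
    _check_rank(X)
    groups = pd.factorize(np.asarray(cluster_ids))[0]

    with warnings.catch_warnings():
        # fractional (non-integer) outcomes are the point of QMLE
        warnings.simplefilter("ignore", DomainWarning)
        warnings.simplefilter("ignore", PerfectSeparationWarning)
        model = sm.GLM(y, X, family=sm.families.Binomial(
            link=sm.families.links.Probit()))
        res = model.fit(cov_type="cluster", cov_kwds={"groups": groups})

    return FitResult(
        params=pd.Series(res.params, index=X.columns),
        vcov=pd.DataFrame(res.cov_params(), index=X.columns,
                          columns=X.columns),
        n_obs=len(y),
        n_clusters=int(groups.max() + 1),
        converged=bool(getattr(res, "converged", True)),
        objective=float(res.llf),
        link="probit",
    )
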