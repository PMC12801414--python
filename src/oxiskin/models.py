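"""The seven-metric accuracy model suite.

Fits, per metric, a regression surface over (device, ITA, SaO2) and reports
standardised estimates with 95% limits plus dark-vs-light skin-tone
contrasts at the exemplar pair ITA -44 vs 46 degrees:

* bias, precision and A_RMS: fractional probit models on the fraction
  scale (SpO2/100, squared deviation from the bias model's prediction, and
  squared SpO2-SaO2 difference respectively) with cluster-robust errors;
* false negative / false positive rates at SpO2 thresholds 92 and 94:
  patient random-intercept logistic models of test positivity,
  marginalised over the hypoxaemic (SaO2 <= 92) and non-hypoxaemic strata;
* AUC: binormal probit ROC regression (placement values of case SpO2 in
  the device-specific control distribution) with patient bootstrap CIs;
* occult hypoxaemia: P(SpO2 > 92) from the threshold-92 logistic model,
  marginalised over the severe-hypoxaemia stratum (SaO2 < 88).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .design import DesignSpec, FittedDesign
from .fracprobit import FitResult, fit_fractional_probit
from .marginal import MarginalResult, marginal_predict
from .relogit import fit_random_intercept_logistic

__all__ = [
    "ModelConfig",
    "MetricSurfaceSet",
    "ToneContrast",
    "run_bias_model",
    "run_precision_model",
    "run_arms_model",
    "run_fn_fp_models",
    "run_roc_regression",
    "run_occult_model",
    "compare_skin_tones",
    "run_model_suite",
    "ModelSuiteResult",
]

RATE_METRICS = {"fnr92", "fnr94", "fpr92", "fpr94", "occult"}


@dataclass(frozen=True)
class ModelConfig:
    """Grid, design and resampling settings shared by the model suite."""

    design: DesignSpec = DesignSpec()
    ita_grid: tuple[float, ...] = tuple(np.arange(-60.0, 62.0, 2.0))
    sao2_anchors: tuple[float, ...] = (88.0, 90.0, 92.0, 94.0, 96.0, 98.0)
    ita_dark: float = -44.0
    ita_light: float = 46.0
    spo2_thresholds: tuple[float, ...] = (92.0, 94.0)
    std_sample_size: int | None = None   # None = all complete observations
    bootstrap_reps: int = 200
    roc_fpr_grid: tuple[float, ...] = tuple(np.round(
        np.arange(0.02, 1.0, 0.02), 2))
    roc_ita_spline: bool = False         # ITA linear in the ROC model
    n_quad: int = 15
    seed: int = 20220601


@dataclass
class MetricSurfaceSet:
    """Gridded standardised estimates for one metric."""

    metric: str
    table: pd.DataFrame                  # grid + estimate, ci_low, ci_high
    fit: FitResult | None = None
    marginal: MarginalResult | None = None

    def at(self, **coords) -> pd.DataFrame:
        mask = np.ones(len(self.table), dtype=bool)
        for col, val in coords.items():
            mask &= np.isclose(self.table[col].to_numpy(float), val) \
                if self.table[col].dtype.kind in "fc" \
                else (self.table[col] == val).to_numpy()
        return self.table[mask]


@dataclass(frozen=True)
class ToneContrast:
    """Dark-vs-light metric contrast (difference, and ratio for rates)."""

    metric: str
    device_model: str
    ita_dark: float
    ita_light: float
    value_dark: float
    value_light: float
    difference: float
    diff_ci_low: float
    diff_ci_high: float
    rate_ratio: float | None = None
    ratio_ci_low: float | None = None
    ratio_ci_high: float | None = None


def _std_sample(df: pd.DataFrame, config: ModelConfig,
                mask: np.ndarray | None = None) -> pd.DataFrame:
    rows = df if mask is None else df[mask]
    if len(rows) == 0:
        raise ValueError("empty standardisation stratum")
    k = config.std_sample_size
    if k is not None and len(rows) > k:
        rng = np.random.default_rng(config.seed)
        rows = rows.iloc[rng.choice(len(rows), size=k, replace=False)]
    return rows


def _grid(config: ModelConfig, devices, with_sao2: bool) -> pd.DataFrame:
    frames = []
    for dev in devices:
        for ita in config.ita_grid:
            if with_sao2:
                for s in config.sao2_anchors:
                    frames.append((dev, ita, s))
            else:
                frames.append((dev, ita))
    cols = ["device_model", "ita_degrees"] + (["sao2_pct"] if with_sao2 else [])
    return pd.DataFrame(frames, columns=cols)


def _fit_fractional(df: pd.DataFrame, y: np.ndarray,
                    config: ModelConfig) -> tuple[FitResult, FittedDesign]:
    design = config.design.fit(df)
    X = design.build(df)
    fit = fit_fractional_probit(y, X, df["patient_id"].to_numpy())
    return fit, design


def run_bias_model(df: pd.DataFrame, config: ModelConfig | None = None
                   ) -> MetricSurfaceSet:
    """Bias surface: 100 x marginal predicted SpO2 fraction minus SaO2."""
    config = config or ModelConfig()
    fit, design = _fit_fractional(df, df["spo2_pct"].to_numpy() / 100.0,
                                  config)
    std = _std_sample(df, config)
    grid = _grid(config, design.device_levels or df["device_model"].unique(),
                 with_sao2=True)
    mres = marginal_predict(fit, design, grid, std)
    tab = mres.table.copy()
    sao2 = tab["sao2_pct"].to_numpy(float)
    tab["spo2_pred_pct"] = 100.0 * tab["estimate"]
    tab["estimate"] = 100.0 * tab["estimate"] - sao2
    tab["ci_low"] = 100.0 * tab["ci_low"] - sao2
    tab["ci_high"] = 100.0 * tab["ci_high"] - sao2
    return MetricSurfaceSet("bias", tab, fit, mres)


def run_precision_model(df: pd.DataFrame, bias: MetricSurfaceSet,
                        config: ModelConfig | None = None) -> MetricSurfaceSet:
    """Precision surface from the squared deviation of SpO2 about the bias
    model's predicted mean."""
    config = config or ModelConfig()
    if bias.fit is None or not bias.fit.converged:
        raise ValueError("bias fit must have converged")
    design = config.design.fit(df)
    X = design.build(df)
    pred = ndtr(X.to_numpy(float) @ bias.fit.params.to_numpy())
    y = (df["spo2_pct"].to_numpy() / 100.0 - pred) ** 2
    fit = fit_fractional_probit(y, X, df["patient_id"].to_numpy())
    std = _std_sample(df, config)
    grid = _grid(config, design.device_levels or df["device_model"].unique(),
                 with_sao2=True)
    mres = marginal_predict(fit, design, grid, std)
    tab = mres.table.copy()
    for col in ("estimate", "ci_low", "ci_high"):
        tab[col] = 100.0 * np.sqrt(np.clip(tab[col], 0.0, None))
    return MetricSurfaceSet("precision", tab, fit, mres)


def run_arms_model(df: pd.DataFrame, config: ModelConfig | None = None
                   ) -> MetricSurfaceSet:
    """A_RMS surface from the squared SpO2-SaO2 difference."""
    config = config or ModelConfig()
    y = ((df["spo2_pct"].to_numpy() - df["sao2_pct"].to_numpy()) / 100.0) ** 2
    fit, design = _fit_fractional(df, y, config)
    std = _std_sample(df, config)
    grid = _grid(config, design.device_levels or df["device_model"].unique(),
                 with_sao2=True)
    mres = marginal_predict(fit, design, grid, std)
    tab = mres.table.copy()
    for col in ("estimate", "ci_low", "ci_high"):
        tab[col] = 100.0 * np.sqrt(np.clip(tab[col], 0.0, None))
    return MetricSurfaceSet("arms", tab, fit, mres)


def _fit_threshold_logistic(df: pd.DataFrame, threshold: float,
                            config: ModelConfig):
    y = (df["spo2_pct"].to_numpy(float) <= threshold).astype(float)
    if y.min() == y.max():
        raise ValueError(f"outcome SpO2<={threshold} has a single class")
    design = config.design.fit(df)
    X = design.build(df)
    fit = fit_random_intercept_logistic(y, X, df["patient_id"].to_numpy(),
                                        n_quad=config.n_quad)
    return fit, design


def run_fn_fp_models(df: pd.DataFrame, config: ModelConfig | None = None
                     ) -> dict[str, MetricSurfaceSet]:
    """FNR and FPR surfaces over (device, ITA) at each SpO2 threshold.

    One random-intercept logistic fit per threshold; the FNR marginalises
    1 - P(SpO2 <= t) over the hypoxaemic stratum (SaO2 <= 92), the FPR
    marginalises P(SpO2 <= t) over the non-hypoxaemic stratum.
    """
    config = config or ModelConfig()
    sao2 = df["sao2_pct"].to_numpy(float)
    out: dict[str, MetricSurfaceSet] = {}
    for t in config.spo2_thresholds:
        fit, design = _fit_threshold_logistic(df, t, config)
        grid = _grid(config, design.device_levels
                     or df["device_model"].unique(), with_sao2=False)
        for kind, mask in (("fnr", sao2 <= 92.0), ("fpr", sao2 > 92.0)):
            std = _std_sample(df, config, mask)
            mres = marginal_predict(fit, design, grid, std)
            tab = mres.table.copy()
            if kind == "fnr":
                est = 1.0 - tab["estimate"]
                lo = 1.0 - tab["ci_high"]
                hi = 1.0 - tab["ci_low"]
                tab["estimate"], tab["ci_low"], tab["ci_high"] = est, lo, hi
            name = f"{kind}{int(t)}"
            out[name] = MetricSurfaceSet(name, tab, fit, mres)
    return out


def _placement_values(spo2_cases, spo2_controls) -> np.ndarray:
    """Fraction of controls with SpO2 below each case value, ties half."""
    controls = np.sort(np.asarray(spo2_controls, dtype=float))
    lo = np.searchsorted(controls, spo2_cases, side="left")
    hi = np.searchsorted(controls, spo2_cases, side="right")
    return (lo + 0.5 * (hi - lo)) / len(controls)


def _roc_auc_table(df: pd.DataFrame, config: ModelConfig,
                   devices: list[str]) -> pd.DataFrame:
    """Point estimates of AUC(device, ITA) from one ROC-GLM fit."""
    sao2 = df["sao2_pct"].to_numpy(float)
    case = sao2 <= 92.0
    pv = np.full(len(df), np.nan)
    dev_arr = df["device_model"].astype(str).to_numpy()
    for dev in devices:
        dmask = dev_arr == dev
        n_case, n_ctrl = int((dmask & case).sum()), int((dmask & ~case).sum())
        if n_case < 10 or n_ctrl < 10:
            raise ValueError(
                f"device {dev}: need >=10 observations per class "
                f"(got {n_case} cases, {n_ctrl} controls)")
        pv[dmask & case] = _placement_values(
            df.loc[dmask & case, "spo2_pct"].to_numpy(float),
            df.loc[dmask & ~case, "spo2_pct"].to_numpy(float))

    cases = df[case].assign(pv=pv[case])
    u_grid = np.asarray(config.roc_fpr_grid)
    quant = ndtri(u_grid)
    # pseudo-observations: one row per (case, u)
    n_c, n_u = len(cases), len(u_grid)
    b = (cases["pv"].to_numpy()[:, None] <= u_grid[None, :]).astype(float)
    pseudo = pd.DataFrame({
        "device_model": np.repeat(cases["device_model"].to_numpy(), n_u),
        "ita_degrees": np.repeat(cases["ita_degrees"].to_numpy(float), n_u),
        "y": b.ravel(),
        "quantile": np.tile(quant, n_c),
    })
    roc_design = DesignSpec(
        ita="rcs" if config.roc_ita_spline else "linear", sao2="none",
        haemoglobin="none", device=True, device_by_ita=True,
        device_by_sao2=False, ita_by_sao2=False, site_effects=False)
    fitted = roc_design.fit(pseudo)
    X = fitted.build(pseudo)
    X["quantile"] = pseudo["quantile"].to_numpy()
    import statsmodels.api as sm
    res = sm.GLM(pseudo["y"].to_numpy(), X,
                 family=sm.families.Binomial(
                     link=sm.families.links.Probit())).fit()
    beta = pd.Series(res.params, index=X.columns)
    slope = float(beta["quantile"])

    rows = []
    for dev in devices:
        for ita in config.ita_grid:
            point = pd.DataFrame({"device_model": [dev],
                                  "ita_degrees": [ita]})
            a = (fitted.build(point).to_numpy(float)
                 @ beta.drop("quantile").to_numpy()).item()
            rows.append({"device_model": dev, "ita_degrees": ita,
                         "estimate": float(ndtr(a / np.sqrt(1 + slope**2)))})
    return pd.DataFrame(rows)


def run_roc_regression(df: pd.DataFrame, config: ModelConfig | None = None
                       ) -> MetricSurfaceSet:
    """Binormal probit ROC regression; AUC surface over (device, ITA).

    Confidence limits are percentile intervals from a patient-level
    (cluster) bootstrap.
    """
    config = config or ModelConfig()
    devices = sorted(df["device_model"].astype(str).unique())
    tab = _roc_auc_table(df, config, devices)

    reps = config.bootstrap_reps
    if reps > 0:
        rng = np.random.default_rng(config.seed)
        patients = df["patient_id"].unique()
        groups = dict(tuple(df.groupby("patient_id")))
        boots = []
        for _ in range(reps):
            pick = rng.choice(patients, size=len(patients), replace=True)
            bdf = pd.concat([groups[p] for p in pick], ignore_index=True)
            try:
                boots.append(_roc_auc_table(bdf, config, devices)
                             ["estimate"].to_numpy())
            except (ValueError, np.linalg.LinAlgError):
                continue
        if boots:
            arr = np.vstack(boots)
            tab["ci_low"] = np.percentile(arr, 2.5, axis=0)
            tab["ci_high"] = np.percentile(arr, 97.5, axis=0)
        else:
            tab["ci_low"] = np.nan
            tab["ci_high"] = np.nan
    else:
        tab["ci_low"] = np.nan
        tab["ci_high"] = np.nan
    return MetricSurfaceSet("auc", tab)


def run_occult_model(df: pd.DataFrame, config: ModelConfig | None = None,
                     fnr92: MetricSurfaceSet | None = None
                     ) -> MetricSurfaceSet:
    """Occult-hypoxaemia surface: P(SpO2 > 92) marginalised over the
    severe-hypoxaemia stratum (SaO2 < 88), reusing the threshold-92
    logistic fit when available."""
    config = config or ModelConfig()
    sao2 = df["sao2_pct"].to_numpy(float)
    if not np.any(sao2 < 88.0):
        raise ValueError("no observations with SaO2 < 88%")
    if fnr92 is not None and fnr92.fit is not None:
        fit = fnr92.fit
        design = config.design.fit(df)
    else:
        fit, design = _fit_threshold_logistic(df, 92.0, config)
    grid = _grid(config, design.device_levels or df["device_model"].unique(),
                 with_sao2=False)
    std = _std_sample(df, config, sao2 < 88.0)
    mres = marginal_predict(fit, design, grid, std)
    tab = mres.table.copy()
    est = 1.0 - tab["estimate"]
    lo = 1.0 - tab["ci_high"]
    hi = 1.0 - tab["ci_low"]
    tab["estimate"], tab["ci_low"], tab["ci_high"] = est, lo, hi
    return MetricSurfaceSet("occult", tab, fit, mres)


def _transform_chain(metric: str, p: float, grad: np.ndarray,
                     ) -> tuple[float, np.ndarray]:
    """Map a fraction-scale estimate and gradient to the metric scale."""
    if metric == "bias":                       # handled with sao2 offset
        return 100.0 * p, 100.0 * grad
    if metric in ("precision", "arms"):
        v = 100.0 * np.sqrt(max(p, 1e-12))
        return v, grad * (100.0 / (2.0 * np.sqrt(max(p, 1e-12))))
    if metric in ("fnr92", "fnr94", "occult"):
        return 1.0 - p, -grad
    return p, grad


def overall_occult_rate(df: pd.DataFrame, config: ModelConfig | None = None,
                        fnr92: MetricSurfaceSet | None = None
                        ) -> tuple[float, float, float]:
    """Model-based occult-hypoxaemia rate marginalised over the observed
    covariate distribution of the severe stratum (no grid overrides): the
    direct counterpart of the empirical rate.

    Returns (estimate, ci_low, ci_high).  Agreement with the empirical
    rate is approximate: the logistic-normal marginal flattens slightly in
    the thin SaO2 < 88 tail relative to the raw stratum frequency.
    """
    config = config or ModelConfig()
    sao2 = df["sao2_pct"].to_numpy(float)
    if not np.any(sao2 < 88.0):
        raise ValueError("no observations with SaO2 < 88%")
    if fnr92 is not None and fnr92.fit is not None:
        fit = fnr92.fit
        design = config.design.fit(df)
    else:
        fit, design = _fit_threshold_logistic(df, 92.0, config)
    std = _std_sample(df, config, sao2 < 88.0)
    mres = marginal_predict(fit, design, pd.DataFrame(index=[0]), std)
    row = mres.table.iloc[0]
    return (1.0 - float(row["estimate"]), 1.0 - float(row["ci_high"]),
            1.0 - float(row["ci_low"]))


def compare_skin_tones(surface: MetricSurfaceSet,
                       ita_dark: float = -44.0, ita_light: float = 46.0,
                       sao2_anchor: float | None = 92.0
                       ) -> list[ToneContrast]:
    """Dark-minus-light contrasts per device with delta-method limits.

    Model-backed surfaces use the fitted parameter covariance and the
    stored prediction gradients, so the correlation between the two grid
    points is respected; rate metrics additionally report a rate ratio
    with limits computed on the log scale.  Surfaces without gradients
    (the bootstrap-based AUC) fall back to a table-based contrast that
    treats the two points as independent.
    """
    if surface.marginal is None or surface.fit is None:
        return _contrast_from_table(surface, ita_dark, ita_light)
    mres = surface.marginal
    tab = mres.table
    has_sao2 = "sao2_pct" in tab.columns
    is_rate = surface.metric in RATE_METRICS
    out = []
    for dev in sorted(tab["device_model"].unique()):
        mask = (tab["device_model"] == dev).to_numpy()
        if has_sao2 and sao2_anchor is not None:
            mask &= np.isclose(tab["sao2_pct"].to_numpy(float), sao2_anchor)
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            continue
        sub_ita = tab["ita_degrees"].to_numpy(float)[idx]
        i_d = idx[np.argmin(np.abs(sub_ita - ita_dark))]
        i_l = idx[np.argmin(np.abs(sub_ita - ita_light))]
        # the marginal table holds raw fraction-scale estimates; transform
        # to the metric scale together with the gradients
        raw_d = float(tab["estimate"].iloc[i_d])
        raw_l = float(tab["estimate"].iloc[i_l])
        v_d, g_d = _transform_chain(surface.metric, raw_d, mres.grads[i_d])
        v_l, g_l = _transform_chain(surface.metric, raw_l, mres.grads[i_l])
        if surface.metric == "bias" and has_sao2:
            anchor = float(tab["sao2_pct"].iloc[i_d])
            v_d -= anchor
            v_l -= anchor
        diff = v_d - v_l
        g = g_d - g_l
        se = float(np.sqrt(max(g @ mres.vcov @ g, 0.0)))
        rr = rlo = rhi = None
        if is_rate and v_d > 0 and v_l > 0:
            rr = v_d / v_l
            g_log = g_d / v_d - g_l / v_l
            se_log = float(np.sqrt(max(g_log @ mres.vcov @ g_log, 0.0)))
            rlo = float(rr * np.exp(-1.96 * se_log))
            rhi = float(rr * np.exp(1.96 * se_log))
        out.append(ToneContrast(
            metric=surface.metric, device_model=str(dev),
            ita_dark=float(tab["ita_degrees"].iloc[i_d]),
            ita_light=float(tab["ita_degrees"].iloc[i_l]),
            value_dark=v_d, value_light=v_l, difference=diff,
            diff_ci_low=diff - 1.96 * se, diff_ci_high=diff + 1.96 * se,
            rate_ratio=rr, ratio_ci_low=rlo, ratio_ci_high=rhi))
    return out


def _contrast_from_table(surface: MetricSurfaceSet, ita_dark: float,
                         ita_light: float) -> list[ToneContrast]:
    """Pointwise contrasts from a gridded table (no parameter covariance:
    CIs by independent-error approximation)."""
    out = []
    tab = surface.table
    is_rate = surface.metric in RATE_METRICS or surface.metric == "auc"
    sao2_vals = ([None] if "sao2_pct" not in tab.columns
                 else [92.0] if 92.0 in set(tab["sao2_pct"]) else
                 [sorted(set(tab["sao2_pct"]))[0]])
    for dev in sorted(tab["device_model"].unique()):
        sub = tab[tab["device_model"] == dev]
        if sao2_vals[0] is not None:
            sub = sub[np.isclose(sub["sao2_pct"].to_numpy(float),
                                 sao2_vals[0])]
        row_d = sub.iloc[(sub["ita_degrees"] - ita_dark).abs().argmin()]
        row_l = sub.iloc[(sub["ita_degrees"] - ita_light).abs().argmin()]
        d, l = float(row_d["estimate"]), float(row_l["estimate"])
        se_d = (row_d["ci_high"] - row_d["ci_low"]) / (2 * 1.96)
        se_l = (row_l["ci_high"] - row_l["ci_low"]) / (2 * 1.96)
        se = float(np.sqrt(se_d**2 + se_l**2))
        diff = d - l
        rr = rlo = rhi = None
        if is_rate and l > 0 and d > 0:
            rr = d / l
            se_log = np.sqrt((se_d / d)**2 + (se_l / l)**2)
            rlo = float(rr * np.exp(-1.96 * se_log))
            rhi = float(rr * np.exp(1.96 * se_log))
        out.append(ToneContrast(
            metric=surface.metric, device_model=str(dev),
            ita_dark=ita_dark, ita_light=ita_light,
            value_dark=d, value_light=l, difference=diff,
            diff_ci_low=diff - 1.96 * se, diff_ci_high=diff + 1.96 * se,
            rate_ratio=rr, ratio_ci_low=rlo, ratio_ci_high=rhi))
    return out


@dataclass
class ModelSuiteResult:
    surfaces: dict[str, MetricSurfaceSet]
    contrasts: pd.DataFrame

    def surface(self, metric: str) -> MetricSurfaceSet:
        return self.surfaces[metric]


def run_model_suite(df: pd.DataFrame, config: ModelConfig | None = None
                    ) -> ModelSuiteResult:
    """Run all seven metrics and assemble the dark-vs-light contrasts."""
    config = config or ModelConfig()
    surfaces: dict[str, MetricSurfaceSet] = {}
    bias = run_bias_model(df, config)
    surfaces["bias"] = bias
    surfaces["precision"] = run_precision_model(df, bias, config)
    surfaces["arms"] = run_arms_model(df, config)
    surfaces.update(run_fn_fp_models(df, config))
    surfaces["auc"] = run_roc_regression(df, config)
    surfaces["occult"] = run_occult_model(df, config,
                                          fnr92=surfaces.get("fnr92"))
    rows = []
    for name, surf in surfaces.items():
        for c in compare_skin_tones(surf, config.ita_dark, config.ita_light):
            rows.append(c.__dict__)
    return ModelSuiteResult(surfaces=surfaces, contrasts=pd.DataFrame(rows))
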