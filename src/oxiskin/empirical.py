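"""Model-free accuracy and diagnostic-accuracy statistics for paired
SpO2-SaO2 observations.

These are the descriptive counterparts of the regression surfaces: bias,
precision and A_RMS (the ISO accuracy-root-mean-square), false negative /
false positive rates at the clinical SpO2 alert thresholds, the empirical
(Mann-Whitney) AUC, and the occult-hypoxaemia rate.  All operate on a tidy
observation table with columns ``spo2_pct`` and ``sao2_pct`` (plus
``patient_id`` where noted) and serve as oracles for the model suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EmpiricalAccuracy",
    "ThresholdDiagnostics",
    "empirical_accuracy",
    "threshold_diagnostics",
    "empirical_auc",
    "occult_hypoxaemia_rate",
    "evaluate_by",
]

HYPOX_SAO2_THRESHOLD = 92.0     # condition positive: SaO2 <= 92%
SEVERE_SAO2_THRESHOLD = 88.0    # severe hypoxaemia: SaO2 < 88%
REASSURING_SPO2 = 92.0          # occult: SpO2 > 92% despite SaO2 < 88%


@dataclass(frozen=True)
class EmpiricalAccuracy:
    n: int
    bias_pp: float
    precision_pp: float
    arms_pp: float


@dataclass(frozen=True)
class ThresholdDiagnostics:
    spo2_threshold: float
    sao2_threshold: float
    fn: int
    tp: int
    fp: int
    tn: int
    fnr: float   # NaN when no condition positives
    fpr: float   # NaN when no condition negatives


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def empirical_accuracy(pairs: pd.DataFrame) -> EmpiricalAccuracy:
    """Bias, precision and A_RMS of the errors SpO2 - SaO2.

    bias = mean error; arms = root mean squared error; precision is the RMS
    deviation about the mean, so that arms^2 = bias^2 + precision^2 exactly
    (uncorrected, divide-by-n variance).
    """
    if len(pairs) == 0:
        raise ValueError("empirical_accuracy requires at least one pair")
    err = pairs["spo2_pct"].to_numpy(float) - pairs["sao2_pct"].to_numpy(float)
    bias = float(np.mean(err))
    arms = float(np.sqrt(np.mean(err**2)))
    precision = float(np.sqrt(max(arms**2 - bias**2, 0.0)))
    return EmpiricalAccuracy(n=len(err), bias_pp=bias,
                             precision_pp=precision, arms_pp=arms)


def threshold_diagnostics(pairs: pd.DataFrame, spo2_threshold: float,
                          sao2_threshold: float = HYPOX_SAO2_THRESHOLD,
                          round_sao2: bool = False) -> ThresholdDiagnostics:
    """Classification counts for the rule "SpO2 <= threshold" against the
    reference condition SaO2 <= 92%.

    ``round_sao2`` applies the descriptive-table convention of rounding
    SaO2 to the nearest integer percentage point (half away from zero)
    before comparison; by default the unrounded values are used.
    """
    spo2 = pairs["spo2_pct"].to_numpy(float)
    sao2 = pairs["sao2_pct"].to_numpy(float)
    if round_sao2:
        sao2 = _round_half_away(sao2)
    cond = sao2 <= sao2_threshold
    test = spo2 <= spo2_threshold
    tp = int(np.sum(cond & test))
    fn = int(np.sum(cond & ~test))
    fp = int(np.sum(~cond & test))
    tn = int(np.sum(~cond & ~test))
    if fn + tp == 0:
        warnings.warn("no condition-positive observations: FNR undefined")
        fnr = float("nan")
    else:
        fnr = fn / (fn + tp)
    if fp + tn == 0:
        warnings.warn("no condition-negative observations: FPR undefined")
        fpr = float("nan")
    else:
        fpr = fp / (fp + tn)
    return ThresholdDiagnostics(spo2_threshold=float(spo2_threshold),
                                sao2_threshold=float(sao2_threshold),
                                fn=fn, tp=tp, fp=fp, tn=tn, fnr=fnr, fpr=fpr)


def empirical_auc(pairs: pd.DataFrame,
                  sao2_threshold: float = HYPOX_SAO2_THRESHOLD) -> float:
    """Mann-Whitney AUC of SpO2 for detecting SaO2 <= 92%.

    The probability that a condition-positive observation has lower SpO2
    than a condition-negative one, ties counted one half; equal to the
    trapezoidal area under the empirical ROC curve.
    """
    spo2 = pairs["spo2_pct"].to_numpy(float)
    cond = pairs["sao2_pct"].to_numpy(float) <= sao2_threshold
    pos, neg = spo2[cond], spo2[~cond]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("AUC requires both condition classes")
    # U counts (neg > pos) pairs with ties as 1/2, i.e. the AUC numerator.
    u = stats.mannwhitneyu(neg, pos, alternative="two-sided").statistic
    return float(u / (len(pos) * len(neg)))


def occult_hypoxaemia_rate(pairs: pd.DataFrame,
                           per_patient: bool = False) -> float:
    """Occult hypoxaemia: reassuring SpO2 (> 92%) despite SaO2 < 88%.

    Observation-level by default.  With ``per_patient=True`` the unit is
    the patient: among patients with any SaO2 < 88%, the fraction with at
    least one qualifying pair (SaO2 < 88% and SpO2 > 92%).  An empty
    severe-hypoxaemia stratum yields NaN with a warning, never zero.
    """
    severe = pairs[pairs["sao2_pct"].to_numpy(float) < SEVERE_SAO2_THRESHOLD]
    if len(severe) == 0:
        warnings.warn("no observations with SaO2 < 88%: rate undefined")
        return float("nan")
    occult = severe["spo2_pct"].to_numpy(float) > REASSURING_SPO2
    if per_patient:
        flags = pd.Series(occult, index=severe["patient_id"].to_numpy())
        return float(flags.groupby(level=0).any().mean())
    return float(np.mean(occult))


def evaluate_by(pairs: pd.DataFrame, by: list[str] | None = None,
                spo2_thresholds: tuple[float, ...] = (92.0, 94.0)
                ) -> pd.DataFrame:
    """Per-group metric table (bias/precision/A_RMS, FNR/FPR at each
    threshold, AUC, occult rate); ``by=None`` gives a single overall row."""
    groups = [("overall", pairs)] if not by else list(pairs.groupby(by))
    rows = []
    for key, grp in groups:
        acc = empirical_accuracy(grp)
        row: dict = {"n": acc.n, "bias_pp": acc.bias_pp,
                     "precision_pp": acc.precision_pp, "arms_pp": acc.arms_pp}
        if by:
            key = key if isinstance(key, tuple) else (key,)
            row = dict(zip(by, key)) | row
        else:
            row = {"group": "overall"} | row
        for t in spo2_thresholds:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d = threshold_diagnostics(grp, t)
            row[f"fnr{int(t)}"] = d.fnr
            row[f"fpr{int(t)}"] = d.fpr
        try:
            row["auc"] = empirical_auc(grp)
        except ValueError:
            row["auc"] = float("nan")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            row["occult"] = occult_hypoxaemia_rate(grp)
        rows.append(row)
    return pd.DataFrame(rows)
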