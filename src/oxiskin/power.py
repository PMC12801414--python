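"""Simulation-based power analysis for the skin-tone bias gradient.

Planning design: n patients each contributing ~12 paired readings; device
error with SaO2-dependent bias but a purely linear skin-tone term scaled so
the bias difference between ITA 28 degrees (lower boundary of the
intermediate category) and -30 degrees (upper boundary of the dark
category) equals ``effect_pp``.  Each replicate fits a fractional probit of
SpO2/100 on device, a restricted cubic spline in SaO2 and a linear ITA
term with patient-cluster-robust standard errors, and performs a two-sided
Wald test of the ITA coefficient.  Power is the rejection fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .design import DesignSpec
from .fracprobit import fit_fractional_probit
from .simulate import GeneratorConfig, generate_dataset

__all__ = ["PowerResult", "power_simulation"]

#: ITA anchors defining the effect scale (intermediate/dark boundaries).
EFFECT_ITA_HIGH = 28.0
EFFECT_ITA_LOW = -30.0

_POWER_DESIGN = DesignSpec(ita="linear", sao2="rcs", haemoglobin="none",
                           device=True, device_by_ita=False,
                           device_by_sao2=False, ita_by_sao2=False,
                           site_effects=False)


@dataclass(frozen=True)
class PowerResult:
    power: float
    rejections: int
    n_reps: int
    alpha: float
    effect_pp: float
    ci_low: float     # Wilson 95% interval for the rejection probability
    ci_high: float

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.power * (1 - self.power) / self.n_reps))


def _wilson(k: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    p = k / n
    denom = 1 + z**2 / n
    centre = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return centre - half, centre + half


def power_simulation(config: GeneratorConfig | None = None,
                     effect_pp: float = 1.5, n_reps: int = 200,
                     alpha: float = 0.05,
                     seed: int | None = None) -> PowerResult:
    """Monte-Carlo power of the two-sided Wald test for a linear ITA bias
    gradient.

    The tone gradient of every device profile is replaced by the linear
    effect (``effect_pp`` over the 58-degree span between ITA 28 and -30);
    with ``effect_pp=0`` the simulation estimates the type-I error rate.
    Skin-tone measurement noise is not simulated here: the planning model
    uses the patients' ITA directly.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be positive")
    config = GeneratorConfig() if config is None else config
    if seed is None:
        seed = config.seed
    # slope per 90 deg so the 28 -> -30 difference equals effect_pp
    grad = effect_pp * 90.0 / (EFFECT_ITA_HIGH - EFFECT_ITA_LOW)
    devices = tuple(replace(d, tone_gradient_pp_per_90deg=grad)
                    for d in config.devices)
    base = config.with_(devices=devices, ita_ref_degrees=EFFECT_ITA_HIGH)

    seed_seq = np.random.SeedSequence(seed)
    rep_seeds = seed_seq.generate_state(n_reps) % (2**31 - 1)
    zcrit = stats.norm.ppf(1 - alpha / 2)
    rejections = 0
    for r in range(n_reps):
        cfg = base.with_(seed=int(rep_seeds[r]))
        study = generate_dataset(cfg, with_readings=False)
        df = study.merged()
        design = _POWER_DESIGN.fit(df)
        X = design.build(df)
        fit = fit_fractional_probit(df["spo2_pct"].to_numpy() / 100.0, X,
                                    df["patient_id"].to_numpy())
        if abs(fit.wald_z("ita")) > zcrit:
            rejections += 1
    power = rejections / n_reps
    lo, hi = _wilson(rejections, n_reps)
    return PowerResult(power=power, rejections=rejections, n_reps=n_reps,
                       alpha=alpha, effect_pp=effect_pp,
                       ci_low=float(lo), ci_high=float(hi))
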