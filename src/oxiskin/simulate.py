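"""Synthetic paired SpO2-SaO2 study generator.

Emulates the structure of a multicentre pulse-oximeter accuracy study in
critically ill adults: ~900 patients across 24 sites, two of five fingertip
device models allocated per site, ~6 arterial samples per patient each read
by both devices (~12 pairs/patient), skin tone over-representing darker
tones, SaO2 concentrated in 93-99% with a small severe-hypoxaemia tail,
and device error that overestimates at low SaO2, underestimates at high
SaO2, and carries a skin-tone gradient (higher readings at darker tones).

The SaO2 marginal was calibrated once to the published descriptive
distribution (rounded bands <88%: 1.7%, 88-92%: 14.1%, 93-94%: 16.6%,
>94%: 67.6%; median 96, IQR 94-97) using a two-component lognormal mixture
for the patient-level saturation deficit plus an AR(1) within-patient
process; the resulting constants are frozen below.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import NamedTuple

import numpy as np
import pandas as pd

from .skin_tone import categorize_ita, compute_ita, skin_tone_table

__all__ = [
    "DeviceProfile",
    "GeneratorConfig",
    "DEFAULT_DEVICES",
    "sample_patients",
    "sample_sao2",
    "generate_spo2",
    "generate_dataset",
    "SimulatedStudy",
]

#: Reference ITA at which the tone term vanishes (median light skin tone).
ITA_REF_DEGREES = 46.0

# Frozen SaO2 process constants (see module docstring).
_SAO2_MU1, _SAO2_TAU1 = 1.3541, 0.3747     # majority (healthier) deficit
_SAO2_MU2, _SAO2_TAU2 = 2.1817, 0.2592     # minority (sicker) deficit
_SAO2_PI_SICK = 0.1599
_SAO2_OMEGA = 0.8312                        # within-patient stationary SD
_SAO2_RHO = 0.5                             # AR(1) coefficient

# Haemoglobin: lognormal matching median 101 g/L, IQR 86-117.
_HB_LOG_MEDIAN = float(np.log(101.0))
_HB_LOG_SD = 0.228

#: ITA category sampling bands (uniform within band), darkest first.
ITA_BANDS: dict[str, tuple[float, float]] = {
    "light": (41.0, 58.0),          # light + very light combined
    "intermediate": (28.0, 41.0),
    "tan": (10.0, 28.0),
    "brown": (-30.0, 10.0),
    "dark": (-60.0, -30.0),
}


@dataclass(frozen=True)
class DeviceProfile:
    """Error model of one fingertip pulse-oximeter model.

    mean reading = sao2 + slope * (tipping_point - sao2)
                 + tone_gradient * (ita_ref - ita) / 90 + patient_effect

    so the device overestimates below its tipping point, underestimates
    above it, and reads higher for darker (lower-ITA) skin.
    """

    label: str
    tipping_point_pct: float
    slope_pp_per_pp: float
    tone_gradient_pp_per_90deg: float
    noise_sd_pp: float = 2.0

    def __post_init__(self) -> None:
        if self.noise_sd_pp < 0:
            raise ValueError("noise_sd_pp must be >= 0")
        if not 80.0 <= self.tipping_point_pct <= 100.0:
            raise ValueError("tipping_point_pct must lie in [80, 100]")

    def mean_reading(self, sao2, ita, patient_effect=0.0,
                     ita_ref: float = ITA_REF_DEGREES):
        sao2 = np.asarray(sao2, dtype=float)
        ita = np.asarray(ita, dtype=float)
        return (sao2
                + self.slope_pp_per_pp * (self.tipping_point_pct - sao2)
                + self.tone_gradient_pp_per_90deg * (ita_ref - ita) / 90.0
                + patient_effect)


#: Five default device models with tipping points and tone gradients
#: spanning the reported range of behaviours (gradients 0.6-1.5 pp per 90
#: degrees of ITA).
DEFAULT_DEVICES: tuple[DeviceProfile, ...] = (
    DeviceProfile("MD300C19", 93.0, 0.35, 0.8),
    DeviceProfile("MD300C13", 91.0, 0.25, 1.5),
    DeviceProfile("PC-60B1", 95.0, 0.30, 0.6),
    DeviceProfile("M70C", 97.0, 0.20, 1.0),
    DeviceProfile("AM802", 94.0, 0.40, 1.2),
)

#: Skin-tone category mixture (light band combines light + very light).
DEFAULT_ITA_MIXTURE: dict[str, float] = {
    "light": 0.123,
    "intermediate": 0.154,
    "tan": 0.219,
    "brown": 0.338,
    "dark": 0.166,
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_patients: int = 900
    n_sites: int = 24
    samples_per_patient: int = 6
    devices_per_patient: int = 2
    devices: tuple[DeviceProfile, ...] = DEFAULT_DEVICES
    ita_mixture: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITA_MIXTURE))
    patient_re_sd_pp: float = 1.5
    ita_ref_degrees: float = ITA_REF_DEGREES
    readings_per_patient: int = 4
    reading_noise_sd: float = 2.7   # CIELAB units; ~3 deg within-patient SE
    seed: int = 20220601

    def __post_init__(self) -> None:
        probs = np.array(list(self.ita_mixture.values()), dtype=float)
        if probs.min() < 0 or abs(probs.sum() - 1.0) > 1e-8:
            raise ValueError("ita_mixture must be non-negative and sum to 1")
        unknown = set(self.ita_mixture) - set(ITA_BANDS)
        if unknown:
            raise ValueError(f"unknown ITA categories: {sorted(unknown)}")
        if min(self.n_patients, self.n_sites, self.samples_per_patient,
               self.devices_per_patient) < 1:
            raise ValueError("counts must be positive")
        if self.devices_per_patient > len(self.devices):
            raise ValueError("devices_per_patient exceeds available devices")

    @property
    def pairs_per_patient(self) -> int:
        return self.samples_per_patient * self.devices_per_patient

    @property
    def n_pairs(self) -> int:
        return self.n_patients * self.pairs_per_patient

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


def _site_device_allocation(config: GeneratorConfig,
                            rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Fixed allocation of a device subset to each site."""
    combos = list(combinations(range(len(config.devices)),
                               config.devices_per_patient))
    order = rng.permutation(len(combos))
    return [combos[order[s % len(combos)]] for s in range(config.n_sites)]


def sample_patients(config: GeneratorConfig,
                    rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Patient table: site, allocated devices, true ITA, haemoglobin,
    patient random effect."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n = config.n_patients
    cats = list(config.ita_mixture)
    probs = np.array([config.ita_mixture[c] for c in cats])
    which = rng.choice(len(cats), size=n, p=probs)
    lo = np.array([ITA_BANDS[cats[k]][0] for k in which])
    hi = np.array([ITA_BANDS[cats[k]][1] for k in which])
    ita = lo + (hi - lo) * rng.random(n)

    sites = np.arange(n) % config.n_sites
    alloc = _site_device_allocation(config, rng)
    hb = np.exp(_HB_LOG_MEDIAN + _HB_LOG_SD * rng.standard_normal(n))
    hb = np.clip(hb, 40.0, 200.0)
    pat_eff = config.patient_re_sd_pp * rng.standard_normal(n)
    width = len(str(n))
    return pd.DataFrame({
        "patient_id": [f"P{i + 1:0{width}d}" for i in range(n)],
        "site_id": [f"S{s + 1:02d}" for s in sites],
        "device_idx": [alloc[s] for s in sites],
        "ita_true": ita,
        "category_true": categorize_ita(ita),
        "haemoglobin_g_per_l": hb,
        "patient_effect": pat_eff,
    })


def sample_sao2(n_patients: int, samples_per_patient: int,
                rng: np.random.Generator) -> np.ndarray:
    """SaO2 draws, shape (n_patients, samples_per_patient).

    Patient-level deficit from a two-component lognormal mixture plus a
    stationary AR(1) within-patient process, clipped to [80, 100].
    """
    sick = rng.random(n_patients) < _SAO2_PI_SICK
    z = rng.standard_normal(n_patients)
    deficit = np.where(sick, np.exp(_SAO2_MU2 + _SAO2_TAU2 * z),
                       np.exp(_SAO2_MU1 + _SAO2_TAU1 * z))
    e = np.empty((n_patients, samples_per_patient))
    e[:, 0] = rng.standard_normal(n_patients)
    for j in range(1, samples_per_patient):
        e[:, j] = (_SAO2_RHO * e[:, j - 1]
                   + np.sqrt(1 - _SAO2_RHO**2) * rng.standard_normal(n_patients))
    sao2 = 100.0 - deficit[:, None] + _SAO2_OMEGA * e
    return np.clip(sao2, 80.0, 100.0)


def generate_spo2(sao2, ita, device: DeviceProfile, patient_effect,
                  rng: np.random.Generator,
                  ita_ref: float = ITA_REF_DEGREES) -> np.ndarray:
    """Integer SpO2 readings: device mean + Gaussian noise, rounded half
    away from zero, clipped to [70, 100]."""
    mean = device.mean_reading(sao2, ita, patient_effect, ita_ref)
    raw = mean + device.noise_sd_pp * rng.standard_normal(np.shape(mean))
    rounded = np.sign(raw) * np.floor(np.abs(raw) + 0.5)
    return np.clip(rounded, 70.0, 100.0)


def _generate_readings(patients: pd.DataFrame, config: GeneratorConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Per-patient spectrophotometer readings consistent with true ITA."""
    n = len(patients)
    r = 16.0 + 14.0 * rng.random(n)         # radius from (L*=50, b*=0)
    ang = np.radians(patients["ita_true"].to_numpy())
    l_true = 50.0 + r * np.sin(ang)
    b_true = r * np.cos(ang)
    rows = []
    for i, pid in enumerate(patients["patient_id"]):
        nl = rng.standard_normal(config.readings_per_patient)
        nb = rng.standard_normal(config.readings_per_patient)
        na = rng.standard_normal(config.readings_per_patient)
        for k in range(config.readings_per_patient):
            rows.append({
                "patient_id": pid, "reading_index": k + 1,
                "l_star": float(np.clip(
                    l_true[i] + config.reading_noise_sd * nl[k], 0, 100)),
                "a_star": float(14.0 + 1.5 * na[k]),
                "b_star": float(b_true[i] + config.reading_noise_sd * nb[k]),
            })
    return pd.DataFrame(rows)


class SimulatedStudy(NamedTuple):
    observations: pd.DataFrame   # schema columns + ita_true
    readings: pd.DataFrame       # spectrophotometer readings
    skin_tones: pd.DataFrame     # aggregated (measured) per-patient ITA
    patients: pd.DataFrame

    def merged(self) -> pd.DataFrame:
        """Observations joined with measured ITA — the modelling table."""
        tones = self.skin_tones[["patient_id", "ita_degrees", "category"]]
        return self.observations.merge(tones, on="patient_id", how="left")


def generate_dataset(config: GeneratorConfig | None = None,
                     with_readings: bool = True) -> SimulatedStudy:
    """Full synthetic study: observation table plus skin-tone measurements.

    With defaults this yields n_patients * samples_per_patient *
    devices_per_patient = 900 * 6 * 2 = 10 800 paired observations.  With
    ``with_readings=False`` the skin-tone table carries the true ITA
    (zero measurement error) and no readings are synthesised.
    """
    config = GeneratorConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    patients = sample_patients(config, rng)
    sao2 = sample_sao2(config.n_patients, config.samples_per_patient, rng)

    frames = []
    ita = patients["ita_true"].to_numpy()
    pat_eff = patients["patient_effect"].to_numpy()
    for d_slot in range(config.devices_per_patient):
        dev_idx = np.array([alloc[d_slot]
                            for alloc in patients["device_idx"]])
        for dev_id in np.unique(dev_idx):
            device = config.devices[dev_id]
            mask = dev_idx == dev_id
            spo2 = generate_spo2(sao2[mask], ita[mask, None], device,
                                 pat_eff[mask, None], rng,
                                 config.ita_ref_degrees)
            sub = patients.loc[mask]
            ns = config.samples_per_patient
            frames.append(pd.DataFrame({
                "patient_id": np.repeat(sub["patient_id"].to_numpy(), ns),
                "site_id": np.repeat(sub["site_id"].to_numpy(), ns),
                "device_model": device.label,
                "spo2_pct": spo2.ravel(),
                "sao2_pct": sao2[mask].ravel(),
                "haemoglobin_g_per_l": np.repeat(
                    sub["haemoglobin_g_per_l"].to_numpy(), ns),
                "sample_index": np.tile(np.arange(1, ns + 1), mask.sum()),
                "ita_true": np.repeat(sub["ita_true"].to_numpy(), ns),
            }))
    obs = (pd.concat(frames, ignore_index=True)
           .sort_values(["patient_id", "device_model", "sample_index"])
           .reset_index(drop=True))

    if with_readings:
        readings = _generate_readings(patients, config, rng)
        tones = skin_tone_table(readings)
    else:
        readings = pd.DataFrame(
            columns=["patient_id", "reading_index", "l_star", "a_star",
                     "b_star"])
        tones = pd.DataFrame({
            "patient_id": patients["patient_id"],
            "ita_degrees": patients["ita_true"],
            "category": patients["category_true"],
            "n_readings": 0,
            "ita_se_degrees": 0.0,
        })
    return SimulatedStudy(observations=obs, readings=readings,
                          skin_tones=tones, patients=patients)
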