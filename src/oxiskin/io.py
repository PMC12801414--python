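"""File schemas, validation and run configuration.

CSV is the sole tabular interchange format; JSON for summaries; YAML for
configuration.  The observation schema is::

    patient_id, site_id, device_model, spo2_pct, sao2_pct,
    haemoglobin_g_per_l, sample_index

Rows violating the invariants (saturations in [0, 100], positive
haemoglobin, unique (patient_id, device_model, sample_index)) are rejected
with row-numbered diagnostics; missing haemoglobin is permitted but
flagged, mirroring how studies omit such patients from adjusted models.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PairedObservation",
    "OBSERVATION_COLUMNS",
    "read_observations",
    "write_observations",
    "read_lab_readings",
    "read_skin_tones",
    "write_skin_tones",
    "RunConfig",
]

logger = logging.getLogger("oxiskin")

OBSERVATION_COLUMNS = ("patient_id", "site_id", "device_model", "spo2_pct",
                       "sao2_pct", "haemoglobin_g_per_l", "sample_index")
READING_COLUMNS = ("patient_id", "reading_index", "l_star", "a_star",
                   "b_star")
SKIN_TONE_COLUMNS = ("patient_id", "ita_degrees", "category", "n_readings",
                     "ita_se_degrees")


@dataclass(frozen=True)
class PairedObservation:
    """One synchronous SpO2-SaO2 pair with its clinical context."""

    patient_id: str
    site_id: str
    device_model: str
    spo2_pct: float
    sao2_pct: float
    haemoglobin_g_per_l: float
    sample_index: int

    def __post_init__(self) -> None:
        for name in ("spo2_pct", "sao2_pct"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        hb = self.haemoglobin_g_per_l
        if np.isfinite(hb) and hb <= 0:
            raise ValueError(f"haemoglobin_g_per_l={hb} must be positive")


def _validate_observations(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(OBSERVATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    problems = []
    for col in ("spo2_pct", "sao2_pct"):
        v = df[col].to_numpy(float)
        bad = np.flatnonzero(~np.isfinite(v) | (v < 0) | (v > 100))
        problems += [f"row {i}: {col}={v[i]} outside [0, 100]" for i in bad]
    hb = df["haemoglobin_g_per_l"].to_numpy(float)
    bad = np.flatnonzero(np.isfinite(hb) & (hb <= 0))
    problems += [f"row {i}: haemoglobin_g_per_l={hb[i]} not positive"
                 for i in bad]
    dup = df.duplicated(["patient_id", "device_model", "sample_index"])
    problems += [f"row {i}: duplicate (patient_id, device_model, "
                 "sample_index)" for i in np.flatnonzero(dup.to_numpy())]
    if problems:
        head = "; ".join(problems[:10])
        raise ValueError(
            f"{len(problems)} invalid row(s): {head}"
            + ("; ..." if len(problems) > 10 else ""))
    n_missing_hb = int((~np.isfinite(hb)).sum())
    if n_missing_hb:
        warnings.warn(f"{n_missing_hb} row(s) with missing haemoglobin; "
                      "they will be dropped from adjusted models")
    return df


def read_observations(path: str | Path) -> pd.DataFrame:
    """Validated observation table from CSV."""
    df = pd.read_csv(path)
    return _validate_observations(df)


def write_observations(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def read_lab_readings(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(READING_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    l = df["l_star"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(l) | (l < 0) | (l > 100))
    if len(bad):
        raise ValueError(f"invalid l_star at rows {bad[:10].tolist()}")
    return df


def read_skin_tones(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"patient_id", "ita_degrees"} - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    return df


def write_skin_tones(df: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in SKIN_TONE_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline settings (YAML-serialisable)."""

    out_dir: str = "results"
    observations: str | None = None      # None => simulate first
    readings: str | None = None
    seed: int = 20220601
    n_patients: int = 900
    n_sites: int = 24
    n_knots: int = 4
    n_quad: int = 15
    bootstrap_reps: int = 200
    std_sample_size: int | None = 500
    ita_grid_step: float = 2.0
    sao2_anchors: tuple[float, ...] = (88.0, 90.0, 92.0, 94.0, 96.0, 98.0)
    spo2_thresholds: tuple[float, ...] = (92.0, 94.0)
    verbose: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sao2_anchors" in raw:
            raw["sao2_anchors"] = tuple(raw["sao2_anchors"])
        if "spo2_thresholds" in raw:
            raw["spo2_thresholds"] = tuple(raw["spo2_thresholds"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["sao2_anchors"] = list(self.sao2_anchors)
        data["spo2_thresholds"] = list(self.spo2_thresholds)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in outputs."""
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]
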