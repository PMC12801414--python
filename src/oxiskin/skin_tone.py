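"""Individual typology angle (ITA) from spectrophotometer CIELAB readings.

ITA is an objective, continuous measure of constitutive skin tone derived
from the CIE L* (lightness) and b* (blue-yellow) coordinates measured by a
handheld spectrophotometer:

    ITA = atan2(L* - 50, b*) * 180 / pi   (degrees)

Lower (more negative) angles correspond to darker skin.  The a* coordinate
(erythema / cutaneous blood flow) is recorded and carried through but never
enters the angle.  Each patient contributes several readings (four in the
intended protocol); the patient-level ITA uses the median L* and median b*
across readings, and the dispersion of the per-reading angles gives a
within-patient standard error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LabReading",
    "SkinTone",
    "ITA_CATEGORIES",
    "compute_ita",
    "categorize_ita",
    "aggregate_readings",
    "skin_tone_table",
]

#: Category boundaries in degrees, descending.  Each category includes its
#: lower bound: very_light >=55, light [41,55), intermediate [28,41),
#: tan [10,28), brown [-30,10), dark <-30.
ITA_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("very_light", 55.0),
    ("light", 41.0),
    ("intermediate", 28.0),
    ("tan", 10.0),
    ("brown", -30.0),
    ("dark", -np.inf),
)


@dataclass(frozen=True)
class LabReading:
    """One spectrophotometer measurement in CIELAB coordinates."""

    l_star: float
    a_star: float
    b_star: float

    def __post_init__(self) -> None:
        for name in ("l_star", "a_star", "b_star"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.l_star <= 100.0:
            raise ValueError(f"l_star must lie in [0, 100], got {self.l_star}")


@dataclass(frozen=True)
class SkinTone:
    """Per-patient aggregated skin tone."""

    patient_id: str
    ita_degrees: float
    category: str
    n_readings: int
    ita_se_degrees: float


def compute_ita(l_star, b_star):
    """Individual typology angle in degrees.

    Uses the two-argument arctangent so the angle remains defined when
    b* <= 0 (range (-180, 180]); on the physiological domain b* > 0 this
    coincides with arctan((L* - 50) / b*) * 180 / pi.  Accepts scalars or
    arrays.
    """
    l_star = np.asarray(l_star, dtype=float)
    b_star = np.asarray(b_star, dtype=float)
    if not (np.all(np.isfinite(l_star)) and np.all(np.isfinite(b_star))):
        raise ValueError("L* and b* must be finite")
    ita = np.degrees(np.arctan2(l_star - 50.0, b_star))
    return float(ita) if ita.ndim == 0 else ita


def categorize_ita(ita_degrees):
    """Map ITA in degrees to its skin-tone category label.

    Scalar in, scalar out; array in, object array out.  Boundaries are
    inclusive on the lower side of each category.
    """
    ita = np.atleast_1d(np.asarray(ita_degrees, dtype=float))
    scalar = np.ndim(ita_degrees) == 0
    if not np.all(np.isfinite(ita)):
        raise ValueError("ITA must be finite")
    out = np.empty(ita.shape, dtype=object)
    out[:] = None
    remaining = np.ones(ita.shape, dtype=bool)
    for label, lower in ITA_CATEGORIES:
        pick = remaining & (ita >= lower)
        out[pick] = label
        remaining &= ~pick
    if scalar:
        return str(out[0])
    return out


def aggregate_readings(readings: Sequence[LabReading] | Iterable[LabReading],
                       patient_id: str) -> SkinTone:
    """Aggregate a patient's readings to a single :class:`SkinTone`.

    The angle is computed from the median L* and median b* (median of the
    components, then the angle — not the median of per-reading angles).
    ``ita_se_degrees`` is the sample standard deviation of the per-reading
    angles divided by sqrt(n), zero when n == 1.
    """
    readings = list(readings)
    if not readings:
        raise ValueError("at least one reading is required")
    l = np.array([r.l_star for r in readings])
    b = np.array([r.b_star for r in readings])
    ita = compute_ita(np.median(l), np.median(b))
    per_reading = compute_ita(l, b)
    n = len(readings)
    se = 0.0 if n == 1 else float(np.std(per_reading, ddof=1) / np.sqrt(n))
    return SkinTone(
        patient_id=str(patient_id),
        ita_degrees=ita,
        category=categorize_ita(ita),
        n_readings=n,
        ita_se_degrees=se,
    )


def skin_tone_table(readings: pd.DataFrame) -> pd.DataFrame:
    """Per-patient skin-tone table from a long table of readings.

    Parameters
    ----------
    readings
        Columns ``patient_id``, ``l_star``, ``a_star``, ``b_star`` (one row
        per reading; a ``reading_index`` column is permitted and ignored).

    Returns
    -------
    DataFrame with columns ``patient_id``, ``ita_degrees``, ``category``,
    ``n_readings``, ``ita_se_degrees``, one row per patient.
    """
    required = {"patient_id", "l_star", "b_star"}
    missing = required - set(readings.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in readings.groupby("patient_id", sort=True):
        tone = aggregate_readings(
            [LabReading(r.l_star, getattr(r, "a_star", 0.0), r.b_star)
             for r in grp.itertuples()],
            patient_id=pid,
        )
        rows.append(tone.__dict__)
    return pd.DataFrame(rows)
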