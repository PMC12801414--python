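"""Design-matrix construction for the accuracy model suite.

All seven metric models share one covariate structure: pulse-oximeter model
(categorical), ITA, SaO2 and haemoglobin as restricted cubic splines,
device x ITA and device x SaO2 interactions, an ITA x SaO2 interaction
(tensor product of the two restricted bases), and site fixed effects.
The ROC regression uses a reduced structure (device, ITA, device x ITA).

`DesignSpec` declares which blocks enter; `DesignSpec.fit` resolves knots
and factor levels on the estimation data and returns a `FittedDesign` whose
`build` produces a named-column matrix for any data frame with the same
columns (including standardisation grids).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .splines import SplineBasis

__all__ = ["DesignSpec", "FittedDesign"]

ITA_COL = "ita_degrees"
SAO2_COL = "sao2_pct"
HB_COL = "haemoglobin_g_per_l"
DEVICE_COL = "device_model"
SITE_COL = "site_id"


@dataclass(frozen=True)
class DesignSpec:
    """Which covariate blocks enter the linear predictor."""

    ita: str = "rcs"            # "rcs" | "linear" | "none"
    sao2: str = "rcs"           # "rcs" | "linear" | "none"
    haemoglobin: str = "rcs"    # "rcs" | "linear" | "none"
    device: bool = True
    device_by_ita: bool = True
    device_by_sao2: bool = True
    ita_by_sao2: bool = True
    site_effects: bool = True
    n_knots: int = 4
    #: explicit knot locations per column (overrides the quantile default);
    #: useful when the clinically relevant range lies in a thin data tail.
    knots: tuple[tuple[str, tuple[float, ...]], ...] = ()

    def fit(self, df: pd.DataFrame) -> "FittedDesign":
        explicit = {col: np.asarray(k, dtype=float) for col, k in self.knots}
        bases: dict[str, SplineBasis] = {}
        for col, mode in ((ITA_COL, self.ita), (SAO2_COL, self.sao2),
                          (HB_COL, self.haemoglobin)):
            if mode == "rcs":
                bases[col] = (SplineBasis(explicit[col])
                              if col in explicit else SplineBasis.from_data(
                                  df[col].to_numpy(float), self.n_knots))
            elif mode not in ("linear", "none"):
                raise ValueError(f"unknown term mode {mode!r} for {col}")
        device_levels = (sorted(df[DEVICE_COL].astype(str).unique())
                         if self.device else [])
        site_levels = (sorted(df[SITE_COL].astype(str).unique())
                       if self.site_effects else [])
        ranges = {col: (float(df[col].min()), float(df[col].max()))
                  for col in (ITA_COL, SAO2_COL)
                  if col in df and getattr(self, _MODE_ATTR[col]) != "none"}
        return FittedDesign(spec=self, bases=bases,
                            device_levels=device_levels,
                            site_levels=site_levels, ranges=ranges)


_MODE_ATTR = {ITA_COL: "ita", SAO2_COL: "sao2", HB_COL: "haemoglobin"}


@dataclass(frozen=True)
class FittedDesign:
    spec: DesignSpec
    bases: dict[str, SplineBasis]
    device_levels: list[str]
    site_levels: list[str]
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def _continuous_block(self, df: pd.DataFrame, col: str,
                          short: str) -> tuple[np.ndarray, list[str]]:
        mode = getattr(self.spec, _MODE_ATTR[col])
        x = df[col].to_numpy(float)
        if mode == "linear":
            return x[:, None], [short]
        basis = self.bases[col]
        mat = basis.transform(x)
        names = [short] + [short + "'" * (j + 1)
                           for j in range(mat.shape[1] - 1)]
        # e.g. ita, ita', ita'' for the nonlinear restricted terms
        return mat, names

    def build(self, df: pd.DataFrame) -> pd.DataFrame:
        """Named-column model matrix (includes the constant)."""
        n = len(df)
        cols: dict[str, np.ndarray] = {"const": np.ones(n)}

        dev_dummies: dict[str, np.ndarray] = {}
        if self.spec.device and self.device_levels:
            dev = df[DEVICE_COL].astype(str).to_numpy()
            unknown = set(dev) - set(self.device_levels)
            if unknown:
                raise ValueError(f"unknown device level(s): {sorted(unknown)}")
            for lev in self.device_levels[1:]:
                dev_dummies[lev] = (dev == lev).astype(float)
                cols[f"device[{lev}]"] = dev_dummies[lev]

        blocks: dict[str, tuple[np.ndarray, list[str]]] = {}
        for col, short in ((ITA_COL, "ita"), (SAO2_COL, "sao2"),
                           (HB_COL, "hb")):
            if getattr(self.spec, _MODE_ATTR[col]) != "none":
                mat, names = self._continuous_block(df, col, short)
                blocks[short] = (mat, names)
                for j, name in enumerate(names):
                    cols[name] = mat[:, j]

        for flag, short in ((self.spec.device_by_ita, "ita"),
                            (self.spec.device_by_sao2, "sao2")):
            if flag and short in blocks and dev_dummies:
                mat, names = blocks[short]
                for lev, d in dev_dummies.items():
                    for j, name in enumerate(names):
                        cols[f"device[{lev}]:{name}"] = d * mat[:, j]

        if self.spec.ita_by_sao2 and "ita" in blocks and "sao2" in blocks:
            imat, inames = blocks["ita"]
            smat, snames = blocks["sao2"]
            for i, iname in enumerate(inames):
                for j, sname in enumerate(snames):
                    cols[f"{iname}:{sname}"] = imat[:, i] * smat[:, j]

        if self.spec.site_effects and self.site_levels:
            site = df[SITE_COL].astype(str).to_numpy()
            for lev in self.site_levels[1:]:
                cols[f"site[{lev}]"] = (site == lev).astype(float)

        return pd.DataFrame(cols, index=df.index)

    def flag_extrapolation(self, df: pd.DataFrame) -> pd.Series:
        """True where ITA or SaO2 falls outside the fitted range."""
        out = pd.Series(False, index=df.index)
        for col, (lo, hi) in self.ranges.items():
            if col in df:
                x = df[col].to_numpy(float)
                out |= (x < lo) | (x > hi)
        return out
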