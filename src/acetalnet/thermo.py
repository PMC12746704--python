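"""Van't Hoff thermodynamics of sugar tautomer equilibria.

The equilibrium constant of a tautomer pair measured over a temperature
series obeys ln K = -dH/(R T) + dS/R; ordinary least squares of ln K on 1/T
yields the apparent standard reaction enthalpy (slope * -R) and entropy
(intercept * R) together with their standard errors.  For d-xylose in
dioxane/water the pyranose -> furanose conversion is endothermic and
entropy-driven (dH ~ 11.3 kJ/mol, dS ~ 13.6 J/(K mol)), so the furanose
share grows with temperature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import R_J, R_KJ

__all__ = [
    "EquilibriumSeries",
    "VantHoffModel",
    "VantHoffResults",
    "vant_hoff_fit",
    "two_point_solve",
    "delta_g_at",
    "tautomer_fractions",
    "ratios_from_peak_areas",
]


@dataclass(frozen=True)
class EquilibriumSeries:
    """Temperature series of equilibrium constants for one tautomer pair."""

    temperatures: np.ndarray  # K, strictly increasing
    k_values: np.ndarray      # dimensionless, > 0
    pair: str = "pyranose->furanose"

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        k = np.asarray(self.k_values, dtype=float)
        if t.shape != k.shape or t.ndim != 1:
            raise ValueError("temperatures and k_values must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")
        if np.any(k <= 0):
            raise ValueError("all equilibrium constants must be positive")
        object.__setattr__(self, "temperatures", t)
        object.__setattr__(self, "k_values", k)

    def __len__(self):
        return len(self.temperatures)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "temperature_K": self.temperatures,
            "temperature_C": self.temperatures - 273.15,
            "K": self.k_values,
        })

    def to_tsv(self, path) -> None:
        df = self.to_frame()[["temperature_C", "K"]]
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, pair: str = "pyranose->furanose") -> "EquilibriumSeries":
        df = pd.read_csv(path, sep="\t")
        if "temperature_K" in df.columns:
            t = df["temperature_K"].to_numpy(float)
        elif "temperature_C" in df.columns:
            t = df["temperature_C"].to_numpy(float) + 273.15
        else:
            raise ValueError(f"{path}: need a temperature_C or temperature_K column")
        order = np.argsort(t)
        return cls(t[order], df["K"].to_numpy(float)[order], pair=pair)


class VantHoffModel:
    """Linear van't Hoff model for a tautomer equilibrium series.

    Examples
    --------
    >>> series = EquilibriumSeries([293.15, 333.15, 373.15], [0.4, 0.55, 0.7])
    >>> res = VantHoffModel(series).fit()
    >>> res.dh, res.ds  # doctest: +SKIP
    """

    def __init__(self, series: EquilibriumSeries):
        self.series = series
        self._x = 1.0 / series.temperatures
        self._y = np.log(series.k_values)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, temperature: str = "temperature_C",
                       k: str = "K", celsius: bool = True,
                       pair: str = "pyranose->furanose") -> "VantHoffModel":
        t = df[temperature].to_numpy(float) + (273.15 if celsius else 0.0)
        order = np.argsort(t)
        return cls(EquilibriumSeries(t[order], df[k].to_numpy(float)[order], pair=pair))

    def fit(self) -> "VantHoffResults":
        """OLS of ln K on 1/T; needs at least 3 points for standard errors."""
        if len(self.series) < 3:
            raise ValueError(
                "van't Hoff fit requires >= 3 temperatures; "
                "use two_point_solve for an exactly determined pair"
            )
        exog = sm.add_constant(self._x)
        ols = sm.OLS(self._y, exog).fit()
        intercept, slope = ols.params
        se_int, se_slope = ols.bse
        return VantHoffResults(
            dh=-slope * R_J / 1000.0,
            ds=intercept * R_J,
            se_dh=se_slope * R_J / 1000.0,
            se_ds=se_int * R_J,
            r_squared=float(ols.rsquared),
            nobs=len(self.series),
            pair=self.series.pair,
            model=self,
        )


@dataclass
class VantHoffResults:
    """Fitted apparent reaction enthalpy/entropy with uncertainties.

    dh in kJ/mol, ds in J/(K mol); standard errors propagated from the
    regression (se(dH) = R * se(slope), se(dS) = R * se(intercept)).
    """

    dh: float
    ds: float
    se_dh: float
    se_ds: float
    r_squared: float
    nobs: int
    pair: str = "pyranose->furanose"
    model: VantHoffModel | None = None

    def delta_g(self, T: float) -> float:
        return delta_g_at(self.dh, self.ds, T)

    def predict_k(self, T) -> np.ndarray:
        T = np.asarray(T, dtype=float)
        return np.exp(-self.dh * 1000.0 / (R_J * T) + self.ds / R_J)

    def conf_int(self, z: float = 1.0) -> dict[str, tuple[float, float]]:
        """Symmetric +-z*se intervals (z=1: the 68% band)."""
        return {
            "dh": (self.dh - z * self.se_dh, self.dh + z * self.se_dh),
            "ds": (self.ds - z * self.se_ds, self.ds + z * self.se_ds),
        }

    def summary(self) -> str:
        lines = [
            "Van't Hoff fit" + (f" [{self.pair}]" if self.pair else ""),
            "=" * 46,
            f"{'n temperatures':<24s}{self.nobs:>10d}",
            f"{'dH (kJ/mol)':<24s}{self.dh:>10.3f}  +/- {self.se_dh:.3f}",
            f"{'dS (J/(K mol))':<24s}{self.ds:>10.3f}  +/- {self.se_ds:.3f}",
            f"{'R^2':<24s}{self.r_squared:>10.4f}",
            f"{'dG(333.15 K) (kJ/mol)':<24s}{self.delta_g(333.15):>10.1f}",
        ]
        return "\n".join(lines)


def vant_hoff_fit(series: EquilibriumSeries) -> VantHoffResults:
    """Functional wrapper over ``VantHoffModel(series).fit()``."""
    return VantHoffModel(series).fit()


def two_point_solve(t1: float, k1: float, t2: float, k2: float) -> tuple[float, float]:
    """Exactly determined (dH, dS) from two (T, K) points — the 2x2 solve.

    Returns (dH kJ/mol, dS J/(K mol)); no uncertainties are defined.
    """
    if t1 == t2:
        raise ValueError("the two temperatures must differ")
    if k1 <= 0 or k2 <= 0:
        raise ValueError("equilibrium constants must be positive")
    slope = (np.log(k2) - np.log(k1)) / (1.0 / t2 - 1.0 / t1)
    intercept = np.log(k1) - slope / t1
    return (-slope * R_J / 1000.0, intercept * R_J)


def delta_g_at(dh: float, ds: float, T: float) -> float:
    """dG = dH - T*dS in kJ/mol (dH kJ/mol, dS J/(K mol))."""
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return dh - T * ds / 1000.0


def tautomer_fractions(dg_list, T: float) -> np.ndarray:
    """Boltzmann fractions of tautomers from their dG relative to a reference.

    fraction_i = exp(-dG_i/RT) / sum_j exp(-dG_j/RT); the reference tautomer
    carries dG = 0.  Always sums to 1.
    """
    dg = np.asarray(list(dg_list), dtype=float)
    if dg.size == 0:
        raise ValueError("need at least one tautomer")
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    w = np.exp(-(dg - dg.min()) / (R_KJ * T))
    return w / w.sum()


def ratios_from_peak_areas(
    area_table: pd.DataFrame,
    numerator,
    denominator,
    pair: str | None = None,
) -> EquilibriumSeries:
    """Equilibrium constants K = sum(numerator areas)/sum(denominator areas)
    per temperature from a long-form NMR peak-area table.

    ``area_table`` has columns temperature_C (or temperature_K), tautomer and
    peak_area; ``numerator``/``denominator`` are tautomer label collections
    (e.g. the two furanose anomers over the two pyranose anomers; the
    open-chain form is excluded from both sides).  Temperatures whose
    denominator integrates to zero are dropped with a warning; a temperature
    where every area is zero raises.
    """
    df = area_table.copy()
    if "temperature_K" not in df.columns:
        df["temperature_K"] = df["temperature_C"] + 273.15
    if (df["peak_area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    numerator = set(numerator)
    denominator = set(denominator)

    temps, ks = [], []
    for t_k, grp in df.groupby("temperature_K", sort=True):
        areas = grp.groupby("tautomer")["peak_area"].sum()
        if areas.sum() == 0:
            raise ValueError(f"all peak areas are zero at T = {t_k} K")
        num = areas.reindex(numerator, fill_value=0.0).sum()
        den = areas.reindex(denominator, fill_value=0.0).sum()
        if den == 0 or num == 0:
            warnings.warn(
                f"dropping T = {t_k} K: zero integrated area on one side of the ratio",
                stacklevel=2,
            )
            continue
        temps.append(t_k)
        ks.append(num / den)
    label = pair or f"{'+'.join(sorted(numerator))}/{'+'.join(sorted(denominator))}"
    return EquilibriumSeries(np.asarray(temps), np.asarray(ks), pair=label)
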