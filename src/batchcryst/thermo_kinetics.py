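"""Solubility, supersaturation, and crystallization rate laws for α-LGA in water.

The equilibrium mole fraction of the α polymorph of l-glutamic acid (LGA) in
water is represented by a quadratic polynomial in temperature.  Supersaturation
is expressed as the ratio ``S = C / C*`` of the solute mole fraction to the
equilibrium mole fraction at the same temperature, and the relative
supersaturation ``σ = S − 1`` drives primary nucleation and crystal growth
through power laws::

    ṅ0 = kN · σ**n        [#/m³·s]   (rate of birth of smallest crystals)
    G  = kG · σ**g        [m/s]      (rate of change of equivalent diameter)

Both laws return exactly zero for σ ≤ 0: dissolution is not modelled.

The module also provides the inverse solubility map (saturation temperature)
and ordinary least-squares estimation of ``(kG, g)`` from measured
(σ, G) pairs in log–log coordinates.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TempConvention",
    "SolubilityPolynomial",
    "SupersaturationState",
    "KineticRateParams",
    "GrowthRateDataset",
    "GrowthFit",
    "solubility",
    "supersaturation",
    "saturation_temperature",
    "nucleation_rate",
    "growth_rate_linear",
    "fit_growth_power_law",
    "mole_fraction_from_loading",
    "TAI_SHEI",
    "PENCHEV",
    "M_LGA",
    "M_WATER",
    "RHO_ALPHA_LGA",
]

#: Molar mass of l-glutamic acid [kg/mol] (literature value).
M_LGA = 147.13e-3
#: Molar mass of water [kg/mol].
M_WATER = 18.015e-3
#: Crystal density of the α polymorph of LGA [kg/m³] (literature value).
RHO_ALPHA_LGA = 1540.0

#: Default temperature validity window for the solubility polynomial [°C].
DEFAULT_VALIDITY_WINDOW = (10.0, 80.0)


class TempConvention(str, enum.Enum):
    """Unit convention for the temperature entering the solubility polynomial.

    The published polynomial is stated with T "in degree Celsius", but with
    Celsius the curve decreases with temperature over the operating range,
    which is unphysical for LGA (cooling could then never supersaturate the
    solution).  With the temperature taken as absolute (Kelvin) the curve is
    increasing on the operating range and reproduces the reported
    supersaturation levels (S ≈ 1.56 for 43 g/kg-water at 45 °C), so
    ``ABSOLUTE_KELVIN`` is the default throughout the package.
    ``CELSIUS_AS_PRINTED`` remains selectable for literal reproduction.
    """

    CELSIUS_AS_PRINTED = "celsius_as_printed"
    ABSOLUTE_KELVIN = "absolute_kelvin"


@dataclass(frozen=True)
class SolubilityPolynomial:
    """Quadratic solubility model ``C*(T) = a0 − a1·T′ + a2·T′²``.

    ``T′`` is the input temperature in °C transformed according to
    ``temp_convention`` (identity, or +273.15 for the Kelvin convention).
    ``C*`` is a mole fraction (mol LGA / mol solution).
    """

    a0: float = 0.08131
    a1: float = 0.000595783
    a2: float = 1.10258e-6
    temp_convention: TempConvention = TempConvention.ABSOLUTE_KELVIN

    def transformed_temperature(self, T_celsius):
        """Map a temperature in °C onto the polynomial's internal scale."""
        T = np.asarray(T_celsius, dtype=float)
        if self.temp_convention is TempConvention.ABSOLUTE_KELVIN:
            return T + 273.15
        return T

    def __call__(self, T_celsius):
        Tp = self.transformed_temperature(T_celsius)
        return self.a0 - self.a1 * Tp + self.a2 * Tp**2


def solubility(
    T_celsius,
    model: SolubilityPolynomial,
    validity_window: tuple[float, float] = DEFAULT_VALIDITY_WINDOW,
):
    """Equilibrium mole fraction of LGA at temperature ``T_celsius`` [°C].

    A temperature outside ``validity_window`` triggers a warning (the
    polynomial is an empirical fit), while a non-positive result raises
    ``ValueError`` naming the offending temperature.
    """
    T = np.asarray(T_celsius, dtype=float)
    lo, hi = validity_window
    if np.any(T < lo) or np.any(T > hi):
        warnings.warn(
            f"temperature outside the solubility validity window "
            f"[{lo}, {hi}] °C; extrapolating the polynomial",
            stacklevel=2,
        )
    cstar = model(T)
    if np.any(cstar <= 0.0):
        bad = np.atleast_1d(T)[np.atleast_1d(cstar) <= 0.0]
        raise ValueError(
            f"solubility polynomial is non-positive at T = {bad.tolist()} °C"
        )
    return cstar if np.ndim(T_celsius) else float(cstar)


@dataclass(frozen=True)
class SupersaturationState:
    """Solution state at one instant: composition, temperature, driving force.

    Attributes
    ----------
    C : solute mole fraction (mol LGA / mol solution)
    T : temperature [°C]
    Cstar : equilibrium mole fraction at ``T``
    S : supersaturation ratio ``C / Cstar``
    sigma : relative supersaturation ``S − 1`` (negative when undersaturated)
    """

    C: float
    T: float
    Cstar: float
    S: float = field(init=False)
    sigma: float = field(init=False)

    def __post_init__(self):
        if self.C < 0.0:
            raise ValueError(f"negative solute mole fraction: {self.C}")
        if self.Cstar <= 0.0:
            raise ValueError(f"non-positive equilibrium mole fraction: {self.Cstar}")
        object.__setattr__(self, "S", self.C / self.Cstar)
        object.__setattr__(self, "sigma", self.S - 1.0)


def supersaturation(
    C: float,
    T_celsius: float,
    model: SolubilityPolynomial,
    validity_window: tuple[float, float] = DEFAULT_VALIDITY_WINDOW,
) -> SupersaturationState:
    """Evaluate the supersaturation state ``(S, σ)`` at ``(C, T)``."""
    cstar = solubility(T_celsius, model, validity_window)
    return SupersaturationState(C=float(C), T=float(T_celsius), Cstar=float(cstar))


def saturation_temperature(
    C: float,
    model: SolubilityPolynomial,
    validity_window: tuple[float, float] = DEFAULT_VALIDITY_WINDOW,
) -> float:
    """Temperature [°C] at which ``C`` equals the equilibrium mole fraction.

    Solves ``a2·T′² − a1·T′ + (a0 − C) = 0`` and returns the real root that
    falls inside the validity window, converted back to °C.  Raises
    ``ValueError`` when no real root lies in the window (e.g. ``C`` above the
    maximum solubility of the window).
    """
    a2, a1, a0 = model.a2, model.a1, model.a0
    disc = a1 * a1 - 4.0 * a2 * (a0 - C)
    if disc < 0.0:
        raise ValueError(f"no real saturation temperature for C = {C}")
    roots_tp = np.array([(a1 - np.sqrt(disc)) / (2 * a2), (a1 + np.sqrt(disc)) / (2 * a2)])
    if model.temp_convention is TempConvention.ABSOLUTE_KELVIN:
        roots_c = roots_tp - 273.15
    else:
        roots_c = roots_tp
    lo, hi = validity_window
    inside = [t for t in roots_c if lo - 1e-9 <= t <= hi + 1e-9]
    if not inside:
        raise ValueError(
            f"no saturation temperature in [{lo}, {hi}] °C for C = {C} "
            f"(roots at {roots_c.tolist()} °C)"
        )
    return float(min(inside, key=lambda t: abs(t - 0.5 * (lo + hi))))


@dataclass(frozen=True)
class KineticRateParams:
    """Power-law rate constants for primary nucleation and crystal growth.

    ``kN`` [#/m³·s] and ``n`` parameterize the nucleation law, ``kG`` [m/s]
    and ``g`` the linear growth law.  ``source`` is a free-text provenance
    label carried through reports.
    """

    kN: float
    n: float
    kG: float
    g: float
    source: str = ""

    def __post_init__(self):
        if self.kN < 0 or self.kG < 0:
            raise ValueError("rate constants must be non-negative")
        if self.n <= 0 or self.g <= 0:
            raise ValueError("rate exponents must be positive")


#: Kinetics estimated from 6 L crash-cooling experiments (600 rpm);
#: the paper-trail label used for simulation Runs 1 and 3.
TAI_SHEI = KineticRateParams(kN=4.02e6, n=1.87, kG=9.76e-8, g=2.34, source="Tai-Shei")

#: Growth kinetics refitted from 20 L slow-cooling data (100 rpm) combined
#: with the same nucleation law; used for simulation Runs 2 and 4.
PENCHEV = KineticRateParams(kN=4.02e6, n=1.87, kG=2.80e-7, g=1.43, source="Penchev")


def nucleation_rate(sigma, params: KineticRateParams):
    """Primary nucleation rate ``kN·σⁿ`` [#/m³·s]; zero for σ ≤ 0."""
    s = np.asarray(sigma, dtype=float)
    out = np.where(s > 0.0, params.kN * np.maximum(s, 0.0) ** params.n, 0.0)
    return out if np.ndim(sigma) else float(out)


def growth_rate_linear(sigma, params: KineticRateParams):
    """Linear growth rate ``kG·σ^g`` [m/s] of the volume-equivalent diameter.

    Zero for σ ≤ 0 — dissolution of existing crystals is not modelled.
    """
    s = np.asarray(sigma, dtype=float)
    out = np.where(s > 0.0, params.kG * np.maximum(s, 0.0) ** params.g, 0.0)
    return out if np.ndim(sigma) else float(out)


@dataclass
class GrowthRateDataset:
    """Measured (relative supersaturation, linear growth rate) pairs."""

    sigma: np.ndarray
    G: np.ndarray

    def __post_init__(self):
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.sigma.shape != self.G.shape or self.sigma.ndim != 1:
            raise ValueError("sigma and G must be 1-D arrays of equal length")
        if np.any(self.sigma <= 0.0) or np.any(self.G <= 0.0):
            raise ValueError("log-log fitting requires sigma > 0 and G > 0")

    def __len__(self) -> int:
        return self.sigma.size

    @classmethod
    def from_records(cls, records: Sequence[tuple[float, float]]) -> "GrowthRateDataset":
        arr = np.asarray(records, dtype=float).reshape(-1, 2)
        return cls(sigma=arr[:, 0], G=arr[:, 1])

    @classmethod
    def from_csv(cls, path: str | Path) -> "GrowthRateDataset":
        import pandas as pd

        df = pd.read_csv(path)
        expected = ["sigma", "G_m_per_s"]
        if list(df.columns) != expected:
            raise ValueError(f"expected columns {expected}, got {list(df.columns)}")
        return cls(sigma=df["sigma"].to_numpy(), G=df["G_m_per_s"].to_numpy())

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame({"sigma": self.sigma, "G_m_per_s": self.G}).to_csv(path, index=False)


@dataclass(frozen=True)
class GrowthFit:
    """Result of the log-log OLS fit of the growth power law."""

    kG: float
    g: float
    se_kG: float  # delta-method standard error, kG·se(ln kG)
    se_g: float
    se_log_kG: float
    r_squared: float

    def as_params(self, kN: float = 0.0, n: float = 1.0, source: str = "fitted") -> KineticRateParams:
        return KineticRateParams(kN=kN, n=n, kG=self.kG, g=self.g, source=source)


def fit_growth_power_law(data: GrowthRateDataset) -> GrowthFit:
    """Estimate ``(kG, g)`` by ordinary least squares on ``ln G`` vs ``ln σ``.

    Returns point estimates with standard errors for both the exponent and
    the rate constant (the latter via the delta method from the intercept's
    standard error).  At least three records are required.
    """
    if len(data) < 3:
        raise ValueError("growth power-law fit requires at least 3 records")
    res = stats.linregress(np.log(data.sigma), np.log(data.G))
    kG = float(np.exp(res.intercept))
    return GrowthFit(
        kG=kG,
        g=float(res.slope),
        se_kG=kG * float(res.intercept_stderr),
        se_g=float(res.stderr),
        se_log_kG=float(res.intercept_stderr),
        r_squared=float(res.rvalue**2),
    )


def mole_fraction_from_loading(
    grams_solute_per_kg_water: float,
    M_solute: float = M_LGA,
    M_solvent: float = M_WATER,
) -> float:
    """Convert a solute loading [g per 1000 g water] to a mole fraction."""
    n_solute = grams_solute_per_kg_water / 1000.0 / M_solute
    n_water = 1.0 / M_solvent
    return n_solute / (n_solute + n_water)
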