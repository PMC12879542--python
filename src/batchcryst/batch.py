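"""Well-mixed batch cooling crystallization integrator.

Couples the discrete-method population balance (growth transfer + nucleation
source) to a lumped solute mole balance and an imposed cooling schedule.  The
state vector is ``[x, α_0 … α_{n−1}]`` where ``x`` is the solute mole fraction
and ``α_i`` the per-bin crystal volume fractions; solute consumption follows
from the solid volume production::

    dn_L/dt = −(ρ_s · V_soln / M_LGA) · dφ_T/dt,      φ_T = Σ α_i

on a fixed water basis (moles of water constant, solution volume treated as
constant — the slurry stays below ~3% solids).  Temperature follows the
schedule exactly; crystallization enthalpy is neglected.

The stiff onset of nucleation is handled by adaptive-step integration
(LSODA by default) with a tight relative tolerance and per-bin absolute
tolerances; a terminal mass-balance audit verifies solute + crystal
conservation on every run.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .pbe import (
    CrystalPopulation,
    GeometricVolumeGrid,
    growth_rates,
    nucleation_rates,
    sauter_mean_diameter,
)
from .thermo_kinetics import (
    M_LGA,
    M_WATER,
    RHO_ALPHA_LGA,
    KineticRateParams,
    SolubilityPolynomial,
    growth_rate_linear,
    mole_fraction_from_loading,
    nucleation_rate,
)

__all__ = [
    "ScheduleMode",
    "ProcessSchedule",
    "SolutionBasis",
    "SolverOptions",
    "BatchTrajectory",
    "OnsetResult",
    "simulate_batch",
    "mass_balance_audit",
    "detect_onset",
    "mszw",
    "peak_supersaturation",
    "desupersaturation_time",
]


class ScheduleMode(str, enum.Enum):
    IMPOSED_RAMP = "imposed_ramp"
    JACKET_FLUX = "jacket_flux"


@dataclass(frozen=True)
class ProcessSchedule:
    """Cooling schedule from ``T0`` to ``T_final`` [°C].

    ``imposed_ramp`` imposes a linear ramp at ``cooling_rate`` [K/min]
    followed by a hold at ``T_final``.  ``jacket_flux`` derives the
    (constant) ramp rate from a constant wall heat flux,
    ``dT/dt = −heat_flux·wetted_area/thermal_mass``; the caller must supply
    the wetted area [m²] and lumped thermal mass [J/K].
    """

    T0: float = 70.0
    T_final: float = 20.0
    cooling_rate: float = 0.6  # K/min, imposed_ramp mode
    mode: ScheduleMode = ScheduleMode.IMPOSED_RAMP
    heat_flux: Optional[float] = None  # W/m², jacket_flux mode
    wetted_area: Optional[float] = None  # m²
    thermal_mass: Optional[float] = None  # J/K

    def __post_init__(self):
        if self.T0 <= self.T_final:
            raise ValueError("T0 must exceed T_final for a cooling schedule")
        if self.mode is ScheduleMode.IMPOSED_RAMP:
            if self.cooling_rate <= 0.0:
                raise ValueError("cooling_rate must be positive")
        else:
            missing = [
                name
                for name in ("heat_flux", "wetted_area", "thermal_mass")
                if getattr(self, name) is None
            ]
            if missing:
                raise ValueError(f"jacket_flux schedule requires {missing}")
            if self.heat_flux <= 0 or self.wetted_area <= 0 or self.thermal_mass <= 0:
                raise ValueError("jacket_flux parameters must be positive")

    @property
    def rate_K_per_s(self) -> float:
        if self.mode is ScheduleMode.IMPOSED_RAMP:
            return self.cooling_rate / 60.0
        return self.heat_flux * self.wetted_area / self.thermal_mass

    @property
    def ramp_duration(self) -> float:
        """Seconds to reach ``T_final``."""
        return (self.T0 - self.T_final) / self.rate_K_per_s

    def temperature(self, t):
        """Temperature [°C] at time ``t`` [s] (held at ``T_final`` after the ramp)."""
        T = self.T0 - self.rate_K_per_s * np.asarray(t, dtype=float)
        T = np.maximum(T, self.T_final)
        return T if np.ndim(t) else float(T)


@dataclass(frozen=True)
class SolutionBasis:
    """Fixed solvent basis converting between mole fraction and amounts.

    The basis is ``mass_water`` kg of water; the solution volume is treated
    as constant throughout the batch (dilute slurry).  ``initial_loading`` is
    the solute charge in g per 1000 g water used to set the default starting
    composition.
    """

    mass_water: float = 1.0  # kg
    M_solute: float = M_LGA  # kg/mol
    M_solvent: float = M_WATER  # kg/mol
    solution_volume: float = 1.043e-3  # m³ (1 kg water + 43 g LGA at ~1000 kg/m³)
    initial_loading: float = 43.0  # g solute / 1000 g water

    @classmethod
    def from_loading(
        cls,
        grams_per_kg_water: float = 43.0,
        mass_water: float = 1.0,
        rho_solution: float = 1000.0,
    ) -> "SolutionBasis":
        mass_solution = mass_water * (1.0 + grams_per_kg_water / 1000.0)
        return cls(
            mass_water=mass_water,
            solution_volume=mass_solution / rho_solution,
            initial_loading=grams_per_kg_water,
        )

    @property
    def moles_water(self) -> float:
        return self.mass_water / self.M_solvent

    @property
    def C0(self) -> float:
        """Initial solute mole fraction from the loading."""
        return mole_fraction_from_loading(
            self.initial_loading, self.M_solute, self.M_solvent
        )

    def moles_solute(self, x: float) -> float:
        """Moles of dissolved solute at mole fraction ``x``."""
        return x / (1.0 - x) * self.moles_water


@dataclass(frozen=True)
class SolverOptions:
    method: str = "LSODA"
    rtol: float = 1e-8
    atol_C: float = 1e-14
    atol_alpha: float = 1e-16
    n_output: int = 1001


@dataclass
class BatchTrajectory:
    """Time series of the batch state on the output grid.

    All arrays share the leading time dimension; ``alpha`` has shape
    ``(n_times, n_bins)``.  ``d32`` is NaN while the vessel is crystal-free.
    """

    time: np.ndarray  # s
    T: np.ndarray  # °C
    C: np.ndarray  # mole fraction
    Cstar: np.ndarray
    S: np.ndarray
    sigma: np.ndarray
    alpha: np.ndarray
    phi_T: np.ndarray
    d32: np.ndarray  # m
    ndot0: np.ndarray  # #/m³·s
    G: np.ndarray  # m/s
    grid: GeometricVolumeGrid
    basis: SolutionBasis
    rho_s: float
    clipped_volume: float = 0.0  # |Σ α<0| removed by the non-negativity guard

    def final_population(self) -> CrystalPopulation:
        return CrystalPopulation(alpha=self.alpha[-1], rho_s=self.rho_s)

    def population_at(self, index: int) -> CrystalPopulation:
        return CrystalPopulation(alpha=self.alpha[index], rho_s=self.rho_s)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "time_s": self.time,
                "T_C": self.T,
                "C_molefrac": self.C,
                "Cstar_molefrac": self.Cstar,
                "S": self.S,
                "sigma": self.sigma,
                "phi_T": self.phi_T,
                "d32_m": self.d32,
                "ndot0_per_m3_s": self.ndot0,
                "G_m_per_s": self.G,
            }
        )
        for i in range(self.grid.n_bins):
            df[f"alpha_{i}"] = self.alpha[:, i]
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _rhs_factory(
    schedule: ProcessSchedule,
    kinetics: KineticRateParams,
    grid: GeometricVolumeGrid,
    solub: SolubilityPolynomial,
    basis: SolutionBasis,
    rho_s: float,
    nucleation_on: bool,
    sigma_override: Optional[float],
):
    n_w = basis.moles_water
    consumption_factor = rho_s * basis.solution_volume / basis.M_solute
    n_bins = grid.n_bins
    V = grid.V
    d = grid.d
    dV = np.diff(V)

    def rhs(t, y):
        x = y[0]
        if x < -1e-12:
            raise RuntimeError(f"negative solute mole fraction {x} at t={t}")
        alpha = np.maximum(y[1:], 0.0)
        T = schedule.temperature(t)
        cstar = solub(T)
        sigma = x / cstar - 1.0
        sig_eff = sigma if sigma_override is None else sigma_override
        G = growth_rate_linear(sig_eff, kinetics)
        ndot0 = nucleation_rate(sig_eff, kinetics) if nucleation_on else 0.0

        dalpha = np.zeros(n_bins)
        if G > 0.0:
            flux = (3.0 * V[:-1] / d[:-1] * G) * (alpha[:-1] / V[:-1]) / dV
            dalpha[:-1] -= V[:-1] * flux
            dalpha[1:] += V[1:] * flux
        dalpha[0] += grid.V0 * ndot0

        n_L = x / (1.0 - x) * n_w
        dn_L = -consumption_factor * dalpha.sum()
        dx = n_w / (n_L + n_w) ** 2 * dn_L
        return np.concatenate([[dx], dalpha])

    return rhs


def simulate_batch(
    schedule: ProcessSchedule,
    kinetics: KineticRateParams,
    grid: GeometricVolumeGrid,
    solubility_model: SolubilityPolynomial,
    basis: SolutionBasis,
    seed_population: Optional[CrystalPopulation] = None,
    C0: Optional[float] = None,
    rho_s: float = RHO_ALPHA_LGA,
    duration: Optional[float] = None,
    nucleation_on: bool = True,
    sigma_override: Optional[float] = None,
    options: SolverOptions = SolverOptions(),
) -> BatchTrajectory:
    """Integrate a well-mixed batch cooling crystallization.

    Parameters
    ----------
    schedule, kinetics, grid, solubility_model, basis
        Process definition; see the respective types.
    seed_population
        Initial crystals; crystal-free when omitted.
    C0
        Initial solute mole fraction; defaults to the basis loading.
    duration
        Simulated time [s]; defaults to the cooling ramp duration.
    nucleation_on
        Disable to simulate growth of seeds only.
    sigma_override
        Freeze the driving force σ seen by the rate laws at a fixed value
        (verification aid); the solute balance still tracks consumption.
    options
        Integrator controls (method, tolerances, number of output samples).

    Returns
    -------
    BatchTrajectory
        State sampled on a uniform output grid.  Raises ``RuntimeError`` on
        solver failure, reporting the last valid time reached.
    """
    if seed_population is not None and seed_population.alpha.size != grid.n_bins:
        raise ValueError("seed population does not match the grid")
    if seed_population is not None and seed_population.rho_s != rho_s:
        rho_s = seed_population.rho_s

    x0 = basis.C0 if C0 is None else float(C0)
    if x0 < 0.0:
        raise ValueError("initial mole fraction must be non-negative")
    alpha0 = (
        np.zeros(grid.n_bins) if seed_population is None else seed_population.alpha.copy()
    )
    t_end = schedule.ramp_duration if duration is None else float(duration)
    y0 = np.concatenate([[x0], alpha0])

    rhs = _rhs_factory(
        schedule, kinetics, grid, solubility_model, basis, rho_s,
        nucleation_on, sigma_override,
    )
    atol = np.concatenate([[options.atol_C], np.full(grid.n_bins, options.atol_alpha)])
    t_eval = np.linspace(0.0, t_end, options.n_output)
    sol = solve_ivp(
        rhs,
        (0.0, t_end),
        y0,
        method=options.method,
        rtol=options.rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        last_t = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(
            f"ODE solver failed at t = {last_t:.1f} s: {sol.message}"
        )

    x = sol.y[0]
    if np.any(x < -1e-12):
        raise RuntimeError("negative solute concentration: mass-balance defect")
    alpha = sol.y[1:].T  # (n_t, n_bins)
    clipped = float(np.abs(np.minimum(alpha, 0.0)).sum())
    alpha = np.maximum(alpha, 0.0)

    T = schedule.temperature(sol.t)
    cstar = solubility_model(T)
    S = x / cstar
    sigma = S - 1.0
    sig_eff = sigma if sigma_override is None else np.full_like(sigma, sigma_override)
    G = growth_rate_linear(sig_eff, kinetics)
    ndot0 = nucleation_rate(sig_eff, kinetics) if nucleation_on else np.zeros_like(sigma)

    phi = alpha.sum(axis=1)
    d32 = np.full_like(phi, np.nan)
    occupied = phi > 0.0
    if occupied.any():
        N = alpha[occupied] / grid.V
        d32[occupied] = (N * grid.d**3).sum(axis=1) / (N * grid.d**2).sum(axis=1)

    return BatchTrajectory(
        time=sol.t,
        T=np.asarray(T),
        C=x,
        Cstar=np.asarray(cstar),
        S=S,
        sigma=sigma,
        alpha=alpha,
        phi_T=phi,
        d32=d32,
        ndot0=np.asarray(ndot0),
        G=np.asarray(G),
        grid=grid,
        basis=basis,
        rho_s=rho_s,
        clipped_volume=clipped,
    )


def mass_balance_audit(traj: BatchTrajectory) -> float:
    """Relative solute + crystal conservation residual over the whole run.

    ``|Δ(moles dissolved) + ρ_s·V_soln·Δφ_T/M| / (initial moles)``; values
    above 1e-6 indicate an integration or bookkeeping defect.  Mass removed
    by the non-negativity clip is charged to the residual.
    """
    basis = traj.basis
    n0 = basis.moles_solute(traj.C[0])
    n_end = basis.moles_solute(traj.C[-1])
    crystal_moles = (
        traj.rho_s
        * basis.solution_volume
        * (traj.phi_T[-1] - traj.phi_T[0] + traj.clipped_volume)
        / basis.M_solute
    )
    return float(abs((n_end - n0) + crystal_moles) / n0)


@dataclass(frozen=True)
class OnsetResult:
    t_onset: float  # s
    T_onset: float  # °C


def detect_onset(traj: BatchTrajectory, threshold: float = 0.01) -> Optional[OnsetResult]:
    """First time the solute concentration drops ``threshold`` below its start.

    Linear interpolation between samples; returns ``None`` when the
    concentration never crosses (e.g. an equilibrium hold).  A threshold of
    zero returns the first strictly decreasing sample.
    """
    C0 = traj.C[0]
    target = (1.0 - threshold) * C0
    if threshold == 0.0:
        dec = np.nonzero(np.diff(traj.C) < 0.0)[0]
        if dec.size == 0:
            return None
        k = dec[0] + 1
        return OnsetResult(t_onset=float(traj.time[k]), T_onset=float(traj.T[k]))
    below = np.nonzero(traj.C < target)[0]
    if below.size == 0:
        return None
    k = below[0]
    if k == 0:
        t_on = float(traj.time[0])
    else:
        t0, t1 = traj.time[k - 1], traj.time[k]
        c0, c1 = traj.C[k - 1], traj.C[k]
        t_on = float(t0 + (target - c0) / (c1 - c0) * (t1 - t0))
    return OnsetResult(t_onset=t_on, T_onset=float(traj.T[0]) if k == 0 else _interp_T(traj, t_on))


def _interp_T(traj: BatchTrajectory, t: float) -> float:
    return float(np.interp(t, traj.time, traj.T))


def mszw(traj: BatchTrajectory, T_sat_nominal: float, threshold: float = 0.01) -> float:
    """Metastable zone width [K]: nominal saturation temperature − onset temperature."""
    onset = detect_onset(traj, threshold)
    if onset is None:
        raise ValueError("no crystallization onset detected in trajectory")
    return T_sat_nominal - onset.T_onset


def peak_supersaturation(traj: BatchTrajectory) -> tuple[float, float]:
    """Time [s] and value of the supersaturation-ratio maximum.

    The peak is refined by parabolic interpolation through the maximum sample
    and its neighbours; an endpoint maximum is returned as-is.
    """
    if traj.S.size == 0:
        raise ValueError("empty trajectory")
    k = int(np.argmax(traj.S))
    if k == 0 or k == traj.S.size - 1:
        return float(traj.time[k]), float(traj.S[k])
    t0, t1, t2 = traj.time[k - 1 : k + 2]
    s0, s1, s2 = traj.S[k - 1 : k + 2]
    denom = s0 - 2.0 * s1 + s2
    if denom >= 0.0:  # flat or degenerate: keep the sample
        return float(t1), float(s1)
    # uniform-spacing parabola vertex
    h = 0.5 * (t2 - t0)
    dt = 0.5 * h * (s0 - s2) / denom
    t_peak = t1 + dt
    s_peak = s1 - 0.25 * (s0 - s2) * dt / h
    return float(t_peak), float(s_peak)


def desupersaturation_time(traj: BatchTrajectory, S_threshold: float) -> float:
    """First time [s] after the S-peak at which ``S`` falls below ``S_threshold``.

    Linear interpolation between samples; NaN when the trajectory never
    desupersaturates below the threshold within the simulated batch.
    """
    k_peak = int(np.argmax(traj.S))
    S_tail = traj.S[k_peak:]
    below = np.nonzero(S_tail < S_threshold)[0]
    if below.size == 0 or traj.S[k_peak] < S_threshold:
        return float("nan")
    k = below[0] + k_peak
    t0, t1 = traj.time[k - 1], traj.time[k]
    s0, s1 = traj.S[k - 1], traj.S[k]
    return float(t0 + (S_threshold - s0) / (s1 - s0) * (t1 - t0))
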