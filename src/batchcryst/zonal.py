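"""Compartment-network (multizonal) crystallizer model.

The vessel is represented as ``n`` interconnected well-mixed zones that
exchange solution and crystals through user-specified volumetric flows
``Q[z→z′]`` [m³/s].  Each zone integrates the same local physics as the
well-mixed batch model (population balance + solute balance), plus
conservative convective exchange:

* solute: molar flow ``Q·c`` with ``c`` the sending zone's molar concentration,
* crystals: each ``α_i`` advected at the sending zone's bin composition
  (no slip or settling between zones),
* enthalpy: temperature relaxation ``Σ Q[z′→z](T_z′ − T_z)/V_z`` assuming
  equal volumetric heat capacity in all zones.

Cooling is imposed globally: the volume-averaged temperature follows the
batch schedule exactly, with the heat removal split across zones by
user-specified weights (a wall-cooled zone receives more than its volume
share, mimicking the cold near-wall layer of a jacketed vessel).  Zone
volumes are constant, which requires the flow matrix to be balanced per zone.

A single-zone network is, by construction, the well-mixed batch model and is
delegated to it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.integrate import solve_ivp

from .batch import (
    BatchTrajectory,
    ProcessSchedule,
    SolutionBasis,
    SolverOptions,
    simulate_batch,
)
from .pbe import CrystalPopulation, GeometricVolumeGrid
from .thermo_kinetics import (
    RHO_ALPHA_LGA,
    KineticRateParams,
    SolubilityPolynomial,
    growth_rate_linear,
    nucleation_rate,
)

__all__ = ["ZoneNetwork", "ZonalResult", "validate_network", "simulate_zonal"]


@dataclass(frozen=True)
class ZoneNetwork:
    """Zone volumes [m³], exchange flow matrix [m³/s], heat-removal weights.

    ``Q[i, j]`` is the volumetric flow from zone ``i`` to zone ``j``
    (diagonal ignored).  Constant zone volumes require per-zone flow balance
    (total outflow = total inflow); heat weights are non-negative and sum
    to 1.
    """

    zone_volumes: np.ndarray
    Q: np.ndarray
    heat_weights: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "zone_volumes", np.asarray(self.zone_volumes, dtype=float))
        object.__setattr__(self, "Q", np.asarray(self.Q, dtype=float))
        object.__setattr__(self, "heat_weights", np.asarray(self.heat_weights, dtype=float))

    @property
    def n_zones(self) -> int:
        return self.zone_volumes.size

    @property
    def total_volume(self) -> float:
        return float(self.zone_volumes.sum())

    def scaled_flows(self, factor: float) -> "ZoneNetwork":
        return replace(self, Q=self.Q * factor)


def validate_network(net: ZoneNetwork) -> list[str]:
    """Check network invariants; returns a list of violations (empty = valid)."""
    issues: list[str] = []
    n = net.n_zones
    if net.Q.shape != (n, n):
        return [f"flow matrix shape {net.Q.shape} does not match {n} zones"]
    if np.any(net.zone_volumes <= 0.0):
        issues.append("zone volumes must be positive")
    off = net.Q - np.diag(np.diag(net.Q))
    if np.any(off < 0.0):
        issues.append("exchange flows must be non-negative")
    outflow = off.sum(axis=1)
    inflow = off.sum(axis=0)
    scale = max(off.max(initial=0.0), 1e-300)
    for z in range(n):
        if abs(outflow[z] - inflow[z]) > 1e-9 * scale:
            issues.append(
                f"zone {z} flow imbalance: out {outflow[z]:.3e} != in {inflow[z]:.3e} m³/s"
            )
    if np.any(net.heat_weights < 0.0):
        issues.append("heat weights must be non-negative")
    if abs(net.heat_weights.sum() - 1.0) > 1e-9:
        issues.append(f"heat weights sum to {net.heat_weights.sum():.6f}, expected 1")
    return issues


@dataclass
class ZonalResult:
    """Per-zone trajectories plus the volume-averaged trajectory.

    The averaged trajectory pools dissolved moles and crystal volume over
    zones (so it is exactly conservative) and evaluates ``S`` at the
    volume-averaged temperature and pooled concentration.
    """

    zones: list[BatchTrajectory]
    averaged: BatchTrajectory
    network: ZoneNetwork


def simulate_zonal(
    net: ZoneNetwork,
    schedule: ProcessSchedule,
    kinetics: KineticRateParams,
    grid: GeometricVolumeGrid,
    solubility_model: SolubilityPolynomial,
    basis: SolutionBasis,
    C0: Optional[float] = None,
    rho_s: float = RHO_ALPHA_LGA,
    duration: Optional[float] = None,
    options: SolverOptions = SolverOptions(),
) -> ZonalResult:
    """Integrate the compartment network under the global cooling schedule.

    ``basis`` describes the whole vessel; water and solution volume are
    apportioned to zones by their volume share.  All zones start at the same
    composition and temperature.
    """
    issues = validate_network(net)
    if issues:
        raise ValueError("invalid zone network: " + "; ".join(issues))

    if net.n_zones == 1:
        # a one-zone network IS the well-mixed batch model
        traj = simulate_batch(
            schedule, kinetics, grid, solubility_model, basis,
            C0=C0, rho_s=rho_s, duration=duration, options=options,
        )
        return ZonalResult(zones=[traj], averaged=traj, network=net)

    nz = net.n_zones
    nb = grid.n_bins
    Vz = net.zone_volumes
    Vtot = net.total_volume
    share = Vz / Vtot
    Q = net.Q - np.diag(np.diag(net.Q))
    Qin_T = Q.T / Vz[:, None]  # Qin_T[z, z'] = Q[z'→z]/V_z
    Qout = Q.sum(axis=1)

    x0 = basis.C0 if C0 is None else float(C0)
    n_w_zone = basis.moles_water * share
    V_soln_zone = basis.solution_volume * share
    consume = rho_s * V_soln_zone / basis.M_solute  # per-zone mol per unit dφ

    rate = schedule.rate_K_per_s
    t_ramp = schedule.ramp_duration
    # per-zone cooling rate so the volume-averaged T follows the ramp
    cool_z = rate * net.heat_weights * Vtot / Vz

    t_end = t_ramp if duration is None else float(duration)
    Vg, dg = grid.V, grid.d
    dV = np.diff(Vg)

    # state layout: [T (nz), x (nz), alpha (nz*nb)]
    def rhs(t, y):
        T = y[:nz]
        x = y[nz : 2 * nz]
        alpha = np.maximum(y[2 * nz :].reshape(nz, nb), 0.0)

        cstar = solubility_model(T)
        sigma = x / cstar - 1.0
        G = growth_rate_linear(sigma, kinetics)
        ndot0 = nucleation_rate(sigma, kinetics)

        dalpha = np.zeros((nz, nb))
        flux = (3.0 * Vg[:-1] / dg[:-1]) * G[:, None] * (alpha[:, :-1] / Vg[:-1]) / dV
        dalpha[:, :-1] -= Vg[:-1] * flux
        dalpha[:, 1:] += Vg[1:] * flux
        dalpha[:, 0] += grid.V0 * ndot0

        n_L = x / (1.0 - x) * n_w_zone
        dn_L = -consume * dalpha.sum(axis=1)

        # conservative convective exchange of dissolved moles
        c_molar = n_L / Vz  # mol solute per m³ of zone
        dn_L += Q.T @ c_molar - Qout * c_molar

        dx = n_w_zone / (n_L + n_w_zone) ** 2 * dn_L

        dalpha += (Qin_T @ alpha) - (Qout / Vz)[:, None] * alpha
        dT = Qin_T @ T - (Qout / Vz) * T
        if t < t_ramp:
            dT = dT - cool_z
        return np.concatenate([dT, dx, dalpha.ravel()])

    y0 = np.concatenate([np.full(nz, schedule.T0), np.full(nz, x0), np.zeros(nz * nb)])
    atol = np.concatenate(
        [np.full(nz, 1e-8), np.full(nz, options.atol_C), np.full(nz * nb, options.atol_alpha)]
    )
    t_eval = np.linspace(0.0, t_end, options.n_output)
    sol = solve_ivp(
        rhs, (0.0, t_end), y0,
        method=options.method, rtol=options.rtol, atol=atol, t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"zonal ODE solver failed: {sol.message}")

    T_all = sol.y[:nz]
    x_all = sol.y[nz : 2 * nz]
    alpha_all = np.maximum(sol.y[2 * nz :].reshape(nz, nb, -1), 0.0)

    zones = [
        _zone_trajectory(
            sol.t, T_all[z], x_all[z], alpha_all[z].T, grid,
            _zone_basis(basis, share[z]), solubility_model, kinetics, rho_s,
        )
        for z in range(nz)
    ]

    # volume-weighted average: pool amounts, evaluate S at pooled C, mean T
    n_L_all = x_all / (1.0 - x_all) * n_w_zone[:, None]
    n_L_tot = n_L_all.sum(axis=0)
    x_avg = n_L_tot / (n_L_tot + basis.moles_water)
    T_avg = (Vz[:, None] * T_all).sum(axis=0) / Vtot
    alpha_avg = (Vz[:, None, None] * alpha_all).sum(axis=0).T / Vtot
    averaged = _zone_trajectory(
        sol.t, T_avg, x_avg, alpha_avg, grid, basis,
        solubility_model, kinetics, rho_s,
    )
    return ZonalResult(zones=zones, averaged=averaged, network=net)


def _zone_basis(basis: SolutionBasis, share: float) -> SolutionBasis:
    return replace(
        basis,
        mass_water=basis.mass_water * share,
        solution_volume=basis.solution_volume * share,
    )


def _zone_trajectory(
    t: np.ndarray,
    T: np.ndarray,
    x: np.ndarray,
    alpha: np.ndarray,  # (n_t, n_bins)
    grid: GeometricVolumeGrid,
    basis: SolutionBasis,
    solubility_model: SolubilityPolynomial,
    kinetics: KineticRateParams,
    rho_s: float,
) -> BatchTrajectory:
    cstar = solubility_model(T)
    S = x / cstar
    sigma = S - 1.0
    phi = alpha.sum(axis=1)
    d32 = np.full_like(phi, np.nan)
    occ = phi > 0.0
    if occ.any():
        N = alpha[occ] / grid.V
        d32[occ] = (N * grid.d**3).sum(axis=1) / (N * grid.d**2).sum(axis=1)
    return BatchTrajectory(
        time=t,
        T=np.asarray(T, dtype=float),
        C=np.asarray(x, dtype=float),
        Cstar=np.asarray(cstar, dtype=float),
        S=S,
        sigma=sigma,
        alpha=alpha,
        phi_T=phi,
        d32=d32,
        ndot0=nucleation_rate(np.maximum(sigma, 0.0), kinetics),
        G=growth_rate_linear(np.maximum(sigma, 0.0), kinetics),
        grid=grid,
        basis=basis,
        rho_s=rho_s,
    )
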