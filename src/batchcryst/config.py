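"""Run configuration: structured input mirroring the study's condition tables.

A run is fully described by a YAML or TOML file with the sections below; all
fields default to the reference case (100 rpm, crash-free linear cooling at
0.6 °C/min from 70 to 20 °C, 43 g LGA per 1000 g water, Tai–Shei power-law
kinetics, 40 geometric bins spanning 1–1000 μm).  Units at the configuration
boundary are the laboratory ones (°C, K/min, μm, g per kg water); everything
is converted to SI on construction.  Unknown keys anywhere are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from .batch import ProcessSchedule, ScheduleMode, SolutionBasis, SolverOptions
from .pbe import GeometricVolumeGrid, build_grid
from .thermo_kinetics import (
    M_LGA,
    M_WATER,
    RHO_ALPHA_LGA,
    KineticRateParams,
    SolubilityPolynomial,
    TempConvention,
)
from .zonal import ZoneNetwork

__all__ = ["RunConfig", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Invalid or unknown configuration content; the message names the field."""


_DEFAULTS: dict[str, dict[str, Any]] = {
    "run": {"label": "Run 1", "rpm": 100, "output_samples": 1001},
    "schedule": {
        "T0_C": 70.0,
        "T_final_C": 20.0,
        "cooling_rate_K_per_min": 0.6,
        "mode": "imposed_ramp",
        "heat_flux_W_per_m2": None,
        "wetted_area_m2": None,
        "thermal_mass_J_per_K": None,
    },
    "kinetics": {
        "kN": 4.02e6,
        "n": 1.87,
        "kG": 9.76e-8,
        "g": 2.34,
        "source": "Tai-Shei",
    },
    "grid": {"d_min_um": 1.0, "d_max_um": 1000.0, "n_bins": 40},
    "solubility": {
        "a0": 0.08131,
        "a1": 0.000595783,
        "a2": 1.10258e-6,
        "temp_convention": "absolute_kelvin",
    },
    "basis": {
        "solute_loading_g_per_kg_water": 43.0,
        "mass_water_kg": 1.0,
        "rho_solution_kg_per_m3": 1000.0,
        "rho_crystal_kg_per_m3": RHO_ALPHA_LGA,
        "M_solute_g_per_mol": M_LGA * 1000.0,
        "M_solvent_g_per_mol": M_WATER * 1000.0,
    },
    "solver": {"method": "LSODA", "rtol": 1e-8, "atol_C": 1e-14, "atol_alpha": 1e-16},
    "network": None,  # optional multizonal section
}

_NETWORK_KEYS = {"zone_volumes_m3", "flows_m3_per_s", "heat_weights", "zone_labels"}


def _merge_section(name: str, defaults: dict, user: dict) -> dict:
    unknown = set(user) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in section '{name}': {sorted(unknown)}")
    merged = dict(defaults)
    merged.update(user)
    return merged


@dataclass
class RunConfig:
    """Validated configuration; ``build_*`` methods construct model objects."""

    run: dict
    schedule: dict
    kinetics: dict
    grid: dict
    solubility: dict
    basis: dict
    solver: dict
    network: Optional[dict] = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown top-level section(s): {sorted(unknown)}")
        sections = {}
        for name, defaults in _DEFAULTS.items():
            if name == "network":
                continue
            user = raw.get(name, {})
            if not isinstance(user, dict):
                raise ConfigError(f"section '{name}' must be a mapping")
            sections[name] = _merge_section(name, defaults, user)
        net = raw.get("network")
        if net is not None:
            unknown = set(net) - _NETWORK_KEYS
            if unknown:
                raise ConfigError(f"unknown key(s) in section 'network': {sorted(unknown)}")
        cfg = cls(network=net, **sections)
        cfg.validate()
        return cfg

    @classmethod
    def default(cls) -> "RunConfig":
        return cls.from_dict({})

    def validate(self) -> None:
        s = self.schedule
        if s["cooling_rate_K_per_min"] is not None and s["cooling_rate_K_per_min"] <= 0:
            raise ConfigError("schedule.cooling_rate_K_per_min must be positive")
        if s["T0_C"] <= s["T_final_C"]:
            raise ConfigError("schedule.T0_C must exceed schedule.T_final_C")
        k = self.kinetics
        if k["kN"] < 0 or k["kG"] < 0:
            raise ConfigError("kinetics rate constants must be non-negative")
        if k["n"] <= 0 or k["g"] <= 0:
            raise ConfigError("kinetics exponents must be positive")
        g = self.grid
        if not (0 < g["d_min_um"] < g["d_max_um"]):
            raise ConfigError("grid.d_min_um must satisfy 0 < d_min < d_max")
        if int(g["n_bins"]) < 2:
            raise ConfigError("grid.n_bins must be at least 2")
        b = self.basis
        for key in (
            "solute_loading_g_per_kg_water",
            "mass_water_kg",
            "rho_solution_kg_per_m3",
            "rho_crystal_kg_per_m3",
        ):
            if b[key] <= 0:
                raise ConfigError(f"basis.{key} must be positive")
        conv = self.solubility["temp_convention"]
        try:
            TempConvention(conv)
        except ValueError:
            raise ConfigError(
                f"solubility.temp_convention must be one of "
                f"{[c.value for c in TempConvention]}, got {conv!r}"
            ) from None
        # the solubility must be positive over the whole schedule
        model = self.build_solubility()
        T_probe = np.linspace(s["T_final_C"], s["T0_C"], 64)
        if np.any(model(T_probe) <= 0.0):
            raise ConfigError(
                "solubility polynomial is non-positive inside the cooling range"
            )

    # ---- builders -------------------------------------------------------
    def build_schedule(self) -> ProcessSchedule:
        s = self.schedule
        return ProcessSchedule(
            T0=s["T0_C"],
            T_final=s["T_final_C"],
            cooling_rate=s["cooling_rate_K_per_min"],
            mode=ScheduleMode(s["mode"]),
            heat_flux=s["heat_flux_W_per_m2"],
            wetted_area=s["wetted_area_m2"],
            thermal_mass=s["thermal_mass_J_per_K"],
        )

    def build_kinetics(self) -> KineticRateParams:
        k = self.kinetics
        return KineticRateParams(kN=k["kN"], n=k["n"], kG=k["kG"], g=k["g"], source=k["source"])

    def build_grid(self) -> GeometricVolumeGrid:
        g = self.grid
        return build_grid(g["d_min_um"] * 1e-6, g["d_max_um"] * 1e-6, int(g["n_bins"]))

    def build_solubility(self) -> SolubilityPolynomial:
        s = self.solubility
        return SolubilityPolynomial(
            a0=s["a0"], a1=s["a1"], a2=s["a2"],
            temp_convention=TempConvention(s["temp_convention"]),
        )

    def build_basis(self) -> SolutionBasis:
        b = self.basis
        basis = SolutionBasis.from_loading(
            grams_per_kg_water=b["solute_loading_g_per_kg_water"],
            mass_water=b["mass_water_kg"],
            rho_solution=b["rho_solution_kg_per_m3"],
        )
        from dataclasses import replace

        return replace(
            basis,
            M_solute=b["M_solute_g_per_mol"] / 1000.0,
            M_solvent=b["M_solvent_g_per_mol"] / 1000.0,
        )

    def build_solver_options(self) -> SolverOptions:
        s = self.solver
        return SolverOptions(
            method=s["method"],
            rtol=s["rtol"],
            atol_C=s["atol_C"],
            atol_alpha=s["atol_alpha"],
            n_output=int(self.run["output_samples"]),
        )

    def build_network(self) -> Optional[ZoneNetwork]:
        if self.network is None:
            return None
        n = self.network
        return ZoneNetwork(
            zone_volumes=np.asarray(n["zone_volumes_m3"], dtype=float),
            Q=np.asarray(n["flows_m3_per_s"], dtype=float),
            heat_weights=np.asarray(n["heat_weights"], dtype=float),
        )

    @property
    def rho_crystal(self) -> float:
        return float(self.basis["rho_crystal_kg_per_m3"])


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML (.yaml/.yml) or TOML (.toml) run configuration."""
    path = Path(path)
    if path.suffix in {".yaml", ".yml"}:
        import yaml

        raw = yaml.safe_load(path.read_text()) or {}
    elif path.suffix == ".toml":
        import tomllib

        raw = tomllib.loads(path.read_text())
    else:
        raise ConfigError(f"unsupported config format: {path.suffix!r}")
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    return RunConfig.from_dict(raw)
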