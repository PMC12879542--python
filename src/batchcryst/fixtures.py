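"""Synthetic fixtures: datasets, seed populations, and network presets.

Everything here is generated, seeded, and deterministic — the same seed
always yields byte-identical files.  The fixtures exercise every module
without external data:

* ``growth_dataset`` — (σ, G) pairs from a known power law with optional
  multiplicative lognormal noise, for the growth-kinetics fitting path;
* ``seeded_population`` — a lognormal volume distribution placed on a
  geometric grid, for seeded-batch and CSD-statistics paths;
* ``equilibrium_case`` — a configuration whose initial composition sits
  exactly on the solubility curve (a fixed point of the simulator);
* ``three_zone_network`` — a top/bulk/wall compartment template with the
  wall zone taking most of the heat removal, qualitatively mimicking the
  cold near-wall layer of a jacketed stirred vessel.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pbe import CrystalPopulation, GeometricVolumeGrid
from .thermo_kinetics import (
    RHO_ALPHA_LGA,
    GrowthRateDataset,
    SolubilityPolynomial,
)
from .zonal import ZoneNetwork

__all__ = [
    "FixtureKind",
    "FixtureSpec",
    "make_fixture",
    "synth_growth_dataset",
    "seeded_lognormal_population",
    "equilibrium_config_dict",
    "three_zone_network",
]


class FixtureKind(str, enum.Enum):
    GROWTH_DATASET = "growth_dataset"
    SEEDED_POPULATION = "seeded_population"
    EQUILIBRIUM_CASE = "equilibrium_case"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int
    kind: FixtureKind
    parameters: dict = field(default_factory=dict)


def synth_growth_dataset(
    kG: float = 2.80e-7,
    g: float = 1.43,
    n: int = 50,
    noise_sd: float = 0.1,
    sigma_range: tuple[float, float] = (0.05, 1.0),
    rng: np.random.Generator | int | None = 0,
) -> GrowthRateDataset:
    """Draw σ log-uniformly and set ``G = kG·σ^g`` times lognormal noise."""
    rng = np.random.default_rng(rng)
    lo, hi = sigma_range
    sigma = np.sort(np.exp(rng.uniform(np.log(lo), np.log(hi), size=n)))
    noise = np.exp(rng.normal(0.0, noise_sd, size=n)) if noise_sd > 0 else 1.0
    return GrowthRateDataset(sigma=sigma, G=kG * sigma**g * noise)


def seeded_lognormal_population(
    grid: GeometricVolumeGrid,
    median_um: float = 50.0,
    gsd: float = 1.5,
    phi_total: float = 1e-4,
    rho_s: float = RHO_ALPHA_LGA,
) -> CrystalPopulation:
    """Lognormal volume-weighted seed distribution on the grid.

    ``median_um`` is the volume-weighted median diameter and ``gsd`` the
    geometric standard deviation; bin weights follow the lognormal density
    in log diameter (uniform log spacing on a ratio-factor grid), normalized
    to a total solids fraction ``phi_total``.
    """
    if gsd <= 1.0:
        raise ValueError("geometric standard deviation must exceed 1")
    logd = np.log(grid.d * 1e6)
    mu, s = np.log(median_um), np.log(gsd)
    w = np.exp(-0.5 * ((logd - mu) / s) ** 2)
    if w.sum() <= 0:
        raise ValueError("seed distribution lies outside the grid")
    return CrystalPopulation(alpha=phi_total * w / w.sum(), rho_s=rho_s)


def equilibrium_config_dict(
    T0_C: float = 70.0,
    solubility: SolubilityPolynomial | None = None,
) -> dict:
    """Config dict whose initial loading saturates the solution at ``T0_C``.

    The loading [g solute per kg water] is back-computed from the solubility
    so that C0 = C*(T0): the crystal-free simulator then has a fixed point
    until cooling begins.
    """
    from .thermo_kinetics import M_LGA, M_WATER

    model = solubility or SolubilityPolynomial()
    x = model(T0_C)
    grams = x / (1.0 - x) * (M_LGA / M_WATER) * 1000.0
    return {
        "schedule": {"T0_C": T0_C},
        "basis": {"solute_loading_g_per_kg_water": float(grams)},
    }


def three_zone_network(
    total_volume: float = 0.020,
    wall_fraction: float = 0.15,
    top_fraction: float = 0.25,
    circulation_flow: float = 2.0e-4,
    wall_heat_weight: float = 0.7,
) -> ZoneNetwork:
    """Top / bulk / wall compartment template for a jacketed stirred vessel.

    A single circulation loop top → bulk → wall → top carries
    ``circulation_flow`` [m³/s]; the wall zone takes ``wall_heat_weight`` of
    the heat removal and the remainder is split between top and bulk by
    volume.  Defaults give a 20 L vessel with a thin cold wall layer.
    """
    v_wall = wall_fraction * total_volume
    v_top = top_fraction * total_volume
    v_bulk = total_volume - v_wall - v_top
    Q = np.zeros((3, 3))
    Q[0, 1] = Q[1, 2] = Q[2, 0] = circulation_flow  # top→bulk→wall→top
    rest = 1.0 - wall_heat_weight
    w_top = rest * v_top / (v_top + v_bulk)
    return ZoneNetwork(
        zone_volumes=np.array([v_top, v_bulk, v_wall]),
        Q=Q,
        heat_weights=np.array([w_top, rest - w_top, wall_heat_weight]),
    )


def make_fixture(spec: FixtureSpec, outdir: str | Path) -> list[Path]:
    """Materialize a fixture as files under ``outdir``; returns written paths.

    The same spec (seed included) always produces byte-identical files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = dict(spec.parameters)
    written: list[Path] = []
    if spec.kind is FixtureKind.GROWTH_DATASET:
        ds = synth_growth_dataset(
            kG=p.pop("kG", 2.80e-7),
            g=p.pop("g", 1.43),
            n=int(p.pop("n", 50)),
            noise_sd=p.pop("noise_sd", 0.1),
            sigma_range=tuple(p.pop("sigma_range", (0.05, 1.0))),
            rng=spec.seed,
        )
        path = outdir / f"growth_dataset_seed{spec.seed}.csv"
        ds.to_csv(path)
        written.append(path)
    elif spec.kind is FixtureKind.SEEDED_POPULATION:
        from .pbe import build_grid

        grid = build_grid(
            p.pop("d_min_um", 1.0) * 1e-6,
            p.pop("d_max_um", 1000.0) * 1e-6,
            int(p.pop("n_bins", 40)),
        )
        pop = seeded_lognormal_population(
            grid,
            median_um=p.pop("median_um", 50.0),
            gsd=p.pop("gsd", 1.5),
            phi_total=p.pop("phi_total", 1e-4),
        )
        path = outdir / f"seed_population_seed{spec.seed}.csv"
        pop.to_csv(path, grid)
        written.append(path)
    elif spec.kind is FixtureKind.EQUILIBRIUM_CASE:
        import yaml

        cfg = equilibrium_config_dict(T0_C=p.pop("T0_C", 70.0))
        path = outdir / f"equilibrium_case_T{cfg['schedule']['T0_C']:g}.yaml"
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
        written.append(path)
    else:  # pragma: no cover
        raise ValueError(f"unknown fixture kind {spec.kind}")
    if p:
        raise ValueError(f"unused fixture parameters: {sorted(p)}")
    return written
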