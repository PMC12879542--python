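"""Summary statistics of a completed batch run, in reporting units."""

from __future__ import annotations

import math
from typing import Optional

from .batch import (
    BatchTrajectory,
    desupersaturation_time,
    detect_onset,
    mass_balance_audit,
    peak_supersaturation,
)
from .csd import csd_mode, csd_percentiles, csd_span, volume_percent_csd

__all__ = ["trajectory_summary", "format_summary"]


def trajectory_summary(
    traj: BatchTrajectory,
    T_sat_nominal: Optional[float] = None,
    onset_threshold: float = 0.01,
    S_threshold: float = 1.10,
) -> dict:
    """Headline numbers of one simulation.

    Times in minutes, temperatures in °C, diameters in μm.  ``mszw_K`` is
    computed against ``T_sat_nominal`` (NaN when no nominal saturation point
    is given or no onset is detected); ``t_desupersat_min`` is NaN when the
    batch never comes within ``S_threshold`` of the solubility curve.
    """
    t_peak, S_peak = peak_supersaturation(traj)
    onset = detect_onset(traj, onset_threshold)
    t_desat = desupersaturation_time(traj, S_threshold)
    out = {
        "t_peak_min": t_peak / 60.0,
        "S_peak": S_peak,
        "S_final": float(traj.S[-1]),
        "t_onset_min": onset.t_onset / 60.0 if onset else math.nan,
        "T_onset_C": onset.T_onset if onset else math.nan,
        "mszw_K": (T_sat_nominal - onset.T_onset)
        if (onset and T_sat_nominal is not None)
        else math.nan,
        "t_desupersat_min": t_desat / 60.0 if not math.isnan(t_desat) else math.nan,
        "phi_T_final": float(traj.phi_T[-1]),
        "d32_final_um": float(traj.d32[-1]) * 1e6 if traj.phi_T[-1] > 0 else math.nan,
        "mass_balance_residual": mass_balance_audit(traj),
    }
    if traj.phi_T[-1] > 0.0:
        csd = volume_percent_csd(traj.final_population(), traj.grid)
        d10, d50, d90 = csd_percentiles(csd)
        out.update(
            csd_mode_um=csd_mode(csd),
            csd_d10_um=d10,
            csd_d50_um=d50,
            csd_d90_um=d90,
            csd_span=csd_span(csd),
        )
    else:
        out.update(
            csd_mode_um=math.nan,
            csd_d10_um=math.nan,
            csd_d50_um=math.nan,
            csd_d90_um=math.nan,
            csd_span=math.nan,
        )
    return out


def format_summary(summary: dict) -> str:
    lines = ["batch summary"]
    labels = {
        "t_peak_min": ("time of supersaturation peak", "min"),
        "S_peak": ("peak supersaturation ratio S", ""),
        "S_final": ("final supersaturation ratio S", ""),
        "t_onset_min": ("crystallization onset (1% solute drop)", "min"),
        "T_onset_C": ("onset temperature", "degC"),
        "mszw_K": ("metastable zone width", "K"),
        "t_desupersat_min": ("time to S < 1.10", "min"),
        "phi_T_final": ("final total solids fraction", ""),
        "d32_final_um": ("final Sauter mean diameter", "um"),
        "csd_mode_um": ("final CSD mode", "um"),
        "csd_d10_um": ("final CSD d10", "um"),
        "csd_d50_um": ("final CSD d50", "um"),
        "csd_d90_um": ("final CSD d90", "um"),
        "csd_span": ("final CSD span (d90-d10)/d50", ""),
        "mass_balance_residual": ("mass-balance audit residual", ""),
    }
    for key, (label, unit) in labels.items():
        value = summary.get(key, math.nan)
        if isinstance(value, float) and math.isnan(value):
            text = "not reached / not detected"
        elif key == "mass_balance_residual":
            text = f"{value:.2e}"
        else:
            text = f"{value:.4g} {unit}".rstrip()
        lines.append(f"  {label:42s} {text}")
    return "\n".join(lines)
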