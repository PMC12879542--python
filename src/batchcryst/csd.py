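"""Volume-based crystal size distribution (CSD) reporting.

Final CSDs are reported as volume percent per size bin against the bin's
volume-equivalent diameter, matching how in-process ultrasonic attenuation
measurements present them.  Summary statistics (mode, percentiles, span) are
computed on the normalized distribution, so they are invariant under the
total amount of solids.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pbe import CrystalPopulation, GeometricVolumeGrid

__all__ = [
    "VolumeCSD",
    "volume_percent_csd",
    "csd_mode",
    "csd_percentiles",
    "csd_span",
    "csd_distance",
]


@dataclass
class VolumeCSD:
    """Normalized volume-percent distribution on a diameter grid [μm]."""

    d_um: np.ndarray
    volume_percent: np.ndarray

    def __post_init__(self):
        self.d_um = np.asarray(self.d_um, dtype=float)
        self.volume_percent = np.asarray(self.volume_percent, dtype=float)
        if self.d_um.shape != self.volume_percent.shape:
            raise ValueError("diameter and volume-percent arrays differ in shape")
        if np.any(self.volume_percent < -1e-12):
            raise ValueError("volume percentages must be non-negative")
        if abs(self.volume_percent.sum() - 100.0) > 1e-6:
            raise ValueError(
                f"volume percentages sum to {self.volume_percent.sum():.6f}, expected 100"
            )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"d_um": self.d_um, "volume_percent": self.volume_percent}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "VolumeCSD":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(d_um=df["d_um"].to_numpy(), volume_percent=df["volume_percent"].to_numpy())


def volume_percent_csd(pop: CrystalPopulation, grid: GeometricVolumeGrid) -> VolumeCSD:
    """Volume-percent CSD ``100·f_i`` against bin diameters (requires solids)."""
    f = pop.volume_fractions()
    return VolumeCSD(d_um=grid.d * 1e6, volume_percent=100.0 * f)


def csd_mode(csd: VolumeCSD) -> float:
    """Peak diameter [μm], refined by log-parabolic 3-point interpolation.

    A parabola in ``(ln d, volume %)`` is fitted through the peak bin and its
    two neighbours; the vertex abscissa is returned.  Edge peaks (or flat
    tops) fall back to the peak-bin diameter.
    """
    v = csd.volume_percent
    k = int(np.argmax(v))
    if k == 0 or k == v.size - 1:
        return float(csd.d_um[k])
    l0, l1, l2 = np.log(csd.d_um[k - 1 : k + 2])
    v0, v1, v2 = v[k - 1 : k + 2]
    denom = v0 - 2.0 * v1 + v2
    if denom >= 0.0:
        return float(csd.d_um[k])
    # uniform log spacing on a ratio-factor grid
    h = 0.5 * (l2 - l0)
    return float(np.exp(l1 + 0.5 * h * (v0 - v2) / denom))


def csd_percentiles(csd: VolumeCSD, percentiles=(10.0, 50.0, 90.0)) -> tuple[float, ...]:
    """Volume-weighted diameter percentiles (default d10, d50, d90) [μm].

    The cumulative volume curve over the occupied bins is interpolated
    linearly in log diameter.  A single occupied bin is treated as a point
    mass (all percentiles at that diameter).
    """
    v = csd.volume_percent
    occ = np.nonzero(v > 0.0)[0]
    if occ.size == 0:
        raise ValueError("empty distribution")
    logd = np.log(csd.d_um[occ])
    cum = np.cumsum(v[occ])
    # anchor the curve at zero cumulative volume at the first occupied bin
    xp = np.concatenate([[0.0], cum])
    fp = np.concatenate([[logd[0]], logd])
    out = tuple(float(np.exp(np.interp(p, xp, fp))) for p in percentiles)
    return out


def csd_span(csd: VolumeCSD) -> float:
    """Distribution span ``(d90 − d10)/d50`` (0 for a point mass)."""
    d10, d50, d90 = csd_percentiles(csd)
    return (d90 - d10) / d50


def csd_distance(a: VolumeCSD, b: VolumeCSD) -> float:
    """Half the L1 distance between two CSDs on a shared grid.

    0 for identical distributions, 100 for fully disjoint ones.
    """
    if a.d_um.shape != b.d_um.shape or not np.allclose(a.d_um, b.d_um, rtol=1e-9):
        raise ValueError("CSDs must share the same diameter grid")
    return float(0.5 * np.abs(a.volume_percent - b.volume_percent).sum())
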