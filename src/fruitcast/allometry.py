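"""Ellipsoid allometry: volume index, density calibration, mass estimation.

A tomato fruit is approximated as a prolate spheroid with long diameter
``l`` and short diameter ``s`` (both cm).  The fruit volume index is

    V = (4/3) * pi * (l/2) * (s/2)^2 = (pi/6) * l * s^2   [cm^3]

Mass is estimated nondestructively from volume through a cultivar-level
density ``d`` (g cm^-3) fitted once per cultivar on destructive
calibration fruits:

    C = V * d   [g]

Because the mass model is strictly proportional, the density fit is a
through-origin least-squares regression: d = sum(V*m) / sum(V^2).  The
reported r^2 is the uncentred coefficient of determination (residuals
relative to the zero line), which is the coherent choice for a no-intercept
model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Tuple

import numpy as np

from .errors import DegenerateDataError, DomainError, InsufficientDataError

__all__ = [
    "DiameterPair",
    "DensityFit",
    "fruit_volume_index",
    "calibrate_density",
    "estimate_mass",
]

#: tolerated relative excess of short over long diameter (caliper noise)
ASPECT_TOLERANCE = 0.05


@dataclass(frozen=True)
class DiameterPair:
    """One caliper measurement: long and short fruit diameters in cm."""

    long_cm: float
    short_cm: float

    def __post_init__(self) -> None:
        if not (self.long_cm > 0 and self.short_cm > 0):
            raise DomainError(
                f"diameters must be positive, got ({self.long_cm}, {self.short_cm})"
            )
        if self.short_cm > self.long_cm * (1 + ASPECT_TOLERANCE):
            raise DomainError(
                f"short diameter {self.short_cm} exceeds long {self.long_cm} "
                f"beyond {ASPECT_TOLERANCE:.0%} tolerance"
            )

    @classmethod
    def from_measurement(cls, long_cm: float, short_cm: float) -> Tuple["DiameterPair", bool]:
        """Build a pair, swapping the readings when short > long beyond tolerance.

        Caliper reading-order mistakes are common in the field; rather than
        rejecting the row we swap and flag it.  Returns ``(pair, swapped)``.
        """
        if short_cm > long_cm * (1 + ASPECT_TOLERANCE):
            return cls(short_cm, long_cm), True
        return cls(long_cm, short_cm), False


@dataclass(frozen=True)
class DensityFit:
    """Cultivar density from through-origin regression of mass on volume."""

    density: float  # g cm^-3
    n_fruits: int
    residual_rms: float  # g
    r2: float

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise DomainError(f"density must be positive, got {self.density}")
        if self.n_fruits < 2:
            raise InsufficientDataError("density fit needs at least 2 fruits")


def fruit_volume_index(dp: DiameterPair) -> float:
    """Ellipsoid volume index V = (pi/6) * l * s^2 in cm^3."""
    return math.pi / 6.0 * dp.long_cm * dp.short_cm**2


def calibrate_density(pairs: Iterable[Tuple[float, float]]) -> DensityFit:
    """Fit cultivar density from (volume cm^3, actual mass g) pairs.

    Through-origin least squares: the slope minimising sum((m - d*V)^2) is
    sum(V*m) / sum(V^2).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise DomainError("pairs must be (volume, mass) tuples")
    if arr.shape[0] < 2:
        raise InsufficientDataError("need at least 2 calibration pairs")
    v, m = arr[:, 0], arr[:, 1]
    if np.any(v <= 0):
        raise DomainError("all calibration volumes must be positive")
    ssv = float(np.sum(v * v))
    if ssv == 0:
        raise DegenerateDataError("all calibration volumes are zero")
    d = float(np.sum(v * m) / ssv)
    resid = m - d * v
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(m**2))  # uncentred: relative to the zero line
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DensityFit(
        density=d,
        n_fruits=arr.shape[0],
        residual_rms=float(np.sqrt(ss_res / arr.shape[0])),
        r2=r2,
    )


def estimate_mass(volume: float, fit: DensityFit) -> float:
    """Nondestructive mass estimate C = V * d in grams."""
    if volume < 0:
        raise DomainError(f"volume must be non-negative, got {volume}")
    return volume * fit.density
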