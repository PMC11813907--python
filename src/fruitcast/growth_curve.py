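"""Per-fruit cubic growth curves on the thermal-time axis.

Because anthesis dates differ between flowers and greenhouse temperature
varies, no two fruits are measured at the same thermal times.  To compare
fruits on a common footing, each fruit's estimated masses C(tau) are fitted
with an ordinary least-squares cubic polynomial within a thermal window,
and the fitted curve is evaluated at fixed thermal anchors (e.g. 200, 300
and 500 degC d).  Poorly-fitting fruits (r^2 below the scheme's gate) are
excluded from model building.

Two preset anchor schemes are provided:

* ``E500`` — window < 625 degC d, anchors (200, 300, 500), r^2 gate 0.94:
  an early-season scheme covering the pericarp cell-division phase, useful
  for thinning decisions.
* ``E800`` — window < 900 degC d, anchors (300, 500, 800), r^2 gate 0.95:
  a late scheme roughly two weeks before harvest, useful for supply-chain
  volume forecasts.

Anchors below the first observed thermal time are obtained by
extrapolating the fitted cubic; such rows carry an ``extrapolated`` flag
rather than being dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np

from .errors import DegenerateDataError, DomainError, GateError, InsufficientDataError

__all__ = [
    "GrowthObservation",
    "AnchorScheme",
    "GrowthCurve",
    "SCHEMES",
    "E500",
    "E800",
    "fit_growth_curve",
    "anchor_sizes",
]


@dataclass(frozen=True)
class GrowthObservation:
    """One estimated mass at one thermal time."""

    tau: float  # degC d since anthesis
    c_fruit: float  # estimated mass, g

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise DomainError(f"thermal time must be non-negative, got {self.tau}")
        if self.c_fruit < 0:
            raise DomainError(f"mass must be non-negative, got {self.c_fruit}")


@dataclass(frozen=True)
class AnchorScheme:
    """Thermal window, anchor set and r^2 inclusion gate for curve fitting."""

    name: str
    window_max: float  # degC d, exclusive upper bound of fitting window
    anchors: Tuple[float, ...]
    r2_gate: float

    def __post_init__(self) -> None:
        anchors = tuple(float(a) for a in self.anchors)
        object.__setattr__(self, "anchors", anchors)
        if not anchors or any(a >= self.window_max for a in anchors):
            raise DomainError("all anchors must lie below window_max")
        if any(b <= a for a, b in zip(anchors, anchors[1:])):
            raise DomainError("anchors must be strictly increasing")
        if not (0 < self.r2_gate <= 1):
            raise DomainError("r2 gate must be in (0, 1]")


E500 = AnchorScheme("E500", window_max=625.0, anchors=(200.0, 300.0, 500.0), r2_gate=0.94)
E800 = AnchorScheme("E800", window_max=900.0, anchors=(300.0, 500.0, 800.0), r2_gate=0.95)
SCHEMES = {"E500": E500, "E800": E800}


@dataclass(frozen=True)
class GrowthCurve:
    """A fitted cubic mass trajectory m(tau) = c0 + c1 tau + c2 tau^2 + c3 tau^3.

    ``coefficients`` are in ascending powers (g per (degC d)^k).
    ``qc_pass`` records whether the fit cleared the scheme's r^2 gate;
    ``monotone_flag`` is True when the fitted derivative is non-negative
    over [0, window_max] (a biologically sensible trajectory).
    """

    coefficients: Tuple[float, float, float, float]
    r2: float
    n_obs: int
    window_max: float
    qc_pass: bool
    monotone_flag: bool
    tau_min: float = float("nan")  # smallest fitted tau (extrapolation bound)
    tau_max: float = float("nan")

    def __call__(self, tau) -> np.ndarray | float:
        return np.polynomial.polynomial.polyval(tau, np.asarray(self.coefficients))


def _monotone_on_window(coeffs: np.ndarray, window_max: float) -> bool:
    """True iff d/dtau of the cubic is >= 0 everywhere on [0, window_max]."""
    deriv = np.polynomial.polynomial.polyder(coeffs)
    grid = np.linspace(0.0, window_max, 513)
    vals = np.polynomial.polynomial.polyval(grid, deriv)
    # tiny negative slopes from round-off do not count as non-monotone
    tol = 1e-9 * max(1.0, float(np.max(np.abs(vals))))
    return bool(np.all(vals >= -tol))


def fit_growth_curve(
    obs: Iterable[GrowthObservation], scheme: AnchorScheme
) -> GrowthCurve:
    """OLS cubic fit of C(tau) on observations with tau < scheme.window_max.

    r^2 is the standard coefficient of determination computed on the
    fitting observations.  The fit is unconstrained; non-monotone curves
    are flagged for audit, not rejected.

    Raises
    ------
    InsufficientDataError
        Fewer than 4 in-window observations.
    DegenerateDataError
        Zero variance in the observed masses.
    """
    pts = [(o.tau, o.c_fruit) for o in obs if o.tau < scheme.window_max]
    if len(pts) < 4:
        raise InsufficientDataError(
            f"need >= 4 observations below {scheme.window_max} degC d, got {len(pts)}"
        )
    tau = np.array([p[0] for p in pts])
    c = np.array([p[1] for p in pts])
    if np.ptp(c) == 0:
        raise DegenerateDataError("all in-window masses identical; cannot gate on r^2")
    # scale tau to [0, 1] for conditioning, then rescale coefficients back
    s = scheme.window_max
    X = np.vander(tau / s, N=4, increasing=True)
    beta, *_ = np.linalg.lstsq(X, c, rcond=None)
    coeffs = beta / s ** np.arange(4)
    fitted = X @ beta
    ss_res = float(np.sum((c - fitted) ** 2))
    ss_tot = float(np.sum((c - c.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot
    return GrowthCurve(
        coefficients=tuple(coeffs),
        r2=r2,
        n_obs=len(pts),
        window_max=scheme.window_max,
        qc_pass=bool(r2 >= scheme.r2_gate),
        monotone_flag=_monotone_on_window(coeffs, scheme.window_max),
        tau_min=float(tau.min()),
        tau_max=float(tau.max()),
    )


def anchor_sizes(curve: GrowthCurve, scheme: AnchorScheme) -> np.ndarray:
    """Evaluate the fitted curve at the scheme's anchors (estimated masses, g).

    Raises :class:`GateError` when the curve failed its r^2 gate.  Negative
    or non-increasing anchor values are legitimate outputs of an
    unconstrained cubic and are left to the caller to flag (see
    :func:`suspect_anchor_values`).
    """
    if not curve.qc_pass:
        raise GateError(
            f"curve r^2 {curve.r2:.4f} below gate {scheme.r2_gate}; fruit excluded"
        )
    vals = np.asarray(curve(np.asarray(scheme.anchors, dtype=float)), dtype=float)
    if not np.all(np.isfinite(vals)):
        raise DomainError("non-finite anchor value")
    return vals


def suspect_anchor_values(values: Sequence[float]) -> bool:
    """Audit flag: True when any anchor mass is negative or the sequence decreases."""
    v = np.asarray(values, dtype=float)
    return bool(np.any(v < 0) or np.any(np.diff(v) < 0))


def is_extrapolated(curve: GrowthCurve, scheme: AnchorScheme) -> bool:
    """True when any anchor lies outside the span of the fitted observations."""
    a = np.asarray(scheme.anchors)
    return bool(np.any(a < curve.tau_min) or np.any(a > curve.tau_max))
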