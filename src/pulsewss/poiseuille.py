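"""Steady and quasi-steady Poiseuille reconstructions.

The clinical comparator: a parabolic radial profile scaled by the
instantaneous mean velocity,

    U_p(r, t) = 2 U(t) (1 - (r/R)^2),   Q(t) = pi R^2 U(t),
    tau_w(t)  = 4 mu U(t) / R,

ignoring all frequency content of the waveform ("quasi-steady").  With a
constant velocity these formulas are the classical steady Poiseuille results
and coincide exactly with the Womersley solution; with a time-varying input
they differ wherever acceleration matters.  The quasi-steady shear can only
reverse when the mean velocity itself reverses.
"""

from __future__ import annotations

import numpy as np

from .womersley import (
    ProfileSeries,
    ShearSeries,
    VesselFluidSpec,
    default_r_grid,
    default_t_grid,
)

__all__ = ["poiseuille_profile", "poiseuille_wss", "poiseuille_flow"]


def _velocity_series(
    U: float | np.ndarray, t_grid: np.ndarray | None, period: float | None
):
    """Normalise scalar-or-series input into (t_grid, u(t), period)."""
    if np.isscalar(U) or (isinstance(U, np.ndarray) and U.ndim == 0):
        if period is None:
            period = 1.0
        t = default_t_grid(period) if t_grid is None else np.asarray(t_grid, float)
        return t, np.full(t.size, float(U)), period
    u = np.asarray(U, dtype=float)
    if t_grid is None:
        raise ValueError("t_grid is required when U is a series")
    t = np.asarray(t_grid, dtype=float)
    if t.size != u.size:
        raise ValueError(f"U series ({u.size}) and t_grid ({t.size}) differ in length")
    if period is None:
        period = float(t[-1] + np.median(np.diff(t)))
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite velocity value")
    return t, u, period


def poiseuille_profile(
    U: float | np.ndarray,
    spec: VesselFluidSpec,
    r_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    period: float | None = None,
) -> ProfileSeries:
    """Quasi-steady parabolic profile U_p(r, t) = 2 U(t) (1 - (r/R)^2).

    ``U`` is the cross-sectional mean velocity: a scalar (steady flow) or a
    series sampled on ``t_grid`` (quasi-steady).  Centerline measurements
    must be halved by the caller before use.
    """
    r = default_r_grid(spec) if r_grid is None else np.asarray(r_grid, dtype=float)
    if np.any(r < 0) or np.any(r > spec.radius * (1 + 1e-12)):
        raise ValueError("r_grid must lie within [0, R]")
    t, u, period = _velocity_series(U, t_grid, period)
    shape = 2.0 * (1.0 - (r / spec.radius) ** 2)
    return ProfileSeries(
        r_grid=r,
        t_grid=t,
        U=np.outer(shape, u),
        method="poiseuille",
        period=period,
    )


def poiseuille_wss(
    U: float | np.ndarray,
    spec: VesselFluidSpec,
    t_grid: np.ndarray | None = None,
    period: float | None = None,
) -> ShearSeries:
    """Quasi-steady wall shear stress tau(t) = 4 mu U(t) / R, antegrade-positive."""
    t, u, period = _velocity_series(U, t_grid, period)
    tau = 4.0 * spec.viscosity * u / spec.radius
    return ShearSeries(t_grid=t, tau_w=tau, method="poiseuille", period=period)


def poiseuille_flow(
    U: float | np.ndarray,
    spec: VesselFluidSpec,
    t_grid: np.ndarray | None = None,
    period: float | None = None,
) -> np.ndarray:
    """Quasi-steady flow rate Q(t) = pi R^2 U(t) in m^3/s."""
    _, u, _ = _velocity_series(U, t_grid, period)
    return np.pi * spec.radius**2 * u
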