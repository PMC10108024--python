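"""Independent numerical checks for the analytic pulsatile-flow solutions.

This module provides test-time ground truth that shares no code path with
the analytic formulas:

* :func:`fd_solve` — an implicit (Crank-Nicolson) finite-difference solver
  for the unsteady axisymmetric Stokes momentum balance

      rho du/dt = G(t) + mu (1/r) d/dr (r du/dr),  u(R) = 0,  du/dr|_0 = 0,

  driven by a harmonic pressure-gradient forcing G(t) = -dp/dx, marched
  from rest cycle by cycle until periodic;
* :func:`numeric_flow` — composite quadrature of 2 pi integral(u r dr); and
* :func:`numeric_wss` — a one-sided second-order wall-gradient estimate,
  sign-flipped to the antegrade-positive convention.

All operations are pure functions of their inputs, so any oracle
disagreement is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import simpson
from scipy.linalg import solve_banded

from .waveform import FourierSpectrum, reconstruct_1d
from .womersley import ProfileSeries, ShearSeries, VesselFluidSpec

__all__ = ["FDGrid", "fd_solve", "numeric_flow", "numeric_wss"]

#: Radial points below which the one-sided wall stencil is considered coarse.
_FINE_NR = 101


@dataclass(frozen=True)
class FDGrid:
    """Discretisation for the time-marching solver.

    ``n_r`` radial points on [0, R]; ``dt`` the time step in seconds;
    ``n_cycles`` the maximum number of cardiac cycles marched while waiting
    for cycle-to-cycle periodicity.
    """

    n_r: int = 201
    dt: float = 2.5e-3
    n_cycles: int = 50

    def __post_init__(self) -> None:
        if self.n_r < 5:
            raise ValueError(f"n_r must be at least 5, got {self.n_r}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_cycles < 3:
            raise ValueError(f"n_cycles must be at least 3, got {self.n_cycles}")


def fd_solve(
    pgrad_spectrum: FourierSpectrum,
    spec: VesselFluidSpec,
    grid: FDGrid = FDGrid(),
    rtol: float = 1e-6,
) -> ProfileSeries:
    """Time-march the pressure-driven pipe-flow PDE to a periodic state.

    ``pgrad_spectrum`` holds the harmonics of -dp/dx in Pa/m.  The scheme is
    Crank-Nicolson in time (unconditionally stable, so dt is set by accuracy)
    and second-order centred in space, with the r = 0 singularity handled by
    symmetry (the diffusion operator reduces to 4 mu (u_1 - u_0)/dr^2 on the
    axis).  Successive cycles are compared in relative L2 norm; the last
    cycle is returned once the difference falls below ``rtol``.
    """
    T = pgrad_spectrum.period
    steps = max(int(round(T / grid.dt)), 8)
    dt = T / steps  # snap so an integer number of steps tiles the cycle
    J = grid.n_r - 1
    dr = spec.radius / J
    r = np.arange(grid.n_r) * dr
    nu = spec.viscosity / spec.density

    # Tridiagonal spatial operator A (rows 0..J-1; u_J = 0 is eliminated).
    lower = np.zeros(J)
    diag = np.zeros(J)
    upper = np.zeros(J)
    diag[0] = -4.0 / dr**2
    upper[0] = 4.0 / dr**2
    j = np.arange(1, J)
    lower[j] = (1.0 - 0.5 / j) / dr**2
    diag[j] = -2.0 / dr**2
    upper[1:J] = 0.0
    upper_vals = (1.0 + 0.5 / j) / dr**2
    upper[j] = np.where(j < J - 1, upper_vals, 0.0)  # u_J = 0 drops the last link

    lam = 0.5 * nu * dt
    # Banded matrix for (I - lam A): rows = [upper, diag, lower]
    ab = np.zeros((3, J))
    ab[0, 1:] = -lam * upper[:-1]
    ab[1, :] = 1.0 - lam * diag
    ab[2, :-1] = -lam * lower[1:]

    def apply_A(u: np.ndarray) -> np.ndarray:
        out = diag * u
        out[:-1] += upper[:-1] * u[1:]
        out[1:] += lower[1:] * u[:-1]
        return out

    t_cycle = np.arange(steps) * dt
    u = np.zeros(J)
    prev_cycle: np.ndarray | None = None
    history = np.zeros((steps, J))
    converged = False
    resid = np.inf
    t_abs = 0.0
    for _ in range(grid.n_cycles):
        for m in range(steps):
            history[m] = u
            g_mid = float(reconstruct_1d(pgrad_spectrum, t_abs + 0.5 * dt)[0])
            rhs = u + lam * apply_A(u) + (dt / spec.density) * g_mid
            u = solve_banded((1, 1), ab, rhs)
            t_abs += dt
        if prev_cycle is not None:
            scale = np.linalg.norm(history)
            resid = np.linalg.norm(history - prev_cycle) / (scale or 1.0)
            if resid < rtol:
                converged = True
                break
        prev_cycle = history.copy()
    if not converged:
        raise RuntimeError(
            f"finite-difference march not periodic after {grid.n_cycles} "
            f"cycles (residual {resid:.3e} > rtol {rtol:.1e})"
        )

    U = np.zeros((grid.n_r, steps))
    U[:J, :] = history.T  # u_J = 0 by construction
    return ProfileSeries(r_grid=r, t_grid=t_cycle, U=U,
                         method="pressure_driven", period=T)


def numeric_flow(p: ProfileSeries) -> np.ndarray:
    """Flow rate 2 pi integral(u r dr) per time sample, by Simpson quadrature."""
    r = p.r_grid
    if not np.isclose(r[0], 0.0):
        raise ValueError("r_grid must start at r = 0 for the flow quadrature")
    return 2.0 * np.pi * simpson(p.U * r[:, None], x=r, axis=0)


def numeric_wss(p: ProfileSeries, spec: VesselFluidSpec) -> ShearSeries:
    """Wall shear stress from a one-sided second-order difference at r = R.

    The literal wall gradient is negated so antegrade shear is positive,
    matching the analytic convention.
    """
    r = p.r_grid
    if r.size < 3:
        raise ValueError("need at least 3 radial points for the wall stencil")
    if r.size < _FINE_NR:
        h = r[-1] - r[-2]
        est = np.max(np.abs(p.U)) * h**2 / max(r[-1], h) ** 3
        warnings.warn(
            f"coarse radial grid ({r.size} points) for the wall stencil; "
            f"estimated truncation error ~{spec.viscosity * est:.2e} Pa",
            stacklevel=2,
        )
    h1 = r[-1] - r[-2]
    h2 = r[-2] - r[-3]
    uw, u1, u2 = p.U[-1], p.U[-2], p.U[-3]
    # general 3-point one-sided first derivative at the last node
    a = (2 * h1 + h2) / (h1 * (h1 + h2))
    b = -(h1 + h2) / (h1 * h2)
    c = h1 / (h2 * (h1 + h2))
    dudr = a * uw + b * u1 + c * u2
    return ShearSeries(
        t_grid=p.t_grid,
        tau_w=-spec.viscosity * dudr,
        method=p.method,
        period=p.period,
    )
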