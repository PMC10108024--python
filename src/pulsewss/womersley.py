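"""Velocity-driven Womersley solution for pulsatile flow in a rigid tube.

Given the harmonic decomposition of a cross-sectional mean velocity waveform,
the axisymmetric velocity profile in a straight rigid vessel of radius R is

    U(r, t) = 2 B0 (1 - (r/R)^2)
            + Real{ sum_n B_n * [1 - J0(L_n r/R)/J0(L_n)]
                              / [1 - 2 J1(L_n)/(L_n J0(L_n))] * e^{i n w t} },

with L_n = alpha sqrt(n) i^{3/2}, alpha = R sqrt(w rho / mu) the Womersley
number, and J0, J1 Bessel functions of the first kind evaluated at complex
argument.  The branch of i^{3/2} is fixed as e^{i 3 pi / 4} (the standard
Womersley convention, giving L_n positive imaginary part).

The per-harmonic normalisation makes the area-averaged velocity of each
harmonic equal its input coefficient, so the cross-sectional mean of
U(., t) reproduces the measured 1D waveform exactly.  Flow rate follows as
Q(t) = pi R^2 U_1D(t), and wall shear stress as the steady Poiseuille part
4 mu B0 / R plus the harmonic wall-gradient terms.

Sign convention: wall shear stress is reported positive in the antegrade
(mean-flow) direction, so steady antegrade flow yields +4 mu U / R even
though the literal radial gradient dU/dr at the wall is negative; retrograde
(proximally directed) shear is negative.

The classical pressure-driven solution is also provided as a comparator; it
takes the harmonics of the axial pressure gradient -dp/dx instead of the
velocity.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Literal

import numpy as np
from scipy.special import jve

from .waveform import FourierSpectrum, reconstruct_1d

__all__ = [
    "DegenerateHarmonicError",
    "VesselFluidSpec",
    "HarmonicFactors",
    "ProfileSeries",
    "ShearSeries",
    "womersley_alpha",
    "harmonic_factors",
    "velocity_profile",
    "centerline_rescale",
    "flow_rate",
    "wall_shear_stress",
    "pressure_driven_profile",
    "default_r_grid",
    "default_t_grid",
]

#: Branch of i^(3/2) used throughout: exp(i 3 pi / 4).
I_3_2 = np.exp(3j * np.pi / 4)

#: Whole-blood defaults: density in kg/m^3, dynamic viscosity in Pa*s.
BLOOD_DENSITY = 1060.0
BLOOD_VISCOSITY = 4.5e-3

DEFAULT_NR = 101
DEFAULT_NT = 200

Method = Literal["womersley", "poiseuille", "pressure_driven"]


class DegenerateHarmonicError(ArithmeticError):
    """A harmonic's Bessel-function factors are numerically degenerate."""


@dataclass(frozen=True)
class VesselFluidSpec:
    """Vessel geometry and fluid properties for one axial location.

    Parameters
    ----------
    radius : float
        Time-averaged lumen radius R in metres.
    omega : float
        Fundamental angular frequency of the cardiac pulse, rad/s.
    viscosity : float
        Dynamic viscosity mu in Pa*s (default 4.5 mPa*s, whole blood).
    density : float
        Density rho in kg/m^3 (default 1060).
    """

    radius: float
    omega: float
    viscosity: float = BLOOD_VISCOSITY
    density: float = BLOOD_DENSITY

    def __post_init__(self) -> None:
        for name in ("radius", "omega", "viscosity", "density"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v}")

    @classmethod
    def from_diameter(
        cls,
        diameter: float,
        omega: float,
        viscosity: float = BLOOD_VISCOSITY,
        density: float = BLOOD_DENSITY,
    ) -> "VesselFluidSpec":
        """Build from the time-averaged lumen diameter (the measured quantity)."""
        return cls(radius=diameter / 2.0, omega=omega,
                   viscosity=viscosity, density=density)

    def alpha(self, n: int = 1) -> float:
        """Womersley number for harmonic n: R * sqrt(n * omega * rho / mu)."""
        return float(
            self.radius * np.sqrt(n * self.omega * self.density / self.viscosity)
        )

    def reynolds(self, mean_velocity: float) -> float:
        """Advisory Reynolds number 2 R U rho / mu for the laminar-flow check."""
        return float(
            2.0 * self.radius * abs(mean_velocity) * self.density / self.viscosity
        )


def womersley_alpha(spec: VesselFluidSpec) -> float:
    """Dimensionless Womersley number alpha = R sqrt(omega rho / mu)."""
    return spec.alpha(1)


def _j_ratios(lam: complex, x: np.ndarray | None = None):
    """Scaled Bessel ratios that stay finite for large |lam|.

    Returns (J1(lam)/J0(lam), J0(lam * x)/J0(lam) for each x in [0, 1]).
    Uses exponentially scaled jve so the ratios never overflow: for x <= 1 the
    rescaling factor exp(-(1-x) |Im lam|) decays.
    """
    j0e = jve(0, lam)
    j1e = jve(1, lam)
    if not np.isfinite(j0e) or abs(j0e) < 1e-300:
        raise DegenerateHarmonicError(
            f"J0 degenerate at Lambda={lam:.4g} (|Lambda|={abs(lam):.4g})"
        )
    ratio10 = j1e / j0e
    if x is None:
        return ratio10, None
    x = np.asarray(x, dtype=float)
    scale = np.exp(-(1.0 - x) * abs(lam.imag))
    ratio0x = jve(0, lam * x) / j0e * scale
    return ratio10, ratio0x


@dataclass(frozen=True)
class HarmonicFactors:
    """Cached complex factors of one Womersley harmonic.

    ``Lambda_n = alpha sqrt(n) i^{3/2}`` with arg(i^{3/2}) = 3 pi / 4;
    ``shape_denominator = 1 - 2 J1(L)/(L J0(L))`` normalises the radial shape
    so its area average is one; ``wall_gradient_factor = L J1(L)/(R J0(L))``
    is the literal dU/dr at the wall of the un-normalised shape.
    """

    n: int
    alpha: float
    radius: float
    Lambda_n: complex
    shape_denominator: complex
    wall_gradient_factor: complex

    def shape(self, r_over_R: np.ndarray) -> np.ndarray:
        """Normalised radial shape (1 - J0(L x)/J0(L)) / shape_denominator."""
        _, ratio0x = _j_ratios(self.Lambda_n, np.asarray(r_over_R, dtype=float))
        return (1.0 - ratio0x) / self.shape_denominator

    @cached_property
    def centerline_value(self) -> complex:
        """Shape at r = 0: (1 - 1/J0(L)) / shape_denominator."""
        lam = self.Lambda_n
        inv_j0 = np.exp(-abs(lam.imag)) / jve(0, lam)
        return complex((1.0 - inv_j0) / self.shape_denominator)


def harmonic_factors(spec: VesselFluidSpec, n: int) -> HarmonicFactors:
    """Bessel-function factors for harmonic n >= 1 of the Womersley solution."""
    if n < 1:
        raise ValueError(f"harmonic index must be >= 1, got {n}")
    alpha = spec.alpha(1)
    lam = complex(alpha * np.sqrt(n) * I_3_2)
    ratio10, _ = _j_ratios(lam)
    denom = 1.0 - 2.0 * ratio10 / lam
    if not np.isfinite(denom) or abs(denom) < 1e-300:
        raise DegenerateHarmonicError(
            f"shape denominator degenerate for n={n}, alpha={alpha:.4g}"
        )
    wall = lam * ratio10 / spec.radius
    return HarmonicFactors(
        n=n,
        alpha=alpha,
        radius=spec.radius,
        Lambda_n=lam,
        shape_denominator=complex(denom),
        wall_gradient_factor=complex(wall),
    )


@dataclass(frozen=True)
class ProfileSeries:
    """Axisymmetric velocity field U(r, t) on a tensor grid.

    ``U`` has shape ``(len(r_grid), len(t_grid))`` with U[i, j] the axial
    velocity at radius ``r_grid[i]`` and time ``t_grid[j]`` (m/s).
    """

    r_grid: np.ndarray
    t_grid: np.ndarray
    U: np.ndarray
    method: Method
    period: float

    def __post_init__(self) -> None:
        r = np.asarray(self.r_grid, dtype=float)
        t = np.asarray(self.t_grid, dtype=float)
        U = np.asarray(self.U, dtype=float)
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "U", U)
        if U.shape != (r.size, t.size):
            raise ValueError(
                f"U shape {U.shape} does not match (n_r={r.size}, n_t={t.size})"
            )
        if not np.all(np.isfinite(U)):
            raise ValueError("non-finite velocity in profile")
        if np.any(np.diff(r) <= 0):
            raise ValueError("r_grid must be strictly ascending")

    @property
    def radius(self) -> float:
        return float(self.r_grid[-1])

    def centerline(self) -> np.ndarray:
        """U(0, t) — valid when r_grid starts at r = 0."""
        return self.U[0]


@dataclass(frozen=True)
class ShearSeries:
    """Wall shear stress tau_w(t) over one cardiac cycle (Pa).

    ``sign_convention`` documents that positive values are antegrade (in the
    mean-flow direction); retrograde shear is negative.
    """

    t_grid: np.ndarray
    tau_w: np.ndarray
    method: Method
    period: float
    sign_convention: str = "antegrade_positive"

    def __post_init__(self) -> None:
        t = np.asarray(self.t_grid, dtype=float)
        tau = np.asarray(self.tau_w, dtype=float)
        object.__setattr__(self, "t_grid", t)
        object.__setattr__(self, "tau_w", tau)
        if t.size != tau.size:
            raise ValueError("t_grid and tau_w differ in length")
        if not np.all(np.isfinite(tau)):
            raise ValueError("non-finite wall shear stress value")
        if not (np.isfinite(self.period) and self.period > 0):
            raise ValueError(f"period must be positive, got {self.period}")


def default_r_grid(spec: VesselFluidSpec, n_r: int = DEFAULT_NR) -> np.ndarray:
    """Uniform radial grid on [0, R] including both endpoints."""
    return np.linspace(0.0, spec.radius, n_r)


def default_t_grid(period: float, n_t: int = DEFAULT_NT) -> np.ndarray:
    """Uniform half-open time grid [0, T)."""
    return np.arange(n_t) * (period / n_t)


def _check_grids(
    spec: VesselFluidSpec,
    spectrum: FourierSpectrum,
    r_grid: np.ndarray | None,
    t_grid: np.ndarray | None,
):
    if not np.isclose(spec.omega, spectrum.omega, rtol=1e-9):
        raise ValueError(
            f"spec.omega={spec.omega:g} does not match spectrum omega="
            f"{spectrum.omega:g}; build the VesselFluidSpec from the waveform"
        )
    r = default_r_grid(spec) if r_grid is None else np.asarray(r_grid, dtype=float)
    t = (
        default_t_grid(spectrum.period)
        if t_grid is None
        else np.atleast_1d(np.asarray(t_grid, dtype=float))
    )
    if r.ndim != 1 or np.any(r < 0) or np.any(r > spec.radius * (1 + 1e-12)):
        raise ValueError("r_grid must lie within [0, R]")
    return r, t


def velocity_profile(
    spectrum: FourierSpectrum,
    spec: VesselFluidSpec,
    r_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
) -> ProfileSeries:
    """Reconstruct the Womersley radial velocity profile U(r, t).

    The spectrum must represent the cross-sectional *mean* velocity; adapt
    centerline measurements with :func:`centerline_rescale` first.  The
    area-average of the returned profile reproduces the input waveform at
    every time point (to quadrature accuracy), and U(R, t) = 0 exactly
    (no-slip).
    """
    if spectrum.mode != "mean":
        raise ValueError(
            "velocity_profile requires a mean-velocity spectrum; apply "
            "centerline_rescale to centerline measurements first"
        )
    r, t = _check_grids(spec, spectrum, r_grid, t_grid)
    x = r / spec.radius
    U = 2.0 * spectrum.B0 * (1.0 - x**2)[:, None] * np.ones((1, t.size))
    if spectrum.N >= 1:
        shapes = np.empty((r.size, spectrum.N), dtype=complex)
        for n in range(1, spectrum.N + 1):
            shapes[:, n - 1] = harmonic_factors(spec, n).shape(x)
        phases = np.exp(
            1j * np.outer(np.arange(1, spectrum.N + 1), spectrum.omega * t)
        )
        U = U + np.real(shapes @ (spectrum.B[:, None] * phases))
    return ProfileSeries(r_grid=r, t_grid=t, U=U, method="womersley",
                         period=spectrum.period)


def centerline_rescale(
    spectrum: FourierSpectrum, spec: VesselFluidSpec
) -> FourierSpectrum:
    """Map a centerline-velocity spectrum onto the mean-velocity equations.

    The steady coefficient is halved (parabolic centerline-to-mean factor);
    each harmonic is divided by its centerline shape value so that the
    reconstructed U(0, t) reproduces the measured centerline waveform.
    """
    if spectrum.mode != "centerline":
        raise ValueError(f"expected a centerline spectrum, got mode={spectrum.mode!r}")
    B = np.empty_like(spectrum.B)
    for n in range(1, spectrum.N + 1):
        c = harmonic_factors(spec, n).centerline_value
        if abs(c) < 1e-12:
            raise DegenerateHarmonicError(
                f"centerline shape value {abs(c):.3g} degenerate for harmonic {n}"
            )
        B[n - 1] = spectrum.B[n - 1] / c
    return FourierSpectrum(
        B0=spectrum.B0 / 2.0,
        B=B,
        omega=spectrum.omega,
        mode="mean",
        label=spectrum.label,
    )


def flow_rate(
    spectrum: FourierSpectrum,
    spec: VesselFluidSpec,
    t_grid: np.ndarray | None = None,
) -> np.ndarray:
    """Volumetric flow rate Q(t) = pi R^2 U_1D(t) in m^3/s.

    For the mean-velocity normalisation, the per-harmonic cross-section
    integral cancels against the shape normalisation, so the flow rate is the
    tube area times the reconstructed 1D waveform.
    """
    if spectrum.mode != "mean":
        raise ValueError("flow_rate requires a mean-velocity spectrum")
    _, t = _check_grids(spec, spectrum, None, t_grid)
    return np.pi * spec.radius**2 * reconstruct_1d(spectrum, t)


def wall_shear_stress(
    spectrum: FourierSpectrum,
    spec: VesselFluidSpec,
    t_grid: np.ndarray | None = None,
) -> ShearSeries:
    """Wall shear stress tau_w(t), antegrade-positive.

    Steady part 4 mu B0 / R (the Poiseuille value) plus the harmonic terms
    -mu * B_n * wall_gradient_factor / shape_denominator, whose sign is
    flipped relative to the literal radial gradient so that antegrade shear
    is positive.  In the alpha -> 0 limit this reduces to the quasi-steady
    value 4 mu U_1D(t) / R.
    """
    if spectrum.mode != "mean":
        raise ValueError("wall_shear_stress requires a mean-velocity spectrum")
    _, t = _check_grids(spec, spectrum, None, t_grid)
    mu, R = spec.viscosity, spec.radius
    tau = np.full(t.size, 4.0 * mu * spectrum.B0 / R)
    if spectrum.N >= 1:
        coeffs = np.empty(spectrum.N, dtype=complex)
        for n in range(1, spectrum.N + 1):
            hf = harmonic_factors(spec, n)
            coeffs[n - 1] = (
                -mu * spectrum.B[n - 1] * hf.wall_gradient_factor / hf.shape_denominator
            )
        phases = np.exp(
            1j * np.outer(np.arange(1, spectrum.N + 1), spectrum.omega * t)
        )
        tau = tau + np.real(coeffs @ phases)
    return ShearSeries(t_grid=t, tau_w=tau, method="womersley",
                       period=spectrum.period)


def pressure_driven_profile(
    pgrad_spectrum: FourierSpectrum,
    spec: VesselFluidSpec,
    r_grid: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
) -> ProfileSeries:
    """Classical pressure-driven Womersley profile.

    ``pgrad_spectrum`` holds the harmonics G_n of the *negative* axial
    pressure gradient -dp/dx in Pa/m.  The solution is the steady Poiseuille
    parabola (G0 R^2 / 4 mu)(1 - (r/R)^2) plus, per harmonic,
    Real{ (G_n / (i rho n omega)) (1 - J0(L_n r/R)/J0(L_n)) e^{i n w t} }.
    """
    r, t = _check_grids(spec, pgrad_spectrum, r_grid, t_grid)
    x = r / spec.radius
    G0 = pgrad_spectrum.B0
    U = (G0 * spec.radius**2 / (4.0 * spec.viscosity)) * (1.0 - x**2)[:, None] * np.ones(
        (1, t.size)
    )
    omega = pgrad_spectrum.omega
    if pgrad_spectrum.N >= 1:
        shapes = np.empty((r.size, pgrad_spectrum.N), dtype=complex)
        for n in range(1, pgrad_spectrum.N + 1):
            hf = harmonic_factors(spec, n)
            _, ratio0x = _j_ratios(hf.Lambda_n, x)
            Gn = pgrad_spectrum.B[n - 1]
            shapes[:, n - 1] = (Gn / (1j * spec.density * n * omega)) * (1.0 - ratio0x)
        phases = np.exp(
            1j * np.outer(np.arange(1, pgrad_spectrum.N + 1), omega * t)
        )
        U = U + np.real(shapes @ phases)
    return ProfileSeries(r_grid=r, t_grid=t, U=U, method="pressure_driven",
                         period=pgrad_spectrum.period)
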