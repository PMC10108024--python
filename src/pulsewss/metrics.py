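"""Hemodynamic summary metrics and method comparison.

The oscillatory shear index (OSI) quantifies how much of the cardiac cycle
the endothelium spends under retrograde wall shear stress:

    OSI = 0.5 * (1 - |integral tau dt| / integral |tau| dt)

over one period, ranging from 0 (non-reversing shear) to 0.5 (purely
oscillatory, zero-mean shear).  Integrals are taken by the trapezoid rule
with periodic closure (the t = T sample equals the t = 0 sample).

`summarize` collects the per-cycle statistics reported for each method
(peak, minimum, cycle-mean, median-over-time, OSI), and `compare` expresses
the quasi-steady Poiseuille estimates relative to the Womersley reference:
positive `pct_diff_median` means Poiseuille overestimates the median shear,
positive `pct_diff_peak` means it underestimates the peak, and positive
`delta_osi` means it underestimates oscillatory shear.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .womersley import Method, ShearSeries

__all__ = ["HemoSummary", "MethodComparison", "osi", "summarize", "compare"]


def _close_cycle(s: ShearSeries):
    """Append the periodic closure sample (t=T, tau(0)) when absent."""
    t, tau = s.t_grid, s.tau_w
    if np.isclose(t[-1], s.period):
        return t, tau
    return np.append(t, s.period), np.append(tau, tau[0])


def osi(s: ShearSeries) -> float:
    """Oscillatory shear index of a single-cycle shear series.

    Returns 0.0 for the degenerate all-zero signal.
    """
    t, tau = _close_cycle(s)
    denom = float(np.trapezoid(np.abs(tau), t))
    if denom == 0.0:
        return 0.0
    num = abs(float(np.trapezoid(tau, t)))
    return float(0.5 * (1.0 - num / denom))


@dataclass(frozen=True)
class HemoSummary:
    """Per-cycle wall shear stress statistics for one reconstruction method."""

    peak_wss: float
    min_wss: float
    time_avg_wss: float
    time_median_wss: float
    osi: float
    method: Method

    def __post_init__(self) -> None:
        # float-roundoff slack: the trapezoid mean of a constant signal can
        # land an ulp above the sample max
        tol = 1e-12 * max(1.0, abs(self.peak_wss), abs(self.min_wss))
        if not self.min_wss - tol <= self.time_avg_wss <= self.peak_wss + tol:
            raise ValueError(
                f"inconsistent summary: min={self.min_wss} mean={self.time_avg_wss} "
                f"peak={self.peak_wss}"
            )
        if not 0.0 <= self.osi <= 0.5 + 1e-12:
            raise ValueError(f"OSI out of range [0, 0.5]: {self.osi}")

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(s: ShearSeries) -> HemoSummary:
    """Peak, minimum, cycle-mean (trapezoid), median-over-samples, and OSI.

    The median is taken over the half-open [0, T) samples; the cycle mean
    uses the trapezoid rule with periodic closure divided by the period.
    """
    t, tau = _close_cycle(s)
    mean = float(np.trapezoid(tau, t) / s.period)
    return HemoSummary(
        peak_wss=float(np.max(s.tau_w)),
        min_wss=float(np.min(s.tau_w)),
        time_avg_wss=mean,
        time_median_wss=float(np.median(s.tau_w)),
        osi=osi(s),
        method=s.method,
    )


@dataclass(frozen=True)
class MethodComparison:
    """Quasi-steady Poiseuille vs Womersley, relative to the Womersley value.

    ``pct_diff_median``: 100 * (P_median - W_median) / W_median — positive
    when Poiseuille overestimates the median shear.
    ``pct_diff_peak``: 100 * (W_peak - P_peak) / W_peak — positive when
    Poiseuille underestimates the peak shear.
    ``delta_osi``: W_osi - P_osi — positive when Poiseuille underestimates
    oscillatory shear.  A field is None when the Womersley reference
    quantity is zero (undefined percentage, flagged rather than NaN).
    """

    pct_diff_median: Optional[float]
    pct_diff_peak: Optional[float]
    delta_osi: float

    def to_dict(self) -> dict:
        return asdict(self)


def compare(poi: HemoSummary, wom: HemoSummary) -> MethodComparison:
    """Compare a quasi-steady Poiseuille summary against the Womersley reference."""
    pct_median = (
        None
        if wom.time_median_wss == 0.0
        else 100.0 * (poi.time_median_wss - wom.time_median_wss) / wom.time_median_wss
    )
    pct_peak = (
        None
        if wom.peak_wss == 0.0
        else 100.0 * (wom.peak_wss - poi.peak_wss) / wom.peak_wss
    )
    return MethodComparison(
        pct_diff_median=pct_median,
        pct_diff_peak=pct_peak,
        delta_osi=wom.osi - poi.osi,
    )
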