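"""Velocity waveforms and their harmonic decomposition.

A pulsed-wave Doppler (or model-derived) recording of arterial velocity over
one cardiac cycle is represented as a :class:`VelocityWaveform`.  Because the
Womersley solution is built harmonic by harmonic, the waveform is decomposed
into complex Fourier coefficients (:class:`FourierSpectrum`) using the
one-sided convention

    U_1D(t) = Real{ B_0 + sum_{n=1}^{N} B_n e^{i n omega t} },

with ``B_0`` the time-averaged mean velocity and ``omega = 2*pi/T`` the
fundamental angular frequency of the cardiac pulse.  The default harmonic
count is ``N = 20``, which captures physiological waveforms sampled at
ordinary ultrasound frame rates.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "WaveformError",
    "VelocityWaveform",
    "FourierSpectrum",
    "load_waveform",
    "resample_uniform",
    "fourier_decompose",
    "reconstruct_1d",
    "spectrum_to_csv",
]

DEFAULT_HARMONICS = 20

#: Hard minimum number of samples per period: periodic cubic interpolation
#: needs four support points.  Eight or more samples are recommended for any
#: real recording.
MIN_SAMPLES = 4

Mode = Literal["mean", "centerline"]


class WaveformError(ValueError):
    """Raised for malformed, inconsistent, or under-sampled velocity input."""


def _as_float_array(x: Iterable[float], name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise WaveformError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class VelocityWaveform:
    """One cardiac cycle of 1D velocity samples.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, all within ``[0, T)``.
    velocities : array of float
        Velocities in m/s (SI).  Finite values only.
    period : float
        Cardiac period ``T`` in seconds.
    mode : {"mean", "centerline"}
        Whether the trace is a cross-sectional mean velocity or the
        centerline (r = 0) velocity.  The reconstruction equations consume
        mean velocity; centerline traces are adapted first
        (see :func:`pulsewss.womersley.centerline_rescale`).
    label : str
        Free-text description carried through to outputs.
    """

    times: np.ndarray
    velocities: np.ndarray
    period: float
    mode: Mode = "mean"
    label: str = ""

    def __post_init__(self) -> None:
        t = _as_float_array(self.times, "times")
        u = _as_float_array(self.velocities, "velocities")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", u)
        if t.size != u.size:
            raise WaveformError(
                f"times ({t.size}) and velocities ({u.size}) differ in length"
            )
        if t.size < MIN_SAMPLES:
            raise WaveformError(
                f"need at least {MIN_SAMPLES} samples per period, got {t.size}"
            )
        if not np.isfinite(self.period) or self.period <= 0:
            raise WaveformError(f"period must be positive, got {self.period}")
        if not np.all(np.isfinite(t)):
            raise WaveformError("non-finite time value in waveform")
        if not np.all(np.isfinite(u)):
            bad = int(np.flatnonzero(~np.isfinite(u))[0])
            raise WaveformError(f"non-finite velocity at sample {bad}")
        dt = np.diff(t)
        if np.any(dt <= 0):
            bad = int(np.flatnonzero(dt <= 0)[0]) + 1
            raise WaveformError(
                f"times must be strictly increasing; sample {bad} "
                f"(t={t[bad]:g} s) does not advance past t={t[bad - 1]:g} s"
            )
        if t[0] < 0 or t[-1] >= t[0] + self.period:
            raise WaveformError(
                f"times must lie within one period [{t[0]:g}, {t[0] + self.period:g})"
            )

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    @property
    def omega(self) -> float:
        """Fundamental angular frequency 2*pi/T in rad/s."""
        return 2.0 * np.pi / self.period

    @property
    def mean(self) -> float:
        """Arithmetic mean of the samples (time-averaged velocity if uniform)."""
        return float(np.mean(self.velocities))

    def is_uniform(self, rtol: float = 1e-8) -> bool:
        """True if samples start at t=0 and are uniformly spaced over [0, T)."""
        t = self.times
        expected = np.arange(t.size) * (self.period / t.size)
        return bool(np.allclose(t, expected, atol=rtol * self.period))


@dataclass(frozen=True)
class FourierSpectrum:
    """One-sided complex harmonic representation of a velocity waveform.

    ``B0`` is real (the mean); ``B[n-1]`` holds the complex coefficient of
    harmonic ``n`` for ``n = 1..N``.  The represented signal is
    ``Real{B0 + sum B_n exp(i n omega t)}``, which is real by construction.
    """

    B0: float
    B: np.ndarray
    omega: float
    mode: Mode = "mean"
    label: str = ""

    def __post_init__(self) -> None:
        B = np.asarray(self.B, dtype=complex)
        object.__setattr__(self, "B", B)
        if B.ndim != 1 or B.size < 1:
            raise WaveformError("spectrum needs at least one harmonic coefficient")
        if not (np.isfinite(self.omega) and self.omega > 0):
            raise WaveformError(f"omega must be positive, got {self.omega}")

    @property
    def N(self) -> int:
        return int(self.B.size)

    @property
    def period(self) -> float:
        return 2.0 * np.pi / self.omega

    def harmonic(self, n: int) -> complex:
        """Coefficient B_n; n=0 returns the real mean."""
        if n == 0:
            return complex(self.B0)
        if not 1 <= n <= self.N:
            raise IndexError(f"harmonic {n} outside 0..{self.N}")
        return complex(self.B[n - 1])


_TIME_SCALE = {"s": 1.0, "ms": 1e-3}
_VEL_SCALE = {"m/s": 1.0, "cm/s": 1e-2}


def load_waveform(
    path: str | Path,
    units: str = "m/s",
    mode: Mode = "mean",
    time_units: str = "s",
    period: float | None = None,
    label: str | None = None,
) -> VelocityWaveform:
    """Read a two-column (time, velocity) delimited text file.

    An optional single header row is skipped automatically.  Velocities may be
    in m/s or cm/s and times in s or ms; both are converted to SI.  Unless
    given explicitly, the period is inferred as the sampled span plus one
    median sampling interval, i.e. the grid is taken as half-open ``[0, T)``.
    """
    path = Path(path)
    if units not in _VEL_SCALE:
        raise WaveformError(f"unknown velocity units {units!r}; use 'm/s' or 'cm/s'")
    if time_units not in _TIME_SCALE:
        raise WaveformError(f"unknown time units {time_units!r}; use 's' or 'ms'")

    times: list[float] = []
    vels: list[float] = []
    with path.open(newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        try:
            dialect = csv.Sniffer().sniff(sample, delimiters=",;\t ")
        except csv.Error:
            dialect = csv.excel
        for i, row in enumerate(csv.reader(fh, dialect), start=1):
            row = [c for c in row if c.strip()]
            if not row:
                continue
            if len(row) < 2:
                raise WaveformError(f"{path.name} row {i}: expected two columns, got {row!r}")
            try:
                t, u = float(row[0]), float(row[1])
            except ValueError:
                if i == 1 and not times:  # header row
                    continue
                raise WaveformError(
                    f"{path.name} row {i}: could not parse {row!r} as numbers"
                ) from None
            times.append(t)
            vels.append(u)

    if len(times) < MIN_SAMPLES:
        raise WaveformError(
            f"{path.name}: found {len(times)} samples; need at least {MIN_SAMPLES}"
        )
    t = np.asarray(times) * _TIME_SCALE[time_units]
    u = np.asarray(vels) * _VEL_SCALE[units]
    dt = np.diff(t)
    dup = np.flatnonzero(dt == 0)
    if dup.size:
        raise WaveformError(
            f"{path.name} row {dup[0] + 2}: duplicated time value t={t[dup[0]]:g} s"
        )
    if np.any(dt < 0):
        bad = int(np.flatnonzero(dt < 0)[0]) + 2
        raise WaveformError(f"{path.name} row {bad}: times decrease")
    t = t - t[0]
    if period is None:
        period = float(t[-1] + np.median(np.diff(t)))
    return VelocityWaveform(t, u, period=period, mode=mode, label=label or path.stem)


def resample_uniform(
    w: VelocityWaveform, M: int, n_harmonics: int | None = None
) -> VelocityWaveform:
    """Resample onto ``M`` uniform points on [0, T) by periodic cubic interpolation.

    If ``n_harmonics`` is given, ``M >= 2*n_harmonics + 2`` is enforced so the
    subsequent DFT resolves every requested harmonic.  When the input grid
    spans essentially the whole closed period (last sample within half a
    median interval of ``T``), a linear detrend between the first and last
    samples removes cycle-to-cycle drift before the periodic fit.
    """
    if n_harmonics is not None and M < 2 * n_harmonics + 2:
        raise WaveformError(
            f"M={M} violates the Nyquist constraint M >= 2N+2 = "
            f"{2 * n_harmonics + 2} for N={n_harmonics} harmonics"
        )
    if M < MIN_SAMPLES:
        raise WaveformError(f"M must be at least {MIN_SAMPLES}, got {M}")

    T = w.period
    t = w.times - w.times[0]
    u = w.velocities.astype(float).copy()
    med_dt = float(np.median(np.diff(t)))

    if T - t[-1] < 0.5 * med_dt and t.size > MIN_SAMPLES:
        # closed-span recording: remove endpoint drift, then wrap exactly
        drift = (u[-1] - u[0]) / (t[-1] - t[0])
        u = u - drift * t
        t_ext = np.concatenate([t[:-1], [T]])
        u_ext = np.concatenate([u[:-1], [u[0]]])
    else:
        t_ext = np.concatenate([t, [T]])
        u_ext = np.concatenate([u, [u[0]]])

    spline = CubicSpline(t_ext, u_ext, bc_type="periodic")
    t_new = np.arange(M) * (T / M)
    return VelocityWaveform(
        t_new, spline(t_new), period=T, mode=w.mode, label=w.label
    )


def fourier_decompose(
    w: VelocityWaveform, N: int = DEFAULT_HARMONICS
) -> FourierSpectrum:
    """Decompose a uniformly sampled waveform into N one-sided harmonics.

    ``B0`` is the arithmetic mean of the samples; for n >= 1,
    ``B_n = (2/M) * sum_k u_k exp(-i n omega t_k)``.
    """
    if N < 1:
        raise WaveformError(f"harmonic count must be >= 1, got {N}")
    M = w.n_samples
    if M < 2 * N + 2:
        raise WaveformError(
            f"waveform has M={M} samples; need M >= 2N+2 = {2 * N + 2} for "
            f"N={N} harmonics (resample first)"
        )
    if not w.is_uniform():
        raise WaveformError(
            "fourier_decompose requires uniform sampling on [0, T); "
            "use resample_uniform first"
        )
    n = np.arange(1, N + 1)
    phase = np.exp(-1j * np.outer(n, w.omega * w.times))  # (N, M)
    B = (2.0 / M) * phase @ w.velocities
    return FourierSpectrum(
        B0=float(np.mean(w.velocities)), B=B, omega=w.omega, mode=w.mode, label=w.label
    )


def reconstruct_1d(s: FourierSpectrum, t: np.ndarray | float) -> np.ndarray:
    """Evaluate Real{B0 + sum B_n e^{i n omega t}} on a time grid."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    n = np.arange(1, s.N + 1)
    phase = np.exp(1j * np.outer(n, s.omega * t))  # (N, nt)
    return s.B0 + np.real(s.B @ phase)


def spectrum_to_csv(s: FourierSpectrum, path: str | Path) -> None:
    """Export harmonics as rows (n, Re B_n, Im B_n); n = 0 is the mean."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["n", "re", "im"])
        writer.writerow([0, repr(s.B0), repr(0.0)])
        for n in range(1, s.N + 1):
            b = s.harmonic(n)
            writer.writerow([n, repr(b.real), repr(b.imag)])
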