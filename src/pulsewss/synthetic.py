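"""Synthetic arterial velocity waveforms for testing and demonstration.

Two kinds of inputs are generated:

* a single-harmonic cosine test waveform (mean 0.20 m/s, period 1.0 s by
  default), used to demonstrate the split of the reconstruction into steady
  and unsteady components; and
* multiharmonic templates emulating the canonical waveform classes of the
  large conduit arteries — a monophasic carotid-like waveform (velocity
  antegrade throughout the cycle) and triphasic brachial-like and
  femoral-like waveforms (forward systolic phase, brief flow reversal,
  secondary forward phase).

Templates are deterministic fixtures: a fixed table of relative harmonic
amplitudes and phases, evaluated as

    u(t) = mean * (1 + sum_n a_n cos(n omega t + phi_n)),

so the discrete time-mean over a uniform grid equals ``mean`` exactly and
the waveform is band-limited to the table.  The tables are designed to
resemble the published waveform classes and to satisfy the class invariants
(monophasic: u >= 0 everywhere; triphasic: min u < 0 < mean); they are not
digitisations of any specific recording.  Heart-rate sweeps reuse the same
table at periods 60/rate, emulating rest (70 beats/min) and two stress
states (100 and 150 beats/min).

Default vessel diameters per template are back-computed from representative
rest-state Womersley numbers in the conduit arteries (alpha of 4.3, 4.2 and
4.8 for carotid, brachial and femoral at 70 beats/min with blood density
1060 kg/m^3 and viscosity 4.5 mPa*s).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .waveform import VelocityWaveform
from .womersley import BLOOD_DENSITY, BLOOD_VISCOSITY

__all__ = [
    "TemplateError",
    "WaveformTemplate",
    "make_cosine",
    "make_template",
    "sweep_states",
    "TEMPLATES",
    "template_names",
    "default_diameter",
]


class TemplateError(ValueError):
    """A generated waveform violates its template's phase-class invariant."""


@dataclass(frozen=True)
class WaveformTemplate:
    """Deterministic multiharmonic waveform recipe.

    ``harmonic_table`` rows are (n, relative amplitude, phase in radians);
    amplitudes are relative to ``mean_velocity``.  ``jitter`` > 0 adds
    seeded, low-amplitude high-harmonic noise for robustness tests
    (default off).
    """

    name: str
    heart_rate: float
    mean_velocity: float
    harmonic_table: tuple[tuple[int, float, float], ...]
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.heart_rate <= 0:
            raise TemplateError(f"heart rate must be positive, got {self.heart_rate}")
        if not self.harmonic_table:
            raise TemplateError("harmonic_table must be nonempty")
        for row in self.harmonic_table:
            n = row[0]
            if int(n) != n or n < 1:
                raise TemplateError(f"harmonic index must be a positive integer: {row}")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def at_rate(self, heart_rate: float) -> "WaveformTemplate":
        return replace(self, heart_rate=heart_rate)


def make_cosine(
    mean: float = 0.20,
    amplitude: float = 0.05,
    period: float = 1.0,
    M: int = 256,
) -> VelocityWaveform:
    """Single-harmonic test waveform u(t) = mean + amplitude cos(2 pi t / T)."""
    if M < 16:
        raise ValueError(f"need at least 16 samples for the cosine test, got {M}")
    t = np.arange(M) * (period / M)
    u = mean + amplitude * np.cos(2.0 * np.pi * t / period)
    return VelocityWaveform(t, u, period=period, mode="mean", label="cosine")


#: Monophasic / triphasic classification used to enforce template invariants.
_MONOPHASIC = {"carotid_like"}
_TRIPHASIC = {"brachial_like", "femoral_like"}


def make_template(template: WaveformTemplate, M: int = 256) -> VelocityWaveform:
    """Evaluate a template on M uniform samples over one period.

    The result is exactly periodic and band-limited to the harmonic table
    (plus the optional seeded jitter band).  The mono/triphasic class
    invariant of named arterial templates is asserted after generation.
    """
    max_n = max(int(row[0]) for row in template.harmonic_table)
    jitter_top = max_n + 5 if template.jitter > 0 else max_n
    if M < 2 * jitter_top + 2:
        raise TemplateError(
            f"M={M} cannot resolve harmonic {jitter_top}; need M >= {2 * jitter_top + 2}"
        )
    T = template.period
    t = np.arange(M) * (T / M)
    omega = 2.0 * np.pi / T
    u = np.ones(M)
    for n, amp, phase in template.harmonic_table:
        u += amp * np.cos(n * omega * t + phase)
    if template.jitter > 0:
        rng = np.random.default_rng(template.seed)
        for n in range(max_n + 1, jitter_top + 1):
            u += (
                template.jitter
                * rng.uniform(0.5, 1.0)
                * np.cos(n * omega * t + rng.uniform(0, 2 * np.pi))
            )
    u *= template.mean_velocity
    w = VelocityWaveform(t, u, period=T, mode="mean", label=template.name)
    _check_phase_class(template.name, w)
    return w


def _check_phase_class(name: str, w: VelocityWaveform) -> None:
    umin = float(np.min(w.velocities))
    if name in _MONOPHASIC and umin < 0:
        raise TemplateError(
            f"{name}: monophasic template produced negative velocity "
            f"(min {umin:.4g} m/s)"
        )
    if name in _TRIPHASIC and not (umin < 0 < w.mean):
        raise TemplateError(
            f"{name}: triphasic template must reverse (min {umin:.4g}, "
            f"mean {w.mean:.4g} m/s)"
        )


def sweep_states(
    template: WaveformTemplate,
    rates: Sequence[float] = (70.0, 100.0, 150.0),
    M: int = 256,
) -> list[VelocityWaveform]:
    """One waveform per heart rate, each with period 60/rate seconds."""
    out = []
    for rate in rates:
        if rate <= 0:
            raise TemplateError(f"heart rate must be positive, got {rate}")
        out.append(make_template(template.at_rate(rate), M=M))
    return out


# ---------------------------------------------------------------------------
# Fixed template fixtures.  Relative harmonic amplitudes/phases designed
# time-domain-first (systolic pulse, dicrotic notch, early-diastolic reverse
# phase where triphasic), truncated to 10 harmonics and frozen.
# ---------------------------------------------------------------------------

_CAROTID_TABLE = (
    (1, 0.54, -1.02),
    (2, 0.384, -1.63),
    (3, 0.407, -2.27),
    (4, 0.365, 3.02),
    (5, 0.232, 2.06),
    (6, 0.137, 1.38),
    (7, 0.1, 0.67),
    (8, 0.064, -0.25),
    (9, 0.033, -1.13),
    (10, 0.016, -1.88),
)

_BRACHIAL_TABLE = (
    (1, 0.658, -0.41),
    (2, 1.023, -0.93),
    (3, 1.287, -2.01),
    (4, 1.043, 3.09),
    (5, 0.581, 2.08),
    (6, 0.297, 1.48),
    (7, 0.197, 0.98),
    (8, 0.138, 0.41),
    (9, 0.104, -0.28),
    (10, 0.07, -1.14),
)

_FEMORAL_TABLE = (
    (1, 0.619, -0.5),
    (2, 0.928, -1.11),
    (3, 1.055, -2.3),
    (4, 0.725, 2.74),
    (5, 0.335, 1.77),
    (6, 0.168, 1.23),
    (7, 0.102, 0.63),
    (8, 0.066, 0.01),
    (9, 0.043, -0.87),
    (10, 0.021, -1.88),
)

TEMPLATES: dict[str, WaveformTemplate] = {
    "carotid_like": WaveformTemplate(
        name="carotid_like",
        heart_rate=70.0,
        mean_velocity=0.24,
        harmonic_table=_CAROTID_TABLE,
    ),
    "brachial_like": WaveformTemplate(
        name="brachial_like",
        heart_rate=70.0,
        mean_velocity=0.08,
        harmonic_table=_BRACHIAL_TABLE,
    ),
    "femoral_like": WaveformTemplate(
        name="femoral_like",
        heart_rate=70.0,
        mean_velocity=0.10,
        harmonic_table=_FEMORAL_TABLE,
    ),
}

#: Rest-state Womersley numbers used to back-compute default diameters.
_REST_ALPHA = {"carotid_like": 4.3, "brachial_like": 4.2, "femoral_like": 4.8}
_REST_OMEGA = 2.0 * np.pi * 70.0 / 60.0


def template_names() -> list[str]:
    return sorted(TEMPLATES)


def default_diameter(name: str) -> float:
    """Time-averaged lumen diameter (m) paired with a template.

    Chosen so the rest-state (70 beats/min) Womersley number matches the
    representative conduit-artery values documented above.
    """
    if name == "cosine":
        return 4e-3
    if name not in _REST_ALPHA:
        raise TemplateError(
            f"unknown template {name!r}; available: {', '.join(template_names())}"
        )
    alpha = _REST_ALPHA[name]
    R = alpha * np.sqrt(BLOOD_VISCOSITY / (_REST_OMEGA * BLOOD_DENSITY))
    return float(2.0 * R)
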