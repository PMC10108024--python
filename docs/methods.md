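# Methods

## Physical model and assumptions

The package models blood flow at a single axial station of a conduit artery
as fully developed, laminar, axisymmetric flow of a Newtonian fluid in a
long, straight, rigid circular tube. Under these assumptions the axial
momentum balance is linear,

ρ ∂u/∂t = G(t) + μ (1/r) ∂/∂r (r ∂u/∂r),  u(R, t) = 0,  ∂u/∂r|₀ = 0,

with G(t) = −∂p/∂x, and the periodic solution decomposes exactly by
harmonic. The classical (pressure-driven) Womersley solution takes the
harmonics of G; the package's primary, velocity-driven formulation instead
takes the harmonics Bₙ of the measured cross-sectional mean velocity
U₁D(t) and normalises each harmonic's radial shape

S_n(r) = (1 − J₀(Λₙ r/R)/J₀(Λₙ)) / (1 − 2J₁(Λₙ)/(Λₙ J₀(Λₙ)))

so that its area average is exactly 1. Consequences used throughout:

* the area-mean of the reconstructed profile reproduces U₁D(t) identically;
* the flow rate collapses to Q(t) = πR²·U₁D(t);
* wall shear stress is the steady Poiseuille part 4μB₀/R plus per-harmonic
  wall-gradient terms.

Assumptions *not* satisfied by real arteries — wall elasticity, taper,
curvature, bifurcations, secondary and transitional/turbulent flow,
non-Newtonian rheology — are out of scope; the model is appropriate for
long non-bifurcating segments of large conduit arteries under laminar
conditions. A Reynolds-number advisory (Re = 2RŪρ/μ, warning above 2000)
is printed by the CLI but never enforced.

## Conventions

* **Fourier convention.** One-sided coefficients: B₀ is the arithmetic mean
  of the uniformly sampled waveform; Bₙ = (2/M) Σₖ uₖ e^{−inωt_k} for
  n ≥ 1, and signals are reconstructed as Re{B₀ + Σ Bₙ e^{inωt}}. No
  windowing is applied: the waveform is treated as exactly periodic.
  Non-uniform inputs are resampled by periodic cubic interpolation to
  M = max(256, 4(2N+2)) points; when a recording spans the closed period
  (its last sample falls within half a median interval of T), a linear
  detrend between first and last samples removes cycle-to-cycle drift
  before the periodic fit.
* **Branch of i^{3/2}.** Fixed as e^{i3π/4}, so Λₙ = α√n·e^{i3π/4} has
  positive imaginary part (the standard Womersley convention). This is
  asserted in the tests.
* **Sign of WSS.** Reported antegrade-positive: steady antegrade flow gives
  τ_w = +4μŪ/R although the literal wall gradient dU/dr|_R is negative.
  The harmonic terms are negated accordingly, which is verified against a
  finite-difference wall-gradient oracle and recovers the quasi-steady
  value 4μU₁D(t)/R in the α → 0 limit. Retrograde (proximally directed)
  shear is negative.
* **Pressure-driven harmonics.** For forcing Re{Gₙ e^{inωt}} the harmonic
  amplitude is Gₙ/(iρnω)·(1 − J₀(Λₙr/R)/J₀(Λₙ)); the sign/branch choice is
  fixed by requiring the α → 0 limit to recover the quasi-steady Poiseuille
  parabola, and is independently confirmed by the finite-difference solver.
* **Centerline inputs.** The governing equations consume mean velocity. A
  centerline spectrum is adapted by halving B₀ and dividing each harmonic
  by its complex centerline shape value Sₙ(0), so U(0,t) reproduces the
  measurement; at α → 0 every factor tends to the parabolic value 2.

## Numerical choices

* **Bessel evaluation.** J₀, J₁ at complex argument via exponentially
  scaled `scipy.special.jve`; only the ratios J₁(Λ)/J₀(Λ) and
  J₀(Λx)/J₀(Λ) (x ≤ 1) enter the formulas, and in scaled form they remain
  finite far beyond the physiological α range (tested at α ≈ 97, n = 20).
  Factors with |J₀| or |shape denominator| below 1e−300 raise a
  degenerate-harmonic error naming the harmonic and α.
* **Grids.** Default radial grid: 101 uniform points on [0, R] including
  both endpoints; default time grid: 200 points on the half-open [0, T).
  Oracle comparisons use 801 radial points so the second-order one-sided
  wall stencil contributes negligible truncation error.
* **Integrals.** OSI and cycle means use the trapezoid rule with periodic
  closure (a t = T sample equal to the t = 0 sample is appended when
  absent). "Time-averaged median" WSS for a 1D signal is implemented as
  the median over the [0, T) time samples, with the cycle mean reported
  alongside, since a circumferential median is not meaningful for an
  axisymmetric 1D signal.
* **Finite-difference oracle.** Crank–Nicolson in time (unconditionally
  stable, so dt is chosen for accuracy: default T/400) and second-order
  centred differences in space with the axis singularity handled by
  symmetry. The march starts from rest and stops when successive cycles
  differ by < 1e−6 in relative L2 norm; the slowest transient decays like
  exp(−j₀₁²μt/ρR²), so the default 50-cycle cap covers α ≤ ~10.
  Second-order spatial convergence is asserted in the tests.
* **Degenerate inputs.** Zero spectra produce identically zero fields; the
  OSI of an identically zero shear signal is defined as 0; comparisons
  against a zero Womersley reference return flagged (None) percentages
  rather than NaN.

## Synthetic waveforms: what they emulate and what they do not

The generator produces the study's input conditions without any external
data:

* **Cosine test** — u(t) = 0.20 + 0.05·cos(2πt/1.0) m/s (mean 20 cm/s,
  period 1.0 s): a single-harmonic input whose reconstruction splits
  cleanly into steady and unsteady parts.
* **Arterial templates** — fixed tables of relative harmonic amplitudes and
  phases, u(t) = ū(1 + Σ aₙ cos(nωt + φₙ)), truncated at 10 harmonics.
  They were designed time-domain-first (sharp systolic upstroke and
  deceleration, dicrotic/secondary features, and for the limb arteries an
  early-diastolic reverse phase) to fall into the canonical waveform
  classes: `carotid_like` is monophasic (velocity ≥ 0 throughout, enforced
  at generation), `brachial_like` and `femoral_like` are triphasic
  (min < 0 < mean, enforced). Mean velocities (0.24, 0.08, 0.10 m/s) are
  representative resting values for the respective arteries.
* **Heart-rate sweep** — the same tables evaluated at 70, 100, 150
  beats/min (periods 60/rate), emulating rest and two cardiovascular
  stress states. α grows with √rate.
* **Default diameters** — back-computed from representative rest-state
  Womersley numbers of the three arteries (α = 4.3, 4.2, 4.8 at
  70 beats/min with the default blood properties), giving D ≈ 6.55, 6.39
  and 7.31 mm, so the fixtures exercise the physiological α ≈ 4–7 regime.

The templates are *not* digitisations of any measured or published
waveform: passing tests demonstrate the correctness of the reconstruction
machinery and the direction and rough magnitude of the
Poiseuille-vs-Womersley contrast in the physiological regime, not
agreement with any specific subject's hemodynamics. Real Doppler traces
additionally contain measurement noise, beat-to-beat variability and
envelope-extraction artefacts that the generator does not model (an
optional seeded high-harmonic jitter is available for robustness tests,
default off).

## Design choices where the design was open

* The DFT normalisation (one-sided, factor 2/M) was chosen so the
  coefficients feed the single-sided harmonic sums directly.
* The flow-rate expression is implemented as Q(t) = πR²U₁D(t), the
  algebraic consequence of the mean-normalised profile; the per-harmonic
  cross-section integral cancels against the shape normalisation.
* Waveforms need at least 4 samples (the minimum for periodic cubic
  interpolation); 8 or more per cycle are recommended, and N is always
  capped by the Nyquist constraint M ≥ 2N + 2.
* Problem sizes in the test and acceptance runs (M = 256-sample waveforms,
  801-point oracle grids, 201-point/400-step finite-difference marches at
  α ∈ {2, 4, 7}) were chosen as the smallest grids at which all oracle
  tolerances are met with an order of magnitude to spare; the entire suite
  completes in seconds.

## Known limitations

* Rigid straight tube, Newtonian fluid, laminar flow — see assumptions.
* The period is taken as exactly the sampled cycle; multi-beat ensemble
  averaging and envelope extraction from Doppler spectrograms are out of
  scope.
* Harmonics above N = 20 (or above the Nyquist limit of the recording) are
  discarded; very sharp waveform features are accordingly smoothed.
* The quasi-steady comparator is evaluated on the same time grid with no
  smoothing, which is the fair like-for-like contrast but means its
  percentages inherit any band-limiting of the input.
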