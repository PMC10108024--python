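"""Steady/unsteady split of the reconstruction on a cosine test waveform.

Builds the single-harmonic test input (mean 20 cm/s, period 1.0 s), feeds it
through the Womersley reconstruction for a 4 mm vessel, and prints the
velocity profile at peak deceleration (t = 0.25 s) split into its steady
(parabolic, Poiseuille) and unsteady (harmonic) components.  The unsteady
part is what the quasi-steady approximation throws away.
"""

import numpy as np

import pulsewss as pw

wave = pw.make_cosine(mean=0.20, amplitude=0.05, period=1.0, M=256)
spectrum = pw.fourier_decompose(wave, N=20)
vessel = pw.VesselFluidSpec.from_diameter(4e-3, omega=wave.omega)
print(f"Womersley number alpha = {vessel.alpha():.2f}")

r = np.linspace(0.0, vessel.radius, 9)
t = np.array([0.25, 0.75])
womersley = pw.velocity_profile(spectrum, vessel, r_grid=r, t_grid=t)

# steady component alone: zero out the harmonics
steady_only = pw.FourierSpectrum(B0=spectrum.B0, B=np.zeros_like(spectrum.B),
                                 omega=spectrum.omega)
steady = pw.velocity_profile(steady_only, vessel, r_grid=r, t_grid=t)

print(f"\n{'r/R':>5} | {'steady':>8} {'unsteady':>9} {'total':>8}   (m/s, at t = 0.25 s)")
for i, ri in enumerate(r):
    tot, std = womersley.U[i, 0], steady.U[i, 0]
    print(f"{ri / vessel.radius:5.2f} | {std:8.4f} {tot - std:9.4f} {tot:8.4f}")

u_in = pw.reconstruct_1d(spectrum, t)
mean = pw.numeric_flow(pw.velocity_profile(spectrum, vessel,
                                           r_grid=np.linspace(0, vessel.radius, 801),
                                           t_grid=t)) / (np.pi * vessel.radius**2)
print(f"\narea-mean of profile at t=0.25 s: {mean[0]:.6f} m/s "
      f"(input waveform value {u_in[0]:.6f} m/s)")
print("The steady column is the parabola 2*B0*(1-(r/R)^2); the unsteady column")
print("is the acceleration-dependent correction the Poiseuille model ignores.")
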