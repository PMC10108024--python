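"""Velocity-driven solution vs the classical pressure-driven solution.

Solves a three-harmonic pressure-gradient problem three ways at alpha = 4:
(1) the classical analytic pressure-driven Womersley profile, (2) an
independent implicit finite-difference march of the momentum equation, and
(3) the velocity-driven reconstruction fed only the area-mean velocity of
the finite-difference solution — i.e. exactly what one measures with
Doppler.  Agreement of (3) with (1)-(2) is what makes the velocity-driven
method usable without invasive pressure-gradient data.
"""

import numpy as np

import pulsewss as pw

omega = 2.0 * np.pi  # 60 beats/min
R = 4.0 * np.sqrt(4.5e-3 / (omega * 1060.0))  # radius giving alpha = 4
vessel = pw.VesselFluidSpec(radius=R, omega=omega)
pgrad = pw.FourierSpectrum(B0=100.0, B=np.array([80 + 30j, 40 - 20j, 15 + 10j]),
                           omega=omega)

fd = pw.fd_solve(pgrad, vessel, pw.FDGrid(n_r=201, dt=1 / 400, n_cycles=60))
analytic = pw.pressure_driven_profile(pgrad, vessel, r_grid=fd.r_grid,
                                      t_grid=fd.t_grid)
peak = np.max(np.abs(analytic.U))
print(f"alpha = {vessel.alpha():.1f}, R = {R * 1e3:.2f} mm, "
      f"peak velocity = {peak:.4f} m/s")
print(f"finite-difference vs analytic profile: max deviation "
      f"{np.max(np.abs(fd.U - analytic.U)) / peak * 100:.4f}% of peak")

# velocity-driven loop: only the mean velocity trace goes in
u_mean = pw.numeric_flow(fd) / (np.pi * R**2)
wave = pw.VelocityWaveform(fd.t_grid, u_mean, period=pgrad.period)
spectrum = pw.fourier_decompose(wave, N=10)
tau_v = pw.wall_shear_stress(spectrum, vessel, fd.t_grid)

fine = pw.pressure_driven_profile(pgrad, vessel,
                                  r_grid=np.linspace(0, R, 801), t_grid=fd.t_grid)
tau_ref = pw.numeric_wss(fine, vessel)
err = np.max(np.abs(tau_v.tau_w - tau_ref.tau_w)) / np.max(np.abs(tau_ref.tau_w))
print(f"velocity-driven WSS vs pressure-driven reference: max deviation "
      f"{err * 100:.4f}% of peak")
print(f"peak WSS = {np.max(tau_ref.tau_w):.3f} Pa, "
      f"min WSS = {np.min(tau_ref.tau_w):.3f} Pa")
print("\nSub-percent agreement: the mean-velocity trace alone carries enough")
print("information to recover the full unsteady wall shear stress.")
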