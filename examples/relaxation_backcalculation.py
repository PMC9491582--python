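"""Back-calculate 15N R1/R2 spin relaxation from a trajectory.

Builds a pseudo-peptide whose N-H bonds undergo isotropic rotational
diffusion with a 2 ns correlation time, runs the full pipeline (P2
correlation function -> constrained multiexponential fit -> spectral
density -> relaxation rates at 600 MHz), and compares with the closed-form
single-Lorentzian answer.
"""
import numpy as np

import idpdyn
from idpdyn.relaxation import MultiExpFit

TAU_C = 2000.0  # ps

traj = idpdyn.rotor_nh_trajectory(n_residues=5, tau_c=TAU_C,
                                  frame_interval=10.0, n_frames=100000, seed=8)
fc = idpdyn.field_constants(600.0)  # proton Larmor frequency in MHz
result = idpdyn.per_residue_pipeline([traj], fc)
print("per-residue back-calculated rates (s^-1):")
print(result.rates.to_string(index=False))

r1_ref, r2_ref = idpdyn.relaxation_rates(
    MultiExpFit(np.array([1.0]), np.array([TAU_C])), fc)
print(f"\nanalytic rigid-rotor reference at tau_c = {TAU_C / 1000:.0f} ns: "
      f"R1 = {r1_ref:.3f}, R2 = {r2_ref:.3f} s^-1")
print("each residue's rates should scatter within a few percent of the "
      "reference; residue 1 is absent (no amide proton at the N-terminus)")

modes = idpdyn.timescale_summary(result.fits, threshold=100.0)
print("\nfitted correlation-time modes (tau NaN = aggregate of sub-100-ps "
      "librational amplitude):")
print(modes.to_string(index=False))
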