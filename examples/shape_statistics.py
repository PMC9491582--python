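"""Gyration-tensor shape statistics of an ideal-chain ensemble.

Generates 20,000 Gaussian chains of 73 beads (a random-coil reference the
size of a small disordered protein), computes per-conformer radius of
gyration, asphericity A and prolateness P, and fits the Flory scaling law
across chain lengths.
"""
import numpy as np

import idpdyn

frames = idpdyn.gaussian_chain_ensemble(n_beads=73, bond_rms=1.0,
                                        n_conformers=20000, seed=1)
summary = idpdyn.shape_summary(frames)
print(f"<Rg>  = {summary.mean_rg:.3f} bond lengths "
      f"(ideal-chain sqrt(<Rg^2>) = {np.sqrt(idpdyn.gaussian_chain_rg2(73)):.3f})")
print(f"<A>   = {summary.mean_asphericity:.3f}   "
      "(0 = sphere, 1 = rod; ideal chains are markedly aspherical)")
print(f"<P>   = {summary.mean_prolateness:.3f}   "
      "(+1 = cigar, -1 = disk; ideal chains are predominantly prolate)")

# Flory scaling: <Rg> = rho0 * N^nu; ideal chains must give nu = 1/2
ns = [16, 32, 64, 128]
mean_rgs = []
for n in ns:
    f = idpdyn.gaussian_chain_ensemble(n, 1.0, 5000, seed=10 + n)
    c = f - f.mean(axis=1, keepdims=True)
    mean_rgs.append(np.sqrt(np.einsum("fia,fia->f", c, c) / n).mean())
fit = idpdyn.fit_flory(mean_rgs, ns)
print(f"Flory fit over N = {ns}: nu = {fit.nu:.3f} (ideal chain: 0.500), "
      f"rho0 = {fit.rho0:.3f}")

# The same inversion applied to a measured ensemble average: a 73-residue
# chain with <Rg> = 28.1 Å and rho0 = 1.927 Å per residue is expanded well
# beyond an ideal coil.
nu = idpdyn.flory_nu(mean_rg=28.1, rho0=1.927, n_residues=73)
print(f"nu from <Rg> = 28.1 Å at N = 73: {nu:.4f} "
      "(> 0.588 of a self-avoiding coil: an expanded disordered chain)")
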