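import numpy as np
import pytest

import idpdyn


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def bead_trajectory():
    """Small Rouse bead-chain trajectory shared by I/O and analysis tests."""
    return idpdyn.harmonic_chain_trajectory(
        n_beads=8, relax_time=100.0, bond_rms=3.8, frame_interval=10.0,
        n_frames=200, seed=7,
    )


@pytest.fixture(scope="session")
def peptide_trajectory():
    """Tiny pseudo-peptide with N/H atoms whose bonds undergo rotational diffusion."""
    return idpdyn.rotor_nh_trajectory(
        n_residues=4, tau_c=300.0, frame_interval=10.0, n_frames=3000, seed=11,
    )
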