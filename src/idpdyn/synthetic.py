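"""Synthetic inputs with known statistical structure.

Every analysis stage in this package assumes a particular kind of signal:
stationary scalar series with multi-exponential memory (radius of
gyration), unit-vector series with exponential orientational correlation
(N-H bonds), ideal-chain conformational ensembles (the random-coil
reference), and residue-pair contact streams.  The generators here produce
exactly those signals with closed-form ground truth, so each stage can be
tested against an oracle without molecular-dynamics input.

All generators are pure functions of (parameters, seed).  The
Ornstein-Uhlenbeck and Rouse-mode updates use the exact stationary
discretization x <- x*exp(-dt/tau) + xi*sigma*sqrt(1 - exp(-2dt/tau)), so
their autocorrelation oracles carry no time-step bias.
"""
from __future__ import annotations

import logging

import numpy as np
from scipy.signal import lfilter
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .trajectory import Topology, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "UnitVectorSeries",
    "ScalarSeries",
    "gaussian_chain_ensemble",
    "gaussian_chain_rg2",
    "rotor_vector_series",
    "multi_ou_series",
    "harmonic_chain_trajectory",
    "rotor_nh_trajectory",
    "synthetic_contact_frames",
]

from dataclasses import dataclass


@dataclass
class UnitVectorSeries:
    """Per-frame 3D unit vectors, e.g. one N-H bond orientation over time."""

    vectors: np.ndarray  # (n_frames, 3)
    frame_interval: float  # ps
    residue_id: int | None = None

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValidationError("vectors must have shape (n_frames, 3)")
        norms = np.linalg.norm(self.vectors, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-8):
            raise ValidationError("vectors must be unit length within 1e-8")


@dataclass
class ScalarSeries:
    """Per-frame real values on a uniform time grid (frame_interval in ps)."""

    values: np.ndarray
    frame_interval: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ValidationError("need a 1-D series of length >= 2")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("series contains non-finite values")


def gaussian_chain_rg2(n_beads: int, bond_rms: float = 1.0) -> float:
    """Closed-form ensemble mean squared radius of gyration b^2 (N^2-1)/(6N)."""
    n = int(n_beads)
    return bond_rms**2 * (n**2 - 1) / (6.0 * n)


def gaussian_chain_ensemble(
    n_beads: int,
    bond_rms: float = 1.0,
    n_conformers: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Freely-jointed ideal chains: i.i.d. isotropic Gaussian bond vectors.

    Each bond vector has root-mean-square length ``bond_rms`` (component
    std bond_rms/sqrt(3)); the chain is non-self-avoiding, the textbook
    perfect random coil.  Returns coordinates (n_conformers, n_beads, 3) Å.
    """
    if n_beads < 2:
        raise ValidationError("n_beads must be >= 2")
    if not (bond_rms > 0 and n_conformers > 0):
        raise ValidationError("bond_rms and n_conformers must be positive")
    rng = np.random.default_rng(seed)
    bonds = rng.normal(0.0, bond_rms / np.sqrt(3.0), size=(n_conformers, n_beads - 1, 3))
    pos = np.concatenate(
        [np.zeros((n_conformers, 1, 3)), np.cumsum(bonds, axis=1)], axis=1
    )
    return pos


def rotor_vector_series(
    tau_c: float,
    frame_interval: float,
    n_frames: int,
    seed: int = 0,
) -> UnitVectorSeries:
    """Isotropic rotational diffusion of a single unit vector.

    The rotational diffusion coefficient is D_r = 1/(6 tau_c); each step
    applies a random rotation drawn from the SO(3) diffusion kernel
    (rotation-vector components i.i.d. N(0, 2 D_r dt)).  The P2
    autocorrelation of the output decays as exp(-t/tau_c) in the
    small-angle regime, which is why frame_interval <= tau_c/10 is asked
    for; coarser sampling is allowed but logged as a discretization-bias
    warning.
    """
    if not (tau_c > 0 and frame_interval > 0 and n_frames >= 2):
        raise ValidationError("tau_c, frame_interval must be > 0 and n_frames >= 2")
    if frame_interval > tau_c / 10.0:
        logger.warning(
            "rotor_vector_series: frame_interval %.3g ps > tau_c/10 = %.3g ps; "
            "the discrete-step P2 decay will be biased away from exp(-t/tau_c)",
            frame_interval, tau_c / 10.0,
        )
    rng = np.random.default_rng(seed)
    d_r = 1.0 / (6.0 * tau_c)
    sigma = np.sqrt(2.0 * d_r * frame_interval)
    rotvecs = rng.normal(0.0, sigma, size=(n_frames - 1, 3))
    mats = Rotation.from_rotvec(rotvecs).as_matrix()
    out = np.empty((n_frames, 3))
    # random initial orientation so ensembles of series are isotropic
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    out[0] = v
    for i in range(n_frames - 1):
        v = mats[i] @ v
        out[i + 1] = v
    # renormalize against slow drift of accumulated float error
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return UnitVectorSeries(out, frame_interval)


def _ou_modes(
    taus: np.ndarray,
    sigmas: np.ndarray,
    frame_interval: float,
    n_frames: int,
    rng: np.random.Generator,
    size: tuple[int, ...] = (),
) -> np.ndarray:
    """Exact stationary OU paths, shape (n_frames, n_modes, *size)."""
    n_modes = len(taus)
    a = np.exp(-frame_interval / np.asarray(taus, dtype=float))
    xi = rng.standard_normal((n_frames, n_modes) + size)
    out = np.empty_like(xi)
    for m in range(n_modes):
        u = xi[:, m] * (sigmas[m] * np.sqrt(1.0 - a[m] ** 2))
        u[0] = xi[0, m] * sigmas[m]  # stationary initial condition
        shp = u.shape
        out[:, m] = lfilter([1.0], [1.0, -a[m]], u.reshape(n_frames, -1), axis=0).reshape(shp)
    return out


def multi_ou_series(
    amplitudes,
    taus,
    variance: float = 1.0,
    frame_interval: float = 1.0,
    n_frames: int = 1000,
    seed: int = 0,
    mean: float = 0.0,
) -> ScalarSeries:
    """Sum of independent stationary Ornstein-Uhlenbeck processes.

    The population autocorrelation of the output is exactly
    sum_i amplitude_i exp(-t/tau_i) and the population variance is
    ``variance``; mode i carries variance amplitude_i * variance.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if amplitudes.shape != taus.shape or amplitudes.ndim != 1:
        raise ValidationError("amplitudes and taus must be 1-D and equal length")
    if np.any(amplitudes < 0):
        raise ValidationError("amplitudes must be non-negative")
    if abs(amplitudes.sum() - 1.0) > 1e-8:
        raise ValidationError(f"amplitudes must sum to 1, got {amplitudes.sum()!r}")
    if np.any(taus <= 0) or variance <= 0 or frame_interval <= 0 or n_frames < 2:
        raise ValidationError("taus, variance, frame_interval must be > 0; n_frames >= 2")
    rng = np.random.default_rng(seed)
    sigmas = np.sqrt(amplitudes * variance)
    modes = _ou_modes(taus, sigmas, frame_interval, n_frames, rng)
    return ScalarSeries(mean + modes.sum(axis=1), frame_interval)


def _rouse_spectrum(n_beads: int, bond_rms: float, relax_time: float):
    """Per-mode relaxation times and component std devs of a discrete Rouse chain.

    Mode p of an N-bead harmonic chain has stiffness proportional to
    sin^2(p pi / 2N); the slowest internal mode (p=1) is pinned to
    ``relax_time`` and the equilibrium variances reproduce ideal-chain
    statistics exactly (<Rg^2> = b^2 (N^2-1)/(6N)).
    """
    p = np.arange(1, n_beads)
    s2 = np.sin(p * np.pi / (2 * n_beads)) ** 2
    taus = relax_time * s2[0] / s2
    sigmas = np.sqrt(bond_rms**2 / (24.0 * n_beads * s2))
    return taus, sigmas


def harmonic_chain_trajectory(
    n_beads: int,
    relax_time: float = 100.0,
    bond_rms: float = 3.8,
    frame_interval: float = 10.0,
    n_frames: int = 1000,
    seed: int = 0,
    label: str = "harmonic-chain",
) -> Trajectory:
    """Overdamped harmonic (Rouse) bead chain packaged as a Trajectory.

    The chain is evolved exactly in its normal-mode representation: each
    Rouse mode is an independent OU process with the discrete-chain
    spectrum, so both equilibrium (ideal-chain) statistics and the mode
    relaxation times are free of integration bias.  The center of mass is
    held at the origin (it carries no shape or contact information).  One
    pseudo-residue per bead lets the gyration, ACF, and contact stages run
    on the result unchanged.
    """
    if n_beads < 2:
        raise ValidationError("n_beads must be >= 2")
    if not (relax_time > 0 and bond_rms > 0 and frame_interval > 0 and n_frames >= 2):
        raise ValidationError("relax_time, bond_rms, frame_interval must be > 0; n_frames >= 2")
    rng = np.random.default_rng(seed)
    taus, sigmas = _rouse_spectrum(n_beads, bond_rms, relax_time)
    modes = _ou_modes(taus, sigmas, frame_interval, n_frames, rng, size=(3,))
    # r_n(t) = 2 sum_p X_p(t) cos(p pi (n + 1/2) / N)
    p = np.arange(1, n_beads)[:, None]
    n = np.arange(n_beads)[None, :]
    cosines = np.cos(p * np.pi * (n + 0.5) / n_beads)  # (n_modes, n_beads)
    coords = 2.0 * np.einsum("tpc,pn->tnc", modes, cosines)
    topo = Topology(
        residue_ids=np.arange(1, n_beads + 1),
        residue_names=["BEA"] * n_beads,
        atom_names=["CA"] * n_beads,
        elements=["C"] * n_beads,
        atom_residue_index=np.arange(n_beads),
    )
    return Trajectory(topo, coords, frame_interval, label=label)


def rotor_nh_trajectory(
    n_residues: int,
    tau_c: float,
    frame_interval: float,
    n_frames: int,
    seed: int = 0,
    spacing: float = 20.0,
    label: str = "rotor-nh",
) -> Trajectory:
    """Pseudo-peptide whose N-H bonds each follow independent rotational diffusion.

    Residue i holds its amide N fixed at (i*spacing, 0, 0) and places H at
    N + 1.02 Å * e_i(t) with e_i from :func:`rotor_vector_series`, so the
    full relaxation pipeline has an exact single-Lorentzian oracle per
    residue.
    """
    if n_residues < 2:
        raise ValidationError("n_residues must be >= 2")
    rng = np.random.default_rng(seed)
    coords = np.empty((n_frames, 2 * n_residues, 3))
    for i in range(n_residues):
        series = rotor_vector_series(tau_c, frame_interval, n_frames,
                                     seed=int(rng.integers(2**31 - 1)))
        n_pos = np.array([i * spacing, 0.0, 0.0])
        coords[:, 2 * i] = n_pos
        coords[:, 2 * i + 1] = n_pos + 1.02 * series.vectors
    topo = Topology(
        residue_ids=np.arange(1, n_residues + 1),
        residue_names=["ALA"] * n_residues,
        atom_names=["N", "H"] * n_residues,
        elements=["N", "H"] * n_residues,
        atom_residue_index=np.repeat(np.arange(n_residues), 2),
    )
    return Trajectory(topo, coords, frame_interval, label=label)


def synthetic_contact_frames(
    n_residues: int,
    pair_probabilities: dict[tuple[int, int], float],
    n_frames: int,
    seed: int = 0,
) -> list[set[tuple[int, int]]]:
    """Bernoulli contact streams: each pair present independently per frame.

    Pairs are 1-based (i, j) with j >= i+3; occupancy estimates computed
    downstream converge to the given probabilities.
    """
    if n_residues < 2 or n_frames < 1:
        raise ValidationError("need n_residues >= 2 and n_frames >= 1")
    pairs = []
    probs = []
    for (i, j), p in sorted(pair_probabilities.items()):
        i, j = int(min(i, j)), int(max(i, j))
        if not (0.0 <= p <= 1.0):
            raise ValidationError(f"probability for pair ({i},{j}) out of [0,1]: {p}")
        if j - i < 3:
            raise ValidationError(f"pair ({i},{j}) is a first/second sequence neighbor")
        if i < 1 or j > n_residues:
            raise ValidationError(f"pair ({i},{j}) outside residues 1..{n_residues}")
        pairs.append((i, j))
        probs.append(p)
    rng = np.random.default_rng(seed)
    present = rng.random((n_frames, len(pairs))) < np.asarray(probs)
    return [
        {pairs[k] for k in np.flatnonzero(row)} for row in present
    ]
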