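"""Gyration-tensor shape statistics for conformational ensembles.

The per-snapshot gyration tensor

    S_ab = (1/2N^2) sum_{i,j} (r_a(i) - r_a(j)) (r_b(i) - r_b(j))

is computed in its algebraically identical central second-moment form
about the unweighted centroid (no masses enter the definition).  Its
ascending eigenvalues 0 <= l1 <= l2 <= l3 give

    Rg^2 = l1 + l2 + l3
    A    = [(l3-l2)^2 + (l3-l1)^2 + (l2-l1)^2] / [2 (l1+l2+l3)^2]
    P    = (2l3-l2-l1)(2l2-l3-l1)(2l1-l2-l3)
           / [2 (l1^2+l2^2+l3^2 - l1l2 - l1l3 - l2l3)^{3/2}]

A in [0, 1] measures deviation from a sphere (1 = rod); P in [-1, 1]
separates prolate (+1, cigar) from oblate (-1, disk) shapes.  At exact
sphericity P's denominator vanishes; the package defines P = 0 there (a
measure-zero case; any fixed finite value keeps ensemble summaries
defined) and logs a note.

The module also provides the normalized Rg variance
sigma^2 = 1 - <Rg>^2/<Rg^2>, the offset-free Rg autocorrelation with a
constrained biexponential fit, and the Flory scaling law <Rg> = rho0 N^nu.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .correlation import (CorrelationFunction, autocorr_sums, average_correlation,
                          log_lag_subsample, scalar_autocorrelation)
from .errors import DegenerateInputError, FitError, IdpdynError, ValidationError
from .synthetic import ScalarSeries
from .trajectory import Trajectory, select_atoms

logger = logging.getLogger(__name__)

__all__ = [
    "ShapeRecord",
    "BiExpFit",
    "FloryFit",
    "ShapeSummary",
    "gyration_tensor",
    "shape_record",
    "shape_records",
    "rg_series",
    "rg_variance",
    "rg_autocorrelation",
    "rg_autocorrelation_ensemble",
    "fit_biexponential",
    "flory_rg",
    "flory_nu",
    "fit_flory",
    "shape_summary",
]

_EIG_TOL = 1e-8


@dataclass
class ShapeRecord:
    """Eigenvalues (Å^2, ascending) and derived shape measures of one snapshot."""

    eigenvalues: tuple[float, float, float]
    rg: float
    asphericity: float
    prolateness: float


@dataclass
class BiExpFit:
    """Constrained biexponential fit a exp(-t/tau_a) + (1-a) exp(-t/tau_b)."""

    amplitudes: tuple[float, float]
    taus: tuple[float, float]  # ps, tau_a <= tau_b
    residual_ss: float

    def __post_init__(self) -> None:
        a, b = self.amplitudes
        if a < -1e-9 or b < -1e-9 or abs(a + b - 1.0) > 1e-6:
            raise ValidationError("amplitudes must be non-negative and sum to 1")
        if min(self.taus) <= 0:
            raise ValidationError("correlation times must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        (a, b), (ta, tb) = self.amplitudes, self.taus
        t = np.asarray(t, dtype=float)
        return a * np.exp(-t / ta) + b * np.exp(-t / tb)


@dataclass
class FloryFit:
    """Power-law parameters of <Rg> = rho0 * N^nu."""

    rho0: float  # Å
    nu: float

    def __post_init__(self) -> None:
        if self.rho0 <= 0:
            raise ValidationError("rho0 must be positive")


def gyration_tensor(frame: np.ndarray, subset: np.ndarray | None = None) -> np.ndarray:
    """Symmetric 3x3 gyration tensor (Å^2) of one coordinate frame.

    Uses the central second-moment form about the unweighted centroid,
    identical to the pairwise-difference form.
    """
    frame = np.asarray(frame, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValidationError("atom subset is empty")
        frame = frame[subset]
    if frame.ndim != 2 or frame.shape[1] != 3 or frame.shape[0] == 0:
        raise ValidationError("frame must be a non-empty (n_atoms, 3) array")
    centered = frame - frame.mean(axis=0)
    return centered.T @ centered / frame.shape[0]


def _shape_from_eigenvalues(lam: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(rg, A, P) from ascending eigenvalue triples, vectorized over rows."""
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    tr = l1 + l2 + l3
    safe_tr = np.where(tr > 0, tr, 1.0)
    asph = np.where(
        tr > 0,
        ((l3 - l2) ** 2 + (l3 - l1) ** 2 + (l2 - l1) ** 2) / (2.0 * safe_tr**2),
        0.0,
    )
    quad = l1**2 + l2**2 + l3**2 - l1 * l2 - l1 * l3 - l2 * l3
    num = (2 * l3 - l2 - l1) * (2 * l2 - l3 - l1) * (2 * l1 - l2 - l3)
    den = 2.0 * np.maximum(quad, 0.0) ** 1.5
    degenerate = den <= _EIG_TOL * np.maximum(safe_tr, 1.0) ** 3
    prol = np.where(degenerate, 0.0, num / np.where(degenerate, 1.0, den))
    if np.any(degenerate):
        logger.info("prolateness undefined for %d near-spherical snapshot(s); set to 0",
                    int(np.count_nonzero(degenerate)))
    prol = np.clip(prol, -1.0, 1.0)
    return np.sqrt(np.maximum(tr, 0.0)), np.clip(asph, 0.0, 1.0), prol


def shape_record(tensor: np.ndarray) -> ShapeRecord:
    """Diagonalize one gyration tensor into a :class:`ShapeRecord`."""
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape != (3, 3) or not np.allclose(tensor, tensor.T, atol=1e-8):
        raise ValidationError("tensor must be symmetric 3x3")
    lam = np.linalg.eigvalsh(tensor)
    scale = max(abs(lam).max(), 1.0)
    if lam[0] < -_EIG_TOL * scale:
        raise IdpdynError(f"tensor is not positive semidefinite: eigenvalue {lam[0]}")
    lam = np.clip(lam, 0.0, None)
    rg, asph, prol = _shape_from_eigenvalues(lam[None, :])
    return ShapeRecord(tuple(lam), float(rg[0]), float(asph[0]), float(prol[0]))


def shape_records(frames: np.ndarray, subset: np.ndarray | None = None) -> pd.DataFrame:
    """Vectorized shape measures for a stack of frames.

    Returns a DataFrame with columns lambda1..3, Rg, asphericity,
    prolateness; one row per frame.
    """
    frames = np.asarray(frames, dtype=float)
    if subset is not None:
        subset = np.asarray(subset)
        if subset.size == 0:
            raise ValidationError("atom subset is empty")
        frames = frames[:, subset]
    centered = frames - frames.mean(axis=1, keepdims=True)
    tensors = np.einsum("fia,fib->fab", centered, centered) / frames.shape[1]
    lam = np.clip(np.linalg.eigvalsh(tensors), 0.0, None)
    rg, asph, prol = _shape_from_eigenvalues(lam)
    return pd.DataFrame({
        "lambda1": lam[:, 0], "lambda2": lam[:, 1], "lambda3": lam[:, 2],
        "Rg": rg, "asphericity": asph, "prolateness": prol,
    })


def rg_series(traj: Trajectory, subset_mode: str = "all") -> ScalarSeries:
    """Per-frame radius of gyration (Å) of a trajectory."""
    subset = select_atoms(traj, subset_mode)
    if subset.size == 0:
        raise ValidationError(f"selection mode {subset_mode!r} matches no atoms")
    records = shape_records(traj.coordinates, subset)
    return ScalarSeries(records["Rg"].to_numpy(), traj.frame_interval)


def rg_variance(series: ScalarSeries) -> float:
    """Normalized variance 1 - <Rg>^2 / <Rg^2> of the fluctuations.

    Dimensionless and invariant under rescaling of the series.  A constant
    series returns 0.
    """
    x = np.asarray(series.values, dtype=float)
    if len(x) < 2:
        raise ValidationError("need at least 2 frames")
    m2 = np.mean(x**2)
    if m2 == 0.0:
        return 0.0
    return float(1.0 - np.mean(x) ** 2 / m2)


def rg_autocorrelation(
    series: ScalarSeries, max_lag_fraction: float = 1.0 / 3.0
) -> CorrelationFunction:
    """Offset-free normalized autocorrelation of an Rg series (FFT-based)."""
    if len(series.values) < 10:
        raise ValidationError("need at least 10 frames for an autocorrelation estimate")
    return scalar_autocorrelation(series.values, series.frame_interval, max_lag_fraction)


def rg_autocorrelation_ensemble(
    series_list: list[ScalarSeries], max_lag_fraction: float = 1.0 / 3.0
) -> CorrelationFunction:
    """Averaged offset-free Rg autocorrelation over replicate trajectories.

    The offset <Rg> and the normalizing variance are taken over the
    *pooled* ensemble rather than per replicate: subtracting each
    replicate's own sample mean biases its autocorrelation downward by
    ~2 tau_corr / T, which is material when a trajectory spans only tens
    of correlation lengths, while the pooled mean estimated from all
    replicates leaves the per-replicate estimates essentially unbiased.
    Each replicate's correlation function then enters the average with
    equal weight and the result is renormalized to C(0) = 1.
    """
    if not series_list:
        raise ValidationError("need at least one series")
    dt = series_list[0].frame_interval
    if any(s.frame_interval != dt for s in series_list):
        raise ValidationError("series must share a frame interval")
    pooled = np.concatenate([s.values for s in series_list])
    grand_mean = pooled.mean()
    grand_var = pooled.var()
    if grand_var == 0.0:
        raise DegenerateInputError("ensemble has zero variance")
    cfs = []
    for s in series_list:
        x = s.values - grand_mean
        n = len(x)
        c = autocorr_sums(x) / (n - np.arange(n)) / grand_var
        n_lags = min(n, max(2, int(np.floor(max_lag_fraction * n)) + 1))
        cfs.append(CorrelationFunction(np.arange(n_lags) * dt, c[:n_lags],
                                       truncation_fraction=max_lag_fraction))
    avg = average_correlation(cfs)
    return CorrelationFunction(avg.lags, avg.values / avg.values[0],
                               n_source_series=len(cfs),
                               truncation_fraction=max_lag_fraction)


def _biexp_start_taus(dt: float, t_max: float) -> list[tuple[float, float]]:
    grid = np.geomspace(max(10.0 * dt, 1e-6), max(t_max, 20.0 * dt), 4)
    return [(grid[i], grid[j]) for i in range(len(grid)) for j in range(i, len(grid))]


def fit_biexponential(corr: CorrelationFunction, lag_sampling: str = "log") -> BiExpFit:
    """Least-squares biexponential fit with a + b = 1, a,b >= 0, taus > 0.

    Deterministic multi-start over log-spaced tau pairs; the amplitude
    split is parameterized through a logistic so the sum-to-one constraint
    holds exactly.  By default the fit uses a log-spaced lag subsample so
    every decade of the decay carries equal weight (pass
    ``lag_sampling="uniform"`` for every lag).  Ties are broken by lowest
    residual, then smallest tau_b.
    """
    if lag_sampling == "log":
        idx = log_lag_subsample(len(corr.lags))
        t = corr.lags[idx]
        y = corr.values[idx]
    elif lag_sampling == "uniform":
        t = corr.lags
        y = corr.values
    else:
        raise ValidationError("lag_sampling must be 'log' or 'uniform'")
    if abs(y[0] - 1.0) > 1e-6:
        raise ValidationError("correlation function must be normalized to C(0) = 1")
    dt = corr.frame_interval if len(t) > 1 else 1.0

    def model(params):
        z, lta, ltb = params
        a = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
        ta, tb = np.exp(np.clip([lta, ltb], -60.0, 60.0))
        return a * np.exp(-t / ta) + (1 - a) * np.exp(-t / tb)

    def jacobian(params):
        z, lta, ltb = params
        a = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
        ta, tb = np.exp(np.clip([lta, ltb], -60.0, 60.0))
        ea, eb = np.exp(-t / ta), np.exp(-t / tb)
        return np.column_stack([
            a * (1 - a) * (ea - eb),
            a * ea * (t / ta),
            (1 - a) * eb * (t / tb),
        ])

    best = None
    for ta0, tb0 in _biexp_start_taus(dt, t[-1] if len(t) > 1 else 1.0):
        try:
            res = least_squares(lambda p: model(p) - y, x0=[0.0, np.log(ta0), np.log(tb0)],
                                jac=jacobian, method="lm", max_nfev=400)
        except Exception:
            continue
        ss = float(np.sum(res.fun**2))
        z, lta, ltb = res.x
        taus = sorted(float(v) for v in np.exp(np.clip([lta, ltb], -60.0, 60.0)))
        key = (round(ss, 14), taus[1])
        if best is None or key < best[0]:
            a = 1.0 / (1.0 + np.exp(-np.clip(z, -500.0, 500.0)))
            amps = (a, 1.0 - a) if np.exp(lta) <= np.exp(ltb) else (1.0 - a, a)
            best = (key, BiExpFit(amplitudes=amps, taus=tuple(taus), residual_ss=ss))
    if best is None:
        raise FitError("biexponential fit failed from every start")
    return best[1]


def flory_rg(rho0: float, nu: float, n_residues: int) -> float:
    """Polymer scaling law <Rg> = rho0 * N^nu (Å)."""
    if rho0 <= 0 or n_residues < 1:
        raise ValidationError("rho0 must be > 0 and n_residues >= 1")
    return float(rho0 * n_residues**nu)


def flory_nu(mean_rg: float, rho0: float, n_residues: int) -> float:
    """Invert the scaling law: nu = ln(<Rg>/rho0) / ln(N)."""
    if mean_rg <= 0 or rho0 <= 0:
        raise ValidationError("mean_rg and rho0 must be positive")
    if n_residues < 2:
        raise ValidationError("n_residues must be >= 2 (log N vanishes at N = 1)")
    return float(np.log(mean_rg / rho0) / np.log(n_residues))


def fit_flory(mean_rgs, n_residues) -> FloryFit:
    """Fit (rho0, nu) by linear regression of ln<Rg> on ln N."""
    rg = np.asarray(mean_rgs, dtype=float)
    n = np.asarray(n_residues, dtype=float)
    if rg.shape != n.shape or len(rg) < 2:
        raise ValidationError("need >= 2 (N, <Rg>) pairs of equal length")
    if np.any(rg <= 0) or np.any(n < 2):
        raise ValidationError("mean Rg values must be > 0 and chain lengths >= 2")
    nu, log_rho0 = np.polyfit(np.log(n), np.log(rg), 1)
    return FloryFit(rho0=float(np.exp(log_rho0)), nu=float(nu))


@dataclass
class ShapeSummary:
    """Pooled ensemble shape distributions with equal frame weight."""

    mean_rg: float
    mean_asphericity: float
    mean_prolateness: float
    rg_hist: pd.DataFrame
    asphericity_hist: pd.DataFrame
    prolateness_hist: pd.DataFrame
    n_frames: int


def _hist(values: np.ndarray, lo: float, hi: float, width: float) -> pd.DataFrame:
    edges = np.arange(lo, hi + width / 2, width)
    if edges[-1] < hi:
        edges = np.append(edges, hi)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame({
        "bin_left": edges[:-1], "bin_right": edges[1:],
        "count": counts, "fraction": counts / max(len(values), 1),
    })


def shape_summary(
    ensemble,
    subset_mode: str = "all",
    rg_bin_width: float = 0.5,
    asphericity_bin_width: float = 0.02,
    prolateness_bin_width: float = 0.04,
) -> ShapeSummary:
    """Histograms and means of Rg, A, P over an ensemble.

    ``ensemble`` may be a coordinate stack (n_frames, n_atoms, 3), a
    Trajectory, or a list of Trajectories; frames are pooled with equal
    weight.  A and P are histogrammed over their full closed ranges; the
    Rg range adapts to the data in steps of the bin width.
    """
    if isinstance(ensemble, Trajectory):
        ensemble = [ensemble]
    if isinstance(ensemble, list) and ensemble and isinstance(ensemble[0], Trajectory):
        tables = [shape_records(t.coordinates, select_atoms(t, subset_mode))
                  for t in ensemble]
        table = pd.concat(tables, ignore_index=True)
    else:
        frames = np.asarray(ensemble, dtype=float)
        if frames.ndim != 3:
            raise ValidationError("ensemble must be (n_frames, n_atoms, 3) or Trajectory(s)")
        table = shape_records(frames)
    rg = table["Rg"].to_numpy()
    rg_hi = max(np.ceil(rg.max() / rg_bin_width) * rg_bin_width, rg_bin_width)
    return ShapeSummary(
        mean_rg=float(rg.mean()),
        mean_asphericity=float(table["asphericity"].mean()),
        mean_prolateness=float(table["prolateness"].mean()),
        rg_hist=_hist(rg, 0.0, rg_hi, rg_bin_width),
        asphericity_hist=_hist(table["asphericity"].to_numpy(), 0.0, 1.0,
                               asphericity_bin_width),
        prolateness_hist=_hist(table["prolateness"].to_numpy(), -1.0, 1.0,
                               prolateness_bin_width),
        n_frames=len(table),
    )
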