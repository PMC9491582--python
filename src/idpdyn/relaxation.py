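"""Back-calculation of 15N R1/R2 spin relaxation from trajectories.

For a disordered chain the orientational correlation function of each
N-H bond cannot be factorized into overall tumbling times internal
motion, so the full second-Legendre correlation function

    C(t) = < P2( e(tau) . e(tau+t) ) >_tau

is estimated directly from the (unaligned) coordinate frames, truncated
to the first third of the trajectory for statistical convergence, and
fitted with a constrained multiexponential

    C(t) = sum_i A_i exp(-t / tau_i),   sum A_i = 1, A_i >= 0, tau_i >= 0

whose analytic spectral density J(w) = sum_i 2 A_i tau_i / (1 + (w tau_i)^2)
enters the standard dipolar + CSA expressions for R1 and R2 evaluated at
{0, wN, wH-wN, wH, wH+wN}.  The N-H bond length is fixed at 1.02 Å and
the 15N chemical shift anisotropy at -160 ppm.  The spectrometer field is
a required configuration value (common choice: 600 MHz proton frequency);
J is even, so the magnitudes |wN|, |wH +/- wN| are used throughout and the
negative 15N gyromagnetic ratio cannot introduce sign errors.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .correlation import (CorrelationFunction, autocorr_sums, average_correlation,
                          log_lag_subsample)
from .errors import FitError, ValidationError
from .synthetic import UnitVectorSeries
from .trajectory import ExperimentalRates, Trajectory

logger = logging.getLogger(__name__)

__all__ = [
    "MultiExpFit",
    "FieldConstants",
    "RelaxationResult",
    "nh_vectors",
    "p2_autocorrelation",
    "average_correlation",
    "fit_multiexponential",
    "spectral_density",
    "field_constants",
    "relaxation_rates",
    "per_residue_pipeline",
    "timescale_summary",
    "compare_to_experiment",
]

# CODATA physical constants (SI)
MU_0_OVER_4PI = 1e-7          # T m / A
HBAR = 1.054571817e-34        # J s
GAMMA_H = 267.52218744e6      # rad s^-1 T^-1
GAMMA_N = -27.1261804e6       # rad s^-1 T^-1 (15N, negative)
R_NH_ANGSTROM = 1.02
DELTA_SIGMA = -160e-6         # 15N CSA (dimensionless)


@dataclass
class MultiExpFit:
    """Non-negative multiexponential decay with amplitudes summing to 1."""

    amplitudes: np.ndarray
    taus: np.ndarray  # ps, sorted ascending
    residual_ss: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.taus = np.asarray(self.taus, dtype=float)
        if self.amplitudes.shape != self.taus.shape or self.amplitudes.ndim != 1:
            raise ValidationError("amplitudes and taus must be 1-D and equal length")
        if np.any(self.amplitudes < -1e-9) or abs(self.amplitudes.sum() - 1.0) > 1e-6:
            raise ValidationError("amplitudes must be non-negative and sum to 1")
        if np.any(self.taus < 0):
            raise ValidationError("correlation times must be non-negative")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.exp(-t[..., None] / np.maximum(self.taus, 1e-300)) @ self.amplitudes


@dataclass
class FieldConstants:
    """Field-dependent frequencies and interaction prefactors for Eqs of motion.

    d00 carries the dipolar interaction strength (s^-2); c00 = d_sigma^2/15
    is the dimensionless CSA prefactor multiplying wN^2 J(wN) terms.
    """

    proton_mhz: float
    omega_h: float   # rad/s
    omega_n: float   # rad/s (magnitude)
    d00: float       # s^-2
    c00: float       # dimensionless
    r_nh: float = R_NH_ANGSTROM
    delta_sigma: float = DELTA_SIGMA

    def __post_init__(self) -> None:
        if self.d00 <= 0 or self.c00 <= 0:
            raise ValidationError("d00 and c00 must be positive")
        ratio = self.omega_n / self.omega_h
        if abs(ratio - abs(GAMMA_N / GAMMA_H)) > 1e-6 * abs(GAMMA_N / GAMMA_H):
            raise ValidationError("omega_n/omega_h must equal |gamma_N/gamma_H|")


def field_constants(proton_mhz: float = 600.0, r_nh: float = R_NH_ANGSTROM,
                    delta_sigma: float = DELTA_SIGMA) -> FieldConstants:
    """Interaction constants at a given proton Larmor frequency (MHz).

    d00 = (1/20) (mu0/4pi)^2 hbar^2 gammaH^2 gammaN^2 <r_NH^-3>^2 with the
    bond length treated as fixed (no vibrational averaging);
    c00 = delta_sigma^2 / 15.
    """
    if proton_mhz <= 0:
        raise ValidationError("proton frequency must be positive")
    omega_h = 2.0 * np.pi * proton_mhz * 1e6
    omega_n = omega_h * abs(GAMMA_N / GAMMA_H)
    r_m = r_nh * 1e-10
    d00 = (MU_0_OVER_4PI**2 * HBAR**2 * GAMMA_H**2 * GAMMA_N**2 / r_m**6) / 20.0
    c00 = delta_sigma**2 / 15.0
    return FieldConstants(proton_mhz=proton_mhz, omega_h=omega_h, omega_n=omega_n,
                          d00=d00, c00=c00, r_nh=r_nh, delta_sigma=delta_sigma)


#: amide-proton names accepted when extracting N-H bond vectors
_AMIDE_H_NAMES = {"H", "HN"}


def nh_vectors(traj: Trajectory) -> tuple[dict[int, UnitVectorSeries], list[tuple[int, str]]]:
    """Normalized N->H bond orientation series per residue.

    Frames are used as stored — no superposition onto a reference — since
    the P2 correlation function of a freely reorienting chain must include
    the overall reorientation.  Prolines and the N-terminal residue carry
    no amide proton and are excluded; any other residue missing N or H is
    excluded with a warning.  Returns (series by residue id, exclusions as
    (residue_id, reason)).
    """
    topo = traj.topology
    names = [n.upper() for n in topo.atom_names]
    series: dict[int, UnitVectorSeries] = {}
    excluded: list[tuple[int, str]] = []
    for rid in topo.residue_ids:
        resname = topo.residue_names[rid - 1].upper()
        if rid == topo.residue_ids[0]:
            excluded.append((int(rid), "N-terminal residue"))
            continue
        if resname.startswith("PRO"):
            excluded.append((int(rid), "proline (no amide H)"))
            continue
        atoms = topo.atoms_of_residue(rid)
        n_idx = [a for a in atoms if names[a] == "N"]
        h_idx = [a for a in atoms if names[a] in _AMIDE_H_NAMES]
        if not n_idx or not h_idx:
            excluded.append((int(rid), "missing amide N or H atom"))
            logger.warning("residue %d (%s): missing amide N/H, excluded from relaxation",
                           rid, resname)
            continue
        vec = traj.coordinates[:, h_idx[0]] - traj.coordinates[:, n_idx[0]]
        norm = np.linalg.norm(vec, axis=1, keepdims=True)
        if np.any(norm == 0):
            excluded.append((int(rid), "degenerate N-H geometry"))
            continue
        series[int(rid)] = UnitVectorSeries(vec / norm, traj.frame_interval,
                                            residue_id=int(rid))
    return series, excluded


def p2_autocorrelation(
    series: UnitVectorSeries, truncation_fraction: float = 1.0 / 3.0
) -> CorrelationFunction:
    """P2 orientational autocorrelation of a unit-vector series via FFT.

    (e . e')^2 expands into the six independent quadratic component
    products (x^2, y^2, z^2, sqrt2*xy, sqrt2*xz, sqrt2*yz), whose scalar
    autocorrelations sum to <(e(tau).e(tau+t))^2>; the Wiener-Khinchin
    evaluation of those six series is algebraically identical to the
    direct double loop.  Lags are reported for t = 0 .. T/3 by default.
    """
    v = series.vectors
    n = v.shape[0]
    if n < 30:
        raise ValidationError("need at least 30 frames for a P2 estimate")
    x, y, z = v[:, 0], v[:, 1], v[:, 2]
    sq2 = np.sqrt(2.0)
    q = np.column_stack([x * x, y * y, z * z, sq2 * x * y, sq2 * x * z, sq2 * y * z])
    s = autocorr_sums(q)
    counts = n - np.arange(n)
    dot_sq = s / counts
    c = 0.5 * (3.0 * dot_sq - 1.0)
    n_lags = min(n, max(2, int(np.floor(truncation_fraction * n)) + 1))
    lags = np.arange(n_lags) * series.frame_interval
    return CorrelationFunction(lags, c[:n_lags], n_source_series=1,
                               truncation_fraction=truncation_fraction)


def _multiexp_model(t: np.ndarray, w: np.ndarray, log_tau: np.ndarray) -> np.ndarray:
    amps = w**2 / np.sum(w**2)
    return np.exp(-t[:, None] / np.exp(np.clip(log_tau, -60.0, 60.0))) @ amps


def _multiexp_jac(t: np.ndarray, w: np.ndarray, log_tau: np.ndarray) -> np.ndarray:
    """Analytic Jacobian of the constrained multiexponential residuals."""
    s = np.sum(w**2)
    amps = w**2 / s
    taus = np.exp(np.clip(log_tau, -60.0, 60.0))
    e = np.exp(-t[:, None] / taus)          # (n_t, n_modes)
    model = e @ amps
    d_w = (2.0 * w / s) * (e - model[:, None])
    d_ltau = amps * e * (t[:, None] / taus)
    return np.hstack([d_w, d_ltau])


def fit_multiexponential(corr: CorrelationFunction, n_modes: int = 6,
                         prune_tol: float = 1e-6,
                         lag_sampling: str = "log") -> MultiExpFit:
    """Constrained nonlinear least-squares multiexponential fit of C(t).

    Amplitudes are parameterized as w_i^2 / sum(w^2), so the sum-to-one
    and non-negativity constraints of the model hold exactly throughout
    the optimization; correlation times are optimized in log space.
    Deterministic multi-start: initial tau grids are log-spaced over
    [frame_interval, max lag] with a few geometric shifts, amplitudes
    start uniform.  ``lag_sampling`` "log" (default) fits on a log-spaced
    lag subsample (see :func:`idpdyn.correlation.log_lag_subsample`); "uniform" uses every
    lag.  Modes with fitted amplitude below ``prune_tol`` are pruned and
    the remainder renormalized; output is sorted by tau.
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
    if n_modes < 1:
        raise ValidationError("n_modes must be >= 1")
    dt = corr.frame_interval if len(t) > 1 else 1.0
    t_max = max(t[-1], 10.0 * dt)

    def residuals(params):
        w = params[:n_modes]
        log_tau = params[n_modes:]
        return _multiexp_model(t, w, log_tau) - y

    def jacobian(params):
        return _multiexp_jac(t, params[:n_modes], params[n_modes:])

    best = None
    failures = []
    for shift in (1.0, 0.3, 3.0):
        tau0 = np.geomspace(dt * shift, t_max * shift, n_modes) if n_modes > 1 \
            else np.array([np.sqrt(dt * t_max) * shift])
        x0 = np.concatenate([np.full(n_modes, 1.0), np.log(tau0)])
        try:
            res = least_squares(residuals, x0=x0, jac=jacobian, method="lm", max_nfev=400)
        except Exception as exc:  # pragma: no cover - defensive
            failures.append(repr(exc))
            continue
        ss = float(np.sum(res.fun**2))
        if best is None or ss < best[0]:
            best = (ss, res.x)
    if best is None:
        raise FitError("multiexponential fit failed from every start: " + "; ".join(failures))
    ss, params = best
    amps = params[:n_modes] ** 2 / np.sum(params[:n_modes] ** 2)
    taus = np.exp(np.clip(params[n_modes:], -60.0, 60.0))
    # Amplitudes below the fit's own rms residual are not statistically
    # identified (indistinguishable from the noise floor of the truncated
    # correlation estimate) yet can dominate J(0) when paired with a long
    # tau; they are pruned along with the numerically-zero modes.
    noise_floor = float(np.sqrt(ss / len(y)))
    keep = amps >= max(prune_tol, noise_floor)
    if not np.any(keep):
        keep = amps == amps.max()
    amps, taus = amps[keep], taus[keep]
    amps = amps / amps.sum()
    order = np.argsort(taus)
    return MultiExpFit(amplitudes=amps[order], taus=taus[order], residual_ss=ss)


def spectral_density(fit: MultiExpFit, omega: float | np.ndarray) -> float | np.ndarray:
    """Analytic spectral density J(omega) in seconds.

    J(w) = sum_i 2 A_i tau_i / (1 + (w tau_i)^2) with tau converted from
    ps to s; the cosine-transform normalization gives (1/pi) int_0^inf J
    d(omega) = C(0) = 1.
    """
    tau_s = fit.taus * 1e-12
    omega = np.asarray(omega, dtype=float)
    j = np.sum(2.0 * fit.amplitudes * tau_s / (1.0 + (omega[..., None] * tau_s) ** 2),
               axis=-1)
    return float(j) if j.ndim == 0 else j


def relaxation_rates(fit: MultiExpFit, fc: FieldConstants) -> tuple[float, float]:
    """R1 and R2 (s^-1) from a fitted correlation function.

    R1 = d00 [3J(wN) + J(wH-wN) + 6J(wH+wN)] + c00 wN^2 J(wN)
    R2 = d00/2 [4J(0) + 3J(wN) + J(wH-wN) + 6J(wH) + 6J(wH+wN)]
         + c00 wN^2 / 6 [4J(0) + 3J(wN)]
    """
    wn, wh = fc.omega_n, fc.omega_h
    j0 = spectral_density(fit, 0.0)
    jn = spectral_density(fit, wn)
    jh = spectral_density(fit, wh)
    jm = spectral_density(fit, abs(wh - wn))
    jp = spectral_density(fit, wh + wn)
    r1 = fc.d00 * (3.0 * jn + jm + 6.0 * jp) + fc.c00 * wn**2 * jn
    r2 = 0.5 * fc.d00 * (4.0 * j0 + 3.0 * jn + jm + 6.0 * jh + 6.0 * jp) \
        + fc.c00 * wn**2 / 6.0 * (4.0 * j0 + 3.0 * jn)
    return float(r1), float(r2)


@dataclass
class RelaxationResult:
    """Per-residue rates from trajectory-averaged correlation functions.

    ``rates`` columns: residue_id, R1, R2, R1_std, R2_std where the std
    columns are standard deviations of rates computed per source
    trajectory (0 when only one trajectory was supplied).  ``fits`` maps
    residue id to the MultiExpFit of the averaged correlation function.
    """

    rates: pd.DataFrame
    fits: dict[int, MultiExpFit]
    excluded_residues: list[tuple[int, str]]
    excluded_trajectories: list[str] = field(default_factory=list)


def per_residue_pipeline(
    trajs: list[Trajectory],
    fc: FieldConstants,
    n_modes: int = 6,
    truncation_fraction: float = 1.0 / 3.0,
    exclude_labels: tuple[str, ...] = (),
) -> RelaxationResult:
    """Full relaxation back-calculation over a set of trajectories.

    Per residue: a P2 correlation function is computed for every
    trajectory, the functions are averaged with equal weight, the average
    is fitted and converted to rates; the per-residue spread is the
    standard deviation of rates obtained from each trajectory's own fit.
    Trajectories named in ``exclude_labels`` are dropped up front
    (manual outlier handling, diagnostic only).
    """
    if not trajs:
        raise ValidationError("need at least one trajectory")
    unknown = set(exclude_labels) - {t.label for t in trajs}
    if unknown:
        raise ValidationError(f"exclusion list names unknown trajectories: {sorted(unknown)}")
    used = [t for t in trajs if t.label not in exclude_labels]
    if not used:
        raise ValidationError("all trajectories excluded")
    per_traj: list[dict[int, CorrelationFunction]] = []
    exclusion_log: dict[int, str] = {}
    for traj in used:
        series, excl = nh_vectors(traj)
        for rid, reason in excl:
            exclusion_log.setdefault(rid, reason)
        per_traj.append({rid: p2_autocorrelation(s, truncation_fraction)
                         for rid, s in series.items()})
    common = sorted(set.intersection(*(set(d) for d in per_traj))) if per_traj else []
    rows = []
    fits: dict[int, MultiExpFit] = {}
    for rid in common:
        cfs = [d[rid] for d in per_traj]
        avg_fit = fit_multiexponential(average_correlation(cfs), n_modes=n_modes)
        fits[rid] = avg_fit
        r1, r2 = relaxation_rates(avg_fit, fc)
        if len(cfs) > 1:
            per = np.array([
                relaxation_rates(fit_multiexponential(cf, n_modes=n_modes), fc)
                for cf in cfs
            ])
            r1_std, r2_std = per.std(axis=0, ddof=0)
        else:
            r1_std = r2_std = 0.0
        rows.append((rid, r1, r2, float(r1_std), float(r2_std)))
    excluded = sorted(exclusion_log.items())
    for rid, reason in excluded:
        logger.info("residue %d excluded from relaxation pipeline: %s", rid, reason)
    return RelaxationResult(
        rates=pd.DataFrame(rows, columns=["residue_id", "R1", "R2", "R1_std", "R2_std"]),
        fits=fits,
        excluded_residues=excluded,
        excluded_trajectories=list(exclude_labels),
    )


def timescale_summary(fits: dict[int, MultiExpFit], threshold: float = 100.0) -> pd.DataFrame:
    """Mode table per residue with sub-threshold modes aggregated.

    Modes with tau >= threshold (ps) are listed individually; all faster
    modes are merged into a single aggregate amplitude (tau reported as
    NaN), mirroring how librational contributions faster than ~100 ps are
    usually summarized.  Amplitudes still sum to 1 per residue.
    """
    rows = []
    for rid, fit in sorted(fits.items()):
        fast = float(fit.amplitudes[fit.taus < threshold].sum())
        if fast > 0:
            rows.append((rid, np.nan, fast, True))
        for a, tau in zip(fit.amplitudes, fit.taus):
            if tau >= threshold:
                rows.append((rid, float(tau), float(a), False))
    return pd.DataFrame(rows, columns=["residue_id", "tau_ps", "amplitude", "is_fast_aggregate"])


def compare_to_experiment(result: RelaxationResult, exp: ExperimentalRates) -> dict[str, float]:
    """RMSE and Pearson correlation against experimental rates.

    Residues are matched by id; missing experimental entries are skipped
    pairwise per rate.  Requires >= 3 residues in common overall.
    """
    calc = result.rates.set_index("residue_id")
    exp_df = pd.DataFrame({"R1": exp.r1, "R2": exp.r2}, index=exp.residue_ids)
    common = calc.index.intersection(exp_df.index)
    if len(common) < 3:
        raise ValidationError(f"need >= 3 residues in common, got {len(common)}")
    out: dict[str, float] = {}
    for rate in ("R1", "R2"):
        a = calc.loc[common, rate].to_numpy(dtype=float)
        b = exp_df.loc[common, rate].to_numpy(dtype=float)
        ok = ~np.isnan(b)
        if ok.sum() < 3:
            out[f"rmse_{rate}"] = np.nan
            out[f"pearson_{rate}"] = np.nan
            continue
        diff = a[ok] - b[ok]
        out[f"rmse_{rate}"] = float(np.sqrt(np.mean(diff**2)))
        with np.errstate(invalid="ignore"):  # NaN for zero-variance inputs
            out[f"pearson_{rate}"] = float(np.corrcoef(a[ok], b[ok])[0, 1])
    out["n_common"] = int(len(common))
    return out
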