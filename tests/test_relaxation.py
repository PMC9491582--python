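"""P2 correlation functions, multiexponential fits, and R1/R2 relaxation theory."""
import numpy as np
import pytest

import idpdyn
from idpdyn.correlation import CorrelationFunction
from idpdyn.errors import ValidationError
from idpdyn.relaxation import (GAMMA_H, GAMMA_N, HBAR, MU_0_OVER_4PI, MultiExpFit,
                               field_constants, relaxation_rates, spectral_density)
from idpdyn.synthetic import UnitVectorSeries


def brute_force_p2(vectors, n_lags):
    """Direct double-loop P2 autocorrelation with unbiased lag counts."""
    n = len(vectors)
    out = np.empty(n_lags)
    for t in range(n_lags):
        dots = np.einsum("ij,ij->i", vectors[: n - t], vectors[t:])
        out[t] = np.mean(0.5 * (3.0 * dots**2 - 1.0))
    return out


def lorentzian_rates(tau_ps, fc):
    """Independent oracle: explicit single-Lorentzian substitution."""
    tau = tau_ps * 1e-12

    def j(w):
        return 2.0 * tau / (1.0 + (w * tau) ** 2)

    wn, wh = fc.omega_n, fc.omega_h
    r1 = fc.d00 * (3 * j(wn) + j(wh - wn) + 6 * j(wh + wn)) + fc.c00 * wn**2 * j(wn)
    r2 = 0.5 * fc.d00 * (4 * j(0) + 3 * j(wn) + j(wh - wn) + 6 * j(wh) + 6 * j(wh + wn)) \
        + fc.c00 * wn**2 / 6.0 * (4 * j(0) + 3 * j(wn))
    return r1, r2


class TestNHVectors:
    def test_known_geometry_gives_exact_unit_vectors(self, peptide_trajectory):
        series, _ = idpdyn.nh_vectors(peptide_trajectory)
        # fixture places H at N + 1.02 * e, so the N->H unit vector is e itself
        rid = next(iter(series))
        vecs = series[rid].vectors
        assert np.allclose(np.linalg.norm(vecs, axis=1), 1.0, atol=1e-12)

    def test_nterminal_residue_excluded(self, peptide_trajectory):
        series, excluded = idpdyn.nh_vectors(peptide_trajectory)
        assert 1 not in series
        assert any(rid == 1 for rid, _ in excluded)

    def test_proline_excluded_and_listed(self, peptide_trajectory):
        topo = peptide_trajectory.topology
        topo_pro = type(topo)(
            residue_ids=topo.residue_ids.copy(),
            residue_names=["ALA", "ALA", "PRO", "ALA"],
            atom_names=list(topo.atom_names),
            elements=list(topo.elements),
            atom_residue_index=topo.atom_residue_index.copy(),
        )
        traj = type(peptide_trajectory)(topo_pro, peptide_trajectory.coordinates,
                                        peptide_trajectory.frame_interval)
        series, excluded = idpdyn.nh_vectors(traj)
        assert 3 not in series
        assert any(rid == 3 and "proline" in reason for rid, reason in excluded)

    def test_global_rotation_changes_vectors_not_correlation(self, peptide_trajectory):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_rotvec([0.4, 0.9, -0.2]).as_matrix()
        rotated = type(peptide_trajectory)(
            peptide_trajectory.topology,
            peptide_trajectory.coordinates @ rot.T,
            peptide_trajectory.frame_interval,
        )
        s0, _ = idpdyn.nh_vectors(peptide_trajectory)
        s1, _ = idpdyn.nh_vectors(rotated)
        rid = next(iter(s0))
        assert not np.allclose(s0[rid].vectors, s1[rid].vectors)
        c0 = idpdyn.p2_autocorrelation(s0[rid])
        c1 = idpdyn.p2_autocorrelation(s1[rid])
        assert np.allclose(c0.values, c1.values, atol=1e-10)


class TestP2Autocorrelation:
    def test_constant_vector_gives_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        cf = idpdyn.p2_autocorrelation(UnitVectorSeries(v, 1.0))
        assert np.allclose(cf.values, 1.0, atol=1e-12)

    def test_ninety_degree_alternation(self):
        """x-hat/z-hat alternation: P2(cos 90) = -1/2 at odd lags, 1 at even."""
        v = np.tile([[1.0, 0, 0], [0, 0, 1.0]], (50, 1))
        cf = idpdyn.p2_autocorrelation(UnitVectorSeries(v, 1.0))
        assert np.allclose(cf.values[::2], 1.0, atol=1e-12)
        assert np.allclose(cf.values[1::2], -0.5, atol=1e-12)

    def test_isotropic_vectors_decorrelate_to_zero(self, rng):
        v = rng.normal(size=(100000, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        cf = idpdyn.p2_autocorrelation(UnitVectorSeries(v, 1.0))
        assert cf.values[0] == pytest.approx(1.0)
        # <P2^2> = 1/5 for iid directions -> noise ~ sqrt(1/5/n)
        assert np.abs(cf.values[1:]).max() < 0.02

    def test_fft_equals_brute_force(self, rng):
        v = rng.normal(size=(500, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        cf = idpdyn.p2_autocorrelation(UnitVectorSeries(v, 1.0))
        oracle = brute_force_p2(v, len(cf.values))
        assert np.abs(cf.values - oracle).max() < 1e-10

    def test_truncation_at_one_third(self):
        v = np.tile([0.0, 0.0, 1.0], (300, 1))
        cf = idpdyn.p2_autocorrelation(UnitVectorSeries(v, 2.0))
        assert cf.lags[-1] == pytest.approx(2.0 * 100)


class TestAverageCorrelation:
    def test_average_of_identical_inputs_is_unchanged(self):
        t = np.arange(0, 50.0)
        cf = CorrelationFunction(t, np.exp(-t / 7.0))
        avg = idpdyn.average_correlation([cf, cf, cf])
        assert np.allclose(avg.values, cf.values)
        assert avg.n_source_series == 3

    def test_linearity_midpoint(self):
        t = np.arange(0, 50.0)
        a = CorrelationFunction(t, np.exp(-t / 7.0))
        b = CorrelationFunction(t, np.exp(-t / 20.0))
        avg = idpdyn.average_correlation([a, b])
        assert np.allclose(avg.values, 0.5 * (a.values + b.values))

    def test_variance_reduction_with_replicas(self, rng):
        replicas = []
        for k in range(10):
            s = idpdyn.rotor_vector_series(200.0, 10.0, 5000, seed=50 + k)
            replicas.append(idpdyn.p2_autocorrelation(s))
        avg = idpdyn.average_correlation(replicas)
        tail = slice(100, None)
        single_var = np.mean([cf.values[tail].var() for cf in replicas])
        assert avg.values[tail].var() < single_var / 4  # ~10x expected

    def test_mismatched_grids_rejected(self):
        a = CorrelationFunction(np.arange(0, 10.0), np.ones(10))
        b = CorrelationFunction(np.arange(0, 20.0), np.ones(20))
        with pytest.raises(ValidationError):
            idpdyn.average_correlation([a, b])


class TestFitMultiexponential:
    def test_exact_single_exponential(self):
        t = np.arange(0, 3000.0, 10.0)
        fit = idpdyn.fit_multiexponential(CorrelationFunction(t, np.exp(-t / 250.0)),
                                          n_modes=6)
        assert fit.residual_ss < 1e-10
        dominant = fit.amplitudes.argmax()
        assert fit.taus[dominant] == pytest.approx(250.0, rel=1e-3)

    def test_exact_three_mode_curve_recovered_within_one_percent(self):
        t = np.arange(0, 60000.0, 10.0)
        amps = np.array([0.2, 0.5, 0.3])
        taus = np.array([30.0, 900.0, 15000.0])
        y = (amps * np.exp(-t[:, None] / taus)).sum(axis=1)
        fit = idpdyn.fit_multiexponential(CorrelationFunction(t, y), n_modes=3)
        assert np.allclose(fit.amplitudes, amps, rtol=0.01, atol=1e-4)
        assert np.allclose(fit.taus, taus, rtol=0.01)

    def test_amplitudes_sum_to_one_after_pruning(self):
        t = np.arange(0, 3000.0, 10.0)
        fit = idpdyn.fit_multiexponential(CorrelationFunction(t, np.exp(-t / 100.0)),
                                          n_modes=6)
        assert fit.amplitudes.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rotor_dominant_mode_within_ten_percent(self):
        s = idpdyn.rotor_vector_series(500.0, 10.0, 100000, seed=31)
        fit = idpdyn.fit_multiexponential(idpdyn.p2_autocorrelation(s))
        tau_eff = float(fit.amplitudes @ fit.taus)
        assert tau_eff == pytest.approx(500.0, rel=0.1)


class TestSpectralDensity:
    def test_single_mode_zero_frequency(self):
        fit = MultiExpFit(np.array([1.0]), np.array([5000.0]))
        assert spectral_density(fit, 0.0) == pytest.approx(2 * 5000e-12)

    def test_nonincreasing_in_frequency(self):
        fit = MultiExpFit(np.array([0.3, 0.7]), np.array([100.0, 8000.0]))
        omegas = np.geomspace(1e3, 1e12, 200)
        j = spectral_density(fit, omegas)
        assert np.all(np.diff(j) <= 1e-30)

    def test_fourier_sum_rule(self):
        from scipy.integrate import quad

        fit = MultiExpFit(np.array([0.25, 0.45, 0.3]), np.array([50.0, 1500.0, 20000.0]))
        # substitute omega = tan(u)/tau0 so the infinite range and the
        # widely separated Lorentzian widths are both resolved
        tau0 = 1.5e-9
        val, _ = quad(lambda u: spectral_density(fit, np.tan(u) / tau0)
                      / np.cos(u) ** 2 / tau0,
                      0, np.pi / 2 - 1e-12, limit=400)
        assert val / np.pi == pytest.approx(1.0, abs=1e-3)


class TestFieldConstants:
    def test_dual_implementation_of_prefactors(self):
        fc = field_constants(600.0)
        d00 = (1.0 / 20.0) * MU_0_OVER_4PI**2 * HBAR**2 * GAMMA_H**2 * GAMMA_N**2 \
            * (1.02e-10) ** -6
        c00 = (160e-6) ** 2 / 15.0
        assert fc.d00 == pytest.approx(d00, rel=1e-12)
        assert fc.c00 == pytest.approx(c00, rel=1e-12)
        assert fc.omega_h == pytest.approx(2 * np.pi * 600e6, rel=1e-12)
        assert fc.omega_n / fc.omega_h == pytest.approx(abs(GAMMA_N / GAMMA_H), rel=1e-9)

    def test_field_scaling_is_exact(self):
        a, b = field_constants(500.0), field_constants(1000.0)
        assert b.omega_h == pytest.approx(2 * a.omega_h, rel=1e-14)
        assert b.omega_n == pytest.approx(2 * a.omega_n, rel=1e-14)

    def test_longer_bond_weakens_dipolar_coupling(self):
        assert field_constants(600.0, r_nh=1.04).d00 < field_constants(600.0).d00


class TestRelaxationRates:
    def test_oracle_equivalence_over_tau_grid(self):
        fc = field_constants(600.0)
        for tau in np.geomspace(10.0, 100000.0, 12):
            fit = MultiExpFit(np.array([1.0]), np.array([tau]))
            r1, r2 = relaxation_rates(fit, fc)
            o1, o2 = lorentzian_rates(tau, fc)
            assert r1 == pytest.approx(o1, rel=1e-10)
            assert r2 == pytest.approx(o2, rel=1e-10)

    def test_fast_limit_rates_vanish(self):
        fc = field_constants(600.0)
        r1, r2 = relaxation_rates(MultiExpFit(np.array([1.0]), np.array([1e-4])), fc)
        assert r1 < 1e-6 and r2 < 1e-6

    def test_r1_has_maximum_r2_monotonic(self):
        fc = field_constants(600.0)
        taus = np.geomspace(10.0, 100000.0, 60)
        rates = np.array([relaxation_rates(MultiExpFit(np.array([1.0]),
                                                       np.array([t])), fc)
                          for t in taus])
        r1, r2 = rates[:, 0], rates[:, 1]
        peak = r1.argmax()
        assert 0 < peak < len(taus) - 1  # interior maximum near omega_N tau ~ 1
        assert np.abs(fc.omega_n * taus[peak] * 1e-12 - 1.0) < 0.5
        assert np.all(np.diff(r2) > 0)

    def test_r2_at_least_r1_for_random_fits(self, rng):
        for mhz in (500.0, 600.0, 850.0):
            fc = field_constants(mhz)
            for _ in range(300):
                n = rng.integers(1, 7)
                amps = rng.dirichlet(np.ones(n))
                taus = 10 ** rng.uniform(0, 5, size=n)
                r1, r2 = relaxation_rates(MultiExpFit(amps, taus), fc)
                assert r2 >= r1 > 0


class TestPipeline:
    def test_single_trajectory_has_zero_spread(self, peptide_trajectory):
        fc = field_constants(600.0)
        res = idpdyn.per_residue_pipeline([peptide_trajectory], fc)
        assert (res.rates["R1_std"] == 0).all()
        assert (res.rates["R2_std"] == 0).all()
        assert res.rates["residue_id"].tolist() == [2, 3, 4]

    def test_rates_invariant_under_global_rotation(self, peptide_trajectory):
        from scipy.spatial.transform import Rotation

        fc = field_constants(600.0)
        rot = Rotation.from_rotvec([1.0, 0.2, 0.5]).as_matrix()
        rotated = type(peptide_trajectory)(
            peptide_trajectory.topology,
            peptide_trajectory.coordinates @ rot.T,
            peptide_trajectory.frame_interval,
        )
        a = idpdyn.per_residue_pipeline([peptide_trajectory], fc).rates
        b = idpdyn.per_residue_pipeline([rotated], fc).rates
        # the P2 correlation functions agree to ~1e-14; the residual
        # difference is fit-convergence noise, so compare at 1e-4
        assert np.allclose(a["R1"], b["R1"], rtol=1e-4)
        assert np.allclose(a["R2"], b["R2"], rtol=1e-4)

    def test_rotor_trajectories_recover_analytic_rates(self):
        """Mean rates over rotor pseudo-residues match the Lorentzian oracle."""
        fc = field_constants(600.0)
        traj = idpdyn.rotor_nh_trajectory(6, tau_c=500.0, frame_interval=10.0,
                                          n_frames=50000, seed=29)
        res = idpdyn.per_residue_pipeline([traj], fc)
        o1, o2 = lorentzian_rates(500.0, fc)
        assert res.rates["R1"].mean() == pytest.approx(o1, rel=0.1)
        assert res.rates["R2"].mean() == pytest.approx(o2, rel=0.1)

    def test_excluding_trajectory_keeps_residue_coverage(self, peptide_trajectory):
        fc = field_constants(600.0)
        other = idpdyn.rotor_nh_trajectory(4, tau_c=300.0, frame_interval=10.0,
                                           n_frames=3000, seed=77, label="corrupt")
        both = idpdyn.per_residue_pipeline([peptide_trajectory, other], fc)
        one = idpdyn.per_residue_pipeline([peptide_trajectory, other], fc,
                                          exclude_labels=("corrupt",))
        assert both.rates["residue_id"].tolist() == one.rates["residue_id"].tolist()
        assert (one.rates[["R1_std", "R2_std"]] == 0).all().all()

    def test_unknown_exclusion_label_rejected(self, peptide_trajectory):
        with pytest.raises(ValidationError):
            idpdyn.per_residue_pipeline([peptide_trajectory], field_constants(600.0),
                                        exclude_labels=("nope",))


class TestTimescaleSummary:
    def test_fast_modes_aggregate(self):
        fits = {5: MultiExpFit(np.array([0.4, 0.6]), np.array([50.0, 2000.0]))}
        table = idpdyn.timescale_summary(fits, threshold=100.0)
        fast = table[table["is_fast_aggregate"]]
        assert fast["amplitude"].iloc[0] == pytest.approx(0.4)
        slow = table[~table["is_fast_aggregate"]]
        assert slow["tau_ps"].iloc[0] == pytest.approx(2000.0)

    def test_all_slow_modes_have_no_aggregate_row(self):
        fits = {1: MultiExpFit(np.array([0.5, 0.5]), np.array([500.0, 2000.0]))}
        table = idpdyn.timescale_summary(fits, threshold=100.0)
        assert not table["is_fast_aggregate"].any()

    def test_amplitude_conservation_per_residue(self):
        fits = {
            2: MultiExpFit(np.array([0.2, 0.3, 0.5]), np.array([10.0, 80.0, 5000.0])),
            3: MultiExpFit(np.array([1.0]), np.array([42.0])),
        }
        table = idpdyn.timescale_summary(fits, threshold=100.0)
        sums = table.groupby("residue_id")["amplitude"].sum()
        assert np.allclose(sums, 1.0)


class TestCompareToExperiment:
    def make_result(self, rids, r1, r2):
        import pandas as pd

        from idpdyn.relaxation import RelaxationResult

        df = pd.DataFrame({"residue_id": rids, "R1": r1, "R2": r2,
                           "R1_std": 0.0, "R2_std": 0.0})
        return RelaxationResult(rates=df, fits={}, excluded_residues=[])

    def test_identical_inputs(self):
        res = self.make_result([2, 3, 4], [1.1, 1.2, 1.3], [4.0, 4.5, 5.0])
        exp = idpdyn.ExperimentalRates(np.array([2, 3, 4]),
                                       np.array([1.1, 1.2, 1.3]),
                                       np.array([4.0, 4.5, 5.0]))
        out = idpdyn.compare_to_experiment(res, exp)
        assert out["rmse_R1"] == pytest.approx(0.0, abs=1e-14)
        assert out["pearson_R1"] == pytest.approx(1.0)

    def test_constant_offset_gives_rmse_offset_pearson_one(self):
        r1 = np.array([1.1, 1.3, 1.6, 1.9])
        res = self.make_result([2, 3, 4, 5], r1 + 0.25, [4.0, 4.5, 5.0, 5.5])
        exp = idpdyn.ExperimentalRates(np.array([2, 3, 4, 5]), r1,
                                       np.array([4.0, 4.5, 5.0, 5.5]))
        out = idpdyn.compare_to_experiment(res, exp)
        assert out["rmse_R1"] == pytest.approx(0.25)
        assert out["pearson_R1"] == pytest.approx(1.0)

    def test_four_point_textbook_example(self):
        calc_r1 = np.array([1.0, 2.0, 3.0, 4.0])
        exp_r1 = np.array([1.1, 1.9, 3.2, 3.7])
        res = self.make_result([1, 2, 3, 4], calc_r1, calc_r1)
        exp = idpdyn.ExperimentalRates(np.array([1, 2, 3, 4]), exp_r1, exp_r1)
        out = idpdyn.compare_to_experiment(res, exp)
        assert out["rmse_R1"] == pytest.approx(
            np.sqrt(np.mean((calc_r1 - exp_r1) ** 2)))
        assert out["pearson_R1"] == pytest.approx(np.corrcoef(calc_r1, exp_r1)[0, 1])

    def test_missing_cells_skipped_pairwise(self):
        res = self.make_result([1, 2, 3, 4], [1.0, 2.0, 3.0, 4.0], [5.0] * 4)
        exp = idpdyn.ExperimentalRates(
            np.array([1, 2, 3, 4]),
            np.array([1.0, 2.0, 3.0, 4.0]),
            np.array([5.0, np.nan, 5.0, 5.0]),
        )
        out = idpdyn.compare_to_experiment(res, exp)
        assert out["rmse_R2"] == pytest.approx(0.0, abs=1e-14)

    def test_too_few_common_residues_rejected(self):
        res = self.make_result([1, 2], [1.0, 2.0], [3.0, 4.0])
        exp = idpdyn.ExperimentalRates(np.array([1, 2]), np.array([1.0, 2.0]),
                                       np.array([3.0, 4.0]))
        with pytest.raises(ValidationError):
            idpdyn.compare_to_experiment(res, exp)
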