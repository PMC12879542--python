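"""Well-mixed batch integrator: conservation, limits, and trajectory metrics."""

import dataclasses

import numpy as np
import pytest

from batchcryst import (
    TAI_SHEI,
    CrystalPopulation,
    KineticRateParams,
    ProcessSchedule,
    SolutionBasis,
    build_grid,
    desupersaturation_time,
    detect_onset,
    mass_balance_audit,
    mszw,
    peak_supersaturation,
    simulate_batch,
)
from batchcryst.batch import ScheduleMode


class TestSchedule:
    def test_ramp_and_hold(self, schedule):
        assert schedule.temperature(0.0) == 70.0
        assert schedule.temperature(600.0) == pytest.approx(64.0)
        assert schedule.temperature(1e6) == 20.0
        assert schedule.ramp_duration == pytest.approx(5000.0)

    def test_jacket_flux_mode_requires_parameters(self):
        with pytest.raises(ValueError, match="jacket_flux"):
            ProcessSchedule(mode=ScheduleMode.JACKET_FLUX)

    def test_jacket_flux_rate(self):
        # 2499 W/m2 over 0.2 m2 against 49980 J/K gives 0.01 K/s = 0.6 K/min
        sched = ProcessSchedule(
            mode=ScheduleMode.JACKET_FLUX,
            heat_flux=2499.0, wetted_area=0.2, thermal_mass=49980.0,
        )
        assert sched.rate_K_per_s == pytest.approx(0.01)

    def test_heating_schedule_rejected(self):
        with pytest.raises(ValueError):
            ProcessSchedule(T0=20.0, T_final=70.0)


class TestEquilibriumAndLimits:
    def test_equilibrium_fixed_point(self, grid40, solub, basis):
        sched = ProcessSchedule(T0=70.0, T_final=20.0, cooling_rate=1e-9)
        traj = simulate_batch(
            sched, TAI_SHEI, grid40, solub, basis, C0=solub(70.0), duration=2000.0
        )
        np.testing.assert_allclose(traj.C, traj.C[0], rtol=1e-12)
        assert np.all(traj.phi_T < 1e-20)  # residual nucleation from the ~0 ramp
        assert detect_onset(traj) is None
        assert mass_balance_audit(traj) < 1e-12

    def test_pure_cooling_closed_form(self, schedule, grid40, solub, basis):
        """With kinetics off and no seeds, S(t) = C0/C*(T(t)) exactly."""
        traj = simulate_batch(
            schedule, TAI_SHEI, grid40, solub, basis, nucleation_on=False
        )
        np.testing.assert_allclose(traj.C, basis.C0, rtol=1e-12)
        np.testing.assert_allclose(traj.S, basis.C0 / solub(traj.T), rtol=1e-12)


class TestSeededGrowth:
    def test_deposition_matches_quadrature_oracle(self, grid40, solub, basis, schedule):
        """Deposited volume equals the trapezoid integral of sum(N_i Gv_i)."""
        alpha0 = np.zeros(40)
        j = np.argmin(np.abs(grid40.d - 50e-6))
        alpha0[j] = 1e10 * grid40.V[j]  # 1e10 #/m3 at ~50 um
        traj = simulate_batch(
            schedule, TAI_SHEI, grid40, solub, basis,
            seed_population=CrystalPopulation(alpha0),
            sigma_override=0.3, nucleation_on=False, duration=1000.0,
        )
        N = traj.alpha / grid40.V
        Gv = 3.0 * grid40.V / grid40.d * traj.G[:, None]
        deposited_oracle = np.trapezoid((N * Gv).sum(axis=1), traj.time)
        deposited = traj.phi_T[-1] - traj.phi_T[0]
        assert deposited == pytest.approx(deposited_oracle, rel=0.01)

    def test_mean_diameter_advances_at_growth_rate(self, solub, basis):
        """Volume-weighted mean diameter advances at ~G on a fine grid."""
        grid = build_grid(1e-6, 1000e-6, 80)
        j = 40
        alpha0 = np.zeros(80)
        alpha0[j] = 1e-9
        G = 1e-8
        kin = KineticRateParams(kN=0.0, n=1.0, kG=G, g=1.0)
        t_decade = 9.0 * grid.d[j] / G
        sched = ProcessSchedule(T0=70.0, T_final=20.0, cooling_rate=1e-9)
        traj = simulate_batch(
            sched, kin, grid, solub, basis,
            seed_population=CrystalPopulation(alpha0),
            sigma_override=1.0, nucleation_on=False, duration=t_decade,
        )
        dv0 = (traj.alpha[0] * grid.d).sum() / traj.alpha[0].sum()
        dv1 = (traj.alpha[-1] * grid.d).sum() / traj.alpha[-1].sum()
        advance = (dv1 - dv0) / (G * t_decade)
        assert advance == pytest.approx(1.0, abs=0.15)

    def test_number_conserved_without_nucleation(self, grid40, solub, basis, schedule):
        alpha0 = np.zeros(40)
        alpha0[8] = 1e-6
        traj = simulate_batch(
            schedule, TAI_SHEI, grid40, solub, basis,
            seed_population=CrystalPopulation(alpha0),
            sigma_override=0.2, nucleation_on=False, duration=2000.0,
        )
        N_total = (traj.alpha / grid40.V).sum(axis=1)
        np.testing.assert_allclose(N_total, N_total[0], rtol=1e-7)


class TestReferenceRun:
    def test_single_supersaturation_maximum(self, reference_run):
        """S rises to one maximum then decays: one sign change of dS/dt."""
        dS = np.diff(reference_run.S)
        signs = np.sign(dS[dS != 0.0])
        flips = np.nonzero(np.diff(signs) != 0)[0]
        assert flips.size == 1

    def test_solids_fraction_nondecreasing(self, reference_run):
        assert np.all(np.diff(reference_run.phi_T) >= -1e-15)

    def test_mass_balance(self, reference_run):
        assert mass_balance_audit(reference_run) < 1e-6

    def test_time_grid_strictly_increasing(self, reference_run):
        assert np.all(np.diff(reference_run.time) > 0)

    def test_trajectory_csv_round_trip(self, reference_run, tmp_path):
        path = tmp_path / "traj.csv"
        reference_run.to_csv(path)
        import pandas as pd

        df = pd.read_csv(path)
        assert len(df) == reference_run.time.size
        np.testing.assert_allclose(df["S"].to_numpy(), reference_run.S, rtol=1e-6)


class TestTrajectoryMetrics:
    def test_onset_interpolation_and_threshold_ordering(self, reference_run):
        onset1 = detect_onset(reference_run, threshold=0.01)
        onset2 = detect_onset(reference_run, threshold=0.02)
        assert onset1 is not None and onset2 is not None
        assert onset2.t_onset > onset1.t_onset
        # a larger detection threshold cannot shrink the metastable zone width
        assert mszw(reference_run, 70.0, threshold=0.02) >= mszw(
            reference_run, 70.0, threshold=0.01
        )

    def test_zero_threshold_returns_first_decrease(self, reference_run):
        onset = detect_onset(reference_run, threshold=0.0)
        k = np.nonzero(np.diff(reference_run.C) < 0)[0][0] + 1
        assert onset.t_onset == pytest.approx(reference_run.time[k])

    def test_mszw_identity(self, reference_run):
        onset = detect_onset(reference_run)
        assert mszw(reference_run, onset.T_onset) == pytest.approx(0.0, abs=1e-12)

    def test_peak_at_endpoint_for_monotone_run(self, schedule, grid40, solub, basis):
        traj = simulate_batch(
            schedule, TAI_SHEI, grid40, solub, basis, nucleation_on=False
        )
        t_peak, S_peak = peak_supersaturation(traj)
        assert t_peak == traj.time[-1]
        assert S_peak == traj.S[-1]

    def test_peak_parabolic_interpolation(self, reference_run):
        t_peak, S_peak = peak_supersaturation(reference_run)
        k = np.argmax(reference_run.S)
        assert S_peak >= reference_run.S[k]
        assert abs(t_peak - reference_run.time[k]) <= np.diff(reference_run.time).max()

    def test_desupersaturation_time_interpolates(self, reference_run):
        traj = dataclasses.replace(
            reference_run, S=np.where(reference_run.S > 0, reference_run.S, 0)
        )
        k = np.argmax(traj.S)
        threshold = 0.5 * (traj.S[k] + traj.S[-1])
        t = desupersaturation_time(traj, threshold)
        assert traj.time[k] < t < traj.time[-1]
        assert np.interp(t, traj.time, traj.S) == pytest.approx(threshold, rel=1e-6)

    def test_desupersaturation_not_reached_is_nan(self, reference_run):
        assert np.isnan(desupersaturation_time(reference_run, 1e-6))

    def test_perturbed_trajectory_fails_audit_honestly(self, reference_run):
        bad = dataclasses.replace(reference_run, C=reference_run.C * 0.95)
        assert mass_balance_audit(bad) > 1e-3
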