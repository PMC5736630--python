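"""MSD estimators, power-law fits, regime labels, drift correction, physics."""
import numpy as np
import pytest
from hypothesis import given, strategies as st

import microrheo as mr
from microrheo.analysis import MSDCurve
from microrheo.tracking import Trajectory, TrajectoryEnsemble


def _traj(pid, x, y, frames=None):
    n = len(x)
    return Trajectory(pid, frames if frames is not None else np.arange(n), x, y)


def _ens(trajs, fps=1.0):
    return TrajectoryEnsemble(list(trajs), fps=fps, pixel_size=1.0)


class TestTrajectoryMSD:
    def test_hand_computed_example(self):
        """Positions (0,0),(1,0),(1,1) at 1 fps: MSD(1)=1, MSD(2)=2."""
        t = _traj(0, [0.0, 1.0, 1.0], [0.0, 0.0, 1.0])
        curve = mr.trajectory_msd(t, 2, fps=1.0)
        assert np.allclose(curve.lag_s, [1.0, 2.0])
        assert np.allclose(curve.msd, [1.0, 2.0])

    def test_constant_trajectory_zero(self):
        t = _traj(0, np.ones(20), np.ones(20))
        assert np.all(mr.trajectory_msd(t, 10, fps=1.0).msd == 0.0)

    @given(st.floats(0.01, 10.0), st.floats(1.0, 120.0))
    def test_ballistic_closed_form(self, v, fps):
        """Constant velocity: MSD(k) = (v k / fps)^2 exactly."""
        frames = np.arange(30)
        t = _traj(0, v * frames / fps, np.zeros(30))
        curve = mr.trajectory_msd(t, 10, fps=fps)
        assert np.allclose(curve.msd, (v * curve.lag_s) ** 2, rtol=1e-9)

    def test_max_lag_truncated_to_span(self):
        t = _traj(0, np.arange(5.0), np.zeros(5))
        curve = mr.trajectory_msd(t, 100, fps=1.0)
        assert len(curve.lag_s) == 4

    def test_too_short_rejected(self):
        with pytest.raises(mr.AnalysisError):
            mr.trajectory_msd(_traj(0, [0.0], [0.0]), 5)


class TestEnsembleMSD:
    def test_mean_of_two_trajectories(self):
        """Per-trajectory MSD(1) of 1 and 3 um^2 averages to 2 um^2."""
        a = _traj(0, [0.0, 1.0, 0.0, 1.0], [0.0] * 4)
        s3 = np.sqrt(3.0)
        b = _traj(1, [0.0, s3, 0.0, s3], [0.0] * 4)
        curve = mr.ensemble_msd(_ens([a, b]), 1, min_traj_length=2)
        assert curve.msd[0] == pytest.approx(2.0)
        assert curve.n_traj[0] == 2

    def test_identical_trajectories_equal_individual(self):
        x = np.cumsum(np.random.default_rng(0).normal(0, 1, 50))
        trajs = [_traj(i, x, np.zeros(50)) for i in range(5)]
        ens_curve = mr.ensemble_msd(_ens(trajs), 10, min_traj_length=2)
        ind_curve = mr.trajectory_msd(trajs[0], 10, fps=1.0)
        assert np.allclose(ens_curve.msd, ind_curve.msd)

    def test_brownian_consistency_and_error_scaling(self):
        """N independent Brownian trajectories give 4Dt within 3 SE at
        N = 200; the standard error shrinks as 1/sqrt(N) down to the
        experimental minimum of 25 trajectories (where the SEM estimate
        itself is too noisy for a strict per-lag 3-SE bound)."""
        def curve_for(n):
            cfg = mr.SimConfig(model="brownian", n_particles=n, n_frames=400,
                               fps=60.0, seed=n, model_params={"D": 0.15})
            return mr.ensemble_msd(mr.simulate(cfg).to_ensemble(), 60,
                                   min_traj_length=110)

        c200 = curve_for(200)
        z = np.abs(c200.msd - mr.brownian_msd(c200.lag_s, 0.15)) / c200.sem
        assert z.max() < 3.0

        c25 = curve_for(25)
        rel_err_25 = np.abs(c25.msd / mr.brownian_msd(c25.lag_s, 0.15) - 1)
        assert rel_err_25.max() < 0.5       # still consistent, just noisier
        ratio = np.median(c25.sem / c25.msd) / np.median(c200.sem / c200.msd)
        assert ratio == pytest.approx(np.sqrt(200 / 25), rel=0.35)

    def test_min_length_error_names_threshold(self):
        short = _traj(0, [0.0, 1.0], [0.0, 0.0])
        with pytest.raises(mr.AnalysisError, match="min_traj_length=110"):
            mr.ensemble_msd(_ens([short]), 10, min_traj_length=110)


class TestPowerLawFit:
    def _grid(self):
        return np.arange(1, 101) / 60.0

    def test_exact_brownian_line(self):
        t = self._grid()
        curve = MSDCurve(t, 4 * 0.15 * t, np.full(100, 200), 60.0)
        fit = mr.fit_power_law(curve)
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)
        assert fit.prefactor == pytest.approx(0.60, rel=1e-9)
        assert fit.d == pytest.approx(1.0, abs=1e-3)

    def test_exact_subdiffusive_power(self):
        t = self._grid()
        curve = MSDCurve(t, 0.5 * t ** 0.4, np.full(100, 200), 60.0)
        assert mr.fit_power_law(curve).exponent == pytest.approx(0.4, abs=1e-9)

    def test_flat_msd_zero_slope(self):
        t = self._grid()
        curve = MSDCurve(t, np.full(100, 0.010), np.full(100, 200), 60.0)
        fit = mr.fit_power_law(curve)
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)
        assert fit.d == pytest.approx(0.1, rel=1e-9)

    @given(st.floats(0.0, 2.0), st.floats(1e-3, 1e3))
    def test_exact_recovery_any_exponent(self, n, a):
        """Noiseless power laws are recovered exactly for any n in [0, 2]."""
        t = self._grid()
        curve = MSDCurve(t, a * t ** n, np.full(100, 10), 60.0)
        fit = mr.fit_power_law(curve)
        assert fit.exponent == pytest.approx(n, abs=1e-8)
        assert fit.prefactor == pytest.approx(a, rel=1e-6)

    def test_window_includes_camera_grid_endpoints(self):
        """The 1/60 s and 100/60 s grid lags sit inside the printed window."""
        t = self._grid()
        curve = MSDCurve(t, t, np.full(100, 10), 60.0)
        fit = mr.fit_power_law(curve)
        assert fit.n_points == 100
        assert fit.ref_lag == pytest.approx(100 / 60)

    def test_too_few_points_rejected(self):
        curve = MSDCurve([0.1, 0.2], [1.0, 2.0], [5, 5], 60.0)
        with pytest.raises(mr.AnalysisError):
            mr.fit_power_law(curve)

    def test_zero_msd_points_excluded(self):
        t = self._grid()
        msd = 4 * 0.15 * t
        msd[:3] = 0.0
        curve = MSDCurve(t, msd, np.full(100, 10), 60.0)
        fit = mr.fit_power_law(curve)
        assert fit.n_points == 97
        assert fit.exponent == pytest.approx(1.0, abs=1e-9)


REGIME_ORDER = {"elastic": 0, "subdiffusive": 1, "diffusive": 2,
                "superdiffusive": 3}


class TestRegimeClassification:
    @pytest.mark.parametrize("n,expected", [
        (0.05, "elastic"), (0.09, "elastic"), (0.11, "subdiffusive"),
        (0.5, "subdiffusive"), (0.9, "diffusive"), (1.0, "diffusive"),
        (1.1, "diffusive"), (1.4, "superdiffusive"),
    ])
    def test_labels(self, n, expected):
        label = mr.classify_regime(n)
        assert label.regime == expected
        assert label.elastic_max == 0.1
        assert label.diffusive_band == (0.9, 1.1)

    def test_elastic_threshold_is_exactly_one_tenth(self):
        from microrheo.analysis import ELASTIC_MAX
        assert ELASTIC_MAX == 0.1

    @given(st.floats(-0.5, 2.5), st.floats(-0.5, 2.5))
    def test_threshold_monotone(self, n1, n2):
        """Increasing n never moves the label toward elastic."""
        lo, hi = sorted([n1, n2])
        assert (REGIME_ORDER[mr.classify_regime(lo).regime]
                <= REGIME_ORDER[mr.classify_regime(hi).regime])

    def test_nonfinite_rejected(self):
        with pytest.raises(mr.ParameterError):
            mr.classify_regime(float("nan"))


class TestDriftCorrection:
    def test_common_mode_removed_to_machine_precision(self):
        """Static particles plus arbitrary drift: corrected displacements 0."""
        rng = np.random.default_rng(0)
        drift = np.cumsum(rng.normal(0, 1.0, (60, 2)), axis=0)
        trajs = [_traj(i, drift[:, 0] + i, drift[:, 1] - i) for i in range(7)]
        corrected = mr.subtract_drift(_ens(trajs, fps=60.0))
        for t in corrected.trajectories:
            assert np.abs(np.diff(t.positions, axis=0)).max() < 1e-12

    def test_single_trajectory_warns_and_zeroes(self):
        t = _traj(0, np.arange(10.0), np.zeros(10))
        with pytest.warns(UserWarning, match="single trajectory"):
            out = mr.subtract_drift(_ens([t]))
        assert np.abs(np.diff(out.trajectories[0].positions, axis=0)).max() < 1e-12

    def test_empty_ensemble_rejected(self):
        with pytest.raises(mr.AnalysisError):
            mr.subtract_drift(_ens([]))

    def test_paired_seed_diffusivity_recovery(self):
        """Drifted and drift-free runs with the same dynamics seed agree on D
        after correction (within 5%), and correction carries the (N-1)/N
        self-subtraction bias."""
        N = 100
        cfg = mr.SimConfig(model="brownian", n_particles=N, n_frames=500,
                           fps=60.0, seed=21, model_params={"D": 0.15})
        truth = mr.simulate(cfg)
        drifted = mr.apply_drift(
            truth, mr.drift_from_velocity([30.0, -18.0], 500, 60.0))

        def fit_D(ens):
            c = mr.ensemble_msd(ens, 20, min_traj_length=400)
            return np.polyfit(c.lag_s, c.msd, 1)[0] / 4

        d_raw = fit_D(truth.to_ensemble())
        d_corr = fit_D(mr.subtract_drift(truth.to_ensemble()))
        d_drift = fit_D(mr.subtract_drift(drifted.to_ensemble()))
        assert d_drift == pytest.approx(d_corr, rel=1e-9)   # exact removal
        assert d_drift == pytest.approx(d_raw, rel=0.05)
        assert d_corr / d_raw == pytest.approx((N - 1) / N, abs=0.01)


class TestDiffusivityReferences:
    def test_apparent_diffusivity_of_brownian_curve(self):
        t = np.arange(1, 101) / 60.0
        curve = MSDCurve(t, 4 * 0.15 * t, np.full(100, 10), 60.0)
        for lag in (0.1, 0.5, 1.67):
            assert mr.apparent_diffusivity(curve, lag) == pytest.approx(0.15)

    def test_flat_msd_gives_decreasing_apparent_diffusivity(self):
        t = np.arange(1, 101) / 60.0
        curve = MSDCurve(t, np.full(100, 0.01), np.full(100, 10), 60.0)
        d1 = mr.apparent_diffusivity(curve, 0.1)
        d2 = mr.apparent_diffusivity(curve, 1.0)
        assert d2 < d1

    def test_out_of_range_lag_rejected(self):
        t = np.arange(1, 11) / 60.0
        curve = MSDCurve(t, t, np.full(10, 5), 60.0)
        with pytest.raises(mr.AnalysisError):
            mr.apparent_diffusivity(curve, 5.0)

    def test_activity_ratio(self):
        assert mr.activity_ratio(0.98, 0.49) == pytest.approx(2.0)

    def test_stokes_einstein_water_probe(self):
        """R = 0.5 um, eta = 0.89 mPa s, T = 298 K -> D = 0.49 um^2/s."""
        d = mr.thermal_diffusivity(0.5e-6, 0.89e-3, 298.0)
        assert d == pytest.approx(0.49, abs=0.005)

    def test_stokes_einstein_scalings(self):
        base = mr.thermal_diffusivity(0.5e-6, 1e-3, 298.0)
        assert mr.thermal_diffusivity(1.0e-6, 1e-3, 298.0) == pytest.approx(base / 2)
        assert mr.thermal_diffusivity(0.5e-6, 2e-3, 298.0) == pytest.approx(base / 2)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(mr.ParameterError):
            mr.thermal_diffusivity(-1e-6, 1e-3)


class TestTrappingEnergy:
    def test_zero_area_zero_energy(self):
        assert mr.trapping_energy(0.05, 0.0).joules == 0.0

    def test_micron_probe_at_oil_water_interface(self):
        """gamma = 53 mN/m over a 0.5 um-radius disk: ~4.2e-14 J ~ 1e7 kT."""
        area = np.pi * (0.5e-6) ** 2
        e = mr.trapping_energy(53e-3, area, 298.0)
        assert e.joules == pytest.approx(4.2e-14, rel=0.02)
        assert e.kT == pytest.approx(1.0e7, rel=0.05)

    @given(st.floats(1e-3, 1.0), st.floats(1e-15, 1e-10))
    def test_linearity_in_tension(self, gamma, area):
        assert mr.trapping_energy(2 * gamma, area).joules == pytest.approx(
            2 * mr.trapping_energy(gamma, area).joules)


class TestTimecourse:
    def _brownian_ages(self, ages, D=0.5, n=30, seed=0):
        out = []
        for k, age in enumerate(ages):
            cfg = mr.SimConfig(model="brownian", n_particles=n, n_frames=360,
                               fps=60.0, seed=seed + k, model_params={"D": D})
            out.append((age, mr.simulate(cfg).to_ensemble(surface_age=age)))
        return out

    def test_all_brownian_ages_stay_diffusive(self):
        result = mr.analyze_timecourse(self._brownian_ages([60, 600, 3600]))
        assert [s.label.regime for s in result.summaries] == ["diffusive"] * 3
        assert result.transition_age is None
        assert result.subdiffusive_onset_age is None

    def test_low_count_age_skipped_with_warning(self):
        ages = self._brownian_ages([60, 600, 3600])
        ages[1] = (600, _ens([_traj(0, np.arange(120.0), np.zeros(120))],
                             fps=60.0))
        with pytest.warns(UserWarning, match="skipped"):
            result = mr.analyze_timecourse(ages, min_traj_count=5)
        assert result.skipped_ages == [600]
        assert len(result.summaries) == 2

    def test_pao1_like_arrest_detected(self):
        scen = mr.build_aging_scenario("PAO1_like", seed=3)
        age_ens = [(a, t.to_ensemble(surface_age=a))
                   for a, t in scen.simulate(seed=3)]
        result = mr.analyze_timecourse(age_ens)
        assert result.subdiffusive_onset_age == 3600.0
        assert result.transition_age is not None
        assert result.transition_age <= 1e4

    def test_pa14_like_never_arrests(self):
        scen = mr.build_aging_scenario("PA14_like", seed=3)
        age_ens = [(a, t.to_ensemble(surface_age=a))
                   for a, t in scen.simulate(seed=3)]
        result = mr.analyze_timecourse(age_ens)
        assert result.transition_age is None
        assert max(result.ages) >= 8e4

    def test_requires_two_ages(self):
        with pytest.raises(mr.AnalysisError):
            mr.analyze_timecourse(self._brownian_ages([60]))
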