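"""OCE inversion: phase conversion, delay estimation, slope fit, modulus."""

import numpy as np
import pytest

from spheromech import oce, synth
from spheromech.errors import (
    ConfigurationError,
    InsufficientDataError,
    MeasurementFailureError,
    NoPropagatingWaveError,
)


def _noiseless_map(speed=2.0, **kw):
    return synth.make_oce_phase_map(
        synth.OCESimConfig(true_speed_mps=speed, phase_noise_std_rad=0.0, **kw)
    )


class TestPhaseToDisplacement:
    def test_known_conversion_value(self):
        """dphi = pi at 1310 nm, n = 1.38 -> u = 1310/(4*1.38) ~ 237.3 nm."""
        phi = np.full((8, 8), np.pi)
        m = oce.SpatioTemporalMap(phi, "phase", 1.0, 1e-5, 1310.0, 1.38)
        u = oce.phase_to_displacement(m, unwrap=False)
        assert u.kind == "displacement"
        assert np.allclose(u.values, 1310.0 / (4 * 1.38))

    def test_zero_phase_gives_zero_displacement(self):
        m = oce.SpatioTemporalMap(np.zeros((8, 8)), "phase", 1.0, 1e-5, 1310.0, 1.38)
        assert np.all(oce.phase_to_displacement(m).values == 0)

    def test_round_trip_inverts_forward_model(self):
        """synth phase conversion followed by the inverse reproduces u exactly."""
        cfg = synth.OCESimConfig(phase_noise_std_rad=0.0)
        m = synth.make_oce_phase_map(cfg)
        u = oce.phase_to_displacement(m)
        # rebuild the forward displacement field directly
        z = np.arange(cfg.n_depth) * cfg.axial_pitch_um
        t = np.arange(cfg.n_frames) * cfg.frame_interval_s
        arrival = cfg.pulse_center_time_s + z[:, None] * 1e-6 / cfg.true_speed_mps
        expected = cfg.displacement_amplitude_nm * np.exp(
            -((t[None, :] - arrival) ** 2) / (2 * cfg.pulse_width_s**2)
        )
        np.testing.assert_allclose(u.values, expected, atol=1e-10)

    def test_missing_wavelength_is_configuration_error(self):
        m = oce.SpatioTemporalMap(np.zeros((8, 8)), "phase", 1.0, 1e-5)
        with pytest.raises(ConfigurationError):
            oce.phase_to_displacement(m)


class TestEstimateDelays:
    def test_delay_difference_matches_forward_arithmetic(self):
        """At c = 2 m/s, 100 um of depth adds 50 us of delay."""
        cfg = synth.OCESimConfig(true_speed_mps=2.0, phase_noise_std_rad=0.0)
        u = oce.phase_to_displacement(synth.make_oce_phase_map(cfg))
        prof = oce.estimate_delays(u)
        i1 = int(round(100 / cfg.axial_pitch_um))
        dt = prof.delays_s[i1] - prof.delays_s[0]
        assert dt == pytest.approx(50e-6, abs=0.3 * cfg.frame_interval_s)

    def test_global_time_shift_gives_constant_delay(self):
        u = oce.phase_to_displacement(_noiseless_map())
        k = 5
        shifted = oce.SpatioTemporalMap(
            np.roll(u.values, k, axis=1), "displacement", u.axial_pitch_um, u.frame_interval_s,
            u.center_wavelength_nm, u.refractive_index,
        )
        prof = oce.estimate_delays(shifted, reference_depth_um=0.0)
        ref_prof = oce.estimate_delays(u, reference_depth_um=0.0)
        # shifting every waveform equally leaves relative delays unchanged
        np.testing.assert_allclose(prof.delays_s, ref_prof.delays_s, atol=1e-7)

    def test_pure_noise_flagged_low_quality(self, rng):
        v = rng.normal(size=(32, 256))
        m = oce.SpatioTemporalMap(v, "displacement", 5.0, 1e-5)
        prof = oce.estimate_delays(m)
        # the reference depth correlates with itself; all others must be poor
        others = np.delete(prof.quality, 0)
        assert np.median(others) < 0.5

    def test_flat_waveform_flagged_not_raised(self):
        u = oce.phase_to_displacement(_noiseless_map())
        v = u.values.copy()
        v[10, :] = 3.14  # constant -> zero variance
        m = oce.SpatioTemporalMap(v, "displacement", u.axial_pitch_um, u.frame_interval_s)
        prof = oce.estimate_delays(m)
        assert prof.quality[10] == 0.0 and np.isnan(prof.delays_s[10])

    def test_antisymmetry_under_reference_swap(self):
        u = oce.phase_to_displacement(_noiseless_map())
        z = u.depths_um
        a = oce.estimate_delays(u, reference_depth_um=z[5])
        b = oce.estimate_delays(u, reference_depth_um=z[40])
        # delay of 40 relative to 5 negates delay of 5 relative to 40
        assert a.delays_s[40] == pytest.approx(-b.delays_s[5], abs=1e-7)

    def test_requires_displacement_kind(self):
        m = _noiseless_map()
        with pytest.raises(ConfigurationError):
            oce.estimate_delays(m)


class TestFitWaveSpeed:
    def test_exact_line_recovers_speed_with_unit_r2(self):
        z = np.linspace(0, 400, 32)
        prof = oce.DelayProfile(z, z * 1e-6 / 2.0, np.ones_like(z), 0.0)
        fit = oce.fit_wave_speed(prof)
        assert fit.speed_mps == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_ols_matches_normal_equation_oracle(self, rng):
        """The OLS slope equals the closed-form normal-equation solution."""
        for _ in range(20):
            z = np.sort(rng.uniform(0, 400, size=12))
            tau = 1e-4 + z * 1e-6 / rng.uniform(0.5, 4) + rng.normal(0, 1e-6, size=12)
            prof = oce.DelayProfile(z, tau, np.ones_like(z), 0.0)
            fit = oce.fit_wave_speed(prof)
            x = z * 1e-6
            X = np.column_stack([np.ones_like(x), x])
            beta = np.linalg.solve(X.T @ X, X.T @ tau)
            assert fit.slope_s_per_m == pytest.approx(beta[1], rel=1e-9)
            assert fit.speed_mps == pytest.approx(1.0 / beta[1], rel=1e-9)

    def test_theil_sen_resists_single_outlier(self):
        z = np.linspace(0, 400, 32)
        tau = z * 1e-6 / 2.0
        tau[3] += 5e-4  # gross outlier
        prof = oce.DelayProfile(z, tau, np.ones_like(z), 0.0)
        fit = oce.fit_wave_speed(prof, fit="theil_sen")
        assert fit.speed_mps == pytest.approx(2.0, rel=0.02)

    def test_constant_delays_raise_no_wave(self):
        z = np.linspace(0, 400, 16)
        prof = oce.DelayProfile(z, np.full_like(z, 1e-4), np.ones_like(z), 0.0)
        with pytest.raises(NoPropagatingWaveError):
            oce.fit_wave_speed(prof)

    def test_too_few_quality_depths_raise(self):
        z = np.linspace(0, 400, 16)
        q = np.zeros_like(z)
        q[:2] = 1.0
        prof = oce.DelayProfile(z, z * 1e-6, q, 0.0)
        with pytest.raises(InsufficientDataError):
            oce.fit_wave_speed(prof)


class TestYoungModulus:
    @pytest.mark.parametrize("c", [0.0, 0.5, 1.0, 2.0, 7.3])
    def test_default_params_give_2980_c_squared(self, c):
        assert oce.young_modulus(c) == pytest.approx(2980.0 * c**2)

    def test_homogeneity_degree_two(self, rng):
        params = oce.ElasticityParams(density_kg_m3=1060, poisson_ratio=0.45)
        for c in rng.uniform(0.1, 5.0, size=10):
            assert oce.young_modulus(2 * c, params) == pytest.approx(4 * oce.young_modulus(c, params))

    def test_negative_speed_rejected(self):
        with pytest.raises(ConfigurationError):
            oce.young_modulus(-1.0)


class TestAnalyzeMeasurement:
    def test_identical_noiseless_triplicate(self):
        maps = [_noiseless_map() for _ in range(3)]
        res = oce.analyze_oce_measurement(maps)
        assert res.wave_speed_mps == pytest.approx(2.0, rel=0.01)
        assert res.speed_stderr_mps == pytest.approx(0.0, abs=1e-9)
        assert res.young_modulus_pa == pytest.approx(2980 * res.wave_speed_mps**2)

    def test_replicate_mean_and_sd(self):
        maps = [_noiseless_map(speed=c) for c in (1.9, 2.0, 2.1)]
        res = oce.analyze_oce_measurement(maps)
        assert res.wave_speed_mps == pytest.approx(2.0, rel=0.01)
        assert res.speed_stderr_mps == pytest.approx(0.1, rel=0.05)
        assert len(res.replicate_speeds_mps) == 3

    def test_partial_failure_warns_and_uses_valid_replicates(self, rng):
        good = [_noiseless_map(), _noiseless_map()]
        noise = oce.SpatioTemporalMap(
            np.clip(rng.normal(0, 0.01, size=(64, 256)), -np.pi, np.pi),
            "phase", 6.25, 1e-5, 1310.0, 1.38,
        )
        with pytest.warns(UserWarning, match="replicate failed"):
            res = oce.analyze_oce_measurement(good + [noise])
        assert len(res.replicate_speeds_mps) == 2

    def test_all_failed_raises_with_reasons(self, rng):
        noise = oce.SpatioTemporalMap(
            np.clip(rng.normal(0, 0.01, size=(64, 256)), -np.pi, np.pi),
            "phase", 6.25, 1e-5, 1310.0, 1.38,
        )
        with pytest.raises(MeasurementFailureError) as exc:
            oce.analyze_oce_measurement([noise])
        assert exc.value.reasons


class TestParameterRecoveryProperties:
    @pytest.mark.parametrize("speed", [0.5, 1.0, 2.0, 4.0])
    def test_noiseless_recovery_under_one_percent(self, speed):
        res = oce.analyze_oce_measurement([_noiseless_map(speed=speed)])
        assert abs(res.wave_speed_mps - speed) / speed < 0.01
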