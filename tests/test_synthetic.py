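"""Generators: seed determinism, calibrated statistical structure, and the
chopper-velocimetry round trip."""

import numpy as np
import pytest

from kdtli import (
    TOFRecord,
    fluctuation_stats,
    fit_fringe,
    make_deflection_series,
    make_fringe_scan,
    make_property_series,
    make_tof_record,
    make_velocity_distribution,
    make_visibility_curve,
    reconstruct_velocities,
    visibility_vs_power,
    LaserSettings,
)
from kdtli.errors import DeconvolutionError, ValidationError
from kdtli.synthetic import m_sequence, _tof_density

D = 266e-9


class TestVelocityDistribution:
    def test_moments_match_request(self):
        dist = make_velocity_distribution(200.0, 0.45, 41)
        assert dist.mean_mps == pytest.approx(200.0, rel=0.005)
        assert dist.fwhm_fraction == pytest.approx(0.45, rel=0.02)

    def test_seed_has_no_effect_on_deterministic_grid(self):
        a = make_velocity_distribution(200.0, 0.45, seed=1)
        b = make_velocity_distribution(200.0, 0.45, seed=99)
        assert np.array_equal(a.velocities_mps, b.velocities_mps)
        assert np.array_equal(a.weights, b.weights)

    def test_zero_spread_limit_is_single_velocity(self):
        dist = make_velocity_distribution(180.0, 0.0)
        assert len(dist) == 1
        assert dist.mean_mps == 180.0


class TestFringeScan:
    def test_seed_determinism(self):
        a = make_fringe_scan(0.32, seed=42)
        b = make_fringe_scan(0.32, seed=42)
        assert np.array_equal(a.counts, b.counts)
        c = make_fringe_scan(0.32, seed=43)
        assert not np.array_equal(a.counts, c.counts)

    def test_zero_visibility_scan_fits_to_zero(self):
        scan = make_fringe_scan(0.0, mean_counts=500.0, seed=2)
        result = fit_fringe(scan, D)
        lo, hi = result.ci68["visibility"]
        assert lo <= 0.0 <= hi or result.visibility < 3 * result.visibility_sigma

    def test_caption_visibility_recovered_within_interval(self):
        hits = 0
        for seed in range(60):
            result = fit_fringe(make_fringe_scan(0.32, seed=seed), D)
            lo, hi = result.ci68["visibility"]
            hits += lo <= 0.32 <= hi
        assert hits >= 30  # ~68% nominal, loose binomial floor


class TestVisibilityCurveGenerator:
    def test_zero_noise_equals_forward_model(self, tocopherol, geometry,
                                             beam180):
        laser = LaserSettings(power_W=1.0)
        powers = np.linspace(1.0, 10.0, 6)
        clean = visibility_vs_power(tocopherol, geometry, laser, beam180,
                                    powers)
        generated = make_visibility_curve(tocopherol, geometry, laser, beam180,
                                          powers, noise_sd=0.0, seed=0)
        assert np.allclose(generated.visibilities, clean.visibilities,
                           atol=1e-12)

    def test_seed_determinism(self, tocopherol, geometry, beam180):
        laser = LaserSettings(power_W=1.0)
        powers = np.linspace(1.0, 10.0, 6)
        a = make_visibility_curve(tocopherol, geometry, laser, beam180, powers,
                                  seed=7)
        b = make_visibility_curve(tocopherol, geometry, laser, beam180, powers,
                                  seed=7)
        assert np.array_equal(a.visibilities, b.visibilities)


class TestDeflectionGenerator:
    def test_zero_noise_exactness(self, tocopherol, beam180):
        from kdtli import ElectrodeModel
        from kdtli.deflectometry import response_curve

        electrode = ElectrodeModel()
        voltages = np.arange(0.0, 6001.0, 500.0)
        series = make_deflection_series(tocopherol, electrode, beam180,
                                        voltages, phase_noise_sd=0.0, seed=0)
        phases, _ = response_curve(tocopherol, electrode, voltages, D, beam180)
        wrapped = np.mod(phases + np.pi, 2 * np.pi) - np.pi
        assert np.allclose(series.phases_rad, wrapped, atol=1e-12)

    def test_noise_scales_interval_width(self, tocopherol, beam180):
        from kdtli import ElectrodeModel, fit_deflection

        electrode = ElectrodeModel()
        voltages = np.arange(0.0, 3001.0, 250.0)
        widths = []
        for noise in (0.02, 0.08):
            fits = []
            for seed in range(5):
                series = make_deflection_series(tocopherol, electrode, beam180,
                                                voltages, phase_noise_sd=noise,
                                                seed=seed)
                fit = fit_deflection(series, electrode, tocopherol.mass_amu,
                                     beam180)
                fits.append(fit.ci68[1] - fit.ci68[0])
            widths.append(np.mean(fits))
        assert widths[1] == pytest.approx(4.0 * widths[0], rel=0.2)


class TestChopperVelocimetry:
    def test_m_sequence_autocorrelation(self):
        seq = m_sequence(7)
        balanced = 2.0 * seq - 1.0
        n = seq.size
        autocorr = np.array([
            balanced @ np.roll(balanced, lag) for lag in range(n)
        ])
        assert autocorr[0] == n
        assert np.all(autocorr[1:] == -1)

    def test_non_m_sequence_rejected(self):
        record = make_tof_record(make_velocity_distribution(200.0, 0.45),
                                 seed=0)
        corrupted = TOFRecord(
            prbs=np.ones_like(record.prbs), bin_s=record.bin_s,
            counts_vs_time=record.counts_vs_time,
            path_length_m=record.path_length_m,
        )
        with pytest.raises(DeconvolutionError):
            reconstruct_velocities(corrupted)

    def test_delta_beam_round_trip(self):
        single = make_velocity_distribution(200.0, 0.0)
        record = make_tof_record(single, seed=1)
        recovered = reconstruct_velocities(record)
        assert recovered.mean_mps == pytest.approx(200.0, rel=0.01)

    def test_noiseless_round_trip_total_variation(self):
        dist = make_velocity_distribution(200.0, 0.45)
        prbs = m_sequence(7)
        q = _tof_density(dist, prbs.size, 50e-6, 0.5)
        conv = np.real(np.fft.ifft(np.fft.fft(prbs) * np.fft.fft(q)))
        record = TOFRecord(prbs=prbs, bin_s=50e-6,
                           counts_vs_time=1e9 * conv / conv.sum(),
                           path_length_m=0.5)
        recovered = reconstruct_velocities(record)
        # map the recovered mass back onto the time bins and compare densities
        t = 0.5 / recovered.velocities_mps
        bins = np.round(t / 50e-6 - 0.5).astype(int)
        q_rec = np.zeros_like(q)
        np.add.at(q_rec, bins, recovered.weights)
        assert 0.5 * np.abs(q_rec - q).sum() < 0.01

    def test_noisy_round_trip_mean_within_one_percent(self):
        dist = make_velocity_distribution(200.0, 0.45)
        means = [
            reconstruct_velocities(make_tof_record(dist, seed=seed)).mean_mps
            for seed in range(10)
        ]
        assert np.mean(means) == pytest.approx(200.0, rel=0.01)

    def test_seed_determinism(self):
        dist = make_velocity_distribution(200.0, 0.45)
        a = make_tof_record(dist, seed=3)
        b = make_tof_record(dist, seed=3)
        assert np.array_equal(a.counts_vs_time, b.counts_vs_time)


class TestPropertySeries:
    def test_zero_targets_give_constant_series(self):
        series = make_property_series((1.8, 54.0, 56.0),
                                      fluctuation_targets=(0.0, 0.0, 0.0),
                                      seed=0)
        assert np.ptp(series.mu_debye_t) == 0.0
        assert np.ptp(series.alpha_stat_A3_t) == 0.0

    def test_seed_determinism_and_nonnegativity(self):
        a = make_property_series((1.8, 54.0, 56.0), seed=5)
        b = make_property_series((1.8, 54.0, 56.0), seed=5)
        assert np.array_equal(a.mu_debye_t, b.mu_debye_t)
        assert np.all(a.mu_debye_t >= 0.0)

    def test_dipole_peak_to_peak_calibration(self):
        """The generator hits the 400% peak-to-peak dipole target on average."""
        values = [
            fluctuation_stats(
                make_property_series((1.8, 54.0, 56.0), seed=seed)
            )["mu_debye"].peak_to_peak_percent
            for seed in range(50)
        ]
        assert np.mean(values) == pytest.approx(400.0, abs=40.0)

    def test_polarizability_stays_constant_within_few_percent(self):
        values = [
            fluctuation_stats(
                make_property_series((1.8, 54.0, 56.0), seed=seed)
            )["alpha_stat_A3"].peak_to_peak_percent
            for seed in range(30)
        ]
        assert np.mean(values) == pytest.approx(3.0, abs=1.0)

    def test_unreachable_target_rejected(self):
        with pytest.raises(ValidationError):
            make_property_series((1.8, 54.0, 56.0),
                                 fluctuation_targets=(5000.0, 3.0, 3.0),
                                 seed=0)
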