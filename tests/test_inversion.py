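"""Parameter extraction: exact recovery on noiseless input, coverage of the
68% intervals, calibrations and the van Vleck dipole inversion."""

import math

import numpy as np
import pytest

from kdtli import (
    DeflectionSeries,
    ElectrodeModel,
    FringeModel,
    FringeScan,
    LaserSettings,
    MoleculeSpec,
    calibrate_K,
    calibrate_intensity,
    extract_dipole_contribution,
    fit_deflection,
    fit_fringe,
    fit_visibility_curve,
    make_deflection_series,
    make_fringe_scan,
    make_velocity_distribution,
    make_visibility_curve,
    van_vleck_chi,
    visibility,
)
from kdtli.conformers import PropertyTimeSeries
from kdtli.errors import (
    FitError,
    IdentifiabilityError,
    UnwrapError,
    ValidationError,
)

D = 266e-9


def noiseless_scan(visibility_value=0.32, offset=1e10, n=24, phase=0.4):
    x = np.linspace(0.0, 2 * D, n, endpoint=False)
    signal = offset * (1 + visibility_value * np.sin(2 * np.pi * x / D + phase))
    return FringeScan(positions_m=x, counts=np.round(signal), dwell_s=1.0,
                      dark_rate_cps=0.0)


class TestFitFringe:
    def test_noiseless_recovery_is_exact(self):
        result = fit_fringe(noiseless_scan(), D)
        assert result.visibility == pytest.approx(0.32, abs=1e-9)
        assert result.phase_rad == pytest.approx(0.4, abs=1e-9)

    def test_agrees_with_dense_reconstruction_visibility(self):
        """Sine-fit visibility equals the (max−min)/(max+min) of the exact
        two-coefficient fringe model."""
        model = FringeModel(coeffs=np.array([100.0, -16.0j]), period_m=D)
        result = fit_fringe(noiseless_scan(0.32, offset=1e10, phase=0.0), D)
        assert result.visibility == pytest.approx(visibility(model), abs=1e-9)

    def test_phase_invariant_under_full_period_shift(self):
        scan = noiseless_scan()
        shifted = FringeScan(positions_m=scan.positions_m + D,
                             counts=scan.counts, dwell_s=1.0, dark_rate_cps=0.0)
        assert fit_fringe(shifted, D).phase_rad == pytest.approx(
            fit_fringe(scan, D).phase_rad, abs=1e-9
        )

    def test_dark_subtraction(self):
        scan = make_fringe_scan(0.32, mean_counts=50000.0, dark_rate_cps=5000.0,
                                seed=11)
        result = fit_fringe(scan, D)
        assert result.visibility == pytest.approx(0.32, abs=0.01)

    def test_rejects_degenerate_scans(self):
        with pytest.raises(FitError):
            fit_fringe(noiseless_scan(n=4), D)
        dark_only = FringeScan(
            positions_m=np.linspace(0, 2 * D, 12, endpoint=False),
            counts=np.full(12, 3.0), dwell_s=1.0, dark_rate_cps=10.0,
        )
        with pytest.raises(FitError):
            fit_fringe(dark_only, D)

    def test_confidence_interval_coverage(self):
        """Nominal 68% intervals cover the truth at the nominal rate
        (binomial band for 200 replicates)."""
        hits = 0
        for seed in range(200):
            scan = make_fringe_scan(0.32, seed=seed)
            lo, hi = fit_fringe(scan, D).ci68["visibility"]
            hits += lo <= 0.32 <= hi
        assert 0.58 <= hits / 200 <= 0.78


class TestFitVisibilityCurve:
    def test_zero_noise_recovery(self, tocopherol, geometry, beam180):
        laser = LaserSettings(power_W=1.0)
        powers = np.linspace(1.0, 10.0, 10)
        curve = make_visibility_curve(tocopherol, geometry, laser, beam180,
                                      powers, noise_sd=0.0, seed=0)
        fit = fit_visibility_curve(curve, tocopherol, geometry, laser, beam180,
                                   compute_ci=False)
        assert fit.alpha_opt_A3 == pytest.approx(58.0, rel=1e-3)

    def test_sign_insensitivity(self, tocopherol, geometry, beam180):
        """A sign flip of α_opt leaves the σ=0 curve, hence the fitted
        magnitude, unchanged."""
        laser = LaserSettings(power_W=1.0)
        powers = np.linspace(1.0, 10.0, 10)
        import dataclasses
        flipped = dataclasses.replace(tocopherol, alpha_opt_A3=-58.0)
        c_pos = make_visibility_curve(tocopherol, geometry, laser, beam180,
                                      powers, noise_sd=0.0, seed=0)
        c_neg = make_visibility_curve(flipped, geometry, laser, beam180,
                                      powers, noise_sd=0.0, seed=0)
        assert np.allclose(c_pos.visibilities, c_neg.visibilities, atol=1e-12)
        fit = fit_visibility_curve(c_neg, tocopherol, geometry, laser, beam180,
                                   compute_ci=False)
        assert fit.alpha_opt_A3 == pytest.approx(58.0, rel=1e-3)

    def test_profile_likelihood_interval_brackets_estimate(
        self, tocopherol, geometry, beam180
    ):
        laser = LaserSettings(power_W=1.0)
        powers = np.linspace(1.0, 10.0, 10)
        curve = make_visibility_curve(tocopherol, geometry, laser, beam180,
                                      powers, noise_sd=0.02, seed=5)
        fit = fit_visibility_curve(curve, tocopherol, geometry, laser, beam180)
        lo, hi = fit.alpha_ci68
        assert lo < fit.alpha_opt_A3 < hi
        assert hi - lo < 10.0  # a few Å³ at this noise level

    def test_flat_curve_not_identifiable(self, tocopherol, geometry, beam180):
        from kdtli.engine import VisibilityCurve

        flat = VisibilityCurve(
            powers_W=np.array([0.0, 1e-9, 2e-9, 3e-9, 4e-9]),
            visibilities=np.zeros(5), sigmas=np.full(5, 0.02),
        )
        with pytest.raises(IdentifiabilityError):
            fit_visibility_curve(flat, tocopherol, geometry,
                                 LaserSettings(power_W=1.0), beam180,
                                 compute_ci=False)


class TestCalibrateIntensity:
    @pytest.mark.parametrize("scale", [1.0, 0.8])
    def test_scale_recovery(self, c60, geometry, beam200, scale):
        template = LaserSettings(power_W=1.0)
        truth = LaserSettings(power_W=1.0, intensity_scale=scale)
        ref = make_visibility_curve(c60, geometry, truth, beam200,
                                    np.linspace(1.0, 10.0, 10),
                                    noise_sd=0.0, seed=0)
        recovered = calibrate_intensity(ref, c60, geometry, template, beam200)
        assert recovered == pytest.approx(scale, abs=0.02)

    def test_scale_degenerate_between_equivalent_references(self, geometry,
                                                            beam200):
        """Two σ=0 species with equal α_opt·P scaling yield the same scale."""
        template = LaserSettings(power_W=1.0)
        truth = LaserSettings(power_W=1.0, intensity_scale=0.9)
        a = MoleculeSpec("a", 720.66, alpha_opt_A3=85.0, sigma_abs_m2=0.0)
        b = MoleculeSpec("b", 720.66, alpha_opt_A3=42.5, sigma_abs_m2=0.0)
        powers_a = np.linspace(1.0, 10.0, 10)
        curve = make_visibility_curve(a, geometry, truth, beam200, powers_a,
                                      noise_sd=0.0, seed=0)
        # species b at doubled powers traverses the identical curve
        curve_b = make_visibility_curve(b, geometry, truth, beam200,
                                        2 * powers_a, noise_sd=0.0, seed=0)
        sa = calibrate_intensity(curve, a, geometry, template, beam200)
        sb = calibrate_intensity(curve_b, b, geometry, template, beam200)
        assert sa == pytest.approx(sb, abs=1e-3)


class TestFitDeflection:
    VOLTAGES = np.arange(0.0, 6001.0, 500.0)

    def test_noiseless_recovery(self, tocopherol, beam180):
        electrode = ElectrodeModel()
        series = make_deflection_series(tocopherol, electrode, beam180,
                                        self.VOLTAGES, phase_noise_sd=0.0,
                                        seed=0)
        fit = fit_deflection(series, electrode, tocopherol.mass_amu, beam180)
        assert fit.chi_A3 == pytest.approx(80.0, rel=1e-6)

    def test_zero_voltage_only_is_not_identifiable(self, tocopherol, beam180):
        series = DeflectionSeries(
            voltages_V=np.zeros(5), phases_rad=np.zeros(5),
            phase_sigmas_rad=np.full(5, 0.05),
        )
        with pytest.raises(IdentifiabilityError):
            fit_deflection(series, ElectrodeModel(), tocopherol.mass_amu,
                           beam180)

    def test_kg_product_degeneracy(self, tocopherol, beam180):
        """Doubling g while halving K leaves the recovered χ unchanged."""
        e1 = ElectrodeModel(geometry_factor_K=2.0e-3, gradient_coeff=4.8e6)
        e2 = ElectrodeModel(geometry_factor_K=1.0e-3, gradient_coeff=9.6e6)
        series = make_deflection_series(tocopherol, e1, beam180, self.VOLTAGES,
                                        phase_noise_sd=0.0, seed=0)
        f1 = fit_deflection(series, e1, tocopherol.mass_amu, beam180)
        f2 = fit_deflection(series, e2, tocopherol.mass_amu, beam180)
        assert f1.chi_A3 == pytest.approx(f2.chi_A3, rel=1e-12)

    def test_sparse_scan_raises_unwrap_error(self, tocopherol, beam180):
        electrode = ElectrodeModel()
        sparse = np.array([0.0, 3000.0, 6000.0, 9000.0])
        series = make_deflection_series(tocopherol, electrode, beam180, sparse,
                                        phase_noise_sd=0.0, seed=0)
        with pytest.raises(UnwrapError):
            fit_deflection(series, electrode, tocopherol.mass_amu, beam180)

    def test_interval_width_shrinks_with_more_voltages(self, tocopherol,
                                                       beam180):
        electrode = ElectrodeModel()
        coarse = np.linspace(0.0, 3000.0, 4)
        fine = np.linspace(0.0, 3000.0, 16)
        widths = []
        for voltages in (coarse, fine):
            series = make_deflection_series(tocopherol, electrode, beam180,
                                            voltages, phase_noise_sd=0.05,
                                            seed=3)
            fit = fit_deflection(series, electrode, tocopherol.mass_amu,
                                 beam180)
            widths.append(fit.ci68[1] - fit.ci68[0])
        assert widths[1] < widths[0]

    def test_coverage_of_68_percent_intervals(self, tocopherol, beam180):
        electrode = ElectrodeModel()
        hits = 0
        for seed in range(200):
            series = make_deflection_series(tocopherol, electrode, beam180,
                                            self.VOLTAGES, seed=seed)
            fit = fit_deflection(series, electrode, tocopherol.mass_amu,
                                 beam180)
            hits += fit.ci68[0] <= 80.0 <= fit.ci68[1]
        assert 0.58 <= hits / 200 <= 0.78


class TestCalibrateK:
    VOLTAGES = np.arange(0.0, 6001.0, 500.0)

    @pytest.mark.parametrize("k_true", [2.0e-3, 1.7e-3])
    def test_k_recovery(self, c60, beam200, k_true):
        truth = ElectrodeModel(geometry_factor_K=k_true)
        template = ElectrodeModel(geometry_factor_K=1.0)  # uncalibrated
        series = make_deflection_series(c60, truth, beam200, self.VOLTAGES,
                                        phase_noise_sd=0.0, seed=0)
        recovered = calibrate_K(series, c60, template, beam200)
        assert recovered == pytest.approx(k_true, rel=1e-6)

    def test_calibration_transfers_to_second_species(self, c60, tocopherol,
                                                     beam200, beam180):
        truth = ElectrodeModel(geometry_factor_K=1.7e-3)
        series_ref = make_deflection_series(c60, truth, beam200, self.VOLTAGES,
                                            phase_noise_sd=0.0, seed=0)
        k_cal = calibrate_K(series_ref, c60, ElectrodeModel(), beam200)
        calibrated = ElectrodeModel(geometry_factor_K=k_cal)
        series = make_deflection_series(tocopherol, truth, beam180,
                                        self.VOLTAGES, phase_noise_sd=0.0,
                                        seed=0)
        fit = fit_deflection(series, calibrated, tocopherol.mass_amu, beam180)
        assert fit.chi_A3 == pytest.approx(80.0, rel=1e-6)


class TestExtractDipole:
    def test_no_dipole_when_chi_equals_static(self):
        assert extract_dipole_contribution(54.0, 54.0, 400.0) == 0.0

    def test_value_from_van_vleck_inversion(self):
        # frozen from the independent hand evaluation of
        # sqrt(3 k_B T (χ−α_stat)_SI)/debye at Δχ = 24 Å³, T = 400 K
        assert extract_dipole_contribution(78.0, 54.0, 400.0) == pytest.approx(
            1.994, abs=0.001
        )

    def test_unphysical_input_rejected(self):
        with pytest.raises(ValidationError):
            extract_dipole_contribution(50.0, 54.0, 400.0)

    def test_round_trip_with_van_vleck_chi(self):
        series = PropertyTimeSeries(
            times_ns=np.arange(5.0), mu_debye_t=np.full(5, 1.8),
            alpha_stat_A3_t=np.full(5, 54.0), alpha_opt_A3_t=np.full(5, 56.0),
            temperature_K=400.0,
        )
        chi = van_vleck_chi(series)
        mu_rms = extract_dipole_contribution(chi, 54.0, 400.0)
        assert mu_rms == pytest.approx(1.8, abs=1e-10)
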