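"""Parameter extraction: fringe sinusoid fits, V(P) inversion to the optical
polarizability (and absorption cross section), deflection-voltage fits to the
electric susceptibility, instrument calibrations, and the van Vleck dipole
inversion.  All uncertainties are 68% confidence intervals.

Fitting conventions
-------------------
* Fringe scans are fit by Poisson-weighted least squares (variance = expected
  counts, iterated), which at the count levels of a typical scan is
  indistinguishable from the full Poisson likelihood.
* The V(P) inversion reports the *magnitude* of α_opt: the interferometer is
  insensitive to its sign (the visibility depends on α_opt only through the
  even kernel coefficients when σ = 0).
* Deflection phases are unwrapped sequentially along the monotone voltage
  grid; an apparent jump larger than π/2 between neighbours is an error, not
  a guess.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq, least_squares

from .deflectometry import DeflectionSeries, ElectrodeModel
from .engine import VisibilityCurve, visibility_vs_power
from .errors import (
    FitError,
    IdentifiabilityError,
    UnwrapError,
    ValidationError,
)
from .gratings import LaserSettings
from .physics import (
    CONSTANTS,
    InterferometerGeometry,
    MoleculeSpec,
    VelocityDistribution,
    polarizability_A3_to_SI,
    polarizability_SI_to_A3,
)

__all__ = [
    "SineFitResult",
    "PolarizabilityFit",
    "SusceptibilityFit",
    "fit_fringe",
    "fit_visibility_curve",
    "calibrate_intensity",
    "fit_deflection",
    "calibrate_K",
    "extract_dipole_contribution",
]


@dataclass
class SineFitResult:
    """Sinusoid fit a + b sin(2πx/d + φ) to a dark-subtracted fringe scan."""

    offset_counts: float
    amplitude_counts: float
    phase_rad: float
    visibility: float
    visibility_sigma: float
    ci68: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        if self.offset_counts <= 0:
            raise FitError("fitted offset must be positive")


def fit_fringe(scan, period_m: float) -> SineFitResult:
    """Poisson-weighted sinusoid fit to a fringe scan.

    The model for the expected counts per point is
    ``dark + a + b sin(2πx/d + φ)`` with the known dark contribution
    ``dark = dark_rate_cps × dwell_s``.  The fit is linear in
    (a, p, q) = (a, b cosφ, b sinφ) and is iterated with weights equal to the
    inverse of the expected counts.  68% intervals come from the parameter
    covariance; the visibility V = b/a and its uncertainty follow by error
    propagation of amplitude and offset.
    """
    x = np.asarray(scan.positions_m, dtype=float)
    counts = np.asarray(scan.counts, dtype=float)
    if x.size < 6:
        raise FitError(f"need at least 6 scan points, got {x.size}")
    if np.ptp(x) < period_m:
        raise FitError("scan must span at least one fringe period")
    dark = scan.dark_rate_cps * scan.dwell_s
    if np.mean(counts) - dark <= 0:
        raise FitError("dark-subtracted mean count rate is not positive")
    theta = 2.0 * math.pi * x / period_m
    design = np.column_stack([np.ones_like(theta), np.sin(theta), np.cos(theta)])
    variance = np.maximum(counts, 1.0)
    params = None
    for _ in range(3):
        w = 1.0 / variance
        xtw = design.T * w
        cov = np.linalg.inv(xtw @ design)
        params = cov @ (xtw @ (counts - dark))
        variance = np.maximum(design @ params + dark, 1e-9)
    a, p, q = params
    if a <= 0:
        raise FitError("fitted signal offset is not positive")
    b = math.hypot(p, q)
    phase = math.atan2(q, p)
    vis = b / a
    # delta method for V = b/a and φ = atan2(q, p)
    if b > 0:
        grad_v = np.array([-b / a**2, p / (b * a), q / (b * a)])
        grad_phi = np.array([0.0, -q / b**2, p / b**2])
    else:
        grad_v = np.array([0.0, 1.0 / a, 1.0 / a])
        grad_phi = np.zeros(3)
    sig_v = float(np.sqrt(grad_v @ cov @ grad_v))
    sig_phi = float(np.sqrt(grad_phi @ cov @ grad_phi))
    sig = np.sqrt(np.diag(cov))
    ci = {
        "offset": (a - sig[0], a + sig[0]),
        "amplitude": (b - math.hypot(sig[1], sig[2]), b + math.hypot(sig[1], sig[2])),
        "phase": (phase - sig_phi, phase + sig_phi),
        "visibility": (vis - sig_v, vis + sig_v),
    }
    return SineFitResult(
        offset_counts=float(a),
        amplitude_counts=float(b),
        phase_rad=float(phase),
        visibility=float(min(vis, 1.0)),
        visibility_sigma=sig_v,
        ci68=ci,
    )


@dataclass
class PolarizabilityFit:
    """Result of the V(P) inversion."""

    alpha_opt_A3: float  # magnitude
    sigma_abs_m2: float
    alpha_ci68: tuple[float, float] | None
    sigma_ci68: tuple[float, float] | None
    goodness: float  # reduced chi-square
    sigma_fixed: bool


def _model_curve(
    alpha_A3: float,
    sigma_m2: float,
    molecule_template: MoleculeSpec,
    geometry: InterferometerGeometry,
    laser_template: LaserSettings,
    distribution: VelocityDistribution,
    powers: np.ndarray,
    max_order: int,
) -> np.ndarray:
    mol = replace(molecule_template, alpha_opt_A3=alpha_A3, sigma_abs_m2=sigma_m2)
    return visibility_vs_power(
        mol, geometry, laser_template, distribution, powers, max_order=max_order
    ).visibilities


def fit_visibility_curve(
    curve: VisibilityCurve,
    molecule_template: MoleculeSpec,
    geometry: InterferometerGeometry,
    laser_template: LaserSettings,
    distribution: VelocityDistribution,
    fit_sigma: bool = False,
    sigma_fixed_m2: float | None = None,
    max_order: int = 10,
    compute_ci: bool = True,
) -> PolarizabilityFit:
    """Invert a visibility-vs-power curve for |α_opt| (and optionally σ).

    Weighted least squares of the forward interferometer model.  When
    ``fit_sigma`` is false, σ is held at ``sigma_fixed_m2`` (default: the
    template's value, or 0).  The 68% interval for |α_opt| is a profile
    likelihood interval at Δχ² = 1.
    """
    if len(curve) < 5:
        raise FitError(f"need at least 5 powers, got {len(curve)}")
    powers = curve.powers_W
    data = curve.visibilities
    sig = curve.sigmas if curve.sigmas is not None else np.ones_like(data)
    if sigma_fixed_m2 is None:
        sigma_fixed_m2 = molecule_template.sigma_abs_m2 or 0.0

    def model(alpha, sigma):
        return _model_curve(alpha, sigma, molecule_template, geometry,
                            laser_template, distribution, powers, max_order)

    # coarse scan for a starting magnitude
    grid = np.array([10.0, 20.0, 40.0, 80.0, 160.0])
    chi2s = []
    for a0 in grid:
        r = (model(a0, sigma_fixed_m2) - data) / sig
        chi2s.append(float(r @ r))
    x0_alpha = grid[int(np.argmin(chi2s))]
    if np.ptp(model(x0_alpha, sigma_fixed_m2)) < 1e-9 and np.ptp(
        model(grid[-1], sigma_fixed_m2)
    ) < 1e-9:
        raise IdentifiabilityError(
            "forward visibility is flat over the power grid; "
            "alpha_opt is not identifiable from this curve"
        )

    if fit_sigma:
        def residuals(x):
            return (model(x[0], x[1]) - data) / sig
        x0 = np.array([x0_alpha, max(sigma_fixed_m2, 1e-22)])
        res = least_squares(residuals, x0, bounds=([0.0, 0.0], [np.inf, np.inf]),
                            xtol=1e-8, ftol=1e-10, diff_step=1e-4)
        alpha_hat, sigma_hat = res.x
    else:
        def residuals(x):
            return (model(x[0], sigma_fixed_m2) - data) / sig
        res = least_squares(residuals, np.array([x0_alpha]),
                            bounds=([0.0], [np.inf]), xtol=1e-8, ftol=1e-10,
                            diff_step=1e-4)
        alpha_hat, sigma_hat = float(res.x[0]), sigma_fixed_m2
    chi2_min = float(res.fun @ res.fun)
    dof = max(len(curve) - res.x.size, 1)

    alpha_ci = None
    if compute_ci:
        def profile_chi2(alpha):
            if fit_sigma:
                r = least_squares(lambda s: (model(alpha, s[0]) - data) / sig,
                                  np.array([max(sigma_hat, 1e-23)]),
                                  bounds=([0.0], [np.inf]))
                return float(r.fun @ r.fun)
            r = (model(alpha, sigma_hat) - data) / sig
            return float(r @ r)

        def excess(alpha):
            return profile_chi2(alpha) - chi2_min - 1.0

        step = max(0.05 * alpha_hat, 0.5)
        hi = alpha_hat + step
        while excess(hi) < 0 and hi < 100 * (alpha_hat + 1):
            hi += step
            step *= 2
        upper = brentq(excess, alpha_hat, hi, xtol=1e-4 * (alpha_hat + 1))
        lo = max(alpha_hat - (upper - alpha_hat) * 4, 0.0)
        if excess(lo) < 0 and lo > 0:
            lo = 0.0
        lower = 0.0 if excess(0.0) < 0 else brentq(
            excess, lo, alpha_hat, xtol=1e-4 * (alpha_hat + 1)
        )
        alpha_ci = (float(lower), float(upper))

    return PolarizabilityFit(
        alpha_opt_A3=float(abs(alpha_hat)),
        sigma_abs_m2=float(sigma_hat),
        alpha_ci68=alpha_ci,
        sigma_ci68=None,
        goodness=chi2_min / dof,
        sigma_fixed=not fit_sigma,
    )


def calibrate_intensity(
    reference_curve: VisibilityCurve,
    reference_molecule: MoleculeSpec,
    geometry: InterferometerGeometry,
    laser_template: LaserSettings,
    distribution: VelocityDistribution,
    max_order: int = 10,
) -> float:
    """In-situ laser-intensity calibration against a reference molecule.

    The reference α_opt (and σ) are known; the returned scale factor
    minimizes the forward-model misfit to the reference V(P) curve and is
    meant to be applied to ``LaserSettings.intensity_scale``.
    """
    if len(reference_curve) < 3:
        raise FitError("reference curve too short for intensity calibration")
    if reference_molecule.alpha_opt_A3 is None:
        raise FitError("reference molecule must have a known alpha_opt_A3")
    data = reference_curve.visibilities
    sig = (reference_curve.sigmas if reference_curve.sigmas is not None
           else np.ones_like(data))
    if np.ptp(data) < 1e-12:
        raise FitError("reference curve carries no visibility modulation")

    def residuals(x):
        laser = LaserSettings(
            power_W=1.0, wavelength_m=laser_template.wavelength_m,
            waist_x_m=laser_template.waist_x_m,
            waist_y_m=laser_template.waist_y_m, intensity_scale=x[0],
        )
        model = visibility_vs_power(
            reference_molecule, geometry, laser, distribution,
            reference_curve.powers_W, max_order=max_order,
        ).visibilities
        return (model - data) / sig

    res = least_squares(residuals, np.array([1.0]), bounds=([1e-6], [1e6]),
                        xtol=1e-12, ftol=1e-12)
    return float(res.x[0])


@dataclass
class SusceptibilityFit:
    """Result of the quadratic deflection-voltage fit."""

    chi_A3: float
    chi_over_mass: float  # SI susceptibility per kg, (C m²/V)/kg
    ci68: tuple[float, float]  # on chi_A3
    quadratic_coefficient: float  # low-voltage slope d(phase)/d(U²), rad/V²
    goodness: float


def _unwrap_sequential(phases: np.ndarray) -> np.ndarray:
    """Sequential unwrap along a monotone voltage grid.

    Each phase is shifted by the multiple of 2π that brings it closest to its
    unwrapped predecessor; a residual jump larger than π/2 raises UnwrapError
    (the scan is too sparse to unwrap unambiguously).
    """
    out = np.array(phases, dtype=float)
    for i in range(1, out.size):
        k = round((out[i - 1] - out[i]) / (2.0 * math.pi))
        out[i] += 2.0 * math.pi * k
        if abs(out[i] - out[i - 1]) > math.pi / 2.0:
            raise UnwrapError(
                f"phase jump of {abs(out[i] - out[i - 1]):.2f} rad between "
                f"neighbouring voltages exceeds π/2; add intermediate voltages"
            )
    return out


def _fit_phase_slope(
    series: DeflectionSeries,
    distribution: VelocityDistribution,
) -> tuple[float, float, float]:
    """Fit κ in phase(U) = arg⟨exp(iκU²/v²)⟩ to an unwrapped series.

    Returns (κ̂, σ_κ, χ²/dof).  κ collects 2πK(χ/m)g/d; callers convert it to
    the physical parameter they calibrate.
    """
    if len(series) < 4:
        raise FitError(f"need at least 4 voltages, got {len(series)}")
    u2 = series.voltages_V**2
    if np.ptp(u2) <= 0:
        raise IdentifiabilityError("deflection series has no voltage variation")
    if series.voltages_V.size > 1 and np.any(np.diff(series.voltages_V) <= 0):
        raise ValidationError("voltages must be strictly increasing")
    phases = _unwrap_sequential(series.phases_rad)
    sig = series.phase_sigmas_rad
    inv_v2 = 1.0 / distribution.velocities_mps**2
    w = distribution.weights

    def model(kappa):
        z = np.exp(1j * kappa * np.outer(u2, inv_v2)) @ w
        return np.unwrap(np.angle(z))

    # linear anchor: weighted slope of phase vs U², mapped through <1/v²>
    wls = 1.0 / sig**2
    slope = float((wls * u2 * phases).sum() / max((wls * u2 * u2).sum(), 1e-300))
    kappa0 = slope / float(w @ inv_v2)

    res = least_squares(lambda x: (model(x[0]) - phases) / sig,
                        np.array([kappa0]), xtol=1e-14, ftol=1e-14)
    kappa = float(res.x[0])
    jac = np.asarray(res.jac)
    jtj = float(np.sum(jac**2))
    if jtj <= 0:
        raise IdentifiabilityError("deflection model is insensitive to chi")
    sigma_kappa = math.sqrt(1.0 / jtj)
    dof = max(len(series) - 1, 1)
    chi2red = float(res.fun @ res.fun) / dof
    return kappa, sigma_kappa, chi2red


def fit_deflection(
    series: DeflectionSeries,
    electrode: ElectrodeModel,
    mass_amu: float,
    distribution: VelocityDistribution,
    period_m: float = 266e-9,
) -> SusceptibilityFit:
    """Extract the electric susceptibility from a deflection-voltage series.

    Weighted fit of the velocity-averaged apparent phase versus U² through
    the full dephasing model; requires a calibrated geometry factor K.
    """
    kappa, sigma_kappa, chi2red = _fit_phase_slope(series, distribution)
    conv = (2.0 * math.pi * electrode.geometry_factor_K
            * electrode.gradient_coeff / (period_m * mass_amu * CONSTANTS.amu_kg))
    chi_si = kappa / conv
    chi_a3 = polarizability_SI_to_A3(chi_si)
    sigma_a3 = polarizability_SI_to_A3(sigma_kappa / conv)
    inv_v2_mean = float(distribution.weights @ (1.0 / distribution.velocities_mps**2))
    return SusceptibilityFit(
        chi_A3=float(chi_a3),
        chi_over_mass=float(chi_si / (mass_amu * CONSTANTS.amu_kg)),
        ci68=(float(chi_a3 - sigma_a3), float(chi_a3 + sigma_a3)),
        quadratic_coefficient=float(kappa * inv_v2_mean),
        goodness=chi2red,
    )


def calibrate_K(
    reference_series: DeflectionSeries,
    reference_molecule: MoleculeSpec,
    electrode_template: ElectrodeModel,
    distribution: VelocityDistribution,
    period_m: float = 266e-9,
) -> float:
    """Calibrate the electrode geometry factor K with a reference molecule of
    known susceptibility (the K·g product is degenerate: only K is fit, g is
    taken from the electrode configuration)."""
    kappa, _, _ = _fit_phase_slope(reference_series, distribution)
    chi_over_m = reference_molecule.chi_SI / reference_molecule.mass_kg
    k_factor = kappa * period_m / (
        2.0 * math.pi * chi_over_m * electrode_template.gradient_coeff
    )
    if k_factor <= 0:
        raise FitError("calibration produced a non-positive geometry factor")
    return float(k_factor)


def extract_dipole_contribution(
    chi_A3: float, alpha_stat_A3: float, temperature_K: float
) -> float:
    """Root-mean-square dynamic dipole moment ⟨µ²⟩^(1/2), in debye, implied by
    the van Vleck relation χ = α_stat + ⟨µ²⟩/3k_BT.

    Raises a domain error when χ < α_stat (unphysical input).
    """
    if temperature_K <= 0:
        raise ValidationError("temperature must be > 0")
    if chi_A3 < alpha_stat_A3:
        raise ValidationError(
            f"chi ({chi_A3} Å³) < alpha_stat ({alpha_stat_A3} Å³): "
            "no real dipole contribution exists"
        )
    mu2_si = 3.0 * CONSTANTS.k_B * temperature_K * polarizability_A3_to_SI(
        chi_A3 - alpha_stat_A3
    )
    return math.sqrt(mu2_si) / CONSTANTS.debye_SI
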