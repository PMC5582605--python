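"""Transmission models of the three gratings.

G1 and G3 are binary nanomechanical masks; their periodic transmission enters
the interference calculation through Fourier coefficients of the sinc type.

G2 is an optical standing wave (period λ_L/2).  A molecule of optical
polarizability α_opt crossing the Gaussian laser profile accumulates the
eikonal phase

    φ(x) = φ₀ cos²(πx/d),     φ₀ = (1/ħ) ∫ α_opt E²(x₀, t)/4 dt,

where the time integral runs along the straight trajectory through the beam
and x₀ is an antinode.  A molecule may also absorb photons in transit; the
expected number at an antinode is n₀ = σ(ω) × fluence / (hc/λ_L).  Absorption
does not remove molecules from the beam (absorbers are still detected): it is
modeled as a position-correlated Poisson process whose jump amplitude is the
local standing-wave field cos(πx/d), so the two-point density transform of G2
is

    K(x, x') = exp[iφ(x) − iφ(x')]
               × exp[ n₀ ( c(x)c(x') − (c(x)² + c(x')²)/2 ) ],

with c(x) = cos(πx/d).  K(x, x) = 1 for every laser power: the grating
conserves molecule number.  Fringe coefficients are numerical Fourier
transforms of this kernel evaluated at the order-dependent two-point
separation set by the Talbot argument L/L_T (see :mod:`kdtli.engine`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .errors import ConfigurationError, ConvergenceError, ValidationError
from .physics import CONSTANTS, InterferometerGeometry, MoleculeSpec

__all__ = [
    "LaserSettings",
    "MaterialGratingModel",
    "OpticalGratingModel",
    "peak_intensity",
    "eikonal_phase",
    "mean_absorbed_photons",
    "material_coeffs",
    "g2_kernel_coeffs",
]


@dataclass
class LaserSettings:
    """Grating-laser parameters.

    ``intensity_scale`` is the dimensionless in-situ calibration factor that
    multiplies the nominal peak intensity (determined with a reference
    molecule, see :func:`kdtli.inversion.calibrate_intensity`).
    """

    power_W: float
    wavelength_m: float = 532e-9
    waist_x_m: float = 20e-6
    waist_y_m: float = 920e-6
    intensity_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.power_W < 0:
            raise ValidationError("laser power must be >= 0")
        if self.waist_x_m <= 0 or self.waist_y_m <= 0:
            raise ValidationError("laser waists must be > 0")
        if self.wavelength_m <= 0:
            raise ValidationError("laser wavelength must be > 0")
        if self.intensity_scale <= 0:
            raise ValidationError("intensity_scale must be > 0")

    @classmethod
    def from_geometry(
        cls, geometry: InterferometerGeometry, power_W: float,
        intensity_scale: float = 1.0,
    ) -> "LaserSettings":
        return cls(
            power_W=power_W,
            wavelength_m=geometry.laser_wavelength_m,
            waist_x_m=geometry.waist_x_m,
            waist_y_m=geometry.waist_y_m,
            intensity_scale=intensity_scale,
        )

    def with_power(self, power_W: float) -> "LaserSettings":
        return LaserSettings(power_W, self.wavelength_m, self.waist_x_m,
                             self.waist_y_m, self.intensity_scale)


def peak_intensity(laser: LaserSettings) -> float:
    """Center intensity I = 2P/(π w_x w_y) of the Gaussian beam, in W/m²,
    multiplied by the in-situ calibration factor."""
    return laser.intensity_scale * 2.0 * laser.power_W / (
        math.pi * laser.waist_x_m * laser.waist_y_m
    )


def _transit_time_integral(laser: LaserSettings, velocity_mps: float) -> float:
    """∫ exp(−2 (vt)²/w_x²) dt by adaptive quadrature (= √(π/2)·w_x/v)."""
    tau = laser.waist_x_m / velocity_mps  # transit time scale
    value, _ = quad(lambda t: math.exp(-2.0 * (velocity_mps * t / laser.waist_x_m) ** 2),
                    -8.0 * tau, 8.0 * tau, epsabs=0.0, epsrel=1e-11)
    return value


def eikonal_phase(
    molecule: MoleculeSpec, laser: LaserSettings, velocity_mps: float
) -> float:
    """Peak eikonal phase φ₀ (radians, signed) at a standing-wave antinode.

    The dipole potential is W = −α_opt E²(x)/4; at an antinode the squared
    field amplitude is 8 I(z)/(c ε₀) (four times the running-wave intensity),
    so φ₀ = (2 α_opt I₀ / ħ c ε₀) ∫ exp(−2(vt/w_x)²) dt.  Linear in α_opt and
    P, proportional to 1/v; the sign follows α_opt.
    """
    if velocity_mps <= 0:
        raise ValidationError("velocity must be > 0")
    alpha_SI = molecule.alpha_opt_SI  # raises ConfigurationError when unset
    if laser.power_W == 0.0 or alpha_SI == 0.0:
        return 0.0
    i_peak = peak_intensity(laser)
    w_peak = 2.0 * alpha_SI * i_peak / (CONSTANTS.c * CONSTANTS.eps0)
    return w_peak * _transit_time_integral(laser, velocity_mps) / CONSTANTS.hbar


def mean_absorbed_photons(
    molecule: MoleculeSpec, laser: LaserSettings, velocity_mps: float
) -> float:
    """Mean number of photons n₀ absorbed at an antinode during transit.

    n₀ = σ × (peak standing-wave fluence) / (photon energy hc/λ_L); the
    antinode intensity is four times the running-wave center intensity.
    Linear in P and σ, proportional to 1/v.
    """
    if velocity_mps <= 0:
        raise ValidationError("velocity must be > 0")
    if molecule.sigma_abs_m2 is None:
        raise ConfigurationError(
            f"molecule {molecule.name!r}: sigma_abs_m2 is required but not set"
        )
    if laser.power_W == 0.0 or molecule.sigma_abs_m2 == 0.0:
        return 0.0
    fluence = 4.0 * peak_intensity(laser) * _transit_time_integral(laser, velocity_mps)
    photon_energy = CONSTANTS.h * CONSTANTS.c / laser.wavelength_m
    return molecule.sigma_abs_m2 * fluence / photon_energy


@dataclass
class MaterialGratingModel:
    """Ideal binary mask: period, open fraction and transmission coefficients."""

    period_m: float
    open_fraction: float
    fourier_coeffs: dict[int, complex]

    def coeff(self, order: int) -> complex:
        return self.fourier_coeffs.get(order, 0.0 + 0.0j)


def material_coeffs(open_fraction: float, max_order: int) -> dict[int, complex]:
    """Fourier coefficients of an ideal binary mask of open fraction f.

    With the phase origin at a slit center, b_n = f sinc(n f) (real,
    Hermitian-symmetric); b_0 = f.
    """
    if not (0.0 < open_fraction < 1.0):
        raise ValidationError("open_fraction must be in (0, 1)")
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    coeffs: dict[int, complex] = {}
    for n in range(-max_order, max_order + 1):
        coeffs[n] = complex(open_fraction * np.sinc(n * open_fraction))
    return coeffs


def material_grating(
    period_m: float, open_fraction: float, max_order: int
) -> MaterialGratingModel:
    return MaterialGratingModel(
        period_m=period_m,
        open_fraction=open_fraction,
        fourier_coeffs=material_coeffs(open_fraction, max_order),
    )


@dataclass
class OpticalGratingModel:
    """Optical grating strength for one molecule, laser setting and speed.

    ``phase_amplitude`` (φ₀) and ``mean_photons`` (n₀) both scale linearly
    with laser power; φ₀ carries the sign of α_opt, n₀ ≥ 0.
    """

    phase_amplitude: float
    mean_photons: float
    period_m: float

    def __post_init__(self) -> None:
        if self.mean_photons < 0:
            raise ValidationError("mean_photons must be >= 0")
        if self.period_m <= 0:
            raise ValidationError("period must be > 0")

    @classmethod
    def from_physical(
        cls,
        molecule: MoleculeSpec,
        laser: LaserSettings,
        velocity_mps: float,
        include_absorption: bool = True,
    ) -> "OpticalGratingModel":
        phi0 = eikonal_phase(molecule, laser, velocity_mps)
        n0 = 0.0
        if include_absorption and molecule.sigma_abs_m2 is not None:
            n0 = mean_absorbed_photons(molecule, laser, velocity_mps)
        return cls(phase_amplitude=phi0, mean_photons=n0,
                   period_m=laser.wavelength_m / 2.0)


def _kernel_coeff_array(
    phi0: np.ndarray,
    n0: np.ndarray,
    xi: np.ndarray,
    max_order: int,
    n_samples: int = 128,
) -> np.ndarray:
    """Order-indexed G2 kernel coefficients B_m, m = 0..max_order, broadcast
    over the leading shape of (phi0, n0, xi).

    For each order m the two-point kernel K(x+Δ/2, x−Δ/2) with separation
    Δ = m·ξ·d is sampled over one period and projected on exp(4πi m x/d).
    Negative orders follow by Hermitian symmetry, B_{−m} = conj(B_m).
    """
    phi0, n0, xi = np.broadcast_arrays(
        np.asarray(phi0, float), np.asarray(n0, float), np.asarray(xi, float)
    )
    lead = phi0.shape
    m = np.arange(max_order + 1).reshape((1,) * len(lead) + (-1, 1))
    theta = (np.arange(n_samples) + 0.5) / n_samples * np.pi  # = πx/d over one period
    theta = theta.reshape((1,) * len(lead) + (1, -1))
    half_sep = 0.5 * np.pi * m * xi[..., None, None]  # πΔ/(2d)·... = π m ξ / 2
    cp = np.cos(theta + half_sep)  # c(x + Δ/2)
    cm = np.cos(theta - half_sep)  # c(x − Δ/2)
    log_kernel = (
        1j * phi0[..., None, None] * (cp**2 - cm**2)
        + n0[..., None, None] * (cp * cm - 0.5 * (cp**2 + cm**2))
    )
    projector = np.exp(4j * m * theta)
    return np.mean(np.exp(log_kernel) * projector, axis=-1)


def g2_kernel_coeffs(
    grating: OpticalGratingModel,
    talbot_argument: float,
    max_order: int,
    n_samples: int = 256,
    convergence_tol: float = 1e-6,
) -> dict[int, complex]:
    """Generalized Fourier coefficients of the G2 density-transform kernel.

    Parameters
    ----------
    grating
        Phase amplitude φ₀ and mean absorbed photon number n₀.
    talbot_argument
        ξ = L/L_T; order m is evaluated at two-point separation m·ξ·d.
    max_order
        Highest coefficient order returned.  If the coefficient at the cutoff
        has not decayed below ``convergence_tol`` a ConvergenceError is
        raised: the expansion would be truncated too early.

    Reduces exactly to the pure-phase result when n₀ = 0, and to the identity
    kernel (B_0 = 1, all else 0) when φ₀ = n₀ = 0.  B_0 = 1 always: the
    optical grating neither blocks nor removes molecules.
    """
    if not np.isfinite(talbot_argument):
        raise ValidationError("talbot_argument must be finite")
    if max_order < 1:
        raise ValidationError("max_order must be >= 1")
    b = _kernel_coeff_array(
        grating.phase_amplitude, grating.mean_photons,
        talbot_argument, max_order, n_samples=n_samples,
    )
    if abs(b[-1]) > convergence_tol:
        raise ConvergenceError(
            f"G2 kernel coefficient at cutoff order {max_order} is "
            f"{abs(b[-1]):.2e} > {convergence_tol:.0e}; increase max_order"
        )
    out: dict[int, complex] = {0: complex(b[0])}
    for order in range(1, max_order + 1):
        out[order] = complex(b[order])
        out[-order] = complex(np.conj(b[order]))
    return out
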