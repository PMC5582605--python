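"""Electrostatic deflectometry of the molecular fringe pattern.

A pair of electrodes close to the second grating exerts a homogeneous force
(χ/2)∂ₓE² on a molecule of electric susceptibility χ, displacing the fringes
by

    Δx = K · (χ/m) · ∂ₓ(E_d²) · 1/v² ,       ∂ₓ(E_d²) = g · U² ,

quadratic in the applied voltage U and ∝ 1/v².  The geometry factor K
absorbs the electrode geometry/position (including the effective
interaction-and-drift length factors of the SI bookkeeping) and is calibrated
against a reference molecule of known susceptibility; the gradient constant
g is a configuration value.  Neither is separable from a single species'
data — only the product K·g enters the phase law.

Because the shift is velocity dependent, a beam with finite velocity spread
dephases: the apparent (velocity-averaged) fringe phase is the argument of
⟨exp(2πiΔx(v)/d)⟩ and the fringe contrast is reduced by its modulus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import FringeModel
from .errors import ValidationError
from .physics import MoleculeSpec, VelocityDistribution

__all__ = [
    "ElectrodeModel",
    "DeflectionSeries",
    "fringe_shift",
    "phase_from_shift",
    "velocity_averaged_response",
]


@dataclass
class ElectrodeModel:
    """Deflection electrode calibration constants.

    ``gradient_coeff`` g maps U² to the field-gradient observable,
    ∂ₓ(E_d²) = g U²; ``geometry_factor_K`` is the calibrated geometry factor.
    Defaults place the 6 kV fringe shift of a χ ≈ 80 Å³, 430 amu molecule at
    180 m/s near half a grating period.
    """

    geometry_factor_K: float = 2.0e-3
    gradient_coeff: float = 4.8e6
    max_voltage_V: float = 10000.0

    def __post_init__(self) -> None:
        if self.geometry_factor_K <= 0:
            raise ValidationError("geometry_factor_K must be > 0")
        if self.gradient_coeff <= 0:
            raise ValidationError("gradient_coeff must be > 0")

    def to_dict(self) -> dict:
        return {
            "geometry_factor_K": self.geometry_factor_K,
            "gradient_coeff": self.gradient_coeff,
            "max_voltage_V": self.max_voltage_V,
        }

    @classmethod
    def from_dict(cls, data) -> "ElectrodeModel":
        return cls(**dict(data))


@dataclass
class DeflectionSeries:
    """Measured fringe phase vs deflection voltage with 68% uncertainties."""

    voltages_V: np.ndarray
    phases_rad: np.ndarray
    phase_sigmas_rad: np.ndarray

    def __post_init__(self) -> None:
        self.voltages_V = np.asarray(self.voltages_V, dtype=float)
        self.phases_rad = np.asarray(self.phases_rad, dtype=float)
        self.phase_sigmas_rad = np.asarray(self.phase_sigmas_rad, dtype=float)
        if not (self.voltages_V.shape == self.phases_rad.shape
                == self.phase_sigmas_rad.shape):
            raise ValidationError("voltage/phase/sigma columns must match in length")
        if np.any(self.voltages_V < 0):
            raise ValidationError("voltages must be >= 0")
        if np.any(self.phase_sigmas_rad <= 0):
            raise ValidationError("phase sigmas must be > 0")

    def __len__(self) -> int:
        return self.voltages_V.size


def fringe_shift(
    molecule: MoleculeSpec,
    electrode: ElectrodeModel,
    voltage_V: float,
    velocity_mps: float,
) -> float:
    """Fringe displacement Δx = K (χ/m) g U² / v² in metres."""
    if velocity_mps <= 0:
        raise ValidationError("velocity must be > 0")
    chi = molecule.chi_SI  # raises ConfigurationError when unset
    return (
        electrode.geometry_factor_K
        * chi
        / molecule.mass_kg
        * electrode.gradient_coeff
        * voltage_V**2
        / velocity_mps**2
    )


def phase_from_shift(displacement_m: float, period_m: float) -> float:
    """Fringe phase 2πΔx/d; a shift of half a period corresponds to π."""
    if period_m <= 0:
        raise ValidationError("period must be > 0")
    return 2.0 * math.pi * displacement_m / period_m


def velocity_averaged_response(
    molecule: MoleculeSpec,
    electrode: ElectrodeModel,
    voltage_V: float,
    fringe: FringeModel,
    distribution: VelocityDistribution,
) -> tuple[float, float]:
    """Apparent fringe phase and contrast factor of the deflected pattern.

    The first-harmonic coefficient of the formed fringe is multiplied by
    exp(iφ(v)) per velocity class, φ(v) = 2πΔx(v)/d, and averaged over the
    beam.  Returns ``(apparent_phase_rad, visibility_factor)`` where the
    factor is the modulus ratio |⟨e^{iφ}⟩| ≤ 1, with equality iff the spread
    vanishes or U = 0.
    """
    phases = np.array([
        phase_from_shift(
            fringe_shift(molecule, electrode, voltage_V, v), fringe.period_m
        )
        for v in distribution.velocities_mps
    ])
    z = np.dot(distribution.weights, np.exp(1j * phases))
    return float(np.angle(z)), float(np.abs(z))


def response_curve(
    molecule: MoleculeSpec,
    electrode: ElectrodeModel,
    voltages_V: np.ndarray,
    period_m: float,
    distribution: VelocityDistribution,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (apparent phase, contrast factor) over a voltage grid.

    Phases are returned unwrapped (continuous in U), anchored at phase 0 for
    U = 0, which is the natural output of a fit to a monotone voltage scan.
    """
    voltages_V = np.asarray(voltages_V, dtype=float)
    chi_over_m = molecule.chi_SI / molecule.mass_kg
    coeff = (
        electrode.geometry_factor_K * chi_over_m * electrode.gradient_coeff
        * 2.0 * math.pi / period_m
    )
    phases = coeff * np.outer(voltages_V**2, 1.0 / distribution.velocities_mps**2)
    z = np.exp(1j * phases) @ distribution.weights
    apparent = np.unwrap(np.angle(z))
    return apparent, np.abs(z)
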