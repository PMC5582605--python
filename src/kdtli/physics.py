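"""Physical constants, unit conversions, molecule/beam/geometry types and the
kinematic relations of near-field matter-wave interferometry.

All internal computation is in SI units.  Å³ (polarizability volumes), debye,
amu and picometres appear only at the I/O boundary, converted through the
helpers in this module, so that there is exactly one conversion site.

The central kinematic quantities for a Talbot-Lau interferometer with
grating period ``d`` and a molecule of de Broglie wavelength ``λ_dB = h/mv``:

* Talbot length ``L_T = d²/λ_dB`` — the near-field self-imaging distance.
* Transverse coherence at distance ``L`` behind a slit of width ``s``:
  ``2 λ_dB L / s``.
* Momentum uncertainty acquired at a slit: ``Δp ≥ h/s``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ConfigurationError, FormulaError, ValidationError

__all__ = [
    "PhysicalConstants",
    "CONSTANTS",
    "ATOMIC_WEIGHTS",
    "MoleculeSpec",
    "InterferometerGeometry",
    "VelocityDistribution",
    "mass_from_formula",
    "de_broglie_wavelength",
    "talbot_length",
    "transverse_coherence",
    "momentum_uncertainty",
    "polarizability_A3_to_SI",
    "polarizability_SI_to_A3",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA-2018 constants, immutable by construction."""

    h: float = 6.62607015e-34  # Planck constant [J s] (exact)
    k_B: float = 1.380649e-23  # Boltzmann constant [J/K] (exact)
    c: float = 299792458.0  # speed of light [m/s] (exact)
    eps0: float = 8.8541878128e-12  # vacuum permittivity [F/m]
    amu_kg: float = 1.66053906660e-27  # unified atomic mass unit [kg]
    debye_SI: float = 3.33564095198e-30  # 1 debye [C m]

    @property
    def hbar(self) -> float:
        return self.h / (2.0 * math.pi)


CONSTANTS = PhysicalConstants()

# IUPAC 2021 abridged standard atomic weights; extend as needed.
ATOMIC_WEIGHTS: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def mass_from_formula(sum_formula: str) -> float:
    """Molecular mass in amu from a Hill-order sum formula like ``C40H56``.

    Raises
    ------
    FormulaError
        If the string contains a token that is not a known element symbol
        followed by an optional positive count.
    """
    if not sum_formula or not isinstance(sum_formula, str):
        raise FormulaError(f"empty or non-string sum formula: {sum_formula!r}")
    pos = 0
    total = 0.0
    while pos < len(sum_formula):
        m = _FORMULA_TOKEN.match(sum_formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise FormulaError(
                f"cannot parse sum formula {sum_formula!r} at {sum_formula[pos:]!r}"
            )
        symbol, count_str = m.group(1), m.group(2)
        if symbol not in ATOMIC_WEIGHTS:
            raise FormulaError(
                f"unknown element symbol {symbol!r} in formula {sum_formula!r}"
            )
        count = int(count_str) if count_str else 1
        if count <= 0:
            raise FormulaError(
                f"non-positive count for {symbol!r} in formula {sum_formula!r}"
            )
        total += ATOMIC_WEIGHTS[symbol] * count
        pos = m.end()
    return total


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not (value > 0.0) or not math.isfinite(value):
            raise ValidationError(f"{name} must be positive and finite, got {value}")


def de_broglie_wavelength(mass_amu: float, velocity_mps: float) -> float:
    """de Broglie wavelength λ = h/(m v) in metres."""
    _require_positive(mass_amu=mass_amu, velocity_mps=velocity_mps)
    return CONSTANTS.h / (mass_amu * CONSTANTS.amu_kg * velocity_mps)


def talbot_length(period_m: float, wavelength_m: float) -> float:
    """Talbot self-imaging length L_T = d²/λ in metres."""
    _require_positive(period_m=period_m, wavelength_m=wavelength_m)
    return period_m**2 / wavelength_m


def transverse_coherence(
    wavelength_m: float, distance_m: float, slit_width_m: float
) -> float:
    """Transverse coherence width 2 λ L / s grown from a slit of width s."""
    _require_positive(
        wavelength_m=wavelength_m, distance_m=distance_m, slit_width_m=slit_width_m
    )
    return 2.0 * wavelength_m * distance_m / slit_width_m


def momentum_uncertainty(slit_width_m: float) -> float:
    """Heisenberg lower bound Δp = h/s for a slit of width s, in kg m/s."""
    _require_positive(slit_width_m=slit_width_m)
    return CONSTANTS.h / slit_width_m


_A3_TO_SI = 4.0 * math.pi * CONSTANTS.eps0 * 1e-30


def polarizability_A3_to_SI(value_A3: float) -> float:
    """Polarizability volume in Å³ → SI polarizability in C m²/V (× 4πε₀ 10⁻³⁰)."""
    if not math.isfinite(value_A3):
        raise ValidationError(f"non-finite polarizability: {value_A3}")
    return value_A3 * _A3_TO_SI


def polarizability_SI_to_A3(value_SI: float) -> float:
    """Inverse of :func:`polarizability_A3_to_SI`."""
    if not math.isfinite(value_SI):
        raise ValidationError(f"non-finite polarizability: {value_SI}")
    return value_SI / _A3_TO_SI


@dataclass
class MoleculeSpec:
    """One molecule's identity and electronic/thermal parameters.

    Polarizabilities are polarizability volumes in Å³ (the tables' unit);
    ``alpha_opt_A3`` is signed (it can be negative when the grating laser is
    blue-detuned to a strong transition), the deflectometry observable is the
    electric susceptibility ``chi_A3 = α_stat + ⟨µ²⟩/3k_BT`` in the same unit.
    """

    name: str
    mass_amu: float
    sum_formula: str | None = None
    alpha_opt_A3: float | None = None
    sigma_abs_m2: float | None = None
    alpha_stat_A3: float | None = None
    mu_debye: float | None = None
    chi_A3: float | None = None
    temperature_K: float | None = None

    def __post_init__(self) -> None:
        _require_positive(mass_amu=self.mass_amu)
        if self.sum_formula is not None:
            formula_mass = mass_from_formula(self.sum_formula)
            if abs(formula_mass - self.mass_amu) > 0.1:
                raise ValidationError(
                    f"mass_amu={self.mass_amu} inconsistent with formula "
                    f"{self.sum_formula} ({formula_mass:.2f} amu)"
                )
        if self.sigma_abs_m2 is not None and self.sigma_abs_m2 < 0:
            raise ValidationError("sigma_abs_m2 must be >= 0")
        if self.mu_debye is not None and self.mu_debye < 0:
            raise ValidationError("mu_debye must be >= 0")
        if self.temperature_K is not None:
            _require_positive(temperature_K=self.temperature_K)

    @classmethod
    def from_formula(cls, name: str, sum_formula: str, **kwargs) -> "MoleculeSpec":
        return cls(name=name, mass_amu=mass_from_formula(sum_formula),
                   sum_formula=sum_formula, **kwargs)

    @property
    def mass_kg(self) -> float:
        return self.mass_amu * CONSTANTS.amu_kg

    @property
    def alpha_opt_SI(self) -> float:
        if self.alpha_opt_A3 is None:
            raise ConfigurationError(
                f"molecule {self.name!r}: alpha_opt_A3 is required but not set"
            )
        return polarizability_A3_to_SI(self.alpha_opt_A3)

    @property
    def chi_SI(self) -> float:
        if self.chi_A3 is None:
            raise ConfigurationError(
                f"molecule {self.name!r}: chi_A3 is required but not set"
            )
        return polarizability_A3_to_SI(self.chi_A3)

    def implied_chi_A3(self) -> float | None:
        """Van Vleck susceptibility from α_stat, µ and T when all are set."""
        if None in (self.alpha_stat_A3, self.mu_debye, self.temperature_K):
            return None
        mu2 = (self.mu_debye * CONSTANTS.debye_SI) ** 2
        return self.alpha_stat_A3 + polarizability_SI_to_A3(
            mu2 / (3.0 * CONSTANTS.k_B * self.temperature_K)
        )

    def to_dict(self) -> dict:
        out = {"name": self.name, "mass_amu": self.mass_amu}
        for key in ("sum_formula", "alpha_opt_A3", "sigma_abs_m2", "alpha_stat_A3",
                    "mu_debye", "chi_A3", "temperature_K"):
            value = getattr(self, key)
            if value is not None:
                out[key] = value
        return out

    @classmethod
    def from_dict(cls, data: Mapping) -> "MoleculeSpec":
        data = dict(data)
        if "mass_amu" not in data and "sum_formula" in data:
            data["mass_amu"] = mass_from_formula(data["sum_formula"])
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigurationError(f"bad [molecule] section: {exc}") from exc


@dataclass
class InterferometerGeometry:
    """Grating periods, separations and laser waists of the interferometer.

    Defaults are the instrument scale used throughout: three gratings of
    period 266 nm separated by 10.5 cm, G1 slit width 110 nm, an optical
    grating made by retro-reflecting a 532 nm laser (standing-wave period
    λ_L/2 = 266 nm) with 20 µm × 920 µm waists.
    """

    grating_period_m: float = 266e-9
    grating_separation_m: float = 0.105
    slit_width_m: float = 110e-9
    open_fraction_g3: float = 110.0 / 266.0
    laser_wavelength_m: float = 532e-9
    waist_x_m: float = 20e-6
    waist_y_m: float = 920e-6

    def __post_init__(self) -> None:
        _require_positive(
            grating_period_m=self.grating_period_m,
            grating_separation_m=self.grating_separation_m,
            slit_width_m=self.slit_width_m,
            laser_wavelength_m=self.laser_wavelength_m,
            waist_x_m=self.waist_x_m,
            waist_y_m=self.waist_y_m,
        )
        if not (0.0 < self.open_fraction_g3 < 1.0):
            raise ValidationError("open_fraction_g3 must be in (0, 1)")
        if abs(self.grating_period_m - self.laser_wavelength_m / 2.0) > 1e-12:
            raise ValidationError(
                "grating period must equal half the laser wavelength "
                f"(got d={self.grating_period_m}, λ_L/2={self.laser_wavelength_m / 2})"
            )
        if self.slit_width_m >= self.grating_period_m:
            raise ValidationError("slit width must be smaller than the period")

    @property
    def open_fraction_g1(self) -> float:
        return self.slit_width_m / self.grating_period_m

    def talbot_argument(self, wavelength_m: float) -> float:
        """L/L_T for a given de Broglie wavelength."""
        return self.grating_separation_m / talbot_length(
            self.grating_period_m, wavelength_m
        )

    def to_dict(self) -> dict:
        return {
            "grating_period_m": self.grating_period_m,
            "grating_separation_m": self.grating_separation_m,
            "slit_width_m": self.slit_width_m,
            "open_fraction_g3": self.open_fraction_g3,
            "laser_wavelength_m": self.laser_wavelength_m,
            "waist_x_m": self.waist_x_m,
            "waist_y_m": self.waist_y_m,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "InterferometerGeometry":
        try:
            return cls(**dict(data))
        except TypeError as exc:
            raise ConfigurationError(f"bad [geometry] section: {exc}") from exc


@dataclass
class VelocityDistribution:
    """Discretized distribution of beam speeds: nodes, probability masses and
    (optionally) the quadrature cell widths used to recover a density.

    ``weights[i]`` is the probability mass carried by node ``velocities[i]``.
    The density needed for FWHM estimation is ``weights/cell_widths``; when no
    cell widths are supplied the local node spacing is used.
    """

    velocities_mps: np.ndarray
    weights: np.ndarray
    cell_widths: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.velocities_mps = np.asarray(self.velocities_mps, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.velocities_mps.ndim != 1 or self.velocities_mps.size == 0:
            raise ValidationError("velocities must be a non-empty 1-d array")
        if self.velocities_mps.shape != self.weights.shape:
            raise ValidationError("velocities and weights must have equal length")
        if np.any(self.velocities_mps <= 0):
            raise ValidationError("all velocities must be positive")
        if self.velocities_mps.size > 1 and np.any(np.diff(self.velocities_mps) <= 0):
            raise ValidationError("velocities must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValidationError("weights must be nonnegative")
        total = self.weights.sum()
        if not total > 0:
            raise ValidationError("weights must not all vanish")
        self.weights = self.weights / total
        if self.cell_widths is not None:
            self.cell_widths = np.asarray(self.cell_widths, dtype=float)
            if self.cell_widths.shape != self.velocities_mps.shape:
                raise ValidationError("cell_widths must match velocities")

    def __len__(self) -> int:
        return self.velocities_mps.size

    @property
    def mean_mps(self) -> float:
        return float(np.dot(self.weights, self.velocities_mps))

    def density(self) -> np.ndarray:
        """Probability density (per m/s) at the velocity nodes."""
        return self._density()

    def _density(self) -> np.ndarray:
        if self.cell_widths is not None:
            widths = self.cell_widths
        else:
            v = self.velocities_mps
            if v.size == 1:
                return np.array([np.inf])
            widths = np.gradient(v)
        return self.weights / widths

    @property
    def fwhm_mps(self) -> float:
        """Full width at half maximum of the (interpolated) speed density."""
        if len(self) == 1:
            return 0.0
        v = self.velocities_mps
        dens = self._density()
        ipk = int(np.argmax(dens))
        half = dens[ipk] / 2.0
        # walk outward from the peak to the half-maximum crossings
        left = v[0]
        for i in range(ipk, 0, -1):
            if dens[i - 1] < half <= dens[i]:
                frac = (half - dens[i - 1]) / (dens[i] - dens[i - 1])
                left = v[i - 1] + frac * (v[i] - v[i - 1])
                break
        right = v[-1]
        for i in range(ipk, len(v) - 1):
            if dens[i + 1] < half <= dens[i]:
                frac = (dens[i] - half) / (dens[i] - dens[i + 1])
                right = v[i] + frac * (v[i + 1] - v[i])
                break
        return float(right - left)

    @property
    def fwhm_fraction(self) -> float:
        return self.fwhm_mps / self.mean_mps

    def singleton(self) -> bool:
        return len(self) == 1

    @classmethod
    def single(cls, velocity_mps: float) -> "VelocityDistribution":
        return cls(np.array([velocity_mps]), np.array([1.0]))


def molecule_copy(molecule: MoleculeSpec, **updates) -> MoleculeSpec:
    """Convenience: a copy of ``molecule`` with selected fields replaced."""
    return replace(molecule, **updates)
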