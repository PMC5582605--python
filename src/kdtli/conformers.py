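"""Conformational averaging of molecular property time series.

Flexible molecules in a hot beam explore many conformations; their static
polarizability is nearly conformation independent while the electric dipole
moment fluctuates strongly.  The thermally averaged response measured by
static-field deflectometry is the van Vleck susceptibility

    χ = ⟨α_stat⟩ + ⟨µ²⟩ / 3 k_B T ,

where ⟨µ²⟩ is the mean of the *squared* dipole magnitude over the sampled
conformations (a moment, not a path property: the result is invariant under
reordering of the snapshots).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .physics import CONSTANTS, polarizability_SI_to_A3

__all__ = [
    "PropertyTimeSeries",
    "FluctuationStats",
    "van_vleck_chi",
    "fluctuation_stats",
    "subsample",
]


@dataclass
class PropertyTimeSeries:
    """Time-indexed µ(t) [D], α_stat(t) and α_opt(t) [Å³] snapshots at a
    source temperature, e.g. sampled along a molecular-dynamics trajectory."""

    times_ns: np.ndarray
    mu_debye_t: np.ndarray
    alpha_stat_A3_t: np.ndarray
    alpha_opt_A3_t: np.ndarray
    temperature_K: float

    def __post_init__(self) -> None:
        self.times_ns = np.asarray(self.times_ns, dtype=float)
        self.mu_debye_t = np.asarray(self.mu_debye_t, dtype=float)
        self.alpha_stat_A3_t = np.asarray(self.alpha_stat_A3_t, dtype=float)
        self.alpha_opt_A3_t = np.asarray(self.alpha_opt_A3_t, dtype=float)
        n = self.times_ns.size
        if n == 0:
            raise ValidationError("property series must be non-empty")
        for name in ("mu_debye_t", "alpha_stat_A3_t", "alpha_opt_A3_t"):
            if getattr(self, name).size != n:
                raise ValidationError(f"{name} must have the same length as times_ns")
        if n > 1 and np.any(np.diff(self.times_ns) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.mu_debye_t < 0):
            raise ValidationError("dipole magnitudes must be >= 0")
        if not self.temperature_K > 0:
            raise ValidationError("temperature must be > 0")

    def __len__(self) -> int:
        return self.times_ns.size


def van_vleck_chi(series: PropertyTimeSeries) -> float:
    """Van Vleck susceptibility in Å³: mean(α_stat) + ⟨µ²⟩_SI/(3 k_B T).

    Uses the mean of squares of the dipole magnitude — by Jensen's inequality
    a fluctuating dipole at fixed mean gives a strictly larger χ than a
    constant one.
    """
    mu2_si = float(np.mean((series.mu_debye_t * CONSTANTS.debye_SI) ** 2))
    dipole_term = mu2_si / (3.0 * CONSTANTS.k_B * series.temperature_K)
    return float(np.mean(series.alpha_stat_A3_t)) + polarizability_SI_to_A3(dipole_term)


@dataclass
class FluctuationStats:
    mean: float
    sd: float
    peak_to_peak_percent: float
    infinite_range: bool = False  # zero mean with nonzero range


def _stats(values: np.ndarray) -> FluctuationStats:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
    rng = float(np.ptp(values))
    if mean == 0.0:
        return FluctuationStats(mean, sd, math.inf if rng > 0 else 0.0,
                                infinite_range=rng > 0)
    return FluctuationStats(mean, sd, 100.0 * rng / mean)


def fluctuation_stats(series: PropertyTimeSeries) -> dict[str, FluctuationStats]:
    """Mean, standard deviation and peak-to-peak percent (100×(max−min)/mean)
    for each property."""
    return {
        "mu_debye": _stats(series.mu_debye_t),
        "alpha_stat_A3": _stats(series.alpha_stat_A3_t),
        "alpha_opt_A3": _stats(series.alpha_opt_A3_t),
    }


def subsample(series: PropertyTimeSeries, step_ns: float) -> PropertyTimeSeries:
    """Nearest-grid decimation of the series to a coarser sampling step.

    Deterministic: for each target time t₀ + k·step the nearest available
    snapshot is selected (each at most once).
    """
    t = series.times_ns
    native = float(np.min(np.diff(t))) if len(series) > 1 else 0.0
    if len(series) > 1 and step_ns < native - 1e-12:
        raise ValidationError(
            f"subsampling step {step_ns} ns is finer than the native spacing "
            f"{native} ns"
        )
    targets = np.arange(t[0], t[-1] + 1e-9, step_ns)
    idx = np.unique([int(np.argmin(np.abs(t - target))) for target in targets])
    return PropertyTimeSeries(
        times_ns=t[idx],
        mu_debye_t=series.mu_debye_t[idx],
        alpha_stat_A3_t=series.alpha_stat_A3_t[idx],
        alpha_opt_A3_t=series.alpha_opt_A3_t[idx],
        temperature_K=series.temperature_K,
    )
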